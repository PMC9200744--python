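# Methods

## The clipping problem

A solution SAXS measurement gives one ensemble-averaged curve I_exp(Q)
with per-point uncertainties σ(Q). An MD trajectory of the same molecule
gives an ordered sequence of conformations. `sasclip` extracts the
longest *contiguous* run of snapshots whose ensemble-averaged theoretical
profile reproduces the measurement. Contiguity is the point: unlike
subset-selection or reweighting approaches (EOM-style minimal ensembles,
maximum-entropy reweighting), a contiguous window is a dynamical object —
a stretch of the force field's own time evolution — so the clipped
ensemble inherits physically consistent kinetics, not just a matching
average.

## Scattering model

Per-frame intensities come from the Debye equation on the bead model,

    I(Q) = Σ_i Σ_j f_i f_j sin(Q r_ij)/(Q r_ij),

with constant (Q-independent) form factors f_i equal to element electron
counts — the standard small-angle approximation. The i = j and Q → 0
terms use the analytic sinc limit 1, so I(0) = (Σ f_i)² holds exactly.
No excluded-volume or hydration-shell corrections are applied; the
fitted scale factor absorbs overall amplitude differences between the
bead-level computation and a measured curve. Each frame's curve is
normalized by its own I(0) before windows are summed.

p(r) is the electron-weighted histogram of pair distances: every
unordered pair with both weights positive contributes f_i·f_j to the bin
containing r_ij. All electrons are treated as sitting at atom centers
and hydrogens are ignored (weight 0 under the default reader settings).
Bins are left-closed, default width 1 Å; the mass identity
Σ_bins p = ((Σf)² − Σf²)/2 pins the convention and is asserted exactly
in the tests.

## Profile fit and acceptance criteria

A window [s, e) of M = e − s frames is fitted as

    I_sim(Q_i) = c · Σ_{j=s}^{e-1} I_sim,j(Q_i) − offs,

where c (scale) and offs (buffer-mismatch offset) solve the weighted
(1/σ²) normal equations ∂χ²/∂c = ∂χ²/∂offs = 0, and

    χ² = 1/(N−1) · Σ_i ((I_exp(Q_i) − I_sim(Q_i))/σ(Q_i))².

The divisor is N−1 by definition of the statistic used here; it is not
adjusted to N−2 for the two fitted parameters. The summed (not averaged)
window profile is fitted, so c absorbs the 1/M factor; model curves are
evaluated directly on the experimental Q grid (no interpolation step
exists anywhere). c is unconstrained in sign; a negative fit is
physically unreasonable and warns.

A window passes when χ² < 3.0 (strict) and — under the improved dual
criteria, the default — every squared residual at Q < 0.25 Å⁻¹ is below
12.5 (strict, every point; equivalently the band maximum). The χ²-only
first-pass criterion is selectable (`use_residual_band=False`). The
low-Q band matters because Q between 0.1 and 0.2 Å⁻¹ probes correlation
lengths 2π/Q of 62.8 down to 31.4 Å — the inter-domain scale — so a
small χ² spread over the whole grid can still hide a wrong domain
arrangement there.

The duration of a clipped series is L_t = (number of snapshots) ×
(frame interval), default 2 ns/frame; note the count, not count − 1. The
minimum-duration rule (L_t > 700 ns) is a *reporting* filter, never part
of the search, so short matches can still be listed and studied.

## Window search

Acceptance is not monotone in window extent: a passing window can
contain failing sub-windows (the fit is to the average, and averaging
across states can match a target no single state does) and vice versa.
Two-pointer or divide-and-conquer shortcuts are therefore unsound and
the search is exhaustive over all O(n²) contiguous windows. Per-frame
normalized profiles are computed once; prefix sums over frames give any
window's summed profile in O(N_Q), and whole length-classes of windows
are fitted with vectorized batch normal equations. The longest-window
query scans lengths from longest to shortest and stops at the first
passing length; ties within a length break to the smallest start
(deterministic output). At the default desk scale (2,500 frames, 100 Q
points) a full search takes a few seconds on one core.

## Conformation descriptors and probability maps

Domain centers are unweighted means of backbone-bead coordinates over
inclusive residue ranges ("center of mass" here follows that averaged-
coordinates convention, not a mass weighting). Per frame the package
reports the hinge angles θ_a-b-b′ and θ_b-b′-a′, the inter-domain
dihedral φ_a-b-b′-a′, two orientation dihedrals using the CGHC-motif COM
as fourth point, and the open–close distance D_a-a′. Dihedrals use the
signed IUPAC convention on (−180°, 180°]; a signed convention is needed
(observed φ ranges straddle 0°) and IUPAC fixes the handedness.
Degenerate frames (collinear centers) are flagged invalid with NaN
descriptors rather than aborting a series.

(θ, θ) probability maps are plain binned counts normalized to sum 1.
The bin width is an explicit parameter (default 5°) and is part of any
reported divergence, since KL values are binning-dependent. A preset for
protein-disulfide-isomerase-family domain ranges ships in
`PDI_FAMILY_DOMAIN_PRESET` (a: 26–130, b-b′: 160–355, a′: 377–482); the
b/b′ split residue is system-specific and must be user-supplied for
four-domain analyses.

## Restricted KL divergence

The divergence between a clipped window's map P_clip and its source
trajectory's map P_orig is evaluated only on C1 ∪ C2, where C1 is the
clipped support (P_clip > 0) and C2 the bins adjacent to C1
(8-neighborhood by default, switchable to 4; the choice is a convention
and is reported). P_orig is renormalized to sum 1 over C1 ∪ C2, then

    KL = Σ_{C1∪C2} P_clip log(P_clip / P̃_orig),

with 0·log(0/x) = 0. Both distributions sum to 1 on the region, so
KL ≥ 0 (Gibbs). The restriction deliberately does *not* penalize a
window for stable states it never visits — it measures local fidelity to
the source distribution. Logarithms are natural (nats) by default and
the base is configurable and reported, since threshold values like
"≈ 0.5 or less" are base-dependent. A bin with P_clip > 0 but
P_orig = 0 raises an undefined-divergence error; it cannot occur when
the clipped frames are a subset of the source frames under identical
binning.

Across enumerated passing windows, median KL decays with window duration
L_t: long windows reproduce the source distribution, short ones do not.
One caveat the restriction itself creates: windows only a few frames
long can sit entirely inside one stable-state bin and score a *low*
restricted KL — precisely the locality the C1 ∪ C2 construction is for.
The decay is therefore asserted between duration strata (short half vs
long half), and duration and divergence are used as two separate
acceptance rules rather than collapsing them into one statistic.

## Isosbestic points, linear response, recombination

If a single conformational coordinate X modulates the intensity
approximately linearly, I(Q, X) ≈ I(Q, X₀) + (X − X₀)·∂I/∂X, then all
curves of an ensemble intersect where ∂I/∂X = 0 — isosbestic points.
Detection is operationalized as local minima of the per-Q sample
standard deviation of log₁₀ I whose spread falls below a tolerance
factor (default 0.25) times the median band spread; the log makes the
result invariant to uniform intensity rescaling. The per-Q linear
response of I on a supplied coordinate (typically D_a-a′) is an
unweighted OLS fit (frame curves carry no σ), reporting slope, intercept
at X₀ = mean(x), and R².

Recombination expresses a secondary observable as X = Σ cᵢ X_i over the
per-series averaged observables of several clipped ensembles. Weights
are constrained to the simplex (cᵢ ≥ 0, Σcᵢ = 1) by default — ensemble
population fractions must be a convex combination for the
mixture-of-dynamics interpretation — solved exactly by active-set
enumeration over supports (the series count is small); an unconstrained
least-squares mode is provided.

## Synthetic hinge system

The generator emulates a four-domain chain (a–b–b′–a′) with concerted
open–close hinge motion: rigid random bead blobs (10 beads, 8 Å radius
per domain, centered so each blob's COM sits exactly on its chain
center) strung on a 30 Å-bond chain whose internal angles follow a
two-state renewal process — closed (90° ± 4°) and open (150° ± 4°) with
geometric dwells of mean 150 frames — sampled every 2 ns for 2,500
frames. The fourth center is placed with a fixed 40° torsion so
dihedrals are non-degenerate. All randomness flows through one seed.

A target profile is the window-averaged normalized curve, scaled,
offset, and given multiplicative Gaussian noise σ(Q) = noise_fraction ·
I(Q) (reported as the uncertainty column, matching the 1/σ² fit
weights). The planted window (500 frames) visits the open state for the
first 37% of its frames and the closed state for the rest, with 60-frame
uniform-state guard runs outside it: open entering, closed leaving. Any
shift or truncation then swaps frames of opposite states and any
extension adds a fixed state, so every near-miss window changes its
open fraction — and balanced two-sided extensions cannot restore the
37/100 mixture within the guard runs. The default noise_fraction is
2 × 10⁻⁵: far below the ~14% median inter-state profile contrast, so
state-composition errors of even one frame exceed the χ² tolerance and
the planted window is the unique longest match. This emulates an
idealized, very-high-precision measurement; real reduced SAXS data carry
relative errors of order 10⁻²–10⁻³, where recovery is approximate (the
returned window over- or under-shoots the planted boundaries by frames
whose state composition the data cannot resolve). Passing the planted-
recovery tests therefore demonstrates the search machinery, not that
experimental noise levels permit frame-exact clipping. The generator
also omits intra-domain flexibility, excluded volume, hydration and any
force-field energetics — it is a stochastic geometry model, sufficient
to exercise clipping, divergence and isosbestic analyses with known
answers.

## Numerical choices and edge cases

- sinc singularities evaluated as the analytic limit 1.
- Normal-equation determinant guarded against (weighted-)constant model
  curves, which raise (single fit) or fail the window (batch search).
- Residual-band and χ² thresholds are strict inequalities; an empty
  residual band yields 0 with an explicit flag and warning.
- Frame indices are 0-based, windows half-open [start, end); residue
  ranges are inclusive at both ends.
- Probability maps clip out-of-range points into edge bins with a
  warning; zero data points raise.
- Report files are TSV + JSON twins whose floats round-trip
  bit-identically (repr serialization).
- Problem sizes in the test suite are desk-scale by design: 2,500-frame
  trajectories with 100 Q points for recovery studies, ≤ 50-frame
  systems for brute-force oracle comparisons, and a 160-frame hinge
  system for divergence trends.

## Known limitations

- Direct Debye on beads is O(n² N_Q) per frame; fine for coarse-grained
  models, slow for large all-atom systems.
- No solvent corrections means absolute curve shapes differ from
  solution-scattering predictors that model hydration; the scale/offset
  fit absorbs amplitude but not shape differences at wider angles.
- KL values depend on bin width, adjacency convention and log base; they
  are comparable only within one reported convention.
- The b/b′ domain split for four-domain descriptor analyses must be
  supplied by the user.
- Binary trajectory formats (XTC/DCD) are not read; use multi-model PDB,
  XYZ or the documented tabular format.
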