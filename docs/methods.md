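# Methods

This note describes the quantitative methods implemented in `nascentquant`
and the modelling choices behind them. Module references are to
`src/nascentquant/`.

## 1. Imaging model and synthetic data (`simulate.py`)

All analyses are exercised on synthetic 3D stacks with exact generative
ground truth; no real microscope data is required.

**Section geometry.** A section is a `(z, y, x)` stack with anisotropic
calibration (default 110 nm lateral, 1000 nm axial voxels). Nuclei are
spheres of radius ~1.5 µm placed by dart-throwing without overlap
(`placement="pack"`), or on a regular grid (`placement="grid"`) when a known
cell count and guaranteed separation matter more than realism (e.g. for
co-occurrence calibration studies).

**Burst states.** Each cell independently draws an on/off state per gene.
Marginal activity is `burst_probs[g]`; pairwise dependence is a common
lift factor `coupling`, so `P(g and h active) = coupling · p_g · p_h`, with
the triple closed by a product rule. The full joint over the 2³ states is
recovered by Möbius inversion of these moments; parameter combinations
whose implied joint has a negative cell are rejected as infeasible
(`ParameterValidityError`) rather than silently clipped. `coupling=0`
models mutual exclusion, `1` independence, `>1` co-regulation.

**Spot rendering.** An active locus is rendered as an anisotropic 3D
Gaussian (PSF-like: σ ≈ 1.2 px lateral, 0.8 slices axial) of chosen
amplitude over a constant background. Noise is Poisson shot noise plus
Gaussian read noise; sparse dim autofluorescent clutter can be added. DAPI
is rendered per nucleus so the integrated DAPI signal is proportional to
nuclear volume. Fixed inter-locus geometry is injected via
`locus_offsets`: per cell, a random 3D rotation of the given offset matrix
(in nm) is applied around the cell's locus anchor, so generative pairwise
separations are exactly the offset-matrix distances.

**Chromatic aberration.** The simulator optionally displaces each
channel's spot positions by a per-channel in-plane similarity transform
(translation, rotation, isotropic scale about the image centre) before
rendering — the same family the registration step estimates, applied at
coordinate level so truth is exact.

**Bead fields.** `render_bead_field` places fiducial beads visible in all
channels, displacing non-reference channels by their true transforms.

## 2. Spot detection (`detection.py`)

The detector follows the classical small-particle chain:

1. **Per-slice Gaussian blur** (σ = 1 px) to suppress single-pixel noise.
2. **Rolling-ball background subtraction** per slice: grey-scale opening
   with a non-flat ball structuring element. For speed, large balls run on
   a block-minimum–shrunk image, then the background is re-expanded;
   `shrink=1` forces the exact computation (used by the test oracle).
3. **Greedy max-not-mask peak finding**: repeatedly take the global
   maximum of the unmasked residual volume (first-occurrence tie-break),
   emit it as a candidate, and mask an anisotropic ellipsoid around it.
   Iteration stops at an intensity floor or candidate cap. This is
   equivalent to a brute-force greedy oracle, which the tests verify
   directly.
4. **Constrained 3D Gaussian refinement**: weighted non-linear least
   squares on a local window fits centre, amplitude, widths and offset,
   with bound constraints keeping the centre inside the window and the
   widths near the PSF prior. Fits that hit constraints, sit on the stack
   edge, or go non-finite are marked rejected with a reason, never
   silently dropped.
5. **Amplitude gate** (`min_amplitude`): candidates below the floor are
   kept in the table but flagged `accepted=False`. This plays the role of
   the supervised spot classifier used on real data — on synthetic data a
   calibrated amplitude floor separates true spots from clutter.

A labelling-based alternative (`segment_spots`: threshold, connected
components, centroids) is provided for cross-checks.

## 3. Chromatic registration (`registration.py`)

Beads are localized per channel with the same sub-pixel refinement, matched
across channels by mutual nearest neighbours, and each non-reference
channel's transform is estimated in closed form (Umeyama similarity fit:
translation + rotation + isotropic scale about the image centre).
Degenerate (collinear) bead sets fall back to translation-only with a
warning; implausible estimates (large rotation or scale far from 1) are
rejected. The correction is always applied to *spot coordinates*
(`apply_transform_to_spots`, which also refreshes the nm columns); images
are never resampled, so intensities are untouched.

## 4. Co-occurrence classification (`colocalization.py`)

Spots from different channels within `radius_nm` (default 500 nm) of each
other are grouped into records (singles, doubles, triples) by greedy
closest-first matching: candidate pairs are processed in increasing
distance order, merging groups only if every cross-channel member pair
remains within the radius (triples require mutual proximity) and no
channel is duplicated. Each spot belongs to exactly one record, and
per-channel totals are conserved across classes. The greedy result equals
the maximal valid grouping whose sorted within-record distance sequence is
lexicographically minimal; the unit tests verify this against an
exhaustive oracle on small instances. Distances are computed in-plane
(`frame="2d"`) or in 3D (`frame="3d"`).

## 5. Random-chance co-occurrence (`colocalization.expected_random_coloc`)

Whether two genes co-burst more often than chance is judged against two
nested null models given only per-channel totals and the cell count `C`:

- **Model (a), cell-level independence:** expected co-active cells
  `n_A · n_B / C` (and the analogous triple product).
- **Model (b):** model (a) multiplied by the Monte-Carlo probability that
  two spots placed independently and uniformly in the same nucleus fall
  within the co-localization radius — co-activity does not guarantee
  proximity.

A 99% predictive interval for the *observed* count under the null is built
by simulation: hypergeometric cell-overlap draws (channel occupancies
clamped to `C`) thinned binomially by the geometric probability. Observed
counts above the interval indicate co-regulation; below, exclusion.

## 6. Per-cell normalization (`quantification.py`)

Cell counts inside an ROI polygon are estimated by the DAPI-ratio method:
integrated background-subtracted DAPI inside the ROI divided by the mean
integrated DAPI of isolated reference nuclei (background taken from a
nucleus-free region). Point-in-polygon uses an even-odd rule with
boundary-inclusive handling. Section summaries combine accepted spot
counts, co-occurrence class counts and the cell count into per-cell rates;
genes not probed in a section are recorded as missing, never zero.

## 7. Inter-locus distances (`distances.py`)

Centre-to-centre 3D distances between co-localized spots (triple records
only, in triangle mode) are gated to a physical window (default 0–1000 nm),
binned, and the main mode is fitted with a 1D Gaussian; the peak's
standard error comes from a non-parametric bootstrap over pairs. Fewer
than 10 gated pairs falls back to the median. Amplitude–distance 2D
histograms support gating diagnostics. The triangle summary embeds the
three pairwise peaks as a planar triangle.

Only in-plane chromatic correction is modelled: axial chromatic shift is
not estimated (single-z bead fields cannot constrain it), matching the
in-plane similarity model throughout.

## 8. Group statistics (`groupstats.py`)

Sections are the unit of replication. Location differences use the
Wilcoxon rank-sum test (normal approximation with tie correction and
continuity correction); variance differences use the two-sided F ratio
test. `compare_groups` runs both per measurement against a reference
group, optionally Benjamini-Hochberg–adjusts the location p-values across
measurements, and annotates significance stars (`*` < 0.05, `**` < 0.01,
`***` < 0.001; the 0.05 boundary is strictly non-significant). Both tests
are verified to hold their nominal type-I error (within [0.04, 0.06] at
α = 0.05 over 10⁴ null simulations) at the sample sizes used.

## 9. Conservation invariants

Throughout the pipeline: per-channel spot totals equal the sum over
co-occurrence classes; histogram mass equals the gated pair count;
spot tables and stacks round-trip losslessly through CSV/TIFF.
These are asserted continuously in the test suite.
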