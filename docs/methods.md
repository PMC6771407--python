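# Methods

## The assay being modelled

A human artificial chromosome (HAC) is a nonessential, centromere-bearing
minichromosome that segregates alongside the natural chromosomes.  When it
carries a destabilised GFP reporter (dGFP — cell-cycle-licensed GFP fusions
degraded within hours of losing their template), a cell that mis-segregates
the HAC goes dark quickly, so the fraction of GFP− nuclei in a well is a
direct proxy for chromosome loss.  An siRNA screen then asks: which gene
knockdowns raise that fraction above the negative (non-targeting) control?

The package implements the full desk-side version of this assay: a
generative model of HAC segregation, image formation and measurement; the
image-analysis and screening statistics; the kinetic model converting
retained fractions into per-generation loss rates; and the exact
contingency statistics used to confirm candidates with micronucleus-type
endpoints.

## Segregation model

Each cell carries the HAC or not.  Per division, a HAC+ cell loses the HAC
with probability R (`loss_rate_per_division`), independently of everything
else; loss is irreversible (re-gain of an acentric fragment is not a
plausible event at these time scales and is not modelled).  HAC+ and HAC−
cells proliferate at the same rate — the HAC is nonessential — so the HAC+
*fraction* follows

    f(N) = f0 · (1 − R)^N

after N (possibly fractional) divisions, independent of population growth.
`simulate_population` offers two modes: `expectation` returns these
expected fractions exactly (used for oracle tests), and `stochastic` draws
the per-cell, per-division Bernoulli process for a seeded, reproducible
finite population.  A fractional trailing division contributes a loss
probability of 1 − (1 − R)^frac.

**Reporter lag.** The dGFP signal outlives the HAC by a few hours.  Cells
that lost the HAC within the last `reporter_lag_hours` (default 9 h) still
score GFP+; the lag is converted to generations through the doubling time
(9 h / 24 h ≈ 0.375 generations), so the expected GFP+ fraction is
f0·(1−R)^(N−lag).  With the default 96 h treatment this shifts measured
GFP-based rates by under one percentage point; control normalisation in
the kinetics module absorbs most of the remainder.

**Defaults as study conditions.** 96 h of treatment; doubling time 24 h
(a realistic figure for HT1080 fibrosarcoma cells — the package never
hard-codes it downstream, the kinetics module always takes a fitted or
supplied T_d); ~2000 analysed cells per well; negative-control layouts
with eight replicate wells per plate; a 5% background GFP− fraction
(`initial_hac_fraction = 0.95`) in plate simulations, reflecting the
background present in real negative controls that the control-normalised
rate estimate cancels.

## Image formation

Fields are rendered as 16-bit two-channel images: elliptical nuclei
(equivalent radius 14–22 px, axis-ratio jitter 0.75–1.0) on a dark
background, with per-pixel Gaussian noise (sd 10 AU).  GFP− and GFP+
nuclei draw their nuclear GFP mean from two well-separated levels (50 vs
400 AU against the screen's fixed 100 AU classification threshold); DAPI
nuclei sit at 3000 AU over a 100 AU background, giving
signal-to-background ≫ 5.  Placement is rejection sampling with a pairwise
minimum centre distance (sum of the two major radii + 2 px), largest
objects first; after a bounded number of tries a `PlacementError` is
raised rather than silently overlapping nuclei, so the ground truth stays
unambiguous.  The default field geometry is 1080×1275 px (a 2160×2550
sensor at 2×2 binning); tests use smaller fields since density, not area,
drives every measured property.

Two kinds of QC-target objects can be planted deliberately: nuclei clipped
by the field border, and strongly elongated objects (axis ratio 0.15)
whose isoperimetric roundness falls well below 0.7, standing in for the
merged/fragmented objects that nuclear segmentation produces in practice.
What the generator does **not** model: optics (PSF, illumination
gradients), texture and chromatin structure, mitotic figures, overlapping
nuclei, cytoplasm.  Passing tests therefore demonstrate the correctness of
the analysis logic under clean bimodal conditions, not robustness to
focus drift or dense clumping on real plates.

## Image analysis

The recipe follows high-content-screening practice with every step
deterministic:

1. **Segmentation** (DAPI): global Otsu threshold (or a fixed value), hole
   filling, removal of objects below `min_nucleus_area` (50 px), optional
   splitting of touching nuclei by watershed on the smoothed distance
   transform.  Watershed seeds are h-maxima of the distance map
   (`split_marker_depth` = 2 px): a maximum must rise at least 2 px above
   its saddle to count, which separates genuinely touching nuclei while
   ignoring rasterisation bumps along a single elongated object.  A blank
   image, or one whose foreground/background contrast after Otsu is below
   1.5, yields an empty mask with a logged warning — Otsu would otherwise
   happily bisect pure background noise.
2. **Features**: area, Crofton perimeter (unbiased on rasterised disks,
   unlike the chain-code perimeter, which drifts with radius), centroid,
   mean GFP under the label, roundness = 4πA/P² clipped to [0, 1], and a
   border flag (any labelled pixel within `border_margin` = 1 px of an
   edge).
3. **QC**: border-touching nuclei and nuclei with roundness strictly below
   0.7 are excluded; a nucleus at exactly 0.7 is retained.  Removal counts
   are reported per reason and logged per well.
4. **Classification**: mean GFP strictly below 100 AU ⇒ GFP−, else GFP+.
   The threshold is raw camera intensity with no normalisation, because
   the screen's threshold was held constant across plates.

## Plate screening

%GFP− per well is computed after pooling nuclei across all fields of the
well (so field order is irrelevant); wells with no QC-passing nuclei are
flagged undefined and excluded from references and tests.  Z-scores use
the plate's sample-well population as reference by default (the
"population mean" convention; negative controls as reference are a config
option) with the sample standard deviation (n−1).  Wells whose QC-passing
cell count falls below `min_count_fraction` (default 0.5 — the assay's
intent is to discard wells too dead to report, and 0.5 of the
negative-control median is a conventional choice) are flagged cytotoxic.
Genes are called hits by a two-sided Welch t-test of their replicate
wells' %GFP− against the negative-control wells at α = 0.05, gated on not
being cytotoxic.  No multiple-testing correction is applied at the
primary-screen stage — primaries go to independent-siRNA reconfirmation —
but Benjamini–Hochberg is available as an option.

## Loss-rate kinetics

All three measurement channels produce a fraction of cells retaining the
reporter: imaging (%GFP+ among QC-passing nuclei), flow cytometry (GFP+
among live events, dead cells gated out on a far-red viability dye) and
FISH (HAC-bearing metaphase spreads).  The rate model is exponential
retention with control normalisation:

    P_t = P_c · (1 − R)^N   ⇒   R = 1 − (P_t / P_c)^(1/N)

The control fraction comes from the scrambled-siRNA condition measured in
the same experiment, which absorbs background GFP− cells and most of the
reporter-lag offset.  N = duration / T_d with T_d fitted by least squares
on log2(count) vs time (≥ 3 strictly positive counts; a non-positive
slope is an error, not a zero).  The inversion is clamped to [0, 1] — a
sample retaining *more* than its control is reported as R = 0 with a
warning, making the estimator one-sided under the null (its median is 0,
its mean slightly positive; the `clamped` flag preserves the information).
The formula lives in a single function (`estimate_loss_rate`) so an
alternative rate dialect can be swapped in one place.

Confidence intervals propagate the independent binomial variances of the
two fractions by the delta method at 95%; FISH proportions additionally
get an exact Clopper–Pearson interval, which behaves at 0 or n successes.

## Exact confirmation statistics

Micronucleus (MNi), nucleoplasmic-bridge (NPB), gamma-H2AX and
abnormal-mitosis scoring reduce to 2×2 tables of cells with/without the
event, treated vs control; cells with multiple events collapse to a
binary per-cell call to match percent-of-cells reporting.  `fisher_exact`
enumerates the full hypergeometric distribution over the observed
margins; the two-sided p sums all outcomes no more probable than the
observed table (the minimum-likelihood convention used by the major
statistics packages — conventions differ, so it is stated), with a 1e-7
relative tolerance when comparing probabilities so symmetric tables count
as exact ties.  The one-sided variant is the upper tail P[X ≥ a].
Bonferroni families always take m from the number of comparisons
supplied, never from a constant (at α = 0.05 a 45-comparison family gives
the adjusted level ≈ 0.0011).  Effect sizes are fold elevations of the
event rate over the control; a zero control rate leaves the fold
undefined and the code says to report absolute rates instead.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical seeds give byte-identical images, tables and exports.
- `simulate_plate` draws per-well GFP− counts binomially with the
  per-cell loss probability — the exact marginal of the per-cell
  Bernoulli process — so whole-plate power/calibration studies stay fast;
  `simulate_population` keeps the explicit per-cell mode.
- Pixel coordinates are 0-based (row, col); label 0 is background.
- Degenerate inputs fail loudly: constant Z-score references, empty
  margins, zero control fractions, infeasible nucleus densities and
  malformed well ids (outside A1–P24) all raise typed errors.
- Gene and well counts always come from the plate map, never from
  constants.

## Problem sizes in the tests and acceptance script

Simulation studies are sized to make their statistical assertions sharp at
desk scale: 50 rendered fields (512×512, 40 nuclei + 5 planted QC targets)
for segmentation quality; 200 stochastic replicates of 2000-cell
populations for loss-rate recovery (3 SE bands); 100 simulated plates for
hit power and 200 for null calibration; all 2×2 tables with margins ≤ 12
(5370 tables) for the exact-test oracle.

## Known limitations

- The imaging model's clean bimodality means classification accuracy near
  1.0; real screens see partial-knockdown intermediate intensities.
- No spatial plate effects (edge evaporation, gradients) are simulated,
  and correspondingly no B-score/polish normalisation is implemented.
- The loss-rate CI treats the control and sample fractions as independent
  binomials; replicate-to-replicate overdispersion is not modelled.
- FISH counts are inputs; there is no spot detection on metaphase images.
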