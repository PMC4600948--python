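# Methods

## The inference problem

A population of surface-immobilized protein complexes contains a mixture of
species carrying one or two copies of a subunit of interest (monomer
fraction *M*, dimer fraction *D* = 1 − *M*). Each subunit carries a small
tag that accepts a fluorophore with labeling efficiency *L* < 1, so dye
counting underestimates subunit counting and must be corrected. Two
independent single-molecule observables constrain *M*:

* **Two-color colocalization.** Two tag variants (call them A and B) are
  co-expressed; with independent assortment a dimer is A/A, B/B or A/B at
  0.25 : 0.25 : 0.5. A first, tag-selective labeling pass puts a red dye on
  labeled A-tag subunits; a second pass puts green on labeled B-tag
  subunits. Counting only spots with red signal (which avoids mistaking
  green-only dimers for monomers), the fraction also carrying green is

      C(M, L) = −2(M − 1)L / (M(L − 2) − L + 4),

  obtained by enumerating every dye configuration of every species and
  conditioning on ≥1 red dye.

* **Photobleaching step counting.** With a single tag labeled red, a spot
  with *k* dyes bleaches to background in *k* discrete steps. The one-step
  fraction among red spots is

      B1(M, L) = (2ML − 2L − M + 2) / (ML − L − M + 2).

Both maps invert in closed form:

    M = (L(C + 2) − 4C) / (L(C + 2) − 2C)
    M = (L(B1 − 2) − 2B1 + 2) / (L(B1 − 2) − B1 + 1)

Eliminating *M* gives an *L*-independent cross-assay consistency relation,
`B1 = (3C − 2)/(C − 2)`, `B2 = −2C/(C − 2)`: the two assays can be checked
against each other without knowing the labeling efficiency. All four maps,
the consistency relation, and a Monte-Carlo oracle that simulates the same
generative model are verified against each other in the test suite
(round-trip identity to 1e−9 on a 0.01 grid; simulation within 3 binomial
standard errors of the closed forms).

**Model boundary.** The two-state model deliberately excludes complexes
with ≥3 subunits. When the observed *C* exceeds what any monomer/dimer
mixture can produce at a given *L* (that is, `L < 4C/(C + 2)`), the
inversion returns the raw out-of-range *M* with `feasible=False` rather
than clamping; `feasibility_scan` maps this region over an *L* range. The
≥3-step photobleaching class is reported separately and never folded into
*B2*. Populations with a substantial higher-order fraction are expected to
fail the scan — that failure is the diagnostic, not an error state.

## Labeling efficiency

*L* is estimated from a depletion experiment: after biotin labeling (same
chemistry and tag as the dye), streptavidin capture removes a fraction
`total_depleted` of the total tagged protein, while a fraction
`biotin_unbound` of the *biotinylated* protein escapes capture. Correcting
the raw depletion by the capture efficiency gives

    L = total_depleted / (1 − biotin_unbound).

The uncorrected depletion is kept as the lower bound and 1.0 as the upper;
every mixture inference is reported at all three (the "Low L" / default /
"High L" columns), since *L* enters the inversion nonlinearly. Defaults are
L = 0.82 with bounds [0.51, 1.00], the values produced by the depletion
arithmetic above with total depletion 0.51 and biotin escape 0.38.

## Uncertainty

Replicate structure is the imaging field. Intervals are field-resampling
bootstrap percentiles (default 1000 replicates, seeded). With the typical
~10 fields a plain percentile interval undercovers (we measured 87–90% for
a nominal 95%), so the quantile levels use the expanded-percentile t-based
small-sample correction, which restored 91–95% empirical coverage in
simulations at M = 0.8, 300 red spots/field × 10 fields. Resamples on which
an estimator fails (e.g. infeasible inversion) are dropped; >50% failures
aborts as unstable.

## Synthetic data

The generator draws exactly the generative model the equations enumerate,
so it serves both as the Monte-Carlo oracle for the closed forms and as the
source of image/trace fixtures with known truth:

* **Population** — species sizes from (M, D, optional ≥3 class), dimer tag
  classes at 0.25 : 0.25 : 0.5 (higher multimers assort binomially),
  independent Bernoulli(L) labeling per subunit. In the two-color protocol
  a labeled A-tag subunit is red and a labeled B-tag subunit is green; the
  possibility that the second-pass chemistry also labels first-pass-skipped
  A tags is *not* modeled, because the closed forms do not include it — the
  generator must match the model it oracles. In the single-color protocol
  every subunit is B-tagged and labeled subunits are red.
* **Fields** — 512×512 px, 0.27 µm/px (a 60×-objective EMCCD geometry; the
  pixel size is a package default, recorded in every manifest, since field
  area depends on it), Gaussian PSF σ = 1.2 px rendered by pixel-integrated
  erf kernels normalized so integrated spot intensity equals dye count ×
  unit intensity exactly in the noiseless limit. Spots are placed uniformly
  with a minimum separation of 4σ (overlapping-spot analysis is out of
  scope) and the density QC flags fields outside 1–4 spots/100 µm².
  Noise is Poisson shot noise plus Gaussian read noise. Default spot
  brightness puts a single dye at peak signal-to-noise ≈ 8, the bright-dye
  regime in which these assays are performed. Acquisition is simplified to
  one averaged image per channel, since colocalization uses only static
  positions.
* **Traces** — each red dye survives an independent exponential time
  (default rate 0.1 s⁻¹ at 100 ms/frame, 750 frames ≈ 7.5 mean lifetimes);
  intensity is (surviving dyes) × unit intensity + Gaussian noise, default
  SNR 4 per dye. Ground truth records dye count, observable step frames,
  and completeness. A dye that bleaches in frame 0 leaves no preceding
  level and therefore no observable step; truth counts only steps at frame
  ≥ 1. Two dyes bleaching in the same frame produce one larger step — an
  acknowledged downward-bias of step counting that the truth table makes
  explicit (distinct observed frames), not a caller defect.
* **Titration / elution** — Poisson counts around A·c/(Kd + c), and a
  two-population memoryless elution model: a productive fraction departs at
  k_specific + k_background when dNTPs allow synthesis-coupled release,
  k_background otherwise; the rest departs at k_background in both arms.
  Rates are schematic defaults (≈half of productive complexes eluting
  specifically by 30 min); only the fractions, not the rates, are analyzed.

What the simulator does *not* emulate: blinking and dye dark states
(a blinking toggle exists only for robustness tests), Cy3/Cy5 FRET,
optical aberrations, stage drift, field inhomogeneity, and EM-gain
stochastics beyond Poisson-Gaussian. Passing tests therefore demonstrate
correctness of the analysis under the stated generative model, not
robustness to every artifact of real movies.

## Numerical and algorithmic choices

* **Spot detection** — matched filter (Gaussian smoothing at the PSF
  scale), threshold median + k·MAD of the filtered image. k = 8 was
  calibrated on blank noise fields: at k = 5 a 512×512 blank yields ~5
  false maxima; k = 8 gives 0 detections on ≥99/100 blanks while spots at
  SNR ≥ 5 are still ~13 filtered-noise sigmas above threshold (measured
  recall ≥ 0.99, RMS localization error ≈ 0.16 px via least-squares
  Gaussian refinement on a 9×9 window; duplicates within 2σ merged keeping
  the brighter).
* **Registration** — translation only (the two channels share one camera
  chip through an image splitter): histogram mode of pairwise coordinate
  differences, refined by the mean residual of matched pairs. No
  affine/polynomial mapping.
* **Pairing** — one-to-one greedy nearest-neighbor within a 2 px radius
  (≈1.7× PSF σ); ties broken by distance. At 1–4 spots/100 µm² the global
  assignment problem degenerates to this, and the chance-colocalization
  baseline 1 − exp(−ρπr²) is exposed for reporting alongside C.
* **Step calling** — recursive binary segmentation on the squared-error
  cost with penalty 2.5·σ²·ln(n), noise σ estimated robustly from first
  differences (MAD/√2). The penalty multiplier was calibrated on synthetic
  single-dye traces at SNR 4 to keep false extra steps below 2% (measured
  0%); 2.5 also resolves inter-bleach segments down to ~2 frames, the
  dominant error mode at realistic bleach rates. Candidate segments are
  merged when their level difference is under 2σ; upward transitions
  (blinking recovery) never increment the count; traces whose final level
  sits more than 3σ from background are flagged `incomplete_bleach` and
  excluded from step-class fractions (exclusions are counted and reported,
  since whether to drop them is a genuine judgment call).
* **Kd fit** — one-site isotherm A·c/(Kd + c) by weighted least squares on
  per-concentration means with per-field SEM weights; no cooperativity or
  ligand-depletion term, concentrations treated as free ligand.
  Normalization to the 30 nM anchor is a reporting convention; the fitted
  Kd is invariant to it. Non-saturating titrations (fitted Kd > 3× the top
  concentration, or SE(Kd) > Kd, or flat counts) are flagged rather than
  reported as affinities. The 30→100 nM saturation check compares the
  observed fold-increase with the one-site prediction and flags a >2×
  excess as a low-affinity secondary binding population.
* **Specific elution** — per matched timepoint,
  `f_buffer(t) − f_dNTP(t)` after within-condition normalization to t = 0;
  scale-invariant by construction. No rate fitting: the downstream claims
  concern fractions at fixed timepoints, not kinetics.

## Reported precision

Monomer fractions are reported to the nearest integer percent (the
precision at which such values are conventionally quoted); the feasibility
scan's default discrepancy tolerance is 0.05 absolute in M, the order of
typical per-assay replicate scatter, and is configurable.

## Problem sizes

The test suite and the acceptance script run at sizes chosen to make
binomial/Poisson sampling error small relative to the tolerances they
check: 10⁵–10⁶ complexes for Monte-Carlo versus closed-form comparisons,
six rendered fields (~380 complexes each) plus ~1200 traces for end-to-end
recovery of M within ±0.04, 100 seeded titrations for Kd-recovery
statistics, and 2×10⁴ spots for elution nulls.

## Known limitations

* The two-observable design cannot invert mixtures with ≥3-mers (three
  unknowns, two observables); such populations are only *detected*, via
  infeasibility and the ≥3-step class.
* Labeling efficiency is treated as known (with bounds), not as a
  parameter with a posterior; no joint (M, L) inference.
* Step counting's simultaneous-bleach bias biases B1 upward slightly at
  high dye counts; negligible for the 1–2 dye regime the model targets.
* The Kd fit's standard errors are asymptotic (from the weighted
  least-squares covariance), not bootstrap; comparisons with independently
  reported ± values are approximate since the weighting scheme behind such
  values is rarely stated.
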