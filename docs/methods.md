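# Methods

## Measurement model

A metabolite with n backbone (labelable) carbons, measured as its Fmoc
derivative, produces an isotopologue area vector m over mass shifts 0..n.
The model is linear: `m ∝ A x`, where x is the molar distribution of tracer
13C counts and A is the (n+1)x(n+1) correction matrix. Column i of A is the
probability distribution of *observed* shifts for a molecule carrying i
tracer atoms, built from three independent sources:

- natural 13C in the n−i unlabeled backbone carbons — Binomial(n−i, a13)
  with a13 = 0.0107;
- natural heavy isotopes of every tag atom: the 15 Fmoc carbons per tag,
  plus (when multi-element correction is enabled) H/N/O/S over the whole
  derivatized formula, each element's single-atom shift pmf convolved to
  its atom count;
- optionally, tracer impurity: each labeled position reverts to 12C with
  probability 1−p (Binomial downshift). Default p = 1 (no purity
  correction); p = 0.97 matches the tracer's stated ≥97 atom % 13C. With
  purity off the matrix is lower-triangular with strictly positive
  diagonal, so the system is always solvable.

All isotope masses and abundances come from one embedded IUPAC table, so
results are bit-stable across platforms. The default correction is
**carbon-only** (backbone + tag carbons): at orbitrap resolutions of
60k–70k the 15N/2H isotopologues of these 300–900 Da ions are only
partially resolved from 13C, and carbon-only correction matches how the
dominant signal is usually processed; full-element correction is one flag
away.

Stripping solves `min ||A x − m||², x ≥ 0` with NNLS and normalizes x to
molar fractions. NNLS rather than triangular back-substitution with
clipping keeps fractions physical under noise; on noise-free data the two
coincide (tested). Reported metrics: per-isotopologue molar fractions f_i
(the "% of the total carbon pool" scale), `sigma13C = Σ_{i≥1} f_i`, the
atom-level enrichment `Σ i·f_i / n` (computed but clearly separate), and
the relative fit residual `||Ax − m|| / ||m||`.

## Route deconvolution

Spermidine (7C) = 4C backbone + 3C aminopropyl unit donated by
decarboxylated SAM. Route kernels are discrete convolutions of backbone
and unit label distributions; both candidate routes share the unit. The
aminopropyl unit defaults to unlabeled (a point mass at shift 0): the
dominant SAM/MTA isotopologues are 13C5 species carrying the label on
ribose, so essentially no label reaches the aminopropyl moiety; a custom
unit distribution can be supplied. The agmatine backbone (5C) is
marginalized to 4C for the ureohydrolase step that removes the guanidino
carbon; the default treats label positions as exchangeable (hypergeometric
thinning), with an "as-is" cap-at-4 alternative for when the removed carbon
is known to be unlabeled.

Weights solve `min ||K w − f||²` subject to w ≥ 0, Σw = 1. Because route
counts are small (2–6), the solver enumerates the active faces of the
simplex and solves the equality-constrained KKT system on each — exact,
deterministic, and free of penalty parameters or iteration-order ties.
Near-collinear kernels (smallest/largest singular value < 1e-6) are flagged
non-identifiable and uniform weights are returned with a warning. Route
weights are exploratory estimates: with realistic enrichments both
backbones are ~97% unlabeled, so the kernels are nearly parallel and weight
estimates amplify measurement noise (~±0.03 s.d. per study at 2% area CV)
even though noise-free recovery is exact.

## Statistics and quantitation

Two-group comparisons default to Welch's unequal-variance t (a classic
pooled-variance flag exists); when both groups have ≤ 8 observations the
Mann-Whitney test uses full enumeration of all C(n_a+n_b, n_a) group
assignments over pooled midranks — exact even with ties, including
fully-identical groups (p = 1) — and the tie-corrected normal approximation
otherwise. No multiplicity correction is applied by default; a
Benjamini-Hochberg helper is provided. Calibration minimizes
`Σ (1/x_i²)(y_i − a − b·x_i)²` (statsmodels WLS), the right weighting when
area CV is constant across the calibration range; back-calculation inverts
the fitted line.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the study design: two arms (tracer vs 12C control,
the control truth being fully unlabeled), n = 3 subjects per arm, cell and
medium compartments. Per sample x metabolite it forward-convolves the true
isotopologue distribution with the same correction matrices used for
stripping, scales by a lognormal total pool area (log10 mean 7.0, sd 0.3 —
mid-range orbitrap areas), applies multiplicative lognormal noise (default
CV 5%) per isotopologue and a small additive baseline (uniform 0–100 area
units), clipping at zero. Presets encode the observed labeling profiles —
`human` (SPD Σ13C 42.8% dominated by 13C2; PUT 2.8% dominated by 13C4;
agmatine 13C2 higher in medium than cells), `mouse` (higher 13C3/13C5 SPD),
and `bacteroides` (single strain, 13C2-SPD ~3.9%) — with minor
isotopologues filled so the summed enrichments match the profile totals.
Inter-subject variance is a placeholder (only mean ± SEM is observable in
the emulated design) and is deliberately folded into the area CV. A planted
`RouteSpec` replaces a product's truth with a kernel mixture built from the
scenario's own precursor truths.

Passing recovery tests therefore demonstrates correctness of the
correction/stripping algebra and estimator behavior under this noise
model; they do not certify performance against chromatographic co-elution,
ion suppression, integration errors, or real inter-subject microbiome
variation, none of which the generator simulates.

Two estimator properties worth knowing, both measured in the test suite:

- NNLS under multiplicative noise slightly redistributes mass into
  near-zero fractions adjacent to large natural-abundance channels
  (heavy-tag species have very large M+1/M+2 natural signal). At 5% CV
  this biases small fractions by up to ~1 percentage point (e.g. a 3.9%
  13C2-SPD pool recovers near 3.2%) and inflates sigma13C of
  weakly-labeled species by well under a point — inside the ±2 point
  tolerance used throughout, and vanishing as noise → 0.
- Control-arm recovery (f0 ≈ 1) is exact without noise; at 5% CV the mean
  stripped control f0 is ~0.987 and single samples can dip lower, which is
  inherent to the information content of the measurement, not to the
  solver.

## mzML I/O

The XIC front end reads centroided mzML (MS1 subset: scan times in minutes
or seconds, polarity, 32/64-bit plain or zlib arrays) with a minimal
authored reader, and the fixture writer emits timestamp-free centroided
mzML; the pair is cross-validated against Bioconductor's mzR in the test
suite. Extraction sums centroid intensity within ±5 ppm (default; typical
for 60k–70k orbitrap data) of each isotopologue m/z per scan and
trapezoid-integrates over retention time — no smoothing, baseline
subtraction, or peak picking, so areas are deterministic and linear in
intensity. Peak tables remain the canonical input; XIC extraction is a
convenience.

## Problem sizes and numerical choices

Test and acceptance runs use 200 replicate studies for recovery rates,
10^4 replicates for type-I-error calibration, and 100 random distributions
per species for round-trip identities — sizes at which every Monte-Carlo
margin in the suite is stable to re-seeding. Ties in the simplex solver
cannot occur (exact face enumeration keeps the first strictly-better
solution); degenerate inputs (all-zero areas, constant vectors, zero
variance in both groups) raise or warn explicitly rather than propagating
NaNs. Randomness always flows from a single named generator seed; no
global state is used.

## Known limitations

- No resolution-aware partial-overlap correction (ultrahigh-resolution
  mode) and no 15N or dual-tracer designs.
- Only [M+H]+ (and generally z = 1) adducts; other adducts are an
  extension point on `DerivatizedSpecies`.
- The route model abstracts cross-feeding between community members as a
  single mixture; it is not a flux model and fits no time courses.
- Which derivative of a metabolite dominates is empirical and encoded in
  the registry, not predicted.
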