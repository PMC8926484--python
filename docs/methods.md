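# Methods

## Scope and data model

The package evaluates batches of a herbal extract from integrated HPLC peak
tables. Nothing upstream of integration is modelled: no baseline
correction, retention-time warping, co-elution or detector saturation.
Inputs are plain-text tables — per-injection peak lists (`peak_id`, `rt` in
minutes, `area` in detector units), marker definitions (name, reference
concentration in mg/ml, common-peak index, linear range in µg, optional
expected rt), and batch × common-peak fingerprint matrices.

## Peak matching

Neither marker assignment nor common-peak identification has a canonical
rule at the peak-table level, so both use the same convention: absolute
retention-time tolerance, default 0.2 min, configurable. Common peaks are
found by single-linkage clustering of the pooled retention times with the
tolerance as cut height (in one dimension this is exactly: sort and split
at gaps larger than the tolerance). A cluster is a common peak iff every
injection contributes exactly one peak within the tolerance of the cluster
mean; a cluster with two peaks of one injection raises an ambiguity error
rather than silently dropping or averaging. Consequences worth knowing:
`n_common` never exceeds the smallest table, matching is invariant to the
order of the tables, and drifting peaks that straddle the tolerance are
lost from the common set rather than mis-joined.

## Calibration

Detector response per marker is a power law over the linear range, fitted
as ordinary least squares of `ln(area)` on `ln(mass)` (natural logs; R² is
the squared Pearson correlation of the transformed points). The fit is on
the points as given — replicate means are not formed internally.
Prediction outside the fitted mass range warns but does not fail, because
single-volume injections routinely sit at the range edges. Inversion
(`mass = exp((ln A − b)/a)`) is exact, so predict∘invert round-trips to
machine precision.

## QAMS and ESM

The relative correction factor `f_ks = (W_k·A_s)/(W_s·A_k)` is computed per
reference injection and summarised over injection volumes (and, for
durability studies, instruments/columns) as mean and sample RSD. The
external-standard content (ESM) is deliberately single-point: the sample
and the mixed reference are injected at the same volume, so
`content% = 100·(A_sample/A_ref)·(m_ref/m_sample)`; curve-inverse ESM is
available through `calibration.invert_area` for users who prefer it. The
QAMS content uses the IRS amount measured in the sample injection and the
summarised factor. An algebraic point the tests exploit: when `f` is
computed from the same reference injection used for ESM, the IRS sample
area cancels and QAMS equals ESM *exactly* on noise-free data, independent
of the response slopes; under multiplicative noise of CV c the relative
discrepancy is O(c).

The default sample load is 40 µg per injection (20 mg extract in 10 ml,
20 µl injected), overridable. All RSDs use the n−1 standard deviation; the
published validation tables reproduce only under this convention.

The ESM-vs-QAMS comparison is a paired two-sided t-test per marker across
batches, with "no significant difference" declared at α = 0.05. A
zero-variance difference vector makes t undefined, so it is reported as
degenerate: p = 1 for an exactly zero shift, p = 0 with the shift recorded
for a constant non-zero offset.

## SQFM

Fingerprint evaluation uses three parameters of a sample profile x against
the reference profile y (the column-mean of the batch matrix — the
"average value" reference fingerprint):

* `S_m = ½·[ Σxy/√(Σx²·Σy²) + Σ(x/y)/√(n·Σ(x/y)²) ]`. Both terms are ≤ 1 by
  Cauchy–Schwarz with equality iff x ∝ y, so S_m ∈ (0, 1] and is scale
  invariant in x.
* `C = 100·Σxy/Σy²` and `P = 100·(Σx/Σy)·cos(x, y)`; `P_m = (C+P)/2` scales
  linearly with x and measures overall constituent content against the
  reference.
* `α = |1 − P/C|`, scale invariant, zero whenever P = C (in particular for
  every proportional profile).

The second S_m term and the α formula are stated here as this package's
reading of the method; both are validated in the tests against the full
published grade column and the reference-profile self-row.

Grading: each parameter receives the best (lowest) grade whose criterion it
satisfies — S_m against descending floors (≥, inclusive), P_m against
nested percentage intervals (inclusive endpoints), α against ascending
ceilings (≤, inclusive) — and the overall grade is the maximum of the
three, with labels Best, Better, Good, Fine, Moderate, Common, Defective,
Inferior for grades 1–8. Grade 8 is a catch-all, so grading never fails.
The worst-of-three rule is the only aggregation consistent with all
published batch grades, which is exactly what the acceptance suite checks.
The grading table is data (overridable via YAML), not code.

Zero or missing common-peak areas are rejected rather than zero-filled:
the ratio term x/y requires positivity and no defensible zero convention
exists for it.

## Hierarchical cluster analysis

Batches are clustered on their common-peak areas or on the scalar P_m.
Defaults are squared Euclidean distance with between-groups (average)
linkage — the defaults of the statistical package named by the original
workflow — with plain Euclidean, complete and Ward available (Ward only
with Euclidean). No variable standardisation by default; peak areas share
units. Cluster membership at a chosen cut k is the contract, not merge
heights; assignments are renumbered by first appearance so they are stable
under internal relabeling and row permutation. The implementation is
scipy's agglomerative clustering; the test suite holds it to an
independent brute-force agglomerative loop on small matrices.

## Synthetic data generator

The generator emulates the assay that motivates the package:

* **Markers**: four saponins (D, A, F, B9) at reference concentrations
  0.614 / 0.242 / 0.496 / 0.385 mg/ml, occupying common peaks 5, 8, 9, 10
  of an 11-peak fingerprint, with the published log-log response
  parameters as ground truth.
* **Reference series**: injections at 3, 5, 10, 15, 20, 25, 30 µl; area =
  `exp(intercept)·mass^slope·(1 + ε)` with ε ~ N(0, noise_cv²).
* **Noise**: multiplicative Gaussian on areas, CV-parameterised, default
  0.5% (the observed precision band; repeatability-like runs use 1.5–2%).
  Chromatographic area noise is proportional, hence multiplicative.
* **Fingerprints**: batch row = base profile × batch scale × per-peak
  shape noise. Default five batches with scales (0.95, 0.55, 1.05, 1.20,
  1.05) and 5% shape noise — one markedly under-dosed batch and moderate
  profile variability, mirroring the quality spread of the motivating
  five-batch study. With shape noise off, profiles are proportional, so
  S_m = 1, α = 0, and each batch's C equals `100·scale_b/mean(scales)` in
  closed form (the reference profile is the scale-mean of the base); the
  ground-truth record carries these expectations.

One integer seed fixes every draw; distinct generator functions use
distinct fixed stream salts so regenerating one input does not perturb
another. What the generator does **not** emulate — retention-time drift,
co-elution, saturation, real between-batch chemistry — bounds what passing
tests show: they validate the arithmetic and statistics of the pipeline,
not its robustness to raw-chromatogram pathologies.

## Numerical and design notes

* Sample RSD (n−1) throughout; RSD is scale invariant and zero for
  constant replicates.
* S_m is clipped to 1 before grading to absorb float round-off in the
  proportional case.
* Merge heights under average linkage are non-decreasing (reducibility),
  which the tests assert; ties in distances are resolved by scipy's
  ordering and are irrelevant to the membership contract.
* The pipeline runner is a pure function of (config, input files, seed);
  reruns are byte-identical, and a YAML sidecar records version, seed and
  config hash.
* Simulation-based tests use fixed seeds and modest ensemble sizes
  (500 runs for the RSD band, 1000 for the t-test null rate, 30-seed
  ensembles for the degradation monotonicity), sized to keep the suite in
  seconds while leaving binomial slack around the asserted rates.

## Known limitations

* Real batch contents and the real five-batch fingerprint areas are not
  reproducible here because the underlying per-batch peak areas were never
  published; the quantification engine is instead verified on printed
  replicate tables, derived arithmetic and synthetic inverse checks.
* Single-point ESM assumes same-volume sample/reference injections; with
  response slopes away from 1, contents at masses far from the reference
  mass inherit the power-law bias of single-point calibration (QAMS and
  ESM inherit it identically, which is why their comparison stays valid).
* The rt-tolerance matcher has no model of systematic drift; heavily
  drifting series should be aligned upstream.
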