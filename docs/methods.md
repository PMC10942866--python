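# Methods

## Data model

The pipeline operates on a proteins × samples matrix of non-negative
label-free MS intensities. Intensity 0 encodes "not detected"; detection is
strictly `intensity > 0`, and all set-level analyses run on this binarized
matrix. Samples are keyed by patient, fraction (U = ultracentrifugation EVs,
S = size-exclusion EV fraction, B = size-exclusion bulk-protein fraction) and
cohort (disease vs control; controls are U-only). Protein identity is the
harmonized, uppercase gene symbol: multi-gene protein groups resolve to the
first listed symbol, outdated symbols are mapped through a frozen offline
alias snapshot, and rows collapsing to one symbol merge with per-sample
*maximum* intensity — the maximum (rather than sum or mean) preserves the
detected/not-detected semantics that all downstream set algebra relies on.
Contaminant removal drops rows flagged as decoy (Reverse),
only-identified-by-site, or contaminant, plus any FASTA header containing
"keratin"/"Keratin"; the filter is idempotent and acts only on rows.

## Set filtering

Per patient, the EV set is `(U ∩ S) \ B`: seen by both orthogonal isolation
methods, absent from the patient's own bulk-protein background. Core lists
pool these sets: `S&U-100` = genes in all n patients; the thresholded list
uses `≥ ⌈f·n⌉` with f = 0.8 by default, so the 11-patient design reproduces
the ≥ 9-of-11 rule; an explicit integer threshold can override the ceiling.
The stringent disease-specific list subtracts from the thresholded core every
gene detected in *any* control sample (any fraction supplied); subtracting
from `S&U-100` instead is available via `base="su100"`. The augmented list
starts from U-minus-B frequency ≥ the same threshold, then requires (i) the
gene in ≥ 1 S sample of *any* disease patient — the within-patient
alternative is stricter and is not the default, a choice recorded in the
output metadata — and (ii) zero control detections. The composed
disease-specific result is the union of stringent and augmented lists;
stringent genes satisfy the augmented criteria by construction. UpSet counts
enumerate only observed membership patterns (capped at 20 patients to guard
the 2^n blow-up); the pattern counts always sum to the union size.

## Cell-type attribution

Marker panels come from scRNA-seq cluster signatures as ranked
differential-expression lists. Cropping retains the top k = 28 markers per
cell type; because a gene may not belong to two types, a marker already
claimed by an earlier-listed type is skipped and the scan continues down the
ranking until k unique markers are collected (an error names any type that
cannot reach k). The relative contribution of type c in patient p is
`100 · mean_c(p) / Σ_c' mean_c'(p)` over the chosen fraction's sample.
Two deliberate readings are configurable:

* **Denominator** — default `type_mean_sum` (sum of per-type means), which
  makes contributions sum to exactly 100 per patient and matches
  stacked-to-100% presentations; `total_intensity` (sum of all marker
  intensities) is the strict-literal alternative.
* **Undetected markers** — default contribute 0 to the mean, keeping k
  constant across patients; `detected_only` averages only detected markers.

Patients with an all-zero denominator are emitted with NaN contributions and
flagged rather than dropped. Contributions are invariant to rescaling a
patient's sample and to marker order; on noiseless, dropout-free synthetic
mixtures they recover the planted weights to 1e-9 (verified in the suite).

Small/large-EV classification against an external reference table uses
p < 0.05 with fold change (small/large) > 1.5 or < −1.5; genes present in
the reference but failing both are "nonsignificant", genes absent are
"not_detected".

## Concordance statistics

* **Enrichment coefficient**: EC = %EV / %cells per patient and cell type,
  both percentage vectors restricted to the malignant/fibroblast/macrophage
  triple and renormalized to 100 (mirroring the removal of peripheral-blood
  populations from FC data). ECs with a zero cell percentage are undefined
  and excluded, with a logged count, from per-type means and the ANOVA.
* **Repeated-measures correlation**: the common within-subject association,
  estimated by least squares on y = subject intercepts + βx;
  r_rm = sign(β)·√(SS_x / (SS_x + SS_err)) with df = N − n_subjects − 1 and a
  two-sided t test. Data in which x is constant within every subject are
  degenerate and returned flagged with NaN r. The implementation is checked
  against both the explicit normal-equations decomposition and an
  independent library implementation.
* **Log-intensity Pearson** between fractions uses natural logs (r is
  base-invariant) over pairs quantified in both fractions; zeros have no
  logarithm and are excluded by default, with a pseudocount mode (+c) for
  sensitivity analysis. Fewer than 3 qualifying pairs is an error.
* **Repeated-measures ANOVA** (one within factor): the classical
  decomposition SS_conditions / SS_subjects / SS_error with
  df = (k−1), (k−1)(n−1); incomplete subjects are dropped and logged. With
  k = 2 the F statistic equals the squared paired-t statistic (asserted to
  1e-9 in the suite). p-values are two-sided throughout.

## Survival scan

Features are either marker intensities in fraction U (UC detects rarer
EV proteins, so selection requires detection by UC; panel markers must also
be seen in ≥ 1 S sample, and the four panel-external disease-specific
proteins MRC1, IDH2, FAS and ITGB8 are appended, deduplicated) or FC cell
proportions. Candidate cutoffs are midpoints between consecutive distinct
values — midpoints avoid the boundary ambiguity of splitting *at* an
observed value — subject to (i) cutoff > 100,000 for intensity features
(no floor for proportions, which live on a different scale) and (ii) ≥ 3
patients on each side, with "high" defined as value strictly greater than
the cutoff. Each admissible split is scored by the standard two-group
log-rank statistic (pooled risk sets handle ties; p from χ² with 1 df); the
minimal-p cutoff wins, ties broken toward the smallest cutoff for
reproducibility. The hazard ratio at the chosen split comes from a
univariate Cox partial-likelihood fit with Efron tie handling,
Newton-Raphson to |Δβ| < 1e-8 (≤ 50 iterations); when all events fall in
one group the likelihood is monotone and the fit reports HR → ∞ or 0 with a
flag instead of iterating. A feature with no admissible cutoff returns a
flagged empty result, not an error.

Minimal-p cutoff selection is optimistic and the scan says so: every result
carries the label "exploratory; cutoff-optimized p-values are not
type-I-calibrated", and an optional permutation adjustment re-runs the full
scan on survival data permuted across patients (seeded), reporting
p_perm = (1 + #{permuted min-p ≤ observed}) / (B + 1).

## Synthetic data

The generator emulates the study conditions: 11 patients with U/S/B
fractions, 5 U-only controls, and a proteome of planted strata —

* 101 **core** proteins present in U and S and absent from B in every
  patient (comprising the 41 panel markers detected by both methods, the 4
  panel-external disease-specific proteins, and 56 filler genes);
* 291 **partial-core** proteins meeting the S&U\B criterion in 9–10 of 11
  patients (so the thresholded core list totals 392);
* 8 **stringent** disease-specific proteins (the core genes absent from all
  controls; every other core/partial gene appears in ≥ 1 control);
* 149 **augmented-only** proteins: U-minus-B in all patients but S-detected
  in only 2 (below the core threshold) and control-free;
* a 3 × 28 marker panel (+2 spare ranks per type to exercise cropping) whose
  U/S intensities scale multiplicatively with per-patient Dirichlet(1.5)
  mixing weights;
* 600 background, 80 bulk-enriched and 20 contaminant/decoy proteins.

Intensities are log-normal: log intensity = μ + σ_gene·z_gene + σ·z_cell
with μ = 16, σ_gene = 1.25, σ = 0.8 (natural-log scale, giving label-free
magnitudes ~10⁷ and an expected between-fraction log-Pearson of
σ_gene²/(σ_gene²+σ²) ≈ 0.71, in the range observed for paired EV isolations).
Detection dropout (Bernoulli per cell; detection probabilities 0.9 / 0.6 /
0.85 for U / S / B) applies to the background and bulk strata, reproducing
the markedly lower proteome coverage of S fractions. The planted signature
strata are modelled as high-abundance proteins above the detection limit, so
their defining patterns hold by construction; setting the probabilities to 1
(`config.without_dropout()`) makes the *entire* matrix noiseless in the
detection sense, under which the pipeline provably recovers every planted
set exactly — the property the test suite asserts. Dropout zeroes
intensities after generation, so binarization semantics match the real
pipeline.

Flow-cytometry proportions are the mixing weights of the first 10 patients
under multiplicative log-normal noise (σ = 0.3), renormalized. A 390-entry
MISEV-style table overlaps the core lists in 18 and 50 genes and the wider
detected proteome in 172. Survival is exponential (baseline hazard
0.0173/month, median ≈ 40 months) with the hazard multiplied by HR = 3 for
patients whose planted marker (MRC1 by default) exceeds its cohort median
intensity; censoring is independent exponential (0.008/month) truncated at
120 months of follow-up. One seed feeds per-stage child streams, so, e.g.,
survival times do not change when the protein complement does.

What the generator does **not** model: peptide-level quantification,
intensity-dependent (non-Bernoulli) missingness, correlated contaminant
structure, batch effects, or any relation between marker intensity and
survival beyond the single planted dichotomy. Passing tests therefore
demonstrate correctness of the algebra and the estimators under the stated
generative model, not robustness to real-data artefacts.

## Problem sizes and numerical choices

The default dataset is ~1,300 proteins × 38 samples and every stage runs in
seconds; oracle-equivalence tests use ≥ 100 randomized instances at ≤ 12
patients / ≤ 300 proteins, the permutation null uses 10,000 draws, and
parameter-recovery simulations use cohorts of n = 200–500 — sizes chosen so
each check has clear statistical resolution while the whole suite stays
interactive. Percentages are reported to two decimals (rounding half-up);
set operations are exact integer computations. Harmonization and reading are
tested for value-identical round-trips (%.17g formatting on write, correctly
rounding parse on read).

## Known limitations

* The nomenclature alias snapshot is deliberately small; unmapped outdated
  symbols pass through unchanged.
* The cutoff-scan p-values mirror the exploratory minimal-p procedure; only
  the optional permutation adjustment is calibrated.
* The augmented pipeline's "any patient" reading of the S-confirmation
  criterion, the su80 base for the stringent subtraction, the
  strictly-greater dichotomization and the smallest-cutoff tie-break are
  documented defaults where reasonable alternatives exist; all are exposed
  as configuration.
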