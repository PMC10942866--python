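# evascites

Analysis of extracellular-vesicle (EV) proteomes from the ascites of
high-grade serous ovarian carcinoma (HGSC) patients.

Ascites — the peritoneal fluid that accumulates in most HGSC patients — is a
liquid window on the tumour microenvironment: it carries malignant cells,
immune and stromal cells, soluble proteins and EVs secreted by all of them.
Label-free tandem-MS proteomes of EVs isolated by two orthogonal methods
(differential ultracentrifugation with sucrose-cushion flotation, fraction
**U**, and size-exclusion chromatography, EV-rich fraction **S**), together
with the bulk-protein SEC fraction **B** as a per-patient contaminant
background, let one ask four questions this package answers:

1. **Which proteins are genuinely EV-associated?** Per patient, the set
   `S&U \ B` = detected by both isolation methods and absent from the bulk
   background. Pooled across the cohort this yields the *core* lists:
   `S&U-100` (in all n patients) and `S&U-80` (in ≥ ⌈0.8 n⌉ patients, i.e.
   ≥ 9 of 11), with UpSet intersection counts and overlap against a
   MISEV2018-style EV-marker category table.
2. **Which of those are disease-specific?** Subtracting every protein seen in
   any control (non-malignant fluid) EV isolate gives the *stringent* list; a
   looser *augmented* pipeline starts from U-minus-B frequency, requires
   confirmation by the orthogonal method (any S sample) and absence from all
   controls.
3. **Which cells produced the EVs?** With a scRNA-seq-derived marker panel
   (top k = 28 differentially expressed genes per cell type), the relative
   contribution of cell type c in patient p is
   `100 · mean_c(p) / Σ_c' mean_c'(p)` where `mean_c(p)` is the mean marker
   intensity. Agreement between isolation methods and against flow-cytometry
   (FC) cell proportions is quantified by the repeated-measures correlation
   r_rm (ANCOVA with subject intercepts, df = N − k − 1), Pearson's r on log
   intensities, enrichment coefficients EC = %EV / %cells, and one-way
   repeated-measures ANOVA.
4. **Do EV markers predict survival?** For each cell-type-specific marker
   (panel markers detected by both methods, plus four disease-specific
   proteins: MRC1, IDH2, FAS, ITGB8), every admissible dichotomizing cutoff
   (midpoints above an intensity floor of 100,000 keeping ≥ 3 patients per
   arm) is scored by the two-group log-rank test; the minimal-p cutoff is
   reported with the univariate Cox hazard ratio (Efron ties). Because
   minimal-p selection is optimistic, outputs are labelled exploratory and a
   permutation-adjusted p is available.

A fully seeded synthetic-data generator (`evascites.simulate`) emulates the
cohort structure — 11 patients × 3 fractions plus 5 control samples, planted
core/specific sets, weight-scaled marker intensities, FC proportions and
censored exponential survival — with the planted truth returned alongside,
so every stage is testable against known ground truth.

## Worked example

```bash
evascites simulate --seed 1 --out data/
cat > run.yaml <<'YAML'
inputs:
  protein_groups: data/protein_groups.tsv
  sample_map: data/sample_map.csv
  marker_panel: data/marker_panel.tsv
  fc_proportions: data/fc_proportions.csv
  clinical: data/clinical.csv
  misev: data/misev.tsv
YAML
evascites run-all --config run.yaml --out out/
```

prints the headline numbers of the run (also stored in `out/report.json`):

```
"n_proteins_raw": 1290,
"n_proteins_filtered": 1270,
"su100": 101,
"su80": 392,
"stringent": 8,
"augmented": 157,
"misev_su100": 18,
"misev_su100_pct": 17.82,
"misev_su80": 50,
"rmcorr_u_vs_s_r": 0.928,
"pearson_log_r": 0.725,
"n_survival_markers": 45,
"best_intensity_p": 0.0009
```

Reading: 20 contaminant/decoy rows were removed; 101 proteins are core in
all 11 patients and 392 in ≥ 9; of the core lists, 8 proteins are unique to
the disease cohort and the augmented pipeline brings the disease-specific
list to 157. Eighteen of the 101 (17.82%) appear in the EV-marker reference
table. Cell-type contributions estimated from the two isolation methods
agree strongly (r_rm = 0.93 across 11 patients × 3 cell types), log
intensities correlate at r = 0.72 between methods, and 45 cell-type-specific
markers qualify for the survival scan, whose best (cutoff-optimized,
exploratory) log-rank p is 9 × 10⁻⁴.

The same stages are available programmatically, statsmodels-style:

```python
from evascites import SurvivalCutoffScan, CellTypeDeconvolution
result = CellTypeDeconvolution(matrix, panel, fraction="U").fit()
scan = SurvivalCutoffScan(features, clinical, floor=1e5).fit(permutations=1000, seed=17)
print(scan.summary())
```

## Layout

```
src/evascites/
  containers.py     intensity/detection matrices, sample keys, marker panels
  io.py             protein-group TSV dialect, sample maps, clinical/FC tables
  reference_data.py frozen gene-alias and contaminant-symbol snapshots
  sets.py           per-patient sets, core lists, disease-specific lists, UpSet
  deconvolution.py  marker cropping, presence, relative contributions
  concordance.py    EC, rmcorr, log-Pearson, repeated-measures ANOVA
  survival.py       log-rank, Cox (Efron), constrained cutoff scan
  simulate.py       synthetic-data generator with planted truth
  workflow.py, cli.py  orchestration and the `evascites` command
docs/methods.md     model and design notes
```
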