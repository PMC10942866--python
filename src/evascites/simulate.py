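"""Synthetic ascitic-EV proteome datasets with planted ground truth.

The generator emulates the structure the analysis assumes: an 11-patient
HGSC cohort with paired U/S/B fractions plus ~5 U-only control samples;
planted core EV proteins (present in U and S, absent from B, across all or
most patients); a small disease-specific subset absent from every control;
a looser "augmented" subset seen by UC everywhere but by SEC in only a
couple of patients; a ranked cell-type marker panel whose intensities scale
with per-patient mixing weights; flow-cytometry proportions derived from the
same weights under multiplicative noise; and right-censored exponential
overall-survival times with a hazard ratio tied to one planted marker.

Default parameter values mirror the study-scale conditions (set sizes
101 / 392 / 8 / 157, a 3 x 28 marker panel with 41 markers detected by both
isolation methods, a 390-entry MISEV-style table overlapping the core lists
in 18 and 50 genes). Detection dropout (S < U) models the lower proteome
coverage of SEC fractions and applies to background and bulk proteins; the
planted signature proteins are modelled as high-abundance proteins above the
detection limit, so their defining patterns hold by construction (see the
methods note).

Everything is deterministic given the seed; per-stage child streams keep,
e.g., survival times invariant to changes in the protein complement.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import IntensityMatrix, MarkerPanel, make_sample_table
from .io import write_protein_groups

#: disease-specific proteins with cell-type-restricted expression: the first
#: four double as panel markers, the last four are panel-external
STRINGENT_MARKER_OVERLAP = ("CD68", "LILRB1", "FCGR1A", "TACSTD2")
STRINGENT_EXTRAS = ("MRC1", "IDH2", "FAS", "ITGB8")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults are the study-scale conditions."""

    seed: int = 0
    n_patients: int = 11
    n_controls: int = 5
    # proteome composition
    n_background: int = 600
    n_bulk: int = 80
    n_contaminants: int = 20
    n_core: int = 101          # full-frequency core (S&U \ B in all patients)
    n_core_partial: int = 291  # core at 9-10 of 11 patients
    partial_min_patients: int = 9
    n_specific_stringent: int = 8
    n_specific_augmented_only: int = 149
    aug_s_patients: int = 2    # S-fraction detections of augmented-only genes
    # marker panel
    cell_types: tuple[str, ...] = ("malignant", "fibroblast", "macrophage")
    k_markers: int = 28
    panel_spare: int = 2       # extra ranked markers per type beyond k
    n_markers_detected_both: int = 41
    weight_alpha: float = 1.5  # Dirichlet concentration of mixing weights
    # intensity model (natural-log scale) and detection dropout;
    # log intensity = mu + sigma_gene * z_gene + sigma * z_cell, so the
    # gene-level component is shared across samples and the expected
    # between-fraction log-Pearson is sigma_gene^2/(sigma_gene^2 + sigma^2)
    log_intensity_mu: float = 16.0
    log_intensity_sigma_gene: float = 1.25
    log_intensity_sigma: float = 0.8
    bulk_log_boost: float = 2.0
    detect_u: float = 0.9
    detect_s: float = 0.6
    detect_b: float = 0.85
    bulk_detect_u: float = 0.3
    bulk_detect_s: float = 0.2
    bulk_detect_control: float = 0.5
    # flow cytometry
    fc_n_patients: int = 10
    fc_noise: float = 0.3
    # survival
    baseline_hazard: float = 0.0173  # per month; median OS ~ 40 months
    planted_hr: float = 3.0
    survival_gene: str = "MRC1"
    censor_hazard: float = 0.008
    max_follow_up: float = 120.0
    # MISEV-style reference table
    misev_total: int = 390
    misev_core_overlap: int = 18
    misev_su80_overlap: int = 50     # including the core overlap
    misev_detected_total: int = 172  # including the su80 overlap

    def without_dropout(self) -> "SyntheticConfig":
        """Copy with all detection probabilities forced to 1."""
        return replace(self, detect_u=1.0, detect_s=1.0, detect_b=1.0)

    def validate(self) -> None:
        if self.n_patients < 2 or self.n_controls < 1:
            raise ValueError("need at least 2 patients and 1 control")
        panel_size = self.k_markers + self.panel_spare
        if self.n_markers_detected_both > self.k_markers * len(self.cell_types):
            raise ValueError("more detected-both markers than cropped panel slots")
        if self.n_core < self.n_markers_detected_both + len(STRINGENT_EXTRAS):
            raise ValueError(
                "n_core must cover the detected-both markers and the "
                f"{len(STRINGENT_EXTRAS)} panel-external specific proteins"
            )
        if not 1 <= self.partial_min_patients <= self.n_patients - 1:
            raise ValueError("partial_min_patients out of range")
        if self.aug_s_patients >= self.partial_min_patients:
            raise ValueError("augmented-only genes must miss the core S threshold")
        if not 0 < self.fc_n_patients <= self.n_patients:
            raise ValueError("fc_n_patients out of range")
        for p in (self.detect_u, self.detect_s, self.detect_b):
            if not 0.0 <= p <= 1.0:
                raise ValueError("detection probabilities must lie in [0, 1]")
        if self.misev_core_overlap > min(self.misev_total, self.n_core - self.n_markers_detected_both - len(STRINGENT_EXTRAS)):
            raise ValueError("misev_core_overlap exceeds available core filler genes")
        if self.misev_su80_overlap - self.misev_core_overlap > self.n_core_partial:
            raise ValueError("misev_su80_overlap exceeds available partial-core genes")
        if self.misev_detected_total - self.misev_su80_overlap > self.n_background:
            raise ValueError("misev_detected_total exceeds available background genes")
        if self.misev_detected_total > self.misev_total:
            raise ValueError("misev_detected_total exceeds misev_total")
        if panel_size < self.k_markers:
            raise ValueError("panel_spare must be non-negative")


@dataclass
class PlantedTruth:
    core_set: frozenset[str]
    su80_set: frozenset[str]
    stringent_set: frozenset[str]
    augmented_set: frozenset[str]        # stringent + augmented-only
    augmented_only_set: frozenset[str]
    weights: pd.DataFrame                # patients x cell types, rows sum to 1
    markers_detected_both: frozenset[str]
    survival_gene: str
    survival_hr: float
    survival_threshold: float
    high_patients: frozenset[str]

    def to_json_dict(self) -> dict:
        return {
            "core_set": sorted(self.core_set),
            "su80_set": sorted(self.su80_set),
            "stringent_set": sorted(self.stringent_set),
            "augmented_set": sorted(self.augmented_set),
            "augmented_only_set": sorted(self.augmented_only_set),
            "weights": {
                str(p): {c: float(self.weights.at[p, c]) for c in self.weights.columns}
                for p in self.weights.index
            },
            "markers_detected_both": sorted(self.markers_detected_both),
            "survival": {
                "gene": self.survival_gene,
                "hr": self.survival_hr,
                "threshold": self.survival_threshold,
                "high_patients": sorted(self.high_patients),
            },
        }


@dataclass
class SyntheticDataset:
    intensities: IntensityMatrix
    panel_raw: MarkerPanel
    fc_proportions: pd.DataFrame
    clinical: pd.DataFrame
    misev: pd.DataFrame
    truth: PlantedTruth
    config: SyntheticConfig


def _panel_gene_names(cfg: SyntheticConfig) -> dict[str, list[str]]:
    """Ranked marker names per cell type; real symbols head each list."""
    seeds = {
        "macrophage": ["CD68", "LILRB1", "FCGR1A", "STAB1"],
        "malignant": ["TACSTD2", "EPCAM", "CKB", "SMIM22"],
        "fibroblast": ["DPP4", "PROCR", "SERPINB2"],
    }
    size = cfg.k_markers + cfg.panel_spare
    prefixes = {"macrophage": "MACM", "malignant": "MALM", "fibroblast": "FIBM"}
    panel: dict[str, list[str]] = {}
    for i, ct in enumerate(cfg.cell_types):
        head = list(seeds.get(ct, []))
        prefix = prefixes.get(ct, f"CT{i}M")
        genes = head + [
            f"{prefix}{j:03d}" for j in range(len(head) + 1, size + 1)
        ]
        panel[ct] = genes[:size]
    return panel


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full dataset with planted truth; deterministic given seed."""
    cfg = config
    cfg.validate()
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_intensity = np.random.default_rng(streams[0])
    rng_presence = np.random.default_rng(streams[1])
    rng_weights = np.random.default_rng(streams[2])
    rng_fc = np.random.default_rng(streams[3])
    rng_survival = np.random.default_rng(streams[4])
    rng_assign = np.random.default_rng(streams[5])

    patients = [f"P{i + 1:02d}" for i in range(cfg.n_patients)]
    controls = [f"K{i + 1:02d}" for i in range(cfg.n_controls)]
    sample_records = []
    for i, pid in enumerate(patients):
        for frac in ("U", "S", "B"):
            sample_records.append((f"{frac}{i + 1}", pid, frac, "HGSC"))
    for i, kid in enumerate(controls):
        sample_records.append((f"C{i + 1}", kid, "U", "CONTROL"))
    samples = make_sample_table(sample_records)
    sample_ids = list(samples.index)
    col = {sid: j for j, sid in enumerate(sample_ids)}
    n_samples = len(sample_ids)

    # -- gene complement ----------------------------------------------------
    panel_names = _panel_gene_names(cfg)
    raw_panel = MarkerPanel(markers={ct: list(gs) for ct, gs in panel_names.items()})
    cropped = {ct: gs[: cfg.k_markers] for ct, gs in panel_names.items()}

    # markers detected by both methods: spread the quota across cell types,
    # taking top-ranked markers first so the real symbols are included
    quota = np.full(len(cfg.cell_types), cfg.n_markers_detected_both // len(cfg.cell_types))
    quota[: cfg.n_markers_detected_both % len(cfg.cell_types)] += 1
    detected_both: list[str] = []
    for q, ct in zip(quota, cfg.cell_types):
        detected_both.extend(cropped[ct][: int(q)])

    extras = [g for g in STRINGENT_EXTRAS]
    n_filler = cfg.n_core - len(detected_both) - len(extras)
    core_filler = [f"CORE{i + 1:03d}" for i in range(n_filler)]
    core_genes = detected_both + extras + core_filler

    stringent_pool = [g for g in STRINGENT_MARKER_OVERLAP if g in detected_both]
    stringent_pool += extras + core_filler
    stringent_genes = stringent_pool[: cfg.n_specific_stringent]

    partial_genes = [f"PCOR{i + 1:03d}" for i in range(cfg.n_core_partial)]
    aug_genes = [f"AUG{i + 1:03d}" for i in range(cfg.n_specific_augmented_only)]
    bg_genes = [f"BG{i + 1:04d}" for i in range(cfg.n_background)]
    bulk_genes = [f"BLK{i + 1:03d}" for i in range(cfg.n_bulk)]

    marker_only = [
        g for gs in panel_names.values() for g in gs if g not in set(detected_both)
    ]
    contam_genes = [f"CON{i + 1:03d}" for i in range(cfg.n_contaminants)]

    genes = (
        core_genes + partial_genes + aug_genes + marker_only
        + bg_genes + bulk_genes + contam_genes
    )
    assert len(set(genes)) == len(genes), "gene name collision in generator"
    gi = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    # -- presence -----------------------------------------------------------
    presence = np.zeros((n_genes, n_samples), dtype=bool)

    def set_presence(gene, patient_idx=None, fractions=(), control=False, value=True):
        i = gi[gene]
        if patient_idx is not None:
            for frac in fractions:
                presence[i, col[f"{frac}{patient_idx + 1}"]] = value
        if control:
            for j in range(cfg.n_controls):
                presence[i, col[f"C{j + 1}"]] = value

    stringent_set = set(stringent_genes)
    for g in core_genes:
        for p in range(cfg.n_patients):
            set_presence(g, p, ("U", "S"))
        if g not in stringent_set:
            set_presence(g, control=True)

    for g in partial_genes:
        n_s = int(rng_assign.integers(cfg.partial_min_patients, cfg.n_patients))
        s_patients = rng_assign.choice(cfg.n_patients, size=n_s, replace=False)
        for p in range(cfg.n_patients):
            set_presence(g, p, ("U",))
        for p in s_patients:
            set_presence(g, int(p), ("S",))
        set_presence(g, control=True)

    for g in aug_genes:
        s_patients = rng_assign.choice(
            cfg.n_patients, size=cfg.aug_s_patients, replace=False
        )
        for p in range(cfg.n_patients):
            set_presence(g, p, ("U",))
        for p in s_patients:
            set_presence(g, int(p), ("S",))

    for g in marker_only:  # detected by UC only
        for p in range(cfg.n_patients):
            set_presence(g, p, ("U",))
        set_presence(g, control=True)

    # background: Bernoulli detection per fraction (the dropout model)
    bg_rows = [gi[g] for g in bg_genes]
    for sid in sample_ids:
        frac = samples.at[sid, "fraction"]
        p_det = {"U": cfg.detect_u, "S": cfg.detect_s, "B": cfg.detect_b}[frac]
        presence[bg_rows, col[sid]] = rng_presence.random(len(bg_rows)) < p_det

    bulk_rows = [gi[g] for g in bulk_genes]
    for sid in sample_ids:
        frac = samples.at[sid, "fraction"]
        cohort = samples.at[sid, "cohort"]
        if frac == "B":
            presence[bulk_rows, col[sid]] = True
        else:
            p_det = (
                cfg.bulk_detect_control
                if cohort == "CONTROL"
                else {"U": cfg.bulk_detect_u, "S": cfg.bulk_detect_s}[frac]
            )
            presence[bulk_rows, col[sid]] = rng_presence.random(len(bulk_rows)) < p_det

    contam_rows = [gi[g] for g in contam_genes]
    for sid in sample_ids:  # contaminants show up broadly
        presence[contam_rows, col[sid]] = rng_presence.random(len(contam_rows)) < 0.8

    # -- intensities --------------------------------------------------------
    z_gene = rng_intensity.standard_normal(n_genes)
    z = rng_intensity.standard_normal((n_genes, n_samples))
    log_int = (
        cfg.log_intensity_mu
        + cfg.log_intensity_sigma_gene * z_gene[:, None]
        + cfg.log_intensity_sigma * z
    )
    values = np.exp(log_int)

    weights = rng_weights.dirichlet(
        np.full(len(cfg.cell_types), cfg.weight_alpha), size=cfg.n_patients
    )
    weights_df = pd.DataFrame(
        weights, index=pd.Index(patients, name="patient_id"), columns=list(cfg.cell_types)
    )
    for ci, ct in enumerate(cfg.cell_types):
        rows = [gi[g] for g in cropped[ct]]
        for p in range(cfg.n_patients):
            w = weights[p, ci]
            for frac in ("U", "S"):
                values[np.ix_(rows, [col[f"{frac}{p + 1}"]])] *= w

    b_cols = [col[sid] for sid in sample_ids if samples.at[sid, "fraction"] == "B"]
    values[np.ix_(bulk_rows, b_cols)] *= np.exp(cfg.bulk_log_boost)

    values = values * presence

    flags = pd.DataFrame(
        {
            "fasta_header": [f"sp|SYN{i:05d}|{g}_HUMAN {g} synthetic protein"
                             for i, g in enumerate(genes)],
            "is_reverse": False,
            "is_crap_contaminant": False,
            "is_only_identified_by_site": False,
        },
        index=pd.Index(genes, name="gene"),
    )
    third = max(1, cfg.n_contaminants // 4)
    for j, g in enumerate(contam_genes):
        i = flags.index.get_loc(g)
        if j < third:
            flags.iloc[i, flags.columns.get_loc("is_reverse")] = True
            flags.iloc[i, flags.columns.get_loc("fasta_header")] = (
                f"REV__sp|SYNR{j:04d}|{g}_HUMAN reversed decoy"
            )
        elif j < 2 * third:
            flags.iloc[i, flags.columns.get_loc("fasta_header")] = (
                f"sp|SYNK{j:04d}|{g}_HUMAN Keratin, type II cytoskeletal"
            )
        elif j < 3 * third:
            flags.iloc[i, flags.columns.get_loc("is_crap_contaminant")] = True
        else:
            flags.iloc[i, flags.columns.get_loc("is_only_identified_by_site")] = True

    matrix = IntensityMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_ids),
        samples=samples,
        flags=flags,
    )

    # -- flow cytometry -----------------------------------------------------
    fc_rows = []
    for p in range(cfg.fc_n_patients):
        noisy = weights[p] * np.exp(
            cfg.fc_noise * rng_fc.standard_normal(len(cfg.cell_types))
        )
        noisy = noisy / noisy.sum()
        for ci, ct in enumerate(cfg.cell_types):
            fc_rows.append((patients[p], ct, float(noisy[ci])))
    fc = pd.DataFrame(fc_rows, columns=["patient_id", "cell_type", "proportion"])

    # -- survival -----------------------------------------------------------
    surv_gene = cfg.survival_gene.upper()
    if surv_gene not in gi:
        raise ValueError(f"survival gene {surv_gene!r} not in the generated proteome")
    u_cols = [col[f"U{p + 1}"] for p in range(cfg.n_patients)]
    marker_vals = values[gi[surv_gene], u_cols]
    threshold = float(np.median(marker_vals))
    high = marker_vals > threshold
    rate = cfg.baseline_hazard * np.where(high, cfg.planted_hr, 1.0)
    t_event = rng_survival.exponential(1.0 / rate)
    t_cens = (
        rng_survival.exponential(1.0 / cfg.censor_hazard, size=cfg.n_patients)
        if cfg.censor_hazard > 0
        else np.full(cfg.n_patients, np.inf)
    )
    t_cens = np.minimum(t_cens, cfg.max_follow_up)
    os_months = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    clinical = pd.DataFrame(
        {"patient_id": patients, "os_months": os_months, "event": event.astype(int)}
    )

    # -- MISEV-style table --------------------------------------------------
    misev_genes = list(core_filler[: cfg.misev_core_overlap])
    misev_genes += partial_genes[: cfg.misev_su80_overlap - cfg.misev_core_overlap]
    misev_genes += bg_genes[: cfg.misev_detected_total - cfg.misev_su80_overlap]
    misev_genes += [
        f"MISEVX{i + 1:03d}" for i in range(cfg.misev_total - len(misev_genes))
    ]
    misev = pd.DataFrame(
        {
            "gene": misev_genes,
            "category": [(i % 5) + 1 for i in range(len(misev_genes))],
        }
    )

    truth = PlantedTruth(
        core_set=frozenset(core_genes),
        su80_set=frozenset(core_genes + partial_genes),
        stringent_set=frozenset(stringent_genes),
        augmented_set=frozenset(stringent_genes + aug_genes),
        augmented_only_set=frozenset(aug_genes),
        weights=weights_df,
        markers_detected_both=frozenset(detected_both),
        survival_gene=surv_gene,
        survival_hr=cfg.planted_hr,
        survival_threshold=threshold,
        high_patients=frozenset(np.array(patients)[high]),
    )
    return SyntheticDataset(
        intensities=matrix,
        panel_raw=raw_panel,
        fc_proportions=fc,
        clinical=clinical,
        misev=misev,
        truth=truth,
        config=cfg,
    )


# -- fixture writing ---------------------------------------------------------

FIXTURE_FILES = {
    "protein_groups": "protein_groups.tsv",
    "sample_map": "sample_map.csv",
    "marker_panel": "marker_panel.tsv",
    "fc_proportions": "fc_proportions.csv",
    "clinical": "clinical.csv",
    "misev": "misev.tsv",
    "truth": "truth.json",
}


def write_fixture(ds: SyntheticDataset, directory) -> dict[str, Path]:
    """Write the dataset in the external-interface formats; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in FIXTURE_FILES.items()}

    write_protein_groups(ds.intensities, paths["protein_groups"])
    sm = ds.intensities.samples.reset_index().rename(columns={"sample_id": "sample_column"})
    sm.to_csv(paths["sample_map"], index=False)
    ds.panel_raw.to_frame().to_csv(paths["marker_panel"], sep="\t", index=False)
    ds.fc_proportions.to_csv(paths["fc_proportions"], index=False)
    ds.clinical.to_csv(paths["clinical"], index=False)
    ds.misev.to_csv(paths["misev"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth.to_json_dict(), fh, indent=1, sort_keys=True)
    return paths


# -- survival-only cohorts ---------------------------------------------------


def simulate_survival_cohort(
    n: int,
    hr: float,
    seed: int,
    baseline_hazard: float = 0.0173,
    censor_hazard: float = 0.008,
    max_follow_up: float = 120.0,
    p_high: float = 0.5,
) -> pd.DataFrame:
    """Right-censored exponential cohort with a binary group effect.

    Used for parameter-recovery checks of the Cox estimator at sample sizes
    far beyond the 11-patient study cohort. Returns columns os_months,
    event, group.
    """
    rng = np.random.default_rng(seed)
    group = rng.random(n) < p_high
    rate = baseline_hazard * np.where(group, hr, 1.0)
    t_event = rng.exponential(1.0 / rate)
    t_cens = np.minimum(
        rng.exponential(1.0 / censor_hazard, size=n)
        if censor_hazard > 0
        else np.full(n, np.inf),
        max_follow_up,
    )
    return pd.DataFrame(
        {
            "patient_id": [f"S{i + 1:04d}" for i in range(n)],
            "os_months": np.minimum(t_event, t_cens),
            "event": (t_event <= t_cens).astype(int),
            "group": group.astype(int),
        }
    )
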