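"""End-to-end orchestration: io -> sets -> contributions -> concordance -> survival.

A run is configured by a small YAML/dict structure::

    inputs:
      protein_groups: path/to/protein_groups.tsv
      sample_map: path/to/sample_map.csv
      marker_panel: path/to/marker_panel.tsv
      fc_proportions: path/to/fc_proportions.csv   # optional
      clinical: path/to/clinical.csv               # optional
      misev: path/to/misev.tsv                     # optional
    params:
      threshold_fraction: 0.8
      k: 28
      min_group: 3
      floor: 100000
      permutations: 0
      seed: 17
      denominator: type_mean_sum
      undetected: zero
      stringent_base: su80
      pseudocount: null

Every interpretive choice (denominator mode, stringent base set, tie rules,
pseudocount) surfaces as an explicit config key with the defaults above. ``run_all`` executes the stages in dependency order, writes
TSV outputs plus a machine-readable ``report.json``, and returns the report
dict. A stage failure raises :class:`WorkflowError` carrying the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import concordance as cc
from . import deconvolution as dc
from . import io as evio
from . import sets as st
from . import survival as sv

logger = logging.getLogger(__name__)

DEFAULT_PARAMS: dict[str, Any] = {
    "threshold_fraction": 0.8,
    "k": 28,
    "min_group": 3,
    "floor": 1e5,
    "permutations": 0,
    "seed": 17,
    "denominator": "type_mean_sum",
    "undetected": "zero",
    "stringent_base": "su80",
    "pseudocount": None,
    "extra_survival_markers": list(sv.DEFAULT_EXTRA_MARKERS),
    "cell_types": list(dc.DEFAULT_CELL_TYPES),
}


class WorkflowError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "inputs" not in cfg:
        raise ValueError("run config must be a mapping with an 'inputs' section")
    return cfg


def run_all(
    inputs: Mapping[str, Any], out_dir, params: Mapping[str, Any] | None = None
) -> dict:
    """Execute the full pipeline; write outputs under ``out_dir``."""
    p = dict(DEFAULT_PARAMS)
    p.update(params or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "package": {"name": "evascites", "version": _pkg_version("evascites")},
        "params": {k: v for k, v in p.items()},
        "inputs": {},
        "headline": {},
        "notes": [],
    }
    try:
        for key, path in inputs.items():
            if path is not None:
                report["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}
    except Exception as exc:  # noqa: BLE001
        raise WorkflowError("inputs", exc) from exc

    # -- stage: io ---------------------------------------------------------
    stage = "io"
    try:
        sample_map = evio.read_sample_map(inputs["sample_map"])
        matrix = evio.read_protein_groups(inputs["protein_groups"], sample_map)
        n_raw = len(matrix.genes)
        matrix = evio.filter_contaminants(matrix)
        matrix = evio.harmonize_gene_names(matrix)
        detection = matrix.binarize()
        report["headline"]["n_proteins_raw"] = n_raw
        report["headline"]["n_proteins_filtered"] = len(matrix.genes)
    except WorkflowError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise WorkflowError(stage, exc) from exc

    # -- stage: sets -------------------------------------------------------
    stage = "sets"
    try:
        patient_sets = st.per_patient_sets(detection)
        rows = [(ps.patient_id, g) for ps in patient_sets for g in sorted(ps.proteins)]
        pd.DataFrame(rows, columns=["patient_id", "gene"]).to_csv(
            out / "per_patient_sets.tsv", sep="\t", index=False
        )
        core = st.core_sets(patient_sets, threshold_fraction=p["threshold_fraction"])
        core.to_frame().to_csv(out / "core_sets.tsv", sep="\t", index=False)
        upset = st.upset_counts(patient_sets)
        upset.patterns.to_csv(out / "upset_patterns.tsv", sep="\t", index=False)
        report["headline"]["su100"] = len(core.su100)
        report["headline"]["su80"] = len(core.su80)
        report["headline"]["upset_union"] = upset.union_size

        has_controls = (detection.samples["cohort"] == "CONTROL").any()
        if has_controls:
            specific = st.hgsc_specific(
                detection,
                core,
                stringent_base=p["stringent_base"],
                threshold_fraction=p["threshold_fraction"],
            )
            specific.to_frame().to_csv(
                out / "specific_sets.tsv", sep="\t", index=False
            )
            report["headline"]["stringent"] = len(specific.stringent)
            report["headline"]["augmented"] = len(specific.augmented)
        else:
            specific = None
            report["notes"].append("no control samples: specific sets skipped")

        if inputs.get("misev"):
            misev = evio.read_misev(inputs["misev"])
            ov100 = st.misev_overlap(core.su100, misev)
            ov80 = st.misev_overlap(core.su80, misev)
            pd.DataFrame(
                [
                    ("su100", ov100.n_genes, ov100.n_overlap, ov100.pct),
                    ("su80", ov80.n_genes, ov80.n_overlap, ov80.pct),
                ],
                columns=["set", "n_genes", "n_overlap", "pct"],
            ).to_csv(out / "misev_overlap.tsv", sep="\t", index=False)
            report["headline"]["misev_su100"] = ov100.n_overlap
            report["headline"]["misev_su100_pct"] = ov100.pct
            report["headline"]["misev_su80"] = ov80.n_overlap
            report["headline"]["misev_su80_pct"] = ov80.pct
    except Exception as exc:  # noqa: BLE001
        raise WorkflowError(stage, exc) from exc

    # -- stage: contributions ---------------------------------------------
    stage = "contributions"
    contribs: dict[str, dc.ContributionTable] = {}
    try:
        panel = dc.crop_panel(evio.read_marker_panel(inputs["marker_panel"]), k=p["k"])
        for frac in ("U", "S"):
            pres = dc.marker_presence(detection, panel, frac)
            pres.table.to_csv(out / f"marker_presence_{frac}.tsv", sep="\t")
            contribs[frac] = dc.relative_contribution(
                matrix,
                panel,
                frac,
                denominator=p["denominator"],
                undetected=p["undetected"],
            )
            contribs[frac].table.to_csv(
                out / f"contributions_{frac}.tsv", sep="\t", index=False
            )
    except Exception as exc:  # noqa: BLE001
        raise WorkflowError(stage, exc) from exc

    # -- stage: concordance -------------------------------------------------
    stage = "concordance"
    try:
        conc: dict[str, Any] = {}
        merged = contribs["U"].table.merge(
            contribs["S"].table,
            on=["patient_id", "cell_type"],
            suffixes=("_u", "_s"),
        ).dropna(subset=["contribution_pct_u", "contribution_pct_s"])
        rm_us = cc.rmcorr(
            merged["contribution_pct_u"],
            merged["contribution_pct_s"],
            merged["patient_id"],
        )
        conc["rmcorr_u_vs_s"] = {
            "r": rm_us.r_rm, "df": rm_us.df, "p": rm_us.p_value,
            "n_subjects": rm_us.n_subjects, "n_obs": rm_us.n_obs,
        }
        report["headline"]["rmcorr_u_vs_s_r"] = rm_us.r_rm

        pl = cc.pearson_log(
            matrix.fraction_frame("U"), matrix.fraction_frame("S"),
            pseudocount=p["pseudocount"],
        )
        conc["pearson_log_u_vs_s"] = {"r": pl.r, "n_pairs": pl.n_pairs}
        report["headline"]["pearson_log_r"] = pl.r

        if inputs.get("fc_proportions"):
            fc = evio.read_cell_proportions(inputs["fc_proportions"])
            for frac in ("U", "S"):
                ec = cc.enrichment_coefficient(
                    contribs[frac], fc, cell_types=tuple(p["cell_types"])
                )
                ec.table.to_csv(out / f"enrichment_{frac}.tsv", sep="\t", index=False)
                report["headline"][f"ec_means_{frac}"] = ec.type_means
                sub = ec.table.dropna(subset=["ec"])
                rm_fc = cc.rmcorr(sub["pct_cells"], sub["pct_ev"], sub["patient_id"])
                conc[f"rmcorr_ev_vs_fc_{frac}"] = {
                    "r": rm_fc.r_rm, "df": rm_fc.df, "p": rm_fc.p_value,
                }
                report["headline"][f"rmcorr_ev_vs_fc_{frac}_r"] = rm_fc.r_rm
                if frac == "U":
                    anova = cc.rm_anova_ec(ec)
                    conc["rm_anova_ec_u"] = {
                        "F": anova.F, "df1": anova.df1, "df2": anova.df2,
                        "p": anova.p_value,
                    }
        with open(out / "concordance.json", "w") as fh:
            json.dump(conc, fh, indent=1)
    except Exception as exc:  # noqa: BLE001
        raise WorkflowError(stage, exc) from exc

    # -- stage: survival ----------------------------------------------------
    stage = "survival"
    try:
        if inputs.get("clinical"):
            clinical = evio.read_clinical(inputs["clinical"])
            selection = sv.select_survival_markers(
                detection, detection, panel,
                extra=tuple(p["extra_survival_markers"]),
            )
            report["headline"]["n_survival_markers"] = len(selection.genes)
            u_frame = matrix.fraction_frame("U")
            features = u_frame.loc[[g for g in selection.genes if g in u_frame.index]]
            scan = sv.scan_all_features(
                features, clinical,
                min_group=p["min_group"], floor=p["floor"],
                permutations=p["permutations"], seed=p["seed"],
            )
            scan.to_frame().to_csv(
                out / "survival_scan_intensity.tsv", sep="\t", index=False
            )
            best = [r for r in scan.results if not r.empty]
            if best:
                top = min(best, key=lambda r: r.logrank_p)
                report["headline"]["best_intensity_feature"] = top.feature_id
                report["headline"]["best_intensity_p"] = top.logrank_p
                report["headline"]["best_intensity_hr"] = top.hr
            report["notes"].append(sv.EXPLORATORY_NOTE)

            if inputs.get("fc_proportions"):
                fc = evio.read_cell_proportions(inputs["fc_proportions"])
                prop_features = fc.pivot(
                    index="cell_type", columns="patient_id", values="proportion"
                )
                prop_scan = sv.scan_all_features(
                    prop_features, clinical,
                    min_group=p["min_group"], floor=None,
                    permutations=p["permutations"], seed=p["seed"],
                )
                prop_scan.to_frame().to_csv(
                    out / "survival_scan_proportions.tsv", sep="\t", index=False
                )
        else:
            report["notes"].append("no clinical table: survival analysis skipped")
    except Exception as exc:  # noqa: BLE001
        raise WorkflowError(stage, exc) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
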