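"""Attribution of EV proteome content to producer cell types.

Cell types leave fingerprints in the EV cargo through their marker proteins.
Given a ranked marker panel derived from single-cell RNA-seq cluster
signatures (cropped to the same number k of markers per cell type, default
k = 28), the relative contribution of cell type c to patient p's EV pool is

    contribution_pct(p, c) = 100 * mean_c(p) / sum_c' mean_c'(p)

where mean_c(p) is the arithmetic mean label-free intensity of c's markers in
the patient's sample of the chosen fraction (U or S). By default markers that
were never quantified enter the mean as zeros so that each type is averaged
over exactly k markers; a detected-only mean is selectable. The default
denominator (sum of per-type means) makes contributions sum to 100 per
patient; the strict "sum of all marker intensities" reading is selectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DetectionMatrix, IntensityMatrix, MarkerPanel

logger = logging.getLogger(__name__)

#: cell types retained for the contribution / survival analyses by default
DEFAULT_CELL_TYPES = ("malignant", "fibroblast", "macrophage")


def crop_panel(raw: MarkerPanel, k: int = 28) -> MarkerPanel:
    """Crop every cell type to its top-k markers, keeping genes unique.

    Markers are taken in rank order; a gene already claimed by an
    earlier-listed cell type is skipped (logged), and the scan continues down
    the ranking until k unclaimed markers are collected. A type that cannot
    reach k raises a ValueError naming it.
    """
    claimed: set[str] = set()
    cropped: dict[str, list[str]] = {}
    for cell_type, genes in raw.markers.items():
        kept: list[str] = []
        for g in genes:
            if g in claimed:
                logger.info(
                    "marker %s already claimed; dropped from cell type %s", g, cell_type
                )
                continue
            kept.append(g)
            claimed.add(g)
            if len(kept) == k:
                break
        if len(kept) < k:
            raise ValueError(
                f"cell type {cell_type!r} has only {len(kept)} unique markers; "
                f"{k} required"
            )
        cropped[cell_type] = kept
    return MarkerPanel(markers=cropped)


@dataclass
class MarkerPresence:
    """Patient x marker detection table for one fraction."""

    table: pd.DataFrame  # patients (index) x marker genes, bool
    never_measured: frozenset[str]  # panel markers absent from the matrix
    fraction: str


def marker_presence(
    d: DetectionMatrix, panel: MarkerPanel, fraction: str
) -> MarkerPresence:
    """Score each panel marker's detection per patient in the given fraction.

    Markers absent from the matrix entirely are reported as all-False and
    listed under ``never_measured``.
    """
    if fraction not in ("U", "S"):
        raise ValueError("fraction must be 'U' or 'S'")
    markers = panel.all_genes()
    patients = [p for p in d.patients("HGSC") if d.has_sample(p, fraction)]
    known = set(d.genes)
    never = frozenset(g for g in markers if g not in known)
    data = np.zeros((len(patients), len(markers)), dtype=bool)
    for i, pid in enumerate(patients):
        col = d.values[d.sample_for(pid, fraction)]
        for j, g in enumerate(markers):
            if g in known:
                data[i, j] = bool(col.at[g])
    table = pd.DataFrame(data, index=pd.Index(patients, name="patient_id"), columns=markers)
    return MarkerPresence(table=table, never_measured=never, fraction=fraction)


@dataclass
class ContributionTable:
    """Long-format per-patient cell-type contributions."""

    table: pd.DataFrame  # patient_id, cell_type, mean_intensity, contribution_pct
    flagged_patients: frozenset[str]  # all-zero denominators; contributions NaN
    fraction: str
    denominator: str
    undetected: str

    def wide(self) -> pd.DataFrame:
        return self.table.pivot(
            index="patient_id", columns="cell_type", values="contribution_pct"
        )

    def summary(self) -> str:
        wide = self.wide()
        lines = [
            f"Cell-type contributions ({self.fraction} fraction, "
            f"denominator={self.denominator}, undetected={self.undetected})",
            wide.round(2).to_string(),
        ]
        if self.flagged_patients:
            lines.append(f"flagged (all-zero) patients: {sorted(self.flagged_patients)}")
        return "\n".join(lines)


def relative_contribution(
    m: IntensityMatrix,
    panel: MarkerPanel,
    fraction: str,
    denominator: str = "type_mean_sum",
    undetected: str = "zero",
) -> ContributionTable:
    """Per-patient relative contribution of each cell type to the EV signal.

    Parameters
    ----------
    m : IntensityMatrix
    panel : MarkerPanel
        Already cropped (equal marker counts per type).
    fraction : str
        "U" or "S".
    denominator : str
        "type_mean_sum" (default; contributions sum to 100) or
        "total_intensity" (strict literal: sum of all marker intensities).
    undetected : str
        "zero" (default; unquantified markers contribute 0 to the mean) or
        "detected_only" (mean over detected markers only).

    Patients whose denominator is zero are emitted with NaN contributions and
    listed in ``flagged_patients``.
    """
    if fraction not in ("U", "S"):
        raise ValueError("fraction must be 'U' or 'S'")
    if denominator not in ("type_mean_sum", "total_intensity"):
        raise ValueError("unknown denominator mode")
    if undetected not in ("zero", "detected_only"):
        raise ValueError("unknown undetected mode")

    patients = [p for p in m.patients("HGSC") if m.has_sample(p, fraction)]
    known = set(m.genes)
    rows = []
    flagged = []
    for pid in patients:
        col = m.values[m.sample_for(pid, fraction)]
        means: dict[str, float] = {}
        total_intensity = 0.0
        for cell_type, genes in panel.markers.items():
            intens = np.array([float(col.at[g]) if g in known else 0.0 for g in genes])
            total_intensity += float(intens.sum())
            if undetected == "zero":
                means[cell_type] = float(intens.mean())
            else:
                pos = intens[intens > 0]
                means[cell_type] = float(pos.mean()) if pos.size else 0.0
        denom = sum(means.values()) if denominator == "type_mean_sum" else total_intensity
        if denom <= 0:
            flagged.append(pid)
        for cell_type in panel.markers:
            pct = 100.0 * means[cell_type] / denom if denom > 0 else float("nan")
            rows.append((pid, cell_type, means[cell_type], pct))
    table = pd.DataFrame(
        rows, columns=["patient_id", "cell_type", "mean_intensity", "contribution_pct"]
    )
    return ContributionTable(
        table=table,
        flagged_patients=frozenset(flagged),
        fraction=fraction,
        denominator=denominator,
        undetected=undetected,
    )


class CellTypeDeconvolution:
    """Model-style front end for the marker-mean contribution computation.

    Examples
    --------
    >>> model = CellTypeDeconvolution(matrix, panel, fraction="U")
    >>> result = model.fit()
    >>> result.wide()  # patients x cell types, percentages summing to 100
    """

    def __init__(
        self,
        intensities: IntensityMatrix,
        panel: MarkerPanel,
        fraction: str = "U",
        denominator: str = "type_mean_sum",
        undetected: str = "zero",
    ) -> None:
        self.intensities = intensities
        self.panel = panel
        self.fraction = fraction
        self.denominator = denominator
        self.undetected = undetected

    def fit(self) -> ContributionTable:
        return relative_contribution(
            self.intensities,
            self.panel,
            self.fraction,
            denominator=self.denominator,
            undetected=self.undetected,
        )


EV_SIZE_CLASSES = ("small_EV", "large_EV", "nonsignificant", "not_detected")


def classify_ev_size(genes, ref: pd.DataFrame) -> pd.DataFrame:
    """Classify genes as small-EV / large-EV enriched against a reference.

    The reference carries, per gene, a differential-abundance p-value and a
    fold change (small EV / large EV). Classes: ``small_EV`` iff p < 0.05 and
    FC > 1.5; ``large_EV`` iff p < 0.05 and FC < -1.5; ``nonsignificant``
    otherwise when the gene is present in the reference; ``not_detected``
    when it is absent from the reference.
    """
    lut = {
        g: (float(p), float(fc))
        for g, p, fc in zip(ref["gene"], ref["p_value"], ref["fc_sev_lev"])
    }
    rows = []
    for g in genes:
        g = str(g).upper()
        if g not in lut:
            cls = "not_detected"
        else:
            p, fc = lut[g]
            if p < 0.05 and fc > 1.5:
                cls = "small_EV"
            elif p < 0.05 and fc < -1.5:
                cls = "large_EV"
            else:
                cls = "nonsignificant"
        rows.append((g, cls))
    return pd.DataFrame(rows, columns=["gene", "ev_size_class"])
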