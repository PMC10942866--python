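"""Reading, filtering and normalisation of protein-group tables and side inputs.

The entry format is the MaxQuant ``proteinGroups.txt`` dialect: a tab-separated
table with one row per protein group, columns ``Gene names``, ``Fasta headers``,
the decoy/artefact flag columns ``Reverse``, ``Only identified by site`` and
``Potential contaminant`` (marked with ``+``), and one ``Intensity <sample>``
column per measured sample. A sample map assigns each intensity column to a
(patient, fraction, cohort) key.

Protein identity throughout the pipeline is the harmonized, uppercase gene
symbol. Multi-gene groups ("GENE1;GENE2") resolve to the first listed symbol;
rows without any gene symbol are dropped (counted in the module logger).
Blank or missing intensity cells read as 0, i.e. not detected.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    FLAG_COLUMNS,
    FRACTIONS,
    IntensityMatrix,
    DetectionMatrix,
    MarkerPanel,
    make_sample_table,
)
from .reference_data import CRAP_SYMBOLS, GENE_ALIAS_SNAPSHOT

logger = logging.getLogger(__name__)

GENE_COLUMN = "Gene names"
FASTA_COLUMN = "Fasta headers"
REVERSE_COLUMN = "Reverse"
ONLY_SITE_COLUMN = "Only identified by site"
CONTAMINANT_COLUMN = "Potential contaminant"


def _first_symbol(raw: str) -> str:
    return str(raw).split(";")[0].strip().upper()


def read_sample_map(path) -> pd.DataFrame:
    """Sample map CSV: columns sample_column, patient_id, fraction, cohort."""
    df = pd.read_csv(path, dtype=str)
    required = ["sample_column", "patient_id", "fraction", "cohort"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sample map missing columns: {missing}")
    return df[required]


def read_protein_groups(path, sample_map: pd.DataFrame) -> IntensityMatrix:
    """Read a proteinGroups-style TSV into an :class:`IntensityMatrix`.

    Parameters
    ----------
    path : path-like
        Tab-separated protein-group table.
    sample_map : DataFrame
        Columns sample_column / patient_id / fraction / cohort. Intensity
        columns not named in the map are ignored.

    Raises
    ------
    KeyError
        If a mapped intensity column (or a required annotation column) is
        absent from the file.
    ValueError
        If an intensity cell is non-numeric (reported with its row index).
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (GENE_COLUMN, FASTA_COLUMN):
        if col not in table.columns:
            raise KeyError(f"required column {col!r} not found in {path}")

    sample_cols = list(sample_map["sample_column"])
    absent = [c for c in sample_cols if c not in table.columns]
    if absent:
        raise KeyError(f"mapped sample column(s) not found in {path}: {absent}")

    symbols = table[GENE_COLUMN].map(_first_symbol)
    keep = symbols != ""
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d rows without a gene symbol", n_dropped)
    table = table.loc[keep].reset_index(drop=True)
    symbols = symbols[keep].reset_index(drop=True)

    def flag(col: str) -> pd.Series:
        if col in table.columns:
            return table[col].str.strip() == "+"
        return pd.Series(False, index=table.index)

    is_reverse = flag(REVERSE_COLUMN)
    is_only_site = flag(ONLY_SITE_COLUMN)
    if CONTAMINANT_COLUMN in table.columns:
        is_crap = table[CONTAMINANT_COLUMN].str.strip() == "+"
    else:
        is_crap = symbols.isin(CRAP_SYMBOLS)

    intens = np.zeros((len(table), len(sample_cols)), dtype=float)
    for j, col in enumerate(sample_cols):
        raw = table[col].str.strip()
        # builtin float() is correctly rounding, so written values round-trip
        for i, sval in enumerate(raw):
            if sval == "":
                continue
            try:
                intens[i, j] = float(sval)
            except ValueError:
                raise ValueError(
                    f"non-numeric intensity in column {col!r}, row {i}: {sval!r}"
                ) from None
            if math.isnan(intens[i, j]):
                intens[i, j] = 0.0

    samples = make_sample_table(
        (row.sample_column, row.patient_id, row.fraction, row.cohort)
        for row in sample_map.itertuples(index=False)
    )
    values = pd.DataFrame(intens, index=symbols.to_numpy(), columns=sample_cols)
    flags = pd.DataFrame(
        {
            "fasta_header": table[FASTA_COLUMN].to_numpy(),
            "is_reverse": is_reverse.to_numpy(),
            "is_crap_contaminant": is_crap.to_numpy(),
            "is_only_identified_by_site": is_only_site.to_numpy(),
        },
        index=symbols.to_numpy(),
    )
    values, flags = _merge_duplicate_symbols(values, flags)
    return IntensityMatrix(values=values, samples=samples, flags=flags)


def write_protein_groups(m: IntensityMatrix, path) -> None:
    """Write an IntensityMatrix back to the proteinGroups TSV dialect."""
    out = pd.DataFrame(
        {
            GENE_COLUMN: m.values.index,
            FASTA_COLUMN: m.flags["fasta_header"].to_numpy(),
            REVERSE_COLUMN: np.where(m.flags["is_reverse"], "+", ""),
            ONLY_SITE_COLUMN: np.where(m.flags["is_only_identified_by_site"], "+", ""),
            CONTAMINANT_COLUMN: np.where(m.flags["is_crap_contaminant"], "+", ""),
        }
    )
    for sid in m.sample_ids:
        out[sid] = m.values[sid].to_numpy()
    # %.17g guarantees float64 round-trips value-identically through the file
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _merge_duplicate_symbols(
    values: pd.DataFrame, flags: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse rows sharing a gene symbol: per-sample max intensity, OR flags.

    The max preserves "detected" semantics: the merged row is detected exactly
    where at least one of the originals was.
    """
    if not values.index.duplicated().any():
        return values, flags
    order = list(dict.fromkeys(values.index))
    merged_vals = values.groupby(level=0, sort=False).max().loc[order]
    grouped = flags.groupby(level=0, sort=False)
    merged_flags = pd.DataFrame(
        {
            "fasta_header": grouped["fasta_header"].agg(
                lambda s: "|".join(x for x in dict.fromkeys(s) if x)
            ),
            "is_reverse": grouped["is_reverse"].any(),
            "is_crap_contaminant": grouped["is_crap_contaminant"].any(),
            "is_only_identified_by_site": grouped["is_only_identified_by_site"].any(),
        }
    ).loc[order]
    return merged_vals, merged_flags


def filter_contaminants(m: IntensityMatrix) -> IntensityMatrix:
    """Drop decoys, site-only identifications, cRAP hits and keratins.

    A row is removed iff it is flagged Reverse or Only-identified-by-site or
    as a contaminant, or its FASTA header contains the substring "keratin" or
    "Keratin". Idempotent; the sample axis is untouched.
    """
    f = m.flags
    keratin = f["fasta_header"].astype(str).map(
        lambda h: ("keratin" in h) or ("Keratin" in h)
    )
    drop = (
        f["is_reverse"]
        | f["is_only_identified_by_site"]
        | f["is_crap_contaminant"]
        | keratin
    )
    keep = list(m.values.index[~drop.to_numpy()])
    return IntensityMatrix(
        values=m.values.loc[keep].copy(),
        samples=m.samples.copy(),
        flags=m.flags.loc[keep].copy(),
    )


def harmonize_gene_names(
    m: IntensityMatrix, alias_map: Mapping[str, str] | None = None
) -> IntensityMatrix:
    """Update outdated gene symbols and merge rows that collapse together.

    ``alias_map`` maps outdated symbol -> current symbol (case-insensitive);
    defaults to the shipped frozen snapshot. Unmapped symbols pass through
    (uppercased). Rows collapsing to one symbol merge with per-sample maximum
    intensity and OR-ed flags.
    """
    if alias_map is None:
        alias_map = GENE_ALIAS_SNAPSHOT
    lut = {str(k).upper(): str(v).upper() for k, v in alias_map.items()}
    new_index = [lut.get(g.upper(), g.upper()) for g in m.values.index]
    values = m.values.copy()
    values.index = pd.Index(new_index, name="gene")
    flags = m.flags.copy()
    flags.index = values.index
    values, flags = _merge_duplicate_symbols(values, flags)
    return IntensityMatrix(values=values, samples=m.samples.copy(), flags=flags)


def binarize(m: IntensityMatrix) -> DetectionMatrix:
    """Detection matrix: True exactly where intensity > 0."""
    return m.binarize()


# -- side-input readers -----------------------------------------------------


def read_marker_panel(path) -> MarkerPanel:
    """Marker panel TSV: cell_type, gene_symbol, rank (rank orders markers)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_type": str, "gene_symbol": str})
    required = ["cell_type", "gene_symbol", "rank"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"marker panel missing columns: {missing}")
    df = df.sort_values(["cell_type", "rank"], kind="stable")
    markers: dict[str, list[str]] = {}
    for ct, sub in df.groupby("cell_type", sort=False):
        markers[str(ct)] = [s.upper() for s in sub["gene_symbol"]]
    return MarkerPanel(markers=markers)


def read_clinical(path) -> pd.DataFrame:
    """Clinical CSV: patient_id, os_months (> 0), event (0/1 death observed)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = ["patient_id", "os_months", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    df = df[required].copy()
    df["os_months"] = df["os_months"].astype(float)
    df["event"] = df["event"].astype(int).astype(bool)
    if not np.all(np.isfinite(df["os_months"])) or (df["os_months"] <= 0).any():
        raise ValueError("os_months must be finite and positive")
    if df["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in clinical table")
    return df


def read_cell_proportions(path, renormalize: bool = True) -> pd.DataFrame:
    """FC proportion CSV: patient_id, cell_type, proportion in [0, 1].

    With ``renormalize`` (default) proportions are rescaled to sum to 1 per
    patient, as required after restricting to a subset of populations.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "cell_type": str})
    required = ["patient_id", "cell_type", "proportion"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cell proportion table missing columns: {missing}")
    df = df[required].copy()
    df["proportion"] = df["proportion"].astype(float)
    if ((df["proportion"] < 0) | (df["proportion"] > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    if renormalize:
        totals = df.groupby("patient_id")["proportion"].transform("sum")
        if (totals <= 0).any():
            raise ValueError("patient with all-zero proportions cannot be renormalized")
        df["proportion"] = df["proportion"] / totals
    else:
        totals = df.groupby("patient_id")["proportion"].sum()
        off = totals[(totals - 1.0).abs() > 1e-9]
        if len(off):
            raise ValueError(
                f"proportions do not sum to 1 for patients: {list(off.index)}"
            )
    return df


def read_misev(path) -> pd.DataFrame:
    """MISEV2018-style category table TSV: gene, category in 1..5."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    required = ["gene", "category"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"MISEV table missing columns: {missing}")
    df = df[required].copy()
    df["gene"] = df["gene"].str.upper()
    df["category"] = df["category"].astype(int)
    if (~df["category"].isin([1, 2, 3, 4, 5])).any():
        raise ValueError("MISEV categories must be in 1..5")
    return df


def read_ev_size_reference(path) -> pd.DataFrame:
    """Small/large-EV enrichment reference TSV: gene, p_value, fc_sev_lev."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    required = ["gene", "p_value", "fc_sev_lev"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"EV size reference missing columns: {missing}")
    df = df[required].copy()
    df["gene"] = df["gene"].str.upper()
    return df
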