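"""Shared in-memory containers for the ascitic-EV proteome pipeline.

The central object is :class:`IntensityMatrix`: a proteins x samples table of
non-negative label-free MS intensities, where an intensity of exactly zero
encodes "protein not detected in this sample". Samples are keyed by
(patient, fraction, cohort):

* fraction ``U`` -- EVs isolated by differential ultracentrifugation with a
  sucrose-cushion flotation step,
* fraction ``S`` -- the EV-rich size-exclusion chromatography fractions,
* fraction ``B`` -- the bulk-protein SEC fractions, used as a per-patient
  background of co-isolated non-EV proteins,

with cohort ``HGSC`` (patients) or ``CONTROL`` (non-malignant fluids,
typically fraction U only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FRACTIONS = ("U", "S", "B")
COHORTS = ("HGSC", "CONTROL")

#: columns required in the sample annotation table (indexed by sample id)
SAMPLE_COLUMNS = ("patient_id", "fraction", "cohort")

#: per-protein flag columns carried alongside the matrix
FLAG_COLUMNS = (
    "fasta_header",
    "is_reverse",
    "is_crap_contaminant",
    "is_only_identified_by_site",
)


def make_sample_table(records: Iterable[tuple[str, str, str, str]]) -> pd.DataFrame:
    """Build a sample annotation table from (sample_id, patient, fraction, cohort)."""
    rows = list(records)
    df = pd.DataFrame(rows, columns=["sample_id", *SAMPLE_COLUMNS])
    df = df.set_index("sample_id")
    _validate_sample_table(df)
    return df


def _validate_sample_table(samples: pd.DataFrame) -> None:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    bad_frac = set(samples["fraction"]) - set(FRACTIONS)
    if bad_frac:
        raise ValueError(f"unknown fractions {sorted(bad_frac)}; expected {FRACTIONS}")
    bad_cohort = set(samples["cohort"]) - set(COHORTS)
    if bad_cohort:
        raise ValueError(f"unknown cohorts {sorted(bad_cohort)}; expected {COHORTS}")
    dup = samples.duplicated(subset=["patient_id", "fraction"])
    if dup.any():
        pairs = samples.loc[dup, ["patient_id", "fraction"]].itertuples(index=False)
        raise ValueError(
            "duplicate (patient_id, fraction) pairs: " + ", ".join(map(str, pairs))
        )


def empty_flags(genes: Sequence[str]) -> pd.DataFrame:
    """Default per-protein flags: no FASTA header, nothing flagged."""
    return pd.DataFrame(
        {
            "fasta_header": ["" for _ in genes],
            "is_reverse": False,
            "is_crap_contaminant": False,
            "is_only_identified_by_site": False,
        },
        index=pd.Index(genes, name="gene"),
    )


@dataclass
class IntensityMatrix:
    """Proteins x samples label-free intensity matrix with sample keys.

    Parameters
    ----------
    values : DataFrame
        Genes (index) x sample ids (columns), non-negative floats; 0 means
        "not detected".
    samples : DataFrame
        Indexed by sample id with columns patient_id, fraction, cohort;
        must cover exactly the columns of ``values``.
    flags : DataFrame, optional
        Per-gene search-engine flags (see :data:`FLAG_COLUMNS`). Defaults to
        an all-clear table.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    flags: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _validate_sample_table(self.samples)
        if list(self.values.columns) != list(self.samples.index):
            if set(self.values.columns) == set(self.samples.index):
                self.samples = self.samples.loc[list(self.values.columns)]
            else:
                raise ValueError("values columns and sample table index disagree")
        vals = self.values.to_numpy(dtype=float, copy=False)
        if vals.size and np.nanmin(vals) < 0:
            raise ValueError("intensities must be non-negative (0 = not detected)")
        if self.values.isna().any().any():
            self.values = self.values.fillna(0.0)
        if self.flags is None:
            self.flags = empty_flags(list(self.values.index))
        else:
            missing = [c for c in FLAG_COLUMNS if c not in self.flags.columns]
            if missing:
                raise ValueError(f"flags table missing columns: {missing}")
            if not self.flags.index.equals(self.values.index):
                self.flags = self.flags.reindex(self.values.index)
                self.flags["fasta_header"] = self.flags["fasta_header"].fillna("")
                for c in FLAG_COLUMNS[1:]:
                    self.flags[c] = self.flags[c].fillna(False).astype(bool)
        self.values.index.name = "gene"

    # -- axis helpers ------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def patients(self, cohort: str = "HGSC") -> list[str]:
        mask = self.samples["cohort"] == cohort
        seen: dict[str, None] = {}
        for pid in self.samples.loc[mask, "patient_id"]:
            seen.setdefault(pid, None)
        return list(seen)

    def has_sample(self, patient_id: str, fraction: str) -> bool:
        mask = (self.samples["patient_id"] == patient_id) & (
            self.samples["fraction"] == fraction
        )
        return bool(mask.any())

    def sample_for(self, patient_id: str, fraction: str) -> str:
        """Sample id for (patient, fraction); KeyError if absent."""
        mask = (self.samples["patient_id"] == patient_id) & (
            self.samples["fraction"] == fraction
        )
        ids = list(self.samples.index[mask])
        if not ids:
            raise KeyError(f"no {fraction} sample for patient {patient_id!r}")
        return ids[0]

    # -- subsetting --------------------------------------------------------

    def subset_samples(self, sample_ids: Sequence[str]) -> "IntensityMatrix":
        return IntensityMatrix(
            values=self.values[list(sample_ids)].copy(),
            samples=self.samples.loc[list(sample_ids)].copy(),
            flags=self.flags.copy(),
        )

    def subset_cohort(self, cohort: str) -> "IntensityMatrix":
        ids = list(self.samples.index[self.samples["cohort"] == cohort])
        return self.subset_samples(ids)

    def fraction_frame(self, fraction: str, cohort: str = "HGSC") -> pd.DataFrame:
        """Genes x patient_id intensity frame for one fraction of one cohort."""
        mask = (self.samples["fraction"] == fraction) & (
            self.samples["cohort"] == cohort
        )
        ids = list(self.samples.index[mask])
        frame = self.values[ids].copy()
        frame.columns = list(self.samples.loc[ids, "patient_id"])
        return frame

    # -- derivation --------------------------------------------------------

    def binarize(self) -> "DetectionMatrix":
        """Detection = intensity strictly greater than zero."""
        vals = self.values.to_numpy(dtype=float)
        if vals.size and vals.min() < 0:
            raise ValueError("negative intensity: matrix invariant violated")
        return DetectionMatrix(values=self.values > 0, samples=self.samples.copy())

    def equals(self, other: "IntensityMatrix") -> bool:
        return (
            self.values.equals(other.values)
            and self.samples.equals(other.samples)
            and self.flags.equals(other.flags)
        )


@dataclass
class DetectionMatrix:
    """Boolean presence/absence matrix sharing axes with an IntensityMatrix."""

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_sample_table(self.samples)
        if list(self.values.columns) != list(self.samples.index):
            if set(self.values.columns) == set(self.samples.index):
                self.samples = self.samples.loc[list(self.values.columns)]
            else:
                raise ValueError("values columns and sample table index disagree")
        self.values = self.values.astype(bool)
        self.values.index.name = "gene"

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def patients(self, cohort: str = "HGSC") -> list[str]:
        mask = self.samples["cohort"] == cohort
        seen: dict[str, None] = {}
        for pid in self.samples.loc[mask, "patient_id"]:
            seen.setdefault(pid, None)
        return list(seen)

    def has_sample(self, patient_id: str, fraction: str) -> bool:
        mask = (self.samples["patient_id"] == patient_id) & (
            self.samples["fraction"] == fraction
        )
        return bool(mask.any())

    def sample_for(self, patient_id: str, fraction: str) -> str:
        mask = (self.samples["patient_id"] == patient_id) & (
            self.samples["fraction"] == fraction
        )
        ids = list(self.samples.index[mask])
        if not ids:
            raise KeyError(f"no {fraction} sample for patient {patient_id!r}")
        return ids[0]

    def detected(self, gene: str, patient_id: str, fraction: str) -> bool:
        return bool(self.values.at[gene, self.sample_for(patient_id, fraction)])

    def detected_genes(self, sample_id: str) -> frozenset[str]:
        col = self.values[sample_id]
        return frozenset(col.index[col])

    def subset_cohort(self, cohort: str) -> "DetectionMatrix":
        ids = list(self.samples.index[self.samples["cohort"] == cohort])
        return DetectionMatrix(
            values=self.values[ids].copy(), samples=self.samples.loc[ids].copy()
        )


@dataclass
class MarkerPanel:
    """Cell type -> ordered marker gene list (rank = differential-expression order)."""

    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        for cell_type, genes in self.markers.items():
            if not genes:
                raise ValueError(f"cell type {cell_type!r} has no markers")
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate markers within cell type {cell_type!r}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.markers)

    def all_genes(self) -> list[str]:
        out: list[str] = []
        for genes in self.markers.values():
            out.extend(genes)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (ct, g, rank + 1)
            for ct, genes in self.markers.items()
            for rank, g in enumerate(genes)
        ]
        return pd.DataFrame(rows, columns=["cell_type", "gene_symbol", "rank"])
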