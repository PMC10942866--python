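"""Per-patient EV protein sets, core lists and disease-specific lists.

The primitive is per-patient set algebra over the detection matrix. For each
patient, the EV set ``S&U \\ B`` contains the genes detected by both isolation
methods (fractions S and U) and absent from the patient's bulk-protein
background (fraction B). Pooling these over patients yields:

* the *core* set at 100% stringency (genes in every patient's set) and at a
  configurable threshold fraction (default 0.8: genes in at least
  ceil(0.8 * n) patients, i.e. >= 9 of 11),
* the *stringent disease-specific* set: core genes not detected in any
  control sample,
* the *augmented disease-specific* set: a looser base of genes found in
  >= threshold patients' U-minus-B, required to be seen by the orthogonal
  method (any S sample) and absent from every control.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .containers import DetectionMatrix


@dataclass(frozen=True)
class PatientSet:
    patient_id: str
    proteins: frozenset[str]


@dataclass
class CoreSetResult:
    per_patient: list[PatientSet]
    frequency: dict[str, int]
    su100: frozenset[str]
    su80: frozenset[str]
    n_patients: int
    threshold_fraction: float
    min_patients: int

    def __post_init__(self) -> None:
        assert self.su100 <= self.su80, "su100 must be a subset of su80"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, n, g in self.su100, g in self.su80)
            for g, n in sorted(self.frequency.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "n_patients", "su100", "su80"])


@dataclass
class HgscSpecificResult:
    stringent: frozenset[str]
    augmented: frozenset[str]
    control_detected: frozenset[str]

    def __post_init__(self) -> None:
        assert self.stringent <= self.augmented
        assert not (self.stringent & self.control_detected)
        assert not (self.augmented & self.control_detected)

    @property
    def augmented_only(self) -> frozenset[str]:
        return self.augmented - self.stringent

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, "stringent") for g in sorted(self.stringent)]
        rows += [(g, "augmented") for g in sorted(self.augmented_only)]
        return pd.DataFrame(rows, columns=["gene", "provenance"])


def su_minus_b(d: DetectionMatrix, patient_id: str) -> PatientSet:
    """Genes detected in both S and U of a patient and absent from B.

    Raises KeyError if the patient lacks any of the three fractions.
    """
    u = d.detected_genes(d.sample_for(patient_id, "U"))
    s = d.detected_genes(d.sample_for(patient_id, "S"))
    b = d.detected_genes(d.sample_for(patient_id, "B"))
    return PatientSet(patient_id=patient_id, proteins=(u & s) - b)


def per_patient_sets(d: DetectionMatrix, cohort: str = "HGSC") -> list[PatientSet]:
    """S&U-minus-B sets for every cohort patient carrying all three fractions."""
    out = []
    for pid in d.patients(cohort):
        if all(d.has_sample(pid, f) for f in ("U", "S", "B")):
            out.append(su_minus_b(d, pid))
    return out


def core_sets(
    sets: Sequence[PatientSet],
    threshold_fraction: float = 0.8,
    min_patients: int | None = None,
) -> CoreSetResult:
    """Pool per-patient sets into 100% and >= threshold-fraction core lists.

    ``min_patients`` overrides the derived integer threshold
    ceil(threshold_fraction * n); for the 11-patient cohort the default
    reproduces "found in >= 9 of 11".
    """
    if not sets:
        raise ValueError("at least one patient set is required")
    n = len(sets)
    if min_patients is None:
        min_patients = math.ceil(threshold_fraction * n)
    freq: Counter[str] = Counter()
    for ps in sets:
        freq.update(ps.proteins)
    su100 = frozenset(g for g, c in freq.items() if c == n)
    su80 = frozenset(g for g, c in freq.items() if c >= min_patients)
    return CoreSetResult(
        per_patient=list(sets),
        frequency=dict(freq),
        su100=su100,
        su80=su80,
        n_patients=n,
        threshold_fraction=threshold_fraction,
        min_patients=min_patients,
    )


def control_detected_genes(d: DetectionMatrix) -> frozenset[str]:
    """Genes with intensity > 0 in at least one control sample (any fraction)."""
    ids = list(d.samples.index[d.samples["cohort"] == "CONTROL"])
    if not ids:
        raise ValueError("no control samples present")
    mask = d.values[ids].any(axis=1)
    return frozenset(d.values.index[mask])


def stringent_specific(
    core: CoreSetResult, control_detection: DetectionMatrix, base: str = "su80"
) -> frozenset[str]:
    """Core genes never detected in any control sample.

    ``base`` selects the starting core list ("su80", the default, or "su100").
    Raises ValueError when no control samples exist (the subtraction would be
    undefined).
    """
    if base not in ("su80", "su100"):
        raise ValueError("base must be 'su80' or 'su100'")
    detected = control_detected_genes(control_detection)
    base_set = core.su80 if base == "su80" else core.su100
    return frozenset(base_set - detected)


def augmented_specific(
    d: DetectionMatrix,
    threshold_fraction: float = 0.8,
    min_patients: int | None = None,
) -> frozenset[str]:
    """Looser disease-specific list anchored on U-minus-B frequency.

    Candidates are genes detected in U and not in B for at least
    ``min_patients`` HGSC patients (default ceil(0.8 * n)); kept if detected
    in at least one S sample of any HGSC patient and in zero control samples.
    """
    patients = [
        pid
        for pid in d.patients("HGSC")
        if d.has_sample(pid, "U") and d.has_sample(pid, "B")
    ]
    if not patients:
        raise ValueError("no HGSC patients with both U and B fractions")
    s_ids = [
        d.sample_for(pid, "S") for pid in d.patients("HGSC") if d.has_sample(pid, "S")
    ]
    if not s_ids:
        raise ValueError("no S samples available for the orthogonal-method criterion")
    control_detected = control_detected_genes(d)  # raises if no controls

    n = len(patients)
    if min_patients is None:
        min_patients = math.ceil(threshold_fraction * n)
    freq: Counter[str] = Counter()
    for pid in patients:
        u = d.detected_genes(d.sample_for(pid, "U"))
        b = d.detected_genes(d.sample_for(pid, "B"))
        freq.update(u - b)
    candidates = {g for g, c in freq.items() if c >= min_patients}
    in_any_s = frozenset(d.values.index[d.values[s_ids].any(axis=1)])
    return frozenset((candidates & in_any_s) - control_detected)


def hgsc_specific(
    d: DetectionMatrix,
    core: CoreSetResult,
    stringent_base: str = "su80",
    threshold_fraction: float = 0.8,
) -> HgscSpecificResult:
    """Compose the stringent and augmented disease-specific lists.

    The returned ``augmented`` set is the union of the stringent list with the
    augmented-pipeline output (the stringent genes satisfy the looser criteria
    by construction, so the union is typically a superset relation check).
    """
    stringent = stringent_specific(core, d, base=stringent_base)
    augmented = augmented_specific(d, threshold_fraction=threshold_fraction)
    return HgscSpecificResult(
        stringent=stringent,
        augmented=frozenset(stringent | augmented),
        control_detected=control_detected_genes(d),
    )


@dataclass
class UpsetResult:
    """Exclusive-intersection counts over patient membership patterns."""

    patients: list[str]
    patterns: pd.DataFrame  # one bool column per patient + 'count'
    union_size: int

    def __post_init__(self) -> None:
        assert int(self.patterns["count"].sum()) == self.union_size


MAX_UPSET_PATIENTS = 20


def upset_counts(sets: Sequence[PatientSet]) -> UpsetResult:
    """Count genes per exclusive membership pattern across patient sets.

    Only patterns with at least one gene are emitted (guarding the 2^n
    blow-up); at most :data:`MAX_UPSET_PATIENTS` sets are accepted.
    """
    if len(sets) > MAX_UPSET_PATIENTS:
        raise ValueError(f"upset_counts capped at {MAX_UPSET_PATIENTS} patients")
    patients = [ps.patient_id for ps in sets]
    membership: dict[str, tuple[bool, ...]] = {}
    union: set[str] = set()
    for ps in sets:
        union |= ps.proteins
    for g in union:
        membership[g] = tuple(g in ps.proteins for ps in sets)
    counts = Counter(membership.values())
    rows = [
        [*pattern, count]
        for pattern, count in sorted(
            counts.items(), key=lambda kv: (-sum(kv[0]), kv[0])
        )
    ]
    patterns = pd.DataFrame(rows, columns=[*patients, "count"])
    return UpsetResult(patients=patients, patterns=patterns, union_size=len(union))


@dataclass
class MisevOverlap:
    n_genes: int
    n_overlap: int
    pct: float
    per_category: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, n) for c, n in sorted(self.per_category.items())]
        return pd.DataFrame(rows, columns=["category", "n_overlap"])


def misev_overlap(genes: Iterable[str], misev: pd.DataFrame) -> MisevOverlap:
    """Overlap of a gene set with a MISEV-style category table.

    The percentage is 100 * overlap / |genes|, reported to two decimals
    (0.00 for an empty gene set).
    """
    gene_set = {str(g).upper() for g in genes}
    cat = dict(zip(misev["gene"], misev["category"]))
    overlap = gene_set & set(cat)
    per_category: Counter[int] = Counter(cat[g] for g in overlap)
    pct = 100.0 * len(overlap) / len(gene_set) if gene_set else 0.0
    return MisevOverlap(
        n_genes=len(gene_set),
        n_overlap=len(overlap),
        pct=float(round(pct, 2)),
        per_category={c: per_category.get(c, 0) for c in (1, 2, 3, 4, 5)},
    )
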