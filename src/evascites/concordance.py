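"""Agreement between EV-derived cell-type signals and orthogonal measurements.

Four statistics quantify concordance:

* the enrichment coefficient EC = (% of cell-type-specific EV signal) /
  (% of that cell type among ascitic cells by flow cytometry), per patient
  and cell type, with arithmetic per-type means;
* the repeated-measures correlation r_rm: the common within-subject linear
  association between two measurements, estimated from an ANCOVA with
  subject-specific intercepts (response y, covariate x, subject as additive
  factor), with df = n_obs - n_subjects - 1;
* Pearson correlation of log-transformed intensities between the two EV
  isolation methods, over (protein, patient) pairs quantified by both;
* one-way repeated-measures ANOVA of the ECs with cell type as the
  within-subject factor.

p-values are two-sided throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .deconvolution import DEFAULT_CELL_TYPES, ContributionTable

logger = logging.getLogger(__name__)


# -- enrichment coefficient -------------------------------------------------


@dataclass
class EnrichmentResult:
    """Per-entry enrichment coefficients and per-cell-type means."""

    table: pd.DataFrame  # patient_id, cell_type, pct_ev, pct_cells, ec
    type_means: dict[str, float]
    n_undefined: int

    def summary(self) -> str:
        lines = ["Enrichment coefficients (EC = %EV / %cells)"]
        for ct, m in self.type_means.items():
            lines.append(f"  {ct}: mean EC {m:.3g}")
        if self.n_undefined:
            lines.append(f"  undefined ECs excluded: {self.n_undefined}")
        return "\n".join(lines)


def enrichment_coefficient(
    contrib: ContributionTable | pd.DataFrame,
    cells: pd.DataFrame,
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES,
) -> EnrichmentResult:
    """EC per (patient, cell type), restricted and renormalized to 100%.

    ``cells`` is the flow-cytometry proportion table (patient_id, cell_type,
    proportion in [0, 1]); proportions are restricted to ``cell_types`` and
    renormalized. EV percentages are renormalized over the same types.
    Entries with a zero cell percentage have undefined EC and are excluded
    from the per-type means (counted in ``n_undefined``).
    """
    ev = contrib.table if isinstance(contrib, ContributionTable) else contrib
    ev = ev[ev["cell_type"].isin(cell_types)].copy()
    cells = cells[cells["cell_type"].isin(cell_types)].copy()
    patients = sorted(set(ev["patient_id"]) & set(cells["patient_id"]))
    if not patients:
        raise ValueError("no shared patients between EV contributions and FC table")

    ev_wide = ev.pivot(index="patient_id", columns="cell_type", values="contribution_pct")
    ev_wide = ev_wide.loc[patients, list(cell_types)]
    ev_wide = ev_wide.div(ev_wide.sum(axis=1), axis=0) * 100.0
    cell_wide = cells.pivot(index="patient_id", columns="cell_type", values="proportion")
    cell_wide = cell_wide.loc[patients, list(cell_types)].fillna(0.0)
    cell_wide = cell_wide.div(cell_wide.sum(axis=1), axis=0) * 100.0

    rows = []
    n_undefined = 0
    for pid in patients:
        for ct in cell_types:
            pct_ev = float(ev_wide.at[pid, ct])
            pct_cells = float(cell_wide.at[pid, ct])
            if pct_cells > 0:
                ec = pct_ev / pct_cells
            else:
                ec = float("nan")
                n_undefined += 1
            rows.append((pid, ct, pct_ev, pct_cells, ec))
    table = pd.DataFrame(
        rows, columns=["patient_id", "cell_type", "pct_ev", "pct_cells", "ec"]
    )
    type_means = {
        ct: float(table.loc[table["cell_type"] == ct, "ec"].dropna().mean())
        for ct in cell_types
    }
    if n_undefined:
        logger.info("excluded %d undefined ECs (zero cell percentage)", n_undefined)
    return EnrichmentResult(table=table, type_means=type_means, n_undefined=n_undefined)


# -- repeated-measures correlation ------------------------------------------


@dataclass
class RmCorrResult:
    r_rm: float
    df: int
    p_value: float
    n_subjects: int
    n_obs: int
    slope: float
    degenerate: bool = False

    def summary(self) -> str:
        return (
            f"Repeated-measures correlation: r_rm = {self.r_rm:.4f}, "
            f"df = {self.df}, p = {self.p_value:.4g} "
            f"({self.n_subjects} subjects, {self.n_obs} observations)"
            + (" [degenerate]" if self.degenerate else "")
        )


class RepeatedMeasuresCorrelation:
    """Common within-subject correlation between paired repeated measurements.

    Fits y = subject intercepts + beta * x by least squares and decomposes
    the ANCOVA sums of squares: r_rm = sign(beta) * sqrt(SS_x / (SS_x +
    SS_error)), tested on t with df = n_obs - n_subjects - 1.
    """

    def __init__(self, x, y, subject) -> None:
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.subject = np.asarray(subject)
        if not (len(self.x) == len(self.y) == len(self.subject)):
            raise ValueError("x, y and subject must have equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("x and y must be finite")
        counts = pd.Series(self.subject).value_counts()
        if len(counts) < 2:
            raise ValueError("at least two subjects are required")
        if (counts < 2).any():
            raise ValueError("every subject needs at least two observations")

    def fit(self) -> RmCorrResult:
        subjects, idx = np.unique(self.subject, return_inverse=True)
        n_obs, n_sub = len(self.x), len(subjects)
        dummies = np.eye(n_sub)[idx]
        reduced = dummies
        full = np.column_stack([dummies, self.x])

        beta_full, *_ = np.linalg.lstsq(full, self.y, rcond=None)
        sse_full = float(np.sum((self.y - full @ beta_full) ** 2))
        beta_red, *_ = np.linalg.lstsq(reduced, self.y, rcond=None)
        sse_red = float(np.sum((self.y - reduced @ beta_red) ** 2))
        ss_x = max(sse_red - sse_full, 0.0)
        slope = float(beta_full[-1])

        # within-subject variation of x must exist for the slope to be defined
        subj_mean_x = np.array([self.x[idx == i].mean() for i in range(n_sub)])
        degenerate = bool(np.allclose(self.x - subj_mean_x[idx], 0.0))

        denom = ss_x + sse_full
        if denom <= 0 or degenerate:
            return RmCorrResult(
                r_rm=float("nan"), df=n_obs - n_sub - 1, p_value=float("nan"),
                n_subjects=n_sub, n_obs=n_obs, slope=slope, degenerate=True,
            )
        r = math.copysign(math.sqrt(ss_x / denom), slope if slope != 0 else 1.0)
        df = n_obs - n_sub - 1
        if df <= 0:
            return RmCorrResult(
                r_rm=r, df=df, p_value=float("nan"), n_subjects=n_sub,
                n_obs=n_obs, slope=slope, degenerate=True,
            )
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt(df / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), df))
        return RmCorrResult(
            r_rm=float(r), df=df, p_value=p, n_subjects=n_sub, n_obs=n_obs,
            slope=slope, degenerate=False,
        )


def rmcorr(x, y, subject) -> RmCorrResult:
    """Convenience wrapper around :class:`RepeatedMeasuresCorrelation`."""
    return RepeatedMeasuresCorrelation(x, y, subject).fit()


# -- Pearson on log intensities ---------------------------------------------


@dataclass
class PearsonLogResult:
    r: float
    p_value: float
    n_pairs: int


def pearson_log(
    u: pd.DataFrame, s: pd.DataFrame, pseudocount: float | None = None
) -> PearsonLogResult:
    """Pearson correlation of log intensities between two isolation methods.

    ``u`` and ``s`` are genes x patients intensity frames for the same
    patients (U and S fractions). By default only (protein, patient) pairs
    with intensity > 0 in both fractions enter (zeros have no logarithm);
    passing a ``pseudocount`` instead log-transforms intensity + pseudocount
    for all pairs. Natural log; Pearson r is base-invariant.
    """
    genes = u.index.intersection(s.index)
    patients = [c for c in u.columns if c in set(s.columns)]
    a = u.loc[genes, patients].to_numpy(dtype=float).ravel()
    b = s.loc[genes, patients].to_numpy(dtype=float).ravel()
    if pseudocount is None:
        mask = (a > 0) & (b > 0)
        la, lb = np.log(a[mask]), np.log(b[mask])
    else:
        la, lb = np.log(a + pseudocount), np.log(b + pseudocount)
    if la.size < 3:
        raise ValueError("fewer than 3 qualifying (protein, patient) pairs")
    r, p = stats.pearsonr(la, lb)
    return PearsonLogResult(r=float(r), p_value=float(p), n_pairs=int(la.size))


# -- repeated-measures ANOVA ------------------------------------------------


@dataclass
class RmAnovaResult:
    F: float
    df1: int
    df2: int
    p_value: float
    n_subjects: int
    n_conditions: int
    dropped_subjects: frozenset[str]

    def summary(self) -> str:
        return (
            f"One-way repeated-measures ANOVA: F({self.df1}, {self.df2}) = "
            f"{self.F:.4f}, p = {self.p_value:.4g}"
        )


def rm_anova(values: pd.DataFrame) -> RmAnovaResult:
    """One-way within-subject ANOVA on a subjects x conditions value grid.

    Subjects with any missing condition are dropped (logged). Standard
    decomposition: SS_conditions (df k-1), SS_subjects, SS_error
    (df (k-1)(n-1)); F = MS_conditions / MS_error.
    """
    complete = values.dropna(axis=0)
    dropped = frozenset(str(s) for s in values.index.difference(complete.index))
    if dropped:
        logger.info("rm_anova dropped incomplete subjects: %s", sorted(dropped))
    data = complete.to_numpy(dtype=float)
    n, k = data.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 subjects and 2 within-subject conditions")
    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * float(np.sum((cond_means - grand) ** 2))
    ss_subj = k * float(np.sum((subj_means - grand) ** 2))
    ss_total = float(np.sum((data - grand) ** 2))
    ss_error = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_error = ss_error / df2
    if ms_error <= 0:
        f_stat, p = (0.0, 1.0) if ss_cond <= 1e-300 else (float("inf"), 0.0)
    else:
        f_stat = (ss_cond / df1) / ms_error
        p = float(stats.f.sf(f_stat, df1, df2))
    return RmAnovaResult(
        F=float(f_stat), df1=df1, df2=df2, p_value=p,
        n_subjects=n, n_conditions=k, dropped_subjects=dropped,
    )


def rm_anova_ec(ec: EnrichmentResult) -> RmAnovaResult:
    """RM-ANOVA of enrichment coefficients with cell type as within factor."""
    wide = ec.table.pivot(index="patient_id", columns="cell_type", values="ec")
    return rm_anova(wide)
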