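"""Constrained cutoff-scan survival analysis over EV markers and cell types.

Each continuous feature (a marker's U-fraction intensity, or a cell type's
flow-cytometry proportion) is dichotomized at every admissible cutoff:
candidate cutoffs are midpoints between consecutive distinct sorted values,
kept only if they exceed the configured floor (100,000 for label-free
intensities; no floor for proportions) and split the cohort into a high group
(value strictly above the cutoff) and a low group of at least ``min_group``
patients each. The cutoff minimizing the two-group log-rank p-value is
selected (ties broken toward the smallest cutoff) and the hazard ratio of
high vs low at that split is estimated by a univariate Cox model with Efron
tie handling.

Minimal-p cutoff selection is optimistic: the selected p-values are not
type-I-calibrated. Scan outputs always carry that label, and an optional
permutation-adjusted p (re-running the full scan on permuted survival data)
is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DetectionMatrix, MarkerPanel

logger = logging.getLogger(__name__)

EXPLORATORY_NOTE = (
    "exploratory; cutoff-optimized p-values are not type-I-calibrated"
)

DEFAULT_EXTRA_MARKERS = ("MRC1", "IDH2", "FAS", "ITGB8")
INTENSITY_FLOOR = 1e5


# -- marker selection --------------------------------------------------------


@dataclass
class MarkerSelection:
    genes: list[str]  # ordered, deduplicated

    def __post_init__(self) -> None:
        assert len(set(self.genes)) == len(self.genes)


def select_survival_markers(
    d_u: DetectionMatrix,
    d_s: DetectionMatrix,
    panel: MarkerPanel,
    extra: tuple[str, ...] = DEFAULT_EXTRA_MARKERS,
) -> MarkerSelection:
    """Panel markers detected by both isolation methods, plus extra genes.

    A panel gene qualifies when detected in at least one U sample and at
    least one S sample. Extra genes (default the four disease-specific
    cell-type-restricted proteins) are appended when detected in at least one
    U sample; duplicates already selected from the panel appear once.
    """
    u_ids = list(
        d_u.samples.index[
            (d_u.samples["cohort"] == "HGSC") & (d_u.samples["fraction"] == "U")
        ]
    )
    s_ids = list(
        d_s.samples.index[
            (d_s.samples["cohort"] == "HGSC") & (d_s.samples["fraction"] == "S")
        ]
    )
    in_u = set(d_u.values.index[d_u.values[u_ids].any(axis=1)])
    in_s = set(d_s.values.index[d_s.values[s_ids].any(axis=1)])
    genes: list[str] = []
    for g in panel.all_genes():
        if g in in_u and g in in_s and g not in genes:
            genes.append(g)
    for g in extra:
        g = g.upper()
        if g in in_u and g not in genes:
            genes.append(g)
    return MarkerSelection(genes=genes)


# -- log-rank test -----------------------------------------------------------


def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test.

    chi2 = (sum_j (O1j - E1j))^2 / sum_j V1j over distinct event times j,
    with the hypergeometric variance V1j and pooled risk sets (standard
    handling of tied event times); p from chi-square with 1 df.

    ``group`` is binary (0/1 or bool); both groups must be non-empty and at
    least one event must be observed.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(group).astype(int)
    if set(np.unique(g)) - {0, 1}:
        raise ValueError("group must be binary")
    if (g == 1).sum() == 0 or (g == 0).sum() == 0:
        raise ValueError("both groups must be non-empty")
    if not e.any():
        raise ValueError("log-rank test requires at least one observed event")

    obs_minus_exp = 0.0
    var_sum = 0.0
    for tj in np.unique(t[e]):
        at_risk = t >= tj
        n = int(at_risk.sum())
        n1 = int((at_risk & (g == 1)).sum())
        dying = e & (t == tj)
        d = int(dying.sum())
        d1 = int((dying & (g == 1)).sum())
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var_sum += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var_sum <= 0:
        return 0.0, 1.0
    chi2 = obs_minus_exp**2 / var_sum
    return float(chi2), float(stats.chi2.sf(chi2, 1))


# -- univariate Cox model (binary covariate, Efron ties) ---------------------


@dataclass
class CoxBinaryResult:
    hr: float
    beta: float
    se_log_hr: float
    converged: bool
    monotone: bool = False  # all events in one group; beta diverges

    def summary(self) -> str:
        if self.monotone:
            return f"Cox (binary): monotone likelihood, HR -> {self.hr}"
        return (
            f"Cox (binary): HR = {self.hr:.4f} "
            f"(log HR {self.beta:.4f} +/- {self.se_log_hr:.4f})"
        )


def _cox_efron_loglik_derivs(beta, times, events, x):
    """Efron partial log-likelihood and its first two derivatives."""
    ll = 0.0
    d1 = 0.0
    d2 = 0.0
    eb = math.exp(beta)
    for tj in np.unique(times[events]):
        at_risk = times >= tj
        dying = events & (times == tj)
        d = int(dying.sum())
        dx = x[dying]
        ll += beta * float(dx.sum())
        # risk-set sums of x^k * exp(beta x): for binary x, exp(beta x) is
        # eb for x=1 and 1 for x=0
        r1 = int((at_risk & (x == 1)).sum())  # group-1 at risk
        r0 = int(at_risk.sum()) - r1
        s0_r = r0 + r1 * eb
        s1_r = r1 * eb  # also equals s2_r for binary x
        e1 = int(dx.sum())  # tied events in group 1
        s0_d = (d - e1) + e1 * eb
        s1_d = e1 * eb
        for ell in range(d):
            frac = ell / d
            s0 = s0_r - frac * s0_d
            s1 = s1_r - frac * s1_d
            ll -= math.log(s0)
            mean = s1 / s0
            d1 -= mean
            d2 -= mean * (1.0 - mean)  # s2 == s1 for binary covariate
        d1 += float(dx.sum())
    return ll, d1, d2


def cox_univariate_binary(
    times, events, group, tol: float = 1e-8, max_iter: int = 50
) -> CoxBinaryResult:
    """Maximum partial-likelihood HR for a single binary covariate.

    Newton-Raphson from beta = 0, Efron tie handling, convergence at
    |delta beta| < 1e-8 (max 50 iterations). When every event falls in one
    group the likelihood is monotone in beta; the estimate is reported as
    HR = inf (all events in the high group) or 0, flagged, instead of
    iterating to divergence.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    x = np.asarray(group).astype(int)
    if set(np.unique(x)) - {0, 1}:
        raise ValueError("group must be binary")
    if not e.any():
        raise ValueError("Cox model requires at least one observed event")
    events_high = int((e & (x == 1)).sum())
    events_low = int((e & (x == 0)).sum())
    if events_high == 0 or events_low == 0:
        hr = float("inf") if events_low == 0 else 0.0
        return CoxBinaryResult(
            hr=hr, beta=math.copysign(math.inf, hr - 1.0 if hr else -1.0),
            se_log_hr=float("inf"), converged=False, monotone=True,
        )

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        _, d1, d2 = _cox_efron_loglik_derivs(beta, t, e, x)
        if d2 >= 0:  # numerically flat; cannot step
            break
        step = d1 / d2
        beta_new = beta - step
        if abs(beta_new - beta) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
        if abs(beta) > 30:  # safeguard against undetected divergence
            break
    _, _, d2 = _cox_efron_loglik_derivs(beta, t, e, x)
    se = math.sqrt(-1.0 / d2) if d2 < 0 else float("inf")
    return CoxBinaryResult(
        hr=float(math.exp(beta)), beta=float(beta), se_log_hr=float(se),
        converged=converged, monotone=False,
    )


# -- cutoff scan -------------------------------------------------------------


@dataclass
class SurvivalScanResult:
    feature_id: str
    cutoff: float = float("nan")
    n_high: int = 0
    n_low: int = 0
    logrank_chi2: float = float("nan")
    logrank_p: float = float("nan")
    hr: float = float("nan")
    hr_direction: str = "high_vs_low"
    hr_flag: str = ""  # "monotone" when the Cox likelihood diverged
    p_perm: float = float("nan")
    n_candidates: int = 0
    empty: bool = False  # no admissible cutoff
    note: str = EXPLORATORY_NOTE

    def to_dict(self) -> dict:
        return {
            "feature": self.feature_id,
            "cutoff": self.cutoff,
            "n_high": self.n_high,
            "n_low": self.n_low,
            "chi2": self.logrank_chi2,
            "p": self.logrank_p,
            "p_perm": self.p_perm,
            "hr": self.hr,
            "hr_flag": self.hr_flag,
            "empty": self.empty,
        }


def _admissible_cutoffs(values: np.ndarray, min_group: int, floor: float | None):
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    out = []
    for c in mids:
        if floor is not None and not c > floor:
            continue
        n_high = int((values > c).sum())
        n_low = len(values) - n_high
        if n_high >= min_group and n_low >= min_group:
            out.append(float(c))
    return out


def cutoff_scan(
    values: pd.Series,
    clinical: pd.DataFrame,
    min_group: int = 3,
    floor: float | None = INTENSITY_FLOOR,
    feature_id: str = "feature",
    permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> SurvivalScanResult:
    """Scan all admissible dichotomizations of one feature for survival effect.

    Parameters
    ----------
    values : Series
        Feature value per patient (index = patient_id).
    clinical : DataFrame
        patient_id, os_months, event.
    min_group : int
        Minimum patients per side of the split.
    floor : float or None
        Cutoffs must strictly exceed this (use None for FC proportions).
    permutations : int
        If > 0, a permutation-adjusted p is computed by re-running the scan
        on survival data permuted across patients.

    Returns a flagged empty result (not an error) when no admissible cutoff
    exists or no event is observed among patients with data.
    """
    clin = clinical.set_index("patient_id")
    patients = [p for p in values.index if p in clin.index and np.isfinite(values[p])]
    if not patients:
        return SurvivalScanResult(feature_id=feature_id, empty=True)
    v = values.loc[patients].to_numpy(dtype=float)
    t = clin.loc[patients, "os_months"].to_numpy(dtype=float)
    e = clin.loc[patients, "event"].to_numpy(dtype=bool)

    candidates = _admissible_cutoffs(v, min_group, floor)
    if not candidates or not e.any():
        return SurvivalScanResult(
            feature_id=feature_id, empty=True, n_candidates=len(candidates)
        )

    def best_split(tt, ee):
        best = None
        for c in candidates:
            g = (v > c).astype(int)
            chi2, p = logrank_test(tt, ee, g)
            # candidates are ascending, so keeping the first strict minimum
            # breaks ties toward the smallest cutoff
            if best is None or p < best[1]:
                best = (c, p, chi2)
        return best

    cut, p, chi2 = best_split(t, e)
    g = (v > cut).astype(int)
    cox = cox_univariate_binary(t, e, g)

    p_perm = float("nan")
    if permutations > 0:
        if rng is None:
            rng = np.random.default_rng()
        hits = 0
        for _ in range(permutations):
            perm = rng.permutation(len(t))
            _, p_b, _ = best_split(t[perm], e[perm])
            if p_b <= p:
                hits += 1
        p_perm = (1 + hits) / (permutations + 1)

    return SurvivalScanResult(
        feature_id=feature_id,
        cutoff=float(cut),
        n_high=int(g.sum()),
        n_low=int(len(g) - g.sum()),
        logrank_chi2=float(chi2),
        logrank_p=float(p),
        hr=cox.hr,
        hr_flag="monotone" if cox.monotone
        else ("nonconverged" if not cox.converged else ""),
        p_perm=p_perm,
        n_candidates=len(candidates),
        empty=False,
    )


# -- whole-panel scan --------------------------------------------------------


@dataclass
class SurvivalScanResults:
    results: list[SurvivalScanResult]
    min_group: int
    floor: float | None
    note: str = EXPLORATORY_NOTE

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results])

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            f"Cutoff-scan survival analysis ({len(self.results)} features, "
            f"min_group={self.min_group}, floor={self.floor})",
            f"NOTE: {self.note}",
        ]
        scanned = df[~df["empty"]]
        if len(scanned):
            lines.append(
                scanned.sort_values("p")[
                    ["feature", "cutoff", "n_high", "n_low", "p", "hr"]
                ].to_string(index=False)
            )
        n_empty = int(df["empty"].sum())
        if n_empty:
            lines.append(f"features without an admissible cutoff: {n_empty}")
        return "\n".join(lines)


class SurvivalCutoffScan:
    """Model-style scan over a feature matrix (features x patients).

    Examples
    --------
    >>> scan = SurvivalCutoffScan(features, clinical, floor=1e5)
    >>> res = scan.fit(permutations=1000, seed=17)
    >>> print(res.summary())
    """

    def __init__(
        self,
        features: pd.DataFrame,
        clinical: pd.DataFrame,
        min_group: int = 3,
        floor: float | None = INTENSITY_FLOOR,
    ) -> None:
        self.features = features
        self.clinical = clinical
        self.min_group = min_group
        self.floor = floor

    def fit(self, permutations: int = 0, seed: int | None = None) -> SurvivalScanResults:
        rng = np.random.default_rng(seed) if permutations > 0 else None
        results = [
            cutoff_scan(
                self.features.loc[fid],
                self.clinical,
                min_group=self.min_group,
                floor=self.floor,
                feature_id=str(fid),
                permutations=permutations,
                rng=rng,
            )
            for fid in self.features.index
        ]
        return SurvivalScanResults(
            results=results, min_group=self.min_group, floor=self.floor
        )


def scan_all_features(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    min_group: int = 3,
    floor: float | None = INTENSITY_FLOOR,
    permutations: int = 0,
    seed: int | None = None,
) -> SurvivalScanResults:
    """Functional front end for :class:`SurvivalCutoffScan`."""
    return SurvivalCutoffScan(features, clinical, min_group, floor).fit(
        permutations=permutations, seed=seed
    )
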