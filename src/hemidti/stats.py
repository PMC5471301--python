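"""Cross-sectional and longitudinal statistics of the asymmetry measure.

Own implementations of the Wilcoxon-Mann-Whitney test (exact by full
enumeration for small tie-free samples, tie-corrected normal approximation
otherwise) and Spearman rank correlation (exact permutation p for small n),
plus the cohort-level orchestration: group comparison with one scan per
patient per group, control noise level, and asymmetry-versus-time
correlation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from math import erf, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "NoiseLevel",
    "mann_whitney",
    "spearman",
    "noise_level",
    "crosssection",
    "longitudinal",
]

# 21 covers the 10-vs-11 group comparison the analysis is built around
EXACT_MAX_N = 21


@dataclass
class GroupComparison:
    labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sds: tuple[float, float]
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal-approximation"
    degenerate: bool = False


@dataclass
class CorrelationResult:
    n: int
    coefficient: float
    p_value: float
    tie_corrected: bool
    method: str  # "t-approximation" | "exact-permutation"
    undefined: bool = False


@dataclass
class NoiseLevel:
    values: np.ndarray
    max_abs: float
    sd: float
    percentile_95: float

    @property
    def summary(self) -> float:
        """Primary noise-level summary: the maximum absolute asymmetry."""
        return self.max_abs


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Number of (a, b) pairs with a > b, counting ties as half."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


@lru_cache(maxsize=64)
def _combo_indices(n_total: int, n_a: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n_total), n_a)), dtype=np.intp)


def _exact_p(pooled: np.ndarray, n_a: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating every group labeling of the pool."""
    n = len(pooled)
    idx = _combo_indices(n, n_a)
    ranks = rankdata(pooled)  # mid-ranks; U = R_a - n_a(n_a+1)/2 holds with ties
    ra = ranks[idx].sum(axis=1)
    u_all = ra - n_a * (n_a + 1) / 2.0
    mu = n_a * (n - n_a) / 2.0
    p = np.mean(np.abs(u_all - mu) >= np.abs(u_obs - mu) - 1e-12)
    return float(min(1.0, p))


def mann_whitney(a, b) -> GroupComparison:
    """Two-sided Wilcoxon-Mann-Whitney comparison of two samples.

    Exact by full enumeration of all C(n_a+n_b, n_a) labelings when the
    pooled sample has at most 21 observations and no ties; tie-corrected
    normal approximation with continuity correction otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    na, nb = len(a), len(b)
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])

    if np.ptp(pooled) == 0:
        return GroupComparison(("a", "b"), (na, nb),
                               (float(a.mean()), float(b.mean())),
                               (float(a.std(ddof=1)) if na > 1 else 0.0,
                                float(b.std(ddof=1)) if nb > 1 else 0.0),
                               u, 1.0, "degenerate", degenerate=True)

    has_ties = len(np.unique(pooled)) < len(pooled)
    if na + nb <= EXACT_MAX_N and not has_ties:
        p = _exact_p(pooled, na, u)
        method = "exact"
    else:
        mu = na * nb / 2.0
        n = na + nb
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        var = na * nb / 12.0 * (n + 1 - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / sqrt(var)
            z = max(z, 0.0)
            p = 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0))))
            p = float(min(1.0, p))
        method = "normal-approximation"
    return GroupComparison(("a", "b"), (na, nb),
                           (float(a.mean()), float(b.mean())),
                           (float(a.std(ddof=1)) if na > 1 else 0.0,
                            float(b.std(ddof=1)) if nb > 1 else 0.0),
                           u, p, method)


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    p-value from the t approximation for n >= 10 and from exact permutation
    of the rank pairing for n < 10. Constant inputs yield an undefined flag.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(n, float("nan"), float("nan"), False,
                                 "undefined", undefined=True)
    rx = rankdata(x)
    ry = rankdata(y)
    ties = (len(np.unique(x)) < n) or (len(np.unique(y)) < n)
    c = float(np.corrcoef(rx, ry)[0, 1])

    if n >= 10:
        if abs(c) >= 1.0:
            p = 0.0
        else:
            t = c * sqrt((n - 2) / (1.0 - c * c))
            p = float(2.0 * sps.t.sf(abs(t), n - 2))
        method = "t-approximation"
    else:
        perms = np.array(list(itertools.permutations(ry)))
        rx0 = rx - rx.mean()
        denom = np.sqrt((rx0**2).sum()) * np.sqrt(((ry - ry.mean()) ** 2).sum())
        cs = (perms - ry.mean()) @ rx0 / denom
        p = float(np.mean(np.abs(cs) >= abs(c) - 1e-12))
        method = "exact-permutation"
    return CorrelationResult(n, c, min(1.0, p), ties, method)


def noise_level(control_deltas) -> NoiseLevel:
    """Summaries of the signed control asymmetries.

    The primary summary is the maximum absolute value (the control spread
    bounds both decreases and increases); SD and the 95th percentile of
    absolute values are reported alongside.
    """
    v = np.asarray(control_deltas, float)
    if len(v) < 2:
        raise ValueError("need at least 2 control sessions")
    return NoiseLevel(values=v, max_abs=float(np.max(np.abs(v))),
                      sd=float(np.std(v, ddof=1)),
                      percentile_95=float(np.percentile(np.abs(v), 95)))


def _delta_table(manifest, delta_results, metric: str) -> pd.DataFrame:
    """Join manifest metadata onto results keyed by 'subject_id/session_id'."""
    rows = []
    by_id = {f"{s.subject_id}/{s.session_id}": s for s in manifest}
    for d in delta_results:
        s = by_id.get(d.session_id)
        if s is None:
            raise KeyError(f"session {d.session_id!r} not in manifest")
        rows.append({
            "subject_id": s.subject_id, "session_id": s.session_id,
            "group": s.group, "rt_status": s.rt_status,
            "delta_t_months": s.delta_t_months,
            "delta": d.global_deltas.get(metric, float("nan")),
            "valid": d.valid,
        })
    return pd.DataFrame(rows)


def crosssection(manifest, delta_results, metric: str = "FA") -> GroupComparison:
    """Pre/without-RT versus post-RT group comparison, one scan per patient.

    Each patient contributes at most one scan per group: the earliest
    available pre-RT scan and/or the earliest post-RT scan (by time since
    radiation, then session id).
    """
    df = _delta_table(manifest, delta_results, metric)
    df = df[(df.group == "patient") & df.valid]
    pre_vals, post_vals = [], []
    for _, sub in df.groupby("subject_id"):
        pre = sub[sub.rt_status == "pre"].sort_values(["delta_t_months", "session_id"])
        post = sub[sub.rt_status == "post"].sort_values(["delta_t_months", "session_id"])
        if len(pre):
            pre_vals.append(pre.iloc[0].delta)
        if len(post):
            post_vals.append(post.iloc[0].delta)
    if not pre_vals:
        raise ValueError("empty group: no pre/without-RT patient scans")
    if not post_vals:
        raise ValueError("empty group: no post-RT patient scans")
    out = mann_whitney(pre_vals, post_vals)
    out.labels = ("pre_rt", "post_rt")
    return out


def longitudinal(manifest, delta_results, metric: str = "FA",
                 min_scans_per_subject: int = 5):
    """Asymmetry-versus-time correlation over all patient scans.

    Pre-RT scans enter at dt = 0. Returns ``(overall, per_subject)`` where
    ``per_subject`` maps subject ids with at least ``min_scans_per_subject``
    scans to their own correlation result.
    """
    df = _delta_table(manifest, delta_results, metric)
    df = df[(df.group == "patient") & df.valid]
    if len(df) < 3:
        raise ValueError("need at least 3 patient sessions")
    overall = spearman(df.delta_t_months.to_numpy(), df.delta.to_numpy())
    per_subject = {}
    for sid, sub in df.groupby("subject_id"):
        if len(sub) >= min_scans_per_subject and sub.delta_t_months.nunique() > 1:
            per_subject[sid] = spearman(sub.delta_t_months.to_numpy(),
                                        sub.delta.to_numpy())
    return overall, per_subject
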