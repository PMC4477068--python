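"""Saline vs acetic-acid group comparison.

Every numeric parameter of the per-measurement summary panel is compared
between the two infusate conditions with the Mann-Whitney U test
(two-sided, no multiplicity adjustment), reported as mean +/- SD per group
with the U statistic, p-value and a significance flag at alpha = 0.05.

The U statistic is computed by midrank summation.  For small tie-free
samples (n_a + n_b <= 12) the two-sided p-value is exact, from the full
permutation distribution of U; otherwise the tie-corrected normal
approximation with continuity correction is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import StatsConfig
from .model import MeasurementSummary

__all__ = [
    "GroupComparison",
    "mann_whitney_u",
    "compare_groups",
    "comparisons_to_frame",
    "StatsError",
]


class StatsError(ValueError):
    """Raised for empty or malformed comparison inputs."""


@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    mean_saline: float
    sd_saline: float
    mean_aa: float
    sd_aa: float
    u_statistic: float
    p_value: float
    n_saline: int
    n_aa: int
    significant: bool


def _rank_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic for group a via midrank summation."""
    pooled = np.concatenate([a, b])
    order = pooled.argsort(kind="stable")
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1, dtype=float)
    # midranks for ties
    sorted_vals = pooled[order]
    i = 0
    while i < len(sorted_vals):
        j = i
        while j + 1 < len(sorted_vals) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        if j > i:
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2.0)


def _exact_u_counts(n_a: int, n_b: int) -> np.ndarray:
    """Null distribution of U as counts over 0..n_a*n_b.

    Standard recurrence c(m, n, u) = c(m-1, n, u-n) + c(m, n-1, u) — the
    largest pooled observation belongs to group a (adding n pairs to U) or
    to group b.  Identical to enumerating all C(n_a+n_b, n_a) equally
    likely rank assignments.
    """
    max_u = n_a * n_b
    # counts[m] holds c(m, n, .) for the current n; start at n = 0 where
    # the only configuration has U = 0
    counts = [np.zeros(max_u + 1) for _ in range(n_a + 1)]
    for m in range(n_a + 1):
        counts[m][0] = 1.0
    for n in range(1, n_b + 1):
        new = [np.zeros(max_u + 1) for _ in range(n_a + 1)]
        new[0][0] = 1.0
        for m in range(1, n_a + 1):
            shifted = np.zeros(max_u + 1)
            shifted[n:] = new[m - 1][: max_u + 1 - n]
            new[m] = shifted + counts[m]
        counts = new
    return counts[n_a]


def mann_whitney_u(group_a: Sequence[float], group_b: Sequence[float],
                   exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U, p)``.

    ``U`` counts, over all cross-group pairs, the members of ``group_a``
    exceeding a member of ``group_b`` (ties count one half).  Exact
    enumeration is used when the pooled sample is small and tie-free;
    otherwise the normal approximation with tie and continuity corrections.
    The reported ``U`` is for ``group_a`` (its complement gives the same
    p-value).
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise StatsError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    u = _rank_u(a, b)

    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()

    if not has_ties and n_a + n_b <= exact_max_n:
        counts = _exact_u_counts(n_a, n_b)
        total = counts.sum()
        k = int(round(u))
        cdf = counts[: k + 1].sum() / total
        sf = counts[k:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
        return u, p

    mu = n_a * n_b / 2.0
    n = n_a + n_b
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))) \
        if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 1.0  # all observations tied
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, float(2.0 * 0.5 * math.erfc(z / math.sqrt(2.0))))
    return u, p


def compare_groups(summaries: Iterable[MeasurementSummary],
                   cfg: StatsConfig | None = None,
                   ) -> list[GroupComparison]:
    """Compare every summary parameter between saline and AA measurements.

    Excluded measurements are dropped first.  One comparison per numeric
    parameter, in the fixed panel order; parameters with fewer than one
    valid value per group are skipped.  No multiple-testing adjustment is
    applied.
    """
    cfg = cfg or StatsConfig()
    rows = [s for s in summaries if not s.excluded]
    saline = [s for s in rows if s.condition == "saline"]
    aa = [s for s in rows if s.condition == "AA"]
    if not saline or not aa:
        raise StatsError("need at least one included measurement per condition")

    out: list[GroupComparison] = []
    for name in MeasurementSummary.parameter_names():
        va = np.array([getattr(s, name) for s in saline], dtype=float)
        vb = np.array([getattr(s, name) for s in aa], dtype=float)
        va = va[np.isfinite(va)]
        vb = vb[np.isfinite(vb)]
        if len(va) == 0 or len(vb) == 0:
            continue
        u, p = mann_whitney_u(va, vb, exact_max_n=cfg.exact_max_n)
        out.append(GroupComparison(
            parameter=name,
            mean_saline=float(va.mean()),
            sd_saline=float(va.std(ddof=1)) if len(va) > 1 else 0.0,
            mean_aa=float(vb.mean()),
            sd_aa=float(vb.std(ddof=1)) if len(vb) > 1 else 0.0,
            u_statistic=u,
            p_value=p,
            n_saline=len(va),
            n_aa=len(vb),
            significant=p < cfg.alpha,
        ))
    return out


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Comparison table in the shape of a mean +/- SD parameter panel."""
    records = []
    for c in comparisons:
        records.append({
            "parameter": c.parameter,
            "saline_mean": c.mean_saline,
            "saline_sd": c.sd_saline,
            "aa_mean": c.mean_aa,
            "aa_sd": c.sd_aa,
            "n_saline": c.n_saline,
            "n_aa": c.n_aa,
            "U": c.u_statistic,
            "p_value": c.p_value,
            "significant": "*" if c.significant else "",
        })
    return pd.DataFrame.from_records(records)
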