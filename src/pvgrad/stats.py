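"""Rank-based association statistics.

Spearman correlation (exact permutation p for small n, t-approximation
otherwise) and the two-sided Wilcoxon rank-sum test (exact enumeration for
small combined n, tie-corrected normal approximation otherwise), plus the
battery correlating every gradient metric — and the conventional lesion
count/volume — with EDSS.  EDSS is ordinal with frequent 0.5-step ties, so
mid-ranks and tie-corrected variances are used throughout.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SpearmanResult",
    "GroupComparisonResult",
    "spearman",
    "wilcoxon_rank_sum",
    "run_association_battery",
    "compare_groups",
]

_EXACT_SPEARMAN_MAX_N = 10
_EXACT_RANKSUM_MAX_N = 12


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str


@dataclass
class GroupComparisonResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str


def _complete_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


_perm_index_cache: dict[int, np.ndarray] = {}
_null_cache: dict[tuple, np.ndarray] = {}


def _perm_indices(n: int) -> np.ndarray:
    """All n! index permutations as an (n!, n) int8 array, cached per n."""
    if n not in _perm_index_cache:
        _perm_index_cache[n] = np.array(
            list(itertools.permutations(range(n))), dtype=np.int8
        )
    return _perm_index_cache[n]


def _exact_spearman_null(rxc: np.ndarray, ryc: np.ndarray) -> np.ndarray:
    """Sorted |rxc . perm(ryc)| over all permutations of ryc.

    The null distribution depends only on the two centred-rank multisets, so
    it is cached on them — a battery correlating many metrics against one
    ordinal outcome (EDSS) pays the enumeration once.
    """
    n = len(rxc)
    key = (tuple(np.round(np.sort(rxc), 9)), tuple(np.round(np.sort(ryc), 9)))
    if key not in _null_cache:
        perms = _perm_indices(n)
        dots = np.empty(len(perms))
        chunk = 200_000
        for start in range(0, len(perms), chunk):
            dots[start:start + chunk] = ryc[perms[start:start + chunk]] @ rxc
        if len(_null_cache) > 8:
            _null_cache.clear()
        _null_cache[key] = np.sort(np.abs(dots))
    return _null_cache[key]


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks (average ranks for ties).
    For n <= 10 the p-value is exact, from full enumeration of the n!
    permutations of one rank vector (conditional on the observed tie
    pattern); for larger n the usual t-approximation is used.  Incomplete
    pairs are dropped; a constant input yields NaN rho (flagged via method
    "undefined").
    """
    x, y = _complete_pairs(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho undefined", UserWarning)
        return SpearmanResult(np.nan, np.nan, n, "undefined")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    rho = float(rxc @ ryc) / denom

    if n <= _EXACT_SPEARMAN_MAX_N:
        obs = abs(float(rxc @ ryc))
        null = _exact_spearman_null(rxc, ryc)
        # one-sided count of |dot| >= obs (within fp tolerance), via sorted null
        idx = np.searchsorted(null, obs - 1e-9, side="left")
        return SpearmanResult(rho, (len(null) - idx) / len(null), n, "exact")

    # t-approximation (identical to the large-n asymptotic of spearmanr)
    if abs(rho) == 1.0:
        return SpearmanResult(rho, 0.0, n, "t-approx")
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return SpearmanResult(rho, float(p), n, "t-approx")


def wilcoxon_rank_sum(a, b) -> GroupComparisonResult:
    """Two-sided Wilcoxon rank-sum test on two independent samples.

    The statistic is the mid-rank sum of sample ``a`` in the pooled ranking.
    For combined n <= 12 the null is enumerated exactly over all C(N, n_a)
    group assignments (conditional on ties); otherwise a tie-corrected
    normal approximation (no continuity correction) is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    N = n_a + n_b
    ranks = sps.rankdata(pooled)
    W = float(ranks[:n_a].sum())
    mu = n_a * (N + 1) / 2.0

    if np.ptp(pooled) == 0:
        warnings.warn("all values tied across both groups", UserWarning)
        return GroupComparisonResult(W, 1.0, n_a, n_b, "degenerate")

    if N <= _EXACT_RANKSUM_MAX_N:
        # Rank-sum null is symmetric about mu for any fixed rank multiset.
        obs = abs(W - mu)
        count = 0
        total = math.comb(N, n_a)
        for combo in itertools.combinations(range(N), n_a):
            w = ranks[list(combo)].sum()
            if abs(w - mu) >= obs - 1e-9:
                count += 1
        return GroupComparisonResult(W, count / total, n_a, n_b, "exact")

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (N * (N - 1))
    var = n_a * n_b / 12.0 * ((N + 1) - tie_term)
    z = (W - mu) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return GroupComparisonResult(W, float(min(p, 1.0)), n_a, n_b, "normal-approx")


def run_association_battery(
    gradients: pd.DataFrame,
    subjects: pd.DataFrame,
    adjust: bool = False,
) -> pd.DataFrame:
    """Spearman correlation of every gradient metric with EDSS.

    ``gradients`` is the long table from ``compute_gradients`` over the
    cohort; ``subjects`` must carry ``subject_id`` and ``edss`` and may carry
    the conventional metrics ``lesion_count`` and ``lesion_volume_mm3``,
    which are correlated with EDSS as two extra rows.  p-values are reported
    unadjusted; ``adjust=True`` appends a Benjamini–Hochberg column
    (``p_bh``) as a convenience beyond the original analysis.
    """
    subs = subjects.dropna(subset=["edss"])
    if len(subs) < 3:
        raise ValueError("need at least 3 subjects with EDSS")
    edss = subs.set_index("subject_id")["edss"]

    rows = []
    keys = ["compartment", "metric", "pair", "tau"]
    for (compartment, metric, pair, tau), grp in gradients.groupby(keys, sort=False):
        merged = grp.set_index("subject_id")["value"].reindex(edss.index)
        res = _safe_spearman(merged.to_numpy(), edss.to_numpy())
        rows.append(
            {
                "compartment": compartment,
                "metric": metric,
                "pair": pair,
                "tau": tau,
                "rho": res.rho,
                "p_value": res.p_value,
                "n": res.n,
                "method": res.method,
            }
        )
    for conv in ("lesion_count", "lesion_volume_mm3"):
        if conv in subs.columns:
            res = _safe_spearman(
                subs[conv].to_numpy(dtype=float), subs["edss"].to_numpy(dtype=float)
            )
            rows.append(
                {
                    "compartment": "conventional",
                    "metric": conv,
                    "pair": "",
                    "tau": np.nan,
                    "rho": res.rho,
                    "p_value": res.p_value,
                    "n": res.n,
                    "method": res.method,
                }
            )
    out = pd.DataFrame(rows)
    if adjust and len(out):
        finite = np.isfinite(out["p_value"].to_numpy(dtype=float))
        p_bh = np.full(len(out), np.nan)
        if finite.any():
            p_bh[finite] = sps.false_discovery_control(
                out.loc[finite, "p_value"].to_numpy(dtype=float)
            )
        out["p_bh"] = p_bh
    return out


def _safe_spearman(x, y) -> SpearmanResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 3:
        return SpearmanResult(np.nan, np.nan, int(keep.sum()), "insufficient-n")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return spearman(x[keep], y[keep])


def compare_groups(
    gradients: pd.DataFrame,
    subjects: pd.DataFrame,
    group_a: str = "earlyMS",
    group_b: str = "progressiveMS",
) -> pd.DataFrame:
    """Two-sided rank-sum comparison of every gradient metric between groups."""
    grp_of = subjects.set_index("subject_id")["group"]
    rows = []
    keys = ["compartment", "metric", "pair", "tau"]
    for (compartment, metric, pair, tau), grp in gradients.groupby(keys, sort=False):
        vals = grp.set_index("subject_id")["value"]
        ga = vals[grp_of.reindex(vals.index) == group_a].dropna()
        gb = vals[grp_of.reindex(vals.index) == group_b].dropna()
        if len(ga) == 0 or len(gb) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = wilcoxon_rank_sum(ga.to_numpy(), gb.to_numpy())
        rows.append(
            {
                "compartment": compartment,
                "metric": metric,
                "pair": pair,
                "tau": tau,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n_a": res.n_a,
                "n_b": res.n_b,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)
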