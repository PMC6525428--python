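"""Between-device comparison via the Mann-Whitney U test.

Replicate metric distributions from two devices are compared with a
rank-based two-sample test.  For the small replicate counts typical of
calibration studies (about ten captures per device) the exact null
distribution is used: every assignment of the pooled observations to the two
groups is enumerated, with midranks for ties, so no distributional or
asymptotic assumption is needed.  For larger samples a normal approximation
with tie-corrected variance and a 0.5 continuity correction takes over.
Two-sided p-values are reported as ``min(1, 2 * one-sided)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import ValidationError
from .metrics import MetricTable, amplitude_summary

#: Largest pooled sample size for which the exact enumeration is used.
EXACT_LIMIT = 20


@dataclass(frozen=True)
class MannWhitneyResult:
    """U statistic (of the first sample), two-sided p and the method used."""

    U: float
    p: float
    method: str
    n1: int
    n2: int


@dataclass(frozen=True)
class ComparisonResult:
    """One device comparison for one metric at one location."""

    metric: str
    direction: str
    z: float
    n1: int
    n2: int
    U: float
    p: float
    method: str
    significant: bool


@lru_cache(maxsize=64)
def _group_assignments(n: int, k: int) -> np.ndarray:
    """All C(n, k) index subsets of size k, as an integer matrix."""
    return np.array(list(combinations(range(n), k)), dtype=np.int16)


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   mode: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    ``U`` is the statistic of the first sample, computed from midranks, so
    ``U_x + U_y = n1 * n2`` always holds.  In exact mode (requires
    ``n1 + n2 <= 20``) the p-value enumerates all ``C(n1+n2, n1)`` group
    assignments of the observed pooled values; ``auto`` uses the exact
    enumeration when feasible and otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValidationError("both samples must be non-empty")
    if mode not in ("exact", "auto", "normal"):
        raise ValidationError(f"unknown mode {mode!r}")
    n = n1 + n2
    if mode == "exact" and n > EXACT_LIMIT:
        raise ValidationError(
            f"exact mode limited to n1 + n2 <= {EXACT_LIMIT}, got {n}")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)                      # midranks
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_LIMIT)
    if use_exact:
        combs = _group_assignments(n, n1)
        u_all = ranks[combs].sum(axis=1) - n1 * (n1 + 1) / 2.0
        eps = 1e-9
        p_le = float(np.mean(u_all <= u_obs + eps))
        p_ge = float(np.mean(u_all >= u_obs - eps))
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return MannWhitneyResult(U=u_obs, p=p, method="exact", n1=n1, n2=n2)
    # normal approximation with tie correction and continuity correction
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return MannWhitneyResult(U=u_obs, p=1.0, method="normal", n1=n1, n2=n2)
    diff = u_obs - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return MannWhitneyResult(U=u_obs, p=p, method="normal", n1=n1, n2=n2)


# ---------------------------------------------------------------------------
# Device comparison


def compare_devices(table_a: MetricTable, table_b: MetricTable,
                    alpha: float = 0.05,
                    mode: str = "auto") -> list[ComparisonResult]:
    """Compare two devices' replicate metric tables cell by cell.

    Runs one Mann-Whitney test per shared (metric, direction, eccentricity)
    plus one per-replicate directional-amplitude comparison for each
    geometry metric and eccentricity shared by both tables.  A result is
    flagged significant when ``p < alpha``.
    """
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    results: list[ComparisonResult] = []

    def extract(df: pd.DataFrame, metric, direction, z):
        sub = df[(df["direction"] == direction) & (df["z_deg"] == z)]
        return sub[metric].dropna().to_numpy()

    keys_a = _metric_cells(table_a.data)
    keys_b = _metric_cells(table_b.data)
    for key in sorted(keys_a & keys_b):
        metric, direction, z = key
        va = extract(table_a.data, metric, direction, z)
        vb = extract(table_b.data, metric, direction, z)
        r = mann_whitney_u(va, vb, mode=mode)
        results.append(ComparisonResult(
            metric=metric, direction=direction, z=z, n1=r.n1, n2=r.n2,
            U=r.U, p=r.p, method=r.method, significant=r.p < alpha))

    amp_a = {(s.metric, s.z): s for s in amplitude_summary(table_a)}
    amp_b = {(s.metric, s.z): s for s in amplitude_summary(table_b)}
    for key in sorted(set(amp_a) & set(amp_b)):
        metric, z = key
        r = mann_whitney_u(amp_a[key].per_replicate,
                           amp_b[key].per_replicate, mode=mode)
        results.append(ComparisonResult(
            metric=f"{metric}_amplitude", direction="all", z=z,
            n1=r.n1, n2=r.n2, U=r.U, p=r.p, method=r.method,
            significant=r.p < alpha))
    if not results:
        raise ValidationError("the two tables share no metric cells")
    return results


def _metric_cells(df: pd.DataFrame) -> set:
    keys = set()
    for metric in ("aspect_ratio", "square_ratio", "contrast"):
        present = df.loc[df[metric].notna(), ["direction", "z_deg"]]
        for direction, z in present.drop_duplicates().itertuples(index=False):
            keys.add((metric, direction, float(z)))
    return keys


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Comparison results as a tidy DataFrame (report schema)."""
    return pd.DataFrame([{
        "metric": r.metric, "direction": r.direction, "z_deg": r.z,
        "n1": r.n1, "n2": r.n2, "U": r.U, "p": r.p,
        "method": r.method, "significant": r.significant,
    } for r in results])
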