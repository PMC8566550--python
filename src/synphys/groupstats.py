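"""Group-comparison contracts used throughout the analyses.

Two fixed recipes: Kruskal-Wallis with Dunn's post-hoc z-tests
(Bonferroni-adjusted over the requested comparisons) for the behavioral
and trace-derived measures, and one-way ANOVA with Dunnett's
many-to-one correction for the vesicular pH comparison.

The omnibus statistics delegate to scipy; Dunn's pairwise z-tests are
computed here from pooled mid-ranks with the standard tie correction:

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))

with T = sum(t^3 - t) / (12 (N - 1)) over tie groups of size t.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = ["PairwiseResult", "kruskal_dunn", "anova_dunnett"]

GroupData = Mapping[str, Sequence[float]]


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p_unadjusted: float
    p_adjusted: float


def _check_groups(groups: GroupData, min_n: int) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {}
    for name, vals in groups.items():
        a = np.asarray(vals, dtype=float)
        if a.size < min_n:
            raise ValueError(f"group {name!r}: needs >= {min_n} observations")
        arrays[name] = a
    return arrays


def kruskal_dunn(
    groups: GroupData,
    comparisons: Sequence[tuple[str, str]] | None = None,
) -> tuple[float, float, list[PairwiseResult]]:
    """Kruskal-Wallis H (tie-corrected) plus Dunn z-tests for selected pairs.

    ``comparisons`` defaults to all pairs.  Two-sided normal p-values are
    Bonferroni-adjusted by the number of requested comparisons (clipped
    at 1).  Returns ``(H, p_omnibus, pairwise_results)``.
    """
    arrays = _check_groups(groups, 1)
    names = list(arrays)
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    for a, b in comparisons:
        if a not in arrays or b not in arrays:
            raise KeyError(f"comparison ({a!r}, {b!r}) names an unknown group")

    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:
        # scipy raises on all-identical data; H is 0 by definition there
        H, p_omni = 0.0, 1.0
    else:
        H, p_omni = stats.kruskal(*arrays.values())

    ranks = stats.rankdata(pooled)
    N = pooled.size
    offsets = np.cumsum([0] + [arrays[n].size for n in names])
    mean_rank = {
        n: ranks[offsets[i] : offsets[i + 1]].mean() for i, n in enumerate(names)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    var_unit = N * (N + 1) / 12.0 - tie_term

    results = []
    m = len(comparisons)
    for a, b in comparisons:
        se = np.sqrt(var_unit * (1.0 / arrays[a].size + 1.0 / arrays[b].size))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        results.append(PairwiseResult(a, b, float(z), float(p), float(min(1.0, p * m))))
    return float(H), float(p_omni), results


def anova_dunnett(
    groups: GroupData, control: str
) -> tuple[float, float, list[PairwiseResult]]:
    """One-way ANOVA F plus Dunnett many-to-one adjusted p-values vs control.

    Each group needs >= 2 observations.  Returns
    ``(F, p_omnibus, pairwise_results)`` with one result per non-control
    group (Dunnett p-values are reported as both unadjusted and adjusted,
    since the adjustment is built into the procedure).
    """
    arrays = _check_groups(groups, 2)
    if control not in arrays:
        raise KeyError(f"control group {control!r} not present")
    others = [n for n in arrays if n != control]
    F, p_omni = stats.f_oneway(*arrays.values())
    dun = stats.dunnett(*[arrays[n] for n in others], control=arrays[control])
    results = [
        PairwiseResult(n, control, float(dun.statistic[i]),
                       float(dun.pvalue[i]), float(dun.pvalue[i]))
        for i, n in enumerate(others)
    ]
    return float(F), float(p_omni), results
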