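"""Hypergeometric enrichment of clinical indicators in predicted groups.

For each (group, indicator) pair the background is the set of classified
tumor samples with known indicator status: N samples of which K carry the
indicator; the group holds n samples of which k carry it.  The enrichment
ratio is (k/n)/(K/N) and the p-value is the upper tail P(X >= k) of
Hypergeometric(N, K, n), BH-adjusted across all tests emitted in one run.
Indicators such as T3 (primary tumor > 5 cm), N3 (extensive nodal spread),
HER2+ and LN+ (nodal metastasis in pathology) all mark more aggressive
disease, so a sound invasiveness classifier should concentrate them in the
predicted-invasive group.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import SampleSheet

logger = logging.getLogger(__name__)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"impossible counts N={N} K={K} n={n} k={k}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_indicators(
    calls: pd.Series,
    sheet: SampleSheet,
    indicators: list[str] | None = None,
    groups: tuple[str, ...] = ("invasive", "noninvasive"),
    p_star: float = 0.01,
) -> pd.DataFrame:
    """One enrichment record per (group, indicator), BH-adjusted jointly.

    ``calls`` maps sample id -> predicted group.  Samples with unknown
    indicator status are excluded from both N and n for that indicator;
    indicators absent from the sheet are skipped (logged).
    """
    if indicators is None:
        indicators = sheet.indicator_names
    in_groups = calls[calls.isin(groups)]
    rows = []
    for ind in indicators:
        if ind not in sheet.data.columns:
            logger.warning("indicator %r absent from sample sheet; skipped", ind)
            continue
        status = sheet.indicator_status(ind).reindex(in_groups.index)
        known = status.notna()
        N = int(known.sum())
        if N == 0:
            logger.warning("indicator %r has no known statuses; skipped", ind)
            continue
        K = int((status[known] == 1).sum())
        for grp in groups:
            sel = known & (in_groups == grp)
            n = int(sel.sum())
            k = int((status[sel] == 1).sum())
            ratio = (k / n) / (K / N) if n > 0 and K > 0 else np.nan
            p = hypergeom_upper_tail(N, K, n, k)
            rows.append((grp, ind, N, K, n, k, ratio, p))
    out = pd.DataFrame(
        rows, columns=["group", "indicator", "N", "K", "n", "k", "ratio", "p"]
    )
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["stars"] = np.where(out["p"] < p_star, "**", "")
    else:
        out["q"] = []
        out["stars"] = []
    return out
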