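"""Marker-panel scoring and concordance statistics over occupancy tables.

Pathway/regulator tables are consumed as generic user-supplied inputs
(binary occupancy, optional Z-scores per dataset); no enrichment scoring
is computed here.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.stats.contingency_tables

from exfoliomics.matrix import CountMatrix

MIN_MARKERS_PRESENT = 2


def marker_scores(
    cm: CountMatrix, panel: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Score each sample against each marker category.

    For every (sample, category) pair: the summed counts over the panel
    genes, the number of panel genes detected (count > 0) and a ``present``
    flag requiring at least :data:`MIN_MARKERS_PRESENT` detected markers.
    Panel genes absent from the matrix contribute zero and are listed in
    the ``missing_genes`` attribute of the returned frame.
    """
    panel = {k: list(dict.fromkeys(v)) for k, v in panel.items()}
    if not panel or all(len(v) == 0 for v in panel.values()):
        raise ValueError("marker panel is empty")
    missing: dict[str, list[str]] = {}
    rows = []
    for category, genes in panel.items():
        present_genes = [g for g in genes if g in cm.counts.index]
        absent = [g for g in genes if g not in cm.counts.index]
        if absent:
            missing[category] = absent
        sub = cm.counts.loc[present_genes] if present_genes else None
        for sample in cm.counts.columns:
            if sub is None:
                total, detected = 0, 0
            else:
                col = sub[sample]
                total = int(col.sum())
                detected = int((col > 0).sum())
            rows.append(
                {
                    "sample_id": sample,
                    "category": category,
                    "total_counts": total,
                    "detected_markers": detected,
                    "present": detected >= MIN_MARKERS_PRESENT,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["missing_genes"] = missing
    return out


def proportion_percent(k: int, n: int) -> int:
    """round(100*k/n) as an integer percent."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return int(np.round(100.0 * k / n))


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-sample z-test for proportions, two-sided.

    z > 0 when the first proportion is larger; identical proportions give
    z = 0, p = 1.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be > 0")
        if not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def mcnemar_test(b: int, c: int, exact_threshold: int = 25) -> tuple[float, float]:
    """McNemar's test from the two discordant counts.

    Exact two-sided binomial when ``b + c < exact_threshold``; otherwise
    the continuity-corrected chi-square.  Returns (statistic, p): the
    statistic is min(b, c) in the exact regime and the chi-square value
    otherwise.  b = c = 0 returns p = 1 with a warning.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be >= 0")
    if b + c == 0:
        warnings.warn("no discordant pairs; p = 1 by definition")
        return 0.0, 1.0
    table = [[0, b], [c, 0]]
    exact = (b + c) < exact_threshold
    res = statsmodels.stats.contingency_tables.mcnemar(
        table, exact=exact, correction=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def occupancy_from_zscores(zscores: pd.DataFrame) -> pd.DataFrame:
    """Binary occupancy: a pathway occupies a dataset when its Z-score is
    present (non-missing)."""
    return zscores.notna().astype(int)


def zscore_correlation(
    table_a: pd.Series, table_b: pd.Series, method: str = "pearson"
) -> tuple[float, float]:
    """Correlate two Z-score columns over their shared, non-missing rows."""
    shared = table_a.dropna().index.intersection(table_b.dropna().index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared rows with Z-scores, got {len(shared)}")
    a = table_a.loc[shared].to_numpy(dtype=float)
    b = table_b.loc[shared].to_numpy(dtype=float)
    if method == "pearson":
        r, p = scipy.stats.pearsonr(a, b)
    elif method == "spearman":
        r, p = scipy.stats.spearmanr(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
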