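"""Low-abundance filtering, upper-quartile normalization and CPM utilities."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
import scipy.stats

from exfoliomics.matrix import CountMatrix


@dataclass
class FilterReport:
    genes_before: int
    genes_after: int
    reads_before: int
    reads_after: int

    @property
    def percent_gene_reduction(self) -> int:
        return percent_reduction(self.genes_before, self.genes_after)

    @property
    def percent_read_reduction(self) -> int:
        return percent_reduction(self.reads_before, self.reads_after)

    def to_dict(self) -> dict:
        return {
            "genes_before": self.genes_before,
            "genes_after": self.genes_after,
            "reads_before": self.reads_before,
            "reads_after": self.reads_after,
            "percent_gene_reduction": self.percent_gene_reduction,
            "percent_read_reduction": self.percent_read_reduction,
        }


@dataclass
class NormalizationResult:
    """Per-sample library sizes and upper-quartile normalization factors.

    Factors are rescaled so their geometric mean is 1; the effective
    library size is ``library_size * norm_factor``.
    """

    library_size: pd.Series
    norm_factor: pd.Series

    @property
    def effective_lib(self) -> pd.Series:
        return self.library_size * self.norm_factor

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "library_size": self.library_size,
                "norm_factor": self.norm_factor,
                "effective_lib": self.effective_lib,
            }
        )


def filter_low_abundance(
    cm: CountMatrix, min_samples: int = 4, min_total: int = 50
) -> tuple[CountMatrix, FilterReport]:
    """Drop genes detected in <= ``min_samples`` samples or with total count
    <= ``min_total`` across all samples.

    Both conditions are inclusive: a gene present in exactly ``min_samples``
    samples is removed, as is one with exactly ``min_total`` reads.
    """
    counts = cm.counts
    n_detected = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    keep = (n_detected > min_samples) & (totals > min_total)
    filtered = CountMatrix(counts.loc[keep], cm.samples)
    report = FilterReport(
        genes_before=int(counts.shape[0]),
        genes_after=int(keep.sum()),
        reads_before=int(totals.sum()),
        reads_after=int(totals[keep].sum()),
    )
    return filtered, report


def percent_reduction(before: Union[int, float], after: Union[int, float]) -> int:
    """Percent reduction from ``before`` to ``after``, rounded to the
    nearest integer (round-half-even, as numpy rounds)."""
    if before <= 0:
        raise ValueError("before must be > 0")
    if not 0 <= after <= before:
        raise ValueError("need 0 <= after <= before")
    return int(np.round(100.0 * (before - after) / before))


def upper_quartile_factors(
    cm: CountMatrix, quantile: float = 0.75
) -> NormalizationResult:
    """Upper-quartile normalization factors.

    For each sample the raw factor is the ``quantile`` point (linear
    interpolation between order statistics) of that sample's *nonzero*
    counts divided by its library size; raw factors are rescaled to
    geometric mean 1.
    """
    counts = cm.counts
    lib = counts.sum(axis=0).astype(float)
    raw = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy()
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise ValueError(f"sample {sample!r} has all-zero counts")
        raw[sample] = np.quantile(nonzero, quantile) / lib[sample]
    raw = pd.Series(raw, dtype=float)
    factors = raw / np.exp(np.mean(np.log(raw)))
    factors.index.name = lib.index.name
    return NormalizationResult(library_size=lib, norm_factor=factors)


def cpm(
    counts: Union[CountMatrix, pd.DataFrame],
    norm: Optional[NormalizationResult] = None,
    log: bool = False,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Counts per million against effective library sizes.

    Without ``norm``, raw library sizes are used (all factors 1).  With
    ``log=True`` returns ``log2((count + prior) / (effective_lib + 2*prior)
    * 1e6)``; the prior keeps zeros finite.
    """
    frame = counts.counts if isinstance(counts, CountMatrix) else counts
    if norm is None:
        eff = frame.sum(axis=0).astype(float)
    else:
        eff = norm.effective_lib.loc[frame.columns].astype(float)
    if (eff <= 0).any():
        bad = eff.index[eff <= 0].tolist()
        raise ValueError(f"non-positive effective library size for: {bad}")
    if not log:
        return frame / eff * 1e6
    return np.log2((frame + prior_count) / (eff + 2.0 * prior_count) * 1e6)


def housekeeping_fraction(
    cm: CountMatrix, hk_gene_ids: Iterable[str]
) -> pd.Series:
    """Per-sample fraction of reads falling in housekeeping genes."""
    hk = list(dict.fromkeys(hk_gene_ids))
    if not hk:
        raise ValueError("housekeeping gene set is empty")
    present = [g for g in hk if g in cm.counts.index]
    if not present:
        missing = hk[:10]
        raise ValueError(
            f"no housekeeping genes found in matrix; first missing ids: {missing}"
        )
    total = cm.counts.sum(axis=0).astype(float)
    hk_total = cm.counts.loc[present].sum(axis=0).astype(float)
    return hk_total / total


def cross_source_correlation(
    logcpm_a: pd.DataFrame, logcpm_b: pd.DataFrame
) -> tuple[float, float]:
    """Spearman correlation of per-gene mean log-CPM between two sources.

    Both matrices are genes x samples (typically restricted to one
    treatment group); only the shared gene universe is used.
    """
    shared = logcpm_a.index.intersection(logcpm_b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    mean_a = logcpm_a.loc[shared].mean(axis=1)
    mean_b = logcpm_b.loc[shared].mean(axis=1)
    rho, p = scipy.stats.spearmanr(mean_a, mean_b)
    return float(rho), float(p)
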