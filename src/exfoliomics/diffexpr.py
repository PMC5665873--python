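"""Negative-binomial dispersion estimation and exact-test differential
expression.

The common dispersion is the maximizer of the profile negative-binomial
log-likelihood summed over genes, with group-specific per-gene means taken
as the group average of effective-library-scaled counts.  The two-group
test conditions on each gene's total pseudo-count after equalizing library
sizes to their geometric mean, and doubles the smaller conditional tail.
Tagwise/trended dispersion and GLM designs are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats

from exfoliomics.matrix import CountMatrix
from exfoliomics.preprocess import NormalizationResult

PHI_FLOOR = 1e-8


@dataclass
class DispersionEstimate:
    common_dispersion: float
    converged: bool = True

    @property
    def bcv(self) -> float:
        return bcv_from_dispersion(self.common_dispersion)


def bcv_from_dispersion(phi: float) -> float:
    """Biological coefficient of variation, sqrt(phi)."""
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    return float(np.sqrt(phi))


def _effective_libs(
    cm: CountMatrix, norm: Optional[NormalizationResult]
) -> np.ndarray:
    if norm is None:
        return cm.counts.sum(axis=0).to_numpy(dtype=float)
    return norm.effective_lib.loc[cm.counts.columns].to_numpy(dtype=float)


def _group_masks(groups: Sequence, columns) -> list[np.ndarray]:
    labels = pd.Series(list(groups), index=columns)
    uniq = list(dict.fromkeys(labels))
    return [(labels == g).to_numpy() for g in uniq]


def _nb_loglik(counts: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Sum of NB log-pmfs with mean mu, variance mu + phi*mu^2."""
    mu = np.maximum(mu, 1e-10)
    if phi < PHI_FLOOR:
        return float(np.sum(scipy.stats.poisson.logpmf(counts, mu)))
    r = 1.0 / phi
    return float(
        np.sum(
            scipy.special.gammaln(counts + r)
            - scipy.special.gammaln(r)
            - scipy.special.gammaln(counts + 1.0)
            + r * np.log(r / (r + mu))
            + counts * np.log(mu / (r + mu))
        )
    )


def estimate_common_dispersion(
    cm: CountMatrix,
    groups: Optional[Sequence] = None,
    norm: Optional[NormalizationResult] = None,
    phi_bounds: tuple[float, float] = (PHI_FLOOR, 20.0),
) -> DispersionEstimate:
    """One dispersion shared by all genes, by adjusted profile likelihood.

    For a candidate phi, each gene's per-sample mean is the group mean of
    count/effective_lib rescaled by the sample's effective library.  The
    summed log-likelihood carries a Cox-Reid adjustment,
    ``-0.5 * sum log(sum_i mu_i / (1 + phi * mu_i))`` per gene and group,
    which removes most of the downward bias introduced by plugging in
    estimated group means; phi maximizes the adjusted likelihood via
    bounded 1-D search on log(phi).
    """
    if groups is None:
        groups = cm.groups()
    counts = cm.counts.to_numpy(dtype=float)
    eff = _effective_libs(cm, norm)
    masks = _group_masks(groups, cm.counts.columns)
    for mask in masks:
        if mask.sum() < 2:
            raise ValueError("each group needs >= 2 samples")

    rates = counts / eff  # genes x samples
    mu = np.zeros_like(counts)
    for mask in masks:
        group_rate = rates[:, mask].mean(axis=1, keepdims=True)
        mu[:, mask] = group_rate * eff[mask]

    def neg_loglik(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        ll = _nb_loglik(counts, mu, phi)
        # Cox-Reid: 0.5*log of the observed information for each group mean
        for mask in masks:
            mu_g = np.maximum(mu[:, mask], 1e-10)
            info = (mu_g / (1.0 + phi * mu_g)).sum(axis=1)
            ll -= 0.5 * float(np.sum(np.log(np.maximum(info, 1e-300))))
        return -ll

    res = scipy.optimize.minimize_scalar(
        neg_loglik,
        bounds=(np.log(phi_bounds[0]), np.log(phi_bounds[1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"dispersion optimization failed: {res.message}")
    phi = float(np.exp(res.x))
    if phi <= phi_bounds[0] * 1.5:
        phi = 0.0  # pinned at the floor: effectively Poisson
    return DispersionEstimate(common_dispersion=phi, converged=bool(res.success))


def _conditional_two_sided_p(
    total: int, n1: int, n2: int, obs1: int, phi: float
) -> float:
    """Exact conditional two-sided p for a 2-group NB split of ``total``.

    Group sums of n iid NB(mu, phi) are NB(n*mu, phi/n).  Conditioning on
    the total, p = 2 * min(lower tail, upper tail) of the observed group-1
    sum, capped at 1.  phi below the floor falls back to the Poisson limit
    (binomial conditional).
    """
    if total == 0:
        return 1.0
    a = np.arange(total + 1)
    if phi < PHI_FLOOR:
        logf = scipy.stats.binom.logpmf(a, total, n1 / (n1 + n2))
    else:
        m = total / (n1 + n2)  # null per-sample mean
        r1, r2 = n1 / phi, n2 / phi
        mu1, mu2 = n1 * m, n2 * m
        logf1 = scipy.stats.nbinom.logpmf(a, r1, r1 / (r1 + mu1))
        logf2 = scipy.stats.nbinom.logpmf(total - a, r2, r2 / (r2 + mu2))
        logf = logf1 + logf2
        logf -= scipy.special.logsumexp(logf)
    prob = np.exp(logf)
    lower = prob[: obs1 + 1].sum()
    upper = prob[obs1:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def exact_test(
    cm: CountMatrix,
    phi: Union[float, DispersionEstimate],
    groups: Optional[Sequence] = None,
    norm: Optional[NormalizationResult] = None,
    group_order: tuple[str, str] = ("control", "NSAID"),
    prior_count: float = 0.125,
) -> pd.DataFrame:
    """Two-group NB exact test per gene.

    Counts are scaled to the geometric-mean effective library and rounded
    (pseudo-counts) so the two groups are exchangeable under the null.
    Returns a DataFrame with columns gene, logFC (second group vs first,
    positive when the treated mean is higher), logCPM, pvalue, fdr.
    """
    if isinstance(phi, DispersionEstimate):
        phi = phi.common_dispersion
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    if groups is None:
        groups = cm.groups()
    labels = pd.Series(list(groups), index=cm.counts.columns)
    ref, alt = group_order
    mask1 = (labels == ref).to_numpy()
    mask2 = (labels == alt).to_numpy()
    if mask1.sum() == 0 or mask2.sum() == 0:
        raise ValueError(f"both groups {group_order} need >= 1 sample")
    if mask1.sum() + mask2.sum() != len(labels):
        raise ValueError("groups contain labels outside group_order")

    counts = cm.counts.to_numpy(dtype=float)
    eff = _effective_libs(cm, norm)
    common_lib = float(np.exp(np.mean(np.log(eff))))
    pseudo = np.rint(counts * (common_lib / eff)).astype(np.int64)

    n1, n2 = int(mask1.sum()), int(mask2.sum())
    sum1 = pseudo[:, mask1].sum(axis=1)
    totals = sum1 + pseudo[:, mask2].sum(axis=1)
    pvals = np.array(
        [
            _conditional_two_sided_p(int(t), n1, n2, int(s1), phi)
            for t, s1 in zip(totals, sum1)
        ]
    )

    mean1 = pseudo[:, mask1].mean(axis=1)
    mean2 = pseudo[:, mask2].mean(axis=1)
    logfc = np.log2(mean2 + prior_count) - np.log2(mean1 + prior_count)
    logcpm = np.log2(
        (pseudo.mean(axis=1) + prior_count) / (common_lib + 2 * prior_count) * 1e6
    )

    out = pd.DataFrame(
        {
            "logFC": logfc,
            "logCPM": logcpm,
            "pvalue": pvals,
            "fdr": bh_adjust(pvals),
        },
        index=cm.counts.index,
    )
    out.index.name = "gene"
    return out


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def ma_table(
    de: pd.DataFrame,
    de_here: Iterable[str] = (),
    de_other: Iterable[str] = (),
) -> pd.DataFrame:
    """Rows of (logCPM, logFC, flag) for MA-plot construction.

    ``flag`` is ``DE_here`` for genes in ``de_here``, ``DE_in_other_source_only``
    for genes in ``de_other`` but not ``de_here``, else ``not_DE``.
    """
    de_here = set(de_here)
    de_other = set(de_other)
    unknown = (de_here | de_other) - set(de.index)
    if unknown:
        raise ValueError(f"flag sets contain unknown gene ids: {sorted(unknown)[:10]}")
    flag = pd.Series("not_DE", index=de.index)
    flag[de.index.isin(de_other - de_here)] = "DE_in_other_source_only"
    flag[de.index.isin(de_here)] = "DE_here"
    out = de[["logCPM", "logFC"]].copy()
    out["flag"] = flag
    return out


def intersect_gene_sets(named_sets: Mapping[str, Iterable[str]]) -> dict:
    """Disjoint Venn-region counts and pairwise overlap percentages.

    The pairwise overlap is Jaccard: ``|A & B| / |A | B| * 100``.
    """
    sets = {name: set(v) for name, v in named_sets.items()}
    if len(sets) < 2:
        raise ValueError("need >= 2 named sets")
    universe = set().union(*sets.values())
    if not universe:
        raise ValueError("union of sets is empty")
    names = list(sets)
    regions: dict[str, int] = {}
    membership_counts: dict[tuple[bool, ...], int] = {}
    for el in universe:
        key = tuple(el in sets[n] for n in names)
        membership_counts[key] = membership_counts.get(key, 0) + 1
    for key, count in membership_counts.items():
        label = "&".join(n for n, inside in zip(names, key) if inside)
        regions[label] = count
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            union = sets[a] | sets[b]
            inter = sets[a] & sets[b]
            pairwise[f"{a}|{b}"] = 100.0 * len(inter) / len(union) if union else 0.0
    return {
        "set_sizes": {n: len(sets[n]) for n in names},
        "regions": regions,
        "pairwise_overlap_percent": pairwise,
    }
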