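"""Bray-Curtis dissimilarity, ANOSIM, NMDS and leading-logFC MDS."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.spatial.distance
import scipy.stats


@dataclass
class AnosimResult:
    r_statistic: float
    p_value: float
    n_permutations: int
    seed: Optional[int]
    method: str  # "permutation" or "exact"

    def to_dict(self) -> dict:
        return {
            "R": self.r_statistic,
            "p": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "method": self.method,
        }


def bray_curtis(abundances: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between samples.

    ``abundances`` is genes x samples with non-negative entries;
    d(i,j) = sum|x_i - x_j| / sum(x_i + x_j), in [0, 1].
    """
    mat = abundances.to_numpy(dtype=float).T  # samples x genes
    if np.any(mat < 0):
        raise ValueError("abundances must be non-negative")
    zero = mat.sum(axis=1) == 0
    if zero.any():
        bad = abundances.columns[zero].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    condensed = scipy.spatial.distance.pdist(mat, metric="braycurtis")
    square = scipy.spatial.distance.squareform(condensed)
    return pd.DataFrame(square, index=abundances.columns, columns=abundances.columns)


def _anosim_r(rank_condensed: np.ndarray, within: np.ndarray, n: int) -> float:
    m = n * (n - 1) / 2
    mean_within = rank_condensed[within].mean()
    mean_between = rank_condensed[~within].mean()
    return float((mean_between - mean_within) / (m / 2.0))


def _within_mask(labels: np.ndarray) -> np.ndarray:
    n = labels.size
    iu = np.triu_indices(n, k=1)
    return labels[iu[0]] == labels[iu[1]]


def anosim(
    dist: pd.DataFrame,
    groups: Sequence,
    n_perm: Union[int, str] = 999,
    seed: Optional[int] = 0,
) -> AnosimResult:
    """Analysis of similarities on a square dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairwise distances ranked with mid-rank ties.  The p-value
    uses the add-one rule, p = (1 + #{R_perm >= R_obs}) / (1 + n_perm).
    With ``n_perm="exact"``, all distinct label assignments are enumerated
    and p is the exact proportion with R_perm >= R_obs.
    """
    d = dist.to_numpy(dtype=float)
    n = d.shape[0]
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    labels = np.asarray(list(groups))
    if labels.size != n:
        raise ValueError("groups length must match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need >= 2 groups")
    if counts.min() < 2:
        singleton = uniq[counts.argmin()]
        raise ValueError(f"group {singleton!r} has < 2 members")

    iu = np.triu_indices(n, k=1)
    ranks = scipy.stats.rankdata(d[iu])
    r_obs = _anosim_r(ranks, _within_mask(labels), n)

    if n_perm == "exact":
        r_perm = np.array(
            [
                _anosim_r(ranks, _within_mask(np.array(perm)), n)
                for perm in _distinct_permutations(labels)
            ]
        )
        p = float(np.mean(r_perm >= r_obs - 1e-12))
        return AnosimResult(r_obs, p, len(r_perm), None, "exact")

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(int(n_perm)):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, _within_mask(perm), n) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + int(n_perm))
    return AnosimResult(r_obs, float(p), int(n_perm), seed, "permutation")


def _distinct_permutations(labels: np.ndarray):
    seen = set()
    for perm in itertools.permutations(labels.tolist()):
        if perm not in seen:
            seen.add(perm)
            yield perm


def classical_mds(dist: np.ndarray, k: int) -> np.ndarray:
    """Torgerson scaling: double-centred squared distances, top-k eigenpairs."""
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def _stress1(d_config: np.ndarray, disparities: np.ndarray) -> float:
    denom = np.sum(d_config**2)
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d_config - disparities) ** 2) / denom))


def _isotonic_fit(x_sorted_idx: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators on y ordered by x_sorted_idx (Kruskal primary
    tie treatment: tied dissimilarities are free to take any order)."""
    y_ord = y[x_sorted_idx]
    # PAV
    solution = y_ord.astype(float).copy()
    weights = np.ones_like(solution)
    blocks = []  # (value, weight)
    for val in solution:
        blocks.append([val, 1.0])
        while len(blocks) > 1 and blocks[-2][0] > blocks[-1][0]:
            v2, w2 = blocks.pop()
            v1, w1 = blocks.pop()
            blocks.append([(v1 * w1 + v2 * w2) / (w1 + w2), w1 + w2])
    fit_ord = np.concatenate([[v] * int(w) for v, w in blocks])
    out = np.empty_like(fit_ord)
    out[x_sorted_idx] = fit_ord
    return out


def nmds(
    dist: pd.DataFrame,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> tuple[pd.DataFrame, float, bool]:
    """Non-metric MDS minimizing Kruskal stress-1.

    Alternates monotone (isotonic) regression of configuration distances on
    dissimilarity order with a Guttman-transform configuration update, from
    one classical-MDS start plus ``n_restarts`` random starts; the best
    configuration is returned with its stress.  Iteration stops early if
    stress would increase (the previous configuration is kept), so the
    stress trace is non-increasing.
    """
    d = dist.to_numpy(dtype=float)
    n = d.shape[0]
    if k >= n:
        raise ValueError("k must be < number of samples")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    diss = d[iu]
    order = np.argsort(diss, kind="stable")

    starts = [classical_mds(d, k)]
    scale = diss.mean() if diss.mean() > 0 else 1.0
    for _ in range(n_restarts):
        starts.append(rng.normal(scale=scale, size=(n, k)))

    best_conf, best_stress, best_conv = None, np.inf, False
    for conf in starts:
        conf, stress, conv = _nmds_single(conf, diss, order, iu, n, max_iter, tol)
        if stress < best_stress:
            best_conf, best_stress, best_conv = conf, stress, conv
    if not best_conv:
        warnings.warn("NMDS did not fully converge; returning best found")
    coords = pd.DataFrame(
        best_conf, index=dist.index, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return coords, best_stress, best_conv


def _nmds_single(conf, diss, order, iu, n, max_iter, tol):
    prev_stress = np.inf
    converged = False
    for _ in range(max_iter):
        d_conf = scipy.spatial.distance.pdist(conf)
        disparities = _isotonic_fit(order, d_conf)
        stress = _stress1(d_conf, disparities)
        if stress > prev_stress + 1e-15:
            break  # keep previous configuration; stress never increases
        if prev_stress - stress < tol:
            converged = True
            prev_stress = stress
            prev_conf = conf
            break
        prev_stress, prev_conf = stress, conf
        # Guttman transform toward the disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d_conf > 0, disparities / d_conf, 0.0)
        b = np.zeros((n, n))
        b[iu] = -ratio
        b += b.T
        np.fill_diagonal(b, -b.sum(axis=1))
        conf = b @ conf / n
    return prev_conf, prev_stress, converged


def mds_leading_logfc(
    logcpm: pd.DataFrame, top_n: int = 500, k: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classical MDS on leading-log-fold-change distances.

    The distance between two samples is the root mean square of the
    ``top_n`` largest absolute per-gene log-expression differences between
    them.  Returns (coordinates, distance matrix).
    """
    n_genes, n_samples = logcpm.shape
    if n_samples < 3:
        raise ValueError("need >= 3 samples")
    if top_n > n_genes:
        warnings.warn(f"top_n={top_n} > {n_genes} genes; using all genes")
        top_n = n_genes
    mat = logcpm.to_numpy(dtype=float)
    dist = np.zeros((n_samples, n_samples))
    for i in range(n_samples):
        for j in range(i + 1, n_samples):
            diff2 = (mat[:, i] - mat[:, j]) ** 2
            top = np.sort(diff2)[::-1][:top_n]
            dist[i, j] = dist[j, i] = np.sqrt(top.mean())
    coords = classical_mds(dist, k)
    cols = [f"MDS{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(coords, index=logcpm.columns, columns=cols),
        pd.DataFrame(dist, index=logcpm.columns, columns=logcpm.columns),
    )
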