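"""Diagonal-covariance sparse canonical correlation analysis.

Finds loading pairs (u, v) maximizing ``u' X' Y v`` subject to unit L2
bounds and L1 budgets ``||u||_1 <= c1*``, ``||v||_1 <= c2*``, by
alternating soft-thresholded updates; the L1 constraint is enforced by a
binary search on the threshold.  Later components come from deflating the
cross-product matrix.  Tuning constants are supplied as fractions in
(0, 1) and mapped affinely onto the feasible L1 range [1, sqrt(dim)];
leave-one-out cross-validation with the unpenalized held-out score
correlation as criterion selects them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

BISECTION_TOL = 1e-8
BISECTION_MAX_STEPS = 60


@dataclass
class SparseCCAResult:
    """Loadings, objective values and sample scores for K components."""

    u: pd.DataFrame  # p x K
    v: pd.DataFrame  # q x K
    d: np.ndarray  # K objective values u' X'Y v
    x_scores: pd.DataFrame  # n x K
    y_scores: pd.DataFrame  # n x K
    c1: float
    c2: float
    score_correlation: np.ndarray  # unpenalized corr(Xu, Yv) per component
    converged: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    @property
    def n_components(self) -> int:
        return self.u.shape[1]


def standardize_columns(
    data: pd.DataFrame, ddof: int = 0
) -> tuple[pd.DataFrame, list]:
    """Center and scale columns to mean 0, SD 1 (population SD by default).

    Constant columns cannot be scaled; they are removed and their labels
    returned alongside the standardized matrix.
    """
    if data.shape[0] < 2:
        raise ValueError("need >= 2 rows to standardize")
    sd = data.std(axis=0, ddof=ddof)
    constant = sd.index[sd == 0].tolist()
    if len(constant) == data.shape[1]:
        raise ValueError("all columns are constant")
    kept = data.drop(columns=constant)
    z = (kept - kept.mean(axis=0)) / kept.std(axis=0, ddof=ddof)
    return z, constant


def soft_threshold(a: np.ndarray, lam: float) -> np.ndarray:
    """Elementwise sign(a) * max(|a| - lam, 0)."""
    if lam < 0:
        raise ValueError("threshold must be >= 0")
    a = np.asarray(a, dtype=float)
    return np.sign(a) * np.maximum(np.abs(a) - lam, 0.0)


def l1_bounded_unit_vector(
    a: np.ndarray,
    c: float,
    tol: float = BISECTION_TOL,
    max_steps: int = BISECTION_MAX_STEPS,
) -> np.ndarray:
    """Unit-L2 soft-thresholded direction with ||w||_1 <= c.

    Returns ``w = S(a, lam) / ||S(a, lam)||_2`` with the smallest lam >= 0
    (found by bisection) satisfying the L1 budget.  Budgets below 1 are
    infeasible for a unit vector; budgets >= sqrt(dim) leave the constraint
    inactive.
    """
    a = np.asarray(a, dtype=float)
    if np.all(a == 0):
        raise ValueError("input vector is zero")
    if c < 1.0:
        raise ValueError("L1 budget below 1 is infeasible for a unit-L2 vector")

    def unit(lam: float) -> np.ndarray:
        s = soft_threshold(a, lam)
        norm = np.linalg.norm(s)
        if norm == 0:
            # lam at/above max|a|: collapse onto the largest coordinate
            w = np.zeros_like(a)
            i = int(np.argmax(np.abs(a)))
            w[i] = np.sign(a[i]) if a[i] != 0 else 1.0
            return w
        return s / norm

    w = unit(0.0)
    if np.abs(w).sum() <= c + tol:
        return w
    lo, hi = 0.0, float(np.abs(a).max())
    for _ in range(max_steps):
        lam = (lo + hi) / 2.0
        w = unit(lam)
        l1 = np.abs(w).sum()
        if abs(l1 - c) <= tol:
            break
        if l1 > c:
            lo = lam
        else:
            hi = lam
    w = unit(hi) if np.abs(w).sum() > c + tol else w
    return w


def budget_from_fraction(c: float, dim: int) -> float:
    """Map a tuning fraction in (0, 1] onto the feasible L1 range [1, sqrt(dim)]."""
    if not 0.0 < c <= 1.0:
        raise ValueError("tuning fraction must lie in (0, 1]")
    return 1.0 + c * (np.sqrt(dim) - 1.0)


def sparse_cca_pair(
    m: np.ndarray,
    c1_budget: float,
    c2_budget: float,
    tol: float = 1e-8,
    max_iter: int = 200,
    v0: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """One sparse loading pair for cross-product matrix ``m = X'Y``.

    Alternates ``u <- l1_bounded_unit_vector(m v, c1)`` and
    ``v <- l1_bounded_unit_vector(m' u, c2)`` until the objective changes
    by less than ``tol``.  Initialized from the leading right singular
    vector of ``m`` unless ``v0`` is given.  Returns (u, v, d, converged).
    """
    m = np.asarray(m, dtype=float)
    if v0 is None:
        _, _, vt = np.linalg.svd(m, full_matrices=False)
        v = vt[0]
    else:
        v = np.asarray(v0, dtype=float)
        v = v / np.linalg.norm(v)
    d_prev = -np.inf
    converged = False
    u = None
    for _ in range(max_iter):
        u = l1_bounded_unit_vector(m @ v, c1_budget)
        v = l1_bounded_unit_vector(m.T @ u, c2_budget)
        d = float(u @ m @ v)
        if d - d_prev < tol and d_prev > -np.inf:
            converged = True
            break
        d_prev = d
    d = float(u @ m @ v)
    u, v = _fix_sign(u, v)
    return u, v, d, converged


def _fix_sign(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make the first nonzero entry of u positive (joint sign flip)."""
    nz = np.nonzero(u)[0]
    if nz.size and u[nz[0]] < 0:
        return -u, -v
    return u, v


def deflate(m: np.ndarray, u: np.ndarray, v: np.ndarray, d: float) -> np.ndarray:
    """Remove a converged component: ``m' = m - d * u v'``."""
    m = np.asarray(m, dtype=float)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if m.shape != (u.size, v.size):
        raise ValueError(
            f"dimension mismatch: m is {m.shape}, u has {u.size}, v has {v.size}"
        )
    return m - d * np.outer(u, v)


def fit_sparse_cca(
    x: pd.DataFrame,
    y: pd.DataFrame,
    c1: float,
    c2: float,
    n_components: int = 2,
    standardize: bool = True,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> SparseCCAResult:
    """Fit K sparse CCA components between two samples-by-variables tables.

    ``c1``/``c2`` are tuning fractions in (0, 1]; rows of ``x`` and ``y``
    must be the same samples in the same order.
    """
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have the same number of rows (samples)")
    if standardize:
        x, _ = standardize_columns(x)
        y, _ = standardize_columns(y)
    xa, ya = x.to_numpy(dtype=float), y.to_numpy(dtype=float)
    p, q = xa.shape[1], ya.shape[1]
    b1 = budget_from_fraction(c1, p)
    b2 = budget_from_fraction(c2, q)

    m = xa.T @ ya
    us, vs, ds, convs, corrs = [], [], [], [], []
    for _ in range(n_components):
        u, v, d, conv = sparse_cca_pair(m, b1, b2, tol=tol, max_iter=max_iter)
        us.append(u)
        vs.append(v)
        ds.append(d)
        convs.append(conv)
        xs, ys = xa @ u, ya @ v
        if xs.std() == 0 or ys.std() == 0:
            corrs.append(0.0)
        else:
            corrs.append(float(np.corrcoef(xs, ys)[0, 1]))
        m = deflate(m, u, v, d)

    comp_names = [f"comp{k + 1}" for k in range(n_components)]
    u_mat = pd.DataFrame(np.column_stack(us), index=x.columns, columns=comp_names)
    v_mat = pd.DataFrame(np.column_stack(vs), index=y.columns, columns=comp_names)
    return SparseCCAResult(
        u=u_mat,
        v=v_mat,
        d=np.array(ds),
        x_scores=pd.DataFrame(xa @ u_mat.to_numpy(), index=x.index, columns=comp_names),
        y_scores=pd.DataFrame(ya @ v_mat.to_numpy(), index=y.index, columns=comp_names),
        c1=c1,
        c2=c2,
        score_correlation=np.array(corrs),
        converged=np.array(convs),
    )


def loo_heldout_scores(
    x: pd.DataFrame, y: pd.DataFrame, c1: float, c2: float, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """First-component held-out sample scores under leave-one-out fitting.

    For each fold, columns are standardized on the training rows and the
    held-out row is projected with the training transform and loadings.
    """
    n = x.shape[0]
    xs = np.empty(n)
    ys = np.empty(n)
    xa, ya = x.to_numpy(dtype=float), y.to_numpy(dtype=float)
    b1 = budget_from_fraction(c1, xa.shape[1])
    b2 = budget_from_fraction(c2, ya.shape[1])
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        xt, xh = _standardize_train_apply(xa[mask], xa[i])
        yt, yh = _standardize_train_apply(ya[mask], ya[i])
        u, v, _, _ = sparse_cca_pair(xt.T @ yt, b1, b2, max_iter=max_iter)
        xs[i] = xh @ u
        ys[i] = yh @ v
    return xs, ys


def _standardize_train_apply(train: np.ndarray, held: np.ndarray):
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mean) / sd, (held - mean) / sd


def loo_cv_tune(
    x: pd.DataFrame,
    y: pd.DataFrame,
    grid: Optional[Sequence[tuple[float, float]]] = None,
    grid_density: int = 5,
    max_iter: int = 100,
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Select (c1, c2) by leave-one-out cross-validation.

    The criterion for each grid point is the absolute Pearson correlation
    between the held-out first-component scores pooled over all folds;
    degenerate (zero-variance) score vectors give criterion 0.  Ties keep
    the first grid point in row-major order.  Returns the winning pair and
    the full criterion table.
    """
    if x.shape[0] < 3:
        raise ValueError("need n >= 3 samples for leave-one-out tuning")
    if grid is None:
        vals = np.linspace(0.1, 0.9, grid_density)
        grid = [(float(a), float(b)) for a in vals for b in vals]
    grid = list(grid)
    if not grid:
        raise ValueError("grid is empty")
    rows = []
    best, best_crit = grid[0], -1.0
    for c1, c2 in grid:
        xs, ys = loo_heldout_scores(x, y, c1, c2, max_iter=max_iter)
        if xs.std() == 0 or ys.std() == 0:
            crit = 0.0
        else:
            crit = float(abs(np.corrcoef(xs, ys)[0, 1]))
        rows.append({"c1": c1, "c2": c2, "criterion": crit})
        if crit > best_crit:
            best, best_crit = (c1, c2), crit
    return best, pd.DataFrame(rows)


def cca_score_table(
    result: SparseCCAResult,
    metadata: pd.DataFrame,
    x_samples: Iterable[str],
    y_samples: Iterable[str],
) -> pd.DataFrame:
    """Per-sample component scores with partner-source coloring values.

    Rows of ``x_scores``/``y_scores`` are matched to the given sample ids
    (same order as the fitted matrices); each output row carries its own
    source's component scores plus the partner source's first-component
    score for the same subject.
    """
    if result.n_components < 2:
        raise ValueError("need >= 2 fitted components")
    x_samples, y_samples = list(x_samples), list(y_samples)
    missing = (set(x_samples) | set(y_samples)) - set(metadata.index)
    if missing:
        raise ValueError(f"metadata missing samples: {sorted(missing)}")
    if len(x_samples) != len(y_samples):
        raise ValueError("x and y sample lists must pair one-to-one")

    rows = []
    for i, (sx, sy) in enumerate(zip(x_samples, y_samples)):
        sub_x = metadata.loc[sx]
        sub_y = metadata.loc[sy]
        if sub_x["subject"] != sub_y["subject"]:
            raise ValueError(
                f"paired samples {sx}/{sy} belong to different subjects"
            )
        common = {
            "subject": sub_x["subject"],
            "group": sub_x["group"],
        }
        rows.append(
            {
                "sample_id": sx,
                "source": sub_x["source"],
                "comp1": result.x_scores.iloc[i, 0],
                "comp2": result.x_scores.iloc[i, 1],
                "partner_comp1": result.y_scores.iloc[i, 0],
                **common,
            }
        )
        rows.append(
            {
                "sample_id": sy,
                "source": sub_y["source"],
                "comp1": result.y_scores.iloc[i, 0],
                "comp2": result.y_scores.iloc[i, 1],
                "partner_comp1": result.x_scores.iloc[i, 0],
                **common,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
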