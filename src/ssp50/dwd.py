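"""Distance-weighted discrimination (DWD) batch adjustment.

DWD finds the direction that best separates two batches by minimizing the sum
of inverse margins plus a penalty on slacks:

    minimize   sum_i 1/r_i + C * sum_i xi_i
    subject to r_i = y_i (w . x_i + b) + xi_i > 0,  xi_i >= 0,  ||w|| <= 1

with y = +1 for the reference batch and -1 for the new batch. Unlike the SVM
hinge loss, every sample's distance to the separating hyperplane contributes,
which makes the direction a stable estimate of the systematic batch offset.
Bias removal ("center at the first mean") shifts the new batch along the
fitted direction until both batch means project to the same point; nothing
orthogonal to the direction is touched.

The solver works on the slack-eliminated objective: for a fixed margin
m = y (w . x + b) the inner minimum over xi is the convex C1 function

    phi(m) = 1/m               if m >= 1/sqrt(C)
           = 2 sqrt(C) - C m   otherwise,

so the program reduces to minimizing sum_i phi(m_i) over the unit ball in w,
which scipy's SLSQP handles reliably. Variables are standardized to unit
pooled variance before solving ("standardized DWD"); zero-variance genes are
excluded and get zero direction weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .core import ExpressionMatrix, SSP50Error

__all__ = ["DWDModel", "fit_dwd", "adjust_batches", "pc_diagnostics", "dwd_objective"]


@dataclass
class DWDModel:
    direction: pd.Series  # unit vector over genes, original (unstandardized) space
    intercept: float  # in standardized coordinates
    penalty_C: float
    standardization: pd.Series  # per-gene scale factors used (pooled SD)
    reference_mean_projection: float

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.direction.to_numpy()))
        if abs(norm - 1.0) > 1e-8:
            raise SSP50Error(f"direction norm {norm} not within 1e-8 of 1")
        if self.penalty_C <= 0:
            raise SSP50Error("penalty_C must be positive")


def dwd_objective(margins: np.ndarray, C: float) -> float:
    """Slack-eliminated DWD loss: sum of phi(m_i) at penalty C."""
    rootC = np.sqrt(C)
    lo = margins < 1.0 / rootC
    out = np.empty_like(margins, dtype=float)
    out[lo] = 2.0 * rootC - C * margins[lo]
    out[~lo] = 1.0 / margins[~lo]
    return float(out.sum())


def _objective_and_grad(
    params: np.ndarray, X: np.ndarray, y: np.ndarray, C: float
) -> tuple[float, np.ndarray]:
    w, b = params[:-1], params[-1]
    margins = y * (X.T @ w + b)
    rootC = np.sqrt(C)
    lo = margins < 1.0 / rootC
    val = float(np.sum(2.0 * rootC - C * margins[lo]) + np.sum(1.0 / margins[~lo]))
    dphi = np.where(lo, -C, -1.0 / np.square(np.where(lo, 1.0, margins)))
    coef = dphi * y
    grad = np.empty_like(params)
    grad[:-1] = X @ coef
    grad[-1] = coef.sum()
    return val, grad


def auto_penalty(X_std: np.ndarray, n_ref: int) -> float:
    """Standard heuristic: C = 100 / (median pairwise inter-batch distance)^2."""
    d = cdist(X_std[:, :n_ref].T, X_std[:, n_ref:].T)
    med = float(np.median(d))
    if med <= 0:
        raise SSP50Error("degenerate data: zero median inter-batch distance")
    return 100.0 / med**2


def fit_dwd(
    X_ref: ExpressionMatrix | pd.DataFrame,
    X_new: ExpressionMatrix | pd.DataFrame,
    penalty_C: float | str = "auto",
) -> DWDModel:
    """Fit the DWD direction separating the reference batch from the new one.

    Both matrices are gene-by-sample over an identical gene index with at
    least two samples each. Returns a model whose direction is a unit vector
    in the original gene space (standardization undone and renormalized).
    """
    A = X_ref.values if isinstance(X_ref, ExpressionMatrix) else X_ref
    B = X_new.values if isinstance(X_new, ExpressionMatrix) else X_new
    if not A.index.equals(B.index):
        raise SSP50Error("batches must share an identical gene index")
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise SSP50Error("each batch needs at least 2 samples")
    genes = A.index
    pooled = np.hstack([A.to_numpy(dtype=float), B.to_numpy(dtype=float)])
    n_ref, n_new = A.shape[1], B.shape[1]
    y = np.concatenate([np.ones(n_ref), -np.ones(n_new)])

    sd = pooled.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise SSP50Error("all genes have zero pooled variance")
    Xs = pooled[keep] / sd[keep, None]

    C = auto_penalty(Xs, n_ref) if penalty_C == "auto" else float(penalty_C)
    if C <= 0:
        raise SSP50Error("penalty_C must be positive")

    mu_ref = Xs[:, :n_ref].mean(axis=1)
    mu_new = Xs[:, n_ref:].mean(axis=1)
    w0 = mu_ref - mu_new
    nrm = np.linalg.norm(w0)
    w0 = w0 / nrm if nrm > 0 else np.ones(Xs.shape[0]) / np.sqrt(Xs.shape[0])
    b0 = -float(w0 @ (mu_ref + mu_new)) / 2.0
    x0 = np.concatenate([w0, [b0]])

    n_w = Xs.shape[0]
    res = minimize(
        _objective_and_grad,
        x0,
        args=(Xs, y, C),
        jac=True,
        method="SLSQP",
        constraints=[
            {
                "type": "ineq",
                "fun": lambda p: 1.0 - p[:-1] @ p[:-1],
                "jac": lambda p: np.concatenate([-2.0 * p[:-1], [0.0]]),
            }
        ],
        options={"maxiter": 1000, "ftol": 1e-12},
    )
    if not res.success and res.status != 8:  # 8 = positive directional derivative, near-optimal
        raise SSP50Error(f"DWD solver failed to converge: {res.message} (objective {res.fun})")
    w_std = res.x[:n_w]
    wn = np.linalg.norm(w_std)
    if wn == 0:
        raise SSP50Error("DWD solver returned a zero direction")
    w_std /= wn

    # Map back to the original gene space and renormalize. The direction is
    # used as a displacement (the batch shift is applied along it), so it
    # transforms with the data: x_orig = sd * x_std means a standardized-space
    # shift along w_std is an original-space shift along sd * w_std.
    w_full = np.zeros(len(genes))
    w_full[keep] = w_std * sd[keep]
    w_full /= np.linalg.norm(w_full)
    direction = pd.Series(w_full, index=genes)

    std = pd.Series(np.where(keep, sd, 0.0), index=genes)
    ref_proj = float(w_full @ A.to_numpy(dtype=float).mean(axis=1))
    return DWDModel(
        direction=direction,
        intercept=float(res.x[-1]),
        penalty_C=C,
        standardization=std,
        reference_mean_projection=ref_proj,
    )


def adjust_batches(
    X_ref: ExpressionMatrix | pd.DataFrame,
    X_new: ExpressionMatrix | pd.DataFrame,
    model: DWDModel,
) -> tuple[ExpressionMatrix | pd.DataFrame, ExpressionMatrix | pd.DataFrame]:
    """Shift the new batch along the DWD direction onto the reference mean.

    Every new-batch sample x becomes x - ((mu_new - mu_ref) . w) w; after the
    shift both batch means project identically on w, and all components
    orthogonal to w are untouched. The reference batch is returned unchanged.
    """
    A = X_ref.values if isinstance(X_ref, ExpressionMatrix) else X_ref
    B = X_new.values if isinstance(X_new, ExpressionMatrix) else X_new
    if not A.index.equals(B.index) or not A.index.equals(model.direction.index):
        raise SSP50Error("gene index mismatch between batches and model")
    w = model.direction.to_numpy()
    mu_ref = A.to_numpy(dtype=float).mean(axis=1)
    mu_new = B.to_numpy(dtype=float).mean(axis=1)
    shift = float((mu_new - mu_ref) @ w)
    B_adj = B.sub(pd.Series(shift * w, index=B.index), axis=0)
    if isinstance(X_new, ExpressionMatrix):
        B_adj = ExpressionMatrix(B_adj, platform=X_new.platform, scale=X_new.scale)
    return X_ref, B_adj


def pc_diagnostics(
    X_pooled: ExpressionMatrix | pd.DataFrame,
    batch_labels: list[str],
    model: DWDModel,
) -> pd.DataFrame:
    """Per-sample coordinates on PC1-PC3 of the pooled gene-centered data,
    with the DWD direction as a fourth axis. Suitable for before/after
    scatter diagnostics of the adjustment."""
    X = X_pooled.values if isinstance(X_pooled, ExpressionMatrix) else X_pooled
    if X.shape[1] != len(batch_labels):
        raise SSP50Error("pooled matrix column count must equal label count")
    if X.shape[1] < 4:
        raise SSP50Error("need at least 4 samples for PC diagnostics")
    arr = X.to_numpy(dtype=float)
    centered = arr - arr.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(centered, full_matrices=False)
    coords = U[:, :3].T @ centered  # 3 x n_samples
    dwd_coord = model.direction.to_numpy() @ arr
    out = pd.DataFrame(
        {
            "PC1": coords[0],
            "PC2": coords[1],
            "PC3": coords[2],
            "DWD": dwd_coord,
            "batch": batch_labels,
        },
        index=X.columns,
    )
    out.index.name = "sample"
    return out
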