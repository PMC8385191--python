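"""Independent brute-force oracles used only by the test suite.

Each function re-derives an expected result by the most literal route
available (explicit loops, exhaustive scans, generic solvers) so the package
implementations are checked against code that shares none of their logic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize


def knn_impute_brute(matrix: pd.DataFrame, k: int) -> pd.DataFrame:
    """Exhaustive gene-wise KNN imputation with inverse-distance weights."""
    X = matrix.to_numpy(dtype=float).copy()
    orig = matrix.to_numpy(dtype=float)
    n, m = X.shape
    for g in range(n):
        for c in range(m):
            if not np.isnan(orig[g, c]):
                continue
            cands = []
            for h in range(n):
                if h == g or np.isnan(orig[h, c]):
                    continue
                shared = ~np.isnan(orig[g]) & ~np.isnan(orig[h])
                if not shared.any():
                    continue
                d = np.sqrt(((orig[g, shared] - orig[h, shared]) ** 2).sum() / shared.sum())
                cands.append((d, h))
            cands.sort(key=lambda t: t[0])  # stable: ties keep row order
            chosen = cands[: min(k, len(cands))]
            if any(d == 0 for d, _ in chosen):
                vals = [orig[h, c] for d, h in chosen if d == 0]
                X[g, c] = np.mean(vals)
            else:
                w = np.array([1.0 / d for d, _ in chosen])
                v = np.array([orig[h, c] for _, h in chosen])
                X[g, c] = (w * v).sum() / w.sum()
    return pd.DataFrame(X, index=matrix.index, columns=matrix.columns)


def background_subtract_brute(
    counts: pd.DataFrame, neg_rows: list[str], floor: float
) -> pd.DataFrame:
    out = {}
    body = [r for r in counts.index if r not in neg_rows]
    for sample in counts.columns:
        bg = counts.loc[neg_rows, sample].mean()
        out[sample] = [max(counts.loc[r, sample] - bg, floor) for r in body]
    return pd.DataFrame(out, index=body)


def hk_normalize_brute(counts: pd.DataFrame, housekeepers: list[str]) -> pd.DataFrame:
    out = {}
    for sample in counts.columns:
        gm = np.prod([counts.loc[h, sample] for h in housekeepers]) ** (1.0 / len(housekeepers))
        out[sample] = [np.log2(counts.loc[r, sample] / gm) for r in counts.index]
    return pd.DataFrame(out, index=counts.index)


def collapse_brute(expr: pd.DataFrame, mapping: dict[str, str]) -> dict[str, str]:
    """gene -> selected probe by exhaustive IQR scan (first-wins on ties)."""
    best: dict[str, tuple[float, str]] = {}
    for probe in expr.index:
        if probe not in mapping:
            continue
        gene = mapping[probe]
        vals = np.sort(expr.loc[probe].to_numpy(dtype=float))
        iqr = np.quantile(vals, 0.75) - np.quantile(vals, 0.25)
        if gene not in best or iqr > best[gene][0]:
            best[gene] = (iqr, probe)
    return {g: p for g, (_, p) in best.items()}


def spearman_brute(x, y) -> float:
    """Average-tie ranks, then the explicit Pearson formula."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def km_brute(times, events) -> tuple[np.ndarray, np.ndarray]:
    """Explicit product-limit estimate over the distinct event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    event_times = np.unique(times[events])
    s = 1.0
    grid, surv = [0.0], [1.0]
    for t in event_times:
        at_risk = (times >= t).sum()
        d = ((times == t) & events).sum()
        s *= 1.0 - d / at_risk
        grid.append(t)
        surv.append(s)
    return np.array(grid), np.array(surv)


def logrank_chi2_brute(times, events, groups) -> float:
    """k-group log-rank chi-square via the explicit O-E / covariance sums."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    k = len(labels)
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in np.unique(times[events]):
        at = times >= t
        n = at.sum()
        d = (events & (times == t)).sum()
        if n <= 1:
            continue
        n_j = np.array([(at & (groups == lab)).sum() for lab in labels], dtype=float)
        d_j = np.array([(events & (times == t) & (groups == lab)).sum() for lab in labels])
        O += d_j
        E += d * n_j / n
        frac = n_j / n
        V += d * (np.diag(frac) - np.outer(frac, frac)) * (n - d) / (n - 1)
    z = (O - E)[: k - 1]
    Vk = V[: k - 1, : k - 1]
    return float(z @ np.linalg.solve(Vk, z))


def kappa_brute(matrix: np.ndarray) -> float:
    """Cohen's kappa recomputed from expanded label pairs via sklearn."""
    from sklearn.metrics import cohen_kappa_score

    a, b = [], []
    n_classes = matrix.shape[0]
    for i in range(n_classes):
        for j in range(matrix.shape[1]):
            a += [i] * int(matrix[i, j])
            b += [j] * int(matrix[i, j])
    labels = list(range(max(matrix.shape)))
    return float(cohen_kappa_score(a, b, labels=labels))


def dwd_objective_oracle(
    X_std: np.ndarray, y: np.ndarray, C: float, seed: int = 0, n_starts: int = 10
) -> float:
    """Best objective of the full DWD program (explicit slacks) by generic
    multistart SLSQP; independent of the package's reduced formulation."""
    rng = np.random.default_rng(seed)
    n = X_std.shape[1]
    p = X_std.shape[0]

    def obj(z):
        w, b, xi = z[:p], z[p], z[p + 1 :]
        r = y * (X_std.T @ w + b) + xi
        if np.any(r <= 0):
            return 1e12
        return np.sum(1.0 / r) + C * np.sum(xi)

    cons = [
        {"type": "ineq", "fun": lambda z: z[p + 1 :]},
        {"type": "ineq", "fun": lambda z: y * (X_std.T @ z[:p] + z[p]) + z[p + 1 :] - 1e-6},
        {"type": "ineq", "fun": lambda z: 1 - z[:p] @ z[:p]},
    ]
    best = np.inf
    for _ in range(n_starts):
        z0 = np.concatenate([rng.normal(0, 0.3, p + 1), np.ones(n)])
        res = minimize(
            obj, z0, constraints=cons, method="SLSQP", options={"maxiter": 3000, "ftol": 1e-14}
        )
        if np.isfinite(res.fun) and res.fun < best and res.fun < 1e11:
            best = float(res.fun)
    return best
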