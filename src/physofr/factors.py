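"""Latent structure of the perceptual ratings: diagnostics, EFA, factor scores.

The 8 rated properties are reduced to a small number of orthogonal
dimensions via exploratory factor analysis: suitability diagnostics
(Bartlett sphericity, KMO), factor-count selection by the modal vote of
parallel analysis, the Kaiser criterion and the scree acceleration factor,
minres (or ML) extraction with varimax rotation, and regression (Thurstone)
factor scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


def bartlett_sphericity(R: np.ndarray, n: int):
    """Bartlett's test that a correlation matrix is the identity.

    statistic = -(n - 1 - (2p + 5)/6) * ln det R,  df = p(p-1)/2.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be a symmetric correlation matrix")
    if n < p + 1:
        warnings.warn("sample size below p + 1: asymptotic chi-square is unreliable")
    sign, logdet = np.linalg.slogdet(R)
    df = p * (p - 1) // 2
    if sign <= 0 or not np.isfinite(logdet):
        warnings.warn("singular correlation matrix: Bartlett statistic is infinite")
        return np.inf, df, 0.0
    statistic = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    return float(statistic), df, float(stats.chi2.sf(statistic, df))


def kmo(R: np.ndarray):
    """Kaiser-Meyer-Olkin sampling adequacy (overall and per item).

    KMO = sum r^2 / (sum r^2 + sum q^2) over off-diagonal entries, with q
    the anti-image partial correlations from the scaled inverse of R.
    """
    R = np.asarray(R, dtype=float)
    try:
        inv = np.linalg.inv(R)
    except np.linalg.LinAlgError as e:
        raise ValueError("correlation matrix is not invertible") from e
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    Q = -inv / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = R[off] ** 2
    q2 = Q[off] ** 2
    overall = r2.sum() / (r2.sum() + q2.sum())
    r2_i = (R ** 2 * off).sum(axis=1)
    q2_i = (Q ** 2 * off).sum(axis=1)
    return float(overall), r2_i / (r2_i + q2_i)


def _eigenvalues(X: np.ndarray) -> np.ndarray:
    R = np.corrcoef(X, rowvar=False)
    return np.sort(np.linalg.eigvalsh(R))[::-1]


def parallel_analysis(X: np.ndarray, n_iter: int = 100, seed: int = 0,
                      quantile: float = 0.95) -> int:
    """Factors whose sample eigenvalue exceeds the random-data envelope."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    obs = _eigenvalues(X)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_iter, p))
    for i in range(n_iter):
        sims[i] = _eigenvalues(rng.standard_normal((n, p)))
    env = np.quantile(sims, quantile, axis=0)
    above = obs > env
    # count the leading run only
    k = 0
    for a in above:
        if not a:
            break
        k += 1
    return k


def acceleration_factor(eigenvalues: np.ndarray) -> int:
    """Scree elbow via the acceleration factor (max second difference)."""
    e = np.asarray(eigenvalues, dtype=float)
    if len(e) < 3:
        return 1
    af = e[2:] - 2 * e[1:-1] + e[:-2]  # af[i] at position i+1 (0-based)
    return int(np.argmax(af) + 1)


def select_n_factors(ratings, methods=("parallel", "kaiser", "acceleration"),
                     *, n_iter: int = 100, seed: int = 0, force: int | None = None) -> int:
    """Modal recommendation over the enabled criteria, ties broken toward
    parallel analysis; ``force`` bypasses selection entirely."""
    if force is not None:
        return int(force)
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 complete rating columns")
    if not methods:
        raise ValueError("no selection method enabled")
    recs = {}
    eig = _eigenvalues(X)
    if "parallel" in methods:
        recs["parallel"] = parallel_analysis(X, n_iter=n_iter, seed=seed)
    if "kaiser" in methods:
        recs["kaiser"] = int((eig > 1.0).sum())
    if "acceleration" in methods:
        recs["acceleration"] = acceleration_factor(eig)
    vals, counts = np.unique(list(recs.values()), return_counts=True)
    best = vals[counts == counts.max()]
    if len(best) == 1:
        return int(best[0])
    return int(recs.get("parallel", best[0]))


def varimax(L: np.ndarray, *, normalize: bool = True, tol: float = 1e-10,
            max_iter: int = 1000) -> np.ndarray:
    """Varimax rotation (SVD algorithm, Kaiser row normalization)."""
    L = np.asarray(L, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L
    h = np.sqrt((L ** 2).sum(axis=1)) if normalize else np.ones(p)
    h[h == 0] = 1.0
    A = L / h[:, None]
    T = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        B = A @ T
        U, s, Vt = np.linalg.svd(A.T @ (B ** 3 - B @ np.diag((B ** 2).sum(axis=0)) / p))
        T = U @ Vt
        d_new = s.sum()
        if d_new <= d * (1 + tol):
            break
        d = d_new
    return (A @ T) * h[:, None]


def varimax_criterion(L: np.ndarray) -> float:
    """Raw varimax simplicity criterion (sum of column variances of squared loadings)."""
    L2 = np.asarray(L, float) ** 2
    return float((L2.var(axis=0)).sum())


@dataclass
class FactorSolution:
    """Varimax-rotated factor solution on the correlation metric."""

    loadings: pd.DataFrame       # items x factors
    uniquenesses: pd.Series
    rotation: str
    prop_var: pd.Series          # explained variance proportion per factor
    corr: pd.DataFrame           # item correlation matrix used for scoring
    means: pd.Series             # item means used for standardization
    sds: pd.Series               # item SDs used for standardization
    method: str

    @property
    def communalities(self) -> pd.Series:
        return 1.0 - self.uniquenesses


def _minres_loadings(R: np.ndarray, k: int):
    """Minimum-residual extraction: optimize uniquenesses, eigen-truncate."""
    p = R.shape[0]
    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))

    def objective(psi):
        e, V = np.linalg.eigh(R - np.diag(psi))
        resid = e[: p - k]
        grad = -2.0 * (V[:, : p - k] ** 2) @ resid
        return float((resid ** 2).sum()), grad

    res = optimize.minimize(objective, np.clip(1 - smc, 0.05, 0.95), jac=True,
                            method="L-BFGS-B", bounds=[(0.005, 1.0)] * p)
    psi = res.x
    if np.any(psi <= 0.005 + 1e-9):
        warnings.warn("Heywood case: uniqueness clamped at the lower bound")
    e, V = np.linalg.eigh(R - np.diag(psi))
    lead = np.argsort(e)[::-1][:k]
    L = V[:, lead] * np.sqrt(np.clip(e[lead], 0.0, None))
    return L, psi


def _ml_loadings(X: np.ndarray, k: int):
    """Maximum-likelihood extraction via scipy on the standard ML discrepancy."""
    R = np.corrcoef(X, rowvar=False)
    p = R.shape[0]

    def loadings_at(psi):
        d = 1.0 / np.sqrt(psi)
        Rs = R * np.outer(d, d)
        e, V = np.linalg.eigh(Rs)
        lead = np.argsort(e)[::-1][:k]
        lam = np.clip(e[lead] - 1.0, 0.0, None)
        return (V[:, lead] * np.sqrt(lam)) * np.sqrt(psi)[:, None]

    def objective(logpsi):
        psi = np.exp(logpsi)
        d = 1.0 / np.sqrt(psi)
        Rs = R * np.outer(d, d)
        e = np.sort(np.linalg.eigvalsh(Rs))[::-1]
        tail = e[k:]
        return float(np.sum(np.log(np.clip(tail, 1e-12, None)) - tail + 1.0) * -1.0)

    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    res = optimize.minimize(objective, np.log(np.clip(1 - smc, 0.05, 0.95)),
                            method="L-BFGS-B",
                            bounds=[(np.log(0.005), 0.0)] * p)
    psi = np.exp(res.x)
    return loadings_at(psi), psi


def fit_efa(ratings: pd.DataFrame, k: int, *, rotation: str = "varimax",
            method: str = "minres") -> FactorSolution:
    """Fit a k-factor EFA on the item correlation matrix and rotate.

    Factors are ordered by explained variance and signed so the
    largest-|loading| item is positive on each factor.
    """
    X = pd.DataFrame(ratings)
    items = list(X.columns)
    if k >= len(items):
        raise ValueError("k must be smaller than the number of items")
    vals = X.to_numpy(dtype=float)
    if np.isnan(vals).any():
        bad = np.flatnonzero(np.isnan(vals).any(axis=1))
        raise ValueError(f"missing item values in rows {bad[:10].tolist()}")
    sds = vals.std(axis=0, ddof=1)
    if np.any(sds <= 1e-12):
        const = [items[i] for i in np.flatnonzero(sds <= 1e-12)]
        raise ValueError(f"zero-variance items: {const}")
    R = np.corrcoef(vals, rowvar=False)

    # suitability diagnostics are advisory only
    try:
        overall_kmo, _ = kmo(R)
        if overall_kmo < 0.5:
            warnings.warn(f"KMO = {overall_kmo:.2f}: sampling adequacy is poor")
        _, _, p_bart = bartlett_sphericity(R, len(vals))
        if p_bart > 0.05:
            warnings.warn("Bartlett sphericity not rejected: items may be uncorrelated")
    except ValueError:
        warnings.warn("suitability diagnostics unavailable (singular correlation matrix)")

    if method == "minres":
        L, psi = _minres_loadings(R, k)
    elif method == "ml":
        L, psi = _ml_loadings(vals, k)
    else:
        raise ValueError("method must be 'minres' or 'ml'")

    if rotation == "varimax":
        L = varimax(L)
    elif rotation not in (None, "none"):
        raise ValueError("only varimax (or none) rotation is supported")

    ssq = (L ** 2).sum(axis=0)
    order = np.argsort(ssq)[::-1]
    L = L[:, order]
    for j in range(k):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    names = [f"F{j + 1}" for j in range(k)]
    return FactorSolution(
        loadings=pd.DataFrame(L, index=items, columns=names),
        uniquenesses=pd.Series(np.clip(psi, 0.0, 1.0), index=items),
        rotation=rotation or "none",
        prop_var=pd.Series((L ** 2).sum(axis=0) / len(items), index=names),
        corr=pd.DataFrame(R, index=items, columns=items),
        means=pd.Series(vals.mean(axis=0), index=items),
        sds=pd.Series(sds, index=items),
        method=method,
    )


def factor_scores(solution: FactorSolution, ratings: pd.DataFrame) -> pd.DataFrame:
    """Regression (Thurstone) factor scores ``Z R^{-1} L`` on standardized items.

    Standardization uses the solution's stored means/SDs (training-set
    statistics when scoring held-out data), so scores are leakage-free.
    """
    X = pd.DataFrame(ratings)[list(solution.loadings.index)]
    vals = X.to_numpy(dtype=float)
    if np.isnan(vals).any():
        bad = np.flatnonzero(np.isnan(vals).any(axis=1))
        raise ValueError(f"missing item values in rows {bad[:10].tolist()}")
    Z = (vals - solution.means.to_numpy()) / solution.sds.to_numpy()
    W = np.linalg.solve(solution.corr.to_numpy(), solution.loadings.to_numpy())
    return pd.DataFrame(Z @ W, index=X.index, columns=solution.loadings.columns)


def align_loadings(L_hat: np.ndarray, L_ref: np.ndarray):
    """Permute/sign-flip estimated loading columns to best match a reference.

    Returns the aligned copy of ``L_hat``; useful for recovery checks where
    factor order and sign are arbitrary.
    """
    from scipy.optimize import linear_sum_assignment

    L_hat = np.asarray(L_hat, float)
    L_ref = np.asarray(L_ref, float)
    C = L_ref.T @ L_hat
    r, c = linear_sum_assignment(-np.abs(C))
    out = L_hat[:, c].copy()
    for j, (rj, cj) in enumerate(zip(r, c)):
        if C[rj, cj] < 0:
            out[:, j] = -out[:, j]
    return out


def pivot_ratings_wide(ratings: pd.DataFrame, value: str = "rating") -> pd.DataFrame:
    """Arrange one column per rated property, rows = (participant, odor, repetition).

    Each trial rates a single property, so the item matrix lives at the
    (participant, odor, repetition) level; trial-wise scores are obtained by
    broadcasting each row's factor scores back to its member trials.
    """
    wide = ratings.pivot_table(index=["participant_id", "odor", "repetition"],
                               columns="property", values=value, aggfunc="mean")
    return wide


def broadcast_scores(ratings: pd.DataFrame, wide_index: pd.Index,
                     scores: pd.DataFrame, names=None) -> pd.DataFrame:
    """Attach per-(participant, odor, repetition) factor scores to each trial."""
    sc = pd.DataFrame(scores.to_numpy(), index=wide_index,
                      columns=names or list(scores.columns)).reset_index()
    return ratings.merge(sc, on=["participant_id", "odor", "repetition"], how="left")
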