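"""Successive projections algorithm (SPA) for variable screening.

SPA is forward selection that minimizes collinearity: starting from one
column, each step projects every unselected column onto the orthogonal
complement of the span of the selected ones and appends the column with the
largest residual norm.  Chains are built for every possible start column and
every subset size up to ``k_max``; each candidate subset is scored by a
cross-validated RMSE (multiple linear regression with leave-one-out CV by
default); the winning subset is the most parsimonious one whose RMSE is
statistically indistinguishable from the global minimum (see
:func:`spa_select`).

Columns are mean-centred and scaled to unit variance before projection, so
variables with wildly different units (areas in nm, unitless indices,
derivatives in nm^-1) compete on an equal footing; the scaling record is
kept on the result.  The algorithm itself is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-9


@dataclass
class DesignMatrix:
    """Standardized samples x variables matrix with its scaling record."""

    data: pd.DataFrame          # original values, listwise-complete
    standardized: np.ndarray    # z-scored columns
    means: pd.Series
    sds: pd.Series

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DesignMatrix":
        df = df.dropna(axis=0, how="any")
        if df.isna().any().any():
            raise ValueError("design matrix still has missing values")
        sds = df.std(ddof=1)
        # constant columns, including numerically-constant ones whose tiny
        # variance is floating-point dust that standardization would amplify
        tol = 1e-10 * (df.abs().mean() + 1.0)
        degenerate = sds[sds <= tol].index.tolist()
        if degenerate:
            logger.warning("dropping %d zero-variance columns: %s",
                           len(degenerate), degenerate[:10])
            df = df.drop(columns=degenerate)
            sds = sds.drop(degenerate)
        if df.shape[1] == 0:
            raise ValueError("no usable columns in design matrix")
        means = df.mean()
        z = (df - means) / sds
        return cls(df, z.to_numpy(dtype=float), means, sds)

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class SelectionResult:
    """SPA output: the winning chain plus the full RMSE trace."""

    selected: list[str]
    start: str
    k: int
    rmse_trace: pd.DataFrame   # index: start name, columns: k, values: CV RMSE
    criterion: float

    def to_dict(self) -> dict:
        return {"selected": list(self.selected), "start": self.start,
                "k": int(self.k), "criterion": float(self.criterion)}


def _chains_batch(Z: np.ndarray, starts: np.ndarray, k: int) -> list[list[int]]:
    """SPA chains for a batch of start columns, built simultaneously.

    Each chain step replaces every unselected column by its component
    orthogonal to the span of the selected ones (maintained incrementally:
    after each append only the newest residual direction needs projecting
    out) and appends the column of maximal residual norm; ties go to the
    first (lowest) column index.  A chain truncates early if every residual
    norm falls below tolerance (rank deficiency).
    """
    n, p = Z.shape
    B = len(starts)
    R = np.broadcast_to(Z, (B, n, p)).copy()
    chains = np.full((B, k), -1, dtype=int)
    chains[:, 0] = starts
    lengths = np.ones(B, dtype=int)
    available = np.ones((B, p), dtype=bool)
    available[np.arange(B), starts] = False
    active = np.ones(B, dtype=bool)
    for _ in range(1, k):
        if not active.any():
            break
        last = chains[np.arange(B), lengths - 1]
        v = R[np.arange(B), :, last]                      # (B, n)
        nv = np.einsum("bi,bi->b", v, v)
        active &= nv >= _RANK_TOL
        safe_nv = np.where(nv < _RANK_TOL, 1.0, nv)
        coef = np.einsum("bi,bip->bp", v, R)
        R -= (v / safe_nv[:, None])[:, :, None] * coef[:, None, :]
        norms = np.einsum("bip,bip->bp", R, R)
        norms[~available] = -np.inf
        nxt = norms.argmax(axis=1)
        ok = active & (norms[np.arange(B), nxt] >= _RANK_TOL)
        chains[ok, lengths[ok]] = nxt[ok]
        available[np.flatnonzero(ok), nxt[ok]] = False
        lengths[ok] += 1
        active = ok
    if np.any(lengths < k):
        logger.info("SPA: %d of %d chains truncated by rank deficiency",
                    int(np.sum(lengths < k)), B)
    return [chains[b, :lengths[b]].tolist() for b in range(B)]


def _chain_indices(Z: np.ndarray, start: int, k: int) -> list[int]:
    """SPA chain as column indices on a standardized matrix."""
    return _chains_batch(Z, np.asarray([start]), k)[0]


def spa_chain(X: DesignMatrix | pd.DataFrame, start: str, k: int) -> list[str]:
    """Ordered SPA chain of length <= k beginning at *start*."""
    dm = X if isinstance(X, DesignMatrix) else DesignMatrix.from_frame(X)
    n, p = dm.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k={k} outside [1, min(n-1={n-1}, p={p})]")
    start_idx = dm.names.index(start)
    return [dm.names[i] for i in _chain_indices(dm.standardized, start_idx, k)]


def loo_mlr_rmse(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out RMSE of ordinary least squares, via the hat matrix."""
    n = X.shape[0]
    A = np.column_stack([np.ones(n), X])
    Q, Rr = np.linalg.qr(A)
    if np.any(np.abs(np.diag(Rr)) < _RANK_TOL * max(1.0, np.abs(Rr[0, 0]))):
        raise np.linalg.LinAlgError("rank-deficient design")
    beta = np.linalg.solve(Rr, Q.T @ y)
    resid = y - A @ beta
    h = np.einsum("ij,ij->i", Q, Q)
    denom = 1.0 - h
    if np.any(denom < 1e-10):
        raise np.linalg.LinAlgError("leverage one: LOO undefined")
    e = resid / denom
    return float(np.sqrt(np.mean(e**2)))


def spa_select(X: DesignMatrix | pd.DataFrame, y, k_max: int | None = None,
               evaluator=loo_mlr_rmse,
               parsimony_alpha: float | None = 0.25) -> SelectionResult:
    """Run SPA from every start and pick a subset by cross-validated RMSE.

    With ``parsimony_alpha=None`` the (start, k) with the smallest RMSE wins
    outright (ties to smaller k, then start name).  By default an F-test
    parsimony rule is applied instead: among all subsets whose RMSE is not
    significantly worse than the global minimum (variance ratio below the
    F(n, n) critical value at *parsimony_alpha*), the smallest k wins, then
    the smallest RMSE, then the start name.  Comparing raw minima across
    thousands of candidate subsets systematically favours lucky noise
    variables; the parsimony rule suppresses that selection bias.
    """
    dm = X if isinstance(X, DesignMatrix) else DesignMatrix.from_frame(X)
    y = np.asarray(pd.Series(y).loc[dm.data.index] if isinstance(y, pd.Series)
                   else y, dtype=float)
    n, p = dm.shape
    if n < 4:
        raise ValueError("need at least 4 samples")
    if k_max is None:
        k_max = min(10, p, n - 2)
    if not 1 <= k_max <= min(n - 1, p):
        raise ValueError(f"k_max={k_max} outside [1, min(n-1, p)]")

    Z = dm.standardized
    names = dm.names
    trace = np.full((p, k_max), np.nan)
    # chains are selection bookkeeping only; single precision suffices for
    # wide matrices and halves the memory traffic of the projection sweeps
    Zc = Z.astype(np.float32) if p > 256 else Z
    chains: list[list[int]] = []
    for lo in range(0, p, 8):
        chains.extend(_chains_batch(Zc, np.arange(lo, min(lo + 8, p)), k_max))
    for s, chain in enumerate(chains):
        for k in range(1, len(chain) + 1):
            try:
                trace[s, k - 1] = evaluator(Z[:, chain[:k]], y)
            except np.linalg.LinAlgError as exc:
                logger.info("subset %s skipped: %s",
                            [names[i] for i in chain[:k]], exc)
    if np.all(np.isnan(trace)):
        raise RuntimeError("evaluator failed on every candidate subset")

    rmse_min = float(np.nanmin(trace))
    if parsimony_alpha is not None:
        fcrit = f_dist.ppf(1.0 - parsimony_alpha, n, n)
        threshold = rmse_min * float(np.sqrt(fcrit)) + 1e-12
    else:
        threshold = rmse_min
    best = None  # (k, rmse, start_name, start_idx)
    for s in range(p):
        for k in range(1, k_max + 1):
            rmse = trace[s, k - 1]
            if np.isnan(rmse) or rmse > threshold:
                continue
            key = (k, rmse, names[s])
            if best is None or key < best[:3]:
                best = (k, rmse, names[s], s)
    k, rmse, start_name, s = best
    trace_df = pd.DataFrame(trace, index=pd.Index(names, name="start"),
                            columns=pd.RangeIndex(1, k_max + 1, name="k"))
    return SelectionResult(selected=[names[i] for i in chains[s][:k]],
                           start=start_name, k=k, rmse_trace=trace_df,
                           criterion=rmse)
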