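"""Constrained-ordination primitives.

Redundancy analysis (RDA) is the PCA of the least-squares projection of a
multivariate response Y onto the span of a predictor matrix X; partial RDA
first removes a conditioning set Z from both.  Significance is assessed by
permutation of the response rows (marginal tests) or of reduced-model
residuals (partial tests).  Forward selection follows the double-stopping
rule: a candidate enters only while its permutation p-value stays below
alpha *and* the cumulative adjusted R² stays below the adjusted R² of the
full candidate model; selection is skipped entirely when the full model is
non-significant.  A minimal NIPALS partial-least-squares regression provides
low-dimensional "biotic" summaries of one community for use as predictors of
the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    CollinearityError,
    DegenerateResponseError,
    DegreesOfFreedomError,
    EmptyCandidateError,
    InvalidParameterError,
    RankError,
    ZeroInformationError,
)

_RANK_TOL = 1e-10


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------
def _as2d(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def clean_columns(
    X: np.ndarray,
    names: list[str] | None = None,
    on_collinear: str = "raise",
) -> tuple[np.ndarray, list[int]]:
    """Detect constant and exactly collinear columns of a centered matrix.

    Returns the cleaned matrix and the kept column indices.  With
    ``on_collinear="raise"`` an offending column raises
    :class:`CollinearityError` naming it; with ``"drop"`` later columns are
    dropped with a warning.
    """
    X = _as2d(X)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    Xc = _center(X)
    kept: list[int] = []
    basis: np.ndarray | None = None
    scale = max(np.abs(Xc).max(), 1.0)
    for j in range(Xc.shape[1]):
        col = Xc[:, j]
        norm = np.linalg.norm(col)
        if norm <= _RANK_TOL * scale * np.sqrt(len(col)):
            if on_collinear == "raise":
                raise CollinearityError(f"column {names[j]!r} is constant")
            warnings.warn(f"dropping constant column {names[j]!r}")
            continue
        if basis is not None:
            resid = col - basis @ (basis.T @ col)
            if np.linalg.norm(resid) <= 1e-8 * norm:
                if on_collinear == "raise":
                    raise CollinearityError(
                        f"column {names[j]!r} is collinear with earlier columns"
                    )
                warnings.warn(f"dropping collinear column {names[j]!r}")
                continue
            vec = resid / np.linalg.norm(resid)
            basis = np.hstack([basis, vec[:, None]])
        else:
            basis = (col / norm)[:, None]
        kept.append(j)
    return X[:, kept], kept


def _orthonormal_basis(X: np.ndarray, tol: float = _RANK_TOL) -> np.ndarray:
    """Orthonormal basis of the column span of a (centered) matrix."""
    if X.size == 0:
        return np.zeros((X.shape[0], 0))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > tol * (s[0] if s.size else 1.0)))
    return U[:, :rank]


def _residualize(A: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Residuals of A after projection on the orthonormal basis Q."""
    if Q.shape[1] == 0:
        return A
    return A - Q @ (Q.T @ A)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------
@dataclass
class RdaResult:
    r2: float
    r2_adj: float
    n: int
    m: int
    eigenvalues: np.ndarray
    pseudo_f: float
    perm_p: float | None = None

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvalues = ev


@dataclass
class ForwardSelectionResult:
    selected: list[str]
    p_values: list[float]
    cumulative_r2_adj: list[float]
    global_r2_adj: float
    global_p: float
    stop_reason: str  # alpha | r2adj_ceiling | exhausted | global_ns


@dataclass
class PlsComponents:
    scores: np.ndarray  # sites x h (X-side component scores)
    x_weights: np.ndarray  # p x h
    y_weights: np.ndarray  # q x h (loadings of Y on each score)
    explained: np.ndarray  # per-component % of Y variance
    cumulative: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.cumulative = np.cumsum(self.explained)


# ---------------------------------------------------------------------------
# RDA and friends
# ---------------------------------------------------------------------------
def rda_fit(
    Y,
    X,
    names: list[str] | None = None,
    on_collinear: str = "raise",
) -> RdaResult:
    """Redundancy analysis of responses Y constrained by predictors X.

    Both matrices are centered internally.  ``r2`` is the proportion of the
    total response sum of squares captured by the least-squares projection of
    Y onto span(X); the eigenvalues are those of the fitted-value covariance
    (nonincreasing).
    """
    Y = _center(_as2d(Y))
    tot = float(np.sum(Y * Y))
    if tot <= 0:
        raise DegenerateResponseError("response matrix has zero variance")
    Xk, kept = clean_columns(X, names, on_collinear)
    n = Y.shape[0]
    if Xk.shape[0] != n:
        raise ValueError("Y and X must have the same number of rows")
    Q = _orthonormal_basis(_center(Xk))
    m = Q.shape[1]
    Yhat = Q @ (Q.T @ Y)
    ss_fit = float(np.sum(Yhat * Yhat))
    r2 = ss_fit / tot
    ev = np.linalg.svd(Yhat, compute_uv=False) ** 2 / max(n - 1, 1)
    ev = ev[: min(m, Y.shape[1])]
    df_res = n - m - 1
    pseudo_f = np.inf if df_res <= 0 or r2 >= 1 else (r2 / m) / ((1 - r2) / df_res)
    r2a = adjusted_r2(r2, n, m) if df_res >= 1 else float("nan")
    return RdaResult(r2=r2, r2_adj=r2a, n=n, m=m, eigenvalues=ev, pseudo_f=pseudo_f)


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment 1 − (1 − R²)(n − 1)/(n − m − 1); may be negative."""
    if n - m - 1 < 1:
        raise DegreesOfFreedomError(f"n - m - 1 = {n - m - 1} < 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _perm_r2(Yc: np.ndarray, Q: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Unadjusted R² of each row-permuted response on the basis Q (vectorized)."""
    tot = float(np.sum(Yc * Yc))
    out = np.empty(perms.shape[0])
    chunk = max(1, int(2e7 // max(Yc.size, 1)))
    for start in range(0, perms.shape[0], chunk):
        idx = perms[start : start + chunk]
        Yp = Yc[idx]  # (c, n, q)
        proj = np.einsum("nm,cnq->cmq", Q, Yp)
        out[start : start + chunk] = np.einsum("cmq,cmq->c", proj, proj) / tot
    return out


def rda_permutation_test(
    Y, X, n_perm: int, seed: int | np.random.Generator | None = None
) -> RdaResult:
    """Marginal permutation test of the RDA model; permutes rows of Y.

    p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = rda_fit(Y, X, on_collinear="drop")
    rng = np.random.default_rng(seed)
    Yc = _center(_as2d(Y))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Xd = clean_columns(X, on_collinear="drop")[0]
    Q = _orthonormal_basis(_center(Xd))
    n, m = Yc.shape[0], Q.shape[1]
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    r2p = _perm_r2(Yc, Q, perms)
    # F is monotone in R² for fixed (n, m); compare on R² directly
    exceed = int(np.sum(r2p >= res.r2 - 1e-12))
    res.perm_p = (1 + exceed) / (n_perm + 1)
    return res


def partial_rda(
    Y,
    X,
    Z=None,
    n_perm: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> RdaResult:
    """Partial RDA of Y on X conditioning on Z.

    Equals :func:`rda_fit` on the residuals of Y and X after least-squares
    removal of Z; the (semipartial) R² is reported on the total variance of
    the original, centered Y.  When ``n_perm`` is given, significance is
    assessed by permuting reduced-model residuals of Y.
    """
    Y = _center(_as2d(Y))
    tot = float(np.sum(Y * Y))
    if tot <= 0:
        raise DegenerateResponseError("response matrix has zero variance")
    if Z is None or _as2d(Z).shape[1] == 0:
        if n_perm is None:
            return rda_fit(Y, X)
        return rda_permutation_test(Y, X, n_perm, seed)
    Xc, _ = clean_columns(X, on_collinear="drop")
    Zc, _ = clean_columns(Z, on_collinear="drop")
    Qz = _orthonormal_basis(_center(Zc))
    Xcc = _center(Xc)
    Xres = _residualize(Xcc, Qz)
    # residue must be judged against the scale of X itself, not of Xres
    if np.linalg.norm(Xres) <= 1e-8 * max(np.linalg.norm(Xcc), 1e-30):
        raise ZeroInformationError("span(X) is contained in span(Z)")
    Yfit_z = Qz @ (Qz.T @ Y)
    Yres = Y - Yfit_z
    Qx = _orthonormal_basis(Xres)
    m, mz = Qx.shape[1], Qz.shape[1]
    n = Y.shape[0]
    Yhat = Qx @ (Qx.T @ Yres)
    ss_fit = float(np.sum(Yhat * Yhat))
    r2 = ss_fit / tot  # semipartial: scaled by the total variance of Y
    ss_res = float(np.sum(Yres * Yres)) - ss_fit
    df_res = n - m - mz - 1
    if df_res < 1:
        raise DegreesOfFreedomError("no residual degrees of freedom")
    pseudo_f = (ss_fit / m) / (ss_res / df_res) if ss_res > 0 else np.inf
    ev = np.linalg.svd(Yhat, compute_uv=False) ** 2 / max(n - 1, 1)
    res = RdaResult(
        r2=r2,
        r2_adj=adjusted_r2(r2, n, m),
        n=n,
        m=m,
        eigenvalues=ev[: min(m, Y.shape[1])],
        pseudo_f=pseudo_f,
    )
    if n_perm is not None:
        if n_perm < 1:
            raise InvalidParameterError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        exceed = 0
        ss_z = Yfit_z  # fixed part under the reduced model
        chunkF = np.empty(n_perm)
        for b in range(n_perm):
            Yp = ss_z + Yres[rng.permutation(n)]
            Yp = Yp - Yp.mean(axis=0, keepdims=True)
            Ypr = _residualize(Yp, Qz)
            fit = Qx @ (Qx.T @ Ypr)
            sf = float(np.sum(fit * fit))
            sr = float(np.sum(Ypr * Ypr)) - sf
            chunkF[b] = (sf / m) / (sr / df_res) if sr > 0 else np.inf
        exceed = int(np.sum(chunkF >= pseudo_f - 1e-12))
        res.perm_p = (1 + exceed) / (n_perm + 1)
    return res


# ---------------------------------------------------------------------------
# forward selection with double stopping
# ---------------------------------------------------------------------------
def forward_select(
    Y,
    candidates,
    names: list[str] | None = None,
    alpha: float = 0.05,
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = None,
) -> ForwardSelectionResult:
    """Forward selection of predictor columns with the double-stopping rule.

    At each step the candidate adding the most unadjusted R² is tested by
    permutation; selection stops when that p-value exceeds ``alpha`` or when
    the cumulative adjusted R² would exceed the adjusted R² of the model with
    every candidate (the global ceiling).  If the global model itself is
    non-significant at ``alpha`` nothing is selected.
    """
    X = _as2d(candidates)
    if X.shape[1] == 0:
        raise EmptyCandidateError("no candidate variables")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    rng = np.random.default_rng(seed)
    Yc = _center(_as2d(Y))
    tot = float(np.sum(Yc * Yc))
    if tot <= 0:
        raise DegenerateResponseError("response matrix has zero variance")

    glob = rda_permutation_test(Yc, X, n_perm, rng)
    if glob.perm_p is not None and glob.perm_p > alpha:
        return ForwardSelectionResult(
            [], [], [], glob.r2_adj, glob.perm_p, "global_ns"
        )

    n = Yc.shape[0]
    Xc = _center(X)
    selected: list[int] = []
    pvals: list[float] = []
    cums: list[float] = []
    basis = np.zeros((n, 0))
    remaining = list(range(X.shape[1]))
    stop = "exhausted"
    while remaining:
        # marginal gain of each remaining candidate given current basis
        gains = np.full(len(remaining), -np.inf)
        vecs = {}
        for i, j in enumerate(remaining):
            resid = _residualize(Xc[:, [j]], basis)
            norm = np.linalg.norm(resid)
            if norm <= 1e-8 * max(np.linalg.norm(Xc[:, j]), 1e-30):
                continue  # adds nothing (duplicate / collinear)
            vec = resid / norm
            proj = vec.T @ Yc
            gains[i] = float(np.sum(proj * proj)) / tot
            vecs[i] = vec
        best = int(np.argmax(gains))
        if not np.isfinite(gains[best]) or gains[best] <= 0:
            break
        j = remaining[best]
        # permutation test of the candidate's partial contribution
        trial = np.hstack([basis, vecs[best]])
        m_trial = trial.shape[1]
        p = _partial_candidate_p(Yc, basis, vecs[best], n_perm, rng)
        if p > alpha:
            stop = "alpha"
            break
        r2_cum = _r2_on_basis(Yc, trial, tot)
        r2a_cum = adjusted_r2(r2_cum, n, m_trial)
        if r2a_cum > glob.r2_adj + 1e-12:
            stop = "r2adj_ceiling"
            break
        selected.append(j)
        pvals.append(p)
        cums.append(r2a_cum)
        basis = trial
        remaining.remove(j)
    return ForwardSelectionResult(
        [names[j] for j in selected],
        pvals,
        cums,
        glob.r2_adj,
        glob.perm_p if glob.perm_p is not None else float("nan"),
        stop,
    )


def _r2_on_basis(Yc: np.ndarray, Q: np.ndarray, tot: float) -> float:
    proj = Q.T @ Yc
    return float(np.sum(proj * proj)) / tot


def _partial_candidate_p(
    Yc: np.ndarray,
    basis: np.ndarray,
    vec: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Permutation p for one candidate direction given an orthonormal basis.

    Residuals of Y under the already-selected model are permuted; the
    statistic is the extra sum of squares captured by the candidate
    direction (F is monotone in it for fixed dfs).
    """
    Yres = _residualize(Yc, basis)
    obs = float(np.sum((vec.T @ Yres) ** 2))
    n = Yc.shape[0]
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    # vec' Yres[perm] for all perms at once
    stat = np.empty(n_perm)
    chunk = max(1, int(2e7 // max(Yres.size, 1)))
    v = vec[:, 0]
    for start in range(0, n_perm, chunk):
        idx = perms[start : start + chunk]
        Yp = Yres[idx]
        proj = np.einsum("n,cnq->cq", v, Yp)
        stat[start : start + chunk] = np.sum(proj * proj, axis=1)
    return (1 + int(np.sum(stat >= obs - 1e-12))) / (n_perm + 1)


# ---------------------------------------------------------------------------
# PLSR (NIPALS)
# ---------------------------------------------------------------------------
def plsr_fit(Y, X, h: int, scale_x: bool = True) -> PlsComponents:
    """Partial least-squares regression of Y on X; returns the first ``h``
    X-side component scores and the % of Y variance each explains.

    Components maximize covariance between X- and Y-side scores (NIPALS
    fixed point, computed via the SVD of the cross-covariance); X is deflated
    on each score, which keeps successive scores mutually orthogonal.
    Predictors are centered (and scaled to unit variance when ``scale_x``);
    responses are centered only.
    """
    X = _center(_as2d(X)).copy()
    Y = _center(_as2d(Y))
    if scale_x:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    tot = float(np.sum(Y * Y))
    if tot <= 0:
        raise DegenerateResponseError("response matrix has zero variance")
    rank = np.linalg.matrix_rank(X, tol=_RANK_TOL * max(1.0, np.abs(X).max()))
    if h > rank:
        raise RankError(f"h={h} exceeds rank(X)={rank}")
    n, p = X.shape
    q = Y.shape[1]
    scores = np.empty((n, h))
    Wmat = np.empty((p, h))
    Cmat = np.empty((q, h))
    expl = np.empty(h)
    Xd = X
    for a in range(h):
        M = Xd.T @ Y
        U, s, _ = np.linalg.svd(M, full_matrices=False)
        w = U[:, 0]
        t = Xd @ w
        tt = float(t @ t)
        c = (Y.T @ t) / tt
        pload = (Xd.T @ t) / tt
        Xd = Xd - np.outer(t, pload)
        scores[:, a] = t
        Wmat[:, a] = w
        Cmat[:, a] = c
        expl[a] = float(np.sum((t @ Y) ** 2)) / tt / tot * 100.0
    return PlsComponents(scores=scores, x_weights=Wmat, y_weights=Cmat, explained=expl)
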