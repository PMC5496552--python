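"""Multiblock redundancy analysis (mbRA).

The predictors come in K thematic blocks X_1..X_K over the same sites.  Per
dimension h the method extracts

* a response weight vector v(h): the dominant eigenvector of
  sum_k Y' P_k Y, where P_k projects onto the span of the (deflated) block
  X_k — so the response component u(h) = Y v(h) is the direction of Y best
  reconstructed jointly by the blocks;
* unit-norm block components t_k(h): the normalized projections of u(h)
  onto each block's span;
* block coefficients a_k(h) ∝ cov(u(h), t_k(h)) with sum_k a_k(h)² = 1;
* the global component t(h) = sum_k a_k(h) t_k(h).

Higher dimensions come from deflating every block on t(h); the response is
never deflated.  Because each deflated block is orthogonal to all previous
global components, the t(h) are mutually orthogonal, and for K = 1 the
per-dimension explained variances coincide with the RDA eigenvalue
proportions (the method is a multiblock extension of redundancy analysis).

Two normalized importance indices summarize a fitted model: BlockImp_k =
sum_h λ_h a_k(h)² / sum_h λ_h and VarImp_j = sum_h λ_h (a_k(h) w_kj(h))² /
sum_h λ_h with unit-norm within-block weight vectors w_k(h); each sums to 1
and is read against the agnostic thresholds 1/K and 1/P.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import BlockCollection
from .exceptions import (
    DegenerateResponseError,
    FoldError,
    InvalidParameterError,
    RankError,
)
from .ordination import _as2d, _center, _orthonormal_basis, _RANK_TOL

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class MbraModel:
    block_names: list[str]
    var_labels: list[str]
    var_block: list[str]  # block name of each variable, concatenation order
    H: int
    # per dimension h (arrays indexed [h] or [h, ...])
    lambdas: np.ndarray  # additional proportion of Y variance per dimension
    a: np.ndarray  # H x K block coefficients, rows have unit sum of squares
    v: np.ndarray  # q x H response weights
    u: np.ndarray  # n x H response components
    t: np.ndarray  # n x H global components (mutually orthogonal)
    t_blocks: np.ndarray  # n x K x H unit-norm block components
    w_star: np.ndarray  # P x H global variable weights a_k * w_kj (unit norm)
    rotations: np.ndarray  # P x H: t_h = X_centered_scaled @ rotations[:, h]
    y_coefs: np.ndarray  # q x H regression coefficients of Y on t_h
    block_explained: np.ndarray  # K x H cumulative explained variance per block
    y_explained: np.ndarray  # H cumulative explained Y variance
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: np.ndarray

    @property
    def K(self) -> int:
        return len(self.block_names)

    @property
    def P(self) -> int:
        return len(self.var_labels)

    def predict(self, blocks: BlockCollection) -> np.ndarray:
        """Predict responses for new sites via the original-variable
        expression of the global components."""
        X = blocks.concat().to_numpy(dtype=float)
        return self.predict_array(X)

    def predict_array(self, X: np.ndarray, h: int | None = None) -> np.ndarray:
        h = self.H if h is None else h
        Xs = (X - self.x_center) / self.x_scale
        T = Xs @ self.rotations[:, :h]
        return T @ self.y_coefs[:, :h].T + self.y_center


@dataclass
class ImportanceResult:
    values: np.ndarray
    labels: list[str]
    threshold: float
    flagged: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.flagged = [
            lab
            for lab, val in zip(self.labels, self.values)
            if val > self.threshold
        ]


@dataclass
class CvResult:
    rmsep: np.ndarray  # mean prediction error per number of components
    h_best: int
    h_max: int
    folds: int
    repeats: int
    seed: int | None


@dataclass
class ToleranceIntervals:
    level: float
    block_lo: np.ndarray
    block_hi: np.ndarray
    var_lo: np.ndarray
    var_hi: np.ndarray
    block_names: list[str]
    var_labels: list[str]
    n_replicates: int
    n_failed: int


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------
def _prepare(Y, blocks: BlockCollection):
    Y = _as2d(Y)
    Xfull = blocks.concat().to_numpy(dtype=float)
    if Y.shape[0] != Xfull.shape[0]:
        raise ValueError("response and blocks must share the site set")
    y_center = Y.mean(axis=0)
    Yc = Y - y_center
    if float(np.sum(Yc * Yc)) <= 0:
        raise DegenerateResponseError("response matrix has zero variance")
    x_center = Xfull.mean(axis=0)
    x_scale = Xfull.std(axis=0, ddof=1)
    const = x_scale <= _RANK_TOL * max(1.0, np.abs(Xfull).max())
    if const.any():
        logger.warning(
            "constant predictor columns scaled to zero weight: %s",
            [blocks.variable_labels()[j] for j in np.where(const)[0]],
        )
    x_scale = np.where(const, 1.0, x_scale)
    Xs = (Xfull - x_center) / x_scale
    Xs[:, const] = 0.0
    widths = [df.shape[1] for df in blocks.blocks.values()]
    idx, start = [], 0
    for w in widths:
        idx.append(slice(start, start + w))
        start += w
    return Yc, Xs, idx, x_center, x_scale, y_center


def mbra_fit(Y, blocks: BlockCollection, H: int) -> MbraModel:
    """Fit an mbRA model with ``H`` dimensions.

    Raises :class:`RankError` when ``H`` exceeds the rank of the concatenated
    (centered, scaled) predictor matrix and :class:`DegenerateResponseError`
    for a zero-variance response.
    """
    if H < 1:
        raise InvalidParameterError("H must be >= 1")
    Yc, Xs, idx, x_center, x_scale, y_center = _prepare(Y, blocks)
    total_rank = np.linalg.matrix_rank(Xs, tol=_RANK_TOL * max(1.0, np.abs(Xs).max()))
    if H > total_rank:
        raise RankError(f"H={H} exceeds rank {total_rank} of the concatenated blocks")
    n, q = Yc.shape
    K = blocks.K
    P = Xs.shape[1]
    tot_y = float(np.sum(Yc * Yc))

    lambdas = np.zeros(H)
    a = np.zeros((H, K))
    v = np.zeros((q, H))
    u = np.zeros((n, H))
    t = np.zeros((n, H))
    t_blocks = np.zeros((n, K, H))
    w_star = np.zeros((P, H))
    rotations = np.zeros((P, H))
    y_coefs = np.zeros((q, H))
    ploads = np.zeros((P, H))

    Xdef = [Xs[:, sl].copy() for sl in idx]
    for h in range(H):
        bases = [_orthonormal_basis(Xk) for Xk in Xdef]
        # criterion matrix sum_k Y' P_k Y
        M = np.zeros((q, q))
        for Q in bases:
            G = Q.T @ Yc
            M += G.T @ G
        evals, evecs = np.linalg.eigh(M)
        vh = evecs[:, -1]
        uh = Yc @ vh
        a_raw = np.zeros(K)
        w_blocks = [np.zeros(Xdef[k].shape[1]) for k in range(K)]
        s_norm = np.zeros(K)
        for k, (Xk, Q) in enumerate(zip(Xdef, bases)):
            if Q.shape[1] == 0:
                continue
            s = Q @ (Q.T @ uh)  # projection of u onto block span
            ns = np.linalg.norm(s)
            if ns <= 1e-12 * max(np.linalg.norm(uh), 1e-30):
                continue
            t_blocks[:, k, h] = s / ns
            a_raw[k] = float(uh @ t_blocks[:, k, h])  # = ||P_k u|| >= 0
            # minimum-norm block weights reproducing the projection
            w = np.linalg.pinv(Xk, rcond=_RANK_TOL) @ uh
            w_blocks[k] = w
            s_norm[k] = ns
        na = np.linalg.norm(a_raw)
        if na <= 0:
            raise RankError(f"no block information left at dimension {h + 1}")
        a[h] = a_raw / na
        th = t_blocks[:, :, h] @ a[h]
        tt = float(th @ th)
        t[:, h] = th
        v[:, h] = vh
        u[:, h] = uh
        # global variable weights: t_h = X_def @ w_star_raw
        w_raw = np.zeros(P)
        for k, sl in enumerate(idx):
            if s_norm[k] > 0:
                w_raw[sl] = a[h, k] * w_blocks[k] / s_norm[k]
        # unit-norm per-block weights for VarImp: a_k * (w_k / ||w_k||)
        for k, sl in enumerate(idx):
            nw = np.linalg.norm(w_blocks[k])
            if nw > 0:
                w_star[sl, h] = a[h, k] * w_blocks[k] / nw
        # rotation to original (centered, scaled) variables
        r = w_raw - rotations[:, :h] @ (ploads[:, :h].T @ w_raw)
        rotations[:, h] = r
        ploads[:, h] = np.concatenate([Xk.T @ th for Xk in Xdef]) / tt
        y_coefs[:, h] = (Yc.T @ th) / tt
        lambdas[h] = float(np.sum((th @ Yc) ** 2)) / tt / tot_y
        # deflate every block on the global component
        for k in range(K):
            Xk = Xdef[k]
            Xdef[k] = Xk - np.outer(th, (th @ Xk) / tt)

    # cumulative explained variances of Y and of each original block
    y_explained = np.cumsum(lambdas)
    block_explained = np.zeros((K, H))
    for k, sl in enumerate(idx):
        Xk0 = Xs[:, sl]
        tot_k = float(np.sum(Xk0 * Xk0))
        for h in range(H):
            T = t[:, : h + 1]
            coef = np.linalg.solve(T.T @ T, T.T @ Xk0)
            fit = T @ coef
            block_explained[k, h] = (
                float(np.sum(fit * fit)) / tot_k if tot_k > 0 else 0.0
            )

    return MbraModel(
        block_names=blocks.names,
        var_labels=blocks.variable_labels(),
        var_block=blocks.block_of(),
        H=H,
        lambdas=lambdas,
        a=a,
        v=v,
        u=u,
        t=t,
        t_blocks=t_blocks,
        w_star=w_star,
        rotations=rotations,
        y_coefs=y_coefs,
        block_explained=block_explained,
        y_explained=y_explained,
        x_center=x_center,
        x_scale=x_scale,
        y_center=y_center,
    )


# ---------------------------------------------------------------------------
# importance indices
# ---------------------------------------------------------------------------
def block_importance(model: MbraModel) -> ImportanceResult:
    """BlockImp_k = sum_h λ_h a_k(h)² / sum_h λ_h; threshold 1/K."""
    w = model.lambdas / model.lambdas.sum()
    values = (model.a**2 * w[:, None]).sum(axis=0)
    return ImportanceResult(values, model.block_names, 1.0 / model.K)


def variable_importance(model: MbraModel) -> ImportanceResult:
    """VarImp_j = sum_h λ_h (a_k w_kj)(h)² / sum_h λ_h; threshold 1/P."""
    w = model.lambdas / model.lambdas.sum()
    contrib = model.w_star**2  # P x H, each column sums to sum_k a_k^2 = 1
    values = contrib @ w
    # renormalize defensively (empty blocks contribute exact zeros)
    s = values.sum()
    if s > 0:
        values = values / s
    return ImportanceResult(values, model.var_labels, 1.0 / model.P)


# ---------------------------------------------------------------------------
# cross-validated dimensionality
# ---------------------------------------------------------------------------
def select_ncomp_cv(
    Y,
    blocks: BlockCollection,
    h_max: int,
    folds: int = 2,
    repeats: int = 100,
    seed: int | None = None,
    rel_tol: float = 1e-6,
) -> CvResult:
    """Choose the number of mbRA dimensions by repeated random k-fold CV.

    The error is the root mean squared error of prediction pooled over all
    response variables and held-out sites; the chosen H* is the smallest h
    whose mean error is within ``rel_tol`` (relative) of the minimum.
    """
    if folds < 2:
        raise FoldError("folds must be >= 2")
    if h_max < 1:
        raise InvalidParameterError("h_max must be >= 1")
    Y = _as2d(Y)
    n = Y.shape[0]
    if n < folds:
        raise FoldError(f"cannot form {folds} folds from {n} sites")
    rng = np.random.default_rng(seed)
    sq_err = np.zeros(h_max)
    counts = np.zeros(h_max)
    frame = blocks.concat()
    for _ in range(repeats):
        perm = rng.permutation(n)
        fold_ids = np.array_split(perm, folds)
        for test_idx in fold_ids:
            train_idx = np.setdiff1d(perm, test_idx, assume_unique=True)
            sub_blocks = BlockCollection(
                {name: df.iloc[train_idx] for name, df in blocks.blocks.items()}
            )
            Xtest = frame.iloc[test_idx].to_numpy(dtype=float)
            Ytest = Y[test_idx]
            # a fold may run out of informative directions (e.g. noiseless
            # low-rank response) before h_max; back off to what it supports
            h_try = _train_hmax(sub_blocks, h_max)
            model = None
            while h_try >= 1:
                try:
                    model = mbra_fit(Y[train_idx], sub_blocks, h_try)
                    break
                except RankError:
                    h_try -= 1
            if model is None:
                continue
            for h in range(1, model.H + 1):
                pred = model.predict_array(Xtest, h=h)
                sq_err[h - 1] += float(np.sum((pred - Ytest) ** 2))
                counts[h - 1] += pred.size
    if not counts.any():
        raise FoldError("no fold supported a fit")
    valid = counts > 0
    rmsep = np.full(h_max, np.inf)
    rmsep[valid] = np.sqrt(sq_err[valid] / counts[valid])
    best = float(np.min(rmsep))
    h_best = int(np.argmax(rmsep <= best * (1 + rel_tol))) + 1
    return CvResult(rmsep=rmsep, h_best=h_best, h_max=h_max, folds=folds,
                    repeats=repeats, seed=seed)


def _train_hmax(blocks: BlockCollection, h_max: int) -> int:
    X = blocks.concat().to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    r = np.linalg.matrix_rank(Xc, tol=_RANK_TOL * max(1.0, np.abs(Xc).max()))
    return max(1, min(h_max, int(r)))


# ---------------------------------------------------------------------------
# bootstrap tolerance intervals
# ---------------------------------------------------------------------------
def bootstrap_intervals(
    Y,
    blocks: BlockCollection,
    H: int,
    B: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> ToleranceIntervals:
    """Percentile tolerance intervals for BlockImp and VarImp.

    Sites are resampled with replacement ``B`` times and the model refitted;
    replicates whose resample loses too much predictor rank are dropped (and
    counted).  Importance indices are sign-free (they square the weights), so
    no axis alignment beyond the per-dimension ordering is needed.
    """
    if B < 2:
        raise InvalidParameterError("B must be >= 2")
    Y = _as2d(Y)
    n = Y.shape[0]
    rng = np.random.default_rng(seed)
    block_vals = []
    var_vals = []
    failed = 0
    ref = mbra_fit(Y, blocks, H)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sub = BlockCollection(
            {name: df.iloc[idx] for name, df in blocks.blocks.items()}
        )
        try:
            m = mbra_fit(Y[idx], sub, H)
        except (RankError, DegenerateResponseError):
            failed += 1
            continue
        block_vals.append(block_importance(m).values)
        var_vals.append(variable_importance(m).values)
    if failed:
        logger.warning("bootstrap: %d of %d replicates dropped (rank failure)",
                       failed, B)
    if not block_vals:
        raise RankError("every bootstrap replicate failed to fit")
    lo_q, hi_q = (1 - level) / 2 * 100, (1 + level) / 2 * 100
    bv = np.array(block_vals)
    vv = np.array(var_vals)
    return ToleranceIntervals(
        level=level,
        block_lo=np.percentile(bv, lo_q, axis=0),
        block_hi=np.percentile(bv, hi_q, axis=0),
        var_lo=np.percentile(vv, lo_q, axis=0),
        var_hi=np.percentile(vv, hi_q, axis=0),
        block_names=ref.block_names,
        var_labels=ref.var_labels,
        n_replicates=B - failed,
        n_failed=failed,
    )
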