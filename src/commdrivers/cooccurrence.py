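"""Matrix-level and pairwise C-score analysis under the fixed–fixed null model.

The C-score of a species pair with row totals R_a, R_b and S shared sites is
(R_a − S)(R_b − S): the number of "checkerboard units".  High values mean
segregation, low values aggregation.  The matrix-level statistic is the mean
over all unique pairs.  Null distributions come from the fixed–fixed (FF)
sequential-swap algorithm, which randomizes the binary matrix while holding
every row and column total fixed.

Pairwise screening applies two criteria: the CL (confidence-limit)
criterion flags a pair whose observed C-score falls outside the central
``level`` confidence band of its own null distribution, delimited as null
mean ± z·sd (z the two-sided normal quantile) — the parametric band is the
only reading that stays calibrated on the heavily discrete per-pair score
distributions, where empirical quantile limits are either wildly
anti-conservative (inclusive) or far too strict (exclusive).  The stricter
empirical Mean-Bayes criterion retains, within each bin of a pooled null
score histogram, only the observed excess over the mean null count,
allocated to the most extreme CL-flagged pairs by |SES|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import NormalDist

import numpy as np
import pandas as pd

from ._swap import ff_swap_chain
from .containers import OccurrenceMatrix
from .exceptions import (
    BinningError,
    InvalidParameterError,
    ProvenanceError,
    TooFewSpeciesError,
)

DEFAULT_N_NULL = 1000
DEFAULT_BURN_IN = 30_000
DEFAULT_THIN = 1000
DEFAULT_BINS = 20


# ---------------------------------------------------------------------------
# C-score primitives
# ---------------------------------------------------------------------------
def c_score_pair(occ_a, occ_b) -> int:
    """Checkerboard units (R_a − S)(R_b − S) for two binary site vectors."""
    a = np.asarray(occ_a)
    b = np.asarray(occ_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ra = int(a.sum())
    rb = int(b.sum())
    s = int((a * b).sum())
    return (ra - s) * (rb - s)


def _pair_scores(values: np.ndarray) -> np.ndarray:
    """C-scores of all unique pairs (upper triangle, row-major order)."""
    A = values.astype(np.int64)
    S = A @ A.T
    R = A.sum(axis=1)
    C = (R[:, None] - S) * (R[None, :] - S)
    iu = np.triu_indices(A.shape[0], k=1)
    return C[iu]


def c_score_matrix(m: OccurrenceMatrix | np.ndarray) -> float:
    """Mean C-score over all unique species pairs."""
    values = m.values if isinstance(m, OccurrenceMatrix) else np.asarray(m)
    if values.shape[0] < 2:
        raise TooFewSpeciesError("need at least two species")
    return float(_pair_scores(values).mean())


# ---------------------------------------------------------------------------
# FF null ensemble
# ---------------------------------------------------------------------------
@dataclass
class NullEnsemble:
    matrices: np.ndarray  # (n_null, R, C) uint8
    burn_in: int
    thin: int
    seed: int
    n_swaps: int
    source_row_totals: np.ndarray
    source_col_totals: np.ndarray
    degenerate: bool = False

    @property
    def n_null(self) -> int:
        return self.matrices.shape[0]


def _has_checkerboard(A: np.ndarray) -> bool:
    A = A.astype(np.int64)
    S = A @ A.T
    R = A.sum(axis=1)
    D = (R[:, None] - S) * (R[None, :] - S)
    np.fill_diagonal(D, 0)
    return bool((D > 0).any())


def ff_swap_null(
    m: OccurrenceMatrix | np.ndarray,
    n_null: int = DEFAULT_N_NULL,
    burn_in: int = DEFAULT_BURN_IN,
    thin: int = DEFAULT_THIN,
    seed: int | None = None,
) -> NullEnsemble:
    """Sample ``n_null`` matrices from the fixed–fixed null model of ``m``.

    A matrix with no swappable 2×2 checkerboard has a singleton null class;
    a warning is issued and the ensemble holds identical copies.
    """
    values = m.values if isinstance(m, OccurrenceMatrix) else np.asarray(m)
    if not np.isin(values, (0, 1)).all():
        raise InvalidParameterError("matrix must be binary")
    if n_null < 1:
        raise InvalidParameterError("n_null must be >= 1")
    values = values.astype(np.uint8)
    seed = 0 if seed is None else int(seed) % (2**31 - 1)
    degenerate = not _has_checkerboard(values)
    if degenerate:
        warnings.warn("matrix has no swappable checkerboard; null class is a "
                      "singleton — ensemble holds copies of the input")
        mats = np.repeat(values[None], n_null, axis=0)
        n_swaps = 0
    else:
        state = values.copy()
        mats, n_swaps = ff_swap_chain(state, n_null, burn_in, thin, seed)
    return NullEnsemble(
        matrices=mats,
        burn_in=burn_in,
        thin=thin,
        seed=seed,
        n_swaps=n_swaps,
        source_row_totals=values.sum(axis=1).astype(np.int64),
        source_col_totals=values.sum(axis=0).astype(np.int64),
        degenerate=degenerate,
    )


def _check_provenance(values: np.ndarray, ensemble: NullEnsemble) -> None:
    if ensemble.matrices.shape[1:] != values.shape:
        raise ProvenanceError("ensemble shape does not match the matrix")
    if not np.array_equal(values.sum(axis=1), ensemble.source_row_totals) or \
       not np.array_equal(values.sum(axis=0), ensemble.source_col_totals):
        raise ProvenanceError("ensemble margins do not match the matrix")


# ---------------------------------------------------------------------------
# matrix-level test
# ---------------------------------------------------------------------------
@dataclass
class MatrixLevelResult:
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    p_upper: float
    p_lower: float
    n_null: int
    degenerate: bool = False


def matrix_level_test(
    m: OccurrenceMatrix | np.ndarray, ensemble: NullEnsemble
) -> MatrixLevelResult:
    """Compare the observed matrix-level C-score with its FF null distribution.

    ``p_upper`` = (1 + #{null >= obs}) / (n_null + 1); a zero null standard
    deviation marks a degenerate test (SES undefined, p = 1).
    """
    values = m.values if isinstance(m, OccurrenceMatrix) else np.asarray(m)
    _check_provenance(values, ensemble)
    obs = c_score_matrix(values)
    nulls = np.array([c_score_matrix(x) for x in ensemble.matrices])
    mean = float(nulls.mean())
    sd = float(nulls.std(ddof=1)) if len(nulls) > 1 else 0.0
    n = len(nulls)
    if sd == 0.0:
        return MatrixLevelResult(obs, mean, 0.0, float("nan"), 1.0, 1.0, n,
                                 degenerate=True)
    ses = (obs - mean) / sd
    p_upper = (1 + int(np.sum(nulls >= obs - 1e-9))) / (n + 1)
    p_lower = (1 + int(np.sum(nulls <= obs + 1e-9))) / (n + 1)
    return MatrixLevelResult(obs, mean, sd, ses, p_upper, p_lower, n)


# ---------------------------------------------------------------------------
# pairwise analysis
# ---------------------------------------------------------------------------
@dataclass
class PairResult:
    species_a: str
    species_b: str
    pair_category: str  # p-p | l-l | p-l
    r_a: int
    r_b: int
    shared: int
    c_obs: int
    null_mean: float
    null_sd: float
    ses: float
    cl_flag: bool
    bayesm_flag: bool
    classification: str  # aggregated | segregated | random
    degenerate: bool = False


def _category(group_a: str, group_b: str) -> str:
    short = {"plant": "p", "leafhopper": "l"}
    pair = sorted(short.get(g, "?") for g in (group_a, group_b))
    if pair == ["l", "p"]:
        return "p-l"
    return f"{pair[0]}-{pair[1]}"


def pairwise_test(
    m: OccurrenceMatrix,
    ensemble: NullEnsemble,
    level: float = 0.95,
    groups: dict | None = None,
) -> list[PairResult]:
    """Per-pair C-score test against the FF null ensemble (CL criterion).

    A pair is CL-flagged when its observed C-score lies outside the
    ``level`` confidence limits of its null distribution, null mean ±
    z·sd with z the two-sided standard-normal quantile; pairs with zero
    null variance are degenerate and never flagged.  Classification:
    segregated when flagged with c_obs above the null mean, aggregated when
    below, random otherwise.
    """
    if not 0 < level < 1:
        raise InvalidParameterError("level must be in (0, 1)")
    values = m.values
    _check_provenance(values, ensemble)
    species = m.species_ids
    if groups is None:
        if m.provenance is not None and "trophic_group" in m.provenance.columns:
            groups = m.provenance["trophic_group"].to_dict()
        else:
            groups = {}
    obs = _pair_scores(values)
    nulls = np.stack([_pair_scores(x) for x in ensemble.matrices])  # (B, npair)
    B = nulls.shape[0]
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1) if B > 1 else np.zeros_like(mean)
    z_crit = NormalDist().inv_cdf((1 + level) / 2)
    iu = np.triu_indices(len(species), k=1)
    A = values.astype(np.int64)
    S = A @ A.T
    R = A.sum(axis=1)
    out: list[PairResult] = []
    for idx, (i, j) in enumerate(zip(*iu)):
        degen = sd[idx] == 0.0
        ses = float((obs[idx] - mean[idx]) / sd[idx]) if not degen else float("nan")
        flag = bool(not degen and abs(ses) > z_crit)
        if flag and obs[idx] > mean[idx]:
            cls = "segregated"
        elif flag and obs[idx] < mean[idx]:
            cls = "aggregated"
        else:
            # flagged with c_obs exactly at the null mean cannot be classified
            cls = "random"
            flag = False
        out.append(
            PairResult(
                species_a=str(species[i]),
                species_b=str(species[j]),
                pair_category=_category(
                    groups.get(species[i], "?"), groups.get(species[j], "?")
                ),
                r_a=int(R[i]),
                r_b=int(R[j]),
                shared=int(S[i, j]),
                c_obs=int(obs[idx]),
                null_mean=float(mean[idx]),
                null_sd=float(sd[idx]),
                ses=ses,
                cl_flag=flag,
                bayesm_flag=False,
                classification=cls,
                degenerate=bool(degen),
            )
        )
    return out


def bayes_m_filter(
    pairs: list[PairResult],
    ensemble: NullEnsemble,
    n_bins: int = DEFAULT_BINS,
) -> list[PairResult]:
    """Empirical Mean-Bayes screening of CL-flagged pairs (in place).

    Pooled null pair scores define ``n_bins`` equal-width bins (top bin
    closed).  For each bin whose observed pair count exceeds the mean null
    count, the excess (rounded up) most extreme CL-flagged pairs by |SES|
    keep their flag; everything else is cleared.  The Bayes-M set is a
    subset of the CL set by construction.
    """
    if n_bins < 2:
        raise BinningError("n_bins must be >= 2")
    null_scores = np.stack([_pair_scores(x) for x in ensemble.matrices])
    obs_scores = np.array([p.c_obs for p in pairs])
    lo = min(float(null_scores.min()), float(obs_scores.min()))
    hi = max(float(null_scores.max()), float(obs_scores.max()))
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    expected = np.zeros(n_bins)
    for nm in null_scores:
        expected += np.histogram(nm, bins=edges)[0]
    expected /= null_scores.shape[0]
    observed = np.histogram(obs_scores, bins=edges)[0]
    bin_of = np.clip(np.digitize(obs_scores, edges) - 1, 0, n_bins - 1)
    for p in pairs:
        p.bayesm_flag = False
    for b in range(n_bins):
        excess = observed[b] - expected[b]
        if excess <= 0:
            continue
        n_extra = int(np.ceil(excess))
        members = [
            (abs(p.ses), k)
            for k, p in enumerate(pairs)
            if bin_of[k] == b and p.cl_flag and np.isfinite(p.ses)
        ]
        members.sort(reverse=True)
        for _, k in members[:n_extra]:
            pairs[k].bayesm_flag = True
    return pairs


def classify_pairs(
    pairs: list[PairResult],
    meta: pd.DataFrame | dict | None = None,
    criterion: str = "cl",
) -> pd.DataFrame:
    """Cross-tabulate flagged pairs by category × classification.

    ``meta`` maps species id to trophic group; when omitted, the categories
    stored on the pairs are used.  ``criterion`` selects which flag defines
    "significant" (``cl`` or ``bayesm``).
    """
    if criterion not in ("cl", "bayesm"):
        raise InvalidParameterError("criterion must be 'cl' or 'bayesm'")
    if meta is not None:
        if isinstance(meta, pd.DataFrame):
            lookup = meta["trophic_group"].to_dict()
        else:
            lookup = dict(meta)
        for p in pairs:
            for sp in (p.species_a, p.species_b):
                if sp not in lookup:
                    raise KeyError(f"species {sp!r} missing from metadata")
            p.pair_category = _category(lookup[p.species_a], lookup[p.species_b])
    table = pd.DataFrame(
        0,
        index=["p-p", "l-l", "p-l"],
        columns=["aggregated", "segregated"],
        dtype=int,
    )
    for p in pairs:
        flagged = p.cl_flag if criterion == "cl" else p.bayesm_flag
        if flagged and p.classification in table.columns:
            table.loc[p.pair_category, p.classification] += 1
    return table


def pairs_to_frame(pairs: list[PairResult]) -> pd.DataFrame:
    """One PairResult per row, ready for TSV export."""
    return pd.DataFrame([vars(p) for p in pairs])
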