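"""Variation partitioning of a community matrix between two predictor sets.

The explained variance is decomposed, on the adjusted-R² scale, into the
pure abiotic fraction [a], the pure biotic fraction [b], the shared fraction
[c] and the unexplained remainder [d]:

    [a] = R²adj(A ∪ B) − R²adj(B)
    [b] = R²adj(A ∪ B) − R²adj(A)
    [c] = R²adj(A) + R²adj(B) − R²adj(A ∪ B)
    [d] = 1 − R²adj(A ∪ B)

[a] and [b] are testable by partial-RDA permutation; [c] is a difference of
adjusted R² values with no associated permutation test and is reported
untested.  Negative adjusted fractions are reported as computed (standard
for adjusted partitions) — truncating them would break the additive
identities above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError, OverfitError
from .ordination import _as2d, partial_rda, rda_fit, rda_permutation_test


@dataclass
class VarpartResult:
    fraction_a: float
    fraction_b: float
    fraction_c: float
    fraction_d: float
    r2adj_abiotic: float
    r2adj_biotic: float
    r2adj_full: float
    p_a: float | None
    p_b: float | None
    p_full: float | None
    n_perm: int


def varpart2(
    Y,
    X_abiotic,
    X_biotic,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> VarpartResult:
    """Two-set variation partitioning with permutation tests for the
    testable fractions ([a], [b] and the full model)."""
    Xa = _as2d(X_abiotic)
    Xb = _as2d(X_biotic)
    if Xa.shape[1] == 0 or Xb.shape[1] == 0:
        raise InvalidParameterError("both predictor sets must be nonempty")
    Y = _as2d(Y)
    n = Y.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res_a = rda_fit(Y, Xa, on_collinear="drop")
        res_b = rda_fit(Y, Xb, on_collinear="drop")
        res_ab = rda_fit(Y, np.hstack([Xa, Xb]), on_collinear="drop")
    if res_ab.m >= n - 1:
        raise OverfitError(
            f"{res_ab.m} combined predictors leave no residual degrees of "
            f"freedom with {n} sites"
        )
    ra, rb, rab = res_a.r2_adj, res_b.r2_adj, res_ab.r2_adj
    frac_a = rab - rb
    frac_b = rab - ra
    frac_c = ra + rb - rab
    frac_d = 1.0 - rab

    p_a = p_b = p_full = None
    if n_perm and n_perm >= 1:
        rng = np.random.default_rng(seed)
        p_full = rda_permutation_test(
            Y, np.hstack([Xa, Xb]), n_perm, rng
        ).perm_p
        p_a = _testable_fraction_p(Y, Xa, Xb, n_perm, rng)
        p_b = _testable_fraction_p(Y, Xb, Xa, n_perm, rng)
    return VarpartResult(
        fraction_a=frac_a,
        fraction_b=frac_b,
        fraction_c=frac_c,
        fraction_d=frac_d,
        r2adj_abiotic=ra,
        r2adj_biotic=rb,
        r2adj_full=rab,
        p_a=p_a,
        p_b=p_b,
        p_full=p_full,
        n_perm=n_perm or 0,
    )


def _testable_fraction_p(Y, X, Z, n_perm, rng) -> float | None:
    """Permutation p of the pure fraction of X conditioning on Z; None when
    X adds no information beyond Z (the fraction is identically zero)."""
    from .exceptions import ZeroInformationError

    try:
        return partial_rda(Y, X, Z, n_perm=n_perm, seed=rng).perm_p
    except ZeroInformationError:
        return None


def summarize_varpart(r: VarpartResult) -> dict:
    """Human-readable report: percentages to one decimal and the ordering
    statement among the explained fractions."""
    total = r.fraction_a + r.fraction_b + r.fraction_c + r.fraction_d
    if abs(total - 1.0) > 1e-10:
        raise InvalidParameterError(
            f"fractions sum to {total!r}, not 1 — inconsistent VarpartResult"
        )
    if r.fraction_c < 0:
        warnings.warn("shared fraction [c] is negative (suppressor structure); "
                      "reported as computed")
    named = {
        "pure abiotic": r.fraction_a,
        "pure biotic": r.fraction_b,
        "shared": r.fraction_c,
    }
    order = sorted(named, key=named.get, reverse=True)
    return {
        "percent": {
            "pure_abiotic": round(100 * r.fraction_a, 1),
            "pure_biotic": round(100 * r.fraction_b, 1),
            "shared": round(100 * r.fraction_c, 1),
            "unexplained": round(100 * r.fraction_d, 1),
        },
        "ordering": " > ".join(order),
        "p_values": {"pure_abiotic": r.p_a, "pure_biotic": r.p_b,
                     "full_model": r.p_full},
        "n_perm": r.n_perm,
    }
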