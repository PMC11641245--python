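"""Permutation inference for genotype effects on per-embryo defect proportions.

Defect proportions violate the usual regression assumptions (bounded
responses, non-normality, heteroscedasticity), so coefficients of simple
linear models are tested by label permutation rather than t/F statistics.

Two models are provided:

* **two-group**: ``Y_j = b0 + b1 I_j + e_j`` with ``I_j`` an indicator for
  the mutant genotype; ``b1`` is the difference of group means and is tested
  by shuffling genotype labels among embryos.  The permutation p-value is
  ``p = (n + 1) / (N + 1)`` where ``n`` counts permutation estimates that
  equal or exceed the observed one ("greater"; other alternatives use the
  analogous exceedance rule).
* **interaction (synergy)**: ``Y_j = b1 Ip_j + b2 Iq_j + b3 Ip_j Iq_j + e_j``
  (no intercept) over single-heterozygote and double-heterozygote embryos;
  synergy is present only if ``b3 != 0``.  Because this is a multiple
  regression, the interaction column is first orthogonalized against the
  main-effect columns (the Smith procedure) and the *residualized* column is
  permuted while the responses and main effects stay fixed.

An exhaustive enumerator over all label assignments serves as the exact
reference for small designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, permutations
from math import comb
from typing import Literal

import numpy as np

__all__ = [
    "ModelFit",
    "PermutationResult",
    "fit_two_group",
    "permutation_test_two_group",
    "exhaustive_two_group",
    "fit_interaction",
    "smith_orthogonalize",
    "permutation_test_interaction",
    "exhaustive_interaction",
]

logger = logging.getLogger(__name__)

Alternative = Literal["greater", "less", "two-sided"]

#: Default number of permutations for sampled tests.
DEFAULT_N_PERM = 1_000_000

_CHUNK = 50_000  # permutations per vectorized block (memory bound)


@dataclass(frozen=True)
class ModelFit:
    """Least-squares fit; ``statistic`` is the coefficient under test."""

    coefficients: dict[str, float]
    residuals: np.ndarray
    statistic: float


@dataclass(frozen=True)
class PermutationResult:
    statistic: float
    n: int
    N: int
    p: float
    alternative: Alternative
    seed: int | None
    mode: Literal["sampled", "exhaustive"]


def _check_groups(y: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=int)
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("y and g must be 1-D arrays of equal length")
    if not set(np.unique(g)) <= {0, 1}:
        raise ValueError("group indicator must be 0/1")
    if (g == 0).sum() == 0 or (g == 1).sum() == 0:
        raise ValueError("both groups must be non-empty")
    return y, g


def _exceedances(
    stats: np.ndarray, observed: float, alternative: Alternative, tol: float = 0.0
) -> int:
    """Count permutation statistics that meet the exceedance rule.

    Ties count toward the exceedance total.  Because responses are often
    lattice-valued (defect proportions), exact ties are common, and the
    vectorized recomputation can round a tied statistic a few ulps either
    side of the observed one; ``tol`` (a small fraction of the statistic's
    scale) makes tie detection robust to that.
    """
    if alternative == "greater":
        return int(np.sum(stats >= observed - tol))
    if alternative == "less":
        return int(np.sum(stats <= observed + tol))
    if alternative == "two-sided":
        return int(np.sum(np.abs(stats) >= abs(observed) - tol))
    raise ValueError(f"unknown alternative {alternative!r}")


def fit_two_group(y: np.ndarray, g: np.ndarray) -> ModelFit:
    """OLS of Y on an intercept and a 0/1 group indicator (closed form).

    ``b0`` is the reference-group mean; ``b1`` (the statistic) is the
    mutant-minus-reference difference of group means.
    """
    y, g = _check_groups(y, g)
    b0 = float(y[g == 0].mean())
    b1 = float(y[g == 1].mean()) - b0
    resid = y - (b0 + b1 * g)
    return ModelFit(coefficients={"b0": b0, "b1": b1}, residuals=resid, statistic=b1)


def _perm_b1_stats(y: np.ndarray, g: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """b1 estimates under random relabelings, preserving group sizes."""
    m = y.size
    n1 = int(g.sum())
    total = float(y.sum())
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(_CHUNK, n_perm - done)
        # each row: a uniform random subset of size n1 receives label 1
        order = np.argsort(rng.random((k, m)), axis=1)[:, :n1]
        s1 = y[order].sum(axis=1)
        out[done : done + k] = s1 / n1 - (total - s1) / (m - n1)
        done += k
    return out


def permutation_test_two_group(
    y: np.ndarray,
    g: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    alternative: Alternative = "greater",
    seed: int | None = 0,
) -> PermutationResult:
    """Permutation p-value for H0: b1 = 0 in the two-group model.

    Genotype labels are randomly shuffled among embryos (group sizes
    preserved); ``p = (n + 1) / (N + 1)`` with ``n`` the number of shuffles
    whose b1 meets the exceedance rule.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y, g = _check_groups(y, g)
    observed = fit_two_group(y, g).statistic
    if np.ptp(y) == 0 and alternative == "two-sided":
        logger.warning("constant response: two-sided permutation p-value is 1 by construction")
    rng = np.random.default_rng(seed)
    stats = _perm_b1_stats(y, g, n_perm, rng)
    n = _exceedances(stats, observed, alternative, tol=1e-9 * float(np.ptp(y)))
    return PermutationResult(
        statistic=observed,
        n=n,
        N=n_perm,
        p=(n + 1) / (n_perm + 1),
        alternative=alternative,
        seed=seed,
        mode="sampled",
    )


def exhaustive_two_group(
    y: np.ndarray,
    g: np.ndarray,
    alternative: Alternative = "greater",
    max_n: int = 20,
) -> PermutationResult:
    """Exact permutation p-value over all distinct label assignments.

    Enumerates every way of assigning the mutant label to ``n1`` of the
    embryos; p is the fraction of assignments (the observed one included)
    meeting the exceedance rule.  Only feasible for small cohorts; serves as
    the oracle for the sampled test.
    """
    y, g = _check_groups(y, g)
    m = y.size
    if m > max_n:
        raise ValueError(f"enumeration bound exceeded ({m} > {max_n})")
    n1 = int(g.sum())
    observed = fit_two_group(y, g).statistic
    total = float(y.sum())
    stats = np.array(
        [
            sum(y[list(idx)]) / n1 - (total - sum(y[list(idx)])) / (m - n1)
            for idx in combinations(range(m), n1)
        ]
    )
    n_exc = _exceedances(stats, observed, alternative, tol=1e-9 * float(np.ptp(y)))
    n_assign = comb(m, n1)
    return PermutationResult(
        statistic=observed,
        n=n_exc,
        N=n_assign,
        p=n_exc / n_assign,
        alternative=alternative,
        seed=None,
        mode="exhaustive",
    )


def _interaction_design(ip: np.ndarray, iq: np.ndarray) -> np.ndarray:
    ip = np.asarray(ip, dtype=float)
    iq = np.asarray(iq, dtype=float)
    if ip.shape != iq.shape or ip.ndim != 1:
        raise ValueError("Ip and Iq must be 1-D arrays of equal length")
    for arr, name in ((ip, "Ip"), (iq, "Iq")):
        if not set(np.unique(arr)) <= {0.0, 1.0}:
            raise ValueError(f"{name} must be 0/1")
    return np.column_stack([ip, iq, ip * iq])


def fit_interaction(
    y: np.ndarray,
    ip: np.ndarray,
    iq: np.ndarray,
    intercept: bool = False,
) -> ModelFit:
    """OLS of Y on [Ip, Iq, Ip*Iq], by default without intercept.

    With the three genotype groups (p-only, q-only, double heterozygote)
    this no-intercept model is saturated: b1 and b2 are the single-
    heterozygote group means and b3 (the statistic) is the double-
    heterozygote mean minus the additive expectation b1 + b2.  An intercept
    can be added for sensitivity analysis.
    """
    y = np.asarray(y, dtype=float)
    X = _interaction_design(ip, iq)
    groups = {(1, 0), (0, 1), (1, 1)}
    present = {tuple(row) for row in np.column_stack([ip, iq]).astype(int)}
    if not groups <= present:
        raise ValueError("p-only, q-only and double-heterozygote groups must all be non-empty")
    names = ["b1", "b2", "b3"]
    if intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["b0"] + names
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    coeffs = dict(zip(names, map(float, beta)))
    return ModelFit(coefficients=coeffs, residuals=resid, statistic=coeffs["b3"])


def smith_orthogonalize(X_nuis: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Residualize the column of interest against the nuisance columns.

    Returns ``z - X (X'X)^{-1} X' z``, i.e. the component of ``z`` orthogonal
    to every nuisance column.
    """
    X = np.atleast_2d(np.asarray(X_nuis, dtype=float))
    if X.shape[0] == 1 and X.shape[1] == len(z):
        X = X.T
    z = np.asarray(z, dtype=float)
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < X.shape[1]:
        raise np.linalg.LinAlgError("nuisance columns are linearly dependent")
    coef = np.linalg.solve(xtx, X.T @ z)
    return z - X @ coef


def _smith_pieces(y: np.ndarray, ip: np.ndarray, iq: np.ndarray):
    """(z_res, y_res, observed b3) for the Smith permutation scheme.

    ``z_res`` is the interaction column orthogonalized against [Ip, Iq] and
    ``y_res`` the response residualized the same way.  The observed
    statistic ``<z_res, y_res> / <z_res, z_res>`` equals the b3 coefficient
    of the full OLS fit (Frisch-Waugh); permuted statistics project the
    shuffled column onto ``y_res`` at the column's original scale, which
    keeps the permutation distribution exchangeable under the additive null
    (b3 = 0) so the test is exact rather than conservative.
    """
    X = _interaction_design(ip, iq)
    X_nuis, z = X[:, :2], X[:, 2]
    z_res = smith_orthogonalize(X_nuis, z)
    y_res = smith_orthogonalize(X_nuis, y)
    observed = float((z_res @ y_res) / (z_res @ z_res))
    return z_res, y_res, observed


def permutation_test_interaction(
    y: np.ndarray,
    ip: np.ndarray,
    iq: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    alternative: Alternative = "greater",
    seed: int | None = 0,
) -> PermutationResult:
    """Smith-procedure permutation test of H0: b3 = 0 (no synergy).

    The interaction column Ip*Iq is orthogonalized against [Ip, Iq]; the
    observed statistic is the coefficient on the orthogonalized column,
    which equals the no-intercept model's b3.  Permutations shuffle the
    entries of the orthogonalized column across embryos while Y, Ip and Iq
    stay fixed, and each shuffled column's coefficient is recomputed against
    the nuisance-residualized response (see :func:`_smith_pieces`).
    ``p = (n + 1) / (N + 1)`` with the default "greater" alternative
    (synergy = excess over the additive expectation).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    fit_interaction(y, ip, iq)  # validates the three-group design
    z_res, y_res, observed = _smith_pieces(y, ip, iq)
    scale = float(z_res @ z_res)
    rng = np.random.default_rng(seed)
    m = y.size
    stats = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(_CHUNK, n_perm - done)
        perm = np.argsort(rng.random((k, m)), axis=1)
        stats[done : done + k] = (z_res[perm] @ y_res) / scale
        done += k
    tol = 1e-9 * float(np.linalg.norm(z_res) * np.linalg.norm(y_res)) / scale
    n = _exceedances(stats, observed, alternative, tol=tol)
    return PermutationResult(
        statistic=observed,
        n=n,
        N=n_perm,
        p=(n + 1) / (n_perm + 1),
        alternative=alternative,
        seed=seed,
        mode="sampled",
    )


def exhaustive_interaction(
    y: np.ndarray,
    ip: np.ndarray,
    iq: np.ndarray,
    alternative: Alternative = "greater",
    max_n: int = 9,
) -> PermutationResult:
    """Exact version of the Smith test: all m! orderings of the residualized column.

    Feasible only for very small designs; serves as the oracle for
    :func:`permutation_test_interaction`.
    """
    y = np.asarray(y, dtype=float)
    m = y.size
    if m > max_n:
        raise ValueError(f"enumeration bound exceeded ({m} > {max_n})")
    z_res, y_res, observed = _smith_pieces(y, ip, iq)
    perms = np.array(list(permutations(range(m))))
    scale = float(z_res @ z_res)
    stats = (z_res[perms] @ y_res) / scale
    tol = 1e-9 * float(np.linalg.norm(z_res) * np.linalg.norm(y_res)) / scale
    n_exc = _exceedances(stats, observed, alternative, tol=tol)
    return PermutationResult(
        statistic=observed,
        n=n_exc,
        N=len(perms),
        p=n_exc / len(perms),
        alternative=alternative,
        seed=None,
        mode="exhaustive",
    )
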