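"""Blomberg's K and its permutation test.

Blomberg's K measures how strongly a continuous trait tracks the phylogeny.
With V the Brownian covariance of the tree and a-hat the GLS estimate of the
root state,

    MSE0 = (x - a 1)' (x - a 1) / (n - 1)          (ordinary squared error)
    MSE  = (x - a 1)' V^-1 (x - a 1) / (n - 1)     (phylogenetically weighted)
    K    = (MSE0 / MSE) / E[MSE0 / MSE]

where the Brownian expectation E[MSE0/MSE] = (tr V - n / (1' V^-1 1)) / (n - 1)
standardizes the ratio so that K = 1 is the Brownian-motion benchmark, K < 1
means less resemblance among relatives than Brownian evolution would produce,
and K > 1 means more.

Significance comes from a tip-shuffle null: trait values are randomly
exchanged across the tips of the phylogeny (999 shuffles by default) and the
observed phylogenetic mean squared error is compared against the shuffled
ones; a small MSE relative to the null means the trait is more clustered on
the tree than chance allows.  The add-one rule p = (1 + #{null <= obs}) /
(n_perm + 1) keeps p in (0, 1].
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .phylo import PhyloCovariance

__all__ = [
    "SignalResult",
    "SingularCovarianceError",
    "DegenerateTraitError",
    "phylogenetic_mean",
    "blomberg_k",
    "permutation_pvalue",
    "signal_test",
    "derive_cell_seed",
    "MIN_N_SIGNAL",
]

#: smallest group size for which K is computed; below this the cell is
#: flagged "insufficient_n" rather than given a numerically meaningless K
MIN_N_SIGNAL = 4


class SingularCovarianceError(ValueError):
    """V is not positive definite; sanitize branch lengths (zero-length
    terminal branches make sister tips indistinguishable)."""


class DegenerateTraitError(ValueError):
    """Trait has zero variance across the group; K is undefined."""


@dataclass(frozen=True)
class SignalResult:
    """Phylogenetic-signal test for one trait x group x habit cell."""

    trait_name: str
    group: str
    habit: str
    n_species: int
    k: float | None
    p_value: float | None
    n_perm: int
    seed: int
    statistic: str = "mse"
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value is not None and self.p_value < 0.05


def _as_matrix(cov: PhyloCovariance | np.ndarray) -> np.ndarray:
    if isinstance(cov, PhyloCovariance):
        return cov.matrix
    return np.asarray(cov, dtype=float)


def _spd_factor(V: np.ndarray):
    try:
        return cho_factor(V, lower=True)
    except LinAlgError as exc:
        raise SingularCovarianceError(
            "phylogenetic covariance is singular or not positive definite; "
            "sanitize branch lengths (zero-length terminal branches) first"
        ) from exc


def phylogenetic_mean(x: np.ndarray, cov: PhyloCovariance | np.ndarray) -> float:
    """GLS estimate of the root state: a = (1'V^-1 1)^-1 1'V^-1 x.

    Reduces to the arithmetic mean when V is a scalar multiple of the
    identity (a star tree with equal branches).
    """
    V = _as_matrix(cov)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size != V.shape[0]:
        raise ValueError("trait vector length must match covariance dimension")
    if x.size < 2:
        raise ValueError("need at least 2 taxa")
    factor = _spd_factor(V)
    w = cho_solve(factor, np.ones_like(x))  # V^-1 1
    return float(w @ x / w.sum())


def _mse_stats(x: np.ndarray, factor, w: np.ndarray) -> tuple[float, float]:
    """(MSE0, MSE) with the root state re-estimated for this x."""
    n = x.size
    a = float(w @ x / w.sum())
    r = x - a
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ cho_solve(factor, r)) / (n - 1)
    return mse0, mse


def _expected_ratio(V: np.ndarray, w: np.ndarray) -> float:
    n = V.shape[0]
    return (float(np.trace(V)) - n / float(w.sum())) / (n - 1)


def blomberg_k(x: np.ndarray, cov: PhyloCovariance | np.ndarray) -> float:
    """Blomberg's K of trait x on the tree behind ``cov``.

    K >= 0, dimensionless, invariant to affine rescaling of the trait.
    Raises :class:`DegenerateTraitError` for a constant trait rather than
    returning 0, because "no variation" and "no signal" are different claims.
    """
    V = _as_matrix(cov)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size != V.shape[0]:
        raise ValueError("trait vector length must match covariance dimension")
    if x.size < 2:
        raise ValueError("need at least 2 taxa")
    if np.ptp(x) == 0:
        raise DegenerateTraitError("trait is constant across taxa; K undefined")
    factor = _spd_factor(V)
    w = cho_solve(factor, np.ones_like(x))
    mse0, mse = _mse_stats(x, factor, w)
    return (mse0 / mse) / _expected_ratio(V, w)


def permutation_pvalue(
    x: np.ndarray,
    cov: PhyloCovariance | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    statistic: str = "mse",
) -> tuple[float, float]:
    """One-tailed tip-shuffle test of phylogenetic signal.

    Returns ``(K, p)``.  The null distribution comes from ``n_perm``
    independent uniform shuffles of the trait values across tips, with the
    root state re-estimated for every shuffled vector.

    statistic:
        ``"mse"`` (default) — signal means *smaller* phylogenetic MSE than
        the shuffled null; p = (1 + #{null MSE <= observed}) / (n_perm + 1).
        ``"k"`` — permute on K itself (signal = larger K).  For a fixed tree
        the two orderings agree up to the per-shuffle variation of MSE0, so
        the choice rarely matters; both are exposed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("mse", "k"):
        raise ValueError(f"unknown permutation statistic {statistic!r}")
    V = _as_matrix(cov)
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateTraitError("trait is constant across taxa; K undefined")
    n = x.size
    if n != V.shape[0]:
        raise ValueError("trait vector length must match covariance dimension")
    factor = _spd_factor(V)
    ones = np.ones(n)
    w = cho_solve(factor, ones)
    s = w.sum()
    expected = _expected_ratio(V, w)

    mse0_obs, mse_obs = _mse_stats(x, factor, w)
    k_obs = (mse0_obs / mse_obs) / expected

    rng = np.random.default_rng(seed)
    # columns = shuffled trait vectors; one triangular solve serves them all
    perms = np.empty((n, n_perm))
    for j in range(n_perm):
        perms[:, j] = rng.permutation(x)
    a_null = (w @ perms) / s
    R = perms - a_null  # broadcast row vector over columns
    VinvR = cho_solve(factor, R)
    mse_null = np.einsum("ij,ij->j", R, VinvR) / (n - 1)
    if statistic == "mse":
        p = (1 + int(np.sum(mse_null <= mse_obs))) / (n_perm + 1)
    else:
        mse0_null = np.einsum("ij,ij->j", R, R) / (n - 1)
        k_null = (mse0_null / mse_null) / expected
        p = (1 + int(np.sum(k_null >= k_obs))) / (n_perm + 1)
    return float(k_obs), float(p)


def derive_cell_seed(root_seed: int, habit: str, group: str, trait_name: str) -> int:
    """Deterministic per-cell seed from the run's root seed.

    Uses a stable hash of (root_seed, habit, group, trait) so each cell is
    reproducible independently of the order cells are evaluated in.
    """
    key = f"{root_seed}|{habit}|{group}|{trait_name}".encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def signal_test(
    x: np.ndarray,
    cov: PhyloCovariance | np.ndarray,
    *,
    trait_name: str,
    group: str,
    habit: str,
    n_perm: int = 999,
    seed: int = 0,
    statistic: str = "mse",
    min_n: int = MIN_N_SIGNAL,
) -> SignalResult:
    """Full per-cell signal test with small-n and degenerate-trait guards.

    Cells with fewer than ``min_n`` species, or a constant trait, get a
    flagged result with K and p absent instead of an exception, so a whole
    report table can be assembled even when some groups are tiny.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < min_n:
        return SignalResult(trait_name, group, habit, n, None, None, n_perm, seed,
                            statistic, note="insufficient_n")
    try:
        k, p = permutation_pvalue(x, cov, n_perm=n_perm, seed=seed, statistic=statistic)
    except DegenerateTraitError:
        return SignalResult(trait_name, group, habit, n, None, None, n_perm, seed,
                            statistic, note="degenerate_trait")
    return SignalResult(trait_name, group, habit, n, k, p, n_perm, seed, statistic)
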