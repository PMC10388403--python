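"""Trait-abundance regression by GLS and phylogenetic GLS.

Species are not independent samples: close relatives resemble each other, so
an ordinary regression of abundance on a trait can mistake shared ancestry
for an ecological relationship.  PGLS fixes the residual covariance to the
Brownian structure sigma^2 V implied by the phylogeny; ordinary least
squares is the special case V = I.  Both are fitted here so the two can be
contrasted trait by trait.

The estimator is textbook GLS with X = [1, x]:

    beta  = (X' V^-1 X)^-1 X' V^-1 y
    s^2   = (y - X beta)' V^-1 (y - X beta) / (n - 2)
    cov   = s^2 (X' V^-1 X)^-1,   t = beta_1 / se(beta_1),  df = n - 2

computed through Cholesky whitening rather than explicit inversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import PhyloCovariance, Phylogeny, compute_vcv, prune_to_taxa
from .signal import SingularCovarianceError, _spd_factor

__all__ = [
    "ModelFit",
    "ConstantPredictorError",
    "fit_gls",
    "fit_trait_abundance",
    "MIN_N_MODEL",
]

#: smallest group size for a regression (df = n - 2 >= 3)
MIN_N_MODEL = 5


class ConstantPredictorError(ValueError):
    """Predictor has no variance; the slope is unidentifiable."""


@dataclass(frozen=True)
class ModelFit:
    """One trait-abundance regression under OLS/GLS or Brownian PGLS."""

    model: str  # "GLS" or "PGLS"
    trait_name: str
    group: str
    habit: str
    beta0: float | None
    beta1: float | None
    se1: float | None
    t: float | None
    df: int | None
    p_value: float | None
    n_species: int
    note: str = ""

    def significant(self, alpha: float = 0.01) -> bool:
        return self.p_value is not None and self.p_value < alpha


def fit_gls(
    y: np.ndarray,
    x: np.ndarray,
    V: PhyloCovariance | np.ndarray | None = None,
    *,
    model: str = "GLS",
    trait_name: str = "",
    group: str = "",
    habit: str = "",
) -> ModelFit:
    """Fit ``y ~ 1 + x`` with residual covariance proportional to V.

    ``V=None`` means the identity, i.e. ordinary least squares.  The
    proportionality constant of V cancels from beta and t, so branch-length
    units never matter.  A perfect fit (zero residual) reports t = +/-inf
    with p = 0 and a "degenerate_fit" note instead of dividing by zero.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if x.size != n:
        raise ValueError("x and y must have the same length")
    if n < 3:
        raise ValueError("need at least 3 observations (df = n - 2 >= 1)")
    if np.ptp(x) == 0:
        raise ConstantPredictorError("predictor is constant; slope unidentifiable")

    X = np.column_stack([np.ones(n), x])
    if V is None:
        Xw, yw = X, y
    else:
        Vm = V.matrix if isinstance(V, PhyloCovariance) else np.asarray(V, dtype=float)
        if Vm.shape != (n, n):
            raise ValueError("covariance dimension must match data length")
        c, lower = _spd_factor(Vm)
        from scipy.linalg import solve_triangular

        Xw = solve_triangular(c, X, lower=lower)
        yw = solve_triangular(c, y, lower=lower)

    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    df = n - 2
    scale = rss / df
    XtX_inv = np.linalg.inv(XtX)

    if scale <= np.finfo(float).eps * float(yw @ yw):
        warnings.warn("degenerate fit: zero residual variance", stacklevel=2)
        t_stat = np.inf if beta[1] > 0 else -np.inf
        return ModelFit(model, trait_name, group, habit, float(beta[0]),
                        float(beta[1]), 0.0, float(t_stat), df, 0.0, n,
                        note="degenerate_fit")

    se1 = float(np.sqrt(scale * XtX_inv[1, 1]))
    t_stat = float(beta[1] / se1)
    p = float(2.0 * stats.t.sf(abs(t_stat), df))
    return ModelFit(model, trait_name, group, habit, float(beta[0]),
                    float(beta[1]), se1, t_stat, p_value=p, df=df, n_species=n)


def fit_trait_abundance(
    trait: pd.Series,
    abundance: pd.Series,
    tree: Phylogeny | None,
    mode: str = "PGLS",
    *,
    response: str = "abundance",
    log10_abundance: bool = False,
    log10_trait: bool = False,
    trait_name: str = "",
    group: str = "",
    habit: str = "",
    min_n: int = MIN_N_MODEL,
) -> ModelFit:
    """Regress species abundance on a trait across one species group.

    ``trait`` and ``abundance`` are species-indexed; their index sets must
    coincide, and for PGLS must be a subset of the tree's tips (the tree is
    pruned to the group before V is computed).  ``response`` selects which
    variable is the regression response — the default puts abundance on the
    left-hand side; for a single predictor the GLS slope t is symmetric in
    that choice but the PGLS t is not, so it is an explicit switch.

    Groups smaller than ``min_n`` yield a flagged fit (no estimates) rather
    than an exception.
    """
    if mode not in ("GLS", "PGLS"):
        raise ValueError(f"unknown mode {mode!r}")
    if response not in ("abundance", "trait"):
        raise ValueError(f"unknown response {response!r}")
    if set(trait.index) != set(abundance.index):
        raise ValueError("trait and abundance species sets differ")
    species = list(trait.index)
    n = len(species)
    if n < min_n:
        return ModelFit(mode, trait_name, group, habit, None, None, None, None,
                        None, None, n, note="insufficient_n")

    t_vals = trait.loc[species].to_numpy(dtype=float)
    a_vals = abundance.loc[species].to_numpy(dtype=float)
    if log10_trait:
        t_vals = np.log10(t_vals)
    if log10_abundance:
        a_vals = np.log10(a_vals)

    if mode == "PGLS":
        if tree is None:
            raise ValueError("PGLS requires a phylogeny")
        missing = set(species) - set(tree.tip_names)
        if missing:
            raise ValueError(f"species not in tree: {sorted(missing)}")
        pruned = prune_to_taxa(tree, species)
        vcv = compute_vcv(pruned)
        # reorder V to the species order of the data
        V = vcv.submatrix(species)
    else:
        V = None

    y, x = (a_vals, t_vals) if response == "abundance" else (t_vals, a_vals)
    try:
        return fit_gls(y, x, V, model=mode, trait_name=trait_name,
                       group=group, habit=habit)
    except ConstantPredictorError:
        return ModelFit(mode, trait_name, group, habit, None, None, None, None,
                        None, None, n, note="constant_predictor")
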