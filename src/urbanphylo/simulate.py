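"""Synthetic phylogenies, traits and communities.

Everything the pipeline consumes can be generated here, with known ground
truth, so each stage is testable without the field data: a Yule (pure-birth)
phylogeny, nine continuous traits evolved by Brownian motion blended with
white noise (``signal_weight`` interpolates between pure phylogenetic signal
at 1 and none at 0), occupancy of nine forest patches stratified into three
urbanization levels (three patches each, mirroring the survey layout), and
negative-binomial abundances whose log-mean depends linearly on a focal
trait plus a Brownian random effect.

Defaults describe a plausible subtropical woody-plant survey: ~100 species,
moderate phylogenetic signal, tens of individuals per species, counts
overdispersed relative to Poisson.  All draws flow from one seed, so every
generated dataset is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from .grouping import LEVELS, TRAITS
from .phylo import Phylogeny, _Node, compute_vcv

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_yule_tree",
    "simulate_bm_traits",
    "simulate_community",
    "simulate_dataset",
    "write_dataset",
]

#: per-trait (mean, sd, lower bound, upper bound) on natural scales;
#: Brownian realizations are affine-mapped onto these and clipped to the
#: physical range (K is affine-invariant, so the mapping preserves signal)
TRAIT_SCALES: dict[str, tuple[float, float, float, float]] = {
    "leaf_N": (20.0, 5.0, 1.0, np.inf),            # g/kg
    "leaf_C": (450.0, 30.0, 100.0, np.inf),        # g/kg
    "leaf_CN": (25.0, 8.0, 1.0, np.inf),
    "leaf_thickness": (0.030, 0.010, 0.002, np.inf),  # cm
    "leaf_area": (30.0, 18.0, 0.5, np.inf),        # cm^2
    "SLA": (15000.0, 5000.0, 500.0, np.inf),       # mm^2/g
    "germination_rate": (60.0, 20.0, 0.0, 100.0),  # %
    "seed_mass": (60.0, 40.0, 0.1, np.inf),        # g / 1000 grains
    "max_height": (12.0, 6.0, 0.5, np.inf),        # m
}

#: impervious-surface sampling windows per urbanization level (percent)
_IMPERVIOUS_RANGES = {"low": (5.0, 18.0), "moderate": (25.0, 45.0), "high": (55.0, 90.0)}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic survey.

    ``occupancy_probs`` are per-patch presence probabilities by urbanization
    level; with three patches per level the default 0.2 gives each species a
    ~49% chance of being present at a given level, which populates all four
    occupancy groups.  ``abundance_slope`` acts on the standardized focal
    trait; ``abundance_phylo_sd`` is the SD of a Brownian random effect on
    the log-mean (phylogenetically correlated abundance residuals);
    ``abundance_dispersion`` is the negative-binomial size parameter
    (``None`` = Poisson limit).
    """

    n_species: int = 100
    birth_rate: float = 1.0
    sigma2_bm: float = 1.0
    signal_weight: float = 0.7
    occupancy_probs: dict[str, float] = field(
        default_factory=lambda: {"low": 0.2, "moderate": 0.2, "high": 0.2}
    )
    focal_trait: str = "max_height"
    abundance_intercept: float = 3.0
    abundance_slope: float = 0.5
    abundance_phylo_sd: float = 0.5
    abundance_dispersion: float | None = 1.0
    tree_fraction: float = 0.6
    n_patches_per_level: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        if self.sigma2_bm < 0:
            raise ValueError("sigma2_bm must be >= 0")
        if not 0.0 <= self.signal_weight <= 1.0:
            raise ValueError("signal_weight must be in [0, 1]")
        for lv in LEVELS:
            p = self.occupancy_probs.get(lv)
            if p is None or not 0.0 < p <= 1.0:
                raise ValueError(f"occupancy_probs[{lv!r}] must be in (0, 1]")
        if self.abundance_dispersion is not None and self.abundance_dispersion <= 0:
            raise ValueError("abundance_dispersion must be > 0 (or None for Poisson)")
        if self.focal_trait not in TRAITS:
            raise ValueError(f"focal_trait must be one of {TRAITS}")
        if not 0.0 <= self.tree_fraction <= 1.0:
            raise ValueError("tree_fraction must be in [0, 1]")
        if self.n_patches_per_level < 1:
            raise ValueError("n_patches_per_level must be >= 1")


@dataclass
class SimulatedDataset:
    """A complete synthetic input set for the analysis pipeline."""

    tree: Phylogeny
    traits: pd.DataFrame      # species, habit, nine trait columns
    patches: pd.DataFrame     # patch_id, impervious_pct
    occupancy: pd.DataFrame   # species, patch_id, count (per-patch counts)
    abundance: pd.DataFrame   # species, total_count
    config: SimulationConfig


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed=0) -> Phylogeny:
    """Grow a rooted binary pure-birth tree with ``n_tips`` labelled tips.

    Lineages split at total rate ``birth_rate * k`` (k = current lineage
    count); waiting times are exponential.  The tree is cut at one extra
    exponential waiting time past the last birth so terminal branches have
    positive length.  Tips are labelled ``s001 ... sNNN``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = _as_rng(seed)
    root = _Node()
    # (parent node, birth time) per active lineage; root starts with two
    active: list[tuple[_Node, float]] = [(root, 0.0), (root, 0.0)]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = int(rng.integers(k))
        parent, born = active.pop(idx)
        node = _Node(length=t - born)
        parent.children.append(node)
        active.append((node, t))
        active.append((node, t))
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    width = max(3, len(str(n_tips)))
    for i, (parent, born) in enumerate(active, start=1):
        leaf = _Node(length=t - born, label=f"s{i:0{width}d}")
        parent.children.append(leaf)
    return Phylogeny(root)


def simulate_bm_traits(
    tree: Phylogeny,
    sigma2: float = 1.0,
    root_value: float = 0.0,
    signal_weight: float = 1.0,
    seed=0,
) -> pd.Series:
    """Evolve one continuous trait on the tree.

    The tip vector is ``root + w * BM + (1 - w) * noise`` where BM is
    multivariate normal with covariance ``sigma2 * V`` and the white-noise
    part is independent per tip with the same marginal variance
    ``sigma2 * V[i, i]``.  ``signal_weight = 1`` therefore gives exact
    Brownian tip covariance; 0 destroys all phylogenetic structure while
    keeping each tip's marginal scale.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if not 0.0 <= signal_weight <= 1.0:
        raise ValueError("signal_weight must be in [0, 1]")
    rng = _as_rng(seed)
    names = tree.tip_names
    n = len(names)
    if sigma2 == 0:
        return pd.Series(np.full(n, float(root_value)), index=names)
    V = compute_vcv(tree).matrix
    L = cholesky(sigma2 * V, lower=True)
    bm = L @ rng.standard_normal(n)
    noise = np.sqrt(sigma2 * np.diag(V)) * rng.standard_normal(n)
    x = root_value + signal_weight * bm + (1.0 - signal_weight) * noise
    return pd.Series(x, index=names)


def _scaled_trait(raw: pd.Series, V_diag_mean: float, scale) -> pd.Series:
    mean, sd, lo, hi = scale
    z = raw / np.sqrt(V_diag_mean)  # unit-ish marginal scale
    return (mean + sd * z).clip(lo, hi)


def simulate_community(
    tree: Phylogeny,
    trait: pd.Series,
    config: SimulationConfig,
    seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw patches, per-patch counts, and per-species total abundances.

    Patch impervious percentages are sampled inside disjoint windows so
    exactly ``n_patches_per_level`` patches land in each urbanization level.
    A species is present in a patch with the level's occupancy probability
    (vectors with no presence anywhere are redrawn).  Species totals are
    negative-binomial around ``exp(intercept + slope * z(trait) + u)`` with
    ``u`` a Brownian random effect (covariance scaled to unit mean
    diagonal), then spread over the species' occupied patches, at least one
    individual per occupied patch.
    """
    config.validate()
    rng = _as_rng(config.seed if seed is None else seed)
    names = tree.tip_names
    if list(trait.index) != names:
        trait = trait.reindex(names)
        if trait.isna().any():
            raise ValueError("focal trait must cover every tree tip")
    n = len(names)

    # patches: 3 per level inside disjoint impervious windows
    rows = []
    pid = 0
    for lv in LEVELS:
        a, b = _IMPERVIOUS_RANGES[lv]
        for _ in range(config.n_patches_per_level):
            pid += 1
            rows.append((f"P{pid}", float(rng.uniform(a, b))))
    patches = pd.DataFrame(rows, columns=["patch_id", "impervious_pct"])
    patch_levels = [lv for lv in LEVELS for _ in range(config.n_patches_per_level)]
    p_patch = np.array([config.occupancy_probs[lv] for lv in patch_levels])
    n_patch = len(patch_levels)

    # occupancy: Bernoulli per patch, redraw all-absent species
    present = np.zeros((n, n_patch), dtype=bool)
    for i in range(n):
        for _ in range(10_000):
            row = rng.random(n_patch) < p_patch
            if row.any():
                present[i] = row
                break
        else:  # pragma: no cover - probability ~0 under valid config
            present[i, int(rng.integers(n_patch))] = True

    # abundance: log-linear in the standardized focal trait + Brownian effect
    tvals = trait.to_numpy(dtype=float)
    sd = tvals.std(ddof=0)
    z = (tvals - tvals.mean()) / sd if sd > 0 else np.zeros(n)
    V = compute_vcv(tree).matrix
    Vs = V / np.diag(V).mean()
    u = config.abundance_phylo_sd * (cholesky(Vs, lower=True) @ rng.standard_normal(n))
    mu = np.exp(config.abundance_intercept + config.abundance_slope * z + u)
    if config.abundance_dispersion is None:
        totals = rng.poisson(mu)
    else:
        k = config.abundance_dispersion
        totals = rng.negative_binomial(k, k / (k + mu))
    n_occ = present.sum(axis=1)
    totals = np.maximum(totals, n_occ)  # >= 1 individual per occupied patch

    occ_rows = []
    for i, sp in enumerate(names):
        occupied = np.flatnonzero(present[i])
        extra = rng.multinomial(int(totals[i]) - len(occupied), np.full(len(occupied), 1.0 / len(occupied)))
        for j, pj in enumerate(occupied):
            occ_rows.append((sp, patches.loc[pj, "patch_id"], 1 + int(extra[j])))
    occupancy = pd.DataFrame(occ_rows, columns=["species", "patch_id", "count"])
    abundance = pd.DataFrame({"species": names, "total_count": totals.astype(int)})
    return patches, occupancy, abundance


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate a full coherent input set (tree, traits, patches, counts)."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = simulate_yule_tree(config.n_species, config.birth_rate, rng)
    names = tree.tip_names
    V_diag_mean = float(np.diag(compute_vcv(tree).matrix).mean())

    cols: dict[str, pd.Series] = {}
    for trait_name in TRAITS:
        raw = simulate_bm_traits(
            tree, config.sigma2_bm, 0.0, config.signal_weight, rng
        )
        scale_var = config.sigma2_bm * V_diag_mean or 1.0  # constant traits if sigma2 = 0
        cols[trait_name] = _scaled_trait(raw, scale_var, TRAIT_SCALES[trait_name])
    habit = np.where(rng.random(len(names)) < config.tree_fraction, "tree", "shrub")
    traits = pd.DataFrame({"species": names, "habit": habit})
    for trait_name in TRAITS:
        traits[trait_name] = cols[trait_name].to_numpy()

    patches, occupancy, abundance = simulate_community(
        tree, cols[config.focal_trait], config, rng
    )
    return SimulatedDataset(tree, traits, patches, occupancy, abundance, config)


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset in exactly the formats the pipeline reads.

    Files: ``tree.nwk`` (newick), ``traits.csv``, ``patches.csv``,
    ``abundance.csv`` (long species / patch_id / count).  Returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": out / "tree.nwk",
        "traits": out / "traits.csv",
        "patches": out / "patches.csv",
        "abundance": out / "abundance.csv",
    }
    paths["tree"].write_text(dataset.tree.to_newick() + "\n")
    dataset.traits.to_csv(paths["traits"], index=False)
    dataset.patches.to_csv(paths["patches"], index=False)
    dataset.occupancy.to_csv(paths["abundance"], index=False)
    return paths
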