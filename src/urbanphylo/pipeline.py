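"""End-to-end analysis: grouping -> phylogenetic signal -> GLS/PGLS tables.

The driver reads four inputs (newick tree; traits CSV with species, habit
and the nine trait columns; patch CSV with impervious percentages; long
abundance CSV with species, patch_id, count), reconciles species names
across them, partitions species into the four urbanization-occupancy
groups, and then fills, separately for trees and shrubs, a 9-trait x
4-group report of Blomberg's K with permutation p-values plus paired
GLS/PGLS trait-abundance regressions.  Every random element derives from
one root seed, so identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import grouping as gr
from .models import ModelFit, fit_trait_abundance
from .phylo import Phylogeny, compute_vcv, parse_newick, prune_to_taxa
from .signal import derive_cell_seed, signal_test

__all__ = ["AnalysisConfig", "AnalysisResult", "run_analysis", "load_inputs"]

logger = logging.getLogger("urbanphylo")


@dataclass
class AnalysisConfig:
    """Everything a run needs; round-trips through YAML."""

    tree: str
    traits: str
    patches: str
    abundance: str
    out_dir: str | None = None
    n_perm: int = 999
    alpha_signal: float = 0.05   # flag convention of the signal tables
    alpha_model: float = 0.01    # flag convention of the regression tables
    response: str = "abundance"  # or "trait"
    log10_abundance: bool = False
    log10_traits: tuple[str, ...] = ()
    min_n_signal: int = 4
    min_n_model: int = 5
    seed: int = 0
    on_mismatch: str = "error"   # or "drop"
    perm_statistic: str = "mse"  # or "k"
    abundance_aggregation: str = "total"  # or "patch_mean"
    substitute_missing_branch_lengths: float | None = None

    def validate(self) -> None:
        if not (0.0 < self.alpha_signal < 1.0 and 0.0 < self.alpha_model < 1.0):
            raise ValueError("alphas must be in (0, 1)")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        if self.abundance_aggregation not in ("total", "patch_mean"):
            raise ValueError("abundance_aggregation must be 'total' or 'patch_mean'")
        if self.response not in ("abundance", "trait"):
            raise ValueError("response must be 'abundance' or 'trait'")
        unknown = set(self.log10_traits) - set(gr.TRAITS)
        if unknown:
            raise ValueError(f"log10_traits not recognised: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "log10_traits" in raw and raw["log10_traits"] is not None:
            raw["log10_traits"] = tuple(raw["log10_traits"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class AnalysisResult:
    groups: pd.DataFrame          # species, group
    signal: pd.DataFrame          # tidy per-cell signal results
    models: pd.DataFrame          # tidy per-cell GLS/PGLS fits
    summary: pd.DataFrame         # per habit/group/trait mean, SE, CI95
    tally: dict
    log: list[str] = field(default_factory=list)
    paths: dict = field(default_factory=dict)


def load_inputs(config: AnalysisConfig):
    """Read and normalize the four input files."""
    tree = parse_newick(
        Path(config.tree).read_text(),
        substitute_missing=config.substitute_missing_branch_lengths,
    )
    traits = pd.read_csv(config.traits)
    patches = pd.read_csv(config.patches)
    abundance = pd.read_csv(config.abundance)
    for df in (traits, abundance):
        if "species" not in df.columns:
            raise ValueError("input table lacks a 'species' column")
        df["species"] = df["species"].map(gr.normalize_taxon_label)
    missing_traits = [t for t in gr.TRAITS if t not in traits.columns]
    if missing_traits:
        raise ValueError(f"trait table lacks columns: {missing_traits}")
    if "habit" not in traits.columns:
        raise ValueError("trait table lacks a 'habit' column")
    bad_habit = set(traits["habit"]) - set(gr.HABITS)
    if bad_habit:
        raise ValueError(f"unknown habit values: {sorted(bad_habit)}")
    if not {"patch_id", "impervious_pct"} <= set(patches.columns):
        raise ValueError("patch table needs 'patch_id' and 'impervious_pct'")
    if not {"patch_id", "count"} <= set(abundance.columns):
        raise ValueError("abundance table needs 'patch_id' and 'count'")
    return tree, traits, patches, abundance


def _aggregate_abundance(abundance: pd.DataFrame, how: str) -> pd.Series:
    """Per-species abundance: total individuals (default) or per-patch mean."""
    counts = abundance[abundance["count"] > 0]
    grouped = counts.groupby("species")["count"]
    return grouped.sum() if how == "total" else grouped.mean()


def run_analysis(config: AnalysisConfig) -> AnalysisResult:
    config.validate()
    log: list[str] = []

    def note(msg: str) -> None:
        logger.info(msg)
        log.append(msg)

    tree, traits, patches, abundance = load_inputs(config)
    note(f"inputs: {tree.n_tips} tree tips, {len(traits)} trait rows, "
         f"{len(patches)} patches, {len(abundance)} abundance rows")

    species = gr.reconcile_species(
        tree.tip_names, traits, abundance, on_mismatch=config.on_mismatch
    )
    note(f"{len(species)} species reconcile across tree, traits and abundance")
    traits = traits[traits["species"].isin(species)].drop_duplicates("species")
    abundance = abundance[abundance["species"].isin(species)]

    groups = gr.assign_species_groups(abundance, patches)
    groups = groups[groups["species"].isin(species)].reset_index(drop=True)
    sizes = groups["group"].value_counts().to_dict()
    note(f"group sizes (pooled habits): "
         + ", ".join(f"{g}={sizes.get(g, 0)}" for g in gr.GROUPS))

    per_species_abundance = _aggregate_abundance(abundance, config.abundance_aggregation)
    habit_of = traits.set_index("species")["habit"]
    group_of = groups.set_index("species")["group"]
    trait_table = traits.set_index("species")

    signal_rows: list[dict] = []
    model_rows: list[dict] = []
    for habit in gr.HABITS:
        for group in gr.GROUPS:
            members = [s for s in species
                       if habit_of.get(s) == habit and group_of.get(s) == group]
            for trait_name in gr.TRAITS:
                vals = trait_table.loc[members, trait_name].dropna()
                cell_species = sorted(vals.index)
                n = len(cell_species)
                cell_seed = derive_cell_seed(config.seed, habit, group, trait_name)

                # --- phylogenetic signal -------------------------------
                if n >= max(config.min_n_signal, 2):
                    sub = prune_to_taxa(tree, cell_species)
                    cov = compute_vcv(sub).submatrix(cell_species)
                    res = signal_test(
                        vals.loc[cell_species].to_numpy(),
                        cov,
                        trait_name=trait_name, group=group, habit=habit,
                        n_perm=config.n_perm, seed=cell_seed,
                        statistic=config.perm_statistic,
                        min_n=config.min_n_signal,
                    )
                else:
                    res = signal_test(
                        vals.to_numpy(), np.eye(max(n, 1)),
                        trait_name=trait_name, group=group, habit=habit,
                        n_perm=config.n_perm, seed=cell_seed,
                        min_n=config.min_n_signal,
                    )
                signal_rows.append({
                    "habit": habit, "group": group, "trait": trait_name,
                    "n": res.n_species, "K": res.k, "p": res.p_value,
                    "significant": (res.p_value is not None
                                    and res.p_value < config.alpha_signal),
                    "note": res.note,
                })

                # --- GLS / PGLS regressions ----------------------------
                log10_trait = trait_name in config.log10_traits
                ab = per_species_abundance.reindex(cell_species)
                for mode in ("GLS", "PGLS"):
                    if n >= config.min_n_model:
                        fit = fit_trait_abundance(
                            vals.loc[cell_species], ab, tree, mode,
                            response=config.response,
                            log10_abundance=config.log10_abundance,
                            log10_trait=log10_trait,
                            trait_name=trait_name, group=group, habit=habit,
                            min_n=config.min_n_model,
                        )
                    else:
                        fit = ModelFit(mode, trait_name, group, habit, None,
                                       None, None, None, None, None, n,
                                       note="insufficient_n")
                    model_rows.append({
                        "habit": habit, "group": group, "trait": trait_name,
                        "model": mode, "n": fit.n_species,
                        "beta0": fit.beta0, "beta1": fit.beta1, "se1": fit.se1,
                        "t": fit.t, "df": fit.df, "p": fit.p_value,
                        "significant": fit.significant(config.alpha_model),
                        "note": fit.note,
                    })

    signal_df = pd.DataFrame(signal_rows)
    model_df = pd.DataFrame(model_rows)

    summary_frames = []
    for habit in gr.HABITS:
        sm = gr.summarize_group_traits(traits, groups, habit=habit)
        sm.insert(0, "habit", habit)
        summary_frames.append(sm)
    summary_df = pd.concat(summary_frames, ignore_index=True)

    tally = {
        "alpha_model": config.alpha_model,
        "alpha_signal": config.alpha_signal,
    }
    for habit in gr.HABITS:
        hm = model_df[model_df["habit"] == habit]
        hs = signal_df[signal_df["habit"] == habit]
        tally[habit] = {
            "pgls_significant": int(hm.loc[hm["model"] == "PGLS", "significant"].sum()),
            "gls_significant": int(hm.loc[hm["model"] == "GLS", "significant"].sum()),
            "signal_significant": int(hs["significant"].sum()),
        }
        note(f"{habit}: {tally[habit]['pgls_significant']} significant PGLS "
             f"relationships (p < {config.alpha_model}), "
             f"{tally[habit]['signal_significant']} significant phylogenetic "
             f"signals (p < {config.alpha_signal})")

    result = AnalysisResult(groups, signal_df, model_df, summary_df, tally, log)
    if config.out_dir is not None:
        result.paths = write_report(result, config)
    return result


# ---------------------------------------------------------------------------
# serialization


def _fmt(v, nd: int = 3) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        if isinstance(v, float) and np.isinf(v):
            return "inf" if v > 0 else "-inf"
        return ""
    return f"{v:.{nd}f}"


def _shape_signal(signal_df: pd.DataFrame, habit: str) -> pd.DataFrame:
    """Trait rows x group (K, p) columns, mirroring the signal report layout."""
    sub = signal_df[signal_df["habit"] == habit]
    out = {"trait": list(gr.TRAITS)}
    for group in gr.GROUPS:
        g = sub[sub["group"] == group].set_index("trait")
        out[f"{group}_K"] = [_fmt(g.loc[t, "K"]) if t in g.index else "" for t in gr.TRAITS]
        out[f"{group}_p"] = [_fmt(g.loc[t, "p"]) if t in g.index else "" for t in gr.TRAITS]
        out[f"{group}_n"] = [int(g.loc[t, "n"]) if t in g.index else 0 for t in gr.TRAITS]
    return pd.DataFrame(out)


def _shape_models(model_df: pd.DataFrame, habit: str) -> pd.DataFrame:
    """Trait x {GLS, PGLS} rows with per-group t and p columns."""
    sub = model_df[model_df["habit"] == habit]
    rows = []
    for trait in gr.TRAITS:
        for mode in ("GLS", "PGLS"):
            row = {"trait": trait, "model": mode}
            cell = sub[(sub["trait"] == trait) & (sub["model"] == mode)]
            for group in gr.GROUPS:
                c = cell[cell["group"] == group]
                if len(c) == 1:
                    row[f"{group}_t"] = _fmt(c["t"].iloc[0])
                    row[f"{group}_p"] = _fmt(c["p"].iloc[0])
                else:
                    row[f"{group}_t"] = row[f"{group}_p"] = ""
            rows.append(row)
    return pd.DataFrame(rows)


def write_report(result: AnalysisResult, config: AnalysisConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["groups"] = out / "group_assignment.csv"
    result.groups.to_csv(paths["groups"], index=False)

    for habit in gr.HABITS:
        p = out / f"signal_{habit}.tsv"
        _shape_signal(result.signal, habit).to_csv(p, sep="\t", index=False)
        paths[f"signal_{habit}"] = p
        p = out / f"models_{habit}.tsv"
        _shape_models(result.models, habit).to_csv(p, sep="\t", index=False)
        paths[f"models_{habit}"] = p

    paths["signal_cells"] = out / "signal_cells.tsv"
    result.signal.to_csv(paths["signal_cells"], sep="\t", index=False, float_format="%.6g")
    paths["model_cells"] = out / "model_cells.tsv"
    result.models.to_csv(paths["model_cells"], sep="\t", index=False, float_format="%.6g")

    paths["summary"] = out / "trait_summary.tsv"
    result.summary.to_csv(paths["summary"], sep="\t", index=False, float_format="%.6g")

    paths["tally"] = out / "tally.json"
    paths["tally"].write_text(json.dumps(result.tally, indent=2, sort_keys=True) + "\n")

    paths["log"] = out / "run_log.txt"
    paths["log"].write_text("\n".join(result.log) + "\n")
    return paths
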