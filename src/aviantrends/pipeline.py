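"""End-to-end orchestration: specimens -> colour scores -> per-species
trends -> phylogenetic meta-analysis.

The pipeline follows a two-step logic: per-species models first (each
species analysed separately, yielding a trend table with one row per
species and trait), then across-species Bayesian meta-analysis of those
trends.  A ``meta_only`` entry point accepts a ready-made trend table in
the same layout, so published per-species estimates can be analysed
without specimen-level data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from . import chromatic_pca, phylo_meta, specimen_data, temporal_models, visual_model
from .phylo_meta import EffectSizeSet, MetaResult, PriorConfig
from .specimen_data import SpecimenRecord, ReflectanceSpectrum
from .synthetic_data import StudyData

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "score_colour",
    "fit_all_species",
    "run_meta_suite",
    "run_pipeline",
    "meta_only",
    "effects_to_frame",
]

log = logging.getLogger("aviantrends")


@dataclass(frozen=True)
class PipelineConfig:
    """Options shared by the pipeline stages."""

    rac_cell: float = 1.0
    gamm_k: int = 10
    select_variance: bool = True
    n_trees: int = 130
    iters_per_tree: int = 1000
    burnin_trees: int = 30
    prior: PriorConfig = field(default_factory=PriorConfig)
    exclude_nonlinear: bool = True
    seed: int = 0
    outdir: Path | None = None


@dataclass
class PipelineResult:
    effects: pd.DataFrame
    meta: dict[str, MetaResult]
    excluded_species: list[str]


def score_colour(
    records: Sequence[SpecimenRecord],
    spectra: dict[str, Sequence[ReflectanceSpectrum]],
    vs: visual_model.VisualSystem | None = None,
) -> pd.DataFrame:
    """Specimen table with PC1 colour scores and carotenoid chroma.

    Spectra are cleaned onto the 1-nm grid, run through the visual model,
    averaged per patch, and summarized per species by covariance-matrix
    PCA with the chroma sign anchor.
    """
    if vs is None:
        vs = visual_model.VisualSystem.violet_default()
    frame = specimen_data.records_to_frame(records)
    xyz = np.full((len(frame), 3), np.nan)
    chroma = np.full(len(frame), np.nan)
    for i, rec in enumerate(records):
        reps = [
            specimen_data.clean_and_resample(s) for s in spectra.get(rec.specimen_id, [])
        ]
        if not reps:
            continue
        coords = visual_model.patch_coordinates(reps, vs)
        xyz[i] = coords.as_array()
        chroma[i] = float(np.mean([visual_model.carotenoid_chroma(s) for s in reps]))
    frame[["x", "y", "z"]] = xyz
    frame["chroma"] = chroma
    frame["pc1"] = np.nan
    for species, idx in frame.groupby("species").groups.items():
        sub = frame.loc[idx]
        ok = sub[["x", "chroma"]].notna().all(axis=1)
        if ok.sum() < 3:
            log.warning("species %s: <3 scored specimens, PC1 skipped", species)
            continue
        pca = chromatic_pca.fit_species_pca(
            sub.loc[ok, ["x", "y", "z"]].to_numpy(),
            sub.loc[ok, "chroma"].to_numpy(),
        )
        frame.loc[sub.index[ok], "pc1"] = pca.scores
    return frame


def fit_all_species(
    frame: pd.DataFrame, config: PipelineConfig = PipelineConfig()
) -> pd.DataFrame:
    """Per-species trend table (one row per species, both traits)."""
    rows = []
    for species, sub in frame.groupby("species", sort=True):
        row: dict = {"species": species}
        for trait, spec in (
            ("wing", temporal_models.ModelSpec.wing(rac_cell=config.rac_cell)),
            ("colour", temporal_models.ModelSpec.colour(rac_cell=config.rac_cell)),
        ):
            resp = "wing_length" if trait == "wing" else "pc1"
            data = sub.dropna(subset=[resp])
            if len(data) < 20:
                log.warning("species %s/%s: too few specimens (%d), skipped",
                            species, trait, len(data))
                continue
            eff, _ = temporal_models.fit_species_trait(
                data, spec, species=species, select_variance=config.select_variance
            )
            row.update(
                {
                    f"{trait}_edf": eff.edf,
                    f"{trait}_beta": eff.beta,
                    f"{trait}_se": eff.se,
                    f"{trait}_df": eff.df,
                    f"{trait}_t": eff.t,
                    f"{trait}_p": eff.p,
                }
            )
            log.info("fitted %s/%s: beta=%.5f se=%.5f edf=%.2f",
                     species, trait, eff.beta, eff.se, eff.edf)
        rows.append(row)
    return pd.DataFrame(rows)


def effects_to_frame(effects: pd.DataFrame, trait: str,
                     covariate: str | None = None) -> EffectSizeSet:
    y = effects[f"{trait}_beta"].to_numpy(float)
    v = effects[f"{trait}_se"].to_numpy(float) ** 2
    x = None if covariate is None else effects[f"{covariate}_beta"].to_numpy(float)
    return EffectSizeSet(species=tuple(effects["species"]), y=y, v=v, x=x)


def run_meta_suite(
    effects: pd.DataFrame,
    trees: Sequence[dendropy.Tree],
    config: PipelineConfig = PipelineConfig(),
) -> tuple[dict[str, MetaResult], list[str]]:
    """Intercept-only meta-analyses for both traits plus the
    wing-on-colour meta-regression; optionally repeated excluding species
    whose GAMM EDF exceeds 3 (strong nonlinearity)."""
    results: dict[str, MetaResult] = {}

    def run(eff: pd.DataFrame, tag: str, seed_offset: int) -> None:
        for j, trait in enumerate(("wing", "colour")):
            es = effects_to_frame(eff, trait)
            chain = phylo_meta.run_tree_set(
                es, trees, config.iters_per_tree, config.burnin_trees,
                config.prior, seed=config.seed + seed_offset + j,
            )
            results[f"{trait}{tag}"] = phylo_meta.summarize_chain(
                chain, phylo_meta.typical_sampling_variance(es.v)
            )
        es = effects_to_frame(eff, "wing", covariate="colour")
        res, _ = phylo_meta.meta_regression(
            es, trees, config.iters_per_tree, config.burnin_trees,
            config.prior, seed=config.seed + seed_offset + 2,
        )
        results[f"regression{tag}"] = res

    run(effects, "", 0)
    excluded: list[str] = []
    if config.exclude_nonlinear:
        edf_cols = [c for c in ("wing_edf", "colour_edf") if c in effects.columns]
        nonlinear = effects[(effects[edf_cols] > 3).any(axis=1)]["species"].tolist()
        excluded = nonlinear
        if nonlinear:
            rest = effects[~effects["species"].isin(nonlinear)]
            run(rest, "_excl", 10)
    return results, excluded


def run_pipeline(study: StudyData, config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Full run on an in-memory study (synthetic or loaded from disk)."""
    log.info("stage 1/4: specimen curation (%d records)", len(study.records))
    records, removed = specimen_data.filter_specimens(study.records)
    log.info("removed per reason: %s", removed)

    log.info("stage 2/4: visual model + PCA colour scoring")
    frame = score_colour(records, study.spectra)

    log.info("stage 3/4: per-species temporal models")
    effects = fit_all_species(frame, config)

    log.info("stage 4/4: phylogenetic meta-analysis")
    trees = [study.tree] * config.n_trees
    meta, excluded = run_meta_suite(effects, trees, config)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        effects.to_csv(outdir / "species_trends.csv", index=False)
        with open(outdir / "meta_summary.txt", "w") as fh:
            for name, res in meta.items():
                fh.write(f"== {name} ==\n{res}\n\n")
    return PipelineResult(effects=effects, meta=meta, excluded_species=excluded)


def meta_only(
    effects_path: str | Path,
    tree_path: str | Path | None = None,
    config: PipelineConfig = PipelineConfig(),
    star: bool = False,
) -> tuple[dict[str, MetaResult], list[str]]:
    """Meta-analytic stage alone, from a trend table in the standard layout.

    ``effects_path`` must have columns species, wing_beta, wing_se,
    colour_beta, colour_se (EDF columns optional).  The tree defaults to
    the bundled stand-in phylogeny; ``star`` replaces it with a star tree
    (the no-phylogeny sensitivity run).
    """
    effects = pd.read_csv(effects_path)
    if star:
        trees = [phylo_meta.star_tree(list(effects["species"]))] * config.n_trees
    else:
        tree_set = phylo_meta.load_tree_set(tree_path or phylo_meta.bundled_tree_path())
        # a single tree is recycled; a posterior sample of trees is chained as-is
        trees = tree_set if len(tree_set) > 1 else tree_set * config.n_trees
    return run_meta_suite(effects, trees, config)
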