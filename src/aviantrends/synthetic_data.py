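"""Synthetic museum-specimen studies with known ground truth.

The generator emulates the structure of a century-scale specimen series:
a pure-birth phylogeny over the study species; per-species true temporal
slopes drawn from a phylogenetic + independent species-effect model;
specimen records with collection year, sex, altitude, subspecies,
two-month season and a spatially autocorrelated residual field; and
five-replicate carotenoid-like reflectance spectra per specimen.

The colour trend is planted in the carotenoid absorption depth of the
spectra — not injected into any colour score directly — so a synthetic
study only shows a recoverable colour trend if the visual-model ->
chromatic-PCA chain preserves it.  Defaults mirror the study conditions:
15 species, 65-162 specimens each, years 1900-2008.

A master seed fans out to per-stage child seeds by fixed offsets, so every
stage is independently reproducible.
"""

from __future__ import annotations

import random
from dataclasses import asdict, dataclass
from pathlib import Path
import dendropy
import numpy as np
import pandas as pd

from .specimen_data import ReflectanceSpectrum, SpecimenRecord, STANDARD_GRID

__all__ = [
    "StudyConfig",
    "SpeciesTruth",
    "StudyData",
    "simulate_tree",
    "simulate_species_effects",
    "simulate_specimens",
    "simulate_spectrum",
    "generate_study",
    "write_study",
]

_SEED_TREE = 11
_SEED_EFFECTS = 23
_SEED_SPECIMENS = 47
_SEED_SPECTRA = 83


@dataclass(frozen=True)
class StudyConfig:
    """Ground-truth parameters of one synthetic study.

    Trait units: wing in mm, colour trend in carotenoid-depth percent
    units per year (it reaches the colour score only through the spectra).
    """

    n_species: int = 15
    specimens_per_species: tuple[int, int] = (65, 162)
    year_span: tuple[int, int] = (1900, 2008)
    # across-species effect model (per-year scale)
    mu_wing: float = -0.01
    sigma2_p_wing: float = 0.0
    sigma2_s_wing: float = 1e-4
    mu_colour: float = 0.0
    sigma2_p_colour: float = 0.0
    sigma2_s_colour: float = 4e-4
    # specimen-level structure
    wing_intercept: float = 60.0
    sex_effect_wing: float = 2.0
    altitude_effect_wing: float = 5e-4
    subspecies_effect_wing: float = 0.5
    residual_sd_wing: float = 1.5
    residual_sd_wing_female: float | None = None  # per-stratum option
    measurement_sd: float = 0.3
    spatial_sill: float = 0.5
    spatial_range: float = 10.0
    # geographic box (degrees)
    lat_range: tuple[float, float] = (-43.0, -11.0)
    lon_range: tuple[float, float] = (115.0, 153.0)
    altitude_range: tuple[float, float] = (0.0, 1500.0)
    # carotenoid-depth model (percent reflectance units); kept shallower
    # than the short-wave reflectance of the pigment-free feather so the
    # 450-nm trough does not clip at zero and saturate the chroma index
    depth_baseline: float = 8.0
    sex_effect_depth: float = 1.0
    season_effect_depth: float = -0.5
    season2_effect_depth: float = -0.25
    residual_sd_depth: float = 1.5
    # spectrum shape
    spectrum_base: float = 5.0
    spectrum_plateau: float = 50.0
    sigmoid_midpoint: float = 480.0
    sigmoid_slope: float = 30.0
    replicate_noise_sd: float = 1.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_p_wing", "sigma2_s_wing", "sigma2_p_colour",
                     "sigma2_s_colour", "spatial_sill"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.year_span
        if not (1900 <= lo <= hi <= 2008):
            raise ValueError("year span must lie within 1900-2008")


@dataclass
class SpeciesTruth:
    """Planted per-species parameters."""

    name: str
    wing_slope: float  # mm / year
    depth_slope: float  # depth percent / year


@dataclass
class StudyData:
    """One complete synthetic study."""

    config: StudyConfig
    tree: dendropy.Tree
    truths: list[SpeciesTruth]
    records: list[SpecimenRecord]
    spectra: dict  # specimen_id -> list[ReflectanceSpectrum]

    def species_names(self) -> list[str]:
        return [t.name for t in self.truths]


def simulate_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Pure-birth tree rescaled to unit depth; deterministic per seed."""
    from dendropy.model import birthdeath

    if n_species <= 2:  # degenerate for a birth process: unit-depth cherry
        labels = ",".join(f"sp{i + 1:02d}:1.0" for i in range(n_species))
        return dendropy.Tree.get(data=f"({labels});", schema="newick")
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=random.Random(seed),
    )
    tree.calc_node_root_distances()
    depth = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    # deterministic tip labels sp01.. in taxon order
    for i, taxon in enumerate(sorted(tree.taxon_namespace, key=lambda t: t.label)):
        taxon.label = f"sp{i + 1:02d}"
    return tree


def simulate_species_effects(
    tree: dendropy.Tree,
    mu: float,
    sigma2_p: float,
    sigma2_s: float,
    seed: int,
) -> dict[str, float]:
    """True slopes mu + a_i + u_i with a ~ N(0, sigma2_p A), u ~ N(0, sigma2_s I)."""
    from .phylo_meta import phylo_correlation

    species = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    corr = phylo_correlation(tree, species)
    rng = np.random.default_rng(seed)
    k = len(species)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(k))
    a = np.sqrt(sigma2_p) * (chol @ rng.standard_normal(k))
    u = np.sqrt(sigma2_s) * rng.standard_normal(k)
    return dict(zip(species, mu + a + u))


def _gaussian_field(
    lat: np.ndarray, lon: np.ndarray, sill: float, range_: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian random field with exponential covariance sill*exp(-d/range)."""
    if sill == 0 or range_ <= 0:
        return np.zeros(lat.size)
    pts = np.column_stack([lat, lon])
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    cov = sill * np.exp(-d / range_) + 1e-8 * np.eye(lat.size)
    return np.linalg.cholesky(cov) @ rng.standard_normal(lat.size)


def simulate_spectrum(
    carotenoid_depth: float,
    seed: int | np.random.Generator,
    config: StudyConfig = StudyConfig(),
    n_replicates: int = 5,
) -> list[ReflectanceSpectrum]:
    """Carotenoid-like reflectance spectra: sigmoid step + 450-nm trough.

    R(lambda) = base + (plateau - base) * logistic((lambda - mid)/slope)
    - depth * gauss(lambda; 450, 30), clamped at zero, with independent
    Gaussian replicate noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wl = STANDARD_GRID
    cfg = config
    sigmoid = 1.0 / (1.0 + np.exp(-(wl - cfg.sigmoid_midpoint) / cfg.sigmoid_slope))
    trough = np.exp(-(((wl - 450.0) / 30.0) ** 2))
    clean = cfg.spectrum_base + (cfg.spectrum_plateau - cfg.spectrum_base) * sigmoid
    clean = clean - carotenoid_depth * trough
    out = []
    for _ in range(n_replicates):
        noisy = clean + rng.normal(0.0, cfg.replicate_noise_sd, wl.size)
        out.append(ReflectanceSpectrum(wl, np.clip(noisy, 0.0, None)))
    return out


def simulate_specimens(
    truth: SpeciesTruth,
    config: StudyConfig,
    seed: int,
    n_specimens: int | None = None,
) -> tuple[list[SpecimenRecord], dict[str, float]]:
    """Specimen records for one species, plus each specimen's true depth.

    Wing length: intercept + slope * (year - 1950) + sex + altitude +
    subspecies + spatial field + noise, measured twice with independent
    measurement error.  Carotenoid depth: baseline + depth-slope *
    (year - 1950) + sex + season + season^2 + noise (the colour trait that
    the spectra will carry).
    """
    rng = np.random.default_rng(seed)
    cfg = config
    if n_specimens is None:
        n_specimens = int(rng.integers(cfg.specimens_per_species[0],
                                       cfg.specimens_per_species[1] + 1))
    n = n_specimens
    years = rng.integers(cfg.year_span[0], cfg.year_span[1] + 1, n)
    months = rng.integers(1, 13, n)
    lat = rng.uniform(*cfg.lat_range, n)
    lon = rng.uniform(*cfg.lon_range, n)
    altitude = rng.uniform(*cfg.altitude_range, n)
    male = rng.integers(0, 2, n)
    # two subspecies split across the longitudinal range
    west = lon < np.median(lon)
    spatial = _gaussian_field(lat, lon, cfg.spatial_sill, cfg.spatial_range, rng)

    wing_true = (
        cfg.wing_intercept
        + truth.wing_slope * (years - 1950)
        + cfg.sex_effect_wing * male
        + cfg.altitude_effect_wing * altitude
        + cfg.subspecies_effect_wing * west
        + spatial
    )
    sd = np.full(n, cfg.residual_sd_wing)
    if cfg.residual_sd_wing_female is not None:
        sd = np.where(male == 1, cfg.residual_sd_wing, cfg.residual_sd_wing_female)
    wing_true = wing_true + rng.normal(0.0, sd)

    season = np.ceil(months / 2.0)
    sc = season - season.mean()
    depth = (
        cfg.depth_baseline
        + truth.depth_slope * (years - 1950)
        + cfg.sex_effect_depth * male
        + cfg.season_effect_depth * sc
        + cfg.season2_effect_depth * sc**2
        + rng.normal(0.0, cfg.residual_sd_depth, n)
    )
    depth = np.clip(depth, 0.0, None)

    records = []
    true_depth = {}
    for i in range(n):
        sid = f"{truth.name}-{i + 1:04d}"
        w1 = wing_true[i] + rng.normal(0.0, cfg.measurement_sd)
        w2 = wing_true[i] + rng.normal(0.0, cfg.measurement_sd)
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                species=truth.name,
                year=int(years[i]),
                latitude=float(lat[i]),
                longitude=float(lon[i]),
                sex="male" if male[i] else "female",
                month=int(months[i]),
                subspecies="west" if west[i] else "east",
                altitude=float(altitude[i]),
                wing_first=float(max(w1, 1e-3)),
                wing_second=float(max(w2, 1e-3)),
            )
        )
        true_depth[sid] = float(depth[i])
    return records, true_depth


def generate_study(config: StudyConfig = StudyConfig(), star: bool = False) -> StudyData:
    """Simulate a complete study: tree, true slopes, specimens, spectra."""
    seed = config.master_seed
    if star:
        from .phylo_meta import star_tree

        tree = star_tree([f"sp{i + 1:02d}" for i in range(config.n_species)])
    else:
        tree = simulate_tree(config.n_species, seed + _SEED_TREE)
    wing_slopes = simulate_species_effects(
        tree, config.mu_wing, config.sigma2_p_wing, config.sigma2_s_wing,
        seed + _SEED_EFFECTS,
    )
    depth_slopes = simulate_species_effects(
        tree, config.mu_colour, config.sigma2_p_colour, config.sigma2_s_colour,
        seed + _SEED_EFFECTS + 1,
    )
    truths = [
        SpeciesTruth(name=s, wing_slope=wing_slopes[s], depth_slope=depth_slopes[s])
        for s in sorted(wing_slopes)
    ]
    records: list[SpecimenRecord] = []
    spectra: dict[str, list[ReflectanceSpectrum]] = {}
    for j, truth in enumerate(truths):
        recs, depths = simulate_specimens(truth, config, seed + _SEED_SPECIMENS + j)
        records.extend(recs)
        spec_rng = np.random.default_rng(seed + _SEED_SPECTRA + j)
        for rec in recs:
            spectra[rec.specimen_id] = simulate_spectrum(
                depths[rec.specimen_id], spec_rng, config
            )
    return StudyData(config=config, tree=tree, truths=truths,
                     records=records, spectra=spectra)


def write_study(study: StudyData, outdir: str | Path) -> None:
    """Write a study in the formats the readers consume.

    Specimen table as CSV, spectra as two-column text files named
    ``<specimen_id>_<k>.txt``, the tree as newick, and a config echo.
    """
    outdir = Path(outdir)
    (outdir / "spectra").mkdir(parents=True, exist_ok=True)
    rows = []
    for r in study.records:
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "species": r.species,
                "subspecies": r.subspecies,
                "year": r.year,
                "month": r.month,
                "latitude": r.latitude,
                "longitude": r.longitude,
                "altitude": r.altitude,
                "sex": r.sex,
                "wing_first": r.wing_first,
                "wing_second": r.wing_second,
                "juvenile": int(r.juvenile),
                "molting": int(r.molting),
                "damaged": int(r.damaged),
                "unsexed": int(r.unsexed),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "specimens.csv", index=False)
    for sid, reps in study.spectra.items():
        for k, spec in enumerate(reps, start=1):
            np.savetxt(
                outdir / "spectra" / f"{sid}_{k}.txt",
                np.column_stack([spec.wavelengths, spec.reflectance]),
                fmt="%.1f %.5f",
            )
    study.tree.write(path=str(outdir / "tree.nwk"), schema="newick")
    import yaml

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(study.config), fh)
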