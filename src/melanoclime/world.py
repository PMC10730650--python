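"""Synthetic world generator.

Builds a complete, seeded input bundle with the statistical structure
the analysis assumes: a planar equal-area grid with spatially
autocorrelated environmental fields (temperature with a latitudinal
gradient and a tropical plateau, elevation, productivity coupled to
temperature, UVB coupled to latitude and elevation), a birth-death
phylogeny, thermal niche centres evolving by Brownian motion (so the
temperature association is phylogenetically conserved), species ranges
as contiguous blocks filtered by temperature and productivity niches,
colour lightness as environmental effects plus a lambda-damped
phylogenetic deviation plus noise, wheel-quantised colour observations
with roughly 1.4 individuals per species, and chytridiomycosis severity
with a planted colour-by-productivity interaction.

Every output is a pure function of (config, master seed).
"""

from __future__ import annotations

import random
from dataclasses import asdict, dataclass, field, fields as dataclass_fields

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.ndimage import gaussian_filter, label

from .colour import ColourObservation, ColourPatch, ColourWheel, build_default_wheel
from .phylo import lambda_transform, vcv_from_tree

TROPICAL_LAT = 0.5  # |lat| below this is 'tropical' in the realm layout


@dataclass
class WorldConfig:
    # grid and environment
    nx: int = 50
    ny: int = 50
    smooth_sigma: float = 3.0      # cells; range of the smoothing kernel
    mat_max: float = 28.0          # deg C at the equator
    mat_drop: float = 22.0         # equator-to-pole decline
    mat_plateau: float = 0.35      # |lat| half-width of the flat tropical belt
    mat_noise_sd: float = 1.2
    mat_lapse: float = 1.0         # deg C cooling per km of elevation
    elev_mean: float = 800.0
    elev_sd: float = 600.0
    evi_mat_corr: float = 0.35      # cross-correlation of EVI with MAT
    evi_mean: float = 0.35
    evi_sd: float = 0.15
    uvb_base: float = 4500.0       # J m^-2 day^-1 scale
    uvb_lat_slope: float = 600.0
    uvb_elev_coef: float = 300.0
    uvb_noise_sd: float = 450.0
    water_fraction_of_cells: float = 0.08
    # phylogeny and trait model
    n_species: int = 300
    birth_rate: float = 1.0
    death_rate: float = 0.3
    family_depth: float = 0.45     # fraction of tree height where families split
    niche_sd: float = 7.0          # sd of thermal niche centres, deg C
    niche_phylo_weight: float = 0.75  # share of niche variance that is Brownian on the tree
    niche_breadth_mat: float = 3.0
    niche_breadth_evi: float = 0.08
    beta_mat: float = 18.0         # lightness units per between-species SD
    beta_elev: float = 2.0
    beta_evi: float = -10.0
    beta_uvb: float = -8.0
    sigma_phylo: float = 18.0      # sd of the lambda-damped phylogenetic deviation
    trait_lambda: float = 0.55
    sigma_resid: float = 4.0
    lightness_base: float = 165.0
    clip_lo: float = 86.0          # kept inside the default wheel's lightness span
    clip_hi: float = 242.0
    # observation model
    individuals_poisson_mean: float = 0.4  # individuals = 1 + Poisson(mean), mean 1.4
    observer_sd: float = 5.0
    missingness: float = 0.15
    quantize: bool = True
    # severity model
    severity_affected_frac: float = 0.2
    severity_base: float = 2.0
    severity_interaction: float = 0.8
    severity_main: float = 0.3
    severity_noise_sd: float = 0.8
    # master seed
    seed: int = 0

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))

    @classmethod
    def from_yaml(cls, path) -> "WorldConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclass_fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _smooth_field(shape, sigma, rng) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def _realm(lat: np.ndarray, xfrac: np.ndarray) -> np.ndarray:
    out = np.where(lat < -TROPICAL_LAT, "south_temperate",
                   np.where(lat > TROPICAL_LAT, "north_temperate",
                            np.where(xfrac < 0.5, "tropical_west", "tropical_east")))
    return out


def simulate_environment(config: WorldConfig) -> pd.DataFrame:
    """Grid cells with coordinates, water fraction, realm and environment."""
    rng = config.rng(1)
    ny, nx = config.ny, config.nx
    yy, xx = np.meshgrid(np.arange(ny) + 0.5, np.arange(nx) + 0.5, indexing="ij")
    lat = (yy - ny / 2.0) / (ny / 2.0)  # [-1, 1]
    abslat = np.abs(lat)

    elev = config.elev_mean + config.elev_sd * _smooth_field((ny, nx), config.smooth_sigma, rng)
    elev = np.clip(elev, 0.0, None)
    zelev = (elev - elev.mean()) / elev.std()

    # temperature: flat tropical belt, linear decline polewards, elevation
    # lapse-rate cooling, smooth noise
    decline = np.clip(abslat - config.mat_plateau, 0.0, None) / (1.0 - config.mat_plateau)
    mat = config.mat_max - config.mat_drop * decline \
        - config.mat_lapse * (elev - elev.mean()) / 1000.0 \
        + config.mat_noise_sd * _smooth_field((ny, nx), config.smooth_sigma, rng)

    rho = config.evi_mat_corr
    zmat = (mat - mat.mean()) / mat.std()
    evi_indep = _smooth_field((ny, nx), config.smooth_sigma, rng)
    evi = config.evi_mean + config.evi_sd * (rho * zmat + np.sqrt(1 - rho**2) * evi_indep)
    evi = np.clip(evi, 0.0, 1.0)

    uvb = config.uvb_base - config.uvb_lat_slope * abslat \
        + config.uvb_elev_coef * zelev \
        + config.uvb_noise_sd * _smooth_field((ny, nx), config.smooth_sigma, rng)

    n_cells = ny * nx
    water = rng.uniform(0.0, 0.4, size=n_cells)
    border = ((yy < 2) | (yy > ny - 2) | (xx < 2) | (xx > nx - 2)).ravel()
    n_water = int(round(config.water_fraction_of_cells * n_cells))
    border_idx = np.flatnonzero(border)
    wet = rng.choice(border_idx, size=min(n_water, len(border_idx)), replace=False)
    water[wet] = rng.uniform(0.55, 0.95, size=len(wet))

    cells = pd.DataFrame({
        "cell_id": [f"c{r:02d}_{c:02d}" for r in range(ny) for c in range(nx)],
        "row": yy.ravel().astype(int), "col": xx.ravel().astype(int),
        "x": xx.ravel(), "y": yy.ravel(),
        "water_fraction": water,
        "realm": _realm(lat, xx / nx).ravel(),
        "MAT": mat.ravel(), "elevation": elev.ravel(),
        "EVI": evi.ravel(), "UVB": uvb.ravel(),
    })
    return cells


@dataclass
class TraitSim:
    tree: dendropy.Tree
    traits: pd.DataFrame      # species_id, family, niche_mat, niche_evi,
                              # range-mean env, true_lightness, clipped
    occupancy: pd.DataFrame   # cell_id, species_id (included land cells only)
    clipped_fraction: float
    dropped_species: list[str] = field(default_factory=list)


def simulate_phylogeny(config: WorldConfig) -> dendropy.Tree:
    """Birth-death tree with unit height and labelled tips sp0001..spN."""
    from dendropy.simulate import treesim
    seed = int(np.random.SeedSequence([config.seed, 2]).generate_state(1)[0] % 2**31)
    tree = treesim.birth_death_tree(
        birth_rate=config.birth_rate, death_rate=config.death_rate,
        num_extant_tips=config.n_species, rng=random.Random(seed))
    height0 = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:04d}"
        # the process stops at a speciation event, leaving the newest tips
        # with zero-length branches; evolve every tip a little further so
        # the covariance matrix is positive definite (still ultrametric)
        leaf.edge.length = (leaf.edge.length or 0.0) + 0.01 * height0
    height = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= height
    tree.is_rooted = True
    return tree


def _assign_families(tree: dendropy.Tree, depth_fraction: float) -> dict[str, str]:
    """Cut the tree at a fixed depth: each crossing lineage is one family."""
    fams: dict[str, str] = {}
    counter = [0]

    def tips_below(node):
        return [lf.taxon.label for lf in node.leaf_iter()]

    depth = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
        if depth[id(node)] >= depth_fraction > depth[id(node.parent_node)]:
            counter[0] += 1
            fam = f"fam{counter[0]:02d}"
            for t in tips_below(node):
                fams[t] = fam
    return fams


def simulate_tree_and_traits(config: WorldConfig, cells: pd.DataFrame) -> TraitSim:
    """Phylogeny, niches, contiguous ranges and true colour lightness.

    Thermal niche centres are Brownian on the tree; the productivity
    preference is the EVI at a random cell inside the species' thermal
    band, so ranges are localized and respond to both axes.  True
    lightness combines z-scaled range-mean environmental effects, a
    lambda-damped phylogenetic deviation, and iid noise, then is clipped
    into [clip_lo, clip_hi].
    """
    tree = simulate_phylogeny(config)
    species = [lf.taxon.label for lf in tree.leaf_node_iter()]
    n = len(species)
    cov = vcv_from_tree(tree).reorder(species)
    C = cov.matrix / np.mean(np.diag(cov.matrix))
    Lc = cholesky(C + 1e-10 * np.eye(n), lower=True)
    rng = config.rng(3)

    land = cells[cells["water_fraction"] <= 0.5].reset_index(drop=True)
    mat = land["MAT"].to_numpy()
    mat_lo, mat_hi = mat.min(), mat.max()

    # BM thermal niche centres, clipped inside the realized temperature range
    # thermal niche: mostly Brownian on the tree (phylogenetic niche
    # conservatism) with an independent component so no clade monopolises
    # a climate band
    wp = config.niche_phylo_weight
    z_m = np.sqrt(wp) * (Lc @ rng.standard_normal(n)) \
        + np.sqrt(1.0 - wp) * rng.standard_normal(n)
    niche_mat = np.clip(mat.mean() + config.niche_sd * z_m, mat_lo + 0.5, mat_hi - 0.5)

    # grid geometry for contiguity
    ny, nx = config.ny, config.nx
    land_mask = np.zeros((ny, nx), dtype=bool)
    land_mask[land["row"], land["col"]] = True
    cell_grid = np.full((ny, nx), -1, dtype=int)
    cell_grid[land["row"], land["col"]] = np.arange(len(land))
    evi_grid = np.zeros((ny, nx))
    evi_grid[land["row"], land["col"]] = land["EVI"]
    mat_grid = np.zeros((ny, nx))
    mat_grid[land["row"], land["col"]] = land["MAT"]

    occ_rows = []
    niche_evi = np.zeros(n)
    dropped = []
    for i, sp in enumerate(species):
        breadth = config.niche_breadth_mat
        placed = False
        for _attempt in range(4):
            band = land_mask & (np.abs(mat_grid - niche_mat[i]) <= breadth)
            idx = np.argwhere(band)
            if len(idx) == 0:
                breadth *= 1.5
                continue
            r, c = idx[rng.integers(len(idx))]
            v = evi_grid[r, c]
            eligible = band & (np.abs(evi_grid - v) <= config.niche_breadth_evi)
            lab, _ = label(eligible)
            comp = lab == lab[r, c]
            rows, colz = np.nonzero(comp)
            niche_evi[i] = v
            occ_rows.append(pd.DataFrame({
                "cell_id": land["cell_id"].to_numpy()[cell_grid[rows, colz]],
                "species_id": sp}))
            placed = True
            break
        if not placed:
            dropped.append(sp)
    occupancy = pd.concat(occ_rows, ignore_index=True)
    kept = [sp for sp in species if sp not in set(dropped)]

    # range-mean environment per species (over occupied land cells)
    env = occupancy.merge(land[["cell_id", "MAT", "elevation", "EVI", "UVB"]], on="cell_id")
    means = env.groupby("species_id", sort=False)[["MAT", "elevation", "EVI", "UVB"]].mean()
    means = means.loc[kept]
    Z = (means - means.mean()) / means.std(ddof=0)

    betas = {"MAT": config.beta_mat, "elevation": config.beta_elev,
             "EVI": config.beta_evi, "UVB": config.beta_uvb}
    env_effect = sum(b * Z[v].to_numpy() for v, b in betas.items())

    C_lam = lambda_transform(C, config.trait_lambda)
    a = config.sigma_phylo * (cholesky(C_lam + 1e-10 * np.eye(n), lower=True)
                              @ rng.standard_normal(n))
    e = config.sigma_resid * rng.standard_normal(n)
    keep_idx = [species.index(sp) for sp in kept]
    raw = config.lightness_base + env_effect + a[keep_idx] + e[keep_idx]
    clipped = (raw < config.clip_lo) | (raw > config.clip_hi)
    true_lightness = np.clip(raw, config.clip_lo, config.clip_hi)

    fams = _assign_families(tree, config.family_depth)
    traits = pd.DataFrame({
        "species_id": kept,
        "family": [fams.get(sp, "fam00") for sp in kept],
        "niche_mat": niche_mat[keep_idx], "niche_evi": niche_evi[keep_idx],
        "range_MAT": means["MAT"].to_numpy(), "range_elevation": means["elevation"].to_numpy(),
        "range_EVI": means["EVI"].to_numpy(), "range_UVB": means["UVB"].to_numpy(),
        "true_lightness": true_lightness, "clipped": clipped,
    })
    return TraitSim(tree, traits, occupancy, float(clipped.mean()), dropped)


def lightness_to_patches(target: float, wheel: ColourWheel) -> list[ColourPatch]:
    """Express a continuous lightness as 1-2 wheel patches in 5% steps.

    Greedy bracketing on the wheel's lightness axis: the two colours
    whose lightness values straddle the target are mixed with coverages
    rounded to 0.05.  Targets outside the wheel's span clip to its
    nearest colour.
    """
    entries = sorted(wheel.entries, key=lambda en: ((en.rgb[0] + en.rgb[1] + en.rgb[2]) / 3.0, en.colour_id))
    lvals = np.array([(en.rgb[0] + en.rgb[1] + en.rgb[2]) / 3.0 for en in entries])
    uniq_vals, uniq_first = np.unique(lvals, return_index=True)
    ids = np.array([entries[i].colour_id for i in uniq_first])
    if target <= uniq_vals[0]:
        return [ColourPatch(int(ids[0]), 1.0)]
    if target >= uniq_vals[-1]:
        return [ColourPatch(int(ids[-1]), 1.0)]
    hi = int(np.searchsorted(uniq_vals, target))
    lo = hi - 1
    w = (target - uniq_vals[lo]) / (uniq_vals[hi] - uniq_vals[lo])
    w = round(w / 0.05) * 0.05
    if w <= 0:
        return [ColourPatch(int(ids[lo]), 1.0)]
    if w >= 1:
        return [ColourPatch(int(ids[hi]), 1.0)]
    return [ColourPatch(int(ids[hi]), round(w, 2)), ColourPatch(int(ids[lo]), round(1 - w, 2))]


def simulate_observations(config: WorldConfig, traits: pd.DataFrame,
                          wheel: ColourWheel | None = None):
    """Wheel-coded colour observations per species.

    Individuals per species are 1 + Poisson(individuals_poisson_mean)
    (mean ~= 1.4); each individual's recorded lightness is the species'
    true value plus observer noise, expressed as wheel patches when
    quantisation is on, otherwise as one exact grey RGB patch.  A
    `missingness` fraction of species yields no observations.
    Returns (observations, missing_species).
    """
    rng = config.rng(4)
    if wheel is None and config.quantize:
        wheel = build_default_wheel()
    observations: list[ColourObservation] = []
    missing: list[str] = []
    for row in traits.sort_values("species_id").itertuples():
        if rng.random() < config.missingness:
            missing.append(row.species_id)
            continue
        n_ind = 1 + int(rng.poisson(config.individuals_poisson_mean))
        for j in range(1, n_ind + 1):
            val = float(np.clip(row.true_lightness + rng.normal(0, config.observer_sd), 0, 255))
            if config.quantize:
                patches = lightness_to_patches(val, wheel)
            else:
                patches = [ColourPatch((val, val, val), 1.0)]
            observations.append(ColourObservation(row.species_id, f"{row.species_id}_i{j}",
                                                  "obs1", patches))
    return observations, missing


def simulate_activity(config: WorldConfig, species: list[str]) -> pd.DataFrame:
    rng = config.rng(5)
    classes = np.array(["diurnal", "nocturnal", "both"])
    labels = classes[rng.choice(3, size=len(species), p=[0.2, 0.6, 0.2])]
    return pd.DataFrame({"species_id": sorted(species), "activity": labels})


def simulate_severity(config: WorldConfig, traits: pd.DataFrame,
                      occupancy: pd.DataFrame) -> pd.DataFrame:
    """Chytridiomycosis severity with a planted colour-by-EVI interaction.

    A random fraction of species is 'affected'; their severity is
    severity_base + interaction * z(lightness) * z(range EVI) +
    main * z(lightness) + noise, floored at 0.1.  Species co-occurring
    with an affected species but not themselves affected are the
    controls, coded 0; species never co-occurring with affected ones
    are absent from the table.
    """
    rng = config.rng(6)
    t = traits.sort_values("species_id").reset_index(drop=True)
    n = len(t)
    affected = np.zeros(n, dtype=bool)
    affected[rng.choice(n, size=int(round(config.severity_affected_frac * n)), replace=False)] = True
    zl = (t["true_lightness"] - t["true_lightness"].mean()) / t["true_lightness"].std(ddof=0)
    ze = (t["range_EVI"] - t["range_EVI"].mean()) / t["range_EVI"].std(ddof=0)
    sev = (config.severity_base + config.severity_interaction * zl * ze
           + config.severity_main * zl + rng.normal(0, config.severity_noise_sd, n))
    sev = np.clip(sev, 0.1, None)

    aff_sp = set(t.loc[affected, "species_id"])
    cells_with_aff = set(occupancy.loc[occupancy["species_id"].isin(aff_sp), "cell_id"])
    cooccur = set(occupancy.loc[occupancy["cell_id"].isin(cells_with_aff), "species_id"])
    rows = []
    for i, row in t.iterrows():
        if affected[i]:
            rows.append({"species_id": row.species_id, "severity": sev[i],
                         "status": "affected", "family": row.family})
        elif row.species_id in cooccur:
            rows.append({"species_id": row.species_id, "severity": 0.0,
                         "status": "control", "family": row.family})
    return pd.DataFrame(rows)


@dataclass
class World:
    config: WorldConfig
    cells: pd.DataFrame
    tree: dendropy.Tree
    traits: pd.DataFrame
    occupancy: pd.DataFrame
    wheel: ColourWheel
    observations: list
    missing_species: list[str]
    activity: pd.DataFrame
    severity: pd.DataFrame
    manifest: dict


def generate_world(config: WorldConfig | None = None, seed: int | None = None) -> World:
    """Generate the full synthetic input bundle from one master seed."""
    if config is None:
        config = WorldConfig()
    if seed is not None:
        config = WorldConfig(**{**asdict(config), "seed": seed})
    cells = simulate_environment(config)
    sim = simulate_tree_and_traits(config, cells)
    wheel = build_default_wheel()
    observations, missing = simulate_observations(config, sim.traits, wheel)
    activity = simulate_activity(config, list(sim.traits["species_id"]))
    severity = simulate_severity(config, sim.traits, sim.occupancy)
    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "n_cells": len(cells),
        "n_water_cells": int((cells["water_fraction"] > 0.5).sum()),
        "n_species": len(sim.traits),
        "dropped_species": sim.dropped_species,
        "clipped_fraction": sim.clipped_fraction,
        "n_observations": len(observations),
        "n_missing_species": len(missing),
        "true_betas": {"MAT": config.beta_mat, "elevation": config.beta_elev,
                       "EVI": config.beta_evi, "UVB": config.beta_uvb},
        "true_lambda": config.trait_lambda,
    }
    return World(config, cells, sim.tree, sim.traits, sim.occupancy, wheel,
                 observations, missing, activity, severity, manifest)
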