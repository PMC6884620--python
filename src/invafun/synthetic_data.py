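"""Synthetic stream-fish communities with known ground truth.

The generator emulates the qualitative structure of a heavily invaded
Mediterranean drainage: a dendritic stream network spanning an altitudinal
gradient; a regional pool of 37 native and 22 exotic species scored on five
categorical ecological functions, with exotics drawn from a restricted
guild-combination pool (restriction factor rho); occupancy of exotic species
decaying with altitude (logistic coupling beta < 0), so invasion degree spans
roughly 0-100% and concentrates in the lowlands; native occupancy suppressed
where invasion pressure is high, and headwater reaches thinned slightly for
species of any origin; abundances
on the ordinal Moyle 1-5 scale; physicochemical variables generated as
declared monotone functions of altitude plus noise; land cover from
altitude-band-conditioned Dirichlet draws.

Ground truth (per-site invasion propensity, exotic pool membership, generating
parameters) is carried separately and never consumed by the analysis stages.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import (
    DEFAULT_GUILD_VOCABULARIES,
    ECOLOGICAL_FUNCTIONS,
    AbundanceMatrix,
    EnvTable,
    SpeciesTable,
    TraitTable,
)
from . import spatial

__all__ = ["SynthConfig", "SynthTruth", "generate_pool", "generate_sites",
           "generate_communities", "generate_dataset", "write_dataset"]

# independent RNG stream ids per generator stage
_STAGE_POOL, _STAGE_SITES, _STAGE_COMMUNITIES = 0, 1, 2


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Generator settings. Defaults mirror the study dimensions: 335 sites,
    37 native and 22 exotic species, invasion concentrated below ~400 m."""

    n_sites: int = 335
    n_native: int = 37
    n_exotic: int = 22
    vocabularies: Mapping[str, Sequence[str]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_GUILD_VOCABULARIES)
    )
    #: fraction of each guild vocabulary available to the exotic pool
    rho: float = 0.3
    altitude_max: float = 1200.0
    lowland_fraction: float = 0.62  # share of sites in the lowland altitude mass
    lowland_scale: float = 60.0  # exponential scale (m) of lowland altitudes
    #: logistic invasion-altitude coupling: propensity = expit(alpha + beta * altitude)
    alpha: float = 1.5
    beta: float = -0.01
    occ_exotic_max: float = 0.45  # per-species exotic occupancy at propensity 1
    occ_native_base: float = 0.35  # per-species native occupancy, uninvaded lowland
    native_suppression: float = 0.85  # native occupancy loss at propensity 1
    headwater_native_factor: float = 0.85  # mild native reduction in order 1-2 reaches
    canal_probability: float = 0.25  # lowland side reaches flagged as canals
    moyle_probs: tuple[float, ...] = (0.35, 0.30, 0.20, 0.10, 0.05)
    rng_seed: int = 0

    def stage_rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.rng_seed, spawn_key=(stage,))
        )


@dataclasses.dataclass
class SynthTruth:
    """Generating state the analysis is supposed to recover, kept out of band."""

    invasion_propensity: pd.Series  # site_id -> expit(alpha + beta * altitude)
    exotic_pools: dict[str, list[str]]  # function -> restricted label subset
    config: SynthConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "invasion_propensity": self.invasion_propensity.round(6).to_dict(),
            "exotic_pools": self.exotic_pools,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self.config).items()
                if k != "vocabularies"
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def generate_pool(config: SynthConfig) -> tuple[SpeciesTable, TraitTable, dict[str, list[str]]]:
    """Draw the regional species pool and its guild traits.

    Native labels are uniform over the full vocabularies; exotic labels come
    from a random subset of ceil(rho * |vocab|) labels per function, emulating
    the introduction of species with a limited combination of traits.
    """
    rng = config.stage_rng(_STAGE_POOL)
    vocab = {fn: list(config.vocabularies[fn]) for fn in ECOLOGICAL_FUNCTIONS}
    for fn, v in vocab.items():
        if not v:
            raise ValueError(f"generate_pool: empty vocabulary for {fn}")
        if int(np.ceil(config.rho * len(v))) < 1:
            raise ValueError(
                f"generate_pool: rho={config.rho} leaves no labels for {fn} "
                f"(|vocab| = {len(v)})"
            )

    native_ids = [f"nat{i + 1:02d}" for i in range(config.n_native)]
    exotic_ids = [f"exo{i + 1:02d}" for i in range(config.n_exotic)]
    species = pd.DataFrame(
        {
            "species_id": native_ids + exotic_ids,
            "origin": ["native"] * config.n_native + ["exotic"] * config.n_exotic,
            "body_mass_class": rng.integers(1, 4, size=config.n_native + config.n_exotic),
        }
    )

    pools = {
        fn: sorted(
            rng.choice(v, size=int(np.ceil(config.rho * len(v))), replace=False).tolist()
        )
        for fn, v in vocab.items()
    }
    traits = {"species_id": native_ids + exotic_ids}
    for fn in ECOLOGICAL_FUNCTIONS:
        native_labels = rng.choice(vocab[fn], size=config.n_native).tolist()
        exotic_labels = rng.choice(pools[fn], size=config.n_exotic).tolist()
        traits[fn] = native_labels + exotic_labels
    return (
        SpeciesTable(species),
        TraitTable(pd.DataFrame(traits), vocabularies=config.vocabularies),
        pools,
    )


def _branching_network(rng: np.random.Generator, n: int) -> nx.DiGraph:
    """Random dendritic network: each new reach attaches upstream of an
    existing one, edges pointing downstream toward the single outlet."""
    g = nx.DiGraph()
    g.add_node("r000")
    for i in range(1, n):
        parent = f"r{int(rng.integers(0, i)):03d}"
        g.add_node(f"r{i:03d}")
        g.add_edge(f"r{i:03d}", parent)
    return g


def generate_sites(config: SynthConfig) -> tuple[EnvTable, nx.DiGraph]:
    """Generate the site environmental table and the stream network.

    Altitudes follow a lowland-mass + upland-tail mixture and increase with
    distance from the outlet; physicochemical variables are monotone functions
    of altitude plus Gaussian/log-normal noise (temperature, conductivity and
    nutrient loads all decrease upstream); land-cover shares are Dirichlet
    draws conditioned on the altitude band.
    """
    rng = config.stage_rng(_STAGE_SITES)
    n = config.n_sites
    network = _branching_network(rng, n)
    reaches = sorted(network.nodes)

    # distance (in reaches) to the outlet drives altitude and geometry
    outlet = "r000"
    depth = {
        node: nx.shortest_path_length(network, node, outlet) for node in reaches
    }
    max_depth = max(depth.values()) or 1

    n_low = int(round(config.lowland_fraction * n))
    lowland = rng.exponential(config.lowland_scale, size=n_low)
    upland = 150.0 + (config.altitude_max - 150.0) * rng.beta(1.2, 2.5, size=n - n_low)
    altitudes = np.clip(np.sort(np.concatenate([lowland, upland])), 0.0, config.altitude_max)
    # deeper (more upstream) reaches get higher altitudes, with jitter
    depth_order = np.argsort(
        np.asarray([depth[r] for r in reaches]) + rng.uniform(0, 0.99, size=n)
    )
    altitude = np.empty(n)
    altitude[depth_order] = altitudes

    # coordinates: walk upstream from the outlet, drifting north-west
    pos = {outlet: (11.80, 44.70)}
    for node in sorted(network.nodes, key=lambda r: depth[r]):
        if node == outlet:
            continue
        parent = next(iter(network.successors(node)))
        px, py = pos[parent]
        pos[node] = (
            px + rng.normal(-0.020, 0.030),
            py + rng.normal(0.012, 0.025),
        )
    lon = np.array([pos[r][0] for r in reaches])
    lat = np.array([pos[r][1] for r in reaches])

    order = spatial.strahler(network)
    orders = np.array([order[r] for r in reaches])
    is_canal = np.array(
        [
            (altitude[i] < 50.0)
            and (orders[i] <= 2)
            and (rng.random() < config.canal_probability)
            for i in range(n)
        ]
    )
    nx.set_node_attributes(
        network, {r: bool(is_canal[i]) for i, r in enumerate(reaches)}, "is_canal"
    )

    def pos_noise(base, decay, sd):
        # log-normal noise around a baseline decaying with altitude
        return np.maximum(
            base * np.exp(-altitude / decay) * np.exp(rng.normal(0, sd, size=n)), 1e-3
        )

    env = pd.DataFrame(
        {
            "site_id": [f"s{i + 1:03d}" for i in range(n)],
            "reach_id": reaches,
            "longitude": lon,
            "latitude": lat,
            "altitude": altitude,
            "water_temperature": np.clip(
                24.0 - 0.012 * altitude + rng.normal(0, 1.5, size=n), 2.0, 30.0
            ),
            "electrical_conductivity": pos_noise(900.0, 350.0, 0.25),
            "cod": pos_noise(18.0, 300.0, 0.35),
            "bod": pos_noise(5.0, 300.0, 0.35),
            "tss": pos_noise(30.0, 280.0, 0.40),
            "total_phosphorus": pos_noise(0.25, 260.0, 0.40),
            "ammonia": pos_noise(0.40, 260.0, 0.45),
            "nitrate": pos_noise(3.5, 320.0, 0.35),
            "stream_order": orders,
            "is_canal": is_canal,
        }
    )

    # land cover: Dirichlet concentration by altitude band
    # columns: urban, agricultural, forest, other_natural, freshwater, brackish_water
    shares = np.empty((n, 6))
    for i in range(n):
        a = altitude[i]
        if a > 400:
            conc = (1.0, 2.0, 14.0, 8.0, 1.0, 0.02)
        elif a > 150:
            conc = (2.5, 8.0, 6.0, 3.0, 1.2, 0.05)
        else:
            near_delta = depth[reaches[i]] <= 2
            conc = (4.0, 14.0, 1.2, 1.0, 1.8, 1.5 if near_delta else 0.1)
        shares[i] = rng.dirichlet(conc)
    for k, col in enumerate(
        ("urban", "agricultural", "forest", "other_natural", "freshwater", "brackish_water")
    ):
        env[col] = shares[:, k]
    return EnvTable(env), network


def generate_communities(
    species: SpeciesTable,
    env: EnvTable,
    config: SynthConfig,
    exotic_pools: dict[str, list[str]] | None = None,
) -> tuple[AbundanceMatrix, SynthTruth]:
    """Draw per-site communities on the Moyle scale.

    Exotic occupancy probability is occ_exotic_max * expit(alpha + beta*alt);
    native occupancy is occ_native_base reduced proportionally to the invasion
    propensity. Headwater reaches (stream order 1-2) mildly thin occupancy of
    both origins, so community size shrinks there without a composition bias.
    Occupied species draw a Moyle class from the configured categorical
    distribution; empty draws are repaired with one species appropriate to the
    site (exotic where propensity > 0.5, else native).
    """
    rng = config.stage_rng(_STAGE_COMMUNITIES)
    from scipy.special import expit

    alt = env.altitude.to_numpy(dtype=float)
    headwater = (env.data["stream_order"].to_numpy() <= 2)
    propensity = expit(config.alpha + config.beta * alt)

    natives = species.subset_ids("native")
    exotics = species.subset_ids("exotic")
    n, = alt.shape
    # headwater reaches support slightly fewer species of any origin, so the
    # reduction thins communities without biasing their composition
    headwater_factor = np.where(headwater, config.headwater_native_factor, 1.0)
    p_exo = config.occ_exotic_max * propensity * headwater_factor
    p_nat = (
        config.occ_native_base
        * (1.0 - config.native_suppression * propensity)
        * headwater_factor
    )

    classes = np.arange(1, 6)
    probs = np.asarray(config.moyle_probs, dtype=float)
    probs = probs / probs.sum()

    grid = np.zeros((n, len(natives) + len(exotics)), dtype=int)
    occ_nat = rng.random((n, len(natives))) < p_nat[:, None]
    occ_exo = rng.random((n, len(exotics))) < p_exo[:, None]
    occ = np.hstack([occ_nat, occ_exo])
    moyle = rng.choice(classes, size=grid.shape, p=probs)
    grid[occ] = moyle[occ]

    empty = grid.sum(axis=1) == 0
    for i in np.flatnonzero(empty):
        if propensity[i] > 0.5 and exotics:
            j = len(natives) + int(rng.integers(0, len(exotics)))
        else:
            j = int(rng.integers(0, len(natives)))
        grid[i, j] = int(rng.choice(classes, p=probs))

    abundance = AbundanceMatrix(
        pd.DataFrame(grid, index=env.site_ids, columns=natives + exotics)
    )
    truth = SynthTruth(
        invasion_propensity=pd.Series(propensity, index=env.site_ids),
        exotic_pools=exotic_pools or {},
        config=config,
    )
    return abundance, truth


def generate_dataset(
    config: SynthConfig = SynthConfig(),
) -> tuple[SpeciesTable, TraitTable, AbundanceMatrix, EnvTable, nx.DiGraph, SynthTruth]:
    """All generator stages in sequence, sharing one master seed."""
    species, traits, pools = generate_pool(config)
    env, network = generate_sites(config)
    abundance, truth = generate_communities(species, env, config, exotic_pools=pools)
    return species, traits, abundance, env, network, truth


def write_dataset(out_dir: str | Path, config: SynthConfig = SynthConfig()) -> None:
    """Write the four dataset CSVs, the network edge list and the truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    species, traits, abundance, env, network, truth = generate_dataset(config)
    species.write_csv(out / "species.csv")
    traits.write_csv(out / "traits.csv")
    abundance.write_csv(out / "abundance.csv")
    env.write_csv(out / "env.csv")
    edges = []
    for node in sorted(network.nodes):
        succ = list(network.successors(node))
        edges.append(
            {
                "reach_id": node,
                "downstream_id": succ[0] if succ else "",
                "is_canal": network.nodes[node].get("is_canal", False),
            }
        )
    pd.DataFrame(edges).to_csv(out / "network.csv", index=False)
    truth.to_json(out / "truth.json")
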