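"""Synthetic two-trophic-level communities with known ground truth.

The generator emulates the structure of a vineyard survey: 68 sites, six
thematic abiotic predictor blocks (management, topography, soil, vegetation
structure, landscape at two radii), a plant community recorded as percent
cover and a leafhopper community recorded as counts, coupled bottom-up to
the plants.  Every random quantity is driven by an explicit seed, and the
generating parameters (latent gradients, per-block effect shares, coupling
strength, planted co-occurrence pairs) are returned as ground truth so that
downstream analyses can be scored against what was actually simulated.

Model: sites receive positions on a small number of latent environmental
gradients; block variables load linearly on a gradient plus Gaussian noise;
species respond to a share-weighted composite gradient through Gaussian
niches (optimum + breadth) with log-normal abundance noise.  Specialist
leafhoppers track their host plants' abundance, generalists a weighted
plant composite; both are mixed with an abiotic niche term weighted
(1 − coupling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BlockCollection, SiteSpeciesMatrix, genus_of
from .exceptions import (
    InvalidParameterError,
    InvalidSpecError,
    TooFewSitesError,
    UnknownHostError,
)


@dataclass
class BlockSpec:
    """Specification of one predictor block.

    ``latent_loading`` is the coefficient (scalar, or one per variable) on
    the block's latent gradient; ``gradient`` indexes which latent gradient
    the block reads.
    """

    name: str
    n_vars: int
    latent_loading: float | list[float] = 1.0
    noise_sd: float = 0.3
    gradient: int = 0

    def __post_init__(self) -> None:
        if self.n_vars < 1:
            raise InvalidSpecError(f"block {self.name!r}: n_vars must be >= 1")
        if self.noise_sd < 0:
            raise InvalidSpecError(f"block {self.name!r}: noise_sd must be >= 0")
        loadings = np.atleast_1d(np.asarray(self.latent_loading, dtype=float))
        if loadings.size not in (1, self.n_vars):
            raise InvalidSpecError(
                f"block {self.name!r}: latent_loading must be scalar or "
                f"length {self.n_vars}"
            )


@dataclass
class GroundTruth:
    """What was actually simulated; the recovery target for the analyses."""

    latent_gradients: np.ndarray  # sites x g
    block_effect_shares: dict[str, float]
    coupling_strength: float
    planted_pairs: list[tuple[str, str, str]]
    seed: int
    block_gradients: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.block_effect_shares.values())
        if abs(total - 1.0) > 1e-12:
            raise InvalidSpecError(f"block_effect_shares sum to {total}, not 1")
        if any(w < 0 for w in self.block_effect_shares.values()):
            raise InvalidSpecError("block_effect_shares must be nonnegative")
        for *_, cls in self.planted_pairs:
            if cls not in ("aggregated", "segregated"):
                raise InvalidSpecError(f"unknown planted pair class {cls!r}")

    def composite_gradient(self) -> np.ndarray:
        """Share-weighted combination of the latent gradients."""
        g = np.zeros(self.latent_gradients.shape[0])
        for name, share in self.block_effect_shares.items():
            g += share * self.latent_gradients[:, self.block_gradients.get(name, 0)]
        return g


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------
def generate_env_blocks(
    n_sites: int,
    specs: list[BlockSpec],
    seed: int,
    block_effect_shares: dict[str, float] | None = None,
) -> tuple[BlockCollection, GroundTruth]:
    """Generate the abiotic predictor blocks and the ground truth record."""
    if n_sites < 3:
        raise TooFewSitesError("need at least 3 sites")
    if not specs:
        raise InvalidSpecError("at least one BlockSpec required")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise InvalidSpecError("block names must be unique")
    rng = np.random.default_rng(seed)
    n_grad = max(s.gradient for s in specs) + 1
    gradients = rng.standard_normal((n_sites, n_grad))
    sites = [f"site{i + 1:02d}" for i in range(n_sites)]
    blocks: dict[str, pd.DataFrame] = {}
    for spec in specs:
        loadings = np.broadcast_to(
            np.atleast_1d(np.asarray(spec.latent_loading, dtype=float)),
            (spec.n_vars,),
        )
        grad = gradients[:, spec.gradient]
        noise = rng.standard_normal((n_sites, spec.n_vars)) * spec.noise_sd
        X = grad[:, None] * loadings[None, :] + noise
        cols = [f"{spec.name}_v{j + 1}" for j in range(spec.n_vars)]
        blocks[spec.name] = pd.DataFrame(X, index=sites, columns=cols)
    if block_effect_shares is None:
        block_effect_shares = {name: 1.0 / len(names) for name in names}
    truth = GroundTruth(
        latent_gradients=gradients,
        block_effect_shares=dict(block_effect_shares),
        coupling_strength=0.0,
        planted_pairs=[],
        seed=seed,
        block_gradients={s.name: s.gradient for s in specs},
    )
    return BlockCollection(blocks), truth


# ---------------------------------------------------------------------------
# plant community
# ---------------------------------------------------------------------------
def generate_plant_community(
    env: BlockCollection,
    n_species: int,
    niche_breadth: float,
    truth: GroundTruth,
    seed: int,
    noise_sd: float = 0.4,
    detection_limit: float = 0.5,
    max_cover: float = 100.0,
    n_genera: int | None = None,
) -> SiteSpeciesMatrix:
    """Gaussian-niche plant community on the composite gradient.

    Expected cover of species s at site i is A_s · exp(−(e_i − μ_s)² / 2σ²)
    with optima μ_s spread over the gradient range and σ = ``niche_breadth``
    × sd(gradient); log-normal multiplicative noise (``noise_sd`` on the log
    scale) is applied, values below ``detection_limit`` become absences, and
    cover is capped at ``max_cover`` percent.
    """
    if niche_breadth <= 0:
        raise InvalidParameterError("niche_breadth must be > 0")
    if n_species < 2:
        raise InvalidParameterError("n_species must be >= 2")
    rng = np.random.default_rng(seed)
    e = truth.composite_gradient()
    n_sites = len(e)
    sigma = niche_breadth * max(e.std(), 1e-12)
    optima = rng.uniform(e.min(), e.max(), size=n_species)
    amplitude = np.minimum(rng.lognormal(np.log(15.0), 0.6, size=n_species),
                           max_cover)
    expected = amplitude[None, :] * np.exp(
        -((e[:, None] - optima[None, :]) ** 2) / (2 * sigma**2)
    )
    if noise_sd > 0:
        expected = expected * rng.lognormal(0.0, noise_sd,
                                            size=(n_sites, n_species))
    cover = np.where(expected >= detection_limit,
                     np.minimum(expected, max_cover), 0.0)

    n_genera = n_genera or max(2, n_species // 3)
    genus_ids = rng.integers(0, n_genera, size=n_species)
    species = []
    counter: dict[int, int] = {}
    for g in genus_ids:
        counter[g] = counter.get(g, 0) + 1
        species.append(f"Plantgen{g + 1:02d} sp{counter[g]}")
    sites = env.site_ids
    data = pd.DataFrame(cover, index=sites, columns=species)
    data = _impose_planted_pairs(data, truth.planted_pairs)
    meta = pd.DataFrame(
        {
            "trophic_group": "plant",
            "guild": "none",
            "host_genera": [""] * n_species,
        },
        index=species,
    )
    return SiteSpeciesMatrix(data, meta)


def _impose_planted_pairs(data: pd.DataFrame, planted) -> pd.DataFrame:
    """Overwrite planted pairs after background generation so the intended
    checkerboard (segregated) or identical occupancy (aggregated) is exact."""
    for sp_a, sp_b, cls in planted:
        if sp_a not in data.columns or sp_b not in data.columns:
            continue  # pair refers to the other community / binary fixture
        a = data[sp_a].to_numpy()
        b = data[sp_b].to_numpy()
        if cls == "segregated":
            b = np.where(a > 0, 0.0, b)
            if not (b > 0).any() and (a == 0).any():
                b[np.argmax(a == 0)] = max(b.max(), 1.0)
        else:  # aggregated: identical occupancy
            scale = (b[b > 0].mean() / max(a[a > 0].mean(), 1e-12)) if (b > 0).any() else 1.0
            b = a * scale
        data[sp_b] = b
    return data


# ---------------------------------------------------------------------------
# leafhopper community
# ---------------------------------------------------------------------------
def default_guild_table(
    n_species: int,
    plants: SiteSpeciesMatrix,
    seed: int,
    specialist_fraction: float = 0.5,
) -> pd.DataFrame:
    """Random guild/host assignment covering ``n_species`` leafhoppers.

    Specialists get one host genus drawn from the plant genera; generalists
    get none (they feed across genera).
    """
    rng = np.random.default_rng(seed)
    genera = sorted({genus_of(s) for s in plants.species_ids})
    species = [f"Hopper sp{i + 1:03d}" for i in range(n_species)]
    rows = []
    for sp in species:
        if rng.random() < specialist_fraction:
            rows.append(
                {"species_id": sp, "guild": "specialist",
                 "host_genera": genera[rng.integers(0, len(genera))]}
            )
        else:
            rows.append({"species_id": sp, "guild": "generalist",
                         "host_genera": ""})
    return pd.DataFrame(rows).set_index("species_id")


def generate_leafhopper_community(
    env: BlockCollection,
    plants: SiteSpeciesMatrix,
    guilds: pd.DataFrame,
    coupling: float,
    seed: int,
    truth: GroundTruth | None = None,
    niche_breadth: float = 1.0,
    mean_abundance: float = 2.0,
    noise: bool = True,
) -> SiteSpeciesMatrix:
    """Leafhopper counts coupled bottom-up to the plant community.

    Specialist expected abundance is proportional to the summed abundance of
    its host plants; generalists follow a random-weight plant composite.
    Both are mixed with an abiotic Gaussian-niche term weighted
    (1 − ``coupling``).  Counts are Poisson draws around the expectation
    (``noise=True``) or its deterministic ceiling (``noise=False``).
    """
    if not 0 <= coupling <= 1:
        raise InvalidParameterError("coupling must lie in [0, 1]")
    if list(env.site_ids) != list(plants.site_ids):
        raise InvalidParameterError("env and plants must share the site set")
    rng = np.random.default_rng(seed)
    n_sites = plants.n_sites
    P = plants.values
    plant_ids = plants.species_ids
    genus_index: dict[str, list[int]] = {}
    for j, s in enumerate(plant_ids):
        genus_index.setdefault(genus_of(s), []).append(j)

    if truth is not None:
        e = truth.composite_gradient()
    else:
        e = rng.standard_normal(n_sites)
    sigma = niche_breadth * max(e.std(), 1e-12)
    species = list(guilds.index)
    expected = np.zeros((n_sites, len(species)))
    for k, sp in enumerate(species):
        guild = guilds.loc[sp, "guild"]
        if guild == "specialist":
            genera = guilds.loc[sp, "host_genera"]
            if isinstance(genera, str):
                genera = [g for g in genera.split(",") if g]
            cols: list[int] = []
            for g in genera:
                if g not in genus_index:
                    raise UnknownHostError(
                        f"specialist {sp!r}: host genus {g!r} not in the "
                        f"plant species list"
                    )
                cols.extend(genus_index[g])
            biotic = P[:, cols].sum(axis=1)
        else:
            weights = rng.dirichlet(np.ones(len(plant_ids)))
            biotic = P @ weights
        mu = rng.uniform(e.min(), e.max())
        abiotic = np.exp(-((e - mu) ** 2) / (2 * sigma**2))
        b_norm = biotic / biotic.mean() if biotic.mean() > 0 else biotic
        a_norm = abiotic / abiotic.mean() if abiotic.mean() > 0 else abiotic
        intensity = rng.lognormal(np.log(mean_abundance), 0.8)
        expected[:, k] = intensity * (coupling * b_norm + (1 - coupling) * a_norm)
    if noise:
        counts = rng.poisson(expected).astype(float)
    else:
        counts = np.ceil(expected)
    data = pd.DataFrame(counts, index=plants.site_ids, columns=species)
    meta = pd.DataFrame(
        {
            "trophic_group": "leafhopper",
            "guild": guilds["guild"],
            "host_genera": guilds["host_genera"],
        },
        index=species,
    )
    if truth is not None:
        truth.coupling_strength = coupling
    return SiteSpeciesMatrix(data, meta)


# ---------------------------------------------------------------------------
# binary fixture generator
# ---------------------------------------------------------------------------
def generate_binary_cooccurrence(
    n_species: int,
    n_sites: int,
    planted_pairs: list[tuple[int, int, str]] | None = None,
    fill: float = 0.3,
    seed: int = 0,
) -> np.ndarray:
    """Bernoulli background occupancy with exact planted pairs.

    ``planted_pairs`` holds (row_a, row_b, class) with class ``segregated``
    (zero shared sites) or ``aggregated`` (identical occupancy).  Returns a
    binary species × sites array.
    """
    if n_species < 2 or n_sites < 2:
        raise InvalidParameterError("need at least 2 species and 2 sites")
    if not 0 < fill < 1:
        raise InvalidParameterError("fill must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    M = (rng.random((n_species, n_sites)) < fill).astype(np.uint8)
    for a, b, cls in planted_pairs or []:
        if not (0 <= a < n_species and 0 <= b < n_species):
            raise IndexError(f"planted pair ({a}, {b}) out of range")
        if cls == "segregated":
            M[b] = np.where(M[a] == 1, 0, M[b])
            if M[b].sum() == 0 and (M[a] == 0).any():
                M[b, np.argmax(M[a] == 0)] = 1
        elif cls == "aggregated":
            M[b] = M[a]
        else:
            raise InvalidParameterError(f"unknown planted class {cls!r}")
    return M


# ---------------------------------------------------------------------------
# the vineyard emulation profile
# ---------------------------------------------------------------------------
VINEYARD_BLOCKS = (
    ("Man", 5),
    ("Top", 5),
    ("Soil", 9),
    ("Struc", 5),
    ("Land200", 6),
    ("Land500", 6),
)

#: Default per-block effect shares: topography dominates, mirroring a strong
#: topographic gradient; remainder spread over the other blocks.
VINEYARD_SHARES = {
    "Man": 0.08,
    "Top": 0.40,
    "Soil": 0.13,
    "Struc": 0.13,
    "Land200": 0.13,
    "Land500": 0.13,
}


def vineyard_profile(
    seed: int,
    n_sites: int = 68,
    n_plants: int = 120,
    n_hoppers: int = 80,
    coupling: float = 0.7,
    niche_breadth: float = 0.4,
):
    """Generate the full vineyard-scale synthetic study.

    Returns ``(env, plants, hoppers, truth)``: six abiotic blocks of widths
    5/5/9/5/6/6 over ``n_sites`` sites, a percent-cover plant community and
    a count leafhopper community coupled bottom-up with the given strength.
    """
    ss = np.random.SeedSequence(seed)
    s_env, s_plants, s_guild, s_hop = (
        int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(4)
    )
    # One latent gradient per block: thematic axes (management intensity,
    # topographic position, ...) vary independently across sites.  Each
    # variable is a noisy indicator with its own loading, so no single
    # variable exhausts the block's information.
    load_rng = np.random.default_rng(child_seed_local := (seed * 2 + 1) % (2**31 - 1))
    specs = [
        BlockSpec(
            name=name,
            n_vars=w,
            latent_loading=list(load_rng.uniform(0.5, 1.2, size=w)),
            noise_sd=1.0,
            gradient=i,
        )
        for i, (name, w) in enumerate(VINEYARD_BLOCKS)
    ]
    env, truth = generate_env_blocks(
        n_sites, specs, seed=s_env, block_effect_shares=VINEYARD_SHARES
    )
    plants = generate_plant_community(
        env, n_plants, niche_breadth=niche_breadth, truth=truth, seed=s_plants
    )
    guilds = default_guild_table(n_hoppers, plants, seed=s_guild)
    hoppers = generate_leafhopper_community(
        env, plants, guilds, coupling=coupling, seed=s_hop, truth=truth,
        niche_breadth=niche_breadth,
    )
    return env, plants, hoppers, truth
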