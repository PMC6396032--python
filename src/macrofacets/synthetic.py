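"""Synthetic watershed datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes:
spatially autocorrelated environmental gradients (built from low-order
dbMEM eigenvectors of the site layout), species with mixed categorical /
quantitative traits in four life forms, a nested rank taxonomy, and
niche-based presence/absence driven by a composite environmental axis.
Defaults mirror the study system's dimensions: 214 sites and 469 species
(93 submerged, 40 floating-leaved, 25 free-floating, 311 emergent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Dataset, ValidationReport, validate_dataset, warn_once
from .spatial import DbMEM

LIFE_FORM_DEFAULTS = {
    "submerged": 93,
    "floating-leaved": 40,
    "free-floating": 25,
    "emergent": 311,
}
CONTINUOUS_PREDICTORS = [
    "MAP", "MAT", "SOLAR", "RUN", "AREA",
    "ALTVAR", "MATVAR", "MAPVAR", "SOLARVAR",
]
# life-form-specific trait tendencies (probabilities / offsets)
_PERENNIAL_P = {
    "submerged": 0.80, "floating-leaved": 0.70,
    "free-floating": 0.50, "emergent": 0.65,
}
_MORPH_P = {
    "submerged": (0.30, 0.30, 0.20, 0.20),
    "floating-leaved": (0.10, 0.20, 0.40, 0.30),
    "free-floating": (0.25, 0.15, 0.40, 0.20),
    "emergent": (0.02, 0.48, 0.10, 0.40),
}
_MORPH_LEVELS = ("turion", "stem", "rosette", "leafy")
_WEIGHT_MU = {
    "submerged": 1.0, "floating-leaved": 1.5,
    "free-floating": -0.5, "emergent": 2.5,
}
_NICHE_OFFSET = {
    "submerged": -0.3, "floating-leaved": 0.1,
    "free-floating": 0.2, "emergent": 0.1,
}


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study.

    ``spatial_structure`` is the share of each environmental gradient that
    is a dbMEM combination (the rest is independent noise);
    ``pure_env_strength`` is the share of the occupancy probability driven
    by the niche response rather than a flat baseline.  ``niche_breadth``
    is the niche standard deviation on the (standardized) composite
    environmental axis.
    """

    n_sites: int = 214
    n_species: int = 469
    life_form_counts: dict = field(
        default_factory=lambda: dict(LIFE_FORM_DEFAULTS)
    )
    layout: str = "uniform"
    spatial_structure: float = 0.8
    pure_env_strength: float = 1.0
    noise_sd: float = 1.0
    niche_breadth: float = 2.0
    p_max: float = 0.85
    taxonomy_counts: tuple | None = None   # (genera, families, orders,
                                           #  subclasses, classes, phyla)
    axis_weights: dict = field(
        default_factory=lambda: {"MAP": 1.0, "MAT": 0.7, "SOLAR": 0.5}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.life_form_counts.values()) != self.n_species:
            raise ValueError("life-form counts must sum to n_species")
        if not 0 <= self.spatial_structure <= 1:
            raise ValueError("spatial_structure must be in [0, 1]")
        if self.niche_breadth <= 0 or self.noise_sd < 0:
            raise ValueError("strengths must be nonnegative")


@dataclass
class GroundTruth:
    structured_env: pd.DataFrame       # dbMEM part of each gradient, pre-noise
    dbmem_weights: pd.DataFrame        # predictor x dbMEM column weights
    axis_weights: dict                 # composite-axis weights (generative set)
    env_axis: pd.Series                # realized composite axis per site
    optima: pd.Series
    breadths: pd.Series
    expected_dominant: str             # "b" when the environment is spatial


# ------------------------------------------------------------- coordinates

def generate_coordinates(
    n_sites: int,
    layout: str = "uniform",
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Distinct planar site centroids: a grid, uniform scatter, or blobs."""
    if n_sites < 4:
        raise ValueError("need at least 4 sites")
    rng = np.random.default_rng(rng)
    labels = [f"site{i + 1:03d}" for i in range(n_sites)]
    if layout == "grid":
        m = math.ceil(math.sqrt(n_sites))
        xy = np.array([(i % m, i // m) for i in range(n_sites)], dtype=float)
    elif layout == "uniform":
        xy = rng.uniform(0.0, 100.0, size=(n_sites, 2))
    elif layout == "clustered":
        centers = rng.uniform(15.0, 85.0, size=(5, 2))
        which = rng.integers(0, 5, size=n_sites)
        xy = centers[which] + rng.normal(0.0, 8.0, size=(n_sites, 2))
    else:
        raise ValueError(f"unknown layout {layout!r}")
    # nudge any exact duplicates apart (vanishingly rare off-grid)
    while len(np.unique(xy, axis=0)) < n_sites:
        _, idx = np.unique(xy, axis=0, return_index=True)
        dup = np.setdiff1d(np.arange(n_sites), idx)
        xy[dup] += rng.normal(0.0, 1e-3, size=(len(dup), 2))
    return pd.DataFrame(xy, index=labels, columns=["x", "y"])


# ------------------------------------------------------------- environment

def generate_environment(
    coords: pd.DataFrame,
    spatial_structure: float = 0.8,
    noise_sd: float = 1.0,
    rng: np.random.Generator | int | None = None,
    n_dbmem: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spatially autocorrelated environmental gradients on a site layout.

    Each continuous predictor is ``beta_s * (dbMEM combination, geometric
    weight decay, random signs) + (1 - beta_s) * N(0, noise_sd)``, then
    standardized.  LANDVAR is the Shannon index of land-cover proportions
    drawn from a Dirichlet whose concentration varies spatially.

    Returns (environment, structured_part, dbmem_weight_matrix).
    """
    rng = np.random.default_rng(rng)
    basis = DbMEM().fit(coords).basis_
    m = min(n_dbmem, basis.shape[1])
    u = basis.iloc[:, :m].to_numpy()
    u = (u - u.mean(axis=0)) / u.std(axis=0, ddof=1)
    n = len(coords)
    env = {}
    struct_parts = {}
    wrows = {}
    for name in CONTINUOUS_PREDICTORS:
        w = 0.75 ** np.arange(m) * rng.choice([-1.0, 1.0], size=m)
        s = u @ w
        s = (s - s.mean()) / s.std(ddof=1)
        noise = rng.normal(0.0, noise_sd, size=n)
        env[name] = spatial_structure * s + (1.0 - spatial_structure) * noise
        struct_parts[name] = s
        wrows[name] = w
    # land cover: 6 classes, concentration modulated by a structured field
    wl = 0.75 ** np.arange(m) * rng.choice([-1.0, 1.0], size=m)
    g = u @ wl
    g = (g - g.mean()) / g.std(ddof=1)
    conc = 1.0 + 4.0 / (1.0 + np.exp(-g))
    base = rng.dirichlet(np.ones(6))
    landvar = np.empty(n)
    for i in range(n):
        p = rng.dirichlet(conc[i] * 6.0 * base + 0.2)
        p = p[p > 0]
        landvar[i] = -np.sum(p * np.log(p))
    env["LANDVAR"] = landvar
    environment = pd.DataFrame(env, index=coords.index)
    structured = pd.DataFrame(struct_parts, index=coords.index)
    weights = pd.DataFrame(
        wrows, index=[f"dbMEM{i + 1}" for i in range(m)]
    ).T
    return environment, structured, weights


# ----------------------------------------------------------------- species

def _default_taxonomy_counts(n_species: int) -> tuple:
    genera = max(1, n_species // 3)
    families = max(1, genera // 3)
    orders = max(1, families // 3)
    subclasses = max(1, orders // 2)
    classes = max(1, min(subclasses, 4))
    phyla = max(1, min(classes, 2))
    return (genera, families, orders, subclasses, classes, phyla)


def generate_species(
    n_species: int,
    life_form_counts: dict | None = None,
    taxonomy_counts: tuple | None = None,
    niche_breadth: float = 2.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Trait table, nested taxonomy, and niche parameters for one species pool.

    Life forms follow the given counts exactly; the other categorical
    traits and the (log-normal) adult weight depend stochastically on life
    form, as do the niche optima, so traits are ecologically structured.
    The taxonomy is built by random nested grouping with the given counts
    per rank (genera, families, orders, subclasses, classes, phyla).
    """
    rng = np.random.default_rng(rng)
    life_form_counts = life_form_counts or dict(LIFE_FORM_DEFAULTS)
    if sum(life_form_counts.values()) != n_species:
        raise ValueError("life-form counts must sum to n_species")
    counts = taxonomy_counts or _default_taxonomy_counts(n_species)
    if len(counts) != 6:
        raise ValueError("taxonomy_counts must have 6 entries (genus..phylum)")

    labels = [f"sp{i + 1:04d}" for i in range(n_species)]
    forms = np.concatenate(
        [np.repeat(k, v) for k, v in life_form_counts.items()]
    )
    rng.shuffle(forms)
    perennial = np.array(
        [rng.random() < _PERENNIAL_P[f] for f in forms]
    )
    morph = np.array(
        [rng.choice(_MORPH_LEVELS, p=_MORPH_P[f]) for f in forms]
    )
    sexual = rng.choice(["monoecism", "dioecy"], size=n_species, p=[0.8, 0.2])
    weight = np.exp(
        np.array([_WEIGHT_MU[f] for f in forms]) + rng.normal(0, 0.8, n_species)
    )
    traits = pd.DataFrame(
        {
            "life_form": forms,
            "life_cycle": np.where(perennial, "perennial", "annual"),
            "morphology": morph,
            "sexual_propagation": sexual,
            "adult_weight": weight,
        },
        index=labels,
    )

    # nested random grouping: species -> genus -> ... -> phylum
    rank_names = ["genus", "family", "order", "subclass", "class", "phylum"]
    prefixes = ["g", "f", "o", "sc", "c", "p"]
    parent = rng.integers(0, counts[0], size=n_species)
    cols = {rank_names[0]: [f"{prefixes[0]}{j + 1:03d}" for j in parent]}
    for lvl in range(1, 6):
        mapping = rng.integers(0, counts[lvl], size=counts[lvl - 1])
        parent = mapping[parent]
        cols[rank_names[lvl]] = [f"{prefixes[lvl]}{j + 1:03d}" for j in parent]
    taxonomy = pd.DataFrame(cols, index=labels)

    optima = (
        np.array([_NICHE_OFFSET[f] for f in forms])
        + rng.normal(1.0, 1.2, n_species)
    )
    breadths = niche_breadth * np.exp(rng.normal(0.0, 0.2, n_species))
    niche = pd.DataFrame(
        {"optimum": optima, "breadth": breadths}, index=labels
    )
    return traits, taxonomy, niche


# ------------------------------------------------------------- occurrences

def generate_occurrences(
    env_axis: pd.Series,
    niche: pd.DataFrame,
    p_max: float = 0.85,
    pure_env_strength: float = 1.0,
    rng: np.random.Generator | int | None = None,
    retry_cap: int = 10,
) -> pd.DataFrame:
    """Niche-based Bernoulli incidence on a composite environmental axis.

    Occupancy probability is ``p_max`` times a Gaussian niche response
    ``exp(-(e_i - mu_j)^2 / (2 sigma_j^2))``, blended (by
    ``pure_env_strength``) with a flat per-species baseline of the same
    mean occupancy.  Empty sites or species are redrawn up to
    ``retry_cap`` times, then left for validation to drop with a warning.
    """
    rng = np.random.default_rng(rng)
    e = env_axis.to_numpy(dtype=float)
    mu = niche["optimum"].to_numpy()
    sig = niche["breadth"].to_numpy()
    resp = np.exp(-((e[:, None] - mu[None, :]) ** 2) / (2.0 * sig[None, :] ** 2))
    flat = resp.mean(axis=0)
    prob = p_max * (
        pure_env_strength * resp + (1.0 - pure_env_strength) * flat[None, :]
    )
    inc = (rng.random(prob.shape) < prob).astype(int)
    for _ in range(retry_cap):
        empty_r = inc.sum(axis=1) == 0
        empty_c = inc.sum(axis=0) == 0
        if not empty_r.any() and not empty_c.any():
            break
        if empty_r.any():
            inc[empty_r] = (
                rng.random((empty_r.sum(), inc.shape[1])) < prob[empty_r]
            ).astype(int)
        if empty_c.any():
            inc[:, empty_c] = (
                rng.random((inc.shape[0], empty_c.sum())) < prob[:, empty_c]
            ).astype(int)
    else:
        warn_once("retry cap reached; empty sites/species will be dropped")
    return pd.DataFrame(inc, index=env_axis.index, columns=niche.index)


# ------------------------------------------------------------ full dataset

def make_dataset(
    scenario: SyntheticScenario,
) -> tuple[Dataset, GroundTruth, ValidationReport]:
    """Generate and validate a full dataset bundle from a scenario.

    All randomness flows from the scenario seed through four named
    substreams (coordinates, environment, species, occurrence), so each
    stage is independently reproducible.
    """
    ss = np.random.SeedSequence(scenario.seed)
    rng_coord, rng_env, rng_sp, rng_occ = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    coords = generate_coordinates(scenario.n_sites, scenario.layout, rng_coord)
    environment, structured, dbw = generate_environment(
        coords, scenario.spatial_structure, scenario.noise_sd, rng_env
    )
    traits, taxonomy, niche = generate_species(
        scenario.n_species,
        scenario.life_form_counts,
        scenario.taxonomy_counts,
        scenario.niche_breadth,
        rng_sp,
    )
    # composite niche axis from the generative predictors, standardized
    axis = pd.Series(0.0, index=coords.index)
    for name, w in scenario.axis_weights.items():
        col = environment[name]
        axis = axis + w * (col - col.mean()) / col.std(ddof=1)
    axis = (axis - axis.mean()) / axis.std(ddof=1)
    occurrence = generate_occurrences(
        axis,
        niche,
        p_max=scenario.p_max,
        pure_env_strength=scenario.pure_env_strength,
        rng=rng_occ,
    )
    dataset, report = validate_dataset(
        occurrence, traits, taxonomy, environment, coords
    )
    truth = GroundTruth(
        structured_env=structured,
        dbmem_weights=dbw,
        axis_weights=dict(scenario.axis_weights),
        env_axis=axis,
        optima=niche["optimum"],
        breadths=niche["breadth"],
        expected_dominant="b" if scenario.spatial_structure > 0.5 else "a",
    )
    return dataset, truth, report
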