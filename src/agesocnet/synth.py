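"""Synthetic longitudinal grooming-network generator.

Emulates the structure of the Cayo Santiago adult-female grooming data:
six social groups followed over an eight-year window, ~50 adult females
per group-year, ages 6-28 with a median death age of 18, matrilines
averaging ~5 close adult female kin, and edge weights expressed as
grooming seconds per dyad observation hour.

The generative model encodes the system's documented age effects:

* the log-odds of a grooming tie decline with each endpoint's age
  (``partner_slope`` per year), so partner numbers fall
  within-individual as females age;
* the kin (same-matriline) tie bonus grows with age
  (``kin_bias_slope`` per year on the log-odds scale), so ties
  concentrate on kin;
* total grooming time per female is age-invariant, so remaining ties
  strengthen as partner numbers fall.

Every dataset carries a :class:`TruthRecord` of its generating
parameters so downstream estimators can be validated by parameter
recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

KIN_COEFFICIENT = 0.25  # kinship proxy for same-matriline dyads

#: Observed group-years: which of the 8 window years each group contributes.
#: Mirrors the unbalanced empirical design (8 + 2 + 3 + 2 + 1 + 3 = 19).
DEFAULT_DESIGN: tuple[tuple[int, ...], ...] = (
    (0, 1, 2, 3, 4, 5, 6, 7),
    (4, 6),
    (3, 5, 7),
    (5, 6),
    (1,),
    (5, 6, 7),
)


class SynthValidationError(ValueError):
    """Raised for infeasible generator parameters."""


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic grooming-data generator.

    Slopes are per year of age.  ``partner_slope`` acts on the log-odds
    of each dyad through both endpoints' ages; ``kin_bias_slope`` acts on
    the same-matriline bonus through the dyad's mean age.
    ``rank_age_interaction`` adds a rank-specific term to the focal
    endpoint's age slope (0 for low rank by convention).
    """

    n_groups: int = 6
    n_years: int = 8
    group_size: int = 50
    matriline_size_mean: float = 5.2
    age_entry: int = 6
    median_death_age: int = 18
    max_age: int = 30
    age_reference: float = 10.0
    age_pyramid_ratio: float = 0.80  # young-skew of the initial age pyramid
    base_tie_logit: float = -2.3  # non-kin tie log-odds at reference age
    kin_base_logodds: float = 1.45  # same-matriline bonus at reference age
    partner_slope: float = -0.06
    kin_bias_slope: float = 0.19
    rank_age_interaction: Mapping[str, float] = field(
        default_factory=lambda: {"high": 0.0, "medium": 0.0, "low": 0.0}
    )
    rank_main_effect: Mapping[str, float] = field(
        default_factory=lambda: {"high": 0.15, "medium": 0.0, "low": -0.15}
    )
    individual_slope_sd: float = 0.01
    individual_intercept_sd: float = 0.15
    total_groom_seconds_mean: float = 20000.0  # per female-year of observation
    total_groom_seconds_shape: float = 10.0
    obs_hours_per_female: float = 60.0
    dirichlet_concentration: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.age_entry < self.median_death_age < self.max_age):
            raise SynthValidationError(
                "require age_entry < median_death_age < max_age, got "
                f"{self.age_entry}, {self.median_death_age}, {self.max_age}"
            )
        if self.n_years < 1 or self.n_groups < 1 or self.group_size < 2:
            raise SynthValidationError("degenerate cohort dimensions")

    @property
    def annual_death_hazard(self) -> float:
        """Per-year death hazard giving the target median adult lifespan.

        With a geometric lifetime beyond the age of adulthood, the
        median death age is ``age_entry + k`` where ``(1-h)^k = 0.5``.
        """
        k = self.median_death_age - self.age_entry
        return 1.0 - 0.5 ** (1.0 / k)


@dataclass(frozen=True)
class TruthRecord:
    """Generating parameter values logged alongside each dataset."""

    partner_slope: float
    kin_bias_slope: float
    rank_age_interaction: dict
    individual_slopes: dict  # id -> per-individual slope deviation
    proportion_old: dict  # (group, year) -> proportion of >18 y females

    def as_dict(self) -> dict:
        return {
            "partner_slope": self.partner_slope,
            "kin_bias_slope": self.kin_bias_slope,
            "rank_age_interaction": dict(self.rank_age_interaction),
            "individual_slopes": {str(k): v for k, v in self.individual_slopes.items()},
            "proportion_old": {
                f"{g}:{y}": v for (g, y), v in self.proportion_old.items()
            },
        }


def _rank_class(frac_dominated: float) -> str:
    """Map the fraction of others dominated to the field's rank classes."""
    if frac_dominated >= 0.80:
        return "high"
    if frac_dominated >= 0.50:
        return "medium"
    return "low"


def _initial_ages(params: SynthParams, size: int, rng: np.random.Generator) -> np.ndarray:
    """Ages from a young-skewed pyramid: P(age) ~ r^(age - entry).

    ``r`` combines survival with population growth; the default yields
    the empirically observed share (~0.03-0.19) of females older than
    the median death age.
    """
    ages = np.arange(params.age_entry, params.max_age + 1)
    w = params.age_pyramid_ratio ** (ages - params.age_entry)
    return rng.choice(ages, size=size, p=w / w.sum())


def generate_cohort(
    params: SynthParams, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate per-group female rosters over the year window.

    Returns one row per female per year alive, with columns
    ``group, year, id, age, matriline, rank, frac_dominated``.  Groups
    hold constant size: each death is replaced by a newly adult
    (``age_entry``-year-old) recruit joining an existing matriline.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    h = params.annual_death_hazard
    rows = []
    next_id = 0
    for g in range(params.n_groups):
        size = params.group_size
        ages = _initial_ages(params, size, rng).astype(float)
        # matriline partition with mean size ~ matriline_size_mean
        n_matrilines = max(1, round(size / params.matriline_size_mean))
        matriline = rng.integers(0, n_matrilines, size=size)
        latent_rank = rng.random(size)  # higher -> dominates more females
        ids = np.arange(next_id, next_id + size)
        next_id += size
        for year in range(params.n_years):
            order = np.argsort(np.argsort(latent_rank))
            frac_dom = order / (size - 1)
            for k in range(size):
                rows.append(
                    {
                        "group": g,
                        "year": year,
                        "id": int(ids[k]),
                        "age": float(ages[k]),
                        "matriline": int(matriline[k]),
                        "rank": _rank_class(frac_dom[k]),
                        "frac_dominated": float(frac_dom[k]),
                    }
                )
            # advance to next year: age, die, recruit
            ages += 1.0
            dead = (rng.random(size) < h) | (ages > params.max_age)
            n_dead = int(dead.sum())
            if n_dead:
                ages[dead] = params.age_entry
                matriline[dead] = rng.choice(matriline[~dead], size=n_dead)
                latent_rank[dead] = rng.random(n_dead)
                ids[dead] = np.arange(next_id, next_id + n_dead)
                next_id += n_dead
    return pd.DataFrame(rows)


def _tie_logits(
    slice_df: pd.DataFrame,
    params: SynthParams,
    slope_dev: np.ndarray,
    intercept_dev: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dyadic tie log-odds for one group-year roster slice."""
    age = slice_df["age"].to_numpy() - params.age_reference
    rank = slice_df["rank"].to_numpy()
    inter = np.array([params.rank_age_interaction.get(r, 0.0) for r in rank])
    main = np.array([params.rank_main_effect.get(r, 0.0) for r in rank])
    slope_i = params.partner_slope + inter + slope_dev
    node_term = main + intercept_dev + slope_i * age
    n = len(slice_df)
    iu, ju = np.triu_indices(n, k=1)
    logits = params.base_tie_logit + node_term[iu] + node_term[ju]
    mat = slice_df["matriline"].to_numpy()
    kin = mat[iu] == mat[ju]
    mean_age = 0.5 * (age[iu] + age[ju])
    logits = logits + kin * (
        params.kin_base_logodds + params.kin_bias_slope * mean_age
    )
    return iu, ju, logits


def generate_group_year_network(
    slice_df: pd.DataFrame,
    params: SynthParams,
    rng: np.random.Generator,
    slope_dev: np.ndarray | None = None,
    intercept_dev: np.ndarray | None = None,
) -> nx.Graph:
    """Generate one weighted grooming network from a roster slice.

    Ties are Bernoulli draws from the dyadic log-odds model; each
    female's age-invariant total grooming time is split over her
    partners by a symmetric Dirichlet; dyadic seconds are symmetrised
    and divided by the dyad's combined observation hours to give rates.
    """
    if slice_df.empty:
        raise ValueError("empty roster slice")
    slice_df = slice_df.reset_index(drop=True)
    n = len(slice_df)
    if slope_dev is None:
        slope_dev = np.zeros(n)
    if intercept_dev is None:
        intercept_dev = np.zeros(n)
    iu, ju, logits = _tie_logits(slice_df, params, slope_dev, intercept_dev)
    p = 1.0 / (1.0 + np.exp(-logits))
    tied = rng.random(p.shape[0]) < p
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for a, b in zip(iu[tied], ju[tied]):
        neighbors[a].append(int(b))
        neighbors[b].append(int(a))
    totals = rng.gamma(
        params.total_groom_seconds_shape,
        params.total_groom_seconds_mean / params.total_groom_seconds_shape,
        size=n,
    )
    seconds: dict[tuple[int, int], float] = {}
    for i in range(n):
        nb = neighbors[i]
        if not nb:
            continue
        shares = rng.dirichlet(np.full(len(nb), params.dirichlet_concentration))
        for j, s in zip(nb, shares):
            key = (min(i, j), max(i, j))
            seconds[key] = seconds.get(key, 0.0) + totals[i] * s
    g = nx.Graph()
    dyad_hours = 2.0 * params.obs_hours_per_female
    for k in range(n):
        row = slice_df.iloc[k]
        g.add_node(
            int(row["id"]),
            age=float(row["age"]),
            rank=row["rank"],
            matriline=int(row["matriline"]),
            group=int(row["group"]),
            year=int(row["year"]),
        )
    ids = slice_df["id"].to_numpy()
    for (a, b), s in seconds.items():
        if s > 0:
            g.add_edge(int(ids[a]), int(ids[b]), weight=s / dyad_hours)
    g.graph["group"] = int(slice_df["group"].iloc[0])
    g.graph["year"] = int(slice_df["year"].iloc[0])
    g.graph["average_relatedness"] = average_relatedness(slice_df)
    return g


def average_relatedness(slice_df: pd.DataFrame) -> float:
    """Mean kinship proxy over dyads: 0.25 for same-matriline pairs."""
    mat = slice_df["matriline"].to_numpy()
    n = len(mat)
    if n < 2:
        return 0.0
    iu, ju = np.triu_indices(n, k=1)
    return float(KIN_COEFFICIENT * np.mean(mat[iu] == mat[ju]))


def generate_dataset(
    params: SynthParams,
    n_networks: int = 19,
    rng: np.random.Generator | None = None,
    design: tuple[tuple[int, ...], ...] | None = None,
) -> tuple[list[nx.Graph], TruthRecord]:
    """Generate a longitudinal dataset of grooming networks plus its truth.

    Group-years follow the unbalanced observation design (by default the
    empirical 8/2/3/2/1/3 pattern); the first ``n_networks`` group-years
    in design order are emitted.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    design = design or DEFAULT_DESIGN[: params.n_groups]
    capacity = sum(len(y) for y in design)
    if n_networks > capacity:
        raise ValueError(
            f"n_networks={n_networks} exceeds the {capacity} designed group-years"
        )
    roster = generate_cohort(params, rng)
    # one random-effect draw per female, stable across her years
    all_ids = roster["id"].unique()
    slope_dev = dict(
        zip(all_ids, rng.normal(0.0, params.individual_slope_sd, size=len(all_ids)))
    )
    intercept_dev = dict(
        zip(
            all_ids,
            rng.normal(0.0, params.individual_intercept_sd, size=len(all_ids)),
        )
    )
    pairs = [
        (g, y) for g, years in enumerate(design) for y in years
    ][:n_networks]
    networks = []
    prop_old = {}
    for g_id, year in pairs:
        sl = roster[(roster["group"] == g_id) & (roster["year"] == year)]
        sdev = np.array([slope_dev[i] for i in sl["id"]])
        idev = np.array([intercept_dev[i] for i in sl["id"]])
        net = generate_group_year_network(sl, params, rng, sdev, idev)
        networks.append(net)
        prop_old[(g_id, year)] = float(
            (sl["age"] > params.median_death_age).mean()
        )
    truth = TruthRecord(
        partner_slope=params.partner_slope,
        kin_bias_slope=params.kin_bias_slope,
        rank_age_interaction=dict(params.rank_age_interaction),
        individual_slopes=slope_dev,
        proportion_old=prop_old,
    )
    return networks, truth


def sample_death_ages(
    params: SynthParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo draw of adult ages at death under the survival model."""
    h = params.annual_death_hazard
    years = rng.geometric(h, size=n)
    return np.minimum(params.age_entry + years, params.max_age)
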