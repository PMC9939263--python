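"""Kin-structured, age-stratified random-network model.

The model generates undirected unweighted social networks for a group of
``n`` individuals partitioned into kin groups (matriline blocks).  Each
individual is either *old* or *young*; every dyad therefore falls into one
of six types (age-class pair x kinship) and receives an edge independently
with a dyad-type-specific linking probability.  The default probabilities
are the empirical mean proportions of linked dyads of each type in the
Cayo Santiago rhesus macaque grooming networks.

The module exposes the elementary operations (population assignment, dyad
classification, a single network draw), large ensemble simulation, an
analytic expectation for mean degree, the restricted-demographic-range
detectability experiment, and a sensitivity sweep over the probability
table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .metrics import binary_global_metrics

logger = logging.getLogger(__name__)

#: Canonical order of the six dyad types.
DYAD_TYPES = (
    "old_old_kin",
    "old_old_nonkin",
    "old_young_kin",
    "old_young_nonkin",
    "young_young_kin",
    "young_young_nonkin",
)

#: Empirical linking probabilities for the Cayo Santiago system.
DEFAULT_LINKING_PROBS = {
    "old_old_kin": 0.33,
    "old_old_nonkin": 0.02,
    "old_young_kin": 0.37,
    "old_young_nonkin": 0.05,
    "young_young_kin": 0.27,
    "young_young_nonkin": 0.08,
}

GLOBAL_METRIC_NAMES = ("mean_degree", "diameter", "transitivity", "density")


class ConfigurationError(ValueError):
    """Raised when a model configuration violates its invariants."""


@dataclass(frozen=True)
class LinkingProbabilityTable:
    """Edge probability for each of the six dyad types."""

    probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LINKING_PROBS)
    )

    def __post_init__(self) -> None:
        missing = set(DYAD_TYPES) - set(self.probs)
        if missing:
            raise ConfigurationError(
                f"linking-probability table missing dyad types: {sorted(missing)}"
            )
        for name in DYAD_TYPES:
            p = self.probs[name]
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(
                    f"linking probability for {name} is {p}, outside [0, 1]"
                )

    def __getitem__(self, dyad_type: str) -> float:
        return self.probs[dyad_type]

    def as_array(self) -> np.ndarray:
        """Probabilities in canonical :data:`DYAD_TYPES` order."""
        return np.array([self.probs[t] for t in DYAD_TYPES], dtype=float)

    def perturbed(self, factor: float | Sequence[float]) -> "LinkingProbabilityTable":
        """Multiplicatively perturb probabilities, clamping to [0, 1].

        ``factor`` may be a scalar (applied to all six entries) or a
        sequence of six per-type factors in canonical order.
        """
        factors = np.broadcast_to(np.asarray(factor, dtype=float), (6,))
        new = self.as_array() * factors
        if (new < 0).any() or (new > 1).any():
            logger.warning(
                "perturbation pushed probabilities outside [0, 1]; clamping"
            )
            new = np.clip(new, 0.0, 1.0)
        return LinkingProbabilityTable(dict(zip(DYAD_TYPES, new.tolist())))


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the network generator.

    Defaults mirror the study system: 50 adult females, 10 matriline
    blocks of 5, the empirical linking-probability table, and the number
    of old individuals drawn uniformly on the integers 0..50.
    """

    n_individuals: int = 50
    n_kin_groups: int = 10
    kin_group_size: int = 5
    linking_probs: LinkingProbabilityTable = field(
        default_factory=LinkingProbabilityTable
    )
    n_old_range: tuple[int, int] = (0, 50)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_kin_groups * self.kin_group_size != self.n_individuals:
            raise ConfigurationError(
                f"{self.n_kin_groups} kin groups of {self.kin_group_size} "
                f"do not partition {self.n_individuals} individuals"
            )
        lo, hi = self.n_old_range
        if not (0 <= lo <= hi <= self.n_individuals):
            raise ConfigurationError(
                f"n_old_range {self.n_old_range} must satisfy "
                f"0 <= lo <= hi <= {self.n_individuals}"
            )


class Individual(NamedTuple):
    id: int
    age_class: str  # "old" | "young"
    kin_group: int


@dataclass(frozen=True)
class Population:
    """Age-class and kin-group assignment for one simulated group."""

    is_old: np.ndarray  # bool, shape (n,)
    kin_group: np.ndarray  # int, shape (n,)

    @property
    def n(self) -> int:
        return self.is_old.shape[0]

    @property
    def n_old(self) -> int:
        return int(self.is_old.sum())

    def individual(self, i: int) -> Individual:
        return Individual(
            id=i,
            age_class="old" if self.is_old[i] else "young",
            kin_group=int(self.kin_group[i]),
        )

    def dyad_type_codes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-dyad type codes over the upper triangle.

        Returns ``(rows, cols, codes)`` where codes index
        :data:`DYAD_TYPES`.
        """
        iu, ju = np.triu_indices(self.n, k=1)
        n_old_ends = self.is_old[iu].astype(int) + self.is_old[ju].astype(int)
        kin = self.kin_group[iu] == self.kin_group[ju]
        # age-pair block: 0 -> old/old, 1 -> old/young, 2 -> young/young
        age_block = 2 - n_old_ends
        codes = age_block * 2 + (~kin).astype(int)
        return iu, ju, codes


def assign_population(
    config: SimConfig, n_old: int, rng: np.random.Generator
) -> Population:
    """Randomly assign age classes and kin groups to the group members.

    ``n_old`` individuals are marked old via a uniform random permutation
    of age labels; kin-group labels are an independent uniform random
    partition into ``n_kin_groups`` blocks of ``kin_group_size``.
    """
    n = config.n_individuals
    if not (0 <= n_old <= n):
        raise ValueError(f"n_old={n_old} out of range [0, {n}]")
    is_old = np.zeros(n, dtype=bool)
    is_old[rng.permutation(n)[:n_old]] = True
    kin = np.repeat(np.arange(config.n_kin_groups), config.kin_group_size)
    kin_group = kin[rng.permutation(n)]
    return Population(is_old=is_old, kin_group=kin_group)


def classify_dyad(a: Individual, b: Individual) -> str:
    """Classify a dyad by its endpoints' age classes and kinship."""
    if a.id == b.id:
        raise ValueError(f"self-dyad: individual {a.id} paired with itself")
    ages = sorted((a.age_class, b.age_class))  # ["old", "young"] ordering
    kin = "kin" if a.kin_group == b.kin_group else "nonkin"
    if ages == ["old", "old"]:
        block = "old_old"
    elif ages == ["old", "young"]:
        block = "old_young"
    else:
        block = "young_young"
    return f"{block}_{kin}"


@dataclass(frozen=True)
class BinaryNetwork:
    """One simulated network: edge list plus population attributes."""

    population: Population
    edges: np.ndarray  # int, shape (m, 2), i < j
    provenance: dict

    @property
    def n(self) -> int:
        return self.population.n

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for i in range(self.n):
            ind = self.population.individual(i)
            g.add_node(i, age_class=ind.age_class, kin_group=ind.kin_group)
        g.add_edges_from(map(tuple, self.edges.tolist()))
        return g

    def to_igraph(self):
        import igraph

        g = igraph.Graph(n=self.n, edges=self.edges.tolist())
        g.vs["age_class"] = [
            "old" if o else "young" for o in self.population.is_old
        ]
        g.vs["kin_group"] = self.population.kin_group.tolist()
        return g


def draw_network(
    pop: Population,
    probs: LinkingProbabilityTable,
    rng: np.random.Generator,
    provenance: dict | None = None,
) -> BinaryNetwork:
    """Draw one network: each dyad gets an edge with its type's probability."""
    iu, ju, codes = pop.dyad_type_codes()
    p = probs.as_array()[codes]
    linked = rng.random(p.shape[0]) < p
    edges = np.column_stack([iu[linked], ju[linked]])
    prov = dict(provenance or {})
    prov.setdefault("n_old", pop.n_old)
    return BinaryNetwork(population=pop, edges=edges, provenance=prov)


@dataclass(frozen=True)
class EnsembleResult:
    """Replicate-level table plus the generating configuration.

    ``replicates`` has one row per simulated network with columns
    ``rep, n_old, proportion_old``, the four global metrics (when
    computed) and the six per-type realized linking proportions
    (``lp_<dyad type>``; NaN when a replicate contains no dyads of a
    type).
    """

    config: SimConfig
    replicates: pd.DataFrame

    @property
    def n_reps(self) -> int:
        return len(self.replicates)

    def mean_linking_proportions(self) -> pd.Series:
        """Across-replicate mean realized linking proportion per dyad type.

        Replicates with no dyads of a type do not contribute to that
        type's mean.
        """
        cols = [f"lp_{t}" for t in DYAD_TYPES]
        out = self.replicates[cols].mean(skipna=True)
        out.index = list(DYAD_TYPES)
        return out

    def binned(self, n_bins: int = 20) -> pd.DataFrame:
        """Global-metric summaries over equal-width proportion-old bins."""
        df = self.replicates
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        idx = np.clip(np.digitize(df["proportion_old"], edges) - 1, 0, n_bins - 1)
        rows = []
        for b in range(n_bins):
            sub = df[idx == b]
            if sub.empty:
                continue
            row = {
                "bin": b,
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "bin_mid": 0.5 * (edges[b] + edges[b + 1]),
                "n": len(sub),
            }
            for m in GLOBAL_METRIC_NAMES:
                if m in sub:
                    row[f"{m}_mean"] = sub[m].mean()
                    row[f"{m}_iqr"] = sub[m].quantile(0.75) - sub[m].quantile(0.25)
            rows.append(row)
        return pd.DataFrame(rows)


def _realized_linking(
    codes: np.ndarray, linked: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    totals = np.bincount(codes, minlength=6).astype(float)
    hits = np.bincount(codes, weights=linked.astype(float), minlength=6)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(totals > 0, hits / np.maximum(totals, 1), np.nan)
    props[totals == 0] = np.nan
    return props, totals


def simulate_ensemble(
    config: SimConfig,
    n_reps: int,
    rng: np.random.Generator | None = None,
    compute_metrics: bool = True,
    n_old_values: Sequence[int] | None = None,
) -> EnsembleResult:
    """Simulate an ensemble of networks.

    For each replicate the number of old individuals is drawn uniformly
    from the integers of ``config.n_old_range`` (or cycled from
    ``n_old_values`` when given), the population is assigned, and a
    network is drawn.  Per-replicate realized linking proportions are
    always recorded; global metrics are recorded unless
    ``compute_metrics`` is False.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.n_old_range
    p = config.linking_probs.as_array()
    rows = []
    for rep in range(n_reps):
        if n_old_values is not None:
            n_old = int(n_old_values[rep % len(n_old_values)])
        else:
            n_old = int(rng.integers(lo, hi + 1))
        pop = assign_population(config, n_old, rng)
        iu, ju, codes = pop.dyad_type_codes()
        linked = rng.random(codes.shape[0]) < p[codes]
        props, _ = _realized_linking(codes, linked)
        row = {
            "rep": rep,
            "n_old": n_old,
            "proportion_old": n_old / config.n_individuals,
            "n_edges": int(linked.sum()),
        }
        row.update({f"lp_{t}": props[k] for k, t in enumerate(DYAD_TYPES)})
        if compute_metrics:
            edges = np.column_stack([iu[linked], ju[linked]])
            row.update(binary_global_metrics(config.n_individuals, edges))
        rows.append(row)
    return EnsembleResult(config=config, replicates=pd.DataFrame(rows))


def expected_mean_degree(n_old: int, config: SimConfig | None = None) -> float:
    """Analytic expected mean degree given the number of old individuals.

    Age labels are assigned by sampling without replacement, so for any
    dyad P(both old) = n_old (n_old - 1) / (n (n - 1)), etc.; kin and
    non-kin dyad counts are fixed by the kin-group design.  The expected
    mean degree is ``(2 / n) * sum_over_types E[#dyads of type] * p(type)``.
    """
    config = config or SimConfig()
    n = config.n_individuals
    if not (0 <= n_old <= n):
        raise ValueError(f"n_old={n_old} out of range [0, {n}]")
    n_kin = config.n_kin_groups * math.comb(config.kin_group_size, 2)
    n_nonkin = math.comb(n, 2) - n_kin
    denom = n * (n - 1)
    p_oo = n_old * (n_old - 1) / denom
    p_yy = (n - n_old) * (n - n_old - 1) / denom
    p_oy = 2 * n_old * (n - n_old) / denom
    p = config.linking_probs
    exp_edges = n_kin * (
        p_oo * p["old_old_kin"]
        + p_oy * p["old_young_kin"]
        + p_yy * p["young_young_kin"]
    ) + n_nonkin * (
        p_oo * p["old_old_nonkin"]
        + p_oy * p["old_young_nonkin"]
        + p_yy * p["young_young_nonkin"]
    )
    return 2.0 * exp_edges / n


def admissible_n_old(
    n: int, prop_old_bounds: tuple[float, float]
) -> np.ndarray:
    """Integer n_old values whose proportion lies within the bounds."""
    lo, hi = prop_old_bounds
    if not (0.0 <= lo <= hi <= 1.0):
        raise ConfigurationError(f"bounds {prop_old_bounds} outside [0, 1]")
    values = np.arange(math.ceil(lo * n), math.floor(hi * n) + 1)
    if values.size == 0:
        raise ConfigurationError(
            f"bounds {prop_old_bounds} admit no integer n_old at n={n}"
        )
    return values


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Slope of y on x by ordinary least squares."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    denom = (xc**2).sum()
    if denom == 0:
        return float("nan")
    return float((xc * y).sum() / denom)


def restricted_range_experiment(
    config: SimConfig,
    n_networks: int = 19,
    prop_old_bounds: tuple[float, float] = (0.04, 0.20),
    n_bouts: int = 50,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detectability experiment with the demographic range restricted.

    Each *bout* simulates ``n_networks`` networks with the number of old
    individuals drawn uniformly from the integers admissible under
    ``prop_old_bounds``, then fits an OLS trend of each global metric on
    proportion old.  Returns ``(slopes, networks)``: one slope row per
    bout, and the underlying per-network metric table.
    """
    if n_networks < 1 or n_bouts < 1:
        raise ValueError("n_networks and n_bouts must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    values = admissible_n_old(config.n_individuals, prop_old_bounds)
    slope_rows = []
    net_frames = []
    for bout in range(n_bouts):
        n_old_draws = rng.choice(values, size=n_networks, replace=True)
        res = simulate_ensemble(
            config, n_networks, rng=rng, n_old_values=n_old_draws
        )
        df = res.replicates.assign(bout=bout)
        net_frames.append(df)
        row = {"bout": bout}
        for m in GLOBAL_METRIC_NAMES:
            row[f"slope_{m}"] = _ols_slope(df["proportion_old"], df[m])
        slope_rows.append(row)
    return pd.DataFrame(slope_rows), pd.concat(net_frames, ignore_index=True)


def default_sensitivity_grid() -> list[tuple[str, np.ndarray]]:
    """Multiplicative perturbations of the linking-probability table.

    {-20%, -10%, +10%, +20%} applied jointly to all six probabilities and
    singly to each probability, plus the identity cell.
    """
    grid: list[tuple[str, np.ndarray]] = [("baseline", np.ones(6))]
    for f in (0.8, 0.9, 1.1, 1.2):
        grid.append((f"all_x{f:.1f}", np.full(6, f)))
        for k, t in enumerate(DYAD_TYPES):
            fac = np.ones(6)
            fac[k] = f
            grid.append((f"{t}_x{f:.1f}", fac))
    return grid


def sensitivity_sweep(
    config: SimConfig,
    perturbation_grid: Iterable[tuple[str, np.ndarray]] | None = None,
    n_reps_per_cell: int = 2000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Re-run the ensemble under perturbed probability tables.

    For each grid cell, fits a linear + quadratic trend of each global
    metric on proportion old and reports the coefficient signs, giving
    the qualitative shape of the demographic effect per cell.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    grid = list(perturbation_grid or default_sensitivity_grid())
    rows = []
    for label, factors in grid:
        table = config.linking_probs.perturbed(factors)
        cell_cfg = replace(config, linking_probs=table)
        res = simulate_ensemble(cell_cfg, n_reps_per_cell, rng=rng)
        df = res.replicates
        x = df["proportion_old"].to_numpy()
        row: dict = {"label": label, "n_reps": n_reps_per_cell}
        for m in GLOBAL_METRIC_NAMES:
            coefs = np.polyfit(x, df[m].to_numpy(), deg=2)  # [quad, lin, const]
            row[f"{m}_mean"] = df[m].mean()
            row[f"{m}_linear_sign"] = int(np.sign(coefs[1]))
            row[f"{m}_quadratic_sign"] = int(np.sign(coefs[0]))
        rows.append(row)
    return pd.DataFrame(rows)
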