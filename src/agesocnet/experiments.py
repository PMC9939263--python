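"""End-to-end computational experiments.

Each experiment wraps lower-level operations, stamps its outputs with a
manifest (experiment name, configuration hash, master seed, package
version) and returns plot-ready tables:

* :func:`run_verify` — the linking-probability verification run;
* :func:`run_fullrange` — demographic gradient over the full
  proportion-old range, with binned curve data;
* :func:`run_restricted` — the restricted-demographic-range
  detectability experiment, including per-bout global-structure fits;
* :func:`run_sensitivity` — the linking-probability sensitivity sweep;
* :func:`run_synthetic_pipeline` — synthetic data -> metrics ->
  trajectory models, with recovery diagnostics against the generating
  truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, abm, metrics, synth, trajectory

logger = logging.getLogger(__name__)

GLOBAL_RESPONSES = ("mean_degree", "diameter", "transitivity")


@dataclass(frozen=True)
class ExperimentManifest:
    experiment: str
    config_hash: str
    master_seed: int
    version: str = __version__

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / f"manifest_{self.experiment}.json"
        path.write_text(json.dumps(asdict(self), indent=2))
        return path


def _manifest(experiment: str, config: object, seed: int) -> ExperimentManifest:
    blob = json.dumps(repr(config), sort_keys=True).encode()
    return ExperimentManifest(
        experiment=experiment,
        config_hash=hashlib.sha256(blob).hexdigest()[:16],
        master_seed=seed,
    )


def run_verify(
    n_reps: int = 10_000,
    seed: int = 0,
    config: abm.SimConfig | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Verification run: realized vs input linking probability per dyad type."""
    config = config or abm.SimConfig()
    rng = np.random.default_rng(seed)
    res = abm.simulate_ensemble(config, n_reps, rng=rng, compute_metrics=False)
    realized = res.mean_linking_proportions()
    table = pd.DataFrame(
        {
            "dyad_type": list(abm.DYAD_TYPES),
            "input_probability": config.linking_probs.as_array(),
            "realized_mean": realized.to_numpy(),
        }
    )
    table["abs_deviation"] = (
        table["realized_mean"] - table["input_probability"]
    ).abs()
    if out_dir is not None:
        _manifest("verify", config, seed).write(out_dir)
        table.to_csv(Path(out_dir) / "verify_linking.csv", index=False)
    return table


def run_fullrange(
    n_reps: int = 20_000,
    seed: int = 0,
    n_bins: int = 20,
    config: abm.SimConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Demographic gradient over the full proportion-old range.

    Returns ``(replicates, binned)``: the per-network metric table and
    equal-width proportion-old bin summaries of the curve shapes.
    """
    config = config or abm.SimConfig()
    rng = np.random.default_rng(seed)
    res = abm.simulate_ensemble(config, n_reps, rng=rng, compute_metrics=True)
    binned = res.binned(n_bins)
    if out_dir is not None:
        _manifest("fullrange", config, seed).write(out_dir)
        res.replicates.to_csv(Path(out_dir) / "fullrange_replicates.csv", index=False)
        binned.to_csv(Path(out_dir) / "fullrange_binned.csv", index=False)
    return res.replicates, binned


def run_restricted(
    n_bouts: int = 50,
    n_networks: int = 19,
    seed: int = 0,
    prop_old_bounds: tuple[float, float] = (0.04, 0.20),
    config: abm.SimConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restricted-range detectability experiment.

    Returns ``(slopes, fits)``: per-bout OLS slopes of each global
    metric on proportion old, and per-bout global-structure model
    coefficients (estimate and 95% interval for proportion old).
    """
    config = config or abm.SimConfig()
    rng = np.random.default_rng(seed)
    slopes, networks = abm.restricted_range_experiment(
        config,
        n_networks=n_networks,
        prop_old_bounds=prop_old_bounds,
        n_bouts=n_bouts,
        rng=rng,
    )
    fit_rows = []
    for bout, sub in networks.groupby("bout"):
        for resp in GLOBAL_RESPONSES:
            try:
                fit = trajectory.fit_global_structure(sub, resp)
                est, lo, hi = fit.coef("proportion_old")
            except trajectory.EstimationError:
                est = lo = hi = float("nan")
            fit_rows.append(
                {
                    "bout": bout,
                    "response": resp,
                    "proportion_old_estimate": est,
                    "ci_low": lo,
                    "ci_high": hi,
                    "ci_overlaps_zero": bool(lo <= 0.0 <= hi),
                }
            )
    fits = pd.DataFrame(fit_rows)
    if out_dir is not None:
        _manifest("restricted", config, seed).write(out_dir)
        slopes.to_csv(Path(out_dir) / "restricted_slopes.csv", index=False)
        fits.to_csv(Path(out_dir) / "restricted_fits.csv", index=False)
    return slopes, fits


def run_sensitivity(
    n_reps_per_cell: int = 2000,
    seed: int = 0,
    config: abm.SimConfig | None = None,
    grid=None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Sensitivity of the demographic-gradient shape to the probability table."""
    config = config or abm.SimConfig()
    rng = np.random.default_rng(seed)
    table = abm.sensitivity_sweep(
        config, perturbation_grid=grid, n_reps_per_cell=n_reps_per_cell, rng=rng
    )
    if out_dir is not None:
        _manifest("sensitivity", config, seed).write(out_dir)
        table.to_csv(Path(out_dir) / "sensitivity.csv", index=False)
    return table


def network_observation_table(
    networks, old_threshold: float = 18.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure a list of grooming networks.

    Returns ``(node_rows, global_rows)``: one row per female per
    network (node metrics + attributes) and one row per network
    (global metrics + proportion old + average relatedness).
    """
    node_frames = []
    global_rows = []
    for net in networks:
        nm = metrics.node_metrics(net)
        attrs = pd.DataFrame(
            [{"node": v, **d} for v, d in net.nodes(data=True)]
        )
        nm = nm.merge(attrs, on="node").rename(columns={"node": "id"})
        node_frames.append(nm)
        gm = metrics.global_metrics(net, old_threshold=old_threshold)
        global_rows.append(
            {
                **gm.as_dict(),
                "group": net.graph.get("group"),
                "year": net.graph.get("year"),
                "average_relatedness": net.graph.get("average_relatedness"),
            }
        )
    return (
        pd.concat(node_frames, ignore_index=True),
        pd.DataFrame(global_rows),
    )


def run_synthetic_pipeline(
    params: synth.SynthParams | None = None,
    n_networks: int = 19,
    seed: int = 0,
    min_age: float = 10.0,
    responses: tuple[str, ...] = ("closeness",),
    fit_global: bool = True,
    out_dir: str | Path | None = None,
) -> dict:
    """Synthetic data -> metrics -> trajectory models, with truth diagnostics.

    Returns a dict with the measured tables, per-response
    :class:`~agesocnet.trajectory.TrajectoryEstimate` objects, optional
    global-structure fits, and the generating :class:`TruthRecord`.
    """
    params = params or synth.SynthParams()
    rng = np.random.default_rng(seed)
    networks, truth = synth.generate_dataset(params, n_networks=n_networks, rng=rng)
    node_rows, global_rows = network_observation_table(
        networks, old_threshold=params.median_death_age
    )
    estimates = {}
    for resp in responses:
        estimates[resp] = trajectory.fit_trajectory(
            node_rows, resp, min_age=min_age
        )
    global_fits = {}
    if fit_global:
        for resp in GLOBAL_RESPONSES:
            try:
                global_fits[resp] = trajectory.fit_global_structure(
                    global_rows, resp
                )
            except trajectory.EstimationError as err:
                logger.warning("global fit for %s failed: %s", resp, err)
    result = {
        "node_rows": node_rows,
        "global_rows": global_rows,
        "estimates": estimates,
        "global_fits": global_fits,
        "truth": truth,
    }
    if out_dir is not None:
        out = Path(out_dir)
        _manifest("synthetic_pipeline", params, seed).write(out)
        node_rows.to_csv(out / "node_metrics.csv", index=False)
        global_rows.to_csv(out / "global_metrics.csv", index=False)
        (out / "truth.json").write_text(json.dumps(truth.as_dict(), indent=2))
        coef_frames = []
        for resp, est in estimates.items():
            coef_frames.append(est.coefficients.assign(response=resp))
        if coef_frames:
            pd.concat(coef_frames, ignore_index=True).to_csv(
                out / "trajectory_coefficients.csv", index=False
            )
    return result
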