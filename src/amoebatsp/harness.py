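"""Seeded trials and Monte-Carlo experiments.

A *trial* runs the coupled controller/amoeba dynamics on one map from the
empty lattice until either (a) the binarized illumination pattern has been
unchanged for ``stability_window`` consecutive iterations *and* the lattice
decodes to a feasible tour — success — or (b) an iteration cap is hit —
failure.  The search time of a successful trial is counted from the first
iteration any lane lit up to the first iteration the lattice first
represented the finally accepted tour, mirroring how wall-clock search
times are scored in the laboratory setup (one iteration = one 6 s control
update there).

An *experiment* sweeps problem sizes, running a fixed number of seeded,
mutually independent trials per n (one shared map per n by default) and
persists per-trial rows as CSV plus a JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .amoeba_core import AmoebaParams, LatticeState, decode_configuration, init_state, step
from .bounceback import BouncebackController, ControlParams, compute_nu_star, derive_control_params
from .instances import (
    BRUTE_FORCE_CAP,
    TSPInstance,
    Tour,
    generate_experiment_instance,
    generate_simulation_instance,
    tour_length,
    write_instance,
)

__all__ = [
    "TrialResult",
    "ExperimentConfig",
    "ConfigurationError",
    "run_trial",
    "run_experiment",
    "trial_seed",
    "instance_seed",
    "SECONDS_PER_ITERATION",
]

#: Display-only conversion between iterations and the experimental control
#: period; never used in any logic.
SECONDS_PER_ITERATION = 6.0


class ConfigurationError(ValueError):
    """A trial or experiment configuration is unusable (e.g. nu >= nu*)."""


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one seeded trial."""

    succeeded: bool
    n: int
    seed: int
    noise_level: float
    total_iters: int
    tour: tuple[str, ...] | None = None
    tour_len: float | None = None
    search_iters: int | None = None
    first_illumination_iter: int | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tour"] = None if self.tour is None else "-".join(self.tour)
        return d


def trial_seed(master_seed: int, n: int, trial_index: int) -> np.random.SeedSequence:
    """Independent per-trial randomness derived from (experiment seed, n, trial)."""
    return np.random.SeedSequence([int(master_seed), int(n), int(trial_index)])


def instance_seed(master_seed: int, n: int) -> int:
    """Deterministic per-n map seed (kept below 2**31)."""
    return int(np.random.SeedSequence([int(master_seed), int(n)]).generate_state(1)[0] % (2**31))


def run_trial(
    instance: TSPInstance,
    seed: int | np.random.SeedSequence,
    control_params: ControlParams | None = None,
    amoeba_params: AmoebaParams | None = None,
    max_iters: int | None = None,
    stability_window: int = 30,
    controller: BouncebackController | None = None,
    return_state: bool = False,
):
    """Run one seeded trial to success or the iteration cap.

    ``controller`` may be passed to reuse a prebuilt weight matrix across
    trials on the same map.  With ``return_state`` the final
    :class:`~amoebatsp.amoeba_core.LatticeState` is returned alongside the
    result (for absorbing-state checks).  Deterministic given
    (instance, seed, params).
    """
    params = amoeba_params or AmoebaParams()
    if controller is None:
        cp = control_params or derive_control_params(instance)
        controller = BouncebackController(instance, cp)
    cp = controller.params
    nu_star = cp.nu_star if cp.nu_star is not None else compute_nu_star(instance, cp.theta)
    if not cp.nu < nu_star:
        raise ConfigurationError(
            f"nu={cp.nu} must be strictly below nu*={nu_star} for this map"
        )
    if stability_window < 1:
        raise ConfigurationError("stability_window must be >= 1")
    if max_iters is None:
        max_iters = 20_000 * instance.n
    rng = np.random.default_rng(seed)
    seed_repr = seed if isinstance(seed, int) else int(seed.generate_state(1)[0] % (2**31))

    state = init_state(instance.n)
    thr = params.solution_threshold
    prev_lit: np.ndarray | None = None
    streak = 0
    prev_elong: np.ndarray | None = None
    current_tour: tuple[str, ...] | None = None
    first_seen: dict[tuple[str, ...], int] = {}

    while state.iteration < max_iters:
        state, pattern = step(state, controller, params, rng)
        lit = pattern.L.ravel() > 0.5
        if prev_lit is not None and np.array_equal(lit, prev_lit):
            streak += 1
        else:
            streak = 0
        prev_lit = lit

        elong = state.X.ravel() >= thr
        if prev_elong is None or not np.array_equal(elong, prev_elong):
            decoded = decode_configuration(state.X, thr, labels=instance.labels)
            current_tour = decoded.order if isinstance(decoded, Tour) else None
            if current_tour is not None and current_tour not in first_seen:
                first_seen[current_tour] = state.iteration
            prev_elong = elong

        if streak >= stability_window and current_tour is not None:
            first_rep = first_seen[current_tour]
            first_ill = state.first_illumination_iter
            result = TrialResult(
                succeeded=True,
                n=instance.n,
                seed=seed_repr,
                noise_level=params.noise_level,
                total_iters=state.iteration,
                tour=current_tour,
                tour_len=tour_length(instance, current_tour),
                search_iters=first_rep - (first_ill or 0),
                first_illumination_iter=first_ill,
            )
            return (result, state) if return_state else result

    result = TrialResult(
        succeeded=False,
        n=instance.n,
        seed=seed_repr,
        noise_level=params.noise_level,
        total_iters=state.iteration,
        first_illumination_iter=state.first_illumination_iter,
    )
    return (result, state) if return_state else result


@dataclass
class ExperimentConfig:
    """Everything a Monte-Carlo sweep depends on; results are a pure
    function of this object.

    ``instance_policy='fixed'`` uses one map per n (all trials share it, as
    in a one-map-per-size study design); ``'per_trial'`` draws a fresh map
    for every trial.  ``max_iters_factor`` caps each trial at
    factor * n iterations.
    """

    n_list: tuple[int, ...] = (4, 5, 6, 7, 8)
    trials_per_n: int = 500
    master_seed: int = 0
    instance_mode: str = "experiment"  # or "simulation"
    instance_policy: str = "fixed"  # or "per_trial"
    max_iters_factor: int = 20_000
    stability_window: int = 30
    delta_in: float = 0.001
    delta_out: float = 0.001
    noise_level: float = 0.0
    solution_threshold: float = 0.6
    allocation: str = "single_random_lane"
    nu_ratio: float = 0.988
    adjacency: str = "cyclic"
    output_dir: str | Path | None = None
    resume: bool = False

    def __post_init__(self) -> None:
        self.n_list = tuple(int(n) for n in self.n_list)
        if self.trials_per_n < 1:
            raise ConfigurationError("trials_per_n must be >= 1")
        if self.stability_window < 1:
            raise ConfigurationError("stability_window must be >= 1")
        if self.instance_mode not in ("experiment", "simulation"):
            raise ConfigurationError(f"unknown instance_mode {self.instance_mode!r}")
        if self.instance_policy not in ("fixed", "per_trial"):
            raise ConfigurationError(f"unknown instance_policy {self.instance_policy!r}")
        if self.instance_mode == "experiment" and max(self.n_list) > BRUTE_FORCE_CAP:
            raise ConfigurationError(
                f"experiment-mode maps need n <= {BRUTE_FORCE_CAP}; use simulation mode"
            )

    def amoeba_params(self) -> AmoebaParams:
        return AmoebaParams(
            delta_in=self.delta_in,
            delta_out=self.delta_out,
            noise_level=self.noise_level,
            solution_threshold=self.solution_threshold,
            allocation=self.allocation,
        )

    def make_instance(self, n: int, seed: int) -> TSPInstance:
        if self.instance_mode == "experiment":
            return generate_experiment_instance(n, seed)
        return generate_simulation_instance(n, seed)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_experiment(
    config: ExperimentConfig,
    progress: bool = False,
) -> tuple[list[TrialResult], dict[int, TSPInstance]]:
    """Run the full sweep; returns all trial rows and the per-(n, trial) maps.

    The instances dict is keyed by n under the fixed-map policy.  When
    ``config.output_dir`` is set, writes ``results.csv`` (one row per
    trial, failures included), ``summary.json`` and the maps as TSPLIB
    files; with ``resume=True`` previously completed (n, trial) rows found
    in ``results.csv`` are kept and skipped.
    """
    out = Path(config.output_dir) if config.output_dir is not None else None
    done: dict[tuple[int, int], dict] = {}
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        csv_path = out / "results.csv"
        if config.resume and csv_path.exists():
            for row in pd.read_csv(csv_path).to_dict("records"):
                done[(int(row["n"]), int(row["trial"]))] = row

    rows: list[dict] = []
    results: list[TrialResult] = []
    instances: dict[int, TSPInstance] = {}
    amoeba = config.amoeba_params()
    for n in config.n_list:
        fixed_instance = None
        controller = None
        if config.instance_policy == "fixed":
            fixed_instance = config.make_instance(n, instance_seed(config.master_seed, n))
            instances[n] = fixed_instance
            controller = BouncebackController(
                fixed_instance,
                derive_control_params(fixed_instance, config.nu_ratio, config.adjacency),
            )
        for trial_idx in range(config.trials_per_n):
            key = (n, trial_idx)
            if key in done:
                row = done[key]
                rows.append(row)
                results.append(_row_to_result(row))
                continue
            if config.instance_policy == "per_trial":
                inst = config.make_instance(
                    n, instance_seed(config.master_seed, n) + trial_idx
                )
                ctl = BouncebackController(
                    inst, derive_control_params(inst, config.nu_ratio, config.adjacency)
                )
            else:
                inst, ctl = fixed_instance, controller
            res = run_trial(
                inst,
                seed=trial_seed(config.master_seed, n, trial_idx),
                amoeba_params=amoeba,
                max_iters=config.max_iters_factor * n,
                stability_window=config.stability_window,
                controller=ctl,
            )
            results.append(res)
            row = res.to_dict()
            row["trial"] = trial_idx
            rows.append(row)
            if progress:
                status = f"len={res.tour_len:.1f}" if res.succeeded else "failed"
                print(f"n={n} trial={trial_idx}: {res.total_iters} iters, {status}")
        if out is not None and config.instance_policy == "fixed":
            write_instance(fixed_instance, out / f"instance_n{n}.tsp")

    if out is not None:
        df = pd.DataFrame(rows)
        df.to_csv(out / "results.csv", index=False)
        from .analysis import fit_scaling, summarize_trials

        summaries = []
        for n in config.n_list:
            trials_n = [r for r in results if r.n == n]
            summaries.append(summarize_trials(trials_n, instances.get(n)))
        payload = {"config": _config_dict(config), "per_n": [s.to_dict() for s in summaries]}
        try:
            fit = fit_scaling(summaries)
            payload["scaling_fit"] = dataclasses.asdict(fit)
        except ValueError:
            pass
        (out / "summary.json").write_text(json.dumps(payload, indent=2))
    return results, instances


def _config_dict(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    d["n_list"] = list(config.n_list)
    d["output_dir"] = None if config.output_dir is None else str(config.output_dir)
    return d


def _row_to_result(row: dict) -> TrialResult:
    def opt(key, cast):
        v = row.get(key)
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else cast(v)

    tour = row.get("tour")
    tour = None if tour is None or (isinstance(tour, float) and np.isnan(tour)) else tuple(str(tour).split("-"))
    return TrialResult(
        succeeded=bool(row["succeeded"]),
        n=int(row["n"]),
        seed=int(row["seed"]),
        noise_level=float(row["noise_level"]),
        total_iters=int(row["total_iters"]),
        tour=tour,
        tour_len=opt("tour_len", float),
        search_iters=opt("search_iters", int),
        first_illumination_iter=opt("first_illumination_iter", int),
    )
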