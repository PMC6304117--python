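"""AmoebaTSP branch dynamics: constant-rate inflow, extinction outflow.

The virtual plasmodium is an n x n lattice of branch occupancies
X_Vk in [0, 1].  Each iteration the controller observes the state (with
optional uniform white noise on the observation only), illuminates lanes,
and then resources move:

* outflow — every illuminated lane loses delta_out, clamped at 0; the
  withdrawn resource is destroyed, never redistributed;
* inflow — a constant amount delta_in per iteration goes to the
  non-illuminated lanes (by default all of it to one uniformly chosen
  lane), clamped at 1 with any excess destroyed.  If every lane is
  illuminated, that iteration's inflow is extinguished too.

The constant total inflow rate is what caps the speed at which a tour
configuration (total occupancy ~ n) can be assembled, giving the
n / delta_in lower bound on iteration counts that underlies the model's
linear search-time scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bounceback import BouncebackController, IlluminationPattern
from .instances import Tour

__all__ = [
    "LatticeState",
    "AmoebaParams",
    "InfeasibleReport",
    "init_state",
    "perturb_observation",
    "allocate_inflow",
    "apply_outflow",
    "step",
    "decode_configuration",
]


@dataclass
class LatticeState:
    """Branch occupancies X_Vk (rows: cities, columns: visiting orders).

    Carries a resource ledger: ``total_influx`` is the resource actually
    deposited by inflow, ``total_destroyed`` the resource removed by
    outflow, so ``X.sum() == total_influx - total_destroyed`` (from an
    empty start) at all times, to float tolerance.
    """

    X: np.ndarray
    iteration: int = 0
    first_illumination_iter: int | None = None
    total_influx: float = 0.0
    total_destroyed: float = 0.0

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def copy(self) -> "LatticeState":
        return LatticeState(
            X=self.X.copy(),
            iteration=self.iteration,
            first_illumination_iter=self.first_illumination_iter,
            total_influx=self.total_influx,
            total_destroyed=self.total_destroyed,
        )


@dataclass(frozen=True)
class AmoebaParams:
    """Rates and thresholds of the branch dynamics.

    delta_in / delta_out are per-iteration resource rates (default 0.001
    each); ``noise_level`` is the half-width d of the uniform observation
    noise; ``solution_threshold`` is the occupancy above which a branch
    counts as "sufficiently elongated" when decoding; ``allocation``
    selects how the constant inflow is spread over non-illuminated lanes.
    """

    delta_in: float = 0.001
    delta_out: float = 0.001
    noise_level: float = 0.0
    solution_threshold: float = 0.6
    allocation: str = "single_random_lane"

    def __post_init__(self) -> None:
        if self.delta_in <= 0 or self.delta_out <= 0:
            raise ValueError("delta_in and delta_out must be positive")
        if self.noise_level < 0:
            raise ValueError("noise level d must be non-negative")
        if not 0 < self.solution_threshold <= 1:
            raise ValueError("solution_threshold must lie in (0, 1]")
        if self.allocation not in ("single_random_lane", "random_weights"):
            raise ValueError(f"unknown allocation scheme {self.allocation!r}")


@dataclass(frozen=True)
class InfeasibleReport:
    """Why an elongation pattern fails to encode a tour."""

    reasons: tuple[str, ...]
    elongated: tuple[tuple[int, int], ...]  # (city, order) pairs

    @property
    def feasible(self) -> bool:
        return False


def init_state(n: int) -> LatticeState:
    """Empty lattice: all branches at X = 0 (the experiment's start condition)."""
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    return LatticeState(X=np.zeros((n, n)))


def perturb_observation(state: LatticeState, d: float, rng: np.random.Generator) -> np.ndarray:
    """The controller's noisy view X + xi, xi ~ U[-d, d] i.i.d. per lane.

    Fresh draws on every call (white noise, no temporal or spatial
    correlation).  The returned array is NOT clamped to [0, 1] — the
    controller's inner sigmoid absorbs out-of-range values — and the
    stored state is never modified.
    """
    if d < 0:
        raise ValueError("noise level d must be non-negative")
    if d == 0:
        return state.X.copy()
    return state.X + rng.uniform(-d, d, size=state.X.shape)


def allocate_inflow(
    state: LatticeState,
    illuminated: np.ndarray,
    params: AmoebaParams,
    rng: np.random.Generator,
) -> LatticeState:
    """Deposit the iteration's constant inflow into non-illuminated lanes.

    ``single_random_lane``: the whole delta_in goes to one lane chosen
    uniformly among non-illuminated lanes.  ``random_weights``: delta_in is
    split over all non-illuminated lanes proportionally to i.i.d. uniform
    weights.  Occupancy is clamped at 1 with the excess destroyed; if every
    lane is illuminated the inflow is extinguished entirely.
    """
    x = state.X.ravel()
    dark = np.flatnonzero(~np.asarray(illuminated).reshape(-1))
    if dark.size == 0:
        return state
    if params.allocation == "single_random_lane":
        lane = dark[rng.integers(dark.size)]
        new = min(1.0, x[lane] + params.delta_in)
        state.total_influx += new - x[lane]
        x[lane] = new
    else:
        w = rng.uniform(size=dark.size)
        total = w.sum()
        if total == 0.0:
            w[:] = 1.0
            total = float(dark.size)
        add = params.delta_in * w / total
        new = np.minimum(1.0, x[dark] + add)
        state.total_influx += float((new - x[dark]).sum())
        x[dark] = new
    return state


def apply_outflow(
    state: LatticeState, illuminated: np.ndarray, params: AmoebaParams
) -> LatticeState:
    """Shrink every illuminated lane by delta_out; the resource is destroyed."""
    x = state.X.ravel()
    lit = np.asarray(illuminated).reshape(-1)
    if lit.any():
        removed = np.minimum(params.delta_out, x[lit])
        state.total_destroyed += float(removed.sum())
        x[lit] -= removed
    return state


def step(
    state: LatticeState,
    controller: BouncebackController,
    params: AmoebaParams,
    rng: np.random.Generator,
) -> tuple[LatticeState, IlluminationPattern]:
    """One full iteration: observe -> illuminate -> outflow -> inflow.

    The controller always sees the *previous* iteration's completed state
    (plus observation noise); all lanes update synchronously.  Mutates and
    returns ``state``; ``state.first_illumination_iter`` is set to the
    1-based iteration count at which any lane first lit up.
    """
    x = state.X.ravel()
    if params.noise_level > 0:
        obs = x + rng.uniform(-params.noise_level, params.noise_level, size=x.size)
    else:
        obs = x
    L = controller.illumination_flat(obs)
    lit = L > 0.5
    state.iteration += 1
    if state.first_illumination_iter is None and lit.any():
        state.first_illumination_iter = state.iteration
    apply_outflow(state, lit, params)
    allocate_inflow(state, lit, params, rng)
    return state, IlluminationPattern(L=L.reshape(state.n, state.n))


def decode_configuration(
    state: LatticeState | np.ndarray,
    solution_threshold: float = 0.6,
    labels: tuple[str, ...] | None = None,
) -> Tour | InfeasibleReport:
    """Read the tour off the lattice, or report why there is none.

    Lanes with X >= threshold count as elongated; the pattern is feasible
    iff the elongated lanes form a permutation (exactly one per city and
    one per visiting order).  The tour lists cities by visiting order.
    Infeasibility is a value, not an error.
    """
    X = np.asarray(getattr(state, "X", state), dtype=float)
    n = X.shape[0]
    elong = X >= solution_threshold
    per_city = elong.sum(axis=1)
    per_order = elong.sum(axis=0)
    if labels is None:
        from .instances import default_labels

        labels = default_labels(n)
    if np.all(per_city == 1) and np.all(per_order == 1):
        cities_by_order = elong.argmax(axis=0)
        return Tour(tuple(labels[v] for v in cities_by_order))
    reasons = []
    for v in np.flatnonzero(per_city == 0):
        reasons.append(f"city {labels[v]} unvisited")
    for v in np.flatnonzero(per_city > 1):
        orders = ", ".join(str(k + 1) for k in np.flatnonzero(elong[v]))
        reasons.append(f"city {labels[v]} visited {int(per_city[v])} times (orders {orders})")
    for k in np.flatnonzero(per_order == 0):
        reasons.append(f"order {k + 1} unassigned")
    for k in np.flatnonzero(per_order > 1):
        cities = ", ".join(labels[v] for v in np.flatnonzero(elong[:, k]))
        reasons.append(f"order {k + 1} assigned to multiple cities ({cities})")
    pairs = tuple(zip(*np.nonzero(elong)))
    return InfeasibleReport(reasons=tuple(reasons), elongated=tuple((int(v), int(k)) for v, k in pairs))
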