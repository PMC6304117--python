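"""Optical bounceback control: inhibitory feedback that encodes TSP constraints.

The controller watches the n x n lattice of branch occupancies X_Vk (city V
visited k-th) and decides which lanes to illuminate.  The update is a
single synchronous pass of a Hopfield-Tank-style recurrent rule:

    L_Vk = 1 - sigma_{1000,-0.5}( sum_{Ul} W_{Vk,Ul} * sigma_{35,0.6}(X_Ul) )

with a purely inhibitory weight matrix W: -lambda between two orders of the
same city (no revisiting), -mu between two cities at the same order (no
simultaneous visits), -nu*dist(V,U) between adjacent visiting orders of
different cities (distance minimisation), else 0.  The inner sigmoid makes
the control sensitive only to substantially grown branches; the steep outer
sigmoid acts as a step at threshold theta = -0.5, so a lane is illuminated
exactly when its weighted conflict input falls below theta.

The distance coupling nu must stay below a critical value
nu* = -theta / max_{V,V',V''} (dist(V,V') + dist(V',V'')), otherwise some
lanes of a legitimate tour would themselves be illuminated.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .instances import TSPInstance

__all__ = [
    "ControlParams",
    "WeightMatrix",
    "IlluminationPattern",
    "BoundaryProximityWarning",
    "BouncebackController",
    "sigmoid",
    "build_weight_matrix",
    "compute_nu_star",
    "compute_nu_star_bruteforce",
    "derive_control_params",
    "update_illumination",
    "is_illuminated",
]

BOUNDARY_TOL = 1e-3


class BoundaryProximityWarning(RuntimeWarning):
    """A lane's conflict input sits within ~1e-3 of the step threshold.

    With lambda = 0.5 the degenerate "two conflicting lanes fully grown"
    configuration lands exactly on the threshold; the resulting
    illumination is decided by the ~1e-7 slack of the inner sigmoid, which
    is worth flagging.
    """


@dataclass(frozen=True)
class ControlParams:
    """Parameters of the bounceback rule.

    lambda_/mu weight the revisit and simultaneity constraints; nu couples
    in the distances and is derived per map as ``nu_ratio * nu_star``.
    ``adjacency`` selects whether visiting orders wrap around (order n is
    adjacent to order 1, closing the tour) or not.
    """

    nu: float
    lambda_: float = 0.5
    mu: float = 0.5
    theta: float = -0.5
    inner_gain: float = 35.0
    inner_thresh: float = 0.6
    outer_gain: float = 1000.0
    outer_thresh: float = -0.5
    nu_star: float | None = None
    nu_ratio: float | None = None
    adjacency: str = "cyclic"

    def __post_init__(self) -> None:
        if self.lambda_ < 0 or self.mu < 0:
            raise ValueError("lambda_ and mu must be non-negative")
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if self.adjacency not in ("cyclic", "literal"):
            raise ValueError(f"adjacency must be 'cyclic' or 'literal', got {self.adjacency!r}")
        if self.theta != self.outer_thresh:
            raise ValueError("theta is the outer step threshold; they must agree")
        if self.nu_star is not None and not self.nu < self.nu_star:
            raise ValueError(
                f"nu={self.nu} must be strictly below nu*={self.nu_star}"
            )


@dataclass(frozen=True)
class WeightMatrix:
    """Inhibitory lane-pair couplings, flattened to (n^2, n^2).

    Lane Vk maps to flat index V*n + k (city-major).  Symmetric,
    non-positive, zero diagonal.
    """

    n: int
    W: np.ndarray

    def lane(self, city: int, order: int) -> int:
        return city * self.n + order

    def entry(self, lane_a: tuple[int, int], lane_b: tuple[int, int]) -> float:
        return float(self.W[self.lane(*lane_a), self.lane(*lane_b)])


@dataclass(frozen=True)
class IlluminationPattern:
    """Per-lane light stimuli L_Vk in [0, 1]; rows are cities, columns orders."""

    L: np.ndarray

    @property
    def binary(self) -> np.ndarray:
        """White/black view: a lane is illuminated iff L > 0.5."""
        return self.L > 0.5

    def lane(self, city: int, order: int) -> float:
        return float(self.L[city, order])


def sigmoid(x, gamma: float, theta: float):
    """Logistic sigmoid 1 / (1 + exp(-gamma*(x - theta))), overflow-safe."""
    return expit(gamma * (np.asarray(x, dtype=float) - theta))


def build_weight_matrix(instance: TSPInstance, params: ControlParams) -> WeightMatrix:
    """Assemble the n^2 x n^2 inhibitory coupling matrix for a map."""
    n = instance.n
    N = n * n
    idx = np.arange(N)
    V = idx // n
    k = idx % n
    same_city = V[:, None] == V[None, :]
    same_order = k[:, None] == k[None, :]
    dk = np.abs(k[:, None] - k[None, :])
    if params.adjacency == "cyclic":
        adjacent = (dk == 1) | (dk == n - 1)
    else:
        adjacent = dk == 1
    W = np.zeros((N, N))
    W[same_city & ~same_order] = -params.lambda_
    W[~same_city & same_order] = -params.mu
    mask = ~same_city & ~same_order & adjacent
    W[mask] = -params.nu * instance.dist[V[:, None], V[None, :]][mask]
    return WeightMatrix(n=n, W=W)


def compute_nu_star(instance: TSPInstance, theta: float = -0.5) -> float:
    """Critical distance coupling nu* = -theta / max two-leg path length.

    The maximum runs over ordered triples of distinct cities; it equals,
    for some middle city, the sum of its two largest distances to other
    cities — which is how it is computed here.
    """
    if instance.n < 3:
        raise ValueError("nu* needs at least 3 cities")
    if theta >= 0:
        raise ValueError("theta must be negative")
    best = 0.0
    for mid in range(instance.n):
        row = np.delete(instance.dist[mid], mid)
        two = np.partition(row, -2)[-2:]
        best = max(best, float(two.sum()))
    return -theta / best


def compute_nu_star_bruteforce(instance: TSPInstance, theta: float = -0.5) -> float:
    """Reference nu* by explicit loop over all ordered triples (test oracle)."""
    if instance.n < 3:
        raise ValueError("nu* needs at least 3 cities")
    best = max(
        instance.dist[v, m] + instance.dist[m, u]
        for v, m, u in itertools.permutations(range(instance.n), 3)
    )
    return -theta / best


def derive_control_params(
    instance: TSPInstance,
    nu_ratio: float = 0.988,
    adjacency: str = "cyclic",
) -> ControlParams:
    """Automatic per-map parameters: nu set just below its critical value.

    nu should be as large as possible (to amplify distance differences) but
    strictly below nu*; the default ratio 0.988 leaves a ~1% safety margin.
    """
    if not 0 < nu_ratio < 1:
        raise ValueError(
            f"nu_ratio must lie strictly inside (0, 1); {nu_ratio} would "
            "violate nu < nu*"
        )
    ns = compute_nu_star(instance)
    return ControlParams(
        nu=nu_ratio * ns, nu_star=ns, nu_ratio=nu_ratio, adjacency=adjacency
    )


def is_illuminated(L_value) -> bool | np.ndarray:
    """A lane counts as illuminated only above 0.5 (strict)."""
    arr = np.asarray(L_value)
    out = arr > 0.5
    return bool(out) if arr.ndim == 0 else out


class BouncebackController:
    """A weight matrix bound to one map, with a fast synchronous update."""

    def __init__(self, instance: TSPInstance, params: ControlParams):
        self.instance = instance
        self.params = params
        self.weights = build_weight_matrix(instance, params)
        self.n = instance.n
        self._warn_boundary = True

    def conflict_input(self, x_flat: np.ndarray) -> np.ndarray:
        """Weighted conflict sum u_Vk = sum_Ul W_{Vk,Ul} * inner_sigmoid(X_Ul)."""
        p = self.params
        s = expit(p.inner_gain * (x_flat - p.inner_thresh))
        return self.weights.W @ s

    def illumination_flat(self, x_flat: np.ndarray) -> np.ndarray:
        p = self.params
        u = self.conflict_input(x_flat)
        if self._warn_boundary and np.any(np.abs(u - p.theta) < BOUNDARY_TOL):
            warnings.warn(
                "conflict input within 1e-3 of the illumination threshold; "
                "the binarized pattern is numerically fragile here",
                BoundaryProximityWarning,
                stacklevel=3,
            )
        return 1.0 - expit(p.outer_gain * (u - p.outer_thresh))


def update_illumination(
    X, W: WeightMatrix | BouncebackController, params: ControlParams | None = None
) -> IlluminationPattern:
    """One synchronous bounceback update; never mutates the observed state.

    ``X`` may be a LatticeState, an n x n array, or a flat vector; values
    outside [0, 1] (noise-perturbed observations) are legal, the inner
    sigmoid absorbs them.
    """
    if isinstance(W, BouncebackController):
        ctl = W
    else:
        if params is None:
            raise ValueError("params required when passing a bare WeightMatrix")
        ctl = BouncebackController.__new__(BouncebackController)
        ctl.instance = None
        ctl.params = params
        ctl.weights = W
        ctl.n = W.n
        ctl._warn_boundary = True
    x = np.asarray(getattr(X, "X", X), dtype=float).reshape(-1)
    L = ctl.illumination_flat(x)
    return IlluminationPattern(L=L.reshape(ctl.n, ctl.n))
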