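"""TSP instances with a controlled tour-length distribution.

This module generates, analyses and serialises the "unrestricted" TSP maps
the simulator runs on: symmetric positive distance matrices that need not
satisfy the triangle inequality.  Two generators are provided:

* ``generate_experiment_instance`` — small maps (n up to the brute-force
  cap) whose tour-length distribution is shaped by rejection sampling to
  have a unique shortest tour of length 100, a unique longest tour of
  length 200, a mean near 150 and a unimodal histogram.
* ``generate_simulation_instance`` — larger maps whose inter-city
  distances are i.i.d. with mean 100, so that the mean feasible tour
  length is 100·n without enumeration.

Exhaustive tour enumeration (one canonical representative per
rotation/reflection class, (n-1)!/2 tours in total) backs the exact
distribution statistics used both by the generator and by the analysis
layer's quality percentiles.
"""

from __future__ import annotations

import itertools
import json
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BRUTE_FORCE_CAP",
    "TSPInstance",
    "Tour",
    "TourDistributionSummary",
    "ExperimentMapConfig",
    "SimulationMapConfig",
    "InvalidTourError",
    "EnumerationCapError",
    "NormalizationError",
    "GenerationError",
    "InstanceParseError",
    "default_labels",
    "tour_length",
    "enumerate_tours",
    "enumerate_tour_lengths",
    "tour_distribution_stats",
    "affine_normalize",
    "generate_experiment_instance",
    "generate_simulation_instance",
    "percentile_rank",
    "write_instance",
    "read_instance",
]

#: Largest n for which exhaustive enumeration is allowed by default
#: ((10-1)!/2 = 181 440 tours — seconds on one CPU).
BRUTE_FORCE_CAP = 10


class InvalidTourError(ValueError):
    """A tour is not a permutation of the instance's cities."""


class EnumerationCapError(ValueError):
    """Exhaustive enumeration requested above the brute-force cap."""


class NormalizationError(ValueError):
    """The affine rescaling produced non-positive distances or is degenerate."""


class GenerationError(RuntimeError):
    """The rejection-sampling budget was exhausted."""


class InstanceParseError(ValueError):
    """A serialized instance file is malformed."""


def default_labels(n: int) -> tuple[str, ...]:
    """City labels A, B, C, ... (then AA, AB, ... beyond 26)."""
    labels = []
    for i in range(n):
        s = ""
        j = i
        while True:
            s = chr(ord("A") + j % 26) + s
            j = j // 26 - 1
            if j < 0:
                break
        labels.append(s)
    return tuple(labels)


@dataclass(frozen=True)
class Tour:
    """A closed tour given as a visiting order (implicit return to start).

    The canonical form of a tour starts at the lexicographically smallest
    city and runs in the direction whose second city is smaller, so each of
    the (n-1)!/2 distinct closed tours has exactly one canonical form.
    """

    order: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise InvalidTourError(f"repeated city in tour {self.order}")
        if len(self.order) < 3:
            raise InvalidTourError("a tour needs at least 3 cities")

    @property
    def n(self) -> int:
        return len(self.order)

    def canonical(self) -> "Tour":
        order = self.order
        i = order.index(min(order))
        rot = order[i:] + order[:i]
        if rot[-1] < rot[1]:
            rot = (rot[0],) + tuple(reversed(rot[1:]))
        return Tour(rot)

    @property
    def is_canonical(self) -> bool:
        return self.order == self.canonical().order


@dataclass
class TSPInstance:
    """A symmetric, positive, zero-diagonal distance matrix over n cities.

    ``mode`` records how the instance came to be: ``experiment`` for
    shaped small maps, ``simulation`` for i.i.d.-distance maps,
    ``external`` for files read from disk or hand-built matrices.
    ``gen_meta`` carries generator provenance (seed, affine coefficients,
    rejection count).
    """

    n: int
    labels: tuple[str, ...]
    dist: np.ndarray
    mode: str = "external"
    gen_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dist = np.asarray(self.dist, dtype=float)
        if self.n < 3:
            raise ValueError(f"need at least 3 cities, got n={self.n}")
        if self.dist.shape != (self.n, self.n):
            raise ValueError(f"distance matrix shape {self.dist.shape} != ({self.n}, {self.n})")
        if len(self.labels) != self.n or len(set(self.labels)) != self.n:
            raise ValueError("labels must be n distinct identifiers")
        if not np.allclose(self.dist, self.dist.T, rtol=1e-9, atol=1e-9):
            i, j = np.unravel_index(np.argmax(np.abs(self.dist - self.dist.T)), self.dist.shape)
            raise ValueError(
                f"asymmetric distances: dist({self.labels[i]},{self.labels[j]})="
                f"{self.dist[i, j]} != {self.dist[j, i]}"
            )
        if np.any(np.diag(self.dist) != 0):
            raise ValueError("diagonal must be zero")
        off = self.dist[~np.eye(self.n, dtype=bool)]
        if np.any(off <= 0):
            raise ValueError("all inter-city distances must be strictly positive")
        if self.mode not in ("experiment", "simulation", "external"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise InvalidTourError(f"unknown city label {label!r}") from None

    def dist_between(self, v: str, u: str) -> float:
        return float(self.dist[self.index(v), self.index(u)])

    def off_diagonal(self) -> np.ndarray:
        """The n(n-1)/2 upper-triangle distances."""
        iu = np.triu_indices(self.n, k=1)
        return self.dist[iu]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TSPInstance):
            return NotImplemented
        return (
            self.n == other.n
            and self.labels == other.labels
            and np.array_equal(self.dist, other.dist)
        )


@dataclass
class TourDistributionSummary:
    """Exact statistics of the full (n-1)!/2 tour-length distribution."""

    count: int
    min_len: float
    max_len: float
    mean_len: float
    min_unique: bool
    max_unique: bool
    histogram: tuple[np.ndarray, np.ndarray]  # (counts, bin_edges)
    all_lengths: np.ndarray | None = None


def tour_length(instance: TSPInstance, tour: Tour | Sequence[str]) -> float:
    """Length of a closed tour, including the edge back to the start."""
    order = tour.order if isinstance(tour, Tour) else tuple(tour)
    if len(order) != instance.n or len(set(order)) != len(order):
        raise InvalidTourError(
            f"tour {order} is not a permutation of the {instance.n} cities"
        )
    idx = np.array([instance.index(lab) for lab in order])
    return float(instance.dist[idx, np.roll(idx, -1)].sum())


def _canonical_perm_indices(n: int) -> np.ndarray:
    """Index matrix of all canonical tours over cities 0..n-1 (sorted labels).

    Row r is a permutation starting at 0 with row[1] < row[-1]; there are
    exactly (n-1)!/2 rows.
    """
    rest = list(range(1, n))
    perms = np.array(list(itertools.permutations(rest)), dtype=np.int64)
    perms = perms[perms[:, 0] < perms[:, -1]]
    first = np.zeros((perms.shape[0], 1), dtype=np.int64)
    return np.hstack([first, perms])


def enumerate_tour_lengths(instance: TSPInstance, cap: int = BRUTE_FORCE_CAP) -> np.ndarray:
    """Lengths of all (n-1)!/2 canonical tours, as a flat array.

    Order matches :func:`enumerate_tours`.  Refuses above ``cap`` to avoid
    an accidental factorial blow-up.
    """
    n = instance.n
    if n > cap:
        raise EnumerationCapError(
            f"n={n} exceeds the brute-force cap {cap}: (n-1)!/2 = "
            f"{math.factorial(n - 1) // 2} tours; raise cap explicitly if you mean it"
        )
    order = np.argsort(np.array(instance.labels))
    perms = order[_canonical_perm_indices(n)]
    nxt = np.roll(perms, -1, axis=1)
    return instance.dist[perms, nxt].sum(axis=1)


def enumerate_tours(
    instance: TSPInstance, cap: int = BRUTE_FORCE_CAP
) -> list[tuple[Tour, float]]:
    """All distinct closed tours (canonical form) with their lengths."""
    n = instance.n
    if n > cap:
        raise EnumerationCapError(
            f"n={n} exceeds the brute-force cap {cap}: (n-1)!/2 = "
            f"{math.factorial(n - 1) // 2} tours; raise cap explicitly if you mean it"
        )
    labels = np.array(instance.labels)
    order = np.argsort(labels)
    perms = order[_canonical_perm_indices(n)]
    nxt = np.roll(perms, -1, axis=1)
    lengths = instance.dist[perms, nxt].sum(axis=1)
    return [
        (Tour(tuple(labels[row])), float(length)) for row, length in zip(perms, lengths)
    ]


def _unimodal_bin_count(n_tours: int, max_bins: int = 10) -> int:
    # With very few tours a 10-bin histogram is all gaps; scale bins with
    # the sample size so the unimodality check stays meaningful at small n.
    return max(1, min(max_bins, int(round(math.sqrt(n_tours)))))


def is_unimodal(counts: Iterable[int]) -> bool:
    """True if the count sequence has a single local maximum (plateaus merged)."""
    merged: list[int] = []
    for c in counts:
        if not merged or merged[-1] != c:
            merged.append(int(c))
    rising = True
    for prev, cur in zip(merged, merged[1:]):
        if cur > prev:
            if not rising:
                return False
        else:
            rising = False
    return True


def tour_distribution_stats(
    instance: TSPInstance,
    cap: int = BRUTE_FORCE_CAP,
    keep_lengths: bool = True,
    uniqueness_rtol: float = 1e-9,
) -> TourDistributionSummary:
    """Exhaustive min/max/mean and histogram of the tour-length distribution."""
    lengths = enumerate_tour_lengths(instance, cap=cap)
    lo, hi = float(lengths.min()), float(lengths.max())
    nbins = _unimodal_bin_count(lengths.size)
    counts, edges = np.histogram(lengths, bins=nbins)
    return TourDistributionSummary(
        count=int(lengths.size),
        min_len=lo,
        max_len=hi,
        mean_len=float(lengths.mean()),
        min_unique=int(np.isclose(lengths, lo, rtol=uniqueness_rtol, atol=1e-12).sum()) == 1,
        max_unique=int(np.isclose(lengths, hi, rtol=uniqueness_rtol, atol=1e-12).sum()) == 1,
        histogram=(counts, edges),
        all_lengths=lengths if keep_lengths else None,
    )


def affine_normalize(
    instance: TSPInstance,
    target_min: float = 100.0,
    target_max: float = 200.0,
    cap: int = BRUTE_FORCE_CAP,
) -> TSPInstance:
    """Rescale distances d' = a·d + b so the extreme tour lengths hit targets.

    Every tour length is a sum of n distances, so the transform maps a tour
    of length L to a·L + n·b; (a, b) solve the 2x2 system pinning the
    enumerated minimum and maximum to ``target_min`` and ``target_max``.
    """
    stats = tour_distribution_stats(instance, cap=cap, keep_lengths=False)
    if not stats.max_len > stats.min_len:
        raise NormalizationError("degenerate instance: all tours have equal length")
    a = (target_max - target_min) / (stats.max_len - stats.min_len)
    b = (target_min - a * stats.min_len) / instance.n
    new_dist = a * instance.dist + b
    np.fill_diagonal(new_dist, 0.0)
    off = new_dist[~np.eye(instance.n, dtype=bool)]
    if np.any(off <= 0):
        bad = int(np.argmax(off <= 0))
        raise NormalizationError(
            f"affine rescaling (a={a:.6g}, b={b:.6g}) produced a non-positive "
            f"distance ({off[bad]:.6g}); reject and resample"
        )
    meta = dict(instance.gen_meta)
    meta["affine"] = {"a": float(a), "b": float(b)}
    return TSPInstance(
        n=instance.n, labels=instance.labels, dist=new_dist,
        mode=instance.mode, gen_meta=meta,
    )


@dataclass
class ExperimentMapConfig:
    """Rejection-sampling recipe for the small shaped maps.

    Raw distances are uniform on [raw_low, raw_high]; the affine rescale
    pins the extreme tour lengths to (target_min, target_max); a candidate
    is accepted when both extremes are unique, the mean tour length lies
    within ``mean_tol`` of ``mean_target`` and the tour-length histogram is
    unimodal.
    """

    raw_low: float = 50.0
    raw_high: float = 150.0
    target_min: float = 100.0
    target_max: float = 200.0
    mean_target: float = 150.0
    mean_tol: float = 2.0
    max_attempts: int = 10_000
    cap: int = BRUTE_FORCE_CAP


@dataclass
class SimulationMapConfig:
    """I.i.d.-distance recipe for larger maps (mean feasible length 100·n)."""

    mean: float = 100.0
    sd: float = 20.0
    floor: float = 10.0
    mean_tol: float = 2.0
    max_attempts: int = 10_000


def _symmetric_from_upper(n: int, upper: np.ndarray) -> np.ndarray:
    dist = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    dist[iu] = upper
    return dist + dist.T


def generate_experiment_instance(
    n: int, seed: int, config: ExperimentMapConfig | None = None
) -> TSPInstance:
    """A shaped small map: unique extreme tours at (100, 200), mean ≈ 150.

    Deterministic given (n, seed, config).  Raises :class:`GenerationError`
    when the rejection budget runs out.
    """
    cfg = config or ExperimentMapConfig()
    if not 4 <= n <= cfg.cap:
        raise ValueError(f"experiment maps need 4 <= n <= {cfg.cap}, got {n}")
    rng = np.random.default_rng(seed)
    m = n * (n - 1) // 2
    labels = default_labels(n)
    perm_idx = None
    for attempt in range(cfg.max_attempts):
        upper = rng.uniform(cfg.raw_low, cfg.raw_high, size=m)
        dist = _symmetric_from_upper(n, upper)
        if perm_idx is None:
            perm_idx = _canonical_perm_indices(n)
        nxt = np.roll(perm_idx, -1, axis=1)
        lengths = dist[perm_idx, nxt].sum(axis=1)
        lo, hi = lengths.min(), lengths.max()
        if not hi > lo:
            continue
        a = (cfg.target_max - cfg.target_min) / (hi - lo)
        b = (cfg.target_min - a * lo) / n
        new_dist = a * dist + b
        np.fill_diagonal(new_dist, 0.0)
        if np.any(new_dist[~np.eye(n, dtype=bool)] <= 0):
            continue
        new_lengths = a * lengths + n * b
        if abs(new_lengths.mean() - cfg.mean_target) > cfg.mean_tol:
            continue
        if np.isclose(new_lengths, cfg.target_min, rtol=1e-9, atol=1e-12).sum() != 1:
            continue
        if np.isclose(new_lengths, cfg.target_max, rtol=1e-9, atol=1e-12).sum() != 1:
            continue
        counts, _ = np.histogram(new_lengths, bins=_unimodal_bin_count(new_lengths.size))
        if not is_unimodal(counts):
            continue
        return TSPInstance(
            n=n, labels=labels, dist=new_dist, mode="experiment",
            gen_meta={
                "seed": int(seed),
                "affine": {"a": float(a), "b": float(b)},
                "rejections": attempt,
            },
        )
    raise GenerationError(
        f"no acceptable {n}-city map in {cfg.max_attempts} attempts (seed={seed})"
    )


def generate_simulation_instance(
    n: int, seed: int, config: SimulationMapConfig | None = None
) -> TSPInstance:
    """A larger map with i.i.d. distances, mean 100, truncated below.

    The edge-occurrence symmetry of closed tours makes the mean feasible
    tour length exactly n x (mean off-diagonal distance), so holding the
    sample mean near 100 pins the mean tour length near 100·n without any
    enumeration.
    """
    cfg = config or SimulationMapConfig()
    if n < 4:
        raise ValueError(f"simulation maps need n >= 4, got {n}")
    if cfg.floor <= 0 or cfg.floor >= cfg.mean:
        raise ValueError("floor must be in (0, mean)")
    rng = np.random.default_rng(seed)
    m = n * (n - 1) // 2
    for attempt in range(cfg.max_attempts):
        upper = rng.normal(cfg.mean, cfg.sd, size=m)
        # redraw truncated entries rather than clipping (keeps the mean honest)
        bad = upper < cfg.floor
        while np.any(bad):
            upper[bad] = rng.normal(cfg.mean, cfg.sd, size=int(bad.sum()))
            bad = upper < cfg.floor
        if abs(upper.mean() - cfg.mean) <= cfg.mean_tol:
            return TSPInstance(
                n=n, labels=default_labels(n), dist=_symmetric_from_upper(n, upper),
                mode="simulation",
                gen_meta={"seed": int(seed), "rejections": attempt},
            )
    raise GenerationError(
        f"sample mean never landed within {cfg.mean_tol} of {cfg.mean} "
        f"in {cfg.max_attempts} attempts (seed={seed})"
    )


def percentile_rank(all_lengths: Sequence[float] | np.ndarray, L: float) -> float:
    """Percentile position of L in the tour-length distribution.

    100 x (number of tours with length <= L) / (number of tours).  Used as
    the "top quality" of a found tour: small is good.
    """
    lengths = np.asarray(all_lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("empty tour-length list")
    tol = 1e-9 * max(1.0, abs(L))
    return 100.0 * float(np.count_nonzero(lengths <= L + tol)) / lengths.size


# ---------------------------------------------------------------------------
# TSPLIB-style serialization (EXPLICIT / FULL_MATRIX, real-valued weights)
# ---------------------------------------------------------------------------

def write_instance(instance: TSPInstance, path) -> None:
    """Write a TSPLIB-dialect file (EXPLICIT FULL_MATRIX, real weights).

    Standard TSPLIB uses integer weights; this dialect keeps full floating
    point precision and carries labels/mode/gen_meta in COMMENT lines.
    """
    lines = [
        f"NAME: {instance.mode}-{instance.n}city",
        "TYPE: TSP",
        f"COMMENT: labels={','.join(instance.labels)}",
        f"COMMENT: mode={instance.mode}",
        f"COMMENT: gen_meta={json.dumps(instance.gen_meta, sort_keys=True)}",
        f"DIMENSION: {instance.n}",
        "EDGE_WEIGHT_TYPE: EXPLICIT",
        "EDGE_WEIGHT_FORMAT: FULL_MATRIX",
        "EDGE_WEIGHT_SECTION",
    ]
    for row in instance.dist:
        lines.append(" ".join(repr(float(x)) for x in row))
    lines.append("EOF")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_instance(path) -> TSPInstance:
    """Read a TSPLIB-dialect file written by :func:`write_instance`.

    Also accepts hand-written files without COMMENT metadata (mode falls
    back to ``external``, labels to A, B, C, ...).  Raises
    :class:`InstanceParseError` naming the offending entry on asymmetry,
    negative distances or shape mismatches.
    """
    with open(path) as fh:
        text = fh.read()
    header, _, body = text.partition("EDGE_WEIGHT_SECTION")
    if not body:
        raise InstanceParseError("missing EDGE_WEIGHT_SECTION")
    n = None
    labels: tuple[str, ...] | None = None
    mode = "external"
    gen_meta: dict = {}
    for line in header.splitlines():
        line = line.strip()
        if not line:
            continue
        key, _, value = line.partition(":")
        key, value = key.strip().upper(), value.strip()
        if key == "DIMENSION":
            n = int(value)
        elif key == "EDGE_WEIGHT_TYPE" and value.upper() != "EXPLICIT":
            raise InstanceParseError(f"unsupported EDGE_WEIGHT_TYPE {value!r}")
        elif key == "EDGE_WEIGHT_FORMAT" and value.upper() != "FULL_MATRIX":
            raise InstanceParseError(f"unsupported EDGE_WEIGHT_FORMAT {value!r}")
        elif key == "COMMENT":
            m = re.match(r"labels=(.*)", value)
            if m:
                labels = tuple(lab.strip() for lab in m.group(1).split(","))
            m = re.match(r"mode=(\w+)", value)
            if m:
                mode = m.group(1)
            m = re.match(r"gen_meta=(.*)", value)
            if m:
                try:
                    gen_meta = json.loads(m.group(1))
                except json.JSONDecodeError as exc:
                    raise InstanceParseError(f"bad gen_meta JSON: {exc}") from exc
    if n is None:
        raise InstanceParseError("missing DIMENSION")
    values = body.replace("EOF", " ").split()
    if len(values) != n * n:
        raise InstanceParseError(
            f"expected {n * n} matrix entries, found {len(values)}"
        )
    try:
        dist = np.array(values, dtype=float).reshape(n, n)
    except ValueError as exc:
        raise InstanceParseError(f"non-numeric matrix entry: {exc}") from exc
    if labels is None:
        labels = default_labels(n)
    if not np.allclose(dist, dist.T, rtol=1e-9, atol=1e-9):
        i, j = np.unravel_index(np.argmax(np.abs(dist - dist.T)), dist.shape)
        raise InstanceParseError(
            f"asymmetric matrix: entry ({i + 1},{j + 1}) = {dist[i, j]} but "
            f"({j + 1},{i + 1}) = {dist[j, i]}"
        )
    off_mask = ~np.eye(n, dtype=bool)
    if np.any(dist[off_mask] <= 0):
        i, j = np.unravel_index(
            int(np.argmax((dist <= 0) & off_mask)), dist.shape
        )
        raise InstanceParseError(
            f"non-positive distance at entry ({i + 1},{j + 1}): {dist[i, j]}"
        )
    try:
        return TSPInstance(n=n, labels=labels, dist=dist, mode=mode, gen_meta=gen_meta)
    except ValueError as exc:
        raise InstanceParseError(str(exc)) from exc
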