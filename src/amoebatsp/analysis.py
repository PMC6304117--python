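"""Statistics over trial batches: success rates, quality ratios, scaling fits.

The headline quantities mirror how performance of the physical computer is
scored:

* success rate — share of trials whose trajectory settled on a feasible
  tour before the iteration cap (failures stay in the denominator);
* quality ratio — mean found tour length L_exp divided by the mean length
  L_mean over *all* (n-1)!/2 feasible tours (exact by enumeration for
  small n, the 100·n construction estimate for larger maps).  A searcher
  picking tours uniformly at random scores 1 by symmetry; values below 1
  quantify genuine optimisation;
* top quality — the percentile position of L_exp within the full
  tour-length distribution (smaller is better);
* scaling fit — ordinary least squares of mean search iterations on n,
  the model's (near-)linear search-time growth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .harness import TrialResult
from .instances import (
    BRUTE_FORCE_CAP,
    TSPInstance,
    enumerate_tour_lengths,
    percentile_rank,
)

__all__ = [
    "ExperimentSummary",
    "ScalingFit",
    "summarize_trials",
    "fit_scaling",
    "quality_report",
    "random_tour_baseline",
]


@dataclass
class ExperimentSummary:
    """Per-n aggregate over a batch of trials on one map."""

    n: int
    total_trials: int
    successful_trials: int
    success_rate_pct: float
    mean_search_iters: float | None
    sd_search_iters: float | None
    mean_total_iters: float
    best_len: float | None
    worst_len: float | None
    mean_found_len: float | None  # L_exp
    mean_feasible_len: float  # L_mean
    mean_feasible_estimated: bool
    quality_ratio: float | None  # L_exp / L_mean
    top_quality_pct: float | None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ScalingFit:
    """Least-squares line through (n, mean search iterations)."""

    slope: float
    intercept: float
    r_squared: float


def summarize_trials(
    trials: list[TrialResult],
    instance: TSPInstance | None = None,
    cap: int = BRUTE_FORCE_CAP,
) -> ExperimentSummary:
    """Aggregate a same-map trial batch into the standard score row.

    ``instance`` supplies the exact tour-length distribution when its size
    allows enumeration; without it (or above the cap) the mean feasible
    length falls back to the 100·n construction estimate and the
    percentile-based top quality is left unset.  Success-rate display
    convention is one decimal (full precision kept in the ratio itself).
    """
    if not trials:
        raise ValueError("empty trial list")
    ns = {t.n for t in trials}
    if len(ns) > 1:
        raise ValueError(f"mixed problem sizes in one batch: {sorted(ns)}")
    n = ns.pop()
    T = len(trials)
    successes = [t for t in trials if t.succeeded]
    S = len(successes)

    all_lengths = None
    if instance is not None and instance.n <= cap:
        all_lengths = enumerate_tour_lengths(instance, cap=cap)
        mean_feasible = float(all_lengths.mean())
        estimated = False
    else:
        mean_feasible = 100.0 * n
        estimated = True

    if S:
        found = np.array([t.tour_len for t in successes], dtype=float)
        search = np.array([t.search_iters for t in successes], dtype=float)
        mean_found = float(found.mean())
        summary_lengths = dict(
            mean_search_iters=float(search.mean()),
            sd_search_iters=float(search.std(ddof=1)) if S > 1 else 0.0,
            best_len=float(found.min()),
            worst_len=float(found.max()),
            mean_found_len=mean_found,
            quality_ratio=mean_found / mean_feasible,
            top_quality_pct=(
                percentile_rank(all_lengths, mean_found) if all_lengths is not None else None
            ),
        )
    else:
        summary_lengths = dict(
            mean_search_iters=None,
            sd_search_iters=None,
            best_len=None,
            worst_len=None,
            mean_found_len=None,
            quality_ratio=None,
            top_quality_pct=None,
        )

    return ExperimentSummary(
        n=n,
        total_trials=T,
        successful_trials=S,
        success_rate_pct=100.0 * S / T,
        mean_total_iters=float(np.mean([t.total_iters for t in trials])),
        mean_feasible_len=mean_feasible,
        mean_feasible_estimated=estimated,
        **summary_lengths,
    )


def fit_scaling(summaries: list[ExperimentSummary]) -> ScalingFit:
    """OLS of mean search iterations on problem size n (needs >= 3 sizes)."""
    pts = [
        (s.n, s.mean_search_iters)
        for s in summaries
        if s.successful_trials > 0 and s.mean_search_iters is not None
    ]
    if len({p[0] for p in pts}) < 3:
        raise ValueError("scaling fit needs >= 3 distinct n with successes")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.allclose(y, y[0]):
        return ScalingFit(slope=0.0, intercept=float(y[0]), r_squared=1.0)
    res = sps.linregress(x, y)
    return ScalingFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


_REPORT_COLUMNS = {
    "n": "n",
    "total_trials": "T",
    "successful_trials": "S",
    "success_rate_pct": "success rate (%)",
    "mean_search_iters": "av. search iters",
    "best_len": "best len",
    "worst_len": "worst len",
    "mean_found_len": "L_exp",
    "mean_feasible_len": "L_mean",
    "quality_ratio": "L_exp/L_mean",
    "top_quality_pct": "top quality (%)",
}


def quality_report(
    summaries: list[ExperimentSummary],
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Tabulate per-n scores; optionally persist CSV + aligned text table.

    Display values are rounded to one decimal (quality ratio to three);
    the returned DataFrame keeps full precision.  An asterisk marks
    estimated (non-enumerated) mean feasible lengths.
    """
    if not summaries:
        raise ValueError("no summaries to report")
    df = pd.DataFrame([s.to_dict() for s in summaries]).sort_values("n")
    if path is not None:
        path = Path(path)
        df.to_csv(path.with_suffix(".csv"), index=False)
        disp = df[list(_REPORT_COLUMNS)].rename(columns=_REPORT_COLUMNS).copy()
        for col in disp.columns:
            coerced = pd.to_numeric(disp[col], errors="coerce")
            if coerced.dtype.kind == "f":
                disp[col] = coerced.round(1)
        disp["L_exp/L_mean"] = pd.to_numeric(df["quality_ratio"], errors="coerce").round(3).values
        star = df["mean_feasible_estimated"].map({True: "*", False: ""}).values
        disp["L_mean"] = [f"{v:.1f}{s}" for v, s in zip(df["mean_feasible_len"], star)]
        path.with_suffix(".txt").write_text(disp.to_string(index=False) + "\n")
    return df.reset_index(drop=True)


def random_tour_baseline(
    instance: TSPInstance,
    draws: int = 1000,
    rng: np.random.Generator | None = None,
    cap: int = BRUTE_FORCE_CAP,
) -> tuple[float, float]:
    """Quality ratio of a searcher that picks tours uniformly at random.

    Returns (quality_ratio, p_value) where the p-value is a two-sided
    one-sample t-test of the drawn lengths against the exact mean feasible
    length — the null model an optimising searcher must beat.
    """
    rng = rng or np.random.default_rng()
    lengths = enumerate_tour_lengths(instance, cap=cap)
    sample = rng.choice(lengths, size=draws, replace=True)
    t = sps.ttest_1samp(sample, popmean=lengths.mean())
    return float(sample.mean() / lengths.mean()), float(t.pvalue)
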