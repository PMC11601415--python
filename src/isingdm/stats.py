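"""Decision statistics: error rates, reaction-time summaries and distributions.

Conventions: the error rate is the fraction of *decided* trials absorbed at
the negative threshold; timeouts are counted but excluded from the error
rate and all reaction-time means.  Reaction-time distributions are compared
on a normalized axis, time divided by the ensemble's mean reaction time.

Two estimators exist for reaction-time ratios and both are provided:
ratios of ensemble means (used on the model side), and per-unit ratios
averaged afterwards (how behavioral tables built from per-participant
ratios are aggregated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .gillespie import TrialResult

__all__ = [
    "DecisionSummary",
    "NormalizedRTDistribution",
    "summarize",
    "normalized_rt_distribution",
    "qq_compare",
    "distribution_mse",
    "wilson_interval",
    "bootstrap_ratio_interval",
]

#: shared binning convention for comparable normalized-RT distributions
DEFAULT_N_BINS = 60
DEFAULT_BIN_RANGE = (0.0, 5.0)


def _to_arrays(results: Iterable[TrialResult] | tuple[np.ndarray, np.ndarray]):
    """Accept a list of TrialResult or a (decisions, rts) array pair."""
    if isinstance(results, tuple) and len(results) >= 2:
        decisions = np.asarray(results[0], dtype=np.int64)
        rts = np.asarray(results[1], dtype=np.float64)
    else:
        results = list(results)
        decisions = np.array([r.decision for r in results], dtype=np.int64)
        rts = np.array([r.rt for r in results], dtype=np.float64)
    return decisions, rts


@dataclass(frozen=True)
class DecisionSummary:
    """Ensemble-level decision statistics."""

    error_rate: float
    se_error: float  # binomial standard error of the error rate
    rt_mean: float
    rt_correct_mean: float  # nan if no correct trials
    rt_wrong_mean: float  # nan if no wrong trials
    rt_ratio_cw: float  # RT_correct / RT_wrong; nan if either side empty
    n_correct: int
    n_wrong: int
    n_timeout: int

    @property
    def n_decided(self) -> int:
        return self.n_correct + self.n_wrong


def summarize(results) -> DecisionSummary:
    """Summarize an ensemble of trials into the standard decision statistics.

    ``results`` is a list of :class:`TrialResult` or a ``(decisions, rts)``
    pair of arrays.  Raises if every trial timed out.
    """
    decisions, rts = _to_arrays(results)
    correct = decisions == 1
    wrong = decisions == -1
    n_c, n_w = int(correct.sum()), int(wrong.sum())
    n_t = int((decisions == 0).sum())
    n_dec = n_c + n_w
    if n_dec == 0:
        raise ValueError("all trials timed out; no decisions to summarize")
    error = n_w / n_dec
    se = float(np.sqrt(error * (1.0 - error) / n_dec))
    rt_mean = float(rts[correct | wrong].mean())
    rt_c = float(rts[correct].mean()) if n_c else float("nan")
    rt_w = float(rts[wrong].mean()) if n_w else float("nan")
    ratio = rt_c / rt_w if (n_c and n_w) else float("nan")
    return DecisionSummary(
        error_rate=error,
        se_error=se,
        rt_mean=rt_mean,
        rt_correct_mean=rt_c,
        rt_wrong_mean=rt_w,
        rt_ratio_cw=ratio,
        n_correct=n_c,
        n_wrong=n_w,
        n_timeout=n_t,
    )


@dataclass(frozen=True)
class NormalizedRTDistribution:
    """Histogram density of reaction times on the rt / mean(rt) axis."""

    bin_edges: np.ndarray
    densities: np.ndarray
    n: int
    mean_rt: float  # the normalization constant actually used

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def decided_rts(results) -> np.ndarray:
    """Reaction times of decided trials only."""
    decisions, rts = _to_arrays(results)
    return rts[decisions != 0]


def normalized_rt_distribution(
    results,
    n_bins: int = DEFAULT_N_BINS,
    bin_range: tuple[float, float] = DEFAULT_BIN_RANGE,
) -> NormalizedRTDistribution:
    """Histogram density of rt / mean(rt) over decided trials.

    The shared default binning (60 bins on [0, 5]) makes two distributions
    directly comparable bin by bin.  A degenerate sample (all reaction
    times equal) still yields a valid single-occupied-bin density.
    """
    rts = decided_rts(results)
    if rts.size < 2:
        raise ValueError("need at least 2 decided trials")
    mean_rt = float(rts.mean())
    norm = rts / mean_rt
    edges = np.linspace(bin_range[0], bin_range[1], n_bins + 1)
    hist, _ = np.histogram(norm, bins=edges)
    width = edges[1] - edges[0]
    inside = hist.sum()
    if inside == 0:
        raise ValueError("no normalized reaction times fall inside the bin range")
    densities = hist / (inside * width)
    return NormalizedRTDistribution(
        bin_edges=edges, densities=densities, n=int(rts.size), mean_rt=mean_rt
    )


def qq_compare(
    a: Sequence[float],
    b: Sequence[float],
    percentiles: np.ndarray | None = None,
) -> np.ndarray:
    """Matched empirical quantiles of two samples.

    Returns an array of shape (p, 2) with columns (quantile of a, quantile
    of b) evaluated on a fixed probability grid (default percentiles
    1..99), the standard quantile-quantile representation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if percentiles is None:
        percentiles = np.arange(1, 100)
    qa = np.percentile(a, percentiles)
    qb = np.percentile(b, percentiles)
    return np.stack([qa, qb], axis=1)


def distribution_mse(
    model: NormalizedRTDistribution, reference: NormalizedRTDistribution
) -> float:
    """Mean squared density difference over a common binning.

    If the two histograms were built on different grids, both samples'
    densities are rebinned onto the model's grid by linear interpolation of
    the density at bin centers (never an error).  Symmetric in its
    arguments on a shared grid.  To compare paired conditions, sum the
    per-condition MSEs.
    """
    if model.bin_edges.shape == reference.bin_edges.shape and np.allclose(
        model.bin_edges, reference.bin_edges
    ):
        d_m, d_r = model.densities, reference.densities
    else:
        centers = model.bin_centers
        d_m = model.densities
        d_r = np.interp(
            centers, reference.bin_centers, reference.densities, left=0.0, right=0.0
        )
    return float(np.mean((d_m - d_r) ** 2))


def wilson_interval(n_wrong: int, n_decided: int, z: float = 1.96):
    """Wilson score interval for a binomial error rate."""
    if n_decided <= 0:
        raise ValueError("need at least one decided trial")
    p = n_wrong / n_decided
    denom = 1.0 + z * z / n_decided
    center = (p + z * z / (2 * n_decided)) / denom
    half = (
        z
        * np.sqrt(p * (1.0 - p) / n_decided + z * z / (4 * n_decided * n_decided))
        / denom
    )
    return float(center - half), float(center + half)


def bootstrap_ratio_interval(
    rts_num: np.ndarray,
    rts_den: np.ndarray,
    seed: int,
    n_resamples: int = 1000,
    ci: float = 0.95,
):
    """Seeded bootstrap CI for a ratio of two ensemble-mean reaction times."""
    rng = np.random.default_rng(seed)
    rts_num = np.asarray(rts_num, dtype=float)
    rts_den = np.asarray(rts_den, dtype=float)
    if rts_num.size == 0 or rts_den.size == 0:
        raise ValueError("both samples must be nonempty")
    idx_n = rng.integers(0, rts_num.size, size=(n_resamples, rts_num.size))
    idx_d = rng.integers(0, rts_den.size, size=(n_resamples, rts_den.size))
    ratios = rts_num[idx_n].mean(axis=1) / rts_den[idx_d].mean(axis=1)
    lo, hi = np.quantile(ratios, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return float(lo), float(hi), float(ratios.std(ddof=1))
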