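"""Rejection-sampling (pattern-filtering) inference for the neutral simulator.

Model-data agreement for each pattern i is scored by the mean relative
deviation

    mRD_i(p) = (1 / n_i) * sum_x |S_sim(i, x) - S_obs(i, x)| / S_obs(i, x),

where x runs over abundance classes (SAD) or evaluation radii (spatial
patterns); scalar patterns have n_i = 1.  Zero or missing observed components
are excluded, with n_i reduced accordingly.  mRD = 0 means a perfect fit.

The inherent variability of the data defines a baseline uncertainty
eps_i for each pattern: the average mRD between each single census and the
across-census average.  A parameter set p is accepted for a chosen pattern
subset when, for every selected pattern i,

    mRD_i(p) < min(f * eps_i, 0.2)

with tolerance factor f >= 1 and a hard 20% cap.  Posteriors are summarised
by 25%/75% quantiles, optionally standardised to [0, 1] by the prior range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .local_dynamics import Arena, Params, immigration_rate
from .summary_stats import CensusSeriesSummary, SummaryStatistics

__all__ = [
    "PATTERN_IDS",
    "DEFAULT_CAP",
    "PriorSpec",
    "DeviationConfig",
    "RejectionResult",
    "mrd",
    "mrd_patterns",
    "pattern_vector",
    "epsilon_from_censuses",
    "acceptance_threshold",
    "pattern_combinations",
    "sample_prior",
    "rejection_filter",
    "posterior_summary",
]

logger = logging.getLogger(__name__)

#: canonical pattern identifiers, in reporting order
PATTERN_IDS = ("mort", "SR", "SAD", "g", "F", "SAR")
#: hard upper bound on any acceptance threshold (20% deviation)
DEFAULT_CAP = 0.2


def mrd(sim, obs) -> float:
    """Mean relative deviation between equal-length statistic vectors.

    Components whose observed value is zero or missing (NaN) are excluded and
    the divisor n_i reduced; if every component is excluded the deviation is
    undefined and NaN is returned (flagged by the caller).
    """
    sim = np.atleast_1d(np.asarray(sim, dtype=np.float64))
    obs = np.atleast_1d(np.asarray(obs, dtype=np.float64))
    if sim.shape != obs.shape:
        raise ValueError(f"shape mismatch: sim {sim.shape} vs obs {obs.shape}")
    valid = np.isfinite(obs) & (obs != 0.0) & np.isfinite(sim)
    if not valid.any():
        return float("nan")
    return float(np.mean(np.abs(sim[valid] - obs[valid]) / obs[valid]))


def pattern_vector(stats: SummaryStatistics, pattern: str) -> np.ndarray:
    """Statistic vector for one pattern id (1-element array for scalars)."""
    if pattern == "mort":
        return np.atleast_1d(np.float64(stats.mort))
    if pattern == "SR":
        return np.atleast_1d(np.float64(stats.sr))
    if pattern == "SAD":
        return stats.sad
    if pattern == "g":
        return stats.g
    if pattern == "F":
        return stats.f
    if pattern == "SAR":
        return stats.sar
    raise KeyError(f"unknown pattern id {pattern!r}")


def _aligned(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-pad the shorter of two vectors (SAD octave alignment)."""
    width = max(len(a), len(b))
    return (
        np.pad(a.astype(np.float64), (0, width - len(a))),
        np.pad(b.astype(np.float64), (0, width - len(b))),
    )


def mrd_patterns(
    sim_stats: SummaryStatistics,
    obs_stats: SummaryStatistics,
    patterns=PATTERN_IDS,
) -> dict[str, float]:
    """mRD per pattern between a simulated and an observed statistics set."""
    out = {}
    for pid in patterns:
        s, o = pattern_vector(sim_stats, pid), pattern_vector(obs_stats, pid)
        if pid == "SAD":
            s, o = _aligned(s, o)
        out[pid] = mrd(s, o)
    return out


def epsilon_from_censuses(
    per_census: list[SummaryStatistics] | CensusSeriesSummary,
    period_mortalities=None,
) -> dict[str, float]:
    """Baseline per-pattern uncertainty eps_i from repeated censuses.

    eps_i is the average mRD between each single census's statistic i and the
    across-census average statistic.  For mortality, the per-period rates play
    the role of the single censuses.  Patterns that cannot be evaluated
    (single census; no survival information) come back as NaN.
    """
    if isinstance(per_census, CensusSeriesSummary):
        period_mortalities = per_census.period_mortalities
        per_census = per_census.per_census
    if len(per_census) < 2:
        logger.warning("epsilon undefined for a single census")
        return {pid: float("nan") for pid in PATTERN_IDS}

    from .summary_stats import average_stats

    avg = average_stats(per_census, period_mortalities)
    eps: dict[str, float] = {}
    for pid in PATTERN_IDS:
        if pid == "mort":
            if period_mortalities is None or len(period_mortalities) < 2:
                eps[pid] = float("nan")
            elif avg.mort == 0.0:
                # identical censuses: zero turnover everywhere is a perfect match
                eps[pid] = 0.0 if np.all(np.asarray(period_mortalities) == 0.0) else float("nan")
            else:
                eps[pid] = float(np.mean([mrd(m, avg.mort) for m in period_mortalities]))
            continue
        devs = []
        for s in per_census:
            a, b = pattern_vector(s, pid), pattern_vector(avg, pid)
            if pid == "SAD":
                a, b = _aligned(a, b)
            devs.append(mrd(a, b))
        eps[pid] = float(np.nanmean(devs))
    return eps


def acceptance_threshold(eps_i: float, f: float, cap: float = DEFAULT_CAP) -> float:
    """Selection threshold min(f * eps_i, cap) for one pattern."""
    if eps_i < 0:
        raise ValueError("eps_i must be nonnegative")
    if f <= 0:
        raise ValueError("tolerance factor f must be positive")
    return min(f * eps_i, cap)


def pattern_combinations(pattern_ids=PATTERN_IDS) -> list[tuple[str, ...]]:
    """All nonempty pattern subsets (2^k - 1 of them), by size then lexicographic."""
    ids = tuple(pattern_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("pattern ids must be distinct")
    ordered = sorted(ids)
    out: list[tuple[str, ...]] = []
    for size in range(1, len(ordered) + 1):
        out.extend(combinations(ordered, size))
    return out


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors for the six model parameters (low, high)."""

    r_t: tuple[float, float] = (1.0, 15.0)
    b_s: tuple[float, float] = (0.95, 1.0)
    a_s: tuple[float, float] = (0.1, 20.0)
    d_m: tuple[float, float] = (5.0, 100.0)
    d_sd: tuple[float, float] = (5.0, 150.0)
    theta: tuple[float, float] = (10.0, 300.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges().items():
            if not lo < hi:
                raise ValueError(f"prior for {name}: low must be < high, got ({lo}, {hi})")
            if lo <= 0:
                raise ValueError(f"prior range for {name} must be positive")

    def ranges(self) -> dict[str, tuple[float, float]]:
        return {
            "r_t": self.r_t,
            "b_s": self.b_s,
            "a_s": self.a_s,
            "d_m": self.d_m,
            "d_sd": self.d_sd,
            "theta": self.theta,
        }


def sample_prior(
    prior: PriorSpec,
    n_sets: int,
    rng: np.random.Generator | int | None = None,
    arena: Arena = Arena(),
) -> list[Params]:
    """n i.i.d. parameter sets from the uniform priors (m derived, not drawn)."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(rng)
    ranges = prior.ranges()
    draws = {name: rng.uniform(lo, hi, n_sets) for name, (lo, hi) in ranges.items()}
    out = []
    for i in range(n_sets):
        out.append(Params(**{name: float(draws[name][i]) for name in ranges}))
    return out


@dataclass(frozen=True)
class DeviationConfig:
    """Per-pattern uncertainty levels plus tolerance settings."""

    epsilon: dict[str, float]
    f: float
    cap: float = DEFAULT_CAP
    patterns: tuple[str, ...] = PATTERN_IDS

    def thresholds(self) -> dict[str, float]:
        return {p: acceptance_threshold(self.epsilon[p], self.f, self.cap) for p in self.patterns}


@dataclass
class RejectionResult:
    """Outcome of filtering simulated parameter sets against observations."""

    accepted: list[tuple[Params, dict[str, float]]]
    all_mrds: list[dict[str, float]]
    n_tried: int
    f: float
    patterns: tuple[str, ...]
    posterior: dict[str, dict[str, float]]

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)

    def accepted_values(self, name: str) -> np.ndarray:
        return np.asarray([getattr(p, name) for p, _ in self.accepted])


def rejection_filter(
    results: list[tuple[Params, SummaryStatistics]],
    obs: SummaryStatistics,
    eps: dict[str, float],
    f: float,
    patterns=PATTERN_IDS,
    cap: float = DEFAULT_CAP,
    prior: PriorSpec | None = None,
) -> RejectionResult:
    """Accept exactly the sets with mRD_i < min(f * eps_i, cap) for all selected i.

    Per-pattern mRDs are recorded for every tried set.  An empty acceptance is
    a valid outcome (flagged in the log) with an empty posterior.
    """
    if not results:
        raise ValueError("no simulation results to filter")
    patterns = tuple(patterns)
    thresholds = {p: acceptance_threshold(eps[p], f, cap) for p in patterns}
    accepted = []
    all_mrds = []
    for params, stats in results:
        devs = mrd_patterns(stats, obs)
        all_mrds.append(devs)
        ok = all(
            np.isfinite(devs[p]) and devs[p] < thresholds[p] for p in patterns
        )
        if ok:
            accepted.append((params, devs))
    if not accepted:
        logger.warning(
            "rejection filter accepted no parameter set (patterns=%s, f=%s)", patterns, f
        )
    posterior = (
        posterior_summary([p for p, _ in accepted], prior or PriorSpec())
        if accepted
        else {}
    )
    return RejectionResult(
        accepted=accepted,
        all_mrds=all_mrds,
        n_tried=len(results),
        f=f,
        patterns=patterns,
        posterior=posterior,
    )


def posterior_summary(accepted: list[Params], prior: PriorSpec) -> dict[str, dict[str, float]]:
    """25%/75% posterior quantiles per parameter, raw and standardised to [0, 1].

    Quantiles use linear interpolation between order statistics (numpy's
    default convention).
    """
    if not accepted:
        raise ValueError("posterior summary of an empty acceptance set")
    out: dict[str, dict[str, float]] = {}
    for name, (lo, hi) in prior.ranges().items():
        vals = np.asarray([getattr(p, name) for p in accepted], dtype=np.float64)
        q25, q75 = np.quantile(vals, [0.25, 0.75])
        out[name] = {
            "q25": float(q25),
            "q75": float(q75),
            "q25_std": float((q25 - lo) / (hi - lo)),
            "q75_std": float((q75 - lo) / (hi - lo)),
        }
    # derived immigration rate, for reporting alongside the free parameters
    m_vals = np.asarray([immigration_rate(p.d_m, Arena()) for p in accepted])
    q25, q75 = np.quantile(m_vals, [0.25, 0.75])
    out["m"] = {"q25": float(q25), "q75": float(q75)}
    return out
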