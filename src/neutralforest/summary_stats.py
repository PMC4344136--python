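"""Six-pattern summary statistics computed identically from any census.

The suite characterises a fully mapped tree community by three non-spatial
patterns — annual mortality rate (``mort``), species richness (``SR``), and
the species abundance distribution in Preston log2 octaves (``SAD``) — and
three spatial point-pattern statistics evaluated at the radii
r = 1, 2, 5, 10, 20, 50 m:

``g(r)``
    Pair-correlation function of all trees: neighbourhood density at distance
    r relative to the overall density lambda; 1 under complete spatial
    randomness, > 1 for aggregation.  Estimated on distance rings of
    half-width h with Ripley isotropic edge correction.
``F(r)``
    Proportion of conspecific neighbour pairs at distance r — the distance
    decay of community similarity (beta-diversity).  Under random labelling
    F(r) = 1 - D, D being Simpson diversity.
``SAR(r)``
    Species-area relationship: mean species count in circles of radius r
    fully contained in the plot, over a fixed set of random centres.

One code path serves simulated and observed censuses alike.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .census_io import Census

__all__ = [
    "DEFAULT_RADII",
    "SummaryStatistics",
    "CensusSeriesSummary",
    "species_richness",
    "sad_octaves",
    "simpson_index",
    "pair_correlation",
    "conspecific_fraction",
    "sar_circles",
    "annualize_mortality",
    "summarize_census",
    "summarize_simulation",
    "summarize_censuses",
    "average_stats",
]

logger = logging.getLogger(__name__)

#: evaluation radii (m) for the three spatial patterns
DEFAULT_RADII = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0)
#: ring half-width (m); rings at the 1 m and 2 m radii do not overlap
DEFAULT_RING_HALFWIDTH = 0.5


def _abundances(census: Census) -> np.ndarray:
    if census.n == 0:
        raise ValueError("empty census")
    _, counts = np.unique(census.species, return_counts=True)
    return counts


def species_richness(census: Census) -> int:
    """Number of distinct species in the census."""
    return int(len(_abundances(census)))


def sad_octaves(census: Census, n_classes: int | None = None) -> np.ndarray:
    """Species abundance distribution in Preston log2 octaves.

    Class k counts species with abundance in [2^k, 2^(k+1)); when
    ``n_classes`` is given the last class is open-ended, otherwise the number
    of classes is set by the maximum abundance.
    """
    counts = _abundances(census)
    if n_classes is not None and n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    octave = np.floor(np.log2(counts)).astype(int)
    if n_classes is None:
        n_classes = int(octave.max()) + 1
    octave = np.minimum(octave, n_classes - 1)
    return np.bincount(octave, minlength=n_classes).astype(np.int64)


def simpson_index(census: Census) -> float:
    """Simpson diversity D: probability two trees drawn without replacement differ."""
    counts = _abundances(census)
    n = counts.sum()
    if n < 2:
        raise ValueError("Simpson index needs at least two trees")
    return float(1.0 - np.sum(counts * (counts - 1)) / (n * (n - 1)))


def _edge_fraction(x: np.ndarray, y: np.ndarray, r: np.ndarray, width: float, height: float):
    """Fraction of the circle of radius r centred at (x, y) inside the plot.

    Rectangle geometry: each edge closer than r removes an arc of half-angle
    arccos(e/r); arcs of two adjacent edges overlap by a1 + a2 - pi/2 when the
    corner lies within r.  Valid for r < min(width, height).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        a_l = np.arccos(np.clip(x / r, 0.0, 1.0))
        a_r = np.arccos(np.clip((width - x) / r, 0.0, 1.0))
        a_b = np.arccos(np.clip(y / r, 0.0, 1.0))
        a_t = np.arccos(np.clip((height - y) / r, 0.0, 1.0))
    ext = 2.0 * (a_l + a_r + a_b + a_t)
    half_pi = 0.5 * math.pi
    for a1, a2 in ((a_l, a_b), (a_l, a_t), (a_r, a_b), (a_r, a_t)):
        ext -= np.maximum(0.0, a1 + a2 - half_pi)
    return 1.0 - ext / (2.0 * math.pi)


def _pair_table(census: Census, rmax: float):
    """Unordered pairs (i, j) with distance < rmax, and the distances."""
    pts = np.column_stack([census.x, census.y])
    pairs = cKDTree(pts).query_pairs(rmax, output_type="ndarray")
    if pairs.size == 0:
        return pairs.reshape(0, 2), np.empty(0)
    d = np.hypot(
        census.x[pairs[:, 0]] - census.x[pairs[:, 1]],
        census.y[pairs[:, 0]] - census.y[pairs[:, 1]],
    )
    return pairs, d


def _ring_edges(radii, h: float):
    radii = np.asarray(radii, dtype=np.float64)
    lo = np.maximum(0.0, radii - h)
    hi = radii + h
    return radii, lo, hi


def _g_from_pairs(census, pairs, d, radii, h):
    radii, lo, hi = _ring_edges(radii, h)
    lam = census.n / census.area
    g = np.empty(len(radii))
    w0 = 1.0 / _edge_fraction(census.x[pairs[:, 0]], census.y[pairs[:, 0]], d, census.width, census.height)
    w1 = 1.0 / _edge_fraction(census.x[pairs[:, 1]], census.y[pairs[:, 1]], d, census.width, census.height)
    for k in range(len(radii)):
        ring = (d >= lo[k]) & (d < hi[k])
        num = w0[ring].sum() + w1[ring].sum()
        ring_area = math.pi * (hi[k] ** 2 - lo[k] ** 2)
        g[k] = num / (lam * census.n * ring_area)
    return g


def _f_from_pairs(census, pairs, d, radii, h):
    radii, lo, hi = _ring_edges(radii, h)
    same = census.species[pairs[:, 0]] == census.species[pairs[:, 1]]
    f = np.empty(len(radii))
    for k in range(len(radii)):
        ring = (d >= lo[k]) & (d < hi[k])
        n_ring = int(ring.sum())
        f[k] = np.nan if n_ring == 0 else same[ring].sum() / n_ring
    return f


def pair_correlation(
    census: Census,
    radii=DEFAULT_RADII,
    ring_halfwidth: float = DEFAULT_RING_HALFWIDTH,
) -> np.ndarray:
    """Ring estimator of the pair-correlation function g(r).

    g_hat(r) = sum over ordered pairs with distance in [r-h, r+h) of the
    Ripley isotropic edge-correction weight, divided by lambda * N * ring
    area.  Rings reaching below zero are truncated at zero.
    """
    if census.n < 2:
        raise ValueError("pair correlation needs at least two trees")
    rmax = max(radii) + ring_halfwidth
    pairs, d = _pair_table(census, rmax)
    return _g_from_pairs(census, pairs, d, radii, ring_halfwidth)


def conspecific_fraction(
    census: Census,
    radii=DEFAULT_RADII,
    ring_halfwidth: float = DEFAULT_RING_HALFWIDTH,
) -> np.ndarray:
    """F(r): share of same-species pairs among pairs at ring distance r.

    Rings that contain no pair are returned as NaN (flagged missing; they are
    excluded from downstream deviation measures).
    """
    if census.n < 2:
        raise ValueError("conspecific fraction needs at least two trees")
    rmax = max(radii) + ring_halfwidth
    pairs, d = _pair_table(census, rmax)
    return _f_from_pairs(census, pairs, d, radii, ring_halfwidth)


def sar_circles(
    census: Census,
    radii=DEFAULT_RADII,
    n_centers: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Species-area relationship: mean species count in circles of radius r.

    Centres are uniform random points such that the largest circle is fully
    contained in the plot; the same centre set is reused across radii, making
    SAR(r) nondecreasing per construction.
    """
    radii = np.asarray(radii, dtype=np.float64)
    rmax = float(radii.max())
    if 2.0 * rmax > min(census.width, census.height):
        raise ValueError(
            f"max radius {rmax} m does not allow full containment in a "
            f"{census.width} x {census.height} m plot"
        )
    rng = np.random.default_rng(rng)
    cx = rng.uniform(rmax, census.width - rmax, n_centers)
    cy = rng.uniform(rmax, census.height - rmax, n_centers)
    centers = np.column_stack([cx, cy])
    _, sp_codes = np.unique(census.species, return_inverse=True)
    tree = cKDTree(np.column_stack([census.x, census.y]))
    sar = np.empty(len(radii))
    for k, r in enumerate(radii):
        balls = tree.query_ball_point(centers, r)
        sar[k] = np.mean([len(np.unique(sp_codes[idx])) if idx else 0 for idx in balls])
    return sar


def annualize_mortality(n0: int, survivors: int, t_years: float) -> float:
    """Compound annual mortality: 1 - (survivors / n0)^(1 / t_years)."""
    if n0 < 1 or not 0 <= survivors <= n0:
        raise ValueError(f"need 0 <= survivors <= n0 with n0 >= 1, got {survivors}/{n0}")
    if t_years <= 0:
        raise ValueError("t_years must be positive")
    return 1.0 - (survivors / n0) ** (1.0 / t_years)


@dataclass
class SummaryStatistics:
    """The six-pattern vector plus auxiliaries for one census (or an average).

    ``mort`` is NaN when no survival information is available (a single
    census).  ``sad`` may be real-valued when averaged across censuses.
    """

    mort: float
    sr: float
    sad: np.ndarray
    g: np.ndarray
    f: np.ndarray
    sar: np.ndarray
    radii: np.ndarray
    simpson: float
    density: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sad = np.asarray(self.sad, dtype=np.float64)
        self.g = np.asarray(self.g, dtype=np.float64)
        self.f = np.asarray(self.f, dtype=np.float64)
        self.sar = np.asarray(self.sar, dtype=np.float64)
        self.radii = np.asarray(self.radii, dtype=np.float64)

    def to_dict(self) -> dict:
        return {
            "mort": None if np.isnan(self.mort) else float(self.mort),
            "SR": float(self.sr),
            "SAD": self.sad.tolist(),
            "g": self.g.tolist(),
            "F": [None if np.isnan(v) else float(v) for v in self.f],
            "SAR": self.sar.tolist(),
            "radii": self.radii.tolist(),
            "simpson": float(self.simpson),
            "density": float(self.density),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SummaryStatistics":
        return cls(
            mort=np.nan if d.get("mort") is None else float(d["mort"]),
            sr=float(d["SR"]),
            sad=np.asarray(d["SAD"], dtype=np.float64),
            g=np.asarray(d["g"], dtype=np.float64),
            f=np.asarray([np.nan if v is None else v for v in d["F"]], dtype=np.float64),
            sar=np.asarray(d["SAR"], dtype=np.float64),
            radii=np.asarray(d["radii"], dtype=np.float64),
            simpson=float(d["simpson"]),
            density=float(d["density"]),
            provenance=d.get("provenance", {}),
        )


def summarize_census(
    census: Census,
    radii=DEFAULT_RADII,
    ring_halfwidth: float = DEFAULT_RING_HALFWIDTH,
    n_centers: int = 1000,
    sar_seed: int | None = 0,
    mort: float = np.nan,
) -> SummaryStatistics:
    """All patterns of a single census; ``mort`` is supplied by the caller."""
    rmax = max(radii) + ring_halfwidth
    pairs, d = _pair_table(census, rmax)
    g = _g_from_pairs(census, pairs, d, radii, ring_halfwidth)
    f = _f_from_pairs(census, pairs, d, radii, ring_halfwidth)
    sar = sar_circles(census, radii, n_centers=n_centers, rng=sar_seed)
    return SummaryStatistics(
        mort=mort,
        sr=species_richness(census),
        sad=sad_octaves(census),
        g=g,
        f=f,
        sar=sar,
        radii=np.asarray(radii, dtype=np.float64),
        simpson=simpson_index(census),
        density=census.n / census.area,
        provenance={
            "ring_halfwidth": ring_halfwidth,
            "n_centers": n_centers,
            "sar_seed": sar_seed,
        },
    )


def summarize_simulation(
    result,
    window_years: int = 20,
    radii=DEFAULT_RADII,
    ring_halfwidth: float = DEFAULT_RING_HALFWIDTH,
    n_centers: int = 1000,
    sar_seed: int | None = 0,
) -> SummaryStatistics:
    """Statistics of a simulation: final census + mortality over the last window.

    ``mort`` is the mean of annual deaths / J over the final ``window_years``
    simulated years (mirroring a 20-year observation window); a shorter run
    uses all years, with a log note.
    """
    deaths = np.asarray(result.annual_death_counts, dtype=np.float64)
    j = result.final_state.size
    if len(deaths) < window_years:
        logger.info(
            "mortality window (%d y) longer than run (%d y); using full run",
            window_years,
            len(deaths),
        )
        window = deaths
    else:
        window = deaths[-window_years:]
    mort = float(np.mean(window) / j) if len(window) else np.nan
    return summarize_census(
        result.final_state.census(),
        radii=radii,
        ring_halfwidth=ring_halfwidth,
        n_centers=n_centers,
        sar_seed=sar_seed,
        mort=mort,
    )


def _pad(vecs: list[np.ndarray]) -> np.ndarray:
    width = max(len(v) for v in vecs)
    return np.vstack([np.pad(v.astype(np.float64), (0, width - len(v))) for v in vecs])


def average_stats(
    per_census: list[SummaryStatistics], period_mortalities=None
) -> SummaryStatistics:
    """Component-wise mean of per-census statistics (SADs padded to align).

    ``mort`` is the mean over inter-census periods when given, else NaN.
    F rings missing in some censuses are averaged over the censuses where
    they exist.
    """
    if not per_census:
        raise ValueError("no statistics to average")
    mort = float(np.mean(period_mortalities)) if period_mortalities is not None and len(period_mortalities) else np.nan
    f_stack = np.vstack([s.f for s in per_census])
    present = np.isfinite(f_stack)
    with np.errstate(invalid="ignore"):
        f_avg = np.where(
            present.any(axis=0),
            np.nansum(np.where(present, f_stack, 0.0), axis=0) / np.maximum(present.sum(axis=0), 1),
            np.nan,
        )
    return SummaryStatistics(
        mort=mort,
        sr=float(np.mean([s.sr for s in per_census])),
        sad=_pad([s.sad for s in per_census]).mean(axis=0),
        g=np.mean(np.vstack([s.g for s in per_census]), axis=0),
        f=f_avg,
        sar=np.mean(np.vstack([s.sar for s in per_census]), axis=0),
        radii=per_census[0].radii,
        simpson=float(np.mean([s.simpson for s in per_census])),
        density=float(np.mean([s.density for s in per_census])),
        provenance={"n_censuses": len(per_census)},
    )


@dataclass
class CensusSeriesSummary:
    """Averaged statistics of a census series plus the per-census breakdown."""

    average: SummaryStatistics
    per_census: list[SummaryStatistics]
    period_mortalities: np.ndarray


def summarize_censuses(
    censuses: list[Census],
    interval_years: float = 5.0,
    radii=DEFAULT_RADII,
    ring_halfwidth: float = DEFAULT_RING_HALFWIDTH,
    n_centers: int = 1000,
    sar_seed: int | None = 0,
) -> CensusSeriesSummary:
    """Statistics of a repeated-census series.

    SR/SAD/g/F/SAR are computed per census and averaged; mortality is the
    matched-survivor compound annual rate per inter-census period (tracked via
    stable tree ids), averaged over periods.  Without ids, mortality is NaN.
    """
    if len(censuses) < 2:
        raise ValueError("need at least two censuses")
    per_census = [
        summarize_census(
            c,
            radii=radii,
            ring_halfwidth=ring_halfwidth,
            n_centers=n_centers,
            sar_seed=sar_seed,
        )
        for c in censuses
    ]
    morts = []
    if all(c.ids is not None for c in censuses):
        for a, b in zip(censuses, censuses[1:]):
            survivors = np.intersect1d(a.ids, b.ids).size
            morts.append(annualize_mortality(a.n, survivors, interval_years))
    else:
        logger.warning("census series lacks stable tree ids; mortality unavailable")
    morts = np.asarray(morts)
    return CensusSeriesSummary(
        average=average_stats(per_census, morts if morts.size else None),
        per_census=per_census,
        period_mortalities=morts,
    )
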