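"""Synthetic census generators emulating a fully mapped tropical-forest plot.

The real 50 ha census data these tools emulate are access-restricted, so the
package ships generators for structurally similar synthetic data: a
logseries species abundance distribution (~300 species over ~21,000 adult
trees) with conspecific aggregation from a Thomas cluster process (Poisson
parents, Gaussian offspring scatter), plus a pseudo-census time series with
constant population size and id-tracked turnover, emulating five censuses at
5-year spacing.  These are first-class, tested data generators — not
stand-ins wired to any particular expected output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .census_io import Census
from .local_dynamics import Arena, _recruit_positions, lognormal_kernel_params

__all__ = ["FixtureSpec", "generate_clustered_community", "generate_pseudo_census_series"]


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions of the synthetic plot.

    ``logser_p`` sets the logseries shape (default gives a mean abundance of
    ~68 trees/species, i.e. ~20,000 trees over 300 species); ``sigma_c`` is
    the Gaussian cluster spread of the Thomas process; ``interval_mortality``
    is the per-interval death probability (default matches ~2%/yr compounded
    over 5 years).
    """

    n_species: int = 300
    logser_p: float = 0.9976
    mean_offspring_per_parent: float = 20.0
    sigma_c: float = 10.0
    width: float = 1000.0
    height: float = 500.0
    n_censuses: int = 5
    interval_years: float = 5.0
    interval_mortality: float = 0.096
    recruit_d_m: float = 30.0
    recruit_d_sd: float = 40.0
    dbh_scale_mm: float = 150.0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_censuses < 1:
            raise ValueError("n_species and n_censuses must be >= 1")
        if not 0.0 < self.logser_p < 1.0:
            raise ValueError("logser_p must lie in (0, 1)")
        if not 0.0 <= self.interval_mortality < 1.0:
            raise ValueError("interval_mortality must lie in [0, 1)")
        if min(self.sigma_c, self.width, self.height, self.interval_years) <= 0:
            raise ValueError("spatial and temporal scales must be positive")


def _truncated_dbh(n: int, spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    """Left-truncated adult stem diameters: 100 mm + exponential tail."""
    return 100.0 + rng.exponential(spec.dbh_scale_mm, n)


def generate_clustered_community(
    spec: FixtureSpec = FixtureSpec(), rng: np.random.Generator | int | None = None
) -> Census:
    """Multi-species clustered census: logseries abundances, Thomas clusters.

    Each species gets a Poisson number of uniformly placed cluster parents and
    its individuals scatter around uniformly assigned parents with isotropic
    Gaussian offsets (s.d. ``sigma_c``); offsets falling outside the plot are
    redrawn so clusters stay intact near edges.
    """
    rng = np.random.default_rng(rng)
    abundances = stats.logser.rvs(spec.logser_p, size=spec.n_species, random_state=rng)
    abundances = np.maximum(abundances, 1)

    xs, ys, sps = [], [], []
    for s, n_s in enumerate(abundances):
        n_parents = 1 + rng.poisson(n_s / spec.mean_offspring_per_parent)
        px = rng.uniform(0.0, spec.width, n_parents)
        py = rng.uniform(0.0, spec.height, n_parents)
        assign = rng.integers(0, n_parents, n_s)
        x = np.empty(n_s)
        y = np.empty(n_s)
        pending = np.arange(n_s)
        while pending.size:
            cand_x = px[assign[pending]] + rng.normal(0.0, spec.sigma_c, pending.size)
            cand_y = py[assign[pending]] + rng.normal(0.0, spec.sigma_c, pending.size)
            ok = (cand_x >= 0) & (cand_x < spec.width) & (cand_y >= 0) & (cand_y < spec.height)
            x[pending[ok]] = cand_x[ok]
            y[pending[ok]] = cand_y[ok]
            pending = pending[~ok]
        xs.append(x)
        ys.append(y)
        sps.append(np.full(n_s, f"sp{s:04d}"))

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    sp = np.concatenate(sps)
    n = len(x)
    return Census(
        x=np.round(x, 2),
        y=np.round(y, 2),
        species=sp,
        width=spec.width,
        height=spec.height,
        ids=np.array([f"t{i:06d}" for i in range(n)]),
        dbh=_truncated_dbh(n, spec, rng),
    )


def generate_pseudo_census_series(
    base: Census,
    spec: FixtureSpec = FixtureSpec(),
    rng: np.random.Generator | int | None = None,
) -> list[Census]:
    """Census time series with id-tracked turnover at constant population size.

    Each interval kills every tree independently with probability
    ``interval_mortality`` and adds equally many recruits: new ids, mother
    species inherited, location from the log-normal recruitment kernel around
    a uniformly chosen surviving mother.
    """
    if base.ids is None:
        raise ValueError("base census needs tree ids for survival tracking")
    rng = np.random.default_rng(rng)
    arena = Arena(base.width, base.height)
    mu_log, sigma_log = lognormal_kernel_params(spec.recruit_d_m, spec.recruit_d_sd)
    censuses = [base]
    current = base
    next_id = base.n
    for _ in range(spec.n_censuses - 1):
        survive = rng.random(current.n) >= spec.interval_mortality
        n_dead = int((~survive).sum())
        sx, sy, ssp = current.x[survive], current.y[survive], current.species[survive]
        sid = current.ids[survive]
        sdbh = current.dbh[survive] if current.dbh is not None else None
        if n_dead and sx.size:
            mothers = rng.integers(0, sx.size, n_dead)
            rx, ry = _recruit_positions(
                sx[mothers], sy[mothers], mu_log, sigma_log, arena, rng, sx, sy
            )
            new_ids = np.array([f"t{next_id + i:06d}" for i in range(n_dead)])
            next_id += n_dead
            current = Census(
                x=np.round(np.concatenate([sx, rx]), 2),
                y=np.round(np.concatenate([sy, ry]), 2),
                species=np.concatenate([ssp, ssp[mothers]]),
                width=base.width,
                height=base.height,
                ids=np.concatenate([sid, new_ids]),
                dbh=np.concatenate([sdbh, _truncated_dbh(n_dead, spec, rng)])
                if sdbh is not None
                else None,
            )
        else:
            current = Census(
                x=sx.copy(), y=sy.copy(), species=ssp.copy(),
                width=base.width, height=base.height, ids=sid.copy(),
                dbh=None if sdbh is None else sdbh.copy(),
            )
        censuses.append(current)
    return censuses
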