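"""Cell-cycle compartment model of ESC -> 2CLC fate transitions.

Cells traverse G1 -> S -> G2/M with fixed phase durations; while in phase p
they convert to the 2-cell-like state with a constant hazard f_p (per hour).
For a cohort with initial cycle-age density rho(a) set by the
synchronization design, the expected converted fraction after time t is

    fraction(t) = Int rho(a) * [1 - exp(-Int_0^t f_phase(a+s) ds)] da,

with the inner integral evaluated exactly piecewise (the hazard is constant
within each phase; ages wrap around the cycle).  The model horizon is one
cycle length: both fates divide, so fractions are unchanged by division and
no division bookkeeping is done.

Because short time courses expose the phases asymmetrically, single designs
leave rate directions unidentified; `fit_feasible_region` therefore maps the
whole set of rate triples compatible with the data (a chi-square-style SSE
acceptance band around the grid minimum) and projects it onto the ratio
plane (f_G1/f_S, f_G2M/f_S) whose axis intercepts summarize phase dominance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellCycleParams",
    "TransitionRates",
    "TimeCourse",
    "FeasibleRegion",
    "GridSpec",
    "DESIGNS",
    "predict_timecourse",
    "fit_feasible_region",
    "summarize_dominance",
]

DESIGNS = ("g1s_release", "g1_sort", "g2m_release", "asynchronous")

_GH_NODES = 7  # Gauss-Hermite nodes for the optional phase-duration dispersion


@dataclass(frozen=True)
class CellCycleParams:
    """Phase durations in hours (optionally with a lognormal dispersion of
    the overall cycle speed, s.d. in hours on the cycle length)."""

    t_g1: float = 3.0
    t_s: float = 6.0
    t_g2m: float = 3.0
    dispersion_h: float = 0.0

    def __post_init__(self) -> None:
        if self.t_s <= 0 or self.t_g1 < 0 or self.t_g2m < 0:
            raise ValueError("phase durations must be non-negative with T_S > 0")

    @property
    def t_cycle(self) -> float:
        return self.t_g1 + self.t_s + self.t_g2m

    def boundaries(self) -> np.ndarray:
        return np.array([0.0, self.t_g1, self.t_g1 + self.t_s, self.t_cycle])


@dataclass(frozen=True)
class TransitionRates:
    """Phase-specific conversion hazards in 1/h."""

    f_g1: float
    f_s: float
    f_g2m: float

    def __post_init__(self) -> None:
        if min(self.f_g1, self.f_s, self.f_g2m) < 0:
            raise ValueError("hazards must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.f_g1, self.f_s, self.f_g2m])


@dataclass
class TimeCourse:
    """Observed or predicted 2CLC-fraction time course for one design."""

    times_h: np.ndarray
    fraction: np.ndarray
    design: str
    n_cells: int | None = None
    replicate: int = 0
    phase_fractions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if np.any(np.diff(self.times_h) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class FeasibleRegion:
    """Grid of evaluated rate triples with fit error and the accepted subset."""

    grid: np.ndarray  # (n, 3) triples (f_g1, f_s, f_g2m)
    sse: np.ndarray
    threshold: float
    accepted: np.ndarray  # boolean mask over grid
    ratio_points: np.ndarray  # (m, 2) (f_g1/f_s, f_g2m/f_s) for accepted triples
    boundary: np.ndarray  # Pareto frontier polyline of the ratio set
    x_intercept: float  # max feasible f_g1/f_s
    y_intercept: float  # max feasible f_g2m/f_s
    sigma_hat: float = np.nan

    def accepted_triples(self) -> np.ndarray:
        return self.grid[self.accepted]


# ---------------------------------------------------------------------------
# phase occupancy


def phase_occupancy(age_h: float, t_h: float, cycle: CellCycleParams) -> np.ndarray:
    """Exact time spent in (G1, S, G2M) when progressing from cycle age
    ``age_h`` for duration ``t_h``, wrapping through the cycle."""
    b = cycle.boundaries()
    tc = cycle.t_cycle
    occ = np.zeros(3)
    a = age_h % tc
    remaining = t_h
    while remaining > 1e-12:
        phase = int(np.searchsorted(b, a, side="right")) - 1
        phase = min(phase, 2)
        to_boundary = b[phase + 1] - a
        step = min(remaining, to_boundary)
        occ[phase] += step
        remaining -= step
        a = (a + step) % tc
    return occ


def _initial_ages(design: str, cycle: CellCycleParams, n_nodes: int = 64):
    """Initial cycle-age nodes and weights for each synchronization design."""
    if design == "g1s_release":
        return np.array([cycle.t_g1]), np.array([1.0])
    if design == "g2m_release":
        return np.array([0.0]), np.array([1.0])  # cycle end == G1 entry
    if design == "g1_sort":
        lo, hi = 0.0, cycle.t_g1
    elif design == "asynchronous":
        lo, hi = 0.0, cycle.t_cycle
    else:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    # midpoint rule on a uniform age density
    edges = np.linspace(lo, hi, n_nodes + 1)
    ages = 0.5 * (edges[:-1] + edges[1:])
    weights = np.full(n_nodes, 1.0 / n_nodes)
    return ages, weights


def occupancy_tensor(
    design: str, times_h: np.ndarray, cycle: CellCycleParams, n_nodes: int = 64
):
    """Phase occupancies D[time, age_node, phase] plus age weights."""
    ages, weights = _initial_ages(design, cycle, n_nodes)
    D = np.empty((len(times_h), len(ages), 3))
    for i, t in enumerate(times_h):
        for j, a in enumerate(ages):
            D[i, j] = phase_occupancy(a, t, cycle)
    return D, weights


def _dispersion_factors(cycle: CellCycleParams):
    """Lognormal cycle-speed factors and weights (Gauss-Hermite)."""
    if cycle.dispersion_h <= 0:
        return np.array([1.0]), np.array([1.0])
    cv = cycle.dispersion_h / cycle.t_cycle
    sigma = np.sqrt(np.log1p(cv**2))
    x, w = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    factors = np.exp(sigma * x - 0.5 * sigma**2)
    return factors, w / w.sum()


def predict_timecourse(
    rates: TransitionRates,
    cycle: CellCycleParams,
    design: str,
    times_h,
    n_nodes: int = 64,
) -> TimeCourse:
    """Expected 2CLC fraction over time for one synchronization design.

    Monotone non-decreasing in time and in each hazard.  Times beyond one
    cycle length raise (no division bookkeeping past the model horizon).
    """
    times_h = np.asarray(times_h, dtype=float)
    if np.any(times_h < 0):
        raise ValueError("times must be non-negative")
    if np.any(times_h > cycle.t_cycle + 1e-9):
        raise ValueError("times beyond one cell-cycle length are outside the model horizon")
    f = rates.as_array()
    factors, wdisp = _dispersion_factors(cycle)
    frac = np.zeros(len(times_h))
    phase_frac = np.zeros((len(times_h), 3))
    for fac, wd in zip(factors, wdisp):
        scaled = CellCycleParams(
            cycle.t_g1 * fac, cycle.t_s * fac, cycle.t_g2m * fac, 0.0
        )
        ages, weights = _initial_ages(design, scaled, n_nodes)
        D, _ = occupancy_tensor(design, times_h, scaled, n_nodes)
        frac += wd * np.einsum("j,ij->i", weights, 1.0 - np.exp(-D @ f))
        # phase composition of the cohort at each time
        b = scaled.boundaries()
        for i, t in enumerate(times_h):
            pos = (ages + t) % scaled.t_cycle
            idx = np.clip(np.searchsorted(b, pos, side="right") - 1, 0, 2)
            for p in range(3):
                phase_frac[i, p] += wd * weights[idx == p].sum()
    pf = pd.DataFrame(phase_frac, columns=["frac_g1", "frac_s", "frac_g2m"])
    return TimeCourse(times_h, np.clip(frac, 0.0, 1.0), design, phase_fractions=pf)


# ---------------------------------------------------------------------------
# feasible-region fit


@dataclass(frozen=True)
class GridSpec:
    n: int = 41
    f_min: float = 1e-4
    f_max: float = 1.0

    def axis(self) -> np.ndarray:
        return np.geomspace(self.f_min, self.f_max, self.n)


def _predictions_for_grid(axis, observed, cycle, n_nodes, batch=4096):
    """SSE of every grid triple against all observed points jointly."""
    by_design: dict[str, list[TimeCourse]] = {}
    for tc in observed:
        by_design.setdefault(tc.design, []).append(tc)
    tensors = []
    for design, tcs in by_design.items():
        times = tcs[0].times_h
        for tc in tcs[1:]:
            if not np.array_equal(tc.times_h, times):
                raise ValueError("replicates of one design must share a time grid")
        D, w = occupancy_tensor(design, times, cycle, n_nodes)
        obs = np.stack([tc.fraction for tc in tcs])  # (reps, n_times)
        tensors.append((D, w, obs))
    g1, g2, g3 = np.meshgrid(axis, axis, axis, indexing="ij")
    grid = np.column_stack([g1.ravel(), g2.ravel(), g3.ravel()])  # (N, 3)
    sse = np.zeros(len(grid))
    for start in range(0, len(grid), batch):
        F = grid[start : start + batch]  # (B, 3)
        total = np.zeros(len(F))
        for D, w, obs in tensors:
            expo = np.einsum("taj,bj->bta", D, F)  # (B, n_times, n_ages)
            pred = 1.0 - np.einsum("a,bta->bt", w, np.exp(-expo))  # (B, n_times)
            resid = pred[:, None, :] - obs[None, :, :]  # (B, reps, n_times)
            total += np.einsum("brt,brt->b", resid, resid)
        sse[start : start + batch] = total
    return grid, sse


def _replicate_sigma(observed: list[TimeCourse]) -> float:
    """Pooled replicate scatter; falls back to binomial error when there are
    no replicated (design, time) points."""
    frames = {}
    for tc in observed:
        frames.setdefault(tc.design, []).append(tc)
    variances = []
    for tcs in frames.values():
        if len(tcs) < 2:
            continue
        obs = np.stack([tc.fraction for tc in tcs])
        variances.append(obs.var(axis=0, ddof=1))
    if variances:
        return float(np.sqrt(np.mean(np.concatenate(variances))))
    # binomial fallback
    p = np.concatenate([tc.fraction for tc in observed])
    n = max((tc.n_cells or 1000) for tc in observed)
    return float(np.sqrt(np.mean(p * (1 - p)) / n))


def _pareto_frontier(points: np.ndarray) -> np.ndarray:
    """Upper-right frontier of a 2-D point set (max x and y simultaneously)."""
    if len(points) == 0:
        return points
    order = np.argsort(points[:, 0])[::-1]
    frontier = []
    best_y = -np.inf
    for idx in order:
        x, y = points[idx]
        if y > best_y:
            frontier.append((x, y))
            best_y = y
    return np.asarray(frontier[::-1])


def fit_feasible_region(
    observed: list[TimeCourse],
    cycle: CellCycleParams,
    grid: GridSpec | None = None,
    z: float = 1.96,
    n_nodes: int = 64,
) -> FeasibleRegion:
    """Map the set of rate triples compatible with the observed time courses.

    For each grid triple the SSE against all observed curves jointly is
    computed; the accepted set is {theta : SSE <= SSE_min + delta} with
    delta = z^2 * sigma_hat^2 * N (N observed points, sigma_hat from
    replicate scatter).  The accepted set is projected onto the ratio plane
    (f_G1/f_S, f_G2M/f_S); the reported intercepts are the maximal feasible
    ratios, i.e. where the frontier cuts the axes.
    """
    if not observed:
        raise ValueError("at least one observed time course is required")
    grid = grid or GridSpec()
    axis = grid.axis()
    triples, sse = _predictions_for_grid(axis, observed, cycle, n_nodes)
    n_points = sum(len(tc.times_h) for tc in observed)
    sigma = _replicate_sigma(observed)
    delta = z**2 * sigma**2 * n_points
    threshold = float(sse.min() + delta)
    accepted = sse <= threshold
    if not accepted.any():
        raise ValueError("no compatible rates; widen grid or tolerance")
    acc = triples[accepted]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.column_stack([acc[:, 0] / acc[:, 1], acc[:, 2] / acc[:, 1]])
    ratios = ratios[np.isfinite(ratios).all(axis=1)]
    boundary = _pareto_frontier(ratios)
    return FeasibleRegion(
        grid=triples,
        sse=sse,
        threshold=threshold,
        accepted=accepted,
        ratio_points=ratios,
        boundary=boundary,
        x_intercept=float(ratios[:, 0].max()),
        y_intercept=float(ratios[:, 1].max()),
        sigma_hat=sigma,
    )


def summarize_dominance(region: FeasibleRegion) -> dict[str, object]:
    """S-phase-dominance verdict: both maximal feasible ratios below 1 means
    f_G1, f_G2M < f_S over the whole compatible set."""
    if not region.accepted.any():
        raise ValueError("empty feasible region")
    s_dominant = bool(region.x_intercept < 1.0 and region.y_intercept < 1.0)
    return {
        "x_intercept": region.x_intercept,
        "y_intercept": region.y_intercept,
        "s_dominant": s_dominant,
    }
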