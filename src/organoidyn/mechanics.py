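"""Mechanical 3D agent-based model of a single-layered spherical organoid.

Cells are point agents with a radius, arranged as a closed monolayer around a
fluid-filled lumen.  Each cell moves in overdamped dynamics under three forces:

1. linear springs along neighbour edges of the shell (cell-cell adhesion and
   volume exclusion),
2. the lumen pressure pushing every cell outwards along the radial direction,
   with the pressure given by an ideal-gas / van 't Hoff law ``P = kappa*n/V``
   for the amount ``n`` of osmotically active substance in the lumen,
3. a harmonic surface-bending restoring force toward the instantaneous
   best-fit sphere, which keeps the monolayer spherical without resisting
   uniform inflation.

Cells secrete substance into the lumen at a constant per-cell rate ``J_in``.
When the mean neighbour distance exceeds a rupture threshold the shell tears
open and substance leaks out at rate ``J_out`` until the shell relaxes below a
reseal threshold.  The interplay of secretion, division (which adds surface)
and rupture produces the inflation--deflation size oscillations that the
package analyses downstream.

Positions follow the Euler--Maruyama discretisation of the overdamped SDE

    dx_i = F_i / gamma * dt + sigma * sqrt(dt) * dW_i

Units are micrometres and hours throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.spatial._qhull import QhullError

from .errors import GeometryError, IntegrationError

logger = logging.getLogger(__name__)

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

# Mean hull-edge length of N quasi-uniform points on a sphere of radius R is
# close to sqrt(8*pi/sqrt(3)) * R / sqrt(N); inverting gives the radius at
# which the mean edge equals the spring rest length.
_PACKING = math.sqrt(math.sqrt(3.0) / (8.0 * math.pi))


def radius_for_count(n_cells: int, rest_length: float) -> float:
    """Sphere radius at which ``n_cells`` hull cells sit ~``rest_length`` apart."""
    return rest_length * math.sqrt(n_cells) * _PACKING


def fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """Quasi-uniform Fibonacci lattice of ``n`` points on a sphere."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = i * _GOLDEN_ANGLE
    pts = radius * np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    # recentre on the cloud's own centroid and re-project so that every point
    # sits at exactly `radius` from the centroid
    for _ in range(80):
        pts = pts - pts.mean(axis=0)
        pts *= radius / np.linalg.norm(pts, axis=1, keepdims=True)
        if np.abs(pts.mean(axis=0)).max() < 1e-9 * max(radius, 1.0):
            break
    return pts


def hull_edges(positions: np.ndarray) -> set[tuple[int, int]]:
    """Neighbour edges from convex-hull (spherical Delaunay) adjacency."""
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 4:
        raise GeometryError(
            f"need at least 4 points for a convex hull, got {len(positions)}"
        )
    try:
        hull = ConvexHull(positions)
    except QhullError as exc:  # coplanar / duplicate degenerate input
        raise GeometryError(f"degenerate point configuration: {exc}") from exc
    edges: set[tuple[int, int]] = set()
    for simplex in hull.simplices:
        for a, b in combinations(simplex.tolist(), 2):
            edges.add((a, b) if a < b else (b, a))
    return edges


@dataclass(frozen=True)
class Cell:
    """A single agent: identifier, 3D position (µm) and radius (µm)."""

    id: int
    position: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.isfinite(pos).all():
            raise ValueError(f"cell {self.id}: position must be a finite 3-vector")
        if not self.radius > 0:
            raise ValueError(f"cell {self.id}: radius must be positive")
        object.__setattr__(self, "position", pos)


@dataclass
class SimulationParams:
    """Mechanical, osmotic and integration constants (µm / hours).

    ``kappa`` lumps the van 't Hoff factor, gas constant and temperature into
    a single pressure-conversion constant, so ``P = kappa * n / V``.
    """

    k_spring: float = 1.0        # spring constant, force/µm
    ell0: float = 10.0           # spring rest length ~ cell diameter, µm
    k_bend: float = 1.0          # sphere-restoring stiffness, force/µm
    kappa: float = 1.0           # pressure per (substance/µm³)
    j_in: float = 2.0            # substance secreted per cell per hour
    j_out: float = 1000.0        # substance leak rate while ruptured, per hour
    ell_rupture: float = 13.0    # rupture threshold on mean neighbour distance, µm
    ell_seal: float = 11.0       # reseal threshold, µm
    gamma: float = 1.0           # drag, force·h/µm
    sigma: float = 0.05          # positional noise amplitude, µm/sqrt(h)
    dt: float = 0.01             # timestep, h
    seed: int = 0
    rebuild_every: int = 5       # hull-adjacency rebuild cadence, steps
    start_pressure_fraction: float = 0.1   # initial P relative to rupture scale
    division_offset: float = 0.2           # daughter offset in units of parent radius
    pressure_coupled_outflux: bool = False # leak rate ∝ pressure instead of constant

    def __post_init__(self) -> None:
        positive = {
            "k_spring": self.k_spring, "ell0": self.ell0, "kappa": self.kappa,
            "ell_rupture": self.ell_rupture, "ell_seal": self.ell_seal,
            "gamma": self.gamma, "dt": self.dt, "rebuild_every": self.rebuild_every,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name, value in {"k_bend": self.k_bend, "j_in": self.j_in,
                            "j_out": self.j_out, "sigma": self.sigma}.items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if not self.ell_seal < self.ell_rupture:
            raise ValueError("ell_seal must be smaller than ell_rupture")
        # documented explicit-Euler stability heuristic
        bound = self.gamma / (4.0 * self.k_spring)
        if self.dt > bound:
            raise ValueError(
                f"dt={self.dt} exceeds the stability bound gamma/(4*k_spring)={bound}"
            )


@dataclass
class DivisionSchedule:
    """Cell-division dynamics driving the realised cell count N(t).

    Modes: ``exponential`` (per-cell rate ``rate``), ``linear`` (``slope``
    cells/hour), ``piecewise_exp_linear`` (exponential until ``t_star`` then
    linear) and ``table`` (linear interpolation of target counts, tracked
    exactly).  Rate modes draw Poisson division counts per step unless
    ``deterministic`` is set, in which case the expected count is tracked and
    realised by rounding.
    """

    mode: str = "linear"
    rate: float = 0.0            # per cell per hour (exponential modes)
    slope: float = 0.0           # cells per hour (linear modes)
    t_star: float | None = None  # exponential→linear transition time, h
    table: Sequence[tuple[float, float]] | None = None
    deterministic: bool = False

    _MODES = ("exponential", "linear", "piecewise_exp_linear", "table")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"unknown division mode {self.mode!r}")
        if self.rate < 0 or self.slope < 0:
            raise ValueError("division rates must be non-negative")
        if self.mode == "piecewise_exp_linear" and self.t_star is None:
            raise ValueError("piecewise_exp_linear requires t_star")
        if self.mode == "table":
            if not self.table:
                raise ValueError("table mode requires a (time, count) table")
            counts = [c for _, c in self.table]
            if any(b < a for a, b in zip(counts, counts[1:])):
                raise ValueError("table target counts must be non-decreasing")

    def instantaneous_rate(self, t: float, n_cells: int) -> float:
        """Expected divisions per hour at time ``t`` with ``n_cells`` cells."""
        if self.mode == "exponential":
            return self.rate * n_cells
        if self.mode == "linear":
            return self.slope
        if self.mode == "piecewise_exp_linear":
            if t <= self.t_star:
                return self.rate * n_cells
            return self.slope
        raise ValueError("table mode has no instantaneous rate")

    def target_count(self, t: float) -> int:
        """Interpolated target cell count (table mode only)."""
        ts = np.array([p[0] for p in self.table], dtype=float)
        cs = np.array([p[1] for p in self.table], dtype=float)
        return int(round(float(np.interp(t, ts, cs))))


@dataclass
class OrganoidState:
    """Full simulator state: cell positions, lumen content and seal status."""

    time: float
    positions: np.ndarray            # (N, 3) µm
    radii: np.ndarray                # (N,) µm
    n: float                         # lumen substance amount, arbitrary moles
    v_lumen: float                   # lumen volume, µm³
    sealed: bool
    neighbour_edges: set[tuple[int, int]] = field(default_factory=set)
    step_count: int = 0
    ruptured_last_step: bool = False
    last_noise: np.ndarray | None = None
    growth_expectation: float | None = None  # deterministic-schedule accumulator

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.positions)

    @property
    def centre(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    @property
    def r_fit(self) -> float:
        """Radius of the best-fit sphere: mean cell–centre distance."""
        return float(np.linalg.norm(self.positions - self.centre, axis=1).mean())

    @property
    def cells(self) -> list[Cell]:
        return [Cell(i, p, r) for i, (p, r) in enumerate(zip(self.positions, self.radii))]

    def pressure(self, params: SimulationParams) -> float:
        return params.kappa * self.n / self.v_lumen

    def edge_array(self) -> np.ndarray:
        return np.array(sorted(self.neighbour_edges), dtype=int).reshape(-1, 2)

    def mean_neighbour_distance(self) -> float:
        edges = self.edge_array()
        if len(edges) == 0:
            return 0.0
        d = self.positions[edges[:, 1]] - self.positions[edges[:, 0]]
        return float(np.linalg.norm(d, axis=1).mean())

    # -- maintenance --------------------------------------------------------
    def rebuild_edges(self) -> None:
        self.neighbour_edges = hull_edges(self.positions)

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("lumen substance amount must be non-negative")
        if not self.v_lumen > 0:
            raise ValueError("lumen volume must be positive")
        if not np.isfinite(self.positions).all():
            raise ValueError("cell positions must be finite")
        if (self.radii <= 0).any():
            raise ValueError("cell radii must be positive")
        n = self.n_cells
        for a, b in self.neighbour_edges:
            if a == b:
                raise ValueError(f"self-edge ({a},{b}) in neighbour graph")
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"edge ({a},{b}) references a missing cell")

    def copy(self) -> "OrganoidState":
        return replace(
            self,
            positions=self.positions.copy(),
            radii=self.radii.copy(),
            neighbour_edges=set(self.neighbour_edges),
            last_noise=None if self.last_noise is None else self.last_noise.copy(),
        )

    @classmethod
    def from_positions(
        cls,
        positions: np.ndarray,
        *,
        radius: float = 5.0,
        n: float = 0.0,
        sealed: bool = True,
        time: float = 0.0,
    ) -> "OrganoidState":
        """Build a state from explicit positions (hull adjacency, fitted volume)."""
        positions = np.asarray(positions, dtype=float)
        state = cls(
            time=time,
            positions=positions,
            radii=np.full(len(positions), float(radius)),
            n=n,
            v_lumen=1.0,
            sealed=sealed,
            neighbour_edges=hull_edges(positions),
        )
        state.v_lumen = (4.0 / 3.0) * math.pi * state.r_fit ** 3
        return state


def rupture_pressure_scale(n_cells: int, r0: float, params: SimulationParams) -> float:
    """Pressure at which springs stretched to the rupture threshold balance it.

    From the per-cell force balance ``P * 4*pi*R²/N = 3*k*l*(l - l0)/R`` with
    ``l = ell_rupture`` and the inflated radius ``R = r0 * ell_rupture/ell0``.
    Used only to set a sensible initial pressure.
    """
    stretch_radius = r0 * params.ell_rupture / params.ell0
    return (
        3.0 * params.k_spring * params.ell_rupture
        * (params.ell_rupture - params.ell0) * n_cells
        / (4.0 * math.pi * stretch_radius ** 3)
    )


def initialize_sphere(
    n0: int,
    r0: float,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
    jitter: float = 0.0,
) -> OrganoidState:
    """Seed ``n0`` cells quasi-uniformly on a sphere of radius ``r0``.

    The lumen starts sealed with substance set so that the initial pressure is
    ``params.start_pressure_fraction`` of the rupture-scale pressure.
    """
    if n0 < 4:
        raise GeometryError(f"need at least 4 cells to form a shell, got {n0}")
    if not r0 > 0:
        raise GeometryError(f"initial radius must be positive, got {r0}")
    positions = fibonacci_sphere(n0, r0)
    if jitter > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        noise = jitter * rng.standard_normal(positions.shape)
        radial = positions / np.linalg.norm(positions, axis=1, keepdims=True)
        noise -= (noise * radial).sum(axis=1, keepdims=True) * radial  # tangential
        positions = positions + noise
        positions *= r0 / np.linalg.norm(positions, axis=1, keepdims=True)
    v0 = (4.0 / 3.0) * math.pi * r0 ** 3
    p0 = params.start_pressure_fraction * rupture_pressure_scale(n0, r0, params)
    state = OrganoidState(
        time=0.0,
        positions=positions,
        radii=np.full(n0, params.ell0 / 2.0),
        n=p0 * v0 / params.kappa,
        v_lumen=v0,
        sealed=True,
        neighbour_edges=hull_edges(positions),
    )
    return state


def compute_forces(state: OrganoidState, params: SimulationParams) -> np.ndarray:
    """Per-cell force field: springs + lumen pressure + sphere-restoring term.

    The pressure acts on an equal area share ``a_i = 4*pi*R_fit²/N`` along the
    outward radial direction; the bending term is harmonic in the deviation of
    each cell's centre distance from the best-fit radius.
    """
    pos = state.positions
    n = len(pos)
    centre = pos.mean(axis=0)
    rvec = pos - centre
    rnorm = np.linalg.norm(rvec, axis=1)
    r_fit = rnorm.mean()
    safe = np.where(rnorm > 1e-12, rnorm, 1.0)
    rhat = rvec / safe[:, None]

    forces = np.zeros_like(pos)

    edges = state.edge_array()
    if len(edges):
        d = pos[edges[:, 1]] - pos[edges[:, 0]]     # i -> j
        length = np.linalg.norm(d, axis=1)
        tiny = length < 1e-9
        if tiny.any():
            logger.warning(
                "capping repulsion for %d degenerate cell pairs (distance < 1e-9)",
                int(tiny.sum()),
            )
            length = np.where(tiny, 1e-9, length)
        unit = d / length[:, None]
        extension = length - params.ell0
        extension[tiny] = -params.ell0              # capped maximum repulsion
        pair = params.k_spring * extension[:, None] * unit
        np.add.at(forces, edges[:, 0], pair)        # pulls i toward j if stretched
        np.add.at(forces, edges[:, 1], -pair)

    pressure = params.kappa * state.n / state.v_lumen
    area_share = 4.0 * math.pi * r_fit ** 2 / n
    forces += pressure * area_share * rhat
    forces += -params.k_bend * (rnorm - r_fit)[:, None] * rhat
    return forces


def update_lumen(
    state: OrganoidState, params: SimulationParams, dt: float
) -> OrganoidState:
    """Secretion, rupture/reseal switching and leak bookkeeping for one step.

    Order: constant per-cell influx; rupture check (sealed shells tear when the
    mean neighbour distance exceeds the rupture threshold); leakage while
    unsealed (floored at zero); reseal check; lumen volume refit.
    """
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    state.n += params.j_in * state.n_cells * dt
    mean_dist = state.mean_neighbour_distance()
    state.ruptured_last_step = False
    if state.sealed and mean_dist > params.ell_rupture:
        state.sealed = False
        state.ruptured_last_step = True
    if not state.sealed:
        if params.pressure_coupled_outflux:
            leak = params.j_out * state.pressure(params) * dt
        else:
            leak = params.j_out * dt
        state.n = max(0.0, state.n - leak)
        if mean_dist < params.ell_seal:
            state.sealed = True
    state.v_lumen = (4.0 / 3.0) * math.pi * state.r_fit ** 3
    return state


def _divisions_this_step(
    state: OrganoidState,
    schedule: DivisionSchedule,
    t: float,
    dt: float,
    rng: np.random.Generator,
) -> int:
    n = state.n_cells
    if schedule.mode == "table":
        return max(0, schedule.target_count(t) - n)
    if schedule.deterministic:
        if state.growth_expectation is None:
            state.growth_expectation = float(n)
        x = state.growth_expectation
        if schedule.mode == "exponential" or (
            schedule.mode == "piecewise_exp_linear" and t <= schedule.t_star
        ):
            x *= math.exp(schedule.rate * dt)
        else:
            x += schedule.slope * dt
        state.growth_expectation = x
        return max(0, int(math.floor(x)) - n)
    lam = schedule.instantaneous_rate(t, n) * dt
    if lam <= 0:
        return 0
    return int(rng.poisson(lam))


def _divide_one(
    state: OrganoidState, rng: np.random.Generator, offset_fraction: float
) -> None:
    n = state.n_cells
    parent = int(rng.integers(n))
    centre = state.centre
    radial = state.positions[parent] - centre
    norm = np.linalg.norm(radial)
    radial = radial / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0])
    while True:
        v = rng.standard_normal(3)
        v -= (v @ radial) * radial
        tnorm = np.linalg.norm(v)
        if tnorm > 1e-9:
            tangent = v / tnorm
            break
    rho = state.radii[parent]
    daughter = state.positions[parent] + offset_fraction * rho * tangent
    state.positions = np.vstack([state.positions, daughter])
    state.radii = np.append(state.radii, rho)  # no cell growth


def divide_cells(
    state: OrganoidState,
    schedule: DivisionSchedule,
    t: float,
    rng: np.random.Generator,
    offset_fraction: float = 0.2,
    dt: float | None = None,
) -> OrganoidState:
    """Realise the divisions due in ``(state.time, t]`` and rebuild adjacency.

    Daughters are placed at a small tangential offset from their parent with
    the same radius (cell growth is neglected).
    """
    if dt is None:
        dt = t - state.time
    if dt <= 0 and schedule.mode != "table":
        return state
    k = _divisions_this_step(state, schedule, t, dt, rng)
    for _ in range(k):
        _divide_one(state, rng, offset_fraction)
    if k:
        state.rebuild_edges()
    return state


def step(
    state: OrganoidState,
    params: SimulationParams,
    schedule: DivisionSchedule,
    rng: np.random.Generator,
) -> OrganoidState:
    """One Euler--Maruyama step: move, exchange substance, divide, advance time."""
    if state.step_count % params.rebuild_every == 0:
        state.rebuild_edges()
    forces = compute_forces(state, params)
    if not np.isfinite(forces).all():
        bad = int(np.argwhere(~np.isfinite(forces).all(axis=1))[0, 0])
        raise IntegrationError(
            f"non-finite force on cell {bad} at step {state.step_count} "
            f"(t={state.time:.4f} h); reduce dt or stiffness"
        )
    # drift and noise applied as separate additions so that the increment
    # decomposes exactly into drift + sigma*sqrt(dt)*xi
    state.positions = state.positions + forces / params.gamma * params.dt
    if params.sigma > 0:
        xi = rng.standard_normal(state.positions.shape)
        state.last_noise = xi
        state.positions = state.positions + params.sigma * math.sqrt(params.dt) * xi
    else:
        state.last_noise = None
    update_lumen(state, params, params.dt)
    divide_cells(
        state, schedule, state.time + params.dt, rng,
        offset_fraction=params.division_offset, dt=params.dt,
    )
    state.time += params.dt
    state.step_count += 1
    return state


@dataclass
class Trajectory:
    """Recorded per-step summaries of a simulation run."""

    time: np.ndarray
    n_cells: np.ndarray
    v_lumen: np.ndarray
    r_fit: np.ndarray
    n_substance: np.ndarray
    pressure: np.ndarray
    sealed: np.ndarray
    rupture_event: np.ndarray
    rupture_times: list[float] = field(default_factory=list)

    @property
    def n_ruptures(self) -> int:
        return len(self.rupture_times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.time,
                "N": self.n_cells,
                "V_lumen": self.v_lumen,
                "R_fit": self.r_fit,
                "n": self.n_substance,
                "sealed": self.sealed.astype(int),
                "rupture_event": self.rupture_event.astype(int),
                "pressure": self.pressure,
            }
        )


def simulate(
    params: SimulationParams,
    schedule: DivisionSchedule,
    t_end: float,
    n0: int = 64,
    r0: float | None = None,
    rng: np.random.Generator | None = None,
    record_every: int = 1,
    jitter: float = 0.0,
) -> Trajectory:
    """Run the model from a fresh spherical shell until ``t_end`` hours.

    ``r0`` defaults to the radius at which the initial cells sit one rest
    length apart.  Summaries are recorded every ``record_every`` steps, always
    including the initial and final states; ``rupture_times`` collects every
    seal-opening event regardless of the recording cadence.
    """
    if not t_end > 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if r0 is None:
        r0 = radius_for_count(n0, params.ell0)
    state = initialize_sphere(n0, r0, params, rng=rng, jitter=jitter)

    rows: list[tuple] = []
    rupture_times: list[float] = []

    def record(ruptured: bool) -> None:
        rows.append(
            (
                state.time, state.n_cells, state.v_lumen, state.r_fit,
                state.n, state.pressure(params), state.sealed, ruptured,
            )
        )

    record(False)
    n_steps = int(round(t_end / params.dt))
    ruptured_since_record = False
    for k in range(n_steps):
        step(state, params, schedule, rng)
        if state.ruptured_last_step:
            rupture_times.append(state.time)
            ruptured_since_record = True
        if (k + 1) % record_every == 0 or k == n_steps - 1:
            record(ruptured_since_record)
            ruptured_since_record = False

    cols = list(zip(*rows))
    return Trajectory(
        time=np.array(cols[0], dtype=float),
        n_cells=np.array(cols[1], dtype=int),
        v_lumen=np.array(cols[2], dtype=float),
        r_fit=np.array(cols[3], dtype=float),
        n_substance=np.array(cols[4], dtype=float),
        pressure=np.array(cols[5], dtype=float),
        sealed=np.array(cols[6], dtype=bool),
        rupture_event=np.array(cols[7], dtype=bool),
        rupture_times=rupture_times,
    )
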