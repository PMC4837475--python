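"""Overdamped active-particle dynamics in a walled, periodic channel.

The model: N self-propelled point particles obey

    γ dx_i/dt = F0 n̂_i + Σ_j F_ij + F_iw

where n̂_i = (cos θ_i, sin θ_i) is the propulsion direction, F_ij is the
truncated 12-6 Lennard-Jones pair force (well depth ε = cell–cell
adhesion), and F_iw is a short-ranged purely repulsive wall force acting
across the channel width.  The angle θ_i diffuses with rotational
diffusion rate D_r (Gaussian white noise), giving a persistent random
walk with persistence time 1/D_r.  In reflective mode a particle that
touches a wall additionally has its propulsion instantly reoriented
perpendicular to the wall, into the interior.  Equations are integrated
with the Euler–Maruyama scheme; the long (y) axis is periodic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
from numba import njit

from .params import ModelParameters

__all__ = [
    "ParticleState",
    "Trajectory",
    "SimulationInstabilityError",
    "CoincidentParticlesError",
    "pair_potential",
    "pair_force",
    "wall_potential",
    "wall_force",
    "update_orientation",
    "wrap_periodic",
    "minimal_image",
    "reflect_if_contacting",
    "net_forces",
    "euler_step",
    "initialize_positions",
    "particle_noise_streams",
    "run_simulation",
    "orientation_autocorrelation",
    "orientation_persistence_time",
]

EVENT_DTYPE = np.dtype([("time", "f8"), ("particle", "i8"), ("side", "i8")])
_ROOT6_2 = 2.0 ** (1.0 / 6.0)


class SimulationInstabilityError(RuntimeError):
    """Raised when a step moves a particle too far or produces non-finite
    coordinates — the integration step is too large for the configuration."""

    def __init__(self, step: int, particle: int, time: float):
        self.step = step
        self.particle = particle
        self.time = time
        super().__init__(
            f"integration unstable at t={time:g} min (step {step}, particle "
            f"{particle}): single-step displacement exceeded the guard or was "
            "non-finite; reduce dt or check the initial condition"
        )


class CoincidentParticlesError(ValueError):
    """Two particles at zero separation: the pair force is undefined."""


# ---------------------------------------------------------------------------
# state containers


@dataclass
class ParticleState:
    """Positions and propulsion orientations of all particles at one time.

    ``positions`` has shape (N, 2) with x across the channel width and y
    along the periodic axis; ``angles`` holds θ_i in radians relative to
    the x axis.
    """

    time: float
    positions: np.ndarray
    angles: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (N, 2)")
        if self.angles.shape != (self.positions.shape[0],):
            raise ValueError("angles must have shape (N,)")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "ParticleState":
        return ParticleState(self.time, self.positions.copy(), self.angles.copy())


@dataclass
class Trajectory:
    """Time-ordered frames of one simulation run.

    ``positions`` has shape (F, N, 2) and ``angles`` (F, N); ``events``
    is a structured array of reflective-reorientation events (time,
    particle, side) logged on wall-zone entry, and ``n_reflections``
    counts every reorientation including re-triggers.
    """

    parameters: ModelParameters
    times: np.ndarray
    positions: np.ndarray
    angles: np.ndarray
    save_interval: float
    events: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=EVENT_DTYPE))
    n_reflections: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.positions.shape[0] != self.times.size:
            raise ValueError("positions/times frame count mismatch")
        if self.positions.shape[1] != self.parameters.n_particles:
            raise ValueError("frame particle count does not match parameters")

    @property
    def n_frames(self) -> int:
        return self.times.size

    def frame(self, i: int) -> ParticleState:
        return ParticleState(float(self.times[i]), self.positions[i], self.angles[i])

    def frames(self) -> Iterator[ParticleState]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def window(self, t_start: float, t_end: float) -> "Trajectory":
        """Frames with t_start <= time <= t_end (order preserved)."""
        mask = (self.times >= t_start) & (self.times <= t_end)
        if not mask.any():
            raise ValueError(
                f"window [{t_start}, {t_end}] contains no frames "
                f"(trajectory spans [{self.times[0]}, {self.times[-1]}])"
            )
        ev = self.events
        if ev.size:
            ev = ev[(ev["time"] >= t_start) & (ev["time"] <= t_end)]
        return Trajectory(
            self.parameters,
            self.times[mask],
            self.positions[mask],
            self.angles[mask],
            self.save_interval,
            ev,
            self.n_reflections,
        )


# ---------------------------------------------------------------------------
# elementary operations


def wrap_periodic(y, length: float):
    """Map positions onto [0, length) along the periodic axis."""
    if length <= 0:
        raise ValueError("length must be > 0")
    w = np.mod(y, length)
    # fmod of a tiny negative value rounds to `length` itself
    return np.where(w >= length, 0.0, w) if np.ndim(w) else (0.0 if w >= length else w)


def minimal_image(dy, length: float):
    """Minimal-image displacement along the periodic axis (in (-L/2, L/2])."""
    if length <= 0:
        raise ValueError("length must be > 0")
    return dy - length * np.round(np.asarray(dy, dtype=float) / length)


def pair_potential(r, epsilon: float, sigma: float, cutoff: float):
    """Truncated 12-6 Lennard-Jones potential U(r) = 4ε[(σ/r)^12 − (σ/r)^6].

    Zero beyond ``cutoff`` (plain truncation, not shifted).
    """
    r = np.asarray(r, dtype=float)
    inside = (r > 0) & (r < cutoff)
    with np.errstate(divide="ignore", invalid="ignore"):
        s6 = np.where(inside, (sigma / np.where(inside, r, 1.0)) ** 6, 0.0)
    return 4.0 * epsilon * (s6 * s6 - s6)


def pair_force(r_vec, epsilon: float, sigma: float, cutoff: float):
    """Force on particle i from particle j, for displacement r_vec = x_i − x_j.

    −∇U of the truncated Lennard-Jones potential: repulsive (along
    +r_vec) below the minimum at 2^(1/6) σ, attractive between the
    minimum and the cutoff, zero beyond.  Antisymmetric under i↔j.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r2 = np.sum(r_vec * r_vec, axis=-1)
    if np.any(r2 == 0):
        raise CoincidentParticlesError(
            "zero pair separation: particles coincide (step too large or bad "
            "initial condition)"
        )
    inside = r2 < cutoff * cutoff
    safe_r2 = np.where(inside, r2, 1.0)
    s2 = sigma * sigma / safe_r2
    s6 = s2 * s2 * s2
    coef = np.where(inside, 24.0 * epsilon * (2.0 * s6 * s6 - s6) / safe_r2, 0.0)
    return coef[..., None] * r_vec


def _wall_scalar_force(s, epsilon_w: float, sigma_w: float, cap: float):
    """Repulsive WCA force at distance s from one wall, clamped at ``cap``.

    Monotonically non-increasing in s; equal to ``cap`` for s <= 0.
    """
    s = np.asarray(s, dtype=float)
    rng = _ROOT6_2 * sigma_w
    inside = (s > 0) & (s < rng)
    safe = np.where(s > 0, s, 1.0)
    s6 = (sigma_w / safe) ** 6
    f = np.where(inside, 24.0 * epsilon_w * (2.0 * s6 * s6 - s6) / safe, 0.0)
    f = np.where(s <= 0, cap, f)
    return np.minimum(f, cap)


def wall_potential(x, params: ModelParameters):
    """Scalar potential of both walls (unclamped WCA, shifted to 0 at range)."""
    x = np.asarray(x, dtype=float)
    total = np.zeros_like(x)
    for s in (x, params.channel_width - x):
        rng = params.wall_range
        inside = (s > 0) & (s < rng)
        safe = np.where(s > 0, s, 1.0)
        s6 = (params.wall_sigma / safe) ** 6
        u = np.where(inside, 4.0 * params.wall_epsilon * (s6 * s6 - s6) + params.wall_epsilon, 0.0)
        total = total + u
    return total


def wall_force(x, params: ModelParameters):
    """Scalar x-force from both walls: +ve pushes right, −ve pushes left.

    Zero in the interior beyond ``wall_range`` from either wall; the
    near-wall magnitude is clamped at ``wall_force_cap`` so overshoot
    past a wall still yields a finite restoring push.
    """
    x = np.asarray(x, dtype=float)
    f_left = _wall_scalar_force(x, params.wall_epsilon, params.wall_sigma, params.wall_force_cap)
    f_right = _wall_scalar_force(
        params.channel_width - x, params.wall_epsilon, params.wall_sigma, params.wall_force_cap
    )
    return f_left - f_right


def update_orientation(theta, dr: float, dt: float, noise_draw):
    """Euler–Maruyama update θ → θ + sqrt(2 D_r dt) ξ."""
    if dr < 0:
        raise ValueError("rotational diffusion rate must be >= 0")
    if dt < 0:
        raise ValueError("dt must be >= 0")
    return theta + math.sqrt(2.0 * dr * dt) * np.asarray(noise_draw, dtype=float)


def reflect_if_contacting(
    state: ParticleState, params: ModelParameters
) -> tuple[ParticleState, list[tuple[float, int, int]]]:
    """Reorient wall-contacting particles perpendicular to the wall.

    In reflective mode every particle within ``reflect_trigger`` of a
    wall has θ set to 0 (left wall, pointing +x) or π (right wall);
    others are untouched.  No-op in non-reflective mode.  Returns the
    new state and a list of (time, particle, side) events, side 0=left,
    1=right.
    """
    if params.boundary_mode != "reflective":
        return state, []
    new = state.copy()
    events: list[tuple[float, int, int]] = []
    trig = params.reflect_trigger
    for i in range(state.n_particles):
        x = state.positions[i, 0]
        if x < trig:
            new.angles[i] = 0.0
            events.append((state.time, i, 0))
        elif x > params.channel_width - trig:
            new.angles[i] = math.pi
            events.append((state.time, i, 1))
    return new, events


def net_forces(state: ParticleState, params: ModelParameters) -> np.ndarray:
    """Total force on every particle: motility + pairs + walls, shape (N, 2).

    Pair displacements use the minimal image along the periodic y axis.
    """
    n = state.n_particles
    f = params.motility_force * np.column_stack(
        (np.cos(state.angles), np.sin(state.angles))
    )
    if params.adhesion_epsilon > 0 and n > 1:
        dx = state.positions[:, 0][:, None] - state.positions[:, 0][None, :]
        dy = state.positions[:, 1][:, None] - state.positions[:, 1][None, :]
        dy = minimal_image(dy, params.channel_length)
        r2 = dx * dx + dy * dy
        np.fill_diagonal(r2, np.inf)
        if np.any(r2 == 0):
            raise CoincidentParticlesError("coincident particles in force evaluation")
        inside = r2 < params.lj_cutoff**2
        s2 = np.where(inside, params.lj_sigma**2 / np.where(inside, r2, 1.0), 0.0)
        s6 = s2 * s2 * s2
        coef = np.where(inside, 24.0 * params.adhesion_epsilon * (2.0 * s6 * s6 - s6), 0.0)
        coef = coef / np.where(inside, r2, 1.0)
        f[:, 0] += np.sum(coef * dx, axis=1)
        f[:, 1] += np.sum(coef * dy, axis=1)
    f[:, 0] += wall_force(state.positions[:, 0], params)
    return f


def euler_step(
    state: ParticleState,
    params: ModelParameters,
    rng: Optional[np.random.Generator] = None,
    noise: Optional[np.ndarray] = None,
) -> tuple[ParticleState, list[tuple[float, int, int]]]:
    """Advance one Euler step of the overdamped Langevin dynamics.

    Order of operations: forces from the current state move the
    positions by dt F/γ; y wraps periodically; orientations take their
    diffusion increment; reflective reorientation (if configured) is
    applied last.  Returns the new state and any reflection events.
    """
    if noise is None:
        if rng is None:
            raise ValueError("provide either rng or a noise array")
        noise = rng.standard_normal(state.n_particles)
    forces = net_forces(state, params)
    disp = (params.dt / params.drag_gamma) * forces
    step_len2 = np.sum(disp * disp, axis=1)
    bad = ~np.isfinite(step_len2) | (step_len2 > params.max_step_displacement**2)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise SimulationInstabilityError(-1, i, state.time)
    positions = state.positions + disp
    positions[:, 1] = wrap_periodic(positions[:, 1], params.channel_length)
    angles = update_orientation(state.angles, params.rotational_diffusion_dr, params.dt, noise)
    new = ParticleState(state.time + params.dt, positions, angles)
    new, events = reflect_if_contacting(new, params)
    return new, events


def initialize_positions(
    params: ModelParameters, rng: Optional[np.random.Generator] = None
) -> ParticleState:
    """Uniform random non-overlapping initial condition.

    Particles are placed one at a time, uniformly in the channel, and a
    draw is rejected while any minimal-image pair distance falls below
    ``min_init_distance``.  Angles are uniform on [0, 2π).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_particles
    max_attempts = 10_000 * n
    pos = np.empty((n, 2))
    placed = 0
    attempts = 0
    while placed < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not place particles without overlap: channel too crowded"
            )
        cand = np.array(
            [
                rng.uniform(0.0, params.channel_width),
                rng.uniform(0.0, params.channel_length),
            ]
        )
        if placed:
            dx = pos[:placed, 0] - cand[0]
            dy = minimal_image(pos[:placed, 1] - cand[1], params.channel_length)
            if np.any(dx * dx + dy * dy < params.min_init_distance**2):
                continue
        pos[placed] = cand
        placed += 1
    angles = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return ParticleState(0.0, pos, angles)


# ---------------------------------------------------------------------------
# jitted integrator


@njit(cache=False)
def _wall_f_nb(s: float, eps_w: float, sigma_w: float, cap: float) -> float:
    if s <= 0.0:
        return cap
    rng = 1.122462048309373 * sigma_w
    if s >= rng:
        return 0.0
    s6 = (sigma_w / s) ** 6
    f = 24.0 * eps_w * (2.0 * s6 * s6 - s6) / s
    if f > cap:
        return cap
    return f


@njit(cache=False)
def _run_kernel(
    px,
    py,
    th,
    noise,
    n_steps,
    dt,
    gamma,
    f0,
    dr,
    eps,
    sigma,
    rcut,
    width,
    length,
    eps_w,
    sigma_w,
    cap_w,
    reflective,
    trigger,
    save_every,
    max_disp,
    out_x,
    out_y,
    out_th,
    ev_time,
    ev_part,
    ev_side,
):
    n = px.shape[0]
    rcut2 = rcut * rcut
    sig2 = sigma * sigma
    amp = (2.0 * dr * dt) ** 0.5
    inv_g = dt / gamma
    max_disp2 = max_disp * max_disp
    ev_cap = ev_time.shape[0]
    n_ev = 0
    n_refl = 0
    in_zone = np.zeros(n, dtype=np.int8)
    fx = np.empty(n)
    fy = np.empty(n)
    # frame 0 is the initial state
    for i in range(n):
        out_x[0, i] = px[i]
        out_y[0, i] = py[i]
        out_th[0, i] = th[i]
    frame = 1
    for step in range(n_steps):
        for i in range(n):
            fx[i] = f0 * np.cos(th[i])
            fy[i] = f0 * np.sin(th[i])
        if eps > 0.0:
            for i in range(n - 1):
                for j in range(i + 1, n):
                    dxp = px[i] - px[j]
                    dyp = py[i] - py[j]
                    dyp -= length * np.round(dyp / length)
                    r2 = dxp * dxp + dyp * dyp
                    if r2 < rcut2:
                        s2 = sig2 / r2
                        s6 = s2 * s2 * s2
                        coef = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
                        fx[i] += coef * dxp
                        fy[i] += coef * dyp
                        fx[j] -= coef * dxp
                        fy[j] -= coef * dyp
        for i in range(n):
            fx[i] += _wall_f_nb(px[i], eps_w, sigma_w, cap_w)
            fx[i] -= _wall_f_nb(width - px[i], eps_w, sigma_w, cap_w)
        for i in range(n):
            ddx = inv_g * fx[i]
            ddy = inv_g * fy[i]
            d2 = ddx * ddx + ddy * ddy
            if not np.isfinite(d2) or d2 > max_disp2:
                return frame, n_ev, n_refl, step, i
            px[i] += ddx
            py[i] += ddy
            py[i] = py[i] % length
            th[i] += amp * noise[step, i]
        if reflective:
            for i in range(n):
                if px[i] < trigger:
                    th[i] = 0.0
                    n_refl += 1
                    if in_zone[i] != 1:
                        if n_ev < ev_cap:
                            ev_time[n_ev] = (step + 1) * dt
                            ev_part[n_ev] = i
                            ev_side[n_ev] = 0
                            n_ev += 1
                    in_zone[i] = 1
                elif px[i] > width - trigger:
                    th[i] = np.pi
                    n_refl += 1
                    if in_zone[i] != 2:
                        if n_ev < ev_cap:
                            ev_time[n_ev] = (step + 1) * dt
                            ev_part[n_ev] = i
                            ev_side[n_ev] = 1
                            n_ev += 1
                    in_zone[i] = 2
                else:
                    in_zone[i] = 0
        if (step + 1) % save_every == 0:
            for i in range(n):
                out_x[frame, i] = px[i]
                out_y[frame, i] = py[i]
                out_th[frame, i] = th[i]
            frame += 1
    return frame, n_ev, n_refl, -1, -1


def particle_noise_streams(seed: int, n_particles: int):
    """Deterministic per-particle noise substreams.

    Returns ``(init_seq, particle_seqs)``: the first spawned child of
    ``SeedSequence(seed)`` seeds the initial condition, the next
    ``n_particles`` children seed the angular-noise stream of each
    particle.  Because streams are per particle, an N-particle run at
    ε=0 (far from walls) factorises exactly into N single-particle runs
    driven by the same substreams.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_particles + 1)
    return children[0], children[1:]


def _generate_noise(particle_seqs, n_steps: int) -> np.ndarray:
    noise = np.empty((n_steps, len(particle_seqs)))
    for i, seq in enumerate(particle_seqs):
        noise[:, i] = np.random.default_rng(seq).standard_normal(n_steps)
    return noise


def run_simulation(
    params: ModelParameters,
    initial_state: Optional[ParticleState] = None,
    particle_seeds: Optional[Sequence] = None,
    engine: str = "numba",
    event_capacity: int = 200_000,
) -> Trajectory:
    """Integrate the model from t=0 to t_total and return the trajectory.

    Fully reproducible from ``params.seed``; ``initial_state`` and
    ``particle_seeds`` (ints or SeedSequences, one per particle)
    override the seed-derived initial condition and noise substreams.
    ``engine`` selects the jitted kernel (default) or the pure-numpy
    reference path (slow; for cross-checking).
    """
    init_seq, default_seqs = particle_noise_streams(params.seed, params.n_particles)
    if initial_state is None:
        state0 = initialize_positions(params, np.random.default_rng(init_seq))
    else:
        state0 = initial_state.copy()
        if state0.n_particles != params.n_particles:
            raise ValueError("initial_state particle count does not match parameters")
    seqs = list(particle_seeds) if particle_seeds is not None else list(default_seqs)
    if len(seqs) != params.n_particles:
        raise ValueError("need one noise substream per particle")
    n_steps = params.n_steps
    noise = _generate_noise(seqs, n_steps)

    if engine == "numpy":
        return _run_numpy(params, state0, noise)
    if engine != "numba":
        raise ValueError(f"unknown engine {engine!r}")

    n_frames = n_steps // params.save_every + 1
    n = params.n_particles
    out_x = np.empty((n_frames, n))
    out_y = np.empty((n_frames, n))
    out_th = np.empty((n_frames, n))
    ev_time = np.empty(event_capacity)
    ev_part = np.empty(event_capacity, dtype=np.int64)
    ev_side = np.empty(event_capacity, dtype=np.int64)
    px = state0.positions[:, 0].copy()
    py = wrap_periodic(state0.positions[:, 1].copy(), params.channel_length)
    th = state0.angles.copy()
    frame, n_ev, n_refl, bad_step, bad_particle = _run_kernel(
        px,
        py,
        th,
        noise,
        n_steps,
        params.dt,
        params.drag_gamma,
        params.motility_force,
        params.rotational_diffusion_dr,
        params.adhesion_epsilon,
        params.lj_sigma,
        params.lj_cutoff,
        params.channel_width,
        params.channel_length,
        params.wall_epsilon,
        params.wall_sigma,
        params.wall_force_cap,
        params.boundary_mode == "reflective",
        params.reflect_trigger,
        params.save_every,
        params.max_step_displacement,
        out_x,
        out_y,
        out_th,
        ev_time,
        ev_part,
        ev_side,
    )
    if bad_step >= 0:
        raise SimulationInstabilityError(bad_step, bad_particle, bad_step * params.dt)
    times = np.arange(n_frames) * params.save_interval
    positions = np.stack((out_x, out_y), axis=-1)
    events = np.empty(n_ev, dtype=EVENT_DTYPE)
    events["time"] = ev_time[:n_ev]
    events["particle"] = ev_part[:n_ev]
    events["side"] = ev_side[:n_ev]
    return Trajectory(
        params, times, positions, out_th, params.save_interval, events, n_refl
    )


def orientation_autocorrelation(angles: np.ndarray, max_lag: int) -> np.ndarray:
    """⟨n̂(t+τ)·n̂(t)⟩ = ⟨cos Δθ⟩ averaged over runs and time origins.

    ``angles`` has shape (runs, frames) on a uniform time grid.
    """
    a = np.atleast_2d(np.asarray(angles, dtype=float))
    corr = np.empty(max_lag + 1)
    corr[0] = 1.0
    for lag in range(1, max_lag + 1):
        corr[lag] = np.cos(a[:, lag:] - a[:, :-lag]).mean()
    return corr


def orientation_persistence_time(
    angles: np.ndarray, frame_interval: float, max_lag: Optional[int] = None
) -> float:
    """Persistence time τ from a single-exponential fit to ⟨n̂(t)·n̂(0)⟩.

    For pure rotational diffusion the autocorrelation is exp(−D_r t),
    so τ estimates 1/D_r.
    """
    from scipy.optimize import curve_fit

    a = np.atleast_2d(np.asarray(angles, dtype=float))
    if max_lag is None:
        max_lag = a.shape[1] - 1
    corr = orientation_autocorrelation(a, max_lag)
    t = np.arange(max_lag + 1) * frame_interval
    popt, _ = curve_fit(
        lambda t, tau: np.exp(-t / tau), t, corr, p0=[60.0], bounds=(1e-9, np.inf)
    )
    return float(popt[0])


def _run_numpy(params: ModelParameters, state0: ParticleState, noise: np.ndarray) -> Trajectory:
    """Reference integrator built from :func:`euler_step` (slow)."""
    state = state0.copy()
    state.positions[:, 1] = wrap_periodic(state.positions[:, 1], params.channel_length)
    frames = [state.copy()]
    all_events: list[tuple[float, int, int]] = []
    n_refl = 0
    for step in range(params.n_steps):
        try:
            state, events = euler_step(state, params, noise=noise[step])
        except SimulationInstabilityError as exc:
            raise SimulationInstabilityError(step, exc.particle, step * params.dt) from None
        n_refl += len(events)
        all_events.extend(events)
        if (step + 1) % params.save_every == 0:
            frames.append(state.copy())
    times = np.array([f.time for f in frames])
    positions = np.stack([f.positions for f in frames])
    angles = np.stack([f.angles for f in frames])
    # keep only zone-entry events, mirroring the kernel's logging rule
    entry: list[tuple[float, int, int]] = []
    last_side: dict[int, int] = {}
    prev_time: dict[int, float] = {}
    for t, i, side in all_events:
        if last_side.get(i) != side or (t - prev_time.get(i, -np.inf)) > 1.5 * params.dt:
            entry.append((t, i, side))
        last_side[i] = side
        prev_time[i] = t
    events_arr = np.array(
        [(t, i, s) for t, i, s in entry], dtype=EVENT_DTYPE
    ) if entry else np.empty(0, dtype=EVENT_DTYPE)
    return Trajectory(
        params, times, positions, angles, params.save_interval, events_arr, n_refl
    )
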