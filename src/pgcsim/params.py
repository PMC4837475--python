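"""Physical and numerical parameters of the channel model.

Working units are cell diameters (d) for length and minutes for time.
The defaults encode the measured biology: 14 cells of diameter 11 μm
moving at 0.05 d/min (0.6 μm/min to the printed precision) with a
directional persistence time of 60 min, confined to a 5 x 36 d channel
that is periodic along its long (y) axis and walled across its short
(x) axis.  Micron-valued outputs are obtained by multiplying d-valued
lengths by ``cell_diameter_um``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Any

__all__ = ["ModelParameters", "BOUNDARY_MODES", "ConfigError"]

BOUNDARY_MODES = ("non_reflective", "reflective")


class ConfigError(ValueError):
    """A parameter value or key is invalid."""


@dataclass
class ModelParameters:
    """All constants of one simulation run.

    Attributes
    ----------
    n_particles:
        Number of cells in the chamber (fixed; no division or death).
    cell_diameter_um:
        Physical size of one length unit d, in μm.
    speed_v0:
        Self-propulsion speed, d/min.  The motility force is
        ``drag_gamma * speed_v0`` so that a free particle moves at
        exactly ``speed_v0``.
    rotational_diffusion_dr:
        Angular diffusion rate of the propulsion direction, 1/min.
        Persistence time is its inverse.
    adhesion_epsilon:
        Depth of the Lennard-Jones pair well (a.u.); cell–cell adhesion
        strength.  ``0`` switches pair interactions off entirely.
    drag_gamma:
        Stokes drag coefficient γ in the overdamped equation of motion
        ``γ dx/dt = F``.  Sets the ratio of interaction forces to the
        propulsion force: the pair-binding threshold sits at
        ``ε_c = 2 v0 γ / 2.686``.
    channel_width, channel_length:
        Chamber dimensions in d.  x ∈ [0, width] is walled,
        y ∈ [0, length) is periodic.
    boundary_mode:
        ``"non_reflective"`` — walls only push; ``"reflective"`` — in
        addition, a cell touching a wall instantly reorients its
        propulsion perpendicular to the wall, into the interior
        (contact-inhibition-like turning).
    lj_sigma, lj_cutoff:
        Lennard-Jones length parameter and truncation radius, in d.
        The default σ = 2^(-1/6) puts the potential minimum at 1 d,
        i.e. touching cells.
    wall_epsilon, wall_sigma:
        WCA wall-potential constants (purely repulsive 12-6 truncated
        at its minimum, acting on the distance to each wall).
    wall_force_cap:
        Clamp on the wall force magnitude, so that a particle placed
        arbitrarily close to a wall is pushed out in finite steps
        instead of tripping the stability guard.
    reflect_threshold:
        Distance from the wall-contact position (``wall_range``) within
        which the reflective reorientation triggers, in d.
    dt:
        Euler time step, min.
    t_total, t_steady_start, t_steady_end:
        Run duration and the steady-state averaging window, min.
    save_interval:
        Frame spacing of the stored trajectory, min; must be an integer
        multiple of ``dt``.
    seed:
        Master seed; per-particle noise streams are spawned from it.
    max_step_displacement:
        Stability guard: the run aborts if any particle moves farther
        than this in a single step, in d.
    min_init_distance:
        Smallest admissible pair separation in the random initial
        condition, in d.
    """

    n_particles: int = 14
    cell_diameter_um: float = 11.0
    speed_v0: float = 0.05
    rotational_diffusion_dr: float = 1.0 / 60.0
    adhesion_epsilon: float = 0.2
    drag_gamma: float = 12.0
    channel_width: float = 5.0
    channel_length: float = 36.0
    boundary_mode: str = "reflective"
    lj_sigma: float = 2.0 ** (-1.0 / 6.0)
    lj_cutoff: float = 2.5 * 2.0 ** (-1.0 / 6.0)
    wall_epsilon: float = 0.02
    wall_sigma: float = 0.15
    wall_force_cap: float = 6.0
    reflect_threshold: float = 0.1
    dt: float = 0.02
    t_total: float = 5000.0
    t_steady_start: float = 4000.0
    t_steady_end: float = 5000.0
    save_interval: float = 5.0
    seed: int = 0
    max_step_displacement: float = 0.1
    min_init_distance: float = 0.9

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ConfigError("n_particles must be >= 1")
        for key in ("speed_v0", "rotational_diffusion_dr", "adhesion_epsilon"):
            if getattr(self, key) < 0:
                raise ConfigError(f"{key} must be >= 0, got {getattr(self, key)}")
        for key in (
            "cell_diameter_um",
            "drag_gamma",
            "channel_width",
            "channel_length",
            "lj_sigma",
            "lj_cutoff",
            "wall_epsilon",
            "wall_sigma",
            "wall_force_cap",
            "dt",
            "save_interval",
        ):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be > 0, got {getattr(self, key)}")
        if self.reflect_threshold < 0:
            raise ConfigError("reflect_threshold must be >= 0")
        if self.boundary_mode not in BOUNDARY_MODES:
            raise ConfigError(
                f"boundary_mode must be one of {BOUNDARY_MODES}, got {self.boundary_mode!r}"
            )
        if not (0 <= self.t_steady_start <= self.t_steady_end <= self.t_total):
            raise ConfigError(
                "need 0 <= t_steady_start <= t_steady_end <= t_total, got "
                f"{self.t_steady_start}, {self.t_steady_end}, {self.t_total}"
            )
        if self.max_step_displacement <= 0:
            raise ConfigError("max_step_displacement must be > 0")
        ratio = self.save_interval / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError(
                f"save_interval ({self.save_interval}) must be an integer multiple "
                f"of dt ({self.dt})"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def motility_force(self) -> float:
        """Magnitude F0 of the self-propulsion force (γ v0)."""
        return self.drag_gamma * self.speed_v0

    @property
    def wall_range(self) -> float:
        """Extent of the wall potential: 2^(1/6) σ_w, the WCA cutoff."""
        return 2.0 ** (1.0 / 6.0) * self.wall_sigma

    @property
    def reflect_trigger(self) -> float:
        """Wall distance below which reflective reorientation fires."""
        return self.wall_range + self.reflect_threshold

    @property
    def persistence_time(self) -> float:
        """1/D_r, min (infinite when D_r = 0)."""
        if self.rotational_diffusion_dr == 0:
            return math.inf
        return 1.0 / self.rotational_diffusion_dr

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total / self.dt))

    @property
    def save_every(self) -> int:
        return int(round(self.save_interval / self.dt))

    # -- (de)serialisation --------------------------------------------------

    def replace(self, **changes: Any) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    @classmethod
    def from_dict(cls, mapping: dict[str, Any]) -> "ModelParameters":
        """Build parameters from a flat mapping, rejecting unknown keys.

        Missing keys take the defaults above, which are the measured
        values of the biological system.
        """
        known = set(cls.field_names())
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ConfigError(f"unknown parameter key(s): {', '.join(unknown)}")
        kwargs: dict[str, Any] = {}
        for key, value in mapping.items():
            if key == "n_particles" or key == "seed":
                kwargs[key] = int(value)
            elif key == "boundary_mode":
                kwargs[key] = str(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)
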