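"""Initial phase fields for spinodal decomposition runs.

Three families of initial conditions are provided:

* **uniform** — i.i.d. noise ``phi ~ U(mu - width/2, mu + width/2)``.  The
  noise mean ``mu`` controls the final solid/pore balance (the dynamics
  conserve the field mean), and the width is held at 0.3 by convention.
* **patterned** — uniform noise plus a weak cosine plane wave
  ``c * cos(q . x)`` that seeds a preferred direction, so the decomposed
  structure inherits a controllable elastic anisotropy.
* **gradient** — uniform noise whose local mean follows a prescribed spatial
  profile ``mu_field``, which after decomposition yields a structure with a
  matching porosity gradient (dense where ``mu`` is high).

All randomness flows through a single counter-based generator (Philox) so a
spec plus its seed reproduces the field bit for bit on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .grids import GridSpec, PhaseField, ValidationError

__all__ = [
    "UniformInitSpec",
    "PatternedInitSpec",
    "GradientInitSpec",
    "init_uniform",
    "init_patterned",
    "init_gradient",
    "make_mu_profile",
]

#: conventional width b - a of the initial noise band
DEFAULT_WIDTH = 0.3


def _rng(seed: int) -> np.random.Generator:
    """Counter-based generator: reproducible across platforms."""
    return np.random.Generator(np.random.Philox(int(seed)))


@dataclass(frozen=True)
class UniformInitSpec:
    """Uniform noise ``U(mu - width/2, mu + width/2)``.

    ``mu`` may range over [-0.7, 0.7]; together with ``width`` the band must
    stay inside the physical order-parameter range [-1, 1].
    """

    mu: float = 0.0
    width: float = DEFAULT_WIDTH
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValidationError(f"width must be positive, got {self.width}")
        if self.mu - self.width / 2 < -1 or self.mu + self.width / 2 > 1:
            raise ValidationError(
                f"noise band [{self.mu - self.width / 2}, {self.mu + self.width / 2}] "
                "extends outside [-1, 1]"
            )

    @property
    def low(self) -> float:
        return self.mu - self.width / 2

    @property
    def high(self) -> float:
        return self.mu + self.width / 2


@dataclass(frozen=True)
class PatternedInitSpec:
    """Uniform noise plus a cosine plane wave of strength ``c`` along ``r``.

    ``r`` must be a unit vector; ``c`` lies in (0, 0.015] (``c = 0`` is
    permitted as the degenerate no-pattern case and equals the uniform init).
    ``wavenumber`` is the integer number of wave periods across the box, so
    the pattern is commensurate with the periodic domain.
    """

    base: UniformInitSpec = dc_field(default_factory=UniformInitSpec)
    c: float = 0.01
    r: tuple[float, float, float] = (0.0, 0.0, 1.0)
    wavenumber: int = 1

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.shape != (3,):
            raise ValidationError("pattern direction r needs 3 components")
        if abs(np.linalg.norm(r) - 1.0) > 1e-9:
            raise ValidationError(f"pattern direction must be a unit vector, |r| = {np.linalg.norm(r)}")
        if not (0 <= self.c <= 0.015):
            raise ValidationError(f"pattern strength c must lie in (0, 0.015], got {self.c}")
        if self.wavenumber < 1:
            raise ValidationError("wavenumber must be a positive integer")
        object.__setattr__(self, "r", tuple(float(v) for v in r))

    def realize(self, grid: GridSpec) -> PhaseField:
        """The initial field this spec describes, on ``grid``."""
        return init_patterned(grid, self)


@dataclass
class GradientInitSpec:
    """Uniform noise with a spatially varying mean ``mu_field``."""

    mu_field: np.ndarray
    width: float = DEFAULT_WIDTH
    seed: int = 0

    def __post_init__(self) -> None:
        self.mu_field = np.asarray(self.mu_field, dtype=np.float64)
        if not self.width > 0:
            raise ValidationError(f"width must be positive, got {self.width}")
        lo, hi = -1 + self.width / 2, 1 - self.width / 2
        if self.mu_field.size and (
            self.mu_field.min() < lo - 1e-12 or self.mu_field.max() > hi + 1e-12
        ):
            raise ValidationError(
                f"mu_field values must lie in [{lo}, {hi}] for width {self.width}"
            )


def init_uniform(grid: GridSpec, spec: UniformInitSpec) -> PhaseField:
    """Draw every voxel independently from ``U(mu - width/2, mu + width/2)``."""
    rng = _rng(spec.seed)
    values = rng.uniform(spec.low, spec.high, size=grid.shape)
    return PhaseField(values, grid, time_index=0)


def init_patterned(grid: GridSpec, spec: PatternedInitSpec) -> PhaseField:
    """Uniform noise plus the plane wave ``c * cos(q . x)``.

    The wavevector is ``q = (2 pi k / L) * r`` with ``L`` the box edge along
    the first axis and ``k`` the integer ``wavenumber``; for axis-aligned
    ``r`` this makes the wave exactly periodic over the box.
    """
    base = init_uniform(grid, spec.base)
    if spec.c == 0:
        return base
    x, y, z = grid.coordinates()
    L = grid.lengths[0]
    q = 2.0 * np.pi * spec.wavenumber / L
    phase = q * (spec.r[0] * x + spec.r[1] * y + spec.r[2] * z)
    return PhaseField(base.values + spec.c * np.cos(phase), grid, time_index=0)


def init_gradient(grid: GridSpec, spec: GradientInitSpec) -> PhaseField:
    """Voxel ``i`` drawn from ``U(mu_field[i] - width/2, mu_field[i] + width/2)``."""
    if spec.mu_field.shape != grid.shape:
        raise ValidationError(
            f"mu_field shape {spec.mu_field.shape} != grid shape {grid.shape}"
        )
    rng = _rng(spec.seed)
    noise = rng.uniform(-spec.width / 2, spec.width / 2, size=grid.shape)
    return PhaseField(spec.mu_field + noise, grid, time_index=0)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    """C1 monotone ramp from 0 to 1 on [0, 1]."""
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


PROFILE_KINDS = ("constant", "radial", "axial", "shell")


def make_mu_profile(kind: str, params: dict, grid: GridSpec) -> np.ndarray:
    """Build a smooth monotone ``mu`` profile over the grid.

    Supported kinds (all distances in voxels, measured on voxel centers):

    * ``constant`` — ``{"mu": value}`` everywhere.
    * ``radial`` — cylinder profile about the z axis:
      ``{"core": mu, "rim": mu, "radius": voxels, "transition": voxels}``;
      ``mu == core`` inside ``radius - transition/2`` and ``rim`` outside
      ``radius + transition/2``, smooth ramp in between.
    * ``axial`` — ramp along z: ``{"start": mu, "end": mu, "center":
      voxels, "transition": voxels}``.
    * ``shell`` — spherical analog of ``radial`` about the volume center.
    """
    if kind not in PROFILE_KINDS:
        raise ValidationError(
            f"unknown profile kind {kind!r}; supported kinds: {PROFILE_KINDS}"
        )
    nx, ny, nz = grid.shape
    if kind == "constant":
        return np.full(grid.shape, float(params["mu"]))

    ii, jj, kk = np.meshgrid(
        np.arange(nx) + 0.5, np.arange(ny) + 0.5, np.arange(nz) + 0.5, indexing="ij"
    )
    transition = float(params.get("transition", 8.0))
    if transition <= 0:
        raise ValidationError("transition width must be positive")

    if kind == "axial":
        start, end = float(params["start"]), float(params["end"])
        center = float(params.get("center", nz / 2))
        t = _smoothstep((kk - (center - transition / 2)) / transition)
        return start + (end - start) * t

    # radial / shell: distance from the axis or from the volume center
    cx, cy, cz = nx / 2, ny / 2, nz / 2
    if kind == "radial":
        dist = np.sqrt((ii - cx) ** 2 + (jj - cy) ** 2)
        default_radius = min(nx, ny) / 4
    else:  # shell
        dist = np.sqrt((ii - cx) ** 2 + (jj - cy) ** 2 + (kk - cz) ** 2)
        default_radius = min(nx, ny, nz) / 4
    core, rim = float(params["core"]), float(params["rim"])
    radius = float(params.get("radius", default_radius))
    t = _smoothstep((dist - (radius - transition / 2)) / transition)
    return core + (rim - core) * t
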