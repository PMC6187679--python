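"""Parametric geometry of the perfused spheroid trap.

Coordinate convention (fixed across the package):

* ``x`` — vertical, 0 at the channel floor, positive upward; the permeable
  PDMS lid occupies ``x in [channel_height, channel_height + pdms_top_thickness]``.
  For the microwell trap the cavity extends to negative ``x``.
* ``y`` — spanwise, 0..channel_width; the two side planes are symmetry planes
  (the trap sits in a periodic array of identical traps).
* ``z`` — streamwise, inlet at ``z = 0``.

All configuration lengths are in µm. The U-shaped barrier is a half annulus
(inner radius ``barrier_inner_radius``, wall thickness ``barrier_thickness``)
opening upstream, continued by two straight rectangular arms; the spheroid
rests against the inside of the downstream half-ring.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TrapVariant",
    "GeometryConfig",
    "InvalidConfigError",
    "GeometryError",
    "TrapSolid",
    "default_config",
    "build_trap_geometry",
]


class TrapVariant(str, enum.Enum):
    INTEGRATED_U = "integrated_u"
    MICROPOST_U = "micropost_u"
    MICROWELL = "microwell"


class InvalidConfigError(ValueError):
    """Raised for geometrically inconsistent configurations."""


class GeometryError(RuntimeError):
    """Raised when a solid model cannot be constructed."""


# Domain codes used by the solid classifier and the mesh tags.
DOMAIN_MEDIUM = 1
DOMAIN_SPHEROID = 2
DOMAIN_PDMS_BARRIER = 3
DOMAIN_PDMS_TOP = 4

DOMAIN_NAMES = {
    DOMAIN_MEDIUM: "medium",
    DOMAIN_SPHEROID: "spheroid",
    DOMAIN_PDMS_BARRIER: "pdms_barrier",
    DOMAIN_PDMS_TOP: "pdms_top",
}


@dataclass(frozen=True)
class GeometryConfig:
    """Full parametric description of channel, trap, spheroid and PDMS lid.

    Lengths in µm. ``spheroid_center`` follows the trap-placement rule
    ``(D/2, width/2, z_barrier + inner_radius - D/2)`` for the U traps: the
    spheroid touches both the channel floor and the downstream inner wall of
    the barrier. ``contact_embed`` is the small overlap applied by the solid
    builder at those contacts so the meshed contact is a patch rather than a
    tangency point.
    """

    channel_width: float = 1000.0
    channel_height: float = 1000.0
    channel_length: float = 2000.0
    barrier_inner_radius: float = 300.0
    barrier_thickness: float = 100.0
    barrier_height: float = 600.0
    barrier_center: tuple[float, float, float] = (0.0, 500.0, 1000.0)
    arm_length: float = 300.0
    trap_variant: TrapVariant = TrapVariant.INTEGRATED_U
    micropost_gap_angle: float = 2.0
    micropost_gap_positions: tuple[float, ...] = (30.0, 150.0)
    microwell_depth: float = 400.0
    spheroid_diameter: float = 500.0
    spheroid_center: tuple[float, float, float] = (250.0, 500.0, 1050.0)
    pdms_top_thickness: float = 1000.0
    contact_embed: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "channel_width", "channel_height", "channel_length",
            "barrier_inner_radius", "barrier_thickness", "barrier_height",
            "arm_length", "spheroid_diameter", "pdms_top_thickness",
        ):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")
        if self.spheroid_diameter > 2.0 * self.barrier_inner_radius:
            raise InvalidConfigError(
                f"spheroid diameter {self.spheroid_diameter} µm exceeds the "
                f"barrier inner diameter {2 * self.barrier_inner_radius} µm"
            )
        if self.contact_embed < 0:
            raise InvalidConfigError("contact_embed must be >= 0")
        if self.trap_variant == TrapVariant.MICROWELL and self.microwell_depth <= 0:
            raise InvalidConfigError("microwell_depth must be > 0")

    @property
    def spheroid_radius(self) -> float:
        return 0.5 * self.spheroid_diameter

    @property
    def x_min(self) -> float:
        """Lowest solid coordinate: cavity bottom for the microwell, else floor."""
        if self.trap_variant == TrapVariant.MICROWELL:
            return -self.microwell_depth
        return 0.0

    @property
    def x_max(self) -> float:
        return self.channel_height + self.pdms_top_thickness


def default_config(
    trap_variant: TrapVariant | str = TrapVariant.INTEGRATED_U,
    spheroid_diameter: float = 500.0,
    **overrides,
) -> GeometryConfig:
    """Standard trap geometry for a given variant and spheroid diameter.

    The spheroid center follows ``(D/2, W/2, z_barrier + r_inner - D/2)`` for
    the U-shaped traps, i.e. the sphere touches the channel floor and the
    downstream inner barrier wall. For the microwell it is centered in the
    cavity, resting on the cavity bottom.

    Raises
    ------
    InvalidConfigError
        If the diameter is outside (0, 2 × inner radius).
    """
    variant = TrapVariant(trap_variant)
    d = float(spheroid_diameter)
    base = GeometryConfig()  # defaults carry the channel dimensions
    ri = overrides.get("barrier_inner_radius", base.barrier_inner_radius)
    if not 0 < d <= 2 * ri:
        raise InvalidConfigError(
            f"spheroid diameter must be in (0, {2 * ri}] µm, got {d}"
        )
    w = overrides.get("channel_width", base.channel_width)
    bc = overrides.get("barrier_center", base.barrier_center)
    if variant == TrapVariant.MICROWELL:
        depth = overrides.get("microwell_depth", base.microwell_depth)
        center = (-depth + d / 2.0, w / 2.0, bc[2])
    else:
        center = (d / 2.0, w / 2.0, bc[2] + ri - d / 2.0)
    overrides.setdefault("spheroid_center", center)
    return replace(base, trap_variant=variant, spheroid_diameter=d, **overrides)


@dataclass
class TrapSolid:
    """Solid-model description of the trap: an exact point classifier.

    The solid is represented implicitly: :meth:`domain_of` returns the domain
    code of any point, which is what both the mesher and the analysis stages
    need. Analytic volumes are available for auditing mesh quality.
    """

    config: GeometryConfig
    include_trap: bool = True
    include_spheroid: bool = True
    sphere_center_um: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        c = self.config
        cx, cy, cz = c.spheroid_center
        e = c.contact_embed
        # Embed the sphere into the floor (or cavity bottom) and, for U traps,
        # into the downstream inner barrier wall, to avoid tangency point
        # contacts that cannot carry a mesh facet.
        if c.trap_variant == TrapVariant.MICROWELL:
            self.sphere_center_um = np.array([cx - e, cy, cz])
        else:
            self.sphere_center_um = np.array([cx - e, cy, cz + e])
        # sanity: sphere must stay inside the channel box
        r = c.spheroid_radius
        if self.sphere_center_um[0] + r > c.channel_height:
            raise GeometryError("spheroid extends above the channel")

    # -- primitive membership tests (vectorized, lengths in µm) ------------

    def _in_sphere(self, pts: np.ndarray) -> np.ndarray:
        d = pts - self.sphere_center_um
        return (d * d).sum(axis=1) <= self.config.spheroid_radius ** 2

    def _in_u_footprint_wall(self, pts: np.ndarray) -> np.ndarray:
        """Horizontal footprint of the U wall (annulus half + two arms)."""
        c = self.config
        _, yc, zc = c.barrier_center
        ri, t, arm = c.barrier_inner_radius, c.barrier_thickness, c.arm_length
        y = pts[:, 1] - yc
        z = pts[:, 2] - zc
        rr = np.hypot(y, z)
        ring = (z >= 0) & (rr >= ri) & (rr <= ri + t)
        if c.trap_variant == TrapVariant.MICROPOST_U:
            theta = np.degrees(np.arctan2(z, y))  # 0..180 on the half ring
            half = 0.5 * c.micropost_gap_angle
            for pos in c.micropost_gap_positions:
                ring &= ~(np.abs(theta - pos) <= half)
        arms = (z >= -arm) & (z < 0) & (np.abs(y) >= ri) & (np.abs(y) <= ri + t)
        return ring | arms

    def _in_u_footprint_inner(self, pts: np.ndarray) -> np.ndarray:
        """Open interior of the U (used as the microwell cavity footprint)."""
        c = self.config
        _, yc, zc = c.barrier_center
        ri, arm = c.barrier_inner_radius, c.arm_length
        y = pts[:, 1] - yc
        z = pts[:, 2] - zc
        half_disc = (z >= 0) & (np.hypot(y, z) <= ri)
        mouth = (z >= -arm) & (z < 0) & (np.abs(y) <= ri)
        return half_disc | mouth

    # -- classifier --------------------------------------------------------

    def domain_of(self, pts_um: np.ndarray) -> np.ndarray:
        """Domain code for each point (n, 3) in µm; 0 marks void (outside)."""
        c = self.config
        pts = np.atleast_2d(np.asarray(pts_um, dtype=float))
        x = pts[:, 0]
        out = np.zeros(len(pts), dtype=np.int8)

        inside_box = (
            (x >= c.x_min) & (x <= c.x_max)
            & (pts[:, 1] >= 0) & (pts[:, 1] <= c.channel_width)
            & (pts[:, 2] >= 0) & (pts[:, 2] <= c.channel_length)
        )
        out[inside_box & (x <= c.channel_height)] = DOMAIN_MEDIUM
        out[inside_box & (x > c.channel_height)] = DOMAIN_PDMS_TOP

        if self.include_trap:
            if c.trap_variant == TrapVariant.MICROWELL:
                # the well is recessed into the impermeable substrate: the
                # sub-floor region outside the cavity is not part of the
                # solid and its walls become no-flux floor boundaries
                below = inside_box & (x < 0)
                cavity = self._in_u_footprint_inner(pts)
                out[below & ~cavity] = 0
                # below-floor cavity interior stays medium
            else:
                wall = (
                    inside_box
                    & (x >= 0)
                    & (x <= c.barrier_height)
                    & self._in_u_footprint_wall(pts)
                )
                out[wall] = DOMAIN_PDMS_BARRIER

        if self.include_spheroid:
            sph = inside_box & self._in_sphere(pts)
            out[sph] = DOMAIN_SPHEROID
        return out

    # -- audits ------------------------------------------------------------

    def spheroid_volume_um3(self) -> float:
        """Analytic spheroid volume minus the embedded spherical caps."""
        c = self.config
        r = c.spheroid_radius
        vol = 4.0 / 3.0 * math.pi * r ** 3
        h = c.contact_embed  # cap height of each embedded contact
        cap = math.pi * h * h * (3 * r - h) / 3.0
        ncaps = 1 if c.trap_variant == TrapVariant.MICROWELL else 2
        return vol - ncaps * cap

    def bounding_volume_um3(self) -> float:
        c = self.config
        box = c.channel_width * c.channel_length * (c.x_max - 0.0)
        if c.trap_variant == TrapVariant.MICROWELL:
            ri, arm = c.barrier_inner_radius, c.arm_length
            cavity_area = 0.5 * math.pi * ri * ri + 2 * ri * arm
            box += cavity_area * c.microwell_depth
        return box

    def axis_breakpoints(self) -> tuple[list[float], list[float], list[float]]:
        """Coordinates that grid planes must pass through, per axis."""
        c = self.config
        _, yc, zc = c.barrier_center
        ri, t, arm = c.barrier_inner_radius, c.barrier_thickness, c.arm_length
        xs = [c.x_min, 0.0, c.barrier_height, c.channel_height, c.x_max]
        ys = [0.0, yc - ri - t, yc - ri, yc + ri, yc + ri + t, c.channel_width]
        zs = [0.0, zc - arm, zc, zc + ri, zc + ri + t, c.channel_length]
        return (sorted(set(xs)), sorted(set(ys)), sorted(set(zs)))


def build_trap_geometry(
    config: GeometryConfig,
    include_trap: bool = True,
    include_spheroid: bool = True,
) -> TrapSolid:
    """Construct the implicit solid model for a validated configuration.

    The ``include_*`` switches build reduced solids (empty duct, suspended
    spheroid without a trap) used by verification oracles.
    """
    return TrapSolid(config=config, include_trap=include_trap,
                     include_spheroid=include_spheroid)
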