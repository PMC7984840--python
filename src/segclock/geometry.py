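"""U-shaped PSM/tailbud domain: coordinates, region membership, confinement.

The presomitic mesoderm (PSM) is modeled as two tubes of radius ``r0`` whose
axes run parallel to the x axis, joined posteriorly by a half torus (the
tailbud) of core radius ``R`` and tube radius ``r0``.  The tissue occupies
y in [0, 2R + 2 r0] and z in [0, 2 r0]:

* left tube axis at (y, z) = (Yc - R, Zc),
* right tube axis at (y, z) = (Yc + R, Zc),
* torus center at (Xc, Yc, Zc), with Yc = R + r0 and Zc = r0.

The posterior tip of the tailbud sits at x = Lx = Xc + R + r0.  The anterior
end of the PSM, x = xa(t), moves posteriorly when the PSM shortens; the PSM
length is L(t) = Lx - xa(t).  All lengths are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryParams",
    "LocalCoords",
    "classify_domain",
    "tube_coords",
    "tube_position",
    "torus_coords",
    "torus_position",
    "boundary_force",
    "region_volume",
    "total_volume",
]

LEFT_PSM = "left_psm"
RIGHT_PSM = "right_psm"
TAILBUD = "tailbud"
ANTERIOR = "anterior"


@dataclass(frozen=True)
class GeometryParams:
    """Geometry of the U-shaped domain (lengths in μm)."""

    r0: float = 25.0  #: tube radius (half the ~50 μm PSM diameter)
    R: float = 50.0  #: torus core radius (half the left-right axis separation)
    L0: float = 400.0  #: initial PSM length Lx - xa(0), xa(0) = 0 (early-somitogenesis range)

    # Derived coordinates; filled in __post_init__.
    Lx: float = field(init=False)
    Xc: float = field(init=False)
    Yc: float = field(init=False)
    Zc: float = field(init=False)

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.R <= 0:
            raise ValueError("r0 and R must be positive")
        if self.L0 <= self.R + self.r0:
            raise ValueError("L0 must exceed R + r0 so the tubes have positive length")
        object.__setattr__(self, "Lx", self.L0)
        object.__setattr__(self, "Xc", self.L0 - self.R - self.r0)
        object.__setattr__(self, "Yc", self.R + self.r0)
        object.__setattr__(self, "Zc", self.r0)

    @property
    def left_axis(self) -> tuple[float, float]:
        return (self.Yc - self.R, self.Zc)

    @property
    def right_axis(self) -> tuple[float, float]:
        return (self.Yc + self.R, self.Zc)


@dataclass(frozen=True)
class LocalCoords:
    """Position of a cell in the local frame of its tissue region.

    ``rho`` is the distance from the tube axis (tubes) or from the torus core
    circle (tailbud); ``q`` the poloidal angle measured from +y (tubes) or
    from the outward mid-plane direction (tailbud); ``p`` the torus azimuth,
    atan2(Δy, Δx) in [-π/2, π/2], defined only in the tailbud.
    """

    domain: str
    x: float
    rho: float
    q: float
    p: float = 0.0


def classify_domain(position, geom: GeometryParams, xa: float):
    """Region tag(s) for one position (3-vector) or an (N, 3) array.

    Points with x < xa are ``anterior`` (arrested territory), points with
    x >= Xc are ``tailbud``, and the remainder split ``left_psm``/``right_psm``
    by which tube axis is nearer in y.
    """
    pos = np.asarray(position, dtype=float)
    single = pos.ndim == 1
    pos = np.atleast_2d(pos)
    tags = np.empty(len(pos), dtype=object)
    x, y = pos[:, 0], pos[:, 1]
    tags[:] = np.where(y < geom.Yc, LEFT_PSM, RIGHT_PSM)
    tags[x >= geom.Xc] = TAILBUD
    tags[x < xa] = ANTERIOR
    return tags[0] if single else tags


def tube_coords(position, geom: GeometryParams, side: str) -> LocalCoords:
    """Local cylindrical coordinates about the given tube axis.

    q = 0 points along +y; a point on the axis gets q = 0 by convention.
    """
    if side not in (LEFT_PSM, RIGHT_PSM, "left", "right"):
        raise ValueError(f"side must be left or right, got {side!r}")
    axis_y, axis_z = geom.left_axis if side in (LEFT_PSM, "left") else geom.right_axis
    x, y, z = np.asarray(position, dtype=float)
    dy, dz = y - axis_y, z - axis_z
    rho = float(np.hypot(dy, dz))
    q = 0.0 if rho == 0.0 else float(np.arctan2(dz, dy)) % (2.0 * np.pi)
    tag = LEFT_PSM if side in (LEFT_PSM, "left") else RIGHT_PSM
    return LocalCoords(domain=tag, x=float(x), rho=rho, q=q)


def tube_position(coords: LocalCoords, geom: GeometryParams) -> np.ndarray:
    """Inverse of :func:`tube_coords`."""
    axis_y, axis_z = geom.left_axis if coords.domain == LEFT_PSM else geom.right_axis
    return np.array(
        [
            coords.x,
            axis_y + coords.rho * np.cos(coords.q),
            axis_z + coords.rho * np.sin(coords.q),
        ]
    )


def torus_coords(position, geom: GeometryParams) -> LocalCoords:
    """Toroidal coordinates about the torus center (Xc, Yc, Zc).

    p = atan2(Δy, Δx) is the azimuth in the torus mid-plane (posterior tip at
    p = 0, tube junctions at ±π/2); rho is the distance from the core circle,
    q the poloidal angle with q = 0 on the outer equator.
    """
    x, y, z = np.asarray(position, dtype=float)
    dx, dy, dz = x - geom.Xc, y - geom.Yc, z - geom.Zc
    p = float(np.arctan2(dy, dx)) if (dx != 0.0 or dy != 0.0) else 0.0
    s = float(np.hypot(dx, dy))  # in-plane distance from torus center
    rho = float(np.hypot(s - geom.R, dz))
    q = 0.0 if rho == 0.0 else float(np.arctan2(dz, s - geom.R)) % (2.0 * np.pi)
    return LocalCoords(domain=TAILBUD, x=float(x), rho=rho, q=q, p=p)


def torus_position(coords: LocalCoords, geom: GeometryParams) -> np.ndarray:
    """Inverse of :func:`torus_coords`."""
    s = geom.R + coords.rho * np.cos(coords.q)
    return np.array(
        [
            geom.Xc + s * np.cos(coords.p),
            geom.Yc + s * np.sin(coords.p),
            geom.Zc + coords.rho * np.sin(coords.q),
        ]
    )


def boundary_force(
    position,
    geom: GeometryParams,
    xa: float,
    mu_b: float = 20.0,
    r_b: float = 1.0,
    r: float | None = None,
) -> np.ndarray:
    """Frictionless confinement force (μm/min) at one position.

    In the tubes the force has zero x component and pushes toward the tube
    axis; each transverse component decays exponentially with the projected
    distance to the wall, magnitude ``mu_b * exp(-δ/r_b)``.  In the half
    toroid all three components follow the analogous toroidal form.  ``r``
    overrides the current tube radius (radius-shrink protocols).
    """
    rr = geom.r0 if r is None else r
    tag = classify_domain(position, geom, xa)
    if tag == ANTERIOR:  # arrested territory: no confinement
        return np.zeros(3)
    if tag == TAILBUD:
        c = torus_coords(position, geom)
        cp, sp = np.cos(c.p), np.sin(c.p)
        cq, sq = np.cos(c.q), np.sin(c.q)
        dx = abs(cp * cq) * (rr - c.rho)
        dy = abs(sp * cq) * (rr - c.rho)
        dz = abs(sq) * (rr - c.rho)
        return np.array(
            [
                -mu_b * np.exp(-dx / r_b) * cp * cq,
                -mu_b * np.exp(-dy / r_b) * sp * cq,
                -mu_b * np.exp(-dz / r_b) * sq,
            ]
        )
    c = tube_coords(position, geom, tag)
    cq, sq = np.cos(c.q), np.sin(c.q)
    dy = abs(cq) * (rr - c.rho)
    dz = abs(sq) * (rr - c.rho)
    return np.array(
        [
            0.0,
            -mu_b * np.exp(-dy / r_b) * cq,
            -mu_b * np.exp(-dz / r_b) * sq,
        ]
    )


def region_volume(
    geom: GeometryParams, xa: float, region: str, r: float | None = None
) -> float:
    """Analytic volume (μm³) of one active region at anterior position xa."""
    rr = geom.r0 if r is None else r
    if xa >= geom.Xc:
        raise ValueError("PSM consumed: xa >= Xc leaves no tube volume")
    if region in (LEFT_PSM, RIGHT_PSM):
        return float(np.pi * rr**2 * (geom.Xc - xa))
    if region == TAILBUD:
        return float(np.pi**2 * geom.R * rr**2)  # half of 2π²Rr²
    raise ValueError(f"unknown region {region!r}")


def total_volume(geom: GeometryParams, xa: float, r: float | None = None) -> float:
    """Active U-domain volume: both tubes plus the half torus."""
    return (
        region_volume(geom, xa, LEFT_PSM, r)
        + region_volume(geom, xa, RIGHT_PSM, r)
        + region_volume(geom, xa, TAILBUD, r)
    )
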