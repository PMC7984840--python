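"""Time-dependent tissue protocols: shortening, radius change, cell flux.

The developmental programs layered on the mechanics:

* PSM shortening — the anterior end moves posteriorly at speed ua, so
  L(t) = Lx - ua t; the constraint va + ua = c keeps the segment length
  S = c·Ta constant across shortening speeds.
* Radius shrinkage — r(t) = r0 - sr t, with cells stranded outside the
  narrowing wall pulled back to ρ = r - 2 r_b.
* Density-controlled influx — every cell lost through the anterior end
  triggers at most one insertion into whichever region (left/right tube,
  tailbud) is most below the target density ϱ0; new cells get a random
  phase, random polarity, and a position clear of the anterior margin ζ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    LEFT_PSM,
    RIGHT_PSM,
    TAILBUD,
    GeometryParams,
    region_volume,
)

__all__ = [
    "ProgramParams",
    "anterior_position",
    "radius_schedule",
    "choose_influx_region",
    "sample_region_position",
    "cell_flux_update",
]


@dataclass(frozen=True)
class ProgramParams:
    """Tissue-program parameters (μm, min)."""

    ua: float = 0.0  #: anterior-end speed (μm/min); 0 → constant tissue
    c: float = 55.0 / 30.0  #: va + ua = c, fixes segment length S = c·Ta (μm/min)
    sr: float = 0.0  #: radius shrink rate (μm/min)
    # Target density: ~998 cells in a 110 × 110 × 55 μm³ test volume.
    rho0: float = 0.0015  #: target cell density (cells/μm³)
    zeta: float = 100.0  #: anterior no-insertion margin (μm)
    retention: float = 150.0  #: arrested cells kept this long (min)

    def __post_init__(self) -> None:
        if self.ua < 0:
            raise ValueError("ua must be >= 0")
        if self.c <= self.ua:
            raise ValueError("need c > ua so that va = c - ua stays positive")
        if self.rho0 <= 0:
            raise ValueError("rho0 must be positive")

    @property
    def va(self) -> float:
        """Anterior advection speed implied by the segment-length constraint."""
        return self.c - self.ua


def anterior_position(t: float, ua: float) -> float:
    """Anterior-end position xa(t) = ua·t (xa(0) = 0)."""
    return ua * t


def radius_schedule(t: float, sr: float, r0: float, floor: float) -> float:
    """Tube radius r(t) = r0 - sr·t, floored to keep the geometry nondegenerate."""
    return max(r0 - sr * t, floor)


def choose_influx_region(
    counts: dict[str, int],
    geom: GeometryParams,
    xa: float,
    rho0: float,
    r: float | None = None,
) -> str | None:
    """Region to insert into after a removal event, or None.

    Densities are measured as active-cell count over the analytic region
    volume.  If every region is at or above ϱ0, no insertion; otherwise the
    most-depleted region wins, ties broken left → right → tailbud.
    """
    deficits = {}
    for region in (LEFT_PSM, RIGHT_PSM, TAILBUD):
        vol = region_volume(geom, xa, region, r)
        deficits[region] = counts.get(region, 0) / vol - rho0
    if all(d >= 0.0 for d in deficits.values()):
        return None
    return min(deficits, key=lambda k: (deficits[k], (LEFT_PSM, RIGHT_PSM, TAILBUD).index(k)))


def sample_region_position(
    region: str,
    geom: GeometryParams,
    xa: float,
    zeta: float,
    rng: np.random.Generator,
    r: float | None = None,
) -> np.ndarray:
    """Uniform random in-domain position, honoring the anterior margin ζ."""
    rr = geom.r0 if r is None else r
    if region in (LEFT_PSM, RIGHT_PSM):
        x_lo = min(xa + zeta, geom.Xc)  # degenerate short PSM: insert near Xc
        x = rng.uniform(x_lo, geom.Xc)
        rho = rr * np.sqrt(rng.uniform())
        q = rng.uniform(0.0, 2.0 * np.pi)
        ay, az = geom.left_axis if region == LEFT_PSM else geom.right_axis
        return np.array([x, ay + rho * np.cos(q), az + rho * np.sin(q)])
    # Half torus: rejection sampling in its bounding box.
    while True:
        dx = rng.uniform(0.0, geom.R + rr)
        dy = rng.uniform(-(geom.R + rr), geom.R + rr)
        dz = rng.uniform(-rr, rr)
        s = np.hypot(dx, dy)
        if (s - geom.R) ** 2 + dz**2 < rr**2:
            return np.array([geom.Xc + dx, geom.Yc + dy, geom.Zc + dz])


def cell_flux_update(
    state,
    geom: GeometryParams,
    program: ProgramParams,
    rng: np.random.Generator,
    r: float | None = None,
) -> None:
    """Handle one removal event: possibly insert one cell (state in place).

    ``state`` is a :class:`segclock.engine.TissueState`.  The inserted cell
    gets phase ~ U[0, 2π), polarity angles ~ U[0, π) × U[0, 2π), and its
    frequency/motility/advection follow from its position at the next step.
    """
    counts = state.active_region_counts(geom)
    region = choose_influx_region(counts, geom, state.xa, program.rho0, r)
    if region is None:
        return
    pos = sample_region_position(region, geom, state.xa, program.zeta, rng, r)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    phi = rng.uniform(0.0, np.pi)
    psi = rng.uniform(0.0, 2.0 * np.pi)
    state.append_cell(pos, theta, phi, psi)
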