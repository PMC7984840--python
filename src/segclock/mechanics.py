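"""Cell mechanics: advection, intrinsic motility, polarity walk, repulsion.

Each cell obeys the overdamped equation of motion

    dx_i/dt = v_d(x_i) + v0(x_i) n_i + Σ_j F(x_i, x_j) + F_b(x_i)

with v_d the advection field of the elongating tissue (in the tailbud frame),
v0 the position-dependent intrinsic speed along the polarity direction n_i,
F a linear elastic contact repulsion with cutoff dc, and F_b the boundary
confinement from :mod:`segclock.geometry`.  The polarity vector performs an
isotropic random walk on the unit sphere with intensity Dphi.

Speeds are in μm/min, times in min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import GeometryParams, boundary_force

__all__ = [
    "MechanicsParams",
    "Polarity",
    "advection_speed",
    "advection_velocity",
    "strain_rate",
    "motility_speed",
    "polarity_step",
    "polarity_walk",
    "polarity_vector",
    "pair_force",
    "neighbor_pairs",
    "net_velocity",
]

# Default anterior advection speed: one 55 μm segment (5 cell diameters)
# per 30-min anterior period.
_VA_DEFAULT = 55.0 / 30.0

# Default advection knot: at the tube-tailbud junction of the default
# geometry (Xc/Lx = 325/400), with vp = va/(1 - xq) so the tube advects as
# a uniform conveyor at va and all axial strain sits in the tailbud.  This
# keeps the density uniform at ϱ0 and routes density-triggered cell
# insertion to the tailbud, whose transit delay protects the anterior wave
# pattern — the regime in which cell-addition noise alone still leaves the
# first five segments intact.
_XQ_DEFAULT = 0.8125
_VP_DEFAULT = _VA_DEFAULT / (1.0 - _XQ_DEFAULT)

_POLE_EPS = 1e-6


@dataclass(frozen=True)
class MechanicsParams:
    """Mechanical parameters (μm, min)."""

    mu: float = 8.71  #: repulsion coefficient (μm/min)
    dc: float = 11.0  #: cell diameter = interaction cutoff (μm)
    mu_b: float = 20.0  #: boundary force coefficient (μm/min)
    r_b: float = 1.0  #: boundary force decay length (μm)
    vs: float = 2.0  #: max intrinsic speed at the posterior tip (μm/min)
    Xv: float = 0.4  #: motility-gradient length scale (fraction of L)
    h: float = 3.0  #: motility-gradient steepness
    Dphi: float = 0.1  #: polarity noise intensity (1/min)
    va: float = _VA_DEFAULT  #: advection speed at the anterior end (μm/min)
    vp_early: float = _VP_DEFAULT  #: posterior advection parameter, t < tg
    vp_late: float = _VP_DEFAULT  #: posterior advection parameter, t >= tg
    xq: float = _XQ_DEFAULT  #: anterior/posterior split (fraction of L)
    tg: float = float("inf")  #: advection-switch time (min); inf disables the switch

    def __post_init__(self) -> None:
        for name in ("mu", "dc", "mu_b", "r_b", "vs", "Xv", "h", "va",
                     "vp_early", "vp_late"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.xq < 1.0:
            raise ValueError("xq must lie strictly between 0 and 1")

    def vp(self, t: float) -> float:
        return self.vp_early if t < self.tg else self.vp_late


@dataclass(frozen=True)
class Polarity:
    """Unit polarity vector stored as spherical angles.

    phi in [0, π] is the polar angle from +z, psi in [0, 2π) the azimuth:
    n = (sin φ cos ψ, sin φ sin ψ, cos φ).
    """

    phi: float
    psi: float

    @property
    def n(self) -> np.ndarray:
        sp = np.sin(self.phi)
        return np.array([sp * np.cos(self.psi), sp * np.sin(self.psi), np.cos(self.phi)])


def advection_speed(x, xa: float, L: float, params: MechanicsParams, t: float = 0.0):
    """Advection speed profile v(χ) >= 0, χ = (x - xa)/L.

    Piecewise linear with a knot at χ = xq: v(0) = va at the anterior end,
    v(1) = 0 at the tailbud tip (the tailbud frame's fixed point).  The
    posterior slope parameter vp switches from vp_early to vp_late at t = tg.
    """
    chi = (np.asarray(x, dtype=float) - xa) / L
    vp = params.vp(t)
    ant = -((params.va - vp * (1.0 - params.xq)) / params.xq) * chi + params.va
    post = -vp * chi + vp
    return np.where(chi <= params.xq, ant, post)


def advection_velocity(x, xa: float, L: float, params: MechanicsParams, t: float = 0.0):
    """Advection velocity vector(s) (-v(χ), 0, 0): cells drift anteriorly."""
    v = np.atleast_1d(advection_speed(x, xa, L, params, t))
    out = np.zeros(v.shape + (3,))
    out[..., 0] = -v
    return out[0] if np.ndim(x) == 0 else out


def strain_rate(chi, params: MechanicsParams, L: float, t: float = 0.0):
    """|∂v/∂x| (1/min): uniform within each of the two advection subdomains."""
    chi = np.asarray(chi, dtype=float)
    vp = params.vp(t)
    ant = abs(params.va - vp * (1.0 - params.xq)) / (params.xq * L)
    post = vp / L
    return np.where(chi <= params.xq, ant, post)


def motility_speed(x, xa: float, L: float, params: MechanicsParams):
    """Intrinsic speed v0(x) = vs / (1 + ((1 - x̄/L)/Xv)^h), x̄ = x - xa.

    Sigmoidal gradient: highest (vs) at the posterior tip, low anteriorly —
    the cell-mixing gradient of the PSM.
    """
    xbar = (np.asarray(x, dtype=float) - xa) / L
    return params.vs / (1.0 + ((1.0 - xbar) / params.Xv) ** params.h)


def polarity_step(
    pol: Polarity, dt: float, Dphi: float, xi_phi: float, xi_psi: float
) -> Polarity:
    """One step of the isotropic random walk on the unit sphere.

    The polarity vector receives a Gaussian kick of size sqrt(2 Dφ dt) in
    the plane tangent to the sphere at n (spanned by the azimuthal unit
    vector m_x = n × e_z / |n × e_z| and m_y = m_x × n) and is renormalized
    to unit length.  In polar/azimuth angles this discretizes the Itô SDE
    dφ = Dφ cot(φ) dt + sqrt(2 Dφ) dW_φ, dψ = sqrt(2 Dφ)/sin(φ) dW_ψ while
    staying stable at the coordinate poles, and its stationary density is
    uniform on the sphere.
    """
    if Dphi == 0.0:
        return pol
    root = np.sqrt(2.0 * Dphi * dt)
    sphi = np.sin(pol.phi)
    nx, ny, nz = sphi * np.cos(pol.psi), sphi * np.sin(pol.psi), np.cos(pol.phi)
    if sphi < 1e-12:  # pole: azimuth degenerate, pick a fixed tangent frame
        mxx, mxy, mxz = 1.0, 0.0, 0.0
        myx, myy, myz = 0.0, 1.0, 0.0
    else:
        mxx, mxy, mxz = ny / sphi, -nx / sphi, 0.0
        # m_y = m_x × n is a unit vector analytically
        myx, myy, myz = -nx * nz / sphi, -ny * nz / sphi, sphi
    nx += root * (xi_psi * mxx + xi_phi * myx)
    ny += root * (xi_psi * mxy + xi_phi * myy)
    nz += root * (xi_psi * mxz + xi_phi * myz)
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    nz /= norm
    phi = np.arccos(min(1.0, max(-1.0, nz)))
    phi = min(max(phi, _POLE_EPS), np.pi - _POLE_EPS)
    psi = np.arctan2(ny, nx) % (2.0 * np.pi)
    return Polarity(phi=float(phi), psi=float(psi))


def polarity_walk(
    phi: np.ndarray,
    psi: np.ndarray,
    dt: float,
    Dphi: float,
    n_steps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized many-walker version of :func:`polarity_step`.

    Applies the same tangent-plane update to arrays of angles for
    ``n_steps`` steps; used for stationary-distribution diagnostics.
    """
    phi = np.array(phi, dtype=float)
    psi = np.array(psi, dtype=float)
    root = np.sqrt(2.0 * Dphi * dt)
    for _ in range(n_steps):
        sphi = np.sin(phi)
        n = np.column_stack(
            [sphi * np.cos(psi), sphi * np.sin(psi), np.cos(phi)]
        )
        # φ is clamped to [1e-6, π - 1e-6], so sin φ never underflows
        s = sphi[:, None]
        mx = np.column_stack([n[:, 1], -n[:, 0], np.zeros(len(n))]) / s
        my = np.column_stack(
            [-n[:, 0] * n[:, 2] / sphi, -n[:, 1] * n[:, 2] / sphi, sphi]
        )
        xi_phi = rng.standard_normal((len(phi), 1))
        xi_psi = rng.standard_normal((len(phi), 1))
        n = n + root * (xi_psi * mx + xi_phi * my)
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        phi = np.arccos(np.clip(n[:, 2], -1.0, 1.0))
        np.clip(phi, _POLE_EPS, np.pi - _POLE_EPS, out=phi)
        psi = np.arctan2(n[:, 1], n[:, 0]) % (2.0 * np.pi)
    return phi, psi


def polarity_vector(phi, psi) -> np.ndarray:
    """Unit vector(s) from polarity angles; vectorized."""
    phi = np.asarray(phi, dtype=float)
    sp = np.sin(phi)
    return np.stack([sp * np.cos(psi), sp * np.sin(psi), np.cos(phi)], axis=-1)


def pair_force(
    xi,
    xj,
    mu: float,
    dc: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Linear elastic repulsion exerted on cell i by cell j.

    Zero beyond the contact distance dc; magnitude μ(1 - d/dc) directed from
    j to i.  Exactly coincident cells are pushed apart along a random unit
    vector (new cells are inserted at random positions, so d = 0 can occur).
    """
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    dvec = xi - xj
    d = float(np.linalg.norm(dvec))
    if d > dc:
        return np.zeros(3)
    if d == 0.0:
        rng = np.random.default_rng(0) if rng is None else rng
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        return mu * u
    return mu * (1.0 - d / dc) * dvec / d


def neighbor_pairs(positions: np.ndarray, dc: float) -> np.ndarray:
    """All index pairs (i < j) with |x_i - x_j| <= dc (kd-tree query)."""
    tree = cKDTree(positions)
    pairs = tree.query_pairs(dc, output_type="ndarray")
    return pairs.reshape(-1, 2)


def net_velocity(
    positions: np.ndarray,
    pol_angles: np.ndarray,
    geom: GeometryParams,
    params: MechanicsParams,
    xa: float,
    t: float = 0.0,
    r: float | None = None,
    pairs: np.ndarray | None = None,
    include_advection: bool = True,
) -> np.ndarray:
    """Net velocity of every cell: the four-term overdamped equation of motion.

    ``pol_angles`` is (N, 2) of (φ, ψ).  ``pairs`` may carry a precomputed
    neighbor list; otherwise one is built with a kd-tree.  This is the
    reference (numpy) assembly, quadratic-free but loop-light; the production
    stepper in :mod:`segclock._kernels` reproduces it bit-for-bit on shared
    inputs.
    """
    positions = np.asarray(positions, dtype=float)
    n_cells = len(positions)
    L = geom.Lx - xa
    vel = np.zeros((n_cells, 3))
    if include_advection:
        vel += advection_velocity(positions[:, 0], xa, L, params, t)
    v0 = motility_speed(positions[:, 0], xa, L, params)
    vel += v0[:, None] * polarity_vector(pol_angles[:, 0], pol_angles[:, 1])
    if pairs is None:
        pairs = neighbor_pairs(positions, params.dc)
    for i, j in pairs:
        f = pair_force(positions[i], positions[j], params.mu, params.dc)
        vel[i] += f
        vel[j] -= f
    for i in range(n_cells):
        vel[i] += boundary_force(
            positions[i], geom, xa, mu_b=params.mu_b, r_b=params.r_b, r=r
        )
    return vel
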