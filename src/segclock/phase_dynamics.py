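"""Phase-oscillator layer of the segmentation clock.

Each cell carries a phase θ obeying

    dθ_i/dt = ω(x_i) + (κ(t)/n_i) Σ_{|x_j-x_i|<=dc} sin(θ_j - θ_i)
              + sqrt(2 Dθ) ξ_i(t)

with a posterior-high frequency profile ω(x) = ω0 U((x - xa)/L) that
generates kinematic waves traveling toward the anterior, local Kuramoto
coupling normalized by the neighbor count, and white phase noise.  The
coupling strength κ(t) encodes Notch-inhibitor (DAPT) washout protocols:
zero before the washout time, then κ0 plus an optional linear ramp.
Phases of cells anterior to xa are arrested, freezing the wave pattern
into stripes whose spacing is the segment length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhaseParams",
    "frequency_profile",
    "coupling_strength",
    "phase_increment",
    "arrest_anterior",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PhaseParams:
    """Phase-dynamics parameters (rad, min)."""

    omega0: float = 0.2094  #: angular frequency at the posterior tip (rad/min)
    sigma: float = 0.7  #: anterior/posterior frequency ratio, in (0, 1]
    k: float = 3.0  #: frequency-profile shape (0 → linear profile)
    kappa0: float = 0.07  #: base coupling strength (1/min)
    kappa_s: float = 0.0  #: coupling ramp slope (1/min²)
    t_washout: float = 0.0  #: time coupling switches on (min); inf → never
    Dtheta: float = 0.0013  #: phase noise intensity (1/min)
    vartheta: float = 3.0 * np.pi / 2.0  #: boundary-setting phase (rad)
    Ta: float = 30.0  #: anterior period = segmentation period (min)

    def __post_init__(self) -> None:
        if self.omega0 <= 0:
            raise ValueError("omega0 must be positive")
        if not 0.0 < self.sigma <= 1.0:
            raise ValueError("sigma must lie in (0, 1]")
        if self.Dtheta < 0:
            raise ValueError("Dtheta must be >= 0")
        if self.kappa0 < 0 or self.kappa0 + min(0.0, self.kappa_s) < 0:
            raise ValueError("coupling must stay nonnegative")


def frequency_profile(x, xa: float, L: float, params: PhaseParams):
    """Autonomous frequency ω(x) = ω0 U(χ), χ = (x - xa)/L.

    U(χ) = σ + (1 - σ)(1 - e^{-kχ})/(1 - e^{-k}); U(0) = σ, U(1) = 1,
    monotone increasing.  k = 0 falls back to the linear limit σ + (1 - σ)χ.
    """
    chi = (np.asarray(x, dtype=float) - xa) / L
    if params.k == 0.0:
        u = params.sigma + (1.0 - params.sigma) * chi
    else:
        u = params.sigma + (1.0 - params.sigma) * (
            -np.expm1(-params.k * chi)
        ) / (-np.expm1(-params.k))
    return params.omega0 * u


def coupling_strength(t, params: PhaseParams):
    """κ(t): 0 before washout, κ_s·t + κ0 afterwards (1/min)."""
    t = np.asarray(t, dtype=float)
    kappa = np.where(t < params.t_washout, 0.0, params.kappa_s * t + params.kappa0)
    if np.any(kappa < 0):
        raise ValueError("coupling strength became negative; invalid kappa_s/kappa0")
    return kappa if kappa.ndim else float(kappa)


def phase_increment(
    theta: np.ndarray,
    x: np.ndarray,
    pairs: np.ndarray,
    xa: float,
    L: float,
    t: float,
    dt: float,
    params: PhaseParams,
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cell phase increment over one step dt (Euler–Maruyama).

    ``pairs`` is the (i, j) neighbor list (cells within dc); the coupling
    term of cell i is κ/n_i Σ sin(θ_j - θ_i) with n_i the neighbor count —
    cells with no neighbors get no coupling.  ``noise`` holds standard
    normal draws (ignored when Dθ = 0).
    """
    n = len(theta)
    omega = frequency_profile(x, xa, L, params)
    kappa = coupling_strength(t, params)
    coup = np.zeros(n)
    count = np.zeros(n)
    if kappa > 0 and len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        s = np.sin(theta[j] - theta[i])
        np.add.at(coup, i, s)
        np.add.at(coup, j, -s)
        np.add.at(count, i, 1.0)
        np.add.at(count, j, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        coup = np.where(count > 0, kappa * coup / np.maximum(count, 1.0), 0.0)
    dtheta = (omega + coup) * dt
    if params.Dtheta > 0 and noise is not None:
        dtheta = dtheta + np.sqrt(2.0 * params.Dtheta * dt) * noise
    return dtheta


def arrest_anterior(
    x: np.ndarray, arrested: np.ndarray, xa: float, t: float, t_arrest: np.ndarray
) -> int:
    """Flag cells that crossed the anterior boundary x = xa (in place).

    Returns the number of newly arrested cells (each is a removal event for
    the density bookkeeping).  Arrested phases are frozen by the stepper;
    arrested cells keep advecting anteriorly at the anterior-end speed.
    """
    newly = (~arrested.astype(bool)) & (x < xa)
    arrested[newly] = True
    t_arrest[newly] = t
    return int(newly.sum())
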