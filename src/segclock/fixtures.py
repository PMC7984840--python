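"""Synthetic phase fields and toy segment records.

Oracles for the observables: point clouds with planted phase patterns
(uniform, axial gradient, random, ideal vortex) at tissue-like density, and
paired Bernoulli segment records for the left-right defect statistics.
These are first-class library code — the CLI can run detector demos on them
without a full simulation — and they share the engine's snapshot schema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeometryParams
from .observables import SegmentRecord
from .tissue_program import sample_region_position
from .geometry import LEFT_PSM, RIGHT_PSM, TAILBUD, region_volume

__all__ = ["PlantedFieldSpec", "make_planted_field", "make_u_domain_positions",
           "make_toy_record", "planted_winding_number"]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PlantedFieldSpec:
    """Recipe for a synthetic phase field in a box.

    ``rule`` is one of uniform | gradient | random | vortex.  The vortex
    rule plants phase = winding · atan2 of the two coordinates transverse
    to ``axis`` about ``center``; winding +1 is counterclockwise seen from
    the positive axis direction.
    """

    box: tuple[float, float, float] = (110.0, 110.0, 55.0)  #: μm
    density: float = 0.0015  #: cells/μm³
    rule: str = "uniform"
    phase0: float = 3.0 * np.pi / 2.0  #: uniform rule's phase
    wavelength: float = 55.0  #: gradient rule: one cycle per segment length
    center: tuple[float, float, float] = (55.0, 55.0, 27.5)
    axis: str = "z"  #: vortex rotation axis, y or z
    winding: int = 1  #: +1 ccw, -1 cw

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.rule not in ("uniform", "gradient", "random", "vortex"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.axis not in ("y", "z") or self.winding not in (-1, 1):
            raise ValueError("vortex axis must be y or z, winding ±1")


def planted_phase(spec: PlantedFieldSpec, positions: np.ndarray,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Phases for given positions under the recipe's assignment rule."""
    n = len(positions)
    if spec.rule == "uniform":
        return np.full(n, spec.phase0 % TWO_PI)
    if spec.rule == "gradient":
        return (spec.phase0 - TWO_PI * positions[:, 0] / spec.wavelength) % TWO_PI
    if spec.rule == "random":
        rng = rng or np.random.default_rng(0)
        return rng.uniform(0.0, TWO_PI, n)
    cx, cy, cz = spec.center
    if spec.axis == "z":
        ang = np.arctan2(positions[:, 1] - cy, positions[:, 0] - cx)
    else:  # about y: in-plane axes (x, z), ccw seen from +y
        ang = np.arctan2(positions[:, 2] - cz, positions[:, 0] - cx)
    return (spec.winding * ang) % TWO_PI


def make_planted_field(
    spec: PlantedFieldSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(positions, phases): i.i.d. uniform positions in the box, planted phases."""
    lx, ly, lz = spec.box
    n = int(round(spec.density * lx * ly * lz))
    positions = rng.uniform(0.0, 1.0, (n, 3)) * np.array(spec.box)
    return positions, planted_phase(spec, positions, rng)


def make_u_domain_positions(
    geom: GeometryParams, density: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform positions in the full U-domain at the given density."""
    regions = (LEFT_PSM, RIGHT_PSM, TAILBUD)
    vols = np.array([region_volume(geom, 0.0, reg) for reg in regions])
    n = int(round(density * vols.sum()))
    picks = rng.choice(3, size=n, p=vols / vols.sum())
    return np.array(
        [sample_region_position(regions[k], geom, 0.0, 0.0, rng) for k in picks]
    )


def planted_winding_number(
    positions: np.ndarray,
    theta: np.ndarray,
    center: np.ndarray,
    radius: float,
    n_path: int = 720,
) -> int:
    """Brute-force winding: sum of wrapped phase steps around a circle.

    Walks a dense circular path about ``center`` in the 2D projection,
    sampling each path point's nearest cell phase, and accumulates the
    wrapped phase differences; the total divided by 2π is the winding
    number (exact on noiseless planted fields).
    """
    ang = np.linspace(0.0, TWO_PI, n_path, endpoint=False)
    path = center[None, :] + radius * np.column_stack([np.cos(ang), np.sin(ang)])
    d2 = ((path[:, None, :] - positions[None, :, :]) ** 2).sum(axis=2)
    ph = theta[np.argmin(d2, axis=1)]
    steps = np.diff(np.append(ph, ph[0]))
    wrapped = (steps + np.pi) % TWO_PI - np.pi
    return int(round(wrapped.sum() / TWO_PI))


def make_toy_record(
    n_segments: int,
    p_defect_left: float,
    p_defect_right: float,
    seed: int = 0,
) -> tuple[SegmentRecord, SegmentRecord]:
    """Paired records with i.i.d. Bernoulli defects per side per boundary."""
    for p in (p_defect_left, p_defect_right):
        if not 0.0 <= p <= 1.0:
            raise ValueError("defect probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    left = SegmentRecord.from_labels(
        "left", rng.uniform(size=n_segments) < p_defect_left
    )
    right = SegmentRecord.from_labels(
        "right", rng.uniform(size=n_segments) < p_defect_right
    )
    return left, right
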