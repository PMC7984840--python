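"""Measurements on simulated tissues.

* Local phase order: mean resultant length Z_m of the phases in thin axial
  slices (width dc), averaged over M consecutive slices — high even across
  a phase gradient, low in disordered tissue.
* Segment-boundary scoring: boundary-setting times are upward crossings of
  the anterior mean phase through ϑ; each boundary is normal iff Z(t, xa)
  stays at or above Zc throughout a confirmation window; normal boundaries
  are numbered (chaining, or by rounding τ/Ta) and everything unnumbered is
  defective.  From the labeled record come ALD, FRS, PLD, defect runs and
  left/right single-defect statistics.
* Phase vorticity: a six-sector ring detector on 2D slice projections that
  reports the winding (θ̂5 - θ̂0)/2π where the cyclically permuted sector
  means ascend linearly — a vortex — and 0 elsewhere; a linear phase
  gradient must not register.

Angles are radians, lengths μm, times min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import LEFT_PSM, RIGHT_PSM, GeometryParams

__all__ = [
    "DetectionParams",
    "VorticityParams",
    "SegmentRecord",
    "Kymograph",
    "circular_mean",
    "slice_order",
    "local_order",
    "anterior_metrics",
    "posterior_mean_phase",
    "detect_boundary_times",
    "classify_boundary",
    "number_boundaries",
    "score_record",
    "defect_runs",
    "single_double_stats",
    "expected_single_fraction",
    "vorticity_at_grid",
    "vorticity_plane",
    "vorticity_profile",
    "kymograph",
    "crossing_times",
]

TWO_PI = 2.0 * np.pi

# Pearson normalization over the six sector indices i = 0..5:
# mean(i) = 5/2 and var(i) = Σ(i - 5/2)²/6 = 35/12.
SECTOR_INDEX_MEAN = 5.0 / 2.0
SECTOR_INDEX_VAR = 35.0 / 12.0


@dataclass(frozen=True)
class DetectionParams:
    """Boundary detection/classification parameters."""

    Zc: float = 0.85  #: order threshold for a normal boundary
    eta: float = 4.0  #: confirmation window (min)
    Delta: float = 0.3  #: numbering tolerance (fraction of Ta)
    M: int = 5  #: slices averaged for Z (segment length ≈ 5 dc)
    dx_slice: float = 11.0  #: slice width Δx = cell diameter dc (μm)

    def __post_init__(self) -> None:
        if not 0.0 < self.Zc <= 1.0:
            raise ValueError("Zc must lie in (0, 1]")
        if self.eta <= 0 or not 0.0 < self.Delta < 0.5 or self.M < 1:
            raise ValueError("invalid detection parameters")


@dataclass(frozen=True)
class VorticityParams:
    """Ring-detector parameters for phase vorticity."""

    slice_thickness: float = 20.0  #: projection slab thickness (μm)
    dx: float = 5.0  #: axial grid spacing (μm)
    dy: float = 2.0  #: transverse grid spacing (μm)
    ring_offset: float = 5.5  #: inner ring radius δl (μm)
    ring_width: float = 14.0  #: ring radial width l (μm)
    # Acceptance thresholds calibrated on synthetic fields: planted ideal
    # vortices are detected at their cores with certainty while disordered
    # fields trigger < 0.2% of ring evaluations (uniform and pure-gradient
    # fields none at all).
    alpha: float = 0.98  #: correlation threshold (calibration constant)
    psi_min: float = 0.75  #: minimum winding accepted (calibration constant)

    def __post_init__(self) -> None:
        if self.ring_offset <= 0 or self.ring_width <= 0:
            raise ValueError("ring dimensions must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class SegmentRecord:
    """Per-side ordered boundary labels with derived defect statistics.

    ``labels[j]`` is True when boundary j (1-based key) is defective;
    ``taus`` maps numbered normal boundaries to their setting times.
    """

    side: str
    labels: dict[int, bool] = field(default_factory=dict)
    taus: dict[int, float] = field(default_factory=dict)

    @property
    def indices(self) -> list[int]:
        return sorted(self.labels)

    @property
    def defective(self) -> list[int]:
        return [j for j in self.indices if self.labels[j]]

    @property
    def ald(self) -> int | None:
        """Anterior limit of defects: smallest defective boundary index."""
        d = self.defective
        return d[0] if d else None

    @property
    def frs(self) -> int | None:
        """First recovered segment, simulation convention: jf - 1 with jf
        the smallest normal boundary index; 0 when boundary 1 is normal."""
        normal = [j for j in self.indices if not self.labels[j]]
        return normal[0] - 1 if normal else None

    @property
    def frs_experimental(self) -> int | None:
        """First recovered segment, scoring convention of stained embryos:
        first normal boundary after boundary 9, minus 1."""
        normal = [j for j in self.indices if not self.labels[j] and j > 9]
        return normal[0] - 1 if normal else None

    @property
    def pld(self) -> int | None:
        """Posterior limit of defects: last defective boundary index."""
        d = self.defective
        return d[-1] if d else None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "side": self.side,
                "boundary_index": j,
                "label": "defective" if self.labels[j] else "normal",
                "tau_min": self.taus.get(j, np.nan),
            }
            for j in self.indices
        ]
        return pd.DataFrame(rows, columns=["side", "boundary_index", "label",
                                           "tau_min"])

    @classmethod
    def from_labels(cls, side: str, defective_flags, start: int = 1) -> "SegmentRecord":
        labels = {start + i: bool(f) for i, f in enumerate(defective_flags)}
        return cls(side=side, labels=labels)


@dataclass
class Kymograph:
    """Time × axial grids of an observable (Z or ψ) for one side."""

    times: np.ndarray  #: (T,) min
    x_rel: np.ndarray  #: (X,) tissue-relative axial positions x - xa (μm)
    xa: np.ndarray  #: (T,) anterior-end position per row (μm)
    values: np.ndarray  #: (T, X)
    side: str
    observable: str

    @property
    def x_abs(self) -> np.ndarray:
        """(T, X) absolute axial positions."""
        return self.xa[:, None] + self.x_rel[None, :]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{x:.3f}" for x in self.x_rel])
        df.insert(0, "t_min", self.times)
        df.insert(1, "xa_um", self.xa)
        return df


# --------------------------------------------------------------------------
# local phase order
# --------------------------------------------------------------------------

def circular_mean(theta: np.ndarray) -> tuple[float, float]:
    """(R, Ψ): modulus and argument of the mean unit phasor."""
    if len(theta) == 0:
        return np.nan, np.nan
    z = np.exp(1j * np.asarray(theta)).mean()
    return float(abs(z)), float(np.angle(z) % TWO_PI)


def side_mask(positions: np.ndarray, side: str, geom: GeometryParams) -> np.ndarray:
    """Left/right split of the tissue by the mid-plane y = Yc."""
    if side in (LEFT_PSM, "left"):
        return positions[:, 1] < geom.Yc
    if side in (RIGHT_PSM, "right"):
        return positions[:, 1] >= geom.Yc
    raise ValueError(f"side must be left or right, got {side!r}")


def slice_order(
    positions: np.ndarray,
    theta: np.ndarray,
    x0: float,
    side: str,
    geom: GeometryParams,
    dx_slice: float,
) -> tuple[float, float]:
    """(Z_m, Ψ_m) for the slice [x0, x0 + Δx) on one side; NaNs when empty."""
    m = side_mask(positions, side, geom)
    m &= (positions[:, 0] >= x0) & (positions[:, 0] < x0 + dx_slice)
    return circular_mean(theta[m])


def local_order(
    positions: np.ndarray,
    theta: np.ndarray,
    x0: float,
    side: str,
    geom: GeometryParams,
    params: DetectionParams,
) -> float:
    """Z(x0): mean of the M slice moduli starting at x0 (missing excluded)."""
    zs = np.array(
        [
            slice_order(positions, theta, x0 + m * params.dx_slice, side, geom,
                        params.dx_slice)[0]
            for m in range(params.M)
        ]
    )
    if np.all(np.isnan(zs)):
        return np.nan
    return float(np.nanmean(zs))


def anterior_metrics(
    positions: np.ndarray,
    theta: np.ndarray,
    xa: float,
    side: str,
    geom: GeometryParams,
    params: DetectionParams,
) -> tuple[float, float]:
    """(Ψ1(t, xa), Z(t, xa)) — the boundary-detection signals for one side."""
    _, psi1 = slice_order(positions, theta, xa, side, geom, params.dx_slice)
    z = local_order(positions, theta, xa, side, geom, params)
    return psi1, z


def posterior_mean_phase(
    positions: np.ndarray, theta: np.ndarray, Lx: float, depth: float = 20.0
) -> float:
    """Circular mean phase of cells within ``depth`` of the posterior tip."""
    m = positions[:, 0] >= Lx - depth
    return circular_mean(theta[m])[1]


# --------------------------------------------------------------------------
# boundary detection and scoring
# --------------------------------------------------------------------------

def crossing_times(
    times: np.ndarray, series_unwrapped: np.ndarray, level: float
) -> np.ndarray:
    """Upward crossings of an unwrapped phase series through level + 2πk."""
    taus = []
    k_lo = int(np.floor((series_unwrapped.min() - level) / TWO_PI))
    k_hi = int(np.ceil((series_unwrapped.max() - level) / TWO_PI))
    for k in range(k_lo, k_hi + 1):
        lev = level + k * TWO_PI
        above = series_unwrapped >= lev
        idx = np.flatnonzero(~above[:-1] & above[1:])
        for i in idx:
            y0, y1 = series_unwrapped[i], series_unwrapped[i + 1]
            frac = (lev - y0) / (y1 - y0)
            taus.append(times[i] + frac * (times[i + 1] - times[i]))
    return np.sort(np.array(taus))


def detect_boundary_times(
    times: np.ndarray,
    psi1: np.ndarray,
    vartheta: float = 3.0 * np.pi / 2.0,
    Ta: float = 30.0,
) -> np.ndarray:
    """Boundary-setting times: crossings of Ψ1 through ϑ, mod 2π.

    The series is temporally unwrapped before crossing detection (the
    phasor argument lives on the circle); crossings closer than Ta/2 are
    merged keeping the first, which suppresses double events from noise.
    """
    finite = np.isfinite(psi1)
    if finite.sum() < 2:
        return np.array([])
    t = np.asarray(times, float)[finite]
    unwrapped = np.unwrap(np.asarray(psi1, float)[finite])
    taus = crossing_times(t, unwrapped, vartheta % TWO_PI)
    merged: list[float] = []
    for tau in taus:
        if not merged or tau - merged[-1] >= Ta / 2.0:
            merged.append(tau)
    return np.array(merged)


def classify_boundary(
    times: np.ndarray,
    z: np.ndarray,
    tau: float,
    params: DetectionParams,
    Ta: float = 30.0,
) -> str | None:
    """normal/defective by Z(t, xa) over [τ - Ta/2, τ - Ta/2 + η].

    Normal iff every sample in the window satisfies Z >= Zc.  Returns None
    when the window is not covered by the series (boundary excluded).
    """
    lo = tau - Ta / 2.0
    hi = lo + params.eta
    if lo < times[0] or hi > times[-1]:
        return None
    m = (times >= lo) & (times <= hi)
    zwin = z[m]
    if len(zwin) == 0 or np.any(~np.isfinite(zwin)):
        return None
    return "normal" if np.all(zwin >= params.Zc) else "defective"


def number_boundaries(
    taus: np.ndarray,
    normal_flags: list[bool],
    Ta: float = 30.0,
    Delta: float = 0.3,
) -> dict[int, float]:
    """Assign segment-boundary numbers to the *normal* detected events.

    If the immediately preceding detected event was normal and numbered j,
    the current one gets j + 1; otherwise the expected number round(τ/Ta),
    reduced by one when the event is more than Δ·Ta early.  Index
    collisions keep the earlier event.
    """
    numbered: dict[int, float] = {}
    prev_number: int | None = None  # number of the immediately preceding event
    for tau, ok in zip(taus, normal_flags):
        if not ok:
            prev_number = None
            continue
        if prev_number is not None:
            j = prev_number + 1
        else:
            r = round(tau / Ta)
            j = r if (r - tau / Ta) < Delta else r - 1
        if j >= 1 and j not in numbered:
            numbered[j] = float(tau)
        prev_number = j
    return numbered


def score_record(
    times: np.ndarray,
    psi1: np.ndarray,
    z: np.ndarray,
    side: str,
    n_boundaries: int,
    params: DetectionParams,
    Ta: float = 30.0,
    vartheta: float = 3.0 * np.pi / 2.0,
) -> SegmentRecord:
    """Full scoring pipeline for one side's anterior time series.

    Detect crossings, classify each, number the normal ones, and label every
    boundary index 1..n_boundaries not claimed by a normal event defective.
    """
    taus = detect_boundary_times(times, psi1, vartheta, Ta)
    flags = [
        classify_boundary(times, z, tau, params, Ta) == "normal" for tau in taus
    ]
    numbered = number_boundaries(taus, flags, Ta, params.Delta)
    record = SegmentRecord(side=side)
    for j in range(1, n_boundaries + 1):
        record.labels[j] = j not in numbered
        if j in numbered:
            record.taus[j] = numbered[j]
    return record


def defect_runs(record: SegmentRecord) -> list[int]:
    """Lengths of maximal defective runs strictly inside (FRS, PLD]."""
    frs, pld = record.frs, record.pld
    if frs is None or pld is None:
        return []
    runs: list[int] = []
    length = 0
    for j in range(frs + 1, pld + 1):
        if record.labels.get(j, False):
            length += 1
        elif length:
            runs.append(length)
            length = 0
    if length:
        runs.append(length)
    return runs


def single_double_stats(
    left: SegmentRecord, right: SegmentRecord, start_after: int = 9
) -> tuple[int, int, float]:
    """(Ns, Nt, Fs) over loci > start_after present on both sides.

    Nt counts loci with at least one side defective, Ns those with exactly
    one; Fs = Ns/Nt (NaN when Nt = 0).
    """
    common = sorted(set(left.labels) & set(right.labels))
    nt = ns = 0
    for j in common:
        if j <= start_after:
            continue
        dl, dr = left.labels[j], right.labels[j]
        if dl or dr:
            nt += 1
            if dl != dr:
                ns += 1
    return ns, nt, (ns / nt if nt else np.nan)


def expected_single_fraction(p: float) -> float:
    """Fs under left-right independence with per-side defect probability p.

    Among loci with at least one defect, the single fraction is
    2p(1-p) / (2p(1-p) + p²) = 2(1-p)/(2-p); the p → 0 limit is 1.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return 2.0 * (1.0 - p) / (2.0 - p)


def arrested_stripe_positions(
    positions: np.ndarray,
    theta: np.ndarray,
    xa: float,
    side: str,
    geom: GeometryParams,
    dx_slice: float,
    vartheta: float = 3.0 * np.pi / 2.0,
) -> np.ndarray:
    """Axial positions of arrested phase stripes (θ = ϑ loci) for x < xa.

    The arrested pattern is sliced at the cell diameter, the slice mean
    phases are spatially unwrapped, and the ϑ-crossings are interpolated;
    consecutive crossings are one segment length apart.
    """
    m = positions[:, 0] < xa
    pos_a, th_a = positions[m], theta[m]
    if len(pos_a) == 0:
        return np.array([])
    xs = np.arange(pos_a[:, 0].min(), xa, dx_slice)
    prof = np.array(
        [slice_order(pos_a, th_a, x0, side, geom, dx_slice)[1] for x0 in xs]
    )
    ok = np.isfinite(prof)
    if ok.sum() < 2:
        return np.array([])
    return crossing_times(xs[ok] + dx_slice / 2.0, np.unwrap(prof[ok]),
                          vartheta % TWO_PI)


# --------------------------------------------------------------------------
# phase vorticity
# --------------------------------------------------------------------------

def vorticity_at_grid(
    points: np.ndarray,
    theta: np.ndarray,
    center: np.ndarray,
    params: VorticityParams,
    handedness: str = "ccw",
) -> float:
    """Winding index ψ in [0, 1] at one grid point of a 2D projection.

    A ring δl <= dist < δl + l around the point is cut into six π/3 sectors
    (counterclockwise from the first in-plane axis).  Sector phases are
    averaged circularly, cyclically permuted to start at the smallest mean
    (ascending i for ccw handedness, descending for cw), and Pearson-
    correlated against i = 0..5.  ψ = (θ̂5 - θ̂0)/2π when the correlation
    exceeds α and the winding is at least ψ_min; otherwise 0 (any empty
    sector also gives 0).
    """
    if handedness not in ("ccw", "cw"):
        raise ValueError("handedness must be 'ccw' or 'cw'")
    d = points - np.asarray(center, float)[None, :]
    dist = np.hypot(d[:, 0], d[:, 1])
    in_ring = (dist >= params.ring_offset) & (
        dist < params.ring_offset + params.ring_width
    )
    if not np.any(in_ring):
        return 0.0
    ang = np.arctan2(d[in_ring, 1], d[in_ring, 0]) % TWO_PI
    sector = np.minimum((ang / (np.pi / 3.0)).astype(int), 5)
    th = theta[in_ring]
    means = np.empty(6)
    for i in range(6):
        sel = sector == i
        if not np.any(sel):
            return 0.0
        means[i] = circular_mean(th[sel])[1]
    k = int(np.argmin(means))
    if handedness == "ccw":
        hat = means[(k + np.arange(6)) % 6]
    else:
        hat = means[(k - np.arange(6)) % 6]
    sd = hat.std()
    if sd == 0.0:
        return 0.0
    i_idx = np.arange(6)
    corr = ((i_idx - SECTOR_INDEX_MEAN) * (hat - hat.mean())).mean() / (
        np.sqrt(SECTOR_INDEX_VAR) * sd
    )
    psi = (hat[5] - hat[0]) / TWO_PI
    if corr > params.alpha and psi >= params.psi_min:
        return float(psi)
    return 0.0


def vorticity_plane(
    points: np.ndarray,
    theta: np.ndarray,
    x_grid: np.ndarray,
    u_grid: np.ndarray,
    params: VorticityParams,
    handedness: str = "ccw",
) -> np.ndarray:
    """Max-over-transverse ψ profile along x for one projected plane."""
    profile = np.zeros(len(x_grid))
    if len(points) == 0:
        return profile
    reach = params.ring_offset + params.ring_width
    order = np.argsort(points[:, 0])
    pts = points[order]
    th = theta[order]
    xs_sorted = pts[:, 0]
    for s, xs in enumerate(x_grid):
        lo = np.searchsorted(xs_sorted, xs - reach)
        hi = np.searchsorted(xs_sorted, xs + reach)
        if lo == hi:
            continue
        sub, sub_th = pts[lo:hi], th[lo:hi]
        best = 0.0
        for u in u_grid:
            psi = vorticity_at_grid(sub, sub_th, np.array([xs, u]), params, handedness)
            if psi > best:
                best = psi
        profile[s] = best
    return profile


def _slice_projections(
    positions: np.ndarray,
    theta: np.ndarray,
    geom: GeometryParams,
    side: str,
    params: VorticityParams,
    r: float | None = None,
):
    """The four 2D slice projections of one side's tissue.

    Two z-slabs projected to (x, y) planes catch vortices about the z axis;
    two y-slabs projected to (x, z) catch vortices about the y axis.
    Projection along a slab's normal preserves the in-plane orientation, so
    all four planes share the handedness convention of their in-plane axes.
    """
    rr = geom.r0 if r is None else r
    thick = params.slice_thickness
    y0 = 0.0 if side in (LEFT_PSM, "left") else 2.0 * geom.R
    x, y, z = positions[:, 0], positions[:, 1], positions[:, 2]
    side_sel = side_mask(positions, side, geom)
    out = []
    for z_lo in (0.0, 2.0 * rr - thick):
        m = side_sel & (z >= z_lo) & (z < z_lo + thick)
        out.append((np.column_stack([x[m], y[m]]), theta[m]))
    for y_lo in (y0, y0 + 2.0 * rr - thick):
        m = side_sel & (y >= y_lo) & (y < y_lo + thick)
        out.append((np.column_stack([x[m], z[m]]), theta[m]))
    return out


def vorticity_profile(
    positions: np.ndarray,
    theta: np.ndarray,
    geom: GeometryParams,
    xa: float,
    side: str,
    params: VorticityParams,
    r: float | None = None,
) -> dict[str, np.ndarray]:
    """ψ(max)(xs) per handedness channel for one side.

    For each of the four slice projections the ring detector runs on a grid
    (axial spacing Δx, transverse spacing Δy = Δz), is max-projected onto
    the x axis, and the four planes are max-combined.  "ccw" means the
    sector means ascend counterclockwise in the projected plane's own axes
    (seen from +z for x-y planes, from +y for x-z planes); reflecting the
    tissue y → -y therefore swaps the two channels.
    Returns {"x": grid, "ccw": profile, "cw": profile}.
    """
    rr = geom.r0 if r is None else r
    x_grid = np.arange(xa, geom.Lx + params.dx / 2.0, params.dx)
    out = {
        "x": x_grid,
        "ccw": np.zeros(len(x_grid)),
        "cw": np.zeros(len(x_grid)),
    }
    y0 = 0.0 if side in (LEFT_PSM, "left") else 2.0 * geom.R
    for points, th in _slice_projections(positions, theta, geom, side, params, r):
        if len(points) == 0:
            continue
        u_lo = y0 if points[:, 1].max() > 2.0 * rr else 0.0  # y vs z transverse
        u_grid = np.arange(u_lo, u_lo + 2.0 * rr + params.dy / 2.0, params.dy)
        for hand in ("ccw", "cw"):
            prof = vorticity_plane(points, th, x_grid, u_grid, params, hand)
            np.maximum(out[hand], prof, out=out[hand])
    return out


# --------------------------------------------------------------------------
# kymographs
# --------------------------------------------------------------------------

def kymograph(
    snapshots: list,
    observable: str,
    side: str,
    geom: GeometryParams,
    det: DetectionParams | None = None,
    vort: VorticityParams | None = None,
) -> Kymograph:
    """Kymograph of Z or ψ from a snapshot series.

    ``snapshots`` is a list of dicts with keys t, xa, positions, theta (the
    engine's snapshot format).  For Z the axial grid steps by dc; for ψ the
    detector's own grid is used and the two handedness channels are
    max-combined.
    """
    det = det or DetectionParams()
    vort = vort or VorticityParams()
    times = np.array([s["t"] for s in snapshots])
    xas = np.array([s["xa"] for s in snapshots])
    L0 = geom.Lx - xas.min()
    if observable == "Z":
        x_rel = np.arange(0.0, L0, det.dx_slice)
        values = np.full((len(snapshots), len(x_rel)), np.nan)
        for ti, snap in enumerate(snapshots):
            for xi, xr in enumerate(x_rel):
                values[ti, xi] = local_order(
                    snap["positions"], snap["theta"], snap["xa"] + xr, side, geom, det
                )
    elif observable == "psi":
        x_rel = np.arange(0.0, L0, vort.dx)
        values = np.zeros((len(snapshots), len(x_rel)))
        for ti, snap in enumerate(snapshots):
            prof = vorticity_profile(
                snap["positions"], snap["theta"], geom, snap["xa"], side, vort,
                r=snap.get("r"),
            )
            both = np.maximum(prof["ccw"], prof["cw"])
            values[ti, : min(len(both), len(x_rel))] = both[: len(x_rel)]
    else:
        raise ValueError("observable must be 'Z' or 'psi'")
    return Kymograph(
        times=times, x_rel=x_rel, xa=xas, values=values, side=side,
        observable=observable,
    )
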