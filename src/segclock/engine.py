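"""Simulation engine: initialization, time stepping, logging, scoring.

The stepper integrates the overdamped mechanics and the phase dynamics with
the Euler–Maruyama method at dt = 0.01 min.  Production runs go through a
numba kernel (:mod:`segclock._kernels`) in blocks of a few tens of steps;
between blocks the engine applies density-controlled cell influx, drops
long-arrested cells, and records the anterior observables that the
segment-boundary scoring consumes.  A pure-numpy reference step with
identical semantics backs the correctness tests.

Randomness: one root ``numpy.random.SeedSequence`` per run, spawned into
fixed substreams (initialization, phase noise, polarity noise, insertion)
so that disabling one noise channel never shifts another channel's draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels, observables
from .geometry import (
    LEFT_PSM,
    RIGHT_PSM,
    TAILBUD,
    GeometryParams,
    region_volume,
    total_volume,
)
from .mechanics import MechanicsParams, net_velocity, neighbor_pairs, polarity_step, Polarity
from .observables import DetectionParams, SegmentRecord, VorticityParams
from .phase_dynamics import PhaseParams, phase_increment
from .tissue_program import ProgramParams, cell_flux_update, sample_region_position

__all__ = [
    "RunConfig",
    "TissueState",
    "RunResult",
    "initialize",
    "step",
    "run",
    "calibrate_omega0",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class RunConfig:
    """Complete, validated description of one simulation."""

    geom: GeometryParams = field(default_factory=GeometryParams)
    mech: MechanicsParams = field(default_factory=MechanicsParams)
    phase: PhaseParams = field(default_factory=PhaseParams)
    program: ProgramParams = field(default_factory=ProgramParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    vorticity: VorticityParams = field(default_factory=VorticityParams)
    dt: float = 0.01  #: integration step (min)
    duration: float = 600.0  #: simulated time (min)
    seed: int = 0
    init_condition: str = "synchronized"  #: or "random_phase"
    obs_dt: float = 1.0  #: cadence of anterior/posterior records (min)
    snapshot_dt: float | None = None  #: full-state snapshot cadence (min)
    block_steps: int = 50  #: kernel steps between event handling
    relax_minutes: float = 10.0  #: initial mechanical relaxation

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration < 0:
            raise ValueError("dt must be > 0 and duration >= 0")
        if self.init_condition not in ("synchronized", "random_phase"):
            raise ValueError("init_condition must be synchronized or random_phase")
        # single source of truth for the anterior advection speed:
        # the segment-length constraint va + ua = c of the tissue program
        if self.mech.va != self.program.va:
            object.__setattr__(
                self, "mech", dataclasses.replace(self.mech, va=self.program.va)
            )
        # slice width follows the cell diameter
        if self.detection.dx_slice != self.mech.dc:
            object.__setattr__(
                self,
                "detection",
                dataclasses.replace(self.detection, dx_slice=self.mech.dc),
            )

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def xa_of(self, t: float) -> float:
        return self.program.ua * t

    def r_of(self, t: float) -> float:
        return max(self.geom.r0 - self.program.sr * t, 2.0 * self.mech.dc)


@dataclass
class TissueState:
    """Mutable particle state of the tissue at one instant."""

    t: float
    pos: np.ndarray  #: (N, 3) μm
    theta: np.ndarray  #: (N,) rad in [0, 2π)
    pphi: np.ndarray  #: (N,) polarity polar angle
    ppsi: np.ndarray  #: (N,) polarity azimuth
    arrested: np.ndarray  #: (N,) uint8
    t_arrest: np.ndarray  #: (N,) min
    xa: float = 0.0
    r: float = 25.0

    @property
    def n_cells(self) -> int:
        return len(self.theta)

    @property
    def active(self) -> np.ndarray:
        return self.arrested == 0

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def active_region_counts(self, geom: GeometryParams) -> dict[str, int]:
        pos = self.pos[self.active]
        in_psm = (pos[:, 0] >= self.xa) & (pos[:, 0] < geom.Xc)
        tailbud = pos[:, 0] >= geom.Xc
        left = in_psm & (pos[:, 1] < geom.Yc)
        return {
            LEFT_PSM: int(left.sum()),
            RIGHT_PSM: int(in_psm.sum() - left.sum()),
            TAILBUD: int(tailbud.sum()),
        }

    def append_cell(self, pos, theta: float, phi: float, psi: float) -> None:
        self.pos = np.vstack([self.pos, np.asarray(pos, float)[None, :]])
        self.theta = np.append(self.theta, theta % TWO_PI)
        self.pphi = np.append(self.pphi, phi)
        self.ppsi = np.append(self.ppsi, psi)
        self.arrested = np.append(self.arrested, np.uint8(0))
        self.t_arrest = np.append(self.t_arrest, np.nan)

    def reorder(self, bin_size: float) -> None:
        """Sort cells by spatial bin for cache-friendly neighbor traversal.

        Purely a memory-layout optimization: all per-cell arrays are
        permuted together, so the dynamics are unchanged.
        """
        key = np.floor(self.pos / bin_size).astype(np.int64)
        order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
        self.pos = np.ascontiguousarray(self.pos[order])
        self.theta = self.theta[order]
        self.pphi = self.pphi[order]
        self.ppsi = self.ppsi[order]
        self.arrested = self.arrested[order]
        self.t_arrest = self.t_arrest[order]

    def drop(self, mask: np.ndarray) -> int:
        """Remove cells where mask is True; returns how many were removed."""
        keep = ~mask
        self.pos = self.pos[keep]
        self.theta = self.theta[keep]
        self.pphi = self.pphi[keep]
        self.ppsi = self.ppsi[keep]
        self.arrested = self.arrested[keep]
        self.t_arrest = self.t_arrest[keep]
        return int(mask.sum())

    def snapshot(self) -> dict:
        return {
            "t": self.t,
            "xa": self.xa,
            "r": self.r,
            "positions": self.pos.copy(),
            "theta": self.theta.copy(),
            "pphi": self.pphi.copy(),
            "ppsi": self.ppsi.copy(),
            "arrested": self.arrested.copy(),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n_cells),
                "t_min": self.t,
                "x_um": self.pos[:, 0],
                "y_um": self.pos[:, 1],
                "z_um": self.pos[:, 2],
                "theta_rad": self.theta,
                "phi_pol_rad": self.pphi,
                "psi_pol_rad": self.ppsi,
                "arrested": self.arrested.astype(int),
            }
        )


@dataclass
class RunResult:
    """Everything a finished run produced."""

    config: RunConfig
    times: np.ndarray  #: observation times (min)
    psi1: dict[str, np.ndarray]  #: anterior mean phase per side
    z_anterior: dict[str, np.ndarray]  #: local order at xa per side
    psi_posterior: np.ndarray  #: circular mean phase near the posterior tip
    n_active: np.ndarray  #: active cell count per observation
    records: dict[str, SegmentRecord]
    events: pd.DataFrame  #: insertion/arrest/drop counts per block
    snapshots: list[dict]
    state: TissueState
    status: str = "ok"


def _spawn_streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ("init", "phase", "polarity", "insertion")
    return {
        name: np.random.default_rng(child)
        for name, child in zip(names, root.spawn(len(names)))
    }


def initialize(
    config: RunConfig, rngs: dict[str, np.random.Generator] | None = None
) -> TissueState:
    """Random placement at target density + 10 min mechanical relaxation.

    Cells are placed uniformly in the U-domain (region chosen by volume),
    then the equation of motion runs without advection and with an extra
    frictionless wall at x = xa = 0 to relax random-overlap stresses.
    Phases are then 3π/2 everywhere (synchronized) or i.i.d. uniform
    (random_phase); polarity angles uniform in [0, π] × [0, 2π).
    """
    rngs = rngs or _spawn_streams(config.seed)
    rng = rngs["init"]
    geom, program = config.geom, config.program
    n0 = int(round(program.rho0 * total_volume(geom, 0.0)))
    if n0 <= 0:
        raise ValueError("configured density/geometry gives no cells")
    vols = {
        reg: region_volume(geom, 0.0, reg) for reg in (LEFT_PSM, RIGHT_PSM, TAILBUD)
    }
    regions = list(vols)
    weights = np.array([vols[reg] for reg in regions])
    weights = weights / weights.sum()
    picks = rng.choice(len(regions), size=n0, p=weights)
    pos = np.array(
        [
            sample_region_position(regions[k], geom, 0.0, zeta=0.0, rng=rng)
            for k in picks
        ]
    )
    if config.init_condition == "synchronized":
        theta = np.full(n0, 3.0 * np.pi / 2.0)
    else:
        theta = rng.uniform(0.0, TWO_PI, n0)
    pphi = rng.uniform(0.0, np.pi, n0)
    ppsi = rng.uniform(0.0, TWO_PI, n0)
    state = TissueState(
        t=0.0,
        pos=pos,
        theta=theta,
        pphi=pphi,
        ppsi=ppsi,
        arrested=np.zeros(n0, np.uint8),
        t_arrest=np.full(n0, np.nan),
        xa=0.0,
        r=geom.r0,
    )
    n_relax = int(round(config.relax_minutes / config.dt))
    if n_relax:
        P = _kernels.pack_params(geom, config.mech, config.phase, program, config.dt)
        dummy = np.zeros((1, 1))
        if config.mech.Dphi > 0:
            noise_phi = rngs["polarity"].standard_normal((n_relax, n0))
            noise_psi = rngs["polarity"].standard_normal((n_relax, n0))
        else:
            noise_phi = noise_psi = dummy
        _kernels.advance_block(
            state.pos, state.theta, state.pphi, state.ppsi, state.arrested,
            state.t_arrest, 0.0, n_relax, P, 1, dummy, noise_phi, noise_psi,
        )
    return state


def step(
    state: TissueState,
    config: RunConfig,
    noise_theta: np.ndarray | None = None,
    noise_phi: np.ndarray | None = None,
    noise_psi: np.ndarray | None = None,
) -> int:
    """One reference Euler–Maruyama step (in place); returns new arrests.

    Semantics mirror one kernel step exactly: increments evaluated from the
    state at t, simultaneous update, then schedules and anterior arrest.
    Noise arrays are per-cell standard normals for this step.
    """
    geom, mech, phase, program = config.geom, config.mech, config.phase, config.program
    t, dt = state.t, config.dt
    xa = config.xa_of(t)
    L = geom.Lx - xa
    r = config.r_of(t)
    active = state.active
    include = active | (state.pos[:, 0] >= xa - mech.dc)
    idx = np.flatnonzero(include)
    pairs_local = neighbor_pairs(state.pos[idx], mech.dc)
    pairs = idx[pairs_local] if len(pairs_local) else np.empty((0, 2), int)

    vel = net_velocity(
        state.pos, np.column_stack([state.pphi, state.ppsi]), geom, mech,
        xa, t=t, r=r, pairs=pairs,
    )
    vel[~active] = [-mech.va, 0.0, 0.0]
    dtheta = phase_increment(
        state.theta, state.pos[:, 0], pairs, xa, L, t, dt, phase,
        noise=noise_theta,
    )
    # simultaneous update
    state.pos += vel * dt
    wrapped = (state.theta + dtheta) % TWO_PI
    state.theta = np.where(active, wrapped, state.theta)
    if mech.Dphi > 0 and noise_phi is not None:
        for i in np.flatnonzero(active):
            pol = polarity_step(
                Polarity(state.pphi[i], state.ppsi[i]), dt, mech.Dphi,
                noise_phi[i], noise_psi[i],
            )
            state.pphi[i], state.ppsi[i] = pol.phi, pol.psi
    state.t = t + dt
    state.xa = config.xa_of(state.t)
    state.r = config.r_of(state.t)
    newly = active & (state.pos[:, 0] < state.xa)
    state.arrested[newly] = 1
    state.t_arrest[newly] = state.t
    return int(newly.sum())


def run(config: RunConfig, progress: bool = False) -> RunResult:
    """Initialize and integrate for the configured duration.

    Returns anterior/posterior observable series, scored segment records per
    side, optional snapshots, and the final state (which retains arrested
    cells for the configured retention window — the stripe pattern).
    """
    rngs = _spawn_streams(config.seed)
    state = initialize(config, rngs)
    geom, mech, phase, program = config.geom, config.mech, config.phase, config.program
    P = _kernels.pack_params(geom, mech, phase, program, config.dt)
    dummy = np.zeros((1, 1))

    block_dt = config.block_steps * config.dt
    n_blocks = int(round(config.duration / block_dt))
    obs_every = max(1, int(round(config.obs_dt / block_dt)))
    snap_every = (
        None
        if config.snapshot_dt is None
        else max(1, int(round(config.snapshot_dt / block_dt)))
    )

    times: list[float] = []
    psi1 = {"left": [], "right": []}
    z_ant = {"left": [], "right": []}
    psi_post: list[float] = []
    n_active: list[int] = []
    snapshots: list[dict] = []
    events: list[dict] = []
    status = "ok"

    def record_obs() -> None:
        times.append(state.t)
        act = state.active
        pos_a, th_a = state.pos[act], state.theta[act]
        for side in ("left", "right"):
            p1, z = observables.anterior_metrics(
                pos_a, th_a, state.xa, side, geom, config.detection
            )
            psi1[side].append(p1)
            z_ant[side].append(z)
        psi_post.append(
            observables.posterior_mean_phase(pos_a, th_a, geom.Lx)
        )
        n_active.append(state.n_active)

    record_obs()
    if snap_every is not None:
        snapshots.append(state.snapshot())

    iterator = range(1, n_blocks + 1)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator)
        except ImportError:
            pass

    reorder_every = max(1, int(round(1.0 / block_dt)))
    for b in iterator:
        if b % reorder_every == 1 or reorder_every == 1:
            state.reorder(mech.dc)
        n = state.n_cells
        if phase.Dtheta > 0:
            nth = rngs["phase"].standard_normal((config.block_steps, n))
        else:
            nth = dummy
        if mech.Dphi > 0:
            nph = rngs["polarity"].standard_normal((config.block_steps, n))
            nps = rngs["polarity"].standard_normal((config.block_steps, n))
        else:
            nph = nps = dummy
        crossings, err = _kernels.advance_block(
            state.pos, state.theta, state.pphi, state.ppsi, state.arrested,
            state.t_arrest, state.t, config.block_steps, P, 0, nth, nph, nps,
        )
        state.t += block_dt
        state.xa = config.xa_of(state.t)
        state.r = config.r_of(state.t)
        if err:
            status = "non-finite state"
            break
        if geom.Xc - state.xa < 2.0 * mech.dc:
            # the tubes (the PSM proper) are consumed before Lx - xa reaches
            # zero because the tailbud occupies the last R + r0 of the axis
            status = "PSM consumed"
            break
        inserted = 0
        for _ in range(crossings):
            before = state.n_cells
            cell_flux_update(state, geom, program, rngs["insertion"], r=state.r)
            inserted += state.n_cells - before
        old = (state.arrested == 1) & (
            state.t - state.t_arrest > program.retention
        )
        dropped = state.drop(old) if np.any(old) else 0
        if crossings or inserted or dropped:
            events.append(
                {
                    "t_min": state.t,
                    "arrested": crossings,
                    "inserted": inserted,
                    "dropped": dropped,
                }
            )
        if b % obs_every == 0:
            record_obs()
        if snap_every is not None and b % snap_every == 0:
            snapshots.append(state.snapshot())

    t_arr = np.array(times)
    n_boundaries = max(0, int(np.floor(config.duration / phase.Ta)) - 1)
    records = {}
    for side in ("left", "right"):
        records[side] = observables.score_record(
            t_arr,
            np.array(psi1[side]),
            np.array(z_ant[side]),
            side,
            n_boundaries,
            config.detection,
            Ta=phase.Ta,
            vartheta=phase.vartheta,
        )
    return RunResult(
        config=config,
        times=t_arr,
        psi1={k: np.array(v) for k, v in psi1.items()},
        z_anterior={k: np.array(v) for k, v in z_ant.items()},
        psi_posterior=np.array(psi_post),
        n_active=np.array(n_active),
        records=records,
        events=pd.DataFrame(events, columns=["t_min", "arrested", "inserted", "dropped"]),
        snapshots=snapshots,
        state=state,
        status=status,
    )


def calibrate_omega0(
    config: RunConfig,
    target_Ta: float | None = None,
    tol: float = 0.01,
    max_iter: int = 6,
    probe_minutes: float = 180.0,
) -> float:
    """Tune ω0 so the measured anterior period equals Ta (shortening runs).

    Waves traveling toward a posteriorly receding anterior end are read out
    at a Doppler-shortened period, so the posterior frequency must be
    lowered to keep the segmentation period at Ta.  A short deterministic
    synchronized run measures the crossing intervals of Ψ1 at xa; a secant
    iteration adjusts ω0 until the measured period is within ``tol``
    (relative) of the target.
    """
    target = target_Ta if target_Ta is not None else config.phase.Ta

    def measure(om0: float) -> float:
        probe = config.replace(
            phase=dataclasses.replace(
                config.phase, omega0=om0, Dtheta=0.0, t_washout=0.0
            ),
            mech=dataclasses.replace(config.mech, Dphi=0.0, vs=0.0),
            init_condition="synchronized",
            duration=probe_minutes,
            snapshot_dt=None,
        )
        res = run(probe)
        taus = observables.detect_boundary_times(
            res.times, res.psi1["left"], probe.phase.vartheta, target
        )
        if len(taus) < 3:
            raise RuntimeError("calibration probe produced too few boundary events")
        intervals = np.diff(taus)
        return float(np.mean(intervals[len(intervals) // 2:]))

    om = config.phase.omega0
    ta = measure(om)
    if abs(ta - target) / target <= tol:
        return om
    # secant on f(ω0) = Ta(ω0) - target, seeded with the no-Doppler guess
    om_prev, ta_prev = om, ta
    om = om * ta / target
    for _ in range(max_iter):
        ta = measure(om)
        if abs(ta - target) / target <= tol:
            return om
        denom = ta - ta_prev
        if denom == 0:
            break
        om_next = om - (ta - target) * (om - om_prev) / denom
        om_prev, ta_prev, om = om, ta, om_next
    return om
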