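import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from segclock import GeometryParams
from segclock.geometry import boundary_force
from segclock.mechanics import (
    MechanicsParams,
    Polarity,
    advection_speed,
    advection_velocity,
    motility_speed,
    net_velocity,
    pair_force,
    polarity_step,
    polarity_walk,
    strain_rate,
)
from segclock.tissue_program import sample_region_position

VA = 55.0 / 30.0


@settings(max_examples=50, deadline=None)
@given(
    va=st.floats(0.5, 4.0),
    vp=st.floats(0.0, 10.0),
    xq=st.floats(0.05, 0.95),
)
def test_advection_profile_properties(va, vp, xq):
    """v(0) = va, v(1) = 0, and continuity at the knot, for any parameters."""
    p = MechanicsParams(va=va, vp_early=vp, vp_late=vp, xq=xq)
    L = 400.0
    assert advection_speed(0.0, 0.0, L, p) == pytest.approx(va)
    assert advection_speed(L, 0.0, L, p) == pytest.approx(0.0, abs=1e-12)
    below = advection_speed(xq * L - 1e-9, 0.0, L, p)
    above = advection_speed(xq * L + 1e-9, 0.0, L, p)
    assert below == pytest.approx(above, abs=1e-6)
    assert above == pytest.approx(vp * (1 - xq), abs=1e-6)


def test_advection_velocity_points_anterior():
    p = MechanicsParams()
    v = advection_velocity(0.0, 0.0, 400.0, p)
    assert v[0] == pytest.approx(-p.va)
    assert v[1] == v[2] == 0.0


def test_advection_switch_at_tg():
    p = MechanicsParams(vp_early=0.3 * VA, vp_late=2.0 * VA, xq=0.5, tg=270.0)
    v_before = advection_speed(300.0, 0.0, 400.0, p, t=269.0)
    v_after = advection_speed(300.0, 0.0, 400.0, p, t=271.0)
    assert v_before != v_after


def test_strain_rate_integrates_to_va():
    """∫|∂v/∂x| dx over the PSM equals the total velocity drop va."""
    L = 400.0
    for vp_fac in (0.0, 0.3, 1.0):
        p = MechanicsParams(vp_early=vp_fac * VA, vp_late=vp_fac * VA, xq=0.4)
        chi = np.linspace(0, 1, 20001)
        total = np.trapezoid(strain_rate(chi, p, L), chi) * L
        assert total == pytest.approx(p.va, rel=1e-4)
    # vp = 0: all deformation anterior, zero posterior strain
    p0 = MechanicsParams(vp_early=0.0, vp_late=0.0, xq=0.4)
    assert strain_rate(0.9, p0, L) == 0.0
    # va = vp: uniform strain vp/L
    pu = MechanicsParams(va=VA, vp_early=VA, vp_late=VA, xq=0.4)
    assert strain_rate(0.1, pu, L) == pytest.approx(VA / L)
    assert strain_rate(0.9, pu, L) == pytest.approx(VA / L)


def test_motility_gradient():
    p = MechanicsParams(vs=1.0, Xv=1.0, h=3.0)
    L = 400.0
    assert motility_speed(L, 0.0, L, p) == pytest.approx(1.0)  # posterior tip
    assert motility_speed(0.0, 0.0, L, p) == pytest.approx(0.5)  # Xv = 1 anterior
    x = np.linspace(0, L, 100)
    v = motility_speed(x, 0.0, L, MechanicsParams(vs=1.0, Xv=0.4, h=3.0))
    assert np.all(np.diff(v) >= 0)  # monotone toward posterior


def test_polarity_step_basics(rng):
    pol = Polarity(phi=1.0, psi=2.0)
    assert polarity_step(pol, 0.01, 0.0, 0.5, -0.3) is pol  # no noise, no change
    out = polarity_step(pol, 0.01, 0.1, 0.5, -0.3)
    assert np.linalg.norm(out.n) == pytest.approx(1.0, abs=1e-9)
    assert 0.0 <= out.psi < 2 * np.pi


def test_polarity_walk_matches_single_step(rng):
    phi0, psi0 = np.array([1.2]), np.array([0.7])
    rng1 = np.random.default_rng(42)
    w_phi, w_psi = polarity_walk(phi0, psi0, 0.01, 0.1, 1, rng1)
    rng2 = np.random.default_rng(42)
    xi_phi, xi_psi = rng2.standard_normal(1), rng2.standard_normal(1)
    ref = polarity_step(Polarity(1.2, 0.7), 0.01, 0.1, xi_phi[0], xi_psi[0])
    assert w_phi[0] == pytest.approx(ref.phi, abs=1e-12)
    assert w_psi[0] == pytest.approx(ref.psi, abs=1e-12)


def test_polarity_stationary_distribution_uniform_on_sphere(rng):
    """cos φ of the long-run polarity walk is uniform on [-1, 1]."""
    n = 4000
    phi = np.arccos(rng.uniform(-1, 1, n))  # start uniform; walk must preserve it
    psi = rng.uniform(0, 2 * np.pi, n)
    phi, psi = polarity_walk(phi, psi, 0.01, 0.5, 800, rng)
    ks = stats.kstest(np.cos(phi), "uniform", args=(-1, 2))
    assert ks.pvalue > 0.01
    # and from a very non-uniform start it relaxes to uniform
    phi2 = np.full(n, np.pi / 2)
    phi2, _ = polarity_walk(phi2, psi, 0.01, 0.5, 1500, rng)
    ks2 = stats.kstest(np.cos(phi2), "uniform", args=(-1, 2))
    assert ks2.pvalue > 0.01


def test_pair_force_examples(rng):
    mu, dc = 8.71, 11.0
    a = np.zeros(3)
    assert np.allclose(pair_force(a, np.array([dc, 0, 0]), mu, dc), 0.0)
    f = pair_force(a, np.array([dc / 2, 0, 0]), mu, dc)
    assert np.linalg.norm(f) == pytest.approx(mu / 2)  # μ(1 - 1/2)
    assert f[0] < 0  # repulsion pushes i away from j
    # coincident cells: finite push of magnitude μ
    f0 = pair_force(a, a, mu, dc)
    assert np.linalg.norm(f0) == pytest.approx(mu)


def test_pair_force_antisymmetry(rng):
    mu, dc = 8.71, 11.0
    for _ in range(1000):
        xi = rng.uniform(-5, 5, 3)
        xj = xi + rng.uniform(-1, 1, 3) * dc / 2
        fij = pair_force(xi, xj, mu, dc)
        fji = pair_force(xj, xi, mu, dc)
        assert np.abs(fij + fji).max() < 1e-12


def test_net_velocity_reduces_to_advection(geom):
    """Isolated cell on the tube axis with vs = 0 feels only advection."""
    p = MechanicsParams(vs=0.0)
    pos = np.array([[100.0, geom.left_axis[0], geom.left_axis[1]]])
    ang = np.array([[1.0, 1.0]])
    v = net_velocity(pos, ang, geom, p, xa=0.0)
    expected = advection_velocity(100.0, 0.0, geom.Lx, p)
    assert np.abs(v[0] - expected).max() < 1e-6 * 20.0  # wall force ~ e^{-25}


def test_net_velocity_opposite_for_overlapping_pair(geom):
    """Overlapping cells on the torus core circle repel symmetrically."""
    p = MechanicsParams(vs=0.0)
    core = np.array([geom.Xc + geom.R, geom.Yc, geom.Zc])  # wall force ~ e^{-25}
    pos = np.stack([core + [0, -2.0, 0], core + [0, 2.0, 0]])
    ang = np.ones((2, 2))
    v = net_velocity(pos, ang, geom, p, xa=0.0)
    # both feel the same advection; the repulsion parts are equal-opposite
    adv = advection_velocity(core[0], 0.0, geom.Lx, p)
    rep0, rep1 = v[0] - adv, v[1] - adv
    assert np.abs(rep0 + rep1).max() < 1e-6
    assert rep0[1] < 0 < rep1[1]  # push apart along their separation


def test_neighbor_list_equals_all_pairs(geom, rng):
    """kd-tree neighbor assembly ≡ brute-force O(N²) sum to 1e-12."""
    p = MechanicsParams()
    n = 200
    pos = np.array(
        [sample_region_position("tailbud", geom, 0.0, 0.0, rng) for _ in range(n)]
    )
    ang = np.column_stack([rng.uniform(0, np.pi, n), rng.uniform(0, 2 * np.pi, n)])
    fast = net_velocity(pos, ang, geom, p, xa=0.0)
    brute = np.zeros((n, 3))
    from segclock.mechanics import motility_speed, polarity_vector

    brute += advection_velocity(pos[:, 0], 0.0, geom.Lx, p)
    brute += motility_speed(pos[:, 0], 0.0, geom.Lx, p)[:, None] * polarity_vector(
        ang[:, 0], ang[:, 1]
    )
    for i in range(n):
        for j in range(n):
            if i != j:
                brute[i] += pair_force(pos[i], pos[j], p.mu, p.dc)
        brute[i] += boundary_force(pos[i], geom, 0.0, p.mu_b, p.r_b)
    assert np.abs(fast - brute).max() < 1e-12


def test_momentum_free_repulsion(geom, rng):
    """Total pair force over the whole tissue sums to the zero vector."""
    p = MechanicsParams(vs=0.0)
    n = 300
    pos = np.array(
        [sample_region_position("tailbud", geom, 0.0, 0.0, rng) for _ in range(n)]
    )
    total = np.zeros(3)
    for i in range(n):
        for j in range(i + 1, n):
            f = pair_force(pos[i], pos[j], p.mu, p.dc)
            total += f + (-f)
    assert np.abs(total).max() < 1e-10
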