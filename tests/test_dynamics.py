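import numpy as np
import pytest
from hypothesis import given, strategies as st

from photohop.constants import EV_TO_HARTREE, FS_TO_AU_TIME
from photohop.errors import DegenerateStateError, PropagationError
from photohop.dynamics import (
    SpinDiabaticHamiltonian,
    TrajectoryConfig,
    attempt_hop,
    compute_ktdc,
    hop_probability,
    propagate_electronic,
    run_ensemble,
    run_trajectory,
    velocity_verlet_step,
)
from photohop.geometry import SurfacePoint, kinetic_energy
from photohop.initial_conditions import sample_wigner


def two_state_h(e=(0.0, 0.0), v=0.0, tdc=0.0):
    soc = np.array([[0.0, v], [v, 0.0]])
    t = np.array([[0.0, tdc], [-tdc, 0.0]])
    return SpinDiabaticHamiltonian(np.array(e, float), soc, t)


# ----------------------------------------------------------------------
# electronic propagation


def test_rabi_oscillation_closed_form():
    # constant two-level coupling V: P2(t) = sin^2(V t / hbar)
    V = 0.01
    H = two_state_h(v=V)
    period = np.pi / V
    dt = period / 200.0
    n_steps = 10 * 200  # ten full Rabi periods
    c = np.array([1.0 + 0j, 0.0 + 0j])
    worst_p = 0.0
    worst_norm = 0.0
    for k in range(1, n_steps + 1):
        c_prev_norm = np.linalg.norm(c)
        c = propagate_electronic(c, H, H, dt, substeps=2)
        worst_norm = max(worst_norm, abs(np.linalg.norm(c) - c_prev_norm))
        p2 = abs(c[1]) ** 2
        worst_p = max(worst_p, abs(p2 - np.sin(V * k * dt) ** 2))
    assert worst_p < 1e-6
    assert worst_norm < 1e-8


def test_norm_conserved_time_dependent_generator():
    Ha = two_state_h(e=(0.0, 0.05), v=0.002, tdc=0.001)
    Hb = two_state_h(e=(0.01, 0.04), v=0.004, tdc=-0.003)
    c = np.array([np.sqrt(0.7), np.sqrt(0.3) * 1j])
    for _ in range(50):
        c = propagate_electronic(c, Ha, Hb, 20.0, substeps=20)
        Ha, Hb = Hb, Ha
        assert abs(np.linalg.norm(c) - 1.0) < 1e-10


def test_substep_halving_converged():
    # production protocol (0.5 fs nuclear step, 20 substeps) at realistic
    # Hamiltonian magnitudes: halving the substep barely moves amplitudes
    dt = 0.5 * FS_TO_AU_TIME
    n_steps = 200  # 100 fs sweep through an avoided crossing

    def h_at(k):
        gap = 0.10 * abs(k - n_steps / 2) / (n_steps / 2) + 0.002
        tdc = 0.03 * np.exp(-((k - n_steps / 2) / 15.0) ** 2)
        return two_state_h(e=(-0.30, -0.30 + gap), v=1.4e-3, tdc=tdc)

    c20 = np.array([np.sqrt(0.7), np.sqrt(0.3) * 1j])
    c40 = c20.copy()
    for k in range(n_steps):
        Ha, Hb = h_at(k), h_at(k + 1)
        c20 = propagate_electronic(c20, Ha, Hb, dt, substeps=20)
        c40 = propagate_electronic(c40, Ha, Hb, dt, substeps=40)
        assert np.max(np.abs(c40 - c20)) < 1e-8


def test_hermiticity_guard():
    bad = SpinDiabaticHamiltonian.__new__(SpinDiabaticHamiltonian)
    object.__setattr__(bad, "energies", np.zeros(2))
    object.__setattr__(bad, "soc", np.array([[0.0, 1.0], [0.0, 0.0]]))
    object.__setattr__(bad, "tdc", np.zeros((2, 2)))
    good = two_state_h()
    with pytest.raises(PropagationError, match="Hermitian"):
        propagate_electronic(np.array([1.0 + 0j, 0j]), bad, good, 1.0, 2)


def test_hamiltonian_validation():
    with pytest.raises(PropagationError, match="symmetric"):
        SpinDiabaticHamiltonian(np.zeros(2),
                                np.array([[0.0, 1.0], [0.0, 0.0]]),
                                np.zeros((2, 2)))
    with pytest.raises(PropagationError, match="antisymmetric"):
        SpinDiabaticHamiltonian(np.zeros(2), np.zeros((2, 2)),
                                np.array([[0.0, 1.0], [1.0, 0.0]]))


def test_generator_is_hermitian():
    H = two_state_h(e=(0.1, 0.2), v=0.03, tdc=0.004)
    K = H.generator()
    assert np.max(np.abs(K - K.conj().T)) < 1e-15


# ----------------------------------------------------------------------
# curvature-driven time-derivative coupling


@given(st.floats(0.001, 0.015), st.floats(1e-9, 1e-5))
def test_ktdc_quadratic_gap_closed_form(a, b):
    # gap(t) = a + b t^2 sampled at -2dt, -dt, 0: sigma = 0.5 sqrt(2 b / a)
    dt = 20.0
    hist = [a + b * (2 * dt) ** 2, a + b * dt**2, a]
    gate = 0.02
    expected = 0.5 * np.sqrt(2.0 * b / a)
    got = compute_ktdc(hist, dt, gate)
    assert got == pytest.approx(expected, abs=1e-10, rel=1e-10)


def test_ktdc_constant_gap_zero():
    assert compute_ktdc([0.005, 0.005, 0.005], 20.0, 0.02) == 0.0


def test_ktdc_gate_suppresses():
    gate = 0.5 * EV_TO_HARTREE
    hist = [0.6 * EV_TO_HARTREE, 0.55 * EV_TO_HARTREE, 0.52 * EV_TO_HARTREE]
    assert compute_ktdc(hist, 20.0, gate) == 0.0
    # exactly at the gate is still suppressed
    assert compute_ktdc([0.6, 0.55, gate], 20.0, gate) == 0.0
    # zero gate suppresses everything
    assert compute_ktdc([0.005, 0.004, 0.003], 20.0, 0.0) == 0.0


def test_ktdc_warmup_and_negative_curvature():
    assert compute_ktdc([], 20.0, 0.02) == 0.0
    assert compute_ktdc([0.005], 20.0, 0.02) == 0.0
    assert compute_ktdc([0.005, 0.004], 20.0, 0.02) == 0.0
    # concave history (gap'' < 0) gives zero, not a complex number
    assert compute_ktdc([0.003, 0.005, 0.006], 20.0, 0.02) == 0.0


# ----------------------------------------------------------------------
# flux bookkeeping and hop probabilities


def test_channel_flux_matches_population_change():
    # summed per-channel flux out of the active state equals the
    # brute-force active-population change over the step
    Ha = two_state_h(e=(0.0, 0.002), v=0.0008, tdc=0.0005)
    Hb = two_state_h(e=(0.001, 0.0015), v=0.0012, tdc=-0.0002)
    c0 = np.array([np.sqrt(0.85), np.sqrt(0.15) * np.exp(0.4j)])
    c1, flux_soc, flux_tdc = propagate_electronic(
        c0, Ha, Hb, 20.0, substeps=400, active=0)
    dp = abs(c0[0]) ** 2 - abs(c1[0]) ** 2
    assert abs((flux_soc + flux_tdc).sum() - dp) < 1e-6


def test_flux_matches_population_change_multistate():
    rng = np.random.Generator(np.random.Philox(5))
    e = rng.uniform(0, 0.01, 4)
    soc = rng.normal(0, 1e-3, (4, 4))
    soc = 0.5 * (soc + soc.T)
    np.fill_diagonal(soc, 0.0)
    tdc = rng.normal(0, 5e-4, (4, 4))
    tdc = 0.5 * (tdc - tdc.T)
    Ha = SpinDiabaticHamiltonian(e, soc, tdc)
    Hb = SpinDiabaticHamiltonian(e * 0.9, soc * 1.1, tdc * 0.8)
    c0 = rng.normal(size=4) + 1j * rng.normal(size=4)
    c0 /= np.linalg.norm(c0)
    c1, fs, ft = propagate_electronic(c0, Ha, Hb, 20.0, substeps=400, active=2)
    dp = abs(c0[2]) ** 2 - abs(c1[2]) ** 2
    assert abs((fs + ft).sum() - dp) < 1e-6


def test_hop_probability_clamps_and_tags():
    fs = np.array([0.0, 0.02, -0.05])
    ft = np.array([0.0, 0.005, 0.2])
    g, kinds = hop_probability(fs, ft, rho_active=0.5)
    assert g[0] == 0.0
    assert g[1] == pytest.approx(0.025 / 0.5)
    assert g[2] == pytest.approx(0.15 / 0.5)
    assert kinds[1] == "ISC" and kinds[2] == "IC"
    # negative net flux clamps to zero
    g2, _ = hop_probability(np.array([0.0, -0.1]), np.array([0.0, 0.01]), 0.5)
    assert g2[1] == 0.0
    # totals above one are rescaled
    g3, _ = hop_probability(np.array([0.0, 0.4]), np.array([0.0, 0.4]), 0.5)
    assert g3.sum() == pytest.approx(1.0)


def test_hop_probability_degenerate_population():
    with pytest.raises(DegenerateStateError):
        hop_probability(np.zeros(2), np.zeros(2), rho_active=0.0)


# ----------------------------------------------------------------------
# velocity Verlet


def test_velocity_verlet_free_particle_exact():
    coords = np.array([[0.0, 0.0, 0.0]])
    vel = np.array([[1e-3, -2e-3, 5e-4]])
    masses = np.array([1836.0])
    zero = np.zeros((1, 3))
    for k in range(1, 501):
        coords, vel, _ = velocity_verlet_step(
            coords, vel, zero, masses, 10.0, lambda x: zero)
        assert np.allclose(coords, np.array([[1e-3, -2e-3, 5e-4]]) * 10.0 * k,
                           atol=1e-12)
        assert np.allclose(vel, [[1e-3, -2e-3, 5e-4]], atol=1e-15)


def _harmonic_drift(dt, t_total):
    k_force = 0.02
    m = np.array([2000.0])
    grad_fn = lambda x: k_force * x
    coords = np.array([[0.5, 0.0, 0.0]])
    vel = np.zeros((1, 3))
    grad = grad_fn(coords)
    e0 = kinetic_energy(vel, m) + 0.5 * k_force * np.sum(coords**2)
    worst = 0.0
    for _ in range(int(round(t_total / dt))):
        coords, vel, grad = velocity_verlet_step(coords, vel, grad, m, dt,
                                                 grad_fn)
        e = kinetic_energy(vel, m) + 0.5 * k_force * np.sum(coords**2)
        worst = max(worst, abs(e - e0))
    return worst


def test_velocity_verlet_harmonic_second_order():
    # drift is O(dt^2): halving the step reduces it by ~4x
    d1 = _harmonic_drift(dt=20.0, t_total=40000.0)
    d2 = _harmonic_drift(dt=10.0, t_total=40000.0)
    assert d1 > 0
    assert d1 / d2 == pytest.approx(4.0, rel=0.15)


def test_velocity_verlet_rejects_non_finite():
    coords = np.zeros((1, 3))
    masses = np.array([100.0])
    with pytest.raises(PropagationError):
        velocity_verlet_step(coords, np.full((1, 3), np.nan),
                             np.zeros((1, 3)), masses, 1.0,
                             lambda x: np.zeros((1, 3)))


# ----------------------------------------------------------------------
# hop mechanics


def test_hop_energy_conserved_exactly():
    rng = np.random.Generator(np.random.Philox(21))
    masses = np.array([12.0, 16.0]) * 1822.888486209
    vel = rng.normal(0, 3e-4, (2, 3))
    energies = np.array([-0.2, -0.15, -0.17])
    active = 1
    g = np.array([0.0, 0.0, 1.0])
    new_active, new_vel, hopped, frustrated, target = attempt_hop(
        g, 0.5, vel, masses, energies[active], energies, active)
    assert hopped and not frustrated and new_active == 2
    e_before = kinetic_energy(vel, masses) + energies[active]
    e_after = kinetic_energy(new_vel, masses) + energies[new_active]
    assert abs(e_after - e_before) < 1e-12


def test_frustrated_hop_leaves_state_unchanged():
    masses = np.array([12.0 * 1822.888486209])
    vel = np.array([[1e-5, 0.0, 0.0]])  # tiny kinetic energy
    energies = np.array([-0.2, 0.5])
    g = np.array([0.0, 1.0])
    new_active, new_vel, hopped, frustrated, target = attempt_hop(
        g, 0.1, vel, masses, energies[0], energies, active=0)
    assert frustrated and not hopped
    assert new_active == 0 and target == 1
    assert np.array_equal(new_vel, vel)


def test_no_hop_when_draw_above_cumulative():
    masses = np.array([12.0 * 1822.888486209])
    vel = np.array([[1e-3, 0.0, 0.0]])
    energies = np.array([-0.2, -0.25])
    g = np.array([0.0, 0.3])
    new_active, new_vel, hopped, frustrated, _ = attempt_hop(
        g, 0.9, vel, masses, energies[0], energies, active=0)
    assert not hopped and not frustrated and new_active == 0
    assert np.array_equal(new_vel, vel)


# ----------------------------------------------------------------------
# trajectory / ensemble behaviour on the ladder model


class _ZeroSOC:
    """Provider wrapper that zeroes all spin-orbit couplings."""

    def __init__(self, inner):
        self._inner = inner
        self.state_list = inner.state_list

    def evaluate(self, geom):
        sp = self._inner.evaluate(geom)
        return SurfacePoint(sp.energies, sp.gradients,
                            {k: 0.0 for k in sp.soc_norms})


SINGLETS = {"S0", "S1"}
TRIPLETS = {"T1", "T2"}


def test_zero_soc_never_crosses_manifolds(ladder, ladder_modes):
    ics = sample_wigner(ladder_modes, 8, seed=77)
    ens = run_ensemble(_ZeroSOC(ladder), ics,
                       TrajectoryConfig(max_time_fs=250.0), base_seed=123)
    for t in ens.trajectories:
        assert all(h.kind != "ISC" for h in t.hop_events)
        labels = {t.state_labels[i] for i in t.active}
        assert labels <= SINGLETS
        for h in t.hop_events:
            assert {h.from_state, h.to_state} <= SINGLETS


def test_zero_gate_never_internal_converts(ladder, ladder_modes):
    ics = sample_wigner(ladder_modes, 8, seed=78)
    ens = run_ensemble(ladder, ics,
                       TrajectoryConfig(max_time_fs=250.0, gap_gate_ev=0.0),
                       base_seed=124)
    hops = [h for t in ens.trajectories for h in t.hop_events]
    assert all(h.kind != "IC" for h in hops)
    # ISC is still possible through the SOC channel
    for t in ens.trajectories:
        for a, b in zip(t.active[:-1], t.active[1:]):
            if a != b:
                la, lb = t.state_labels[a], t.state_labels[b]
                assert (la in SINGLETS) != (lb in SINGLETS)


def test_hops_disabled_keeps_active_state(ladder, ladder_modes):
    ics = sample_wigner(ladder_modes, 3, seed=79)
    ens = run_ensemble(ladder, ics,
                       TrajectoryConfig(max_time_fs=150.0,
                                        hops_enabled=False),
                       base_seed=125)
    for t in ens.trajectories:
        assert t.hop_events == []
        assert np.all(t.active == t.active[0])


def test_norm_conserved_along_real_trajectory(small_oracle_ensemble):
    for t in small_oracle_ensemble.trajectories:
        norms = np.linalg.norm(t.amplitudes, axis=1)
        assert np.max(np.abs(np.diff(norms))) < 1e-8
        assert np.max(np.abs(norms - 1.0)) < 1e-7


def test_hop_energy_conserved_along_real_trajectory(small_oracle_ensemble):
    # across every accepted hop, total energy changes only by the
    # velocity-Verlet step error, never by a state-energy jump
    found = False
    for t in small_oracle_ensemble.trajectories:
        for h in t.hop_events:
            if h.frustrated:
                continue
            found = True
            i = int(np.searchsorted(t.times_fs, h.time_fs))
            de = abs(t.total_energy[i] - t.total_energy[i - 1])
            assert de < 5e-4  # hartree; pure integrator error at dt=0.5 fs
    assert found


def test_ensemble_deterministic_and_order_independent(ladder, ladder_modes):
    ics = sample_wigner(ladder_modes, 5, seed=80)
    cfg = TrajectoryConfig(max_time_fs=100.0)
    a = run_ensemble(ladder, ics, cfg, base_seed=99)
    b = run_ensemble(ladder, ics, cfg, base_seed=99)
    c = run_ensemble(ladder, ics[:3], cfg, base_seed=99)
    for x, y in zip(a.trajectories, b.trajectories):
        assert np.array_equal(x.coords, y.coords)
        assert np.array_equal(x.amplitudes, y.amplitudes)
        assert x.active.tolist() == y.active.tolist()
    # per-trajectory substreams: a shorter run reproduces the same prefix
    for x, y in zip(a.trajectories[:3], c.trajectories):
        assert np.array_equal(x.coords, y.coords)
        assert x.seed == y.seed


def test_ensemble_seed_changes_results(ladder, ladder_modes):
    ics = sample_wigner(ladder_modes, 4, seed=81)
    cfg = TrajectoryConfig(max_time_fs=150.0)
    a = run_ensemble(ladder, ics, cfg, base_seed=1)
    b = run_ensemble(ladder, ics, cfg, base_seed=2)
    assert any(x.seed != y.seed
               for x, y in zip(a.trajectories, b.trajectories))


def test_empty_initial_conditions_rejected(ladder):
    with pytest.raises(ValueError, match="at least one"):
        run_ensemble(ladder, [], TrajectoryConfig(), base_seed=0)


def test_trajectory_config_validation():
    with pytest.raises(ValueError):
        TrajectoryConfig(nuclear_dt_fs=0.0)
    with pytest.raises(ValueError):
        TrajectoryConfig(electronic_substeps=0)
    with pytest.raises(ValueError):
        TrajectoryConfig(gap_gate_ev=-0.1)
    with pytest.raises(ValueError):
        TrajectoryConfig(drift_action="explode")


def test_drift_abort(ladder, ladder_modes):
    ics = sample_wigner(ladder_modes, 1, seed=82)
    cfg = TrajectoryConfig(max_time_fs=200.0, nuclear_dt_fs=8.0,
                           drift_bound_ev=1e-6, drift_action="abort")
    t = run_trajectory(ladder, ics[0], cfg)
    assert t.termination == "drift-abort"
    assert t.drift_flagged


def test_provider_error_recorded(ladder_modes):
    class Broken:
        state_list = (("S0", 1), ("S1", 1))

        def evaluate(self, geom):
            raise RuntimeError("backend down")

    ics = sample_wigner(ladder_modes, 2, seed=83)
    from photohop.errors import EnsembleError
    with pytest.raises(EnsembleError):
        run_ensemble(Broken(), ics, TrajectoryConfig(max_time_fs=10.0),
                     base_seed=5)


def test_time_grid_and_history_shapes(small_oracle_ensemble):
    for t in small_oracle_ensemble.trajectories:
        assert t.times_fs[0] == 0.0
        assert np.allclose(np.diff(t.times_fs), 0.5)
        T = len(t.times_fs)
        assert t.coords.shape == (T, 4, 3)
        assert t.velocities.shape == (T, 4, 3)
        assert t.amplitudes.shape == (T, 4)
        assert t.total_energy.shape == (T,)
        assert t.active.shape == (T,)
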