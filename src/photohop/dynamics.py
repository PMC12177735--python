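"""Generalized fewest-switches surface hopping with intersystem crossing.

Nuclei follow the active spin-diabatic surface with velocity Verlet;
electronic amplitudes are propagated on a finer substep grid through the
effective Hermitian generator

    K = diag(E)/hbar + H_SOC/hbar - i sigma,

where H_SOC carries the (real, symmetric) spin-orbit couplings between the
designated singlet-triplet pairs and sigma is the antisymmetric
time-derivative-coupling matrix within each spin manifold.  sigma is
estimated from the curvature of the adiabatic energy gap (the
curvature-driven / Baeck-An approximation), activated only when the gap is
below a configurable gate (0.5 eV by default), so no nonadiabatic coupling
vectors are required.  Hop probabilities follow Tully's fewest-switches
prescription with the population flux split into an internal-conversion
(TDC) and an intersystem-crossing (SOC) channel; on a hop, velocities are
rescaled uniformly so total energy is conserved exactly, and energetically
forbidden upward hops are frustrated (state and velocities unchanged).

No decoherence correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .constants import (
    EV_TO_HARTREE,
    FS_TO_AU_TIME,
    HARTREE_TO_EV,
    WAVENUMBER_TO_HARTREE,
)
from .errors import (
    DegenerateStateError,
    EnsembleError,
    PropagationError,
)
from .geometry import Geometry, SurfacePoint, kinetic_energy
from .initial_conditions import InitialCondition

__all__ = [
    "TrajectoryConfig",
    "SpinDiabaticHamiltonian",
    "HopEvent",
    "Trajectory",
    "Ensemble",
    "velocity_verlet_step",
    "compute_ktdc",
    "propagate_electronic",
    "hop_probability",
    "attempt_hop",
    "run_trajectory",
    "run_ensemble",
]


@dataclass(frozen=True)
class TrajectoryConfig:
    """Propagation protocol. Times in fs, gate in eV, SOC bias in cm^-1."""

    max_time_fs: float = 400.0
    nuclear_dt_fs: float = 0.5
    electronic_substeps: int = 20
    gap_gate_ev: float = 0.5
    hops_enabled: bool = True
    soc_bias_cm: float = 0.0
    initial_state: str = "S1"
    drift_bound_ev: float = 0.5
    drift_action: str = "flag"  # "flag" keeps propagating; "abort" stops
    check_uncertainty: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.nuclear_dt_fs <= 0:
            raise ValueError("nuclear_dt must be positive")
        if self.electronic_substeps < 1:
            raise ValueError("electronic_substeps must be >= 1")
        if self.gap_gate_ev < 0:
            raise ValueError("gap_gate must be nonnegative")
        if self.drift_action not in ("flag", "abort"):
            raise ValueError("drift_action must be 'flag' or 'abort'")


@dataclass(frozen=True)
class SpinDiabaticHamiltonian:
    """Electronic Hamiltonian pieces at one instant (atomic units).

    energies: state energies, hartree; soc: symmetric SOC matrix, hartree,
    nonzero only on designated singlet-triplet pairs; tdc: antisymmetric
    time-derivative couplings, 1/a.u. time, nonzero only within a manifold.
    """

    energies: np.ndarray
    soc: np.ndarray
    tdc: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, float)
        s = np.asarray(self.soc, float)
        t = np.asarray(self.tdc, float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "soc", s)
        object.__setattr__(self, "tdc", t)
        if np.max(np.abs(s - s.T)) > 1e-12:
            raise PropagationError("SOC matrix must be symmetric")
        if np.max(np.abs(t + t.T)) > 1e-12:
            raise PropagationError("TDC matrix must be antisymmetric")

    def generator(self) -> np.ndarray:
        """Hermitian K such that dc/dt = -i K c."""
        return np.diag(self.energies).astype(complex) + self.soc - 1j * self.tdc


@dataclass(frozen=True)
class HopEvent:
    time_fs: float
    from_state: str
    to_state: str
    coords: np.ndarray  # bohr
    kind: str  # "IC" | "ISC"
    frustrated: bool = False


@dataclass
class Trajectory:
    state_labels: tuple[str, ...]
    times_fs: np.ndarray
    coords: np.ndarray          # (T, n, 3) bohr
    velocities: np.ndarray      # (T, n, 3) a.u.
    active: np.ndarray          # (T,) state indices
    total_energy: np.ndarray    # (T,) hartree
    amplitudes: np.ndarray      # (T, S) complex
    hop_events: list[HopEvent]
    termination: str            # reached-max-time | uncertainty-stop |
                                # drift-abort | provider-error
    drift_flagged: bool
    seed: int
    diagnostic: str = ""

    @property
    def final_active_label(self) -> str:
        return self.state_labels[int(self.active[-1])]

    @property
    def n_steps(self) -> int:
        return len(self.times_fs) - 1

    def drift_ev(self) -> np.ndarray:
        return np.abs(self.total_energy - self.total_energy[0]) * HARTREE_TO_EV


@dataclass
class Ensemble:
    trajectories: list[Trajectory]
    base_seed: int

    def __len__(self):
        return len(self.trajectories)

    def summary(self) -> dict:
        terms: dict[str, int] = {}
        for t in self.trajectories:
            terms[t.termination] = terms.get(t.termination, 0) + 1
        end_drift = [t.drift_ev()[-1] for t in self.trajectories]
        pre_hop = []
        for t in self.trajectories:
            real_hops = [h for h in t.hop_events if not h.frustrated]
            if real_hops:
                i = int(np.searchsorted(t.times_fs, real_hops[0].time_fs) - 1)
                i = max(i, 0)
            else:
                i = len(t.times_fs) - 1
            pre_hop.append(np.max(t.drift_ev()[: i + 1]) if i >= 0 else 0.0)
        return {
            "n_trajectories": len(self.trajectories),
            "terminations": terms,
            "mean_abs_drift_end_ev": float(np.mean(end_drift)),
            "mean_abs_drift_before_first_hop_ev": float(np.mean(pre_hop)),
        }


# ----------------------------------------------------------------------
# elementary operations


def velocity_verlet_step(
    coords: np.ndarray,
    vel: np.ndarray,
    grad: np.ndarray,
    masses_au: np.ndarray,
    dt: float,
    grad_fn: Callable[[np.ndarray], np.ndarray],
):
    """One velocity-Verlet step on the active-state gradient (a.u.).

    Returns (coords', vel', grad') with grad' evaluated at coords'.
    """
    if not (np.all(np.isfinite(grad)) and np.all(np.isfinite(vel))):
        raise PropagationError("non-finite force or velocity")
    minv = 1.0 / masses_au[:, None]
    vel_half = vel - 0.5 * dt * grad * minv
    new_coords = coords + dt * vel_half
    new_grad = grad_fn(new_coords)
    if not np.all(np.isfinite(new_grad)):
        raise PropagationError("non-finite force after step")
    new_vel = vel_half - 0.5 * dt * new_grad * minv
    return new_coords, new_vel, new_grad


def compute_ktdc(
    gap_history: Sequence[float],
    dt: float,
    gap_gate: float,
) -> float:
    """Curvature-driven TDC magnitude from the last three gap values (a.u.).

    sigma = 1/2 sqrt(gap''/gap) when the curvature-to-gap ratio is
    positive, zero otherwise; forced to zero when the current gap is at or
    above the gate, and during the two-step warm-up.
    """
    if len(gap_history) < 3:
        return 0.0
    g0, g1, g2 = gap_history[-3], gap_history[-2], gap_history[-1]
    if g2 <= 0.0 or g2 >= gap_gate:
        return 0.0
    curvature = (g2 - 2.0 * g1 + g0) / dt**2
    ratio = curvature / g2
    if ratio <= 0.0:
        return 0.0
    return 0.5 * np.sqrt(ratio)


def propagate_electronic(
    wf: np.ndarray,
    H_start: SpinDiabaticHamiltonian,
    H_end: SpinDiabaticHamiltonian,
    nuclear_dt: float,
    substeps: int,
    active: int | None = None,
):
    """Advance amplitudes across one nuclear step (a.u.).

    The generator is linearly interpolated entry-wise across the step and
    applied per substep by a fourth-order commutator-free Magnus scheme
    (two exact exponentials built from the two Gauss-Legendre nodes of the
    substep; Blanes-Moan CF4).  Each factor is a unitary exponential of a
    Hermitian matrix, so the norm is conserved to machine precision, and
    for a time-independent generator the scheme is exact.  When
    `active` is given, the population flux out of that state is
    accumulated separately for the SOC channel and the TDC channel;
    returns (wf', flux_soc, flux_tdc), otherwise just wf'.
    """
    c = np.asarray(wf, complex).copy()
    n = c.shape[0]
    K0 = H_start.generator()
    K1 = H_end.generator()
    herm_err = max(np.max(np.abs(K0 - K0.conj().T)), np.max(np.abs(K1 - K1.conj().T)))
    if herm_err > 1e-10:
        raise PropagationError(f"non-Hermitian effective Hamiltonian ({herm_err:.2e})")
    dt_sub = nuclear_dt / substeps
    fracs = (np.arange(substeps) + 0.5) / substeps
    dK = (K1 - K0)[None, :, :]
    # Gauss-Legendre nodes of each substep and the CF4 exponents
    node = np.sqrt(3.0) / 6.0 / substeps
    Ka = K0[None, :, :] + (fracs - node)[:, None, None] * dK
    Kb = K0[None, :, :] + (fracs + node)[:, None, None] * dK
    wa = (3.0 + 2.0 * np.sqrt(3.0)) / 12.0
    wb = (3.0 - 2.0 * np.sqrt(3.0)) / 12.0
    A = dt_sub * (wa * Ka + wb * Kb)  # early-weighted exponent, applied first
    B = dt_sub * (wb * Ka + wa * Kb)
    w1, U1 = np.linalg.eigh(A)
    w2, U2 = np.linalg.eigh(B)
    ph1 = np.exp(-1j * w1)
    ph2 = np.exp(-1j * w2)

    def substep(s, c):
        c = U1[s] @ (ph1[s] * (U1[s].conj().T @ c))
        return U2[s] @ (ph2[s] * (U2[s].conj().T @ c))

    if active is None:
        for s in range(substeps):
            c = substep(s, c)
        return c

    cs = np.empty((substeps + 1, n), complex)
    cs[0] = c
    for s in range(substeps):
        c = substep(s, c)
        cs[s + 1] = c
    # trapezoid accumulation of the per-channel flux out of `active`
    soc_rows = H_start.soc[active][None, :] + fracs[:, None] * (
        H_end.soc[active] - H_start.soc[active]
    )[None, :]
    tdc_rows = H_start.tdc[active][None, :] + fracs[:, None] * (
        H_end.tdc[active] - H_start.tdc[active]
    )[None, :]
    rho_pre = cs[:-1] * np.conj(cs[:-1, active])[:, None]
    rho_post = cs[1:] * np.conj(cs[1:, active])[:, None]
    rho_mid = 0.5 * (rho_pre + rho_post)
    flux_soc = (-2.0 * np.imag(soc_rows * rho_mid)).sum(axis=0) * dt_sub
    flux_tdc = (2.0 * np.real(tdc_rows * rho_mid)).sum(axis=0) * dt_sub
    flux_soc[active] = 0.0
    flux_tdc[active] = 0.0
    return c, flux_soc, flux_tdc


def _flux(c, soc, tdc, a):
    """Instantaneous population flux out of state a, per channel."""
    rho_ka = c * np.conj(c[a])
    f_soc = -2.0 * np.imag(soc[a] * rho_ka)
    f_tdc = 2.0 * np.real(tdc[a] * rho_ka)
    f_soc[a] = 0.0
    f_tdc[a] = 0.0
    return f_soc, f_tdc


def hop_probability(
    flux_soc: np.ndarray,
    flux_tdc: np.ndarray,
    rho_active: float,
):
    """Fewest-switches hop probabilities from accumulated channel fluxes.

    g_k = max(0, F_k) / rho_active, clamped so the total is <= 1; each
    state is tagged by its dominant flux channel ("IC" or "ISC").
    """
    if rho_active <= 1e-12:
        raise DegenerateStateError("active-state population vanished")
    total = flux_soc + flux_tdc
    g = np.maximum(total, 0.0) / rho_active
    s = g.sum()
    if s > 1.0:
        g = g / s
    kinds = [
        "ISC" if abs(fs) >= abs(ft) else "IC"
        for fs, ft in zip(flux_soc, flux_tdc)
    ]
    return g, kinds


def attempt_hop(
    g: np.ndarray,
    draw: float,
    vel: np.ndarray,
    masses_au: np.ndarray,
    e_active: float,
    energies: np.ndarray,
    active: int,
):
    """Cumulative-probability target selection and exact-energy rescaling.

    Returns (new_active, new_vel, hopped, frustrated, target).  On a hop,
    velocities are scaled uniformly so E_kin + E_state is unchanged; an
    upward hop with insufficient kinetic energy is frustrated (state and
    velocities untouched).
    """
    cum = np.cumsum(g)
    target = None
    for k in range(len(g)):
        if k == active or g[k] <= 0.0:
            continue
        if draw < cum[k]:
            target = k
            break
    if target is None:
        return active, vel, False, False, None
    ke = kinetic_energy(vel, masses_au)
    ke_new = ke + (e_active - energies[target])
    if ke_new <= 0.0 or ke <= 0.0:
        return active, vel, False, True, target
    factor = np.sqrt(ke_new / ke)
    return target, vel * factor, True, False, target


# ----------------------------------------------------------------------
# trajectory and ensemble drivers


def _manifold_pairs(state_list):
    by_mult: dict[int, list[int]] = {}
    for i, (_, mult) in enumerate(state_list):
        by_mult.setdefault(mult, []).append(i)
    pairs = []
    for idxs in by_mult.values():
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                pairs.append((idxs[a], idxs[b]))
    return pairs


def _soc_matrix(sp: SurfacePoint, state_index: dict[str, int], n: int,
                bias_cm: float) -> np.ndarray:
    soc = np.zeros((n, n))
    for (la, lb), val in sp.soc_norms.items():
        v = max(0.0, val + bias_cm) * WAVENUMBER_TO_HARTREE
        i, j = state_index[la], state_index[lb]
        soc[i, j] = soc[j, i] = v
    return soc


def run_trajectory(
    provider,
    ic: InitialCondition,
    config: TrajectoryConfig,
) -> Trajectory:
    """Propagate a single surface-hopping trajectory.

    `provider` supplies state energies/gradients/SOC norms (analytic model
    or trained committee); a committee provider is also monitored for
    uncertainty breaches, which early-stop the trajectory at the breaching
    geometry.
    """
    state_list = provider.state_list
    labels = [lbl for lbl, _ in state_list]
    state_index = {lbl: i for i, lbl in enumerate(labels)}
    n_states = len(labels)
    mpairs = _manifold_pairs(state_list)
    dt = config.nuclear_dt_fs * FS_TO_AU_TIME
    gate = config.gap_gate_ev * EV_TO_HARTREE
    n_steps = int(round(config.max_time_fs / config.nuclear_dt_fs))
    rng = np.random.Generator(
        np.random.Philox(np.random.SeedSequence(entropy=int(config.seed)))
    )

    has_uncertainty = hasattr(provider, "evaluate_with_uncertainty")

    def evaluate(geom):
        if has_uncertainty:
            sp, unc = provider.evaluate_with_uncertainty(geom)
            breach = (
                provider.uncertainty_breach(unc)
                if config.check_uncertainty
                else None
            )
        else:
            sp, breach = provider.evaluate(geom), None
        return sp, breach

    geom0 = ic.geometry
    masses_au = geom0.masses_au
    active = state_index[config.initial_state]

    times = [0.0]
    coords_hist = [geom0.coords.copy()]
    vel_hist = [np.asarray(ic.velocities, float).copy()]
    active_hist = [active]
    amp_hist = []
    etot_hist = []
    hops: list[HopEvent] = []
    termination = "reached-max-time"
    diagnostic = ""
    drift_flagged = False

    c = np.zeros(n_states, complex)
    c[active] = 1.0
    amp_hist.append(c.copy())

    try:
        sp, breach = evaluate(geom0)
    except Exception as exc:  # provider failure must not kill the ensemble
        return Trajectory(
            state_labels=tuple(labels),
            times_fs=np.array(times),
            coords=np.array(coords_hist),
            velocities=np.array(vel_hist),
            active=np.array(active_hist),
            total_energy=np.array([np.nan]),
            amplitudes=np.array(amp_hist),
            hop_events=[],
            termination="provider-error",
            drift_flagged=False,
            seed=config.seed,
            diagnostic=str(exc),
        )
    e_tot0 = sp.energies[active] + kinetic_energy(vel_hist[0], masses_au)
    etot_hist.append(e_tot0)

    gap_histories = {p: [abs(sp.energies[p[1]] - sp.energies[p[0]])] for p in mpairs}

    def tdc_matrix():
        m = np.zeros((n_states, n_states))
        for (i, j) in mpairs:
            sigma = compute_ktdc(gap_histories[(i, j)], dt, gate)
            m[i, j] = sigma
            m[j, i] = -sigma
        return m

    H_cur = SpinDiabaticHamiltonian(
        sp.energies, _soc_matrix(sp, state_index, n_states, config.soc_bias_cm),
        tdc_matrix(),
    )

    coords = geom0.coords.copy()
    vel = vel_hist[0].copy()
    grad = sp.gradients[active]
    sp_box: list = [sp, None]  # [current SurfacePoint, pending breach]

    def grad_fn(x):
        s, b = evaluate(geom0.with_coords(x))
        sp_box[0], sp_box[1] = s, b
        return s.gradients[active]

    try:
        for step in range(n_steps):
            t_fs = (step + 1) * config.nuclear_dt_fs
            coords, vel, grad = velocity_verlet_step(
                coords, vel, grad, masses_au, dt, grad_fn
            )
            sp_new, breach = sp_box[0], sp_box[1]

            for p in mpairs:
                gap_histories[p].append(
                    abs(sp_new.energies[p[1]] - sp_new.energies[p[0]])
                )
                if len(gap_histories[p]) > 3:
                    gap_histories[p].pop(0)
            H_new = SpinDiabaticHamiltonian(
                sp_new.energies,
                _soc_matrix(sp_new, state_index, n_states, config.soc_bias_cm),
                tdc_matrix(),
            )

            rho_a = abs(c[active]) ** 2
            c, flux_soc, flux_tdc = propagate_electronic(
                c, H_cur, H_new, dt, config.electronic_substeps, active=active
            )

            draw = rng.random()  # drawn every step: trajectory comparability
            if config.hops_enabled and rho_a > 1e-12:
                g, kinds = hop_probability(flux_soc, flux_tdc, rho_a)
                new_active, vel2, hopped, frustrated, target = attempt_hop(
                    g, draw, vel, masses_au,
                    sp_new.energies[active], sp_new.energies, active,
                )
                if hopped or frustrated:
                    hops.append(
                        HopEvent(
                            time_fs=t_fs,
                            from_state=labels[active],
                            to_state=labels[target],
                            coords=coords.copy(),
                            kind=kinds[target],
                            frustrated=frustrated,
                        )
                    )
                if hopped:
                    active = new_active
                    vel = vel2
                    grad = sp_new.gradients[active]

            e_tot = sp_new.energies[active] + kinetic_energy(vel, masses_au)
            drift_ev = abs(e_tot - e_tot0) * HARTREE_TO_EV

            times.append(t_fs)
            coords_hist.append(coords.copy())
            vel_hist.append(vel.copy())
            active_hist.append(active)
            amp_hist.append(c.copy())
            etot_hist.append(e_tot)
            H_cur = H_new

            if breach is not None:
                termination = "uncertainty-stop"
                diagnostic = f"uncertainty breach: {breach}"
                break
            if drift_ev > config.drift_bound_ev:
                drift_flagged = True
                if config.drift_action == "abort":
                    termination = "drift-abort"
                    break
    except Exception as exc:
        termination = "provider-error"
        diagnostic = str(exc)

    return Trajectory(
        state_labels=tuple(labels),
        times_fs=np.array(times),
        coords=np.array(coords_hist),
        velocities=np.array(vel_hist),
        active=np.array(active_hist),
        total_energy=np.array(etot_hist),
        amplitudes=np.array(amp_hist),
        hop_events=hops,
        termination=termination,
        drift_flagged=drift_flagged,
        seed=config.seed,
        diagnostic=diagnostic,
    )


def run_ensemble(
    provider,
    ics: Sequence[InitialCondition],
    config: TrajectoryConfig,
    base_seed: int,
) -> Ensemble:
    """Run independent trajectories with per-trajectory seed substreams.

    Trajectory i uses the Philox substream (base_seed, i), so results are
    identical regardless of execution order or worker count.
    """
    if len(ics) == 0:
        raise ValueError("at least one initial condition is required")
    trajectories = []
    for i, ic in enumerate(ics):
        seed_i = int(
            np.random.SeedSequence(entropy=int(base_seed), spawn_key=(i,))
            .generate_state(1)[0] % (2**31)
        )
        traj = run_trajectory(provider, ic, replace(config, seed=seed_i))
        trajectories.append(traj)
    if all(t.termination == "provider-error" for t in trajectories):
        raise EnsembleError(
            "all trajectories failed: "
            + "; ".join(t.diagnostic for t in trajectories[:3])
        )
    return Ensemble(trajectories=trajectories, base_seed=int(base_seed))
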