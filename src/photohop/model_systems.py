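"""Analytic multi-state model surfaces (the electronic-structure oracle).

These models play the role a multiconfigurational ab initio method plays in
a real study: given a geometry they return state energies, Cartesian
gradients, and spin-orbit-coupling (SOC) norms.  All potentials are
functions of interatomic distances only (Morse/Gaussian bond terms plus
Gaussian diabatic couplings), so energies and SOC norms are invariant under
rigid rotation and translation, and gradients follow by the chain rule
through the distance Jacobian.

Two families are provided:

* 1D validation models (single avoided crossing, dual crossing,
  singlet-triplet crossing with constant SOC, two-state harmonic wells),
  represented as two-atom systems whose model coordinate is the
  interatomic distance.  Equal atomic masses of 4000 a.u. give the
  customary scattering-model reduced mass of 2000 a.u.

* A 4-atom, 4-state (S0, S1, T1, T2) "mini-ladderdiene" with two breakable
  bonds R1 (carbonyl-side), R2, and a carbonyl-like bond R3 that controls
  the SOC norms.  Its Franck-Condon vertical gaps are calibrated to
  3.60 eV (S1), 3.40 eV (T1) and 3.55 eV (T2), the ring-opened product
  basin lies below the reactant on S0 (exothermic stepwise opening), and
  SOC norms grow monotonically with R3 over 1.0-2.0 angstrom.

The spin-diabatic convention is used throughout: each spin manifold's
diabatic block is diagonalized separately (states adiabatic within a
multiplicity, ordered by energy), while SOC norms remain inter-manifold
quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize

from .constants import (
    AMU_TO_AU,
    ANGSTROM_TO_BOHR,
    BOHR_TO_ANGSTROM,
    EV_TO_HARTREE,
    HARTREE_TO_WAVENUMBER,
)
from .errors import ConfigurationError, ShapeError, StationarityError
from .geometry import Geometry, SurfacePoint
from .initial_conditions import NormalModeSet

__all__ = [
    "ModelSpec",
    "build_model",
    "eval_model_1d",
    "eval_ladder_model",
    "normal_modes",
    "LadderModel",
]


@dataclass(frozen=True)
class ModelSpec:
    """Registry handle for an analytic model.

    parameters override the model's documented defaults; state_list is
    informational (each model fixes its own states).
    """

    model_id: str
    parameters: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# scalar distance terms; each returns (value, d value / d R)

def _gauss_well(R, depth, center, width):
    g = np.exp(-((R - center) ** 2) / (2.0 * width**2))
    v = -depth * g
    return v, -v * (R - center) / width**2


def _harm(R, k, center):
    return 0.5 * k * (R - center) ** 2, k * (R - center)


def _quartic(R, k, center):
    return k * (R - center) ** 4, 4.0 * k * (R - center) ** 3


def _rep(R, amp, rho):
    v = amp * np.exp(-R / rho)
    return v, -v / rho


def _sigmoid(R, amp, center, width):
    s = 1.0 / (1.0 + np.exp(-(R - center) / width))
    return amp * s, amp * s * (1.0 - s) / width


# ----------------------------------------------------------------------
# generic machinery


def _eigh_small(V: np.ndarray):
    """eigh with a closed form for the 1x1 and 2x2 blocks (hot path)."""
    n = V.shape[0]
    if n == 1:
        return V[0].copy(), np.array([[1.0]])
    if n == 2:
        a, b, c = V[0, 0], V[1, 1], V[0, 1]
        half = 0.5 * (a + b)
        rad = np.hypot(0.5 * (a - b), c)
        w = np.array([half - rad, half + rad])
        # eigenvector of the lower state
        theta = 0.5 * np.arctan2(2.0 * c, a - b)
        cs, sn = np.cos(theta), np.sin(theta)
        U = np.array([[cs, -sn], [sn, cs]])
        # swap columns if needed so column 0 carries the lower eigenvalue
        e0 = U[:, 0] @ V @ U[:, 0]
        if abs(e0 - w[0]) > abs(e0 - w[1]):
            U = U[:, ::-1].copy()
        return w, U
    return np.linalg.eigh(V)


class AnalyticModel:
    """Base: distance-based diabatic blocks, per-manifold adiabatization."""

    # subclasses define:
    atom_labels: tuple[str, ...]
    masses_amu: np.ndarray
    state_list: tuple[tuple[str, int], ...]  # (label, multiplicity)
    soc_pairs: tuple[tuple[str, str], ...]
    pairs: tuple[tuple[int, int], ...]  # atom index pairs entering the model

    def diabatic(self, dists: np.ndarray):
        """Return ({manifold: (V, dV)}, {soc_pair: value_cm}).

        V is (n, n) hartree; dV is (n_pairs, n, n) hartree/bohr.
        Manifold keys follow multiplicity grouping of state_list.
        """
        raise NotImplementedError

    # -- shared helpers ------------------------------------------------

    @property
    def state_labels(self) -> tuple[str, ...]:
        return tuple(lbl for lbl, _ in self.state_list)

    def manifold_indices(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for i, (_, mult) in enumerate(self.state_list):
            out.setdefault(mult, []).append(i)
        return out

    def reference_geometry(self) -> Geometry:
        raise NotImplementedError

    def evaluate(self, geom: Geometry) -> SurfacePoint:
        if geom.n_atoms != len(self.atom_labels):
            raise ShapeError(
                f"model expects {len(self.atom_labels)} atoms, got {geom.n_atoms}"
            )
        coords = geom.coords
        npairs = len(self.pairs)
        dists = np.empty(npairs)
        # d r_p / d x: (n_pairs, n_atoms, 3)
        ddist = np.zeros((npairs, geom.n_atoms, 3))
        for p, (i, j) in enumerate(self.pairs):
            rij = coords[i] - coords[j]
            r = np.linalg.norm(rij)
            dists[p] = r
            u = rij / r
            ddist[p, i] = u
            ddist[p, j] = -u

        blocks, soc = self.diabatic(dists)

        n_states = len(self.state_list)
        energies = np.empty(n_states)
        gradients = np.empty((n_states, geom.n_atoms, 3))
        ddist_flat = ddist.reshape(npairs, -1)
        for mult, idxs in self.manifold_indices().items():
            V, dV = blocks[mult]
            w, U = _eigh_small(V)
            # ascending eigenvalues map onto the listed state order
            for local, state_idx in enumerate(idxs):
                energies[state_idx] = w[local]
                vec = U[:, local]
                # Hellmann-Feynman per distance coordinate
                dE_dr = np.einsum("i,pij,j->p", vec, dV, vec)
                gradients[state_idx] = (dE_dr @ ddist_flat).reshape(
                    geom.n_atoms, 3
                )
        return SurfacePoint(
            energies=energies,
            gradients=gradients,
            soc_norms={pair: max(0.0, float(soc.get(pair, 0.0))) for pair in self.soc_pairs},
        )

    def make_geometry(self, coords_bohr: np.ndarray) -> Geometry:
        return Geometry(self.atom_labels, coords_bohr, self.masses_amu)


# ----------------------------------------------------------------------
# 1D two-atom models


class _OneDModel(AnalyticModel):
    """Two atoms; the model coordinate is their separation (bohr)."""

    def __init__(self, params: dict, defaults: dict):
        unknown = set(params) - set(defaults)
        if unknown:
            raise ConfigurationError(f"unknown parameters: {sorted(unknown)}")
        self.p = {**defaults, **params}
        self.atom_labels = ("X", "X")
        m = self.p["mass_au"] / AMU_TO_AU
        self.masses_amu = np.array([m, m])
        self.pairs = ((0, 1),)

    def geometry_at(self, x: float) -> Geometry:
        coords = np.array([[0.0, 0.0, 0.0], [float(x), 0.0, 0.0]])
        return self.make_geometry(coords)

    def reference_geometry(self) -> Geometry:
        return self.geometry_at(self.p.get("x0", 4.0))


class AvoidedCrossing1D(_OneDModel):
    """Symmetric avoided crossing: diabats +/- a tanh(b u), Gaussian coupling."""

    DEFAULTS = dict(a=0.01, b=1.6, c=0.005, d=1.0, x0=4.0, mass_au=4000.0)
    state_list = (("S0", 1), ("S1", 1))
    soc_pairs = ()

    def __init__(self, params):
        super().__init__(params, self.DEFAULTS)

    def diabatic(self, dists):
        p, u = self.p, dists[0] - self.p["x0"]
        t = np.tanh(p["b"] * u)
        v11, d11 = p["a"] * t, p["a"] * p["b"] * (1 - t**2)
        g = np.exp(-p["d"] * u**2)
        v12, d12 = p["c"] * g, -2.0 * p["c"] * p["d"] * u * g
        V = np.array([[v11, v12], [v12, -v11]])
        dV = np.array([[[d11, d12], [d12, -d11]]])
        return {1: (V, dV)}, {}


class DualCrossing1D(_OneDModel):
    """Two diabats crossing twice (Gaussian-well upper state)."""

    DEFAULTS = dict(a=0.10, b=0.28, e0=0.05, c=0.015, d=0.06, x0=4.0, mass_au=4000.0)
    state_list = (("S0", 1), ("S1", 1))
    soc_pairs = ()

    def __init__(self, params):
        super().__init__(params, self.DEFAULTS)

    def diabatic(self, dists):
        p, u = self.p, dists[0] - self.p["x0"]
        g1 = np.exp(-p["b"] * u**2)
        v22, d22 = -p["a"] * g1 + p["e0"], 2.0 * p["a"] * p["b"] * u * g1
        g2 = np.exp(-p["d"] * u**2)
        v12, d12 = p["c"] * g2, -2.0 * p["c"] * p["d"] * u * g2
        V = np.array([[0.0, v12], [v12, v22]])
        dV = np.array([[[0.0, d12], [d12, d22]]])
        return {1: (V, dV)}, {}


class SingletTriplet1D(_OneDModel):
    """Crossing harmonic singlet/triplet diabats with a constant SOC norm."""

    DEFAULTS = dict(kS=0.02, kT=0.02, xS=4.0, xT=4.6, dT=0.005, soc_cm=50.0,
                    x0=4.0, mass_au=4000.0)
    state_list = (("S0", 1), ("T1", 3))
    soc_pairs = (("S0", "T1"),)

    def __init__(self, params):
        super().__init__(params, self.DEFAULTS)

    def diabatic(self, dists):
        p, r = self.p, dists[0]
        vs, ds = _harm(r, p["kS"], p["xS"])
        vt, dt = _harm(r, p["kT"], p["xT"])
        vt, dt = vt + p["dT"], dt
        return (
            {1: (np.array([[vs]]), np.array([[[ds]]])),
             3: (np.array([[vt]]), np.array([[[dt]]]))},
            {("S0", "T1"): p["soc_cm"]},
        )


class Harmonic2State1D(_OneDModel):
    """Two displaced harmonic singlet wells; closed-form training fixture."""

    DEFAULTS = dict(k=0.02, x0=4.0, delta=0.3, gap=0.01, c=0.002, d=1.0,
                    mass_au=4000.0)
    state_list = (("S0", 1), ("S1", 1))
    soc_pairs = ()

    def __init__(self, params):
        super().__init__(params, self.DEFAULTS)

    def diabatic(self, dists):
        p, r = self.p, dists[0]
        v11, d11 = _harm(r, p["k"], p["x0"])
        v22, d22 = _harm(r, p["k"], p["x0"] + p["delta"])
        v22 += p["gap"]
        g = np.exp(-p["d"] * (r - p["x0"] - 0.5 * p["delta"]) ** 2)
        v12 = p["c"] * g
        d12 = -2.0 * p["c"] * p["d"] * (r - p["x0"] - 0.5 * p["delta"]) * g
        V = np.array([[v11, v12], [v12, v22]])
        dV = np.array([[[d11, d12], [d12, d22]]])
        return {1: (V, dV)}, {}


# ----------------------------------------------------------------------
# 4-atom, 4-state toy ladder model


def _default_ladder_params() -> dict:
    """Documented defaults; energies in eV, lengths in angstrom."""
    return dict(
        # per-state bond-opening profiles applied to both R1 and R2:
        # (closed depth, closed width, open depth, open center, open width)
        s0_bond=dict(Dc=3.2, sc=0.28, Do=3.7, Ro=3.10, so=0.50),
        s1_bond=dict(Dc=1.4, sc=0.34, Do=1.9, Ro=3.12, so=0.55),
        t1_bond=dict(Dc=0.9, sc=0.50, Do=2.2, Ro=3.15, so=0.70),
        t2_bond=dict(Dc=1.4, sc=0.32, Do=1.5, Ro=3.12, so=0.55),
        # closed-well depth multiplier for R2 (the unsubstituted-ring bond):
        # > 1 keeps a barrier on R2 so the carbonyl-side bond R1 opens first
        bond_asym=dict(s0=1.0, s1=1.5, t1=1.9, t2=1.3),
        # closed-well centers for the two breakable bonds
        Rc1=1.62, Rc2=1.64,
        # carbonyl-like R3 term per state: (force constant eV/A^2, minimum A)
        r3_s0=(50.0, 1.22), r3_s1=(30.0, 1.38), r3_t1=(35.0, 1.30),
        r3_t2=(45.0, 1.26),
        # scaffold restraints on the remaining three distances
        restraint_k=1.0,
        # quartic confinement of the breakable bonds
        conf_k=0.02, conf_center=2.4,
        # short-range repulsion on R1, R2
        rep_amp=40.0, rep_rho=0.25,
        # diabatic couplings, Gaussian in the diabatic gap:
        # eps * exp(-(dV/lam)^2), both eV
        coupling_singlet=(0.06, 0.5), coupling_triplet=(0.04, 0.5),
        # SOC norms, cm^-1: base + amp * sigmoid((R3 - c)/w)
        soc_center=1.30, soc_width=0.05,
        soc_S1_T1=(15.0, 280.0), soc_S1_T2=(10.0, 120.0),
        soc_S0_T1=(5.0, 80.0), soc_S0_T2=(5.0, 80.0),
        # calibrated Franck-Condon vertical gaps, eV
        gap_s1=3.60, gap_t1=3.40, gap_t2=3.55,
    )


class LadderModel(AnalyticModel):
    """4-state toy with a stepwise, exothermic two-bond ring-opening landscape.

    Atoms: C0-C1-C2=O3.  R1 = r(C0,C1), R2 = r(C1,C2), R3 = r(C2,O3).
    On construction the reactant geometry is relaxed to a proper S0
    stationary point and per-state offsets are calibrated so the vertical
    gaps at the reference match the documented values exactly.
    """

    state_list = (("S0", 1), ("S1", 1), ("T1", 3), ("T2", 3))
    soc_pairs = (("S1", "T2"), ("S1", "T1"), ("S0", "T2"), ("S0", "T1"))
    atom_labels = ("C", "C", "C", "O")
    # distance order: R1, R2, R3, then scaffold distances r02, r03, r13
    pairs = ((0, 1), (1, 2), (2, 3), (0, 2), (0, 3), (1, 3))
    BOND_INDICES = {"R1": (0, 1), "R2": (1, 2), "R3": (2, 3)}

    def __init__(self, params: dict | None = None):
        defaults = _default_ladder_params()
        params = dict(params or {})
        unknown = set(params) - set(defaults)
        if unknown:
            raise ConfigurationError(f"unknown parameters: {sorted(unknown)}")
        self.p = {**defaults, **params}
        self.masses_amu = np.array([12.0, 12.0, 12.0, 15.99491461956])
        self._offsets = np.zeros(4)  # hartree, order S0 S1 T1 T2
        guess = self._guess_coords()
        # restraint centers frozen at the guess scaffold distances
        self._rest_ref = np.array(
            [np.linalg.norm(guess[i] - guess[j]) for (i, j) in self.pairs[3:]]
        )
        self._reference = self._relax_s0(guess)
        self._calibrate_gaps()

    # -- construction helpers -----------------------------------------

    def _guess_coords(self) -> np.ndarray:
        p = self.p
        a = ANGSTROM_TO_BOHR
        c0 = np.array([0.0, 0.0, 0.0])
        c1 = c0 + np.array([p["Rc1"], 0.0, 0.0]) * a
        u = np.array([0.5, 0.82, 0.20])
        c2 = c1 + p["Rc2"] * a * u / np.linalg.norm(u)
        w = np.array([0.30, 0.50, 0.80])
        o3 = c2 + p["r3_s0"][1] * a * w / np.linalg.norm(w)
        return np.stack([c0, c1, c2, o3])

    def _relax_s0(self, guess: np.ndarray) -> Geometry:
        def fg(x):
            sp = self.evaluate(self.make_geometry(x.reshape(-1, 3)))
            return sp.energies[0], sp.gradients[0].ravel()

        res = minimize(fg, guess.ravel(), jac=True, method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 500})
        x = res.x
        # Newton polish on the translation/rotation-deflated Hessian
        for _ in range(8):
            g = fg(x)[1]
            if np.linalg.norm(g) < 1e-11:
                break
            H = _fd_hessian(lambda y: fg(y)[1], x, step=1e-4)
            step = np.linalg.lstsq(H, -g, rcond=1e-8)[0]
            x = x + step
        return self.make_geometry(x.reshape(-1, 3))

    def _calibrate_gaps(self):
        targets = np.array(
            [0.0, self.p["gap_s1"], self.p["gap_t1"], self.p["gap_t2"]]
        ) * EV_TO_HARTREE

        def residual(o):
            self._offsets[1:] = o
            e = self.evaluate(self._reference).energies
            return (e - e[0]) - targets

        from scipy.optimize import least_squares

        e0 = self.evaluate(self._reference).energies
        start = targets[1:] - (e0[1:] - e0[0]) + self._offsets[1:]
        sol = least_squares(lambda o: residual(o)[1:], start, xtol=3e-16,
                            ftol=3e-16, gtol=None)
        self._offsets[1:] = sol.x
        resid = residual(sol.x)[1:]
        if np.max(np.abs(resid)) > 1e-10:
            raise ConfigurationError(
                "Franck-Condon gap calibration failed; residual "
                f"{resid} hartree — check coupling/gap parameters"
            )

    def reference_geometry(self) -> Geometry:
        return self._reference

    def basin_geometry(self, open_r1: bool = False,
                       open_r2: bool = False) -> Geometry:
        """S0-relaxed structure in the requested bond-opening basin(s).

        The reference is displaced into the open basin along the bond
        direction(s) and re-relaxed on S0; with both flags False this is
        just the reference.  Used to assemble interpolated training paths
        reactant -> single-open intermediate -> fully open product.
        """
        if not (open_r1 or open_r2):
            return self._reference
        coords = self._reference.coords.copy()
        ro = self.p["s0_bond"]["Ro"] * ANGSTROM_TO_BOHR
        if open_r1:
            u = coords[0] - coords[1]
            coords[0] = coords[1] + ro * u / np.linalg.norm(u)
        if open_r2:
            u = coords[1] - coords[2]
            d = np.linalg.norm(u)
            shift = (ro - d) * u / d
            coords[0] += shift
            coords[1] += shift

        def fg(x):
            sp = self.evaluate(self.make_geometry(x.reshape(-1, 3)))
            return sp.energies[0], sp.gradients[0].ravel()

        res = minimize(fg, coords.ravel(), jac=True, method="BFGS",
                       options={"gtol": 1e-9, "maxiter": 500})
        return self.make_geometry(res.x.reshape(-1, 3))

    def stretched_geometry(self, bond: str, length_angstrom: float,
                           open_r1: bool = False,
                           open_r2: bool = False) -> Geometry:
        """Basin structure with one bond reset to a prescribed length.

        The terminal atom of `bond` is moved along the bond direction so
        the distance equals `length_angstrom`; no re-relaxation.  Used to
        seed training paths toward localized features away from the
        minima (e.g. the carbonyl-stretched singlet funnel).
        """
        if bond not in self.BOND_INDICES:
            raise ConfigurationError(
                f"unknown bond {bond!r}; expected one of "
                f"{sorted(self.BOND_INDICES)}")
        geom = self.basin_geometry(open_r1=open_r1, open_r2=open_r2)
        i, j = self.BOND_INDICES[bond]
        coords = geom.coords.copy()
        u = coords[j] - coords[i]
        coords[j] = coords[i] + (length_angstrom * ANGSTROM_TO_BOHR) * (
            u / np.linalg.norm(u))
        return geom.with_coords(coords)

    # -- potential -----------------------------------------------------

    def _bond_profile(self, R, prof, Rc, depth_scale=1.0):
        """Double-basin profile in eV/angstrom units: (value, dvalue/dR)."""
        p = self.p
        v1, d1 = _gauss_well(R, depth_scale * prof["Dc"], Rc, prof["sc"])
        v2, d2 = _gauss_well(R, prof["Do"], prof["Ro"], prof["so"])
        v3, d3 = _rep(R, p["rep_amp"], p["rep_rho"])
        v4, d4 = _quartic(R, p["conf_k"], p["conf_center"])
        return v1 + v2 + v3 + v4, d1 + d2 + d3 + d4

    def _diabats_ev(self, dists_A: np.ndarray):
        """Diabatic state energies (eV) + derivatives wrt the 6 distances (A)."""
        p = self.p
        R1, R2, R3 = dists_A[:3]
        n = len(dists_A)
        V = np.zeros(4)
        dV = np.zeros((4, n))
        profs = [p["s0_bond"], p["s1_bond"], p["t1_bond"], p["t2_bond"]]
        r3s = [p["r3_s0"], p["r3_s1"], p["r3_t1"], p["r3_t2"]]
        asym = [p["bond_asym"][s] for s in ("s0", "s1", "t1", "t2")]
        for k in range(4):
            v, d = self._bond_profile(R1, profs[k], p["Rc1"])
            V[k] += v
            dV[k, 0] += d
            v, d = self._bond_profile(R2, profs[k], p["Rc2"],
                                      depth_scale=asym[k])
            V[k] += v
            dV[k, 1] += d
            kco, r0 = r3s[k]
            v, d = _harm(R3, kco, r0)
            V[k] += v
            dV[k, 2] += d
            for m, rref in enumerate(self._rest_ref):
                v, d = _harm(dists_A[3 + m], p["restraint_k"],
                             rref * BOHR_TO_ANGSTROM)
                V[k] += v
                dV[k, 3 + m] += d
        return V, dV

    def diabatic(self, dists):
        dists_A = dists * BOHR_TO_ANGSTROM
        V_ev, dV_ev = self._diabats_ev(dists_A)
        # to hartree and hartree/bohr, plus calibrated offsets
        V = V_ev * EV_TO_HARTREE + self._offsets
        dV = dV_ev * EV_TO_HARTREE * BOHR_TO_ANGSTROM  # d/dbohr

        def block(i, j, eps_ev, lam_ev):
            eps, lam = eps_ev * EV_TO_HARTREE, lam_ev * EV_TO_HARTREE
            dgap = V[j] - V[i]
            ddgap = dV[j] - dV[i]
            u = dgap / lam
            c = eps * np.exp(-(u**2))
            dc = c * (-2.0 * u) * ddgap / lam
            B = np.array([[V[i], c], [c, V[j]]])
            dB = np.stack(
                [np.array([[dV[i, p], dc[p]], [dc[p], dV[j, p]]])
                 for p in range(len(dists))]
            )
            return B, dB

        p = self.p
        singlet = block(0, 1, *p["coupling_singlet"])
        triplet = block(2, 3, *p["coupling_triplet"])

        R3_A = dists_A[2]
        soc = {}
        for pair, key in [
            (("S1", "T2"), "soc_S1_T2"), (("S1", "T1"), "soc_S1_T1"),
            (("S0", "T2"), "soc_S0_T2"), (("S0", "T1"), "soc_S0_T1"),
        ]:
            base, amp = p[key]
            soc[pair] = base + _sigmoid(R3_A, amp, p["soc_center"],
                                        p["soc_width"])[0]
        return {1: singlet, 3: triplet}, soc

    def bond_lengths_angstrom(self, geom: Geometry) -> dict[str, float]:
        return {
            name: geom.distance(i, j) * BOHR_TO_ANGSTROM
            for name, (i, j) in self.BOND_INDICES.items()
        }


# ----------------------------------------------------------------------
# registry and ModelSpec-facing API

_REGISTRY: dict[str, Callable[[dict], AnalyticModel]] = {
    "avoided_crossing": AvoidedCrossing1D,
    "dual_crossing": DualCrossing1D,
    "singlet_triplet": SingletTriplet1D,
    "harmonic_2state": Harmonic2State1D,
    "ladder": LadderModel,
}


def build_model(spec: ModelSpec) -> AnalyticModel:
    try:
        builder = _REGISTRY[spec.model_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown model_id {spec.model_id!r}; known: {sorted(_REGISTRY)}"
        ) from None
    return builder(spec.parameters)


def eval_model_1d(spec: ModelSpec | _OneDModel, x: float) -> SurfacePoint:
    """Evaluate a registered 1D model at separation x (bohr)."""
    model = spec if isinstance(spec, AnalyticModel) else build_model(spec)
    if not isinstance(model, _OneDModel):
        raise ConfigurationError(f"{model.__class__.__name__} is not a 1D model")
    return model.evaluate(model.geometry_at(x))


def eval_ladder_model(spec: ModelSpec | LadderModel, geom: Geometry) -> SurfacePoint:
    model = spec if isinstance(spec, AnalyticModel) else build_model(spec)
    if not isinstance(model, LadderModel):
        raise ConfigurationError(f"{model.__class__.__name__} is not the ladder model")
    return model.evaluate(geom)


# ----------------------------------------------------------------------
# normal modes


def _fd_hessian(grad_fn, x0: np.ndarray, step: float) -> np.ndarray:
    n = x0.size
    H = np.empty((n, n))
    for i in range(n):
        xp = x0.copy(); xp[i] += step
        xm = x0.copy(); xm[i] -= step
        H[:, i] = (grad_fn(xp) - grad_fn(xm)) / (2.0 * step)
    return 0.5 * (H + H.T)


def _tr_rot_projector(geom: Geometry) -> np.ndarray:
    """Mass-weighted projector removing rigid translations and rotations."""
    m = geom.masses_au
    n = geom.n_atoms
    com = (m[:, None] * geom.coords).sum(axis=0) / m.sum()
    r = geom.coords - com
    vecs = []
    sq = np.sqrt(m)
    for ax in range(3):
        v = np.zeros((n, 3))
        v[:, ax] = sq
        vecs.append(v.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        v = sq[:, None] * np.cross(np.tile(e, (n, 1)), r)
        vecs.append(v.ravel())
    V = np.stack(vecs, axis=1)
    Q, R = np.linalg.qr(V)
    keep = np.abs(np.diag(R)) > 1e-8
    Q = Q[:, keep]
    return np.eye(3 * n) - Q @ Q.T


def normal_modes(
    spec: ModelSpec | AnalyticModel,
    geom: Geometry | None = None,
    fd_step: float = 1e-3,
    cutoff_cm: float = 5.0,
) -> NormalModeSet:
    """Harmonic analysis on the model's lowest state at (or near) a minimum.

    Mass-weighted Hessian by central finite differences of the analytic
    gradients (step in bohr), symmetrized; translations and rotations are
    projected out and, together with any mode below `cutoff_cm` in absolute
    wavenumber, excluded from sampling.  A retained imaginary frequency
    raises StationarityError.
    """
    model = spec if isinstance(spec, AnalyticModel) else build_model(spec)
    if geom is None:
        geom = model.reference_geometry()

    def grad0(xflat):
        sp = model.evaluate(geom.with_coords(xflat.reshape(-1, 3)))
        return sp.gradients[0].ravel()

    H = _fd_hessian(grad0, geom.coords.ravel(), fd_step)
    m = geom.masses_au
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(m, 3))
    Hmw = H * np.outer(inv_sqrt_m, inv_sqrt_m)
    P = _tr_rot_projector(geom)
    Hproj = P @ Hmw @ P
    lam, vecs = np.linalg.eigh(0.5 * (Hproj + Hproj.T))
    freqs = np.sign(lam) * np.sqrt(np.abs(lam)) * HARTREE_TO_WAVENUMBER
    retained = np.abs(freqs) >= cutoff_cm
    if np.any(freqs[retained] < 0):
        bad = freqs[retained][freqs[retained] < 0]
        raise StationarityError(
            f"imaginary retained frequencies {bad} cm^-1: geometry is not a minimum"
        )
    modes = vecs.T.reshape(-1, geom.n_atoms, 3)
    return NormalModeSet(
        frequencies=freqs,
        mode_vectors=modes,
        reference_geometry=geom,
        retained_mask=retained,
    )
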