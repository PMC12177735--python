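"""Ensemble mechanism analysis.

Classifies snapshots into the four ring-opening regions by the lengths of
the two breakable bonds, builds state populations over the ensemble, fits
the intersystem-crossing time constant, computes the ring-opening quantum
yield with per-pathway attribution, summarizes where hops occur, assembles
the species/state reaction network, and reports energy conservation.

Early-stopped trajectories (uncertainty breach, drift abort) contribute to
populations only up to their stopping time — they leave the denominator
afterwards rather than being padded — and are excluded from yields and the
reaction network by default (an `include_early_stopped` flag adds them
back for sensitivity checks).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import curve_fit

from .constants import BOHR_TO_ANGSTROM
from .dynamics import Ensemble, Trajectory
from .errors import ConfigurationError, EnsembleError, FitFailureError

# a breakable bond longer than this (angstrom) counts as opened; chosen
# between the closed (~1.6 A) and open (~2.9-3.3 A) basin values
OPEN_THRESHOLD_ANGSTROM = 2.2

# region naming follows the ring-opening progression: 1 closed reactant,
# 2 carbonyl-side bond R1 opened, 3 the other bond R2 opened, 4 both
# opened (product)
REGION_NAMES = {1: "closed", 2: "open-R1", 3: "open-R2", 4: "product"}
REGION_SPECIES = {1: "reactant", 2: "intermediate-R1",
                  3: "intermediate-R2", 4: "product"}

DEFAULT_BOND_INDICES = {"R1": (0, 1), "R2": (1, 2)}

COMPLETED = "reached-max-time"


def classify_geometry(
    coords_bohr: np.ndarray,
    bond_indices: dict[str, tuple[int, int]] | None = None,
    open_threshold: float = OPEN_THRESHOLD_ANGSTROM,
) -> int:
    """Ring-opening region (1-4) of one snapshot.

    bond_indices must map both breakable bonds "R1" and "R2" to atom-index
    pairs; lengths are compared against `open_threshold` (angstrom).
    """
    bi = bond_indices if bond_indices is not None else DEFAULT_BOND_INDICES
    for key in ("R1", "R2"):
        if key not in bi:
            raise ConfigurationError(f"bond_indices is missing {key!r}")
    c = np.asarray(coords_bohr, float)
    r1 = np.linalg.norm(c[bi["R1"][0]] - c[bi["R1"][1]]) * BOHR_TO_ANGSTROM
    r2 = np.linalg.norm(c[bi["R2"][0]] - c[bi["R2"][1]]) * BOHR_TO_ANGSTROM
    o1, o2 = r1 > open_threshold, r2 > open_threshold
    if o1 and o2:
        return 4
    if o1:
        return 2
    if o2:
        return 3
    return 1


def _analyzable(ensemble: Ensemble) -> list[Trajectory]:
    out = [t for t in ensemble.trajectories if t.termination != "provider-error"]
    if not out:
        raise EnsembleError("no analyzable trajectories (all provider errors)")
    return out


def _counted(ensemble: Ensemble, include_early_stopped: bool) -> list[Trajectory]:
    trajs = _analyzable(ensemble)
    if include_early_stopped:
        return trajs
    kept = [t for t in trajs if t.termination == COMPLETED]
    if not kept:
        raise EnsembleError(
            "every trajectory stopped early; pass include_early_stopped=True "
            "to analyze them anyway"
        )
    return kept


# ----------------------------------------------------------------------
# populations and kinetics


@dataclass(frozen=True)
class PopulationSeries:
    """Fraction of surviving trajectories in each state versus time."""

    times_fs: np.ndarray        # (T,), strictly increasing
    state_labels: tuple[str, ...]
    fractions: np.ndarray       # (T, S), rows sum to 1 where counts > 0
    counts: np.ndarray          # (T,) surviving-trajectory denominator


def state_populations(
    ensemble: Ensemble,
    grid_fs: np.ndarray | None = None,
) -> PopulationSeries:
    """Active-state populations on a common time grid.

    By default the grid is the time axis of the longest trajectory.  A
    trajectory contributes its active state at each grid time up to its own
    final frame and leaves the denominator afterwards (this is how
    early-stopped surrogate trajectories are handled).
    """
    trajs = _analyzable(ensemble)
    labels = trajs[0].state_labels
    if grid_fs is None:
        grid = max(trajs, key=lambda t: len(t.times_fs)).times_fs
    else:
        grid = np.asarray(grid_fs, float)
        if grid.size == 0:
            raise ValueError("empty time grid")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("time grid must be strictly increasing")
    n_t, n_s = len(grid), len(labels)
    counts = np.zeros(n_t, dtype=int)
    occ = np.zeros((n_t, n_s))
    for t in trajs:
        if t.state_labels != labels:
            raise EnsembleError("trajectories disagree on the state list")
        # index of the last own frame at or before each grid time; the
        # trajectory leaves the denominator after its own final frame
        pos = np.searchsorted(t.times_fs, grid + 1e-9) - 1
        alive = (pos >= 0) & (grid <= t.times_fs[-1] + 1e-9)
        pos_alive = pos[alive]
        counts[alive] += 1
        occ[np.flatnonzero(alive), t.active[pos_alive]] += 1.0
    fractions = np.divide(occ, counts[:, None], where=counts[:, None] > 0,
                          out=np.zeros_like(occ))
    return PopulationSeries(times_fs=grid, state_labels=labels,
                            fractions=fractions, counts=counts)


@dataclass(frozen=True)
class KineticsFit:
    """Exponential-decay fit of a donor population."""

    tau_fs: float
    model: str                       # "exp-linear" | "exp-log"
    residual_norm: float
    window_fs: tuple[float, float]
    donor: tuple[str, ...]

    @property
    def tau_ps(self) -> float:
        return self.tau_fs / 1000.0


def fit_isc_time_constant(
    series: PopulationSeries,
    donor_state: str | tuple[str, ...] = ("S0", "S1"),
    fit_window_fs: tuple[float, float] | None = None,
    log_scale: bool = False,
    min_count: int = 1,
) -> KineticsFit:
    """Time constant (fs) of the donor-population exponential decay.

    The donor fraction is normalized at the window start and fitted to
    exp(-(t - t0)/tau), by default with unweighted least squares on the
    linear scale (`log_scale` switches to a log-linear fit).  Raises
    FitFailureError when the series does not decay within the window.
    """
    donor = (donor_state,) if isinstance(donor_state, str) else tuple(donor_state)
    idx = [i for i, lbl in enumerate(series.state_labels) if lbl in donor]
    if not idx:
        raise FitFailureError(f"donor states {donor} not in the series")
    mask = series.counts >= min_count
    if fit_window_fs is not None:
        lo, hi = fit_window_fs
        if lo >= hi:
            raise ValueError("fit window must have lo < hi")
        if lo < series.times_fs[0] - 1e-9 or hi > series.times_fs[-1] + 1e-9:
            raise ValueError("fit window outside the data range")
        mask &= (series.times_fs >= lo) & (series.times_fs <= hi)
    t = series.times_fs[mask]
    p = series.fractions[mask][:, idx].sum(axis=1)
    if len(t) < 3:
        raise FitFailureError("too few time points for a kinetics fit")
    if p[0] <= 0:
        raise FitFailureError("donor population vanishes at the window start")
    if p[-1] >= p[0] - 1e-12:
        raise FitFailureError("donor population does not decay in the window")
    t0 = t[0]
    y = p / p[0]
    span = float(t[-1] - t0)
    p0 = [max(span / 2.0, 1.0)]
    if log_scale:
        pos = y > 0
        if np.count_nonzero(pos) < 3:
            raise FitFailureError("donor population hits zero; cannot log-fit")

        def model_fn(tt, tau):
            return -(tt - t0) / tau

        try:
            popt, _ = curve_fit(model_fn, t[pos], np.log(y[pos]), p0=p0,
                                bounds=(1e-6, np.inf), maxfev=10000)
        except RuntimeError as exc:
            raise FitFailureError(f"log-linear fit did not converge: {exc}")
        resid = np.log(y[pos]) - model_fn(t[pos], popt[0])
        name = "exp-log"
    else:

        def model_fn(tt, tau):
            return np.exp(-(tt - t0) / tau)

        try:
            popt, _ = curve_fit(model_fn, t, y, p0=p0,
                                bounds=(1e-6, np.inf), maxfev=10000)
        except RuntimeError as exc:
            raise FitFailureError(f"exponential fit did not converge: {exc}")
        resid = y - model_fn(t, popt[0])
        name = "exp-linear"
    return KineticsFit(
        tau_fs=float(popt[0]),
        model=name,
        residual_norm=float(np.linalg.norm(resid)),
        window_fs=(float(t0), float(t[-1])),
        donor=donor,
    )


# ----------------------------------------------------------------------
# yields and pathways


def _pathway_class(traj: Trajectory) -> str:
    """Pathway label: the first real hop pair, or remaining-<launch state>."""
    real = [h for h in traj.hop_events if not h.frustrated]
    if not real:
        return f"remaining-{traj.state_labels[int(traj.active[0])]}"
    first = real[0]
    return f"via {first.from_state}->{first.to_state}"


@dataclass(frozen=True)
class YieldReport:
    n_trajectories: int                   # counted trajectories
    n_excluded_early: int                 # early-stopped, excluded
    n_product: int
    yield_percent: float
    by_pathway: dict[str, int]            # product counts per pathway class
    pathway_counts: dict[str, int]        # all counted trajectories per class
    final_regions: dict[str, int]         # region name -> count
    final_states: dict[str, int]          # active label at the end -> count


def quantum_yield(
    ensemble: Ensemble,
    bond_indices: dict[str, tuple[int, int]] | None = None,
    open_threshold: float = OPEN_THRESHOLD_ANGSTROM,
    include_early_stopped: bool = False,
) -> YieldReport:
    """Ring-opened product yield over the ensemble's final snapshots.

    A trajectory counts as product when its final geometry has both
    breakable bonds open, regardless of the final electronic state.  The
    per-pathway attribution (`by_pathway`) splits the product count by the
    first hop pair and sums exactly to it; `pathway_counts` gives the same
    split over all counted trajectories.
    """
    trajs = _counted(ensemble, include_early_stopped)
    n_excluded = len(_analyzable(ensemble)) - len(trajs)
    by_pathway: dict[str, int] = {}
    pathway_counts: dict[str, int] = {}
    final_regions: dict[str, int] = {}
    final_states: dict[str, int] = {}
    n_product = 0
    for t in trajs:
        region = classify_geometry(t.coords[-1], bond_indices, open_threshold)
        name = REGION_NAMES[region]
        final_regions[name] = final_regions.get(name, 0) + 1
        lbl = t.final_active_label
        final_states[lbl] = final_states.get(lbl, 0) + 1
        cls = _pathway_class(t)
        pathway_counts[cls] = pathway_counts.get(cls, 0) + 1
        if region == 4:
            n_product += 1
            by_pathway[cls] = by_pathway.get(cls, 0) + 1
    return YieldReport(
        n_trajectories=len(trajs),
        n_excluded_early=n_excluded,
        n_product=n_product,
        yield_percent=100.0 * n_product / len(trajs),
        by_pathway=by_pathway,
        pathway_counts=pathway_counts,
        final_regions=final_regions,
        final_states=final_states,
    )


# ----------------------------------------------------------------------
# hop geography


@dataclass(frozen=True)
class HopRegionStatistics:
    pair: tuple[str, str]
    when: str
    n_matching: int
    region_fractions: dict[str, float]            # over matching subset
    region_counts: dict[str, int]
    mean_bond_lengths: dict[str, float] | None    # angstrom; None if empty
    times_fs: tuple[float, ...]                   # hop times (latest-hop mode)


def hop_region_statistics(
    ensemble: Ensemble,
    pair: tuple[str, str],
    when: str = "latest-hop",
    bond_indices: dict[str, tuple[int, int]] | None = None,
    open_threshold: float = OPEN_THRESHOLD_ANGSTROM,
) -> HopRegionStatistics:
    """Region statistics of trajectories that hopped pair[0] -> pair[1].

    For each matching trajectory, classify its latest matching real hop
    geometry (`when="latest-hop"`) or its final snapshot
    (`when="final-snapshot"`); report fractions over the matching subset.
    With no matching trajectory anywhere, returns an empty-result sentinel
    (n_matching 0, None bond lengths) rather than raising.
    """
    if when not in ("latest-hop", "final-snapshot"):
        raise ValueError("when must be 'latest-hop' or 'final-snapshot'")
    bi = bond_indices if bond_indices is not None else DEFAULT_BOND_INDICES
    coords_list, times = [], []
    region_counts: dict[str, int] = {}
    for t in _analyzable(ensemble):
        matching = [h for h in t.hop_events
                    if not h.frustrated
                    and h.from_state == pair[0] and h.to_state == pair[1]]
        if not matching:
            continue
        if when == "latest-hop":
            coords = matching[-1].coords
            times.append(matching[-1].time_fs)
        else:
            coords = t.coords[-1]
        coords_list.append(coords)
        name = REGION_NAMES[classify_geometry(coords, bi, open_threshold)]
        region_counts[name] = region_counts.get(name, 0) + 1
    n = len(coords_list)
    if n == 0:
        return HopRegionStatistics(pair=pair, when=when, n_matching=0,
                                   region_fractions={}, region_counts={},
                                   mean_bond_lengths=None, times_fs=())
    mean_bl = {}
    for bond, (i, j) in bi.items():
        ds = [np.linalg.norm(c[i] - c[j]) * BOHR_TO_ANGSTROM
              for c in coords_list]
        mean_bl[bond] = float(np.mean(ds))
    return HopRegionStatistics(
        pair=pair,
        when=when,
        n_matching=n,
        region_fractions={k: v / n for k, v in region_counts.items()},
        region_counts=region_counts,
        mean_bond_lengths=mean_bl,
        times_fs=tuple(float(x) for x in times),
    )


# ----------------------------------------------------------------------
# reaction network


def _node_sequence(traj: Trajectory, bond_indices, open_threshold):
    """Deduplicated (species-region, state-label) sequence along a trajectory."""
    seq = []
    for coords, a in zip(traj.coords, traj.active):
        r = classify_geometry(coords, bond_indices, open_threshold)
        node = (REGION_NAMES[r], traj.state_labels[int(a)])
        if not seq or seq[-1] != node:
            seq.append(node)
    return seq


def build_reaction_network(
    ensemble: Ensemble,
    bond_indices: dict[str, tuple[int, int]] | None = None,
    open_threshold: float = OPEN_THRESHOLD_ANGSTROM,
    include_early_stopped: bool = False,
) -> nx.DiGraph:
    """Directed (species, state) network of observed transitions.

    Nodes are "region|state" strings with `species` and `state`
    attributes; `terminal_count` / `terminal_percent` give the share of
    trajectories ending there (terminal percentages sum to 100 up to
    rounding).  Edges carry `count` (trajectories making the transition at
    least once), `percent`, and `label`, where shares below 1% are
    rendered "0%" with the count retained.  String node names keep the
    graph directly serializable to GML/GraphML.
    """
    trajs = _counted(ensemble, include_early_stopped)
    n = len(trajs)
    g = nx.DiGraph()
    edge_traj_counts: dict[tuple[str, str], int] = {}

    def node_name(node):
        region_name, state = node
        return f"{region_name}|{state}"

    def ensure(node):
        name = node_name(node)
        if name not in g:
            g.add_node(name, species=node[0], state=node[1],
                       terminal_count=0, terminal_percent=0.0)
        return name

    for t in trajs:
        seq = _node_sequence(t, bond_indices, open_threshold)
        names = [ensure(x) for x in seq]
        seen_edges = set(zip(names[:-1], names[1:]))
        for e in seen_edges:
            edge_traj_counts[e] = edge_traj_counts.get(e, 0) + 1
        g.nodes[names[-1]]["terminal_count"] += 1
    for name in g.nodes:
        g.nodes[name]["terminal_percent"] = (
            100.0 * g.nodes[name]["terminal_count"] / n
        )
    for (a, b), cnt in sorted(edge_traj_counts.items()):
        pct = 100.0 * cnt / n
        label = f"{pct:.0f}%" if pct >= 1.0 else "0%"
        g.add_edge(a, b, count=cnt, percent=pct, label=label)
    return g


# ----------------------------------------------------------------------
# energy conservation


def energy_drift_report(ensemble: Ensemble) -> dict:
    """Absolute total-energy drift statistics over the ensemble (eV).

    Reports the end-of-run drift, the peak drift, and the drift before
    each trajectory's first real hop.
    """
    trajs = _analyzable(ensemble)
    end = [t.drift_ev()[-1] for t in trajs]
    peak = [float(np.max(t.drift_ev())) for t in trajs]
    pre_hop = []
    for t in trajs:
        real = [h for h in t.hop_events if not h.frustrated]
        if real:
            i = int(np.searchsorted(t.times_fs, real[0].time_fs - 1e-9))
            i = max(i, 1)
        else:
            i = len(t.times_fs)
        pre_hop.append(float(np.max(t.drift_ev()[:i])))
    return {
        "n_trajectories": len(trajs),
        "mean_end_drift_ev": float(np.mean(end)),
        "max_end_drift_ev": float(np.max(end)),
        "mean_peak_drift_ev": float(np.mean(peak)),
        "max_peak_drift_ev": float(np.max(peak)),
        "mean_drift_before_first_hop_ev": float(np.mean(pre_hop)),
        "n_drift_flagged": sum(1 for t in trajs if t.drift_flagged),
    }
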