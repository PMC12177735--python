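"""Uncertainty-driven adaptive sampling loop.

Each round trains a fresh committee on the current dataset, runs
surrogate-driven surface-hopping trajectories with uncertainty monitoring
enabled, harvests the geometries at which the committee spread breached a
threshold, labels them with the reference model, filters unphysical
outliers and duplicates, and grows the dataset.  The loop stops early when
a round produces no breaches (every trajectory runs to completion within
the committee's confidence region).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ..dynamics import TrajectoryConfig, run_ensemble
from ..geometry import Geometry, SurfacePoint
from .committee import (
    CommitteeModel,
    TrainConfig,
    UncertaintyThresholds,
    train_committee,
)
from .descriptor import featurize

# labeled points whose lowest-state energy exceeds the dataset minimum by
# more than this are dissociative/unphysical and are discarded (hartree)
ENERGY_OUTLIER_HARTREE = 1.0
DEDUPE_TOL = 1e-8


@dataclass
class AdaptiveRound:
    index: int
    n_train: int
    terminations: dict[str, int]
    n_harvested: int
    n_discarded_outlier: int
    n_discarded_duplicate: int
    n_added: int
    validation_energy_mae: list[list[float]] = field(default_factory=list)


@dataclass
class AdaptiveResult:
    model: CommitteeModel
    dataset: list[tuple[Geometry, SurfacePoint]]
    rounds: list[AdaptiveRound]
    converged: bool


def _round_seed(seed: int, round_index: int, stream: int) -> int:
    ss = np.random.SeedSequence(entropy=int(seed),
                                spawn_key=(round_index, stream))
    return int(ss.generate_state(1)[0] % (2**31))


def _harvest(ensemble) -> list[np.ndarray]:
    """Final coordinates of every uncertainty-stopped trajectory."""
    out = []
    for traj in ensemble.trajectories:
        if traj.termination == "uncertainty-stop":
            out.append(traj.coords[-1].copy())
    return out


def harvest_trajectory_geometries(
    oracle,
    initial_conditions,
    dynamics_config: TrajectoryConfig,
    stride: int,
    seed: int,
) -> list[Geometry]:
    """Strided snapshots from short reference trajectories.

    Runs `initial_conditions` with the reference model and returns every
    `stride`-th frame of every trajectory.  Used to seed the initial
    training set with geometries from the regions dynamics actually
    visits, which straight-line interpolation paths and Franck-Condon
    Wigner sampling alone do not cover.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    ensemble = run_ensemble(
        oracle,
        initial_conditions,
        replace(dynamics_config, check_uncertainty=False),
        base_seed=seed,
    )
    template = initial_conditions[0].geometry
    out: list[Geometry] = []
    for traj in ensemble.trajectories:
        for coords in traj.coords[::stride]:
            out.append(template.with_coords(coords.copy()))
    return out


def adaptive_sample(
    oracle,
    dataset: Sequence[tuple[Geometry, SurfacePoint]],
    initial_conditions,
    rounds: int,
    dynamics_config: TrajectoryConfig | None = None,
    train_config: TrainConfig | None = None,
    thresholds: UncertaintyThresholds | None = None,
    seed: int = 0,
    energy_outlier: float = ENERGY_OUTLIER_HARTREE,
    dedupe_tol: float = DEDUPE_TOL,
) -> AdaptiveResult:
    """Grow `dataset` by uncertainty-driven sampling against `oracle`.

    oracle: reference provider with .evaluate(geom) and .state_list;
    dataset: initial labeled (geometry, surface point) pairs;
    initial_conditions: sampled phase-space points used every round;
    rounds: maximum number of train/propagate/harvest cycles.

    Returns the final trained committee, the grown dataset, per-round
    statistics, and whether the loop converged (a round with no breaches).
    """
    if rounds < 1:
        raise ValueError("at least one round is required")
    if len(dataset) == 0:
        raise ValueError("initial dataset must not be empty")
    dataset = list(dataset)
    dynamics_config = dynamics_config or TrajectoryConfig()
    train_config = train_config or TrainConfig()
    thresholds = thresholds or UncertaintyThresholds()
    template = dataset[0][0]

    feats_seen = [featurize(g).values for g, _ in dataset]
    e_floor = min(float(sp.energies.min()) for _, sp in dataset)

    round_log: list[AdaptiveRound] = []
    model: CommitteeModel | None = None
    converged = False

    for r in range(rounds):
        model = train_committee(
            dataset,
            replace(train_config, seed=_round_seed(seed, r, 0)),
            state_list=oracle.state_list,
            thresholds=thresholds,
        )
        ensemble = run_ensemble(
            model,
            initial_conditions,
            replace(dynamics_config, check_uncertainty=True),
            base_seed=_round_seed(seed, r, 1),
        )
        harvested = _harvest(ensemble)
        n_outlier = n_dup = n_added = 0
        for coords in harvested:
            geom = template.with_coords(coords)
            feats = featurize(geom).values
            if any(
                np.max(np.abs(feats - f)) < dedupe_tol for f in feats_seen
            ):
                n_dup += 1
                continue
            sp = oracle.evaluate(geom)
            if float(sp.energies.min()) > e_floor + energy_outlier:
                n_outlier += 1
                continue
            dataset.append((geom, sp))
            feats_seen.append(feats)
            e_floor = min(e_floor, float(sp.energies.min()))
            n_added += 1

        round_log.append(
            AdaptiveRound(
                index=r,
                n_train=len(dataset) - n_added,
                terminations=ensemble.summary()["terminations"],
                n_harvested=len(harvested),
                n_discarded_outlier=n_outlier,
                n_discarded_duplicate=n_dup,
                n_added=n_added,
                validation_energy_mae=[
                    m["val_energy_mae"]
                    for m in model.training_report["members"]
                ],
            )
        )
        if len(harvested) == 0:
            converged = True
            break

    if round_log and round_log[-1].n_added > 0 and not converged:
        # points were added in the final round: retrain so the returned
        # model reflects the full dataset
        model = train_committee(
            dataset,
            replace(train_config, seed=_round_seed(seed, rounds, 0)),
            state_list=oracle.state_list,
            thresholds=thresholds,
        )
    return AdaptiveResult(
        model=model, dataset=dataset, rounds=round_log, converged=converged
    )
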