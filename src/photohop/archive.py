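"""Dataset and ensemble archives (.npz containers with a JSON metadata key).

The labeled-dataset archive stores (geometry, surface point) pairs as
stacked arrays; the ensemble archive stores per-trajectory arrays under
prefixed keys (trajectory lengths differ, so they cannot be stacked).
Everything loads back without the training stack.
"""

from __future__ import annotations

import json

import numpy as np

from .dynamics import Ensemble, HopEvent, Trajectory
from .geometry import Geometry, SurfacePoint

_TRAJ_ARRAYS = ("times_fs", "coords", "velocities", "active",
                "total_energy", "amplitudes")


# ----------------------------------------------------------------------
# labeled dataset


def save_dataset(path, dataset, provenance=None) -> None:
    """Save (Geometry, SurfacePoint) pairs; provenance strings optional."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    g0, sp0 = dataset[0]
    soc_pairs = list(sp0.soc_norms.keys())
    arrays = {
        "coords": np.stack([g.coords for g, _ in dataset]),
        "energies": np.stack([sp.energies for _, sp in dataset]),
        "gradients": np.stack([sp.gradients for _, sp in dataset]),
        "soc_norms": np.array(
            [[sp.soc_norms[p] for p in soc_pairs] for _, sp in dataset]
        ) if soc_pairs else np.zeros((len(dataset), 0)),
        "masses": g0.masses,
    }
    meta = {
        "atom_labels": list(g0.atom_labels),
        "soc_pairs": [list(p) for p in soc_pairs],
        "provenance": list(provenance) if provenance is not None else [],
        "n_points": len(dataset),
    }
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_dataset(path):
    """Load a dataset archive; returns (pairs, provenance list)."""
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta_json"]))
    labels = tuple(meta["atom_labels"])
    soc_pairs = [tuple(p) for p in meta["soc_pairs"]]
    masses = data["masses"]
    pairs = []
    for i in range(meta["n_points"]):
        geom = Geometry(labels, data["coords"][i], masses)
        sp = SurfacePoint(
            energies=data["energies"][i],
            gradients=data["gradients"][i],
            soc_norms={p: float(v) for p, v in
                       zip(soc_pairs, data["soc_norms"][i])},
        )
        pairs.append((geom, sp))
    return pairs, meta["provenance"]


# ----------------------------------------------------------------------
# ensembles


def save_ensemble(path, ensemble: Ensemble) -> None:
    arrays = {}
    metas = []
    for i, t in enumerate(ensemble.trajectories):
        for name in _TRAJ_ARRAYS:
            arrays[f"t{i}_{name}"] = np.asarray(getattr(t, name))
        metas.append({
            "hop_events": [
                {"time_fs": h.time_fs, "from_state": h.from_state,
                 "to_state": h.to_state, "kind": h.kind,
                 "frustrated": h.frustrated,
                 "coords": np.asarray(h.coords).tolist()}
                for h in t.hop_events
            ],
            "termination": t.termination,
            "drift_flagged": t.drift_flagged,
            "seed": t.seed,
            "diagnostic": t.diagnostic,
            "state_labels": list(t.state_labels),
        })
    arrays["meta_json"] = np.array(json.dumps({
        "base_seed": ensemble.base_seed,
        "n_trajectories": len(ensemble.trajectories),
        "trajectories": metas,
    }))
    np.savez(path, **arrays)


def load_ensemble(path) -> Ensemble:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta_json"]))
    trajectories = []
    for i, tm in enumerate(meta["trajectories"]):
        hops = [
            HopEvent(
                time_fs=h["time_fs"], from_state=h["from_state"],
                to_state=h["to_state"], coords=np.array(h["coords"]),
                kind=h["kind"], frustrated=h["frustrated"],
            )
            for h in tm["hop_events"]
        ]
        kwargs = {name: data[f"t{i}_{name}"] for name in _TRAJ_ARRAYS}
        trajectories.append(Trajectory(
            state_labels=tuple(tm["state_labels"]),
            hop_events=hops,
            termination=tm["termination"],
            drift_flagged=tm["drift_flagged"],
            seed=tm["seed"],
            diagnostic=tm["diagnostic"],
            **kwargs,
        ))
    return Ensemble(trajectories=trajectories,
                    base_seed=meta["base_seed"])
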