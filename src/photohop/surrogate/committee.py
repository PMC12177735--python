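"""Committee-of-networks surrogate with uncertainty quantification.

Two independently initialized networks predict the state energies (their
analytic input derivatives supply the gradients, fitted jointly through a
combined loss), and two more predict the SOC norms through a softplus
output head (norms are nonnegative).  The committee mean is the
prediction; the member spread (population standard deviation) is the
uncertainty, used to early-stop trajectories and drive adaptive sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from ..errors import UntrainedModelError
from ..geometry import Geometry, SurfacePoint
from .descriptor import featurize_with_jacobian
from .network import MLP, train

DEFAULT_STATE_MULTIPLICITY = {"S": 1, "T": 3}


@dataclass(frozen=True)
class UncertaintyThresholds:
    """Committee-spread thresholds triggering trajectory early stop.

    Defaults follow the adaptive-sampling protocol: 0.05 hartree in energy,
    0.25 hartree/bohr in gradient, 60 cm^-1 in SOC norm.
    """

    energy: float = 0.05
    gradient: float = 0.25
    soc_norm: float = 60.0

    def __post_init__(self):
        if min(self.energy, self.gradient, self.soc_norm) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class TrainConfig:
    split_fraction: float = 0.9  # training fraction (9:1 split)
    epochs: int = 400
    batch_size: int = 64
    learning_rate: float = 1e-3
    learning_rate_final: float = 1e-4
    w_energy: float = 1.0
    w_grad: float = 1.0
    hidden: tuple[int, int] = (64, 64)
    activation: str = "leaky_softplus"
    n_members: int = 2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.w_energy < 0 or self.w_grad < 0:
            raise ValueError("loss weights must be nonnegative")


def _member_seed(seed: int, kind: int, member: int) -> int:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(kind, member))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class CommitteeModel:
    state_list: tuple[tuple[str, int], ...]
    soc_pairs: tuple[tuple[str, str], ...]
    atom_labels: tuple[str, ...]
    members_energy: list = field(default_factory=list)
    members_soc: list = field(default_factory=list)
    normalization: dict = field(default_factory=dict)
    thresholds: UncertaintyThresholds = field(default_factory=UncertaintyThresholds)
    training_report: dict = field(default_factory=dict)
    config: TrainConfig = field(default_factory=TrainConfig)
    trained: bool = False

    # -- prediction ------------------------------------------------------

    def _member_outputs(self, geom: Geometry):
        if not self.trained or not self.members_energy:
            raise UntrainedModelError("committee has not been trained")
        feats, J = featurize_with_jacobian(geom)
        nz = self.normalization
        x = ((feats - nz["mu_f"]) / nz["sig_f"])[None, :]
        Jeff = (J / nz["sig_f"][:, None])[None, :, :]
        energies, grads = [], []
        for net in self.members_energy:
            yn, Gn = net.forward_with_input_grad(x)
            e = yn[0] * nz["sig_e"] + nz["mu_e"]
            g = np.einsum("sd,dc->sc", Gn[0], Jeff[0]) * nz["sig_e"]
            energies.append(e)
            grads.append(g.reshape(len(self.state_list), -1, 3))
        socs = [net.forward(x)[0] * nz["sig_s"] for net in self.members_soc]
        return np.array(energies), np.array(grads), np.array(socs)

    def evaluate_with_uncertainty(self, geom: Geometry):
        E, G, S = self._member_outputs(geom)
        e_mean, g_mean, s_mean = E.mean(0), G.mean(0), np.maximum(S.mean(0), 0.0)
        e_std, g_std, s_std = E.std(0), G.std(0), S.std(0)
        sp = SurfacePoint(
            energies=e_mean,
            gradients=g_mean,
            soc_norms={p: float(v) for p, v in zip(self.soc_pairs, s_mean)},
        )
        unc = {
            "energy": e_std,
            "gradient": g_std,
            "soc_norm": {p: float(v) for p, v in zip(self.soc_pairs, s_std)},
        }
        return sp, unc

    def evaluate(self, geom: Geometry) -> SurfacePoint:
        return self.evaluate_with_uncertainty(geom)[0]

    def uncertainty_breach(self, unc: dict) -> str | None:
        """Name of the first threshold the spread exceeds, else None."""
        th = self.thresholds
        if np.max(unc["energy"]) > th.energy:
            return "energy"
        if np.max(np.abs(unc["gradient"])) > th.gradient:
            return "gradient"
        if unc["soc_norm"] and max(unc["soc_norm"].values()) > th.soc_norm:
            return "soc_norm"
        return None

    # -- persistence -------------------------------------------------------

    def save(self, path):
        arrays = {}
        for i, net in enumerate(self.members_energy):
            for k, v in net.parameters().items():
                arrays[f"energy_{i}_{k}"] = v
        for i, net in enumerate(self.members_soc):
            for k, v in net.parameters().items():
                arrays[f"soc_{i}_{k}"] = v
        for k, v in self.normalization.items():
            arrays[f"norm_{k}"] = np.asarray(v)
        meta = {
            "state_list": list(map(list, self.state_list)),
            "soc_pairs": list(map(list, self.soc_pairs)),
            "atom_labels": list(self.atom_labels),
            "thresholds": asdict(self.thresholds),
            "config": {**asdict(self.config),
                       "hidden": list(self.config.hidden)},
            "training_report": self.training_report,
            "n_members": len(self.members_energy),
        }
        arrays["meta_json"] = np.array(json.dumps(meta))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "CommitteeModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta_json"]))
        cfg = dict(meta["config"])
        cfg["hidden"] = tuple(cfg["hidden"])
        config = TrainConfig(**cfg)
        norm = {k[5:]: data[k] for k in data.files if k.startswith("norm_")}
        norm = {k: (float(v) if v.ndim == 0 else v) for k, v in norm.items()}
        state_list = tuple((s, int(m)) for s, m in meta["state_list"])
        soc_pairs = tuple((a, b) for a, b in meta["soc_pairs"])
        model = cls(
            state_list=state_list,
            soc_pairs=soc_pairs,
            atom_labels=tuple(meta["atom_labels"]),
            thresholds=UncertaintyThresholds(**meta["thresholds"]),
            training_report=meta["training_report"],
            config=config,
            trained=True,
        )
        n_feat = norm["mu_f"].shape[0]
        for i in range(meta["n_members"]):
            net = MLP(n_feat, len(state_list), hidden=config.hidden)
            net.set_parameters({k: data[f"energy_{i}_{k}"] for k in
                                ("W1", "b1", "W2", "b2", "W3", "b3")})
            model.members_energy.append(net)
            if soc_pairs:
                snet = MLP(n_feat, len(soc_pairs), hidden=config.hidden,
                           softplus_head=True)
                snet.set_parameters({k: data[f"soc_{i}_{k}"] for k in
                                     ("W1", "b1", "W2", "b2", "W3", "b3")})
                model.members_soc.append(snet)
        model.normalization = norm
        return model


def _prepare_arrays(dataset: Sequence[tuple[Geometry, SurfacePoint]]):
    feats, jacs, energies, grads, socs = [], [], [], [], []
    soc_pairs = tuple(dataset[0][1].soc_norms.keys())
    for geom, sp in dataset:
        f, J = featurize_with_jacobian(geom)
        feats.append(f)
        jacs.append(J)
        energies.append(sp.energies)
        grads.append(sp.gradients.reshape(sp.energies.shape[0], -1))
        socs.append([sp.soc_norms[p] for p in soc_pairs])
    return (np.array(feats), np.array(jacs), np.array(energies),
            np.array(grads), np.array(socs), soc_pairs)


def split_indices(n: int, split_fraction: float, seed: int):
    """Seeded by-point random split into (train, validation) indices."""
    rng = np.random.Generator(np.random.Philox(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(9,))))
    order = rng.permutation(n)
    n_train = max(1, int(round(n * split_fraction)))
    n_train = min(n_train, n - 1) if n > 1 else 1
    return order[:n_train], order[n_train:]


def train_committee(
    dataset: Sequence[tuple[Geometry, SurfacePoint]],
    config: TrainConfig | None = None,
    state_list: tuple[tuple[str, int], ...] | None = None,
    thresholds: UncertaintyThresholds | None = None,
) -> CommitteeModel:
    """Train the committee on (geometry, surface point) pairs.

    Member networks share the descriptor and the seeded 9:1 split but are
    independently initialized.  Predicted gradients are analytic
    derivatives of the predicted energies, fitted through the combined
    energy+gradient loss.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    config = config or TrainConfig()
    X, J, E, G, S, soc_pairs = _prepare_arrays(dataset)
    n, n_feat = X.shape
    n_states = E.shape[1]
    if state_list is None:
        state_list = tuple(
            (f"E{k}", 1) for k in range(n_states)
        )

    mu_f = X.mean(axis=0)
    sig_f = np.maximum(X.std(axis=0), 1e-12)
    mu_e = E.mean(axis=0)
    sig_e = max(float((E - mu_e).std()), 1e-12)
    sig_s = max(float(S.std()), 1e-12) if S.size else 1.0

    Xn = (X - mu_f) / sig_f
    En = (E - mu_e) / sig_e
    Gn = G / sig_e
    Jeff = J / sig_f[None, :, None]
    Sn = S / sig_s

    itr, ival = split_indices(n, config.split_fraction, config.seed)
    if len(ival) == 0:
        ival = itr[:1]

    model = CommitteeModel(
        state_list=state_list,
        soc_pairs=soc_pairs,
        atom_labels=dataset[0][0].atom_labels,
        normalization={"mu_f": mu_f, "sig_f": sig_f, "mu_e": mu_e,
                       "sig_e": sig_e, "sig_s": sig_s},
        thresholds=thresholds or UncertaintyThresholds(),
        config=config,
    )

    report_members = []
    for m in range(config.n_members):
        net = MLP(n_feat, n_states, hidden=config.hidden,
                  seed=_member_seed(config.seed, 1, m))
        train(net, Xn[itr], En[itr], Jeff[itr], Gn[itr],
              epochs=config.epochs, batch_size=config.batch_size,
              lr=config.learning_rate, lr_final=config.learning_rate_final,
              w_energy=config.w_energy, w_grad=config.w_grad,
              seed=_member_seed(config.seed, 2, m))
        model.members_energy.append(net)

        yv, Gv = net.forward_with_input_grad(Xn[ival])
        e_pred = yv * sig_e + mu_e
        g_pred = np.einsum("nsd,ndc->nsc", Gv, Jeff[ival]) * sig_e
        member_report = {
            "val_energy_mae": np.mean(np.abs(e_pred - E[ival]), axis=0).tolist(),
            "val_gradient_mae": float(np.mean(np.abs(g_pred - G[ival]))),
        }
        if len(soc_pairs):
            snet = MLP(n_feat, len(soc_pairs), hidden=config.hidden,
                       seed=_member_seed(config.seed, 3, m),
                       softplus_head=True)
            train(snet, Xn[itr], Sn[itr],
                  epochs=config.epochs, batch_size=config.batch_size,
                  lr=config.learning_rate, lr_final=config.learning_rate_final,
                  seed=_member_seed(config.seed, 4, m))
            model.members_soc.append(snet)
            s_pred = snet.forward(Xn[ival]) * sig_s
            member_report["val_soc_mae"] = np.mean(
                np.abs(s_pred - S[ival]), axis=0).tolist()
        report_members.append(member_report)

    model.training_report = {
        "members": report_members,
        "n_train": int(len(itr)),
        "n_val": int(len(ival)),
        "train_indices": itr.tolist(),
        "val_indices": ival.tolist(),
    }
    model.trained = True
    return model


def predict(model: CommitteeModel, geom: Geometry):
    """Committee-mean SurfacePoint and per-quantity member spreads."""
    return model.evaluate_with_uncertainty(geom)
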