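"""Anti-cancer activity classifiers.

The primary model is a directed-bond message-passing network over the
molecular graph, optionally concatenated with auxiliary per-drug feature
blocks (PCA-compressed DTI, AMFP-compressed DDI, 2D physicochemical
descriptors) before the feed-forward head.  An ensemble (default two
members differing only by seed) averages member probabilities.

Baselines operate on 2048-bit Morgan fingerprints: gradient-boosted trees
(XGBoost) and an SVM whose ranking scores are decision-function margins and
whose thresholded predictions use Platt-calibrated probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .chem import Molecule, morgan_fingerprint
from .curation import LabeledDataset
from .features import AuxiliaryFeatures
from .mpnn import MPNN, MolGraph, mol_to_graph

AUX_BLOCK_NAMES = ("dti", "ddi", "physchem")


class DegenerateLabelsError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters for one model variant; every field is recorded in
    outputs so runs are reproducible."""

    variant: str = "mpnn"  # mpnn | gbm_fingerprint | svm_fingerprint
    aux_feature_blocks: tuple[str, ...] = ()
    hidden_dim: int = 300
    message_depth: int = 3
    ffn_layers: int = 2
    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("mpnn", "gbm_fingerprint", "svm_fingerprint"):
            raise ValueError(f"unknown variant {self.variant!r}")
        for b in self.aux_feature_blocks:
            if b not in AUX_BLOCK_NAMES:
                raise ValueError(f"unknown auxiliary block {b!r}")


# -- physicochemical descriptors -------------------------------------------

_PHYSCHEM_FUNCS = [
    ("mol_weight", Descriptors.MolWt),
    ("logp", Crippen.MolLogP),
    ("tpsa", rdMolDescriptors.CalcTPSA),
    ("hbd", Lipinski.NumHDonors),
    ("hba", Lipinski.NumHAcceptors),
    ("rotatable_bonds", Lipinski.NumRotatableBonds),
    ("ring_count", rdMolDescriptors.CalcNumRings),
    ("aromatic_rings", rdMolDescriptors.CalcNumAromaticRings),
    ("heavy_atoms", Descriptors.HeavyAtomCount),
    ("fraction_csp3", rdMolDescriptors.CalcFractionCSP3),
    ("molar_refractivity", Crippen.MolMR),
    ("heteroatoms", rdMolDescriptors.CalcNumHeteroatoms),
]

PHYSCHEM_DIM = len(_PHYSCHEM_FUNCS)


def physchem_descriptors(mol: Molecule) -> np.ndarray:
    """Fixed-length vector of 2D physicochemical descriptors.

    Individual descriptor failures yield NaN; callers standardizing on a
    training set replace NaN with the training column mean.
    """
    rd = mol.to_rdkit()
    out = np.empty(PHYSCHEM_DIM)
    for i, (_, fn) in enumerate(_PHYSCHEM_FUNCS):
        try:
            out[i] = float(fn(rd))
        except Exception:  # pragma: no cover - RDKit 2D descriptors rarely fail
            out[i] = np.nan
    return out


# -- auxiliary feature assembly ---------------------------------------------

def _aux_matrix(
    molecules: Sequence[Molecule],
    features: Optional[Mapping[str, AuxiliaryFeatures]],
    blocks: tuple[str, ...],
) -> Optional[np.ndarray]:
    """Concatenate the selected feature blocks, row per molecule."""
    if not blocks:
        return None
    parts = []
    for mol in molecules:
        row = []
        for block in blocks:
            if block == "physchem":
                row.append(physchem_descriptors(mol))
            else:
                if features is None or mol.id not in features:
                    raise ValueError(
                        f"auxiliary block {block!r} requested but no features "
                        f"for molecule {mol.id!r}"
                    )
                feats = features[mol.id]
                row.append(feats.dti_block if block == "dti" else feats.ddi_block)
        parts.append(np.concatenate(row))
    return np.stack(parts)


@dataclass
class Standardizer:
    """Column-wise z-scoring with training-set statistics; NaNs are filled
    with the training mean before scaling."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "Standardizer":
        mean = np.nanmean(x, axis=0)
        std = np.nanstd(x, axis=0)
        std[std == 0] = 1.0
        return cls(mean=mean, std=std)

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.where(np.isnan(x), self.mean, x)
        return (x - self.mean) / self.std


# -- trained models ----------------------------------------------------------

@dataclass
class TrainedModel:
    """One trained member: either an MPNN or a fingerprint baseline."""

    config: ModelConfig
    network: Optional[MPNN] = None
    sk_model: object = None
    standardizer: Optional[Standardizer] = None

    def predict_scores(
        self,
        molecules: Sequence[Molecule],
        features: Optional[Mapping[str, AuxiliaryFeatures]] = None,
        graphs: Optional[Sequence[MolGraph]] = None,
        calibrated: bool = False,
    ) -> np.ndarray:
        if self.config.variant == "mpnn":
            if graphs is None:
                graphs = [mol_to_graph(m) for m in molecules]
            aux = _aux_matrix(molecules, features, self.config.aux_feature_blocks)
            if aux is not None:
                aux = self.standardizer.transform(aux)
            return self.network.predict_proba(graphs, aux)
        fps = np.stack([morgan_fingerprint(m).bits for m in molecules]).astype(float)
        if self.config.variant == "gbm_fingerprint":
            return self.sk_model.predict_proba(fps)[:, 1]
        # SVM: decision-function margin for ranking, Platt probability when
        # a calibrated score in [0, 1] is required.
        if calibrated:
            return self.sk_model.predict_proba(fps)[:, 1]
        return self.sk_model.decision_function(fps)


@dataclass
class TrainedEnsemble:
    """Seed-replicated members; prediction is the arithmetic member mean."""

    members: list[TrainedModel]
    config: ModelConfig
    member_seeds: list[int] = field(default_factory=list)


@dataclass
class PredictionSet:
    scores: dict[str, float]
    config: ModelConfig


def _check_labels(labels: np.ndarray) -> None:
    if len(set(labels.tolist())) < 2:
        raise DegenerateLabelsError("training set contains a single class")


def train_mpnn(
    train: LabeledDataset,
    features: Optional[Mapping[str, AuxiliaryFeatures]],
    config: ModelConfig,
) -> TrainedModel:
    """Train one message-passing network on the labeled dataset.

    Auxiliary blocks listed in the config are z-scored with training-set
    statistics and concatenated to the molecule readout.  With no blocks
    selected the model is structure-only and ignores any feature table.
    """
    molecules = train.molecules
    labels = np.array([train.labels[m.id] for m in molecules], dtype=float)
    _check_labels(labels)
    graphs = [mol_to_graph(m) for m in molecules]
    aux = _aux_matrix(molecules, features, config.aux_feature_blocks)
    standardizer = None
    if aux is not None:
        standardizer = Standardizer.fit(aux)
        aux = standardizer.transform(aux)
    net = MPNN(
        hidden_dim=config.hidden_dim,
        message_depth=config.message_depth,
        ffn_layers=config.ffn_layers,
        aux_dim=aux.shape[1] if aux is not None else 0,
        seed=config.seed,
    )
    net.fit(
        graphs,
        labels,
        aux,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        seed=config.seed,
    )
    return TrainedModel(config=config, network=net, standardizer=standardizer)


def train_baseline(
    train: LabeledDataset,
    kind: str,
    config: Optional[ModelConfig] = None,
) -> TrainedModel:
    """Fingerprint baselines: XGBoost trees or an RBF SVM.

    The SVM's ranking score is its decision-function margin (monotone in
    probability); Platt-calibrated probabilities back its thresholded
    class predictions.
    """
    if kind not in ("gbm_fingerprint", "svm_fingerprint"):
        raise ValueError(f"unknown baseline kind {kind!r}")
    config = replace(config or ModelConfig(), variant=kind)
    molecules = train.molecules
    labels = np.array([train.labels[m.id] for m in molecules])
    _check_labels(labels)
    fps = np.stack([morgan_fingerprint(m).bits for m in molecules]).astype(float)
    if kind == "gbm_fingerprint":
        model = XGBClassifier(
            n_estimators=200,
            max_depth=5,
            learning_rate=0.1,
            random_state=config.seed,
            n_jobs=1,
            eval_metric="logloss",
        )
        model.fit(fps, labels)
    else:
        model = SVC(kernel="rbf", probability=True, random_state=config.seed)
        model.fit(fps, labels)
    return TrainedModel(config=config, sk_model=model)


def train_ensemble(
    train: LabeledDataset,
    features: Optional[Mapping[str, AuxiliaryFeatures]],
    config: ModelConfig,
    n_members: int = 2,
) -> TrainedEnsemble:
    """Train ``n_members`` replicas differing only by seed (seed, seed+1, ...)."""
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    members, seeds = [], []
    for k in range(n_members):
        member_config = replace(config, seed=config.seed + k)
        if config.variant == "mpnn":
            members.append(train_mpnn(train, features, member_config))
        else:
            members.append(train_baseline(train, config.variant, member_config))
        seeds.append(member_config.seed)
    return TrainedEnsemble(members=members, config=config, member_seeds=seeds)


def save_ensemble(ensemble: TrainedEnsemble, out_dir) -> None:
    """Persist an ensemble as a directory: `config.json`, per-member MPNN
    weights (npz) or pickled sklearn/xgboost models, and feature-scaling
    statistics."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    import joblib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = asdict(ensemble.config)
    meta["member_seeds"] = ensemble.member_seeds
    meta["n_members"] = len(ensemble.members)
    (out / "config.json").write_text(json.dumps(meta, indent=2))
    for k, member in enumerate(ensemble.members):
        if member.config.variant == "mpnn":
            net = member.network
            arrays = {"W_i": net.W_i, "W_h": net.W_h, "W_o": net.W_o}
            for j, (w, b) in enumerate(zip(net.ffn_W, net.ffn_b)):
                arrays[f"ffn_W{j}"] = w
                arrays[f"ffn_b{j}"] = b
            if member.standardizer is not None:
                arrays["aux_mean"] = member.standardizer.mean
                arrays["aux_std"] = member.standardizer.std
            np.savez(out / f"member{k}.npz", **arrays)
        else:
            joblib.dump(member.sk_model, out / f"member{k}.joblib")


def load_ensemble(in_dir) -> TrainedEnsemble:
    import json
    from pathlib import Path

    import joblib

    src = Path(in_dir)
    meta = json.loads((src / "config.json").read_text())
    member_seeds = meta.pop("member_seeds")
    n_members = meta.pop("n_members")
    meta["aux_feature_blocks"] = tuple(meta["aux_feature_blocks"])
    config = ModelConfig(**meta)
    members = []
    for k in range(n_members):
        member_config = replace(config, seed=member_seeds[k])
        if config.variant == "mpnn":
            data = np.load(src / f"member{k}.npz")
            standardizer = None
            if "aux_mean" in data:
                standardizer = Standardizer(mean=data["aux_mean"], std=data["aux_std"])
            aux_dim = int(standardizer.mean.shape[0]) if standardizer else 0
            net = MPNN(
                hidden_dim=config.hidden_dim,
                message_depth=config.message_depth,
                ffn_layers=config.ffn_layers,
                aux_dim=aux_dim,
                seed=member_config.seed,
            )
            net.W_i = data["W_i"]; net.W_h = data["W_h"]; net.W_o = data["W_o"]
            net.ffn_W = [data[f"ffn_W{j}"] for j in range(config.ffn_layers)]
            net.ffn_b = [data[f"ffn_b{j}"] for j in range(config.ffn_layers)]
            members.append(TrainedModel(config=member_config, network=net,
                                        standardizer=standardizer))
        else:
            members.append(TrainedModel(
                config=member_config,
                sk_model=joblib.load(src / f"member{k}.joblib"),
            ))
    return TrainedEnsemble(members=members, config=config, member_seeds=member_seeds)


def predict(
    ensemble: TrainedEnsemble,
    molecules: Sequence[Molecule],
    features: Optional[Mapping[str, AuxiliaryFeatures]] = None,
    calibrated: bool = False,
) -> PredictionSet:
    """Mean member score per molecule; deterministic given trained weights."""
    graphs = None
    if ensemble.config.variant == "mpnn":
        graphs = [mol_to_graph(m) for m in molecules]
    stacked = np.stack([
        m.predict_scores(molecules, features, graphs, calibrated) for m in ensemble.members
    ])
    mean = stacked.mean(axis=0)
    return PredictionSet(
        scores={mol.id: float(s) for mol, s in zip(molecules, mean)},
        config=ensemble.config,
    )
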