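"""Synthetic benchmark generator with planted, configurable signal.

Stands in for the license-gated study data (drug catalogue, drug-target
matrix, drug-drug adjacency, anti-cancer labels) so that every pipeline
stage is testable end to end.  Molecules are assembled from fixed
ring-system templates with random substituents, which guarantees chemical
validity and controllable scaffold sharing.  The binary label's logit mixes
three planted signal channels:

* structure — presence of a nitro substituent on the molecule;
* DTI — membership in latent target-profile class 0 (class-specific target
  columns are hit densely, background sparsely);
* DDI — membership in community 0 of a stochastic block model adjacency.

The intercept is calibrated so the expected positive rate matches the
configured value (default 1/3, echoing the study's 451:918 class balance),
then labels are flipped with probability ``label_noise``.  A fraction of
drugs is withheld from each interaction matrix to exercise imputation; the
withheld ids are recorded in the ground truth.

All randomness flows from one seed: sub-generators draw from child streams
spawned deterministically, so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .chem import Molecule
from .curation import CatalogueEntry
from .matrices import InteractionMatrix, from_entries, write_triplets

# Ring-system templates; {0} and {1} mark substitution sites.
TEMPLATES = [
    "c1cc({0})ccc1{1}",                    # benzene
    "c1ccc2cc({0})c({1})cc2c1",            # naphthalene
    "c1nc({0})ccc1{1}",                    # pyridine
    "C1CC({0})CCC1{1}",                    # cyclohexane
    "c1cc({0})c({1})s1",                   # thiophene
    "c1ncc({0})c({1})n1",                  # pyrimidine
    "c1oc({0})cc1-c1ccc({1})cc1",          # furyl-phenyl
    "C1CC({0})c2ccccc2C1{1}",              # tetralin-like
    "c1cc2ccccc2nc1{0}",                   # quinoline (single site)
    "C1CN({0})CCC1{1}",                    # piperidine
]

# Substituent vocabulary; ring-closure digits >= 5 avoid template clashes.
SUBSTITUENTS = [
    "C", "CC", "CCC", "O", "OC", "N", "F", "Cl",
    "[N+](=O)[O-]",   # nitro: the planted structure motif
    "c5ccccc5", "c5ccncc5", "C5CCCCC5",
]

NITRO_SMARTS = Chem.MolFromSmarts("[N+](=O)[O-]")


@dataclass(frozen=True)
class BenchmarkConfig:
    n_drugs: int = 1000
    n_targets: int = 120
    n_scaffold_templates: int = 8
    ddi_communities: int = 4
    n_dti_classes: int = 4
    signal_weights: tuple[float, float, float] = (2.5, 1.5, 1.5)  # structure, dti, ddi
    label_noise: float = 0.1
    positive_rate: float = 1.0 / 3.0
    mask_fraction_dti: float = 0.1
    mask_fraction_ddi: float = 0.1
    trial_fraction: float = 0.05
    dti_p_hit: float = 0.6
    dti_p_background: float = 0.02
    ddi_p_within: float = 0.25
    ddi_p_between: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        for f in (self.mask_fraction_dti, self.mask_fraction_ddi):
            if not (0 <= f < 1):
                raise ValueError("mask fractions must be in [0, 1)")
        if self.n_scaffold_templates < 2 or self.n_scaffold_templates > len(TEMPLATES):
            raise ValueError(
                f"n_scaffold_templates must be in [2, {len(TEMPLATES)}]"
            )


@dataclass
class GroundTruth:
    """Latent generator state sufficient to compute the oracle score.

    ``dti_signal`` and ``ddi_signal`` are the graded per-drug channel
    scores the labels are sampled from: the z-scored fraction of class-0
    target-block columns hit, and the z-scored fraction of neighbours
    belonging to community 0, both computed on the full (pre-masking)
    matrices.
    """

    dti_class: dict[str, int]
    ddi_community: dict[str, int]
    motif: dict[str, bool]
    dti_signal: dict[str, float]
    ddi_signal: dict[str, float]
    oracle_score: dict[str, float]
    intercept: float
    masked_dti_ids: list[str]
    masked_ddi_ids: list[str]


@dataclass
class BenchmarkBundle:
    config: BenchmarkConfig
    catalogue: list[CatalogueEntry]
    dti: InteractionMatrix
    ddi: InteractionMatrix
    labels: dict[str, int]
    ground_truth: GroundTruth

    @property
    def molecules(self) -> list[Molecule]:
        return [e.molecule for e in self.catalogue]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic independent child seeds for the sub-generators."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def generate_molecules(
    n: int, n_templates: int, seed: int
) -> list[Molecule]:
    """Assemble *n* valid molecules from ring templates plus substituents.

    Templates are cycled round-robin, so at least ``n_templates`` distinct
    Bemis-Murcko scaffolds occur; ring-bearing substituents add further
    scaffold diversity.  Invalid assemblies (none with the shipped
    vocabulary) would be resampled up to 20 times before erroring.
    """
    if not (2 <= n_templates <= len(TEMPLATES)) or n < n_templates:
        raise ValueError("need n >= n_templates >= 2")
    rng = np.random.default_rng(seed)
    molecules = []
    for i in range(n):
        template = TEMPLATES[i % n_templates]
        n_slots = 2 if "{1}" in template else 1
        for attempt in range(20):
            subs = rng.choice(SUBSTITUENTS, size=n_slots)
            smiles = template.format(*subs)
            if Chem.MolFromSmiles(smiles) is not None:
                break
        else:
            raise RuntimeError(f"could not assemble a valid molecule from {template}")
        molecules.append(Molecule(id=f"D{i:05d}", smiles=smiles))
    return molecules


def has_motif(mol: Molecule) -> bool:
    """True when the molecule carries the planted nitro substituent."""
    return mol.to_rdkit().HasSubstructMatch(NITRO_SMARTS)


def generate_interactions(
    mols: Sequence[Molecule], config: BenchmarkConfig
) -> tuple[InteractionMatrix, InteractionMatrix, GroundTruth]:
    """Plant latent classes and sample the DTI and DDI matrices.

    DTI: each drug belongs to one of ``n_dti_classes`` classes; the class's
    own target block is hit with ``dti_p_hit``, the rest with
    ``dti_p_background``.  DDI: stochastic block model over
    ``ddi_communities`` communities (symmetric, empty diagonal).  A
    fraction of drugs is withheld from each matrix; withheld ids are
    recorded so imputation provenance can be audited downstream.
    """
    s_class, s_dti, s_ddi, s_mask = _child_seeds(config.seed, 5)[:4]
    ids = [m.id for m in mols]
    n = len(ids)
    rng_class = np.random.default_rng(s_class)
    dti_class = rng_class.integers(0, config.n_dti_classes, size=n)
    ddi_community = rng_class.integers(0, config.ddi_communities, size=n)

    rng_mask = np.random.default_rng(s_mask)
    n_mask_dti = int(round(config.mask_fraction_dti * n))
    n_mask_ddi = int(round(config.mask_fraction_ddi * n))
    masked_dti = sorted(rng_mask.choice(ids, size=n_mask_dti, replace=False).tolist())
    masked_ddi = sorted(rng_mask.choice(ids, size=n_mask_ddi, replace=False).tolist())

    # DTI
    rng_dti = np.random.default_rng(s_dti)
    block = config.n_targets // config.n_dti_classes
    target_ids = [f"T{t:04d}" for t in range(config.n_targets)]
    probs = np.full((n, config.n_targets), config.dti_p_background)
    for k, cls in enumerate(dti_class):
        lo = cls * block
        probs[k, lo : lo + block] = config.dti_p_hit
    hits = rng_dti.random((n, config.n_targets)) < probs
    row_pos = {i: k for k, i in enumerate(ids)}
    dti_rows = [i for i in ids if i not in set(masked_dti)]
    dti_entries = [
        (i, target_ids[t])
        for i in dti_rows
        for t in np.flatnonzero(hits[row_pos[i]])
    ]
    dti = from_entries(dti_rows, target_ids, dti_entries, "DTI")

    # DDI (stochastic block model over all drugs, masked rows withheld)
    rng_ddi = np.random.default_rng(s_ddi)
    same = ddi_community[:, None] == ddi_community[None, :]
    p = np.where(same, config.ddi_p_within, config.ddi_p_between)
    adj = np.triu(rng_ddi.random((n, n)) < p, k=1)
    adj = adj | adj.T
    ddi_ids = [i for i in ids if i not in set(masked_ddi)]
    keep = np.array([row_pos[i] for i in ddi_ids])
    sub = np.triu(adj[np.ix_(keep, keep)], k=1)
    ddi_entries = [(ddi_ids[a], ddi_ids[b]) for a, b in zip(*np.nonzero(sub))]
    ddi = from_entries(ddi_ids, ddi_ids, ddi_entries, "DDI")

    # graded channel scores, computed before masking
    block0 = hits[:, :block].mean(axis=1)
    dti_signal = (block0 - block0.mean()) / max(block0.std(), 1e-12)
    deg = adj.sum(axis=1)
    comm0_frac = np.where(
        deg > 0, adj[:, ddi_community == 0].sum(axis=1) / np.maximum(deg, 1), 0.0
    )
    ddi_signal = (comm0_frac - comm0_frac.mean()) / max(comm0_frac.std(), 1e-12)

    gt = GroundTruth(
        dti_class={i: int(dti_class[row_pos[i]]) for i in ids},
        ddi_community={i: int(ddi_community[row_pos[i]]) for i in ids},
        motif={m_.id: has_motif(m_) for m_ in mols},
        dti_signal={i: float(dti_signal[row_pos[i]]) for i in ids},
        ddi_signal={i: float(ddi_signal[row_pos[i]]) for i in ids},
        oracle_score={},
        intercept=0.0,
        masked_dti_ids=masked_dti,
        masked_ddi_ids=masked_ddi,
    )
    return dti, ddi, gt


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def generate_labels(
    ground_truth: GroundTruth,
    signal_weights: tuple[float, float, float],
    label_noise: float,
    seed: int,
    positive_rate: float = 1.0 / 3.0,
) -> dict[str, int]:
    """Sample binary labels from the planted logistic model.

    logit = w_structure * motif + w_dti * dti_signal + w_ddi * ddi_signal
    + intercept, where the channel signals are the graded z-scored class-0
    target-hit fraction and community-0 neighbour fraction.  The intercept
    is solved by bisection so the expected positive rate *after* noise
    flips equals ``positive_rate``.  Labels are Bernoulli draws from the
    logistic probability, then flipped with probability ``label_noise``.
    The pre-noise probabilities are stored in the ground truth as the
    oracle score.
    """
    w_s, w_dti, w_ddi = signal_weights
    ids = sorted(ground_truth.dti_class)
    raw = np.array([
        w_s * float(ground_truth.motif[i])
        + w_dti * ground_truth.dti_signal[i]
        + w_ddi * ground_truth.ddi_signal[i]
        for i in ids
    ])

    # post-noise rate is (1 - 2*noise) * mean(p) + noise
    target = (positive_rate - label_noise) / (1.0 - 2.0 * label_noise)
    target = min(max(target, 1e-6), 1 - 1e-6)
    lo, hi = -30.0, 30.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if float(np.mean(_sigmoid(raw + mid))) < target:
            lo = mid
        else:
            hi = mid
    intercept = 0.5 * (lo + hi)
    p = _sigmoid(raw + intercept)

    rng = np.random.default_rng(seed)
    labels = (rng.random(len(ids)) < p).astype(int)
    flips = rng.random(len(ids)) < label_noise
    labels = np.where(flips, 1 - labels, labels)

    ground_truth.intercept = float(intercept)
    ground_truth.oracle_score = {i: float(pi) for i, pi in zip(ids, p)}
    return {i: int(y) for i, y in zip(ids, labels)}


def make_benchmark(
    config: BenchmarkConfig, out_dir: Optional[str | Path] = None
) -> BenchmarkBundle:
    """Compose molecules, interactions, labels and catalogue flags.

    Catalogue flags: every drug is approved; positives carry the
    known-anticancer flag; a ``trial_fraction`` of the remaining drugs is
    flagged as examined in a cancer trial.  When ``out_dir`` is given, all
    artifacts are written in the pipeline's standard text formats.
    """
    seeds = _child_seeds(config.seed, 5)
    mols = generate_molecules(config.n_drugs, config.n_scaffold_templates, seeds[4])
    dti, ddi, gt = generate_interactions(mols, config)
    labels = generate_labels(
        gt, config.signal_weights, config.label_noise, seeds[3],
        positive_rate=config.positive_rate,
    )

    rng = np.random.default_rng(seeds[2])
    negatives = [m.id for m in mols if labels[m.id] == 0]
    n_trial = int(round(config.trial_fraction * len(negatives)))
    trial_ids = set(rng.choice(negatives, size=n_trial, replace=False).tolist())
    catalogue = [
        CatalogueEntry(
            molecule=m,
            approved=True,
            in_cancer_trial=m.id in trial_ids,
            known_anticancer=labels[m.id] == 1,
        )
        for m in mols
    ]
    bundle = BenchmarkBundle(
        config=config, catalogue=catalogue, dti=dti, ddi=ddi,
        labels=labels, ground_truth=gt,
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: BenchmarkBundle, out_dir: Path) -> None:
    from . import io as oio

    out_dir.mkdir(parents=True, exist_ok=True)
    oio.write_catalogue(bundle.catalogue, out_dir / "catalogue.csv")
    write_triplets(bundle.dti, out_dir / "dti.tsv")
    write_triplets(bundle.ddi, out_dir / "ddi.tsv")
    oio.write_labels(bundle.labels, out_dir / "labels.csv")
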