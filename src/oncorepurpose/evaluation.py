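"""Scaffold-based splitting, the five-metric suite, and feature ablation.

Molecules sharing a Bemis-Murcko scaffold never span partitions, so the
test set measures generalization to unseen chemotypes.  The "balanced"
variant additionally steers each partition's class ratio toward the
dataset's overall ratio.  Metrics: ROC AUC (ties half-credit), AUPR
(step-wise summation, i.e. average precision), accuracy, Cohen's kappa and
Matthews correlation at a fixed threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    cohen_kappa_score,
    matthews_corrcoef,
    roc_auc_score,
)

from .chem import bemis_murcko_scaffold
from .curation import LabeledDataset
from .features import AuxiliaryFeatures
from .models import ModelConfig, train_ensemble, predict

logger = logging.getLogger(__name__)

DEFAULT_FRACTIONS = (0.8, 0.1, 0.1)
PARTITIONS = ("train", "validation", "test")


class InfeasibleSplitError(ValueError):
    pass


class UndefinedMetricError(ValueError):
    pass


@dataclass
class SplitPlan:
    assignment: dict[str, str]      # id -> train | validation | test
    fractions: tuple[float, float, float]
    seed: int
    scaffold_of: dict[str, str]

    def ids(self, partition: str) -> list[str]:
        return sorted(i for i, p in self.assignment.items() if p == partition)

    def subset(self, dataset: LabeledDataset, partition: str) -> LabeledDataset:
        keep = set(self.ids(partition))
        mols = [m for m in dataset.molecules if m.id in keep]
        return LabeledDataset(
            molecules=mols,
            labels={i: dataset.labels[i] for i in keep},
            provenance={i: dataset.provenance[i] for i in keep},
        )


@dataclass
class MetricReport:
    auc: float
    aupr: float
    accuracy: float
    kappa: float
    mcc: float
    n_pos: int
    n_neg: int
    threshold: float


@dataclass
class AblationReport:
    rows: dict[str, MetricReport]          # variant name -> mean over repeats
    raw: dict[str, list[MetricReport]]     # variant name -> per-repeat reports
    n_repeats: int


def scaffold_split(
    dataset: LabeledDataset,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
    balanced: bool = True,
) -> SplitPlan:
    """Assign whole scaffold groups to train/validation/test.

    Groups larger than half the target test size are forced into train
    (demoted back to the greedy pool when too few groups would remain to
    populate validation and test).  The remaining groups are visited in
    seeded shuffled order; a group is placed in validation or test only if
    it fits under that partition's target size, otherwise it goes to
    train.  When ``balanced``, ties between validation and test are
    resolved toward the partition whose class ratio moves closest to the
    dataset's overall positive rate.

    An unfillable test partition raises ``InfeasibleSplitError``; an empty
    validation partition is tolerated with a warning (it can be genuinely
    impossible with few scaffold groups).
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions) or abs(sum(fractions) - 1) > 1e-9:
        raise ValueError("fractions must be three positive reals summing to 1")
    ids = sorted(dataset.labels)
    n = len(ids)
    scaffold_of = {m.id: bemis_murcko_scaffold(m) for m in dataset.molecules}
    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(scaffold_of[i], []).append(i)
    if len(groups) < 2:
        only = max(groups, key=lambda s: len(groups[s]), default="")
        raise InfeasibleSplitError(
            f"dataset has fewer than 2 scaffold groups (blocking scaffold {only!r})"
        )

    target = {
        "validation": int(round(fractions[1] * n)),
        "test": int(round(fractions[2] * n)),
    }
    overall_pos = dataset.n_pos / n

    group_list = sorted(groups.values(), key=lambda g: g[0])
    big = sorted(
        (g for g in group_list if len(g) > target["test"] / 2), key=len
    )
    small = [g for g in group_list if len(g) <= target["test"] / 2]
    while len(small) < 2 and big:
        small.append(big.pop(0))  # demote the smallest forced groups
    rng = np.random.default_rng(seed)
    rng.shuffle(small)

    assignment: dict[str, str] = {}
    size = {"train": 0, "validation": 0, "test": 0}
    pos = {"train": 0, "validation": 0, "test": 0}

    def place(group: list[str], part: str) -> None:
        for i in group:
            assignment[i] = part
        size[part] += len(group)
        pos[part] += sum(dataset.labels[i] for i in group)

    for g in big:
        place(g, "train")

    pool = list(small)
    for part in ("test", "validation"):
        while size[part] < target[part] and pool:
            fits = [g for g in pool if size[part] + len(g) <= target[part]]
            if not fits:
                break
            if balanced:
                g_best = min(
                    fits,
                    key=lambda g: abs(
                        (pos[part] + sum(dataset.labels[i] for i in g))
                        / (size[part] + len(g))
                        - overall_pos
                    ),
                )
            else:
                g_best = fits[0]  # seeded shuffled order
            pool.remove(g_best)
            place(g_best, part)
    for g in pool:
        place(g, "train")

    if size["test"] == 0:
        blocking = max(groups, key=lambda s: len(groups[s]))
        raise InfeasibleSplitError(
            f"cannot fill test partition (blocking scaffold {blocking!r})"
        )
    if size["validation"] == 0:
        logger.warning("validation partition is empty (scaffold groups too coarse)")
    return SplitPlan(
        assignment=assignment,
        fractions=tuple(fractions),
        seed=seed,
        scaffold_of=scaffold_of,
    )


def compute_metrics(
    labels: Mapping[str, int],
    scores: Mapping[str, float],
    threshold: float = 0.5,
    threshold_scores: Optional[Mapping[str, float]] = None,
) -> MetricReport:
    """AUC/AUPR from continuous scores; accuracy, kappa and MCC from the
    confusion matrix at ``threshold``.

    AUC uses pairwise concordance with half credit for ties; AUPR is
    step-wise (non-interpolated) precision-recall summation.  MCC is 0 by
    convention when any confusion-matrix margin is empty.
    ``threshold_scores`` optionally supplies a separate calibrated score for
    the confusion matrix (used for SVM margins, which are not on [0, 1]).
    """
    if set(labels) != set(scores):
        raise ValueError("labels and scores must cover identical ids")
    ids = sorted(labels)
    y = np.array([labels[i] for i in ids])
    s = np.array([scores[i] for i in ids], dtype=float)
    ts = (
        np.array([threshold_scores[i] for i in ids], dtype=float)
        if threshold_scores is not None
        else s
    )
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("both classes required to compute AUC")
    pred = (ts >= threshold).astype(int)
    return MetricReport(
        auc=float(roc_auc_score(y, s)),
        aupr=float(average_precision_score(y, s)),
        accuracy=float(accuracy_score(y, pred)),
        kappa=float(cohen_kappa_score(y, pred)),
        mcc=float(matthews_corrcoef(y, pred)),
        n_pos=n_pos,
        n_neg=n_neg,
        threshold=threshold,
    )


def _mean_report(reports: Sequence[MetricReport]) -> MetricReport:
    return MetricReport(
        auc=float(np.mean([r.auc for r in reports])),
        aupr=float(np.mean([r.aupr for r in reports])),
        accuracy=float(np.mean([r.accuracy for r in reports])),
        kappa=float(np.mean([r.kappa for r in reports])),
        mcc=float(np.mean([r.mcc for r in reports])),
        n_pos=reports[0].n_pos,
        n_neg=reports[0].n_neg,
        threshold=reports[0].threshold,
    )


def run_ablation(
    dataset: LabeledDataset,
    features: Optional[Mapping[str, AuxiliaryFeatures]],
    variants: Mapping[str, ModelConfig],
    n_repeats: int = 3,
    base_seed: int = 0,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    n_members: int = 2,
    balanced: bool = True,
) -> AblationReport:
    """Repeated scaffold-split evaluation of several model variants.

    Repeat r uses one scaffold split with seed ``base_seed + r`` shared by
    all variants; each variant's ensemble is trained on the train partition
    and scored on the test partition.  Rows are per-variant means over
    repeats; raw per-repeat reports are retained.
    """
    raw: dict[str, list[MetricReport]] = {name: [] for name in variants}
    for r in range(n_repeats):
        plan = scaffold_split(dataset, fractions, seed=base_seed + r, balanced=balanced)
        train = plan.subset(dataset, "train")
        test = plan.subset(dataset, "test")
        test_labels = dict(test.labels)
        for name, config in variants.items():
            ensemble = train_ensemble(train, features, config, n_members=n_members)
            preds = predict(ensemble, test.molecules, features)
            threshold_scores = None
            if config.variant == "svm_fingerprint":
                threshold_scores = predict(
                    ensemble, test.molecules, features, calibrated=True
                ).scores
            report = compute_metrics(
                test_labels, preds.scores, threshold_scores=threshold_scores
            )
            raw[name].append(report)
            logger.info("repeat %d, variant %s: AUC %.3f", r, name, report.auc)
    rows = {name: _mean_report(reports) for name, reports in raw.items()}
    return AblationReport(rows=rows, raw=raw, n_repeats=n_repeats)
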