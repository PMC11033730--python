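import numpy as np
import pytest

from oncorepurpose.chem import bemis_murcko_scaffold
from oncorepurpose.curation import LabeledDataset
from oncorepurpose.evaluation import (
    InfeasibleSplitError,
    UndefinedMetricError,
    compute_metrics,
    run_ablation,
    scaffold_split,
)
from oncorepurpose.models import ModelConfig
from oncorepurpose.synthetic import generate_molecules


# --- independent metric oracles -------------------------------------------

def oracle_auc(y, s):
    """Pairwise concordance with half credit for ties."""
    pos = [si for si, yi in zip(s, y) if yi == 1]
    neg = [si for si, yi in zip(s, y) if yi == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def oracle_aupr(y, s):
    """Step-wise summation over the full threshold sweep (average precision)."""
    order = sorted(range(len(s)), key=lambda i: (-s[i], i))
    n_pos = sum(y)
    tp = fp = 0
    auc = 0.0
    prev_recall = 0.0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and s[order[j]] == s[order[i]]:
            j += 1
        for k in range(i, j):  # ties enter together
            if y[order[k]] == 1:
                tp += 1
            else:
                fp += 1
        precision = tp / (tp + fp)
        recall = tp / n_pos
        auc += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return auc


def oracle_confusion(y, s, threshold=0.5):
    tp = sum(1 for yi, si in zip(y, s) if yi == 1 and si >= threshold)
    fp = sum(1 for yi, si in zip(y, s) if yi == 0 and si >= threshold)
    fn = sum(1 for yi, si in zip(y, s) if yi == 1 and si < threshold)
    tn = sum(1 for yi, si in zip(y, s) if yi == 0 and si < threshold)
    return tp, fp, tn, fn


def oracle_mcc(tp, fp, tn, fn):
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    return 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)


def oracle_kappa(tp, fp, tn, fn):
    n = tp + fp + tn + fn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n**2
    return 0.0 if pe == 1 else (po - pe) / (1 - pe)


def _as_maps(y, s):
    ids = [f"m{i}" for i in range(len(y))]
    return dict(zip(ids, y)), dict(zip(ids, s))


class TestComputeMetrics:
    def test_perfect_separation(self):
        labels, scores = _as_maps([1, 1, 0, 0], [0.9, 0.8, 0.4, 0.1])
        r = compute_metrics(labels, scores)
        assert r.auc == 1.0 and r.aupr == 1.0

    def test_interleaved_scores_match_pair_count(self):
        # pos-neg pairs: .9>.8, .9>.2, .3>.2 concordant; .3<.8 discordant
        labels, scores = _as_maps([1, 0, 1, 0], [0.9, 0.8, 0.3, 0.2])
        assert compute_metrics(labels, scores).auc == 0.75

    def test_hand_evaluated_confusion_formulas(self):
        # TP=2 FP=1 TN=2 FN=0: MCC = 4/sqrt(36), kappa = (0.8-0.48)/0.52
        labels, scores = _as_maps([1, 1, 0, 0, 0], [0.9, 0.8, 0.7, 0.3, 0.2])
        r = compute_metrics(labels, scores, threshold=0.5)
        assert r.mcc == pytest.approx(4 / 6, abs=1e-10)
        assert r.kappa == pytest.approx((0.8 - 0.48) / 0.52, abs=1e-10)
        assert r.accuracy == pytest.approx(0.8)

    def test_single_class_rejected(self):
        labels, scores = _as_maps([1, 1], [0.5, 0.6])
        with pytest.raises(UndefinedMetricError):
            compute_metrics(labels, scores)

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics({"a": 1, "b": 0}, {"a": 0.5, "c": 0.2})

    def test_agrees_with_brute_force_oracles(self, rng):
        """All five metrics vs exhaustive oracles, 200 random instances."""
        for _ in range(200):
            n = int(rng.integers(4, 51))
            y = rng.integers(0, 2, size=n).tolist()
            if sum(y) in (0, n):
                y[0] = 1 - y[0]
            # mix continuous scores with deliberate ties
            s = np.round(rng.random(n), 1).tolist()
            labels, scores = _as_maps(y, s)
            r = compute_metrics(labels, scores)
            # dict ordering differs from list ordering; rebuild aligned lists
            ids = sorted(labels)
            ya = [labels[i] for i in ids]
            sa = [scores[i] for i in ids]
            tp, fp, tn, fn = oracle_confusion(ya, sa)
            assert r.auc == pytest.approx(oracle_auc(ya, sa), abs=1e-10)
            assert r.aupr == pytest.approx(oracle_aupr(ya, sa), abs=1e-10)
            assert r.accuracy == pytest.approx((tp + tn) / n, abs=1e-10)
            assert r.mcc == pytest.approx(oracle_mcc(tp, fp, tn, fn), abs=1e-10)
            assert r.kappa == pytest.approx(oracle_kappa(tp, fp, tn, fn), abs=1e-10)

    def test_permutation_invariance(self, rng):
        y = rng.integers(0, 2, size=30)
        y[0], y[1] = 0, 1
        s = rng.random(30)
        base = None
        for _ in range(50):
            perm = rng.permutation(30)
            labels = {f"m{i}": int(y[i]) for i in perm}
            scores = {f"m{i}": float(s[i]) for i in perm}
            r = compute_metrics(labels, scores)
            key = (r.auc, r.aupr, r.accuracy, r.kappa, r.mcc)
            base = base or key
            assert key == base

    def test_auc_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        s = rng.random(40)
        labels = {f"m{i}": int(y[i]) for i in range(40)}
        r1 = compute_metrics(labels, {f"m{i}": float(s[i]) for i in range(40)})
        r2 = compute_metrics(labels, {f"m{i}": float(np.exp(3 * s[i])) for i in range(40)})
        assert r1.auc == r2.auc and r1.aupr == r2.aupr


def _dataset(n=500, seed=0, positive_rate=0.35):
    mols = generate_molecules(n, 8, seed=seed)
    rng = np.random.default_rng(seed + 1000)  # decouple labels from structures
    labels = {m.id: int(rng.random() < positive_rate) for m in mols}
    ids = list(labels)
    labels[ids[0]], labels[ids[1]] = 0, 1
    return LabeledDataset(molecules=mols, labels=labels,
                          provenance={m.id: "x" for m in mols})


class TestScaffoldSplit:
    def test_unique_scaffolds_give_exact_fractions(self):
        # one molecule per scaffold: 100 distinct alkane chain lengths would
        # all share the empty scaffold, so use distinct ring assemblies
        mols = generate_molecules(400, 8, seed=12)
        seen, unique = set(), []
        for m in mols:
            s = bemis_murcko_scaffold(m)
            if s not in seen:
                seen.add(s)
                unique.append(m)
        unique = unique[:60]
        assert len(unique) == 60
        ds = LabeledDataset(
            molecules=unique,
            labels={m.id: i % 2 for i, m in enumerate(unique)},
            provenance={m.id: "x" for m in unique},
        )
        plan = scaffold_split(ds, (0.8, 0.1, 0.1), seed=0, balanced=False)
        sizes = {p: len(plan.ids(p)) for p in ("train", "validation", "test")}
        assert sizes == {"train": 48, "validation": 6, "test": 6}

    def test_large_group_forced_into_train(self):
        from oncorepurpose.chem import Molecule

        benzenes = [f"CC{'C' * i}c1ccccc1" for i in range(90)]
        pyridines = [f"CC{'C' * i}c1ccncc1" for i in range(10)]
        mols = [Molecule(f"b{i}", s) for i, s in enumerate(benzenes)] + \
               [Molecule(f"p{i}", s) for i, s in enumerate(pyridines)]
        ds = LabeledDataset(molecules=mols,
                            labels={m.id: i % 2 for i, m in enumerate(mols)},
                            provenance={m.id: "x" for m in mols})
        plan = scaffold_split(ds, (0.8, 0.1, 0.1), seed=0)
        big_ids = [m.id for m in mols if m.id.startswith("b")]
        assert all(plan.assignment[i] == "train" for i in big_ids)

    def test_partition_audit_on_synthetic_dataset(self):
        """Zero scaffold overlap, sizes near fractions, balanced class ratio."""
        ds = _dataset(n=500, seed=20)
        n = 500
        overall = ds.n_pos / n
        for seed in (0, 1, 2):
            plan = scaffold_split(ds, (0.8, 0.1, 0.1), seed=seed, balanced=True)
            parts = {p: plan.ids(p) for p in ("train", "validation", "test")}
            assert sum(len(v) for v in parts.values()) == n
            scaffold_sets = {
                p: {plan.scaffold_of[i] for i in ids} for p, ids in parts.items()
            }
            assert not scaffold_sets["train"] & scaffold_sets["test"]
            assert not scaffold_sets["train"] & scaffold_sets["validation"]
            assert not scaffold_sets["validation"] & scaffold_sets["test"]
            for p, frac in zip(("train", "validation", "test"), (0.8, 0.1, 0.1)):
                assert abs(len(parts[p]) / n - frac) <= 0.02
            test_ratio = np.mean([ds.labels[i] for i in parts["test"]])
            assert abs(test_ratio - overall) <= 0.05

    def test_single_scaffold_dataset_rejected(self):
        from oncorepurpose.chem import Molecule

        mols = [Molecule(f"m{i}", "C" * (i + 2)) for i in range(10)]  # all acyclic
        ds = LabeledDataset(molecules=mols,
                            labels={m.id: i % 2 for i, m in enumerate(mols)},
                            provenance={m.id: "x" for m in mols})
        with pytest.raises(InfeasibleSplitError):
            scaffold_split(ds, (0.8, 0.1, 0.1), seed=0)

    def test_bad_fractions_rejected(self):
        ds = _dataset(n=50, seed=1)
        with pytest.raises(ValueError):
            scaffold_split(ds, (0.5, 0.2, 0.2), seed=0)


class TestRunAblation:
    def test_single_variant_single_repeat_is_plain_report(self):
        ds = _dataset(n=150, seed=30)
        config = ModelConfig(hidden_dim=16, message_depth=2, epochs=2, seed=0)
        rep = run_ablation(ds, None, {"only": config}, n_repeats=1,
                           base_seed=5, n_members=1)
        assert rep.rows["only"] == rep.raw["only"][0]

    def test_duplicate_variants_identical_rows(self):
        ds = _dataset(n=150, seed=30)
        config = ModelConfig(hidden_dim=16, message_depth=2, epochs=2, seed=0)
        rep = run_ablation(ds, None, {"a": config, "b": config}, n_repeats=1,
                           base_seed=5, n_members=1)
        assert rep.rows["a"] == rep.rows["b"]

    def test_mean_rows_are_arithmetic_means(self):
        ds = _dataset(n=200, seed=31)
        config = ModelConfig(hidden_dim=16, message_depth=2, epochs=2, seed=0)
        rep = run_ablation(ds, None, {"m": config}, n_repeats=3,
                           base_seed=1, n_members=1)
        assert rep.rows["m"].auc == pytest.approx(
            np.mean([r.auc for r in rep.raw["m"]]), abs=1e-10
        )
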