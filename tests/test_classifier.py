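import numpy as np
import pytest

from upna_ppi import (ClassifierSpec, ConfigurationError, EmbeddingTable,
                      PairClassifier, ProteinSequence, build_pair_dataset,
                      canonical_pair, crossvalidate, make_inductive_split,
                      train_classifier)
from upna_ppi.classifier import assert_inductive_purity
from upna_ppi.evaluation import roc_pr


class TestInductiveSplit:
    def test_floor_sizes_remainder_to_train(self):
        prots = [f"p{i}" for i in range(10)]
        split = make_inductive_split(prots, (0.8, 0.1, 0.1), seed=0)
        sizes = {g: sum(1 for v in split.values() if v == g)
                 for g in ("train", "val", "test")}
        assert sizes == {"train": 8, "val": 1, "test": 1}

    def test_pinned_never_in_train(self):
        prots = [f"p{i}" for i in range(20)]
        for seed in range(10):
            split = make_inductive_split(prots, (0.6, 0.2, 0.2),
                                         pinned_eval=["p3"], seed=seed)
            assert split["p3"] in ("val", "test")

    def test_determinism(self):
        prots = [f"p{i}" for i in range(30)]
        a = make_inductive_split(prots, (0.6, 0.2, 0.2), seed=7)
        b = make_inductive_split(prots, (0.6, 0.2, 0.2), seed=7)
        assert a == b

    def test_empty_train_rejected(self):
        with pytest.raises(ConfigurationError):
            make_inductive_split(["a", "b"], (0.0, 0.5, 0.5), seed=0)


class TestBuildPairDataset:
    def test_cross_group_pairs_dropped_and_counted(self):
        split = {"a": "train", "b": "test", "c": "train"}
        data = build_pair_dataset([("a", "b")], [("a", "c")], split)
        assert data.n_dropped == 1
        assert data.pairs == [("a", "c", 0, "tppni")]

    def test_within_group_retained_with_counts(self):
        split = {x: "train" for x in "abcd"}
        data = build_pair_dataset([("a", "b"), ("c", "d")], [("a", "c")], split)
        assert data.counts()["train"] == {0: 1, 1: 2}

    def test_unknown_protein_raises(self):
        with pytest.raises(KeyError):
            build_pair_dataset([("a", "zzz")], [], {"a": "train"})


def _separable_problem(n_prot=60, seed=0):
    """Tiny linearly separable task: type-X binds type-Y, nothing else.

    Sequences are homopolymer-ish so the pooled embedding cleanly encodes
    the type letter.
    """
    rng = np.random.default_rng(seed)
    letters = {"X": "AAAAAAAA", "Y": "CCCCCCCC", "Z": "DDDDDDDD"}
    kinds = rng.choice(["X", "Y", "Z"], size=n_prot)
    seqs = {f"p{i:02d}": ProteinSequence(f"p{i:02d}", letters[k])
            for i, k in enumerate(kinds)}
    kind_of = {f"p{i:02d}": k for i, k in enumerate(kinds)}
    vec = {"AAA": [3.0, 0.0, 0.1], "CCC": [0.0, 3.0, -0.1], "DDD": [1.5, 1.5, 0.0]}
    rng2 = np.random.default_rng(1)
    vectors = {}
    import itertools
    for t in ("".join(x) for x in itertools.product("ACD", repeat=3)):
        vectors[t] = vec.get(t, rng2.normal(size=3) * 0.05)
    table = EmbeddingTable.from_vectors(vectors)
    ids = sorted(seqs)
    pos, neg = [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            if {kind_of[a], kind_of[b]} == {"X", "Y"}:
                pos.append((a, b))
            else:
                neg.append((a, b))
    rng3 = np.random.default_rng(2)
    neg = [neg[i] for i in rng3.choice(len(neg), size=len(pos), replace=False)]
    return seqs, table, pos, neg


SMALL_SPEC = dict(hidden=(32, 16, 8), batch_size=64, pca_components=None)


class TestTraining:
    def test_learns_separable_rule(self):
        seqs, table, pos, neg = _separable_problem()
        split = make_inductive_split(sorted(seqs), (0.6, 0.2, 0.2), seed=0)
        data = build_pair_dataset(pos, neg, split)
        res = train_classifier(data, seqs, table, ClassifierSpec(seed=0, **SMALL_SPEC))
        # training loss decreases over the first epochs
        tl = res.history["train_loss"]
        assert tl[min(4, len(tl) - 1)] < tl[0]
        val = data.pairs_in("val")
        preds = res.predict_pairs([(a, b) for a, b, _y, _s in val])
        correct = sum((preds[(a, b)] >= 0.5) == y for a, b, y, _s in val)
        assert correct / len(val) > 0.95

    def test_shuffled_labels_give_chance_auroc(self):
        seqs, table, pos, neg = _separable_problem()
        rng = np.random.default_rng(3)
        pairs = pos + neg
        labels = np.array([1] * len(pos) + [0] * len(neg))
        labels = labels[rng.permutation(len(labels))]
        pos_s = [p for p, y in zip(pairs, labels) if y == 1]
        neg_s = [p for p, y in zip(pairs, labels) if y == 0]
        split = make_inductive_split(sorted(seqs), (0.6, 0.2, 0.2), seed=1)
        data = build_pair_dataset(pos_s, neg_s, split)
        res = train_classifier(data, seqs, table, ClassifierSpec(seed=1, **SMALL_SPEC))
        te = data.pairs_in("test")
        preds = res.predict_pairs([(a, b) for a, b, _y, _s in te])
        lab = {canonical_pair(a, b): y for a, b, y, _s in te}
        auroc, _ = roc_pr(preds, lab)
        assert 0.25 <= auroc <= 0.75  # chance up to small-sample noise

    def test_patience_zero_stops_one_epoch_after_non_improvement(self):
        seqs, table, pos, neg = _separable_problem()
        split = make_inductive_split(sorted(seqs), (0.6, 0.2, 0.2), seed=0)
        data = build_pair_dataset(pos, neg, split)
        res = train_classifier(data, seqs, table,
                               ClassifierSpec(seed=0, patience=0, **SMALL_SPEC))
        h = res.history
        vl = h["val_loss"]
        if h["n_epochs"] < 200:  # stopped early
            # every epoch before the last improved on the best-so-far
            best = np.inf
            for v in vl[:-1]:
                assert v < best
                best = v
            assert vl[-1] >= best

    def test_single_class_training_rejected(self):
        seqs, table, pos, neg = _separable_problem()
        split = make_inductive_split(sorted(seqs), (0.6, 0.2, 0.2), seed=0)
        data = build_pair_dataset(pos, [], split)
        with pytest.raises(ConfigurationError):
            train_classifier(data, seqs, table, ClassifierSpec(seed=0, **SMALL_SPEC))


class TestPrediction:
    def test_order_symmetry_exact(self, trained0, fixture0):
        res = trained0["results"]
        pairs = list(trained0["preds"])[:5]
        for a, b in pairs:
            pab = res.predict_pairs([(a, b)])[(a, b)]
            pba = res.predict_pairs([(b, a)])[(a, b)]
            assert pab == pba

    def test_probabilities_in_range(self, trained0):
        assert all(0.0 <= p <= 1.0 for p in trained0["preds"].probs.values())

    def test_missing_sequence_raises(self, trained0):
        with pytest.raises(KeyError, match="unknownprot"):
            trained0["results"].predict_pairs([("unknownprot", "P0001")])

    def test_inductive_purity(self, trained0):
        assert_inductive_purity(trained0["data"])

    def test_save_load_round_trip(self, trained0, tmp_path):
        from upna_ppi.classifier import PairClassifierResults

        res = trained0["results"]
        path = tmp_path / "fold.joblib"
        res.save(path)
        res2 = PairClassifierResults.load(path)
        pairs = list(trained0["preds"])[:4]
        x = np.stack([np.concatenate([res.embeddings[a], res.embeddings[b]])
                      for a, b in pairs])
        np.testing.assert_allclose(res2.predict_proba_matrix(x),
                                   res.predict_proba_matrix(x))


class TestCrossvalidate:
    def test_fold_structure_and_determinism(self):
        seqs, table, pos, neg = _separable_problem(n_prot=40)
        spec = ClassifierSpec(seed=0, **SMALL_SPEC)
        out1 = crossvalidate(pos, neg, seqs, table, spec, k=2, seeds=[5, 6])
        out2 = crossvalidate(pos, neg, seqs, table, spec, k=2, seeds=[5, 6])
        assert len(out1) == 2
        splits1 = [o[3].dataset.split for o in out1]
        splits2 = [o[3].dataset.split for o in out2]
        assert splits1 == splits2
        # per-fold test protein groups come from independent re-draws
        t0 = {p for p, g in splits1[0].items() if g == "test"}
        t1 = {p for p, g in splits1[1].items() if g == "test"}
        assert t0 != t1

    def test_k_below_two_rejected(self):
        seqs, table, pos, neg = _separable_problem(n_prot=30)
        with pytest.raises(ValueError):
            crossvalidate(pos, neg, seqs, table, None, k=1)


def test_spec_requires_three_hidden_layers():
    with pytest.raises(ValueError):
        ClassifierSpec(hidden=(64, 32))
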