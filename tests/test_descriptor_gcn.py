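"""Descriptor GCN: splitting, forward pass, metrics, training, embeddings."""

import itertools

import numpy as np
import pytest
from rdkit import Chem

from odortl._nn import EarlyStopper
from odortl.chemio import DescriptorVocabulary, parse_smiles, to_molecular_graph
from odortl.descriptor_gcn import (
    DescriptorDataset,
    GCNConfig,
    GCNModel,
    auc_prc,
    embedding_matrix,
    extract_embeddings,
    f1,
    gcn_forward,
    split_dataset,
    train_gcn,
)

VOCAB3 = DescriptorVocabulary(("fruity", "floral", "green"))


def average_precision_bruteforce(y, s):
    """Threshold-enumeration PR area: sum over descending unique score
    thresholds of (recall step) x precision."""
    y = np.asarray(y)
    s = np.asarray(s)
    total_pos = int(y.sum())
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(s), reverse=True):
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        precision = tp / (tp + fp)
        recall = tp / total_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestSplitDataset:
    def test_exact_fraction_sizes(self):
        parts = split_dataset(list(range(10)), (0.6, 0.2, 0.2), seed=0)
        assert tuple(len(p) for p in parts) == (6, 2, 2)

    def test_deterministic_given_seed(self):
        a = split_dataset(list(range(50)), seed=3)
        b = split_dataset(list(range(50)), seed=3)
        assert a == b
        assert a != split_dataset(list(range(50)), seed=4)

    def test_partition_property_at_database_scale(self):
        items = list(range(273))
        train, val, test = split_dataset(items, (0.6, 0.2, 0.2), seed=1)
        assert len(train) in (163, 164)
        assert len(val) in (54, 55)
        assert len(test) in (54, 55)
        assert set(train) | set(val) | set(test) == set(items)
        assert not (set(train) & set(val) or set(train) & set(test) or set(val) & set(test))

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(list(range(10)), (0.6, 0.2, 0.1), seed=0)


class TestForward:
    def test_probabilities_in_unit_interval(self, fixture_graphs):
        model = GCNModel(GCNConfig(seed=0), VOCAB3)
        probs = gcn_forward(fixture_graphs, model)
        assert probs.shape == (len(fixture_graphs), 3)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_atom_permutation_leaves_output_unchanged(self, fixture_rows):
        model = GCNModel(GCNConfig(seed=1), VOCAB3)
        rng = np.random.default_rng(5)
        for row in fixture_rows:
            mol = row.molecule.to_mol()
            ref = gcn_forward([to_molecular_graph(mol)], model)
            for _ in range(10):
                perm = rng.permutation(mol.GetNumAtoms()).tolist()
                sm = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)
                out = gcn_forward([to_molecular_graph(parse_smiles(sm))], model)
                assert np.max(np.abs(out - ref)) < 1e-5

    def test_zeroed_output_layer_gives_half_probability(self, fixture_graphs):
        model = GCNModel(GCNConfig(seed=0), VOCAB3)
        model.params["out_W"][...] = 0.0
        model.params["out_b"][...] = 0.0
        probs = gcn_forward(fixture_graphs[:3], model)
        assert np.allclose(probs, 0.5)

    def test_feature_schema_mismatch_raises(self):
        model = GCNModel(GCNConfig(seed=0), VOCAB3)
        g = to_molecular_graph(parse_smiles("CCO"))
        bad = type(g)(node_features=g.node_features[:, :4], edges=g.edges, n_atoms=g.n_atoms)
        with pytest.raises(ValueError, match="schema"):
            gcn_forward([bad], model)

    def test_empty_batch_rejected(self):
        model = GCNModel(GCNConfig(seed=0), VOCAB3)
        with pytest.raises(ValueError):
            gcn_forward([], model)


class TestAucPrc:
    def test_perfect_ranking_scores_one(self):
        y = np.array([[1], [1], [0], [0]])
        s = np.array([[0.9], [0.8], [0.2], [0.1]])
        assert auc_prc(y, s) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # thresholds 0.9/0.8/0.7/0.1 -> precision at the two recall steps: 1 and 2/3
        y = np.array([1, 0, 1, 0]).reshape(-1, 1)
        s = np.array([0.9, 0.8, 0.7, 0.1]).reshape(-1, 1)
        assert auc_prc(y, s) == pytest.approx(0.5 * (1 + 2 / 3))

    def test_constant_scores_give_prevalence(self):
        y = np.array([1, 0, 0, 1, 0]).reshape(-1, 1)
        s = np.full((5, 1), 0.4)
        assert auc_prc(y, s) == pytest.approx(0.4)

    def test_degenerate_label_skipped_with_warning(self):
        y = np.array([[1, 1], [0, 1], [1, 1]])
        s = np.array([[0.9, 0.5], [0.1, 0.5], [0.8, 0.5]])
        with pytest.warns(UserWarning, match="degenerate"):
            val = auc_prc(y, s)
        assert val == pytest.approx(1.0)  # only the informative label counts

    def test_all_labels_degenerate_is_an_error(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                auc_prc(np.ones((3, 2)), np.random.default_rng(0).random((3, 2)))

    def test_matches_bruteforce_on_all_small_instances(self, rng):
        """Exhaustive check against threshold enumeration for every binary
        matrix up to 4x3 (degenerate columns excluded on both routes)."""
        for n, m in [(4, 3), (3, 2), (2, 1), (4, 1)]:
            scores = rng.random((n, m))
            for bits in itertools.product([0, 1], repeat=n * m):
                y = np.array(bits).reshape(n, m)
                valid = [j for j in range(m) if 0 < y[:, j].sum() < n]
                if not valid:
                    continue
                expected = np.mean(
                    [average_precision_bruteforce(y[:, j], scores[:, j]) for j in valid]
                )
                if len(valid) < m:
                    with pytest.warns(UserWarning):
                        got = auc_prc(y, scores)
                else:
                    got = auc_prc(y, scores)
                assert got == pytest.approx(expected, abs=1e-12)


class TestF1:
    def test_perfect_predictions(self):
        y = np.array([[1, 0], [0, 1]])
        assert f1(y, y.astype(float)) == pytest.approx(1.0)

    def test_balanced_errors_give_half(self):
        # TP=1, FP=1, FN=1 -> precision = recall = 0.5
        y = np.array([1, 1, 0, 0])
        p = np.array([0.9, 0.1, 0.9, 0.1])
        assert f1(y, p) == pytest.approx(0.5)

    def test_no_positives_anywhere_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert f1(np.zeros((2, 2)), np.zeros((2, 2))) == 0.0

    def test_all_probabilities_zero_with_true_positives(self):
        assert f1(np.array([1, 0, 1]), np.zeros(3)) == 0.0

    def test_matches_bruteforce_micro_f1_on_small_instances(self, rng):
        for _ in range(50):
            y = rng.integers(0, 2, size=(4, 3))
            p = rng.random((4, 3))
            pred = (p >= 0.5).astype(int)
            tp = int(((pred == 1) & (y == 1)).sum())
            fp = int(((pred == 1) & (y == 0)).sum())
            fn = int(((pred == 0) & (y == 1)).sum())
            if tp + fp + fn == 0:
                continue
            expected = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
            assert f1(y, p) == pytest.approx(expected)


class TestEarlyStopping:
    def test_worsening_loss_stops_after_patience_plus_one_epochs(self):
        stopper = EarlyStopper(patience=30)
        epochs = 0
        for epoch, loss in enumerate(np.arange(1.0, 100.0)):
            epochs += 1
            if stopper.update(epoch, float(loss)):
                break
        assert epochs == 31
        assert stopper.best_epoch == 0

    def test_best_epoch_tracks_minimum(self):
        stopper = EarlyStopper(patience=5)
        losses = [3.0, 2.0, 2.5, 1.0, 1.5, 1.6, 1.7, 1.8, 1.9]
        for e, l in enumerate(losses):
            stopped = stopper.update(e, l)
        assert stopper.best_epoch == 3
        assert stopped  # 5 epochs without improvement after the minimum


class TestTraining:
    def test_substructure_label_is_learnable(self, trained_gcn_setup):
        """Noise-free 'fruity' = ester-presence must be nearly perfectly
        ranked on held-out molecules."""
        setup = trained_gcn_setup
        graphs = [to_molecular_graph(r.molecule) for r in setup["test"]]
        y = np.stack([r.labels for r in setup["test"]])
        probs = gcn_forward(graphs, setup["model"])
        j = setup["vocabulary"].index("fruity")
        assert average_precision_bruteforce(y[:, j], probs[:, j]) > 0.9

    def test_training_loss_decreases(self, trained_gcn_setup):
        history = trained_gcn_setup["history"]
        assert history.train_loss[-1] < history.train_loss[0]

    def test_best_epoch_minimizes_validation_loss(self, trained_gcn_setup):
        history = trained_gcn_setup["history"]
        assert history.val_loss[history.best_epoch] == min(history.val_loss)

    def test_returned_model_has_best_validation_loss(self, trained_gcn_setup):
        setup = trained_gcn_setup
        graphs = [to_molecular_graph(r.molecule) for r in setup["val"]]
        y = np.stack([r.labels for r in setup["val"]]).astype(float)
        val_loss = setup["model"]._loss(graphs, y)
        assert val_loss == pytest.approx(min(setup["history"].val_loss), abs=1e-9)

    def test_history_no_longer_than_epoch_cap(self, trained_gcn_setup):
        assert len(trained_gcn_setup["history"]) <= trained_gcn_setup["config"].max_epochs

    def test_tiny_vocabulary_rejected(self):
        mols = [parse_smiles("CCO", "a"), parse_smiles("CCCCO", "b")]
        from odortl.chemio import DescriptorRecord
        vocab = DescriptorVocabulary(("only",))
        recs = [DescriptorRecord(m, np.array([1])) for m in mols]
        with pytest.raises(ValueError):
            train_gcn(DescriptorDataset(recs, vocab), GCNConfig(seed=0))


class TestEmbeddings:
    def test_embedding_length_is_128(self, trained_gcn_setup, fixture_rows):
        embs = extract_embeddings(trained_gcn_setup["model"], [r.molecule for r in fixture_rows[:3]])
        assert all(e.shape == (128,) and np.all(np.isfinite(e)) for e in embs)

    def test_spelling_invariance(self, trained_gcn_setup):
        model = trained_gcn_setup["model"]
        a, b = extract_embeddings(model, [parse_smiles("CCO"), parse_smiles("OCC")])
        assert np.max(np.abs(a - b)) < 1e-10

    def test_repeated_extraction_bitwise_identical(self, trained_gcn_setup, fixture_rows):
        model = trained_gcn_setup["model"]
        mols = [r.molecule for r in fixture_rows[:5]]
        assert np.array_equal(embedding_matrix(model, mols), embedding_matrix(model, mols))

    def test_permutation_invariance_within_tolerance(self, trained_gcn_setup, fixture_rows):
        model = trained_gcn_setup["model"]
        rng = np.random.default_rng(7)
        for row in fixture_rows:
            mol = row.molecule.to_mol()
            ref = model.embed(to_molecular_graph(mol))
            for _ in range(10):
                perm = rng.permutation(mol.GetNumAtoms()).tolist()
                sm = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)
                emb = model.embed(to_molecular_graph(parse_smiles(sm)))
                assert np.max(np.abs(emb - ref)) < 1e-5


class TestPersistence:
    def test_checkpoint_roundtrip(self, trained_gcn_setup, fixture_graphs, tmp_path):
        model = trained_gcn_setup["model"]
        prefix = str(tmp_path / "gcn")
        model.save(prefix)
        reloaded = GCNModel.load(prefix)
        assert np.array_equal(
            gcn_forward(fixture_graphs[:4], model), gcn_forward(fixture_graphs[:4], reloaded)
        )
        assert reloaded.vocabulary == model.vocabulary

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = GCNConfig(seed=9, learning_rate=0.0013)
        path = tmp_path / "gcn.yaml"
        cfg.to_yaml(path)
        assert GCNConfig.from_yaml(path) == cfg
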