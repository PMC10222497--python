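"""Self-consistent model system: MCC matrix, summary, overlap."""

import numpy as np
import pytest

from semicorr.attributes import AttributeKey, profile_smiles
from semicorr.consistency import build_matrix, summarize, validation_overlap, ConsistencyMatrix
from semicorr.descriptor import CorrelationWeightTable, CWEntry, SemiCorrelationModel
from semicorr.metrics import mcc_score
from semicorr.splits import FourWaySplit, make_splits


def _constant_model(c0):
    """A model that predicts the same category everywhere (no attributes)."""
    return SemiCorrelationModel(table=CorrelationWeightTable(), T=1, n_epochs=0, C0=c0, C1=0.0)


def _count_model(token, c1, threshold_count):
    """Predict active iff count(token) >= threshold_count."""
    t = CorrelationWeightTable()
    t.entries[AttributeKey.make([token])] = CWEntry(cw=1.0, document_frequency=5)
    return SemiCorrelationModel(
        table=t, T=1, n_epochs=0, C0=0.5 - c1 * (threshold_count - 0.5), C1=c1
    )


def test_identical_models_constant_matrix(small_dataset):
    smiles = small_dataset["smiles"].tolist()
    labels = small_dataset["label"].to_numpy()
    profiles = [profile_smiles(s) for s in smiles]
    splits = make_splits(len(smiles), k=3, seed=1)
    # same split list with the same model: each row is identical
    models = [_count_model("Cl", 1.0, 2)] * 3
    mat = build_matrix(models, splits, profiles, labels)
    assert np.allclose(mat.mcc[0], mat.mcc[1])
    assert np.allclose(mat.mcc[0], mat.mcc[2])


def test_matrix_cells_match_manual_enumeration():
    """Ten-compound toy system with hand-computable predictions."""
    smiles = ["C", "CC", "CCC", "CCCC", "O", "OO", "CO", "OC", "CCO", "OCC"]
    labels = np.array([0, 1, 1, 1, 0, 0, 0, 0, 1, 1])
    profiles = [profile_smiles(s) for s in smiles]
    splits = [
        FourWaySplit(np.array([0, 1]), np.array([2, 3]), np.array([4, 5]), np.array([6, 7, 8, 9])),
        FourWaySplit(np.array([6, 7]), np.array([8, 9]), np.array([0, 1]), np.array([2, 3, 4, 5])),
    ]
    # model A: active iff count(C) >= 2; model B: active iff count(C) >= 1
    models = [_count_model("C", 1.0, 2), _count_model("C", 1.0, 1)]
    mat = build_matrix(models, splits, profiles, labels)
    # manual: model A on V1 = {CO,OC,CCO,OCC}: counts 1,1,2,2 -> pred 0,0,1,1 vs obs 0,0,1,1 -> MCC 1
    assert mat.mcc[0, 0] == pytest.approx(1.0)
    # model A on V2 = {CCC,CCCC,O,OO}: pred 1,1,0,0 vs obs 1,1,0,0 -> 1
    assert mat.mcc[0, 1] == pytest.approx(1.0)
    # model B on V1: counts 1,1,2,2 -> pred 1,1,1,1 vs obs 0,0,1,1 -> MCC 0 (zero marginal)
    assert mat.mcc[1, 0] == pytest.approx(0.0)
    # model B on V2: pred 1,1,0,0 -> 1
    assert mat.mcc[1, 1] == pytest.approx(1.0)


def test_matrix_requires_matching_lengths(small_dataset):
    smiles = small_dataset["smiles"].tolist()
    profiles = [profile_smiles(s) for s in smiles]
    splits = make_splits(len(smiles), k=2, seed=0)
    with pytest.raises(ValueError):
        build_matrix([_constant_model(1.0)], splits, profiles, small_dataset["label"].to_numpy())


class TestSummarize:
    def test_constant_matrix(self):
        s = summarize(ConsistencyMatrix(np.full((4, 4), 0.37)))
        assert s["mean_offdiag"] == pytest.approx(0.37)
        assert s["sd_offdiag"] == 0.0

    def test_forced_two_by_two(self):
        s = summarize(ConsistencyMatrix(np.array([[0.6, 0.4], [0.5, 0.7]])))
        assert s["mean_offdiag"] == pytest.approx(0.45)
        assert s["sd_offdiag"] == pytest.approx(0.05)
        assert s["mean_all"] == pytest.approx(0.55)

    def test_against_bruteforce_loop(self, rng):
        m = rng.uniform(-1, 1, size=(5, 5))
        s = summarize(ConsistencyMatrix(m))
        cells = [m[i, j] for i in range(5) for j in range(5) if i != j]
        assert s["mean_offdiag"] == pytest.approx(np.mean(cells), abs=1e-12)
        assert s["sd_offdiag"] == pytest.approx(np.std(cells), abs=1e-12)

    def test_requires_k_at_least_two(self):
        with pytest.raises(ValueError):
            summarize(ConsistencyMatrix(np.array([[1.0]])))


class TestValidationOverlap:
    def test_identical_splits_full_overlap(self):
        (s,) = make_splits(40, k=1, seed=2)
        ov = validation_overlap([s, s])
        assert np.allclose(ov, 1.0)

    def test_disjoint_validation_sets(self):
        a = FourWaySplit(np.array([0, 1]), np.array([2, 3]), np.array([4, 5]), np.array([6, 7]))
        b = FourWaySplit(np.array([6, 7]), np.array([0, 1]), np.array([2, 3]), np.array([4, 5]))
        ov = validation_overlap([a, b])
        assert ov[0, 1] == 0.0 and ov[1, 0] == 0.0
        assert ov[0, 0] == 1.0

    def test_quarter_subsets_jaccard_expectation(self):
        """Independent ~25% subsets of n have expected Jaccard ~ 1/7."""
        splits = make_splits(1000, k=6, seed=4)
        ov = validation_overlap(splits)
        off = ov[~np.eye(6, dtype=bool)]
        assert abs(off.mean() - 1 / 7) < 0.03
        assert np.allclose(ov, ov.T)


def test_diagonal_equals_independent_validation_mcc(small_dataset, fitted_clf):
    """Matrix diagonal must agree with the metrics module computed directly."""
    smiles = small_dataset["smiles"].tolist()
    labels = small_dataset["label"].to_numpy()
    profiles = [profile_smiles(s) for s in smiles]
    split = fitted_clf.split_
    mat = build_matrix([fitted_clf.model_, fitted_clf.model_], [split, split], profiles, labels)
    _, pred = fitted_clf.model_.predict_profiles([profiles[i] for i in split.validation])
    assert mat.mcc[0, 0] == mcc_score(labels[split.validation], pred)
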