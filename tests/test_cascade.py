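"""Cascade training, grid search, two-level prediction, serialization."""

import numpy as np
import pytest

from nrcascade import errors
from nrcascade.cascade import (
    DEFAULT_LEVEL1_PARAMS,
    DEFAULT_LEVEL2_PARAMS,
    SVMConfig,
    TwoLevelNRClassifier,
    default_config,
    grid_search,
    load_model,
    run_benchmark_protocol,
    save_model,
    train_level,
)
from nrcascade.encode import SequenceEncoder
from nrcascade.simdata import Motif, SyntheticSpec, generate_collection


@pytest.fixture(scope="module")
def small_cascade_data():
    """Well-separated 3-subfamily + negatives collection (fast)."""
    motifs = {
        "NR1": (Motif("C-RK-AGV", 8), Motif("RK-RK-RK", 8)),
        "NR2": (Motif("C-RK-AGV", 8), Motif("DE-DE-DE", 8)),
        "NR3": (Motif("C-RK-AGV", 8), Motif("YMTS-YMTS-YMTS", 8)),
    }
    spec = SyntheticSpec(
        n_per_class={"non-NR": 30, "NR1": 15, "NR2": 15, "NR3": 15},
        length_range=(60, 150),
        planted_motifs=motifs,
        seed=11,
    )
    coll = generate_collection(spec)
    return list(coll.records), list(coll.labels)


@pytest.fixture(scope="module")
def fitted_model(small_cascade_data):
    records, labels = small_cascade_data
    model = TwoLevelNRClassifier(
        feature_set="aac+ctf", gamma1=2.0, C1=8.0, gamma2=8.0, C2=8.0, seed=0
    )
    return model.fit(records, labels)


class TestTrainLevel:
    def test_separable_clusters_reach_unit_training_accuracy(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (20, 5)), rng.normal(3, 0.1, (20, 5))])
        y = ["0"] * 20 + ["1"] * 20
        clf = train_level(X, y, SVMConfig(gamma=1.0, C=10.0))
        assert (clf.predict(X) == np.asarray(y)).all()

    def test_duplicating_every_point_keeps_training_labels(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (15, 4)), rng.normal(2, 0.5, (15, 4))])
        y = ["0"] * 15 + ["1"] * 15
        config = SVMConfig(gamma=0.5, C=5.0)
        base = train_level(X, y, config).predict(X)
        doubled = train_level(np.vstack([X, X]), y + y, config).predict(X)
        np.testing.assert_array_equal(base, doubled)

    def test_single_class_input_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(errors.ConfigurationError, match="2 classes"):
            train_level(X, ["1"] * 10, SVMConfig())

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(errors.ConfigurationError, match="gamma"):
            SVMConfig(gamma=0.0)
        with pytest.raises(errors.ConfigurationError, match="C"):
            SVMConfig(C=-1.0)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(errors.ConsistencyError):
            train_level(rng.normal(size=(5, 3)), ["0", "1"], SVMConfig())


@pytest.fixture(scope="module")
def xy():
    rng = np.random.default_rng(4)
    X = np.vstack([rng.normal(0, 0.3, (20, 4)), rng.normal(2, 0.3, (20, 4))])
    return X, ["0"] * 20 + ["1"] * 20


class TestGridSearch:
    def test_single_point_grid_returns_that_point(self, xy):
        X, y = xy
        res = grid_search(X, y, [0.5], [3.0], k=4, seed=0)
        assert (res.best.gamma, res.best.C) == (0.5, 3.0)
        assert len(res.table) == 1

    def test_winner_is_argmax_over_table(self, xy):
        X, y = xy
        res = grid_search(X, y, [0.01, 0.5, 8.0], [0.1, 1.0, 10.0], k=4, seed=0)
        assert res.best_score == res.table["mean_accuracy"].max()
        assert len(res.table) == 9

    def test_ties_break_to_smaller_c_then_gamma(self, xy):
        X, y = xy  # fully separable: wide region of the grid ties at 1.0
        res = grid_search(X, y, [0.5, 1.0], [5.0, 50.0], k=4, seed=0)
        ties = res.table[res.table["mean_accuracy"] == res.best_score]
        assert res.best.C == ties["C"].min()
        sub = ties[ties["C"] == res.best.C]
        assert res.best.gamma == sub["gamma"].min()

    def test_fixed_seed_reproduces_winner(self, xy):
        X, y = xy
        a = grid_search(X, y, [0.1, 1.0], [1.0, 10.0], k=4, seed=9)
        b = grid_search(X, y, [0.1, 1.0], [1.0, 10.0], k=4, seed=9)
        assert a.best == b.best and a.table.equals(b.table)

    def test_empty_grid_and_bad_k_rejected(self, xy):
        X, y = xy
        with pytest.raises(errors.ConfigurationError):
            grid_search(X, y, [], [1.0])
        with pytest.raises(errors.ConfigurationError):
            grid_search(X, y, [1.0], [1.0], k=1)


class TestDefaults:
    def test_published_level2_settings_cover_all_feature_sets(self):
        assert set(DEFAULT_LEVEL2_PARAMS) == {
            "aac", "cgr", "ctf", "aac+cgr", "aac+ctf", "ctf+cgr", "aac+cgr+ctf",
        }
        assert default_config("aac+ctf", level=2) == SVMConfig(0.0159, 10.3440)
        assert default_config("ctf", level=2) == SVMConfig(0.0192, 11.0849)

    def test_level1_aac_ctf_uses_first_level_settings(self):
        assert DEFAULT_LEVEL1_PARAMS["aac+ctf"] == (0.1899, 10.1197)
        assert default_config("ctf+aac", level=1) == SVMConfig(0.1899, 10.1197)


class TestTwoLevelCascade:
    def test_negatives_never_reach_level_two(self, fitted_model, small_cascade_data):
        records, _ = small_cascade_data
        level1 = fitted_model.predict_level1(records)
        cascade = fitted_model.predict(records)
        # cascade consistency: exactly the level-1 positives get subfamilies
        assert ((level1 == "1") == (cascade != "non-NR")).all()

    def test_planted_subfamily_recovered_end_to_end(self, fitted_model):
        spec = SyntheticSpec(
            n_per_class={"NR3": 5},
            length_range=(60, 150),
            planted_motifs={
                "NR3": (Motif("C-RK-AGV", 8), Motif("YMTS-YMTS-YMTS", 8))
            },
            seed=99,
        )
        probes = generate_collection(spec).records
        assert (fitted_model.predict(probes) == "NR3").all()

    def test_background_probe_is_rejected_at_level_one(self, fitted_model):
        spec = SyntheticSpec(n_per_class={"non-NR": 5}, length_range=(60, 150), seed=77)
        probes = generate_collection(spec).records
        assert (fitted_model.predict(probes) == "non-NR").all()

    def test_inference_is_deterministic(self, fitted_model, small_cascade_data):
        records, _ = small_cascade_data
        np.testing.assert_array_equal(
            fitted_model.predict(records), fitted_model.predict(records)
        )

    def test_unknown_labels_rejected_at_fit(self, small_cascade_data):
        records, labels = small_cascade_data
        bad = ["NR9" if lab == "NR1" else lab for lab in labels]
        with pytest.raises(errors.ConfigurationError, match="NR9"):
            TwoLevelNRClassifier().fit(records, bad)

    def test_unencodable_record_carries_id(self, fitted_model):
        from nrcascade.seqio import ProteinRecord

        short = ProteinRecord(id="tiny", residues="MK")  # too short for CTF
        with pytest.raises(errors.SequenceDomainError, match="tiny"):
            fitted_model.predict([short])

    def test_save_load_roundtrip_predictions(
        self, fitted_model, small_cascade_data, tmp_path
    ):
        records, _ = small_cascade_data
        path = tmp_path / "model.joblib"
        save_model(fitted_model, path)
        reloaded = load_model(path)
        np.testing.assert_array_equal(
            reloaded.predict(records), fitted_model.predict(records)
        )
        assert reloaded.feature_set == fitted_model.feature_set

    def test_sklearn_param_interface(self):
        model = TwoLevelNRClassifier(feature_set="ctf", gamma1=1.0)
        params = model.get_params()
        assert params["feature_set"] == "ctf" and params["gamma1"] == 1.0
        model.set_params(C1=5.0)
        assert model.C1 == 5.0


class TestBenchmarkProtocol:
    def test_report_structure_on_small_collection(self, small_cascade_data):
        records, labels = small_cascade_data
        from nrcascade.seqio import LabeledCollection

        coll = LabeledCollection(
            records=tuple(records),
            labels=tuple(labels),
            label_set=tuple(sorted(set(labels))),
        )
        report = run_benchmark_protocol(
            coll,
            feature_sets=("aac", "ctf"),
            k=3,
            seed=0,
            configs={("aac", 1): SVMConfig(2.0, 8.0), ("aac", 2): SVMConfig(2.0, 8.0),
                     ("ctf", 1): SVMConfig(8.0, 8.0), ("ctf", 2): SVMConfig(8.0, 8.0)},
        )
        assert set(report["level1"]) == {"aac", "ctf"}
        for fset, block in report["level1"].items():
            assert {"dimension", "mean", "pooled", "gamma", "C"} <= set(block)
            assert {"sens", "spec", "acc", "mcc"} <= set(block["mean"])
        for fset, block in report["level2"].items():
            assert {"sens", "spec", "acc", "mcc"} <= set(block["mean_overall"])
            assert "per_class" in block["pooled"]
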