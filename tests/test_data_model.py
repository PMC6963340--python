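import json

import numpy as np
import pytest

from gradepanel.data_model import (
    ExpressionMatrix,
    LabelVector,
    load_model,
    map_gleason_score_to_group,
    read_expression_matrix,
    read_labels,
    serialize_model,
    write_expression_matrix,
    write_labels,
)
from gradepanel.hierarchy import predict


class TestGleasonMapping:
    @pytest.mark.parametrize(
        "score,group",
        [
            ("6", 1),
            ("3+4=7", 2),
            ("4+3=7", 3),
            ("8", 4),
            ("9", 5),
            ("10", 5),
            (" 3 + 4 = 7 ", 2),
            ("4 + 3", 3),
            ("3+4", 2),
            ("group3", 3),
        ],
    )
    def test_recognised_scores(self, score, group):
        assert map_gleason_score_to_group(score) == group

    @pytest.mark.parametrize("bad", ["7", "2", "3+3=6", "5+5=10", "", "high"])
    def test_unrecognised_scores_rejected_with_value_in_message(self, bad):
        with pytest.raises(ValueError, match="Unrecognised"):
            map_gleason_score_to_group(bad)

    def test_mapping_total_and_constant(self):
        """The consolidation is a fixed total function on its vocabulary."""
        table = {"6": 1, "3+4=7": 2, "4+3=7": 3, "8": 4, "9": 5, "10": 5}
        for _ in range(3):
            for score, group in table.items():
                assert map_gleason_score_to_group(score) == group


class TestExpressionMatrix:
    def test_shape_and_id_validation(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            ExpressionMatrix(["s1"], ["f1", "f2"], np.ones((2, 2)))
        with pytest.raises(ValueError, match="duplicate sample"):
            ExpressionMatrix(["s1", "s1"], ["f1"], np.ones((2, 1)))
        with pytest.raises(ValueError, match="negative TPM"):
            ExpressionMatrix(["s1"], ["f1"], np.array([[-1.0]]))
        with pytest.raises(ValueError, match="non-finite"):
            ExpressionMatrix(["s1"], ["f1"], np.array([[np.nan]]))

    def test_round_trip_both_orientations(self, tmp_path):
        m = ExpressionMatrix(
            ["s1", "s2", "s3"], ["fA", "fB"], np.arange(6, dtype=float).reshape(3, 2)
        )
        for orientation in ("features_by_samples", "samples_by_features"):
            path = tmp_path / f"{orientation}.tsv"
            write_expression_matrix(m, path, orientation)
            back = read_expression_matrix(path, orientation)
            assert back.sample_ids == m.sample_ids
            assert back.feature_ids == m.feature_ids
            np.testing.assert_array_equal(back.values, m.values)

    def test_transposed_read_recovers_same_matrix(self, tmp_path):
        m = ExpressionMatrix(["s1", "s2"], ["fA", "fB", "fC"], np.ones((2, 3)))
        write_expression_matrix(m, tmp_path / "a.tsv", "features_by_samples")
        write_expression_matrix(m, tmp_path / "b.tsv", "samples_by_features")
        a = read_expression_matrix(tmp_path / "a.tsv", "features_by_samples")
        b = read_expression_matrix(tmp_path / "b.tsv", "samples_by_features")
        np.testing.assert_array_equal(a.values, b.values)

    def test_non_numeric_cell_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("fid\ts1\ts2\nfA\t1.0\tNA\nfB\t2.0\t3.0\n")
        with pytest.raises(ValueError, match="fA"):
            read_expression_matrix(path)

    def test_subset_features_missing_named(self):
        m = ExpressionMatrix(["s1"], ["fA"], np.ones((1, 1)))
        with pytest.raises(KeyError, match="fZ"):
            m.subset_features(["fZ"])


class TestLabels:
    def test_scores_map_to_groups(self, tmp_path):
        path = tmp_path / "labels.tsv"
        path.write_text("s1\t6\ns2\t8\ns3\t9\n")
        lv = read_labels(path)
        assert lv.sample_ids == ["s1", "s2", "s3"]
        assert lv.groups.tolist() == [1, 4, 5]

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(Exception):
            read_labels(path)

    def test_duplicate_sample_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("s1\t6\ns1\t8\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_labels(path)

    def test_alignment_reports_missing_ids_both_ways(self):
        m = ExpressionMatrix(["s1", "s2"], ["fA"], np.ones((2, 1)))
        lv = LabelVector(["s2", "s3"], np.array([1, 2]))
        with pytest.raises(ValueError) as exc:
            lv.aligned_to(m)
        assert "s1" in str(exc.value) and "s3" in str(exc.value)

    def test_alignment_reorders_to_matrix(self, tmp_path):
        m = ExpressionMatrix(["s2", "s1"], ["fA"], np.ones((2, 1)))
        lv = LabelVector(["s1", "s2"], np.array([1, 4]))
        assert lv.aligned_to(m).groups.tolist() == [4, 1]

    def test_write_read_round_trip(self, tmp_path, small_dataset):
        path = tmp_path / "labels.tsv"
        write_labels(small_dataset.labels, path)
        back = read_labels(path)
        assert back.groups.tolist() == small_dataset.labels.groups.tolist()


class TestModelSerialization:
    def test_round_trip_predictions_identical(self, tmp_path, trained_small, small_dataset):
        model = trained_small.model
        path = tmp_path / "model.json"
        serialize_model(model, path)
        loaded = load_model(path)
        assert loaded.class_order == model.class_order
        assert [n.selected_feature_ids for n in loaded.nodes] == [
            n.selected_feature_ids for n in model.nodes
        ]
        p1 = predict(model, small_dataset.matrix)
        p2 = predict(loaded, small_dataset.matrix)
        np.testing.assert_array_equal(p1, p2)

    def test_version_mismatch_rejected(self, tmp_path, trained_small):
        path = tmp_path / "model.json"
        serialize_model(trained_small.model, path)
        doc = json.loads(path.read_text())
        doc["schema_version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="schema version"):
            load_model(path)

    def test_corrupted_file_rejected(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text("{not json")
        with pytest.raises(ValueError, match="corrupted"):
            load_model(path)

    def test_missing_feature_at_prediction_time(self, trained_small):
        model = trained_small.model
        needed = model.required_features[0]
        matrix = ExpressionMatrix(
            ["s1"], ["unrelated_feature"], np.ones((1, 1))
        )
        with pytest.raises(KeyError, match=needed):
            predict(model, matrix)
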