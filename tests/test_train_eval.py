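"""Training loop, confusion metrics, and per-case reporting."""

import numpy as np
import pandas as pd
import pytest

from seizgraph.eeg_io import INTER_ICTAL, PRE_ICTAL
from seizgraph.network import ArchConfig
from seizgraph.train_eval import (
    ConfusionCounts,
    MetricsReport,
    TrainConfig,
    build_sequences,
    compute_metrics,
    confusion_counts,
    featurize_segment,
    format_report,
    per_case_report,
    predict_sequences,
    split_windows,
    train_model,
    write_predictions_csv,
    write_report_csv,
)

TINY_ARCH = ArchConfig(n_channels=4, order_K=2, width_1=6, width_2=6,
                       hidden_size=8, mlp_hidden=4, seq_len=3)


@pytest.fixture(scope="module")
def tiny_windows(tiny_sim):
    from seizgraph.synthetic import make_dataset

    ds = make_dataset(tiny_sim, n_per_class=12, seed=3)
    return [featurize_segment(seg, TINY_ARCH) for seg in ds]


class TestSequencesAndSplit:
    def test_sequence_shapes_and_labels(self, tiny_windows):
        seqs = build_sequences(tiny_windows, seq_len=3)
        assert all(s.B1.shape[0] == 3 for s in seqs)
        # 12 windows per class, stride 1 -> 10 sequences per class
        assert sum(s.label == PRE_ICTAL for s in seqs) == 10
        assert sum(s.label == INTER_ICTAL for s in seqs) == 10

    def test_stride_reduces_sequence_count(self, tiny_windows):
        n1 = len(build_sequences(tiny_windows, seq_len=3, stride=1))
        n2 = len(build_sequences(tiny_windows, seq_len=3, stride=2))
        assert n2 < n1

    def test_split_is_blocked_no_shared_windows(self, tiny_windows):
        train, test = split_windows(tiny_windows, split_fraction=0.3)
        train_ids = {id(w) for w in train}
        assert not train_ids & {id(w) for w in test}
        # held-out windows come after training windows within each group
        for label in (PRE_ICTAL, INTER_ICTAL):
            t_max = max(w.start_time for w in train if w.label == label)
            e_min = min(w.start_time for w in test if w.label == label)
            assert t_max < e_min

    def test_split_fraction_respected(self, tiny_windows):
        train, test = split_windows(tiny_windows, split_fraction=0.25)
        assert len(test) == 6  # 3 of 12 per class
        assert len(train) == 18


class TestTrainModel:
    def test_single_class_rejected(self, tiny_sim):
        from seizgraph.synthetic import generate_segment

        segs = [generate_segment(PRE_ICTAL, tiny_sim, seed=i) for i in range(4)]
        with pytest.raises(ValueError, match="both classes"):
            train_model(segs, TrainConfig(epochs=1), TINY_ARCH)

    def test_loss_descends_on_separable_data(self, small_dataset):
        cfg = TrainConfig(epochs=15, batch_size=8, seed=2)
        result = train_model(small_dataset, cfg, TINY_ARCH)
        assert result.loss_history[-1] < result.loss_history[0]

    def test_same_seed_reproduces_history_and_parameters(self, small_dataset):
        cfg = TrainConfig(epochs=4, batch_size=8, seed=9)
        a = train_model(small_dataset, cfg, TINY_ARCH)
        b = train_model(small_dataset, cfg, TINY_ARCH)
        assert a.loss_history == b.loss_history
        assert a.model.parameter_hash() == b.model.parameter_hash()

    def test_heldout_predictions_on_separable_data(self, small_dataset):
        cfg = TrainConfig(epochs=15, batch_size=8, seed=2)
        result = train_model(small_dataset, cfg, TINY_ARCH)
        pred, truth, p_pre = predict_sequences(result.model, result.test_sequences)
        acc = np.mean([p == t for p, t in zip(pred, truth)])
        assert acc >= 0.75
        assert len(p_pre) == len(result.test_sequences)


class TestConfusionCounts:
    def test_perfect_classifier(self):
        pred = [PRE_ICTAL] * 50 + [INTER_ICTAL] * 50
        c = confusion_counts(pred, pred)
        assert (c.TP, c.TN, c.FP, c.FN) == (50, 50, 0, 0)

    def test_inverted_classifier(self):
        truth = [PRE_ICTAL] * 50 + [INTER_ICTAL] * 50
        pred = [INTER_ICTAL] * 50 + [PRE_ICTAL] * 50
        c = confusion_counts(pred, truth)
        assert (c.TP, c.TN) == (0, 0)
        assert (c.FP, c.FN) == (50, 50)

    def test_manual_tally_of_mixed_outcomes(self):
        P, I = PRE_ICTAL, INTER_ICTAL
        truth = [P, P, P, P, I, I, I, I, I, P]
        pred_ = [P, I, P, P, I, P, I, I, P, I]
        c = confusion_counts(pred_, truth)
        assert (c.TP, c.FN, c.TN, c.FP) == (3, 2, 3, 2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_counts([PRE_ICTAL], [])


class TestComputeMetrics:
    def test_perfect_case(self):
        m = compute_metrics(ConfusionCounts(TP=50, FP=0, TN=50, FN=0))
        assert m.accuracy == m.sensitivity == m.specificity == m.ppv == m.npv == 100.0
        assert m.fpr == 0.0
        assert m.f1 == 1.0

    def test_worked_example(self):
        m = compute_metrics(ConfusionCounts(TP=40, FN=10, TN=45, FP=5))
        assert m.sensitivity == pytest.approx(80.0)
        assert m.specificity == pytest.approx(90.0)
        assert m.accuracy == pytest.approx(85.0)
        assert m.f1 == pytest.approx(80.0 / 95.0)
        assert m.fpr == pytest.approx(0.1)

    def test_undefined_sensitivity_reported_missing(self):
        m = compute_metrics(ConfusionCounts(TP=0, FN=0, TN=5, FP=5))
        assert m.sensitivity is None
        assert m.ppv is not None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    @pytest.mark.parametrize("seed", range(5))
    def test_metric_identities(self, seed):
        rng = np.random.default_rng(seed)
        tp, fp, tn, fn = (int(v) for v in rng.integers(1, 100, size=4))
        m = compute_metrics(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
        assert m.sensitivity / 100 + fn / (tp + fn) == pytest.approx(1.0)
        assert m.specificity / 100 + m.fpr == pytest.approx(1.0)
        precision, recall = m.ppv / 100, m.sensitivity / 100
        harmonic = 2 * precision * recall / (precision + recall)
        assert m.f1 == pytest.approx(harmonic)


class TestPerCaseReport:
    def _metrics(self, sens):
        return MetricsReport(specificity=90.0, sensitivity=sens, ppv=95.0,
                             npv=95.0, fpr=0.1, accuracy=92.0, f1=0.93)

    def test_single_case_average_is_identity(self):
        df = per_case_report({"case1": self._metrics(100.0)})
        pd.testing.assert_series_equal(df.loc["Average"], df.loc["case1"],
                                       check_names=False)

    def test_two_case_mean(self):
        df = per_case_report({"a": self._metrics(100.0), "b": self._metrics(80.0)})
        assert df.loc["Average", "sensitivity"] == pytest.approx(90.0)

    def test_constant_rows_average_unchanged(self):
        df = per_case_report({f"c{i}": self._metrics(97.0) for i in range(24)})
        assert df.loc["Average", "sensitivity"] == pytest.approx(97.0)
        assert len(df) == 25

    def test_missing_metric_skipped_in_average(self):
        a = self._metrics(100.0)
        b = MetricsReport(specificity=80.0, sensitivity=None, ppv=None, npv=90.0,
                          fpr=0.2, accuracy=85.0, f1=0.8)
        df = per_case_report({"a": a, "b": b})
        assert df.loc["Average", "sensitivity"] == pytest.approx(100.0)

    def test_csv_and_text_outputs(self, tmp_path):
        df = per_case_report({"a": self._metrics(99.0)})
        out = tmp_path / "report.csv"
        write_report_csv(df, out)
        back = pd.read_csv(out, index_col=0)
        assert "sensitivity" in back.columns
        assert "Average" in back.index
        text = format_report(df)
        assert "sensitivity" in text


def test_predictions_csv(tmp_path, tiny_windows):
    from seizgraph.network import SeizureModel

    seqs = build_sequences(tiny_windows, seq_len=3)[:4]
    model = SeizureModel.initialize(TINY_ARCH, np.random.default_rng(0))
    pred, truth, p_pre = predict_sequences(model, seqs)
    path = tmp_path / "pred.csv"
    write_predictions_csv(path, seqs, pred, p_pre)
    lines = path.read_text().strip().splitlines()
    assert lines[0].startswith("source_id,")
    assert len(lines) == 5
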