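"""Training, evaluation metrics, and per-case reporting.

Training minimizes cross entropy plus an L2 penalty with Adam (initial
learning rate 0.01) over the full encoder + predictor stack. Evaluation uses
the standard seizure-prediction indicator suite derived from the confusion
counts with pre-ictal as the positive class: accuracy, sensitivity,
specificity, PPV and NPV on the percentage scale, and FPR and F1 on the
ratio scale. Per-case tables carry one row per patient/case plus an
unweighted "Average" row.

Sequences: predictions are made over runs of ``seq_len`` consecutive
same-label windows (chronological order within a source). The train/test
split is blocked at the segment level inside every (source, label) group —
the leading fraction of segments trains, the trailing fraction is held out,
and sequences are formed within each side only, so overlapping windows never
straddle the split.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .eeg_io import INTER_ICTAL, PRE_ICTAL, EEGSegment, Label
from .graph_encoder import chebyshev_operator_stack, scaled_laplacian
from .network import Adam, ArchConfig, SeizureModel
from .reconstruction import build_channel_graph, channel_energy_matrix
from .temporal_predictor import CLASS_ORDER

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    lambda_reg: float = 5e-4
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    split_fraction: float = 0.3  # held-out fraction

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be nonnegative")


# ---------------------------------------------------------------------------
# featurization and sequence building
# ---------------------------------------------------------------------------

@dataclass
class WindowFeatures:
    """Per-window precomputed encoder inputs."""

    X: np.ndarray   # (C, F0) node features
    Tm: np.ndarray  # (K, C, C) Chebyshev operators T_k(L~)
    B1: np.ndarray  # (K, C, F0) = Tm @ X
    label: Label
    source_id: str
    start_time: float


def featurize_segment(seg: EEGSegment, arch: ArchConfig) -> WindowFeatures:
    """Segment -> band-energy graph -> precomputed convolution inputs."""
    bem = channel_energy_matrix(seg, depth=arch.depth, wavelet_name=arch.wavelet)
    g = build_channel_graph(bem, mode=arch.graph_mode, seg=seg)
    spec = scaled_laplacian(g.adjacency)
    Tm = chebyshev_operator_stack(spec, arch.order_K)
    X = bem.relative if arch.use_relative else bem.energies
    B1 = np.einsum("kij,jf->kif", Tm, X)
    return WindowFeatures(X=X, Tm=Tm, B1=B1, label=seg.label,
                          source_id=seg.source_id, start_time=seg.start_time)


@dataclass
class SequenceSample:
    """One chronologically ordered run of windows with a single label."""

    B1: np.ndarray  # (T, K, C, F0)
    Tm: np.ndarray  # (T, K, C, C)
    label: Label
    source_id: str
    start_time: float


def _group_windows(windows: Sequence[WindowFeatures]
                   ) -> dict[tuple[str, Label], list[WindowFeatures]]:
    groups: dict[tuple[str, Label], list[WindowFeatures]] = {}
    for w in windows:
        groups.setdefault((w.source_id, w.label), []).append(w)
    for g in groups.values():
        g.sort(key=lambda w: w.start_time)
    return groups


def build_sequences(windows: Sequence[WindowFeatures], seq_len: int,
                    stride: int = 1) -> list[SequenceSample]:
    """Sliding runs of ``seq_len`` consecutive windows within each
    (source, label) group, stride in windows."""
    if seq_len < 1 or stride < 1:
        raise ValueError("seq_len and stride must be >= 1")
    sequences = []
    for (source, label), group in sorted(_group_windows(windows).items()):
        for i in range(0, len(group) - seq_len + 1, stride):
            run = group[i : i + seq_len]
            sequences.append(SequenceSample(
                B1=np.stack([w.B1 for w in run]),
                Tm=np.stack([w.Tm for w in run]),
                label=label,
                source_id=source,
                start_time=run[0].start_time,
            ))
    return sequences


def _stack(sequences: Sequence[SequenceSample]
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    B1 = np.stack([s.B1 for s in sequences])
    Tm = np.stack([s.Tm for s in sequences])
    Y = np.zeros((len(sequences), 2))
    for i, s in enumerate(sequences):
        Y[i, CLASS_ORDER.index(s.label)] = 1.0
    return B1, Tm, Y


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: SeizureModel
    loss_history: list[float]
    train_sequences: list[SequenceSample]
    test_sequences: list[SequenceSample]
    arch: ArchConfig


def split_windows(windows: Sequence[WindowFeatures], split_fraction: float
                  ) -> tuple[list[WindowFeatures], list[WindowFeatures]]:
    """Blocked split per (source, label) group: leading segments train,
    trailing ``split_fraction`` are held out."""
    train: list[WindowFeatures] = []
    test: list[WindowFeatures] = []
    for _, group in sorted(_group_windows(windows).items()):
        n_test = max(1, int(round(split_fraction * len(group))))
        cut = len(group) - n_test
        train.extend(group[:cut])
        test.extend(group[cut:])
    return train, test


def train_model(
    dataset: Sequence[EEGSegment],
    cfg: TrainConfig,
    arch: ArchConfig | None = None,
) -> TrainResult:
    """End-to-end gradient training of encoder + predictor.

    Deterministic given ``cfg.seed`` (numpy single-threaded reference mode):
    parameter initialization and batch shuffling both derive from the seed.
    """
    if arch is None:
        arch = ArchConfig()
    labels = {seg.label for seg in dataset}
    if labels != {PRE_ICTAL, INTER_ICTAL}:
        raise ValueError(f"dataset must contain both classes, has {sorted(labels)}")

    windows = [featurize_segment(seg, arch) for seg in dataset]
    train_w, test_w = split_windows(windows, cfg.split_fraction)
    train_seqs = build_sequences(train_w, arch.seq_len)
    test_seqs = build_sequences(test_w, arch.seq_len)
    if not train_seqs:
        raise ValueError("no training sequences; dataset too small for seq_len")

    B1, Tm, Y = _stack(train_seqs)
    n = len(train_seqs)

    init_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    model = SeizureModel.initialize(arch, init_rng)
    opt = Adam(model, learning_rate=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))

    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            cache: dict = {}
            P = model.forward(B1[idx], Tm[idx], cache)
            epoch_losses.append(model.loss_batch(P, Y[idx], cfg.lambda_reg))
            grads = model.backward(cache, Y[idx], cfg.lambda_reg)
            opt.step(grads)
        history.append(float(np.mean(epoch_losses)))
        logger.debug("epoch %d loss %.4f", epoch, history[-1])

    return TrainResult(model=model, loss_history=history,
                       train_sequences=train_seqs, test_sequences=test_seqs,
                       arch=arch)


def predict_sequences(model: SeizureModel, sequences: Sequence[SequenceSample]
                      ) -> tuple[list[Label], list[Label], np.ndarray]:
    """Predicted labels, true labels, and p(pre_ictal) per sequence."""
    if not sequences:
        raise ValueError("no sequences to evaluate")
    B1, Tm, _ = _stack(sequences)
    P = model.forward(B1, Tm)
    pred = [CLASS_ORDER[i] for i in np.argmax(P, axis=1)]
    truth = [s.label for s in sequences]
    return pred, truth, P[:, CLASS_ORDER.index(PRE_ICTAL)]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion_counts(predictions: Sequence[Label], truth: Sequence[Label],
                     positive_class: Label = PRE_ICTAL) -> ConfusionCounts:
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth differ in length")
    tp = fp = tn = fn = 0
    for p, t in zip(predictions, truth):
        if t == positive_class:
            if p == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


@dataclass
class MetricsReport:
    """Indicator suite; percentages for the first five, ratios for FPR/F1.

    A metric whose denominator is zero is undefined and reported as None
    (never as 0).
    """

    specificity: float | None
    sensitivity: float | None
    ppv: float | None
    npv: float | None
    fpr: float | None
    accuracy: float | None
    f1: float | None

    FIELDS = ("specificity", "sensitivity", "ppv", "npv", "fpr", "accuracy", "f1")

    def as_dict(self) -> dict[str, float | None]:
        return {k: getattr(self, k) for k in self.FIELDS}


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, specificity, sensitivity, PPV, NPV (percent), FPR, F1 (ratio)."""
    if c.total == 0:
        raise ValueError("cannot compute metrics for zero evaluated segments")

    def pct(num: int, den: int) -> float | None:
        r = _ratio(num, den)
        return None if r is None else 100.0 * r

    return MetricsReport(
        specificity=pct(c.TN, c.TN + c.FP),
        sensitivity=pct(c.TP, c.TP + c.FN),
        ppv=pct(c.TP, c.TP + c.FP),
        npv=pct(c.TN, c.TN + c.FN),
        fpr=_ratio(c.FP, c.FP + c.TN),
        accuracy=pct(c.TP + c.TN, c.total),
        f1=_ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN),
    )


def per_case_report(case_results: Mapping[str, MetricsReport]) -> pd.DataFrame:
    """One row per case plus an unweighted 'Average' row (missing metrics are
    skipped in the average for their column)."""
    if not case_results:
        raise ValueError("case_results must be nonempty")
    rows = {case: rep.as_dict() for case, rep in case_results.items()}
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    df = df[list(MetricsReport.FIELDS)]
    df.loc["Average"] = df.mean(axis=0, skipna=True)
    df.index.name = "case_id"
    return df


def write_report_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, float_format="%.4f")


def format_report(df: pd.DataFrame) -> str:
    return df.to_string(float_format=lambda v: f"{v:.4f}", na_rep="missing")


def run_synthetic_experiment(
    n_per_class: int = 200,
    seed: int = 0,
    epochs: int = 50,
    sim_config: "SimConfig | None" = None,
    arch: ArchConfig | None = None,
) -> tuple[MetricsReport, TrainResult]:
    """Full pipeline on generated data: simulate -> featurize -> train ->
    evaluate held-out sequences. The default regimes plant disjoint dominant
    sub-bands (low vs high frequency) and couplings 0.1 vs 0.9.
    """
    from .synthetic import SimConfig, make_dataset

    if sim_config is None:
        sim_config = SimConfig(seed=seed)
    dataset = make_dataset(sim_config, n_per_class=n_per_class, seed=seed)
    cfg = TrainConfig(epochs=epochs, seed=seed)
    result = train_model(dataset, cfg, arch)
    pred, truth, _ = predict_sequences(result.model, result.test_sequences)
    metrics = compute_metrics(confusion_counts(pred, truth))
    return metrics, result


def write_predictions_csv(path: str | Path, sequences: Sequence[SequenceSample],
                          pred: Sequence[Label], p_pre: np.ndarray) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_id", "start_time", "true_label", "p_pre", "predicted"])
        for s, lab, p in zip(sequences, pred, p_pre):
            writer.writerow([s.source_id, f"{s.start_time:.3f}", s.label,
                             f"{p:.6f}", lab])
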