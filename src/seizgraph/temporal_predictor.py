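"""GRU-based temporal classifier over chronologically ordered status codes.

A gated recurrent unit folds the sequence of per-window status codes into a
hidden state. Per step, with input s_t and previous state C_{t-1}:

    R_t = sigmoid(W_r s_t + U_r C_{t-1})          (reset gate)
    N_t = sigmoid(W_z s_t + U_z C_{t-1})          (update gate)
    C~_t = tanh(W s_t + R_t * (U C_{t-1}))        (candidate state)
    C_t = (1 - N_t) * C_{t-1} + N_t * C~_t

(* is elementwise; gates are bias-free). The reset gate is applied
elementwise to the recurrent term, the standard GRU reading of the candidate
update. The final hidden state feeds a small MLP (one ReLU hidden layer,
softmax output) that emits probabilities over {inter-ictal, pre-ictal}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .eeg_io import INTER_ICTAL, PRE_ICTAL, Label
from .graph_encoder import StatusCode, _glorot

#: class order of the probability vector
CLASS_ORDER: tuple[Label, Label] = (INTER_ICTAL, PRE_ICTAL)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class GRUParams:
    """Bias-free GRU weights (input width 18, hidden width configurable)."""

    W_r: np.ndarray
    U_r: np.ndarray
    W_z: np.ndarray
    U_z: np.ndarray
    W: np.ndarray
    U: np.ndarray

    def __post_init__(self) -> None:
        h, d = self.W_r.shape
        for name in ("W_z", "W"):
            if getattr(self, name).shape != (h, d):
                raise ValueError(f"{name} must have shape {(h, d)}")
        for name in ("U_r", "U_z", "U"):
            if getattr(self, name).shape != (h, h):
                raise ValueError(f"{name} must have shape {(h, h)}")

    @property
    def hidden_size(self) -> int:
        return self.W_r.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_r.shape[1]

    @classmethod
    def initialize(cls, rng: np.random.Generator, input_size: int = 18,
                   hidden_size: int = 32) -> "GRUParams":
        wx = lambda: _glorot(rng, (hidden_size, input_size), input_size, hidden_size)
        wh = lambda: _glorot(rng, (hidden_size, hidden_size), hidden_size, hidden_size)
        return cls(W_r=wx(), U_r=wh(), W_z=wx(), U_z=wh(), W=wx(), U=wh())


@dataclass
class GRUState:
    """Hidden state C_t after step t (t = 0 means the zero initial state)."""

    C: np.ndarray
    t: int = 0

    @classmethod
    def zero(cls, hidden_size: int) -> "GRUState":
        return cls(C=np.zeros(hidden_size), t=0)


def gru_step(s_t: np.ndarray | StatusCode, state: GRUState, params: GRUParams) -> GRUState:
    """One GRU update. Gates lie in (0,1), the candidate in (-1,1)."""
    s = s_t.values if isinstance(s_t, StatusCode) else np.asarray(s_t, dtype=np.float64)
    if s.shape != (params.input_size,):
        raise ValueError(f"input must have shape ({params.input_size},)")
    if state.C.shape != (params.hidden_size,):
        raise ValueError(f"state must have shape ({params.hidden_size},)")
    c_prev = state.C
    r = _sigmoid(params.W_r @ s + params.U_r @ c_prev)
    n = _sigmoid(params.W_z @ s + params.U_z @ c_prev)
    c_tilde = np.tanh(params.W @ s + r * (params.U @ c_prev))
    c = (1.0 - n) * c_prev + n * c_tilde
    return GRUState(C=c, t=state.t + 1)


def run_sequence(codes: Sequence[StatusCode], params: GRUParams) -> GRUState:
    """Fold the GRU over status codes in chronological order."""
    if len(codes) == 0:
        raise ValueError("sequence must be nonempty")
    indices = [c.window_index for c in codes]
    if any(b <= a for a, b in zip(indices, indices[1:])):
        raise ValueError(f"window indices must be strictly increasing, got {indices}")
    state = GRUState.zero(params.hidden_size)
    for code in codes:
        state = gru_step(code, state, params)
    return state


@dataclass
class MLPHeadParams:
    """One hidden ReLU layer, then a dense map to two class logits."""

    W_hidden: np.ndarray
    b_hidden: np.ndarray
    W_out: np.ndarray
    b_out: np.ndarray

    @classmethod
    def initialize(cls, rng: np.random.Generator, input_size: int = 32,
                   hidden_size: int = 16, n_classes: int = 2) -> "MLPHeadParams":
        return cls(
            W_hidden=_glorot(rng, (hidden_size, input_size), input_size, hidden_size),
            b_hidden=np.zeros(hidden_size),
            W_out=_glorot(rng, (n_classes, hidden_size), hidden_size, n_classes),
            b_out=np.zeros(n_classes),
        )


@dataclass
class PredictorOutput:
    """Class probabilities over (inter_ictal, pre_ictal) and the argmax."""

    probabilities: np.ndarray
    predicted_label: Label

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.shape != (2,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be a 2-vector summing to 1")
        self.probabilities = p


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def mlp_predict(state: GRUState, head_params: MLPHeadParams) -> PredictorOutput:
    """Final hidden state -> class probabilities."""
    h = np.maximum(head_params.W_hidden @ state.C + head_params.b_hidden, 0.0)
    logits = head_params.W_out @ h + head_params.b_out
    p = softmax(logits)
    return PredictorOutput(probabilities=p,
                           predicted_label=CLASS_ORDER[int(np.argmax(p))])


PROB_FLOOR = 1e-12


def loss(out: PredictorOutput, true_label: Label,
         all_weights: Iterable[np.ndarray] = (), lambda_reg: float = 0.0) -> float:
    """Cross entropy against the one-hot true label plus L2 regularization.

    The penalty is (lambda_reg / 2) * sum of squared entries over the weight
    matrices in ``all_weights`` (biases excluded by the caller).
    """
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be nonnegative")
    if true_label not in CLASS_ORDER:
        raise ValueError(f"unknown label {true_label!r}")
    p_true = out.probabilities[CLASS_ORDER.index(true_label)]
    ce = -float(np.log(max(p_true, PROB_FLOOR)))
    reg = 0.5 * lambda_reg * sum(float(np.sum(np.square(w))) for w in all_weights)
    return ce + reg
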