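"""Batched end-to-end model: graph encoder + GRU + MLP with analytic
gradients and an Adam optimizer.

The module-level operations in :mod:`graph_encoder` and
:mod:`temporal_predictor` define the model one window / one step at a time;
training needs the same computation batched over sequences with gradients.
Because the Chebyshev operators T_k(L~) depend only on the window's graph —
never on the learnable parameters — they are precomputed per window
(``chebyshev_operator_stack``), which reduces both convolution layers to
tensor contractions. All gradients below are hand-derived; a finite-
difference check in the test suite pins them down.

Shapes (B sequences, T windows, K Chebyshev orders, C channels, F features):
    Tm : (B, T, K, C, C)   precomputed T_k(L~) per window
    B1 : (B, T, K, C, F0)  precomputed T_k(L~) @ X per window
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_encoder import EncoderParams
from .temporal_predictor import MLPHeadParams, GRUParams, _sigmoid


@dataclass
class ArchConfig:
    """Architecture hyperparameters (defaults sized for 18-channel graphs)."""

    n_channels: int = 18
    n_bands: int = 16
    order_K: int = 3
    width_1: int = 32
    width_2: int = 32
    hidden_size: int = 32
    mlp_hidden: int = 16
    seq_len: int = 5  # consecutive windows per prediction
    depth: int = 4
    wavelet: str = "db4"
    graph_mode: str = "energy_vectors"
    use_relative: bool = True


class SeizureModel:
    """Parameter container + batched forward/backward passes."""

    def __init__(self, encoder: EncoderParams, gru: GRUParams, head: MLPHeadParams):
        self.encoder = encoder
        self.gru = gru
        self.head = head

    @classmethod
    def initialize(cls, arch: ArchConfig, rng: np.random.Generator) -> "SeizureModel":
        enc = EncoderParams.initialize(
            rng, n_channels=arch.n_channels, n_bands=arch.n_bands,
            order_K=arch.order_K, width_1=arch.width_1, width_2=arch.width_2,
        )
        gru = GRUParams.initialize(rng, input_size=arch.n_channels,
                                   hidden_size=arch.hidden_size)
        head = MLPHeadParams.initialize(rng, input_size=arch.hidden_size,
                                        hidden_size=arch.mlp_hidden)
        return cls(enc, gru, head)

    # (owner object, attribute, is_weight) — biases are exempt from L2
    def _param_spec(self) -> list[tuple[object, str, bool]]:
        return [
            (self.encoder, "theta_1", True),
            (self.encoder, "theta_2", True),
            (self.encoder, "fc_weights", True),
            (self.encoder, "fc_bias", False),
            (self.gru, "W_r", True), (self.gru, "U_r", True),
            (self.gru, "W_z", True), (self.gru, "U_z", True),
            (self.gru, "W", True), (self.gru, "U", True),
            (self.head, "W_hidden", True),
            (self.head, "b_hidden", False),
            (self.head, "W_out", True),
            (self.head, "b_out", False),
        ]

    def parameters(self) -> dict[str, np.ndarray]:
        return {name: getattr(obj, name) for obj, name, _ in self._param_spec()}

    def weight_matrices(self) -> list[np.ndarray]:
        return [getattr(obj, name) for obj, name, is_w in self._param_spec() if is_w]

    def parameter_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for _, name, _ in self._param_spec():
            h.update(self.parameters()[name].tobytes())
        return h.hexdigest()

    # ------------------------------------------------------------------
    # forward
    # ------------------------------------------------------------------
    def forward(self, B1: np.ndarray, Tm: np.ndarray, cache: dict | None = None
                ) -> np.ndarray:
        """Batched probabilities, shape (B, 2) over (inter_ictal, pre_ictal)."""
        enc, gru, head = self.encoder, self.gru, self.head
        O1 = np.einsum("btkcf,kfg->btcg", B1, enc.theta_1)
        H1 = np.maximum(O1, 0.0)
        M2 = np.einsum("btkij,btjg->btkig", Tm, H1)
        O2 = np.einsum("btkcg,kgh->btch", M2, enc.theta_2)
        H2 = np.maximum(O2, 0.0)
        nB, nT = H2.shape[:2]
        Hf = H2.reshape(nB, nT, -1)
        S = Hf @ enc.fc_weights + enc.fc_bias  # (B, T, C)

        C_prev = np.zeros((nB, gru.hidden_size))
        steps = []
        for t in range(nT):
            s_t = S[:, t]
            r = _sigmoid(s_t @ gru.W_r.T + C_prev @ gru.U_r.T)
            n = _sigmoid(s_t @ gru.W_z.T + C_prev @ gru.U_z.T)
            ucp = C_prev @ gru.U.T
            c_tilde = np.tanh(s_t @ gru.W.T + r * ucp)
            C = (1.0 - n) * C_prev + n * c_tilde
            steps.append((r, n, ucp, c_tilde, C_prev, s_t))
            C_prev = C

        A1 = C_prev @ head.W_hidden.T + head.b_hidden
        Z1 = np.maximum(A1, 0.0)
        logits = Z1 @ head.W_out.T + head.b_out
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        P = e / e.sum(axis=1, keepdims=True)

        if cache is not None:
            cache.update(B1=B1, Tm=Tm, O1=O1, M2=M2, O2=O2, Hf=Hf,
                         steps=steps, C_final=C_prev, A1=A1, Z1=Z1, P=P)
        return P

    def loss_batch(self, P: np.ndarray, Y: np.ndarray, lambda_reg: float) -> float:
        """Mean cross entropy over the batch + (lambda/2) sum of squared weights."""
        p_true = np.clip((P * Y).sum(axis=1), 1e-12, None)
        ce = float(-np.log(p_true).mean())
        reg = 0.5 * lambda_reg * sum(float(np.sum(w * w)) for w in self.weight_matrices())
        return ce + reg

    # ------------------------------------------------------------------
    # backward
    # ------------------------------------------------------------------
    def backward(self, cache: dict, Y: np.ndarray, lambda_reg: float
                 ) -> dict[str, np.ndarray]:
        """Gradient of ``loss_batch`` w.r.t. every parameter."""
        enc, gru, head = self.encoder, self.gru, self.head
        P, Z1, A1 = cache["P"], cache["Z1"], cache["A1"]
        nB = P.shape[0]
        grads: dict[str, np.ndarray] = {}

        dlogits = (P - Y) / nB
        grads["W_out"] = dlogits.T @ Z1
        grads["b_out"] = dlogits.sum(axis=0)
        dA1 = (dlogits @ head.W_out) * (A1 > 0)
        grads["W_hidden"] = dA1.T @ cache["C_final"]
        grads["b_hidden"] = dA1.sum(axis=0)
        dC = dA1 @ head.W_hidden

        steps = cache["steps"]
        nT = len(steps)
        dS = np.zeros((nB, nT, gru.input_size))
        for name in ("W_r", "U_r", "W_z", "U_z", "W", "U"):
            grads[name] = np.zeros_like(getattr(gru, name))
        for t in range(nT - 1, -1, -1):
            r, n, ucp, c_tilde, c_prev, s_t = steps[t]
            dn = dC * (c_tilde - c_prev)
            dan = dn * n * (1.0 - n)
            dct = dC * n
            dac = dct * (1.0 - c_tilde**2)
            dr = dac * ucp
            dar = dr * r * (1.0 - r)
            dacr = dac * r
            grads["W_r"] += dar.T @ s_t
            grads["U_r"] += dar.T @ c_prev
            grads["W_z"] += dan.T @ s_t
            grads["U_z"] += dan.T @ c_prev
            grads["W"] += dac.T @ s_t
            grads["U"] += dacr.T @ c_prev
            dS[:, t] = dar @ gru.W_r + dan @ gru.W_z + dac @ gru.W
            dC = dC * (1.0 - n) + dan @ gru.U_z + dar @ gru.U_r + dacr @ gru.U

        Hf = cache["Hf"]
        flat_in = Hf.shape[-1]
        grads["fc_weights"] = Hf.reshape(-1, flat_in).T @ dS.reshape(-1, gru.input_size)
        grads["fc_bias"] = dS.sum(axis=(0, 1))
        dHf = dS @ enc.fc_weights.T
        dH2 = dHf.reshape(cache["O2"].shape)
        dO2 = dH2 * (cache["O2"] > 0)
        grads["theta_2"] = np.einsum("btkcg,btch->kgh", cache["M2"], dO2)
        # T_k(L~) is symmetric (polynomial of a symmetric matrix), so the
        # adjoint of M2 = Tm @ H1 reuses Tm directly
        tmp = np.einsum("btkij,btjh->btkih", cache["Tm"], dO2)
        dH1 = np.einsum("btkih,kgh->btig", tmp, enc.theta_2)
        dO1 = dH1 * (cache["O1"] > 0)
        grads["theta_1"] = np.einsum("btkcf,btcg->kfg", cache["B1"], dO1)

        if lambda_reg:
            for obj, name, is_w in self._param_spec():
                if is_w:
                    grads[name] = grads[name] + lambda_reg * getattr(obj, name)
        return grads


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, model: SeizureModel, learning_rate: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        params = model.parameters()
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        params = self.model.parameters()
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
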