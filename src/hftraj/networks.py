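"""Recurrent architectures for heart-failure trajectory modelling.

Three variants share a uniform stepwise contract (``init_state`` /
``step``), which both teacher-forced training and auto-regressive rollout
drive:

* ``dhtm`` — dense input layer, a stack of GRU blocks with pre-norm layer
  normalization and residual connections, and a sigmoid HFH output head.
* ``dhtm_c`` — a two-branch multi-task network: the first dense→GRU branch
  emits the three acute co-morbidity (CM) probabilities; its pre-sigmoid CM
  logits feed a second dense→GRU branch; both GRU outputs and the CM
  probabilities are concatenated into the HFH head. No residual connections
  or layer normalization (the auxiliary CM loss already supplies frequent
  gradient feedback).
* ``lstm`` — a plain stacked-LSTM baseline with the same dense-in /
  sigmoid-out wrapper and neither residual connections nor normalization.

All state and outputs flow through the in-package autodiff engine so the
same forward code serves prediction and gradient-based training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, matmul, sigmoid, tanh, transpose

VARIANTS = ("dhtm", "dhtm_c", "lstm")


class ContractError(ValueError):
    """An input violates an architectural precondition."""


@dataclass
class ModelSpec:
    """Architecture hyperparameters shared by every variant."""

    variant: str = "dhtm"
    hidden_width: int = 64
    n_recurrent_layers: int = 2
    use_residual: bool = True
    use_layer_norm: bool = True
    input_width: int = 20
    n_acute_cm: int = 3

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ContractError(f"unknown variant {self.variant!r}")
        if self.variant in ("dhtm_c", "lstm"):
            # these variants never use the DHTM-only stabilization tricks
            self.use_residual = False
            self.use_layer_norm = False
        if not 1 <= self.n_recurrent_layers <= 4:
            raise ContractError("n_recurrent_layers must be in 1..4")
        if self.hidden_width < 1 or self.input_width < 1:
            raise ContractError("widths must be positive")


@dataclass
class GruParams:
    """Gate weights over the concatenated [state, input] vector.

    Each weight matrix has ``hidden_width`` rows and
    ``hidden_width + input_width`` columns: ``z = σ(W_z [h, x] + b_z)``,
    ``r = σ(W_r [h, x] + b_r)``, ``h̃ = tanh(W_h [r⊙h, x] + b_h)`` and
    ``h' = (1 − z) ⊙ h + z ⊙ h̃``.
    """

    W_z: np.ndarray
    W_r: np.ndarray
    W_h: np.ndarray
    b_z: np.ndarray | None = None
    b_r: np.ndarray | None = None
    b_h: np.ndarray | None = None

    def validate(self) -> tuple[int, int]:
        H = self.W_z.shape[0]
        width = self.W_z.shape[1]
        for name in ("W_z", "W_r", "W_h"):
            W = getattr(self, name)
            if W.shape != (H, width):
                raise ContractError(f"{name} shape {W.shape} != ({H}, {width})")
        if width <= H:
            raise ContractError("columns must equal hidden + input width")
        return H, width - H


def gru_step(params: GruParams, h_prev: np.ndarray, x: np.ndarray) -> np.ndarray:
    """One gated-recurrent-unit update on plain numpy arrays.

    Accepts single vectors or ``(batch, width)`` arrays. Outputs stay
    strictly inside (−1, 1) whenever the previous state does, because the
    update is a convex combination of the previous state and a tanh term.
    """
    H, I = params.validate()
    squeeze = np.asarray(h_prev).ndim == 1
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=float))
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if h_prev.shape[1] != H:
        raise ContractError(f"h_prev width {h_prev.shape[1]} != hidden {H}")
    if x.shape[1] != I:
        raise ContractError(f"input width {x.shape[1]} != expected {I}")
    cell = _GruCell.from_params(params)
    out = cell.step(Tensor(h_prev), Tensor(x)).data
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# parameterized layers (autodiff Tensors)
# ---------------------------------------------------------------------------

def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int):
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class _Dense:
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = Tensor(_uniform_init(rng, (n_in, n_out), n_in), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x):
        return matmul(x, self.W) + self.b

    def params(self):
        return [self.W, self.b]


class _GruCell:
    """GRU gates stored in the (hidden, hidden+input) orientation."""

    def __init__(self, rng, n_in: int, hidden: int):
        width = hidden + n_in
        self.W_z = Tensor(_uniform_init(rng, (hidden, width), width), requires_grad=True)
        self.W_r = Tensor(_uniform_init(rng, (hidden, width), width), requires_grad=True)
        self.W_h = Tensor(_uniform_init(rng, (hidden, width), width), requires_grad=True)
        self.b_z = Tensor(np.zeros(hidden), requires_grad=True)
        self.b_r = Tensor(np.zeros(hidden), requires_grad=True)
        self.b_h = Tensor(np.zeros(hidden), requires_grad=True)
        self.hidden = hidden

    @classmethod
    def from_params(cls, params: GruParams) -> "_GruCell":
        H, I = params.validate()
        cell = cls.__new__(cls)
        cell.hidden = H
        for name in ("W_z", "W_r", "W_h"):
            setattr(cell, name, Tensor(getattr(params, name)))
        for name, H_ in (("b_z", H), ("b_r", H), ("b_h", H)):
            b = getattr(params, name)
            setattr(cell, name, Tensor(np.zeros(H_) if b is None else b))
        return cell

    def step(self, h, x):
        hx = concat([h, x], axis=1)
        z = sigmoid(matmul(hx, transpose(self.W_z)) + self.b_z)
        r = sigmoid(matmul(hx, transpose(self.W_r)) + self.b_r)
        rhx = concat([r * h, x], axis=1)
        h_tilde = tanh(matmul(rhx, transpose(self.W_h)) + self.b_h)
        return (1.0 - z) * h + z * h_tilde

    def params(self):
        return [self.W_z, self.W_r, self.W_h, self.b_z, self.b_r, self.b_h]


class _LstmCell:
    def __init__(self, rng, n_in: int, hidden: int):
        width = hidden + n_in
        init = lambda: Tensor(_uniform_init(rng, (hidden, width), width), requires_grad=True)
        self.W_i, self.W_f, self.W_o, self.W_c = init(), init(), init(), init()
        self.b_i = Tensor(np.zeros(hidden), requires_grad=True)
        # forget-gate bias starts at 1 so early training keeps cell memory
        self.b_f = Tensor(np.ones(hidden), requires_grad=True)
        self.b_o = Tensor(np.zeros(hidden), requires_grad=True)
        self.b_c = Tensor(np.zeros(hidden), requires_grad=True)
        self.hidden = hidden

    def step(self, state, x):
        h, c = state
        hx = concat([h, x], axis=1)
        i = sigmoid(matmul(hx, transpose(self.W_i)) + self.b_i)
        f = sigmoid(matmul(hx, transpose(self.W_f)) + self.b_f)
        o = sigmoid(matmul(hx, transpose(self.W_o)) + self.b_o)
        c_tilde = tanh(matmul(hx, transpose(self.W_c)) + self.b_c)
        c_new = f * c + i * c_tilde
        h_new = o * tanh(c_new)
        return (h_new, c_new)

    def params(self):
        return [self.W_i, self.W_f, self.W_o, self.W_c,
                self.b_i, self.b_f, self.b_o, self.b_c]


class _LayerNorm:
    def __init__(self, width: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(width), requires_grad=True)
        self.bias = Tensor(np.zeros(width), requires_grad=True)
        self.eps = eps

    def __call__(self, x):
        m = ad.tmean(x, axis=1, keepdims=True)
        centered = x - m
        var = ad.tmean(centered * centered, axis=1, keepdims=True)
        return centered / ad.sqrt(var + self.eps) * self.gain + self.bias

    def params(self):
        return [self.gain, self.bias]


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class _Network:
    """Common stepwise interface: init_state(batch) / step(state, x)."""

    spec: ModelSpec

    def params(self) -> list[Tensor]:
        raise NotImplementedError

    def init_state(self, batch: int):
        raise NotImplementedError

    def step(self, state, x: Tensor):
        """Advance one time step; returns (new_state, outputs dict)."""
        raise NotImplementedError

    def _check_input(self, x: Tensor):
        if x.data.ndim != 2 or x.data.shape[1] != self.spec.input_width:
            raise ContractError(
                f"expected (batch, {self.spec.input_width}) input, got {x.data.shape}"
            )


class DhtmNetwork(_Network):
    def __init__(self, spec: ModelSpec, seed: int = 0):
        assert spec.variant == "dhtm"
        self.spec = spec
        rng = np.random.default_rng(seed)
        H = spec.hidden_width
        self.dense_in = _Dense(rng, spec.input_width, H)
        self.grus = [_GruCell(rng, H, H) for _ in range(spec.n_recurrent_layers)]
        self.norms = (
            [_LayerNorm(H) for _ in range(spec.n_recurrent_layers)]
            if spec.use_layer_norm
            else [None] * spec.n_recurrent_layers
        )
        self.head = _Dense(rng, H, 1)

    def params(self):
        ps = self.dense_in.params() + self.head.params()
        for g in self.grus:
            ps += g.params()
        for n in self.norms:
            if n is not None:
                ps += n.params()
        return ps

    def init_state(self, batch: int):
        H = self.spec.hidden_width
        return [Tensor(np.zeros((batch, H))) for _ in self.grus]

    def step(self, state, x):
        self._check_input(x)
        u = self.dense_in(x)
        new_state = []
        for gru, norm, h_prev in zip(self.grus, self.norms, state):
            v = norm(u) if norm is not None else u
            h = gru.step(h_prev, v)
            new_state.append(h)
            u = (u + h) if self.spec.use_residual else h
        logit = self.head(u)
        return new_state, {"hf_logit": logit}


class DhtmcNetwork(_Network):
    def __init__(self, spec: ModelSpec, seed: int = 0):
        assert spec.variant == "dhtm_c"
        self.spec = spec
        rng = np.random.default_rng(seed)
        H, K = spec.hidden_width, spec.n_acute_cm
        self.dense_in = _Dense(rng, spec.input_width, H)
        self.gru1 = _GruCell(rng, H, H)
        self.cm_head = _Dense(rng, H, K)
        self.dense2 = _Dense(rng, K, H)
        self.gru2 = _GruCell(rng, H, H)
        self.head = _Dense(rng, 2 * H + K, 1)

    def params(self):
        return (
            self.dense_in.params() + self.gru1.params() + self.cm_head.params()
            + self.dense2.params() + self.gru2.params() + self.head.params()
        )

    def init_state(self, batch: int):
        H = self.spec.hidden_width
        return [Tensor(np.zeros((batch, H))), Tensor(np.zeros((batch, H)))]

    def step(self, state, x):
        self._check_input(x)
        h1_prev, h2_prev = state
        h1 = self.gru1.step(h1_prev, self.dense_in(x))
        cm_logits = self.cm_head(h1)
        cm_probs = sigmoid(cm_logits)
        h2 = self.gru2.step(h2_prev, self.dense2(cm_logits))
        logit = self.head(concat([h1, h2, cm_probs], axis=1))
        return [h1, h2], {"hf_logit": logit, "cm_logits": cm_logits,
                          "cm_probs": cm_probs}


class LstmNetwork(_Network):
    def __init__(self, spec: ModelSpec, seed: int = 0):
        assert spec.variant == "lstm"
        self.spec = spec
        rng = np.random.default_rng(seed)
        H = spec.hidden_width
        self.dense_in = _Dense(rng, spec.input_width, H)
        self.cells = [_LstmCell(rng, H, H) for _ in range(spec.n_recurrent_layers)]
        self.head = _Dense(rng, H, 1)

    def params(self):
        ps = self.dense_in.params() + self.head.params()
        for c in self.cells:
            ps += c.params()
        return ps

    def init_state(self, batch: int):
        H = self.spec.hidden_width
        return [
            (Tensor(np.zeros((batch, H))), Tensor(np.zeros((batch, H))))
            for _ in self.cells
        ]

    def step(self, state, x):
        self._check_input(x)
        u = self.dense_in(x)
        new_state = []
        for cell, st in zip(self.cells, state):
            st_new = cell.step(st, u)
            new_state.append(st_new)
            u = st_new[0]
        logit = self.head(u)
        return new_state, {"hf_logit": logit}


_NETWORK_CLASSES = {"dhtm": DhtmNetwork, "dhtm_c": DhtmcNetwork, "lstm": LstmNetwork}


def build_network(spec: ModelSpec, seed: int = 0) -> _Network:
    return _NETWORK_CLASSES[spec.variant](spec, seed)


@dataclass
class TrainedModel:
    """A fitted network plus the feature-encoding contract from training.

    ``input_mean`` / ``input_std`` record the per-column affine
    normalization fitted on the training split; every forward pass (and the
    auto-regressive rollout feedback) applies the same transform to raw
    inputs before the first dense layer.
    """

    spec: ModelSpec
    network: _Network
    feature_names: list[str] = field(default_factory=list)
    input_mean: np.ndarray | None = None
    input_std: np.ndarray | None = None

    def parameters(self) -> list[Tensor]:
        return self.network.params()

    def encode(self, x_raw: np.ndarray) -> np.ndarray:
        """Apply the training-time normalization to raw input vectors."""
        x = np.asarray(x_raw, dtype=float)
        if self.input_mean is None:
            return x
        return (x - self.input_mean) / self.input_std


def _run_sequence(model: TrainedModel, inputs: np.ndarray):
    inputs = np.asarray(inputs, dtype=float)
    single = inputs.ndim == 2
    if single:
        inputs = inputs[None]
    if inputs.ndim != 3 or inputs.shape[2] != model.spec.input_width:
        raise ContractError(
            f"expected (batch, T, {model.spec.input_width}) inputs, got {inputs.shape}"
        )
    inputs = model.encode(inputs)
    B, T, _ = inputs.shape
    state = model.network.init_state(B)
    outs = []
    for t in range(T):
        state, out = model.network.step(state, Tensor(inputs[:, t, :]))
        outs.append(out)
    return outs, single


def dhtm_forward(model: TrainedModel, inputs: np.ndarray) -> np.ndarray:
    """HFH probabilities per step for the dhtm (or lstm) variant.

    ``inputs`` is (T, 20) for one patient or (batch, T, 20); the output at
    position i is the predicted probability of HFH at step i+1 and depends
    only on inputs 0..i.
    """
    if model.spec.variant not in ("dhtm", "lstm"):
        raise ContractError(f"dhtm_forward requires dhtm/lstm, got {model.spec.variant}")
    outs, single = _run_sequence(model, inputs)
    probs = np.stack(
        [ad.sigmoid(o["hf_logit"]).data[:, 0] for o in outs], axis=1
    )
    return probs[0] if single else probs


def lstm_forward(model: TrainedModel, inputs: np.ndarray) -> np.ndarray:
    """Alias contract for the plain-LSTM baseline."""
    if model.spec.variant != "lstm":
        raise ContractError(f"lstm_forward requires lstm, got {model.spec.variant}")
    return dhtm_forward(model, inputs)


def dhtmc_forward(model: TrainedModel, inputs: np.ndarray):
    """(acute-CM probabilities, HFH probabilities) per step for dhtm_c.

    Returns ``(cm_probs, hf_probs)`` with shapes (T, 3) and (T,) for a
    single patient, or (batch, T, 3) and (batch, T).
    """
    if model.spec.variant != "dhtm_c":
        raise ContractError(f"dhtmc_forward requires dhtm_c, got {model.spec.variant}")
    outs, single = _run_sequence(model, inputs)
    hf = np.stack([ad.sigmoid(o["hf_logit"]).data[:, 0] for o in outs], axis=1)
    cm = np.stack([o["cm_probs"].data for o in outs], axis=1)
    return (cm[0], hf[0]) if single else (cm, hf)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

_PARAM_ORDER_NOTE = (
    "parameters are serialized in the order network.params() yields them"
)


def save_checkpoint(model: TrainedModel, path) -> None:
    """Single-archive checkpoint: spec + feature contract + named arrays."""
    meta = {
        "spec": asdict(model.spec),
        "feature_names": list(model.feature_names),
        "input_mean": None if model.input_mean is None else model.input_mean.tolist(),
        "input_std": None if model.input_std is None else model.input_std.tolist(),
        "note": _PARAM_ORDER_NOTE,
    }
    arrays = {f"param_{i:04d}": p.data for i, p in enumerate(model.parameters())}
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> TrainedModel:
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        spec = ModelSpec(**meta["spec"])
        network = build_network(spec, seed=0)
        params = network.params()
        for i, p in enumerate(params):
            data = archive[f"param_{i:04d}"]
            if data.shape != p.data.shape:
                raise ContractError(
                    f"checkpoint param {i} shape {data.shape} != expected {p.data.shape}"
                )
            p.data = data.astype(float)
    mean = meta.get("input_mean")
    std = meta.get("input_std")
    return TrainedModel(
        spec=spec,
        network=network,
        feature_names=meta["feature_names"],
        input_mean=None if mean is None else np.asarray(mean, dtype=float),
        input_std=None if std is None else np.asarray(std, dtype=float),
    )
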