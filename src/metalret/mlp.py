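"""From-scratch single-hidden-layer perceptron with an RPROP trainer.

The retention blocks are small feed-forward networks (7-5-1 or 6-5-1):
a hidden layer of hyperbolic-tangent units with curvature 0.7
(φ(x) = tanh(0.7·x)) and a single linear output.  Training is full-batch
resilient backpropagation (iRPROP−): each weight carries its own step
size, grown by η⁺ = 1.2 while the gradient keeps its sign and shrunk by
η⁻ = 0.5 on a sign flip, at which point the stored gradient is zeroed so
the direction update is skipped once.  Only gradient signs are used, so
the trainer is insensitive to the loss scale.

Errors follow the squared-deviation convention on the normalised output
scale: per example Err_i = (y_model − y_ref)², aggregated as the plain
arithmetic mean over the (training or test) set, with min and max
reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

SELU_LAMBDA = 1.0507
SELU_ALPHA = 1.6732

_KINDS = ("sigmoid", "tanh", "linear", "relu", "threshold", "selu")


@dataclass(frozen=True)
class ActivationSpec:
    """Activation function family with a slope multiplier.

    ``curvature`` b premultiplies the argument, φ(x) = base(b·x);
    ``gain`` a scales the linear kind, φ(x) = a·x.
    """

    kind: str = "tanh"
    curvature: float = 1.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown activation kind {self.kind!r}")
        if self.curvature <= 0:
            raise ValueError("curvature must be positive")


def activation_eval(
    spec: ActivationSpec, x: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """Value and analytic derivative of the activation, elementwise."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("activation input must be finite")
    z = spec.curvature * x
    b = spec.curvature
    if spec.kind == "sigmoid":
        s = 1.0 / (1.0 + np.exp(-z))
        return s, b * s * (1.0 - s)
    if spec.kind == "tanh":
        t = np.tanh(z)
        return t, b * (1.0 - t * t)
    if spec.kind == "linear":
        return spec.gain * z, np.full_like(x, spec.gain * b)
    if spec.kind == "relu":
        return np.maximum(z, 0.0), b * (z > 0).astype(float)
    if spec.kind == "threshold":
        return (z > 0).astype(float), np.zeros_like(x)
    # selu: λ·z for z>0, λ·α·(e^z − 1) otherwise
    pos = z > 0
    value = np.where(
        pos, SELU_LAMBDA * z, SELU_LAMBDA * SELU_ALPHA * (np.exp(np.minimum(z, 0.0)) - 1.0)
    )
    deriv = np.where(
        pos, SELU_LAMBDA * b, SELU_LAMBDA * SELU_ALPHA * np.exp(np.minimum(z, 0.0)) * b
    )
    return value, deriv


TANH_07 = ActivationSpec(kind="tanh", curvature=0.7)
LINEAR = ActivationSpec(kind="linear")


@dataclass
class MLPModel:
    """One retention block: input → hidden (tanh) → single output."""

    w_hidden: np.ndarray  # (n_hidden, n_inputs)
    b_hidden: np.ndarray  # (n_hidden,)
    w_out: np.ndarray  # (1, n_hidden)
    b_out: np.ndarray  # (1,)
    hidden_activation: ActivationSpec = TANH_07
    output_activation: ActivationSpec = LINEAR
    seed: int | None = None

    def __post_init__(self) -> None:
        self.w_hidden = np.asarray(self.w_hidden, dtype=float)
        self.b_hidden = np.asarray(self.b_hidden, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        self.b_out = np.asarray(self.b_out, dtype=float)
        h, p = self.w_hidden.shape
        if self.b_hidden.shape != (h,) or self.w_out.shape != (1, h) or (
            self.b_out.shape != (1,)
        ):
            raise ValueError("inconsistent layer shapes")

    @property
    def n_inputs(self) -> int:
        return self.w_hidden.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.w_hidden.shape[0]

    def params(self) -> dict[str, np.ndarray]:
        return {
            "w_hidden": self.w_hidden,
            "b_hidden": self.b_hidden,
            "w_out": self.w_out,
            "b_out": self.b_out,
        }

    def copy(self) -> "MLPModel":
        return MLPModel(
            w_hidden=self.w_hidden.copy(),
            b_hidden=self.b_hidden.copy(),
            w_out=self.w_out.copy(),
            b_out=self.b_out.copy(),
            hidden_activation=self.hidden_activation,
            output_activation=self.output_activation,
            seed=self.seed,
        )


def init_network(
    n_inputs: int,
    n_hidden: int = 5,
    seed: int | None = None,
    hidden_activation: ActivationSpec = TANH_07,
    output_activation: ActivationSpec = LINEAR,
) -> MLPModel:
    """Fresh block with weights uniform on [−0.5, 0.5] and zero biases."""
    if n_inputs < 1 or n_hidden < 1:
        raise ValueError("layer sizes must be positive")
    rng = np.random.default_rng(seed)
    return MLPModel(
        w_hidden=rng.uniform(-0.5, 0.5, size=(n_hidden, n_inputs)),
        b_hidden=np.zeros(n_hidden),
        w_out=rng.uniform(-0.5, 0.5, size=(1, n_hidden)),
        b_out=np.zeros(1),
        hidden_activation=hidden_activation,
        output_activation=output_activation,
        seed=seed,
    )


def forward(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Network output for a batch (or single vector) of inputs."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X2 = np.atleast_2d(X)
    if X2.shape[1] != model.n_inputs:
        raise ValueError(
            f"expected {model.n_inputs} inputs, got {X2.shape[1]}"
        )
    hidden, _ = activation_eval(
        model.hidden_activation, X2 @ model.w_hidden.T + model.b_hidden
    )
    out, _ = activation_eval(
        model.output_activation, hidden @ model.w_out.T + model.b_out
    )
    y = out[:, 0]
    return float(y[0]) if single else y


def gradient(
    model: MLPModel, X: np.ndarray, y: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean-squared-error loss and its gradient w.r.t. every parameter.

    Loss = (1/N)·Σ (y_model − y_ref)², no ½ factor, matching the error
    convention used for reporting.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n == 0:
        raise ValueError("empty batch")
    if X.shape != (n, model.n_inputs):
        raise ValueError("batch shapes disagree")

    pre_h = X @ model.w_hidden.T + model.b_hidden  # (n, h)
    act_h, dact_h = activation_eval(model.hidden_activation, pre_h)
    pre_o = act_h @ model.w_out.T + model.b_out  # (n, 1)
    act_o, dact_o = activation_eval(model.output_activation, pre_o)

    resid = act_o[:, 0] - y
    loss = float(np.mean(resid**2))

    # d(loss)/d(pre_o): 2·resid/N times output-activation slope
    delta_o = (2.0 / n) * resid[:, None] * dact_o  # (n, 1)
    g_w_out = delta_o.T @ act_h  # (1, h)
    g_b_out = delta_o.sum(axis=0)  # (1,)
    delta_h = (delta_o @ model.w_out) * dact_h  # (n, h)
    g_w_hidden = delta_h.T @ X  # (h, p)
    g_b_hidden = delta_h.sum(axis=0)  # (h,)
    return loss, {
        "w_hidden": g_w_hidden,
        "b_hidden": g_b_hidden,
        "w_out": g_w_out,
        "b_out": g_b_out,
    }


@dataclass
class RpropConfig:
    """Resilient-backpropagation hyperparameters.

    η⁻ (descent step) halves the per-weight step on a gradient sign flip;
    η⁺ (split factor) grows it while the sign persists; Δ₀ is the common
    initial step.  Steps are clamped to [Δ_min, Δ_max] at all times.
    """

    eta_minus: float = 0.5
    eta_plus: float = 1.2
    delta_init: float = 0.5
    delta_min: float = 1e-6
    delta_max: float = 50.0
    epochs: int = 10_000

    def __post_init__(self) -> None:
        if not (0 < self.eta_minus < 1 < self.eta_plus):
            raise ValueError("need 0 < eta_minus < 1 < eta_plus")
        if not (0 < self.delta_min <= self.delta_init <= self.delta_max):
            raise ValueError("need delta_min <= delta_init <= delta_max")
        if self.epochs < 1:
            raise ValueError("epochs must be positive")


@dataclass
class RpropState:
    """Per-weight adaptive step sizes and previous gradient signs."""

    steps: dict[str, np.ndarray]
    prev_grad: dict[str, np.ndarray]

    @classmethod
    def for_params(
        cls, params: dict[str, np.ndarray], config: RpropConfig
    ) -> "RpropState":
        return cls(
            steps={k: np.full_like(v, config.delta_init) for k, v in params.items()},
            prev_grad={k: np.zeros_like(v) for k, v in params.items()},
        )


def rprop_step(
    params: dict[str, np.ndarray],
    grads: dict[str, np.ndarray],
    state: RpropState,
    config: RpropConfig,
) -> None:
    """One iRPROP− update, in place.

    Sign agreement with the previous gradient grows the step by η⁺;
    disagreement shrinks it by η⁻ and zeroes the stored gradient so the
    weight is not moved in that coordinate this iteration.
    """
    for name, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in {name}")
        step = state.steps[name]
        prev = state.prev_grad[name]
        prod = prev * g
        np.minimum(
            np.where(prod > 0, step * config.eta_plus, step),
            config.delta_max,
            out=step,
        )
        np.maximum(
            np.where(prod < 0, step * config.eta_minus, step),
            config.delta_min,
            out=step,
        )
        g_eff = np.where(prod < 0, 0.0, g)
        params[name] -= np.sign(g_eff) * step
        state.prev_grad[name] = g_eff


def train(
    model: MLPModel,
    X: np.ndarray,
    y: np.ndarray,
    config: RpropConfig | None = None,
) -> tuple[MLPModel, np.ndarray]:
    """Full-batch RPROP training; returns the best-epoch model and history.

    The per-epoch history records the training error before each update
    (length = epochs).  RPROP does not guarantee monotone descent, so the
    weights with the lowest training error seen — including after the
    final update — are the ones returned.
    """
    config = config or RpropConfig()
    model = model.copy()
    params = model.params()
    state = RpropState.for_params(params, config)
    history = np.empty(config.epochs)
    best_loss = math.inf
    best_params = {k: v.copy() for k, v in params.items()}
    for epoch in range(config.epochs):
        loss, grads = gradient(model, X, y)
        if not math.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        history[epoch] = loss
        if loss < best_loss:
            best_loss = loss
            best_params = {k: v.copy() for k, v in params.items()}
        rprop_step(params, grads, state, config)
    final_loss, _ = gradient(model, X, y)
    if final_loss < best_loss:
        best_params = params
    for k, v in best_params.items():
        params[k][...] = v
    return model, history


@dataclass(frozen=True)
class ErrorReport:
    """Per-example squared errors with their mean, min, and max."""

    per_example: np.ndarray
    mean: float
    min: float
    max: float
    n: int

    @classmethod
    def from_residuals(cls, residuals: np.ndarray) -> "ErrorReport":
        errs = np.asarray(residuals, dtype=float) ** 2
        if errs.size == 0:
            raise ValueError("empty residual vector")
        return cls(
            per_example=errs,
            mean=float(errs.mean()),
            min=float(errs.min()),
            max=float(errs.max()),
            n=int(errs.size),
        )


def evaluate(model: MLPModel, X: np.ndarray, y: np.ndarray) -> ErrorReport:
    """Squared-error report of the model on a (normalised) dataset."""
    y = np.asarray(y, dtype=float).ravel()
    pred = np.atleast_1d(forward(model, X))
    return ErrorReport.from_residuals(pred - y)
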