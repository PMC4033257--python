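"""Simple recurrent (Elman) network forward model.

The network predicts the next COG patch from the current patch, a copy
of the previous hidden activations (context units), and the normalized
(x, y) coordinates of the upcoming fixation.  At full size the input
layer has 2083 units (1681 patch pixels + 400 context + 2 coordinates),
the hidden layer 400 units and the output layer 1681 units; logistic
activations throughout and all biases fixed at zero.  Training is
pattern-wise backprop on a half-sum-of-squares loss with learning rate
0.1; RMSE per output pixel is the reported metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .cog import COGSequence

__all__ = [
    "SRNWeights",
    "SRNConfig",
    "init_weights",
    "initial_state",
    "forward_step",
    "loss_gradients",
    "train_step",
    "run_sequence",
    "CONTEXT_INIT",
]

CONTEXT_INIT = 0.5


@dataclass
class SRNWeights:
    """Input->hidden and hidden->output weight matrices (no bias terms)."""

    w1: np.ndarray  # (n_pixels + n_hidden + 2, n_hidden)
    w2: np.ndarray  # (n_hidden, n_pixels)

    def __post_init__(self) -> None:
        n_in, n_hidden = self.w1.shape
        if self.w2.shape[0] != n_hidden:
            raise ValueError("w1/w2 hidden dimensions disagree")
        if n_in != self.w2.shape[1] + n_hidden + 2:
            raise ValueError("input size must be n_pixels + n_hidden + 2")

    @property
    def n_hidden(self) -> int:
        return self.w1.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.w2.shape[1]

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[0]

    def copy(self) -> "SRNWeights":
        return SRNWeights(self.w1.copy(), self.w2.copy())


@dataclass(frozen=True)
class SRNConfig:
    """Training hyper-parameters."""

    learning_rate: float = 0.1
    n_hidden: int = 400
    reset_interval: int | None = None  # None = canonical full recurrence
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


def init_weights(seed: int, n_pixels: int = 1681, n_hidden: int = 400) -> SRNWeights:
    """Uniform(0, 1) weights divided by the fan-in of the receiving layer."""
    rng = np.random.default_rng(seed)
    n_in = n_pixels + n_hidden + 2
    w1 = rng.random((n_in, n_hidden)) / n_in
    w2 = rng.random((n_hidden, n_pixels)) / n_hidden
    return SRNWeights(w1=w1, w2=w2)


def initial_state(n_hidden: int = 400) -> np.ndarray:
    """Fresh context vector: all units at 0.5."""
    return np.full(n_hidden, CONTEXT_INIT)


def _input_vector(w: SRNWeights, sample: np.ndarray, state: np.ndarray,
                  coords_next) -> np.ndarray:
    sample = np.asarray(sample, dtype=float).ravel()
    state = np.asarray(state, dtype=float).ravel()
    if sample.size != w.n_pixels:
        raise ValueError(f"sample has {sample.size} pixels, expected {w.n_pixels}")
    if state.size != w.n_hidden:
        raise ValueError(f"context has {state.size} units, expected {w.n_hidden}")
    coords = np.asarray(coords_next, dtype=float).ravel()
    if coords.size != 2:
        raise ValueError("coords_next must have two components")
    return np.concatenate([sample, state, coords])


def forward_step(w: SRNWeights, sample: np.ndarray, state: np.ndarray,
                 coords_next) -> tuple[np.ndarray, np.ndarray]:
    """One forward pass; returns (predicted next patch, new context)."""
    x = _input_vector(w, sample, state, coords_next)
    hidden = expit(x @ w.w1)
    output = expit(hidden @ w.w2)
    return output, hidden.copy()


def loss_gradients(w: SRNWeights, sample, state, coords_next, target):
    """Analytic gradients of 1/2 * sum((output - target)^2).

    Returns (grad_w1, grad_w2, output, hidden).  The context is treated
    as a fixed input (no backprop through time).
    """
    x = _input_vector(w, sample, state, coords_next)
    hidden = expit(x @ w.w1)
    output = expit(hidden @ w.w2)
    target = np.asarray(target, dtype=float).ravel()
    if target.size != w.n_pixels:
        raise ValueError("target size mismatch")
    delta_out = (output - target) * output * (1.0 - output)
    grad_w2 = np.outer(hidden, delta_out)
    delta_hidden = (w.w2 @ delta_out) * hidden * (1.0 - hidden)
    grad_w1 = np.outer(x, delta_hidden)
    return grad_w1, grad_w2, output, hidden


def train_step(w: SRNWeights, sample, state, coords_next, target,
               lr: float = 0.1) -> tuple[SRNWeights, float, np.ndarray]:
    """One pattern-wise gradient step; weights are updated in place.

    Returns (weights, rmse, new context), the context coming from the
    pre-update forward pass.
    """
    grad_w1, grad_w2, output, hidden = loss_gradients(w, sample, state,
                                                      coords_next, target)
    target = np.asarray(target, dtype=float).ravel()
    rmse = float(np.sqrt(np.mean((output - target) ** 2)))
    if not np.isfinite(rmse):
        raise FloatingPointError("non-finite prediction error")
    w.w1 -= lr * grad_w1
    w.w2 -= lr * grad_w2
    return w, rmse, hidden.copy()


def run_sequence(w: SRNWeights, seq: COGSequence, mode: str = "train",
                 reset_interval: int | None = None, lr: float = 0.1
                 ) -> tuple[float, SRNWeights]:
    """Present one COG sequence and return (mean per-pattern RMSE, weights).

    The context starts at 0.5.  Sample t is presented with the
    coordinates of sample t+1; the target is sample t+1's patch; the last
    sample is never presented as input.  With ``reset_interval`` k, the
    context is reset to 0.5 after every k presented samples (before the
    next presentation).  In test mode the weights are left untouched.
    """
    if mode not in ("train", "test"):
        raise ValueError("mode must be 'train' or 'test'")
    L = len(seq)
    if L < 2:
        raise ValueError("sequence must contain at least 2 samples")
    if reset_interval is not None and reset_interval < 1:
        raise ValueError("reset_interval must be >= 1")

    patches = seq.patches.reshape(L, -1).astype(float)
    state = initial_state(w.n_hidden)
    total = 0.0
    for t in range(L - 1):
        if reset_interval is not None and t > 0 and t % reset_interval == 0:
            state = initial_state(w.n_hidden)
        if mode == "train":
            w, rmse, state = train_step(w, patches[t], state, seq.coords[t + 1],
                                        patches[t + 1], lr=lr)
        else:
            output, state = forward_step(w, patches[t], state, seq.coords[t + 1])
            rmse = float(np.sqrt(np.mean((output - patches[t + 1]) ** 2)))
        total += rmse
    return total / (L - 1), w
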