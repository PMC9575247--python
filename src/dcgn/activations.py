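"""Elementwise activation functions and their derivatives.

The network's default nonlinearity is the Gaussian Error Linear Unit
(GELU), ``x * Phi(x)`` with ``Phi`` the standard normal CDF.  Two forms are
provided: the exact one via the error function, and the widely used tanh
approximation ``0.5*x*(1 + tanh(sqrt(2/pi)*(x + 0.044715*x**3)))``.  relu,
elu and tanh are included for activation-comparison experiments.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr
from scipy.stats import norm

_TANH_C = np.sqrt(2.0 / np.pi)
_TANH_A = 0.044715


def gelu_exact(x: np.ndarray) -> np.ndarray:
    """Exact GELU: ``x * Phi(x)`` with Phi the N(0,1) CDF."""
    x = np.asarray(x, dtype=float)
    return x * ndtr(x)


def gelu_exact_grad(x: np.ndarray) -> np.ndarray:
    """d/dx [x*Phi(x)] = Phi(x) + x*phi(x)."""
    x = np.asarray(x, dtype=float)
    return ndtr(x) + x * norm.pdf(x)


def gelu_approx(x: np.ndarray) -> np.ndarray:
    """Tanh approximation of GELU."""
    x = np.asarray(x, dtype=float)
    inner = _TANH_C * (x + _TANH_A * x**3)
    return 0.5 * x * (1.0 + np.tanh(inner))


def gelu_approx_grad(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    inner = _TANH_C * (x + _TANH_A * x**3)
    t = np.tanh(inner)
    dinner = _TANH_C * (1.0 + 3.0 * _TANH_A * x**2)
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def relu_grad(x: np.ndarray) -> np.ndarray:
    return (np.asarray(x, dtype=float) > 0.0).astype(float)


def elu(x: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0.0, x, alpha * np.expm1(x))


def elu_grad(x: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0.0, 1.0, alpha * np.exp(x))


def tanh(x: np.ndarray) -> np.ndarray:
    return np.tanh(np.asarray(x, dtype=float))


def tanh_grad(x: np.ndarray) -> np.ndarray:
    return 1.0 - np.tanh(np.asarray(x, dtype=float)) ** 2


def linear(x: np.ndarray) -> np.ndarray:
    return np.asarray(x, dtype=float)


def linear_grad(x: np.ndarray) -> np.ndarray:
    return np.ones_like(np.asarray(x, dtype=float))


#: activation name -> (function, derivative)
ACTIVATIONS = {
    "gelu_exact": (gelu_exact, gelu_exact_grad),
    "gelu_approx": (gelu_approx, gelu_approx_grad),
    "relu": (relu, relu_grad),
    "elu": (elu, elu_grad),
    "tanh": (tanh, tanh_grad),
    "linear": (linear, linear_grad),
}


def activation_apply(kind: str, x: np.ndarray) -> np.ndarray:
    """Apply the activation named ``kind`` elementwise.

    Raises
    ------
    ValueError
        If ``kind`` is not a known activation name.
    """
    try:
        fn, _ = ACTIVATIONS[kind]
    except KeyError:
        raise ValueError(
            f"unknown activation {kind!r}; expected one of {sorted(ACTIVATIONS)}"
        ) from None
    return fn(x)


def activation_grad(kind: str, x: np.ndarray) -> np.ndarray:
    """Elementwise derivative of the activation named ``kind`` at ``x``."""
    try:
        _, grad = ACTIVATIONS[kind]
    except KeyError:
        raise ValueError(
            f"unknown activation {kind!r}; expected one of {sorted(ACTIVATIONS)}"
        ) from None
    return grad(x)
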