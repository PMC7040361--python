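"""Mercer kernels for the kernel recursive least squares predictor."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KernelSpec", "kernel_eval", "kernel_vector", "gram_matrix"]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice and hyperparameters.

    gaussian:   k(x, x') = exp(-||x - x'||^2 / (2 sigma^2))
    polynomial: k(x, x') = (x.x' + c)^p          (c >= 0, integer p >= 1)
    sigmoid:    k(x, x') = tanh(s * x.x' + t)    (s, t >= 0)

    All scale parameters default to 1.
    """

    kind: str = "gaussian"
    sigma: float = 1.0
    c: float = 1.0
    p: int = 1
    s: float = 1.0
    t: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "polynomial", "sigmoid"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "gaussian" and self.sigma == 0:
            raise ValueError("gaussian kernel requires sigma != 0")
        if self.kind == "polynomial":
            if self.c < 0:
                raise ValueError("polynomial kernel requires c >= 0")
            if int(self.p) != self.p or self.p < 1:
                raise ValueError("polynomial kernel requires integer p >= 1")
        if self.kind == "sigmoid" and (self.s < 0 or self.t < 0):
            raise ValueError("sigmoid kernel requires s, t >= 0")


def kernel_eval(spec: KernelSpec, x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("kernel arguments must have equal shape")
    return float(_apply(spec, x[None, :], y)[0])


def _apply(spec: KernelSpec, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Kernel between each row of X and the single vector y."""
    if spec.kind == "gaussian":
        d2 = np.sum((X - y[None, :]) ** 2, axis=1)
        return np.exp(-d2 / (2.0 * spec.sigma**2))
    if spec.kind == "polynomial":
        return (X @ y + spec.c) ** spec.p
    return np.tanh(spec.s * (X @ y) + spec.t)


def kernel_vector(spec: KernelSpec, dictionary: np.ndarray, x: np.ndarray) -> np.ndarray:
    """[k(d_1, x), ..., k(d_m, x)] for the dictionary rows."""
    if dictionary.size == 0:
        return np.zeros(0)
    return _apply(spec, dictionary, np.asarray(x, dtype=float))


def gram_matrix(spec: KernelSpec, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.stack([_apply(spec, X, X[i]) for i in range(X.shape[0])], axis=0)
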