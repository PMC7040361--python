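"""Online estimators: exponentially weighted RLS and KRLS with ALD.

The kernel recursive least squares (KRLS) recursion maintains the exact
kernel ridge regression solution over the samples seen so far: with Gram
matrix K_k over the dictionary and ridge R*lambda,

    a(k) = (K_k + R*lambda*I)^(-1) y(1:k),    Q(k) = (K_k + R*lambda*I)^(-1),

grown one rank at a time via the block-inverse (Schur complement) update.
The approximate-linear-dependency (ALD) criterion keeps the dictionary
sparse: a new regressor whose projection residual delta onto the dictionary's
feature-space span falls below a threshold nu updates the coefficients
without being admitted (the standard dictionary-fixed ALD update, which
tracks the least-squares solution over ALL samples while storing only the
novel ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelSpec, kernel_eval, kernel_vector

__all__ = ["RlsState", "rls_update", "rls_predict", "KrlsState", "krls_init", "krls_update", "krls_predict"]


# --------------------------------------------------------------------------
# RLS
# --------------------------------------------------------------------------


@dataclass
class RlsState:
    """Exponentially weighted recursive least squares state.

    theta starts at zero and P at ``p0 * I`` (large p0 ~ uninformative
    prior); ``lam`` in (0, 1] is the forgetting factor.
    """

    theta: np.ndarray
    P: np.ndarray
    lam: float = 0.98

    @classmethod
    def initialize(cls, dim: int, lam: float = 0.98, p0: float = 1e6) -> "RlsState":
        if not 0 < lam <= 1:
            raise ValueError("forgetting factor must be in (0, 1]")
        return cls(theta=np.zeros(dim), P=p0 * np.eye(dim), lam=lam)


def rls_predict(state: RlsState, phi: np.ndarray) -> float:
    return float(state.theta @ phi)


def rls_update(state: RlsState, phi: np.ndarray, y: float) -> tuple[RlsState, float, float]:
    """One RLS step; returns (state, prediction-before-update, error).

    g = P phi / (lam + phi' P phi);  theta += g e;  P = (P - g phi' P)/lam.
    """
    phi = np.asarray(phi, dtype=float)
    if not (np.all(np.isfinite(phi)) and np.isfinite(y)):
        raise ValueError("non-finite input to rls_update")
    if phi.shape != state.theta.shape:
        raise ValueError("regressor length does not match state dimension")
    y_hat = float(state.theta @ phi)
    e = float(y) - y_hat
    Pphi = state.P @ phi
    denom = state.lam + phi @ Pphi
    g = Pphi / denom
    state.theta = state.theta + g * e
    state.P = (state.P - np.outer(g, Pphi)) / state.lam
    state.P = 0.5 * (state.P + state.P.T)  # keep symmetric against round-off
    return state, y_hat, e


# --------------------------------------------------------------------------
# KRLS with ALD sparsification
# --------------------------------------------------------------------------


@dataclass
class KrlsState:
    """Kernel RLS state: dictionary, coefficients a, regularized inverse Gram Q.

    ``P`` is the auxiliary covariance used by the dictionary-fixed ALD
    update; ``ald_threshold`` (nu) <= 0 disables sparsification so every
    sample grows the dictionary. ``dict_cap`` bounds the dictionary size:
    once reached, further samples take the reduced update regardless of
    their novelty.
    """

    dictionary: np.ndarray  # (m, dim) retained regressors
    a: np.ndarray  # (m,) coefficients
    Q: np.ndarray  # (m, m) regularized inverse Gram
    P: np.ndarray  # (m, m) auxiliary covariance for reduced updates
    kernel: KernelSpec
    lam: float = 0.98
    reg: float = 1e-8
    ald_threshold: float = 1e-4
    dict_cap: int | None = 500
    n_seen: int = 1

    @property
    def dict_size(self) -> int:
        return len(self.a)

    @property
    def ridge(self) -> float:
        return self.reg * self.lam


def krls_init(
    phi: np.ndarray,
    y: float,
    kernel: KernelSpec | None = None,
    *,
    reg: float = 1e-8,
    lam: float = 0.98,
    ald_threshold: float = 1e-4,
    dict_cap: int | None = 500,
) -> KrlsState:
    """First-sample state: Q(1) = [R lam + k(phi,phi)]^-1, a(1) = Q(1) y(1)."""
    kernel = kernel or KernelSpec()
    phi = np.asarray(phi, dtype=float)
    if not (np.all(np.isfinite(phi)) and np.isfinite(y)):
        raise ValueError("non-finite input to krls_init")
    if not 0 < lam <= 1:
        raise ValueError("forgetting factor must be in (0, 1]")
    if reg <= 0:
        raise ValueError("regularizer R must be positive")
    k11 = kernel_eval(kernel, phi, phi)
    denom = reg * lam + k11
    if denom <= 0:
        raise ValueError(f"R*lam + k(phi,phi) = {denom} is not positive")
    q = 1.0 / denom
    return KrlsState(
        dictionary=phi[None, :].copy(),
        a=np.array([q * y]),
        Q=np.array([[q]]),
        P=np.array([[1.0]]),
        kernel=kernel,
        lam=lam,
        reg=reg,
        ald_threshold=ald_threshold,
        dict_cap=dict_cap,
    )


def krls_predict(state: KrlsState, phi: np.ndarray) -> float:
    """y_hat = sum_j a_j k(dict_j, phi)."""
    return float(state.a @ kernel_vector(state.kernel, state.dictionary, phi))


def krls_update(state: KrlsState, phi: np.ndarray, y: float) -> tuple[KrlsState, float, float]:
    """One KRLS step; returns (state, prediction-before-update, error e(k)).

    K(k) is the kernel vector against the dictionary, z = Q K the projection
    coefficients, delta = R lam + k(phi,phi) - z'K the projection residual.
    Novel samples (delta > nu, dictionary under cap) grow Q and a by the
    rank-one block-inverse update; dependent samples take the reduced
    dictionary-fixed update.
    """
    phi = np.asarray(phi, dtype=float)
    if not (np.all(np.isfinite(phi)) and np.isfinite(y)):
        raise ValueError("non-finite input to krls_update")
    K = kernel_vector(state.kernel, state.dictionary, phi)
    z = state.Q @ K
    kxx = kernel_eval(state.kernel, phi, phi)
    delta = state.ridge + kxx - z @ K
    y_hat = float(K @ state.a)
    e = float(y) - y_hat

    grow = delta > state.ald_threshold
    if state.dict_cap is not None and state.dict_size >= state.dict_cap:
        grow = False
    if grow:
        if delta <= 0:
            raise FloatingPointError(
                f"degenerate projection residual delta={delta:.3e} while growing the "
                f"dictionary (size {state.dict_size}); increase R or the ALD threshold"
            )
        m = state.dict_size
        Q_new = np.empty((m + 1, m + 1))
        Q_new[:m, :m] = state.Q + np.outer(z, z) / delta
        Q_new[:m, m] = -z / delta
        Q_new[m, :m] = -z / delta
        Q_new[m, m] = 1.0 / delta
        a_new = np.empty(m + 1)
        a_new[:m] = state.a - z * (e / delta)
        a_new[m] = e / delta
        P_new = np.zeros((m + 1, m + 1))
        P_new[:m, :m] = state.P
        P_new[m, m] = 1.0
        state.dictionary = np.vstack([state.dictionary, phi])
        state.Q = Q_new
        state.a = a_new
        state.P = P_new
    else:
        # dictionary-fixed ALD update: phi ~ sum_j z_j dict_j in feature space
        Pz = state.P @ z
        q = Pz / (1.0 + z @ Pz)
        state.P = state.P - np.outer(q, Pz)
        state.a = state.a + (state.Q @ q) * e
    state.n_seen += 1
    return state, y_hat, e
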