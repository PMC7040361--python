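"""q-step-ahead prediction of ΔHbO/ΔHbR and %FIT evaluation.

Brain activity per channel is modelled as a low-order ARX form

    y(k) = sum_n a_n y(k-n) + sum_m b_m u(k-m) + c_o + e(k)

with the dHRF u as input (exogenous physiological regressors are supported
in the regressor builder but excluded by default). Coefficients are
estimated online by RLS or KRLS-ALD. Multi-step prediction uses the DIRECT
strategy: a separate predictor per horizon q is trained on the pairs
(phi(k), y(k+q)), which is causal — the regressor at time k only contains
values observed by time k. An ITERATED strategy (feeding predictions back
into the output lags of a one-step model) is available via ``strategy``.

Accuracy is scored with the percentage-fit criterion

    %FIT = 100 * (1 - sum (y - y_hat)^2 / sum (y - mean(y))^2),

i.e. percent of variance captured (an NRMSE-style rooted variant is
available); %FIT <= 100, and is undefined for a constant measured series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .estimators import (
    KrlsState,
    RlsState,
    krls_init,
    krls_predict,
    krls_update,
    rls_predict,
    rls_update,
)
from .hrf import DhrfSeries
from .kernels import KernelSpec
from .record import FnirsRecord

__all__ = [
    "ModelOrders",
    "PredictorConfig",
    "PredictionResult",
    "DegenerateSignalError",
    "build_regressor",
    "percent_fit",
    "horizon_seconds",
    "predict_series",
    "fit_predict_q",
    "SignalPredictionModel",
    "PredictionResults",
]


class DegenerateSignalError(ValueError):
    """Measured series has zero variance; %FIT is undefined."""


def horizon_seconds(q: int, fs: float, *, decimals: int = 2) -> float:
    """Horizon length q/fs in seconds, truncated (not rounded) to ``decimals``.

    Truncation is the reporting convention for horizon labels (e.g. q=20 at
    9.19 Hz is 2.176 s, labelled 2.17 s).
    """
    scale = 10.0**decimals
    return float(np.trunc(q / fs * scale) / scale)


@dataclass(frozen=True)
class ModelOrders:
    """ARX orders: output lags n_o, input lags m_o, exogenous lags p_o."""

    n_o: int = 1
    m_o: int = 1
    p_o: int = 0

    def __post_init__(self) -> None:
        if self.n_o < 0 or self.m_o < 0 or self.p_o < 0:
            raise ValueError("model orders must be nonnegative")

    @property
    def dim(self) -> int:
        return self.n_o + self.m_o + self.p_o + 1


@dataclass(frozen=True)
class PredictorConfig:
    """Estimator choice and hyperparameters (defaults match the study settings)."""

    model: str = "krls"  # "rls" | "krls"
    kernel: KernelSpec = field(default_factory=KernelSpec)
    orders: ModelOrders = field(default_factory=ModelOrders)
    lam: float = 0.98
    reg: float = 1e-8
    ald_threshold: float = 1e-4
    dict_cap: int | None = 500
    strategy: str = "direct"  # "direct" | "iterated"
    rls_p0: float = 1e6

    def __post_init__(self) -> None:
        if self.model not in ("rls", "krls"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.strategy not in ("direct", "iterated"):
            raise ValueError(f"unknown strategy {self.strategy!r}")

    @property
    def tag(self) -> str:
        return self.model if self.model == "rls" else f"krls-{self.kernel.kind}"


@dataclass
class PredictionResult:
    """Aligned prediction for one (channel, chromophore, horizon)."""

    channel: int
    chromophore: str
    model: str
    q: int
    y_pred: np.ndarray
    y_true: np.ndarray
    fit_pct: float | None
    degenerate: bool = False
    dict_size: int | None = None


def build_regressor(
    y_history: np.ndarray,
    u_history: np.ndarray,
    orders: ModelOrders,
    k: int,
    w_history: np.ndarray | None = None,
) -> np.ndarray:
    """phi(k) = [y(k-1)..y(k-n_o), u(k-1)..u(k-m_o), w lags, 1].

    Lags reaching before the start of the histories are zero-padded.
    """
    if k < 0:
        raise ValueError("sample index must be nonnegative")
    phi = np.zeros(orders.dim)
    pos = 0
    for n in range(1, orders.n_o + 1):
        if 0 <= k - n < len(y_history):
            phi[pos] = y_history[k - n]
        pos += 1
    for m in range(1, orders.m_o + 1):
        if 0 <= k - m < len(u_history):
            phi[pos] = u_history[k - m]
        pos += 1
    for p in range(1, orders.p_o + 1):
        if w_history is not None and 0 <= k - p < len(w_history):
            phi[pos] = w_history[k - p]
        pos += 1
    phi[-1] = 1.0
    return phi


def percent_fit(y: np.ndarray, y_hat: np.ndarray, *, variant: str = "plain") -> float:
    """Percentage fit of y_hat to y.

    ``plain``: 100*(1 - SS_res/SS_tot); ``nrmse``: 100*(1 - sqrt(SS_res/SS_tot)).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("series must have equal length")
    if len(y) < 2:
        raise ValueError("need at least two samples")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateSignalError("measured series is constant; %FIT undefined")
    ratio = float(np.sum((y - y_hat) ** 2)) / ss_tot
    if variant == "plain":
        return 100.0 * (1.0 - ratio)
    if variant == "nrmse":
        return 100.0 * (1.0 - np.sqrt(ratio))
    raise ValueError(f"unknown %FIT variant {variant!r}")


def _make_state(config: PredictorConfig, phi0: np.ndarray, y0: float):
    if config.model == "rls":
        state = RlsState.initialize(config.orders.dim, lam=config.lam, p0=config.rls_p0)
        return rls_update(state, phi0, y0)[0]
    return krls_init(
        phi0,
        y0,
        config.kernel,
        reg=config.reg,
        lam=config.lam,
        ald_threshold=config.ald_threshold,
        dict_cap=config.dict_cap,
    )


def predict_series(
    y: np.ndarray,
    u: np.ndarray,
    q: int,
    config: PredictorConfig,
    *,
    test_start: int,
) -> tuple[np.ndarray, int | None]:
    """Run one predictor over a series; return (y_hat over the full grid, dict size).

    The predictor streams over k = 0..N-q-1: it predicts y(k+q) from phi(k)
    and then absorbs the observed pair (phi(k), y(k+q)). Predictions for
    targets before ``test_start`` are the training-phase outputs; %FIT is
    scored downstream on targets >= test_start only.
    """
    y = np.asarray(y, dtype=float)
    u = np.asarray(u, dtype=float)
    if q < 1:
        raise ValueError("horizon q must be >= 1")
    n = len(y)
    if q >= n - test_start:
        raise ValueError(f"horizon q={q} is not below the test-segment length")
    y_hat = np.full(n, np.nan)

    if config.strategy == "iterated":
        return _predict_series_iterated(y, u, q, config, y_hat)

    predictor = None
    update = rls_update if config.model == "rls" else krls_update
    predict = rls_predict if config.model == "rls" else krls_predict
    # at issue time k the newest observation is y(k), so the regressor is
    # phi(k+1) = [y(k)..., u(k)..., 1]; the q-step target is y(k+q)
    for k in range(n - q):
        phi = build_regressor(y, u, config.orders, k + 1)
        if predictor is None:
            y_hat[k + q] = 0.0
            predictor = _make_state(config, phi, y[k + q])
        else:
            y_hat[k + q] = predict(predictor, phi)
            predictor, _, _ = update(predictor, phi, y[k + q])
    dict_size = predictor.dict_size if isinstance(predictor, KrlsState) else None
    return y_hat, dict_size


def _predict_series_iterated(y, u, q, config, y_hat):
    """One-step model; q-step forecasts by feeding predictions back into lags."""
    predictor = None
    update = rls_update if config.model == "rls" else krls_update
    predict = rls_predict if config.model == "rls" else krls_predict
    n = len(y)
    for k in range(1, n):
        phi = build_regressor(y, u, config.orders, k)
        if predictor is None:
            predictor = _make_state(config, phi, y[k])
            continue
        # roll the model forward q steps from time k-1 using its own outputs
        if k - 1 + q < n:
            y_work = y[: k].copy()
            for step in range(q):
                phi_f = build_regressor(
                    np.concatenate([y_work]), u, config.orders, k + step
                )
                y_next = predict(predictor, phi_f)
                y_work = np.append(y_work, y_next)
            y_hat[k - 1 + q] = y_work[-1]
        predictor, _, _ = update(predictor, phi, y[k])
    dict_size = predictor.dict_size if isinstance(predictor, KrlsState) else None
    return y_hat, dict_size


def fit_predict_q(
    record: FnirsRecord,
    u: DhrfSeries | np.ndarray,
    q: int,
    config: PredictorConfig | None = None,
    *,
    test_session: int = 2,
    channels: list[int] | None = None,
    chromophores: tuple[str, ...] = ("hbo", "hbr"),
    fit_variant: str = "plain",
) -> list[PredictionResult]:
    """Train online through the resting prefix + earlier sessions, score on the test session.

    Returns one :class:`PredictionResult` per (channel, chromophore), with
    predictions aligned to the test-session samples and %FIT over them.
    """
    config = config or PredictorConfig()
    u_arr = u.values if isinstance(u, DhrfSeries) else np.asarray(u, dtype=float)
    if len(u_arr) != record.n_samples:
        raise ValueError("dHRF grid does not match the record length")
    test = record.session_slice(test_session)
    results = []
    for ch in channels or record.channels:
        for chrom in chromophores:
            y = record.series(ch, chrom)
            y_hat_full, dict_size = predict_series(y, u_arr, q, config, test_start=test.start)
            y_true = y[test]
            y_pred = y_hat_full[test]
            try:
                fit = percent_fit(y_true, y_pred, variant=fit_variant)
                degenerate = False
            except DegenerateSignalError:
                fit, degenerate = None, True
            results.append(
                PredictionResult(
                    channel=ch,
                    chromophore=chrom,
                    model=config.tag,
                    q=q,
                    y_pred=y_pred,
                    y_true=y_true,
                    fit_pct=fit,
                    degenerate=degenerate,
                    dict_size=dict_size,
                )
            )
    return results


# --------------------------------------------------------------------------
# Model / Results façade
# --------------------------------------------------------------------------


class SignalPredictionModel:
    """Online q-step-ahead prediction model over a (filtered) fNIRS record.

    Parameters mirror :class:`PredictorConfig`; ``horizons`` is the list of
    prediction steps. ``fit()`` streams every per-channel, per-chromophore,
    per-horizon predictor over the record and returns
    :class:`PredictionResults`.
    """

    def __init__(
        self,
        record: FnirsRecord,
        u: DhrfSeries | np.ndarray,
        *,
        model: str = "krls",
        kernel: KernelSpec | str = "gaussian",
        orders: ModelOrders | None = None,
        lam: float = 0.98,
        reg: float = 1e-8,
        ald_threshold: float = 1e-4,
        dict_cap: int | None = 500,
        strategy: str = "direct",
        horizons: tuple[int, ...] = (1, 5, 10, 15, 20),
        test_session: int = 2,
        channels: list[int] | None = None,
        fit_variant: str = "plain",
    ) -> None:
        if isinstance(kernel, str):
            kernel = KernelSpec(kind=kernel)
        self.record = record
        self.u = u
        self.config = PredictorConfig(
            model=model,
            kernel=kernel,
            orders=orders or ModelOrders(),
            lam=lam,
            reg=reg,
            ald_threshold=ald_threshold,
            dict_cap=dict_cap,
            strategy=strategy,
        )
        self.horizons = tuple(horizons)
        self.test_session = test_session
        self.channels = channels
        self.fit_variant = fit_variant

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, fs: float, u: np.ndarray, **kwargs
    ) -> "SignalPredictionModel":
        """Build from a wide-format frame (columns chNN_hbo / chNN_hbr)."""
        hbo_cols = sorted(c for c in df.columns if c.endswith("_hbo"))
        channels = [int(c[2:4]) for c in hbo_cols]
        hbo = df[hbo_cols].to_numpy()
        hbr = df[[c.replace("_hbo", "_hbr") for c in hbo_cols]].to_numpy()
        record = FnirsRecord(hbo=hbo, hbr=hbr, fs=fs, channels=channels)
        return cls(record, u, **kwargs)

    def fit(self) -> "PredictionResults":
        results: list[PredictionResult] = []
        for q in self.horizons:
            results.extend(
                fit_predict_q(
                    self.record,
                    self.u,
                    q,
                    self.config,
                    test_session=self.test_session,
                    channels=self.channels,
                    fit_variant=self.fit_variant,
                )
            )
        return PredictionResults(self, results)


class PredictionResults:
    """Fitted predictions: per-series %FIT table, aligned series, summary."""

    def __init__(self, model: SignalPredictionModel, results: list[PredictionResult]) -> None:
        self.model = model
        self.results = results

    @property
    def fits(self) -> pd.DataFrame:
        rows = [
            {
                "channel": r.channel,
                "chromophore": r.chromophore,
                "model": r.model,
                "q": r.q,
                "fit_pct": r.fit_pct,
                "degenerate": r.degenerate,
                "dict_size": r.dict_size,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def result(self, channel: int, chromophore: str, q: int) -> PredictionResult:
        for r in self.results:
            if (r.channel, r.chromophore, r.q) == (channel, chromophore, q):
                return r
        raise KeyError((channel, chromophore, q))

    def mean_fit(self, q: int, chromophore: str | None = None, channels=None) -> float:
        df = self.fits
        df = df[(df.q == q) & ~df.degenerate]
        if chromophore is not None:
            df = df[df.chromophore == chromophore]
        if channels is not None:
            df = df[df.channel.isin(channels)]
        return float(df.fit_pct.mean())

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "q-step-ahead prediction results",
            "=" * 46,
            f"model: {cfg.tag}    strategy: {cfg.strategy}",
            f"orders: n_o={cfg.orders.n_o} m_o={cfg.orders.m_o} p_o={cfg.orders.p_o}    "
            f"lambda={cfg.lam} R={cfg.reg:g}",
            f"test session: {self.model.test_session}    "
            f"channels: {len(self.fits.channel.unique())}",
            "-" * 46,
            f"{'q':>4} {'sec':>6} {'%FIT HbO':>14} {'%FIT HbR':>14}",
        ]
        fs = self.model.record.fs
        df = self.fits
        for q in self.model.horizons:
            secs = np.trunc(q / fs * 100) / 100
            row = []
            for chrom in ("hbo", "hbr"):
                sub = df[(df.q == q) & (df.chromophore == chrom) & ~df.degenerate]
                row.append(f"{sub.fit_pct.mean():6.1f} ± {sub.fit_pct.std(ddof=1):4.1f}")
            lines.append(f"{q:>4} {secs:>6.2f} {row[0]:>14} {row[1]:>14}")
        lines.append("=" * 46)
        return "\n".join(lines)
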