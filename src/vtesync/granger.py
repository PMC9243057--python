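"""Bivariate Granger prediction between mPFC and dHPC LFP.

Directionality is assessed by nested autoregressions: the univariate model
predicts a channel from its own k lags,

    x_t = sum_{n=1..k} a_n x_{t-n} + e_t,

and the bivariate model adds the other channel's lags,

    x_t = sum a_n x_{t-n} + sum b_n y_{t-n} + eps_t.

The time-domain Granger prediction is GC_{y->x} = log(Var[e]/Var[eps]).
Both models are estimated by ordinary least squares on the same lag-
embedded sample window, so the nesting inequality Var[eps] <= Var[e] (and
hence GC >= 0) holds exactly in-sample.  Frequency-resolved estimates use
Geweke's decomposition: from the fitted VAR's transfer function
H(f) = (I - sum_k A_k e^{-i 2 pi f k / fs})^{-1} and innovation covariance
Sigma, the spectral matrix is S(f) = H Sigma H*, and the directional
measure at each frequency is the log ratio of total to intrinsic power
after normalizing away the cross-innovation term.  Model order is chosen
by BIC per session over lags 1-20, then averaged over sessions and
rounded (half-to-even) to a single study-wide order.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .behavior import norm_diff
from .defaults import FREQ_GRID

__all__ = [
    "ArModelFit",
    "GrangerSpectrum",
    "OrderSelection",
    "fit_var",
    "time_domain_gc",
    "select_order",
    "spectral_gc",
    "gc_condition_contrast",
]

_VAR_FLOOR = 1e-12


@dataclass
class ArModelFit:
    """OLS estimates of the univariate and bivariate autoregressions.

    ``coeffs`` holds the bivariate coefficient matrices A_1..A_k (each
    2x2, row = predicted channel, ordered x then y); ``sigma`` is the
    bivariate innovation covariance; ``uni_var`` the univariate residual
    variances per channel.  All residual moments come from the same
    sample window (observations k..n-1) so nesting holds exactly.
    """

    order: int
    coeffs: np.ndarray            # (k, 2, 2)
    sigma: np.ndarray             # (2, 2)
    uni_var: np.ndarray           # (2,)
    sampling_rate: float
    n_obs: int

    def companion_spectral_radius(self) -> float:
        k = self.order
        comp = np.zeros((2 * k, 2 * k))
        for i in range(k):
            comp[0:2, 2 * i : 2 * i + 2] = self.coeffs[i]
        if k > 1:
            comp[2:, :-2] = np.eye(2 * (k - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    def is_stable(self) -> bool:
        return self.companion_spectral_radius() < 1.0


@dataclass
class GrangerSpectrum:
    """Frequency-resolved directional prediction for one channel pair."""

    frequencies: np.ndarray
    gc_x_to_y: np.ndarray
    gc_y_to_x: np.ndarray
    time_domain: dict[str, float]
    order_used: int


@dataclass
class OrderSelection:
    """Per-session BIC curves and the pooled study-wide model order."""

    bic_curves: list[np.ndarray]      # one per session, index 0 = lag 1
    session_orders: list[int]
    global_order: int


def _lag_matrix(x: np.ndarray, y: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix of k lags of both channels and the target rows.

    Columns ordered x_{t-1..t-k} then y_{t-1..t-k}; targets are
    (x_t, y_t) for t = k..n-1.
    """
    n = len(x)
    rows = n - k
    design = np.empty((rows, 2 * k))
    for lag in range(1, k + 1):
        design[:, lag - 1] = x[k - lag : n - lag]
        design[:, k + lag - 1] = y[k - lag : n - lag]
    targets = np.column_stack([x[k:], y[k:]])
    return design, targets


def fit_var(
    x: np.ndarray, y: np.ndarray, order: int, sampling_rate: float = 1.0
) -> ArModelFit:
    """Fit univariate and bivariate AR models of the given order by OLS.

    Series are de-meaned internally.  Requires length > 10 x order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if order < 1:
        raise ValueError("order must be >= 1")
    n = len(x)
    if n <= 10 * order:
        raise ValueError(f"series too short (n={n}) for order {order}")
    x = x - x.mean()
    y = y - y.mean()
    design, targets = _lag_matrix(x, y, order)
    rows = design.shape[0]
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (constant or collinear series)")

    beta, _, _, _ = np.linalg.lstsq(design, targets, rcond=None)
    resid = targets - design @ beta
    sigma = resid.T @ resid / rows

    # univariate fits on the same window: own lags only
    uni_var = np.empty(2)
    for ch, own in ((0, slice(0, order)), (1, slice(order, 2 * order))):
        d = design[:, own]
        b, _, _, _ = np.linalg.lstsq(d, targets[:, ch], rcond=None)
        r = targets[:, ch] - d @ b
        uni_var[ch] = r @ r / rows

    coeffs = np.empty((order, 2, 2))
    for lag in range(order):
        coeffs[lag, 0, 0] = beta[lag, 0]
        coeffs[lag, 0, 1] = beta[order + lag, 0]
        coeffs[lag, 1, 0] = beta[lag, 1]
        coeffs[lag, 1, 1] = beta[order + lag, 1]

    target_var = np.array([x @ x / n, y @ y / n])
    for ch in range(2):
        for v in (sigma[ch, ch], uni_var[ch]):
            if v <= 0 or (target_var[ch] > 0 and v < 1e-10 * target_var[ch]):
                raise ValueError(
                    "vanishing residual variance: degenerate (noiseless) series")
    return ArModelFit(order=order, coeffs=coeffs, sigma=sigma, uni_var=uni_var,
                      sampling_rate=sampling_rate, n_obs=rows)


def _floored(v: float) -> float:
    if v < _VAR_FLOOR:
        warnings.warn("residual variance floored at 1e-12", stacklevel=3)
        return _VAR_FLOOR
    return v


def time_domain_gc(fit: ArModelFit) -> dict[str, float]:
    """GC per direction: log(univariate / bivariate residual variance).

    'x_to_y' asks whether x's past improves prediction of y beyond y's
    own past, and vice versa.  Nonnegative by the OLS nesting property.
    """
    return {
        "x_to_y": float(np.log(_floored(fit.uni_var[1]) / _floored(fit.sigma[1, 1]))),
        "y_to_x": float(np.log(_floored(fit.uni_var[0]) / _floored(fit.sigma[0, 0]))),
    }


def select_order(
    sessions: list[tuple[np.ndarray, np.ndarray]], max_lag: int = 20
) -> OrderSelection:
    """BIC-based VAR order, pooled across sessions.

    Per session, BIC(k) = n ln det(Sigma_k) + p ln n with p = 4k estimated
    coefficients, minimized over k in [1, max_lag] (ties to the smaller
    lag); the study-wide order is the rounded (half-to-even) mean of the
    per-session argmins.
    """
    if not sessions:
        raise ValueError("need at least one session")
    curves = []
    orders = []
    for x, y in sessions:
        n = len(x)
        if max_lag >= n / 10:
            raise ValueError(f"max_lag {max_lag} too large for series of length {n}")
        bic = np.empty(max_lag)
        for k in range(1, max_lag + 1):
            fit = fit_var(x, y, k)
            n_eff = fit.n_obs
            sign, logdet = np.linalg.slogdet(fit.sigma)
            if sign <= 0:
                logdet = np.log(_VAR_FLOOR)
            bic[k - 1] = n_eff * logdet + 4 * k * np.log(n_eff)
        curves.append(bic)
        orders.append(int(np.argmin(bic)) + 1)  # argmin takes the first (smallest) lag
    global_order = int(round(float(np.mean(orders))))
    global_order = min(max(global_order, 1), max_lag)
    return OrderSelection(bic_curves=curves, session_orders=orders,
                          global_order=global_order)


def spectral_gc(
    fit: ArModelFit,
    grid: np.ndarray = FREQ_GRID,
    sampling_rate: float | None = None,
) -> GrangerSpectrum:
    """Geweke frequency-domain Granger prediction on the analysis grid.

    From the fitted VAR: A(f) = I - sum_k A_k e^{-i 2 pi f k / fs},
    H(f) = A(f)^{-1}, S(f) = H Sigma H*.  The y->x measure at f is
    ln(S_xx / (Htilde_xx Sigma_xx Htilde_xx*)) with
    Htilde_xx = H_xx + (Sigma_xy/Sigma_xx) H_xy, which removes the
    instantaneous cross-innovation contribution; symmetrically for x->y.
    """
    fs = sampling_rate if sampling_rate is not None else fit.sampling_rate
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if not fit.is_stable():
        raise ValueError(
            f"unstable VAR (spectral radius {fit.companion_spectral_radius():.3f})"
        )
    grid = np.asarray(grid, dtype=float)
    sig = fit.sigma
    sxx, syy, sxy = sig[0, 0], sig[1, 1], sig[0, 1]
    gc_xy = np.empty(len(grid))
    gc_yx = np.empty(len(grid))
    eye = np.eye(2)
    k = fit.order
    for i, f in enumerate(grid):
        z = np.exp(-1j * 2 * np.pi * f * np.arange(1, k + 1) / fs)
        a_f = eye - np.tensordot(z, fit.coeffs, axes=(0, 0))
        h = np.linalg.inv(a_f)
        s_f = h @ sig @ h.conj().T
        # y -> x
        h_tilde_xx = h[0, 0] + (sxy / sxx) * h[0, 1]
        intrinsic_x = (h_tilde_xx * sxx * np.conj(h_tilde_xx)).real
        gc_yx[i] = np.log(max(s_f[0, 0].real, _VAR_FLOOR) / max(intrinsic_x, _VAR_FLOOR))
        # x -> y
        h_tilde_yy = h[1, 1] + (sxy / syy) * h[1, 0]
        intrinsic_y = (h_tilde_yy * syy * np.conj(h_tilde_yy)).real
        gc_xy[i] = np.log(max(s_f[1, 1].real, _VAR_FLOOR) / max(intrinsic_y, _VAR_FLOOR))
    tol = -1e-10
    if np.any(gc_xy < tol) or np.any(gc_yx < tol):
        warnings.warn("negative spectral GC beyond tolerance; clipping", stacklevel=2)
    return GrangerSpectrum(
        frequencies=grid,
        gc_x_to_y=np.maximum(gc_xy, 0.0),
        gc_y_to_x=np.maximum(gc_yx, 0.0),
        time_domain=time_domain_gc(fit),
        order_used=fit.order,
    )


def gc_condition_contrast(
    gc_by_condition: dict[str, dict[str, dict[str, float]]],
) -> dict[str, dict[str, float]]:
    """Normalized difference of theta-mean GC, muscimol vs collapsed control.

    ``gc_by_condition[rat][direction]`` must hold {'muscimol': v,
    'control': v}; returns per rat per direction
    (muscimol - control)/(muscimol + control).
    """
    out: dict[str, dict[str, float]] = {}
    for rat, by_dir in gc_by_condition.items():
        out[rat] = {}
        for direction, vals in by_dir.items():
            out[rat][direction] = norm_diff(vals["muscimol"], vals["control"])
    return out
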