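"""The log t convergence regression and one-sided HAC test.

Under the time-varying factor representation X_it = delta_it * mu_t, relative
convergence of a panel means every unit's loading delta_it approaches a common
limit delta.  Operationally that is measured through the relative transition
parameter

    h_it = X_it / (N^-1 sum_j X_jt),

whose cross-sectional variance H_t = N^-1 sum_i (h_it - 1)^2 decays to zero
under convergence, at a rate governed by the decay exponent alpha of the
idiosyncratic loading noise.  The test regresses

    log(H_1 / H_t) - 2 log(log t)  on  {1, log t},   t = [rT], ..., T,

where the slope estimates b = 2*alpha.  Convergence (b >= 0) is the null of a
one-sided t test with an autocorrelation-robust (Bartlett kernel) standard
error: the null is rejected when t_b < -1.65 at the 5% level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .panel import PanelData, PanelError

__all__ = [
    "TransitionSet",
    "LogTResult",
    "LogTModel",
    "compute_transition",
    "fit_logt",
    "decide_convergence",
    "DEFAULT_CRITICAL",
]

#: one-sided 5% critical value for the convergence t statistic
DEFAULT_CRITICAL = -1.65

# H_t at or below this is treated as exactly zero (identical series give an
# exact 0.0; genuine converging panels stay many orders of magnitude above)
_ZERO_H = 1e-30


@dataclass
class TransitionSet:
    """Relative transition matrix h_it and cross-sectional variance path H_t."""

    h: np.ndarray          # (N, T) relative transition parameters
    H: np.ndarray          # (T,) cross-sectional variance of h
    ids: list[str]
    years: list[int]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table (country_id, year, h)."""
        n, t = self.h.shape
        return pd.DataFrame({
            "country_id": np.repeat(self.ids, t),
            "year": np.tile(self.years, n),
            "h": self.h.ravel(),
        })


def compute_transition(panel: PanelData) -> TransitionSet:
    """Relative transition parameters h_it and their variance path H_t.

    h_it divides each unit's log expenditure by the cross-sectional mean at t,
    so mean_i h_it = 1 at every t and H_t = mean_i (h_it - 1)^2 traces how the
    cross-section tightens (H_t -> 0) or stays dispersed over time.

    Raises
    ------
    PanelError
        If the panel is not on the log scale, or the cross-sectional mean is
        (numerically) zero at some period, which makes h undefined there.
    """
    if panel.scale != "log":
        raise PanelError("compute_transition expects a log-scale panel")
    x = panel.values
    mean = x.mean(axis=0)
    bad = np.flatnonzero(np.abs(mean) < 1e-12)
    if bad.size:
        raise PanelError(
            f"degenerate panel: cross-sectional mean is zero at year "
            f"{panel.years[int(bad[0])]}")
    h = x / mean
    H = ((h - 1.0) ** 2).mean(axis=0)
    return TransitionSet(h=h, H=H, ids=list(panel.ids), years=list(panel.years))


@dataclass
class LogTResult:
    """Fitted log t regression with the one-sided convergence test.

    Attributes
    ----------
    a_hat, b_hat : float
        Intercept and slope; b_hat estimates 2*alpha, the decay rate of the
        loading heterogeneity.
    s_b : float
        Autocorrelation-robust (Bartlett kernel) standard error of the slope.
    t_b : float
        One-sided statistic b_hat / s_b; values below the critical value
        (default -1.65) reject convergence.
    r : float
        Trimming fraction; the regression starts at t = max(2, floor(rT)).
    start_index : int
        First 1-based time index entering the regression window.
    hac_lags : int
        Bartlett lag truncation actually used.
    residuals : ndarray
        Regression residuals over the trimmed window.
    degenerate : bool
        True when H_t vanishes inside the window (all series identical):
        the regressand is undefined and the panel converges exactly; the
        coefficient fields are NaN in that case.
    nobs, n_units : int
        Number of regression points and of panel units.
    """

    a_hat: float
    b_hat: float
    s_b: float
    t_b: float
    r: float
    start_index: int
    hac_lags: int
    residuals: np.ndarray
    degenerate: bool
    nobs: int
    n_units: int

    @property
    def alpha_hat(self) -> float:
        """Implied decay exponent alpha = b/2."""
        return self.b_hat / 2.0

    def decision(self, critical: float = DEFAULT_CRITICAL) -> str:
        return decide_convergence(self, critical)

    def to_dict(self) -> dict:
        """Flat record for CSV/JSON export."""
        return {
            "a": self.a_hat, "b": self.b_hat, "s_b": self.s_b, "t_b": self.t_b,
            "r": self.r, "start_index": self.start_index,
            "hac_lags": self.hac_lags, "nobs": self.nobs,
            "n_units": self.n_units, "degenerate": self.degenerate,
            "decision": self.decision(),
        }

    def summary(self) -> str:
        """Plain-text summary of the fit and the convergence decision."""
        lines = ["log t convergence regression",
                 "-" * 34,
                 f"units:         {self.n_units}",
                 f"window:        t = {self.start_index}..{self.start_index + self.nobs - 1}"
                 f"  (r = {self.r})",
                 f"HAC lags:      {self.hac_lags}"]
        if self.degenerate:
            lines += ["result:        exact convergence (H_t = 0 in window)"]
        else:
            lines += [f"a_hat:         {self.a_hat: .4f}",
                      f"b_hat (=2a):   {self.b_hat: .4f}",
                      f"s_b (HAC):     {self.s_b: .4f}",
                      f"t_b:           {self.t_b: .4f}",
                      f"decision:      {self.decision()} (critical {DEFAULT_CRITICAL})"]
        return "\n".join(lines)


def _default_hac_lags(T: int) -> int:
    return int(math.floor(T ** (1.0 / 3.0)))


def _fit_logt_from_H(H: np.ndarray, r: float, hac_lags: int | None,
                     n_units: int) -> LogTResult:
    """Core fit from an H_t path; shared by the model class and the club search."""
    T = H.shape[0]
    if T < 5:
        raise PanelError(f"need T >= 5, got {T}")
    if not (0.2 <= r <= 0.3):
        raise PanelError(f"trimming fraction r={r} outside [0.2, 0.3]")
    start = max(2, math.floor(r * T))       # 1-based; log log t defined from t=2
    if start > T - 2:
        raise PanelError(
            f"fewer than 3 regression points after trimming (start={start}, T={T})")
    lags = _default_hac_lags(T) if hac_lags is None else int(hac_lags)
    nobs = T - start + 1
    lags = max(0, min(lags, nobs - 1))

    window = H[start - 1:]
    if H[0] <= _ZERO_H or np.any(window <= _ZERO_H):
        return LogTResult(
            a_hat=math.nan, b_hat=math.nan, s_b=math.nan, t_b=math.nan,
            r=r, start_index=start, hac_lags=lags,
            residuals=np.full(nobs, math.nan), degenerate=True,
            nobs=nobs, n_units=n_units)

    t = np.arange(start, T + 1, dtype=float)
    y = np.log(H[0] / window) - 2.0 * np.log(np.log(t))
    X = sm.add_constant(np.log(t))
    fit = sm.OLS(y, X).fit(cov_type="HAC",
                           cov_kwds={"maxlags": lags, "use_correction": False})
    a_hat, b_hat = fit.params
    s_b = float(fit.bse[1])
    return LogTResult(
        a_hat=float(a_hat), b_hat=float(b_hat), s_b=s_b, t_b=float(b_hat / s_b),
        r=r, start_index=start, hac_lags=lags,
        residuals=np.asarray(fit.resid), degenerate=False,
        nobs=nobs, n_units=n_units)


class LogTModel:
    """The log t convergence regression for a balanced log-scale panel.

    Parameters
    ----------
    panel : PanelData
        Log-scale balanced panel (N >= 2, T >= 5).
    r : float, default 0.3
        Trimming fraction in [0.2, 0.3]; 0.3 is the recommended choice for
        small and moderate samples (T <= 50).
    hac_lags : int, optional
        Bartlett kernel lag truncation; defaults to floor(T^(1/3)).

    Examples
    --------
    >>> res = LogTModel(log_panel).fit()          # doctest: +SKIP
    >>> res.t_b < -1.65                            # doctest: +SKIP
    """

    def __init__(self, panel: PanelData, r: float = 0.3,
                 hac_lags: int | None = None):
        if panel.scale != "log":
            raise PanelError("LogTModel expects a log-scale panel")
        self.panel = panel
        self.r = float(r)
        self.hac_lags = hac_lags

    def fit(self) -> LogTResult:
        trans = compute_transition(self.panel)
        return _fit_logt_from_H(trans.H, self.r, self.hac_lags,
                                self.panel.n_units)


def fit_logt(panel: PanelData, r: float = 0.3,
             hac_lags: int | None = None) -> LogTResult:
    """Fit the log t regression on a log-scale panel (see :class:`LogTModel`)."""
    return LogTModel(panel, r=r, hac_lags=hac_lags).fit()


def decide_convergence(result: LogTResult,
                       critical: float = DEFAULT_CRITICAL) -> str:
    """Map a fitted log t result to {"converge", "diverge", "exact"}.

    "exact" flags the degenerate all-identical-series case; otherwise the
    one-sided test rejects convergence iff t_b < critical (strict).
    """
    if result.degenerate:
        return "exact"
    return "diverge" if result.t_b < critical else "converge"
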