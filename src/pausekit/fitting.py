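"""Error-weighted nonlinear fitting of pause assays, stopped-flow traces
and binding titrations.

Pause assays are fit to single- or double-exponential decays of the
pause-RNA fraction; the double-exponential amplitudes are the fast (*a*)
and slow (*b*) pause fractions, their rates the apparent escape rate
constants, and the extrapolated t→0 intercept below one measures pause
bypass.  Because the measured curves contain an arrival transient (the
pre-pause RNA converting to pause RNA), decay fits start at the curve
maximum.

Two amplitude conventions are in use for pause efficiencies: fractions of
total RNA ("total") and fractions of the pause-captured RNA ("captured").
:func:`pause_metrics` exposes both and names the one used in its output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .curves import FluorescenceTrace, ProgressCurve
from .synthetic import binding_model, stopped_flow_model

__all__ = [
    "FitError",
    "SingleExpFit",
    "BiexpFit",
    "PauseMetrics",
    "StoppedFlowFit",
    "BindingFit",
    "fit_single_exponential",
    "fit_double_exponential",
    "pause_metrics",
    "fit_stopped_flow",
    "fit_binding",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge or the data cannot identify it."""


# ---------------------------------------------------------------------------
# shared machinery
# ---------------------------------------------------------------------------

def _multistart_fit(model, t, y, sigma, starts, bounds):
    """Best of several curve_fit starts (weighted when sigma given)."""
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)
        if not np.all(np.isfinite(sigma)) or np.any(sigma <= 0):
            sigma = None  # degenerate uncertainties: fall back to unweighted
    best = None
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                model, t, y, p0=p0, sigma=sigma, bounds=bounds,
                maxfev=20000, absolute_sigma=False,
            )
        except (RuntimeError, ValueError):
            continue
        resid = y - model(t, *popt)
        if sigma is not None:
            resid = resid / sigma
        rss = float(resid @ resid)
        if best is None or rss < best[2] - 1e-12:
            best = (popt, pcov, rss)
    if best is None:
        raise FitError("no multistart converged")
    return best


def _pool_replicates(curves: Sequence[ProgressCurve]):
    """Average replicates on their common grid; per-point SD of the mean."""
    if not curves:
        raise ValueError("no curves given")
    t0 = curves[0].times
    for c in curves[1:]:
        if c.times.shape != t0.shape or not np.allclose(c.times, t0):
            raise ValueError("replicates must share one time grid")
    Y = np.vstack([c.fractions for c in curves])
    mean = Y.mean(axis=0)
    n = len(curves)
    if n >= 6:
        # per-point SDs are stable enough to weight with
        sd_mean = Y.std(axis=0, ddof=1) / np.sqrt(n)
        floor = max(np.median(sd_mean) * 0.25, 1e-6)
        sd_mean = np.maximum(sd_mean, floor)
    elif n >= 3:
        # per-point SDs from so few replicates are too noisy to weight
        # with individually; pool them into one scalar uncertainty
        pooled = float(np.sqrt(np.mean(Y.var(axis=0, ddof=1))) / np.sqrt(n))
        sd_mean = np.full(t0.size, max(pooled, 1e-6))
    else:
        sd_mean = None  # fall back to unweighted
    return t0, mean, sd_mean


# ---------------------------------------------------------------------------
# single exponential
# ---------------------------------------------------------------------------

@dataclass
class SingleExpFit:
    amplitude: float
    rate: float
    offset: float
    se: dict[str, float]
    cov: np.ndarray
    flags: list[str] = field(default_factory=list)
    kind: str = "decay"

    @property
    def tau(self) -> float:
        return 1.0 / self.rate


def fit_single_exponential(
    curve: ProgressCurve,
    kind: str = "decay",
    offset: bool = False,
) -> SingleExpFit:
    """Weighted single-exponential fit.

    ``kind="decay"`` fits ``y = A e^(−k t) (+ c)``; ``kind="rise"`` fits the
    quench-flow form ``y = A (1 − e^(−k t)) (+ c)``.  Flags (not errors) mark
    unidentifiable fits: flat data or a time span shorter than one
    half-life of the fitted rate.
    """
    t, y, sigma = curve.times, curve.fractions, curve.sd
    if t.size < 4:
        raise FitError("need at least 4 points for a single-exponential fit")
    flags: list[str] = []
    if np.ptp(y) < 1e-12:
        return SingleExpFit(
            amplitude=0.0, rate=np.nan, offset=float(y[0]),
            se={"amplitude": np.nan, "rate": np.nan},
            cov=np.full((2, 2), np.nan),
            flags=["unidentifiable: constant data"], kind=kind,
        )

    sign = -1.0 if kind == "decay" else 1.0

    if offset:
        def model(tt, A, k, c):
            return A * (np.exp(-k * tt) if kind == "decay" else 1 - np.exp(-k * tt)) + c
        bounds = ([0, 1e-8, -0.5], [2.0, 1e4, 1.0])
    else:
        def model(tt, A, k):
            return A * (np.exp(-k * tt) if kind == "decay" else 1 - np.exp(-k * tt))
        bounds = ([0, 1e-8], [2.0, 1e4])

    span = t[-1] - t[0]
    k_grid = np.geomspace(0.2 / max(span, 1e-9), 50.0 / max(span, 1e-9), 6)
    amp0 = float(np.ptp(y))
    starts = [[amp0, k] + ([float(y.min())] if offset else []) for k in k_grid]
    popt, pcov, _ = _multistart_fit(model, t, y, sigma, starts, bounds)
    k_hat = popt[1]
    if span < np.log(2) / k_hat:
        flags.append("insufficient span: data cover less than one half-life")
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    names = ["amplitude", "rate"] + (["offset"] if offset else [])
    return SingleExpFit(
        amplitude=float(popt[0]),
        rate=float(k_hat),
        offset=float(popt[2]) if offset else 0.0,
        se=dict(zip(names, se)),
        cov=pcov,
        flags=flags,
        kind=kind,
    )


# ---------------------------------------------------------------------------
# double exponential (pause assay)
# ---------------------------------------------------------------------------

@dataclass
class BiexpFit:
    """Double-exponential pause decay: a·e^(−k_p,app t) + b·e^(−k_sp,app t).

    ``a`` and ``b`` are extrapolated t→0 amplitudes of the fast and slow
    pause phases; ``bypass = 1 − a − b``.  The ordering convention
    ``k_p_app >= k_sp_app`` is enforced by post-hoc swap.
    """

    a: float
    b: float
    k_p_app: float
    k_sp_app: float
    se: dict[str, float]
    cov: np.ndarray
    residuals: np.ndarray
    fit_times: np.ndarray
    n_exponentials_preferred: int
    f_test_p: float
    dof: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def bypass(self) -> float:
        return 1.0 - self.a - self.b

    @property
    def bypass_se(self) -> float:
        # var(1 - a - b) = var(a) + var(b) + 2 cov(a, b)
        v = self.cov[0, 0] + self.cov[2, 2] + 2.0 * self.cov[0, 2]
        return float(np.sqrt(max(v, 0.0)))

    def ci95(self, name: str) -> tuple[float, float]:
        """95% confidence interval using the Student-t critical value."""
        value = {"a": self.a, "b": self.b, "k_p_app": self.k_p_app,
                 "k_sp_app": self.k_sp_app, "bypass": self.bypass}[name]
        se = self.bypass_se if name == "bypass" else self.se[name]
        crit = stats.t.ppf(0.975, self.dof) if self.dof > 0 else 1.96
        return (value - crit * se, value + crit * se)


def _biexp(t, a, k1, b, k2):
    return a * np.exp(-k1 * t) + b * np.exp(-k2 * t)


def fit_double_exponential(
    curves: Sequence[ProgressCurve] | ProgressCurve,
    from_maximum: bool = True,
) -> BiexpFit:
    """Error-weighted double-exponential fit of replicated pause curves.

    Replicates are averaged on their common grid and error-weighted
    (per-point SD of the mean with ≥6 replicates, a pooled SD with 3–5,
    unweighted below that).  The fit starts just past the curve maximum —
    the peak point itself still carries arrival-transient curvature — so
    amplitudes are extrapolated t→0 intercepts and an intercept sum below
    one measures bypass.  A weighted-RSS F-test (α = 0.05) reports whether
    a single exponential would suffice.
    """
    if isinstance(curves, ProgressCurve):
        curves = [curves]
    t, y, sigma = _pool_replicates(curves)
    if from_maximum:
        i0 = min(int(np.argmax(y)) + 1, y.size - 1)
        t, y = t[i0:], y[i0:]
        sigma = sigma[i0:] if sigma is not None else None
    if t.size < 6:
        raise FitError("need at least 6 points beyond the curve maximum")

    flags: list[str] = []
    span = t[-1] - t[0]
    kg = np.geomspace(0.5 / span, 100.0 / span, 5)
    amp = float(np.max(y))
    starts = []
    for k1 in kg:
        for ratio in (10.0, 100.0):
            starts.append([0.8 * amp, k1, 0.2 * amp, k1 / ratio])
    bounds = ([0.0, 1e-8, 0.0, 1e-8], [1.05, 1e4, 1.05, 1e4])
    popt, pcov, rss2 = _multistart_fit(_biexp, t, y, sigma, starts, bounds)

    a, k1, b, k2 = popt
    if k1 < k2:  # enforce ordering convention post hoc
        a, b, k1, k2 = b, a, k2, k1
        perm = [2, 3, 0, 1]
        pcov = pcov[np.ix_(perm, perm)]

    if k2 > 0 and k1 / max(k2, 1e-300) < 3.0:
        flags.append("identifiability: rates within 3x of each other")
    if a + b > 1.0 + 0.15:
        flags.append("amplitude: a + b exceeds 1 beyond tolerance")

    # nested F-test against a single exponential on the same points
    def single(tt, A, k):
        return A * np.exp(-k * tt)

    p1, _, rss1 = _multistart_fit(
        single, t, y, sigma, [[amp, k] for k in kg], ([0, 1e-8], [1.5, 1e4])
    )
    dof2 = t.size - 4
    if dof2 > 0 and rss2 > 0:
        f = max((rss1 - rss2) / 2.0, 0.0) / (rss2 / dof2)
        p_f = float(stats.f.sf(f, 2, dof2))
    else:
        p_f = np.nan
    n_pref = 2 if (np.isfinite(p_f) and p_f < 0.05) else 1
    if n_pref == 1:
        flags.append("model selection: single exponential not rejected (F-test)")

    resid = y - _biexp(t, a, k1, b, k2)
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    return BiexpFit(
        a=float(a), b=float(b), k_p_app=float(k1), k_sp_app=float(k2),
        se={"a": se[0], "k_p_app": se[1], "b": se[2], "k_sp_app": se[3]},
        cov=pcov, residuals=resid, fit_times=t,
        n_exponentials_preferred=n_pref, f_test_p=p_f,
        dof=max(t.size - 4, 1), flags=flags,
    )


# ---------------------------------------------------------------------------
# pause metrics
# ---------------------------------------------------------------------------

@dataclass
class PauseMetrics:
    """Pause efficiencies, lifetime and pause strength.

    ``E`` is the total pause efficiency (E_a + E_b), ``tau`` the lifetime
    of the major pause species (1 / k_p,app) and ``PS = E · tau`` the pause
    strength in seconds.  ``convention`` records whether efficiencies are
    fractions of total RNA or of the captured (non-bypass) fraction.
    """

    E: float
    E_a: float
    E_b: float
    tau: float
    PS: float
    PS_se: float
    convention: str

    def __post_init__(self) -> None:
        if abs(self.E - (self.E_a + self.E_b)) > 1e-9:
            raise ValueError("E must equal E_a + E_b")


def pause_metrics(fit: BiexpFit, convention: str = "total") -> PauseMetrics:
    """Derive pause efficiencies and pause strength from a converged fit.

    ``convention="total"``: E_a = a, E_b = b (fractions of all RNA).
    ``convention="captured"``: amplitudes renormalized by a + b + bypass
    (the fitted t→0 total), which equals 1 for fully normalized data.
    """
    if not np.isfinite(fit.k_p_app) or fit.k_p_app <= 0:
        raise FitError("zero or invalid fast escape rate")
    a, b = fit.a, fit.b
    if convention == "captured":
        total = a + b + fit.bypass  # == 1 by construction of bypass
        E_a, E_b = a / total, b / total
    elif convention == "total":
        E_a, E_b = a, b
    else:
        raise ValueError(f"unknown convention {convention!r}")
    E = E_a + E_b
    tau = 1.0 / fit.k_p_app
    PS = E * tau

    # delta method on PS = (a + b) / k1 using the fit covariance
    g = np.array([
        1.0 / fit.k_p_app,            # d/da
        -(a + b) / fit.k_p_app ** 2,  # d/dk1
        1.0 / fit.k_p_app,            # d/db
        0.0,                          # d/dk2
    ])
    PS_se = float(np.sqrt(max(g @ fit.cov @ g, 0.0)))
    return PauseMetrics(E=E, E_a=E_a, E_b=E_b, tau=tau, PS=PS, PS_se=PS_se,
                        convention=convention)


# ---------------------------------------------------------------------------
# stopped flow
# ---------------------------------------------------------------------------

@dataclass
class StoppedFlowFit:
    """F(t) = A(1−e^(−k1,obs t)) + B(1−e^(−k2,obs t)); k1_obs ≥ k2_obs.

    The fast-species rate ``k1_obs`` is reported as the translocation rate.
    """

    A: float
    B: float
    k1_obs: float
    k2_obs: float
    se: dict[str, float]
    cov: np.ndarray
    flags: list[str] = field(default_factory=list)

    @property
    def translocation_rate(self) -> float:
        return self.k1_obs


def fit_stopped_flow(trace: FluorescenceTrace) -> StoppedFlowFit:
    """Fit a normalized stopped-flow unquenching trace."""
    t, y, sigma = trace.times, trace.signal, trace.sd
    span = t[-1] - t[0]
    kg = np.geomspace(0.5 / span, 500.0 / span, 6)
    plateau = float(np.median(y[-max(3, t.size // 10):]))
    starts = []
    for k1 in kg:
        starts.append([0.7 * plateau, k1, 0.3 * plateau, k1 / 10.0])
    bounds = ([0, 1e-8, 0, 1e-8], [5.0, 1e6, 5.0, 1e6])
    popt, pcov, _ = _multistart_fit(
        lambda tt, A, k1, B, k2: stopped_flow_model(tt, A, k1, B, k2),
        t, y, sigma, starts, bounds,
    )
    A, k1, B, k2 = popt
    if k1 < k2:
        A, B, k1, k2 = B, A, k2, k1
        perm = [2, 3, 0, 1]
        pcov = pcov[np.ix_(perm, perm)]
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    return StoppedFlowFit(
        A=float(A), B=float(B), k1_obs=float(k1), k2_obs=float(k2),
        se={"A": se[0], "k1_obs": se[1], "B": se[2], "k2_obs": se[3]},
        cov=pcov,
    )


# ---------------------------------------------------------------------------
# binding
# ---------------------------------------------------------------------------

@dataclass
class BindingFit:
    """Hyperbolic binding fit: F = F_max · c / (K_d + c)."""

    K_d: float
    F_max: float
    se: dict[str, float]
    cov: np.ndarray
    no_binding: bool
    flags: list[str] = field(default_factory=list)


def fit_binding(titration: pd.DataFrame) -> BindingFit:
    """Fit a binding titration (columns ``conc_uM``, ``signal``,
    optional ``sd``).

    Reports a no-binding verdict when the fitted F_max 95% CI includes
    zero.  Flags unidentifiable designs where all concentrations sit far
    below or above the fitted K_d.
    """
    c = titration["conc_uM"].to_numpy(dtype=float)
    y = titration["signal"].to_numpy(dtype=float)
    sigma = titration["sd"].to_numpy(dtype=float) if "sd" in titration else None
    if c.size < 5:
        raise FitError("need at least 5 concentrations")
    flags: list[str] = []
    cmax = c.max()
    starts = [[max(y.max(), 1e-6), kd] for kd in np.geomspace(cmax / 100, cmax * 10, 6)]
    bounds = ([0.0, 1e-9], [10 * max(abs(y).max(), 1e-6), 1e9])
    popt, pcov, _ = _multistart_fit(
        lambda cc, fmax, kd: binding_model(cc, fmax, kd), c, y, sigma, starts, bounds
    )
    F_max, K_d = float(popt[0]), float(popt[1])
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    # "no binding evident": F_max CI includes zero, or the fitted amplitude
    # sits below the residual noise floor (the linearized SE is far too
    # optimistic when K_d is unidentifiable at F_max ~ 0)
    rms = float(np.sqrt(np.mean((y - binding_model(c, F_max, K_d)) ** 2)))
    no_binding = bool(F_max - 1.96 * se[0] <= 0.0 or F_max <= 2.0 * rms)
    pos = c[c > 0]
    if pos.size and (pos.max() < K_d / 5 or pos.min() > K_d * 5) and not no_binding:
        flags.append("unidentifiable: concentrations do not span K_d")
    return BindingFit(
        K_d=K_d, F_max=F_max,
        se={"F_max": se[0], "K_d": se[1]},
        cov=pcov, no_binding=no_binding, flags=flags,
    )
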