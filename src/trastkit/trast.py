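"""Stationary TRAST curves: pulse-train simulation, normalization, fitting.

A TRAST measurement records the time-averaged fluorescence <F_exc(w)> from
an ensemble under rectangular excitation pulse trains of varying pulse
width w, at constant total illumination time t_ill = N*w.  Dark-state
buildup during the pulse depresses <F_exc(w)> as w grows past the
dark-state relaxation time; normalizing each point to a reference width w0
(short enough that no dark state accumulates) cancels concentration,
detection and quantum-yield factors and yields the TRAST curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np

from ._results import FitResults
from .photophysics import (
    Excitation,
    FluorophoreModel,
    IsomerizationModel,
    evolve_population,
    on_off_rates,
    rate_matrix,
)

__all__ = [
    "PulseTrain",
    "TrastCurve",
    "MonoexpTrastParams",
    "pulse_response",
    "mean_pulse_fluorescence",
    "trast_curve",
    "mixture_trast_curve",
    "interpulse_recovery",
    "MonoexpTrastModel",
    "MixtureTrastModel",
    "fit_trast",
    "default_width_grid",
]


@dataclass(frozen=True)
class PulseTrain:
    """Rectangular excitation modulation: N pulses of width w at duty cycle eta."""

    w: float
    n_pulses: int = 1
    duty_cycle: float = 0.01
    w0: float | None = None

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("pulse width must be > 0")
        if not 0 < self.duty_cycle <= 1:
            raise ValueError("duty cycle must be in (0, 1]")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")

    @property
    def t_ill(self) -> float:
        """Total illumination time N*w (s)."""
        return self.n_pulses * self.w

    @property
    def period(self) -> float:
        """Pulse repetition period w / eta (s)."""
        return self.w / self.duty_cycle

    @classmethod
    def series(
        cls,
        widths: np.ndarray,
        t_ill: float = 5e-3,
        duty_cycle: float = 0.01,
        w0: float | None = None,
    ) -> list["PulseTrain"]:
        """Constant-illumination-time series: N adjusted per width."""
        widths = np.asarray(widths, dtype=float)
        w0 = float(widths.min()) if w0 is None else w0
        return [
            cls(
                w=float(w),
                n_pulses=max(1, int(round(t_ill / w))),
                duty_cycle=duty_cycle,
                w0=w0,
            )
            for w in widths
        ]


@dataclass
class TrastCurve:
    """Normalized TRAST curve: <F_exc(w)>_norm on a strictly increasing w grid."""

    widths: np.ndarray
    values: np.ndarray
    sd: np.ndarray | None = None
    w0: float | None = None

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.widths.ndim != 1 or self.widths.size != self.values.size:
            raise ValueError("widths and values must be 1-D and equal length")
        if np.any(np.diff(self.widths) <= 0):
            raise ValueError("widths must be strictly increasing")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.values.shape:
                raise ValueError("sd must match values")
        if self.w0 is None:
            self.w0 = float(self.widths[0])

    def __len__(self) -> int:
        return self.widths.size


@dataclass(frozen=True)
class MonoexpTrastParams:
    """Monoexponential emissive-state decay [S](t) = 1 - A(1 - e^{-t/tau})."""

    a_trast: float
    tau_trast: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.a_trast <= 1.0:
            raise ValueError("a_trast must be in [0, 1]")
        if self.tau_trast <= 0:
            raise ValueError("tau_trast must be > 0")


def default_width_grid(n: int = 30, w_min: float = 1e-7, w_max: float = 1e-3):
    """Log-spaced pulse-width grid, default 30 points from 100 ns to 1 ms."""
    return np.geomspace(w_min, w_max, n)


def _two_state_params(model: FluorophoreModel, exc: Excitation) -> MonoexpTrastParams:
    k_on, k_off = on_off_rates(model, exc)
    lam = k_on + k_off
    if lam == 0.0:
        return MonoexpTrastParams(a_trast=0.0, tau_trast=np.inf)
    return MonoexpTrastParams(a_trast=k_on / lam, tau_trast=1.0 / lam)


def pulse_response(
    model: FluorophoreModel, exc: Excitation, t_grid: np.ndarray
) -> np.ndarray:
    """Relative fluorescence F(t) during one rectangular pulse, F(0+) = 1.

    Proportional to the emissive-manifold occupancy; detection efficiency,
    quantum yields and concentration fold into the (dropped) prefactor.
    """
    return evolve_population(model, exc, t_grid)[:, 0]


def _mean_relax(w: np.ndarray, a: float, tau: float) -> np.ndarray:
    """Closed-form (1/w) int_0^w [1 - A(1-e^{-t/tau})] dt, stable for w << tau."""
    w = np.asarray(w, dtype=float)
    if not np.isfinite(tau):
        return np.ones_like(w)
    x = w / tau
    with np.errstate(invalid="ignore"):
        frac = np.where(x > 1e-12, -np.expm1(-x) / np.where(x > 0, x, 1.0), 1.0 - x / 2)
    return 1.0 - a + a * frac


def mean_pulse_fluorescence(
    model: FluorophoreModel | MonoexpTrastParams,
    exc: Excitation | None,
    w,
) -> np.ndarray | float:
    """Pulse-averaged relative fluorescence <F_exc(w)> = (1/w) int_0^w F dt.

    Uses the closed form 1 - A + (A tau / w)(1 - e^{-w/tau}) for two-state
    schemes and monoexponential parameter sets; the three-state extension
    is integrated exactly through the eigen-decomposition of its rate
    matrix.
    """
    w_arr = np.atleast_1d(np.asarray(w, dtype=float))
    if np.any(w_arr <= 0):
        raise ValueError("pulse width must be > 0")
    if isinstance(model, MonoexpTrastParams):
        out = _mean_relax(w_arr, model.a_trast, model.tau_trast)
    else:
        m = rate_matrix(model, exc)
        if m.shape[0] == 2:
            p = _two_state_params(model, exc)
            out = _mean_relax(w_arr, p.a_trast, p.tau_trast)
        else:
            out = _mean_occupancy_general(m, w_arr)
    return out if np.ndim(w) else float(out[0])


def _mean_occupancy_general(m: np.ndarray, w: np.ndarray) -> np.ndarray:
    """(1/w) int_0^w [e^{Mt} p0]_0 dt via eigen-decomposition (exact)."""
    vals, vecs = np.linalg.eig(m)
    p0 = np.zeros(m.shape[0])
    p0[0] = 1.0
    coeff = np.linalg.solve(vecs, p0)
    out = np.empty_like(w)
    for i, wi in enumerate(w):
        x = vals * wi
        phi = np.where(np.abs(x) > 1e-12, np.expm1(x) / np.where(x != 0, x, 1.0), 1.0)
        out[i] = np.real(vecs[0, :] @ (coeff * phi))
    return out


def _check_series(pulse_trains) -> tuple[np.ndarray, float, float]:
    if len(pulse_trains) == 0:
        raise ValueError("empty pulse-train series")
    widths = np.array([pt.w for pt in pulse_trains], dtype=float)
    w0s = {pt.w0 for pt in pulse_trains if pt.w0 is not None}
    if len(w0s) > 1:
        raise ValueError(f"inconsistent normalization width w0 across series: {w0s}")
    w0 = w0s.pop() if w0s else float(widths.min())
    if w0 > widths.min() + 1e-30:
        raise ValueError("w0 must not exceed the smallest pulse width")
    eta = pulse_trains[0].duty_cycle
    return widths, w0, eta


def trast_curve(
    model: FluorophoreModel | MonoexpTrastParams,
    exc: Excitation | None,
    pulse_trains,
    per_pulse: bool | None = None,
) -> TrastCurve:
    """Simulate a normalized TRAST curve for a pulse-train series.

    With the default low duty cycle the fluorophore recovers fully between
    pulses and the per-train sum collapses to the single-pulse average.
    ``per_pulse=True`` (automatic for duty cycles above 0.05) instead
    propagates incomplete inter-pulse recovery through the train via
    :func:`interpulse_recovery` and averages over all pulses.
    """
    widths, w0, eta = _check_series(pulse_trains)
    order = np.argsort(widths)
    if per_pulse is None:
        per_pulse = eta > 0.05
    if per_pulse and not isinstance(model, MonoexpTrastParams):
        means = np.array(
            [_train_mean_fluorescence(model, exc, pt) for pt in pulse_trains]
        )
        ref = _train_mean_fluorescence(
            model, exc, PulseTrain(w=w0, n_pulses=1, duty_cycle=eta)
        )
    else:
        means = np.asarray(mean_pulse_fluorescence(model, exc, widths))
        ref = float(mean_pulse_fluorescence(model, exc, w0))
    if abs(1.0 - ref) > 1e-3:
        warnings.warn(
            f"reference width w0={w0:g}s already shows {100 * (1 - ref):.2f}% "
            "dark-state buildup; normalization is biased",
            stacklevel=2,
        )
    values = means / ref
    return TrastCurve(widths=widths[order], values=values[order], w0=w0)


def _train_mean_fluorescence(
    model: FluorophoreModel, exc: Excitation, train: PulseTrain
) -> float:
    """Train-averaged <F> including incomplete inter-pulse recovery."""
    starts, _ = interpulse_recovery(model, exc, train)
    p = _two_state_params(model, exc)
    a, tau = p.a_trast, p.tau_trast
    base = float(_mean_relax(np.array([train.w]), a, tau)[0])
    # a pulse starting at bright fraction n0 relaxes from n0 instead of 1:
    # mean = ss + (n0 - ss) * (tau/w)(1 - e^{-w/tau}); rewrite via base.
    ss = 1.0 - a
    frac = (base - ss) / a if a > 0 else 1.0
    means = ss + (starts - ss) * frac
    return float(np.mean(means))


def interpulse_recovery(
    model: FluorophoreModel, exc: Excitation, train: PulseTrain
) -> tuple[np.ndarray, float]:
    """Start-of-pulse bright fractions along a pulse train, plus their limit.

    During each pulse of width w the bright fraction relaxes toward the
    illuminated steady state; during the dark gap of length w(1-eta)/eta
    the dark state returns to the bright one only through the thermal
    channel (rate ``k_biso_th`` for isomerization schemes, ``k_t`` for
    triplet schemes).  The recursion for the bright fraction at pulse
    starts is affine and converges geometrically; the fixed point is
    returned alongside the per-pulse sequence.
    """
    if train.duty_cycle >= 1.0:
        return np.ones(train.n_pulses), 1.0
    p = _two_state_params(model, exc)
    a, tau = p.a_trast, p.tau_trast
    decay = np.exp(-train.w / tau) if np.isfinite(tau) else 1.0
    ss = 1.0 - a
    k_dark = (
        model.k_biso_th if isinstance(model, IsomerizationModel) else model.k_t
    )
    t_gap = train.w * (1.0 - train.duty_cycle) / train.duty_cycle
    g = np.exp(-k_dark * t_gap)
    # n_{i+1} = 1 - (1 - n_i(w)) g,  n_i(w) = ss + (n_i - ss) decay
    # => n_{i+1} = (1 - g + g*ss*(1-decay)) + g*decay*n_i
    slope = g * decay
    offset = 1.0 - g + g * ss * (1.0 - decay)
    starts = np.empty(train.n_pulses)
    n = 1.0
    for i in range(train.n_pulses):
        starts[i] = n
        n = offset + slope * n
    limit = offset / (1.0 - slope) if slope < 1.0 else 1.0
    return starts, limit


def mixture_trast_curve(
    params_cy5: MonoexpTrastParams,
    r_cy5: float,
    q_ratio: float,
    pulse_trains,
) -> TrastCurve:
    """TRAST curve of a two-species mix: flat rhodamine + relaxing cyanine.

    The detected signal is the brightness-weighted sum of a constant
    component (fraction 1-R, relative brightness Q) and the cyanine's
    monoexponential relaxation (fraction R); the mixture relaxation
    amplitude is R*A / (R + (1-R)*Q).
    """
    if not 0.0 <= r_cy5 <= 1.0:
        raise ValueError("r_cy5 must be in [0, 1]")
    if q_ratio <= 0:
        raise ValueError("q_ratio must be > 0")
    widths, w0, _ = _check_series(pulse_trains)
    order = np.argsort(widths)
    widths = widths[order]
    vals = _mixture_values(widths, w0, params_cy5, r_cy5, q_ratio)
    return TrastCurve(widths=widths, values=vals, w0=w0)


def _mixture_values(widths, w0, params, r, q):
    num = (1.0 - r) * q + r * _mean_relax(widths, params.a_trast, params.tau_trast)
    den = (1.0 - r) * q + r * _mean_relax(
        np.atleast_1d(w0), params.a_trast, params.tau_trast
    )
    return num / den[0]


# ---------------------------------------------------------------------------
# Fitting


class MonoexpTrastModel:
    """Monoexponential TRAST model fitted to one measured curve.

    Free parameters: relaxation amplitude ``a_trast`` and relaxation time
    ``tau_trast``.  Residuals are weighted by 1/sd when the curve carries
    per-point uncertainties, unweighted otherwise.
    """

    def __init__(self, curve: TrastCurve):
        if len(curve) < 4:
            raise ValueError("need at least 2 more points than free parameters")
        self.curve = curve

    def _predict(self, a: float, tau: float) -> np.ndarray:
        ref = _mean_relax(np.atleast_1d(self.curve.w0), a, tau)[0]
        return _mean_relax(self.curve.widths, a, tau) / ref

    def fit(
        self, a0: float = 0.3, tau0: float = 1e-5, bounds: dict | None = None
    ) -> FitResults:
        params = lmfit.Parameters()
        params.add("a_trast", value=a0, min=0.0, max=1.0)
        params.add("tau_trast", value=tau0, min=1e-9, max=1.0)
        if bounds:
            for name, (lo, hi) in bounds.items():
                params[name].min, params[name].max = lo, hi
        weights = None if self.curve.sd is None else 1.0 / self.curve.sd

        def resid(p):
            r = self._predict(p["a_trast"].value, p["tau_trast"].value) - (
                self.curve.values
            )
            return r if weights is None else r * weights

        out = lmfit.minimize(resid, params, method="leastsq")
        return FitResults(out, model_name="monoexp TRAST")


class MixtureTrastModel:
    """Global two-species TRAST fit across a series of mixture curves.

    The cyanine's (A, tau) come from a pure-dye fit and stay fixed; the
    brightness ratio Q is shared across all curves while each curve's
    cyanine fraction R may vary within ``r_tol`` of its externally
    determined value (e.g. from FCS on the same solutions).
    """

    def __init__(
        self,
        curves: list[TrastCurve],
        r_external: np.ndarray,
        params_cy5: MonoexpTrastParams,
        r_tol: float = 0.03,
    ):
        if len(curves) != len(r_external):
            raise ValueError("one external R per curve required")
        self.curves = list(curves)
        self.r_external = np.asarray(r_external, dtype=float)
        self.params_cy5 = params_cy5
        self.r_tol = r_tol

    def fit(self, q0: float = 2.0) -> FitResults:
        params = lmfit.Parameters()
        params.add("q_ratio", value=q0, min=1e-3, max=1e3)
        for i, r in enumerate(self.r_external):
            lo, hi = max(0.0, r - self.r_tol), min(1.0, r + self.r_tol)
            params.add(f"r_{i}", value=r, min=lo, max=hi, vary=lo < hi)

        def resid(p):
            out = []
            for i, curve in enumerate(self.curves):
                pred = _mixture_values(
                    curve.widths,
                    curve.w0,
                    self.params_cy5,
                    p[f"r_{i}"].value,
                    p["q_ratio"].value,
                )
                out.append(pred - curve.values)
            return np.concatenate(out)

        out = lmfit.minimize(resid, params, method="leastsq")
        return FitResults(out, model_name="mixture TRAST (global Q)")


def fit_trast(
    curve: TrastCurve | list[TrastCurve],
    model_spec: str = "monoexp",
    **kwargs,
) -> FitResults:
    """Functional front-end: fit a TRAST curve (or mixture series).

    ``model_spec='monoexp'`` fits (A, tau) to a single curve;
    ``model_spec='mixture'`` performs the global mixture fit and requires
    ``r_external`` and ``params_cy5`` keyword arguments.
    """
    if model_spec == "monoexp":
        init = {k: kwargs.pop(k) for k in ("a0", "tau0", "bounds") if k in kwargs}
        return MonoexpTrastModel(curve).fit(**init)
    if model_spec == "mixture":
        fit_kw = {k: kwargs.pop(k) for k in ("q0",) if k in kwargs}
        return MixtureTrastModel(curve, **kwargs).fit(**fit_kw)
    raise ValueError(f"unknown model_spec {model_spec!r}")
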