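"""Thermal-inactivation, melt-curve and steady-state kinetics analytics.

Three fits, each returning a results object in the statsmodels style
(parameters, standard errors where defined, ``summary()`` text):

* **Arrhenius inactivation.**  First-order inactivation rate constants k(T)
  measured at several temperatures follow ln k = ln A − Ea/(R·T).  Ordinary
  least squares of ln k on 1/T yields the activation energy Ea (kJ·mol⁻¹)
  and intercept ln A.  The half-inactivation temperature T50% is the
  temperature at which activity halves over 30 min, i.e. where
  k = ln 2 / 1800 s⁻¹:  T50% = Ea·1000 / (R·(lnA − ln k_half)).

* **Two-state melt.**  A denaturation trace (e.g. CD at 222 nm, 20–90 °C)
  is modelled as N ⇌ D with linear folded/unfolded baselines and a logistic
  transition; the fraction unfolded F_U is recovered from the baselines and
  Tm is the temperature where F_U = 0.5 (the logistic midpoint by
  construction).

* **Michaelis–Menten.**  Direct nonlinear least squares of
  v = Vmax·S / (KM + S); kcat = Vmax / [E] when the enzyme concentration is
  supplied.

Units: temperatures are °C at the interface and Kelvin internally; Ea is
kJ·mol⁻¹ at the interface; R = 8.314 J·mol⁻¹·K⁻¹.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, stats

from .errors import FitError

__all__ = [
    "R_GAS",
    "K_HALF_30MIN",
    "InactivationSeries",
    "ArrheniusFit",
    "T50Result",
    "MeltCurve",
    "TwoStateFit",
    "MMFit",
    "fit_arrhenius",
    "t50_from_fit",
    "fit_two_state_melt",
    "fit_michaelis_menten",
]

R_GAS = 8.314  # J mol^-1 K^-1
#: rate constant for 50% activity loss over 30 min: ln2 / 1800 s
K_HALF_30MIN = float(np.log(2.0) / 1800.0)
CELSIUS_OFFSET = 273.15


@dataclasses.dataclass
class InactivationSeries:
    """(temperature, rate constant) pairs from heat-inactivation assays."""

    temperature_k: np.ndarray
    k_per_s: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.temperature_k = np.asarray(self.temperature_k, dtype=float)
        self.k_per_s = np.asarray(self.k_per_s, dtype=float)
        if self.temperature_k.shape != self.k_per_s.shape:
            raise FitError("temperature and rate arrays differ in length")
        if np.any(self.temperature_k <= 0):
            raise FitError("temperatures must be positive Kelvin")
        if len(np.unique(self.temperature_k)) != len(self.temperature_k):
            raise FitError("temperatures must be distinct")

    @classmethod
    def from_celsius(cls, temperature_c, k_per_s, label: str = "") -> "InactivationSeries":
        return cls(np.asarray(temperature_c, dtype=float) + CELSIUS_OFFSET,
                   k_per_s, label)


@dataclasses.dataclass
class ArrheniusFit:
    """OLS fit of ln k on 1/T: Ea = −slope·R, lnA = intercept."""

    ea_kj_mol: float
    ln_a: float
    r_squared: float
    n_points: int
    ea_stderr_kj_mol: float = float("nan")
    ln_a_stderr: float = float("nan")

    def predict_k(self, temperature_k) -> np.ndarray:
        t = np.asarray(temperature_k, dtype=float)
        return np.exp(self.ln_a - self.ea_kj_mol * 1000.0 / (R_GAS * t))

    def summary(self) -> str:
        return (
            "Arrhenius inactivation fit (ln k = lnA - Ea/RT)\n"
            f"  n points   : {self.n_points}\n"
            f"  Ea         : {self.ea_kj_mol:.3f} +/- {self.ea_stderr_kj_mol:.3f} kJ/mol\n"
            f"  lnA        : {self.ln_a:.4f} +/- {self.ln_a_stderr:.4f} (k in 1/s)\n"
            f"  R^2        : {self.r_squared:.6f}\n"
        )


@dataclasses.dataclass
class T50Result:
    """Half-inactivation temperature for a 30-min incubation."""

    t50_celsius: float
    k_half: float = K_HALF_30MIN


@dataclasses.dataclass
class MeltCurve:
    """A denaturation trace: signal vs temperature (°C), e.g. CD at 222 nm."""

    temperature_c: np.ndarray
    signal: np.ndarray
    wavelength_note: str = "222 nm"

    def __post_init__(self) -> None:
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature_c.shape != self.signal.shape:
            raise FitError("temperature and signal arrays differ in length")
        if np.any(np.diff(self.temperature_c) <= 0):
            raise FitError("melt-curve temperatures must be strictly increasing")


@dataclasses.dataclass
class TwoStateFit:
    """Two-state (N ⇌ D) melt fit with linear baselines.

    ``fraction_unfolded`` is computed per input point from the fitted
    baselines; Tm is the logistic midpoint, so F_U(Tm) = 0.5 by construction.
    """

    tm_celsius: float
    steepness_per_c: float  # logistic width parameter (1/steepness scale)
    folded_baseline: tuple[float, float]  # intercept, slope
    unfolded_baseline: tuple[float, float]
    fraction_unfolded: np.ndarray
    tm_stderr: float = float("nan")
    r_squared: float = float("nan")

    def summary(self) -> str:
        return (
            "Two-state melt fit (N <-> D, linear baselines)\n"
            f"  Tm         : {self.tm_celsius:.2f} +/- {self.tm_stderr:.2f} C\n"
            f"  steepness  : {self.steepness_per_c:.4f} /C\n"
            f"  folded bl  : {self.folded_baseline[0]:.4g} + {self.folded_baseline[1]:.4g}*T\n"
            f"  unfolded bl: {self.unfolded_baseline[0]:.4g} + {self.unfolded_baseline[1]:.4g}*T\n"
            f"  R^2        : {self.r_squared:.6f}\n"
        )


@dataclasses.dataclass
class MMFit:
    """Michaelis–Menten parameters with asymptotic standard errors."""

    vmax: float
    km_mm: float
    vmax_stderr: float
    km_stderr: float
    kcat_per_s: float | None = None
    kcat_stderr: float | None = None
    r_squared: float = float("nan")

    def summary(self) -> str:
        lines = [
            "Michaelis-Menten fit (v = Vmax*S/(KM+S))",
            f"  Vmax : {self.vmax:.4g} +/- {self.vmax_stderr:.4g}",
            f"  KM   : {self.km_mm:.4g} +/- {self.km_stderr:.4g} mM",
        ]
        if self.kcat_per_s is not None:
            lines.append(
                f"  kcat : {self.kcat_per_s:.4g} +/- {self.kcat_stderr:.4g} 1/s"
            )
        lines.append(f"  R^2  : {self.r_squared:.6f}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------


def fit_arrhenius(series: InactivationSeries) -> ArrheniusFit:
    """Ordinary least squares of ln k on 1/T.

    Ea = −slope × R (reported in kJ·mol⁻¹), lnA = intercept (k in s⁻¹).
    """
    if len(series.temperature_k) < 3:
        raise FitError(f"need >= 3 points, got {len(series.temperature_k)}")
    if np.any(series.k_per_s <= 0):
        raise FitError("rate constants must be positive for an Arrhenius fit")
    x = 1.0 / series.temperature_k
    y = np.log(series.k_per_s)
    res = stats.linregress(x, y)
    return ArrheniusFit(
        ea_kj_mol=float(-res.slope * R_GAS / 1000.0),
        ln_a=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(x),
        ea_stderr_kj_mol=float(res.stderr * R_GAS / 1000.0),
        ln_a_stderr=float(res.intercept_stderr),
    )


def t50_from_fit(fit: ArrheniusFit, incubation_s: float = 1800.0) -> T50Result:
    """Invert the Arrhenius law at the 30-min half-loss rate constant.

    Solves lnA − Ea/(R·T) = ln k_half for T:
    T = Ea·1000 / (R·(lnA − ln k_half)), reported in °C.
    """
    k_half = float(np.log(2.0) / incubation_s)
    denom = fit.ln_a - np.log(k_half)
    if denom <= 0:
        raise FitError(
            "no finite positive-temperature solution: lnA <= ln(k_half) "
            f"({fit.ln_a:.3f} <= {np.log(k_half):.3f})"
        )
    t_kelvin = fit.ea_kj_mol * 1000.0 / (R_GAS * denom)
    return T50Result(t50_celsius=float(t_kelvin - CELSIUS_OFFSET), k_half=k_half)


# ---------------------------------------------------------------------------


def _two_state_signal(t, tm, width, af, bf, au, bu):
    """Signal model: baselines mixed by a logistic fraction unfolded."""
    f_u = 1.0 / (1.0 + np.exp(-(t - tm) / width))
    return (af + bf * t) * (1.0 - f_u) + (au + bu * t) * f_u


def fit_two_state_melt(
    curve: MeltCurve, constant_baselines: bool = False
) -> TwoStateFit:
    """Fit a two-state melt with linear (default) or constant baselines.

    Requires >= 8 points spanning a detectable transition.  The recovered Tm
    is invariant to linear rescaling of the signal axis.
    """
    t = curve.temperature_c
    y = curve.signal
    if len(t) < 8:
        raise FitError(f"need >= 8 points, got {len(t)}")
    span = float(y.max() - y.min())
    if span <= 0 or span < 1e-9 * max(1.0, abs(float(y.mean()))):
        raise FitError("no transition detectable: flat signal")

    n_edge = max(2, len(t) // 10)
    af0, bf0 = float(y[:n_edge].mean()), 0.0
    au0, bu0 = float(y[-n_edge:].mean()), 0.0
    # initial Tm: temperature where the signal crosses the midpoint
    mid = 0.5 * (af0 + au0)
    idx = int(np.argmin(np.abs(y - mid)))
    tm0 = float(t[idx])
    width0 = max((t[-1] - t[0]) / 20.0, 0.5)

    if constant_baselines:
        def f(tt, tm, width, af, au):
            return _two_state_signal(tt, tm, width, af, 0.0, au, 0.0)
        p0 = [tm0, width0, af0, au0]
    else:
        def f(tt, tm, width, af, bf, au, bu):
            return _two_state_signal(tt, tm, width, af, bf, au, bu)
        p0 = [tm0, width0, af0, bf0, au0, bu0]

    try:
        popt, pcov = optimize.curve_fit(f, t, y, p0=p0, maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"two-state melt fit did not converge: {exc}") from exc
    if constant_baselines:
        tm, width, af, au = popt
        bf = bu = 0.0
    else:
        tm, width, af, bf, au, bu = popt
    if not (t[0] - 20 <= tm <= t[-1] + 20):
        raise FitError(
            f"fitted Tm {tm:.1f} C lies far outside the measured range; "
            "no transition detectable"
        )
    folded = af + bf * t
    unfolded = au + bu * t
    denom = unfolded - folded
    tiny = 1e-12 * max(1.0, float(np.abs(denom).max()))
    f_u = np.clip((y - folded) / np.where(np.abs(denom) < tiny, tiny, denom), 0.0, 1.0)
    resid = y - f(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    tm_se = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else float("nan")
    return TwoStateFit(
        tm_celsius=float(tm),
        steepness_per_c=float(1.0 / width),
        folded_baseline=(float(af), float(bf)),
        unfolded_baseline=(float(au), float(bu)),
        fraction_unfolded=f_u,
        tm_stderr=tm_se,
        r_squared=r2,
    )


# ---------------------------------------------------------------------------


def fit_michaelis_menten(
    substrate_mm,
    rate,
    enzyme_conc: float | None = None,
) -> MMFit:
    """Direct nonlinear least-squares fit of v = Vmax·S/(KM + S).

    ``rate`` is in s⁻¹ (or any signal unit); when ``enzyme_conc`` is given
    in the same concentration unit used for Vmax's numerator,
    kcat = Vmax / enzyme_conc.  Requires >= 4 substrate levels; standard
    errors come from the asymptotic covariance, so sparse or one-sided
    designs yield honestly wide errors rather than silent success.
    """
    s = np.asarray(substrate_mm, dtype=float)
    v = np.asarray(rate, dtype=float)
    if s.shape != v.shape:
        raise FitError("substrate and rate arrays differ in length")
    mask = s > 0
    if np.count_nonzero(mask) < 4:
        raise FitError("need >= 4 nonzero substrate levels")
    s, v = s[mask], v[mask]

    vmax0 = float(v.max()) * 1.2
    km0 = float(np.median(s))

    def f(ss, vmax, km):
        return vmax * ss / (km + ss)

    try:
        popt, pcov = optimize.curve_fit(
            f, s, v, p0=[vmax0, km0], maxfev=20000,
            bounds=([0.0, 0.0], [np.inf, np.inf]),
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax, km = popt
    if vmax <= 0 or km <= 0:
        raise FitError("fit collapsed to a non-positive Vmax or KM")
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan, np.nan]
    resid = v - f(s, *popt)
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    kcat = kcat_se = None
    if enzyme_conc is not None:
        if enzyme_conc <= 0:
            raise FitError("enzyme concentration must be positive")
        kcat = float(vmax / enzyme_conc)
        kcat_se = float(perr[0] / enzyme_conc)
    return MMFit(
        vmax=float(vmax),
        km_mm=float(km),
        vmax_stderr=float(perr[0]),
        km_stderr=float(perr[1]),
        kcat_per_s=kcat,
        kcat_stderr=kcat_se,
        r_squared=r2,
    )
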