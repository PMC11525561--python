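"""Enzyme-kinetics assay math: fluorescence plates to fitted parameters.

Implements the quantitative workup shared by both LCAT activity readouts —
the DHE-esterification (acyltransferase) assay and the MUP hydrolysis
(phospholipase) assay:

* standard-curve fitting (fluorescence AU per µM of product);
* fluorescence → rate conversion:
  rate = (signal − background) / slope / time, in µM h⁻¹;
* Michaelis–Menten fitting, v = Vmax·S/(Km+S), by Levenberg–Marquardt
  nonlinear least squares;
* catalytic efficiency, k_cat/K_m with k_cat = Vmax/[E];
* percent change of a parameter vs. the no-PAM control, with the
  round-to-nearest-10% convention used when quoting prose percentages;
* 4-parameter-logistic (4PL) dose–response fitting on log10 concentration
  for EC50 estimation.

Fitting classes follow the statsmodels idiom: a model object built from data
whose ``fit()`` returns a results object with estimates, standard errors and
a ``summary()``; triplicate plates are fitted per replicate and summarized
as mean ± SEM of the parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

__all__ = [
    "PlateData",
    "StandardCurve",
    "fit_standard_curve",
    "signal_to_rate",
    "MichaelisMenten",
    "MMResults",
    "fit_michaelis_menten",
    "catalytic_efficiency",
    "percent_change",
    "DoseResponse",
    "DoseResponseResults",
    "fit_dose_response",
    "fit_mm_per_replicate",
]

PLATE_COLUMNS = (
    "condition_label",
    "replicate_id",
    "substrate_conc",
    "signal",
    "background_signal",
    "time_h",
)


@dataclass
class PlateData:
    """Long-format assay plate: one row per well.

    Columns: condition_label, replicate_id, substrate_conc (µM), signal (AU),
    background_signal (AU, matched per condition), time_h (h).
    """

    wells: pd.DataFrame
    standard_curve: pd.DataFrame | None = None  # columns conc, signal

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValueError(f"plate table missing columns: {missing}")
        if (self.wells["substrate_conc"] < 0).any():
            raise ValueError("substrate_conc must be >= 0")
        if (self.wells["time_h"] <= 0).any():
            raise ValueError("time_h must be > 0")

    @classmethod
    def from_csv(cls, path) -> "PlateData":
        return cls(wells=pd.read_csv(path, sep=None, engine="python"))


@dataclass
class StandardCurve:
    """Linear fluorescence-vs-concentration calibration; only the slope is
    used for conversion (background handling stays explicit)."""

    slope: float  # AU per µM
    intercept: float
    r_squared: float
    conc: np.ndarray
    signal: np.ndarray
    nonpositive_slope: bool = False


def fit_standard_curve(conc, signal) -> StandardCurve:
    """OLS line through standard wells; flags a non-positive slope."""
    conc = np.asarray(conc, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if len(conc) < 3:
        raise ValueError("need at least 3 standard points")
    if np.ptp(conc) == 0:
        raise ValueError("standard concentrations have zero spread")
    res = scipy.stats.linregress(conc, signal)
    curve = StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        conc=conc,
        signal=signal,
        nonpositive_slope=res.slope <= 0,
    )
    if curve.nonpositive_slope:
        warnings.warn("standard curve has non-positive slope", stacklevel=2)
    return curve


def signal_to_rate(plate: PlateData, curve: StandardCurve) -> pd.DataFrame:
    """Convert well fluorescence to reaction rates (µM h⁻¹).

    rate = (signal − background) / slope / time.  Negative net signals are
    clipped to a zero rate and flagged in the ``clipped`` column.
    """
    if curve.slope <= 0:
        raise ValueError("standard-curve slope must be positive for conversion")
    wells = plate.wells.copy()
    missing = wells["background_signal"].isna()
    if missing.any():
        conditions = sorted(wells.loc[missing, "condition_label"].unique())
        raise ValueError(f"missing background signal for conditions: {conditions}")
    net = wells["signal"] - wells["background_signal"]
    rate = net / curve.slope / wells["time_h"]
    wells["clipped"] = rate < 0
    wells["rate"] = rate.clip(lower=0.0)
    return wells


def _mm(S, vmax, km):
    return vmax * S / (km + S)


class MichaelisMenten:
    """Michaelis–Menten model v = Vmax·S/(Km+S) for one condition.

    Initialization: Vmax₀ = 1.2·max(v); Km₀ = substrate concentration whose
    rate is nearest half of max(v).  Solved by Levenberg–Marquardt with a
    1e-10 relative tolerance; standard errors come from the Jacobian at the
    solution.
    """

    def __init__(self, substrate_conc, rate, condition_label: str = ""):
        self.S = np.asarray(substrate_conc, dtype=float)
        self.v = np.asarray(rate, dtype=float)
        if self.S.shape != self.v.shape:
            raise ValueError("substrate_conc and rate differ in length")
        if len(np.unique(self.S[self.S > 0])) < 4:
            raise ValueError("need at least 4 distinct non-zero substrate levels")
        if np.any(self.v < 0):
            raise ValueError("rates must be non-negative")
        self.condition_label = condition_label

    @classmethod
    def from_rates(cls, rates: pd.DataFrame, condition_label: str | None = None):
        df = rates
        if condition_label is not None:
            df = df[df["condition_label"] == condition_label]
        df = df[df["substrate_conc"] > 0]
        return cls(
            df["substrate_conc"].to_numpy(),
            df["rate"].to_numpy(),
            condition_label=condition_label or "",
        )

    def fit(self, maxfev: int = 500 * 3) -> "MMResults":
        mask = self.S > 0
        S, v = self.S[mask], self.v[mask]
        vmax0 = 1.2 * float(np.max(v))
        if vmax0 <= 0:
            raise RuntimeError("all rates are zero; nothing to fit")
        half = 0.5 * float(np.max(v))
        km0 = float(S[np.argmin(np.abs(v - half))])
        km0 = max(km0, 1e-6)
        try:
            popt, pcov = scipy.optimize.curve_fit(
                _mm,
                S,
                v,
                p0=(vmax0, km0),
                method="lm",
                xtol=1e-10,
                ftol=1e-10,
                maxfev=maxfev,
            )
        except RuntimeError as exc:
            raise RuntimeError(
                f"Michaelis-Menten fit did not converge for "
                f"{self.condition_label or 'condition'}: {exc}"
            ) from None
        vmax, km = (float(p) for p in popt)
        ses = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else (np.nan, np.nan)
        km_at_bound = km <= 1e-6 or km >= 100 * float(np.max(S))
        if km_at_bound:
            warnings.warn(
                f"Km driven to a boundary ({km:.3g} µM) for "
                f"{self.condition_label or 'condition'}",
                stacklevel=2,
            )
        return MMResults(
            vmax=vmax,
            km=abs(km),
            vmax_se=float(ses[0]),
            km_se=float(ses[1]),
            condition_label=self.condition_label,
            km_at_bound=km_at_bound,
            model=self,
        )


@dataclass
class MMResults:
    """Fitted Michaelis–Menten parameters for one condition."""

    vmax: float  # µM h⁻¹
    km: float  # µM
    vmax_se: float
    km_se: float
    condition_label: str = ""
    km_at_bound: bool = False
    kcat: float | None = None  # h⁻¹, set by catalytic_efficiency
    efficiency: float | None = None  # µM⁻¹ h⁻¹
    model: MichaelisMenten | None = None

    def predict(self, S) -> np.ndarray:
        return _mm(np.asarray(S, dtype=float), self.vmax, self.km)

    def summary(self) -> str:
        lines = [
            f"Michaelis-Menten fit: {self.condition_label or '(unnamed)'}",
            f"  Vmax : {self.vmax:.4g} µM/h (SE {self.vmax_se:.3g})",
            f"  Km   : {self.km:.4g} µM (SE {self.km_se:.3g})",
        ]
        if self.kcat is not None:
            lines.append(f"  kcat : {self.kcat:.4g} /h")
        if self.efficiency is not None:
            lines.append(f"  kcat/Km : {self.efficiency:.4g} /(µM·h)")
        if self.km_at_bound:
            lines.append("  warning: Km at boundary")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.model is not None:
            ax.scatter(self.model.S, self.model.v, label="wells")
            Ss = np.linspace(0, self.model.S.max() * 1.05, 100)
        else:
            Ss = np.linspace(0, 5 * self.km, 100)
        ax.plot(Ss, self.predict(Ss), label="MM fit")
        ax.set_xlabel("substrate (µM)")
        ax.set_ylabel("rate (µM/h)")
        ax.legend()
        return ax


def fit_michaelis_menten(S, v, condition_label: str = "") -> MMResults:
    """Functional wrapper over :class:`MichaelisMenten`."""
    return MichaelisMenten(S, v, condition_label=condition_label).fit()


def catalytic_efficiency(fit: MMResults, enzyme_conc: float) -> float:
    """k_cat/K_m in µM⁻¹ h⁻¹; also stores kcat and efficiency on the fit.

    ``enzyme_conc`` is the molar enzyme concentration in µM (converting a
    mass concentration requires the enzyme's molecular weight).  Efficiency
    ratios between conditions are independent of the value used.
    """
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be > 0")
    fit.kcat = fit.vmax / enzyme_conc
    fit.efficiency = fit.kcat / fit.km
    return fit.efficiency


def percent_change(
    treated: float, control: float, round_to: float | None = 10.0
) -> float:
    """Percent change of a parameter vs. control, 100·(treated−control)/control.

    ``round_to`` rounds half away from zero to the nearest step (default the
    10%-step convention used when quoting activity increases in prose); pass
    None for the raw value.
    """
    if control <= 0:
        raise ValueError("control must be > 0")
    pct = 100.0 * (treated - control) / control
    if round_to is None:
        return pct
    steps = math.floor(abs(pct) / round_to + 0.5)
    return math.copysign(steps * round_to, pct)


def _four_pl(logc, bottom, top, log_ec50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logc) * hill))


class DoseResponse:
    """4PL dose–response model on log10 concentration.

    resp = bottom + (top − bottom) / (1 + 10^((log10 EC50 − log10 C)·hill)).

    Responses are percent of the no-PAM control (100% = control).  Zero-dose
    wells inform the bottom initialization but are excluded from the
    log-scale regression.  Initialization: bottom₀ = mean zero-dose response
    (else 100), top₀ = max response, hill₀ = 1, EC50₀ = geometric
    mid-concentration.
    """

    def __init__(self, conc, response, condition_label: str = ""):
        self.conc = np.asarray(conc, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if self.conc.shape != self.response.shape:
            raise ValueError("conc and response differ in length")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be >= 0")
        pos = np.unique(self.conc[self.conc > 0])
        if len(pos) < 5:
            raise ValueError("need at least 5 distinct non-zero concentrations")
        span = np.log10(pos.max() / pos.min())
        if span < 3 - 1e-9:
            warnings.warn(
                f"dose range spans only {span:.2f} log-decades (< 3)", stacklevel=2
            )
        self.condition_label = condition_label

    def fit(
        self,
        fix_bottom: float | None = None,
        effect_tolerance: float = 5.0,
        maxfev: int = 2000,
    ) -> "DoseResponseResults":
        mask = self.conc > 0
        logc = np.log10(self.conc[mask])
        resp = self.response[mask]
        zero_resp = self.response[~mask]

        # flat response: no dose effect to fit, EC50 undefined
        dose_means = [np.mean(resp[logc == lc]) for lc in np.unique(logc)]
        if np.ptp(dose_means) < effect_tolerance:
            return DoseResponseResults(
                ec50=math.nan,
                hill=math.nan,
                top=float(np.mean(resp)),
                bottom=float(np.mean(resp)),
                ec50_se=math.nan,
                no_effect=True,
                condition_label=self.condition_label,
                model=self,
            )

        bottom0 = (
            fix_bottom
            if fix_bottom is not None
            else (float(np.mean(zero_resp)) if len(zero_resp) else 100.0)
        )
        top0 = float(np.max(resp))
        ec50_0 = float(np.sqrt(self.conc[mask].min() * self.conc[mask].max()))
        if fix_bottom is None:
            p0 = (bottom0, top0, np.log10(ec50_0), 1.0)
            fun = _four_pl
        else:
            p0 = (top0, np.log10(ec50_0), 1.0)

            def fun(lc, top, log_ec50, hill):
                return _four_pl(lc, fix_bottom, top, log_ec50, hill)

        try:
            popt, pcov = scipy.optimize.curve_fit(
                fun, logc, resp, p0=p0, method="lm", xtol=1e-12, ftol=1e-12,
                maxfev=maxfev,
            )
        except RuntimeError as exc:
            raise RuntimeError(
                f"dose-response fit did not converge for "
                f"{self.condition_label or 'condition'}: {exc}"
            ) from None
        if fix_bottom is None:
            bottom, top, log_ec50, hill = (float(p) for p in popt)
            log_ec50_se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.nan
        else:
            top, log_ec50, hill = (float(p) for p in popt)
            bottom = float(fix_bottom)
            log_ec50_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
        ec50 = 10.0**log_ec50
        # delta method on the log10 scale
        ec50_se = ec50 * math.log(10.0) * log_ec50_se

        extrapolated = not (self.conc[mask].min() <= ec50 <= self.conc[mask].max())
        if extrapolated:
            warnings.warn(
                f"EC50 {ec50:.3g} µM lies outside the tested range", stacklevel=2
            )
        return DoseResponseResults(
            ec50=ec50,
            hill=hill,
            top=top,
            bottom=bottom,
            ec50_se=ec50_se,
            no_effect=abs(top - bottom) < effect_tolerance,
            extrapolated=extrapolated,
            condition_label=self.condition_label,
            model=self,
        )


@dataclass
class DoseResponseResults:
    """Fitted 4PL parameters; ``no_effect`` mirrors a flat dose–response."""

    ec50: float  # µM
    hill: float
    top: float  # percent of control
    bottom: float
    ec50_se: float
    no_effect: bool = False
    extrapolated: bool = False
    condition_label: str = ""
    model: DoseResponse | None = None

    def predict(self, conc) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return _four_pl(np.log10(conc), self.bottom, self.top, np.log10(self.ec50), self.hill)

    def summary(self) -> str:
        if self.no_effect:
            return (
                f"Dose-response fit: {self.condition_label or '(unnamed)'}\n"
                f"  no effect (response flat at ~{self.top:.1f}%)"
            )
        lines = [
            f"Dose-response fit: {self.condition_label or '(unnamed)'}",
            f"  EC50   : {self.ec50:.4g} µM (SE {self.ec50_se:.3g})",
            f"  Hill   : {self.hill:.3g}",
            f"  top    : {self.top:.4g} %",
            f"  bottom : {self.bottom:.4g} %",
        ]
        if self.extrapolated:
            lines.append("  warning: EC50 outside tested range")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.model is not None:
            mask = self.model.conc > 0
            ax.scatter(self.model.conc[mask], self.model.response[mask], label="wells")
        if not self.no_effect:
            cs = np.logspace(
                np.log10(self.ec50) - 3, np.log10(self.ec50) + 3, 100
            )
            ax.plot(cs, self.predict(cs), label="4PL fit")
        ax.set_xscale("log")
        ax.set_xlabel("PAM (µM)")
        ax.set_ylabel("activity (% of control)")
        ax.legend()
        return ax


def fit_dose_response(conc, response, condition_label: str = "", **kwargs) -> DoseResponseResults:
    """Functional wrapper over :class:`DoseResponse`."""
    return DoseResponse(conc, response, condition_label=condition_label).fit(**kwargs)


def fit_mm_per_replicate(
    rates: pd.DataFrame,
    condition_label: str,
    pooled: bool = False,
) -> pd.DataFrame:
    """Fit Michaelis–Menten per replicate (default) or pooled.

    Per-replicate fitting yields one (Vmax, Km) per replicate, summarized
    elsewhere as mean ± SEM — the triplicate convention for tabulated kinetic
    parameters.  ``pooled=True`` fits all wells of the condition at once.
    Returns a tidy frame: condition_label, replicate_id, vmax, km, vmax_se,
    km_se.
    """
    df = rates[rates["condition_label"] == condition_label]
    if df.empty:
        raise ValueError(f"no wells for condition {condition_label!r}")
    rows = []
    if pooled:
        fit = MichaelisMenten.from_rates(df, condition_label).fit()
        rows.append(("pooled", fit))
    else:
        for rep, sub in df.groupby("replicate_id"):
            fit = MichaelisMenten(
                sub.loc[sub["substrate_conc"] > 0, "substrate_conc"],
                sub.loc[sub["substrate_conc"] > 0, "rate"],
                condition_label=f"{condition_label}/{rep}",
            ).fit()
            rows.append((rep, fit))
    return pd.DataFrame(
        {
            "condition_label": condition_label,
            "replicate_id": [r for r, _ in rows],
            "vmax": [f.vmax for _, f in rows],
            "km": [f.km for _, f in rows],
            "vmax_se": [f.vmax_se for _, f in rows],
            "km_se": [f.km_se for _, f in rows],
        }
    )
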