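"""Radiotracer uptake kinetics: initial rates, Michaelis–Menten and IC50
fits, Cheng–Prusoff conversion and wild-type normalization.

The two curve fits follow the statsmodels convention: a model object is
built from a dataset, ``fit()`` returns a results object carrying the
estimates, their standard errors, diagnostics and a ``summary()`` table.

Conventions
-----------
* Initial rates are least-squares slopes over the linear uptake window
  (default 2 min), estimated per replicate and averaged; the SE comes from
  the replicate spread.
* V% = 100·(rate_mutant − rate_background)/(rate_wt − rate_background),
  floored at 0; values below the background-resolution bound (2% of wt)
  are reported as ``"<2"``.
* The IC50 model is the competitive form with unit Hill slope,
  v(I) = V0/(1 + I/IC50); a free slope is available as a diagnostic.
* Ki = IC50/(1 + L/Km) (Cheng–Prusoff). Constants fitted beyond the
  maximum tested concentration are censored at that bound (``">3000"``).
* The saturation fit defaults to relative-error weighting: assay noise is
  multiplicative (replicate SD proportional to the mean), so weighted least
  squares with sigma proportional to the signal is the correctly specified
  objective — it keeps the mean fitted Km unbiased even when the true Km
  lies beyond the assayed range. Unweighted raw-signal least squares is
  available via ``weighting=None``; the competition fit is unweighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .containers import CensoredValue, UptakeDataset
from .synthetic import michaelis_menten_rate

__all__ = [
    "RateEstimate",
    "initial_rate",
    "VPercent",
    "relative_uptake",
    "MichaelisMentenModel",
    "MichaelisMentenResults",
    "fit_michaelis_menten",
    "CompetitionModel",
    "InhibitionResults",
    "fit_ic50",
    "cheng_prusoff",
]

_FIT_KW = dict(method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000)


# ---------------------------------------------------------------------------
# initial rates and wild-type normalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateEstimate:
    """An initial uptake rate (signal per minute) with replicate-spread SE."""

    value: float
    se: float
    n_replicates: int


def initial_rate(tc: UptakeDataset, window: float = 2.0) -> RateEstimate:
    """Least-squares slope of accumulated signal vs time over the linear window.

    The slope is estimated per replicate (line with intercept) and averaged;
    the SE is the standard error of the replicate mean.
    """
    if tc.kind != "timecourse":
        raise ValueError("initial_rate expects a timecourse dataset")
    slopes = []
    for _, rep in tc.data.groupby("replicate"):
        mask = rep["x"].to_numpy(float) <= window
        t = rep["x"].to_numpy(float)[mask]
        y = rep["signal"].to_numpy(float)[mask]
        if len(t) < 2:
            raise ValueError(f"fewer than 2 time points inside the {window}-min window")
        slope = np.polyfit(t, y, 1)[0]
        slopes.append(slope)
    slopes = np.asarray(slopes)
    se = float(slopes.std(ddof=1) / np.sqrt(len(slopes))) if len(slopes) > 1 else float("nan")
    return RateEstimate(value=float(slopes.mean()), se=se, n_replicates=len(slopes))


@dataclass(frozen=True)
class VPercent:
    """Background-subtracted uptake rate as percent of wild type.

    Values below ``resolution`` (default 2, the loss-of-function bound) are
    displayed as ``"<2"``.
    """

    value: float
    resolution: float = 2.0

    @property
    def below_resolution(self) -> bool:
        return self.value < self.resolution

    def __str__(self) -> str:
        if self.below_resolution:
            return f"<{self.resolution:g}"
        return f"{self.value:.1f}"

    def __float__(self) -> float:
        return self.value


def relative_uptake(
    rate_mutant: float | RateEstimate,
    rate_wt: float | RateEstimate,
    rate_background: float | RateEstimate,
    resolution: float = 2.0,
) -> VPercent:
    """V% = 100·(mutant − background)/(wt − background), floored at 0."""
    m = float(rate_mutant.value if isinstance(rate_mutant, RateEstimate) else rate_mutant)
    w = float(rate_wt.value if isinstance(rate_wt, RateEstimate) else rate_wt)
    b = float(
        rate_background.value if isinstance(rate_background, RateEstimate) else rate_background
    )
    if w <= b:
        raise ValueError("wild-type rate must exceed the background rate (assay invalid)")
    value = max(100.0 * (m - b) / (w - b), 0.0)
    return VPercent(value=value, resolution=resolution)


# ---------------------------------------------------------------------------
# Michaelis–Menten saturation fit
# ---------------------------------------------------------------------------


@dataclass
class MichaelisMentenResults:
    """Estimates from a saturation-curve fit: Km, Vmax, SEs, diagnostics."""

    Km: float
    Vmax: float
    Km_se: float
    Vmax_se: float
    cov: np.ndarray
    residual_norm: float
    converged: bool
    reliable: bool
    conc_range: tuple[float, float]
    n_obs: int

    def summary(self) -> str:
        lines = [
            "Michaelis-Menten saturation fit",
            "===============================",
            f"  n observations : {self.n_obs}",
            f"  tested range   : {self.conc_range[0]:g}-{self.conc_range[1]:g} uM",
            f"  Km   : {self.Km:10.4g} +/- {self.Km_se:.3g} uM",
            f"  Vmax : {self.Vmax:10.4g} +/- {self.Vmax_se:.3g}",
            f"  residual norm  : {self.residual_norm:.4g}",
            f"  converged      : {self.converged}",
            f"  reliable       : {self.reliable}",
        ]
        return "\n".join(lines)


class MichaelisMentenModel:
    """Nonlinear least-squares model v = Vmax·S/(Km+S) on raw signals.

    Initial guesses come from a Hanes–Woolf linearization of the replicate
    means; both parameters are constrained positive. The default fit uses
    relative-error weighting (see the module docstring); pass
    ``weighting=None`` for unweighted least squares. A fitted Km more than
    ten-fold outside the tested concentration range flags the result as
    unreliable.
    """

    def __init__(self, dataset: UptakeDataset):
        if dataset.kind != "saturation":
            raise ValueError("MichaelisMentenModel expects a saturation dataset")
        if len(dataset.x_values) < 4:
            raise ValueError("need >=4 distinct concentrations spanning the curve")
        self.dataset = dataset
        self.S = dataset.data["x"].to_numpy(float)
        self.v = dataset.data["signal"].to_numpy(float)

    def _start_values(self) -> tuple[float, float]:
        means = self.dataset.means()
        S = means.index.to_numpy(float)
        v = means.to_numpy(float)
        ok = v > 0
        if ok.sum() >= 2:
            # Hanes-Woolf: S/v = Km/Vmax + S/Vmax
            slope, intercept = np.polyfit(S[ok], S[ok] / v[ok], 1)
            if slope > 0 and intercept > 0:
                return intercept / slope, 1.0 / slope
        vmax0 = max(v.max(), 1e-6)
        km0 = S[np.argmin(np.abs(v - vmax0 / 2))] if len(S) else 1.0
        return max(km0, 1e-6), vmax0

    def fit(self, weighting: Literal[None, "relative"] = "relative") -> MichaelisMentenResults:
        km0, vmax0 = self._start_values()
        sigma = None
        if weighting == "relative":
            sigma = np.maximum(np.abs(self.v), 1e-12)
        converged = True
        try:
            popt, pcov = curve_fit(
                michaelis_menten_rate,
                self.S,
                self.v,
                p0=[km0, vmax0],
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                sigma=sigma,
                **_FIT_KW,
            )
        except RuntimeError:
            converged = False
            popt = np.array([np.nan, np.nan])
            pcov = np.full((2, 2), np.nan)
        km, vmax = popt
        se = np.sqrt(np.diag(pcov))
        resid = self.v - michaelis_menten_rate(self.S, km, vmax) if converged else np.array([np.nan])
        lo, hi = float(self.S.min()), float(self.S.max())
        reliable = converged and (lo / 10.0 <= km <= hi * 10.0)
        if not reliable:
            warnings.warn("saturation fit flagged unreliable (non-convergence or Km far outside tested range)")
        return MichaelisMentenResults(
            Km=float(km),
            Vmax=float(vmax),
            Km_se=float(se[0]),
            Vmax_se=float(se[1]),
            cov=pcov,
            residual_norm=float(np.sqrt(np.nansum(resid**2))),
            converged=converged,
            reliable=reliable,
            conc_range=(lo, hi),
            n_obs=len(self.S),
        )


def fit_michaelis_menten(
    ds: UptakeDataset, weighting: Literal[None, "relative"] = "relative"
) -> MichaelisMentenResults:
    """Fit a saturation dataset; see :class:`MichaelisMentenModel`."""
    return MichaelisMentenModel(ds).fit(weighting=weighting)


# ---------------------------------------------------------------------------
# IC50 competition fit and Cheng–Prusoff
# ---------------------------------------------------------------------------


def _ic50_curve(I: np.ndarray, V0: float, ic50: float) -> np.ndarray:
    return V0 / (1.0 + I / ic50)


def _ic50_curve_free_slope(I: np.ndarray, V0: float, ic50: float, h: float) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(I > 0, (I / ic50) ** h, 0.0)
    return V0 / (1.0 + ratio)


@dataclass
class InhibitionResults:
    """Estimates from a competition fit: IC50 (possibly censored), V0, SEs."""

    IC50: float | CensoredValue
    IC50_se: float
    V0: float
    V0_se: float
    hill_slope: float
    residual_norm: float
    converged: bool
    max_tested: float
    substrate: str
    tracer_conc: float | None

    @property
    def censored(self) -> bool:
        return isinstance(self.IC50, CensoredValue)

    def ki(self, Km: float) -> float | CensoredValue:
        """Cheng–Prusoff conversion using the tracer concentration on record."""
        if self.tracer_conc is None:
            raise ValueError("dataset carries no tracer concentration L")
        return cheng_prusoff(self.IC50, self.tracer_conc, Km)

    def summary(self) -> str:
        ic50 = str(self.IC50) if self.censored else f"{self.IC50:.4g}"
        lines = [
            "Competition (IC50) fit",
            "======================",
            f"  substrate      : {self.substrate}",
            f"  tracer L       : {self.tracer_conc} uM",
            f"  IC50 : {ic50} uM" + ("" if self.censored else f" +/- {self.IC50_se:.3g}"),
            f"  V0   : {self.V0:.4g} +/- {self.V0_se:.3g}",
            f"  Hill slope     : {self.hill_slope:g}",
            f"  residual norm  : {self.residual_norm:.4g}",
            f"  converged      : {self.converged}",
        ]
        return "\n".join(lines)


class CompetitionModel:
    """Competitive-inhibition dose-response model v(I) = V0/(1 + I/IC50).

    The Hill slope is fixed at 1 (competitive inhibition of a
    Michaelis–Menten carrier at fixed tracer concentration implies unit
    slope); ``fit(free_slope=True)`` frees it as a diagnostic. An IC50
    fitted beyond the maximum tested concentration — including a flat,
    uninhibited response — is reported censored at that bound.
    """

    def __init__(self, dataset: UptakeDataset):
        if dataset.kind != "competition":
            raise ValueError("CompetitionModel expects a competition dataset")
        x = dataset.x_values
        if len(x) < 4:
            raise ValueError("need >=4 inhibitor concentrations")
        if 0.0 not in x:
            raise ValueError("competition fit needs the I=0 anchor")
        self.dataset = dataset
        self.I = dataset.data["x"].to_numpy(float)
        self.v = dataset.data["signal"].to_numpy(float)

    def _start_values(self) -> tuple[float, float]:
        means = self.dataset.means()
        I = means.index.to_numpy(float)
        v = means.to_numpy(float)
        v0 = float(v[I == 0].mean()) if (I == 0).any() else float(v.max())
        v0 = max(v0, 1e-9)
        below = I[(v <= v0 / 2) & (I > 0)]
        ic50 = float(below.min()) if below.size else float(I.max())
        return v0, max(ic50, 1e-6)

    def fit(self, free_slope: bool = False) -> InhibitionResults:
        v0_0, ic50_0 = self._start_values()
        max_tested = float(self.I.max())
        converged = True
        if free_slope:
            fun, p0, bounds = (
                _ic50_curve_free_slope,
                [v0_0, ic50_0, 1.0],
                ([1e-12, 1e-12, 0.1], [np.inf, np.inf, 10.0]),
            )
        else:
            fun, p0, bounds = _ic50_curve, [v0_0, ic50_0], ([1e-12, 1e-12], [np.inf, np.inf])
        try:
            popt, pcov = curve_fit(fun, self.I, self.v, p0=p0, bounds=bounds, **_FIT_KW)
            se = np.sqrt(np.diag(pcov))
        except RuntimeError:
            converged = False
            popt = np.full(len(p0), np.nan)
            se = np.full(len(p0), np.nan)
        v0, ic50 = float(popt[0]), float(popt[1])
        hill = float(popt[2]) if free_slope else 1.0
        if converged:
            resid = self.v - fun(self.I, *popt)
            residual_norm = float(np.sqrt(np.sum(resid**2)))
        else:
            residual_norm = float("nan")
        ic50_out: float | CensoredValue
        if not converged or not np.isfinite(ic50) or ic50 > max_tested:
            # beyond the assay range (or no inhibition signal at all)
            ic50_out = CensoredValue(bound=max_tested, op=">")
            ic50_se = float("nan")
        else:
            ic50_out = ic50
            ic50_se = float(se[1])
        return InhibitionResults(
            IC50=ic50_out,
            IC50_se=ic50_se,
            V0=v0,
            V0_se=float(se[0]),
            hill_slope=hill,
            residual_norm=residual_norm,
            converged=converged,
            max_tested=max_tested,
            substrate=self.dataset.condition,
            tracer_conc=self.dataset.tracer_conc,
        )


def fit_ic50(ds: UptakeDataset, free_slope: bool = False) -> InhibitionResults:
    """Fit a competition dataset; see :class:`CompetitionModel`."""
    return CompetitionModel(ds).fit(free_slope=free_slope)


def cheng_prusoff(
    IC50: float | CensoredValue, L: float, Km: float
) -> float | CensoredValue:
    """Ki = IC50/(1 + L/Km).

    ``L`` is the tracer (permeant) concentration. A censored IC50 propagates
    to a censored Ki reported at the same assay bound (the convention used
    for constants beyond the tested range).
    """
    if L < 0:
        raise ValueError("tracer concentration must be >= 0")
    if not Km > 0:
        raise ValueError("Km must be > 0")
    if isinstance(IC50, CensoredValue):
        if IC50.op != ">":
            raise ValueError("only '>'-censored IC50 values occur in competition fits")
        return IC50
    if not IC50 > 0:
        raise ValueError("IC50 must be > 0")
    return IC50 / (1.0 + L / Km)
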