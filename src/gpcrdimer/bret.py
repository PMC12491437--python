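"""BRET quantification: net ratios, curve fits and the Emax/EC50 bias factor.

Bioluminescence resonance energy transfer (BRET) reports molecular
proximity between a luciferase donor (emission read at 475 nm) and a
fluorophore acceptor (535 nm).  The pipeline turns raw dual-emission plate
readings into derived quantities:

- *net BRET*: the 535/475 ratio averaged over repeat cycles minus the
  donor-only control ratio.
- *saturation fit*: net BRET vs acceptor/donor expression fitted to
  one-site specific binding, y = BRETmax * x / (BRET50 + x).  BRETmax
  reflects protomer proximity; BRET50 protomer-protomer affinity.
- *kinetics fit*: ligand-induced BRET vs time fitted to one-phase
  association, y = plateau * (1 - exp(-k t)) with y0 = 0 by construction
  (basal-subtracted traces).  Halftime = ln 2 / k and initial rate =
  k * span (span = plateau - y0) are exact derived fields.
- *dose-response fit*: y = baseline + (Emax - baseline) / (1 + EC50/conc)
  with the Hill slope fixed at 1 by default; reported as -log10 EC50.
- *bias factor*: Emax/EC50 per signaling pathway, expressed as fold change
  versus a reference condition.

All fits are bounded nonlinear least squares with documented initialization
heuristics; non-convergent or degenerate fits are returned flagged rather
than raised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .simulate import kinetics_model, saturation_model

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))

__all__ = [
    "SaturationFit",
    "KineticsFit",
    "DoseResponseFit",
    "BiasResult",
    "net_bret",
    "net_acceptor",
    "ligand_induced_trace",
    "SaturationCurve",
    "AssociationKinetics",
    "DoseResponseCurve",
    "fit_saturation",
    "fit_kinetics",
    "fit_dose_response",
    "bias_factor",
]


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SaturationFit:
    bretmax: float
    bret50: float
    bretmax_se: float
    bret50_se: float
    rss: float
    converged: bool


@dataclass(frozen=True)
class KineticsFit:
    k_per_s: float
    plateau: float
    halftime_s: float  # ln(2)/k, exact
    initial_rate: float  # k * span, exact
    span: float  # plateau - y0; y0 = 0 for ligand-induced traces
    k_se: float
    plateau_se: float
    rss: float
    converged: bool


@dataclass(frozen=True)
class DoseResponseFit:
    ec50_m: float
    neg_log_ec50: float  # -log10(EC50 [M])
    emax: float
    baseline: float
    rss: float
    converged: bool


@dataclass(frozen=True)
class BiasResult:
    pathway: str
    condition: str
    emax_over_ec50: float
    fold_change: float  # versus the reference condition, same pathway


# ---------------------------------------------------------------------------
# ratio arithmetic
# ---------------------------------------------------------------------------


def _mean_ratio(readings: pd.DataFrame) -> float:
    """Mean 535/475 ratio over cycles; non-positive 475 rows are dropped."""
    em475 = readings["em475"].to_numpy(dtype=float)
    em535 = readings["em535"].to_numpy(dtype=float)
    ok = em475 > 0
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("dropping %d readings with non-positive 475 nm emission", n_bad)
    if not ok.any():
        raise ValueError("no usable readings (all 475 nm emissions non-positive)")
    return float((em535[ok] / em475[ok]).mean())


def net_bret(
    readings: pd.DataFrame,
    donor_only: str,
    by: str = "condition",
) -> pd.Series:
    """Net BRET per condition: mean cycle ratio minus the donor-only ratio.

    ``readings`` is long-format with at least ``em475``, ``em535`` and the
    grouping column ``by``; ``donor_only`` names the negative-control
    condition whose mean ratio is subtracted from every other condition.
    """
    if donor_only not in set(readings[by]):
        raise ValueError(f"donor-only condition {donor_only!r} not present")
    donor_ratio = _mean_ratio(readings[readings[by] == donor_only])
    out = {}
    for cond, grp in readings.groupby(by, sort=False):
        if cond == donor_only:
            continue
        out[cond] = _mean_ratio(grp) - donor_ratio
    return pd.Series(out, name="net_bret")


def net_acceptor(
    readings: pd.DataFrame,
    donor_only: str,
    value: str = "venus",
    by: str = "condition",
) -> pd.Series:
    """Net acceptor fluorescence: condition mean minus the donor-only mean."""
    if donor_only not in set(readings[by]):
        raise ValueError(f"donor-only condition {donor_only!r} not present")
    donor_mean = readings.loc[readings[by] == donor_only, value].astype(float).mean()
    means = (
        readings[readings[by] != donor_only]
        .groupby(by, sort=False)[value]
        .mean()
        .astype(float)
    )
    return (means - donor_mean).rename("net_acceptor")


def ligand_induced_trace(
    basal: pd.DataFrame,
    post: pd.DataFrame,
    vehicle: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Ligand-induced BRET trace: post-agonist ratios minus the basal mean.

    ``basal`` holds pre-addition readings (``em475``, ``em535``); ``post``
    holds the time series with a ``time_s`` column (t = 0 at agonist
    addition, strictly increasing).  An optional ``vehicle`` trace on the
    same time grid is subtracted pointwise to remove addition artifacts.
    Returns a frame with ``time_s`` and ``y`` (ligand-induced BRET ratio).
    """
    if len(basal) == 0:
        raise ValueError("basal readings are required before agonist addition")
    t = post["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("post-agonist timestamps must be strictly increasing")
    basal_ratio = _mean_ratio(basal)
    y = post["em535"].to_numpy(dtype=float) / post["em475"].to_numpy(dtype=float) - basal_ratio
    if vehicle is not None:
        tv = vehicle["time_s"].to_numpy(dtype=float)
        if len(tv) != len(t) or not np.allclose(tv, t):
            raise ValueError("vehicle trace must share the post-agonist time grid")
        yv = (
            vehicle["em535"].to_numpy(dtype=float)
            / vehicle["em475"].to_numpy(dtype=float)
            - basal_ratio
        )
        y = y - yv
    return pd.DataFrame({"time_s": t, "y": y})


# ---------------------------------------------------------------------------
# curve-fit estimators
# ---------------------------------------------------------------------------

_MAXFEV = 1000
_XTOL = 1e-8


def _as_xy(X, y):
    x = np.asarray(X, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if len(x) != len(y):
        raise ValueError("X and y must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return x, y


class SaturationCurve(RegressorMixin, BaseEstimator):
    """One-site specific-binding fit y = BRETmax * x / (BRET50 + x).

    x is the net acceptor / donor expression ratio, y the net BRET.
    Initialization: BRETmax0 = max(y), BRET50 at the x nearest half-max;
    both parameters bounded non-negative.

    Attributes: ``bretmax_``, ``bret50_``, ``bretmax_se_``, ``bret50_se_``,
    ``rss_``, ``converged_``.
    """

    def __init__(self, min_points: int = 4):
        self.min_points = min_points

    def fit(self, X, y):
        x, yv = _as_xy(X, y)
        if len(np.unique(x)) < self.min_points:
            raise ValueError(f"need >= {self.min_points} distinct x values")
        bmax0 = max(float(yv.max()), 1e-12)
        b50_0 = max(float(x[np.argmin(np.abs(yv - bmax0 / 2.0))]), 1e-12)
        self.converged_ = True
        try:
            popt, pcov = curve_fit(
                saturation_model,
                x,
                yv,
                p0=[bmax0, b50_0],
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                xtol=_XTOL,
                maxfev=_MAXFEV,
            )
        except RuntimeError:
            popt, pcov = np.array([bmax0, b50_0]), np.full((2, 2), np.nan)
            self.converged_ = False
        self.bretmax_, self.bret50_ = map(float, popt)
        se = np.sqrt(np.diag(pcov))
        self.bretmax_se_, self.bret50_se_ = map(float, se)
        self.rss_ = float(((yv - saturation_model(x, *popt)) ** 2).sum())
        if self.bretmax_ <= 1e-9 or self.bret50_ <= 1e-12:
            # flat or degenerate data: parameters unidentifiable
            self.converged_ = False
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return saturation_model(x, self.bretmax_, self.bret50_)

    def result(self) -> SaturationFit:
        return SaturationFit(
            self.bretmax_,
            self.bret50_,
            self.bretmax_se_,
            self.bret50_se_,
            self.rss_,
            self.converged_,
        )


class AssociationKinetics(RegressorMixin, BaseEstimator):
    """One-phase association fit y = plateau * (1 - exp(-k t)), y0 = 0.

    Ligand-induced traces are basal-subtracted, which pins y0 at zero; a
    free-y0 variant (``fit_y0=True``) is available for raw ratio traces.
    Derived quantities are computed exactly from the fitted parameters:
    ``halftime_s_ = ln(2)/k`` and ``initial_rate_ = k * span`` with
    ``span_ = plateau - y0``.

    A fit with fewer than ``min_points`` samples, or a time window shorter
    than two fitted halftimes, logs a warning.
    """

    def __init__(self, fit_y0: bool = False, min_points: int = 8):
        self.fit_y0 = fit_y0
        self.min_points = min_points

    def fit(self, X, y):
        t, yv = _as_xy(X, y)
        if len(t) < self.min_points:
            logger.warning("kinetics fit on %d points (< %d)", len(t), self.min_points)
        plateau0 = max(float(np.mean(yv[-max(3, len(yv) // 5):])), 1e-12)
        half_idx = np.argmin(np.abs(yv - plateau0 / 2.0))
        if t[half_idx] > 0:
            t_half0 = float(t[half_idx])
        else:
            positive = t[t > 0]
            t_half0 = float(np.median(positive)) if len(positive) else 1.0
        k0 = LN2 / t_half0

        if self.fit_y0:
            def model(tt, k, plateau, y0):
                return y0 + (plateau - y0) * (1.0 - np.exp(-k * tt))

            p0 = [k0, plateau0, float(yv[0])]
            bounds = ([0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf])
        else:
            model = kinetics_model
            p0 = [k0, plateau0]
            bounds = ([0.0, 0.0], [np.inf, np.inf])

        self.converged_ = True
        try:
            popt, pcov = curve_fit(
                model, t, yv, p0=p0, bounds=bounds, xtol=_XTOL, maxfev=_MAXFEV
            )
        except RuntimeError:
            popt, pcov = np.array(p0), np.full((len(p0),) * 2, np.nan)
            self.converged_ = False
        self.k_ = float(popt[0])
        self.plateau_ = float(popt[1])
        self.y0_ = float(popt[2]) if self.fit_y0 else 0.0
        se = np.sqrt(np.diag(pcov))
        self.k_se_, self.plateau_se_ = float(se[0]), float(se[1])
        self.rss_ = float(((yv - model(t, *popt)) ** 2).sum())
        if self.k_ <= 0:
            self.converged_ = False
        self.span_ = self.plateau_ - self.y0_
        self.halftime_s_ = LN2 / self.k_ if self.k_ > 0 else np.inf
        self.initial_rate_ = self.k_ * self.span_
        if self.k_ > 0 and t.max() < 2.0 * self.halftime_s_:
            logger.warning(
                "kinetics trace spans %.3g s, less than two halftimes (%.3g s)",
                t.max(),
                self.halftime_s_,
            )
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return self.y0_ + (self.plateau_ - self.y0_) * (1.0 - np.exp(-self.k_ * t))

    def result(self) -> KineticsFit:
        return KineticsFit(
            self.k_,
            self.plateau_,
            self.halftime_s_,
            self.initial_rate_,
            self.span_,
            self.k_se_,
            self.plateau_se_,
            self.rss_,
            self.converged_,
        )


class DoseResponseCurve(RegressorMixin, BaseEstimator):
    """Concentration-response fit with the Hill slope fixed at 1 by default.

    y = baseline + (Emax - baseline) / (1 + (EC50/conc)^hill); EC50 is
    fitted on the log10 scale for stability and reported both as molar and
    as -log10 EC50.  ``variable_slope=True`` frees the Hill coefficient.
    """

    def __init__(self, variable_slope: bool = False, min_points: int = 5):
        self.variable_slope = variable_slope
        self.min_points = min_points

    def fit(self, X, y):
        conc, yv = _as_xy(X, y)
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive (molar)")
        if len(np.unique(conc)) < self.min_points:
            raise ValueError(f"need >= {self.min_points} distinct concentrations")
        logc = np.log10(conc)
        base0, emax0 = float(yv.min()), float(yv.max())
        half = (base0 + emax0) / 2.0
        logec50_0 = float(logc[np.argmin(np.abs(yv - half))])

        if self.variable_slope:
            def model(lc, baseline, emax, logec50, hill):
                return baseline + (emax - baseline) / (1.0 + 10 ** (hill * (logec50 - lc)))

            p0 = [base0, emax0, logec50_0, 1.0]
            bounds = (
                [-np.inf, -np.inf, logc.min() - 6, 0.1],
                [np.inf, np.inf, logc.max() + 6, 10.0],
            )
        else:
            def model(lc, baseline, emax, logec50):
                return baseline + (emax - baseline) / (1.0 + 10 ** (logec50 - lc))

            p0 = [base0, emax0, logec50_0]
            bounds = (
                [-np.inf, -np.inf, logc.min() - 6],
                [np.inf, np.inf, logc.max() + 6],
            )

        self.converged_ = True
        try:
            popt, _ = curve_fit(
                model, logc, yv, p0=p0, bounds=bounds, xtol=_XTOL, maxfev=_MAXFEV
            )
        except RuntimeError:
            popt = np.array(p0)
            self.converged_ = False
        self.baseline_, self.emax_ = float(popt[0]), float(popt[1])
        self.log_ec50_ = float(popt[2])
        self.hill_ = float(popt[3]) if self.variable_slope else 1.0
        self.ec50_m_ = 10.0**self.log_ec50_
        self.neg_log_ec50_ = -self.log_ec50_
        self.rss_ = float(((yv - model(logc, *popt)) ** 2).sum())
        span = float(yv.max() - yv.min())
        if span <= 0 or abs(self.emax_ - self.baseline_) < 1e-12:
            # constant response: EC50 unidentifiable
            self.converged_ = False
        return self

    def predict(self, X):
        conc = np.asarray(X, dtype=float).reshape(-1)
        return self.baseline_ + (self.emax_ - self.baseline_) / (
            1.0 + (self.ec50_m_ / conc) ** self.hill_
        )

    def result(self) -> DoseResponseFit:
        return DoseResponseFit(
            self.ec50_m_,
            self.neg_log_ec50_,
            self.emax_,
            self.baseline_,
            self.rss_,
            self.converged_,
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def fit_saturation(x, y) -> SaturationFit:
    """Fit net BRET vs acceptor/donor ratio to one-site specific binding."""
    return SaturationCurve().fit(x, y).result()


def fit_kinetics(trace: pd.DataFrame | np.ndarray, y=None, fit_y0: bool = False) -> KineticsFit:
    """Fit a ligand-induced trace to one-phase association.

    Accepts either a trace frame with ``time_s``/``y`` columns or separate
    time and value arrays.
    """
    if isinstance(trace, pd.DataFrame):
        t, yv = trace["time_s"], trace["y"]
    else:
        t, yv = trace, y
    return AssociationKinetics(fit_y0=fit_y0).fit(t, yv).result()


def fit_dose_response(conc, y, variable_slope: bool = False) -> DoseResponseFit:
    """Fit a concentration-response curve; reports -log10 EC50."""
    return DoseResponseCurve(variable_slope=variable_slope).fit(conc, y).result()


def bias_factor(
    fits: pd.DataFrame,
    reference_condition: str,
) -> pd.DataFrame:
    """Emax/EC50 bias factors with fold change versus a reference condition.

    ``fits`` needs columns ``pathway``, ``condition``, ``emax``, ``ec50_m``
    and optionally ``converged`` (non-converged rows are rejected).  Within
    each pathway the fold change is Emax/EC50 relative to the reference
    condition, which therefore maps to exactly 1.
    """
    required = {"pathway", "condition", "emax", "ec50_m"}
    if not required.issubset(fits.columns):
        raise ValueError(f"fits must have columns {sorted(required)}")
    if "converged" in fits.columns and not fits["converged"].all():
        bad = fits.loc[~fits["converged"], ["pathway", "condition"]]
        raise ValueError(f"bias factor requires converged fits; failing rows:\n{bad}")
    rows = []
    for pathway, grp in fits.groupby("pathway", sort=False):
        conds = grp.set_index("condition")
        if reference_condition not in conds.index:
            raise ValueError(
                f"reference condition {reference_condition!r} missing for pathway {pathway!r}"
            )
        values = conds["emax"] / conds["ec50_m"]
        ref = values.loc[reference_condition]
        for cond, val in values.items():
            rows.append(
                BiasResult(
                    pathway=str(pathway),
                    condition=str(cond),
                    emax_over_ec50=float(val),
                    fold_change=float(val / ref),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
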