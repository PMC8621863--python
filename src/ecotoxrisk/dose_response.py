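"""Concentration-effect modelling and test-validity gating.

The curve model is the two-parameter log-logistic (Hill) function on the
percent-effect scale,

    effect(c) = 100 / (1 + (EC50 / c)^h),

with floor 0 and ceiling 100: the effect at the EC50 is exactly 50 %.
Continuous endpoints are fitted by weighted least squares on level-mean
percent inhibition; the quantal immobilisation endpoint by binomial maximum
likelihood on vessel counts.  95 % confidence limits for the EC50 come from
a seeded nonparametric bootstrap over replicate vessels (expanded
percentile interval; see ``_expanded_percentile_ci``).

Percent effects for growth endpoints are computed on growth increments
(final minus initial density or frond area) relative to the control mean;
stimulation (negative inhibition) is preserved in reports but clipped to
zero before fitting and mixture arithmetic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .datasets import DoseResponseDataset, Endpoint, Organism
from .units import AnalyteConcentration, UnitError

__all__ = [
    "FittedCurve",
    "ValidityReport",
    "EffectTable",
    "log_logistic",
    "percent_effect",
    "check_validity",
    "fit_log_logistic",
    "ec50_to_analyte_concentration",
    "write_curves_json",
    "read_curves_json",
    "InvalidControlError",
    "MonotonicityError",
    "CannotEvaluateError",
]

#: Control-validity thresholds per organism: (description, threshold).
VALIDITY_RULES = {
    Organism.P_subcapitata: ("control fold-growth over 72 h", 16.0),
    Organism.S_polyrhiza: ("mean control frond area growth (mm^2)", 10.0),
    Organism.D_magna: ("control immobilisation (%)", 10.0),
}


class InvalidControlError(ValueError):
    """Control growth is non-positive; percent inhibition is undefined."""


class MonotonicityError(ValueError):
    """Mean effect decreases with concentration; the model does not apply."""


class CannotEvaluateError(ValueError):
    """A validity criterion cannot be evaluated from the data provided."""


def log_logistic(c, ec50: float, hill_slope: float):
    """Two-parameter log-logistic percent effect, 100 / (1 + (EC50/c)^h).

    Evaluated in log space for numerical stability at extreme ratios;
    ``c`` must be positive (controls are excluded from the fit).
    """
    c = np.asarray(c, dtype=float)
    z = hill_slope * (np.log(c) - math.log(ec50))
    return 100.0 * special.expit(z)


@dataclass
class EffectTable:
    """Per-level percent effects derived from one dataset.

    ``replicate_effects[i]`` are the raw per-vessel effects at ``levels[i]``;
    ``mean_effect`` may exceed 100 or fall below 0 and is reported raw, with
    ``mean_effect_clipped`` restricted to [0, 100] for fitting/mixture use.
    """

    levels: np.ndarray
    replicate_effects: list[np.ndarray]
    mean_effect: np.ndarray
    control_value: float
    endpoint: Endpoint

    @property
    def mean_effect_clipped(self) -> np.ndarray:
        return np.clip(self.mean_effect, 0.0, 100.0)

    def replicates_at(self, level: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.levels - level)))
        if not np.isclose(self.levels[idx], level):
            raise KeyError(f"no exposure level {level}")
        return self.replicate_effects[idx]


@dataclass
class ValidityReport:
    """Outcome of the organism-specific control validity criterion."""

    organism: Organism
    criterion: str
    criterion_value: float
    threshold: float
    passed: bool


@dataclass
class FittedCurve:
    """A fitted two-parameter log-logistic concentration-effect curve."""

    ec50: float
    hill_slope: float
    ec50_ci95: tuple[float, float] | None
    converged: bool
    residual_summary: float
    exposure_unit: str = "percent_v_v"
    extrapolated: bool = False
    n_bootstrap: int = 0
    organism: Organism | None = None
    label: str = ""
    duration_h: int | None = None

    def effect_at(self, c) -> np.ndarray:
        return log_logistic(c, self.ec50, self.hill_slope)


# ---------------------------------------------------------------------------
# percent effects


def percent_effect(
    dataset: DoseResponseDataset, control_reference: float | None = None
) -> EffectTable:
    """Compute per-vessel and level-mean percent effects.

    Growth endpoints: ``100 * (1 - G_treat / G_ctrl)`` with ``G`` the growth
    increment over the test and ``G_ctrl`` the control mean (or the supplied
    ``control_reference``, e.g. a nominal control growth).  Immobilisation:
    ``100 * immobilised / exposed``; the level mean pools vessels.
    """
    levels = dataset.levels
    quantal = dataset.design.endpoint.is_quantal
    if quantal:
        ctrl_counts = dataset.control_responses
        ctrl_n = dataset.control_n_exposed
        control_value = 100.0 * ctrl_counts.sum() / ctrl_n.sum()
        reps, means = [], []
        for lv in levels:
            k = dataset.responses_at(lv)
            n = dataset.n_exposed_at(lv)
            reps.append(100.0 * k / n)
            means.append(100.0 * k.sum() / n.sum())
    else:
        ctrl = (
            float(control_reference)
            if control_reference is not None
            else float(dataset.control_responses.mean())
        )
        if ctrl <= 0:
            raise InvalidControlError(
                f"control mean growth {ctrl!r} is non-positive; cannot normalise"
            )
        control_value = ctrl
        reps, means = [], []
        for lv in levels:
            r = dataset.responses_at(lv)
            eff = 100.0 * (1.0 - r / ctrl)
            reps.append(eff)
            means.append(float(eff.mean()))
    return EffectTable(
        levels=levels,
        replicate_effects=reps,
        mean_effect=np.asarray(means, dtype=float),
        control_value=control_value,
        endpoint=dataset.design.endpoint,
    )


# ---------------------------------------------------------------------------
# validity gates


def check_validity(dataset: DoseResponseDataset) -> ValidityReport:
    """Apply the organism's standard control-validity criterion.

    * microalga: control density must grow >= 16-fold over 72 h;
    * duckweed: mean control frond-area growth >= 10 mm^2;
    * daphnid: control immobilisation <= 10 %.
    """
    organism = dataset.organism
    criterion, threshold = VALIDITY_RULES[organism]
    if organism is Organism.P_subcapitata:
        if dataset.control_t0 is None or dataset.control_t0 <= 0:
            raise CannotEvaluateError(
                "algal fold-growth criterion needs a positive time-0 control "
                "density (dataset.control_t0)"
            )
        growth = float(dataset.control_responses.mean())
        value = (dataset.control_t0 + growth) / dataset.control_t0
        passed = value >= threshold
    elif organism is Organism.S_polyrhiza:
        value = float(dataset.control_responses.mean())
        passed = value >= threshold
    else:  # D. magna
        counts = dataset.control_responses
        n = dataset.control_n_exposed
        value = 100.0 * counts.sum() / n.sum()
        passed = value <= threshold
    return ValidityReport(organism, criterion, float(value), threshold, bool(passed))


# ---------------------------------------------------------------------------
# fitting


def _init_params(levels: np.ndarray, mean_effect: np.ndarray) -> tuple[float, float]:
    """Scale-covariant starting values from a logit-log regression."""
    eff = np.clip(mean_effect, 0.5, 99.5)
    y = np.log(eff / (100.0 - eff))
    x = np.log(levels)
    slope, intercept = np.polyfit(x, y, 1)
    if not np.isfinite(slope) or slope <= 0.05:
        slope = 1.0
    log_ec50 = -intercept / slope
    lo, hi = math.log(levels.min()) - 25.0, math.log(levels.max()) + 25.0
    return float(np.clip(log_ec50, lo, hi)), float(np.clip(slope, 0.05, 50.0))


def _fit_continuous(
    levels: np.ndarray,
    mean_effect: np.ndarray,
    weights: np.ndarray,
    x0: tuple[float, float] | None = None,
    tol: float = 1e-14,
) -> tuple[float, float, bool, float]:
    eff = np.clip(mean_effect, 0.0, 100.0)
    log_c = np.log(levels)
    sw = np.sqrt(weights)
    if x0 is None:
        x0 = _init_params(levels, eff)

    def resid(p):
        z = p[1] * (log_c - p[0])
        return sw * (100.0 * special.expit(z) - eff)

    def jac(p):
        z = p[1] * (log_c - p[0])
        s = special.expit(z)
        d = 100.0 * s * (1.0 - s)
        return np.column_stack((-sw * d * p[1], sw * d * (log_c - p[0])))

    sol = optimize.least_squares(
        resid,
        x0=list(x0),
        jac=jac,
        bounds=([log_c.min() - 30.0, 1e-3], [log_c.max() + 30.0, 100.0]),
        xtol=tol,
        ftol=tol,
        gtol=tol,
    )
    ec50 = math.exp(sol.x[0])
    rmse = float(np.sqrt(np.mean((log_logistic(levels, ec50, sol.x[1]) - eff) ** 2)))
    return ec50, float(sol.x[1]), bool(sol.success), rmse


def _fit_quantal(
    levels: np.ndarray,
    counts: list[np.ndarray],
    n_exposed: list[np.ndarray],
    x0: tuple[float, float] | None = None,
    tol: float = 1e-10,
) -> tuple[float, float, bool, float]:
    k = np.concatenate([np.asarray(c, float) for c in counts])
    n = np.concatenate([np.asarray(m, float) for m in n_exposed])
    log_c = np.concatenate(
        [np.full(len(c), math.log(lv)) for lv, c in zip(levels, counts)]
    )
    pooled = np.array([c.sum() / m.sum() for c, m in zip(counts, n_exposed)]) * 100.0
    if x0 is None:
        x0 = _init_params(levels, pooled)

    def nll(p):
        z = p[1] * (log_c - p[0])
        # log(p) and log(1-p) via softplus for stability
        log_p = -np.logaddexp(0.0, -z)
        log_q = -np.logaddexp(0.0, z)
        return -np.sum(k * log_p + (n - k) * log_q)

    sol = optimize.minimize(
        nll,
        x0=list(x0),
        method="Nelder-Mead",
        options={"xatol": tol, "fatol": tol, "maxiter": 2000},
    )
    ec50 = math.exp(sol.x[0])
    rmse = float(
        np.sqrt(np.mean((log_logistic(levels, ec50, sol.x[1]) - pooled) ** 2))
    )
    return ec50, float(abs(sol.x[1])), bool(sol.success), rmse


def fit_log_logistic(
    dataset: DoseResponseDataset,
    n_bootstrap: int = 1000,
    seed: int | None = None,
    control_reference: float | None = None,
) -> FittedCurve:
    """Fit the two-parameter log-logistic curve and bootstrap the EC50 CI.

    Parameters
    ----------
    dataset
        Replicate responses with controls; needs >= 3 exposure levels.
    n_bootstrap
        Resamples for the percentile CI; 0 skips the CI.
    seed
        Seed for the bootstrap resampler (required for reproducibility
        whenever ``n_bootstrap > 0``).
    control_reference
        Optional fixed control growth used for normalisation instead of the
        control mean estimated from the data.

    Raises
    ------
    MonotonicityError
        If mean effect correlates negatively with concentration
        (Spearman rho < 0): the monotone model is not applicable.
    """
    effects = percent_effect(dataset, control_reference=control_reference)
    levels = effects.levels
    finite = np.isfinite(effects.mean_effect)
    if finite.sum() < 3:
        raise ValueError("need >=3 exposure levels with finite effects")
    rho = stats.spearmanr(levels[finite], effects.mean_effect[finite]).statistic
    if np.isfinite(rho) and rho < 0:
        raise MonotonicityError(
            f"mean effect decreases with concentration (Spearman rho={rho:.2f})"
        )
    clipped = effects.mean_effect_clipped
    extrapolated = not (np.any(clipped < 50.0) and np.any(clipped >= 50.0))

    quantal = dataset.design.endpoint.is_quantal
    if quantal:
        counts = [dataset.responses_at(lv) for lv in levels]
        ns = [dataset.n_exposed_at(lv) for lv in levels]
        ec50, h, ok, rmse = _fit_quantal(levels, counts, ns)
    else:
        weights = np.array([len(r) for r in effects.replicate_effects], dtype=float)
        ec50, h, ok, rmse = _fit_continuous(levels, effects.mean_effect, weights)

    ci: tuple[float, float] | None = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boot = _bootstrap_ec50(
            dataset,
            effects,
            n_bootstrap,
            rng,
            control_reference=control_reference,
            x0=(math.log(ec50), h),
        )
        if len(boot) >= max(20, n_bootstrap // 2):
            n_rep = np.array([len(r) for r in effects.replicate_effects])
            ci = _expanded_percentile_ci(boot, n_rep)
        else:
            ok = False
    return FittedCurve(
        ec50=ec50,
        hill_slope=h,
        ec50_ci95=ci,
        converged=ok,
        residual_summary=rmse,
        exposure_unit=dataset.design.exposure_unit,
        extrapolated=extrapolated,
        n_bootstrap=n_bootstrap,
        organism=dataset.organism,
        label=dataset.label,
        duration_h=dataset.design.duration_h,
    )


def _expanded_percentile_ci(
    boot_ec50: np.ndarray, n_replicates: np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """Small-sample expanded percentile interval on the log-EC50 scale.

    Plain percentile intervals are systematically narrow when each level
    carries only a few vessels: resampling n values underestimates the
    sampling variance by a factor (n-1)/n, and the normal-range quantiles
    ignore the t-ness of the variance estimate.  Following Hesterberg's
    expanded-percentile correction, the percentile distances from the
    bootstrap median are inflated by sqrt(n/(n-1)) * t_{nu,a/2} / z_{a/2},
    with n the mean vessels per level and nu the residual degrees of
    freedom of the level-mean fit (levels minus two parameters), the
    standard small-sample convention for regression intervals.
    """
    alpha = 1.0 - level
    logs = np.log(boot_ec50)
    n_bar = float(n_replicates.mean())
    nu = max(len(n_replicates) - 2, 1)
    factor = (
        math.sqrt(n_bar / max(n_bar - 1.0, 1e-9))
        * stats.t.ppf(1 - alpha / 2, nu)
        / stats.norm.ppf(1 - alpha / 2)
    )
    med = float(np.median(logs))
    lo = med + factor * (float(np.percentile(logs, 100 * alpha / 2)) - med)
    hi = med + factor * (float(np.percentile(logs, 100 * (1 - alpha / 2))) - med)
    return math.exp(lo), math.exp(hi)


def _bootstrap_ec50(
    dataset: DoseResponseDataset,
    effects: EffectTable,
    n_bootstrap: int,
    rng: np.random.Generator,
    control_reference: float | None = None,
    x0: tuple[float, float] | None = None,
) -> np.ndarray:
    """Percentile-bootstrap EC50 replicates by resampling vessels per level.

    Resamples are refitted warm-started from the point estimate with a
    looser tolerance than the primary fit (1e-8; the CI is quoted to far
    fewer digits than that).
    """
    levels = effects.levels
    quantal = dataset.design.endpoint.is_quantal
    out = []
    if quantal:
        counts = [dataset.responses_at(lv) for lv in levels]
        ns = [dataset.n_exposed_at(lv) for lv in levels]
        for _ in range(n_bootstrap):
            bc, bn = [], []
            for c, n in zip(counts, ns):
                idx = rng.integers(0, len(c), len(c))
                bc.append(c[idx])
                bn.append(n[idx])
            try:
                ec50, _, ok, _ = _fit_quantal(levels, bc, bn, x0=x0, tol=1e-6)
            except Exception:
                continue
            if ok and np.isfinite(ec50):
                out.append(ec50)
    else:
        raw = [dataset.responses_at(lv) for lv in levels]
        ctrl = dataset.control_responses
        weights = np.array([len(r) for r in raw], dtype=float)
        for _ in range(n_bootstrap):
            if control_reference is not None:
                g_ctrl = float(control_reference)
            else:
                g_ctrl = float(ctrl[rng.integers(0, len(ctrl), len(ctrl))].mean())
            if g_ctrl <= 0:
                continue
            means = np.array(
                [
                    100.0 * (1.0 - r[rng.integers(0, len(r), len(r))].mean() / g_ctrl)
                    for r in raw
                ]
            )
            try:
                ec50, _, ok, _ = _fit_continuous(
                    levels, means, weights, x0=x0, tol=1e-8
                )
            except Exception:
                continue
            if ok and np.isfinite(ec50):
                out.append(ec50)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# unit conversion of % v/v EC50s


def ec50_to_analyte_concentration(
    ec50_pct: float, stock: AnalyteConcentration
) -> tuple[float, str]:
    """Convert a % v/v EC50 of a dilution series to an analyte mass EC50.

    The leachate stock carries ``stock.value`` of the target analyte per
    litre, so a dilution of ``ec50_pct`` % v/v contains
    ``ec50_pct/100 * stock.value`` in the stock's unit.
    """
    if not (0.0 < ec50_pct <= 100.0):
        raise ValueError("percent v/v EC50 must lie in (0, 100]")
    if not isinstance(stock, AnalyteConcentration):
        raise UnitError("stock concentration must be an AnalyteConcentration")
    return ec50_pct / 100.0 * stock.value, stock.unit


# ---------------------------------------------------------------------------
# JSON I/O of fitted curves


def write_curves_json(curves: Sequence[FittedCurve], path: str | Path) -> None:
    records = []
    for cv in curves:
        records.append(
            {
                "label": cv.label,
                "organism": cv.organism.value if cv.organism else None,
                "duration_h": cv.duration_h,
                "ec50": cv.ec50,
                "unit": cv.exposure_unit,
                "ci_low": cv.ec50_ci95[0] if cv.ec50_ci95 else None,
                "ci_high": cv.ec50_ci95[1] if cv.ec50_ci95 else None,
                "hill": cv.hill_slope,
                "converged": cv.converged,
                "extrapolated": cv.extrapolated,
                "n_bootstrap": cv.n_bootstrap,
            }
        )
    Path(path).write_text(json.dumps(records, indent=2))


def read_curves_json(path: str | Path) -> list[FittedCurve]:
    records = json.loads(Path(path).read_text())
    out = []
    for r in records:
        ci = None
        if r.get("ci_low") is not None and r.get("ci_high") is not None:
            ci = (r["ci_low"], r["ci_high"])
        out.append(
            FittedCurve(
                ec50=r["ec50"],
                hill_slope=r["hill"],
                ec50_ci95=ci,
                converged=r["converged"],
                residual_summary=float("nan"),
                exposure_unit=r.get("unit", "percent_v_v"),
                extrapolated=r.get("extrapolated", False),
                n_bootstrap=r.get("n_bootstrap", 0),
                organism=Organism(r["organism"]) if r.get("organism") else None,
                label=r.get("label", ""),
                duration_h=r.get("duration_h"),
            )
        )
    return out
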