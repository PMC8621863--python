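"""Ion/particulate toxicity partitioning and mixture-interaction tests.

Two algebraically equivalent models are used on complementary tasks:

* response addition, ``E_total = 1 - (1 - E_ion)(1 - E_particle)`` on the
  0-1 effect scale, inverted to recover the particulate contribution from
  the measured total and ion-only effects;
* the independent-action predictive formula on the percent scale,
  ``P(E) = P_x + P_y - P_x P_y / 100``, giving the expected effect of a
  binary mixture from its constituents' individual effects.

An observed mixture effect is classified against the prediction with a
one-sample two-sided t-test of replicate observed effects at per-comparison
alpha (default 0.05): significant differences are synergistic or
antagonistic (signed by the mean deviation), insignificant ones additive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import DoseResponseDataset
from .dose_response import FittedCurve, percent_effect

__all__ = [
    "DecompositionFlag",
    "MixtureDecomposition",
    "Verdict",
    "Direction",
    "BinaryPrediction",
    "decompose_particle_effect",
    "compose_effects",
    "predict_independent_action",
    "classify_interaction",
    "mixture_report",
    "AlignmentError",
]

#: Effects entering response-addition denominators are capped here to avoid
#: division blow-up at complete kill.
EFFECT_CAP = 0.999


class AlignmentError(ValueError):
    """Paired datasets do not share a common exposure series."""


class DecompositionFlag(str, Enum):
    ok = "ok"
    clipped_negative = "clipped_negative"
    ion_exceeds_total = "ion_exceeds_total"
    ion_saturated = "ion_saturated"  # e_ion = 1: particle effect undefined


class Verdict(str, Enum):
    additive = "additive"
    synergistic_or_antagonistic = "synergistic_or_antagonistic"
    not_evaluated = "not_evaluated"


class Direction(str, Enum):
    synergistic = "synergistic"
    antagonistic = "antagonistic"
    none = "none"


@dataclass(frozen=True)
class MixtureDecomposition:
    """Per-level partition of total effect into ion and particulate parts."""

    level: float
    e_total: float
    e_ion: float
    e_particle: float
    flag: DecompositionFlag


@dataclass(frozen=True)
class BinaryPrediction:
    """Observed-vs-predicted comparison for one binary mixture."""

    p_x: float
    p_y: float
    p_expected: float
    p_observed_mean: float
    p_observed_sd: float
    n_observed: int
    verdict: Verdict
    direction: Direction
    p_value: float
    alpha: float
    degenerate_variance: bool = False


def _check_fraction(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


def compose_effects(e_ion: float, e_particle: float) -> float:
    """Response-addition composition ``1 - (1 - e_ion)(1 - e_particle)``."""
    e_ion = _check_fraction("e_ion", e_ion)
    e_particle = _check_fraction("e_particle", e_particle)
    return 1.0 - (1.0 - e_ion) * (1.0 - e_particle)


def decompose_particle_effect(e_total: float, e_ion: float) -> MixtureDecomposition:
    """Invert response addition for the particulate effect.

    ``e_particle = 1 - (1 - e_total)/(1 - e_ion)``.  A negative result means
    the ion effect already exceeds the total; it is reported as 0 with flag
    ``ion_exceeds_total``.  ``e_ion = 1`` leaves the particle effect
    undefined (flag ``ion_saturated``).
    """
    e_total = _check_fraction("e_total", e_total)
    e_ion = _check_fraction("e_ion", e_ion)
    if e_ion == 1.0:
        return MixtureDecomposition(
            np.nan, e_total, e_ion, np.nan, DecompositionFlag.ion_saturated
        )
    e_particle = 1.0 - (1.0 - e_total) / (1.0 - e_ion)
    flag = DecompositionFlag.ok
    if e_particle < 0.0:
        # float rounding can push an exactly-accounted effect a few ulp
        # below zero; only substantive deficits get the clipping flag
        if e_particle < -1e-9:
            flag = DecompositionFlag.ion_exceeds_total
        e_particle = 0.0
    return MixtureDecomposition(np.nan, e_total, e_ion, float(e_particle), flag)


def predict_independent_action(p_x: float, p_y: float) -> float:
    """Expected percent effect of a binary mixture under independent action."""
    p_x, p_y = float(p_x), float(p_y)
    for name, p in (("p_x", p_x), ("p_y", p_y)):
        if not 0.0 <= p <= 100.0:
            raise ValueError(f"{name} must lie in [0, 100], got {p!r}")
    return p_x + p_y - p_x * p_y / 100.0


def classify_interaction(
    observed,
    expected: float,
    alpha: float = 0.05,
    p_x: float = np.nan,
    p_y: float = np.nan,
) -> BinaryPrediction:
    """Classify replicate observed effects against the predicted effect.

    One-sample two-sided t-test of the observed percent effects against the
    scalar expectation.  ``p < alpha`` gives a synergistic-or-antagonistic
    verdict, signed by ``mean(observed) - expected``; otherwise additive.
    Zero observed variance with a mean different from the expectation is an
    exact difference and is reported with the degenerate-variance flag.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.size < 2:
        raise ValueError("need >=2 observed replicates")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    mean = float(observed.mean())
    sd = float(observed.std(ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        # replicates are numerically identical (e.g. noiseless data or a
        # saturated endpoint): the comparison is exact, up to float rounding
        agree = math.isclose(mean, expected, rel_tol=1e-9, abs_tol=1e-9)
        p_value = 1.0 if agree else 0.0
    else:
        p_value = float(stats.ttest_1samp(observed, expected).pvalue)
    if p_value < alpha:
        verdict = Verdict.synergistic_or_antagonistic
        direction = (
            Direction.synergistic if mean > expected else Direction.antagonistic
        )
    else:
        verdict = Verdict.additive
        direction = Direction.none
    return BinaryPrediction(
        p_x=float(p_x),
        p_y=float(p_y),
        p_expected=float(expected),
        p_observed_mean=mean,
        p_observed_sd=sd,
        n_observed=int(observed.size),
        verdict=verdict,
        direction=direction,
        p_value=p_value,
        alpha=alpha,
        degenerate_variance=degenerate,
    )


ParticleEffect = Callable[[float], float] | Mapping[float, float] | FittedCurve


def _particle_fraction(particle_effect: ParticleEffect, level: float) -> float:
    if isinstance(particle_effect, FittedCurve):
        return float(particle_effect.effect_at(level)) / 100.0
    if isinstance(particle_effect, Mapping):
        return float(particle_effect[level])
    return float(particle_effect(level))


def mixture_report(
    total: DoseResponseDataset,
    ion: DoseResponseDataset,
    alpha: float = 0.05,
    particle_effect: ParticleEffect | None = None,
    control_reference: float | None = None,
) -> pd.DataFrame:
    """Per-level decomposition and interaction classification for a pair.

    ``total`` and ``ion`` must share the same exposure series.  Level-mean
    effects (clipped to [0, 0.999]) feed the response-addition
    decomposition.  Classification of observed total effects against the
    independent-action prediction needs an external particulate reference
    curve (``particle_effect``: a FittedCurve, a mapping level->fraction, or
    a callable) — without one the prediction would be algebraically
    identical to the observed mean and the comparison empty; rows are then
    marked ``not_evaluated``.

    Returns a tidy frame: level, e_total, e_ion, e_particle, flag,
    p_expected, p_observed_mean, p_value, verdict, direction.
    """
    lv_total, lv_ion = total.levels, ion.levels
    if len(lv_total) != len(lv_ion) or not np.allclose(lv_total, lv_ion):
        unmatched = sorted(
            set(np.round(lv_total, 12)).symmetric_difference(np.round(lv_ion, 12))
        )
        raise AlignmentError(f"exposure series differ; unmatched levels: {unmatched}")
    eff_total = percent_effect(total, control_reference=control_reference)
    eff_ion = percent_effect(ion, control_reference=control_reference)
    rows = []
    for i, lv in enumerate(lv_total):
        e_tot = float(np.clip(eff_total.mean_effect[i] / 100.0, 0.0, EFFECT_CAP))
        e_ion_ = float(np.clip(eff_ion.mean_effect[i] / 100.0, 0.0, EFFECT_CAP))
        dec = decompose_particle_effect(e_tot, e_ion_)
        row = {
            "level": lv,
            "e_total": e_tot,
            "e_ion": e_ion_,
            "e_particle": dec.e_particle,
            "flag": dec.flag.value,
        }
        if particle_effect is not None:
            # the 0.999 cap protects only the RA denominator; the IA
            # prediction takes the plain clipped percent effect
            p_ion = float(np.clip(eff_ion.mean_effect[i], 0.0, 100.0))
            p_part = 100.0 * float(
                np.clip(_particle_fraction(particle_effect, lv), 0.0, 1.0)
            )
            expected = predict_independent_action(p_ion, p_part)
            pred = classify_interaction(
                eff_total.replicate_effects[i], expected, alpha,
                p_x=p_ion, p_y=p_part,
            )
            row.update(
                p_expected=expected,
                p_observed_mean=pred.p_observed_mean,
                p_value=pred.p_value,
                verdict=pred.verdict.value,
                direction=pred.direction.value,
            )
        else:
            row.update(
                p_expected=np.nan,
                p_observed_mean=float(eff_total.mean_effect[i]),
                p_value=np.nan,
                verdict=Verdict.not_evaluated.value,
                direction=Direction.none.value,
            )
        rows.append(row)
    return pd.DataFrame(rows)
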