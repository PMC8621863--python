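"""Synthetic acute-toxicity experiments with known ground truth.

Emulates the standard three-species acute battery: five exposure levels in
a 10-fold dilution series (0.01-100 % v/v) plus controls, triplicate
vessels (octuplicate for duckweed; five neonates per vessel for daphnids),
a monotone log-logistic concentration-effect relation, multiplicative
lognormal noise on continuous responses and binomial sampling for
immobilisation.  A paired total/ion-only experiment realises the
response-addition composition with a configurable interaction
(additive, synergistic or antagonistic), so every downstream estimator can
be checked against generative truth.

All randomness flows through explicit seeds; no global state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .datasets import (
    ENDPOINT_ORGANISM,
    VALID_ENDPOINT_DURATIONS,
    DesignError,
    DoseResponseDataset,
    Endpoint,
    ExposureDesign,
    tidy_frame,
)
from .dose_response import log_logistic

__all__ = [
    "Interaction",
    "GroundTruth",
    "make_default_design",
    "simulate_dose_response",
    "simulate_mixture_experiment",
    "generative_effects",
]

#: The standard dilution series: 10-fold steps from 0.01 to 100 % v/v.
DEFAULT_LEVELS = (0.01, 0.1, 1.0, 10.0, 100.0)


class Interaction(str, Enum):
    additive = "additive"
    synergistic = "synergistic"
    antagonistic = "antagonistic"


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters for one (possibly paired) experiment.

    ``ec50_true``/``hill_slope`` parameterise the particle-only effect curve
    (or the single curve for a plain experiment); ``ion_fraction_curve`` is
    the (ec50, slope) of the ion-only curve for paired mixture experiments.
    ``interaction_strength`` is an effect-scale perturbation (fraction, >=0)
    added to (synergistic) or subtracted from (antagonistic) the
    response-addition composition, clipped to [0, 1].
    ``control_fold_growth`` fixes the simulated algal control 72 h/0 h
    density ratio so the fold-growth validity gate can be exercised.
    """

    ec50_true: float
    hill_slope: float
    control_mean: float = 1.0
    noise_cv: float = 0.10
    ion_fraction_curve: tuple[float, float] | None = None
    interaction: Interaction = Interaction.additive
    interaction_strength: float = 0.0
    background_immobilisation: float = 0.0
    control_fold_growth: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "interaction", Interaction(self.interaction))
        if not self.ec50_true > 0:
            raise ValueError("ec50_true must be positive")
        if not self.hill_slope > 0:
            raise ValueError("hill_slope must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.interaction_strength < 0:
            raise ValueError("interaction_strength must be >= 0")
        if (self.interaction is Interaction.additive) != (
            self.interaction_strength == 0
        ):
            raise ValueError(
                "interaction_strength must be 0 exactly when interaction is additive"
            )
        if not 0 <= self.background_immobilisation <= 1:
            raise ValueError("background_immobilisation must lie in [0, 1]")
        if self.ion_fraction_curve is not None:
            ec50_ion, slope_ion = self.ion_fraction_curve
            if ec50_ion <= 0 or slope_ion <= 0:
                raise ValueError("ion_fraction_curve parameters must be positive")


def make_default_design(endpoint: Endpoint | str, duration_h: int) -> ExposureDesign:
    """The standard design for an endpoint: 10-fold series, battery replication.

    Triplicate for algal growth and daphnid immobilisation (five neonates
    per beaker), octuplicate for duckweed frond growth.
    """
    endpoint = Endpoint(endpoint)
    if duration_h not in VALID_ENDPOINT_DURATIONS[endpoint]:
        raise DesignError(
            f"{endpoint.value} at {duration_h} h is not a supported pair"
        )
    n_replicates = 8 if endpoint is Endpoint.frond_area_growth else 3
    organisms = 5 if endpoint.is_quantal else 1
    return ExposureDesign(
        levels=DEFAULT_LEVELS,
        n_replicates=n_replicates,
        organisms_per_replicate=organisms,
        endpoint=endpoint,
        duration_h=duration_h,
    )


# ---------------------------------------------------------------------------
# generative curves


def generative_effects(
    truth: GroundTruth, levels
) -> dict[str, np.ndarray]:
    """Ground-truth effect fractions at ``levels``.

    Returns ``particle``, and when an ion curve is present also ``ion`` and
    ``total`` (the response-addition composition perturbed by the configured
    interaction, clipped to [0, 1]).
    """
    levels = np.asarray(levels, dtype=float)
    e_particle = log_logistic(levels, truth.ec50_true, truth.hill_slope) / 100.0
    out = {"particle": e_particle}
    if truth.ion_fraction_curve is not None:
        ec50_ion, slope_ion = truth.ion_fraction_curve
        e_ion = log_logistic(levels, ec50_ion, slope_ion) / 100.0
        e_total = 1.0 - (1.0 - e_ion) * (1.0 - e_particle)
        if truth.interaction is Interaction.synergistic:
            e_total = e_total + truth.interaction_strength
        elif truth.interaction is Interaction.antagonistic:
            e_total = e_total - truth.interaction_strength
        out["ion"] = e_ion
        out["total"] = np.clip(e_total, 0.0, 1.0)
    return out


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def _simulate_from_fractions(
    design: ExposureDesign,
    truth: GroundTruth,
    effect_fraction: np.ndarray,
    rng: np.random.Generator,
    label: str,
) -> DoseResponseDataset:
    records = []
    quantal = design.endpoint.is_quantal
    unit = design.response_unit
    n = design.n_replicates
    # controls
    if quantal:
        k = rng.binomial(design.organisms_per_replicate,
                         truth.background_immobilisation, size=n)
        for i in range(n):
            records.append(
                dict(exposure_value=0.0, exposure_unit=design.exposure_unit,
                     replicate_id=f"c{i + 1}", response_value=int(k[i]),
                     response_unit=unit, n_exposed=design.organisms_per_replicate,
                     is_control=True)
            )
    else:
        resp = truth.control_mean * _lognormal_noise(rng, truth.noise_cv, n)
        for i in range(n):
            records.append(
                dict(exposure_value=0.0, exposure_unit=design.exposure_unit,
                     replicate_id=f"c{i + 1}", response_value=float(resp[i]),
                     response_unit=unit, n_exposed=np.nan, is_control=True)
            )
    # treated levels
    for lv, frac in zip(design.levels, effect_fraction):
        if quantal:
            k = rng.binomial(design.organisms_per_replicate, frac, size=n)
            for i in range(n):
                records.append(
                    dict(exposure_value=lv, exposure_unit=design.exposure_unit,
                         replicate_id=f"r{i + 1}", response_value=int(k[i]),
                         response_unit=unit, n_exposed=design.organisms_per_replicate,
                         is_control=False)
                )
        else:
            resp = (
                truth.control_mean
                * (1.0 - frac)
                * _lognormal_noise(rng, truth.noise_cv, n)
            )
            for i in range(n):
                records.append(
                    dict(exposure_value=lv, exposure_unit=design.exposure_unit,
                         replicate_id=f"r{i + 1}", response_value=float(resp[i]),
                         response_unit=unit, n_exposed=np.nan, is_control=False)
                )
    control_t0 = None
    if design.endpoint is Endpoint.algal_growth:
        # growth increment g over t0 gives fold = 1 + g/t0
        control_t0 = truth.control_mean / (truth.control_fold_growth - 1.0)
    return DoseResponseDataset(
        design=design,
        data=tidy_frame(records),
        organism=ENDPOINT_ORGANISM[design.endpoint],
        label=label,
        control_t0=control_t0,
    )


def simulate_dose_response(
    design: ExposureDesign,
    truth: GroundTruth,
    seed: int | None = None,
    label: str = "synthetic",
) -> DoseResponseDataset:
    """Simulate one experiment from the single (particle) effect curve.

    Continuous endpoints draw replicate responses
    ``control_mean * (1 - inhibition(c)/100) * lognormal(cv)``;
    immobilisation draws per-vessel counts
    ``Binomial(organisms_per_replicate, inhibition(c)/100)``.  Controls sit
    at zero inhibition plus the configured background immobilisation.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    frac = generative_effects(truth, design.levels)["particle"]
    return _simulate_from_fractions(design, truth, frac, rng, label)


def simulate_mixture_experiment(
    design: ExposureDesign,
    truth: GroundTruth,
    seed: int | None = None,
    label: str = "synthetic",
) -> tuple[DoseResponseDataset, DoseResponseDataset]:
    """Simulate a paired (total, ion-only) experiment.

    The ion-only dataset follows ``truth.ion_fraction_curve``; the total
    dataset follows the response-addition composition of ion and particle
    curves, perturbed by the configured interaction.
    """
    if truth.ion_fraction_curve is None:
        raise ValueError("mixture simulation requires truth.ion_fraction_curve")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    eff = generative_effects(truth, design.levels)
    total = _simulate_from_fractions(design, truth, eff["total"], rng,
                                     f"{label}:total")
    ion = _simulate_from_fractions(design, truth, eff["ion"], rng, f"{label}:ion")
    return total, ion
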