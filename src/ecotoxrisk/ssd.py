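"""Species sensitivity distributions from per-species EC/LC50s.

Species are ranked by ascending EC/LC50 and assigned empirical cumulative
probabilities by a plotting position — Hazen ``(i - 0.5)/n`` by default,
Weibull ``i/(n + 1)`` optionally.  A log-normal distribution can be fitted
to log10 EC50 by maximum likelihood, from which the HC5 (concentration
hazardous to 5 % of species) is derived; with the typical three-species
acute battery this parametric step is fragile and is flagged as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .units import UnitError

__all__ = ["SSDCurve", "build_ssd", "sensitivity_order", "plot_ssd"]

_POSITIONS = ("hazen", "weibull")


@dataclass
class SSDCurve:
    """Ranked species sensitivities with plotting positions.

    ``entries`` columns: species, ec50, unit, rank, cumulative_probability,
    tied.  ``fit`` holds (mean, sd) of log10 EC50 when requested; ``hc5``
    the fitted 5th percentile concentration.
    """

    entries: pd.DataFrame
    unit: str
    plotting_position: str
    fit: tuple[float, float] | None = None
    hc5: float | None = None

    @property
    def species(self) -> list[str]:
        return self.entries["species"].tolist()


def _normalise_input(
    ec50s: Mapping[str, float | tuple[float, str]], unit: str | None
) -> tuple[pd.DataFrame, str]:
    rows = []
    units = set()
    for species, value in ec50s.items():
        if isinstance(value, (tuple, list)):
            val, u = value
        else:
            val, u = value, unit
        if u is None:
            raise UnitError(f"EC50 for {species!r} has no unit")
        units.add(u)
        rows.append({"species": str(species), "ec50": float(val), "unit": u})
    if len(units) > 1:
        raise UnitError(f"mixed EC50 units {sorted(units)}; convert first")
    df = pd.DataFrame(rows)
    if (df["ec50"] <= 0).any():
        raise ValueError("EC50s must be positive")
    return df, units.pop()


def build_ssd(
    ec50s: Mapping[str, float | tuple[float, str]],
    unit: str | None = "ug_per_L",
    fit_lognormal: bool = False,
    plotting_position: str = "hazen",
) -> SSDCurve:
    """Build an SSD from a species -> EC50 map.

    ``ec50s`` values are plain numbers (with the shared ``unit``) or
    ``(value, unit)`` pairs, which must all agree.  Ties share the midpoint
    of their plotting positions, ordered stably by species name.
    """
    if plotting_position not in _POSITIONS:
        raise ValueError(f"plotting_position must be one of {_POSITIONS}")
    if len(ec50s) < 2:
        raise ValueError("an SSD needs >=2 species")
    df, resolved_unit = _normalise_input(ec50s, unit)
    df = df.sort_values(["ec50", "species"], kind="stable").reset_index(drop=True)
    n = len(df)
    ranks = np.arange(1, n + 1, dtype=float)
    if plotting_position == "hazen":
        pos = (ranks - 0.5) / n
    else:
        pos = ranks / (n + 1.0)
    # tie groups share the midpoint position
    df["rank"] = ranks
    df["cumulative_probability"] = pos
    df["tied"] = df.duplicated("ec50", keep=False)
    if df["tied"].any():
        df["cumulative_probability"] = df.groupby("ec50")[
            "cumulative_probability"
        ].transform("mean")
    fit = None
    hc5 = None
    if fit_lognormal:
        logs = np.log10(df["ec50"].to_numpy())
        mean = float(logs.mean())
        sd = float(logs.std(ddof=0))  # maximum-likelihood scale
        fit = (mean, sd)
        hc5 = float(10.0 ** (mean + stats.norm.ppf(0.05) * sd))
        if n < 5:
            warnings.warn(
                f"log-normal SSD fitted to only {n} species; the HC5 is "
                "fragile at this sample size",
                stacklevel=2,
            )
    return SSDCurve(
        entries=df,
        unit=resolved_unit,
        plotting_position=plotting_position,
        fit=fit,
        hc5=hc5,
    )


def sensitivity_order(ssd: SSDCurve) -> list[str]:
    """Species from most to least sensitive (ascending EC/LC50)."""
    return ssd.species


def plot_ssd(ssd: SSDCurve, path: str | Path, title: str = "") -> None:
    """Write a static SSD figure (empirical points, optional fitted CDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    x = ssd.entries["ec50"]
    y = ssd.entries["cumulative_probability"]
    ax.semilogx(x, y, "o", color="tab:blue")
    for _, row in ssd.entries.iterrows():
        ax.annotate(
            row["species"],
            (row["ec50"], row["cumulative_probability"]),
            textcoords="offset points",
            xytext=(6, -4),
            fontsize=8,
        )
    if ssd.fit is not None:
        mean, sd = ssd.fit
        grid = np.logspace(
            np.log10(x.min()) - 1.0, np.log10(x.max()) + 1.0, 200
        )
        ax.semilogx(
            grid,
            stats.norm.cdf((np.log10(grid) - mean) / max(sd, 1e-12)),
            "-",
            color="tab:grey",
            label="log-normal fit",
        )
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel(f"EC/LC50 ({ssd.unit})")
    ax.set_ylabel("fraction of species affected")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
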