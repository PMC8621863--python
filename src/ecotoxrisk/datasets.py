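"""Core containers for acute aquatic toxicity experiments.

A :class:`DoseResponseDataset` holds one organism-endpoint experiment:
replicate responses along a dilution (or mass-concentration) series plus
unexposed controls, in tidy long format.  Continuous endpoints (algal
optical-density growth, duckweed frond-area growth) store the growth
increment over the test; the quantal endpoint (daphnid immobilisation)
stores immobilised counts out of ``n_exposed``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Endpoint",
    "Organism",
    "ExposureDesign",
    "DoseResponseDataset",
    "DesignError",
    "VALID_ENDPOINT_DURATIONS",
    "ENDPOINT_ORGANISM",
]


class DesignError(ValueError):
    """Raised for an exposure design the supported test batteries do not allow."""


class Endpoint(str, Enum):
    """Acute endpoint measured in a test."""

    algal_growth = "algal_growth"          # 72 h optical-density growth
    frond_area_growth = "frond_area_growth"  # 72 h duckweed frond area (mm^2)
    immobilisation = "immobilisation"      # 24/48 h daphnid immobilisation

    @property
    def is_quantal(self) -> bool:
        return self is Endpoint.immobilisation


class Organism(str, Enum):
    P_subcapitata = "P_subcapitata"  # green microalga (primary producer)
    S_polyrhiza = "S_polyrhiza"      # giant duckweed (macrophyte)
    D_magna = "D_magna"              # water flea (primary consumer)


#: Endpoint/duration pairs the supported acute test battery defines.
VALID_ENDPOINT_DURATIONS: Mapping[Endpoint, frozenset[int]] = {
    Endpoint.algal_growth: frozenset({72}),
    Endpoint.frond_area_growth: frozenset({72}),
    Endpoint.immobilisation: frozenset({24, 48}),
}

#: Default test organism for each endpoint.
ENDPOINT_ORGANISM: Mapping[Endpoint, Organism] = {
    Endpoint.algal_growth: Organism.P_subcapitata,
    Endpoint.frond_area_growth: Organism.S_polyrhiza,
    Endpoint.immobilisation: Organism.D_magna,
}

#: Response unit recorded per endpoint.
ENDPOINT_RESPONSE_UNIT: Mapping[Endpoint, str] = {
    Endpoint.algal_growth: "od684_growth",
    Endpoint.frond_area_growth: "mm2",
    Endpoint.immobilisation: "count",
}


@dataclass(frozen=True)
class ExposureDesign:
    """Layout of one acute exposure experiment.

    Parameters
    ----------
    levels
        Strictly increasing positive exposure values (excluding the control,
        which is always present in generated data).
    n_replicates
        Vessels per exposure level.
    organisms_per_replicate
        Individuals per vessel; 1 for continuous endpoints, conventionally 5
        neonates per beaker for daphnid immobilisation.
    endpoint, duration_h
        Endpoint and exposure duration; only the standard pairings
        (growth endpoints at 72 h, immobilisation at 24 or 48 h) are valid.
    exposure_unit
        ``"percent_v_v"`` for leachate dilution series or a mass unit such
        as ``"ug_per_L"``.
    """

    levels: tuple[float, ...]
    n_replicates: int
    organisms_per_replicate: int
    endpoint: Endpoint
    duration_h: int
    exposure_unit: str = "percent_v_v"

    def __post_init__(self) -> None:
        levels = tuple(float(x) for x in self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) < 2:
            raise DesignError("need at least two exposure levels")
        arr = np.asarray(levels)
        if not np.all(arr > 0):
            raise DesignError("exposure levels must be positive (control is implicit)")
        if not np.all(np.diff(arr) > 0):
            raise DesignError("exposure levels must be strictly increasing")
        if self.n_replicates < 1 or self.organisms_per_replicate < 1:
            raise DesignError("replication counts must be positive")
        endpoint = Endpoint(self.endpoint)
        object.__setattr__(self, "endpoint", endpoint)
        if self.duration_h not in VALID_ENDPOINT_DURATIONS[endpoint]:
            raise DesignError(
                f"{endpoint.value} at {self.duration_h} h is not a supported "
                f"endpoint/duration pair"
            )
        if endpoint.is_quantal:
            if self.organisms_per_replicate < 2:
                raise DesignError("immobilisation needs >1 organism per vessel")
        elif self.organisms_per_replicate != 1:
            raise DesignError("continuous endpoints use 1 organism unit per vessel")

    @property
    def response_unit(self) -> str:
        return ENDPOINT_RESPONSE_UNIT[self.endpoint]


_CSV_COLUMNS = [
    "exposure_value",
    "exposure_unit",
    "replicate_id",
    "response_value",
    "response_unit",
    "n_exposed",
    "is_control",
]


@dataclass
class DoseResponseDataset:
    """Tidy replicate responses for one organism-endpoint experiment.

    ``data`` columns: exposure_value, exposure_unit, replicate_id,
    response_value, response_unit, n_exposed (quantal only, else NA),
    is_control.  ``control_t0`` carries the mean time-zero density for
    algal tests, needed by the fold-growth validity criterion.
    """

    design: ExposureDesign
    data: pd.DataFrame
    organism: Organism
    label: str = ""
    control_t0: float | None = None

    def __post_init__(self) -> None:
        self.organism = Organism(self.organism)
        df = self.data
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        controls = df[df["is_control"]]
        if controls.empty:
            raise ValueError("dataset has no control rows")
        treated = df[~df["is_control"]]
        if treated["exposure_value"].nunique() < 2:
            raise ValueError("need >=2 non-control exposure levels")
        if self.design.endpoint.is_quantal:
            resp = df["response_value"].to_numpy()
            n_exp = df["n_exposed"].to_numpy(dtype=float)
            if not np.allclose(resp, np.round(resp)):
                raise ValueError("immobilisation responses must be integer counts")
            if np.any(resp < 0) or np.any(resp > n_exp):
                raise ValueError("immobilised counts must lie in [0, n_exposed]")

    # -- accessors ---------------------------------------------------------

    @property
    def levels(self) -> np.ndarray:
        """Sorted non-control exposure values."""
        vals = self.data.loc[~self.data["is_control"], "exposure_value"].unique()
        return np.sort(vals.astype(float))

    def responses_at(self, level: float) -> np.ndarray:
        sel = (~self.data["is_control"]) & np.isclose(
            self.data["exposure_value"].astype(float), level
        )
        return self.data.loc[sel, "response_value"].to_numpy(dtype=float)

    def n_exposed_at(self, level: float) -> np.ndarray:
        sel = (~self.data["is_control"]) & np.isclose(
            self.data["exposure_value"].astype(float), level
        )
        return self.data.loc[sel, "n_exposed"].to_numpy(dtype=float)

    @property
    def control_responses(self) -> np.ndarray:
        return self.data.loc[self.data["is_control"], "response_value"].to_numpy(
            dtype=float
        )

    @property
    def control_n_exposed(self) -> np.ndarray:
        return self.data.loc[self.data["is_control"], "n_exposed"].to_numpy(dtype=float)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write tidy CSV with a ``#``-prefixed metadata preamble."""
        meta = {
            "endpoint": self.design.endpoint.value,
            "duration_h": self.design.duration_h,
            "organism": self.organism.value,
            "label": self.label,
            "n_replicates": self.design.n_replicates,
            "organisms_per_replicate": self.design.organisms_per_replicate,
            "exposure_unit": self.design.exposure_unit,
        }
        if self.control_t0 is not None:
            meta["control_t0"] = repr(float(self.control_t0))
        buf = io.StringIO()
        for key, value in meta.items():
            buf.write(f"# {key}={value}\n")
        self.data[_CSV_COLUMNS].to_csv(buf, index=False)
        Path(path).write_text(buf.getvalue())

    @classmethod
    def from_csv(cls, path: str | Path) -> "DoseResponseDataset":
        text = Path(path).read_text()
        meta: dict[str, str] = {}
        body_lines: list[str] = []
        for line in text.splitlines():
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
            else:
                body_lines.append(line)
        df = pd.read_csv(io.StringIO("\n".join(body_lines)))
        df["is_control"] = df["is_control"].astype(bool)
        treated = df[~df["is_control"]]
        design = ExposureDesign(
            levels=tuple(np.sort(treated["exposure_value"].unique().astype(float))),
            n_replicates=int(meta["n_replicates"]),
            organisms_per_replicate=int(meta["organisms_per_replicate"]),
            endpoint=Endpoint(meta["endpoint"]),
            duration_h=int(meta["duration_h"]),
            exposure_unit=meta.get("exposure_unit", "percent_v_v"),
        )
        t0 = meta.get("control_t0")
        return cls(
            design=design,
            data=df,
            organism=Organism(meta["organism"]),
            label=meta.get("label", ""),
            control_t0=float(t0) if t0 not in (None, "") else None,
        )


def tidy_frame(records: Iterable[dict]) -> pd.DataFrame:
    """Assemble a tidy response table, filling quantal-only columns with NA."""
    df = pd.DataFrame(list(records))
    for col in _CSV_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[_CSV_COLUMNS]
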