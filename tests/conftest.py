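import numpy as np
import pytest

from ecotoxrisk.datasets import (
    DoseResponseDataset,
    Endpoint,
    ExposureDesign,
    Organism,
    tidy_frame,
)


@pytest.fixture
def algal_design() -> ExposureDesign:
    return ExposureDesign(
        levels=(0.01, 0.1, 1.0, 10.0, 100.0),
        n_replicates=3,
        organisms_per_replicate=1,
        endpoint=Endpoint.algal_growth,
        duration_h=72,
    )


@pytest.fixture
def continuous_dataset_factory():
    """Build a continuous-endpoint dataset from explicit growth values."""

    def build(
        levels,
        responses_per_level,
        controls,
        endpoint=Endpoint.algal_growth,
        organism=None,
        control_t0=None,
        duration_h=72,
    ) -> DoseResponseDataset:
        records = []
        for i, g in enumerate(controls):
            records.append(
                dict(exposure_value=0.0, exposure_unit="percent_v_v",
                     replicate_id=f"c{i}", response_value=float(g),
                     response_unit="od684_growth", n_exposed=np.nan,
                     is_control=True)
            )
        for lv, resp in zip(levels, responses_per_level):
            for i, g in enumerate(resp):
                records.append(
                    dict(exposure_value=float(lv), exposure_unit="percent_v_v",
                         replicate_id=f"r{i}", response_value=float(g),
                         response_unit="od684_growth", n_exposed=np.nan,
                         is_control=False)
                )
        design = ExposureDesign(
            levels=tuple(levels),
            n_replicates=max(len(r) for r in responses_per_level),
            organisms_per_replicate=1,
            endpoint=endpoint,
            duration_h=duration_h,
        )
        if organism is None:
            organism = {
                Endpoint.algal_growth: Organism.P_subcapitata,
                Endpoint.frond_area_growth: Organism.S_polyrhiza,
            }[endpoint]
        return DoseResponseDataset(
            design=design,
            data=tidy_frame(records),
            organism=organism,
            control_t0=control_t0,
        )

    return build


@pytest.fixture
def quantal_dataset_factory():
    """Build an immobilisation dataset from explicit vessel counts."""

    def build(levels, counts_per_level, control_counts, n_per_vessel=5,
              duration_h=48) -> DoseResponseDataset:
        records = []
        for i, k in enumerate(control_counts):
            records.append(
                dict(exposure_value=0.0, exposure_unit="percent_v_v",
                     replicate_id=f"c{i}", response_value=int(k),
                     response_unit="count", n_exposed=n_per_vessel,
                     is_control=True)
            )
        for lv, counts in zip(levels, counts_per_level):
            for i, k in enumerate(counts):
                records.append(
                    dict(exposure_value=float(lv), exposure_unit="percent_v_v",
                         replicate_id=f"r{i}", response_value=int(k),
                         response_unit="count", n_exposed=n_per_vessel,
                         is_control=False)
                )
        design = ExposureDesign(
            levels=tuple(levels),
            n_replicates=max(len(c) for c in counts_per_level),
            organisms_per_replicate=n_per_vessel,
            endpoint=Endpoint.immobilisation,
            duration_h=duration_h,
        )
        return DoseResponseDataset(
            design=design,
            data=tidy_frame(records),
            organism=Organism.D_magna,
        )

    return build
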