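import math

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "seedwind",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("seedwind")


@pytest.fixture
def holotype_like():
    """A complete specimen with every trait at mid-range values."""
    from seedwind.morphometrics import SpecimenRecord

    return SpecimenRecord(
        specimen_id="HOLO-001",
        taxon_hypothesis="alasemenia_tria",
        measurements={
            "ovule_length_mm": 30.0,
            "ovule_max_width_mm": 4.5,
            "wing_max_width_mm": 1.8,
            "wing_free_length_mm": 12.0,
            "nucellus_length_mm": 11.0,
            "nucellus_max_width_mm": 1.5,
            "branch_width_mm": 0.6,
            "dichotomy_angle_deg": 90.0,
            "wing_count": 3,
        },
    )


@pytest.fixture
def brute_force_windward():
    """Independent evaluation of the shadowing rule: explicit sort, no vectorisation."""

    def evaluate(n, theta, swing=1.0):
        projections = sorted(
            abs(math.sin(theta + 2.0 * math.pi * k / n)) for k in range(n)
        )
        if n == 1:
            return swing * projections[0]
        return swing * (projections[-1] + projections[-2])

    return evaluate
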