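import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_specimens():
    """Six specimens from three sheets with hand-set property values."""
    from veneermatch.measurements import Specimen

    rows = [
        ("A-1", "A", 1.30, 15.0, -0.50),
        ("A-2", "A", 1.32, 15.4, -0.45),
        ("B-1", "B", 1.10, 12.0, -0.20),
        ("B-2", "B", 1.12, 12.2, -0.25),
        ("C-1", "C", 1.50, 18.0, -0.80),
        ("C-2", "C", 1.52, 18.3, -0.75),
    ]
    return [
        Specimen(
            specimen_id=sid,
            sheet_id=sheet,
            dry_weight=dry,
            moisture_absorption=moist,
            mode_skewness=skew,
        )
        for sid, sheet, dry, moist, skew in rows
    ]


@pytest.fixture
def specimen_table(tmp_path, small_specimens):
    from veneermatch.measurements import write_specimens

    path = tmp_path / "specimens.csv"
    write_specimens(small_specimens, path)
    return path
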