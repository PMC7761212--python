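import statistics
import warnings

import pytest
from hypothesis import HealthCheck, settings

import hemequil as hq

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.filter_too_much],
)
settings.load_profile("default")


@pytest.fixture
def column():
    """The default synthetic column (AHb1 monomer/dimer endpoints)."""
    return hq.DEFAULT_COLUMN


@pytest.fixture(scope="session")
def refs():
    return hq.make_reference_shapes()


def recover_kd_median(preset_name: str, seeds=range(1, 11)) -> float:
    """Run the full SEC -> Manning pipeline on a preset; median Kd over seeds."""
    preset = hq.SEC_PRESETS[preset_name]
    kds = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", hq.HemequilWarning)
        for seed in seeds:
            chroms = hq.simulate_sec_series(preset, seed)
            points = hq.equilibrium_points_from_chromatograms(chroms, preset.column)
            kds.append(hq.fit_kd_manning(points).kd_uM)
    return statistics.median(kds)
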