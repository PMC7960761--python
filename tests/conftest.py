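import numpy as np
import pytest

from osmoscan.curves import CurveParams, fraction_presets, synth_curve


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def preset_truths():
    """Ground-truth indices of the five fraction presets."""
    return {fp.label: synth_curve(fp.params)[1] for fp in fraction_presets()}


@pytest.fixture
def wb_curve():
    """Noiseless whole-blood preset curve with its exact truth (0.5 grid)."""
    params = CurveParams(grid_step=0.5)
    return synth_curve(params)
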