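import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from varipept import rescoring, synthetic
from varipept.pipeline import compute_feature_tables


@pytest.fixture(scope="session")
def default_sim():
    """One synthetic run under the default study conditions."""
    return synthetic.simulate(synthetic.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_tables(default_sim):
    return compute_feature_tables(
        default_sim.psms,
        default_sim.ms2,
        default_sim.ms1,
        rescore_cfg=rescoring.RescoreConfig(seed=1),
    )


@pytest.fixture(scope="session")
def truth_by_spectrum(default_sim):
    return {t["spectrum_id"]: t for t in default_sim.truth}
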