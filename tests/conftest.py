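import numpy as np
import pytest

from wgdwave import LTTCurve


@pytest.fixture
def flat_ltt() -> LTTCurve:
    """Constant lineage count on [0, 100] mya: the null reduces to uniform."""
    dt = 0.1
    mids = np.arange(0, 100, dt) + dt / 2
    return LTTCurve(times=mids, counts=np.full(mids.size, 5.0), dt=dt)
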