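import numpy as np
import pytest

from synclamp.ssa import FUSION, ReleaseRecord


def make_record(fusion_times, n_simulations, t_end, sim_ids=None,
                nfree=None) -> ReleaseRecord:
    """Build a ReleaseRecord directly from fusion times (test helper)."""
    times = np.asarray(fusion_times, float)
    if sim_ids is None:
        sim_ids = np.arange(times.size, dtype=np.int64)
    if nfree is None:
        nfree = np.full(times.size, np.nan)
    return ReleaseRecord(
        sim_id=np.asarray(sim_ids, np.int64),
        event_type=np.full(times.size, FUSION, np.int8),
        t_ms=times,
        n_free_at_event=np.asarray(nfree, float),
        total_simulations=n_simulations,
        t_end=float(t_end),
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
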