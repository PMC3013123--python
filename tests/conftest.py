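import numpy as np
import pytest

from dnabreathe import (
    EPBDParameters,
    LangevinConfig,
    PromoterSequence,
    simulate_ensemble,
)


@pytest.fixture(scope="session")
def params():
    return EPBDParameters()


@pytest.fixture
def seq_small():
    # 20 bp, AT-rich centre, TSS at internal index 10
    return PromoterSequence("small", "GCGCG" + "ATATATATAT" + "CGCGC", 10)


@pytest.fixture(scope="session")
def tiny_ensemble(params):
    """A short but real Langevin ensemble shared across tests (~1 s)."""
    seq = PromoterSequence("tiny", "GCGCGATATATATATCGCGC", 10)
    cfg = LangevinConfig(
        n_equil_steps=2500,
        n_prod_steps=10000,
        sample_stride=25,
        n_replicas=3,
        seed=42,
        store_velocities=True,
    )
    return simulate_ensemble(seq, params, cfg)


def brute_force_runs(mask_2d):
    """Per-column exhaustive run extraction oracle: list of
    (col, birth, death) by direct frame-by-frame scanning."""
    runs = []
    n_frames, n_cols = mask_2d.shape
    for c in range(n_cols):
        open_since = None
        for f in range(n_frames):
            if mask_2d[f, c] and open_since is None:
                open_since = f
            elif not mask_2d[f, c] and open_since is not None:
                runs.append((c, open_since, f))
                open_since = None
        if open_since is not None:
            runs.append((c, open_since, n_frames))
    return runs
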