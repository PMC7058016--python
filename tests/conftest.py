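import warnings

import numpy as np
import pytest

import lovkin as lk


@pytest.fixture(autouse=True)
def _quiet_scale_warnings():
    """Rate-scale advisory warnings are irrelevant to most tests."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="characteristic time")
        yield


@pytest.fixture(scope="session")
def paper_rates():
    """The reference irradiation-scale rate constants (1/k = 9000, 1000, 3260 s)."""
    return lk.REFERENCE_RATES


@pytest.fixture(scope="session")
def rate_triples():
    """20 randomized log-uniform rate triples in [1e-5, 1e-2] s^-1, including
    near-degenerate pairs."""
    rng = np.random.default_rng(20240917)
    triples = []
    for i in range(20):
        k = 10 ** rng.uniform(-5, -2, size=3)
        if i % 4 == 1:      # near-degenerate k1 ~ k2
            k[1] = k[0] * (1 + 1e-9)
        elif i % 4 == 2:    # near-degenerate k2 ~ k3
            k[2] = k[1] * (1 - 1e-9)
        elif i % 4 == 3:    # near-degenerate k1 ~ k3
            k[2] = k[0] * (1 + 5e-10)
        triples.append(lk.RateConstants(*k, check_scale=False))
    return triples


@pytest.fixture(scope="session")
def c450a_noiseless_curves():
    cfg = lk.default_config("C450A", seed=0).silenced()
    return cfg, lk.generate_triplet_experiment(cfg)


def collect_net_traces(phos_traces):
    """Group window traces by set and background-subtract each set."""
    by = {}
    for tr in phos_traces:
        by.setdefault(tr.irradiation_time, {})[tr.filter_window] = tr
    return [
        lk.subtract_filter_background(w["1250-1300"], w["1200-1250"], w["1300-1350"])
        for w in (by[k] for k in sorted(by))
    ]
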