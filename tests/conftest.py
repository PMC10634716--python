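import numpy as np
import pandas as pd
import pytest

from factorfinder import benchmark_config, build_null_table, simulate_dataset
from factorfinder.peaks import CallerParams, call_peaks
from factorfinder.readwrite import empty_contact_frame, order_contact_frame


def make_contact_frame(rows):
    """Contact frame from (pos1, strand1, len1, pos2, strand2, len2) tuples.

    len None means censored; all sides on chromosome 'chrT'.
    """
    if not rows:
        return empty_contact_frame()
    rec = []
    for pos1, s1, l1, pos2, s2, l2 in rows:
        rec.append({
            "chrom1": "chrT", "pos1": pos1, "strand1": s1,
            "len1": 0 if l1 is None else l1, "obs1": l1 is not None,
            "chrom2": "chrT", "pos2": pos2, "strand2": s2,
            "len2": 0 if l2 is None else l2, "obs2": l2 is not None,
        })
    frame = pd.DataFrame(rec)
    for c in ("pos1", "len1", "pos2", "len2"):
        frame[c] = frame[c].astype(np.int64)
    return order_contact_frame(frame)


@pytest.fixture(scope="session")
def tiny_null_table():
    """Small-N table for exact-enumeration comparisons."""
    return build_null_table(n_min=5, n_max=8, reps=300_000, seed=3)


@pytest.fixture(scope="session")
def null_table():
    """Null table covering the window counts seen in the simulations."""
    return build_null_table(n_min=5, n_max=150, reps=300_000, seed=4)


@pytest.fixture(scope="session")
def benchmark(null_table):
    """Default peak-calling benchmark run: simulated dataset plus calls."""
    sim = simulate_dataset(benchmark_config(), seed=1)
    peaks = call_peaks(sim.contacts, params=CallerParams(), table=null_table)
    return sim, peaks
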