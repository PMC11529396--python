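import itertools

import numpy as np
import pandas as pd
import pytest

from ctdetect import (
    DuplexCountTable,
    PanelFingerprint,
    SampleRecord,
    SiteRecord,
    make_panel,
)


@pytest.fixture
def toy_panel() -> PanelFingerprint:
    return PanelFingerprint(
        (
            SiteRecord("siteA", "chr1", 100, "A", "T"),
            SiteRecord("siteB", "chr2", 200, "C", "G"),
            SiteRecord("siteC", "chr3", 300, "G", "A"),
        ),
        name="toy",
    )


@pytest.fixture
def toy_table(toy_panel) -> DuplexCountTable:
    df = pd.DataFrame(
        {
            "sample_id": ["s1"] * 3 + ["s2"] * 3,
            "site_id": ["siteA", "siteB", "siteC"] * 2,
            "t": [10, 20, 30, 5, 5, 5],
            "n": [0, 3, 1, 0, 0, 0],
        }
    )
    return DuplexCountTable(df, panel=toy_panel)


@pytest.fixture
def toy_metadata() -> list[SampleRecord]:
    return [
        SampleRecord("s1", "control", "none", 0.0, 1e7, 0.3, "t0"),
        SampleRecord("s2", "primed", "liposome", 100.0, 2e8, 0.3, "t0"),
    ]


def brute_force_detection_probability(t, f, threshold):
    """Independent oracle: exhaustive enumeration over all 2^S detection outcomes."""
    t = np.asarray(t, dtype=float)
    if threshold == 0:
        return 1.0
    p = np.where(t > 0, 1.0 - (1.0 - f) ** t, 0.0)
    total = 0.0
    for bits in itertools.product((0, 1), repeat=len(t)):
        if sum(bits) >= threshold:
            total += np.prod([pj if b else 1.0 - pj for b, pj in zip(bits, p)])
    return float(total)


def random_count_table(rng, n_samples=3, n_sites=4, max_t=50, panel=None):
    """Random valid count table (0 <= n <= t), optionally bound to a panel."""
    if panel is None:
        panel = make_panel(n_sites)
    sites = panel.site_ids
    rows = []
    for i in range(n_samples):
        t = rng.integers(0, max_t + 1, size=len(sites))
        n = rng.integers(0, t + 1)
        for j, sid in enumerate(sites):
            rows.append({"sample_id": f"s{i}", "site_id": sid, "t": int(t[j]), "n": int(n[j])})
    return DuplexCountTable(pd.DataFrame(rows), panel=panel)
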