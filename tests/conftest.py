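import numpy as np
import pytest

from methaplo.io_formats import ReadPatternSet, RegionPanel, SampleMeta


@pytest.fixture
def small_panel():
    return {
        "R1": RegionPanel("R1", "chr1", (100, 110, 120)),
        "R2": RegionPanel("R2", "chr2", (500, 510)),
    }


@pytest.fixture
def two_cpg_panel():
    return RegionPanel("R", "chr1", (100, 110))


@pytest.fixture
def small_rps():
    return ReadPatternSet(
        [
            ("s1", "R1", "MUM", 3),
            ("s1", "R1", "UUU", 1),
            ("s1", "R2", "MU", 5),
            ("s2", "R1", "MMM", 2),
            ("s2", "R2", "UN", 4),
        ]
    )


@pytest.fixture
def small_meta():
    return {
        "s1": SampleMeta("s1", "case", age=50.0, conversion_rate=0.99),
        "s2": SampleMeta("s2", "control", age=55.0, conversion_rate=0.98),
    }


def random_complete_rps(rng: np.random.Generator, n_samples=3, n_regions=2,
                        max_len=5, max_patterns=6, max_count=20):
    """Random ReadPatternSet whose patterns contain no 'N'."""
    entries = []
    lengths = {f"R{r}": int(rng.integers(1, max_len + 1)) for r in range(n_regions)}
    for s in range(n_samples):
        for rid, L in lengths.items():
            for _ in range(int(rng.integers(1, max_patterns + 1))):
                pat = "".join(rng.choice(["M", "U"], size=L))
                entries.append((f"s{s}", rid, pat, int(rng.integers(1, max_count))))
    panels = {
        rid: RegionPanel(rid, "chr1", tuple(range(100, 100 + 10 * L, 10)))
        for rid, L in lengths.items()
    }
    return ReadPatternSet(entries), panels
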