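import numpy as np
import pandas as pd
import pytest

from pchic.classify import classify_frame
from pchic.genome import Arm, GenomeAnnotation, Intervals
from pchic.simulate import SyntheticConfig, make_toy_genome, simulate_hic_pairs


@pytest.fixture(scope="session")
def toy():
    """Default synthetic genome used across integration-style tests."""
    return make_toy_genome(SyntheticConfig(seed=101))


@pytest.fixture(scope="session")
def classified_small(toy):
    """200k classified synthetic pairs (no planted EU-PCH effects)."""
    pairs = simulate_hic_pairs(toy, 200_000, seed=102)
    return classify_frame(pairs, toy.annotation, toy.catalog)


@pytest.fixture
def simple_annotation():
    """Two metacentric chromosomes plus a fully heterochromatic 4th.

    2L/3L carry PCH at the right (centromeric) end, 2R/3R at the left; 1 Mb
    arms with 200 kb PCH blocks, 300 kb conservative offset.
    """
    arms = [
        Arm("2L", "2", 1_000_000),
        Arm("2R", "2", 1_000_000),
        Arm("3L", "3", 1_000_000),
        Arm("3R", "3", 1_000_000),
        Arm("4", "4", 200_000),
    ]
    pch = {
        "2L": Intervals.from_pairs([(800_000, 1_000_000)]),
        "2R": Intervals.from_pairs([(0, 200_000)]),
        "3L": Intervals.from_pairs([(800_000, 1_000_000)]),
        "3R": Intervals.from_pairs([(0, 200_000)]),
        "4": Intervals.from_pairs([(0, 200_000)]),
    }
    return GenomeAnnotation(
        arms=arms, pch=pch, het_chromosomes={"4"}, eu_offset_bp=300_000
    )


def make_pairs_frame(rows):
    """Build an unclassified pairs frame from (arm1, pos1, mapq1, repeat1,
    te1, arm2, pos2, mapq2, repeat2, te2) tuples."""
    cols = ["arm1", "pos1", "mapq1", "repeat1", "te1",
            "arm2", "pos2", "mapq2", "repeat2", "te2"]
    df = pd.DataFrame(rows, columns=cols)
    df.insert(0, "read_id", np.arange(len(df)))
    for i in (1, 2):
        df[f"pos{i}"] = df[f"pos{i}"].fillna(-1).astype(np.int64)
        df[f"te{i}"] = df[f"te{i}"].astype(bool)
    return df
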