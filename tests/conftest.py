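import numpy as np
import pytest

from pistop.io_formats import Interval, IntervalSet, ReadRecord, SequenceSet
from pistop.synthetic_data import CleavageModel, CompositionModel, generate_cluster


@pytest.fixture(scope="session")
def uniform_cluster() -> SequenceSet:
    """A 20 kb cluster with symmetric base composition (no CpG depletion)."""
    model = CompositionModel(base_probs=(0.25, 0.25, 0.25, 0.25), cpg_depletion=1.0)
    return generate_cluster(20_000, model, seed=11)


@pytest.fixture(scope="session")
def at_rich_cluster() -> SequenceSet:
    """A 20 kb cluster with the default AT-rich, CpG-depleted composition."""
    return generate_cluster(20_000, seed=7)


@pytest.fixture
def tiny_seqs() -> SequenceSet:
    return SequenceSet({"t1": "CCTAAGGCCTTAGGAATTAAC"})


def cluster_regions(cluster: SequenceSet) -> IntervalSet:
    (name,) = cluster.keys()
    return IntervalSet([Interval(name, 0, len(cluster[name]), "+", name)])


def uniform_random_reads(cluster: SequenceSet, n: int, length: int, seed: int):
    """Reads with 5' ends drawn uniformly over the cluster (no sequence bias)."""
    (name,) = cluster.keys()
    L = len(cluster[name])
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, L - length, size=n)
    return [ReadRecord(name, int(s), int(s) + length, "+", 1) for s in starts]
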