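import numpy as np
import pytest

from matcnv.genome import build_genome_model, toy_genome
from matcnv.simulate import CohortSpec, TruthVariant, simulate_cohort


@pytest.fixture(scope="session")
def toy_model():
    """Standard desk-scale genome: 4 autosomes + X, 165 Mb, 8,250 bins."""
    return toy_genome()


@pytest.fixture(scope="session")
def mini_model():
    """Very small genome for fast unit tests: 30 Mb, 1,500 bins."""
    return build_genome_model(
        {"chr1": 12_000_000, "chr2": 10_000_000, "chrX": 8_000_000})


@pytest.fixture(scope="session")
def mini_cohort(mini_model):
    """20 diploid samples on the mini genome, default noise/bias/batch."""
    spec = CohortSpec(n_samples=20, reads_range=(70_000, 90_000), seed=101)
    return simulate_cohort(mini_model, spec)


@pytest.fixture(scope="session")
def gain_variant():
    """A 400 kb maternal het duplication on chr1 of the mini genome."""
    return TruthVariant("chr1", 3_000_000, 3_400_000, 3, "maternal", 1.0)


def brute_force_split(x):
    """Independent exhaustive arc search for the circular split
    statistic: every arc (i, j], pooled-SD two-sample Z, first maximum
    in (i, j) lexicographic order."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    best = (-1.0, -1, -1)
    for i in range(n):
        for j in range(i + 1, n + 1):
            k = j - i
            if k == n:
                continue
            inside = x[i:j]
            outside = np.concatenate([x[:i], x[j:]])
            ss = (((inside - inside.mean()) ** 2).sum()
                  + ((outside - outside.mean()) ** 2).sum())
            s2 = ss / (n - 2)
            diff = inside.mean() - outside.mean()
            if s2 <= 0:
                t = np.inf if diff != 0 else 0.0
            else:
                t = abs(diff) / np.sqrt(s2 * (1 / k + 1 / (n - k)))
            if t > best[0]:
                best = (t, i, j)
    if best[1] < 0 or best[0] == 0.0:
        return 0.0, -1, -1
    return best
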