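import numpy as np
import pandas as pd
import pytest

from lofpipe.expression import GeneSet
from lofpipe.motifs import PWM


@pytest.fixture
def toy_ranked():
    """Five-gene ranked list with hand-checkable running sums."""
    return pd.Series([3.0, 2.0, 1.0, -1.0, -2.0],
                     index=["g1", "g2", "g3", "g4", "g5"])


@pytest.fixture
def random_ranked():
    rng = np.random.default_rng(42)
    genes = [f"G{i:03d}" for i in range(60)]
    scores = np.sort(rng.normal(size=60))[::-1]
    return pd.Series(scores, index=genes)


@pytest.fixture
def strong_pwm():
    """Near-deterministic 8-mer PWM with uniform background."""
    probs = np.full((8, 4), 0.01)
    for j, base in enumerate([0, 2, 1, 3, 0, 0, 2, 1]):  # ACGTAAGC... by index
        probs[j, base] = 0.97
    return PWM(motif_id="toy8", probs=probs)


@pytest.fixture
def lof_geneset():
    return GeneSet("lof", ("g1", "g3", "g4"))
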