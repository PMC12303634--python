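import numpy as np
import pandas as pd
import pytest

from mrpipe.harmonize import HarmonizedPairs
from mrpipe.synthetic_data import SimScenario, simulate_sumstats_pair
from mrpipe.harmonize import harmonize


def pairs_from_arrays(g, sg, G, sG, n_exp=100_000.0, n_out=100_000.0,
                      exposure="exp", outcome="out"):
    """Build HarmonizedPairs directly from effect arrays (test helper)."""
    g = np.asarray(g, dtype=float)
    J = len(g)
    df = pd.DataFrame(
        dict(
            rsid=[f"rs{i + 1:05d}" for i in range(J)],
            ea=["A"] * J, oa=["G"] * J,
            gamma=g, se_gamma=np.asarray(sg, dtype=float),
            Gamma=np.asarray(G, dtype=float), se_Gamma=np.asarray(sG, dtype=float),
            n_exp=float(n_exp), n_out=float(n_out),
        )
    )
    audit = pd.DataFrame(dict(rsid=df["rsid"], action="kept"))
    return HarmonizedPairs(exposure, outcome, df, audit)


@pytest.fixture
def clean_pairs():
    """Harmonized pairs from one clean simulated study (J=30, beta=0.3)."""
    s = SimScenario(seed=42, n_snps=30, true_beta=0.3)
    exposure, outcome, _ = simulate_sumstats_pair(s)
    return harmonize(exposure, outcome)


@pytest.fixture
def helpers():
    class H:
        pairs_from_arrays = staticmethod(pairs_from_arrays)
    return H
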