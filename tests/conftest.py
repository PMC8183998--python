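import pandas as pd
import pytest

from cisreg.imbalance import BetaBinomialParams


@pytest.fixture
def untreated_params():
    """Beta-binomial null shapes of the untreated condition."""
    return BetaBinomialParams(alpha=40.78, beta=39.26)


@pytest.fixture
def treated_params():
    return BetaBinomialParams(alpha=41.76, beta=40.10)


@pytest.fixture
def tiny_counts():
    """Hand-built per-sample allele counts exercising the filter rules."""
    rows = [
        # passes: depths 15/12, ref 20 >= 3, alt 7 >= 3
        ("v1", "s1", "treated", 12, 3), ("v1", "s1", "untreated", 8, 4),
        # fails: alt observed 2 < 3 across conditions
        ("v2", "s1", "treated", 10, 0), ("v2", "s1", "untreated", 10, 2),
        # fails: untreated depth 9 < 10
        ("v3", "s1", "treated", 20, 10), ("v3", "s1", "untreated", 5, 4),
        # fails: only one condition observed
        ("v4", "s1", "treated", 30, 30),
        # v1 again in a second sample: passes
        ("v1", "s2", "treated", 6, 6), ("v1", "s2", "untreated", 7, 7),
    ]
    return pd.DataFrame(
        [{"variant_id": v, "chrom": "chr1", "pos": 100, "sample_id": s,
          "condition": c, "ref_count": r, "alt_count": a}
         for v, s, c, r, a in rows])
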