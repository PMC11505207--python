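import numpy as np
import pandas as pd
import pytest

from mrmediate import HarmonizedSet, SummaryStats


def make_harmonized(bx, sx, by, sy, exposure="EXP", outcome="OUT") -> HarmonizedSet:
    """Build a HarmonizedSet directly from effect arrays (test helper)."""
    n = len(bx)
    df = pd.DataFrame(
        {
            "SNP": [f"rs{i}" for i in range(n)],
            "CHR": ["1"] * n,
            "POS": np.arange(n) * 20_000_000 + 1,
            "EA": ["A"] * n,
            "OA": ["G"] * n,
            "beta_exp": np.asarray(bx, float),
            "se_exp": np.asarray(sx, float),
            "beta_out": np.asarray(by, float),
            "se_out": np.asarray(sy, float),
        }
    )
    return HarmonizedSet(exposure_id=exposure, outcome_id=outcome, df=df)


def make_panel(rows, trait_id="TRAIT", trait_type="continuous") -> SummaryStats:
    """Panel from a list of dicts with any subset of the generic columns."""
    defaults = {"CHR": "1", "POS": 1000, "EA": "A", "OA": "G",
                "EAF": 0.3, "SE": 0.01, "N": 10_000.0}
    recs = []
    for i, row in enumerate(rows):
        rec = {"SNP": f"rs{i}", **defaults, **row}
        recs.append(rec)
    df = pd.DataFrame.from_records(
        recs, columns=["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
    )
    return SummaryStats(trait_id=trait_id, trait_type=trait_type, df=df)


@pytest.fixture
def ivw_example() -> HarmonizedSet:
    """Three-SNP worked example with beta=0.5, fixed-effect se=1/15, Q=2."""
    return make_harmonized(
        bx=[0.1, 0.2, 0.3],
        sx=[0.01, 0.01, 0.01],
        by=[0.05, 0.08, 0.18],
        sy=[0.02, 0.02, 0.03],
    )
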