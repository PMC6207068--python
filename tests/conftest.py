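import pandas as pd
import pytest

from armcall import ArmTable, GeneTable


@pytest.fixture(scope="session")
def arms():
    return ArmTable.hg19()


@pytest.fixture(scope="session")
def genes():
    return GeneTable.hg19()


def make_segments(rows, sample_id="s1"):
    """Build a segment table from (chrom, start, end, n_probes, log2, label) tuples."""
    return pd.DataFrame(
        [
            {
                "sample_id": sample_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_probes": n_probes,
                "log2_ratio": log2,
                "annotation": label,
            }
            for chrom, start, end, n_probes, log2, label in rows
        ]
    )


@pytest.fixture
def seg_builder():
    return make_segments
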