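import pandas as pd
import pytest

from isocoord.genome import GenomicInterval, TranscriptModel


def iv(start, end, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


@pytest.fixture
def toy_gene():
    """Four isoforms of one + strand gene: inclusion/skipping of exon
    (300, 400) crossed with two transcript end sites (600 vs 800)."""
    exon_a, exon_b = iv(100, 200), iv(300, 400)
    models = []
    for j, end in enumerate((600, 800), start=1):
        exon_c = iv(500, end)
        cds = iv(150, 550)
        models.append(
            TranscriptModel(f"T_inc_p{j}", "G1", [exon_a, exon_b, exon_c], "+", cds)
        )
        models.append(
            TranscriptModel(f"T_skp_p{j}", "G1", [exon_a, exon_c], "+", cds)
        )
    return models


@pytest.fixture
def toy_counts():
    """Transcript-by-sample counts for the toy gene, two samples."""
    return pd.DataFrame(
        {
            "s1": [70, 30, 20, 80],
            "s2": [60, 40, 10, 90],
        },
        index=["T_inc_p1", "T_skp_p1", "T_inc_p2", "T_skp_p2"],
    )


@pytest.fixture
def sample_map():
    return {"s1": "t00", "s2": "t30"}
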