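import numpy as np
import pytest

from crcscreen.io_formats import TranscriptModel, VariantRecord


@pytest.fixture
def plus_model():
    """Single-segment + strand model: CDS 101..200 (length 100)."""
    return TranscriptModel(
        gene_id="G1", transcript_id="G1.t1", chrom="chr1", strand="+",
        cds_segments=((101, 200),),
    )


@pytest.fixture
def minus_model():
    return TranscriptModel(
        gene_id="G2", transcript_id="G2.t1", chrom="chr1", strand="-",
        cds_segments=((101, 200),),
    )


@pytest.fixture
def two_segment_model():
    """+ strand, segments 101-160 and 301-340 (CDS length 100)."""
    return TranscriptModel(
        gene_id="G3", transcript_id="G3.t1", chrom="chr1", strand="+",
        cds_segments=((101, 160), (301, 340)),
    )


def make_variant(pos=150, ref="C", alt="T", chrom="chr1", quality=150.0,
                 depth=50, sample_id="S1", is_known=False):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, quality=quality,
        depth=depth, sample_id=sample_id, is_known=is_known,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
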