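import numpy as np
import pandas as pd
import pytest

from splicerank.events import GenomicInterval, TranscriptModel


def make_transcript(transcript_id, gene_id, exons, chrom="chr1", strand="+"):
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
    )


@pytest.fixture
def three_exon_transcript():
    return make_transcript("t1", "g1", [(0, 100), (200, 300), (400, 500)])


@pytest.fixture
def toy_gtf(tmp_path):
    """One 3-exon transcript with 1-based exons 1-100, 201-300, 401-500."""
    lines = []
    for s, e in [(1, 100), (201, 300), (401, 500)]:
        lines.append(
            f'chr1\ttoy\texon\t{s}\t{e}\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
    path = tmp_path / "toy.gtf"
    path.write_text("".join(lines))
    return path


def inclusion_table(values: dict[str, dict[str, float]], kind="RI") -> pd.DataFrame:
    """values: event_id -> sample_id -> PIR."""
    rows = [
        (eid, sid, kind, v, 100.0, True)
        for eid, per_sample in values.items()
        for sid, v in per_sample.items()
    ]
    return pd.DataFrame(
        rows,
        columns=["event_id", "sample_id", "kind", "value", "coverage", "passed_filter"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
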