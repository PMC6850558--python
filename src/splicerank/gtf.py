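"""GTF reading: transcript models from Ensembl/GENCODE-style annotation.

Only ``exon`` features are consumed; each must carry ``gene_id`` and
``transcript_id`` attributes. GTF coordinates are 1-based inclusive and
are converted to the package-internal 0-based half-open convention here,
at the I/O boundary. Attribute strings are parsed with gffutils so both
GTF and GFF3 dialect quirks are handled.
"""

from __future__ import annotations

from typing import Iterable

import gffutils

from .events import GenomicInterval, TranscriptModel


class GTFParseError(ValueError):
    """Raised for malformed GTF input, naming the offending line."""


def parse_gtf(path) -> list[TranscriptModel]:
    """Read a GTF file into one :class:`TranscriptModel` per transcript.

    Raises :class:`GTFParseError` naming the line number for malformed
    records, and :class:`AnnotationError` naming the transcript for models
    with overlapping exons.
    """
    exons: dict[str, tuple[str, list[GenomicInterval]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") < 8:
                raise GTFParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise GTFParseError(f"{path}:{lineno}: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            try:
                gene_id = feat.attributes["gene_id"][0]
                transcript_id = feat.attributes["transcript_id"][0]
            except KeyError as exc:
                raise GTFParseError(
                    f"{path}:{lineno}: exon record missing {exc} attribute"
                ) from exc
            if feat.strand not in ("+", "-"):
                raise GTFParseError(f"{path}:{lineno}: exon without strand")
            try:
                iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            except ValueError as exc:
                raise GTFParseError(f"{path}:{lineno}: {exc}") from exc
            if transcript_id not in exons:
                exons[transcript_id] = (gene_id, [])
                order.append(transcript_id)
            exons[transcript_id][1].append(iv)

    models = []
    for transcript_id in order:
        gene_id, ivs = exons[transcript_id]
        models.append(
            TranscriptModel(transcript_id=transcript_id, gene_id=gene_id, exons=ivs)
        )
    return models


def write_gtf(models: Iterable[TranscriptModel], path, source: str = "splicerank") -> None:
    """Write transcript models back out as exon records (GTF dialect)."""
    with open(path, "w") as fh:
        for m in models:
            for i, e in enumerate(m.exons, start=1):
                attrs = (
                    f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                    f'exon_number "{i}";'
                )
                fh.write(
                    f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )
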