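"""Splicing-event models and catalog construction.

Candidate alternative-splicing events are built purely from transcript
annotation: every intron of a multi-exon transcript is a retained-intron
(RI) candidate, every internal exon a skipped-exon (SE) candidate, and
alternative 5'/3' splice sites (A5SS/A3SS) and mutually exclusive exon
pairs (MXE) are derived from intron/exon combinatorics within a gene.
Events from different transcripts with identical defining coordinates are
deduplicated, so quantification downstream is per genomic feature, not per
transcript.

All coordinates are 0-based half-open; GTF input is converted on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Sequence


class CatalogFormatError(ValueError):
    """Raised when an event-catalog file cannot be interpreted."""


class AnnotationError(ValueError):
    """Raised when transcript models violate their invariants."""


EVENT_KINDS = ("RI", "SE", "MXE", "A5SS", "A3SS")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval: ``[start, end)`` on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """One transcript as an ordered chain of exons on a single strand."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"transcript {self.transcript_id} spans multiple chroms/strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id} has overlapping exons "
                    f"({a.start}-{a.end} and {b.start}-{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    def internal_exons(self) -> list[GenomicInterval]:
        return self.exons[1:-1]


@dataclass
class SplicingEvent:
    """A candidate splicing event with its supporting junction sets.

    ``core`` is the intron for RI and the cassette exon for SE. Junctions
    are stored as the *introns* whose exon-exon junctions provide evidence
    for inclusion or exclusion of the core feature. RI events additionally
    carry their two exon-intron ``boundaries`` (5' then 3' relative to
    strand).
    """

    event_id: str
    kind: str
    gene_id: str
    core: GenomicInterval
    inclusion_junctions: frozenset[GenomicInterval] = field(default_factory=frozenset)
    exclusion_junctions: frozenset[GenomicInterval] = field(default_factory=frozenset)
    boundaries: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "RI":
            if len(self.exclusion_junctions) != 1 or len(self.boundaries) != 2:
                raise ValueError(
                    f"RI event {self.event_id} needs one exclusion junction "
                    "and two boundaries"
                )
        if self.kind == "SE":
            if len(self.inclusion_junctions) != 2 or len(self.exclusion_junctions) != 1:
                raise ValueError(
                    f"SE event {self.event_id} needs two inclusion junctions "
                    "and one exclusion junction"
                )

    @property
    def chrom(self) -> str:
        return self.core.chrom

    @property
    def strand(self) -> str:
        return self.core.strand

    def sort_key(self) -> tuple:
        return (self.chrom, self.core.start, self.core.end, self.kind, self.event_id)


def _event_id(kind: str, core: GenomicInterval, *extra: GenomicInterval) -> str:
    parts = [kind, core.chrom, str(core.start), str(core.end), core.strand]
    for iv in extra:
        parts.append(f"{iv.start}-{iv.end}")
    return ":".join(parts)


def build_ri_events(models: Iterable[TranscriptModel]) -> list[SplicingEvent]:
    """One RI event per distinct intron across all transcripts.

    Every intron bounded by exons on both sides is a retention candidate;
    the exclusion junction is the intron's own exon-exon junction and the
    boundaries are its two exon-intron transition points (strand-oriented:
    the 5' boundary of a minus-strand intron is its ``end`` coordinate).
    """
    seen: dict[tuple, SplicingEvent] = {}
    for m in models:
        for intron in m.introns:
            key = (intron.chrom, intron.strand, intron.start, intron.end)
            if key in seen:
                continue
            if intron.strand == "+":
                boundaries = (intron.start, intron.end)
            else:
                boundaries = (intron.end, intron.start)
            seen[key] = SplicingEvent(
                event_id=_event_id("RI", intron),
                kind="RI",
                gene_id=m.gene_id,
                core=intron,
                inclusion_junctions=frozenset(),
                exclusion_junctions=frozenset({intron}),
                boundaries=boundaries,
            )
    return sorted(seen.values(), key=SplicingEvent.sort_key)


def build_se_events(models: Iterable[TranscriptModel]) -> list[SplicingEvent]:
    """One SE event per distinct internal (non-terminal) exon.

    Inclusion evidence comes from the two flanking introns; exclusion from
    the junction skipping the exon (upstream exon end to downstream exon
    start in the defining transcript).
    """
    seen: dict[tuple, SplicingEvent] = {}
    for m in models:
        exons = m.exons
        for i in range(1, len(exons) - 1):
            exon = exons[i]
            up = GenomicInterval(m.chrom, exons[i - 1].end, exon.start, m.strand)
            down = GenomicInterval(m.chrom, exon.end, exons[i + 1].start, m.strand)
            skip = GenomicInterval(m.chrom, exons[i - 1].end, exons[i + 1].start, m.strand)
            key = (exon.chrom, exon.strand, exon.start, exon.end, up.start, down.end)
            if key in seen:
                continue
            seen[key] = SplicingEvent(
                event_id=_event_id("SE", exon, skip),
                kind="SE",
                gene_id=m.gene_id,
                core=exon,
                inclusion_junctions=frozenset({up, down}),
                exclusion_junctions=frozenset({skip}),
            )
    return sorted(seen.values(), key=SplicingEvent.sort_key)


def build_mxe_events(models: Iterable[TranscriptModel]) -> list[SplicingEvent]:
    """Mutually exclusive exon pairs within a gene.

    Two internal exons form an MXE event when they are non-overlapping,
    never co-occur in any transcript of the gene, and some transcript pair
    places them between identical upstream and downstream exon boundaries.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)

    events: dict[tuple, SplicingEvent] = {}
    for gene_id, txs in by_gene.items():
        # internal exon -> (flanking upstream exon end, downstream exon start)
        contexts: dict[GenomicInterval, set[tuple[int, int]]] = {}
        membership: dict[GenomicInterval, set[str]] = {}
        for tx in txs:
            exons = tx.exons
            exon_set = set(exons)
            for i in range(1, len(exons) - 1):
                e = exons[i]
                contexts.setdefault(e, set()).add((exons[i - 1].end, exons[i + 1].start))
            for e in exon_set:
                membership.setdefault(e, set()).add(tx.transcript_id)

        internal = sorted(contexts, key=lambda e: (e.start, e.end))
        for e1, e2 in combinations(internal, 2):
            if e1.overlaps(e2):
                continue
            if membership[e1] & membership[e2]:
                continue  # co-occur in some transcript
            shared = {
                (up, down)
                for (up, down) in contexts[e1] & contexts[e2]
                if up <= min(e1.start, e2.start) and down >= max(e1.end, e2.end)
            }
            if not shared:
                continue
            up, down = sorted(shared)[0]
            chrom, strand = e1.chrom, e1.strand
            first, second = sorted((e1, e2), key=lambda e: e.start)
            inc1 = {
                GenomicInterval(chrom, up, first.start, strand),
                GenomicInterval(chrom, first.end, down, strand),
            }
            inc2 = {
                GenomicInterval(chrom, up, second.start, strand),
                GenomicInterval(chrom, second.end, down, strand),
            }
            # inclusion = junctions of the strand-wise first exon; the
            # partner's junctions are the exclusion set
            if strand == "+":
                inclusion, exclusion = inc1, inc2
            else:
                inclusion, exclusion = inc2, inc1
            key = (chrom, strand, first.start, first.end, second.start, second.end)
            if key in events:
                continue
            events[key] = SplicingEvent(
                event_id=_event_id("MXE", first, second),
                kind="MXE",
                gene_id=gene_id,
                core=first,
                inclusion_junctions=frozenset(inclusion),
                exclusion_junctions=frozenset(exclusion),
            )
    return sorted(events.values(), key=SplicingEvent.sort_key)


def build_ass_events(models: Iterable[TranscriptModel]) -> list[SplicingEvent]:
    """Alternative 5'/3' splice-site events from intron pairs.

    Two introns of one gene sharing exactly one boundary define an event;
    whether the varying end is the donor (A5SS) or acceptor (A3SS) depends
    on strand. The shorter intron carries the inclusion junction (more of
    the exon is included), the longer one the exclusion junction.
    """
    by_gene: dict[str, set[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, set()).update(m.introns)
        gene_of[m.gene_id] = m.gene_id

    events: dict[tuple, SplicingEvent] = {}
    for gene_id, introns in by_gene.items():
        for i1, i2 in combinations(sorted(introns), 2):
            share_start = i1.start == i2.start and i1.end != i2.end
            share_end = i1.end == i2.end and i1.start != i2.start
            if not (share_start or share_end):
                continue
            strand = i1.strand
            # which splice site varies: the intron start is the donor on
            # '+' and the acceptor on '-'
            varies_at_start = share_end
            if varies_at_start:
                kind = "A5SS" if strand == "+" else "A3SS"
            else:
                kind = "A3SS" if strand == "+" else "A5SS"
            short, long_ = sorted((i1, i2), key=len)
            key = (i1.chrom, strand, i1.start, i1.end, i2.start, i2.end, kind)
            if key in events:
                continue
            events[key] = SplicingEvent(
                event_id=_event_id(kind, short, long_),
                kind=kind,
                gene_id=gene_id,
                core=short,
                inclusion_junctions=frozenset({short}),
                exclusion_junctions=frozenset({long_}),
            )
    return sorted(events.values(), key=SplicingEvent.sort_key)


def build_all_events(models: Sequence[TranscriptModel]) -> list[SplicingEvent]:
    """Full deduplicated catalog over every event kind."""
    events = (
        build_ri_events(models)
        + build_se_events(models)
        + build_mxe_events(models)
        + build_ass_events(models)
    )
    return sorted(events, key=SplicingEvent.sort_key)


# --------------------------------------------------------------------------
# catalog I/O: tab-separated, JSON-encoded junction sets, deterministic order

_CATALOG_COLUMNS = [
    "chrom",
    "start",
    "end",
    "event_id",
    "kind",
    "strand",
    "gene_id",
    "inclusion_junctions",
    "exclusion_junctions",
    "boundaries",
]


def _ivs_to_json(ivs: frozenset[GenomicInterval]) -> str:
    return json.dumps(sorted([iv.start, iv.end] for iv in ivs))


def _ivs_from_json(chrom: str, strand: str, text: str) -> frozenset[GenomicInterval]:
    return frozenset(
        GenomicInterval(chrom, int(s), int(e), strand) for s, e in json.loads(text)
    )


def write_event_catalog(events: Iterable[SplicingEvent], path) -> None:
    events = sorted(events, key=SplicingEvent.sort_key)
    ids = [e.event_id for e in events]
    if len(ids) != len(set(ids)):
        raise CatalogFormatError("duplicate event_id in catalog")
    with open(path, "w") as fh:
        fh.write("\t".join(_CATALOG_COLUMNS) + "\n")
        for ev in events:
            fh.write(
                "\t".join(
                    [
                        ev.chrom,
                        str(ev.core.start),
                        str(ev.core.end),
                        ev.event_id,
                        ev.kind,
                        ev.strand,
                        ev.gene_id,
                        _ivs_to_json(ev.inclusion_junctions),
                        _ivs_to_json(ev.exclusion_junctions),
                        json.dumps(list(ev.boundaries)),
                    ]
                )
                + "\n"
            )


def read_event_catalog(path) -> list[SplicingEvent]:
    events: list[SplicingEvent] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _CATALOG_COLUMNS:
            raise CatalogFormatError(f"unexpected catalog header in {path}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_CATALOG_COLUMNS):
                raise CatalogFormatError(f"{path}:{lineno}: wrong field count")
            chrom, start, end, event_id, kind, strand, gene_id, inc, exc, bnd = fields
            if kind not in EVENT_KINDS:
                raise CatalogFormatError(f"{path}:{lineno}: unknown kind {kind!r}")
            if event_id in seen_ids:
                raise CatalogFormatError(f"{path}:{lineno}: duplicate event_id {event_id}")
            seen_ids.add(event_id)
            events.append(
                SplicingEvent(
                    event_id=event_id,
                    kind=kind,
                    gene_id=gene_id,
                    core=GenomicInterval(chrom, int(start), int(end), strand),
                    inclusion_junctions=_ivs_from_json(chrom, strand, inc),
                    exclusion_junctions=_ivs_from_json(chrom, strand, exc),
                    boundaries=tuple(json.loads(bnd)),
                )
            )
    return events


def write_ri_bed(events: Iterable[SplicingEvent], path) -> None:
    """Plain BED6 export of RI intron coordinates."""
    with open(path, "w") as fh:
        for ev in sorted(events, key=SplicingEvent.sort_key):
            if ev.kind != "RI":
                continue
            fh.write(
                f"{ev.chrom}\t{ev.core.start}\t{ev.core.end}\t"
                f"{ev.event_id}\t0\t{ev.strand}\n"
            )


def events_by_id(events: Iterable[SplicingEvent]) -> dict[str, SplicingEvent]:
    return {e.event_id: e for e in events}


def iter_kind(events: Iterable[SplicingEvent], kind: str) -> Iterator[SplicingEvent]:
    return (e for e in events if e.kind == kind)
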