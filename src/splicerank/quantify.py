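"""PIR/PSI quantification from junction and boundary read evidence.

For a retained-intron (RI) event the retention level is

    PIR = mean(EI5, EI3) / (mean(EI5, EI3) + EE)

where EI5/EI3 count contiguous reads spanning the 5'/3' exon-intron
boundary and EE counts spliced reads whose skipped segment is exactly the
intron. The mean of the two boundary counts (rather than their sum) keeps
the two boundaries symmetric and the value in [0, 1]. Exon-centric events
(SE/MXE/A5SS/A3SS) use the analogous PSI with per-junction inclusion and
exclusion counts.

Counts can be supplied as a pre-tabulated long table (event_id, sample_id,
label, count) or tallied from a coordinate-sorted indexed BAM.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .events import SplicingEvent

COUNT_COLUMNS = ["event_id", "sample_id", "label", "count"]
RI_LABELS = ("EI5", "EI3", "EE")


@dataclass
class EventCounts:
    """Read evidence for one event in one sample.

    RI events use ``ei5``/``ei3``/``ee``; other kinds carry per-junction
    ``inclusion_reads``/``exclusion_reads`` keyed by junction label.
    """

    event_id: str
    sample_id: str
    ei5: int | None = None
    ei3: int | None = None
    ee: int | None = None
    inclusion_reads: dict[str, int] = field(default_factory=dict)
    exclusion_reads: dict[str, int] = field(default_factory=dict)

    def _validate(self, values) -> None:
        for v in values:
            if v is None or v < 0 or int(v) != v:
                raise ValueError(
                    f"counts for {self.event_id}/{self.sample_id} must be "
                    f"non-negative integers, got {v!r}"
                )


@dataclass
class InclusionRecord:
    """PIR or PSI for one event in one sample; ``value`` is NaN when the
    denominator coverage is zero."""

    event_id: str
    sample_id: str
    value: float
    coverage: float
    passed_filter: bool = False

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


def compute_pir(counts: EventCounts) -> InclusionRecord:
    """Percentage of intron retention from boundary and junction reads."""
    counts._validate([counts.ei5, counts.ei3, counts.ee])
    boundary = 0.5 * (counts.ei5 + counts.ei3)
    coverage = boundary + counts.ee
    value = boundary / coverage if coverage > 0 else float("nan")
    return InclusionRecord(counts.event_id, counts.sample_id, value, coverage)


def compute_psi(counts: EventCounts) -> InclusionRecord:
    """Percent spliced-in from inclusion/exclusion junction reads."""
    counts._validate(list(counts.inclusion_reads.values()))
    counts._validate(list(counts.exclusion_reads.values()))
    if not counts.inclusion_reads or not counts.exclusion_reads:
        raise ValueError(f"event {counts.event_id}: empty junction count set")
    inc = float(np.mean(list(counts.inclusion_reads.values())))
    exc = float(np.mean(list(counts.exclusion_reads.values())))
    coverage = inc + exc
    value = inc / coverage if coverage > 0 else float("nan")
    return InclusionRecord(counts.event_id, counts.sample_id, value, coverage)


# --------------------------------------------------------------------------
# vectorized table path

def build_inclusion_table(
    counts: pd.DataFrame, events: list[SplicingEvent]
) -> pd.DataFrame:
    """Inclusion table (event_id, sample_id, kind, value, coverage,
    passed_filter) from a long counts table."""
    if (counts["count"] < 0).any():
        raise ValueError("negative counts in counts table")
    kind_of = {e.event_id: e.kind for e in events}
    unknown = set(counts["event_id"]) - set(kind_of)
    if unknown:
        raise ValueError(f"counts reference unknown events, e.g. {sorted(unknown)[:3]}")

    df = counts.copy()
    df["kind"] = df["event_id"].map(kind_of)
    df["role"] = np.where(
        df["kind"] == "RI",
        df["label"].map({"EI5": "inc", "EI3": "inc", "EE": "exc"}),
        df["label"].str.split(":").str[0],
    )
    if df["role"].isna().any():
        bad = df.loc[df["role"].isna(), "label"].unique()[:3]
        raise ValueError(f"unrecognized count labels, e.g. {list(bad)}")
    agg = (
        df.groupby(["event_id", "sample_id", "kind", "role"])["count"]
        .mean()
        .unstack("role", fill_value=0.0)
        .reset_index()
    )
    for col in ("inc", "exc"):
        if col not in agg:
            agg[col] = 0.0
    agg["coverage"] = agg["inc"] + agg["exc"]
    with np.errstate(invalid="ignore"):
        agg["value"] = np.where(
            agg["coverage"] > 0, agg["inc"] / agg["coverage"], np.nan
        )
    agg["passed_filter"] = False
    out = agg[["event_id", "sample_id", "kind", "value", "coverage", "passed_filter"]]
    out.columns.name = None
    return out.sort_values(["event_id", "sample_id"], ignore_index=True)


def apply_coverage_filter(
    table: pd.DataFrame,
    groups: dict[str, list[str]],
    min_coverage: float = 10,
    min_samples: int | None = None,
) -> pd.DataFrame:
    """Set ``passed_filter`` per event.

    An event passes when its coverage is >= ``min_coverage`` (with a
    defined value) in at least ``min_samples`` samples of *every* group
    (default: all samples of every group).
    """
    table = table.copy()
    ok_row = (table["coverage"] >= min_coverage) & table["value"].notna()
    passed_events = None
    for group, samples in groups.items():
        sub = table[table["sample_id"].isin(samples)]
        need = len(samples) if min_samples is None else min(min_samples, len(samples))
        n_ok = ok_row[sub.index].groupby(sub["event_id"]).sum()
        ok_events = set(n_ok[n_ok >= need].index)
        passed_events = ok_events if passed_events is None else passed_events & ok_events
    table["passed_filter"] = table["event_id"].isin(passed_events or set())
    return table


# --------------------------------------------------------------------------
# BAM counting

def _junction_and_boundary_maps(events: list[SplicingEvent]):
    junctions: dict[tuple, list[tuple[str, str]]] = {}
    boundaries: dict[str, dict[int, list[tuple[str, str]]]] = {}
    for ev in events:
        if ev.kind == "RI":
            intron = ev.core
            junctions.setdefault((intron.chrom, intron.start, intron.end), []).append(
                (ev.event_id, "EE")
            )
            for pos, lab in zip(ev.boundaries, ("EI5", "EI3")):
                boundaries.setdefault(ev.chrom, {}).setdefault(pos, []).append(
                    (ev.event_id, lab)
                )
        else:
            for role, ivs in (
                ("inc", sorted(ev.inclusion_junctions)),
                ("exc", sorted(ev.exclusion_junctions)),
            ):
                for i, iv in enumerate(ivs):
                    junctions.setdefault((iv.chrom, iv.start, iv.end), []).append(
                        (ev.event_id, f"{role}:{i}")
                    )
    return junctions, boundaries


def _aligned_segments(read: pysam.AlignedSegment):
    """Maximal reference-contiguous aligned segments and the N-skips
    between them."""
    segments, skips = [], []
    pos = read.reference_start
    seg_start = pos
    open_seg = False
    for op, length in read.cigartuples:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference
            if not open_seg:
                seg_start = pos
                open_seg = True
            pos += length
        elif op == 3:  # N: splice
            if open_seg:
                segments.append((seg_start, pos))
                open_seg = False
            skips.append((pos, pos + length))
            pos += length
        # I, S, H, P consume no reference
    if open_seg:
        segments.append((seg_start, pos))
    return segments, skips


def count_event_reads(
    bam_path,
    events: list[SplicingEvent],
    sample_id: str,
    min_overhang: int = 8,
    min_mapq: int = 10,
) -> pd.DataFrame:
    """Tally junction and boundary evidence from an indexed BAM.

    A spliced read whose skipped segment exactly matches an event junction
    increments that junction's counter; a contiguous aligned segment with
    at least ``min_overhang`` aligned nt on each side of an exon-intron
    boundary increments EI5/EI3. Reads below ``min_mapq`` and secondary or
    supplementary alignments are ignored, and a read increments any given
    counter at most once; retention (EI) and splicing (EE) evidence from
    one read never both count for the same event.
    """
    junctions, boundaries = _junction_and_boundary_maps(events)
    sorted_bpos = {c: sorted(d) for c, d in boundaries.items()}

    tallies: dict[tuple[str, str], int] = {}
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if not bam.has_index():
            raise IOError(f"BAM index missing for {bam_path}")
        catalog_chroms = {e.chrom for e in events}
        missing = sorted(catalog_chroms - set(bam.references))
        if missing:
            raise ValueError(
                f"catalog chromosomes absent from BAM header: {missing}"
            )
        for chrom in sorted(catalog_chroms):
            bpos = sorted_bpos.get(chrom, [])
            bmap = boundaries.get(chrom, {})
            for read in bam.fetch(chrom):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.mapping_quality < min_mapq
                    or not read.cigartuples
                ):
                    continue
                segments, skips = _aligned_segments(read)
                hits: set[tuple[str, str]] = set()
                splice_hits: set[str] = set()
                for s, e in skips:
                    left_ok = any(
                        seg_e == s and seg_e - seg_s >= min_overhang
                        for seg_s, seg_e in segments
                    )
                    right_ok = any(
                        seg_s == e and seg_e - seg_s >= min_overhang
                        for seg_s, seg_e in segments
                    )
                    if not (left_ok and right_ok):
                        continue
                    for event_id, label in junctions.get((chrom, s, e), ()):
                        hits.add((event_id, label))
                        if label == "EE":
                            splice_hits.add(event_id)
                for seg_s, seg_e in segments:
                    lo = bisect_left(bpos, seg_s + min_overhang)
                    while lo < len(bpos) and bpos[lo] + min_overhang <= seg_e:
                        for event_id, label in bmap[bpos[lo]]:
                            if event_id not in splice_hits:
                                hits.add((event_id, label))
                        lo += 1
                for key in hits:
                    tallies[key] = tallies.get(key, 0) + 1

    rows = []
    for ev in events:
        labels: list[str]
        if ev.kind == "RI":
            labels = list(RI_LABELS)
        else:
            labels = [f"inc:{i}" for i in range(len(ev.inclusion_junctions))] + [
                f"exc:{i}" for i in range(len(ev.exclusion_junctions))
            ]
        for lab in labels:
            rows.append(
                (ev.event_id, sample_id, lab, tallies.get((ev.event_id, lab), 0))
            )
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"event_id": str, "sample_id": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table {path} missing columns {sorted(missing)}")
    return df


def write_inclusion_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_inclusion_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"event_id": str, "sample_id": str})
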