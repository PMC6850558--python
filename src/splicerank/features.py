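"""Sequence features of introns and retained-vs-background KS analysis.

Significantly retained introns are compared to a background set (introns
with |ΔPIR| < 0.05 and p > 0.05 in the same contrast) feature by feature
with two-sample Kolmogorov-Smirnov statistics, BH-adjusted across
features. The registry implements a documented subset of the classical
intron-retention feature catalog (GC content and GC differential,
lengths, splice-site strength, polypyrimidine tract, transcript
position); users can plug additional feature functions into
``FEATURE_REGISTRY``.

Splice-site strength is scored with log-odds position weight matrices
trained on all annotated introns of the supplied catalog (pseudocount 1,
uniform background), so the scores are deterministic functions of the
annotation and need no external model. The donor window is the last 3
exonic plus first 6 intronic nt; the acceptor window is the last 23
intronic nt ending at the 3' splice site. All sequences are
reverse-complemented for minus-strand introns before feature extraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from statsmodels.stats.multitest import multipletests

from .events import GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

DONOR_EXON_NT, DONOR_INTRON_NT = 3, 6
ACCEPTOR_NT = 23
PPT_WINDOW = 30

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# IUPAC fractional base composition: code -> probability vector over ACGT
_IUPAC: dict[str, np.ndarray] = {}
for code, bases in {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}.items():
    v = np.zeros(4)
    for b in bases:
        v["ACGT".index(b)] = 1.0 / len(bases)
    _IUPAC[code] = v


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


def _base_probs(seq: str) -> np.ndarray:
    """(len, 4) fractional base composition, IUPAC-aware."""
    out = np.zeros((len(seq), 4))
    for i, c in enumerate(seq.upper()):
        try:
            out[i] = _IUPAC[c]
        except KeyError:
            raise ValueError(f"unexpected base {c!r} in sequence") from None
    return out


def gc_fraction(seq: str) -> float:
    """GC fraction with IUPAC ambiguity codes counted fractionally."""
    if not seq:
        return float("nan")
    probs = _base_probs(seq)
    return float(probs[:, [1, 2]].sum() / len(seq))


def pyrimidine_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    probs = _base_probs(seq)
    return float(probs[:, [1, 3]].sum() / len(seq))


@dataclass
class PWM:
    """Log-odds position weight matrix over ACGT, uniform background."""

    log_odds: np.ndarray  # (width, 4), bits

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    def score(self, seq: str) -> float:
        """Expected log-odds score in bits; IUPAC codes contribute their
        fractional composition."""
        if len(seq) != self.width:
            raise ValueError(f"sequence length {len(seq)} != PWM width {self.width}")
        return float((_base_probs(seq) * self.log_odds).sum())

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @classmethod
    def train(cls, seqs: list[str], pseudocount: float = 1.0) -> "PWM":
        if not seqs:
            raise ValueError("cannot train a PWM on an empty sequence set")
        width = len(seqs[0])
        counts = np.full((width, 4), pseudocount)
        for s in seqs:
            if len(s) != width:
                raise ValueError("PWM training sequences must share one length")
            counts += _base_probs(s)
        freqs = counts / counts.sum(axis=1, keepdims=True)
        return cls(log_odds=np.log2(freqs / 0.25))


class GenomeSequence:
    """Minimal genome accessor: pyfaidx Fasta or an in-memory dict."""

    def __init__(self, source):
        self._src = source

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if start < 0:
            raise ValueError(f"interval {chrom}:{start}-{end} out of genome bounds")
        if isinstance(self._src, dict):
            seq = self._src[chrom]
            if end > len(seq):
                raise ValueError(f"interval {chrom}:{start}-{end} out of genome bounds")
            return seq[start:end].upper()
        rec = self._src[chrom]
        if end > len(rec):
            raise ValueError(f"interval {chrom}:{start}-{end} out of genome bounds")
        return str(rec[start:end]).upper()


@dataclass
class IntronContext:
    """Strand-oriented sequences and metadata for one annotated intron."""

    intron: GenomicInterval
    intron_seq: str  # 5'->3' on the transcript strand
    exon5_seq: str
    exon3_seq: str
    donor_window: str
    acceptor_window: str
    relative_position: float  # 0 at transcript 5' end, 1 at 3' end


def _intron_context(
    intron: GenomicInterval,
    exon_up: GenomicInterval,
    exon_down: GenomicInterval,
    index: int,
    n_introns: int,
    genome: GenomeSequence,
) -> IntronContext:
    chrom = intron.chrom
    iseq = genome.fetch(chrom, intron.start, intron.end)
    useq = genome.fetch(chrom, exon_up.start, exon_up.end)
    dseq = genome.fetch(chrom, exon_down.start, exon_down.end)
    if intron.strand == "+":
        exon5, exon3 = useq, dseq
        rel = index / max(n_introns - 1, 1)
    else:
        iseq = revcomp(iseq)
        exon5, exon3 = revcomp(dseq), revcomp(useq)
        rel = (n_introns - 1 - index) / max(n_introns - 1, 1)
    donor = exon5[-DONOR_EXON_NT:] + iseq[:DONOR_INTRON_NT]
    acceptor = iseq[-ACCEPTOR_NT:]
    return IntronContext(
        intron=intron,
        intron_seq=iseq,
        exon5_seq=exon5,
        exon3_seq=exon3,
        donor_window=donor if len(donor) == DONOR_EXON_NT + DONOR_INTRON_NT else "",
        acceptor_window=acceptor if len(acceptor) == ACCEPTOR_NT else "",
        relative_position=rel,
    )


FEATURE_REGISTRY: dict = {
    "intron_gc": lambda ctx, pwms: gc_fraction(ctx.intron_seq),
    "exon5_gc": lambda ctx, pwms: gc_fraction(ctx.exon5_seq),
    "exon3_gc": lambda ctx, pwms: gc_fraction(ctx.exon3_seq),
    "gc_differential": lambda ctx, pwms: gc_fraction(ctx.intron_seq)
    - 0.5 * (gc_fraction(ctx.exon5_seq) + gc_fraction(ctx.exon3_seq)),
    "intron_length_log10": lambda ctx, pwms: math.log10(len(ctx.intron_seq)),
    "exon5_length_log10": lambda ctx, pwms: math.log10(len(ctx.exon5_seq)),
    "exon3_length_log10": lambda ctx, pwms: math.log10(len(ctx.exon3_seq)),
    "donor_score": lambda ctx, pwms: (
        pwms["donor"].score(ctx.donor_window) if ctx.donor_window else float("nan")
    ),
    "acceptor_score": lambda ctx, pwms: (
        pwms["acceptor"].score(ctx.acceptor_window)
        if ctx.acceptor_window
        else float("nan")
    ),
    "polypyrimidine_frac": lambda ctx, pwms: pyrimidine_fraction(
        ctx.intron_seq[-PPT_WINDOW:]
    ),
    "relative_position": lambda ctx, pwms: ctx.relative_position,
}


def intron_contexts(
    models: list[TranscriptModel], genome: GenomeSequence
) -> dict[GenomicInterval, IntronContext]:
    """One strand-oriented context per distinct annotated intron."""
    contexts: dict[GenomicInterval, IntronContext] = {}
    for m in models:
        introns = m.introns
        n = len(introns)
        for i, intron in enumerate(introns):
            if intron in contexts:
                continue
            contexts[intron] = _intron_context(
                intron, m.exons[i], m.exons[i + 1], i, n, genome
            )
    return contexts


def train_splice_pwms(
    contexts: dict[GenomicInterval, IntronContext], pseudocount: float = 1.0
) -> dict[str, PWM]:
    donors = [c.donor_window for c in contexts.values() if c.donor_window]
    acceptors = [c.acceptor_window for c in contexts.values() if c.acceptor_window]
    return {
        "donor": PWM.train(donors, pseudocount),
        "acceptor": PWM.train(acceptors, pseudocount),
    }


def compute_features(
    introns: list[GenomicInterval],
    genome: GenomeSequence,
    models: list[TranscriptModel],
    registry: dict | None = None,
) -> pd.DataFrame:
    """Feature matrix (introns x features) for the requested introns.

    PWMs are trained once from *all* annotated introns of the catalog, so
    scores are comparable between any intron subsets.
    """
    registry = registry or FEATURE_REGISTRY
    contexts = intron_contexts(models, genome)
    pwms = train_splice_pwms(contexts)
    rows = {}
    for intron in introns:
        if intron not in contexts:
            raise KeyError(f"intron {intron} not present in the annotation")
        ctx = contexts[intron]
        rows[f"{intron.chrom}:{intron.start}-{intron.end}:{intron.strand}"] = {
            name: fn(ctx, pwms) for name, fn in registry.items()
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "intron_id"
    return df


def select_background(
    results: pd.DataFrame,
    delta_max: float = 0.05,
    p_min: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Split RI results into (retained, background) event-id sets.

    Retained: events called significant in the increased direction.
    Background: events with |mean ΔPIR| < delta_max and p > p_min in the
    increased direction.
    """
    inc = results[results["direction"] == "increased"]
    if "kind" in inc.columns:
        inc = inc[inc["kind"] == "RI"]
    retained = sorted(inc.loc[inc["significant"], "event_id"])
    bg_mask = (inc["mean_delta"].abs() < delta_max) & (inc["p"] > p_min)
    background = sorted(inc.loc[bg_mask & ~inc["significant"], "event_id"])
    if not background:
        raise ValueError("empty background set; feature comparison is not meaningful")
    return retained, background


def ks_compare(retained: pd.DataFrame, background: pd.DataFrame) -> pd.DataFrame:
    """Two-sample KS statistic per feature, BH-adjusted across features.

    ``shift_sign`` is +1 when the retained distribution is stochastically
    larger (higher median). Features that are entirely missing in either
    set are dropped with a warning. Result is sorted by D descending.
    """
    if retained.empty or background.empty:
        raise ValueError("both feature sets must be non-empty")
    if set(retained.columns) != set(background.columns):
        raise ValueError("feature registries of the two sets differ")
    rows = []
    for feat in retained.columns:
        x = retained[feat].dropna().to_numpy()
        y = background[feat].dropna().to_numpy()
        if x.size == 0 or y.size == 0:
            logger.warning("feature %s has no defined values; dropped", feat)
            continue
        res = ks_2samp(x, y, method="auto")
        sign = 1 if np.median(x) >= np.median(y) else -1
        rows.append((feat, float(res.statistic), float(res.pvalue), sign))
    out = pd.DataFrame(rows, columns=["feature", "D", "p", "shift_sign"])
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    out = out[["feature", "D", "p", "p_adj", "shift_sign"]]
    return out.sort_values(["D", "feature"], ascending=[False, True], ignore_index=True)
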