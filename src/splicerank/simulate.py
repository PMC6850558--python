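"""Synthetic annotation, genome and count generator.

Emulates the data structure behind a two-condition replicate RNA-seq
intron-retention study so that every pipeline stage is testable without
external data:

* multi-exon genes on one synthetic chromosome, canonical GT..AG splice
  sites, per-intron GC drawn around a genomic baseline with an optional
  GC offset for "affected" introns (the feature signal);
* per-event junction evidence with negative-binomial depth
  (variance = m + dispersion * m^2) and binomial splitting between
  retention and splicing evidence at each intron's true PIR, with the
  affected introns shifted by ``delta_pir_effect`` in group A only (the
  directional-asymmetry signal). Each exon-intron boundary is sampled at
  the full local depth, which is what makes the mean-boundary PIR
  estimator consistent;
* gene counts with log-normal biological variability and an expression
  decrease of ``nmd_coupling`` log2 units for genes carrying an affected
  intron (the retention-expression coupling signal).

Everything is deterministic given ``seed``. A truth table records the
per-event true PIR by group and the affected flags, so sensitivity and
empirical FDR of the downstream test are exactly computable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .events import GenomicInterval, SplicingEvent, TranscriptModel
from .quantify import COUNT_COLUMNS


@dataclass
class SimConfig:
    """Study conditions for the generator (defaults are the conditions
    the package's validation suite runs under; see docs/methods.md)."""

    n_genes: int = 450
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_len: tuple[int, int] = (80, 300)
    intron_len: tuple[int, int] = (100, 1500)
    n_replicates: int = 3
    depth_mean: float = 50.0
    dispersion: float = 0.1
    pir_baseline: tuple[float, float] = (2.0, 18.0)  # Beta(a, b), mean 0.1
    psi_baseline: tuple[float, float] = (8.0, 2.0)
    affected_fraction: float = 0.1
    delta_pir_effect: float = 0.3
    symmetric_effects: bool = False
    gc_shift: float = 0.10
    base_gc: float = 0.42
    gc_sd: float = 0.05
    exon_gc: float = 0.50
    nmd_coupling: float = 1.0
    expr_noise_sd: float = 1.0  # per-gene log2FC biological noise
    gene_depth_mean: float = 200.0
    gene_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("affected_fraction", "gc_shift", "base_gc", "exon_gc"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_mean <= 0 or self.gene_depth_mean <= 0:
            raise ValueError("depth means must be positive")
        if self.dispersion < 0 or self.gene_dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        for name in ("exons_per_gene", "exon_len", "intron_len"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"infeasible range for {name}: ({lo}, {hi})")
        if self.exons_per_gene[0] < 2:
            raise ValueError("genes need at least two exons to carry introns")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("exons_per_gene", "exon_len", "intron_len", "pir_baseline",
                    "psi_baseline"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=list)


@dataclass
class SimAnnotation:
    """Generated annotation plus the per-intron ground truth."""

    models: list[TranscriptModel]
    genome: dict[str, str]
    affected_introns: set[GenomicInterval]
    intron_gene: dict[GenomicInterval, str] = field(default_factory=dict)

    @property
    def introns(self) -> list[GenomicInterval]:
        seen = []
        for m in self.models:
            seen.extend(m.introns)
        return sorted(set(seen))


def _nb(rng: np.random.Generator, mean, dispersion: float, size=None) -> np.ndarray:
    """Negative binomial with variance = mean + dispersion * mean^2;
    Poisson when dispersion is zero."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def simulate_annotation(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SimAnnotation:
    """Generate transcript models and genome sequence on one synthetic
    chromosome, marking ``affected_fraction`` of introns as affected and
    offsetting their GC content by ``gc_shift``."""
    rng = rng or np.random.default_rng(config.seed)
    chrom = "chrS1"
    pieces: list[str] = []
    pos = 0
    models: list[TranscriptModel] = []
    affected: set[GenomicInterval] = set()
    intron_gene: dict[GenomicInterval, str] = {}

    spacer = 200
    for g in range(config.n_genes):
        gene_id = f"G{g:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        pieces.append(_random_seq(rng, spacer, config.base_gc))
        pos += spacer
        exons: list[GenomicInterval] = []
        for i in range(n_exons):
            elen = int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
            exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
            pieces.append(_random_seq(rng, elen, config.exon_gc))
            pos += elen
            if i == n_exons - 1:
                break
            ilen = int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
            intron = GenomicInterval(chrom, pos, pos + ilen, strand)
            is_affected = rng.random() < config.affected_fraction
            gc = float(
                np.clip(
                    rng.normal(config.base_gc, config.gc_sd)
                    + (config.gc_shift if is_affected else 0.0),
                    0.2,
                    0.8,
                )
            )
            seq = list(_random_seq(rng, ilen, gc))
            # canonical splice dinucleotides, strand-oriented
            if strand == "+":
                seq[0:2] = "GT"
                seq[-2:] = "AG"
            else:
                seq[0:2] = "CT"
                seq[-2:] = "AC"
            pieces.append("".join(seq))
            pos += ilen
            if is_affected:
                affected.add(intron)
            intron_gene[intron] = gene_id
        models.append(
            TranscriptModel(transcript_id=f"{gene_id}.t1", gene_id=gene_id, exons=exons)
        )
    genome = {chrom: "".join(pieces)}
    return SimAnnotation(
        models=models, genome=genome, affected_introns=affected,
        intron_gene=intron_gene,
    )


def simulate_counts(
    events: list[SplicingEvent],
    sim: SimAnnotation,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Junction/boundary counts per event and sample, plus the truth
    table.

    RI events: each sample draws a local depth T ~ NB(depth_mean,
    dispersion); both exon-intron boundaries are sampled at that depth
    (EI5, EI3 ~ Binomial(T, PIR)) and the exon-exon junction at the
    complementary rate (EE ~ Binomial(T, 1 - PIR)). Affected introns get
    ``delta_pir_effect`` added to their true PIR in group A (subtracted
    for half of them when ``symmetric_effects``). Other event kinds draw
    a stable PSI from ``psi_baseline`` with no group effect.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n = config.n_replicates
    samples_a = [f"A{i+1}" for i in range(n)]
    samples_b = [f"B{i+1}" for i in range(n)]

    rows: list[tuple] = []
    truth_rows: list[tuple] = []
    a, b = config.pir_baseline
    for ev in sorted(events, key=SplicingEvent.sort_key):
        if ev.kind == "RI":
            base = float(rng.beta(a, b))
            is_affected = ev.core in sim.affected_introns
            effect = config.delta_pir_effect if is_affected else 0.0
            if is_affected and config.symmetric_effects and rng.random() < 0.5:
                effect = -effect
            pir_a = float(np.clip(base + effect, 0.0, 1.0))
            pir_b = base
            for sample, pir in [(s, pir_a) for s in samples_a] + [
                (s, pir_b) for s in samples_b
            ]:
                t = int(_nb(rng, config.depth_mean, config.dispersion))
                ei5 = int(rng.binomial(t, pir))
                ei3 = int(rng.binomial(t, pir))
                ee = int(rng.binomial(t, 1.0 - pir))
                rows += [
                    (ev.event_id, sample, "EI5", ei5),
                    (ev.event_id, sample, "EI3", ei3),
                    (ev.event_id, sample, "EE", ee),
                ]
            truth_rows.append(
                (ev.event_id, ev.gene_id, "RI", is_affected, pir_a, pir_b)
            )
        else:
            psi = float(rng.beta(*config.psi_baseline))
            n_inc = len(ev.inclusion_junctions)
            n_exc = len(ev.exclusion_junctions)
            for sample in samples_a + samples_b:
                t = int(_nb(rng, config.depth_mean, config.dispersion))
                for i in range(n_inc):
                    rows.append(
                        (ev.event_id, sample, f"inc:{i}", int(rng.binomial(t, psi)))
                    )
                for i in range(n_exc):
                    rows.append(
                        (ev.event_id, sample, f"exc:{i}", int(rng.binomial(t, 1 - psi)))
                    )
            truth_rows.append((ev.event_id, ev.gene_id, ev.kind, False, psi, psi))

    counts = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    truth = pd.DataFrame(
        truth_rows,
        columns=["event_id", "gene_id", "kind", "affected", "true_value_a",
                 "true_value_b"],
    )
    return counts, truth


def simulate_gene_counts(
    genes: list[str],
    affected_genes: set[str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Gene x sample count table with NMD-like coupling.

    Per-gene baseline log2 expression is Normal around
    log2(gene_depth_mean); group A means are shifted by -nmd_coupling for
    genes carrying an affected intron. Per-sample biological noise is
    scaled so the resulting log2 fold change has standard deviation about
    ``expr_noise_sd`` at the configured replicate number.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    n = config.n_replicates
    samples = [f"A{i+1}" for i in range(n)] + [f"B{i+1}" for i in range(n)]
    base = rng.normal(np.log2(config.gene_depth_mean), 1.0, size=len(genes))
    shift = np.array([config.nmd_coupling if g in affected_genes else 0.0 for g in genes])
    sample_sd = config.expr_noise_sd * np.sqrt(n / 2.0)
    data = {}
    for j, sample in enumerate(samples):
        group_a = j < n
        log2_mu = base - (shift if group_a else 0.0) + rng.normal(
            0.0, sample_sd, size=len(genes)
        )
        data[sample] = _nb(rng, 2.0 ** log2_mu, config.gene_dispersion)
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))


def sample_sheet(config: SimConfig) -> pd.DataFrame:
    n = config.n_replicates
    return pd.DataFrame(
        {
            "sample_id": [f"A{i+1}" for i in range(n)] + [f"B{i+1}" for i in range(n)],
            "group": ["A"] * n + ["B"] * n,
        }
    )


def affected_gene_set(sim: SimAnnotation) -> set[str]:
    return {sim.intron_gene[i] for i in sim.affected_introns}
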