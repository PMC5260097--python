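"""Synthetic multi-gene, multi-isoform RNA-seq data with known truth.

The simulator lays out a small artificial single-chromosome genome of
multi-exon genes separated by explicit intergenic gaps (both below and
above the 50 bp bundle-merging threshold, so bundle behaviour on both
sides of the boundary is exercised).  Each gene carries several isoforms
sharing its exon skeleton; paired-end fragments are sampled uniformly
along each isoform's mature sequence with normally distributed lengths,
projected across exon junctions to genomic blocks, and written as a
coordinate-sorted, indexed BAM together with a GTF annotation and a truth
table of per-isoform fragment counts and FPKMs.

Everything is driven by a single mandatory seed; the same configuration
and seed reproduce every output byte for byte.  Sequence content is
irrelevant to quantification, so reads carry placeholder bases and
qualities of the correct length.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .errors import ConfigError
from .model import Annotation, GenomeInterval, TranscriptModel, write_gtf

__all__ = ["SimConfig", "SimResult", "simulate", "holdout_protocol"]


@dataclass
class SimConfig:
    """Study conditions for one simulated sample.

    Defaults describe a 20-gene, ~60-isoform locus set with 200,000
    paired-end fragments of length N(200, 50) at read length 75 — large
    enough that shared-exon ambiguity, bundle merging on both sides of the
    50 bp rule, and depth-dependent recovery are all represented.
    """

    seed: int
    n_genes: int = 20
    isoforms_per_gene: Tuple[int, int] = (2, 4)  # inclusive range
    exons_per_gene: Tuple[int, int] = (4, 8)  # inclusive range
    exon_len: Tuple[int, int] = (100, 400)
    intron_len: Tuple[int, int] = (80, 400)
    intergenic_gaps: Tuple[int, ...] = (10, 30, 60, 120, 200, 1000)
    abundances: Optional[Dict[str, float]] = None  # isoform -> relative weight
    frag_len_mean: float = 200.0
    frag_len_sd: float = 50.0
    read_len: int = 75
    n_fragments: int = 200_000
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for name in ("isoforms_per_gene", "exons_per_gene", "exon_len", "intron_len"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigError(f"bad range {name}={getattr(self, name)}")
        if not (
            any(g <= 50 for g in self.intergenic_gaps)
            and any(g > 50 for g in self.intergenic_gaps)
        ):
            raise ConfigError(
                "intergenic_gaps must include values on both sides of 50 bp"
            )
        if self.read_len < 1 or self.n_fragments < 0 or self.n_genes < 1:
            raise ConfigError("read_len, n_fragments, n_genes must be positive")
        if self.exon_len[0] < 1:
            raise ConfigError("exon lengths must be >= 1")


@dataclass
class SimResult:
    """Paths and in-memory objects produced by :func:`simulate`."""

    annotation_path: str
    alignment_path: str
    truth_path: str
    config_path: str
    annotation: Annotation
    truth: pd.DataFrame  # per-transcript truth table


def _build_annotation(cfg: SimConfig, rng: np.random.Generator) -> Tuple[Annotation, Dict[str, int]]:
    """Lay out genes left to right; return annotation + transcript locus ids."""
    txs: List[TranscriptModel] = []
    locus_of: Dict[str, int] = {}
    cursor = 1000
    gaps = list(cfg.intergenic_gaps)
    for g in range(cfg.n_genes):
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exon_lens = rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1, size=n_ex)
        intron_lens = rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1, size=max(0, n_ex - 1))
        exons: List[GenomeInterval] = []
        pos = cursor
        for i, el in enumerate(exon_lens):
            exons.append(GenomeInterval(cfg.chrom, pos, pos + int(el)))
            pos += int(el)
            if i < n_ex - 1:
                pos += int(intron_lens[i])
        gene_id = f"G{g:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_iso = int(
            rng.integers(cfg.isoforms_per_gene[0], cfg.isoforms_per_gene[1] + 1)
        )
        chosen: List[Tuple[int, ...]] = [tuple(range(n_ex))]  # full-length isoform
        attempts = 0
        while len(chosen) < n_iso and attempts < 50:
            attempts += 1
            keep = [0] + [
                i for i in range(1, n_ex - 1) if rng.random() < 0.7
            ] + [n_ex - 1]
            key = tuple(dict.fromkeys(keep))
            if key not in chosen:
                chosen.append(key)
        for k, subset in enumerate(chosen):
            tid = f"{gene_id}.T{k}"
            txs.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene_id,
                    chrom=cfg.chrom,
                    strand=strand,
                    exons=tuple(exons[i] for i in subset),
                )
            )
            locus_of[tid] = g
        cursor = exons[-1].end + gaps[g % len(gaps)]
    return Annotation.from_transcripts(txs), locus_of


def _effective_length(length: int, mean: float) -> int:
    return max(1, length - int(round(mean)) + 1)


def _make_read_pair(
    header: pysam.AlignmentHeader,
    qname: str,
    tx: TranscriptModel,
    mstart: int,
    fraglen: int,
    read_len: int,
) -> Tuple[pysam.AlignedSegment, pysam.AlignedSegment]:
    """Project a mature-coordinate fragment to a properly paired read pair."""
    rl = min(read_len, fraglen)
    m1 = tx.transcript_to_genome_blocks(mstart, mstart + rl)
    m2 = tx.transcript_to_genome_blocks(mstart + fraglen - rl, mstart + fraglen)

    def seg(blocks, read1: bool, mate_blocks) -> pysam.AlignedSegment:
        a = pysam.AlignedSegment(header)
        a.query_name = qname
        a.reference_id = 0
        a.reference_start = blocks[0][0]
        a.mapping_quality = 60
        cig = []
        for i, (s, e) in enumerate(blocks):
            if i > 0:
                cig.append((3, s - blocks[i - 1][1]))  # N
            cig.append((0, e - s))  # M
        a.cigartuples = cig
        a.flag = (
            0x1 | 0x2 | (0x40 if read1 else 0x80) | (0x20 if read1 else 0x10)
        )
        a.next_reference_id = 0
        a.next_reference_start = mate_blocks[0][0]
        span_lo = min(blocks[0][0], mate_blocks[0][0])
        span_hi = max(blocks[-1][1], mate_blocks[-1][1])
        a.template_length = (span_hi - span_lo) if read1 else -(span_hi - span_lo)
        a.query_sequence = "A" * rl
        a.query_qualities = pysam.qualitystring_to_array("I" * rl)
        return a

    return seg(m1, True, m2), seg(m2, False, m1)


def simulate(config: SimConfig, outdir: str) -> SimResult:
    """Generate annotation, sorted+indexed BAM, truth table, config echo."""
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    annotation, locus_of = _build_annotation(config, rng)

    ordered = sorted(annotation.transcripts.values(), key=lambda t: t.transcript_id)
    lengths = np.array([tx.length for tx in ordered])
    min_len = int(lengths.min())
    if min_len < config.read_len:
        raise ConfigError(
            f"isoform of length {min_len} shorter than read length {config.read_len}"
        )
    eff = np.array(
        [_effective_length(tx.length, config.frag_len_mean) for tx in ordered],
        dtype=float,
    )
    if config.abundances is not None:
        rho = np.array([config.abundances.get(tx.transcript_id, 0.0) for tx in ordered])
        if rho.sum() <= 0:
            raise ConfigError("abundances sum to zero over simulated isoforms")
    else:
        rho = rng.lognormal(mean=0.0, sigma=1.0, size=len(ordered))
    p = rho * eff
    p = p / p.sum()
    counts = (
        rng.multinomial(config.n_fragments, p)
        if config.n_fragments > 0
        else np.zeros(len(ordered), dtype=int)
    )

    genome_len = max(tx.span.end for tx in ordered) + 1000
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": config.chrom, "LN": int(genome_len)}],
        }
    )

    records: List[pysam.AlignedSegment] = []
    frag_no = 0
    for tx, n in zip(ordered, counts):
        if n == 0:
            continue
        L = tx.length
        flens = np.rint(
            rng.normal(config.frag_len_mean, config.frag_len_sd, size=n)
        ).astype(int)
        flens = np.clip(flens, config.read_len, L)
        starts = rng.integers(0, L - flens + 1)
        for fl, st in zip(flens, starts):
            qname = f"frag{frag_no:07d}"
            frag_no += 1
            r1, r2 = _make_read_pair(
                header, qname, tx, int(st), int(fl), config.read_len
            )
            records.append(r1)
            records.append(r2)

    # sort in memory and write directly: keeps output bytes a pure function
    # of the records (an external sort would inject @PG provenance lines)
    records.sort(key=lambda a: (a.reference_start, a.query_name, a.flag))
    bam_path = os.path.join(outdir, "sample.bam")
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bf:
        for a in records:
            bf.write(a)
    pysam.index(bam_path)

    gtf_path = os.path.join(outdir, "annotation.gtf")
    write_gtf(annotation, gtf_path)

    n_total = int(counts.sum())
    truth = pd.DataFrame(
        {
            "transcript_id": [tx.transcript_id for tx in ordered],
            "gene_id": [tx.gene_id for tx in ordered],
            "locus": [locus_of[tx.transcript_id] for tx in ordered],
            "length": lengths,
            "effective_length": eff.astype(int),
            "true_count": counts,
            "true_fpkm": [
                (c / ((e / 1000.0) * (n_total / 1e6)) if n_total > 0 else 0.0)
                for c, e in zip(counts, eff)
            ],
        }
    )
    truth_path = os.path.join(outdir, "truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)

    config_path = os.path.join(outdir, "config.json")
    with open(config_path, "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")

    return SimResult(
        annotation_path=gtf_path,
        alignment_path=bam_path,
        truth_path=truth_path,
        config_path=config_path,
        annotation=annotation,
        truth=truth,
    )


def holdout_protocol(
    annotation: Annotation, k: int, seed: int
) -> Tuple[Annotation, List[TranscriptModel]]:
    """Remove k random transcripts from the reference to act as novel queries.

    Returns (reduced annotation, held-out transcripts).  Selection is
    uniform without replacement and fully determined by ``seed``.
    """
    ids = sorted(annotation.transcripts)
    if k >= len(ids):
        raise ValueError(f"k={k} must be < number of transcripts ({len(ids)})")
    rng = np.random.default_rng(seed)
    held = sorted(rng.choice(ids, size=k, replace=False).tolist())
    reduced = annotation.without(held)
    return reduced, [annotation[tid] for tid in held]
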