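"""Shared fixtures and small constructors for the test suite."""

import numpy as np
import pysam
import pytest

from locquant import (
    AlignedFragment,
    Annotation,
    GenomeInterval,
    SimConfig,
    TranscriptModel,
    simulate,
)


def make_tx(tid, exons, gene=None, chrom="chr1", strand="+"):
    """Build a TranscriptModel from (start, end) exon pairs."""
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene or f"gene_{tid}",
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomeInterval(chrom, s, e) for s, e in exons),
    )


def make_frag(fid, blocks, introns=(), chrom="chr1", paired=False):
    return AlignedFragment(
        fragment_id=fid,
        chrom=chrom,
        blocks=tuple(GenomeInterval(chrom, s, e) for s, e in blocks),
        introns=tuple(GenomeInterval(chrom, s, e) for s, e in introns),
        paired=paired,
    )


def write_bam(path, records, chrom="chr1", length=1_000_000):
    """Write pre-built (qname, flag, pos, cigar, mpos) tuples as a sorted BAM.

    ``records`` entries: (qname, flag, pos, cigartuples, next_pos, tlen).
    """
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": length}]}
    )
    segs = []
    for qname, flag, pos, cigar, next_pos, tlen in records:
        a = pysam.AlignedSegment(header)
        a.query_name = qname
        a.flag = flag
        a.reference_id = 0
        a.reference_start = pos
        a.mapping_quality = 60
        a.cigartuples = cigar
        a.next_reference_id = 0 if next_pos is not None else -1
        a.next_reference_start = next_pos if next_pos is not None else -1
        a.template_length = tlen
        rlen = sum(ln for op, ln in cigar if op in (0, 7, 8, 1))
        a.query_sequence = "A" * rlen
        a.query_qualities = pysam.qualitystring_to_array("I" * rlen)
        segs.append(a)
    segs.sort(key=lambda a: (a.reference_start, a.query_name, a.flag))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bf:
        for a in segs:
            bf.write(a)
    pysam.index(str(path))
    return str(path)


SMALL_CONFIG = dict(n_genes=5, n_fragments=5000)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A 5-gene, 5000-fragment sample shared by read-only tests."""
    outdir = tmp_path_factory.mktemp("small_sim")
    return simulate(SimConfig(seed=42, **SMALL_CONFIG), str(outdir))
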