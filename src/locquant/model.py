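"""Core domain types and I/O for gene annotations and read alignments.

Coordinate convention
---------------------
All coordinates inside the package are 0-based half-open ``[start, end)``,
the convention of BAM and BED.  GTF is 1-based fully-closed; :func:`read_gtf`
and :func:`write_gtf` convert at the boundary and nowhere else.

Counting unit
-------------
The unit of counting is the *fragment* (one sequenced cDNA insert — both
mates of a pair together), matching the F in FPKM.  :func:`fetch_fragments`
collapses mate pairs by query name, so a properly paired read pair yields a
single :class:`AlignedFragment`, and an unpaired read yields a single-mate
fragment.  Only primary alignments are counted; strand is ignored for
counting (unstranded protocol assumed).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pysam

from .errors import GtfParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeInterval",
    "TranscriptModel",
    "AlignedFragment",
    "Annotation",
    "read_gtf",
    "write_gtf",
    "fetch_fragments",
]


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if not self.start < self.end:
            raise ValidationError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def _check_exons(chrom: str, exons: Sequence[GenomeInterval], owner: str) -> None:
    if not exons:
        raise ValidationError(f"transcript {owner!r} has no exons")
    for ex in exons:
        if ex.chrom != chrom:
            raise ValidationError(
                f"transcript {owner!r}: exon on {ex.chrom}, transcript on {chrom}"
            )
    for a, b in zip(exons, exons[1:]):
        if b.start < a.end:
            raise ValidationError(
                f"transcript {owner!r}: exons [{a.start},{a.end}) and "
                f"[{b.start},{b.end}) overlap or are unsorted"
            )


@dataclass
class TranscriptModel:
    """An exon chain with gene/transcript identity on a strand.

    Exons are sorted by start and pairwise non-overlapping; the transcript
    span is the interval from the first exon start to the last exon end.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[GenomeInterval, ...]

    def __post_init__(self) -> None:
        self.exons = tuple(self.exons)
        if self.strand not in ("+", "-", "."):
            raise ValidationError(
                f"transcript {self.transcript_id!r}: bad strand {self.strand!r}"
            )
        _check_exons(self.chrom, self.exons, self.transcript_id)

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.exons[0].start, self.exons[-1].end)

    @property
    def length(self) -> int:
        """Mature (spliced) length in bp."""
        return sum(e.length for e in self.exons)

    @property
    def introns(self) -> Tuple[GenomeInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomeInterval(self.chrom, a.end, b.start))
        return tuple(out)

    # -- mature <-> genome projection ------------------------------------

    def genome_to_transcript(self, gpos: int) -> int:
        """Map a genomic position lying within an exon to mature coordinates.

        Mature coordinates run 5'->3' along the genome (strand is not
        flipped; only relative distances are used downstream).
        """
        off = 0
        for ex in self.exons:
            if ex.start <= gpos < ex.end:
                return off + (gpos - ex.start)
            off += ex.length
        raise ValueError(
            f"position {gpos} not exonic in transcript {self.transcript_id}"
        )

    def transcript_to_genome_blocks(self, tstart: int, tend: int) -> List[Tuple[int, int]]:
        """Project a mature interval [tstart, tend) to genomic blocks."""
        if not (0 <= tstart < tend <= self.length):
            raise ValueError(
                f"mature interval [{tstart},{tend}) outside transcript of "
                f"length {self.length}"
            )
        blocks: List[Tuple[int, int]] = []
        off = 0
        for ex in self.exons:
            lo = max(tstart, off)
            hi = min(tend, off + ex.length)
            if lo < hi:
                blocks.append((ex.start + (lo - off), ex.start + (hi - off)))
            off += ex.length
        return blocks

    def implied_mature_length(self, span: GenomeInterval) -> Optional[int]:
        """Length on the mature sequence implied by a genomic span.

        Returns None when either endpoint is not exonic.
        """
        try:
            t0 = self.genome_to_transcript(span.start)
            t1 = self.genome_to_transcript(span.end - 1) + 1
        except ValueError:
            return None
        return t1 - t0


@dataclass
class AlignedFragment:
    """One sequenced fragment's aligned footprint (mates collapsed).

    ``blocks`` is the union of the aligned blocks of both mates (merged
    where overlapping or abutting); ``introns`` are gaps signalled as splices
    (N CIGAR) within either mate.  The unsequenced inner gap between mates is
    *not* an intron.  A fragment is counted once regardless of mate count.
    """

    fragment_id: str
    chrom: str
    blocks: Tuple[GenomeInterval, ...]
    introns: Tuple[GenomeInterval, ...] = ()
    paired: bool = False

    def __post_init__(self) -> None:
        self.blocks = tuple(self.blocks)
        self.introns = tuple(self.introns)
        if not self.blocks:
            raise ValidationError(f"fragment {self.fragment_id!r} has no blocks")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"fragment {self.fragment_id!r}: blocks unsorted/overlapping"
                )

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.blocks[0].start, self.blocks[-1].end)

    @property
    def aligned_bases(self) -> int:
        return sum(b.length for b in self.blocks)


@dataclass
class Annotation:
    """A collection of transcript models grouped by gene."""

    transcripts: Dict[str, TranscriptModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, tx in self.transcripts.items():
            if tx.transcript_id != tid:
                raise ValidationError(f"key {tid!r} != transcript_id {tx.transcript_id!r}")

    @classmethod
    def from_transcripts(cls, txs: Iterable[TranscriptModel]) -> "Annotation":
        d: Dict[str, TranscriptModel] = {}
        for tx in txs:
            if tx.transcript_id in d:
                raise ValidationError(f"duplicate transcript_id {tx.transcript_id!r}")
            d[tx.transcript_id] = tx
        return cls(d)

    @property
    def genes(self) -> Dict[str, List[str]]:
        g: Dict[str, List[str]] = {}
        for tx in self._ordered():
            g.setdefault(tx.gene_id, []).append(tx.transcript_id)
        return g

    def _ordered(self) -> List[TranscriptModel]:
        return sorted(
            self.transcripts.values(),
            key=lambda t: (t.chrom, t.span.start, t.span.end, t.transcript_id),
        )

    def __len__(self) -> int:
        return len(self.transcripts)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Annotation):
            return NotImplemented
        return self.transcripts == other.transcripts

    def chroms(self) -> List[str]:
        return sorted({tx.chrom for tx in self.transcripts.values()})

    def without(self, transcript_ids: Iterable[str]) -> "Annotation":
        drop = set(transcript_ids)
        return Annotation(
            {tid: tx for tid, tx in self.transcripts.items() if tid not in drop}
        )

    def with_transcript(self, tx: TranscriptModel) -> "Annotation":
        if tx.transcript_id in self.transcripts:
            raise ValidationError(f"transcript_id {tx.transcript_id!r} already present")
        d = dict(self.transcripts)
        d[tx.transcript_id] = tx
        return Annotation(d)

    def overlapping(self, region: GenomeInterval) -> List[TranscriptModel]:
        """Transcripts whose span overlaps ``region``, in genomic order."""
        return [tx for tx in self._ordered() if tx.span.overlaps(region)]


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path: str) -> Annotation:
    """Read an Ensembl/GENCODE-dialect GTF into an :class:`Annotation`.

    Only ``exon`` feature lines are used; coordinates are converted from
    1-based inclusive to internal 0-based half-open.  Raises
    :class:`GtfParseError` (naming the line number) on malformed lines and
    :class:`ValidationError` on overlapping exons within a transcript.
    """
    exons: Dict[str, List[GenomeInterval]] = {}
    meta: Dict[str, Tuple[str, str, str]] = {}  # tid -> (gene_id, chrom, strand)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
            if fields[2] != "exon":
                continue
            try:
                start1 = int(fields[3])
                end1 = int(fields[4])
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            attrs = dict(_ATTR_RE.findall(fields[8]))
            if "transcript_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon missing transcript_id")
            if "gene_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon missing gene_id")
            tid = attrs["transcript_id"]
            info = (attrs["gene_id"], fields[0], fields[6])
            if tid in meta and meta[tid] != info:
                raise GtfParseError(
                    f"line {lineno}: transcript {tid!r} changes gene/chrom/strand"
                )
            meta[tid] = info
            exons.setdefault(tid, []).append(
                GenomeInterval(fields[0], start1 - 1, end1)
            )
    txs = []
    for tid, exl in exons.items():
        gene_id, chrom, strand = meta[tid]
        exl.sort(key=lambda e: (e.start, e.end))
        txs.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=tuple(exl),
            )
        )
    return Annotation.from_transcripts(txs)


def write_gtf(annotation: Annotation, path: str) -> None:
    """Write an annotation as GTF (1-based inclusive, exon lines only).

    Output is canonically ordered so that a read/write cycle is a fixed
    point: ``write_gtf(read_gtf(p))`` reproduces ``p`` byte for byte when
    ``p`` itself was written by this function.
    """
    with open(path, "w") as fh:
        for tx in annotation._ordered():
            for ex in tx.exons:
                fh.write(
                    f"{tx.chrom}\tlocquant\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f'{tx.strand}\t.\tgene_id "{tx.gene_id}"; '
                    f'transcript_id "{tx.transcript_id}";\n'
                )


# ---------------------------------------------------------------------------
# Alignment reading
# ---------------------------------------------------------------------------


def _read_blocks_introns(
    read: pysam.AlignedSegment,
) -> Tuple[List[Tuple[int, int]], List[Tuple[int, int]]]:
    """Reference blocks (M/=/X/D runs) and introns (N runs) of one mate."""
    blocks: List[Tuple[int, int]] = []
    introns: List[Tuple[int, int]] = []
    pos = read.reference_start
    cur_start: Optional[int] = None
    for op, ln in read.cigartuples or ():
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference within a block
            if cur_start is None:
                cur_start = pos
            pos += ln
        elif op == 3:  # N: splice
            if cur_start is not None:
                blocks.append((cur_start, pos))
                cur_start = None
            introns.append((pos, pos + ln))
            pos += ln
        # I, S, H, P consume no reference
    if cur_start is not None:
        blocks.append((cur_start, pos))
    return blocks, introns


def _merge_blocks(blocks: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Union of blocks from both mates; merge overlapping or abutting runs."""
    blocks = sorted(blocks)
    out: List[Tuple[int, int]] = []
    for s, e in blocks:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _make_fragment(qname: str, reads: List[pysam.AlignedSegment]) -> AlignedFragment:
    chrom = reads[0].reference_name
    blocks: List[Tuple[int, int]] = []
    introns: set = set()
    for r in reads:
        b, i = _read_blocks_introns(r)
        blocks.extend(b)
        introns.update(i)
    merged = _merge_blocks(blocks)
    return AlignedFragment(
        fragment_id=qname,
        chrom=chrom,
        blocks=tuple(GenomeInterval(chrom, s, e) for s, e in merged),
        introns=tuple(
            GenomeInterval(chrom, s, e) for s, e in sorted(introns)
        ),
        paired=len(reads) > 1,
    )


def _usable(read: pysam.AlignedSegment) -> bool:
    return not (read.is_unmapped or read.is_secondary or read.is_supplementary)


def _find_mate(
    af: pysam.AlignmentFile, read: pysam.AlignedSegment
) -> Optional[pysam.AlignedSegment]:
    """Locate the mapped mate of ``read`` via a point fetch at its position."""
    if read.next_reference_id < 0 or read.mate_is_unmapped:
        return None
    chrom = af.get_reference_name(read.next_reference_id)
    for cand in af.fetch(chrom, read.next_reference_start, read.next_reference_start + 1):
        if (
            cand.query_name == read.query_name
            and _usable(cand)
            and cand.is_read1 != read.is_read1
            and cand.reference_start == read.next_reference_start
        ):
            return cand
    return None


def fetch_fragments(
    alignment_path: str,
    region: Optional[GenomeInterval] = None,
) -> List[AlignedFragment]:
    """Fetch mapped fragments, mates collapsed, each counted exactly once.

    With ``region`` the alignment must be coordinate-sorted and indexed;
    every fragment whose span overlaps the region is returned once (a mate
    lying outside the region is recovered by a point fetch so the fragment's
    full footprint is known).  Unmapped, secondary and supplementary records
    are excluded.  Fragments are returned sorted by (span start, span end,
    fragment id) for deterministic downstream processing.
    """
    groups: Dict[str, List[pysam.AlignedSegment]] = {}
    with pysam.AlignmentFile(alignment_path) as af:
        if region is None:
            iterator = af.fetch(until_eof=True)
            for read in iterator:
                if _usable(read):
                    groups.setdefault(read.query_name, []).append(read)
        else:
            if region.chrom not in af.references:
                logger.warning(
                    "region chrom %s absent from alignment header of %s",
                    region.chrom,
                    alignment_path,
                )
                return []
            for read in af.fetch(region.chrom, region.start, region.end):
                if _usable(read):
                    groups.setdefault(read.query_name, []).append(read)
            # recover mates that fall outside the fetch window
            for qname in list(groups):
                reads = groups[qname]
                if len(reads) == 1 and reads[0].is_paired and not reads[0].mate_is_unmapped:
                    mate = _find_mate(af, reads[0])
                    if mate is not None:
                        reads.append(mate)

    fragments = []
    for qname, reads in groups.items():
        # keep at most one record per mate role
        seen = {}
        for r in reads:
            seen.setdefault((r.is_read1, r.reference_start), r)
        frag = _make_fragment(qname, list(seen.values()))
        if region is None or frag.span.overlaps(region):
            fragments.append(frag)
    fragments.sort(key=lambda f: (f.chrom, f.span.start, f.span.end, f.fragment_id))
    return fragments
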