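"""Reference bundles and minimum spanning bundle (MSB) inference.

A *bundle* is a maximal continuous genomic region covered by overlapping
fragments and/or known gene models, where runs separated by gaps of at most
``gap_threshold`` bp (default 50) are joined.  Bundles are the independent
units of expression estimation: by construction no fragment span crosses
from one bundle into another, so quantifying inside a bundle gives the same
answer as quantifying the whole file.

The *minimum spanning bundle* of a novel transcript is obtained by merging
the transcript's genomic span with every reference bundle it overlaps or
approaches within the gap threshold, iterated to a fixed point.  The result
equals the bundle that would arise from rebuilding bundles from scratch with
the novel transcript's span added to the interval set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple
import logging

import numpy as np

from .errors import IndexFormatError
from .model import Annotation, GenomeInterval, TranscriptModel, fetch_fragments, AlignedFragment

logger = logging.getLogger(__name__)

__all__ = [
    "Bundle",
    "BundleIndex",
    "MSBResult",
    "build_bundle_index",
    "save_index",
    "load_index",
    "export_bed",
    "infer_msb",
    "DEFAULT_GAP_THRESHOLD",
]

DEFAULT_GAP_THRESHOLD = 50

INDEX_VERSION = 1


@dataclass(frozen=True)
class Bundle:
    """One maximal merged region with its member transcripts and local depth."""

    region: GenomeInterval
    member_transcript_ids: frozenset
    local_fragment_total: int
    local_base_total: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "member_transcript_ids", frozenset(self.member_transcript_ids)
        )


@dataclass
class BundleIndex:
    """Per-sample reference bundles plus the global mapped-fragment total.

    ``global_fragment_total`` may exceed the sum of bundle-local totals only
    in pathological inputs; with bundles built from the same alignment every
    fragment belongs to exactly one bundle.
    """

    sample_id: str
    bundles: Dict[str, List[Bundle]] = field(default_factory=dict)
    global_fragment_total: int = 0
    global_base_total: int = 0
    gap_threshold: int = DEFAULT_GAP_THRESHOLD

    def __post_init__(self) -> None:
        for chrom, bl in self.bundles.items():
            bl.sort(key=lambda b: b.region.start)
            for a, b in zip(bl, bl[1:]):
                if b.region.start - a.region.end <= self.gap_threshold:
                    raise IndexFormatError(
                        f"bundles on {chrom} at {a.region} and {b.region} are "
                        f"within gap_threshold={self.gap_threshold}"
                    )

    def all_bundles(self) -> List[Bundle]:
        return [b for chrom in sorted(self.bundles) for b in self.bundles[chrom]]

    def n_bundles(self) -> int:
        return sum(len(v) for v in self.bundles.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BundleIndex):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.bundles == other.bundles
            and self.global_fragment_total == other.global_fragment_total
            and self.global_base_total == other.global_base_total
            and self.gap_threshold == other.gap_threshold
        )


@dataclass
class MSBResult:
    """The minimum spanning bundle of one novel transcript."""

    region: GenomeInterval
    reference_transcripts: List[TranscriptModel]
    novel_transcript: TranscriptModel
    source_bundles: List[Bundle]


def _merge_sorted_intervals(
    iv: np.ndarray, gap_threshold: int
) -> List[Tuple[int, int]]:
    """Merge (start, end) rows, joined when the gap is <= gap_threshold.

    ``iv`` need not be sorted; merging is transitive (single sweep after
    sorting by start).
    """
    if len(iv) == 0:
        return []
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out: List[Tuple[int, int]] = []
    cur_s, cur_e = int(iv[0, 0]), int(iv[0, 1])
    for s, e in iv[1:]:
        s, e = int(s), int(e)
        if s - cur_e <= gap_threshold:
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return out


def build_bundle_index(
    alignment_path: Optional[str],
    annotation: Annotation,
    gap_threshold: int = DEFAULT_GAP_THRESHOLD,
    *,
    sample_id: Optional[str] = None,
    fragments: Optional[Sequence[AlignedFragment]] = None,
) -> BundleIndex:
    """Build per-chromosome bundles from fragment spans and transcript spans.

    Fragment spans and reference transcript spans are pooled per chromosome
    and merged transitively: two intervals join when they overlap or the gap
    between them is at most ``gap_threshold`` bp.  Each maximal merged
    interval becomes a :class:`Bundle` carrying the reference transcripts
    whose span overlaps it and the count of fragments whose span overlaps it.

    ``fragments`` may be supplied directly (already fetched) to avoid
    re-reading the alignment; otherwise ``alignment_path`` is read in full.
    """
    if fragments is None:
        fragments = fetch_fragments(alignment_path) if alignment_path else []
        if alignment_path:
            import pysam

            with pysam.AlignmentFile(alignment_path) as af:
                header_chroms = set(af.references)
            missing = set(annotation.chroms()) - header_chroms
            if missing:
                logger.warning(
                    "annotation chroms %s absent from alignment header; bundles "
                    "there are built from annotation spans alone",
                    sorted(missing),
                )

    frag_by_chrom: Dict[str, List[AlignedFragment]] = {}
    for f in fragments:
        frag_by_chrom.setdefault(f.chrom, []).append(f)

    tx_by_chrom: Dict[str, List[TranscriptModel]] = {}
    for tx in annotation.transcripts.values():
        tx_by_chrom.setdefault(tx.chrom, []).append(tx)

    bundles: Dict[str, List[Bundle]] = {}
    for chrom in sorted(set(frag_by_chrom) | set(tx_by_chrom)):
        frags = frag_by_chrom.get(chrom, [])
        txs = tx_by_chrom.get(chrom, [])
        spans = np.array(
            [(f.span.start, f.span.end) for f in frags]
            + [(t.span.start, t.span.end) for t in txs],
            dtype=np.int64,
        ).reshape(-1, 2)
        merged = _merge_sorted_intervals(spans, gap_threshold)
        if not merged:
            continue
        starts = np.array([m[0] for m in merged])
        # assign each fragment to its (unique) containing bundle by span start
        chrom_bundles: List[Bundle] = []
        frag_counts = [0] * len(merged)
        base_totals = [0] * len(merged)
        if frags:
            fs = np.array([f.span.start for f in frags])
            idx = np.searchsorted(starts, fs, side="right") - 1
            for f, i in zip(frags, idx):
                frag_counts[i] += 1
                base_totals[i] += f.aligned_bases
        for i, (s, e) in enumerate(merged):
            region = GenomeInterval(chrom, s, e)
            members = frozenset(
                t.transcript_id for t in txs if t.span.overlaps(region)
            )
            chrom_bundles.append(
                Bundle(
                    region=region,
                    member_transcript_ids=members,
                    local_fragment_total=frag_counts[i],
                    local_base_total=base_totals[i],
                )
            )
        bundles[chrom] = chrom_bundles

    return BundleIndex(
        sample_id=sample_id or (alignment_path or "in-memory"),
        bundles=bundles,
        global_fragment_total=len(fragments),
        global_base_total=sum(f.aligned_bases for f in fragments),
        gap_threshold=gap_threshold,
    )


# ---------------------------------------------------------------------------
# Index persistence: versioned TSV
# ---------------------------------------------------------------------------


def save_index(index: BundleIndex, path: str) -> None:
    """Write the index as a versioned tab-separated file."""
    with open(path, "w") as fh:
        fh.write(f"#version={INDEX_VERSION}\n")
        fh.write(f"#sample_id={index.sample_id}\n")
        fh.write(f"#global_fragment_total={index.global_fragment_total}\n")
        fh.write(f"#global_base_total={index.global_base_total}\n")
        fh.write(f"#gap_threshold={index.gap_threshold}\n")
        for chrom in sorted(index.bundles):
            for b in index.bundles[chrom]:
                members = ",".join(sorted(b.member_transcript_ids))
                fh.write(
                    f"{chrom}\t{b.region.start}\t{b.region.end}\t"
                    f"{b.local_fragment_total}\t{b.local_base_total}\t{members}\n"
                )


def load_index(path: str) -> BundleIndex:
    """Read an index written by :func:`save_index`; strict about format."""
    header: Dict[str, str] = {}
    bundles: Dict[str, List[Bundle]] = {}
    try:
        fh = open(path)
    except OSError as exc:
        raise IndexFormatError(f"cannot open index {path}: {exc}") from exc
    with fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise IndexFormatError(f"line {lineno}: malformed header line")
                k, v = line[1:].split("=", 1)
                header[k] = v
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise IndexFormatError(
                    f"line {lineno}: expected 6 fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                nfrag, nbase = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise IndexFormatError(f"line {lineno}: non-integer field") from exc
            members = frozenset(x for x in fields[5].split(",") if x)
            bundles.setdefault(fields[0], []).append(
                Bundle(
                    region=GenomeInterval(fields[0], start, end),
                    member_transcript_ids=members,
                    local_fragment_total=nfrag,
                    local_base_total=nbase,
                )
            )
    if header.get("version") != str(INDEX_VERSION):
        raise IndexFormatError(
            f"index version {header.get('version')!r} != {INDEX_VERSION}"
        )
    for key in ("sample_id", "global_fragment_total", "gap_threshold"):
        if key not in header:
            raise IndexFormatError(f"missing header field #{key}")
    try:
        return BundleIndex(
            sample_id=header["sample_id"],
            bundles=bundles,
            global_fragment_total=int(header["global_fragment_total"]),
            global_base_total=int(header.get("global_base_total", "0")),
            gap_threshold=int(header["gap_threshold"]),
        )
    except ValueError as exc:
        raise IndexFormatError(f"non-integer header field: {exc}") from exc


def export_bed(index: BundleIndex, path: str) -> None:
    """Write bundles as BED for inspection in a genome browser."""
    with open(path, "w") as fh:
        for chrom in sorted(index.bundles):
            for i, b in enumerate(index.bundles[chrom]):
                fh.write(
                    f"{chrom}\t{b.region.start}\t{b.region.end}\t"
                    f"bundle_{chrom}_{i}\t{b.local_fragment_total}\t.\n"
                )


# ---------------------------------------------------------------------------
# MSB inference
# ---------------------------------------------------------------------------


def infer_msb(
    novel: TranscriptModel,
    index: BundleIndex,
    annotation: Annotation,
) -> MSBResult:
    """Infer the minimum spanning bundle of a novel transcript.

    Starting from the transcript's genomic span, every bundle that overlaps
    the current region or lies within ``index.gap_threshold`` bp of it is
    merged in, repeating until a fixed point.  Because bundles in an index
    are pairwise separated by more than the threshold, the fixed point is a
    contiguous run of bundles and is reached by expanding left and right
    over the sorted bundle list.
    """
    gap = index.gap_threshold
    span = novel.span
    chrom_bundles = index.bundles.get(novel.chrom, [])
    lo, hi = span.start, span.end
    merged: List[Bundle] = []
    if chrom_bundles:
        starts = [b.region.start for b in chrom_bundles]
        ends = [b.region.end for b in chrom_bundles]
        # leftmost bundle whose end is within gap of (or past) current lo
        i = 0
        while i < len(chrom_bundles) and ends[i] + gap < lo:
            i += 1
        j = i
        while j < len(chrom_bundles) and starts[j] <= hi + gap:
            merged.append(chrom_bundles[j])
            lo = min(lo, starts[j])
            hi = max(hi, ends[j])
            j += 1
    region = GenomeInterval(novel.chrom, lo, hi)
    refs = annotation.overlapping(region)
    return MSBResult(
        region=region,
        reference_transcripts=refs,
        novel_transcript=novel,
        source_bundles=merged,
    )
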