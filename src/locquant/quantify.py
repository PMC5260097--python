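"""Within-bundle abundance estimation.

Fragments overlapping a bundle are assigned to the isoforms they are
compatible with, and an EM over the isoform mixture distributes shared
fragments.  The likelihood is the standard isoform-mixture model with
uniform start positions: the probability of a fragment under transcript
``t`` is proportional to ``theta_t / effective_length(t)`` when the
fragment is compatible with ``t`` and zero otherwise.

Relative FPKM uses the *local* (within-bundle) fragment total as its
per-million depth denominator; rescaling by local/global totals (see
:mod:`locquant.normalize`) turns it into the value a whole-transcriptome
quantification would report.

There is no randomness anywhere in this module: EM starts from a uniform
mixture, so identical inputs always give identical outputs, and isoforms
with identical compatibility patterns receive equal shares (the symmetric
fixed point).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bundles import BundleIndex, MSBResult, build_bundle_index
from .errors import ValidationError
from .model import AlignedFragment, Annotation, GenomeInterval, TranscriptModel, fetch_fragments

__all__ = [
    "FragLenModel",
    "CompatibilityMatrix",
    "QuantRecord",
    "is_compatible",
    "effective_length",
    "estimate_frag_len",
    "em_quantify",
    "quantify_in_msb",
    "quantify_sample",
    "DEFAULT_FRAG_LEN",
]

#: Fallback fragment-length model used when a bundle has too few uniquely
#: assignable paired fragments to estimate one locally.
DEFAULT_FRAG_LEN = (200.0, 50.0)

#: Minimum number of uniquely assignable paired fragments required before
#: the local fragment-length estimate is trusted over the fallback.
MIN_FLM_FRAGMENTS = 20


@dataclass(frozen=True)
class FragLenModel:
    """Fragment-length distribution summary (mean/sd in bp)."""

    mean: float
    sd: float
    source: str = "fixed"  # {"estimated", "fixed"}

    def __post_init__(self) -> None:
        if self.mean < 1 or self.sd < 0:
            raise ValidationError(f"bad fragment length model {self}")


@dataclass
class CompatibilityMatrix:
    """Boolean fragment x transcript compatibility relation."""

    fragment_ids: List[str]
    transcript_ids: List[str]
    compatible: np.ndarray  # bool, shape (n_fragments, n_transcripts)


@dataclass
class QuantRecord:
    """Per-transcript quantification result inside one bundle/MSB."""

    transcript_id: str
    expected_fragments: float
    effective_length: int
    relative_fpkm: float
    local_fragment_total: int
    global_fragment_total: int
    local_base_total: int = 0
    global_base_total: int = 0


# ---------------------------------------------------------------------------
# Compatibility
# ---------------------------------------------------------------------------


def is_compatible(fragment: AlignedFragment, transcript: TranscriptModel) -> bool:
    """True iff the fragment could have been sequenced from the transcript.

    Requires (a) every aligned block to lie within the transcript's exon
    union, and (b) every splice gap of the fragment to coincide exactly with
    a transcript intron.  For paired fragments the unsequenced inner gap
    between mates is not a splice gap, so it may silently span any number of
    transcript introns; under the monotone genome-to-mature projection the
    implied mature fragment length is then automatically consistent.
    """
    if fragment.chrom != transcript.chrom:
        return False
    exons = transcript.exons
    for b in fragment.blocks:
        ok = False
        for ex in exons:
            if ex.start <= b.start and b.end <= ex.end:
                ok = True
                break
        if not ok:
            return False
    tx_introns = {(i.start, i.end) for i in transcript.introns}
    for i in fragment.introns:
        if (i.start, i.end) not in tx_introns:
            return False
    return True


class _FlatFragments:
    """Flattened block/intron arrays for a fixed fragment list.

    Built once per bundle and reused across transcripts so compatibility is
    computed with vectorized searchsorted/isin instead of Python loops.
    """

    def __init__(self, fragments: Sequence[AlignedFragment]):
        self.n = len(fragments)
        bs, be, bidx = [], [], []
        ic, iidx = [], []
        for i, f in enumerate(fragments):
            for b in f.blocks:
                bs.append(b.start)
                be.append(b.end)
                bidx.append(i)
            for iv in f.introns:
                ic.append(iv.start * (1 << 32) + iv.end)
                iidx.append(i)
        self.block_start = np.array(bs, dtype=np.int64)
        self.block_end = np.array(be, dtype=np.int64)
        self.block_frag = np.array(bidx, dtype=np.intp)
        self.intron_code = np.array(ic, dtype=np.int64)
        self.intron_frag = np.array(iidx, dtype=np.intp)
        self.chroms = np.array([f.chrom for f in fragments])
        self.span_start = np.array([f.span.start for f in fragments], dtype=np.int64)
        self.span_end = np.array([f.span.end for f in fragments], dtype=np.int64)
        self.paired = np.array([f.paired for f in fragments], dtype=bool)

    def compatible_with(self, tx: TranscriptModel) -> np.ndarray:
        ok = np.ones(self.n, dtype=bool)
        ok &= self.chroms == tx.chrom
        if len(self.block_start):
            ex_s = np.array([e.start for e in tx.exons], dtype=np.int64)
            ex_e = np.array([e.end for e in tx.exons], dtype=np.int64)
            pos = np.searchsorted(ex_s, self.block_start, side="right") - 1
            inside = (pos >= 0) & (self.block_end <= ex_e[np.clip(pos, 0, None)])
            bad = np.zeros(self.n, dtype=bool)
            np.logical_or.at(bad, self.block_frag[~inside], True)
            ok &= ~bad
        if len(self.intron_code):
            tx_codes = np.array(
                [i.start * (1 << 32) + i.end for i in tx.introns], dtype=np.int64
            )
            good = np.isin(self.intron_code, tx_codes)
            bad = np.zeros(self.n, dtype=bool)
            np.logical_or.at(bad, self.intron_frag[~good], True)
            ok &= ~bad
        return ok

    def implied_lengths(self, tx: TranscriptModel) -> np.ndarray:
        """Implied mature fragment length of every fragment on ``tx``.

        Valid only where the fragment is compatible with ``tx`` (both span
        endpoints exonic); other entries carry arbitrary values and must be
        masked by the caller.
        """
        ex_s = np.array([e.start for e in tx.exons], dtype=np.int64)
        cum = np.concatenate(
            [[0], np.cumsum([e.length for e in tx.exons])[:-1]]
        ).astype(np.int64)

        def project(gpos: np.ndarray) -> np.ndarray:
            idx = np.clip(
                np.searchsorted(ex_s, gpos, side="right") - 1, 0, None
            )
            return cum[idx] + (gpos - ex_s[idx])

        return project(self.span_end - 1) + 1 - project(self.span_start)


def compatibility_matrix(
    fragments: Sequence[AlignedFragment],
    transcripts: Sequence[TranscriptModel],
) -> CompatibilityMatrix:
    """Vectorized all-pairs compatibility."""
    flat = _FlatFragments(fragments)
    mat = np.zeros((len(fragments), len(transcripts)), dtype=bool)
    for j, tx in enumerate(transcripts):
        mat[:, j] = flat.compatible_with(tx)
    return CompatibilityMatrix(
        fragment_ids=[f.fragment_id for f in fragments],
        transcript_ids=[t.transcript_id for t in transcripts],
        compatible=mat,
    )


# ---------------------------------------------------------------------------
# Effective length and fragment-length estimation
# ---------------------------------------------------------------------------


def effective_length(transcript: TranscriptModel, flm: FragLenModel) -> int:
    """Number of distinct fragment start positions: max(1, L - mean + 1)."""
    return max(1, transcript.length - int(round(flm.mean)) + 1)


def estimate_frag_len(
    fragments: Sequence[AlignedFragment],
    transcripts: Sequence[TranscriptModel],
    compat: Optional[CompatibilityMatrix] = None,
    min_fragments: int = MIN_FLM_FRAGMENTS,
) -> FragLenModel:
    """Estimate the fragment-length distribution locally.

    Uses paired fragments compatible with exactly one of ``transcripts``;
    each contributes its implied length on that transcript's mature
    sequence.  Falls back to a fixed N(200, 50) model when fewer than
    ``min_fragments`` informative fragments exist (e.g. single-end data).
    """
    if compat is None:
        compat = compatibility_matrix(fragments, transcripts)
    mat = compat.compatible
    lengths: List[int] = []
    if mat.size:
        unique = mat.sum(axis=1) == 1
        which = mat.argmax(axis=1)
        for i in np.flatnonzero(unique):
            f = fragments[i]
            if not f.paired:
                continue
            L = transcripts[which[i]].implied_mature_length(f.span)
            if L is not None and L >= 1:
                lengths.append(L)
    if len(lengths) < min_fragments:
        return FragLenModel(*DEFAULT_FRAG_LEN, source="fixed")
    arr = np.array(lengths, dtype=float)
    return FragLenModel(float(arr.mean()), float(arr.std()), source="estimated")


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def em_quantify(
    fragments: Sequence[AlignedFragment],
    transcripts: Sequence[TranscriptModel],
    flm: FragLenModel,
    max_iter: int = 1000,
    tol: float = 1e-8,
    compat: Optional[CompatibilityMatrix] = None,
    return_loglik_trace: bool = False,
):
    """Isoform-mixture EM over fragment assignments.

    For a compatible (fragment, transcript) pair the likelihood weight is
    the standard length-aware mixture term

        P(f | t)  ∝  phi(l_ft; mean, sd) / (L_t - l_ft + 1)

    where ``l_ft`` is the fragment's implied length on the transcript's
    mature sequence, ``phi`` the normal density of the fragment-length
    model and the denominator the number of start positions a fragment of
    that length has on the transcript.  Unpaired fragments carry no length
    information and fall back to 1/effective_length(t).  Incompatible
    pairs have weight 0.

    The mixture weights start uniform over transcripts with at least one
    compatible fragment; the E-step assigns each assignable fragment
    fractionally among its compatible transcripts in proportion to
    theta_t * P(f|t), and the M-step renormalizes.  Iteration stops when
    max |delta theta| < tol or after ``max_iter`` rounds.  Returns
    ``{transcript_id: expected_fragments}`` where the expected counts sum
    to the number of assignable fragments; fragments compatible with no
    transcript are excluded from the likelihood.

    With ``return_loglik_trace`` the per-iteration log-likelihood is also
    returned, up to a per-fragment additive constant from row scaling (it
    is non-decreasing; tests assert this).
    """
    if not transcripts:
        raise ValidationError("em_quantify requires at least one transcript")
    tids = [t.transcript_id for t in transcripts]
    if compat is None:
        compat = compatibility_matrix(fragments, transcripts)
    C = compat.compatible
    n_frag, n_tx = C.shape
    eff = np.array([effective_length(t, flm) for t in transcripts], dtype=float)

    flat = _FlatFragments(fragments)
    sd = max(flm.sd, 1.0)
    tx_len = np.array([t.length for t in transcripts], dtype=float)
    W = np.zeros_like(C, dtype=float)
    for j, tx in enumerate(transcripts):
        col = C[:, j]
        if not col.any():
            continue
        ell = flat.implied_lengths(tx).astype(float)
        z = (ell - flm.mean) / sd
        pdf = np.exp(-0.5 * np.clip(z * z, None, 1400.0)) / (
            sd * np.sqrt(2.0 * np.pi)
        )
        w = pdf / np.clip(tx_len[j] - ell + 1.0, 1.0, None)
        w = np.where(flat.paired, w, 1.0 / eff[j])
        W[:, j] = np.where(col, w, 0.0)
    # a compatible pair never gets exactly zero weight (deep-tail underflow)
    W[C & (W <= 0.0)] = 1e-300
    # per-fragment scaling: leaves the EM trajectory and posteriors
    # unchanged, shifts the log-likelihood by a constant, avoids underflow
    row_max = W.max(axis=1)
    W[row_max > 0] /= row_max[row_max > 0, None]
    assignable = C.any(axis=1)
    A = W[assignable]
    N = int(assignable.sum())
    trace: List[float] = []
    if N == 0:
        result = {tid: 0.0 for tid in tids}
        return (result, trace) if return_loglik_trace else result

    active = C[assignable].any(axis=0)
    theta = np.where(active, 1.0, 0.0)
    theta /= theta.sum()
    for _ in range(max_iter):
        denom = A @ theta  # > 0 for assignable fragments with active theta
        if return_loglik_trace:
            trace.append(float(np.log(denom).sum()))
        theta_new = theta * (A.T @ (1.0 / denom)) / N
        delta = np.abs(theta_new - theta).max()
        theta = theta_new
        if delta < tol:
            break
    result = {tid: float(theta[j] * N) for j, tid in enumerate(tids)}
    return (result, trace) if return_loglik_trace else result


# ---------------------------------------------------------------------------
# Bundle-level quantification
# ---------------------------------------------------------------------------


def _relative_fpkm(expected: float, eff_len: int, local_total: int) -> float:
    if eff_len <= 0 or local_total <= 0:
        return 0.0
    return expected / ((eff_len / 1000.0) * (local_total / 1e6))


def _records_for_bundle(
    fragments: Sequence[AlignedFragment],
    transcripts: Sequence[TranscriptModel],
    index: BundleIndex,
    flm: Optional[FragLenModel],
    em_kwargs: dict,
) -> List[QuantRecord]:
    compat = compatibility_matrix(fragments, transcripts)
    if flm is None:
        flm = estimate_frag_len(fragments, transcripts, compat=compat)
    expected = em_quantify(fragments, transcripts, flm, compat=compat, **em_kwargs)
    local_total = len(fragments)
    local_bases = sum(f.aligned_bases for f in fragments)
    records = []
    for tx in transcripts:
        eff = effective_length(tx, flm)
        exp = expected[tx.transcript_id]
        records.append(
            QuantRecord(
                transcript_id=tx.transcript_id,
                expected_fragments=exp,
                effective_length=eff,
                relative_fpkm=_relative_fpkm(exp, eff, local_total),
                local_fragment_total=local_total,
                global_fragment_total=index.global_fragment_total,
                local_base_total=local_bases,
                global_base_total=index.global_base_total,
            )
        )
    return records


def quantify_in_msb(
    msb: MSBResult,
    alignment_path: Optional[str] = None,
    index: Optional[BundleIndex] = None,
    flm: Optional[FragLenModel] = None,
    *,
    fragments: Optional[Sequence[AlignedFragment]] = None,
    **em_kwargs,
) -> List[QuantRecord]:
    """Quantify the novel transcript and its MSB co-members locally.

    Fragments overlapping the MSB region are fetched (or passed in), the EM
    is run over the novel transcript together with every reference
    transcript inside the MSB, and relative FPKM is computed with the local
    fragment total as depth.  The novel transcript's record comes first.
    Fragments that overlap the MSB but are compatible with none of its
    transcripts still count toward the local total (they are part of the
    local sequencing depth) but not toward the likelihood.
    """
    if index is None:
        raise ValidationError("quantify_in_msb requires the sample's BundleIndex")
    if fragments is None:
        if alignment_path is None:
            raise ValidationError("need alignment_path or fragments")
        fragments = fetch_fragments(alignment_path, msb.region)
    transcripts = [msb.novel_transcript] + [
        t
        for t in msb.reference_transcripts
        if t.transcript_id != msb.novel_transcript.transcript_id
    ]
    return _records_for_bundle(fragments, transcripts, index, flm, em_kwargs)


def quantify_sample(
    annotation: Annotation,
    alignment_path: Optional[str] = None,
    gap_threshold: int = 50,
    flm: Optional[FragLenModel] = None,
    *,
    fragments: Optional[Sequence[AlignedFragment]] = None,
    index: Optional[BundleIndex] = None,
    **em_kwargs,
) -> Dict[str, QuantRecord]:
    """Whole-transcriptome quantification: every bundle, independently.

    This is the standard (global) pipeline the local MSB path is benchmarked
    against: bundles are built from all fragments plus the full annotation,
    and each bundle is quantified with the same estimator and the same local
    fragment-length rule as :func:`quantify_in_msb`.  Returns a mapping
    transcript_id -> QuantRecord covering every annotated transcript.
    """
    if fragments is None:
        if alignment_path is None:
            raise ValidationError("need alignment_path or fragments")
        fragments = fetch_fragments(alignment_path)
    if index is None:
        index = build_bundle_index(
            None, annotation, gap_threshold, fragments=fragments
        )

    # assign fragments to bundles by span start (unique by construction)
    frag_by_chrom: Dict[str, List[AlignedFragment]] = {}
    for f in fragments:
        frag_by_chrom.setdefault(f.chrom, []).append(f)

    out: Dict[str, QuantRecord] = {}
    for chrom, chrom_bundles in index.bundles.items():
        frags = frag_by_chrom.get(chrom, [])
        starts = np.array([b.region.start for b in chrom_bundles], dtype=np.int64)
        per_bundle: List[List[AlignedFragment]] = [[] for _ in chrom_bundles]
        if frags:
            fs = np.array([f.span.start for f in frags], dtype=np.int64)
            idx = np.searchsorted(starts, fs, side="right") - 1
            for f, i in zip(frags, idx):
                per_bundle[int(i)].append(f)
        for b, bfrags in zip(chrom_bundles, per_bundle):
            txs = annotation.overlapping(b.region)
            if not txs:
                continue
            for rec in _records_for_bundle(bfrags, txs, index, flm, em_kwargs):
                out[rec.transcript_id] = rec
    # annotated transcripts in read-free regions may form bundles of their own
    for tid, tx in annotation.transcripts.items():
        if tid not in out:
            eff = effective_length(tx, flm or FragLenModel(*DEFAULT_FRAG_LEN))
            out[tid] = QuantRecord(
                transcript_id=tid,
                expected_fragments=0.0,
                effective_length=eff,
                relative_fpkm=0.0,
                local_fragment_total=0,
                global_fragment_total=index.global_fragment_total,
                local_base_total=0,
                global_base_total=index.global_base_total,
            )
    return out
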