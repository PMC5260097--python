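"""Hold-out benchmarking of the local quantification path.

Known transcripts are removed from the reference and re-submitted as novel
queries; each is quantified through the MSB-local path and compared with
the whole-transcriptome run and with the simulator's truth table.  Because
a query is evaluated against the reference lacking only that transcript,
the matching whole-transcriptome run is the full-annotation run, computed
once for all queries.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .bundles import build_bundle_index, infer_msb
from .model import Annotation, fetch_fragments
from .normalize import correct_fpkm
from .quantify import compatibility_matrix, quantify_in_msb, quantify_sample
from .simdata import holdout_protocol

__all__ = ["run_holdout_evaluation"]


def run_holdout_evaluation(
    annotation: Annotation,
    alignment_path: str,
    k: int,
    seed: int,
    truth: Optional[pd.DataFrame] = None,
    gap_threshold: int = 50,
) -> pd.DataFrame:
    """Quantify ``k`` randomly held-out transcripts locally and globally.

    Returns one row per held-out transcript with the corrected FPKM from
    the MSB-local path (``local_fpkm``), from the whole-transcriptome run
    (``global_fpkm``), the EM mass-conservation error of the local run
    (``conservation_err``: |sum of expected counts - assignable fragment
    count|), and, when a simulator truth table is given, the true fragment
    count and FPKM.
    """
    fragments = fetch_fragments(alignment_path)
    _, held = holdout_protocol(annotation, k, seed)
    glob = quantify_sample(
        annotation, gap_threshold=gap_threshold, fragments=fragments
    )
    truth_idx = truth.set_index("transcript_id") if truth is not None else None

    rows = []
    for tx in held:
        tid = tx.transcript_id
        reduced = annotation.without([tid])
        index = build_bundle_index(
            None, reduced, gap_threshold, fragments=fragments, sample_id="holdout"
        )
        msb = infer_msb(tx, index, reduced)
        local_frags = fetch_fragments(alignment_path, msb.region)
        records = quantify_in_msb(msb, index=index, fragments=local_frags)
        local_rec = records[0]
        txs = [msb.novel_transcript] + [
            t for t in msb.reference_transcripts if t.transcript_id != tid
        ]
        compat = compatibility_matrix(local_frags, txs)
        assignable = int(compat.compatible.any(axis=1).sum())
        conservation_err = abs(
            sum(r.expected_fragments for r in records) - assignable
        )
        row = {
            "transcript_id": tid,
            "msb_start": msb.region.start,
            "msb_end": msb.region.end,
            "local_total": local_rec.local_fragment_total,
            "local_fpkm": correct_fpkm(local_rec),
            "global_fpkm": correct_fpkm(glob[tid]),
            "conservation_err": conservation_err,
        }
        if truth_idx is not None:
            row["true_count"] = int(truth_idx.loc[tid, "true_count"])
            row["true_fpkm"] = float(truth_idx.loc[tid, "true_fpkm"])
        rows.append(row)
    return pd.DataFrame(rows)
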