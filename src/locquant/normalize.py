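"""Post-processing: corrected FPKM, cross-sample normalization, averaging.

A relative FPKM uses within-bundle depth as its per-million denominator;
multiplying by (local total / global total) rescales it to the value a
whole-transcriptome run would report:

    corrected FPKM = relative FPKM x local total / global total

The totals are fragment counts by default; a ``totals="bases"`` switch uses
summed aligned base totals instead (the two differ by the ratio of local to
global mean fragment length).  Corrected FPKMs are then made comparable
across samples by DESeq-style median-of-ratios ("geometric") normalization
over a set of reference transcripts, and replicates of the same cell type
are averaged after normalization.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import DepthError, ValidationError
from .quantify import QuantRecord

__all__ = [
    "ExpressionMatrix",
    "correct_fpkm",
    "geometric_normalize",
    "average_replicates",
    "write_matrix",
    "write_zip",
]


@dataclass
class ExpressionMatrix:
    """Transcripts x samples of corrected FPKM with per-sample size factors."""

    values: pd.DataFrame  # rows: transcript_ids, columns: sample_ids
    size_factors: pd.Series = None
    replicate_groups: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.size_factors is None:
            self.size_factors = pd.Series(1.0, index=self.values.columns)
        if list(self.size_factors.index) != list(self.values.columns):
            raise ValidationError("size_factors index must match sample columns")
        if (self.size_factors <= 0).any():
            raise ValidationError("size factors must be positive")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")

    @property
    def transcript_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)


def correct_fpkm(record: QuantRecord, totals: str = "count") -> float:
    """Rescale a relative FPKM to the whole-transcriptome scale.

    ``totals="count"`` (default) uses fragment counts for the local/global
    ratio; ``totals="bases"`` uses summed aligned base totals.
    """
    if totals == "count":
        local, glob = record.local_fragment_total, record.global_fragment_total
    elif totals == "bases":
        local, glob = record.local_base_total, record.global_base_total
    else:
        raise ValidationError(f"unknown totals mode {totals!r}")
    if glob <= 0:
        raise DepthError("global total is zero: sample has no mapped fragments")
    if local <= 0:
        return 0.0
    return record.relative_fpkm * local / glob


def geometric_normalize(
    matrix: ExpressionMatrix,
    reference_values: Optional[pd.DataFrame] = None,
) -> ExpressionMatrix:
    """Median-of-ratios normalization across samples.

    For each reference transcript that is nonzero in every sample, compute
    its geometric mean across samples; each sample's size factor is the
    median over those transcripts of (sample value / geometric mean),
    rescaled so the factors have unit geometric mean (hence their product
    is 1).  Values are divided by the factor.  A single sample, or the
    absence of any everywhere-nonzero reference transcript, yields factors
    of exactly 1 (the latter with a warning).
    """
    import logging

    ref = matrix.values if reference_values is None else reference_values
    samples = matrix.sample_ids
    if reference_values is not None and list(ref.columns) != samples:
        raise ValidationError("reference_values columns must match sample ids")

    factors = pd.Series(1.0, index=samples)
    if len(samples) > 1:
        arr = ref.to_numpy(dtype=float)
        usable = (arr > 0).all(axis=1)
        if usable.any():
            logmat = np.log(arr[usable])
            geo = logmat.mean(axis=1)  # log geometric mean per transcript
            ratios = logmat - geo[:, None]
            f = np.exp(np.median(ratios, axis=0))
            f /= np.exp(np.mean(np.log(f)))  # unit geometric mean
            factors = pd.Series(f, index=samples)
        else:
            logging.getLogger(__name__).warning(
                "no reference transcript nonzero in all samples; "
                "size factors default to 1"
            )
    normalized = matrix.values.div(factors, axis=1)
    return ExpressionMatrix(
        values=normalized,
        size_factors=factors,
        replicate_groups=dict(matrix.replicate_groups),
    )


def average_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average samples of the same cell type (applied after normalization).

    The output has one column per cell-type label, ordered by first
    appearance of the label among the sample columns; values are arithmetic
    means of the group's (normalized) values.
    """
    groups = matrix.replicate_groups
    missing = [s for s in matrix.sample_ids if s not in groups]
    if missing:
        raise ValidationError(f"replicate_groups missing samples: {missing}")
    order: List[str] = []
    for s in matrix.sample_ids:
        if groups[s] not in order:
            order.append(groups[s])
    cols = {}
    for label in order:
        members = [s for s in matrix.sample_ids if groups[s] == label]
        cols[label] = matrix.values[members].mean(axis=1)
    out = pd.DataFrame(cols, index=matrix.values.index)
    return ExpressionMatrix(
        values=out,
        size_factors=pd.Series(1.0, index=out.columns),
        replicate_groups={label: label for label in order},
    )


def write_matrix(matrix: ExpressionMatrix, path: str, factors_path: Optional[str] = None) -> None:
    """Write the matrix as TSV (4 decimal places) plus optional size factors."""
    df = matrix.values.map(lambda v: f"{v:.4f}")
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t")
    if factors_path is not None:
        with open(factors_path, "w") as fh:
            fh.write("sample_id\tsize_factor\n")
            for s, f in matrix.size_factors.items():
                fh.write(f"{s}\t{f:.6f}\n")


def write_zip(tables: Mapping[str, str], path: str) -> None:
    """Bundle named per-sample TSV tables into one ZIP archive.

    ``tables`` maps archive member name -> file path on disk.
    """
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(tables):
            zf.write(tables[name], arcname=name)
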