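"""Composite signature scores: RPKM conversion, calibrator normalization,
median aggregation, and the qPCR 2^-ddCt input path.

A composite score for a sample is the median, over the signature genes found
in the matrix, of that sample's expression divided by a calibrator sample's
expression. By construction the calibrator itself scores 1, and a typical
control scores close to 1, so patient scores read directly as fold changes
over the healthy baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import ExpressionMatrix, GeneSignature, ValidationError

__all__ = [
    "counts_to_rpkm",
    "select_calibrator",
    "calibrator_normalize",
    "composite_score",
    "ddct_relative_expression",
    "ScoreResult",
]


@dataclass
class ScoreResult:
    """Per-sample composite score values plus the calibrator used.

    Scores are in fold-change units relative to ``calibrator_sample``;
    ``genes_used`` lists the signature genes that survived the drop rules
    (present in the matrix, non-zero in the calibrator).
    """

    signature_name: str
    calibrator_sample: str
    scores: dict[str, float]
    genes_used: list[str]


def counts_to_rpkm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert raw counts to reads per kilobase per million mapped reads.

    ``rpkm[g, s] = counts[g, s] * 1e9 / (length_bp[g] * library_size[s])``
    where the library size is the column sum of counts over all genes.
    """
    if matrix.value_kind != "counts":
        raise ValidationError(
            f"counts_to_rpkm requires counts input, got {matrix.value_kind!r}"
        )
    if matrix.gene_lengths is None:
        raise ValidationError("counts_to_rpkm requires gene_lengths")
    library = matrix.values.sum(axis=0)
    zero = np.flatnonzero(library == 0)
    if zero.size:
        raise ValidationError(
            f"sample {matrix.sample_ids[int(zero[0])]!r} has zero library size"
        )
    lengths = np.array([matrix.gene_lengths[g] for g in matrix.gene_ids], dtype=float)
    rpkm = matrix.values * 1e9 / (lengths[:, None] * library[None, :])
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
        values=rpkm,
        value_kind="rpkm",
        gene_lengths=dict(matrix.gene_lengths),
    )


def _signature_rows(matrix: ExpressionMatrix, signature: GeneSignature):
    present = [g for g in signature.genes if g in set(matrix.gene_ids)]
    absent = [g for g in signature.genes if g not in set(matrix.gene_ids)]
    if absent:
        warnings.warn(
            f"signature {signature.name!r}: genes absent from matrix, dropped: "
            f"{absent}",
            stacklevel=3,
        )
    if not present:
        raise ValidationError(
            f"no gene of signature {signature.name!r} is present in the matrix"
        )
    idx = [matrix.gene_index(g) for g in present]
    return present, matrix.values[idx, :]


def select_calibrator(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    control_ids: list[str],
) -> str:
    """Pick a default calibrator: the control whose signature-gene profile is
    closest (L1 distance on log2(x+1) values) to the control median profile.

    Deterministic; ties break on the order of ``control_ids``.
    """
    if not control_ids:
        raise ValidationError("select_calibrator needs at least one control id")
    _, rows = _signature_rows(matrix, signature)
    cols = [matrix.sample_index(s) for s in control_ids]
    log_vals = np.log2(rows[:, cols] + 1.0)
    med = np.median(log_vals, axis=1, keepdims=True)
    dist = np.abs(log_vals - med).sum(axis=0)
    return control_ids[int(np.argmin(dist))]


def calibrator_normalize(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    calibrator: str,
) -> tuple[list[str], np.ndarray]:
    """Per-gene fold changes of signature genes relative to a calibrator sample.

    Signature genes absent from the matrix, or with zero expression in the
    calibrator, are dropped with a warning. Returns the retained gene ids and
    a genes x samples grid of ratios.
    """
    genes, rows = _signature_rows(matrix, signature)
    cal_col = matrix.sample_index(calibrator)
    cal = rows[:, cal_col]
    nonzero = cal > 0
    dropped = [g for g, ok in zip(genes, nonzero) if not ok]
    if dropped:
        warnings.warn(
            f"signature {signature.name!r}: zero calibrator expression, dropped: "
            f"{dropped}",
            stacklevel=2,
        )
    if not np.any(nonzero):
        raise ValidationError(
            f"every available gene of signature {signature.name!r} has zero "
            f"expression in calibrator {calibrator!r}"
        )
    genes = [g for g, ok in zip(genes, nonzero) if ok]
    norm = rows[nonzero, :] / cal[nonzero, None]
    return genes, norm


def composite_score(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    calibrator: str | None = None,
    control_ids: list[str] | None = None,
) -> ScoreResult:
    """Median of calibrator-normalized signature-gene expression, per sample.

    If ``calibrator`` is None it is chosen with :func:`select_calibrator`
    from ``control_ids`` (required in that case). With an even number of
    retained genes the median is the mean of the two central values.
    """
    if calibrator is None:
        if not control_ids:
            raise ValidationError(
                "composite_score needs a calibrator id or control_ids to pick one"
            )
        calibrator = select_calibrator(matrix, signature, control_ids)
    genes, norm = calibrator_normalize(matrix, signature, calibrator)
    scores = np.median(norm, axis=0)
    return ScoreResult(
        signature_name=signature.name,
        calibrator_sample=calibrator,
        scores={s: float(v) for s, v in zip(matrix.sample_ids, scores)},
        genes_used=genes,
    )


def ddct_relative_expression(
    ct_target: float, ct_reference: float, dct_calibrator: float
) -> float:
    """Standard 2^-ddCt conversion of qPCR cycle thresholds to fold change.

    ``ddCt = (ct_target - ct_reference) - dct_calibrator``; the result feeds
    :func:`composite_score` with ``value_kind="relative"``.
    """
    for v in (ct_target, ct_reference, dct_calibrator):
        if not np.isfinite(v):
            raise ValidationError("cycle threshold values must be finite")
    return float(2.0 ** -((ct_target - ct_reference) - dct_calibrator))
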