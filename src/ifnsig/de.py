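"""Case-versus-control differential expression and upregulation filtering.

The engine is deliberately transparent: a two-sided Welch t test on
log2(x + 1) per gene, Benjamini-Hochberg adjustment across all tested genes,
and a linear-scale ratio-of-means fold change stabilized with a small
pseudo-value. Genes are called upregulated when the fold change is at least
``fc_threshold`` (default 1.5) and the FDR is strictly below
``fdr_threshold`` (default 0.05).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, SampleTable, ValidationError

__all__ = ["bh_adjust", "de_test", "filter_upregulated", "top_n_by_significance"]

#: pseudo-value added to both group means before taking their ratio, so that
#: genes silent in one group get a large-but-finite fold change.
FOLD_CHANGE_EPS = 0.01


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-D sequence")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def de_test(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    case_label: str,
    control_label: str,
) -> pd.DataFrame:
    """Per-gene differential expression between two sample groups.

    Returns a DataFrame indexed by gene id with columns ``fold_change``
    (linear case/control ratio of means), ``log2_fc``, ``p_value``, ``fdr``
    and ``upregulated`` (at the default 1.5 / 0.05 thresholds).
    """
    if matrix.value_kind not in ("rpkm", "relative"):
        raise ValidationError(
            f"de_test expects rpkm or relative values, got {matrix.value_kind!r}"
        )
    case_ids = [s for s in samples.ids_with_label(case_label) if s in set(matrix.sample_ids)]
    control_ids = [
        s for s in samples.ids_with_label(control_label) if s in set(matrix.sample_ids)
    ]
    if not case_ids and not samples.ids_with_label(case_label):
        raise ValidationError(f"unknown group label {case_label!r}")
    if not control_ids and not samples.ids_with_label(control_label):
        raise ValidationError(f"unknown group label {control_label!r}")
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValidationError(
            f"need >= 2 samples per group, got {len(case_ids)} {case_label!r} "
            f"vs {len(control_ids)} {control_label!r}"
        )
    case = matrix.values[:, [matrix.sample_index(s) for s in case_ids]]
    control = matrix.values[:, [matrix.sample_index(s) for s in control_ids]]

    fold = (case.mean(axis=1) + FOLD_CHANGE_EPS) / (
        control.mean(axis=1) + FOLD_CHANGE_EPS
    )
    with np.errstate(invalid="ignore"):
        t_res = stats.ttest_ind(
            np.log2(case + 1.0), np.log2(control + 1.0), axis=1, equal_var=False
        )
    p = np.asarray(t_res.pvalue, dtype=float)
    # genes constant in both groups have zero variance and undefined t; they
    # are by construction non-differential
    p = np.where(np.isnan(p), 1.0, p)
    fdr = bh_adjust(p)
    df = pd.DataFrame(
        {
            "fold_change": fold,
            "log2_fc": np.log2(fold),
            "p_value": p,
            "fdr": fdr,
        },
        index=pd.Index(matrix.gene_ids, name="gene"),
    )
    df["upregulated"] = (df["fold_change"] >= 1.5) & (df["fdr"] < 0.05)
    return df


def filter_upregulated(
    de: pd.DataFrame, fc_threshold: float = 1.5, fdr_threshold: float = 0.05
) -> set[str]:
    """Genes with fold change >= ``fc_threshold`` and FDR < ``fdr_threshold``.

    The fold-change comparison is inclusive and the FDR comparison strict.
    """
    if fc_threshold <= 0 or fdr_threshold <= 0:
        raise ValidationError("thresholds must be positive")
    mask = (de["fold_change"] >= fc_threshold) & (de["fdr"] < fdr_threshold)
    return set(de.index[mask])


def top_n_by_significance(
    de: pd.DataFrame,
    n: int = 100,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
) -> list[str]:
    """The ``n`` most significantly upregulated genes, in rank order.

    Ranking is by smallest p-value; ties break by larger fold change, then
    lexicographic gene id. If fewer than ``n`` genes pass the upregulation
    filter, all of them are returned.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    up = de.loc[sorted(filter_upregulated(de, fc_threshold, fdr_threshold))]
    ranked = up.assign(_gene=up.index.astype(str)).sort_values(
        by=["p_value", "fold_change", "_gene"], ascending=[True, False, True]
    )
    return list(ranked.index[:n])
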