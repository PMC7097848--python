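"""Gene-set over-representation and overlap significance.

Two closely related questions are answered here:

* Is a query gene list (e.g. the upregulated genes of a cohort) enriched in
  any module of a co-expression module library? — :func:`module_enrichment`,
  a hypergeometric upper-tail test per module with BH adjustment across the
  tested modules.
* Is the overlap between two gene sets (a Venn intersection) larger than
  chance? — :func:`overlap_test`, the same hypergeometric tail confirmed by
  a seeded bootstrap that redraws one set uniformly from the universe.

The universe for both tests should be the set of genes actually detected in
the experiment, not the genome: the hypergeometric model describes draws
from the sampled frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ModuleLibrary, ValidationError
from .de import bh_adjust

__all__ = ["hypergeom_tail", "module_enrichment", "overlap_test", "OverlapResult"]


def hypergeom_tail(overlap: int, size_a: int, size_b: int, universe: int) -> float:
    """Upper-tail P(X >= overlap) for X ~ Hypergeometric(universe, size_a, size_b).

    The population has ``universe`` genes of which ``size_a`` are "successes";
    ``size_b`` genes are drawn without replacement.
    """
    overlap, size_a, size_b, universe = map(int, (overlap, size_a, size_b, universe))
    if universe < 0 or not (0 <= size_a <= universe) or not (0 <= size_b <= universe):
        raise ValidationError(
            f"inconsistent sizes: universe={universe}, a={size_a}, b={size_b}"
        )
    if overlap < 0 or overlap > min(size_a, size_b):
        raise ValidationError(
            f"overlap {overlap} outside [0, min({size_a}, {size_b})]"
        )
    if overlap == 0:
        return 1.0
    # survival function is evaluated in log space internally by scipy
    return float(stats.hypergeom.sf(overlap - 1, universe, size_a, size_b))


def module_enrichment(
    query: set[str], library: ModuleLibrary, universe: set[str]
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each library module.

    Modules are intersected with the universe before testing; modules with an
    empty intersection are skipped with a warning. Returns a DataFrame indexed
    by module name with columns ``overlap_count``, ``module_size`` (within the
    universe), ``p_value`` and ``fdr`` (BH across the tested modules), sorted
    by p-value.
    """
    query = set(query)
    universe = set(universe)
    stray = sorted(query - universe)
    if stray:
        raise ValidationError(
            f"{len(stray)} query genes outside the universe, first: {stray[:5]}"
        )
    rows = []
    for name, genes in library.items():
        in_universe = genes & universe
        if not in_universe:
            warnings.warn(
                f"module {name!r} has no genes in the universe; skipped",
                stacklevel=2,
            )
            continue
        k = len(query & in_universe)
        rows.append(
            {
                "module": name,
                "overlap_count": k,
                "module_size": len(in_universe),
                "p_value": hypergeom_tail(k, len(in_universe), len(query), len(universe)),
            }
        )
    df = pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame(
        columns=["overlap_count", "module_size", "p_value"]
    )
    df["fdr"] = bh_adjust(df["p_value"].to_numpy()) if len(df) else []
    return df.sort_values(["p_value", "module_size"]) if len(df) else df


@dataclass
class OverlapResult:
    """Observed overlap of two gene sets with hypergeometric and bootstrap p.

    ``bootstrap_p`` uses the add-one estimator
    ``(1 + #{resamples with overlap >= observed}) / (n_bootstrap + 1)`` and is
    therefore never exactly zero; its resolution is ``1/(n_bootstrap + 1)``.
    """

    size_a: int
    size_b: int
    universe_size: int
    intersection: int
    hypergeom_p: float
    bootstrap_p: float
    n_bootstrap: int
    seed: int


def overlap_test(
    set_a: set[str],
    set_b: set[str],
    universe: set[str],
    n_bootstrap: int = 10_000,
    seed: int = 0,
    symmetric: bool = False,
) -> OverlapResult:
    """Significance of the intersection of two gene sets.

    The bootstrap null redraws a size-matched ``set_a`` uniformly without
    replacement from the universe, holding ``set_b`` fixed (with
    ``symmetric=True`` both sets are redrawn), and counts resamples whose
    overlap reaches the observed one.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    for label, s in (("set_a", set_a), ("set_b", set_b)):
        stray = sorted(s - universe)
        if stray:
            raise ValidationError(
                f"{label} has genes outside the universe, first: {stray[:5]}"
            )
    if n_bootstrap < 100:
        raise ValidationError("n_bootstrap must be >= 100")
    observed = len(set_a & set_b)
    hyper_p = hypergeom_tail(observed, len(set_a), len(set_b), len(universe))

    rng = np.random.default_rng(seed)
    genes = np.array(sorted(universe))
    in_b = np.isin(genes, np.array(sorted(set_b)))
    n_u, n_a, n_b = len(genes), len(set_a), len(set_b)
    hits = 0
    for _ in range(n_bootstrap):
        idx = rng.choice(n_u, size=n_a, replace=False)
        if symmetric:
            idx_b = rng.choice(n_u, size=n_b, replace=False)
            mask = np.zeros(n_u, dtype=bool)
            mask[idx_b] = True
            k = int(mask[idx].sum())
        else:
            k = int(in_b[idx].sum())
        if k >= observed:
            hits += 1
    boot_p = (1 + hits) / (n_bootstrap + 1)
    return OverlapResult(
        size_a=n_a,
        size_b=n_b,
        universe_size=n_u,
        intersection=observed,
        hypergeom_p=hyper_p,
        bootstrap_p=boot_p,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )
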