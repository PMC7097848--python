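"""In-memory containers for expression data, sample metadata and gene sets.

All downstream stages (scoring, differential expression, enrichment,
stratification) consume these validated containers, so malformed data is
rejected at construction time and never propagates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "GeneSignature",
    "ModuleLibrary",
    "ValidationError",
]

VALUE_KINDS = ("counts", "rpkm", "relative")


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


@dataclass
class ExpressionMatrix:
    """A gene x sample grid of non-negative expression values.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique row and column identifiers.
    values
        Array of shape ``(len(gene_ids), len(sample_ids))`` with values >= 0.
        When ``value_kind == "counts"`` values must be integral.
    value_kind
        One of ``"counts"`` (raw read counts), ``"rpkm"`` (reads per kilobase
        per million mapped reads) or ``"relative"`` (e.g. qPCR fold changes).
    gene_lengths
        Optional mapping gene id -> transcript length in base pairs; required
        to convert counts to RPKM and must then cover every gene.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    value_kind: str
    gene_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValidationError(f"duplicate gene id: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if np.any(self.values < 0):
            g, s = map(int, np.argwhere(self.values < 0)[0])
            raise ValidationError(
                f"negative value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if self.value_kind == "counts" and not np.allclose(
            self.values, np.round(self.values)
        ):
            raise ValidationError("counts must be integers")
        if self.gene_lengths is not None:
            missing = [g for g in self.gene_ids if g not in self.gene_lengths]
            if missing:
                raise ValidationError(
                    f"gene_lengths missing for {len(missing)} genes, "
                    f"first: {missing[0]!r}"
                )
            bad = [g for g in self.gene_ids if self.gene_lengths[g] <= 0]
            if bad:
                raise ValidationError(f"non-positive gene length for {bad[0]!r}")

    # -- convenience accessors -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in matrix") from None

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, idx],
            value_kind=self.value_kind,
            gene_lengths=dict(self.gene_lengths) if self.gene_lengths else None,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


_FLAG_TRUE = {"1", "yes", "true"}
_FLAG_FALSE = {"0", "no", "false"}
_FLAG_MISSING = {"na"}


def parse_flag_token(token: object) -> bool | None:
    """Map a clinical-flag token to True / False / None (missing)."""
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return None
    if isinstance(token, (bool, np.bool_)):
        return bool(token)
    s = str(token).strip().lower()
    if s in _FLAG_TRUE:
        return True
    if s in _FLAG_FALSE:
        return False
    if s in _FLAG_MISSING or s == "":
        return None
    raise ValidationError(f"unrecognized clinical flag token: {token!r}")


@dataclass
class SampleTable:
    """Per-sample group membership, cohort and binary clinical flags.

    ``group`` is the case/control axis; ``subtype`` carries the free-form
    clinical label (GPP, PV, CAPS, healthy, ...). Flags are tri-state:
    True, False or None (missing); missing values are dropped pairwise from
    downstream contingency tables.
    """

    sample_ids: list[str]
    group: list[str]
    cohort: list[str]
    subtype: list[str] | None = None
    flags: dict[str, dict[str, bool | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sample_ids) == 0:
            raise ValidationError("sample table is empty")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValidationError(f"duplicate sample id: {dup!r}")
        n = len(self.sample_ids)
        if len(self.group) != n or len(self.cohort) != n:
            raise ValidationError("group/cohort length does not match sample_ids")
        bad = sorted(set(self.group) - {"case", "control"})
        if bad:
            raise ValidationError(f"group must be 'case' or 'control', got {bad[0]!r}")
        if self.subtype is None:
            self.subtype = list(self.group)
        elif len(self.subtype) != n:
            raise ValidationError("subtype length does not match sample_ids")
        for name, values in self.flags.items():
            unknown = sorted(set(values) - set(self.sample_ids))
            if unknown:
                raise ValidationError(
                    f"flag {name!r} refers to unknown sample {unknown[0]!r}"
                )
            for v in values.values():
                if v is not None and not isinstance(v, (bool, np.bool_)):
                    raise ValidationError(
                        f"flag {name!r} has non-boolean value {v!r}"
                    )

    def __len__(self) -> int:
        return len(self.sample_ids)

    def ids_with_label(self, label: str) -> list[str]:
        """Samples whose group or subtype equals ``label``."""
        return [
            s
            for s, g, t in zip(self.sample_ids, self.group, self.subtype)
            if g == label or t == label
        ]

    def flag_values(self, flag: str) -> dict[str, bool]:
        """Non-missing values of a flag, keyed by sample id."""
        if flag not in self.flags:
            raise KeyError(f"unknown clinical flag {flag!r}")
        return {s: v for s, v in self.flags[flag].items() if v is not None}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "group": self.group,
                "subtype": self.subtype,
                "cohort": self.cohort,
            }
        ).set_index("sample_id")
        for name, values in self.flags.items():
            df[name] = [values.get(s) for s in self.sample_ids]
        return df


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered list of unique gene identifiers.

    Gene identifiers are opaque, case-sensitive strings (no alias mapping).
    """

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(str(g) for g in self.genes))
        if len(self.genes) < 1:
            raise ValidationError(f"signature {self.name!r} has no genes")
        dup = _first_duplicate(self.genes)
        if dup is not None:
            raise ValidationError(
                f"duplicate gene {dup!r} in signature {self.name!r}"
            )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ModuleLibrary:
    """A collection of named gene modules (gene sets), as read from GMT."""

    modules: dict[str, frozenset[str]]
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.modules.items():
            if len(genes) == 0:
                raise ValidationError(f"module {name!r} is empty")
            self.modules[name] = frozenset(str(g) for g in genes)

    def __len__(self) -> int:
        return len(self.modules)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.modules[name]

    def items(self):
        return self.modules.items()
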