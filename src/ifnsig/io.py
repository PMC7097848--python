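"""Readers and writers for expression matrices, sample tables and GMT files.

File conventions
----------------
* Expression matrix: dense TSV/CSV, genes in rows, first column gene ids,
  header row sample ids. Delimiter is chosen from the extension
  (``.tsv``/``.txt`` -> tab, ``.csv`` -> comma).
* Gene lengths: two-column TSV ``gene_id<TAB>length_bp``.
* Sample table: delimited table with ``sample_id``, ``group``, ``cohort``
  columns, an optional ``subtype`` column, and any further columns parsed as
  tri-state clinical flags (``1/0/yes/no/true/false/NA``).
* Module library: Broad-dialect GMT (name, description, member genes,
  tab-separated, one module per line).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import (
    ExpressionMatrix,
    ModuleLibrary,
    SampleTable,
    ValidationError,
    parse_flag_token,
)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_lengths",
    "read_sample_table",
    "write_sample_table",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
]


def _delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_gene_lengths(path: str | Path) -> dict[str, int]:
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path), header=None, comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: gene length file needs two columns")
    lengths: dict[str, int] = {}
    for gene, length in zip(df.iloc[:, 0], df.iloc[:, 1]):
        gene = str(gene)
        if gene in lengths:
            raise ValidationError(f"{path}: duplicate gene id {gene!r}")
        lengths[gene] = int(length)
    return lengths


def read_expression_matrix(
    path: str | Path,
    value_kind: str,
    lengths_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a dense gene x sample expression table.

    Duplicate gene or sample ids, negative cells and (for counts with a
    lengths file) genes without a length raise :class:`ValidationError`
    naming the offender.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path), index_col=0)
    lengths = read_gene_lengths(lengths_path) if lengths_path is not None else None
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        value_kind=value_kind,
        gene_lengths=lengths,
    )


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.to_frame().rename_axis("gene_id").to_csv(path, sep=_delimiter(path))


def read_sample_table(path: str | Path) -> SampleTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path), dtype=str, keep_default_na=False)
    required = {"sample_id", "group", "cohort"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise ValidationError(f"{path}: empty sample table")
    flag_cols = [c for c in df.columns if c not in required | {"subtype"}]
    sample_ids = [str(s) for s in df["sample_id"]]
    flags = {
        col: {
            s: parse_flag_token(tok) for s, tok in zip(sample_ids, df[col])
        }
        for col in flag_cols
    }
    return SampleTable(
        sample_ids=sample_ids,
        group=list(df["group"]),
        cohort=list(df["cohort"]),
        subtype=list(df["subtype"]) if "subtype" in df.columns else None,
        flags=flags,
    )


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    path = Path(path)
    df = samples.to_frame().reset_index()
    for name in samples.flags:
        df[name] = [
            "NA" if v is None else ("1" if v else "0") for v in df[name]
        ]
    df.to_csv(path, sep=_delimiter(path), index=False)


def read_gmt(path: str | Path) -> ModuleLibrary:
    """Read a GMT module library; duplicate genes within a line are dropped."""
    path = Path(path)
    modules: dict[str, frozenset[str]] = {}
    annotations: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >= 3"
                )
            name, description, *genes = fields
            if name in modules:
                raise ValidationError(
                    f"{path}: duplicate module name {name!r} at line {lineno}"
                )
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise ValidationError(f"{path}: module {name!r} has no genes")
            modules[name] = frozenset(genes)
            annotations[name] = description
    return ModuleLibrary(modules=modules, annotations=annotations)


def write_gmt(library: ModuleLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in library.items():
            description = library.annotations.get(name, "")
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    """One gene id per line; blank lines and ``#`` comments ignored."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.add(g)
    return genes


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
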