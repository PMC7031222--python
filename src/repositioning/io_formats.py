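"""Readers and writers for every external format the pipeline touches.

Tabular dialect: tab-separated, UTF-8, header row mandatory for DE tables,
ortholog maps and instance annotations.  Gene-set files use GMT; matrices use
GCT 1.2 or plain TSV.  Gene-id matching is exact and case-sensitive
throughout — silent case-folding hides mapping bugs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "DETable",
    "OrthologMap",
    "ProfileMatrix",
    "read_gmt",
    "write_gmt",
    "read_profile_matrix",
    "write_profile_matrix",
    "read_annotations",
    "read_ortholog_map",
    "read_de_table",
    "write_results",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DETable:
    """One differential-expression contrast: gene, log2 fold change, adjusted p."""

    contrast_label: str
    table: pd.DataFrame  # columns: gene_id, log2fc, p_adj

    def __post_init__(self) -> None:
        t = self.table
        expected = ["gene_id", "log2fc", "p_adj"]
        if list(t.columns) != expected:
            raise ValidationError(
                f"DE table columns must be {expected}, got {list(t.columns)}"
            )
        if t["gene_id"].duplicated().any():
            dup = t.loc[t["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(
                f"duplicate gene id {dup!r} in DE table {self.contrast_label!r}"
            )
        if not np.isfinite(t["log2fc"].to_numpy()).all():
            raise ValidationError(f"non-finite log2fc in {self.contrast_label!r}")
        p = t["p_adj"].to_numpy()
        if not ((p >= 0) & (p <= 1)).all():
            raise ValidationError(f"p_adj outside [0, 1] in {self.contrast_label!r}")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class OrthologMap:
    """Source-to-target gene pairs; may be one-to-many in either direction."""

    pairs: pd.DataFrame  # columns: source_gene, target_gene

    def __post_init__(self) -> None:
        if list(self.pairs.columns) != ["source_gene", "target_gene"]:
            raise ValidationError(
                "ortholog map columns must be ['source_gene', 'target_gene']"
            )
        self.pairs = self.pairs.drop_duplicates(ignore_index=True)

    def targets_of(self, gene: str) -> list[str]:
        sel = self.pairs.loc[self.pairs["source_gene"] == gene, "target_gene"]
        return sel.tolist()

    def as_dict(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, t in self.pairs.itertuples(index=False):
            out.setdefault(s, []).append(t)
        return out

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ProfileMatrix:
    """Genes x treatment-instances matrix of scores or precomputed ranks.

    ``values[i, j]`` is the score (or rank) of ``gene_universe[i]`` in
    instance ``instances[j]``.  When ``is_ranks`` is true every column is a
    permutation of ``1..n`` with rank 1 = most up-regulated.
    """

    gene_universe: list[str]
    instances: list[str]
    values: np.ndarray
    annotations: pd.DataFrame  # columns: instance_id, compound_id, cell_line
    is_ranks: bool = False

    def __post_init__(self) -> None:
        n, m = self.values.shape
        if n != len(self.gene_universe) or m != len(self.instances):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_universe)} genes x {len(self.instances)} instances"
            )
        if len(set(self.gene_universe)) != n:
            raise ValidationError("gene universe contains duplicate ids")
        if len(set(self.instances)) != m:
            raise ValidationError("duplicate instance ids")
        ann = self.annotations
        if list(ann.columns) != ["instance_id", "compound_id", "cell_line"]:
            raise ValidationError(
                "annotations columns must be ['instance_id', 'compound_id', 'cell_line']"
            )
        if sorted(ann["instance_id"]) != sorted(self.instances):
            raise ValidationError(
                "every instance id must have exactly one annotation row"
            )
        if self.is_ranks:
            self._assert_rank_columns()

    def _assert_rank_columns(self) -> None:
        n = len(self.gene_universe)
        v = self.values
        for j in range(v.shape[1]):
            col = np.sort(v[:, j].astype(np.int64))
            if not np.array_equal(col, np.arange(1, n + 1)):
                raise ValidationError(
                    f"column {self.instances[j]!r} is not a permutation of 1..{n}"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_universe)

    def compound_of(self, instance_id: str) -> str:
        ann = self.annotations
        return ann.loc[ann["instance_id"] == instance_id, "compound_id"].iloc[0]


def _columns_are_permutations(values: np.ndarray) -> bool:
    n = values.shape[0]
    if not np.allclose(values, np.round(values)):
        return False
    ref = np.arange(1, n + 1)
    return all(
        np.array_equal(np.sort(values[:, j].astype(np.int64)), ref)
        for j in range(values.shape[1])
    )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[tuple[str, str, list[str]]]:
    """Read a GMT file into (set_name, description, genes) triples.

    Gene order is preserved; duplicate genes within a line are removed
    keeping the first occurrence.  Lines with fewer than 3 tab-separated
    fields are a format error.
    """
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            seen: dict[str, None] = {}
            for g in fields[2:]:
                if g and g not in seen:
                    seen[g] = None
            out.append((name, desc, list(seen)))
    return out


def write_gmt(
    signatures: Iterable[tuple[str, str, Sequence[str]]], path: str | Path
) -> None:
    """Write (set_name, description, genes) triples as GMT.

    Round-trips through :func:`read_gmt`.  Names must be non-empty and
    tab-free; an empty gene list still emits a 3-field line.
    """
    lines = []
    for name, desc, genes in signatures:
        if not name or "\t" in name:
            raise ValidationError(f"invalid gene-set name {name!r}")
        if "\t" in desc:
            raise ValidationError(f"description for {name!r} contains a tab")
        body = list(genes) if genes else [""]
        lines.append("\t".join([name, desc, *body]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# profile matrices (GCT 1.2 / TSV)
# ---------------------------------------------------------------------------

def _parse_matrix_body(
    header: list[str], rows: list[list[str]], path: str | Path
) -> tuple[list[str], list[str], np.ndarray]:
    instances = header[1:]
    genes, data = [], []
    for i, fields in enumerate(rows):
        if len(fields) != 1 + len(instances):
            raise FormatError(
                f"{path}: row {i + 1} has {len(fields)} fields, "
                f"expected {1 + len(instances)}"
            )
        genes.append(fields[0])
        vals = []
        for j, cell in enumerate(fields[1:]):
            try:
                vals.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell at row {i + 1}, column {j + 1}: {cell!r}"
                ) from None
        data.append(vals)
    return genes, instances, np.asarray(data, dtype=float)


def read_profile_matrix(
    path: str | Path,
    annotations: pd.DataFrame | str | Path,
    dialect: str = "gct",
    values_are_ranks: bool | None = None,
) -> ProfileMatrix:
    """Read a genes x instances matrix (GCT 1.2 or TSV) plus its annotations.

    ``values_are_ranks=None`` auto-detects: the matrix is treated as ranks
    iff every column is a permutation of ``1..n`` (override with an explicit
    boolean if a scores matrix happens to look like ranks).
    """
    if dialect not in ("gct", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    text = path.read_text(encoding="utf-8").splitlines()
    if dialect == "gct":
        if not text or text[0].strip() != "#1.2":
            raise FormatError(f"{path}: missing '#1.2' GCT version line")
        try:
            n_str, m_str = text[1].split("\t")[:2]
            n_decl, m_decl = int(n_str), int(m_str)
        except (IndexError, ValueError):
            raise FormatError(f"{path}: malformed GCT dimensions line") from None
        header = text[2].split("\t")
        if len(header) < 3 or header[0] != "Name":
            raise FormatError(f"{path}: malformed GCT header line")
        instances = header[2:]
        body = [ln.split("\t") for ln in text[3:] if ln]
        if len(body) != n_decl or len(instances) != m_decl:
            raise FormatError(
                f"{path}: dims line declares {n_decl} x {m_decl} but body has "
                f"{len(body)} rows x {len(instances)} columns"
            )
        genes, data = [], []
        for i, fields in enumerate(body):
            if len(fields) != 2 + m_decl:
                raise FormatError(f"{path}: row {i + 1} has {len(fields)} fields")
            genes.append(fields[0])  # Description column ignored
            try:
                data.append([float(c) for c in fields[2:]])
            except ValueError:
                raise FormatError(f"{path}: non-numeric cell in row {i + 1}") from None
        values = np.asarray(data, dtype=float)
    else:
        header = text[0].split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: TSV matrix needs a gene column + instances")
        instances = header[1:]
        rows = [ln.split("\t") for ln in text[1:] if ln]
        genes, instances, values = _parse_matrix_body(header, rows, path)

    if not isinstance(annotations, pd.DataFrame):
        annotations = read_annotations(annotations)
    if values_are_ranks is None:
        values_are_ranks = _columns_are_permutations(values)
    if values_are_ranks:
        values = values.astype(np.int64)
    return ProfileMatrix(
        gene_universe=genes,
        instances=list(instances),
        values=values,
        annotations=annotations,
        is_ranks=bool(values_are_ranks),
    )


def write_profile_matrix(pm: ProfileMatrix, path: str | Path) -> None:
    """Write a ProfileMatrix as GCT 1.2 (Description column written as 'na')."""
    n, m = pm.values.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#1.2\n")
        fh.write(f"{n}\t{m}\n")
        fh.write("\t".join(["Name", "Description", *pm.instances]) + "\n")
        fmt = (lambda v: str(int(v))) if pm.is_ranks else (lambda v: repr(float(v)))
        for i, g in enumerate(pm.gene_universe):
            fh.write("\t".join([g, "na", *(fmt(v) for v in pm.values[i])]) + "\n")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the instance annotation table (instance_id, compound_id, cell_line)."""
    df = _read_tsv(path, ["instance_id", "compound_id", "cell_line"])
    if df["instance_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate instance_id in annotations")
    return df


# ---------------------------------------------------------------------------
# small tables
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, columns: list[str]):
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file (header required)") from None
    if list(df.columns) != columns:
        raise FormatError(
            f"{path}: expected header {columns}, got {list(df.columns)}"
        )
    return df


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column source->target gene map (header required)."""
    df = _read_tsv(path, ["source_gene", "target_gene"])
    return OrthologMap(pairs=df)


def read_de_table(path: str | Path, contrast_label: str | None = None) -> DETable:
    """Read a three-column DE table (gene_id, log2fc, p_adj; header required)."""
    df = _read_tsv(path, ["gene_id", "log2fc", "p_adj"])
    for col in ("log2fc", "p_adj"):
        try:
            df[col] = df[col].astype(float)
        except ValueError:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()].iloc[0]
            raise FormatError(f"{path}: non-numeric {col} value {bad!r}") from None
    label = contrast_label if contrast_label is not None else Path(path).stem
    try:
        return DETable(contrast_label=label, table=df)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from None


RESULT_COLUMNS_PREFIX = ["compound_id", "direction"]
RESULT_COLUMNS_SUFFIX = ["meta_rp", "p_integrated", "q_fdr", "final_rank"]


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write an integrated-results table as TSV with fixed column order.

    Columns: compound, direction, one ``p:<signature>`` column per signature,
    meta statistic, integrated p, BH q, final rank.
    """
    sig_cols = [c for c in table.columns if c.startswith("p:")]
    ordered = RESULT_COLUMNS_PREFIX + sig_cols + RESULT_COLUMNS_SUFFIX
    missing = set(ordered) - set(table.columns)
    if missing:
        raise ValidationError(f"results table missing columns {sorted(missing)}")
    table[ordered].to_csv(path, sep="\t", index=False)
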