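"""Readers, writers and run manifests shared by the pipeline stages.

TSV dialect throughout: tab-separated, UTF-8, "." decimal, NA token "NA".
Gene identifiers are case-sensitive; systematic ORF names are canonical.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .interactome import ProteinGroupTable
from .riprank import CountMatrix, TargetSet
from .setstats import GeneSet, AnnotationTable

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_design",
    "read_protein_groups",
    "write_protein_groups",
    "import_xlsx_table",
    "read_gene_set",
    "write_gene_set",
    "read_annotation",
    "RunManifest",
]

NA = "NA"


class IOValidationError(ValueError):
    pass


#: default MaxQuant proteinGroups.txt column mapping
DEFAULT_PG_COLUMNS = {
    "id": "Protein IDs",
    "lfq_prefix": "LFQ intensity ",
    "razor_unique": "Razor + unique peptides",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
}


def read_design(path: str | Path) -> pd.DataFrame:
    """Design TSV with columns sample, condition (or group), replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns:
        raise IOValidationError(f"design file {path} lacks a 'sample' column")
    return df


def read_count_matrix(
    path: str | Path, design: str | Path | pd.DataFrame, format: str = "plain_tsv"
) -> CountMatrix:
    """Load a counts TSV plus design into a validated CountMatrix.

    ``format="plain_tsv"``: first column gene id, remaining columns samples.
    ``format="featurecounts"``: native featureCounts layout (comment lines
    starting with '#', columns Geneid/Chr/Start/End/Strand/Length then
    samples); column 1 and columns 7+ are taken.
    """
    if format not in ("plain_tsv", "featurecounts"):
        raise IOValidationError(f"unknown count matrix format {format!r}")
    df = pd.read_csv(path, sep="\t", comment="#" if format == "featurecounts" else None)
    if format == "featurecounts":
        if df.shape[1] < 7:
            raise IOValidationError(
                f"featureCounts table {path} has {df.shape[1]} columns; expected >= 7"
            )
        df = pd.concat([df.iloc[:, [0]], df.iloc[:, 6:]], axis=1)
    gene_ids = df.iloc[:, 0].astype(str).tolist()
    dup = df.iloc[:, 0][df.iloc[:, 0].duplicated()].unique().tolist()
    if dup:
        raise IOValidationError(f"duplicate gene ids in {path}: {', '.join(map(str, dup))}")
    mat = df.iloc[:, 1:]
    samples = [str(c) for c in mat.columns]
    values = mat.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise IOValidationError(f"non-numeric counts in {path}")
    if np.any(values < 0) or not np.allclose(values, np.round(values)):
        raise IOValidationError(f"counts in {path} must be non-negative integers")
    if not isinstance(design, pd.DataFrame):
        design = read_design(design)
    design = design.set_index("sample")
    missing = [s for s in samples if s not in design.index]
    if missing:
        raise IOValidationError(f"samples missing from design: {', '.join(missing)}")
    cond_col = "condition" if "condition" in design.columns else "group"
    condition = [str(design.loc[s, cond_col]) for s in samples]
    replicate = [int(design.loc[s, "replicate"]) for s in samples]
    return CountMatrix(gene_ids, values.astype(np.int64), samples, condition, replicate)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")


def read_protein_groups(
    path: str | Path,
    design: str | Path | pd.DataFrame,
    column_map: dict[str, str] | None = None,
) -> ProteinGroupTable:
    """Load a proteinGroups-style TSV into a validated ProteinGroupTable.

    LFQ columns are selected by prefix; "+" in the reverse/contaminant
    columns parses to True (MaxQuant convention). Raises naming the column
    when a mapped column is absent or the prefix matches nothing.
    """
    cmap = {**DEFAULT_PG_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path, sep="\t")
    for key in ("id", "razor_unique"):
        if cmap[key] not in df.columns:
            raise IOValidationError(f"missing mapped column {cmap[key]!r} in {path}")
    lfq_cols = [c for c in df.columns if c.startswith(cmap["lfq_prefix"])]
    if not lfq_cols:
        raise IOValidationError(
            f"LFQ prefix {cmap['lfq_prefix']!r} matches no columns in {path}"
        )
    samples = [c[len(cmap["lfq_prefix"]):] for c in lfq_cols]

    def plus_flag(col: str) -> np.ndarray:
        if col not in df.columns:
            return np.zeros(len(df), bool)
        return df[col].astype(str).str.strip().eq("+").to_numpy()

    if not isinstance(design, pd.DataFrame):
        design = read_design(design)
    design = design.set_index("sample")
    missing = [s for s in samples if s not in design.index]
    if missing:
        raise IOValidationError(f"samples missing from design: {', '.join(missing)}")
    grp_col = "group" if "group" in design.columns else "condition"
    group = [str(design.loc[s, grp_col]) for s in samples]
    return ProteinGroupTable(
        group_ids=df[cmap["id"]].astype(str).tolist(),
        values=df[lfq_cols].to_numpy(float),
        samples=samples,
        group=group,
        razor_unique_peptides=df[cmap["razor_unique"]].to_numpy(int),
        reverse_flag=plus_flag(cmap["reverse"]),
        contaminant_flag=plus_flag(cmap["contaminant"]),
    )


def write_protein_groups(
    table: ProteinGroupTable, path: str | Path, column_map: dict[str, str] | None = None
) -> None:
    """Write the internal table back to the proteinGroups-style TSV layout."""
    cmap = {**DEFAULT_PG_COLUMNS, **(column_map or {})}
    df = pd.DataFrame({cmap["id"]: table.group_ids})
    df[cmap["razor_unique"]] = table.razor_unique_peptides
    df[cmap["reverse"]] = np.where(table.reverse_flag, "+", "")
    df[cmap["contaminant"]] = np.where(table.contaminant_flag, "+", "")
    for j, s in enumerate(table.samples):
        df[cmap["lfq_prefix"] + s] = table.values[:, j]
    df.to_csv(path, sep="\t", index=False, na_rep=NA)


def import_xlsx_table(
    path: str | Path,
    sheet: str | int = 0,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read one worksheet, optionally renaming columns via ``column_map``.

    ``column_map`` maps source column name -> canonical name; a missing
    source column is an error naming it. Used to ingest supplementary
    workbooks (e.g. an enrichment table whose log2FoldChange/pvalue columns
    feed Vfactor selection).
    """
    try:
        df = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    except ValueError as e:
        raise IOValidationError(f"cannot read sheet {sheet!r} from {path}: {e}") from e
    if column_map:
        missing = [c for c in column_map if c not in df.columns]
        if missing:
            raise IOValidationError(
                f"columns missing from {path}: {', '.join(missing)}"
            )
        df = df.rename(columns=column_map)
    return df


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """One gene id per line; blank lines and '#' comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return GeneSet.from_iterable(name or Path(path).stem, genes)


def write_gene_set(ts: TargetSet | GeneSet, path: str | Path) -> None:
    genes = ts.gene_ids if isinstance(ts, TargetSet) else sorted(ts.genes)
    Path(path).write_text("\n".join(genes) + "\n")


def read_annotation(path: str | Path, universe: GeneSet | None = None) -> AnnotationTable:
    """Two-column TSV (gene, category) -> AnnotationTable.

    Without an explicit universe, the universe is the set of genes listed.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "category"], dtype=str)
    if universe is None:
        universe = GeneSet.from_iterable("universe", df["gene"].unique())
    cats = {
        name: GeneSet.from_iterable(name, sub["gene"])
        for name, sub in df.groupby("category")
    }
    return AnnotationTable(universe=universe, categories=cats)


class RunManifest:
    """Reproducibility record: command, parameters, input digests, seed."""

    def __init__(self, command: str, parameters: dict, seed: int | None = None):
        self.command = command
        self.parameters = parameters
        self.seed = seed
        self.input_digests: dict[str, str] = {}

    def add_input(self, path: str | Path) -> None:
        h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.input_digests[str(path)] = h

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "parameters": _jsonable(self.parameters),
            "seed": self.seed,
            "input_digests": self.input_digests,
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str))
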