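"""Tabular formats, identifier normalization, and container types.

Everything on disk is plain TSV (UTF-8, tab-separated, "." decimal; gzip
is handled transparently by pandas via the file extension) or JSON.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A file does not match its documented schema."""


# ---------------------------------------------------------------------------
# identifier normalization

_MP_GENE_RE = re.compile(r"^mp(?:[0-9]+|[uv])g[0-9]+", re.IGNORECASE)
_ISOFORM_SUFFIX_RE = re.compile(r"\.[0-9]+$")


def normalize_gene_id(raw: str, strip_isoform_suffix: bool = True) -> str:
    """Canonical form of a gene identifier.

    Annotation tools lower-case identifiers (Mercator emits ``mp1g00001.1``
    for ``Mp1g00001.1``), and transcript-level ids carry an isoform suffix
    ``.N``.  This single function is applied to every identifier read from
    disk: surrounding quotes/whitespace are stripped, liverwort-style ids
    get their canonical capitalization back, and (by default, configurable)
    the isoform suffix is removed so transcripts collapse to genes.
    """
    gid = raw.strip().strip("'\"")
    if strip_isoform_suffix:
        gid = _ISOFORM_SUFFIX_RE.sub("", gid)
    if _MP_GENE_RE.match(gid):
        gid = "M" + gid[1].lower() + gid[2:]
    return gid


# ---------------------------------------------------------------------------
# container types


@dataclass
class ExpressionMatrix:
    """TPM-like expression values (genes x samples) with sample metadata.

    ``values``: DataFrame indexed by gene, one column per sample id.
    ``metadata``: DataFrame with columns sample, condition, replicate, batch.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise SchemaError("expression matrix contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise SchemaError("expression values must be non-negative")
        if list(self.values.columns) != list(self.metadata["sample"]):
            raise SchemaError("sample metadata does not cover the matrix columns exactly")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, conditions) -> list[str]:
        wanted = set(conditions)
        return [
            s for s, c in zip(self.metadata["sample"], self.metadata["condition"]) if c in wanted
        ]


@dataclass
class AnnotationMap:
    """Gene-level annotations: functional bins, TF families, gene families."""

    gene_to_bins: dict[str, set[str]] = field(default_factory=dict)
    gene_to_tf_family: dict[str, str] = field(default_factory=dict)
    gene_to_family: dict[str, str] = field(default_factory=dict)

    def genes_in_bin(self, bin_code: str, universe=None) -> set[str]:
        genes = {g for g, bins in self.gene_to_bins.items() if bin_code in bins}
        if universe is not None:
            genes &= set(universe)
        return genes

    def bins(self) -> set[str]:
        out: set[str] = set()
        for bins in self.gene_to_bins.values():
            out |= bins
        return out


@dataclass(frozen=True)
class ReferenceNetwork:
    """Curated regulator -> target edges used to benchmark inferred networks."""

    edges: frozenset[tuple[str, str]]
    species: str = ""

    @property
    def regulators(self) -> set[str]:
        return {r for r, _ in self.edges}

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self.edges}


# ---------------------------------------------------------------------------
# readers / writers

_DE_COLUMNS = ("gene", "log2fc", "pvalue", "padj")


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    return df


def read_expression(values_path, metadata_path, strip_isoform_suffix: bool = True) -> ExpressionMatrix:
    """Read a genes-by-samples TPM matrix plus its sample-metadata table."""
    values_path = Path(values_path)
    try:
        # raw header first: pandas would silently mangle duplicate sample ids
        header = pd.read_csv(values_path, sep="\t", header=None, nrows=1).iloc[0].tolist()
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{values_path}: file is empty") from None
    sample_ids = [str(c) for c in header[1:]]
    dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
    if dups:
        raise SchemaError(f"{values_path}: duplicate sample id(s) {dups}")
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    if values.isna().any().any():
        raise SchemaError(f"{values_path}: NaN in expression values")
    values.index = [normalize_gene_id(g, strip_isoform_suffix) for g in values.index]
    meta = _read_tsv(metadata_path, ("sample", "condition", "replicate", "batch"))
    return ExpressionMatrix(values=values, metadata=meta)


def write_expression(matrix: ExpressionMatrix, values_path, metadata_path) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="gene")
    matrix.metadata.to_csv(metadata_path, sep="\t", index=False)


def read_de_table(path, strip_isoform_suffix: bool = True) -> pd.DataFrame:
    """Read one differential-expression contrast (gene, log2fc, pvalue, padj)."""
    df = _read_tsv(path, _DE_COLUMNS)
    for col in ("log2fc", "padj"):
        if df[col].isna().any():
            raise SchemaError(f"{path}: NaN in required numeric column {col!r}")
    df = df.copy()
    df["gene"] = [normalize_gene_id(g, strip_isoform_suffix) for g in df["gene"]]
    return df


def write_de_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_mercator(path, strip_isoform_suffix: bool = True) -> AnnotationMap:
    """Read a Mercator X4 functional annotation (five single-quoted columns).

    Layout: BINCODE, NAME, IDENTIFIER, DESCRIPTION, TYPE.  Rows without an
    identifier describe the bin hierarchy itself and are skipped.  A gene may
    appear under several bins; identifiers are case-normalized.
    """
    path = Path(path)
    ann = AnnotationMap()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t", quotechar="'")
        header = next(reader, None)
        if header is None:
            raise SchemaError(f"{path}: file is empty")
        cols = [c.strip().strip("'\"").upper() for c in header]
        try:
            i_bin = cols.index("BINCODE")
            i_id = cols.index("IDENTIFIER")
        except ValueError as exc:
            raise SchemaError(f"{path}: missing required column {exc}") from None
        for row in reader:
            if len(row) <= max(i_bin, i_id):
                continue
            bincode = row[i_bin].strip().strip("'\"")
            ident = row[i_id].strip().strip("'\"")
            if not ident:
                continue
            if not all(part.isdigit() for part in bincode.split(".")):
                raise SchemaError(f"{path}: malformed bin code {bincode!r}")
            gene = normalize_gene_id(ident, strip_isoform_suffix)
            ann.gene_to_bins.setdefault(gene, set()).add(bincode)
    return ann


def read_edge_list(path, species: str = "", strip_isoform_suffix: bool = True) -> ReferenceNetwork:
    """Read a two-column regulator/target edge list; duplicates collapse."""
    df = _read_tsv(path, ("regulator", "target"))
    edges = frozenset(
        (
            normalize_gene_id(str(r), strip_isoform_suffix),
            normalize_gene_id(str(t), strip_isoform_suffix),
        )
        for r, t in zip(df["regulator"], df["target"])
    )
    return ReferenceNetwork(edges=edges, species=species)


def write_edge_list(net: ReferenceNetwork, path) -> None:
    df = pd.DataFrame(sorted(net.edges), columns=["regulator", "target"])
    df.to_csv(path, sep="\t", index=False)


def read_family_map(path, strip_isoform_suffix: bool = True) -> AnnotationMap:
    """Read a gene -> gene-family/orthogroup table (columns gene, family)."""
    df = _read_tsv(path, ("gene", "family"))
    if df["family"].isna().any():
        raise SchemaError(f"{path}: NaN in required column 'family'")
    ann = AnnotationMap()
    for g, fam in zip(df["gene"], df["family"]):
        ann.gene_to_family[normalize_gene_id(str(g), strip_isoform_suffix)] = str(fam)
    return ann


def write_family_map(ann: AnnotationMap, path) -> None:
    df = pd.DataFrame(sorted(ann.gene_to_family.items()), columns=["gene", "family"])
    df.to_csv(path, sep="\t", index=False)


def read_tf_table(path, strip_isoform_suffix: bool = True) -> AnnotationMap:
    """Read a gene -> TF-family table (columns gene, tf_family)."""
    df = _read_tsv(path, ("gene", "tf_family"))
    ann = AnnotationMap()
    for g, fam in zip(df["gene"], df["tf_family"]):
        ann.gene_to_tf_family[normalize_gene_id(str(g), strip_isoform_suffix)] = str(fam)
    return ann


def write_tf_table(ann: AnnotationMap, path) -> None:
    df = pd.DataFrame(sorted(ann.gene_to_tf_family.items()), columns=["gene", "tf_family"])
    df.to_csv(path, sep="\t", index=False)


def read_degsets(path) -> dict[str, dict[str, set[str]]]:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return {
        cond: {"up": set(d["up"]), "down": set(d["down"])} for cond, d in raw.items()
    }


def write_degsets(degsets: dict[str, dict[str, set[str]]], path) -> None:
    payload = {
        cond: {"up": sorted(d["up"]), "down": sorted(d["down"])} for cond, d in degsets.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset, tuple)):
            return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, default=_default)
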