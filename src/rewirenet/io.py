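"""Readers and writers for the external file formats of the pipeline.

Expression matrices, probe annotations, sample sheets, cancer-gene lists,
PPI edge lists, GMT pathway collections and curated signaling-link tables
are all plain TSV/text.  Everything is parsed into pandas / plain-Python
containers, canonicalized (sorted gene order, unordered pairs, no
self-loops) so that downstream stages are deterministic regardless of the
row order of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

CONDITIONS = ("PB", "PT", "RB", "RT")
PARENTAL = ("PB", "PT")
RESISTANT = ("RB", "RT")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered gene pair as a lexicographically sorted tuple."""
    return (a, b) if a <= b else (b, a)


@dataclass
class ExpressionMatrix:
    """Gene-level expression, genes x samples, with condition labels.

    ``values`` holds one row per gene symbol and one column per sample.
    ``conditions`` maps each sample to one of PB/PT/RB/RT (parental /
    resistant, basal / treatment) and ``replicates`` to a positive
    replicate index.
    """

    values: pd.DataFrame
    conditions: pd.Series
    replicates: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][:5].tolist()
            raise FormatError(f"duplicate gene symbols: {dup}")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        if self.values.size == 0:
            raise FormatError("empty expression matrix")
        missing = [s for s in self.values.columns if s not in self.conditions.index]
        if missing:
            raise FormatError(f"samples without condition label: {missing[:5]}")
        bad = set(self.conditions.loc[list(self.values.columns)]) - set(CONDITIONS)
        if bad:
            raise FormatError(f"unknown condition labels: {sorted(bad)}")
        arr = self.values.to_numpy()
        if not pd.notna(arr).all() or not pd.DataFrame(arr).apply(
            lambda c: pd.api.types.is_numeric_dtype(c)
        ).all():
            raise FormatError("expression values must be finite numbers")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, conditions: Iterable[str]) -> list[str]:
        want = set(conditions)
        return [s for s in self.samples if self.conditions[s] in want]

    def subset_conditions(self, conditions: Iterable[str]) -> "ExpressionMatrix":
        cols = self.samples_for(conditions)
        return ExpressionMatrix(
            self.values[cols],
            self.conditions.loc[cols],
            self.replicates.loc[cols],
        )

    def condition_mean(self, gene: str, condition: str) -> float:
        """Mean expression of ``gene`` over the replicates of one condition."""
        cols = self.samples_for([condition])
        if not cols:
            raise KeyError(f"no samples for condition {condition}")
        return float(self.values.loc[gene, cols].mean())


def read_sample_sheet(path: str | Path) -> tuple[pd.Series, pd.Series]:
    """Sidecar TSV (sample_id, condition, replicate) -> label series."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    for col in ("sample_id", "condition", "replicate"):
        if col not in df.columns:
            raise FormatError(f"sample sheet missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in sample sheet")
    df = df.set_index("sample_id")
    return df["condition"], df["replicate"].astype(int)


def read_probe_annotation(path: str | Path) -> dict[str, str]:
    """TSV (probe_id, gene_symbol) -> probe->gene mapping (a function)."""
    df = pd.read_csv(path, sep="\t", dtype=str).iloc[:, :2]
    df.columns = ["probe_id", "gene_symbol"]
    df = df.dropna()
    df["probe_id"] = df["probe_id"].str.strip()
    df["gene_symbol"] = df["gene_symbol"].str.strip()
    df = df[df["gene_symbol"] != ""]
    if df["probe_id"].duplicated().any():
        raise FormatError("probe annotation maps a probe to several genes")
    return dict(zip(df["probe_id"], df["gene_symbol"]))


def read_expression(
    path: str | Path,
    conditions: pd.Series,
    replicates: pd.Series,
    annotation: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a probe- or gene-level expression TSV.

    The first column holds probe/gene identifiers, the header row the
    sample ids.  With an ``annotation``, probe rows are mapped to gene
    symbols, unmapped probes dropped, and multi-probe genes collapsed to
    the arithmetic mean of their probes.  Gene order is lexicographic.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.has_duplicates:
        raise FormatError("duplicate sample ids in expression header")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric expression cell: {exc}") from exc
    df.index = df.index.astype(str).str.strip()
    if annotation is not None:
        genes = df.index.to_series().map(dict(annotation))
        df = df[genes.notna().to_numpy()]
        if df.empty:
            raise FormatError("no probes mapped to genes")
        df = df.groupby(genes.dropna().to_numpy()).mean()
    else:
        if df.index.has_duplicates:
            raise FormatError("duplicate gene symbols in gene-level matrix")
    df = df.sort_index()
    return ExpressionMatrix(df, conditions, replicates)


def read_gene_list(path: str | Path) -> set[str]:
    """Plain-text gene list, one symbol per line; blanks ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        sym = line.strip()
        if sym:
            out.add(sym)
    return out


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file: name <tab> description <tab> gene ... per line.

    Duplicate genes within a set are deduplicated; empty sets rejected.
    """
    collection: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FormatError(f"malformed GMT line {lineno}: fewer than 2 fields")
        name = fields[0].strip()
        genes = {g.strip() for g in fields[2:] if g.strip()}
        if not genes:
            raise FormatError(f"empty gene set {name!r} at line {lineno}")
        collection[name] = genes
    return collection


def read_ppi(path: str | Path) -> set[tuple[str, str]]:
    """PPI edge list TSV (gene_a, gene_b); canonical unordered pairs."""
    return read_link_network(path)


def read_link_network(path: str | Path) -> set[tuple[str, str]]:
    """TSV of gene pairs (source, target[, type...]).

    Pairs are canonicalized to unordered form, self-loops dropped and
    duplicates merged; extra columns (relation type, sign) are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.empty:
        raise FormatError("empty link network file")
    if df.shape[1] < 2:
        raise FormatError("link network needs >=2 columns")
    first = str(df.iloc[0, 0]).lower()
    if first in {"source", "gene_a", "from"}:  # tolerate a header row
        df = df.iloc[1:]
    pairs = set()
    for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]):
        a, b = str(a).strip(), str(b).strip()
        if not a or not b or a == b:
            continue
        pairs.add(canonical_pair(a, b))
    return pairs


# ---------------------------------------------------------------------------
# writers (all tables sorted lexicographically by gene pair for determinism)


def write_pairs(path: str | Path, pairs: Iterable[tuple[str, str]]) -> None:
    rows = sorted(canonical_pair(*p) for p in pairs)
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False
    )


def write_expression(path: str | Path, expr: ExpressionMatrix) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def write_sample_sheet(path: str | Path, expr: ExpressionMatrix) -> None:
    pd.DataFrame(
        {
            "sample_id": expr.samples,
            "condition": [expr.conditions[s] for s in expr.samples],
            "replicate": [int(expr.replicates[s]) for s in expr.samples],
        }
    ).to_csv(path, sep="\t", index=False)


def write_gene_sets(path: str | Path, collection: Mapping[str, set[str]]) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection):
            genes = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\tna\t{genes}\n")
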