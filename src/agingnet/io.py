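"""Readers and writers for every on-disk format the pipeline touches.

Supported dialects
------------------
* count matrix: TSV, first column gene id, header row of sample ids;
  optional companion TSV of gene lengths (gene_id, length_bp) and a
  required TSV of group labels (sample_id, group).
* BioGRID TAB: a minimal required-column subset of the tab2 format
  (Official Symbol Interactor A/B, Organism Interactor A/B); any extra
  columns are carried along but ignored.
* PSI-MITAB: 15+ tab-separated columns; gene symbols are taken from the
  alias columns (precedence: an alias tagged ``(gene name)``, then one
  tagged ``(display_short)``), taxids from columns 10/11.
* GMT annotation sets, SIF and GraphML network exports, TSV result tables.

Gene symbols are canonicalized to uppercase for matching; the original
casing is preserved for display.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

BIOGRID = "BIOGRID"
INTACT = "INTACT"
OTHER = "OTHER"


class ParseError(ValueError):
    """A file violated the documented dialect."""


class ValidationError(ValueError):
    """Parsed content violated a container invariant."""


def canonical_symbol(symbol: str) -> str:
    """Uppercase form used for all matching and joins."""
    return symbol.strip().upper()


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order-independent key for an undirected symbol pair."""
    ca, cb = canonical_symbol(a), canonical_symbol(b)
    return (ca, cb) if ca <= cb else (cb, ca)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene x sample read counts with gene lengths and sample group labels.

    Attributes
    ----------
    counts : pandas.DataFrame
        Nonnegative integer counts, index = gene ids, columns = sample ids.
    gene_length_bp : pandas.Series
        Positive transcript length in base pairs per gene, same index.
    group_of : dict
        Sample id -> group label, covering every sample.
    """

    counts: pd.DataFrame
    gene_length_bp: pd.Series
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {', '.join(map(str, dupes))}")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        missing = [s for s in self.counts.columns if s not in self.group_of]
        if missing:
            raise ValidationError(f"samples without group label: {', '.join(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts")
        lengths = self.gene_length_bp.reindex(self.counts.index)
        if lengths.isna().any():
            absent = lengths.index[lengths.isna()]
            raise ValidationError(
                f"genes without length: {', '.join(map(str, absent[:5]))}"
            )
        if (lengths <= 0).any():
            raise ValidationError("non-positive gene length")
        self.gene_length_bp = lengths.astype(int)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]


@dataclass(frozen=True)
class InteractionRecord:
    """One database edge: a gene-symbol pair with species and provenance."""

    symbol_a: str
    symbol_b: str
    taxid_a: str
    taxid_b: str
    source_db: str = OTHER
    evidence: str = ""
    pubmed_id: str | None = None

    def __post_init__(self) -> None:
        if not self.symbol_a or not self.symbol_b:
            raise ValidationError("interaction record with empty gene symbol")

    @property
    def pair_key(self) -> tuple[str, str]:
        return canonical_pair(self.symbol_a, self.symbol_b)

    @property
    def intra_species(self) -> bool:
        return self.taxid_a == self.taxid_b


@dataclass
class AnnotationCollection:
    """Named annotation terms, each a description plus a gene-symbol set."""

    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def add(self, term: str, description: str, genes: Iterable[str]) -> None:
        if term in self.terms:
            raise ValidationError(f"duplicate term name: {term}")
        gene_set = frozenset(canonical_symbol(g) for g in genes)
        if not gene_set:
            raise ValidationError(f"term {term!r} has an empty gene set")
        self.terms[term] = (description, gene_set)

    def genes(self, term: str) -> frozenset[str]:
        return self.terms[term][1]

    def __iter__(self):
        return iter(self.terms)

    def __len__(self) -> int:
        return len(self.terms)


# ---------------------------------------------------------------------------
# count matrix I/O
# ---------------------------------------------------------------------------


def read_count_matrix(
    path: str | Path,
    groups_path: str | Path,
    lengths_path: str | Path | None = None,
) -> CountMatrix:
    """Read a TSV count matrix plus group labels (and optional lengths).

    The matrix file holds gene ids in the first column and one column per
    sample; if ``lengths_path`` is omitted the matrix must contain a
    ``length`` column immediately after the gene id.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected gene id column plus samples")
    gene_col = df.columns[0]
    dup = df[gene_col][df[gene_col].duplicated()]
    if not dup.empty:
        raise ParseError(f"{path}: duplicated gene row(s): {', '.join(dup.unique())}")
    df = df.set_index(gene_col)

    if lengths_path is not None:
        ldf = pd.read_csv(lengths_path, sep="\t", dtype=str).set_index(
            pd.read_csv(lengths_path, sep="\t", dtype=str).columns[0]
        )
        lengths = ldf.iloc[:, 0].astype(int)
        count_cols = [c for c in df.columns if c != "length"]
    elif "length" in df.columns:
        lengths = df["length"].astype(int)
        count_cols = [c for c in df.columns if c != "length"]
    else:
        raise ParseError(f"{path}: no lengths file given and no 'length' column")

    counts = pd.DataFrame(index=df.index)
    for col in count_cols:
        for lineno, raw in enumerate(df[col], start=2):
            if not re.fullmatch(r"\d+", str(raw)):
                raise ParseError(
                    f"{path}: non-integer count {raw!r} in column {col}, line {lineno}"
                )
        counts[col] = df[col].astype(int)

    group_of = read_group_labels(groups_path)
    return CountMatrix(counts=counts, gene_length_bp=lengths, group_of=group_of)


def read_group_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected columns sample_id, group")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    out = cm.counts.copy()
    out.insert(0, "length", cm.gene_length_bp)
    out.to_csv(path, sep="\t", index_label="gene_id")


def write_group_labels(group_of: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in group_of.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# BioGRID TAB dialect
# ---------------------------------------------------------------------------

_BIOGRID_REQUIRED = [
    "Official Symbol Interactor A",
    "Official Symbol Interactor B",
    "Organism Interactor A",
    "Organism Interactor B",
]


def read_biogrid_tab(path: str | Path) -> list[InteractionRecord]:
    """Parse a BioGRID TAB-dialect edge list into interaction records.

    Comment lines (starting ``#`` but not the header itself) are skipped.
    """
    path = Path(path)
    records: list[InteractionRecord] = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if header is None:
                # header may carry a leading '#'
                candidate = [fields[0].lstrip("#")] + fields[1:]
                if all(col in candidate for col in _BIOGRID_REQUIRED):
                    header = candidate
                    continue
                if line.startswith("#"):
                    continue
                raise ParseError(
                    f"{path}: missing required BioGRID columns "
                    f"{_BIOGRID_REQUIRED} in header"
                )
            if line.startswith("#"):
                continue
            row = dict(zip(header, fields))
            records.append(
                InteractionRecord(
                    symbol_a=row["Official Symbol Interactor A"],
                    symbol_b=row["Official Symbol Interactor B"],
                    taxid_a=row["Organism Interactor A"],
                    taxid_b=row["Organism Interactor B"],
                    source_db=BIOGRID,
                    evidence=row.get("Experimental System", ""),
                    pubmed_id=row.get("Pubmed ID") or None,
                )
            )
        if header is None:
            raise ParseError(f"{path}: no BioGRID header line found")
    return records


def write_biogrid_tab(records: Iterable[InteractionRecord], path: str | Path) -> None:
    cols = _BIOGRID_REQUIRED + ["Experimental System", "Pubmed ID"]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [r.symbol_a, r.symbol_b, r.taxid_a, r.taxid_b, r.evidence,
                     r.pubmed_id or "-"]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# PSI-MITAB dialect
# ---------------------------------------------------------------------------

_TAXID_RE = re.compile(r"taxid:(-?\d+)")
_GENE_NAME_RE = re.compile(r"[^:|]+:([^|(]+)\(gene name\)")
_SHORT_LABEL_RE = re.compile(r"[^:|]+:([^|(]+)\(display_short\)")


@dataclass
class MitabReport:
    """Per-file accounting of rows a lenient MITAB parse skipped."""

    rows: int = 0
    skipped_no_symbol: int = 0
    skipped_bad_taxid: int = 0


def _mitab_symbol(alias_field: str) -> str | None:
    m = _GENE_NAME_RE.search(alias_field)
    if m:
        return m.group(1).strip()
    m = _SHORT_LABEL_RE.search(alias_field)
    if m:
        return m.group(1).strip()
    return None


def read_mitab(
    path: str | Path, strict: bool = False
) -> tuple[list[InteractionRecord], MitabReport]:
    """Parse a PSI-MITAB file into interaction records plus a skip report.

    Rows lacking a gene-name alias for either interactor are skipped and
    counted; a malformed taxid field is skipped in lenient mode (default)
    and raises in strict mode.
    """
    path = Path(path)
    records: list[InteractionRecord] = []
    report = MitabReport()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 15:
                raise ParseError(
                    f"{path}: MITAB row with {len(fields)} columns (need >= 15)"
                )
            report.rows += 1
            sym_a = _mitab_symbol(fields[4]) or _mitab_symbol(fields[2])
            sym_b = _mitab_symbol(fields[5]) or _mitab_symbol(fields[3])
            if sym_a is None or sym_b is None:
                report.skipped_no_symbol += 1
                continue
            tax_a = _TAXID_RE.search(fields[9])
            tax_b = _TAXID_RE.search(fields[10])
            if tax_a is None or tax_b is None:
                if strict:
                    raise ParseError(f"{path}: malformed taxid field: {line[:80]!r}")
                report.skipped_bad_taxid += 1
                continue
            pubmed = None
            pm = re.search(r"pubmed:(\d+)", fields[8])
            if pm:
                pubmed = pm.group(1)
            records.append(
                InteractionRecord(
                    symbol_a=sym_a,
                    symbol_b=sym_b,
                    taxid_a=tax_a.group(1),
                    taxid_b=tax_b.group(1),
                    source_db=INTACT,
                    evidence=fields[6],
                    pubmed_id=pubmed,
                )
            )
    return records, report


def write_mitab(records: Iterable[InteractionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            row = [
                f"uniprotkb:{r.symbol_a}",
                f"uniprotkb:{r.symbol_b}",
                "-",
                "-",
                f"uniprotkb:{r.symbol_a}(gene name)",
                f"uniprotkb:{r.symbol_b}(gene name)",
                r.evidence or "-",
                "-",
                f"pubmed:{r.pubmed_id}" if r.pubmed_id else "-",
                f"taxid:{r.taxid_a}",
                f"taxid:{r.taxid_b}",
                "-",
                "psi-mi:intact",
                "-",
                "-",
            ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> AnnotationCollection:
    """Read a GMT file: one line per term = name, description, genes..."""
    path = Path(path)
    coll = AnnotationCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: GMT line {lineno} has {len(fields)} fields (need >= 3)"
                )
            coll.add(fields[0], fields[1], fields[2:])
    return coll


def write_gmt(coll: AnnotationCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in coll.terms.items():
            fh.write("\t".join([term, desc] + sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# network and table exports
# ---------------------------------------------------------------------------


def write_sif(net: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    """Write one 'A pp B' line per undirected edge; isolated nodes get a
    bare single-field line so they survive a Cytoscape import."""
    with open(path, "w") as fh:
        for a, b in sorted(canonical_pair(a, b) for a, b in net.edges()):
            fh.write(f"{a} {relation} {b}\n")
        for node in sorted(n for n in net.nodes() if net.degree(n) == 0):
            fh.write(f"{node}\n")


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    out = nx.Graph()
    for n, data in net.nodes(data=True):
        out.add_node(n, **{k: _graphml_scalar(v) for k, v in data.items()})
    for a, b, data in net.edges(data=True):
        out.add_edge(a, b, **{k: _graphml_scalar(v) for k, v in data.items()})
    nx.write_graphml(out, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def _graphml_scalar(value):
    # GraphML attributes must be scalars; sets/lists are joined
    if isinstance(value, (set, frozenset)):
        return "|".join(sorted(map(str, value)))
    if isinstance(value, (list, tuple)):
        return "|".join(map(str, value))
    return value


def write_gene_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_MINIMAL)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(value):
    if isinstance(value, (set, frozenset)):
        return sorted(value)
    raise TypeError(f"not JSON serializable: {type(value)}")
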