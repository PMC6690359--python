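"""Readers and writers for every external format the pipeline touches.

Formats handled here:

* protein quantification tables (TSV): accession, gene symbol, heavy/light
  abundance ratio, peptide count;
* gene sets (Broad-style GMT): one set per line, tab-separated
  ``name<TAB>description<TAB>member...``;
* protein--protein interaction edge tables (STRING-style TSV) with a
  confidence score per edge, either already on the unit interval
  (``unit`` dialect) or on STRING's 0--1000 export scale (``string_1000``);
* sparse single-cell count matrices (MatrixMarket triplet plus gene / cell
  label TSVs, with a per-cell condition column);
* signature report TSVs (the combined cross-experiment output).

All text readers transparently accept gzip-compressed files.  Gene symbols
are the universal key throughout the pipeline: they are upper-cased on
load, and an optional accession-to-symbol mapping table can be applied when
the quantification table lacks a symbol column.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, UsageError

__all__ = [
    "ProteinQuantRecord",
    "RatioTable",
    "LoadReport",
    "GeneSet",
    "SingleCellMatrix",
    "CONDITIONS",
    "read_ratio_table",
    "write_ratio_table",
    "read_gmt",
    "write_gmt",
    "read_ppi_edges",
    "write_ppi_edges",
    "read_signature",
    "write_signature",
    "read_singlecell",
    "write_singlecell",
]

#: Canonical cell-condition tags of the antigen-stimulation single-cell design:
#: CMV pp65 tetramer-positive/-negative, PRAME tetramer-positive/-negative,
#: and unstimulated (nonreactive) T cells.
CONDITIONS = ("cmv_pos", "cmv_neg", "prame_pos", "prame_neg", "nonreactive")

SEARCH_DBS = ("swissprot", "uniprot", "other")


def _open_text(path: str | Path, mode: str = "rt"):
    """Open a text file, transparently decompressing ``.gz``."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# quantification tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinQuantRecord:
    """One protein's heavy/light quantification from one database search.

    The ratio is the heavy/light isotope abundance ratio of the pooled
    comparison (dimensionless, strictly positive); ``peptide_count`` is the
    number of peptides supporting the quantification.
    """

    accession: str
    gene_symbol: str
    ratio: float
    peptide_count: int = 0
    search_db: str = "swissprot"

    def __post_init__(self) -> None:
        if self.ratio <= 0 or not math.isfinite(self.ratio):
            raise ValueError(f"ratio must be finite and > 0, got {self.ratio}")
        if self.peptide_count < 0:
            raise ValueError("peptide_count must be >= 0")
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")


@dataclass(frozen=True)
class LoadReport:
    """Row-level accounting from a quantification-table load."""

    n_rows: int = 0
    n_kept: int = 0
    n_dropped_ratio: int = 0
    n_unmapped: int = 0
    n_duplicates_collapsed: int = 0


@dataclass
class RatioTable:
    """Protein-level heavy/light ratios for one pooled experiment.

    Records are keyed by ``(gene_symbol, search_db)``; at most one record per
    key.
    """

    experiment_id: str
    records: dict[tuple[str, str], ProteinQuantRecord] = field(default_factory=dict)
    load_report: LoadReport | None = None

    def __eq__(self, other: object) -> bool:  # load_report excluded: metadata
        if not isinstance(other, RatioTable):
            return NotImplemented
        return (self.experiment_id == other.experiment_id
                and self.records == other.records)

    def add(self, record: ProteinQuantRecord) -> None:
        key = (record.gene_symbol, record.search_db)
        if key in self.records:
            raise ValueError(f"duplicate record for {key}")
        self.records[key] = record

    def genes(self) -> set[str]:
        return {g for g, _ in self.records}

    def __len__(self) -> int:
        return len(self.records)


_DEFAULT_QUANT_COLUMNS = {
    "accession": "accession",
    "gene_symbol": "gene_symbol",
    "ratio": "ratio",
    "peptide_count": "peptide_count",
}


def read_ratio_table(
    path: str | Path,
    experiment_id: str,
    search_db: str = "swissprot",
    columns: Mapping[str, str] | None = None,
    accession_map: Mapping[str, str] | str | Path | None = None,
) -> RatioTable:
    """Load a TSV quantification table into a :class:`RatioTable`.

    Parameters
    ----------
    path:
        Tab-separated file with a header row.  The column layout of
        supplement-style tables varies, so ``columns`` maps the logical names
        ``accession``, ``gene_symbol``, ``ratio``, ``peptide_count`` to the
        actual header names.  ``peptide_count`` is optional (defaults to 0);
        ``gene_symbol`` may be omitted when ``accession_map`` is supplied.
    accession_map:
        Either a mapping or a 2-column TSV (accession, symbol) applied at
        load.  When given, it overrides any symbol column; unmapped
        accessions are dropped and counted in the load report.

    Rows with a non-positive or unparsable ratio are dropped (counted in the
    load report).  Duplicate gene symbols within a search database are
    collapsed keeping the record with the larger peptide count (ties broken
    by larger ratio).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(_DEFAULT_QUANT_COLUMNS)
    if columns:
        cols.update(columns)

    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and df.columns.size == 0:
        raise FormatError(f"{path}: empty table")

    mandatory = ["accession", "ratio"]
    if accession_map is None:
        mandatory.append("gene_symbol")
    for logical in mandatory:
        if cols[logical] not in df.columns:
            raise FormatError(f"{path}: missing mandatory column '{cols[logical]}'")

    if isinstance(accession_map, (str, Path)):
        mdf = pd.read_csv(accession_map, sep="\t", header=None, dtype=str)
        if mdf.shape[1] < 2:
            raise FormatError(f"{accession_map}: accession map needs 2 columns")
        accession_map = dict(zip(mdf.iloc[:, 0], mdf.iloc[:, 1]))

    n_rows = len(df)
    # to_numeric only masks unparsable cells; values come from exact parsing
    # (pandas' fast csv float parser is not round-trip safe)
    parsable = pd.to_numeric(df[cols["ratio"]], errors="coerce").notna()
    ratios = pd.Series(np.nan, index=df.index, dtype=float)
    ratios[parsable] = df.loc[parsable, cols["ratio"]].astype(float)
    ok = ratios.notna() & (ratios > 0) & np.isfinite(ratios)
    n_dropped_ratio = int((~ok).sum())
    df = df[ok].copy()
    df["_ratio"] = ratios[ok]

    if cols["peptide_count"] in df.columns:
        pep = pd.to_numeric(df[cols["peptide_count"]], errors="coerce")
        df["_pep"] = pep.fillna(0).clip(lower=0).astype(int)
    else:
        df["_pep"] = 0

    n_unmapped = 0
    if accession_map is not None:
        symbols = df[cols["accession"]].map(accession_map)
        n_unmapped = int(symbols.isna().sum())
        df = df[symbols.notna()].copy()
        df["_symbol"] = symbols[symbols.notna()].str.upper()
    else:
        symbols = df[cols["gene_symbol"]].astype(str).str.strip()
        empty = (symbols == "") | symbols.isna()
        n_unmapped = int(empty.sum())
        df = df[~empty].copy()
        df["_symbol"] = symbols[~empty].str.upper()

    if df.empty:
        raise FormatError(f"{path}: no usable rows after parsing")

    # dedup: best-supported quantification wins (peptide count, then ratio)
    df = df.sort_values(["_symbol", "_pep", "_ratio"], kind="mergesort")
    deduped = df.drop_duplicates("_symbol", keep="last")
    n_dup = len(df) - len(deduped)

    table = RatioTable(experiment_id=experiment_id)
    for _, row in deduped.iterrows():
        table.add(ProteinQuantRecord(
            accession=str(row[cols["accession"]]),
            gene_symbol=str(row["_symbol"]),
            ratio=float(row["_ratio"]),
            peptide_count=int(row["_pep"]),
            search_db=search_db,
        ))
    table.load_report = LoadReport(
        n_rows=n_rows,
        n_kept=len(table),
        n_dropped_ratio=n_dropped_ratio,
        n_unmapped=n_unmapped,
        n_duplicates_collapsed=n_dup,
    )
    return table


def write_ratio_table(path: str | Path, table: RatioTable) -> None:
    """Serialize a :class:`RatioTable` to TSV (one row per record)."""
    rows = sorted(table.records.values(), key=lambda r: (r.gene_symbol, r.search_db))
    with _open_text(path, "wt") as fh:
        fh.write("accession\tgene_symbol\tratio\tpeptide_count\n")
        for r in rows:
            fh.write(f"{r.accession}\t{r.gene_symbol}\t{r.ratio!r}\t{r.peptide_count}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named gene set (exclusion list or other-disease penalty list)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a Broad-dialect GMT file: ``name<TAB>description<TAB>member...``.

    Member symbols are upper-cased and deduplicated within each line; set
    order is preserved.  A data line with fewer than three fields raises
    :class:`FormatError` with its line number.
    """
    sets: list[GeneSet] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 "
                                  f"tab-separated fields, got {len(fields)}")
            members = frozenset(m.strip().upper() for m in fields[2:] if m.strip())
            if not members:
                raise FormatError(f"{path}: line {lineno}: set has no members")
            sets.append(GeneSet(fields[0], fields[1], members))
    return sets


def write_gmt(path: str | Path, sets: Sequence[GeneSet]) -> None:
    with _open_text(path, "wt") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# PPI edge tables
# ---------------------------------------------------------------------------

def read_ppi_edges(
    path: str | Path,
    score_dialect: str = "unit",
    columns: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Read a STRING-style edge table into an undirected confidence graph.

    Each edge carries a ``confidence`` attribute in [0, 1] — the probability
    that the interaction exists given the available evidence.  The
    ``string_1000`` dialect divides scores by 1000 before storing (STRING
    file exports use a 0--1000 integer scale); the dialect is explicit and
    never guessed from the data, to avoid silent thousand-fold errors.

    Self-loops are silently dropped; duplicate unordered pairs are collapsed
    keeping the maximum confidence.  A score outside [0, 1] after
    normalization raises :class:`FormatError`.
    """
    if score_dialect not in ("unit", "string_1000"):
        raise FormatError(f"unknown score dialect {score_dialect!r}")
    cols = {"gene_a": "gene_a", "gene_b": "gene_b", "score": "score"}
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for logical in ("gene_a", "gene_b", "score"):
        if cols[logical] not in df.columns:
            raise FormatError(f"{path}: missing mandatory column '{cols[logical]}'")
    if pd.to_numeric(df[cols["score"]], errors="coerce").isna().any():
        raise FormatError(f"{path}: unparsable score values")
    scores = df[cols["score"]].astype(float)  # exact round-trip parsing
    if score_dialect == "string_1000":
        scores = scores / 1000.0
    if ((scores < 0) | (scores > 1)).any():
        bad = scores[(scores < 0) | (scores > 1)].iloc[0]
        raise FormatError(f"{path}: confidence {bad} outside [0, 1] "
                          f"after {score_dialect} normalization")
    graph = nx.Graph()
    a = df[cols["gene_a"]].astype(str).str.upper()
    b = df[cols["gene_b"]].astype(str).str.upper()
    for ga, gb, conf in zip(a, b, scores.astype(float)):
        if ga == gb:
            continue
        if graph.has_edge(ga, gb):
            if conf > graph[ga][gb]["confidence"]:
                graph[ga][gb]["confidence"] = conf
        else:
            graph.add_edge(ga, gb, confidence=conf)
    return graph


def write_ppi_edges(path: str | Path, graph: nx.Graph,
                    score_dialect: str = "unit") -> None:
    """Write a confidence graph back to an edge TSV."""
    with _open_text(path, "wt") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for a, b, data in sorted(graph.edges(data=True),
                                 key=lambda e: tuple(sorted(e[:2]))):
            a, b = sorted((a, b))
            conf = data["confidence"]
            if score_dialect == "string_1000":
                fh.write(f"{a}\t{b}\t{conf * 1000:.6g}\n")
            else:
                fh.write(f"{a}\t{b}\t{conf!r}\n")


# ---------------------------------------------------------------------------
# signature reports
# ---------------------------------------------------------------------------

_SIG_SCORE_FIELDS = ("experiment_id", "ratio", "connectivity", "relevance",
                     "penalty_hits", "penalty_factor", "final_score")


def write_signature(path: str | Path, signature) -> None:
    """Write a combined cross-experiment signature to a TSV report.

    Rows are sorted by descending combined score, ties broken alphabetically
    by gene symbol.  The per-experiment score chains (ratio, connectivity,
    relevance, penalty, final) are serialized in full so that the report
    round-trips losslessly through :func:`read_signature`.
    """
    if not signature.entries:
        raise UsageError("refusing to write an empty signature")
    header = ["gene", "combined_score", "provenance"]
    for prefix in ("a", "b"):
        header += [f"{prefix}_{f}" for f in _SIG_SCORE_FIELDS]
    order = sorted(signature.entries.values(),
                   key=lambda e: (-e.combined_score, e.gene))
    with _open_text(path, "wt") as fh:
        fh.write("#experiments\t" + "\t".join(signature.experiment_ids) + "\n")
        fh.write("\t".join(header) + "\n")
        for entry in order:
            by_exp = {s.experiment_id: s for s in entry.scores}
            row = [entry.gene, repr(entry.combined_score), entry.provenance]
            for exp_id in signature.experiment_ids:
                s = by_exp.get(exp_id)
                if s is None:
                    row += [""] * len(_SIG_SCORE_FIELDS)
                else:
                    row += [s.experiment_id, repr(s.ratio), repr(s.connectivity),
                            repr(s.relevance), str(s.penalty_hits),
                            repr(s.penalty_factor), repr(s.final_score)]
            fh.write("\t".join(row) + "\n")


def read_signature(path: str | Path):
    """Read a signature report written by :func:`write_signature`."""
    from .scoring import CandidateScore, CombinedSignature, SignatureEntry

    with _open_text(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#experiments\t"):
            raise FormatError(f"{path}: missing #experiments header line")
        experiment_ids = tuple(first.split("\t")[1:])
        header = fh.readline().rstrip("\n").split("\t")
        n_fields = len(_SIG_SCORE_FIELDS)
        entries: dict[str, SignatureEntry] = {}
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            gene, combined, provenance = cells[0], float(cells[1]), cells[2]
            scores = []
            for block in range(2):
                chunk = cells[3 + block * n_fields: 3 + (block + 1) * n_fields]
                if not chunk or chunk[0] == "":
                    continue
                scores.append(CandidateScore(
                    gene=gene,
                    experiment_id=chunk[0],
                    ratio=float(chunk[1]),
                    connectivity=float(chunk[2]),
                    relevance=float(chunk[3]),
                    penalty_hits=int(chunk[4]),
                    penalty_factor=float(chunk[5]),
                    final_score=float(chunk[6]),
                ))
            entries[gene] = SignatureEntry(gene=gene, combined_score=combined,
                                           provenance=provenance,
                                           scores=tuple(scores))
    return CombinedSignature(entries=entries, experiment_ids=experiment_ids)


# ---------------------------------------------------------------------------
# single-cell count matrices
# ---------------------------------------------------------------------------

@dataclass
class SingleCellMatrix:
    """Sparse gene-by-cell count matrix with per-cell condition labels."""

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix  # genes x cells, non-negative integers
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError("counts shape does not match gene/cell labels")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        missing = [c for c in self.cells if c not in self.condition_of]
        if missing:
            raise ValueError(f"cells without condition label: {missing[:3]}...")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.cells:
            cond = self.condition_of[c]
            if cond not in seen:
                seen.append(cond)
        return seen

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SingleCellMatrix):
            return NotImplemented
        return (self.genes == other.genes and self.cells == other.cells
                and self.condition_of == other.condition_of
                and (self.counts != other.counts).nnz == 0)


def write_singlecell(out_dir: str | Path, matrix: SingleCellMatrix) -> None:
    """Write an MTX triplet: ``matrix.mtx``, ``genes.tsv``, ``cells.tsv``.

    ``cells.tsv`` carries two columns: cell identifier and condition tag.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"), matrix.counts.tocoo(),
                     field="integer")
    (out_dir / "genes.tsv").write_text("".join(g + "\n" for g in matrix.genes))
    with open(out_dir / "cells.tsv", "w") as fh:
        for c in matrix.cells:
            fh.write(f"{c}\t{matrix.condition_of[c]}\n")


def read_singlecell(in_dir: str | Path) -> SingleCellMatrix:
    """Read the MTX triplet written by :func:`write_singlecell`."""
    in_dir = Path(in_dir)
    mtx_path = in_dir / "matrix.mtx"
    if not mtx_path.exists():
        raise FileNotFoundError(mtx_path)
    counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    genes = (in_dir / "genes.tsv").read_text().splitlines()
    cells, condition_of = [], {}
    for line in (in_dir / "cells.tsv").read_text().splitlines():
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{in_dir / 'cells.tsv'}: expected 2 columns")
        cells.append(fields[0])
        condition_of[fields[0]] = fields[1]
    return SingleCellMatrix(genes=genes, cells=cells, counts=counts,
                            condition_of=condition_of)
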