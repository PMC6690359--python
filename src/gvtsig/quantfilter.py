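"""Candidate selection from heavy/light abundance ratios.

The first two processing steps of the pipeline: keep proteins upregulated in
the heavy-labeled pool (heavy/light ratio strictly greater than a fold
threshold, 1.2 by default) and then remove proteins that appear in
GVHD-specific or common-protein exclusion gene sets.  The threshold is a
strict inequality — a protein quantified at exactly the threshold does not
pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import ConfigError
from .io_formats import GeneSet, RatioTable

__all__ = ["CandidateSet", "filter_by_ratio", "exclude_genesets"]

MODES = ("any_db", "primary_db")


@dataclass
class CandidateSet:
    """Ordered set of upregulated candidate genes for one experiment.

    ``genes`` is ordered by descending selection ratio, ties alphabetical.
    ``ratio_of`` stores, per gene, the maximum ratio among the database
    searches in which it passed; ``provenance`` records those databases.
    ``exclusion_report`` maps exclusion-set name to the number of candidates
    it removed (populated by :func:`exclude_genesets`).
    """

    experiment_id: str
    genes: tuple[str, ...]
    ratio_of: dict[str, float]
    provenance: dict[str, frozenset[str]]
    exclusion_report: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("candidate genes must be unique")
        if set(self.genes) != set(self.ratio_of):
            raise ValueError("ratio_of must cover exactly the candidate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.ratio_of


def _order(ratio_of: dict[str, float]) -> tuple[str, ...]:
    return tuple(sorted(ratio_of, key=lambda g: (-ratio_of[g], g)))


def filter_by_ratio(table: RatioTable, threshold: float = 1.2,
                    mode: str = "any_db") -> CandidateSet:
    """Select genes whose heavy/light ratio strictly exceeds ``threshold``.

    ``mode="any_db"`` admits a gene that passes in at least one database
    search and records which; ``mode="primary_db"`` considers only
    swissprot-tagged records.  An empty table yields an empty candidate set.
    """
    if threshold <= 0:
        raise ConfigError(f"threshold must be > 0, got {threshold}")
    if mode not in MODES:
        raise ConfigError(f"mode must be one of {MODES}, got {mode!r}")

    ratio_of: dict[str, float] = {}
    provenance: dict[str, set[str]] = {}
    for (gene, db), record in table.records.items():
        if mode == "primary_db" and db != "swissprot":
            continue
        if record.ratio > threshold:
            if gene not in ratio_of or record.ratio > ratio_of[gene]:
                ratio_of[gene] = record.ratio
            provenance.setdefault(gene, set()).add(db)
    return CandidateSet(
        experiment_id=table.experiment_id,
        genes=_order(ratio_of),
        ratio_of=ratio_of,
        provenance={g: frozenset(dbs) for g, dbs in provenance.items()},
    )


def exclude_genesets(candidates: CandidateSet,
                     exclusions: Sequence[GeneSet]) -> CandidateSet:
    """Remove candidates found in any exclusion gene set.

    Returns a new :class:`CandidateSet` whose ``exclusion_report`` counts,
    per exclusion set, how many of the input candidates were members (a gene
    in several sets is counted in each).  An empty exclusion list is the
    identity.
    """
    excluded = set().union(*(s.members for s in exclusions)) if exclusions else set()
    report = {s.name: sum(1 for g in candidates.genes if g in s.members)
              for s in exclusions}
    kept = {g: r for g, r in candidates.ratio_of.items() if g not in excluded}
    return CandidateSet(
        experiment_id=candidates.experiment_id,
        genes=tuple(g for g in candidates.genes if g in kept),
        ratio_of=kept,
        provenance={g: p for g, p in candidates.provenance.items() if g in kept},
        exclusion_report=report,
    )
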