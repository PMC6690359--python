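"""Relevance, penalty and final scores, and cross-experiment combination.

Steps 4--6 of the pipeline.  Each candidate gene's heavy/light ratio is the
primary datum; the network and the disease-specificity penalties modulate
it multiplicatively:

* **connectivity** ``c(g)`` — the summed confidence of a core gene's retained
  subnetwork edges, normalized by the maximum over core genes, so
  ``c`` is in [0, 1];
* **relevance** ``relevance(g) = ratio(g) * (1 + alpha * c(g))`` — network
  support can at most multiply the ratio by ``1 + alpha``; ``alpha = 0``
  collapses relevance to the raw ratio;
* **penalty factor** ``1 / (1 + beta * k(g))`` where ``k(g)`` counts the
  other-disease gene sets containing ``g``; ``beta = 0`` switches penalties
  off.  A gene hit by two sets at ``beta = 0.5`` has its score halved;
* **final score** ``relevance * penalty_factor``.

Penalties re-rank but never remove: candidate-set membership is decided by
the ratio filter alone, and final scores below 1 are retained in the
signature.  Scores from two experiments are combined over the union of
their gene lists; genes found in both receive the geometric mean of their
final scores (scale-respecting for ratio-like quantities), singletons carry
their own final score, and provenance records which experiments contributed.

The multiplicative forms are deliberately isolated behind this module's
surface so an alternative scoring strategy can be swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, UsageError
from .io_formats import GeneSet
from .network import SubNetwork
from .quantfilter import CandidateSet

__all__ = [
    "CandidateScore",
    "SignatureEntry",
    "CombinedSignature",
    "connectivity_weights",
    "relevance_scores",
    "penalty_factors",
    "final_scores",
    "combine_experiments",
]


@dataclass(frozen=True)
class CandidateScore:
    """The full ratio -> relevance -> penalty -> final chain for one gene."""

    gene: str
    experiment_id: str
    ratio: float
    connectivity: float
    relevance: float
    penalty_hits: int
    penalty_factor: float
    final_score: float


@dataclass(frozen=True)
class SignatureEntry:
    gene: str
    combined_score: float
    provenance: str  # training_only | validation_only | both
    scores: tuple[CandidateScore, ...]


@dataclass
class CombinedSignature:
    """The cross-experiment signature: gene -> combined score + provenance."""

    entries: dict[str, SignatureEntry]
    experiment_ids: tuple[str, str]

    def __len__(self) -> int:
        return len(self.entries)

    def genes(self) -> list[str]:
        return sorted(self.entries)

    def strata_counts(self) -> dict[str, int]:
        """Counts of combined scores above, below, and exactly at 1."""
        above = sum(1 for e in self.entries.values() if e.combined_score > 1)
        below = sum(1 for e in self.entries.values() if e.combined_score < 1)
        return {"above_1": above, "below_1": below,
                "equal_1": len(self.entries) - above - below}

    def ranked_genes(self) -> list[str]:
        """Genes by descending combined score, ties alphabetical."""
        return [e.gene for e in sorted(self.entries.values(),
                                       key=lambda e: (-e.combined_score, e.gene))]


def connectivity_weights(sub: SubNetwork) -> dict[str, float]:
    """Normalized network support for each core gene.

    ``raw(g)`` sums the confidences of retained edges from core gene ``g``
    to any retained node (core or outer); weights are ``raw / max(raw)``
    over core genes, or all zero when no core gene has an edge.  Outer
    genes receive no weight — they contribute context, not candidates.
    """
    if not sub.core_genes:
        raise UsageError("subnetwork has no core genes")
    raw = {}
    for g in sub.core_genes:
        if g in sub.graph:
            raw[g] = sum(d["confidence"] for _, _, d in sub.graph.edges(g, data=True))
        else:
            raw[g] = 0.0
    top = max(raw.values())
    if top == 0:
        return {g: 0.0 for g in raw}
    return {g: v / top for g, v in raw.items()}


def relevance_scores(candidates: CandidateSet, weights: Mapping[str, float],
                     alpha: float = 1.0) -> dict[str, float]:
    """``relevance(g) = ratio(g) * (1 + alpha * c(g))``; missing weight is 0."""
    if alpha < 0:
        raise ConfigError(f"alpha must be >= 0, got {alpha}")
    return {g: candidates.ratio_of[g] * (1.0 + alpha * weights.get(g, 0.0))
            for g in candidates.genes}


def penalty_factors(genes: Iterable[str], penalty_library: Sequence[GeneSet],
                    beta: float = 0.5) -> dict[str, tuple[int, float]]:
    """Per gene: (number of penalty sets containing it, score multiplier).

    ``factor = 1 / (1 + beta * hits)``; ``beta = 0`` turns every factor into
    1, reproducing a no-penalty run without touching the candidate list.
    """
    if beta < 0:
        raise ConfigError(f"beta must be >= 0, got {beta}")
    out = {}
    for g in genes:
        k = sum(1 for s in penalty_library if g in s.members)
        out[g] = (k, 1.0 / (1.0 + beta * k))
    return out


def final_scores(candidates: CandidateSet, weights: Mapping[str, float],
                 penalties: Mapping[str, tuple[int, float]],
                 alpha: float = 1.0) -> list[CandidateScore]:
    """Assemble the per-gene score chain, sorted by descending final score.

    ``penalties`` comes from :func:`penalty_factors` (which owns ``beta``);
    a gene absent from it is treated as unpenalized.  The without-penalty
    score is the ``relevance`` field of each record.
    """
    relevance = relevance_scores(candidates, weights, alpha)
    scores = []
    for g in candidates.genes:
        c = weights.get(g, 0.0)
        k, factor = penalties.get(g, (0, 1.0))
        rel = relevance[g]
        scores.append(CandidateScore(
            gene=g, experiment_id=candidates.experiment_id,
            ratio=candidates.ratio_of[g], connectivity=c, relevance=rel,
            penalty_hits=k, penalty_factor=factor, final_score=rel * factor,
        ))
    scores.sort(key=lambda s: (-s.final_score, s.gene))
    return scores


def combine_experiments(a: Sequence[CandidateScore], b: Sequence[CandidateScore],
                        method: str = "geometric") -> CombinedSignature:
    """Combine two experiments' score lists over the union of their genes.

    Genes scored in both experiments get the geometric (default) or
    arithmetic mean of their two final scores; genes found in only one
    carry that experiment's final score.  Provenance tags the first input
    as training and the second as validation.
    """
    if method not in ("geometric", "arithmetic"):
        raise ConfigError(f"unknown combination method {method!r}")
    if not a or not b:
        raise UsageError("both experiments must contribute at least one score")
    id_a = a[0].experiment_id
    id_b = b[0].experiment_id
    if id_a == id_b:
        raise UsageError(f"both inputs carry experiment_id {id_a!r}; "
                         "combination needs two distinct experiments")
    by_a = {s.gene: s for s in a}
    by_b = {s.gene: s for s in b}
    entries: dict[str, SignatureEntry] = {}
    for gene in set(by_a) | set(by_b):
        sa, sb = by_a.get(gene), by_b.get(gene)
        if sa is not None and sb is not None:
            if method == "geometric":
                combined = math.sqrt(sa.final_score * sb.final_score)
            else:
                combined = 0.5 * (sa.final_score + sb.final_score)
            entries[gene] = SignatureEntry(gene, combined, "both", (sa, sb))
        elif sa is not None:
            entries[gene] = SignatureEntry(gene, sa.final_score,
                                           "training_only", (sa,))
        else:
            entries[gene] = SignatureEntry(gene, sb.final_score,
                                           "validation_only", (sb,))
    return CombinedSignature(entries=entries, experiment_ids=(id_a, id_b))
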