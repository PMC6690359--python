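"""Expression-category classification of signature genes in T-cell scRNA-seq.

The signature derived from plasma proteomics is checked against single-cell
RNA profiles of T cells sorted and stimulated by a tumor antigen (PRAME)
versus a viral antigen (CMV pp65).  Each gene is classified by where it is
detected:

* ``prame_specific`` — expressed in PRAME-stimulated T cells but not
  CMV-stimulated ones (candidate antitumoral marker);
* ``general_activation`` — expressed in both antigen-stimulated
  populations (generic T-cell activation);
* ``cmv_specific`` — expressed only in CMV-stimulated cells;
* ``not_expressed`` — detected in no condition.

"Expressed" is operationalized as the detection fraction (share of cells
with a nonzero count) reaching a threshold ``theta`` in that condition.
The classifier is deliberately simple and isolated behind this module's
surface so a differential-expression-based rule can replace it.  The
overlap summary reports the category partition of a signature and the
share of signature genes expressed in T cells at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, UsageError
from .io_formats import CONDITIONS, SingleCellMatrix

__all__ = ["CategoryAssignment", "OverlapSummary", "CATEGORIES",
           "detection_fractions", "classify_genes", "overlap_summary"]

CATEGORIES = ("prame_specific", "general_activation", "cmv_specific",
              "not_expressed")


@dataclass
class CategoryAssignment:
    """Per-gene expression category plus the fractions it was derived from.

    ``flagged`` lists genes detected only in antigen-negative or nonreactive
    cells: they map to ``not_expressed`` (not expressed in *activated*
    cells) but deserve a second look.
    """

    category_of: dict[str, str]
    fractions: pd.DataFrame
    theta: float
    flagged: frozenset[str] = field(default_factory=frozenset)

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for cat in self.category_of.values():
            out[cat] += 1
        return out


@dataclass(frozen=True)
class OverlapSummary:
    """Category partition of a signature plus the expressed-in-T-cells share."""

    counts: dict[str, int]
    total_genes: int
    total_expressed: int
    percentage_expressed: int  # nearest integer percent
    missing_genes: int = 0


def detection_fractions(matrix: SingleCellMatrix,
                        conditions: Sequence[str] | None = None) -> pd.DataFrame:
    """Fraction of cells with a nonzero count, per gene and condition.

    Returns a genes x conditions DataFrame of values in [0, 1].  Every
    requested condition (default: the five canonical antigen-stimulation
    conditions) must have at least one cell.
    """
    conditions = list(conditions) if conditions is not None else list(CONDITIONS)
    cell_conds = np.array([matrix.condition_of[c] for c in matrix.cells])
    detected = (matrix.counts > 0)
    out = pd.DataFrame(index=list(matrix.genes), columns=conditions, dtype=float)
    for cond in conditions:
        mask = cell_conds == cond
        n = int(mask.sum())
        if n == 0:
            raise UsageError(f"condition {cond!r} has no cells")
        out[cond] = np.asarray(detected[:, mask].sum(axis=1)).ravel() / n
    return out


def classify_genes(fractions: pd.DataFrame, theta: float = 0.1) -> CategoryAssignment:
    """Assign each gene an expression category from its detection fractions.

    A gene counts as expressed in a condition when its detection fraction is
    at least ``theta``.  Categories follow from expression in the two
    antigen-positive conditions (``prame_pos``, ``cmv_pos``); genes
    expressed only in negative or nonreactive cells are classified
    ``not_expressed`` and flagged.
    """
    if not 0 < theta < 1:
        raise ConfigError(f"theta must be in (0, 1), got {theta}")
    for needed in ("prame_pos", "cmv_pos"):
        if needed not in fractions.columns:
            raise UsageError(f"fractions table lacks condition {needed!r}")
    category_of: dict[str, str] = {}
    flagged = set()
    for gene, row in fractions.iterrows():
        in_prame = row["prame_pos"] >= theta
        in_cmv = row["cmv_pos"] >= theta
        if in_prame and in_cmv:
            category_of[gene] = "general_activation"
        elif in_prame:
            category_of[gene] = "prame_specific"
        elif in_cmv:
            category_of[gene] = "cmv_specific"
        else:
            category_of[gene] = "not_expressed"
            others = [c for c in fractions.columns if c not in ("prame_pos", "cmv_pos")]
            if any(row[c] >= theta for c in others):
                flagged.add(gene)
    return CategoryAssignment(category_of=category_of, fractions=fractions,
                              theta=theta, flagged=frozenset(flagged))


def overlap_summary(signature, assignment: CategoryAssignment) -> OverlapSummary:
    """Partition a signature's genes by expression category.

    ``signature`` may be a combined cross-experiment signature object or any
    iterable of gene symbols.  Genes without an assignment are counted as
    ``not_expressed`` with a warning.  ``total_expressed`` is the number of
    signature genes in any expressed category and ``percentage_expressed``
    its share of the signature, rounded to the nearest integer percent.
    """
    if hasattr(signature, "entries"):
        genes = list(signature.entries)
    else:
        genes = list(signature)
    if not genes:
        raise UsageError("signature is empty")
    counts = {c: 0 for c in CATEGORIES}
    missing = 0
    for g in genes:
        cat = assignment.category_of.get(g)
        if cat is None:
            missing += 1
            cat = "not_expressed"
        counts[cat] += 1
    if missing:
        warnings.warn(f"{missing} signature genes had no expression assignment; "
                      "counted as not_expressed", stacklevel=2)
    total = len(genes)
    expressed = total - counts["not_expressed"]
    pct = int(round(100.0 * expressed / total))
    return OverlapSummary(counts=counts, total_genes=total,
                          total_expressed=expressed,
                          percentage_expressed=pct, missing_genes=missing)
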