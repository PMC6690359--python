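"""Paired synthetic plasma-proteomics experiments with planted ground truth.

No public quantification tables exist for the paired-DLI design this
pipeline targets, so every stage is exercised against a generator that
emulates it: two pooled isotope-ratio experiments (a training and a
validation comparison) over a shared gene universe of

* **signature** genes — truly upregulated in the heavy (GVT-without-GVHD)
  pool of both experiments; their ratios are drawn from a LogNormal
  left-truncated at the 1.2 fold threshold, so the planted signal always
  passes the ratio filter and recovery tests measure specificity, not luck;
* **gvhd** confounders — ratios drawn from the same elevated distribution
  (they look like signal) but always present in at least one exclusion
  gene set, so the exclusion step should remove every one;
* **background** and **contaminant** genes — ratios LogNormal(0, sd),
  i.e. centered on no change; contaminants additionally populate the
  other-disease penalty library.

The interaction network is preferential-attachment (scale-free, like real
PPI networks) over the whole universe, with extra high-confidence edges
planted among signature genes so that the planted module is densely
connected — mirroring the clustered structure the scoring step rewards.
Penalty sets sample a small decoy fraction of background genes and never
contain signature genes (a config switch allows contaminated penalty sets
for robustness testing).

A companion generator emits a labeled single-cell count matrix over five
antigen-stimulation conditions with per-gene expression-category truth.

Everything is driven by one integer seed; the same seed reproduces the
bundle exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.stats import norm

from .errors import ConfigError, UsageError
from .io_formats import (CONDITIONS, GeneSet, ProteinQuantRecord, RatioTable,
                         SingleCellMatrix, write_gmt, write_ppi_edges,
                         write_ratio_table, write_singlecell)

__all__ = ["SimConfig", "TruthLabels", "SyntheticBundle",
           "generate_experiments", "generate_singlecell", "write_bundle"]

#: Default mix of single-cell truth categories (PRAME-specific, general
#: activation, CMV-specific, not expressed), matching the partition reported
#: for the 61-gene signature: 11/61, 32/61, 0, 18/61.
SC_CATEGORY_FRACTIONS = {
    "prame_specific": 11 / 61,
    "general_activation": 32 / 61,
    "cmv_specific": 0.0,
    "not_expressed": 18 / 61,
}

_EXPRESSED_IN = {
    "prame_specific": {"prame_pos"},
    "general_activation": {"cmv_pos", "prame_pos"},
    "cmv_specific": {"cmv_pos"},
    "not_expressed": set(),
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic paired-experiment design.

    Ratio parameters are on the natural-log scale: planted signature genes
    draw heavy/light ratios from LogNormal(``signature_ratio_logmean``,
    ``signature_ratio_logsd``) left-truncated at the fold threshold 1.2;
    null genes from LogNormal(0, ``background_ratio_logsd``).
    ``dropout_prob`` is the per-experiment chance that a protein is simply
    not identified in that run.
    """

    n_background: int = 700
    n_signature: int = 60
    n_gvhd: int = 80
    n_contaminant: int = 50
    signature_ratio_logmean: float = math.log(1.6)
    signature_ratio_logsd: float = 0.25
    background_ratio_logsd: float = 0.15
    dropout_prob: float = 0.15
    ppi_attach: int = 2
    planted_extra_edges: int = 120
    n_penalty_sets: int = 20
    penalty_decoy_frac: float = 0.05
    penalty_allow_signature: bool = False
    contaminant_penalty_prob: float = 0.5
    n_exclusion_sets: int = 2
    ratio_threshold: float = 1.2
    # single-cell design
    n_cells_per_condition: int = 200
    sc_expressed_mean: float = 2.0
    sc_background_mean: float = 0.02
    sc_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_background", "n_signature", "n_gvhd", "n_contaminant",
                     "planted_extra_edges", "n_penalty_sets",
                     "n_cells_per_condition"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.dropout_prob < 1:
            raise ConfigError("dropout_prob must be in [0, 1)")
        if not 0 <= self.penalty_decoy_frac <= 1:
            raise ConfigError("penalty_decoy_frac must be in [0, 1]")
        if self.ppi_attach < 1:
            raise ConfigError("ppi_attach must be >= 1")
        if self.n_exclusion_sets < 1:
            raise ConfigError("n_exclusion_sets must be >= 1")
        if self.ratio_threshold <= 0:
            raise ConfigError("ratio_threshold must be > 0")


@dataclass
class TruthLabels:
    """Ground truth: proteomics class per gene, expression category per gene."""

    class_of: dict[str, str] = field(default_factory=dict)
    sc_class_of: dict[str, str] = field(default_factory=dict)

    def genes_of(self, cls: str) -> set[str]:
        return {g for g, c in self.class_of.items() if c == cls}


@dataclass
class SyntheticBundle:
    """Everything one pipeline run needs, plus the truth to grade it with."""

    config: SimConfig
    training: RatioTable
    validation: RatioTable
    exclusion_sets: list[GeneSet]
    penalty_library: list[GeneSet]
    network: nx.Graph
    truth: TruthLabels


def _truncated_lognormal(rng: np.random.Generator, n: int, logmean: float,
                         logsd: float, lower: float) -> np.ndarray:
    """LogNormal draws conditioned on exceeding ``lower`` (inverse-CDF)."""
    f = norm.cdf((math.log(lower) - logmean) / logsd)
    u = f + (1.0 - f) * rng.random(n)
    return np.exp(logmean + logsd * norm.ppf(u))


def generate_experiments(config: SimConfig) -> SyntheticBundle:
    """Generate the paired ratio tables, gene sets, network, and truth."""
    rng = np.random.default_rng(config.seed)

    signature = [f"SIG{i:03d}" for i in range(1, config.n_signature + 1)]
    gvhd = [f"GVH{i:03d}" for i in range(1, config.n_gvhd + 1)]
    background = [f"BKG{i:03d}" for i in range(1, config.n_background + 1)]
    contaminant = [f"CNT{i:03d}" for i in range(1, config.n_contaminant + 1)]
    universe = signature + gvhd + background + contaminant
    accession = {g: f"ACC{i:05d}" for i, g in enumerate(universe, start=1)}

    truth = TruthLabels(class_of={
        **{g: "signature" for g in signature},
        **{g: "gvhd" for g in gvhd},
        **{g: "background" for g in background},
        **{g: "contaminant" for g in contaminant},
    })

    def one_table(experiment_id: str) -> RatioTable:
        elevated_n = len(signature) + len(gvhd)
        elevated = _truncated_lognormal(
            rng, elevated_n, config.signature_ratio_logmean,
            config.signature_ratio_logsd, config.ratio_threshold)
        null = np.exp(config.background_ratio_logsd
                      * rng.standard_normal(len(background) + len(contaminant)))
        ratios = dict(zip(signature + gvhd, elevated))
        ratios.update(zip(background + contaminant, null))
        peptides = 1 + rng.poisson(4, len(universe))
        dropped = rng.random(len(universe)) < config.dropout_prob
        table = RatioTable(experiment_id=experiment_id)
        for i, g in enumerate(universe):
            if dropped[i]:
                continue
            table.add(ProteinQuantRecord(
                accession=accession[g], gene_symbol=g, ratio=float(ratios[g]),
                peptide_count=int(peptides[i]), search_db="swissprot"))
        return table

    training = one_table("training")
    validation = one_table("validation")

    # exclusion lists: overlapping slices that together cover every gvhd gene
    exclusion_sets = []
    if gvhd:
        k = config.n_exclusion_sets
        per = math.ceil(len(gvhd) / k)
        overlap = max(1, per // 4)
        for i in range(k):
            lo = max(0, i * per - overlap)
            hi = min(len(gvhd), (i + 1) * per)
            members = frozenset(gvhd[lo:hi])
            if members:
                exclusion_sets.append(GeneSet(
                    name=f"GVHD_PRIOR_{i + 1:02d}",
                    description="GVHD-specific proteins from prior comparisons",
                    members=members))

    # scale-free interaction network with a dense planted signature module
    n = len(universe)
    base = nx.barabasi_albert_graph(n, config.ppi_attach,
                                    seed=int(rng.integers(2 ** 31)))
    perm = rng.permutation(n)
    relabel = {i: universe[perm[i]] for i in range(n)}
    network = nx.relabel_nodes(base, relabel)
    for a, b in network.edges:
        network[a][b]["confidence"] = float(rng.uniform(0.2, 0.95))
    if len(signature) >= 2:
        planted = 0
        attempts = 0
        max_attempts = 50 * max(1, config.planted_extra_edges)
        while planted < config.planted_extra_edges and attempts < max_attempts:
            attempts += 1
            i, j = rng.integers(len(signature), size=2)
            if i == j:
                continue
            a, b = signature[i], signature[j]
            if network.has_edge(a, b):
                continue
            network.add_edge(a, b, confidence=float(rng.uniform(0.7, 0.99)))
            planted += 1

    # other-disease penalty library: background decoys (+ contaminants)
    penalty_library = []
    n_decoys = max(1, round(config.penalty_decoy_frac * len(background)))
    for i in range(config.n_penalty_sets):
        members = set(rng.choice(background, size=min(n_decoys, len(background)),
                                 replace=False))
        members |= {g for g in contaminant
                    if rng.random() < config.contaminant_penalty_prob}
        if config.penalty_allow_signature:
            members |= {g for g in signature
                        if rng.random() < config.penalty_decoy_frac}
        if members:
            penalty_library.append(GeneSet(
                name=f"OTHER_DISEASE_{i + 1:02d}",
                description="proteins reported in an unrelated disease",
                members=frozenset(members)))

    return SyntheticBundle(config=config, training=training,
                           validation=validation,
                           exclusion_sets=exclusion_sets,
                           penalty_library=penalty_library,
                           network=network, truth=truth)


def generate_singlecell(
    config: SimConfig,
    signature_genes: Sequence[str],
    conditions: Sequence[str] = CONDITIONS,
    category_fractions: dict[str, float] | None = None,
) -> tuple[SingleCellMatrix, TruthLabels]:
    """Simulate antigen-stimulation single-cell counts for signature genes.

    Each gene is assigned a truth category (largest-remainder split of
    ``category_fractions``); counts per cell are negative-binomial with a
    high mean in conditions where the category says "expressed" and a
    near-zero mean elsewhere.  Returns the matrix and the per-gene truth.
    """
    if len(conditions) < 2:
        raise ConfigError("need at least 2 cell conditions")
    if not signature_genes:
        raise UsageError("signature gene list is empty")
    fracs = dict(category_fractions or SC_CATEGORY_FRACTIONS)
    unknown = set(fracs) - set(_EXPRESSED_IN)
    if unknown:
        raise ConfigError(f"unknown single-cell categories: {sorted(unknown)}")

    rng = np.random.default_rng([config.seed, 1])
    genes = list(signature_genes)
    n = len(genes)

    # largest-remainder apportionment of genes to categories
    cats = list(fracs)
    ideal = np.array([fracs[c] for c in cats], dtype=float)
    ideal = ideal / ideal.sum() * n
    counts = np.floor(ideal).astype(int)
    for i in np.argsort(-(ideal - counts))[: n - counts.sum()]:
        counts[i] += 1
    order = rng.permutation(n)
    sc_class_of = {}
    pos = 0
    for cat, c in zip(cats, counts):
        for idx in order[pos:pos + c]:
            sc_class_of[genes[idx]] = cat
        pos += c

    cells, condition_of = [], {}
    for cond in conditions:
        for i in range(config.n_cells_per_condition):
            cid = f"{cond}_c{i:04d}"
            cells.append(cid)
            condition_of[cid] = cond

    r = config.sc_dispersion
    dense = np.zeros((n, len(cells)), dtype=np.int64)
    col = 0
    for cond in conditions:
        width = config.n_cells_per_condition
        for gi, g in enumerate(genes):
            mu = (config.sc_expressed_mean
                  if cond in _EXPRESSED_IN[sc_class_of[g]]
                  else config.sc_background_mean)
            p = r / (r + mu)
            dense[gi, col:col + width] = rng.negative_binomial(r, p, size=width)
        col += width

    matrix = SingleCellMatrix(genes=genes, cells=cells, counts=dense,
                              condition_of=condition_of)
    return matrix, TruthLabels(sc_class_of=sc_class_of)


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle in the exact formats the readers consume.

    Emits ``training.tsv``, ``validation.tsv``, ``exclusions.gmt``,
    ``penalty.gmt``, ``ppi.tsv`` and a ``truth.tsv`` label table; returns
    the path of each artifact.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "training": out_dir / "training.tsv",
        "validation": out_dir / "validation.tsv",
        "exclusions": out_dir / "exclusions.gmt",
        "penalty": out_dir / "penalty.gmt",
        "ppi": out_dir / "ppi.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_ratio_table(paths["training"], bundle.training)
    write_ratio_table(paths["validation"], bundle.validation)
    write_gmt(paths["exclusions"], bundle.exclusion_sets)
    write_gmt(paths["penalty"], bundle.penalty_library)
    write_ppi_edges(paths["ppi"], bundle.network)
    with open(paths["truth"], "w") as fh:
        fh.write("gene\tclass\n")
        for g in sorted(bundle.truth.class_of):
            fh.write(f"{g}\t{bundle.truth.class_of[g]}\n")
    return paths
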