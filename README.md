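# gvtsig

Network-weighted prioritization of plasma-proteomics biomarkers for the
graft-versus-tumor (GVT) effect without graft-versus-host disease (GVHD).

After allogeneic hematopoietic cell transplantation, donor lymphocyte
injection (DLI) is given at relapse to induce the graft-versus-tumor
effect, but it frequently triggers GVHD as well. A plasma signature that
marks GVT *without* GVHD would let clinicians stratify patients. `gvtsig`
implements the systems-biology pipeline that turns paired isotope-labeled
(heavy/light) plasma proteome comparisons into such a signature:

1. **Ratio filter** — keep proteins upregulated in the heavy-labeled
   (GVT-positive, GVHD-negative) pool: heavy/light ratio strictly > 1.2.
2. **Exclusion** — remove proteins on GVHD-specific / common-protein gene
   lists from prior experiments (GMT files).
3. **Subnetwork** — project candidates onto a STRING-style protein–protein
   interaction graph at a confidence cutoff (default 0.7), optionally
   extended by *outer genes* one interaction hop away.
4. **Relevance scores** — for candidate *g* with heavy/light ratio *r(g)*
   and normalized subnetwork connectivity *ĉ(g) ∈ [0, 1]*
   (summed edge confidence, scaled by the core maximum):

   relevance(g) = r(g) · (1 + α·ĉ(g)),  α ≥ 0 (default 1)

5. **Penalty scores** — down-weight proteins reported in *k(g)* unrelated
   diseases without touching the candidate list:

   final(g) = relevance(g) / (1 + β·k(g)),  β ≥ 0 (default 0.5)

   Final scores below 1 are retained — penalties re-rank, never remove.
6. **Combination** — union the two experiments; genes scored in both get
   the geometric mean of their final scores, singletons keep their own,
   and provenance (training / validation / both) is recorded. The scored
   subnetwork is rendered as a **GeneTerrain**: a force-directed layout
   whose surface is the sum of per-gene Gaussian peaks with height equal
   to the score.

A companion module classifies signature genes in antigen-stimulation
single-cell RNA-seq (PRAME± / CMV pp65± / nonreactive T cells) into
PRAME-specific, general-activation, CMV-specific and not-expressed
categories by detection fraction, and summarizes the overlap.

Because the original quantification tables are not publicly deposited,
the package ships a first-class synthetic generator
(`gvtsig.synthetic_data`) that emulates the paired design with planted
signature, GVHD-confounder, background and contaminant proteins plus a
scale-free PPI network — every stage is testable against known truth.

## Worked example

```sh
gvtsig run-all --simulate --seed 42 --out-dir runs/demo
```

or equivalently from Python:

```python
from gvtsig.cli import PipelineConfig, run_pipeline
manifest = run_pipeline(PipelineConfig(sim_seed=42), "runs/demo", simulate=True)
```

On the default synthetic bundle at seed 42 this prints/records:

```
n_candidates_training    122
n_candidates_validation  133
signature_size           206
strata                   {'above_1': 116, 'below_1': 90, 'equal_1': 0}
overlap                  {... 'total_expressed': 145, 'percentage_expressed': 70}
```

122 and 133 proteins survive the ratio filter and exclusion lists in the
training and validation experiments; their union after scoring is a
206-gene signature, 116 with combined final score above 1 and 90 below
(sub-1 scores are retained by design). Of the signature genes, 70% are
detected in antigen-stimulated T cells of the simulated single-cell
experiment. The run directory also contains `signature.tsv` (the full
per-gene score chains), `terrain.tsv`/`terrain.png` (the GeneTerrain
raster) and `manifest.json` with every parameter and seed needed to
reproduce the run byte-for-byte.

Recovery of planted truth on the same bundle
(`gvtsig.cli.evaluate_recovery`): precision = recall = 0.97 for the 60
planted signature genes among the top-60 ranked genes, with zero planted
GVHD confounders surviving exclusion.

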