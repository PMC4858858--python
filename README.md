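# riscprimer

Post-transcriptional regulation analysis of the naive-to-primed pluripotency
transition (mouse ES → epiblast-like, "ELA", cells), built as a tested,
reusable pipeline with synthetic-data generators that carry known ground
truth.

During early differentiation, the RNA-induced silencing complex (RISC)
releases and loads specific mRNAs. This package implements the integrated
analysis that quantifies that remodeling from four assay types:

* **Ago-RIP arrays** — Argonaute-bound vs total mRNA intensities across a
  differentiation time course. The Ago channel's log2 intensity distribution
  is bimodal; a two-component Gaussian mixture fit yields a bound-call
  threshold **T1 = μ₁ + 3σ₁** (a designed false-positive rate of 0.001 under
  the background component). Ago enrichment per stage *n* is
  **Eₙ = log₂(Ago) − log₂(total)** after quantile normalization, and a gene
  is *released* at a transition when `bound_n ∧ Eₙ ≥ T2 ∧ Eₙ₊₁ ≤ T3 ∧
  |ΔE| ≥ 1.5` (with T2 = 2, T3 = 0.5; *loaded* is the mirror rule).
* **Ribosome IP / input RNA-seq (TRAP-style)** — counts are scaled with
  median-of-ratios size factors, filtered on expression (mean ≥ 50 normalized
  counts in at least one condition) and replicate variability (sd ≤ 20% of
  the mean), and summarized as ribosome enrichment **R = mean IP / mean
  input** per condition and its change **log₂RiboΔE = log₂(R_ELA/R_ES)**.
* **Small-RNA counts** — RPM-normalized miRNA expression over the four
  culture conditions (ES#, ES, ELA#, ELA); the ground-state signature
  **set D** is the miRNAs with mean log₂ RPM ≥ 5 and log₂ FC ≤ −1.
* **3′UTR target scanning** — a miRanda-style affine-gap local aligner with
  seed (positions 2–8) up-weighting and a per-pair duplex energy estimate;
  hits pass at score ≥ 140 and energy ≤ −10 kcal/mol, per-gene scores are
  summed over set-D miRNAs, and gene families are tested against
  scrambled-UTR nulls with rank-sum statistics.

Cross-cutting statistics (sign-test concordance with random-gene and
scrambled-order controls, the DE-gene filter |log₂FC| ≥ 1 ∧ adj. p < 0.05 ∧
mean log₂ expr ≥ 7.5, complete-linkage Euclidean clustering, family
enrichment comparisons) and an end-to-end orchestrator complete the package.

## Worked example

```bash
riscprimer run --out demo --seed 7
```

runs the full synthetic pipeline (simulate → ago → ribo → mirna →
integration) and prints the run-report counts:

```
{
 "bound_per_stage": {"ELA": 2133, "ES": 2133, "NEU": 2133, "NPC": 2133},
 "family_binding_p": {
  "CYP450": 0.328, "DNMT": 4.1e-13, "KDM": 1.3e-10, "SWI_SNF": 7.3e-17
 },
 "loaded_per_transition": {"ELA->NPC": 122, "ES->ELA": 120, "NPC->NEU": 115},
 "n_genes": 10000,
 "n_set_d": 23,
 "released_per_transition": {"ELA->NPC": 121, "ES->ELA": 112, "NPC->NEU": 121},
 "ribo_down": 107, "ribo_genes_kept": 9297, "ribo_up": 117
}
```

Reading it: of 10,000 simulated genes, ~21% are called Ago-bound per stage;
~112 genes are called released at the naive-to-primed (ES→ELA) transition
(125 were planted); the three chromatin-regulator families carrying planted
set-D target sites test far below p = 0.01 against the scrambled-UTR null
while the control family (CYP450) does not. The emitted
`demo/integration.tsv` couples the calls: genes with ΔE ≤ −2 average
log₂RiboΔE ≈ +2 (released mRNAs gain ribosome occupancy), the signature
anti-correlation between RISC binding and translation.

Every stage is also available separately (`riscprimer simulate|ago|ribo|
mirna|stats`) on TSV/FASTA/GMT inputs; thresholds are exposed as flags
(`--t2 --t3 --delta-min --relaxed --min-mean --max-cv --min-score
--max-energy ...`).

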