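# pgskit

Polygenic score calculation with genetic-ancestry-aware normalization.

A polygenic score (PGS) summarizes genetic predisposition to a trait as a
weighted sum of allele dosages,

    PGS_i = Σ_j w_j · d_ij ,

where `d_ij ∈ [0, 2]` is individual *i*'s dosage of the effect allele of
variant *j* and `w_j` its published effect weight. Computing this reliably
is harder than the formula suggests: scoring files and target genotypes
disagree on allele order and strand, report only the effect allele, or
collide with multi-allelic sites — and the raw sums are confounded by
genetic ancestry, with means and variances that differ between populations
without implying any difference in risk.

pgskit is for statistical geneticists and biobank analysts who need to

* **calculate** scores from PGS scoring files (`#`-header TSV, plain or
  gzipped) against VCF target genotypes, whole-file or split per
  chromosome, with an auditable log of every matched and excluded variant;
* **estimate ancestry similarity** by projecting each sample into a PCA of
  a labelled reference panel using the OADP method (online augmentation,
  decomposition and Procrustes), which avoids the shrinkage-toward-the-
  origin bias of naive projection, and assigning the *most similar*
  reference population by Mahalanobis distance;
* **normalize** each raw sum onto three relative scales reported together:

  | scale | definition |
  |---|---|
  | `Z_MostSimilarPop` | `(S − μ_pop)/σ_pop` against the most similar reference population's score distribution (plus a mid-rank percentile) |
  | `Z_norm1` | residual of `S` from an OLS regression of reference scores on PCs, over the reference residual sd (mean correction, label-free) |
  | `Z_norm2` | the same residual over an ancestry-predicted sd from a second regression of squared residuals on PCs (mean + variance correction) |

A Balding–Nichols simulator generates labelled multi-population panels,
target cohorts (including admixed samples), scoring files, and injected
matching hazards with ground truth, so the entire pipeline is testable
offline.

## Worked example

```bash
# 1. synthesize a 3-population reference panel, target cohort and score
pgskit simulate --n-pops 3 --n-ref 50 --n-target 30 --m-variants 500 \
    --seed 42 --out-dir demo

# 2. run the full pipeline
pgskit run --target demo/target.vcf --scoring demo/scoring_file.txt \
    --reference-vcf demo/reference.vcf \
    --reference-labels demo/reference_labels.tsv \
    --pcs 4 --out-dir demo/out
```

which prints the artifact paths

```
match_log: demo/out/match_log.tsv.gz
scores: demo/out/scores.tsv
adjusted_scores: demo/out/adjusted_scores.tsv
report_json: demo/out/report.json
report_text: demo/out/report.txt
```

`scores.tsv` holds the raw results; for example its first data row

```
sample_id	score_id	sum	denom	avg	n_variants_used
tgt_POP1_1	PGSSIM001	-4.438653635	1000	-0.004438653635	500
```

says sample `tgt_POP1_1` scored a weighted SUM of −4.44 over all 500
matched variants (denominator 1000 = 2 × 500; AVG is SUM/DENOM).
`adjusted_scores.tsv` adds the relative scales:

```
sample_id	score_id	sum_raw	most_similar_pop	percentile_MostSimilarPop	Z_MostSimilarPop	Z_norm1	Z_norm2
tgt_POP1_1	PGSSIM001	-4.438653635	POP1	0.02	-2.073104071	-2.112211356	-1.998204917
```

— this sample is most genetically similar to reference population POP1 and
sits at its 2nd percentile, about −2 sd on all three relative scales
(the three agree here because the cohort matches the panel; they diverge
for admixed or unrepresented ancestries, where the label-free `Z_norm*`
scales are the meaningful ones). `report.txt` summarizes matching (e.g.
`PGSSIM001: 500/500 kept (rate 1.0000, passed vs 0.75)`), the assignment
counts per population, and the per-population score distributions before
and after adjustment.

The same pipeline is available as a library (`pgskit.run_pipeline`, or the
stage functions in `pgskit.matching`, `pgskit.scoring`, `pgskit.ancestry`,
`pgskit.adjustment`), and `match` / `score` / `ancestry` / `adjust`
subcommands run individual stages.

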