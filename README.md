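# cdkpredx

Analysis toolkit for transcriptomic biomarkers of treatment response in
two-arm neoadjuvant breast cancer trials comparing CDK4/6 inhibition plus
endocrine therapy against chemotherapy. It implements the full path from a
gene-level RNA-seq count matrix to biomarker-by-treatment interaction
statistics: normalization and sample QC, metagene signature scoring, the
CDKPredX three-module classifier, pre-ranked gene-set enrichment, and
contingency/logistic association statistics — together with a synthetic
cohort generator so every stage can be exercised end to end without access
to patient-level trial data.

## The science in brief

**Normalization.** Raw counts are filtered (genes with total count ≤ 10
dropped), divided by gene lengths rescaled to their per-gene geometric mean
across samples, scaled between samples by trimmed-mean-of-M-values (TMM)
factors, converted to transcripts per million against the TMM-effective
library size, and log2-transformed (log2 TMM-TPM). Sample outliers are
flagged when their median Euclidean distance to all other samples exceeds
P75 + 3·IQR of the per-sample median distances.

**CDKPredX.** For three gene modules — proliferation (Pr), ER signaling
(Er) and immune activity (Im) — the metagene score of sample *j* is the
unweighted mean of log2 expression over the module genes. Scores are
dichotomized at cohort quantiles: the lower quartile for Pr, the median for
Er and Im (ties: score ≥ threshold → high). A sample is **CDKPredX+** when

&nbsp;&nbsp;&nbsp;&nbsp;Pr high ∧ Er high ∧ Im low

and CDKPredX− otherwise. Positive tumors are highly proliferative,
ER-driven and immunologically cold — the phenotype that responds to CDK4/6
inhibition plus endocrine therapy but poorly to chemotherapy.

**Association statistics.** Within biomarker strata, the treatment effect
on a binary endpoint (e.g. objective response at 12 weeks, ORR12) is the
2×2 odds ratio OR = ad/bc with Wald CI exp(ln OR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d));
Fisher's exact test is available for small tables. Differential treatment
effect is tested in the logistic model

&nbsp;&nbsp;&nbsp;&nbsp;logit P(response) = c₀ + c₁·arm + c₂·biomarker + c₃·arm×biomarker

with the interaction p-value from the likelihood-ratio test of c₃
(Wald as an alternative). Printed one-decimal response percentages can be
reconstructed into the unique consistent integer tables.

**Enrichment.** Genes are ranked by −log10(p)·sign(log2FC) from a Welch
test between responders and non-responders; pre-ranked GSEA uses the
weighted running-sum enrichment score (weight 1 on |rank score|), a
gene-label permutation null, sign-matched NES and permutation p, and
Benjamini–Hochberg adjustment across sets (set sizes restricted to 10–500).

## Worked example

Run the whole pipeline on a simulated 180-patient cohort (2000 genes, two
injected expression outliers):

```yaml
# config.yaml
outdir: demo/out
seed: 7
simulation:
  n_samples: 180
  n_genes: 2000
  seed: 7
  outlier_count: 2
  outlier_shift: 5.0
thresholds:
  gsea_n_perm: 500
```

```text
$ cdkpredx run --config config.yaml
[simulate] drawing synthetic cohort (seed=7)
[normalize] low-count filter + length scaling + TMM + log2-TPM
[qc] flagged 3 outlier samples
[classify] 27/177 positive
[associate] interaction p = 0.0414 (n=177)
[gsea] tested 2 sets
run complete; manifest written to demo/out/manifest.json
```

QC removed the two injected outliers (plus one borderline sample); 27 of
the 177 retained samples were called CDKPredX+. The association table
(`demo/out/associations.tsv`) shows the biomarker-by-treatment pattern the
generator encodes — CDK4/6i-vs-chemo odds ratio 2.29 (95% CI 0.42–12.50)
among CDKPredX+ patients versus 0.35 (0.18–0.69) among CDKPredX−, with
interaction p = 0.041 — and `demo/out/gsea.tsv` shows the proliferation
module enriched among non-responders at this mixed-arm endpoint
(ES −0.92, NES −2.37, adjusted p = 0.008).

Each stage is also available as a subcommand (`simulate`, `normalize`,
`qc`, `score`, `classify`, `associate`, `gsea`, `validate`) and as plain
library functions (`cdkpredx.log2_tmm_tpm`, `cdkpredx.classify_cdkpredx`,
`cdkpredx.logistic_interaction`, ...).

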