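# riboten

Ribosome-profiling analysis of **translational efficiency (TE)** and its
dependence on ORF length, for experiments comparing a mutant against wild
type with matched footprint (FP) and total-RNA libraries — plus bespoke
quantification of polysome A254 gradient traces.

TE for gene *g* in condition *c* is the normalized footprint density over
the normalized total-mRNA density,

```
TE_gc = (k_FP,gc / s_FP) / (k_total,gc / s_total)
```

with median-of-ratios size factors *s* (DESeq-style; RPKM-type length
normalization is deliberately avoided because TE ratios cancel length
within a gene). The change between mutant and wild type is

```
dTE_g = log2(TE_g,mut / TE_g,wt)      (also reported as percent change)
```

The package answers the questions that arise when an initiation factor or
ribosomal protein (e.g. Asc1/RACK1) is lost and short-ORF mRNAs are
disproportionately affected:

* **Counting** — positional rules for footprint reads in transcript
  coordinates: a read counts iff it maps uniquely and lies wholly inside
  the window from 12 nt upstream of the start codon (plus a 30-codon
  exclusion) to 18 nt upstream of the stop codon; genes need ≥ 128 reads
  pooled over libraries.
* **Length dependence** — binned dTE profiles (bins of 100 genes sorted
  by ORF length), Spearman correlations of dTE against gene attributes,
  partial Spearman correlations (residuals after linear regression) to
  separate ORF-length from transcript-length effects, and z-score (≤ −1)
  selection of the most decreased genes.
* **Gene-set shifts** — one-sided Mann–Whitney U tests of a set
  (closed-loop association group, RP/MRP, GO-like category) against the
  remaining genes, with an ORF-length correction: regress dTE on log10
  ORF length and re-test the residuals, isolating any set effect beyond
  what length alone explains.
* **Polysome traces** — minima-as-boundaries peak integration of A254
  curves above a two-half-minimum baseline, positional 40S/60S/80S/polysome
  labeling, and the 60S/40S and polysome/monosome (P/M) ratios.
* **Synthetic data** — a generator for the full experiment (annotations,
  planted TE structure, negative-binomial counts, read-level alignments
  with decoys, Gaussian-mixture traces) with known ground truth, so every
  stage is testable end to end.

## Worked example

```python
import numpy as np
import riboten as rt

cfg = rt.SimulationConfig(
    n_genes=4000, seed=7,
    group_defs=(rt.GroupDef("short_rp_like", quantile_range=(0.0, 0.05),
                            size=150, extra_shift_log2=0.0),),
)
annotation, truth, counts = rt.simulate_experiment(cfg)
result = rt.te_analysis(counts, wt="WT", mut="mut", min_pooled=128)
table = result.table            # te_wt, te_mut, dte_log2, dte_percent

r = rt.correlate_attribute(table.dte_log2,
                           np.log10(annotation.orf_lengths()[table.index]))
gs = rt.GeneSet.from_ids("short_rp_like", truth.groups["short_rp_like"])
raw = rt.mwu_geneset_test(table.dte_log2, gs, "less")
corr = rt.length_corrected_test(table.dte_log2,
                                annotation.orf_lengths()[table.index], [gs])

trace, _ = rt.simulate_trace(rt.default_polysome_spec(seed=7))
peaks, ratios = rt.quantify_trace(trace)
```

This prints (via the obvious f-strings):

```
retained 4000/4000 genes
Spearman(dTE, log10 ORF length) r=0.221 p=1.25e-45
set median dTE -20.3% raw p=1.00e-08  length-corrected p=0.49
60S/40S=1.83  P/M=1.70
```

Read: the mutant's TE changes correlate positively with ORF length (short
ORFs lose the most TE); the planted 150-gene short-ORF set shows a ~20%
median TE decrease that is highly significant before length correction —
but because the set's effect here is *entirely* length-mediated, the
corrected rank test on residuals is null (p ≈ 0.5). Had the set carried
an extra shift beyond the length trend, the corrected p would stay small.
The trace ratios match the simulated profile's planted areas.

## Command line

Each stage runs standalone on the previous stage's text outputs:

```bash
riboten simulate --config sim.yaml --outdir data --seed 1
riboten count --annotation data/annotation.tsv \
    --alignments data/alignments_FP_WT_rep1.tsv -o counts.tsv
riboten te --counts data/counts.tsv --min-pooled 128 -o te.tsv
riboten lengthprofile --te te.tsv --annotation data/annotation.tsv \
    --bin-size 100 -o profile.tsv
riboten groups --te te.tsv --annotation data/annotation.tsv \
    --sets sets.gmt --alternative less --length-correct -o groups.tsv
riboten trace --input trace.csv -o peaks.tsv --ratios ratios.tsv
riboten run-all --config pipeline.yaml   # all stages + run manifest
```

Exit codes: 0 ok, 1 usage error, 2 data error.

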