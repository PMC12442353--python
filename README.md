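# mwsip

Multi-window high-resolution DNA stable isotope probing (MW-HR-SIP)
analysis for amplicon count data: identify ¹³C-incorporating taxa from
CsCl buoyant-density gradient fractions, quantify their growth and
life-history traits, account for carbon mineralization, and test whether
carbon-cycling function tracks phylogeny. A fully seeded synthetic
experiment generator makes every stage verifiable against known ground
truth.

Intended users are microbial ecologists running DNA-SIP microcosm
experiments (e.g. soil communities fed ¹³C-labeled substrates such as
xylose or cellulose) who have ASV count tables, per-fraction buoyant
densities, predicted 16S rRNA gene copy numbers (*rrn*), a phylogeny, and
headspace CO₂ time series.

## The method in brief

A taxon that assimilates a ¹³C substrate produces denser DNA. For each of
three overlapping heavy buoyant-density windows (1.70–1.73, 1.72–1.75,
1.74–1.77 g/mL), fractions of ¹³C treatments are compared with the
matching fractions of ¹²C controls. Counts are pruned (total ≥ 2),
sparsity-filtered (prevalence cutoff chosen per comparison to maximize
BH-significant taxa), normalized with median-of-ratios size factors, and
tested per taxon with a one-sided negative-binomial Wald test of

  H0: log₂(μ₁₃C / μ₁₂C) ≤ 0.25  vs  H1: log₂(μ₁₃C / μ₁₂C) > 0.25.

A taxon is an **incorporator** if BH-adjusted p < 0.1 with l2fc > 0.25 in
at least one window. Downstream traits per incorporator:

- **latency** = max(0, first label day − peak mineralization day),
- **max l2fc** = log₂(max post-addition normalized abundance / baseline),
  floored at 0, where normalized abundance = (relative abundance /
  taxon *rrn* / sample mean *rrn*) × DNA yield,
- **degree of ¹³C assimilation** = best per-window l2fc estimate,

plus rarefaction, richness/Pielou/Faith's PD, Wilcoxon rank-sum group
comparisons, cumulative mineralization and rates (mg C h⁻¹), and a
Spearman/Mantel correlation between cophenetic and modified-Gower
("altGower") functional distances. Details and defaults: `docs/methods.md`.

## Worked example

Simulate a 100-taxon community in which 10% of taxa assimilate xylose,
run the incorporator caller over four sampling days, and compute traits:

```python
from mwsip.synthetic_data import simulate_community, simulate_gradient, GradientDesign
from mwsip.gradient_sip import mw_hr_sip, degree_of_assimilation
from mwsip.growth_traits import latency

truth = simulate_community(n_taxa=100, frac_incorporators_per_substrate=0.1, seed=1)
design = GradientDesign()          # 24 fractions, 1.67-1.78 g/mL, 10k reads each
t13 = {d: [simulate_gradient(truth, design, "13C", "xylose", d, seed=10 + d)]
       for d in (1, 3, 7, 14)}
t12 = {d: [simulate_gradient(truth, design, "12C", "xylose", d, seed=90 + d)]
       for d in (1, 3, 7, 14)}

calls, window_results = mw_hr_sip(t13, t12)
inc = calls[calls["is_incorporator"]]
print("incorporators called:", len(inc), "of", len(truth.taxon_ids), "taxa")

deg = degree_of_assimilation(window_results)
summary = inc.assign(degree=deg.reindex(inc.index),
                     latency=[latency(d, 2.0) for d in inc["first_label_day"]])
print(summary.head(6).round(2).to_string())
```

Output:

```
incorporators called: 10 of 100 taxa
          is_incorporator  first_label_day  degree  latency
taxon_id
ASV0008              True              1.0    7.73      0.0
ASV0017              True              1.0    8.60      0.0
ASV0024              True              3.0    5.99      1.0
ASV0027              True              3.0    8.46      1.0
ASV0028              True              1.0    7.60      0.0
ASV0050              True              1.0    7.53      0.0
```

All 10 truly labeled taxa (and no unlabeled ones) are recovered.
`first_label_day` is the earliest sampling day with a positive call;
`degree` is the taxon's log₂ enrichment in its best heavy window; and
`latency` measures days between peak xylose mineralization (day 2, as
recovered by the mineralization module) and first detected labeling —
taxa labeled on day 1 assimilated the substrate during its main
decomposition pulse and get latency 0.

The same analysis runs from the shell on TSV inputs:

```bash
mwsip simulate --seed 2 --outdir demo                 # synthetic experiment + analysis
mwsip identify --counts demo/counts_all_NTH.tsv \
               --metadata demo/metadata_NTH.tsv --out demo/calls.tsv
mwsip traits --incorporators demo/calls.tsv --counts demo/counts_all_NTH.tsv \
             --metadata demo/metadata_NTH.tsv --rrn demo/rrn_NTH.tsv \
             --mineralization demo/mineralization_series_NTH.tsv --out demo/traits.tsv
mwsip mineralization --series demo/mineralization_series_NTH.tsv --outdir demo/min
mwsip phylofunc --traits demo/traits.tsv --tree demo/tree_NTH.nwk --outdir demo/pf
mwsip run --config pipeline.yaml                      # full pipeline from YAML
```

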