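# serumrna

Circulating small non-coding RNAs (sncRNAs) — miRNAs, tRNA-derived
fragments (tsRNAs/tRFs), rRNA-derived fragments (rsRNAs) and YRNA-derived
fragments (ysRNAs) — are measurable in blood serum and bone-marrow
supernatant and carry diagnostic signal for acute myeloid leukaemia (AML).
`serumrna` is a tested, reusable reimplementation of that liquid-biopsy
analysis for 15–45 nt small-RNA reads:

1. **Hierarchical annotation** of collapsed reads against a curated
   parental-RNA reference (miRNA → rRNA → YRNA → tRNA → mt-tRNA → piRNA →
   other ncRNA → spike-in; ungapped full-length matching through a 15-mer
   seed index, tRNAs matched on CCA-appended mature sequences), producing
   fragment-level count matrices, class proportions and RPM-weighted
   length distributions.
2. **Fragment characterization**: tsRNA cleavage subtypes on mature-tRNA
   coordinates (5′ / inner′ / 3′ / 3′CCA, the latter two reported jointly),
   most-specific-parent assignment inside the 45S ⊃ {18S, 5.8S, 28S} rRNA
   nesting, positional coverage profiles with peak calling, and ysRNA
   gene / 5′-end composition.
3. **Differential expression** with a negative-binomial conditional exact
   test: TMM normalization, moment-based common dispersion φ
   (Var = μ + φμ²), group sums tested conditionally on their total
   (Binomial(t, ½) in the Poisson limit), significance at p ≤ 0.05 and
   |log₂FC| ≥ 1.
4. **Marker-panel selection and classification**: three-criterion filter
   (significant DE, mean RPM > 10, univariate logistic significance at
   α = 0.05 on log₂(RPM+1)), bagged-tree ensembles with out-of-bag scoring,
   and Mann–Whitney AUC on discovery and held-out validation cohorts.
5. **Paired blood/bone-marrow concordance**: Pearson r between paired PBS
   and BMS profiles on log₁₀(RPM+1), pooled over per-feature centered
   deviations and per subject.

Because raw serum small-RNA cohorts of this kind are controlled-access,
the package bundles a
first-class **synthetic-data generator** whose defaults encode the
published serum landscape — class shares rsRNA 62.86%, ysRNA 14.97%,
tsRNA 4.22%, miRNA 3.09%; 28S:18S ≈ 88:10 within rsRNA with canonical
positional peaks (18S 674–692, 897–919, 1194–1223, 1838–1862; 28S
1336–1355, 1963–1982, 2895–2920); 70% 5′ cytoplasmic tsRNAs and
inner′-skewed mitochondrial tsRNAs; RNY4-dominant, ~30 nt, 90% 5′ ysRNAs —
so every pipeline stage is a parameter-recovery test with known ground
truth.  The reference is built with 15-mer-uniqueness rejection sampling,
which makes annotation unambiguous by construction.

## Worked example

The analysis is organised as numbered drivers under `analysis/`; each is a
thin script over the library in `src/serumrna/` and writes its tables under
`results/analysis/`.

```sh
python analysis/02_serum_composition.py --seed 1
```

prints

```
100000 reads, 14964 distinct; unannotated: 0
annotated class shares (%):
  rsRNA         62.70
  ysRNA         15.21
  piRNA          8.95
  other_ncRNA    5.82
  tsRNA          4.23
  miRNA          3.09
length-distribution modes (nt): {'miRNA': 22, 'tsRNA': 31, 'rsRNA': 20, 'ysRNA': 30}
```

i.e. the annotation engine recovers the mixture's encoded composition to a
few tenths of a percentage point at 100,000 reads, with ysRNAs peaking at
~30 nt (the rsRNA mode sits at the width of the narrow 28S peaks, which cap
fragment length; see docs/methods.md).  `analysis/03_fragment_landscape.py` then recovers the planted
positional structure exactly:

```
18S: 4 peaks: #1 674-692, #2 897-919, #3 1194-1223, #4 1838-1862
28S: 3 peaks: #1 1336-1355, #2 1963-1982, #3 2895-2920
cyto-tsRNA cleavage groups (%): {'5p': 69.9, 'inner': 20.5, '3p': 9.5}
ysRNA gene fractions (%): {'RNY1': 20.3, 'RNY3': 14.8, 'RNY4': 55.1, 'RNY5': 9.8} | 5' share 90.1%
```

`analysis/04_differential_expression.py` and
`analysis/05_marker_panels.py` run the AML-vs-control stages on a simulated
discovery cohort (30 AML + 12 controls) with a planted 6-feature 5′-tsRNA
panel: all six planted tsRNA markers (and only those six) pass the
three-criterion selection, the tsRNA panel (6 features) is smaller than the
miRNA panel (14) and classifies validation samples at least as well
(both AUC 1.000 here).  `analysis/06_compartment_concordance.py` shows the
paired PBS/BMS correlation tracking the generator's shared-signal fraction
(pooled centered r = 0.04 / 0.41 / 0.77 / 0.96 at fractions
0 / 0.4 / 0.8 / 1.0).

The same stages are available as a CLI over a YAML config:

```sh
serumrna all --demo --outdir results/demo     # end-to-end smoke run
serumrna de --config myconfig.yaml --seed 3
```

Exit codes: 0 success, 2 configuration error, 3 stage error.  Every output
table carries a provenance header (version, seed, config hash) and reruns
with an identical config are byte-identical.

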