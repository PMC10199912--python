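# admixscan

Genome-wide scans for positive selection in **admixed populations**, with a
built-in ground-truth simulator.

Admixed cohorts — the motivating case is North African populations carrying
an autochthonous Maghrebi-like component alongside European-, sub-Saharan
African- and Middle-Eastern-like ancestry — pose a special problem for
selection scans: a candidate signal may reflect (i) selection private to the
autochthonous component, (ii) a sweep inherited from a source population
(adaptive admixture or a residual source signal), or (iii) selection acting
*after* admixture on haplotypes of one ancestry. `admixscan` implements the
statistics needed to detect and distinguish these cases, and a simulator
that generates phased cohorts with known admixture structure and known sweep
placement so every stage can be validated end to end.

## Statistics

| statistic | definition | use |
|---|---|---|
| F_ST | Weir–Cockerham (1984) variance-component estimator `a/(a+b+c)`, per SNP | allele-frequency differentiation between target and source |
| EHH / iHH | extended haplotype homozygosity around a core allele; iHH is its trapezoidal integral truncated at EHH < 0.05 | building block of the haplotype tests |
| iHS | `ln(iHH_A / iHH_D)`, standardized within derived-allele-frequency bins | within-population sweep signal |
| XP-EHH | `ln(iHH_pop1 / iHH_pop2)` on pooled alleles over a joint truncation extent, standardized genome-wide | cross-population sweep near fixation |
| F_CS | Fisher's combined score `−2(ln p₁ + ln p₂)` on rank-based p-values `p = rank/(N+1)`, applied to the intersection of the top-1% F_ST and |XP-EHH| outliers; combined p from χ²(4) | joint differentiation outliers |
| LAD | `(α_k(s) − ᾱ_k)/σ_k`, the standardized local-ancestry deviation of component *k* at SNP *s*; \|LAD\| > 4.42 flags putative post-admixture selection | ancestry-skew detection |

Candidate regions (merged outlier runs) are classified **private**,
**shared-with-source** or **post-admixture** from the overlap pattern of
target scans, source scans and significant LAD regions. Per-SNP exact
Hardy–Weinberg filtering, missingness and MAF QC, LD pruning, ancestral-
allele polarization, haplotype LD (`D`, `D'`, `r²`) and gene annotation are
included.

## Worked example

Simulate a cohort in which a hard sweep (s = 0.05, 400 generations) ran in
the autochthonous component before admixture, then scan it with iHS:

```python
from admixscan import simdata as sd, selstats as ss, outliers as ol, ancestryscan as anc

cfg = sd.SimulationConfig(seed=42)              # 4 ancestries, q_EUR = 0.153
bundle = sd.simulate_scenario("private_sweep", cfg)
print("sweep placed at", f"{bundle.truth['sweep_pos']:,} bp")

ihs = ss.ihs_scan(bundle.target, bundle.variants)
top = ol.top_fraction_outliers(ihs, "abs", q=0.001)   # top 0.1% of |iHS|
print(top.table[["pos", "score", "p"]].to_string(index=False))

prof = anc.tracts_to_locus_dosage(bundle.tracts, bundle.target.positions,
                                  list(cfg.ancestries))
print({k: round(v, 3) for k, v in zip(prof.labels, prof.genome_mean)})
```

Output:

```
sweep placed at 24,814,437 bp
     pos     score        p
24562872  7.337371 0.000818
24707082 -7.228569 0.001091
24753282  8.623745 0.000273
24814437 -8.385597 0.000545
{'MAG': 0.601, 'EUR': 0.163, 'WEA': 0.152, 'MEA': 0.084}
```

All four top-0.1% |iHS| SNPs sit within 260 kb of the true sweep locus (the
locus itself scores −8.4: long derived-allele haplotypes), and the cohort's
genome-wide ancestry dosages match the configured admixture proportions
(0.60 / 0.153 / 0.15 / 0.097).

The same stages run from the shell:

```bash
admixscan simulate --scenario shared_sweep --seed 1 --out bundle/
admixscan run-all --config run.yaml        # QC → scans → combine → LAD → classify
```

`run-all` writes per-stage score tables, a classification report and a
manifest; a rerun with the same inputs and seed is bit-identical.

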