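# genofirst

Genetics-first phenotype outlier prediction from missense variants.

Most human-genetics methods start from a phenotype and ask which variants
associate with it.  `genofirst` turns that around: starting from a single
genome and a background cohort, it predicts — for thousands of ontology
terms at once — the phenotypes for which that genome is a *genetic
extreme outlier*, and only afterwards confirms the predictions against
collected phenotype answers.  This reaches the territory association
methods cannot: rare and low-frequency missense variants of moderate
penetrance, acting alone, severally, or combinatorially, in cohorts far
too small for burden testing.

## The model

1. **Functional distance.**  A missense substitution mapped to match
   state *s* of a protein-domain profile HMM scores
   `d = |ln P_s(ref) / P_s(alt)|` — the evolutionary intolerance of the
   substitution in that domain family.  Between two genomes a site
   contributes 0 (genotypes agree), `d` (one allele apart) or `4d`
   (opposite homozygotes).

2. **Term profiles.**  Domain-to-ontology-term annotations (dcGO-style)
   collapse variants across genes: a term's profile is every catalogued
   variant falling in a domain linked to that term, weighted by `d`.

3. **Outlier scores.**  Summing site contributions gives an
   all-against-all distance matrix per term.  A Gaussian kernel and the
   spectrum of the normalised graph Laplacian detect hidden structure
   (largest eigengap); with structure, K-means on the top eigenvectors
   assigns clusters and an individual scores
   `s = local + mu * global`, where the cluster-size penalty

   ```
   mu = (exp(((n_cohort - n_cluster)/n_cohort) * gamma) - 1) / (exp(gamma) - 1)
   ```

   (gamma = 9) suppresses the between-cluster term for large clusters —
   over 99% for clusters holding more than half the cohort.  Without
   structure the score is simply the mean distance to everyone else.
   Raw scores become comparable across terms through

   ```
   s_trans(p) = cbrt( exp(-phi * rank(p)/N) * s(p)/sum(s) * (s(p)-min s)/(max s-min s) )
   ```

   (phi = 150), a [0, 1] scale on which calls are made at 0.022.

4. **Explanation.**  Each call is dissected by ablation into required
   versus contributing variants, typed `1-a`/`1-b`/`2-a`/`2-b`, classed
   by allele frequency, and credited with any *combinatorial
   contribution* — score gained because clustering exposes an allele
   rare within the individual's own cluster though common overall.

5. **Confirmation.**  Decoy-mixed questionnaires, question QC, and three
   permutation tests (global, threshold-rate, per-phenotype with an
   expected-by-chance excess curve) measure whether predictions beat
   chance; for clinically annotated cohorts, predictions confirm via a
   graph information-content close-match on the ontology.

A synthetic-world generator (`genofirst.simulate`) builds every input the
pipeline consumes — HMM emission tables, domain hits, domain-term maps,
an ontology, a variant catalogue, Hardy-Weinberg genotypes, planted
outliers with truth records, and simulated answers — so the whole
framework runs and tests offline.  See `docs/methods.md` for the full
model account and design choices.

## Worked example

`examples/score_outliers.py` plants a single rare homozygous variant at a
strongly conserved domain position in one subject and scores the affected
term against a 300-genome background:

```
planted outlier: subj000 on term T0003 via v000_sr
term profile: 7 missense sites in domains linked to T0003

hidden structure: False (k=None)
top 5 transformed scores (0-1 scale, comparable across terms):
    subj000  raw=  52.62  transformed=0.5253
     bg0216  raw=  13.49  transformed=0.1783
     bg0117  raw=   4.32  transformed=0.0632
     bg0252  raw=   4.32  transformed=0.0632
     bg0090  raw=   3.95  transformed=0.0465
```

The planted subject's raw score (mean genetic distance to the cohort,
52.6) towers over the background because its opposite-homozygous genotype
at a high-intolerance site contributes fourfold distance to everyone;
transformed to the universal scale it sits far above the 0.022 call
threshold.  The other examples show call explanation
(`classify_call.py`), end-to-end confirmation with permutation tests
(`confirm_predictions.py`) and ontology close-matching
(`ontology_close_match.py`).

A thin CLI mirrors the library (`genofirst simulate|score|classify|run|
evaluate`); run `genofirst run --help` for the knobs.

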