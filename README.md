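# domenrich

Gene set enrichment analysis over **protein domain families**, for complete
result lists from quantitative high-throughput experiments — RNAi screens,
expression microarrays, ChIP-seq scores, comparative proteomics — without any
prior hit-selection or thresholding step.

Classical enrichment tools intersect a *pre-filtered* hit list with functional
annotations, which makes the outcome hostage to the hit-selection threshold
and discards the measured effect sizes. `domenrich` instead takes the **whole
uploaded population** of (identifier, value) pairs, maps every identifier
through gene → transcript → protein-domain annotations from the member
databases integrated under InterPro (Pfam, SMART, PROSITE, PRINTS,
SUPERFAMILY, ...), and asks, for every domain family, whether its values are
systematically higher or lower than the remaining values. Genes with moderate
effects contribute; a domain can emerge as significant even when none of its
members passes a conventional z-score cut-off.

## The statistics

For a domain family with values $x_1,\dots,x_{n_1}$ and background values
$y_1,\dots,y_{n_2}$ (the complement of the domain set within the uploaded
population — never an external genome-wide background):

* **Mann–Whitney U-test** (two-sided). With
  $U = \#\{(i,j): x_i > y_j\} + \tfrac12\,\#\{(i,j): x_i = y_j\}$,
  the two-sided p-value is computed from the **exact null distribution of U**
  — a dynamic-programming count over all $\binom{n_1+n_2}{n_1}$ rank
  assignments — whenever $\min(n_1,n_2) \le 25$ and the combined sample is
  tie-free. Domain families are frequently smaller than 10 proteins, where
  the usual normal approximation is poor. Larger or tied samples use the
  normal approximation with tie-corrected variance and continuity correction;
  a seeded Monte-Carlo permutation mode is available for small tied sets.
* **ρ overlap statistic**: $\rho = U /(n_1 n_2)$, the probability that a
  random domain value exceeds a random background value (ties count half).
  ρ = 0.5 means the two distributions overlap completely; ρ = 0 or 1 means
  complete separation. $|\rho - 0.5|$ is the recommended sort key for rows
  that already passed a significance threshold.
* **Multiple testing**: Benjamini–Hochberg step-up FDR-adjusted p-values
  *and* Storey q-values (π₀ estimated on the λ-grid 0.05…0.95 with a cubic
  smoothing spline; π₀ = 1 fallback for families of fewer than 100 tests).
  Because the member databases are partially redundant — the same protein
  family recurs under different accessions in different databases — testing
  and correction are performed **for each member database independently**;
  pooling them would penalise every domain for appearing several times.

The report has one row per domain family: member database, feature accession,
description, number of associated identifiers, median of their values, raw
p-value, BH FDR-adjusted p-value, Storey q-value, ρ, and the InterPro
umbrella accession.

## Worked example

The package ships a small worked example: the published polyploidy RNAi
z-scores of the seven plexins from a genome-scale cell cycle progression
screen, embedded in a synthetic screen background, with a feature grouping
the six plexins that carry a cytoplasmic RasGAP domain (PLXNC1 lacks it) and
an alternate all-seven grouping.

```python
from domenrich import DomainEnrichment
from domenrich.simulate import plexin_fixture

store, measurements = plexin_fixture(n_background=500, seed=0)
results = DomainEnrichment(measurements, store).fit()
print(results.significant().table.to_string(index=False))
```

```
database        feature_id                                                          description  n_identifiers  median      p_value        fdr_p      q_value      rho umbrella_id
   SYNTH SYN:RASGAP_PLEXIN   Plexin cytoplasmic RasGAP domain (synthetic placeholder accession)              6   3.235 9.997746e-10 1.199729e-08 1.199729e-08 0.989355  IPRSYN0001
   SYNTH SYN:PLEXIN_FAMILY Plexin family, all assayed members (synthetic placeholder accession)              7   3.140 1.462163e-06 8.772979e-06 8.772979e-06 0.939429  IPRSYN0002
```

Both plexin groupings are significantly enriched for the polyploidy
phenotype against the synthetic background: the RasGAP grouping has ρ ≈ 0.99
(near-complete separation from the background distribution) and the
all-plexins set reports the median z-score 3.14 — even though only one plexin
(PLXNA1, z = 13.15) would survive the screen's legacy z > 6 hit filter. That
is the point of testing the complete list: a coherent family of moderate
effects is detectable without per-gene thresholds. (The background here is
synthetic, so these p-values illustrate the mechanics, not the original
genome-wide analysis.)

The same analysis from the shell:

```sh
domenrich simulate -o sim/ --seed 11        # synthetic input bundle + truth
domenrich run -m sim/measurements.tsv -a sim/annotations.tsv \
              -s sim/synonyms.tsv -o report.tsv
domenrich validate -m sim/measurements.tsv -a sim/annotations.tsv
```

Input formats (tab-delimited, UTF-8):

* measurements: two columns `identifier`, `value`; header optional;
* annotations: `gene_id`, `transcript_id`, `database`, `feature_id`,
  `description`, `umbrella_id` (BioMart-style export; column names
  configurable via `ColumnSpec`);
* synonyms (optional): `user_id`, `ensembl_id`, `level` ∈ {gene, transcript}.

Gene-level identifiers fan out to all transcripts of the gene and collect the
union of their domain features; transcript/protein-level identifiers link
directly. Identifiers with no domain annotation stay in the background
population.

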