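# Methods

## Model and procedure

`domenrich` tests, for every protein domain family, whether the experimental
values of its member genes are located higher or lower than the values of the
rest of the uploaded population. The procedure is:

1. **Identifier association.** User identifiers are translated to Ensembl
   gene or transcript identifiers (via an optional synonym table at a uniform
   level; identifiers that already are Ensembl ids resolve directly).
   Gene-level identifiers fan out to *all* transcripts of the gene and the
   union of their domain features — alternative splicing means different gene
   products can carry different domains, and a gene-level value cannot be
   attributed to one isoform, so it is credited to every feature the gene can
   produce. Transcript/protein-level identifiers link only to their own
   transcript's features. The resulting (feature, identifier) pairs are
   deduplicated so one identifier contributes one value per feature, however
   many of its transcripts carry the feature. An ambiguous synonym (one user
   identifier, several Ensembl genes) fans out to all matches with a warning,
   consistent with the gene-level stance on ambiguity. Identifiers resolving
   to zero features are reported as unmapped but **kept in the background
   population**: the test background is defined as the whole uploaded
   population minus the domain set.
2. **Per-feature test.** Domain group = the feature's values; background =
   the complement within the uploaded population (so `n_domain + n_rest`
   always equals the number of measurements). Two-sided Mann-Whitney U,
   plus the ρ overlap statistic.
3. **Per-database correction.** BH-adjusted p-values and Storey q-values are
   computed across the features of one member database at a time. The member
   databases are partially redundant (the same family appears under several
   accessions), so pooling them would inflate the number of effective tests
   with near-duplicates and systematically understate significance.

## Test statistics and numerical choices

* **U and ρ.** U is computed from midranks as `R1 − n1(n1+1)/2`, which counts
  cross-pairs won by the domain group with ties at half weight; hence
  ρ = U/(n1·n2) directly. ρ is reported rather than a rank-biserial or AUC
  label, but it *is* the common-language effect size / AUC: the probability a
  random domain value exceeds a random background value.
* **Exact path.** When `min(n1, n2) ≤ exact_threshold` (default 25) and the
  combined sample is tie-free, the null distribution of U is obtained by the
  dynamic-programming recurrence `f(m, n, u) = f(m−1, n, u−n) + f(m, n−1, u)`
  (the largest pooled rank is either in the domain group, winning n pairs, or
  not). Counts are held as float64 — exact up to 2⁵³ per cell and amply
  precise beyond, since p-values are ratios of these counts; tables are
  cached per (n1, n2). The two-sided p is `min(1, 2·min(P(U≤u), P(U≥u)))`,
  matching full enumeration over all C(n1+n2, n1) labellings (tested
  exhaustively for n1, n2 ≤ 6).
* **Tie policy.** Any tie in the combined sample invalidates the tie-free
  permutation null, whether or not the tie spans the two groups, so ties
  always route to the tie-corrected normal approximation (continuity
  correction 0.5) or, on request, to a seeded Monte-Carlo permutation test
  (`method="permutation"`), recommended for very small tied sets. The exact
  and approximate paths agree to within 0.01 near the switching threshold
  (property-tested); the `method` field of every result records which path
  ran.
* **Degenerate input.** All values identical across both groups: p = 1,
  ρ = 0.5, with a logged note. p-values are floored at the smallest positive
  normal double and never reported as exactly 0.
* **BH and Storey.** Both are step-up procedures
  `q(p_(i)) = min_{j≥i} π₀·m·p_(j)/j` with π₀ = 1 for BH; sharing the
  implementation makes "Storey with π₀ = 1 equals BH" exact to the bit. The
  adjusted value is clamped from below at the raw p (float rounding of
  `m·p/i` can otherwise undercut it by one ulp). π₀ is estimated on the λ
  grid 0.05, 0.10, …, 0.95 as `#{p > λ}/(m(1−λ))`, smoothed with a cubic
  smoothing spline and read off at λ = 0.95, clamped to (0, 1]; a
  non-positive spline value falls back to π₀ = 1 (conservative, logged), as
  does any family of fewer than `pi0_min_tests` (default 100) tests, where
  the spline fit is unstable — q-values then reduce to BH.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_set_size` | 2 | smallest domain set tested; kept low because domain families are often tiny and the exact test handles them |
| `exact_threshold` | 25 | largest `min(n1, n2)` for the exact U null (tie-free only) |
| `alpha` | 0.05 | BH significance level used by `significant()` |
| `lambda_grid` | 0.05…0.95 step 0.05 | Storey π₀ grid |
| `pi0_min_tests` | 100 | family size below which π₀ = 1 |
| `duplicate_policy` | `error` | repeated measurement identifiers: hard error by default; `mean`/`median`/`first` opt-in, because silently averaging replicate probes is a decision the user should make |
| `case_fold` | off | identifier matching is case-sensitive by default; gene symbols are case-meaningful across species |
| `n_permutations`, `seed` | 10 000, None | permutation mode only |

Values are in the units of the uploaded experiment (z-scores,
log-fold-changes, ...); the package never rescales them — only ranks matter.

## Synthetic data generator

`simulate.SimulationSpec` generates an annotation universe and measurement
vector with the structural features that stress the pipeline: several member
databases, optionally *redundancy partners* that repeat another database's
gene memberships under fresh accessions (mimicking the partial redundancy of
the member databases); 1–3 transcripts per gene with features placed on
random transcript subsets, so gene-level fan-out and deduplication are
exercised; a fraction (default 10%) of genes with zero annotations, which
must survive into the background; background values N(0, 1) on the z-score
scale; and optional planted features whose member genes draw from a
location-shifted normal. Defaults describe a modest screen of 1000 genes and
one database of 50 features of 5–25 genes. Annotation topology and
measurement values are drawn from independent streams of the seed, so
changing the database layout never perturbs the measurement vector.

What the generator does **not** emulate: realistic domain co-occurrence and
nested-family structure, heavy-tailed or batch-structured screen noise,
correlated values within families beyond the planted mean shift, and real
annotation-release content. Passing tests therefore demonstrate the
statistical machinery (calibration under the null, recovery of planted
shifts, invariance properties), not performance on any particular real
screen.

The plexin worked example embeds the seven published polyploidy z-scores in
a synthetic background under placeholder accessions. Which plexins carry the
cytoplasmic RasGAP domain is fixture metadata (default: all but PLXNC1) and
configurable. Because the original genome-wide screen background is external
data and not packaged, the fixture supports ingestion, median and ρ checks —
not a reproduction of the originally published enrichment p-value.

## Design choices where the design was open

* **Flat files, no live database.** Annotations come from a BioMart-style
  export with a configurable column mapping; reproducible and testable
  offline.
* **Two-sided testing throughout**; the direction of an effect is read from
  ρ (> 0.5 enriched high, < 0.5 enriched low).
* **Transcripts absent from the annotation file** (e.g. non-protein-coding
  isoforms) simply contribute no features; the loader does not require a
  complete transcriptome.
* **Both FDR columns are reported** (BH-adjusted p and Storey q); the
  significance helper defaults to BH at α = 0.05 rather than guessing which
  column a user prefers.
* The model front end (`DomainEnrichment(...).fit()`) and the functional
  route (`run_analysis`) are the same computation; the CLI (`run`,
  `simulate`, `validate`) is a thin wrapper over them.

## Problem sizes used in the checks

The calibration and recovery checks run at desk scale chosen to make their
statistical criteria sharp: null calibration uses 20 seeds × (1000 genes, 50
features of 5–25 genes), i.e. 1000 null p-values, whose rejection fraction at
α = 0.05 is compared within 3 binomial standard deviations; planted-feature
recovery uses 20 seeds × (500 genes, 20 features of 20 genes, one feature
shifted by +2 SD) and requires the planted feature to rank first in ≥ 19
seeds. Exact-test correctness is verified exhaustively against full
enumeration for all group sizes up to 6, and against a 200 000-replicate
permutation oracle for a 25-vs-200 shifted configuration.

## Known limitations

* The exact path requires a completely tie-free sample; heavily discretised
  values (integer scores) always take the approximate or permutation path.
* π₀ estimation needs on the order of hundreds of tests; small member
  databases fall back to π₀ = 1, making q conservative (equal to BH).
* Mapping quality is bounded by the supplied annotation and synonym tables;
  the package does not resolve identifier versions or cross-release drift.
* Values are assumed exchangeable under the null within the uploaded
  population; structured noise (plate effects, batch) should be normalised
  out upstream.
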