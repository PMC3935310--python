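# Methods

This note documents the models, parameters and numerical choices behind
`subcell`, and what the synthetic test bed does and does not show.

## Evidence model

All evidence is reduced to (protein, compartment term, channel, stars)
records. The star scale is an ordinal confidence, deliberately not a
probability. Channel caps (knowledge 5, experiments 4, text mining 4,
predictions 3) encode an a-priori reliability ordering: a sequence-based
prediction can never outrank a direct experimental annotation, however
confident the predictor.

**Knowledge channel.** Evidence codes map to base stars — 4 for directly
assayed or author/curator-stated codes (CURATED, IDA, TAS, NAS), 3 for
the broad experimental/inferential group (PROBABLE, EXP, IPI, IMP, IGI,
IEP, ISS, ISO, ISA, ISM, IBA, IBD, IKR, IMR, IRD, IC), 2 for weak
automatic inference (POTENTIAL, IGC, IEA) and 1 for BY SIMILARITY, RCA
and NR. Annotations from the five curated databases (UniProtKB, MGI,
SGD, FlyBase, WormBase) are upgraded by one star, capping at five.
Codes are matched case-insensitively with collapsed whitespace. Unknown
codes score one star with a warning rather than failing the import: the
source vocabularies evolve, and a conservative floor keeps runs alive
without inflating confidence.

**Experiments channel.** Antibody-screen records carry either a
multi-antibody *reliability* level (high/medium/low/very low → 4/3/2/1
stars; at least two antibodies are validated but the count itself does
not enter the score) or a single-antibody *validation* level
(supportive → 3, uncertain → 1, non-supportive → not imported).

**Predictions channel.** Two transforms are provided. k-NN-style scores
v out of k neighbours map linearly, stars = 3·v/k (default k = 32).
Posterior probabilities map as stars = min(3, −log₁₀(1−p)) with p ≤ 0.5
dropped, so each additional "nine" of posterior adds one star — this
spreads out the mass that naive-Bayes-style predictors pile up near 1.
Both transforms are module-local and monotone, and can be swapped
without touching anything downstream.

## Slim projection

Evidence at fine-grained terms is projected onto a labeled compartment
slim (11 terms for animal and fungal schemas, 12 for plant; the animal
slim has a lysosome where the others have a vacuole, and the plant slim
adds the plastid). Projection walks the reflexive transitive closure
over `is_a` and `part_of` edges only, within the cellular-component
namespace; a term descending from two slim terms projects to both (the
slim makes no exclusivity claim). Per (protein, slim term, channel) the
maximum star value survives; the integrated score is the maximum across
channels, with absent channels simply not participating (no zero
imputation). Projection is idempotent because slim terms are their own
ancestors. Obsolete terms are skipped with a warning and counted;
records whose term has no slim ancestor are dropped and counted.

## Text mining

Tagging is exact dictionary matching: case-insensitive, token-boundary
respecting, longest match wins at overlaps. Protein names that collide
with a compartment label are discarded from the dictionary; names above
a corpus-frequency threshold (default 2,000 matches) are blocked —
recognised so they cannot shadow shorter names, but never emitted.
Orthographic-variant expansion and stemming are out of scope; the corpus
arrives pre-segmented into sentences.

Counting uses per-abstract indicator deltas: an abstract mentioning
protein P and localization L contributes w_s + w_a if some sentence
contains both and w_a otherwise, regardless of how many times either is
repeated inside the abstract. The weights exist in the scoring scheme as
tunable parameters; the defaults w_s = 2.0, w_a = 1.0 weight a
same-sentence co-mention three times an abstract-level one.

The co-occurrence score S(P,L) = C^α (C·C··/(C_P·C_L))^(1−α) with
α = 0.6 interpolates between the raw count (robust to marginal
popularity at α = 1) and an observed/expected ratio (α = 0). Because C
grows with the literature, S is calibrated to a z-score against a
Gaussian background fitted from the lower quantiles of the observed
score distribution: mean = 40th percentile (the mode of the low-scoring
random component), sigma = (P40 − P20)/Φ⁻¹(0.8) ≈ (P40 − P20)/0.8416.
Percentiles use linear interpolation between order statistics.
Calibration requires at least five distinct scores and a positive
spread; a degenerate distribution raises a calibration error rather than
emitting garbage z-scores. Stars are z/2 clamped to [0, 4]; negative-z
pairs are kept at zero stars and filtering is left to consumers.
Calibration is per corpus run (marginals are per organism, so a
multi-organism installation calibrates per organism).

The sigma estimator is one reading of "estimated from the difference
between the 20th and 40th percentiles"; it treats the observed P20 as
the background Gaussian's 20th percentile relative to a mean at P40.
Alternative readings (e.g. half-width interpretations) rescale all
z-scores by a constant and therefore change star values but not
rankings.

## Benchmark

Positives are (protein, slim compartment) pairs with five-star knowledge
evidence. Negatives pair an anchored protein (one with five-star
evidence somewhere) with every slim compartment for which *no* record
exists in the knowledge, experiments or predictions channels at any star
level — the strictest reading of "no evidence", including
prediction-only support. The channel under evaluation (text mining) is
deliberately excluded from the negative predicate; including it would
disqualify every scored pair and leave the ROC without false positives
by construction.

ROC curves rank scored pairs by descending stars, processing ties as
blocks. Benchmark pairs that never received a score cannot be predicted
positive at any threshold, so curves truncate before sensitivity 1 /
FPR 1; the truncation point is reported (`max_fpr_reached`,
`max_sens_reached`) against full-benchmark denominators. The AUC is the
trapezoid area over the attained range — i.e. ranking quality among the
scored pairs — and coincides with the Mann–Whitney statistic when
everything is scored.

## Co-localization network

Links are (protein, slim compartment) pairs with integrated stars
strictly above 2 (dropping weak text-mining and prediction evidence).
The null model permutes the compartment endpoints of the link list: a
single shuffle of the compartment column per replicate, which preserves
both degree sequences exactly. Duplicate links arising within a
replicate collapse for counting, matching the set semantics of "number
of proteins shared". Bipartite swap randomization would sample the
uniform distribution over simple bipartite graphs with the same margins;
the endpoint permutation is the more direct reading of "links were
permuted" and is kept behind the same interface.

Empirical p-values are the fraction of replicates with a shared count at
least the observed one, floored at 1/n_perm: the plain fraction can be
zero, which Benjamini–Hochberg cannot rank. The floor interacts with the
FDR level: at q = 0.001 over 55 compartment pairs, a lone pair at the
floor of a 10,000-replicate null cannot pass BH (1/10⁴ > q/55); roughly
m/10 pairs must reach the floor together, or n_perm must be raised
(the `--permutations` flag reaches 10⁶, where the floor is no
constraint). Default n_perm is 10,000 as a desk-scale compromise;
results on the default synthetic study are insensitive to raising it.

## The synthetic test bed

The generator emulates the statistical structure the analyses assume,
not biological realism:

* **Membership model.** Each of the default 2,000 proteins gets one
  uniform compartment plus, with probability 0.3, a second one. Eight
  compartment pairs mirroring trafficking-pathway biology
  (nucleus–cytosol, cytosol–cytoskeleton, nucleus–cytoskeleton,
  ER–Golgi, Golgi–plasma membrane, ER–peroxisome, plasma
  membrane–endosome, endosome–lysosome) are planted with excess
  co-membership rates of 0.20–0.35. Planting is sequential, so indirect
  correlations along chains (e.g. ER–plasma membrane through the Golgi)
  are real features of the world and may legitimately reach
  significance. Because the single-or-double membership mechanism
  conditions on every protein having at least one compartment, unplanted
  co-membership sits at the mechanism's own baseline (2m/k² for
  multi-localization rate m and k compartments), slightly below the
  product of marginals; the permutation test is calibrated against
  margins, so this does not produce false positives.
* **Corpus.** 20 abstracts per protein on average. 90% of
  protein-bearing abstracts co-mention a true compartment, 10% a false
  one (the noise the z-calibration's background component models); half
  of all co-mentions are same-sentence; 20% cite a fine-grained child
  term so projection is exercised end to end; 10% of abstracts mention
  only proteins or only compartments, feeding marginals without pairs.
  1% of proteins are *confounded*: repeatedly co-mentioned with the
  nucleus or plasma membrane without residing there, reproducing the
  known functional-association failure mode of co-mention mining —
  these compartments show visibly lower per-compartment AUCs. The
  density matters: the calibration assumes background pairs dominate the
  score distribution's lower quantiles, and sparse literature (few
  mentions per true pair) blurs true pairs into the background.
* **Annotations.** 75% of truth pairs receive a curated annotation,
  two thirds of them at a fine-grained child term; half draw a four-star
  code from a trusted source (five stars after upgrade), the rest weaker
  codes and mixed sources. 30% of proteins also get an antibody-screen
  record with mixed reliability/validation levels. Annotations are keyed
  by a UniProt-style accession so identifier unification through the
  alias table is exercised; the table plants one ambiguous alias (two
  canonical ids), one protein name colliding with a compartment label,
  and one promiscuous acronym above the blocking threshold.
* **Predictions.** The k-NN tool predicts a true compartment with
  probability 0.8 (22–32 of 32 neighbours) plus one low-score scatter
  compartment; the posterior tool concentrates ≥ 80% of its mass in
  [0, 0.1] ∪ [0.9, 1].

What passing tests show: the implementation recovers planted signal
under the stated conditions — pooled benchmark AUC ≈ 0.95, all eight
planted pairs significant at a 0.1% FDR with no spurious pairs, and an
independence world yielding none. What they do not show: performance on
real literature (no orthographic variation, no ambiguity beyond the
planted cases, template sentences), on real ontologies (the toy ontology
is three levels deep), or with realistic annotation bias (coverage is
uniform across proteins). In real data, incomplete annotation also
leaks true-but-unannotated pairs into the benchmark negatives; the
synthetic study reproduces this in proportion to its coverage parameter.

## Numerical and degenerate-input choices

* Percentile convention: linear interpolation (the common "type 7").
* ROC ties: trapezoid through tie blocks; no within-tie ordering effect.
* Star comparisons use exact floats; caps are asserted at construction
  of every evidence record, not assumed.
* Ambiguous aliases are dropped, not fanned out (precision over recall);
  unmapped aliases are dropped; both are counted and logged.
* Empty inputs: an empty knowledge channel yields an empty benchmark
  with a warning; an empty alias table, empty protein dictionary, or a
  degenerate score distribution raise errors before any output is
  written.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; sub-generators derive fixed offsets from the world seed, so
  identical configurations are byte-identical on disk.

## Problem sizes

The default study (2,000 proteins, 40,000 abstracts, 10,000
permutations) runs in seconds on one CPU and is the size at which the
signal-recovery properties are asserted; the permutation count reaches
10⁶ by flag for production-scale analyses.
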