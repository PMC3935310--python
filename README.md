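# subcell

Unify heterogeneous evidence about protein subcellular localization —
curated database annotations, antibody-based screens, literature text
mining and sequence-based predictions — onto common protein and
compartment identifiers and a single 1–5 star confidence scale, then use
the unified table for two downstream analyses: a ROC benchmark of the
text-mining channel against a knowledge-derived gold standard, and a
compartment co-localization network obtained by fixed-margin permutation
testing of shared-protein counts.

The package is aimed at computational biologists who need comparable
localization confidence scores across evidence types, and at method
developers who want a fully synthetic, self-contained test bed for
localization-evidence integration (no database downloads required).

## The scoring model

**Channels and stars.** Every piece of evidence becomes one
(protein, compartment, channel, stars) record. Stars range from 1 (lowest
confidence) to 5 (highest); each channel has a hard cap so that weaker
evidence types can never outrank reliable curation:

| channel     | source of stars                                             | cap |
|-------------|-------------------------------------------------------------|-----|
| knowledge   | GO evidence code (4★: CURATED, IDA, TAS, NAS; 3★: EXP, IMP, ISS, IC, …; 2★: IEA, IGC, POTENTIAL; 1★: BY SIMILARITY, RCA, NR) + 1★ upgrade for UniProtKB/MGI/SGD/FlyBase/WormBase | 5 |
| experiments | antibody reliability level (high/medium/low/very&nbsp;low → 4/3/2/1★) or validation level (supportive → 3★, uncertain → 1★, non-supportive dropped) | 4 |
| textmining  | z-score / 2 of the co-occurrence score (below)              | 4 |
| predictions | k-NN score: 3·v/k; posterior p: −log₁₀(1−p), dropped if p ≤ 0.5 | 3 |

**Slim projection.** Fine-grained cellular-component terms are
backtracked onto 11 labeled compartments (12 for plants) through `is_a`
and `part_of` edges; when several records land on the same (protein,
compartment) cell, the strongest wins.

**Text-mining score.** Co-mentions accumulate a weighted count over
abstracts k,

    C(P,L) = Σₖ (wₛ δₛᵏ + wₐ δₐᵏ),

with per-abstract indicator deltas for same-sentence and same-abstract
co-mention (defaults wₛ = 2, wₐ = 1). The co-occurrence score is

    S(P,L) = C(P,L)^α · ( C(P,L)·C(·,·) / (C(P,·)·C(·,L)) )^(1−α),  α = 0.6,

and is calibrated to a z-score against a Gaussian background whose mean
is the 40th percentile of the observed score distribution and whose
standard deviation is (P40 − P20)/Φ⁻¹(0.8).

**Co-localization network.** Links with more than two stars form a
bipartite protein–compartment membership. Shared-protein counts per
compartment pair are tested against a null that permutes the compartment
endpoints of the link list (preserving every protein's and compartment's
link count exactly), with empirical p-values and Benjamini–Hochberg
correction at a 0.1% FDR.

## Worked example

Generate a synthetic study — a 2,000-protein world with planted
localization truth, a 40,000-abstract corpus, curated annotations,
antibody records and predictor outputs — and push it through the whole
pipeline from the shell:

```sh
subcell synth all --seed 7 -o fixtures/
subcell knowledge   --gaf fixtures/knowledge.gaf --aliases fixtures/aliases.tsv -o out/knowledge.tsv
subcell experiments --hpa fixtures/hpa.tsv --location-map fixtures/locations.tsv -o out/experiments.tsv
subcell textmine    --corpus fixtures/corpus.tsv --lexicon fixtures/lexicon.tsv -o out/scored.tsv
subcell predictions --psort fixtures/psort.tsv --yloc fixtures/yloc.tsv \
                    --location-map fixtures/locations.tsv -o out/predictions.tsv
subcell unify --obo fixtures/ontology.obo --slim fixtures/slim.yaml \
              --knowledge out/knowledge.tsv --experiments out/experiments.tsv \
              --textmining out/scored.tsv --predictions out/predictions.tsv \
              -o out/integrated.tsv
subcell benchmark --obo fixtures/ontology.obo --slim fixtures/slim.yaml \
                  --knowledge out/knowledge.tsv --experiments out/experiments.tsv \
                  --predictions out/predictions.tsv --scored out/scored.tsv \
                  -o out/benchmark.tsv --roc-out out/roc.tsv
subcell network --integrated out/integrated.tsv --permutations 10000 --seed 1 -o out/network.tsv
```

The `benchmark` and `network` steps report to stderr:

```
benchmark: pooled AUC 0.950 (1180 pos / 8115 neg)
network: 8/55 compartment pairs significant -> out/network.tsv
```

meaning the text-mining stars rank five-star-annotated (protein,
compartment) pairs above evidence-free pairs with AUC 0.95 over the
scored range, and exactly the 8 planted co-localized compartment pairs
(nucleus–cytosol, ER–Golgi, and the other trafficking-pathway pairs)
pass the 0.1% FDR out of the 55 tested, each with empirical p = 1/10000.
The same pipeline is available in memory via
`subcell.pipeline.run_world`.

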