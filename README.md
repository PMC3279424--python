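# ppiscore

Evidence integration and confidence scoring for human protein–protein
interaction (PPI) networks.

Experimentally measured human PPIs are scattered across curated databases
(BioGRID, IntAct, MINT, DIP, HPRD, …) and primary high-throughput studies,
each with its own identifiers, detection-method vocabulary and curation
depth. Systems-biology analyses usually need one non-redundant network in
which every interaction carries a continuous confidence value, so that a
user can trade coverage against reliability with a single threshold.
`ppiscore` builds that artifact: it merges user-supplied source datasets
onto canonical protein/gene identifiers, pools the evidence per interaction,
and scores it.

## The score

Each merged interaction carries an evidence bundle: the set of studies
(PubMed ids) reporting it, the distinct detection techniques used, and the
non-human species in which orthologs of the pair were observed to interact.
Three evidence quantities are squashed through a saturating curve and
combined as a weighted sum:

```
s_i(n) = 1 − exp(−a_i · n),            i ∈ {s, o, t}

S = w_s·s_s(n_studies) + w_o·s_o(n_organisms) + w_t·s_t(technique_mass)
    with w_s + w_o + w_t = 1
```

where `technique_mass` is the sum of curated reliability scores (0–10) of
the distinct techniques — structure-grade in vitro methods such as X-ray
crystallography score 10, affinity/complementation assays cluster around 5,
indirect evidence like colocalization scores 1. The packaged default
parameters `a_s=2.3, a_o=1.6, a_t=0.2, w_s=0.6, w_o=0.1, w_t=0.3` place a
single-study interaction with one average (score-5) technique at S ≈ 0.7295,
just below the 0.73 upper-quartile boundary: high confidence effectively
requires multi-study or cross-organism support. Ortholog evidence only ever
*boosts* an interaction — a pair never enters the network on non-human
evidence alone.

The six parameters can be re-derived for any reference dataset with
study-level annotations by an exhaustive grid search: each candidate is
ranked by a leave-one-study-out objective (does the score enrich the PPIs a
held-out study shares with the rest of the data above the upper quartile?),
with the score distribution's interquartile range breaking ties. See
`docs/methods.md` for the full model.

## Worked example

Everything below runs offline on generated fixtures:

```
$ ppiscore make-fixtures --outdir fixtures --seed 7 --n-proteins 120 \
      --n-interactions 300 --with-screen
wrote fixtures to fixtures (6 core files)

$ ppiscore score --source fixtures/source_synthA.tsv \
      --source fixtures/source_synthB.tsv --source fixtures/source_synthC.tsv \
      --mapping fixtures/id_mapping.tsv --orthologs fixtures/orthologs.tsv \
      --out scored.tsv
INFO ppiscore: effective parameters: {'a_s': 2.3, 'a_o': 1.6, 'a_t': 0.2, 'w_s': 0.6, 'w_o': 0.1, 'w_t': 0.3}
INFO ppiscore: merged 490 records into 292 interactions (27 genetic excluded, 7 dropped unmappable, 6 ortholog-only discarded)
wrote 292 scored interactions to scored.tsv
```

490 raw records collapse to 292 unique interactions: genetic-interaction
records are excluded, records with unmappable endpoints are dropped (each
drop is reported), duplicates across sources are merged with their evidence
unioned, and ortholog evidence that has no human experimental support to
attach to is discarded. The flat output has six columns — UniProt id and
Entrez Gene id per partner, the score at two decimals, and the evidence
comment:

```
P00001  100001  P00024  100024  0.65  experiments:in vivo;pmids:900000001,900000014,900000021;sources:synthA,synthB,synthC
P00001  100001  P00026  100026  0.83  experiments:gst pull down,in vivo;pmids:900000020;sources:synthB;organisms:Saccharomyces cerevisiae
```

The first interaction was seen in three studies but only with a weak
technique (`in vivo`, score 1) → S = 0.65; the second has one study but two
techniques plus yeast ortholog support → S = 0.83.

Evaluating the network against the generated bait-based screen stratifies it
at the upper quartile and tests whether high-confidence interactions are
recalled better:

```
$ ppiscore evaluate --network scored.tsv --baits fixtures/screen_baits.txt \
      --pairs fixtures/screen_pairs.tsv
INFO ppiscore: using upper-quartile threshold 0.79
subset          size  detectable  overlap (recall)
score >= 0.79   87    74          18 (24.3%)
score < 0.79    205   176         10 (5.7%)
one-sided Fisher p = 3.65e-04
```

Only interactions touching a bait count as detectable; here the screen was
planted with higher recall in the high stratum, and the one-sided Fisher
test recovers that direction. `ppiscore subnetwork` extracts layer-0/1
neighborhoods at a confidence threshold, `ppiscore optimize` runs the grid
search, and `ppiscore convert` bridges the flat format and PSI-MI TAB 2.5.

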