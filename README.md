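# spanner

Rank-flexible taxonomic assignment of metagenomic sequences from their
*profiles* of homology matches.

## The problem

Assigning a metagenomic read or gene to a taxon from its BLAST-style hits is
easy when a close relative is in the reference database and treacherous when
it is not. The best-hit baseline always commits to a full lineage and is
therefore wrong below some rank whenever the true organism is novel. The
classic LCA remedy — assign the lowest common ancestor of all hits within a
bitscore fraction `p` of the best — is safe but conservative, and it
collapses catastrophically when a single distant match enters the hit list,
as happens for laterally transferred (LGT) genes: one hit from the wrong
domain drags the LCA to "cellular organisms", i.e. unclassified.

This package implements a profile-matching classifier that sits between the
two. Each sequence is represented by its **LCA Profile**: the set of its
matches `(taxon, bitscore, e-value)` within `p` of the best bitscore,
deduplicated to the best hit per taxon. Reference sequences get profiles
from an all-vs-all search of the reference database. A query is assigned by
*comparing whole profiles*: genes from the same lineage — including genes
with odd evolutionary histories — tend to exhibit the same matching pattern,
so a query whose profile contains a strange distant hit is still matched to
reference profiles carrying the same signature.

## The similarity: a pyramid match kernel

Two profiles are compared on a 2D grid: one axis groups matched taxa by the
taxonomy, the other carries the e-values, transformed to `-log10 e` and
min–max normalized per profile. Over `h` iterations (`h` = 8 canonical
ranks) the grid coarsens: at iteration `i` taxa are binned by their ancestor
at rank depth `h - i` and the e-value axis has `2^(h-i)` equal bins, ending
with a single cell. The iteration's intersection count

&nbsp;&nbsp;&nbsp;&nbsp;`I_i = Σ_cells min(count_a, count_b)`

is weighted by `w_i = 2^(1-i)`, and the similarity is `Σ_i w_i · I_i`.
Unlike the classic pyramid match kernel, *total* (not newly formed)
intersections are weighted at every level, rewarding profiles that agree at
fine granularity repeatedly.

The query is scored against every reference profile; references scoring at
least `y` × the best score are retained, and the assignment is the LCA of
their source taxa, truncated to genus by default. Depths are the ordinals 0
("cellular organisms", effectively unclassified) to 7 (species).

## Worked example

The four-rank miniature fixture (`make_worked_example`) compares a
three-match "star" profile with a three-match "circle" profile:

```python
import spanner as sp

star, circle, tax = sp.make_worked_example()
res = sp.pmk_score(star, circle, tax, sp.PMKConfig(h=4))
for i, w, n in res.per_iteration:
    print(f"iteration {i}: weight {w:<6g} intersections {n}  cumulative {res.cumulative()[i-1]}")
print("similarity:", res.score)
```

prints

```
iteration 1: weight 1      intersections 0  cumulative 0.0
iteration 2: weight 0.5    intersections 1  cumulative 0.5
iteration 3: weight 0.25   intersections 2  cumulative 1.0
iteration 4: weight 0.125  intersections 3  cumulative 1.375
similarity: 1.375
```

No pair of matches shares a species-level cell; one pair co-bins at genus,
two at family, and all three in the single root cell — so the weighted total
is ½ + (¼ + ¼) + (⅛ + ⅛ + ⅛) = 1.375.

The LGT contrast on a synthetic world — a confounded query whose lineage
shares its donor with the reference proteins of that lineage:

```python
tax8 = sp.make_toy_taxonomy((2, 2, 1, 1, 2, 2, 2))
world = sp.simulate_reference_world(tax8, sp.SimConfig(lgt_rate=0.5, seed=11), p=0.85)
qid = sorted(q for q in world.query_hits if world.truth[q] in world.confounded)[0]
profile = sp.build_profile(world.query_hits[qid], p=0.85, source_id=qid)
print(sp.lca_assign(profile, tax8).assigned_taxon)
print(sp.spanner_assign(profile, world.ref_set, 0.95, tax8).assigned_taxon)
```

prints

```
root
root.0.0.0.0.0.0
```

The profile holds the true species plus a hit in the other domain
(`root.1.1.0.0.1.0.0`), so LCA collapses to the root (unclassified) while
profile matching recovers the correct genus at depth 6.

## Command line

```
spanner simulate   --out-dir world --seed 7          # synthetic hit tables
spanner build-ref  --blast world/ref_hits.tsv --taxon-map world/taxon_map.tsv \
                   --taxonomy world/taxonomy.tsv --p 0.85 --out refs.tsv
spanner classify   --blast world/query_hits.tsv --taxon-map world/taxon_map.tsv \
                   --taxonomy world/taxonomy.tsv --ref refs.tsv \
                   --method spanner --y 0.95 --out calls.tsv
spanner evaluate   --blast world/ref_hits.tsv --taxon-map world/taxon_map.tsv \
                   --taxonomy world/taxonomy.tsv --truth world/truth.tsv \
                   --novelty-rank species --out-prefix eval
```

Inputs are standard tabular (outfmt-6-style) hit files, a
`subject_id<TAB>taxon_id` map, and a taxonomy in either the NCBI
`nodes.dmp`/`names.dmp` dump dialect or a simple 4-column TSV. Defaults are
`p = 0.85` and `y = 0.95`.

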