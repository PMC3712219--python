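# Methods

## Model

A sequence's homology evidence is summarized as an **LCA Profile**: among
its tabular search hits, the best hit per taxon is kept, then every match
with bitscore below `p × best` is discarded (the boundary is inclusive:
`bitscore ≥ p × best` is kept, with a 1e-9 relative epsilon so the rule
survives binary floating-point representation of `p`). Deduplication runs
before thresholding so a taxon's weaker secondary hits never influence the
threshold. The empty profile is an explicit sentinel and classifies as
unclassified (the root).

Three classifiers share the assignment contract:

* **best-BLAST** — the top-bitscore hit's lineage (ties: ascending e-value,
  then lexicographic taxon id), truncated to the maximum depth.
* **LCA** — lowest common ancestor of all profile taxa.
* **profile matching (spanner)** — the query profile is scored against every
  reference profile with the pyramid match kernel below; references with
  score `≥ y × best` are retained (inclusive, mirroring `p`) and the
  assignment is the LCA of their source taxa.

Assignments are truncated to genus (ordinal depth 6) by default; species
and strain naming in reference databases is too inconsistent to assign
deeper. Depth 0, "cellular organisms", is the unclassified outcome.

## Taxonomy

The eight canonical ranks are ordinals 0–7: cellular organisms, domain,
phylum, class, order, family, genus, species. Loaded taxonomies (NCBI dump
or simple TSV) are canonicalized: nodes at non-canonical ranks ("no rank"
intermediates, subspecies, strains; `superkingdom` is treated as a spelling
of `domain`) are collapsed onto their nearest canonical ancestor and kept as
aliases, so strains resolve to their species. Collapsing is this package's
choice of normalization; preserving intermediate nodes would leave the
kernel's level/rank correspondence undefined. A malformed input (multiple
roots, unknown parents, cycles, rank inversions) is a structural error at
load time.

## Kernel

Matches are embedded on a 2D grid. The e-value coordinate is
`x = -log10(max(e, floor))` min–max rescaled per profile to [0, 1] (best
match → 1.0); per-profile normalization makes genes with different
substitution rates comparable, and a profile with all-equal e-values (in
particular a singleton) maps every point to 1.0. The floor default is
1e-180 because search tools report 0.0 below their representable range.

Iteration `i` of `h` bins the taxonomy axis by the ancestor at rank depth
`h - i` (a match whose lineage does not reach that depth bins by its deepest
available ancestor) and the e-value axis into `2^(h-i)` half-open bins
closed at the top (`index = min(floor(pos·n), n-1)`, so 1.0 lands in the
last bin). The final iteration is therefore a single cell, which guarantees
`I_h = min(|a|, |b|)`. Intersections are *total* per-cell minima, weighted
`2^(1-i)` and summed. Consequences used as test oracles:

* `I_i` is non-decreasing (both axes only coarsen, and the bins nest);
* identical profiles score `n (2 - 2^(1-h))`;
* profiles sharing no ancestor below the root score `2^(1-h) min(n_a, n_b)`;
* the kernel is symmetric and bounded by the identical-profile value.

`h` must equal the taxonomy's rank count; the mismatch is a hard error
rather than a silent clamp.

## Evaluation

Each rank is an ordinal. For an assignment at depth `d` against a truth
lineage, *precision* = `d`, *correct* = depth of the LCA of the assigned
taxon and the truth's deepest node (equivalently the longest common prefix
of the two lineages), and *incorrect* = precision − correct, an exact
integer identity preserved by averaging.

The leave-one-out experiment takes each reference sequence in turn as the
query, deletes every reference profile from its clade at the novelty rank,
masks matches to that clade out of the remaining profiles and the query's
own, and re-applies `p` relative to the new best bitscore — masking precedes
thresholding, so hits that sat below the original threshold re-enter once
the clade is removed. For this reason the experiment consumes *untrimmed*
(p = 0) profiles and takes the working `p` as a parameter. Classification
is capped one rank above the novelty rank (the correct taxon at the novelty
rank no longer exists in the database). An assignment reaching the cap with
a wrong lineage is penalized through the incorrect-rank count, not
truncated; truncation is available separately via `max_depth`.

## Synthetic data generator

The generator emulates search output at the hit-table level — no sequences
are simulated, because all of the classifier's mathematics consumes
`(taxon, bitscore, e-value)` triples. Defaults, chosen once as the
package's study conditions:

| parameter | default | rationale |
|---|---|---|
| taxonomy shape | (2,2,1,1,2,2,2) | 32 species, 16 genera, two domains: every rank that the metrics exercise is populated while leave-one-out over all references stays sub-second |
| refs per species | 2 | smallest value that makes reference-profile agreement non-trivial |
| bitscore base | 500 | a typical strong protein hit |
| decay per rank | 0.8 | 20% bitscore loss per rank of taxonomic distance; with `p = 0.85` a clean profile holds the self hit and close relatives only |
| noise | lognormal σ = 0.02 | mild multiplicative noise; keeps bitscores positive |
| e-value map | `e = 10^(-0.3·bit)` | fixed monotone map, mirroring the bitscore–e-value coupling of real output |
| LGT strength | 0.922 = √0.85 | the donor hit sits at the geometric center of the `p = 0.85` retention window: inside the profile yet below the self hit — the configuration that defines the confounder — with symmetric margin against noise |

Self-hits carry no noise: a self-alignment is exact, and its bitscore is the
profile's anchor. Lineage-consistent confounding is the point of the LGT
scenario: a confounded species' queries *and* its reference proteins carry a
hit to the same distant-domain donor, so the database contains profiles
exhibiting the query's anomalous pattern — the mechanism that lets profile
matching stay precise where LCA collapses.

What the generator does **not** model: gene prediction and fragment-length
effects, compositional signal, uneven taxon sampling, rate variation across
genes beyond the per-profile e-value normalization, multiple hits per
genome, and real taxonomies' missing intermediate ranks (the toy trees are
complete and balanced; the taxonomy loader, not the generator, is exercised
on ragged inputs). Passing tests on these worlds demonstrate the internal
consistency and the qualitative phenomena of the method, not field accuracy
on real metagenomes.

## Numerical and design choices

* Threshold boundaries for `p` and `y` are inclusive, with a 1e-9 relative
  epsilon against float dust.
* Deterministic orderings everywhere: profiles sort by bitscore descending
  (ties: e-value ascending, then taxon id); reference rankings by score
  descending then id; batch output by query id.
* `y` is only meaningful for profile matching; the CLI warns and ignores it
  for other methods.
* The leave-one-out drop rule removes same-clade reference profiles
  entirely, in addition to masking their appearances inside other profiles —
  the stricter reading of "the genome is absent from the database".
* All randomness flows through `numpy.random.default_rng` seeded from the
  configuration; every generator output is a pure function of (config,
  seed).

## Problem sizes

The bundled experiments run on the default 32-species world (64 reference
profiles; leave-one-out over all of them takes ~0.3 s) and the suite's
kernel cross-validation uses 200 random profile pairs of up to 30 matches.
These sizes populate every code path and phenomenon the package claims;
larger worlds scale linearly in references × queries.

## Known limitations

* The kernel ranks reference profiles; it is not calibrated as a
  probability, and `y` trades precision against incorrect ranks without an
  error model.
* Canonicalizing to exactly eight ranks discards sub-species resolution by
  design.
* With very small profiles (1–2 matches) the e-value axis carries little
  information (all points at 1.0 after per-profile normalization), so
  discrimination rests on the taxonomy axis alone.
* The evaluation treats the reference taxonomy as ground truth; taxonomic
  misannotation in real databases is out of scope.
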