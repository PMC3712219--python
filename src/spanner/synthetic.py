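"""Synthetic worlds: toy taxonomies and simulated homology-hit tables.

The generator operates at the hit-table level, where all of the
classifier's mathematics lives: it emulates the outcome of a protein
search without simulating sequences.  Each query receives one hit per
reference species whose bitscore decays geometrically with the taxonomic
distance to the query's true species, perturbed by mild multiplicative
lognormal noise; e-values are derived from bitscores by a fixed monotone
map, as in real search output.  An optional lateral-gene-transfer (LGT)
confounder gives a query (and, crucially, the reference proteins of its
own lineage) a high-scoring hit to a fixed donor species in the other
domain — the pattern that collapses naive LCA assignment to the root
while leaving the profile-similarity signal intact.

Everything is a pure function of (config, seed) and the generated worlds
round-trip through the real tabular parsers via :func:`write_world_tables`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .profiles import (
    LCAProfile,
    Match,
    ReferenceSet,
    build_profile,
    build_reference_set,
)
from .taxonomy import CANONICAL_RANKS, Taxonomy


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the package's study conditions.

    ``taxonomy_shape`` gives the branching factor at each of the seven
    ranks below the root (domain ... species).  Bitscores start at
    ``bitscore_base`` for a self-hit and shrink by ``decay_per_rank`` per
    rank of taxonomic distance; ``noise_sigma`` is the sigma of the
    multiplicative lognormal perturbation.  With probability ``lgt_rate`` a
    species lineage is confounded: its queries (and a ``ref_confound_frac``
    fraction of its reference proteins) carry a donor hit at
    ``lgt_strength`` x ``bitscore_base`` to a fixed species in another
    domain; the default 0.922 = sqrt(0.85) places the donor at the
    geometric center of the customary p = 0.85 retention window — inside
    the profile yet below the self hit, the configuration that defines the
    confounder.  E-values follow ``10^(-evalue_decades_per_bit x bitscore)``.
    """

    taxonomy_shape: tuple[int, ...] = (2, 2, 1, 1, 2, 2, 2)
    n_refs_per_species: int = 2
    n_queries_per_species: int = 1
    bitscore_base: float = 500.0
    decay_per_rank: float = 0.8
    evalue_decades_per_bit: float = 0.3
    noise_sigma: float = 0.02
    lgt_rate: float = 0.0
    lgt_strength: float = 0.922
    ref_confound_frac: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.taxonomy_shape) != 7:
            raise ValueError("taxonomy_shape needs 7 branching factors (domain..species)")
        if any(b < 1 for b in self.taxonomy_shape):
            raise ValueError("branching factors must be >= 1")
        if not 0.0 < self.decay_per_rank < 1.0:
            raise ValueError("decay_per_rank must lie in (0, 1)")
        for name in ("lgt_rate", "lgt_strength", "ref_confound_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.bitscore_base <= 0 or self.evalue_decades_per_bit <= 0:
            raise ValueError("bitscore_base and evalue_decades_per_bit must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_refs_per_species < 1 or self.n_queries_per_species < 1:
            raise ValueError("need at least one reference and one query per species")


def make_toy_taxonomy(shape: Sequence[int]) -> Taxonomy:
    """Complete balanced taxonomy over the eight canonical ranks.

    ``shape`` gives seven branching factors (domain down to species); ids
    are deterministic dotted paths rooted at ``"root"``.
    """
    shape = tuple(shape)
    if len(shape) != 7:
        raise ValueError("shape needs 7 branching factors (domain..species)")
    if any(b < 1 for b in shape):
        raise ValueError("branching factors must be >= 1")
    nodes: dict[str, tuple[str | None, str, str]] = {
        "root": (None, CANONICAL_RANKS[0], "root")
    }
    level = ["root"]
    for depth, factor in enumerate(shape, start=1):
        rank = CANONICAL_RANKS[depth]
        nxt = []
        for parent in level:
            for k in range(factor):
                taxon = f"{parent}.{k}"
                nodes[taxon] = (parent, rank, taxon)
                nxt.append(taxon)
        level = nxt
    return Taxonomy(nodes)


def make_worked_example() -> tuple[LCAProfile, LCAProfile, Taxonomy]:
    """The canonical regression anchor for the kernel: two three-match
    profiles on a four-rank taxonomy arranged so the per-iteration total
    intersections are exactly (0, 1, 2, 3) and the similarity is 1.375.

    At iteration 1 no two matches share a species-level cell; one pair
    co-bins at (genus, quarter-axis) in iteration 2; two pairs at
    (family, half-axis) in iteration 3; and all three profiles' points
    fall into the single root cell at iteration 4, giving
    0.5 + (0.25 + 0.25) + (0.125 x 3) = 1.375.
    """
    rank_order = ("order", "family", "genus", "species")
    nodes: dict[str, tuple[str | None, str, str]] = {
        "O1": (None, "order", "O1"),
        "F1": ("O1", "family", "F1"),
        "F2": ("O1", "family", "F2"),
        "G1": ("F1", "genus", "G1"),
        "G2": ("F1", "genus", "G2"),
        "G3": ("F2", "genus", "G3"),
        "S1": ("G1", "species", "S1"),
        "S2": ("G2", "species", "S2"),
        "S3": ("G3", "species", "S3"),
        "S4": ("G1", "species", "S4"),
        "S5": ("G2", "species", "S5"),
        "S6": ("G3", "species", "S6"),
    }
    tax = Taxonomy(nodes, rank_order=rank_order)

    def hits(spec: Sequence[tuple[str, float]]) -> list[Match]:
        # bitscore kept consistent with the e-value exponent
        return [
            Match(subject_taxon=t, bitscore=exp * 2.0, evalue=10.0 ** (-exp))
            for t, exp in spec
        ]

    # normalized e-value positions: star (1.0, 0.6, 0.0); circle (1.0, 0.0, 0.3)
    star = build_profile(
        hits([("S1", 103.0), ("S2", 63.0), ("S3", 3.0)]), p=0.0, source_id="star"
    )
    circle = build_profile(
        hits([("S4", 103.0), ("S5", 3.0), ("S6", 33.0)]), p=0.0, source_id="circle"
    )
    return star, circle, tax


def _evalue(bitscore: float, cfg: SimConfig) -> float:
    return 10.0 ** (-cfg.evalue_decades_per_bit * bitscore)


def _noise(rng: np.random.Generator, cfg: SimConfig) -> float:
    return float(rng.lognormal(0.0, cfg.noise_sigma)) if cfg.noise_sigma else 1.0


def _foreign_species(true_species: str, tax: Taxonomy) -> list[str]:
    domain = tax.ancestor(true_species, 1, exact=True)
    return [s for s in tax.species() if tax.ancestor(s, 1, exact=True) != domain]


def simulate_hits(
    true_species: str,
    tax: Taxonomy,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    donor: str | None = None,
    draw_lgt: bool = True,
) -> list[Match]:
    """One hit per reference species, decaying with taxonomic distance.

    Taxonomic distance is the species depth minus the depth of the LCA
    with ``true_species`` (0 for a self-hit).  If ``donor`` is given — or
    drawn internally with probability ``cfg.lgt_rate`` when ``draw_lgt``
    is set — that distant-domain species' hit is boosted to
    ``lgt_strength x bitscore_base``, emulating a laterally transferred
    gene.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if tax.depth(true_species) != tax.max_depth:
        raise ValueError(f"{true_species!r} is not a species-rank taxon")
    if donor is None and draw_lgt and cfg.lgt_rate > 0 and rng.random() < cfg.lgt_rate:
        foreign = _foreign_species(true_species, tax)
        if not foreign:
            raise ValueError("LGT requested but the taxonomy has a single domain")
        donor = foreign[rng.integers(len(foreign))]
    hits = []
    for species in tax.species():
        if species == donor:
            bit = cfg.bitscore_base * cfg.lgt_strength * _noise(rng, cfg)
        else:
            dist = tax.max_depth - tax.depth(tax.lca([true_species, species]))
            # a self-alignment is exact: the distance-0 hit carries no noise
            noise = 1.0 if dist == 0 else _noise(rng, cfg)
            bit = cfg.bitscore_base * cfg.decay_per_rank**dist * noise
        hits.append(Match(subject_taxon=species, bitscore=bit, evalue=_evalue(bit, cfg)))
    return hits


@dataclass(frozen=True)
class World:
    """A complete simulated study: references, queries and ground truth."""

    ref_set: ReferenceSet
    ref_hits: dict[str, list[Match]] = field(repr=False)
    query_hits: dict[str, list[Match]] = field(repr=False)
    truth: dict[str, str]
    confounded: frozenset[str]
    donors: dict[str, str]


def simulate_reference_world(tax: Taxonomy, cfg: SimConfig, p: float = 0.85) -> World:
    """Generate an all-vs-all-style reference set plus a query panel.

    Confounding is lineage-consistent: a confounded species' queries and a
    ``ref_confound_frac`` fraction of its reference proteins all carry a
    hit to the *same* donor, so the reference database contains profiles
    exhibiting the query's anomalous matching pattern.
    """
    rng = np.random.default_rng(cfg.seed)
    species = tax.species()
    confounded: set[str] = set()
    donors: dict[str, str] = {}
    if cfg.lgt_rate > 0:
        foreign_by_species = {s: _foreign_species(s, tax) for s in species}
        for s in species:
            if rng.random() < cfg.lgt_rate:
                foreign = foreign_by_species[s]
                if not foreign:
                    raise ValueError("LGT requested but the taxonomy has a single domain")
                confounded.add(s)
                donors[s] = foreign[rng.integers(len(foreign))]

    truth: dict[str, str] = {}
    ref_hits: dict[str, list[Match]] = {}
    for s in species:
        for j in range(cfg.n_refs_per_species):
            ref_id = f"{s}|ref{j}"
            donor = None
            if s in confounded and rng.random() < cfg.ref_confound_frac:
                donor = donors[s]
            ref_hits[ref_id] = simulate_hits(s, tax, cfg, rng=rng, donor=donor,
                                             draw_lgt=False)
            truth[ref_id] = s
    query_hits: dict[str, list[Match]] = {}
    for s in species:
        for k in range(cfg.n_queries_per_species):
            qid = f"{s}|q{k}"
            donor = donors.get(s)
            query_hits[qid] = simulate_hits(s, tax, cfg, rng=rng, donor=donor,
                                            draw_lgt=False)
            truth[qid] = s

    taxon_map = {rid: truth[rid] for rid in ref_hits}
    ref_set = build_reference_set(ref_hits, taxon_map, p, taxonomy=tax)
    return World(
        ref_set=ref_set,
        ref_hits=ref_hits,
        query_hits=query_hits,
        truth=truth,
        confounded=frozenset(confounded),
        donors=donors,
    )


# -- on-disk round trip ----------------------------------------------------


def _write_outfmt6(path: Path, hits: Mapping[str, Sequence[Match]]) -> None:
    """Write hits as standard 12-column tabular search output.

    Subjects are written as one representative sequence id per species
    (``<species>|rep``); alignment bookkeeping columns carry placeholder
    values since the simulator works at the hit level.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for qid in sorted(hits):
            for m in hits[qid]:
                fh.write(
                    f"{qid}\t{m.subject_taxon}|rep\t50.0\t100\t0\t0\t1\t100\t1\t100\t"
                    f"{m.evalue:.6e}\t{m.bitscore:.3f}\n"
                )


def write_world_tables(world: World, tax: Taxonomy, out_dir: str | Path) -> dict[str, Path]:
    """Write a world as plain-text tables that round-trip through the parsers.

    Emits the taxonomy (simple TSV), reference all-vs-all and query hit
    tables (tabular search format), the subject-to-taxon map and the truth
    table; returns the path of each file by role.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "taxonomy": out_dir / "taxonomy.tsv",
        "ref_hits": out_dir / "ref_hits.tsv",
        "query_hits": out_dir / "query_hits.tsv",
        "taxon_map": out_dir / "taxon_map.tsv",
        "truth": out_dir / "truth.tsv",
    }
    tax.to_simple_tsv(paths["taxonomy"])
    _write_outfmt6(paths["ref_hits"], world.ref_hits)
    _write_outfmt6(paths["query_hits"], world.query_hits)
    with open(paths["taxon_map"], "w", encoding="utf-8") as fh:
        for s in tax.species():
            fh.write(f"{s}|rep\t{s}\n")
        for rid in sorted(world.ref_hits):
            fh.write(f"{rid}\t{world.truth[rid]}\n")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        for sid in sorted(world.truth):
            fh.write(f"{sid}\t{world.truth[sid]}\n")
    return paths


def read_taxon_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``subject_id<TAB>taxon_id`` table."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            subject, taxon = line.split("\t")
            out[subject] = taxon
    return out
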