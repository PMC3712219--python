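"""Ranked taxonomy with lineage and lowest-common-ancestor queries.

The classifier works on a fixed eight-rank hierarchy whose depths are the
ordinals 0 ("cellular organisms", effectively unclassified) through 7
(species).  A taxonomy loaded from disk is *canonicalized* at load time:
nodes whose rank is not one of the eight canonical ranks (``no rank``
intermediates, subspecies, strains, ...) are collapsed onto their nearest
canonical ancestor and kept only as aliases, so every surviving node sits at
a well-defined ordinal depth.  Strains therefore resolve to their species.

Two on-disk dialects are supported: the NCBI ``nodes.dmp``/``names.dmp``
dump format and a simple four-column TSV.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

CANONICAL_RANKS: tuple[str, ...] = (
    "cellular organisms",
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: rank-name spellings that map onto a canonical rank instead of collapsing
_RANK_SYNONYMS = {"superkingdom": "domain"}


class TaxonomyError(Exception):
    """Base class for taxonomy problems."""


class TaxonomyStructureError(TaxonomyError):
    """The input does not describe a valid rooted ranked tree."""


class UnknownTaxonError(TaxonomyError, KeyError):
    """A taxon id does not resolve in the taxonomy."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return self.args[0] if self.args else ""


@dataclass(frozen=True)
class Lineage:
    """Root-to-node ranked path: a tuple of (rank depth, taxon id) pairs.

    Depths are strictly increasing and the first entry is always the root.
    Depths need not be contiguous (a lineage may lack e.g. an order-rank
    ancestor if the source taxonomy had none).
    """

    entries: tuple[tuple[int, str], ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def deepest_depth(self) -> int:
        return self.entries[-1][0]

    @property
    def deepest_taxon(self) -> str:
        return self.entries[-1][1]

    def at_depth(self, depth: int, exact: bool = True) -> str | None:
        """Taxon at ``depth``; with ``exact=False`` the deepest one at or above."""
        best = None
        for d, t in self.entries:
            if d == depth:
                return t
            if d > depth:
                break
            best = t
        return None if exact else best

    def truncate(self, depth: int) -> "Lineage":
        """Prefix of the lineage containing the entries at depth <= ``depth``."""
        return Lineage(tuple((d, t) for d, t in self.entries if d <= depth))


class Taxonomy:
    """A canonical rooted ranked tree with LCA and lineage queries.

    Parameters
    ----------
    nodes:
        Mapping of taxon id -> (parent id, rank name, display name).  The
        single root has parent ``None`` and carries the first rank of
        ``rank_order``.  All ranks must appear in ``rank_order`` and every
        parent must sit at a strictly smaller depth.
    rank_order:
        Rank names from root to leaf; depth of a node is the index of its
        rank.  Defaults to the eight canonical ranks.
    aliases:
        Optional mapping of collapsed (non-canonical) taxon ids onto the
        canonical node they resolve to.
    """

    def __init__(
        self,
        nodes: Mapping[str, tuple[str | None, str, str]],
        rank_order: Sequence[str] = CANONICAL_RANKS,
        aliases: Mapping[str, str] | None = None,
    ) -> None:
        self.rank_order: tuple[str, ...] = tuple(rank_order)
        if len(set(self.rank_order)) != len(self.rank_order) or not self.rank_order:
            raise TaxonomyStructureError("rank_order must be a non-empty unique sequence")
        self._depth_of_rank = {r: i for i, r in enumerate(self.rank_order)}
        self._nodes: dict[str, tuple[str | None, str, str]] = dict(nodes)
        self._aliases: dict[str, str] = dict(aliases or {})
        self._lineages: dict[str, Lineage] = {}

        roots = [t for t, (p, _, _) in self._nodes.items() if p is None]
        if len(roots) != 1:
            raise TaxonomyStructureError(f"expected exactly one root, found {len(roots)}")
        self.root: str = roots[0]
        if self._nodes[self.root][1] != self.rank_order[0]:
            raise TaxonomyStructureError(
                f"root {self.root!r} must carry rank {self.rank_order[0]!r}"
            )
        for taxon, (parent, rank, _) in self._nodes.items():
            if rank not in self._depth_of_rank:
                raise TaxonomyStructureError(f"node {taxon!r} has unknown rank {rank!r}")
            if parent is None:
                continue
            if parent not in self._nodes:
                raise TaxonomyStructureError(f"node {taxon!r} has unknown parent {parent!r}")
            if self._depth_of_rank[self._nodes[parent][1]] >= self._depth_of_rank[rank]:
                raise TaxonomyStructureError(
                    f"parent of {taxon!r} is not at a shallower rank"
                )
        for alias, target in self._aliases.items():
            if target not in self._nodes:
                raise TaxonomyStructureError(f"alias {alias!r} points at unknown node {target!r}")

    # -- basic queries ----------------------------------------------------

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._nodes or taxon in self._aliases

    def __len__(self) -> int:
        return len(self._nodes)

    def taxa(self) -> list[str]:
        return sorted(self._nodes)

    def resolve(self, taxon: str) -> str:
        """Resolve a taxon id (possibly a collapsed alias) to a canonical node."""
        if taxon in self._nodes:
            return taxon
        if taxon in self._aliases:
            return self._aliases[taxon]
        raise UnknownTaxonError(f"unknown taxon id {taxon!r}")

    def rank(self, taxon: str) -> str:
        return self._nodes[self.resolve(taxon)][1]

    def name(self, taxon: str) -> str:
        return self._nodes[self.resolve(taxon)][2]

    def parent(self, taxon: str) -> str | None:
        return self._nodes[self.resolve(taxon)][0]

    def depth(self, taxon: str) -> int:
        return self._depth_of_rank[self.rank(taxon)]

    def rank_name(self, depth: int) -> str:
        return self.rank_order[depth]

    @property
    def max_depth(self) -> int:
        return len(self.rank_order) - 1

    def taxa_at_depth(self, depth: int) -> list[str]:
        rank = self.rank_order[depth]
        return sorted(t for t, (_, r, _) in self._nodes.items() if r == rank)

    def species(self) -> list[str]:
        """Leaf-rank taxa (the deepest rank of ``rank_order``)."""
        return self.taxa_at_depth(self.max_depth)

    # -- lineage / LCA ----------------------------------------------------

    def lineage(self, taxon: str) -> Lineage:
        node = self.resolve(taxon)
        cached = self._lineages.get(node)
        if cached is not None:
            return cached
        chain: list[tuple[int, str]] = []
        cur: str | None = node
        while cur is not None:
            chain.append((self.depth(cur), cur))
            cur = self._nodes[cur][0]
        lin = Lineage(tuple(reversed(chain)))
        self._lineages[node] = lin
        return lin

    def ancestor(self, taxon: str, depth: int, exact: bool = False) -> str | None:
        """Ancestor-or-self of ``taxon`` at ``depth``.

        With ``exact=False`` (default) returns the deepest ancestor at or
        above ``depth`` — the binning rule used on the taxonomy axis for
        matches whose lineage does not reach the requested rank.
        """
        return self.lineage(taxon).at_depth(depth, exact=exact)

    def lca(self, taxa: Iterable[str]) -> str:
        """Lowest common ancestor of a non-empty collection of taxa.

        Commutative and idempotent; a single taxon is its own LCA.
        """
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca() requires at least one taxon")
        common = list(self.lineage(taxa[0]).entries)
        for taxon in taxa[1:]:
            other = self.lineage(taxon).entries
            n = 0
            for a, b in zip(common, other):
                if a != b:
                    break
                n += 1
            common = common[:n]
            if len(common) == 1:
                break
        return common[-1][1]

    # -- serialization ----------------------------------------------------

    def checksum(self) -> str:
        """Stable hex digest of the canonical node table (provenance sidecars)."""
        h = hashlib.sha256()
        h.update(("|".join(self.rank_order)).encode())
        for taxon in self.taxa():
            parent, rank, name = self._nodes[taxon]
            h.update(f"\n{taxon}\t{parent or ''}\t{rank}\t{name}".encode())
        return h.hexdigest()

    def to_simple_tsv(self, path: str | Path) -> None:
        """Write the canonical tree in the simple-TSV dialect."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("taxon_id\tparent_id\trank\tname\n")
            for taxon in self.taxa():
                parent, rank, name = self._nodes[taxon]
                fh.write(f"{taxon}\t{parent or ''}\t{rank}\t{name}\n")


# -- loading ---------------------------------------------------------------


def _canonicalize(
    raw: dict[str, tuple[str | None, str, str]],
    rank_order: Sequence[str],
) -> tuple[dict[str, tuple[str | None, str, str]], dict[str, str]]:
    """Collapse non-canonical ranks onto their nearest canonical ancestor."""
    depth_of = {r: i for i, r in enumerate(rank_order)}
    # a root either has an empty parent (simple TSV) or is its own parent
    # (NCBI dump); any OTHER self-parented node is a cycle
    none_roots = [t for t, (p, _, _) in raw.items() if p in (None, "")]
    self_roots = [t for t, (p, _, _) in raw.items() if p == t]
    if none_roots:
        if len(none_roots) > 1:
            raise TaxonomyStructureError(
                f"expected exactly one root, found {len(none_roots)}"
            )
        root = none_roots[0]
        if self_roots:
            raise TaxonomyStructureError(f"cycle detected at taxon {self_roots[0]!r}")
    else:
        if len(self_roots) != 1:
            raise TaxonomyStructureError(
                f"expected exactly one root, found {len(self_roots)}"
            )
        root = self_roots[0]

    def norm_rank(rank: str) -> str:
        rank = rank.strip().lower()
        return _RANK_SYNONYMS.get(rank, rank)

    is_canonical = {
        t: (t == root or norm_rank(r) in depth_of) for t, (_, r, _) in raw.items()
    }

    def canonical_ancestor(taxon: str) -> str:
        """Nearest strict ancestor of ``taxon`` that survives canonicalization."""
        seen = {taxon}
        cur = raw[taxon][0]
        while True:
            if cur in (None, ""):
                return root
            if cur not in raw:
                raise TaxonomyStructureError(
                    f"node {taxon!r} has unknown ancestor {cur!r}"
                )
            if cur in seen:
                raise TaxonomyStructureError(f"cycle detected at taxon {cur!r}")
            seen.add(cur)
            if cur == root or is_canonical[cur]:
                return cur
            cur = raw[cur][0]

    nodes: dict[str, tuple[str | None, str, str]] = {}
    aliases: dict[str, str] = {}
    for taxon, (parent, rank, name) in raw.items():
        if taxon == root:
            nodes[taxon] = (None, rank_order[0], name)
        elif is_canonical[taxon]:
            nodes[taxon] = (canonical_ancestor(taxon), norm_rank(rank), name)
        else:
            aliases[taxon] = canonical_ancestor(taxon)
    return nodes, aliases


def _parse_simple_tsv(path: str | Path) -> dict[str, tuple[str | None, str, str]]:
    raw: dict[str, tuple[str | None, str, str]] = {}
    with open(path, encoding="utf-8") as fh:
        next(fh, None)  # header line
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise TaxonomyStructureError(
                    f"{path}: line {lineno}: expected 4 tab-separated fields"
                )
            taxon, parent, rank, name = fields
            raw[taxon] = (parent or None, rank, name)
    return raw


def _parse_ncbi_dump(
    nodes_path: str | Path, names_path: str | Path
) -> dict[str, tuple[str | None, str, str]]:
    names: dict[str, str] = {}
    with open(names_path, encoding="utf-8") as fh:
        for line in fh:
            fields = [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
            if len(fields) >= 4 and fields[3] == "scientific name":
                names[fields[0]] = fields[1]
    raw: dict[str, tuple[str | None, str, str]] = {}
    with open(nodes_path, encoding="utf-8") as fh:
        for line in fh:
            fields = [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
            if len(fields) < 3:
                raise TaxonomyStructureError(f"{nodes_path}: malformed line: {line!r}")
            taxon, parent, rank = fields[0], fields[1], fields[2]
            raw[taxon] = (parent, rank, names.get(taxon, taxon))
    return raw


def load_taxonomy(
    source: str | Path | tuple[str | Path, str | Path],
    dialect: str = "simple-tsv",
    rank_order: Sequence[str] = CANONICAL_RANKS,
) -> Taxonomy:
    """Load and canonicalize a taxonomy.

    ``dialect`` is ``"simple-tsv"`` (one file: taxon_id, parent_id, rank,
    name with a header line) or ``"ncbi-dump"`` (a directory containing
    ``nodes.dmp`` and ``names.dmp``, or a (nodes, names) pair of paths).
    """
    if dialect == "simple-tsv":
        raw = _parse_simple_tsv(source)  # type: ignore[arg-type]
    elif dialect == "ncbi-dump":
        if isinstance(source, tuple):
            nodes_path, names_path = source
        else:
            base = Path(source)
            nodes_path, names_path = base / "nodes.dmp", base / "names.dmp"
        raw = _parse_ncbi_dump(nodes_path, names_path)
    else:
        raise ValueError(f"unknown taxonomy dialect {dialect!r}")
    nodes, aliases = _canonicalize(raw, rank_order)
    return Taxonomy(nodes, rank_order=rank_order, aliases=aliases)
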