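"""Rank-flexible taxonomic assignment.

Three classifiers share one output contract:

* ``spanner_assign`` — score the query's LCA Profile against every
  reference profile with the pyramid match kernel, keep references within
  a fraction ``y`` of the best score, and assign the lowest common
  ancestor of their source taxa.
* ``lca_assign`` — the MEGAN-style baseline: the LCA of every taxon in the
  query's profile.
* ``best_blast_assign`` — the top-bitscore hit's lineage.

All assignments are truncated to a configurable maximum depth (genus by
default, because species/strain naming in reference databases is too
inconsistent to assign against).  The root ("cellular organisms", depth 0)
is the explicit unclassified outcome.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .pmk import PMKConfig, score_against_references
from .profiles import LCAProfile, Match, ReferenceSet, build_profile
from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)

GENUS_DEPTH = 6

#: relative slack mirroring the bitscore threshold: keep score >= y * best
_REL_EPS = 1e-9


@dataclass(frozen=True)
class Assignment:
    query_id: str
    assigned_taxon: str
    assigned_depth: int
    method: str
    #: (reference id or taxon, score) pairs that determined the call
    support: tuple[tuple[str, float], ...] = ()
    p_used: float | None = None
    y_used: float | None = None
    best_score: float | None = None
    note: str = ""


def _truncated(tax: Taxonomy, taxon: str, max_depth: int) -> tuple[str, int]:
    node = tax.ancestor(taxon, max_depth, exact=False)
    assert node is not None  # the root is always available
    return node, tax.depth(node)


def _root_assignment(
    query_id: str,
    method: str,
    tax: Taxonomy,
    note: str,
    **kwargs,
) -> Assignment:
    return Assignment(
        query_id=query_id,
        assigned_taxon=tax.root,
        assigned_depth=0,
        method=method,
        note=note,
        **kwargs,
    )


def spanner_assign(
    q: LCAProfile,
    refs: ReferenceSet,
    y: float,
    tax: Taxonomy,
    cfg: PMKConfig | None = None,
    max_depth: int = GENUS_DEPTH,
) -> Assignment:
    """Assign the LCA of the best-matching reference profiles' source taxa.

    References scoring >= ``y`` x the best pyramid score are retained
    (inclusive boundary, mirroring ``p``).  An empty query profile, an
    empty reference set after filtering, or a best score of zero all yield
    the root (unclassified) assignment.
    """
    if not 0.0 <= y <= 1.0:
        raise ValueError(f"y must lie in [0, 1], got {y}")
    if not refs.profiles:
        raise ValueError("reference set is empty")
    if cfg is None:
        cfg = PMKConfig(h=len(tax.rank_order))
    if q.is_empty:
        return _root_assignment(q.source_id, "spanner", tax, "empty query profile",
                                p_used=q.p_used, y_used=y)
    scored = score_against_references(q, refs, tax, cfg)
    best = scored[0][2]
    if best <= 0.0:
        return _root_assignment(
            q.source_id, "spanner", tax, "no informative match (best score 0)",
            p_used=q.p_used, y_used=y, best_score=best,
        )
    threshold = y * best
    retained = [s for s in scored if s[2] >= threshold - _REL_EPS * threshold]
    node = tax.lca({taxon for _, taxon, _ in retained})
    assigned, depth = _truncated(tax, node, max_depth)
    return Assignment(
        query_id=q.source_id,
        assigned_taxon=assigned,
        assigned_depth=depth,
        method="spanner",
        support=tuple((sid, score) for sid, _, score in retained),
        p_used=q.p_used,
        y_used=y,
        best_score=best,
    )


def lca_assign(
    q: LCAProfile,
    tax: Taxonomy,
    max_depth: int = GENUS_DEPTH,
) -> Assignment:
    """Assign the lowest common ancestor of every taxon in the profile."""
    if q.is_empty:
        return _root_assignment(q.source_id, "lca", tax, "empty query profile",
                                p_used=q.p_used)
    node = tax.lca(q.taxa())
    assigned, depth = _truncated(tax, node, max_depth)
    return Assignment(
        query_id=q.source_id,
        assigned_taxon=assigned,
        assigned_depth=depth,
        method="lca",
        support=tuple((m.subject_taxon, m.bitscore) for m in q.matches),
        p_used=q.p_used,
    )


def best_blast_assign(
    hits: Sequence[Match],
    tax: Taxonomy,
    query_id: str = "",
    max_depth: int = GENUS_DEPTH,
) -> Assignment:
    """Assign the lineage of the single best hit (rank-specific baseline).

    Ties on bitscore break by ascending e-value, then lexicographic taxon
    id.  Empty input yields the root assignment.
    """
    if not hits:
        return _root_assignment(query_id, "best-blast", tax, "no hits")
    top = min(hits, key=lambda m: m.sort_key)
    assigned, depth = _truncated(tax, top.subject_taxon, max_depth)
    return Assignment(
        query_id=query_id,
        assigned_taxon=assigned,
        assigned_depth=depth,
        method="best-blast",
        support=((top.subject_taxon, top.bitscore),),
    )


METHODS = ("spanner", "lca", "best-blast")


def classify_batch(
    queries: Mapping[str, Sequence[Match]],
    refs: ReferenceSet | None,
    method: str,
    *,
    p: float,
    tax: Taxonomy,
    y: float | None = None,
    cfg: PMKConfig | None = None,
    max_depth: int = GENUS_DEPTH,
) -> list[Assignment]:
    """Classify every query with one method; deterministic (sorted) order.

    Profiles are built at ``p`` for the profile-based methods; best-BLAST
    works on the raw hits.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if method == "spanner":
        if refs is None:
            raise ValueError("spanner requires a reference set")
        if y is None:
            raise ValueError("spanner requires the y threshold")
    out: list[Assignment] = []
    for qid in sorted(queries):
        hits = queries[qid]
        if method == "best-blast":
            out.append(best_blast_assign(hits, tax, query_id=qid, max_depth=max_depth))
            continue
        profile = build_profile(hits, p, qid)
        if method == "lca":
            out.append(lca_assign(profile, tax, max_depth=max_depth))
        else:
            out.append(spanner_assign(profile, refs, y, tax, cfg, max_depth=max_depth))
        logger.debug("classified %s with %s", qid, method)
    return out


def assignments_to_rows(
    assignments: Sequence[Assignment], tax: Taxonomy
) -> list[dict[str, object]]:
    """Flatten assignments into the tabular output schema."""
    rows = []
    for a in assignments:
        lineage = ";".join(t for _, t in tax.lineage(a.assigned_taxon))
        rows.append(
            {
                "query_id": a.query_id,
                "method": a.method,
                "assigned_taxon": a.assigned_taxon,
                "assigned_rank_name": tax.rank_name(a.assigned_depth),
                "assigned_depth": a.assigned_depth,
                "lineage": lineage,
                "n_support": len(a.support),
                "best_score": "" if a.best_score is None else a.best_score,
                "y": "" if a.y_used is None else a.y_used,
                "p": "" if a.p_used is None else a.p_used,
            }
        )
    return rows
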