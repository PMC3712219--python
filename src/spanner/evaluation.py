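"""Ordinal evaluation of rank-flexible assignments and leave-one-out trials.

Each of the eight ranks is an ordinal value, 0 ("cellular organisms") to 7
(species).  An assignment's *precision* is the number of ranks it commits
to (its depth); its *correct ranks* are the deepest depth at which the
assigned lineage still agrees with the truth; the difference is the number
of *incorrect ranks*.  An assignment can therefore be partially correct —
e.g. classified to genus but accurate only to class scores precision 6,
correct 3, incorrect 3 — and averaging the three quantities over a dataset
makes the precision/error trade-off between classifiers explicit.

The leave-one-out experiment simulates taxonomic novelty: each reference
sequence in turn becomes the query, every reference profile from its clade
at the novelty rank is dropped from the database, matches to that clade
are masked out of the remaining profiles (and the query's own), and the
classifiers run capped one rank above the novelty rank, since the correct
taxon at the novelty rank no longer exists in the database.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .assign import (
    Assignment,
    METHODS,
    best_blast_assign,
    lca_assign,
    spanner_assign,
)
from .pmk import PMKConfig
from .profiles import ReferenceSet, mask_novelty
from .taxonomy import Lineage, Taxonomy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalRecord:
    """Per-query ordinal scores; incorrect = precision - correct, exactly."""

    query_id: str
    precision_ranks: int
    correct_ranks: int

    def __post_init__(self) -> None:
        if not 0 <= self.correct_ranks <= self.precision_ranks:
            raise ValueError(
                f"{self.query_id}: correct_ranks {self.correct_ranks} outside "
                f"[0, {self.precision_ranks}]"
            )

    @property
    def incorrect_ranks(self) -> int:
        return self.precision_ranks - self.correct_ranks


@dataclass(frozen=True)
class EvalSummary:
    n: int
    mean_precision: float
    mean_correct: float
    mean_incorrect: float
    #: target_depth - mean_precision, e.g. "ranks above genus" for target 6
    mean_ranks_above_target: float | None = None


def score_assignment(a: Assignment, truth: Lineage, tax: Taxonomy) -> EvalRecord:
    """Score one assignment against the query's known lineage.

    The correct-rank count is the depth of the LCA of the assigned taxon
    and the truth's deepest node — equivalently, the longest common prefix
    of the two lineages.
    """
    correct = tax.depth(tax.lca([a.assigned_taxon, truth.deepest_taxon]))
    return EvalRecord(
        query_id=a.query_id,
        precision_ranks=a.assigned_depth,
        correct_ranks=correct,
    )


def summarize(
    records: Sequence[EvalRecord], target_depth: int | None = None
) -> EvalSummary:
    """Arithmetic means over a non-empty set of records."""
    if not records:
        raise ValueError("cannot summarize zero records")
    n = len(records)
    mean_precision = sum(r.precision_ranks for r in records) / n
    mean_correct = sum(r.correct_ranks for r in records) / n
    mean_incorrect = sum(r.incorrect_ranks for r in records) / n
    above = None if target_depth is None else target_depth - mean_precision
    return EvalSummary(
        n=n,
        mean_precision=mean_precision,
        mean_correct=mean_correct,
        mean_incorrect=mean_incorrect,
        mean_ranks_above_target=above,
    )


@dataclass(frozen=True)
class LeaveOneOutResult:
    method: str
    records: tuple[EvalRecord, ...]
    summary: EvalSummary
    assignments: tuple[Assignment, ...]


def _resolve_novelty_rank(novelty_rank: int | str, tax: Taxonomy) -> int:
    if isinstance(novelty_rank, str):
        try:
            novelty_rank = tax.rank_order.index(novelty_rank)
        except ValueError:
            raise ValueError(f"unknown rank name {novelty_rank!r}") from None
    if not 1 <= novelty_rank <= tax.max_depth:
        raise ValueError(
            f"novelty rank must lie in [1, {tax.max_depth}], got {novelty_rank}"
        )
    return novelty_rank


def leave_one_out_experiment(
    refs: ReferenceSet,
    novelty_rank: int | str,
    methods: Sequence[str],
    tax: Taxonomy,
    cfg: PMKConfig | None = None,
    p: float = 0.85,
    y: float = 0.95,
    max_depth: int | None = None,
) -> dict[str, LeaveOneOutResult]:
    """Run the novelty benchmark with every reference profile as a query.

    ``refs`` should be built *untrimmed* (p = 0, every hit kept): masking
    precedes thresholding, so once the held-out query's own clade is
    removed, matches that sat below the original threshold re-enter its
    profile relative to the new best bitscore.  The working threshold
    ``p`` is applied by the masking step itself.

    ``novelty_rank`` may be a depth (7 = species) or a rank name.  The
    assignment cap defaults to one rank above the novelty rank.  Reference
    profiles sharing the query's novelty-rank ancestor are removed from the
    database entirely (a genome absent from the database contributes no
    profiles); the remaining profiles, and the query's own, are masked of
    matches to that clade and re-thresholded at ``p``.
    """
    novelty_depth = _resolve_novelty_rank(novelty_rank, tax)
    cap = novelty_depth - 1 if max_depth is None else max_depth
    for method in methods:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if cfg is None:
        cfg = PMKConfig(h=len(tax.rank_order))
    clades = {
        tax.ancestor(r.source_taxon, novelty_depth, exact=False)
        for r in refs.profiles
    }
    if len(clades) < 2:
        raise ValueError(
            f"all reference profiles share one {tax.rank_name(novelty_depth)!r} "
            "clade; holding it out would leave nothing to classify against"
        )

    per_method: dict[str, list[tuple[Assignment, EvalRecord]]] = {m: [] for m in methods}
    for query in refs.profiles:
        truth = tax.lineage(query.source_taxon)
        clade = truth.at_depth(novelty_depth, exact=True)
        if clade is None:
            raise ValueError(
                f"reference {query.source_id!r} lineage does not reach the "
                f"novelty rank {tax.rank_name(novelty_depth)!r}"
            )
        kept = [
            r
            for r in refs.profiles
            if tax.ancestor(r.source_taxon, novelty_depth, exact=True) != clade
        ]
        masked_refs = [
            m
            for m in (mask_novelty(r, truth, novelty_depth, p, tax) for r in kept)
            if not m.is_empty
        ]
        masked_set = ReferenceSet(profiles=tuple(masked_refs), p=p, taxonomy=tax)
        masked_query = mask_novelty(query, truth, novelty_depth, p, tax)

        for method in methods:
            if method == "best-blast":
                a = best_blast_assign(
                    masked_query.matches, tax, query_id=query.source_id, max_depth=cap
                )
            elif method == "lca":
                a = lca_assign(masked_query, tax, max_depth=cap)
            elif not masked_set.profiles:
                a = Assignment(
                    query_id=query.source_id,
                    assigned_taxon=tax.root,
                    assigned_depth=0,
                    method="spanner",
                    note="no reference profiles survive masking",
                    y_used=y,
                    p_used=p,
                )
            else:
                a = spanner_assign(masked_query, masked_set, y, tax, cfg, max_depth=cap)
            per_method[method].append((a, score_assignment(a, truth, tax)))
        logger.debug("leave-one-out query %s done", query.source_id)

    out = {}
    for method, pairs in per_method.items():
        records = tuple(rec for _, rec in pairs)
        out[method] = LeaveOneOutResult(
            method=method,
            records=records,
            summary=summarize(records, target_depth=cap),
            assignments=tuple(a for a, _ in pairs),
        )
    return out


def plot_precision_incorrect(
    summaries: Mapping[str, EvalSummary], out_path: str
) -> None:
    """Scatter of mean precision vs mean incorrect ranks, one point per label.

    Optional hook; imports matplotlib lazily so the core has no plotting
    dependency.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, s in summaries.items():
        ax.scatter(s.mean_precision, s.mean_incorrect, label=label)
    ax.set_xlabel("taxonomic precision (mean ranks assigned)")
    ax.set_ylabel("mean incorrect ranks")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
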