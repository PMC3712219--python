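"""Pyramid match kernel over a taxonomy x normalized-e-value grid.

Two LCA Profiles are compared by embedding each match as a point on a 2D
grid: one axis groups the matched taxa by taxonomy, the other carries the
match e-values normalized per profile.  The kernel runs ``h`` iterations
over successively coarser grids.  At iteration ``i`` the taxonomy axis bins
points by their ancestor at rank depth ``h - i`` (species bins first, one
root bin last) and the e-value axis has ``2^(h-i)`` equal bins, so the
final iteration is a single cell spanning the whole grid.  The iteration's
intersection count is the histogram intersection (sum of per-cell minima)
of the two profiles' point sets, and the similarity is the sum of the
*total* per-iteration counts weighted by ``2^(1-i)``.

Weighting totals rather than newly-formed matches departs from the classic
pyramid match kernel and is deliberate: it rewards profiles that agree at
fine granularity at every level of the hierarchy.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass


from .profiles import LCAProfile, ReferenceSet
from .taxonomy import Taxonomy


@dataclass(frozen=True)
class PMKConfig:
    """Kernel settings.

    ``h`` is the number of hierarchy levels and must equal the taxonomy's
    rank count (8 for the canonical ranks).  ``evalue_floor`` is the
    smallest representable e-value for the log transform; BLAST reports 0.0
    below its representable range and the transform needs a finite value.
    """

    h: int = 8
    evalue_floor: float = 1e-180

    def __post_init__(self) -> None:
        if self.h < 2:
            raise ValueError(f"h must be >= 2, got {self.h}")
        if self.evalue_floor <= 0:
            raise ValueError("evalue_floor must be positive")


@dataclass(frozen=True)
class GridPoint:
    """One match embedded on the grid: its taxon and e-value axis position."""

    taxon: str
    evalue_pos: float  # in [0, 1]; 1.0 is the profile's best (smallest) e-value


@dataclass(frozen=True)
class PMKResult:
    """Similarity score plus the per-iteration (i, weight, intersections) trace."""

    score: float
    per_iteration: tuple[tuple[int, float, int], ...]

    @property
    def intersections(self) -> tuple[int, ...]:
        return tuple(n for _, _, n in self.per_iteration)

    @property
    def weights(self) -> tuple[float, ...]:
        return tuple(w for _, w, _ in self.per_iteration)

    def cumulative(self) -> tuple[float, ...]:
        """Running weighted sum after each iteration."""
        out, total = [], 0.0
        for _, w, n in self.per_iteration:
            total += w * n
            out.append(total)
        return tuple(out)


def normalize_evalues(profile: LCAProfile, cfg: PMKConfig = PMKConfig()) -> list[GridPoint]:
    """Place a profile's matches on the e-value axis.

    Each e-value is transformed to ``-log10(max(e, floor))`` and min-max
    rescaled *within the profile*, so the best match sits at 1.0 and the
    worst at 0.0.  A profile whose transformed e-values are all equal (in
    particular a single match) maps every point to 1.0.  Normalizing per
    profile makes the axis comparable between genes evolving at different
    rates.
    """
    if profile.is_empty:
        raise ValueError(f"profile {profile.source_id!r} is empty")
    xs = [-math.log10(max(m.evalue, cfg.evalue_floor)) for m in profile.matches]
    lo, hi = min(xs), max(xs)
    if hi == lo:
        return [GridPoint(m.subject_taxon, 1.0) for m in profile.matches]
    return [
        GridPoint(m.subject_taxon, (x - lo) / (hi - lo))
        for m, x in zip(profile.matches, xs)
    ]


def _ebin(pos: float, nbins: int) -> int:
    # half-open bins closed at the top: 1.0 lands in the last bin
    return min(int(pos * nbins), nbins - 1)


def pmk_score(
    a: LCAProfile,
    b: LCAProfile,
    tax: Taxonomy,
    cfg: PMKConfig = PMKConfig(),
) -> PMKResult:
    """Score the similarity of two non-empty LCA Profiles.

    Symmetric in its profile arguments; intersections are counted on total
    per-cell minima so they are non-decreasing across iterations as the
    bins coarsen.
    """
    if cfg.h != len(tax.rank_order):
        raise ValueError(
            f"h={cfg.h} does not match the taxonomy's {len(tax.rank_order)} ranks"
        )
    points_a = normalize_evalues(a, cfg)
    points_b = normalize_evalues(b, cfg)
    per_iteration = []
    score = 0.0
    for i in range(1, cfg.h + 1):
        depth = cfg.h - i
        nbins = 2 ** (cfg.h - i)
        count_a = Counter(
            (tax.ancestor(gp.taxon, depth), _ebin(gp.evalue_pos, nbins))
            for gp in points_a
        )
        count_b = Counter(
            (tax.ancestor(gp.taxon, depth), _ebin(gp.evalue_pos, nbins))
            for gp in points_b
        )
        inter = sum(min(n, count_b[key]) for key, n in count_a.items())
        weight = 2.0 ** (1 - i)
        score += weight * inter
        per_iteration.append((i, weight, inter))
    return PMKResult(score=score, per_iteration=tuple(per_iteration))


def score_against_references(
    q: LCAProfile,
    refs: ReferenceSet,
    tax: Taxonomy,
    cfg: PMKConfig = PMKConfig(),
) -> list[tuple[str, str, float]]:
    """Score a query against every reference profile.

    Returns (reference source_id, source_taxon, score) triples sorted by
    score descending, then source_id ascending — a deterministic ranking.
    """
    if not refs.profiles:
        raise ValueError("reference set is empty")
    if q.is_empty:
        raise ValueError(f"query profile {q.source_id!r} is empty")
    scored = [
        (r.source_id, r.source_taxon or "", pmk_score(q, r, tax, cfg).score)
        for r in refs.profiles
    ]
    scored.sort(key=lambda t: (-t[2], t[0]))
    return scored
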