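"""LCA Profiles: best-hit-per-taxon, bitscore-thresholded homology matches.

A sequence's *LCA Profile* is the set of its homology matches retained
within a fraction ``p`` of the best bitscore, deduplicated to the single
best hit per matched taxon.  Profiles are built for queries (from a
query-vs-reference search) and for every reference sequence (from an
all-vs-all search of the reference database, self-hits included).

The leave-one-out novelty machinery lives here too: masking removes every
match inside the clade a query is pretended to be novel to, then re-applies
the ``p`` threshold relative to the new best bitscore.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .taxonomy import Lineage, Taxonomy

logger = logging.getLogger(__name__)

#: relative slack so the inclusive boundary (keep bitscore >= p * best)
#: survives binary floating-point dust, e.g. 0.85 * 100 > 85 in IEEE doubles
_REL_EPS = 1e-9


@dataclass(frozen=True)
class Match:
    """One homology hit: the taxon matched, its bitscore and e-value."""

    subject_taxon: str
    bitscore: float
    evalue: float

    @property
    def sort_key(self) -> tuple[float, float, str]:
        # bitscore descending; ties by ascending e-value then taxon id
        return (-self.bitscore, self.evalue, self.subject_taxon)


@dataclass(frozen=True)
class LCAProfile:
    """A sequence's retained matches, sorted by bitscore descending.

    An empty ``matches`` tuple is the explicit empty-profile sentinel and is
    classified downstream as unassigned.
    """

    source_id: str
    matches: tuple[Match, ...]
    p_used: float
    source_taxon: str | None = None

    def __len__(self) -> int:
        return len(self.matches)

    @property
    def is_empty(self) -> bool:
        return not self.matches

    @property
    def best_bitscore(self) -> float:
        return self.matches[0].bitscore

    def taxa(self) -> tuple[str, ...]:
        return tuple(m.subject_taxon for m in self.matches)


class BlastParseError(ValueError):
    """A tabular hit file could not be parsed."""


def parse_blast_tab(
    path: str | Path,
    taxon_map: Mapping[str, str],
    *,
    qseq_col: int = 0,
    sseq_col: int = 1,
    evalue_col: int = 10,
    bitscore_col: int = 11,
) -> dict[str, list[Match]]:
    """Read a BLAST tabular (outfmt-6-style) file, grouped by query.

    Column positions follow the outfmt 6 default order and are configurable
    for compatible dialects.  Subjects absent from ``taxon_map`` are dropped
    with a logged count; an empty file yields an empty mapping.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return {}
    needed = max(qseq_col, sseq_col, evalue_col, bitscore_col)
    if df.shape[1] <= needed:
        raise BlastParseError(
            f"{path}: expected at least {needed + 1} tab-separated columns, "
            f"found {df.shape[1]}"
        )
    numeric: dict[int, pd.Series] = {}
    for col in (evalue_col, bitscore_col):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna()
        if bad.any():
            lineno = int(bad.idxmax()) + 1
            raise BlastParseError(
                f"{path}: line {lineno}: non-numeric value in column {col + 1}"
            )
        numeric[col] = values

    hits: dict[str, list[Match]] = {}
    dropped = 0
    for qid, sid, evalue, bitscore in zip(
        df[qseq_col], df[sseq_col], numeric[evalue_col], numeric[bitscore_col]
    ):
        taxon = taxon_map.get(sid)
        if taxon is None:
            dropped += 1
            continue
        hits.setdefault(qid, []).append(
            Match(subject_taxon=taxon, bitscore=float(bitscore), evalue=float(evalue))
        )
    if dropped:
        logger.info("%s: dropped %d hits with unmapped subject ids", path, dropped)
    return hits


def build_profile(
    hits: Sequence[Match],
    p: float,
    source_id: str,
    source_taxon: str | None = None,
) -> LCAProfile:
    """Build an LCA Profile: dedupe to the best hit per taxon, then keep
    matches with bitscore >= p x the best bitscore (inclusive boundary).

    Deduplication happens before thresholding so a taxon's weaker secondary
    hits never influence the threshold.  Empty input yields the explicit
    empty-profile sentinel.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if not hits:
        return LCAProfile(source_id=source_id, matches=(), p_used=p, source_taxon=source_taxon)
    best_per_taxon: dict[str, Match] = {}
    for match in sorted(hits, key=lambda m: m.sort_key):
        best_per_taxon.setdefault(match.subject_taxon, match)
    best = max(m.bitscore for m in best_per_taxon.values())
    threshold = p * best
    kept = [
        m
        for m in best_per_taxon.values()
        if m.bitscore >= threshold - _REL_EPS * max(1.0, abs(threshold))
    ]
    kept.sort(key=lambda m: m.sort_key)
    return LCAProfile(
        source_id=source_id, matches=tuple(kept), p_used=p, source_taxon=source_taxon
    )


@dataclass
class ReferenceSet:
    """One LCA Profile per reference sequence, each with a known source taxon."""

    profiles: tuple[LCAProfile, ...]
    p: float
    taxonomy: Taxonomy | None = None

    def __post_init__(self) -> None:
        if self.taxonomy is not None:
            for prof in self.profiles:
                if prof.source_taxon is None or prof.source_taxon not in self.taxonomy:
                    raise ValueError(
                        f"reference {prof.source_id!r}: source taxon "
                        f"{prof.source_taxon!r} does not resolve in the taxonomy"
                    )

    def __len__(self) -> int:
        return len(self.profiles)

    # -- serialization: TSV of match rows + JSON sidecar ------------------

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        path = Path(path)
        rows = [
            (prof.source_id, prof.source_taxon, m.subject_taxon, m.bitscore, m.evalue)
            for prof in self.profiles
            for m in prof.matches
        ]
        pd.DataFrame(
            rows,
            columns=["source_id", "source_taxon", "subject_taxon", "bitscore", "evalue"],
        ).to_csv(path, sep="\t", index=False)
        meta = {
            "p": self.p,
            "n_profiles": len(self.profiles),
            "taxonomy_checksum": self.taxonomy.checksum() if self.taxonomy else None,
        }
        sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        taxonomy: Taxonomy | None = None,
        sidecar: str | Path | None = None,
    ) -> "ReferenceSet":
        path = Path(path)
        sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text())
        p = float(meta["p"])
        if taxonomy is not None and meta.get("taxonomy_checksum") not in (
            None,
            taxonomy.checksum(),
        ):
            raise ValueError(
                f"{sidecar}: taxonomy checksum does not match the supplied taxonomy"
            )
        df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                         dtype={"source_id": str, "source_taxon": str,
                                "subject_taxon": str})
        profiles = []
        for (source_id, source_taxon), grp in df.groupby(
            ["source_id", "source_taxon"], sort=True
        ):
            hits = [
                Match(subject_taxon=r.subject_taxon, bitscore=float(r.bitscore),
                      evalue=float(r.evalue))
                for r in grp.itertuples()
            ]
            profiles.append(build_profile(hits, p, str(source_id), str(source_taxon)))
        return cls(profiles=tuple(profiles), p=p, taxonomy=taxonomy)


def build_reference_set(
    all_vs_all_hits: Mapping[str, Sequence[Match]],
    taxon_map: Mapping[str, str],
    p: float,
    taxonomy: Taxonomy | None = None,
) -> ReferenceSet:
    """Build one reference LCA Profile per sequence in an all-vs-all table.

    Self-hits are retained — they define each profile's best bitscore.  A
    reference with no usable hits is skipped with a warning.
    """
    profiles = []
    for seq_id in sorted(all_vs_all_hits):
        taxon = taxon_map.get(seq_id)
        if taxon is None:
            raise KeyError(f"reference sequence {seq_id!r} has no taxon mapping")
        prof = build_profile(all_vs_all_hits[seq_id], p, seq_id, source_taxon=taxon)
        if prof.is_empty:
            logger.warning("reference %s has no hits; skipped", seq_id)
            continue
        profiles.append(prof)
    return ReferenceSet(profiles=tuple(profiles), p=p, taxonomy=taxonomy)


def mask_novelty(
    profile: LCAProfile,
    truth: Lineage,
    novelty_rank: int,
    p: float,
    taxonomy: Taxonomy,
) -> LCAProfile:
    """Simulate taxonomic novelty: drop matches inside the truth's clade.

    Every match whose taxon shares the truth lineage's ancestor at
    ``novelty_rank`` is removed, then the ``p`` threshold is re-applied
    relative to the new best bitscore (masking precedes thresholding).  If
    nothing survives, the empty-profile sentinel is returned.
    """
    clade = truth.at_depth(novelty_rank, exact=True)
    if clade is None:
        raise ValueError(
            f"truth lineage of {profile.source_id!r} does not reach depth {novelty_rank}"
        )
    survivors = [
        m
        for m in profile.matches
        if taxonomy.ancestor(m.subject_taxon, novelty_rank, exact=True) != clade
    ]
    return build_profile(survivors, p, profile.source_id, profile.source_taxon)
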