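"""Independent brute-force oracles and random-input helpers for the suite."""
from __future__ import annotations

import numpy as np

from spanner import LCAProfile, Match, Taxonomy, build_profile
from spanner.pmk import PMKConfig, normalize_evalues


def naive_pmk_trace(
    a: LCAProfile, b: LCAProfile, tax: Taxonomy, cfg: PMKConfig
) -> tuple[float, tuple[int, ...]]:
    """Reference kernel: materialize the full dense 2D histogram per level.

    Taxonomy binning walks each lineage's entries directly (last entry at or
    above the level's depth) instead of going through the ancestor helper,
    and the intersection is an element-wise minimum over the whole grid.
    """
    points = {}
    for label, prof in (("a", a), ("b", b)):
        points[label] = [(gp.taxon, gp.evalue_pos) for gp in normalize_evalues(prof, cfg)]
    nodes = tax.taxa()
    node_ix = {t: i for i, t in enumerate(nodes)}
    inters = []
    for i in range(1, cfg.h + 1):
        depth = cfg.h - i
        nbins = 2 ** (cfg.h - i)
        grids = {}
        for label in ("a", "b"):
            grid = np.zeros((len(nodes), nbins), dtype=np.int64)
            for taxon, pos in points[label]:
                ancestors = [t for d, t in tax.lineage(taxon).entries if d <= depth]
                ebin = min(int(pos * nbins), nbins - 1)
                grid[node_ix[ancestors[-1]], ebin] += 1
            grids[label] = grid
        inters.append(int(np.minimum(grids["a"], grids["b"]).sum()))
    score = sum(2.0 ** (1 - i) * n for i, n in enumerate(inters, start=1))
    return score, tuple(inters)


def random_profile(
    tax: Taxonomy,
    rng: np.random.Generator,
    size: int,
    source_id: str = "q",
    include_internal: bool = True,
) -> LCAProfile:
    """A profile of ``size`` distinct taxa with random scores and e-values.

    Taxa are drawn from the species pool and (optionally) internal nodes, so
    shallow-lineage binning gets exercised too.
    """
    pool = list(tax.species())
    if include_internal:
        pool += [t for t in tax.taxa() if t not in pool and t != tax.root]
    pool.sort()
    idx = rng.permutation(len(pool))[:size]
    hits = [
        Match(
            subject_taxon=pool[i],
            bitscore=float(rng.uniform(50.0, 500.0)),
            evalue=float(10.0 ** -rng.uniform(3.0, 150.0)),
        )
        for i in idx
    ]
    return build_profile(hits, p=0.0, source_id=source_id)
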