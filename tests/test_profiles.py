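import logging

import pytest
from hypothesis import given, settings, strategies as st

import spanner as sp
from spanner import BlastParseError, Match, build_profile, mask_novelty


def _match(taxon, bitscore, evalue=1e-50):
    return Match(subject_taxon=taxon, bitscore=bitscore, evalue=evalue)


class TestParseBlastTab:
    ROW = "{q}\t{s}\t90.0\t100\t5\t0\t1\t100\t1\t100\t{e}\t{b}\n"

    def _write(self, path, rows):
        path.write_text("".join(rows))
        return path

    def test_three_hits_one_query(self, tmp_path):
        path = self._write(
            tmp_path / "hits.tsv",
            [self.ROW.format(q="q1", s=f"s{i}", e=1e-50, b=100 + i) for i in range(3)],
        )
        hits = sp.parse_blast_tab(path, {f"s{i}": f"t{i}" for i in range(3)})
        assert set(hits) == {"q1"}
        assert len(hits["q1"]) == 3
        assert {m.subject_taxon for m in hits["q1"]} == {"t0", "t1", "t2"}

    def test_unmapped_subject_dropped_with_logged_count(self, tmp_path, caplog):
        path = self._write(
            tmp_path / "hits.tsv",
            [self.ROW.format(q="q1", s=f"s{i}", e=1e-50, b=100) for i in range(3)],
        )
        with caplog.at_level(logging.INFO, logger="spanner.profiles"):
            hits = sp.parse_blast_tab(path, {"s0": "t0", "s1": "t1"})
        assert len(hits["q1"]) == 2
        assert "dropped 1" in caplog.text

    def test_non_numeric_bitscore_names_line(self, tmp_path):
        path = self._write(
            tmp_path / "hits.tsv",
            [
                self.ROW.format(q="q1", s="s0", e=1e-50, b=100),
                self.ROW.format(q="q1", s="s1", e=1e-50, b="oops"),
            ],
        )
        with pytest.raises(BlastParseError, match="line 2"):
            sp.parse_blast_tab(path, {"s0": "t0", "s1": "t1"})

    def test_empty_file_yields_empty_map(self, tmp_path):
        path = self._write(tmp_path / "hits.tsv", [])
        assert sp.parse_blast_tab(path, {}) == {}

    def test_too_few_columns_is_an_error(self, tmp_path):
        path = self._write(tmp_path / "hits.tsv", ["q1\ts0\t1e-5\n"])
        with pytest.raises(BlastParseError):
            sp.parse_blast_tab(path, {"s0": "t0"})


class TestBuildProfile:
    def test_threshold_arithmetic(self):
        hits = [_match("a", 100.0), _match("b", 90.0), _match("c", 80.0)]
        prof = build_profile(hits, p=0.85, source_id="q")
        assert [m.bitscore for m in prof.matches] == [100.0, 90.0]

    def test_best_hit_per_taxon_kept(self):
        hits = [_match("a", 95.0, 1e-40), _match("a", 100.0, 1e-60)]
        prof = build_profile(hits, p=0.0, source_id="q")
        assert len(prof) == 1
        assert prof.matches[0].bitscore == 100.0

    def test_boundary_is_inclusive(self):
        hits = [_match("a", 100.0), _match("b", 100.0), _match("c", 99.0)]
        prof = build_profile(hits, p=1.0, source_id="q")
        assert prof.taxa() == ("a", "b")

    def test_empty_hits_yield_sentinel(self):
        prof = build_profile([], p=0.85, source_id="q")
        assert prof.is_empty

    def test_sorted_with_documented_tie_break(self):
        hits = [
            _match("b", 100.0, 1e-50),
            _match("a", 100.0, 1e-60),
            _match("c", 100.0, 1e-60),
        ]
        prof = build_profile(hits, p=0.0, source_id="q")
        assert prof.taxa() == ("a", "c", "b")

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        bitscores=st.lists(st.floats(min_value=1.0, max_value=1000.0), min_size=1,
                           max_size=12),
        p_lo=st.floats(min_value=0.0, max_value=1.0),
        p_hi=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_monotone_in_p(self, bitscores, p_lo, p_hi):
        """Raising p never adds matches: higher-p profiles are subsets."""
        p_lo, p_hi = min(p_lo, p_hi), max(p_lo, p_hi)
        hits = [_match(f"t{i}", b) for i, b in enumerate(bitscores)]
        lo = build_profile(hits, p_lo, "q")
        hi = build_profile(hits, p_hi, "q")
        assert set(hi.matches) <= set(lo.matches)

    def test_dedupe_commutes_with_threshold_on_singleton_taxa(self, rng):
        """When each taxon has one hit, order of dedupe and threshold is moot."""
        for _ in range(20):
            hits = [
                _match(f"t{i}", float(b))
                for i, b in enumerate(rng.uniform(10, 500, size=8))
            ]
            p = float(rng.uniform(0, 1))
            via_build = build_profile(hits, p, "q").matches
            best = max(h.bitscore for h in hits)
            pre_thresholded = [h for h in hits if h.bitscore >= p * best - 1e-9]
            assert build_profile(pre_thresholded, 0.0, "q").matches == via_build


class TestReferenceSet:
    def test_mutual_hits_lead_with_self(self, tax8):
        s1, s2 = tax8.species()[:2]
        hits = {
            "r1": [_match(s1, 200.0), _match(s2, 180.0)],
            "r2": [_match(s2, 210.0), _match(s1, 180.0)],
        }
        refs = sp.build_reference_set(hits, {"r1": s1, "r2": s2}, p=0.85, taxonomy=tax8)
        assert len(refs) == 2
        by_id = {r.source_id: r for r in refs.profiles}
        assert by_id["r1"].matches[0].subject_taxon == s1
        assert by_id["r2"].matches[0].subject_taxon == s2

    def test_singleton_profile_survives(self, tax8):
        s1 = tax8.species()[0]
        refs = sp.build_reference_set(
            {"r1": [_match(s1, 200.0)]}, {"r1": s1}, p=0.85, taxonomy=tax8
        )
        assert len(refs) == 1
        assert len(refs.profiles[0]) == 1

    def test_raising_p_shrinks_every_profile(self, tax8, rng):
        species = tax8.species()
        hits = {
            f"r{i}": [
                _match(s, float(rng.uniform(100, 300))) for s in species[:6]
            ]
            for i in range(4)
        }
        tmap = {f"r{i}": species[i] for i in range(4)}
        lo = sp.build_reference_set(hits, tmap, p=0.85, taxonomy=tax8)
        hi = sp.build_reference_set(hits, tmap, p=0.95, taxonomy=tax8)
        for plo, phi in zip(lo.profiles, hi.profiles):
            assert set(phi.matches) <= set(plo.matches)

    def test_tsv_roundtrip(self, tmp_path, tax8):
        s1, s2 = tax8.species()[:2]
        hits = {
            "r1": [_match(s1, 200.0, 1e-60), _match(s2, 180.0, 1e-50)],
            "r2": [_match(s2, 210.0, 1e-62)],
        }
        refs = sp.build_reference_set(hits, {"r1": s1, "r2": s2}, p=0.85, taxonomy=tax8)
        out = tmp_path / "refs.tsv"
        refs.to_tsv(out)
        back = sp.ReferenceSet.from_tsv(out, taxonomy=tax8)
        assert back.p == refs.p
        assert tuple(r.matches for r in back.profiles) == tuple(
            r.matches for r in refs.profiles
        )


class TestMaskNovelty:
    @pytest.fixture()
    def family_profile(self, tax8):
        """Matches to the same species, a congener, and a same-family cousin."""
        genus = tax8.taxa_at_depth(6)[0]
        fam_other_genus = f"{genus[:-2]}.1"
        self_sp, congener = f"{genus}.0", f"{genus}.1"
        cousin = f"{fam_other_genus}.0"
        hits = [
            _match(self_sp, 200.0, 1e-80),
            _match(congener, 150.0, 1e-60),
            _match(cousin, 120.0, 1e-40),
        ]
        return build_profile(hits, p=0.0, source_id="q", source_taxon=self_sp), self_sp

    def test_species_masking_keeps_relatives(self, tax8, family_profile):
        prof, self_sp = family_profile
        masked = mask_novelty(prof, tax8.lineage(self_sp), novelty_rank=7, p=0.0,
                              taxonomy=tax8)
        assert self_sp not in masked.taxa()
        assert len(masked) == 2

    def test_class_masking_empties_profile(self, tax8, family_profile):
        prof, self_sp = family_profile
        masked = mask_novelty(prof, tax8.lineage(self_sp), novelty_rank=3, p=0.0,
                              taxonomy=tax8)
        assert masked.is_empty

    def test_threshold_reapplied_after_masking(self, tax8, family_profile):
        # survivors {150, 120}: the new threshold 0.85 x 150 excludes 120
        prof, self_sp = family_profile
        masked = mask_novelty(prof, tax8.lineage(self_sp), novelty_rank=7, p=0.85,
                              taxonomy=tax8)
        assert [m.bitscore for m in masked.matches] == [150.0]

    def test_masked_clade_never_survives(self, tax8, rng):
        """No retained taxon may share the truth's ancestor at the mask rank."""
        species = tax8.species()
        for _ in range(20):
            truth_sp = species[int(rng.integers(len(species)))]
            hits = [
                _match(s, float(rng.uniform(50, 400)))
                for s in species
            ]
            prof = build_profile(hits, p=0.0, source_id="q")
            rank = int(rng.integers(1, 8))
            truth = tax8.lineage(truth_sp)
            masked = mask_novelty(prof, truth, rank, p=0.5, taxonomy=tax8)
            clade = truth.at_depth(rank)
            for t in masked.taxa():
                assert tax8.ancestor(t, rank, exact=True) != clade
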