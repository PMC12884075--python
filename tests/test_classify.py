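import numpy as np
import pytest

from iod.classify import (
    SiteCall,
    bin_and_select,
    classify_hits,
    filter_hits,
    infer_occupancy,
    normalized_difference,
    refine,
)
from iod.match import MatchHit, build_query_set, find_hits
from iod.registry import AttBRecord, GIRecord, ReferenceDB
from iod import simdata


def mk_hit(attb="a1", part="full", contig="c1", start=1000, end=1039, strand="+",
           mm=0, gaps=0, aln=None):
    aln = aln or (end - start + 1 + gaps)
    ident = aln - mm - gaps
    return MatchHit(query_id=f"{attb}|{part}", contig=contig, start=start, end=end,
                    strand=strand, aln_len=aln, identities=ident, mismatches=mm,
                    gap_columns=gaps, identity_pct=100.0 * ident / aln,
                    score=2.0 * ident - 3.0 * mm - 5.0 * gaps, attb_ref=attb, part=part)


def mini_db(gi_lengths: dict[str, list[int]], seq="ACGT" * 12, ib=(13, 30)) -> ReferenceDB:
    """gi_lengths: attb_id -> list of reference-GI lengths."""
    gis, attbs = {}, []
    for attb_id, lengths in gi_lengths.items():
        refs = []
        for i, L in enumerate(lengths):
            gi_id = f"{attb_id}_gi{i}"
            gis[gi_id] = GIRecord(gi_id=gi_id, contig_accession="x", start=1, end=L,
                                  length=L, support_score=5.0, attb_seq=seq,
                                  idblock_start=ib[0], idblock_end=ib[1],
                                  target_class="tRNA", integrase_ids=["p"])
            refs.append(gi_id)
        attbs.append(AttBRecord(attb_id=attb_id, sequence=seq, idblock_start=ib[0],
                                idblock_end=ib[1], family="tyrosine", gi_refs=refs,
                                integrase_refs=["p"]))
    return ReferenceDB(attbs=attbs, gis=gis, integrases={}, taxonomy={})


class TestFilterHits:
    def test_single_full_hit_kept(self):
        kept, pool, rejected = filter_hits([mk_hit()])
        assert len(kept) == 1 and not pool and not rejected

    def test_full_hit_with_nested_halves_is_one_locus(self):
        hits = [
            mk_hit(part="full", start=1000, end=1051),
            mk_hit(part="L", start=1000, end=1035),
            mk_hit(part="R", start=1016, end=1051),
        ]
        kept, pool, _ = filter_hits(hits)
        assert len(kept) == 3 and not pool

    def test_low_identity_rejected(self):
        # 40 columns, 3 mismatches -> 92.5% identity
        h = mk_hit(mm=3)
        kept, pool, rejected = filter_hits([h])
        assert rejected == [h] and not kept

    def test_two_gap_columns_rejected(self):
        h = mk_hit(end=1041, gaps=2, aln=42)
        assert filter_hits([h])[2] == [h]

    def test_distant_halves_go_to_pool(self):
        hits = [
            mk_hit(part="L", start=10_000, end=10_035),
            mk_hit(part="R", start=50_000, end=50_035),
        ]
        kept, pool, _ = filter_hits(hits)
        assert not kept and len(pool) == 2

    def test_two_full_loci_go_to_pool(self):
        hits = [mk_hit(start=1000, end=1039), mk_hit(start=9000, end=9039)]
        kept, pool, _ = filter_hits(hits)
        assert not kept and len(pool) == 2

    def test_half_only_locus_not_kept(self):
        kept, pool, _ = filter_hits([mk_hit(part="L")])
        assert not kept and len(pool) == 1


class TestNormalizedDifference:
    def test_exact(self):
        assert normalized_difference(40_000, 40_000) == 0.0

    def test_signed(self):
        assert normalized_difference(40_000, 36_000) == pytest.approx(4_000 / 76_000)
        assert normalized_difference(36_000, 40_000) == pytest.approx(-4_000 / 76_000)

    def test_antisymmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            e, a = rng.uniform(1, 1e6, size=2)
            assert normalized_difference(e, a) == pytest.approx(-normalized_difference(a, e))

    def test_threshold_equals_ratio_window(self):
        # |nd| < 0.05  <=>  actual/expected in (19/21, 21/19)
        rng = np.random.default_rng(1)
        for _ in range(2000):
            e = float(rng.uniform(100, 1e6))
            a = float(rng.uniform(100, 1e6))
            nd_ok = abs(normalized_difference(e, a)) < 0.05
            ratio_ok = 19 / 21 < a / e < 21 / 19
            assert nd_ok == ratio_ok


class TestInferOccupancy:
    def pair(self, actual, contig="c1", strand="+"):
        l = mk_hit(part="L", start=10_000, end=10_035, strand=strand, contig=contig)
        r_end = 10_000 + actual - 1
        r = mk_hit(part="R", start=r_end - 35, end=r_end, strand=strand, contig=contig)
        return [l, r]

    def test_exact_length_occupied(self):
        db = mini_db({"a1": [40_000]})
        ev = infer_occupancy(self.pair(40_000), db, {"c1": 100_000})
        assert ev["a1"].normalized_difference == 0.0
        assert ev["a1"].actual == 40_000

    def test_just_over_threshold_not_occupied(self):
        db = mini_db({"a1": [40_000]})
        ev = infer_occupancy(self.pair(36_000), db, {"c1": 100_000})
        assert "a1" not in ev  # nd = 0.0526

    def test_just_under_threshold_occupied(self):
        db = mini_db({"a1": [10_000]})
        ev = infer_occupancy(self.pair(9_100), db, {"c1": 100_000})
        assert ev["a1"].normalized_difference == pytest.approx(900 / 19_100)

    def test_best_gi_selected(self):
        db = mini_db({"a1": [9_500, 10_000, 11_000]})
        ev = infer_occupancy(self.pair(10_000), db, {"c1": 100_000})
        assert ev["a1"].gi_ref == "a1_gi1"

    def test_minus_strand_pair(self):
        # on the minus strand the R half sits left of the L half
        r = mk_hit(part="R", start=10_000, end=10_035, strand="-")
        l = mk_hit(part="L", start=17_965, end=18_000, strand="-")
        db = mini_db({"a1": [8_001]})
        ev = infer_occupancy([l, r], db, {"c1": 100_000})
        assert ev["a1"].actual == 8_001

    def test_strand_mismatch_no_pair(self):
        l = mk_hit(part="L", start=10_000, end=10_035, strand="+")
        r = mk_hit(part="R", start=17_965, end=18_000, strand="-")
        db = mini_db({"a1": [8_001]})
        assert infer_occupancy([l, r], db, {"c1": 100_000}) == {}

    def test_cross_contig(self):
        # L on contig A pointing right: distance to terminus = 60_000 - 50_001 + 1
        l = mk_hit(part="L", contig="cA", start=50_001, end=50_036, strand="+")
        # R on contig B pointing right: island occupies B's left terminus
        r = mk_hit(part="R", contig="cB", start=1_965, end=2_000, strand="+")
        expected = (60_000 - 50_001 + 1) + 2_000
        db = mini_db({"a1": [expected]})
        ev = infer_occupancy([l, r], db, {"cA": 60_000, "cB": 40_000})
        assert ev["a1"].cross_contig is True
        assert ev["a1"].actual == expected

    def test_no_reference_length_skipped(self, caplog):
        db = mini_db({})
        with caplog.at_level("WARNING"):
            ev = infer_occupancy(self.pair(10_000), db, {"c1": 100_000})
        assert ev == {}


def call(attb="a1", start=1000, end=1040, score=80.0, support=5.0, contig="c1"):
    return SiteCall(attb_ref=attb, contig=contig, start=start, end=end, strand="+",
                    status="candidate", reason="ok", best_hit_score=score,
                    ref_gi=f"{attb}_gi0", ref_gi_support=support)


class TestRefine:
    def test_candidate_inside_occupied(self):
        db = mini_db({"a1": [40_000]})
        attbs = {a.attb_id: a for a in db.attbs}
        occ = call("a2", start=4_000, end=44_000)
        occ.status = "occupied"
        cand = call("a1", start=5_000, end=5_040)
        genome = {"c1": "ACGT" * 20_000}
        final, questionable = refine([cand], [occ], genome, attbs, homopolymer_min=50)
        assert final == []
        assert questionable[0].reason == "in_occupied"

    def test_multi_idblock_copy(self):
        rng = np.random.default_rng(3)
        seq = simdata.random_dna(rng, 12) + simdata.random_dna(rng, 18) + simdata.random_dna(rng, 12)
        a = AttBRecord(attb_id="a1", sequence=seq, idblock_start=13, idblock_end=30,
                       family="tyrosine", gi_refs=[], integrase_refs=[])
        genome = simdata.random_genome(20_000, seed=4)
        contig = next(iter(genome))
        ib = a.idblock_seq
        genome[contig] = genome[contig][:2_000] + seq + genome[contig][2_000 + len(seq):]
        genome[contig] = genome[contig][:10_000] + ib + genome[contig][10_000 + len(ib):]
        cand = call("a1", start=2_001, end=2_000 + len(seq))
        final, questionable = refine([cand], [], genome, {"a1": a})
        assert questionable[0].reason == "multi_idblock"

    def test_homopolymer_idblock(self):
        seq = "CGTACGTACGTA" + "A" * 12 + "CGTACGTACGTG"
        a = AttBRecord(attb_id="a1", sequence=seq, idblock_start=13, idblock_end=24,
                       family="tyrosine", gi_refs=[], integrase_refs=[])
        genome = {"c1": "CGCGCGCG" * 1000}
        final, questionable = refine([call("a1")], [], genome, {"a1": a})
        assert questionable[0].reason == "homopolymer_idblock"

    def test_clean_candidate_survives(self):
        rng = np.random.default_rng(5)
        seq = simdata.random_dna(rng, 44)
        a = AttBRecord(attb_id="a1", sequence=seq, idblock_start=15, idblock_end=30,
                       family="tyrosine", gi_refs=[], integrase_refs=[])
        genome = simdata.random_genome(20_000, seed=6)
        contig = next(iter(genome))
        genome[contig] = genome[contig][:2_000] + seq + genome[contig][2_000 + 44:]
        final, questionable = refine([call("a1", start=2_001, end=2_044)], [], genome, {"a1": a})
        assert len(final) == 1 and not questionable


class TestBinAndSelect:
    def test_higher_score_wins_overlap(self):
        a = call("a1", start=1000, end=1040, score=80.0)
        b = call("a2", start=1020, end=1060, score=70.0)
        ranked, dupes = bin_and_select([a, b])
        assert [c.attb_ref for c in ranked] == ["a1"]
        assert dupes[0].attb_ref == "a2" and dupes[0].reason == "overlap_loser"

    def test_tie_broken_by_gi_support(self):
        a = call("a1", score=80.0, support=7.2)
        b = call("a2", start=1020, end=1060, score=80.0, support=9.5)
        ranked, _ = bin_and_select([a, b])
        assert ranked[0].attb_ref == "a2"

    def test_rank_order_by_support(self):
        calls = [
            call("a1", start=1_000, end=1_040, support=5.0),
            call("a2", start=5_000, end=5_040, support=9.0),
            call("a3", start=9_000, end=9_040, support=7.0),
        ]
        ranked, dupes = bin_and_select(calls)
        assert [c.attb_ref for c in ranked] == ["a2", "a3", "a1"]
        assert [c.rank for c in ranked] == [1, 2, 3]
        assert dupes == []

    def test_non_overlap_different_contig(self):
        a = call("a1", contig="c1")
        b = call("a2", contig="c2")
        ranked, dupes = bin_and_select([a, b])
        assert len(ranked) == 2 and not dupes


@pytest.mark.parametrize("gi_len", [5_000, 10_000, 40_000, 100_000])
def test_planted_occupied_length_sweep(tmp_path, gi_len):
    synth = simdata.synth_reference_db(tmp_path / "db", n_species=1,
                                       attbs_per_species=2, seed=21)
    db = synth.db
    attb = sorted(db.attbs, key=lambda a: a.attb_id)[0]
    for g in attb.gi_refs:
        db.gis[g].length = gi_len
        db.gis[g].end = db.gis[g].start + gi_len - 1
    genome = simdata.random_genome(gi_len + 10_000, seed=22, contig="t1")
    truth = simdata.FixtureTruth(seed=22)
    genome = simdata.plant_occupied(genome, attb, gi_len, "t1", 3_000, truth=truth)
    hits = find_hits(build_query_set([attb]), genome)
    result = classify_hits(hits, db, genome)
    assert [c.attb_ref for c in result.occupied] == [attb.attb_id]
    assert result.evidence[attb.attb_id].normalized_difference == 0.0
    assert result.evidence[attb.attb_id].actual == gi_len


def test_near_length_never_occupied(tmp_path):
    synth = simdata.synth_reference_db(tmp_path / "db", n_species=1,
                                       attbs_per_species=2, seed=31)
    db = synth.db
    attb = sorted(db.attbs, key=lambda a: a.attb_id)[0]
    for g in attb.gi_refs:
        db.gis[g].length = 10_000
    genome = simdata.random_genome(20_000, seed=32, contig="t1")
    genome = simdata.plant_occupied(genome, attb, 9_000, "t1", 3_000,
                                    truth=simdata.FixtureTruth(seed=32))
    hits = find_hits(build_query_set([attb]), genome)
    result = classify_hits(hits, db, genome)
    assert result.occupied == []
    assert [c.reason for c in result.questionable] == ["multi_hit"]


def test_cross_contig_classification(tmp_path):
    synth = simdata.synth_reference_db(tmp_path / "db", n_species=1,
                                       attbs_per_species=2, seed=41)
    db = synth.db
    attb = sorted(db.attbs, key=lambda a: a.attb_id)[0]
    gi_len = 8_000
    for g in attb.gi_refs:
        db.gis[g].length = gi_len
    genome = {}
    genome.update(simdata.random_genome(12_000, seed=42, contig="tA"))
    genome.update(simdata.random_genome(12_000, seed=43, contig="tB"))
    genome = simdata.plant_occupied_split(genome, attb, gi_len, "tA", "tB",
                                          truth=simdata.FixtureTruth(seed=43))
    hits = find_hits(build_query_set([attb]), genome)
    result = classify_hits(hits, db, genome)
    assert [c.attb_ref for c in result.occupied] == [attb.attb_id]
    ev = result.evidence[attb.attb_id]
    assert ev.cross_contig is True
    assert ev.actual == gi_len


def test_hit_order_invariance(standard_fx, standard_db):
    from iod.sketch import load_sketches, rank_neighbors, sketch_genome, collect_attbs

    genome = standard_fx.genome
    queried = standard_db.attbs
    hits = find_hits(build_query_set(queried), genome)
    res_fwd = classify_hits(hits, standard_db, genome)
    res_rev = classify_hits(list(reversed(hits)), standard_db, genome)

    def summary(res):
        return (
            [(c.attb_ref, c.rank, c.start) for c in res.ranked],
            sorted((c.attb_ref, c.reason) for c in res.questionable),
            sorted(c.attb_ref for c in res.occupied),
        )

    assert summary(res_fwd) == summary(res_rev)
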