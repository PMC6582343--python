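import random

import pytest

from mitoforge.findmitoscaf import (
    ConfigurationError,
    ScaffoldCandidate,
    SelectionConfig,
    assign_taxon,
    build_candidates,
    confident_score,
    filter_by_rank,
    select_scaffolds,
)
from mitoforge.io_formats import GeneAnnotation, HomologyHit, SeqRecord


def _pcg(gene, completeness, seq_id="s", start=0):
    start = start or abs(hash(gene)) % 1000
    return GeneAnnotation(gene=gene, seq_id=seq_id, start=start,
                          end=start + 300, strand="+", kind="PCG",
                          completeness=completeness)


def _cand(seq_id, genes, a=1.0, length=1000):
    rec = SeqRecord(id=seq_id, sequence="ACGT" * (length // 4))
    anns = [_pcg(g, c, seq_id) for g, c in genes]
    return ScaffoldCandidate(record=rec, annotations=anns, reliability=a)


def _hit(qid, gene, taxon, bitscore=100.0, qs=1, qe=300):
    return HomologyHit(
        query_id=qid, subject_gene=gene, subject_taxon=taxon,
        percent_identity=95.0, query_start=qs, query_end=qe,
        subject_start=1, subject_end=100, evalue=1e-30, bitscore=bitscore)


class TestConfidentScore:
    def test_single_complete_gene_unit_weight(self):
        assert confident_score(_cand("s", [("COX1", 100.0)], a=1.0)) == 100.0

    def test_weighted_sum(self):
        c = _cand("s", [("COX1", 100.0), ("ND2", 50.0)], a=10.0)
        assert confident_score(c) == 1500.0

    def test_no_pcgs_scores_zero(self):
        assert confident_score(_cand("s", [], a=7.0)) == 0.0

    def test_nonpositive_reliability_rejected(self):
        c = _cand("s", [("COX1", 100.0)], a=1.0)
        c.reliability = 0.0
        with pytest.raises(ValueError):
            confident_score(c)

    def test_trna_rrna_excluded_from_score(self):
        c = _cand("s", [("COX1", 100.0)], a=2.0)
        c.annotations.append(GeneAnnotation(
            gene="rrn12", seq_id="s", start=500, end=1400, strand="+",
            kind="rRNA", completeness=100.0))
        assert confident_score(c) == 200.0

    def test_raising_completeness_never_lowers_rank(self):
        low = _cand("a", [("COX1", 40.0), ("ND2", 60.0)], a=3.0)
        high = _cand("a", [("COX1", 90.0), ("ND2", 60.0)], a=3.0)
        assert confident_score(high) >= confident_score(low)


class TestAssignTaxon:
    def test_majority_vote(self, taxonomy):
        c = _cand("c1", [])
        genes = ["COX1", "ND1", "ND2", "ND3", "ND4", "CYTB"]
        hits = [_hit("c1", g, "t_mus_musculus", qs=1 + i * 400,
                     qe=300 + i * 400) for i, g in enumerate(genes[:5])]
        hits.append(_hit("c1", genes[5], "t_tribolium_cast", qs=2200,
                         qe=2500))
        assert assign_taxon(c, hits, taxonomy) == "t_mus_musculus"

    def test_single_locus(self, taxonomy):
        c = _cand("c1", [])
        hits = [_hit("c1", "COX1", "t_tribolium_cast")]
        assert assign_taxon(c, hits, taxonomy) == "t_tribolium_cast"

    def test_no_hits_gives_none(self, taxonomy):
        assert assign_taxon(_cand("c1", []), [], taxonomy) is None

    def test_tie_broken_by_summed_bitscore(self, taxonomy):
        hits = [
            _hit("c1", "COX1", "t_mus_musculus", bitscore=50.0),
            _hit("c1", "ND2", "t_tribolium_cast", bitscore=500.0,
                 qs=1000, qe=1300),
        ]
        assert assign_taxon(_cand("c1", []), hits, taxonomy) == \
            "t_tribolium_cast"

    def test_unknown_taxon_rejected(self, taxonomy):
        hits = [_hit("c1", "COX1", "t_martian")]
        with pytest.raises(KeyError):
            assign_taxon(_cand("c1", []), hits, taxonomy)


class TestFilterByRank:
    def test_lineage_inside_required_order_kept(self, taxonomy):
        c = _cand("c1", [])
        c.assigned_taxon = "t_mus_musculus"
        config = SelectionConfig(required_taxon="Rodentia",
                                 required_rank="order")
        kept, rejected = filter_by_rank([c], config, taxonomy)
        assert kept == [c] and rejected == []

    def test_outsider_rejected(self, taxonomy):
        c = _cand("c1", [])
        c.assigned_taxon = "t_tribolium_cast"
        config = SelectionConfig(required_taxon="Rodentia",
                                 required_rank="order")
        kept, rejected = filter_by_rank([c], config, taxonomy)
        assert kept == [] and rejected[0].action == "reject_rank"

    def test_unassigned_rejected(self, taxonomy):
        c = _cand("c1", [])
        config = SelectionConfig(required_taxon="Rodentia",
                                 required_rank="order")
        kept, rejected = filter_by_rank([c], config, taxonomy)
        assert kept == [] and rejected[0].action == "reject_unassigned"

    def test_unknown_required_taxon_rejected(self, taxonomy):
        config = SelectionConfig(required_taxon="Atlantis",
                                 required_rank="order")
        with pytest.raises(ConfigurationError):
            filter_by_rank([], config, taxonomy)


class TestSelectScaffolds:
    def test_single_complete_sequence_stops_search(self):
        full = _cand("mt", [(g, 100.0) for g in (
            "ATP6", "ATP8", "COX1", "COX2", "COX3", "CYTB", "ND1", "ND2",
            "ND3", "ND4", "ND4L", "ND5", "ND6")], a=50.0)
        extra = _cand("other", [("COX1", 80.0)], a=5.0)
        res = select_scaffolds([full, extra])
        assert [c.record.id for c in res.selected] == ["mt"]
        assert any(d.action == "stop" for d in res.log)

    def test_complete_gene_conflict_skips_whole_sequence(self):
        top = _cand("s1", [("COX1", 100.0)], a=50.0)
        lower = _cand("s2", [("COX1", 60.0), ("ND2", 100.0)], a=5.0)
        res = select_scaffolds([top, lower])
        assert [c.record.id for c in res.selected] == ["s1"]
        skip = next(d for d in res.skipped if d.seq_id == "s2")
        assert "COX1" in skip.reason
        assert "ND2" not in res.genes_found  # lost with the skipped seq

    def test_incomplete_incomplete_both_kept(self):
        a = _cand("s1", [("COX1", 70.0)], a=50.0)
        b = _cand("s2", [("COX1", 40.0)], a=5.0)
        res = select_scaffolds([a, b])
        assert {c.record.id for c in res.selected} == {"s1", "s2"}
        assert res.genes_found["COX1"] == ("s1", 70.0)

    def test_complete_copy_demotes_prior_incomplete(self):
        a = _cand("s1", [("COX1", 70.0)], a=50.0)
        b = _cand("s2", [("COX1", 100.0)], a=5.0)
        res = select_scaffolds([a, b])
        assert res.genes_found["COX1"] == ("s2", 100.0)
        assert any(d.action == "demote" for d in res.log)

    def test_retention_rule_at_five_pcgs(self):
        five = _cand("p5", [(g, 50.0) for g in
                            ("COX1", "COX2", "COX3", "ND1", "ND2")], a=1.0)
        four = _cand("p4", [(g, 50.0) for g in
                            ("COX1", "COX2", "COX3", "ND1")], a=1.0)
        res = select_scaffolds([five, four])
        retained = {c.record.id for c in res.retained_extra}
        assert "p5" in retained and "p4" not in retained

    def test_input_order_invariance(self):
        cands = [
            _cand("a", [("COX1", 100.0), ("ND1", 100.0)], a=10.0),
            _cand("b", [("COX1", 50.0), ("ND2", 100.0)], a=8.0),
            _cand("c", [("ND3", 100.0)], a=2.0),
            _cand("d", [("ND2", 70.0)], a=1.0),
        ]
        baseline = select_scaffolds(cands)
        rng = random.Random(5)
        for _ in range(5):
            shuffled = cands[:]
            rng.shuffle(shuffled)
            res = select_scaffolds(shuffled)
            assert [c.record.id for c in res.selected] == \
                [c.record.id for c in baseline.selected]
            assert res.genes_found == baseline.genes_found

    def test_every_candidate_partitioned_once(self):
        cands = [
            _cand("a", [("COX1", 100.0)], a=10.0),
            _cand("b", [("COX1", 80.0)], a=5.0),
            _cand("c", [], a=1.0),
        ]
        res = select_scaffolds(cands)
        selected = {c.record.id for c in res.selected}
        skipped = {d.seq_id for d in res.skipped}
        assert selected | skipped == {"a", "b", "c"}
        assert selected & skipped == set()

    def test_empty_candidate_list(self):
        res = select_scaffolds([])
        assert res.selected == [] and res.genes_found == {}


class TestEndToEndDecoys:
    def test_planted_genome_wins_over_decoys(self, truth, taxonomy, refs,
                                             sim_config):
        from mitoforge import simulate
        from mitoforge.annotator import GeneticCode, annotate_sequence

        decoys, infos, depths = simulate.make_decoys(truth, sim_config)
        candidates = [truth.genome] + decoys
        hom, trna, rrna = simulate.make_hits(candidates, truth, infos,
                                             sim_config)
        code = GeneticCode(sim_config.code_table)
        anns = []
        for rec in candidates:
            anns.extend(annotate_sequence(rec, hom, trna, rrna, code, refs,
                                          circular=(rec.id == "mt_genome")))
        all_depths = {"mt_genome": sim_config.depth, **depths}
        cands = build_candidates(candidates, anns, hom, taxonomy, all_depths)
        config = SelectionConfig(required_taxon="Rodentia",
                                 required_rank="order")
        kept, rejected = filter_by_rank(cands, config, taxonomy)
        # nuclear contigs have no hits -> all rejected as unassigned
        assert {d.seq_id for d in rejected} >= \
            {f"nuc{i+1}" for i in range(sim_config.n_nuclear_contigs)}
        res = select_scaffolds(kept, config)
        assert [c.record.id for c in res.selected] == ["mt_genome"]

    def test_stored_score_matches_equation(self, truth, taxonomy, refs,
                                           sim_config):
        from mitoforge import simulate
        from mitoforge.annotator import GeneticCode, annotate_sequence

        decoys, infos, depths = simulate.make_decoys(truth, sim_config)
        candidates = [truth.genome] + decoys
        hom, trna, rrna = simulate.make_hits(candidates, truth, infos,
                                             sim_config)
        code = GeneticCode(sim_config.code_table)
        anns = []
        for rec in candidates:
            anns.extend(annotate_sequence(rec, hom, trna, rrna, code, refs))
        all_depths = {"mt_genome": sim_config.depth, **depths}
        cands = build_candidates(candidates, anns, hom, taxonomy, all_depths)
        for c in cands:
            expected = c.reliability * sum(
                a.completeness for a in c.pcg_annotations)
            if c.pcg_annotations:
                assert c.score == expected
            else:
                assert c.score == 0.0
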