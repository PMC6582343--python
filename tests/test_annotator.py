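import pytest

from mitoforge.annotator import (
    GeneticCode,
    Locus,
    ReferenceGeneTable,
    annotate_sequence,
    call_control_region,
    cluster_hits,
    compute_completeness,
    integrate_cm_hits,
    refine_boundaries,
)
from mitoforge.io_formats import CMHit, GeneAnnotation, HomologyHit, revcomp
from mitoforge import simulate


def _hit(gene="COX1", qs=1, qe=300, ss=1, se=100, ev=1e-40, bs=200.0,
         strand="+", qid="c1"):
    h = HomologyHit(
        query_id=qid, subject_gene=gene, subject_taxon="t_mus_musculus",
        percent_identity=99.0, query_start=qs, query_end=qe,
        subject_start=ss, subject_end=se, evalue=ev, bitscore=bs)
    h.strand = strand
    return h


class TestGeneticCode:
    def test_vertebrate_table_sets(self):
        code = GeneticCode(2)
        assert {"ATG", "ATA", "GTG"} <= code.start_codons
        assert code.is_stop("AGA") and code.is_stop("TAA")
        assert not code.is_stop("TGA")  # TGA codes Trp in mito code

    def test_invertebrate_table_sets(self):
        code = GeneticCode(5)
        assert "ATT" in code.start_codons
        assert not code.is_stop("AGA")

    def test_unsupported_table_rejected(self):
        with pytest.raises(ValueError):
            GeneticCode(3)


class TestClusterHits:
    def test_nearby_same_gene_hits_merge(self):
        loci = cluster_hits([_hit(qs=100, qe=400), _hit(qs=380, qe=900)])
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (99, 900)

    def test_distinct_genes_never_merge(self):
        loci = cluster_hits([_hit("COX1"), _hit("ND2")])
        assert len(loci) == 2

    def test_gap_over_30bp_does_not_merge(self):
        loci = cluster_hits([_hit(qs=1, qe=100), _hit(qs=132, qe=300)])
        assert len(loci) == 2
        loci = cluster_hits([_hit(qs=1, qe=100), _hit(qs=131, qe=300)])
        assert len(loci) == 1

    def test_representative_is_best_evalue(self):
        h_good = _hit(qs=1, qe=300, ev=1e-50)
        h_bad = _hit(qs=250, qe=600, ev=1e-10)
        loci = cluster_hits([h_bad, h_good])
        assert loci[0].representative is h_good

    def test_empty_input(self):
        assert cluster_hits([]) == []


def _orf(code, n_codons, stop="TAA"):
    """Deterministic ORF: ATG + n_codons sense codons + stop."""
    body = "".join(["GCT", "CTT", "GGT", "TCT"][i % 4]
                   for i in range(n_codons))
    return "ATG" + body + stop


class TestRefineBoundaries:
    code = GeneticCode(2)

    def _locus(self, seq, gene_start, gene_end_nostop, aa):
        # hit covering the coding part, protein coords from 1
        rep = _hit(gene="COX1", qs=gene_start + 1, qe=gene_end_nostop,
                   ss=1, se=aa)
        return Locus(gene="COX1", seq_id="c1", strand="+",
                     start=gene_start, end=gene_end_nostop,
                     representative=rep, hits=[rep])

    def test_atg_at_hit_start_is_canonical_unchanged(self):
        gene = _orf(self.code, 40)
        seq = "CCCCCCCCCC" + gene + "CCCCCCCCCC"
        locus = self._locus(seq, 10, 10 + len(gene) - 3, 41)
        ann = refine_boundaries(locus, seq, self.code)
        assert ann.start == 10 and ann.start_status == "canonical"
        assert ann.end == 10 + len(gene)
        assert ann.stop_status == "complete"
        assert not ann.invalid

    def test_stop_up_to_60nt_downstream_is_found(self):
        gene_nostop = _orf(self.code, 40)[:-3]
        filler = "GCT" * 3  # 9 nt in frame, no stop
        seq = "AAAAAAAAA" + gene_nostop + filler + "TAA" + "CCCC"
        locus = self._locus(seq, 9, 9 + len(gene_nostop), 41)
        ann = refine_boundaries(locus, seq, self.code)
        assert ann.stop_status == "complete"
        assert seq[ann.end - 3:ann.end] == "TAA"

    def test_truncated_t_stop_abutting_next_feature(self):
        gene_nostop = _orf(self.code, 40)[:-3]
        seq = "AAAAAAAAA" + gene_nostop + "T" + "GGGGGGG"
        boundary = 9 + len(gene_nostop) + 1  # next feature starts here
        locus = self._locus(seq, 9, 9 + len(gene_nostop), 41)
        ann = refine_boundaries(locus, seq, self.code,
                                downstream_limit=boundary)
        assert ann.stop_status == "truncated_T"
        assert ann.end == boundary

    def test_minus_strand_coordinates_map_back(self):
        gene = _orf(self.code, 40)
        fwd = "CCCCCCCCCC" + gene + "CCCCCCCCCC"
        seq = revcomp(fwd)
        L = len(seq)
        rep = _hit(gene="COX1", qs=L - (10 + len(gene) - 3) + 1,
                   qe=L - 10, ss=1, se=41, strand="-")
        locus = Locus(gene="COX1", seq_id="c1", strand="-",
                      start=L - (10 + len(gene) - 3), end=L - 10,
                      representative=rep, hits=[rep])
        ann = refine_boundaries(locus, seq, self.code)
        assert (ann.start, ann.end) == (L - 10 - len(gene), L - 10)
        assert ann.stop_status == "complete"

    def test_interior_stop_flags_invalid(self):
        gene = _orf(self.code, 10)
        broken = gene[:15] + "TAA" + gene[18:]
        seq = "AAAAAAAAA" + broken + "CCCC"
        locus = self._locus(seq, 9, 9 + len(broken) - 3, 11)
        ann = refine_boundaries(locus, seq, self.code)
        assert ann.invalid

    def test_locus_outside_sequence_rejected(self):
        locus = self._locus("ACGT" * 100, 10, 600, 100)
        with pytest.raises(ValueError):
            refine_boundaries(locus, "ACGT" * 20, self.code)


class TestCompleteness:
    def test_half_length_gene(self, refs):
        # 150 codons against a 300-aa shortest reference -> 50%
        table = ReferenceGeneTable(
            {**{g: 300 for g in simulate.PROTEIN_LENGTHS},
             "rrn12": 900, "rrn16": 1400})
        ann = GeneAnnotation(gene="COX1", seq_id="s", start=0, end=450,
                             strand="+", kind="PCG")
        assert compute_completeness(ann, table) == 50.0

    def test_over_length_gene_capped_at_100(self, refs):
        ann = GeneAnnotation(gene="ATP8", seq_id="s", start=0, end=3000,
                             strand="+", kind="PCG")
        assert compute_completeness(ann, refs) == 100.0

    def test_truncated_stop_counts_one_codon(self, refs):
        # 459 full codons + 1 bare T -> 460 units
        ann = GeneAnnotation(gene="ND4", seq_id="s", start=0, end=1378,
                             strand="+", kind="PCG",
                             stop_status="truncated_T")
        assert compute_completeness(ann, refs) == 100.0

    def test_missing_reference_entry_rejected(self, refs):
        ann = GeneAnnotation(gene="xyz", seq_id="s", start=0, end=100,
                             strand="+", kind="rRNA")
        with pytest.raises(KeyError):
            compute_completeness(ann, refs)


class TestIntegrateCMHits:
    def _trna(self, ev, feature="trnK", qid="c1", start=100, score=40.0):
        return CMHit(query_id=qid, feature=feature, start=start,
                     end=start + 69, strand="+", evalue=ev, score=score)

    def test_evalue_boundary_inclusive(self):
        kept = integrate_cm_hits([self._trna(0.001)], [])
        dropped = integrate_cm_hits([self._trna(0.0011)], [])
        assert len(kept) == 1 and len(dropped) == 0

    def test_best_evalue_hit_wins(self):
        anns = integrate_cm_hits(
            [self._trna(1e-8, start=100), self._trna(1e-3, start=500)], [])
        assert len(anns) == 1
        assert anns[0].start == 99

    def test_rrna_global_mode_preferred(self):
        glob = CMHit("c1", "rrn12", 100, 999, "+", 1e-5, 200.0, "global")
        loc = CMHit("c1", "rrn12", 100, 1050, "+", 1e-9, 300.0, "local")
        anns = integrate_cm_hits([], [glob, loc])
        assert len(anns) == 1 and anns[0].end == 999

    def test_rrna_local_mode_used_when_global_absent(self):
        loc = CMHit("c1", "rrn16", 100, 1400, "+", 1e-9, 300.0, "local")
        anns = integrate_cm_hits([], [loc])
        assert len(anns) == 1

    def test_empty_inputs(self):
        assert integrate_cm_hits([], []) == []


class TestControlRegion:
    def _complete_annotations(self, gap, L=None):
        """A synthetic complete gene set with one intergenic gap."""
        anns = []
        pos = 0
        for gene in simulate.PCG_NAMES:
            anns.append(GeneAnnotation(gene=gene, seq_id="s", start=pos,
                                       end=pos + 300, strand="+", kind="PCG",
                                       completeness=100.0))
            pos += 300
        for gene in simulate.TRNA_NAMES:
            anns.append(GeneAnnotation(gene=gene, seq_id="s", start=pos,
                                       end=pos + 70, strand="+", kind="tRNA",
                                       completeness=100.0))
            pos += 70
        for gene in simulate.RRNA_NAMES:
            anns.append(GeneAnnotation(gene=gene, seq_id="s", start=pos,
                                       end=pos + 900, strand="+", kind="rRNA",
                                       completeness=100.0))
            pos += 900
        L = L or pos + gap
        return anns, "A" * L

    def test_gap_600_emits_control_region(self, refs):
        anns, seq = self._complete_annotations(600)
        cr = call_control_region(anns, seq, refs, circular=True)
        assert cr is not None and cr.length == 600

    def test_gap_599_does_not(self, refs):
        anns, seq = self._complete_annotations(599)
        assert call_control_region(anns, seq, refs, circular=True) is None

    def test_missing_trna_blocks_call(self, refs):
        anns, seq = self._complete_annotations(1000)
        anns = [a for a in anns if a.gene != "trnK"]
        assert call_control_region(anns, seq, refs, circular=True) is None

    def test_incomplete_pcg_blocks_call(self, refs):
        anns, seq = self._complete_annotations(1000)
        anns[0].completeness = 99.0
        assert call_control_region(anns, seq, refs, circular=True) is None


class TestSimulatorRoundTrip:
    def test_planted_genome_annotates_exactly(self, truth, refs, genome_hits,
                                              sim_config):
        hom, trna, rrna = genome_hits
        code = GeneticCode(sim_config.code_table)
        anns = annotate_sequence(truth.genome, hom, trna, rrna, code, refs,
                                 circular=True)
        got = {(a.gene, a.start, a.end, a.strand) for a in anns}
        expected = {(a.gene, a.start, a.end, a.strand)
                    for a in truth.annotations}
        assert got == expected
        for a in anns:
            if a.kind in ("PCG", "rRNA"):
                assert a.completeness == 100.0
            if a.kind == "PCG":
                assert not a.invalid

    def test_truncated_stop_recovered(self, truth, refs, genome_hits,
                                      sim_config):
        hom, trna, rrna = genome_hits
        code = GeneticCode(sim_config.code_table)
        anns = annotate_sequence(truth.genome, hom, trna, rrna, code, refs,
                                 circular=True)
        nd4 = next(a for a in anns if a.gene == simulate.TRUNCATED_STOP_GENE)
        assert nd4.stop_status.startswith("truncated")

    def test_strand_involution(self, truth, refs, sim_config):
        from mitoforge.io_formats import SeqRecord
        rc_rec = SeqRecord(id=truth.genome.id,
                           sequence=revcomp(truth.genome.sequence))
        hom, trna, rrna = simulate.make_hits([rc_rec], truth, None,
                                             sim_config)
        code = GeneticCode(sim_config.code_table)
        anns = annotate_sequence(rc_rec, hom, trna, rrna, code, refs,
                                 circular=True)
        L = len(truth.genome.sequence)
        got = {(a.gene, a.start, a.end, a.strand) for a in anns
               if a.kind != "control_region"}
        flip = {"+": "-", "-": "+"}
        expected = {(a.gene, L - a.end, L - a.start, flip[a.strand])
                    for a in truth.annotations if a.kind != "control_region"}
        assert got == expected
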