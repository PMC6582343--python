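"""Synthetic-data generator with planted truth.

Everything the pipeline consumes can be produced here without any
download: a circular mitogenome carrying 13 protein-coding genes, 22
tRNAs, 2 rRNAs and a control region in a configurable gene order and
A+T content; paired-end reads with a substitution error model; NUMT
decoys (nuclear copies of mitogenome fragments at reduced identity,
embedded in nuclear flanks) and random nuclear background contigs; and
homology / covariance-model hit tables consistent with the planted
truth, standing in for the external tBlastn / MiTFi / Infernal searches.

One seeded numpy PRNG (PCG64 via ``numpy.random.default_rng``) drives
all randomness, so every artefact is reproducible from the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from .annotator import GeneticCode, ReferenceGeneTable
from .io_formats import (
    CMHit,
    GeneAnnotation,
    HomologyHit,
    PCG_NAMES,
    RRNA_NAMES,
    SeqRecord,
    TRNA_NAMES,
    revcomp,
)

# Protein lengths (amino acids, stop excluded) approximating a mammalian
# mitogenome; the shortest-reference table is derived from these.
PROTEIN_LENGTHS = {
    "ND1": 318, "ND2": 347, "COX1": 513, "COX2": 227, "ATP8": 67,
    "ATP6": 226, "COX3": 261, "ND3": 115, "ND4L": 98, "ND4": 459,
    "ND5": 603, "ND6": 174, "CYTB": 380,
}
RRNA_LENGTHS = {"rrn12": 900, "rrn16": 1400}
TRNA_LENGTH = 70

# Human-like vertebrate gene order: (name, kind, strand). The control
# region occupies the remainder of the circle after trnP.
VERTEBRATE_GENE_ORDER: tuple[tuple[str, str, str], ...] = (
    ("trnF", "tRNA", "+"), ("rrn12", "rRNA", "+"), ("trnV", "tRNA", "+"),
    ("rrn16", "rRNA", "+"), ("trnL1", "tRNA", "+"), ("ND1", "PCG", "+"),
    ("trnI", "tRNA", "+"), ("trnQ", "tRNA", "-"), ("trnM", "tRNA", "+"),
    ("ND2", "PCG", "+"), ("trnW", "tRNA", "+"), ("trnA", "tRNA", "-"),
    ("trnN", "tRNA", "-"), ("trnC", "tRNA", "-"), ("trnY", "tRNA", "-"),
    ("COX1", "PCG", "+"), ("trnS1", "tRNA", "-"), ("trnD", "tRNA", "+"),
    ("COX2", "PCG", "+"), ("trnK", "tRNA", "+"), ("ATP8", "PCG", "+"),
    ("ATP6", "PCG", "+"), ("COX3", "PCG", "+"), ("trnG", "tRNA", "+"),
    ("ND3", "PCG", "+"), ("trnR", "tRNA", "+"), ("ND4L", "PCG", "+"),
    ("ND4", "PCG", "+"), ("trnH", "tRNA", "+"), ("trnS2", "tRNA", "+"),
    ("trnL2", "tRNA", "+"), ("ND5", "PCG", "+"), ("ND6", "PCG", "-"),
    ("trnE", "tRNA", "-"), ("CYTB", "PCG", "+"), ("trnT", "tRNA", "+"),
    ("trnP", "tRNA", "-"),
)

# the gene given a polyadenylation-completed stop, and its bare ending
TRUNCATED_STOP_GENE = "ND4"
TRUNCATED_STOP_BASES = "T"

PLANTED_TAXON = "t_mus_musculus"

# taxon_id, name, rank, parent_id — planted rodent lineage plus a beetle
# outgroup under the shared animal root
TAXONOMY_ROWS: tuple[tuple[str, str, str, str], ...] = (
    ("t_animalia", "Animalia", "kingdom", ""),
    ("t_chordata", "Chordata", "phylum", "t_animalia"),
    ("t_mammalia", "Mammalia", "class", "t_chordata"),
    ("t_rodentia", "Rodentia", "order", "t_mammalia"),
    ("t_muridae", "Muridae", "family", "t_rodentia"),
    ("t_mus", "Mus", "genus", "t_muridae"),
    ("t_mus_musculus", "Mus musculus", "species", "t_mus"),
    ("t_arthropoda", "Arthropoda", "phylum", "t_animalia"),
    ("t_insecta", "Insecta", "class", "t_arthropoda"),
    ("t_coleoptera", "Coleoptera", "order", "t_insecta"),
    ("t_tenebrionidae", "Tenebrionidae", "family", "t_coleoptera"),
    ("t_tribolium", "Tribolium", "genus", "t_tenebrionidae"),
    ("t_tribolium_cast", "Tribolium castaneum", "species", "t_tribolium"),
)


@dataclass
class SimConfig:
    seed: int = 1
    genome_length: int = 16000
    at_content: float = 0.65
    gene_order: Sequence[tuple[str, str, str]] = VERTEBRATE_GENE_ORDER
    read_length: int = 150
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    depth: float = 100.0
    error_rate: float = 0.005
    n_numts: int = 5
    numt_identity: float = 0.90
    n_nuclear_contigs: int = 20
    nuclear_at: float = 0.58
    code_table: int = 2
    n_noise_hits: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.at_content < 1.0:
            raise ValueError("at_content must be in (0,1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0,0.1)")


@dataclass
class TruthSet:
    genome: SeqRecord
    annotations: list[GeneAnnotation]
    proteins: dict[str, str]            # gene -> amino-acid sequence
    gene_sequences: dict[str, str]      # gene -> coding-strand nt sequence
    taxon: str = PLANTED_TAXON
    code_table: int = 2
    circular: bool = True

    @property
    def control_region(self) -> Optional[GeneAnnotation]:
        for a in self.annotations:
            if a.kind == "control_region":
                return a
        return None


@dataclass
class DecoyInfo:
    """Bookkeeping for one NUMT decoy: where its mitochondrial fragment
    came from and where it sits inside the decoy record."""

    record_id: str
    genome_start: int   # 0-based on the (conceptually doubled) genome
    genome_end: int
    insert_offset: int  # fragment start within the decoy sequence
    identity: float


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, at: float) -> str:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _random_codons(
    rng: np.random.Generator, n: int, at: float, code: GeneticCode
) -> list[str]:
    """Sample n sense codons with per-base A+T probability ``at``."""
    codons: list[str] = []
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    while len(codons) < n:
        draw = rng.choice(_BASES, size=(n, 3), p=p)
        for row in draw:
            c = "".join(row)
            if not code.is_stop(c) and len(codons) < n:
                codons.append(c)
    return codons


def make_genome(config: SimConfig) -> TruthSet:
    """Plant a circular mitogenome with the configured gene order.

    Features abut directly; the control region takes up whatever length
    remains to reach ``genome_length`` and must come out >= 600 bp. One
    gene (ND4 by default) is written with a truncated stop so the
    annotation path for polyadenylation-completed stops is exercised.
    """
    rng = np.random.default_rng(config.seed)
    code = GeneticCode(config.code_table)

    order = list(config.gene_order)
    if sorted(n for n, k, _ in order if k == "PCG") != sorted(PCG_NAMES):
        raise ValueError("gene order must contain exactly the 13 PCGs")
    if sorted(n for n, k, _ in order if k == "tRNA") != sorted(TRNA_NAMES):
        raise ValueError("gene order must contain exactly the 22 tRNAs")
    if sorted(n for n, k, _ in order if k == "rRNA") != sorted(RRNA_NAMES):
        raise ValueError("gene order must contain exactly the 2 rRNAs")

    proteins: dict[str, str] = {}
    gene_sequences: dict[str, str] = {}
    pieces: list[str] = []
    annotations: list[GeneAnnotation] = []

    # protein-coding genes first so the non-coding A+T can compensate
    pcg_seqs: dict[str, str] = {}
    for gene, aa_len in PROTEIN_LENGTHS.items():
        codons = _random_codons(rng, aa_len - 1, config.at_content, code)
        if gene == TRUNCATED_STOP_GENE:
            stop = TRUNCATED_STOP_BASES
        else:
            stop = "TAA"
        seq = "ATG" + "".join(codons) + stop
        pcg_seqs[gene] = seq
        proteins[gene] = "M" + "".join(code.translate(c) for c in codons)
        gene_sequences[gene] = seq

    coding_len = sum(len(s) for s in pcg_seqs.values())
    coding_at = sum(s.count("A") + s.count("T") for s in pcg_seqs.values())
    noncoding_len = config.genome_length - coding_len
    cr_len = (config.genome_length - coding_len
              - TRNA_LENGTH * 22 - sum(RRNA_LENGTHS.values()))
    if cr_len < 600:
        raise ValueError(
            f"genome_length {config.genome_length} leaves only {cr_len} bp "
            "for the control region (>= 600 required)"
        )
    target_at = config.at_content * config.genome_length
    nc_at = float(np.clip((target_at - coding_at) / max(noncoding_len, 1),
                          0.05, 0.95))

    pos = 0
    for gene, kind, strand in order:
        if kind == "PCG":
            seq = pcg_seqs[gene]
        elif kind == "tRNA":
            seq = _random_seq(rng, TRNA_LENGTH, nc_at)
            gene_sequences[gene] = seq
        else:
            seq = _random_seq(rng, RRNA_LENGTHS[gene], nc_at)
            gene_sequences[gene] = seq
        placed = revcomp(seq) if strand == "-" else seq
        stop_status = "complete"
        if kind == "PCG" and gene == TRUNCATED_STOP_GENE:
            stop_status = ("truncated_TA" if TRUNCATED_STOP_BASES == "TA"
                           else "truncated_T")
        annotations.append(GeneAnnotation(
            gene=gene, seq_id="mt_genome", start=pos, end=pos + len(placed),
            strand=strand, kind=kind, completeness=100.0,
            stop_status=stop_status if kind == "PCG" else "complete",
        ))
        pieces.append(placed)
        pos += len(placed)

    cr_seq = _random_seq(rng, cr_len, nc_at)
    annotations.append(GeneAnnotation(
        gene="control_region", seq_id="mt_genome", start=pos,
        end=pos + cr_len, strand="+", kind="control_region",
        completeness=100.0,
    ))
    pieces.append(cr_seq)
    genome = "".join(pieces)
    assert len(genome) == config.genome_length

    return TruthSet(
        genome=SeqRecord(id="mt_genome", sequence=genome,
                         description="planted circular mitogenome"),
        annotations=annotations,
        proteins=proteins,
        gene_sequences=gene_sequences,
        code_table=config.code_table,
    )


def reference_table(margin: float = 0.0) -> ReferenceGeneTable:
    """Shortest-reference lengths derived from the planted gene lengths.

    ``margin`` shrinks the reference lengths by that fraction, emulating
    a database whose shortest counterparts are slightly shorter than the
    focal species' genes.
    """
    refs = {g: max(1, int(round(n * (1 - margin))))
            for g, n in PROTEIN_LENGTHS.items()}
    refs.update({g: max(1, int(round(n * (1 - margin))))
                 for g, n in RRNA_LENGTHS.items()})
    return ReferenceGeneTable(refs)


def make_reads(truth: TruthSet, config: SimConfig):
    """Uniform circular paired-end sampling with substitution errors.

    Returns a list of ReadPair; qualities are constant Q=35 and errors
    are drawn independently of quality.
    """
    from .readqc import Read, ReadPair

    rng = np.random.default_rng(config.seed + 1)
    genome = truth.genome.sequence
    L = len(genome)
    rl = config.read_length
    if rl >= L:
        raise ValueError("read_length must be below genome_length")
    doubled = genome + genome
    n_pairs = int(round(L * config.depth / (2 * rl)))
    quals = [35] * rl
    pairs = []
    for i in range(n_pairs):
        start = int(rng.integers(0, L))
        insert = int(np.clip(rng.normal(config.insert_mean, config.insert_sd),
                             2 * rl, L - 1))
        frag = doubled[start:start + insert]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        r1, r2 = frag[:rl], revcomp(frag[-rl:])
        if config.error_rate > 0:
            r1 = _mutate(rng, r1, rng.binomial(rl, config.error_rate))
            r2 = _mutate(rng, r2, rng.binomial(rl, config.error_rate))
        pairs.append(ReadPair(
            read1=Read(f"read{i}/1", r1, list(quals)),
            read2=Read(f"read{i}/2", r2, list(quals)),
        ))
    return pairs


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    if n_mut <= 0:
        return seq
    n_mut = min(n_mut, len(seq))
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    chars = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def make_decoys(
    truth: TruthSet, config: SimConfig
) -> tuple[list[SeqRecord], list[DecoyInfo], dict[str, float]]:
    """NUMT decoys plus nuclear background contigs.

    Each NUMT is a 10-40% fragment of the planted genome mutated down to
    ``numt_identity`` and embedded in random nuclear flanks; nuclear
    contigs are random sequence at the nuclear A+T content. Returns the
    records, the truth bookkeeping for the NUMTs, and a per-sequence
    mean-depth table (NUMTs and nuclear contigs sit at low, nuclear-like
    depth).
    """
    rng = np.random.default_rng(config.seed + 2)
    genome = truth.genome.sequence
    L = len(genome)
    doubled = genome + genome
    records: list[SeqRecord] = []
    infos: list[DecoyInfo] = []
    depths: dict[str, float] = {}
    for i in range(config.n_numts):
        frac = rng.uniform(0.10, 0.40)
        flen = int(frac * L)
        gs = int(rng.integers(0, L))
        frag = doubled[gs:gs + flen]
        n_mut = int(round((1 - config.numt_identity) * flen))
        frag = _mutate(rng, frag, n_mut)
        left = _random_seq(rng, int(rng.integers(200, 800)), config.nuclear_at)
        right = _random_seq(rng, int(rng.integers(200, 800)), config.nuclear_at)
        rid = f"numt{i + 1}"
        records.append(SeqRecord(
            id=rid, sequence=left + frag + right,
            description="synthetic NUMT decoy"))
        infos.append(DecoyInfo(
            record_id=rid, genome_start=gs, genome_end=gs + flen,
            insert_offset=len(left), identity=config.numt_identity))
        depths[rid] = float(rng.uniform(2.0, 8.0))
    for i in range(config.n_nuclear_contigs):
        length = int(rng.integers(1000, 4000))
        rid = f"nuc{i + 1}"
        records.append(SeqRecord(
            id=rid, sequence=_random_seq(rng, length, config.nuclear_at),
            description="synthetic nuclear contig"))
        depths[rid] = float(rng.uniform(1.0, 5.0))
    return records, infos, depths


# ---------------------------------------------------------------------------
# hit-table generation


def _locate_on_genome(seq: str, genome: str, max_error: float = 0.12):
    """Locate a candidate on the (doubled) circular genome.

    Returns (orientation, target_start, target_end_exclusive) or None.
    """
    doubled = genome + genome
    best = None
    for orient, q in (("+", seq), ("-", revcomp(seq))):
        res = edlib.align(q, doubled, mode="HW", task="locations",
                          k=int(max_error * len(q)))
        if res["editDistance"] == -1:
            continue
        if best is None or res["editDistance"] < best[0]:
            loc = res["locations"][0]
            best = (res["editDistance"], orient, loc[0], loc[1] + 1)
    if best is None:
        return None
    return best[1], best[2], best[3]


def _segment_identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 100.0 * (1.0 - d / max(len(a), len(b)))


def _evalue_for(aln_len_nt: int, identity: float) -> float:
    """Monotone surrogate: e-value decreases with alignment length times
    identity; floored at 1e-180."""
    return max(10.0 ** (-min(180.0, aln_len_nt * identity / 100.0 / 10.0)),
               1e-180)


def make_hits(
    candidates: Sequence[SeqRecord],
    truth: TruthSet,
    decoy_infos: Optional[Sequence[DecoyInfo]] = None,
    config: Optional[SimConfig] = None,
) -> tuple[list[HomologyHit], list[CMHit], list[CMHit]]:
    """Emit homology and CM hit tables consistent with the planted truth.

    For every candidate that carries planted genome sequence (located by
    alignment, or by bookkeeping for NUMT decoys), each overlapped gene
    region yields one hit with coordinates mapped onto the candidate,
    identity measured from the actual substrings, an e-value decreasing
    with length x identity, and the planted taxon as subject taxon.
    """
    config = config or SimConfig()
    genome = truth.genome.sequence
    L = len(genome)
    decoy_by_id = {d.record_id: d for d in (decoy_infos or [])}
    hom: list[HomologyHit] = []
    trna: list[CMHit] = []
    rrna: list[CMHit] = []

    for rec in candidates:
        if rec.id in decoy_by_id:
            d = decoy_by_id[rec.id]
            mapping = ("+", d.genome_start, d.genome_end, d.insert_offset)
        else:
            loc = _locate_on_genome(rec.sequence, genome)
            if loc is None:
                continue
            orient, ts, te = loc
            mapping = (orient, ts, te, 0)
        _emit_hits_for_candidate(rec, mapping, truth, hom, trna, rrna)

    if config.n_noise_hits:
        rng = np.random.default_rng(config.seed + 3)
        feats = list(TRNA_NAMES)
        for _ in range(config.n_noise_hits):
            rec = candidates[int(rng.integers(0, len(candidates)))]
            s = int(rng.integers(1, max(2, len(rec.sequence) - 60)))
            trna.append(CMHit(
                query_id=rec.id, feature=feats[int(rng.integers(0, len(feats)))],
                start=s, end=s + 59, strand="+",
                evalue=float(rng.uniform(0.011, 0.5)), score=5.0,
            ))
    return hom, trna, rrna


def _emit_hits_for_candidate(rec, mapping, truth, hom, trna, rrna) -> None:
    orient, ts, te, offset = mapping
    genome = truth.genome.sequence
    L = len(genome)
    doubled = genome + genome
    Lc = len(rec.sequence)

    for ann in truth.annotations:
        if ann.kind == "control_region":
            continue
        for shift in (0, L):
            s, e = ann.start + shift, ann.end + shift
            ov_s, ov_e = max(s, ts), min(e, te)
            if ov_e - ov_s < 30:
                continue
            # frame-aligned overlap coordinates on the doubled genome;
            # protein hits never cover the stop codon
            if ann.kind == "PCG":
                aa_span = 3 * len(truth.proteins[ann.gene])
                if ann.strand == "+":
                    ov_e = min(ov_e, s + aa_span)
                    ov_s = s + 3 * ((ov_s - s + 2) // 3)
                    ov_e = s + 3 * ((ov_e - s) // 3)
                else:
                    ov_s = max(ov_s, e - aa_span)
                    # codons counted from the coding start at the gene's
                    # forward-strand 3' end (= e), running downward
                    ov_s = e - 3 * ((e - ov_s) // 3)
                    ov_e = e - 3 * ((e - ov_e + 2) // 3)
                if ov_e - ov_s < 30:
                    continue
            # map to candidate coordinates (genome frame first)
            g_s = ov_s - ts + offset
            g_e = ov_e - ts + offset
            if orient == "+":
                c_s, c_e = g_s, g_e
                c_strand = ann.strand
            else:
                c_s, c_e = Lc - g_e, Lc - g_s
                c_strand = "-" if ann.strand == "+" else "+"
            if c_s < 0 or c_e > Lc or c_e <= c_s:
                continue
            cand_sub = rec.sequence[c_s:c_e]
            truth_sub = doubled[ov_s:ov_e]
            if orient == "-":
                cand_sub = revcomp(cand_sub)
            ident = _segment_identity(cand_sub, truth_sub)
            if ident < 55.0:
                continue
            if ann.kind == "PCG":
                aa_len = len(truth.proteins[ann.gene])
                if ann.strand == "+":
                    sstart = (ov_s - s) // 3 + 1
                    send = min(aa_len, (ov_e - s) // 3)
                else:
                    sstart = (e - ov_e) // 3 + 1
                    send = min(aa_len, (e - ov_s) // 3)
                if send < sstart:
                    continue
                aln_nt = ov_e - ov_s
                hit = HomologyHit(
                    query_id=rec.id, subject_gene=ann.gene,
                    subject_taxon=truth.taxon,
                    percent_identity=round(ident, 2),
                    query_start=c_s + 1, query_end=c_e,
                    subject_start=sstart, subject_end=send,
                    evalue=_evalue_for(aln_nt, ident),
                    bitscore=round(2.0 * aln_nt * ident / 100.0 / 3.0, 1),
                )
                hit.strand = c_strand
                hom.append(hit)
            else:
                feat_len = ann.end - ann.start
                # a tRNA cloverleaf is found whole or not at all; long
                # rRNAs also yield partial (local-style) hits
                min_cov = 0.7 * feat_len if ann.kind == "tRNA" else 60
                if (ov_e - ov_s) < min_cov:
                    continue
                cm = CMHit(
                    query_id=rec.id, feature=ann.gene,
                    start=c_s + 1, end=c_e, strand=c_strand,
                    evalue=_evalue_for(ov_e - ov_s, ident),
                    score=round((ov_e - ov_s) * ident / 200.0, 1),
                    mode="global",
                )
                (trna if ann.kind == "tRNA" else rrna).append(cm)
            # no break: a gene split across the ends of a rotated contig
            # legitimately yields one partial hit per end


def write_fixtures(config: SimConfig, outdir: str | os.PathLike) -> dict:
    """Generate the full fixture bundle into ``outdir``.

    Emits genome.fasta, truth.gff3, reads_1.fq / reads_2.fq,
    decoys.fasta, hits.tsv / trna.tsv / rrna.tsv (for the genome and the
    decoys), taxa.tsv, depths.tsv, gene_lengths.tsv and genes.fasta (the
    reference gene sequences, coding-strand orientation).
    Returns the in-memory objects for callers that keep going.
    """
    from .io_formats import (
        write_cm_table, write_depths, write_fasta, write_fastq_pairs,
        write_gff3, write_hits_table, write_taxonomy,
    )

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    truth = make_genome(config)
    reads = make_reads(truth, config)
    decoys, infos, depths = make_decoys(truth, config)
    refs = reference_table()
    candidates = [truth.genome] + decoys
    hom, trna, rrna = make_hits(candidates, truth, infos, config)

    write_fasta([truth.genome], os.path.join(outdir, "genome.fasta"))
    write_gff3(truth.annotations, os.path.join(outdir, "truth.gff3"),
               seq_lengths={truth.genome.id: len(truth.genome.sequence)})
    write_fastq_pairs(reads, os.path.join(outdir, "reads_1.fq"),
                      os.path.join(outdir, "reads_2.fq"))
    if decoys:
        write_fasta(decoys, os.path.join(outdir, "decoys.fasta"))
    write_hits_table(hom, os.path.join(outdir, "hits.tsv"))
    write_cm_table(trna, os.path.join(outdir, "trna.tsv"))
    write_cm_table(rrna, os.path.join(outdir, "rrna.tsv"))
    write_taxonomy(TAXONOMY_ROWS, os.path.join(outdir, "taxa.tsv"))
    all_depths = {truth.genome.id: config.depth, **depths}
    write_depths(all_depths, os.path.join(outdir, "depths.tsv"))
    refs.to_tsv(os.path.join(outdir, "gene_lengths.tsv"))
    write_fasta(
        [SeqRecord(id=g, sequence=s) for g, s in
         sorted(truth.gene_sequences.items())],
        os.path.join(outdir, "genes.fasta"),
    )
    return {
        "truth": truth, "reads": reads, "decoys": decoys,
        "decoy_infos": infos, "depths": all_depths, "refs": refs,
        "hits": hom, "trna": trna, "rrna": rrna,
    }
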