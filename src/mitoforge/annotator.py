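"""Gene annotation for candidate mitochondrial sequences.

Protein-coding genes (PCGs) are located from protein-vs-nucleotide
homology hits: hits for the same gene and strand are clustered into
loci, the reading frame is anchored by the hit's protein coordinates,
and start/stop codons are refined at codon resolution under the chosen
mitochondrial genetic code. Mitochondrial CDSs frequently end on a bare
``T`` or ``TA`` that is completed to a TAA stop by 3' polyadenylation of
the mRNA; such truncated stops are recognised when they abut the next
feature (or the sequence end) in frame.

tRNA and rRNA features come from covariance-model hit tables and are
filtered (tRNA e-value <= 0.001 by default) and deduplicated here. A
putative control region is called only when the full gene complement
(13 PCGs, 22 tRNAs, 2 rRNAs) is recovered in full and the largest
remaining intergenic interval is at least 600 bp.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from Bio.Data import CodonTable

from .io_formats import (
    CMHit,
    FormatError,
    GeneAnnotation,
    HomologyHit,
    PCG_NAMES,
    RRNA_NAMES,
    TRNA_NAMES,
    revcomp,
)

DEFAULT_TRNA_EVALUE_CUTOFF = 1e-3
CONTROL_REGION_MIN_LEN = 600
BOUNDARY_SCAN_WINDOW = 60  # nt scanned either side when refining codons

# Start/stop codon sets per mitochondrial translation table. The codon ->
# amino-acid maps come from Biopython's NCBI tables; the start/stop sets
# below are the conventional ones for animal mitogenomes.
_START_SETS = {
    2: {"ATG", "ATA", "GTG"},
    5: {"ATG", "ATA", "ATT", "ATC", "GTG", "TTG"},
}
_STOP_SETS = {
    2: {"TAA", "TAG", "AGA", "AGG"},
    5: {"TAA", "TAG"},
}


class GeneticCode:
    """Mitochondrial genetic code: 2 = vertebrate, 5 = invertebrate."""

    def __init__(self, table_id: int):
        if table_id not in (2, 5):
            raise ValueError(f"unsupported genetic code table {table_id}")
        self.table_id = table_id
        ncbi = CodonTable.unambiguous_dna_by_id[table_id]
        self.codon_map = dict(ncbi.forward_table)
        for stop in ncbi.stop_codons:
            self.codon_map[stop] = "*"
        self.start_codons = frozenset(_START_SETS[table_id])
        self.stop_codons = frozenset(_STOP_SETS[table_id])

    def translate(self, codon: str) -> str:
        if codon in self.stop_codons:
            return "*"
        return self.codon_map.get(codon, "X")

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def is_start(self, codon: str) -> bool:
        return codon in self.start_codons


class ReferenceGeneTable:
    """Minimum reference length per gene: amino acids for the 13 PCGs,
    nucleotides for the two rRNAs."""

    def __init__(self, min_lengths: dict[str, int]):
        missing = set(PCG_NAMES) - set(min_lengths)
        missing |= set(RRNA_NAMES) - set(min_lengths)
        if missing:
            raise FormatError(
                f"reference table missing genes: {sorted(missing)}"
            )
        if any(v <= 0 for v in min_lengths.values()):
            raise FormatError("reference lengths must be positive")
        self.min_lengths = dict(min_lengths)

    def __getitem__(self, gene: str) -> int:
        return self.min_lengths[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.min_lengths

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "ReferenceGeneTable":
        df = pd.read_csv(str(path), sep="\t", header=None, dtype=str)
        return cls({r[0]: int(r[1]) for r in df.itertuples(index=False)})

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as out:
            for gene, n in self.min_lengths.items():
                out.write(f"{gene}\t{n}\n")


@dataclass
class Locus:
    """A clustered homology locus for one gene on one strand.

    Coordinates are 0-based half-open on the candidate sequence.
    """

    gene: str
    seq_id: str
    strand: str
    start: int
    end: int
    representative: HomologyHit
    hits: list[HomologyHit] = field(default_factory=list)

    @property
    def total_bitscore(self) -> float:
        return sum(h.bitscore for h in self.hits)


def cluster_hits(hits: Sequence[HomologyHit], merge_gap: int = 30) -> list[Locus]:
    """Merge hits for one query into per-gene loci.

    Hits for the same gene on the same strand whose query intervals
    overlap or lie within ``merge_gap`` bp are merged into one locus
    spanning their union; the lowest-evalue (tie: highest bitscore) hit
    becomes the representative. Distinct genes never merge.
    """
    by_key: dict[tuple[str, str, str], list[HomologyHit]] = {}
    for h in hits:
        by_key.setdefault((h.query_id, h.subject_gene, h.strand), []).append(h)
    loci: list[Locus] = []
    for (qid, gene, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: (h.query_start, h.query_end))
        current: list[HomologyHit] = []
        end = -10 ** 9
        for h in group + [None]:  # sentinel flushes the last cluster
            if h is not None and (not current or h.query_start - 1 <= end + merge_gap):
                current.append(h)
                end = max(end, h.query_end)
                continue
            if current:
                rep = min(current, key=lambda x: (x.evalue, -x.bitscore))
                loci.append(Locus(
                    gene=gene, seq_id=qid, strand=strand,
                    start=min(x.query_start for x in current) - 1,
                    end=max(x.query_end for x in current),
                    representative=rep, hits=list(current),
                ))
            if h is not None:
                current = [h]
                end = h.query_end
    loci.sort(key=lambda l: (l.seq_id, l.start, l.gene))
    return loci


def resolve_strand_conflicts(loci: Sequence[Locus]) -> list[Locus]:
    """When one gene has overlapping loci on both strands of the same
    sequence, keep the strand with the higher summed bitscore."""
    out = list(loci)
    doomed: set[int] = set()
    for i, a in enumerate(out):
        for j in range(i + 1, len(out)):
            b = out[j]
            if (a.seq_id != b.seq_id or a.gene != b.gene
                    or a.strand == b.strand):
                continue
            if a.start < b.end and b.start < a.end:
                loser = j if a.total_bitscore >= b.total_bitscore else i
                doomed.add(loser)
    return [l for i, l in enumerate(out) if i not in doomed]


def _first_inframe_at_or_after(pos: int, anchor: int) -> int:
    """Smallest position >= pos congruent to anchor modulo 3."""
    return pos + (anchor - pos) % 3


def _refine_forward(
    seq: str,
    anchor: int,
    locus_end: int,
    code: GeneticCode,
    downstream_limit: Optional[int],
) -> tuple[int, int, str, str, bool]:
    """Codon-level refinement on the forward strand.

    ``anchor`` is the expected 0-based position of codon 1, derived from
    the representative hit's protein coordinates. Returns
    (start, end, start_status, stop_status, invalid).
    """
    L = len(seq)
    limit = L if downstream_limit is None else min(downstream_limit, L)
    if anchor < 0:
        anchor %= 3  # first in-frame position inside the sequence

    start = None
    start_status = "canonical"
    # outward (upstream) first, then inward (downstream)
    for d in range(0, BOUNDARY_SCAN_WINDOW + 1, 3):
        p = anchor - d
        if p < 0:
            break
        if code.is_start(seq[p:p + 3]):
            start = p
            break
    if start is None:
        for d in range(3, BOUNDARY_SCAN_WINDOW + 1, 3):
            p = anchor + d
            if p + 3 > locus_end:
                break
            if code.is_start(seq[p:p + 3]):
                start = p
                break
    if start is None:
        start = max(anchor, anchor % 3)
        start_status = "missing"

    # stop: nearest in-frame stop codon scanning downstream from the
    # locus end, allowing it to begin just inside the hit (protein hits
    # exclude the stop codon itself)
    stop_status = "missing"
    end = None
    lo = _first_inframe_at_or_after(max(start + 3, locus_end - 3), start)
    p = lo
    while p + 3 <= min(locus_end + BOUNDARY_SCAN_WINDOW, limit, L):
        if code.is_stop(seq[p:p + 3]):
            end = p + 3
            stop_status = "complete"
            break
        p += 3
    if end is None:
        # truncated stop abutting the downstream boundary
        b = limit
        p = start + 3 * ((b - start) // 3)
        rem = b - p
        if rem == 2 and seq[p:p + 2] == "TA":
            end = p + 2
            stop_status = "truncated_TA"
        elif rem == 1 and seq[p:p + 1] == "T":
            end = p + 1
            stop_status = "truncated_T"
        else:
            end = max(start + 3, _first_inframe_at_or_after(locus_end - 2, start))
            end = min(end, L)
            stop_status = "missing"

    # interior stops before the chosen stop invalidate the annotation
    invalid = False
    last_full = end - 3 if stop_status == "complete" else end
    p = start
    while p + 3 <= last_full:
        if code.is_stop(seq[p:p + 3]):
            invalid = True
            break
        p += 3
    return start, end, start_status, stop_status, invalid


def refine_boundaries(
    locus: Locus,
    sequence: str,
    code: GeneticCode,
    downstream_limit: Optional[int] = None,
) -> GeneAnnotation:
    """Determine precise start/stop codons for a PCG locus.

    The reading frame is anchored by the representative hit's protein
    coordinates. The start codon is searched in frame up to 60 nt
    upstream (outward) of the expected codon-1 position, then downstream
    (inward); the stop codon is searched in frame up to 60 nt downstream
    of the locus end. Failing a standard stop, a final in-frame ``TA`` or
    ``T`` immediately abutting ``downstream_limit`` (next feature start
    or sequence end) is accepted as a polyadenylation-completed stop.
    Minus-strand loci are refined on the reverse complement and mapped
    back.
    """
    L = len(sequence)
    if locus.start < 0 or locus.end > L:
        raise ValueError(
            f"{locus.gene}: locus [{locus.start},{locus.end}) outside "
            f"sequence of length {L}"
        )
    rep = locus.representative
    if locus.strand == "+":
        anchor = (rep.query_start - 1) - 3 * (rep.subject_start - 1)
        start, end, ss, ts, invalid = _refine_forward(
            sequence, anchor, locus.end, code, downstream_limit,
        )
    else:
        rc = revcomp(sequence)
        # on the reverse complement the protein N-terminus maps to the
        # hit's query_end
        anchor = (L - rep.query_end) - 3 * (rep.subject_start - 1)
        s2, e2, ss, ts, invalid = _refine_forward(
            rc, anchor, L - locus.start, code, downstream_limit,
        )
        start, end = L - e2, L - s2
    return GeneAnnotation(
        gene=locus.gene, seq_id=locus.seq_id, start=start, end=end,
        strand=locus.strand, kind="PCG",
        start_status=ss, stop_status=ts, invalid=invalid,
        evalue=locus.representative.evalue,
    )


def compute_completeness(
    annotation: GeneAnnotation, refs: ReferenceGeneTable
) -> float:
    """Completeness C of a gene: annotated length over the shortest
    reference counterpart, as a percentage capped at 100.

    PCG lengths are measured in codons (a truncated stop counts as one
    codon) against the reference amino-acid length; rRNAs in nucleotides.
    tRNA completeness is presence-based (100 when annotated).
    """
    if annotation.kind == "tRNA":
        return 100.0
    if annotation.gene not in refs:
        raise KeyError(f"no reference length for gene {annotation.gene!r}")
    ref_len = refs[annotation.gene]
    if annotation.kind == "PCG":
        units = math.ceil(annotation.length / 3)
    else:
        units = annotation.length
    return min(100.0, 100.0 * units / ref_len)


def integrate_cm_hits(
    trna_hits: Sequence[CMHit],
    rrna_hits: Sequence[CMHit],
    evalue_cutoff: float = DEFAULT_TRNA_EVALUE_CUTOFF,
) -> list[GeneAnnotation]:
    """Turn covariance-model hit tables into tRNA/rRNA annotations.

    tRNA hits above the e-value cutoff are dropped (<= is kept). Per
    feature per sequence only the best-evalue hit survives. rRNA hits
    from the global search mode are preferred; local-mode hits are used
    only when no global hit exists for that feature on that sequence.
    """
    out: list[GeneAnnotation] = []

    kept_trna = [h for h in trna_hits if h.evalue <= evalue_cutoff]
    best: dict[tuple[str, str], CMHit] = {}
    for h in kept_trna:
        key = (h.query_id, h.feature)
        if key not in best or (h.evalue, -h.score) < (best[key].evalue, -best[key].score):
            best[key] = h
    for (qid, feat), h in sorted(best.items()):
        out.append(GeneAnnotation(
            gene=feat, seq_id=qid, start=h.start - 1, end=h.end,
            strand=h.strand, kind="tRNA", completeness=100.0,
            evalue=h.evalue,
        ))

    by_feat: dict[tuple[str, str], list[CMHit]] = {}
    for h in rrna_hits:
        by_feat.setdefault((h.query_id, h.feature), []).append(h)
    for (qid, feat), group in sorted(by_feat.items()):
        global_hits = [h for h in group if h.mode == "global"]
        pool = global_hits if global_hits else group
        h = min(pool, key=lambda x: (x.evalue, -x.score))
        out.append(GeneAnnotation(
            gene=feat, seq_id=qid, start=h.start - 1, end=h.end,
            strand=h.strand, kind="rRNA", evalue=h.evalue,
        ))
    return out


def call_control_region(
    annotations: Sequence[GeneAnnotation],
    sequence: str,
    refs: ReferenceGeneTable,
    circular: bool = False,
    min_length: int = CONTROL_REGION_MIN_LEN,
) -> Optional[GeneAnnotation]:
    """Call the putative control region (D-loop).

    Emitted only when all 13 PCGs and both rRNAs are annotated at
    completeness 100 and all 22 tRNAs are present, and the largest
    inter-feature interval (wrapping the origin when the sequence is
    circular) is at least ``min_length`` bp. A control region spanning
    the origin is reported by its longer arc.
    """
    anns = [a for a in annotations if a.kind != "control_region"]
    pcgs = {a.gene for a in anns if a.kind == "PCG" and a.completeness >= 100.0}
    rrnas = {a.gene for a in anns if a.kind == "rRNA" and a.completeness >= 100.0}
    trnas = {a.gene for a in anns if a.kind == "tRNA"}
    if pcgs != set(PCG_NAMES) or rrnas != set(RRNA_NAMES) or trnas != set(TRNA_NAMES):
        return None

    L = len(sequence)
    ivs = sorted((a.start, a.end) for a in anns)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    gaps: list[tuple[int, int, int]] = []  # (length, start, end)
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        gaps.append((s2 - e1, e1, s2))
    first_s, last_e = merged[0][0], merged[-1][1]
    if circular:
        gaps.append(((L - last_e) + first_s, last_e, first_s))  # wraps origin
    else:
        if first_s > 0:
            gaps.append((first_s, 0, first_s))
        if last_e < L:
            gaps.append((L - last_e, last_e, L))
    if not gaps:
        return None
    glen, gs, ge = max(gaps, key=lambda g: (g[0], -g[1]))
    if glen < min_length:
        return None
    if circular and ge <= gs:  # wrapped: report the longer arc
        arc1 = (gs, L)
        arc2 = (0, ge)
        gs, ge = max((arc1, arc2), key=lambda a: a[1] - a[0])
        if ge <= gs:
            return None
    seq_id = anns[0].seq_id
    return GeneAnnotation(
        gene="control_region", seq_id=seq_id, start=gs, end=ge,
        strand="+", kind="control_region", completeness=100.0,
    )


def annotate_sequence(
    record,
    hits: Sequence[HomologyHit],
    trna_hits: Sequence[CMHit],
    rrna_hits: Sequence[CMHit],
    code: GeneticCode,
    refs: ReferenceGeneTable,
    circular: bool = False,
    trna_evalue_cutoff: float = DEFAULT_TRNA_EVALUE_CUTOFF,
) -> list[GeneAnnotation]:
    """Full annotation of one candidate sequence.

    Order of operations: CM features first (they bound truncated stops),
    then PCG loci clustered, strand-resolved and codon-refined, then
    completeness, then the control region.
    """
    seq = record.sequence
    my_hits = [h for h in hits if h.query_id == record.id]
    my_trna = [h for h in trna_hits if h.query_id == record.id]
    my_rrna = [h for h in rrna_hits if h.query_id == record.id]

    cm_anns = integrate_cm_hits(my_trna, my_rrna, trna_evalue_cutoff)
    for a in cm_anns:
        if a.kind == "rRNA":
            a.completeness = compute_completeness(a, refs)

    loci = resolve_strand_conflicts(cluster_hits(my_hits))
    boundaries = sorted(
        {a.start for a in cm_anns} | {a.end for a in cm_anns}
        | {l.start for l in loci} | {l.end for l in loci}
    )
    pcg_anns: list[GeneAnnotation] = []
    for locus in loci:
        # the locus's own boundaries must not cap its stop search, hence
        # the strict comparisons
        if locus.strand == "+":
            nxt = [b for b in boundaries if b > locus.end]
            limit = min(nxt) if nxt else None
        else:
            L = len(seq)
            prev = [b for b in boundaries if b < locus.start]
            limit = (L - max(prev)) if prev else None
        ann = refine_boundaries(locus, seq, code, downstream_limit=limit)
        ann.completeness = compute_completeness(ann, refs)
        pcg_anns.append(ann)

    # drop overlapping duplicate annotations of the same gene (keep the
    # more complete, then lower-evalue one)
    pcg_anns.sort(key=lambda a: (-a.completeness, a.evalue or 0.0))
    final_pcgs: list[GeneAnnotation] = []
    for a in pcg_anns:
        clash = any(
            b.gene == a.gene and a.start < b.end and b.start < a.end
            for b in final_pcgs
        )
        if not clash:
            final_pcgs.append(a)

    anns = sorted(final_pcgs + cm_anns, key=lambda a: (a.start, a.end))
    cr = call_control_region(anns, seq, refs, circular=circular)
    if cr is not None:
        anns.append(cr)
        anns.sort(key=lambda a: (a.start, a.end))
    return anns
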