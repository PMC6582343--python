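"""Readers and writers for the external formats the toolkit touches.

Internal coordinates are 0-based half-open throughout the package; every
file-facing function converts to/from the 1-based inclusive convention of
GFF3 and BLAST tabular output.

Formats handled here:

* FASTA / FASTQ (phred+33) via Biopython;
* a 14-column homology hit table: the standard 12-column BLAST tabular
  layout extended with ``subject_gene`` and ``subject_taxon`` columns
  (the protein reference set knows the gene identity and source taxon of
  every subject, so the hits carry them);
* covariance-model hit tables for tRNA/rRNA features
  (``query_id  feature  start  end  strand  evalue  score  [mode]``);
* a taxonomy lineage table (``taxon_id  name  rank  parent_id``);
* GFF3 with feature types gene/CDS/tRNA/rRNA/D_loop.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

PCG_NAMES = (
    "ATP6", "ATP8", "COX1", "COX2", "COX3", "CYTB",
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
)

TRNA_NAMES = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)

RRNA_NAMES = ("rrn12", "rrn16")

RANKS = ("species", "genus", "family", "order", "class", "phylum", "kingdom")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SeqRecord:
    """A named uppercase DNA sequence over {A,C,G,T,N}."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.sequence:
            raise FormatError(f"empty sequence for record {self.id!r}")
        seq = self.sequence.upper().replace("U", "T")
        if set(seq) - set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise FormatError(f"record {self.id!r}: invalid characters {bad}")
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_COMP)[::-1]


@dataclass
class HomologyHit:
    """One protein-vs-nucleotide homology hit (BLAST-tabular dialect).

    Query coordinates are 1-based inclusive nucleotide positions on the
    candidate sequence, already normalized so ``query_start <= query_end``;
    the original coordinate order is preserved as ``strand``. Subject
    coordinates are 1-based inclusive amino-acid positions on the
    reference protein.
    """

    query_id: str
    subject_gene: str
    subject_taxon: str
    percent_identity: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.subject_gene not in PCG_NAMES:
            raise FormatError(f"unknown PCG name {self.subject_gene!r}")
        if self.query_start > self.query_end:
            self.query_start, self.query_end = self.query_end, self.query_start
            self.strand = "-"
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r}")
        if self.evalue < 0 or self.bitscore < 0:
            raise FormatError("negative evalue/bitscore")


@dataclass
class CMHit:
    """A covariance-model hit (tRNA or rRNA feature) on a candidate sequence."""

    query_id: str
    feature: str
    start: int
    end: int
    strand: str
    evalue: float
    score: float
    mode: str = "global"

    def __post_init__(self) -> None:
        if self.feature not in TRNA_NAMES + RRNA_NAMES:
            raise FormatError(f"unknown CM feature {self.feature!r}")
        if self.start > self.end:
            raise FormatError(f"CM hit start > end for {self.feature}")
        if self.evalue < 0:
            raise FormatError("negative evalue")
        if self.mode not in ("global", "local"):
            raise FormatError(f"bad CM search mode {self.mode!r}")


@dataclass
class GeneAnnotation:
    """One located gene feature.

    ``start``/``end`` are 0-based half-open on ``seq_id``; writers convert.
    ``completeness`` is the percentage C of annotated length over the
    shortest reference counterpart, capped at 100.
    """

    gene: str
    seq_id: str
    start: int
    end: int
    strand: str
    kind: str  # PCG | tRNA | rRNA | control_region
    completeness: float = 0.0
    start_status: str = "canonical"   # canonical | missing
    stop_status: str = "complete"     # complete | truncated_TA | truncated_T | missing
    evalue: Optional[float] = None
    invalid: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene}: empty or inverted interval")
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"{self.gene}: completeness outside [0,100]")

    @property
    def length(self) -> int:
        return self.end - self.start


class TaxonomyTable:
    """A rank-labelled lineage tree keyed by taxon id."""

    def __init__(self, entries: Sequence[tuple[str, str, str, str]]):
        self.name: dict[str, str] = {}
        self.rank: dict[str, str] = {}
        self.parent: dict[str, str] = {}
        for taxon_id, name, rank, parent_id in entries:
            if rank not in RANKS:
                raise FormatError(f"unknown rank {rank!r} for taxon {taxon_id}")
            self.name[taxon_id] = name
            self.rank[taxon_id] = rank
            self.parent[taxon_id] = parent_id
        roots = [t for t, p in self.parent.items() if p in ("", "-", t)]
        if len(roots) != 1:
            raise FormatError(f"taxonomy must have exactly one root, found {roots}")
        self.root = roots[0]
        for t, p in self.parent.items():
            if t != self.root and p not in self.name:
                raise FormatError(f"taxon {t}: unresolvable parent {p!r}")

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.name

    def lineage(self, taxon_id: str) -> list[str]:
        """Taxon ids from ``taxon_id`` up to the root, inclusive."""
        if taxon_id not in self.name:
            raise KeyError(f"taxon {taxon_id!r} not in taxonomy")
        out = [taxon_id]
        while out[-1] != self.root:
            out.append(self.parent[out[-1]])
        return out

    def find_by_name(self, name: str, rank: str) -> Optional[str]:
        for t, n in self.name.items():
            if n == name and self.rank[t] == rank:
                return t
        return None


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Read a FASTA file into validated records (uppercased, U->T)."""
    records = [
        SeqRecord(id=r.id, sequence=str(r.seq), description=r.description)
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate record ids {dup}")
    return records


def write_fasta(records: Sequence[SeqRecord], path: str | os.PathLike) -> None:
    bio = [
        BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_fastq_pairs(
    path1: str | os.PathLike, path2: Optional[str | os.PathLike] = None
) -> Iterator["ReadPair"]:
    """Yield mate pairs from two phred+33 FASTQ files (or single reads if
    ``path2`` is None), in file order.

    Raises a pairing error when the two files hold different record counts.
    """
    from .readqc import Read, ReadPair  # local import to avoid a cycle

    it1 = SeqIO.parse(str(path1), "fastq")
    if path2 is None:
        for r in it1:
            yield ReadPair(
                read1=Read(r.id, str(r.seq).upper(),
                           list(r.letter_annotations["phred_quality"]))
            )
        return
    it2 = SeqIO.parse(str(path2), "fastq")
    sentinel = object()
    while True:
        r1 = next(it1, sentinel)
        r2 = next(it2, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        if r1 is sentinel or r2 is sentinel:
            raise FormatError(
                f"mate files {path1} / {path2} differ in record count"
            )
        yield ReadPair(
            read1=Read(r1.id, str(r1.seq).upper(),
                       list(r1.letter_annotations["phred_quality"])),
            read2=Read(r2.id, str(r2.seq).upper(),
                       list(r2.letter_annotations["phred_quality"])),
        )


def write_fastq_pairs(pairs, path1, path2) -> None:
    """Write mate pairs back to two phred+33 FASTQ files."""
    def _bio(read):
        rec = BioSeqRecord(Seq(read.sequence), id=read.id, description="")
        rec.letter_annotations["phred_quality"] = list(read.qualities)
        return rec

    with open(path1, "w") as h1, open(path2, "w") as h2:
        for p in pairs:
            SeqIO.write([_bio(p.read1)], h1, "fastq")
            if p.read2 is not None:
                SeqIO.write([_bio(p.read2)], h2, "fastq")


# ---------------------------------------------------------------------------
# Hit tables

_HIT_COLUMNS = [
    "query_id", "subject_gene", "subject_taxon", "percent_identity",
    "alignment_length", "mismatches", "gap_opens",
    "query_start", "query_end", "subject_start", "subject_end",
    "evalue", "bitscore", "strand_hint",
]


def read_hits_table(path: str | os.PathLike) -> list[HomologyHit]:
    """Read the 14-column homology hit table.

    Layout: BLAST outfmt-6's 12 columns with ``subject_gene`` and
    ``subject_taxon`` inserted after ``query_id``. Strand is inferred from
    the query coordinate order (reversed coordinates mean the minus
    strand) and coordinates are normalized so query_start <= query_end.
    """
    try:
        df = pd.read_csv(str(path), sep="\t", header=None, comment="#",
                         dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 14:
        raise FormatError(
            f"{path}: expected 14 tab-separated columns, found {df.shape[1]}"
        )
    df.columns = _HIT_COLUMNS
    hits = []
    for row in df.itertuples(index=False):
        try:
            hits.append(HomologyHit(
                query_id=row.query_id,
                subject_gene=row.subject_gene,
                subject_taxon=row.subject_taxon,
                percent_identity=float(row.percent_identity),
                query_start=int(row.query_start),
                query_end=int(row.query_end),
                subject_start=int(row.subject_start),
                subject_end=int(row.subject_end),
                evalue=float(row.evalue),
                bitscore=float(row.bitscore),
            ))
        except (TypeError, ValueError) as exc:
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{path}: malformed hit row {tuple(row)!r}") from exc
    return hits


def write_hits_table(hits: Sequence[HomologyHit], path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        for h in hits:
            qs, qe = (h.query_start, h.query_end)
            if h.strand == "-":
                qs, qe = qe, qs
            aln_len = h.query_end - h.query_start + 1
            out.write("\t".join(map(str, [
                h.query_id, h.subject_gene, h.subject_taxon,
                f"{h.percent_identity:.2f}", aln_len, 0, 0,
                qs, qe, h.subject_start, h.subject_end,
                f"{h.evalue:.3g}", f"{h.bitscore:.1f}", h.strand,
            ])) + "\n")


def read_cm_table(path: str | os.PathLike) -> list[CMHit]:
    """Read a covariance-model hit table (tRNA or rRNA).

    Columns: query_id, feature, start, end, strand, evalue, score and an
    optional eighth column giving the search mode (global/local; rRNA
    searches fall back to local mode when the global pass finds nothing).
    """
    try:
        df = pd.read_csv(str(path), sep="\t", header=None, comment="#",
                         dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] not in (7, 8):
        raise FormatError(f"{path}: expected 7 or 8 columns, got {df.shape[1]}")
    hits = []
    for row in df.itertuples(index=False):
        try:
            hits.append(CMHit(
                query_id=row[0], feature=row[1],
                start=int(row[2]), end=int(row[3]), strand=row[4],
                evalue=float(row[5]), score=float(row[6]),
                mode=row[7] if df.shape[1] == 8 else "global",
            ))
        except (TypeError, ValueError) as exc:
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{path}: malformed CM row {tuple(row)!r}") from exc
    return hits


def write_cm_table(hits: Sequence[CMHit], path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        for h in hits:
            out.write("\t".join(map(str, [
                h.query_id, h.feature, h.start, h.end, h.strand,
                f"{h.evalue:.3g}", f"{h.score:.1f}", h.mode,
            ])) + "\n")


def read_taxonomy(path: str | os.PathLike) -> TaxonomyTable:
    """Read the 4-column lineage table: taxon_id, name, rank, parent_id."""
    df = pd.read_csv(str(path), sep="\t", header=None, dtype=str,
                     keep_default_na=False)
    if df.shape[1] != 4:
        raise FormatError(f"{path}: taxonomy table needs 4 columns")
    return TaxonomyTable([tuple(r) for r in df.itertuples(index=False)])


def write_taxonomy(entries, path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        for e in entries:
            out.write("\t".join(e) + "\n")


def read_depths(path: str | os.PathLike) -> dict[str, float]:
    """Read per-sequence mean depth (seq_id <tab> depth)."""
    df = pd.read_csv(str(path), sep="\t", header=None, dtype=str)
    return {r[0]: float(r[1]) for r in df.itertuples(index=False)}


def write_depths(depths: dict[str, float], path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        for sid, d in depths.items():
            out.write(f"{sid}\t{d:.2f}\n")


# ---------------------------------------------------------------------------
# GFF3

_KIND_TO_SO = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
               "control_region": "D_loop"}
_SO_TO_KIND = {v: k for k, v in _KIND_TO_SO.items()}


def write_gff3(
    annotations: Sequence[GeneAnnotation],
    path: str | os.PathLike,
    seq_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write annotations as GFF3 (gene parent + typed child per feature).

    Coordinates are converted from the internal 0-based half-open
    representation to 1-based inclusive. When ``seq_lengths`` is given,
    features outside their sequence raise a validation error and
    ``##sequence-region`` pragmas are emitted.
    """
    lines = ["##gff-version 3"]
    if seq_lengths:
        for sid, length in seq_lengths.items():
            lines.append(f"##sequence-region {sid} 1 {length}")
    for i, a in enumerate(annotations):
        if seq_lengths and a.seq_id in seq_lengths:
            if a.end > seq_lengths[a.seq_id] or a.start < 0:
                raise ValueError(
                    f"{a.gene}: [{a.start},{a.end}) outside {a.seq_id} "
                    f"(length {seq_lengths[a.seq_id]})"
                )
        start1, end1 = a.start + 1, a.end
        gid = f"gene{i}_{a.gene}"
        attrs = [f"ID={gid}", f"Name={a.gene}"]
        lines.append("\t".join([
            a.seq_id, "mitoforge", "gene", str(start1), str(end1),
            ".", a.strand, ".", ";".join(attrs),
        ]))
        child_attrs = [
            f"ID={gid}.t", f"Parent={gid}", f"gene={a.gene}",
            f"completeness={a.completeness:.4g}",
            f"start_status={a.start_status}",
            f"stop_status={a.stop_status}",
        ]
        if a.stop_status in ("truncated_TA", "truncated_T"):
            child_attrs.append("incomplete_stop=true")
        if a.evalue is not None:
            child_attrs.append(f"evalue={a.evalue:.3g}")
        if a.invalid:
            child_attrs.append("invalid=true")
        phase = "0" if a.kind == "PCG" else "."
        lines.append("\t".join([
            a.seq_id, "mitoforge", _KIND_TO_SO[a.kind], str(start1),
            str(end1), ".", a.strand, phase, ";".join(child_attrs),
        ]))
    with open(path, "w") as out:
        out.write("\n".join(lines) + "\n")


def read_gff3(path: str | os.PathLike) -> list[GeneAnnotation]:
    """Read back annotations written by :func:`write_gff3`."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    out = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in _SO_TO_KIND:
            continue
        attrs = feat.attributes
        out.append(GeneAnnotation(
            gene=attrs["gene"][0],
            seq_id=feat.seqid,
            start=feat.start - 1,
            end=feat.end,
            strand=feat.strand,
            kind=_SO_TO_KIND[feat.featuretype],
            completeness=float(attrs.get("completeness", ["0"])[0]),
            start_status=attrs.get("start_status", ["canonical"])[0],
            stop_status=attrs.get("stop_status", ["complete"])[0],
            evalue=float(attrs["evalue"][0]) if "evalue" in attrs else None,
            invalid=attrs.get("invalid", ["false"])[0] == "true",
        ))
    return out
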