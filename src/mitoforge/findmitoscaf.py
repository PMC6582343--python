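"""Identify mitochondrial sequences among mixed contigs and pick the
final scaffold set.

Candidates are assigned a taxon from their best protein homologs, then
filtered against a user-required clade (order/family/genus). Each
survivor gets a confident score

    S_j = A * sum_i C_i

where A is the assembly reliability (mean k-mer/edge coverage for native
contigs, a user-supplied mean mapped depth for external assemblies) and
C_i is the completeness percentage of the i-th protein-coding gene on
the sequence. Selection walks candidates by descending score, accepting
the top sequence and skipping any later sequence that carries a gene
already recovered complete; sequences whose copy of a gene is complete
where the previously accepted copy was incomplete replace that copy.
The search stops once all 13 PCGs are located complete or candidates run
out. Independently of conflicts, any candidate bearing at least 5 PCGs
is flagged for retention so its identity can be confirmed downstream
(e.g. parasite or contaminant genomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io_formats import (
    GeneAnnotation,
    HomologyHit,
    PCG_NAMES,
    SeqRecord,
    TaxonomyTable,
)


class ConfigurationError(ValueError):
    pass


@dataclass
class ScaffoldCandidate:
    record: SeqRecord
    annotations: list[GeneAnnotation] = field(default_factory=list)
    reliability: float = 1.0            # the weight factor A
    assigned_taxon: Optional[str] = None

    @property
    def pcg_annotations(self) -> list[GeneAnnotation]:
        return [a for a in self.annotations if a.kind == "PCG"]

    @property
    def pcg_genes(self) -> dict[str, float]:
        """gene -> best completeness among this candidate's PCG copies."""
        out: dict[str, float] = {}
        for a in self.pcg_annotations:
            out[a.gene] = max(out.get(a.gene, 0.0), a.completeness)
        return out

    @property
    def score(self) -> float:
        return confident_score(self)


@dataclass
class SelectionConfig:
    required_taxon: Optional[str] = None
    required_rank: str = "order"
    pcg_target: int = 13
    retain_min_pcgs: int = 5

    def __post_init__(self) -> None:
        if self.required_rank not in ("order", "family", "genus"):
            raise ConfigurationError(
                f"required_rank must be order/family/genus, got "
                f"{self.required_rank!r}"
            )
        if self.retain_min_pcgs < 1:
            raise ConfigurationError("retain_min_pcgs must be >= 1")


@dataclass
class Decision:
    seq_id: str
    action: str     # accept | skip | demote | reject_rank | reject_unassigned
    reason: str = ""


@dataclass
class SelectionResult:
    selected: list[ScaffoldCandidate] = field(default_factory=list)
    genes_found: dict[str, tuple[str, float]] = field(default_factory=dict)
    retained_extra: list[ScaffoldCandidate] = field(default_factory=list)
    skipped: list[Decision] = field(default_factory=list)
    log: list[Decision] = field(default_factory=list)


def confident_score(candidate: ScaffoldCandidate) -> float:
    """S_j = A * sum of PCG completeness percentages (tRNA/rRNA excluded)."""
    if candidate.reliability <= 0:
        raise ValueError(
            f"{candidate.record.id}: reliability A must be positive"
        )
    pcgs = candidate.pcg_annotations
    if not pcgs:
        return 0.0
    return candidate.reliability * sum(a.completeness for a in pcgs)


def assign_taxon(
    candidate: ScaffoldCandidate,
    hits: Sequence[HomologyHit],
    taxonomy: TaxonomyTable,
) -> Optional[str]:
    """Majority vote over the best hit per PCG locus; ties broken by the
    highest summed bitscore; no PCG hits -> None."""
    from .annotator import cluster_hits

    my_hits = [h for h in hits if h.query_id == candidate.record.id]
    loci = cluster_hits(my_hits)
    if not loci:
        return None
    votes: dict[str, int] = {}
    weight: dict[str, float] = {}
    for locus in loci:
        taxon = locus.representative.subject_taxon
        if taxon not in taxonomy:
            raise KeyError(
                f"hit taxon {taxon!r} absent from the taxonomy table"
            )
        votes[taxon] = votes.get(taxon, 0) + 1
        weight[taxon] = weight.get(taxon, 0.0) + locus.total_bitscore
    return max(votes, key=lambda t: (votes[t], weight[t], t))


def filter_by_rank(
    candidates: Sequence[ScaffoldCandidate],
    config: SelectionConfig,
    taxonomy: TaxonomyTable,
) -> tuple[list[ScaffoldCandidate], list[Decision]]:
    """Keep candidates whose lineage passes through the required taxon at
    the required rank; unassigned candidates are rejected."""
    if config.required_taxon is None:
        return list(candidates), []
    req_id = taxonomy.find_by_name(config.required_taxon, config.required_rank)
    if req_id is None and config.required_taxon in taxonomy:
        req_id = config.required_taxon  # allow passing a taxon id directly
    if req_id is None:
        raise ConfigurationError(
            f"required taxon {config.required_taxon!r} at rank "
            f"{config.required_rank!r} not found in the taxonomy"
        )
    kept: list[ScaffoldCandidate] = []
    rejected: list[Decision] = []
    for c in candidates:
        if c.assigned_taxon is None:
            rejected.append(Decision(c.record.id, "reject_unassigned",
                                     "no PCG homology, taxon unassigned"))
        elif req_id in taxonomy.lineage(c.assigned_taxon):
            kept.append(c)
        else:
            rejected.append(Decision(
                c.record.id, "reject_rank",
                f"assigned taxon {c.assigned_taxon} outside "
                f"{config.required_taxon} ({config.required_rank})",
            ))
    return kept, rejected


def _rank_key(c: ScaffoldCandidate):
    # descending score, ties: longer sequence first, then id
    return (-c.score, -len(c.record.sequence), c.record.id)


def select_scaffolds(
    candidates: Sequence[ScaffoldCandidate],
    config: Optional[SelectionConfig] = None,
) -> SelectionResult:
    """Conflict-aware greedy selection over score-ranked candidates."""
    config = config or SelectionConfig()
    result = SelectionResult()
    ranked = sorted(candidates, key=_rank_key)

    for c in ranked:
        if len(c.pcg_genes) >= config.retain_min_pcgs:
            result.retained_extra.append(c)

    def _n_complete() -> int:
        return sum(1 for _, comp in result.genes_found.values()
                   if comp >= 100.0)

    done = False
    for c in ranked:
        if done:
            result.skipped.append(Decision(
                c.record.id, "skip", "search already complete"))
            result.log.append(result.skipped[-1])
            continue
        genes = c.pcg_genes
        if not genes:
            result.skipped.append(Decision(
                c.record.id, "skip", "no PCG annotations"))
            result.log.append(result.skipped[-1])
            continue
        if not result.selected:
            result.selected.append(c)
            for g, comp in genes.items():
                result.genes_found[g] = (c.record.id, comp)
            result.log.append(Decision(
                c.record.id, "accept", "highest confident score"))
        else:
            conflict_complete = [
                g for g in genes
                if g in result.genes_found
                and result.genes_found[g][1] >= 100.0
            ]
            if conflict_complete:
                d = Decision(
                    c.record.id, "skip",
                    "carries gene(s) already complete: "
                    + ",".join(sorted(conflict_complete)),
                )
                result.skipped.append(d)
                result.log.append(d)
                continue
            result.selected.append(c)
            for g, comp in genes.items():
                prior = result.genes_found.get(g)
                if prior is None or comp > prior[1]:
                    if prior is not None and comp >= 100.0 > prior[1]:
                        result.log.append(Decision(
                            c.record.id, "demote",
                            f"complete {g} replaces incomplete copy on "
                            f"{prior[0]}",
                        ))
                    result.genes_found[g] = (c.record.id, comp)
            result.log.append(Decision(
                c.record.id, "accept",
                "contributes genes: " + ",".join(sorted(genes))))
        if _n_complete() >= config.pcg_target:
            done = True
            result.log.append(Decision(
                c.record.id, "stop",
                f"all {config.pcg_target} PCGs located complete"))
    return result


def build_candidates(
    records: Sequence[SeqRecord],
    annotations: Sequence[GeneAnnotation],
    hits: Sequence[HomologyHit],
    taxonomy: Optional[TaxonomyTable],
    depths: Optional[dict[str, float]] = None,
) -> list[ScaffoldCandidate]:
    """Assemble ScaffoldCandidate objects from per-sequence pieces.

    Reliability A comes from ``depths`` (mean edge coverage for native
    contigs, mean mapped depth for external assemblies); sequences
    missing from the table default to A=1.
    """
    by_seq: dict[str, list[GeneAnnotation]] = {}
    for a in annotations:
        by_seq.setdefault(a.seq_id, []).append(a)
    out = []
    for rec in records:
        c = ScaffoldCandidate(
            record=rec,
            annotations=by_seq.get(rec.id, []),
            reliability=(depths or {}).get(rec.id, 1.0),
        )
        if taxonomy is not None:
            c.assigned_taxon = assign_taxon(c, hits, taxonomy)
        out.append(c)
    return out
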