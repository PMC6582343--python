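"""Minimal de Bruijn contig assembler for mitogenome-scale read sets.

The graph uses canonical (strand-merged) k-mers: every edge is stored
once under the lexicographic minimum of the k-mer and its reverse
complement, and adjacency is resolved in both orientations during
traversal. k is required to be odd, so no k-mer is its own reverse
complement.

Error removal follows the strategies standard in coverage-based contig
assembly: low-frequency k-mers are dropped outright, edges much weaker
than their neighbours are removed by a relative (percentage) threshold
computed from adjacent graph elements, and short weak dead-end paths
(tips) are clipped. Assembly stops at contigs; no scaffolding is done.

Two orchestration modes exist: quick mode assembles with the single
k-mer size 71, multi-kmer mode runs a ladder of k values and pools the
contigs, dropping any contig fully contained in a longer one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean
from typing import Iterable, Optional, Sequence

import edlib

from .io_formats import revcomp

DEFAULT_QUICK_K = 71
DEFAULT_MULTI_KS = (31, 51, 71, 91)
DEFAULT_MIN_KMER_FREQ = 2
DEFAULT_PRUNE_FRACTION = 0.05
DEFAULT_MIN_CONTIG_LEN = 200


class ParameterError(ValueError):
    pass


@dataclass
class KmerTable:
    k: int
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class Contig:
    id: str
    sequence: str
    mean_edge_coverage: float
    k_used: int
    circular: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


class DBGraph:
    """Canonical-k-mer de Bruijn graph with per-edge coverage."""

    def __init__(self, k: int, edges: Optional[dict[str, float]] = None):
        self.k = k
        # canonical k-mer -> coverage
        self.edges: dict[str, float] = dict(edges or {})
        self._out: Optional[dict[str, list[str]]] = None

    def copy(self) -> "DBGraph":
        return DBGraph(self.k, self.edges)

    def __len__(self) -> int:
        return len(self.edges)

    # -- adjacency -----------------------------------------------------

    def _adjacency(self) -> dict[str, list[str]]:
        """Map from (k-1)-mer node to oriented k-mers leaving it."""
        if self._out is None:
            out: dict[str, list[str]] = {}
            for e in self.edges:
                for w in (e, revcomp(e)):
                    out.setdefault(w[:-1], []).append(w)
            for v in out.values():
                v.sort()
            self._out = out
        return self._out

    def out_edges(self, node: str) -> list[str]:
        return self._adjacency().get(node, [])

    def in_edges(self, node: str) -> list[str]:
        # an edge entering `node` is an edge leaving revcomp(node),
        # read in the opposite orientation
        return [revcomp(w) for w in self._adjacency().get(revcomp(node), [])]

    def coverage(self, oriented_kmer: str) -> float:
        return self.edges[canonical(oriented_kmer)]

    def incident_edges(self, node: str) -> set[str]:
        """Canonical edges touching the junction that `node` represents."""
        inc = {canonical(w) for w in self.out_edges(node)}
        inc |= {canonical(w) for w in self.in_edges(node)}
        return inc

    def remove_edges(self, canon_kmers: Iterable[str]) -> None:
        for e in canon_kmers:
            self.edges.pop(e, None)
        self._out = None


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _check_k(k: int, reads: Optional[Sequence[str]] = None) -> None:
    if k % 2 == 0 or not 15 <= k <= 127:
        raise ParameterError(f"k must be odd and in [15,127], got {k}")
    if reads is not None:
        min_len = min((len(r) for r in reads), default=0)
        if k >= min_len:
            raise ParameterError(
                f"k={k} is not below the minimum read length {min_len}"
            )


def count_kmers(reads: Iterable[str], k: int) -> KmerTable:
    """Count canonical k-mers over all reads; windows containing N are
    skipped."""
    if k % 2 == 0 or not 15 <= k <= 127:
        raise ParameterError(f"k must be odd and in [15,127], got {k}")
    counts: dict[str, int] = {}
    for seq in reads:
        L = len(seq)
        if L < k:
            continue
        rc = revcomp(seq)
        if "N" in seq:
            npos = [i for i, c in enumerate(seq) if c == "N"]
            j = 0
            for i in range(L - k + 1):
                while j < len(npos) and npos[j] < i:
                    j += 1
                if j < len(npos) and npos[j] < i + k:
                    continue
                f = seq[i:i + k]
                r = rc[L - k - i:L - i]
                key = f if f <= r else r
                counts[key] = counts.get(key, 0) + 1
        else:
            for i in range(L - k + 1):
                f = seq[i:i + k]
                r = rc[L - k - i:L - i]
                key = f if f <= r else r
                counts[key] = counts.get(key, 0) + 1
    return KmerTable(k=k, counts=counts)


def build_graph(table: KmerTable, min_kmer_freq: int = DEFAULT_MIN_KMER_FREQ) -> DBGraph:
    """Drop k-mers below the absolute frequency cutoff and build the graph."""
    if min_kmer_freq < 1:
        raise ParameterError("min_kmer_freq must be >= 1")
    edges = {km: c for km, c in table.counts.items() if c >= min_kmer_freq}
    return DBGraph(table.k, edges)


def prune_relative(graph: DBGraph, fraction: float = DEFAULT_PRUNE_FRACTION) -> DBGraph:
    """Relative-coverage filtration of edges.

    An edge is removed when its coverage is strictly below ``fraction``
    times the maximum coverage among edges sharing either of its endpoint
    junctions (itself included, so an isolated edge is never removed).
    Applied iteratively to a fixpoint.
    """
    if not 0.0 < fraction < 1.0:
        raise ParameterError("fraction must be in (0,1)")
    g = graph.copy()
    while True:
        doomed = []
        for e, cov in g.edges.items():
            neighbours = g.incident_edges(e[:-1]) | g.incident_edges(e[1:])
            m = max(g.edges[n] for n in neighbours)
            if cov < fraction * m:
                doomed.append(e)
        if not doomed:
            return g
        g.remove_edges(doomed)


def clip_tips(graph: DBGraph, max_tip_len: Optional[int] = None) -> DBGraph:
    """Remove short weak dead-end paths.

    A tip is an unbranched path starting at a node with no incoming
    edges. It is clipped when its sequence length is below
    ``max_tip_len`` (default 2k) and the coverage of its junction-side
    edge is strictly below the strongest other edge at the junction it
    attaches to; an exact tie keeps both branches. Iterates to fixpoint.
    """
    if max_tip_len is None:
        max_tip_len = 2 * graph.k
    if max_tip_len < graph.k:
        raise ParameterError("max_tip_len must be >= k")
    g = graph.copy()
    while True:
        clipped: set[str] = set()
        for e in sorted(g.edges):
            for w in (e, revcomp(e)):
                if g.in_edges(w[:-1]):
                    continue
                # walk forward through unbranched nodes
                path = [w]
                while True:
                    s = path[-1][1:]
                    outs = g.out_edges(s)
                    if len(outs) != 1 or len(g.in_edges(s)) != 1:
                        break
                    if canonical(outs[0]) in {canonical(p) for p in path}:
                        break  # closed a cycle; not a tip
                    path.append(outs[0])
                    if len(path) + g.k - 1 >= max_tip_len:
                        break
                tip_len = len(path) + g.k - 1
                if tip_len >= max_tip_len:
                    continue
                junction = path[-1][1:]
                path_canon = {canonical(p) for p in path}
                others = (g.incident_edges(junction)) - path_canon
                if not others:
                    continue  # isolated linear piece, not a tip
                if g.edges[canonical(path[-1])] < max(g.edges[o] for o in others):
                    clipped |= path_canon
        if not clipped:
            return g
        g.remove_edges(clipped)


def assemble_contigs(graph: DBGraph) -> list[Contig]:
    """Extract maximal unbranched paths as contigs.

    Traversal starts from canonical edges in lexicographic order, so the
    output is deterministic. An unbranched cycle (the expected shape for
    a clean circular mitogenome) is emitted as a rotation of the circle
    with the k-1 duplicated terminal bases stripped.
    """
    k = graph.k
    visited: set[str] = set()
    contigs: list[Contig] = []

    def _through(node: str) -> bool:
        return (len(graph.out_edges(node)) == 1
                and len(graph.in_edges(node)) == 1)

    for start in sorted(graph.edges):
        if start in visited:
            continue
        path = [start]
        visited.add(start)
        circular = False
        # forward
        while True:
            s = path[-1][1:]
            if not _through(s):
                break
            nxt = graph.out_edges(s)[0]
            if canonical(nxt) in visited:
                circular = (nxt == path[0])
                break
            path.append(nxt)
            visited.add(canonical(nxt))
        # backward
        if not circular:
            while True:
                p = path[0][:-1]
                if not _through(p):
                    break
                prv = graph.in_edges(p)[0]
                if canonical(prv) in visited:
                    break
                path.insert(0, prv)
                visited.add(canonical(prv))
        # a path that returns to its own start node traversed the whole
        # circle even if a residual branch at that junction prevented the
        # clean cycle closure above
        if (not circular and len(path) > 2
                and path[0][:-1] == path[-1][1:]):
            circular = True
        seq = path[0] + "".join(w[-1] for w in path[1:])
        if circular:
            seq = seq[:len(path)]  # strip the k-1 wrap-around overlap
        else:
            seq = min(seq, revcomp(seq))
        cov = mean(graph.edges[canonical(w)] for w in path)
        contigs.append(Contig(
            id=f"contig{len(contigs) + 1}",
            sequence=seq,
            mean_edge_coverage=cov,
            k_used=k,
            circular=circular,
        ))
    # stable, deterministic ordering: longest first, then sequence
    contigs.sort(key=lambda c: (-len(c.sequence), c.sequence))
    for i, c in enumerate(contigs, 1):
        c.id = f"contig{i}"
    return contigs


def _contained(shorter: Contig, longer: Contig, min_identity: float = 0.99) -> bool:
    """Is `shorter` contained in `longer` at >= min_identity over its full
    length (either strand)?"""
    max_dist = int((1.0 - min_identity) * len(shorter.sequence))
    target = longer.sequence + (longer.sequence[:len(shorter.sequence)]
                                if longer.circular else "")
    for q in (shorter.sequence, revcomp(shorter.sequence)):
        res = edlib.align(q, target, mode="HW", task="distance", k=max_dist)
        if res["editDistance"] != -1:
            return True
    return False


def assemble_for_k(
    reads: Sequence[str],
    k: int,
    min_kmer_freq: int = DEFAULT_MIN_KMER_FREQ,
    prune_fraction: float = DEFAULT_PRUNE_FRACTION,
    max_tip_len: Optional[int] = None,
    min_contig_len: int = DEFAULT_MIN_CONTIG_LEN,
) -> list[Contig]:
    """Single-k pipeline: count -> filter -> prune -> clip -> contigs."""
    _check_k(k, reads)
    table = count_kmers(reads, k)
    graph = build_graph(table, min_kmer_freq)
    graph = prune_relative(graph, prune_fraction)
    graph = clip_tips(graph, max_tip_len)
    contigs = assemble_contigs(graph)
    # very short leftovers (isolated error islands) carry no signal
    min_len = max(k, min_contig_len)
    return [c for c in contigs if len(c.sequence) >= min_len]


def assemble(
    reads: Sequence[str],
    mode: str = "quick",
    kmer_list: Optional[Sequence[int]] = None,
    min_kmer_freq: int = DEFAULT_MIN_KMER_FREQ,
    prune_fraction: float = DEFAULT_PRUNE_FRACTION,
) -> list[Contig]:
    """Assemble reads in quick mode (k=71 only) or multi-kmer mode.

    Multi-kmer mode runs every usable k in the list, pools the contigs
    and drops any contig fully contained (>= 99% identity over its whole
    length) in a longer contig from the pool.
    """
    if mode not in ("quick", "multi"):
        raise ParameterError(f"mode must be 'quick' or 'multi', got {mode!r}")
    min_len = min((len(r) for r in reads), default=0)
    if mode == "quick":
        ks: list[int] = [DEFAULT_QUICK_K] if kmer_list is None else list(kmer_list)[:1]
    else:
        ks = list(kmer_list) if kmer_list is not None else list(DEFAULT_MULTI_KS)
        ks = [k for k in ks if k < min_len]
    if not ks or all(k >= min_len for k in ks):
        raise ParameterError(
            f"no usable k below the minimum read length ({min_len})"
        )
    pooled: list[Contig] = []
    for k in ks:
        pooled.extend(assemble_for_k(reads, k, min_kmer_freq, prune_fraction))
    if mode == "quick" or len(ks) == 1:
        for i, c in enumerate(sorted(pooled, key=lambda c: (-len(c), c.sequence)), 1):
            c.id = f"contig{i}"
        return sorted(pooled, key=lambda c: (-len(c), c.sequence))
    pooled.sort(key=lambda c: (-len(c.sequence), c.sequence, c.k_used))
    kept: list[Contig] = []
    for c in pooled:
        if any(_contained(c, longer) for longer in kept):
            continue
        kept.append(c)
    for i, c in enumerate(kept, 1):
        c.id = f"contig{i}"
    return kept
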