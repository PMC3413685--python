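"""De Bruijn graph assembly at a single odd k, with isotig generation.

Nodes are canonical k-mers (lexicographic minimum of a k-mer and its
reverse complement; k must be odd so no k-mer is its own reverse
complement).  Contigs are maximal unbranched paths; isotigs are
source-to-sink paths through the contig-adjacency graph, enumerated up
to a configurable cap and ranked by mean k-mer coverage, so a two-branch
bubble yields two isotigs in one isogroup.  The whole construction is
independent of read input order and strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ACGT = frozenset("ACGT")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class Contig:
    contig_id: str
    sequence: str  # canonical orientation (min of seq, revcomp)
    mean_kmer_coverage: float
    origin_k: int

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Isotig:
    isotig_id: str
    sequence: str
    isogroup_id: str
    origin_k: int

    def __len__(self) -> int:
        return len(self.sequence)


class DeBruijnGraph:
    """Canonical k-mer multiset with implied (k-1)-overlap adjacency."""

    def __init__(self, k: int):
        if k % 2 == 0:
            raise ValueError(f"k must be odd (got {k}): canonical k-mers require it")
        if k < 3:
            raise ValueError("k too small")
        self.k = k
        self.counts: dict[str, int] = {}

    def add_sequence(self, seq: str) -> None:
        k = self.k
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if not _ACGT.issuperset(kmer):
                continue
            c = canonical(kmer)
            self.counts[c] = self.counts.get(c, 0) + 1

    def __len__(self) -> int:
        return len(self.counts)

    def successors(self, oriented_kmer: str, nodes: set[str]) -> list[str]:
        """Oriented k-mers reachable by shifting one base right."""
        suffix = oriented_kmer[1:]
        return [suffix + b for b in "ACGT" if canonical(suffix + b) in nodes]

    def predecessors(self, oriented_kmer: str, nodes: set[str]) -> list[str]:
        prefix = oriented_kmer[:-1]
        return [b + prefix for b in "ACGT" if canonical(b + prefix) in nodes]


def build_graph(reads: Iterable, k: int) -> DeBruijnGraph:
    """Count canonical k-mers over reads (strings or objects with ``bases``).

    The result is identical for any permutation of the reads and for
    reads replaced by their reverse complements.
    """
    graph = DeBruijnGraph(k)
    for read in reads:
        seq = read if isinstance(read, str) else read.bases
        graph.add_sequence(seq)
    return graph


def extract_contigs(graph: DeBruijnGraph, min_count: int = 1) -> list[Contig]:
    """Maximal unbranched paths, each reported once in canonical orientation.

    k-mers with count < ``min_count`` are pruned first.  Iteration order
    is over sorted k-mers, so output is deterministic.
    """
    nodes = {km for km, c in graph.counts.items() if c >= min_count}
    visited: set[str] = set()
    contigs: list[Contig] = []

    def is_unbranched_junction(cur: str, nxt: str) -> bool:
        # extendable iff cur has exactly one successor and that successor
        # has exactly one predecessor
        return (
            len(graph.successors(cur, nodes)) == 1
            and len(graph.predecessors(nxt, nodes)) == 1
        )

    for start in sorted(nodes):
        if start in visited:
            continue
        # walk right then left from the start k-mer in its stored orientation
        path = [start]
        member = {start}
        cur = start
        while True:
            succ = graph.successors(cur, nodes)
            if len(succ) != 1:
                break
            nxt = succ[0]
            cn = canonical(nxt)
            if cn in member or cn in visited or len(graph.predecessors(nxt, nodes)) != 1:
                break
            path.append(nxt)
            member.add(cn)
            cur = nxt
        cur = start
        while True:
            pred = graph.predecessors(cur, nodes)
            if len(pred) != 1:
                break
            prv = pred[0]
            cp = canonical(prv)
            if cp in member or cp in visited or len(graph.successors(prv, nodes)) != 1:
                break
            path.insert(0, prv)
            member.add(cp)
            cur = prv
        visited |= member
        seq = path[0] + "".join(p[-1] for p in path[1:])
        seq = min(seq, revcomp(seq))
        cov = sum(graph.counts[canonical(p)] for p in path) / len(path)
        contigs.append(Contig("", seq, cov, graph.k))
    contigs.sort(key=lambda c: (-len(c.sequence), c.sequence))
    for i, c in enumerate(contigs, 1):
        c.contig_id = f"k{graph.k}_contig_{i}"
    return contigs


# ---------------------------------------------------------------------------
# Isotig construction


def _contig_digraph(contigs: list[Contig], k: int) -> nx.DiGraph:
    """Doubled digraph over oriented contigs: node (i, +1)/(i, -1); edge
    when the (k-1)-suffix of one oriented contig equals the (k-1)-prefix
    of the next (the node-centric de Bruijn adjacency)."""
    g = nx.DiGraph()
    by_prefix: dict[str, list[tuple[int, int]]] = {}
    oriented: dict[tuple[int, int], str] = {}
    for i, c in enumerate(contigs):
        for o in (1, -1):
            s = c.sequence if o == 1 else revcomp(c.sequence)
            oriented[(i, o)] = s
            g.add_node((i, o))
            by_prefix.setdefault(s[: k - 1], []).append((i, o))
    for u, s in oriented.items():
        for v in by_prefix.get(s[-(k - 1):], ()):
            if v[0] == u[0]:
                continue  # no self-loops through a contig's own mirror
            g.add_edge(u, v)
    return g


def build_isotigs(
    graph: DeBruijnGraph,
    contigs: list[Contig],
    read_pairs=None,
    max_paths: int = 16,
    min_length: int = 0,
) -> tuple[list[Isotig], dict[str, str]]:
    """Enumerate isotigs (transcript variants) per isogroup.

    An isogroup is a connected component of the contig graph.  Isotigs
    are the distinct source-to-sink paths of the component, ranked by
    length-weighted mean k-mer coverage and capped at ``max_paths`` (a
    warning is emitted when the cap truncates).  ``read_pairs`` is
    accepted for interface compatibility (pairing-aware ranking is not
    used by the bounded enumeration).

    Returns (isotigs, isotig_id -> isogroup_id map).
    """
    k = graph.k
    dg = _contig_digraph(contigs, k)
    undirected = nx.Graph()
    undirected.add_nodes_from(range(len(contigs)))
    for (i, _), (j, _) in dg.edges:
        undirected.add_edge(i, j)
    components = sorted(nx.connected_components(undirected), key=lambda c: sorted(c)[0])

    isotigs: list[Isotig] = []
    isogroup_of: dict[str, str] = {}
    for gi, comp in enumerate(components, 1):
        isogroup_id = f"k{k}_Locus_{gi}"
        comp_nodes = {(i, o) for i in comp for o in (1, -1)}
        sub = dg.subgraph(comp_nodes)
        sources = sorted(n for n in comp_nodes if sub.in_degree(n) == 0)
        sinks = {n for n in comp_nodes if sub.out_degree(n) == 0}
        paths: list[list[tuple[int, int]]] = []
        truncated = False
        budget = max(64, 8 * max_paths)

        def dfs(node, acc, used):
            nonlocal truncated
            if len(paths) >= budget:
                truncated = True
                return
            if node in sinks:
                paths.append(acc[:])
                return
            for nxt in sorted(sub.successors(node)):
                if nxt[0] in used:
                    continue
                acc.append(nxt)
                used.add(nxt[0])
                dfs(nxt, acc, used)
                acc.pop()
                used.discard(nxt[0])

        if sources:
            for s in sources:
                dfs(s, [s], {s[0]})
        else:
            # cyclic component: fall back to the contigs themselves
            paths = [[(i, 1)] for i in sorted(comp)]

        def path_seq(path) -> str:
            parts = []
            for i, o in path:
                s = contigs[i].sequence if o == 1 else revcomp(contigs[i].sequence)
                parts.append(s if not parts else s[k - 1 :])
            return "".join(parts)

        def path_cov(path) -> float:
            num = sum(contigs[i].mean_kmer_coverage * len(contigs[i]) for i, _ in path)
            den = sum(len(contigs[i]) for i, _ in path)
            return num / den

        seen: dict[str, tuple[float, str]] = {}
        for p in paths:
            s = path_seq(p)
            key = min(s, revcomp(s))  # a path and its mirror are one isotig
            if key not in seen:
                seen[key] = (path_cov(p), s)
        ranked = sorted(seen.values(), key=lambda t: (-t[0], t[1]))
        if truncated or len(ranked) > max_paths:
            warnings.warn(
                f"{isogroup_id}: path enumeration capped at {max_paths} "
                f"(component has more variants)",
                stacklevel=2,
            )
        for j, (cov, s) in enumerate(ranked[:max_paths], 1):
            if len(s) < min_length:
                continue
            iid = f"{isogroup_id}.{j}"
            isotigs.append(Isotig(iid, s, isogroup_id, k))
            isogroup_of[iid] = isogroup_id
    return isotigs, isogroup_of


# ---------------------------------------------------------------------------
# Assembly statistics


def n50(lengths: list[int]) -> int:
    """Largest L such that sequences of length >= L hold half of all bases."""
    if not lengths:
        return 0
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if 2 * acc >= total:
            return L
    return 0


def assembly_stats(sequences: Iterable[str]) -> dict[str, int]:
    """Summary table: min/max/2nd/3rd longest, total, average (floor),
    N50 and counts above 0/100/500/1000 bp."""
    lengths = sorted((len(s) for s in sequences), reverse=True)
    if not lengths:
        return {key: 0 for key in (
            "min_length", "max_length", "second_longest", "third_longest",
            "total_length", "avg_length", "n50",
            "count_gt_0", "count_gt_100", "count_gt_500", "count_gt_1000",
        )}
    return {
        "min_length": lengths[-1],
        "max_length": lengths[0],
        "second_longest": lengths[1] if len(lengths) > 1 else lengths[0],
        "third_longest": lengths[2] if len(lengths) > 2 else lengths[-1],
        "total_length": sum(lengths),
        "avg_length": sum(lengths) // len(lengths),
        "n50": n50(lengths),
        "count_gt_0": len(lengths),
        "count_gt_100": sum(1 for L in lengths if L > 100),
        "count_gt_500": sum(1 for L in lengths if L > 500),
        "count_gt_1000": sum(1 for L in lengths if L > 1000),
    }
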