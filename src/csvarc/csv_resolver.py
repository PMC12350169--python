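"""Complex-SV resolution via a variant-scored DAG over alignment records.

Alignment records of one query are the nodes; a directed edge a -> b exists
when b starts at or after a's query end (within a small slack) and carries
the variants implied by that junction.  Edges cost a junction-opening penalty
plus a per-variant cost; traversing a node earns a credit proportional to its
matched bases, so paths that explain more of the query through real alignment
beat paths that hide it inside large indels.  The graph is acyclic by
construction, so the minimum-cost source-to-sink path is found by single-pass
relaxation in topological order, in O(N + E); a literal Bellman-Ford mode is
provided for cross-checking.  Variants on the optimal path are accepted, and
runs with more than one repair junction are named by their ordered token
signature (e.g. DEL-INV-DEL).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .align_variants import (
    call_inter_alignment,
    call_intra_alignment,
    filter_excluded_regions,
    pair_variants,
    trim_query_overlaps,
)
from .records import (
    AlignmentRecord,
    CSVCall,
    IntervalAnnotation,
    VariantCall,
)

logger = logging.getLogger(__name__)


@dataclass
class ResolverParams:
    """Tunable scoring for anchor selection and path adjudication.

    junction_open      cost of opening a junction (one per path edge)
    variant_base_cost  flat cost per variant on an edge or node
    variant_log_scale  additional cost log10(1 + length) / variant_log_scale
    match_weight       credit per '=' base of a traversed record
    anchor_min_len     minimum aligned length for an anchor record
    anchor_min_identity minimum '='-fraction for an anchor record
    query_slack        allowed query overlap (bp) when creating an edge
    bellman_ford       use literal Bellman-Ford relaxation rounds
    """

    junction_open: float = 1.0
    variant_base_cost: float = 0.1
    variant_log_scale: float = 10.0
    match_weight: float = 1e-3
    anchor_min_len: int = 1000
    anchor_min_identity: float = 0.9
    query_slack: int = 50
    bellman_ford: bool = False

    def variant_cost(self, v: VariantCall) -> float:
        return self.variant_base_cost + math.log10(1 + v.length) / self.variant_log_scale


@dataclass
class PathGraph:
    """DAG with alignment records as nodes and variants on the edges.

    Record nodes are 0..n-1 in query order; node n is the source and n+1 the
    sink.  Edges only advance in query coordinate, so the graph is acyclic.
    """

    records: list[AlignmentRecord]
    node_cost: list[float]
    edges: list[tuple[int, int, float, list[VariantCall]]]
    source: int
    sink: int
    adjacency: dict[int, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        self.adjacency = {}
        for idx, (u, v, _, _) in enumerate(self.edges):
            if v <= u and u != self.source:
                raise ValueError("edge does not advance in query order")
            self.adjacency.setdefault(u, []).append(idx)

    @property
    def n_nodes(self) -> int:
        return len(self.records) + 2


def select_anchors(
    records: Sequence[AlignmentRecord], params: Optional[ResolverParams] = None
) -> list[AlignmentRecord]:
    """Records long and clean enough to anchor a complex event."""
    params = params or ResolverParams()
    return [
        r
        for r in records
        if r.query_span >= params.anchor_min_len
        and r.aligned_identity >= params.anchor_min_identity
    ]


def build_variant_graph(
    records: Sequence[AlignmentRecord],
    intra_variants: dict[int, list[VariantCall]],
    inter_variants: dict[tuple[int, int], list[VariantCall]],
    params: Optional[ResolverParams] = None,
    anchors: Optional[Sequence[int]] = None,
) -> PathGraph:
    params = params or ResolverParams()
    recs = sorted(records, key=lambda r: (r.query_start, r.query_end))
    n = len(recs)
    source, sink = n, n + 1
    node_cost = []
    for i, r in enumerate(recs):
        cost = sum(params.variant_cost(v) for v in intra_variants.get(i, []))
        if r.strand == "-":
            # inverted record: its span is an inversion candidate on the path
            cost += params.variant_base_cost + math.log10(1 + r.target_span) / params.variant_log_scale
        cost -= params.match_weight * r.matches
        node_cost.append(cost)
    node_cost += [0.0, 0.0]
    if anchors is not None:
        anchor_idx = list(anchors)
    else:
        anchor_ids = {id(r) for r in select_anchors(recs, params)}
        anchor_idx = [i for i, r in enumerate(recs) if id(r) in anchor_ids]
    edges: list[tuple[int, int, float, list[VariantCall]]] = []
    for i in range(n):
        for j in range(i + 1, n):
            if (
                recs[i].target_name == recs[j].target_name
                and recs[j].query_start >= recs[i].query_end - params.query_slack
            ):
                variants = inter_variants.get((i, j), [])
                cost = params.junction_open + sum(params.variant_cost(v) for v in variants)
                edges.append((i, j, cost, variants))
    for i in anchor_idx:
        edges.append((source, i, 0.0, []))
        edges.append((i, sink, 0.0, []))
    return PathGraph(recs, node_cost, edges, source, sink)


@dataclass
class PathResult:
    path: list[int]  # record node indices, query order
    cost: float
    variants: list[VariantCall]  # node + edge variants along the path


def solve_optimal_path(
    graph: PathGraph,
    intra_variants: Optional[dict[int, list[VariantCall]]] = None,
    bellman_ford: bool = False,
) -> Optional[PathResult]:
    """Minimum-cost source-to-sink path of a variant DAG.

    Default is single-pass relaxation in topological order, O(N + E) in nodes
    and edges; ``bellman_ford=True`` runs literal |V|-1 relaxation rounds and
    gives the same answer (negative node credits are fine: the graph is
    acyclic).  Ties are broken toward fewer edges, then the lexicographically
    smallest node path.  Returns None when the sink is unreachable.
    """
    INF = (math.inf, math.inf, ())
    best: dict[int, tuple[float, int, tuple]] = {graph.source: (0.0, 0, ())}

    def relax(edge) -> bool:
        u, v, cost, _ = edge
        bu = best.get(u)
        if bu is None:
            return False
        cand = (bu[0] + cost + graph.node_cost[v] if v != graph.sink
                else bu[0] + cost,
                bu[1] + 1,
                bu[2] + ((v,) if v < len(graph.records) else ()))
        if cand < best.get(v, INF):
            best[v] = cand
            return True
        return False

    if bellman_ford:
        for _ in range(graph.n_nodes - 1):
            changed = False
            for e in graph.edges:
                changed |= relax(e)
            if not changed:
                break
    else:
        order = [graph.source] + list(range(len(graph.records))) + [graph.sink]
        for u in order:
            for eidx in graph.adjacency.get(u, []):
                relax(graph.edges[eidx])

    if graph.sink not in best:
        logger.info("sink unreachable: no path call")
        return None
    cost, _, path = best[graph.sink]
    variants: list[VariantCall] = []
    if intra_variants:
        for node in path:
            variants.extend(intra_variants.get(node, []))
    by_pair = {(u, v): vs for u, v, _, vs in graph.edges}
    for u, v in zip(path, path[1:]):
        variants.extend(by_pair.get((u, v), []))
    variants.sort(key=lambda v: (v.pos, v.end))
    return PathResult(list(path), cost, variants)


def classify_csv_signature(
    accepted: Sequence[VariantCall],
    junction_count: int,
    chrom: str = "",
    query_name: str = "",
    anchors: tuple = ((), ()),
) -> Optional[CSVCall]:
    """Name an accepted variant set; None means simple-variant passthrough.

    Tokens are the SV-class variants in target order, hyphen-joined.  An event
    spanning at most one repair junction is not complex.
    """
    svs = sorted((v for v in accepted if v.is_sv and v.vtype != "SNV"),
                 key=lambda v: (v.pos, v.end))
    for v in svs:
        if v.vtype not in ("INS", "DEL", "INV", "INVDUP", "DUP"):
            raise ValueError(f"unknown variant type {v.vtype}")
    if junction_count <= 1 or len(svs) < 2:
        return None
    chrom = chrom or svs[0].chrom
    return CSVCall(
        chrom=chrom,
        signature="-".join(v.vtype for v in svs),
        variants=list(accepted),
        anchors=anchors,
        span=(min(v.pos for v in svs), max(v.end for v in svs)),
        junction_count=junction_count,
        query_name=query_name or svs[0].query_name,
    )


@dataclass
class ResolveResult:
    csv_calls: list[CSVCall]
    simple_variants: list[VariantCall]
    dropped_csvs: list[CSVCall] = field(default_factory=list)


def resolve_complex(
    records: Sequence[AlignmentRecord],
    ref,
    query,
    exclusions: Optional[Iterable[IntervalAnnotation]] = None,
    params: Optional[ResolverParams] = None,
) -> ResolveResult:
    """Full pipeline: trim, score, solve the path, accept and name variants.

    Complex calls whose span intersects an exclusion interval (e.g.
    centromeric repeats) are eliminated; simple variants are filtered the
    same way.
    """
    params = params or ResolverParams()
    by_query: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        by_query.setdefault(r.query_name, []).append(r)
    exclusions = list(exclusions) if exclusions is not None else []
    csv_calls: list[CSVCall] = []
    dropped: list[CSVCall] = []
    simple: list[VariantCall] = []
    groups: list[tuple[str, list[AlignmentRecord]]] = []
    for qname, qrecs in sorted(by_query.items()):
        qrecs = trim_query_overlaps(qrecs)
        by_target: dict[str, list[AlignmentRecord]] = {}
        for r in qrecs:
            by_target.setdefault(r.target_name, []).append(r)
        groups.extend((qname, v) for _, v in sorted(by_target.items()))
    for qname, recs in groups:
        trimmed = sorted(recs, key=lambda r: (r.query_start, r.query_end))
        intra = {i: call_intra_alignment(r, ref, query) for i, r in enumerate(trimmed)}
        anchors = select_anchors(trimmed, params)
        if not anchors:
            logger.warning("query %s: no anchor records, event skipped", qname)
            continue
        inter: dict[tuple[int, int], list[VariantCall]] = {}
        for i in range(len(trimmed)):
            for j in range(i + 1, len(trimmed)):
                if trimmed[j].query_start >= trimmed[i].query_end - params.query_slack:
                    inter[(i, j)] = pair_variants(trimmed[i], trimmed[j], ref, query)
        graph = build_variant_graph(trimmed, intra, inter, params)
        result = solve_optimal_path(graph, intra, bellman_ford=params.bellman_ford)
        if result is None:
            continue
        path = result.path
        # intra-record variants are ordinary calls regardless of clustering
        path_simple: list[VariantCall] = []
        for i in path:
            path_simple.extend(intra.get(i, []))
        # candidate events live between plus-strand anchor records: cut the
        # path at those boundary nodes and treat each piece as one event
        anchor_ids = {id(r) for r in anchors}
        boundary = [
            k for k, i in enumerate(path)
            if trimmed[i].strand == "+" and id(trimmed[i]) in anchor_ids
        ]
        cuts = sorted({0, len(path) - 1, *boundary})
        segments = [
            path[a : b + 1] for a, b in zip(cuts, cuts[1:])
        ] or ([path] if len(path) > 1 else [])
        for seg in segments:
            if len(seg) < 2:
                continue
            seg_records = [trimmed[i] for i in seg]
            accepted = call_inter_alignment(seg_records, ref, query)
            junction_count = sum(
                1
                for u, v in zip(seg, seg[1:])
                if any(w.is_sv for w in inter.get((u, v), []))
            )
            anchor_spans = (
                (seg_records[0].target_start, seg_records[0].target_end),
                (seg_records[-1].target_start, seg_records[-1].target_end),
            )
            call = classify_csv_signature(
                accepted, junction_count, chrom=seg_records[0].target_name,
                query_name=qname, anchors=anchor_spans,
            )
            if call is not None:
                hits = [
                    a for a in exclusions
                    if a.chrom == call.chrom and a.overlaps(call.span[0], call.span[1])
                ]
                (dropped if hits else csv_calls).append(call)
            else:
                path_simple.extend(accepted)
        kept, _ = filter_excluded_regions(path_simple, exclusions)
        kept.sort(key=lambda v: (v.pos, v.end))
        simple.extend(kept)
    return ResolveResult(csv_calls, simple, dropped)
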