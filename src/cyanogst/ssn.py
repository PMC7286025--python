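"""Sequence similarity networks: all-vs-all alignment, thresholding, clusters.

Nodes are sequences; an edge is kept when the E-value of the global pairwise
alignment is at or below the threshold (default 1e-11, the strictest of the
thresholds used in the study; 1e-10 and 1e-5 reproduce its relaxed views).
Connected components approximate families; concordance summaries compare
components against class or catalytic-type labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from cyanogst import align as _align
from cyanogst.seqio import SequenceSet, ValidationError

#: E-value thresholds printed for the study's networks
DEFAULT_THRESHOLD = 1e-11
ALTERNATE_THRESHOLDS = (1e-11, 1e-10, 1e-5)


@dataclass
class SimilarityNetwork:
    """Undirected graph of sequences with bit-score/E-value edge attributes."""

    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def sorted_edges(self):
        """(a, b, bit_score) triples in deterministic lexicographic order."""
        out = []
        for a, b, data in self.graph.edges(data=True):
            x, y = sorted((a, b))
            out.append((x, y, data["bit_score"]))
        return sorted(out)


def build_network(
    seqs: SequenceSet,
    threshold: float = DEFAULT_THRESHOLD,
    matrix: dict | None = None,
    gap_open: float = _align.DEFAULT_GAP_OPEN,
    gap_extend: float = _align.DEFAULT_GAP_EXTEND,
    lam: float = _align.DEFAULT_LAMBDA,
    kappa: float = _align.DEFAULT_K,
) -> SimilarityNetwork:
    """All-vs-all global alignment; keep edges with E-value <= threshold."""
    if threshold <= 0:
        raise ValidationError("E-value threshold must be positive")
    records = list(seqs)
    if len(records) < 2:
        raise ValidationError("a network needs at least 2 sequences")
    matrix = matrix if matrix is not None else _align.default_matrix()
    g = nx.Graph()
    for rec in records:
        g.add_node(rec.id, order=rec.order_label)
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            raw = _align.align_score(a.residues, b.residues, matrix, gap_open, gap_extend)
            ev = _align.evalue(raw, len(a.residues), len(b.residues), lam, kappa)
            if ev <= threshold:
                g.add_edge(
                    a.id,
                    b.id,
                    raw_score=raw,
                    bit_score=_align.bit_score(raw, lam, kappa),
                    evalue=ev,
                )
    return SimilarityNetwork(graph=g, threshold=threshold)


def components(net: SimilarityNetwork) -> list[frozenset]:
    """Connected components by union-find, largest first (ties: min label)."""
    parent = {n: n for n in net.graph.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in net.graph.edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, set] = {}
    for node in net.graph.nodes:
        groups.setdefault(find(node), set()).add(node)
    comps = [frozenset(members) for members in groups.values()]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


@dataclass
class ConcordanceReport:
    """How well network components agree with external labels."""

    purity: dict[frozenset, float]
    majority_label: dict[frozenset, str]
    split_labels: dict[str, int] = field(default_factory=dict)  # label -> n comps
    merged_components: list[frozenset] = field(default_factory=list)

    @property
    def mean_purity(self) -> float:
        sizes = np.array([len(c) for c in self.purity])
        vals = np.array(list(self.purity.values()))
        return float((vals * sizes).sum() / sizes.sum())


def cluster_label_concordance(
    partition: list[frozenset], labels: dict[str, str]
) -> ConcordanceReport:
    """Per-component purity plus which labels are split or merged.

    Purity of a component is the fraction held by its most common label; a
    label spread over several components is "split"; a component holding
    several labels is "merged".
    """
    purity: dict[frozenset, float] = {}
    majority: dict[frozenset, str] = {}
    label_comps: dict[str, int] = {}
    merged: list[frozenset] = []
    for comp in partition:
        tally: dict[str, int] = {}
        for node in comp:
            if node not in labels:
                raise ValidationError(f"node {node!r} has no label")
            tally[labels[node]] = tally.get(labels[node], 0) + 1
        top = max(sorted(tally), key=lambda lab: tally[lab])
        purity[comp] = tally[top] / len(comp)
        majority[comp] = top
        for lab in tally:
            label_comps[lab] = label_comps.get(lab, 0) + 1
        if len(tally) > 1:
            merged.append(comp)
    split = {lab: n for lab, n in label_comps.items() if n > 1}
    return ConcordanceReport(
        purity=purity,
        majority_label=majority,
        split_labels=split,
        merged_components=merged,
    )
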