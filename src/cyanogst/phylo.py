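"""Multiple alignment, evolutionary distances, neighbor-joining and bootstrap.

Desk-scale phylogenetics for GST sequence sets: a center-star progressive
aligner ("once a gap, always a gap"), a gap-fraction column filter, pairwise
amino-acid distances (p, gamma-Poisson, or ML under JTT+Gamma with pairwise
deletion), between-order mean divergence, neighbor-joining with nonparametric
bootstrap support, and clade/monophyly queries.  Trees are held as dendropy
objects; the algorithms themselves are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from io import StringIO

import dendropy
import numpy as np
import pandas as pd

from cyanogst import align as _align
from cyanogst import jtt as _jtt
from cyanogst.seqio import ORDERS, SequenceSet, ValidationError

#: distances beyond this are reported as the cap and flagged as saturated
SATURATION_CAP = 10.0

#: default gap penalties for the progressive-alignment stage.  GST domains
#: align nearly end-to-end; a stiffer gap-open than the pairwise-scoring
#: default keeps twilight-zone pairs from scattering spurious gaps.
MSA_GAP_OPEN = 30.0
MSA_GAP_EXTEND = 1.0

GAP = "-"


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows keyed by sequence id (insertion-ordered)."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValidationError("an alignment needs at least 2 rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValidationError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def degapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace(GAP, "")

    def columns(self) -> np.ndarray:
        """Character matrix, shape (n_rows, n_columns)."""
        return np.array([list(s) for s in self.rows.values()])


def center_star_msa(
    seqs: SequenceSet,
    matrix: dict | None = None,
    gap_open: float = MSA_GAP_OPEN,
    gap_extend: float = MSA_GAP_EXTEND,
) -> MultipleAlignment:
    """Center-star progressive alignment.

    The center is the sequence maximising the total pairwise alignment score
    against all others (ties break to input order); every other sequence is
    pairwise-aligned to the center and merged under "once a gap, always a
    gap".  Deterministic given the inputs.
    """
    records = list(seqs)
    if len(records) < 2:
        raise ValidationError("center-star alignment needs at least 2 sequences")
    matrix = matrix if matrix is not None else _align.default_matrix()
    n = len(records)
    totals = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = _align.align_score(
                records[i].residues, records[j].residues, matrix, gap_open, gap_extend
            )
            totals[i] += s
            totals[j] += s
    center_idx = int(np.argmax(totals))
    center = records[center_idx]

    master = list(center.residues)  # center row, grows gaps as sequences merge
    aligned: dict[str, list[str]] = {center.id: list(center.residues)}
    order = [center.id]
    for rec in records:
        if rec.id == center.id:
            continue
        res = _align.global_align(
            center.residues, rec.residues, matrix, gap_open, gap_extend
        )
        ca, cs = res.aligned_a, res.aligned_b
        new_master: list[str] = []
        new_row: list[str] = []
        inserts: list[int] = []  # master-column insert points for existing rows
        im = ip = 0
        while im < len(master) or ip < len(ca):
            if im < len(master) and master[im] == GAP and (
                ip >= len(ca) or ca[ip] != GAP
            ):
                new_master.append(GAP)
                new_row.append(GAP)
                im += 1
            elif ip < len(ca) and ca[ip] == GAP:
                # the new pairwise alignment opens a gap in the center
                inserts.append(len(new_master))
                new_master.append(GAP)
                new_row.append(cs[ip])
                ip += 1
            else:
                new_master.append(master[im])
                new_row.append(cs[ip])
                im += 1
                ip += 1
        if inserts:
            for rid in order:
                row = aligned[rid]
                for k, pos in enumerate(inserts):
                    row.insert(pos, GAP)
        master = new_master
        aligned[rec.id] = new_row
        order.append(rec.id)

    by_input = {rec.id: "".join(aligned[rec.id]) for rec in records}
    return MultipleAlignment(by_input)


def trim_columns(msa: MultipleAlignment, max_gap_fraction: float) -> MultipleAlignment:
    """Drop columns whose gap fraction exceeds the threshold (order kept)."""
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValidationError("max_gap_fraction must lie in [0, 1]")
    cols = msa.columns()
    frac = (cols == GAP).mean(axis=0)
    keep = frac <= max_gap_fraction
    if not keep.any():
        raise ValidationError("column filter removed every column")
    kept = cols[:, keep]
    return MultipleAlignment(
        {rid: "".join(kept[k]) for k, rid in enumerate(msa.ids)}
    )


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal.

    ``capped`` flags label pairs whose estimate hit the saturation cap; ``se``
    holds standard errors when the method provides them.
    """

    labels: list[str]
    values: np.ndarray
    method: str = "p"
    alpha: float | None = None
    se: np.ndarray | None = None
    capped: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise ValidationError("distances must be non-negative")
        if not np.isfinite(v).all():
            raise ValidationError("distances must be finite (saturation is capped)")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(
            self.values[self.labels.index(a), self.labels.index(b)]
        )

    def to_tsv(self, path) -> None:
        """Labelled square TSV: lower triangle distances, upper triangle SEs."""
        n = len(self.labels)
        grid = [["" for _ in range(n)] for _ in range(n)]
        for i in range(n):
            for j in range(n):
                if i > j:
                    grid[i][j] = f"{self.values[i, j]:.4f}"
                elif i < j and self.se is not None:
                    grid[i][j] = f"{self.se[i, j]:.4f}"
        with open(path, "w") as fh:
            fh.write("label\t" + "\t".join(self.labels) + "\n")
            for i, lbl in enumerate(self.labels):
                fh.write(lbl + "\t" + "\t".join(grid[i]) + "\n")


def _encode_msa(msa: MultipleAlignment) -> np.ndarray:
    lut = np.full(128, -1, dtype=np.int8)
    for k, aa in enumerate(_jtt.AA_ORDER):
        lut[ord(aa)] = k
    mat = np.array(
        [np.frombuffer(s.encode(), dtype=np.uint8) for s in msa.rows.values()]
    )
    return lut[mat]


def gamma_poisson_distance(p: float, alpha: float) -> float:
    """Gamma-corrected Poisson distance ``alpha * ((1-p)^(-1/alpha) - 1)``."""
    if not 0.0 <= p < 1.0:
        return float("inf")
    return alpha * ((1.0 - p) ** (-1.0 / alpha) - 1.0)


def pairwise_distance(
    msa: MultipleAlignment,
    method: str = "gamma-poisson",
    alpha: float = 1.0,
    k: int = 4,
    cap: float = SATURATION_CAP,
) -> DistanceMatrix:
    """All-pairs distances with pairwise deletion (both residues standard).

    Methods: ``p`` (mismatch fraction), ``gamma-poisson`` (closed-form gamma
    rate correction, delta-method SE), ``ml-jtt-gamma`` (per-pair ML under
    JTT with k-category discrete gamma, curvature SE).  Estimates above
    ``cap`` are reported as the cap and flagged.
    """
    if method not in ("p", "gamma-poisson", "ml-jtt-gamma"):
        raise ValidationError(f"unknown distance method {method!r}")
    codes = _encode_msa(msa)
    labels = msa.ids
    n = len(labels)
    D = np.zeros((n, n))
    SE = np.zeros((n, n))
    capped: set[frozenset] = set()
    for i in range(n):
        for j in range(i + 1, n):
            both = (codes[i] >= 0) & (codes[j] >= 0)
            m = int(both.sum())
            if m == 0:
                raise ValidationError(
                    f"no pairwise-complete columns for {labels[i]}/{labels[j]}"
                )
            mism = int((codes[i][both] != codes[j][both]).sum())
            p = mism / m
            se_p = np.sqrt(p * (1.0 - p) / m)
            if method == "p":
                d, se = p, se_p
            elif method == "gamma-poisson":
                d = gamma_poisson_distance(p, alpha)
                se = (
                    (1.0 - p) ** (-1.0 / alpha - 1.0) * se_p
                    if p < 1.0
                    else float("nan")
                )
            else:
                ai = codes[i][both].astype(np.int64)
                bj = codes[j][both].astype(np.int64)
                counts = np.bincount(20 * ai + bj, minlength=400).reshape(20, 20)
                counts = (counts + counts.T) / 2.0  # symmetrise a,b roles
                d, se = _jtt.ml_distance(counts, alpha=alpha, k=k)
            if d > cap or not np.isfinite(d):
                d, se = cap, float("nan")
                capped.add(frozenset((labels[i], labels[j])))
            D[i, j] = D[j, i] = d
            SE[i, j] = SE[j, i] = se
    return DistanceMatrix(
        labels=labels,
        values=D,
        method=method,
        alpha=None if method == "p" else alpha,
        se=SE,
        capped=capped,
    )


def between_group_mean(dm: DistanceMatrix, groups: dict[str, str]) -> DistanceMatrix:
    """Arithmetic mean distance over all cross pairs of each group pair.

    The SE reported for a group pair is the standard error of its
    contributing pairwise distances.  Diagonal is zero by convention.
    """
    missing = [lbl for lbl in dm.labels if lbl not in groups]
    if missing:
        raise ValidationError(f"ungrouped labels: {missing[:5]}")
    seen: list[str] = []
    for lbl in dm.labels:
        g = groups[lbl]
        if g not in seen:
            seen.append(g)
    group_names = [o for o in ORDERS if o in seen] + [
        g for g in seen if g not in ORDERS
    ]
    idx = {g: [k for k, lbl in enumerate(dm.labels) if groups[lbl] == g] for g in group_names}
    for g, members in idx.items():
        if not members:
            raise ValidationError(f"empty group {g!r}")
    n = len(group_names)
    M = np.zeros((n, n))
    SE = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            block = dm.values[np.ix_(idx[group_names[a]], idx[group_names[b]])]
            vals = block.ravel()
            M[a, b] = M[b, a] = vals.mean()
            SE[a, b] = SE[b, a] = (
                vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
            )
    return DistanceMatrix(
        labels=group_names, values=M, method=dm.method, alpha=dm.alpha, se=SE
    )


def reference_divergence() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The published between-order divergence table shipped with the package.

    Returns ``(distances, ses)``: distances from the lower triangle
    (symmetrised), standard errors from the upper triangle.
    """
    text = (
        resources.files("cyanogst.data")
        .joinpath("order_divergence_reference.tsv")
        .read_text()
    )
    raw = pd.read_csv(StringIO(text), sep="\t", index_col=0)
    labels = list(raw.columns)
    vals = raw.to_numpy(dtype=float)
    dist = np.zeros_like(vals)
    ses = np.zeros_like(vals)
    il = np.tril_indices_from(vals, k=-1)
    iu = np.triu_indices_from(vals, k=1)
    dist[il] = vals[il]
    dist += dist.T
    ses[iu] = vals[iu]
    ses += ses.T
    return (
        pd.DataFrame(dist, index=labels, columns=labels),
        pd.DataFrame(ses, index=labels, columns=labels),
    )


@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths and optional % bootstrap supports."""

    tree: dendropy.Tree
    negative_branches_clamped: int = 0
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def newick(self) -> str:
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each normalised to the side without the first leaf."""
        return set(_edge_splits(self.tree).values())


def _leafset(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _edge_splits(tree: dendropy.Tree) -> dict:
    """Map internal (non-root, non-leaf) node -> normalised non-trivial split."""
    all_leaves = _leafset(tree.seed_node)
    anchor = min(all_leaves)
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = _leafset(node)
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        if anchor in side:
            side = all_leaves - side
        out[node] = side
    return out


def neighbor_joining(
    dm: DistanceMatrix,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Pair selection minimises the Q criterion; ties break to the first pair in
    label order.  Negative branch-length estimates are clamped to zero and
    counted.  Exact on additive matrices.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    tns = taxon_namespace or dendropy.TaxonNamespace(dm.labels)
    nodes = []
    for lbl in dm.labels:
        taxon = tns.get_taxon(lbl)
        if taxon is None:
            taxon = tns.new_taxon(lbl)
        nodes.append(dendropy.Node(taxon=taxon))
    D = dm.values.copy()
    active = list(range(n))
    clamped = 0
    node_of = {i: nodes[i] for i in active}

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ai, aj = map(int, np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))[0])
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, clamped = 0.0, clamped + 1
        if lj < 0:
            lj, clamped = 0.0, clamped + 1
        parent = dendropy.Node()
        node_of[i].edge.length = li
        node_of[j].edge.length = lj
        parent.add_child(node_of[i])
        parent.add_child(node_of[j])
        new_row = 0.5 * (D[i, active] + D[j, active] - dij)
        D[i, active] = new_row
        D[active, i] = new_row
        D[i, i] = 0.0
        node_of[i] = parent
        active.remove(j)

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        if lk < 0:
            lk, clamped = 0.0, clamped + 1
        node_of[k].edge.length = lk
        root.add_child(node_of[k])
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return PhyloTree(tree=tree, negative_branches_clamped=clamped)


def _star_tree(labels, tns=None) -> PhyloTree:
    tns = tns or dendropy.TaxonNamespace(labels)
    root = dendropy.Node()
    for lbl in labels:
        taxon = tns.get_taxon(lbl) or tns.new_taxon(lbl)
        child = dendropy.Node(taxon=taxon)
        child.edge.length = 0.0
        root.add_child(child)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return PhyloTree(tree=tree)


def bootstrap_support(
    msa: MultipleAlignment,
    replicates: int = 500,
    method: str = "gamma-poisson",
    alpha: float = 1.0,
    seed: int | np.random.Generator = 0,
    cap: float = SATURATION_CAP,
) -> PhyloTree:
    """NJ tree from the full alignment, with column-bootstrap % supports.

    Columns are resampled with replacement per replicate; support of an
    internal edge is the percentage of replicate trees containing the same
    leaf-set split.  An alignment of (near-)identical rows yields the star
    tree with all supports 100 by convention.
    """
    if replicates < 1:
        raise ValidationError("need at least 1 bootstrap replicate")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    dm = pairwise_distance(msa, method=method, alpha=alpha, cap=cap)
    if dm.values.max() < 1e-12:
        star = _star_tree(msa.ids)
        star.supports = {}
        return star
    result = neighbor_joining(dm)
    splits = _edge_splits(result.tree)
    counts = {side: 0 for side in splits.values()}
    cols = msa.columns()
    ncol = cols.shape[1]
    tns = result.tree.taxon_namespace
    for _ in range(replicates):
        pick = rng.integers(0, ncol, size=ncol)
        boot = MultipleAlignment(
            {rid: "".join(cols[k][pick]) for k, rid in enumerate(msa.ids)}
        )
        bdm = pairwise_distance(boot, method=method, alpha=alpha, cap=cap)
        if bdm.values.max() < 1e-12:
            continue
        btree = neighbor_joining(bdm, taxon_namespace=tns)
        bsplits = set(_edge_splits(btree.tree).values())
        for side in counts:
            if side in bsplits:
                counts[side] += 1
    supports = {side: 100.0 * c / replicates for side, c in counts.items()}
    for node, side in splits.items():
        node.label = f"{supports[side]:.0f}"
    result.supports = supports
    return result


def monophyly_check(tree: PhyloTree, groups: dict[str, str]) -> dict[str, bool]:
    """Is each group a clade under some rooting (bipartition semantics)?"""
    all_leaves = frozenset(tree.leaf_labels)
    sides = set()
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        sides.add(_leafset(node))
    out = {}
    for g in sorted(set(groups.values())):
        members = frozenset(lbl for lbl, gg in groups.items() if gg == g)
        if not members <= all_leaves:
            raise ValidationError(f"group {g!r} has leaves not in the tree")
        out[g] = (
            len(members) in (1, len(all_leaves))
            or members in sides
            or (all_leaves - members) in sides
        )
    return out
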