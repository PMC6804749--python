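"""Distance matrices, neighbor joining, tree-based species delimitation,
haplotype networks, and branch-length tree congruence (K-score).

Trees are dendropy objects throughout. Neighbor joining is the standard
Saitou-Nei agglomeration and exists as plumbing: the pipeline consumes
externally inferred trees when available, and the internal NJ keeps the
synthetic path deterministic and hermetic.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import dendropy
import networkx as nx
import numpy as np
from dendropy.calculate import treecompare

from .matrix import AlignedMatrix
from .sites import Haplotype

logger = logging.getLogger(__name__)

_ACGT_MASK = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    _ACGT_MASK[_b] = True


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # (n, n) symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        self.values = v


def pdistance_matrix(m: AlignedMatrix, gap_mode: str = "pairwise_deletion"
                     ) -> DistanceMatrix:
    """Uncorrected p-distances.

    ``pairwise_deletion`` (default) compares only columns where both
    sequences are A/C/G/T; ``gaps_as_state`` also scores gap characters as
    a fifth state (columns where either has N stay excluded). A pair with
    zero comparable sites is an error naming the pair.
    """
    arr = m.to_array()
    if gap_mode == "pairwise_deletion":
        ok = _ACGT_MASK[arr]
    elif gap_mode == "gaps_as_state":
        ok = _ACGT_MASK[arr] | (arr == ord("-"))
    else:
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    n = m.n
    d = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            usable = ok[i] & ok[j]
            ns = int(usable.sum())
            if ns == 0:
                raise ValueError(
                    f"no comparable sites between {m.ids[i]!r} and {m.ids[j]!r}")
            d[i, j] = d[j, i] = (arr[i, usable] != arr[j, usable]).sum() / ns
    return DistanceMatrix(list(m.ids), d)


def substitution_distances(m: AlignedMatrix) -> DistanceMatrix:
    """Integer substitution counts (differing columns where both are A/C/G/T),
    the mutational distance used for haplotype networks (InDels excluded)."""
    arr = m.to_array()
    ok = _ACGT_MASK[arr]
    n = m.n
    d = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            usable = ok[i] & ok[j]
            d[i, j] = d[j, i] = (arr[i, usable] != arr[j, usable]).sum()
    return DistanceMatrix(list(m.ids), d)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining. Negative branch lengths are clamped to
    zero with the deficit moved to the sister branch, so cherry spans are
    preserved. Ties in the Q criterion resolve to the smallest index pair."""
    n0 = len(dm.ids)
    if n0 < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = dm.values.copy()
    labels = [f"{_quote(t)}" for t in dm.ids]
    active = list(range(n0))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        a, b = active[i_], active[j_]
        dij = d[a, b]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2.0 * (k - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        new = np.zeros(d.shape[0] + 1)
        for t_ in active:
            if t_ not in (a, b):
                new[t_] = 0.5 * (d[a, t_] + d[b, t_] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new[:-1]
        d[:-1, -1] = new[:-1]
        labels.append(f"({labels[a]}:{li:.12g},{labels[b]}:{lj:.12g})")
        active = [t_ for t_ in active if t_ not in (a, b)] + [d.shape[0] - 1]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    newick = f"({labels[a]}:{la:.12g},{labels[b]}:{lb:.12g},{labels[c]}:{lc:.12g});"
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def _quote(label: str) -> str:
    if any(c in label for c in " ();:,[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# species delimitation


@dataclass
class DelimitationRow:
    group: str
    closest_group: str
    monophyletic: bool
    intra_dist: float
    inter_dist_closest: float
    intra_over_inter: float
    av_mrca_tips: float


def _node_to_tip_distance(tip_node, ancestor) -> float:
    dist = 0.0
    node = tip_node
    while node is not ancestor:
        dist += node.edge.length or 0.0
        node = node.parent_node
        if node is None:
            raise ValueError("ancestor is not on the tip's root path")
    return dist


def root_on_outgroup(tree: dendropy.Tree, outgroup_tips: list[str]) -> dendropy.Tree:
    """Clone and reroot on the edge above the outgroup (tip or MRCA),
    splitting that edge halfway."""
    t = tree.clone(depth=1)
    t.is_rooted = True
    taxa = [x for x in t.taxon_namespace if x.label in set(outgroup_tips)]
    if not taxa:
        raise ValueError(f"outgroup tips {outgroup_tips} not found in tree")
    node = t.mrca(taxa=taxa) if len(taxa) > 1 else t.find_node_with_taxon_label(taxa[0].label)
    if node.parent_node is None:  # outgroup MRCA is the root: root via ingroup
        ingroup = [x for x in t.taxon_namespace if x.label not in set(outgroup_tips)]
        node = t.mrca(taxa=ingroup)
    length = node.edge.length or 0.0
    t.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0,
                     update_bipartitions=True)
    return t


def delimit_species(tree: dendropy.Tree, groups: dict[str, str], outgroup: str
                    ) -> list[DelimitationRow]:
    """Per-group monophyly and patristic-distance summaries on a tree rooted
    at the outgroup group: mean intra-group distance, mean distance to the
    closest group, their ratio (0 when intra = 0), and the mean MRCA-to-tip
    path length."""
    labels_on_tree = {t.label for t in tree.taxon_namespace}
    by_group: dict[str, list[str]] = {}
    for tip, g in groups.items():
        if tip in labels_on_tree:
            by_group.setdefault(g, []).append(tip)
    for g, tips in by_group.items():
        if not tips:
            raise ValueError(f"group {g!r} has no tips on the tree")
    if outgroup not in by_group:
        raise ValueError(f"outgroup group {outgroup!r} absent from tree")

    t = root_on_outgroup(tree, by_group[outgroup])
    pdm = t.phylogenetic_distance_matrix()
    taxon = {x.label: x for x in t.taxon_namespace}

    def mean_between(g1: str, g2: str) -> float:
        vals = [pdm.patristic_distance(taxon[a], taxon[b])
                for a in by_group[g1] for b in by_group[g2]]
        return float(np.mean(vals))

    rows = []
    for g in by_group:
        tips = by_group[g]
        g_taxa = [taxon[a] for a in tips]
        if len(tips) == 1:
            mono, intra, av = True, 0.0, 0.0
        else:
            mrca = t.mrca(taxa=g_taxa)
            clade_tips = {lf.taxon.label for lf in mrca.leaf_iter()}
            mono = clade_tips == set(tips)
            pairs = [pdm.patristic_distance(taxon[a], taxon[b])
                     for a, b in itertools.combinations(tips, 2)]
            intra = float(np.mean(pairs))
            tip_nodes = [t.find_node_with_taxon_label(a) for a in tips]
            av = float(np.mean([_node_to_tip_distance(nd, mrca) for nd in tip_nodes]))
        others = [o for o in by_group if o != g]
        inter_by = {o: mean_between(g, o) for o in others}
        closest = min(inter_by, key=lambda o: (inter_by[o], o))
        inter = inter_by[closest]
        ratio = 0.0 if intra == 0 else intra / inter
        rows.append(DelimitationRow(g, closest, mono, intra, inter, ratio, av))
    return rows


# ---------------------------------------------------------------------------
# haplotype network


def minimum_spanning_network(haps: list[Haplotype], epsilon: int = 0) -> nx.Graph:
    """Union-of-all-MSTs haplotype network over substitution distances
    (gaps/Ns excluded), keeping tied alternative edges; with epsilon > 0,
    edges within epsilon of the component-merge threshold are added too.

    Haplotypes at substitution distance 0 (gap-only differences) are merged
    into one node. Nodes are keyed by the first member id and carry count,
    members and group composition.
    """
    if not haps:
        raise ValueError("no haplotypes")
    reps = AlignedMatrix([h.members[0] for h in haps],
                         [h.representative for h in haps])
    d = substitution_distances(reps).values.astype(int)
    n = len(haps)

    # merge zero-distance haplotypes
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n - 1):
        for j in range(i + 1, n):
            if d[i, j] == 0 and find(i) != find(j):
                parent[find(j)] = find(i)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    order = sorted(clusters, key=lambda r: min(clusters[r]))
    node_members = [sorted(clusters[r]) for r in order]
    idx_of = {i: ci for ci, mem in enumerate(node_members) for i in mem}
    k = len(node_members)

    g = nx.Graph()
    for ci, mem in enumerate(node_members):
        members = [a for i in mem for a in haps[i].members]
        comp: dict[str, int] = {}
        for i in mem:
            for grp, cnt in haps[i].groups.items():
                comp[grp] = comp.get(grp, 0) + cnt
        g.add_node(haps[mem[0]].members[0], count=len(members),
                   members=members, groups=comp)
    names = list(g.nodes)
    if k == 1:
        return g

    dk = np.full((k, k), np.inf)
    for i in range(n - 1):
        for j in range(i + 1, n):
            a, b = idx_of[i], idx_of[j]
            if a != b:
                dk[a, b] = dk[b, a] = min(dk[a, b], d[i, j])

    # bottleneck (component-merge) thresholds via level-wise Kruskal
    comp = list(range(k))

    def cfind(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    thresh = np.zeros((k, k))
    edges = sorted({(int(dk[i, j]), i, j) for i in range(k - 1)
                    for j in range(i + 1, k) if np.isfinite(dk[i, j])})
    for w, level in itertools.groupby(edges, key=lambda e: e[0]):
        level = list(level)
        merged_pairs = []
        for _, i, j in level:
            if cfind(i) != cfind(j):
                merged_pairs.append((i, j))
        members_of: dict[int, list[int]] = {}
        for x in range(k):
            members_of.setdefault(cfind(x), []).append(x)
        newly = set()
        for i, j in merged_pairs:
            ri, rj = cfind(i), cfind(j)
            if ri != rj:
                newly.update((a, b) for a in members_of[ri] for b in members_of[rj])
                members_of[ri] = members_of[ri] + members_of[rj]
                comp[rj] = ri
            else:  # already merged within this level: same threshold
                pass
        for a, b in newly:
            thresh[a, b] = thresh[b, a] = w

    for i in range(k - 1):
        for j in range(i + 1, k):
            if np.isfinite(dk[i, j]) and dk[i, j] <= thresh[i, j] + epsilon:
                g.add_edge(names[i], names[j], weight=int(dk[i, j]))
    if not nx.is_connected(g):  # pragma: no cover - MST union is connected
        logger.warning("haplotype network is not connected")
    return g


# ---------------------------------------------------------------------------
# tree congruence


@dataclass
class TreeComparison:
    k_factor: float    # least-squares scaling K of tree b onto tree a
    k_score: float     # RMS path-length residual after scaling
    rf_distance: int   # unrooted Robinson-Foulds bipartition count


def _patristic_matrix(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    pdm = tree.phylogenetic_distance_matrix()
    taxon = {x.label: x for x in tree.taxon_namespace}
    k = len(labels)
    out = np.zeros((k, k))
    for i in range(k - 1):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxon[labels[i]],
                                                           taxon[labels[j]])
    return out


def compare_trees(a: dendropy.Tree, b: dendropy.Tree) -> TreeComparison:
    """Branch-length congruence of two trees on the same tips.

    K is the least-squares factor scaling b's path lengths onto a's; the
    K-score is the RMS residual over tip pairs after scaling (0 iff the
    path-length matrices are proportional). ``rf_distance`` is the unrooted
    Robinson-Foulds bipartition count.
    """
    la = {t.label for t in a.taxon_namespace if t.label}
    lb = {t.label for t in b.taxon_namespace if t.label}
    if la != lb:
        raise ValueError(f"tip sets differ; symmetric difference: {sorted(la ^ lb)}")
    labels = sorted(la)
    da = _patristic_matrix(a, labels)
    db = _patristic_matrix(b, labels)
    iu = np.triu_indices(len(labels), k=1)
    va, vb = da[iu], db[iu]
    denom = float(np.sum(vb * vb))
    k_factor = float(np.sum(va * vb) / denom) if denom > 0 else 0.0
    k_score = float(np.sqrt(np.mean((va - k_factor * vb) ** 2)))

    tns = dendropy.TaxonNamespace()
    a2 = dendropy.Tree.get(data=a.as_string(schema="newick"), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    b2 = dendropy.Tree.get(data=b.as_string(schema="newick"), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    a2.is_rooted = b2.is_rooted = False
    a2.encode_bipartitions()
    b2.encode_bipartitions()
    rf = int(treecompare.symmetric_difference(a2, b2))
    return TreeComparison(k_factor, k_score, rf)
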