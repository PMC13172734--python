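"""Distance phylogenies, bootstrap, clade separation and valency events.

The internal tree path is neighbor joining on p- or K2P distances with a
classical column bootstrap; externally produced newick trees are accepted
everywhere a tree is an input.  Valency history is counted under two
parsimony models: a single-gain (Dollo-style) model in which multivalency
arises once and is lost repeatedly, and unconstrained Fitch parsimony.
Tie-breaking is lexicographic on taxon ids throughout, so all outputs are
deterministic for fixed inputs and seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np

from .seqcore import GAP

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class DistanceMatrix:
    taxa: List[str]
    d: np.ndarray
    model: str

    def __post_init__(self) -> None:
        if self.d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")


@dataclass
class ValencyTree:
    """A tree whose tips carry valency states, with optional edge support."""

    tree: dendropy.Tree
    tip_states: Dict[str, int] = field(default_factory=dict)
    support: Dict[frozenset, float] = field(default_factory=dict)

    @property
    def taxa(self) -> List[str]:
        return sorted(l.taxon.label for l in self.tree.leaf_node_iter())


@dataclass
class EventCount:
    rooting: str
    gains: int
    losses: int
    events: Dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# distances


def _seq_pairs(seqs) -> List[Tuple[str, str]]:
    out = []
    for s in seqs:
        if hasattr(s, "id"):
            out.append((s.id, s.seq))
        else:
            out.append(s)  # (id, seq) tuples
    return out


def distance_matrix(aligned_seqs, model: str = "p_distance") -> DistanceMatrix:
    """Pairwise p- or Kimura-2-parameter distances from an alignment.

    Sites where either sequence has a gap or ambiguity are skipped for that
    pair.  K2P saturation (non-positive log argument) raises, naming the
    offending pair.
    """
    pairs = _seq_pairs(aligned_seqs)
    names = [p[0] for p in pairs]
    L = len(pairs[0][1])
    if any(len(p[1]) != L for p in pairs):
        raise ValueError("sequences must be aligned to equal length")
    n = len(pairs)
    d = np.zeros((n, n))
    skip = set(GAP) | {"N", "X"}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = pairs[i][1], pairs[j][1]
            comparable = mism = ts = tv = 0
            for x, y in zip(a, b):
                if x in skip or y in skip:
                    continue
                comparable += 1
                if x != y:
                    mism += 1
                    if (x, y) in TRANSITIONS:
                        ts += 1
                    else:
                        tv += 1
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns between {names[i]} and {names[j]}")
            if model == "p_distance":
                dist = mism / comparable
            elif model == "K2P":
                P, Q = ts / comparable, tv / comparable
                arg1, arg2 = 1 - 2 * P - Q, 1 - 2 * Q
                if arg1 <= 0 or arg2 <= 0:
                    raise ValueError(
                        f"K2P saturation between {names[i]} and {names[j]}")
                dist = -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
            else:
                raise ValueError(f"unknown distance model {model!r}")
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(names, d, model)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> ValencyTree:
    """Neighbor joining with lexicographic tie-breaking on taxon ids.

    On an additive distance matrix the true topology and branch lengths are
    recovered exactly.  The result is unrooted (basal trifurcation).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(sorted(dm.taxa))
    nodes: Dict[str, dendropy.Node] = {}
    for name in dm.taxa:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(name)
        nodes[name] = nd
    D: Dict[str, Dict[str, float]] = {
        a: {b: float(dm.d[i, j]) for j, b in enumerate(dm.taxa) if b != a}
        for i, a in enumerate(dm.taxa)}
    active = sorted(dm.taxa)
    counter = 0
    while len(active) > 3:
        m = len(active)
        r = {a: sum(D[a][b] for b in active if b != a) for a in active}
        best_key, pair = None, None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * D[a][b] - r[a] - r[b]
                key = (q, a, b)
                if best_key is None or key < best_key:
                    best_key, pair = key, (a, b)
        a, b = pair
        da = 0.5 * D[a][b] + (r[a] - r[b]) / (2 * (m - 2))
        db = D[a][b] - da
        parent = dendropy.Node()
        ca, cb = nodes.pop(a), nodes.pop(b)
        parent.add_child(ca)
        parent.add_child(cb)
        ca.edge.length = da
        cb.edge.length = db
        new = f"__nj{counter}"
        counter += 1
        nodes[new] = parent
        D[new] = {}
        for c in active:
            if c in (a, b):
                continue
            val = 0.5 * (D[a][c] + D[b][c] - D[a][b])
            D[new][c] = val
            D[c][new] = val
        del D[a], D[b]
        active = sorted([c for c in active if c not in (a, b)] + [new])
    x, y, z = active
    root = dendropy.Node()
    for p, q1, q2 in ((x, y, z), (y, x, z), (z, x, y)):
        nd = nodes[p]
        root.add_child(nd)
        nd.edge.length = 0.5 * (D[p][q1] + D[p][q2] - D[q1][q2])
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return ValencyTree(tree)


# ---------------------------------------------------------------------------
# bipartitions and bootstrap


def bipartition_keys(tree: dendropy.Tree) -> Dict[frozenset, dendropy.Node]:
    """Canonical keys for all non-trivial bipartitions (unrooted sense).

    The key is the leaf set on the side not containing the lexicographically
    smallest taxon, so it is invariant to the direction of the edge.
    """
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(leaves)
    out: Dict[frozenset, dendropy.Node] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in nd.leaf_iter())
        key = below if ref not in below else leaves - below
        if 2 <= len(key) <= len(leaves) - 2:
            out[key] = nd
    return out


def bootstrap_support(aligned_seqs, reps: int = 1000, seed: int = 0,
                      model: str = "p_distance") -> ValencyTree:
    """Classical column bootstrap on the internal NJ path.

    Alignment columns are resampled with replacement ``reps`` times, a tree
    is rebuilt per replicate, and each internal edge of the point-estimate
    tree is annotated with the percentage of replicates containing its
    bipartition.  Taxa are canonically sorted first so support values do
    not depend on input order.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    pairs = sorted(_seq_pairs(aligned_seqs))
    names = [p[0] for p in pairs]
    arr = np.array([list(p[1]) for p in pairs])
    point = nj_tree(distance_matrix(pairs, model))
    keys = bipartition_keys(point.tree)
    counts = {k: 0 for k in keys}
    rng = np.random.default_rng(seed)
    L = arr.shape[1]
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        rep_seqs = ["".join(row) for row in arr[:, cols]]
        rep_dm = distance_matrix(list(zip(names, rep_seqs)), model)
        rep_keys = bipartition_keys(nj_tree(rep_dm).tree)
        for k in counts:
            if k in rep_keys:
                counts[k] += 1
    support = {k: 100.0 * c / reps for k, c in counts.items()}
    for k, nd in keys.items():
        nd.label = f"{support[k]:.0f}"
    point.support = support
    return point


# ---------------------------------------------------------------------------
# clade separation


@dataclass
class SeparationReport:
    separation: bool
    edge_support: Optional[float]
    monophyly: Dict[str, bool]


def domain_clade_separation(vt: Union[ValencyTree, dendropy.Tree],
                            labels: Dict[str, str]) -> SeparationReport:
    """Test whether C-terminal domains split from N-terminal plus singles.

    Reports whether some edge of the unrooted tree bipartitions the
    C-labelled tips from the union of N-labelled and single-domain tips,
    with that edge's bootstrap support when available, plus per-label
    rooted monophyly.
    """
    tree = vt.tree if isinstance(vt, ValencyTree) else vt
    support = vt.support if isinstance(vt, ValencyTree) else {}
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    missing = [l for l in leaves if l not in labels]
    if missing:
        raise ValueError(f"missing tip labels: {missing}")
    c_set = frozenset(l for l in leaves if labels[l] == "C")
    all_set = frozenset(leaves)
    ref = min(all_set)
    target = c_set if ref not in c_set else all_set - c_set
    keys = bipartition_keys(tree)
    # pendant edges realise trivial bipartitions: handle |C| == 1 and
    # |complement| == 1 directly
    separation = target in keys or len(c_set) in (1, len(leaves) - 1)
    edge_support = support.get(target) if support else None
    monophyly = {}
    for lab in sorted(set(labels.values())):
        tips = frozenset(l for l in leaves if labels[l] == lab)
        monophyly[lab] = _is_monophyletic(tree, tips)
    return SeparationReport(bool(separation) and len(c_set) > 0,
                            edge_support, monophyly)


def _is_monophyletic(tree: dendropy.Tree, tips: frozenset) -> bool:
    """Clade test under the tree's given root (leafset equality)."""
    if not tips:
        return False
    if len(tips) == 1:
        return True
    for nd in tree.preorder_node_iter():
        below = frozenset(l.taxon.label for l in nd.leaf_iter())
        if below == tips:
            return True
    return False


# ---------------------------------------------------------------------------
# valency event counting


def _binary_states(tip_states: Dict[str, int]) -> Dict[str, int]:
    return {k: (1 if v >= 2 else 0) for k, v in tip_states.items()}


def count_valency_events(tree: Union[ValencyTree, dendropy.Tree],
                         tip_states: Dict[str, int],
                         rooting: Optional[frozenset] = None,
                         model: str = "dollo_single_gain") -> EventCount:
    """Count valency gains and losses on a rooted tree.

    States collapse to binary (multivalent when valency >= 2).  Under
    ``dollo_single_gain`` one gain is placed on the edge above the MRCA of
    all multivalent tips (the loss-minimising placement compatible with a
    single origin) and the minimum losses below it are counted; ``fitch``
    returns the unconstrained minimum-change count.  ``rooting`` names a
    candidate root edge by the leaf set on one of its sides.
    """
    src = tree.tree if isinstance(tree, ValencyTree) else tree
    t = src.clone(depth=1)
    t.is_rooted = True  # counting is always relative to a chosen root
    leaves = [l.taxon.label for l in t.leaf_node_iter()]
    missing = [l for l in leaves if l not in tip_states]
    if missing:
        raise ValueError(f"states missing for tips: {missing}")
    if rooting is not None:
        edge = _find_edge(t, frozenset(rooting))
        t.reroot_at_edge(edge, update_bipartitions=False)
    states = _binary_states(tip_states)
    root_id = "|".join(sorted(rooting)) if rooting is not None else "as_given"
    if model == "fitch":
        changes, events = _fitch(t, states)
        gains = sum(1 for v in events.values() if v == "gain")
        losses = sum(1 for v in events.values() if v == "loss")
        return EventCount(root_id, gains, losses, events)
    if model != "dollo_single_gain":
        raise ValueError(f"unknown event model {model!r}")
    multi = [l for l in leaves if states[l] == 1]
    events: Dict[str, str] = {}
    if not multi:
        return EventCount(root_id, 0, 0, events)
    if len(multi) == len(leaves):
        events["root"] = "gain"
        return EventCount(root_id, 1, 0, events)
    mrca = t.mrca(taxon_labels=multi) if len(multi) > 1 else \
        next(l for l in t.leaf_node_iter() if l.taxon.label == multi[0])
    has_multi: Dict[int, bool] = {}
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            has_multi[id(nd)] = states[nd.taxon.label] == 1
        else:
            has_multi[id(nd)] = any(has_multi[id(c)]
                                    for c in nd.child_nodes())
    events[_node_key(mrca)] = "gain"
    losses = 0
    for nd in mrca.preorder_iter():
        if nd is mrca:
            continue
        parent = nd.parent_node
        if has_multi[id(parent)] and not has_multi[id(nd)]:
            losses += 1
            events[_node_key(nd)] = "loss"
    return EventCount(root_id, 1, losses, events)


def _node_key(nd: dendropy.Node) -> str:
    return "|".join(sorted(l.taxon.label for l in nd.leaf_iter()))


def _find_edge(t: dendropy.Tree, side: frozenset):
    leaves = frozenset(l.taxon.label for l in t.leaf_node_iter())
    for nd in t.preorder_node_iter():
        if nd.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in nd.leaf_iter())
        if below == side or below == leaves - side:
            return nd.edge
    raise ValueError(f"no edge with side {sorted(side)}")


def _fitch(t: dendropy.Tree, states: Dict[str, int]):
    sets: Dict[int, frozenset] = {}
    changes = 0
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            sets[id(nd)] = frozenset([states[nd.taxon.label]])
        else:
            inter = None
            for c in nd.child_nodes():
                s = sets[id(c)]
                inter = s if inter is None else inter & s
            if inter:
                sets[id(nd)] = inter
            else:
                union = frozenset()
                for c in nd.child_nodes():
                    union |= sets[id(c)]
                # each empty-intersection junction costs child_count - 1 in
                # the general multifurcating case; binary trees cost 1
                sets[id(nd)] = union
                changes += 1
    # top-down assignment to label the change edges
    events: Dict[str, str] = {}
    assign: Dict[int, int] = {}
    for nd in t.preorder_node_iter():
        s = sets[id(nd)]
        if nd.parent_node is None:
            assign[id(nd)] = min(s)
        else:
            p = assign[id(nd.parent_node)]
            assign[id(nd)] = p if p in s else min(s)
            if assign[id(nd)] != p:
                events[_node_key(nd)] = (
                    "gain" if assign[id(nd)] == 1 else "loss")
    return changes, events


def enumerate_rootings(tree: Union[ValencyTree, dendropy.Tree],
                       tip_states: Dict[str, int],
                       model: str = "dollo_single_gain"
                       ) -> Tuple[List[EventCount], Dict[str, int]]:
    """Event counts for every candidate root edge of an unrooted tree."""
    src = tree.tree if isinstance(tree, ValencyTree) else tree
    leaves = frozenset(l.taxon.label for l in src.leaf_node_iter())
    ref = min(leaves)
    seen = set()
    results: List[EventCount] = []
    for nd in src.preorder_node_iter():
        if nd.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in nd.leaf_iter())
        key = below if ref not in below else leaves - below
        if not key or key in seen or len(key) == len(leaves):
            continue
        seen.add(key)
        results.append(count_valency_events(src, tip_states, rooting=key,
                                            model=model))
    summary = {"min_losses": min(r.losses for r in results),
               "max_losses": max(r.losses for r in results),
               "min_gains": min(r.gains for r in results),
               "max_gains": max(r.gains for r in results)}
    return results, summary
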