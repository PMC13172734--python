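"""Independent brute-force oracles used by the property tests.

These deliberately re-derive each quantity by exhaustive enumeration with
no code shared with the package implementation beyond trivial helpers.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Tuple

import numpy as np

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
SPACING_BOUNDS = ((2, 7), (3, 10), (1, 4), (3, 13))


def brute_local_match(a: str, b: str, min_length: int
                      ) -> Optional[Tuple[int, int, int, int, int, int]]:
    """Enumerate every ungapped segment pair; +1/-1 scoring.

    Returns (score, length, a_start, b_start, a_end, b_end) 1-based of the
    winner under the (score desc, length desc, a_start, b_start) tie rule.
    """
    n, m = len(a), len(b)
    best = None
    for i in range(n):
        for j in range(m):
            score = 0
            for L in range(1, min(n - i, m - j) + 1):
                pa, pb = a[i + L - 1], b[j + L - 1]
                ok = pa == pb and pa not in "NX"
                score += 1 if ok else -1
                if L >= min_length and score > 0:
                    key = (-score, -L, i, j)
                    if best is None or key < best[0]:
                        best = (key, (score, L, i + 1, j + 1, i + L, j + L))
    return best[1] if best else None


def brute_inverted_repeats(s: str, min_arm: int, max_mismatch: int
                           ) -> List[Tuple[Tuple[int, int], Tuple[int, int], int, int]]:
    """All maximal arm pairs ((l0,l1),(r0,r1),len,mismatches), 1-based."""
    n = len(s)

    def mism(a: int, b: int, d: int) -> int:
        cnt = 0
        for i in range(a, b + 1):
            j = d - i
            if not (s[i] in COMP and s[j] in COMP and COMP[s[i]] == s[j]
                    and s[i] not in "N"):
                cnt += 1
        return cnt

    out = []
    for d in range(1, 2 * n - 2):
        i_min = max(0, d - n + 1)
        i_max = (d - 1) // 2
        for a in range(i_min, i_max + 1):
            for b in range(a + min_arm - 1, i_max + 1):
                if mism(a, b, d) > max_mismatch:
                    continue
                left_ok = a == i_min or mism(a - 1, b, d) > max_mismatch
                right_ok = b == i_max or mism(a, b + 1, d) > max_mismatch
                if left_ok and right_ok:
                    out.append(((a + 1, b + 1), (d - b + 1, d - a + 1),
                                b - a + 1, mism(a, b, d)))
    out.sort()
    return out


def brute_frameworks(pep: str, greedy: bool = True) -> List[Tuple[int, ...]]:
    """All (or greedy non-overlapping) framework cysteine sextets, 0-based."""
    n = len(pep)
    combos = []
    for c0 in range(n):
        if pep[c0] != "C":
            continue
        for x1, x2, x3, x4 in itertools.product(
                *[range(lo, hi + 1) for lo, hi in SPACING_BOUNDS]):
            c1 = c0 + 1 + x1
            c2 = c1 + 1 + x2
            c3 = c2 + 1
            c4 = c3 + 1 + x3
            c5 = c4 + 1 + x4
            if c5 >= n:
                continue
            if all(pep[c] == "C" for c in (c1, c2, c3, c4, c5)):
                combos.append((c0, c1, c2, c3, c4, c5))
    combos.sort()
    if not greedy:
        return combos
    out = []
    cursor = 0
    starts = sorted({c[0] for c in combos})
    for c0 in starts:
        if c0 < cursor:
            continue
        cands = [c for c in combos if c[0] == c0]
        best = min(cands, key=lambda c: (c[5], c))
        out.append(best)
        cursor = best[5] + 1
    return out


def brute_coverage(intervals, lo: int, hi: int) -> int:
    """Per-bp union coverage of [lo, hi] 1-based inclusive."""
    width = hi - lo + 1
    mask = np.zeros(width, dtype=bool)
    for s, e in intervals:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 <= e2:
            mask[s2 - lo : e2 - lo + 1] = True
    return int(mask.sum())


def brute_min_changes(tree, states: Dict[str, int],
                      single_gain: bool = False) -> int:
    """Minimum state changes over all internal assignments (rooted tree).

    With ``single_gain`` only assignments with at most one 0->1 edge are
    allowed and the returned value is the number of 1->0 edges of the best
    such assignment (gain edge above the root counts when the root is 1).
    """
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    best = None
    for assign in itertools.product([0, 1], repeat=len(internals)):
        amap = {id(nd): s for nd, s in zip(internals, assign)}
        for leaf in tree.leaf_node_iter():
            amap[id(leaf)] = 1 if states[leaf.taxon.label] >= 2 else 0
        gains = losses = 0
        root = tree.seed_node
        if amap[id(root)] == 1:
            gains += 1  # origin on the root edge
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            p, c = amap[id(nd.parent_node)], amap[id(nd)]
            if p == 0 and c == 1:
                gains += 1
            elif p == 1 and c == 0:
                losses += 1
        if single_gain:
            if gains > 1:
                continue
            # must actually explain every multivalent tip
            score = losses
        else:
            score = gains + losses - (1 if amap[id(root)] == 1 else 0)
        if best is None or score < best:
            best = score
    return best


def separation_oracle(tree, labels: Dict[str, str]) -> bool:
    """Does any edge bipartition the C tips from everything else?"""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    c_set = frozenset(l for l in leaves if labels[l] == "C")
    if not c_set:
        return False
    if len(c_set) in (1, len(leaves) - 1):
        return True
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in nd.leaf_iter())
        if below == c_set or leaves - below == c_set:
            return True
    return False
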