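"""Domain-loss forensics: 3'UTR pseudogene remnants and loss mechanisms.

When a tandem ICK domain is lost, the molecular route leaves a diagnostic
trace in the transcript: a nonsense point mutation leaves the lost domain
intact but untranslated in the new 3'UTR; a small deletion re-frames a
downstream stop; unequal crossing-over fuses the two domains into one
chimera with no UTR remnant; a transposable-element insertion interrupts
the coding region.  This module detects degraded domain remnants with a
dinucleotide-shuffle null, locates crossover breakpoints, and classifies
each monovalent/ancestor pair into one of those mechanisms.

Positions are reported 1-based from the start codon of the transcript.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .architecture import partition_architecture
from .seqcore import (GAP, AMBIGUOUS, NtSeq, LocalMatch, ToxinPrecursor,
                      best_local_match, global_align, local_score_batch,
                      revcomp, translate, _match_matrix)

STOP_CODONS = {"TAA", "TAG", "TGA"}

MECHANISMS = ("nonsense_point", "deletion_stop", "fusion_crossover",
              "te_disruption", "unresolved")


# ---------------------------------------------------------------------------
# position-specific scoring profiles


@dataclass
class Pssm:
    """Log-odds position-specific scoring matrix with additive pseudocounts."""

    alphabet: str
    length: int
    log_odds: np.ndarray  # (length, |alphabet|), bits
    background: np.ndarray
    pseudocount: float

    def _encode(self, seq: str) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.alphabet)}
        return np.array([idx.get(c, -1) for c in seq.upper()], dtype=np.int64)

    def score(self, window: str) -> float:
        """Score one sequence of exactly the profile length."""
        if len(window) != self.length:
            raise ValueError("window length must equal profile length")
        enc = self._encode(window)
        cols = np.arange(self.length)
        ok = enc >= 0
        # unknown symbols contribute the column minimum (strong penalty)
        vals = np.where(ok, self.log_odds[cols, np.clip(enc, 0, None)],
                        self.log_odds.min(axis=1))
        return float(vals.sum())

    def scan(self, seq: str) -> np.ndarray:
        """Window scores at every offset of ``seq`` (empty if too short)."""
        n = len(seq)
        if n < self.length:
            return np.zeros(0)
        enc = self._encode(seq)
        per_pos = np.empty((n, self.length))
        for j in range(self.length):
            col = self.log_odds[j]
            per_pos[:, j] = np.where(enc >= 0, col[np.clip(enc, 0, None)],
                                     col.min())
        # score at offset o = sum_j per_pos[o + j, j]
        out = np.zeros(n - self.length + 1)
        for j in range(self.length):
            out += per_pos[j : j + len(out), j]
        return out


def build_pssm(aligned: Sequence, pseudocount: float = 0.5) -> Pssm:
    """Column log-odds profile from a pre-aligned set of sequences.

    Gap characters are excluded from the counts; the background is the
    overall symbol frequency of the input with the same pseudocount.
    """
    seqs = [(s.seq if hasattr(s, "seq") else s).upper() for s in aligned]
    if not seqs:
        raise ValueError("need at least one aligned sequence")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("ragged alignment: sequences differ in length")
    symbols = set("".join(seqs)) - {GAP} - AMBIGUOUS
    alphabet = "ACGT" if symbols <= set("ACGT") else \
        "ACDEFGHIKLMNPQRSTVWY"
    idx = {c: i for i, c in enumerate(alphabet)}
    counts = np.zeros((L, len(alphabet)))
    for s in seqs:
        for j, c in enumerate(s):
            if c in idx:
                counts[j, idx[c]] += 1
    col_tot = counts.sum(axis=1, keepdims=True)
    probs = (counts + pseudocount) / (col_tot + pseudocount * len(alphabet))
    bg_counts = counts.sum(axis=0)
    bg = (bg_counts + pseudocount) / (bg_counts.sum() + pseudocount * len(alphabet))
    log_odds = np.log2(probs / bg[None, :])
    return Pssm(alphabet, L, log_odds, bg, pseudocount)


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle (Altschul-Erickson)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle ``seq`` preserving its exact dinucleotide counts.

    Samples a uniform random Eulerian walk on the dinucleotide transition
    multigraph (Altschul-Erickson): for every vertex except the terminal
    character one outgoing edge is reserved as its last exit, accepted only
    when the reserved edges form an arborescence into the terminal vertex.
    """
    s = seq.upper()
    if len(s) <= 2 or len(set(s)) == 1:
        return s
    edges: Dict[str, list] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    first, last = s[0], s[-1]
    vertices = sorted(set(s))
    while True:
        last_edge = {}
        for v in vertices:
            if v == last or v not in edges or not edges[v]:
                continue
            last_edge[v] = edges[v][int(rng.integers(len(edges[v])))]
        ok = True
        for v in last_edge:
            seen = set()
            u = v
            while u != last and u in last_edge and u not in seen:
                seen.add(u)
                u = last_edge[u]
            if u != last:
                ok = False
                break
        if ok:
            break
    walk_edges: Dict[str, list] = {}
    for v in vertices:
        rest = list(edges.get(v, []))
        if v in last_edge:
            rest.remove(last_edge[v])
        order = rng.permutation(len(rest))
        rest = [rest[i] for i in order]
        if v in last_edge:
            rest.append(last_edge[v])
        walk_edges[v] = rest
    out = [first]
    ptr = {v: 0 for v in vertices}
    v = first
    for _ in range(len(s) - 1):
        nxt = walk_edges[v][ptr[v]]
        ptr[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# UTR remnant scanning


@dataclass
class RemnantHit:
    """A significant donor-domain trace in a query transcript."""

    target_interval: Tuple[int, int]  # 1-based in CDS+3'UTR
    frame: Optional[int]  # reading frame for translated hits, None for nt
    score: float
    empirical_p: float
    length: int
    in_utr: bool
    level: str  # "nt" or "aa"


def _ungapped_score(match: Optional[LocalMatch]) -> float:
    if match is None:
        return 0.0
    return 2 * match.matches - match.length


def _frame_to_nt(frame: int, aa_start: int, aa_end: int, n: int
                 ) -> Tuple[int, int]:
    """Map a 1-based peptide interval of one frame to transcript coords."""
    if frame > 0:
        s = (frame - 1) + (aa_start - 1) * 3 + 1
        e = (frame - 1) + aa_end * 3
        return s, min(e, n)
    # reverse frames index into the reverse complement
    rs = (-frame - 1) + (aa_start - 1) * 3 + 1
    re_ = (-frame - 1) + aa_end * 3
    return max(1, n - re_ + 1), n - rs + 1


def scan_utr_remnant(query: Union[ToxinPrecursor, NtSeq], donor,
                     cds_end: Optional[int] = None,
                     null_shuffles: int = 1000, seed: int = 0,
                     p_threshold: float = 0.01,
                     min_length: int = 15,
                     levels: Tuple[str, ...] = ("nt", "aa")) -> List[RemnantHit]:
    """Search a transcript (CDS + 3'UTR) for remnants of a lost domain.

    Scores the best ungapped nucleotide match and the best translated
    (all six frames) match against the donor domain, and assigns each an
    empirical p-value from ``null_shuffles`` dinucleotide-preserving
    shuffles of the query.  Hits with p below ``p_threshold`` are returned,
    annotated with whether they fall in the 3'UTR.
    """
    if isinstance(query, ToxinPrecursor):
        qs = query.transcript
        boundary = len(query.cds)
    else:
        if cds_end is None:
            raise ValueError("cds_end (CDS/UTR boundary) is required")
        qs = query.seq if hasattr(query, "seq") else str(query)
        boundary = cds_end
    if null_shuffles < 100:
        raise ValueError("null_shuffles must be >= 100")
    rng = np.random.default_rng(seed)
    shuffles = [dinucleotide_shuffle(qs, rng) for _ in range(null_shuffles)]
    hits: List[RemnantHit] = []

    if isinstance(donor, Pssm):
        obs_scores = donor.scan(qs)
        if len(obs_scores):
            obs = float(obs_scores.max())
            pos = int(np.argmax(obs_scores))
            null = np.array([donor.scan(sh).max() if len(donor.scan(sh)) else
                             -math.inf for sh in shuffles])
            p = (1 + int((null >= obs).sum())) / (null_shuffles + 1)
            if p < p_threshold:
                iv = (pos + 1, pos + donor.length)
                hits.append(RemnantHit(iv, None, obs, p, donor.length,
                                       _mostly_in_utr(iv, boundary), "nt"))
        return hits

    ds = donor.seq if hasattr(donor, "seq") else str(donor)

    # nucleotide level
    obs_match = best_local_match(qs, ds, min_length=min_length) \
        if "nt" in levels else None
    if obs_match is not None:
        obs = _ungapped_score(obs_match)
        null = local_score_batch(shuffles, ds, min_length=min_length)
        p = (1 + int((null >= obs).sum())) / (null_shuffles + 1)
        if p < p_threshold:
            iv = (obs_match.a_start, obs_match.a_end)
            hits.append(RemnantHit(iv, None, obs, p, obs_match.length,
                                   _mostly_in_utr(iv, boundary), "nt"))

    if "aa" not in levels:
        return hits
    # translated level, all six frames
    dpep = translate(ds, 1).replace("*", "X")
    aa_min = max(5, min_length // 3)
    frames = (1, 2, 3, -1, -2, -3)
    best_frame, best_aa = None, None
    for f in frames:
        try:
            pep = translate(qs, f)
        except ValueError:
            continue
        m = best_local_match(pep.replace("*", "X"), dpep, min_length=aa_min)
        if m is not None and (best_aa is None or
                              _ungapped_score(m) > _ungapped_score(best_aa)):
            best_frame, best_aa = f, m
    if best_aa is not None:
        obs = _ungapped_score(best_aa)
        null = np.zeros(null_shuffles)
        for f in frames:
            peps = []
            for sh in shuffles:
                try:
                    peps.append(translate(sh, f).replace("*", "X"))
                except ValueError:
                    peps.append("X" * aa_min)
            null = np.maximum(null,
                              local_score_batch(peps, dpep, min_length=aa_min))
        p = (1 + int((null >= obs).sum())) / (null_shuffles + 1)
        if p < p_threshold:
            iv = _frame_to_nt(best_frame, best_aa.a_start, best_aa.a_end,
                              len(qs))
            hits.append(RemnantHit(iv, best_frame, obs, p,
                                   best_aa.length * 3,
                                   _mostly_in_utr(iv, boundary), "aa"))
    return hits


def _mostly_in_utr(interval: Tuple[int, int], cds_end: int) -> bool:
    s, e = interval
    in_utr = max(0, e - max(s, cds_end + 1) + 1)
    return in_utr * 2 > (e - s + 1)


# ---------------------------------------------------------------------------
# crossover breakpoints


@dataclass
class CrossoverBreakpoint:
    """Inferred unequal-crossing-over switch point in a chimeric CDS."""

    interval: Tuple[int, int]  # 1-based: switch lies after these positions
    chimeric: bool
    margin: int  # interior max minus best single-parent score
    p_value: float  # changepoint permutation p on informative sites
    scores: np.ndarray
    facilitating: Optional[LocalMatch]


def _match_profile(chimera: str, donor: str) -> np.ndarray:
    """Per-position match indicator of ``chimera`` against ``donor``.

    Equal-length sequences are compared position by position (a gapped
    aligner would harvest chance matches from homologous-but-diverged
    regions and blur the switch contrast); otherwise the chimera is
    globally aligned to the donor once and identity columns score 1.
    """
    out = np.zeros(len(chimera), dtype=np.int64)
    if len(chimera) == len(donor):
        for i, (ca, cb) in enumerate(zip(chimera, donor)):
            if ca == cb and ca not in AMBIGUOUS:
                out[i] = 1
        return out
    aln = global_align(chimera, donor)
    i = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != GAP:
            if cb != GAP and ca == cb and ca not in AMBIGUOUS:
                out[i] = 1
            i += 1
    return out


def _split_stat(x: np.ndarray) -> Tuple[int, np.ndarray]:
    """Max interior two-segment score minus the best single-segment score.

    ``x`` holds +1 where a site favours parent 1 and -1 where it favours
    parent 2; the statistic is the CUSUM-style excess of the best
    changepoint model over the best no-changepoint model.
    """
    n = len(x)
    pre = np.concatenate(([0], np.cumsum(x)))  # prefix sum of +-1 labels
    # score(b) = (#favour-1 before b) + (#favour-2 after b)
    ones_before = (np.arange(n + 1) + pre) // 2
    twos_after = ((n - np.arange(n + 1)) - (pre[n] - pre)) // 2
    scores = ones_before + twos_after
    boundary = max(int(scores[0]), int(scores[n]))
    return int(scores.max()) - boundary, scores


def locate_crossover_breakpoint(chimera, d1, d2, min_stretch: int = 10,
                                permutations: int = 199,
                                seed: int = 0) -> CrossoverBreakpoint:
    """Find where a putative fusion CDS switches from domain 1 to domain 2.

    The chimera is compared to each parent domain; for every split point b
    the score is (matches to d1 before b) + (matches to d2 from b on).
    The argmax defines the breakpoint, reported as the interval of split
    points attaining the maximum because identical interdomain stretches
    make the exact point unidentifiable in principle.  Chimerism is judged
    by a changepoint permutation test on the informative sites (positions
    where exactly one parent matches): under a single-parent origin their
    order is exchangeable, under a fusion they segregate around the
    breakpoint.  The best ungapped d1-versus-d2 local match near the
    breakpoint is returned as the putative recombination-facilitating
    stretch.
    """
    cs = chimera.seq if hasattr(chimera, "seq") else str(chimera)
    s1 = d1.seq if hasattr(d1, "seq") else str(d1)
    s2 = d2.seq if hasattr(d2, "seq") else str(d2)
    if not cs or not s1 or not s2:
        raise ValueError("chimera and both domains must be non-empty")
    n = len(cs)
    m1 = _match_profile(cs, s1)
    m2 = _match_profile(cs, s2)
    p1 = np.concatenate(([0], np.cumsum(m1)))
    total2 = int(m2.sum())
    p2 = np.concatenate(([0], np.cumsum(m2)))
    scores = p1 + (total2 - p2)  # scores[b], b = 0..n
    best = int(scores.max())
    arg = np.flatnonzero(scores == best)
    interior = 0 not in arg and n not in arg
    margin = best - max(int(scores[0]), int(scores[n]))
    # permutation null on informative sites only
    info = np.flatnonzero(m1 != m2)
    p_value = 1.0
    if len(info) >= 4 and margin > 0:
        labels = np.where(m1[info] == 1, 1, -1)
        obs, _ = _split_stat(labels)
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(permutations):
            perm, _ = _split_stat(rng.permutation(labels))
            hits += perm >= obs
        p_value = (1 + hits) / (permutations + 1)
    chimeric = interior and p_value <= 0.05
    lo, hi = int(arg.min()), int(arg.max())
    window = (max(1, lo - 10), min(len(s1), hi + 10))
    facil = best_local_match(s1, s2, min_length=min_stretch, a_window=window)
    if facil is None:
        facil = best_local_match(s1, s2, min_length=min_stretch)
    return CrossoverBreakpoint((lo, hi), chimeric, margin, p_value, scores,
                               facil)


def crossover_byproducts(d1, d2, breakpoint: int, linker: str = ""
                         ) -> Tuple[str, str]:
    """Both reciprocal products of unequal crossing-over at ``breakpoint``.

    Returns (contracted, expanded): the single-domain fusion D1-prefix +
    D2-suffix, and the three-domain product D1 + fused(D2-prefix/D1-suffix)
    + D2 with the interdomain linker duplicated alongside.  Total length is
    conserved: |contracted| + |expanded| = 2(|D1| + |D2| + |linker|).
    """
    s1 = d1.seq if hasattr(d1, "seq") else str(d1)
    s2 = d2.seq if hasattr(d2, "seq") else str(d2)
    b = int(breakpoint)
    if not (0 <= b <= min(len(s1), len(s2))):
        raise ValueError("breakpoint outside both domains")
    contracted = s1[:b] + s2[b:]
    expanded = s1 + linker + s2[:b] + s1[b:] + linker + s2
    return contracted, expanded


# ---------------------------------------------------------------------------
# mechanism classification


@dataclass
class LossCall:
    """Mechanism verdict for one monovalent/ancestor precursor pair."""

    mechanism: str
    evidence: dict
    candidates: Dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")


def _first_stop(nt: str) -> Optional[int]:
    """0-based nt index of the first in-frame stop codon, or None."""
    for i in range(0, len(nt) - 2, 3):
        if nt[i : i + 3] in STOP_CODONS:
            return i
    return None


def _column_maps(aligned_a: str, aligned_b: str):
    """Per-column 1-based positions (0 where the column is a gap)."""
    pa, pb = [], []
    ia = ib = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != GAP:
            ia += 1
        if cb != GAP:
            ib += 1
        pa.append(ia if ca != GAP else 0)
        pb.append(ib if cb != GAP else 0)
    return pa, pb


def classify_loss_mechanism(mono: ToxinPrecursor, ancestor: ToxinPrecursor,
                            tes: Optional[Sequence] = None,
                            extend_min: int = 30,
                            max_deletion: int = 30) -> LossCall:
    """Classify the molecular mechanism behind a domain loss.

    Decision cascade: (1) a TE annotation overlapping the region where the
    missing domain should lie calls te_disruption; (2) a premature stop
    (diagnosed by a recognisable remnant of the ancestor's distal domain
    downstream of the ORF) explained by restoring a 1-30 bp deletion
    relative to the ancestor calls deletion_stop; (3) a premature stop
    aligned to a non-stop ancestor codon with an intact reading frame calls
    nonsense_point; (4) a chimeric prefix/suffix signal against the two
    ancestral domains calls fusion_crossover; otherwise unresolved.  All
    checks performed are retained in ``candidates``.
    """
    anc_arch = partition_architecture(ancestor.mature_peptide, ancestor.id)
    mono_arch = partition_architecture(mono.mature_peptide, mono.id)
    if anc_arch.valency < 2:
        raise ValueError("ancestor must be multivalent")
    if anc_arch.valency < mono_arch.valency + 1:
        raise ValueError("ancestor valency must exceed the mono valency")
    mono_tx = mono.transcript
    anc_cds = ancestor.cds
    # semi-global: the transcript's 3' tail beyond the ancestor CDS is free
    aln = global_align(mono_tx, anc_cds, free_a_suffix=True)
    mono_pos, anc_pos = _column_maps(aln.aligned_a, aln.aligned_b)

    # observed ORF boundary in the mono transcript
    stop0 = _first_stop(mono_tx)
    orf_end = (stop0 + 3) if stop0 is not None else len(mono_tx)

    # a lost domain leaves a recognisable trace downstream of the stop;
    # its presence separates truncation mechanisms from domain fusion.
    # The donor is the ancestor's whole distal region (last domain through
    # the natural stop) so late truncations inside the domain still match.
    pro_nt = 3 * ancestor.pro_end
    distal_start = pro_nt + 3 * (anc_arch.domains[-1].start - 1)
    distal = anc_cds[distal_start:]
    remnant = None
    if stop0 is not None and len(mono_tx) - orf_end >= 12 and distal:
        m = best_local_match(mono_tx[orf_end:], distal, min_length=12)
        # a long trace is convincing anywhere; a short one only counts when
        # it begins right after the stop (true remnants are stop-adjacent,
        # chance matches scatter uniformly over the UTR)
        if m is not None and m.identity >= 0.7 and \
                (m.matches >= 25 or (m.matches >= 12 and m.a_start <= 30)):
            remnant = m
    premature = remnant is not None

    candidates: Dict[str, dict] = {}
    if remnant is not None:
        candidates["utr_remnant"] = {
            "interval": (orf_end + remnant.a_start, orf_end + remnant.a_end),
            "identity": remnant.identity, "length": remnant.length}

    # --- (1) TE disruption: insertion at/after the ORF boundary -----------
    if tes:
        for te in tes:
            if te.end >= orf_end - extend_min and te.start <= len(mono_tx):
                ev = {"te": te,
                      "disrupted_region": (max(1, orf_end - 2), len(mono_tx))}
                candidates["te_disruption"] = ev
                return LossCall("te_disruption", ev, candidates)

    if premature:
        stop_iv = (stop0 + 1, stop0 + 3)
        # --- (2) deletion re-framing a stop ------------------------------
        del_ev = _deletion_candidate(aln, mono_tx, anc_cds, stop0,
                                     max_deletion, extend_min)
        if del_ev is not None:
            candidates["deletion_stop"] = del_ev
        # --- (3) nonsense point mutation ----------------------------------
        non_ev = _nonsense_candidate(aln, mono_pos, anc_pos, mono_tx,
                                     anc_cds, stop0, extend_min)
        if non_ev is not None:
            candidates["nonsense_point"] = non_ev
        if del_ev is not None:
            return LossCall("deletion_stop", del_ev, candidates)
        if non_ev is not None:
            return LossCall("nonsense_point", non_ev, candidates)
        ev = {"note": "premature stop without a supported single-event cause",
              "stop_interval": stop_iv}
        return LossCall("unresolved", ev, candidates)

    # --- (4) fusion by unequal crossing-over ------------------------------
    if anc_arch.valency >= 2 and mono_arch.valency >= 1:
        d_first = _domain_cds(ancestor, anc_arch, 0)
        d_last = _domain_cds(ancestor, anc_arch, -1)
        # compare domain span against domain spans: the mono leader and
        # tail match neither parent and only blur the switch signal
        chim = _domain_cds(mono, mono_arch, 0)
        if chim and d_first and d_last:
            bp = locate_crossover_breakpoint(chim, d_first, d_last)
            ev = {"breakpoint_interval": bp.interval,
                  "facilitating": bp.facilitating,
                  "margin": bp.margin,
                  "p_value": bp.p_value}
            candidates["fusion_crossover"] = ev
            if bp.chimeric:
                return LossCall("fusion_crossover", ev, candidates)
    return LossCall("unresolved", {"note": "no mechanism signature found"},
                    candidates)


def _mature_cds(p: ToxinPrecursor) -> str:
    cds = p.cds
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        cds = cds[:-3]
    return cds[p.pro_end * 3 :]


def domain_cds(p: ToxinPrecursor, arch, which: int) -> str:
    """Nucleotide CDS of one framework domain of a partitioned precursor."""
    mature_cds = _mature_cds(p)
    dom = arch.domains[which]
    return mature_cds[(dom.start - 1) * 3 : dom.end * 3]


_domain_cds = domain_cds


def _deletion_candidate(aln, mono_tx, anc_cds, stop0, max_deletion,
                        extend_min, merge_gap: int = 6):
    """Find a 1-30 bp deletion whose restoration abolishes the early stop.

    The aligner may split one deletion into several gap runs when a base
    inside the deleted span happens to match; runs separated by at most
    ``merge_gap`` aligned columns are therefore clustered into one
    candidate before the restoration test.
    """
    mono_pos, anc_pos = _column_maps(aln.aligned_a, aln.aligned_b)
    runs = []  # (start col, end col) of gap runs on either side
    col = 0
    ncol = len(aln.aligned_a)
    while col < ncol:
        if aln.aligned_a[col] == GAP or aln.aligned_b[col] == GAP:
            start = col
            while col < ncol and (aln.aligned_a[col] == GAP or
                                  aln.aligned_b[col] == GAP):
                col += 1
            runs.append((start, col - 1))
        else:
            col += 1
    clusters = []
    for run in runs:
        if clusters and run[0] - clusters[-1][-1][1] - 1 <= merge_gap:
            clusters[-1].append(run)
        else:
            clusters.append([run])
    best = None
    for cluster in clusters:
        c0, c1 = cluster[0][0], cluster[-1][1]
        # ignore the trailing free region where the ancestor has ended
        if all(not anc_pos[c] for c in range(c0, c1 + 1)):
            continue
        a0 = next((anc_pos[c] for c in range(c0, c1 + 1) if anc_pos[c]), 0)
        a1 = next((anc_pos[c] for c in range(c1, c0 - 1, -1) if anc_pos[c]),
                  0)
        if not a0 or not a1:
            continue
        m0 = mono_pos[c0 - 1] if c0 > 0 else 0  # mono bases kept before
        m1 = next((mono_pos[c] - 1 for c in range(c1 + 1, ncol)
                   if mono_pos[c]), len(mono_tx))
        # net lost bases over the whole cluster: paired insertion/deletion
        # wobble around a substitution nets to zero and is rejected
        net = (a1 - a0 + 1) - (m1 - m0)
        if not (1 <= net <= max_deletion):
            continue
        if m0 > stop0 + 2:  # deletion must not lie beyond the stop
            continue
        # a frameshifting deletion upstream of the stop explains it by
        # construction; an in-frame deletion must pass the restoration
        # test (reverting it pushes the first stop downstream)
        supported = net % 3 != 0
        if not supported:
            restored = mono_tx[:m0] + anc_cds[a0 - 1 : a1] + mono_tx[m1:]
            new_stop = _first_stop(restored)
            new_end = (new_stop + 3) if new_stop is not None \
                else len(restored)
            supported = new_end >= stop0 + 3 + net + 3
        if supported:
            # refine to the contiguous span of length `net` inside the
            # cluster that best reproduces the mono sequence (the aligner
            # may have split the gap around a coincidentally matching base)
            w0, w1 = max(0, m0 - 12), min(len(mono_tx), m1 + 12)
            best_start, best_mm = a0 - 1, None
            for start in range(a0 - 1, a1 - net + 1):
                cand = anc_cds[: start] + anc_cds[start + net :]
                mm = sum(1 for x, y in zip(cand[w0:w1], mono_tx[w0:w1])
                         if x != y)
                if best_mm is None or mm < best_mm:
                    best_mm, best_start = mm, start
            ev = {"deletion_interval": (best_start + 1, best_start + net),
                  "deletion_length": net,
                  "stop_interval": (stop0 + 1, stop0 + 3)}
            # prefer the deletion closest to the observed stop
            if best is None or m0 > best[0]:
                best = (m0, ev)
    return best[1] if best else None


def _nonsense_candidate(aln, mono_pos, anc_pos, mono_tx, anc_cds, stop0,
                        extend_min: int = 30):
    """Check whether a single substitution explains the premature stop."""
    # reading frame upstream of the stop must be intact (net indels % 3 == 0)
    net = 0
    for c in range(len(aln.aligned_a)):
        if mono_pos[c] and mono_pos[c] > stop0:
            break
        if aln.aligned_a[c] == GAP:
            net -= 1
        elif aln.aligned_b[c] == GAP:
            net += 1
    if net % 3 != 0:
        return None
    # ancestor triplet aligned to the mono stop codon
    trip_pos = []
    for c in range(len(aln.aligned_a)):
        if mono_pos[c] in (stop0 + 1, stop0 + 2, stop0 + 3) and \
                aln.aligned_a[c] != GAP:
            trip_pos.append(anc_pos[c])
    if len(trip_pos) != 3 or 0 in trip_pos:
        return None
    if trip_pos[2] - trip_pos[0] != 2:
        return None  # ancestor side is not contiguous
    if trip_pos[2] > len(anc_cds) - extend_min:
        return None  # maps to the ancestor's natural terminus, not internal
    anc_codon = anc_cds[trip_pos[0] - 1 : trip_pos[2]]
    if anc_codon in STOP_CODONS:
        return None
    stop_codon = mono_tx[stop0 : stop0 + 3]
    diffs = [k for k in range(3) if anc_codon[k] != stop_codon[k]]
    if not diffs:
        return None
    if len(diffs) == 1:
        codon_from = anc_codon
        k = diffs[0]
    else:
        # extra divergence hit the codon: revert the single base whose
        # change created the stop
        k = None
        for cand in diffs:
            reverted = (stop_codon[:cand] + anc_codon[cand] +
                        stop_codon[cand + 1 :])
            if reverted not in STOP_CODONS:
                k = cand
                break
        if k is None:
            return None
        codon_from = stop_codon[:k] + anc_codon[k] + stop_codon[k + 1 :]
    return {"codon_from": codon_from,
            "codon_to": stop_codon,
            "stop_position_bp": stop0 + 1 + k,
            "stop_interval": (stop0 + 1, stop0 + 3),
            "ancestor_codon_interval": (trip_pos[0], trip_pos[2])}


def verify_loss_call(call: LossCall, mono: ToxinPrecursor,
                     ancestor: ToxinPrecursor) -> bool:
    """Re-check a nonsense/deletion call by replaying it on the ancestor.

    nonsense_point: substituting codon_from -> codon_to at the aligned
    ancestor position must yield a stop at the reported mono position.
    deletion_stop: deleting the reported ancestor span must produce an
    in-frame stop at the reported interval.
    """
    anc = ancestor.cds
    if call.mechanism == "nonsense_point":
        a0, a1 = call.evidence["ancestor_codon_interval"]
        mutated = anc[: a0 - 1] + call.evidence["codon_to"] + anc[a1:]
        new_stop = _first_stop(mutated)
        return new_stop is not None and \
            (new_stop + 1, new_stop + 3) == call.evidence["stop_interval"]
    if call.mechanism == "deletion_stop":
        d0, d1 = call.evidence["deletion_interval"]
        deleted = anc[: d0 - 1] + anc[d1:]
        new_stop = _first_stop(deleted)
        return new_stop is not None and \
            (new_stop + 1, new_stop + 3) == call.evidence["stop_interval"]
    raise ValueError(f"no replay check for mechanism {call.mechanism!r}")
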