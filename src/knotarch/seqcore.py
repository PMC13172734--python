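"""Sequence containers, FASTA I/O, alignment and repeat-finding primitives.

Everything downstream (framework scanning, loss forensics, TE association)
is built on the small set of operations here: deterministic global/local
alignment with a single documented scoring scheme (match +1, mismatch -1,
gap -2), ungapped identity counting of the "n/m residues" style, tiled
window identity profiles, a best ungapped local-match finder, and an
inverted-repeat (palindrome) finder equivalent to the inverted diagonals of
a self dot-plot.

Coordinates are 0-based half-open internally; every reported position is
1-based inclusive. Ambiguity codes (N for DNA, X for protein) never match
anything, including themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = set("ACGTNRYSWKMBDHV")
DNA_UNAMBIGUOUS = set("ACGT")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}

#: symbols that never match anything in identity counting
AMBIGUOUS = {"N", "X"}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP = dict(_TABLE.forward_table)
_CODON_MAP.update({c: "*" for c in _TABLE.stop_codons})

GAP = "-"


# ---------------------------------------------------------------------------
# containers


@dataclass
class NtSeq:
    """A named nucleotide sequence (uppercase, IUPAC DNA alphabet)."""

    id: str
    seq: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"invalid DNA symbols in {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AaSeq:
    """A named amino-acid sequence (uppercase, 20 residues plus X and *)."""

    id: str
    seq: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - AA_ALPHABET
        if bad:
            raise ValueError(f"invalid protein symbols in {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ToxinPrecursor:
    """One toxin precursor: CDS (with optional 3'UTR), peptide and regions.

    ``signal_end`` and ``pro_end`` are 1-based inclusive peptide coordinates
    of the last residue of the signal peptide and the propeptide; the mature
    peptide starts at ``pro_end + 1``.  ``cds`` runs from the start codon and
    includes the terminal stop codon where one exists.
    """

    id: str
    cds: str
    utr3: str = ""
    peptide: str = ""
    signal_end: int = 0
    pro_end: int = 0
    species: str = ""
    family: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        self.utr3 = self.utr3.upper()
        if not self.peptide and len(self.cds) >= 3:
            pep = translate(self.cds, 1)
            self.peptide = pep[:-1] if pep.endswith("*") else pep

    @property
    def transcript(self) -> str:
        """CDS plus 3'UTR, 1-based from the start codon."""
        return self.cds + self.utr3

    @property
    def mature_peptide(self) -> str:
        return self.peptide[self.pro_end:]


@dataclass
class IdentityResult:
    """Match count over a column count, as printed in 'n/m residues' figures."""

    matches: int
    columns: int
    identity: float
    mode: str

    def __post_init__(self) -> None:
        if not (0 <= self.matches <= self.columns or self.columns == 0):
            raise ValueError("need columns >= matches >= 0")


@dataclass
class WindowProfile:
    """Non-overlapping tiled windows with one identity (or density) each."""

    window_size: int
    windows: list  # of (start, end, value); 1-based inclusive
    final_window_width: int


@dataclass
class LocalMatch:
    """Best ungapped segment pair; all coordinates 1-based inclusive."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    length: int
    matches: int
    identity: float


@dataclass
class InvertedRepeat:
    """Arm pair where the right arm reverse-complements the left arm."""

    left_arm: tuple  # (start, end) 1-based inclusive
    right_arm: tuple
    arm_length: int
    mismatches: int


@dataclass
class Alignment:
    aligned_a: str
    aligned_b: str
    score: int


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path, alphabet: Literal["nt", "aa", "auto"] = "auto"):
    """Read a multi-FASTA file into NtSeq/AaSeq records.

    Duplicate ids and empty records are errors. With ``alphabet='auto'`` a
    record is nucleotide when all its symbols are IUPAC DNA codes.
    """
    out = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if not s:
            raise ValueError(f"empty FASTA record: {rec.id!r}")
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        if alphabet == "nt":
            out.append(NtSeq(rec.id, s))
        elif alphabet == "aa":
            out.append(AaSeq(rec.id, s))
        else:
            cls = NtSeq if set(s) <= DNA_ALPHABET else AaSeq
            out.append(cls(rec.id, s))
    return out


def write_fasta(seqs: Iterable, path) -> None:
    """Write records as multi-FASTA wrapped at 60 columns."""
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# basic sequence arithmetic


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def translate(nt: str, frame: int = 1) -> str:
    """Translate one reading frame; stops are '*', unknown codons are 'X'.

    Frames 1..3 offset into the forward strand; -1..-3 into the reverse
    complement.  Standard genetic code only.
    """
    if frame not in (1, 2, 3, -1, -2, -3):
        raise ValueError(f"invalid frame {frame}")
    s = nt.upper()
    if frame < 0:
        s = revcomp(s)
    s = s[abs(frame) - 1:]
    if len(s) < 3:
        raise ValueError("sequence shorter than one codon after frame offset")
    s = s[: len(s) - len(s) % 3]
    return "".join(_CODON_MAP.get(s[i : i + 3], "X") for i in range(0, len(s), 3))


def six_frame(nt: str) -> dict:
    """All six translations keyed by frame (1, 2, 3, -1, -2, -3)."""
    return {f: translate(nt, f) for f in (1, 2, 3, -1, -2, -3)}


def _bytes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _ambiguous_for(*seqs: str) -> set:
    """Ambiguity symbols for the inferred alphabet: N for DNA, X for protein.

    Sequences drawn entirely from {A,C,G,T,N} are treated as DNA (where N
    is a wildcard that never matches); anything else is protein, where N is
    asparagine and only X is ambiguous.  Extended IUPAC degeneracy codes
    are compared by plain equality.
    """
    chars = set("".join(seqs)) - {GAP}
    return {"N"} if chars <= DNA_UNAMBIGUOUS | {"N"} else {"X"}


def _match_matrix(a: str, b: str) -> np.ndarray:
    """Boolean (len(a), len(b)) matrix; ambiguity codes never match."""
    A, B = _bytes(a), _bytes(b)
    eq = A[:, None] == B[None, :]
    for sym in _ambiguous_for(a, b) | {GAP}:
        code = ord(sym)
        eq &= (A[:, None] != code) & (B[None, :] != code)
    return eq


def _positions_match(a: str, b: str) -> np.ndarray:
    A, B = _bytes(a), _bytes(b)
    eq = A == B
    for sym in _ambiguous_for(a, b) | {GAP}:
        code = ord(sym)
        eq &= (A != code) & (B != code)
    return eq


# ---------------------------------------------------------------------------
# global / local alignment (Needleman-Wunsch and Smith-Waterman)

MATCH = 1
MISMATCH = -1
GAP_SCORE = -2


def global_align(a: str, b: str, match: int = MATCH, mismatch: int = MISMATCH,
                 gap: int = GAP_SCORE, free_a_suffix: bool = False) -> Alignment:
    """Needleman-Wunsch with linear gaps and a deterministic traceback.

    Ties resolve by preferring the diagonal move, then the vertical move
    (gap in ``b``), then the horizontal move (gap in ``a``); the optimal
    alignment returned is therefore unique for fixed inputs.

    With ``free_a_suffix`` the trailing unaligned suffix of ``a`` is not
    penalised (semi-global): used to align a full CDS against a longer
    transcript whose 3' tail has no counterpart.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    la, lb = len(a), len(b)
    S = np.where(_match_matrix(a, b), match, mismatch).astype(np.int32)
    H = np.zeros((la + 1, lb + 1), dtype=np.int32)
    P = np.zeros((la + 1, lb + 1), dtype=np.uint8)  # 0 diag, 1 up, 2 left
    H[0, :] = gap * np.arange(lb + 1)
    H[:, 0] = gap * np.arange(la + 1)
    P[0, 1:] = 2
    P[1:, 0] = 1
    # anti-diagonal wavefront keeps the inner update fully vectorised
    for d in range(2, la + lb + 1):
        i0, i1 = max(1, d - lb), min(la, d - 1)
        if i0 > i1:
            continue
        ii = np.arange(i0, i1 + 1)
        jj = d - ii
        diag = H[ii - 1, jj - 1] + S[ii - 1, jj - 1]
        up = H[ii - 1, jj] + gap
        left = H[ii, jj - 1] + gap
        best = np.maximum(diag, np.maximum(up, left))
        ptr = np.where(diag == best, 0, np.where(up == best, 1, 2))
        H[ii, jj] = best
        P[ii, jj] = ptr
    # traceback
    out_a, out_b = [], []
    i, j = la, lb
    if free_a_suffix:
        i = int(np.argmax(H[:, lb]))  # earliest maximal row on ties
        for k in range(la, i, -1):
            out_a.append(a[k - 1])
            out_b.append(GAP)
    score = int(H[i, lb]) if free_a_suffix else int(H[la, lb])
    while i > 0 or j > 0:
        p = P[i, j]
        if p == 0 and i > 0 and j > 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif p == 1 and i > 0:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                     score)


def local_align(a: str, b: str, match: int = MATCH, mismatch: int = MISMATCH,
                gap: int = GAP_SCORE) -> Alignment:
    """Smith-Waterman; traceback starts at the first-maximal cell."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    la, lb = len(a), len(b)
    S = np.where(_match_matrix(a, b), match, mismatch).astype(np.int32)
    H = np.zeros((la + 1, lb + 1), dtype=np.int32)
    P = np.zeros((la + 1, lb + 1), dtype=np.uint8)  # 0 stop/diag, 1 up, 2 left
    for d in range(2, la + lb + 1):
        i0, i1 = max(1, d - lb), min(la, d - 1)
        if i0 > i1:
            continue
        ii = np.arange(i0, i1 + 1)
        jj = d - ii
        diag = H[ii - 1, jj - 1] + S[ii - 1, jj - 1]
        up = H[ii - 1, jj] + gap
        left = H[ii, jj - 1] + gap
        best = np.maximum(0, np.maximum(diag, np.maximum(up, left)))
        ptr = np.where(diag == best, 0, np.where(up == best, 1, 2))
        H[ii, jj] = best
        P[ii, jj] = ptr
    if H.max() <= 0:
        return Alignment("", "", 0)
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    out_a, out_b = [], []
    while H[i, j] > 0:
        p = P[i, j]
        if p == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif p == 1:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                     int(H.max()))


def alignment_matches(aligned_a: str, aligned_b: str) -> int:
    """Identical non-gap, non-ambiguous column count of a fixed alignment."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    return int(_positions_match(aligned_a, aligned_b).sum())


def pairwise_identity(a, b, mode: Literal["global", "local", "ungapped"] = "global",
                      ) -> IdentityResult:
    """Percent-identity bookkeeping under three conventions.

    ``global``   aligns end to end and counts gap columns in the denominator;
    ``local``    counts over the best gapped local alignment only;
    ``ungapped`` requires equal lengths and counts per-position matches.
    """
    sa = a.seq if hasattr(a, "seq") else a
    sb = b.seq if hasattr(b, "seq") else b
    if not sa or not sb:
        raise ValueError("empty input sequence")
    if mode == "ungapped":
        if len(sa) != len(sb):
            raise ValueError("ungapped identity requires equal lengths")
        m = int(_positions_match(sa, sb).sum())
        return IdentityResult(m, len(sa), m / len(sa), mode)
    if mode == "global":
        aln = global_align(sa, sb)
    elif mode == "local":
        aln = local_align(sa, sb)
        if not aln.aligned_a:
            return IdentityResult(0, 0, 0.0, mode)
    else:
        raise ValueError(f"unknown identity mode {mode!r}")
    cols = len(aln.aligned_a)
    m = alignment_matches(aln.aligned_a, aln.aligned_b)
    return IdentityResult(m, cols, m / cols, mode)


# ---------------------------------------------------------------------------
# window profiles


def window_identity_profile(aligned_a: str, aligned_b: str,
                            window_size: int) -> WindowProfile:
    """Tile an alignment left to right into non-overlapping identity windows.

    Gap columns count as mismatches; a short final window is retained and
    its true width recorded.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    n = len(aligned_a)
    window_size = min(window_size, n)
    eq = _positions_match(aligned_a, aligned_b)
    windows = []
    for start in range(0, n, window_size):
        end = min(start + window_size, n)
        width = end - start
        ident = float(eq[start:end].sum()) / width
        windows.append((start + 1, end, ident))
    final_width = windows[-1][1] - windows[-1][0] + 1
    return WindowProfile(window_size, windows, final_width)


# ---------------------------------------------------------------------------
# ungapped local matches


def best_local_match(a, b, min_length: int = 1,
                     a_window: Optional[tuple] = None) -> Optional[LocalMatch]:
    """Highest-scoring ungapped segment pair under +1/-1 scoring.

    Ties break toward the longer segment, then the smaller ``a`` start, then
    the smaller ``b`` start.  Segments shorter than ``min_length`` or with a
    non-positive score are never reported.  ``a_window`` (1-based inclusive)
    restricts candidates to segments intersecting that interval of ``a``.
    """
    sa = a.seq if hasattr(a, "seq") else a
    sb = b.seq if hasattr(b, "seq") else b
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if not sa or not sb:
        return None
    n, m = len(sa), len(sb)
    S = np.where(_match_matrix(sa, sb), 1, -1).astype(np.int64)
    w0 = w1 = None
    if a_window is not None:
        w0, w1 = a_window[0] - 1, a_window[1] - 1  # 0-based inclusive
    best = None
    best_key = None
    for k in range(-(n - 1), m):
        diag = np.diagonal(S, offset=k)
        L = len(diag)
        if L < min_length:
            continue
        i0 = max(0, -k)
        j0 = i0 + k
        P = np.concatenate(([0], np.cumsum(diag)))
        runmin = np.minimum.accumulate(P)
        idx = np.arange(L + 1)
        # index of the earliest prefix attaining the running minimum:
        # a strict decrease resets the argmin, ties keep the earlier index
        reset = np.concatenate(([True], P[1:] < runmin[:-1]))
        first_argmin = np.maximum.accumulate(np.where(reset, idx, 0))
        e_lo = min_length
        s_cap_const = L - min_length
        if w0 is not None:
            # a segment [s, e) on this diagonal covers a rows i0+s .. i0+e-1
            e_lo = max(e_lo, w0 - i0 + 1)
            s_cap_const = min(s_cap_const, w1 - i0)
            if s_cap_const < 0 or e_lo > L:
                continue
        e_vals = np.arange(e_lo, L + 1)
        if len(e_vals) == 0:
            continue
        s_cap = np.minimum(e_vals - min_length, s_cap_const)
        scores = P[e_vals] - runmin[s_cap]
        cmax = int(scores.max())
        if cmax <= 0:
            continue
        for t in np.flatnonzero(scores == cmax):
            e = int(e_vals[t])
            s = int(first_argmin[s_cap[t]])
            length = e - s
            matches = (cmax + length) // 2
            a_start0 = i0 + s
            b_start0 = j0 + s
            key = (-cmax, -length, a_start0, b_start0)
            if best_key is None or key < best_key:
                best_key = key
                best = LocalMatch(a_start0 + 1, a_start0 + length,
                                  b_start0 + 1, b_start0 + length,
                                  length, matches, matches / length)
    return best


def local_score_batch(queries: Sequence[str], donor: str,
                      min_length: int = 1, chunk: int = 128) -> np.ndarray:
    """Max ungapped +1/-1 local score of ``donor`` against many queries.

    Scoring is identical to :func:`best_local_match` but only the score is
    returned; used to rank shuffle nulls cheaply.  Queries must share one
    length.
    """
    if not queries:
        return np.zeros(0)
    n = len(queries[0])
    m = len(donor)
    if any(len(q) != n for q in queries):
        raise ValueError("queries must have equal length")
    L = min(n, m)
    if L < min_length:
        return np.zeros(len(queries))
    D = _bytes(donor)
    ii, jj = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
    diag_id = jj - ii + n - 1
    pos = np.minimum(ii, jj)
    ndiag = n + m - 1
    amb_codes = [ord(s) for s in _ambiguous_for(donor, *queries[:1])]
    out = np.empty(len(queries))
    for c0 in range(0, len(queries), chunk):
        batch = queries[c0 : c0 + chunk]
        Q = np.stack([_bytes(q) for q in batch])
        eq = Q[:, :, None] == D[None, None, :]
        for code in amb_codes:
            eq &= (Q[:, :, None] != code) & (D[None, None, :] != code)
        S = np.where(eq, 1, -1).astype(np.int32)
        Dm = np.full((len(batch), ndiag, L), -10000, dtype=np.int32)
        Dm[:, diag_id, pos] = S
        P = np.concatenate(
            [np.zeros((len(batch), ndiag, 1), dtype=np.int64),
             np.cumsum(Dm, axis=2, dtype=np.int64)], axis=2)
        runmin = np.minimum.accumulate(P[:, :, : L - min_length + 1], axis=2)
        scores = P[:, :, min_length:] - runmin
        out[c0 : c0 + len(batch)] = scores.reshape(len(batch), -1).max(axis=1)
    return np.maximum(out, 0)


# ---------------------------------------------------------------------------
# inverted repeats (self dot-plot against the reverse complement)


def find_inverted_repeats(seq, min_arm: int = 3,
                          max_mismatch: int = 0) -> list:
    """All maximal non-overlapping inverted-repeat arm pairs.

    An arm pair (left ``[a, b]``, right ``[j1, j2]``) lies on one
    anti-diagonal of the self-versus-reverse-complement dot plot:
    position ``a+t`` of the left arm pairs with position ``j2-t`` of the
    right arm.  A pair is reported when the pairing holds with at most
    ``max_mismatch`` mismatches and neither arm can be extended (outward or
    inward) without breaking the mismatch budget, the sequence bounds, or
    arm disjointness.
    """
    s = (seq.seq if hasattr(seq, "seq") else seq).upper()
    if min_arm < 3:
        raise ValueError("min_arm must be >= 3")
    n = len(s)
    comp = s.translate(_COMPLEMENT)  # complement without reversal
    results = []
    for d in range(1, 2 * n - 2):  # d = i + j with i < j
        i_min = max(0, d - n + 1)
        i_max = (d - 1) // 2
        width = i_max - i_min + 1
        if width < min_arm:
            continue
        mism = np.array(
            [0 if (s[i] == comp[d - i] and s[i] not in AMBIGUOUS) else 1
             for i in range(i_min, i_max + 1)], dtype=np.int64)
        csum = np.concatenate(([0], np.cumsum(mism)))
        # two-pointer over [i_min, i_max]; a = left end index rel. to i_min
        a_of = np.empty(width, dtype=np.int64)
        a = 0
        for b in range(width):
            while csum[b + 1] - csum[a] > max_mismatch:
                a += 1
            a_of[b] = a
        for b in range(width):
            if b + 1 < width and a_of[b + 1] == a_of[b]:
                continue  # right-extensible: not maximal
            a = int(a_of[b])
            length = b - a + 1
            if length < min_arm:
                continue
            la, lb = i_min + a, i_min + b
            results.append(InvertedRepeat(
                left_arm=(la + 1, lb + 1),
                right_arm=(d - lb + 1, d - la + 1),
                arm_length=length,
                mismatches=int(csum[b + 1] - csum[a]),
            ))
    results.sort(key=lambda r: (r.left_arm, r.right_arm))
    return results
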