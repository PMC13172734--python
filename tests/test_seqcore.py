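"""Sequence primitives: identity counting, windows, local matches, repeats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from Bio.Seq import Seq

from knotarch import seqcore as sc
from oracles import brute_inverted_repeats, brute_local_match

DNA = st.text(alphabet="ACGT", min_size=1, max_size=60)


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


# ---------------------------------------------------------------------------
# FASTA


def test_fasta_roundtrip(tmp_path, rng):
    seqs = [sc.NtSeq(f"s{i}", _random_dna(rng, int(rng.integers(10, 200))))
            for i in range(100)]
    path = tmp_path / "x.fa"
    sc.write_fasta(seqs, path)
    back = sc.read_fasta(path, alphabet="nt")
    assert [b.id for b in back] == [s.id for s in seqs]
    assert [b.seq for b in back] == [s.seq for s in seqs]


def test_fasta_lowercase_normalised(tmp_path):
    (tmp_path / "y.fa").write_text(">a\nacgt\n")
    assert sc.read_fasta(tmp_path / "y.fa")[0].seq == "ACGT"


def test_fasta_duplicate_id_error(tmp_path):
    (tmp_path / "dup.fa").write_text(">a\nACGT\n>a\nACGT\n")
    with pytest.raises(ValueError, match="a"):
        sc.read_fasta(tmp_path / "dup.fa")


# ---------------------------------------------------------------------------
# identity


@pytest.mark.parametrize("a,b,matches,columns", [
    ("VPIS", "APIT", 2, 4),   # linker vs tail of the bivalent knottin
    ("ACGT", "ACGT", 4, 4),
    ("ACGT", "TTTT", 1, 4),
])
def test_ungapped_identity_counts(a, b, matches, columns):
    r = sc.pairwise_identity(a, b, mode="ungapped")
    assert (r.matches, r.columns) == (matches, columns)
    assert r.identity == pytest.approx(matches / columns)


def test_ungapped_requires_equal_length():
    with pytest.raises(ValueError):
        sc.pairwise_identity("ACGT", "ACG", mode="ungapped")
    with pytest.raises(ValueError):
        sc.pairwise_identity("", "ACG", mode="ungapped")


def test_ambiguity_never_matches():
    assert sc.pairwise_identity("NNNN", "NNNN", mode="ungapped").matches == 0
    assert sc.pairwise_identity("XA", "XA", mode="ungapped").matches == 1


def test_global_identity_counts_gap_columns():
    r = sc.pairwise_identity("ACGTACGT", "ACGACGT", mode="global")
    assert r.columns == 8  # one gap column in the denominator
    assert r.matches == 7


@settings(derandomize=True, max_examples=60, deadline=None)
@given(DNA, DNA)
def test_identity_symmetric(a, b):
    for mode in ("global", "local"):
        ra = sc.pairwise_identity(a, b, mode=mode)
        rb = sc.pairwise_identity(b, a, mode=mode)
        assert ra.identity == pytest.approx(rb.identity)


# ---------------------------------------------------------------------------
# window profiles


def test_window_profile_examples():
    p = sc.window_identity_profile("A" * 10, "A" * 10, 5)
    assert [w[2] for w in p.windows] == [1.0, 1.0]
    a, b = "AAAAAAAAAA", "AACAAAAAAA"
    p = sc.window_identity_profile(a, b, 5)
    assert [w[2] for w in p.windows] == [0.8, 1.0]
    p = sc.window_identity_profile("A" * 12, "A" * 12, 5)
    assert len(p.windows) == 3 and p.final_window_width == 2


def test_window_profile_oversized_window():
    p = sc.window_identity_profile("ACGT", "ACGT", 100)
    assert len(p.windows) == 1 and p.windows[0] == (1, 4, 1.0)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.integers(1, 9), DNA)
def test_window_matches_sum_to_global(w, a):
    rng = np.random.default_rng(len(a))
    b = "".join(c if rng.random() < 0.7 else "ACGT"[int(rng.integers(4))]
                for c in a)
    prof = sc.window_identity_profile(a, b, w)
    total = sum(round(v * (e - s + 1)) for s, e, v in prof.windows)
    assert total == sc.pairwise_identity(a, b, mode="ungapped").matches
    # windows tile the alignment exactly
    assert prof.windows[0][0] == 1 and prof.windows[-1][1] == len(a)
    for (s1, e1, _), (s2, e2, _) in zip(prof.windows, prof.windows[1:]):
        assert s2 == e1 + 1


# ---------------------------------------------------------------------------
# translation


def test_translate_examples():
    assert sc.translate("ATGTGA", 1) == "M*"
    assert sc.translate("TGT", 1) == "C"
    assert sc.translate("TGA", 1) == "*"
    with pytest.raises(ValueError):
        sc.translate("AC", 1)


def test_six_frame_matches_reference_translator(rng):
    nt = _random_dna(rng, 60)
    frames = sc.six_frame(nt)
    for f in (1, 2, 3):
        s = nt[f - 1:]
        s = s[: len(s) - len(s) % 3]
        assert frames[f] == str(Seq(s).translate())
        r = str(Seq(nt).reverse_complement())[f - 1:]
        r = r[: len(r) - len(r) % 3]
        assert frames[-f] == str(Seq(r).translate())


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.text(alphabet="ACGT", min_size=3, max_size=50))
def test_translate_revcomp_is_reverse_frame(nt):
    assert sc.translate(sc.revcomp(nt), 1) == sc.translate(nt, -1)


# ---------------------------------------------------------------------------
# local matches


def test_local_match_trivial_cases():
    assert sc.best_local_match("A" * 30, "C" * 30, 5) is None
    with pytest.raises(ValueError):
        sc.best_local_match("ACGT", "ACGT", 0)


def test_local_match_recovers_planted_segment(rng):
    a = _random_dna(rng, 300)
    b = _random_dna(rng, 300)
    seg = _random_dna(rng, 30)
    a2 = a[:100] + seg + a[130:]
    b2 = b[:50] + seg + b[80:]
    m = sc.best_local_match(a2, b2, min_length=10)
    # the planted diagonal wins; break-even flanks may extend the segment
    assert m.a_start <= 101 and m.a_end >= 130
    assert m.b_start - m.a_start == 51 - 101
    assert m.matches - (m.length - m.matches) >= 30


@pytest.mark.parametrize("seed", range(12))
def test_local_match_agrees_with_bruteforce(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 60))
    a = _random_dna(rng, n)
    b = _random_dna(rng, int(rng.integers(20, 60)))
    if seed % 3 == 0:  # plant some shared sequence
        k = int(rng.integers(8, 15))
        seg = _random_dna(rng, k)
        a = a[:5] + seg + a[5 + k:]
        b = b[:2] + seg + b[2 + k:]
    min_len = int(rng.integers(1, 8))
    got = sc.best_local_match(a, b, min_len)
    exp = brute_local_match(a, b, min_len)
    if exp is None:
        assert got is None
    else:
        score, L, a0, b0, a1, b1 = exp
        assert (got.a_start, got.b_start, got.a_end, got.b_end) == \
            (a0, b0, a1, b1)
        assert 2 * got.matches - got.length == score


def test_local_score_batch_matches_single(rng):
    donor = _random_dna(rng, 40)
    queries = [_random_dna(rng, 120) for _ in range(20)]
    batch = sc.local_score_batch(queries, donor, min_length=6)
    for q, s in zip(queries, batch):
        m = sc.best_local_match(q, donor, 6)
        exp = 0 if m is None else 2 * m.matches - m.length
        assert s == exp


def test_local_match_window_restriction(rng):
    a = _random_dna(rng, 120)
    b = _random_dna(rng, 120)
    seg1, seg2 = _random_dna(rng, 20), _random_dna(rng, 14)
    a2 = seg1 + a[20:90] + seg2 + a[104:]
    b2 = seg1 + b[20:90] + seg2 + b[104:]
    full = sc.best_local_match(a2, b2, 8)
    assert full.a_start == 1  # the longer plant wins overall
    windowed = sc.best_local_match(a2, b2, 8, a_window=(91, 104))
    assert windowed.a_start <= 104 and windowed.a_end >= 91
    assert windowed.matches >= 14


# ---------------------------------------------------------------------------
# inverted repeats


def test_inverted_repeat_canonical_palindrome():
    hits = sc.find_inverted_repeats("GAATTC", min_arm=3, max_mismatch=0)
    assert len(hits) == 1
    assert hits[0].left_arm == (1, 3) and hits[0].right_arm == (4, 6)
    assert hits[0].mismatches == 0


def test_inverted_repeat_min_arm_validation():
    with pytest.raises(ValueError):
        sc.find_inverted_repeats("ACGT", min_arm=2)


@pytest.mark.parametrize("seed,max_mm", [(0, 0), (1, 0), (2, 1), (3, 1),
                                         (4, 2)])
def test_inverted_repeats_agree_with_bruteforce(seed, max_mm):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(60, 150))
    s = _random_dna(rng, n)
    if seed % 2:  # plant a palindrome
        arm = _random_dna(rng, 10)
        s = s[:20] + arm + s[30:40] + sc.revcomp(arm) + s[50:]
    got = [(h.left_arm, h.right_arm, h.arm_length, h.mismatches)
           for h in sc.find_inverted_repeats(s, min_arm=6,
                                             max_mismatch=max_mm)]
    assert got == brute_inverted_repeats(s, 6, max_mm)
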