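"""Pseudogene remnant detection and loss-mechanism classification."""

from collections import Counter

import numpy as np
import pytest

from knotarch import forensics as fx
from knotarch.architecture import partition_architecture
from knotarch.seqcore import NtSeq, revcomp
from knotarch.simulate import (SimConfig, apply_duplication, evolve_branch,
                               make_ancestor, simulate_loss_pair)


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


# ---------------------------------------------------------------------------
# PSSM


def test_pssm_hand_computed_log_odds():
    """3-sequence x 4-column toy alignment, pseudocount 0.5."""
    pssm = fx.build_pssm(["ACGT", "ACGA", "ATGA"], pseudocount=0.5)
    expected = np.array([
        [0.833350, -0.836501, -1.321928, -0.836501],
        [-1.974005, 1.485427, -1.321928, 0.748461],
        [-1.974005, -0.836501, 1.485427, -0.836501],
        [0.347923, -0.836501, -1.321928, 0.748461]])
    assert pssm.alphabet == "ACGT"
    np.testing.assert_allclose(pssm.log_odds, expected, atol=1e-5)
    assert pssm.score("ACGT") == pytest.approx(4.552665, abs=1e-5)


def test_pssm_single_sequence_scores_itself_maximal():
    pssm = fx.build_pssm(["ACGTAC"])
    # per-column self-score is the column maximum
    for j, c in enumerate("ACGTAC"):
        col = pssm.log_odds[j]
        assert col[pssm.alphabet.index(c)] == pytest.approx(col.max())


def test_pssm_consensus_dominates():
    pssm = fx.build_pssm(["AAC", "AGC", "ATC"])
    col0 = pssm.log_odds[0]
    assert np.argmax(col0) == pssm.alphabet.index("A")


def test_pssm_ragged_alignment_error():
    with pytest.raises(ValueError, match="ragged"):
        fx.build_pssm(["ACGT", "ACG"])


def test_pssm_scan_equals_windowed_scores(rng):
    pssm = fx.build_pssm([_random_dna(rng, 12) for _ in range(4)])
    seq = _random_dna(rng, 60)
    scores = pssm.scan(seq)
    assert len(scores) == 49
    for off in (0, 17, 48):
        assert scores[off] == pytest.approx(pssm.score(seq[off : off + 12]))


# ---------------------------------------------------------------------------
# dinucleotide shuffle


@pytest.mark.parametrize("seed", range(5))
def test_dinucleotide_shuffle_preserves_counts(seed):
    rng = np.random.default_rng(seed)
    s = _random_dna(rng, 200)
    sh = fx.dinucleotide_shuffle(s, rng)
    dinucs = lambda x: Counter(x[i : i + 2] for i in range(len(x) - 1))
    assert dinucs(sh) == dinucs(s)
    assert sh[0] == s[0] and sh[-1] == s[-1]
    assert Counter(sh) == Counter(s)


def test_dinucleotide_shuffle_deterministic():
    s = "ACGTACGGTTAACCGATCGATCGGCTAACGT"
    a = fx.dinucleotide_shuffle(s, np.random.default_rng(7))
    b = fx.dinucleotide_shuffle(s, np.random.default_rng(7))
    assert a == b


# ---------------------------------------------------------------------------
# UTR remnant scanning


def test_remnant_scan_recovers_planted_domain(rng):
    """A 10%-diverged domain copy planted in a 3'UTR is found in the UTR."""
    donor = _random_dna(rng, 100)
    degraded = "".join(c if rng.random() > 0.10 else
                       "ACGT"[int(rng.integers(4))] for c in donor)
    cds = _random_dna(rng, 180)
    utr = _random_dna(rng, 40) + degraded + _random_dna(rng, 40)
    hits = fx.scan_utr_remnant(NtSeq("q", cds + utr), NtSeq("d", donor),
                               cds_end=180, null_shuffles=200, seed=0)
    nt_hits = [h for h in hits if h.level == "nt"]
    assert nt_hits and nt_hits[0].in_utr
    s, e = nt_hits[0].target_interval
    plant = (221, 320)
    overlap = min(e, plant[1]) - max(s, plant[0]) + 1
    assert overlap >= 0.8 * 100


def test_remnant_scan_null_is_quiet(rng):
    hits_found = 0
    for i in range(8):
        q = _random_dna(rng, 300)
        d = _random_dna(rng, 90)
        hits = fx.scan_utr_remnant(NtSeq("q", q), NtSeq("d", d), cds_end=150,
                                   null_shuffles=150, seed=i)
        hits_found += bool(hits)
    assert hits_found <= 1


def test_remnant_scan_requires_boundary(rng):
    with pytest.raises(ValueError):
        fx.scan_utr_remnant(NtSeq("q", _random_dna(rng, 100)),
                            NtSeq("d", _random_dna(rng, 30)))


def test_remnant_frame_interval_mapping():
    assert fx._frame_to_nt(1, 2, 4, 100) == (4, 12)
    assert fx._frame_to_nt(2, 1, 2, 100) == (2, 7)
    # reverse frame: positions count from the 3' end
    s, e = fx._frame_to_nt(-1, 1, 2, 100)
    assert (s, e) == (95, 100)


# ---------------------------------------------------------------------------
# crossover breakpoints


def test_breakpoint_identical_domains_unidentifiable(rng):
    d = _random_dna(rng, 90)
    bp = fx.locate_crossover_breakpoint(d, d, d)
    assert not bp.chimeric
    assert bp.interval[0] == 0 and bp.interval[1] == len(d)


@pytest.mark.parametrize("seed", range(10))
def test_breakpoint_recovered_on_synthetic_fusions(seed):
    """Fusion of 20%-diverged copies: the interval contains the true b."""
    rng = np.random.default_rng(seed)
    d1 = _random_dna(rng, 90)
    d2 = "".join(c if rng.random() > 0.2 else "ACGT"[int(rng.integers(4))]
                 for c in d1)
    b = int(rng.integers(25, 65))
    chim = d1[:b] + d2[b:]
    bp = fx.locate_crossover_breakpoint(chim, d1, d2)
    assert bp.chimeric
    assert bp.interval[0] <= b <= bp.interval[1]


def test_crossover_byproducts_identity_and_conservation(rng):
    d = _random_dna(rng, 60)
    contracted, expanded = fx.crossover_byproducts(d, d, 30)
    assert contracted == d
    d1, d2 = _random_dna(rng, 60), _random_dna(rng, 60)
    linker = _random_dna(rng, 12)
    c, e = fx.crossover_byproducts(d1, d2, 25, linker=linker)
    assert len(c) + len(e) == 2 * (len(d1) + len(d2) + len(linker))
    assert d1 in e and d2 in e  # both parents survive verbatim


# ---------------------------------------------------------------------------
# mechanism classification


@pytest.mark.parametrize("mech", ["nonsense_point", "deletion_stop",
                                  "fusion_crossover", "te_disruption"])
def test_classify_recovers_fresh_events(mech):
    """At zero post-event divergence the evidence matches the planted truth."""
    mono, anc, tes, ev = simulate_loss_pair(mech, seed=51, divergence=0.0)
    call = fx.classify_loss_mechanism(mono, anc, tes=tes)
    assert call.mechanism == mech
    if mech == "nonsense_point":
        assert call.evidence["stop_position_bp"] == ev["cds_pos"]
        assert call.evidence["codon_to"] in fx.STOP_CODONS
        assert sum(a != b for a, b in zip(call.evidence["codon_from"],
                                          call.evidence["codon_to"])) == 1
        assert fx.verify_loss_call(call, mono, anc)
    elif mech == "deletion_stop":
        a0, a1 = call.evidence["deletion_interval"]
        t0, t1 = ev["cds_interval"]
        assert call.evidence["deletion_length"] == t1 - t0 + 1
        assert abs(a0 - t0) <= 6  # gap placement within a repeat is free
    elif mech == "fusion_crossover":
        assert call.evidence["facilitating"] is not None
        assert call.evidence["p_value"] <= 0.05
    else:
        assert call.evidence["te"].family == ev["family"]


def test_verify_deletion_replay():
    mono, anc, tes, ev = simulate_loss_pair("deletion_stop", seed=77,
                                            divergence=0.0)
    call = fx.classify_loss_mechanism(mono, anc)
    assert call.mechanism == "deletion_stop"
    assert fx.verify_loss_call(call, mono, anc)


def test_classify_requires_multivalent_ancestor():
    mono, anc, tes, ev = simulate_loss_pair("nonsense_point", seed=5,
                                            divergence=0.0)
    with pytest.raises(ValueError, match="multivalent"):
        fx.classify_loss_mechanism(mono, mono)


def test_classify_monotone_degradation():
    """Recovery does not improve as divergence grows (checked in expectation)."""
    rates = []
    for div in (0.02, 0.16):
        ok = 0
        for s in range(12):
            mono, anc, tes, ev = simulate_loss_pair(
                "nonsense_point", seed=900 + s, divergence=div)
            call = fx.classify_loss_mechanism(mono, anc, tes=tes)
            ok += call.mechanism == "nonsense_point"
        rates.append(ok / 12)
    assert rates[-1] <= rates[0]
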