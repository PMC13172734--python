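"""Framework scanning, architecture partitioning and gene-structure checks."""

import numpy as np
import pytest

from knotarch.architecture import (linker_conservation, linker_tail_homology,
                                   partition_architecture,
                                   scan_ick_frameworks,
                                   validate_gene_structure)
from knotarch.genemodels import GeneModel
from knotarch.simulate import (SimConfig, apply_duplication, domain_peptide,
                               make_ancestor)
from oracles import brute_frameworks

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_peptide(rng, n, p_cys=0.25):
    out = []
    for _ in range(n):
        if rng.random() < p_cys:
            out.append("C")
        else:
            out.append(AA[int(rng.integers(len(AA)))])
    return "".join(out)


# ---------------------------------------------------------------------------
# scanner


def test_scanner_minimal_spacing_framework():
    hits = scan_ick_frameworks("CAACAAACCACAAAC")
    assert len(hits) == 1
    assert (hits[0].start, hits[0].end) == (1, 15)
    assert hits[0].spacings == (2, 3, 1, 3)


def test_scanner_no_cysteines():
    assert scan_ick_frameworks("AAAAA") == []
    with pytest.raises(ValueError):
        scan_ick_frameworks("")


def test_scanner_match_invariants(rng):
    for _ in range(200):
        pep = _random_peptide(rng, int(rng.integers(15, 80)))
        for m in scan_ick_frameworks(pep, all_matches=True):
            assert all(pep[p - 1] == "C" for p in m.cys_positions)
            assert m.cys_positions[3] - m.cys_positions[2] == 1
            assert list(m.cys_positions) == sorted(m.cys_positions)


@pytest.mark.parametrize("seed", range(5))
def test_scanner_agrees_with_bruteforce(seed):
    """Greedy non-overlapping scan matches exhaustive spacing enumeration."""
    rng = np.random.default_rng(seed)
    for _ in range(250):
        pep = _random_peptide(rng, int(rng.integers(10, 80)),
                              p_cys=float(rng.uniform(0.1, 0.4)))
        got = [(tuple(p - 1 for p in m.cys_positions))
               for m in scan_ick_frameworks(pep)]
        assert got == brute_frameworks(pep, greedy=True)
        got_all = [tuple(p - 1 for p in m.cys_positions)
                   for m in scan_ick_frameworks(pep, all_matches=True)]
        assert got_all == brute_frameworks(pep, greedy=False)


# ---------------------------------------------------------------------------
# partitioning


def test_partition_monovalent(rng):
    dom = domain_peptide((3, 5, 2, 4), rng)
    pep = "MA" + dom + "QRST"
    arch = partition_architecture(pep, "p1")
    assert arch.valency == 1
    assert arch.leader == "MA" and arch.tail == "QRST"
    assert arch.linkers == []
    assert arch.reconstruct() == pep


def test_partition_bivalent_planted_spacer(rng):
    dom = domain_peptide((4, 6, 2, 5), rng)
    spacer = "VPISQR"
    pep = dom + spacer + dom + "APIT"
    arch = partition_architecture(pep)
    assert arch.valency == 2
    assert arch.linkers[0].seq == spacer
    assert arch.tail == "APIT"
    assert arch.reconstruct() == pep


def test_partition_non_ick():
    arch = partition_architecture("MKLLAVAA")
    assert arch.valency == 0 and not arch.is_ick
    assert arch.reconstruct() == "MKLLAVAA"


def test_reconstruction_character_exact(rng):
    """Partition must reconstruct random peptides exactly, ICK or not."""
    for _ in range(300):
        pep = _random_peptide(rng, int(rng.integers(5, 90)))
        assert partition_architecture(pep).reconstruct() == pep


def test_trivalent_architecture(rng):
    cfg = SimConfig(seed=9)
    gene = make_ancestor(cfg)
    g2, _ = apply_duplication(gene, rng)
    g3, _ = apply_duplication(g2, rng)
    arch = partition_architecture(g3.precursor().mature_peptide)
    assert arch.valency == 3
    assert len(arch.linkers) == 2


# ---------------------------------------------------------------------------
# linker conservation and linker/tail homology


def test_linker_conservation_identical():
    archs = []
    for i in range(3):
        pep_dom = "C" + "AA" + "C" + "DEF" + "CC" + "G" + "C" + "HIK" + "C"
        pep = pep_dom + "VPIS" + pep_dom
        archs.append(partition_architecture(pep, f"p{i}"))
    table = linker_conservation(archs)
    assert all(flag for _, flag in table.positions)
    assert table.mean_pairwise_identity == pytest.approx(1.0)
    assert table.conserved_prefix() == 4


def test_linker_conservation_prefix():
    dom = "C" + "AA" + "C" + "DEF" + "CC" + "G" + "C" + "HIK" + "C"
    linkers = ["VPIS", "VPIT", "VPIAG"]
    archs = [partition_architecture(dom + lk + dom, f"p{i}")
             for i, lk in enumerate(linkers)]
    table = linker_conservation(archs)
    assert table.conserved_prefix() == 3  # V, P, I conserved; position 4 not


def test_linker_conservation_needs_two_multivalent():
    dom = "C" + "AA" + "C" + "DEF" + "CC" + "G" + "C" + "HIK" + "C"
    arch = partition_architecture(dom + "VPIS" + dom)
    with pytest.raises(ValueError):
        linker_conservation([arch])


def test_linker_tail_homology_values():
    dom = "C" + "AA" + "C" + "DEF" + "CC" + "G" + "C" + "HIK" + "C"
    arch = partition_architecture(dom + "VPIS" + dom + "APIT")
    r = linker_tail_homology(arch)
    assert (r.matches, r.columns) == (2, 4)
    # fresh duplication: linker copied from the ancestral tail
    arch2 = partition_architecture(dom + "APIT" + dom + "APIT")
    assert linker_tail_homology(arch2).identity == pytest.approx(1.0)


def test_linker_tail_homology_monovalent_error():
    dom = "C" + "AA" + "C" + "DEF" + "CC" + "G" + "C" + "HIK" + "C"
    with pytest.raises(ValueError):
        linker_tail_homology(partition_architecture(dom + "QRST"))


def test_linker_tail_decay_with_divergence():
    """Expected linker/tail identity decays monotonically with divergence."""
    from knotarch.simulate import evolve_branch

    cfg = SimConfig(seed=5)
    means = []
    for steps in (0, 2, 6):
        vals = []
        for rep in range(25):
            rng = np.random.default_rng(1000 + rep)
            g, _ = apply_duplication(make_ancestor(SimConfig(seed=rep)), rng)
            for _ in range(steps):
                g, _ = evolve_branch(g, cfg, 1.0, rng)
            arch = partition_architecture(g.precursor().mature_peptide)
            if arch.valency >= 2 and arch.tail:
                vals.append(linker_tail_homology(arch).identity)
        means.append(np.mean(vals))
    assert means[0] == pytest.approx(1.0)
    assert means[0] > means[1] > means[2]


# ---------------------------------------------------------------------------
# gene structure


def test_conformant_gene_passes(ancestor_gene):
    rep = validate_gene_structure(ancestor_gene.gene_model(),
                                  ancestor_gene.contig_seq)
    assert rep.verdicts == {"three_exons": True, "phase_1_then_2": True,
                            "mature_in_last_exon": True,
                            "no_interdomain_intron": True}
    assert rep.intron_phases == [1, 2]


def test_two_exon_gene_fails_exon_count(ancestor_gene):
    g = ancestor_gene
    model = g.gene_model()
    # merge exons 2 and 3 (drop the second intron from the contig)
    p = g.parts
    contig = (p["flank5"] + p["exon1"] + p["intron1"] + p["exon2"] +
              p["exon3cds"] + p["utr3"] + p["flank3"])
    s1 = len(p["flank5"]) + 1
    e1 = (s1, s1 + len(p["exon1"]) - 1)
    s2 = e1[1] + 1 + len(p["intron1"])
    e2 = (s2, s2 + len(p["exon2"]) + len(p["exon3cds"]) + len(p["utr3"]) - 1)
    cds2 = (s2, s2 + len(p["exon2"]) + len(p["exon3cds"]) - 1)
    model2 = GeneModel(g.gene_id, g.gene_id, "+", [e1, e2], [e1, cds2])
    rep = validate_gene_structure(model2, contig)
    assert not rep.verdicts["three_exons"]


def test_interdomain_intron_detected(bivalent_gene):
    """An intron inserted between the two domains must be flagged."""
    g = bivalent_gene
    p = g.parts
    arch = partition_architecture(g.precursor().mature_peptide)
    pro_end = g.signal_len + g.pro_len
    # CDS position inside the linker, between domain 1 end and domain 2 start
    cut_cds = 3 * (pro_end + arch.domains[0].end + 1)
    off3 = g.cds_offset3
    cut = cut_cds - off3  # position within exon3cds
    intron = "GT" + "ATATAT" * 20 + "AG"
    e3a, e3b = p["exon3cds"][:cut], p["exon3cds"][cut:]
    contig = (p["flank5"] + p["exon1"] + p["intron1"] + p["exon2"] +
              p["intron2"] + e3a + intron + e3b + p["utr3"] + p["flank3"])
    pos = len(p["flank5"]) + 1
    e1 = (pos, pos + len(p["exon1"]) - 1)
    pos = e1[1] + 1 + len(p["intron1"])
    e2 = (pos, pos + len(p["exon2"]) - 1)
    pos = e2[1] + 1 + len(p["intron2"])
    e3 = (pos, pos + len(e3a) - 1)
    pos = e3[1] + 1 + len(intron)
    e4 = (pos, pos + len(e3b) + len(p["utr3"]) - 1)
    cds4 = (pos, pos + len(e3b) - 1)
    model = GeneModel(g.gene_id, g.gene_id, "+", [e1, e2, e3, e4],
                      [e1, e2, e3, cds4])
    rep = validate_gene_structure(model, contig)
    assert rep.interdomain_intron
    assert not rep.verdicts["no_interdomain_intron"]


def test_frame_inconsistency_raises(ancestor_gene):
    g = ancestor_gene
    model = g.gene_model()
    bad = GeneModel(g.gene_id, g.gene_id, "+", model.exons,
                    [(s, e - 1) for s, e in model.cds[:1]] + model.cds[1:])
    with pytest.raises(ValueError, match="junction"):
        validate_gene_structure(bad, g.contig_seq)
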