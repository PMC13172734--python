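"""TE flank densities, resampling comparison, tracks and shared families."""

import numpy as np
import pytest
from scipy import stats

from knotarch import teassoc as ta
from oracles import brute_coverage

RM_OUT = """\
   SW   perc perc perc  query     position in query    matching repeat
score   div. del. ins.  sequence  begin end (left)     repeat class/family  begin end (left) ID

 1306   15.6  6.2  0.0  ctg1      100   520  (8000) +  Mariner-7  DNA/Tc1-Mariner   1  450  (0)   1
  567    8.1  0.0  1.2  ctg1      600   900  (7600) C  Gypsy-3    LTR/Gypsy         2  300  (10)  2
  220    2.0  0.0  0.0  ctg2      50    120   (500) +  R2-1       LINE/R2           1   70  (0)   3
"""


def _genes_and_tes(rng, n_genes=10, contig_len=30000, flank=2000):
    genes, tes = [], []
    lengths = {}
    for i in range(n_genes):
        contig = f"c{i}"
        start = int(rng.integers(flank + 1, contig_len - flank - 3000))
        end = start + int(rng.integers(500, 2500))
        genes.append(ta.Gene(f"g{i}", contig, start, end, is_ick=i % 2 == 0))
        lengths[contig] = contig_len
        for _ in range(int(rng.integers(0, 12))):
            s = int(rng.integers(1, contig_len - 500))
            e = s + int(rng.integers(50, 900))
            cls = "II" if rng.random() < 0.6 else "I"
            tes.append(ta.TeAnnotation(contig, s, e, family=f"f{int(rng.integers(8))}",
                                       te_class=cls))
    return genes, tes, lengths


# ---------------------------------------------------------------------------
# readers


def test_repeatmasker_out_parser(tmp_path):
    p = tmp_path / "rm.out"
    p.write_text(RM_OUT)
    tes = ta.read_repeatmasker_out(p)
    assert len(tes) == 3
    assert tes[0].contig == "ctg1" and (tes[0].start, tes[0].end) == (100, 520)
    assert tes[0].te_class == "II" and tes[0].divergence == 15.6
    assert tes[1].te_class == "I"  # LTR/Gypsy is a retroelement
    assert tes[2].superfamily == "R2"


def test_bed_roundtrip(tmp_path):
    p = tmp_path / "tes.bed"
    p.write_text("c1\t99\t520\tMariner-7|Tc1/Mariner|II|15.60\n")
    tes = ta.read_te_bed(p)
    assert tes[0].start == 100 and tes[0].end == 520
    assert tes[0].family == "Mariner-7" and tes[0].te_class == "II"


# ---------------------------------------------------------------------------
# flank density


def test_density_trivial_cases():
    genes = [ta.Gene("g", "c", 6000, 8000)]
    lengths = {"c": 20000}
    df, exc = ta.flank_te_density(genes, [], lengths, flank_bp=5000)
    assert df["density_all"].iloc[0] == 0.0
    # one TE covering the whole upstream flank, nothing downstream
    tes = [ta.TeAnnotation("c", 1000, 5999, te_class="II")]
    df, _ = ta.flank_te_density(genes, tes, lengths, flank_bp=5000)
    assert df["density_all"].iloc[0] == pytest.approx(0.5)
    assert df["density_II"].iloc[0] == pytest.approx(0.5)
    assert df["density_I"].iloc[0] == 0.0
    with pytest.raises(ValueError):
        ta.flank_te_density(genes, tes, lengths, flank_bp=0)


def test_density_excludes_genes_without_full_flanks():
    genes = [ta.Gene("edge", "c", 100, 600), ta.Gene("ok", "c", 6000, 8000)]
    df, excluded = ta.flank_te_density(genes, [], {"c": 20000}, flank_bp=5000)
    assert excluded == ["edge"]
    assert set(df["gene_id"]) | set(excluded) == {"edge", "ok"}


@pytest.mark.parametrize("seed", range(6))
def test_density_agrees_with_per_bp_oracle(seed):
    rng = np.random.default_rng(seed)
    genes, tes, lengths = _genes_and_tes(rng)
    flank = 2000
    df, excluded = ta.flank_te_density(genes, tes, lengths, flank_bp=flank)
    for _, row in df.iterrows():
        g = next(x for x in genes if x.gene_id == row["gene_id"])
        ivs_all = [(t.start, t.end) for t in tes if t.contig == g.contig]
        cov = (brute_coverage(ivs_all, g.start - flank, g.start - 1) +
               brute_coverage(ivs_all, g.end + 1, g.end + flank))
        assert row["density_all"] == pytest.approx(cov / (2 * flank))
        ivs2 = [(t.start, t.end) for t in tes
                if t.contig == g.contig and t.te_class == "II"]
        cov2 = (brute_coverage(ivs2, g.start - flank, g.start - 1) +
                brute_coverage(ivs2, g.end + 1, g.end + flank))
        assert row["density_II"] == pytest.approx(cov2 / (2 * flank))


def test_density_order_independent(rng):
    genes, tes, lengths = _genes_and_tes(rng)
    df1, _ = ta.flank_te_density(genes, tes, lengths, flank_bp=2000)
    rng.shuffle(tes)
    df2, _ = ta.flank_te_density(genes, tes, lengths, flank_bp=2000)
    assert df1.equals(df2)


# ---------------------------------------------------------------------------
# permutation test


def test_permutation_errors():
    with pytest.raises(ValueError):
        ta.permutation_flank_test([0.1], [0.2, 0.3], reps=0)
    with pytest.raises(ValueError):
        ta.permutation_flank_test([0.1, 0.2, 0.3], [0.2], reps=10)
    with pytest.raises(ValueError):
        ta.permutation_flank_test([], [0.2], reps=10)


def test_permutation_p_positive_and_reproducible(rng):
    ick = rng.random(20) * 0.5 + 0.4
    pool = rng.random(100) * 0.5
    r1 = ta.permutation_flank_test(ick, pool, reps=500, seed=3)
    r2 = ta.permutation_flank_test(ick, pool, reps=500, seed=3)
    assert r1.permutation_p == r2.permutation_p > 0
    assert r1.observed_diff == pytest.approx(ick.mean() - pool.mean())


def test_permutation_p_converges_with_reps(rng):
    ick = rng.normal(0.55, 0.1, 30)
    pool = rng.normal(0.5, 0.1, 300)
    ps = [ta.permutation_flank_test(ick, pool, reps=r, seed=0).permutation_p
          for r in (100, 1000, 10000)]
    assert abs(ps[1] - ps[2]) < 0.05
    assert abs(ps[0] - ps[2]) < 0.15


# ---------------------------------------------------------------------------
# window tracks and shared families


def test_window_track_single_te_tile():
    tes = [ta.TeAnnotation("c", 101, 200)]
    prof, mean = ta.window_density_track(("c", 1, 400), tes, 1000,
                                         window_bp=100)
    vals = [w[2] for w in prof.windows]
    assert vals == [0.0, 1.0, 0.0, 0.0]
    assert mean == pytest.approx(100 / 1000)


def test_window_track_conserves_total_coverage(rng):
    tes = [ta.TeAnnotation("c", int(s), int(s) + int(l))
           for s, l in zip(rng.integers(1, 5000, 30),
                           rng.integers(10, 400, 30))]
    prof, _ = ta.window_density_track(("c", 1, 5500), tes, 6000,
                                      window_bp=100)
    total = sum(v * (e - s + 1) for s, e, v in prof.windows)
    exp = brute_coverage([(t.start, t.end) for t in tes], 1, 5500)
    assert total == pytest.approx(exp)


def test_shared_families_examples():
    tes = [ta.TeAnnotation("c", 10, 20, family="A"),
           ta.TeAnnotation("c", 100, 120, family="B"),
           ta.TeAnnotation("c", 500, 520, family="B"),
           ta.TeAnnotation("c", 530, 560, family="C")]
    n, ta_, tb, shared = ta.shared_te_families(("c", 1, 150), ("c", 450, 600),
                                               tes)
    assert (n, ta_, tb, shared) == (1, 2, 2, ["B"])
    n, *_ = ta.shared_te_families(("c", 1, 50), ("c", 450, 600), tes)
    assert n == 0


def test_pairwise_only_families():
    tes = [ta.TeAnnotation("c", 10, 20, family="A"),
           ta.TeAnnotation("c", 110, 120, family="A"),
           ta.TeAnnotation("c", 210, 220, family="A"),
           ta.TeAnnotation("c", 15, 25, family="B"),
           ta.TeAnnotation("c", 115, 125, family="B")]
    regions = {"g1": ("c", 1, 50), "g2": ("c", 100, 150),
               "g3": ("c", 200, 250)}
    out = ta.pairwise_only_families(regions, tes)
    # A is in all three regions, so only B counts as pairwise-shared
    assert out["g1|g2"] == {"B"}
    assert out["g1|g3"] == set()


@pytest.mark.parametrize("seed", range(4))
def test_shared_families_vs_set_oracle(seed):
    rng = np.random.default_rng(seed)
    tes = [ta.TeAnnotation("c", int(s), int(s) + 30,
                           family=f"f{int(rng.integers(6))}")
           for s in rng.integers(1, 2000, 40)]
    ra, rb = ("c", 1, 800), ("c", 700, 1600)
    n, na, nb, shared = ta.shared_te_families(ra, rb, tes)
    fam = lambda lo, hi: {t.family for t in tes
                          if t.start <= hi and t.end >= lo}
    assert set(shared) == fam(*ra[1:]) & fam(*rb[1:])
    assert (na, nb) == (len(fam(*ra[1:])), len(fam(*rb[1:])))
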