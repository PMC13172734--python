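"""Transposable-element density around genes and resampling comparisons.

Density is always a coverage fraction: TE intervals are union-merged before
counting so overlapping RepeatMasker annotations are not double-counted.
The ICK-versus-background comparison follows a resampling design: the mean
flank density of the toxin genes is compared against repeatedly drawn
equal-sized random subsets of the non-toxin genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .seqcore import WindowProfile

TE_CLASS_I = "I"    # retroelements (LINEs, LTR/Gypsy, ...)
TE_CLASS_II = "II"  # DNA transposons (Tc1/Mariner, hAT, ...)


@dataclass
class TeAnnotation:
    """One TE insertion interval (1-based inclusive)."""

    contig: str
    start: int
    end: int
    family: str = ""
    superfamily: str = ""
    te_class: str = "unknown"  # "I", "II" or "unknown"
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"TE interval start {self.start} > end {self.end}")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")


@dataclass
class Gene:
    gene_id: str
    contig: str
    start: int
    end: int
    is_ick: bool = False


@dataclass
class FlankDensityResult:
    per_gene: pd.DataFrame
    group_means: Dict[str, float]
    observed_diff: float
    permutation_p: float
    reps: int
    seed: int


# ---------------------------------------------------------------------------
# annotation readers

_RM_CLASS_MAP = {
    "DNA": TE_CLASS_II, "RC": TE_CLASS_II,
    "LINE": TE_CLASS_I, "SINE": TE_CLASS_I, "LTR": TE_CLASS_I,
    "Retroposon": TE_CLASS_I,
}


def classify_te(repeat_class: str) -> Tuple[str, str, str]:
    """Split a RepeatMasker class/family string into (family, superfamily, class)."""
    base = repeat_class.split("/")[0]
    superfamily = repeat_class.split("/")[1] if "/" in repeat_class else base
    te_class = _RM_CLASS_MAP.get(base, "unknown")
    return repeat_class, superfamily, te_class


def read_repeatmasker_out(path) -> List[TeAnnotation]:
    """Parse a RepeatMasker ``.out`` table (whitespace-delimited dialect)."""
    tes = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or not parts[0].replace(".", "").isdigit():
                continue  # header or blank
            div = float(parts[1])
            contig, start, end = parts[4], int(parts[5]), int(parts[6])
            name, repeat_class = parts[9], parts[10]
            family, superfamily, te_class = classify_te(repeat_class)
            tes.append(TeAnnotation(contig, start, end, family=name,
                                    superfamily=superfamily,
                                    te_class=te_class, divergence=div))
    return tes


def read_te_bed(path) -> List[TeAnnotation]:
    """BED with optional name column 'family|superfamily|class|divergence'."""
    tes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            contig, start, end = parts[0], int(parts[1]) + 1, int(parts[2])
            family = superfamily = ""
            te_class, div = "unknown", 0.0
            if len(parts) > 3 and parts[3]:
                bits = parts[3].split("|")
                family = bits[0]
                if len(bits) > 1:
                    superfamily = bits[1]
                if len(bits) > 2:
                    te_class = bits[2]
                if len(bits) > 3:
                    div = float(bits[3])
            tes.append(TeAnnotation(contig, start, end, family, superfamily,
                                    te_class, div))
    return tes


# ---------------------------------------------------------------------------
# interval arithmetic


def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    ivs = sorted(intervals)
    out: List[Tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def covered_bp(intervals: Iterable[Tuple[int, int]],
               lo: int, hi: int) -> int:
    """Union coverage of [lo, hi] (1-based inclusive) by the intervals."""
    total = 0
    for s, e in merge_intervals(intervals):
        s, e = max(s, lo), min(e, hi)
        if s <= e:
            total += e - s + 1
    return total


# ---------------------------------------------------------------------------
# flank densities


def flank_te_density(genes: Sequence[Gene], tes: Sequence[TeAnnotation],
                     contig_lengths: Dict[str, int],
                     flank_bp: int = 5000,
                     classes: Sequence[str] = (TE_CLASS_I, TE_CLASS_II),
                     ) -> Tuple[pd.DataFrame, List[str]]:
    """Per-gene TE coverage fraction of the two flanks, overall and per class.

    Density = covered bp / (2 * flank_bp), with TE intervals clipped to the
    flanks and union-merged.  Genes lacking a full flank on either side are
    excluded and returned separately.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    by_contig: Dict[str, List[TeAnnotation]] = {}
    for te in tes:
        by_contig.setdefault(te.contig, []).append(te)
    rows, excluded = [], []
    for g in genes:
        clen = contig_lengths.get(g.contig)
        if clen is None:
            raise ValueError(f"unknown contig {g.contig!r} for {g.gene_id}")
        left = (g.start - flank_bp, g.start - 1)
        right = (g.end + 1, g.end + flank_bp)
        if left[0] < 1 or right[1] > clen:
            excluded.append(g.gene_id)
            continue
        contig_tes = by_contig.get(g.contig, [])
        row = {"gene_id": g.gene_id, "is_ick": g.is_ick}
        for label, subset in [("all", contig_tes)] + [
                (c, [t for t in contig_tes if t.te_class == c])
                for c in classes]:
            ivs = [(t.start, t.end) for t in subset]
            cov = covered_bp(ivs, *left) + covered_bp(ivs, *right)
            row[f"density_{label}"] = cov / (2 * flank_bp)
        rows.append(row)
    cols = ["gene_id", "is_ick"] + [f"density_{c}" for c in
                                    ["all", *classes]]
    df = pd.DataFrame(rows, columns=cols)
    return df, excluded


def permutation_flank_test(ick_densities: Sequence[float],
                           nonick_densities: Sequence[float],
                           reps: int = 1000, seed: int = 0
                           ) -> FlankDensityResult:
    """Resampling comparison of toxin-gene flank density against background.

    The observed statistic is mean(ICK) - mean(non-ICK pool); the null
    distribution replaces the ICK group with random equal-sized subsets of
    the non-ICK pool, drawn without replacement ``reps`` times.  The
    two-sided empirical p uses the add-one correction and is never zero.
    """
    ick = np.asarray(ick_densities, dtype=float)
    pool = np.asarray(nonick_densities, dtype=float)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if ick.size == 0 or pool.size == 0:
        raise ValueError("both groups must be non-empty")
    if pool.size < ick.size:
        raise ValueError("non-ICK pool smaller than the ICK set")
    rng = np.random.default_rng(seed)
    pool_mean = pool.mean()
    obs = ick.mean() - pool_mean
    # vectorised without-replacement subsets: argsort of uniform noise
    order = np.argsort(rng.random((reps, pool.size)), axis=1)[:, : ick.size]
    perm = pool[order].mean(axis=1) - pool_mean
    p = (1 + int((np.abs(perm) >= abs(obs)).sum())) / (reps + 1)
    per_gene = pd.DataFrame({
        "group": ["ick"] * ick.size + ["non_ick"] * pool.size,
        "density": np.concatenate([ick, pool]),
    })
    return FlankDensityResult(per_gene,
                              {"ick": float(ick.mean()),
                               "non_ick": float(pool_mean)},
                              float(obs), float(p), reps, seed)


# ---------------------------------------------------------------------------
# windowed tracks and shared families


def window_density_track(region: Tuple[str, int, int],
                         tes: Sequence[TeAnnotation],
                         contig_length: int,
                         window_bp: int = 100,
                         te_class: Optional[str] = None
                         ) -> Tuple[WindowProfile, float]:
    """Tiled TE-coverage track over a region plus the whole-contig mean.

    The contig mean is the union TE coverage of the contig divided by its
    length; plotted as the red baseline against which local enrichment in
    introns and flanks is judged.
    """
    contig, lo, hi = region
    lo, hi = max(1, lo), min(contig_length, hi)
    sel = [t for t in tes if t.contig == contig and
           (te_class is None or t.te_class == te_class)]
    ivs = [(t.start, t.end) for t in sel]
    windows = []
    for s in range(lo, hi + 1, window_bp):
        e = min(s + window_bp - 1, hi)
        windows.append((s, e, covered_bp(ivs, s, e) / (e - s + 1)))
    final_width = windows[-1][1] - windows[-1][0] + 1 if windows else 0
    contig_mean = covered_bp(ivs, 1, contig_length) / contig_length
    return WindowProfile(window_bp, windows, final_width), contig_mean


def shared_te_families(region_a: Tuple[str, int, int],
                       region_b: Tuple[str, int, int],
                       tes: Sequence[TeAnnotation]
                       ) -> Tuple[int, int, int, List[str]]:
    """Distinct TE families shared between two gene regions.

    Returns (shared count, total distinct in A, total distinct in B,
    sorted shared family list); families are compared at the family level.
    """
    fam_a = _families_in(region_a, tes)
    fam_b = _families_in(region_b, tes)
    shared = sorted(fam_a & fam_b)
    return len(shared), len(fam_a), len(fam_b), shared


def pairwise_only_families(regions: Dict[str, Tuple[str, int, int]],
                           tes: Sequence[TeAnnotation]) -> Dict[str, set]:
    """Families shared by at least two regions but not by all of them."""
    fams = {name: _families_in(reg, tes) for name, reg in regions.items()}
    all_shared = set.intersection(*fams.values()) if fams else set()
    out: Dict[str, set] = {}
    names = sorted(fams)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out[f"{a}|{b}"] = (fams[a] & fams[b]) - all_shared
    return out


def _families_in(region: Tuple[str, int, int],
                 tes: Sequence[TeAnnotation]) -> set:
    contig, lo, hi = region
    return {t.family for t in tes
            if t.contig == contig and t.start <= hi and t.end >= lo
            and t.family}
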