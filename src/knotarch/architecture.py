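"""ICK framework detection and domain-architecture partitioning.

The inhibitor cystine knot (ICK) fold carries six cysteines in the pattern

    C x(2-7) C x(3-10) C C x(1-4) C x(3-13) C

with the third and fourth cysteines adjacent.  A mature peptide is
partitioned into leader / domains / linkers / C-terminal tail around the
non-overlapping framework matches; the domain count is the peptide's
valency.  The module also validates the conserved three-exon toxin gene
structure (phase-1 then phase-2 introns, mature peptide wholly in the last
exon, no intron between tandem domains).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .genemodels import GeneModel
from .seqcore import AaSeq, IdentityResult, pairwise_identity, translate

#: inter-cysteine spacing bounds (x1, x2, x3, x4)
SPACING_BOUNDS = ((2, 7), (3, 10), (1, 4), (3, 13))


@dataclass
class FrameworkMatch:
    """One framework hit; peptide coordinates are 1-based inclusive."""

    start: int
    end: int
    cys_positions: Tuple[int, int, int, int, int, int]
    spacings: Tuple[int, int, int, int]

    def __post_init__(self) -> None:
        c = self.cys_positions
        if list(c) != sorted(c):
            raise ValueError("cysteine positions must be strictly increasing")
        if c[3] - c[2] != 1:
            raise ValueError("cysteines 3 and 4 must be adjacent")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class Linker:
    seq: str
    start: int  # 1-based inclusive in the mature peptide
    end: int


@dataclass
class DomainArchitecture:
    """Partition of one mature peptide into domains, linkers and tail."""

    precursor_id: str
    mature: str
    valency: int
    domains: List[FrameworkMatch] = field(default_factory=list)
    domain_seqs: List[str] = field(default_factory=list)
    linkers: List[Linker] = field(default_factory=list)
    tail: str = ""
    leader: str = ""
    is_ick: bool = True

    def reconstruct(self) -> str:
        """leader + domain1 + linker1 + ... + domainN + tail, character-exact."""
        parts = [self.leader]
        for i, dom in enumerate(self.domain_seqs):
            parts.append(dom)
            if i < len(self.linkers):
                parts.append(self.linkers[i].seq)
        parts.append(self.tail)
        return "".join(parts)


@dataclass
class StructureReport:
    gene_id: str
    exon_count: int
    intron_phases: List[int]
    mature_in_last_exon: bool
    interdomain_intron: bool
    verdicts: Dict[str, bool]


# ---------------------------------------------------------------------------
# framework scanning


def _matches_from(cys: Sequence[int], c0: int, n: int) -> List[Tuple[int, ...]]:
    """All framework cysteine sextets starting at position c0 (0-based)."""
    (a1, b1), (a2, b2), (a3, b3), (a4, b4) = SPACING_BOUNDS
    cset = set(cys)
    out = []
    for c1 in cys:
        if not (a1 <= c1 - c0 - 1 <= b1):
            if c1 - c0 - 1 > b1:
                break
            continue
        for c2 in cys:
            if c2 <= c1:
                continue
            if not (a2 <= c2 - c1 - 1 <= b2):
                if c2 - c1 - 1 > b2:
                    break
                continue
            c3 = c2 + 1
            if c3 not in cset:
                continue
            for c4 in cys:
                if c4 <= c3:
                    continue
                if not (a3 <= c4 - c3 - 1 <= b3):
                    if c4 - c3 - 1 > b3:
                        break
                    continue
                for c5 in cys:
                    if c5 <= c4:
                        continue
                    if not (a4 <= c5 - c4 - 1 <= b4):
                        if c5 - c4 - 1 > b4:
                            break
                        continue
                    out.append((c0, c1, c2, c3, c4, c5))
    return out


def _to_match(combo: Tuple[int, ...]) -> FrameworkMatch:
    c = combo
    spacings = (c[1] - c[0] - 1, c[2] - c[1] - 1, c[4] - c[3] - 1,
                c[5] - c[4] - 1)
    return FrameworkMatch(c[0] + 1, c[5] + 1,
                          tuple(p + 1 for p in c), spacings)


def scan_ick_frameworks(peptide, all_matches: bool = False) -> List[FrameworkMatch]:
    """Find ICK cysteine frameworks in a mature peptide.

    Default mode returns non-overlapping matches chosen greedily left to
    right, with the shortest total span winning among matches that share a
    start (further ties break on the lexicographically smallest spacing
    tuple).  ``all_matches`` instead returns every start/spacing combination.
    Extra cysteines inside the x-spacers do not invalidate a match.
    """
    s = (peptide.seq if hasattr(peptide, "seq") else peptide).upper()
    if not s:
        raise ValueError("peptide must be non-empty")
    cys = [i for i, ch in enumerate(s) if ch == "C"]
    if all_matches:
        combos = []
        for c0 in cys:
            combos.extend(_matches_from(cys, c0, len(s)))
        combos.sort()
        return [_to_match(c) for c in combos]
    out: List[FrameworkMatch] = []
    cursor = 0
    for c0 in cys:
        if c0 < cursor:
            continue
        combos = _matches_from(cys, c0, len(s))
        if not combos:
            continue
        best = min(combos, key=lambda c: (c[5], tuple(c)))
        out.append(_to_match(best))
        cursor = best[5] + 1
    return out


# ---------------------------------------------------------------------------
# architecture partitioning


def partition_architecture(mature, precursor_id: str = "") -> DomainArchitecture:
    """Partition a mature peptide around its framework matches.

    Each domain spans first to last framework cysteine; linker_i is the
    residues strictly between consecutive domains; the tail follows the last
    framework cysteine.  The concatenation leader + domains/linkers + tail
    reconstructs the input exactly.
    """
    s = (mature.seq if hasattr(mature, "seq") else mature).upper()
    pid = precursor_id or (mature.id if hasattr(mature, "id") else "")
    matches = scan_ick_frameworks(s)
    if not matches:
        return DomainArchitecture(pid, s, 0, [], [], [], tail="", leader=s,
                                  is_ick=False)
    domains = matches
    domain_seqs = [s[m.start - 1 : m.end] for m in matches]
    linkers = []
    for d1, d2 in zip(matches, matches[1:]):
        linkers.append(Linker(s[d1.end : d2.start - 1], d1.end + 1,
                              d2.start - 1))
    leader = s[: matches[0].start - 1]
    tail = s[matches[-1].end :]
    return DomainArchitecture(pid, s, len(matches), domains, domain_seqs,
                              linkers, tail, leader, True)


@dataclass
class ConservationTable:
    positions: List[Tuple[set, bool]]  # residue set, fully-conserved flag
    mean_pairwise_identity: float
    n_linkers: int

    def conserved_prefix(self) -> int:
        run = 0
        for _, ok in self.positions:
            if not ok:
                break
            run += 1
        return run


def linker_conservation(architectures: Sequence[DomainArchitecture]
                        ) -> ConservationTable:
    """Per-position linker conservation across multivalent architectures.

    Linkers are left-aligned with no internal alignment: position j is fully
    conserved when a single residue occupies it in every linker of length
    >= j+1.  Mean pairwise identity is computed on ungapped shared prefixes.
    """
    multi = [a for a in architectures if a.valency >= 2]
    if len(multi) < 2:
        raise ValueError("need at least 2 multivalent architectures")
    linkers = [lk.seq for a in multi for lk in a.linkers]
    maxlen = max(len(l) for l in linkers)
    positions = []
    for j in range(maxlen):
        residues = {l[j] for l in linkers if len(l) > j}
        positions.append((residues, len(residues) == 1))
    total, pairs = 0.0, 0
    for i in range(len(linkers)):
        for j in range(i + 1, len(linkers)):
            n = min(len(linkers[i]), len(linkers[j]))
            if n == 0:
                continue
            m = sum(1 for a, b in zip(linkers[i][:n], linkers[j][:n]) if a == b)
            total += m / n
            pairs += 1
    mean = total / pairs if pairs else 1.0
    return ConservationTable(positions, mean, len(linkers))


def linker_tail_homology(arch: DomainArchitecture) -> IdentityResult:
    """Ungapped identity between the interdomain linker and the tail end.

    Compares the linker prefix with the equally long suffix of the
    C-terminal tail over min(linker, tail) residues; a fresh intra-exon
    duplication (linker copied from the ancestral tail) scores 1.0 and the
    value decays with divergence.
    """
    if arch.valency < 2:
        raise ValueError("linker/tail homology needs a multivalent architecture")
    linker = arch.linkers[-1].seq
    if not linker:
        raise ValueError("empty linker")
    if not arch.tail:
        raise ValueError("empty C-terminal tail")
    n = min(len(linker), len(arch.tail))
    return pairwise_identity(linker[:n], arch.tail[-n:], mode="ungapped")


# ---------------------------------------------------------------------------
# gene-structure validation


def validate_gene_structure(gene: GeneModel, contig_seq: str,
                            arch: Optional[DomainArchitecture] = None
                            ) -> StructureReport:
    """Check the conserved 3-exon layout of an ICK toxin gene.

    Verdicts: exactly three exons; intron phases 1 then 2 (phase = spliced
    CDS length mod 3 at the junction, i.e. bases of the interrupted codon
    already emitted); mature-peptide coding wholly inside the final exon;
    no intron between two domain-coding segments.
    """
    if not gene.cds:
        raise ValueError(f"{gene.gene_id}: no CDS segments")
    spliced = gene.spliced_cds(contig_seq)
    if len(spliced) % 3 != 0:
        raise ValueError(
            f"{gene.gene_id}: inconsistent CDS frame; junctions at "
            f"{gene.cds_junctions()}")
    junctions = gene.cds_junctions()
    phases = [j % 3 for j in junctions]
    peptide = translate(spliced, 1)
    if peptide.endswith("*"):
        peptide = peptide[:-1]
    if arch is None:
        # without cleavage annotation, take the mature region to run from
        # the first framework cysteine to the end of the precursor
        full = partition_architecture(peptide)
        arch = partition_architecture(
            peptide[full.domains[0].start - 1 :] if full.is_ick else peptide)
    mature = arch.mature
    mature_in_last = False
    interdomain_intron = False
    idx = peptide.find(mature) if mature else -1
    if idx >= 0:
        m0 = idx * 3  # 0-based nt offset of mature region in spliced CDS
        m1 = m0 + len(mature) * 3
        last_exon_cds_start = junctions[-1] if junctions else 0
        mature_in_last = m0 >= last_exon_cds_start
        for d1, d2 in zip(arch.domains, arch.domains[1:]):
            lo = m0 + d1.end * 3          # spliced-CDS bases up to domain i end
            hi = m0 + (d2.start - 1) * 3  # bases before domain i+1 start
            if any(lo <= j <= hi for j in junctions):
                interdomain_intron = True
    verdicts = {
        "three_exons": len(gene.exons) == 3,
        "phase_1_then_2": phases == [1, 2],
        "mature_in_last_exon": mature_in_last,
        "no_interdomain_intron": not interdomain_intron,
    }
    return StructureReport(gene.gene_id, len(gene.exons), phases,
                           mature_in_last, interdomain_intron, verdicts)
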