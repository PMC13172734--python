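"""Truth-tagged simulator of ICK toxin gene families.

Generates single-domain three-exon toxin genes (signal / pro / mature exons
separated by phase-1 and phase-2 introns, mature peptide wholly in exon 3),
duplicates the domain within exon 3 so the ancestral C-terminal tail
becomes the interdomain linker, evolves the family along a tree under a
Kimura-style substitution process, applies the four domain-loss mechanisms,
and places a transposable-element landscape enriched in class II elements
around toxin genes.  Every stochastic choice is drawn from one seeded
generator and logged, so replaying the truth log reproduces each tip
byte-exactly.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .architecture import partition_architecture
from .genemodels import GeneModel
from .seqcore import NtSeq, ToxinPrecursor, best_local_match, translate
from .teassoc import Gene, TeAnnotation

STOPS = {"TAA", "TAG", "TGA"}

#: codons per residue, sorted for deterministic sampling
_CODONS: Dict[str, List[str]] = {}
for _c1 in "ACGT":
    for _c2 in "ACGT":
        for _c3 in "ACGT":
            _cod = _c1 + _c2 + _c3
            _aa = translate(_cod, 1)
            _CODONS.setdefault(_aa, []).append(_cod)

#: residues used for non-framework positions (no C, to keep architectures
#: unambiguous; no W to limit accidental stop-adjacent codons)
SPACER_RESIDUES = "ADEFGHIKLNPQRSTVY"


@dataclass
class TeFamilySpec:
    family: str
    superfamily: str
    te_class: str
    length: int
    weight: float


def default_te_catalogue() -> List[TeFamilySpec]:
    """Class II dominated catalogue (Tc1/Mariner heavy), as in mygalomorph
    spider genomes."""
    return [
        TeFamilySpec("Tc1-1", "Tc1/Mariner", "II", 1300, 0.22),
        TeFamilySpec("Tc1-2", "Tc1/Mariner", "II", 1100, 0.12),
        TeFamilySpec("Mariner-1", "Tc1/Mariner", "II", 950, 0.11),
        TeFamilySpec("hAT-1", "hAT", "II", 650, 0.08),
        TeFamilySpec("Helitron-1", "Helitron", "II", 800, 0.07),
        TeFamilySpec("Gypsy-1", "Gypsy", "I", 1500, 0.12),
        TeFamilySpec("Copia-1", "Copia", "I", 1200, 0.06),
        TeFamilySpec("LINE-R2", "R2", "I", 1100, 0.12),
        TeFamilySpec("Penelope-1", "Penelope", "I", 900, 0.10),
    ]


@dataclass
class SimConfig:
    """Study conditions for the synthetic toxin family."""

    seed: int = 0
    n_tips: int = 8
    tree_newick: Optional[str] = None
    branch_length: float = 1.0
    subst_rate: float = 0.03         # substitutions/site per branch-length unit
    ts_tv_ratio: float = 2.0
    utr_rate_multiplier: float = 2.0  # released constraint after a stop
    protect_framework_cys: bool = True
    event_script: List[Tuple[str, str, Optional[str]]] = field(
        default_factory=list)  # (node label, "duplication"|"loss", mechanism)
    #: spacings sized so one domain is 36 residues, the scale of the mature
    #: knottin domains this family carries
    spacings: Tuple[int, int, int, int] = (7, 9, 3, 11)
    leader_len: int = 2
    tail_len: int = 4
    signal_len: int = 18
    pro_len: int = 13
    intron_lens: Tuple[int, int] = (700, 900)
    flank_len: int = 6000
    utr3_len: int = 220
    te_catalogue: List[TeFamilySpec] = field(
        default_factory=default_te_catalogue)
    te_per_gene: float = 6.0          # expected insertions per gene region
    te_flank_enrichment: float = 3.0  # toxin genes vs background

    def __post_init__(self) -> None:
        bounds = ((2, 7), (3, 10), (1, 4), (3, 13))
        for x, (lo, hi) in zip(self.spacings, bounds):
            if not (lo <= x <= hi):
                raise ValueError(f"framework spacing {x} outside [{lo},{hi}]")
        for name in ("leader_len", "tail_len", "signal_len", "pro_len",
                     "flank_len", "utr3_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


COMPONENTS = ("flank5", "exon1", "intron1", "exon2", "intron2",
              "exon3cds", "utr3", "flank3")


@dataclass
class SimGene:
    """A toxin gene as ordered components of one contig."""

    gene_id: str
    parts: Dict[str, str]
    signal_len: int
    pro_len: int
    tes: List[TeAnnotation] = field(default_factory=list)

    @property
    def cds(self) -> str:
        return (self.parts["exon1"] + self.parts["exon2"] +
                self.parts["exon3cds"])

    @property
    def contig_seq(self) -> str:
        return "".join(self.parts[c] for c in COMPONENTS)

    @property
    def cds_offset3(self) -> int:
        return len(self.parts["exon1"]) + len(self.parts["exon2"])

    def orf_end(self) -> int:
        """0-based index one past the first in-frame stop (or CDS end)."""
        cds = self.cds
        for i in range(0, len(cds) - 2, 3):
            if cds[i : i + 3] in STOPS:
                return i + 3
        return len(cds)

    def precursor(self) -> ToxinPrecursor:
        """Observable transcript: ORF up to the first stop, rest is 3'UTR."""
        cds = self.cds
        end = self.orf_end()
        return ToxinPrecursor(self.gene_id, cds[:end],
                              utr3=cds[end:] + self.parts["utr3"],
                              signal_end=self.signal_len,
                              pro_end=self.signal_len + self.pro_len)

    def gene_model(self, contig: str = "") -> GeneModel:
        p = self.parts
        pos = len(p["flank5"]) + 1
        exons, cds = [], []
        e1 = (pos, pos + len(p["exon1"]) - 1)
        pos = e1[1] + 1 + len(p["intron1"])
        e2 = (pos, pos + len(p["exon2"]) - 1)
        pos = e2[1] + 1 + len(p["intron2"])
        e3 = (pos, pos + len(p["exon3cds"]) + len(p["utr3"]) - 1)
        cds3 = (pos, pos + len(p["exon3cds"]) - 1)
        exons = [e1, e2, e3]
        cds = [e1, e2, cds3]
        return GeneModel(self.gene_id, contig or self.gene_id, "+",
                         exons, cds)

    def valency(self) -> int:
        return partition_architecture(self.precursor().mature_peptide).valency


@dataclass
class TruthLog:
    """Root state plus ordered per-node event/substitution records."""

    config: dict
    root_parts: Dict[str, str]
    records: List[dict] = field(default_factory=list)
    tip_valency: Dict[str, int] = field(default_factory=dict)
    te_registry: List[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"config": self.config,
                           "root_parts": self.root_parts,
                           "records": self.records,
                           "tip_valency": self.tip_valency,
                           "te_registry": self.te_registry}, indent=1)


# ---------------------------------------------------------------------------
# ancestor construction


def _codons_for(peptide: str, rng: np.random.Generator) -> str:
    out = []
    for aa in peptide:
        opts = _CODONS[aa]
        out.append(opts[int(rng.integers(len(opts)))])
    return "".join(out)


def _random_peptide(n: int, rng: np.random.Generator) -> str:
    return "".join(SPACER_RESIDUES[int(rng.integers(len(SPACER_RESIDUES)))]
                   for _ in range(n))


def _random_nt(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[int(rng.integers(4))] for _ in range(n))


def domain_peptide(spacings: Tuple[int, int, int, int],
                   rng: np.random.Generator) -> str:
    x1, x2, x3, x4 = spacings
    return ("C" + _random_peptide(x1, rng) + "C" + _random_peptide(x2, rng) +
            "CC" + _random_peptide(x3, rng) + "C" + _random_peptide(x4, rng) +
            "C")


def make_ancestor(cfg: SimConfig,
                  rng: Optional[np.random.Generator] = None) -> SimGene:
    """A single-domain precursor gene passing all structural checks.

    Three exons with intron phases 1 then 2; the mature peptide (leader +
    one framework domain + tail) is wholly encoded by exon 3.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    signal = "M" + _random_peptide(cfg.signal_len - 1, rng)
    pro = _random_peptide(cfg.pro_len, rng)
    body = (_random_peptide(cfg.leader_len, rng) +
            domain_peptide(cfg.spacings, rng))
    # the tail later becomes the interdomain linker; keep it one point
    # mutation away from a stop so nonsense-mediated losses stay possible
    for _ in range(100):
        tail = _random_peptide(cfg.tail_len, rng)
        tail_cds = _codons_for(tail, rng)
        if any(_single_sub_stops(tail_cds[i : i + 3])
               for i in range(0, len(tail_cds), 3)):
            break
    mature = body + tail
    peptide = signal + pro + mature
    cds = _codons_for(signal + pro + body, rng) + tail_cds + "TAA"
    e1_len = 3 * cfg.signal_len + 1          # phase 1 junction
    e2_len = 3 * cfg.pro_len - 2             # cumulative phase 2
    parts = {
        "flank5": _random_nt(cfg.flank_len, rng),
        "exon1": cds[:e1_len],
        "intron1": _intron(cfg.intron_lens[0], rng),
        "exon2": cds[e1_len : e1_len + e2_len],
        "intron2": _intron(cfg.intron_lens[1], rng),
        "exon3cds": cds[e1_len + e2_len :],
        "utr3": _random_nt(cfg.utr3_len, rng),
        "flank3": _random_nt(cfg.flank_len, rng),
    }
    gene = SimGene("ancestor", parts, cfg.signal_len, cfg.pro_len)
    if gene.valency() != 1:
        raise ValueError("infeasible config: ancestor is not single-domain")
    return gene


def _intron(n: int, rng: np.random.Generator) -> str:
    core = _random_nt(max(0, n - 4), rng)
    return "GT" + core + "AG"


# ---------------------------------------------------------------------------
# events


def apply_duplication(gene: SimGene,
                      rng: Optional[np.random.Generator] = None
                      ) -> Tuple[SimGene, dict]:
    """Tandem-duplicate the domain+tail segment within exon 3.

    The ancestral tail copy becomes the new interdomain linker; no intron is
    inserted and valency increments by one.
    """
    g = copy.deepcopy(gene)
    prec = g.precursor()
    arch = partition_architecture(prec.mature_peptide)
    if arch.valency < 1:
        raise ValueError("cannot duplicate a non-ICK precursor")
    pro_end = g.signal_len + g.pro_len
    # duplicate from the first cysteine of the LAST domain to the tail end
    a_aa = pro_end + arch.domains[-1].start - 1
    b_aa = pro_end + len(prec.mature_peptide)
    a_nt, b_nt = 3 * a_aa, 3 * b_aa
    off3 = g.cds_offset3
    e3 = g.parts["exon3cds"]
    la, lb = a_nt - off3, b_nt - off3
    g.parts["exon3cds"] = e3[:lb] + e3[la:lb] + e3[lb:]
    record = {"op": "duplication", "cds_interval": [a_nt + 1, b_nt],
              "insert_at": b_nt + 1}
    return g, record


def _edit_exon3(gene: SimGene, cds_start: int, cds_end: int,
                replacement: str) -> None:
    """Replace CDS positions [cds_start, cds_end) (0-based) inside exon 3."""
    off3 = gene.cds_offset3
    if cds_start < off3:
        raise ValueError("edit extends outside exon 3")
    e3 = gene.parts["exon3cds"]
    gene.parts["exon3cds"] = (e3[: cds_start - off3] + replacement +
                              e3[cds_end - off3 :])


def _single_sub_stops(codon: str) -> List[Tuple[int, str, str]]:
    out = []
    for k in range(3):
        for b in "ACGT":
            if b == codon[k]:
                continue
            mut = codon[:k] + b + codon[k + 1 :]
            if mut in STOPS:
                out.append((k, codon[k], b))
    return out


def apply_loss(gene: SimGene, mechanism: str,
               rng: np.random.Generator,
               max_tries: int = 300) -> Tuple[SimGene, dict]:
    """Apply one domain-loss event of the requested mechanism.

    nonsense_point substitutes one base in the last interdomain linker to
    create an in-frame stop; deletion_stop removes 1-30 bp so a downstream
    stop comes into frame; fusion_crossover recombines the first and last
    domains inside their best local match; te_disruption inserts a
    catalogue TE immediately before the last domain.
    """
    g = copy.deepcopy(gene)
    prec = g.precursor()
    arch = partition_architecture(prec.mature_peptide)
    if arch.valency < 2:
        raise ValueError("loss requires a multivalent precursor")
    pro_end = g.signal_len + g.pro_len
    # aa coordinates (0-based, peptide-wide) of the last linker and domains
    link = arch.linkers[-1]
    link_aa = (pro_end + link.start - 1, pro_end + link.end)  # [lo, hi)
    last_dom = arch.domains[-1]
    first_dom = arch.domains[0]
    last_dom_nt = (3 * (pro_end + last_dom.start - 1),
                   3 * (pro_end + last_dom.end))
    record: dict = {"op": "loss", "mechanism": mechanism}

    if mechanism == "nonsense_point":
        cands = []
        for aa in range(link_aa[0], link_aa[1]):
            codon = g.cds[3 * aa : 3 * aa + 3]
            for k, frm, to in _single_sub_stops(codon):
                cands.append((3 * aa + k, frm, to))
        if not cands:
            raise ValueError("no stop creatable by one substitution")
        pos, frm, to = cands[int(rng.integers(len(cands)))]
        _edit_exon3(g, pos, pos + 1, to)
        record.update({"cds_pos": pos + 1, "from": frm, "to": to})
        return g, record

    if mechanism == "deletion_stop":
        lo_nt, hi_nt = 3 * link_aa[0], 3 * link_aa[1]
        for _ in range(max_tries):
            length = int(rng.integers(1, 31))
            if hi_nt - lo_nt <= length:
                continue
            start = int(rng.integers(lo_nt, hi_nt - length))
            deleted = g.cds[start : start + length]
            trial = copy.deepcopy(g)
            _edit_exon3(trial, start, start + length, "")
            end = trial.orf_end()
            # premature stop after the retained domains, before the last one
            if 3 * (pro_end + first_dom.end) < end < last_dom_nt[1] - length:
                record.update({"cds_interval": [start + 1, start + length],
                               "deleted_seq": deleted})
                return trial, record
        raise ValueError("could not realise a deletion-induced stop")

    if mechanism == "fusion_crossover":
        d1_nt = g.cds[3 * (pro_end + first_dom.start - 1) :
                      3 * (pro_end + first_dom.end)]
        dk_nt = g.cds[last_dom_nt[0] : last_dom_nt[1]]
        m = best_local_match(d1_nt, dk_nt, min_length=8)
        if m is None:
            raise ValueError("no interdomain similarity to recombine")
        b = int(rng.integers(m.a_start, m.a_end + 1))  # within the match
        b2 = m.b_start + (b - m.a_start)
        p1 = 3 * (pro_end + first_dom.start - 1) + b
        p2 = last_dom_nt[0] + b2
        _edit_exon3(g, p1, p2, "")
        record.update({"breakpoint_d1": b, "breakpoint_d2": b2,
                       "cds_removed": [p1 + 1, p2],
                       "facilitating": [m.a_start, m.a_end, m.identity]})
        return g, record

    if mechanism == "te_disruption":
        catalogue = default_te_catalogue()
        weights = np.array([f.weight for f in catalogue])
        weights = weights / weights.sum()
        fam = catalogue[int(rng.choice(len(weights), p=weights))]
        te_seq = _random_nt(fam.length, rng)
        pos = last_dom_nt[0]
        trial = copy.deepcopy(g)
        _edit_exon3(trial, pos, pos, te_seq)
        end = trial.orf_end()
        if end > pos + fam.length + 30:
            raise ValueError("TE insertion did not pseudogenise the ORF")
        # genomic coordinates: exon3-local offset plus upstream components
        upstream = sum(len(g.parts[c]) for c in
                       ("flank5", "exon1", "intron1", "exon2", "intron2"))
        g_start = upstream + (pos - g.cds_offset3) + 1
        trial.tes.append(TeAnnotation(g.gene_id, g_start,
                                      g_start + fam.length - 1,
                                      family=fam.family,
                                      superfamily=fam.superfamily,
                                      te_class=fam.te_class))
        record.update({"cds_pos": pos + 1, "family": fam.family,
                       "superfamily": fam.superfamily,
                       "te_class": fam.te_class, "te_seq": te_seq})
        return trial, record

    raise ValueError(f"unknown loss mechanism {mechanism!r}")


# ---------------------------------------------------------------------------
# substitution process


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _mutate(seq: str, p: float, rng: np.random.Generator,
            protected: Optional[set] = None,
            ts_tv: float = 2.0) -> Tuple[str, List[Tuple[int, str, str]]]:
    """K2P-style substitutions at per-site probability ``p``."""
    if p <= 0 or not seq:
        return seq, []
    n = len(seq)
    hits = np.flatnonzero(rng.random(n) < p)
    if not len(hits):
        return seq, []
    out = list(seq)
    subs = []
    p_ts = ts_tv / (ts_tv + 1.0)
    for i in hits:
        i = int(i)
        if protected and i in protected:
            continue
        base = out[i]
        if base not in "ACGT":
            continue
        if rng.random() < p_ts:
            new = _TRANSITION[base]
        else:
            tv = _TRANSVERSIONS[base]
            new = tv[int(rng.integers(2))]
        out[i] = new
        subs.append((i, base, new))
    return "".join(out), subs


def _protected_cds_positions(gene: SimGene, protect_cys: bool) -> set:
    """Start codon, current ORF stop, and framework cysteine codons."""
    prot = {0, 1, 2}
    end = gene.orf_end()
    if end <= len(gene.cds):
        prot |= {end - 3, end - 2, end - 1}
    if protect_cys:
        prec = gene.precursor()
        arch = partition_architecture(prec.mature_peptide)
        pro_end = gene.signal_len + gene.pro_len
        for dom in arch.domains:
            for cpos in dom.cys_positions:
                aa = pro_end + cpos - 1
                prot |= {3 * aa, 3 * aa + 1, 3 * aa + 2}
    return prot


def _first_stop_end(cds: str) -> int:
    for i in range(0, len(cds) - 2, 3):
        if cds[i : i + 3] in STOPS:
            return i + 3
    return len(cds)


def evolve_branch(gene: SimGene, cfg: SimConfig, branch_length: float,
                  rng: np.random.Generator) -> Tuple[SimGene, List]:
    """Substitutions over one branch.

    The functional ORF evolves at the base rate under purifying selection:
    framework cysteines, start and stop codons are protected and draws that
    would create a new premature stop are rejected.  The pseudogenised
    remnant beyond the first stop and the 3'UTR evolve unconstrained at the
    released-constraint multiplier.
    """
    g = copy.deepcopy(gene)
    p = cfg.subst_rate * branch_length
    subs_log = []
    protected = _protected_cds_positions(g, cfg.protect_framework_cys)
    cds = g.cds
    orf_end = g.orf_end()
    cand, subs = _mutate(cds[:orf_end], p, rng,
                         {i for i in protected if i < orf_end},
                         cfg.ts_tv_ratio)
    # codon-level purifying selection: revert any codon that a draw turned
    # into a premature stop, leaving all other substitutions in place
    cand_l = list(cand)
    reverted = set()
    for i in range(0, orf_end - 3, 3):
        if "".join(cand_l[i : i + 3]) in STOPS:
            cand_l[i : i + 3] = cds[i : i + 3]
            reverted |= {i, i + 1, i + 2}
    head = "".join(cand_l)
    subs_h = [(i, a, b) for i, a, b in subs if i not in reverted]
    tail, subs_t = _mutate(cds[orf_end:], p * cfg.utr_rate_multiplier, rng,
                           {i - orf_end for i in protected if i >= orf_end},
                           cfg.ts_tv_ratio)
    new_cds = head + tail
    l1, l2 = len(g.parts["exon1"]), len(g.parts["exon2"])
    g.parts["exon1"] = new_cds[:l1]
    g.parts["exon2"] = new_cds[l1 : l1 + l2]
    g.parts["exon3cds"] = new_cds[l1 + l2 :]

    def _log(i, a, b):
        if i < l1:
            subs_log.append(["exon1", i, a, b])
        elif i < l1 + l2:
            subs_log.append(["exon2", i - l1, a, b])
        else:
            subs_log.append(["exon3cds", i - l1 - l2, a, b])

    for i, a, b in subs_h:
        _log(i, a, b)
    for i, a, b in subs_t:
        _log(i + orf_end, a, b)
    for comp in ("intron1", "intron2", "flank5", "flank3"):
        seq = g.parts[comp]
        prot = {0, 1, len(seq) - 2, len(seq) - 1} if comp.startswith("intron") \
            else set()
        mut, subs = _mutate(seq, p, rng, prot, cfg.ts_tv_ratio)
        g.parts[comp] = mut
        for i, a, b in subs:
            subs_log.append([comp, i, a, b])
    seq = g.parts["utr3"]
    mut, subs = _mutate(seq, p * cfg.utr_rate_multiplier, rng, None,
                        cfg.ts_tv_ratio)
    g.parts["utr3"] = mut
    for i, a, b in subs:
        subs_log.append(["utr3", i, a, b])
    return g, subs_log


# ---------------------------------------------------------------------------
# family simulation


@dataclass
class SimBundle:
    config: SimConfig
    tree: dendropy.Tree
    genes: Dict[str, SimGene]
    truth: TruthLog

    def precursors(self) -> Dict[str, ToxinPrecursor]:
        return {k: g.precursor() for k, g in self.genes.items()}

    def contigs(self) -> List[NtSeq]:
        return [NtSeq(k, g.contig_seq) for k, g in sorted(self.genes.items())]

    def gene_models(self) -> List[GeneModel]:
        return [g.gene_model() for _, g in sorted(self.genes.items())]

    def te_annotations(self) -> List[TeAnnotation]:
        out = []
        for _, g in sorted(self.genes.items()):
            out.extend(g.tes)
        return out


def _default_tree(n_tips: int, branch_length: float,
                  rng: np.random.Generator) -> str:
    """Random bifurcating topology by successive joining, unit branches."""
    nodes = [f"t{i+1}" for i in range(n_tips)]
    while len(nodes) > 1:
        pick = sorted(int(x) for x in
                      rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[pick[0]], nodes[pick[1]]
        merged = f"({a}:{branch_length},{b}:{branch_length})"
        nodes = [n for k, n in enumerate(nodes) if k not in pick]
        nodes.append(merged)
    return nodes[0] + ";"


def _node_label(nd: dendropy.Node) -> str:
    if nd.is_leaf():
        return nd.taxon.label
    return nd.label or ""


def simulate_family(cfg: SimConfig) -> SimBundle:
    """Evolve an ancestral gene along a tree with scripted events.

    The event script lists (node label, op, mechanism) entries applied at
    the start of the branch leading to that node; substitutions follow.
    Identical configs (including seed) produce identical bundles.
    """
    rng = np.random.default_rng(cfg.seed)
    newick = cfg.tree_newick or _default_tree(cfg.n_tips, cfg.branch_length,
                                              rng)
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=False)
    # unlabeled internal nodes get deterministic preorder labels so the
    # truth log can be replayed against the exact same tree
    idx = 0
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        if not ((nd.taxon and nd.taxon.label) or nd.label):
            idx += 1
            nd.label = f"n{idx}"
    newick = tree.as_string(schema="newick",
                            suppress_rooting=True).strip()
    labels = set()
    for nd in tree.preorder_node_iter():
        lab = nd.taxon.label if nd.taxon else nd.label
        if lab:
            if lab in labels:
                raise ValueError(f"duplicate node label {lab!r}")
            labels.add(lab)
    script_nodes = {s[0] for s in cfg.event_script}
    unknown = script_nodes - labels
    if unknown:
        raise ValueError(f"event script names unknown nodes: {sorted(unknown)}")

    root_gene = make_ancestor(cfg, rng)
    cfg_dict = _config_dict(cfg)
    cfg_dict["tree_newick"] = newick
    # events scripted on the root apply before the tree walk
    seed_nd = tree.seed_node
    root_label = seed_nd.taxon.label if seed_nd.taxon else seed_nd.label
    root_events = []
    for s_node, op, mech in cfg.event_script:
        if s_node != root_label:
            continue
        if op == "duplication":
            root_gene, ev = apply_duplication(root_gene, rng)
        elif op == "loss":
            root_gene, ev = apply_loss(root_gene, mech, rng)
        else:
            raise ValueError(f"unknown scripted op {op!r}")
        root_events.append(ev)
    truth = TruthLog(config=cfg_dict, root_parts=dict(root_gene.parts))
    if root_events:
        truth.records.append({"node": root_label, "events": root_events,
                              "substitutions": [],
                              "note": "applied before the root state"})
    states: Dict[int, SimGene] = {id(tree.seed_node): root_gene}
    genes: Dict[str, SimGene] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        lab = nd.taxon.label if nd.taxon else (nd.label or f"__{id(nd)}")
        parent_gene = states[id(nd.parent_node)]
        g = copy.deepcopy(parent_gene)
        rec = {"node": lab, "events": [], "substitutions": []}
        for s_node, op, mech in cfg.event_script:
            if s_node != lab:
                continue
            if op == "duplication":
                g, ev = apply_duplication(g, rng)
            elif op == "loss":
                g, ev = apply_loss(g, mech, rng)
            else:
                raise ValueError(f"unknown scripted op {op!r}")
            rec["events"].append(ev)
        bl = nd.edge.length if nd.edge.length is not None else \
            cfg.branch_length
        g, subs = evolve_branch(g, cfg, bl, rng)
        rec["substitutions"] = subs
        truth.records.append(rec)
        states[id(nd)] = g
        if nd.is_leaf():
            g = copy.deepcopy(g)
            g.gene_id = lab
            for te in g.tes:
                te.contig = lab
            genes[lab] = g
    # background TE landscape around every tip gene
    for lab in sorted(genes):
        _place_tes(genes[lab], cfg, rng, enriched=True)
    for lab, g in genes.items():
        truth.tip_valency[lab] = g.valency()
        for te in g.tes:
            truth.te_registry.append(
                {"contig": te.contig, "start": te.start, "end": te.end,
                 "family": te.family, "class": te.te_class})
    return SimBundle(cfg, tree, genes, truth)


def _config_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["te_catalogue"] = [asdict(t) for t in cfg.te_catalogue]
    return d


def _place_tes(gene: SimGene, cfg: SimConfig, rng: np.random.Generator,
               enriched: bool) -> None:
    """Insert TE annotations (intervals only) into flanks and introns."""
    lam = cfg.te_per_gene * (cfg.te_flank_enrichment if enriched else 1.0)
    n = int(rng.poisson(lam))
    weights = np.array([f.weight for f in cfg.te_catalogue])
    weights = weights / weights.sum()
    # host segments: flanks and introns (never exon borders)
    segments = []
    pos = 1
    for comp in COMPONENTS:
        ln = len(gene.parts[comp])
        if comp in ("flank5", "intron1", "intron2", "flank3"):
            segments.append((pos, pos + ln - 1))
        pos += ln
    seg_lens = np.array([e - s + 1 for s, e in segments], dtype=float)
    seg_p = seg_lens / seg_lens.sum()
    for _ in range(n):
        fam = cfg.te_catalogue[int(rng.choice(len(weights), p=weights))]
        si = int(rng.choice(len(segments), p=seg_p))
        s0, s1 = segments[si]
        span = min(fam.length, s1 - s0)
        start = int(rng.integers(s0, max(s0 + 1, s1 - span + 1)))
        gene.tes.append(TeAnnotation(gene.gene_id, start, start + span - 1,
                                     family=fam.family,
                                     superfamily=fam.superfamily,
                                     te_class=fam.te_class,
                                     divergence=float(rng.exponential(8.0))))


# ---------------------------------------------------------------------------
# truth replay


def replay_truth_log(truth: TruthLog) -> Dict[str, Dict[str, str]]:
    """Re-apply the logged events and substitutions from the root state.

    Returns per-tip component dictionaries; by construction these must
    match the simulated tips byte-exactly.
    """
    cfg = truth.config
    if not cfg.get("tree_newick"):
        raise ValueError("replay requires the tree newick in the config")
    tree = dendropy.Tree.get(data=cfg["tree_newick"], schema="newick",
                             suppress_internal_node_taxa=False)
    recs = {r["node"]: r for r in truth.records}
    out: Dict[str, Dict[str, str]] = {}
    sig, pro = cfg["signal_len"], cfg["pro_len"]
    node_state: Dict[int, Dict[str, str]] = {
        id(tree.seed_node): dict(truth.root_parts)}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        lab = nd.taxon.label if nd.taxon else (nd.label or f"__{id(nd)}")
        parts = dict(node_state[id(nd.parent_node)])
        rec = recs[lab]
        g = SimGene(lab, parts, sig, pro)
        for ev in rec["events"]:
            g = _replay_event(g, ev)
        for comp, i, a, b in rec["substitutions"]:
            s = g.parts[comp]
            if s[i] != a:
                raise ValueError(f"replay mismatch at {lab}:{comp}:{i}")
            g.parts[comp] = s[:i] + b + s[i + 1 :]
        node_state[id(nd)] = g.parts
        if nd.is_leaf():
            out[lab] = dict(g.parts)
    return out


def _replay_event(g: SimGene, ev: dict) -> SimGene:
    g = copy.deepcopy(g)
    if ev["op"] == "duplication":
        a, b = ev["cds_interval"][0] - 1, ev["cds_interval"][1]
        off3 = g.cds_offset3
        e3 = g.parts["exon3cds"]
        la, lb = a - off3, b - off3
        g.parts["exon3cds"] = e3[:lb] + e3[la:lb] + e3[lb:]
        return g
    mech = ev["mechanism"]
    if mech == "nonsense_point":
        pos = ev["cds_pos"] - 1
        _edit_exon3(g, pos, pos + 1, ev["to"])
    elif mech == "deletion_stop":
        a, b = ev["cds_interval"][0] - 1, ev["cds_interval"][1]
        _edit_exon3(g, a, b, "")
    elif mech == "fusion_crossover":
        a, b = ev["cds_removed"][0] - 1, ev["cds_removed"][1]
        _edit_exon3(g, a, b, "")
    elif mech == "te_disruption":
        pos = ev["cds_pos"] - 1
        _edit_exon3(g, pos, pos, ev["te_seq"])
    else:
        raise ValueError(f"unknown logged mechanism {mech!r}")
    return g


# ---------------------------------------------------------------------------
# convenience generators used by validation studies


def simulate_loss_pair(mechanism: str, seed: int,
                       divergence: float = 0.05,
                       cfg: Optional[SimConfig] = None,
                       interdomain_divergence: float = 0.22
                       ) -> Tuple[ToxinPrecursor, ToxinPrecursor, List[TeAnnotation], dict]:
    """One (monovalent descendant, bivalent ancestor) pair with truth.

    Builds a bivalent ancestor whose domains have diverged from each other
    by ``interdomain_divergence`` (default ~80% interdomain identity, in
    line with tandem ICK domains whose most similar stretch is ~84%),
    applies one scripted loss of the given mechanism, then diverges both
    lineages so the pair differs by about ``divergence`` per site.
    """
    cfg = cfg or SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    event = None
    for _ in range(20):  # resample when a mechanism is infeasible
        anc = make_ancestor(cfg, rng)
        biv, _ = apply_duplication(anc, rng)
        # let the two domains drift apart (cysteines under purifying
        # selection stay put)
        bl = interdomain_divergence / (2 * cfg.subst_rate)
        biv, _ = evolve_branch(biv, cfg, bl, rng)
        try:
            mono, event = apply_loss(biv, mechanism, rng)
            break
        except ValueError:
            continue
    if event is None:
        raise ValueError(f"could not realise mechanism {mechanism!r}")
    half_bl = divergence / (2 * cfg.subst_rate)
    mono, _ = evolve_branch(mono, cfg, half_bl, rng)
    biv, _ = evolve_branch(biv, cfg, half_bl, rng)
    tes = []
    if mechanism == "te_disruption":
        # classification reads the transcript, so report the insertion in
        # transcript coordinates
        tes = [TeAnnotation(mono.gene_id, event["cds_pos"],
                            event["cds_pos"] + len(event["te_seq"]) - 1,
                            family=event["family"],
                            superfamily=event["superfamily"],
                            te_class=event["te_class"])]
    return mono.precursor(), biv.precursor(), tes, event


def simulate_te_landscape(n_ick: int, n_background: int, seed: int,
                          enrichment: float = 3.0,
                          flank_bp: int = 5000,
                          gene_len: int = 3000,
                          te_per_gene: float = 6.0,
                          catalogue: Optional[List[TeFamilySpec]] = None
                          ) -> Tuple[List[Gene], List[TeAnnotation], Dict[str, int]]:
    """Gene set + TE annotations with configurable flank enrichment.

    Each gene sits on its own contig with full flanks; toxin (ICK) genes
    receive ``enrichment`` times the background expected TE count.
    """
    rng = np.random.default_rng(seed)
    catalogue = catalogue or default_te_catalogue()
    weights = np.array([f.weight for f in catalogue])
    weights = weights / weights.sum()
    genes: List[Gene] = []
    tes: List[TeAnnotation] = []
    contig_lengths: Dict[str, int] = {}
    margin = 200
    for i in range(n_ick + n_background):
        is_ick = i < n_ick
        gid = f"{'ick' if is_ick else 'bg'}{i}"
        contig = f"c_{gid}"
        start = flank_bp + margin + 1
        end = start + gene_len - 1
        clen = end + flank_bp + margin
        genes.append(Gene(gid, contig, start, end, is_ick=is_ick))
        contig_lengths[contig] = clen
        lam = te_per_gene * (enrichment if is_ick else 1.0)
        for _ in range(int(rng.poisson(lam))):
            fam = catalogue[int(rng.choice(len(weights), p=weights))]
            side = rng.random() < 0.5
            lo = 1 if side else end + 1
            hi = start - 1 if side else clen
            span = min(fam.length, hi - lo)
            s = int(rng.integers(lo, max(lo + 1, hi - span + 1)))
            tes.append(TeAnnotation(contig, s, s + span - 1,
                                    family=fam.family,
                                    superfamily=fam.superfamily,
                                    te_class=fam.te_class,
                                    divergence=float(rng.exponential(8.0))))
    return genes, tes, contig_lengths
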