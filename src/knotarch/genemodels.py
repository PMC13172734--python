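"""Minimal gene-model container plus GFF3 reading and writing.

A :class:`GeneModel` is the strand-resolved exon/CDS skeleton of one
three-exon toxin gene; parsing of GFF3 files goes through :mod:`gffutils`.
All coordinates are 1-based inclusive, GFF3 style.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import gffutils


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str = "+"
    exons: List[Tuple[int, int]] = field(default_factory=list)
    cds: List[Tuple[int, int]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for s, e in self.exons + self.cds:
            if s > e:
                raise ValueError(f"{self.gene_id}: interval start {s} > end {e}")

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def spliced_cds(self, contig_seq: str) -> str:
        """Concatenate CDS segments in translation order."""
        parts = [contig_seq[s - 1 : e] for s, e in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            from .seqcore import revcomp

            seq = revcomp(seq)
        return seq

    def cds_junctions(self) -> List[int]:
        """Cumulative spliced-CDS length at each intron, in coding order."""
        lengths = [e - s + 1 for s, e in self.cds]
        if self.strand == "-":
            lengths = lengths[::-1]
        out, acc = [], 0
        for ln in lengths[:-1]:
            acc += ln
            out.append(acc)
        return out


def gene_models_from_gff3(path) -> Dict[str, GeneModel]:
    """Load gene/mRNA/exon/CDS features from a GFF3 file."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    out: Dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        exons, cds = [], []
        for f in db.children(gene, featuretype="exon"):
            exons.append((f.start, f.end))
        for f in db.children(gene, featuretype="CDS"):
            cds.append((f.start, f.end))
        out[gene.id] = GeneModel(gene.id, gene.seqid, gene.strand or "+",
                                 exons, cds)
    return out


def write_gff3(models, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            s, e = g.span
            fh.write("\t".join([g.contig, "knotarch", "gene", str(s), str(e),
                                ".", g.strand, ".", f"ID={g.gene_id}"]) + "\n")
            mrna = f"{g.gene_id}.t1"
            fh.write("\t".join([g.contig, "knotarch", "mRNA", str(s), str(e),
                                ".", g.strand, ".",
                                f"ID={mrna};Parent={g.gene_id}"]) + "\n")
            for i, (xs, xe) in enumerate(g.exons, 1):
                fh.write("\t".join([g.contig, "knotarch", "exon", str(xs),
                                    str(xe), ".", g.strand, ".",
                                    f"ID={mrna}.exon{i};Parent={mrna}"]) + "\n")
            phase = 0
            for i, (cs, ce) in enumerate(
                    g.cds if g.strand == "+" else g.cds[::-1], 1):
                fh.write("\t".join([g.contig, "knotarch", "CDS", str(cs),
                                    str(ce), ".", g.strand, str(phase),
                                    f"ID={mrna}.cds;Parent={mrna}"]) + "\n")
                phase = (3 - ((ce - cs + 1 - phase) % 3)) % 3
    return None
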