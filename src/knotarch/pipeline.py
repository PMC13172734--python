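"""End-to-end orchestration: config, candidate filtering, staged runs.

A run is a pure function of (inputs, config, seeds): the consolidated JSON
report carries a content hash, so identical configs produce identical
reports.  Defaults follow the field's working conventions for this kind of
analysis: 5,000 bp flanks, 100 bp TE-density windows, 5 bp sequence-identity
windows, 1,000 resampling replicates and a 40% identity filter (the
"twilight zone" boundary for homology inference).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import forensics, phylo, teassoc
from .architecture import (linker_conservation, linker_tail_homology,
                           partition_architecture, scan_ick_frameworks,
                           validate_gene_structure)
from .seqcore import AaSeq, pairwise_identity, write_fasta
from .simulate import SimConfig, simulate_family, simulate_te_landscape
from .genemodels import write_gff3

STAGES = ("simulate", "detect", "forensics", "teassoc", "phylo")


@dataclass
class RunConfig:
    """All tunables of a pipeline run, serialisable to/from YAML."""

    stages: List[str] = field(default_factory=lambda: list(STAGES))
    out_dir: str = "knotarch_out"
    seed: int = 0
    # inputs (optional; the simulate stage supplies them otherwise)
    peptides_fasta: Optional[str] = None
    # tunables with field-standard defaults
    flank_bp: int = 5000
    te_window_bp: int = 100
    seq_window_bp: int = 5
    reps: int = 1000
    min_identity: float = 0.40
    remnant_p_threshold: float = 0.01
    distance_model: str = "p_distance"
    bootstrap_reps: int = 200
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    #: which defaults trace to the analysis conventions vs this package
    PROVENANCE = {
        "flank_bp": "convention: +/- 5,000 bp gene flanks",
        "te_window_bp": "convention: non-overlapping 100 bp windows",
        "seq_window_bp": "convention: non-overlapping 5 bp windows",
        "reps": "convention: 1,000 resampling replicates",
        "min_identity": "convention: 40% identity twilight-zone filter",
        "remnant_p_threshold": "package convention",
        "distance_model": "package convention",
        "bootstrap_reps": "package convention",
    }

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def filter_homolog_candidates(candidates: Sequence[AaSeq], reference,
                              min_identity: float = 0.40
                              ) -> Tuple[List[AaSeq], List[Tuple[str, str]]]:
    """Filter a candidate homolog set by identity and framework presence.

    Keeps candidates with global identity >= ``min_identity`` to the
    reference AND at least one ICK framework match; dropped entries carry a
    reason code ("identity" or "framework").  The upstream similarity
    search that produced the candidates is outside this package's scope.
    """
    ref = reference.seq if hasattr(reference, "seq") else reference
    if not ref:
        raise ValueError("reference must be non-empty")
    kept, dropped = [], []
    for cand in candidates:
        ident = pairwise_identity(cand.seq, ref, mode="global").identity
        if ident < min_identity:
            dropped.append((cand.id, "identity"))
            continue
        if not scan_ick_frameworks(cand.seq):
            dropped.append((cand.id, "framework"))
            continue
        kept.append(cand)
    return kept, dropped


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    Writes per-stage artifacts under ``config.out_dir`` plus one
    consolidated JSON report with the config hash; rerunning the same
    config yields an identical report hash.
    """
    if not config.stages:
        raise ValueError("no stages requested")
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.config_hash(),
                    "config": asdict(config), "stages": {}}
    bundle = None

    if "simulate" in config.stages:
        sim_cfg = SimConfig(seed=config.seed, **config.sim)
        bundle = simulate_family(sim_cfg)
        write_fasta(bundle.contigs(), out / "contigs.fna")
        peps = [AaSeq(k, p.peptide) for k, p in
                sorted(bundle.precursors().items())]
        write_fasta(peps, out / "precursors.faa")
        write_gff3(bundle.gene_models(), out / "genes.gff3")
        (out / "truth.json").write_text(bundle.truth.to_json())
        with open(out / "tes.bed", "w") as fh:
            for te in bundle.te_annotations():
                name = f"{te.family}|{te.superfamily}|{te.te_class}|{te.divergence:.2f}"
                fh.write(f"{te.contig}\t{te.start - 1}\t{te.end}\t{name}\n")
        report["stages"]["simulate"] = {
            "n_tips": len(bundle.genes),
            "tip_valency": bundle.truth.tip_valency,
        }

    precursors = bundle.precursors() if bundle else {}

    if "detect" in config.stages:
        archs = {}
        if precursors:
            for name, prec in sorted(precursors.items()):
                archs[name] = partition_architecture(prec.mature_peptide, name)
        elif config.peptides_fasta:
            from .seqcore import read_fasta

            for rec in read_fasta(config.peptides_fasta, alphabet="aa"):
                archs[rec.id] = partition_architecture(rec.seq, rec.id)
        stage = {"valency": {k: a.valency for k, a in archs.items()}}
        multi = [a for a in archs.values() if a.valency >= 2]
        if len(multi) >= 2:
            cons = linker_conservation(multi)
            stage["linker_conserved_prefix"] = cons.conserved_prefix()
            stage["linker_mean_identity"] = round(
                cons.mean_pairwise_identity, 4)
        if bundle:
            structure = {}
            for name, g in sorted(bundle.genes.items()):
                rep = validate_gene_structure(g.gene_model(), g.contig_seq,
                                              archs[name])
                structure[name] = rep.verdicts
            stage["structure"] = structure
        report["stages"]["detect"] = stage
        with open(out / "architectures.tsv", "w") as fh:
            fh.write("id\tvalency\tlinkers\ttail\n")
            for k, a in sorted(archs.items()):
                fh.write(f"{k}\t{a.valency}\t"
                         f"{','.join(l.seq for l in a.linkers)}\t{a.tail}\n")

    if "forensics" in config.stages and bundle:
        valency = bundle.truth.tip_valency
        multis = sorted(k for k, v in valency.items() if v >= 2)
        monos = sorted(k for k, v in valency.items() if v == 1)
        calls = {}
        if multis:
            anc_name = multis[0]
            for m in monos:
                tes = [t for t in bundle.genes[m].tes]
                call = forensics.classify_loss_mechanism(
                    precursors[m], precursors[anc_name])
                calls[m] = {"mechanism": call.mechanism,
                            "ancestor": anc_name}
        report["stages"]["forensics"] = {"calls": calls}
        (out / "loss_calls.json").write_text(json.dumps(calls, indent=1))

    if "teassoc" in config.stages and bundle:
        genes = []
        contig_lengths = {}
        for name, g in sorted(bundle.genes.items()):
            model = g.gene_model()
            s, e = model.span
            genes.append(teassoc.Gene(name, name, s, e, is_ick=True))
            contig_lengths[name] = len(g.contig_seq)
        df, excluded = teassoc.flank_te_density(
            genes, bundle.te_annotations(), contig_lengths,
            flank_bp=min(config.flank_bp,
                         bundle.config.flank_len - 10))
        report["stages"]["teassoc"] = {
            "mean_flank_density": round(float(df["density_all"].mean()), 4)
            if len(df) else None,
            "excluded": excluded,
        }
        df.to_csv(out / "flank_density.tsv", sep="\t", index=False)

    if "phylo" in config.stages and bundle:
        # prepropeptide region is untouched by domain events, so the tip
        # CDS prefixes form a trivial alignment
        pre_len = 3 * (bundle.config.signal_len + bundle.config.pro_len)
        seqs = [(k, p.cds[:pre_len]) for k, p in
                sorted(precursors.items())]
        dm = phylo.distance_matrix(seqs, config.distance_model)
        vt = phylo.nj_tree(dm)
        vt.tip_states = dict(bundle.truth.tip_valency)
        counts, summary = phylo.enumerate_rootings(vt, vt.tip_states)
        report["stages"]["phylo"] = {
            "n_taxa": len(dm.taxa),
            "losses_across_rootings": [summary["min_losses"],
                                       summary["max_losses"]],
        }
        vt.tree.write(path=str(out / "tree.nwk"), schema="newick")

    payload = json.dumps(report, sort_keys=True, default=str)
    report["report_hash"] = hashlib.sha256(payload.encode()).hexdigest()[:16]
    (out / "report.json").write_text(json.dumps(report, indent=1,
                                                default=str))
    return report
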