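# Methods

`knotarch` reconstructs how multi-domain inhibitor-cystine-knot (ICK)
peptide toxins gain and lose domains. This note records the models and
conventions the package commits to, the reasoning behind the genuinely
open design choices, and what the bundled simulator does and does not
emulate.

## The domain model

An ICK domain is recognised from its cysteine framework

    C x(2–7) C x(3–10) C C x(1–4) C x(3–13) C

with six cysteines, the third and fourth adjacent. A mature peptide is
partitioned around its non-overlapping framework matches: the *domain*
runs from the first to the last framework cysteine; residues strictly
between consecutive domains form *linkers*; residues after the final
cysteine are the *C-terminal tail*; anything before the first domain is
the *leader*. The domain count is the peptide's *valency*. This
convention is chosen because it makes the partition reconstruction-exact
(leader + domains + linkers + tail concatenates back to the input,
character for character), which every downstream coordinate calculation
relies on. Where several framework matches share a start, the shortest
total span wins and scanning proceeds greedily left to right; an
`all_matches` mode preserves auditability. Extra cysteines inside the
x-spacers do not invalidate a match.

The conserved gene architecture checked by `validate_gene_structure` is
three exons — signal peptide, propeptide, mature peptide — separated by a
phase-1 and then a phase-2 intron (phase = spliced CDS length mod 3 at
the junction), with the mature peptide wholly inside exon 3 and no intron
between tandem domains. Intra-exon tandem duplication predicts exactly
this layout; exon shuffling would leave an interdomain intron.

## Alignment and identity conventions

One scoring scheme is used throughout: match +1, mismatch −1, linear gap
−2, deterministic Needleman–Wunsch traceback (diagonal, then vertical,
then horizontal). Global identity counts gap columns in the denominator;
ungapped identity counts per-position matches over the full length —
this reproduces the "n/m residues" bookkeeping used in comparative work
on these toxins (e.g. a four-residue linker against a four-residue tail
scoring 2/4). Ambiguity symbols (N for DNA, X for protein) never match
anything, including themselves; the alphabet is inferred, with sequences
drawn entirely from {A,C,G,T,N} treated as DNA. A semi-global variant
(free unaligned transcript tail) aligns a CDS against a longer
transcript; penalising the tail would shred the shorter sequence across
the longer one to harvest chance matches.

`best_local_match` finds the highest-scoring ungapped segment pair under
+1/−1 scoring, with ties resolved toward the longer segment and then the
smaller start coordinates. Because ties favour length, a planted exact
segment may be reported inside a longer break-even extension; the score
and containment are what is guaranteed. `find_inverted_repeats`
enumerates all maximal arm pairs on the anti-diagonals of the
self-versus-reverse-complement dot plot, with an explicit mismatch
budget; arms may not overlap.

## Loss-mechanism forensics

For a monovalent descendant and its multivalent ancestor, the classifier
evaluates a cascade and keeps the full evidence table:

1. **TE disruption** — a transposable-element annotation overlapping the
   transcript at or beyond the ORF boundary, where the missing domain
   should lie.
2. **Premature stop?** The transcript region beyond the first in-frame
   stop is searched for a remnant of the ancestor's distal region (last
   domain through the natural stop). A long trace (≥25 matched bases at
   ≥70% identity) counts anywhere; a short one (≥12 matches) only when it
   begins within 30 bp of the stop, because genuine remnants are
   stop-adjacent while chance matches scatter uniformly over the UTR.
   Without a remnant the stop is taken to be the natural one.
3. **Deletion-induced stop** — a 1–30 bp deletion (relative to the
   ancestor, gap runs clustered across aligner wobble and required to
   have net length ≥1 so paired insertion/deletion artefacts around a
   substitution are rejected) upstream of the stop. A frameshifting
   deletion upstream of the stop is accepted as causal by construction;
   an in-frame deletion must pass a restoration test (re-inserting the
   ancestral bases pushes the first stop downstream). Full-length ORF
   restoration is deliberately *not* required: the released remnant
   evolves fast and legitimately accumulates new stops.
4. **Nonsense point mutation** — the stop codon aligns to a contiguous,
   in-frame, internal, non-stop ancestor codon with an intact reading
   frame upstream. The evidence records a `codon_from → codon_to` pair
   differing at exactly one position (when divergence has added a second
   difference, the base whose change created the stop is the one
   reported) and the 1-based transcript position of that base.
5. **Fusion by unequal crossing-over** — evaluated when no premature
   stop is diagnosed. The mono's domain span is compared position-wise
   against each ancestral domain; for every split point b the score is
   (matches to domain 1 before b) + (matches to domain 2 from b). The
   breakpoint is reported as the *interval* of split points attaining the
   maximum — identical interdomain stretches make the point
   unidentifiable in principle. Chimerism is accepted when the argmax is
   interior and a changepoint permutation test on the informative sites
   (positions where exactly one parent matches) rejects the single-parent
   null at α = 0.05. Under a single-parent origin the informative-site
   labels are exchangeable, so the permutation null is exact and the test
   self-calibrates to however much the two domains have diverged. The
   best ungapped domain-1 versus domain-2 local match near the breakpoint
   is reported as the putative recombination-facilitating stretch, and
   `crossover_byproducts` emits both reciprocal products (the contracted
   single-domain fusion and the expanded three-domain peptide), which
   conserve total length exactly.

Positions are 1-based from the start codon, per the coordinate style
used when such events are described in the literature.

Remnant detection for its own sake (`scan_utr_remnant`) scores the best
ungapped nucleotide match and the best translated match over all six
frames against the donor domain, and assigns each an empirical p-value
from dinucleotide-preserving shuffles of the query (Altschul–Erickson
Eulerian-walk sampling; 1,000 shuffles and p < 0.01 by default). Profiles
are position-specific scoring matrices with additive pseudocounts rather
than full profile HMMs: at this scale a PSSM performs the same detection
task with a transparent null.

## TE association

Density is always a coverage fraction: TE intervals are union-merged, so
overlapping annotations never double-count. Genes without a full flank
(default ±5,000 bp) on both sides are excluded and listed. The
toxin-versus-background comparison keeps the field's resampling design:
observed statistic = mean toxin-flank density − mean background density;
the null replaces the toxin group with equal-sized random subsets of the
background pool, drawn without replacement (1,000 times by default), and
the two-sided empirical p carries the add-one correction so it is never
zero. Windowed tracks (default 100 bp, non-overlapping) come with the
whole-contig mean density as the baseline. Shared insertions between
paralog regions are compared at the TE-family level, with a
pairwise-but-not-universal filter for synteny questions.

## Phylogenetics and valency events

The internal tree path is neighbor joining on p- or Kimura-2-parameter
distances with a classical column bootstrap; external newick trees and
alignments are first-class inputs everywhere, and maximum-likelihood
inference is deliberately out of scope. Tie-breaking is lexicographic on
taxon ids, so trees, supports and event counts are bit-reproducible.
K2P saturation raises an error naming the pair rather than silently
truncating.

Valency states collapse to binary (multivalent = two or more domains).
The single-gain (Dollo-style) model places the one gain on the edge
above the most recent common ancestor of all multivalent tips — the
loss-minimising placement compatible with a single origin — and counts
the minimum losses below it; Fitch parsimony gives the unconstrained
minimum. `enumerate_rootings` repeats the count for every candidate root
edge of an unrooted tree, because loss counts are rooting-dependent: on
the bundled topology fixture (a wholly single-domain clade, an early
paralog group, and three mixed clades) the two competing rootings give
three versus four independent losses.

## The simulator

`knotarch.simulate` generates truth-tagged families: a single-domain
three-exon ancestor (exon CDS lengths 3·signal+1 and 3·pro−2 give intron
phases 1 and 2; mature peptide wholly in exon 3), intra-exon duplication
that copies the domain-plus-tail segment so the ancestral tail becomes
the interdomain linker, the four loss mechanisms, and K2P substitutions
(transition:transversion 2:1) along a labelled tree. Defaults, with the
reasoning:

- framework spacings (7, 9, 3, 11) — a 36-residue domain, the scale of
  the mature toxins this analysis targets;
- signal 18 aa, propeptide 13 aa, leader 2 aa, tail 4 aa, 3'UTR 220 bp,
  introns 700/900 bp, flanks 6 kb;
- substitution probability 0.03 per site per branch-length unit;
- interdomain divergence at loss time ≈ 0.22 per site (~80% interdomain
  nucleotide identity): in the motivating family the *most similar*
  interdomain stretch is 84% over 25 bp, so whole-domain identity lies
  below that;
- remnant/UTR regions evolve at 2× the base rate (released constraint);
- TE catalogue dominated by class II elements, Tc1/Mariner heaviest, and
  a 3× flank-enrichment factor around toxin genes.

Purifying selection is emulated structurally: framework cysteine codons,
the start codon and the ORF-defining stop are protected, and any
substitution draw that creates a new premature stop in the functional
ORF is reverted at that codon only (whole-draw rejection would bias
realised divergence downward). Protecting the premature stop of a
pseudogenised transcript is a sampling statement, not selection: tips
*observed* as monovalent are by definition those that still carry their
stop. The ancestor's tail is drawn so that at least one codon is a
single substitution away from a stop, keeping scripted nonsense losses
feasible; after deep divergence that codon can still be lost, in which
case the event raises and callers resample.

Every stochastic choice comes from one seeded generator and is logged;
replaying the truth log from the root state reproduces each tip
byte-exactly, and identical configs produce identical bundles.

What the simulator does **not** emulate: population-level processes
(coalescence, recombination graphs, selection coefficients), indel
background noise outside the scripted events, alternative splicing,
alternative genetic codes, TE sequence realism beyond length/family
bookkeeping, and genome-scale context (a gene per contig). Passing the
recovery studies therefore demonstrates that the analysis logic is
correct and calibrated under its stated assumptions — not that real
transcriptome data are this clean.

## Validation studies and problem sizes

The seeded studies in `knotarch.studies` score every stage against
generator truth: 200 loss events (50 per mechanism, pair divergence
drawn up to 10%/site), 100 constructed fusions for breakpoint
containment, 1,000 null scans for the remnant type-I rate (nucleotide
level, 199 shuffles per scan) and 100 planted-remnant scans for
recovery, 500 null runs for permutation-p uniformity (KS) and 100
enriched landscapes for power, a scripted one-gain/four-loss family for
Dollo counting, and the rooting fixture above. These sizes were chosen
so the full suite runs comfortably on a single CPU while keeping the
binomial noise on each rate a few percent.

## Known limitations

- Nonsense and deletion calls need a recognisable UTR remnant; once the
  remnant has degraded beyond the detection floor the call is honestly
  `unresolved`.
- Fusions whose breakpoint sits within ~10–15 bp of a domain edge leave
  almost no informative sites on the short side and are frequently
  unidentifiable in principle; the permutation test then (correctly)
  declines to call them.
- The breakpoint interval, not a point, is the deliverable; within
  identical interdomain stretches no method can do better.
- The permutation flank test assumes the background pool is large
  relative to the toxin set (as in real annotations); with a pool close
  in size to the group the subset null degenerates.
- Coordinates assume transcripts start at the start codon; 5'UTRs are
  not modelled.
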