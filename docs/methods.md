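# Methods

## Scope and model of the biology

The package analyses a gene architecture in which a disordered C-terminal
protein region, encoded by a run of exons (labelled 37–46 after the
vertebrate co-repressor convention), carries short linear motifs — CoRNR
boxes (`L/I.x.x.I/H.I.x.x.x.I/L`) and a C-terminal SHARP-interaction
motif — and in which binary alternative-splicing events (an internal 5′
donor inside exon 37, cassette exons) determine each isoform's motif
complement. Three computations sit at the core: scoring 5′ splice donors in
bits, scanning for single substitutions that create a GT donor, and
enumerating the isoform space.

## Coordinates and splicing

Internal coordinates are 0-based half-open; GFF3 I/O is 1-based inclusive.
All analyses run on the sense strand: minus-strand exons are
reverse-complemented on extraction, and an internal-donor *cut index* is
always a sense-strand retained length (a cut at c keeps the exon's first c
sense bases). A frame-preserving event removes a multiple of 3 bases;
frame-breaking choices are permitted but flagged `frameshift` and translated
to the first stop. Translation uses the standard code and returns the
peptide up to (not including) the first stop plus a stop-seen flag.

## Donor windows and scorers

A donor window is 9 bases: the last 3 retained exonic bases and the next 6
bases (exon remainder first, then intron), putting the GT at window
positions 4–5. This is the convention of the maximum-entropy donor models
used in the splice-site literature; a 9-mer cannot literally centre a
dinucleotide, so "centred on the GT" descriptions map to this layout.
Windows containing N are flagged invalid and never scored.

Scores are log₂(P_model(w)/P_background(w)) in bits, with an independent
base-frequency background (uniform by default) or, when supplied, a decoy
model in the denominator.

- **PWM**: per-position frequencies f = (count + α)/(n + 4α) with
  pseudocount α = 0.5 by default (small-sample stability; the choice is not
  critical and is exposed everywhere).
- **Maximum entropy**: the distribution of maximal entropy whose declared
  marginals (all singletons plus, by default, adjacent pairs — nearest-
  neighbour dependence without enumerating 4⁹ parameters) equal the
  smoothed empirical marginals, fitted by iterative proportional fitting
  (IPF). Smoothing adds one uniform mass m = 4α over the joint, so the
  marginals of different constraint orders are mutually consistent (a
  convergence requirement for IPF) and the singleton marginals reproduce
  the PWM formula exactly; with singleton constraints only the fitted model
  is analytically the PWM, which the tests assert to 1e-6 bits. Fitting
  iterates until the worst marginal discrepancy falls below `tol` (1e-9
  default) and fails loudly, naming the worst constraint, if `max_iter` is
  exhausted. The model stores per-constraint factor tables and the
  normalizer, never a full 4⁹ table; fitting itself uses a transient 4⁹
  joint (2 MB), which is cheap at this size.
- **Table**: a window→score lookup so that externally produced score sets
  (e.g. published donor-model tables, which this package does not
  redistribute) can drive the identical scan machinery.

Model files are plain text with floats written as `repr`, so
serialization round-trips bit-exactly.

A gene's validated donors are summarized as mean and sample SD (n−1) of
their scores; the mutation scan reports z = (score − mean)/sd and flags
candidates exceeding the mean, the reporting criterion for a "strong"
reconstituted site. Both raw score and z are emitted, since ranking by
either is monotone-identical for a fixed reference distribution.

## Mutation scan

Exactly six dinucleotides are one substitution from GT (AT, CT, TT, GA, GC,
GG); the scan enumerates them all, applies the substitution, and scores the
resulting window. Existing GT sites (distance 0) are surveyed only under a
flag, so a paralogue's real internal donor can be examined with the same
code path. Candidates within 3 bases of the exon start (or lacking 6 bases
of downstream context) are flagged rather than scored with padding.
Frame compatibility of a donor at cut c in an exon of length L is
(L − c) mod 3 = 0. The in-frame stop scan reads codons from a frame offset
and reports the first TAA/TAG/TGA within a horizon — the signature of an
internal donor whose disuse would truncate the protein.

## Conservation scan

Orthologous windows default to 115 bases centred on the reference internal
donor. The reference site is anchored in each species by Needleman–Wunsch
global alignment (match +1, mismatch −1, gap open −4, gap extend −1 —
declared defaults, configurable; no alignment parameters are canonical for
this task). Calls: `yes` (GT with score ≥ threshold), `weak` (GT below
threshold), `gt_absent` (substituted), `no` (aligned to a gap). The weak
threshold defaults to mean − 2 SD of the validated donors when stats are
supplied, else 0 bits; "poor consensus donor" has no canonical numeric cut,
so the threshold is explicit and adjustable.

## Isoform space

k binary events give exactly 2^k isoforms, enumerated in binary-counting
order (default choice = 0, last event fastest). Isoform identity is the
choice vector, not the protein string: distinct transcripts yielding equal
proteins remain distinct isoforms. The motif complement is the multiset of
(pattern, status) hits on the isoform's protein. Note that patterns sharing
one consensus (the three CoRNR boxes ship with identical specs) each hit
every CoRNR site; complement differences between isoforms therefore appear
once per pattern name.

## Synthetic data generator

The generator emulates the structures the analyses need, never splicing
outcomes or expression: a 10-exon gene (exon lengths multiples of 3,
introns 250 bases by default with canonical GT..AG ends and an optional
short-intron override), four binary events, three CoRNR boxes and one
C-terminal SHARP-like motif planted in a random background peptide, donor
windows drawn per position from a declared 9×4 frequency model
approximating the vertebrate consensus (C/A)AG|GTAAGT with 70–90%
consensus weight (exact weights live in `data/default_config.yaml`, not in
code), and optionally a cryptic GA one substitution from a strong donor
context. "Strong" defaults to the expected log-odds of a model draw
(GT-forced), so a planted site is a representative-or-better donor rather
than a lucky weak sample; a numeric floor can be set in the config.

Determinism: every generator is a pure function of (config, seed).
Back-translation uses the alphabetically first codon per amino acid —
deterministic, with no claim of codon realism. Chance motif matches in the
background peptide are scrubbed by rewriting one free constrained residue
to G (no shipped pattern allows G at a constrained position); the generator
then re-derives every planted feature from its own output (motif scan of
the translated CDS, donor windows rebuilt from the genome, cryptic GA
present) and rebuilds from a derived substream in the rare case a donor
overwrite recreated a motif by chance.

What the generator does *not* emulate — real codon usage, branch points and
splicing-regulatory elements, intron length variation, alignment-degrading
divergence, genuine MaxEntScan score tables — bounds what green tests show:
they demonstrate the machinery is correct on its declared model, not that
any particular real gene will reproduce a published figure. Reproducing the
published X. laevis NCoR1 numbers (three convertible sites above a
validated-donor mean just over 8 bits) requires the user to supply the real
genomic sequences, validated donor list and a MaxEntScan-compatible score
table via the `table` model kind; the pipeline then runs unchanged. This
optional external validation needs downloads and is deliberately outside
the test suite.

## Problem sizes in the shipped checks

The self-checks run at sizes chosen to keep the whole suite fast while
leaving no sampling doubt: 500 random 200-base exons for scan/brute-force
equivalence, 100 windows for the maxent–PWM limit, a fully enumerated
64-sequence IPF oracle, 2000 training windows for parameter recovery
(TV ≤ 0.05 per position), 50 seeded loci for planted-site ranking (≥95%
top-ranked), the exhaustive frame rule to exon length 60, and 200 planted
proteins for motif-status recovery.

## Known limitations

- One gene model per gene_id; no trans-splicing, non-canonical acceptors or
  multi-isoform GFF3 reconciliation.
- No acceptor-site, branch-point or ESE/ISS modelling; the scan is
  GT-donor-specific (no GC–AG or U12 AT–AC introns).
- SANT domains are not detected; the family-validation rule takes the count
  from external annotation, as in practice that check is done against
  curated domain databases.
- No prediction of splicing outcome: donor strength is necessary but not
  sufficient, and outcome depends on cellular context beyond sequence.
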