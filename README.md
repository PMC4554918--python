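# slimsplice

Tools for analysing how genes diversify through **short linear motifs
(SLiMs)** and **alternative splicing**, in the style of the NCoR-family
nuclear co-repressors. In those genes a disordered C-terminal region carries
CoRNR boxes — nuclear-receptor interaction motifs with the consensus
`L/I.x.x.I/H.I.x.x.x.I/L` — spread across ~10 exons, and alternative
splicing (internal 5′ splice donors, cassette exons) varies the motif
complement between protein isoforms. A single point mutation that destroys
an internal donor GT (leaving, say, a GA) silently removes an entire axis of
isoform diversity; conversely, one substitution can reconstitute it.

The package provides, as a library plus a `slimsplice` command line:

- **Motif toolkit** — degenerate pattern parsing, protein scanning with
  complete/partial calls (a *partial* motif mismatches only at a key
  position, e.g. the diagnostic C-terminal L/I of the CoRNR box), mapping of
  peptide hits back to their encoding exons, species × motif acquisition
  matrices, and the orthologue validation rule (≥2 CoRNR boxes, a C-terminal
  SHARP motif in the correct order, ≥2 externally annotated SANT domains).
- **Splice-donor scoring** — nine-base donor windows (3 exonic + 6
  intron-side bases, GT at window positions 4–5) scored in bits as
  log₂(P_model/P_background), with trainable scorers: a position weight
  matrix, a maximum-entropy model with declared marginal constraints fitted
  by iterative proportional fitting, and a lookup table for externally
  produced score sets.
- **Mutation scan** — enumerate every dinucleotide one substitution away
  from GT in an exon, score the reconstituted donor window, standardize
  against the gene's validated donors (z = (s − mean)/sd), and flag
  reading-frame compatibility ((exon length − cut) mod 3 = 0).
- **Conservation scan** — survey GT positions and strengths across
  orthologous windows and classify the homologue of a reference donor site
  (present / weak / GT lost / unalignable) via global pairwise alignment.
- **Isoform space** — enumerate all 2^k transcripts over k binary splicing
  events, with each isoform's motif complement.
- **Synthetic data** — seeded generators for gene models with canonical
  GT..AG introns, donor windows from a declared base-frequency model,
  planted motifs and cryptic sites, and orthologue panels, all with recorded
  ground truth.

## Worked example

Simulate a locus in which the internal donor of exon 37 has decayed to GA,
train a donor model on 2000 simulated donor windows, and ask which single
substitutions would reconstitute a strong donor:

```python
import slimsplice as ss
from slimsplice.genomics import downstream_flank, exon_sense_sequence

cfg = ss.ncor1_like_config()
training, _ = ss.simulate_donor_training_set(cfg["donor_model"], 2000, seed=1)
model = ss.train_pwm(training)

locus = ss.simulate_locus(cfg, seed=1)
stats = ss.donor_score_stats(locus.donors, model)

exon = locus.gene.exon("37")
cands = ss.enumerate_gt_candidates(
    exon_sense_sequence(locus.genome, locus.gene, exon),
    downstream_flank(locus.genome, locus.gene, exon, 6), exon_label="37")
ranked = ss.score_candidates(cands, model, stats)
```

Output (top of the ranking):

```
validated donors: mean 8.52 bits, sd 2.67 (n=9)
pos  dinuc  sub   window     score      z  >mean  in-frame
105  GA     1>T  CAGGTAAGA   11.16   0.98  True   True
157  GA     1>T  GAGGTATGT    9.53   0.38  True   False
 43  GA     1>T  CAGGTAAAC    7.13  -0.52  False  False
planted cryptic site: ('37', 105)
```

The top candidate is the planted GA at position 105: converting it to GT
yields a donor scoring 11.2 bits, about 1 SD above the mean of the gene's
validated donors, and splicing there preserves the reading frame into exon
38 — exactly the signature of a site whose splicing capacity could be
restored by one point mutation. The same analysis is available as
`slimsplice mutation-scan`; `slimsplice --help` lists the other commands
(simulate, scan-motifs, map-motifs, acquisition-matrix, validate-family,
train-donor-model, score-donors, conservation-scan, enumerate-isoforms).

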