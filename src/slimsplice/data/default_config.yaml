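# Default synthetic locus: a 10-exon C-terminal co-repressor gene region in
# the NCoR2 style. Exon lengths are multiples of 3 so cassette events and the
# internal donor are frame-preserving; labels follow the vertebrate 37-46
# numbering. The donor base-frequency model approximates the vertebrate
# consensus (C/A)AG|GTAAGT with 70-90% consensus weight per position.
gene_id: simNCoR2
contig: chrSim
strand: "+"
flank: 100
intron_length: 250
intron_length_overrides: {}
exons:
  - {label: "37", length: 168}
  - {label: "38", length: 90}
  - {label: "39", length: 96}
  - {label: "40", length: 102}
  - {label: "41", length: 84}
  - {label: "42", length: 120}
  - {label: "43", length: 90}
  - {label: "44", length: 108}
  - {label: "45", length: 96}
  - {label: "46", length: 120}
motifs:
  - {name: CoRNR1, spec: "L/I.x.x.I/H.I.x.x.x.I/L", exon: "37", aa_offset: 38, status: complete}
  - {name: CoRNR2, spec: "L/I.x.x.I/H.I.x.x.x.I/L", exon: "39", aa_offset: 10, status: complete}
  - {name: CoRNR3, spec: "L/I.x.x.I/H.I.x.x.x.I/L", exon: "42", aa_offset: 12, status: complete}
  # synthetic stand-in for the C-terminal SHARP-interaction motif
  - {name: SHARP, spec: "L.x.D.x.I.x.x.L", exon: "46", aa_offset: 28, status: complete}
events:
  - {event_id: e37b, kind: alternative_internal_donor, exon: "37", cut_index: 105}
  - {event_id: e40, kind: cassette_exon, exon: "40"}
  - {event_id: e43, kind: cassette_exon, exon: "43"}
  - {event_id: e44, kind: cassette_exon, exon: "44"}
cryptic_site: null
# strength floor for a planted internal/cryptic donor context: "mean" means
# the expected log-odds of a model draw (a representative-or-better donor);
# a number fixes an absolute floor in bits against the uniform background
planted_donor_min_score: mean
background: [0.25, 0.25, 0.25, 0.25]
# 9 x 4 base frequencies, columns A C G T, rows = window positions 1-9
# (3 exonic, then 6 intron-side; positions 4-5 are the GT dinucleotide)
donor_model:
  - [0.37, 0.37, 0.13, 0.13]
  - [0.70, 0.10, 0.10, 0.10]
  - [0.08, 0.04, 0.80, 0.08]
  - [0.01, 0.01, 0.97, 0.01]
  - [0.01, 0.01, 0.01, 0.97]
  - [0.70, 0.05, 0.20, 0.05]
  - [0.75, 0.08, 0.09, 0.08]
  - [0.05, 0.05, 0.85, 0.05]
  - [0.09, 0.08, 0.08, 0.75]
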