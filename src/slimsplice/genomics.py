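"""Sequence and gene-model primitives.

Internal coordinates are 0-based half-open throughout; GFF3 input/output uses
the standard 1-based inclusive convention. All splicing and motif analyses run
on the sense (transcribed) strand: minus-strand exon sequences are
reverse-complemented on extraction, and internal-donor cut indices are always
sense-strand retained lengths.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class AlphabetError(ValueError):
    """A sequence contains characters outside its declared alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence over a declared alphabet, upper-cased on ingest."""

    id: str
    seq: str
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        allowed = NUCLEOTIDE_ALPHABET if self.alphabet == "nucleotide" else PROTEIN_ALPHABET
        for pos, ch in enumerate(self.seq):
            if ch not in allowed:
                raise AlphabetError(
                    f"record {self.id!r}: illegal {self.alphabet} character "
                    f"{ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.seq)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_sequences(
    path: str | Path,
    alphabet: str = "nucleotide",
    rna_to_dna: bool = False,
) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, in file order.

    Sequences are upper-cased; with ``rna_to_dna`` every U is rewritten to T
    before the alphabet check. An empty file is an error, as is any character
    outside the declared alphabet (reported with record id and position).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rna_to_dna:
            seq = seq.replace("U", "T")
        records.append(SequenceRecord(id=rec.id, seq=seq, alphabet=alphabet))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_sequences(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i : i + 70] + "\n")


@dataclass
class Exon:
    """One exon: genomic interval plus optional internal (cryptic) donor cuts.

    ``internal_donors`` are retained-length positions in sense orientation: a
    cut at ``c`` means splicing from an internal donor keeps the first ``c``
    sense-strand bases of the exon.
    """

    label: str
    start: int
    end: int
    internal_donors: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"exon {self.label!r}: start {self.start} must be < end {self.end}")
        for c in self.internal_donors:
            if not 0 < c < len(self):
                raise ValueError(
                    f"exon {self.label!r}: internal donor cut {c} outside (0, {len(self)})"
                )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SpliceEvent:
    """A binary alternative-splicing event on one exon.

    ``cassette_exon`` events include or exclude the whole exon;
    ``alternative_internal_donor`` events choose between the exon's terminal
    donor (the "long" form) and an internal donor at ``cut_index`` (the
    "short" form, retaining only the first ``cut_index`` sense bases).
    """

    event_id: str
    kind: str
    exon_label: str
    cut_index: int | None = None

    DEFAULT_CHOICES = {"cassette_exon": "included", "alternative_internal_donor": "long"}
    ALT_CHOICES = {"cassette_exon": "excluded", "alternative_internal_donor": "short"}

    def __post_init__(self) -> None:
        if self.kind not in ("cassette_exon", "alternative_internal_donor"):
            raise ValueError(f"unknown splice event kind {self.kind!r}")
        if self.kind == "alternative_internal_donor" and self.cut_index is None:
            raise ValueError(f"event {self.event_id!r}: internal-donor event needs cut_index")


@dataclass
class GeneModel:
    """Strand-aware exon architecture of one gene.

    Exons are stored in transcription order (5'→3' on the sense strand) and
    must be non-overlapping with unique labels. ``cds_start_phase`` is the
    number of bases at the start of the spliced sequence that complete an
    upstream codon (0 for models whose first exon starts a codon).
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[Exon]
    cds_start_phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not 0 <= self.cds_start_phase <= 2:
            raise ValueError(f"gene {self.gene_id!r}: cds_start_phase must be 0-2")
        labels = [e.label for e in self.exons]
        if len(set(labels)) != len(labels):
            raise ValueError(f"gene {self.gene_id!r}: duplicate exon labels")
        by_start = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(by_start, by_start[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"gene {self.gene_id!r}: exons {a.label!r} and {b.label!r} overlap"
                )
        expected = by_start if self.strand == "+" else by_start[::-1]
        if [e.label for e in expected] != labels:
            raise ValueError(
                f"gene {self.gene_id!r}: exons not in transcription order for strand "
                f"{self.strand!r}"
            )

    def exon(self, label: str) -> Exon:
        for e in self.exons:
            if e.label == label:
                return e
        raise KeyError(f"gene {self.gene_id!r} has no exon labelled {label!r}")


def exon_sense_sequence(genome: SequenceRecord, gene: GeneModel, exon: Exon) -> str:
    """The exon's sequence on the transcribed strand."""
    raw = genome.seq[exon.start : exon.end]
    return raw if gene.strand == "+" else reverse_complement(raw)


def downstream_flank(
    genome: SequenceRecord, gene: GeneModel, exon: Exon, length: int
) -> str:
    """Genomic sequence immediately 3' of the exon in transcription direction."""
    if gene.strand == "+":
        return genome.seq[exon.end : exon.end + length]
    return reverse_complement(genome.seq[max(0, exon.start - length) : exon.start])


def _resolve_choices(
    events: Sequence[SpliceEvent], choices: Mapping[str, str] | None
) -> dict[str, str]:
    ids = [ev.event_id for ev in events]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate event_id among splice events")
    resolved = {ev.event_id: SpliceEvent.DEFAULT_CHOICES[ev.kind] for ev in events}
    for key, sel in (choices or {}).items():
        if key not in resolved:
            raise KeyError(f"unknown splice event key {key!r}")
        resolved[key] = sel
    by_id = {ev.event_id: ev for ev in events}
    for key, sel in resolved.items():
        ev = by_id[key]
        valid = {SpliceEvent.DEFAULT_CHOICES[ev.kind], SpliceEvent.ALT_CHOICES[ev.kind]}
        if sel not in valid:
            raise ValueError(f"event {key!r}: selection {sel!r} not in {sorted(valid)}")
    return resolved


def retained_segments(
    gene: GeneModel,
    events: Sequence[SpliceEvent] = (),
    choices: Mapping[str, str] | None = None,
) -> list[tuple[Exon, int]]:
    """Per-exon retained sense length after applying splice-event choices.

    Returns ``(exon, retained_length)`` pairs in transcription order; excluded
    cassette exons are omitted.
    """
    resolved = _resolve_choices(events, choices)
    cut_for: dict[str, int] = {}
    skip: set[str] = set()
    for ev in events:
        sel = resolved[ev.event_id]
        exon = gene.exon(ev.exon_label)  # validates the label
        if ev.kind == "cassette_exon" and sel == "excluded":
            skip.add(ev.exon_label)
        elif ev.kind == "alternative_internal_donor" and sel == "short":
            if not 0 < ev.cut_index < len(exon):
                raise ValueError(
                    f"event {ev.event_id!r}: cut {ev.cut_index} invalid for exon "
                    f"{ev.exon_label!r} of length {len(exon)}"
                )
            cut_for[ev.exon_label] = ev.cut_index
    out = []
    for exon in gene.exons:
        if exon.label in skip:
            continue
        out.append((exon, cut_for.get(exon.label, len(exon))))
    return out


def spliced_cds(
    gene: GeneModel,
    genome: SequenceRecord,
    events: Sequence[SpliceEvent] = (),
    choices: Mapping[str, str] | None = None,
) -> str:
    """Concatenate retained exon segments (sense strand, transcription order)."""
    parts = []
    for exon, cut in retained_segments(gene, events, choices):
        parts.append(exon_sense_sequence(genome, gene, exon)[:cut])
    return "".join(parts)


def cds_to_genomic(
    gene: GeneModel,
    cds_start: int,
    cds_end: int,
    events: Sequence[SpliceEvent] = (),
    choices: Mapping[str, str] | None = None,
) -> list[tuple[str, int, int]]:
    """Map a spliced-CDS interval to genomic sub-intervals.

    Returns ``(exon_label, genomic_start, genomic_end)`` triples in
    transcription order; the interval may span several exons.
    """
    if not 0 <= cds_start < cds_end:
        raise ValueError("require 0 <= cds_start < cds_end")
    segs = retained_segments(gene, events, choices)
    total = sum(cut for _, cut in segs)
    if cds_end > total:
        raise ValueError(f"CDS interval [{cds_start}, {cds_end}) outside spliced length {total}")
    out = []
    offset = 0
    for exon, cut in segs:
        lo = max(cds_start, offset)
        hi = min(cds_end, offset + cut)
        if lo < hi:
            a, b = lo - offset, hi - offset  # sense coords within the retained part
            if gene.strand == "+":
                out.append((exon.label, exon.start + a, exon.start + b))
            else:
                out.append((exon.label, exon.end - b, exon.end - a))
        offset += cut
    return out


def translate(cds: str, allow_partial: bool = False) -> tuple[str, bool]:
    """Standard-code translation up to (not including) the first stop.

    Returns ``(peptide, stop_seen)``. A trailing partial codon is an error
    unless ``allow_partial`` is set, in which case it is dropped.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    if len(cds) % 3:
        if not allow_partial:
            raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
        cds = cds[: len(cds) - len(cds) % 3]
    aa = str(Seq(cds).translate())
    stop = "*" in aa
    peptide = aa.split("*", 1)[0] if stop else aa
    return peptide, stop


# ---------------------------------------------------------------------------
# GFF3 input/output


def _gff_attrs(pairs: list[tuple[str, str]]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs)


def write_gene_models(
    models: Iterable[GeneModel], path: str | Path, source: str = "slimsplice"
) -> None:
    """Emit gene/mRNA/exon/CDS (+ internal donor) features as GFF3.

    Coordinates go out 1-based inclusive; exon features carry a ``label``
    attribute; internal donors are ``five_prime_cis_splice_site`` features
    with ``exon_label`` and ``cut_index`` attributes.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in models:
            gstart = min(e.start for e in gene.exons) + 1
            gend = max(e.end for e in gene.exons)
            gid = gene.gene_id
            fh.write(
                "\t".join(
                    [gene.contig, source, "gene", str(gstart), str(gend), ".",
                     gene.strand, ".", _gff_attrs([("ID", gid)])]
                ) + "\n"
            )
            mid = f"{gid}.t1"
            fh.write(
                "\t".join(
                    [gene.contig, source, "mRNA", str(gstart), str(gend), ".",
                     gene.strand, ".", _gff_attrs([("ID", mid), ("Parent", gid)])]
                ) + "\n"
            )
            phase = gene.cds_start_phase
            for exon in gene.exons:  # transcription order
                coords = (str(exon.start + 1), str(exon.end))
                fh.write(
                    "\t".join(
                        [gene.contig, source, "exon", *coords, ".", gene.strand, ".",
                         _gff_attrs([("ID", f"{mid}.exon.{exon.label}"),
                                     ("Parent", mid), ("label", exon.label)])]
                    ) + "\n"
                )
                fh.write(
                    "\t".join(
                        [gene.contig, source, "CDS", *coords, ".", gene.strand,
                         str(phase),
                         _gff_attrs([("ID", f"{mid}.cds"), ("Parent", mid),
                                     ("label", exon.label)])]
                    ) + "\n"
                )
                phase = (3 - (len(exon) - phase) % 3) % 3
                for cut in exon.internal_donors:
                    if gene.strand == "+":
                        pos = exon.start + cut  # first base after the cut
                        coords2 = (str(pos + 1), str(pos + 2))
                    else:
                        pos = exon.end - cut
                        coords2 = (str(pos - 1), str(pos))
                    fh.write(
                        "\t".join(
                            [gene.contig, source, "five_prime_cis_splice_site",
                             *coords2, ".", gene.strand, ".",
                             _gff_attrs([("Parent", mid), ("exon_label", exon.label),
                                         ("cut_index", str(cut))])]
                        ) + "\n"
                    )


def read_gene_models(
    path: str | Path, donors_tsv: str | Path | None = None
) -> list[GeneModel]:
    """Read gene models from GFF3 (via an in-memory gffutils database).

    Exon features must carry a ``label`` attribute (a bare sequential number
    is assigned when absent). Internal donors may come either from
    ``five_prime_cis_splice_site`` features with ``exon_label``/``cut_index``
    attributes or from a sidecar TSV (``gene_id, exon_label, cut_index``).
    GFF3 1-based inclusive coordinates are converted to the internal 0-based
    half-open convention, and minus-strand exon lists are put in
    transcription order.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique", force=True,
    )
    sidecar: dict[tuple[str, str], list[int]] = {}
    if donors_tsv is not None:
        with open(donors_tsv) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                key = (row["gene_id"], row["exon_label"])
                sidecar.setdefault(key, []).append(int(row["cut_index"]))

    models = []
    for gene in db.features_of_type("gene"):
        gid = gene.id
        exon_feats = list(db.children(gene, featuretype="exon"))
        if not exon_feats:
            raise ValueError(f"gene {gid!r}: no exon features in {path}")
        donors: dict[str, list[int]] = {}
        for feat in db.children(gene, featuretype="five_prime_cis_splice_site"):
            donors.setdefault(feat.attributes["exon_label"][0], []).append(
                int(feat.attributes["cut_index"][0])
            )
        exon_feats.sort(key=lambda f: f.start)
        if gene.strand == "-":
            exon_feats = exon_feats[::-1]
        exons = []
        for i, feat in enumerate(exon_feats):
            label = feat.attributes.get("label", [str(i + 1)])[0]
            cuts = sorted(donors.get(label, []) + sidecar.get((gid, label), []))
            exons.append(Exon(label=label, start=feat.start - 1, end=feat.end,
                              internal_donors=cuts))
        cds_feats = list(db.children(gene, featuretype="CDS"))
        phase = 0
        if cds_feats:
            first = (min if gene.strand == "+" else max)(cds_feats, key=lambda f: f.start)
            if first.frame not in (None, "", "."):
                phase = int(first.frame)
        models.append(
            GeneModel(gene_id=gid, contig=gene.seqid, strand=gene.strand,
                      exons=exons, cds_start_phase=phase)
        )
    if not models:
        raise ValueError(f"no gene features found in {path}")
    return models
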