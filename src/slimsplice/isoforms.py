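"""Transcript isoform enumeration over binary alternative-splicing events.

k independent binary events (cassette exons, alternative internal donors)
yield exactly 2^k isoforms — e.g. four alternatively spliced exons give the
16 C-terminal isoforms characteristic of NCoR2. Each isoform carries its
choice vector, spliced CDS, translated protein and, when patterns are given,
its motif complement: the multiset of SLiM hits on the isoform's protein,
which is how alternative splicing varies the number of CoRNR boxes between
isoforms. Isoform identity is the choice vector, not the protein string, so
choices yielding identical proteins remain distinct isoforms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

from .genomics import GeneModel, SequenceRecord, SpliceEvent, spliced_cds, translate
from .motifs import SLiMPattern, scan_protein

__all__ = ["SpliceEvent", "Isoform", "enumerate_isoforms", "isoform_motif_complement",
           "read_events_tsv", "write_events_tsv"]


@dataclass(frozen=True)
class Isoform:
    """One transcript choice over the declared events, with its products.

    ``frameshift`` flags choice vectors whose removed length is not a
    multiple of 3 relative to the full-length transcript; such isoforms are
    still enumerated but their translation runs only to the first stop.
    """

    choice_vector: tuple[tuple[str, str], ...]  # (event_id, selection), input order
    cds: str
    protein: str
    stop_seen: bool
    frameshift: bool
    motif_complement: tuple[tuple[str, str], ...] | None = None

    @property
    def choices(self) -> dict[str, str]:
        return dict(self.choice_vector)


def enumerate_isoforms(
    gene: GeneModel,
    genome: SequenceRecord,
    events: Sequence[SpliceEvent],
    patterns: Sequence[SLiMPattern] | None = None,
) -> list[Isoform]:
    """All 2^k isoforms of a gene under k binary splicing events.

    Isoforms come out in deterministic binary-counting order: the default
    selection (exon included / long form) counts as 0, the alternative as 1,
    with the last event in input order varying fastest. Duplicate event ids
    are an error.
    """
    ids = [ev.event_id for ev in events]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate event_id among splice events")
    for ev in events:
        exon = gene.exon(ev.exon_label)  # raises KeyError for unknown labels
        if ev.kind == "alternative_internal_donor" and not 0 < ev.cut_index < len(exon):
            raise ValueError(
                f"event {ev.event_id!r}: cut_index {ev.cut_index} invalid for "
                f"exon {ev.exon_label!r} (length {len(exon)})"
            )
    full_len = len(spliced_cds(gene, genome))
    option_pairs = [
        (SpliceEvent.DEFAULT_CHOICES[ev.kind], SpliceEvent.ALT_CHOICES[ev.kind])
        for ev in events
    ]
    isoforms = []
    for combo in itertools.product(*option_pairs):
        choices = {ev.event_id: sel for ev, sel in zip(events, combo)}
        cds = spliced_cds(gene, genome, events, choices)
        frameshift = (full_len - len(cds)) % 3 != 0
        protein, stop = translate(cds, allow_partial=True)
        iso = Isoform(
            choice_vector=tuple(choices.items()),
            cds=cds, protein=protein, stop_seen=stop, frameshift=frameshift,
        )
        if patterns is not None:
            iso = Isoform(
                choice_vector=iso.choice_vector, cds=iso.cds, protein=iso.protein,
                stop_seen=iso.stop_seen, frameshift=iso.frameshift,
                motif_complement=isoform_motif_complement(iso, patterns),
            )
        isoforms.append(iso)
    return isoforms


def isoform_motif_complement(
    isoform: Isoform, patterns: Sequence[SLiMPattern]
) -> tuple[tuple[str, str], ...]:
    """Multiset of (pattern_name, status) hits on the isoform's protein."""
    hits = []
    for pat in patterns:
        for h in scan_protein(isoform.protein, pat, allow_partial=True):
            hits.append((h.pattern_name, h.status))
    return tuple(sorted(hits))


def read_events_tsv(path) -> list[SpliceEvent]:
    """Read events: ``event_id, kind, exon_label, cut_index`` (TSV)."""
    import csv

    events = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            cut = row.get("cut_index", "")
            events.append(
                SpliceEvent(
                    event_id=row["event_id"], kind=row["kind"],
                    exon_label=row["exon_label"],
                    cut_index=int(cut) if cut not in ("", None) else None,
                )
            )
    return events


def write_events_tsv(events: Sequence[SpliceEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("event_id\tkind\texon_label\tcut_index\n")
        for ev in events:
            cut = "" if ev.cut_index is None else str(ev.cut_index)
            fh.write(f"{ev.event_id}\t{ev.kind}\t{ev.exon_label}\t{cut}\n")
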