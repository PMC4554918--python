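"""Short linear motif (SLiM) patterns: parsing, protein scanning, exon mapping.

A SLiM pattern is a short degenerate consensus such as the CoRNR box
``L/I.x.x.I/H.I.x.x.x.I/L`` by which NCoR-family co-repressors bind unliganded
nuclear receptors: dot-separated positions, each either a wildcard ``x`` or a
slash-separated set of allowed residues. A window matching every constrained
position is a *complete* hit; a window failing at exactly one *key* position
(by default the most C-terminal constrained position, the diagnostic terminal
L/I of the CoRNR box) is a *partial* hit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genomics import (
    GeneModel,
    SequenceRecord,
    SpliceEvent,
    cds_to_genomic,
    translate,
    spliced_cds,
)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: The CoRNR box consensus by which co-repressors engage nuclear receptors.
CORNR_CONSENSUS = "L/I.x.x.I/H.I.x.x.x.I/L"


class PatternError(ValueError):
    """A SLiM pattern specification failed to parse."""


@dataclass(frozen=True)
class SLiMPattern:
    """A degenerate position pattern.

    ``positions`` holds one ``frozenset`` of allowed residues per position
    (``None`` marks a wildcard). ``key_positions`` is the subset of constrained
    positions at which a single mismatch still yields a partial call.
    """

    name: str
    positions: tuple[frozenset | None, ...]
    key_positions: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.key_positions <= set(self.constrained_positions()):
            raise PatternError(f"pattern {self.name!r}: key_positions must be constrained positions")

    def __len__(self) -> int:
        return len(self.positions)

    def constrained_positions(self) -> tuple[int, ...]:
        return tuple(i for i, p in enumerate(self.positions) if p is not None)

    def mismatches(self, window: str) -> list[int]:
        """Constrained positions at which ``window`` fails the pattern."""
        return [
            i for i, allowed in enumerate(self.positions)
            if allowed is not None and window[i] not in allowed
        ]


def parse_slim_pattern(
    spec: str, name: str, key_positions: Iterable[int] | None = None
) -> SLiMPattern:
    """Parse a dot-separated degenerate pattern like ``L/I.x.x.I/H.I.x.x.x.I/L``.

    Each token is ``x`` (wildcard) or slash-separated single-letter residues.
    ``key_positions`` defaults to the most C-terminal constrained position.
    """
    positions: list[frozenset | None] = []
    for idx, token in enumerate(spec.split(".")):
        if token == "":
            raise PatternError(f"pattern {name!r}: empty token at index {idx}")
        if token in ("x", "X"):
            positions.append(None)
            continue
        residues = token.split("/")
        for r in residues:
            if len(r) != 1 or r.upper() not in AMINO_ACIDS:
                raise PatternError(
                    f"pattern {name!r}: bad residue {r!r} in token {idx} ({token!r})"
                )
        positions.append(frozenset(r.upper() for r in residues))
    constrained = [i for i, p in enumerate(positions) if p is not None]
    if key_positions is not None:
        keys = frozenset(key_positions)
    else:
        # default: the most C-terminal constrained position (the diagnostic
        # terminal L/I of the CoRNR box); all-wildcard patterns have none
        keys = frozenset({constrained[-1]}) if constrained else frozenset()
    return SLiMPattern(name=name, positions=tuple(positions), key_positions=keys)


def read_patterns(path: str | Path) -> list[SLiMPattern]:
    """Read a pattern file: ``name<TAB>spec<TAB>key_positions(csv, optional)``."""
    patterns = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            name, spec = fields[0], fields[1]
            keys = None
            if len(fields) > 2 and fields[2].strip():
                keys = [int(k) for k in fields[2].split(",")]
            patterns.append(parse_slim_pattern(spec, name, keys))
    return patterns


def write_patterns(patterns: Iterable[SLiMPattern], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pat in patterns:
            spec = ".".join(
                "x" if p is None else "/".join(sorted(p)) for p in pat.positions
            )
            keys = ",".join(str(k) for k in sorted(pat.key_positions))
            fh.write(f"{pat.name}\t{spec}\t{keys}\n")


@dataclass(frozen=True)
class MotifHit:
    """A located pattern match on a protein (0-based half-open coordinates)."""

    pattern_name: str
    protein_id: str
    start: int
    end: int
    status: str  # "complete" | "partial"
    mismatched_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.status == "complete" and self.mismatched_positions:
            raise ValueError("complete hit cannot carry mismatches")


def scan_protein(
    protein: str | SequenceRecord,
    pattern: SLiMPattern,
    allow_partial: bool = False,
    protein_id: str | None = None,
) -> list[MotifHit]:
    """Scan every window of a protein against a pattern.

    Complete hits match every constrained position; when ``allow_partial``,
    windows mismatching at exactly one key position are reported as partial.
    Overlapping hits are all reported, sorted by start.
    """
    if isinstance(protein, SequenceRecord):
        protein_id = protein_id or protein.id
        protein = protein.seq
    protein_id = protein_id or ""
    L = len(pattern)
    hits = []
    for i in range(len(protein) - L + 1):
        mism = pattern.mismatches(protein[i : i + L])
        if not mism:
            hits.append(MotifHit(pattern.name, protein_id, i, i + L, "complete"))
        elif allow_partial and len(mism) == 1 and mism[0] in pattern.key_positions:
            hits.append(
                MotifHit(pattern.name, protein_id, i, i + L, "partial", tuple(mism))
            )
    return hits


def map_hit_to_exons(
    hit: MotifHit,
    gene: GeneModel,
    genome: SequenceRecord,
    events: Sequence[SpliceEvent] = (),
    choices: Mapping[str, str] | None = None,
) -> tuple[list[tuple[str, int, int]], list[str]]:
    """Project a peptide hit back onto the genome.

    The hit must derive from ``translate(spliced_cds(gene, genome, events,
    choices))``. Peptide coordinates become CDS nucleotide coordinates
    (x3, phase-adjusted) and then genomic sub-intervals; the second return
    value lists the labels of all exons overlapped, in transcription order.
    """
    nt_start = gene.cds_start_phase + 3 * hit.start
    nt_end = gene.cds_start_phase + 3 * hit.end
    try:
        segs = cds_to_genomic(gene, nt_start, nt_end, events, choices)
    except ValueError as exc:
        raise ValueError(f"hit {hit.pattern_name!r} at [{hit.start},{hit.end}) "
                         f"falls outside the CDS: {exc}") from exc
    labels = []
    for label, _, _ in segs:
        if label not in labels:
            labels.append(label)
    return segs, labels


def motif_acquisition_matrix(
    hits_by_species: Mapping[str, Sequence[MotifHit]],
    motif_names: Sequence[str],
    species_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Species x motif grid of {absent, partial, complete} calls.

    A complete hit dominates a partial one for the same motif; species with no
    hits for a motif are marked absent.
    """
    species = list(species_order) if species_order is not None else list(hits_by_species)
    grid = pd.DataFrame("absent", index=species, columns=list(motif_names))
    for sp in species:
        for hit in hits_by_species.get(sp, ()):
            if hit.pattern_name not in grid.columns:
                continue
            current = grid.at[sp, hit.pattern_name]
            if hit.status == "complete":
                grid.at[sp, hit.pattern_name] = "complete"
            elif current == "absent":
                grid.at[sp, hit.pattern_name] = "partial"
    return grid


def validate_family_membership(
    ordered_hits: Sequence[MotifHit],
    sant_count: int,
    cornr_prefix: str = "CoRNR",
    sharp_name: str = "SHARP",
) -> tuple[bool, list[str]]:
    """NCoR-family orthologue validation rule.

    Accept iff the protein carries at least two complete CoRNR-box hits, a
    SHARP-interaction hit positioned after every CoRNR hit and C-terminal to
    every other motif hit, and at least two (externally annotated) SANT
    domains. Returns ``(accept, reasons)`` where reasons name each failed
    clause ("CoRNR", "SHARP", "order", "SANT").
    """
    reasons = []
    cornr = [h for h in ordered_hits if h.pattern_name.startswith(cornr_prefix)]
    complete_cornr = [h for h in cornr if h.status == "complete"]
    sharp = [h for h in ordered_hits if h.pattern_name == sharp_name]
    if len(complete_cornr) < 2:
        reasons.append("CoRNR")
    if not sharp:
        reasons.append("SHARP")
    else:
        last_sharp = max(sharp, key=lambda h: h.start)
        if any(h.start > last_sharp.start for h in ordered_hits):
            reasons.append("order")
        elif cornr and max(h.start for h in cornr) > last_sharp.start:
            reasons.append("order")
    if sant_count < 2:
        reasons.append("SANT")
    return (not reasons), reasons


def scan_gene_model(
    gene: GeneModel,
    genome: SequenceRecord,
    patterns: Sequence[SLiMPattern],
    allow_partial: bool = True,
    events: Sequence[SpliceEvent] = (),
    choices: Mapping[str, str] | None = None,
) -> list[MotifHit]:
    """Translate a gene model and scan the peptide with every pattern."""
    cds = spliced_cds(gene, genome, events, choices)
    peptide, _ = translate(cds, allow_partial=True)
    hits: list[MotifHit] = []
    for pat in patterns:
        hits.extend(scan_protein(peptide, pat, allow_partial, protein_id=gene.gene_id))
    return sorted(hits, key=lambda h: (h.start, h.pattern_name))


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": h.protein_id,
                "pattern_name": h.pattern_name,
                "start": h.start,
                "end": h.end,
                "status": h.status,
                "mismatched_positions": ",".join(map(str, h.mismatched_positions)),
            }
            for h in hits
        ],
        columns=["protein_id", "pattern_name", "start", "end", "status",
                 "mismatched_positions"],
    )


def hits_to_bed(
    rows: Iterable[tuple[MotifHit, GeneModel, list[tuple[str, int, int]]]],
) -> str:
    """Render genomic projections of hits as BED (0-based half-open) text."""
    lines = []
    for hit, gene, segs in rows:
        for label, gstart, gend in segs:
            lines.append(
                "\t".join(
                    [gene.contig, str(gstart), str(gend),
                     f"{hit.protein_id}:{hit.pattern_name}:{label}",
                     "0", gene.strand]
                )
            )
    return "\n".join(lines) + ("\n" if lines else "")
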