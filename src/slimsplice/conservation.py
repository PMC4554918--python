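"""Cross-species survey of donor-site presence and strength.

Given orthologous sequence windows (one per species, typically 115 bases
centred on a reference internal splice donor), survey every GT dinucleotide
and its donor-window score, anchor the reference site in each species by
global pairwise alignment, and classify the homologous position: the site may
be retained with a strong context, retained as a GT in a poor context
("weak"), substituted away (``gt_absent`` — the pattern of a paralogue that
lost splicing by point mutation), or unalignable (``no``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align

from .donors import DonorStats, DonorWindow, SpliceScoreModel, score_window
from .mutscan import frame_compatible


@dataclass(frozen=True)
class ConservationRecord:
    """Per-species outcome of the reference-site conservation check."""

    species: str
    gt_positions_and_scores: tuple[tuple[int, float | None], ...]
    has_site1: str  # "yes" | "weak" | "gt_absent" | "no"
    site1_score: float | None = None
    in_frame: bool | None = None


def window_gt_survey(
    window_seq: str, model: SpliceScoreModel
) -> list[tuple[int, float | None]]:
    """Every GT in a sequence window with its donor score.

    Returns ``(position, score)`` per GT occurrence that has enough flanking
    context for a full 9-base donor window (3 bases before the G, 4 after the
    T); overlapping GTs are each reported.
    """
    window_seq = window_seq.upper()
    out = []
    for pos in range(len(window_seq) - 1):
        if window_seq[pos : pos + 2] != "GT":
            continue
        if pos < 3 or pos + 6 > len(window_seq):
            continue
        score = score_window(model, DonorWindow(window_seq[pos - 3 : pos + 6]))
        out.append((pos, score))
    return out


def make_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def map_homologous_site(
    ref_seq: str,
    ref_position: int,
    other_seq: str,
    aligner: Align.PairwiseAligner | None = None,
) -> int | None:
    """Position in ``other_seq`` aligned to ``ref_position``, or None.

    Needleman-Wunsch global alignment (defaults: match +1, mismatch -1, gap
    open -4, gap extend -1); a reference column aligned to a gap in the other
    sequence returns None (site deleted).
    """
    if not ref_seq or not other_seq:
        raise ValueError("both sequences must be non-empty")
    if not 0 <= ref_position < len(ref_seq):
        raise ValueError(f"ref_position {ref_position} outside reference")
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(ref_seq.upper(), other_seq.upper())[0]
    ref_blocks, other_blocks = aln.aligned
    for (rs, re), (os_, oe) in zip(ref_blocks, other_blocks):
        if rs <= ref_position < re:
            return os_ + (ref_position - rs)
    return None


def site_conservation_table(
    windows: Mapping[str, str],
    ref_species: str,
    ref_site_position: int,
    model: SpliceScoreModel,
    weak_threshold: float | None = None,
    stats: DonorStats | None = None,
    frame_info: Mapping[str, tuple[int, int]] | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> list[ConservationRecord]:
    """Classify the homologue of a reference donor site in each species.

    ``windows`` maps species to orthologous window sequences; the reference
    site is anchored in each species by pairwise alignment against the
    reference. ``weak_threshold`` (bits) separates "yes" from "weak" GT calls
    and defaults to mean - 2 SD of the validated-donor stats when given, else
    0. ``frame_info`` optionally maps species to ``(exon_length, cut_index)``
    so the frame flag can be reported for species where the site is a GT.
    """
    if ref_species not in windows:
        raise KeyError(f"reference species {ref_species!r} not in the window mapping")
    if weak_threshold is None:
        weak_threshold = stats.mean - 2 * stats.sd if stats is not None else 0.0
    ref_seq = windows[ref_species].upper()
    records = []
    for species, seq in windows.items():
        seq = seq.upper()
        survey = tuple(window_gt_survey(seq, model))
        if species == ref_species:
            pos = ref_site_position
        else:
            pos = map_homologous_site(ref_seq, ref_site_position, seq, aligner)
        site_score = None
        in_frame = None
        if pos is None or pos + 2 > len(seq):
            call = "no"
        elif seq[pos : pos + 2] != "GT":
            call = "gt_absent"
        else:
            site_score = score_window(model, DonorWindow(seq[pos - 3 : pos + 6])) \
                if pos >= 3 and pos + 6 <= len(seq) else None
            call = "yes" if site_score is not None and site_score >= weak_threshold else "weak"
            if frame_info and species in frame_info:
                exon_length, cut = frame_info[species]
                in_frame = frame_compatible(exon_length, cut)
        records.append(
            ConservationRecord(
                species=species, gt_positions_and_scores=survey,
                has_site1=call, site1_score=site_score, in_frame=in_frame,
            )
        )
    return records


def conservation_to_frame(records: Sequence[ConservationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "species": r.species,
                "has_site1": r.has_site1,
                "site1_score": r.site1_score,
                "in_frame": r.in_frame,
                "n_gt": len(r.gt_positions_and_scores),
                "gt_track": ";".join(
                    f"{p}:{s:.3f}" if s is not None else f"{p}:NA"
                    for p, s in r.gt_positions_and_scores
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["species", "has_site1", "site1_score", "in_frame", "n_gt", "gt_track"]
    )
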