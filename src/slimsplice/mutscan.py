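"""Single-substitution GT-creation scan for cryptic splice donors.

Given an exon, enumerate every dinucleotide that is, or could become by one
base change, a GT; score the resulting nine-base donor window; standardize
against the gene's validated-donor score distribution; and flag whether
splicing from that position would preserve the reading frame into the next
exon (excised length divisible by 3). This is the computation that asks, for
a gene that has lost an internal donor (a GA where its paralogue keeps a GT),
which single point mutations would reconstitute a strong donor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .donors import DonorStats, DonorWindow, SpliceScoreModel, extract_donor_window, score_window

#: Dinucleotides exactly one substitution away from GT.
CONVERTIBLE = frozenset({"AT", "CT", "TT", "GA", "GC", "GG"})

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class MutationCandidate:
    """A dinucleotide convertible to GT by at most one substitution.

    ``position`` is the 0-based index of the dinucleotide's first base within
    the exon; ``substitution`` is ``(offset, new_base)`` with offset 0 or 1,
    or None for an existing GT. The donor cut implied by the candidate is
    ``position`` itself (the GT begins the excised/intron-side sequence).
    """

    exon_label: str
    position: int
    original: str
    substitution: tuple[int, str] | None
    window: DonorWindow | None = None
    score: float | None = None
    z: float | None = None
    exceeds_mean: bool | None = None
    frame_compatible: bool | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        dist = sum(a != b for a, b in zip(self.original, "GT"))
        if dist > 1:
            raise ValueError(f"{self.original!r} is not within one substitution of GT")
        if (self.substitution is None) != (dist == 0):
            raise ValueError("substitution must be None exactly for an existing GT")


def frame_compatible(exon_length: int, cut: int) -> bool:
    """True iff splicing at retained length ``cut`` preserves the frame.

    The excised 3' portion of the exon has length ``exon_length - cut``;
    downstream exons stay in frame iff that length is divisible by 3. A cut at
    the exon end (nothing removed) is trivially compatible.
    """
    if not 0 < cut <= exon_length:
        raise ValueError(f"cut {cut} out of range (0, {exon_length}]")
    return (exon_length - cut) % 3 == 0


def enumerate_gt_candidates(
    exon_seq: str,
    downstream_flank: str = "",
    include_existing: bool = False,
    exon_label: str = "",
) -> list[MutationCandidate]:
    """Enumerate candidate donor positions over one exon, unscored.

    One candidate per dinucleotide at Hamming distance 1 from GT (and, with
    ``include_existing``, distance 0, so genes whose internal donor is a real
    GT can be surveyed by the same machinery). The mutated window is built
    from the exon sequence with the substitution applied; candidates too close
    to the exon start or end for a full window are flagged rather than
    silently dropped.
    """
    exon_seq = exon_seq.upper()
    if len(exon_seq) < 4:
        raise ValueError(f"exon length {len(exon_seq)} < 4")
    L = len(exon_seq)
    out = []
    for i in range(L - 1):
        dinuc = exon_seq[i : i + 2]
        if dinuc == "GT":
            if not include_existing:
                continue
            sub = None
            mutated = exon_seq
        elif dinuc in CONVERTIBLE:
            offset = 0 if dinuc[0] != "G" else 1
            new_base = "G" if offset == 0 else "T"
            sub = (offset, new_base)
            mutated = exon_seq[: i + offset] + new_base + exon_seq[i + offset + 1 :]
        else:
            continue
        flags: list[str] = []
        window = None
        if i < 3:
            flags.append("insufficient_exonic_context")
        elif len(mutated) - i + len(downstream_flank) < 6:
            flags.append("insufficient_downstream_context")
        else:
            window = extract_donor_window(mutated, downstream_flank, cut=i,
                                          source=(exon_label, i))
            if not window.valid:
                flags.append("ambiguous_bases")
        frame = frame_compatible(L, i) if i > 0 else None
        out.append(
            MutationCandidate(
                exon_label=exon_label, position=i, original=dinuc, substitution=sub,
                window=window, frame_compatible=frame, flags=tuple(flags),
            )
        )
    return out


def score_candidates(
    candidates: Sequence[MutationCandidate],
    model: SpliceScoreModel,
    stats: DonorStats,
) -> list[MutationCandidate]:
    """Score, standardize and rank candidates.

    z = (score - mean)/sd against the validated-donor distribution;
    ``exceeds_mean`` marks candidates predicted stronger than the average
    validated donor — the reporting criterion for a strong reconstituted
    site. Sorted by score descending, ties broken by ascending position;
    unscorable candidates sort last.
    """
    if stats.n < 2:
        raise ValueError("donor stats must come from at least 2 windows")
    scored = []
    for cand in candidates:
        score = score_window(model, cand.window) if cand.window is not None else None
        if score is None:
            scored.append(replace(cand, score=None, z=None, exceeds_mean=None))
            continue
        z = (score - stats.mean) / stats.sd if stats.sd > 0 else float("nan")
        scored.append(
            replace(cand, score=score, z=z, exceeds_mean=score > stats.mean)
        )
    return sorted(
        scored,
        key=lambda c: (c.score is None, -(c.score if c.score is not None else 0.0), c.position),
    )


def inframe_stop_scan(
    seq: str, frame_offset: int = 0, horizon: int | None = None
) -> int | None:
    """First in-frame stop codon start within ``horizon`` bases, or None.

    Scans codons beginning at ``frame_offset``; a stop closely downstream of
    an internal donor marks a site whose disuse would truncate the protein.
    ``horizon`` counts bases from ``frame_offset`` (default: to sequence end).
    """
    seq = seq.upper()
    if not 0 <= frame_offset <= 2:
        raise ValueError("frame_offset must be 0-2")
    if horizon is None:
        horizon = len(seq) - frame_offset
    if frame_offset + horizon > len(seq):
        raise ValueError("horizon extends beyond the sequence")
    limit = frame_offset + horizon
    for p in range(frame_offset, limit - 2, 3):
        if seq[p : p + 3] in STOP_CODONS:
            return p
    return None


def candidates_to_frame(candidates: Sequence[MutationCandidate]):
    """Tabulate a scan as a pandas DataFrame (the TSV column layout)."""
    rows = []
    for c in candidates:
        sub = "" if c.substitution is None else f"{c.substitution[0]}{c.substitution[1]}"
        rows.append(
            {
                "exon_label": c.exon_label,
                "position": c.position,
                "original": c.original,
                "substitution": sub,
                "window": c.window.seq if c.window is not None else "",
                "score": c.score,
                "z": c.z,
                "exceeds_mean": c.exceeds_mean,
                "frame_compatible": c.frame_compatible,
                "flags": ",".join(c.flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["exon_label", "position", "original", "substitution", "window",
                 "score", "z", "exceeds_mean", "frame_compatible", "flags"],
    )
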