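"""Seeded synthetic-data generators with recorded ground truth.

Every pipeline stage is testable offline against loci built here: multi-exon
gene models with canonical GT..AG introns, donor nine-mers drawn from a
declared base-frequency model, decoy background sequence, planted protein
motifs (complete or deliberately key-mismatched), an optional planted cryptic
GA one substitution away from a strong donor context, binary
alternative-splicing events, and orthologue panels in which a reference donor
site is retained, weakened, substituted to GA or deleted. All generators are
pure functions of (config, seed), and every planted feature is recorded in a
:class:`SyntheticTruth` that can be re-verified against the emitted files.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from Bio.Data import CodonTable

from .donors import BASES, BASE_INDEX, DonorWindow, write_donor_tsv
from .genomics import (
    Exon,
    GeneModel,
    SequenceRecord,
    SpliceEvent,
    exon_sense_sequence,
    downstream_flank,
    reverse_complement,
    spliced_cds,
    translate,
    write_gene_models,
    write_sequences,
)
from .isoforms import write_events_tsv
from .motifs import SLiMPattern, parse_slim_pattern, scan_protein

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# first codon per amino acid, alphabetically, from the standard table:
# deterministic back-translation (codon realism is not the point here)
_FIRST_CODON = {}
for codon, aa in sorted(CodonTable.unambiguous_dna_by_id[1].forward_table.items()):
    _FIRST_CODON.setdefault(aa, codon)


def default_config() -> dict:
    """The packaged default locus configuration (deep copy, safe to edit)."""
    text = resources.files("slimsplice").joinpath("data/default_config.yaml").read_text()
    return yaml.safe_load(text)


def ncor1_like_config() -> dict:
    """Default locus re-specified in the NCoR1 pattern.

    The internal donor event on exon 37 is removed and replaced by a planted
    cryptic GA at the same position: the site's strong donor context is
    intact but the obligatory GT has been lost by point mutation, which is
    exactly what the single-substitution scan is meant to recover.
    """
    cfg = default_config()
    cut = next(
        ev["cut_index"] for ev in cfg["events"]
        if ev["kind"] == "alternative_internal_donor" and ev["exon"] == "37"
    )
    cfg["gene_id"] = "simNCoR1"
    cfg["events"] = [ev for ev in cfg["events"] if ev.get("event_id") != "e37b"]
    cfg["cryptic_site"] = {"exon": "37", "position": cut}
    return cfg


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated locus, verifiable from the emitted files."""

    planted_motifs: list[tuple[str, str, int, str]]  # (pattern, gene_id, aa_pos, status)
    planted_donors: list[tuple[str, int]]  # (exon_label, cut_index)
    planted_cryptic_site: tuple[str, int] | None
    events: list[SpliceEvent]
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_motifs": [list(t) for t in self.planted_motifs],
            "planted_donors": [list(t) for t in self.planted_donors],
            "planted_cryptic_site": (
                list(self.planted_cryptic_site) if self.planted_cryptic_site else None
            ),
            "events": [dataclasses.asdict(ev) for ev in self.events],
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class SimulatedLocus:
    gene: GeneModel
    genome: SequenceRecord
    donors: list[DonorWindow]
    events: list[SpliceEvent]
    patterns: list[SLiMPattern]
    truth: SyntheticTruth


def _check_freq_model(freq_model) -> np.ndarray:
    arr = np.asarray(freq_model, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("frequency model must be k x 4 (columns A,C,G,T)")
    if np.any(arr < 0) or not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("frequency model rows must be non-negative and sum to 1")
    return arr / arr.sum(axis=1, keepdims=True)


def _sample_window(freq: np.ndarray, rng: np.random.Generator, force_gt: bool = True) -> str:
    bases = [BASES[rng.choice(4, p=freq[i])] for i in range(freq.shape[0])]
    if force_gt:
        bases[3], bases[4] = "G", "T"
    return "".join(bases)


def _planted_strength_floor(spec, freq: np.ndarray, background: np.ndarray) -> float:
    """Resolve the strength floor for planted donor contexts.

    ``"mean"`` (the default) is the expected log-odds of a window drawn from
    the model with GT forced at positions 4-5 — a planted site must look like
    a representative-or-better donor, not a lucky weak draw. A number is an
    absolute floor in bits.
    """
    if spec != "mean":
        return float(spec)
    total = 0.0
    for i in range(freq.shape[0]):
        if i == 3:
            total += math.log2(freq[i, BASE_INDEX["G"]] / background[BASE_INDEX["G"]])
        elif i == 4:
            total += math.log2(freq[i, BASE_INDEX["T"]] / background[BASE_INDEX["T"]])
        else:
            total += float(
                sum(
                    freq[i, b] * math.log2(freq[i, b] / background[b])
                    for b in range(4) if freq[i, b] > 0
                )
            )
    return total


def _window_log_odds(freq: np.ndarray, seq: str, background: np.ndarray) -> float:
    return float(
        sum(
            math.log2(freq[i, BASE_INDEX[b]] / background[BASE_INDEX[b]])
            for i, b in enumerate(seq)
        )
    )


def simulate_donor_training_set(
    freq_model,
    n: int,
    seed: int,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> tuple[list[DonorWindow], list[DonorWindow]]:
    """Sample n donor windows from a 9x4 frequency model, plus n decoys.

    Positives are drawn per position from the model with positions 4-5 forced
    to GT; decoys come from the independent background model. Output is a
    pure function of (model, n, seed).
    """
    freq = _check_freq_model(freq_model)
    bg = np.asarray(background, dtype=float)
    rng = np.random.default_rng(seed)
    positives = [
        DonorWindow(_sample_window(freq, rng), source=("sim", "donor", i))
        for i in range(n)
    ]
    decoys = [
        DonorWindow(
            "".join(BASES[rng.choice(4, p=bg)] for _ in range(freq.shape[0])),
            source=("sim", "decoy", i),
        )
        for i in range(n)
    ]
    return positives, decoys


def _plant_motifs(
    peptide: list[str],
    placements: Sequence[dict],
    patterns: dict[str, SLiMPattern],
    exon_aa_bounds: dict[str, tuple[int, int]],
    rng: np.random.Generator,
) -> list[tuple[str, int, str]]:
    """Write realized motif residues into the peptide; returns (name, pos, status)."""
    planted = []
    for spec in placements:
        pat = patterns[spec["name"]]
        lo, hi = exon_aa_bounds[spec["exon"]]
        g = lo + int(spec["aa_offset"])
        if g + len(pat) > len(peptide):
            raise ValueError(f"motif {spec['name']!r} runs past the peptide")
        # exons are codon-aligned here, so a motif crosses a splice junction
        # exactly when it straddles an interior exon boundary (in aa units)
        boundaries = {b for _, b in exon_aa_bounds.values() if b < len(peptide)}
        crosses = any(g < b < g + len(pat) for b in boundaries)
        if crosses and not spec.get("span_junction", False):
            raise ValueError(
                f"motif {spec['name']!r} at exon {spec['exon']!r} offset "
                f"{spec['aa_offset']} collides with a splice junction "
                "(set span_junction to request this)"
            )
        for k, allowed in enumerate(pat.positions):
            if allowed is None:
                peptide[g + k] = AA20[rng.integers(len(AA20))]
            else:
                choices = sorted(allowed)
                peptide[g + k] = choices[rng.integers(len(choices))]
        status = spec.get("status", "complete")
        if status == "partial":
            key = max(pat.key_positions)
            allowed = pat.positions[key]
            for alt in "KGASTNQ":
                if alt not in allowed:
                    peptide[g + key] = alt
                    break
        planted.append((spec["name"], g, status))
    return planted


def _scrub_background_hits(
    peptide: list[str],
    patterns: Sequence[SLiMPattern],
    planted: Sequence[tuple[str, int, str]],
) -> None:
    """Destroy chance motif matches outside the planted sites.

    The generator's truth must be exhaustive: any window matching a pattern
    (completely or at one key mismatch) that was not deliberately planted is
    broken by rewriting one constrained residue to G, which none of the
    shipped patterns allow at a constrained position. Patterns sharing one
    consensus (the three CoRNR boxes) legitimately co-hit each planted site,
    so "planted" is judged by position-set identity, not pattern name. Only
    non-key positions that are not constrained in a planted motif are
    rewritten: a residue constrained by a planted motif must stay, and a key
    position would leave a partial hit behind. The occasional unscrubable
    hit is left for the caller's consistency check to catch and rebuild.
    """
    by_name = {p.name: p for p in patterns}
    protected = set()  # absolute positions constrained by a planted motif
    planted_sites = set()  # (pattern shape, start)
    for name, g, _ in planted:
        pat = by_name[name]
        protected.update(g + i for i in pat.constrained_positions())
        planted_sites.add((pat.positions, g))
    for _ in range(20):
        dirty = False
        for pat in patterns:
            for hit in scan_protein("".join(peptide), pat, allow_partial=True):
                if (pat.positions, hit.start) in planted_sites:
                    continue
                target = next(
                    (i for i in pat.constrained_positions()
                     if i not in pat.key_positions
                     and hit.start + i not in protected
                     and peptide[hit.start + i] != "G"),
                    None,
                )
                if target is None:
                    continue
                peptide[hit.start + target] = "G"
                dirty = True
        if not dirty:
            return


def _truth_consistent(locus: SimulatedLocus) -> bool:
    """Re-derive every planted feature from the emitted objects."""
    cds = spliced_cds(locus.gene, locus.genome)
    peptide, stop = translate(cds)
    if not stop or "*" in peptide:
        return False
    # compare on pattern shape: patterns sharing a consensus co-hit each
    # planted site under every name, which is correct scanner behaviour
    shape = {p.name: p.positions for p in locus.patterns}
    expected = {
        (shape[name], pos, status)
        for name, _, pos, status in locus.truth.planted_motifs
    }
    observed = set()
    for pat in locus.patterns:
        for h in scan_protein(peptide, pat, allow_partial=True):
            observed.add((pat.positions, h.start, h.status))
    if observed != expected:
        return False
    for w in locus.donors:
        _, exon_label, cut = w.source
        exon = locus.gene.exon(exon_label)
        seq = exon_sense_sequence(locus.genome, locus.gene, exon)
        flank = downstream_flank(locus.genome, locus.gene, exon, 6)
        rebuilt = (seq + flank)[cut - 3 : cut + 6]
        if rebuilt != w.seq:
            return False
    if locus.truth.planted_cryptic_site is not None:
        exon_label, pos = locus.truth.planted_cryptic_site
        seq = exon_sense_sequence(locus.genome, locus.gene, locus.gene.exon(exon_label))
        if seq[pos : pos + 2] != "GA":
            return False
    return True


def _build_locus(config: dict, seed: int, attempt: int) -> SimulatedLocus:
    rng = np.random.default_rng([seed, attempt])
    freq = _check_freq_model(config["donor_model"])
    background = np.asarray(config.get("background", [0.25] * 4), dtype=float)
    min_score = _planted_strength_floor(
        config.get("planted_donor_min_score", "mean"), freq, background
    )
    exon_specs = config["exons"]
    lengths = [int(e["length"]) for e in exon_specs]
    labels = [str(e["label"]) for e in exon_specs]
    if any(l % 3 for l in lengths):
        raise ValueError("exon lengths must be multiples of 3 in this generator")

    total = sum(lengths)
    n_aa = total // 3 - 1  # last codon is the stop
    patterns = {
        m["name"]: parse_slim_pattern(m["spec"], m["name"]) for m in config["motifs"]
    }
    bounds = {}
    off = 0
    for label, L in zip(labels, lengths):
        bounds[label] = (off // 3, (off + L) // 3)
        off += L

    peptide = [AA20[rng.integers(len(AA20))] for _ in range(n_aa)]
    planted = _plant_motifs(peptide, config["motifs"], patterns, bounds, rng)
    _scrub_background_hits(peptide, list(patterns.values()), planted)
    cds = "".join(_FIRST_CODON[aa] for aa in peptide) + "TAA"
    exon_seqs = []
    off = 0
    for L in lengths:
        exon_seqs.append(list(cds[off : off + L]))
        off += L

    protected_codons = set()
    for name, g, _ in planted:
        protected_codons.update(range(g, g + len(patterns[name])))

    def overwrite(exon_idx: int, start_in_exon: int, bases: str) -> None:
        exon_off = sum(lengths[:exon_idx])
        lo_codon = (exon_off + start_in_exon) // 3
        hi_codon = (exon_off + start_in_exon + len(bases) + 2) // 3
        if any(c in protected_codons for c in range(lo_codon, hi_codon)):
            raise ValueError(
                f"donor placement in exon {labels[exon_idx]!r} collides with a planted motif"
            )
        for k, b in enumerate(bases):
            exon_seqs[exon_idx][start_in_exon + k] = b

    def codons_ok(exon_idx: int, start_in_exon: int, n: int) -> bool:
        exon_off = sum(lengths[:exon_idx])
        lo = (exon_off + start_in_exon) // 3 * 3 - exon_off
        hi = start_in_exon + n
        seq = "".join(exon_seqs[exon_idx])
        for p in range(lo, hi, 3):
            codon = seq[p : p + 3]
            if len(codon) == 3 and codon in ("TAA", "TAG", "TGA"):
                if exon_idx == len(lengths) - 1 and p == lengths[-1] - 3:
                    continue  # the genuine terminal stop
                return False
        return True

    # terminal donors of every non-terminal exon, drawn from the donor model
    donor_records: list[tuple[str, int, str]] = []  # (exon_label, cut, window)
    intron_first6: list[str] = []
    for idx in range(len(lengths) - 1):
        for _ in range(200):
            win = _sample_window(freq, rng)
            overwrite(idx, lengths[idx] - 3, win[:3])
            if codons_ok(idx, lengths[idx] - 3, 3):
                break
        else:
            raise RuntimeError("could not place a terminal donor without a stop codon")
        donor_records.append((labels[idx], lengths[idx], win))
        intron_first6.append(win[3:9])

    # internal donor (NCoR2 pattern) and/or cryptic GA (NCoR1 pattern)
    internal_events = [
        ev for ev in config["events"] if ev["kind"] == "alternative_internal_donor"
    ]
    cryptic = config.get("cryptic_site")
    internal_cuts: dict[str, list[int]] = {}

    def plant_internal(exon_label: str, cut: int, as_ga: bool) -> str:
        idx = labels.index(exon_label)
        if not 3 <= cut <= lengths[idx] - 6:
            raise ValueError(f"internal site at {cut} needs context within exon {exon_label!r}")
        for _ in range(500):
            win = _sample_window(freq, rng)
            if _window_log_odds(freq, win, background) < min_score:
                continue
            placed = win if not as_ga else win[:4] + "A" + win[5:]
            overwrite(idx, cut - 3, placed)
            if codons_ok(idx, cut - 3, 9):
                return win
        raise RuntimeError("could not place a strong internal donor context")

    truth_cryptic = None
    for ev in internal_events:
        win = plant_internal(ev["exon"], int(ev["cut_index"]), as_ga=False)
        donor_records.append((ev["exon"], int(ev["cut_index"]), win))
        internal_cuts.setdefault(ev["exon"], []).append(int(ev["cut_index"]))
    if cryptic is not None:
        plant_internal(cryptic["exon"], int(cryptic["position"]), as_ga=True)
        truth_cryptic = (str(cryptic["exon"]), int(cryptic["position"]))

    # assemble the genome: flank + exons with GT..AG introns + flank
    flank_len = int(config.get("flank", 100))
    intron_default = int(config.get("intron_length", 250))
    overrides = config.get("intron_length_overrides") or {}

    def bg_seq(n: int) -> str:
        return "".join(BASES[rng.choice(4, p=background)] for _ in range(n))

    parts = [bg_seq(flank_len)]
    exon_coords = []
    pos = flank_len
    for idx, L in enumerate(lengths):
        exon_coords.append((pos, pos + L))
        parts.append("".join(exon_seqs[idx]))
        pos += L
        if idx < len(lengths) - 1:
            ilen = int(overrides.get(labels[idx], intron_default))
            if ilen < 12:
                raise ValueError(f"intron after exon {labels[idx]!r} too short ({ilen})")
            intron = intron_first6[idx] + bg_seq(ilen - 8) + "AG"
            parts.append(intron)
            pos += ilen
    parts.append(bg_seq(flank_len))
    region = "".join(parts)

    strand = config.get("strand", "+")
    if strand == "-":
        M = len(region)
        region = reverse_complement(region)
        exon_coords = [(M - e, M - s) for s, e in exon_coords]

    exons = [
        Exon(label=lab, start=s, end=e, internal_donors=sorted(internal_cuts.get(lab, [])))
        for lab, (s, e) in zip(labels, exon_coords)
    ]
    gene = GeneModel(
        gene_id=config["gene_id"], contig=config["contig"], strand=strand,
        exons=exons, cds_start_phase=0,
    )
    genome = SequenceRecord(id=config["contig"], seq=region)

    events = [
        SpliceEvent(
            event_id=ev["event_id"], kind=ev["kind"], exon_label=str(ev["exon"]),
            cut_index=ev.get("cut_index"),
        )
        for ev in config["events"]
    ]
    donors = [
        DonorWindow(seq=win, source=(config["gene_id"], lab, cut))
        for lab, cut, win in donor_records
    ]
    truth = SyntheticTruth(
        planted_motifs=[(name, config["gene_id"], g, status) for name, g, status in planted],
        planted_donors=[(lab, cut) for lab, cut, _ in donor_records],
        planted_cryptic_site=truth_cryptic,
        events=events,
        seed=seed,
    )
    return SimulatedLocus(
        gene=gene, genome=genome, donors=donors, events=events,
        patterns=list(patterns.values()), truth=truth,
    )


def simulate_locus(
    config: dict | None = None, seed: int = 0, out_dir: str | Path | None = None
) -> SimulatedLocus:
    """Build a synthetic locus; optionally write its files to ``out_dir``.

    The generator validates its own truth before returning (planted motifs
    are the only pattern hits on the translated CDS; recorded donor windows
    rebuild from the genome; the cryptic GA reads GA). On the rare chance
    collision — e.g. a donor overwrite completing a motif by accident — the
    locus is rebuilt from a derived substream, keeping the output a pure
    function of (config, seed).

    Files written: ``genome.fasta``, ``genes.gff3``, ``donors.tsv``,
    ``events.tsv``, ``truth.json``.
    """
    config = copy.deepcopy(config) if config is not None else default_config()
    locus = None
    for attempt in range(20):
        locus = _build_locus(config, seed, attempt)
        if _truth_consistent(locus):
            break
    else:
        raise RuntimeError("simulate_locus: no self-consistent locus in 20 attempts")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_sequences([locus.genome], out / "genome.fasta")
        write_gene_models([locus.gene], out / "genes.gff3")
        write_donor_tsv(locus.donors, out / "donors.tsv")
        write_events_tsv(locus.events, out / "events.tsv")
        locus.truth.to_json(out / "truth.json")
    return locus


def reference_site_window(
    locus: SimulatedLocus, exon_label: str, cut: int, width: int = 115
) -> tuple[str, int]:
    """A width-base window centred on an internal donor site.

    Returns ``(window_sequence, site_position_in_window)``; the site's
    dinucleotide starts at the returned position. Context comes from the
    exon's sense sequence extended by downstream intron.
    """
    exon = locus.gene.exon(exon_label)
    seq = exon_sense_sequence(locus.genome, locus.gene, exon)
    seq += downstream_flank(locus.genome, locus.gene, exon, width)
    half = width // 2
    start = cut - half
    if start < 0 or start + width > len(seq):
        raise ValueError("window does not fit around the site")
    return seq[start : start + width], half


#: Recognized orthologue-panel edit modes.
PANEL_MODES = ("retain", "weaken", "lose_gt_to_GA", "delete_region")


def simulate_ortholog_panel(
    ref_window: str,
    species_specs: Mapping[str, str | dict],
    seed: int,
    site_position: int,
    freq_model=None,
) -> tuple[dict[str, str], dict[str, str]]:
    """Derive per-species orthologue windows from a reference window.

    ``species_specs`` maps species name to a mode (or a dict with ``mode``
    and optionally ``n_substitutions`` for background divergence away from
    the site). Modes: ``retain`` keeps the site; ``weaken`` keeps the GT but
    rewrites its context to the least-likely base per window position under
    ``freq_model`` (a poor consensus donor); ``lose_gt_to_GA`` substitutes
    the T (the paralogue-loss pattern); ``delete_region`` removes 15 bases
    around the site. Returns ``(windows, expected)`` where expected maps each
    species to the conservation call its edit should produce.
    """
    rng = np.random.default_rng(seed)
    ref = ref_window.upper()
    if ref[site_position : site_position + 2] != "GT":
        raise ValueError("reference window must carry GT at site_position")
    windows: dict[str, str] = {}
    expected: dict[str, str] = {}
    for species, spec in species_specs.items():
        if isinstance(spec, str):
            spec = {"mode": spec}
        mode = spec["mode"]
        if mode not in PANEL_MODES:
            raise ValueError(f"unknown panel mode {mode!r} for species {species!r}")
        seq = list(ref)
        nsub = int(spec.get("n_substitutions", 0))
        guarded = set(range(site_position - 3, site_position + 6))
        for _ in range(nsub):
            while True:
                p = int(rng.integers(len(seq)))
                if p not in guarded:
                    break
            seq[p] = BASES[(BASE_INDEX[seq[p]] + 1 + int(rng.integers(3))) % 4]
        if mode == "retain":
            expected[species] = "yes"
        elif mode == "weaken":
            if freq_model is None:
                raise ValueError("weaken mode needs freq_model to pick anti-consensus bases")
            freq = _check_freq_model(freq_model)
            for wpos, p in [(i, site_position - 3 + i) for i in (0, 1, 2, 5, 6, 7, 8)]:
                seq[p] = BASES[int(np.argmin(freq[wpos]))]
            expected[species] = "weak"
        elif mode == "lose_gt_to_GA":
            seq[site_position + 1] = "A"
            expected[species] = "gt_absent"
        elif mode == "delete_region":
            del seq[site_position - 6 : site_position + 9]
            expected[species] = "no"
        windows[species] = "".join(seq)
    return windows, expected
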