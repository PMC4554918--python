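"""5' splice-donor strength scoring over nine-base windows.

A donor window is the 3 exonic bases preceding the cut plus the 6 following
bases (exon remainder, then intron), so the candidate GT dinucleotide sits at
window positions 4-5 (1-based) — the convention of maximum-entropy donor
models. Scores are log-odds in bits against an independent base-frequency
background.

Three scorer kinds share one interface:

``pwm``
    position weight matrix of pseudocounted per-position base frequencies;
    score is the sum of per-position log2 frequency ratios.
``maxent``
    the maximum-entropy distribution over windows whose declared marginals
    (all singletons plus, by default, adjacent pairs) match the pseudocounted
    empirical marginals, fitted by iterative proportional fitting (IPF). The
    model stores per-constraint factor tables and the normalizer, never the
    full 4^9 table. With singleton constraints only it reduces analytically
    to the PWM.
``table``
    an externally produced window→score lookup, so published donor-model
    scores can be reproduced when the user supplies the tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
UNIFORM = np.full(4, 0.25)


class ConvergenceError(RuntimeError):
    """IPF failed to satisfy its marginal constraints within max_iter."""


@dataclass(frozen=True)
class DonorWindow:
    """A nine-base donor context, flagged invalid when it contains N."""

    seq: str
    source: tuple | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())

    @property
    def valid(self) -> bool:
        return all(b in BASE_INDEX for b in self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DonorStats:
    """Mean and sample standard deviation (n-1) of validated-donor scores."""

    mean: float
    sd: float
    n: int


def extract_donor_window(
    exon_seq: str,
    downstream_flank: str,
    cut: int,
    source: tuple | None = None,
) -> DonorWindow:
    """Build the 9-mer for a donor cut at retained length ``cut``.

    The window is the last 3 retained exonic bases plus the next 6 bases,
    drawn first from the exon remainder and then from the flank — so both
    terminal donors (cut at the exon end, intron supplies 6 bases) and
    internal donors (exon remainder supplies them) use one code path.
    """
    exon_seq, downstream_flank = exon_seq.upper(), downstream_flank.upper()
    if cut < 3:
        raise ValueError(f"cut {cut}: fewer than 3 retained exonic bases for the window")
    if cut > len(exon_seq):
        raise ValueError(f"cut {cut} beyond exon length {len(exon_seq)}")
    downstream = exon_seq[cut:] + downstream_flank
    if len(downstream) < 6:
        raise ValueError(
            f"cut {cut}: only {len(downstream)} bases of downstream (intron-side) context, need 6"
        )
    return DonorWindow(seq=exon_seq[cut - 3 : cut] + downstream[:6], source=source)


def _as_freq_array(freqs) -> np.ndarray:
    arr = np.asarray(freqs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("frequency table must be k x 4")
    if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("frequency table rows must each sum to 1")
    return arr


@dataclass
class SpliceScoreModel:
    """A trained donor scorer; see the module docstring for the kinds."""

    kind: str
    n_positions: int = 9
    background: np.ndarray = field(default_factory=lambda: UNIFORM.copy())
    pseudocount: float = 0.5
    # pwm
    freqs: np.ndarray | None = None
    # maxent
    constraints: list[tuple[int, ...]] | None = None
    factors: dict[tuple[int, ...], np.ndarray] | None = None
    log2_z: float | None = None
    # table
    table: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-6):
            raise ValueError("background frequencies must sum to 1")


def _check_windows(windows: Sequence[DonorWindow], n_positions: int) -> list[DonorWindow]:
    valid = [w for w in windows if w.valid and len(w) == n_positions]
    if not valid:
        raise ValueError("no valid training windows")
    return valid


def train_pwm(
    positives: Sequence[DonorWindow],
    pseudocount: float = 0.5,
    background: Sequence[float] = UNIFORM,
    n_positions: int = 9,
) -> SpliceScoreModel:
    """Train a position weight matrix: f = (count + a) / (n + 4a)."""
    valid = _check_windows(positives, n_positions)
    counts = np.zeros((n_positions, 4))
    for w in valid:
        for pos, b in enumerate(w.seq):
            counts[pos, BASE_INDEX[b]] += 1
    freqs = (counts + pseudocount) / (len(valid) + 4 * pseudocount)
    return SpliceScoreModel(
        kind="pwm", n_positions=n_positions, freqs=freqs,
        background=np.asarray(background, dtype=float), pseudocount=pseudocount,
    )


def default_maxent_constraints(n_positions: int = 9) -> list[tuple[int, ...]]:
    """All singletons plus adjacent pairs (nearest-neighbour dependence)."""
    cons: list[tuple[int, ...]] = [(i,) for i in range(n_positions)]
    cons += [(i, i + 1) for i in range(n_positions - 1)]
    return cons


def _empirical_marginals(
    valid: Sequence[DonorWindow],
    constraints: Sequence[tuple[int, ...]],
    pseudocount: float,
) -> dict[tuple[int, ...], np.ndarray]:
    """Marginals of the smoothed empirical distribution.

    Smoothing adds a single uniform mass m = 4a over the whole joint, so the
    marginals of every constraint are mutually consistent (a requirement for
    IPF convergence) and the singleton marginals equal the PWM frequencies
    (count + a) / (n + 4a).
    """
    n = len(valid)
    m = 4.0 * pseudocount
    out = {}
    for cons in constraints:
        shape = (4,) * len(cons)
        counts = np.zeros(shape)
        for w in valid:
            idx = tuple(BASE_INDEX[w.seq[p]] for p in cons)
            counts[idx] += 1
        out[cons] = (counts + m / 4 ** len(cons)) / (n + m)
    return out


def _broadcast_shape(cons: tuple[int, ...], n_positions: int) -> list[int]:
    return [4 if i in cons else 1 for i in range(n_positions)]


def _joint_from_factors(
    factors: dict[tuple[int, ...], np.ndarray], n_positions: int
) -> np.ndarray:
    # constraint tuples are kept sorted, so a plain reshape aligns each
    # factor's axes with the joint's axes in C order
    joint = np.ones((4,) * n_positions)
    for cons, table in factors.items():
        joint = joint * table.reshape(_broadcast_shape(cons, n_positions))
    return joint


def train_maxent(
    positives: Sequence[DonorWindow],
    constraints: Sequence[tuple[int, ...]] | None = None,
    pseudocount: float = 0.5,
    tol: float = 1e-9,
    max_iter: int = 500,
    background: Sequence[float] = UNIFORM,
    n_positions: int = 9,
) -> SpliceScoreModel:
    """Fit the maximum-entropy window distribution by IPF.

    ``constraints`` is a list of position tuples whose marginals the fitted
    distribution must reproduce; it must include every singleton. Fitting
    cycles multiplicative factor updates until the worst marginal discrepancy
    (max absolute difference) drops below ``tol``. The fitted model stores the
    per-constraint factors and log2 of the normalizer.
    """
    if constraints is None:
        constraints = default_maxent_constraints(n_positions)
    constraints = [tuple(sorted(c)) for c in constraints]
    singletons = {(i,) for i in range(n_positions)}
    if not singletons <= set(constraints):
        missing = sorted(singletons - set(constraints))
        raise ValueError(f"constraints must include all singletons; missing {missing}")
    valid = _check_windows(positives, n_positions)
    target = _empirical_marginals(valid, constraints, pseudocount)
    factors = {cons: np.ones((4,) * len(cons)) for cons in constraints}

    joint = _joint_from_factors(factors, n_positions)
    worst: tuple[float, tuple[int, ...]] = (math.inf, constraints[0])
    for _ in range(max_iter):
        worst = (0.0, constraints[0])
        for cons in constraints:
            axes = tuple(i for i in range(n_positions) if i not in cons)
            marg = joint.sum(axis=axes) / joint.sum()
            disc = float(np.max(np.abs(marg - target[cons])))
            if disc > worst[0]:
                worst = (disc, cons)
            with np.errstate(divide="ignore", invalid="ignore"):
                update = np.where(marg > 0, target[cons] / marg, 0.0)
            factors[cons] = factors[cons] * update
            joint = joint * update.reshape(_broadcast_shape(cons, n_positions))
        if worst[0] < tol:
            break
    else:
        raise ConvergenceError(
            f"IPF did not converge in {max_iter} iterations; worst constraint "
            f"{worst[1]} off by {worst[0]:.3g}"
        )
    log2_z = math.log2(_joint_from_factors(factors, n_positions).sum())
    return SpliceScoreModel(
        kind="maxent", n_positions=n_positions, constraints=list(constraints),
        factors=factors, log2_z=log2_z,
        background=np.asarray(background, dtype=float), pseudocount=pseudocount,
    )


def log2_probability(model: SpliceScoreModel, seq: str) -> float:
    """log2 P_model(window) for pwm and maxent models."""
    idx = [BASE_INDEX[b] for b in seq]
    if model.kind == "pwm":
        return float(sum(math.log2(model.freqs[pos, i]) for pos, i in enumerate(idx)))
    if model.kind == "maxent":
        total = 0.0
        for cons, table in model.factors.items():
            val = table[tuple(idx[p] for p in cons)]
            if val <= 0:
                return -math.inf
            total += math.log2(val)
        return total - model.log2_z
    raise ValueError(f"model kind {model.kind!r} has no probability")


def score_window(
    model: SpliceScoreModel,
    window: DonorWindow | str,
    background: SpliceScoreModel | None = None,
) -> float | None:
    """Score a window in bits: log2(P_model / P_background).

    The background is the model's independent base-frequency vector unless a
    decoy model is passed, in which case the score is log2(P_model/P_decoy).
    Invalid (N-containing) windows return None rather than a score.
    """
    if isinstance(window, str):
        window = DonorWindow(window)
    if not window.valid or len(window) != model.n_positions:
        return None
    if model.kind == "table":
        return model.table.get(window.seq)
    lp = log2_probability(model, window.seq)
    if background is not None:
        return lp - log2_probability(background, window.seq)
    bg = sum(math.log2(model.background[BASE_INDEX[b]]) for b in window.seq)
    return lp - bg


def donor_score_stats(
    validated: Sequence[DonorWindow], model: SpliceScoreModel
) -> DonorStats:
    """Mean and sample SD of the scores of validated donor windows."""
    scores = [score_window(model, w) for w in validated]
    scores = [s for s in scores if s is not None]
    if len(scores) < 2:
        raise ValueError(f"need at least 2 valid windows for stats, got {len(scores)}")
    arr = np.asarray(scores)
    return DonorStats(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=len(arr))


# ---------------------------------------------------------------------------
# Serialization: plain TSV-ish text, floats written with repr() so that
# save -> load round-trips bit-exactly.


def _fmt(x: float) -> str:
    return repr(float(x))


def save_model(model: SpliceScoreModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#kind\t{model.kind}\n")
        fh.write(f"#n_positions\t{model.n_positions}\n")
        fh.write(f"#pseudocount\t{_fmt(model.pseudocount)}\n")
        fh.write("#background\t" + "\t".join(_fmt(v) for v in model.background) + "\n")
        if model.kind == "pwm":
            for row in model.freqs:
                fh.write("\t".join(_fmt(v) for v in row) + "\n")
        elif model.kind == "maxent":
            fh.write(f"#log2_z\t{_fmt(model.log2_z)}\n")
            for cons, table in model.factors.items():
                cstr = ",".join(map(str, cons))
                flat = "\t".join(_fmt(v) for v in table.ravel())
                fh.write(f"factor\t{cstr}\t{flat}\n")
        elif model.kind == "table":
            for mer, score in model.table.items():
                fh.write(f"{mer}\t{_fmt(score)}\n")
        else:
            raise ValueError(f"unknown model kind {model.kind!r}")


def load_model(path: str | Path) -> SpliceScoreModel:
    meta: dict[str, str] = {}
    pwm_rows: list[list[float]] = []
    factors: dict[tuple[int, ...], np.ndarray] = {}
    table: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, rest = line[1:].partition("\t")
                meta[key] = rest
                continue
            fields = line.split("\t")
            if fields[0] == "factor":
                cons = tuple(int(x) for x in fields[1].split(","))
                vals = np.array([float(x) for x in fields[2:]])
                factors[cons] = vals.reshape((4,) * len(cons))
            elif meta.get("kind") == "table":
                table[fields[0]] = float(fields[1])
            else:
                pwm_rows.append([float(x) for x in fields])
    kind = meta["kind"]
    n_positions = int(meta.get("n_positions", 9))
    background = np.array([float(x) for x in meta["background"].split("\t")])
    pseudocount = float(meta.get("pseudocount", 0.5))
    if kind == "pwm":
        return SpliceScoreModel(kind="pwm", n_positions=n_positions,
                                freqs=np.array(pwm_rows), background=background,
                                pseudocount=pseudocount)
    if kind == "maxent":
        return SpliceScoreModel(kind="maxent", n_positions=n_positions,
                                constraints=sorted(factors), factors=factors,
                                log2_z=float(meta["log2_z"]), background=background,
                                pseudocount=pseudocount)
    if kind == "table":
        return SpliceScoreModel(kind="table", n_positions=n_positions, table=table,
                                background=background, pseudocount=pseudocount)
    raise ValueError(f"unknown model kind {kind!r} in {path}")


def read_donor_tsv(path: str | Path) -> list[DonorWindow]:
    """Read a validated-donor list: gene_id, exon_label, cut_index, window."""
    import csv

    windows = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            source = (row["gene_id"], row["exon_label"], int(row["cut_index"]))
            windows.append(DonorWindow(seq=row["window"], source=source))
    if not windows:
        raise ValueError(f"no donor windows in {path}")
    return windows


def write_donor_tsv(windows: Iterable[DonorWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\texon_label\tcut_index\twindow\n")
        for w in windows:
            gene_id, exon_label, cut = w.source if w.source else ("", "", "")
            fh.write(f"{gene_id}\t{exon_label}\t{cut}\t{w.seq}\n")
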