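"""Truth-set filtering, call-vs-truth matching and threshold selection.

Mirrors how array-based substitution detection is benchmarked against a
known truth set: substitutions that the platform cannot resolve (close
pairs, repeated 21-mer context, extreme GC) are removed from the truth
before scoring; calls are then matched to truth records within a small
positional tolerance, and the calling threshold is chosen to maximise
true positives minus false positives.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._codes import PROBE_LENGTH, CENTER, encode, revcomp
from .detection import SubstitutionCall
from .simulate import TruthRecord, TruthSet

DEFAULT_TOL_BP = 2
DEFAULT_GC_LOW = 0.2
DEFAULT_GC_HIGH = 0.8


@dataclass
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    sensitivity: float
    matches: list[tuple[SubstitutionCall, TruthRecord, int]]
    exact_position: int
    exact_position_and_base: int
    curve: list[tuple[float, int, int]] = field(default_factory=list)


def _centered_window(genome: str, pos: int, circular: bool) -> str | None:
    L = len(genome)
    idx = np.arange(pos - 1 - CENTER, pos + CENTER)
    if circular:
        idx = idx % L
    elif idx[0] < 0 or idx[-1] >= L:
        return None
    return "".join(genome[i] for i in idx)


def filter_truth_substitutions(truth: TruthSet, genome: str,
                               neighbor_bp: int = PROBE_LENGTH,
                               kmer: int = PROBE_LENGTH,
                               gc_low: float = DEFAULT_GC_LOW,
                               gc_high: float = DEFAULT_GC_HIGH,
                               circular: bool = True) -> TruthSet:
    """Drop truth records that an array of 21-mer probes cannot resolve:

    1. another truth record within ``neighbor_bp`` (both are dropped);
    2. the centered ``kmer``-mer occurs more than once in the genome or
       its reverse complement (repeated context);
    3. the GC fraction of the centered 21-bp window lies outside
       [gc_low, gc_high].
    """
    L = len(genome)
    positions = truth.positions()

    # (2): multiplicity of every k-mer over both strands
    counts: dict[str, int] = {}
    n_windows = L if circular else L - kmer + 1
    for i in range(n_windows):
        if i + kmer <= L:
            w = genome[i:i + kmer]
        else:
            w = genome[i:] + genome[:i + kmer - L]
        counts[w] = counts.get(w, 0) + 1

    kept = []
    for rec in truth.records:
        if len(positions) > 1:
            d = np.abs(positions - rec.position)
            if circular:
                d = np.minimum(d, L - d)
            if np.sort(d)[1] <= neighbor_bp:
                continue
        win = _centered_window(genome, rec.position, circular)
        if win is None:
            continue
        if counts.get(win, 0) + counts.get(revcomp(win), 0) > 1:
            continue
        gc = (win.count("G") + win.count("C")) / len(win)
        if gc < gc_low or gc > gc_high:
            continue
        kept.append(rec)
    return TruthSet(kept, list(truth.deletions))


def match_calls(calls: Sequence[SubstitutionCall], truth: TruthSet,
                tol_bp: int = DEFAULT_TOL_BP,
                genome_length: int | None = None,
                circular: bool = True) -> EvaluationResult:
    """Greedy nearest matching of calls to truth records within tol_bp.

    Each call and each truth record is used at most once; pairs are taken
    in order of increasing distance (ties by call position).  Reports
    exact-position matches and exact position-plus-base matches
    separately.
    """
    pairs = []
    for ci, call in enumerate(calls):
        for ti, rec in enumerate(truth.records):
            d = abs(call.position - rec.position)
            if circular and genome_length:
                d = min(d, genome_length - d)
            if d <= tol_bp:
                pairs.append((d, call.position, ci, ti))
    pairs.sort()
    used_c, used_t = set(), set()
    matches = []
    for d, _, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        matches.append((calls[ci], truth.records[ti], d))
    tp = len(matches)
    fp = len(calls) - tp
    fn = len(truth) - tp
    exact = sum(1 for c, t, d in matches if d == 0)
    exact_base = sum(1 for c, t, d in matches
                     if d == 0 and c.alt_base == t.alt_base)
    sens = tp / len(truth) if len(truth) else float("nan")
    return EvaluationResult(tp, fp, fn, sens, matches, exact, exact_base)


def threshold_curve(calls: Sequence[SubstitutionCall], truth: TruthSet,
                    thetas: Iterable[float] | None = None,
                    tol_bp: int = DEFAULT_TOL_BP,
                    genome_length: int | None = None,
                    circular: bool = True) -> list[tuple[float, int, int]]:
    """(theta_L, tp, fp) over a grid of calling thresholds.

    ``calls`` should be the unthresholded per-region maxima (theta_L =
    -inf); each grid point keeps only calls with llr strictly above it.
    """
    if thetas is None:
        llrs = sorted({c.llr for c in calls})
        thetas = [llrs[0] - 1.0] + [l - 1e-9 for l in llrs]
    curve = []
    for theta in thetas:
        subset = [c for c in calls if c.llr > theta]
        res = match_calls(subset, truth, tol_bp, genome_length, circular)
        curve.append((float(theta), res.tp, res.fp))
    return curve


def best_threshold(curve: Sequence[tuple[float, int, int]]) -> float:
    """theta_L maximising tp - fp; ties break toward the larger threshold
    (fewer calls)."""
    if not curve:
        raise ValueError("empty threshold curve")
    best = max(curve, key=lambda p: (p[1] - p[2], p[0]))
    return float(best[0])
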