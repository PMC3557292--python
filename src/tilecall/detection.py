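"""Substitution detection from two-sample tiling-array intensities.

Given a fitted energy model, per-position residual statistics compare the
observed mutant/wild-type log-intensity ratios of every probe covering a
genome position with the ratios the model predicts under a substitution
hypothesis.  Positions where the running average of the null residual
exceeds a screening threshold theta_R form candidate regions; short
regions (10-79 bp) are scanned for the (position, base) pair maximising a
log-likelihood ratio, long regions (>= 80 bp) are flagged as structural
(e.g. deletions) and excluded from substitution calling.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from ._codes import BASES, CENTER, check_base
from .design import TilingDesign
from .thermo import DesignPredictor, EnergyModel

DEFAULT_WINDOW = 11
DEFAULT_K_SD = 2.0
MIN_REGION = 10
MAX_REGION = 80


@dataclass
class IntensityTable:
    """Observed linear-scale probe intensities for one sample."""

    sample_id: str
    values: pd.Series  # probe_id -> intensity (> 0)

    def __post_init__(self):
        self.values = pd.Series(self.values, dtype=float)
        if (self.values <= 0).any() or not np.isfinite(self.values).all():
            n_bad = int(((self.values <= 0)
                         | ~np.isfinite(self.values)).sum())
            raise ValueError(
                f"intensities must be finite and strictly positive "
                f"({n_bad} offending probes in sample {self.sample_id!r})")

    def aligned(self, design: TilingDesign) -> np.ndarray:
        """Intensities in design order; raises if any probe is missing."""
        out = self.values.reindex(design.probe_ids())
        if out.isna().any():
            raise ValueError(
                f"{int(out.isna().sum())} design probes missing from "
                f"sample {self.sample_id!r}")
        return out.to_numpy()

    def to_tsv(self, path) -> None:
        self.values.rename("intensity").rename_axis("probe_id").to_csv(
            path, sep="\t")

    @classmethod
    def from_tsv(cls, path, sample_id: str | None = None) -> "IntensityTable":
        df = pd.read_csv(path, sep="\t")
        return cls(sample_id or str(path),
                   pd.Series(df["intensity"].to_numpy(),
                             index=df["probe_id"]))


@dataclass
class CandidateRegion:
    """A contiguous run of positions above the screening threshold."""

    start: int
    end: int  # closed interval; end < start only when wrapping the origin
    mean_residual: float
    structural: bool

    def positions(self, genome_length: int) -> np.ndarray:
        if self.end >= self.start:
            return np.arange(self.start, self.end + 1)
        return np.concatenate([np.arange(self.start, genome_length + 1),
                               np.arange(1, self.end + 1)])

    def length(self, genome_length: int) -> int:
        if self.end >= self.start:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end


@dataclass
class SubstitutionCall:
    position: int
    ref_base: str
    alt_base: str
    llr: float
    region: CandidateRegion


@dataclass
class ResidualProfile:
    """Per-position null residuals D_i and their running average."""

    null_residual: np.ndarray
    running_avg: np.ndarray
    theta_R: float
    window: int
    k_sd: float
    circular: bool
    alt_residual: dict = field(default_factory=dict)

    @property
    def genome_length(self) -> int:
        return len(self.null_residual)


def _window_sum(x: np.ndarray, w: int, circular: bool) -> np.ndarray:
    """Centered sliding-window sum (truncated at linear genome ends)."""
    half = w // 2
    if circular:
        xp = np.concatenate([x[-half:], x, x[:half]])
        cs = np.concatenate([[0.0], np.cumsum(xp)])
        return cs[w:] - cs[:-w]
    cs = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return cs[hi] - cs[lo]


def observed_log_ratios(design: TilingDesign, wt: IntensityTable,
                        mut: IntensityTable) -> np.ndarray:
    return np.log(mut.aligned(design)) - np.log(wt.aligned(design))


def position_residual(model: EnergyModel, design: TilingDesign,
                      wt: IntensityTable, mut: IntensityTable, i: int,
                      b: Optional[str] = None,
                      folding: np.ndarray | None = None,
                      predictor: DesignPredictor | None = None) -> float:
    """Residual sum of squares E_i(b) over all probes covering position i.

    ``b=None`` gives the null residual D_i (predicted ratios are all zero
    under the reference hypothesis).
    """
    if predictor is None:
        predictor = DesignPredictor(model, design, folding)
    obs = observed_log_ratios(design, wt, mut)
    if b is None or b == design.genome_sequence[i - 1]:
        idx = design.covering_indices(i)
        return float(np.sum(obs[idx] ** 2))
    idx, pred = predictor.hyp_log_ratios(i, b)
    return float(np.sum((obs[idx] - pred) ** 2))


def _runs_above(above: np.ndarray, circular: bool) -> list[tuple[int, int]]:
    """Maximal runs of True as 1-based closed intervals (a wrapping run on
    a circular genome is reported with end < start)."""
    L = len(above)
    if not above.any():
        return []
    if above.all():
        return [(1, L)]
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = sorted(int(e) + 2 for e in edges if above[e + 1])
    ends = sorted(int(e) + 1 for e in edges if not above[e + 1])
    if above[0]:
        starts.insert(0, 1)
    if above[-1]:
        ends.append(L)
    runs = list(zip(starts, ends))
    if circular and above[0] and above[-1] and len(runs) > 1:
        first, last = runs[0], runs[-1]
        runs = runs[1:-1] + [(last[0], first[1])]
    return runs


def residual_profile(model: EnergyModel, design: TilingDesign,
                     wt: IntensityTable, mut: IntensityTable,
                     window: int = DEFAULT_WINDOW,
                     k_sd: float = DEFAULT_K_SD,
                     folding: np.ndarray | None = None,
                     exclude_structural: bool = True) -> ResidualProfile:
    """Null residuals D_i for every position, their running average over
    ``window`` positions, and the screening threshold
    theta_R = mean(D) + k_sd * sd(D).

    A large deletion drives D_i so high over so many positions that it
    would dominate the genome-wide mean and standard deviation and mask
    every substitution; with ``exclude_structural`` (the default) the
    threshold is therefore re-estimated iteratively with the positions of
    structural-scale runs (length >= 80) removed from the statistics,
    mirroring how deletion regions are taken out of the analysis before
    substitution screening.
    """
    if window % 2 == 0:
        raise ValueError("running-average window must be odd")
    obs = observed_log_ratios(design, wt, mut)
    L = design.genome_length
    per_center = np.zeros(L)
    np.add.at(per_center, design.centers - 1, obs ** 2)
    d = _window_sum(per_center, 2 * CENTER + 1, design.circular)
    avg = _window_sum(d, window, design.circular)
    if design.circular:
        avg = avg / window
    else:
        half = window // 2
        counts = np.minimum(np.arange(L) + half + 1, L) - \
            np.maximum(np.arange(L) - half, 0)
        avg = avg / counts

    mask = np.ones(L, dtype=bool)
    theta = float(d.mean() + k_sd * d.std())
    if exclude_structural:
        for _ in range(5):
            theta = float(d[mask].mean() + k_sd * d[mask].std())
            new_mask = np.ones(L, dtype=bool)
            for s, e in _runs_above(avg > theta, design.circular):
                length = e - s + 1 if e >= s else L - s + 1 + e
                if length >= MAX_REGION:
                    if e >= s:
                        new_mask[s - 1:e] = False
                    else:
                        new_mask[s - 1:] = False
                        new_mask[:e] = False
            if (new_mask == mask).all():
                break
            mask = new_mask
    return ResidualProfile(d, avg, theta, window, k_sd, design.circular)


def screen_candidate_regions(profile: ResidualProfile,
                             min_len: int = MIN_REGION,
                             max_len: int = MAX_REGION
                             ) -> list[CandidateRegion]:
    """Maximal runs of positions whose running average exceeds theta_R.

    Runs shorter than ``min_len`` are dropped; runs of ``max_len`` or more
    are flagged structural (deletion-like) and excluded from substitution
    calling downstream.
    """
    above = profile.running_avg > profile.theta_R
    L = len(above)
    runs = _runs_above(above, profile.circular)
    regions = []
    for s, e in runs:
        length = e - s + 1 if e >= s else L - s + 1 + e
        if length < min_len:
            continue
        if e >= s:
            mean_res = float(profile.null_residual[s - 1:e].mean())
        else:
            mean_res = float(np.concatenate(
                [profile.null_residual[s - 1:],
                 profile.null_residual[:e]]).mean())
        regions.append(CandidateRegion(s, e, mean_res,
                                       structural=length >= max_len))
    regions.sort(key=lambda r: r.start)
    return regions


def likelihood_ratio(model: EnergyModel, design: TilingDesign,
                     wt: IntensityTable, mut: IntensityTable, i: int, b: str,
                     folding: np.ndarray | None = None,
                     predictor: DesignPredictor | None = None) -> float:
    """Log-likelihood ratio D_i - E_i(b) favoring substitution to b at i
    (up to a neglected positive constant)."""
    check_base(b)
    if b.upper() == design.genome_sequence[i - 1]:
        raise ValueError("alt base must differ from the reference base")
    if predictor is None:
        predictor = DesignPredictor(model, design, folding)
    obs = observed_log_ratios(design, wt, mut)
    idx, pred = predictor.hyp_log_ratios(i, b.upper())
    return float(np.sum(obs[idx] ** 2) - np.sum((obs[idx] - pred) ** 2))


def call_substitutions(model: EnergyModel, design: TilingDesign,
                       wt: IntensityTable, mut: IntensityTable,
                       regions: Iterable[CandidateRegion],
                       theta_L: float,
                       folding: np.ndarray | None = None,
                       predictor: DesignPredictor | None = None
                       ) -> list[SubstitutionCall]:
    """One call per non-structural region: the (position, base) maximising
    the likelihood ratio, emitted iff it strictly exceeds theta_L.

    Ties at the maximum break toward the smaller position, then A<C<G<T.
    """
    if predictor is None:
        predictor = DesignPredictor(model, design, folding)
    obs = observed_log_ratios(design, wt, mut)
    genome = design.genome_code
    calls = []
    for region in regions:
        if region.structural:
            continue
        best = None  # (llr, position, alt)
        for pos in region.positions(design.genome_length):
            pos = int(pos)
            ref_code = genome[pos - 1]
            if ref_code > 3:
                continue
            for alt_code in range(4):
                if alt_code == ref_code:
                    continue
                idx, pred = predictor.hyp_log_ratios(pos, BASES[alt_code])
                llr = float(np.sum(obs[idx] ** 2)
                            - np.sum((obs[idx] - pred) ** 2))
                if best is None or llr > best[0]:
                    best = (llr, pos, alt_code)
        if best is not None and best[0] > theta_L:
            llr, pos, alt_code = best
            calls.append(SubstitutionCall(
                pos, BASES[genome[pos - 1]], BASES[alt_code], llr, region))
    return calls


def detect(model: EnergyModel, design: TilingDesign, wt: IntensityTable,
           mut: IntensityTable, theta_L: float,
           window: int = DEFAULT_WINDOW, k_sd: float = DEFAULT_K_SD,
           folding: np.ndarray | None = None
           ) -> tuple[list[SubstitutionCall], list[CandidateRegion],
                      ResidualProfile]:
    """Full screening + calling pipeline for one wt/mutant sample pair."""
    predictor = DesignPredictor(model, design, folding)
    profile = residual_profile(model, design, wt, mut, window, k_sd,
                               predictor.folding)
    regions = screen_candidate_regions(profile)
    calls = call_substitutions(model, design, wt, mut, regions, theta_L,
                               predictor=predictor)
    return calls, regions, profile
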