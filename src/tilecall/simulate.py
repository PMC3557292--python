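"""Seeded forward-model simulator: synthetic genomes, implanted variants,
ground-truth energy models and noisy two-sample intensity tables.

The simulator replaces array data that a wet-lab experiment would provide:
it draws a random genome, implants well-spaced single-base substitutions
(and optional deletions), samples a ground-truth energy model, and pushes
both the reference and the mutant genome through the finite-hybridization
forward model with multiplicative log-normal noise.  Every artifact is a
pure function of the configuration, so a fixed seed reproduces the whole
dataset bit-for-bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._codes import BASES, CENTER, encode
from .design import TilingDesign, _OFFSETS, build_tiling_design
from .detection import IntensityTable
from .thermo import (EnergyModel, N_WEIGHTS, adjusted_specific_energies,
                     folding_energies, log_intensity_from_energies,
                     triplet_codes, _weighted_energy)

# Sampling intervals for the ground-truth model, chosen so that probes sit
# in the responsive (non-saturated) part of the binding isotherm and a
# single mismatch drops the predicted intensity by a factor of roughly
# 2-10, as on real arrays.
DEFAULT_MODEL_RANGES = {
    "eps_specific": (0.1, 0.7),
    "eps_nonspecific": (0.02, 0.3),
    "penalty": (1.0, 3.0),
    "weights": (0.2, 1.0),
    "alpha": (0.9, 1.1),
    "intensity_scale": (800.0, 1200.0),
    "background": (20.0, 60.0),
    "conc_nonspecific": (0.01, 0.05),
}

# substitutions are kept this far away from deletion edges so that point
# candidate regions never merge with structural ones
DELETION_MARGIN = 100


@dataclass(frozen=True)
class TruthRecord:
    position: int
    ref_base: str
    alt_base: str


@dataclass
class TruthSet:
    records: list[TruthRecord] = field(default_factory=list)
    deletions: list[tuple[int, int]] = field(default_factory=list)  # closed

    def positions(self) -> np.ndarray:
        return np.array([r.position for r in self.records], dtype=int)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SimConfig:
    """Study conditions for one simulated two-sample experiment."""

    genome_length: int = 50_000
    gc_content: float = 0.5
    n_substitutions: int = 20
    min_spacing: int = 100
    deletions: list[tuple[int, int]] = field(default_factory=list)
    noise_sd: float = 0.05
    seed: int = 17
    model_ranges: dict = field(default_factory=lambda: dict(
        DEFAULT_MODEL_RANGES))

    def __post_init__(self):
        if self.min_spacing < 22:
            raise ValueError("min_spacing must be at least 22 bp (one probe "
                             "length plus one)")
        if self.n_substitutions * self.min_spacing >= self.genome_length:
            raise ValueError("substitutions at this spacing do not fit")


def random_genome(length: int, gc_content: float, seed: int) -> str:
    """I.i.d. random genome with the requested GC fraction."""
    if length < 1000:
        raise ValueError("genome length must be at least 1000 bp")
    if not 0.0 < gc_content < 1.0:
        raise ValueError("gc_content must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    at, gc = (1 - gc_content) / 2, gc_content / 2
    codes = rng.choice(4, size=length, p=[at, gc, gc, at])
    return "".join(np.array(list(BASES))[codes])


def _circular_distance(a: np.ndarray, b: int, L: int) -> np.ndarray:
    d = np.abs(a - b)
    return np.minimum(d, L - d)


def implant_substitutions(genome: str, n: int, min_spacing: int, seed: int,
                          exclude: Sequence[tuple[int, int]] = ()
                          ) -> tuple[str, TruthSet]:
    """Implant n uniform substitutions at pairwise (circular) distance
    >= min_spacing, avoiding the closed intervals in ``exclude``."""
    L = len(genome)
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    attempts = 0
    max_attempts = 200 * max(n, 1) + 1000
    while len(chosen) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n} substitutions at spacing "
                f"{min_spacing}; at most ~{L // min_spacing} are feasible")
        pos = int(rng.integers(1, L + 1))
        if genome[pos - 1] not in BASES:
            continue
        if chosen and _circular_distance(np.array(chosen), pos,
                                         L).min() < min_spacing:
            continue
        if any(s - DELETION_MARGIN <= pos <= e + DELETION_MARGIN
               for s, e in exclude):
            continue
        chosen.append(pos)
    mutant = list(genome)
    records = []
    for pos in sorted(chosen):
        ref = genome[pos - 1]
        alts = [b for b in BASES if b != ref]
        alt = alts[int(rng.integers(3))]
        mutant[pos - 1] = alt
        records.append(TruthRecord(pos, ref, alt))
    return "".join(mutant), TruthSet(records)


def sample_true_model(model_ranges: dict | None = None,
                      seed: int = 0) -> EnergyModel:
    """Draw a ground-truth energy model uniformly within per-group ranges.

    Position weights are arranged to peak at the probe center and decrease
    monotonically toward both ends.
    """
    ranges = dict(DEFAULT_MODEL_RANGES)
    if model_ranges:
        ranges.update(model_ranges)
    rng = np.random.default_rng(seed)

    def u(group, size=None):
        lo, hi = ranges[group]
        return rng.uniform(lo, hi, size)

    raw_w = np.sort(u("weights", N_WEIGHTS))[::-1]
    weights = np.empty(N_WEIGHTS)
    # assign the largest draws center-out: 11, 10, 12, 9, 13, ...
    order = [N_WEIGHTS // 2]
    for step in range(1, N_WEIGHTS // 2 + 1):
        if N_WEIGHTS // 2 - step >= 0:
            order.append(N_WEIGHTS // 2 - step)
        if N_WEIGHTS // 2 + step < N_WEIGHTS:
            order.append(N_WEIGHTS // 2 + step)
    for rank, k in enumerate(order):
        weights[k] = raw_w[rank]

    return EnergyModel(
        eps_specific=u("eps_specific", 64),
        eps_nonspecific=u("eps_nonspecific", 64),
        penalty=u("penalty", (64, 3)),
        weights=weights,
        alpha=float(u("alpha")),
        intensity_scale=float(u("intensity_scale")),
        background=float(u("background")),
        conc_nonspecific=float(u("conc_nonspecific")),
    )


def _target_codes(design: TilingDesign, variant_code: np.ndarray
                  ) -> np.ndarray:
    """Probe-space target 21-mers extracted from a variant genome."""
    mat = (design.centers - 1)[:, None] + _OFFSETS[None, :]
    if design.circular:
        mat = mat % design.genome_length
    win = variant_code[mat]
    rev = design.strands == 1
    win[rev] = 3 - win[rev][:, ::-1]
    return win


def simulate_intensities(model: EnergyModel, design: TilingDesign,
                         genome_variant: str | np.ndarray,
                         folding: np.ndarray | None = None,
                         noise_sd: float = 0.0, seed: int = 0,
                         deletions: Sequence[tuple[int, int]] = (),
                         sample_id: str = "sample") -> IntensityTable:
    """Push a (possibly mutated) genome through the forward model.

    Probes whose span overlaps a deleted interval lose their specific
    binding term and report non-specific signal plus background only.
    Noise is multiplicative log-normal: intensity = exp(log I + eps) with
    eps ~ Normal(0, noise_sd^2).
    """
    var_code = genome_variant if isinstance(genome_variant, np.ndarray) \
        else encode(str(genome_variant).upper())
    if len(var_code) != design.genome_length:
        raise ValueError("variant genome length must match the design")
    probe_enc = design.probe_codes()
    pm_enc = design.pm_codes()
    target_enc = _target_codes(design, var_code)
    if folding is None:
        folding = folding_energies(probe_enc)
    g_s = adjusted_specific_energies(model, pm_enc, probe_enc, target_enc)
    g_ns = _weighted_energy(model.eps_nonspecific, model.weights,
                            triplet_codes(probe_enc))
    specific_on = None
    if deletions:
        specific_on = np.ones(len(design), dtype=bool)
        for s, e in deletions:
            specific_on &= ~((design.centers >= s - CENTER)
                             & (design.centers <= e + CENTER))
    log_i = log_intensity_from_energies(model, g_s, g_ns, folding,
                                        specific_on)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        log_i = log_i + rng.normal(0.0, noise_sd, size=len(log_i))
    return IntensityTable(sample_id,
                          pd.Series(np.exp(log_i),
                                    index=design.probe_ids()))


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: str
    mutant: str
    truth: TruthSet
    model: EnergyModel
    design: TilingDesign
    folding: np.ndarray
    wt: IntensityTable
    mut: IntensityTable


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a complete two-sample experiment from one configuration."""
    master = np.random.SeedSequence(config.seed)
    s_genome, s_model, s_subs, s_wt, s_mut = [
        int(s.generate_state(1)[0] % (2 ** 31))
        for s in master.spawn(5)]
    genome = random_genome(config.genome_length, config.gc_content, s_genome)
    model = sample_true_model(config.model_ranges, s_model)
    design = build_tiling_design(genome, resolution=1, circular=True,
                                 genome_id=f"sim{config.seed}")
    folding = folding_energies(design.probe_codes())
    mutant, truth = implant_substitutions(
        genome, config.n_substitutions, config.min_spacing, s_subs,
        exclude=config.deletions)
    truth.deletions = list(config.deletions)
    wt = simulate_intensities(model, design, genome, folding,
                              config.noise_sd, s_wt, sample_id="wt")
    mut = simulate_intensities(model, design, mutant, folding,
                               config.noise_sd, s_mut,
                               deletions=config.deletions, sample_id="mut")
    return SimulatedDataset(config, genome, mutant, truth, model, design,
                            folding, wt, mut)
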