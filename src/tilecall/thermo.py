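"""Finite-hybridization (FH) model of tiling-array probe intensity.

A probe's signal is modelled as an equilibrium between four states of the
probe site: unbound, self-folded, bound to its specific target, and bound
to the non-specific target pool.  With reaction coefficients

    K_s  = exp(alpha * G_s),   K_ns = exp(alpha * G_ns),
    K_f  = exp(alpha * G_f),

the predicted (linear-scale) intensity is

    I = A * (K_s + K_ns * C_ns) / (1 + K_f + K_s + K_ns * C_ns) + B

where A is the optical scale, B the optical background, C_ns the effective
non-specific target concentration, and alpha a fitted scaling constant
absorbing RT.  G_s and G_ns are position-weighted sums of local triplet
energies over the probe; every probe-target mismatch subtracts a
context-dependent penalty from G_s.  All free energies are on the fitted
(dimensionless) scale; larger G means stronger binding.

The model has exactly 343 free parameters: 64 specific triplet energies,
64 non-specific triplet energies, 192 mismatch penalties (64 triplets x 3
alternative central bases), 19 position weights, and 4 global scalars.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._codes import BASES, CENTER, PROBE_LENGTH, check_base, encode
from .design import Probe, TilingDesign, _OFFSETS

N_TRIPLETS = 64
N_WEIGHTS = PROBE_LENGTH - 2  # triplet centers at probe positions 2..20
N_PARAMETERS = 64 + 64 + 192 + N_WEIGHTS + 4  # == 343

SCHEMA_VERSION = 1


@dataclass
class EnergyModel:
    """The 343 fitted parameters of the finite-hybridization model."""

    eps_specific: np.ndarray      # (64,) specific triplet energies
    eps_nonspecific: np.ndarray   # (64,) non-specific triplet energies
    penalty: np.ndarray           # (64, 3) mismatch penalties >= 0
    weights: np.ndarray           # (19,) position weights in [0, 1]
    alpha: float                  # energy scaling (scaled inverse RT)
    intensity_scale: float        # A, optical counts at saturation
    background: float             # B, optical background counts
    conc_nonspecific: float       # C_ns, effective non-specific pool

    def __post_init__(self):
        self.eps_specific = np.asarray(self.eps_specific, dtype=float)
        self.eps_nonspecific = np.asarray(self.eps_nonspecific, dtype=float)
        self.penalty = np.asarray(self.penalty, dtype=float).reshape(64, 3)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.eps_specific.shape != (64,):
            raise ValueError("eps_specific must have 64 entries")
        if self.eps_nonspecific.shape != (64,):
            raise ValueError("eps_nonspecific must have 64 entries")
        if self.weights.shape != (N_WEIGHTS,):
            raise ValueError(f"weights must have {N_WEIGHTS} entries")
        for name in ("alpha", "intensity_scale", "background",
                     "conc_nonspecific"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    # -- flat parameter vector ----------------------------------------
    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            self.eps_specific, self.eps_nonspecific, self.penalty.ravel(),
            self.weights,
            [self.alpha, self.intensity_scale, self.background,
             self.conc_nonspecific],
        ])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "EnergyModel":
        v = np.asarray(v, dtype=float)
        if v.shape != (N_PARAMETERS,):
            raise ValueError(f"parameter vector must have {N_PARAMETERS} "
                             f"entries, got {v.shape}")
        return cls(v[:64], v[64:128], v[128:320].reshape(64, 3),
                   v[320:339], *v[339:343])

    @property
    def n_parameters(self) -> int:
        return len(self.to_vector())

    # -- JSON serialization -------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "eps_specific": self.eps_specific.tolist(),
            "eps_nonspecific": self.eps_nonspecific.tolist(),
            "penalty": self.penalty.tolist(),
            "weights": self.weights.tolist(),
            "alpha": self.alpha,
            "intensity_scale": self.intensity_scale,
            "background": self.background,
            "conc_nonspecific": self.conc_nonspecific,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "EnergyModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(np.array(doc["eps_specific"]),
                   np.array(doc["eps_nonspecific"]),
                   np.array(doc["penalty"]), np.array(doc["weights"]),
                   doc["alpha"], doc["intensity_scale"], doc["background"],
                   doc["conc_nonspecific"])


@dataclass(frozen=True)
class Hypothesis:
    """A single-base substitution hypothesis (both fields None = reference)."""

    position: Optional[int] = None
    alt_base: Optional[str] = None

    def __post_init__(self):
        if (self.position is None) != (self.alt_base is None):
            raise ValueError("position and alt_base must be set together")
        if self.alt_base is not None:
            check_base(self.alt_base)

    @property
    def is_reference(self) -> bool:
        return self.position is None


REFERENCE = Hypothesis()


# ---------------------------------------------------------------------
# triplet energies
# ---------------------------------------------------------------------
def triplet_index(prev: str, center: str, nxt: str) -> int:
    """Base-4 code of a triplet: 16*prev + 4*center + next (A,C,G,T=0..3)."""
    return 16 * check_base(prev) + 4 * check_base(center) + check_base(nxt)


def triplet_codes(enc: np.ndarray) -> np.ndarray:
    """(n, 21) base codes -> (n, 19) triplet indices for centers 2..20."""
    e = enc.astype(np.int64)
    return 16 * e[..., :-2] + 4 * e[..., 1:-1] + e[..., 2:]


def _weighted_energy(eps: np.ndarray, weights: np.ndarray,
                     trips: np.ndarray) -> np.ndarray:
    return eps[trips] @ weights


def _check_21mer(seq: str) -> np.ndarray:
    enc = encode(seq)
    if len(enc) != PROBE_LENGTH or (enc > 3).any():
        raise ValueError("probe sequence must be a 21-mer over ACGT")
    return enc


def specific_energy(model: EnergyModel, probe_seq: str) -> float:
    """Position-weighted nearest-neighbor energy of specific binding."""
    enc = _check_21mer(probe_seq)
    return float(_weighted_energy(model.eps_specific, model.weights,
                                  triplet_codes(enc[None, :]))[0])


def nonspecific_energy(model: EnergyModel, probe_seq: str) -> float:
    """Same weighted triplet sum over the non-specific energy table."""
    enc = _check_21mer(probe_seq)
    return float(_weighted_energy(model.eps_nonspecific, model.weights,
                                  triplet_codes(enc[None, :]))[0])


# ---------------------------------------------------------------------
# mismatch-adjusted specific energy
# ---------------------------------------------------------------------
def adjusted_specific_energies(model: EnergyModel, pm_enc: np.ndarray,
                               probe_enc: np.ndarray,
                               target_enc: np.ndarray) -> np.ndarray:
    """Vectorized G_s with one penalty subtracted per probe-target mismatch.

    ``pm_enc`` holds the reference (PM) sequence of each probe's locus in
    probe space; penalties are looked up by the PM triplet context at the
    mismatch site and by the substituted base.  Mismatches at the two
    terminal probe positions have no triplet context and carry no penalty
    (the position weights also vanish toward the probe ends).
    """
    g = _weighted_energy(model.eps_specific, model.weights,
                         triplet_codes(pm_enc))
    mm = probe_enc != target_enc
    mm[:, 0] = False
    mm[:, -1] = False
    rows, cols = np.nonzero(mm)
    if len(rows):
        pm = pm_enc.astype(np.int64)
        trip = (16 * pm[rows, cols - 1] + 4 * pm[rows, cols]
                + pm[rows, cols + 1])
        ref = pm[rows, cols]
        pb = probe_enc[rows, cols].astype(np.int64)
        tb = target_enc[rows, cols].astype(np.int64)
        sub = np.where(pb != ref, pb, tb)
        alt_idx = sub - (sub > ref)
        g = g.copy() if not g.flags.writeable else g
        np.subtract.at(g, rows, model.penalty[trip, alt_idx])
    return g


def _genome_codes(genome) -> np.ndarray:
    if isinstance(genome, np.ndarray):
        return genome
    return encode(str(genome).upper())


def _locus_window(genome_code: np.ndarray, center: int, strand: str,
                  circular: bool) -> np.ndarray:
    mat = center - 1 + _OFFSETS
    L = len(genome_code)
    if circular:
        mat = mat % L
    elif mat[0] < 0 or mat[-1] >= L:
        raise ValueError("probe window extends past a linear genome end")
    win = genome_code[mat].copy()
    if strand == "-":
        win = 3 - win[::-1]
    return win


def mismatch_adjusted_energy(model: EnergyModel, probe: Probe, genome,
                             hyp: Hypothesis = REFERENCE,
                             circular: bool = True) -> float:
    """Specific binding energy of a probe against the (possibly mutated)
    target, with one penalty per probe-target mismatch."""
    code = _genome_codes(genome).copy()
    if hyp is not None and not hyp.is_reference:
        b = check_base(hyp.alt_base)
        if code[hyp.position - 1] == b:
            raise ValueError("hypothesis alt base equals the reference base")
        code[hyp.position - 1] = b
    pm = _locus_window(_genome_codes(genome), probe.position, probe.strand,
                       circular)
    target = _locus_window(code, probe.position, probe.strand, circular)
    probe_enc = _check_21mer(probe.sequence)
    n_mm = int((probe_enc != target).sum())
    if n_mm > 2:
        raise ValueError(
            f"{n_mm} probe-target mismatches; the model assumes at most one "
            "substitution per probe length")
    return float(adjusted_specific_energies(
        model, pm[None, :], probe_enc[None, :], target[None, :])[0])


# ---------------------------------------------------------------------
# probe self-folding
# ---------------------------------------------------------------------
# Unified DNA/DNA nearest-neighbor stacking table (-dG37, kcal/mol),
# indexed by 4*first + second base code of the 5' arm dinucleotide.
DEFAULT_STACK_TABLE = np.array([
    1.00, 1.44, 1.28, 0.88,   # AA AC AG AT
    1.45, 1.84, 2.17, 1.28,   # CA CC CG CT
    1.30, 2.24, 1.84, 1.44,   # GA GC GG GT
    0.58, 1.30, 1.45, 1.00,   # TA TC TG TT
])
DEFAULT_LOOP_PENALTY = 3.5
DEFAULT_MIN_LOOP = 3


def _stem_candidates(n: int, min_loop: int):
    """All (i, j, l): arm seq[i:i+l] paired with seq[j:j+l], l >= 2."""
    for l in range(2, (n - min_loop) // 2 + 1):
        for i in range(0, n - 2 * l - min_loop + 1):
            for j in range(i + l + min_loop, n - l + 1):
                yield i, j, l


def folding_energy(probe_seq: str,
                   nn_stack_table: np.ndarray = DEFAULT_STACK_TABLE,
                   loop_penalty: float = DEFAULT_LOOP_PENALTY,
                   min_loop: int = DEFAULT_MIN_LOOP) -> float:
    """Deterministic stem-loop estimate of a probe's self-folding energy.

    Enumerates every single-stem hairpin (two reverse-complementary arms of
    length >= 2 separated by a loop of >= ``min_loop`` bases), scores it as
    the sum of nearest-neighbor stack terms minus a loop penalty, and
    returns the best score clipped at zero.
    """
    enc = _check_21mer(probe_seq)
    n = len(enc)
    best = 0.0
    for i, j, l in _stem_candidates(n, min_loop):
        if all(enc[i + k] == 3 - enc[j + l - 1 - k] for k in range(l)):
            score = sum(nn_stack_table[4 * enc[i + k] + enc[i + k + 1]]
                        for k in range(l - 1)) - loop_penalty
            best = max(best, score)
    return float(best)


def folding_energies(enc: np.ndarray,
                     nn_stack_table: np.ndarray = DEFAULT_STACK_TABLE,
                     loop_penalty: float = DEFAULT_LOOP_PENALTY,
                     min_loop: int = DEFAULT_MIN_LOOP) -> np.ndarray:
    """Vectorized stem-loop folding energies for an (n, 21) code array."""
    enc = np.asarray(enc)
    n_probes, n = enc.shape
    stack = nn_stack_table[4 * enc[:, :-1].astype(np.int64) + enc[:, 1:]]
    cs = np.concatenate([np.zeros((n_probes, 1)), np.cumsum(stack, axis=1)],
                        axis=1)
    best = np.zeros(n_probes)
    comp = 3 - enc
    for i, j, l in _stem_candidates(n, min_loop):
        ok = np.ones(n_probes, dtype=bool)
        for k in range(l):
            ok &= enc[:, i + k] == comp[:, j + l - 1 - k]
        if ok.any():
            score = cs[:, i + l - 1] - cs[:, i] - loop_penalty
            np.maximum(best, np.where(ok, score, 0.0), out=best)
    return best


# ---------------------------------------------------------------------
# predicted intensity
# ---------------------------------------------------------------------
def log_intensity_from_energies(model: EnergyModel, g_s: np.ndarray,
                                g_ns: np.ndarray, g_f: np.ndarray,
                                specific_on: np.ndarray | None = None
                                ) -> np.ndarray:
    """Overflow-safe log of the FH intensity, fully in log space.

    ``specific_on`` (boolean) switches off the specific binding term, which
    models probes whose specific target is absent (e.g. a deleted region).
    """
    a = model.alpha
    log_ks = a * np.asarray(g_s, dtype=float)
    if specific_on is not None:
        log_ks = np.where(specific_on, log_ks, -np.inf)
    log_knsc = a * np.asarray(g_ns, dtype=float) + np.log(
        model.conc_nonspecific)
    log_num = np.logaddexp(log_ks, log_knsc)
    log_den = np.logaddexp(np.logaddexp(0.0, a * np.asarray(g_f, dtype=float)),
                           log_num)
    return np.logaddexp(np.log(model.intensity_scale) + log_num - log_den,
                        np.log(model.background))


def predict_log_intensity(model: EnergyModel, probe: Probe, genome,
                          hyp: Hypothesis = REFERENCE,
                          folding: float = 0.0,
                          circular: bool = True) -> float:
    """Predicted log signal intensity of one probe under a hypothesis."""
    g_s = mismatch_adjusted_energy(model, probe, genome, hyp, circular)
    g_ns = nonspecific_energy(model, probe.sequence)
    return float(log_intensity_from_energies(
        model, np.array([g_s]), np.array([g_ns]), np.array([folding]))[0])


def predict_log_ratio(model: EnergyModel, probe: Probe, genome,
                      hyp: Hypothesis, folding: float = 0.0,
                      circular: bool = True) -> float:
    """Predicted mutant/wild-type log-intensity ratio of one probe.

    Exactly zero under the reference hypothesis and for probes whose span
    does not contain the hypothesised position.
    """
    if hyp is None or hyp.is_reference:
        return 0.0
    return (predict_log_intensity(model, probe, genome, hyp, folding,
                                  circular)
            - predict_log_intensity(model, probe, genome, REFERENCE, folding,
                                    circular))


# ---------------------------------------------------------------------
# design-level prediction engine (shared by fitting, detection, simulation)
# ---------------------------------------------------------------------
class DesignPredictor:
    """Precomputed per-probe encodings and reference predictions for a
    design, enabling fast hypothesis-level prediction."""

    def __init__(self, model: EnergyModel, design: TilingDesign,
                 folding: np.ndarray | None = None):
        self.model = model
        self.design = design
        self.pm_enc = design.pm_codes()
        self.probe_enc = design.probe_codes()
        if folding is None:
            folding = folding_energies(self.probe_enc)
        self.folding = np.asarray(folding, dtype=float)
        if self.folding.shape != (len(design),):
            raise ValueError("folding energies must align with the design")
        self.g_ns = _weighted_energy(model.eps_nonspecific, model.weights,
                                     triplet_codes(self.probe_enc))
        self.ref_log_intensity = self._log_intensity(self.pm_enc,
                                                     np.arange(len(design)))

    def _log_intensity(self, target_enc: np.ndarray, idx: np.ndarray,
                       specific_on: np.ndarray | None = None) -> np.ndarray:
        g_s = adjusted_specific_energies(self.model, self.pm_enc[idx],
                                         self.probe_enc[idx], target_enc)
        return log_intensity_from_energies(self.model, g_s, self.g_ns[idx],
                                           self.folding[idx], specific_on)

    def _hyp_targets(self, idx: np.ndarray, position: int,
                     alt_code: int) -> np.ndarray:
        """Reference windows of the selected probes with the substitution
        applied at the right probe-space column."""
        d = self.design
        delta = (position - d.centers[idx]).astype(np.int64)
        if d.circular:
            L = d.genome_length
            delta = (delta + L // 2) % L - L // 2
        fwd = d.strands[idx] == 0
        cols = np.where(fwd, CENTER + delta, CENTER - delta)
        target = self.pm_enc[idx].copy()
        target[np.arange(len(idx)), cols] = np.where(fwd, alt_code,
                                                     3 - alt_code)
        return target

    def hyp_log_ratios(self, position: int, alt_base: str
                       ) -> tuple[np.ndarray, np.ndarray]:
        """(probe indices covering position, predicted log ratios)."""
        idx = self.design.covering_indices(position)
        alt_code = check_base(alt_base)
        ref_code = self.design.genome_code[position - 1]
        if alt_code == ref_code:
            raise ValueError("hypothesis alt base equals the reference base")
        target = self._hyp_targets(idx, position, alt_code)
        return idx, self._log_intensity(target, idx) - \
            self.ref_log_intensity[idx]
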