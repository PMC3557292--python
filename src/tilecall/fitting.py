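"""Estimation of the 343 energy-model parameters from wild-type data.

The objective is the residual sum of squares between observed and
predicted log intensities of the reference sample over the design (PM
probes exercise the triplet energies and weights, MM probes additionally
carry one mismatch penalty each).  The search is a seeded population
stage (differential evolution) followed by a deterministic trust-region
least-squares polish; the whole fit is bit-reproducible given the inputs
and the configuration.  The parameterization is not fully identifiable
(e.g. a common rescaling of weights and energies compensated by alpha),
so fit quality is judged on predicted intensities, not parameter values.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import differential_evolution, least_squares

from ._codes import CENTER
from .design import TilingDesign
from .detection import IntensityTable
from .thermo import (DesignPredictor, EnergyModel, N_PARAMETERS, N_WEIGHTS,
                     folding_energies, triplet_codes)

logger = logging.getLogger(__name__)

DEFAULT_BOUNDS = {
    "eps_specific": (0.0, 10.0),
    "eps_nonspecific": (0.0, 10.0),
    "penalty": (0.0, 10.0),
    "weights": (0.0, 1.0),
    # global scalars are searched in log space
    "alpha": (0.05, 20.0),
    "intensity_scale": (1.0, 1e7),
    "background": (1e-2, 1e5),
    "conc_nonspecific": (1e-5, 10.0),
}
_SCALARS = ("alpha", "intensity_scale", "background", "conc_nonspecific")


@dataclass
class FitConfig:
    seed: int
    optimizer: str = "population_search"
    population_size: int = 32
    generations: int = 40
    bounds: dict = field(default_factory=dict)
    tolerance: float = 1e-10
    patience: int = 10
    subset_fraction: float = 1.0
    polish: bool = True
    polish_max_nfev: Optional[int] = None

    def __post_init__(self):
        if self.optimizer != "population_search":
            raise ValueError("only the population_search optimizer is "
                             "supported")
        if self.population_size < 8:
            raise ValueError("population_size must be at least 8")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible fits")
        merged = dict(DEFAULT_BOUNDS)
        merged.update(self.bounds)
        self.bounds = merged
        for lo, hi in self.bounds.values():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("bounds must be finite intervals")


@dataclass
class FitDiagnostics:
    objective: float
    rmse: float
    trajectory: np.ndarray  # best-so-far objective per generation
    generations_run: int
    seed: int
    n_probes_fit: int
    n_probes_total: int


def _search_bounds(config: FitConfig) -> tuple[np.ndarray, np.ndarray]:
    """(lower, upper) in search space (scalars log-transformed)."""
    b = config.bounds
    lo, hi = [], []
    for group, count in (("eps_specific", 64), ("eps_nonspecific", 64),
                         ("penalty", 192), ("weights", N_WEIGHTS)):
        lo += [b[group][0]] * count
        hi += [b[group][1]] * count
    for name in _SCALARS:
        lo.append(np.log(b[name][0]))
        hi.append(np.log(b[name][1]))
    return np.array(lo), np.array(hi)


def _to_search(v: np.ndarray) -> np.ndarray:
    x = v.copy()
    x[-4:] = np.log(x[-4:])
    return x


def _from_search(x: np.ndarray) -> np.ndarray:
    v = np.asarray(x, dtype=float).copy()
    v[-4:] = np.exp(v[-4:])
    return v


class _Objective:
    """Fast residual engine for reference-sample fitting.

    Under the reference hypothesis the only probe-target mismatch is the
    central base of MM probes, so the per-probe prediction reduces to a
    handful of table gathers that are cheap to re-evaluate inside the
    optimizer loop.
    """

    def __init__(self, design: TilingDesign, observed_wt: IntensityTable,
                 folding: np.ndarray, idx: np.ndarray):
        self.obs_log = np.log(observed_wt.aligned(design))[idx]
        pm_enc = design.pm_codes(idx)
        probe_enc = design.probe_codes(idx)
        self.pm_trip = triplet_codes(pm_enc)
        self.probe_trip = triplet_codes(probe_enc)
        self.folding = np.asarray(folding, dtype=float)[idx]
        alts = design.alts[idx]
        self.is_mm = alts >= 0
        pm64 = pm_enc.astype(np.int64)
        self.center_trip = (16 * pm64[:, CENTER - 1] + 4 * pm64[:, CENTER]
                            + pm64[:, CENTER + 1])
        ref_center = pm64[:, CENTER]
        a = alts.astype(np.int64)
        self.alt_idx = np.where(self.is_mm, a - (a > ref_center), 0)
        self.n = len(idx)

    def residuals(self, x: np.ndarray) -> np.ndarray:
        v = _from_search(x)
        eps_s, eps_ns = v[:64], v[64:128]
        penalty = v[128:320].reshape(64, 3)
        w = v[320:320 + N_WEIGHTS]
        alpha, a_scale, background, conc_ns = v[-4:]
        g_s = eps_s[self.pm_trip] @ w
        g_s = g_s - np.where(self.is_mm,
                             penalty[self.center_trip, self.alt_idx], 0.0)
        g_ns = eps_ns[self.probe_trip] @ w
        log_num = np.logaddexp(alpha * g_s, alpha * g_ns + np.log(conc_ns))
        log_den = np.logaddexp(np.logaddexp(0.0, alpha * self.folding),
                               log_num)
        pred = np.logaddexp(np.log(a_scale) + log_num - log_den,
                            np.log(background))
        return pred - self.obs_log

    def __call__(self, x: np.ndarray) -> float:
        r = self.residuals(x)
        val = float(r @ r)
        if not np.isfinite(val):
            logger.debug("discarding candidate with non-finite objective")
            return 1e300
        return val


def objective(model: EnergyModel, design: TilingDesign,
              observed_wt: IntensityTable,
              folding: np.ndarray | None = None) -> float:
    """Residual sum of squares of log intensities over the whole design."""
    predictor = DesignPredictor(model, design, folding)
    obs = np.log(observed_wt.aligned(design))
    r = obs - predictor.ref_log_intensity
    return float(r @ r)


def heuristic_init(design: TilingDesign, observed_wt: IntensityTable,
                   config: FitConfig) -> EnergyModel:
    """Data-driven starting point: background and scale from the observed
    intensity range, flat energies, tent-shaped position weights."""
    vals = observed_wt.values.to_numpy()
    b = config.bounds
    background = float(np.clip(0.8 * vals.min(), *b["background"]))
    scale = float(np.clip(2.0 * (vals.max() - background),
                          *b["intensity_scale"]))
    k = np.arange(N_WEIGHTS)
    weights = np.clip(1.0 - 0.8 * np.abs(k - N_WEIGHTS // 2)
                      / (N_WEIGHTS // 2), *b["weights"])
    return EnergyModel(
        eps_specific=np.full(64, 0.4), eps_nonspecific=np.full(64, 0.15),
        penalty=np.full((64, 3), 1.5), weights=weights,
        alpha=1.0, intensity_scale=scale, background=background,
        conc_nonspecific=0.02)


def fit_parameters(design: TilingDesign, observed_wt: IntensityTable,
                   config: FitConfig, init: EnergyModel | None = None,
                   folding: np.ndarray | None = None
                   ) -> tuple[EnergyModel, FitDiagnostics]:
    """Fit the 343 parameters to observed wild-type log intensities.

    Runs a seeded differential-evolution population stage over the full
    parameter vector, then (by default) polishes the best member with a
    bounded trust-region least-squares refinement.  ``subset_fraction``
    fits on a seeded uniform probe subset, which is how genome-scale
    designs stay tractable.
    """
    rng = np.random.default_rng(config.seed)
    n_total = len(design)
    if folding is None:
        folding = folding_energies(design.probe_codes())
    if config.subset_fraction < 1.0:
        n_fit = max(int(round(config.subset_fraction * n_total)), 500)
        idx = np.sort(rng.choice(n_total, size=min(n_fit, n_total),
                                 replace=False))
    else:
        idx = np.arange(n_total)
    fun = _Objective(design, observed_wt, folding, idx)

    lo, hi = _search_bounds(config)
    x0 = _to_search((init or heuristic_init(design, observed_wt,
                                            config)).to_vector())
    x0 = np.clip(x0, lo, hi)

    pop = rng.uniform(lo, hi, size=(config.population_size, N_PARAMETERS))
    pop[0] = x0

    trajectory = []
    best_seen = [np.inf]
    stall = [0]

    def callback(xk, convergence=None):
        val = fun(xk)
        improved = best_seen[0] - val > config.tolerance
        trajectory.append(min(val, best_seen[0]))
        best_seen[0] = min(val, best_seen[0])
        stall[0] = 0 if improved else stall[0] + 1
        return stall[0] >= config.patience

    result = differential_evolution(
        fun, bounds=list(zip(lo, hi)), init=pop,
        maxiter=config.generations, tol=0, seed=config.seed,
        polish=False, callback=callback)
    x_best = np.clip(result.x, lo, hi)

    if config.polish:
        # the trust-region refinement is basin-sensitive, so polish both
        # the population's best member and the deterministic start
        starts = [x_best]
        if not np.allclose(x_best, x0):
            starts.append(x0)
        for start in starts:
            ls = least_squares(
                lambda x: np.nan_to_num(fun.residuals(x), nan=1e6,
                                        posinf=1e6, neginf=-1e6),
                start, bounds=(lo, hi), method="trf", x_scale="jac",
                max_nfev=config.polish_max_nfev)
            if fun(ls.x) < fun(x_best):
                x_best = ls.x
        trajectory.append(min(fun(x_best), best_seen[0]))

    final = fun(x_best)
    model = EnergyModel.from_vector(_from_search(x_best))
    diag = FitDiagnostics(
        objective=final,
        rmse=float(np.sqrt(final / fun.n)),
        trajectory=np.minimum.accumulate(np.array(trajectory))
        if trajectory else np.array([final]),
        generations_run=int(result.nit),
        seed=config.seed,
        n_probes_fit=fun.n,
        n_probes_total=n_total,
    )
    logger.info("fit finished: objective %.4g, rmse %.4g over %d probes",
                final, diag.rmse, fun.n)
    return model, diag
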