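"""Model/Results front end for the finite-hybridization intensity model.

``FiniteHybridizationModel`` bundles the data of one fitting problem (a
tiling design, observed wild-type intensities and per-probe folding
energies); ``fit()`` returns a ``FHResults`` object carrying the fitted
energy parameters, fit diagnostics and a text summary, from which
prediction, simulation and substitution calling hang off.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import detection, evaluate, fitting, simulate
from .design import TilingDesign, read_design_tsv
from .detection import IntensityTable
from .thermo import DesignPredictor, EnergyModel, folding_energies


class FiniteHybridizationModel:
    """A fitting problem: design + observed reference-sample intensities."""

    def __init__(self, design: TilingDesign, observed: IntensityTable,
                 folding: np.ndarray | None = None):
        self.design = design
        self.observed = observed
        if folding is None:
            folding = folding_energies(design.probe_codes())
        self.folding = np.asarray(folding, dtype=float)
        # validates completeness up front
        observed.aligned(design)

    @classmethod
    def from_tables(cls, design_tsv, intensity_tsv,
                    folding_tsv=None) -> "FiniteHybridizationModel":
        from .io import read_folding_tsv
        design = read_design_tsv(design_tsv)
        observed = IntensityTable.from_tsv(intensity_tsv, "wt")
        folding = (read_folding_tsv(folding_tsv, design)
                   if folding_tsv else None)
        return cls(design, observed, folding)

    def objective(self, params: EnergyModel) -> float:
        return fitting.objective(params, self.design, self.observed,
                                 self.folding)

    def fit(self, config: fitting.FitConfig | None = None,
            init: EnergyModel | None = None, *, seed: int | None = None,
            **kwargs) -> "FHResults":
        if config is None:
            if seed is None:
                raise ValueError("provide a FitConfig or a seed")
            config = fitting.FitConfig(seed=seed, **kwargs)
        params, diag = fitting.fit_parameters(
            self.design, self.observed, config, init=init,
            folding=self.folding)
        return FHResults(self, params, diag)

    def results(self, params: EnergyModel) -> "FHResults":
        """Wrap externally obtained parameters (e.g. a known true model)."""
        return FHResults(self, params, None)


class FHResults:
    """Fitted finite-hybridization model tied to its data."""

    def __init__(self, model: FiniteHybridizationModel, params: EnergyModel,
                 diagnostics: Optional[fitting.FitDiagnostics]):
        self.model = model
        self.params = params
        self.diagnostics = diagnostics
        self._predictor: DesignPredictor | None = None

    @property
    def predictor(self) -> DesignPredictor:
        if self._predictor is None:
            self._predictor = DesignPredictor(self.params, self.model.design,
                                              self.model.folding)
        return self._predictor

    # ------------------------------------------------------------------
    def predict(self) -> np.ndarray:
        """Predicted log intensities of every design probe (reference)."""
        return self.predictor.ref_log_intensity

    @property
    def rmse(self) -> float:
        obs = np.log(self.model.observed.aligned(self.model.design))
        return float(np.sqrt(np.mean((obs - self.predict()) ** 2)))

    def simulate(self, genome_variant: str | None = None,
                 noise_sd: float = 0.0, seed: int = 0,
                 deletions: Sequence[tuple[int, int]] = (),
                 sample_id: str = "sim") -> IntensityTable:
        variant = genome_variant or self.model.design.genome_sequence
        return simulate.simulate_intensities(
            self.params, self.model.design, variant, self.model.folding,
            noise_sd, seed, deletions, sample_id)

    # ------------------------------------------------------------------
    def residual_profile(self, mut: IntensityTable,
                         window: int = detection.DEFAULT_WINDOW,
                         k_sd: float = detection.DEFAULT_K_SD
                         ) -> detection.ResidualProfile:
        return detection.residual_profile(
            self.params, self.model.design, self.model.observed, mut,
            window, k_sd, self.model.folding)

    def call_substitutions(self, mut: IntensityTable, theta_L: float,
                           window: int = detection.DEFAULT_WINDOW,
                           k_sd: float = detection.DEFAULT_K_SD):
        """(calls, regions, profile) for a mutant sample vs this model."""
        profile = self.residual_profile(mut, window, k_sd)
        regions = detection.screen_candidate_regions(profile)
        calls = detection.call_substitutions(
            self.params, self.model.design, self.model.observed, mut,
            regions, theta_L, predictor=self.predictor)
        return calls, regions, profile

    # ------------------------------------------------------------------
    def summary(self) -> str:
        lines = ["Finite-hybridization model fit",
                 "=" * 46]
        d = self.model.design
        lines.append(f"{'Genome':<28}{d.genome_id} "
                     f"({d.genome_length:,} bp, "
                     f"{'circular' if d.circular else 'linear'})")
        lines.append(f"{'Probes in design':<28}{len(d):,} "
                     f"(resolution {d.resolution} bp)")
        lines.append(f"{'Free parameters':<28}{self.params.n_parameters}")
        if self.diagnostics is not None:
            g = self.diagnostics
            lines.append(f"{'Probes used in fit':<28}{g.n_probes_fit:,}")
            lines.append(f"{'Objective (RSS, log units)':<28}"
                         f"{g.objective:.6g}")
            lines.append(f"{'Fit RMSE (log units)':<28}{g.rmse:.6g}")
            lines.append(f"{'Generations run':<28}{g.generations_run}")
            lines.append(f"{'Seed':<28}{g.seed}")
        lines.append("-" * 46)
        p = self.params
        rows = [
            ("specific energies (64)", p.eps_specific),
            ("non-specific energies (64)", p.eps_nonspecific),
            ("mismatch penalties (192)", p.penalty.ravel()),
            ("position weights (19)", p.weights),
        ]
        lines.append(f"{'parameter group':<28}{'min':>8}{'mean':>8}"
                     f"{'max':>8}")
        for name, arr in rows:
            lines.append(f"{name:<28}{arr.min():>8.3f}{arr.mean():>8.3f}"
                         f"{arr.max():>8.3f}")
        for name, val in (("alpha", p.alpha),
                          ("intensity scale A", p.intensity_scale),
                          ("background B", p.background),
                          ("non-specific conc C_ns", p.conc_nonspecific)):
            lines.append(f"{name:<28}{val:>8.4g}")
        return "\n".join(lines)
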