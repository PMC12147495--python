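"""Model / Results interface over the sub-dataset ensemble pipeline.

`VariabilityEnsembleModel` is constructed from a :class:`MaterialDataset`
plus a feature combination and run settings; ``fit(seed)`` executes the
whole pipeline (featurize -> resample N sub-datasets -> nested-CV model
selection per sub-dataset -> per-material out-of-fold estimate vectors)
and returns a :class:`VariabilityResults` carrying the estimates, the
fitted measured/predicted Gaussians, per-material Jensen-Shannon
divergences, the aggregate (D_JS, r^2) pair, and plotting helpers.

Example
-------
>>> from bonevar import SyntheticConfig, generate_synthetic_dataset
>>> from bonevar import VariabilityEnsembleModel, fast_zoo, default_band_config
>>> dataset, truth = generate_synthetic_dataset(SyntheticConfig(seed=1))
>>> bands = default_band_config()
>>> model = VariabilityEnsembleModel(dataset, combo="E", zoo=fast_zoo(),
...                                  n_subdatasets=20, ftir_bands=bands["ftir"],
...                                  xrd_bands=bands["xrd"])
>>> res = model.fit(seed=1)
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MaterialDataset, MethodCombo
from .ensemble import EnsemblePrediction, ModelZoo, default_zoo, predict_ensemble
from .evaluation import (
    IntegrationGrid,
    MethodEvaluation,
    evaluate_method,
    rectangle_summary,
)
from .features import BandList

__all__ = ["VariabilityEnsembleModel", "VariabilityResults"]


class VariabilityEnsembleModel:
    """Predict the distribution (mean and spread) of a repeated response.

    Parameters
    ----------
    dataset : MaterialDataset
        Materials with base features, repeated measurements and optional
        spectra / images.
    combo : str or MethodCombo
        Which feature blocks enter X ("A" = base only .. "H" = all).
    zoo : ModelZoo, optional
        Candidate regressors; defaults to the full 13-method zoo.
    n_subdatasets : int
        Number of resampled sub-datasets (= estimates per material).
    inner_folds, outer_folds : int
        Nested cross-validation configuration; selection happens on the
        inner folds, estimates come from the outer held-out folds.
    ftir_bands, xrd_bands : BandList, optional
        Band positions for the spectral blocks (required when the combo
        uses them).
    log_base : "e" or "2"
        Log base for the divergences (nats or bits).
    """

    def __init__(
        self,
        dataset: MaterialDataset,
        combo: str | MethodCombo = "A",
        zoo: ModelZoo | None = None,
        n_subdatasets: int = 100,
        inner_folds: int = 5,
        outer_folds: int = 10,
        ftir_bands: BandList | None = None,
        xrd_bands: BandList | None = None,
        lbp_normalize: bool = True,
        impute_components: int = 1,
        log_base: str = "e",
        grid: IntegrationGrid | None = None,
    ) -> None:
        self.dataset = dataset
        self.combo = combo if isinstance(combo, MethodCombo) else MethodCombo.from_label(combo)
        self.zoo = zoo or default_zoo()
        self.n_subdatasets = n_subdatasets
        self.inner_folds = inner_folds
        self.outer_folds = outer_folds
        self.ftir_bands = ftir_bands
        self.xrd_bands = xrd_bands
        self.lbp_normalize = lbp_normalize
        self.impute_components = impute_components
        self.log_base = log_base
        self.grid = grid

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, combo: str | MethodCombo = "A", **kwargs
    ) -> "VariabilityEnsembleModel":
        """Build from a long-format frame (material_id, measurement, features)."""
        from .data import MaterialSample

        required = {"material_id", "measurement"}
        if not required.issubset(frame.columns):
            raise ValueError(f"frame must have columns {sorted(required)}")
        feature_names = [c for c in frame.columns if c not in required]
        samples = []
        for mid, grp in frame.groupby("material_id", sort=False):
            feats = {c: float(grp[c].iloc[0]) for c in feature_names}
            samples.append(
                MaterialSample(str(mid), feats, grp["measurement"].astype(float).tolist())
            )
        dataset = MaterialDataset(samples=samples, feature_names=feature_names)
        return cls(dataset, combo=combo, **kwargs)

    def fit(self, seed: int = 0) -> "VariabilityResults":
        """Run the pipeline and score it; deterministic given ``seed``."""
        prediction = predict_ensemble(
            self.dataset,
            self.combo,
            self.zoo,
            n_subdatasets=self.n_subdatasets,
            inner_folds=self.inner_folds,
            outer_folds=self.outer_folds,
            seed=seed,
            ftir_bands=self.ftir_bands,
            xrd_bands=self.xrd_bands,
            lbp_normalize=self.lbp_normalize,
            impute_components=self.impute_components,
        )
        evaluation = evaluate_method(
            self.dataset,
            prediction,
            combo_label=self.combo.label,
            grid=self.grid,
            base=self.log_base,
        )
        return VariabilityResults(model=self, prediction=prediction, evaluation=evaluation, seed=seed)


@dataclass
class VariabilityResults:
    """Fitted ensemble: estimates, Gaussians, divergences, diagnostics."""

    model: VariabilityEnsembleModel
    prediction: EnsemblePrediction
    evaluation: MethodEvaluation
    seed: int

    # -- headline numbers ------------------------------------------------
    @property
    def aggregate_d_js(self) -> float:
        return self.evaluation.aggregate_d_js

    @property
    def r_squared(self) -> float:
        return self.evaluation.r_squared

    @property
    def d_js(self) -> pd.Series:
        return pd.Series(self.evaluation.d_js_by_material, name="d_js")

    @property
    def estimates(self) -> pd.DataFrame:
        """Rows = materials, columns = sub-datasets."""
        return self.prediction.to_frame()

    @property
    def n_models_fitted(self) -> int:
        return self.prediction.n_models_fitted

    def per_material_frame(self) -> pd.DataFrame:
        """Tidy per-material report of fitted Gaussians and D_JS."""
        rows = []
        for m in self.evaluation.per_material:
            rows.append(
                {
                    "material_id": m.material_id,
                    "measured_mean": m.measured.mean,
                    "measured_sd": m.measured.sd,
                    "n_measurements": m.measured.n,
                    "sd_substituted": m.measured.sd_substituted,
                    "predicted_mean": m.predicted.mean,
                    "predicted_sd": m.predicted.sd,
                    "d_js": m.d_js,
                }
            )
        return pd.DataFrame(rows).set_index("material_id")

    def rectangles(self, spread_multiplier: float = 2.0) -> pd.DataFrame:
        """Dispersion rectangles (measured width vs predicted height)."""
        return pd.DataFrame(
            rectangle_summary(self.model.dataset, self.prediction, spread_multiplier)
        ).set_index("material_id")

    def chosen_method_counts(self) -> pd.Series:
        flat = [m for sub in self.prediction.chosen_methods for m in sub]
        return pd.Series(flat, name="method").value_counts()

    def summary(self) -> str:
        """Plain-text summary table in the statsmodels spirit."""
        per = self.per_material_frame()
        unit = "nats" if self.model.log_base == "e" else "bits"
        lines = [
            "Sub-dataset ensemble variability results",
            "=" * 56,
            f"Feature combo:        {self.evaluation.combo_label} "
            f"(FT-IR={self.model.combo.use_ftir}, XRD={self.model.combo.use_xrd}, "
            f"SEM={self.model.combo.use_sem})",
            f"Materials:            {len(per)}",
            f"Sub-datasets:         {self.prediction.n_subdatasets}",
            f"Models fitted:        {self.n_models_fitted} "
            f"({self.prediction.n_subdatasets} sub-datasets x "
            f"{self.model.outer_folds} outer folds)",
            f"Seed:                 {self.seed}",
            "-" * 56,
            f"Aggregate D_JS:       {self.aggregate_d_js:.4f} {unit} (mean over materials)",
            f"r^2 of means:         {self.r_squared:.4f}",
            f"D_JS range:           [{per.d_js.min():.4f}, {per.d_js.max():.4f}]",
            f"SD-substituted:       {int(per.sd_substituted.sum())} materials (n <= 2)",
            "-" * 56,
            "Method selection counts:",
        ]
        for name, cnt in self.chosen_method_counts().items():
            lines.append(f"  {name:<16} {cnt}")
        return "\n".join(lines)

    # -- plots -----------------------------------------------------------
    def plot_mean_scatter(self, ax=None, spread_multiplier: float = 2.0):
        from .plots import mean_scatter_with_rectangles

        return mean_scatter_with_rectangles(self, ax=ax, spread_multiplier=spread_multiplier)

    def plot_distributions(self, ax=None):
        from .plots import paired_strip_plot

        return paired_strip_plot(self, ax=ax)

    def plot_d_js(self, ax=None):
        from .plots import d_js_bar_chart

        return d_js_bar_chart(self, ax=ax)
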