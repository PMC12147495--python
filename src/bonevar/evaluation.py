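"""Distributional scoring of predictions against repeated measurements.

Both the measured values of a material (its repeated animal experiments)
and the predicted values (one estimate per sub-dataset model) are
summarised as normal distributions. Prediction quality per material is
the Jensen-Shannon divergence between the two fitted Gaussians,

    D_KL(P||Q) = integral p(x) log(p(x)/q(x)) dx
    D_JS(P,Q)  = [ D_KL(P||M) + D_KL(Q||M) ] / 2,   M = (P+Q)/2,

evaluated numerically because the JS divergence between Gaussians has no
closed form (the mixture M is not Gaussian). In natural log D_JS lies in
[0, ln 2]; 0 means identical distributions. The conventional r^2 on
per-material means is reported alongside as the mean-accuracy metric.

Materials measured only once or twice cannot yield a meaningful sample
SD, so their measured-distribution SD is substituted by the average of
the sample SDs of materials with three or more measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GaussianSummary",
    "MaterialEvaluation",
    "MethodEvaluation",
    "IntegrationGrid",
    "fit_gaussian_measured",
    "compute_fallback_sd",
    "fit_gaussian_predicted",
    "kl_divergence",
    "js_divergence",
    "r_squared_of_means",
    "evaluate_method",
    "rectangle_summary",
]

_DENSITY_FLOOR = 1e-300


class DegenerateDistributionError(ValueError):
    """Three or more identical measurements give a zero sample SD."""


class FallbackUndefinedError(ValueError):
    """No material has >= 3 measurements, so no fallback SD exists."""


@dataclass(frozen=True)
class GaussianSummary:
    """Fitted normal for measured or predicted values (percent units)."""

    mean: float
    sd: float
    n: int
    sd_substituted: bool = False  # measured-side fallback-SD rule applied
    sd_floored: bool = False  # predicted-side zero-variance floor applied

    def __post_init__(self) -> None:
        if not (self.sd > 0):
            raise ValueError(f"sd must be positive, got {self.sd}")
        if self.sd_substituted and self.n > 2:
            raise ValueError("sd_substituted only applies to n <= 2")


@dataclass(frozen=True)
class IntegrationGrid:
    """Uniform trapezoidal grid spanning both distributions' support.

    The grid covers [min(mu) - pad*max(sd), max(mu) + pad*max(sd)]; with
    the default pad of 10 SDs and 20001 points the numerical KL agrees
    with the closed-form Gaussian KL to well below 1e-6.
    """

    n_points: int = 20001
    pad_sds: float = 10.0

    def build(self, p: GaussianSummary, q: GaussianSummary) -> np.ndarray:
        lo = min(p.mean, q.mean) - self.pad_sds * max(p.sd, q.sd)
        hi = max(p.mean, q.mean) + self.pad_sds * max(p.sd, q.sd)
        return np.linspace(lo, hi, self.n_points)


def _normal_logpdf(x: np.ndarray, g: GaussianSummary) -> np.ndarray:
    # analytic log-density: immune to float underflow far in the tails
    z = (x - g.mean) / g.sd
    return -0.5 * z * z - np.log(g.sd) - 0.5 * np.log(2.0 * np.pi)


def fit_gaussian_measured(measurements, fallback_sd: float | None = None) -> GaussianSummary:
    """Fit a normal to a material's repeated measurements.

    With n >= 3 the sample SD (n-1 denominator) is used; with n <= 2 the
    SD is replaced by ``fallback_sd`` (the cross-material average SD, see
    :func:`compute_fallback_sd`) and flagged as substituted.
    """
    y = np.asarray(measurements, dtype=float)
    if y.size == 0:
        raise ValueError("measurements must be non-empty")
    mean = float(y.mean())
    if y.size <= 2:
        if fallback_sd is None or not fallback_sd > 0:
            raise ValueError("fallback_sd > 0 required for materials with <= 2 measurements")
        return GaussianSummary(mean=mean, sd=float(fallback_sd), n=int(y.size), sd_substituted=True)
    sd = float(y.std(ddof=1))
    if sd == 0:
        raise DegenerateDistributionError("zero sample SD with n >= 3 measurements")
    return GaussianSummary(mean=mean, sd=sd, n=int(y.size))


def compute_fallback_sd(dataset) -> float:
    """Average sample SD over materials with >= 3 measurements."""
    sds = [
        float(np.std(s.measurements, ddof=1))
        for s in dataset.samples
        if len(s.measurements) >= 3
    ]
    if not sds:
        raise FallbackUndefinedError("no material has 3 or more measurements")
    return float(np.mean(sds))


def fit_gaussian_predicted(estimates, sd_floor: float = 1e-6) -> GaussianSummary:
    """Fit a normal to the vector of per-sub-dataset estimates."""
    y = np.asarray(estimates, dtype=float)
    if y.size < 2:
        raise ValueError("at least 2 estimates required")
    sd = float(y.std(ddof=1))
    floored = sd < sd_floor
    return GaussianSummary(
        mean=float(y.mean()), sd=max(sd, sd_floor), n=int(y.size), sd_floored=floored
    )


def kl_divergence(
    p: GaussianSummary, q: GaussianSummary, grid: IntegrationGrid | None = None
) -> float:
    """Numerical KL divergence between two fitted Gaussians (nats)."""
    grid = grid or IntegrationGrid()
    x = grid.build(p, q)
    log_p = _normal_logpdf(x, p)
    log_q = _normal_logpdf(x, q)
    px = np.exp(log_p)
    integrand = np.where(px > _DENSITY_FLOOR, px * (log_p - log_q), 0.0)
    return max(float(np.trapezoid(integrand, x)), 0.0)


def js_divergence(
    p: GaussianSummary,
    q: GaussianSummary,
    grid: IntegrationGrid | None = None,
    base: str = "e",
) -> float:
    """Numerical JS divergence between two fitted Gaussians.

    The mixture density m = (p + q)/2 is evaluated pointwise on a grid
    shared by both KL terms. Bounded by ln 2 (or 1 for ``base="2"``).
    """
    grid = grid or IntegrationGrid()
    x = grid.build(p, q)
    log_p = _normal_logpdf(x, p)
    log_q = _normal_logpdf(x, q)
    # log of the pointwise mixture density m = (p + q) / 2
    log_m = np.logaddexp(log_p, log_q) - np.log(2.0)
    px, qx = np.exp(log_p), np.exp(log_q)
    kl_pm = np.where(px > _DENSITY_FLOOR, px * (log_p - log_m), 0.0)
    kl_qm = np.where(qx > _DENSITY_FLOOR, qx * (log_q - log_m), 0.0)
    val = 0.5 * (float(np.trapezoid(kl_pm, x)) + float(np.trapezoid(kl_qm, x)))
    val = max(val, 0.0)
    if base == "2":
        val /= np.log(2.0)
    elif base != "e":
        raise ValueError("base must be 'e' (nats) or '2' (bits)")
    return val


def gaussian_kl_closed_form(p: GaussianSummary, q: GaussianSummary) -> float:
    """Closed-form Gaussian KL: ln(s2/s1) + (s1^2 + (m1-m2)^2)/(2 s2^2) - 1/2.

    Exists only for the plain KL (not JS); used as an independent check
    of the numerical integration.
    """
    return float(
        np.log(q.sd / p.sd) + (p.sd**2 + (p.mean - q.mean) ** 2) / (2.0 * q.sd**2) - 0.5
    )


def r_squared_of_means(measured_means, predicted_means) -> float:
    """Coefficient of determination of predicted vs measured means.

    1 - SS_res/SS_tot about the measured mean; negative when predictions
    are worse than the constant-mean baseline.
    """
    m = np.asarray(measured_means, dtype=float)
    p = np.asarray(predicted_means, dtype=float)
    if m.shape != p.shape or m.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 means")
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("measured means are all equal; r^2 undefined")
    ss_res = float(np.sum((m - p) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class MaterialEvaluation:
    material_id: str
    measured: GaussianSummary
    predicted: GaussianSummary
    d_js: float


@dataclass
class MethodEvaluation:
    """Per-material D_JS plus the (aggregate D_JS, r^2) pair for one combo."""

    combo_label: str
    per_material: list[MaterialEvaluation]
    aggregate_d_js: float
    r_squared: float

    @property
    def d_js_by_material(self) -> dict[str, float]:
        return {m.material_id: m.d_js for m in self.per_material}


def evaluate_method(
    dataset,
    prediction,
    combo_label: str = "?",
    grid: IntegrationGrid | None = None,
    base: str = "e",
) -> MethodEvaluation:
    """Score an ensemble prediction against the measured distributions.

    ``prediction`` is an EnsemblePrediction (or anything with an
    ``estimates`` mapping material_id -> vector). Aggregate D_JS is the
    arithmetic mean over materials; r^2 compares per-material measured
    and predicted means.
    """
    fallback = compute_fallback_sd(dataset)
    per_material: list[MaterialEvaluation] = []
    measured_means, predicted_means = [], []
    for s in dataset.samples:
        est = np.asarray(prediction.estimates[s.material_id], dtype=float)
        p_meas = fit_gaussian_measured(s.measurements, fallback_sd=fallback)
        p_pred = fit_gaussian_predicted(est)
        d = js_divergence(p_meas, p_pred, grid=grid, base=base)
        per_material.append(MaterialEvaluation(s.material_id, p_meas, p_pred, d))
        measured_means.append(p_meas.mean)
        predicted_means.append(p_pred.mean)
    return MethodEvaluation(
        combo_label=combo_label,
        per_material=per_material,
        aggregate_d_js=float(np.mean([m.d_js for m in per_material])),
        r_squared=r_squared_of_means(measured_means, predicted_means),
    )


def rectangle_summary(dataset, prediction, spread_multiplier: float = 2.0):
    """Per-material dispersion rectangles for the mean-vs-mean scatter.

    Width = spread of the measured values, height = spread of the
    predicted values (both ``spread_multiplier`` x SD); an aspect ratio
    (height/width) near 1 means the variability was predicted well.
    Returns a list of dicts per material.
    """
    fallback = compute_fallback_sd(dataset)
    rows = []
    for s in dataset.samples:
        est = np.asarray(prediction.estimates[s.material_id], dtype=float)
        p_meas = fit_gaussian_measured(s.measurements, fallback_sd=fallback)
        p_pred = fit_gaussian_predicted(est)
        width = spread_multiplier * p_meas.sd
        height = spread_multiplier * p_pred.sd
        rows.append(
            {
                "material_id": s.material_id,
                "mean_x": p_meas.mean,
                "mean_y": p_pred.mean,
                "width": width,
                "height": height,
                "aspect_ratio": height / width,
            }
        )
    return rows
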