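"""Synthetic datasets with the statistical structure the method assumes.

The generator emulates a 38-material artificial-bone study: each
material has a latent two-phase composition (a hydroxyapatite-like and a
beta-TCP-like calcium-phosphate phase) and a latent crystallinity. The
composition drives the true mean bone formation rate; the crystallinity
drives the material-specific measurement SD (heteroscedastic noise,
independent of the mean). Both latents are expressed in the observable
blocks:

* FT-IR and XRD traces are sums of Gaussian peaks at fixed
  phase-signature positions whose areas follow the phase fractions and
  whose widths narrow with crystallinity, plus baseline and noise —
  so band intensities at the signatures carry both latents;
* images are Gaussian-filtered noise textures whose correlation length
  follows crystallinity, so LBP histograms carry it too;
* base features (synthesis temperature, reagent amount, ...) are only
  weakly tied to composition, mimicking a study where the short-time
  spectral measurements are far more informative than the synthesis log.

Repeated measurements are drawn i.i.d. from N(true mean, true SD) with a
configured count histogram (by default 17 of 38 materials are measured
once). Ground truth (true mean, true SD, latents) is returned separately
so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .data import MaterialDataset, MaterialSample
from .features import BandList

__all__ = [
    "SyntheticConfig",
    "FTIR_SIGNATURES",
    "XRD_SIGNATURES",
    "default_band_config",
    "generate_synthetic_dataset",
    "generate_null_dataset",
]

# Phase-signature positions for the two calcium-phosphate-like phases.
# FT-IR (wavenumber, cm^-1): phosphate nu4 / nu3 / nu1 regions.
FTIR_SIGNATURES = {
    "phase1": (565.0, 602.0, 1025.0, 1090.0),  # hydroxyapatite-like
    "phase2": (552.0, 945.0, 972.0, 1120.0),  # beta-TCP-like
}
# XRD (2-theta, degrees): strongest reflections of each phase.
XRD_SIGNATURES = {
    "phase1": (25.9, 31.8, 32.9),
    "phase2": (27.8, 31.0, 34.4),
}


def default_band_config(window_ftir: float = 6.0, window_xrd: float = 0.3):
    """Band lists matching the generator's phase signatures.

    Returns ``{"ftir": BandList, "xrd": BandList}``; in a real study
    these would be the instrument-specific HAp / beta-TCP band
    positions, supplied in the run configuration.
    """
    ftir = sorted(FTIR_SIGNATURES["phase1"] + FTIR_SIGNATURES["phase2"])
    xrd = sorted(XRD_SIGNATURES["phase1"] + XRD_SIGNATURES["phase2"])
    return {
        "ftir": BandList(ftir, window=window_ftir),
        "xrd": BandList(xrd, window=window_xrd),
    }


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    n_materials: int = 38
    # measurement-count histogram: count -> number of materials
    count_histogram: dict[int, int] = field(
        default_factory=lambda: {1: 17, 2: 2, 3: 3, 4: 4, 5: 6, 6: 6}
    )
    n_base_features: int = 5
    noise_sd_range: tuple[float, float] = (2.0, 12.0)  # percent units
    # How the material-specific measurement SD arises:
    #   "composition"    — grows with the distance of the phase fraction
    #                      from the balanced mixture (default: near-pure
    #                      phases respond less reproducibly in vivo);
    #                      symmetric in c, hence uncorrelated with the
    #                      monotone mean trend, but expressed in the
    #                      phase-signature bands.
    #   "crystallinity"  — linear in the crystallinity latent.
    #   "independent"    — drawn i.i.d., unpredictable from any feature.
    #   "mean"           — increases with the true mean.
    sd_link: str = "composition"
    # response model for the true mean as a function of composition c:
    #   "saturating" — sigmoidal dose-response
    #                  intercept + span / (1 + exp(-steepness*(c - 0.5)))
    #   "quadratic"  — intercept + linear*c + quad*c^2
    mean_shape: str = "saturating"
    mean_intercept: float = 20.0
    mean_span: float = 55.0
    mean_steepness: float = 8.0
    mean_linear: float = 50.0
    mean_quad: float = 10.0
    base_feature_snr: float = 0.5  # weak composition signal in base features
    ftir_axis: tuple[float, float, float] = (400.0, 2000.0, 2.0)  # start, stop, step
    xrd_axis: tuple[float, float, float] = (10.0, 60.0, 0.05)
    spectrum_noise_sd: float = 0.01
    image_size: int = 64
    image_missing_fraction: float = 0.0  # fraction of materials without an image
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.count_histogram.values()) != self.n_materials:
            raise ValueError(
                f"count histogram sums to {sum(self.count_histogram.values())}, "
                f"expected n_materials={self.n_materials}"
            )
        lo, hi = self.noise_sd_range
        if not (0 <= lo <= hi):
            raise ValueError("noise_sd_range must satisfy 0 <= low <= high")
        if any(c < 1 for c in self.count_histogram):
            raise ValueError("measurement counts must be >= 1")
        if self.sd_link not in ("composition", "crystallinity", "independent", "mean"):
            raise ValueError(f"unknown sd_link {self.sd_link!r}")
        if self.mean_shape not in ("saturating", "quadratic"):
            raise ValueError(f"unknown mean_shape {self.mean_shape!r}")


def _peak(axis: np.ndarray, centre: float, area: float, width: float) -> np.ndarray:
    return area * np.exp(-0.5 * ((axis - centre) / width) ** 2) / (width * np.sqrt(2 * np.pi))


def _spectrum(axis, signatures, frac1, crystallinity, rng, noise_sd, width0,
              crystallinity_scales_area: bool = False):
    """Two-phase peak spectrum; widths narrow as crystallinity grows.

    For diffraction (``crystallinity_scales_area``) the integrated peak
    intensity also grows mildly with crystallinity, as amorphous content
    diffracts weakly. Both crystallinity effects are kept mild so that
    the band features are dominated by the phase composition; texture
    images carry the stronger crystallinity signal.
    """
    width = width0 * (1.3 - 0.1 * crystallinity)  # slightly sharper when crystalline
    area_scale = (0.9 + 0.1 * crystallinity) if crystallinity_scales_area else 1.0
    y = np.zeros_like(axis)
    for pos in signatures["phase1"]:
        y += _peak(axis, pos, area=(1.0 - frac1) * width0 * area_scale, width=width)
    for pos in signatures["phase2"]:
        y += _peak(axis, pos, area=frac1 * width0 * area_scale, width=width)
    baseline = 0.02 + 0.01 * (axis - axis[0]) / (axis[-1] - axis[0])
    return y + baseline + rng.normal(0.0, noise_sd, size=axis.shape)


def _texture(size: int, crystallinity: float, rng) -> np.ndarray:
    """Filtered-noise texture; grain scale follows crystallinity."""
    sigma = 0.5 + 3.0 * crystallinity
    img = gaussian_filter(rng.normal(size=(size, size)), sigma=sigma)
    img = (img - img.min()) / (img.max() - img.min() + 1e-12)
    return 255.0 * img


def _base_features(c: np.ndarray, u: np.ndarray, snr: float, rng) -> np.ndarray:
    """Weakly informative synthesis/experiment features (one row per material)."""
    n = len(c)
    temp = 900.0 + 80.0 * snr * c + rng.normal(0, 60, n)  # heating temperature, C
    reagent = 10.0 + 2.0 * snr * (1 - c) + rng.normal(0, 1.5, n)  # Ca reagent, g
    beads = np.clip(0.15 + 0.1 * snr * u + rng.normal(0, 0.08, n), 0, None)  # carbon beads
    weeks = rng.choice([12.0, 24.0], size=n)  # implantation duration
    density = 70.0 + 10.0 * snr * c + rng.normal(0, 8, n)  # relative density, %
    return np.column_stack([temp, reagent, beads, weeks, density])


_BASE_FEATURE_NAMES = [
    "heating_temp_c",
    "reagent_ca_g",
    "carbon_beads_g",
    "implant_weeks",
    "relative_density_pct",
]


def _build(config: SyntheticConfig, null_response: bool):
    rng = np.random.default_rng(config.seed)
    n = config.n_materials

    c = rng.uniform(0.0, 1.0, n)  # phase-2 fraction (composition latent)
    u = rng.uniform(0.0, 1.0, n)  # crystallinity latent, independent of c

    if config.mean_shape == "saturating":
        true_mean = config.mean_intercept + config.mean_span / (
            1.0 + np.exp(-config.mean_steepness * (c - 0.5))
        )
    else:
        true_mean = config.mean_intercept + config.mean_linear * c + config.mean_quad * c**2
    true_mean = np.clip(true_mean, 0.0, 100.0)
    if null_response:
        # response decoupled from every feature-driving latent
        true_mean = rng.uniform(true_mean.min(), true_mean.max(), n)
    lo, hi = config.noise_sd_range
    if null_response or config.sd_link == "independent":
        true_sd = rng.uniform(lo, hi, n)
    elif config.sd_link == "composition":
        true_sd = lo + (hi - lo) * np.abs(2.0 * c - 1.0)
    elif config.sd_link == "crystallinity":
        true_sd = lo + (hi - lo) * u
    else:  # "mean"
        span = true_mean.max() - true_mean.min() + 1e-12
        true_sd = lo + (hi - lo) * (true_mean - true_mean.min()) / span

    # assign measurement counts per the configured histogram, shuffled
    counts = np.array(
        [k for k, m in sorted(config.count_histogram.items()) for _ in range(m)]
    )
    rng.shuffle(counts)

    base = _base_features(c, u, config.base_feature_snr, rng)
    feature_names = list(_BASE_FEATURE_NAMES[: config.n_base_features])
    if config.n_base_features > len(_BASE_FEATURE_NAMES):
        extra = config.n_base_features - len(_BASE_FEATURE_NAMES)
        base = np.column_stack([base, rng.normal(size=(n, extra))])
        feature_names += [f"extra_{i}" for i in range(extra)]
    base = base[:, : config.n_base_features]

    f0, f1, fstep = config.ftir_axis
    ftir_axis = np.arange(f0, f1 + fstep / 2, fstep)
    x0, x1, xstep = config.xrd_axis
    xrd_axis = np.arange(x0, x1 + xstep / 2, xstep)

    samples, spectra, images = [], {}, {}
    n_missing_img = int(round(config.image_missing_fraction * n))
    missing_img = set(rng.choice(n, size=n_missing_img, replace=False).tolist())

    for i in range(n):
        mid = f"M{i + 1:02d}"
        sd = max(true_sd[i], 0.0)
        y = rng.normal(true_mean[i], sd, size=counts[i]) if sd > 0 else np.full(counts[i], true_mean[i])
        y = np.clip(y, 0.0, 100.0)
        samples.append(
            MaterialSample(
                material_id=mid,
                base_features=dict(zip(feature_names, base[i].tolist())),
                measurements=[float(v) for v in y],
            )
        )
        spectra[mid] = {
            "ftir": (
                ftir_axis,
                _spectrum(ftir_axis, FTIR_SIGNATURES, c[i], u[i], rng,
                          config.spectrum_noise_sd, width0=10.0),
            ),
            "xrd": (
                xrd_axis,
                _spectrum(xrd_axis, XRD_SIGNATURES, c[i], u[i], rng,
                          config.spectrum_noise_sd, width0=0.4,
                          crystallinity_scales_area=True),
            ),
        }
        images[mid] = None if i in missing_img else _texture(config.image_size, u[i], rng)

    dataset = MaterialDataset(
        samples=samples, feature_names=feature_names, spectra=spectra, images=images
    )
    truth = pd.DataFrame(
        {
            "material_id": [s.material_id for s in samples],
            "true_mean": true_mean,
            "true_sd": true_sd,
            "latent_composition": c,
            "latent_crystallinity": u,
            "n_measurements": counts,
        }
    ).set_index("material_id")
    return dataset, truth


def generate_synthetic_dataset(config: SyntheticConfig | None = None):
    """Signal-bearing dataset + ground truth (true mean/SD per material)."""
    config = config or SyntheticConfig()
    return _build(config, null_response=False)


def generate_null_dataset(config: SyntheticConfig | None = None) -> MaterialDataset:
    """Dataset whose responses are independent of every feature block."""
    config = config or SyntheticConfig()
    dataset, _ = _build(config, null_response=True)
    return dataset
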