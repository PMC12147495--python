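"""Core data model: materials with repeated response measurements.

A *material* is one artificial-bone formulation described by a fixed
feature vector (synthesis conditions, animal-experiment conditions,
physical properties) plus optional FT-IR / XRD spectra and a grayscale
SEM-like image. Because implantation experiments are repeated on several
animals, each material carries 1..k measurements of the response (bone
formation rate, in percent). The feature blocks beyond the base table are
switched on and off by a :class:`MethodCombo` — eight labelled
combinations (A = base features only, H = base + FT-IR + XRD + image).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .features import BandList, compute_lbp_codes, lbp_histogram, select_band_intensities

__all__ = [
    "MaterialSample",
    "MaterialDataset",
    "MethodCombo",
    "FeatureTable",
    "COMBO_LABELS",
    "load_dataset",
    "save_dataset",
    "summarize_measurements",
    "assemble_feature_matrix",
]


class DatasetFormatError(ValueError):
    """Raised when an on-disk dataset violates the expected layout."""


class DatasetConsistencyError(ValueError):
    """Raised when feature values vary within a single material."""


class MissingBlockError(ValueError):
    """Raised when a feature combo requests a block the dataset lacks."""


@dataclass
class MaterialSample:
    """One material: identifier, base features, repeated measurements."""

    material_id: str
    base_features: dict[str, float]
    measurements: list[float]

    def __post_init__(self) -> None:
        if len(self.measurements) == 0:
            raise ValueError(f"material {self.material_id!r}: measurements must be non-empty")
        if not all(math.isfinite(v) for v in self.measurements):
            raise ValueError(f"material {self.material_id!r}: non-finite measurement")
        for k, v in self.base_features.items():
            if not math.isfinite(v):
                raise ValueError(f"material {self.material_id!r}: non-finite feature {k!r}")

    @property
    def n_measurements(self) -> int:
        return len(self.measurements)


@dataclass
class MaterialDataset:
    """Ordered collection of materials plus optional spectra and images.

    ``spectra`` maps material_id -> {"ftir": (axis, intensity), "xrd": ...};
    each axis must be strictly increasing and the same length as its
    intensity vector. ``images`` maps material_id -> 2-D float array, or
    ``None`` for a material whose image is missing (to be imputed
    downstream).
    """

    samples: list[MaterialSample]
    feature_names: list[str]
    spectra: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = field(default_factory=dict)
    images: dict[str, np.ndarray | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.material_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("material_ids must be unique")
        for s in self.samples:
            if set(s.base_features) != set(self.feature_names):
                raise DatasetConsistencyError(
                    f"material {s.material_id!r}: feature keys differ from dataset schema"
                )
        for mid, blocks in self.spectra.items():
            for kind, (axis, intensity) in blocks.items():
                axis = np.asarray(axis, dtype=float)
                if axis.ndim != 1 or len(axis) != len(intensity):
                    raise ValueError(f"spectrum {mid}/{kind}: axis/intensity length mismatch")
                if not np.all(np.diff(axis) > 0):
                    raise ValueError(f"spectrum {mid}/{kind}: axis must be strictly increasing")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def material_ids(self) -> list[str]:
        return [s.material_id for s in self.samples]

    @property
    def has_ftir(self) -> bool:
        return bool(self.spectra) and all("ftir" in self.spectra.get(m, {}) for m in self.material_ids)

    @property
    def has_xrd(self) -> bool:
        return bool(self.spectra) and all("xrd" in self.spectra.get(m, {}) for m in self.material_ids)

    @property
    def has_images(self) -> bool:
        # A block with some missing images is still present: missing entries
        # become NaN rows for the imputer.
        return bool(self.images) and any(v is not None for v in self.images.values())

    def measurements_list(self) -> list[np.ndarray]:
        return [np.asarray(s.measurements, dtype=float) for s in self.samples]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: one row per measurement, features repeated."""
        rows = []
        for s in self.samples:
            for y in s.measurements:
                row = {"material_id": s.material_id, "measurement": y}
                row.update(s.base_features)
                rows.append(row)
        return pd.DataFrame(rows, columns=["material_id", "measurement", *self.feature_names])


# Table of the eight feature-block combinations: (ftir, xrd, sem).
COMBO_LABELS: dict[str, tuple[bool, bool, bool]] = {
    "A": (False, False, False),
    "B": (True, False, False),
    "C": (False, True, False),
    "D": (False, False, True),
    "E": (True, True, False),
    "F": (True, False, True),
    "G": (False, True, True),
    "H": (True, True, True),
}


@dataclass(frozen=True)
class MethodCombo:
    """One of the eight labelled feature-block combinations A..H."""

    label: str
    use_ftir: bool
    use_xrd: bool
    use_sem: bool

    @classmethod
    def from_label(cls, label: str) -> "MethodCombo":
        label = label.upper()
        if label not in COMBO_LABELS:
            raise ValueError(f"combo label must be one of {sorted(COMBO_LABELS)}, got {label!r}")
        f, x, s = COMBO_LABELS[label]
        return cls(label=label, use_ftir=f, use_xrd=x, use_sem=s)

    def __post_init__(self) -> None:
        expected = COMBO_LABELS.get(self.label.upper())
        if expected is not None and expected != (self.use_ftir, self.use_xrd, self.use_sem):
            raise ValueError(
                f"flags {(self.use_ftir, self.use_xrd, self.use_sem)} do not match label {self.label!r}"
            )


@dataclass
class FeatureTable:
    """Feature matrix X: rows = materials, columns = named features."""

    material_ids: list[str]
    matrix: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.material_ids), len(self.column_names)):
            raise ValueError("matrix shape does not match ids/columns")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.material_ids, columns=self.column_names)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.matrix).any())


def load_dataset(
    path: str | Path,
    spectra_dir: str | Path | None = None,
    image_dir: str | Path | None = None,
) -> MaterialDataset:
    """Read a dataset from the on-disk layout.

    ``path`` is a long-format CSV with columns ``material_id``,
    ``measurement`` and one column per base feature (constant within a
    material). ``spectra_dir`` holds two-column CSVs named
    ``<material_id>_ftir.csv`` / ``<material_id>_xrd.csv``; ``image_dir``
    holds one grayscale PNG/TIFF per material named ``<material_id>.png``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"material_id": str})
    required = {"material_id", "measurement"}
    if not required.issubset(df.columns):
        raise DatasetFormatError(f"missing required columns {sorted(required - set(df.columns))}")
    feature_names = [c for c in df.columns if c not in required]

    samples: list[MaterialSample] = []
    for mid, grp in df.groupby("material_id", sort=False):
        feats: dict[str, float] = {}
        for c in feature_names:
            vals = grp[c].to_numpy(dtype=float)
            if not np.all(vals == vals[0]):
                raise DatasetConsistencyError(f"feature {c!r} varies within material {mid!r}")
            feats[c] = float(vals[0])
        samples.append(MaterialSample(str(mid), feats, grp["measurement"].astype(float).tolist()))

    spectra: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    if spectra_dir is not None:
        spectra_dir = Path(spectra_dir)
        for s in samples:
            blocks = {}
            for kind in ("ftir", "xrd"):
                f = spectra_dir / f"{s.material_id}_{kind}.csv"
                if f.exists():
                    arr = pd.read_csv(f)
                    blocks[kind] = (
                        arr.iloc[:, 0].to_numpy(dtype=float),
                        arr.iloc[:, 1].to_numpy(dtype=float),
                    )
            if blocks:
                spectra[s.material_id] = blocks

    images: dict[str, np.ndarray | None] = {}
    if image_dir is not None:
        image_dir = Path(image_dir)
        any_file = False
        for s in samples:
            img = None
            for ext in (".png", ".tif", ".tiff"):
                f = image_dir / f"{s.material_id}{ext}"
                if f.exists():
                    img = np.asarray(Image.open(f).convert("L"), dtype=float)
                    any_file = True
                    break
            images[s.material_id] = img
        if not any_file:
            images = {}

    return MaterialDataset(samples=samples, feature_names=feature_names, spectra=spectra, images=images)


def save_dataset(dataset: MaterialDataset, out_dir: str | Path) -> Path:
    """Write a dataset in the layout :func:`load_dataset` reads.

    Materials whose image is ``None`` get no image file (missing-image
    case). Returns the output directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset.to_long_frame().to_csv(out_dir / "measurements.csv", index=False)
    if dataset.spectra:
        sdir = out_dir / "spectra"
        sdir.mkdir(exist_ok=True)
        for mid, blocks in dataset.spectra.items():
            for kind, (axis, intensity) in blocks.items():
                pd.DataFrame({"axis": axis, "intensity": intensity}).to_csv(
                    sdir / f"{mid}_{kind}.csv", index=False
                )
    if dataset.images:
        idir = out_dir / "images"
        idir.mkdir(exist_ok=True)
        for mid, img in dataset.images.items():
            if img is None:
                continue
            arr = np.clip(np.asarray(img, dtype=float), 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(idir / f"{mid}.png")
    return out_dir


def summarize_measurements(dataset: MaterialDataset) -> dict[str, int]:
    """Per-material measurement counts (basis of the count histogram)."""
    return {s.material_id: s.n_measurements for s in dataset.samples}


def _spectral_block(
    dataset: MaterialDataset, kind: str, bands: BandList, prefix: str
) -> tuple[np.ndarray, list[str]]:
    cols = [f"{prefix}_{p:g}" for p in sorted(bands.positions)]
    ordered = BandList(positions=sorted(bands.positions), window=bands.window)
    rows = []
    for mid in dataset.material_ids:
        blocks = dataset.spectra.get(mid, {})
        if kind not in blocks:
            raise MissingBlockError(f"material {mid!r} lacks a {kind} spectrum")
        axis, intensity = blocks[kind]
        rows.append(select_band_intensities(axis, intensity, ordered))
    return np.vstack(rows), cols


def assemble_feature_matrix(
    dataset: MaterialDataset,
    combo: MethodCombo | str,
    ftir_bands: BandList | None = None,
    xrd_bands: BandList | None = None,
    lbp_normalize: bool = True,
) -> FeatureTable:
    """Build the X matrix for one feature combination.

    Columns are deterministic: base features in schema order, then FT-IR
    band intensities ascending by wavenumber, XRD bands ascending by
    angle, then the 256 LBP histogram bins. A material with a missing
    image contributes NaN LBP columns (filled later by the imputer).
    """
    if isinstance(combo, str):
        combo = MethodCombo.from_label(combo)

    blocks: list[np.ndarray] = []
    names: list[str] = list(dataset.feature_names)
    base = np.array(
        [[s.base_features[c] for c in dataset.feature_names] for s in dataset.samples], dtype=float
    )
    blocks.append(base)

    if combo.use_ftir:
        if ftir_bands is None:
            raise ValueError("combo uses FT-IR but no ftir_bands given")
        if not dataset.has_ftir:
            raise MissingBlockError("combo uses FT-IR but dataset has no FT-IR spectra")
        b, c = _spectral_block(dataset, "ftir", ftir_bands, "ftir")
        blocks.append(b)
        names.extend(c)
    if combo.use_xrd:
        if xrd_bands is None:
            raise ValueError("combo uses XRD but no xrd_bands given")
        if not dataset.has_xrd:
            raise MissingBlockError("combo uses XRD but dataset has no XRD spectra")
        b, c = _spectral_block(dataset, "xrd", xrd_bands, "xrd")
        blocks.append(b)
        names.extend(c)
    if combo.use_sem:
        if not dataset.has_images:
            raise MissingBlockError("combo uses SEM images but dataset has none")
        rows = []
        for mid in dataset.material_ids:
            img = dataset.images.get(mid)
            if img is None:
                rows.append(np.full(256, np.nan))
            else:
                rows.append(lbp_histogram(compute_lbp_codes(img), normalize=lbp_normalize))
        blocks.append(np.vstack(rows))
        names.extend(f"lbp_{b}" for b in range(256))

    return FeatureTable(
        material_ids=list(dataset.material_ids),
        matrix=np.hstack(blocks),
        column_names=names,
    )
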