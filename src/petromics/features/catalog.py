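"""The 103-feature catalog and full-descriptor assembly.

``catalog.yaml`` pins the identity and order of every feature: 85
texture/fractal features (26 first-order + 20 GLCM + 13 GLRLM + 13 GLSZM +
4 GLDM + 5 NGTDM + 4 fractal) plus 18 SUV summaries. The manifest is
versioned; a FeatureVector records which version produced it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ..core import TumorROI
from .fractal import fractal_features
from .intensity import first_order_features, suv_features
from .matrices import TextureMatrixSet
from .quantize import quantize

TEXTURE_FEATURE_COUNT = 85
SUV_FEATURE_COUNT = 18
TOTAL_FEATURE_COUNT = TEXTURE_FEATURE_COUNT + SUV_FEATURE_COUNT


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered feature manifest; the single source of truth for names."""

    version: int
    families: dict[str, dict]

    @property
    def names(self) -> list[str]:
        return [f for fam in self.families.values() for f in fam["features"]]

    @property
    def texture_names(self) -> list[str]:
        return [
            f
            for fam in self.families.values()
            if fam["kind"] == "texture"
            for f in fam["features"]
        ]

    @property
    def suv_names(self) -> list[str]:
        return [
            f
            for fam in self.families.values()
            if fam["kind"] == "suv"
            for f in fam["features"]
        ]


def load_catalog(path: str | Path | None = None) -> FeatureCatalog:
    """Load the feature manifest (the packaged default, or an override file)."""
    if path is None:
        text = (
            resources.files("petromics.features").joinpath("catalog.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return FeatureCatalog(version=int(raw["version"]), families=raw["families"])


_DEFAULT_CATALOG: FeatureCatalog | None = None


def default_catalog() -> FeatureCatalog:
    global _DEFAULT_CATALOG
    if _DEFAULT_CATALOG is None:
        _DEFAULT_CATALOG = load_catalog()
    return _DEFAULT_CATALOG


@dataclass(frozen=True)
class FeatureVector:
    """Named, ordered 103-element tumor descriptor."""

    names: tuple[str, ...]
    values: np.ndarray
    catalog_version: int
    subject_id: str = "anon"
    label: int | None = None

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def extract_all(
    roi: TumorROI,
    n_levels: int = 64,
    distance: int = 1,
    fractal_window: int = 5,
    catalog: FeatureCatalog | None = None,
) -> FeatureVector:
    """Compute the full 103-feature descriptor of one tumor ROI.

    Raises if any feature comes out non-finite (the per-family degenerate
    fallbacks should make that impossible), naming the offender.
    """
    cat = catalog if catalog is not None else default_catalog()
    q = quantize(roi, n_levels=n_levels)
    mats = TextureMatrixSet.build(q, distance=distance)

    from .texture import texture_matrix_features

    computed: dict[str, float] = {}
    computed.update(first_order_features(roi))
    computed.update(texture_matrix_features(mats))
    computed.update(fractal_features(roi, window=fractal_window))
    computed.update(suv_features(roi))

    names = cat.names
    missing = [n for n in names if n not in computed]
    if missing:
        raise KeyError(f"catalog features not computed: {missing}")
    values = np.array([computed[n] for n in names], dtype=float)
    bad = [n for n, v in zip(names, values) if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature value(s): {bad}")
    return FeatureVector(
        names=tuple(names),
        values=values,
        catalog_version=cat.version,
        subject_id=roi.subject_id,
        label=roi.label,
    )


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack FeatureVectors into a DataFrame (subject_id, label, 103 columns)."""
    if not vectors:
        raise ValueError("no feature vectors")
    names = vectors[0].names
    rows = []
    for fv in vectors:
        if fv.names != names:
            raise ValueError("inconsistent feature catalogs across vectors")
        row: dict[str, object] = {"subject_id": fv.subject_id, "label": fv.label}
        row.update(fv.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
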