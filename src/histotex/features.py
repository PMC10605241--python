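"""Per-tile extraction of the 33 GLCM + GLRLM texture features.

The default direction policy evaluates both matrices at the four standard
unit displacements — horizontal (0,1), diagonal (-1,1), vertical (-1,0) and
anti-diagonal (-1,-1) — and averages the features over directions, which is
the conventional way to obtain an orientation-robust texture descriptor.

:class:`TextureFeatureExtractor` wraps the whole tile -> 33-feature pipeline
(grayscale conversion, min–max quantization, matrix construction, feature
formulas) as a scikit-learn transformer so it composes with pipelines and
model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .glcm import GLCM_FEATURE_NAMES, compute_glcm, glcm_features
from .glrlm import GLRLM_FEATURE_NAMES, compute_glrlm, glrlm_features
from .images import DEFAULT_MIN_COVERAGE, QuantizedImage, RawImage, ROIMask, quantize, to_grayscale

__all__ = [
    "FEATURE_NAMES",
    "DirectionPolicy",
    "extract_features",
    "TextureFeatureExtractor",
    "write_feature_table",
    "read_feature_table",
]

#: Canonical order of the 33 feature columns: 22 GLCM then 11 GLRLM.
FEATURE_NAMES: list[str] = GLCM_FEATURE_NAMES + GLRLM_FEATURE_NAMES

#: Metadata columns preceding the features in a feature table.
META_COLUMNS = ["source_id", "patient_id", "label"]

DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass(frozen=True)
class DirectionPolicy:
    """Displacement set and aggregation rule for direction-dependent features."""

    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    aggregation: str = "mean"  # "mean" or "per-direction"

    def __post_init__(self) -> None:
        if len(self.offsets) == 0:
            raise ValueError("need at least one offset")
        if len(set(self.offsets)) != len(self.offsets):
            raise ValueError("offsets must be distinct")
        if self.aggregation not in ("mean", "per-direction"):
            raise ValueError("aggregation must be 'mean' or 'per-direction'")


def extract_features(
    q: QuantizedImage,
    policy: DirectionPolicy | None = None,
    symmetric: bool = True,
    log_base: float = 2.0,
) -> pd.Series | pd.DataFrame:
    """Compute the 33 features of one quantized tile.

    Returns a Series (canonical feature order) under mean aggregation, or a
    DataFrame with one row per direction under ``aggregation='per-direction'``.
    """
    policy = policy or DirectionPolicy()
    rows = []
    for off in policy.offsets:
        g = glcm_features(compute_glcm(q, off, symmetric=symmetric), log_base=log_base)
        r = glrlm_features(compute_glrlm(q, off))
        rows.append({**g, **r})
    frame = pd.DataFrame(rows, index=[str(o) for o in policy.offsets])[FEATURE_NAMES]
    if policy.aggregation == "per-direction":
        return frame
    return frame.mean(axis=0)


class TextureFeatureExtractor(TransformerMixin, BaseEstimator):
    """Tile images -> 33 texture features, as a scikit-learn transformer.

    Parameters
    ----------
    n_levels : int
        Gray-level count Ng for quantization (8 by default; 16 and 32 are the
        other conventional choices).
    offsets : sequence of (dr, dc)
        Unit displacements for GLCM pairs and GLRLM run directions.
    aggregation : {"mean", "per-direction"}
        Whether transform() averages features over directions (default) or
        emits one row per direction per image.
    symmetric : bool
        Symmetrize the GLCM before normalization.
    log_base : float
        Base for all entropy-type features.
    min_coverage : float
        Tiles whose ROI mask covers less than this fraction are rejected.
    """

    def __init__(
        self,
        n_levels: int = 8,
        offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS,
        aggregation: str = "mean",
        symmetric: bool = True,
        log_base: float = 2.0,
        min_coverage: float = DEFAULT_MIN_COVERAGE,
    ) -> None:
        self.n_levels = n_levels
        self.offsets = offsets
        self.aggregation = aggregation
        self.symmetric = symmetric
        self.log_base = log_base
        self.min_coverage = min_coverage

    def _policy(self) -> DirectionPolicy:
        return DirectionPolicy(tuple(tuple(o) for o in self.offsets), self.aggregation)

    def fit(self, X: Iterable, y=None) -> "TextureFeatureExtractor":
        self._policy()  # validate parameters
        if not 2 <= self.n_levels:
            raise ValueError("n_levels must be >= 2")
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X: Iterable, masks: Sequence[ROIMask | None] | None = None) -> pd.DataFrame:
        """Extract features for an iterable of RawImage or 2-D/3-D arrays.

        Returns a DataFrame with the 33 canonical feature columns (plus
        metadata columns when the inputs are labeled RawImages).
        """
        self.fit(X)
        policy = self._policy()
        images = list(X)
        if masks is not None and len(masks) != len(images):
            raise ValueError("masks must match images one-to-one")
        rows, meta = [], []
        for k, item in enumerate(images):
            img = item if isinstance(item, RawImage) else RawImage(np.asarray(item))
            mask = masks[k] if masks is not None else None
            if mask is not None and mask.coverage_fraction < self.min_coverage:
                raise ValueError(
                    f"tile {img.source_id or k}: mask coverage "
                    f"{mask.coverage_fraction:.2f} below minimum {self.min_coverage}"
                )
            q = quantize(to_grayscale(img), self.n_levels, mask)
            fv = extract_features(q, policy, symmetric=self.symmetric, log_base=self.log_base)
            if policy.aggregation == "per-direction":
                for direction, row in fv.iterrows():
                    rows.append(row)
                    meta.append((img.source_id, img.patient_id, img.label, direction))
            else:
                rows.append(fv)
                meta.append((img.source_id, img.patient_id, img.label, None))
        out = pd.DataFrame(rows).reset_index(drop=True)[FEATURE_NAMES]
        meta_df = pd.DataFrame(meta, columns=META_COLUMNS + ["direction"])
        if policy.aggregation == "per-direction":
            out.insert(0, "direction", meta_df["direction"].values)
        for col in reversed(META_COLUMNS):
            out.insert(0, col, meta_df[col].values)
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(FEATURE_NAMES, dtype=object)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV and check that all 33 canonical columns are present."""
    table = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return table
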