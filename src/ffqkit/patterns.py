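"""Dietary-pattern derivation and scoring by principal components.

Patterns are axes of a PCA over the standardised recoded frequency matrix
(times/week for the 43 food items, alcohol excluded by construction), with
the retained components varimax-rotated and signed so each component's
largest-magnitude loading is positive.  Scores are the standardised
projection onto the rotated loadings, so the training cohort has mean zero
per component and a participant one standard deviation above the mean on a
single item scores that item's loading row.

Pattern names ("health conscious", "traditional", "processed",
"confectionery", "vegetarian" in the source cohort) are manual metadata
attached after inspecting loadings, never assigned algorithmically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = ["PatternModel", "fit_patterns", "score_patterns"]


@dataclass
class PatternModel:
    """Retained-component loadings and the scoring transform."""

    items: list[str]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray          # items x k, orthonormal columns
    rotation: str = "varimax"
    names: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def loadings_frame(self) -> pd.DataFrame:
        cols = self.names or [f"PC{i + 1}" for i in range(self.k)]
        return pd.DataFrame(self.loadings, index=self.items, columns=cols)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "items": self.items,
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "loadings": self.loadings.tolist(),
            "rotation": self.rotation,
            "names": self.names,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PatternModel":
        d = json.loads(Path(path).read_text())
        return cls(
            items=d["items"],
            means=np.asarray(d["means"], dtype=float),
            scales=np.asarray(d["scales"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            rotation=d["rotation"],
            names=list(d["names"]),
        )


def fit_patterns(
    matrix: pd.DataFrame, k: int, rotation: str = "varimax"
) -> tuple[PatternModel, pd.DataFrame]:
    """Fit ``k`` dietary patterns to a participants x items frequency matrix.

    Returns the fitted model and the training scores (participants x k).
    Deterministic given the input: components are extracted in
    explained-variance order, rotated, then signed so the
    largest-magnitude loading of each component is positive.
    """
    if k > matrix.shape[1]:
        raise ValueError(f"k={k} exceeds the {matrix.shape[1]} items")
    X = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("frequency matrix contains non-finite values")
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    if np.any(scales == 0):
        bad = [matrix.columns[i] for i in np.where(scales == 0)[0]]
        raise ValueError(f"all-constant items cannot be standardised: {bad}")
    Z = (X - means) / scales

    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_.T  # items x k, orthonormal columns
    if rotation == "varimax" and k > 1:
        loadings, _ = rotate_factors(loadings, "varimax")
    elif rotation not in ("varimax", "none"):
        raise ValueError(f"unknown rotation {rotation!r}")
    # sign convention
    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] = -loadings[:, j]

    model = PatternModel(
        items=list(matrix.columns),
        means=means,
        scales=scales,
        loadings=loadings,
        rotation=rotation,
    )
    scores = score_patterns(model, matrix)
    return model, scores


def score_patterns(model: PatternModel, frequencies: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Score participants on the fitted patterns (standardised projection).

    Requires the complete item set of the fit; frequency recoding upstream
    makes missing answers zero, so a genuinely absent item column is an
    error, not a silent zero.
    """
    if isinstance(frequencies, pd.Series):
        frequencies = frequencies.to_frame().T
    missing = [i for i in model.items if i not in frequencies.columns]
    if missing:
        raise KeyError(f"missing items for scoring: {missing}")
    X = frequencies[model.items].to_numpy(dtype=float)
    Z = (X - model.means) / model.scales
    scores = Z @ model.loadings
    cols = model.names or [f"PC{i + 1}" for i in range(model.k)]
    return pd.DataFrame(scores, index=frequencies.index, columns=cols)
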