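"""Length standardization, corpus matrices, 2-D embedding, era separation.

Per-piece surprise/uncertainty time courses have piece-dependent lengths;
they are standardized by piecewise-linear interpolation onto a common grid
(the length of the longest piece), stacked into a pieces x length matrix,
embedded in 2-D with t-SNE, and scored for era separability with a
leave-one-out k-nearest-neighbour label accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.manifold import TSNE

from .errors import DataError, ManifestError, ParameterError

#: t-SNE defaults used for piece embeddings.
TSNE_PERPLEXITY = 2
TSNE_RANDOM_STATE = 40
TSNE_EARLY_EXAGGERATION = 20


def interpolate_timecourse(series: Sequence[float], target_length: int) -> np.ndarray:
    """Resample a series to ``target_length`` points by linear interpolation.

    Both grids are normalized to [0, 1]; endpoints are preserved exactly,
    and the output equals the input when the lengths already match.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 2:
        raise DataError("series must be 1-D with at least 2 points")
    if target_length < 2:
        raise DataError("target_length must be >= 2")
    if target_length == len(series):
        return series.copy()
    x_old = np.linspace(0.0, 1.0, len(series))
    x_new = np.linspace(0.0, 1.0, target_length)
    return np.interp(x_new, x_old, series)


class TimecourseResampler(BaseEstimator, TransformerMixin):
    """Transformer stacking variable-length series into a common-length matrix.

    ``fit`` learns the target length (the longest input series, unless
    ``target_length`` is fixed); ``transform`` interpolates every series
    to it and returns a 2-D array.
    """

    def __init__(self, target_length: int | None = None) -> None:
        self.target_length = target_length

    def fit(self, X: Sequence[Sequence[float]], y=None) -> "TimecourseResampler":
        lengths = [len(np.asarray(s)) for s in X]
        if not lengths:
            raise DataError("no series given")
        if min(lengths) < 2:
            raise DataError("every series needs at least 2 points")
        self.target_length_ = (
            int(self.target_length) if self.target_length is not None else max(lengths)
        )
        return self

    def transform(self, X: Sequence[Sequence[float]]) -> np.ndarray:
        if not hasattr(self, "target_length_"):
            raise DataError("resampler is not fitted")
        return np.vstack(
            [interpolate_timecourse(s, self.target_length_) for s in X]
        )


@dataclass(frozen=True)
class DynamicsMatrix:
    """Corpus matrix of standardized time courses plus piece metadata."""

    values: np.ndarray
    feature: str
    stream_kind: str
    metadata: pd.DataFrame
    target_length: int

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.metadata):
            raise ManifestError("matrix rows do not align with metadata rows")
        if not np.isfinite(self.values).all():
            raise DataError("matrix contains non-finite values")

    @property
    def n_pieces(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = pd.DataFrame(
            self.values, columns=[f"t{i}" for i in range(self.target_length)]
        )
        return pd.concat([self.metadata.reset_index(drop=True), cols], axis=1)


def assemble_matrix(
    timecourses: Mapping[str, Sequence[float]],
    manifest: pd.DataFrame,
    feature: str,
    stream_kind: str,
) -> DynamicsMatrix:
    """Interpolate every piece's series to the longest length and stack.

    Row order follows the manifest. A manifest piece without a time course
    is a :class:`ManifestError`.
    """
    if len(manifest) < 2:
        raise DataError("need at least 2 pieces")
    missing = [pid for pid in manifest["piece_id"] if pid not in timecourses]
    if missing:
        raise ManifestError(f"missing time courses for pieces: {missing[:5]}")
    series = [np.asarray(timecourses[pid], dtype=float) for pid in manifest["piece_id"]]
    resampler = TimecourseResampler().fit(series)
    values = resampler.transform(series)
    return DynamicsMatrix(
        values=values,
        feature=feature,
        stream_kind=stream_kind,
        metadata=manifest.reset_index(drop=True),
        target_length=resampler.target_length_,
    )


@dataclass(frozen=True)
class Embedding2D:
    """2-D t-SNE coordinates for the pieces of one dynamics matrix."""

    coords: np.ndarray
    params: dict
    feature: str
    stream_kind: str
    metadata: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.coords, columns=["x", "y"])
        for col in ("piece_id", "era", "year"):
            if col in self.metadata.columns:
                frame[col] = self.metadata[col].to_numpy()
        return frame


def embed_tsne(
    matrix: DynamicsMatrix,
    perplexity: float = TSNE_PERPLEXITY,
    random_state: int = TSNE_RANDOM_STATE,
    early_exaggeration: float = TSNE_EARLY_EXAGGERATION,
) -> Embedding2D:
    """Embed pieces in 2-D with t-SNE on Euclidean row distances.

    Deterministic for a fixed ``random_state`` and input. Requires more
    pieces than the perplexity.
    """
    n = matrix.n_pieces
    if n <= perplexity or n < 4:
        raise ParameterError(
            f"need more pieces ({n}) than perplexity ({perplexity}), at least 4"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        early_exaggeration=early_exaggeration,
        random_state=random_state,
        init="pca",
        learning_rate="auto",
    )
    coords = tsne.fit_transform(matrix.values)
    if not np.isfinite(coords).all():
        raise DataError("t-SNE produced non-finite coordinates")
    return Embedding2D(
        coords=np.asarray(coords, dtype=float),
        params={
            "perplexity": perplexity,
            "random_state": random_state,
            "early_exaggeration": early_exaggeration,
        },
        feature=matrix.feature,
        stream_kind=matrix.stream_kind,
        metadata=matrix.metadata,
    )


def era_separation_score(
    X: DynamicsMatrix | Embedding2D | np.ndarray,
    labels: Sequence,
    k: int = 3,
) -> float:
    """Leave-one-out k-NN label accuracy (Euclidean distance).

    For each piece, the labels of its k nearest other pieces vote; ties
    are broken by the single nearest neighbour. Returns the fraction of
    pieces whose own label wins.
    """
    if isinstance(X, DynamicsMatrix):
        X = X.values
    elif isinstance(X, Embedding2D):
        X = X.coords
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    if len(labels) != n:
        raise DataError("one label per piece required")
    if len(np.unique(labels)) < 2:
        raise DataError("need at least 2 label classes")
    if not 1 <= k < n:
        raise ParameterError(f"k={k} must satisfy 1 <= k < n_pieces={n}")
    dist = cdist(X, X)
    np.fill_diagonal(dist, np.inf)
    correct = 0
    for i in range(n):
        order = np.argsort(dist[i], kind="stable")
        nearest = order[:k]
        votes: dict = {}
        for j in nearest:
            votes[labels[j]] = votes.get(labels[j], 0) + 1
        top = max(votes.values())
        winners = [lab for lab, v in votes.items() if v == top]
        predicted = winners[0] if len(winners) == 1 else labels[order[0]]
        correct += predicted == labels[i]
    return correct / n


def plot_embedding(
    embedding: Embedding2D,
    path: str | Path | None = None,
    cmap: str = "Greys_r",
):
    """Scatter the embedding with year-graded coloring (darker = older)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = embedding.to_frame()
    fig, ax = plt.subplots(figsize=(5, 4))
    years = frame["year"] if "year" in frame.columns else None
    sc = ax.scatter(
        frame["x"], frame["y"], c=years, cmap=cmap, edgecolors="k", linewidths=0.3
    )
    if years is not None:
        fig.colorbar(sc, ax=ax, label="year")
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.set_title(f"{embedding.feature} / {embedding.stream_kind}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
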