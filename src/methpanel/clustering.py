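"""Sample-level hierarchical clustering of methylation/expression profiles.

Distance between two samples is 1 minus the Pearson correlation of their
feature profiles; trees are built with Ward agglomeration (Ward.D2
Lance-Williams update on the precomputed distance matrix).  Cluster stability
is assessed by an ordinary feature bootstrap: features are resampled with
replacement, the tree is rebuilt, and each internal node's support is the
fraction of bootstrap trees containing the same leaf set (bootstrap
probability; multiscale/approximately-unbiased corrections are deliberately
not applied).

Also houses the expression-matrix preprocessing used before expression
clustering: a detection-p-value completeness filter and quantile
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class Dendrogram:
    """Agglomeration result: a scipy-style linkage plus leaf labels.

    ``linkage`` has one row per merge: child id, child id, height, size.
    Leaf i is labels[i]; internal node n_leaves+k is the k-th merge.
    ``support`` maps an internal node's frozenset of leaf labels to its
    bootstrap probability in [0, 1].
    """

    linkage: np.ndarray
    labels: list[str]
    support: dict[frozenset, float] | None = field(default=None)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def clades(self) -> list[frozenset]:
        """Leaf-label sets of all internal nodes, in merge order."""
        n = self.n_leaves
        sets: list[frozenset] = [frozenset([lab]) for lab in self.labels]
        out = []
        for a, b, _h, _s in self.linkage:
            merged = sets[int(a)] | sets[int(b)]
            sets.append(merged)
            out.append(merged)
        return out

    def to_newick(self) -> str:
        """Newick string; bootstrap supports (if present) label internal nodes."""
        n = self.n_leaves
        nodes: list[str] = list(self.labels)
        sets: list[frozenset] = [frozenset([lab]) for lab in self.labels]
        heights = [0.0] * n
        for a, b, h, _s in self.linkage:
            a, b = int(a), int(b)
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            merged = sets[a] | sets[b]
            label = ""
            if self.support is not None and merged in self.support:
                label = f"{self.support[merged]:.3f}"
            nodes.append(f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g}){label}")
            sets.append(merged)
            heights.append(h)
        return nodes[-1] + ";"


def correlation_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample distance matrix d(i,j) = 1 - Pearson r(profile_i, profile_j).

    ``profiles`` is samples (rows) x features (columns), complete (no missing
    values).  A sample with zero variance across features has no defined
    correlation and is an error naming the sample.
    """
    if profiles.shape[0] < 2 or profiles.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    if profiles.isna().any().any():
        raise ValueError("profiles contain missing values; drop incomplete features first")
    x = profiles.to_numpy(float)
    sd = x.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"zero-variance sample: {profiles.index[flat[0]]}")
    d = 1.0 - np.corrcoef(x)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrize away rounding
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def ward_cluster(dist: pd.DataFrame) -> Dendrogram:
    """Agglomerative Ward clustering of a precomputed distance matrix.

    Applies the Ward.D2 Lance-Williams update to the given distances (the
    convention scipy uses for ``method='ward'`` on a condensed matrix).
    """
    d = dist.to_numpy(float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if (d < -1e-12).any():
        raise ValueError("distance matrix has negative entries")
    condensed = squareform(np.clip(d, 0.0, None), checks=False)
    z = hierarchy.linkage(condensed, method="ward")
    return Dendrogram(linkage=z, labels=[str(s) for s in dist.index])


def bootstrap_support(
    profiles: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> Dendrogram:
    """Feature-bootstrap cluster support for the Ward tree of ``profiles``.

    Resamples feature columns with replacement ``n_boot`` times; the support of
    an internal node of the full-data tree is the fraction of bootstrap trees
    containing an internal node with the same leaf set.  Reproducible for a
    given seed.  Degenerate bootstrap draws (a sample left with zero variance)
    are redrawn.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    tree = ward_cluster(correlation_distance(profiles))
    counts = {clade: 0 for clade in tree.clades()}
    rng = np.random.default_rng(seed)
    n_feat = profiles.shape[1]
    done = 0
    while done < n_boot:
        cols = rng.integers(0, n_feat, size=n_feat)
        boot = profiles.iloc[:, cols]
        try:
            bt = ward_cluster(correlation_distance(boot))
        except ValueError:
            continue  # zero-variance resample; redraw
        for clade in set(bt.clades()):
            if clade in counts:
                counts[clade] += 1
        done += 1
    tree.support = {clade: c / n_boot for clade, c in counts.items()}
    return tree


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with optional detection p-values."""

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy(float) < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.detection_p is not None and not self.detection_p.shape == self.values.shape:
            raise ValueError("detection p-value matrix shape mismatch")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def detection_filter(expr: ExpressionMatrix, alpha: float = 0.05) -> ExpressionMatrix:
    """Keep genes detected (p <= alpha) in every sample.  Threshold inclusive."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if expr.detection_p is None:
        raise ValueError("expression matrix has no detection p-values")
    keep = (expr.detection_p <= alpha).all(axis=1)
    return ExpressionMatrix(
        values=expr.values.loc[keep].copy(),
        detection_p=expr.detection_p.loc[keep].copy(),
    )


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Standard quantile normalization across samples.

    Each column's sorted values are replaced by the cross-column means of the
    sorted rows; tied values within a column receive the mean of their rank
    range, so every column has the identical value distribution afterwards.
    """
    df = expr.values
    if df.isna().any().any():
        raise ValueError("quantile normalization requires a complete matrix")
    rank_means = pd.DataFrame(
        np.sort(df.to_numpy(float), axis=0), columns=df.columns
    ).mean(axis=1)
    # average-tie ranks are half-integers; interpolate between adjacent rank means
    ranks = df.rank(method="average", axis=0) - 1.0
    lo = np.floor(ranks).astype(int)
    hi = np.ceil(ranks).astype(int)
    frac = ranks - lo
    rm = rank_means.to_numpy()
    out = rm[lo.to_numpy()] * (1 - frac.to_numpy()) + rm[hi.to_numpy()] * frac.to_numpy()
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=df.index, columns=df.columns),
        detection_p=None if expr.detection_p is None else expr.detection_p.copy(),
    )
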