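"""Pairwise principal component analysis of preprocessed spectra.

Spectra from two experimental groups are pooled, column (wavenumber) means
are subtracted, and the centered matrix is decomposed by singular values.
No variance scaling is applied, the convention in vibrational spectroscopy.
Explained-variance fractions are squared singular values over their total;
signs follow a deterministic convention (the loading element of largest
magnitude is positive), so reruns are bit-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import BandDefinition
from .errors import SchemaError
from .hypermap import SpectralAxis
from .roi import SpectraSet

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Scores, loadings and explained variance of a pairwise comparison."""

    axis: SpectralAxis
    scores: np.ndarray              # (n_spectra, k)
    loadings: np.ndarray            # (k, n_wavenumbers), orthonormal rows
    explained_variance: np.ndarray  # (k,) fractions of total variance
    labels: pd.DataFrame
    mean_spectrum: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pairwise_pca(set_a: SpectraSet, set_b: SpectraSet,
                 n_components: int = 5) -> PCAResult:
    """PCA of two pooled spectra sets on an identical axis."""
    if set_a.axis != set_b.axis:
        raise SchemaError("spectra sets are on different axes")
    X = np.vstack([set_a.spectra, set_b.spectra])
    if X.shape[0] < 2:
        raise SchemaError("pairwise PCA needs >= 2 spectra in total")
    labels = pd.concat([set_a.labels, set_b.labels], ignore_index=True)

    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((S ** 2).sum())
    tol = S.max() * max(Xc.shape) * np.finfo(float).eps if S.size else 0.0
    rank = int((S > tol).sum())
    k = min(n_components, rank)
    if k < n_components:
        logger.warning("n_components=%d exceeds data rank %d; reduced to %d",
                       n_components, rank, k)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # deterministic sign: largest-magnitude loading element is positive
    for i in range(k):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    explained = (S ** 2) / total if total > 0 else np.zeros(k)
    return PCAResult(axis=set_a.axis, scores=U * S, loadings=Vt,
                     explained_variance=explained, labels=labels,
                     mean_spectrum=mean)


def group_separation(result: PCAResult, component: int = 0) -> float:
    """Point-biserial correlation between one score and the group label."""
    groups = result.labels["group"].to_numpy()
    names = pd.unique(groups)
    if names.size != 2:
        raise SchemaError(f"expected exactly 2 groups, found {list(names)}")
    indicator = (groups == names[1]).astype(float)
    return float(np.corrcoef(result.scores[:, component], indicator)[0, 1])


def loading_band_mass(result: PCAResult, band: BandDefinition,
                      component: int = 0) -> float:
    """Fraction of a loading's squared mass inside one wavenumber window."""
    w = result.axis.wavenumbers
    sel = (w >= band.lo) & (w <= band.hi)
    loading = result.loadings[component]
    return float((loading[sel] ** 2).sum() / (loading ** 2).sum())


# ---------------------------------------------------------------------------
# Tables and plots
# ---------------------------------------------------------------------------

def scores_table(result: PCAResult) -> pd.DataFrame:
    out = result.labels.copy()
    for i in range(result.n_components):
        out[f"PC{i + 1}"] = result.scores[:, i]
    return out


def loadings_table(result: PCAResult) -> pd.DataFrame:
    out = pd.DataFrame({"wavenumber": result.axis.wavenumbers})
    for i in range(result.n_components):
        out[f"PC{i + 1}"] = result.loadings[i]
    return out


def explained_variance_table(result: PCAResult) -> pd.DataFrame:
    return pd.DataFrame({
        "component": [f"PC{i + 1}" for i in range(result.n_components)],
        "explained_variance_fraction": result.explained_variance,
    })


_GROUP_COLORS = ("black", "red")   # legend order: wt first, mutant second


def plot_scores(result: PCAResult, path: str | Path,
                components: tuple[int, int] = (0, 1)) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    i, j = components
    groups = result.labels["group"].to_numpy()
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, color in zip(pd.unique(groups), _GROUP_COLORS):
        sel = groups == name
        ax.scatter(result.scores[sel, i], result.scores[sel, j],
                   s=12, c=color, label=str(name))
    ev = result.explained_variance
    ax.set_xlabel(f"PC{i + 1} ({100 * ev[i]:.1f}%)")
    ax.set_ylabel(f"PC{j + 1} ({100 * ev[j]:.1f}%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_loading(result: PCAResult, path: str | Path,
                 component: int = 0) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(result.axis.wavenumbers, result.loadings[component],
            lw=0.8, color="black")
    ax.axhline(0.0, lw=0.5, color="gray")
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel(f"PC{component + 1} loading")
    ax.invert_xaxis()   # spectroscopy convention: high wavenumber left
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
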