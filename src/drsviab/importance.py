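"""Frequency-contribution analysis: PCA loadings and Shapley attributions.

Two complementary views of which frequencies carry the class signal:

* standardized PCA over the spectra (each frequency one variable), reporting
  per-component loadings, explained variance and the dominant frequency --
  the grid point with the largest positive loading;
* model-agnostic Shapley attribution of a classifier's output probability to
  individual frequencies, estimated by permutation sampling with
  interventional background-mean replacement.  With mean replacement the
  efficiency identity (attributions sum to f(x) - f(background mean)) holds
  exactly for every permutation, so the Monte-Carlo error affects only the
  per-feature split, not the total.

Both feed a reduced-band recommendation: the smallest contiguous band
containing every dominant PCA frequency and the top-decile
mean-|attribution| frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .dataset import LabeledDataset

__all__ = [
    "PcaReport",
    "AttributionReport",
    "pca_frequency_importance",
    "shapley_attribution",
    "aggregate_attributions",
    "select_band",
]


@dataclass(frozen=True)
class PcaReport:
    """Standardized-PCA summary over frequency variables."""

    frequencies: np.ndarray
    n_components: int
    variance_explained: np.ndarray
    loadings: np.ndarray  # (n_components, n_frequencies)
    dominant_frequency: np.ndarray  # Hz, per component
    dropped_frequencies: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        d = {"frequency_hz": self.frequencies}
        for i in range(self.n_components):
            d[f"pc{i + 1}_loading"] = self.loadings[i]
        return pd.DataFrame(d)


def pca_frequency_importance(
    data: LabeledDataset, n_components: int = 2, channel: str = "eps_real"
) -> PcaReport:
    """PCA of the standardized spectra with one variable per frequency.

    ``channel`` selects which part of the permittivity feeds the analysis
    (default the dielectric constant eps').  Components are sign-fixed so
    the largest-magnitude loading is positive; the dominant frequency of a
    component is the grid point with the largest positive loading.
    Zero-variance frequency columns are dropped with a warning.
    """
    if len(data) < 2:
        raise ValueError("PCA needs at least 2 records")
    X, _ = data.to_arrays()
    ch = {"eps_real": 0, "eps_imag": 1}[channel]
    M = X[:, :, ch]
    freqs = data.spectra[0].grid.points

    var = M.var(axis=0)
    dropped = tuple(freqs[var == 0])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance frequency column(s)",
            stacklevel=2,
        )
        keep = var > 0
        M, freqs = M[:, keep], freqs[keep]

    Z = StandardScaler().fit_transform(M)
    n_components = min(n_components, Z.shape[1], Z.shape[0] - 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_.copy()
    for i in range(n_components):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    dominant = np.array(
        [freqs[int(np.argmax(loadings[i]))] for i in range(n_components)]
    )
    return PcaReport(
        frequencies=freqs,
        n_components=n_components,
        variance_explained=pca.explained_variance_ratio_.copy(),
        loadings=loadings,
        dominant_frequency=dominant,
        dropped_frequencies=dropped,
    )


@dataclass(frozen=True)
class AttributionReport:
    """Per-frequency Shapley attribution of one model decision."""

    frequencies: np.ndarray
    attributions: np.ndarray  # signed, per frequency
    baseline_value: float  # model output on the background mean
    prediction_value: float  # model output on the record
    efficiency_gap: float
    se: np.ndarray  # Monte-Carlo standard error per frequency
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": self.frequencies,
                "shap": self.attributions,
                "se": self.se,
            }
        )


def shapley_attribution(
    predict,
    record,
    background,
    n_permutations: int = 128,
    seed: int = 0,
    feature_groups: list[np.ndarray] | None = None,
    frequencies: np.ndarray | None = None,
) -> AttributionReport:
    """Permutation-sampling Shapley values with background-mean replacement.

    Parameters
    ----------
    predict : callable
        Maps an (n, p) feature matrix to a scalar model output per row
        (e.g. the non-viable class probability).
    record : array (p,)
        The instance to explain.
    background : array (m, p)
        Reference records; features outside the growing coalition are fixed
        at the background mean (interventional marginalisation).
    feature_groups : list of index arrays, optional
        Columns attributed jointly (e.g. the eps'/eps'' pair at one
        frequency).  Defaults to one group per column.
    frequencies : array, optional
        Labels (Hz) per group for the report; defaults to group indices.

    Each sampled permutation inserts groups one at a time and records the
    marginal change of the model output; attributions average these over
    permutations.  The efficiency identity holds exactly per permutation.
    """
    if n_permutations < 2:
        raise ValueError("need at least 2 permutations")
    record = np.asarray(record, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.size == 0:
        raise ValueError("background must be non-empty")
    p = record.size
    if feature_groups is None:
        feature_groups = [np.array([j]) for j in range(p)]
    G = len(feature_groups)
    if frequencies is None:
        frequencies = np.arange(G, dtype=float)

    base_vec = background.mean(axis=0)
    baseline = float(predict(base_vec[None, :])[0])
    fx = float(predict(record[None, :])[0])

    rng = np.random.default_rng(seed)
    contribs = np.zeros((n_permutations, G))
    for k in range(n_permutations):
        order = rng.permutation(G)
        # coalition matrix: row t = background with groups order[:t+1] set
        X = np.tile(base_vec, (G, 1))
        cols_so_far: list[int] = []
        for t, gi in enumerate(order):
            cols_so_far.extend(feature_groups[gi])
            X[t:, feature_groups[gi]] = record[feature_groups[gi]]
        vals = predict(X)
        prev = baseline
        for t, gi in enumerate(order):
            contribs[k, gi] = vals[t] - prev
            prev = vals[t]
    attr = contribs.mean(axis=0)
    se = contribs.std(axis=0, ddof=1) / np.sqrt(n_permutations)
    gap = float(attr.sum() - (fx - baseline))
    return AttributionReport(
        frequencies=np.asarray(frequencies, dtype=float),
        attributions=attr,
        baseline_value=baseline,
        prediction_value=fx,
        efficiency_gap=gap,
        se=se,
        n_permutations=n_permutations,
    )


def aggregate_attributions(reports: list[AttributionReport]) -> pd.DataFrame:
    """Mean and mean-|.| attribution per frequency over several records."""
    freqs = reports[0].frequencies
    A = np.stack([r.attributions for r in reports])
    return pd.DataFrame(
        {
            "frequency_hz": freqs,
            "mean_shap": A.mean(axis=0),
            "mean_abs_shap": np.abs(A).mean(axis=0),
        }
    )


def select_band(
    pca: PcaReport,
    attr: pd.DataFrame,
    top_quantile: float = 0.9,
    uniform_rtol: float = 1e-9,
) -> tuple[float, float]:
    """Smallest contiguous band covering the dominant PCA frequencies and
    the top-decile mean-|attribution| frequencies.

    Uniform attributions (no frequency stands out) fall back to the full
    band with a warning; a degenerate single-frequency band is widened by
    one grid step on each side.
    """
    freqs = np.asarray(attr["frequency_hz"], dtype=float)
    imp = np.asarray(attr["mean_abs_shap"], dtype=float)
    full = (float(freqs[0]), float(freqs[-1]))
    spread = imp.max() - imp.min()
    if imp.max() == 0 or spread <= uniform_rtol * max(imp.max(), 1.0):
        warnings.warn("attributions are uniform; falling back to the full band",
                      stacklevel=2)
        return full
    thresh = np.quantile(imp, top_quantile)
    top = freqs[imp >= thresh]
    marked = np.concatenate([top, pca.dominant_frequency])
    lo, hi = float(marked.min()), float(marked.max())
    if lo == hi:
        i = int(np.argmin(np.abs(freqs - lo)))
        lo = float(freqs[max(i - 1, 0)])
        hi = float(freqs[min(i + 1, len(freqs) - 1)])
    return (lo, hi)
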