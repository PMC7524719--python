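"""Climatic predictor construction.

Six bioclimatic variables with incommensurate units are summarized by a PCA
on the correlation matrix (variables z-scored first); the first three
components serve as the current-climate predictors. Past climate change is
expressed as anomalies between a Last Glacial Maximum ensemble mean and the
present-day value; by default the magnitude |LGM - present| is used so that
larger values mean more climate change. All predictors are standardized to
zero mean and unit sample variance before modelling, with the scaling stored
for exact back-transformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass
class PcaResult:
    """Scores of retained components plus full loadings/variance accounting."""

    scores: pd.DataFrame          # country x retained components (PC1..PCk)
    loadings: pd.DataFrame        # variable x all components
    variance_explained: np.ndarray  # proportion per component, sums to 1


def climate_pca(bioclim: pd.DataFrame, n_components: int = 3) -> PcaResult:
    """Correlation-matrix PCA of the bioclim table; retain ``n_components`` scores.

    Component signs are pinned so the largest-magnitude loading of each
    component is positive (PCA signs are otherwise arbitrary, and downstream
    coefficient signs must be reproducible).
    """
    if bioclim.shape[0] < bioclim.shape[1] + 1:
        raise ValueError("need more countries than climate variables")
    if bioclim.isna().any().any():
        raise ValueError("bioclim table has missing cells")
    sd = bioclim.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant climate column(s): {constant}")
    z = (bioclim - bioclim.mean()) / sd

    pca = PCA()
    raw_scores = pca.fit_transform(z.to_numpy())
    components = pca.components_  # (n_comp, n_var)
    # sign convention: largest-|loading| entry positive per component
    flip = np.sign(components[np.arange(components.shape[0]),
                              np.argmax(np.abs(components), axis=1)])
    components = components * flip[:, None]
    raw_scores = raw_scores * flip[None, :]

    names = [f"PC{i + 1}" for i in range(components.shape[0])]
    scores = pd.DataFrame(raw_scores[:, :n_components], index=bioclim.index,
                          columns=names[:n_components])
    loadings = pd.DataFrame(components.T, index=bioclim.columns, columns=names)
    return PcaResult(scores=scores, loadings=loadings,
                     variance_explained=pca.explained_variance_ratio_)


def lgm_anomaly(current: pd.Series, lgm_ensemble_mean: pd.Series,
                signed: bool = False) -> pd.Series:
    """Climate-change covariate: LGM ensemble mean minus present-day value.

    Default is the absolute magnitude (higher = more change since the LGM);
    pass ``signed=True`` for the raw signed difference.
    """
    if not current.index.equals(lgm_ensemble_mean.index):
        raise ValueError("current and LGM series must share the same country index")
    diff = lgm_ensemble_mean - current
    return diff if signed else diff.abs()


@dataclass
class Scaler:
    """Column means/SDs recorded by :func:`standardize_predictors`."""

    means: pd.Series
    sds: pd.Series

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X - self.means[X.columns]) / self.sds[X.columns]

    def inverse(self, Z: pd.DataFrame) -> pd.DataFrame:
        return Z * self.sds[Z.columns] + self.means[Z.columns]


def standardize_predictors(X: pd.DataFrame) -> tuple[pd.DataFrame, Scaler]:
    """Center and scale every column to mean 0, sample SD 1."""
    sds = X.std(ddof=1)
    constant = sds.index[sds == 0].tolist()
    if constant:
        raise ValueError(f"constant predictor column(s): {constant}")
    scaler = Scaler(means=X.mean(), sds=sds)
    return scaler.transform(X), scaler
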