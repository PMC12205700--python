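"""PCA of the per-plot environment / hemeroby variable block.

Correlation-matrix PCA: variables are standardised (mean 0, sample SD 1),
the correlation matrix is eigendecomposed, and components with eigenvalue
> 1 are retained (Kaiser criterion).  Loadings are scaled eigenvectors and
equal the Pearson correlation between each variable and each component's
scores.  Loadings can be masked by the significance of that correlation
(two-sided t-test), mirroring published ordination tables that display only
significant factor weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    """Correlation-matrix PCA output.

    eigenvalues: descending, summing to the number of variables;
    explained_pct: percentages of total variance; loadings: variable x
    component correlations in [-1, 1]; scores: plot x component (unit
    variance is NOT imposed; scores are projections of the standardised
    data); retained: number of eigenvalues > 1 (Kaiser).
    """

    eigenvalues: np.ndarray
    explained_pct: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame
    retained: int
    n_plots: int

    def component(self, k: int) -> pd.Series:
        return self.scores.iloc[:, k]


def pca_environment(plot_table: pd.DataFrame) -> OrdinationResult:
    """Correlation-matrix PCA of a per-plot variable table.

    Rows with any missing value are dropped with a warning; zero-variance
    variables are dropped with a warning.  Component signs are fixed so the
    variable with the largest |loading| on each component loads positive.
    """
    x = plot_table.copy()
    complete = x.dropna(axis=0, how="any")
    if len(complete) < len(x):
        logger.warning(
            "pca_environment: dropped %d plot(s) with missing values",
            len(x) - len(complete),
        )
    x = complete
    sd = x.std(ddof=1)
    dead = sd.index[(sd == 0) | sd.isna()].tolist()
    if dead:
        logger.warning("pca_environment: dropped zero-variance variables %s", dead)
        x = x.drop(columns=dead)
        sd = sd.drop(dead)
    if x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError(
            f"pca_environment needs >= 3 complete plots and >= 2 variables, "
            f"got {x.shape}"
        )

    z = (x - x.mean()) / sd
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    loadings = eigvec * np.sqrt(eigval)[None, :]
    # deterministic sign: largest-|loading| variable positive per component
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            eigvec[:, k] *= -1

    comp_names = [f"PC{k + 1}" for k in range(len(eigval))]
    scores = pd.DataFrame(
        z.to_numpy() @ eigvec, index=x.index, columns=comp_names
    )
    loadings_df = pd.DataFrame(loadings, index=x.columns, columns=comp_names)
    return OrdinationResult(
        eigenvalues=eigval,
        explained_pct=100.0 * eigval / eigval.sum(),
        loadings=loadings_df,
        scores=scores,
        retained=int((eigval > 1.0).sum()),
        n_plots=len(x),
    )


def filter_significant_loadings(
    res: OrdinationResult, n: int | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Mask loadings whose variable-score correlation is not significant.

    A loading r is kept when the two-sided p of t = r * sqrt((n-2)/(1-r^2))
    on n-2 degrees of freedom is below ``alpha``; masked loadings become
    NaN (rendered as empty cells on export).
    """
    if n is None:
        n = res.n_plots
    if n <= 2:
        raise ValueError("loading significance needs n > 2 plots")
    r = res.loadings.to_numpy(dtype=float)
    r2 = np.clip(r * r, 0.0, 1.0 - 1e-15)
    t = np.abs(r) * np.sqrt((n - 2) / (1.0 - r2))
    p = 2.0 * stats.t.sf(t, df=n - 2)
    masked = res.loadings.where(p < alpha)
    return masked


def summarize_by_group(
    plot_table: pd.DataFrame, groups: pd.Series | dict
) -> pd.DataFrame:
    """Per-group mean +- sample SD of every variable, ordered by group label.

    Returns a frame indexed by group with ``<var>_mean`` and ``<var>_sd``
    columns (SD missing for single-plot groups).
    """
    groups = pd.Series(groups)
    tab = plot_table.join(groups.rename("group"), how="inner")
    rows = []
    for label, sub in sorted(tab.groupby("group"), key=lambda kv: str(kv[0])):
        row: dict = {"group": label, "n_plots": len(sub)}
        for col in plot_table.columns:
            vals = sub[col].dropna()
            row[f"{col}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) >= 2 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
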