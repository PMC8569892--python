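"""Environment–module–community linkage.

Quantifies how environmental variation propagates to community turnover
through network modules, with a two-layer piecewise path model fitted on
pairwise dissimilarities:

* layer 1 — one linear model per module: the module's Bray–Curtis
  β-diversity regressed on the pairwise (z-standardised) distances of
  every environmental variable;
* layer 2 — one linear model for the whole community: community
  β-diversity regressed on the module β-diversities.

All vectors are the upper triangles of symmetric sample-pair matrices,
z-standardised before fitting, so coefficients are standardized path
coefficients.  Pairwise distances are not independent observations;
P-values therefore come either from ordinary least squares (default,
matching common piecewise path practice on distances) or from a
Mantel-style permutation of sample identities (``p_method="permutation"``),
which respects the dependence structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform

from .preprocess import OTUTable

logger = logging.getLogger(__name__)


def bray_curtis(table: OTUTable, otu_subset=None, samples=None) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarity BC(x, y) = Σ|x−y| / Σ(x+y)
    over the given OTU subset.

    A pair where both profiles sum to zero over the subset has no
    defined dissimilarity and is returned as NaN.
    """
    if not table.is_relative:
        raise ValueError("Bray-Curtis is computed on relative abundances")
    otus = list(otu_subset) if otu_subset is not None else list(table.otu_ids)
    if not otus:
        raise ValueError("empty OTU subset")
    sub = table.data[otus]
    if samples is not None:
        sub = sub.loc[list(samples)]
    X = sub.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = pdist(X, metric="braycurtis")
    D = squareform(d)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=sub.index, columns=sub.index)


def env_distance(env: pd.DataFrame, variable: str, samples=None) -> pd.DataFrame:
    """Pairwise absolute difference of one z-standardised environmental
    variable; translation- and scale-invariant in the raw values."""
    if variable not in env.columns:
        raise ValueError(f"variable {variable!r} not in the environmental table")
    v = env[variable]
    if samples is not None:
        v = v.loc[list(samples)]
    v = v.dropna()
    sd = v.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        logger.warning("environmental variable %r is constant; distances are 0",
                       variable)
        z = v * 0.0
    else:
        z = (v - v.mean()) / sd
    arr = z.to_numpy()
    D = np.abs(arr[:, None] - arr[None, :])
    return pd.DataFrame(D, index=v.index, columns=v.index)


@dataclass
class PathModelResult:
    """Standardized path coefficients for env -> module -> community."""

    paths: pd.DataFrame  # columns: response, predictor, coefficient, p_value, significant
    r2: dict  # response -> R²
    p_method: str
    n_pairs: int

    def coefficient(self, response: str, predictor: str) -> float:
        sel = self.paths[(self.paths["response"] == response)
                         & (self.paths["predictor"] == predictor)]
        return float(sel["coefficient"].iloc[0])


def _upper_vector(D: pd.DataFrame, order) -> np.ndarray:
    M = D.loc[order, order].to_numpy(dtype=float)
    iu = np.triu_indices(len(order), 1)
    return M[iu]


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0 or np.isnan(sd):
        return v - v.mean()
    return (v - v.mean()) / sd


def _fit_layer(y_mat: pd.DataFrame, X_mats: dict, order, alpha: float,
               p_method: str, n_perm: int, rng) -> tuple[list, float]:
    iu = np.triu_indices(len(order), 1)
    y = _zscore(_upper_vector(y_mat, order))
    names = list(X_mats)
    X = np.column_stack([_zscore(_upper_vector(X_mats[k], order)) for k in names])
    if X.shape[1] > 1 and np.linalg.cond(X.T @ X) > 1e8:
        warnings.warn("collinear predictors in path model; coefficients "
                      "reported but unstable", stacklevel=2)
    Xc = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, Xc).fit()
    coefs = fit.params[1:]
    if p_method == "ols":
        pvals = fit.pvalues[1:]
    elif p_method == "permutation":
        # Mantel-style: permute sample identities of the response matrix
        pinv = np.linalg.pinv(Xc)
        perm_cols = np.empty((len(y), n_perm))
        M = y_mat.loc[order, order].to_numpy(dtype=float)
        for j in range(n_perm):
            p = rng.permutation(len(order))
            perm_cols[:, j] = _zscore(M[np.ix_(p, p)][iu])
        perm_coefs = (pinv @ perm_cols)[1:]
        pvals = ((np.abs(perm_coefs) >= np.abs(coefs)[:, None]).sum(axis=1) + 1) \
            / (n_perm + 1)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    rows = [
        {"predictor": name, "coefficient": float(c), "p_value": float(p),
         "significant": bool(p < alpha)}
        for name, c, p in zip(names, coefs, pvals)
    ]
    return rows, float(fit.rsquared)


def fit_path_model(env_dists: dict, module_betas: dict,
                   community_beta: pd.DataFrame, alpha: float = 0.05,
                   p_method: str = "ols", n_perm: int = 999,
                   seed: int = 0) -> PathModelResult:
    """Fit the two-layer piecewise path model.

    Parameters
    ----------
    env_dists:
        variable name -> square pairwise-distance DataFrame.
    module_betas:
        module id -> square Bray-Curtis DataFrame (major modules).
    community_beta:
        square Bray-Curtis DataFrame for the whole community.
    """
    order = list(community_beta.index)
    for D in list(env_dists.values()) + list(module_betas.values()):
        missing = set(order) - set(D.index)
        if missing:
            raise ValueError(f"distance matrices disagree on samples: {missing}")
    rng = np.random.default_rng(seed)
    rows, r2 = [], {}
    for mod, beta in module_betas.items():
        layer, rsq = _fit_layer(beta, env_dists, order, alpha, p_method,
                                n_perm, rng)
        for row in layer:
            rows.append({"response": f"module {mod}", **row})
        r2[f"module {mod}"] = rsq
    layer, rsq = _fit_layer(
        community_beta,
        {f"module {m}": b for m, b in module_betas.items()},
        order, alpha, p_method, n_perm, rng)
    for row in layer:
        rows.append({"response": "community", **row})
    r2["community"] = rsq
    return PathModelResult(
        paths=pd.DataFrame(rows), r2=r2, p_method=p_method,
        n_pairs=len(order) * (len(order) - 1) // 2,
    )


def module_contribution_summary(result: PathModelResult) -> pd.DataFrame:
    """Sign and significance of each module's path to community
    β-diversity."""
    sel = result.paths[result.paths["response"] == "community"].copy()
    sel["direction"] = np.where(sel["coefficient"] >= 0, "positive", "negative")
    sel["summary"] = [
        f"{d}, {'significant' if s else 'n.s.'}"
        for d, s in zip(sel["direction"], sel["significant"])
    ]
    return sel[["predictor", "coefficient", "p_value", "direction",
                "summary"]].reset_index(drop=True)
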