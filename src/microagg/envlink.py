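"""Environment-community regressions.

Two families of fits:

* within-core dissimilarity regressions — pairwise Aitchison community
  dissimilarity of same-core aggregate pairs against the absolute
  difference of a z-standardized environmental variable, pooled across
  cores within a depth layer into one ordinary-least-squares line per
  variable (cores with fewer than three aggregates are excluded);

* richness-environment model selection — per depth layer and predictor,
  linear vs quadratic polynomial regression of rarefied ASV richness, the
  quadratic kept only when both the nested F-test (ANOVA) and AIC favour
  it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from microagg.iotables import SampleFrame
from microagg.ordination import DistanceMatrix

__all__ = ["DissimRegression", "RichnessModel", "zscore",
           "within_core_pair_table", "dissimilarity_regression",
           "richness_env_model"]


@dataclass(frozen=True)
class DissimRegression:
    env_variable: str
    depth_layer: str
    n_pairs: int
    slope: float
    intercept: float
    R2: float
    p_value: float

    @property
    def highlighted(self) -> bool:
        """Strong association flag: R2 > 0.1 with a significant slope."""
        return self.R2 > 0.1 and self.p_value <= 0.05


@dataclass(frozen=True)
class RichnessModel:
    predictor: str
    depth_layer: str
    chosen_form: str            # "linear" or "quadratic"
    coefficients: tuple         # intercept-first, of the chosen form
    R2: float
    AIC_linear: float
    AIC_quadratic: float
    F_p: float                  # nested ANOVA p (quadratic vs linear)
    n: int


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, sample standard deviation 1 (ddof=1)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)] if np.isnan(v).any() else v
    if len(np.unique(v)) < 2:
        raise ValueError("constant input cannot be z-scored")
    values = np.asarray(values, dtype=float)
    m = np.nanmean(values)
    s = np.nanstd(values, ddof=1)
    return (values - m) / s


def within_core_pair_table(D: DistanceMatrix, samples: SampleFrame,
                           env_var: str, depth_layer: str,
                           min_aggregates: int = 3) -> pd.DataFrame:
    """Paired (community, environment) dissimilarities of same-core pairs.

    The environment variable is z-scored within the depth layer (over
    aggregates with a measurement); the pairwise environmental distance is
    |dz|.  Cores with fewer than ``min_aggregates`` measured aggregates
    are excluded.  Returns columns (core_id, id1, id2, commD, envD).
    """
    meta = samples.data
    ids_in_D = [i for i in D.ids if i in meta.index]
    sub = meta.loc[ids_in_D]
    sub = sub[(sub["sample_type"] == "aggregate")
              & (sub["depth_layer"] == depth_layer)
              & sub[env_var].notna()]
    if sub.empty:
        raise ValueError(f"no measured aggregates in {depth_layer!r}")
    z = pd.Series(zscore(sub[env_var].to_numpy(float)), index=sub.index)
    pos = {s: k for k, s in enumerate(D.ids)}
    m = np.asarray(D.matrix)
    rows = []
    for core_id, grp in sub.groupby("core_id", observed=True, sort=True):
        ids = sorted(grp.index)
        if len(ids) < min_aggregates:
            continue
        for i1, i2 in itertools.combinations(ids, 2):
            rows.append({"core_id": core_id, "id1": i1, "id2": i2,
                         "commD": float(m[pos[i1], pos[i2]]),
                         "envD": float(abs(z[i1] - z[i2]))})
    if not rows:
        raise ValueError("no qualifying same-core pairs")
    return pd.DataFrame(rows)


def dissimilarity_regression(pairs: pd.DataFrame, env_variable: str = "",
                             depth_layer: str = "") -> DissimRegression:
    """OLS of community dissimilarity on environmental dissimilarity."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs to fit")
    x = pairs["envD"].to_numpy(float)
    y = pairs["commD"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("zero-variance environmental distances")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return DissimRegression(env_variable=env_variable,
                            depth_layer=depth_layer,
                            n_pairs=len(pairs),
                            slope=float(model.params[1]),
                            intercept=float(model.params[0]),
                            R2=float(model.rsquared),
                            p_value=float(model.pvalues[1]))


def richness_env_model(richness, x, predictor: str = "",
                       depth_layer: str = "",
                       alpha: float = 0.05) -> RichnessModel:
    """Linear vs quadratic richness-environment regression.

    The quadratic form is chosen only when the nested F-test p-value is
    <= alpha AND the quadratic AIC is lower; otherwise linear.
    """
    y = np.asarray(richness, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x = y[ok], x[ok]
    if len(y) < 5:
        raise ValueError("need at least 5 points")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    # fit on a standardized predictor for conditioning (gene copies reach
    # 1e9, whose square overwhelms float64 least squares); model choice is
    # invariant to the affine rescaling and coefficients are mapped back
    mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    z = (x - mu) / sd
    X1 = sm.add_constant(z)
    X2 = sm.add_constant(np.column_stack([z, z ** 2]))
    lin = sm.OLS(y, X1).fit()
    quad = sm.OLS(y, X2).fit()
    f_test = quad.compare_f_test(lin)
    f_p = float(f_test[1])
    use_quad = (f_p <= alpha) and (quad.aic < lin.aic)
    chosen = quad if use_quad else lin
    if use_quad:
        a, b, c = (float(v) for v in quad.params)
        coefs = (a - b * mu / sd + c * mu ** 2 / sd ** 2,
                 b / sd - 2 * c * mu / sd ** 2,
                 c / sd ** 2)
    else:
        a, b = (float(v) for v in lin.params)
        coefs = (a - b * mu / sd, b / sd)
    return RichnessModel(predictor=predictor, depth_layer=depth_layer,
                         chosen_form="quadratic" if use_quad else "linear",
                         coefficients=coefs,
                         R2=float(chosen.rsquared),
                         AIC_linear=float(lin.aic),
                         AIC_quadratic=float(quad.aic),
                         F_p=f_p, n=int(len(y)))
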