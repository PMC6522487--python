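"""Multiple regression on distance matrices (MRM).

The strict lower triangles of the response and predictor matrices are
unfolded to vectors, optionally rank-transformed (average ties), and fit by
ordinary least squares.  Significance comes from jointly permuting the
response matrix's row/column labels (Mantel-style) and refitting: a
coefficient's p-value is the fraction of permutations with |b_perm| >=
|b_obs| and the model p the fraction with R^2_perm >= R^2_obs, both with
the (+1)/(n_perm+1) estimator so p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skbio import DistanceMatrix

from .predictors import PredictorSet


@dataclass(frozen=True)
class MrmResult:
    """Partial regression coefficients and permutation p-values."""

    coefficients: pd.Series      # includes "intercept"
    coefficient_p: pd.Series     # permutation p per predictor (not intercept)
    r_squared: float
    model_p: float
    n_perm: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.coefficients.index:
            rows.append({
                "term": name,
                "coefficient": self.coefficients[name],
                "p": self.coefficient_p.get(name, np.nan),
            })
        rows.append({"term": "model_r2", "coefficient": self.r_squared,
                     "p": self.model_p})
        return pd.DataFrame(rows)


def _tri_vector(matrix: np.ndarray, tril: tuple) -> np.ndarray:
    return matrix[tril]


def _ranked_matrix(matrix: np.ndarray, tril: tuple) -> np.ndarray:
    """Matrix whose off-diagonal entries are average-tie ranks of the
    lower-triangle values (symmetric fill), so that label permutations of
    the ranked matrix commute with ranking."""
    ranks = rankdata(matrix[tril])
    out = np.zeros_like(matrix, dtype=float)
    out[tril] = ranks
    out = out + out.T
    return out


def mrm_fit(response: DistanceMatrix, predictors: PredictorSet | dict,
            n_perm: int = 1000, rank: bool = True, seed: int = 0) -> MrmResult:
    """Fit MRM of a response distance matrix on predictor distance matrices.

    Parameters
    ----------
    response : DistanceMatrix
        Community dissimilarity (e.g. UniFrac) among samples.
    predictors : PredictorSet or dict of name -> DistanceMatrix
        Must share the response's label set.
    n_perm : int
        Number of label permutations for the null distribution.
    rank : bool
        Rank-transform all unfolded vectors (average ties) before fitting.
    seed : int
        Seed for the permutation stream.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    members = predictors.members if isinstance(predictors, PredictorSet) else dict(predictors)
    ids = list(response.ids)
    for name, dm in members.items():
        if set(dm.ids) != set(ids):
            raise ValueError(f"predictor {name} labels do not match response")
    n = len(ids)
    tril = np.tril_indices(n, k=-1)

    resp_mat = np.asarray(response.data, dtype=float)
    pred_vecs = []
    names = list(members)
    for name in names:
        dm = members[name].filter(ids)
        vec = _tri_vector(np.asarray(dm.data, dtype=float), tril)
        if rank:
            vec = rankdata(vec)
        pred_vecs.append(vec)
    if rank:
        resp_mat = _ranked_matrix(resp_mat, tril)

    y = _tri_vector(resp_mat, tril)
    if np.ptp(y) == 0:
        raise ValueError("constant response vector")
    x = np.column_stack([np.ones(len(y))] + pred_vecs)
    pinv = np.linalg.pinv(x)
    hat = x @ pinv

    def fit(vec: np.ndarray) -> tuple[np.ndarray, float]:
        beta = pinv @ vec
        fitted = hat @ vec
        ss_res = float(np.sum((vec - fitted) ** 2))
        ss_tot = float(np.sum((vec - vec.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        return beta, r2

    beta_obs, r2_obs = fit(y)

    rng = np.random.default_rng(seed)
    count_coef = np.zeros(len(names))
    count_r2 = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_perm = _tri_vector(resp_mat[np.ix_(perm, perm)], tril)
        beta_p, r2_p = fit(y_perm)
        count_coef += np.abs(beta_p[1:]) >= np.abs(beta_obs[1:])
        count_r2 += r2_p >= r2_obs

    coef_p = (count_coef + 1.0) / (n_perm + 1.0)
    model_p = (count_r2 + 1.0) / (n_perm + 1.0)
    return MrmResult(
        coefficients=pd.Series(beta_obs, index=["intercept"] + names),
        coefficient_p=pd.Series(coef_p, index=names),
        r_squared=r2_obs,
        model_p=model_p,
        n_perm=n_perm,
        seed=seed,
    )
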