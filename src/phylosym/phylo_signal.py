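"""Phylogenetic signal: PGLS under Brownian motion and local Moran's I (LIPA).

PGLS quantifies how much of a per-species response (alpha diversity, PCoA
axes, per-OTU presence) diet explains once the expected covariance of
residuals under Brownian motion on the host tree is accounted for.

LIPA — a per-tip local Moran's I with phylogenetic proximity weights —
localizes phylogenetic signal: which host tips carry values (here, OTU
presence residuals after regressing out diet by binomial regression) more
similar to their phylogenetic neighbours than expected by chance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import solve_triangular
from skbio import TreeNode

from .sensitivity import bh_adjust

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

def brownian_covariance(tree: TreeNode, tips=None) -> pd.DataFrame:
    """Expected trait covariance among tips under Brownian motion.

    C[i, j] is the root-to-MRCA shared branch length of tips i and j;
    C[i, i] is the root-to-tip depth.
    """
    tip_names = [t.name for t in tree.tips()]
    if tips is not None:
        tips = list(tips)
        missing = set(tips) - set(tip_names)
        if missing:
            raise ValueError(f"tips not in tree: {sorted(missing)}")
    else:
        tips = tip_names
    index = {name: i for i, name in enumerate(tips)}
    n = len(tips)
    cov = np.zeros((n, n))

    # depth-first accumulation: at each node, pairs of tips in different
    # child subtrees share exactly that node's depth
    def walk(node, depth):
        if node.is_tip():
            if node.name in index:
                i = index[node.name]
                cov[i, i] = depth
                return [i]
            return []
        groups = []
        for child in node.children:
            groups.append(walk(child, depth + (child.length or 0.0)))
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        cov[i, j] = cov[j, i] = depth
        return [i for g in groups for i in g]

    walk(tree, 0.0)
    return pd.DataFrame(cov, index=tips, columns=tips)


@dataclass(frozen=True)
class PglsResult:
    """Generalized least squares fit under a Brownian covariance."""

    coefficients: pd.Series
    std_errors: pd.Series
    r_squared: float
    model_p: float
    f_statistic: float
    log_likelihood: float
    n: int


def pgls_fit(tree: TreeNode, response: pd.Series,
             predictors: pd.DataFrame) -> PglsResult:
    """PGLS of a per-species response on a per-species design.

    b = (X' C^-1 X)^-1 X' C^-1 y with C the Brownian covariance; the model
    p-value is the GLS F-test of all non-intercept terms and R^2 is defined
    on the GLS-whitened scale.
    """
    species = list(response.index)
    x_df = predictors.loc[species]
    cov = brownian_covariance(tree, tips=species)
    c = cov.to_numpy()
    y = response.to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(species)), x_df.to_numpy(dtype=float)])
    names = ["intercept"] + list(x_df.columns)

    try:
        chol = np.linalg.cholesky(c)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular Brownian covariance matrix") from exc
    # whiten: z = L^-1 v so that Cov(L^-1 eps) = sigma^2 I
    yw = solve_triangular(chol, y, lower=True)
    xw = solve_triangular(chol, x, lower=True)

    rank = np.linalg.matrix_rank(xw)
    if rank < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(xw, yw, rcond=None)
    resid = yw - xw @ beta
    n, p = x.shape
    df_resid = n - p
    sigma2 = float(resid @ resid) / df_resid
    xtx_inv = np.linalg.inv(xw.T @ xw)
    se = np.sqrt(np.diag(xtx_inv) * sigma2)

    # null model: intercept only, same whitening
    x0w = xw[:, :1]
    beta0, _, _, _ = np.linalg.lstsq(x0w, yw, rcond=None)
    resid0 = yw - x0w @ beta0
    rss = float(resid @ resid)
    rss0 = float(resid0 @ resid0)
    q = p - 1
    if q == 0 or rss == 0:
        f_stat, model_p = np.nan, np.nan
    else:
        f_stat = ((rss0 - rss) / q) / (rss / df_resid)
        model_p = float(stats.f.sf(f_stat, q, df_resid))
    r2 = 1.0 - rss / rss0 if rss0 > 0 else np.nan

    # Brownian-GLS log-likelihood with sigma^2 profiled at rss/n
    sign, logdet = np.linalg.slogdet(c)
    sigma2_ml = rss / n
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet + n)

    return PglsResult(
        coefficients=pd.Series(beta, index=names),
        std_errors=pd.Series(se, index=names),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        model_p=model_p,
        f_statistic=f_stat,
        log_likelihood=float(loglik),
        n=n,
    )


@dataclass(frozen=True)
class PglsScreenResult:
    """A family of PGLS fits with BH-adjusted model p-values."""

    results: dict[str, PglsResult]
    adjusted_p: pd.Series
    skipped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, res in self.results.items():
            rows.append({
                "response": name,
                "r_squared": res.r_squared,
                "p": res.model_p,
                "adjusted_p": self.adjusted_p[name],
            })
        return pd.DataFrame(rows)


def pgls_screen(tree: TreeNode, responses: pd.DataFrame,
                diet_design: pd.DataFrame) -> PglsScreenResult:
    """Fit PGLS per response column and BH-adjust model p within the family.

    ``responses`` is species x responses (one family: e.g. alpha metrics,
    the first k PCoA eigenvectors, or per-OTU presence); zero-variance
    responses are skipped with a log message.
    """
    results: dict[str, PglsResult] = {}
    skipped: list[str] = []
    for col in responses.columns:
        y = responses[col].astype(float)
        if np.ptp(y.to_numpy()) == 0:
            logger.info("response %s has zero variance; skipped", col)
            skipped.append(str(col))
            continue
        results[str(col)] = pgls_fit(tree, y, diet_design)
    if not results:
        return PglsScreenResult(results={}, adjusted_p=pd.Series(dtype=float),
                                skipped=skipped)
    raw = pd.Series({k: v.model_p for k, v in results.items()})
    adj = pd.Series(bh_adjust(raw.to_numpy()), index=raw.index)
    return PglsScreenResult(results=results, adjusted_p=adj, skipped=skipped)


# ---------------------------------------------------------------------------
# Diet residualization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidualMatrix:
    """Species x OTUs residuals from binomial regression of presence on diet.

    ``fallback`` marks OTUs where perfect separation forced response
    residuals; ``skipped`` lists all-present/all-absent OTUs excluded from
    downstream signal tests.
    """

    residuals: pd.DataFrame
    fallback: list[str]
    skipped: list[str]


def regress_out_diet(presence: pd.DataFrame, diet_design: pd.DataFrame,
                     trials: pd.Series | None = None) -> ResidualMatrix:
    """Regress diet out of OTU presence by binomial regression.

    Per OTU, presence ~ diet is fit as a binomial GLM and deviance
    residuals are returned.  ``presence`` may be binary (one observation
    per row) or per-species prevalence proportions in [0, 1]; in the
    latter case ``trials`` gives the number of samples behind each row
    and enters the GLM as variance weights.  On perfect separation the
    fit is replaced by response residuals (presence - fitted probability)
    and flagged.  All-present or all-absent OTUs yield zero-variance
    residuals and are listed in ``skipped``.
    """
    x = sm.add_constant(diet_design.loc[presence.index].astype(float), has_constant="add")
    var_weights = (trials.loc[presence.index].to_numpy(dtype=float)
                   if trials is not None else None)
    resid = pd.DataFrame(index=presence.index, columns=presence.columns,
                         dtype=float)
    fallback: list[str] = []
    skipped: list[str] = []
    for otu in presence.columns:
        y = presence[otu].astype(float).to_numpy()
        if y.min() == y.max():
            resid[otu] = 0.0
            skipped.append(str(otu))
            continue
        separated = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.GLM(y, x, family=sm.families.Binomial(),
                             var_weights=var_weights).fit(maxiter=50)
                mu = np.asarray(fit.mu)
                # perfect separation: fitted probabilities pinned at the data
                if np.all(np.abs(y - mu) < 1e-6) or not np.all(np.isfinite(fit.params)):
                    separated = True
            except Exception:
                separated = True
                mu = None
        if separated:
            if mu is None:
                mu = np.full_like(y, y.mean())
            resid[otu] = y - mu
            fallback.append(str(otu))
            logger.info("OTU %s: perfect separation, response residuals used", otu)
        else:
            resid[otu] = np.asarray(fit.resid_deviance)
    return ResidualMatrix(residuals=resid, fallback=fallback, skipped=skipped)


# ---------------------------------------------------------------------------
# LIPA
# ---------------------------------------------------------------------------

def phylo_proximity_weights(tree: TreeNode, tips=None) -> pd.DataFrame:
    """Row-normalized inverse-patristic proximity weights (W_ii = 0)."""
    dm = tree.tip_tip_distances()
    if tips is not None:
        dm = dm.filter(list(tips))
    d = np.asarray(dm.data, dtype=float)
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    w = w / w.sum(axis=1, keepdims=True)
    return pd.DataFrame(w, index=list(dm.ids), columns=list(dm.ids))


def local_morans_i(trait: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Local Moran's I per tip: I_i = (z_i / m2) * sum_j W_ij z_j."""
    z = trait - trait.mean()
    m2 = float(z @ z) / len(z)
    if m2 == 0:
        raise ValueError("constant trait")
    return (z / m2) * (weights @ z)


def lipa(tree_or_weights, trait: pd.Series, n_perm: int = 9999,
         seed: int = 0) -> pd.DataFrame:
    """Local phylogenetic signal (local Moran's I) per host tip.

    The null permutes trait values across tips; the test is one-sided for
    positive local autocorrelation (clustering), with the (+1)/(n_perm+1)
    estimator.  Returns a frame indexed by tip with columns I and p.
    """
    if isinstance(tree_or_weights, TreeNode):
        w_df = phylo_proximity_weights(tree_or_weights, tips=list(trait.index))
    else:
        w_df = tree_or_weights
    tips = list(trait.index)
    w = w_df.loc[tips, tips].to_numpy()
    x = trait.to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 tips")
    i_obs = local_morans_i(x, w)

    rng = np.random.default_rng(seed)
    n = len(x)
    z = x - x.mean()
    m2 = float(z @ z) / n
    perms = rng.random((n_perm, n)).argsort(axis=1)
    zp = z[perms]                                  # n_perm x n
    i_perm = (zp / m2) * (zp @ w.T)
    count = (i_perm >= i_obs[None, :]).sum(axis=0)
    p = (count + 1.0) / (n_perm + 1.0)
    return pd.DataFrame({"I": i_obs, "p": p}, index=tips)


@dataclass(frozen=True)
class LipaResult:
    """Per (tip, OTU) local Moran's I with permutation p and significance.

    ``otu_p`` summarizes each OTU across tips with a global Moran's I
    permutation test: the mean of the local I values (which equals the
    global Moran's I under the same weights) compared to its own
    permutation distribution.  This one-number-per-OTU test accumulates
    diffuse signal across tips and is the OTU-level significance call;
    the per-cell values localize the signal to host tips.
    """

    i_values: pd.DataFrame        # tips x OTUs
    p_values: pd.DataFrame        # tips x OTUs
    significant: pd.DataFrame     # tips x OTUs boolean, raw p < alpha
    otu_p: pd.Series              # per OTU, global Moran's I permutation p
    n_perm: int
    alpha: float
    excluded: list[str] = field(default_factory=list)

    def significant_otus(self) -> list[str]:
        """OTUs whose global Moran's I permutation p is below alpha."""
        return [str(o) for o in self.otu_p.index if self.otu_p[o] < self.alpha]

    def to_frame(self) -> pd.DataFrame:
        long = []
        for otu in self.i_values.columns:
            for tip in self.i_values.index:
                long.append({
                    "otu": otu, "tip": tip,
                    "I": self.i_values.loc[tip, otu],
                    "p": self.p_values.loc[tip, otu],
                    "significant": bool(self.significant.loc[tip, otu]),
                })
        return pd.DataFrame(long)


def lipa_screen(tree: TreeNode, residuals: ResidualMatrix | pd.DataFrame,
                n_perm: int = 9999, seed: int = 0,
                alpha: float = 0.05) -> LipaResult:
    """Apply LIPA per OTU to its diet-residualized presence vector.

    Zero-variance residual columns (e.g. all-present OTUs) are excluded and
    logged.  Cell significance is raw p < alpha; family-level control is
    the sensitivity framework's job.
    """
    res = residuals.residuals if isinstance(residuals, ResidualMatrix) else residuals
    tips = list(res.index)
    w_df = phylo_proximity_weights(tree, tips=tips)
    w = w_df.loc[tips, tips].to_numpy()
    n = len(tips)

    rng = np.random.default_rng(seed)
    i_cols, p_cols, otu_p, excluded = {}, {}, {}, []
    for otu in res.columns:
        x = res[otu].to_numpy(dtype=float)
        z = x - x.mean()
        m2 = float(z @ z) / n
        if m2 == 0:
            excluded.append(str(otu))
            logger.info("OTU %s: zero-variance residuals, excluded from LIPA", otu)
            continue
        i_obs = (z / m2) * (w @ z)
        perms = rng.random((n_perm, n)).argsort(axis=1)
        zp = z[perms]
        i_perm = (zp / m2) * (zp @ w.T)
        count = (i_perm >= i_obs[None, :]).sum(axis=0)
        i_cols[otu] = i_obs
        p_cols[otu] = (count + 1.0) / (n_perm + 1.0)
        # OTU-level call: global Moran's I (= mean local I) against its
        # permutation distribution
        global_count = int((i_perm.mean(axis=1) >= i_obs.mean()).sum())
        otu_p[otu] = (global_count + 1.0) / (n_perm + 1.0)
    i_df = pd.DataFrame(i_cols, index=tips)
    p_df = pd.DataFrame(p_cols, index=tips)
    return LipaResult(
        i_values=i_df, p_values=p_df, significant=p_df < alpha,
        otu_p=pd.Series(otu_p, dtype=float), n_perm=n_perm, alpha=alpha,
        excluded=excluded,
    )
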