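"""Cophylogeny tests: PACo (Procrustes) and Parafit (cross-products).

Both tests ask whether host and symbiont phylogenetic distances are more
congruent, through the observed host-symbiont associations, than expected
under a null model.  PACo superimposes the symbiont ordination onto the
host ordination (least-squares Procrustes over the association links) and
uses a quasiswap null that preserves the association matrix's row and
column sums — a symmetric, conservative null that does not assume either
partner tracks the other.  Parafit sums squared entries of the
principal-coordinate cross-product through the association matrix and
permutes each symbiont's host associations independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from skbio import DistanceMatrix

from .diversity import pcoa


# ---------------------------------------------------------------------------
# Association matrix
# ---------------------------------------------------------------------------

def validate_association(a: pd.DataFrame) -> pd.DataFrame:
    """Hosts x symbionts binary association matrix with no empty rows/cols."""
    vals = a.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("association matrix must be binary")
    if (vals.sum(axis=1) == 0).any():
        raise ValueError("association matrix has an all-zero host row")
    if (vals.sum(axis=0) == 0).any():
        raise ValueError("association matrix has an all-zero symbiont column")
    return a.astype(int)


# ---------------------------------------------------------------------------
# quasiswap null
# ---------------------------------------------------------------------------

def quasiswap_null(a: pd.DataFrame, n_matrices: int, seed: int = 0,
                   burnin_factor: int = 10, thin_factor: int = 2):
    """Generate binary matrices with exactly A's row and column sums.

    A checkerboard-swap Markov chain started at A (itself a margin-
    respecting fill): a 2x2 submatrix of the form [[1,0],[0,1]] or
    [[0,1],[1,0]] is swapped to the other form, which preserves all
    margins.  ``burnin_factor * #1s`` attempted swaps precede the first
    draw and ``thin_factor * #1s`` attempted swaps separate draws.
    Yields DataFrames; deterministic given ``seed``.
    """
    a = validate_association(a)
    m = a.to_numpy().copy()
    n_rows, n_cols = m.shape
    fill = int(m.sum())
    rng = np.random.default_rng(seed)
    burnin = burnin_factor * fill
    thin = max(thin_factor * fill, 1)

    def attempt_swaps(k: int) -> None:
        rows = rng.integers(0, n_rows, size=2 * k).reshape(k, 2)
        cols = rng.integers(0, n_cols, size=2 * k).reshape(k, 2)
        for t in range(k):
            r1, r2 = rows[t]
            c1, c2 = cols[t]
            if r1 == r2 or c1 == c2:
                continue
            x11, x12 = m[r1, c1], m[r1, c2]
            x21, x22 = m[r2, c1], m[r2, c2]
            if x11 == x22 and x12 == x21 and x11 != x12:
                m[r1, c1], m[r2, c2] = x12, x12
                m[r1, c2], m[r2, c1] = x11, x11

    attempt_swaps(burnin)
    for _ in range(n_matrices):
        attempt_swaps(thin)
        yield pd.DataFrame(m.copy(), index=a.index, columns=a.columns)


# ---------------------------------------------------------------------------
# PACo
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PacoResult:
    """Global Procrustes fit and per-link residuals."""

    m2: float
    p: float
    residuals: pd.Series        # indexed by (host, symbiont), sqrt of squared residual
    n_perm: int
    seed: int

    def residuals_frame(self) -> pd.DataFrame:
        df = self.residuals.rename("residual").reset_index()
        df.columns = ["host", "symbiont", "residual"]
        return df


def _procrustes_m2(x: np.ndarray, y: np.ndarray,
                   per_row: bool = False):
    """Least-squares superimposition of y onto x.

    Translation, rotation/reflection and scaling of y minimizing
    ||x - s y R||^2; returns the residual sum of squares (and per-row
    squared residuals when requested).
    """
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    k = max(xc.shape[1], yc.shape[1])
    if xc.shape[1] < k:
        xc = np.hstack([xc, np.zeros((xc.shape[0], k - xc.shape[1]))])
    if yc.shape[1] < k:
        yc = np.hstack([yc, np.zeros((yc.shape[0], k - yc.shape[1]))])
    u, s, vt = np.linalg.svd(yc.T @ xc)
    yy = float((yc * yc).sum())
    if yy == 0:
        raise ValueError("degenerate symbiont configuration")
    scale = s.sum() / yy
    rot = u @ vt
    fitted = scale * (yc @ rot)
    diff = xc - fitted
    sq = (diff * diff).sum(axis=1)
    m2 = float(sq.sum())
    if per_row:
        return m2, sq
    return m2


def paco(host_d: DistanceMatrix, symbiont_d: DistanceMatrix,
         association: pd.DataFrame, n_perm: int = 1000,
         seed: int = 0) -> PacoResult:
    """Procrustean approach to cophylogeny with quasiswap null.

    Both distance matrices are ordinated by Cailliez-corrected PCoA; paired
    coordinate matrices are built with one row per association link (host
    coordinates vs symbiont coordinates) and the symbiont configuration is
    superimposed onto the host configuration.  The global statistic m^2 is
    the residual sum of squares; small m^2 means congruence, so
    p = (#{m2_perm <= m2_obs} + 1) / (n_perm + 1).
    """
    a = validate_association(association)
    hosts = list(a.index)
    symbionts = list(a.columns)
    h_ord = pcoa(host_d.filter(hosts), cailliez=True)
    s_ord = pcoa(symbiont_d.filter(symbionts), cailliez=True)
    h_coords = h_ord.coordinates.to_numpy()
    s_coords = s_ord.coordinates.to_numpy()
    if min(h_coords.shape[0], s_coords.shape[0]) < 2:
        raise ValueError("degenerate configuration: fewer than 2 points")

    amat = a.to_numpy()
    rows, cols = np.nonzero(amat)
    m2_obs, sq = _procrustes_m2(h_coords[rows], s_coords[cols], per_row=True)
    links = pd.MultiIndex.from_arrays(
        [[hosts[i] for i in rows], [symbionts[j] for j in cols]],
        names=["host", "symbiont"])
    residuals = pd.Series(np.sqrt(sq), index=links, name="residual")

    count = 0
    for a_perm in quasiswap_null(a, n_perm, seed=seed):
        r, c = np.nonzero(a_perm.to_numpy())
        m2_perm = _procrustes_m2(h_coords[r], s_coords[c])
        if m2_perm <= m2_obs:
            count += 1
    p = (count + 1.0) / (n_perm + 1.0)
    return PacoResult(m2=m2_obs, p=p, residuals=residuals,
                      n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Parafit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParafitResult:
    """Global and per-link Parafit statistics with permutation p-values."""

    statistic: float
    p: float
    link_statistics: pd.Series   # indexed by (host, symbiont)
    link_p: pd.Series
    n_perm: int
    seed: int


def parafit(host_d: DistanceMatrix, symbiont_d: DistanceMatrix,
            association: pd.DataFrame, n_perm: int = 1000,
            seed: int = 0) -> ParafitResult:
    """Parafit global and per-link cophylogeny test.

    With B the host and C the symbiont Cailliez-corrected principal
    coordinates, the global statistic is the sum of squared entries of
    D = C' A' B.  The null permutes, independently for each symbiont, its
    row of associations across hosts; large statistics indicate
    congruence.  The per-link statistic is the global statistic minus the
    statistic with that link removed, tested against the same permutation
    stream.
    """
    a = validate_association(association)
    hosts = list(a.index)
    symbionts = list(a.columns)
    b = pcoa(host_d.filter(hosts), cailliez=True).coordinates.to_numpy()
    c = pcoa(symbiont_d.filter(symbionts), cailliez=True).coordinates.to_numpy()
    amat = a.to_numpy().astype(float)

    def global_stat(mat: np.ndarray) -> tuple[float, np.ndarray]:
        d = c.T @ mat.T @ b                      # k_s x k_h
        return float((d * d).sum()), d

    def link_stats(mat: np.ndarray, d: np.ndarray, g: float,
                   link_rows: np.ndarray, link_cols: np.ndarray) -> np.ndarray:
        # removing link (h, s) subtracts the outer product c_s b_h' from D:
        # stat_without = g - 2 c_s' D b_h + |c_s|^2 |b_h|^2
        cs = c[link_cols]                        # L x k_s
        bh = b[link_rows]                        # L x k_h
        cross = np.einsum("lk,kj,lj->l", cs, d, bh)
        norms = (cs * cs).sum(axis=1) * (bh * bh).sum(axis=1)
        stat_without = g - 2.0 * cross + norms
        return g - stat_without                  # per-link contribution

    g_obs, d_obs = global_stat(amat)
    rows, cols = np.nonzero(amat)
    ls_obs = link_stats(amat, d_obs, g_obs, rows, cols)

    rng = np.random.default_rng(seed)
    n_hosts = len(hosts)
    count_global = 0
    count_link = np.zeros(len(rows))
    for _ in range(n_perm):
        perm_mat = np.empty_like(amat)
        perms = [rng.permutation(n_hosts) for _ in range(len(symbionts))]
        for j, perm in enumerate(perms):
            perm_mat[:, j] = amat[perm, j]
        g_perm, d_perm = global_stat(perm_mat)
        if g_perm >= g_obs:
            count_global += 1
        # track each original link through its symbiont's permutation
        perm_rows = np.empty(len(rows), dtype=int)
        for idx, (h, s) in enumerate(zip(rows, cols)):
            perm_rows[idx] = np.argmax(perms[s] == h)
        ls_perm = link_stats(perm_mat, d_perm, g_perm, perm_rows, cols)
        count_link += ls_perm >= ls_obs

    links = pd.MultiIndex.from_arrays(
        [[hosts[i] for i in rows], [symbionts[j] for j in cols]],
        names=["host", "symbiont"])
    return ParafitResult(
        statistic=g_obs,
        p=(count_global + 1.0) / (n_perm + 1.0),
        link_statistics=pd.Series(ls_obs, index=links, name="statistic"),
        link_p=pd.Series((count_link + 1.0) / (n_perm + 1.0), index=links,
                         name="p"),
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# residual group comparison
# ---------------------------------------------------------------------------

def residual_group_comparison(residuals: pd.Series,
                              host_class: pd.Series,
                              host_diet: pd.Series) -> pd.DataFrame:
    """Two-factor ANOVA of per-link Procrustes residuals on class and diet.

    ``residuals`` is keyed by (host, symbiont); ``host_class`` and
    ``host_diet`` map hosts to their class and general diet.  Returns a
    frame with per-factor F and p.
    """
    hosts = residuals.index.get_level_values("host")
    df = pd.DataFrame({
        "residual": residuals.to_numpy(),
        "host_class": host_class.loc[hosts].to_numpy(),
        "diet": host_diet.loc[hosts].to_numpy(),
    })
    counts_class = df.groupby("host_class").size()
    counts_diet = df.groupby("diet").size()
    if (len(counts_class) < 2 and len(counts_diet) < 2):
        raise ValueError("need at least 2 groups in class or diet")
    model = smf.ols("residual ~ C(host_class) + C(diet)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = table.rename(index={"C(host_class)": "host_class",
                              "C(diet)": "diet"})
    return out[["F", "PR(>F)"]].rename(columns={"PR(>F)": "p"}).drop(
        index="Residual")
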