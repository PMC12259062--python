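"""Per-trio mixed-effects regression and putative-transport-trio (PTT) calling.

For a trio (protein m, coding gene g, ICT gene t) within one phenotype group,
the surface-protein abundance is modeled as

    E_{m,c} = eta0 + eta1 * X_{g,c} + eta2 * X_{t,c} + sum_j zeta_j V_{j,c}
              + u_{s(c)} + eps_c,      u_s ~ N(0, sigma_u^2), eps ~ N(0, sigma_eps^2)

with a random intercept per sample absorbing the non-independence of cells
from one donor.  Estimation is restricted maximum likelihood; the test of
interest is a Wald z-test on eta2 (does the transport gene's transcription
predict protein abundance beyond the coding gene's own transcription?).
Trios significant at Benjamini-Hochberg FDR < 0.05 within a phenotype group
are flagged as putative transport trios.

A reduced model dropping the ICT term quantifies what the transport gene
adds; per (protein, gene) pair the full model is summarized by the maximum
eta1, the minimum p(eta1) and the mean R^2 across that pair's trios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .dataset import CiteSeqDataset, DatasetError
from .stats import bh_adjust
from .trios import Trio, TrioCatalog

__all__ = [
    "PttFit",
    "fit_trio",
    "fit_pair_reduced",
    "scan_trios",
    "compare_reduced",
    "summarize_ptt",
]

PTT_TABLE_COLUMNS = [
    "protein", "coding_gene", "ict_gene", "group",
    "eta0", "eta1", "eta2", "se_eta1", "se_eta2", "p_eta1", "p",
    "fdr", "is_ptt", "sigma_u2", "sigma_e2", "r2", "n_cells", "n_samples",
    "converged",
]


@dataclass
class PttFit:
    """One restricted-ML fit of the trio model."""

    eta0: float
    eta1: float | None          # None in the reduced model? kept for symmetry
    eta2: float | None
    zeta: dict[str, float]
    sigma_u2: float
    sigma_e2: float
    se_eta1: float
    se_eta2: float | None
    p_eta1: float
    p_eta2: float | None
    r2: float
    n_cells: int
    n_samples: int
    converged: bool


def _group_subset(ds: CiteSeqDataset, group: str | None) -> CiteSeqDataset:
    if group is None:
        return ds
    return ds.subset_phenotype(group)


def _design(ds, gene_cols: list[str], covariates: list[str]):
    cols = [np.ones(ds.n_cells)]
    names = ["intercept"]
    for g in gene_cols:
        x = ds.rna[g].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise DatasetError(f"degenerate predictor: {g} is constant in this group")
        cols.append(x)
        names.append(g)
    for v in covariates:
        cols.append(ds.obs[v].to_numpy(dtype=float))
        names.append(v)
    return np.column_stack(cols), names


def _fit_mixed(y, X, names, groups) -> tuple[dict, bool]:
    """REML random-intercept fit; returns coefficient table + converged flag."""
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # retry ladder: the default optimizer occasionally stalls or lands
        # on a spurious boundary iterate; among converged candidates keep
        # the one with the best restricted likelihood
        for method in (None, "powell", "nm"):
            try:
                kw = {} if method is None else {"method": method}
                candidate = sm.MixedLM(y, X, groups=groups).fit(reml=True, **kw)
            except (np.linalg.LinAlgError, ValueError):
                continue
            better = (
                res is None
                or (candidate.converged and not res.converged)
                or (candidate.converged == res.converged
                    and np.isfinite(candidate.llf) and candidate.llf > res.llf)
            )
            if better:
                res = candidate
            if res.converged and method is None:
                break
    if res is None:
        return {}, False
    converged = bool(res.converged)
    k = X.shape[1]
    fe = np.asarray(res.fe_params, dtype=float)[:k]
    se = np.asarray(res.bse, dtype=float)[:k]
    sigma_u2 = float(np.asarray(res.cov_re)[0, 0])
    scale = float(res.scale)
    if sigma_u2 <= 1e-10 * scale:
        # at the sigma_u^2 = 0 boundary GLS reduces exactly to OLS; the
        # optimizer's boundary iterate can instead absorb the group means,
        # so recompute the fixed effects directly
        fe, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ fe
        dof = max(len(y) - k, 1)
        s2 = float(resid @ resid) / dof
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        scale = s2
        sigma_u2 = 0.0
    z = np.divide(fe, se, out=np.full(k, np.nan), where=se > 0)
    p = 2 * sps.norm.sf(np.abs(z))
    # fitted values including the sample intercepts, for conditional R^2;
    # at the sigma_u^2 = 0 boundary the RE covariance is singular and the
    # best predictions are simply zero
    try:
        u = {g: float(np.asarray(v)[0]) for g, v in res.random_effects.items()}
    except (ValueError, np.linalg.LinAlgError):
        u = {}
    fitted = X @ fe + np.array([u.get(g, 0.0) for g in groups])
    if np.std(fitted) > 0 and np.std(y) > 0:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    else:
        r2 = 0.0
    out = {
        "coef": dict(zip(names, fe)),
        "se": dict(zip(names, se)),
        "p": dict(zip(names, p)),
        "sigma_u2": sigma_u2,
        "sigma_e2": scale,
        "r2": r2,
    }
    return out, converged


def fit_trio(
    ds: CiteSeqDataset,
    trio: Trio,
    covariates: list[str] | None = None,
    group: str | None = None,
) -> PttFit:
    """Fit the full trio model within one phenotype group."""
    covariates = list(covariates or [])
    sub = _group_subset(ds, group)
    samples = sub.obs["sample_id"].astype(str).to_numpy()
    n_samples = len(np.unique(samples))
    if n_samples < 2:
        raise DatasetError("need at least 2 samples per group for the random intercept")
    y = sub.adt[trio.protein].to_numpy(dtype=float)
    X, names = _design(sub, [trio.coding_gene, trio.ict_gene], covariates)
    res, converged = _fit_mixed(y, X, names, samples)
    if not res:
        return PttFit(eta0=np.nan, eta1=np.nan, eta2=np.nan, zeta={},
                      sigma_u2=np.nan, sigma_e2=np.nan, se_eta1=np.nan,
                      se_eta2=np.nan, p_eta1=np.nan, p_eta2=np.nan, r2=np.nan,
                      n_cells=sub.n_cells, n_samples=n_samples, converged=False)
    g, t = trio.coding_gene, trio.ict_gene
    return PttFit(
        eta0=res["coef"]["intercept"],
        eta1=res["coef"][g], eta2=res["coef"][t],
        zeta={v: res["coef"][v] for v in covariates},
        sigma_u2=res["sigma_u2"], sigma_e2=res["sigma_e2"],
        se_eta1=res["se"][g], se_eta2=res["se"][t],
        p_eta1=res["p"][g], p_eta2=res["p"][t],
        r2=res["r2"], n_cells=sub.n_cells, n_samples=n_samples,
        converged=converged,
    )


def fit_pair_reduced(
    ds: CiteSeqDataset,
    protein: str,
    coding_gene: str,
    covariates: list[str] | None = None,
    group: str | None = None,
) -> PttFit:
    """Reduced model without the ICT term: E ~ 1 + X_g + V + (1|sample)."""
    covariates = list(covariates or [])
    sub = _group_subset(ds, group)
    samples = sub.obs["sample_id"].astype(str).to_numpy()
    y = sub.adt[protein].to_numpy(dtype=float)
    X, names = _design(sub, [coding_gene], covariates)
    res, converged = _fit_mixed(y, X, names, samples)
    if not res:
        raise DatasetError(f"reduced model failed for pair ({protein}, {coding_gene})")
    return PttFit(
        eta0=res["coef"]["intercept"], eta1=res["coef"][coding_gene], eta2=None,
        zeta={v: res["coef"][v] for v in covariates},
        sigma_u2=res["sigma_u2"], sigma_e2=res["sigma_e2"],
        se_eta1=res["se"][coding_gene], se_eta2=None,
        p_eta1=res["p"][coding_gene], p_eta2=None,
        r2=res["r2"], n_cells=sub.n_cells,
        n_samples=len(np.unique(samples)), converged=converged,
    )


def scan_trios(
    ds: CiteSeqDataset,
    catalog: TrioCatalog,
    group: str | None = None,
    covariates: list[str] | None = None,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Fit every trio in the catalog and call PTTs at BH FDR < ``fdr_level``.

    Non-convergent or degenerate fits are kept in the table with
    ``converged=False`` but excluded from the BH family (an invalid p-value
    would distort the FDR of the others).
    """
    rows = []
    for trio in catalog:
        try:
            fit = fit_trio(ds, trio, covariates=covariates, group=group)
        except DatasetError:
            fit = None
        if fit is None:
            rows.append((trio.protein, trio.coding_gene, trio.ict_gene, group,
                         *(np.nan,) * 12, 0, 0, False))
            continue
        rows.append((
            trio.protein, trio.coding_gene, trio.ict_gene, group,
            fit.eta0, fit.eta1, fit.eta2, fit.se_eta1, fit.se_eta2,
            fit.p_eta1, fit.p_eta2, np.nan, False,
            fit.sigma_u2, fit.sigma_e2, fit.r2, fit.n_cells, fit.n_samples,
            fit.converged,
        ))
    table = pd.DataFrame(rows, columns=PTT_TABLE_COLUMNS)
    ok = table["converged"].fillna(False).astype(bool) & table["p"].notna()
    table.loc[ok, "fdr"] = bh_adjust(table.loc[ok, "p"])
    table["is_ptt"] = ok & (table["fdr"] < fdr_level)
    return table


def compare_reduced(
    ds: CiteSeqDataset,
    catalog: TrioCatalog,
    group: str | None = None,
    covariates: list[str] | None = None,
    ptt_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full-vs-reduced comparison per (protein, coding gene) pair.

    The full model is summarized per pair by the maximum eta1, the minimum
    p(eta1) and the mean R^2 across the pair's converged trios; the reduced
    model drops the ICT term.  Pass a precomputed ``ptt_table`` to reuse the
    full-model fits.
    """
    if ptt_table is None:
        ptt_table = scan_trios(ds, catalog, group=group, covariates=covariates)
    conv = ptt_table[ptt_table["converged"].astype(bool)]
    rows = []
    for (m, g), sub in conv.groupby(["protein", "coding_gene"], sort=True):
        red = fit_pair_reduced(ds, m, g, covariates=covariates, group=group)
        rows.append((
            m, g, len(sub),
            sub["eta1"].max(), sub["p_eta1"].min(), sub["r2"].mean(),
            red.eta1, red.p_eta1, red.r2,
        ))
    return pd.DataFrame(rows, columns=[
        "protein", "coding_gene", "n_trios",
        "full_eta1_max", "full_p_min", "full_r2_mean",
        "reduced_eta1", "reduced_p", "reduced_r2",
    ])


def summarize_ptt(
    tables: dict[str, pd.DataFrame],
    protein_abundance: pd.Series | None = None,
) -> dict:
    """Cross-group PTT summary.

    Counts distinct ICT genes per protein per group, intersects PTT sets
    across groups, and (optionally) correlates mean protein abundance with
    the number of recruited ICT genes.
    """
    if not tables:
        raise DatasetError("need at least one PTT table")
    counts = {}
    ptt_sets = {}
    for name, tab in tables.items():
        hits = tab[tab["is_ptt"].astype(bool)]
        counts[name] = hits.groupby("protein")["ict_gene"].nunique()
        ptt_sets[name] = set(map(tuple, hits[["protein", "coding_gene", "ict_gene"]].to_numpy()))
    inter = set.intersection(*ptt_sets.values()) if ptt_sets else set()
    union = set.union(*ptt_sets.values()) if ptt_sets else set()
    out = {
        "ict_counts": pd.DataFrame(counts).fillna(0).astype(int),
        "n_shared_all_groups": len(inter),
        "n_union": len(union),
        "shared_trios": sorted(inter),
    }
    if protein_abundance is not None:
        merged = out["ict_counts"].sum(axis=1)
        common = merged.index.intersection(protein_abundance.index)
        if len(common) >= 3:
            r, p = sps.pearsonr(protein_abundance.loc[common], merged.loc[common])
            out["abundance_ict_pearson_r"] = float(r)
            out["abundance_ict_pearson_p"] = float(p)
    return out
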