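"""L1-regularized multi-exposure mediation with BIC model selection.

Many ICT genes are evaluated jointly as exposures on one surface-protein
mediator and a binary phenotype outcome:

    E_c = phi0 + sum_t alpha_t X_{t,c} + sigma              (mediator)
    D_c = omega0 + sum_t delta_t X_{t,c} + beta E_c + xi    (outcome)

with the penalty

    P(alpha, delta; lambda) = lambda * w(1,r) * (sum_t |alpha_t| + sum_t |delta_t|),
    w(1,r) = r^{1/4}

applied to the per-exposure effects only; ``beta`` (protein -> phenotype)
and both intercepts are never penalized, so the mediator's influence on the
outcome is always retained.  Because the penalized objective separates over
the two equations — the mediator equation involves only ``alpha``, the
outcome equation only ``(delta, beta)`` — the joint minimizer is the
combination of two independently penalized least-squares problems; both code
paths are implemented and must agree (a tested invariant).

The solver is cyclic coordinate descent with soft-thresholding on centered
data, warm-started along an ascending lambda grid (default 11 points on
[0.005, 0.03]); the selected lambda minimizes

    BIC = n log(RSS_mediator/n) + n log(RSS_outcome/n) + k log(n)

with k = (number of nonzero penalized coefficients) + 3 (beta and the two
intercepts).  Ties break toward the smaller lambda.  The sparsity pattern at
the selected lambda classifies each gene: full (alpha_t beta != 0, delta_t = 0),
partial (both nonzero), null (only delta_t != 0), dropped (both zero).
The regularized fit carries no p-values by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import CiteSeqDataset, DatasetError

__all__ = [
    "MultiMediationFit",
    "PathResult",
    "default_lambda_grid",
    "penalty_weight",
    "filter_strong_effects",
    "fit_multi_mediation",
    "lambda_path",
    "classify_multi",
    "compare_modules",
]

MULTI_CLASSES = ("full", "partial", "null", "dropped")


def penalty_weight(r: int) -> float:
    """Penalty balance weight w(1, r) = r^(1/4); w(1,1) = 1."""
    return float(r) ** 0.25


def default_lambda_grid(n_points: int = 11) -> np.ndarray:
    return np.linspace(0.005, 0.03, n_points)


@dataclass
class MultiMediationFit:
    exposures: list[str]
    phi0: float
    omega0: float
    alpha: np.ndarray
    delta: np.ndarray
    beta: float
    lam: float
    weight: float
    rss_mediator: float
    rss_outcome: float
    n: int
    converged: bool
    n_sweeps: int

    @property
    def support_alpha(self) -> list[str]:
        return [g for g, a in zip(self.exposures, self.alpha) if a != 0.0]

    @property
    def support_delta(self) -> list[str]:
        return [g for g, d in zip(self.exposures, self.delta) if d != 0.0]

    @property
    def k_nonzero(self) -> int:
        return int((self.alpha != 0).sum() + (self.delta != 0).sum())

    @property
    def bic(self) -> float:
        n = self.n
        k = self.k_nonzero + 3
        with np.errstate(divide="ignore"):
            return float(
                n * np.log(self.rss_mediator / n)
                + n * np.log(self.rss_outcome / n)
                + k * np.log(n)
            )


@dataclass
class PathResult:
    fits: list[MultiMediationFit]
    bics: np.ndarray
    selected_index: int
    classification: pd.DataFrame = field(default=None)

    @property
    def selected(self) -> MultiMediationFit:
        return self.fits[self.selected_index]

    @property
    def lambda_star(self) -> float:
        return self.selected.lam

    def path_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lambda": [f.lam for f in self.fits],
            "bic": self.bics,
            "k_nonzero": [f.k_nonzero for f in self.fits],
        })


def _soft(z: float, thr: float) -> float:
    if z > thr:
        return z - thr
    if z < -thr:
        return z + thr
    return 0.0


def _cd_lasso(
    y: np.ndarray,
    Z: np.ndarray,
    penalty: np.ndarray,
    b0: np.ndarray | None = None,
    tol: float = 1e-7,
    max_sweeps: int = 10_000,
    check_objective: bool = False,
) -> tuple[float, np.ndarray, float, bool, int]:
    """Minimize (1/2n)||y - c0 - Z b||^2 + sum_j penalty_j |b_j|.

    ``penalty`` is the absolute per-coefficient threshold (already includes
    lambda and the balance weight; 0 = unpenalized).  Returns
    (intercept, b, rss, converged, sweeps).
    """
    n, k = Z.shape
    zbar = Z.mean(axis=0)
    ybar = y.mean()
    Zc = Z - zbar
    yc = y - ybar
    col_ss = (Zc * Zc).sum(axis=0) / n
    if (col_ss == 0).any():
        raise DatasetError("degenerate predictor: constant column in penalized design")
    b = np.zeros(k) if b0 is None else b0.copy()
    r = yc - Zc @ b

    def objective() -> float:
        return float((r @ r) / (2 * n) + penalty @ np.abs(b))

    prev_obj = objective() if check_objective else None
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        max_delta = 0.0
        for j in range(k):
            bj = b[j]
            rho = (Zc[:, j] @ r) / n + col_ss[j] * bj
            new = _soft(rho, penalty[j]) / col_ss[j]
            if new != bj:
                r += Zc[:, j] * (bj - new)
                b[j] = new
                max_delta = max(max_delta, abs(new - bj))
        if check_objective:
            obj = objective()
            if obj > prev_obj + 1e-10:
                raise AssertionError("coordinate-descent objective increased")
            prev_obj = obj
        if max_delta < tol:
            converged = True
            break
    resid = yc - Zc @ b
    rss = float(resid @ resid)
    intercept = float(ybar - zbar @ b)
    return intercept, b, rss, converged, sweeps


def filter_strong_effects(
    ptt_table: pd.DataFrame,
    protein: str,
    threshold: float = 0.1,
) -> list[str]:
    """ICT genes with |eta2| strictly above ``threshold`` in any PTT of the protein."""
    sub = ptt_table[(ptt_table["protein"] == protein) & ptt_table["is_ptt"].astype(bool)]
    if sub.empty:
        raise DatasetError(f"no PTT rows for protein {protein!r}")
    strong = sub[sub["eta2"].abs() > threshold]
    genes = sorted(strong["ict_gene"].unique())
    if not genes:
        import warnings

        warnings.warn(f"no ICT genes pass |eta2| > {threshold} for {protein}", stacklevel=2)
    return genes


def _prepare(ds: CiteSeqDataset, protein: str, exposures: list[str],
             contrast: tuple[str, str] | None, outcome: np.ndarray | None = None):
    if outcome is not None:
        sub = ds
        d = np.asarray(outcome, dtype=float)
        if len(d) != ds.n_cells:
            raise DatasetError("outcome length does not match the dataset")
    elif contrast is not None:
        ref, case = contrast
        sub = ds.subset_phenotype(ref, case)
        d = (sub.obs["phenotype"].astype(str) == str(case)).to_numpy(dtype=float)
    else:
        raise DatasetError("either contrast or outcome is required")
    if d.min() == d.max():
        raise DatasetError("constant phenotype: one contrast group is empty")
    X = sub.rna[list(exposures)].to_numpy(dtype=float)
    e = sub.adt[protein].to_numpy(dtype=float)
    # z-score exposures and mediator so lambda is scale-free
    sd_x = X.std(axis=0)
    if (sd_x == 0).any():
        bad = [g for g, s in zip(exposures, sd_x) if s == 0]
        raise DatasetError(f"degenerate predictor: constant exposures {bad}")
    X = (X - X.mean(axis=0)) / sd_x
    if e.std() == 0:
        raise DatasetError(f"degenerate mediator: {protein} constant in this contrast")
    e = (e - e.mean()) / e.std()
    return X, e, d


def fit_multi_mediation(
    ds: CiteSeqDataset,
    protein: str,
    exposures: list[str],
    contrast: tuple[str, str] | None,
    lam: float,
    outcome: np.ndarray | None = None,
    weight: float | None = None,
    warm: MultiMediationFit | None = None,
    tol: float = 1e-7,
    max_sweeps: int = 10_000,
    mode: str = "decoupled",
    check_objective: bool = False,
) -> MultiMediationFit:
    """One penalized fit at a fixed lambda.

    ``mode="decoupled"`` solves the mediator and outcome equations as two
    independent penalized problems (they share no parameters);
    ``mode="joint"`` sweeps the concatenated coordinates of both equations
    together.  The two must agree — the objective separates.
    """
    if lam < 0:
        raise DatasetError("lambda must be non-negative")
    exposures = list(exposures)
    r = len(exposures)
    w = penalty_weight(r) if weight is None else float(weight)
    X, e, d = _prepare(ds, protein, exposures, contrast, outcome=outcome)
    n = len(e)
    Z_out = np.column_stack([X, e])
    pen_med = np.full(r, lam * w)
    pen_out = np.append(np.full(r, lam * w), 0.0)  # beta unpenalized

    a0 = warm.alpha.copy() if warm is not None else None
    b0 = np.append(warm.delta, warm.beta) if warm is not None else None

    if mode == "decoupled":
        phi0, alpha, rss_m, conv_a, sw_a = _cd_lasso(
            e, X, pen_med, a0, tol=tol, max_sweeps=max_sweeps, check_objective=check_objective)
        omega0, bd, rss_o, conv_b, sw_b = _cd_lasso(
            d, Z_out, pen_out, b0, tol=tol, max_sweeps=max_sweeps, check_objective=check_objective)
    elif mode == "joint":
        phi0, alpha, rss_m, conv_a, sw_a, omega0, bd, rss_o, conv_b, sw_b = _joint_cd(
            e, X, pen_med, d, Z_out, pen_out, a0, b0, tol=tol, max_sweeps=max_sweeps)
    else:
        raise DatasetError(f"unknown mode {mode!r}")

    return MultiMediationFit(
        exposures=exposures, phi0=phi0, omega0=omega0,
        alpha=alpha, delta=bd[:r], beta=float(bd[r]),
        lam=float(lam), weight=w,
        rss_mediator=rss_m, rss_outcome=rss_o,
        n=n, converged=bool(conv_a and conv_b), n_sweeps=max(sw_a, sw_b),
    )


def _joint_cd(y1, Z1, pen1, y2, Z2, pen2, b1_init, b2_init, tol, max_sweeps):
    """Coordinate descent over the concatenated coordinates of both equations."""
    n = len(y1)
    Z1c, Z2c = Z1 - Z1.mean(axis=0), Z2 - Z2.mean(axis=0)
    y1c, y2c = y1 - y1.mean(), y2 - y2.mean()
    ss1 = (Z1c * Z1c).sum(axis=0) / n
    ss2 = (Z2c * Z2c).sum(axis=0) / n
    b1 = np.zeros(Z1.shape[1]) if b1_init is None else b1_init.copy()
    b2 = np.zeros(Z2.shape[1]) if b2_init is None else b2_init.copy()
    r1 = y1c - Z1c @ b1
    r2 = y2c - Z2c @ b2
    conv = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        max_delta = 0.0
        for j in range(Z1.shape[1]):
            old = b1[j]
            rho = (Z1c[:, j] @ r1) / n + ss1[j] * old
            new = _soft(rho, pen1[j]) / ss1[j]
            if new != old:
                r1 += Z1c[:, j] * (old - new)
                b1[j] = new
                max_delta = max(max_delta, abs(new - old))
        for j in range(Z2.shape[1]):
            old = b2[j]
            rho = (Z2c[:, j] @ r2) / n + ss2[j] * old
            new = _soft(rho, pen2[j]) / ss2[j]
            if new != old:
                r2 += Z2c[:, j] * (old - new)
                b2[j] = new
                max_delta = max(max_delta, abs(new - old))
        if max_delta < tol:
            conv = True
            break
    rss1 = float((y1c - Z1c @ b1) @ (y1c - Z1c @ b1))
    rss2 = float((y2c - Z2c @ b2) @ (y2c - Z2c @ b2))
    i1 = float(y1.mean() - Z1.mean(axis=0) @ b1)
    i2 = float(y2.mean() - Z2.mean(axis=0) @ b2)
    return i1, b1, rss1, conv, sweeps, i2, b2, rss2, conv, sweeps


def lambda_path(
    ds: CiteSeqDataset,
    protein: str,
    exposures: list[str],
    contrast: tuple[str, str] | None,
    grid: np.ndarray | None = None,
    outcome: np.ndarray | None = None,
    **fit_kwargs,
) -> PathResult:
    """Warm-started fits over an ascending lambda grid; select by minimum BIC.

    Ties in BIC break toward the smaller lambda (the less sparse model,
    preserving candidates for the module comparison).  The nonzero count is
    expected to be non-increasing in lambda; violations are logged, not
    raised (with warm starts and finite tolerance small inversions can
    occur on near-tied data).
    """
    grid = default_lambda_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise DatasetError("empty lambda grid")
    grid = np.sort(grid)
    fits: list[MultiMediationFit] = []
    warm = None
    for lam in grid:
        fit = fit_multi_mediation(ds, protein, exposures, contrast, lam,
                                  outcome=outcome, warm=warm, **fit_kwargs)
        fits.append(fit)
        warm = fit
    if not any(f.converged for f in fits):
        raise DatasetError("no lambda produced a converged fit")
    ks = [f.k_nonzero for f in fits]
    if any(k2 > k1 for k1, k2 in zip(ks, ks[1:])):
        import logging

        logging.getLogger(__name__).info(
            "nonzero count not monotone along the lambda path: %s", ks)
    bics = np.array([f.bic if f.converged else np.inf for f in fits])
    sel = int(np.argmin(bics))  # first minimum = smallest lambda on ties
    result = PathResult(fits=fits, bics=bics, selected_index=sel)
    result.classification = classify_multi(result.selected)
    return result


def classify_multi(fit: MultiMediationFit) -> pd.DataFrame:
    """Per-gene mediation label from the sparsity pattern at one fit."""
    labels = []
    for a, dl in zip(fit.alpha, fit.delta):
        ind = a * fit.beta
        if ind != 0 and dl == 0:
            labels.append("full")
        elif ind != 0 and dl != 0:
            labels.append("partial")
        elif ind == 0 and dl != 0:
            labels.append("null")
        else:
            labels.append("dropped")
    return pd.DataFrame({
        "ict_gene": fit.exposures,
        "alpha": fit.alpha,
        "delta": fit.delta,
        "beta": fit.beta,
        "lambda": fit.lam,
        "class": labels,
    })


_M2_TO_COMMON = {"full": "full", "partial": "partial", "none": "null", "not_daICT": "NA"}
_M3_TO_COMMON = {"full": "full", "partial": "partial", "null": "null", "dropped": "NA"}
_ORDER = ["full", "partial", "null", "NA"]


def compare_modules(
    module2_table: pd.DataFrame,
    module3_classification: pd.DataFrame,
) -> dict:
    """Cross-tabulate single- vs multi-exposure mediation classes per ICT gene.

    Rows are the single-exposure classes, columns the regularized classes;
    genes present in one analysis only fall in the NA row/column.  Also
    summarizes |indirect| and |delta| effect sizes from the single-exposure
    fits for genes retained vs dropped by the regularized model.
    """
    m2 = module2_table.set_index("ict_gene")
    m3 = module3_classification.set_index("ict_gene")
    shared = m2.index.intersection(m3.index)
    if len(shared) == 0:
        raise DatasetError("no shared (protein, ICT gene) keys between the two modules")
    all_genes = m2.index.union(m3.index)
    rows, cols = [], []
    for g in all_genes:
        rows.append(_M2_TO_COMMON[m2.loc[g, "class"]] if g in m2.index else "NA")
        cols.append(_M3_TO_COMMON[m3.loc[g, "class"]] if g in m3.index else "NA")
    trans = pd.crosstab(
        pd.Categorical(rows, categories=_ORDER),
        pd.Categorical(cols, categories=_ORDER),
        dropna=False,
    )
    trans.index.name = "module2"
    trans.columns.name = "module3"

    retained_mask = m3.loc[shared, "class"] != "dropped"
    eff = m2.loc[shared]
    summary = pd.DataFrame({
        "mean_abs_indirect": [
            eff.loc[retained_mask.values, "indirect"].abs().mean(),
            eff.loc[~retained_mask.values, "indirect"].abs().mean(),
        ],
        "mean_abs_delta": [
            eff.loc[retained_mask.values, "delta"].abs().mean(),
            eff.loc[~retained_mask.values, "delta"].abs().mean(),
        ],
        "n": [int(retained_mask.sum()), int((~retained_mask).sum())],
    }, index=["retained", "dropped"])
    return {"transitions": trans, "effect_sizes": summary}
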