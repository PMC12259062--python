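"""Single-exposure mediation: ICT transcription -> protein abundance -> phenotype.

For one ICT gene t, one surface protein m and a binary phenotype contrast
(D in {0, 1}, coded per cell from sample-level labels), two least-squares
regressions are fitted on the cells of the two groups:

    E_c = phi0 + alpha * X_{t,c} + sigma            (mediator equation)
    D_c = omega0 + beta * E_c + delta * X_{t,c} + xi  (outcome equation)

``delta`` is the direct effect of the ICT gene on phenotype, ``alpha * beta``
the indirect effect transmitted through the surface protein, and the total
effect is ``delta + alpha * beta`` — identical, in the no-covariate linear
case, to the slope of the single regression D ~ X_t.  The indirect-effect
p-value uses the Sobel (delta-method) standard error by default,
``sqrt(alpha^2 se(beta)^2 + beta^2 se(alpha)^2)``, with a seeded percentile
bootstrap as an option.  The outcome equation is linear even though D is
binary (a linear-probability reading); this is what makes the effect
decomposition exact.

Genes with a significant indirect and/or direct effect at ``level`` are
disease-associated ICT (daICT) genes, classified as:

    full     p(indirect) < level and p(delta) >= level
    partial  both < level
    none     only p(delta) < level
    not_daICT otherwise
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataset import CiteSeqDataset, DatasetError

__all__ = [
    "MediationFit",
    "fit_single_mediation",
    "classify_mediation",
    "scan_mediation",
]

CLASSES = ("full", "partial", "none", "not_daICT")


@dataclass
class MediationFit:
    phi0: float
    alpha: float
    omega0: float
    beta: float
    delta: float
    indirect: float
    total: float
    se_alpha: float
    se_beta: float
    se_delta: float
    se_indirect: float
    p_indirect: float
    p_delta: float
    n: int
    contrast: tuple[str, str]       # (reference label -> 0, case label -> 1)


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least squares with coefficient SEs and two-sided t p-values."""
    n, k = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise DatasetError("singular design in mediation regression")
    resid = y - X @ coef
    dof = n - k
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = np.divide(coef, se, out=np.full(k, np.nan), where=se > 0)
    p = 2 * sps.t.sf(np.abs(t), dof)
    return coef, se, p


def _mediation_core(x: np.ndarray, e: np.ndarray, d: np.ndarray):
    ones = np.ones_like(x)
    c1, s1, p1 = _ols(e, np.column_stack([ones, x]))
    c2, s2, p2 = _ols(d, np.column_stack([ones, e, x]))
    phi0, alpha = c1
    omega0, beta, delta = c2
    se_alpha, se_beta, se_delta = s1[1], s2[1], s2[2]
    indirect = alpha * beta
    se_ind = np.sqrt(alpha ** 2 * se_beta ** 2 + beta ** 2 * se_alpha ** 2)
    if se_ind > 0:
        z = indirect / se_ind
        p_ind = 2 * sps.norm.sf(abs(z))
    else:
        p_ind = 1.0
    return (phi0, alpha, omega0, beta, delta, indirect,
            se_alpha, se_beta, se_delta, se_ind, float(p_ind), float(p2[2]))


def fit_single_mediation(
    ds: CiteSeqDataset,
    trio,
    group_pair: tuple[str, str] | None = None,
    outcome: np.ndarray | None = None,
    bootstrap: int = 0,
    seed: int | None = None,
) -> MediationFit:
    """Fit the two mediation regressions for one trio on a two-group contrast.

    ``group_pair`` is (reference, case): reference cells are coded D=0,
    case cells D=1.  Alternatively pass a per-cell numeric ``outcome``
    (aligned to ``ds``) to fit on a continuous phenotype — the mode used for
    exact coefficient-recovery checks.  With ``bootstrap > 0`` the
    indirect-effect p-value is replaced by a seeded percentile-bootstrap p
    (cells resampled with replacement).
    """
    if outcome is not None:
        sub = ds
        d = np.asarray(outcome, dtype=float)
        if len(d) != ds.n_cells:
            raise DatasetError("outcome length does not match the dataset")
        ref, case = "", "outcome"
    elif group_pair is not None:
        ref, case = group_pair
        sub = ds.subset_phenotype(ref, case)
        pheno = sub.obs["phenotype"].astype(str)
        d = (pheno == str(case)).to_numpy(dtype=float)
    else:
        raise DatasetError("either group_pair or outcome is required")
    if d.min() == d.max():
        raise DatasetError("constant phenotype: one contrast group is empty")
    protein = trio.protein if hasattr(trio, "protein") else trio[0]
    ict = trio.ict_gene if hasattr(trio, "ict_gene") else trio[-1]
    x = sub.rna[ict].to_numpy(dtype=float)
    e = sub.adt[protein].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise DatasetError(f"degenerate predictor: {ict} is constant in this contrast")

    (phi0, alpha, omega0, beta, delta, indirect,
     se_a, se_b, se_d, se_ind, p_ind, p_delta) = _mediation_core(x, e, d)

    if bootstrap:
        rng = np.random.default_rng(seed)
        n = len(x)
        draws = np.empty(bootstrap)
        for b in range(bootstrap):
            idx = rng.integers(0, n, n)
            if d[idx].min() == d[idx].max() or np.std(x[idx]) == 0:
                draws[b] = np.nan
                continue
            draws[b] = _mediation_core(x[idx], e[idx], d[idx])[5]
        draws = draws[~np.isnan(draws)]
        if len(draws):
            # two-sided percentile p: how often the bootstrap indirect crosses 0
            frac = min((draws <= 0).mean(), (draws >= 0).mean())
            p_ind = float(min(1.0, 2 * frac + 2.0 / (len(draws) + 1)))

    return MediationFit(
        phi0=phi0, alpha=alpha, omega0=omega0, beta=beta, delta=delta,
        indirect=indirect, total=delta + indirect,
        se_alpha=se_a, se_beta=se_b, se_delta=se_d, se_indirect=se_ind,
        p_indirect=p_ind, p_delta=p_delta, n=len(x),
        contrast=(str(ref), str(case)),
    )


def classify_mediation(fit: MediationFit, level: float = 0.05) -> str:
    """Classify a fit into full / partial / none mediation or not_daICT."""
    sig_ind = fit.p_indirect < level
    sig_dir = fit.p_delta < level
    if sig_ind and not sig_dir:
        return "full"
    if sig_ind and sig_dir:
        return "partial"
    if sig_dir:
        return "none"
    return "not_daICT"


def scan_mediation(
    ds: CiteSeqDataset,
    ptt_table: pd.DataFrame,
    group_pair: tuple[str, str],
    protein: str | None = None,
    level: float = 0.05,
    adjust: str = "none",
    bootstrap: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run single-exposure mediation for every PTT (protein, ICT gene) pair.

    PTT rows (``is_ptt`` true) are deduplicated on (protein, ICT gene) — the
    mediator equation does not involve the coding gene, so trios differing
    only in the subunit gene give the same model.  Returns one row per pair
    with coefficients, effects, p-values, class and a daICT flag.

    ``adjust="bh"`` applies Benjamini-Hochberg across the scanned genes to
    both p-value families before classification; the default classifies on
    nominal p-values at ``level``.
    """
    if adjust not in ("none", "bh"):
        raise DatasetError(f"unknown adjustment {adjust!r}; use 'none' or 'bh'")
    hits = ptt_table[ptt_table["is_ptt"].astype(bool)]
    if protein is not None:
        hits = hits[hits["protein"] == protein]
    keys = hits[["protein", "ict_gene"]].drop_duplicates()
    rows = []
    fits = []
    for m, t in keys.itertuples(index=False):
        try:
            fit = fit_single_mediation(ds, (m, None, t), group_pair,
                                       bootstrap=bootstrap, seed=seed)
        except DatasetError:
            continue
        fits.append(fit)
        rows.append((m, t, f"{group_pair[1]}_vs_{group_pair[0]}",
                     fit.alpha, fit.beta, fit.delta, fit.indirect, fit.total,
                     fit.se_alpha, fit.se_beta, fit.se_delta, fit.se_indirect,
                     fit.p_indirect, fit.p_delta))
    out = pd.DataFrame(rows, columns=[
        "protein", "ict_gene", "contrast",
        "alpha", "beta", "delta", "indirect", "total",
        "se_alpha", "se_beta", "se_delta", "se_indirect",
        "p_indirect", "p_delta",
    ])
    if adjust == "bh" and len(out):
        from dataclasses import replace

        from .stats import bh_adjust

        out["p_indirect"] = bh_adjust(out["p_indirect"])
        out["p_delta"] = bh_adjust(out["p_delta"])
        fits = [replace(f, p_indirect=pi, p_delta=pdl)
                for f, pi, pdl in zip(fits, out["p_indirect"], out["p_delta"])]
    out["class"] = [classify_mediation(f, level=level) for f in fits]
    out["is_daict"] = out["class"] != "not_daICT"
    return out
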