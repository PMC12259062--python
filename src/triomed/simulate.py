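"""Synthetic paired RNA/ADT data with planted trio and mediation structure.

The generator emulates the generative assumptions of the modeling stack —
Gaussian gene expression on the normalized scale, a sample-level random
intercept on protein abundance, linear mediation links — so that every
module can be exercised with known ground truth:

    X_{t,c}, X_{g,c} ~ N(0, 1)                     (ICT / coding transcription)
    u_s ~ N(0, sigma_u^2)                          (sample random intercept)
    E_c = eta0 + eta1 X_{g,c} + sum_t eta2_t X_{t,c} + u_s + eps_c

Two outcome modes:

``binary_sample``
    Phenotype labels are assigned at the *sample* level (as in a real
    multi-donor study) and effect sizes are realized as group shifts: in
    case samples the ICT channels are shifted by ``x_shift`` and the protein
    by ``protein_shift``.
``continuous_latent``
    A continuous per-cell outcome D_c = omega0 + sum_t delta_t X_{t,c}
    + beta E_c + xi_c is emitted alongside the labels; exact coefficient
    recovery is only well-posed in this mode, which is what the solver
    recovery tests use.

Count emission is Gaussian by default (values are already on the normalized
scale); ``negative_binomial`` emits raw counts from the latent expression for
exercising QC and normalization.  The same seed always reproduces the same
dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import CiteSeqDataset

__all__ = ["SimConfig", "GroundTruth", "simulate_citeseq", "make_fixture", "FIXTURES"]


@dataclass
class SimConfig:
    n_samples: dict[str, int] = field(default_factory=lambda: {"healthy": 4, "severe": 4})
    cells_per_sample: float = 100
    cells_dispersion: float = 0.0   # 0 = exactly cells_per_sample; else Poisson jitter
    n_ict: int = 5
    n_background: int = 5
    n_decoy_proteins: int = 3
    protein: str = "PROT1"
    coding_gene: str = "CODG1"
    eta0: float = 0.0
    eta1: float = 0.5
    eta2: np.ndarray | None = None        # per-ICT effect on the protein; default zeros
    delta: np.ndarray | None = None       # per-ICT direct effect on the outcome
    beta: float = 0.0                     # protein -> outcome
    omega0: float = 0.0
    sigma_u: float = 0.5
    sigma_eps: float = 1.0
    xi_sd: float = 1.0
    x_shift: np.ndarray | None = None     # binary mode: ICT mean shift in case group
    protein_shift: float = 0.0            # binary mode: protein shift in case group
    outcome_mode: str = "binary_sample"   # or "continuous_latent"
    emission: str = "gaussian"            # or "negative_binomial"
    nb_dispersion: float = 0.5
    case_label: str | None = None         # binary mode: which group gets the shifts
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_u", "sigma_eps", "xi_sd", "nb_dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("eta2", "delta", "x_shift"):
            v = getattr(self, name)
            if v is None:
                setattr(self, name, np.zeros(self.n_ict))
            else:
                v = np.asarray(v, dtype=float)
                if v.shape != (self.n_ict,):
                    raise ValueError(f"{name} must have length n_ict={self.n_ict}")
                setattr(self, name, v)
        total = sum(self.n_samples.values()) * max(self.cells_per_sample, 0)
        if total <= 0:
            raise ValueError("infeasible config: zero cells")


@dataclass
class GroundTruth:
    config: SimConfig
    x_ict: np.ndarray           # cells x n_ict latent expression
    x_coding: np.ndarray
    e_latent: np.ndarray
    d_latent: np.ndarray | None
    u: dict[str, float]
    d_code: np.ndarray          # per-cell numeric phenotype code
    ict_genes: list[str]

    def daict_labels(self) -> pd.DataFrame:
        """Mediation class implied by the planted (alpha=eta2, beta, delta)."""
        cfg = self.config
        labels = []
        for a, dl in zip(cfg.eta2, cfg.delta):
            ind = a * cfg.beta
            if ind != 0 and dl == 0:
                labels.append("full")
            elif ind != 0 and dl != 0:
                labels.append("partial")
            elif dl != 0:
                labels.append("null")
            else:
                labels.append("dropped")
        return pd.DataFrame({"ict_gene": self.ict_genes, "class": labels})


def _nb_counts(rng: np.random.Generator, latent: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with mean exp(1 + 0.7 * latent), var = mu + disp * mu^2."""
    mu = np.exp(1.0 + 0.7 * latent)
    if dispersion == 0:
        return rng.poisson(mu).astype(float)
    k = 1.0 / dispersion
    p = k / (k + mu)
    return rng.negative_binomial(k, p).astype(float)


def simulate_citeseq(config: SimConfig) -> tuple[CiteSeqDataset, GroundTruth]:
    """Generate one dataset plus its ground truth from a config."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    labels = sorted(cfg.n_samples)
    codes = {lab: i for i, lab in enumerate(labels)}
    sample_ids, sample_label = [], {}
    for lab in labels:
        for i in range(cfg.n_samples[lab]):
            sid = f"{lab}_s{i}"
            sample_ids.append(sid)
            sample_label[sid] = lab

    cells_sample = []
    for sid in sample_ids:
        if cfg.cells_dispersion == 0:
            n_c = int(cfg.cells_per_sample)
        else:
            n_c = max(1, int(rng.poisson(cfg.cells_per_sample)))
        cells_sample.extend([sid] * n_c)
    cells_sample = np.array(cells_sample)
    n = len(cells_sample)
    cell_ids = [f"cell{i:05d}" for i in range(n)]
    d_code = np.array([codes[sample_label[s]] for s in cells_sample], dtype=float)
    if len(labels) > 1:
        case = cfg.case_label if cfg.case_label is not None else labels[-1]
        if case not in codes:
            raise ValueError(f"case_label {case!r} not among phenotype labels {labels}")
        is_case = (d_code == codes[case]).astype(float)
    else:
        is_case = d_code * 0

    x_ict = rng.normal(size=(n, cfg.n_ict))
    if cfg.outcome_mode == "binary_sample":
        x_ict = x_ict + np.outer(is_case, cfg.x_shift)
    x_g = rng.normal(size=n)
    u_vals = rng.normal(0.0, cfg.sigma_u, size=len(sample_ids))
    u = dict(zip(sample_ids, u_vals))
    eps = rng.normal(0.0, cfg.sigma_eps, size=n)
    e_latent = (cfg.eta0 + cfg.eta1 * x_g + x_ict @ cfg.eta2
                + np.array([u[s] for s in cells_sample]) + eps)
    if cfg.outcome_mode == "binary_sample":
        e_latent = e_latent + cfg.protein_shift * is_case

    d_latent = None
    if cfg.outcome_mode == "continuous_latent":
        xi = rng.normal(0.0, cfg.xi_sd, size=n)
        d_latent = cfg.omega0 + x_ict @ cfg.delta + cfg.beta * e_latent + xi
    elif cfg.outcome_mode != "binary_sample":
        raise ValueError(f"unknown outcome_mode {cfg.outcome_mode!r}")

    ict_genes = [f"ICT{i:03d}" for i in range(cfg.n_ict)]
    bg_genes = [f"BG{i:03d}" for i in range(cfg.n_background)]
    bg = rng.normal(size=(n, cfg.n_background))
    rna_latent = np.column_stack([x_g, x_ict, bg])
    rna_cols = [cfg.coding_gene] + ict_genes + bg_genes

    decoys = [f"DECOY{i}" for i in range(cfg.n_decoy_proteins)]
    adt_latent = np.column_stack([e_latent] + [rng.normal(size=n) for _ in decoys]) \
        if decoys else e_latent[:, None]
    adt_cols = [cfg.protein] + decoys

    if cfg.emission == "gaussian":
        rna_vals, adt_vals = rna_latent, adt_latent
        rna_layer = adt_layer = "normalized"
    elif cfg.emission == "negative_binomial":
        rna_vals = _nb_counts(rng, rna_latent, cfg.nb_dispersion)
        adt_vals = _nb_counts(rng, adt_latent, cfg.nb_dispersion)
        rna_layer = adt_layer = "counts"
    else:
        raise ValueError(f"unknown emission {cfg.emission!r}")

    rna = pd.DataFrame(rna_vals, index=cell_ids, columns=rna_cols)
    adt = pd.DataFrame(adt_vals, index=cell_ids, columns=adt_cols)
    obs = pd.DataFrame({
        "sample_id": cells_sample,
        "phenotype": [sample_label[s] for s in cells_sample],
    }, index=pd.Index(cell_ids, name="cell_id"))
    if d_latent is not None:
        obs["D_latent"] = d_latent

    ds = CiteSeqDataset(rna=rna, adt=adt, obs=obs,
                        rna_layer=rna_layer, adt_layer=adt_layer,
                        phenotype_codes=codes)
    truth = GroundTruth(config=cfg, x_ict=x_ict, x_coding=x_g, e_latent=e_latent,
                        d_latent=d_latent, u=u, d_code=d_code, ict_genes=ict_genes)
    return ds, truth


# ----------------------------------------------------------------------
# fixture registry: deterministic small datasets shared across the tests
def _tiny_null(seed: int) -> SimConfig:
    return SimConfig(
        n_samples={"healthy": 2, "severe": 2}, cells_per_sample=50,
        n_ict=4, n_background=4, eta1=0.0, sigma_u=0.3, seed=seed,
    )


def _one_strong_trio(seed: int) -> SimConfig:
    eta2 = np.zeros(10)
    eta2[0] = 1.0
    return SimConfig(
        n_samples={"healthy": 8}, cells_per_sample=100,
        n_ict=10, n_background=5, eta1=0.5, eta2=eta2,
        sigma_u=0.5, sigma_eps=1.0, seed=seed,
    )


def _sparse_mediation_20(seed: int) -> SimConfig:
    eta2 = np.zeros(20)
    delta = np.zeros(20)
    eta2[:3] = 0.5
    delta[:3] = 0.4
    return SimConfig(
        n_samples={"healthy": 4, "severe": 4}, cells_per_sample=250,
        n_ict=20, n_background=5, eta1=0.3, eta2=eta2, delta=delta,
        beta=0.5, sigma_u=0.1, sigma_eps=1.0, xi_sd=1.0,
        outcome_mode="continuous_latent", seed=seed,
    )


FIXTURES = {
    "tiny-null": _tiny_null,
    "one-strong-trio": _one_strong_trio,
    "sparse-mediation-20": _sparse_mediation_20,
}


def make_fixture(name: str, seed: int = 0) -> tuple[CiteSeqDataset, GroundTruth]:
    """Build a registered fixture dataset; deterministic in (name, seed)."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    return simulate_citeseq(FIXTURES[name](seed))
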