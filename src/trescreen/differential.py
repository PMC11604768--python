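"""Negative-binomial likelihood-ratio testing of promoter activity.

Each promoter is tested for condition-dependent activity by jointly
modelling its barcodes' raw DNA and RNA counts:

* DNA: ``x_js ~ NB(g_s * d_j, alpha_dna)`` — per-barcode plasmid abundances
  ``d_j`` with per-sample depth factors ``g_s`` (upper-quartile scaling;
  batch/condition structure of the plasmid libraries enters through these
  offsets).
* RNA: ``y_js ~ NB(f_s * d_j * exp(beta_{cond(s)}), alpha_rna)`` — the same
  latent abundances scaled by a per-condition transcription effect.

The two matrices are maximized jointly (alternating Newton updates over the
``log d_j`` and the condition effects), so DNA uncertainty propagates into
the test instead of being charged to the RNA dispersion.  The full model has
one free effect per condition; the reduced model a single shared effect.
The RNA dispersion is shared within the promoter and estimated by
Cox-Reid-adjusted profile maximum likelihood under the full model (the
adjustment removes the downward bias induced by the per-barcode nuisance
abundances), then held fixed for the reduced fit, guaranteeing a
nonnegative LRT.  The DNA dispersion is a bias-corrected method-of-moments
estimate; it only weights how strongly the DNA counts pin the abundances.

The LRT statistic ``2 (l_full - l_reduced)`` is referred to a chi-square
with (#conditions - 1) degrees of freedom (Wilks); the natural-log condition
contrast is reported in log base 2.  FDR control is Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .quantify import CountMatrix, upper_quartile_factors

LN2 = float(np.log(2.0))
_ALPHA_FLOOR = 1e-8
_PHI_RNA_BOUNDS = (np.log(1e-6), np.log(50.0))


@dataclass
class ModelSpec:
    """Covariate structure of the DNA and RNA models."""

    with_replicates: bool = True

    @property
    def dna_covariates(self) -> tuple:
        if self.with_replicates:
            return ("barcode", "batch", "condition")
        return ("barcode", "condition")

    @property
    def rna_covariates(self) -> tuple:
        return ("condition",)


def cap_barcodes(barcodes, dna_counts, cap: int = 100) -> list:
    """Retain at most ``cap`` barcodes, the highest by plasmid DNA abundance.

    ``dna_counts`` maps barcode -> total DNA count.  Ties at the cutoff are
    broken toward the lexicographically smaller barcode; deterministic.
    """
    barcodes = list(barcodes)
    if len(barcodes) <= cap:
        return barcodes
    return sorted(barcodes, key=lambda bc: (-dna_counts[bc], bc))[:cap]


def _nb_ll(y, mu, r, gl_y1) -> float:
    return float(
        np.sum(
            gammaln(y + r) - gammaln(r) - gl_y1
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _phi_dna_moments(x: np.ndarray, g: np.ndarray) -> float:
    """Bias-corrected method-of-moments NB dispersion of the DNA counts."""
    S = x.shape[1]
    if S < 2:
        return _ALPHA_FLOOR
    mu = (x / g).mean(axis=1)[:, None] * g[None, :]
    keep = mu[:, 0] > 0
    if not keep.any():
        return _ALPHA_FLOOR
    mu, xx = mu[keep], x[keep]
    num = np.sum(((xx - mu) ** 2 - mu) * (S / (S - 1.0)))
    den = np.sum(mu**2)
    return float(min(max(num / den, _ALPHA_FLOOR), 10.0))


class _JointFitter:
    """Alternating-Newton maximizer of the joint DNA+RNA likelihood for one
    promoter, with warm starts across dispersion-profile evaluations.

    Internally the DNA and RNA matrices are stacked column-wise into a single
    observation matrix with a per-column size parameter, so the abundance
    update is one vectorized Newton step; the degenerate scale direction
    (all log-abundances up, all condition effects down) is removed with an
    explicit one-dimensional DNA-anchored step each round."""

    def __init__(self, x, y, g, f, r1, groups):
        self.x, self.y, self.g, self.f = x, y, g, f
        self.r1 = r1
        self.n_dna = x.shape[1]
        self.groups = groups  # list of boolean masks over RNA columns
        self.z = np.concatenate([x, y], axis=1)
        self.gl_z = gammaln(self.z + 1)
        self.y_groups = [np.ascontiguousarray(y[:, cols]) for cols in groups]
        self.f_groups = [f[cols] for cols in groups]
        self.eta0 = np.log(np.maximum((x / g).mean(axis=1), 0.05))

    def _beta_newton(self, yy, ee, r2, beta):
        for _ in range(12):
            mu = ee * np.exp(beta)
            w = (yy + r2) / (mu + r2)
            gsc = float(np.sum(yy - mu * w))
            h = float(np.sum(r2 * mu * w / (mu + r2)))
            if h <= 0:
                break
            step = min(3.0, max(-3.0, gsc / h))
            beta += step
            if abs(step) < 1e-9:
                break
        return beta

    def fit(self, r2, groups=None, eta=None, betas=None, max_rounds=30):
        x, g, r1 = self.x, self.g, self.r1
        z, n_dna = self.z, self.n_dna
        if groups is None:
            groups, y_groups, f_groups = self.groups, self.y_groups, self.f_groups
        else:
            y_groups = [np.ascontiguousarray(self.y[:, cols]) for cols in groups]
            f_groups = [self.f[cols] for cols in groups]
        eta = self.eta0.copy() if eta is None else eta.copy()
        d = np.exp(eta)
        if betas is None:
            betas = np.array(
                [
                    np.log(
                        max(yy.sum(), 0.5) / max(float(d.sum()) * float(ff.sum()), 1e-12)
                    )
                    for yy, ff in zip(y_groups, f_groups)
                ]
            )
        else:
            betas = betas.copy()
        r_col = np.empty(z.shape[1])
        r_col[:n_dna] = r1
        r_col[n_dna:] = r2
        colscale = np.empty(z.shape[1])
        colscale[:n_dna] = g
        for _ in range(max_rounds):
            biggest = 0.0
            # condition effects given abundances
            d = np.exp(eta)
            for b, (yy, ff) in enumerate(zip(y_groups, f_groups)):
                ee = d[:, None] * ff[None, :]
                new = self._beta_newton(yy, ee, r2, betas[b])
                biggest = max(biggest, abs(new - betas[b]))
                betas[b] = new
            for b, cols in enumerate(groups):
                colscale[n_dna:][cols] = self.f[cols] * np.exp(betas[b])
            # abundances given effects (stacked DNA+RNA Newton, vectorized)
            for _ in range(3):
                mu = np.exp(eta)[:, None] * colscale[None, :]
                w = (z + r_col) / (mu + r_col)
                s = (z - mu * w).sum(axis=1)
                info = (r_col * mu * w / (mu + r_col)).sum(axis=1)
                step = np.clip(s / np.maximum(info, 1e-12), -3.0, 3.0)
                eta = np.clip(eta + step, -20.0, 25.0)
                mx = float(np.max(np.abs(step)))
                biggest = max(biggest, mx)
                if mx < 1e-9:
                    break
            # the scale direction (eta + c, betas - c): anchored by DNA only
            dmat = np.exp(eta)[:, None] * g[None, :]
            c = 0.0
            for _ in range(3):
                mu1 = dmat * np.exp(c)
                w1 = (x + r1) / (mu1 + r1)
                gsc = float(np.sum(x - mu1 * w1))
                h = float(np.sum(r1 * mu1 * w1 / (mu1 + r1)))
                if h <= 0:
                    break
                step = min(3.0, max(-3.0, gsc / h))
                c += step
                if abs(step) < 1e-10:
                    break
            if c != 0.0:
                eta = eta + c
                betas = betas - c
                for b, cols in enumerate(groups):
                    colscale[n_dna:][cols] = self.f[cols] * np.exp(betas[b])
                biggest = max(biggest, abs(c))
            if biggest < 1e-7:
                break
        mu = np.exp(eta)[:, None] * colscale[None, :]
        ll = float(
            np.sum(
                gammaln(z + r_col) - gammaln(r_col) - self.gl_z
                + r_col * np.log(r_col / (r_col + mu))
                + z * np.log(mu / (r_col + mu))
            )
        )
        mu1 = mu[:, :n_dna]
        mu2 = mu[:, n_dna:]
        return eta, betas, ll, mu1, mu2

    def cr_penalty(self, mu1, mu2, r2, groups=None) -> float:
        """0.5 log det of the observed information over the nuisance mean
        parameters (log-abundances and condition effects)."""
        x, y, r1 = self.x, self.y, self.r1
        groups = self.groups if groups is None else groups
        I_d = (r1 * mu1 * (x + r1) / (mu1 + r1) ** 2).sum(axis=1)
        I_d += (r2 * mu2 * (y + r2) / (mu2 + r2) ** 2).sum(axis=1)
        I_d = np.maximum(I_d, 1e-12)
        logdet = float(np.sum(np.log(I_d)))
        for cols in groups:
            I_rna = r2 * mu2[:, cols] * (y[:, cols] + r2) / (mu2[:, cols] + r2) ** 2
            I_bb = float(I_rna.sum())
            I_db = I_rna.sum(axis=1)
            schur = I_bb - float(np.sum(I_db**2 / I_d))
            logdet += np.log(max(schur, 1e-12))
        return 0.5 * logdet


def fit_promoter(
    dna: np.ndarray,
    rna: np.ndarray,
    rna_conditions,
    dna_factors: np.ndarray,
    rna_factors: np.ndarray,
    reference: str,
    spec: ModelSpec | None = None,
) -> dict:
    """Fit the joint NB model for one promoter and run the condition LRT.

    Parameters
    ----------
    dna, rna : arrays of shape (n_barcodes, n_dna) and (n_barcodes, n_rna)
        Raw counts, rows aligned across the two matrices.
    rna_conditions : sequence of condition labels, one per RNA column.
    dna_factors, rna_factors : per-sample depth factors.
    reference : condition against which the log2 fold change is reported.

    Returns a dict with log2_fc, lrt_stat, df, p_value, n_barcodes_used and
    flags.  Barcodes with all-zero DNA are excluded; a promoter with no
    DNA-supported barcode or with all-zero RNA gets an undefined fold change
    and p = 1.
    """
    x = np.asarray(dna, float)
    y = np.asarray(rna, float)
    g = np.asarray(dna_factors, float)
    f = np.asarray(rna_factors, float)
    rna_conditions = np.asarray(rna_conditions)
    conds = [reference] + [c for c in pd.unique(rna_conditions) if c != reference]
    df_lrt = len(conds) - 1
    if df_lrt < 1:
        raise ValueError("need at least two conditions")
    for c in conds:
        if not (rna_conditions == c).any():
            raise ValueError(f"condition {c!r} has no RNA sample")

    keep = (x / g).mean(axis=1) > 0
    base = {
        "log2_fc": np.nan,
        "lrt_stat": 0.0,
        "df": df_lrt,
        "p_value": 1.0,
        "n_barcodes_used": int(keep.sum()),
        "converged": True,
        "all_zero_rna": False,
        "alpha_rna": np.nan,
        "alpha_dna": np.nan,
    }
    if not keep.any():
        base.update(converged=False, all_zero_rna=True)
        return base
    x, y = x[keep], y[keep]
    if y.sum() == 0:
        base["all_zero_rna"] = True
        return base

    phi_dna = _phi_dna_moments(x, g)
    r1 = 1.0 / phi_dna
    groups_full = [rna_conditions == c for c in conds]
    fitter = _JointFitter(x, y, g, f, r1, groups_full)

    state = {"eta": None, "betas": None}

    def neg_apl(log_phi):
        r2 = float(np.exp(-log_phi))
        eta, betas, ll, mu1, mu2 = fitter.fit(
            r2, eta=state["eta"], betas=state["betas"], max_rounds=8
        )
        state["eta"], state["betas"] = eta, betas
        return -(ll - fitter.cr_penalty(mu1, mu2, r2))

    opt = minimize_scalar(
        neg_apl, bounds=_PHI_RNA_BOUNDS, method="bounded",
        options={"xatol": 5e-3},
    )
    phi_rna = float(np.exp(opt.x))
    r2 = 1.0 / phi_rna
    eta_f, betas_f, ll_f, _, _ = fitter.fit(
        r2, eta=state["eta"], betas=state["betas"], max_rounds=40
    )
    groups_red = [np.ones(y.shape[1], dtype=bool)]
    _, _, ll_r, _, _ = fitter.fit(
        r2, groups=groups_red, eta=eta_f, max_rounds=40
    )
    lrt = max(0.0, 2.0 * (ll_f - ll_r))
    ln_fc = betas_f[1] - betas_f[0] if len(conds) == 2 else np.nan
    base.update(
        log2_fc=ln_fc / LN2,
        lrt_stat=lrt,
        p_value=float(chi2.sf(lrt, df_lrt)),
        alpha_rna=phi_rna,
        alpha_dna=phi_dna,
        converged=bool(np.isfinite(lrt)),
    )
    return base


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_differential(
    counts: CountMatrix,
    barcode_to_promoter: dict,
    conditions=None,
    reference=None,
    spec: ModelSpec | None = None,
    cap: int = 100,
) -> pd.DataFrame:
    """Run the differential stage over every promoter in a count matrix.

    Depth factors are computed by upper-quartile scaling separately within
    the DNA and the RNA samples (reference = first sample of each material).
    Returns a DataFrame with one row per promoter, BH-adjusted FDR included.
    """
    dna_samples = counts.samples("DNA")
    rna_samples = counts.samples("RNA")
    if not dna_samples or not rna_samples:
        raise ValueError("need both DNA and RNA samples")
    meta = counts.meta.set_index("sample_id")
    rna_conditions = meta.loc[rna_samples, "condition"].to_numpy()
    if conditions is None:
        conditions = list(pd.unique(rna_conditions))
    if reference is None:
        reference = conditions[0]
    use = np.isin(rna_conditions, conditions)
    rna_samples = [s for s, u in zip(rna_samples, use) if u]
    rna_conditions = rna_conditions[use]

    dna_factors = upper_quartile_factors(counts.values[dna_samples]).to_numpy()
    rna_factors = upper_quartile_factors(counts.values[rna_samples]).to_numpy()

    dna_mat = counts.values[dna_samples].to_numpy(float)
    rna_mat = counts.values[rna_samples].to_numpy(float)
    dna_total = dict(zip(counts.values.index, dna_mat.sum(axis=1)))
    row_of = {bc: i for i, bc in enumerate(counts.values.index)}

    promoter_barcodes: dict = {}
    for bc in counts.values.index:
        prom = barcode_to_promoter.get(bc)
        if prom is not None:
            promoter_barcodes.setdefault(prom, []).append(bc)

    rows = []
    for prom in sorted(promoter_barcodes):
        bcs = cap_barcodes(promoter_barcodes[prom], dna_total, cap=cap)
        idx = [row_of[bc] for bc in bcs]
        res = fit_promoter(
            dna_mat[idx], rna_mat[idx], rna_conditions,
            dna_factors, rna_factors, reference, spec,
        )
        res["promoter_id"] = prom
        rows.append(res)
    out = pd.DataFrame(rows).set_index("promoter_id")
    out["fdr"] = adjust_fdr(out["p_value"].to_numpy())
    cols = [
        "log2_fc", "lrt_stat", "df", "p_value", "fdr",
        "n_barcodes_used", "converged", "all_zero_rna",
    ]
    extra = [c for c in out.columns if c not in cols]
    return out[cols + extra]


def write_results_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t")
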