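"""Bayesian probit threshold animal model on a pedigree.

Sex (male = 1, female = 0) is treated as the indicator that a latent
liability exceeds 0.  For phenotyped individual i,

    l_i = x_i' beta + a_i + m_dam(i) + e_i,    e_i ~ N(0, 1),

with ``a ~ N(0, A sigma2_a)`` over the whole pedigree (A the numerator
relationship matrix) and one maternal effect per dam,
``m ~ N(0, I sigma2_m)``.  The residual variance is fixed at 1: with a
single binary record per individual it is not identifiable and fixing it is
the standard identifiability constraint for the threshold/probit link.

Inference is by data augmentation (Albert–Chib): liabilities are drawn from
truncated normals, then *all* location effects are redrawn jointly.  The
joint draw is computed through a reduced-animal-model factorization:
breeding values of parents (individuals with descendants) are sampled from
the mixed-model equations with terminal Mendelian deviations integrated
into the residual, and the terminal deviations are then drawn from their
exact conditionals.  This factorizes the joint Gaussian of
(beta, a, m) | l and is algebraically identical to a one-shot block draw,
but costs a dense Cholesky of order (n_parents + n_dams + p) instead of a
sparse factorization of the full pedigree each iteration.  Variance
components get scaled-inverse-chi-square updates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp
from scipy.special import ndtr, ndtri

from .pedigree import PedigreeTable, inbreeding_coefficients, mendelian_variance_scale, inverse_relationship

__all__ = [
    "ModelSpec",
    "Prior",
    "MCMCSettings",
    "STUDY_SETTINGS",
    "DESK_SETTINGS",
    "PosteriorSamples",
    "Diagnostics",
    "ThresholdModel",
    "build_model",
    "gibbs_sample",
    "diagnostics",
    "effective_sample_size",
    "potential_scale_reduction",
    "pmcmc",
    "posterior_summary",
    "heritability_liability",
]


@dataclass(frozen=True)
class ModelSpec:
    """Model structure: fixed effects, random effects, fixed residual.

    The intercept is always present.  ``fixed_effects`` may additionally
    name "block" and "parental_origin" (reference level FF when present);
    ``random_effects`` is a subset of {"animal", "dam"}.
    """

    fixed_effects: tuple[str, ...] = ("block", "parental_origin")
    random_effects: tuple[str, ...] = ("animal", "dam")
    residual_variance: float = 1.0

    def __post_init__(self):
        if self.residual_variance <= 0:
            raise ValueError("residual variance must be positive")


@dataclass(frozen=True)
class Prior:
    """Scaled-inverse-chi-square priors (scale V, belief nu) per variance
    component; flat-ish zero-mean normal on fixed effects."""

    v_animal: float = 1.0
    nu_animal: float = 0.002
    v_dam: float = 1.0
    nu_dam: float = 0.002
    beta_variance: float = 1e10

    def __post_init__(self):
        if min(self.v_animal, self.nu_animal, self.v_dam, self.nu_dam) <= 0:
            raise ValueError("prior V and nu must be positive")


@dataclass(frozen=True)
class MCMCSettings:
    n_chains: int = 6
    n_iterations: int = 1_000_000
    burn_in: int = 100_000
    thin: int = 5_000
    seed: Optional[int] = None

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("burn_in must be in [0, n_iterations)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin

    @property
    def total_retained(self) -> int:
        return self.n_chains * self.retained_per_chain


#: The study-scale settings (6 chains x 1M iterations, burn-in 100k, thin
#: 5k -> 1080 retained draws) and a desk-scale default sized for quick runs.
STUDY_SETTINGS = MCMCSettings(n_chains=6, n_iterations=1_000_000, burn_in=100_000, thin=5_000)
DESK_SETTINGS = MCMCSettings(n_chains=2, n_iterations=3_000, burn_in=500, thin=5)


class ThresholdModel:
    """Design matrices and pedigree bookkeeping for the Gibbs sampler."""

    def __init__(self, phenotypes: pd.DataFrame, pedigree: Optional[PedigreeTable], spec: ModelSpec):
        self.spec = spec
        self.pedigree = pedigree
        df = phenotypes.reset_index(drop=True)
        if not set(df["sex"]).issubset({"male", "female"}):
            raise ValueError("phenotype sex must be male or female")
        self.y = (df["sex"] == "male").to_numpy(dtype=np.int8)
        self.ids = df["id"].astype(str).tolist()
        n = len(df)

        # --- fixed-effect design, reference coding
        cols = [np.ones(n)]
        names = ["intercept"]
        for term in spec.fixed_effects:
            if term == "intercept":
                continue
            if term not in df.columns:
                raise ValueError(f"fixed effect {term!r} not in phenotype table")
            levels = sorted(df[term].astype(str).unique())
            if term == "parental_origin" and "FF" in levels:
                levels = ["FF"] + [l for l in levels if l != "FF"]
            if len(levels) < 2:
                warnings.warn(f"fixed effect {term!r} has a single level; dropped")
                continue
            vals = df[term].astype(str).to_numpy()
            for lev in levels[1:]:
                cols.append((vals == lev).astype(float))
                names.append(f"{term}[{lev}]")
        self.X = np.column_stack(cols)
        self.x_names = names
        self.p = self.X.shape[1]

        # --- animal effect via reduced-animal-model bookkeeping
        self.has_animal = "animal" in spec.random_effects
        self.has_dam = "dam" in spec.random_effects
        w_blocks = [sp.csr_matrix(self.X)]
        if self.has_animal:
            if pedigree is None:
                raise ValueError("animal effect requires a pedigree")
            idx = pedigree.index
            for i in self.ids:
                if i not in idx:
                    raise ValueError(f"orphan phenotype: {i!r} not in pedigree")
            row_ped = np.array([idx[i] for i in self.ids])
            parent_ped = sorted(pedigree.parents_of())
            self.n_parents = len(parent_ped)
            pcol = -np.ones(len(pedigree), dtype=np.int64)
            pcol[parent_ped] = np.arange(self.n_parents)
            F = inbreeding_coefficients(pedigree)
            dscale = mendelian_variance_scale(pedigree, F)
            s_idx, d_idx = pedigree.sire_idx, pedigree.dam_idx

            # parent sub-pedigree: ancestrally closed, so links stay inside
            from .pedigree import PedigreeRecord, validate_and_sort

            sub = [pedigree.records[i] for i in parent_ped]
            subped = validate_and_sort(sub)
            # validate_and_sort preserves relative order (already topological)
            assert [r.id for r in subped] == [r.id for r in sub]
            self.App_inv = inverse_relationship(subped).toarray()
            self.par_s_col = np.array([pcol[s_idx[i]] if s_idx[i] >= 0 else -1 for i in parent_ped])
            self.par_d_col = np.array([pcol[d_idx[i]] if d_idx[i] >= 0 else -1 for i in parent_ped])
            self.par_dscale = dscale[parent_ped]

            is_parent_row = pcol[row_ped] >= 0
            self.rowsP = np.where(is_parent_row)[0]
            self.rowP_col = pcol[row_ped[self.rowsP]]
            self.rowsT = np.where(~is_parent_row)[0]
            t_ped = row_ped[self.rowsT]
            self.rowT_scol = np.array([pcol[s_idx[i]] if s_idx[i] >= 0 else -1 for i in t_ped])
            self.rowT_dcol = np.array([pcol[d_idx[i]] if d_idx[i] >= 0 else -1 for i in t_ped])
            self.rowT_d = dscale[t_ped]
            # terminal pedigree members with no phenotype record
            terminal_all = np.setdiff1d(np.arange(len(pedigree)), np.array(parent_ped))
            self.n_unphen_terminal = len(np.setdiff1d(terminal_all, t_ped))
            self.n_ped = len(pedigree)

            rows = np.concatenate([self.rowsP, self.rowsT, self.rowsT])
            colsa = np.concatenate([self.rowP_col, self.rowT_scol, self.rowT_dcol])
            vals = np.concatenate(
                [np.ones(len(self.rowsP)), 0.5 * np.ones(2 * len(self.rowsT))]
            )
            keep = colsa >= 0
            Za = sp.coo_matrix(
                (vals[keep], (rows[keep], colsa[keep])), shape=(n, self.n_parents)
            )
            w_blocks.append(Za.tocsr())
        else:
            self.n_parents = 0
            self.rowsT = np.array([], dtype=np.int64)
            self.rowT_d = np.array([])
            self.n_unphen_terminal = 0
            self.n_ped = 0

        if self.has_dam:
            if "dam" not in df.columns:
                raise ValueError("dam effect requires a 'dam' phenotype column")
            dam_vals = df["dam"]
            known = dam_vals.notna()
            levels = sorted(dam_vals[known].astype(str).unique())
            self.dam_levels = levels
            code = {l: k for k, l in enumerate(levels)}
            self.n_dams = len(levels)
            r = np.where(known)[0]
            c = np.array([code[str(v)] for v in dam_vals[known]])
            Zm = sp.coo_matrix((np.ones(len(r)), (r, c)), shape=(n, self.n_dams))
            w_blocks.append(Zm.tocsr())
        else:
            self.n_dams = 0

        self.W = sp.hstack(w_blocks).tocsr()
        self.dim = self.p + self.n_parents + self.n_dams
        self.n_records = n


def build_model(
    phenotypes: pd.DataFrame,
    pedigree: Optional[PedigreeTable] = None,
    spec: ModelSpec = ModelSpec(),
) -> ThresholdModel:
    """Assemble design matrices and pedigree structures for sampling."""
    return ThresholdModel(phenotypes, pedigree, spec)


def _sample_truncated(rng: np.random.Generator, mean: np.ndarray, male: np.ndarray) -> np.ndarray:
    """Liabilities from N(mean, 1) truncated above 0 (male) or below (female)."""
    u = rng.uniform(size=mean.shape)
    c = ndtr(-mean)  # P(l <= 0)
    q = np.where(male, c + u * (1.0 - c), u * c)
    return mean + ndtri(np.clip(q, 1e-15, 1.0 - 1e-16))


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, one row block per chain."""

    beta: np.ndarray  # (n_chains, n_kept, p)
    sigma2_a: Optional[np.ndarray]  # (n_chains, n_kept)
    sigma2_m: Optional[np.ndarray]
    x_names: list[str]
    settings: MCMCSettings
    design_matrix: Optional[np.ndarray] = None

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_kept(self) -> int:
        return self.beta.shape[1]

    def parameter_names(self) -> list[str]:
        out = [f"beta:{n}" for n in self.x_names]
        if self.sigma2_a is not None:
            out.append("sigma2_a")
        if self.sigma2_m is not None:
            out.append("sigma2_m")
        return out

    def chains(self, name: str) -> np.ndarray:
        """(n_chains, n_kept) array for one named parameter."""
        if name == "sigma2_a":
            if self.sigma2_a is None:
                raise KeyError(name)
            return self.sigma2_a
        if name == "sigma2_m":
            if self.sigma2_m is None:
                raise KeyError(name)
            return self.sigma2_m
        key = name.removeprefix("beta:")
        if key in self.x_names:
            return self.beta[:, :, self.x_names.index(key)]
        raise KeyError(name)

    def stacked(self, name: str) -> np.ndarray:
        return self.chains(name).reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        n = self.n_chains * self.n_kept
        rows["chain"] = np.repeat(np.arange(1, self.n_chains + 1), self.n_kept)
        for name in self.parameter_names():
            rows[name] = self.stacked(name)
        return pd.DataFrame(rows)


def _log_scale_prior(lam: float, nu: float, v: float) -> float:
    """Log prior density of a signed component scale lambda (sigma2 = lam^2)
    induced by the scaled-inverse-chi-square prior on sigma2."""
    return -(nu + 1.0) * np.log(abs(lam)) - nu * v / (2.0 * lam * lam)


def gibbs_sample(
    model: ThresholdModel,
    settings: MCMCSettings = DESK_SETTINGS,
    prior: Prior = Prior(),
    interweave: bool = True,
) -> PosteriorSamples:
    """Run the data-augmented Gibbs sampler; chains are independent.

    Per iteration: (i) truncated-normal liability draw; (ii) joint draw of
    all location effects (beta, parent breeding values, maternal effects via
    the mixed-model equations; terminal Mendelian deviations from their
    conditionals); (iii) scaled-inverse-chi-square draws of sigma2_a and
    sigma2_m with the residual fixed at 1.

    ``interweave`` adds an ancillarity-sufficiency interweaving step per
    variance component: holding the scaled effects (a / sigma_a, m / sigma_m)
    fixed, the component's scale is re-drawn in the non-centered
    parameterization, where it acts as a regression coefficient, via a
    Metropolis draw whose acceptance ratio carries the exact prior.  This
    breaks the notoriously slow random walk of variance components under
    probit data augmentation and is valid for any prior.
    """
    n_kept = settings.retained_per_chain
    if n_kept < 1:
        raise ValueError("settings retain no draws")
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    beta_out = np.empty((settings.n_chains, n_kept, model.p))
    sa_out = np.empty((settings.n_chains, n_kept)) if model.has_animal else None
    sm_out = np.empty((settings.n_chains, n_kept)) if model.has_dam else None

    W = model.W
    y_male = model.y.astype(bool)
    n = model.n_records
    p, npar, ndam = model.p, model.n_parents, model.n_dams
    dim = model.dim

    for ci, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        theta = np.zeros(dim)
        phi_t = np.zeros(len(model.rowsT))
        sigma2_a = 0.3 if model.has_animal else 0.0
        sigma2_m = 0.1 if model.has_dam else 0.0
        eta_lin = W @ theta
        kept = 0
        for it in range(1, settings.n_iterations + 1):
            # (i) liabilities
            eta = eta_lin.copy()
            if model.has_animal and len(model.rowsT):
                eta[model.rowsT] += phi_t
            liab = _sample_truncated(rng, eta, y_male)

            # (ii) joint location update (terminal deviations marginalized)
            rinv = np.ones(n)
            if model.has_animal and len(model.rowsT):
                rinv[model.rowsT] = 1.0 / (1.0 + model.rowT_d * sigma2_a)
            Wr = W.multiply(rinv[:, None]).tocsr()
            C = (W.T @ Wr).toarray()
            b = W.T @ (rinv * liab)
            C[np.arange(p), np.arange(p)] += 1.0 / prior.beta_variance
            if model.has_animal:
                C[p : p + npar, p : p + npar] += model.App_inv / sigma2_a
            if model.has_dam:
                j = np.arange(p + npar, dim)
                C[j, j] += 1.0 / sigma2_m
            L = la.cholesky(C, lower=True)
            mean = la.cho_solve((L, True), b)
            z = rng.standard_normal(dim)
            theta = mean + la.solve_triangular(L, z, lower=True, trans="T")
            eta_lin = W @ theta

            if model.has_animal and len(model.rowsT):
                w = (model.rowT_d * sigma2_a) * rinv[model.rowsT]
                resid = liab[model.rowsT] - eta_lin[model.rowsT]
                phi_t = w * resid + np.sqrt(w) * rng.standard_normal(len(w))

            # (iii) variance components
            if model.has_animal:
                aP = theta[p : p + npar]
                psi = aP.copy()
                ok = model.par_s_col >= 0
                psi[ok] -= 0.5 * aP[model.par_s_col[ok]]
                ok = model.par_d_col >= 0
                psi[ok] -= 0.5 * aP[model.par_d_col[ok]]
                saa = float(np.sum(psi**2 / model.par_dscale))
                if len(model.rowsT):
                    saa += float(np.sum(phi_t**2 / model.rowT_d))
                if model.n_unphen_terminal:
                    saa += sigma2_a * rng.chisquare(model.n_unphen_terminal)
                dfa = model.n_ped + prior.nu_animal
                sigma2_a = (saa + prior.nu_animal * prior.v_animal) / rng.chisquare(dfa)
            if model.has_dam:
                m = theta[p + npar :]
                dfm = ndam + prior.nu_dam
                sigma2_m = (np.sum(m**2) + prior.nu_dam * prior.v_dam) / rng.chisquare(dfm)

            # (iv) interweaving: redraw each scale in the non-centered frame
            if interweave and (model.has_animal or model.has_dam):
                x_part = model.X @ theta[:p]
                m_row = eta_lin * 0.0
                if model.has_dam:
                    m_row = W[:, p + npar :] @ theta[p + npar :]
                if model.has_animal and sigma2_a > 1e-300:
                    za_part = eta_lin - x_part - m_row
                    a_row = za_part.copy()
                    if len(model.rowsT):
                        a_row[model.rowsT] += phi_t
                    lam = np.sqrt(sigma2_a)
                    u = a_row / lam
                    v = float(u @ u)
                    if v > 0:
                        r = liab - x_part - m_row
                        lam_new = float(u @ r) / v + rng.standard_normal() / np.sqrt(v)
                        if lam_new != 0.0 and np.log(rng.uniform()) < (
                            _log_scale_prior(lam_new, prior.nu_animal, prior.v_animal)
                            - _log_scale_prior(lam, prior.nu_animal, prior.v_animal)
                        ):
                            fac = lam_new / lam
                            theta[p : p + npar] *= fac
                            phi_t = phi_t * fac
                            eta_lin += (fac - 1.0) * za_part
                            sigma2_a = lam_new * lam_new
                if model.has_dam and sigma2_m > 1e-300:
                    m_row = W[:, p + npar :] @ theta[p + npar :]
                    lam = np.sqrt(sigma2_m)
                    u = m_row / lam
                    v = float(u @ u)
                    if v > 0:
                        r = liab - (eta_lin - m_row)
                        if model.has_animal and len(model.rowsT):
                            r = r.copy()
                            r[model.rowsT] -= phi_t
                        lam_new = float(u @ r) / v + rng.standard_normal() / np.sqrt(v)
                        if lam_new != 0.0 and np.log(rng.uniform()) < (
                            _log_scale_prior(lam_new, prior.nu_dam, prior.v_dam)
                            - _log_scale_prior(lam, prior.nu_dam, prior.v_dam)
                        ):
                            fac = lam_new / lam
                            theta[p + npar :] *= fac
                            eta_lin += (fac - 1.0) * m_row
                            sigma2_m = lam_new * lam_new

            if it > settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
                if kept < n_kept:
                    beta_out[ci, kept] = theta[:p]
                    if sa_out is not None:
                        sa_out[ci, kept] = sigma2_a
                    if sm_out is not None:
                        sm_out[ci, kept] = sigma2_m
                    kept += 1
    return PosteriorSamples(
        beta=beta_out,
        sigma2_a=sa_out,
        sigma2_m=sm_out,
        x_names=model.x_names,
        settings=settings,
        design_matrix=model.X,
    )


# ---------------------------------------------------------------------------
# summaries and diagnostics


def _autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n = len(x)
    x = x - x.mean()
    f = np.fft.rfft(x, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[: max_lag + 1].real / n
    if acov[0] == 0:
        return np.zeros(max_lag + 1)
    return acov / acov[0]


def effective_sample_size(x: np.ndarray) -> float:
    """ESS of one chain via Geyer's initial-positive-sequence truncation.

    The integrated autocorrelation time sums lag pairs (rho_2m + rho_2m+1)
    until the first non-positive pair.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.ptp(x) == 0:
        return float(n)
    rho = _autocorr(x, n - 1)
    s = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        s += pair
        t += 2
    tau = max(1.0, 1.0 + 2.0 * s)
    return float(min(n, n / tau))


def potential_scale_reduction(chains: np.ndarray) -> float:
    """PSRF across chains: sqrt(1 + B/(n W)).

    B/n is the variance of chain means and W the mean within-chain
    variance; identical chains give exactly 1.
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    if m < 2:
        raise ValueError("PSRF needs at least two chains")
    W = chains.var(axis=1, ddof=1).mean()
    Bn = chains.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0
    return float(np.sqrt(1.0 + Bn / W))


@dataclass
class Diagnostics:
    """ESS, PSRF and retained-draw autocorrelations per parameter."""

    ess: dict[str, float]
    psrf: dict[str, Optional[float]]
    autocorr: dict[str, np.ndarray]
    total_retained: int


def diagnostics(samples: PosteriorSamples, max_lag: int = 10) -> Diagnostics:
    ess: dict[str, float] = {}
    psrf: dict[str, Optional[float]] = {}
    acf: dict[str, np.ndarray] = {}
    for name in samples.parameter_names():
        ch = samples.chains(name)
        ess[name] = float(min(ch.size, sum(effective_sample_size(c) for c in ch)))
        if ch.shape[0] >= 2:
            psrf[name] = potential_scale_reduction(ch)
        else:
            warnings.warn("single chain: PSRF not computed")
            psrf[name] = None
        acf[name] = np.mean(
            [_autocorr(c, min(max_lag, len(c) - 1))[1:] for c in ch], axis=0
        )
    return Diagnostics(
        ess=ess, psrf=psrf, autocorr=acf, total_retained=samples.n_chains * samples.n_kept
    )


def pmcmc(draws: np.ndarray) -> float:
    """Twice the smaller tail proportion around zero, floored at 1/n."""
    draws = np.asarray(draws)
    n = len(draws)
    if n < 1:
        raise ValueError("need at least one draw")
    lo = min(np.sum(draws > 0), np.sum(draws < 0))
    return float(min(1.0, max(2.0 * lo / n, 1.0 / n)))


@dataclass(frozen=True)
class PosteriorSummary:
    mean: float
    hpd_low: float
    hpd_high: float


def posterior_summary(draws: np.ndarray, prob: float = 0.95) -> PosteriorSummary:
    """Posterior mean and shortest (HPD) interval containing ``prob`` mass."""
    draws = np.sort(np.asarray(draws, dtype=float))
    n = len(draws)
    if n < 10:
        raise ValueError("need at least 10 draws")
    m = max(1, int(np.floor(prob * n)))
    if m >= n:
        m = n - 1
    widths = draws[m:] - draws[: n - m]
    j = int(np.argmin(widths))
    return PosteriorSummary(mean=float(draws.mean()), hpd_low=float(draws[j]), hpd_high=float(draws[j + m]))


def heritability_liability(
    samples: PosteriorSamples,
    mode: str = "random_only",
    design: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-draw latent-scale heritability.

    random_only:  h2 = sa / (sa + sm + 1).
    with_fixed:   h2 = sa / (sa + sm + Var_rows(X beta) + 1), the fixed-effect
    linear-predictor variance over observed design rows recomputed per draw
    so the estimate is not inflated by variance absorbed into fixed effects.
    """
    if samples.sigma2_a is None:
        raise ValueError("samples contain no additive variance component")
    sa = samples.stacked("sigma2_a")
    sm = samples.stacked("sigma2_m") if samples.sigma2_m is not None else np.zeros_like(sa)
    if mode == "random_only":
        vf = 0.0
    elif mode == "with_fixed":
        X = design if design is not None else samples.design_matrix
        if X is None:
            raise ValueError("design required for with_fixed heritability")
        eta = X @ samples.beta.reshape(-1, samples.beta.shape[-1]).T
        vf = eta.var(axis=0, ddof=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return sa / (sa + sm + vf + 1.0)
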