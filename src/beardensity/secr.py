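"""Full-likelihood spatially explicit capture-recapture (SECR).

Detection follows the hazard half-normal model: an animal whose
activity center sits a distance d from a detector accrues detection
hazard lambda(d) = lambda0 * exp(-d^2 / (2 sigma^2)) per occasion, and
is detected with probability g(d) = 1 - exp(-lambda(d)). Activity
centers are latent and marginalized over a gridded habitat mask whose
cells carry density covariates; density is log-linear over the mask.

Estimation maximizes the full likelihood (Poisson or binomial prior on
the number of activity centers), with multiplicative covariate effects
on lambda0 (trap type, trap-specific behavioral response bk, linear
time trend T, grizzly presence GB, habitat cover) and on sigma (trap
type, T, GB). Model selection uses AICc with the number of detected
individuals as the sample size, via a two-step sweep: observation
model first under flat density, then density covariates on the winning
base model.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp
from statsmodels.tools.numdiff import approx_hess

from .containers import CaptureHistory, DetectorArray, MaskGrid
from .mask import compute_rpsv

_BARRIER = 1e10
_LP_GUARD = 50.0

#: lambda0 covariates allowed by the observation model.
LAMBDA0_TERMS = ("traptype", "bk", "T", "GB", "cover")
#: sigma covariates allowed by the observation model.
SIGMA_TERMS = ("traptype", "T", "GB")


# ---------------------------------------------------------------------------
# detection function


def hazard(d, lambda0, sigma):
    """Hazard half-normal detection hazard lambda(d)."""
    d = np.asarray(d, dtype=float)
    if np.any(np.asarray(lambda0) < 0):
        raise ValueError("lambda0 must be non-negative")
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    return lambda0 * np.exp(-(d**2) / (2.0 * sigma**2))


def hazard_to_prob(lam):
    """Per-occasion detection probability g = 1 - exp(-lambda)."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("hazard must be non-negative")
    return -np.expm1(-lam)


# ---------------------------------------------------------------------------
# model specifications


@dataclass(frozen=True)
class ObservationModel:
    """Additive log-scale formulas for lambda0 and sigma."""

    lambda0: tuple = ()
    sigma: tuple = ()

    def __post_init__(self):
        bad = set(self.lambda0) - set(LAMBDA0_TERMS)
        bad |= set(self.sigma) - set(SIGMA_TERMS)
        if bad:
            raise ValueError(f"unknown observation terms: {sorted(bad)}")

    @property
    def name(self) -> str:
        l0 = "+".join(self.lambda0) or "1"
        s = "+".join(self.sigma) or "1"
        return f"l0~{l0} s~{s}"


@dataclass(frozen=True)
class DensityModel:
    """Log-linear density formula over mask covariates.

    ``tenure`` enters as a categorical with reference level
    "protected"; every other term is linear in the named covariate.
    """

    terms: tuple = ()

    @property
    def name(self) -> str:
        return "D~" + ("+".join(self.terms) or "1")


#: Table of default step-1 observation-model candidates (17 models).
STEP1_CANDIDATES = [
    ObservationModel((), ()),
    ObservationModel(("bk",), ()),
    ObservationModel(("traptype",), ()),
    ObservationModel((), ("traptype",)),
    ObservationModel(("traptype",), ("traptype",)),
    ObservationModel(("T",), ()),
    ObservationModel(("T",), ("T",)),
    ObservationModel((), ("T",)),
    ObservationModel(("traptype", "bk"), ("traptype",)),
    ObservationModel(("traptype", "bk"), ()),
    ObservationModel(("traptype", "bk"), ("T",)),
    ObservationModel(("GB", "T"), ()),
    ObservationModel(("GB", "T", "traptype"), ()),
    ObservationModel(("T", "cover"), ("GB",)),
    ObservationModel(("traptype", "bk"), ("GB",)),
    ObservationModel(("T", "cover", "bk"), ()),
    ObservationModel(("traptype", "cover", "bk"), ()),
]

#: Default step-2 density candidates (single-covariate models).
STEP2_CANDIDATES = [
    DensityModel(("burn",)),
    DensityModel(("tenure",)),
    DensityModel(("harvest",)),
    DensityModel(("tertiary_rd",)),
    DensityModel(("canopy",)),
    DensityModel(("water",)),
    DensityModel(("ndvi",)),
    DensityModel(("rddens",)),
]


# ---------------------------------------------------------------------------
# design matrices


def _detector_design(detectors: DetectorArray, terms, allow_bk: bool):
    """(K, S, p) design over detector-occasions; bk contributes a zero
    column (naive animals) whose index is returned for per-individual
    adjustment."""
    K, S = detectors.usage.shape
    cols = [np.ones((K, S))]
    names = ["(Intercept)"]
    bk_idx = None
    for term in terms:
        if term == "traptype":
            for level in ("fence", "opp"):
                if (detectors.det_type == level).any():
                    ind = (detectors.det_type == level).astype(float)
                    cols.append(np.repeat(ind[:, None], S, axis=1))
                    names.append(f"traptype[{level}]")
        elif term == "bk":
            if not allow_bk:
                raise ValueError("bk is a lambda0-only covariate")
            bk_idx = len(cols)
            cols.append(np.zeros((K, S)))
            names.append("bk")
        elif term == "T":
            cols.append(np.repeat(np.arange(S, dtype=float)[None, :], K, 0))
            names.append("T")
        elif term == "GB":
            if "GB" not in detectors.time_varying:
                raise ValueError("detector array has no GB covariate")
            cols.append(detectors.time_varying["GB"].astype(float))
            names.append("GB")
        elif term == "cover":
            if "cover" not in detectors.covariates.columns:
                raise ValueError("detector array has no cover covariate")
            cov = detectors.covariates["cover"].to_numpy()
            levels = sorted(set(cov.tolist()))
            for level in levels[1:]:
                ind = (cov == level).astype(float)
                cols.append(np.repeat(ind[:, None], S, axis=1))
                names.append(f"cover[{level}]")
        else:
            raise ValueError(f"unknown observation term {term!r}")
    return np.stack(cols, axis=-1), names, bk_idx


def _density_design(mask: MaskGrid, terms):
    M = mask.n_cells
    cols = [np.ones(M)]
    names = ["(Intercept)"]
    for term in terms:
        if term == "tenure":
            if "tenure" not in mask.covariates.columns:
                raise ValueError("mask has no tenure covariate")
            ten = mask.covariates["tenure"].to_numpy()
            for level in ("private", "crown"):  # reference: protected
                cols.append((ten == level).astype(float))
                names.append(f"tenure[{level}]")
        else:
            if term not in mask.covariates.columns:
                raise ValueError(f"mask has no covariate {term!r}")
            cols.append(mask.covariates[term].to_numpy(float))
            names.append(term)
    return np.column_stack(cols), names


class SecrDesign:
    """Precomputed quantities for likelihood evaluation."""

    def __init__(
        self,
        obs: ObservationModel,
        dens: DensityModel,
        history: CaptureHistory,
        detectors: DetectorArray,
        mask: MaskGrid,
    ):
        history.check_usage(detectors)
        self.obs = obs
        self.dens = dens
        self.usage = detectors.usage.astype(float)
        self.K, self.S = detectors.usage.shape
        self.M = mask.n_cells
        self.a = mask.cell_area
        self.n = history.n_individuals
        dx = detectors.x[:, None] - mask.x[None, :]
        dy = detectors.y[:, None] - mask.y[None, :]
        self.d2 = dx**2 + dy**2  # (K, M)

        self.X_l, self.l_names, self.bk_idx = _detector_design(
            detectors, obs.lambda0, allow_bk=True
        )
        self.X_s, self.s_names, _ = _detector_design(
            detectors, obs.sigma, allow_bk=False
        )
        self.X_D, self.d_names = _density_design(mask, dens.terms)
        self.pD = self.X_D.shape[1]
        self.pl = self.X_l.shape[2]
        self.ps = self.X_s.shape[2]
        self.n_params = self.pD + self.pl + self.ps
        self.names = (
            [f"D.{nm}" for nm in self.d_names]
            + [f"lambda0.{nm}" for nm in self.l_names]
            + [f"sigma.{nm}" for nm in self.s_names]
        )

        # per-individual detection cells and bk-positive cells
        self.det_pairs = []
        self.det_bk = []
        self.bk_pairs = []
        om = history.detections
        for i in range(self.n):
            kd, sd = np.nonzero(om[i])
            first = {}
            for k, s in zip(kd, sd):
                first[k] = min(first.get(k, s), s)
            bk_flag = np.array(
                [s > first[k] for k, s in zip(kd, sd)], dtype=bool
            )
            kb_list, sb_list = [], []
            for k, f in first.items():
                later = np.nonzero(detectors.usage[k, f + 1:])[0] + f + 1
                kb_list.extend([k] * later.size)
                sb_list.extend(later.tolist())
            self.det_pairs.append((kd, sd))
            self.det_bk.append(bk_flag)
            self.bk_pairs.append(
                (np.asarray(kb_list, dtype=int), np.asarray(sb_list, dtype=int))
            )

    def split(self, theta):
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_params:
            raise ValueError(
                f"theta has {theta.size} entries, design needs {self.n_params}"
            )
        return (
            theta[: self.pD],
            theta[self.pD: self.pD + self.pl],
            theta[self.pD + self.pl:],
        )


def negloglik(
    theta,
    design: SecrDesign,
    distribution: str = "poisson",
) -> float:
    """Negative log full likelihood with activity centers marginalized
    over the mask.

    Poisson: -logL = Lambda*pbar - sum_i log( sum_m Pr(omega_i|x_m) D_m a )
                     + log n!
    Binomial: the Poisson count term is replaced by a binomial count
    term with continuous N = Lambda via gamma functions, histories
    conditioned on detection.
    """
    if distribution not in ("poisson", "binomial"):
        raise ValueError("distribution must be 'poisson' or 'binomial'")
    thD, thl, ths = design.split(theta)
    lpD = design.X_D @ thD  # (M,)
    log_l0 = design.X_l @ thl  # (K, S)
    log_sig = design.X_s @ ths
    if (
        np.any(lpD > _LP_GUARD)
        or np.any(np.abs(log_l0) > _LP_GUARD)
        or np.any(np.abs(log_sig) > _LP_GUARD)
    ):
        return _BARRIER

    sig2 = np.exp(2.0 * log_sig)  # (K, S)
    # lam[k, s, m]: per-occasion hazard for a naive animal
    lam = np.exp(
        log_l0[:, :, None] - design.d2[:, None, :] / (2.0 * sig2[:, :, None])
    ) * design.usage[:, :, None]
    Lam_m = lam.sum(axis=(0, 1))  # (M,) total naive hazard
    pdot = -np.expm1(-Lam_m)  # P(detected at least once | x_m)
    D = np.exp(lpD)
    Da = D * design.a
    expected_n = float(pdot @ Da)

    beta_bk = thl[design.bk_idx] if design.bk_idx is not None else 0.0
    mult = np.exp(beta_bk)

    sum_li = 0.0
    log_a = np.log(design.a)
    for i in range(design.n):
        kd, sd = design.det_pairs[i]
        lam_det = lam[kd, sd, :]
        tot_i = Lam_m
        if design.bk_idx is not None:
            kb, sb = design.bk_pairs[i]
            if kb.size:
                tot_i = Lam_m + (mult - 1.0) * lam[kb, sb, :].sum(axis=0)
            if design.det_bk[i].any():
                lam_det = lam_det.copy()
                lam_det[design.det_bk[i]] *= mult
        with np.errstate(divide="ignore"):
            log_p_det = np.log(-np.expm1(-lam_det))
        log_pr = log_p_det.sum(axis=0) + lam_det.sum(axis=0) - tot_i
        li = logsumexp(log_pr + lpD + log_a)
        if not np.isfinite(li):
            return _BARRIER
        sum_li += li

    n = design.n
    if distribution == "poisson":
        nll = expected_n - sum_li + gammaln(n + 1)
    else:
        Lambda = float(Da.sum())
        pbar = expected_n / Lambda
        if Lambda <= n or pbar >= 1.0:
            return _BARRIER
        ll = (
            gammaln(Lambda + 1)
            - gammaln(Lambda - n + 1)
            - gammaln(n + 1)
            + (Lambda - n) * np.log1p(-pbar)
            + sum_li
            - n * np.log(Lambda)
        )
        nll = -ll
    if not np.isfinite(nll):
        return _BARRIER
    return float(nll)


# ---------------------------------------------------------------------------
# information criteria


def aicc(ll: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; n is the number of detected
    individuals."""
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= K + 1")
    return -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(values) -> np.ndarray:
    """Akaike weights from AICc (or delta-AICc) values."""
    v = np.asarray(values, dtype=float)
    delta = v - v.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Maximum-likelihood SECR fit."""

    obs: ObservationModel
    dens: DensityModel
    names: list
    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    ll: float
    K: int
    n: int
    aicc: float
    converged: bool
    distribution: str
    pD: int
    pl: int
    ps: int
    mask_area: float
    grad_norm: float = np.nan
    warnings_: list = field(default_factory=list)

    @property
    def name(self) -> str:
        return f"{self.dens.name} {self.obs.name}"

    @property
    def density_beta(self) -> np.ndarray:
        return self.beta[: self.pD]

    @property
    def density_vcov(self) -> np.ndarray:
        return self.vcov[: self.pD, : self.pD]

    def real_params(self) -> dict:
        """Back-transformed D, lambda0, sigma at reference levels
        (rub detector, naive animal, T = 0, GB = 0, protected tenure),
        with 95% CIs. D is bears/km^2; CIs are lognormal (Wald on the
        log scale)."""
        out = {}
        for label, idx in (
            ("D", 0),
            ("lambda0", self.pD),
            ("sigma", self.pD + self.pl),
        ):
            b = self.beta[idx]
            s = self.se[idx]
            est = float(np.exp(b))
            out[label] = {
                "estimate": est,
                "se": est * s if np.isfinite(s) else np.nan,
                "lcl": float(np.exp(b - 1.96 * s)),
                "ucl": float(np.exp(b + 1.96 * s)),
            }
        return out

    @property
    def rse_density(self) -> float:
        """Relative standard error of D-hat (delta method on the log
        scale)."""
        return float(self.se[0])

    def to_dict(self) -> dict:
        return {
            "model": self.name,
            "coefficients": {
                nm: {"estimate": float(b), "se": float(s)}
                for nm, b, s in zip(self.names, self.beta, self.se)
            },
            "vcov": self.vcov.tolist(),
            "logLik": self.ll,
            "K": self.K,
            "n": self.n,
            "AICc": self.aicc,
            "converged": self.converged,
            "distribution": self.distribution,
            "real": self.real_params(),
            "RSE_D": self.rse_density,
        }


def _start_values(design: SecrDesign, history, detectors) -> np.ndarray:
    theta = np.zeros(design.n_params)
    area = design.M * design.a
    theta[0] = np.log(max(design.n, 1) / area)
    exposures = detectors.usage.sum(axis=1).max()
    rate = history.n_detections / max(design.n * exposures, 1.0)
    rate = min(max(rate, 1e-4), 0.9)
    theta[design.pD] = np.log(-np.log1p(-rate))
    try:
        sig0 = compute_rpsv(history, detectors)
        if sig0 <= 0:
            raise ValueError
    except ValueError:
        sig0 = 2.0 * np.sqrt(design.a)
    theta[design.pD + design.pl] = np.log(sig0)
    return theta


def fit_secr(
    obs: ObservationModel,
    dens: DensityModel,
    history: CaptureHistory,
    detectors: DetectorArray,
    mask: MaskGrid,
    distribution: str = "poisson",
    n_starts: int = 3,
    seed: int = 0,
    fixed: dict | None = None,
    compute_se: bool = True,
    pgtol: float = 1e-5,
    maxiter: int = 500,
) -> FitResult:
    """Fit a SECR model by quasi-Newton maximization on the log scale.

    Default starts: ln sigma at ln RPSV, ln lambda0 from the naive
    per-occasion capture rate, ln D at ln(n / mask area); three starts
    (two jittered) guard against local optima. Standard errors come
    from the numerical Hessian; ``fixed`` pins named coefficients at
    given working-scale values (profile-likelihood style).
    """
    if history.n_individuals == 0:
        raise ValueError("empty capture history: nothing to fit")
    design = SecrDesign(obs, dens, history, detectors, mask)
    msgs = []
    if design.n_params >= design.n:
        msgs.append(
            f"K={design.n_params} parameters for n={design.n} individuals; "
            "design may be unidentifiable"
        )
        warnings.warn(msgs[-1])

    fixed = fixed or {}
    unknown = set(fixed) - set(design.names)
    if unknown:
        raise ValueError(f"fixed refers to unknown coefficients: {unknown}")
    fixed_idx = np.array(
        [design.names.index(nm) for nm in fixed], dtype=int
    )
    fixed_val = np.array([fixed[nm] for nm in fixed], dtype=float)
    free = np.setdiff1d(np.arange(design.n_params), fixed_idx)

    def embed(th_free):
        th = np.empty(design.n_params)
        th[free] = th_free
        if fixed_idx.size:
            th[fixed_idx] = fixed_val
        return th

    def obj(th_free):
        return negloglik(embed(th_free), design, distribution)

    start0 = _start_values(design, history, detectors)
    rng = np.random.default_rng(seed)
    best = None
    for j in range(max(n_starts, 1)):
        th0 = start0[free].copy()
        if j > 0:
            th0 = th0 + rng.normal(scale=0.3, size=th0.size)
        res = minimize(
            obj,
            th0,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": pgtol},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = embed(best.x)
    ll = -float(best.fun)
    converged = bool(best.success) and best.fun < _BARRIER / 2
    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan
    if not converged:
        msgs.append(f"optimizer did not converge: {best.message}")
        warnings.warn(msgs[-1])

    k_free = free.size
    se = np.full(design.n_params, np.nan)
    vcov = np.full((design.n_params, design.n_params), np.nan)
    if compute_se and converged:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            H = approx_hess(best.x, obj)
        try:
            v_free = np.linalg.inv(H)
            d = np.diag(v_free)
            if np.all(np.isfinite(v_free)) and np.all(d > 0):
                vcov[:] = 0.0
                vcov[np.ix_(free, free)] = v_free
                se[:] = 0.0
                se[free] = np.sqrt(d)
                if fixed_idx.size:
                    se[fixed_idx] = np.nan
            else:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            msgs.append("singular Hessian: standard errors unavailable")
            warnings.warn(msgs[-1])

    try:
        ic = aicc(ll, k_free, design.n)
    except ValueError:
        ic = np.inf
        msgs.append("AICc undefined (n <= K + 1)")
    return FitResult(
        obs=obs,
        dens=dens,
        names=design.names,
        beta=theta,
        se=se,
        vcov=vcov,
        ll=ll,
        K=k_free,
        n=design.n,
        aicc=ic,
        converged=converged,
        distribution=distribution,
        pD=design.pD,
        pl=design.pl,
        ps=design.ps,
        mask_area=design.M * design.a,
        grad_norm=grad_norm,
        warnings_=msgs,
    )


# ---------------------------------------------------------------------------
# model selection


def model_table(fits, names=None) -> pd.DataFrame:
    """AICc ranking with delta-AICc and Akaike weights.

    All fits must be on the same data (same number of detected
    individuals). Ties in AICc resolve in favor of fewer parameters.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to rank")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits mix datasets with different n: {sorted(ns)}")
    if names is None:
        names = [f.name for f in fits]
    tab = pd.DataFrame(
        {
            "model": names,
            "K": [f.K for f in fits],
            "LL": [f.ll for f in fits],
            "AICc": [f.aicc for f in fits],
        }
    )
    tab["dAICc"] = tab["AICc"] - tab["AICc"].min()
    tab["w"] = akaike_weights(tab["AICc"].to_numpy())
    tab = tab.sort_values(["AICc", "K"], kind="mergesort").reset_index(drop=True)
    return tab


@dataclass
class TwoStepResult:
    base_obs: ObservationModel
    best_fit: FitResult
    step1_table: pd.DataFrame
    step2_table: pd.DataFrame
    step1_fits: list
    step2_fits: list
    failures: dict


def run_two_step(
    step1_candidates,
    step2_candidates,
    history: CaptureHistory,
    detectors: DetectorArray,
    mask: MaskGrid,
    **fit_kw,
) -> TwoStepResult:
    """Two-step AICc model selection.

    Step 1 fits every observation-model candidate under flat density
    (D ~ 1) and keeps the most parsimonious; step 2 fits the density
    candidates on that base. Fit failures are recorded per candidate
    and skipped, not fatal to the sweep.
    """
    step1_candidates = list(step1_candidates)
    step2_candidates = list(step2_candidates)
    if not step1_candidates or not step2_candidates:
        raise ValueError("candidate lists must be nonempty")

    failures = {}
    flat = DensityModel(())

    def _sweep(cands, fitter):
        fits, names = [], []
        for cand in cands:
            try:
                fits.append(fitter(cand))
                names.append(fits[-1].name)
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                failures[cand.name] = str(exc)
        if not fits:
            raise RuntimeError("every candidate model failed to fit")
        return fits, names

    fits1, names1 = _sweep(
        step1_candidates,
        lambda obs: fit_secr(obs, flat, history, detectors, mask, **fit_kw),
    )
    tab1 = model_table(fits1, names1)
    order1 = sorted(range(len(fits1)), key=lambda i: (fits1[i].aicc, fits1[i].K))
    base = fits1[order1[0]].obs

    fits2, names2 = _sweep(
        step2_candidates,
        lambda dm: fit_secr(base, dm, history, detectors, mask, **fit_kw),
    )
    tab2 = model_table(fits2, names2)
    order2 = sorted(range(len(fits2)), key=lambda i: (fits2[i].aicc, fits2[i].K))
    best = fits2[order2[0]]
    return TwoStepResult(base, best, tab1, tab2, fits1, fits2, failures)


# ---------------------------------------------------------------------------
# prediction


def predict_density(fit: FitResult, mask: MaskGrid) -> pd.DataFrame:
    """Per-cell density surface D-hat(x) with delta-method 95% CIs.

    Returns a frame (x, y, D, lcl, ucl) in bears/km^2.
    """
    X, names = _density_design(mask, fit.dens.terms)
    lp = X @ fit.density_beta
    V = fit.density_vcov
    if np.all(np.isfinite(V)):
        se_lp = np.sqrt(np.einsum("ij,jk,ik->i", X, V, X))
    else:
        se_lp = np.full(mask.n_cells, np.nan)
    return pd.DataFrame(
        {
            "x": mask.x,
            "y": mask.y,
            "D": np.exp(lp),
            "lcl": np.exp(lp - 1.96 * se_lp),
            "ucl": np.exp(lp + 1.96 * se_lp),
        }
    )


def region_abundance(
    fit: FitResult,
    mask: MaskGrid,
    region_col: str = "tenure",
    regions=None,
    n_draws: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Abundance by region via discrete summation over mask cells.

    N-hat(region) = sum of D-hat(x) * a over the region's cells; the CI
    comes from parametric resampling of the density coefficients from
    their estimated covariance.
    """
    surface = predict_density(fit, mask)
    labels = mask.covariates[region_col].to_numpy()
    if regions is None:
        regions = list(pd.unique(labels))
    a = mask.cell_area
    X, _ = _density_design(mask, fit.dens.terms)
    V = fit.density_vcov
    draws = None
    if np.all(np.isfinite(V)):
        rng = np.random.default_rng(seed)
        th = rng.multivariate_normal(
            fit.density_beta, V, size=n_draws, method="svd"
        )
        draws = np.exp(X @ th.T) * a  # (M, n_draws)
    rows = []
    for region in regions:
        in_region = labels == region
        if not in_region.any():
            warnings.warn(f"region {region!r} has no mask cells")
            rows.append({"region": region, "nhat": 0.0,
                         "lcl": np.nan, "ucl": np.nan})
            continue
        nhat = float(surface["D"].to_numpy()[in_region].sum() * a)
        if draws is not None:
            sums = draws[in_region].sum(axis=0)
            lcl, ucl = np.percentile(sums, [2.5, 97.5])
        else:
            lcl = ucl = np.nan
        rows.append({"region": region, "nhat": nhat,
                     "lcl": float(lcl), "ucl": float(ucl)})
    return pd.DataFrame(rows)
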