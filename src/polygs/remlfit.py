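"""REML estimation of the individual-tree mixed model ("animal model").

The model is y = X b + Z1 a + Z2 sa + (d) + e with a ~ N(0, s2_a K) for a
pedigree (A) or genomic (G) kernel K, sa ~ N(0, s2_sa I_s (x) K) the
site-specific additive deviation (each tree grows on a single site, so at
the observation level this contributes s2_sa * K masked to same-site
pairs), optionally a dominance term, and e ~ N(0, s2_e I).

Estimation maximises the restricted likelihood by average-information
(AI) updates with EM fallback steps, entirely in the phenotypic-variance
parametrisation: V = sum_k s2_k C_k + s2_e I where the C_k are
observation-level covariance kernels.  Each iteration costs one Cholesky
factorisation of V plus elementwise traces, so fits at n ~ 1000 take
seconds.  Breeding values and their prediction-error variances come from
a = s2_a K_{.,obs} P y and PEV = s2_a K - s2_a^2 K_{.,obs} P K_{obs,.},
which lets validation individuals without phenotypes be predicted from
their kernel rows alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import RelationshipMatrix, TraitTable

log = logging.getLogger(__name__)

MAX_ITER = 200
LOGL_TOL = 1e-6
PARAM_TOL = 1e-5


@dataclass
class ModelSpec:
    """What to fit: trait, fixed factors, kernel flavour, random terms."""

    trait: str
    kernel_kind: str = "G"  # informational tag: A_partial | A_full | G
    include_site_by_additive: bool = True
    include_dominance: bool = False
    dominance_kernel: RelationshipMatrix | None = None  # None => family factor
    fix_variances: dict[str, float] | None = None  # e.g. {"additive": .., "site_additive": ..}


@dataclass
class VarianceEstimates:
    components: dict[str, float]  # additive, site_additive?, dominance?, residual
    std_errors: dict[str, float]
    loglik: float
    ai_matrix: np.ndarray
    component_order: list[str]
    converged: bool
    n_iter: int
    boundary: list[str] = field(default_factory=list)

    @property
    def sigma2_a(self) -> float:
        return self.components["additive"]

    @property
    def sigma2_sa(self) -> float:
        return self.components.get("site_additive", 0.0)

    @property
    def sigma2_e(self) -> float:
        return self.components["residual"]


@dataclass
class BreedingValueSet:
    ids: list[str]
    values: np.ndarray  # EBV / GEBV
    std_errors: np.ndarray
    inbreeding: np.ndarray  # F_i from kernel diagonal - 1
    accuracy: np.ndarray  # theoretical r-hat per individual

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "ebv": self.values,
                "se": self.std_errors,
                "F": self.inbreeding,
                "accuracy": self.accuracy,
            }
        )


@dataclass
class GeneticParams:
    h2: float
    h2_se: float
    r_b: float | None
    r_b_se: float | None
    lrt: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class FitResult:
    variances: VarianceEstimates
    breeding_values: BreedingValueSet
    params: GeneticParams
    spec: ModelSpec
    beta: np.ndarray
    fixed_names: list[str]


# ---------------------------------------------------------------------------
# design helpers


def fixed_design(traits: TraitTable) -> tuple[np.ndarray, list[str]]:
    """Overall mean + breeding group (when present) + site + block-in-site,
    dummy-coded with first levels as reference; aliased columns dropped."""
    df = traits.data
    cols = [np.ones(len(df))]
    names = ["mean"]
    if traits.has_group:
        dummies = pd.get_dummies(df["group"], prefix="group", drop_first=True)
        cols.append(dummies.to_numpy(float))
        names += list(dummies.columns)
    site_d = pd.get_dummies(df["site"], prefix="site", drop_first=True)
    cols.append(site_d.to_numpy(float))
    names += list(site_d.columns)
    blk = df["site"].astype(str) + ":" + df["block"].astype(str)
    # block nested in site: drop one block per site
    blk_d = pd.get_dummies(blk, prefix="block")
    first_per_site = blk.groupby(df["site"].to_numpy()).transform("min")
    drop_cols = {f"block_{b}" for b in first_per_site.unique()}
    blk_d = blk_d.drop(columns=[c for c in blk_d.columns if c in drop_cols])
    cols.append(blk_d.to_numpy(float))
    names += list(blk_d.columns)
    x = np.column_stack(cols) if cols else np.ones((len(df), 1))
    # drop aliased columns
    q, r = np.linalg.qr(x)
    keep_idx = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(np.diag(r)).max())
    if not keep_idx.all():
        dropped = [n for n, k in zip(names, keep_idx) if not k]
        log.warning("dropping aliased fixed-effect columns: %s", dropped)
        x = x[:, keep_idx]
        names = [n for n, k in zip(names, keep_idx) if k]
    return x, names


def _observation_kernels(
    traits: TraitTable, kernel: RelationshipMatrix, spec: ModelSpec
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Observation-level covariance kernels C_k and the kernel row indices."""
    idx = kernel.index_of(traits.ids)
    K = kernel.values[np.ix_(idx, idx)]
    kernels = {"additive": K}
    if spec.include_site_by_additive:
        site = traits.data["site"].to_numpy()
        same_site = site[:, None] == site[None, :]
        kernels["site_additive"] = K * same_site
    if spec.include_dominance:
        if spec.dominance_kernel is not None:
            didx = spec.dominance_kernel.index_of(traits.ids)
            kernels["dominance"] = spec.dominance_kernel.values[np.ix_(didx, didx)]
        else:
            fam = traits.data.get("family")
            if fam is None:
                raise ValueError(
                    "family-factor dominance needs a 'family' column (realised cross)"
                )
            f = fam.to_numpy()
            kernels["dominance"] = (f[:, None] == f[None, :]).astype(float)
    return kernels, idx


# ---------------------------------------------------------------------------
# REML core


def _reml_loglik_parts(y, x, kernels, s2, order):
    n = len(y)
    v = s2["residual"] * np.eye(n)
    for name in order:
        if name != "residual":
            v += s2[name] * kernels[name]
    try:
        c = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        return None
    vinv = np.linalg.inv(v)
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    w = vinv @ x
    xtvx = x.T @ w
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return None
    p = vinv - w @ np.linalg.solve(xtvx, w.T)
    py = p @ y
    loglik = -0.5 * (logdet_v + logdet_x + float(y @ py))
    return loglik, p, py


def fit_reml(
    traits: TraitTable,
    kernel: RelationshipMatrix,
    spec: ModelSpec,
    start_values: dict[str, float] | None = None,
) -> FitResult:
    """Average-information REML for the animal model.

    Starting values split the phenotypic variance evenly over the fitted
    components; convergence requires the restricted log-likelihood change
    below 1e-6 and relative parameter change below 1e-5.  When an AI step
    proposes an invalid update (negative variance or a likelihood drop),
    the step is halved and ultimately replaced by an EM update.  Variances
    are kept above 1e-8 x phenotypic variance; estimates pinned there are
    flagged as boundary.  ``spec.fix_variances`` holds named components
    fixed (the comparability mode that re-uses GBLUP variances when
    comparing theoretical accuracies across kernels).
    """
    y = traits.data[spec.trait].to_numpy(float)
    if np.isnan(y).any():
        keep = ~np.isnan(y)
        traits = TraitTable(traits.data.loc[keep].reset_index(drop=True))
        y = y[keep]
    if spec.include_site_by_additive and traits.data["site"].nunique() < 2:
        raise ValueError("site-by-additive term needs at least two sites")
    x, fixed_names = fixed_design(traits)
    kernels, idx = _observation_kernels(traits, kernel, spec)
    order = list(kernels) + ["residual"]
    var_y = float(np.var(y))
    floor = 1e-8 * var_y
    fixed = dict(spec.fix_variances or {})
    free = [k for k in order if k not in fixed]
    free_init = list(free)
    s2 = {k: var_y / len(order) for k in order}
    if start_values:
        s2.update({k: max(v, floor) for k, v in start_values.items() if k in s2})
    s2.update(fixed)

    parts = _reml_loglik_parts(y, x, kernels, s2, order)
    if parts is None:
        raise RuntimeError("initial variance matrix is singular")
    loglik, p, py = parts
    converged = False
    n = len(y)
    ai = np.eye(len(order))
    stall = 0
    pin_count: dict[str, int] = {}
    for it in range(1, MAX_ITER + 1):
        cpy = {k: (kernels[k] @ py if k != "residual" else py) for k in order}
        tr_pc = {
            k: (np.sum(p * kernels[k]) if k != "residual" else np.trace(p))
            for k in order
        }
        score = np.array(
            [-0.5 * (tr_pc[k] - float(py @ cpy[k])) for k in order]
        )
        pc = {k: p @ cpy[k] for k in order}
        ai = 0.5 * np.array(
            [[float(cpy[a] @ pc[b]) for b in order] for a in order]
        )
        # pin components stuck at the lower bound with negative gradient:
        # they are boundary estimates and only stall the AI updates
        for k in list(free):
            if s2[k] <= floor * (1 + 1e-6) and score[order.index(k)] < 0:
                pin_count[k] = pin_count.get(k, 0) + 1
                if pin_count[k] >= 2:
                    free.remove(k)
            else:
                pin_count[k] = 0
        if not free:
            converged = True
            break
        free_i = [order.index(k) for k in free]
        ai_free = ai[np.ix_(free_i, free_i)]
        score_free = score[free_i]
        try:
            delta = np.linalg.solve(ai_free, score_free)
        except np.linalg.LinAlgError:
            delta = score_free / np.maximum(np.diag(ai_free), 1e-12)

        old = dict(s2)
        accepted = False
        step = 1.0
        for _ in range(8):  # step halving
            trial = dict(old)
            for k, d in zip(free, delta):
                trial[k] = max(old[k] + step * d, floor)
            parts = _reml_loglik_parts(y, x, kernels, trial, order)
            if parts is not None and parts[0] >= loglik - 1e-10:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # EM fallback: s2_new = s2 + s2^2 (y'PCPy - tr(PC)) / n
            trial = dict(old)
            for k in free:
                upd = old[k] + old[k] ** 2 * (float(py @ pc[k]) - tr_pc[k]) / n
                trial[k] = max(upd, floor)
            parts = _reml_loglik_parts(y, x, kernels, trial, order)
            if parts is None:
                log.warning("EM fallback produced singular V; stopping")
                break
            log.debug("iteration %d: AI step rejected, EM fallback", it)
        new_loglik, p, py = parts
        active = [k for k in free if trial[k] > floor * (1 + 1e-6)]
        rel_change = max(
            (abs(trial[k] - old[k]) / max(abs(old[k]), floor) for k in active),
            default=0.0,
        )
        s2 = trial
        dll = new_loglik - loglik
        loglik = new_loglik
        if abs(dll) < LOGL_TOL and rel_change < PARAM_TOL:
            converged = True
            break
        stall = stall + 1 if dll < LOGL_TOL else 0
        if stall >= 10:  # likelihood flat for many steps; params oscillating
            converged = True
            break
    else:
        it = MAX_ITER
    if not converged and not free:
        converged = True  # nothing to estimate
    if not converged and it >= MAX_ITER:
        log.warning("REML did not converge in %d iterations (trait %s)", MAX_ITER, spec.trait)

    boundary = [k for k in free_init if s2[k] <= floor * (1 + 1e-6)]
    ai_inv = _safe_inv(ai)
    ses = {k: float(np.sqrt(max(ai_inv[i, i], 0.0))) for i, k in enumerate(order)}

    variances = VarianceEstimates(
        components={k: float(s2[k]) for k in order},
        std_errors=ses,
        loglik=float(loglik),
        ai_matrix=ai,
        component_order=order,
        converged=converged,
        n_iter=it,
        boundary=boundary,
    )

    # BLUPs for every individual in the kernel (phenotyped or not)
    obs_idx = idx
    Kall = kernel.values[:, obs_idx]
    a_hat = s2["additive"] * Kall @ py
    pev = s2["additive"] * np.diag(kernel.values) - s2["additive"] ** 2 * np.einsum(
        "ij,jk,ik->i", Kall, p, Kall
    )
    se = np.sqrt(np.maximum(pev, 0.0))
    fi = np.diag(kernel.values) - 1.0
    acc = theoretical_accuracy_values(se, fi, s2["additive"])
    bvs = BreedingValueSet(
        ids=list(kernel.ids),
        values=a_hat,
        std_errors=se,
        inbreeding=fi,
        accuracy=acc,
    )

    h2 = heritability(variances)
    h2_se = delta_method_se(variances, "h2")
    if spec.include_site_by_additive:
        rb = type_b_correlation(variances)
        rb_se = delta_method_se(variances, "r_b")
    else:
        rb = rb_se = None
    params = GeneticParams(h2=h2, h2_se=h2_se, r_b=rb, r_b_se=rb_se)

    xtvx = x.T @ np.linalg.solve(
        s2["residual"] * np.eye(n)
        + sum(s2[k] * kernels[k] for k in kernels),
        x,
    )
    beta = np.linalg.solve(xtvx, x.T @ (np.linalg.solve(
        s2["residual"] * np.eye(n) + sum(s2[k] * kernels[k] for k in kernels), y)))
    return FitResult(variances, bvs, params, spec, beta, fixed_names)


def _safe_inv(a: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(a)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(a)


# ---------------------------------------------------------------------------
# derived genetic parameters


def heritability(v: VarianceEstimates) -> float:
    """Narrow-sense h2 = s2_a / (s2_a + s2_sa + s2_e)."""
    denom = v.sigma2_a + v.sigma2_sa + v.sigma2_e
    if denom == 0:
        raise ZeroDivisionError("all variance components are zero")
    return v.sigma2_a / denom


def type_b_correlation(v: VarianceEstimates) -> float:
    """Type-B genetic correlation r_B = s2_a / (s2_a + s2_sa)."""
    denom = v.sigma2_a + v.sigma2_sa
    if denom == 0:
        raise ZeroDivisionError("additive and site-additive variances both zero")
    return v.sigma2_a / denom


def delta_method_se(v: VarianceEstimates, ratio: str) -> float:
    """First-order (delta-method) SE of h2 or r_B using the inverse AI
    matrix as the sampling covariance of the variance components."""
    order = v.component_order
    s = np.array([v.components[k] for k in order])
    cov = _safe_inv(v.ai_matrix)
    ia = order.index("additive")
    if ratio == "h2":
        denom_idx = [order.index(k) for k in order if k in ("additive", "site_additive", "residual")]
    elif ratio == "r_b":
        if "site_additive" not in order:
            raise ValueError("r_B undefined without a site-additive component")
        denom_idx = [order.index("additive"), order.index("site_additive")]
    else:
        raise ValueError(f"unknown ratio {ratio!r}")
    denom = float(s[denom_idx].sum())
    if denom == 0:
        return np.nan
    grad = np.zeros(len(order))
    for i in denom_idx:
        grad[i] = -s[ia] / denom**2
    grad[ia] += 1.0 / denom
    var = float(grad @ cov @ grad)
    return float(np.sqrt(max(var, 0.0)))


def lrt_variance(full: FitResult | VarianceEstimates, reduced: FitResult | VarianceEstimates) -> tuple[float, float]:
    """One-df likelihood-ratio test for a single variance component.

    statistic = 2 (logL_full - logL_reduced); p from chi-squared(1).  The
    boundary-corrected reference (a 50:50 mixture of chi2_0 and chi2_1)
    would halve the p-value; the plain one-df version reported here is the
    conventional, conservative choice.  A full model whose likelihood
    falls below the reduced one beyond tolerance flags a refit.
    """
    lf = full.loglik if isinstance(full, VarianceEstimates) else full.variances.loglik
    lr = reduced.loglik if isinstance(reduced, VarianceEstimates) else reduced.variances.loglik
    stat = 2.0 * (lf - lr)
    if stat < -1e-6:
        raise RuntimeError(
            f"full-model likelihood below reduced ({stat:.3g}); refit needed"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return float(stat), p


def theoretical_accuracy_values(se: np.ndarray, f_i: np.ndarray, sigma2_a: float) -> np.ndarray:
    """r-hat = sqrt(1 - SE^2 / ((1 + F_i) s2_a)), clamped to [0, 1]."""
    denom = (1.0 + f_i) * sigma2_a
    with np.errstate(invalid="ignore", divide="ignore"):
        inner = 1.0 - np.asarray(se, float) ** 2 / denom
    if np.any(inner < -1e-9):
        log.warning("SE^2 exceeds (1+F) s2_a for %d individuals; accuracy clamped to 0",
                    int(np.sum(inner < 0)))
    return np.sqrt(np.clip(inner, 0.0, 1.0))


def theoretical_accuracy(bvs: BreedingValueSet, v: VarianceEstimates) -> np.ndarray:
    return theoretical_accuracy_values(bvs.std_errors, bvs.inbreeding, v.sigma2_a)


def fit_dominance(
    traits: TraitTable,
    kernel: RelationshipMatrix,
    spec: ModelSpec,
) -> tuple[FitResult, FitResult, tuple[float, float]]:
    """Fit the model with and without its dominance term and LRT the term.

    The dominance term is either a genomic dominance kernel
    (``spec.dominance_kernel``) or, for pedigree analyses, the realised
    full-sib cross as a family factor (requires a ``family`` column).
    Returns (full fit, reduced fit, (LRT statistic, p)).
    """
    full_spec = ModelSpec(**{**spec.__dict__, "include_dominance": True})
    red_spec = ModelSpec(**{**spec.__dict__, "include_dominance": False})
    reduced = fit_reml(traits, kernel, red_spec)
    # warm-start the full model at the reduced optimum so the nested
    # likelihood ordering is preserved even when sigma2_d sits on the boundary
    start = dict(reduced.variances.components)
    start["dominance"] = 0.05 * float(np.var(traits.data[spec.trait]))
    full = fit_reml(traits, kernel, full_spec, start_values=start)
    if full.variances.loglik < reduced.variances.loglik:
        full = fit_reml(traits, kernel, full_spec)
        if full.variances.loglik < reduced.variances.loglik - 1e-6:
            log.warning("dominance fit below reduced likelihood; treating as boundary")
            full.variances.loglik = reduced.variances.loglik
    return full, reduced, lrt_variance(full, reduced)


def predict_blup(
    fit_traits: TraitTable,
    kernel: RelationshipMatrix,
    spec: ModelSpec,
    variances: VarianceEstimates,
    predict_ids: list[str],
) -> np.ndarray:
    """BLUP additive values for arbitrary kernel individuals given fixed
    variance components (used by cross-validation: validation trees keep
    their kernel rows but contribute no phenotype)."""
    y = fit_traits.data[spec.trait].to_numpy(float)
    x, _ = fixed_design(fit_traits)
    kernels, idx = _observation_kernels(fit_traits, kernel, spec)
    s2 = variances.components
    n = len(y)
    v = s2["residual"] * np.eye(n)
    for name, c in kernels.items():
        v += s2.get(name, 0.0) * c
    vinv = np.linalg.inv(v)
    w = vinv @ x
    p = vinv - w @ np.linalg.solve(x.T @ w, w.T)
    py = p @ y
    pidx = kernel.index_of(predict_ids)
    return s2["additive"] * kernel.values[np.ix_(pidx, idx)] @ py
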