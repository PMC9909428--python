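"""Two-latent-variable structural equation model with a binary outcome.

Model
-----
Continuous indicators (CLR genus abundances, standardized) load each on one
of two latent factors; a binary disease variable is the endogenous outcome,
handled through a latent-response (probit threshold) formulation: the
observed 0/1 variable arises from an underlying standard-normal response
crossing a threshold.  With standardized latents (variance 1, correlation
``c``) and standardized observed variables, the free parameters are the
loadings ``a_ij``, the two structural paths ``b1, b2`` and ``c``; residual
variances follow from the standardization identities ``v_ij = 1 - a_ij**2``
and ``psi_y = 1 - (b1**2 + b2**2 + 2*b1*b2*c)``.

Estimation
----------
The sample statistics are Pearson correlations among indicators and
polyserial (biserial) correlations between each indicator and the binary
outcome, the latter by two-step maximum likelihood given the probit
threshold.  Parameters minimize the diagonally weighted least-squares (DWLS)
discrepancy: squared residuals between sample and model-implied correlations
weighted by inverse asymptotic variances.  Standard errors come from the
weighted Jacobian at the optimum (diagonal-weight approximation); fit is
summarized by chi-square, GFI, AGFI and RMSEA.

Model modification mirrors backward elimination: indicators are deleted
first to clear inadmissible (Heywood) variance components, then to force
loading p-values below ``alpha``; among the admissible models visited the
one maximizing the total absolute structural path, subject to RMSEA < 0.08,
is adopted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SemSpec",
    "FitIndices",
    "FittedSem",
    "build_model_spec",
    "fit_sem",
    "fit_indices",
    "rmsea",
    "modify_model",
    "polyserial_binary",
]

log = logging.getLogger(__name__)

LATENTS = ("lv1", "lv2")


class ModelConstructionError(RuntimeError):
    """No admissible model could be reached by the modification procedure."""


@dataclass
class SemSpec:
    """Structure of the SEM: indicator assignment and the outcome regression."""

    indicators: dict[str, list[str]]  # latent -> indicator names
    outcome: str = "atopic_dermatitis"
    latent_cov_free: bool = True

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for lv, inds in self.indicators.items():
            if lv not in LATENTS:
                raise ValueError(f"unknown latent {lv!r}")
            for g in inds:
                if g in seen:
                    raise ValueError(f"indicator {g!r} assigned to both latents")
                seen.add(g)
        if not all(self.indicators.get(lv) for lv in LATENTS):
            raise ValueError("each latent needs at least one indicator")

    @property
    def all_indicators(self) -> list[str]:
        return [g for lv in LATENTS for g in self.indicators[lv]]

    @property
    def under_identified(self) -> bool:
        return any(len(self.indicators[lv]) < 2 for lv in LATENTS)

    def drop(self, indicator: str) -> "SemSpec":
        new = {lv: [g for g in inds if g != indicator]
               for lv, inds in self.indicators.items()}
        return SemSpec(new, self.outcome, self.latent_cov_free)

    def to_text(self) -> str:
        lines = [f"{lv} =~ " + " + ".join(self.indicators[lv]) for lv in LATENTS]
        lines.append(f"{self.outcome} ~ lv1 + lv2")
        lines.append("lv1 ~~ lv2")
        return "\n".join(lines)


@dataclass
class FitIndices:
    chi2: float
    df: int
    gfi: float
    agfi: float | None
    rmsea: float

    def as_dict(self) -> dict:
        return {"chi2": self.chi2, "df": self.df, "GFI": self.gfi,
                "AGFI": self.agfi, "RMSEA": self.rmsea}


@dataclass
class FittedSem:
    """Standardized DWLS solution with SEs, fit indices and diagnostics."""

    spec: SemSpec
    estimates: pd.DataFrame  # lhs, op, rhs, est, se, z, p, ci.lower, ci.upper
    fit: FitIndices
    n_samples: int
    converged: bool
    heywood: list[str] = field(default_factory=list)
    # frozen standardization moments of the fitting population
    train_means: pd.Series | None = None
    train_sds: pd.Series | None = None
    # internal state used for index computation / refits
    sample_stats: dict = field(default_factory=dict, repr=False)

    def param(self, lhs: str, op: str, rhs: str) -> pd.Series:
        m = self.estimates
        row = m[(m.lhs == lhs) & (m.op == op) & (m.rhs == rhs)]
        if row.empty:
            raise KeyError(f"no parameter {lhs} {op} {rhs}")
        return row.iloc[0]

    def loadings(self) -> pd.Series:
        m = self.estimates
        sel = m[m.op == "=~"]
        return pd.Series(sel.est.to_numpy(), index=sel.rhs.to_numpy())

    def residual_variances(self) -> pd.Series:
        m = self.estimates
        sel = m[(m.op == "~~") & (m.lhs == m.rhs) & (~m.lhs.isin(LATENTS))
                & (m.lhs != self.spec.outcome)]
        return pd.Series(sel.est.to_numpy(), index=sel.rhs.to_numpy())

    def paths(self) -> pd.Series:
        m = self.estimates
        sel = m[m.op == "~"]
        return pd.Series(sel.est.to_numpy(), index=sel.rhs.to_numpy())

    def latent_correlation(self) -> float:
        return float(self.param("lv1", "~~", "lv2").est)

    def to_csv(self, path) -> None:
        self.estimates.to_csv(path, index=False)


def build_model_spec(markers: dict[str, float], outcome: str = "atopic_dermatitis") -> SemSpec:
    """Assign marker genera to latents by effect-size sign.

    Genera with positive effects (more abundant in the disease group) become
    lv1 indicators; negative effects (more abundant in controls) become lv2
    indicators.  A spec with a single indicator on either side is valid but
    flagged under-identified for a free fit.
    """
    pos = sorted((g for g, e in markers.items() if e > 0),
                 key=lambda g: -abs(markers[g]))
    neg = sorted((g for g, e in markers.items() if e < 0),
                 key=lambda g: -abs(markers[g]))
    if not pos or not neg:
        raise ValueError("need at least one positive- and one negative-effect genus")
    spec = SemSpec({"lv1": pos, "lv2": neg}, outcome=outcome)
    if spec.under_identified:
        log.warning("model spec is under-identified for a free fit "
                    "(a latent has a single indicator)")
    return spec


# ---------------------------------------------------------------------------
# Sample statistics
# ---------------------------------------------------------------------------

def polyserial_binary(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-step ML polyserial correlation of a continuous x with binary y.

    Returns ``(rho, asymptotic variance of rho)``.  Step 1 estimates the
    probit threshold from the marginal prevalence; step 2 maximizes the
    conditional likelihood of y given x over the latent correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(x)
    p1 = y.mean()
    if p1 <= 0 or p1 >= 1:
        raise ValueError("outcome must have both levels")
    tau = stats.norm.ppf(1 - p1)
    z = (x - x.mean()) / x.std()

    def nll(rho: float) -> float:
        s = np.sqrt(1 - rho * rho)
        q = (rho * z - tau) / s
        logp1 = stats.norm.logcdf(q)
        logp0 = stats.norm.logcdf(-q)
        return -np.sum(np.where(y == 1, logp1, logp0))

    res = optimize.minimize_scalar(nll, bounds=(-0.998, 0.998), method="bounded",
                                   options={"xatol": 1e-8})
    rho = float(res.x)
    h = 1e-4
    d2 = (nll(rho + h) - 2 * nll(rho) + nll(rho - h)) / h**2
    if not np.isfinite(d2) or d2 <= 0:
        d2 = n  # fall back to a unit-information curvature
    return rho, 1.0 / d2


def _sample_stats(spec: SemSpec, clr: pd.DataFrame, outcome: np.ndarray) -> dict:
    """Correlation vector, weights and bookkeeping for a DWLS fit."""
    names = spec.all_indicators
    missing = [g for g in names if g not in clr.columns]
    if missing:
        raise ValueError(f"spec variables absent from data: {missing}")
    y = np.asarray(outcome).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("outcome must be binary with both levels present")
    X = clr[names].to_numpy(dtype=float)
    n = X.shape[0]
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if (sds <= 0).any():
        bad = names[int(np.argmin(sds))]
        raise ValueError(f"indicator {bad!r} has zero variance")
    Z = (X - means) / sds
    R = np.corrcoef(Z, rowvar=False)
    p = len(names)
    pairs: list[tuple[int, int]] = [(i, j) for i in range(p) for j in range(i + 1, p)]
    s = [R[i, j] for i, j in pairs]
    avar = [(1 - R[i, j] ** 2) ** 2 / n for i, j in pairs]
    for j in range(p):
        rho, var = polyserial_binary(Z[:, j], y)
        pairs.append((j, p))  # index p stands for the outcome
        s.append(rho)
        avar.append(var)
    avar = np.maximum(np.asarray(avar), 1e-12)
    return {
        "names": names, "pairs": pairs, "s": np.asarray(s), "avar": avar,
        "n": n, "means": pd.Series(means, index=names),
        "sds": pd.Series(sds, index=names),
    }


# ---------------------------------------------------------------------------
# DWLS fit
# ---------------------------------------------------------------------------

def _implied(theta: np.ndarray, spec: SemSpec, pairs, p: int) -> np.ndarray:
    lam = theta[:p]
    b1, b2 = theta[p], theta[p + 1]
    c = theta[p + 2] if spec.latent_cov_free else 0.0
    factor = np.empty(p, dtype=int)
    k = 0
    for f, lv in enumerate(LATENTS):
        for _ in spec.indicators[lv]:
            factor[k] = f
            k += 1
    phi = np.array([[1.0, c], [c, 1.0]])
    b = np.array([b1, b2])
    fy = phi @ b  # cov(F, y*)
    out = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        if j < p:
            out[k] = lam[i] * lam[j] * phi[factor[i], factor[j]]
        else:
            out[k] = lam[i] * fy[factor[i]]
    return out


def fit_sem(
    spec: SemSpec,
    clr: pd.DataFrame,
    outcome: np.ndarray,
    stats_cache: dict | None = None,
) -> FittedSem:
    """Fit the SEM by diagonally weighted least squares.

    ``clr`` is a sample x genus matrix (columns at least the spec
    indicators); ``outcome`` the binary disease vector aligned with its rows.
    Observed variables are standardized internally (the moments are frozen
    on the fitted population for later scoring).  Non-convergence is flagged
    but estimates are still returned.
    """
    st = stats_cache or _sample_stats(spec, clr, outcome)
    names, pairs, s, avar, n = st["names"], st["pairs"], st["s"], st["avar"], st["n"]
    p = len(names)
    w = 1.0 / avar
    sw = np.sqrt(w)

    n_free = p + 2 + (1 if spec.latent_cov_free else 0)
    q = p + 1
    df = q * (q - 1) // 2 - n_free
    if df < 0:
        log.warning("model has negative degrees of freedom (%d); "
                    "estimates are not identified", df)

    def resid(theta: np.ndarray) -> np.ndarray:
        return sw * (_implied(theta, spec, pairs, p) - s)

    # start loadings at the outcome-correlation signs, paths at small values
    theta0 = np.concatenate([np.full(p, 0.5), [0.1, -0.1], [0.0][: int(spec.latent_cov_free)]])
    lo = np.concatenate([np.full(p, -1.8), [-3.0, -3.0], [-0.99][: int(spec.latent_cov_free)]])
    hi = -lo
    sol = optimize.least_squares(resid, theta0, bounds=(lo, hi), method="trf",
                                 xtol=1e-12, ftol=1e-12, gtol=1e-10)
    converged = bool(sol.status > 0 and np.all(np.isfinite(sol.x)))
    theta = sol.x
    J = sol.jac
    try:
        acov = np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular weight matrix in the DWLS fit; consider removing an indicator"
        ) from exc
    se = np.sqrt(np.clip(np.diag(acov), 0, None))

    lam = theta[:p]
    b = theta[p:p + 2]
    c = float(theta[p + 2]) if spec.latent_cov_free else 0.0
    resid_var = 1 - lam**2
    se_resid = 2 * np.abs(lam) * se[:p]
    psi = 1 - (b[0] ** 2 + b[1] ** 2 + 2 * b[0] * b[1] * c)
    # delta method for psi over (b1, b2, c)
    idx = [p, p + 1] + ([p + 2] if spec.latent_cov_free else [])
    grad = np.array([-2 * b[0] - 2 * b[1] * c, -2 * b[1] - 2 * b[0] * c]
                    + ([-2 * b[0] * b[1]] if spec.latent_cov_free else []))
    psi_var = float(grad @ acov[np.ix_(idx, idx)] @ grad)
    se_psi = np.sqrt(max(psi_var, 0.0))

    heywood = [names[i] for i in range(p) if resid_var[i] < 0]
    if psi < 0:
        heywood.append(spec.outcome)

    rows = []

    def add(lhs, op, rhs, est, se_v):
        if se_v is not None and se_v > 0:
            z = est / se_v
            pval = 2 * stats.norm.sf(abs(z))
            lo_ci, hi_ci = est - 1.96 * se_v, est + 1.96 * se_v
        else:
            z = pval = np.nan
            lo_ci = hi_ci = est
            se_v = 0.0
        rows.append(dict(lhs=lhs, op=op, rhs=rhs, est=float(est), se=float(se_v),
                         z=float(z), p=float(pval),
                         **{"ci.lower": float(lo_ci), "ci.upper": float(hi_ci)}))

    k = 0
    for lv in LATENTS:
        for g in spec.indicators[lv]:
            add(lv, "=~", g, lam[k], se[k])
            k += 1
    add(spec.outcome, "~", "lv1", b[0], se[p])
    add(spec.outcome, "~", "lv2", b[1], se[p + 1])
    for i, g in enumerate(names):
        add(g, "~~", g, resid_var[i], se_resid[i])
    add(spec.outcome, "~~", spec.outcome, psi, se_psi)
    add("lv1", "~~", "lv1", 1.0, None)
    add("lv2", "~~", "lv2", 1.0, None)
    add("lv1", "~~", "lv2", c, se[p + 2] if spec.latent_cov_free else None)
    est_df = pd.DataFrame(rows)

    st["sigma"] = _implied(theta, spec, pairs, p)
    st["w_unit"] = w / n  # unit-N weights for the discrepancy
    st["df"] = df
    fitted = FittedSem(
        spec=spec, estimates=est_df, fit=None, n_samples=n, converged=converged,
        heywood=heywood, train_means=st["means"], train_sds=st["sds"],
        sample_stats=st,
    )
    fitted.fit = fit_indices(fitted)
    return fitted


def rmsea(chi2: float, df: int, n: int) -> float:
    """Root-mean-square error of approximation."""
    if df <= 0:
        return 0.0
    return float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))


def fit_indices(f: FittedSem) -> FitIndices:
    """Chi-square, GFI, AGFI and RMSEA from the DWLS discrepancy.

    chi2 = (N-1) * F with F the weighted sum of squared correlation
    residuals (unit-N weights); GFI compares the residual weighted sum of
    squares against the total for the sample correlations; AGFI applies the
    parsimony correction and is undefined (None) at df = 0.
    """
    st = f.sample_stats
    s, sigma, w, df, n = st["s"], st["sigma"], st["w_unit"], st["df"], st["n"]
    F = float(np.sum(w * (s - sigma) ** 2))
    chi2 = (n - 1) * F
    total = float(np.sum(w * s**2))
    gfi = 1.0 - F / total if total > 0 else 1.0
    q = len(f.spec.all_indicators) + 1
    agfi = None if df <= 0 else 1.0 - (q * (q + 1) / (2.0 * df)) * (1.0 - gfi)
    return FitIndices(chi2=chi2, df=max(df, 0), gfi=gfi, agfi=agfi,
                      rmsea=rmsea(chi2, df, n))


# ---------------------------------------------------------------------------
# Model modification
# ---------------------------------------------------------------------------

def _admissible(f: FittedSem, alpha: float, rmsea_max: float) -> bool:
    if f.heywood or f.spec.under_identified or not f.converged:
        return False
    m = f.estimates
    load_p = m[m.op == "=~"].p
    path_p = m[m.op == "~"].p
    if (load_p >= alpha).any() or (path_p >= alpha).any():
        return False
    return f.fit.rmsea < rmsea_max


def modify_model(
    f: FittedSem,
    clr: pd.DataFrame,
    outcome: np.ndarray,
    alpha: float = 0.05,
    rmsea_max: float = 0.08,
) -> tuple[FittedSem, list[dict]]:
    """Backward-eliminate indicators until the model is admissible.

    Phase 1 deletes, one at a time, the indicator with the most negative
    variance component while any Heywood case exists.  Phase 2 deletes the
    indicator with the largest non-significant loading p-value.  Among all
    admissible models visited, the one maximizing the summed absolute
    structural paths subject to RMSEA < ``rmsea_max`` is returned together
    with the deletion log.  If no admissible model is visited a
    :class:`ModelConstructionError` is raised (the model "could not be
    constructed").
    """
    visited: list[FittedSem] = [f]
    deletions: list[dict] = []
    current = f

    def refit(spec: SemSpec) -> FittedSem:
        fit = fit_sem(spec, clr, outcome)
        visited.append(fit)
        return fit

    # Phase 1: clear Heywood cases.
    while current.heywood:
        resv = current.residual_variances()
        cand = [g for g in current.heywood if g != current.spec.outcome]
        if not cand:
            break  # only the outcome residual is negative; indicators can't fix it
        worst = min(cand, key=lambda g: resv[g])
        spec = current.spec.drop(worst)
        deletions.append({"phase": 1, "indicator": worst,
                          "residual_variance": float(resv[worst])})
        if spec.under_identified:
            log.warning("deleting %s leaves a latent with <2 indicators; stopping", worst)
            break
        current = refit(spec)

    # Phase 2: clear non-significant loadings.
    while True:
        m = current.estimates
        bad = m[(m.op == "=~") & (m.p >= alpha)]
        if bad.empty:
            break
        worst_row = bad.sort_values("p", ascending=False).iloc[0]
        worst = worst_row.rhs
        spec = current.spec.drop(worst)
        deletions.append({"phase": 2, "indicator": worst, "p": float(worst_row.p)})
        if spec.under_identified:
            log.warning("deleting %s leaves a latent with <2 indicators; stopping", worst)
            break
        current = refit(spec)

    admissible = [m for m in visited if _admissible(m, alpha, rmsea_max)]
    if not admissible:
        raise ModelConstructionError(
            "the structural equation model could not be constructed: no admissible "
            "candidate (significant loadings and paths, no Heywood case, "
            f"RMSEA < {rmsea_max}) was reached"
        )
    best = max(admissible, key=lambda m: float(np.abs(m.paths()).sum()))
    return best, deletions
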