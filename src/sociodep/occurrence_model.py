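"""Occurrence of social units at depredation events: binomial mixed model.

Each retained vessel sighting contributes one binary record per social
unit (present = 1 iff at least one member was photographed), after an
exclusion rule that drops re-sightings of the same units around the same
vessel within 12 h (vessels are typically followed between consecutive
hauls, which would otherwise inflate occurrence probabilities).

The model is a binomial GLMM with logit link,

    logit P(present) = X beta + sum_g Z_g u_g,   u_g ~ N(0, sigma_g^2 I)

with categorical fixed terms (year, month, social unit; treatment coding,
first level as reference) and categorical random intercepts (the five-level
photographic-effort band; optionally sighting and unit-within-sighting for
the pseudoreplication check).  Fitting maximises the Laplace-approximated
marginal likelihood: for each variance configuration the joint penalised
likelihood is maximised over (beta, u) by Newton iterations (PIRLS) and
the profiled Laplace objective is optimised over log sigma^2; with a
single grouping factor the final log-likelihood is evaluated by adaptive
Gauss-Hermite quadrature (15 nodes).  Model comparison uses AICc with
n = number of records; goodness of fit uses the latent-scale
Nakagawa-Schielzeth R^2 (marginal and conditional, logit residual
variance pi^2/3).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, special, stats
from scipy.sparse.linalg import splu
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.stattools import durbin_watson

logger = logging.getLogger(__name__)

LOGIT_RESIDUAL_VAR = np.pi ** 2 / 3.0


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with small-sample correction."""
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined: n <= K + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def count_parameters(fixed_level_counts, n_random_terms: int) -> int:
    """K = intercept + sum(levels - 1) per fixed factor + variance terms."""
    return 1 + sum(l - 1 for l in fixed_level_counts) + n_random_terms


# ---------------------------------------------------------------------------
# Occurrence table construction
# ---------------------------------------------------------------------------

def dedup_12h(sightings, partition, window_hours: float = 12.0):
    """Drop within-window re-sightings of the same units at the same vessel.

    Scanning each vessel's sightings in time order, a sighting is dropped
    when every unit photographed in it was already photographed around
    that vessel within the preceding ``window_hours``; the window is
    anchored at each unit's first sighting in the window (a sighting past
    the window re-anchors that unit).
    """
    member_unit = {m: u for u, ms in partition.units.items() for m in ms}
    window = pd.Timedelta(hours=window_hours)
    by_vessel: dict[str, list] = {}
    for s in sightings:
        by_vessel.setdefault(s.vessel_id, []).append(s)
    kept = []
    for vessel in sorted(by_vessel, key=str):
        anchors: dict[str, pd.Timestamp] = {}
        for s in sorted(by_vessel[vessel], key=lambda s: (s.start_time, s.sighting_id)):
            units = {member_unit[i] for i in s.individual_ids if i in member_unit}
            if not units:
                continue
            repeats = {u for u in units
                       if u in anchors and s.start_time - anchors[u] < window}
            if repeats == units:
                continue
            kept.append(s)
            for u in units - repeats:
                anchors[u] = s.start_time
    kept.sort(key=lambda s: (s.start_time, s.sighting_id))
    return kept


def build_occurrence_table(ds, partition, dedup_hours: float = 12.0) -> pd.DataFrame:
    """Long unit-by-sighting table of binary occurrence records."""
    from .sightings_io import VESSEL
    member_unit = {m: u for u, ms in partition.units.items() for m in ms}
    vessel = [s for s in ds.sightings if s.platform == VESSEL
              and any(i in member_unit for i in s.individual_ids)]
    retained = dedup_12h(vessel, partition, dedup_hours) if dedup_hours else vessel
    units = sorted(partition.units)
    rows = []
    for s in retained:
        present_units = {member_unit[i] for i in s.individual_ids if i in member_unit}
        for u in units:
            rows.append(dict(
                sighting_id=s.sighting_id, unit=u,
                present=int(u in present_units),
                year=str(s.year), month=f"{s.start_time.month:02d}",
                effort=s.effort_category, vessel_id=s.vessel_id,
                timestamp=s.start_time,
            ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _fixed_design(records: pd.DataFrame, fixed_terms):
    n = len(records)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    levels: dict[str, list[str]] = {}
    for term in fixed_terms:
        levs = sorted(records[term].astype(str).unique())
        if len(levs) < 2:
            raise ValueError(f"fixed term {term!r} has fewer than 2 levels")
        levels[term] = levs
        codes = pd.Categorical(records[term].astype(str), categories=levs).codes
        for k, lev in enumerate(levs[1:], start=1):
            cols.append((codes == k).astype(float))
            names.append(f"{term}[{lev}]")
    return np.column_stack(cols), names, levels


def _random_codes(records: pd.DataFrame, term: str):
    if ":" in term:
        parts = term.split(":")
        key = records[parts[0]].astype(str)
        for p in parts[1:]:
            key = key + ":" + records[p].astype(str)
    else:
        key = records[term].astype(str)
    codes, uniques = pd.factorize(key, sort=True)
    return codes.astype(np.int64), list(uniques)


def _sparse_Z(codes: np.ndarray, q: int) -> sparse.csr_matrix:
    n = codes.size
    return sparse.csr_matrix((np.ones(n), (np.arange(n), codes)), shape=(n, q))


# ---------------------------------------------------------------------------
# PIRLS + Laplace
# ---------------------------------------------------------------------------

def _bernoulli_loglik(y, eta):
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _pirls(y, X, Z, dinv, beta0, u0, max_iter=100, tol=1e-9):
    """Joint Newton maximisation of the penalised Bernoulli log-likelihood.

    Returns (beta, u, penalised loglik, u-block Hessian, converged).
    ``dinv`` is the per-coefficient prior precision vector (len q).
    """
    p = X.shape[1]
    q = 0 if Z is None else Z.shape[1]
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    u = np.zeros(q) if u0 is None else u0.copy()

    def eta_of(b, uu):
        e = X @ b
        if q:
            e = e + Z @ uu
        return e

    def pen_ll(b, uu):
        val = _bernoulli_loglik(y, eta_of(b, uu))
        if q:
            val -= 0.5 * float(np.sum(dinv * uu * uu))
        return val

    cur = pen_ll(beta, u)
    converged = False
    for _ in range(max_iter):
        eta = eta_of(beta, u)
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        resid = y - mu
        gb = X.T @ resid
        if q:
            gu = Z.T @ resid - dinv * u
            grad = np.concatenate([gb, gu])
        else:
            grad = gb
        if np.linalg.norm(grad) < tol * max(1.0, abs(cur)):
            converged = True
            break
        if q and p + q > 400:
            Xs = sparse.csr_matrix(X)
            C = sparse.hstack([Xs, Z], format="csr")
            A = (C.T.multiply(w) @ C
                 + sparse.diags(np.concatenate([np.zeros(p), dinv])))
            step = splu(A.tocsc()).solve(grad)
        else:
            Xw = X * w[:, None]
            if q:
                Zd = Z.toarray() if sparse.issparse(Z) else Z
                Zw = Zd * w[:, None]
                A = np.block([[X.T @ Xw, Xw.T @ Zd],
                              [Zw.T @ X, Zd.T @ Zw + np.diag(dinv)]])
            else:
                A = X.T @ Xw
            A = A + 1e-12 * np.eye(A.shape[0])
            step = np.linalg.solve(A, grad)
        # damped Newton
        t = 1.0
        for _ in range(30):
            nb = beta + t * step[:p]
            nu = u + t * step[p:] if q else u
            new = pen_ll(nb, nu)
            if new >= cur - 1e-12:
                break
            t *= 0.5
        beta, u, cur = nb, nu, new
    eta = eta_of(beta, u)
    mu = special.expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    if q:
        if sparse.issparse(Z):
            W = sparse.diags(w)
            Huu = (Z.T @ W @ Z + sparse.diags(dinv)).tocsc()
        else:
            Huu = Z.T @ (Z * w[:, None]) + np.diag(dinv)
    else:
        Huu = None
    return beta, u, cur, Huu, converged, w


def _logdet(H) -> float:
    if H is None:
        return 0.0
    if sparse.issparse(H):
        lu = splu(H)
        return float(np.sum(np.log(np.abs(lu.U.diagonal()))))
    sign, ld = np.linalg.slogdet(H)
    return float(ld)


def _laplace_loglik(pen_ll, Huu, dinv) -> float:
    """log marginal likelihood: penalised ll - 1/2 logdet(Huu) + 1/2 logdet(Dinv)."""
    if Huu is None:
        return pen_ll
    return pen_ll - 0.5 * _logdet(Huu) + 0.5 * float(np.sum(np.log(dinv)))


def _agh_loglik(y, eta_fixed, codes, sigma2, n_nodes=15):
    """Adaptive Gauss-Hermite marginal log-likelihood, single grouping factor."""
    t_nodes, w_nodes = np.polynomial.hermite.hermgauss(n_nodes)
    sigma2 = max(sigma2, 1e-12)
    total = 0.0
    for g in np.unique(codes):
        idx = codes == g
        yg, eg = y[idx], eta_fixed[idx]

        def negg(u):
            return -(np.sum(yg * (eg + u) - np.logaddexp(0.0, eg + u))
                     - u * u / (2.0 * sigma2))

        # scalar Newton for the conditional mode
        u_hat = 0.0
        for _ in range(50):
            mu = special.expit(eg + u_hat)
            g1 = np.sum(yg - mu) - u_hat / sigma2
            g2 = -np.sum(mu * (1 - mu)) - 1.0 / sigma2
            step = -g1 / g2
            u_hat += step
            if abs(step) < 1e-12:
                break
        h = np.sum(special.expit(eg + u_hat) * (1 - special.expit(eg + u_hat))) + 1.0 / sigma2
        scale = np.sqrt(2.0 / h)
        uk = u_hat + scale * t_nodes
        log_f = np.array([
            np.sum(yg * (eg + u) - np.logaddexp(0.0, eg + u)) - u * u / (2.0 * sigma2)
            for u in uk
        ]) - 0.5 * np.log(2.0 * np.pi * sigma2)
        total += special.logsumexp(log_f + t_nodes ** 2 + np.log(w_nodes)) + np.log(scale)
    return float(total)


# ---------------------------------------------------------------------------
# Model fit container
# ---------------------------------------------------------------------------

@dataclass
class GLMMFit:
    params: pd.Series
    cov_params: pd.DataFrame
    sigma2: dict[str, float]
    loglik: float
    K: int
    aicc: float
    r2_marginal: float
    r2_conditional: float
    n: int
    fixed_terms: tuple
    random_terms: tuple
    levels: dict[str, list[str]]
    method: str
    converged: bool
    separation_flag: bool
    formula: str
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    z_codes: dict[str, np.ndarray] = field(repr=False)
    records: pd.DataFrame = field(repr=False)
    u_hat: dict[str, np.ndarray] = field(repr=False)

    def linear_predictor(self, include_random: bool = True) -> np.ndarray:
        eta = self.X @ self.params.to_numpy()
        if include_random:
            for term, codes in self.z_codes.items():
                eta = eta + self.u_hat[term][codes]
        return eta


def _formula_string(fixed_terms, random_terms) -> str:
    fx = " + ".join(fixed_terms) if fixed_terms else "1"
    rd = " + ".join(f"(1|{t})" for t in random_terms)
    return f"present ~ {fx}" + (f" + {rd}" if rd else "")


def fit_glmm(records: pd.DataFrame,
             fixed_terms=("year", "month", "unit"),
             random_terms=("effort",),
             response: str = "present",
             fixed_sigma2: float | dict | None = None,
             agh_nodes: int = 15) -> GLMMFit:
    """Maximum-likelihood binomial GLMM with categorical random intercepts.

    With a single random term the reported log-likelihood is evaluated by
    adaptive Gauss-Hermite quadrature at the optimum; with several terms
    (or none) the Laplace (resp. exact logistic) value is reported.
    ``fixed_sigma2`` pins the variance component(s) instead of profiling
    them (``fixed_sigma2=0`` reduces the model to plain logistic
    regression while keeping the variance parameter in K).
    """
    fixed_terms = tuple(fixed_terms)
    random_terms = tuple(random_terms)
    y = records[response].to_numpy(dtype=float)
    X, names, levels = _fixed_design(records, fixed_terms)
    p = X.shape[1]
    n = len(records)

    codes_list, q_list, z_terms = [], [], {}
    for term in random_terms:
        codes, uniq = _random_codes(records, term)
        codes_list.append(codes)
        q_list.append(len(uniq))
        z_terms[term] = codes
    if random_terms:
        Z = sparse.hstack(
            [_sparse_Z(c, q) for c, q in zip(codes_list, q_list)], format="csr")
    else:
        Z = None

    def dinv_of(log_s2):
        s2 = np.exp(log_s2)
        return np.concatenate([np.full(q, 1.0 / max(s, 1e-10))
                               for q, s in zip(q_list, s2)])

    state = {"beta": None, "u": None}

    def profiled_negll(log_s2):
        dinv = dinv_of(np.atleast_1d(log_s2))
        beta, u, pll, Huu, conv, w = _pirls(y, X, Z, dinv, state["beta"], state["u"])
        state["beta"], state["u"] = beta, u
        return -_laplace_loglik(pll, Huu, dinv)

    if not random_terms:
        beta, u, pll, Huu, conv, w = _pirls(y, X, None, np.empty(0), None, None)
        log_s2_hat = np.empty(0)
        method = "logistic"
        ll = pll
    else:
        if fixed_sigma2 is not None:
            if isinstance(fixed_sigma2, dict):
                s2 = [max(float(fixed_sigma2[t]), 1e-10) for t in random_terms]
            else:
                s2 = [max(float(fixed_sigma2), 1e-10)] * len(random_terms)
            log_s2_hat = np.log(s2)
        elif len(random_terms) == 1:
            res = optimize.minimize_scalar(profiled_negll, bounds=(-18.0, 5.0),
                                           method="bounded",
                                           options={"xatol": 1e-5})
            log_s2_hat = np.array([res.x])
        else:
            # multi-term variance profiles are flat near the optimum; a
            # coarse simplex tolerance resolves LL to well under 0.01
            x0 = np.full(len(random_terms), np.log(0.25))
            res = optimize.minimize(profiled_negll, x0, method="Nelder-Mead",
                                    options={"xatol": 0.03, "fatol": 1e-3,
                                             "maxfev": 150})
            log_s2_hat = np.minimum(res.x, 5.0)
        dinv = dinv_of(log_s2_hat)
        beta, u, pll, Huu, conv, w = _pirls(y, X, Z, dinv, state["beta"], state["u"])
        if len(random_terms) == 1 and agh_nodes:
            ll = _agh_loglik(y, X @ beta, codes_list[0],
                             float(np.exp(log_s2_hat[0])), n_nodes=agh_nodes)
            method = "agh"
        else:
            ll = _laplace_loglik(pll, Huu, dinv)
            method = "laplace"

    if not conv:
        eta = X @ beta
        gnorm = float(np.linalg.norm(X.T @ (y - special.expit(eta))))
        raise RuntimeError(f"GLMM did not converge (gradient norm {gnorm:.3g})")
    separation = bool(np.any(np.abs(beta) > 15.0))
    if separation:
        warnings.warn("possible separation: |beta| > 15 for some coefficient")

    # covariance of beta from the joint (beta, u) Hessian at the mode
    q_total = 0 if Z is None else Z.shape[1]
    if q_total:
        Zd = Z.toarray() if q_total <= 2000 else None
        if Zd is not None:
            Xw = X * w[:, None]
            A = np.block([[X.T @ Xw, Xw.T @ Zd],
                          [(Zd * w[:, None]).T @ X,
                           Zd.T @ (Zd * w[:, None]) + np.diag(dinv_of(log_s2_hat))]])
            cov_full = np.linalg.inv(A + 1e-12 * np.eye(A.shape[0]))
            cov_beta = cov_full[:p, :p]
        else:
            Xs = sparse.csr_matrix(X)
            C = sparse.hstack([Xs, Z], format="csr")
            W = sparse.diags(w)
            A = (C.T @ W @ C).tolil()
            dv = dinv_of(log_s2_hat)
            for k in range(q_total):
                A[p + k, p + k] += dv[k]
            lu = splu(A.tocsc())
            cols = np.zeros((p + q_total, p))
            for k in range(p):
                e = np.zeros(p + q_total)
                e[k] = 1.0
                cols[:, k] = lu.solve(e)
            cov_beta = cols[:p, :]
    else:
        Xw = X * w[:, None]
        cov_beta = np.linalg.inv(X.T @ Xw + 1e-12 * np.eye(p))

    sigma2 = {t: float(np.exp(ls)) for t, ls in zip(random_terms, log_s2_hat)}
    K = p + len(random_terms)
    vf = float(np.var(X @ beta))
    vr = float(sum(sigma2.values()))
    denom = vf + vr + LOGIT_RESIDUAL_VAR
    u_hat = {}
    off = 0
    for term, q in zip(random_terms, q_list):
        u_hat[term] = u[off:off + q]
        off += q
    return GLMMFit(
        params=pd.Series(beta, index=names),
        cov_params=pd.DataFrame(cov_beta, index=names, columns=names),
        sigma2=sigma2, loglik=float(ll), K=K, aicc=aicc(float(ll), K, n),
        r2_marginal=vf / denom, r2_conditional=(vf + vr) / denom, n=n,
        fixed_terms=fixed_terms, random_terms=random_terms, levels=levels,
        method=method, converged=conv, separation_flag=separation,
        formula=_formula_string(fixed_terms, random_terms),
        X=X, y=y, z_codes=z_terms, records=records, u_hat=u_hat)


# ---------------------------------------------------------------------------
# Forward AICc selection
# ---------------------------------------------------------------------------

def select_model(records: pd.DataFrame,
                 candidate_order=("year", "month", "unit"),
                 random_terms=("effort",),
                 nested_extension=("sighting_id", "sighting_id:unit"),
                 agh_nodes: int = 15) -> tuple[pd.DataFrame, list[GLMMFit]]:
    """Forward model ladder compared by AICc.

    Fits the null model then adds the candidate fixed terms in order,
    reporting K, LL, AICc, Akaike weights, latent-scale R^2 (percent) and
    the nested likelihood-ratio X^2 against the previous model.  When
    ``nested_extension`` is given, the full model is refitted with the
    extra random structure (the pseudoreplication check) and compared to
    the full model with df = number of added variance terms.
    """
    fits: list[GLMMFit] = []
    rows = []
    prev = None
    ladder = [tuple(candidate_order[:k]) for k in range(len(candidate_order) + 1)]
    for fx in ladder:
        fit = fit_glmm(records, fixed_terms=fx, random_terms=random_terms,
                       agh_nodes=agh_nodes)
        x2 = df = pval = float("nan")
        if prev is not None:
            x2 = max(0.0, 2.0 * (fit.loglik - prev.loglik))
            df = fit.K - prev.K
            pval = float(stats.chi2.sf(x2, df))
        rows.append(dict(model=fit.formula, K=fit.K, LL=fit.loglik,
                         AICc=fit.aicc, r2m_pct=100 * fit.r2_marginal,
                         r2c_pct=100 * fit.r2_conditional,
                         X2=x2, df=df, p_value=pval))
        fits.append(fit)
        prev = fit
    if nested_extension:
        full = fits[-1]
        ext = fit_glmm(records, fixed_terms=full.fixed_terms,
                       random_terms=tuple(random_terms) + tuple(nested_extension),
                       agh_nodes=agh_nodes)
        x2 = max(0.0, 2.0 * (ext.loglik - full.loglik))
        df = ext.K - full.K
        rows.append(dict(model=ext.formula, K=ext.K, LL=ext.loglik,
                         AICc=ext.aicc, r2m_pct=100 * ext.r2_marginal,
                         r2c_pct=100 * ext.r2_conditional,
                         X2=x2, df=df, p_value=float(stats.chi2.sf(x2, df))))
        fits.append(ext)
    ladder_df = pd.DataFrame(rows)
    d = ladder_df.AICc - ladder_df.AICc.min()
    w = np.exp(-0.5 * d)
    ladder_df["wAICc"] = w / w.sum()
    ladder_df["rank"] = ladder_df.AICc.rank(method="first").astype(int)
    return ladder_df, fits


# ---------------------------------------------------------------------------
# Simulation-based diagnostics
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsReport:
    dispersion_ratio: float
    dispersion_p: float
    ks_statistic: float
    ks_p: float
    outlier_p: float
    zero_inflation_ratio: float
    zero_inflation_p: float
    durbin_watson: float
    durbin_watson_p: float
    gvif: dict[str, float]
    n_simulations: int


def _simulate_from_fit(fit: GLMMFit, n_sim: int, rng: np.random.Generator) -> np.ndarray:
    """n_sim response vectors from the fitted model, re-drawing random effects."""
    eta_fix = fit.X @ fit.params.to_numpy()
    n = fit.n
    sims = np.empty((n_sim, n), dtype=np.int8)
    for s in range(n_sim):
        eta = eta_fix.copy()
        for term, codes in fit.z_codes.items():
            q = int(codes.max()) + 1
            u = rng.normal(0.0, np.sqrt(fit.sigma2[term]), size=q)
            eta = eta + u[codes]
        sims[s] = rng.random(n) < special.expit(eta)
    return sims


def _gvif(fit: GLMMFit) -> dict[str, float]:
    """Generalised VIF per fixed term from the fixed-effects design."""
    Xc = fit.X[:, 1:]
    names = list(fit.params.index[1:])
    if Xc.shape[1] == 0:
        return {}
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(Xc, rowvar=False)
    R = np.atleast_2d(R)
    det_all = np.linalg.det(R)
    out = {}
    for term in fit.fixed_terms:
        idx = [k for k, nm in enumerate(names) if nm.startswith(f"{term}[")]
        other = [k for k in range(len(names)) if k not in idx]
        if not idx:
            continue
        if det_all <= 1e-12:
            out[term] = float("inf")
            continue
        d1 = np.linalg.det(R[np.ix_(idx, idx)])
        d2 = np.linalg.det(R[np.ix_(other, other)]) if other else 1.0
        out[term] = float(d1 * d2 / det_all)
    return out


def diagnose(fit: GLMMFit, n_sim: int = 1000, seed: int | None = 0) -> DiagnosticsReport:
    """DHARMa-style simulation residual checks of a fitted occurrence model."""
    rng = np.random.default_rng(seed)
    sims = _simulate_from_fit(fit, n_sim, rng)
    y = fit.y

    # scaled residuals: rank of the observation in its simulated distribution
    p_less = (sims < y[None, :]).mean(axis=0)
    p_eq = (sims == y[None, :]).mean(axis=0)
    scaled = p_less + rng.random(fit.n) * p_eq
    ks_stat, ks_p = stats.kstest(scaled, "uniform")
    n_out = int(((scaled <= 1.0 / (n_sim + 1)) | (scaled >= n_sim / (n_sim + 1.0))).sum())
    expected_out = 2.0 * fit.n / (n_sim + 1.0)
    outlier_p = float(stats.binomtest(n_out, fit.n, min(1.0, expected_out / fit.n)).pvalue)

    mu = special.expit(fit.linear_predictor(include_random=True))
    sd = np.sqrt(np.clip(mu * (1 - mu), 1e-10, None))
    var_obs = float(np.var((y - mu) / sd))
    var_sim = np.var((sims - mu[None, :]) / sd[None, :], axis=1)
    dispersion = var_obs / float(var_sim.mean())
    disp_p = float(2 * min((var_sim >= var_obs).mean(), (var_sim <= var_obs).mean()))
    disp_p = min(1.0, disp_p + 1.0 / n_sim)

    zeros_obs = float((y == 0).sum())
    zeros_sim = (sims == 0).sum(axis=1).astype(float)
    zi_ratio = zeros_obs / float(zeros_sim.mean())
    zi_p = float(2 * min((zeros_sim >= zeros_obs).mean(), (zeros_sim <= zeros_obs).mean()))
    zi_p = min(1.0, zi_p + 1.0 / n_sim)

    order = np.argsort(fit.records["timestamp"].to_numpy(), kind="stable")
    dw = float(durbin_watson(scaled[order] - 0.5))
    z = (1.0 - dw / 2.0) * np.sqrt(fit.n)
    dw_p = float(2 * stats.norm.sf(abs(z)))

    return DiagnosticsReport(
        dispersion_ratio=dispersion, dispersion_p=disp_p,
        ks_statistic=float(ks_stat), ks_p=float(ks_p), outlier_p=outlier_p,
        zero_inflation_ratio=zi_ratio, zero_inflation_p=zi_p,
        durbin_watson=dw, durbin_watson_p=dw_p,
        gvif=_gvif(fit), n_simulations=n_sim)


# ---------------------------------------------------------------------------
# Estimated marginal means
# ---------------------------------------------------------------------------

@dataclass
class EmmResult:
    emmeans: pd.DataFrame     # unit, prob, lo95, hi95, eta, se
    contrasts: pd.DataFrame   # unit_a, unit_b, estimate, se, z, p, p_holm
    level: float


def emmeans_units(fit: GLMMFit, level: float = 0.95,
                  term: str = "unit") -> EmmResult:
    """Per-unit marginal probabilities and Holm-adjusted pairwise contrasts.

    The linear predictor is averaged on the link scale over a balanced
    reference grid of the other fixed factors (equal level weights) with
    random effects at zero; CIs are delta-method on the link scale then
    back-transformed.
    """
    if term not in fit.fixed_terms:
        raise ValueError(f"model has no fixed term {term!r}")
    names = list(fit.params.index)
    beta = fit.params.to_numpy()
    cov = fit.cov_params.to_numpy()
    zcrit = stats.norm.ppf(0.5 + level / 2.0)

    base = np.zeros(len(names))
    base[names.index("(Intercept)")] = 1.0
    for other in fit.fixed_terms:
        if other == term:
            continue
        levs = fit.levels[other]
        for lev in levs[1:]:
            base[names.index(f"{other}[{lev}]")] = 1.0 / len(levs)

    units = fit.levels[term]
    L = np.tile(base, (len(units), 1))
    for k, u in enumerate(units[1:], start=1):
        L[k, names.index(f"{term}[{u}]")] = 1.0

    eta = L @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", L, cov, L))
    emm = pd.DataFrame({
        "unit": units, "eta": eta, "se": se,
        "prob": special.expit(eta),
        "lo95": special.expit(eta - zcrit * se),
        "hi95": special.expit(eta + zcrit * se),
    })

    rows = []
    for a in range(len(units)):
        for b in range(a + 1, len(units)):
            c = L[a] - L[b]
            est = float(c @ beta)
            cse = float(np.sqrt(c @ cov @ c))
            zst = est / cse if cse > 0 else float("inf")
            rows.append(dict(unit_a=units[a], unit_b=units[b],
                             estimate=est, se=cse, z=zst,
                             p=float(2 * stats.norm.sf(abs(zst)))))
    contrasts = pd.DataFrame(rows)
    if len(contrasts):
        contrasts["p_holm"] = multipletests(contrasts["p"], method="holm")[1]
    return EmmResult(emm, contrasts, level)
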