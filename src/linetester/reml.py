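"""REML estimation of variance components for the trial mixed models.

The engine fits Gaussian mixed models of the form

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, s2_k I),   e ~ N(0, s2_e I)

by restricted maximum likelihood, using the mixed model equations with
average-information (AI) updates after a couple of EM warm-up steps.  All
factors are plain categorical main effects or interactions of columns of the
plot table; ``a:b`` (or ``a%in%b``) denotes the combined factor.  Negative
variance updates are projected to the zero boundary, matching how boundary
components are reported (as 0.00) in combining-ability tables.

Convenience wrappers fit the three standard models of a multi-environment
testcross analysis:

* :func:`fit_genotype_model` — env and rep-within-env fixed; block, genotype,
  genotype×env random.  Its components feed broad-sense heritability.
* :func:`fit_lxt_single_env` — one environment; rep fixed; block, line,
  tester, line×tester random.
* :func:`fit_lxt_across_env` — env and rep-within-env fixed; block, line,
  tester, line×tester and all their interactions with environment random.

:func:`lrt_variance_component` tests a single variance component with the
boundary-corrected 50:50 chi-square mixture reference.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.stats import chi2

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "FitResult",
    "RemlError",
    "fit_reml",
    "fit_genotype_model",
    "fit_lxt_single_env",
    "fit_lxt_across_env",
    "lrt_variance_component",
    "entry_blues",
]

# problems whose mixed-model-equation dimension is below this use dense Cholesky
_DENSE_LIMIT = 700
# after absorbing the largest random factor, remainders up to this use dense Cholesky
_ABSORB_DENSE_LIMIT = 2600
_MAX_ITER = 500
_LOGL_RTOL = 1e-8
_PAR_RTOL = 1e-6


class RemlError(RuntimeError):
    """Non-convergence or estimability failure in a REML fit."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative fixed/random structure for one response trait."""

    response: str
    fixed_terms: tuple[str, ...]
    random_terms: tuple[str, ...]
    data_scope: str = "across_environments"

    def __post_init__(self):
        fixed = tuple(_norm_term(t) for t in self.fixed_terms)
        rand = tuple(_norm_term(t) for t in self.random_terms)
        object.__setattr__(self, "fixed_terms", fixed)
        object.__setattr__(self, "random_terms", rand)
        dup = set(fixed) & set(rand)
        if dup:
            raise ValueError(f"terms in both fixed and random parts: {sorted(dup)}")

    @classmethod
    def parse(cls, formula: str, data_scope: str = "across_environments") -> "ModelSpec":
        """Parse a compact model string.

        Example::

            ModelSpec.parse("GY ~ fixed(env + rep%in%env) + "
                            "random(block%in%rep%in%env + line + tester + line:tester)")
        """
        lhs, rhs = formula.split("~", 1)
        fixed_m = re.search(r"fixed\(([^)]*)\)", rhs)
        random_m = re.search(r"random\(([^)]*)\)", rhs)
        fixed = [t.strip() for t in fixed_m.group(1).split("+")] if fixed_m else []
        rand = [t.strip() for t in random_m.group(1).split("+")] if random_m else []
        return cls(lhs.strip(), tuple(t for t in fixed if t), tuple(t for t in rand if t),
                   data_scope)


def _norm_term(term: str) -> str:
    """``a%in%b`` and ``a:b`` both denote the combined factor; normalise to ``:``."""
    return ":".join(p.strip() for p in term.replace("%in%", ":").split(":"))


@dataclass
class VarianceComponents:
    """Fitted variance of each random term plus the residual."""

    components: dict[str, float]
    residual: float
    loglik: float
    converged: bool
    n_iter: int = 0

    def __getitem__(self, term: str) -> float:
        if term == "residual":
            return self.residual
        return self.components[_norm_term(term)]

    def as_dict(self) -> dict[str, float]:
        out = dict(self.components)
        out["residual"] = self.residual
        return out


@dataclass
class FitResult:
    spec: ModelSpec
    components: VarianceComponents
    fixed_effects: pd.Series
    fixed_se: pd.Series
    blups: dict[str, pd.Series]
    blup_se: dict[str, pd.Series]
    loglik: float
    converged: bool
    n_obs: int
    residual_df: int
    n_iter: int = 0
    entry_means: pd.Series | None = None
    sed: float | None = None

    @property
    def grand_mean(self) -> float:
        return float(self.fixed_effects.get("(Intercept)", np.nan))


# ---------------------------------------------------------------- factors ---

def _combined_factor(df: pd.DataFrame, term: str) -> tuple[np.ndarray, list[str]]:
    cols = term.split(":")
    for c in cols:
        if c not in df.columns:
            raise RemlError(f"term {term!r}: column {c!r} not in data")
    key = df[cols[0]].astype(str)
    for c in cols[1:]:
        key = key + ":" + df[c].astype(str)
    cat = pd.Categorical(key)
    return np.asarray(cat.codes), [str(l) for l in cat.categories]


def _indicator(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    n = codes.shape[0]
    return sp.csr_matrix((np.ones(n), (np.arange(n), codes)), shape=(n, n_levels))


def _fixed_design(df: pd.DataFrame, terms: tuple[str, ...]):
    """Intercept + full indicators per term, pruned to a full-rank column set.

    Rank detection uses pivoted Cholesky of X'X, so aliased columns (e.g. the
    redundancy between env and rep-within-env indicators) are dropped
    deterministically.
    """
    n = len(df)
    blocks = [sp.csr_matrix(np.ones((n, 1)))]
    names = ["(Intercept)"]
    for term in terms:
        codes, levels = _combined_factor(df, term)
        blocks.append(_indicator(codes, len(levels)))
        names.extend(f"{term}[{l}]" for l in levels)
    X = sp.hstack(blocks, format="csc")
    G = (X.T @ X).toarray()
    # pivoted Cholesky: rank-revealing for the PSD Gram matrix
    c, piv, rank, _ = sla.lapack.dpstrf(G, lower=1)
    keep = np.sort(piv[:rank] - 1)
    Xr = X[:, keep].toarray()
    kept_names = [names[i] for i in keep]
    return Xr, kept_names


# ------------------------------------------------------------ the engine ---

class _MME:
    """Mixed-model-equation workspace for fixed structure, varying variances.

    Three factorisation strategies by problem size:

    * small systems — dense Cholesky of the full coefficient matrix;
    * large systems — the largest random factor is absorbed by a Schur
      complement (its Z'Z block is diagonal, since each plot carries exactly
      one level of every factor), leaving a dense system over the remaining
      equations; the absorbed term's inverse diagonal is recovered from
      sparse quadratic forms against the Schur inverse;
    * very large remainders — sparse LU of the full system as a fallback.
    """

    def __init__(self, y, X, Zs):
        self.y = y
        self.X = sp.csr_matrix(X)
        self.Zs = Zs
        self.n = y.shape[0]
        self.p = X.shape[1]
        self.qs = [Z.shape[1] for Z in Zs]
        self.W = sp.hstack([self.X] + list(Zs), format="csr")
        self.WtW = (self.W.T @ self.W).tocsc()
        self.Wty = self.W.T @ y
        self.yty = float(y @ y)
        self.dim = self.p + sum(self.qs)
        offs = [self.p]
        for q in self.qs:
            offs.append(offs[-1] + q)
        self.offsets = offs  # random-term k occupies offsets[k]:offsets[k+1]

        self.mode = "dense" if self.dim <= _DENSE_LIMIT else "sparse"
        if self.mode == "dense":
            self.WtW_d = self.WtW.toarray()
        elif self.qs:
            a = int(np.argmax(self.qs))
            if self.dim - self.qs[a] <= _ABSORB_DENSE_LIMIT:
                self.mode = "absorb"
                self.absorb = a
                pa = np.arange(self.offsets[a], self.offsets[a + 1])
                pr = np.concatenate([np.arange(self.offsets[a]),
                                     np.arange(self.offsets[a + 1], self.dim)])
                self.perm_a, self.perm_r = pa, pr
                WtW = self.WtW
                self.WtW_rr = WtW[pr][:, pr].toarray()
                self.WtW_ra = WtW[pr][:, pa].tocsc()
                self.counts_a = WtW[pa, pa].A1 if hasattr(WtW[pa, pa], "A1") \
                    else np.asarray(WtW[pa, pa]).ravel()

    def _diag_vec(self, s2):
        d = np.zeros(self.dim)
        for k, v in enumerate(s2):
            d[self.offsets[k]:self.offsets[k + 1]] = 1.0 / v
        return d

    def factorize(self, s2, s2e):
        d = self._diag_vec(s2)
        if self.mode == "dense":
            C = self.WtW_d / s2e + np.diag(d)
            cf = sla.cho_factor(C, lower=True, check_finite=False)
            logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            return ("dense", cf, logdet)
        if self.mode == "absorb":
            d_a = self.counts_a / s2e + 1.0 / s2[self.absorb]
            C_ra = self.WtW_ra / s2e
            S = self.WtW_rr / s2e + np.diag(d[self.perm_r])
            T = C_ra.multiply(1.0 / d_a).tocsc()
            S -= (T @ C_ra.T).toarray()
            cf = sla.cho_factor(S, lower=True, check_finite=False)
            logdet = float(np.sum(np.log(d_a))) \
                + 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            return ("absorb", (cf, C_ra, d_a), logdet)
        C = (self.WtW / s2e + sp.diags(d)).tocsc()
        lu = spla.splu(C, permc_spec="MMD_AT_PLUS_A",
                       options={"SymmetricMode": True})
        logdet = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        return ("sparse", lu, logdet)

    def solve(self, fac, rhs):
        kind, f, _ = fac
        if kind == "dense":
            return sla.cho_solve(f, rhs, check_finite=False)
        if kind == "absorb":
            cf, C_ra, d_a = f
            one_d = rhs.ndim == 1
            R = rhs[:, None] if one_d else rhs
            r_a = R[self.perm_a]
            r_r = R[self.perm_r]
            x_r = sla.cho_solve(cf, r_r - C_ra @ (r_a / d_a[:, None]),
                                check_finite=False)
            x_a = (r_a - C_ra.T @ x_r) / d_a[:, None]
            out = np.empty_like(R)
            out[self.perm_r] = x_r
            out[self.perm_a] = x_a
            return out[:, 0] if one_d else out
        if rhs.ndim == 1:
            return f.solve(rhs)
        return f.solve(np.asarray(rhs, order="F"))

    def inv_diag(self, fac):
        kind, f, _ = fac
        if kind == "dense":
            Cinv = sla.cho_solve(f, np.eye(self.dim), check_finite=False)
            return np.diag(Cinv).copy()
        if kind == "absorb":
            cf, C_ra, d_a = f
            nr = len(self.perm_r)
            Sinv = sla.cho_solve(cf, np.eye(nr), check_finite=False)
            out = np.empty(self.dim)
            out[self.perm_r] = np.diag(Sinv)
            # diag of the absorbed block: 1/d_j + (c_j/d_j)' S^{-1} (c_j/d_j)
            indptr, indices, data = C_ra.indptr, C_ra.indices, C_ra.data
            qa = len(d_a)
            qf = np.empty(qa)
            for j in range(qa):
                s, e = indptr[j], indptr[j + 1]
                idx = indices[s:e]
                v = data[s:e]
                qf[j] = v @ (Sinv[np.ix_(idx, idx)] @ v)
            out[self.perm_a] = 1.0 / d_a + qf / d_a**2
            return out
        out = np.empty(self.dim)
        chunk = 1024
        for s in range(0, self.dim, chunk):
            e = min(s + chunk, self.dim)
            rhs = np.zeros((self.dim, e - s), order="F")
            rhs[np.arange(s, e), np.arange(e - s)] = 1.0
            sol = f.solve(rhs)
            out[s:e] = sol[np.arange(s, e), np.arange(e - s)]
        return out


def _reml_core(y, X, Zs, term_names, extra_logl_const=0.0):
    """AI-REML with EM warm-up.  Returns components, effects, loglik."""
    mme = _MME(y, X, Zs)
    n, p, m = mme.n, mme.p, len(Zs)
    ybar = float(np.mean(y))
    vary = float(np.var(y, ddof=1)) if n > 1 else 0.0
    scale = max(vary, 1e-12 * (1.0 + ybar * ybar))
    floor = 1e-8 * scale

    if vary <= 1e-14 * (1.0 + ybar * ybar):
        # degenerate: all observations equal
        comps = VarianceComponents({t: 0.0 for t in term_names}, floor, math.inf, True, 0)
        return comps, np.full(p, np.nan), mme, None

    s2 = np.full(m, vary / (m + 1))
    s2e = vary / (m + 1)
    const = (n - p) * math.log(2.0 * math.pi)

    # restricted likelihood via the MME identity
    # log|V| + log|X'V^{-1}X| = log|R| + log|G| + log|C|
    def loglik_state(s2, s2e):
        fac = mme.factorize(s2, s2e)
        theta = mme.solve(fac, mme.Wty / s2e)
        ypy = (mme.yty - float(theta @ mme.Wty)) / s2e
        logdetG = float(sum(q * math.log(v) for q, v in zip(mme.qs, s2)))
        ll = -0.5 * (n * math.log(s2e) + logdetG + fac[2] + ypy + const)
        return ll, fac, theta, ypy

    ll, fac, theta, ypy = loglik_state(s2, s2e)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        inv_d = mme.inv_diag(fac)
        tr = np.array([float(np.sum(inv_d[mme.offsets[k]:mme.offsets[k + 1]]))
                       for k in range(m)])
        uu = np.array([float(np.sum(theta[mme.offsets[k]:mme.offsets[k + 1]] ** 2))
                       for k in range(m)])
        resid = y - mme.W @ theta
        ee = float(resid @ resid)

        if it <= 2:
            # EM warm-up: monotone, slow, safe
            new_s2 = (uu + tr) / np.array(mme.qs, dtype=float)
            new_s2e = (mme.yty - float(theta @ mme.Wty)) / (n - p)
            new_s2 = np.maximum(new_s2, floor)
            new_s2e = max(new_s2e, floor)
        else:
            # scores of the restricted likelihood
            qs = np.array(mme.qs, dtype=float)
            tPZZ = (qs - tr / s2) / s2
            score = -0.5 * (tPZZ - uu / s2**2)
            tP = (n - p - float(np.sum((qs - tr / s2)))) / s2e
            score_e = -0.5 * (tP - ee / s2e**2)
            grad = np.append(score, score_e)
            params = np.append(s2, s2e)
            # active set: components on the zero boundary whose likelihood
            # decreases in them (KKT) stay pinned this iteration
            free = (params > 2.0 * floor) | (grad > 0.0)
            free[m] = True  # residual always free
            fidx = np.flatnonzero(free)
            # average-information matrix over the free parameters
            F = np.empty((n, len(fidx)))
            for c_, k in enumerate(fidx):
                if k < m:
                    uk = theta[mme.offsets[k]:mme.offsets[k + 1]]
                    F[:, c_] = (Zs[k] @ uk) / s2[k]
                else:
                    F[:, c_] = resid / s2e
            RHS = (mme.W.T @ F) / s2e
            TH = mme.solve(fac, RHS)
            PF = (F - mme.W @ TH) / s2e
            AI = 0.5 * (F.T @ PF)
            AI[np.diag_indices_from(AI)] += 1e-10 * np.trace(AI) / len(fidx)
            try:
                step_f = np.linalg.solve(AI, grad[fidx])
            except np.linalg.LinAlgError:
                step_f = grad[fidx] / np.maximum(np.diag(AI), 1e-12)
            step = np.zeros(m + 1)
            step[fidx] = step_f
            ok = False
            for _ in range(12):
                cand = np.maximum(params + step, floor)
                c_s2, c_s2e = cand[:m], cand[m]
                try:
                    c_ll, c_fac, c_theta, c_ypy = loglik_state(c_s2, c_s2e)
                except (sla.LinAlgError, RuntimeError, ValueError):
                    step *= 0.5
                    continue
                if np.isfinite(c_ll) and c_ll >= ll - 1e-10 * (1.0 + abs(ll)):
                    ok = True
                    break
                step *= 0.5
            if ok:
                new_s2, new_s2e = c_s2, c_s2e
            else:
                # EM fallback
                new_s2 = np.maximum((uu + tr) / np.array(mme.qs, dtype=float), floor)
                new_s2e = max((mme.yty - float(theta @ mme.Wty)) / (n - p), floor)

        dpar = np.max(np.abs(np.append(new_s2, new_s2e) - np.append(s2, s2e))) / scale
        s2, s2e = new_s2, new_s2e
        new_ll, fac, theta, ypy = loglik_state(s2, s2e)
        dll = abs(new_ll - ll) / (1.0 + abs(new_ll))
        ll = new_ll
        if it > 2 and dll < _LOGL_RTOL and dpar < _PAR_RTOL:
            converged = True
            break

    if not converged and it >= _MAX_ITER:
        raise RemlError(
            f"REML did not converge in {_MAX_ITER} iterations "
            f"(last logL {ll:.6f}, components {dict(zip(term_names, s2))})")

    # boundary reporting: components at the numerical floor are zero
    s2_rep = np.where(s2 <= 2.0 * floor, 0.0, s2)
    comps = VarianceComponents(dict(zip(term_names, s2_rep.tolist())), float(s2e),
                               float(ll + extra_logl_const), converged, it)
    return comps, theta, mme, fac


def fit_reml(records: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit ``spec`` to the plot records by REML.

    Rows with a missing response are dropped (listwise per trait, no
    imputation).  Deterministic: initialisation is an equal partition of the
    phenotypic variance, with no randomisation anywhere.
    """
    if spec.response not in records.columns:
        raise RemlError(f"response {spec.response!r} not in data")
    df = records.loc[records[spec.response].notna()].reset_index(drop=True)
    n = len(df)
    if n < 2:
        raise RemlError("need at least 2 observations with a non-missing response")
    y = df[spec.response].to_numpy(float)

    X, xnames = _fixed_design(df, spec.fixed_terms)
    Zs, term_levels = [], {}
    for term in spec.random_terms:
        codes, levels = _combined_factor(df, term)
        if len(levels) < 2:
            raise RemlError(f"random term {term!r} has fewer than 2 levels")
        Zs.append(_indicator(codes, len(levels)))
        term_levels[term] = levels

    comps, theta, mme, fac = _reml_core(y, X, Zs, list(spec.random_terms))

    p = mme.p
    if fac is None:  # degenerate all-equal data
        fixed = pd.Series(np.nan, index=xnames)
        fixed.iloc[0] = float(np.mean(y))
        blups = {t: pd.Series(0.0, index=term_levels[t]) for t in spec.random_terms}
        blup_se = {t: pd.Series(0.0, index=term_levels[t]) for t in spec.random_terms}
        return FitResult(spec, comps, fixed, pd.Series(0.0, index=xnames), blups,
                         blup_se, comps.loglik, True, n, n - p, 0)

    inv_d = mme.inv_diag(fac)
    fixed = pd.Series(theta[:p], index=xnames)
    fixed_se = pd.Series(np.sqrt(np.maximum(inv_d[:p], 0.0)), index=xnames)
    blups, blup_se = {}, {}
    for k, term in enumerate(spec.random_terms):
        s, e = mme.offsets[k], mme.offsets[k + 1]
        blups[term] = pd.Series(theta[s:e], index=term_levels[term])
        blup_se[term] = pd.Series(np.sqrt(np.maximum(inv_d[s:e], 0.0)),
                                  index=term_levels[term])
    return FitResult(spec, comps, fixed, fixed_se, blups, blup_se, comps.loglik,
                     comps.converged, n, n - p, comps.n_iter)


# ------------------------------------------------------- standard models ---

def _n_levels(df: pd.DataFrame, col: str) -> int:
    return int(df[col].nunique()) if col in df else 0


def fit_genotype_model(records: pd.DataFrame, trait: str,
                       entry_col: str = "entry") -> FitResult:
    """Combined-analysis genotype model for one trait.

    Fixed: environment and replicate-within-environment.  Random: incomplete
    block within rep within env, genotype, genotype×environment.  With a
    single environment, the environment terms are dropped (with a warning)
    and the model reduces to the within-trial form.
    """
    n_env = _n_levels(records, "env")
    if n_env >= 2:
        spec = ModelSpec(trait, ("env", "rep:env"),
                         ("block:rep:env", entry_col, f"{entry_col}:env"))
    else:
        warnings.warn("single environment: genotype-by-environment term dropped")
        spec = ModelSpec(trait, ("rep",), ("block:rep", entry_col),
                         data_scope="single_environment")
    return fit_reml(records, spec)


def fit_lxt_single_env(records: pd.DataFrame, trait: str) -> FitResult:
    """Within-environment line-by-tester model (testcross entries only)."""
    df = records
    if "entry_kind" in df:
        df = df.loc[df["entry_kind"] == "testcross"]
    if _n_levels(df, "env") > 1:
        raise RemlError("fit_lxt_single_env expects data from one environment")
    spec = ModelSpec(trait, ("rep",), ("block:rep", "line", "tester", "line:tester"),
                     data_scope="single_environment")
    return fit_reml(df, spec)


def fit_lxt_across_env(records: pd.DataFrame, trait: str) -> FitResult:
    """Across-environment line-by-tester model (testcross entries only).

    Environment and rep-within-environment fixed; line, tester, line×tester,
    their interactions with environment, and block random.  Returns all seven
    variance components (plus residual).
    """
    df = records
    if "entry_kind" in df:
        df = df.loc[df["entry_kind"] == "testcross"]
    n_env = _n_levels(df, "env")
    if n_env < 2:
        warnings.warn("single environment: environment interaction terms dropped")
        return fit_lxt_single_env(df, trait)
    spec = ModelSpec(trait, ("env", "rep:env"),
                     ("block:rep:env", "line", "tester", "line:tester",
                      "line:env", "tester:env", "line:tester:env"))
    return fit_reml(df, spec)


def lrt_variance_component(full: FitResult, reduced: FitResult) -> dict:
    """Likelihood-ratio test of one variance component on the boundary.

    The reduced model must drop exactly one random term from the full model
    (same response, same fixed effects, same data).  The null distribution is
    the 50:50 mixture of a point mass at zero and chi-square with 1 df, the
    standard correction for testing a variance on its boundary.
    """
    f, r = full.spec, reduced.spec
    if f.response != r.response or tuple(f.fixed_terms) != tuple(r.fixed_terms):
        raise ValueError("models differ in response or fixed effects; LRT not valid")
    dropped = set(f.random_terms) - set(r.random_terms)
    if len(dropped) != 1 or not set(r.random_terms) <= set(f.random_terms):
        raise ValueError("reduced model must drop exactly one random term")
    if full.n_obs != reduced.n_obs:
        raise ValueError("models were fitted to different numbers of observations")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = 1.0 if stat <= 0.0 else 0.5 * float(chi2.sf(stat, df=1))
    return {
        "term": next(iter(dropped)),
        "statistic": stat,
        "p_value": p,
        "significant_0.05": p < 0.05,
        "significant_0.01": p < 0.01,
        "significant_0.001": p < 0.001,
    }


# -------------------------------------------------------------- entry BLUEs ---

def entry_blues(records: pd.DataFrame, trait: str,
                entry_col: str = "entry") -> tuple[pd.Series, float, int, float]:
    """Adjusted entry means (BLUEs) from a fixed-entry mixed model.

    Entries are refitted as fixed (env and rep-within-env also fixed, block
    random) and each entry's BLUE is its average fitted fixed-effect value,
    so all means share the same environmental baseline.

    Returns
    -------
    means : Series indexed by entry
    err_var : average sampling variance of an entry mean
    df : residual degrees of freedom of the fit
    sed : average standard error of a difference between two entry means
    """
    df = records.loc[records[trait].notna()].reset_index(drop=True)
    n_env = _n_levels(df, "env")
    if n_env >= 2:
        fixed = ("env", "rep:env", entry_col)
        rand = ("block:rep:env",)
    else:
        fixed = ("rep", entry_col)
        rand = ("block:rep",)
    spec = ModelSpec(trait, fixed, rand)
    y = df[trait].to_numpy(float)
    X, xnames = _fixed_design(df, fixed)
    Zs, term_levels = [], {}
    for term in rand:
        codes, levels = _combined_factor(df, term)
        Zs.append(_indicator(codes, len(levels)))
        term_levels[term] = levels
    comps, theta, mme, fac = _reml_core(y, X, Zs, list(rand))
    p = mme.p
    beta = theta[:p]

    entries = pd.Categorical(df[entry_col].astype(str))
    ent_levels = list(entries.categories)
    # contrast row of each entry: average of its X rows (fixed part only)
    A = sp.csr_matrix((np.ones(len(df)), (entries.codes, np.arange(len(df)))),
                      shape=(len(ent_levels), len(df)))
    counts = np.asarray(A.sum(axis=1)).ravel()
    L = (A @ sp.csr_matrix(mme.X)).toarray() / counts[:, None]
    means = pd.Series(L @ beta, index=ent_levels, name=trait)

    if fac is None:
        return means, 0.0, mme.n - p, 0.0
    # Cov(beta) = top-left block of C^{-1}
    rhs = np.zeros((mme.dim, p), order="F")
    rhs[np.arange(p), np.arange(p)] = 1.0
    covb = mme.solve(fac, rhs)[:p, :]
    V = L @ covb @ L.T
    dv = np.diag(V)
    n_e = len(ent_levels)
    err_var = float(np.mean(dv))
    if n_e > 1:
        sum_off = float(V.sum() - dv.sum())
        mean_off = sum_off / (n_e * (n_e - 1))
        sed = math.sqrt(max(2.0 * err_var - 2.0 * mean_off, 0.0))
    else:
        sed = 0.0
    return means, err_var, mme.n - p, sed
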