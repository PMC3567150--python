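"""Repeated-records pedigree animal models estimated by AI-REML.

The model for a vector of records y is

    y = X b + Z a + W pe + e,
    Var(a) = A * V_POLY,  Var(pe) = I * V_pe,  Var(e) = I * V_e,

where b holds the fixed effects (stud.sex.year classes, an age covariate,
and optional major-locus covariates: STX17 coded GG=0/Gg=1, ASIP additive
AA=0/Aa=1/aa=2 and dominance AA=0/Aa=1/aa=0), a the polygenic breeding
values of all pedigree members, pe the permanent-environment effects of
recorded animals, and A the additive relationship matrix.

Variance components are estimated by average-information REML on the
mixed-model equations (MME), with expectation-maximisation (EM) fallback
steps whenever an AI update would leave the parameter space or reduce the
restricted likelihood.  Standard errors come from the inverse AI matrix at
convergence; breeding values are BLUP solutions of the MME at the
converged components.

The bivariate model stacks two (possibly different) record sets, with a
2x2 polygenic covariance matrix G0 (Var(a) = G0 (x) A), a 2x2
permanent-environment matrix PE0, and trait-specific residual variances.
A residual covariance is estimable only when records of the two traits are
explicitly paired one-to-one; otherwise it is structurally zero (the
package's trait windows never pair a young-horse with an adult record).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve, lapack

from .genotypes import GenotypeTable
from .pedigree import Pedigree, mendelian_sampling_variances

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "Design",
    "FitResult",
    "BivariateFit",
    "ConvergenceError",
    "RankDeficiencyError",
    "build_design",
    "reml_univariate",
    "reml_bivariate",
    "reml_loglik_univariate",
    "reml_loglik_bivariate",
    "predict_ebv",
    "standardize_ebv",
]

LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


class RankDeficiencyError(ValueError):
    """A fixed-effect term is confounded (no usable contrast)."""


@dataclass
class ModelSpec:
    """Which terms enter the model for one trait."""

    trait: str | None = None
    class_terms: tuple = ("stud", "sex", "year")
    age_covariate: bool = True
    stx17_covariate: bool = False
    asip_additive: bool = False
    asip_dominance: bool = False
    include_pe: bool = True


@dataclass
class Design:
    """Assembled design structures for one trait's records."""

    y: np.ndarray
    X: np.ndarray
    x_names: list
    rec_animal: np.ndarray  # record -> pedigree position (Z incidence)
    ped: Pedigree
    spec: ModelSpec
    n_dropped: int = 0
    trait: str = ""

    @property
    def n(self):
        return len(self.y)

    @property
    def n_fixed(self):
        return self.X.shape[1]

    def recorded_positions(self):
        return np.unique(self.rec_animal)


def build_design(
    records: pd.DataFrame,
    spec: ModelSpec,
    gt: GenotypeTable | None = None,
    ped: Pedigree | None = None,
) -> Design:
    """Build y, a full-column-rank X, and record->animal incidence maps.

    Records of animals lacking a genotype required by the spec are dropped
    (the count is logged and stored on the Design).  Class-factor dummy
    columns made redundant by the intercept or by each other are removed;
    a redundant *covariate* raises :class:`RankDeficiencyError`.
    """
    if ped is None:
        raise ValueError("a Pedigree is required")
    df = records.copy()
    df["animal"] = df["animal"].astype(str)
    unknown = [a for a in df["animal"].unique() if a not in ped._index]
    if unknown:
        raise ValueError(
            f"records reference animals absent from the pedigree: {unknown[:5]}"
        )

    needs_stx = spec.stx17_covariate
    needs_asip = spec.asip_additive or spec.asip_dominance
    if (needs_stx or needs_asip) and gt is None:
        raise ValueError("genotypes required by the model spec")
    n_before = len(df)
    if needs_stx:
        stx = gt.codes(df["animal"], "stx17")
        keep = stx >= 1  # GG (2) or Gg (1); gg and unknown have no code
        df, stx = df[keep], stx[keep]
    if needs_asip:
        asip = gt.codes(df["animal"], "asip")
        keep = np.isfinite(asip)
        df, asip = df[keep], asip[keep]
        if needs_stx:
            stx = stx[keep.values if hasattr(keep, "values") else keep]
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("dropped %d records lacking required genotypes", n_dropped)
    if df.empty:
        raise ValueError("no records left after genotype filtering")
    df = df.reset_index(drop=True)

    cols = [np.ones(len(df))]
    names = ["intercept"]
    cls_cols = {"intercept"}
    present = [t for t in spec.class_terms if t in df.columns]
    if present:
        combo = df[present].astype(str).agg(".".join, axis=1)
        levels = sorted(pd.unique(combo))
        for lev in levels[1:]:  # first (sorted) level is the reference
            cols.append((combo == lev).astype(float).values)
            names.append(f"class[{lev}]")
            cls_cols.add(names[-1])
    if spec.age_covariate:
        cols.append(df["age_months"].astype(float).values / 12.0)
        names.append("age_years")
    if needs_stx:
        code = np.asarray(stx, dtype=float)
        cols.append(np.where(code == 1, 1.0, 0.0))  # Gg=1, GG=0
        names.append("alpha_stx17")
    if needs_asip:
        a = np.asarray(asip, dtype=float)
        if spec.asip_additive:
            cols.append(2.0 - a)  # counts of the a allele: AA=0, Aa=1, aa=2
            names.append("alpha_asip")
        if spec.asip_dominance:
            cols.append(np.where(a == 1, 1.0, 0.0))
            names.append("delta_asip")

    X = np.column_stack(cols)
    for j, nm in enumerate(names):
        if nm not in cls_cols and len(np.unique(X[:, j])) < 2:
            raise RankDeficiencyError(
                f"covariate {nm!r} has a single observed value (confounded)"
            )
    X, names = _drop_dependent_columns(X, names, cls_cols)

    rec_animal = ped.positions(df["animal"])
    return Design(
        y=df["value"].astype(float).values,
        X=X,
        x_names=names,
        rec_animal=rec_animal,
        ped=ped,
        spec=spec,
        n_dropped=n_dropped,
        trait=spec.trait or (df["trait"].iloc[0] if "trait" in df else ""),
    )


def _drop_dependent_columns(X, names, cls_cols):
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    drop = sorted(piv[rank:])
    for j in drop:
        if names[j] not in cls_cols:
            raise RankDeficiencyError(
                f"covariate {names[j]!r} is confounded with other fixed effects"
            )
    keep = [j for j in range(X.shape[1]) if j not in set(drop)]
    if drop:
        logger.debug("dropped %d dependent class columns", len(drop))
    return X[:, keep], [names[j] for j in keep]


# ---------------------------------------------------------------------------
# shared dense-MME helpers
# ---------------------------------------------------------------------------


def _chol_logdet_inv(C):
    """Cholesky factor, log-determinant, and full inverse of SPD C."""
    c, low = cho_factor(C, lower=True, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    inv, info = lapack.dpotri(c, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("dpotri failed")
    inv = np.tril(inv) + np.tril(inv, -1).T
    return (c, low), logdet, inv


def _incidence(rows, n_rows, n_cols):
    data = np.ones(len(rows))
    return sparse.csr_matrix(
        (data, (np.arange(n_rows), rows)), shape=(n_rows, n_cols)
    )


# ---------------------------------------------------------------------------
# univariate REML
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Converged univariate fit."""

    components: dict
    se: dict
    fixed_effects: pd.DataFrame
    ebv: pd.DataFrame
    loglik: float
    converged: bool
    n_iter: int
    trace: list = field(default_factory=list, repr=False)
    ai_inverse: np.ndarray | None = None
    design: Design | None = field(default=None, repr=False)


class _UnivariateMME:
    """Precomputed cross-products; per-theta evaluation of the REML pieces."""

    def __init__(self, design: Design, A_inv):
        self.design = design
        ped = design.ped
        n, q_a = design.n, ped.n
        self.include_pe = design.spec.include_pe
        rec_pos = design.recorded_positions()
        self.pe_index = {p: k for k, p in enumerate(rec_pos)}
        self.pe_positions = rec_pos
        q_w = len(rec_pos) if self.include_pe else 0

        Xs = sparse.csr_matrix(design.X)
        Z = _incidence(design.rec_animal, n, q_a)
        blocks = [Xs, Z]
        if self.include_pe:
            w_rows = np.array([self.pe_index[p] for p in design.rec_animal])
            blocks.append(_incidence(w_rows, n, q_w))
        self.M = sparse.hstack(blocks, format="csr")
        self.MtM = (self.M.T @ self.M).toarray()
        self.Mty = self.M.T @ design.y
        self.yty = float(design.y @ design.y)
        self.p = design.n_fixed
        self.q_a, self.q_w, self.n = q_a, q_w, n
        self.sl_b = slice(0, self.p)
        self.sl_a = slice(self.p, self.p + q_a)
        self.sl_w = slice(self.p + q_a, self.p + q_a + q_w)
        self.A_inv = A_inv.toarray() if sparse.issparse(A_inv) else np.asarray(A_inv)
        self.logdet_A = float(
            np.sum(np.log(mendelian_sampling_variances(ped)))
        )

    def evaluate(self, theta, need_info=True):
        """REML pieces at theta = (v_poly, v_pe, v_e); v_pe ignored if no pe."""
        v_a, v_pe, v_e = theta
        C = self.MtM / v_e
        C[self.sl_a, self.sl_a] += self.A_inv / v_a
        if self.include_pe:
            idx = np.arange(self.p + self.q_a, self.p + self.q_a + self.q_w)
            C[idx, idx] += 1.0 / v_pe
        rhs = self.Mty / v_e
        chol, logdet_C, C_inv = _chol_logdet_inv(C)
        sol = cho_solve(chol, rhs, check_finite=False)
        yPy = (self.yty - self.Mty @ sol) / v_e
        loglik = -0.5 * (
            self.n * np.log(v_e)
            + self.q_a * np.log(v_a)
            + self.logdet_A
            + (self.q_w * np.log(v_pe) if self.include_pe else 0.0)
            + logdet_C
            + yPy
            + (self.n - self.p) * LOG2PI
        )
        state = {
            "theta": np.asarray(theta, dtype=float),
            "loglik": float(loglik),
            "sol": sol,
            "C_inv": C_inv,
            "chol": chol,
            "yPy": float(yPy),
        }
        if not need_info:
            return state

        u_a = sol[self.sl_a]
        uAu = float(u_a @ (self.A_inv @ u_a))
        tr_aa = float(np.sum(self.A_inv * C_inv[self.sl_a, self.sl_a]))
        e_hat = self.design.y - self.M @ sol
        Py = e_hat / v_e
        ete = float(e_hat @ e_hat)

        names = ["v_poly", "v_pe", "v_e"] if self.include_pe else ["v_poly", "v_e"]
        F = [self.M[:, self.sl_a] @ u_a / v_a]
        score = [
            -0.5 * (self.q_a / v_a - tr_aa / v_a**2 - uAu / v_a**2)
        ]
        em = {"v_poly": (uAu + tr_aa) / self.q_a}
        if self.include_pe:
            u_w = sol[self.sl_w]
            tr_ww = float(np.trace(C_inv[self.sl_w, self.sl_w]))
            F.append(self.M[:, self.sl_w] @ u_w / v_pe)
            score.append(
                -0.5 * (self.q_w / v_pe - tr_ww / v_pe**2 - (u_w @ u_w) / v_pe**2)
            )
            em["v_pe"] = (float(u_w @ u_w) + tr_ww) / self.q_w
        else:
            tr_ww = 0.0
        q_tot = self.q_a + self.q_w
        tr_P = (
            self.n
            - self.p
            - q_tot
            + tr_aa / v_a
            + (tr_ww / v_pe if self.include_pe else 0.0)
        ) / v_e
        F.append(Py)
        score.append(-0.5 * (tr_P - ete / v_e**2))
        em["v_e"] = v_e * yPy / (self.n - self.p)

        F = np.column_stack(F)
        rhs_F = self.M.T @ F / v_e
        S_F = cho_solve(chol, rhs_F, check_finite=False)
        PF = (F - self.M @ S_F) / v_e
        AI = 0.5 * (F.T @ PF)
        state.update(
            score=np.array(score),
            AI=AI,
            em=em,
            names=names,
            u_a=u_a,
            e_hat=e_hat,
        )
        return state


def _information_inverse(AI):
    """Inverse AI matrix for standard errors; pseudo-inverse at a boundary
    (where the AI matrix is singular along unidentified directions)."""
    try:
        return np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        warnings.warn(
            "AI matrix singular at the solution; SEs use a pseudo-inverse",
            stacklevel=2,
        )
        return np.linalg.pinv(AI)


def _default_init_univariate(y, include_pe):
    vp = float(np.var(y))
    vp = vp if vp > 0 else 1.0
    return np.array([0.3 * vp, 0.2 * vp if include_pe else np.nan, 0.5 * vp])


class _Reparam:
    """Unconstrained reparameterization of the variance parameters.

    Scalar variances are optimized on the log scale; each 2x2 covariance
    matrix uses a log-Cholesky parameterization (log of the two diagonal
    factor entries, raw off-diagonal).  The feasible set maps to all of
    R^k, so AI updates can never leave the parameter space, and a singular
    covariance matrix (zero variance, correlation +/-1) is a flat tail of
    the transformed surface rather than a hard boundary.

    ``blocks`` is a list of ("log", i) scalar entries and ("chol", (i, j, k))
    entries, where (i, j, k) index the (11, 12, 22) elements in theta.
    ``var_floor`` bounds every variance (diagonal) away from zero.
    """

    def __init__(self, blocks, n_par, var_floor=1e-300):
        self.blocks = blocks
        self.n_par = n_par
        self._lf = np.log(var_floor)  # floor for log-variance entries
        self._hf = 0.5 * self._lf  # floor for log-Cholesky diagonal entries

    def to_phi(self, theta):
        phi = np.empty(self.n_par)
        for kind, idx in self.blocks:
            if kind == "log":
                phi[idx] = np.log(max(theta[idx], np.exp(self._lf)))
            else:
                i, j, k = idx
                a = np.exp(max(0.5 * np.log(max(theta[i], np.exp(self._lf))), self._hf))
                b = theta[j] / a
                c2 = max(theta[k] - b * b, np.exp(self._lf))
                phi[i] = np.log(a)
                phi[j] = b
                phi[k] = 0.5 * np.log(c2)
        return phi

    def to_theta(self, phi):
        theta = np.empty(self.n_par)
        for kind, idx in self.blocks:
            if kind == "log":
                theta[idx] = np.exp(max(phi[idx], self._lf))
            else:
                i, j, k = idx
                a = np.exp(max(phi[i], self._hf))
                b = phi[j]
                c = np.exp(max(phi[k], self._hf))
                theta[i] = a * a
                theta[j] = a * b
                theta[k] = b * b + c * c
        return theta

    def jacobian(self, phi):
        """J[t, p] = d theta_t / d phi_p."""
        J = np.zeros((self.n_par, self.n_par))
        for kind, idx in self.blocks:
            if kind == "log":
                J[idx, idx] = np.exp(max(phi[idx], self._lf))
            else:
                i, j, k = idx
                a = np.exp(max(phi[i], self._hf))
                b = phi[j]
                c = np.exp(max(phi[k], self._hf))
                J[i, i] = 2.0 * a * a
                J[j, i] = a * b
                J[j, j] = a
                J[k, j] = 2.0 * b
                J[k, k] = 2.0 * c * c
        return J


def _iterate_reml(evaluate, theta0, reparam, tol, max_iter, scale=None):
    """AI-REML driver with EM fallback, in the unconstrained parameterization.

    evaluate(theta) -> state with loglik/score/AI/em_vector (all in the
    original variance-parameter space); ``scale`` gives per-parameter
    magnitudes for the relative-change convergence test.
    """
    theta = np.array(theta0, dtype=float)
    if scale is None:
        scale = np.full_like(theta, max(np.abs(theta).max(), 1.0) * 1e-3)
    phi = reparam.to_phi(theta)
    theta = reparam.to_theta(phi)
    state = evaluate(theta)
    trace = [
        {"iter": 0, "step": "init", "loglik": state["loglik"], "theta": theta.copy()}
    ]
    converged = False
    flat_streak = 0
    for it in range(1, max_iter + 1):
        score, AI = state["score"], state["AI"]
        J = reparam.jacobian(phi)
        score_phi = J.T @ score
        AI_phi = J.T @ AI @ J
        step = "AI"
        theta_new = None
        # Levenberg-Marquardt damping: with a flat (boundary) direction the
        # transformed AI matrix is near singular and the raw Newton step
        # explodes; damping shortens it toward the gradient direction.
        damp = np.diag(np.abs(np.diag(AI_phi)) + 1e-12)
        for lam in (0.0, 1e-6, 1e-3, 1e-1, 1e1, 1e3):
            try:
                delta = np.linalg.solve(AI_phi + lam * damp, score_phi)
            except np.linalg.LinAlgError:
                continue
            if not np.all(np.isfinite(delta)):
                continue
            cand_phi = phi + delta
            cand = reparam.to_theta(cand_phi)
            try:
                cand_state = evaluate(cand)
            except np.linalg.LinAlgError:
                continue
            if cand_state["loglik"] >= state["loglik"] - 1e-8:
                theta_new, new_state = cand, cand_state
                phi_new = cand_phi
                break
        if theta_new is None:
            step = "EM"
            phi_new = reparam.to_phi(state["em_vector"])
            theta_new = reparam.to_theta(phi_new)
            new_state = evaluate(theta_new)
            # a true EM step is uphill; halve if a pseudo-EM covariance
            # update (paired residual) ever overshoots
            for _ in range(4):
                if new_state["loglik"] >= state["loglik"] - 1e-8:
                    break
                phi_new = phi + (phi_new - phi) / 2.0
                theta_new = reparam.to_theta(phi_new)
                new_state = evaluate(theta_new)

        dl = new_state["loglik"] - state["loglik"]
        rel = np.max(
            np.abs(theta_new - theta) / np.maximum(np.abs(theta), scale)
        )
        theta, phi, state = theta_new, phi_new, new_state
        trace.append(
            {
                "iter": it,
                "step": step,
                "loglik": state["loglik"],
                "theta": theta.copy(),
                "delta_loglik": float(dl),
                "max_rel_change": float(rel),
            }
        )
        logger.debug(
            "iter %d [%s] logL=%.6f dl=%.3g rel=%.3g", it, step, state["loglik"], dl, rel
        )
        flat_streak = flat_streak + 1 if abs(dl) < tol else 0
        # converged when the likelihood is flat and the components are
        # stable; on a degenerate ridge (singular covariance at the
        # optimum) the within-ridge coordinates never settle, so a
        # persistently flat likelihood suffices
        if abs(dl) < tol and (rel < 1e-5 or flat_streak >= 3):
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations", trace
        )
    return theta, state, trace


def reml_univariate(
    design: Design,
    A_inv,
    init=None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> FitResult:
    """Estimate (V_POLY, V_pe, V_e) by AI-REML with EM fallback."""
    mme = _UnivariateMME(design, A_inv)
    include_pe = mme.include_pe
    if include_pe:
        counts = np.bincount(design.rec_animal, minlength=design.ped.n)
        if (counts[mme.pe_positions] > 1).sum() == 0:
            warnings.warn(
                "no animal has repeated records: V_pe is weakly identified",
                stacklevel=2,
            )
    vp = float(np.var(design.y))
    vp = vp if vp > 0 else 1.0
    floor_val = max(1e-8 * vp, 1e-300)
    theta0_full = np.asarray(
        init if init is not None else _default_init_univariate(design.y, include_pe),
        dtype=float,
    )
    names = ["v_poly", "v_pe", "v_e"] if include_pe else ["v_poly", "v_e"]
    active = [0, 1, 2] if include_pe else [0, 2]
    theta0 = theta0_full[active]

    def expand(th):
        if include_pe:
            return th
        return np.array([th[0], 1.0, th[1]])  # placeholder v_pe, unused

    def evaluate(th):
        st = mme.evaluate(expand(th))
        st["em_vector"] = np.array([st["em"][nm] for nm in names])
        return st

    reparam = _Reparam(
        [("log", i) for i in range(len(names))], len(names), var_floor=floor_val
    )
    theta, state, trace = _iterate_reml(
        evaluate, theta0, reparam, tol, max_iter,
        scale=np.full(len(names), 1e-3 * vp),
    )

    ai_inv = _information_inverse(state["AI"])
    se_active = np.sqrt(np.clip(np.diag(ai_inv), 0, None))
    components = dict(zip(names, theta))
    se = dict(zip(names, se_active))
    if not include_pe:
        components["v_pe"] = 0.0
        se["v_pe"] = 0.0
    theta = expand(theta)

    C_inv, sol = state["C_inv"], state["sol"]
    fixed = pd.DataFrame(
        {
            "term": design.x_names,
            "estimate": sol[mme.sl_b],
            "se": np.sqrt(np.clip(np.diag(C_inv)[mme.sl_b], 0, None)),
        }
    )
    ebv = _ebv_table(design, theta[0], sol[mme.sl_a], np.diag(C_inv)[mme.sl_a])
    return FitResult(
        components=components,
        se=se,
        fixed_effects=fixed,
        ebv=ebv,
        loglik=state["loglik"],
        converged=True,
        n_iter=len(trace) - 1,
        trace=trace,
        ai_inverse=ai_inv,
        design=design,
    )


def _ebv_table(design, v_a, u_hat, pev):
    ped = design.ped
    diag_a = 1.0 + _inbreeding_cached(ped)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = 1.0 - pev / (diag_a * v_a)
    has_rec = np.zeros(ped.n, dtype=bool)
    has_rec[design.rec_animal] = True
    return pd.DataFrame(
        {
            "id": ped.ids,
            "ebv": u_hat,
            "reliability": np.clip(rel, 0.0, 1.0),
            "has_records": has_rec,
        }
    )


_F_CACHE = {}


def _inbreeding_cached(ped):
    key = id(ped)
    if key not in _F_CACHE:
        from .pedigree import inbreeding

        _F_CACHE[key] = inbreeding(ped)
    return _F_CACHE[key]


def reml_loglik_univariate(design: Design, A_inv, theta) -> float:
    """Restricted log-likelihood at fixed components (MME evaluation)."""
    return _UnivariateMME(design, A_inv).evaluate(theta, need_info=False)["loglik"]


# ---------------------------------------------------------------------------
# bivariate REML
# ---------------------------------------------------------------------------


@dataclass
class BivariateFit:
    """Converged bivariate fit; G0/PE0/R0 are 2x2 covariance matrices."""

    G0: np.ndarray
    PE0: np.ndarray
    R0: np.ndarray
    r_poly: float
    r_poly_se: float
    r_e: float
    r_e_se: float
    fixed_effects: pd.DataFrame
    ebv: pd.DataFrame
    loglik: float
    converged: bool
    n_iter: int
    trace: list = field(default_factory=list, repr=False)
    ai_inverse: np.ndarray | None = None
    param_names: list = field(default_factory=list)
    designs: tuple = field(default=(), repr=False)


class _BivariateMME:
    """Stacked two-trait MME with kron(G0, A) and kron(PE0, I) structure."""

    def __init__(self, d1: Design, d2: Design, A_inv, paired=False):
        if d1.ped is not d2.ped:
            raise ValueError("both designs must share one pedigree")
        self.d1, self.d2 = d1, d2
        ped = d1.ped
        self.q_a = ped.n
        self.n1, self.n2 = d1.n, d2.n
        self.n = self.n1 + self.n2
        self.paired = paired
        if paired:
            if self.n1 != self.n2 or not np.array_equal(
                d1.rec_animal, d2.rec_animal
            ):
                raise ValueError(
                    "paired residuals require identically ordered record sets"
                )
        rec_union = np.unique(np.concatenate([d1.rec_animal, d2.rec_animal]))
        self.pe_positions = rec_union
        self.q_w = len(rec_union)
        pe_index = {p: k for k, p in enumerate(rec_union)}

        p1, p2 = d1.n_fixed, d2.n_fixed
        self.p = p1 + p2
        X = sparse.block_diag(
            [sparse.csr_matrix(d1.X), sparse.csr_matrix(d2.X)], format="csr"
        )
        rows = np.arange(self.n)
        za_cols = np.concatenate(
            [d1.rec_animal, self.q_a + d2.rec_animal]
        )
        Z = sparse.csr_matrix(
            (np.ones(self.n), (rows, za_cols)), shape=(self.n, 2 * self.q_a)
        )
        w_cols = np.concatenate(
            [
                [pe_index[p] for p in d1.rec_animal],
                [self.q_w + pe_index[p] for p in d2.rec_animal],
            ]
        ).astype(int)
        W = sparse.csr_matrix(
            (np.ones(self.n), (rows, w_cols)), shape=(self.n, 2 * self.q_w)
        )
        self.M = sparse.hstack([X, Z, W], format="csr")
        self.y = np.concatenate([d1.y, d2.y])
        self.trait_of = np.concatenate(
            [np.zeros(self.n1, dtype=int), np.ones(self.n2, dtype=int)]
        )
        # per-trait cross-products: M' R^-1 M = sum_t MtM_t / v_e_t (unpaired)
        m1 = self.M[: self.n1]
        m2 = self.M[self.n1 :]
        self.MtM1 = (m1.T @ m1).toarray()
        self.MtM2 = (m2.T @ m2).toarray()
        self.MtM12 = (m1.T @ m2).toarray() if paired else None
        self.Mty1 = m1.T @ d1.y
        self.Mty2 = m2.T @ d2.y
        self.yty1 = float(d1.y @ d1.y)
        self.yty2 = float(d2.y @ d2.y)
        self.yty12 = float(d1.y @ d2.y) if paired else 0.0

        self.A_inv = A_inv.toarray() if sparse.issparse(A_inv) else np.asarray(A_inv)
        self.logdet_A = float(np.sum(np.log(mendelian_sampling_variances(ped))))
        self.sl_b = slice(0, self.p)
        self.sl_a = slice(self.p, self.p + 2 * self.q_a)
        self.sl_w = slice(self.p + 2 * self.q_a, self.p + 2 * self.q_a + 2 * self.q_w)
        self.m = self.p + 2 * self.q_a + 2 * self.q_w

        # parameter layout
        self.param_names = ["g11", "g12", "g22", "p11", "p12", "p22", "r1", "r2"]
        if paired:
            self.param_names.append("r12")

    # -- parameter vector <-> matrices ------------------------------------
    def unpack(self, theta):
        g11, g12, g22, p11, p12, p22, r1, r2 = theta[:8]
        r12 = theta[8] if self.paired else 0.0
        G0 = np.array([[g11, g12], [g12, g22]])
        PE0 = np.array([[p11, p12], [p12, p22]])
        R0 = np.array([[r1, r12], [r12, r2]])
        return G0, PE0, R0

    def evaluate(self, theta, need_info=True):
        G0, PE0, R0 = self.unpack(theta)
        for nm, Mx in (("G0", G0), ("PE0", PE0), ("R0", R0)):
            if np.linalg.eigvalsh(Mx).min() <= 0:
                raise np.linalg.LinAlgError(f"{nm} not positive definite")
        G0_inv = np.linalg.inv(G0)
        PE0_inv = np.linalg.inv(PE0)
        R0_inv = np.linalg.inv(R0)

        if self.paired:
            MtRM = (
                R0_inv[0, 0] * self.MtM1
                + R0_inv[1, 1] * self.MtM2
                + R0_inv[0, 1] * (self.MtM12 + self.MtM12.T)
            )
            rhs = (
                R0_inv[0, 0] * self.Mty1
                + R0_inv[1, 1] * self.Mty2
                + R0_inv[0, 1]
                * (
                    self.M[: self.n1].T @ self.d2.y
                    + self.M[self.n1 :].T @ self.d1.y
                )
            )
            yRy = (
                R0_inv[0, 0] * self.yty1
                + R0_inv[1, 1] * self.yty2
                + 2.0 * R0_inv[0, 1] * self.yty12
            )
            logdet_R = self.n1 * float(np.log(np.linalg.det(R0)))
        else:
            MtRM = self.MtM1 / R0[0, 0] + self.MtM2 / R0[1, 1]
            rhs = self.Mty1 / R0[0, 0] + self.Mty2 / R0[1, 1]
            yRy = self.yty1 / R0[0, 0] + self.yty2 / R0[1, 1]
            logdet_R = self.n1 * np.log(R0[0, 0]) + self.n2 * np.log(R0[1, 1])

        C = MtRM.copy()
        C[self.sl_a, self.sl_a] += np.kron(G0_inv, self.A_inv)
        idx_w = np.arange(self.sl_w.start, self.sl_w.stop)
        Wblock = np.kron(PE0_inv, np.eye(self.q_w))
        C[self.sl_w, self.sl_w] += Wblock
        chol, logdet_C, C_inv = _chol_logdet_inv(C)
        sol = cho_solve(chol, rhs, check_finite=False)
        yPy = yRy - rhs @ sol
        sign, logdet_G0 = np.linalg.slogdet(G0)
        _, logdet_PE0 = np.linalg.slogdet(PE0)
        loglik = -0.5 * (
            logdet_R
            + self.q_a * logdet_G0
            + 2.0 * self.logdet_A
            + self.q_w * logdet_PE0
            + logdet_C
            + yPy
            + (self.n - self.p) * LOG2PI
        )
        state = {
            "theta": np.asarray(theta, dtype=float),
            "loglik": float(loglik),
            "sol": sol,
            "C_inv": C_inv,
            "chol": chol,
        }
        if not need_info:
            return state

        # residual-space quantities
        e_hat = self.y - self.M @ sol
        Py = self._apply_Rinv(e_hat, R0_inv)
        U = sol[self.sl_a].reshape(2, self.q_a)  # rows: trait
        Upe = sol[self.sl_w].reshape(2, self.q_w)

        # block traces: TA[j,k] = tr(A^-1 C^aa_{jk}); TP[j,k] = tr(C^pe_{jk})
        C_aa = C_inv[self.sl_a, self.sl_a]
        C_pp = C_inv[self.sl_w, self.sl_w]
        TA = np.empty((2, 2))
        TP = np.empty((2, 2))
        UAU = np.empty((2, 2))
        UPU = np.empty((2, 2))
        AiU = (self.A_inv @ U.T).T
        for j in range(2):
            for k in range(2):
                blk = C_aa[
                    j * self.q_a : (j + 1) * self.q_a,
                    k * self.q_a : (k + 1) * self.q_a,
                ]
                TA[j, k] = float(np.sum(self.A_inv * blk))
                TP[j, k] = float(
                    np.trace(
                        C_pp[
                            j * self.q_w : (j + 1) * self.q_w,
                            k * self.q_w : (k + 1) * self.q_w,
                        ]
                    )
                )
                UAU[j, k] = float(U[j] @ AiU[k])
                UPU[j, k] = float(Upe[j] @ Upe[k])

        # score and AI over the parameter vector
        elem = {
            0: np.array([[1.0, 0.0], [0.0, 0.0]]),
            1: np.array([[0.0, 1.0], [1.0, 0.0]]),
            2: np.array([[0.0, 0.0], [0.0, 1.0]]),
        }
        score = []
        F_cols = []
        GU = G0_inv @ U  # 2 x q_a
        PU = PE0_inv @ Upe
        for i, B in elem.items():
            # d l / d G0_param
            S = G0_inv @ B @ G0_inv
            tr_term = self.q_a * np.sum(B * G0_inv) - np.sum(S * TA)
            quad = np.sum(S * UAU)
            score.append(-0.5 * (tr_term - quad))
            f = self.M[:, self.sl_a] @ (B @ GU).reshape(-1)
            F_cols.append(f)
        for i, B in elem.items():
            S = PE0_inv @ B @ PE0_inv
            tr_term = self.q_w * np.sum(B * PE0_inv) - np.sum(S * TP)
            quad = np.sum(S * UPU)
            score.append(-0.5 * (tr_term - quad))
            f = self.M[:, self.sl_w] @ (B @ PU).reshape(-1)
            F_cols.append(f)
        # residual parameters
        T_RM = self._apply_Rinv_matrix(self.M, R0_inv)  # R^-1 M (sparse-ish)
        res_elems = [np.array([[1.0, 0.0], [0.0, 0.0]]), np.array([[0.0, 0.0], [0.0, 1.0]])]
        if self.paired:
            res_elems.append(np.array([[0.0, 1.0], [1.0, 0.0]]))
        for B in res_elems:
            dV_Py = self._apply_block(Py, B)
            quad = float(Py @ dV_Py)
            # tr(R^-1 dV)
            if self.paired:
                tr_R = self.n1 * float(np.sum(R0_inv * B))
            else:
                tr_R = (self.n1 if B[0, 0] else self.n2) * float(np.sum(R0_inv * B))
            # N = (R^-1 M)' dV (R^-1 M); tr(C^-1 N)
            dV_TRM = self._apply_block_matrix(T_RM, B)
            N = (T_RM.T @ dV_TRM).toarray()
            tr_CN = float(np.sum(C_inv * N))
            score.append(-0.5 * ((tr_R - tr_CN) - quad))
            F_cols.append(self._apply_block(Py, B))

        F = np.column_stack(F_cols)
        rhs_F = T_RM.T @ F
        S_F = cho_solve(chol, rhs_F, check_finite=False)
        PF = self._apply_Rinv_dense(F - self.M @ S_F, R0_inv)
        AI = 0.5 * (F.T @ PF)

        # EM updates (matrix form for G0/PE0; residual via yPy-style scaling)
        G0_em = (UAU + TA) / self.q_a
        PE0_em = (UPU + TP) / self.q_w
        em_vec = [G0_em[0, 0], G0_em[0, 1], G0_em[1, 1], PE0_em[0, 0], PE0_em[0, 1], PE0_em[1, 1]]
        # residual EM: Harville-style one-parameter updates
        k = 6
        for B, nrec in zip(res_elems, [self.n1, self.n2, self.n1][: len(res_elems)]):
            i = len(em_vec)
            th = theta[i]
            g_i = score[i]
            em_vec.append(th + 2.0 * th**2 * g_i / max(nrec, 1))
        state.update(
            score=np.array(score),
            AI=AI,
            em_vector=np.array(em_vec),
            U=U,
            Upe=Upe,
            e_hat=e_hat,
        )
        return state

    # residual-structure helpers ------------------------------------------
    def _apply_Rinv(self, v, R0_inv):
        out = np.empty_like(v)
        if self.paired:
            v1, v2 = v[: self.n1], v[self.n1 :]
            out[: self.n1] = R0_inv[0, 0] * v1 + R0_inv[0, 1] * v2
            out[self.n1 :] = R0_inv[0, 1] * v1 + R0_inv[1, 1] * v2
        else:
            out[: self.n1] = v[: self.n1] * R0_inv[0, 0]
            out[self.n1 :] = v[self.n1 :] * R0_inv[1, 1]
        return out

    def _apply_Rinv_dense(self, V, R0_inv):
        out = np.empty_like(V)
        if self.paired:
            V1, V2 = V[: self.n1], V[self.n1 :]
            out[: self.n1] = R0_inv[0, 0] * V1 + R0_inv[0, 1] * V2
            out[self.n1 :] = R0_inv[0, 1] * V1 + R0_inv[1, 1] * V2
        else:
            out[: self.n1] = V[: self.n1] * R0_inv[0, 0]
            out[self.n1 :] = V[self.n1 :] * R0_inv[1, 1]
        return out

    def _apply_Rinv_matrix(self, M, R0_inv):
        if self.paired:
            # rows are [trait1 pairs; trait2 pairs]; mixes rows across traits
            top = sparse.hstack(
                [
                    sparse.identity(self.n1) * R0_inv[0, 0],
                    sparse.identity(self.n1) * R0_inv[0, 1],
                ]
            )
            bot = sparse.hstack(
                [
                    sparse.identity(self.n1) * R0_inv[0, 1],
                    sparse.identity(self.n1) * R0_inv[1, 1],
                ]
            )
            Rm = sparse.vstack([top, bot]).tocsr()
            return Rm @ M
        d = np.empty(self.n)
        d[: self.n1] = R0_inv[0, 0]
        d[self.n1 :] = R0_inv[1, 1]
        return sparse.diags(d) @ M

    def _apply_block(self, v, B):
        """Apply dV = (B (x) I_pairs) (paired) or diag-by-trait (unpaired)."""
        out = np.zeros_like(v)
        if self.paired:
            v1, v2 = v[: self.n1], v[self.n1 :]
            out[: self.n1] = B[0, 0] * v1 + B[0, 1] * v2
            out[self.n1 :] = B[1, 0] * v1 + B[1, 1] * v2
        else:
            if B[0, 0]:
                out[: self.n1] = v[: self.n1]
            if B[1, 1]:
                out[self.n1 :] = v[self.n1 :]
        return out

    def _apply_block_matrix(self, M, B):
        if not self.paired:
            d = np.zeros(self.n)
            if B[0, 0]:
                d[: self.n1] = 1.0
            if B[1, 1]:
                d[self.n1 :] = 1.0
            return sparse.diags(d) @ M
        top = sparse.hstack(
            [sparse.identity(self.n1) * B[0, 0], sparse.identity(self.n1) * B[0, 1]]
        )
        bot = sparse.hstack(
            [sparse.identity(self.n1) * B[1, 0], sparse.identity(self.n1) * B[1, 1]]
        )
        return (sparse.vstack([top, bot]).tocsr()) @ M


def reml_bivariate(
    design1: Design,
    design2: Design,
    A_inv,
    init=None,
    tol: float = 1e-6,
    max_iter: int = 200,
    paired: bool = False,
) -> BivariateFit:
    """Two-trait AI-REML: G0 (x) A polygenic, PE0 (x) I permanent-environment,
    trait-specific residuals (plus a residual covariance when ``paired``)."""
    mme = _BivariateMME(design1, design2, A_inv, paired=paired)
    v1, v2 = float(np.var(design1.y)), float(np.var(design2.y))
    v1, v2 = (v if v > 0 else 1.0 for v in (v1, v2))
    floor_val = 1e-8 * min(v1, v2)
    if init is None:
        theta0 = np.array(
            [0.3 * v1, 0.0, 0.3 * v2, 0.2 * v1, 0.0, 0.2 * v2, 0.5 * v1, 0.5 * v2]
            + ([0.0] if paired else [])
        )
    else:
        theta0 = np.asarray(init, dtype=float)
    n_par = len(mme.param_names)
    blocks = [("chol", (0, 1, 2)), ("chol", (3, 4, 5))]
    if paired:
        blocks.append(("chol", (6, 8, 7)))  # (r1, r12, r2) as a 2x2 matrix
    else:
        blocks += [("log", 6), ("log", 7)]
    reparam = _Reparam(blocks, n_par, var_floor=floor_val)
    v12 = np.sqrt(v1 * v2)
    scale_map = {
        "g11": v1, "g22": v2, "g12": v12,
        "p11": v1, "p22": v2, "p12": v12,
        "r1": v1, "r2": v2, "r12": v12,
    }
    scales = 1e-3 * np.array([scale_map[nm] for nm in mme.param_names])
    theta, state, trace = _iterate_reml(
        mme.evaluate, theta0, reparam, tol, max_iter, scale=scales
    )

    G0, PE0, R0 = mme.unpack(theta)
    for nm, Mx in (("G0", G0), ("PE0", PE0)):
        if np.linalg.eigvalsh(Mx).min() < -1e-8 * max(1.0, np.abs(Mx).max()):
            raise ConvergenceError(f"{nm} not PSD at the solution", trace)

    ai_inv = _information_inverse(state["AI"])
    r_poly, r_poly_se = _correlation_with_se(
        theta, ai_inv, mme.param_names, "g11", "g12", "g22"
    )
    if paired:
        r_e, r_e_se = _correlation_with_se(
            theta, ai_inv, mme.param_names, "r1", "r12", "r2"
        )
    else:
        r_e, r_e_se = 0.0, 0.0

    C_inv, sol = state["C_inv"], state["sol"]
    fixed = pd.DataFrame(
        {
            "trait": [design1.trait] * design1.n_fixed
            + [design2.trait] * design2.n_fixed,
            "term": design1.x_names + design2.x_names,
            "estimate": sol[mme.sl_b],
            "se": np.sqrt(np.clip(np.diag(C_inv)[mme.sl_b], 0, None)),
        }
    )
    U = state["U"]
    pev = np.diag(C_inv)[mme.sl_a].reshape(2, mme.q_a)
    ped = design1.ped
    diag_a = 1.0 + _inbreeding_cached(ped)
    ebv = pd.DataFrame({"id": ped.ids})
    for t, dsn in enumerate((design1, design2)):
        label = dsn.trait or f"trait{t + 1}"
        ebv[f"ebv_{label}"] = U[t]
        with np.errstate(invalid="ignore", divide="ignore"):
            ebv[f"rel_{label}"] = np.clip(
                1.0 - pev[t] / (diag_a * max(G0[t, t], floor_val)), 0.0, 1.0
            )
    has1 = np.zeros(ped.n, dtype=bool)
    has1[design1.rec_animal] = True
    has2 = np.zeros(ped.n, dtype=bool)
    has2[design2.rec_animal] = True
    ebv["has_records"] = has1 | has2

    return BivariateFit(
        G0=G0,
        PE0=PE0,
        R0=R0,
        r_poly=r_poly,
        r_poly_se=r_poly_se,
        r_e=r_e,
        r_e_se=r_e_se,
        fixed_effects=fixed,
        ebv=ebv,
        loglik=state["loglik"],
        converged=True,
        n_iter=len(trace) - 1,
        trace=trace,
        ai_inverse=ai_inv,
        param_names=list(mme.param_names),
        designs=(design1, design2),
    )


def _correlation_with_se(theta, cov, names, k11, k12, k22):
    idx = {nm: i for i, nm in enumerate(names)}
    a, c, b = theta[idx[k11]], theta[idx[k12]], theta[idx[k22]]
    r = c / np.sqrt(a * b)
    grad = np.zeros(len(names))
    grad[idx[k11]] = -0.5 * r / a
    grad[idx[k12]] = 1.0 / np.sqrt(a * b)
    grad[idx[k22]] = -0.5 * r / b
    var = float(grad @ cov @ grad)
    return float(r), float(np.sqrt(max(var, 0.0)))


def reml_loglik_bivariate(design1, design2, A_inv, theta, paired=False) -> float:
    return _BivariateMME(design1, design2, A_inv, paired=paired).evaluate(
        theta, need_info=False
    )["loglik"]


# ---------------------------------------------------------------------------
# EBV post-processing
# ---------------------------------------------------------------------------


def predict_ebv(fit) -> pd.DataFrame:
    """BLUP breeding-value table of a converged fit."""
    return fit.ebv.copy()


def standardize_ebv(ebvs, subset_mask=None) -> np.ndarray:
    """Standardize EBVs to mean 0, SD 1 (over recorded animals by default)."""
    x = np.asarray(ebvs, dtype=float)
    ref = x if subset_mask is None else x[np.asarray(subset_mask, dtype=bool)]
    sd = ref.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize constant EBVs (zero SD)")
    return (x - ref.mean()) / sd
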