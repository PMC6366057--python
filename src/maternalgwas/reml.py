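"""Restricted maximum likelihood for animal models and genomic models.

One engine covers every variance-component model in the pipeline:

* :func:`fit_reml` — average-information (AI) REML for an arbitrary set
  of random terms, each contributing a covariance matrix ``theta_j *
  B_j`` to the phenotypic covariance ``V``. Step-halving keeps the
  restricted log-likelihood non-decreasing; an EM-style fixed-point
  update takes over when an AI step cannot improve. Disconnected
  family blocks (common under half-sib structure with a pedigree
  relationship matrix) are detected and processed independently, which
  makes desk-scale maternal-model fits cheap.
* :func:`fit_single_kernel_reml` — the one-random-term special case
  (genomic REML) via eigendecomposition of the kernel, profiling out
  the total variance; O(n) per likelihood evaluation after the initial
  eigendecomposition. This is the engine behind GREML heritabilities
  and the association-scan null models.
* :func:`fit_bivariate_greml` — two traits sharing one genomic kernel,
  for genetic correlations between pre-corrected phenotypes.

Asymptotic standard errors come from the inverse average-information
(or numeric observed-information) matrix at convergence.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse
from scipy.sparse import csgraph

from .io_formats import FOUNDER, Pedigree, PhenotypeTable, ValidationError
from .kinship import RelationshipMatrix, build_A, build_chrom_G, build_loco
from .qc import _fixed_effect_design

logger = logging.getLogger(__name__)

VAR_FLOOR_FRACTION = 1e-6
LOGL_TOL = 1e-8
THETA_TOL = 1e-6


class ConvergenceError(RuntimeError):
    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory or []


@dataclasses.dataclass
class RandomTerm:
    """One random effect's contribution ``theta * B`` to ``V``.

    ``kind`` is "variance" (theta constrained non-negative) or
    "covariance" (theta free in sign, e.g. a direct-maternal genetic
    covariance).
    """

    name: str
    B: np.ndarray
    kind: str = "variance"


@dataclasses.dataclass
class VarianceComponents:
    """REML estimates with asymptotic standard errors."""

    estimates: dict
    se: dict
    loglik: float
    n_iter: int
    converged: bool
    trajectory: list
    param_cov: np.ndarray
    param_names: list

    @property
    def sigma_p(self) -> float:
        """Total phenotypic variance: sum of all components (a
        covariance component enters once)."""
        return float(sum(self.estimates.values()))

    def ratio(self, name: str):
        """(component / total, delta-method SE) for one component."""
        theta = np.array([self.estimates[k] for k in self.param_names])
        total = theta.sum()
        i = self.param_names.index(name)
        h = theta[i] / total
        grad = np.full(len(theta), -theta[i] / total ** 2)
        grad[i] += 1.0 / total
        var = float(grad @ self.param_cov @ grad)
        return float(h), float(np.sqrt(max(var, 0.0)))

    @property
    def h2_direct(self):
        key = "direct" if "direct" in self.estimates else "genomic"
        return self.ratio(key)[0] if key in self.estimates else None

    @property
    def h2_maternal(self):
        return self.ratio("maternal")[0] if "maternal" in self.estimates else None


# ---------------------------------------------------------------------------
# generic AI-REML over independent blocks
# ---------------------------------------------------------------------------

def _blocks_of(terms, n):
    pattern = np.zeros((n, n), dtype=bool)
    for t in terms:
        pattern |= np.abs(t.B) > 1e-12
    n_comp, labels = csgraph.connected_components(
        sparse.csr_matrix(pattern), directed=False)
    return [np.flatnonzero(labels == c) for c in range(n_comp)]


class _REMLWorkspace:
    """Blocked evaluation of the restricted likelihood and AI pieces."""

    def __init__(self, y, X, terms, blocks):
        self.y = y
        self.X = X
        self.terms = terms
        self.blocks = blocks
        self.Bb = [[t.B[np.ix_(b, b)] for t in terms] for b in blocks]
        self.Xb = [X[b] for b in blocks]
        self.yb = [y[b] for b in blocks]

    def loglik(self, theta):
        """Restricted logL (constants dropped); None if V not PD."""
        logdetV = 0.0
        p = self.X.shape[1]
        C = np.zeros((p, p))
        Xty = np.zeros(p)
        yty = 0.0
        for Bb, Xb, yb in zip(self.Bb, self.Xb, self.yb):
            V = sum(th * B for th, B in zip(theta, Bb))
            try:
                L = linalg.cho_factor(V, lower=True, check_finite=False)
            except linalg.LinAlgError:
                return None
            logdetV += 2.0 * np.sum(np.log(np.diag(L[0])))
            W = linalg.cho_solve(L, Xb, check_finite=False)
            v = linalg.cho_solve(L, yb, check_finite=False)
            C += Xb.T @ W
            Xty += Xb.T @ v
            yty += yb @ v
        sign, logdetC = np.linalg.slogdet(C)
        if sign <= 0:
            return None
        alpha = np.linalg.solve(C, Xty)
        yPy = yty - Xty @ alpha
        return -0.5 * (logdetV + logdetC + yPy)

    def derivatives(self, theta):
        """(logL, score, AI) at theta. Returns (None, None, None) if
        V is not positive definite."""
        k = len(self.terms)
        p = self.X.shape[1]
        logdetV = 0.0
        C = np.zeros((p, p))
        Xty = np.zeros(p)
        yty = 0.0
        cache = []
        for Bb, Xb, yb in zip(self.Bb, self.Xb, self.yb):
            V = sum(th * B for th, B in zip(theta, Bb))
            try:
                L = linalg.cho_factor(V, lower=True, check_finite=False)
            except linalg.LinAlgError:
                return None, None, None
            logdetV += 2.0 * np.sum(np.log(np.diag(L[0])))
            Vi, info = linalg.lapack.dpotri(L[0], lower=True)
            if info != 0:
                return None, None, None
            Vi = np.tril(Vi) + np.tril(Vi, -1).T
            W = Vi @ Xb
            v = Vi @ yb
            C += Xb.T @ W
            Xty += Xb.T @ v
            yty += yb @ v
            cache.append((Vi, W, v))
        sign, logdetC = np.linalg.slogdet(C)
        if sign <= 0:
            return None, None, None
        Cinv = np.linalg.inv(C)
        alpha = Cinv @ Xty
        yPy = yty - Xty @ alpha
        logL = -0.5 * (logdetV + logdetC + yPy)

        Py = [v - W @ alpha for (Vi, W, v) in cache]
        trPB = np.zeros(k)
        yPBPy = np.zeros(k)
        t_vecs = [[] for _ in range(k)]
        for bi, (Bb, (Vi, W, v)) in enumerate(zip(self.Bb, cache)):
            for j, B in enumerate(Bb):
                trPB[j] += np.sum(Vi * B) - np.sum(
                    (W.T @ B @ W) * Cinv)
                tj = B @ Py[bi]
                t_vecs[j].append(tj)
                yPBPy[j] += Py[bi] @ tj
        score = -0.5 * (trPB - yPBPy)

        # P t_k with the cross-block fixed-effect coupling
        Pt = []
        for jk in range(k):
            s_blocks = [cache[bi][0] @ t_vecs[jk][bi]
                        for bi in range(len(self.blocks))]
            g = np.zeros(p)
            for bi in range(len(self.blocks)):
                g += self.Xb[bi].T @ s_blocks[bi]
            Pt.append([s_blocks[bi] - cache[bi][1] @ (Cinv @ g)
                       for bi in range(len(self.blocks))])
        AI = np.zeros((k, k))
        for j in range(k):
            for l in range(j, k):
                val = 0.5 * sum(t_vecs[j][bi] @ Pt[l][bi]
                                for bi in range(len(self.blocks)))
                AI[j, l] = AI[l, j] = val
        return logL, score, (AI, trPB, yPBPy)


def fit_reml(y, X, terms, include_residual=True, weights=None,
             max_iter=200, theta0=None) -> VarianceComponents:
    """AI-REML with EM fallback for an arbitrary random-term set.

    ``terms`` is a list of :class:`RandomTerm`; a residual term with
    ``B = diag(1/weights)`` (identity when unweighted) is appended
    unless already present. Variances are constrained to at least
    ``1e-6 * var(y)``; convergence requires the change in restricted
    logL below 1e-8 and the maximum relative parameter change below
    1e-6.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.shape[0] != n:
        raise ValidationError("X rows must match y length")
    if n <= X.shape[1]:
        raise ValidationError("more fixed-effect columns than records")
    terms = list(terms)
    if include_residual:
        D = np.eye(n) if weights is None else np.diag(1.0 / np.asarray(weights))
        terms.append(RandomTerm("residual", D, "variance"))
    names = [t.name for t in terms]
    kinds = [t.kind for t in terms]
    var_y = float(np.var(y))
    floor = VAR_FLOOR_FRACTION * max(var_y, 1e-6)

    ws = _REMLWorkspace(y, X, terms, _blocks_of(terms, n))

    if theta0 is None:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        s2 = float(np.var(y - X @ beta))
        n_var = sum(1 for kd in kinds if kd == "variance")
        theta = np.array([s2 / n_var if kd == "variance" else 0.0
                          for kd in kinds])
    else:
        theta = np.asarray(theta0, dtype=float).copy()
    theta = _clamp(theta, kinds, floor)

    logL = ws.loglik(theta)
    if logL is None:
        raise ValidationError(
            "phenotypic covariance not positive definite at the starting "
            "values; check the covariance inputs for PSD")
    trajectory = [logL]

    for it in range(1, max_iter + 1):
        cur_logL, score, extras = ws.derivatives(theta)
        AI, trPB, yPBPy = extras
        # active set: parameters pinned at the floor with an outward
        # gradient stay fixed this iteration
        active = np.array([
            not (kinds[j] == "variance" and theta[j] <= floor * (1 + 1e-9)
                 and score[j] < 0)
            for j in range(len(theta))])
        step = np.zeros_like(theta)
        if active.any():
            step[active] = _solve_ai(AI[np.ix_(active, active)],
                                     score[active])
        accepted = False
        new_theta, new_logL = theta, cur_logL
        for _ in range(16):
            cand = _clamp(theta + step, kinds, floor)
            cand_logL = ws.loglik(cand)
            if cand_logL is not None and cand_logL >= cur_logL - 1e-12:
                new_theta, new_logL, accepted = cand, cand_logL, True
                break
            step = step / 2.0
        if not accepted:
            # EM-style fixed point for the variances
            cand = theta.copy()
            for j, kd in enumerate(kinds):
                if kd == "variance" and trPB[j] > 0 and theta[j] > floor:
                    cand[j] = theta[j] * yPBPy[j] / trPB[j]
            cand = _clamp(cand, kinds, floor)
            cand_logL = ws.loglik(cand)
            if cand_logL is not None and cand_logL > cur_logL:
                new_theta, new_logL, accepted = cand, cand_logL, True
        delta_logL = new_logL - cur_logL
        rel = np.max(np.abs(new_theta - theta)
                     / np.maximum(np.abs(theta), floor))
        theta = new_theta
        trajectory.append(new_logL)
        if (accepted and abs(delta_logL) < LOGL_TOL and rel < THETA_TOL) \
                or (not accepted and np.max(np.abs(score)) < 1e-6):
            break
        if not accepted:
            # neither AI nor EM can improve: treat as converged at a
            # (possibly boundary) maximum
            break
    else:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations", trajectory)

    _, _, extras = ws.derivatives(theta)
    AI = extras[0]
    param_cov = _safe_inverse(AI)
    se = np.sqrt(np.clip(np.diag(param_cov), 0.0, None))
    return VarianceComponents(
        estimates=dict(zip(names, map(float, theta))),
        se=dict(zip(names, map(float, se))),
        loglik=float(trajectory[-1]),
        n_iter=it,
        converged=True,
        trajectory=trajectory,
        param_cov=param_cov,
        param_names=names,
    )


def _clamp(theta, kinds, floor):
    out = theta.copy()
    for j, kd in enumerate(kinds):
        if kd == "variance":
            out[j] = max(out[j], floor)
    return out


def _solve_ai(AI, score):
    k = AI.shape[0]
    ridge = 1e-8 * max(np.trace(AI) / k, 1.0)
    for _ in range(8):
        try:
            return np.linalg.solve(AI + ridge * np.eye(k), score)
        except np.linalg.LinAlgError:
            ridge *= 10.0
    return score / max(np.abs(np.diag(AI)).max(), 1.0)


def _safe_inverse(M):
    try:
        return np.linalg.inv(M)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(M)


# ---------------------------------------------------------------------------
# single-kernel (genomic) REML via eigendecomposition
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SingleKernelFit:
    """Converged one-kernel REML fit with its rotation cached.

    The cached pieces (eigenvectors ``U``, eigenvalues ``lam``, the
    residual-weight square roots) are what a mixed-model association
    scan needs to test SNPs at the null variance ratio.
    """

    sigma_u2: float
    sigma_e2: float
    loglik: float
    U: np.ndarray
    lam: np.ndarray
    sqrt_w: np.ndarray
    X: np.ndarray
    y: np.ndarray
    param_cov: np.ndarray

    @property
    def h2(self) -> float:
        return self.sigma_u2 / (self.sigma_u2 + self.sigma_e2)

    @property
    def rotated_X(self) -> np.ndarray:
        return self.U.T @ (self.X * self.sqrt_w[:, None])

    @property
    def rotated_y(self) -> np.ndarray:
        return self.U.T @ (self.y * self.sqrt_w)

    @property
    def marginal_variances(self) -> np.ndarray:
        return self.sigma_u2 * self.lam + self.sigma_e2


def _restricted_logl_rotated(lam, ystar, Xstar, sigma_u2, sigma_e2):
    v = sigma_u2 * lam + sigma_e2
    if np.any(v <= 0):
        return -np.inf
    Xw = Xstar / v[:, None]
    C = Xstar.T @ Xw
    sign, logdetC = np.linalg.slogdet(C)
    if sign <= 0:
        return -np.inf
    alpha = np.linalg.solve(C, Xw.T @ ystar)
    yPy = np.sum(ystar ** 2 / v) - (Xw.T @ ystar) @ alpha
    return -0.5 * (np.sum(np.log(v)) + logdetC + yPy)


def fit_single_kernel_reml(y, X, K: np.ndarray,
                           weights=None) -> SingleKernelFit:
    """REML for ``y = Xb + u + e`` with ``u ~ (0, K sigma_u2)``.

    The heritability ratio is profiled on the eigenbasis of ``K`` (an
    initial grid refined by bounded scalar optimization), giving the
    global restricted-likelihood maximum without iteration-order
    concerns. Record weights enter the residual as ``diag(1/w)``.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if n <= X.shape[1]:
        raise ValidationError("more fixed-effect columns than records")
    sqrt_w = np.ones(n) if weights is None else np.sqrt(np.asarray(weights, float))
    Kw = K * sqrt_w[:, None] * sqrt_w[None, :]
    lam, U = linalg.eigh(Kw)
    lam = np.clip(lam, 0.0, None)
    ystar = U.T @ (y * sqrt_w)
    Xstar = U.T @ (X * sqrt_w[:, None])
    p = X.shape[1]
    dof = n - p

    def profiled(h2):
        w = h2 * lam + (1.0 - h2)
        Xw = Xstar / w[:, None]
        C = Xstar.T @ Xw
        sign, logdetC = np.linalg.slogdet(C)
        if sign <= 0:
            return np.inf
        alpha = np.linalg.solve(C, Xw.T @ ystar)
        yPy = np.sum(ystar ** 2 / w) - (Xw.T @ ystar) @ alpha
        if yPy <= 0:
            return np.inf
        sp = yPy / dof
        return 0.5 * (np.sum(np.log(w)) + logdetC + dof * np.log(sp) + dof)

    grid = np.linspace(1e-6, 1.0 - 1e-6, 41)
    vals = np.array([profiled(h) for h in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(profiled, bounds=(lo, hi),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    h2 = float(res.x)
    w = h2 * lam + (1.0 - h2)
    Xw = Xstar / w[:, None]
    C = Xstar.T @ Xw
    alpha = np.linalg.solve(C, Xw.T @ ystar)
    yPy = float(np.sum(ystar ** 2 / w) - (Xw.T @ ystar) @ alpha)
    sp = yPy / dof
    sigma_u2, sigma_e2 = h2 * sp, (1.0 - h2) * sp
    logL = _restricted_logl_rotated(lam, ystar, Xstar, sigma_u2, sigma_e2)

    # observed information by central differences on (sigma_u2, sigma_e2)
    theta = np.array([sigma_u2, sigma_e2])
    eps = np.maximum(1e-4 * np.abs(theta), 1e-8)
    H = np.zeros((2, 2))
    f0 = logL

    def f(t):
        return _restricted_logl_rotated(lam, ystar, Xstar, t[0], t[1])

    for a in range(2):
        for b in range(a, 2):
            ta = theta.copy(); tb = theta.copy(); tab = theta.copy()
            ta[a] += eps[a]
            tb[b] += eps[b]
            tab[a] += eps[a]; tab[b] += eps[b]
            H[a, b] = H[b, a] = (f(tab) - f(ta) - f(tb) + f0) / (eps[a] * eps[b])
    param_cov = _safe_inverse(-H)
    return SingleKernelFit(float(sigma_u2), float(sigma_e2), float(logL),
                           U, lam, sqrt_w, X, y, param_cov)


# ---------------------------------------------------------------------------
# model-level wrappers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ModelFit:
    """Everything a Model-1 fit must retain for BLUP and pre-correction."""

    vc: VarianceComponents
    y: np.ndarray
    X: np.ndarray
    records: pd.DataFrame           # trait records used (in fit order)
    animal_ids: list                # record -> animal id
    dam_ids: list                   # record -> dam id
    pedigree: Pedigree
    A: RelationshipMatrix           # over the full pedigree
    include_cov_um: bool
    trait: str


def fit_maternal_model(pheno: PhenotypeTable, ped: Pedigree, trait: str,
                       include_cov_um: bool = False):
    """Maternal animal model: fixed effects + direct u (animal, A) +
    maternal m (dam, A) + permanent environment (dam, I) + residual.

    Returns ``(VarianceComponents, ModelFit)``. The direct-maternal
    genetic covariance is off by default, matching the model with
    independent u and m.
    """
    df = pheno.for_trait(trait)
    if df.empty:
        raise ValidationError(f"no records for trait {trait}")
    ped_animals = set(ped.records["animal"])
    dam_of = dict(zip(ped.records["animal"], ped.records["dam"]))
    dams = []
    for a in df["animal"]:
        d = dam_of.get(a, FOUNDER)
        if d == FOUNDER or d not in ped_animals:
            raise ValidationError(
                f"phenotyped animal {a} has no known dam in the pedigree")
        dams.append(d)
    animals = df["animal"].tolist()

    A = build_A(ped)
    pos = {a: i for i, a in enumerate(A.ids)}
    needed = list(dict.fromkeys(animals + dams))
    sub = A.matrix[np.ix_([pos[a] for a in needed], [pos[a] for a in needed])]
    loc = {a: i for i, a in enumerate(needed)}
    ai = np.array([loc[a] for a in animals])
    di = np.array([loc[d] for d in dams])

    B_u = sub[np.ix_(ai, ai)]
    B_m = sub[np.ix_(di, di)]
    dam_codes = pd.factorize(pd.Series(dams))[0]
    B_pe = (dam_codes[:, None] == dam_codes[None, :]).astype(float)
    terms = [RandomTerm("direct", B_u),
             RandomTerm("maternal", B_m),
             RandomTerm("maternal_pe", B_pe)]
    if include_cov_um:
        cross = sub[np.ix_(ai, di)]
        terms.insert(2, RandomTerm("cov_direct_maternal",
                                   cross + cross.T, "covariance"))
    counts = np.bincount(dam_codes)
    if counts.max() == 1:
        warnings.warn(
            "every dam has a single offspring: maternal permanent "
            "environment and maternal genetic variance are weakly "
            "identified")
    X = _fixed_effect_design(df)
    y = df["weight_kg"].to_numpy(float)
    vc = fit_reml(y, X, terms)
    fit = ModelFit(vc, y, X, df, animals, dams, ped, A, include_cov_um, trait)
    return vc, fit


def _greml_inputs(pheno_or_series, G: RelationshipMatrix, trait):
    """Align phenotype values with the kernel's individuals."""
    if isinstance(pheno_or_series, PhenotypeTable):
        df = pheno_or_series.for_trait(trait)
        df = df[df["animal"].isin(G.ids)]
        ids = df["animal"].tolist()
        y = df["weight_kg"].to_numpy(float)
        X = _fixed_effect_design(df)
    else:
        s = pd.Series(pheno_or_series).dropna()
        ids = [a for a in G.ids if a in s.index]
        y = s.reindex(ids).to_numpy(float)
        X = np.ones((len(ids), 1))
    if len(ids) < 3:
        raise ValidationError("too few genotyped phenotyped animals")
    K = G.subset(ids).matrix
    return y, X, K, ids


def fit_greml(pheno_or_precorrected, G: RelationshipMatrix,
              trait: str | None = None) -> VarianceComponents:
    """Genomic REML with a single genomic random term.

    Accepts either a :class:`PhenotypeTable` (full fixed-effect set for
    ``trait``) or a pre-corrected value series keyed by animal
    (intercept-only). Heritability is ``sigma_u2 / (sigma_u2 +
    sigma_e2)`` and available as ``result.ratio("genomic")``.
    """
    y, X, K, _ = _greml_inputs(pheno_or_precorrected, G, trait)
    skf = fit_single_kernel_reml(y, X, K)
    se = np.sqrt(np.clip(np.diag(skf.param_cov), 0.0, None))
    return VarianceComponents(
        estimates={"genomic": skf.sigma_u2, "residual": skf.sigma_e2},
        se={"genomic": float(se[0]), "residual": float(se[1])},
        loglik=skf.loglik, n_iter=1, converged=True,
        trajectory=[skf.loglik], param_cov=skf.param_cov,
        param_names=["genomic", "residual"])


def fit_bivariate_greml(y1, y2, G: RelationshipMatrix):
    """Bivariate genomic REML on the common genotyped set.

    ``y1`` / ``y2`` are series keyed by animal (intercept-only fixed
    effects, as pre-corrected phenotypes require). Returns
    ``(genetic_correlation, se)``; the correlation is clamped to
    [-1, 1] with a warning if a boundary fit pushes it outside.
    """
    s1, s2 = pd.Series(y1).dropna(), pd.Series(y2).dropna()
    ids = [a for a in G.ids if a in s1.index and a in s2.index]
    if len(ids) < 4:
        raise ValidationError("too few animals shared between traits")
    K = G.subset(ids).matrix
    lam, U = linalg.eigh(K)
    lam = np.clip(lam, 0.0, None)
    Y = np.column_stack([s1.reindex(ids).to_numpy(float),
                         s2.reindex(ids).to_numpy(float)])
    Ystar = U.T @ Y
    ones_star = U.T @ np.ones(len(ids))

    def unpack(x):
        Lg = np.array([[np.exp(x[0]), 0.0], [x[1], np.exp(x[2])]])
        Le = np.array([[np.exp(x[3]), 0.0], [x[4], np.exp(x[5])]])
        return Lg @ Lg.T, Le @ Le.T

    def neg_logl_mats(Eg, Ee):
        a = lam * Eg[0, 0] + Ee[0, 0]
        b = lam * Eg[0, 1] + Ee[0, 1]
        c = lam * Eg[1, 1] + Ee[1, 1]
        det = a * c - b * b
        if np.any(det <= 0) or np.any(a <= 0):
            return np.inf
        y1s, y2s = Ystar[:, 0], Ystar[:, 1]
        # inverse of each 2x2 block applied to y* and to the intercepts
        iy1 = (c * y1s - b * y2s) / det
        iy2 = (-b * y1s + a * y2s) / det
        ix11 = c * ones_star / det
        ix21 = -b * ones_star / det
        ix12 = -b * ones_star / det
        ix22 = a * ones_star / det
        C = np.array([
            [np.sum(ones_star * ix11), np.sum(ones_star * ix12)],
            [np.sum(ones_star * ix21), np.sum(ones_star * ix22)]])
        r = np.array([np.sum(ones_star * iy1), np.sum(ones_star * iy2)])
        sign, logdetC = np.linalg.slogdet(C)
        if sign <= 0:
            return np.inf
        q = float(np.sum(y1s * iy1) + np.sum(y2s * iy2))
        yPy = q - r @ np.linalg.solve(C, r)
        return 0.5 * (np.sum(np.log(det)) + logdetC + yPy)

    def neg_logl(x):
        Eg, Ee = unpack(x)
        return neg_logl_mats(Eg, Ee)

    # start from the empirical covariance split half genetic, half
    # residual; keeps the optimizer in the basin matching the data's
    # sign of the cross-covariance
    C_emp = np.cov(Y.T) / 2.0 + 1e-6 * np.diag(np.diag(np.cov(Y.T)) + 1e-12)
    L0 = np.linalg.cholesky(C_emp)
    half = np.array([np.log(L0[0, 0]), L0[1, 0], np.log(L0[1, 1])])
    x0 = np.concatenate([half, half])
    res = optimize.minimize(neg_logl, x0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-8,
                                     "fatol": 1e-10})
    Eg, Ee = unpack(res.x)
    denom = np.sqrt(Eg[0, 0] * Eg[1, 1])
    rg = Eg[0, 1] / denom if denom > 0 else 0.0
    if not -1.0 <= rg <= 1.0:
        warnings.warn("genetic correlation outside [-1, 1]; clamped")
        rg = float(np.clip(rg, -1.0, 1.0))

    # delta-method SE via numeric Hessian in the unconstrained space
    H = _numeric_hessian(neg_logl, res.x)
    cov_x = _safe_inverse(H)
    grad = _numeric_gradient(lambda x: _rg_of(unpack(x)[0]), res.x)
    var_rg = float(grad @ cov_x @ grad)
    return float(rg), float(np.sqrt(max(var_rg, 0.0)))


def _rg_of(Eg):
    d = np.sqrt(max(Eg[0, 0] * Eg[1, 1], 1e-300))
    return Eg[0, 1] / d


def _numeric_gradient(f, x, eps=1e-5):
    g = np.zeros_like(x)
    for i in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g


def _numeric_hessian(f, x, eps=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for a in range(k):
        for b in range(a, k):
            xa, xb, xab = x.copy(), x.copy(), x.copy()
            xa[a] += eps
            xb[b] += eps
            xab[a] += eps; xab[b] += eps
            H[a, b] = H[b, a] = (f(xab) - f(xa) - f(xb) + f0) / eps ** 2
    return H


def precorrect_phenotypes(model_fit: ModelFit) -> pd.Series:
    """Phenotypes stripped of fixed effects: u + m + pe + e per record.

    Equals ``y - X b_hat`` with the GLS fixed-effect solutions at the
    REML estimates, so adjusted value + fixed-effect prediction
    reconstructs the raw phenotype exactly.
    """
    beta = gls_fixed_effects(model_fit)
    adjusted = model_fit.y - model_fit.X @ beta
    return pd.Series(adjusted, index=model_fit.animal_ids)


def gls_fixed_effects(model_fit: ModelFit) -> np.ndarray:
    """Fixed-effect solutions at the converged variance components."""
    V = _model_V(model_fit)
    L = linalg.cho_factor(V, lower=True)
    W = linalg.cho_solve(L, model_fit.X)
    v = linalg.cho_solve(L, model_fit.y)
    return np.linalg.solve(model_fit.X.T @ W, model_fit.X.T @ v)


def _model_V(model_fit: ModelFit) -> np.ndarray:
    """Rebuild the record covariance matrix at the REML estimates."""
    vc = model_fit.vc
    A = model_fit.A
    pos = {a: i for i, a in enumerate(A.ids)}
    ai = np.array([pos[a] for a in model_fit.animal_ids])
    di = np.array([pos[d] for d in model_fit.dam_ids])
    n = len(ai)
    V = vc.estimates["direct"] * A.matrix[np.ix_(ai, ai)]
    V += vc.estimates["maternal"] * A.matrix[np.ix_(di, di)]
    if "cov_direct_maternal" in vc.estimates:
        cross = A.matrix[np.ix_(ai, di)]
        V += vc.estimates["cov_direct_maternal"] * (cross + cross.T)
    codes = pd.factorize(pd.Series(model_fit.dam_ids))[0]
    V += vc.estimates["maternal_pe"] * (
        codes[:, None] == codes[None, :]).astype(float)
    V += vc.estimates["residual"] * np.eye(n)
    return V


# ---------------------------------------------------------------------------
# chromosome-wise partition of genomic variance
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ChromPartition:
    """Per-chromosome genomic variances from joint two-kernel fits."""

    table: pd.DataFrame
    total_genomic_variance: float
    sum_ratio: float                # sum_i var_i / total genomic variance
    r2_snp_count: float
    r2_length: float


def fit_chromosome_partition(pheno_or_series, geno, trait=None,
                             allele_freqs=None) -> ChromPartition:
    """For each chromosome, fit G_chrom + G_rest jointly and partition
    the genomic variance.

    Reports per-chromosome variance, heritability ``var_i / (var_i +
    var_rest + var_e)``, the proportion of the summed chromosome
    variances, the ratio of the summed chromosome variances to the
    full-set genomic variance, and the R^2 of SNP count (and bp length)
    against chromosome variance.
    """
    from .kinship import build_G

    chroms = sorted(geno.snp_map["chrom"].unique())
    if len(chroms) < 2:
        raise ValidationError("need at least 2 chromosomes to partition")
    if allele_freqs is None:
        allele_freqs = geno.allele_frequencies()

    G_full = build_G(geno, allele_freqs=allele_freqs)
    y, X, K_full, ids = _greml_inputs(pheno_or_series, G_full, trait)
    total_fit = fit_single_kernel_reml(y, X, K_full)

    rows = []
    for c in chroms:
        Gc = build_chrom_G(geno, c, allele_freqs=allele_freqs).subset(ids)
        Gl = build_loco(geno, c, allele_freqs=allele_freqs).subset(ids)
        vc = fit_reml(y, X, [RandomTerm("chrom", Gc.matrix),
                             RandomTerm("rest", Gl.matrix)])
        var_c = vc.estimates["chrom"]
        var_rest = vc.estimates["rest"]
        var_e = vc.estimates["residual"]
        sub = geno.snp_map[geno.snp_map["chrom"] == c]
        rows.append({
            "chrom": c,
            "var_chrom": var_c,
            "se_var_chrom": vc.se["chrom"],
            "var_rest": var_rest,
            "var_residual": var_e,
            "h2_chrom": var_c / (var_c + var_rest + var_e),
            "n_snps": len(sub),
            "length_bp": int(sub["pos"].max() - sub["pos"].min() + 1),
        })
    table = pd.DataFrame(rows)
    total_var = table["var_chrom"].sum()
    table["proportion_of_genomic"] = table["var_chrom"] / total_var
    sum_ratio = total_var / total_fit.sigma_u2 if total_fit.sigma_u2 > 0 \
        else np.nan

    def _r2(x, v):
        if np.std(x) == 0 or np.std(v) == 0:
            return 0.0
        return float(np.corrcoef(x, v)[0, 1] ** 2)

    return ChromPartition(
        table=table,
        total_genomic_variance=float(total_fit.sigma_u2),
        sum_ratio=float(sum_ratio),
        r2_snp_count=_r2(table["n_snps"], table["var_chrom"]),
        r2_length=_r2(table["length_bp"], table["var_chrom"]),
    )
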