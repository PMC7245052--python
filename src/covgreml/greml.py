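"""Restricted maximum likelihood for GRM-based variance components.

Model
-----
For traits t = 1..T (T = 1 or 2) measured on the same n individuals (here,
trait 1 is the offspring phenotype and trait 2 the maternal phenotype of a
mother-offspring dyad, with the GRM computed from offspring genotypes):

    y = X beta + g + e,   g ~ N(0, Sigma_g x A),   e ~ N(0, Sigma_e x I)

where ``x`` is the Kronecker product over (trait, individual), A is the
genetic relatedness matrix and Sigma_g, Sigma_e are the T x T genetic and
residual (co)variance component matrices.  The restricted log-likelihood is

    l(theta) = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ] - (N - p)/2 log 2 pi

with V = Sigma_g x A + Sigma_e x I, P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1,
N = nT and p = rank(X).  The full 2 pi constant is included so values are
directly comparable with a dense-matrix evaluation.

Fitting is unconstrained (components may go negative, mirroring GCTA's
``reml-no-constrain``): one EM-flavoured first step from a phenotypic-
covariance-based start, then average-information (AI) updates with
step-halving, falling back to the EM update for any iteration in which the
AI step fails.  All per-iteration algebra runs in the eigenbasis of A, where
V is block-diagonal with T x T blocks, so each iteration is O(n) after a
single O(n^3) eigendecomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grm import GRMatrix
from .phenotypes import DesignPair

LOG2PI = float(np.log(2.0 * np.pi))

#: Relative conditioning floor for V's eigenbasis blocks.  Unconstrained
#: fits can press against the boundary of the positive-definite cone, where
#: float64 evaluation of the likelihood becomes unreliable (a block that is
#: analytically indefinite can pass a Cholesky through rounding and return
#: an inflated log-likelihood).  Points whose worst block eigenvalue falls
#: below COND_FLOOR times the best are treated as infeasible, which keeps
#: the maximization well-posed for the AI updates and for any direct
#: optimizer run on the same surface.
COND_FLOOR = 1e-8


class SingularVError(ValueError):
    """V(theta) is singular / not positive definite at the requested theta."""

    def __init__(self, theta):
        self.theta = np.asarray(theta, dtype=float)
        super().__init__(f"V(theta) is not positive definite at theta = {self.theta}")


def _as_grm_values(grm) -> np.ndarray:
    if isinstance(grm, GRMatrix):
        return grm.values
    return np.asarray(grm, dtype=float)


def _theta_to_matrices(theta: np.ndarray, n_traits: int) -> tuple[np.ndarray, np.ndarray]:
    theta = np.asarray(theta, dtype=float)
    if n_traits == 1:
        sg = np.array([[theta[0]]])
        se = np.array([[theta[1]]])
    else:
        sg = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
        se = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
    return sg, se


def _matrices_to_theta(sg: np.ndarray, se: np.ndarray) -> np.ndarray:
    if sg.shape == (1, 1):
        return np.array([sg[0, 0], se[0, 0]])
    return np.array([sg[0, 0], sg[0, 1], sg[1, 1], se[0, 0], se[0, 1], se[1, 1]])


def _elementary(n_traits: int) -> list[np.ndarray]:
    if n_traits == 1:
        return [np.array([[1.0]])]
    return [
        np.array([[1.0, 0.0], [0.0, 0.0]]),
        np.array([[0.0, 1.0], [1.0, 0.0]]),
        np.array([[0.0, 0.0], [0.0, 1.0]]),
    ]


def _blocks_well_conditioned(M: np.ndarray) -> bool:
    """Feasibility of the (n, T, T) eigenbasis blocks of V: every block
    eigenvalue must be positive and no smaller than COND_FLOOR times the
    largest block eigenvalue."""
    if M.shape[1] == 1:
        eigs = M[:, 0, 0]
        emin, emax = eigs.min(), eigs.max()
    else:
        tr = M[:, 0, 0] + M[:, 1, 1]
        det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
        disc = np.sqrt(np.maximum(tr**2 - 4 * det, 0.0))
        emin = ((tr - disc) / 2.0).min()
        emax = ((tr + disc) / 2.0).max()
    return bool(emin > 0 and emin > COND_FLOOR * emax)


def restricted_loglik(theta, y_stacked, X_blockdiag, grm) -> float:
    """Dense-matrix restricted log-likelihood.

    Forms V = Sigma_g x A + Sigma_e x I explicitly (trait-major stacking)
    and evaluates the REML criterion with generic determinant/solve
    routines.  Intended for small n; the model classes use an equivalent
    O(n)-per-evaluation eigenbasis path.
    """
    A = _as_grm_values(grm)
    n = A.shape[0]
    y = np.asarray(y_stacked, dtype=float).ravel()
    X = np.asarray(X_blockdiag, dtype=float)
    n_traits = y.size // n
    if y.size != n * n_traits or n_traits not in (1, 2):
        raise ValueError("y_stacked length must be n or 2n")
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient")
    sg, se = _theta_to_matrices(theta, n_traits)
    d = np.linalg.eigvalsh((A + A.T) / 2.0)
    M = d[:, None, None] * sg + se
    if not _blocks_well_conditioned(M):
        raise SingularVError(theta)
    V = np.kron(sg, A) + np.kron(se, np.eye(n))
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        raise SingularVError(theta) from None
    logdet_v = 2.0 * np.log(np.diag(L)).sum()
    Vinv_y = np.linalg.solve(V, y)
    Vinv_X = np.linalg.solve(V, X)
    C = X.T @ Vinv_X
    sign, logdet_c = np.linalg.slogdet(C)
    if sign <= 0:
        raise SingularVError(theta)
    beta = np.linalg.solve(C, X.T @ Vinv_y)
    ypy = y @ Vinv_y - (X.T @ Vinv_y) @ beta
    n_total = n * n_traits
    return float(-0.5 * (logdet_v + logdet_c + ypy) - 0.5 * (n_total - p) * LOG2PI)


@dataclass
class _EigenWorkspace:
    """Quantities fixed across iterations: A's eigenbasis and rotated data."""

    d: np.ndarray  # (n,) eigenvalues of A
    Y: np.ndarray  # (n, T) rotated traits
    Xb: np.ndarray  # (n, T, p) rotated block design
    n_traits: int
    p: int

    @classmethod
    def build(cls, ys: list[np.ndarray], Xs: list[np.ndarray], A: np.ndarray):
        n = A.shape[0]
        T = len(ys)
        d, U = np.linalg.eigh((A + A.T) / 2.0)
        Y = np.column_stack([U.T @ np.asarray(y, dtype=float) for y in ys])
        ps = [X.shape[1] for X in Xs]
        p = sum(ps)
        Xb = np.zeros((n, T, p))
        off = 0
        for t, X in enumerate(Xs):
            Xb[:, t, off : off + ps[t]] = U.T @ np.asarray(X, dtype=float)
            off += ps[t]
        return cls(d=d, Y=Y, Xb=Xb, n_traits=T, p=p)


@dataclass
class _Evaluation:
    """Per-theta quantities reused by loglik, score, AI and EM updates."""

    loglik: float
    Minv: np.ndarray  # (n, T, T)
    MinvX: np.ndarray  # (n, T, p)
    C: np.ndarray  # (p, p) = X'V^-1 X
    Py: np.ndarray  # (n, T) residual projection of y


def _evaluate(ws: _EigenWorkspace, sg: np.ndarray, se: np.ndarray) -> _Evaluation | None:
    n = ws.d.shape[0]
    M = ws.d[:, None, None] * sg + se
    if not _blocks_well_conditioned(M):
        return None
    try:
        L = np.linalg.cholesky(M)
        logdet_v = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError:
        return None
    MinvY = np.einsum("nts,ns->nt", Minv, ws.Y)
    MinvX = np.einsum("nts,nsp->ntp", Minv, ws.Xb)
    C = np.einsum("ntp,ntq->pq", ws.Xb, MinvX)
    sign, logdet_c = np.linalg.slogdet(C)
    if sign <= 0:
        return None
    XtVy = np.einsum("ntp,nt->p", ws.Xb, MinvY)
    beta = np.linalg.solve(C, XtVy)
    ypy = np.einsum("nt,nt->", ws.Y, MinvY) - XtVy @ beta
    resid = ws.Y - np.einsum("ntp,p->nt", ws.Xb, beta)
    Py = np.einsum("nts,ns->nt", Minv, resid)
    n_total = n * ws.n_traits
    ll = -0.5 * (logdet_v + logdet_c + ypy) - 0.5 * (n_total - ws.p) * LOG2PI
    return _Evaluation(loglik=float(ll), Minv=Minv, MinvX=MinvX, C=C, Py=Py)


def _score_and_ai(
    ws: _EigenWorkspace, ev: _Evaluation
) -> tuple[np.ndarray, np.ndarray]:
    """REML score vector and average-information matrix at the current theta.

    score_j = -1/2 [ tr(P Vdot_j) - y' P Vdot_j P y ]
    AI_jk  = 1/2 y' P Vdot_j P Vdot_k P y
    """
    d = ws.d
    ones = np.ones_like(d)
    elems = _elementary(ws.n_traits)
    weights = [(E, d) for E in elems] + [(E, ones) for E in elems]
    q = len(weights)
    Cinv = np.linalg.inv(ev.C)

    score = np.empty(q)
    us = []
    for j, (E, c) in enumerate(weights):
        tr_vinv_vdot = np.einsum("n,nts,st->", c, ev.Minv, E)
        Tj = np.einsum("n,ntp,ts,nsq->pq", c, ev.MinvX, E, ev.MinvX)
        tr_p_vdot = tr_vinv_vdot - np.trace(Cinv @ Tj)
        u = c[:, None] * (ev.Py @ E)
        ypvpy = np.einsum("nt,nt->", u, ev.Py)
        score[j] = -0.5 * (tr_p_vdot - ypvpy)
        us.append(u)

    # P u for each direction, then AI by symmetric dot products
    pus = []
    for u in us:
        Minvu = np.einsum("nts,ns->nt", ev.Minv, u)
        Xtu = np.einsum("ntp,nt->p", ws.Xb, Minvu)
        pu = Minvu - np.einsum("ntp,p->nt", ev.MinvX, np.linalg.solve(ev.C, Xtu))
        pus.append(pu)
    AI = np.empty((q, q))
    for j in range(q):
        for k in range(j, q):
            AI[j, k] = AI[k, j] = 0.5 * np.einsum("nt,nt->", us[j], pus[k])
    return score, AI


def _em_update(
    ws: _EigenWorkspace, ev: _Evaluation, sg: np.ndarray, se: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Classical EM-REML update of both component matrices.

    Sigma_new = Sigma + (1/n) Sigma [ Q - T ] Sigma, with Q the quadratic
    form of Py against the random effect's covariance kernel and T the
    matching trace of P blocks; guaranteed not to decrease the likelihood.
    """
    n = ws.d.shape[0]
    d = ws.d
    Cinv = np.linalg.inv(ev.C)
    out = []
    for (sigma, c) in ((sg, d), (se, np.ones_like(d))):
        Q = np.einsum("n,nt,ns->ts", c, ev.Py, ev.Py)
        Tm = np.einsum("n,nts->ts", c, ev.Minv) - np.einsum(
            "n,ntp,pq,nsq->ts", c, ev.MinvX, Cinv, ev.MinvX
        )
        new = sigma + (sigma @ (Q - Tm) @ sigma) / n
        out.append((new + new.T) / 2.0)
    return out[0], out[1]


@dataclass
class GREMLOptions:
    """Optimizer settings for AI-REML."""

    max_iter: int = 100
    tol_loglik: float = 1e-4
    tol_theta: float = 1e-4
    max_halvings: int = 10
    #: Newton-decrement threshold for the end-of-run stationarity check; a
    #: larger predicted likelihood gain triggers the derivative-free polish.
    stationarity_tol: float = 1e-3
    polish: bool = True


@dataclass
class GREMLResults:
    """Variance-component estimates from a (bivariate) GREML fit.

    ``params`` is ordered (sigma_g1, sigma_g12, sigma_g2, sigma_e1,
    sigma_e12, sigma_e2) for two traits and (sigma_g, sigma_e) for one.
    ``sampling_cov`` is the inverse average-information matrix at the
    optimum; ``bse`` are its diagonal square roots.
    """

    params: np.ndarray
    param_names: list[str]
    loglik: float
    n_iter: int
    converged: bool
    sampling_cov: np.ndarray = field(repr=False)
    n_obs: int = 0
    n_traits: int = 1
    em_fallbacks: int = 0

    def __post_init__(self) -> None:
        lookup = dict(zip(self.param_names, self.params))
        for name, value in lookup.items():
            setattr(self, name, float(value))

    @property
    def llf(self) -> float:
        return self.loglik

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.abs(np.diag(self.sampling_cov)))

    def cov_params(self) -> np.ndarray:
        return self.sampling_cov

    def summary(self) -> str:
        lines = [
            "GREML variance components (unconstrained AI-REML)",
            f"  n = {self.n_obs}, traits = {self.n_traits}, "
            f"logL = {self.loglik:.4f}, iterations = {self.n_iter}, "
            f"converged = {self.converged}",
            f"  {'component':<10} {'estimate':>10} {'SE':>10}",
        ]
        for name, est, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"  {name:<10} {est:>10.4f} {se:>10.4f}")
        if self.n_traits == 2:
            rg, rg_ok = genetic_correlation(self)
            rg_txt = f"{rg:.4f}" if rg_ok else "undefined"
            lines.append(f"  genetic correlation r_G = {rg_txt}")
            for t in (1, 2):
                h2, h2_ok = snp_heritability(self, t)
                h2_txt = f"{h2:.4f}" if h2_ok else "undefined"
                lines.append(f"  SNP h2 (trait {t}) = {h2_txt}")
        return "\n".join(lines)


class _GREMLBase:
    """Shared AI-REML machinery; subclasses define traits and designs."""

    def __init__(self, ys: list[np.ndarray], Xs: list[np.ndarray], grm) -> None:
        A = _as_grm_values(grm)
        n = A.shape[0]
        self.n = n
        self.n_traits = len(ys)
        for y, X in zip(ys, Xs):
            if len(y) != n or X.shape[0] != n:
                raise ValueError("y / X / GRM dimensions do not match")
            if np.isnan(np.asarray(y, dtype=float)).any():
                raise ValueError("phenotypes must be complete cases (no NaN)")
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError("fixed-effect design is rank deficient")
        min_n = sum(X.shape[1] for X in Xs) + 3 * self.n_traits
        if n < min_n:
            raise ValueError(f"need at least {min_n} individuals")
        self._ys = [np.asarray(y, dtype=float) for y in ys]
        self._Xs = [np.asarray(X, dtype=float) for X in Xs]
        self._A = A
        self._ws = _EigenWorkspace.build(self._ys, self._Xs, A)

    # -- public likelihood surface -------------------------------------
    def loglike(self, theta) -> float:
        """Restricted log-likelihood via the eigenbasis path (matches the
        dense :func:`restricted_loglik` within numerical tolerance)."""
        sg, se = _theta_to_matrices(theta, self.n_traits)
        ev = _evaluate(self._ws, sg, se)
        if ev is None:
            raise SingularVError(theta)
        return ev.loglik

    def _param_names(self) -> list[str]:
        if self.n_traits == 1:
            return ["sigma_g", "sigma_e"]
        return ["sigma_g1", "sigma_g12", "sigma_g2", "sigma_e1", "sigma_e12", "sigma_e2"]

    def _start(self) -> tuple[np.ndarray, np.ndarray]:
        S = np.cov(np.column_stack(self._ys), rowvar=False, ddof=1)
        S = np.atleast_2d(S)
        return S / 2.0, S / 2.0

    def fit(
        self,
        options: GREMLOptions | None = None,
        start: np.ndarray | None = None,
    ) -> GREMLResults:
        opts = options or GREMLOptions()
        if start is not None:
            sg, se = _theta_to_matrices(np.asarray(start, dtype=float), self.n_traits)
        else:
            sg, se = self._start()
        ev = _evaluate(self._ws, sg, se)
        if ev is None:
            # degenerate start (e.g. zero-variance trait); nudge to identity scale
            sg = np.eye(self.n_traits) * 0.5
            se = np.eye(self.n_traits) * 0.5
            ev = _evaluate(self._ws, sg, se)
            if ev is None:
                raise SingularVError(_matrices_to_theta(sg, se))

        em_fallbacks = 0
        converged = False
        n_iter = 0
        first_step = start is None  # EM-flavoured opening step from the default start
        AI = np.eye(2 if self.n_traits == 1 else 6)
        for n_iter in range(1, opts.max_iter + 1):
            theta_old = _matrices_to_theta(sg, se)
            ll_old = ev.loglik
            used_em = False
            if first_step:
                sg_new, se_new = _em_update(self._ws, ev, sg, se)
                ev_new = _evaluate(self._ws, sg_new, se_new)
                if ev_new is None:  # pathological EM step; keep current point
                    sg_new, se_new, ev_new = sg, se, ev
                used_em = True
                first_step = False
            else:
                score, AI = _score_and_ai(self._ws, ev)
                ev_new = None
                try:
                    delta = np.linalg.solve(AI, score)
                    if not np.isfinite(delta).all():
                        raise np.linalg.LinAlgError
                except np.linalg.LinAlgError:
                    delta = None
                if delta is not None:
                    step = 1.0
                    for _ in range(opts.max_halvings + 1):
                        cand = theta_old + step * delta
                        sg_c, se_c = _theta_to_matrices(cand, self.n_traits)
                        ev_c = _evaluate(self._ws, sg_c, se_c)
                        if ev_c is not None and ev_c.loglik >= ll_old - 1e-10:
                            sg_new, se_new, ev_new = sg_c, se_c, ev_c
                            break
                        step /= 2.0
                if ev_new is None:  # AI step failed -> EM for this iteration
                    sg_new, se_new = _em_update(self._ws, ev, sg, se)
                    ev_c = _evaluate(self._ws, sg_new, se_new)
                    if ev_c is None:
                        sg_new, se_new, ev_new = sg, se, ev
                    else:
                        ev_new = ev_c
                    used_em = True
                    em_fallbacks += 1

            theta_new = _matrices_to_theta(sg_new, se_new)
            d_ll = ev_new.loglik - ll_old
            d_theta = np.max(np.abs(theta_new - theta_old) / (np.abs(theta_old) + 1.0))
            sg, se, ev = sg_new, se_new, ev_new
            del used_em  # convergence judged on the move, not the step type
            if n_iter > 1 and abs(d_ll) < opts.tol_loglik and d_theta < opts.tol_theta:
                converged = True
                break

        # Stationarity check: at small n the unconstrained optimum can sit
        # near the boundary of the positive-definite cone, where AI steps
        # stall; if the Newton decrement predicts a material likelihood
        # gain, polish with a derivative-free search on the same surface.
        score, AI = _score_and_ai(self._ws, ev)
        if opts.polish and _newton_decrement(score, AI) > opts.stationarity_tol:
            polished = self._polish(_matrices_to_theta(sg, se), ev.loglik)
            if polished is not None:
                sg, se = _theta_to_matrices(polished, self.n_traits)
                ev = _evaluate(self._ws, sg, se)
                score, AI = _score_and_ai(self._ws, ev)
                converged = _newton_decrement(score, AI) <= opts.stationarity_tol

        try:
            sampling_cov = np.linalg.inv(AI)
            sampling_cov = (sampling_cov + sampling_cov.T) / 2.0
        except np.linalg.LinAlgError:
            sampling_cov = np.full_like(AI, np.nan)
        return GREMLResults(
            params=_matrices_to_theta(sg, se),
            param_names=self._param_names(),
            loglik=ev.loglik,
            n_iter=n_iter,
            converged=converged,
            sampling_cov=sampling_cov,
            n_obs=self.n,
            n_traits=self.n_traits,
            em_fallbacks=em_fallbacks,
        )


    def _polish(self, theta_current: np.ndarray, ll_current: float):
        """Derivative-free refinement for fits that stall short of a
        stationary point (Nelder-Mead on the eigenbasis likelihood, from
        the current iterate, the default start and seeded dispersed
        starts).  Returns the best theta found, or None if nothing beat
        the current point."""
        from scipy.optimize import minimize

        def neg_ll(theta):
            sg, se = _theta_to_matrices(theta, self.n_traits)
            ev = _evaluate(self._ws, sg, se)
            return 1e12 if ev is None else -ev.loglik

        sg0, se0 = self._start()
        starts = [theta_current, _matrices_to_theta(sg0, se0)]
        rng = np.random.default_rng(0)
        scale = np.abs(_matrices_to_theta(sg0, se0)) + 0.1
        starts += [scale * rng.uniform(0.3, 2.0, scale.size) for _ in range(5)]
        best_theta, best_ll = None, ll_current
        for x0 in starts:
            res = minimize(
                neg_ll, x0, method="Nelder-Mead",
                options={"maxfev": 4000, "xatol": 1e-8, "fatol": 1e-10},
            )
            if -res.fun > best_ll + 1e-10:
                best_ll, best_theta = -res.fun, res.x
        # restart from the incumbent until the surface stops yielding:
        # Nelder-Mead simplexes collapse prematurely near the PD boundary
        for _ in range(5):
            if best_theta is None:
                break
            res = minimize(
                neg_ll, best_theta, method="Nelder-Mead",
                options={"maxfev": 4000, "xatol": 1e-9, "fatol": 1e-11},
            )
            if -res.fun > best_ll + 1e-6:
                best_ll, best_theta = -res.fun, res.x
            else:
                break
        return best_theta


def _newton_decrement(score: np.ndarray, AI: np.ndarray) -> float:
    """Predicted likelihood gain 1/2 s' AI^+ s, with AI projected to the
    PSD cone (AI is PSD analytically; numerical breakdown near the
    boundary can make it indefinite)."""
    if not np.isfinite(score).all() or not np.isfinite(AI).all():
        return np.inf
    w, Q = np.linalg.eigh((AI + AI.T) / 2.0)
    floor = max(np.abs(w).max(), 1.0) * 1e-10
    w = np.maximum(w, floor)
    z = Q.T @ score
    return float(0.5 * np.sum(z**2 / w))


class UnivariateGREML(_GREMLBase):
    """Single-trait GREML model: y = X beta + g + e with g ~ N(0, sigma_g A)."""

    def __init__(self, y, grm, X=None) -> None:
        y = np.asarray(y, dtype=float)
        if X is None:
            X = np.ones((len(y), 1))
        super().__init__([y], [np.asarray(X, dtype=float)], grm)


class BivariateGREML(_GREMLBase):
    """Bivariate GREML model partitioning the trait covariance.

    Trait 1 is conventionally the offspring phenotype and trait 2 the
    maternal phenotype; the GRM comes from offspring genotypes, so
    ``sigma_g12`` is the covariance between the traits that is tagged by
    offspring SNPs.
    """

    def __init__(self, y1, y2, grm, X1=None, X2=None) -> None:
        y1 = np.asarray(y1, dtype=float)
        y2 = np.asarray(y2, dtype=float)
        if X1 is None:
            X1 = np.ones((len(y1), 1))
        if X2 is None:
            X2 = np.ones((len(y2), 1))
        super().__init__([y1, y2], [np.asarray(X1, float), np.asarray(X2, float)], grm)

    @classmethod
    def from_design_pair(cls, y1, y2, design: DesignPair, grm) -> "BivariateGREML":
        return cls(y1, y2, grm, X1=design.X1, X2=design.X2)


def fit_bivariate_greml(
    y1, y2, design: DesignPair | None, grm, options: GREMLOptions | None = None,
    start=None,
) -> GREMLResults:
    """Convenience wrapper: build a :class:`BivariateGREML` and fit it."""
    if design is None:
        model = BivariateGREML(y1, y2, grm)
    else:
        model = BivariateGREML.from_design_pair(y1, y2, design, grm)
    return model.fit(options=options, start=start)


def fit_univariate_greml(y, X, grm, options: GREMLOptions | None = None) -> GREMLResults:
    return UnivariateGREML(y, grm, X=X).fit(options=options)


def genetic_correlation(vc: GREMLResults) -> tuple[float, bool]:
    """r_G = sigma_g12 / sqrt(sigma_g1 * sigma_g2).

    Returns ``(value, defined)``; under an unconstrained fit a variance
    component may be negative, making the square root undefined, in which
    case ``defined`` is False and the value is NaN.  Values outside [-1, 1]
    are returned as-is.
    """
    if vc.n_traits != 2:
        raise ValueError("genetic correlation requires a bivariate fit")
    prod = vc.sigma_g1 * vc.sigma_g2
    if prod <= 0:
        return float("nan"), False
    return float(vc.sigma_g12 / np.sqrt(prod)), True


def snp_heritability(vc: GREMLResults, trait: int = 1) -> tuple[float, bool]:
    """h2 = sigma_g / (sigma_g + sigma_e) for the requested trait (1-based).

    Returns ``(value, defined)``: undefined when the total variance is zero;
    values outside [0, 1] are returned unclamped with ``defined`` True.
    """
    if vc.n_traits == 1:
        sg, se = vc.sigma_g, vc.sigma_e
    elif trait == 1:
        sg, se = vc.sigma_g1, vc.sigma_e1
    elif trait == 2:
        sg, se = vc.sigma_g2, vc.sigma_e2
    else:
        raise ValueError("trait must be 1 or 2")
    total = sg + se
    if total == 0:
        return float("nan"), False
    return float(sg / total), True


__all__ = [
    "restricted_loglik",
    "SingularVError",
    "GREMLOptions",
    "GREMLResults",
    "UnivariateGREML",
    "BivariateGREML",
    "fit_bivariate_greml",
    "fit_univariate_greml",
    "genetic_correlation",
    "snp_heritability",
]
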