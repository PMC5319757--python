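"""Pattern search guided by simplex derivatives (SID-PSM).

A derivative-free, bound-constrained direct search of directional type.  Each
iteration runs an optional *search step* — minimize a quadratic model of the
objective (interpolation, minimum-Frobenius-norm, or regression, depending on
how many cached evaluations are available) over a ball around the current
iterate — and, when the search step fails, a *poll step* that evaluates
x_k + alpha_k d for directions d in a positive generating set, ordered by the
angle they make with the negative simplex gradient (the descent indicator).
Every objective evaluation is cached and recycled for model building, which
is what makes the method cheap in function evaluations.

All internal arithmetic happens in the unit box (affine scaling of the
bounds) so that decision variables of very different magnitudes — pulse width
in tens of microseconds next to currents of a few milliamperes — share a
common step-size geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "OptProblem",
    "QuadModel",
    "SimplexGradient",
    "check_poisedness",
    "simplex_gradient",
    "build_quadratic_model",
    "minimize_model_in_ball",
    "sidpsm_minimize",
]


@dataclass
class OptProblem:
    """Bound-constrained minimization problem min F(x), lower <= x <= upper."""

    objective: callable
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape or np.any(self.lower >= self.upper):
            raise ValueError("bounds must satisfy lower < upper componentwise")

    @property
    def d(self) -> int:
        return self.lower.size


@dataclass
class QuadModel:
    """Quadratic model m(y) = c + g.y + y.H.y/2 around the current iterate."""

    c: float
    g: np.ndarray
    H: np.ndarray
    kind: str
    sample_count: int

    def __call__(self, y: np.ndarray) -> float:
        return float(self.c + self.g @ y + 0.5 * y @ self.H @ y)

    def gradient(self, y: np.ndarray) -> np.ndarray:
        return self.g + self.H @ y


@dataclass
class SimplexGradient:
    """Simplex gradient with the geometry (poisedness) of its sample set."""

    gradient: np.ndarray
    S: np.ndarray
    Lambda: float
    poised: bool


def check_poisedness(S_scaled: np.ndarray, Lambda: float) -> bool:
    """True iff the scaled displacement matrix is Lambda-poised.

    Lambda-poisedness requires ||Sigma^{-1}|| <= Lambda, where Sigma holds the
    singular values of the scaled matrix; a rank-deficient set (zero singular
    value) is never poised.
    """
    S_scaled = np.atleast_2d(np.asarray(S_scaled, dtype=float))
    sv = np.linalg.svd(S_scaled, compute_uv=False)
    n_expected = min(S_scaled.shape)
    if sv.size < n_expected or sv[-1] <= 0:
        return False
    return bool(1.0 / sv[-1] <= Lambda)


def simplex_gradient(
    points: np.ndarray, values: np.ndarray, Delta: float, Lambda: float = 100.0
) -> SimplexGradient:
    """Simplex gradient of F at points[0] from the sample set.

    Solves S^T g = delta(F) exactly in the determined case (r = d); under- and
    overdetermined sets use the pseudo-inverse form built from the singular
    value decomposition of the scaled matrix S^T / Delta.
    """
    if Delta <= 0:
        raise ValueError("scaling radius Delta must be positive")
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if points.shape[0] < 2:
        raise ValueError("need at least one displacement")
    S = (points[1:] - points[0]).T  # d x r
    delta = values[1:] - values[0]
    d, r = S.shape
    A = S.T / Delta  # r x d
    poised = check_poisedness(A, Lambda)
    if r == d and poised:
        try:
            g = np.linalg.solve(S.T, delta)
            return SimplexGradient(gradient=g, S=S, Lambda=Lambda, poised=True)
        except np.linalg.LinAlgError:  # pragma: no cover - caught by poisedness
            pass
    U, sv, Vt = np.linalg.svd(A, full_matrices=False)
    inv = np.zeros_like(sv)
    good = sv > 1e-14 * max(sv[0], 1.0)
    inv[good] = 1.0 / sv[good]
    g = Vt.T @ (inv * (U.T @ (delta / Delta)))
    return SimplexGradient(gradient=g, S=S, Lambda=Lambda, poised=poised)


def _quad_basis(Y: np.ndarray) -> np.ndarray:
    """Rows of the scaled quadratic monomial basis [y_i^2/2, y_i y_j/sqrt(2)]."""
    n, d = Y.shape
    cols = [0.5 * Y[:, i] ** 2 for i in range(d)]
    for i in range(d):
        for j in range(i + 1, d):
            cols.append(Y[:, i] * Y[:, j] / np.sqrt(2.0))
    return np.column_stack(cols)


def _coeff_to_hessian(alpha_q: np.ndarray, d: int) -> np.ndarray:
    H = np.zeros((d, d))
    H[np.diag_indices(d)] = alpha_q[:d]
    idx = d
    for i in range(d):
        for j in range(i + 1, d):
            H[i, j] = H[j, i] = alpha_q[idx] / np.sqrt(2.0)
            idx += 1
    return H


def build_quadratic_model(
    points: np.ndarray, values: np.ndarray, d: int | None = None
) -> QuadModel | None:
    """Quadratic model from cached evaluations centered at points[0].

    With p_k = len(points) - 1 displacements and q = (d+1)(d+2)/2 - 1:

    - p_k < d + 1: no model (returns None; the caller skips the search step);
    - d + 1 <= p_k < q: minimum-Frobenius-norm model (minimize ||H||_F^2
      subject to the interpolation conditions, via the standard KKT system);
    - p_k = q: determined interpolation;
    - p_k > q: least-squares regression.

    A numerically singular system returns None with a warning.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if d is None:
        d = points.shape[1]
    p_k = points.shape[0] - 1
    if p_k < d + 1:
        return None
    q = (d + 1) * (d + 2) // 2 - 1
    Y = points - points[0]
    L = np.column_stack([np.ones(p_k + 1), Y])  # linear basis [1, y]
    Q = _quad_basis(Y)
    n_quad = Q.shape[1]
    try:
        if d + 1 <= p_k < q:
            # MFN: minimize ||alpha_q||^2 (== ||H||_F^2 in the scaled basis)
            # subject to Q alpha_q + L alpha_l = F
            n_pts = p_k + 1
            kkt = np.block([
                [Q @ Q.T, L],
                [L.T, np.zeros((d + 1, d + 1))],
            ])
            rhs = np.concatenate([values, np.zeros(d + 1)])
            sol = np.linalg.solve(kkt, rhs)
            mu, alpha_l = sol[:n_pts], sol[n_pts:]
            alpha_q = Q.T @ mu
            kind = "mfn"
        elif p_k == q:
            M = np.column_stack([L, Q])
            sol = np.linalg.solve(M, values)
            alpha_l, alpha_q = sol[: d + 1], sol[d + 1:]
            kind = "determined"
        else:
            M = np.column_stack([L, Q])
            sol, *_ = np.linalg.lstsq(M, values, rcond=None)
            alpha_l, alpha_q = sol[: d + 1], sol[d + 1:]
            kind = "regression"
    except np.linalg.LinAlgError:
        warnings.warn("singular interpolation system; skipping model", RuntimeWarning)
        return None
    if not np.all(np.isfinite(alpha_l)) or not np.all(np.isfinite(alpha_q)):
        warnings.warn("non-finite model coefficients; skipping model", RuntimeWarning)
        return None
    H = _coeff_to_hessian(alpha_q, d)
    return QuadModel(
        c=float(alpha_l[0]), g=alpha_l[1:].copy(), H=H, kind=kind,
        sample_count=p_k,
    )


def _trust_region_step(g: np.ndarray, H: np.ndarray, radius: float) -> np.ndarray:
    """Exact minimizer of g.y + y.H.y/2 over ||y|| <= radius (More-Sorensen).

    The dimension is small (d <= 4), so an eigendecomposition plus a 1-D
    root-find on the Lagrange multiplier is cheap and robust, including the
    hard case.
    """
    evals, evecs = np.linalg.eigh(0.5 * (H + H.T))
    gt = evecs.T @ g
    lam_min = evals[0]

    def step_norm(lam):
        denom = evals + lam
        return np.linalg.norm(gt / denom)

    # interior Newton step if H is PD and the step fits the ball
    if lam_min > 0 and step_norm(0.0) <= radius:
        return evecs @ (-gt / evals)
    lo = max(0.0, -lam_min) + 1e-14
    # hard case: gradient orthogonal to the lowest eigenvector
    if abs(gt[0]) < 1e-14 * max(np.linalg.norm(gt), 1.0) and step_norm(lo) < radius:
        denom = evals + lo
        denom[np.abs(denom) < 1e-14] = np.inf
        y = -gt / denom
        residual = np.sqrt(max(radius**2 - np.dot(y, y), 0.0))
        y[0] += residual * np.sign(y[0]) if y[0] != 0 else residual
        return evecs @ y
    hi = lo + 1.0
    while step_norm(hi) > radius:
        hi = 2.0 * hi
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if step_norm(mid) > radius:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12 * max(1.0, hi):
            break
    denom = evals + hi
    return evecs @ (-gt / denom)


def minimize_model_in_ball(
    model: QuadModel,
    center: np.ndarray,
    radius: float,
    lower: np.ndarray,
    upper: np.ndarray,
) -> np.ndarray:
    """Minimizer of the model over ball(center, radius), clipped to the box.

    The ball-constrained subproblem is solved exactly (trust-region step);
    the Cauchy point is kept as a fallback candidate and the better model
    value wins after clipping to the bounds.
    """
    d = center.size
    g0 = model.gradient(np.zeros(d))
    candidates = [center + _trust_region_step(g0, model.H, radius)]
    gnorm = np.linalg.norm(g0)
    if gnorm > 0:
        candidates.append(center - radius * g0 / gnorm)
    best, best_val = center, np.inf
    for cand in candidates:
        y = cand - center
        norm = np.linalg.norm(y)
        if norm > radius and norm > 0:
            cand = center + y * (radius / norm)
        cand = np.clip(cand, lower, upper)
        val = model(cand - center)
        if val < best_val:
            best, best_val = cand, val
    return best


def _select_model_points(
    cache_pts: np.ndarray,
    cache_vals: np.ndarray,
    x_k: np.ndarray,
    cap: int,
    locality: float | None = None,
):
    """80% nearest / 20% farthest sample selection around the iterate.

    With ``locality`` set, points farther than that radius are ignored as
    long as at least cap points remain closer (keeps the model local once
    the search has zoomed in); the 20% "far" points are the farthest of the
    retained set.
    """
    dists = np.linalg.norm(cache_pts - x_k, axis=1)
    order = np.argsort(dists)
    if locality is not None and cache_pts.shape[0] > cap:
        within = order[dists[order] <= locality]
        if within.size >= cap:
            order = within
    if order.size <= cap:
        sel = order
    else:
        n_near = int(np.ceil(0.8 * cap))
        n_far = cap - n_near
        sel = np.concatenate([order[:n_near], order[::-1][:n_far]])
    # current iterate first (it is the nearest point to itself)
    return cache_pts[sel], cache_vals[sel]


def sidpsm_minimize(
    problem: OptProblem,
    x0: np.ndarray,
    options: dict | None = None,
) -> dict:
    """Run SID-PSM on a bound-constrained problem from a feasible start.

    Options (defaults in parentheses): ``budget`` max objective evaluations
    (2000), ``alpha0`` initial step in unit-box units (0.25), ``tol_alpha``
    stop threshold on the scaled step (1e-6), ``Lambda`` poisedness constant
    (100), ``use_search`` enable the quadratic-model search step (True),
    ``order_poll`` enable descent-indicator poll ordering (True).  Disabling
    both reduces the method to a plain generalized pattern search.

    Returns a dict with ``x_best``, ``F_best``, ``n_evals`` and the iteration
    ``history`` (list of per-iteration records).
    """
    opts = dict(options or {})
    budget = int(opts.get("budget", 2000))
    alpha0 = float(opts.get("alpha0", 0.25))
    tol_alpha = float(opts.get("tol_alpha", 1e-6))
    Lambda = float(opts.get("Lambda", 100.0))
    use_search = bool(opts.get("use_search", True))
    order_poll = bool(opts.get("order_poll", True))

    lower, upper = problem.lower, problem.upper
    span = upper - lower
    d = problem.d
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < lower) or np.any(x0 > upper):
        raise ValueError("x0 must satisfy the bounds")

    # unit-box scaling
    def to_unit(x):
        return (x - lower) / span

    def from_unit(u):
        return lower + u * span

    cache_pts: list[np.ndarray] = []
    cache_vals: list[float] = []
    n_evals = 0

    def evaluate(u: np.ndarray) -> float:
        nonlocal n_evals
        for p, v in zip(cache_pts, cache_vals):
            if np.max(np.abs(p - u)) < 1e-12:
                return v
        try:
            val = float(problem.objective(from_unit(u)))
            if not np.isfinite(val):
                val = np.inf
        except Exception:
            val = np.inf
        n_evals += 1
        cache_pts.append(u.copy())
        cache_vals.append(val)
        return val

    directions = np.vstack([np.eye(d), -np.eye(d)])  # +-e_i, positive generating
    max_dir_norm = 1.0
    cap = (d + 1) * (d + 2) - 1

    u_k = to_unit(x0)
    f_k = evaluate(u_k)
    alpha = alpha0
    prev_alpha = alpha0
    prev_success = False
    history = []

    while alpha >= tol_alpha and n_evals < budget:
        record = {"alpha": alpha, "x": from_unit(u_k), "F": f_k, "n_evals": n_evals}
        success = False
        pts = np.asarray(cache_pts)
        vals = np.asarray(cache_vals)

        # ---- search step -------------------------------------------------
        if use_search and pts.shape[0] >= d + 2:
            sigma_k = 2.0 if prev_success else 1.0
            radius = sigma_k * prev_alpha * max_dir_norm
            mpts, mvals = _select_model_points(
                pts, vals, u_k, cap, locality=max(8.0 * radius, 0.05)
            )
            model = build_quadratic_model(mpts, mvals, d)
            if model is not None:
                cand = minimize_model_in_ball(
                    model, u_k, radius, np.zeros(d), np.ones(d)
                )
                f_cand = evaluate(cand)
                if f_cand < f_k:
                    # expansion trial: extrapolate along the accepted step
                    ext = np.clip(u_k + 2.0 * (cand - u_k), 0.0, 1.0)
                    if np.max(np.abs(ext - cand)) > 1e-12:
                        f_ext = evaluate(ext)
                        if f_ext < f_cand:
                            cand, f_cand = ext, f_ext
                    u_k, f_k = cand, f_cand
                    success = True
                    record["step"] = "search"

        # ---- poll step ---------------------------------------------------
        if not success:
            order = np.arange(directions.shape[0])
            if order_poll and pts.shape[0] >= 2:
                radius = alpha * max_dir_norm
                spts, svals = _select_model_points(pts, vals, u_k, d + 1)
                try:
                    sg = simplex_gradient(spts, svals, max(radius, 1e-12), Lambda)
                    if sg.poised and np.linalg.norm(sg.gradient) > 0:
                        desc = -sg.gradient / np.linalg.norm(sg.gradient)
                        cosines = directions @ desc
                        order = np.argsort(-cosines)
                except (ValueError, np.linalg.LinAlgError):
                    pass
            any_feasible = False
            for idx in order:
                cand = u_k + alpha * directions[idx]
                if np.any(cand < 0.0) or np.any(cand > 1.0):
                    continue  # infeasible poll points are discarded
                any_feasible = True
                f_cand = evaluate(cand)
                if f_cand < f_k:
                    u_k, f_k = cand, f_cand
                    success = True
                    record["step"] = "poll"
                    break
                if n_evals >= budget:
                    break
            if not any_feasible:
                record["all_infeasible"] = True

        # ---- step-size update -------------------------------------------
        prev_alpha = alpha
        prev_success = success
        if success:
            alpha = min(2.0 * alpha, alpha0)
        else:
            alpha = 0.5 * alpha
            record["step"] = record.get("step", "fail")
        record["success"] = success
        history.append(record)

    # best cached feasible point
    vals = np.asarray(cache_vals)
    pts = np.asarray(cache_pts)
    best = int(np.argmin(vals))
    return {
        "x_best": from_unit(pts[best]),
        "F_best": float(vals[best]),
        "n_evals": n_evals,
        "history": history,
    }
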