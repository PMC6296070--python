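"""Pseudo-arclength continuation of equilibrium branches.

Traces the fixed-point curve of the model against a free parameter
(lumen butyrate ``k_Bo`` or lumen LPS ``k_bl``) by a predictor-corrector
scheme parametrized by arclength, which passes around folds where the
branch turns back in the parameter.  Folds (saddle-node / limit points)
are detected by a sign change of the parameter component of the branch
tangent, refined by Newton on a bordered extended system, and equipped
with the quadratic coefficient of the one-dimensional fold normal form

    a = 1/2 <p, B2(q, q)>,

where q and p are the right and left null vectors of the Jacobian at
the fold (normalized <q,q> = 1, <p,q> = 1) and B2 the bilinear second
derivative of the vector field.  a < 0 at both folds of an S-shaped
hysteresis whose outer layers are stable.

Sign convention: the sign of a flips with q -> -q, so q is oriented to
have a positive component in the last state variable (butyrate for the
gut model).  Magnitudes are invariant under the convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equilibria import SearchSpec, find_fixed_points, newton_refine, stability_of
from .model import (
    ModelParameters,
    STATE_NAMES,
    jacobian,
    rhs,
    rhs_param_derivative,
    state_dim,
)

__all__ = [
    "BranchCurve",
    "BranchPoint",
    "FoldPoint",
    "StepControl",
    "trace_branch",
    "refine_fold",
    "fold_normal_form",
    "solve_fold_system",
    "quadratic_coefficient",
    "upper_branch_slope",
]

FREE_PARAMS = ("k_Bo", "k_bl")


@dataclass(frozen=True)
class BranchPoint:
    param: float
    state: np.ndarray
    stability: str
    piece: int = 0  # index of the contiguous traced curve this point belongs to


@dataclass
class FoldPoint:
    """A saddle-node (limit) point on an equilibrium branch."""

    free_param: str
    param: float
    state: np.ndarray
    q: np.ndarray  # right null vector, <q,q> = 1, oriented q[-1] > 0
    p: np.ndarray  # left null vector, <p,q> = 1
    a: float | None = None  # quadratic normal-form coefficient

    def to_dict(self) -> dict:
        names = STATE_NAMES[: self.state.size]
        return {
            "free_param": self.free_param,
            "param": float(self.param),
            "state": {n: float(v) for n, v in zip(names, self.state)},
            "normal_form_a": None if self.a is None else float(self.a),
        }


@dataclass(frozen=True)
class StepControl:
    """Adaptive arclength step sizes (initial 0.5, clamped to [1e-3, 5])."""

    initial: float = 0.5
    min_step: float = 1e-3
    max_step: float = 5.0
    grow: float = 1.3
    shrink: float = 0.5
    max_steps: int = 5000
    newton_tol: float = 1e-10
    max_newton_iter: int = 12


@dataclass
class BranchCurve:
    """An equilibrium branch with folds and stable/unstable layers."""

    free_param: str
    variant: str
    points: list[BranchPoint]
    folds: list[FoldPoint] = field(default_factory=list)
    hopf_candidates: list[float] = field(default_factory=list)

    @property
    def params_values(self) -> np.ndarray:
        return np.array([pt.param for pt in self.points])

    def layers(self) -> dict[str, list[BranchPoint]]:
        """Partition the branch into lower / middle / upper layers.

        Each traced piece is split where the linear stability changes
        (which, for this system, happens only at folds).  Unstable
        segments are pooled as the middle layer; stable segments are
        named by their butyrate level relative to the fold states
        (upper = high B = non-inflamed, lower = low B = inflamed).
        """
        segments: list[list[BranchPoint]] = []
        for piece in sorted({pt.piece for pt in self.points}):
            pts = [pt for pt in self.points if pt.piece == piece]
            current: list[BranchPoint] = []
            prev_cls: str | None = None
            for pt in pts:
                cls = pt.stability if pt.stability != "marginal" else prev_cls
                if prev_cls is not None and cls != prev_cls and current:
                    segments.append(current)
                    current = []
                current.append(pt)
                prev_cls = cls if cls is not None else prev_cls
            if current:
                segments.append(current)

        stable_segments = []
        middle: list[BranchPoint] = []
        for seg in segments:
            n_stable = sum(pt.stability == "stable" for pt in seg)
            if n_stable >= len(seg) / 2:
                stable_segments.append(seg)
            else:
                middle.extend(seg)

        out: dict[str, list[BranchPoint]] = {"middle": middle}
        if not stable_segments:
            return out
        if self.folds:
            # a stable layer sits above or below the fold state(s) in B
            threshold = float(np.mean([f.state[-1] for f in self.folds]))
        else:
            threshold = float(np.median([pt.state[-1] for pt in self.points]))
        for seg in stable_segments:
            label = "upper" if np.mean([pt.state[-1] for pt in seg]) >= threshold else "lower"
            out[label] = out.get(label, []) + seg
        return out

    def layer_arrays(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(free-parameter values, B values) of a layer, sorted by parameter."""
        pts = self.layers().get(name, [])
        if not pts:
            return np.array([]), np.array([])
        order = np.argsort([pt.param for pt in pts])
        x = np.array([pts[i].param for i in order])
        b = np.array([pts[i].state[-1] for i in order])
        keep = np.concatenate([[True], np.diff(x) > 1e-12])
        return x[keep], b[keep]

    def to_frame(self) -> pd.DataFrame:
        names = STATE_NAMES[: state_dim(self.variant)]
        layer_of: dict[int, str] = {}
        for lname, pts in self.layers().items():
            for pt in pts:
                layer_of[id(pt)] = lname
        rows = []
        for pt in self.points:
            row = {self.free_param: pt.param}
            row.update({n: v for n, v in zip(names, pt.state)})
            row["stability"] = pt.stability
            row["layer"] = layer_of.get(id(pt), "middle")
            row["piece"] = pt.piece
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _bordered_tangent(x, alpha, params, variant, free_param, t_prev):
    """Unit tangent of the branch from a bordered linear solve."""
    n = x.size
    J = jacobian(x, params.with_(**{free_param: alpha}), variant, check=False)
    f_a = rhs_param_derivative(x, params.with_(**{free_param: alpha}), variant, free_param)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = J
    A[:n, n] = f_a
    A[n, :] = t_prev
    b = np.zeros(n + 1)
    b[n] = 1.0
    t = np.linalg.solve(A, b)
    return t / np.linalg.norm(t)


def _corrector(u_pred, t_pred, params, variant, free_param, ctrl: StepControl):
    """Newton correction orthogonal to the predictor tangent."""
    n = u_pred.size - 1
    u = u_pred.copy()
    for it in range(ctrl.max_newton_iter):
        x, alpha = u[:n], u[n]
        if alpha < 0:
            return None, it
        p_here = params.with_(**{free_param: alpha})
        f = rhs(x, p_here, variant, check=False)
        g = t_pred @ (u - u_pred)
        res = max(np.max(np.abs(f)), abs(g))
        if res < ctrl.newton_tol:
            return u, it
        J = jacobian(x, p_here, variant, check=False)
        f_a = rhs_param_derivative(x, p_here, variant, free_param)
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = J
        A[:n, n] = f_a
        A[n, :] = t_pred
        rhs_vec = -np.concatenate([f, [g]])
        try:
            du = np.linalg.solve(A, rhs_vec)
        except np.linalg.LinAlgError:
            return None, it
        u = u + du
        if np.linalg.norm(du) > 10.0 * (1.0 + np.linalg.norm(u_pred)):
            return None, it
    return None, ctrl.max_newton_iter


def _correct_at_param(x_guess, alpha, params, variant, free_param):
    return newton_refine(x_guess, params.with_(**{free_param: alpha}), variant)


def _trace_from(
    x0,
    alpha0,
    params,
    variant,
    free_param,
    prange,
    direction,
    ctrl: StepControl,
    piece: int,
):
    """One continuation sweep starting at an equilibrium on a range end."""
    lo, hi = prange
    n = x0.size
    u = np.concatenate([x0, [alpha0]])
    t_prev = np.zeros(n + 1)
    t_prev[n] = direction
    t = _bordered_tangent(u[:n], u[n], params, variant, free_param, t_prev)
    if t[n] * direction < 0:
        t = -t

    def classify(x, alpha):
        _, cls = stability_of(x, params.with_(**{free_param: alpha}), variant)
        return cls

    points = [BranchPoint(u[n], u[:n].copy(), classify(u[:n], u[n]), piece)]
    tangents = [t]
    h = ctrl.initial
    steps = 0
    while steps < ctrl.max_steps:
        steps += 1
        u_pred = u + h * t
        u_new, n_iter = _corrector(u_pred, t, params, variant, free_param, ctrl)
        if u_new is None:
            h *= ctrl.shrink
            if h < ctrl.min_step:
                # branch may terminate on a range boundary (e.g. the k_bl >= 0
                # clamp); try to land the endpoint there before giving up
                target = lo if t[n] < 0 else hi
                x_end = _correct_at_param(u[:n], target, params, variant, free_param)
                if x_end is not None and abs(u[n] - target) < 10.0 * ctrl.initial:
                    points.append(
                        BranchPoint(target, x_end, classify(x_end, target), piece)
                    )
                    tangents.append(t)
                else:
                    warnings.warn(
                        f"corrector failed at {free_param}={u[n]:.6g}; stopping branch"
                    )
                break
            continue
        t_new = _bordered_tangent(u_new[:n], u_new[n], params, variant, free_param, t)
        if t_new @ t < 0:
            t_new = -t_new
        u, t = u_new, t_new
        points.append(BranchPoint(u[n], u[:n].copy(), classify(u[:n], u[n]), piece))
        tangents.append(t)
        if n_iter <= 3:
            h = min(h * ctrl.grow, ctrl.max_step)
        elif n_iter >= ctrl.max_newton_iter - 2:
            h = max(h * ctrl.shrink, ctrl.min_step)
        if not (lo - 1e-9 <= u[n] <= hi + 1e-9):
            # clamp the exit point onto the range boundary
            alpha_end = float(np.clip(u[n], lo, hi))
            x_end = _correct_at_param(u[:n], alpha_end, params, variant, free_param)
            if x_end is not None:
                points[-1] = BranchPoint(
                    alpha_end, x_end, classify(x_end, alpha_end), piece
                )
            break
    return points, tangents


def _detect_fold_brackets(points, tangents):
    """Indices i where the tangent parameter component changes sign."""
    n = points[0].state.size
    out = []
    for i in range(len(tangents) - 1):
        s0, s1 = tangents[i][n], tangents[i + 1][n]
        if s0 == 0.0 or s1 == 0.0 or s0 * s1 < 0:
            out.append(i)
    return out


def refine_fold(
    approx_state,
    approx_param: float,
    params: ModelParameters,
    variant: str,
    free_param: str,
    *,
    tol: float = 1e-10,
    max_iter: int = 40,
    orient_toward: np.ndarray | None = None,
) -> FoldPoint:
    """Newton solve of the bordered fold system {f = 0, J q = 0, <q,q> = 1}.

    Unknowns are the state, the free parameter and the right null vector
    q; the Jacobian of the extended system is assembled with analytic J
    and finite differences for the second-order blocks.

    ``orient_toward``: optional state on the stable branch adjoining the
    fold; q is flipped to point from the fold toward it.  With that
    orientation the normal-form coefficient is negative exactly when the
    adjoining branch is attracting along the center direction, which is
    the reading under which both folds of an S-shaped hysteresis with
    stable outer layers carry a < 0.  Without it, q is oriented to have
    a positive last (butyrate) component.
    """
    def f(x, alpha):
        return rhs(x, params.with_(**{free_param: alpha}), variant, check=False)

    def jac(x, alpha):
        return jacobian(x, params.with_(**{free_param: alpha}), variant, check=False)

    def f_alpha(x, alpha):
        return rhs_param_derivative(
            x, params.with_(**{free_param: alpha}), variant, free_param
        )

    x, alpha, q, p_vec = solve_fold_system(
        f,
        jac,
        f_alpha,
        approx_state,
        approx_param,
        tol=tol,
        max_iter=max_iter,
        orient_toward=orient_toward,
    )
    return FoldPoint(free_param=free_param, param=alpha, state=x, q=q, p=p_vec)


def solve_fold_system(
    f,
    jac,
    f_alpha,
    x0,
    alpha0: float,
    *,
    tol: float = 1e-10,
    max_iter: int = 40,
    orient_toward: np.ndarray | None = None,
):
    """Generic bordered fold solver for a system f(x, alpha).

    ``f``, ``jac`` and ``f_alpha`` are callables of (x, alpha) giving the
    vector field, its state Jacobian and its parameter derivative.
    Returns (x, alpha, q, p) at the fold with <q,q> = 1, <p,q> = 1.
    """
    x = np.asarray(x0, dtype=float).copy()
    alpha = float(alpha0)
    n = x.size
    eig, vecs = np.linalg.eig(jac(x, alpha))
    q = np.real(vecs[:, np.argmin(np.abs(eig))])
    q /= np.linalg.norm(q)

    def G(x, alpha, q):
        return np.concatenate(
            [f(x, alpha), jac(x, alpha) @ q, [0.5 * (q @ q - 1.0)]]
        )

    for _ in range(max_iter):
        g = G(x, alpha, q)
        if np.max(np.abs(g)) < tol:
            break
        J = jac(x, alpha)
        f_a = np.atleast_1d(f_alpha(x, alpha))
        # d(Jq)/dx and d(Jq)/dalpha by central differences of the Jacobian
        dJq_dx = np.zeros((n, n))
        hx = 1e-6 * (1.0 + np.abs(x))
        for i in range(n):
            e = np.zeros(n)
            e[i] = hx[i]
            dJq_dx[:, i] = (jac(x + e, alpha) - jac(x - e, alpha)) @ q / (2.0 * hx[i])
        ha = 1e-6 * (1.0 + abs(alpha))
        dJq_da = (jac(x, alpha + ha) - jac(x, alpha - ha)) @ q / (2.0 * ha)

        A = np.zeros((2 * n + 1, 2 * n + 1))
        A[:n, :n] = J
        A[:n, n] = f_a
        A[n : 2 * n, :n] = dJq_dx
        A[n : 2 * n, n] = dJq_da
        A[n : 2 * n, n + 1 :] = J
        A[2 * n, n + 1 :] = q
        try:
            du = np.linalg.solve(A, -g)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"fold refinement: singular extended system: {exc}")
        x = x + du[:n]
        alpha = alpha + du[n]
        q = q + du[n + 1 :]
    else:
        raise RuntimeError(
            f"fold refinement did not converge (residual {np.max(np.abs(g)):.2e} "
            f"at parameter {alpha:.6g})"
        )

    q /= np.linalg.norm(q)
    if orient_toward is not None:
        if q @ (np.asarray(orient_toward, dtype=float) - x) < 0:
            q = -q
    elif q[-1] < 0:
        q = -q
    # left null vector, normalized <p, q> = 1
    eigT, vecsT = np.linalg.eig(jac(x, alpha).T)
    p_vec = np.real(vecsT[:, np.argmin(np.abs(eigT))])
    p_vec = p_vec / (p_vec @ q)
    return x, alpha, q, p_vec


def fold_normal_form(
    fold: FoldPoint,
    params: ModelParameters,
    variant: str,
    *,
    h_rel: float = 1e-3,
) -> float:
    """Quadratic normal-form coefficient a = 1/2 <p, B2(q, q)> at a fold.

    B2(q, q) is the second directional derivative of the rhs along q,
    evaluated by a central second difference.  With the stated
    normalization (<q,q> = 1, <p,q> = 1, q oriented with positive last
    component) a < 0 marks a fold whose colliding branches form the
    stable/unstable pair of an attracting hysteresis layer.
    """
    p_loc = params.with_(**{fold.free_param: fold.param})
    a = quadratic_coefficient(
        lambda x: rhs(x, p_loc, variant, check=False),
        fold.state,
        fold.q,
        fold.p,
        h_rel=h_rel,
    )
    fold.a = a
    return a


def quadratic_coefficient(f, x, q, p, *, h_rel: float = 1e-3) -> float:
    """a = 1/2 <p, B2(q, q)> for a generic vector field f(x) at a fold.

    The bilinear second derivative along q is taken by a central second
    difference with step scaled to the state magnitude.
    """
    x = np.asarray(x, dtype=float)
    h = h_rel * (1.0 + float(np.linalg.norm(x)))
    b2 = (f(x + h * q) - 2.0 * f(x) + f(x - h * q)) / h**2
    a = 0.5 * float(np.asarray(p) @ b2)
    if abs(a) < 1e-12:
        warnings.warn("degenerate fold: |a| < 1e-12")
    return a


def trace_branch(
    params: ModelParameters,
    variant: str = "core",
    free_param: str = "k_Bo",
    prange: tuple[float, float] = (10.0, 300.0),
    step_control: StepControl | None = None,
    *,
    search_spec: SearchSpec | None = None,
    compute_normal_forms: bool = True,
) -> BranchCurve:
    """Trace all equilibrium layers of the model over a parameter range.

    Starts from every equilibrium found at each end of the range and
    continues inward; sweeps whose starting point already lies on a
    traced piece are skipped, so disconnected layers (as for the lumen
    LPS parameter, where the inflamed branch never folds back) are still
    covered.  Folds are refined on the bordered extended system and, by
    default, equipped with their normal-form coefficient.  Eigenvalues
    are monitored for imaginary-axis crossings away from folds (Hopf
    candidates); none occur for the published parameter set.
    """
    if free_param not in FREE_PARAMS:
        raise ValueError(f"free_param must be one of {FREE_PARAMS}")
    lo, hi = float(prange[0]), float(prange[1])
    if lo < 0:
        raise ValueError(f"{free_param} range must be nonnegative")
    ctrl = step_control or StepControl()
    spec = search_spec or SearchSpec()

    all_points: list[BranchPoint] = []
    all_tangent_runs: list[tuple[list[BranchPoint], list[np.ndarray]]] = []
    piece = 0
    for alpha_end, direction in ((lo, +1.0), (hi, -1.0)):
        p_end = params.with_(**{free_param: alpha_end})
        for fp in find_fixed_points(p_end, variant, spec):
            covered = any(
                abs(pt.param - alpha_end) < 1e-6
                and np.allclose(pt.state, fp.state, rtol=1e-3, atol=1e-6)
                for pt in all_points
            )
            if covered:
                continue
            pts, tans = _trace_from(
                fp.state,
                alpha_end,
                params,
                variant,
                free_param,
                (lo, hi),
                direction,
                ctrl,
                piece,
            )
            all_points.extend(pts)
            all_tangent_runs.append((pts, tans))
            piece += 1

    curve = BranchCurve(free_param=free_param, variant=variant, points=all_points)

    # fold detection and refinement per traced run
    for pts, tans in all_tangent_runs:
        for i in _detect_fold_brackets(pts, tans):
            x_mid = 0.5 * (pts[i].state + pts[i + 1].state)
            a_mid = 0.5 * (pts[i].param + pts[i + 1].param)
            # nearest stable point along the branch fixes the q orientation
            toward = None
            for k in range(len(pts)):
                for j in (i - k, i + 1 + k):
                    if 0 <= j < len(pts) and pts[j].stability == "stable":
                        toward = pts[j].state
                        break
                if toward is not None:
                    break
            try:
                fold = refine_fold(
                    x_mid, a_mid, params, variant, free_param, orient_toward=toward
                )
            except RuntimeError as exc:
                warnings.warn(str(exc))
                continue
            if not (lo - 1e-6 <= fold.param <= hi + 1e-6):
                continue
            if any(
                abs(fold.param - f.param) < 1e-6 * (1.0 + abs(f.param))
                and np.allclose(fold.state, f.state, rtol=1e-4, atol=1e-8)
                for f in curve.folds
            ):
                continue
            if compute_normal_forms:
                fold_normal_form(fold, params, variant)
            curve.folds.append(fold)
    curve.folds.sort(key=lambda f: f.param)

    # Hopf monitoring: complex pair crossing the imaginary axis between
    # consecutive points, away from folds
    for pts, _ in all_tangent_runs:
        for i in range(len(pts) - 1):
            e0, _ = stability_of(
                pts[i].state, params.with_(**{free_param: pts[i].param}), variant
            )
            e1, _ = stability_of(
                pts[i + 1].state, params.with_(**{free_param: pts[i + 1].param}), variant
            )
            c0 = e0[np.abs(e0.imag) > 1e-10]
            c1 = e1[np.abs(e1.imag) > 1e-10]
            if c0.size and c1.size and np.max(c0.real) * np.max(c1.real) < 0:
                curve.hopf_candidates.append(0.5 * (pts[i].param + pts[i + 1].param))
    return curve


def upper_branch_slope(
    params: ModelParameters,
    variant: str,
    k_Bo_values: tuple[float, float] = (900.0, 1000.0),
) -> float:
    """Finite-difference slope dB/dk_Bo of the high-butyrate layer.

    For large lumen butyrate the inflammatory subsystem is suppressed
    and the balance of transport, diffusion and decay gives the linear
    asymptote B ~ k_Bo (1 + k_d) / k_B.
    """
    b_vals = []
    for k in k_Bo_values:
        p = params.with_(k_Bo=k)
        guess = np.array([1e-4, 1e-3, 0.1, 0.01, k * (1.0 + p.k_d) / p.k_B])
        if variant == "base":
            raise ValueError("slope check applies to the 5-component variants")
        x = newton_refine(guess, p, variant)
        if x is None:
            raise RuntimeError(f"no upper-branch equilibrium found at k_Bo={k}")
        b_vals.append(x[-1])
    return float((b_vals[1] - b_vals[0]) / (k_Bo_values[1] - k_Bo_values[0]))
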