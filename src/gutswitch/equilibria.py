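"""Equilibrium location, linear stability, and invariant-box checks.

Equilibria are found by damped Newton iteration from a deterministic
multistart grid, deduplicated and sorted by the butyrate component.  The
box checks verify numerically that the vector field points into a large
box P of the positive orthant (so trajectories are trapped and at least
one equilibrium must exist in its interior) and that no equilibrium sits
in a small ball around the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ModelParameters, STATE_NAMES, jacobian, rhs, state_dim

__all__ = [
    "FixedPoint",
    "InvariantBox",
    "SearchSpec",
    "find_fixed_points",
    "newton_refine",
    "stability_of",
    "verify_box_invariance",
]

#: eigenvalue real parts within this of zero are classified "marginal"
TOL_STAB = 1e-8
#: scaled residual max-norm required of a reported equilibrium
TOL_RESIDUAL = 1e-9


def scaled_residual(x: np.ndarray, params: ModelParameters, variant: str) -> float:
    """Max-norm of the rhs, scaled per-component by max(1, |x_i|).

    The two stable states differ by ~4 orders of magnitude in several
    components, so an unscaled norm would over-weight the large ones.
    """
    f = rhs(x, params, variant, check=False)
    return float(np.max(np.abs(f) / np.maximum(1.0, np.abs(x))))


@dataclass(frozen=True)
class FixedPoint:
    """An equilibrium with its linearization."""

    state: np.ndarray
    params: ModelParameters
    variant: str
    eigenvalues: np.ndarray
    stability: str  # "stable" | "unstable" | "marginal"
    residual: float

    @property
    def B(self) -> float:
        return float(self.state[-1]) if self.variant != "base" else float("nan")

    def to_dict(self) -> dict:
        names = STATE_NAMES[: state_dim(self.variant)]
        return {
            "state": {n: float(v) for n, v in zip(names, self.state)},
            "eigenvalues": [[float(ev.real), float(ev.imag)] for ev in self.eigenvalues],
            "stability": self.stability,
            "residual": float(self.residual),
            "variant": self.variant,
        }


@dataclass(frozen=True)
class SearchSpec:
    """Deterministic multistart grid for equilibrium search.

    N starts on a fixed list of admissible fractions; the remaining
    components on a log-spaced grid spanning [floor, ceiling].
    """

    n_values: tuple[float, ...] = (0.001, 0.01, 0.1, 0.5, 0.9)
    log_floor: float = 1e-4
    log_ceiling: float = 1e4
    points_per_axis: int = 4
    max_newton_iter: int = 80
    dedup_rtol: float = 1e-6

    def starts(self, variant: str) -> np.ndarray:
        grid = np.geomspace(self.log_floor, self.log_ceiling, self.points_per_axis)
        n = state_dim(variant)
        axes = [np.asarray(self.n_values)] + [grid] * (n - 1)
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)


def newton_refine(
    x0: np.ndarray,
    params: ModelParameters,
    variant: str,
    *,
    max_iter: int = 80,
    tol: float = TOL_RESIDUAL,
) -> np.ndarray | None:
    """Damped Newton iteration on the rhs with the analytic Jacobian.

    Returns the converged state, or ``None`` if the iteration leaves the
    admissible region or fails to converge.
    """
    x = np.asarray(x0, dtype=float).copy()
    for _ in range(max_iter):
        f = rhs(x, params, variant, check=False)
        res = np.max(np.abs(f) / np.maximum(1.0, np.abs(x)))
        if res < tol:
            return x
        J = jacobian(x, params, variant, check=False)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            return None
        # backtracking damping on the scaled residual
        lam = 1.0
        for _ in range(30):
            x_new = x + lam * step
            if x_new[0] < 1.0 + 1e-9 and np.all(x_new > -1e-12):
                f_new = rhs(np.clip(x_new, 0.0, None), params, variant, check=False)
                if np.linalg.norm(f_new) < (1.0 - 0.25 * lam) * np.linalg.norm(f) + tol:
                    x = np.clip(x_new, 0.0, None)
                    break
            lam *= 0.5
        else:
            return None
    return None


def stability_of(
    state, params: ModelParameters, variant: str = "core", *, tol_stab: float = TOL_STAB
) -> tuple[np.ndarray, str]:
    """Eigenvalues of the analytic Jacobian and the stability class.

    "stable" iff every real part < -tol_stab, "unstable" iff some real
    part > +tol_stab, "marginal" otherwise (an eigenvalue pinned to the
    imaginary axis, as at a fold).
    """
    eig = np.linalg.eigvals(jacobian(state, params, variant, check=False))
    re = eig.real
    if np.all(re < -tol_stab):
        cls = "stable"
    elif np.any(re > tol_stab):
        cls = "unstable"
    else:
        cls = "marginal"
    return eig, cls


def _make_fixed_point(x: np.ndarray, params: ModelParameters, variant: str) -> FixedPoint:
    eig, cls = stability_of(x, params, variant)
    return FixedPoint(
        state=x,
        params=params,
        variant=variant,
        eigenvalues=eig,
        stability=cls,
        residual=scaled_residual(x, params, variant),
    )


def find_fixed_points(
    params: ModelParameters,
    variant: str = "core",
    search_spec: SearchSpec | None = None,
) -> list[FixedPoint]:
    """All equilibria reachable from the multistart grid, sorted by B.

    Deterministic for a fixed grid; duplicates are merged when states
    agree within the spec's relative tolerance.
    """
    spec = search_spec or SearchSpec()
    found: list[np.ndarray] = []
    for x0 in spec.starts(variant):
        x = newton_refine(x0, params, variant, max_iter=spec.max_newton_iter)
        if x is None:
            continue
        if any(
            np.allclose(x, y, rtol=spec.dedup_rtol, atol=spec.dedup_rtol)
            for y in found
        ):
            continue
        found.append(x)
    found.sort(key=lambda s: s[-1])
    return [_make_fixed_point(x, params, variant) for x in found]


@dataclass(frozen=True)
class InvariantBox:
    """The trapping box P: 0 <= N <= 1, 0 <= L <= L0, 0 <= R,T,B <= K.

    L0 = k_bl/k_l + delta.  K must exceed L0 and be large enough that
    the decay terms dominate on the outer faces; epsilon bounds the
    origin ball in which the butyrate and LPS inflows are checked to be
    strictly positive.
    """

    delta: float = 1.0
    K: float = 1e4
    epsilon: float = 1e-4

    def L0(self, params: ModelParameters) -> float:
        return params.k_bl / params.k_l + self.delta

    def validate(self, params: ModelParameters) -> None:
        if self.delta <= 0 or self.epsilon <= 0:
            raise ValueError("delta and epsilon must be > 0")
        if self.K <= self.L0(params):
            raise ValueError(f"K = {self.K} must exceed L0 = {self.L0(params)}")
        if params.d <= 0:
            raise ValueError("all rate constants must be > 0 for the box argument")


@dataclass
class FaceReport:
    face: str
    passed: bool
    worst_margin: float
    worst_point: np.ndarray | None = None


@dataclass
class BoxReport:
    faces: list[FaceReport] = field(default_factory=list)
    origin_ball_ok: bool = True
    origin_worst: float = np.inf

    @property
    def passed(self) -> bool:
        return self.origin_ball_ok and all(f.passed for f in self.faces)


def verify_box_invariance(
    params: ModelParameters,
    variant: str = "core",
    box: InvariantBox | None = None,
    n_samples: int = 200,
    *,
    rng: np.random.Generator | int | None = 0,
) -> BoxReport:
    """Sample every face of the box P and check the flow points inward.

    For each upper face the outward normal component of the rhs must be
    negative; on the zero faces of L and B (and in the whole
    epsilon-ball at the origin) the inflow must be strictly positive.
    The worst margin per face (most positive outward component) is
    reported.  Only the five-component variants are supported.
    """
    if variant == "base":
        raise ValueError("box invariance check is defined for the 5-component variants")
    box = box or InvariantBox()
    box.validate(params)
    rng = np.random.default_rng(rng)
    L0 = box.L0(params)
    highs = np.array([1.0, box.K, box.K, L0, box.K])
    report = BoxReport()

    # upper faces: component i pinned at its ceiling, outward normal +e_i
    for i, name in enumerate(STATE_NAMES):
        pts = rng.uniform(0.0, 1.0, size=(n_samples, 5)) * highs
        pts[:, i] = highs[i]
        vals = np.array([rhs(x, params, variant, check=False)[i] for x in pts])
        worst = int(np.argmax(vals))
        report.faces.append(
            FaceReport(
                face=f"{name}={highs[i]:g}",
                passed=bool(np.all(vals < 0.0)),
                worst_margin=float(vals[worst]),
                worst_point=pts[worst],
            )
        )

    # zero faces with strict inflow: L = 0 and B = 0
    for i, name in ((3, "L"), (4, "B")):
        pts = rng.uniform(0.0, 1.0, size=(n_samples, 5)) * highs
        pts[:, i] = 0.0
        vals = np.array([rhs(x, params, variant, check=False)[i] for x in pts])
        worst = int(np.argmin(vals))
        report.faces.append(
            FaceReport(
                face=f"{name}=0",
                passed=bool(np.all(vals > 0.0)),
                worst_margin=float(-vals[worst]),
                worst_point=pts[worst],
            )
        )

    # no equilibrium in the epsilon-ball around the origin: inflow of both
    # L and B is strictly positive whenever every component <= epsilon
    pts = rng.uniform(0.0, box.epsilon, size=(n_samples, 5))
    inflows = np.array(
        [rhs(x, params, variant, check=False)[[3, 4]] for x in pts]
    )
    report.origin_worst = float(np.min(inflows))
    report.origin_ball_ok = bool(np.all(inflows > 0.0))
    return report
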