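"""Right-hand sides, Jacobians and canonical parameter sets.

The model describes the antagonism between the NF-kB inflammatory
signalling system of a gut epithelial cell and butyrate, a bacterial
fermentation product with anti-inflammatory action.  State variables:

``N``
    nuclear NF-kB fraction (dimensionless, bounded in [0, 1] by the
    cytosolic recruitment term ``1 - N``),
``R``
    aggregate repressor level (IkB, A20, ...),
``T``
    aggregate pro-inflammatory cytokine level (TNF, IL-1, IL-6),
``L``
    within-cell LPS level (lipopolysaccharide entering through a leaky
    epithelial barrier),
``B``
    within-cell butyrate level.

Three variants are implemented:

``base``
    the four-component (N, R, T, L) inflammation model without butyrate,
``core``
    the five-component model in which butyrate blocks nuclear NF-kB
    import and LPS influx while cytokines repress the butyrate
    transporter,
``extended``
    the core model with an additional cooperative (Hill) factor on the
    butyrate transporter term, representing the positive feedback loop
    butyrate -> mucin layer -> mucin-adhered SCFA producers -> lumen
    butyrate.

All units are arbitrary: the model is qualitative and is analysed for
its switching structure, not for calibrated concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Iterator, Literal

import numpy as np

__all__ = [
    "ModelParameters",
    "PARAM_NAMES",
    "STATE_NAMES",
    "VARIANTS",
    "preset",
    "state_dim",
    "rhs",
    "jacobian",
    "rhs_param_derivative",
    "validate_state",
]

Variant = Literal["base", "core", "extended"]
VARIANTS: tuple[str, ...] = ("base", "core", "extended")

STATE_NAMES: tuple[str, ...] = ("N", "R", "T", "L", "B")

#: parameters that must be strictly positive (denominators / decay rates)
_STRICT_POSITIVE = frozenset(
    {"k_s", "k_r", "k_n", "k_br", "k_t", "k_l", "k_B", "k_bt", "k_lb", "k_2B"}
)


@dataclass(frozen=True)
class ModelParameters:
    """Immutable rate/threshold constants of the gut inflammation-butyrate model.

    All constants are nonnegative; those appearing in denominators or as
    decay rates must be strictly positive.  ``k_Bo`` is the lumen
    butyrate level (the main bifurcation parameter), ``k_bl`` the lumen
    LPS supply, ``k_2B`` the transporter Hill threshold used only by the
    extended variant.
    """

    k_a: float = 12.0     # NF-kB activation strength by cytokines
    k_s: float = 1.0      # cytokine threshold for NF-kB activation (Hill, n=3)
    k_ai: float = 5.0     # repressor-mediated NF-kB inactivation
    k_r: float = 0.5      # NF-kB saturation threshold of the inactivation terms
    k_bn: float = 4.7     # butyrate block of nuclear NF-kB import
    k_b: float = 5.0      # repressor production by NF-kB
    k_br: float = 0.5     # repressor decay
    k_n: float = 0.2      # NF-kB threshold for cytokine production (Hill, n=2)
    k_p: float = 7.0      # cytokine production strength
    k_t: float = 0.2      # cytokine decay
    k_tl: float = 2.8     # cytokine activation by within-cell LPS
    k_bl: float = 1.02    # lumen LPS supply
    k_lb: float = 3.4     # butyrate threshold for barrier tightening (Hill, n=2)
    k_l: float = 0.7      # within-cell LPS decay
    k_bt: float = 2.1     # cytokine threshold for transporter repression (Hill, n=2)
    k_d: float = 0.125    # passive butyrate diffusion coefficient
    k_B: float = 2.9      # within-cell butyrate decay
    k_Bo: float = 130.0   # lumen butyrate level (bifurcation parameter)
    k_2B: float = 5.0     # transporter Hill threshold (extended variant only)

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v!r}")
            if f.name in _STRICT_POSITIVE and v == 0:
                raise ValueError(f"parameter {f.name} must be > 0")

    def with_(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the named constants replaced."""
        unknown = set(overrides) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    def __iter__(self) -> Iterator[float]:
        return (getattr(self, f.name) for f in fields(self))

    @property
    def u(self) -> float:
        """Largest rate constant (excluding the drive k_Bo)."""
        return max(v for name, v in self.to_dict().items() if name != "k_Bo")

    @property
    def d(self) -> float:
        """Smallest rate constant (excluding the drive k_Bo)."""
        return min(v for name, v in self.to_dict().items() if name != "k_Bo")


PARAM_NAMES: tuple[str, ...] = tuple(f.name for f in fields(ModelParameters))

#: named presets; "fig2a" carries the published hysteresis parameter set,
#: which is also the dataclass default.
_PRESETS: dict[str, dict[str, float]] = {
    "fig2a": {},
}


def preset(name: str = "fig2a") -> ModelParameters:
    """Return a named parameter preset."""
    try:
        overrides = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
    return ModelParameters(**overrides)


def state_dim(variant: str) -> int:
    """Number of dynamical components of a variant (4 for base, else 5)."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    return 4 if variant == "base" else 5


def validate_state(state: np.ndarray, variant: str, *, tol: float = 0.0) -> np.ndarray:
    """Check dimension and admissibility of a state vector.

    Raises ``ValueError`` on a negative component or N > 1 (beyond
    ``tol``, which allows for solver round-off).
    """
    x = np.asarray(state, dtype=float)
    n = state_dim(variant)
    if x.shape != (n,):
        raise ValueError(
            f"variant {variant!r} needs a {n}-component state, got shape {x.shape}"
        )
    if np.any(x < -tol):
        raise ValueError(f"negative state component: {x}")
    if x[0] > 1.0 + tol:
        raise ValueError(f"N = {x[0]} exceeds 1")
    return x


def _hill_up(x: float, k: float, n: int) -> float:
    """Activating Hill term x^n / (x^n + k^n)."""
    xn = x**n
    return xn / (xn + k**n)


def rhs(state, params: ModelParameters, variant: str = "core", *, check: bool = True):
    """Time derivatives of the selected model variant.

    The core system is

        dN/dt = k_a T^3/(T^3+k_s^3) (1-N) - (k_ai R + k_bn B) N/(N+k_r)
        dR/dt = k_b N - k_br R
        dT/dt = k_p N^2/(N^2+k_n^2) - k_t T + k_tl L
        dL/dt = k_bl k_lb^2/(B^2+k_lb^2) - k_l L
        dB/dt = k_Bo k_bt^2/(T^2+k_bt^2) + k_d k_Bo - k_B B

    The base variant drops B (and the butyrate terms of dN/dt, dL/dt);
    the extended variant multiplies the transporter term of dB/dt by the
    cooperative factor B^2/(B^2 + k_2B^2).
    """
    p = params
    if check:
        x = validate_state(state, variant)
    else:
        x = np.asarray(state, dtype=float)

    if variant == "base":
        N, R, T, L = x
        dN = p.k_a * _hill_up(T, p.k_s, 3) * (1.0 - N) - p.k_ai * R * N / (N + p.k_r)
        dR = p.k_b * N - p.k_br * R
        dT = p.k_p * _hill_up(N, p.k_n, 2) - p.k_t * T + p.k_tl * L
        dL = p.k_bl - p.k_l * L
        return np.array([dN, dR, dT, dL])

    N, R, T, L, B = x
    dN = p.k_a * _hill_up(T, p.k_s, 3) * (1.0 - N) - (
        p.k_ai * R + p.k_bn * B
    ) * N / (N + p.k_r)
    dR = p.k_b * N - p.k_br * R
    dT = p.k_p * _hill_up(N, p.k_n, 2) - p.k_t * T + p.k_tl * L
    dL = p.k_bl * p.k_lb**2 / (B**2 + p.k_lb**2) - p.k_l * L
    transporter = p.k_Bo * p.k_bt**2 / (T**2 + p.k_bt**2)
    if variant == "extended":
        transporter *= B**2 / (B**2 + p.k_2B**2)
    dB = transporter + p.k_d * p.k_Bo - p.k_B * B
    return np.array([dN, dR, dT, dL, dB])


def jacobian(state, params: ModelParameters, variant: str = "core", *, check: bool = True):
    """Analytic Jacobian d(rhs)/d(state) of the selected variant."""
    p = params
    if check:
        x = validate_state(state, variant)
    else:
        x = np.asarray(state, dtype=float)

    if variant == "base":
        N, R, T, L = x
        B = 0.0
    else:
        N, R, T, L, B = x

    h3 = _hill_up(T, p.k_s, 3)
    dh3 = 3.0 * p.k_s**3 * T**2 / (T**3 + p.k_s**3) ** 2
    g = N / (N + p.k_r)
    dg = p.k_r / (N + p.k_r) ** 2
    dh2 = 2.0 * p.k_n**2 * N / (N**2 + p.k_n**2) ** 2

    if variant == "base":
        J = np.zeros((4, 4))
        J[0, 0] = -p.k_a * h3 - p.k_ai * R * dg
        J[0, 1] = -p.k_ai * g
        J[0, 2] = p.k_a * dh3 * (1.0 - N)
        J[1, 0] = p.k_b
        J[1, 1] = -p.k_br
        J[2, 0] = p.k_p * dh2
        J[2, 2] = -p.k_t
        J[2, 3] = p.k_tl
        J[3, 3] = -p.k_l
        return J

    inhib = p.k_ai * R + p.k_bn * B
    J = np.zeros((5, 5))
    J[0, 0] = -p.k_a * h3 - inhib * dg
    J[0, 1] = -p.k_ai * g
    J[0, 2] = p.k_a * dh3 * (1.0 - N)
    J[0, 4] = -p.k_bn * g
    J[1, 0] = p.k_b
    J[1, 1] = -p.k_br
    J[2, 0] = p.k_p * dh2
    J[2, 2] = -p.k_t
    J[2, 3] = p.k_tl
    J[3, 3] = -p.k_l
    J[3, 4] = -p.k_bl * p.k_lb**2 * 2.0 * B / (B**2 + p.k_lb**2) ** 2
    hbt = p.k_bt**2 / (T**2 + p.k_bt**2)
    dhbt = -p.k_bt**2 * 2.0 * T / (T**2 + p.k_bt**2) ** 2
    if variant == "extended":
        hB = B**2 / (B**2 + p.k_2B**2)
        dhB = 2.0 * p.k_2B**2 * B / (B**2 + p.k_2B**2) ** 2
        J[4, 2] = p.k_Bo * dhbt * hB
        J[4, 4] = p.k_Bo * hbt * dhB - p.k_B
    else:
        J[4, 2] = p.k_Bo * dhbt
        J[4, 4] = -p.k_B
    return J


def rhs_param_derivative(state, params: ModelParameters, variant: str, name: str):
    """Analytic derivative of the rhs with respect to one rate constant.

    Implemented for the two continuation parameters ``k_Bo`` (lumen
    butyrate) and ``k_bl`` (lumen LPS); other names fall back to a
    central finite difference.
    """
    p = params
    x = np.asarray(state, dtype=float)
    n = state_dim(variant)
    out = np.zeros(n)
    if name == "k_Bo" and variant != "base":
        N, R, T, L, B = x
        hbt = p.k_bt**2 / (T**2 + p.k_bt**2)
        if variant == "extended":
            hbt *= B**2 / (B**2 + p.k_2B**2)
        out[4] = hbt + p.k_d
        return out
    if name == "k_bl":
        if variant == "base":
            out[3] = 1.0
        else:
            B = x[4]
            out[3] = p.k_lb**2 / (B**2 + p.k_lb**2)
        return out
    # generic fallback
    h = 1e-6 * max(1.0, abs(getattr(p, name)))
    f_plus = rhs(x, p.with_(**{name: getattr(p, name) + h}), variant, check=False)
    f_minus = rhs(x, p.with_(**{name: getattr(p, name) - h}), variant, check=False)
    return (f_plus - f_minus) / (2.0 * h)
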