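"""Change of variables of a lumen-butyrate density through the hysteresis.

A cohort of guts with lumen butyrate levels x ~ p(x) (Gaussian by
default) maps to within-cell butyrate levels y = h(x), where h is a
stable layer of the hysteresis.  The standard change of variables

    q(y) = p(x) / |h'(x)|,   y = h(x),

applied separately to the upper (non-inflamed) and lower (inflamed)
layers and weighted by the probability of occupying each, yields a
bimodal within-cell density even though the input is unimodal.  Near a
fold h' diverges on the middle layer and the layer ends; occupation of
the fold point itself is dynamically unstable, so a small parameter
neighborhood around each fold is excluded from the transform and its
probability mass is reported as excluded rather than redistributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import norm

from .continuation import BranchCurve

__all__ = ["InputDensity", "LayerMap", "DensityTransform", "transform_density"]


@dataclass(frozen=True)
class InputDensity:
    """Gaussian density of the lumen butyrate level x = k_Bo."""

    mean: float = 130.0
    sd: float = 40.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")

    def pdf(self, x) -> np.ndarray:
        return norm.pdf(x, loc=self.mean, scale=self.sd)

    def mass(self, lo: float, hi: float) -> float:
        return float(
            norm.cdf(hi, self.mean, self.sd) - norm.cdf(lo, self.mean, self.sd)
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mean, self.sd, size=n)


@dataclass
class LayerMap:
    """Monotone spline map y = h(x) of one stable hysteresis layer."""

    name: str
    x: np.ndarray  # free-parameter values, strictly increasing
    y: np.ndarray  # within-cell butyrate on the layer
    spline: PchipInterpolator
    inverse: PchipInterpolator  # x = h^-1(y), monotone since h is

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.x[-1])

    @property
    def y_range(self) -> tuple[float, float]:
        return float(np.min(self.y)), float(np.max(self.y))

    def h(self, x) -> np.ndarray:
        return self.spline(x)

    def h_prime(self, x) -> np.ndarray:
        return self.spline.derivative()(x)

    def h_inv(self, y) -> np.ndarray:
        return self.inverse(y)


@dataclass
class DensityTransform:
    """Result of pushing p(x) through the stable hysteresis layers."""

    input_density: InputDensity
    weights: dict[str, float]
    layers: dict[str, LayerMap]
    y_grid: np.ndarray
    q_layers: dict[str, np.ndarray]
    q_combined: np.ndarray
    retained_mass: float
    excluded_mass: float
    #: per-layer excluded parameter windows around the fold terminating it
    excluded_windows: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def modes(self, *, min_height: float = 1e-8) -> list[float]:
        """Locations of strict local maxima of the combined density."""
        q = self.q_combined
        y = self.y_grid
        out = []
        for i in range(1, len(q) - 1):
            if q[i] > min_height and q[i] > q[i - 1] and q[i] >= q[i + 1]:
                if not out or y[i] - out[-1] > 1e-9:
                    out.append(float(y[i]))
        return out

    def total_mass(self) -> float:
        return float(np.trapezoid(self.q_combined, self.y_grid))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"y": self.y_grid})
        for name, q in self.q_layers.items():
            df[f"q_{name}"] = q
        df["q_combined"] = self.q_combined
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "modes": self.modes(),
            "retained_mass": self.retained_mass,
            "excluded_mass": self.excluded_mass,
            "weights": self.weights,
            "mean": self.input_density.mean,
            "sd": self.input_density.sd,
        }


def _layer_maps(branch: BranchCurve, min_points: int = 4) -> dict[str, LayerMap]:
    maps = {}
    for name in ("lower", "upper"):
        x, y = branch.layer_arrays(name)
        if x.size < min_points:
            continue
        dy = np.diff(y)
        if not (np.all(dy > 0) or np.all(dy < 0)):
            # PCHIP requires monotone x (guaranteed); h must be invertible
            raise ValueError(f"layer {name!r} is not monotone in the free parameter")
        if dy[0] > 0:
            inverse = PchipInterpolator(y, x)
        else:
            inverse = PchipInterpolator(y[::-1], x[::-1])
        maps[name] = LayerMap(
            name=name, x=x, y=y, spline=PchipInterpolator(x, y), inverse=inverse
        )
    return maps


def transform_density(
    branch: BranchCurve,
    p: InputDensity,
    weights: dict[str, float] | None = None,
    fold_exclusion: float = 0.01,
    *,
    n_grid: int = 2000,
    layers: dict[str, LayerMap] | None = None,
) -> DensityTransform:
    """Push the lumen density through each stable layer of the branch.

    ``weights`` assigns the occupation probability of each stable layer
    (default: equal split between upper and lower); ``fold_exclusion``
    is the half-width of the excluded parameter window around each fold,
    relative to the fold's parameter value.  The combined output density
    integrates to the input mass retained after exclusion.
    """
    maps = layers if layers is not None else _layer_maps(branch)
    if not maps:
        raise ValueError("branch has no usable stable layer")
    if weights is None:
        w = 1.0 / len(maps)
        weights = {name: w for name in maps}
    if abs(sum(weights.values()) - 1.0) > 1e-9 or any(v < 0 for v in weights.values()):
        raise ValueError("weights must be nonnegative and sum to 1")

    windows = [
        (f.param * (1.0 - fold_exclusion), f.param * (1.0 + fold_exclusion))
        for f in branch.folds
    ]

    # a window applies to a layer only if its fold terminates that layer
    # (h' diverges there); a layer passing the other fold's parameter value
    # is smooth and keeps its mass
    def _applicable(lm: LayerMap) -> list[tuple[float, float]]:
        lo, hi = lm.domain
        out = []
        for (wlo, whi) in windows:
            width = whi - wlo
            mid = 0.5 * (wlo + whi)
            if min(abs(mid - lo), abs(mid - hi)) <= max(width, 1e-9):
                out.append((wlo, whi))
        return out

    layer_windows = {name: _applicable(lm) for name, lm in maps.items()}

    # mass bookkeeping per layer (analytic, via the input cdf)
    retained = 0.0
    excluded = 0.0
    y_min, y_max = np.inf, -np.inf
    for name, lm in maps.items():
        lo, hi = lm.domain
        w_mass = p.mass(lo, hi)
        w_excl = sum(
            p.mass(max(lo, wlo), min(hi, whi))
            for wlo, whi in layer_windows[name]
            if whi > lo and wlo < hi
        )
        retained += weights[name] * (w_mass - w_excl)
        excluded += weights[name] * w_excl
        ylo, yhi = lm.y_range
        y_min, y_max = min(y_min, ylo), max(y_max, yhi)

    # evaluate q(y) = w p(h^-1(y)) / |h'(h^-1(y))| on a common y grid,
    # zeroing the images of the excluded fold windows
    pad = 0.02 * (y_max - y_min)
    y_grid = np.linspace(y_min - pad, y_max + pad, n_grid)
    q_layers = {}
    for name, lm in maps.items():
        ylo, yhi = lm.y_range
        q = np.zeros_like(y_grid)
        inside = (y_grid >= ylo) & (y_grid <= yhi)
        x = lm.h_inv(y_grid[inside])
        hp = lm.h_prime(x)
        if np.any(np.abs(hp) < 1e-12):
            raise FloatingPointError(
                f"|h'| < 1e-12 on layer {name!r} outside the fold exclusion zones"
            )
        qx = weights[name] * p.pdf(x) / np.abs(hp)
        for wlo, whi in layer_windows[name]:
            qx[(x >= wlo) & (x <= whi)] = 0.0
        q[inside] = qx
        q_layers[name] = q
    q_combined = np.sum(list(q_layers.values()), axis=0)
    return DensityTransform(
        input_density=p,
        weights=dict(weights),
        layers=maps,
        y_grid=y_grid,
        q_layers=q_layers,
        q_combined=q_combined,
        retained_mass=retained,
        excluded_mass=excluded,
        excluded_windows=layer_windows,
    )


def monte_carlo_histogram(
    maps: dict[str, LayerMap],
    p: InputDensity,
    weights: dict[str, float],
    windows: dict[str, list[tuple[float, float]]],
    n_draws: int,
    rng: np.random.Generator,
    bins: np.ndarray,
) -> np.ndarray:
    """Histogram of y = h(x) for x ~ p, layer chosen by the weights.

    Draws falling outside the chosen layer's domain or inside that
    layer's fold exclusion window are discarded, mirroring the excluded
    mass of the deterministic transform.  Returns the density-normalized
    histogram.
    """
    names = list(maps)
    probs = np.array([weights[n] for n in names])
    choice = rng.choice(len(names), size=n_draws, p=probs / probs.sum())
    x = p.sample(n_draws, rng)
    ys = []
    for i, name in enumerate(names):
        lm = maps[name]
        lo, hi = lm.domain
        xi = x[choice == i]
        ok = (xi >= lo) & (xi <= hi)
        for wlo, whi in windows.get(name, []):
            ok &= ~((xi >= wlo) & (xi <= whi))
        ys.append(lm.h(xi[ok]))
    y = np.concatenate(ys)
    hist, _ = np.histogram(y, bins=bins, density=True)
    return hist
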