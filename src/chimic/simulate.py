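"""Seeded generators for every synthetic input used by the statistics.

Three families:

* Functional relationships y = f(x) with relative uniform noise,
  ``Y = f(X) + (U - 0.5) * level * RANGE`` where U ~ Uniform(0, 1) and RANGE
  is the span of f over its domain, so ``level`` is a noise amplitude
  relative to the signal.  X defaults to the midpoint grid
  ``(k + 1/2)/n`` over the domain -- the randomness of this protocol lies in
  the noise term -- with an i.i.d.-uniform option.
* The five relationships of the power study (linear, parabolic, sinusoidal,
  circular, checkerboard) with Gaussian noise of amplitude ``a``.
* Independent Uniform(0, 1) pairs, the null configuration.

All generators are bit-reproducible given a seed and never touch global RNG
state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core_grid import PairedSample

__all__ = [
    "FunctionSpec",
    "NoiseSpec",
    "CATALOG",
    "sample_function",
    "sample_table3",
    "independent_pair",
    "TABLE3_RELATIONSHIPS",
]


@dataclass(frozen=True)
class FunctionSpec:
    """A named functional relationship with its x-domain and signal range."""

    name: str
    f: Callable[[np.ndarray], np.ndarray]
    x_domain: tuple[float, float]
    range_span: float | None = None

    def span(self) -> float:
        """RANGE of f over the domain (dense-grid evaluation if not given)."""
        if self.range_span is not None:
            return self.range_span
        lo, hi = self.x_domain
        y = self.f(np.linspace(lo, hi, 20001))
        return float(y.max() - y.min())


def _catalog() -> dict[str, FunctionSpec]:
    specs = [
        FunctionSpec("linear", lambda x: x, (0.0, 1.0), 1.0),
        # vertex interior so the relationship is genuinely non-monotone
        FunctionSpec("parabolic", lambda x: 4.0 * x**2, (-0.5, 0.5), 1.0),
        FunctionSpec("sinusoidal", lambda x: np.sin(4 * np.pi * x), (0.0, 1.0), 2.0),
        FunctionSpec("sine-one-period", lambda x: np.sin(2 * np.pi * x), (0.0, 1.0), 2.0),
        FunctionSpec("cosine", lambda x: np.cos(2 * np.pi * x), (0.0, 1.0), 2.0),
        FunctionSpec("cubic", lambda x: (2.0 * x - 1.0) ** 3, (0.0, 1.0), 2.0),
        FunctionSpec("exponential", lambda x: np.exp(2.0 * x), (0.0, 1.0)),
        FunctionSpec("sqrt", lambda x: np.sqrt(x), (0.0, 1.0), 1.0),
        FunctionSpec(
            "logistic", lambda x: 1.0 / (1.0 + np.exp(-12.0 * (x - 0.5))), (0.0, 1.0)
        ),
        FunctionSpec("vee", lambda x: np.abs(2.0 * x - 1.0), (0.0, 1.0), 1.0),
    ]
    return {s.name: s for s in specs}


#: the noiseless-function catalog; configurable stand-in list, the first
#: three entries are the relationships the figures are built on
CATALOG: dict[str, FunctionSpec] = _catalog()


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model and level for a functional relationship."""

    model: str = "uniform-eq4"
    level: float = 0.0

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("noise level must be non-negative")
        if self.model not in ("uniform-eq4", "gaussian-table3"):
            raise ValueError(f"unknown noise model {self.model!r}")


def _resolve(spec: FunctionSpec | str) -> FunctionSpec:
    if isinstance(spec, FunctionSpec):
        return spec
    try:
        return CATALOG[spec]
    except KeyError:
        raise ValueError(
            f"unknown function {spec!r}; catalog: {sorted(CATALOG)}"
        ) from None


def sample_function(
    spec: FunctionSpec | str,
    n: int,
    noise: NoiseSpec | float = 0.0,
    seed: int | np.random.Generator = 0,
    x_mode: str = "grid",
) -> PairedSample:
    """Sample ``Y = f(X) + (U - 0.5) * level * RANGE``.

    ``x_mode="grid"`` places X at domain midpoints (k + 1/2)/n (the seed
    then only drives the noise); ``x_mode="uniform"`` draws X i.i.d.
    uniform on the domain.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    spec = _resolve(spec)
    if not isinstance(noise, NoiseSpec):
        noise = NoiseSpec(level=float(noise))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = spec.x_domain
    if x_mode == "grid":
        x = lo + (hi - lo) * (np.arange(n) + 0.5) / n
    elif x_mode == "uniform":
        x = rng.uniform(lo, hi, n)
    else:
        raise ValueError("x_mode must be 'grid' or 'uniform'")
    y = spec.f(x)
    if noise.level > 0:
        y = y + (rng.uniform(size=n) - 0.5) * noise.level * spec.span()
    return PairedSample(x, y)


TABLE3_RELATIONSHIPS = ("linear", "parabolic", "sinusoidal", "circular", "checkerboard")

#: solid squares (i + j even) of the 4x5 unit-square checkerboard
_SOLID_SQUARES = [(i, j) for i in range(4) for j in range(5) if (i + j) % 2 == 0]


def sample_table3(
    relationship: str,
    n: int,
    a: float,
    seed: int | np.random.Generator = 0,
) -> PairedSample:
    """One trial data set of the power study at noise amplitude ``a``.

    xi, eta ~ N(0,1); theta ~ Uniform[-pi, pi); (X0, Y0) uniform on the
    solid squares of the 4x5 checkerboard.
    """
    if a <= 0:
        raise ValueError("amplitude a must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if relationship == "linear":
        x = rng.standard_normal(n)
        y = 2.0 / 3.0 * x + a * rng.standard_normal(n)
    elif relationship == "parabolic":
        x = rng.standard_normal(n)
        y = x**2 + a * rng.standard_normal(n)
    elif relationship == "sinusoidal":
        x = 2.5 * rng.uniform(-np.pi, np.pi, n)
        y = 2.0 * np.cos(x) + a * rng.standard_normal(n)
    elif relationship == "circular":
        theta = rng.uniform(-np.pi, np.pi, n)
        x = 10.0 * np.cos(theta) + a * rng.standard_normal(n)
        y = 10.0 * np.sin(theta) + a * rng.standard_normal(n)
    elif relationship == "checkerboard":
        sq = np.asarray(_SOLID_SQUARES)[rng.integers(len(_SOLID_SQUARES), size=n)]
        x0 = sq[:, 0] + rng.uniform(size=n)
        y0 = sq[:, 1] + rng.uniform(size=n)
        x = 10.0 * x0 + a * rng.standard_normal(n)
        y = 10.0 * y0 + a * rng.standard_normal(n)
    else:
        raise ValueError(
            f"unknown relationship {relationship!r}; choose from {TABLE3_RELATIONSHIPS}"
        )
    return PairedSample(x, y)


def independent_pair(n: int, seed: int | np.random.Generator = 0) -> PairedSample:
    """n i.i.d. Uniform(0,1) pairs with X and Y independent."""
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return PairedSample(rng.uniform(size=n), rng.uniform(size=n))
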