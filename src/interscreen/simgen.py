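"""Synthetic cohort generation for interaction-test calibration studies.

The generative model is a linear outcome

    Y = g0 + gG*G + gE*E + gGE*G*E + gZ*Z + eps

where ``G`` is a biallelic SNP dosage (0/1/2) drawn under Hardy-Weinberg
equilibrium, ``E`` is an exposure (in the eQTL setting, the mRNA level of a
transcription factor) that may interact with ``G``, ``Z`` is a second,
non-interacting exposure, and ``eps`` is residual noise.  Effect sizes are
parameterized on the *variance-fraction* scale: with all predictors
standardized to mean 0 / variance 1 and mutually independent, a coefficient
``sqrt(tau)`` makes its term explain exactly a fraction ``tau`` of
``var(Y)`` when the residual is scaled so ``var(Y) = 1``.

Two simulation regimes are supported:

* fixed-fraction scenarios (:class:`ScenarioConfig` / :func:`build_cohort`),
  used for the transformation demos and the interaction-strength sweeps, and
* the randomized-effects robustness grid (:class:`GridConfig` /
  :func:`draw_grid_replicate`), where coefficients are drawn U(0,1) per
  replicate and the residual is scaled to hit a per-replicate explained
  variance drawn uniformly over a configurable range (0-80% by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Literal

import numpy as np

__all__ = [
    "ScenarioConfig",
    "Cohort",
    "GridCell",
    "GridConfig",
    "sample_genotypes",
    "sample_skewed",
    "coef_from_tau",
    "build_cohort",
    "draw_grid_replicate",
    "SKEW_SLANT",
]

Dist = Literal["normal", "right_skew"]

#: Shape (slant) parameter of the right-skewed normal.  alpha=5 gives a
#: pronounced right skew (standardized skewness ~0.851) while keeping all
#: moments finite; the distribution is recentred/rescaled analytically to
#: population mean 0 and variance 1.
SKEW_SLANT = 5.0

_DISTS = ("normal", "right_skew")


class InvalidParameterError(ValueError):
    """A simulation parameter is outside its admissible range."""


def _check_dist(name: str, value: str) -> None:
    if value not in _DISTS:
        raise InvalidParameterError(f"{name} must be one of {_DISTS}, got {value!r}")


@dataclass(frozen=True)
class ScenarioConfig:
    """One fixed simulation scenario.

    Parameters
    ----------
    n : sample count (>= 10).
    caf : coded-allele frequency of G, in (0, 0.5].
    tau_g, tau_e, tau_z, tau_ge : variance fractions in [0, 1) for the G, E
        and Z main effects and the GxE interaction; their sum must be < 1 so
        the residual variance ``1 - sum`` is strictly positive.
    dist_e, dist_z, dist_eps : marginal distribution of E, Z and the residual,
        ``"normal"`` or ``"right_skew"`` (both standardized to mean 0, var 1).
    mean_e : location shift applied to the *recorded* exposure vector only
        (the outcome is always assembled from centered components, so the
        variance fractions stay exact; the shift is absorbed by the G main
        effect / intercept under any model that includes them).
    standardize_predictors : provenance flag; the generator always calibrates
        on the standardized scale.
    seed : root seed; identical (config, seed) replays bitwise-identically.
    """

    n: int
    caf: float
    tau_g: float = 0.0
    tau_e: float = 0.0
    tau_z: float = 0.0
    tau_ge: float = 0.0
    dist_e: Dist = "normal"
    dist_z: Dist = "normal"
    dist_eps: Dist = "normal"
    mean_e: float = 0.0
    standardize_predictors: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise InvalidParameterError(f"n must be >= 10, got {self.n}")
        if not (0.0 < self.caf <= 0.5):
            raise InvalidParameterError(f"caf must be in (0, 0.5], got {self.caf}")
        for name in ("tau_g", "tau_e", "tau_z", "tau_ge"):
            tau = getattr(self, name)
            if not (0.0 <= tau < 1.0):
                raise InvalidParameterError(f"{name} must be in [0, 1), got {tau}")
        if self.tau_sum >= 1.0:
            raise InvalidParameterError(
                f"variance fractions sum to {self.tau_sum}; must be < 1"
            )
        for name in ("dist_e", "dist_z", "dist_eps"):
            _check_dist(name, getattr(self, name))

    @property
    def tau_sum(self) -> float:
        return self.tau_g + self.tau_e + self.tau_z + self.tau_ge


@dataclass
class Cohort:
    """One realized replicate of the generative model.

    ``g_raw`` holds 0/1/2 dosages, ``g_std`` the theoretically standardized
    dosage ``(g_raw - 2*caf) / sqrt(2*caf*(1-caf))``; ``eps`` is the true
    (already scaled) generative residual, retained so that fitted-model
    residual variance can be compared against it per genotype class.
    """

    g_raw: np.ndarray
    g_std: np.ndarray
    e: np.ndarray
    z: np.ndarray
    eps: np.ndarray
    y: np.ndarray
    config: ScenarioConfig | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.y.shape[0]


def sample_genotypes(n: int, caf: float, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` independent 0/1/2 dosages under Hardy-Weinberg equilibrium.

    Genotype probabilities are ((1-caf)^2, 2*caf*(1-caf), caf^2), i.e. a
    Binomial(2, caf) count of coded alleles.
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if not (0.0 < caf <= 0.5):
        raise InvalidParameterError(f"caf must be in (0, 0.5], got {caf}")
    return rng.binomial(2, caf, size=n).astype(np.int64)


def sample_skewed(
    n: int, rng: np.random.Generator, slant: float = SKEW_SLANT
) -> np.ndarray:
    """Draw from a right-skewed normal standardized to mean 0, variance 1.

    Uses the Azzalini skew-normal construction ``delta*|Z0| + sqrt(1-delta^2)*Z1``
    with ``delta = slant/sqrt(1+slant^2)``, followed by the analytic
    location/scale correction (mean ``delta*sqrt(2/pi)``, variance
    ``1 - 2*delta^2/pi``).  ``slant=0`` reduces exactly to a standard normal
    (internal check mode).
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if slant == 0.0:
        return rng.standard_normal(n)
    delta = slant / math.sqrt(1.0 + slant * slant)
    z0 = rng.standard_normal(n)
    z1 = rng.standard_normal(n)
    x = delta * np.abs(z0) + math.sqrt(1.0 - delta * delta) * z1
    mean = delta * math.sqrt(2.0 / math.pi)
    sd = math.sqrt(1.0 - 2.0 * delta * delta / math.pi)
    return (x - mean) / sd


def _sample_dist(
    dist: str, n: int, rng: np.random.Generator, size: tuple[int, ...] | None = None
) -> np.ndarray:
    shape = size if size is not None else (n,)
    if dist == "normal":
        return rng.standard_normal(shape)
    if dist == "right_skew":
        flat = sample_skewed(int(np.prod(shape)), rng)
        return flat.reshape(shape)
    raise InvalidParameterError(f"unknown distribution {dist!r}")


def coef_from_tau(tau: float) -> float:
    """Coefficient giving a term variance fraction ``tau`` of a unit-variance Y.

    With standardized independent predictors (mean 0, var 1) the product
    term also has variance 1 (``var(G*E) = E[G^2]E[E^2] = 1``), so the
    coefficient is simply ``sqrt(tau)``.
    """
    if not (0.0 <= tau < 1.0):
        raise InvalidParameterError(f"tau must be in [0, 1), got {tau}")
    return math.sqrt(tau)


def standardize_dosage(g_raw: np.ndarray, caf) -> np.ndarray:
    """Standardize dosages by theoretical HWE moments (mean 2p, var 2p(1-p)).

    ``caf`` may be a scalar or an array broadcastable against ``g_raw``
    (per-SNP frequencies for a dosage matrix).
    """
    return (g_raw - 2.0 * caf) / np.sqrt(2.0 * caf * (1.0 - caf))


def build_cohort(config: ScenarioConfig) -> Cohort:
    """Realize one cohort under the fixed-fraction generative model.

    The outcome is assembled from centered, unit-variance components with
    coefficients ``sqrt(tau)`` per term, and the residual is drawn from
    ``dist_eps`` then scaled so ``var(eps) = 1 - sum(tau)``; hence
    ``var(Y) -> 1`` as n grows, with each term owning exactly its fraction.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    g_raw = sample_genotypes(n, config.caf, rng)
    g_std = standardize_dosage(g_raw, config.caf)
    e0 = _sample_dist(config.dist_e, n, rng)
    z0 = _sample_dist(config.dist_z, n, rng)
    eps0 = _sample_dist(config.dist_eps, n, rng)

    c_g = coef_from_tau(config.tau_g)
    c_e = coef_from_tau(config.tau_e)
    c_z = coef_from_tau(config.tau_z)
    c_ge = coef_from_tau(config.tau_ge)
    resid_sd = math.sqrt(1.0 - config.tau_sum)
    eps = eps0 * resid_sd

    y = c_g * g_std + c_e * e0 + c_ge * g_std * e0 + c_z * z0 + eps
    return Cohort(
        g_raw=g_raw,
        g_std=g_std,
        e=e0 + config.mean_e,
        z=z0,
        eps=eps,
        y=y,
        config=config,
    )


# ---------------------------------------------------------------------------
# Randomized-effects robustness grid
# ---------------------------------------------------------------------------

MAIN_EFFECT_REGIMES = ("both", "e_only", "z_only", "neither")
DIST_REGIMES = ("normal", "right_skew")
EpsRule = Literal["uniform_r2", "unit"]


@dataclass(frozen=True)
class GridCell:
    """One cell of the robustness grid.

    ``main_effect_regime`` controls which of the E/Z *main* effects are
    active; the G main effect and the GxE interaction are always drawn.
    ``dist_regime`` applies to E, Z and eps jointly.  The special regimes
    ``main_effect_regime="random"`` (gZ active in half the replicates, gE
    always) and ``dist_regime="random"`` (normal/right-skew per replicate)
    reproduce the aggregate mixture condition used when quoting a single
    inflation factor for a (sample size, allele frequency) pair.
    """

    n: int
    caf: float
    dist_regime: str = "normal"
    main_effect_regime: str = "both"
    r2_total_range: tuple[float, float] = (0.0, 0.8)
    eps_rule: EpsRule = "uniform_r2"

    def __post_init__(self) -> None:
        if self.n < 10:
            raise InvalidParameterError(f"n must be >= 10, got {self.n}")
        if not (0.0 < self.caf <= 0.5):
            raise InvalidParameterError(f"caf must be in (0, 0.5], got {self.caf}")
        if self.dist_regime not in _DISTS + ("random",):
            raise InvalidParameterError(f"bad dist_regime {self.dist_regime!r}")
        if self.main_effect_regime not in MAIN_EFFECT_REGIMES + ("random",):
            raise InvalidParameterError(
                f"bad main_effect_regime {self.main_effect_regime!r}"
            )
        lo, hi = self.r2_total_range
        if not (0.0 <= lo <= hi < 1.0):
            raise InvalidParameterError(
                f"r2_total_range must satisfy 0 <= lo <= hi < 1, got {self.r2_total_range}"
            )
        if self.eps_rule not in ("uniform_r2", "unit"):
            raise InvalidParameterError(f"bad eps_rule {self.eps_rule!r}")


@dataclass(frozen=True)
class GridConfig:
    """Full factorial robustness grid (default 4 x 3 x 2 x 4 = 96 cells)."""

    n_list: tuple[int, ...] = (100, 500, 1000, 5000)
    caf_list: tuple[float, ...] = (0.05, 0.3, 0.5)
    dist_regimes: tuple[str, ...] = ("normal", "right_skew")
    main_effect_regimes: tuple[str, ...] = MAIN_EFFECT_REGIMES
    replicates_per_cell: int = 20_000
    r2_total_range: tuple[float, float] = (0.0, 0.8)
    eps_rule: EpsRule = "uniform_r2"
    seed: int = 0

    def cells(self) -> list[GridCell]:
        return [
            GridCell(
                n=n,
                caf=caf,
                dist_regime=d,
                main_effect_regime=m,
                r2_total_range=self.r2_total_range,
                eps_rule=self.eps_rule,
            )
            for n, caf, d, m in product(
                self.n_list, self.caf_list, self.dist_regimes, self.main_effect_regimes
            )
        ]

    def cell_rng(self, cell_index: int) -> np.random.Generator:
        """Independent, order-free substream for one cell."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(cell_index,))
        )


def draw_grid_batch(
    cell: GridCell, replicates: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, dict]:
    """Draw a batch of grid replicates as (replicates, n) matrices.

    Returns ``(y, g_raw, g_std, z, eps, meta)`` where meta records the drawn
    coefficients and explained-variance targets.  Coefficients gG and gGE
    are always U(0,1); gE / gZ are U(0,1) or 0 per the cell regime.  The
    residual is scaled per the cell's eps_rule: under ``"uniform_r2"`` the
    per-replicate systematic variance S = sum of squared coefficients is
    matched to a drawn target R^2 ~ U(r2_total_range) via
    ``var(eps) = S * (1/R^2 - 1)``; under ``"unit"`` var(eps) = 1.
    """
    r, n = replicates, cell.n
    if r < 1:
        raise InvalidParameterError("replicates must be >= 1")

    g_g = rng.uniform(0.0, 1.0, size=r)
    g_ge = rng.uniform(0.0, 1.0, size=r)
    regime = cell.main_effect_regime
    if regime == "random":
        g_e = rng.uniform(0.0, 1.0, size=r)
        g_z = np.where(rng.random(r) < 0.5, rng.uniform(0.0, 1.0, size=r), 0.0)
    else:
        e_on = regime in ("both", "e_only")
        z_on = regime in ("both", "z_only")
        g_e = rng.uniform(0.0, 1.0, size=r) if e_on else np.zeros(r)
        g_z = rng.uniform(0.0, 1.0, size=r) if z_on else np.zeros(r)

    g_raw = rng.binomial(2, cell.caf, size=(r, n)).astype(np.int64)
    g_std = standardize_dosage(g_raw, cell.caf)
    if cell.dist_regime == "random":
        # one distribution regime per replicate, shared by E, Z and eps
        skewed = rng.random(r) < 0.5
        e0 = np.empty((r, n))
        z0 = np.empty((r, n))
        eps0 = np.empty((r, n))
        for mask, dist in ((~skewed, "normal"), (skewed, "right_skew")):
            k = int(mask.sum())
            if k:
                e0[mask] = _sample_dist(dist, 0, rng, size=(k, n))
                z0[mask] = _sample_dist(dist, 0, rng, size=(k, n))
                eps0[mask] = _sample_dist(dist, 0, rng, size=(k, n))
    else:
        e0 = _sample_dist(cell.dist_regime, 0, rng, size=(r, n))
        z0 = _sample_dist(cell.dist_regime, 0, rng, size=(r, n))
        eps0 = _sample_dist(cell.dist_regime, 0, rng, size=(r, n))

    s_var = g_g**2 + g_e**2 + g_z**2 + g_ge**2
    if cell.eps_rule == "uniform_r2":
        lo, hi = cell.r2_total_range
        r2 = rng.uniform(lo, hi, size=r)
        r2 = np.maximum(r2, 1e-12)  # guard the measure-zero R^2 = 0 draw
        eps_var = s_var * (1.0 / r2 - 1.0)
    else:
        r2 = s_var / (s_var + 1.0)
        eps_var = np.ones(r)

    eps = eps0 * np.sqrt(eps_var)[:, None]
    y = (
        g_g[:, None] * g_std
        + g_e[:, None] * e0
        + g_ge[:, None] * g_std * e0
        + g_z[:, None] * z0
        + eps
    )
    meta = {
        "gamma_g": g_g,
        "gamma_e": g_e,
        "gamma_z": g_z,
        "gamma_ge": g_ge,
        "r2_target": r2,
        "eps_var": eps_var,
    }
    return y, g_raw, g_std, z0, eps, meta


def draw_grid_replicate(cell: GridCell, rng: np.random.Generator) -> Cohort:
    """Draw a single grid replicate (the batch generator at batch size 1)."""
    y, g_raw, g_std, z0, eps, meta = draw_grid_batch(cell, 1, rng)
    return Cohort(
        g_raw=g_raw[0],
        g_std=g_std[0],
        e=np.full(cell.n, np.nan),  # E is the unmeasured exposure in the grid
        z=z0[0],
        eps=eps[0],
        y=y[0],
        config=None,
        meta={k: float(v[0]) for k, v in meta.items()},
    )


def cohort_to_frame(cohort: Cohort):
    """Tab-separated-friendly view of a cohort (sample_id, G, E, Z, Y)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(cohort.n)],
            "G": cohort.g_raw,
            "E": cohort.e,
            "Z": cohort.z,
            "Y": cohort.y,
        }
    )
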