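"""Calibration metrics and the headline simulation experiments.

Turns batches of replicate p-values into the quantities used to judge an
interaction test's validity: empirical type I error, the genomic inflation
factor lambda_GC, QQ-plot coordinates, and per-genotype residual-variance
profiles.  Also drives the two canonical experiments:

* :func:`run_tau_sweep` -- interaction strength tau_GxE swept from 0 to 30%
  of var(Y) at n=400, 10,000 replicates per point, measuring how a true
  G-by-E interaction (E unmeasured) inflates the G-by-Z test; and
* :func:`run_grid` / :func:`run_robustness` -- the randomized-effects
  robustness study over sample size x allele frequency x distribution x
  main-effect regimes, scoring all five strategies by lambda_GC.

:func:`null_selected_r2` reproduces the expected effect-size distribution
among null associations passing a Benjamini-Hochberg-style threshold, used
to judge winner's-curse-style selection in an eQTL screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from . import simgen
from .inttests import STRATEGIES, batch_ols, interaction_pvalues_batch
from .simgen import GridCell, GridConfig, standardize_dosage
from .transforms import rank_inverse_normal

__all__ = [
    "ScenarioSummary",
    "VarianceProfile",
    "type1_error",
    "lambda_gc",
    "qq_points",
    "variance_by_genotype",
    "run_tau_sweep",
    "run_grid",
    "run_grid_cell",
    "run_robustness",
    "run_transform_demo",
    "null_selected_r2",
]

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.454936...


@dataclass
class ScenarioSummary:
    """Per-scenario calibration summary across strategies."""

    scenario_id: str
    n_replicates: int
    type1: dict[str, float] = field(default_factory=dict)
    lambda_gc: dict[str, float] = field(default_factory=dict)
    qq: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


@dataclass
class VarianceProfile:
    """Residual-variance heterogeneity by genotype class.

    ``delta_var`` is the variance of the fitted-model residual delta within
    each genotype class, ``eps_var`` the variance of the true generative
    residual; their difference isolates the heteroscedasticity induced by
    an interaction with an unmeasured factor (the two residuals differ only
    through the misspecification).
    """

    classes: np.ndarray
    counts: np.ndarray
    delta_var: np.ndarray
    eps_var: np.ndarray
    diff: np.ndarray
    excluded_classes: tuple[int, ...] = ()


def _check_pvals(pvals: np.ndarray) -> np.ndarray:
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value batch")
    return p


def type1_error(pvals: np.ndarray, alpha: float) -> float:
    """Fraction of p-values at or below ``alpha``."""
    p = _check_pvals(pvals)
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(np.mean(p <= alpha))


def lambda_gc(pvals: np.ndarray) -> float:
    """Genomic inflation factor: median chi-square over the chi2(1) median."""
    p = _check_pvals(pvals)
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_1_MEDIAN)


def qq_points(pvals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed -log10(p), most significant first.

    Expected quantiles sit at (i - 0.5)/N for rank i.
    """
    p = _check_pvals(pvals)
    n = p.size
    observed = -np.log10(np.sort(p))
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    return expected, observed


def qq_envelope(n: int, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise Beta order-statistic confidence band for a uniform QQ plot."""
    i = np.arange(1, n + 1)
    lo = stats.beta.ppf((1 - level) / 2, i, n - i + 1)
    hi = stats.beta.ppf(1 - (1 - level) / 2, i, n - i + 1)
    return -np.log10(hi), -np.log10(lo)


def variance_by_genotype(
    delta: np.ndarray, g_raw: np.ndarray, eps: np.ndarray
) -> VarianceProfile:
    """Within-genotype-class variances of delta and eps and their difference.

    Classes with fewer than 2 observations are excluded (flagged).
    """
    d = np.asarray(delta, dtype=float)
    g = np.asarray(g_raw)
    e = np.asarray(eps, dtype=float)
    if not (d.shape == g.shape == e.shape):
        raise ValueError("delta, g_raw, eps must be aligned")
    classes, counts, dvar, evar, excluded = [], [], [], [], []
    for c in np.unique(g):
        mask = g == c
        cnt = int(mask.sum())
        if cnt < 2:
            excluded.append(int(c))
            continue
        classes.append(int(c))
        counts.append(cnt)
        dvar.append(float(np.var(d[mask], ddof=1)))
        evar.append(float(np.var(e[mask], ddof=1)))
    dvar = np.array(dvar)
    evar = np.array(evar)
    return VarianceProfile(
        classes=np.array(classes),
        counts=np.array(counts),
        delta_var=dvar,
        eps_var=evar,
        diff=dvar - evar,
        excluded_classes=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# Interaction-strength sweep (tau_GxE from 0 to 30% of var(Y))
# ---------------------------------------------------------------------------

SWEEP_REGIMES = ("none", "g", "e", "z")


def _class_variances_batch(
    values: np.ndarray, g_raw: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean within-class variance of (reps, n) values by genotype, per class.

    Returns ``(mean_var, mean_count)`` arrays of length 3 (classes 0, 1, 2);
    replicates where a class has < 2 members are skipped for that class.
    """
    mean_var = np.full(3, np.nan)
    mean_cnt = np.zeros(3)
    for c in range(3):
        mask = g_raw == c
        cnt = mask.sum(axis=1)
        ok = cnt >= 2
        if not ok.any():
            continue
        m, v, k = mask[ok], values[ok], cnt[ok]
        s = (v * m).sum(axis=1)
        mu = s / k
        ss = ((v - mu[:, None]) ** 2 * m).sum(axis=1)
        mean_var[c] = float(np.mean(ss / (k - 1)))
        mean_cnt[c] = float(np.mean(cnt))
    return mean_var, mean_cnt


def run_tau_sweep(
    tau_grid: np.ndarray | list[float],
    regime: str = "none",
    n: int = 400,
    reps: int = 10_000,
    caf: float = 0.1,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[list[ScenarioSummary], list[VarianceProfile]]:
    """Sweep the interaction variance fraction and measure STD-test inflation.

    For each tau in ``tau_grid`` the outcome carries a G-by-E interaction
    explaining tau of var(Y) (E unmeasured downstream) and, per ``regime``
    ("none", "g", "e" or "z"), one main effect explaining the same fraction.
    Each point runs ``reps`` replicates of ``n`` individuals, tests the
    G-by-Z interaction with the standard OLS Wald test, and records the
    empirical type I error at ``alpha`` plus the mean per-genotype
    (delta - eps) residual-variance profile.
    """
    if regime not in SWEEP_REGIMES:
        raise ValueError(f"regime must be one of {SWEEP_REGIMES}, got {regime!r}")
    summaries: list[ScenarioSummary] = []
    profiles: list[VarianceProfile] = []
    rng = np.random.default_rng(seed)
    for tau in tau_grid:
        tau = float(tau)
        tau_main = tau if regime != "none" else 0.0
        total = tau + tau_main
        if not (0.0 <= tau < 1.0) or total >= 1.0:
            raise ValueError(f"inadmissible tau {tau} for regime {regime!r}")
        c_ge = math.sqrt(tau)
        c_main = math.sqrt(tau_main)
        resid_sd = math.sqrt(1.0 - total)

        pvals = np.empty(reps)
        acc_dvar = np.zeros(3)
        acc_evar = np.zeros(3)
        acc_cnt = np.zeros(3)
        chunks = 0
        chunk = max(1, int(2_000_000 // n))
        for start in range(0, reps, chunk):
            r = min(chunk, reps - start)
            g_raw = rng.binomial(2, caf, size=(r, n)).astype(np.int64)
            g_std = standardize_dosage(g_raw, caf)
            e = rng.standard_normal((r, n))
            z = rng.standard_normal((r, n))
            eps = rng.standard_normal((r, n)) * resid_sd
            y = c_ge * g_std * e + eps
            if regime == "g":
                y += c_main * g_std
            elif regime == "e":
                y += c_main * e
            elif regime == "z":
                y += c_main * z

            poly = g_raw.min(axis=1) != g_raw.max(axis=1)
            pv = np.full(r, np.nan)
            if poly.any():
                ones = np.ones((int(poly.sum()), n))
                x = np.stack(
                    [ones, g_std[poly], z[poly], g_std[poly] * z[poly]], axis=2
                )
                beta, resid, xtx_inv = batch_ols(x, y[poly])
                sigma2 = np.einsum("rn,rn->r", resid, resid) / (n - 4)
                se2 = sigma2 * xtx_inv[:, 3, 3]
                wald = beta[:, 3] ** 2 / se2
                pv[poly] = stats.chi2.sf(wald, 1)
                dvar, cnt = _class_variances_batch(resid, g_raw[poly])
                evar, _ = _class_variances_batch(eps[poly], g_raw[poly])
                w = pv[poly].size
                acc_dvar += np.nan_to_num(dvar) * w
                acc_evar += np.nan_to_num(evar) * w
                acc_cnt += cnt * w
                chunks += w
            pvals[start : start + r] = pv

        valid = pvals[~np.isnan(pvals)]
        sid = f"tau{tau:g}_{regime}"
        summaries.append(
            ScenarioSummary(
                scenario_id=sid,
                n_replicates=valid.size,
                type1={"std": type1_error(valid, alpha)},
                lambda_gc={"std": lambda_gc(np.clip(valid, 1e-300, 1.0))},
            )
        )
        dvar = acc_dvar / max(chunks, 1)
        evar = acc_evar / max(chunks, 1)
        profiles.append(
            VarianceProfile(
                classes=np.arange(3),
                counts=acc_cnt / max(chunks, 1),
                delta_var=dvar,
                eps_var=evar,
                diff=dvar - evar,
            )
        )
    return summaries, profiles


# ---------------------------------------------------------------------------
# Randomized-effects robustness grid
# ---------------------------------------------------------------------------


def run_grid_cell(
    cell: GridCell,
    replicates: int,
    rng: np.random.Generator,
    strategies: tuple[str, ...] = STRATEGIES,
    alpha: float = 0.05,
    keep_qq: bool = False,
    min_replicates: int = 100,
) -> ScenarioSummary:
    """Run one grid cell and summarize each strategy's calibration."""
    if replicates < min_replicates:
        raise ValueError(
            f"{replicates} replicates is below the minimum batch size "
            f"({min_replicates}) for a meaningful inflation factor"
        )
    for s in strategies:
        if s not in STRATEGIES:
            raise ValueError(f"unknown strategy {s!r}")
    n = cell.n
    chunk = max(1, int(2_000_000 // n))
    collected: dict[str, list[np.ndarray]] = {s: [] for s in strategies}
    for start in range(0, replicates, chunk):
        r = min(chunk, replicates - start)
        y, g_raw, g_std, z, _eps, _meta = simgen.draw_grid_batch(cell, r, rng)
        for s in strategies:
            g_in = g_raw if s == "sat" else g_std
            collected[s].append(interaction_pvalues_batch(y, g_in, z, strategy=s))
    sid = f"n{n}_caf{cell.caf:g}_{cell.dist_regime}_{cell.main_effect_regime}"
    summary = ScenarioSummary(scenario_id=sid, n_replicates=replicates)
    for s in strategies:
        pv = np.concatenate(collected[s])
        pv = pv[~np.isnan(pv)]
        summary.type1[s] = type1_error(pv, alpha)
        summary.lambda_gc[s] = lambda_gc(pv)
        if keep_qq:
            summary.qq[s] = qq_points(pv)
    return summary


def run_grid(
    grid: GridConfig,
    strategies: tuple[str, ...] = STRATEGIES,
    alpha: float = 0.05,
    keep_qq: bool = False,
) -> pd.DataFrame:
    """Run the full robustness grid; tidy one row per cell x strategy.

    Each cell consumes an independent substream of the grid seed, so any
    single cell can be re-run in isolation and reproduce its summary.
    """
    rows = []
    for i, cell in enumerate(grid.cells()):
        summary = run_grid_cell(
            cell,
            grid.replicates_per_cell,
            grid.cell_rng(i),
            strategies=strategies,
            alpha=alpha,
            keep_qq=keep_qq,
        )
        for s in strategies:
            rows.append(
                {
                    "cell": summary.scenario_id,
                    "n": cell.n,
                    "caf": cell.caf,
                    "dist_regime": cell.dist_regime,
                    "main_effect_regime": cell.main_effect_regime,
                    "strategy": s,
                    "lambda_gc": summary.lambda_gc[s],
                    "type1_error": summary.type1[s],
                    "replicates": summary.n_replicates,
                }
            )
    return pd.DataFrame(rows)


def run_robustness(
    n: int,
    caf: float,
    replicates: int = 20_000,
    seed: int = 0,
    strategies: tuple[str, ...] = ("hc3",),
    alpha: float = 0.05,
) -> ScenarioSummary:
    """Aggregate robustness condition for one (n, CAF) pair.

    Mirrors how a single inflation factor is quoted per sample-size /
    allele-frequency panel: per replicate, gamma_G, gamma_E, gamma_GE are
    U(0,1), gamma_Z is U(0,1) in half the replicates, E/Z/eps are normal or
    right-skewed at random, and the drawn coefficients explain a U(0, 0.8)
    fraction of var(Y).
    """
    cell = GridCell(n=n, caf=caf, dist_regime="random", main_effect_regime="random")
    rng = np.random.default_rng(seed)
    return run_grid_cell(cell, replicates, rng, strategies=strategies, alpha=alpha)


# ---------------------------------------------------------------------------
# Transformation demo (induced / removed interaction)
# ---------------------------------------------------------------------------


def run_transform_demo(
    scenario: str, n: int = 10_000, seed: int = 0
) -> dict[str, float]:
    """Interaction p-values before/after rank transform in the demo regimes.

    ``scenario="main_effects"``: G (CAF 0.1) and E (mean 5) each explain 20%
    of var(Y), no interaction, right-skewed residual -- the rank transform
    *induces* an interaction here.  ``scenario="interaction"``: main effects
    10% each plus a 20% G-by-E interaction -- the transform *removes* it.
    Returns STD-test p-values on the raw and transformed outcome.
    """
    from .inttests import test_interaction

    if scenario == "main_effects":
        cfg = simgen.ScenarioConfig(
            n=n, caf=0.1, tau_g=0.2, tau_e=0.2, tau_ge=0.0,
            dist_eps="right_skew", mean_e=5.0, seed=seed,
        )
    elif scenario == "interaction":
        cfg = simgen.ScenarioConfig(
            n=n, caf=0.1, tau_g=0.1, tau_e=0.1, tau_ge=0.2,
            dist_eps="right_skew", mean_e=5.0, seed=seed,
        )
    else:
        raise ValueError("scenario must be 'main_effects' or 'interaction'")
    cohort = simgen.build_cohort(cfg)
    raw = test_interaction(cohort.y, cohort.g_raw, cohort.e, strategy="std")
    rkt = test_interaction(
        cohort.y, cohort.g_raw, cohort.e, strategy="std", apply_rkt=True
    )
    # Wald statistics allow ordering comparisons when p-values underflow
    return {
        "p_raw": raw.p,
        "p_rkt": rkt.p,
        "wald_raw": raw.wald,
        "wald_rkt": rkt.wald,
    }


# ---------------------------------------------------------------------------
# Null-selection expectation (winner's curse under a BH threshold)
# ---------------------------------------------------------------------------


def null_selected_r2(
    m_tests: int,
    n_samples: int,
    q_level: float,
    k_discoveries: int,
    method: str = "analytic",
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Expected r2 among null single-predictor tests passing a BH threshold.

    Reconstructs the per-test p threshold as ``q * k / m``; under the null
    the r2 of a simple regression at n samples is Beta(1/2, (n-2)/2), and
    the p threshold maps to an r2 threshold through the F(1, n-2) relation
    ``F = r2 (n-2) / (1 - r2)``.  Returns ``(p_threshold, mean_r2, max_r2)``
    where mean_r2 is the truncated-Beta mean above the threshold and max_r2
    the expected maximum over m draws (upper 1/(m+1) tail quantile for the
    analytic route).
    """
    if k_discoveries > m_tests:
        raise ValueError("k_discoveries cannot exceed m_tests")
    if n_samples < 4:
        raise ValueError("need n_samples >= 4")
    if not (0.0 < q_level <= 1.0):
        raise ValueError("q_level must be in (0, 1]")
    p_thr = min(1.0, q_level * k_discoveries / m_tests)
    a, b = 0.5, (n_samples - 2) / 2.0
    if p_thr >= 1.0:
        r2_thr = 0.0
    else:
        f_crit = stats.f.isf(p_thr, 1, n_samples - 2)
        r2_thr = f_crit / (f_crit + n_samples - 2)

    if method == "analytic":
        tail = 1.0 - special.betainc(a, b, r2_thr)
        if tail <= 0.0:
            raise ValueError("selection threshold leaves no null mass")
        # int_t^1 x Beta(a,b) dx = a/(a+b) * (1 - I_t(a+1, b))
        mean_r2 = (a / (a + b)) * (1.0 - special.betainc(a + 1.0, b, r2_thr)) / tail
        max_r2 = float(stats.beta.isf(1.0 / (m_tests + 1), a, b))
    elif method == "simulate":
        if rng is None:
            raise ValueError("simulation route needs an rng")
        chunk = 2_000_000
        total, count = 0.0, 0
        max_r2 = 0.0
        remaining = m_tests
        while remaining > 0:
            k = min(chunk, remaining)
            draws = rng.beta(a, b, size=k)
            sel = draws[draws >= r2_thr]
            total += float(sel.sum())
            count += sel.size
            max_r2 = max(max_r2, float(draws.max()))
            remaining -= k
        if count == 0:
            raise ValueError("no simulated null draw exceeded the threshold")
        mean_r2 = total / count
    else:
        raise ValueError("method must be 'analytic' or 'simulate'")
    return p_thr, float(mean_r2), float(max_r2)
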