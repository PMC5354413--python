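"""Interaction-test strategies and marginal association tests.

The tested model is the (possibly misspecified) regression

    Y ~ b0 + bG*G + bZ*Z + bGZ*G*Z + delta

where the truly interacting exposure E may be absent.  Five strategies
produce a Wald test of the G-by-Z interaction:

* ``std``  -- OLS with the naive covariance sigma^2 (X'X)^-1;
* ``hc0``  -- White sandwich covariance (X'X)^-1 X' diag(d_i^2) X (X'X)^-1;
* ``hc3``  -- jackknife-style sandwich with d_i^2 / (1 - h_ii)^2 weights;
* ``bin``  -- Z replaced by a median-split indicator (standard covariance);
* ``sat``  -- saturated model with genotype dummy main effects (G=1, G=2),
  Z and Z^2 main effects, and the ordinal G*Z interaction term.

All strategies report ``chi2 = (beta/se)^2`` against a chi-square with one
degree of freedom (a t reference is available behind ``use_t``).  The
outcome may optionally be rank-inverse-normal transformed first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .transforms import rank_inverse_normal

__all__ = [
    "STRATEGIES",
    "OLSFit",
    "InteractionResult",
    "fit_ols",
    "hc_covariance",
    "test_interaction",
    "marginal_test",
    "CollinearityError",
    "UntestableVariantError",
    "DegenerateExposureError",
    "UndefinedHC3Error",
]

STRATEGIES = ("std", "hc0", "hc3", "bin", "sat")

_P_FLOOR = 1e-300  # keep p strictly positive for -log10 / chi-square transforms


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


class UntestableVariantError(ValueError):
    """Genotype vector has fewer than two distinct values."""


class DegenerateExposureError(ValueError):
    """Exposure vector is constant."""


class UndefinedHC3Error(ValueError):
    """A unit-leverage observation makes the HC3 weights undefined."""


@dataclass
class OLSFit:
    """Least-squares fit with the quantities the sandwich estimators need."""

    beta: np.ndarray
    residuals: np.ndarray
    hat: np.ndarray
    cov_naive: np.ndarray
    sigma2: float
    labels: tuple[str, ...]
    design: np.ndarray
    xtx_inv: np.ndarray
    df_resid: int


@dataclass
class InteractionResult:
    strategy: str
    transform_applied: bool
    beta_gz: float
    se_gz: float
    wald: float
    p: float
    df_resid: int
    dropped_columns: tuple[str, ...] = ()


def fit_ols(
    design: np.ndarray, y: np.ndarray, labels: Sequence[str] | None = None
) -> OLSFit:
    """Ordinary least squares with hat diagonals and the naive covariance.

    ``design`` must already contain its intercept column.  Raises
    :class:`CollinearityError` naming the offending columns when the design
    is rank deficient.
    """
    x = np.asarray(design, dtype=float)
    yv = np.asarray(y, dtype=float)
    if x.ndim != 2:
        raise ValueError("design must be 2-D")
    n, p = x.shape
    if labels is None:
        labels = tuple(f"x{j}" for j in range(p))
    labels = tuple(labels)
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} observations for {p} columns")

    # QR solves the system; pivoted QR localizes any rank deficiency
    qm, rm = np.linalg.qr(x, mode="reduced")
    diag = np.abs(np.diag(rm))
    tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    if np.any(diag <= tol):
        from scipy.linalg import qr as scipy_qr

        _, rp, piv = scipy_qr(x, mode="economic", pivoting=True)
        dp = np.abs(np.diag(rp))
        bad = piv[dp <= max(n, p) * np.finfo(float).eps * dp.max()]
        raise CollinearityError(
            "rank-deficient design; offending columns: "
            + ", ".join(labels[j] for j in sorted(bad))
        )

    beta = np.linalg.solve(rm, qm.T @ yv)
    resid = yv - x @ beta
    rinv = np.linalg.inv(rm)
    xtx_inv = rinv @ rinv.T
    hat = np.einsum("ij,ij->i", qm, qm)
    df_resid = n - p
    sigma2 = float(resid @ resid) / df_resid
    cov_naive = sigma2 * xtx_inv
    return OLSFit(
        beta=beta,
        residuals=resid,
        hat=hat,
        cov_naive=cov_naive,
        sigma2=sigma2,
        labels=labels,
        design=x,
        xtx_inv=xtx_inv,
        df_resid=df_resid,
    )


def hc_covariance(fit: OLSFit, flavor: str) -> np.ndarray:
    """Heteroscedasticity-consistent coefficient covariance (HC0 or HC3)."""
    if flavor not in ("hc0", "hc3"):
        raise ValueError(f"flavor must be 'hc0' or 'hc3', got {flavor!r}")
    w = fit.residuals**2
    if flavor == "hc3":
        one_minus_h = 1.0 - fit.hat
        if np.any(one_minus_h <= np.finfo(float).eps ** 0.5):
            raise UndefinedHC3Error("unit-leverage observation: HC3 undefined")
        w = w / one_minus_h**2
    meat = (fit.design * w[:, None]).T @ fit.design
    return fit.xtx_inv @ meat @ fit.xtx_inv


def _binarize_median(z: np.ndarray) -> np.ndarray:
    # 0 for values strictly below the median, 1 otherwise (ties go to 1)
    return (z >= np.median(z)).astype(float)


def _wald_p(beta: float, se2: float, df_resid: int, use_t: bool) -> tuple[float, float]:
    wald = beta * beta / se2
    if use_t:
        p = 2.0 * stats.t.sf(np.sqrt(wald), df_resid)
    else:
        p = stats.chi2.sf(wald, 1)
    return wald, max(float(p), _P_FLOOR)


def test_interaction(
    y: np.ndarray,
    g: np.ndarray,
    z: np.ndarray,
    strategy: str = "std",
    apply_rkt: bool = False,
    use_t: bool = False,
) -> InteractionResult:
    """Test the G-by-Z interaction under one of the five strategies."""
    strategy = strategy.lower()
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}, got {strategy!r}")
    yv = np.asarray(y, dtype=float)
    gv = np.asarray(g, dtype=float)
    zv = np.asarray(z, dtype=float)
    if not (yv.shape == gv.shape == zv.shape) or yv.ndim != 1:
        raise ValueError("y, g, z must be 1-D vectors of equal length")
    if np.unique(gv).size < 2:
        raise UntestableVariantError("monomorphic genotype vector")
    if np.all(zv == zv[0]):
        raise DegenerateExposureError("constant exposure vector")
    if apply_rkt:
        yv = rank_inverse_normal(yv)

    n = yv.shape[0]
    ones = np.ones(n)
    dropped: tuple[str, ...] = ()

    if strategy in ("std", "hc0", "hc3"):
        x = np.column_stack([ones, gv, zv, gv * zv])
        labels = ("const", "G", "Z", "G:Z")
        term = 3
    elif strategy == "bin":
        zb = _binarize_median(zv)
        if np.all(zb == zb[0]):
            raise DegenerateExposureError("median split produced a constant indicator")
        x = np.column_stack([ones, gv, zb, gv * zb])
        labels = ("const", "G", "Zbin", "G:Zbin")
        term = 3
    else:  # sat
        cols = [ones]
        labels_l = ["const"]
        for level in (1, 2):
            d = (gv == level).astype(float)
            if d.any():
                cols.append(d)
                labels_l.append(f"G{level}")
            else:
                dropped = dropped + (f"G{level}",)
        cols.extend([zv, zv * zv, gv * zv])
        labels_l.extend(["Z", "Z2", "G:Z"])
        x = np.column_stack(cols)
        labels = tuple(labels_l)
        term = len(labels) - 1

    fit = fit_ols(x, yv, labels)
    if strategy in ("hc0", "hc3"):
        cov = hc_covariance(fit, strategy)
    else:
        cov = fit.cov_naive
    se2 = float(cov[term, term])
    beta = float(fit.beta[term])
    wald, p = _wald_p(beta, se2, fit.df_resid, use_t)
    return InteractionResult(
        strategy=strategy,
        transform_applied=apply_rkt,
        beta_gz=beta,
        se_gz=float(np.sqrt(se2)),
        wald=wald,
        p=p,
        df_resid=fit.df_resid,
        dropped_columns=dropped,
    )


class DegeneratePredictorError(DegenerateExposureError):
    """Predictor in a marginal test is constant."""


def marginal_test(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Simple-regression slope test: returns ``(beta, r2, p)``.

    The p-value is the F(1, n-2) tail of ``r2*(n-2)/(1-r2)``, identical to
    the two-sided t test of the slope.
    """
    yv = np.asarray(y, dtype=float)
    xv = np.asarray(x, dtype=float)
    n = yv.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise DegeneratePredictorError("constant predictor")
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    beta = sxy / sxx
    if syy == 0.0:
        return beta, 0.0, 1.0
    r2 = (sxy * sxy) / (sxx * syy)
    if r2 >= 1.0:
        return beta, 1.0, 0.0
    f = r2 * (n - 2) / (1.0 - r2)
    p = float(stats.f.sf(f, 1, n - 2))
    return beta, r2, p


# ---------------------------------------------------------------------------
# Batched fitting for simulation loops (replicates x samples matrices)
# ---------------------------------------------------------------------------


def batch_ols(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched least squares: ``x`` (r, n, p), ``y`` (r, n).

    Returns ``(beta, resid, xtx_inv)`` with shapes (r, p), (r, n), (r, p, p).
    Caller must have removed rank-deficient replicates.
    """
    xt = x.transpose(0, 2, 1)
    xtx = xt @ x
    xty = np.einsum("rnp,rn->rp", x, y)
    beta = np.linalg.solve(xtx, xty[..., None])[..., 0]
    resid = y - np.einsum("rnp,rp->rn", x, beta)
    xtx_inv = np.linalg.inv(xtx)
    return beta, resid, xtx_inv


def _batch_wald(
    x: np.ndarray, y: np.ndarray, term: int, cov: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Wald test of one design column across a replicate batch.

    ``x``: (r, n, p) stacked designs; ``y``: (r, n).  Returns
    ``(beta, se2, p)`` each of shape (r,).  Caller must have removed
    rank-deficient replicates.
    """
    r, n, p = x.shape
    beta, resid, xtx_inv = batch_ols(x, y)
    if cov == "naive":
        sigma2 = np.einsum("rn,rn->r", resid, resid) / (n - p)
        se2 = sigma2 * xtx_inv[:, term, term]
    else:
        w = resid**2
        if cov == "hc3":
            a = np.einsum("rpq,rnq->rnp", xtx_inv, x)
            h = np.einsum("rnp,rnp->rn", a, x)
            w = w / (1.0 - h) ** 2
        meat = np.einsum("rnp,rn,rnq->rpq", x, w, x)
        cov_mat = xtx_inv @ meat @ xtx_inv
        se2 = cov_mat[:, term, term]
    wald = beta[:, term] ** 2 / se2
    pvals = np.maximum(stats.chi2.sf(wald, 1), _P_FLOOR)
    return beta[:, term], se2, pvals


def interaction_pvalues_batch(
    y: np.ndarray,
    g: np.ndarray,
    z: np.ndarray,
    strategy: str = "std",
    chunk: int = 4000,
) -> np.ndarray:
    """Interaction p-values for a batch of replicates (rows).

    ``y``, ``g``, ``z`` are (replicates, n) arrays; ``g`` may be raw or
    standardized dosage for std/hc0/hc3/bin but must be raw 0/1/2 for sat.
    Replicates with a monomorphic genotype (or, for sat, a genotype support
    that leaves the interaction column collinear) get ``nan``.
    """
    strategy = strategy.lower()
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}, got {strategy!r}")
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    z = np.asarray(z, dtype=float)
    r, n = y.shape
    out = np.full(r, np.nan)

    poly = g.min(axis=1) != g.max(axis=1)  # polymorphic replicates

    for start in range(0, r, chunk):
        sl = slice(start, min(start + chunk, r))
        ys, gs, zs = y[sl], g[sl], z[sl]
        ok = poly[sl]
        if not ok.any():
            continue
        idx = np.nonzero(ok)[0]
        ysub, gsub, zsub = ys[idx], gs[idx], zs[idx]
        k = ysub.shape[0]
        ones = np.ones((k, n))
        if strategy in ("std", "hc0", "hc3"):
            x = np.stack([ones, gsub, zsub, gsub * zsub], axis=2)
            cov = "naive" if strategy == "std" else strategy
            _, _, pv = _batch_wald(x, ysub, 3, cov)
        elif strategy == "bin":
            med = np.median(zsub, axis=1, keepdims=True)
            zb = (zsub >= med).astype(float)
            x = np.stack([ones, gsub, zb, gsub * zb], axis=2)
            _, _, pv = _batch_wald(x, ysub, 3, "naive")
        else:  # sat: split the chunk by genotype support so designs stay full rank
            pv = np.full(k, np.nan)
            has1 = (gsub == 1).any(axis=1)
            has2 = (gsub == 2).any(axis=1)
            has0 = (gsub == 0).any(axis=1)
            for mask, dummies in (
                (has1 & has2 & has0, (1, 2)),
                (has1 & ~has2, (1,)),
                (has2 & ~has1 & has0, (2,)),
                (has1 & has2 & ~has0, (1,)),  # G in {1,2}: one dummy is redundant
            ):
                m = np.nonzero(mask)[0]
                if m.size == 0:
                    continue
                gm, zm, ym = gsub[m], zsub[m], ysub[m]
                cols = [np.ones((m.size, n))]
                cols += [(gm == lvl).astype(float) for lvl in dummies]
                cols += [zm, zm * zm, gm * zm]
                x = np.stack(cols, axis=2)
                _, _, pvm = _batch_wald(x, ym, x.shape[2] - 1, "naive")
                pv[m] = pvm
        out[np.arange(r)[sl][idx]] = pv
    return out


def marginal_r2_batch(y: np.ndarray, x_mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized simple-regression r2 and p of one outcome against many predictors.

    ``y``: (n,); ``x_mat``: (n, m).  Constant predictor columns get r2=0, p=1.
    """
    yv = np.asarray(y, dtype=float)
    x = np.asarray(x_mat, dtype=float)
    n = yv.shape[0]
    yc = yv - yv.mean()
    xc = x - x.mean(axis=0, keepdims=True)
    sxx = np.einsum("nm,nm->m", xc, xc)
    syy = float(yc @ yc)
    sxy = yc @ xc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where((sxx > 0) & (syy > 0), sxy**2 / (sxx * syy), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        f = r2 * (n - 2) / (1.0 - r2)
    p = stats.f.sf(f, 1, n - 2)
    p = np.where(r2 >= 1.0, 0.0, p)
    p = np.where(sxx > 0, p, 1.0)
    return r2, p
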