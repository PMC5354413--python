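"""Two-step SNP x TF x target trio screening on genotype/expression matrices.

Step 1 maps cis-eQTLs: every SNP within a window (default 250 kb) of a probe
is tested for marginal association, p-values are Benjamini-Hochberg adjusted
across all tested pairs, pairs with q <= 0.01 are kept, and the single most
significant SNP is retained per probe.  Step 2 pairs each retained
(SNP, target) hit with candidate transcription-factor probes -- those whose
expression is nominally associated with the target (p < 0.05) and whose
genomic position is more than an exclusion distance (default 10 Mb) from the
SNP or on another chromosome, to avoid shared-cis confounding -- and tests
the SNP-by-TF interaction on the target's expression under four strategies:
standard OLS (std), HC3 sandwich (h3), and both repeated on rank-inverse-
normal-transformed expression (rkt, rkt.h3).

A synthetic dataset generator plants cis main effects, SNP-by-TF
interactions, and interactions with *unmeasured* factors (the mechanism that
inflates the standard test), recording ground truth for power/calibration
checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .inttests import interaction_pvalues_batch, marginal_r2_batch
from .simgen import standardize_dosage
from .transforms import rank_inverse_normal

__all__ = [
    "ScreeningDataset",
    "EqtlHit",
    "Trio",
    "TrioResult",
    "generate_screening_dataset",
    "select_cis_eqtls",
    "build_trios",
    "screen_trios",
    "stratified_lambda",
    "results_to_frame",
    "SCREEN_STRATEGIES",
]

SCREEN_STRATEGIES = ("std", "h3", "rkt", "rkt_h3")

DEFAULT_CIS_WINDOW = 250_000
DEFAULT_Q_MAX = 0.01
DEFAULT_TF_P_MAX = 0.05
DEFAULT_EXCLUSION = 10_000_000
DEFAULT_SIG_THRESHOLD = 1e-8


@dataclass
class ScreeningDataset:
    """Aligned genotype/expression matrices with genomic annotation.

    ``genotypes``: samples x SNPs dosage (0/1/2) DataFrame;
    ``expression``: samples x probes DataFrame; annotation tables give one
    representative coordinate per feature, and ``probe_annot.is_tf`` flags
    transcription-factor probes.  ``truth`` records planted effects.
    """

    genotypes: pd.DataFrame
    expression: pd.DataFrame
    snp_annot: pd.DataFrame
    probe_annot: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genotypes.index.equals(self.expression.index):
            raise ValueError("sample axes of genotype and expression matrices differ")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]


@dataclass(frozen=True)
class EqtlHit:
    probe: str
    snp: str
    p: float
    q: float
    r2: float


@dataclass(frozen=True)
class Trio:
    snp: str
    target: str
    tf: str
    tf_marginal_p: float


@dataclass
class TrioResult:
    snp: str
    target: str
    tf: str
    tf_marginal_p: float
    p: dict[str, float] = field(default_factory=dict)
    rank: dict[str, int] = field(default_factory=dict)
    significant: dict[str, bool] = field(default_factory=dict)


def generate_screening_dataset(
    n_samples: int = 1000,
    n_snps: int = 300,
    n_probes: int = 400,
    n_tfs: int = 200,
    cis_fraction: float = 0.5,
    cis_tau_range: tuple[float, float] = (0.3, 0.8),
    interaction_fraction: float = 0.0,
    interaction_tau_range: tuple[float, float] = (0.1, 0.3),
    hidden_interaction_fraction: float = 0.0,
    hidden_interaction_tau: float = 0.25,
    tf_main_tau: float = 0.1,
    seed: int = 0,
    n_chromosomes: int = 22,
    chrom_length: int = 100_000_000,
    cis_offset_max: int = 100_000,
) -> ScreeningDataset:
    """Simulate a genotype + expression dataset with planted structure.

    The first ``n_tfs`` probes are transcription factors with independent
    standard-normal expression; the remainder are targets.  A fraction
    ``cis_fraction`` of targets receives a dedicated cis SNP (placed within
    ``cis_offset_max`` of the probe) whose standardized dosage explains a
    U(cis_tau_range) fraction of the target's variance -- magnitudes chosen
    to emulate the large (r2 >= 30%) marginal effects seen for cis-eQTLs on
    expression.  Of those cis targets, ``interaction_fraction`` also carry a
    SNP-by-TF interaction with a measured TF (plus a TF main effect of
    ``tf_main_tau`` so the TF passes the marginal filter), and
    ``hidden_interaction_fraction`` carry a SNP-by-U interaction with an
    *unmeasured* factor U plus main effects of a few measured TFs (these
    targets are where standard interaction screening inflates).  Remaining
    SNPs are placed uniformly at random; per-SNP coded-allele frequencies
    are U(0.05, 0.5) under Hardy-Weinberg equilibrium.
    """
    if min(n_samples, n_snps, n_probes) < 1 or n_tfs >= n_probes:
        raise ValueError("need positive dimensions and n_tfs < n_probes")
    for name, frac in (
        ("cis_fraction", cis_fraction),
        ("interaction_fraction", interaction_fraction),
        ("hidden_interaction_fraction", hidden_interaction_fraction),
    ):
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)

    snp_ids = [f"snp{i}" for i in range(n_snps)]
    tf_ids = [f"tf{i}" for i in range(n_tfs)]
    target_ids = [f"gene{i}" for i in range(n_probes - n_tfs)]
    probe_ids = tf_ids + target_ids

    probe_chrom = rng.integers(1, n_chromosomes + 1, size=n_probes)
    probe_pos = rng.integers(1, chrom_length + 1, size=n_probes)
    probe_annot = pd.DataFrame(
        {
            "id": probe_ids,
            "chrom": probe_chrom,
            "pos": probe_pos,
            "is_tf": [True] * n_tfs + [False] * len(target_ids),
        }
    ).set_index("id")

    # choose cis targets and co-locate a SNP with each
    n_targets = len(target_ids)
    n_cis = int(round(cis_fraction * n_targets))
    n_cis = min(n_cis, n_snps)
    cis_targets = list(rng.choice(target_ids, size=n_cis, replace=False))
    snp_chrom = rng.integers(1, n_chromosomes + 1, size=n_snps)
    snp_pos = rng.integers(1, chrom_length + 1, size=n_snps)
    for j, tgt in enumerate(cis_targets):
        t_chrom = probe_annot.at[tgt, "chrom"]
        t_pos = int(probe_annot.at[tgt, "pos"])
        snp_chrom[j] = t_chrom
        offset = int(rng.integers(-cis_offset_max, cis_offset_max + 1))
        snp_pos[j] = int(np.clip(t_pos + offset, 1, chrom_length))
    snp_annot = pd.DataFrame(
        {"id": snp_ids, "chrom": snp_chrom, "pos": snp_pos}
    ).set_index("id")

    cafs = rng.uniform(0.05, 0.5, size=n_snps)
    geno = rng.binomial(2, cafs[None, :], size=(n_samples, n_snps)).astype(np.int64)
    g_std = standardize_dosage(geno, cafs[None, :])

    tf_expr = rng.standard_normal((n_samples, n_tfs))

    # planted roles among cis targets
    n_int = int(round(interaction_fraction * n_cis))
    n_hidden = int(round(hidden_interaction_fraction * n_cis))
    roles = np.array(["plain"] * n_cis, dtype=object)
    order = rng.permutation(n_cis)
    roles[order[:n_int]] = "interaction"
    roles[order[n_int : n_int + n_hidden]] = "hidden"

    target_expr = np.empty((n_samples, n_targets))
    truth: dict = {"cis": [], "interactions": [], "hidden": []}
    tgt_index = {t: i for i, t in enumerate(target_ids)}

    def _eligible_tfs(snp_idx: int) -> np.ndarray:
        # TFs outside the exclusion zone of the SNP (so planted trios survive)
        s_chrom = snp_chrom[snp_idx]
        s_pos = snp_pos[snp_idx]
        tf_chrom = probe_chrom[:n_tfs]
        tf_pos = probe_pos[:n_tfs]
        far = (tf_chrom != s_chrom) | (
            np.abs(tf_pos.astype(np.int64) - s_pos) > DEFAULT_EXCLUSION
        )
        return np.nonzero(far)[0]

    cis_index = {t: j for j, t in enumerate(cis_targets)}
    for i, tgt in enumerate(target_ids):
        # collect (unit-variance component, variance fraction) pairs, then
        # rescale proportionally if the planted budget would exceed 0.9 so
        # the residual variance stays positive; realized fractions go into
        # the truth ledger
        parts: list[tuple[np.ndarray, float]] = []
        records: list[tuple[str, dict]] = []
        if tgt in cis_index:
            j = cis_index[tgt]
            tau_cis = float(rng.uniform(*cis_tau_range))
            parts.append((g_std[:, j], tau_cis))
            rec_cis = {"snp": snp_ids[j], "probe": tgt, "tau": tau_cis}
            records.append(("cis", rec_cis))
            role = roles[j]
            if role == "interaction":
                elig = _eligible_tfs(j)
                k = int(rng.choice(elig))
                tau_ge = float(rng.uniform(*interaction_tau_range))
                parts.append((tf_expr[:, k], tf_main_tau))
                parts.append((g_std[:, j] * tf_expr[:, k], tau_ge))
                records.append(
                    (
                        "interactions",
                        {"snp": snp_ids[j], "probe": tgt, "tf": tf_ids[k], "tau": tau_ge},
                    )
                )
            elif role == "hidden":
                u = rng.standard_normal(n_samples)
                parts.append((g_std[:, j] * u, hidden_interaction_tau))
                elig = _eligible_tfs(j)
                ks = rng.choice(elig, size=min(3, elig.size), replace=False)
                for k in ks:
                    parts.append((tf_expr[:, int(k)], tf_main_tau))
                records.append(
                    (
                        "hidden",
                        {
                            "snp": snp_ids[j],
                            "probe": tgt,
                            "tau": hidden_interaction_tau,
                            "assoc_tfs": [tf_ids[int(k)] for k in ks],
                        },
                    )
                )
        tau_used = sum(t for _, t in parts)
        scale = 1.0
        if tau_used > 0.9:
            scale = 0.9 / tau_used
            tau_used = 0.9
        comps = np.zeros(n_samples)
        for vec, tau in parts:
            comps = comps + np.sqrt(tau * scale) * vec
        for kind, rec in records:
            rec["tau"] *= scale
            truth[kind].append(rec)
        eps = rng.standard_normal(n_samples) * np.sqrt(1.0 - tau_used)
        target_expr[:, i] = comps + eps

    sample_ids = [f"s{i}" for i in range(n_samples)]
    genotypes = pd.DataFrame(geno, index=sample_ids, columns=snp_ids)
    expression = pd.DataFrame(
        np.hstack([tf_expr, target_expr]), index=sample_ids, columns=probe_ids
    )
    return ScreeningDataset(
        genotypes=genotypes,
        expression=expression,
        snp_annot=snp_annot,
        probe_annot=probe_annot,
        truth=truth,
    )


def select_cis_eqtls(
    ds: ScreeningDataset,
    window: int = DEFAULT_CIS_WINDOW,
    q_max: float = DEFAULT_Q_MAX,
) -> list[EqtlHit]:
    """Step 1: cis association scan, BH adjustment, top SNP per probe.

    Tests every SNP-probe pair on the same chromosome with
    ``|SNP pos - probe pos| <= window`` (inclusive), adjusts across all
    tested pairs, keeps q <= ``q_max`` and returns one hit per probe (the
    smallest p, ties broken by SNP id).
    """
    snp_chrom = ds.snp_annot["chrom"].to_numpy()
    snp_pos = ds.snp_annot["pos"].to_numpy(dtype=np.int64)
    snp_ids = np.asarray(ds.snp_annot.index)
    geno = ds.genotypes.to_numpy(dtype=float)

    records: list[tuple[str, str, float, float]] = []  # probe, snp, p, r2
    for probe, row in ds.probe_annot.iterrows():
        near = (snp_chrom == row["chrom"]) & (
            np.abs(snp_pos - int(row["pos"])) <= window
        )
        if not near.any():
            continue
        idx = np.nonzero(near)[0]
        y = ds.expression[probe].to_numpy(dtype=float)
        r2, p = marginal_r2_batch(y, geno[:, idx])
        for j, pj, r2j in zip(idx, p, r2):
            records.append((str(probe), str(snp_ids[j]), float(pj), float(r2j)))

    if not records:
        warnings.warn("no cis SNP-probe pairs within the window", stacklevel=2)
        return []

    pvals = np.array([r[2] for r in records])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    best: dict[str, EqtlHit] = {}
    for (probe, snp, p, r2), q in zip(records, qvals):
        if q > q_max:
            continue
        cur = best.get(probe)
        if cur is None or (p, snp) < (cur.p, cur.snp):
            best[probe] = EqtlHit(probe=probe, snp=snp, p=p, q=float(q), r2=r2)
    return [best[k] for k in sorted(best)]


def build_trios(
    ds: ScreeningDataset,
    hits: list[EqtlHit],
    tf_marginal_p_max: float = DEFAULT_TF_P_MAX,
    exclusion_distance: int = DEFAULT_EXCLUSION,
) -> list[Trio]:
    """Step 2 candidate construction: pair each hit with admissible TFs.

    A TF probe qualifies for a (SNP, target) hit when its marginal
    association with the target is nominally significant
    (p < ``tf_marginal_p_max``) and it lies farther than
    ``exclusion_distance`` from the SNP (or on another chromosome), to avoid
    a shared cis effect masquerading as interaction.  The target probe
    itself never serves as its own TF.
    """
    tf_annot = ds.probe_annot[ds.probe_annot["is_tf"]]
    tf_ids = np.asarray(tf_annot.index)
    tf_chrom = tf_annot["chrom"].to_numpy()
    tf_pos = tf_annot["pos"].to_numpy(dtype=np.int64)
    tf_expr = ds.expression[list(tf_ids)].to_numpy(dtype=float)

    trios: list[Trio] = []
    for hit in hits:
        s_chrom = ds.snp_annot.at[hit.snp, "chrom"]
        s_pos = int(ds.snp_annot.at[hit.snp, "pos"])
        far = (tf_chrom != s_chrom) | (np.abs(tf_pos - s_pos) > exclusion_distance)
        not_self = tf_ids != hit.probe
        y = ds.expression[hit.probe].to_numpy(dtype=float)
        _, p_marg = marginal_r2_batch(y, tf_expr)
        keep = far & not_self & (p_marg < tf_marginal_p_max)
        for k in np.nonzero(keep)[0]:
            trios.append(
                Trio(
                    snp=hit.snp,
                    target=hit.probe,
                    tf=str(tf_ids[k]),
                    tf_marginal_p=float(p_marg[k]),
                )
            )
    return trios


def screen_trios(
    ds: ScreeningDataset,
    trios: list[Trio],
    sig_threshold: float = DEFAULT_SIG_THRESHOLD,
    chunk: int = 2000,
) -> list[TrioResult]:
    """Step 2 testing: four interaction p-values and ranks per trio.

    Strategies: std (OLS Wald), h3 (HC3 sandwich), and both on the
    rank-inverse-normal-transformed target (rkt, rkt_h3).  Trios whose SNP
    is monomorphic in the analyzed samples are skipped (dropped) with a
    warning.  Ranks are 1..#trios per strategy, ascending p, ties broken by
    (snp, target, tf) identity; significance is flagged at
    p < ``sig_threshold``.
    """
    if not trios:
        raise ValueError("empty trio list")
    n = ds.n_samples

    y_raw_cache: dict[str, np.ndarray] = {}
    y_rkt_cache: dict[str, np.ndarray] = {}
    for t in trios:
        if t.target not in y_raw_cache:
            y = ds.expression[t.target].to_numpy(dtype=float)
            y_raw_cache[t.target] = y
            y_rkt_cache[t.target] = rank_inverse_normal(y)

    results: list[TrioResult] = []
    dropped = 0
    kept_idx: list[int] = []
    g_rows, z_rows, yraw_rows, yrkt_rows = [], [], [], []
    for i, t in enumerate(trios):
        g = ds.genotypes[t.snp].to_numpy(dtype=float)
        if g.min() == g.max():
            dropped += 1
            continue
        kept_idx.append(i)
        g_rows.append(g)
        z_rows.append(ds.expression[t.tf].to_numpy(dtype=float))
        yraw_rows.append(y_raw_cache[t.target])
        yrkt_rows.append(y_rkt_cache[t.target])
    if dropped:
        warnings.warn(f"skipped {dropped} trios with monomorphic SNPs", stacklevel=2)
    if not kept_idx:
        raise ValueError("no testable trios (all SNPs monomorphic)")

    m = len(kept_idx)
    pmat = {s: np.empty(m) for s in SCREEN_STRATEGIES}
    for start in range(0, m, chunk):
        sl = slice(start, min(start + chunk, m))
        g = np.asarray(g_rows[sl.start : sl.stop])
        z = np.asarray(z_rows[sl.start : sl.stop])
        y0 = np.asarray(yraw_rows[sl.start : sl.stop])
        y1 = np.asarray(yrkt_rows[sl.start : sl.stop])
        pmat["std"][sl] = interaction_pvalues_batch(y0, g, z, strategy="std")
        pmat["h3"][sl] = interaction_pvalues_batch(y0, g, z, strategy="hc3")
        pmat["rkt"][sl] = interaction_pvalues_batch(y1, g, z, strategy="std")
        pmat["rkt_h3"][sl] = interaction_pvalues_batch(y1, g, z, strategy="hc3")

    ids = [(trios[i].snp, trios[i].target, trios[i].tf) for i in kept_idx]
    ranks = {}
    for s in SCREEN_STRATEGIES:
        order = sorted(range(m), key=lambda j: (pmat[s][j], ids[j]))
        rk = np.empty(m, dtype=int)
        rk[order] = np.arange(1, m + 1)
        ranks[s] = rk

    for j, i in enumerate(kept_idx):
        t = trios[i]
        results.append(
            TrioResult(
                snp=t.snp,
                target=t.target,
                tf=t.tf,
                tf_marginal_p=t.tf_marginal_p,
                p={s: float(pmat[s][j]) for s in SCREEN_STRATEGIES},
                rank={s: int(ranks[s][j]) for s in SCREEN_STRATEGIES},
                significant={
                    s: bool(pmat[s][j] < sig_threshold) for s in SCREEN_STRATEGIES
                },
            )
        )
    return results


def stratified_lambda(
    results: list[TrioResult],
    strata_edges: list[float] | np.ndarray,
    min_stratum: int = 100,
) -> pd.DataFrame:
    """Inflation factor per TF-marginal-p stratum per strategy.

    ``strata_edges`` are bin edges over (0, 1] for the TF-target marginal
    p-value; each row reports one stratum x strategy with its test count and
    a reliability flag (strata under ``min_stratum`` tests are flagged).
    """
    from .evalmetrics import lambda_gc

    if not results:
        raise ValueError("empty result list")
    edges = np.asarray(strata_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("strata_edges must be increasing with >= 2 values")
    pm = np.array([r.tf_marginal_p for r in results])
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (pm > lo) & (pm <= hi) if lo > 0 else (pm >= lo) & (pm <= hi)
        cnt = int(mask.sum())
        for s in SCREEN_STRATEGIES:
            if cnt == 0:
                lam = np.nan
            else:
                pv = np.array([r.p[s] for (r, m) in zip(results, mask) if m])
                lam = lambda_gc(np.clip(pv, 1e-300, 1.0))
            rows.append(
                {
                    "stratum_lo": lo,
                    "stratum_hi": hi,
                    "strategy": s,
                    "lambda_gc": lam,
                    "n_tests": cnt,
                    "reliable": cnt >= min_stratum,
                }
            )
    return pd.DataFrame(rows)


def results_to_frame(results: list[TrioResult]) -> pd.DataFrame:
    """Tidy trio-result table (one row per trio)."""
    rows = []
    for r in results:
        row = {
            "snp": r.snp,
            "target": r.target,
            "tf": r.tf,
            "tf_marginal_p": r.tf_marginal_p,
        }
        for s in SCREEN_STRATEGIES:
            row[f"p_{s}"] = r.p[s]
            row[f"rank_{s}"] = r.rank[s]
            row[f"sig_{s}"] = r.significant[s]
        rows.append(row)
    return pd.DataFrame(rows)
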