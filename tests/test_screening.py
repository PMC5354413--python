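"""Two-step trio screening: dataset generator, filters, testing, stratification."""

import numpy as np
import pandas as pd
import pytest

from interscreen import screening as scr
from interscreen.evalmetrics import lambda_gc


def _tiny_dataset():
    """Hand-built dataset with known geometry for filter checks.

    Probes: geneA (chr1:1,000,000, target), tf0 (chr1:4,000,000, within the
    10 Mb exclusion of snps on chr1), tf1 (chr2:50,000,000, far), tf2
    (chr1:80,000,000, >10 Mb away on the same chromosome).
    SNPs: snpA (chr1:1,100,000, cis to geneA at 100 kb), snpB
    (chr2:10,000,000, distal to geneA).
    """
    rng = np.random.default_rng(5)
    n = 400
    g_a = rng.binomial(2, 0.4, n).astype(np.int64)
    g_b = rng.binomial(2, 0.4, n).astype(np.int64)
    tf0 = rng.standard_normal(n)
    tf1 = rng.standard_normal(n)
    tf2 = rng.standard_normal(n)
    g_std = (g_a - g_a.mean()) / g_a.std()
    # strong cis effect of snpA; tf1 associated with geneA, tf2 not
    gene_a = 0.7 * g_std + 0.4 * tf1 + rng.standard_normal(n) * 0.6
    samples = [f"s{i}" for i in range(n)]
    genotypes = pd.DataFrame({"snpA": g_a, "snpB": g_b}, index=samples)
    expression = pd.DataFrame(
        {"tf0": tf0, "tf1": tf1, "tf2": tf2, "geneA": gene_a}, index=samples
    )
    snp_annot = pd.DataFrame(
        {"id": ["snpA", "snpB"], "chrom": [1, 2], "pos": [1_100_000, 10_000_000]}
    ).set_index("id")
    probe_annot = pd.DataFrame(
        {
            "id": ["tf0", "tf1", "tf2", "geneA"],
            "chrom": [1, 2, 1, 1],
            "pos": [4_000_000, 50_000_000, 80_000_000, 1_000_000],
            "is_tf": [True, True, True, False],
        }
    ).set_index("id")
    return scr.ScreeningDataset(
        genotypes=genotypes,
        expression=expression,
        snp_annot=snp_annot,
        probe_annot=probe_annot,
    )


class TestGenerator:
    def test_replay_identical(self):
        kw = dict(n_samples=100, n_snps=30, n_probes=40, n_tfs=20, seed=3)
        a = scr.generate_screening_dataset(**kw)
        b = scr.generate_screening_dataset(**kw)
        assert a.genotypes.equals(b.genotypes)
        assert a.expression.equals(b.expression)
        assert a.snp_annot.equals(b.snp_annot)

    def test_truth_ledger_records_planted_effects(self):
        ds = scr.generate_screening_dataset(
            n_samples=200, n_snps=50, n_probes=60, n_tfs=30,
            cis_fraction=0.5, interaction_fraction=0.4, seed=1,
        )
        assert len(ds.truth["cis"]) == 15
        assert len(ds.truth["interactions"]) == 6
        for rec in ds.truth["interactions"]:
            assert rec["tf"].startswith("tf")

    def test_dimension_validation(self):
        with pytest.raises(ValueError):
            scr.generate_screening_dataset(n_probes=10, n_tfs=10)
        with pytest.raises(ValueError):
            scr.generate_screening_dataset(cis_fraction=1.5)

    def test_misaligned_samples_rejected(self):
        ds = scr.generate_screening_dataset(
            n_samples=50, n_snps=10, n_probes=12, n_tfs=5, seed=0
        )
        with pytest.raises(ValueError):
            scr.ScreeningDataset(
                genotypes=ds.genotypes.iloc[:40],
                expression=ds.expression,
                snp_annot=ds.snp_annot,
                probe_annot=ds.probe_annot,
            )


class TestCisSelection:
    def test_planted_cis_effects_recovered(self):
        ds = scr.generate_screening_dataset(
            n_samples=500, n_snps=60, n_probes=80, n_tfs=30,
            cis_fraction=0.5, cis_tau_range=(0.5, 0.5), seed=21,
        )
        hits = scr.select_cis_eqtls(ds)
        found = {(h.snp, h.probe) for h in hits}
        planted = {(r["snp"], r["probe"]) for r in ds.truth["cis"]}
        assert planted <= found

    def test_global_null_yields_essentially_no_hits(self):
        ds = scr.generate_screening_dataset(
            n_samples=300, n_snps=100, n_probes=120, n_tfs=40,
            cis_fraction=0.0, seed=30,
        )
        hits = scr.select_cis_eqtls(ds)
        assert len(hits) <= 1  # BH at q<=0.01 controls false discoveries

    def test_top_snp_per_probe_rule(self):
        ds = _tiny_dataset()
        # add a second, weaker cis SNP for geneA
        rng = np.random.default_rng(9)
        weak = rng.binomial(2, 0.4, ds.n_samples).astype(np.int64)
        ds.genotypes["snpC"] = weak
        ds.snp_annot.loc["snpC"] = {"chrom": 1, "pos": 1_050_000}
        hits = scr.select_cis_eqtls(ds)
        gene_hits = [h for h in hits if h.probe == "geneA"]
        assert len(gene_hits) == 1
        assert gene_hits[0].snp == "snpA"

    def test_zero_window_restricts_to_colocated(self):
        ds = _tiny_dataset()
        with pytest.warns(UserWarning):
            hits = scr.select_cis_eqtls(ds, window=0)
        assert hits == []


class TestTrioFilters:
    def test_exclusion_and_marginal_filters(self):
        ds = _tiny_dataset()
        hits = scr.select_cis_eqtls(ds)
        trios = scr.build_trios(ds, hits)
        pairs = {(t.snp, t.tf) for t in trios if t.target == "geneA"}
        # tf0 is 2.9 Mb from snpA on chr1 -> excluded; tf2 unassociated -> excluded;
        # tf1 is on another chromosome and strongly associated -> included
        assert ("snpA", "tf1") in pairs
        assert ("snpA", "tf0") not in pairs
        assert ("snpA", "tf2") not in pairs

    def test_filters_match_bruteforce_oracle(self):
        ds = scr.generate_screening_dataset(
            n_samples=300, n_snps=40, n_probes=60, n_tfs=30,
            cis_fraction=0.6, cis_tau_range=(0.4, 0.7), seed=17,
        )
        window, qmax, tfp, excl = 250_000, 0.01, 0.05, 10_000_000
        hits = scr.select_cis_eqtls(ds, window=window, q_max=qmax)
        trios = scr.build_trios(ds, hits, tf_marginal_p_max=tfp,
                                exclusion_distance=excl)
        got = {(t.snp, t.target, t.tf) for t in trios}

        # exhaustive re-derivation with plain loops and scalar tests
        from interscreen.inttests import marginal_test

        want = set()
        for hit in hits:
            assert hit.q <= qmax
            sc = ds.snp_annot.at[hit.snp, "chrom"]
            sp = int(ds.snp_annot.at[hit.snp, "pos"])
            pc = ds.probe_annot.at[hit.probe, "chrom"]
            pp = int(ds.probe_annot.at[hit.probe, "pos"])
            assert sc == pc and abs(sp - pp) <= window  # cis rule
            y = ds.expression[hit.probe].to_numpy()
            for tf, row in ds.probe_annot[ds.probe_annot["is_tf"]].iterrows():
                if tf == hit.probe:
                    continue
                same_chrom = row["chrom"] == sc
                if same_chrom and abs(int(row["pos"]) - sp) <= excl:
                    continue
                _, _, p = marginal_test(y, ds.expression[tf].to_numpy())
                if p < tfp:
                    want.add((hit.snp, hit.probe, str(tf)))
        assert got == want


class TestScreenTrios:
    def test_ranks_are_permutations(self):
        ds = scr.generate_screening_dataset(
            n_samples=300, n_snps=60, n_probes=100, n_tfs=60,
            cis_fraction=0.6, seed=23,
        )
        hits = scr.select_cis_eqtls(ds)
        trios = scr.build_trios(ds, hits)
        res = scr.screen_trios(ds, trios)
        m = len(res)
        for s in scr.SCREEN_STRATEGIES:
            assert sorted(r.rank[s] for r in res) == list(range(1, m + 1))

    def test_monomorphic_snp_skipped_with_warning(self):
        ds = _tiny_dataset()
        hits = scr.select_cis_eqtls(ds)
        trios = scr.build_trios(ds, hits)
        ds.genotypes["snpA"] = 0  # degrade after selection
        with pytest.warns(UserWarning, match="monomorphic"):
            with pytest.raises(ValueError):
                scr.screen_trios(ds, [t for t in trios if t.snp == "snpA"])

    def test_planted_interaction_ranks_at_top(self):
        ds = scr.generate_screening_dataset(
            n_samples=1000, n_snps=150, n_probes=400, n_tfs=300,
            cis_fraction=0.8, interaction_fraction=0.03,
            interaction_tau_range=(0.2, 0.2), seed=31,
        )
        hits = scr.select_cis_eqtls(ds)
        trios = scr.build_trios(ds, hits)
        res = scr.screen_trios(ds, trios)
        m = len(res)
        idx = {(r.snp, r.target, r.tf): r for r in res}
        planted = [
            idx[(rec["snp"], rec["probe"], rec["tf"])]
            for rec in ds.truth["interactions"]
            if (rec["snp"], rec["probe"], rec["tf"]) in idx
        ]
        assert planted, "planted trios must survive the filters"
        top = max(1, int(0.01 * m))
        frac_top = np.mean([r.rank["h3"] <= top for r in planted])
        assert frac_top >= 0.95
        assert all(r.significant["h3"] for r in planted)

    def test_empty_trio_list_rejected(self):
        ds = _tiny_dataset()
        with pytest.raises(ValueError):
            scr.screen_trios(ds, [])


class TestStratifiedLambda:
    def _null_results(self, seed=41):
        ds = scr.generate_screening_dataset(
            n_samples=400, n_snps=80, n_probes=200, n_tfs=120,
            cis_fraction=0.8, seed=seed,
        )
        hits = scr.select_cis_eqtls(ds)
        trios = scr.build_trios(ds, hits)
        return scr.screen_trios(ds, trios)

    def test_single_stratum_equals_unstratified(self):
        res = self._null_results()
        table = scr.stratified_lambda(res, [0.0, 1.0])
        for s in scr.SCREEN_STRATEGIES:
            pv = np.array([r.p[s] for r in res])
            overall = lambda_gc(np.clip(pv, 1e-300, 1.0))
            row = table[(table["strategy"] == s)]
            assert row["lambda_gc"].iloc[0] == pytest.approx(overall, rel=1e-12)
            assert int(row["n_tests"].iloc[0]) == len(res)

    def test_small_strata_flagged_unreliable(self):
        res = self._null_results()
        table = scr.stratified_lambda(res, [0.0, 1e-30, 1.0])
        tiny = table[table["stratum_hi"] == 1e-30]
        assert not tiny["reliable"].any()

    def test_bad_edges_rejected(self):
        res = self._null_results()
        with pytest.raises(ValueError):
            scr.stratified_lambda(res, [0.5])
        with pytest.raises(ValueError):
            scr.stratified_lambda(res, [0.5, 0.1])


def test_results_frame_columns():
    ds = _tiny_dataset()
    hits = scr.select_cis_eqtls(ds)
    trios = scr.build_trios(ds, hits)
    res = scr.screen_trios(ds, trios)
    frame = scr.results_to_frame(res)
    assert {"snp", "target", "tf", "tf_marginal_p", "p_std", "p_h3",
            "p_rkt", "p_rkt_h3", "rank_std", "sig_h3"} <= set(frame.columns)
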