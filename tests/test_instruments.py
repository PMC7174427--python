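"""Clumping, loci, instrument strength, Steiger and exclusion filters."""

import numpy as np
import pytest

from causalmr import (
    LDMatrix,
    define_loci,
    exclude_pleiotropic,
    f_statistic,
    harmonize,
    i2_gx,
    ld_clump,
    merge_cross_trait_loci,
    simulate_two_sample,
    SimConfig,
    steiger_filter,
    variant_r2,
)
from causalmr.instruments import WEAK_F_THRESHOLD

from conftest import make_hset
from test_summary_stats import rec, table


def ld_from(ids, pairs):
    """Build an LDMatrix from sparse (i, j, r2) triples."""
    n = len(ids)
    idx = {v: i for i, v in enumerate(ids)}
    m = np.eye(n)
    for a, b, r2 in pairs:
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = r2
    return LDMatrix(list(ids), m)


def clump_oracle(records, ld, p_threshold, r2_max, window_bp):
    """Independent fixpoint characterization of the greedy lead set.

    In p-order (ties by chrom, pos, id), a candidate is a lead iff no
    already-accepted lead on the same chromosome within the window tags it
    at r2 >= r2_max. Checked by direct recursion, not by replaying the
    implementation's removal bookkeeping.
    """
    cands = sorted(
        (r for r in records if r.pval < p_threshold),
        key=lambda r: (r.pval, r.chrom, r.pos, r.variant_id),
    )
    leads = []

    def suppressed(r):
        return any(
            l.chrom == r.chrom
            and abs(l.pos - r.pos) <= window_bp
            and ld.lookup(l.variant_id, r.variant_id) >= r2_max
            for l in leads
        )

    for r in cands:
        if not suppressed(r):
            leads.append(r)
    return [l.variant_id for l in leads]


class TestClump:
    def test_dominant_lead_absorbs_linked_variant(self):
        t = table([rec("rs1", pos=100_000, pval=1e-12), rec("rs2", pos=110_000, pval=1e-9)])
        ld = ld_from(["rs1", "rs2"], [("rs1", "rs2", 1.0)])
        leads = ld_clump(t, ld)
        assert [l.variant_id for l in leads] == ["rs1"]

    def test_outside_window_both_lead(self):
        t = table([rec("rs1", pos=1_000_000, pval=1e-12), rec("rs2", pos=7_000_000, pval=1e-9)])
        ld = ld_from(["rs1", "rs2"], [("rs1", "rs2", 0.9)])
        leads = ld_clump(t, ld)
        assert [l.variant_id for l in leads] == ["rs1", "rs2"]

    def test_subthreshold_never_leads_nor_suppresses(self):
        t = table([rec("rs1", pos=100_000, pval=1e-4), rec("rs2", pos=110_000, pval=1e-9)])
        ld = ld_from(["rs1", "rs2"], [("rs1", "rs2", 1.0)])
        leads = ld_clump(t, ld)
        assert [l.variant_id for l in leads] == ["rs2"]

    def test_missing_candidate_errors(self):
        t = table([rec("rs1", pos=100_000, pval=1e-12)])
        ld = ld_from(["rsX"], [])
        with pytest.raises(KeyError, match="rs1"):
            ld_clump(t, ld)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_definition_oracle_on_dense_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        ids = [f"rs{i}" for i in range(n)]
        recs = [
            rec(
                ids[i],
                chrom=int(rng.integers(1, 3)),
                pos=int(rng.integers(1, 80) * 100_000),
                pval=float(10.0 ** -rng.uniform(4, 14)),
            )
            for i in range(n)
        ]
        # random symmetric r2 with dense LD
        m = rng.uniform(0, 1, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        ld = LDMatrix(ids, m)
        t = table(recs)
        got = [l.variant_id for l in ld_clump(t, ld, p_threshold=1e-6, r2_max=0.3, window_bp=2_000_000)]
        want = clump_oracle(recs, ld, 1e-6, 0.3, 2_000_000)
        assert got == want

    def test_lead_set_pairwise_independent_and_order_invariant(self, rng):
        n = 20
        ids = [f"rs{i}" for i in range(n)]
        recs = [
            rec(ids[i], chrom=1, pos=int(rng.integers(1, 100) * 50_000),
                pval=float(10.0 ** -rng.uniform(6, 15)))
            for i in range(n)
        ]
        m = rng.uniform(0, 0.6, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        ld = LDMatrix(ids, m)
        leads = ld_clump(table(recs), ld, p_threshold=1e-5, r2_max=0.2, window_bp=1_000_000)
        for i, a in enumerate(leads):
            for b in leads[i + 1:]:
                if a.chrom == b.chrom and abs(a.pos - b.pos) <= 1_000_000:
                    assert ld.lookup(a.variant_id, b.variant_id) < 0.2
        shuffled = list(recs)
        rng.shuffle(shuffled)
        leads2 = ld_clump(table(shuffled), ld, p_threshold=1e-5, r2_max=0.2, window_bp=1_000_000)
        assert [l.variant_id for l in leads] == [l.variant_id for l in leads2]


class TestLoci:
    def test_locus_bounds(self):
        (loc,) = define_loci([rec("rs1", pos=5_000_000)])
        assert (loc.start, loc.end) == (4_000_000, 6_000_000)

    def test_start_clamped_at_one(self):
        (loc,) = define_loci([rec("rs1", pos=200_000)])
        assert loc.start == 1

    def test_overlapping_loci_collapse_to_most_significant(self):
        l1 = rec("rs1", pos=5_000_000, pval=1e-10)
        l2 = rec("rs2", pos=6_500_000, pval=1e-12)
        loci = define_loci([l1, l2])
        assert len(loci) == 1 and loci[0].lead.variant_id == "rs2"

    def test_cross_trait_merge_keeps_best_lead_and_unions_traits(self):
        tv = define_loci([rec("rs1", pos=5_000_000, pval=1e-9)], trait="tv")
        pc = define_loci([rec("rs2", pos=5_300_000, pval=1e-15)], trait="computer")
        merged = merge_cross_trait_loci({"tv": tv, "computer": pc})
        assert len(merged) == 1
        assert merged[0].lead.variant_id == "rs2"
        assert merged[0].traits == {"tv", "computer"}

    def test_distant_leads_stay_separate(self):
        tv = define_loci([rec("rs1", pos=5_000_000)], trait="tv")
        pc = define_loci([rec("rs2", pos=7_500_000)], trait="computer")
        assert len(merge_cross_trait_loci({"tv": tv, "computer": pc})) == 2

    def test_merge_matches_connected_components_oracle(self, rng):
        import networkx as nx

        leads = {}
        for trait in ("tv", "computer", "driving"):
            leads[trait] = [
                rec(f"{trait}_{i}", chrom=int(rng.integers(1, 3)),
                    pos=int(rng.integers(1, 60) * 200_000),
                    pval=float(10.0 ** -rng.uniform(8, 15)))
                for i in range(3)
            ]
        sets = {t: define_loci(ls, trait=t) for t, ls in leads.items()}
        merged = merge_cross_trait_loci(sets, flank=1_000_000)

        g = nx.Graph()
        pooled = [(t, loc) for t, ls in sets.items() for loc in ls]
        for i, (_, a) in enumerate(pooled):
            g.add_node(i)
            for j, (_, b) in enumerate(pooled[:i]):
                if a.chrom == b.chrom and abs(a.lead.pos - b.lead.pos) <= 1_000_000:
                    g.add_edge(i, j)
        want = sorted(
            min((pooled[i][1].lead for i in comp), key=lambda l: (l.pval, l.variant_id)).variant_id
            for comp in nx.connected_components(g)
        )
        got = sorted(loc.lead.variant_id for loc in merged)
        assert got == want


class TestStrength:
    def test_r2_zero_at_null_effect(self):
        r = rec(beta=0.0)
        assert variant_r2(r, "eaf_beta") == 0.0
        assert variant_r2(r, "t_stat") == 0.0

    def test_eaf_beta_symmetric(self):
        a = rec(eaf=0.2, beta=0.05)
        b = rec(eaf=0.8, beta=-0.05)
        assert variant_r2(a, "eaf_beta") == pytest.approx(variant_r2(b, "eaf_beta"))

    def test_t_stat_matches_regression_r2(self, rng):
        n, maf, b = 2000, 0.3, 0.15
        g = rng.binomial(2, maf, n).astype(float)
        y = b * g + rng.normal(0, 1, n)
        # realized regression r2
        r_emp = np.corrcoef(g, y)[0, 1] ** 2
        # summary-stat route: slope and SE from the same regression
        gc = g - g.mean()
        slope = np.sum(gc * y) / np.sum(gc**2)
        resid = y - y.mean() - slope * gc
        se = np.sqrt(np.sum(resid**2) / (n - 2) / np.sum(gc**2))
        r_formula = variant_r2(
            rec(beta=slope, se=se, eaf=maf, n=n), "t_stat"
        )
        assert r_formula == pytest.approx(r_emp, abs=2e-3)

    def test_f_algebra(self):
        assert f_statistic(0.5, 4) == pytest.approx(2.0)
        assert f_statistic(0.0, 100) == 0.0
        assert f_statistic(1e-4, 408_815) == pytest.approx(40.9, abs=0.05)
        assert f_statistic(1e-4, 408_815) > WEAK_F_THRESHOLD

    def test_f_monotone_in_r2_and_n(self, rng):
        r2s = np.sort(rng.uniform(0, 0.5, 10))
        fs = [f_statistic(r, 1000) for r in r2s]
        assert all(a < b for a, b in zip(fs, fs[1:]))
        ns = np.sort(rng.integers(10, 10_000, 10))
        fs = [f_statistic(0.01, int(n)) for n in np.unique(ns)]
        assert all(a < b for a, b in zip(fs, fs[1:]))

    def test_f_domain_errors(self):
        with pytest.raises(ValueError):
            f_statistic(1.0, 100)
        with pytest.raises(ValueError):
            f_statistic(0.1, 2)

    def test_i2gx_zero_when_effects_identical(self):
        h = make_hset([0.1, 0.1, 0.1], [0.01, 0.01, 0.01], [0.04, 0.04, 0.04], [0.01] * 3)
        s = i2_gx(h)
        assert s.q_gx == pytest.approx(0.0)
        assert s.i2_gx == 0.0

    def test_i2gx_high_when_dispersion_dwarfs_noise(self):
        h = make_hset([0.10, 0.08, 0.12], [0.001] * 3, [0.04] * 3, [0.01] * 3)
        s = i2_gx(h)
        # hand Q_GX: weighted mean 0.1, Q = ((0)^2+(0.02)^2+(0.02)^2)/0.001^2 = 800
        assert s.q_gx == pytest.approx(800.0, rel=1e-6)
        assert s.i2_gx > 0.99

    def test_doubling_sigma_quarters_q(self):
        h1 = make_hset([0.10, 0.08, 0.12], [0.01] * 3, [0.04] * 3, [0.01] * 3)
        h2 = make_hset([0.10, 0.08, 0.12], [0.02] * 3, [0.04] * 3, [0.01] * 3)
        assert i2_gx(h1).q_gx == pytest.approx(4 * i2_gx(h2).q_gx)


class TestSteiger:
    def test_exposure_dominant_kept(self):
        # |t_X| = 12 vs |t_Y| = 2 at comparable n
        h = make_hset([0.12, 0.10], [0.01, 0.01], [0.002, 0.002], [0.001, 0.001],
                      n_x=100_000, n_y=100_000)
        filtered, results = steiger_filter(h)
        assert all(r.keep for r in results)

    def test_outcome_dominant_removed(self):
        h = make_hset([0.02, 0.10], [0.01, 0.01], [0.12, 0.002], [0.01, 0.001],
                      n_x=100_000, n_y=100_000)
        filtered, results = steiger_filter(h)
        assert not results[0].keep and results[1].keep
        assert ("rs1", "steiger_removed") in filtered.dropped

    def test_equal_r2_kept(self):
        h = make_hset([0.1, 0.1], [0.01, 0.01], [0.1, 0.1], [0.01, 0.01],
                      n_x=100_000, n_y=100_000)
        _, results = steiger_filter(h)
        assert all(r.keep for r in results)

    def test_idempotent(self):
        h = make_hset([0.02, 0.10], [0.01, 0.01], [0.12, 0.002], [0.01, 0.001],
                      n_x=100_000, n_y=100_000)
        f1, _ = steiger_filter(h)
        f2, _ = steiger_filter(f1)
        assert f1.variant_ids == f2.variant_ids


class TestExclusion:
    def test_listed_for_selected_trait_removed(self):
        h = make_hset([0.1, 0.1], [0.01] * 2, [0.03, 0.03], [0.01] * 2)
        out = exclude_pleiotropic(h, [("rs1", "years of education")], traits={"years of education"})
        assert out.variant_ids == ["rs2"]
        assert ("rs1", "pleiotropy_excluded") in out.dropped

    def test_trait_filter_respected(self):
        h = make_hset([0.1, 0.1], [0.01] * 2, [0.03, 0.03], [0.01] * 2)
        out = exclude_pleiotropic(h, [("rs1", "bmi")], traits={"years of education"})
        assert out.variant_ids == ["rs1", "rs2"]

    def test_empty_exclusion_is_identity(self):
        h = make_hset([0.1], [0.01], [0.03], [0.01])
        assert exclude_pleiotropic(h, []) is h

    def test_ld_proxy_removed(self):
        h = make_hset([0.1, 0.1], [0.01] * 2, [0.03, 0.03], [0.01] * 2)
        ld = ld_from(["rs1", "rs2", "rsPleio"], [("rs1", "rsPleio", 0.9)])
        out = exclude_pleiotropic(h, [("rsPleio", "bmi")], ld=ld)
        assert out.variant_ids == ["rs2"]

    def test_monotone_and_idempotent(self):
        h = make_hset([0.1, 0.1, 0.1], [0.01] * 3, [0.03] * 3, [0.01] * 3)
        excl = [("rs1", "x")]
        once = exclude_pleiotropic(h, excl)
        twice = exclude_pleiotropic(once, excl)
        assert set(once.variant_ids) <= set(h.variant_ids)
        assert once.variant_ids == twice.variant_ids
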