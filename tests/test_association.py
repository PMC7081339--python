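"""Scan statistics: ANOVA, ranking, recurrence, Spearman, BH adjustment."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import haploscan as hs
from haploscan.association import P_FLOOR

from conftest import make_phenotypes


def brute_force_anova(values, labels):
    """Independent oracle: explicit per-group sums of squares + F-tail via
    scipy.stats.f_oneway, effect size via a one-factor OLS R^2."""
    import pandas as pd
    import statsmodels.formula.api as smf

    groups = [
        [v for v, l in zip(values, labels) if l == g]
        for g in sorted(set(labels))
    ]
    f_stat, p = stats.f_oneway(*groups)
    df = pd.DataFrame({"y": values, "g": [str(l) for l in labels]})
    r2 = smf.ols("y ~ C(g)", data=df).fit().rsquared
    return float(f_stat), float(p), float(r2)


class TestAnovaBlock:
    def test_hand_worked_example(self):
        """Groups {0,1} vs {2,3}: grand mean 1.5, SSB=4, SSW=1 => F=8,
        df=(1,2), eta^2=0.8; P is the F(1,2) upper tail at 8 (~0.106)."""
        r = hs.anova_block([0.0, 1.0, 2.0, 3.0], [0, 0, 1, 1])
        assert r.F == pytest.approx(8.0)
        assert (r.df1, r.df2) == (1, 2)
        assert r.effect_size == pytest.approx(0.8)
        assert r.p == pytest.approx(float(stats.f.sf(8.0, 1, 2)), rel=1e-12)
        assert r.p == pytest.approx(0.10557, abs=1e-4)

    def test_constant_trait_null_identity(self):
        r = hs.anova_block([2.0] * 6, [0, 0, 1, 1, 2, 2])
        assert (r.F, r.p, r.effect_size) == (0.0, 1.0, 0.0)

    def test_zero_within_variance(self):
        r = hs.anova_block([1.0, 1.0, 5.0, 5.0], [0, 0, 1, 1])
        assert r.effect_size == 1.0
        assert r.p_is_floor and r.p <= P_FLOOR

    def test_permutation_symmetry(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=12)
        labels = rng.integers(0, 3, size=12)
        perm = rng.permutation(12)
        a = hs.anova_block(values, labels)
        b = hs.anova_block(values[perm], labels[perm])
        assert a.F == pytest.approx(b.F) and a.p == pytest.approx(b.p)

    def test_missing_labels_and_values_dropped(self):
        a = hs.anova_block([0.0, 1.0, 2.0, 3.0, 99.0], [0, 0, 1, 1, -1])
        b = hs.anova_block([0.0, 1.0, 2.0, 3.0], [0, 0, 1, 1])
        assert a.F == pytest.approx(b.F)

    @pytest.mark.parametrize(
        "values,labels,reason",
        [
            ([1.0, 2.0, 3.0], [0, 0, 0], "fewer_than_2_groups"),
            ([1.0, 2.0, 3.0], [0, 1, 2], "df2=0"),
            ([], [], "no_data"),
        ],
    )
    def test_untestable_reasons(self, values, labels, reason):
        r = hs.anova_block(values, labels)
        assert not r.testable and r.reason == reason

    @given(st.integers(0, 10_000))
    def test_agrees_with_brute_force_oracle(self, seed):
        """Random instances (N <= 20, G <= 5): F, P and eta^2 match the
        independent sums-of-squares/OLS oracle to 1e-10 relative error."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 21))
        g = int(rng.integers(2, 6))
        labels = np.concatenate([np.arange(g), rng.integers(0, g, size=n - g)])
        values = rng.normal(size=n)
        r = hs.anova_block(values, labels)
        f_o, p_o, eta_o = brute_force_anova(values.tolist(), labels.tolist())
        assert r.F == pytest.approx(f_o, rel=1e-10)
        assert r.p == pytest.approx(p_o, rel=1e-10)
        assert r.effect_size == pytest.approx(eta_o, rel=1e-10)


class TestRankResults:
    def _result(self, p, effect=0.5, chrom="chr1", start=100, block_id="b"):
        return hs.AssociationResult(
            block_id=block_id, chrom=chrom, span_start=start, span_end=start + 1,
            timepoint="0", n_groups=2, group_sizes=[2, 2], F=1.0, df1=1, df2=2,
            p=p, effect_size=effect,
        )

    def test_orders_by_p(self):
        rs = [self._result(0.5), self._result(0.001), self._result(0.2)]
        ranked = hs.rank_results(rs)
        assert [r.p for r in ranked] == [0.001, 0.2, 0.5]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_tie_break_by_effect_then_position(self):
        rs = [
            self._result(0.05, effect=0.3, start=100),
            self._result(0.05, effect=0.6, start=300),
            self._result(0.05, effect=0.6, start=200),
        ]
        ranked = hs.rank_results(rs)
        assert [(r.effect_size, r.span_start) for r in ranked] == [
            (0.6, 200), (0.6, 300), (0.3, 100)
        ]

    def test_untestable_last_and_unranked(self):
        bad = hs.anova_block([1.0, 2.0], [0, 1])
        ranked = hs.rank_results([bad, self._result(0.9)])
        assert ranked[-1].testable is False and ranked[-1].rank is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hs.rank_results([])


class TestScanTimepoint:
    def test_causal_block_ranks_first_at_zero_noise(self):
        cfg = hs.SimulationConfig(
            seed=5,
            missing_rate=0.0,
            flip_rate=0.0,
            strain_noise_sd=0.0,
            noise_sd=0.0,
            causal_spec=hs.CausalSpec(
                active_timepoints=("0",), beta=2.0, n_groups=2
            ),
        )
        genotypes, phenotypes, truth = hs.simulate_panel(cfg)
        params = hs.BlockParams()
        filtered = hs.filter_snps(genotypes, params)
        blocks = hs.build_blocks(filtered, params)
        scan = hs.scan_timepoint(blocks, filtered.strain_names, phenotypes, "0")
        top = scan.results[0]
        cb = truth.causal_block
        causal_pos = {genotypes.variants[i].pos for i in range(cb.start, cb.stop)}
        top_pos = {
            filtered.variants[i].pos for i in range(
                next(b.start for b in blocks if b.block_id == top.block_id),
                next(b.stop for b in blocks if b.block_id == top.block_id),
            )
        }
        assert top.rank == 1
        assert causal_pos & top_pos, "top-ranked block must overlap the causal block"

    def test_all_own_group_block_untestable(self):
        rng = np.random.default_rng(1)
        labels = np.arange(5)
        block = hs.HaplotypeBlock(
            block_id="b0", chrom="chr1", start=0, stop=1, span_start=100,
            span_end=100, labels=labels, n_groups=5, group_sizes=[1] * 5,
        )
        pheno = make_phenotypes(
            [(f"s{i}", "0", 1, float(rng.normal())) for i in range(5)]
        )
        scan = hs.scan_timepoint([block], [f"s{i}" for i in range(5)], pheno, "0")
        assert scan.results[0].testable is False
        assert scan.untestable_reasons["df2=0"] == 1

    def test_no_strain_overlap_is_input_error(self):
        block = hs.HaplotypeBlock(
            block_id="b0", chrom="chr1", start=0, stop=1, span_start=100,
            span_end=100, labels=np.array([0, 0, 1]), n_groups=2,
            group_sizes=[2, 1],
        )
        pheno = make_phenotypes([("x1", "0", 1, 1.0), ("x2", "0", 1, 2.0),
                                 ("x3", "0", 1, 3.0)])
        with pytest.raises(hs.InputError, match="overlap"):
            hs.scan_timepoint([block], ["a", "b", "c"], pheno, "0")


class TestRecurrentCandidates:
    def _scans(self, p_by_tp):
        """One block b0 (gene g1) with given P per timepoint, plus a null
        block b1 (gene g2)."""
        scans = []
        for tp, p in p_by_tp.items():
            rs = [
                hs.AssociationResult(
                    block_id="b0", chrom="chr1", span_start=1, span_end=2,
                    timepoint=tp, n_groups=2, group_sizes=[2, 2], F=1.0,
                    df1=1, df2=14, p=p, effect_size=0.5,
                ),
                hs.AssociationResult(
                    block_id="b1", chrom="chr1", span_start=5, span_end=6,
                    timepoint=tp, n_groups=2, group_sizes=[2, 2], F=1.0,
                    df1=1, df2=14, p=0.9, effect_size=0.1,
                ),
            ]
            scans.append(hs.ScanResult(timepoint=tp, results=hs.rank_results(rs),
                                       alpha=0.001))
        return scans

    GENE_MAP = {"b0": ["g1"], "b1": ["g2"]}

    def test_recurrence_counting(self):
        scans = self._scans({"0": 1e-5, "4": 1e-4, "16": 0.5, "24": 5e-4,
                             "48": 0.9, "72": 0.9})
        cands = hs.recurrent_candidates(scans, self.GENE_MAP, alpha=0.001,
                                        min_timepoints=3)
        assert [c.gene for c in cands] == ["g1"]
        assert cands[0].recurrence == 3
        assert set(cands[0].supporting_blocks) == {"0", "4", "24"}
        assert cands[0].best_p["0"] == 1e-5

    def test_two_timepoint_gene_excluded(self):
        scans = self._scans({"0": 1e-5, "4": 1e-4, "16": 0.5, "24": 0.5,
                             "48": 0.9, "72": 0.9})
        assert hs.recurrent_candidates(scans, self.GENE_MAP) == []

    def test_min_timepoints_one_is_union(self):
        scans = self._scans({"0": 1e-5, "4": 0.5})
        cands = hs.recurrent_candidates(scans, self.GENE_MAP, min_timepoints=1)
        assert [c.gene for c in cands] == ["g1"]

    def test_min_timepoints_equal_scans_is_intersection(self):
        scans = self._scans({"0": 1e-5, "4": 1e-5})
        cands = hs.recurrent_candidates(scans, self.GENE_MAP, min_timepoints=2)
        assert [c.gene for c in cands] == ["g1"]
        scans = self._scans({"0": 1e-5, "4": 0.5})
        assert hs.recurrent_candidates(scans, self.GENE_MAP, min_timepoints=2) == []

    def test_min_timepoints_exceeding_scans_rejected(self):
        scans = self._scans({"0": 1e-5})
        with pytest.raises(ValueError, match="min_timepoints"):
            hs.recurrent_candidates(scans, self.GENE_MAP, min_timepoints=2)

    def test_uncovered_block_rejected(self):
        scans = self._scans({"0": 1e-5})
        with pytest.raises(ValueError, match="cover"):
            hs.recurrent_candidates(scans, {"b0": ["g1"]}, min_timepoints=1)


class TestStrainEffectAnova:
    def test_hand_worked_example(self):
        """Replicates {0,1} vs {2,3} by strain: same arithmetic as the block
        worked case, F=8, df=(1,2)."""
        pheno = make_phenotypes(
            [("a", "0", 1, 0.0), ("a", "0", 2, 1.0),
             ("b", "0", 1, 2.0), ("b", "0", 2, 3.0)]
        )
        r = hs.strain_effect_anova(pheno, "0")
        assert r.F == pytest.approx(8.0) and (r.df1, r.df2) == (1, 2)

    def test_constant_values(self):
        pheno = make_phenotypes(
            [("a", "0", 1, 5.0), ("a", "0", 2, 5.0),
             ("b", "0", 1, 5.0), ("b", "0", 2, 5.0)]
        )
        r = hs.strain_effect_anova(pheno, "0")
        assert (r.F, r.p) == (0.0, 1.0)

    def test_single_replicate_untestable(self):
        pheno = make_phenotypes([("a", "0", 1, 1.0), ("b", "0", 1, 2.0)])
        r = hs.strain_effect_anova(pheno, "0")
        assert not r.testable and r.reason == "df2=0"

    def test_strain_relabeling_invariance(self):
        rows = [(f"s{i}", "0", r, float(i * r)) for i in range(4) for r in (1, 2)]
        renamed = [(f"strain_{s}", t, r, v) for s, t, r, v in rows]
        a = hs.strain_effect_anova(make_phenotypes(rows), "0")
        b = hs.strain_effect_anova(make_phenotypes(renamed), "0")
        assert a.p == pytest.approx(b.p)


class TestTimepointSpearman:
    @staticmethod
    def _pheno(x, y):
        rows = [(f"s{i}", "0", 1, float(v)) for i, v in enumerate(x)]
        rows += [(f"s{i}", "4", 1, float(v)) for i, v in enumerate(y)]
        return make_phenotypes(rows)

    def test_hand_rank_formula(self):
        """x=(1,2,3,4), y=(1,3,2,4): rho = 1 - 6*2/(4*15) = 0.8."""
        mat = hs.timepoint_spearman(self._pheno([1, 2, 3, 4], [1, 3, 2, 4]))
        assert mat.loc["0", "4"] == pytest.approx(0.8)
        assert mat.loc["0", "0"] == 1.0 and mat.loc["4", "0"] == mat.loc["0", "4"]

    def test_monotone_transform_gives_unit_rho(self):
        x = [1.0, 2.0, 5.0, 9.0]
        y = [v**3 + 1 for v in x]
        mat = hs.timepoint_spearman(self._pheno(x, y))
        assert mat.loc["0", "4"] == pytest.approx(1.0)

    def test_reversed_order_gives_minus_one(self):
        mat = hs.timepoint_spearman(self._pheno([1, 2, 3, 4], [4, 3, 2, 1]))
        assert mat.loc["0", "4"] == pytest.approx(-1.0)

    def test_insufficient_shared_strains_flagged_nan(self):
        rows = [("a", "0", 1, 1.0), ("b", "0", 1, 2.0), ("c", "0", 1, 3.0),
                ("a", "4", 1, 1.0), ("b", "4", 1, 2.0)]
        mat = hs.timepoint_spearman(make_phenotypes(rows))
        assert math.isnan(mat.loc["0", "4"])


class TestBenjaminiHochberg:
    def test_single_value_unchanged(self):
        assert hs.benjamini_hochberg([0.03]) == pytest.approx([0.03])

    def test_hand_step_up(self):
        """(0.01,0.02,0.03,0.04): step-up gives 0.04 everywhere."""
        adj = hs.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hs.benjamini_hochberg([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_in_range(self, ps):
        adj = hs.benjamini_hochberg(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all((adj >= 0) & (adj <= 1))
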