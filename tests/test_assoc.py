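"""Expression statistics, target linking, SNP and LD utilities."""

import numpy as np
import pytest
from scipy import stats

from acedhs.assoc import (
    ExpressionMatrix,
    SNPRecord,
    assign_targets,
    filter_snps_by_af,
    ld_r2,
    relative_expression,
    relative_expression_batch,
    snp_overlap,
    species_ttest,
    zscore_normalize,
)
from acedhs.intervals import GenomicInterval
from acedhs.simulate import generate_expression_matrix


def make_expr(values, species):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        species=species,
    )


class TestZscore:
    def test_row_standardised(self):
        m = make_expr([[1.0, 2.0, 3.0]], ["h", "h", "h"])
        z = zscore_normalize(m)
        assert np.allclose(z.values, [[-1.0, 0.0, 1.0]])  # sd of [1,2,3] is 1

    def test_constant_row_zeroed(self):
        m = make_expr([[5.0, 5.0, 5.0]], ["h", "h", "h"])
        with pytest.warns(UserWarning):
            z = zscore_normalize(m)
        assert np.all(z.values == 0)

    def test_idempotent(self, rng):
        m = make_expr(rng.normal(size=(6, 8)), ["h"] * 4 + ["c"] * 4)
        z1 = zscore_normalize(m)
        z2 = zscore_normalize(z1)
        assert np.allclose(z1.values, z2.values, atol=1e-12)


class TestSpeciesTtest:
    def test_identical_groups(self):
        m = make_expr([[1.0, 2.0, 1.0, 2.0]], ["h", "h", "m", "m"])
        t, p = species_ttest(m, "g0", "h", "m")
        assert p > 0.9

    def test_large_shift_significant(self):
        m = make_expr([[1.0, 2.0, 3.0, 11.0, 12.0, 13.0]], ["h"] * 3 + ["m"] * 3)
        t, p = species_ttest(m, "g0", "h", "m")
        assert p < 0.01

    def test_matches_scipy_welch_on_random_draws(self, rng):
        for _ in range(100):
            a = rng.normal(size=5)
            b = rng.normal(loc=0.3, size=7)
            m = make_expr([np.concatenate([a, b])], ["h"] * 5 + ["m"] * 7)
            t, p = species_ttest(m, "g0", "h", "m")
            t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(float(t_ref), abs=1e-10)
            assert p == pytest.approx(float(p_ref), abs=1e-10)

    def test_small_group_errors(self):
        m = make_expr([[1.0, 2.0, 3.0]], ["h", "m", "m"])
        with pytest.raises(ValueError):
            species_ttest(m, "g0", "h", "m")


class TestAssignTargets:
    def test_identical_vectors_linked(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        links = assign_targets({"d": v}, {"g": v.copy()})
        assert links == {"d": ["g"]}

    def test_threshold_strict(self):
        # build vectors with r exactly 0.7 via two-point mixture
        rng = np.random.default_rng(5)
        x = rng.normal(size=2000)
        e = rng.normal(size=2000)
        r0 = 0.7
        y = r0 * x + np.sqrt(1 - r0**2) * e
        # rescale y so empirical r is exactly 0.7 is fiddly; instead check both sides
        r = np.corrcoef(x, y)[0, 1]
        links = assign_targets({"d": x}, {"g": y}, r_threshold=r)
        assert links == {"d": []}  # strict >: equality not linked
        links = assign_targets({"d": x}, {"g": y}, r_threshold=r - 1e-9)
        assert links == {"d": ["g"]}

    def test_affine_invariance(self, rng):
        x = rng.normal(size=10)
        y = 0.95 * x + 0.05 * rng.normal(size=10)
        base = assign_targets({"d": x}, {"g": y})
        scaled = assign_targets({"d": 3.0 * x - 7.0}, {"g": 0.5 * y + 2.0})
        assert base == scaled

    def test_matches_corrcoef_oracle(self, rng):
        dhs = {f"d{i}": rng.normal(size=8) for i in range(5)}
        genes = {f"g{j}": rng.normal(size=8) for j in range(6)}
        links = assign_targets(dhs, genes, r_threshold=0.3)
        for did, dv in dhs.items():
            expected = [
                gid for gid, gv in genes.items()
                if np.corrcoef(dv, gv)[0, 1] > 0.3
            ]
            assert links[did] == expected

    def test_zero_variance_skipped(self, rng):
        with pytest.warns(UserWarning):
            links = assign_targets(
                {"d": np.ones(5)}, {"g": rng.normal(size=5)}
            )
        assert links == {"d": []}


class TestSNPs:
    def _snp(self, pos, af=0.2, sid="rs1"):
        return SNPRecord(id=sid, chrom="chrS", position=pos, ref="A", alt="G",
                         alt_frequency=af)

    def test_half_open_membership(self):
        el = [GenomicInterval("chrS", 100, 200, id="e1")]
        inside = snp_overlap([self._snp(100)], el, {"rs1": "gX"}, {"e1": []})
        outside = snp_overlap([self._snp(200, sid="rs2")], el, {}, {"e1": []})
        assert len(inside) == 1 and len(outside) == 0

    def test_concordance_flag(self):
        el = [GenomicInterval("chrS", 0, 50, id="e1")]
        links = {"e1": ["gA", "gB"]}
        tab = snp_overlap(
            [self._snp(10, sid="rs1"), self._snp(20, sid="rs2")],
            el, {"rs1": "gA", "rs2": "gZ"}, links,
        )
        assert tab.set_index("snp")["concordant"].to_dict() == {
            "rs1": True, "rs2": False,
        }

    def test_planted_concordance_counts(self, rng):
        elements = [
            GenomicInterval("chrS", i * 100, i * 100 + 50, id=f"e{i}")
            for i in range(16)
        ]
        links = {f"e{i}": [f"g{i}"] for i in range(16)}
        snps, reported = [], {}
        for i in range(16):
            sid = f"rs{i}"
            snps.append(self._snp(i * 100 + 10, sid=sid))
            reported[sid] = f"g{i}" if i < 8 else "unrelated"
        tab = snp_overlap(snps, elements, reported, links)
        assert int(tab["concordant"].sum()) == 8

    def test_af_filter_strict(self):
        snps = [
            self._snp(1, af=0.009, sid="a"),
            self._snp(2, af=0.01, sid="b"),
            self._snp(3, af=0.079, sid="c"),
            self._snp(4, af=0.995, sid="d"),  # MAF 0.005
        ]
        kept = {s.id for s in filter_snps_by_af(snps)}
        assert kept == {"c"}

    def test_genotype_frequency_consistency_enforced(self):
        with pytest.raises(ValueError):
            SNPRecord(id="x", chrom="chrS", position=1, ref="A", alt="G",
                      alt_frequency=0.9, genotypes=[0, 0, 0, 0])


class TestLD:
    def test_identical_dosages_r2_one(self):
        g = [0, 1, 2, 1, 0, 2]
        assert ld_r2(g, g) == pytest.approx(1.0)

    def test_allele_relabeling_invariance(self, rng):
        a = rng.integers(0, 3, size=50)
        b = rng.integers(0, 3, size=50)
        assert ld_r2(a, b) == pytest.approx(ld_r2(2 - a, b), abs=1e-12)

    def test_independent_sites_low_r2(self, rng):
        a = rng.binomial(2, 0.3, size=1000)
        b = rng.binomial(2, 0.4, size=1000)
        assert ld_r2(a, b) < 0.01

    def test_matches_direct_correlation(self):
        a = [0, 0, 1, 1, 2, 2]
        b = [0, 1, 1, 1, 2, 1]
        r = np.corrcoef(a, b)[0, 1]
        assert ld_r2(a, b) == pytest.approx(r * r, abs=1e-12)

    def test_monomorphic_errors(self):
        with pytest.raises(ValueError):
            ld_r2([1, 1, 1], [0, 1, 2])


class TestRelativeExpression:
    @pytest.mark.parametrize(
        "ct_t,ct_r,expected", [(20.0, 20.0, 1.0), (21.0, 20.0, 0.5), (18.0, 20.0, 4.0)]
    )
    def test_two_power_minus_dct(self, ct_t, ct_r, expected):
        assert relative_expression(ct_t, ct_r) == pytest.approx(expected)

    def test_batch_normalised_to_control_mean(self):
        ct_t = np.array([20.0, 21.0, 19.0, 18.0])
        ct_r = np.full(4, 20.0)
        control = np.array([True, True, False, False])
        rel = relative_expression_batch(ct_t, ct_r, control)
        assert rel[control].mean() == pytest.approx(1.0)


class TestGeneratedExpression:
    def test_no_noise_no_shift_identical_samples(self):
        m = generate_expression_matrix(5, 3, noise_sd=0.0, seed=1)
        for row in m.values:
            assert np.allclose(row, row[0])

    def test_planted_shift_detected(self):
        m = generate_expression_matrix(
            20, 10,
            shifted_genes={"g0003": {"human": 2.0}},
            noise_sd=0.1, seed=2,
        )
        t, p = species_ttest(m, "g0003", "human", "macaque")
        assert p < 0.01 and t > 0

    def test_same_seed_identical(self):
        a = generate_expression_matrix(6, 4, noise_sd=0.3, seed=9)
        b = generate_expression_matrix(6, 4, noise_sd=0.3, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_tsv_round_trip(self, tmp_path):
        m = generate_expression_matrix(4, 3, noise_sd=0.2, seed=3)
        m.to_tsv(tmp_path / "e.tsv")
        back = ExpressionMatrix.from_tsv(tmp_path / "e.tsv")
        assert back.species == m.species
        assert np.allclose(back.values, m.values, atol=1e-5)
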