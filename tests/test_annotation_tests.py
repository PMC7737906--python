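"""Annotation-class gene tests: coding/UTR subclass composition, dTSS
weighting, enhancer confidence weighting, and cross-tissue TWAS."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, norm

from omnigene.annotation_tests import (
    coding_test,
    cross_tissue_correlation,
    ct_twas,
    dtss_test,
    dtss_weights,
    enhancer_test,
    gene_class_tests,
    socs_test,
    twas_single_tissue,
    utr_test,
)
from omnigene.core_tests import acat_combine, qtype_test
from omnigene.io_ld import (
    AnnotationStore,
    GeneModel,
    HaplotypePanel,
    LDProvider,
    SummaryStatTable,
    TissueWeightMatrix,
    VariantKey,
)


def _panel(m=8, n=400, seed=0, rho=0.5):
    """Small panel with AR-ish LD via a shared latent factor chain."""
    rng = np.random.default_rng(seed)
    X = np.empty((n, m))
    X[:, 0] = rng.standard_normal(n)
    for j in range(1, m):
        X[:, j] = rho * X[:, j - 1] + math.sqrt(1 - rho**2) * rng.standard_normal(n)
    H = (X < norm.ppf(0.35)).astype(np.int8)
    for j in range(m):
        if H[:, j].std() == 0:
            H[0, j] = 1 - H[0, j]
    variants = [VariantKey("1", 1000 + 500 * j, "A", "G") for j in range(m)]
    return HaplotypePanel(H, variants)


def _stats(panel, z):
    return SummaryStatTable(
        pd.DataFrame(
            {
                "chrom": [v.chrom for v in panel.variants],
                "pos": [v.pos for v in panel.variants],
                "ref": [v.ref for v in panel.variants],
                "alt": [v.alt for v in panel.variants],
                "z": z,
            }
        )
    )


def _annotations(rows):
    return AnnotationStore(
        pd.DataFrame(rows, columns=list(AnnotationStore.COLUMNS))
    )


@pytest.fixture(scope="module")
def small():
    panel = _panel()
    rng = np.random.default_rng(1)
    z = rng.normal(size=len(panel.variants))
    z[0] = 2.0
    return panel, _stats(panel, z), LDProvider(panel)


class TestCodingUTR:
    def test_single_subclass_single_variant_is_chi2(self, small):
        panel, stats, ld = small
        v = panel.variants[0]
        ann = _annotations([(v.chrom, v.pos, v.ref, v.alt, "g", "coding", "missense", 1.0)])
        out = coding_test("g", stats, ann, ld)
        assert out.p == pytest.approx(chi2.sf(4.0, 1), abs=1e-9)

    def test_equal_subclass_pvalues_combine_to_same(self, small):
        panel, stats, ld = small
        v = panel.variants[0]
        ann = _annotations(
            [(v.chrom, v.pos, v.ref, v.alt, "g", "coding", "missense", 1.0),
             (v.chrom, v.pos, v.ref, v.alt, "g", "coding", "nonsense", 1.0)]
        )
        out = coding_test("g", stats, ann, ld)
        assert out.p == pytest.approx(chi2.sf(4.0, 1), rel=1e-9)

    def test_three_subclass_composition_oracle(self, small):
        panel, stats, ld = small
        rows = []
        for j, sub in [(0, "missense"), (1, "missense"), (2, "synonymous"),
                       (3, "synonymous"), (4, "nonsense")]:
            v = panel.variants[j]
            rows.append((v.chrom, v.pos, v.ref, v.alt, "g", "coding", sub, 1.0))
        ann = _annotations(rows)
        out = coding_test("g", stats, ann, ld)
        manual = []
        for sub, idx in [("missense", [0, 1]), ("nonsense", [4]), ("synonymous", [2, 3])]:
            keys = [panel.variants[j] for j in idx]
            manual.append(qtype_test(stats.z_for(keys), np.ones(len(keys)), ld.ld(keys)).p)
        assert out.p == pytest.approx(acat_combine(manual), rel=1e-9)

    def test_absent_class_returns_none(self, small):
        _, stats, ld = small
        assert coding_test("g", stats, _annotations([]), ld) is None

    def test_utr_single_region_reduces_to_qtype(self, small):
        panel, stats, ld = small
        keys = [panel.variants[1], panel.variants[2]]
        rows = [(v.chrom, v.pos, v.ref, v.alt, "g", "utr", "3utr", 1.0) for v in keys]
        out = utr_test("g", stats, _annotations(rows), ld)
        want = qtype_test(stats.z_for(keys), np.ones(2), ld.ld(keys)).p
        assert out.p == pytest.approx(want, rel=1e-9)

    def test_hmp_combiner_available(self, small):
        panel, stats, ld = small
        rows = [
            (v.chrom, v.pos, v.ref, v.alt, "g", "coding", sub, 1.0)
            for v, sub in zip(panel.variants[:4], ["missense", "missense", "nonsense", "synonymous"])
        ]
        out = coding_test("g", stats, _annotations(rows), ld, combiner="hmp")
        assert 0 < out.p <= 1


class TestDTSS:
    def test_weight_one_at_tss(self):
        for alpha in [1e-4, 5e-5, 1e-5, 5e-6]:
            assert dtss_weights([0], alpha)[0] == 1.0

    def test_analytic_decay(self):
        w = dtss_weights([100_000], 1e-5)
        assert w[0] == pytest.approx(math.exp(-1), abs=1e-12)

    def test_weights_monotone_in_distance_and_alpha(self):
        d = np.array([0, 1_000, 50_000, 400_000])
        w_small = dtss_weights(d, 5e-6)
        w_big = dtss_weights(d, 1e-4)
        assert np.all(np.diff(w_small) < 0) and np.all(np.diff(w_big) < 0)
        assert np.all(w_big <= w_small)
        assert np.all((0 < w_small) & (w_small <= 1))

    def test_beyond_window_excluded(self):
        w = dtss_weights([600_000], 1e-5, window=500_000)
        assert w[0] == 0.0

    def test_single_variant_identity_for_any_grid(self, small):
        panel, _, _ = small
        v = panel.variants[0]
        z1 = np.zeros(len(panel.variants))
        z1[0] = 2.0
        solo = SummaryStatTable(
            pd.DataFrame({"chrom": [v.chrom], "pos": [v.pos], "ref": [v.ref],
                          "alt": [v.alt], "z": [2.0]})
        )
        gm = GeneModel("g", "1", "+", v.pos, v.pos + 10_000)
        out = dtss_test(gm, solo)
        assert out.p == pytest.approx(2 * norm.sf(2.0), rel=1e-9)

    def test_no_variants_in_window_returns_none(self, small):
        _, stats, _ = small
        gm = GeneModel("g", "1", "+", 10_000_000, 10_050_000)
        assert dtss_test(gm, stats) is None


class TestEnhancer:
    def test_single_enhancer_single_variant(self, small):
        panel, stats, ld = small
        v = panel.variants[0]
        ann = _annotations([(v.chrom, v.pos, v.ref, v.alt, "g", "enhancer", "E1", 1.0)])
        out = enhancer_test("g", stats, ann, ld)
        assert out.p == pytest.approx(chi2.sf(4.0, 1), abs=1e-9)

    def test_equal_weights_match_unweighted_qtype(self, small):
        panel, stats, ld = small
        keys = panel.variants[:4]
        ann = _annotations(
            [(v.chrom, v.pos, v.ref, v.alt, "g", "enhancer", "E1", 0.7) for v in keys]
        )
        out = enhancer_test("g", stats, ann, ld)
        want = qtype_test(stats.z_for(keys), np.ones(4), ld.ld(keys)).p
        assert out.p == pytest.approx(want, rel=1e-6)

    def test_weight_scale_invariance(self, small):
        panel, stats, ld = small
        rows = []
        for j, (e, w) in enumerate([("E1", 0.5), ("E1", 0.5), ("E2", 1.5), ("E2", 1.5)]):
            v = panel.variants[j]
            rows.append((v.chrom, v.pos, v.ref, v.alt, "g", "enhancer", e, w))
        p1 = enhancer_test("g", stats, _annotations(rows), ld).p
        rows10 = [(c, p, r, a, g, cl, s, 10 * w) for c, p, r, a, g, cl, s, w in rows]
        p2 = enhancer_test("g", stats, _annotations(rows10), ld).p
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_multi_enhancer_variant_weights_sum(self, small):
        panel, stats, ld = small
        v = panel.variants[0]
        # one variant in two enhancers (w=0.5 each) == one enhancer with w=1
        ann2 = _annotations(
            [(v.chrom, v.pos, v.ref, v.alt, "g", "enhancer", "E1", 0.5),
             (v.chrom, v.pos, v.ref, v.alt, "g", "enhancer", "E2", 0.5)]
        )
        ann1 = _annotations([(v.chrom, v.pos, v.ref, v.alt, "g", "enhancer", "E", 1.0)])
        assert enhancer_test("g", stats, ann2, ld).stat == pytest.approx(
            enhancer_test("g", stats, ann1, ld).stat)

    def test_acat_form(self, small):
        panel, stats, ld = small
        keys = panel.variants[:3]
        ann = _annotations(
            [(v.chrom, v.pos, v.ref, v.alt, "g", "enhancer", "E1", 2.0) for v in keys]
        )
        out = enhancer_test("g", stats, ann, ld, form="acat")
        want = acat_combine(stats.p_for(keys), [2.0] * 3)
        assert out.p == pytest.approx(want, rel=1e-9)


class TestTWAS:
    def test_single_variant_returns_z(self, small):
        panel, stats, ld = small
        w = TissueWeightMatrix()
        w.add("g", "t", [panel.variants[0]], [1.0])
        res = twas_single_tissue("g", "t", stats, w, ld)
        assert res.S == pytest.approx(stats.z_for([panel.variants[0]])[0], rel=1e-9)

    def test_two_independent_variants_analytic(self):
        rng = np.random.default_rng(3)
        H = (rng.random((4000, 2)) < 0.4).astype(np.int8)
        variants = [VariantKey("1", 1, "A", "G"), VariantKey("1", 2, "C", "T")]
        panel = HaplotypePanel(H, variants)
        stats = _stats(panel, np.array([1.0, 1.0]))
        ld = LDProvider(panel, eps=0.0)
        w = TissueWeightMatrix()
        w.add("g", "t", variants, [1.0, 1.0])
        res = twas_single_tissue("g", "t", stats, w, ld)
        # independent columns: b'Rb ~ 2, S ~ sqrt(2)
        assert res.S == pytest.approx(math.sqrt(2), abs=0.1)

    def test_perfect_ld_opposite_weights_sentinel(self):
        col = np.array([0, 1, 1, 0, 1] * 20, dtype=np.int8)
        variants = [VariantKey("1", 1, "A", "G"), VariantKey("1", 2, "C", "T")]
        panel = HaplotypePanel(np.column_stack([col, col]), variants)
        stats = _stats(panel, np.array([1.0, 1.0]))
        ld = LDProvider(panel, eps=0.0)
        w = TissueWeightMatrix()
        w.add("g", "t", variants, [1.0, -1.0])
        assert twas_single_tissue("g", "t", stats, w, ld) is None

    def test_missing_weight_mass_sentinel(self, small):
        panel, stats, ld = small
        w = TissueWeightMatrix()
        outside = VariantKey("9", 99, "A", "G")
        w.add("g", "t", [panel.variants[0], outside], [0.1, 5.0])
        assert twas_single_tissue("g", "t", stats, w, ld) is None


class TestCTTWAS:
    def _weights(self, panel, specs):
        w = TissueWeightMatrix()
        for tissue, idx, b in specs:
            w.add("g", tissue, [panel.variants[j] for j in idx], b)
        return w

    def test_single_tissue_all_methods_agree(self, small):
        panel, stats, ld = small
        w = self._weights(panel, [("t0", [0, 1], [0.5, 1.0])])
        ps = [ct_twas("g", stats, w, ld, method=m).p for m in ("ct-a", "ct-h", "ct-q", "ct-m")]
        assert all(p == pytest.approx(ps[0], rel=1e-9) for p in ps)

    def test_duplicate_tissues_perfect_correlation(self, small):
        panel, stats, ld = small
        w = self._weights(panel, [("t0", [0, 1], [0.5, 1.0]), ("t1", [0, 1], [0.5, 1.0])])
        RS = cross_tissue_correlation("g", ["t0", "t1"], stats, w, ld)
        assert RS[0, 1] == pytest.approx(1.0, abs=1e-9)
        single = ct_twas("g", stats, self._weights(panel, [("t0", [0, 1], [0.5, 1.0])]), ld, "ct-m")
        dup = ct_twas("g", stats, w, ld, method="ct-m")
        assert dup.p == pytest.approx(single.p, abs=5e-3)

    def test_tissue_order_invariance_cta_cth(self, small):
        panel, stats, ld = small
        wa = self._weights(panel, [("a", [0, 1], [1.0, 0.3]), ("b", [2, 3], [-0.5, 0.8])])
        wb = self._weights(panel, [("b", [2, 3], [-0.5, 0.8]), ("a", [0, 1], [1.0, 0.3])])
        for m in ("ct-a", "ct-h"):
            assert ct_twas("g", stats, wa, ld, m).p == pytest.approx(
                ct_twas("g", stats, wb, ld, m).p, rel=1e-12)

    def test_ctq_sign_flip_invariance(self, small):
        panel, stats, ld = small
        wa = self._weights(panel, [("a", [0, 1], [1.0, 0.3]), ("b", [2, 3], [-0.5, 0.8])])
        wb = self._weights(panel, [("a", [0, 1], [-1.0, -0.3]), ("b", [2, 3], [-0.5, 0.8])])
        assert ct_twas("g", stats, wa, ld, "ct-q").stat == pytest.approx(
            ct_twas("g", stats, wb, ld, "ct-q").stat, rel=1e-9)

    def test_ctq_monte_carlo_oracle(self, small):
        """CT-Q mixture chi-squared null vs simulation from R_S."""
        panel, stats, ld = small
        w = self._weights(
            panel,
            [("a", [0, 1, 2], [1.0, 0.3, -0.4]), ("b", [1, 2, 3], [-0.5, 0.8, 0.2]),
             ("c", [4, 5], [0.9, -0.6])],
        )
        out = ct_twas("g", stats, w, ld, "ct-q")
        RS = cross_tissue_correlation("g", ["a", "b", "c"], stats, w, ld)
        RS = 0.999 * RS + 0.001 * np.eye(3)
        rng = np.random.default_rng(8)
        X = rng.standard_normal((10**6, 3)) @ np.linalg.cholesky(RS).T
        tail = ((X**2).sum(axis=1) >= out.stat).mean()
        se = math.sqrt(max(tail * (1 - tail), 1e-9) / 10**6)
        assert abs(out.p - tail) <= 3 * se + 1e-4

    def test_no_tissues_returns_none(self, small):
        _, stats, ld = small
        assert ct_twas("g", stats, TissueWeightMatrix(), ld) is None


class TestPipeline:
    def test_socs_equal_weight_window(self, small):
        panel, stats, ld = small
        gm = GeneModel("g", "1", "+", 1000, 2000)
        out = socs_test(gm, stats, ld, window=10_000)
        keys = panel.variants  # all within 10 kb of the body
        want = qtype_test(stats.z_for(keys), np.ones(len(keys)), ld.ld(keys)).p
        assert out.p == pytest.approx(want, rel=1e-9)

    def test_gene_class_tests_on_fixture(self, fixture_set, ld_provider):
        from omnigene.simulate import CausalConfig, build_locus, sample_causal_effects, simulate_zscores

        locus = build_locus("G003", fixture_set)
        rng = np.random.default_rng(0)
        cfg = CausalConfig("coding", 0.001)
        eff = sample_causal_effects(locus, cfg, rng)
        sim = simulate_zscores(locus, eff, cfg, rng)
        stats = sim.to_summary_table()
        gm = fixture_set.gene_models["G003"]
        out = gene_class_tests(gm, stats, fixture_set.annotations,
                               fixture_set.weights, ld_provider)
        assert {"coding", "utr", "dtss"} <= set(out)
        assert all(0 < t.p <= 1 for t in out.values())
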