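"""Fold-change DEG calling, candidate intersection, ddCt arithmetic and
hypergeometric enrichment (vs an exact-fraction enumeration oracle)."""
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from wrkykit import screen as sc
from wrkykit import simulate as sim
from wrkykit.io import WrkykitError


def _table(seed=0, **kw):
    return sim.gen_fpkm_table(seed=seed, **kw)


class TestFoldChange:
    def test_closed_form(self):
        table, _ = _table(noise_sigma=0.0)
        # construct a tiny table directly instead: means 7 vs 1, pc 1 -> log2(8/2)=2
        import pandas as pd

        values = pd.DataFrame(
            {"b1": [1.0], "b2": [1.0], "t1": [7.0], "t2": [7.0]}, index=["g"]
        )
        meta = pd.DataFrame(
            {"variety": ["WF", "WF", "RF", "RF"], "stage": ["bud"] * 4},
            index=pd.Index(["b1", "b2", "t1", "t2"], name="sample"),
        )
        t = sc.ExpressionTable(values, meta)
        c = sc.Contrast("c", ("b1", "b2"), ("t1", "t2"), "bud")
        assert sc.log2_fold_change(t, c)["g"] == pytest.approx(2.0)

    def test_equal_means_zero(self):
        table, _ = _table(n_planted_pos=0, n_planted_neg=0, noise_sigma=0.0)
        c = sc.contrast_from_table(table, "c", "WF", "RF", "bud")
        fc = sc.log2_fold_change(table, c)
        assert all(abs(v) < 1e-12 for v in fc.values())

    def test_missing_sample_is_error(self):
        table, _ = _table()
        c = sc.Contrast("c", ("nope",), ("WF_bud_r1",), "bud")
        with pytest.raises(WrkykitError, match="nope"):
            sc.log2_fold_change(table, c)

    def test_antisymmetry(self):
        """Swapping baseline and treatment negates every log2FC."""
        table, _ = _table(seed=3)
        fwd = sc.contrast_from_table(table, "f", "WF", "RF", "bud")
        rev = sc.Contrast("r", fwd.treatment, fwd.baseline, "bud")
        a = sc.log2_fold_change(table, fwd)
        b = sc.log2_fold_change(table, rev)
        for g in a:
            assert a[g] == pytest.approx(-b[g], abs=1e-12)


class TestDegCalling:
    def test_boundary_inclusive(self):
        deg = sc.call_degs({"a": 1.0, "b": -1.0, "c": 0.99, "d": -0.99})
        assert deg.up == {"a"} and deg.down == {"b"}

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        fc = {f"g{i}": float(v) for i, v in enumerate(rng.normal(0, 2, 200))}
        lo = sc.call_degs(fc, threshold=1.0)
        hi = sc.call_degs(fc, threshold=2.0)
        assert hi.up <= lo.up and hi.down <= lo.down


class TestCandidateScreen:
    def test_set_algebra(self):
        d1 = sc.DegSet("c1", "bud", {"a", "b", "c"}, {"x"})
        d2 = sc.DegSet("c2", "bud", {"b", "c", "d"}, {"x", "y"})
        r = sc.screen_candidates(d1, d2)
        assert r.positive == {"b", "c"} and r.negative == {"x"}

    def test_stage_mismatch_is_error(self):
        d1 = sc.DegSet("c1", "bud", set(), set())
        d2 = sc.DegSet("c2", "full_bloom", set(), set())
        with pytest.raises(WrkykitError):
            sc.screen_candidates(d1, d2)

    def test_planted_recovery_across_seeds(self):
        """Precision and recall >=0.95 for 8-fold planted effects with
        lognormal replicate noise, over 20 seeded replicates."""
        precisions, recalls = [], []
        for seed in range(20):
            table, truth = _table(seed=seed)
            degs = {}
            for v in ("RF", "PF"):
                c = sc.contrast_from_table(table, f"WFvs{v}", "WF", v, "bud")
                degs[v] = sc.call_degs(sc.log2_fold_change(table, c), c.name, "bud")
            res = sc.screen_candidates(degs["RF"], degs["PF"])
            found = res.positive | res.negative
            planted = set(truth.positive) | set(truth.negative)
            tp = len(found & planted)
            precisions.append(tp / len(found) if found else 1.0)
            recalls.append(tp / len(planted))
        assert min(precisions) >= 0.95 and min(recalls) >= 0.95

    def test_noiseless_recovery_exact(self):
        table, truth = _table(seed=4, noise_sigma=0.0)
        degs = {}
        for v in ("RF", "PF"):
            c = sc.contrast_from_table(table, f"WFvs{v}", "WF", v, "bud")
            degs[v] = sc.call_degs(sc.log2_fold_change(table, c), c.name, "bud")
        res = sc.screen_candidates(degs["RF"], degs["PF"])
        assert res.positive == set(truth.positive)
        assert res.negative == set(truth.negative)

    def test_no_planting_no_candidates(self):
        table, _ = _table(seed=5, n_planted_pos=0, n_planted_neg=0)
        degs = {}
        for v in ("RF", "PF"):
            c = sc.contrast_from_table(table, f"WFvs{v}", "WF", v, "bud")
            degs[v] = sc.call_degs(sc.log2_fold_change(table, c), c.name, "bud")
        res = sc.screen_candidates(degs["RF"], degs["PF"])
        assert res.n_candidates == 0


class TestDdct:
    def test_closed_form_fold_two(self):
        ct_target = {"w1": 25.0, "r1": 24.0}
        ct_ref = [{"w1": 20.0, "r1": 20.0}]
        folds = sc.ddct_fold_change(
            ct_target, ct_ref, {"WF": ["w1"], "RF": ["r1"]}, "WF"
        )
        assert folds["WF"] == pytest.approx(1.0)
        assert folds["RF"] == pytest.approx(2.0)  # ddCt = -1

    def test_two_references_averaged(self):
        # refs at 20 and 22: effective reference Ct 21
        ct_target = {"s": 24.0}
        refs = [{"s": 20.0}, {"s": 22.0}]
        folds = sc.ddct_fold_change(ct_target, refs, {"WF": ["s"]}, "WF")
        assert folds["WF"] == pytest.approx(1.0)  # calibrator identity

    def test_missing_ct_is_error(self):
        with pytest.raises(WrkykitError, match="s2"):
            sc.ddct_fold_change(
                {"s1": 20.0}, [{"s1": 19.0, "s2": 19.0}],
                {"WF": ["s1"], "RF": ["s2"]}, "WF",
            )


def oracle_upper_tail(N, K, n, k):
    """P(X >= k) summed with exact fractions."""
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return float(total)


class TestEnrichment:
    def test_k_zero_tail_is_one(self):
        res = sc.fisher_enrichment(
            {"a"}, {"a", "b", "c", "d"}, {"t": {"b", "c"}}
        )
        assert res[0].k == 0 and res[0].p == pytest.approx(1.0)

    def test_extreme_enrichment_significant(self):
        pop = {f"g{i}" for i in range(1000)}
        study = {f"g{i}" for i in range(5)}
        res = sc.fisher_enrichment(study, pop, {"t": set(study)})
        assert res[0].significant and res[0].p < 1e-10

    def test_matches_enumeration_oracle(self):
        """Random configurations up to N=2000 agree with the exact-fraction
        enumeration to 1e-12."""
        rng = np.random.default_rng(8)
        for _ in range(40):
            N = int(rng.integers(20, 2000))
            pop = {f"g{i}" for i in range(N)}
            n = int(rng.integers(1, min(60, N)))
            study = {f"g{i}" for i in rng.choice(N, size=n, replace=False)}
            K = int(rng.integers(1, N))
            term = {f"g{i}" for i in rng.choice(N, size=K, replace=False)}
            res = sc.fisher_enrichment(study, pop, {"t": term})
            r = res[0]
            assert r.p == pytest.approx(
                oracle_upper_tail(N, r.K, r.n, r.k), abs=1e-12
            )

    def test_bonferroni_properties(self):
        pop = {f"g{i}" for i in range(100)}
        study = {f"g{i}" for i in range(10)}
        terms = {f"t{j}": {f"g{i}" for i in range(j, j + 20)} for j in range(5)}
        res = sc.fisher_enrichment(study, pop, terms)
        for r in res:
            assert r.padj >= r.p and r.padj <= 1.0
        single = sc.fisher_enrichment(study, pop, {"t0": terms["t0"]})
        assert single[0].padj == pytest.approx(single[0].p)

    def test_study_outside_population_is_error(self):
        with pytest.raises(WrkykitError):
            sc.fisher_enrichment({"zz"}, {"a"}, {"t": {"a"}})
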