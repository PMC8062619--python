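"""Differential expression, BH adjustment, enrichment and efficacy tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

import aktx
from conftest import bh_bruteforce, make_norm


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        out = aktx.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_hand_computed_with_monotonicity(self):
        out = aktx.bh_adjust([0.01, 0.04, 0.03])
        assert np.allclose(out, [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert aktx.bh_adjust([0.2]) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            aktx.bh_adjust([0.5, 1.5])

    def test_bruteforce_oracle_equivalence(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 51)))
            assert np.allclose(aktx.bh_adjust(p), bh_bruteforce(p))

    def test_bounds_against_raw_and_bonferroni(self):
        rng = np.random.default_rng(1)
        p = rng.random(40)
        adj = aktx.bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= np.minimum(p * p.size, 1.0) + 1e-12).all()


def _paired_norm(pre, post, genes=None):
    """Matrix with columns Pk_pre / Pk_post from per-gene value lists."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    n_genes, n_pat = pre.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    cols, data = [], []
    for j in range(n_pat):
        cols += [f"P{j:02d}_pre", f"P{j:02d}_post"]
    values = np.empty((n_genes, 2 * n_pat))
    values[:, 0::2] = pre
    values[:, 1::2] = post
    df = pd.DataFrame(values, index=genes, columns=cols)
    ann = []
    for j in range(n_pat):
        for tp in ("pre", "post"):
            ann.append(
                aktx.SampleAnnotation(
                    sample_id=f"P{j:02d}_{tp}", patient_id=f"P{j:02d}", timepoint=tp,
                    response="IR", adverse_event="no",
                    lesion_count_lmax=5, lesion_count_week14=2,
                )
            )
    return make_norm(df), ann


class TestPairedDe:
    def test_null_identity_post_equals_pre(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(2, 10, size=(6, 4))
        norm, ann = _paired_norm(x, x)
        res = aktx.paired_de(norm, ann)
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["p_value"], 1.0)

    def test_p_matches_t_distribution_oracle(self):
        rng = np.random.default_rng(5)
        pre = rng.uniform(2, 10, size=(20, 8))
        post = pre + rng.normal(0.3, 0.5, size=pre.shape)
        norm, ann = _paired_norm(pre, post)
        res = aktx.paired_de(norm, ann)
        d = post - pre
        n = d.shape[1]
        t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n))
        p = 2 * stats.t.cdf(-np.abs(t), df=n - 1)
        assert np.allclose(res.loc[[f"g{i}" for i in range(20)], "p_value"], p)
        assert np.allclose(res.loc[[f"g{i}" for i in range(20)], "log2fc"], d.mean(axis=1))

    def test_direction_consistent_with_sign(self):
        rng = np.random.default_rng(2)
        pre = rng.uniform(4, 8, size=(10, 6))
        post = pre + rng.normal(0, 1, size=pre.shape)
        norm, ann = _paired_norm(pre, post)
        res = aktx.paired_de(norm, ann)
        nz = res[res["log2fc"] != 0]
        assert ((nz["log2fc"] > 0) == (nz["direction"] == "up")).all()
        assert (res["adj_p"] >= res["p_value"] - 1e-12).all()

    def test_too_few_pairs_errors(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(2, 10, size=(3, 1))
        norm, ann = _paired_norm(x, x)
        with pytest.raises(aktx.DesignError):
            aktx.paired_de(norm, ann)

    def test_lod_genes_reported_untested(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(2, 10, size=(4, 3))
        x[0] = 0.0
        norm, ann = _paired_norm(x, x)
        norm = aktx.NormalizedMatrix(
            values=norm.values, lod_zeroed=frozenset(["g0"]),
            scale_factors=norm.scale_factors, log2=True,
        )
        res = aktx.paired_de(norm, ann)
        assert "g0" not in res.index
        assert res.attrs["untested"] == ("g0",)


def _group_norm(cr, ir, genes=None):
    cr = np.asarray(cr, dtype=float)
    ir = np.asarray(ir, dtype=float)
    genes = genes or [f"g{i}" for i in range(cr.shape[0])]
    cols = [f"C{j}_pre" for j in range(cr.shape[1])] + [
        f"I{j}_pre" for j in range(ir.shape[1])
    ]
    df = pd.DataFrame(np.hstack([cr, ir]), index=genes, columns=cols)
    ann = []
    for j in range(cr.shape[1]):
        ann.append(aktx.SampleAnnotation(f"C{j}_pre", f"C{j}", "pre", "CR", "yes", 5, 0))
    for j in range(ir.shape[1]):
        ann.append(aktx.SampleAnnotation(f"I{j}_pre", f"I{j}", "pre", "IR", "no", 5, 2))
    return make_norm(df), ann


class TestGroupDe:
    def test_shifted_group_detected_with_direction(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(5, 6, size=(5, 9))
        cr = base[:, :4].copy()
        cr[0] += 3.0  # g0 strongly up in CR
        norm, ann = _group_norm(cr, base[:, 4:])
        res = aktx.group_de(norm, ann, grouping="response")
        assert res.index[0] == "g0"
        assert res.loc["g0", "p_value"] < 0.01
        assert res.loc["g0", "direction"] == "up"
        assert res["p_value"].is_monotonic_increasing

    def test_welch_matches_scipy_per_gene(self):
        rng = np.random.default_rng(4)
        cr = rng.normal(5, 1, size=(12, 5))
        ir = rng.normal(5, 2, size=(12, 9))
        norm, ann = _group_norm(cr, ir)
        res = aktx.group_de(norm, ann, grouping="response")
        for i in (0, 5, 11):
            t, p = stats.ttest_ind(cr[i], ir[i], equal_var=False)
            assert res.loc[f"g{i}", "p_value"] == pytest.approx(p)
            assert res.loc[f"g{i}", "log2fc"] == pytest.approx(cr[i].mean() - ir[i].mean())

    def test_adverse_event_grouping(self):
        rng = np.random.default_rng(6)
        cr = rng.normal(5, 1, size=(4, 4))
        ir = rng.normal(5, 1, size=(4, 5))
        norm, ann = _group_norm(cr, ir)
        res = aktx.group_de(norm, ann, grouping="adverse_event")
        assert len(res) == 4  # AE == CR columns in this fixture

    def test_small_group_errors(self):
        rng = np.random.default_rng(0)
        norm, ann = _group_norm(rng.normal(5, 1, (3, 1)), rng.normal(5, 1, (3, 6)))
        with pytest.raises(aktx.DesignError):
            aktx.group_de(norm, ann, grouping="response")

    def test_type_one_error_near_nominal_under_null(self):
        """Fraction of p < 0.05 over ~1000 null genes within [0.035, 0.065]."""
        manifest = aktx.generate_panel(
            aktx.PanelConfig(n_base_endogenous=1000, n_housekeeping=30, n_spike_in=0)
        )
        sim = aktx.SimulationConfig(
            n_patients=20, n_matched_pairs=20, frac_cr=0.5, frac_ae=0.5,
            n_de_genes_response=0, n_de_genes_treatment=0, seed=12,
        )
        counts, ann, _ = aktx.simulate_counts(manifest, sim)
        norm = aktx.normalize(counts, manifest, log_transform=True)
        res = aktx.group_de(norm, ann, genes=manifest.measured_genes)
        frac = (res["p_value"] < 0.05).mean()
        assert 0.035 < frac < 0.065


class TestDeCountEnrichment:
    def test_printed_study_counts_are_highly_enriched(self):
        assert aktx.de_count_enrichment(103, 788, 0.05) < 0.001

    def test_zero_significant_gives_one(self):
        assert aktx.de_count_enrichment(0, 788, 0.05) == 1.0

    def test_matches_bruteforce_pmf_sum(self):
        n, total, alpha = 39, 788, 0.05
        expected = sum(
            comb(total, k, exact=True) * alpha**k * (1 - alpha) ** (total - k)
            for k in range(n, total + 1)
        )
        assert aktx.de_count_enrichment(n, total, alpha) == pytest.approx(expected, rel=1e-9)

    def test_monotone_decreasing_in_count(self):
        ps = [aktx.de_count_enrichment(k, 100, 0.05) for k in range(0, 30, 3)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            aktx.de_count_enrichment(5, 10, 1.5)


class TestLesionReduction:
    def test_hand_computed_t(self):
        """diffs (4, 3): mean 3.5, sd ~0.7071 -> t = 7.0 exactly."""
        res = aktx.lesion_reduction_test([5, 3], [1, 0])
        assert res.statistic == pytest.approx(7.0)
        assert res.df == 1
        assert res.tails == "two"

    def test_no_change_gives_t0_p1(self):
        res = aktx.lesion_reduction_test([4, 6, 2], [4, 6, 2])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            lmax = rng.integers(1, 20, size=12)
            week = rng.integers(0, 20, size=12)
            if (lmax - week).std(ddof=1) == 0:
                continue
            res = aktx.lesion_reduction_test(lmax, week)
            d = lmax - week
            t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
            assert res.statistic == pytest.approx(t)
            assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), d.size - 1))

    def test_from_annotations_uses_unique_patients(self, small_run):
        _, ann, _ = small_run
        res = aktx.lesion_reduction_from_annotations(ann)
        n_patients = len({a.patient_id for a in ann})
        assert res.df == n_patients - 1
        assert res.statistic > 0
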