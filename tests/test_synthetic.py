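"""Generators: panel structure, count model, lesions, networks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import aktx
from aktx.synthetic import ConfigurationError


class TestPanel:
    def test_default_panel_has_788_measured_genes(self, default_manifest):
        assert len(default_manifest.measured_genes) == 788
        assert len(default_manifest.genes_of_class("endogenous")) == 730
        assert len(default_manifest.housekeeping_genes) == 40
        assert len(default_manifest.genes_of_class("spike_in")) == 18

    def test_minimal_panel_counts(self):
        m = aktx.generate_panel(
            aktx.PanelConfig(n_base_endogenous=1, n_housekeeping=1, n_spike_in=0)
        )
        assert len(m.measured_genes) == 2
        assert m.genes_of_class("endogenous") == ("GENE0001",)
        assert m.genes_of_class("housekeeping") == ("HK01",)

    def test_positive_ladder_strictly_decreasing(self, default_manifest):
        conc = [
            default_manifest.positive_control(l).nominal_concentration for l in "ABCDEF"
        ]
        assert all(a > b for a, b in zip(conc, conc[1:]))
        # geometric with ratio 1/4
        ratios = [b / a for a, b in zip(conc, conc[1:])]
        assert np.allclose(ratios, 0.25)

    def test_same_seed_identical(self):
        a = aktx.generate_panel(aktx.PanelConfig(seed=5))
        b = aktx.generate_panel(aktx.PanelConfig(seed=5))
        assert a == b

    @pytest.mark.parametrize("kwargs", [{"n_base_endogenous": 0}, {"n_pos_controls": 7}])
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            aktx.PanelConfig(**kwargs)


class TestCounts:
    def test_determinism(self, small_manifest):
        sim = aktx.SimulationConfig(n_patients=6, n_matched_pairs=4, seed=11,
                                    n_de_genes_response=2, n_de_genes_treatment=1)
        c1, a1, t1 = aktx.simulate_counts(small_manifest, sim)
        c2, a2, t2 = aktx.simulate_counts(small_manifest, sim)
        assert c1.equals(c2)
        assert a1 == a2
        assert t1.response_effects == t2.response_effects

    def test_counts_nonnegative_integers(self, small_run):
        counts, _, _ = small_run
        assert (counts.to_numpy() >= 0).all()
        assert counts.dtypes.map(lambda d: np.issubdtype(d, np.integer)).all()

    def test_null_model_group_difference_centered_at_zero(self, small_manifest):
        """No planted effects: per-gene CR-IR log2 mean difference ~ 0."""
        sim = aktx.SimulationConfig(
            n_patients=12, n_matched_pairs=12, frac_cr=0.5,
            n_de_genes_response=0, n_de_genes_treatment=0, log2fc_effect=0.0, seed=3,
        )
        counts, ann, _ = aktx.simulate_counts(small_manifest, sim)
        pre = [a for a in ann if a.timepoint == "pre"]
        cr = [a.sample_id for a in pre if a.response == "CR"]
        ir = [a.sample_id for a in pre if a.response == "IR"]
        # normalization removes the shared library-size offset between groups
        norm = aktx.normalize(counts, small_manifest, log_transform=True)
        tested = [g for g in small_manifest.measured_genes if g not in norm.lod_zeroed]
        X = norm.values.loc[tested]
        diff = X[cr].mean(axis=1) - X[ir].mean(axis=1)
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se

    def test_cohort_structure(self, small_run):
        _, ann, truth = small_run
        per_patient = {}
        for a in ann:
            per_patient.setdefault(a.patient_id, []).append(a.timepoint)
        for tps in per_patient.values():
            assert len(tps) == len(set(tps)) <= 2
        assert len(truth.matched_patients) == 8
        for a in ann:
            assert (a.response == "CR") == (a.lesion_count_week14 == 0)
            assert a.lesion_count_week14 <= a.lesion_count_lmax

    def test_planted_effects_only_on_measured_noncontrol_genes(self, small_run):
        _, _, truth = small_run
        planted = set(truth.response_effects) | set(truth.treatment_effects)
        assert all(g.startswith(("GENE", "SPK")) for g in planted)

    def test_housekeeping_low_variance(self, small_manifest):
        sim = aktx.SimulationConfig(n_patients=10, n_matched_pairs=10, seed=2,
                                    n_de_genes_response=0, n_de_genes_treatment=0,
                                    library_size_cv=0.0)
        counts, _, _ = aktx.simulate_counts(small_manifest, sim)
        hk = counts.loc[list(small_manifest.housekeeping_genes)]
        endo = counts.loc[list(small_manifest.genes_of_class("endogenous"))]
        cv_hk = (hk.std(axis=1) / hk.mean(axis=1)).median()
        cv_endo = (endo.std(axis=1) / endo.mean(axis=1)).median()
        assert cv_hk < cv_endo


class TestLesions:
    def test_full_clearance_forces_cr(self):
        df = aktx.simulate_lesion_counts(10, mean_lmax=8, clearance_prob=1.0, seed=0)
        assert (df["week14"] == 0).all()

    def test_week14_bounded_by_lmax(self):
        df = aktx.simulate_lesion_counts(200, mean_lmax=6, clearance_prob=0.4, seed=1)
        assert (df["week14"] <= df["lmax"]).all()
        assert (df["lmax"] >= 1).all()

    def test_empty_cohort(self):
        df = aktx.simulate_lesion_counts(0, mean_lmax=5, clearance_prob=0.5, seed=0)
        assert len(df) == 0

    def test_null_mode_type_one_error_near_nominal(self):
        """Paired t on exchangeable (lmax, week14) rejects at ~5%."""
        rejections = 0
        reps = 1000
        for seed in range(reps):
            df = aktx.simulate_lesion_counts(
                12, mean_lmax=8, clearance_prob=0.0, seed=seed, null=True
            )
            res = aktx.lesion_reduction_test(df["lmax"], df["week14"])
            rejections += res.p_value < 0.05
        assert 0.03 < rejections / reps < 0.075

    def test_bad_config(self):
        with pytest.raises(ConfigurationError):
            aktx.simulate_lesion_counts(5, mean_lmax=-1, clearance_prob=0.5, seed=0)


class TestNetworkGenerator:
    def test_single_undirected_edge_expands_to_pair(self):
        net, _ = aktx.generate_background_network(2, 0, 1, seed=0)
        assert net.n_edges == 2
        a, b = net.edges
        assert a.pair_id == b.pair_id is not None
        assert (a.source, a.target) == (b.target, b.source)

    def test_planted_hub_out_degree(self):
        net, truth = aktx.generate_background_network(
            50, 30, 10, planted_hubs=[{"hub_size": 10}], seed=4
        )
        (hub, children), = truth.hub_children.items()
        assert len(net.out_edges(hub)) >= 10
        assert set(children) <= {e.target for e in net.out_edges(hub)}

    def test_determinism(self):
        a, _ = aktx.generate_background_network(30, 40, 15, seed=9)
        b, _ = aktx.generate_background_network(30, 40, 15, seed=9)
        assert a == b

    def test_oversized_hub_rejected(self):
        with pytest.raises(ConfigurationError):
            aktx.generate_background_network(5, 0, 0, planted_hubs=[{"hub_size": 5}])
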