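"""Determinism, spatial structure, niche generation and error bookkeeping."""

import numpy as np
import pytest

from c3c4niche import contrast_tests as ct
from c3c4niche import occurrence_qc as qc
from c3c4niche import synthetic_world as sw


class TestMakeWorld:
    def test_same_seed_bit_identical(self):
        w1 = sw.make_world(sw.WorldConfig(seed=4))
        w2 = sw.make_world(sw.WorldConfig(seed=4))
        np.testing.assert_array_equal(w1.tmean.layers, w2.tmean.layers)
        np.testing.assert_array_equal(w1.prec.layers, w2.prec.layers)
        np.testing.assert_array_equal(w1.soils["pH"].values, w2.soils["pH"].values)

    def test_different_seed_differs(self):
        w1 = sw.make_world(sw.WorldConfig(seed=4))
        w2 = sw.make_world(sw.WorldConfig(seed=5))
        assert not np.array_equal(w1.tmean.layers, w2.tmean.layers)

    def test_equator_warmer_than_high_latitude(self, default_world):
        layers = default_world.env_layers()
        mat = layers["MAT"]
        spec = mat.spec
        eq_row = spec.index_of(1.0, 0.0)[0]
        cold_row = spec.index_of(65.0, 0.0)[0]
        assert mat.values[eq_row].mean() > mat.values[cold_row].mean() + 10

    def test_seasonal_amplitude_grows_with_latitude(self, default_world):
        t = default_world.tmean.layers
        spec = default_world.tmean.spec
        eq_row = spec.index_of(1.0, 0.0)[0]
        far_row = spec.index_of(65.0, 0.0)[0]
        amp = t.max(axis=0) - t.min(axis=0)
        assert amp[far_row].mean() > amp[eq_row].mean() + 5

    def test_soil_fields_within_plausible_ranges(self, default_world):
        ranges = {"organic_carbon": (0, 40), "TEB": (0, 80), "CEC": (0, 90), "pH": (3, 10)}
        for var, (lo, hi) in ranges.items():
            vals = default_world.soils[var].values
            assert vals.min() >= lo and vals.max() <= hi

    def test_neighbor_correlation_increases_with_smoothing(self):
        def moran_like(seed, scale):
            w = sw.make_world(sw.WorldConfig(seed=seed, smoothing_cells=scale,
                                             temperature_noise_sd=5.0))
            f = w.soils["pH"].values
            a = f - f.mean()
            return float(
                (a[:, :-1] * a[:, 1:]).mean()
                / (a.std() ** 2)
            )
        rough = np.mean([moran_like(s, 0.0) for s in range(3)])
        smooth = np.mean([moran_like(s, 4.0) for s in range(3)])
        assert smooth > rough + 0.3

    def test_ocean_blobs_when_requested(self):
        w = sw.make_world(sw.WorldConfig(seed=4, ocean_fraction=0.3))
        frac = 1.0 - w.mask.values.mean()
        assert 0.2 < frac < 0.4


class TestSimulateLineages:
    def test_zero_sigma_s_shares_one_optimum_per_type(self, default_world):
        lc = sw.LineageConfig(seed=3, n_lineages=3, sigma_S=0.0,
                              fraction_without_c4=0.0)
        groups, truth = sw.simulate_lineages(lc, default_world)
        g = groups[0]
        for t in ("C3", "C3-C4", "C4"):
            opts = [tuple(truth.species_optima[s].values()) for s in g.members[t]]
            assert len(set(opts)) == 1

    def test_zero_lineage_spread_decorrelates_sisters(self):
        # rho = 0: focal and reference group values share nothing but noise
        lc = sw.LineageConfig(seed=3, n_lineages=60, sigma_L=0.0,
                              fraction_without_c4=0.0)
        groups, truth = sw.simulate_lineages(lc)
        gns = truth.group_niches(groups)
        pairs = ct.build_contrasts(gns, "C3C4_vs_C3_all", "growing_season_temperature")
        tau, _ = ct.kendall_tau([p.reference for p in pairs], [p.focal for p in pairs])
        assert abs(tau) < 0.3

    def test_high_conservatism_yields_positive_tau(self):
        # rho = 0.9 -> sigma_L = 3 sigma_S; tau positive in >95% of seeds
        positive = 0
        for s in range(200):
            lc = sw.LineageConfig(seed=5000 + s, n_lineages=15, sigma_L=3.0,
                                  sigma_S=1.0, fraction_without_c4=0.0)
            groups, truth = sw.simulate_lineages(lc)
            gns = truth.group_niches(groups)
            pairs = ct.build_contrasts(
                gns, "C3C4_vs_C3_all", "growing_season_temperature"
            )
            tau, _ = ct.kendall_tau(
                [p.reference for p in pairs], [p.focal for p in pairs]
            )
            positive += tau > 0
        assert positive / 200 > 0.95

    def test_fraction_without_c4(self):
        lc = sw.LineageConfig(seed=3, n_lineages=19, fraction_without_c4=5 / 19)
        groups, _ = sw.simulate_lineages(lc)
        assert sum(not g.has_C4_sister for g in groups) == 5

    def test_unknown_delta_variable_rejected(self):
        lc = sw.LineageConfig(seed=3, delta_c3c4={"bogus_variable": 1.0})
        with pytest.raises(ValueError, match="unknown variables"):
            sw.simulate_lineages(lc)

    def test_determinism(self):
        lc = sw.LineageConfig(seed=8, n_lineages=4)
        _, t1 = sw.simulate_lineages(lc)
        _, t2 = sw.simulate_lineages(lc)
        assert t1.species_optima == t2.species_optima


class TestSimulateOccurrences:
    def test_error_counts_match_rates_exactly(self, qc_bundle):
        truth, lc = qc_bundle["truth"], qc_bundle["config"]
        n = truth.n_clean_records
        kinds = [e["kind"] for e in truth.injected_errors]
        assert kinds.count("duplicate") == round(lc.duplicate_rate * n)
        assert kinds.count("off_land") == round(lc.off_land_rate * n)
        assert kinds.count("institution_proximity") == round(lc.institution_rate * n)
        assert kinds.count("out_of_range") == round(lc.out_of_range_rate * n)

    def test_qc_recovers_all_injected_errors_without_false_drops(self, qc_bundle):
        records = qc_bundle["records"]
        truth = qc_bundle["truth"]
        cleaned, _ = qc.clean(records, qc_bundle["world"].mask, qc.QcConfig())
        clean_part = cleaned[: truth.n_clean_records]
        error_part = cleaned[truth.n_clean_records:]
        assert sum(not r.retained for r in clean_part) == 0
        recovered = sum(not r.retained for r in error_part)
        assert recovered / len(error_part) >= 0.99

    def test_round_trip_through_qc_reader_bit_exact(self, qc_bundle, tmp_path):
        records = qc_bundle["records"]
        path = tmp_path / "occ.csv"
        qc.write_occurrences(records, path, include_qc=False)
        back = qc.read_occurrences(path)
        assert len(back) == len(records)
        for a, b in zip(records[:500], back[:500]):
            assert a.taxon == b.taxon
            assert a.latitude == b.latitude and a.longitude == b.longitude

    def test_narrow_kernel_concentrates_on_best_cells(self, default_world):
        lc = sw.LineageConfig(
            seed=5, n_lineages=1, species_per_type=1, fraction_without_c4=1.0,
            occurrences_per_species=50, tau={"MAT": 1e-8},
            duplicate_rate=0, off_land_rate=0, institution_rate=0, out_of_range_rate=0,
        )
        groups, truth = sw.simulate_lineages(lc, default_world)
        records = sw.simulate_occurrences(groups, truth, default_world, lc)
        mat = default_world.env_layers()["MAT"]
        sp = groups[0].members["C3"][0]
        opt = truth.species_optima[sp]["MAT"]
        vals = [
            mat.value_at(r.latitude, r.longitude)
            for r in records if r.taxon == sp
        ]
        # all samples land in cells whose MAT is essentially the optimum
        assert np.nanmax(np.abs(np.array(vals) - opt)) < 1e-6

    def test_determinism_of_records(self, default_world):
        lc = sw.LineageConfig(seed=6, n_lineages=2, occurrences_per_species=10)
        g1, t1 = sw.simulate_lineages(lc, default_world)
        r1 = sw.simulate_occurrences(g1, t1, default_world, lc)
        g2, t2 = sw.simulate_lineages(lc, default_world)
        r2 = sw.simulate_occurrences(g2, t2, default_world, lc)
        assert [(a.taxon, a.latitude, a.longitude) for a in r1] == [
            (b.taxon, b.latitude, b.longitude) for b in r2
        ]


class TestRecoverParameters:
    def test_more_occurrences_reduce_median_error(self, default_world):
        from c3c4niche import env_extraction as ee
        from c3c4niche import niche_summary as ns

        means = {}
        for n_occ in (20, 200):
            lc = sw.LineageConfig(
                seed=21, n_lineages=6, fraction_without_c4=0.0,
                occurrences_per_species=n_occ,
                duplicate_rate=0, off_land_rate=0, institution_rate=0,
                out_of_range_rate=0,
            )
            groups, truth = sw.simulate_lineages(lc, default_world)
            records = sw.simulate_occurrences(groups, truth, default_world, lc)
            cleaned, _ = qc.clean(records, default_world.mask, qc.QcConfig())
            matrix = ee.assemble_env_matrix(cleaned, default_world.env_layers())
            rep = sw.recover_parameters(ns.all_species_medians(matrix), truth, lc)
            errs = [e["abs_error_tau"] for e in rep["median_errors"]]
            means[n_occ] = float(np.mean(errs))
        assert means[200] < means[20]

    def test_realized_rho_tracks_configuration(self):
        lc = sw.LineageConfig(seed=23, n_lineages=200, species_per_type=4,
                              sigma_L=1.0, sigma_S=1.0, fraction_without_c4=0.0)
        _, truth = sw.simulate_lineages(lc)
        rep = sw.recover_parameters({}, truth, lc)
        rhos = [v["rho"] for v in rep["realized_variance"].values()]
        assert rep["configured_rho"] == pytest.approx(0.5)
        assert np.mean(rhos) == pytest.approx(0.5, abs=0.1)
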