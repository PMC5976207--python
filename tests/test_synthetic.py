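"""Simulator unit tests: event placement, bivalent resolution, foci, qPCR."""

import numpy as np
import pytest

import ftlmap as fm
from ftlmap.classify import classify_interval, tabulate
from ftlmap.linkage import perkins_distance

from conftest import make_tetrad


class TestEventPlacement:
    def test_zero_rate_gives_no_events(self, rng):
        assert fm.place_type1_events(50.0, 2.0, 0.0, rng).size == 0
        assert fm.place_type2_events(50.0, 0.0, rng).size == 0

    def test_negative_arguments_rejected(self, rng):
        with pytest.raises(ValueError):
            fm.place_type1_events(-1.0, 1.0, 1.0, rng)
        with pytest.raises(ValueError):
            fm.place_type1_events(10.0, 0.5, 1.0, rng)
        with pytest.raises(ValueError):
            fm.place_type2_events(10.0, -0.2, rng)

    def test_positions_sorted_within_interval(self, rng):
        for _ in range(200):
            pos = fm.place_type1_events(30.0, 4.0, 3.0, rng)
            assert np.all(pos >= 0) and np.all(pos <= 30.0)
            assert np.all(np.diff(pos) >= 0)

    def test_poisson_limit_mean_count(self, rng):
        """nu=1, rate 1 on 50 cM: count is Poisson(1); MC mean within 3 SE."""
        n = 10_000
        counts = [fm.place_type1_events(50.0, 1.0, 1.0, rng).size for _ in range(n)]
        se = np.sqrt(1.0 / n)
        assert abs(np.mean(counts) - 1.0) < 3 * se

    def test_interference_tightens_spacing(self, rng):
        """Gamma interarrival CV = 1/sqrt(nu): nu=10 spacing is more regular."""

        def interarrival_cv(nu):
            gaps = []
            for _ in range(4_000):
                pos = fm.place_type1_events(200.0, nu, 1.0, rng)
                gaps.extend(np.diff(pos))
            gaps = np.asarray(gaps)
            return gaps.std() / gaps.mean()

        cv1, cv10 = interarrival_cv(1.0), interarrival_cv(10.0)
        assert cv10 < cv1
        assert cv10 == pytest.approx(1 / np.sqrt(10), rel=0.15)
        assert cv1 == pytest.approx(1.0, rel=0.1)

    def test_type2_disjoint_counts_independent(self, rng):
        """Poisson process: counts on disjoint halves are uncorrelated."""
        left, right = [], []
        for _ in range(10_000):
            pos = fm.place_type2_events(20.0, 2.0, rng)
            left.append(np.sum(pos < 10.0))
            right.append(np.sum(pos >= 10.0))
        r = np.corrcoef(left, right)[0, 1]
        assert abs(r) < 0.05

    def test_type2_rate_doubling_doubles_mean(self, rng):
        n = 10_000
        m1 = np.mean([fm.place_type2_events(50.0, 1.0, rng).size for _ in range(n)])
        m2 = np.mean([fm.place_type2_events(50.0, 2.0, rng).size for _ in range(n)])
        assert m2 / m1 == pytest.approx(2.0, abs=0.15)


class TestResolveTetrad:
    def test_no_chiasmata_is_parental_ditype(self, two_marker_map, rng):
        t = fm.resolve_tetrad(np.array([]), two_marker_map, rng)
        full = sum(1 for g in t.grains if g == {"A", "B"})
        empty = sum(1 for g in t.grains if not g)
        assert (full, empty) == (2, 2)
        assert classify_interval(t, ("A", "B")) is fm.IntervalClass.PD

    def test_single_chiasma_is_tetratype(self, two_marker_map, rng):
        """One chiasma between the markers always yields a tetratype."""
        for _ in range(50):
            t = fm.resolve_tetrad(np.array([5.0]), two_marker_map, rng)
            assert classify_interval(t, ("A", "B")) is fm.IntervalClass.T

    def test_double_chiasma_pd_t_npd_1_2_1(self, two_marker_map, rng):
        """Two chiasmata, free chromatid choice: 2-/3-/4-strand doubles give
        PD:T:NPD = 1:2:1 (exact enumeration of the 16 strand choices)."""
        n = 12_000
        tallies = {"PD": 0, "T": 0, "NPD": 0, "OTHER": 0}
        for _ in range(n):
            t = fm.resolve_tetrad(np.array([3.0, 6.0]), two_marker_map, rng)
            tallies[classify_interval(t, ("A", "B")).value] += 1
        assert tallies["OTHER"] == 0
        for cls, expect in (("PD", 0.25), ("T", 0.5), ("NPD", 0.25)):
            se = np.sqrt(expect * (1 - expect) / n)
            assert abs(tallies[cls] / n - expect) < 4 * se


class TestTetradDataset:
    def test_both_pathways_off_all_pd(self, two_marker_map):
        cfg = fm.SimConfig(n_meioses=300, type1_active=False, type2_active=False)
        ds = fm.simulate_tetrad_dataset(cfg, two_marker_map)
        counts = tabulate(ds, ("A", "B"))
        assert (counts.PD, counts.T, counts.NPD, counts.OTHER) == (300, 0, 0, 0)

    def test_seeded_determinism(self, two_marker_map):
        cfg = fm.SimConfig(n_meioses=500, seed=42)
        a = fm.simulate_tetrad_dataset(cfg, two_marker_map)
        b = fm.simulate_tetrad_dataset(cfg, two_marker_map)
        assert np.array_equal(a.alleles, b.alleles)

    def test_perkins_recovery_10cM(self, two_marker_map, poisson_config):
        """Estimated distance on simulated data within 3 SE of configured."""
        ds = fm.simulate_tetrad_dataset(poisson_config(10_000, seed=7), two_marker_map)
        res = perkins_distance(tabulate(ds, ("A", "B")))
        assert abs(res.X - 10.0) < 3 * res.SE

    def test_rate_factor_scales_distance(self, two_marker_map, poisson_config):
        """type1_rate_factor 1.0 -> 1.5 raises the distance by the Type I share."""
        r1 = perkins_distance(tabulate(
            fm.simulate_tetrad_dataset(
                poisson_config(10_000, seed=8), two_marker_map), ("A", "B")))
        r15 = perkins_distance(tabulate(
            fm.simulate_tetrad_dataset(
                poisson_config(10_000, seed=9, type1_rate_factor=1.5),
                two_marker_map), ("A", "B")))
        expected = 10.0 * (0.85 * 1.5 + 0.15)
        se = np.hypot(r1.SE, r15.SE)
        assert abs(r15.X - expected) < 3 * r15.SE
        assert r15.X - r1.X > 2 * se  # clear increase

    def test_dataset_sequence_protocol(self, two_marker_map):
        ds = fm.simulate_tetrad_dataset(fm.SimConfig(n_meioses=10), two_marker_map)
        assert len(ds) == 10
        assert isinstance(ds[0], fm.Tetrad)
        assert len(list(ds)) == 10


class TestFoci:
    def test_dsb_mean_recovered(self, rng):
        cfg = fm.SimConfig(dsb_mean=200.0)
        recs = fm.simulate_foci_dataset(cfg, 10_000, "gH2AX", rng)
        mean = np.mean([r.count for r in recs])
        assert abs(mean - 200.0) < 3 * np.sqrt(200.0 / 10_000)

    def test_spo11_scenario_scales_dsbs(self, rng):
        cfg = fm.scenario_config("spo11", "20C")
        recs = fm.simulate_foci_dataset(cfg, 10_000, "gH2AX", rng)
        assert np.mean([r.count for r in recs]) == pytest.approx(20.0, abs=0.5)

    def test_dsb_homeostasis(self, rng):
        """gH2AX mean does not move with the Type I rate factor."""
        m = []
        for factor in (1.0, 1.5):
            cfg = fm.SimConfig(type1_rate_factor=factor)
            recs = fm.simulate_foci_dataset(cfg, 10_000, "gH2AX", rng)
            m.append(np.mean([r.count for r in recs]))
        assert abs(m[0] - m[1]) < 4 * np.sqrt(2 * 200.0 / 10_000)

    def test_mlh1_tracks_type1_pathway(self, rng):
        """MLH1 foci follow the Type I rate; msh4 leaves only background."""
        base = fm.simulate_foci_dataset(fm.SimConfig(), 5_000, "MLH1", rng)
        up = fm.simulate_foci_dataset(
            fm.SimConfig(type1_rate_factor=1.5), 5_000, "MLH1", rng)
        off = fm.simulate_foci_dataset(
            fm.SimConfig(type1_active=False), 5_000, "MLH1", rng)
        mean = lambda rs: np.mean([r.count for r in rs])
        assert mean(up) > mean(base) * 1.3
        assert mean(off) == pytest.approx(0.5, abs=0.1)  # background only

    def test_unknown_antibody_rejected(self, rng):
        with pytest.raises(ValueError):
            fm.simulate_foci_dataset(fm.SimConfig(), 10, "HEI10", rng)


class TestViability:
    def test_mean_recovery_and_nonnegativity(self, rng):
        counts = fm.simulate_pollen_viability(5_000, 665.7, rng)
        assert counts.min() >= 0
        # gamma-Poisson: var = mu + mu^2/shape
        se = np.sqrt((665.7 + 665.7**2 / 16.0) / 5_000)
        assert abs(counts.mean() - 665.7) < 4 * se


class TestQpcr:
    def test_no_effects_fold_near_one(self, rng):
        from ftlmap.group_stats import ddct_fold_change, delta_ct

        plate = fm.simulate_qpcr_plate({}, 24, 3, rng)
        dct = delta_ct(plate, "BHLH122", "TUB4")
        res = ddct_fold_change(dct, "0mM")
        for t, fold in res.fold_change.items():
            assert fold == pytest.approx(1.0, abs=0.35)

    def test_log2fc_3_recovered_as_fold_8(self, rng):
        from ftlmap.group_stats import ddct_fold_change, delta_ct

        effects = {"BHLH122": {"200mM": 3.0}}
        plate = fm.simulate_qpcr_plate(effects, 24, 3, rng)
        res = ddct_fold_change(delta_ct(plate, "BHLH122", "TUB4"), "0mM")
        assert res.fold_change["200mM"] == pytest.approx(8.0, rel=0.25)

    def test_control_gene_ct_invariant_across_treatments(self, rng):
        plate = fm.simulate_qpcr_plate(fm.SALT_TREATMENT_LOG2FC, 24, 3, rng)
        by_treatment = {}
        for r in plate:
            if r.gene == "TUB4":
                by_treatment.setdefault(r.treatment, []).append(r.ct)
        means = [np.mean(v) for v in by_treatment.values()]
        assert max(means) - min(means) < 0.3  # cycles; noise only

    def test_control_gene_effects_rejected(self, rng):
        with pytest.raises(ValueError):
            fm.simulate_qpcr_plate({"TUB4": {"200mM": 1.0}}, 3, 3, rng)


class TestScenarios:
    def test_scenario_switches(self):
        assert not fm.scenario_config("msh4", "20C").type1_active
        assert not fm.scenario_config("mus81", "28C").type2_active
        assert fm.scenario_config("fancm", "20C").type2_scale == 10.0
        spo = fm.scenario_config("spo11", "20C")
        assert spo.spo11 and spo.dsb_scale == pytest.approx(0.1)
        assert fm.scenario_config("WT", "28C").type1_rate_factor == pytest.approx(1.228)

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            fm.scenario_config("zip4", "20C")
        with pytest.raises(ValueError):
            fm.scenario_config("WT", "25C")

    def test_config_validation(self):
        with pytest.raises(ValueError):
            fm.SimConfig(interference_shape=0.5)
        with pytest.raises(ValueError):
            fm.SimConfig(type1_rate_factor=-1.0)
        with pytest.raises(ValueError):
            fm.MarkerMap.from_tuples([("a", "A", 0.0)])
        with pytest.raises(ValueError):
            fm.MarkerMap.from_tuples([("a", "A", 0.0), ("b", "A", 5.0)])
        with pytest.raises(ValueError):
            fm.MarkerMap.from_tuples([("a", "A", 5.0), ("b", "B", 5.0)])
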