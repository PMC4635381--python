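"""The three-value log score, interpretation bands, and re-identification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import archaeotype as at

from conftest import make_peak_list, make_reference


class TestScore:
    def test_identical_candidate_scores_exactly_three(self):
        mzs = [3000.0, 6000.0, 9000.0, 12000.0]
        intens = [10.0, 40.0, 20.0, 30.0]
        ref = make_reference(mzs, intens)
        res = at.score(make_peak_list(mzs, intens), ref)
        assert (res.v1, res.v2, res.v3) == (1.0, 1.0, 1.0)
        assert res.score == 3.0

    def test_no_matches_floors_at_zero(self):
        ref = make_reference([3000.0, 6000.0, 9000.0])
        cand = make_peak_list([4000.0, 7000.0, 10000.0])
        res = at.score(cand, ref)
        assert res.v1 == res.v2 == 0.0
        assert res.score == 0.0
        assert res.band == at.BAND_UNRELIABLE

    def test_three_of_four_peaks_with_proportional_intensities(self):
        ref = make_reference([3000.0, 6000.0, 9000.0, 12000.0],
                             [10.0, 40.0, 20.0, 30.0])
        # candidate carries the 3 tallest reference peaks, intensities x2
        cand = make_peak_list([6000.0, 9000.0, 12000.0], [80.0, 40.0, 60.0])
        res = at.score(cand, ref)
        assert res.v1 == 0.75
        assert res.v2 == 1.0
        assert res.v3 == 1.0
        assert res.score == pytest.approx(math.log10(750.0), abs=1e-12)

    def test_empty_inputs_rejected(self):
        ref = make_reference([3000.0])
        with pytest.raises(at.InputError):
            at.score(at.PeakList(peaks=()), ref)
        with pytest.raises(at.InputError):
            at.score(
                make_peak_list([3000.0]),
                at.ReferenceSpectrum(strain_id="e", peaks=(), n_replicates_used=1),
            )

    def test_fewer_than_three_matches_zero_symmetry(self):
        ref = make_reference([3000.0, 6000.0], [10.0, 20.0])
        res = at.score(make_peak_list([3000.0, 6000.0], [10.0, 20.0]), ref)
        assert res.v3 == 0.0

    def test_anticorrelated_intensities_clamp_to_zero(self):
        mzs = [3000.0, 6000.0, 9000.0, 12000.0]
        ref = make_reference(mzs, [10.0, 20.0, 30.0, 40.0])
        res = at.score(make_peak_list(mzs, [40.0, 30.0, 20.0, 10.0]), ref)
        assert res.v3 == 0.0
        assert res.score == 0.0

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=25)
    def test_scale_invariant_in_candidate_intensities(self, scale):
        mzs = [3000.0, 6000.0, 9000.0, 12000.0, 15000.0]
        intens = [10.0, 40.0, 20.0, 30.0, 25.0]
        ref = make_reference(mzs, intens)
        base = at.score(make_peak_list(mzs, intens), ref)
        scaled = at.score(
            make_peak_list(mzs, [v * scale for v in intens]), ref
        )
        assert scaled.score == base.score

    @pytest.mark.parametrize("seed", range(10))
    def test_score_bounded_and_three_only_at_perfection(self, seed):
        rng = np.random.default_rng(seed)
        ref = make_reference(np.sort(rng.uniform(2500, 19000, 15)),
                             rng.uniform(10, 100, 15))
        cand = make_peak_list(np.sort(rng.uniform(2500, 19000, 15)),
                              rng.uniform(10, 100, 15))
        res = at.score(cand, ref)
        assert 0.0 <= res.score <= 3.0
        if res.score == 3.0:
            assert res.v1 == res.v2 == res.v3 == 1.0

    def test_removing_matched_candidate_peak_never_increases_v1(self):
        mzs = [3000.0, 6000.0, 9000.0, 12000.0, 15000.0]
        intens = [10.0, 40.0, 20.0, 30.0, 25.0]
        ref = make_reference(mzs, intens)
        full = at.score(make_peak_list(mzs, intens), ref)
        for drop in range(len(mzs)):
            sub = [m for k, m in enumerate(mzs) if k != drop]
            si = [v for k, v in enumerate(intens) if k != drop]
            res = at.score(make_peak_list(sub, si), ref)
            assert res.v1 <= full.v1


class TestBand:
    @pytest.mark.parametrize("value,expected", [
        (3.00, at.BAND_SPECIES),
        (2.30, at.BAND_SPECIES),
        (2.29, at.BAND_GENUS),
        (2.00, at.BAND_GENUS),
        (1.99, at.BAND_UNRELIABLE),
        (0.00, at.BAND_UNRELIABLE),
    ])
    def test_band_boundaries(self, value, expected):
        assert at.band(value) == expected

    @pytest.mark.parametrize("value", [-0.1, 3.01])
    def test_out_of_range_rejected(self, value):
        with pytest.raises(at.InputError):
            at.band(value)


class TestIdentify:
    def test_single_entry_library(self):
        ref = make_reference([3000.0, 6000.0, 9000.0])
        results = at.identify(make_peak_list([3000.0, 6000.0, 9000.0]), [ref])
        assert len(results) == 1
        assert results[0].strain_id == "ref"

    def test_empty_library_rejected(self):
        with pytest.raises(at.InputError):
            at.identify(make_peak_list([3000.0]), [])

    def test_results_sorted_best_first_ties_by_strain(self):
        mzs = [3000.0, 6000.0, 9000.0, 12000.0]
        intens = [10.0, 20.0, 30.0, 40.0]
        refs = [make_reference(mzs, intens, strain_id=s) for s in ("b", "a")]
        results = at.identify(make_peak_list(mzs, intens), refs)
        assert [r.strain_id for r in results] == ["a", "b"]
        assert results[0].score == results[1].score == 3.0

    def test_taxonomic_separation_self_species_genus(self):
        """Mean self-score > same-species score > other-genus score."""
        self_s, species_s, genus_s = [], [], []
        for seed in range(5):
            spec = at.PanelSpec(n_genera=2, species_per_genus=2,
                                strains_per_species=2, n_replicates=10, seed=seed)
            models, spectra, _ = at.make_panel(spec, at.SimulationConfig(seed=seed))
            lib = {}
            for m in models:
                pls = [at.preprocess(s) for s in spectra[m.strain_id]]
                lib[m.strain_id] = at.build_msp(pls, m.strain_id)[0]
            cand_model = models[0]
            cand_spec, _ = at.simulate_replicate(
                cand_model, at.SimulationConfig(seed=1000 + seed), "probe"
            )
            cand = at.preprocess(cand_spec)
            genus, species = cand_model.taxonomy
            for m in models:
                s = at.score(cand, lib[m.strain_id]).score
                if m.strain_id == cand_model.strain_id:
                    self_s.append(s)
                elif m.taxonomy[1] == species:
                    species_s.append(s)
                elif m.taxonomy[0] != genus:
                    genus_s.append(s)
        assert np.mean(self_s) > np.mean(species_s) > np.mean(genus_s)


class TestReidentify:
    def test_three_perfect_replicates(self):
        mzs = [3000.0, 6000.0, 9000.0, 12000.0]
        intens = [10.0, 20.0, 30.0, 40.0]
        ref = make_reference(mzs, intens)
        reps = [make_peak_list(mzs, intens) for _ in range(3)]
        summary = at.reidentify(reps, ref)
        assert summary.mean == 3.0 and summary.sd == 0.0
        assert summary.formatted() == "3.000 ± 0.000"

    def test_simulated_triplicates_tight_scores(self, strain_model):
        cfg0 = at.SimulationConfig(seed=50)
        reps10 = [
            at.preprocess(at.simulate_replicate(strain_model, cfg0, f"r{i:02d}")[0])
            for i in range(10)
        ]
        msp, _ = at.build_msp(reps10, strain_model.strain_id)
        means, sds = [], []
        for seed in range(10):
            cfg = at.SimulationConfig(seed=3000 + seed)
            trip = [
                at.preprocess(at.simulate_replicate(strain_model, cfg, f"t{i}")[0])
                for i in range(3)
            ]
            summary = at.reidentify(trip, msp)
            means.append(summary.mean)
            sds.append(summary.sd)
            assert min(summary.scores) <= summary.mean <= max(summary.scores)
        assert all(2.0 <= m <= 3.0 for m in means)
        assert all(s < 0.2 for s in sds)

    def test_fewer_than_two_replicates_rejected(self):
        ref = make_reference([3000.0])
        with pytest.raises(at.InputError):
            at.reidentify([make_peak_list([3000.0])], ref)
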