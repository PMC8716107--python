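"""Generator contracts: determinism, type process, rate laws, round trips."""

import json

import numpy as np
import pytest

from axonstat import morphometry, skeleton_io, synthetic
from axonstat.group_stats import fit_lognormal
from axonstat.synthetic import (
    AxonGenParams,
    TypeProcessParams,
    sample_type_sequence,
)
from axonstat.types import ValidationError, VTYPES
from axonstat.varicosity import classify_varicosity


class TestTypeProcess:
    def test_full_persistence_locks_the_type(self):
        types = TypeProcessParams(rho=1.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = sample_type_sequence(12, types, rng)
            assert len(set(seq)) == 1

    def test_degenerate_frequencies(self):
        types = TypeProcessParams(f=[1.0, 0, 0, 0], rho=0.0)
        rng = np.random.default_rng(1)
        assert sample_type_sequence(50, types, rng) == [0] * 50

    def test_iid_frequencies_match_f(self):
        types = TypeProcessParams(rho=0.0)
        rng = np.random.default_rng(2)
        draws = np.array(sample_type_sequence(12_000, types, rng))
        for t in range(4):
            p = types.f[t]
            se = np.sqrt(p * (1 - p) / len(draws))
            assert abs(np.mean(draws == t) - p) <= 3 * se

    def test_mixture_mode_with_full_weight(self):
        types = TypeProcessParams(mode="mixture", mixture_weight=1.0)
        rng = np.random.default_rng(3)
        for _ in range(10):
            seq = sample_type_sequence(10, types, rng)
            assert len(set(seq)) == 1

    def test_common_random_numbers_couple_rho_values(self):
        # same seed: raising rho only converts fresh draws into repeats
        base = sample_type_sequence(
            30, TypeProcessParams(rho=0.0), np.random.default_rng(9)
        )
        pers = sample_type_sequence(
            30, TypeProcessParams(rho=0.4), np.random.default_rng(9)
        )
        assert base[0] == pers[0]
        diffs = [i for i in range(1, 30) if base[i] != pers[i]]
        for i in diffs:  # every divergence is a persistence event
            assert pers[i] == pers[i - 1]

    def test_invalid_params(self):
        with pytest.raises(ValidationError):
            TypeProcessParams(f=[0.5, 0.5, 0.2, -0.2])
        with pytest.raises(ValidationError):
            TypeProcessParams(rho=1.5)
        with pytest.raises(ValidationError):
            AxonGenParams(branch_rate_per_um=-0.1)


class TestGenerateAxon:
    def test_all_varicosities_share_type_at_rho_one(self):
        params = synthetic.study_defaults("saline")
        rec, _ = synthetic.generate_axon(params, TypeProcessParams(rho=1.0), seed=5)
        types = {v.vtype for v in rec.varicosities}
        assert len(types) == 1

    def test_degenerate_f_gives_all_type_I(self):
        params = synthetic.study_defaults("saline")
        rec, _ = synthetic.generate_axon(
            params, TypeProcessParams(f=[1.0, 0, 0, 0]), seed=6
        )
        assert all(v.vtype == "I" for v in rec.varicosities)
        assert all(v.vesicle_diameters == () for v in rec.varicosities)

    def test_branch_poisson_rate_law(self):
        """Pooled branch events / pooled cable within 3 Poisson SDs of the rate."""
        params = synthetic.study_defaults("cocaine")  # 0.04 branches/µm
        total_b = total_l = 0.0
        pairs = synthetic.generate_group(40, "cocaine", params, seed=21)
        for rec, truth in pairs:
            total_b += truth.n_branch_events
            total_l += truth.total_cable_um
        assert total_l > 10_000
        rate = total_b / total_l
        se = np.sqrt(0.04 * total_l) / total_l
        assert abs(rate - 0.04) <= 3 * se

    def test_branch_count_matches_skeleton_degree_formula(self, small_study):
        for rec, truth in small_study:
            assert morphometry.count_branches(rec.skeleton) == truth.n_branch_events

    def test_spacing_moment_check(self):
        params = synthetic.study_defaults("saline")
        spacings = []
        for rec, _ in synthetic.generate_group(40, "saline", params, seed=22):
            spacings.extend(morphometry.intervaricosity_distances(rec))
        fit = fit_lognormal(spacings)
        n = len(spacings)
        assert n > 800
        assert abs(fit.mu - params.spacing_mu_log_nm) <= 3 * params.spacing_sigma_log / np.sqrt(n)
        assert abs(fit.sigma - params.spacing_sigma_log) <= 3 * params.spacing_sigma_log / np.sqrt(2 * n)

    def test_saline_axons_have_no_swellings(self, small_study):
        for rec, _ in small_study:
            if rec.group == "saline":
                assert rec.swellings == []

    def test_mito_lengths_match_ground_truth(self, small_study):
        for rec, truth in small_study[:4]:
            measured = [morphometry.mito_length(rec.skeleton, c) for c in rec.mito_segments]
            assert measured == pytest.approx(truth.mito_lengths_um, abs=1e-9)

    def test_classification_recovers_ground_truth(self, small_study):
        for rec, truth in small_study:
            for v, true_type in zip(rec.varicosities, truth.varicosity_types):
                assert classify_varicosity(v.vesicle_diameters) == true_type == v.vtype

    def test_dendrite_preset_scales_mito_by_diameter(self):
        params = synthetic.study_defaults("saline", "MSN_dendrite")
        rec, truth = synthetic.generate_axon(params, seed=8, compartment="MSN_dendrite")
        assert truth.dendrite_diameter_nm is not None
        assert rec.varicosities == []


class TestGenerateGroup:
    def test_byte_identical_under_fixed_seed(self):
        params = synthetic.study_defaults("saline")
        a = synthetic.generate_group(3, "saline", params, seed=33)
        b = synthetic.generate_group(3, "saline", params, seed=33)
        assert skeleton_io.write_nml([r for r, _ in a]) == skeleton_io.write_nml(
            [r for r, _ in b]
        )

    def test_different_seeds_differ(self):
        params = synthetic.study_defaults("saline")
        a = synthetic.generate_group(2, "saline", params, seed=33)
        b = synthetic.generate_group(2, "saline", params, seed=34)
        assert skeleton_io.write_nml([r for r, _ in a]) != skeleton_io.write_nml(
            [r for r, _ in b]
        )

    def test_group_label_is_stamped(self, small_study):
        assert {r.group for r, _ in small_study} == {"saline", "cocaine"}


class TestGenerateStudy:
    def config(self, n=2):
        return {
            "scale_nm": [20.0, 20.0, 40.0],
            "groups": [
                {"label": "saline", "compartment": "DA_axon", "n_axons": n,
                 "params": {"length_range_um": [30.0, 60.0]}, "types": {}},
                {"label": "cocaine", "compartment": "DA_axon", "n_axons": n,
                 "params": {"length_range_um": [30.0, 60.0]}, "types": {}},
            ],
        }

    def test_emitted_files_parse_back(self, tmp_path):
        records, _ = synthetic.build_study(self.config(), seed=3)
        synthetic.generate_study(self.config(), seed=3, outdir=tmp_path)
        loaded = synthetic.load_study(tmp_path)
        assert loaded == records

    def test_zero_axons_empty_manifest(self, tmp_path):
        config = self.config(n=0)
        manifest = synthetic.generate_study(config, seed=1, outdir=tmp_path)
        assert manifest["axons"] == {}
        assert synthetic.load_study(tmp_path) == []

    def test_regeneration_is_identical(self, tmp_path):
        m1 = synthetic.generate_study(self.config(), seed=7, outdir=tmp_path / "a")
        m2 = synthetic.generate_study(self.config(), seed=7, outdir=tmp_path / "b")
        for name in ("saline_DA_axon.nml", "cocaine_DA_axon.nml", "ground_truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
        assert m1["config_hash"] == m2["config_hash"]

    def test_ground_truth_file_aligns_with_records(self, tmp_path):
        synthetic.generate_study(self.config(), seed=5, outdir=tmp_path)
        truths = json.loads((tmp_path / "ground_truth.json").read_text())
        records = synthetic.load_study(tmp_path)
        assert len(truths) == len(records)
        by_id = {t["axon_id"]: t for t in truths}
        for rec in records:
            truth = by_id[rec.axon_id]
            assert [v.vtype for v in rec.varicosities] == truth["varicosity_types"]
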