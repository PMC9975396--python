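"""Synthetic cohort generator: templates, sampling, determinism, ground truth."""

import dataclasses

import numpy as np
import pytest

from fcnorm.atlas import DEFAULT_ATLAS, FBNAtlas
from fcnorm.connectivity import correlation_matrix, motion_qc, vectorize
from fcnorm.simulate import (
    CohortConfig,
    ConfigError,
    InvalidPerturbationError,
    default_config,
    generate_cohort,
    generate_motion_table,
    make_base_correlation,
    nearest_correlation,
    perturb_correlation,
    sample_subject_timeseries,
)


def _is_valid_correlation(m, min_eig=1e-8):
    return (
        np.allclose(m, m.T)
        and np.all(np.diag(m) == 1.0)
        and np.linalg.eigvalsh(m).min() > min_eig
    )


class TestBaseCorrelation:
    def test_zero_correlation_single_block_is_identity(self, atlas):
        m = make_base_correlation(
            atlas, block_structure=(atlas.labels,), seed=0, within=0.0,
            between=0.0, noise_sd=0.0,
        )
        assert np.array_equal(m, np.eye(14))

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_always_valid_correlation(self, seed):
        m = make_base_correlation(seed=seed)
        assert _is_valid_correlation(m)

    def test_two_block_means(self):
        atlas = DEFAULT_ATLAS
        blocks = (atlas.labels[:7], atlas.labels[7:])
        m = make_base_correlation(
            atlas, block_structure=blocks, seed=3, within=0.5, between=0.0,
            noise_sd=0.0,
        )
        within = np.concatenate([m[:7, :7][np.triu_indices(7, 1)],
                                 m[7:, 7:][np.triu_indices(7, 1)]])
        between = m[:7, 7:].ravel()
        assert within.mean() == pytest.approx(0.5, abs=0.02)
        assert abs(between.mean()) < 0.02
        assert within.mean() > between.mean()

    def test_bad_block_partition_rejected(self, atlas):
        with pytest.raises(ConfigError):
            make_base_correlation(atlas, block_structure=(atlas.labels[:5],))


class TestPerturbation:
    def test_empty_list_returns_base_unchanged(self):
        base = make_base_correlation(seed=0)
        assert np.array_equal(perturb_correlation(base, []), base)

    def test_out_of_range_entry_rejected(self):
        with pytest.raises(InvalidPerturbationError):
            perturb_correlation(np.eye(14), [(("BGN", "LN"), 1.2)])

    def test_single_offset_lands_on_both_symmetric_positions(self, atlas):
        out = perturb_correlation(np.eye(14), [(("BGN", "LN"), 0.4)])
        i, j = atlas.index("BGN"), atlas.index("LN")
        assert out[i, j] == pytest.approx(0.4, abs=1e-6)
        assert out[j, i] == pytest.approx(0.4, abs=1e-6)
        mask = np.ones((14, 14), dtype=bool)
        mask[i, j] = mask[j, i] = False
        np.fill_diagonal(mask, False)
        assert np.abs(out[mask]).max() < 1e-6
        assert _is_valid_correlation(out)

    def test_projection_restores_definiteness(self):
        # push identity far enough that re-projection is required
        perts = [(("ASN", "AN"), 0.95), (("AN", "BGN"), 0.95), (("ASN", "BGN"), -0.9)]
        out = perturb_correlation(np.eye(14), perts)
        assert _is_valid_correlation(out)


class TestSubjectSampling:
    def test_identity_template_long_series_uncorrelated(self):
        atlas3 = FBNAtlas(labels=("A", "B", "C"))
        ts = sample_subject_timeseries(np.eye(3), 0.0, 100_000, seed=5, atlas=atlas3)
        r = correlation_matrix(ts, atlas3).values
        off = r[np.triu_indices(3, 1)]
        assert np.abs(off).max() < 0.02

    def test_template_entry_recovered_empirically(self, atlas):
        tpl = perturb_correlation(np.eye(14), [(("HVN", "PVN"), 0.8)])
        ts = sample_subject_timeseries(tpl, 0.0, 20_000, seed=11)
        r = correlation_matrix(ts).values
        i, j = atlas.index("HVN"), atlas.index("PVN")
        assert r[i, j] == pytest.approx(0.8, abs=0.05)

    def test_same_seed_bit_identical(self):
        tpl = make_base_correlation(seed=2)
        a = sample_subject_timeseries(tpl, 0.05, 150, seed=42)
        b = sample_subject_timeseries(tpl, 0.05, 150, seed=42)
        assert a.equals(b)

    def test_columns_standardized(self):
        ts = sample_subject_timeseries(make_base_correlation(seed=0), 0.1, 200, seed=0)
        arr = ts.to_numpy()
        assert np.allclose(arr.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(arr.std(axis=0), 1.0, atol=1e-12)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            sample_subject_timeseries(np.eye(14), 0.0, 29, seed=0)


class TestCohort:
    def test_counts_and_empty_truth(self):
        cfg = CohortConfig(
            n_per_group={"H-Train": 4, "H-Test": 2}, n_timepoints=40, seed=0
        )
        cohort = generate_cohort(cfg)
        assert len(cohort.timeseries) == 6
        assert cohort.truth.perturbed == {}
        assert list(cohort.manifest["group"]).count("H-Train") == 4

    def test_truth_manifest_records_injected_pairs(self, atlas):
        cfg = CohortConfig(
            n_per_group={"H-Train": 4, "H-Test": 2, "SCZ": 2},
            n_timepoints=40,
            perturbations={"SCZ": [(("ASN", "BGN"), 0.3), (("BGN", "HVN"), 0.3)]},
            seed=0,
        )
        cohort = generate_cohort(cfg)
        expected = {atlas.pair_to_feature("ASN", "BGN"),
                    atlas.pair_to_feature("BGN", "HVN")}
        assert cohort.truth.pairs("SCZ") == expected

    def test_unknown_perturbation_group_rejected(self):
        cfg = CohortConfig(
            n_per_group={"H-Train": 4, "H-Test": 2},
            perturbations={"Ghost": [(("ASN", "BGN"), 0.3)]},
        )
        with pytest.raises(ConfigError, match="Ghost"):
            generate_cohort(cfg)

    def test_missing_healthy_sets_rejected(self):
        with pytest.raises(ConfigError):
            generate_cohort(CohortConfig(n_per_group={"SCZ": 3}))

    def test_deterministic_and_extendable(self, small_cohort_config):
        a = generate_cohort(small_cohort_config)
        b = generate_cohort(small_cohort_config)
        sid = a.manifest["subject_id"].iloc[-1]
        assert a.timeseries[sid].equals(b.timeseries[sid])
        # enlarging the last group must not reshuffle earlier subjects
        bigger = dataclasses.replace(
            small_cohort_config,
            n_per_group={**small_cohort_config.n_per_group, "SCZ-Test-U": 20},
        )
        c = generate_cohort(bigger)
        assert c.timeseries["H-Train_000"].equals(a.timeseries["H-Train_000"])
        assert c.timeseries[sid].equals(a.timeseries[sid])

    def test_round_trip_through_disk(self, tmp_path, small_cohort_config):
        from fcnorm.simulate import load_cohort

        cfg = dataclasses.replace(
            small_cohort_config,
            n_per_group={"H-Train": 3, "H-Test-U": 2},
            perturbations={},
        )
        cohort = generate_cohort(cfg, out_dir=tmp_path)
        manifest, ts, truth = load_cohort(tmp_path)
        assert list(manifest["subject_id"]) == list(cohort.manifest["subject_id"])
        sid = manifest["subject_id"].iloc[0]
        assert np.allclose(ts[sid].to_numpy(), cohort.timeseries[sid].to_numpy(),
                           atol=1e-9)
        assert truth.perturbed == cohort.truth.perturbed

    def test_injected_pairs_deviate_more_than_others(self, atlas):
        # separation: patient subjects' empirical correlations move away
        # from the healthy template mostly at the injected pairs
        base = make_base_correlation(seed=5)
        perts = [(("ASN", "BGN"), 0.3), (("BGN", "HVN"), -0.3), (("LN", "PN"), 0.3)]
        tpl = perturb_correlation(base, perts, atlas)
        injected = {atlas.pair_to_feature(a, b) for (a, b), _ in perts}
        base_vec = vectorize_template(base, atlas)
        devs = []
        for s in range(30):
            ts = sample_subject_timeseries(tpl, 0.06, 150, seed=1000 + s)
            devs.append(np.abs(vectorize_template(
                correlation_matrix(ts, atlas).values, atlas) - base_vec))
        devs = np.mean(devs, axis=0)
        inj = sorted(injected)
        rest = [k for k in range(atlas.n_pairs) if k not in injected]
        assert devs[inj].mean() > devs[rest].mean()


def vectorize_template(m, atlas):
    rows, cols = atlas.pair_rows_cols()
    return m[rows, cols]


class TestMotionTables:
    def test_clean_table_passes_qc(self):
        for seed in range(5):
            m = generate_motion_table(100, contaminate=False, seed=seed)
            assert motion_qc(m).passed

    def test_contaminated_table_fails_qc(self):
        for seed in range(5):
            m = generate_motion_table(100, contaminate=True, seed=seed)
            assert not motion_qc(m).passed

    def test_same_seed_identical(self):
        a = generate_motion_table(60, contaminate=True, seed=9)
        b = generate_motion_table(60, contaminate=True, seed=9)
        assert np.array_equal(a.translations_mm, b.translations_mm)
        assert np.array_equal(a.rotations_deg, b.rotations_deg)


class TestNearestCorrelation:
    def test_projection_of_indefinite_matrix(self):
        m = np.full((4, 4), 0.9)
        m[0, 1] = m[1, 0] = -0.9
        np.fill_diagonal(m, 1.0)
        assert np.linalg.eigvalsh(m).min() < 0
        out = nearest_correlation(m)
        assert _is_valid_correlation(out)

    def test_pd_input_unchanged(self):
        m = make_base_correlation(seed=1)
        assert np.allclose(nearest_correlation(m), m, atol=1e-12)
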