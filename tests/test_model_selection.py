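import numpy as np
import pandas as pd
import pytest

from sriselect import (
    CloudSpec,
    ValidationTable,
    benchmark_vectors,
    build_report,
    euclidean_distance,
    generate_blob_cloud,
    load_benchmark_sri,
    rank_models,
    rmsd_ics,
)
from sriselect.errors import PairingError, ParameterError
from sriselect.ics import build_frame, transform_to_ics

from conftest import random_rotation


class TestEuclideanDistance:
    def test_identical_vectors(self):
        v = np.arange(8.0)
        assert euclidean_distance(v, v) == 0.0

    def test_unit_cube_diagonal(self):
        assert euclidean_distance(np.zeros(8), np.ones(8)) == pytest.approx(
            np.sqrt(8.0)
        )

    def test_benchmark_insulin_distance_matches_direct_arithmetic(self):
        bv = benchmark_vectors("insulin")
        a, b = bv["predicted"], bv["models"]["5"]
        # independent elementwise oracle
        acc = 0.0
        for x, y in zip(a, b):
            acc += (x - y) ** 2
        assert euclidean_distance(a, b) == pytest.approx(acc**0.5)
        assert euclidean_distance(a, b) == pytest.approx(4.755, abs=5e-3)

    def test_length_mismatch_raises(self):
        with pytest.raises(ParameterError):
            euclidean_distance(np.zeros(7), np.zeros(8))


class TestRankModels:
    def test_benchmark_albumin_predicted_reference(self):
        bv = benchmark_vectors("albumin")
        assert rank_models(bv["models"], bv["predicted"]).best == "4"

    def test_benchmark_insulin_calculated_reference(self):
        bv = benchmark_vectors("insulin")
        assert rank_models(bv["models"], bv["calculated"]).best == "5"

    def test_reference_equal_to_a_model_wins_with_zero_distance(self):
        bv = benchmark_vectors("ferritin")
        ranking = rank_models(bv["models"], bv["models"]["2"])
        assert ranking.best == "2"
        assert ranking.distances["2"] == 0.0

    def test_tie_broken_by_label_order(self):
        models = {"b": np.ones(8), "a": np.ones(8)}
        assert rank_models(models, np.zeros(8)).best == "a"

    def test_selection_recovery_under_small_noise(self, rng):
        bv = benchmark_vectors("lysozyme")
        models = bv["models"]
        for planted in models:
            vecs = list(models.values())
            dmin = min(
                np.linalg.norm(vecs[i] - vecs[j])
                for i in range(len(vecs))
                for j in range(i + 1, len(vecs))
            )
            noise = rng.normal(size=8)
            noise *= 0.4 * dmin / np.linalg.norm(noise)
            ref = models[planted] + noise
            assert rank_models(models, ref).best == planted

    def test_empty_models_raise(self):
        with pytest.raises(ParameterError):
            rank_models({}, np.zeros(8))


@pytest.fixture(scope="module")
def cloud():
    spec = CloudSpec(
        points_per_octant=40,
        radial_mean=15.0,
        radial_sd_per_octant=np.full(8, 1.0),
        seed=21,
    )
    return generate_blob_cloud(spec)


class TestRmsd:
    def test_self_rmsd_zero(self, cloud):
        rmsd, n = rmsd_ics(cloud, cloud)
        assert rmsd == 0.0 and n == len(cloud)

    def test_rigid_motion_removed_by_invariant_frames(self, cloud):
        R = random_rotation(4)
        moved = cloud.with_positions(cloud.positions @ R.T + np.array([8.0, -2.0, 3.0]))
        rmsd, _ = rmsd_ics(moved, cloud)
        assert rmsd < 1e-6

    def test_matches_direct_formula_oracle(self, cloud, rng):
        other = cloud.with_positions(cloud.positions + rng.normal(0, 0.4, cloud.positions.shape))
        rmsd, n = rmsd_ics(other, cloud)
        a = transform_to_ics(other, build_frame(other)).positions
        b = transform_to_ics(cloud, build_frame(cloud)).positions
        expected = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        assert n == len(cloud)
        assert rmsd == pytest.approx(float(expected), abs=1e-12)

    def test_by_order_pairing_truncates(self, cloud):
        shorter = type(cloud)(
            residues=cloud.residues[:100],
            positions=cloud.positions[:100],
        )
        rmsd, n = rmsd_ics(cloud, shorter, pairing="by_order")
        assert n == 100 and np.isfinite(rmsd)

    def test_disjoint_residue_numbers_raise(self, cloud):
        from sriselect import ResidueId

        renumbered = type(cloud)(
            residues=[
                ResidueId("B", r.residue_number + 10_000, r.icode, r.residue_name)
                for r in cloud.residues
            ],
            positions=cloud.positions,
        )
        with pytest.raises(PairingError):
            rmsd_ics(renumbered, cloud)

    def test_kabsch_mode_not_larger_than_ics_mode(self, cloud, rng):
        other = cloud.with_positions(
            cloud.positions + rng.normal(0, 0.8, cloud.positions.shape)
        )
        r_ics, _ = rmsd_ics(other, cloud, mode="ics")
        r_kab, _ = rmsd_ics(other, cloud, mode="kabsch")
        assert r_kab <= r_ics + 1e-9


class TestBuildReport:
    def test_only_predicted_reference_fills_dp_column(self):
        bv = benchmark_vectors("cytochrome_c")
        report = build_report(bv["models"], sri_p=bv["predicted"])
        assert report.best_by_dp == "1"
        assert report.best_by_dc is None
        assert "dp_mod" in report.table and "dc_mod" not in report.table

    def test_ferritin_calculated_reference_selects_model_3(self):
        bv = benchmark_vectors("ferritin")
        report = build_report(bv["models"], sri_c=bv["calculated"])
        assert report.best_by_dc == "3"

    def test_validation_scores_passed_through_untouched(self):
        bv = benchmark_vectors("lysozyme")
        scores = pd.DataFrame(
            {"model": list(bv["models"]), "ramachandran": [93.8, 93.8, 91.2, 94.7, 94.7]}
        ).set_index("model")
        report = build_report(
            bv["models"], sri_p=bv["predicted"], validation=ValidationTable(scores=scores)
        )
        assert list(report.table["ramachandran"]) == [93.8, 93.8, 91.2, 94.7, 94.7]

    def test_rmsd_block_with_structures(self):
        spec = CloudSpec(
            points_per_octant=30,
            radial_mean=15.0,
            radial_sd_per_octant=np.full(8, 1.0),
            seed=2,
        )
        ref = generate_blob_cloud(spec)
        g = np.random.default_rng(0)
        structures = {
            "1": ref.with_positions(ref.positions + g.normal(0, 1.0, ref.positions.shape)),
            "2": ref.with_positions(ref.positions + g.normal(0, 0.05, ref.positions.shape)),
        }
        from sriselect import compute_sri

        sris = {k: compute_sri(v).values for k, v in structures.items()}
        report = build_report(
            sris,
            sri_c=compute_sri(ref).values,
            structures=structures,
            reference_structure=ref,
        )
        assert report.best_by_rmsd == "2"
        assert report.mean_rmsd == pytest.approx(
            np.mean([report.table["rmsd"]["1"], report.table["rmsd"]["2"]])
        )
        assert "best model by RMSD" in report.format_text()

    def test_missing_references_raise(self):
        with pytest.raises(ParameterError):
            build_report({"1": np.ones(8)})


def test_benchmark_table_is_complete():
    df = load_benchmark_sri()
    assert len(df) == 6 * 7
    assert set(df["role"]) == {
        "predicted",
        "calculated_reference",
        "calculated_model",
    }
    sri_cols = [f"sri_{k}" for k in range(1, 9)]
    assert np.isfinite(df[sri_cols].to_numpy()).all()
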