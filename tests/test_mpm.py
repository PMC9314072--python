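"""Data model, I/O, admissibility screens and eigen-analysis."""

import numpy as np
import pytest

from demres.mpm import (
    MPMCollection,
    MPMError,
    MPMRecord,
    eigen_analysis,
    filter_collection,
    mean_matrix,
    normalize,
    read_collection,
    validate_mpm,
    write_collection,
)
from tests.conftest import draw_valid_mpms


def _rec(A, pid="p", **kw):
    kw.setdefault("species_name", "Testus testus")
    kw.setdefault("kingdom", "animal")
    return MPMRecord(population_id=pid, mat_A=np.asarray(A, float), **kw)


class TestRecordConstruction:
    def test_reconstructs_A_from_parts(self):
        r = MPMRecord(
            species_name="x", population_id="p", kingdom="plant",
            mat_U=np.array([[0.1, 0.0], [0.2, 0.3]]),
            mat_F=np.array([[0.0, 2.0], [0.0, 0.0]]),
            mat_C=np.array([[0.05, 0.0], [0.0, 0.0]]),
        )
        np.testing.assert_allclose(r.mat_A, [[0.15, 2.0], [0.2, 0.3]])

    def test_inconsistent_parts_rejected(self):
        with pytest.raises(MPMError, match="A != U \\+ F \\+ C"):
            MPMRecord(
                species_name="x", population_id="badrec", kingdom="animal",
                mat_A=np.array([[0.0, 4.0], [0.5, 0.0]]),
                mat_U=np.array([[0.0, 0.0], [0.4, 0.0]]),
                mat_F=np.array([[0.0, 4.0], [0.0, 0.0]]),
                mat_C=np.zeros((2, 2)),
            )

    @pytest.mark.parametrize(
        "bad",
        [
            {"mat_A": [[0.1, 0.2, 0.3], [0.1, 0.2, 0.3]]},  # non-square
            {"mat_A": [[0.1, -0.2], [0.1, 0.2]]},  # negative entry
            {"mat_A": [[np.nan, 0.2], [0.1, 0.2]]},  # non-finite
        ],
    )
    def test_malformed_matrices_rejected(self, bad):
        with pytest.raises(MPMError):
            MPMRecord(species_name="x", population_id="p", kingdom="animal", **{
                k: np.asarray(v, float) for k, v in bad.items()
            })

    def test_missing_A_and_parts_rejected(self):
        with pytest.raises(MPMError, match="cannot reconstruct"):
            MPMRecord(species_name="x", population_id="nomat", kingdom="animal")

    def test_duplicate_population_ids_rejected(self):
        a = _rec([[0.5]], pid="dup")
        b = _rec([[0.6]], pid="dup")
        with pytest.raises(MPMError, match="duplicate"):
            MPMCollection(records=[a, b])

    def test_age_pools_with_stage(self):
        r = _rec([[0.5]], state_variable="age")
        assert r.pooled_state_variable == "stage"
        assert _rec([[0.5]], state_variable="size").pooled_state_variable == "size"


class TestIO:
    def test_roundtrip_json(self, tmp_path, iteroparous_2x2, semelparous_2x2):
        coll = MPMCollection(records=[iteroparous_2x2, semelparous_2x2])
        path = tmp_path / "coll.json"
        write_collection(coll, path)
        back = read_collection(path, format="json")
        assert len(back) == 2
        for orig, rt in zip(coll, back):
            np.testing.assert_array_equal(orig.mat_A, rt.mat_A)
            assert orig.species_name == rt.species_name
            assert orig.is_mean_matrix == rt.is_mean_matrix
        assert back[1].mat_U is not None
        np.testing.assert_array_equal(back[1].mat_U, semelparous_2x2.mat_U)

    def test_csv_bundle(self, tmp_path):
        (tmp_path / "metadata.csv").write_text(
            "species_name,population_id,kingdom\nTestus testus,p1,animal\n"
        )
        (tmp_path / "matrices.csv").write_text(
            "population_id,part,row,col,value\n"
            "p1,A,0,1,4.0\np1,A,1,0,0.5\n"
        )
        coll = read_collection(tmp_path, format="csv-bundle")
        assert len(coll) == 1
        np.testing.assert_allclose(coll[0].mat_A, [[0.0, 4.0], [0.5, 0.0]])


class TestMeanMatrix:
    def test_elementwise_mean(self):
        a = _rec([[0, 2], [0.5, 0]], pid="a")
        b = _rec([[0, 4], [0.3, 0]], pid="b")
        m = mean_matrix([a, b])
        np.testing.assert_allclose(m.mat_A, [[0, 3], [0.4, 0]])
        assert m.is_mean_matrix

    def test_single_record_identity(self, iteroparous_2x2):
        m = mean_matrix([iteroparous_2x2])
        np.testing.assert_array_equal(m.mat_A, iteroparous_2x2.mat_A)
        assert m.is_mean_matrix

    def test_dimension_mismatch(self):
        with pytest.raises(MPMError, match="mismatch"):
            mean_matrix([_rec([[0.5]], pid="a"), _rec(np.eye(3) * 0.1, pid="b")])

    def test_empty_input(self):
        with pytest.raises(MPMError):
            mean_matrix([])


class TestValidation:
    def test_lower_triangular_is_reducible(self):
        rep = validate_mpm(_rec([[0.5, 0.0], [0.3, 0.8]]))
        assert not rep.irreducible and not rep.passed

    def test_single_loop_is_imprimitive(self, semelparous_2x2):
        rep = validate_mpm(semelparous_2x2)
        assert rep.irreducible and not rep.primitive

    def test_self_loop_matrix_passes_all(self, iteroparous_2x2):
        rep = validate_mpm(iteroparous_2x2)
        assert rep.irreducible and rep.primitive and rep.ergodic and rep.passed

    def test_zero_left_eigenvector_entry_is_non_ergodic(self):
        # v' A = 0.8 v' forces v2 = 0 for this matrix
        rep = validate_mpm(_rec([[0.8, 0.0], [0.1, 0.3]]))
        assert not rep.ergodic

    def test_zero_matrix_fails_everything(self):
        rep = validate_mpm(_rec(np.zeros((2, 2))))
        assert rep == rep.__class__(False, False, False, ("zero matrix",))

    def test_primitive_implies_irreducible_on_random_matrices(self):
        for rec in draw_valid_mpms(50, seed=5):
            rep = validate_mpm(rec)
            assert not rep.primitive or rep.irreducible

    def test_graph_irreducibility_matches_matrix_power_test(self):
        # (I + A)^(s-1) strictly positive iff A irreducible
        rng = np.random.default_rng(42)
        for _ in range(1000):
            s = int(rng.integers(2, 9))
            A = rng.random((s, s)) * (rng.random((s, s)) < 0.4)
            rec = _rec(A, pid="rand")
            graph_result = validate_mpm(rec).irreducible
            power = np.linalg.matrix_power(np.eye(s) + A, s - 1)
            assert graph_result == bool(np.all(power > 0))


class TestEigenAnalysis:
    def test_single_loop_eigensystem(self, semelparous_2x2):
        eig = eigen_analysis(semelparous_2x2)
        assert eig.lambda1 == pytest.approx(np.sqrt(2), abs=1e-9)
        assert eig.lambda2_mod == pytest.approx(np.sqrt(2), abs=1e-9)
        assert eig.damping_ratio == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(eig.w, [0.738796, 0.261204], atol=1e-6)

    def test_self_loop_eigensystem(self, iteroparous_2x2):
        eig = eigen_analysis(iteroparous_2x2)
        assert eig.lambda1 == pytest.approx(1.163941, abs=1e-6)
        assert eig.lambda2_mod == pytest.approx(0.463941, abs=1e-6)
        assert eig.damping_ratio == pytest.approx(2.508812, abs=1e-6)

    def test_one_by_one_matrix(self):
        eig = eigen_analysis(_rec([[0.5]]))
        assert eig.lambda1 == 0.5
        assert eig.lambda2_mod is None and eig.damping_ratio is None
        np.testing.assert_array_equal(eig.w, [1.0])

    def test_eigenvector_equations_hold(self):
        for rec in draw_valid_mpms(100, seed=3):
            eig = eigen_analysis(rec)
            A = rec.mat_A
            np.testing.assert_allclose(A @ eig.w, eig.lambda1 * eig.w, atol=1e-8)
            np.testing.assert_allclose(eig.v @ A, eig.lambda1 * eig.v, atol=1e-8)
            assert eig.w.sum() == pytest.approx(1.0, abs=1e-10)
            assert eig.v @ eig.w == pytest.approx(1.0, abs=1e-8)


class TestNormalize:
    def test_unit_spectral_radius(self):
        for rec in draw_valid_mpms(100, seed=9):
            a_hat = normalize(rec)
            rho = np.abs(np.linalg.eigvals(a_hat.mat_A_hat)).max()
            assert rho == pytest.approx(1.0, abs=1e-10)

    def test_column_sums_of_worked_example(self, iteroparous_2x2):
        a_hat = normalize(iteroparous_2x2)
        np.testing.assert_allclose(
            a_hat.mat_A_hat.sum(axis=0), [0.515490, 1.804215], atol=1e-6
        )

    def test_idempotent(self, iteroparous_2x2):
        once = normalize(iteroparous_2x2).mat_A_hat
        rec2 = MPMRecord(
            species_name="x", population_id="p", kingdom="animal", mat_A=once
        )
        twice = normalize(rec2).mat_A_hat
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_zero_matrix_errors(self):
        with pytest.raises(MPMError):
            normalize(_rec(np.zeros((2, 2))))


class TestFilter:
    def test_each_exclusion_reason_logged(self, iteroparous_2x2):
        base = iteroparous_2x2.mat_A
        records = [
            MPMRecord("a", "keep", "animal", mat_A=base),
            MPMRecord("b", "cap", "animal", mat_A=base, captive=True),
            MPMRecord("c", "man", "animal", mat_A=base, treatment="manipulated"),
            MPMRecord("d", "per", "animal", mat_A=base, periodicity_years=0.5),
            MPMRecord("e", "red", "animal", mat_A=np.array([[0.5, 0.0], [0.3, 0.8]])),
        ]
        kept, log = filter_collection(MPMCollection(records=records))
        assert [r.population_id for r in kept] == ["keep"]
        assert len(log) == 4
        assert set(log.population_id) == {"cap", "man", "per", "red"}

    def test_empty_collection(self):
        kept, log = filter_collection(MPMCollection(records=[]))
        assert len(kept) == 0 and len(log) == 0

    def test_mean_matrix_used_when_only_option(self, iteroparous_2x2):
        rec = MPMRecord(
            "a", "popA|mean", "animal", mat_A=iteroparous_2x2.mat_A, is_mean_matrix=True
        )
        kept, log = filter_collection(MPMCollection(records=[rec]))
        assert len(kept) == 1 and kept[0].is_mean_matrix

    def test_individual_records_preferred_over_mean(self, iteroparous_2x2):
        A = iteroparous_2x2.mat_A
        records = [
            MPMRecord("a", "popA|1999", "animal", mat_A=A),
            MPMRecord("a", "popA|2000", "animal", mat_A=2 * A),
            MPMRecord("a", "popA|mean", "animal", mat_A=3 * A, is_mean_matrix=True),
        ]
        kept, log = filter_collection(MPMCollection(records=records))
        assert len(kept) == 1
        np.testing.assert_allclose(kept[0].mat_A, 1.5 * A)  # mean of the individuals
        assert "superseded" in log.reason.iloc[0]
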