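"""Reading, probe collapse, KNN imputation, scaling, cohort assembly."""

import numpy as np
import pandas as pd
import pytest

from hcg import omics_io
from hcg.omics_io import (GeneSampleMatrix, OmicsError, apply_scaler,
                          assemble_cohort, collapse_probes, fit_scaler,
                          impute_knn, read_matrix)


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadMatrix:
    def test_maf_collapse_duplicate_variant(self, tmp_path):
        path = _write(tmp_path, "mut.tsv",
                      "sample\tgene\tvariant_class\n"
                      "s1\tgeneA\tmissense\n"
                      "s1\tgeneA\tnonsense\n"
                      "s2\tgeneB\tmissense\n")
        mat = read_matrix(path, "mutation")
        assert mat.values.loc["geneA", "s1"] == 1.0
        assert mat.values.loc["geneB", "s2"] == 1.0
        assert mat.values.loc["geneA", "s2"] == 0.0

    def test_gene_by_sample_table(self, tmp_path):
        path = _write(tmp_path, "cna.tsv",
                      "gene\ts1\ts2\ngA\t1.5\t0\ngB\t-2\t0.25\n")
        mat = read_matrix(path, "cna")
        assert mat.values.loc["gB", "s1"] == -2.0

    def test_empty_file_errors(self, tmp_path):
        with pytest.raises(OmicsError):
            read_matrix(_write(tmp_path, "e.tsv", ""), "cna")

    def test_malformed_cell_names_position(self, tmp_path):
        path = _write(tmp_path, "bad.tsv", "gene\ts1\ngA\tnot_a_number\n")
        with pytest.raises(OmicsError, match="gA"):
            read_matrix(path, "cna")

    def test_beta_out_of_range_rejected(self, tmp_path):
        path = _write(tmp_path, "meth.tsv", "gene\ts1\ngA\t1.2\n")
        with pytest.raises(OmicsError, match="beta"):
            read_matrix(path, "methylation")

    def test_mutation_non_boolean_rejected(self, tmp_path):
        path = _write(tmp_path, "mut.tsv", "gene\ts1\ngA\t2\n")
        with pytest.raises(OmicsError):
            read_matrix(path, "mutation")

    def test_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.random((5, 3)),
                          index=[f"g{i}" for i in range(5)],
                          columns=["s1", "s2", "s3"])
        mat = GeneSampleMatrix(df, "methylation")
        omics_io.write_matrix(mat, tmp_path / "m.tsv")
        back = read_matrix(tmp_path / "m.tsv", "methylation")
        pd.testing.assert_frame_equal(back.values, mat.values)


class TestCollapseProbes:
    def test_mean_of_two_probes(self):
        probes = pd.DataFrame({"s": [0.2, 0.4]}, index=["p1", "p2"])
        out = collapse_probes(probes, {"p1": "G", "p2": "G"})
        assert out.values.loc["G", "s"] == pytest.approx(0.3)

    def test_single_probe_identity(self):
        probes = pd.DataFrame({"s1": [0.7], "s2": [0.1]}, index=["p1"])
        out = collapse_probes(probes, {"p1": "G"})
        assert out.values.loc["G", "s1"] == 0.7

    def test_mean_over_observed_only(self):
        probes = pd.DataFrame({"s": [0.2, np.nan]}, index=["p1", "p2"])
        out = collapse_probes(probes, {"p1": "G", "p2": "G"})
        assert out.values.loc["G", "s"] == pytest.approx(0.2)

    def test_all_probes_missing_stays_missing(self):
        probes = pd.DataFrame({"s": [np.nan, np.nan]}, index=["p1", "p2"])
        out = collapse_probes(probes, {"p1": "G", "p2": "G"})
        assert np.isnan(out.values.loc["G", "s"])

    def test_unmapped_probe_dropped(self):
        probes = pd.DataFrame({"s": [0.2, 0.9]}, index=["p1", "px"])
        out = collapse_probes(probes, {"p1": "G"})
        assert list(out.values.index) == ["G"]

    def test_single_probe_per_gene_conserves_sample_mean(self):
        rng = np.random.default_rng(1)
        probes = pd.DataFrame(rng.random((6, 3)),
                              index=[f"p{i}" for i in range(6)],
                              columns=["s1", "s2", "s3"])
        pmap = {f"p{i}": f"G{i}" for i in range(6)}
        out = collapse_probes(probes, pmap)
        np.testing.assert_allclose(np.sort(out.values.mean(axis=0)),
                                   np.sort(probes.mean(axis=0)))


class TestImputeKnn:
    def test_complete_matrix_unchanged(self):
        df = pd.DataFrame(np.random.default_rng(2).random((5, 4)),
                          index=[f"g{i}" for i in range(5)],
                          columns=[f"s{i}" for i in range(4)])
        out = impute_knn(GeneSampleMatrix(df, "methylation"))
        pd.testing.assert_frame_equal(out.values, df)

    def test_nearest_duplicate_imputes_its_value(self):
        df = pd.DataFrame({
            "s1": [0.5, 0.6, np.nan],
            "s2": [0.5, 0.6, 0.9],      # duplicate of s1 on observed genes
            "s3": [0.0, 0.0, 0.1],
        }, index=["g1", "g2", "g3"])
        out = impute_knn(GeneSampleMatrix(df, "methylation"), k=1)
        assert out.values.loc["g3", "s1"] == pytest.approx(0.9)

    def test_k2_matches_brute_force_distances(self):
        # 5 samples, one missing cell; oracle: mean over the 2 samples with the
        # smallest mean squared difference on mutually observed genes
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.random((4, 5)),
                          index=[f"g{i}" for i in range(4)],
                          columns=[f"s{i}" for i in range(5)])
        df.loc["g0", "s0"] = np.nan
        out = impute_knn(GeneSampleMatrix(df, "methylation"), k=2)
        target = df.drop(index="g0")["s0"]
        dists = {}
        for s in ["s1", "s2", "s3", "s4"]:
            diff = df.drop(index="g0")[s] - target
            dists[s] = float((diff ** 2).mean())
        nearest = sorted(dists, key=dists.get)[:2]
        expected = df.loc["g0", nearest].mean()
        assert out.values.loc["g0", "s0"] == pytest.approx(expected)

    def test_high_missing_features_removed(self):
        df = pd.DataFrame({
            "s1": [np.nan, 0.2], "s2": [np.nan, 0.4], "s3": [0.8, np.nan],
        }, index=["g_bad", "g_ok"])
        out = impute_knn(GeneSampleMatrix(df, "methylation"), k=1,
                         max_missing_fraction=0.5)
        assert list(out.values.index) == ["g_ok"]
        assert not out.values.isna().to_numpy().any()

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.random((6, 8)),
                          index=[f"g{i}" for i in range(6)],
                          columns=[f"s{i}" for i in range(8)])
        mask = rng.random((6, 8)) < 0.15
        df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))
        once = impute_knn(GeneSampleMatrix(df, "methylation"), k=3)
        twice = impute_knn(once, k=3)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_wrong_modality_rejected(self):
        df = pd.DataFrame({"s1": [1.0]}, index=["g"])
        with pytest.raises(OmicsError):
            impute_knn(GeneSampleMatrix(df, "mutation"))


class TestScaling:
    def test_fit_min_max(self):
        df = pd.DataFrame({"s1": [2.0], "s2": [4.0], "s3": [6.0]}, index=["g"])
        params = fit_scaler(GeneSampleMatrix(df, "cna"))
        assert params.min["g"] == 2 and params.max["g"] == 6

    def test_apply_basic(self):
        df = pd.DataFrame({"s1": [2.0], "s2": [4.0], "s3": [6.0]}, index=["g"])
        mat = GeneSampleMatrix(df, "cna")
        out = apply_scaler(mat, fit_scaler(mat))
        np.testing.assert_allclose(out.values.loc["g"], [0.0, 0.5, 1.0])

    def test_constant_feature_maps_to_zero(self):
        df = pd.DataFrame({"s1": [3.0], "s2": [3.0]}, index=["g"])
        mat = GeneSampleMatrix(df, "cna")
        out = apply_scaler(mat, fit_scaler(mat))
        assert (out.values.loc["g"] == 0.0).all()

    def test_out_of_range_clipped(self):
        train = GeneSampleMatrix(
            pd.DataFrame({"s1": [0.0], "s2": [10.0]}, index=["g"]), "cna")
        params = fit_scaler(train)
        test = GeneSampleMatrix(pd.DataFrame({"t1": [12.0]}, index=["g"]), "cna")
        out = apply_scaler(test, params)
        assert out.values.loc["g", "t1"] == 1.0

    def test_train_range_property(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(10, 7)) * 4,
                          index=[f"g{i}" for i in range(10)],
                          columns=[f"s{i}" for i in range(7)])
        mat = GeneSampleMatrix(df, "cna")
        out = apply_scaler(mat, fit_scaler(mat))
        vals = out.values.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_missing_params_error(self):
        mat = GeneSampleMatrix(pd.DataFrame({"s1": [1.0]}, index=["g2"]), "cna")
        params = fit_scaler(GeneSampleMatrix(
            pd.DataFrame({"s1": [1.0]}, index=["g1"]), "cna"))
        with pytest.raises(OmicsError):
            apply_scaler(mat, params)


class TestAssemble:
    def _parts(self, extra_mut=()):
        samples = ["s1", "s2", "s3"]
        def mk(modality, cols):
            return GeneSampleMatrix(
                pd.DataFrame(np.zeros((2, len(cols))),
                             index=["g1", "g2"], columns=cols), modality)
        mut = mk("mutation", samples + list(extra_mut))
        cna = mk("cna", samples)
        meth = mk("methylation", samples)
        clin = omics_io.ClinicalTable(pd.DataFrame({
            "age": [50, 60, 70], "sex": ["female", "male", "female"],
            "os_time": [1.0, 2.0, 3.0], "os_event": [1, 0, 1]},
            index=samples))
        return mut, cna, meth, clin

    def test_intersection(self):
        mut, cna, meth, clin = self._parts(extra_mut=["s9"])
        cohort = assemble_cohort(mut, cna, meth, clin)
        assert list(cohort.samples) == ["s1", "s2", "s3"]

    def test_identical_sets_preserved(self):
        cohort = assemble_cohort(*self._parts())
        assert cohort.n_samples == 3

    def test_bad_label_rejected(self):
        mut, cna, meth, clin = self._parts()
        labels = pd.Series(["EBV+", "CIN", "GS"], index=["s1", "s2", "s3"])
        with pytest.raises(OmicsError):
            assemble_cohort(mut, cna, meth, clin, labels)

    def test_empty_intersection_errors(self):
        mut, cna, meth, clin = self._parts()
        other = GeneSampleMatrix(
            pd.DataFrame(np.zeros((2, 1)), index=["g1", "g2"],
                         columns=["zz"]), "cna")
        with pytest.raises(OmicsError):
            assemble_cohort(mut, other, meth, clin)
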