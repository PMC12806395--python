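"""Alteration rates, OVR difference tests, MANOVA integration check."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from hcg.markers import (MarkerError, alteration_rates, difference_tests,
                         manova_check, per_sample_rates)
from hcg.omics_io import ClinicalTable, GeneSampleMatrix, OmicsCohort
from hcg.simulate import SimulationConfig, simulate_cohort


def _cohort_from(mut, cna, meth, labels):
    samples = list(mut.columns)
    clin = ClinicalTable(pd.DataFrame({
        "age": 60.0, "sex": "female", "os_time": 1.0, "os_event": 1},
        index=samples))
    return OmicsCohort(GeneSampleMatrix(mut, "mutation"),
                       GeneSampleMatrix(cna, "cna"),
                       GeneSampleMatrix(meth, "methylation"),
                       clin, pd.Series(labels, index=samples))


class TestRates:
    def test_all_zero_mutations(self):
        samples = [f"s{i}" for i in range(4)]
        z = pd.DataFrame(0.0, index=["g1", "g2"], columns=samples)
        m = pd.DataFrame(0.5, index=["g1", "g2"], columns=samples)
        cohort = _cohort_from(z, z.copy(), m, ["CIN", "CIN", "MSI", "MSI"])
        rates = alteration_rates(cohort)
        assert (rates["mutation"].dropna() == 0.0).all()
        assert (rates["methylation"].dropna() == 0.5).all()

    def test_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(6)]
        genes = [f"g{i}" for i in range(8)]
        mut = pd.DataFrame(rng.integers(0, 2, (8, 6)).astype(float),
                           index=genes, columns=samples)
        cna = pd.DataFrame(rng.choice([0.0, 1.0, -2.0], (8, 6)),
                           index=genes, columns=samples)
        meth = pd.DataFrame(rng.random((8, 6)), index=genes, columns=samples)
        labels = ["CIN", "CIN", "CIN", "MSI", "MSI", "MSI"]
        cohort = _cohort_from(mut, cna, meth, labels)
        rates = alteration_rates(cohort)
        for sub in ("CIN", "MSI"):
            idx = [i for i, l in enumerate(labels) if l == sub]
            n_k = len(idx)
            mut_sum = sum(mut.iloc[g, i] for g in range(8) for i in idx)
            cna_sum = sum(1.0 for g in range(8) for i in idx
                          if cna.iloc[g, i] != 0.0)
            meth_sum = sum(meth.iloc[g, i] for g in range(8) for i in idx)
            assert rates.loc[sub, "mutation"] == pytest.approx(
                mut_sum / (n_k * 8), abs=1e-15)
            assert rates.loc[sub, "cna"] == pytest.approx(
                cna_sum / (n_k * 8), abs=1e-15)
            assert rates.loc[sub, "methylation"] == pytest.approx(
                meth_sum / (n_k * 8), abs=1e-15)

    def test_cna_indicator_continuous_threshold(self):
        samples = ["s1", "s2"]
        z = pd.DataFrame(0.0, index=["g"], columns=samples)
        m = pd.DataFrame(0.5, index=["g"], columns=samples)
        cna = pd.DataFrame([[0.2, 0.4]], index=["g"], columns=samples)
        cohort = _cohort_from(z, cna, m, ["CIN", "MSI"])
        discrete = alteration_rates(cohort)                      # |v| > 1e-9
        continuous = alteration_rates(cohort, cna_continuous=True)  # |v| >= 0.3
        assert discrete.loc["CIN", "cna"] == 1.0
        assert continuous.loc["CIN", "cna"] == 0.0
        assert continuous.loc["MSI", "cna"] == 1.0

    def test_empty_subtype_is_nan(self):
        samples = ["s1", "s2"]
        z = pd.DataFrame(0.0, index=["g"], columns=samples)
        m = pd.DataFrame(0.5, index=["g"], columns=samples)
        cohort = _cohort_from(z, z.copy(), m, ["CIN", "CIN"])
        rates = alteration_rates(cohort)
        assert np.isnan(rates.loc["EBV", "mutation"])


class TestFisherOracle:
    @staticmethod
    def _fisher_two_sided_oracle(a, b, c, d):
        """Exhaustive hypergeometric enumeration with fixed margins."""
        row1, row2 = a + b, c + d
        col1 = a + c
        n = row1 + row2
        def table_p(x):
            return (comb(row1, x, exact=True)
                    * comb(row2, col1 - x, exact=True)) / comb(n, col1,
                                                               exact=True)
        p_obs = table_p(a)
        total = 0.0
        for x in range(max(0, col1 - row2), min(row1, col1) + 1):
            px = table_p(x)
            if px <= p_obs * (1 + 1e-9):
                total += px
        return min(total, 1.0)

    def test_worked_table(self):
        _, p = stats.fisher_exact([[8, 2], [1, 9]], alternative="two-sided")
        assert p == pytest.approx(self._fisher_two_sided_oracle(8, 2, 1, 9),
                                  rel=1e-9)

    def test_enumeration_small_margins(self):
        for a, b, c, d in itertools.product(range(0, 5), repeat=4):
            if (a + c) == 0 or (b + d) == 0 or (a + b) == 0 or (c + d) == 0:
                continue
            _, p = stats.fisher_exact([[a, b], [c, d]],
                                      alternative="two-sided")
            assert p == pytest.approx(
                self._fisher_two_sided_oracle(a, b, c, d), rel=1e-9), \
                (a, b, c, d)


class TestDifferenceTests:
    def _strong_cfg(self, seed):
        # strong planted effects for recovery checks
        return SimulationConfig(
            n_samples=200, n_genes=60, n_marker_genes=3,
            marker_mutation_rate=0.6, marker_cna_rate=0.8,
            marker_meth_shift=0.4, marker_home_boost=1.0,
            mutation_dispersion=0.0, cna_dispersion=0.0,
            methylation_sample_sd=0.0, missing_rate=0.0,
            subtype_proportions=(0.25, 0.25, 0.25, 0.25), seed=seed)

    def test_planted_markers_recovered_with_directions(self):
        recovered, planted, dir_errors = 0, 0, 0
        for seed in range(3):
            cohort, truth = simulate_cohort(self._strong_cfg(seed))
            table = difference_tests(cohort, alpha=1e-5)
            found = {(r.gene, r.modality): (r.subtype, r.direction)
                     for r in table.itertuples()}
            for r in truth.markers.itertuples():
                planted += 1
                hit = found.get((r.gene, r.modality))
                if hit and hit[0] == r.subtype:
                    recovered += 1
                    if r.modality != "mutation" and hit[1] != r.direction:
                        dir_errors += 1
        assert recovered >= 0.9 * planted
        assert dir_errors == 0

    def test_direction_convention_hypermethylated(self):
        # EBV-hypermethylated marker must carry "+"
        cohort, truth = simulate_cohort(self._strong_cfg(5))
        table = difference_tests(cohort, alpha=1e-5)
        ebv_meth = table[(table.subtype == "EBV")
                         & (table.modality == "methylation")]
        planted = truth.markers[(truth.markers.subtype == "EBV") &
                                (truth.markers.modality == "methylation")]
        hits = ebv_meth[ebv_meth.gene.isin(planted.gene)]
        assert len(hits) > 0
        assert (hits.direction == "+").all()

    def test_null_yields_no_markers(self):
        cfg = SimulationConfig(
            n_samples=120, n_genes=80, n_marker_genes=0,
            mutation_rates=(0.05,) * 4, cna_event_rates=(0.1,) * 4,
            methylation_means=(0.3,) * 4, mutation_dispersion=0.0,
            cna_dispersion=0.0, methylation_sample_sd=0.0,
            subtype_proportions=(0.25, 0.25, 0.25, 0.25),
            missing_rate=0.0, seed=8)
        cohort, _ = simulate_cohort(cfg)
        table = difference_tests(cohort, alpha=1e-5)
        assert len(table) == 0

    def test_adjusted_p_at_least_raw(self):
        cohort, _ = simulate_cohort(self._strong_cfg(2))
        table = difference_tests(cohort, alpha=1.0)
        assert (table.adjusted_p >= table.raw_p - 1e-15).all()

    def test_dedup_one_row_per_gene_modality(self):
        cohort, _ = simulate_cohort(self._strong_cfg(3))
        table = difference_tests(cohort, alpha=1.0)
        assert not table.duplicated(subset=["gene", "modality"]).any()

    def test_feature_subset_restricts_tests(self):
        cohort, truth = simulate_cohort(self._strong_cfg(4))
        gene = truth.markers.iloc[0]
        subset = [f"{gene.modality}:{gene.gene}"]
        table = difference_tests(cohort, feature_subset=subset, alpha=1.0)
        assert set(table.modality) <= {gene.modality}
        assert set(table.gene) <= {gene.gene}


class TestManova:
    def test_permuted_identical_groups_p_one(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("xyz"))
        b = a.sample(frac=1.0, random_state=1).reset_index(drop=True)
        wilks, p = manova_check(a, b)
        assert wilks == pytest.approx(1.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_shifted_mean_detected(self):
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            a = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("xyz"))
            b = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("xyz"))
            b["x"] += 1.0
            _, p = manova_check(a, b)
            if p < 0.01:
                detected += 1
        assert detected >= 19

    def test_type_i_error_calibrated(self):
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            a = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("xyz"))
            b = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("xyz"))
            _, p = manova_check(a, b)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_variable_mismatch_rejected(self):
        a = pd.DataFrame(np.zeros((10, 2)), columns=["x", "y"])
        b = pd.DataFrame(np.zeros((10, 2)), columns=["x", "z"])
        with pytest.raises(MarkerError):
            manova_check(a, b)

    def test_small_groups_rejected(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame(rng.normal(size=(3, 3)), columns=list("xyz"))
        b = pd.DataFrame(rng.normal(size=(3, 3)), columns=list("xyz"))
        with pytest.raises(MarkerError):
            manova_check(a, b)

    def test_per_sample_rates_as_integration_variables(self, tiny_cohort):
        rates = per_sample_rates(tiny_cohort)
        assert list(rates.columns) == ["mutation_rate", "cna_rate",
                                       "methylation_rate"]
        assert len(rates) == tiny_cohort.n_samples
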