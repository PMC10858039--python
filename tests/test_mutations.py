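"""Somatic mutation calling, dropout filtering and patient summaries."""

import numpy as np
import pandas as pd
import pytest

from estrpipe.errors import DataError
from estrpipe.mutations import (
    call_cohort_mutations,
    call_mutations,
    rank_patients_by_deletion,
    select_healthy_reference,
    step_size_histogram,
    summarize_cohort,
    summarize_patient,
)
from estrpipe.simulate import SimulationConfig, generate_cohort


def _sample_calls(sample_id, genotypes):
    rows = [
        {
            "sample_id": sample_id,
            "locus_id": locus,
            "allele_a": min(pair),
            "allele_b": max(pair),
            "depth": 50,
        }
        for locus, pair in genotypes.items()
    ]
    frame = pd.DataFrame(rows)
    frame["depth"] = frame["depth"].astype("Int64")
    return frame


class TestHealthyReference:
    def test_most_calls_wins(self):
        samples = pd.DataFrame(
            {
                "sample_id": ["B1", "N1"],
                "sample_type": ["blood_normal", "solid_tissue_normal"],
                "n_calls": [12000, 11000],
            }
        )
        assert select_healthy_reference(samples) == "B1"

    def test_single_healthy_sample(self):
        samples = pd.DataFrame(
            {"sample_id": ["N1"], "sample_type": ["solid_tissue_normal"], "n_calls": [5]}
        )
        assert select_healthy_reference(samples) == "N1"

    def test_tie_prefers_blood(self):
        samples = pd.DataFrame(
            {
                "sample_id": ["N1", "B1"],
                "sample_type": ["solid_tissue_normal", "blood_normal"],
                "n_calls": [10000, 10000],
            }
        )
        assert select_healthy_reference(samples) == "B1"

    def test_no_healthy_sample_errors(self):
        samples = pd.DataFrame(
            {"sample_id": ["T1"], "sample_type": ["primary_tumour"], "n_calls": [9]}
        )
        with pytest.raises(DataError):
            select_healthy_reference(samples)


class TestCallMutations:
    def test_insertion_event(self):
        events, comparisons, nd = call_mutations(
            _sample_calls("H", {"L1": (10, 10)}),
            _sample_calls("T", {"L1": (10, 12)}),
            "P1",
        )
        assert nd == 0 and len(events) == 1
        ev = events.iloc[0]
        assert (ev["step_1"], ev["step_2"]) == (0, 2)
        assert ev["delta_mean"] == 1.0
        assert ev["has_insertion"] and not ev["has_deletion"]

    def test_identical_genotype_no_event(self):
        events, comparisons, _ = call_mutations(
            _sample_calls("H", {"L1": (10, 12)}),
            _sample_calls("T", {"L1": (12, 10)}),
            "P1",
        )
        assert events.empty and len(comparisons) == 1 and not comparisons.iloc[0]["mutated"]

    def test_homozygous_unseen_allele_excluded_as_dropout(self):
        events, comparisons, nd = call_mutations(
            _sample_calls("H", {"L1": (10, 12)}),
            _sample_calls("T", {"L1": (14, 14)}),
            "P1",
        )
        assert nd == 1 and events.empty and comparisons.empty

    def test_homozygous_for_seen_allele_is_a_mutation(self):
        events, _, nd = call_mutations(
            _sample_calls("H", {"L1": (10, 12)}),
            _sample_calls("T", {"L1": (12, 12)}),
            "P1",
        )
        assert nd == 0 and len(events) == 1

    def test_deletion_event_delta(self):
        events, _, _ = call_mutations(
            _sample_calls("H", {"L1": (10, 12)}),
            _sample_calls("T", {"L1": (9, 12)}),
            "P1",
        )
        ev = events.iloc[0]
        assert ev["delta_mean"] == -0.5 and ev["has_deletion"] and not ev["has_insertion"]

    def test_only_shared_loci_compared(self):
        events, comparisons, _ = call_mutations(
            _sample_calls("H", {"L1": (10, 10), "L2": (8, 8)}),
            _sample_calls("T", {"L1": (10, 10), "L3": (9, 9)}),
            "P1",
        )
        assert comparisons["locus_id"].tolist() == ["L1"]

    def test_duplicate_locus_is_a_data_error(self):
        dup = pd.concat(
            [_sample_calls("H", {"L1": (10, 10)})] * 2, ignore_index=True
        )
        with pytest.raises(DataError, match="L1"):
            call_mutations(dup, _sample_calls("T", {"L1": (10, 10)}), "P1")


class TestStepHistogram:
    def test_masses(self):
        events = pd.DataFrame(
            {
                "patient_id": ["P"] * 4,
                "step_1": [1, -1, -1, -1],
                "step_2": [0, 0, 0, 0],
            }
        )
        hist = step_size_histogram(events)
        masses = dict(zip(hist["step"], hist["mass"]))
        assert masses == {1: 0.25, -1: 0.75}

    def test_groups_each_sum_to_one(self):
        events = pd.DataFrame(
            {
                "patient_id": ["P1", "P1", "P2"],
                "step_1": [1, 2, -1],
                "step_2": [0, -1, -2],
            }
        )
        labels = pd.Series({"P1": "MSS", "P2": "MSI"})
        hist = step_size_histogram(events, labels)
        sums = hist.groupby("group")["mass"].sum()
        assert np.allclose(sums, 1.0)

    def test_symmetric_generator_gives_symmetric_histogram(self):
        # no MSI deletion bias: insertions and deletions equally likely
        config = SimulationConfig(
            n_patients_mss=30,
            n_patients_msi=0,
            n_patients_validation=0,
            n_loci=800,
            n_estr=0,
            base_mutation_rate_per_locus=0.05,
            seed=5,
        )
        cohort = generate_cohort(config)
        events, _, _ = call_cohort_mutations(cohort.calls, cohort.metadata)
        hist = step_size_histogram(events)
        counts = dict(zip(hist["step"], hist["count"]))
        magnitudes = sorted({abs(s) for s in counts})
        pairs = [
            (counts.get(m, 0), counts.get(-m, 0))
            for m in magnitudes
            if counts.get(m, 0) + counts.get(-m, 0) >= 20
        ]
        # chi-square of observed vs mirrored counts: symmetric within noise
        chi2 = sum((a - b) ** 2 / (a + b) for a, b in pairs)
        from scipy import stats

        assert stats.chi2.sf(chi2, df=len(pairs)) > 0.001


class TestSummaries:
    def _events(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "patient_id",
                "locus_id",
                "delta_mean",
                "has_insertion",
                "has_deletion",
            ],
        )

    def test_fraction_mutated(self):
        events = self._events(
            [("P1", f"L{i}", 1.0, True, False) for i in range(5)]
        )
        summary = summarize_patient(events, 100, "P1", "MSS")
        assert summary.frac_mutated == 0.05

    def test_mixed_event_counts_in_both_fractions(self):
        events = self._events([("P1", "L1", 0.0, True, True)])
        summary = summarize_patient(events, 10, "P1", "MSI")
        assert summary.frac_with_insertion == 0.1 and summary.frac_with_deletion == 0.1

    def test_zero_compared_errors(self):
        with pytest.raises(DataError):
            summarize_patient(self._events([]), 0, "P1")

    def test_deletion_only_patient_has_zero_insertion_fraction(self):
        config = SimulationConfig(
            n_patients_mss=0,
            n_patients_msi=3,
            n_patients_validation=0,
            n_loci=400,
            n_estr=0,
            insertion_bias=0.0,
            base_mutation_rate_per_locus=0.05,
            seed=2,
        )
        cohort = generate_cohort(config)
        events, comparisons, _ = call_cohort_mutations(cohort.calls, cohort.metadata)
        summaries = summarize_cohort(events, comparisons, cohort.metadata)
        assert (summaries["frac_with_insertion"] == 0).all()
        assert (summaries["frac_with_deletion"] > 0).all()


class TestDeletionRanking:
    def _summaries(self, fracs, labels):
        return pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(len(fracs))],
                "msi_label": labels,
                "frac_with_deletion": fracs,
            }
        )

    def test_perfect_separation_auc_one(self):
        summaries = self._summaries([0.5, 0.4, 0.1, 0.05], ["MSI", "MSI", "MSS", "MSS"])
        ordered, auc = rank_patients_by_deletion(summaries)
        assert auc == 1.0
        assert ordered["frac_with_deletion"].is_monotonic_decreasing

    def test_shuffled_labels_auc_near_half(self):
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(50):
            fracs = rng.random(40)
            labels = rng.permutation(["MSI"] * 10 + ["MSS"] * 30)
            _, auc = rank_patients_by_deletion(self._summaries(fracs, list(labels)))
            aucs.append(auc)
        # null AUC mean 0.5 with SE ~ sqrt(1/12 * (1/10 + 1/30)) / sqrt(50)
        se = np.sqrt((10 + 30 + 1) / (12 * 10 * 30)) / np.sqrt(50)
        assert abs(np.mean(aucs) - 0.5) < 3 * se

    def test_single_label_cohort_flagged(self):
        _, auc = rank_patients_by_deletion(self._summaries([0.1, 0.2], ["MSS", "MSS"]))
        assert auc is None


class TestPlantedRecovery:
    def test_exact_recovery_without_dropout(self):
        config = SimulationConfig(
            n_patients_mss=10,
            n_patients_msi=5,
            n_patients_validation=0,
            n_loci=500,
            n_estr=0,
            seed=9,
        )
        cohort = generate_cohort(config)
        events, _, dropout = call_cohort_mutations(cohort.calls, cohort.metadata)
        called = {
            (e.patient_id, e.locus_id, e.healthy_a, e.healthy_b, e.tumour_a, e.tumour_b)
            for e in events.itertuples()
        }
        planted = {
            (m["patient_id"], m["locus_id"], *m["healthy"], *m["tumour"])
            for m in cohort.truth.planted_mutations
        }
        assert called == planted
        assert sum(dropout.values()) == 0

    def test_dropout_filter_removes_planted_artifacts(self):
        config = SimulationConfig(
            n_patients_mss=10,
            n_patients_msi=5,
            n_patients_validation=0,
            n_loci=500,
            n_estr=0,
            dropout_fraction=0.05,
            seed=9,
        )
        cohort = generate_cohort(config)
        events, _, dropout = call_cohort_mutations(cohort.calls, cohort.metadata)
        n_planted_dropout = len(cohort.truth.planted_dropout)
        assert n_planted_dropout > 0
        # artifacts are homozygous for an unseen allele by construction:
        # the filter removes every one of them (>= 95% required)
        assert sum(dropout.values()) >= 0.95 * n_planted_dropout
        called = {(e.patient_id, e.locus_id) for e in events.itertuples()}
        artifacts = {
            (m["patient_id"], m["locus_id"]) for m in cohort.truth.planted_dropout
        }
        assert not called & artifacts
        planted = {
            (m["patient_id"], m["locus_id"]) for m in cohort.truth.planted_mutations
        }
        assert called == planted
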