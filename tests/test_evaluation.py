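"""Evaluation harness: set families, scores, leakage, hold-out guard."""

import math

import numpy as np
import pytest

from gagir.evaluation import (
    LeakageError,
    PipelineConfig,
    TrainingSetSpec,
    augmented_sets,
    canonical_tasks,
    holdout_sets,
    loo_sets,
    prediction_score,
    run_experiment,
    validate_holdout,
)
from gagir.feature_selection import GAConfig
from gagir.forest import ForestConfig
from gagir.spectra import SpectrumLibrary
from gagir.synthetic_data import SynthConfig, default_composition, generate_library


def tiny_config(seed=0, ga=True):
    """Fast pipeline settings for harness-mechanics tests."""
    return PipelineConfig(
        seed=seed,
        ga=GAConfig(mu=6, lambda_=12, generations=4, cv="loo") if ga else None,
        fitness_forest=ForestConfig(n_trees=8),
        final_forest=ForestConfig(n_trees=30),
    )


class TestTrainingSetFamilies:
    def test_loo_over_16_gives_16_sets_of_15(self):
        ids = [f"s{i}" for i in range(16)]
        sets = loo_sets(ids)
        assert len(sets) == 16
        assert all(s.m == 15 for s in sets)
        assert sorted(s.excluded_sample_ids[0] for s in sets) == sorted(ids)

    @pytest.mark.parametrize("n", [3, 5, 9])
    def test_loo_counts_general(self, n):
        sets = loo_sets([str(i) for i in range(n)])
        assert len(sets) == n and all(s.m == n - 1 for s in sets)

    def test_loo_below_three_rejected(self):
        with pytest.raises(ValueError):
            loo_sets(["a", "b"])

    def test_augmented_counts_match_binomials(self):
        base = [f"d{i}" for i in range(16)]
        add = [f"t{i}" for i in range(6)]
        sets = augmented_sets(base, add, [1, 2, 3, 4, 5])
        assert len(sets) == 62
        by_family = {}
        for s in sets:
            by_family.setdefault(s.family_tag, []).append(s)
        assert {k: len(v) for k, v in sorted(by_family.items())} == {
            "X_m=17": 6, "X_m=18": 15, "X_m=19": 20, "X_m=20": 15, "X_m=21": 6,
        }
        for k, fam in by_family.items():
            m = int(k.split("=")[1])
            assert all(s.m == m for s in fam)
            assert all(len(s.excluded_sample_ids) == 16 + 6 - m for s in fam)

    def test_k_zero_gives_base_only(self):
        sets = augmented_sets(["a", "b"], ["c"], [0])
        assert len(sets) == 1 and sets[0].included_sample_ids == ("a", "b")

    def test_k_above_addable_rejected(self):
        with pytest.raises(ValueError):
            augmented_sets(["a"], ["b", "c"], [3])

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            augmented_sets(["a", "b"], ["b"], [1])
        with pytest.raises(ValueError):
            TrainingSetSpec(("a", "b"), ("b",), "x")


class TestPredictionScore:
    @pytest.mark.parametrize(
        "pairs,expected",
        [
            ([(1, 1), (1, 1), (0, 1), (1, 1)], 0.75),
            ([(1, 1), (0, 0)], 1.0),
            ([(1, 0), (0, 1)], 0.0),
        ],
    )
    def test_fraction_correct(self, pairs, expected):
        bools = [(bool(p), bool(t)) for p, t in pairs]
        assert prediction_score(bools) == expected

    def test_order_invariant(self):
        pairs = [(True, True), (False, True), (True, False), (True, True)]
        assert prediction_score(pairs) == prediction_score(pairs[::-1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            prediction_score([])


class TestRunExperiment:
    def test_model_count_is_sets_times_tasks(self, di_library):
        sets = loo_sets(di_library.sample_ids)[:1]
        tasks = canonical_tasks()[:2]
        report = run_experiment(di_library, sets, tasks, tiny_config())
        assert report.model_count == 2
        assert report.trained_count + len(report.skipped) == 2

    def test_unknown_sample_id_rejected(self, di_library):
        bad = [TrainingSetSpec(tuple(di_library.sample_ids[:4]), ("nope",), "x")]
        with pytest.raises(KeyError):
            run_experiment(di_library, bad, canonical_tasks()[:1], tiny_config())

    def test_single_class_task_skipped_not_dropped(self, di_library):
        cs_only = [s for s in di_library.sample_ids if s.startswith("cs")]
        sets = [TrainingSetSpec(tuple(cs_only[:7]), (cs_only[7],), "cs")]
        tasks = [t for t in canonical_tasks() if t.task_id == "class_hs_cs"]
        report = run_experiment(di_library, sets, tasks, tiny_config())
        assert report.trained_count == 0
        assert [t for _, t in report.skipped] == ["class_hs_cs"]
        assert report.model_count == 1

    def test_deterministic_report(self, di_library):
        sets = loo_sets(di_library.sample_ids)[:2]
        tasks = canonical_tasks()[1:3]
        r1 = run_experiment(di_library, sets, tasks, tiny_config(seed=3))
        r2 = run_experiment(di_library, sets, tasks, tiny_config(seed=3))
        assert r1.to_json() == r2.to_json()

    def test_excluded_sample_never_influences_model(self, di_library):
        """Permuting an excluded sample's spectrum leaves the trained model
        byte-identical (no leakage through scaling or selection)."""
        sets = loo_sets(di_library.sample_ids)[:1]
        excluded = sets[0].excluded_sample_ids[0]
        tasks = canonical_tasks()[1:2]

        r1 = run_experiment(di_library, sets, tasks, tiny_config(seed=1))

        rng = np.random.default_rng(0)
        tampered = []
        for spec, m in di_library.samples:
            if m.sample_id == excluded:
                from gagir.spectra import Spectrum

                spec = Spectrum(
                    spec.sample_id,
                    spec.wavenumbers,
                    rng.permutation(spec.intensities),
                )
            tampered.append((spec, m))
        r2 = run_experiment(SpectrumLibrary(tampered), sets, tasks, tiny_config(seed=1))
        assert r1.outcomes[0].model_digest == r2.outcomes[0].model_digest
        assert r1.outcomes[0].selected_features == r2.outcomes[0].selected_features

    def test_report_export_shapes(self, tmp_path, di_library):
        sets = loo_sets(di_library.sample_ids)[:2]
        tasks = canonical_tasks()[1:3]
        report = run_experiment(di_library, sets, tasks, tiny_config())
        d = report.to_dict()
        assert d["model_count"] == 4
        assert set(d["per_task_scores"]) <= {"ns", "s2"}
        csv_path = tmp_path / "report.csv"
        report.to_csv(csv_path)
        assert csv_path.read_text().count("\n") == 1 + sum(
            len(o.predictions) for o in report.outcomes
        )


class TestValidateHoldout:
    def test_seven_sets_times_five_tasks(self, full_library):
        di = [m.sample_id for _, m in full_library.samples if m.oligomer_length == "di"]
        tet = [m.sample_id for _, m in full_library.samples if m.oligomer_length == "tetra"]
        sets = holdout_sets(di, tet, "hexa-01")
        assert len(sets) == 7  # six X_m=21 + one X_m=22
        assert {s.family_tag for s in sets} == {"X_m=21", "X_m=22"}
        report = validate_holdout(full_library, sets, "hexa-01",
                                  canonical_tasks()[1:2], tiny_config())
        assert all(o.predictions[0].sample_id == "hexa-01" for o in report.outcomes)

    def test_hexasaccharide_recovered_across_all_tasks(self, full_library):
        """Every X_m=21 / X_m=22 model classifies the held-out synthetic
        hexasaccharide correctly on all five tasks, with high vote
        confidence (uniformly ≥ 0.9 for the complete X_m=22 set)."""
        di = [m.sample_id for _, m in full_library.samples if m.oligomer_length == "di"]
        tet = [m.sample_id for _, m in full_library.samples if m.oligomer_length == "tetra"]
        sets = holdout_sets(di, tet, "hexa-01")
        report = validate_holdout(
            full_library, sets, "hexa-01", canonical_tasks(), PipelineConfig.reduced(seed=11)
        )
        preds = [o.predictions[0] for o in report.outcomes]
        assert len(preds) == 35
        assert all(p.correct for p in preds)
        assert np.mean([p.confidence for p in preds]) >= 0.8
        for o in report.outcomes:
            if o.training_set.family_tag == "X_m=22":
                assert o.predictions[0].confidence >= 0.9

    def test_leakage_guard(self, full_library):
        di = [m.sample_id for _, m in full_library.samples if m.oligomer_length == "di"]
        bad = [TrainingSetSpec(tuple(di + ["hexa-01"]), (), "X")]
        with pytest.raises(LeakageError):
            validate_holdout(full_library, bad, "hexa-01", canonical_tasks()[:1])
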