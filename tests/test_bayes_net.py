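from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oxyreq.bayes_net import (
    BayesParams,
    OneStepModel,
    TwoStepModel,
    classify,
    posterior,
    predict_one_step_loocv,
    predict_two_step_loocv,
)
from oxyreq.core_io import (
    AA_ONLY_SCHEME,
    ClassScheme,
    LikelihoodTable,
    ONE_STEP_SCHEME,
    PresenceMatrix,
    STEP1_SCHEME,
    STEP2_SCHEME,
)
from oxyreq.evaluation import confusion_table, per_class_mcc
from oxyreq.feature_selection import (
    EmptyClassError,
    SelectionParams,
    select_class_associated_domains,
)
from oxyreq.synthetic_data import SyntheticSpec, generate


def table_2class(likelihoods, domains=None):
    likelihoods = np.atleast_2d(likelihoods)
    n = likelihoods.shape[0]
    return LikelihoodTable(
        classes=("A", "B"),
        domain_ids=domains or [f"PF{j:05d}" for j in range(1, n + 1)],
        likelihoods=likelihoods,
        associated_class=["A"] * n,
    )


class TestPosterior:
    def test_empty_table_is_prior_with_tie(self, caplog):
        table = LikelihoodTable.empty(("A", "B"))
        with caplog.at_level("WARNING"):
            res = posterior(set(), table)
        assert res.posteriors.tolist() == pytest.approx([0.5, 0.5])
        assert res.tie
        assert res.predicted == "A"  # canonical tie-break: first class

    def test_single_domain_present(self):
        table = table_2class([[0.9, 0.2]])
        res = posterior({"PF00001"}, table)
        assert res.probability("A") == pytest.approx(0.45 / 0.55)
        assert res.predicted == "A"
        assert not res.tie

    def test_pseudo_count_floors_absence(self):
        # p(present|A) = 1.0 observed absent: likelihood clamps to 0.1, not 0
        table = table_2class([[1.0, 0.5]])
        res = posterior(set(), table, BayesParams(pseudo_count=0.1))
        assert res.probability("A") > 0
        assert res.probability("A") == pytest.approx(0.1 / (0.1 + 0.5))

    def test_pc_zero_zeroes_class(self):
        table = table_2class([[1.0, 0.5]])
        res = posterior(set(), table, BayesParams(pseudo_count=0.0))
        assert res.probability("A") == 0.0

    def test_pc_never_exactly_zero(self):
        table = table_2class([[1.0, 0.5], [1.0, 0.5], [0.0, 0.5]])
        res = posterior({"PF00003"}, table, BayesParams(pseudo_count=0.1))
        assert 0 < res.probability("A") < 1

    def test_symmetry_swap(self):
        lik = np.array([[0.9, 0.2], [0.3, 0.7], [0.6, 0.4]])
        profile = {"PF00001", "PF00003"}
        res = posterior(profile, table_2class(lik))
        # swapping the class columns reverses the posterior vector exactly
        res_swapped = posterior(profile, table_2class(lik[:, ::-1]))
        assert res_swapped.posteriors[::-1].tolist() == pytest.approx(
            res.posteriors.tolist(), abs=1e-12
        )
        # complementing both the table and the profile leaves it unchanged
        # (the clamp window [PC, 1-PC] is symmetric)
        complement = {"PF00002"}
        res_comp = posterior(complement, table_2class(1.0 - lik))
        assert res_comp.posteriors.tolist() == pytest.approx(
            res.posteriors.tolist(), abs=1e-12
        )

    def test_unknown_profile_domains_ignored(self):
        table = table_2class([[0.9, 0.2]])
        assert posterior({"PF00001", "PF99999"}, table).posteriors.tolist() == (
            posterior({"PF00001"}, table).posteriors.tolist()
        )

    def test_column_order_invariance(self):
        lik = np.array([[0.9, 0.2], [0.3, 0.7]])
        t1 = table_2class(lik)
        t2 = LikelihoodTable(
            classes=("B", "A"),
            domain_ids=list(t1.domain_ids),
            likelihoods=lik[:, ::-1],
            associated_class=["A", "A"],
        )
        r1 = posterior({"PF00001"}, t1)
        r2 = posterior({"PF00001"}, t2)
        assert r1.probability("A") == pytest.approx(r2.probability("A"), abs=1e-12)

    @given(
        data=st.data(),
        n_domains=st.integers(0, 20),
        n_classes=st.integers(2, 4),
        pc=st.floats(0.0, 0.4),
    )
    @settings(max_examples=150, deadline=None)
    def test_log_space_matches_direct_product(self, data, n_domains, n_classes, pc):
        lik = np.array(
            [
                [data.draw(st.floats(0.0, 1.0)) for _ in range(n_classes)]
                for _ in range(n_domains)
            ]
        )
        bits = np.array([data.draw(st.integers(0, 1)) for _ in range(n_domains)], float)
        classes = tuple(f"c{k}" for k in range(n_classes))
        table = LikelihoodTable(
            classes,
            [f"PF{j:05d}" for j in range(1, n_domains + 1)],
            lik,
            [classes[0]] * n_domains,
        )
        params = BayesParams(pseudo_count=pc)
        res = posterior(bits, table, params)
        # independent direct-product oracle in exact rational arithmetic
        # (a float product of 20 tiny likelihoods can underflow to zero)
        scores = [Fraction(1, n_classes)] * n_classes
        for j in range(n_domains):
            for k in range(n_classes):
                l = lik[j, k] if bits[j] else 1.0 - lik[j, k]
                if pc > 0:
                    l = min(max(l, pc), 1.0 - pc)
                scores[k] *= Fraction(l)
        assert res.posteriors.sum() == pytest.approx(1.0, abs=1e-9)
        total = sum(scores)
        if total > 0:
            expected = [float(s / total) for s in scores]
        else:  # every class zeroed (possible only at pc == 0): prior fallback
            expected = [1.0 / n_classes] * n_classes
        assert res.posteriors.tolist() == pytest.approx(expected, abs=1e-9)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            BayesParams(pseudo_count=0.5)
        with pytest.raises(ValueError):
            BayesParams(prior=(0.5, 0.6))
        with pytest.raises(ValueError):
            BayesParams(pc_mode="bogus")


def identical_genomes_matrix(n_per_class=3):
    genome_ids, labels = [], {}
    for cls in ("aerobe", "anaerobe", "facultative"):
        for i in range(n_per_class):
            g = f"{cls}_{i}"
            genome_ids.append(g)
            labels[g] = cls
    values = np.ones((len(genome_ids), 5), dtype=np.uint8)
    domains = [f"PF{j:05d}" for j in range(1, 6)]
    return PresenceMatrix(genome_ids, domains, values), labels


class TestOneStepLoocv:
    def test_planted_recovery(self, planted):
        _, m, labels = planted
        run = predict_one_step_loocv(m, labels)
        correct = sum(run.predictions[g] == labels[g] for g in run.genome_ids)
        assert correct / len(run.genome_ids) > 0.95

    def test_identical_genomes_tie_to_first_class(self):
        m, labels = identical_genomes_matrix()
        run = predict_one_step_loocv(m, labels)
        for g in run.genome_ids:
            assert run.predictions[g] == "aerobe"
            assert run.posteriors[g].tie

    def test_genome_order_invariance(self, planted):
        _, m, labels = planted
        rng = np.random.default_rng(1)
        perm = rng.permutation(m.n_genomes)
        m2 = PresenceMatrix(
            [m.genome_ids[i] for i in perm], list(m.domain_ids), m.values[perm]
        )
        run1 = predict_one_step_loocv(m, labels)
        run2 = predict_one_step_loocv(m2, labels)
        assert run1.predictions == run2.predictions

    def test_fold_excludes_held_out_genome(self, planted):
        # retraining twice without the held-out genome gives the identical table
        _, m, labels = planted
        g = m.genome_ids[0]
        t1 = select_class_associated_domains(m.drop_genomes([g]), labels, ONE_STEP_SCHEME)
        t2 = select_class_associated_domains(m.drop_genomes([g]), labels, ONE_STEP_SCHEME)
        assert t1.domain_ids == t2.domain_ids
        assert np.array_equal(t1.likelihoods, t2.likelihoods)
        run = predict_one_step_loocv(m, labels, store_tables=True)
        (fold_table,) = run.fold_tables[g]
        assert fold_table.domain_ids == t1.domain_ids
        assert np.array_equal(fold_table.likelihoods, t1.likelihoods)

    def test_class_with_two_members_errors(self):
        m, labels = identical_genomes_matrix(n_per_class=2)
        with pytest.raises(EmptyClassError):
            predict_one_step_loocv(m, labels)

    def test_fast_mode_close_to_full(self, planted):
        _, m, labels = planted
        full = predict_one_step_loocv(m, labels)
        fast = predict_one_step_loocv(m, labels, refit_selection=False)
        agree = sum(full.predictions[g] == fast.predictions[g] for g in full.genome_ids)
        assert agree / len(full.genome_ids) > 0.9


class TestTwoStepLoocv:
    def test_planted_recovery(self, planted):
        _, m, labels = planted
        run = predict_two_step_loocv(m, labels)
        correct = sum(run.predictions[g] == labels[g] for g in run.genome_ids)
        assert correct / len(run.genome_ids) > 0.95
        mccs = per_class_mcc(confusion_table(labels, run, run.classes))
        assert all(v > 0.9 for v in mccs.values())

    def test_step1_beats_one_step_anaerobe_dichotomy(self, planted):
        _, m, labels = planted
        two = predict_two_step_loocv(m, labels)
        one = predict_one_step_loocv(m, labels)
        def anaerobe_acc(preds):
            return np.mean(
                [(preds[g] == "anaerobe") == (labels[g] == "anaerobe") for g in preds]
            )
        step1_preds = {
            g: "anaerobe" if two.step1[g].predicted == "anaerobe" else "respiring"
            for g in two.step1
        }
        acc_step1 = np.mean(
            [
                (step1_preds[g] == "anaerobe") == (labels[g] == "anaerobe")
                for g in step1_preds
            ]
        )
        assert acc_step1 >= anaerobe_acc(one.predictions)

    def test_anaerobe_prediction_has_no_step2(self, planted):
        _, m, labels = planted
        run = predict_two_step_loocv(m, labels)
        predicted_anaerobe = [g for g, p in run.predictions.items() if p == "anaerobe"]
        assert predicted_anaerobe  # fixture contains anaerobes
        for g in predicted_anaerobe:
            assert g not in run.step2
        for g in run.genome_ids:
            assert g in run.step1
            if run.predictions[g] != "anaerobe":
                assert g in run.step2

    def test_zero_domain_genome_still_predicted(self, planted):
        _, m, labels = planted
        values = m.values.copy()
        values[0] = 0
        m2 = PresenceMatrix(list(m.genome_ids), list(m.domain_ids), values)
        run = predict_two_step_loocv(m2, labels)
        assert m.genome_ids[0] in run.predictions

    def test_agrees_with_flat_dichotomy_on_two_class_data(self, planted):
        # with only aerobes and anaerobes, step 1 of the nested network and a
        # flat aerobe-vs-anaerobe task train on the same dichotomy and must
        # predict identically (respiring == aerobe)
        _, m, labels = planted
        fac = [g for g in m.genome_ids if labels[g] == "facultative"]
        m2 = m.drop_genomes(fac)
        flat = predict_one_step_loocv(m2, labels, scheme=AA_ONLY_SCHEME)
        step1 = predict_one_step_loocv(m2, labels, scheme=STEP1_SCHEME)
        rename = {"respiring": "aerobe", "anaerobe": "anaerobe"}
        assert {g: rename[p] for g, p in step1.predictions.items()} == flat.predictions

    def test_label_shuffle_null_mcc(self, planted):
        # single-shuffle MCC on 90 genomes is noisy (sd ~ 0.2), so the null
        # is asserted on the mean over 10 fixed-seed shuffles
        _, m, labels = planted
        rng = np.random.default_rng(2024)
        sums = {c: 0.0 for c in ("aerobe", "anaerobe", "facultative")}
        n_shuffles = 10
        for _ in range(n_shuffles):
            shuffled = dict(zip(labels.keys(), rng.permutation(list(labels.values()))))
            run = predict_two_step_loocv(m, shuffled)
            mccs = per_class_mcc(confusion_table(shuffled, run, run.classes))
            for cls, v in mccs.items():
                sums[cls] += v / n_shuffles
        for cls, v in sums.items():
            assert abs(v) <= 0.15, (cls, v)


class TestClassify:
    def build_models(self, planted):
        _, m, labels = planted
        t1 = select_class_associated_domains(m, labels, STEP1_SCHEME)
        respiring = m.drop_genomes([g for g in m.genome_ids if labels[g] == "anaerobe"])
        t2 = select_class_associated_domains(respiring, labels, STEP2_SCHEME)
        flat = select_class_associated_domains(m, labels, ONE_STEP_SCHEME)
        return OneStepModel(flat), TwoStepModel(t1, t2)

    def test_planted_profile_recovered(self, planted):
        spec, m, labels = planted
        one, two = self.build_models(planted)
        # fresh profile carrying exactly the anaerobe-associated block
        profile = set(spec.planted_domains()["anaerobe"])
        assert classify(profile, one).predicted == "anaerobe"
        final, p1, p2 = two.predict_detailed(profile)
        assert final == "anaerobe"
        assert p2 is None

    def test_empty_profile_valid(self, planted):
        one, two = self.build_models(planted)
        res = classify(set(), one)
        assert res.posteriors.sum() == pytest.approx(1.0)

    def test_missing_step2_table_errors(self, planted):
        _, m, labels = planted
        t1 = select_class_associated_domains(m, labels, STEP1_SCHEME)
        broken = TwoStepModel(t1, None)
        profile = set(m.present_domains(m.genome_ids[0]))  # an aerobe genome
        with pytest.raises(ValueError, match="step-2"):
            broken.predict_detailed(profile)

    def test_model_save_load_round_trip(self, planted, tmp_path):
        one, two = self.build_models(planted)
        one.save(tmp_path / "one")
        two.save(tmp_path / "two")
        one2 = OneStepModel.load(tmp_path / "one")
        two2 = TwoStepModel.load(tmp_path / "two")
        profile = {"PFSYN00001", "PFSYN00042"}
        assert classify(profile, one).posteriors.tolist() == pytest.approx(
            classify(profile, one2).posteriors.tolist()
        )
        assert two.predict_detailed(profile)[0] == two2.predict_detailed(profile)[0]
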