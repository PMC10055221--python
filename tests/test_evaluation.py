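import itertools
import math

import numpy as np
import pytest

from predstack.alphabet import AA_TO_INDEX, CANONICAL_AA, N_AA
from predstack.errors import ConfigError, InputError
from predstack.evaluation import (
    AGREEMENT_LABELS,
    DEFAULT_CLASS_MAP,
    accuracy_correlation,
    agreement_summary,
    class_accuracy,
    classify_agreement,
    count_band,
    protein_accuracy,
    rsa_confidence_histogram,
    top_prediction,
    validate_class_map,
)
from predstack.formats_io import PredictionSet, SiteRecord

from conftest import one_hot

MODEL_TYPES = {"s1": "structure", "s2": "structure", "q1": "sequence", "q2": "sequence"}


class TestTopPrediction:
    def test_uniform_ties_to_alphabet_first(self, uniform_vector):
        assert top_prediction(uniform_vector) == ("A", 0.05)

    def test_clear_maximum(self):
        v = np.full(N_AA, 0.3 / 19)
        v[AA_TO_INDEX["W"]] = 0.7
        assert top_prediction(v) == ("W", 0.7)

    def test_two_way_tie(self):
        v = np.zeros(N_AA)
        v[AA_TO_INDEX["C"]] = 0.5
        v[AA_TO_INDEX["Y"]] = 0.5
        assert top_prediction(v) == ("C", 0.5)

    def test_non_finite_rejected(self):
        v = np.full(N_AA, 0.05)
        v[3] = np.nan
        with pytest.raises(ValueError):
            top_prediction(v)


class TestProteinAccuracy:
    def _build(self, tops, wts):
        pset = PredictionSet(model_ids=["m"])
        labels = []
        for i, (top, wt) in enumerate(zip(tops, wts), start=1):
            pset.entries[("p", i, "m")] = one_hot(top, 0.8)
            labels.append(SiteRecord("p", i, wt))
        return pset, labels

    def test_three_of_four(self):
        pset, labels = self._build("ACDE", "ACDY")
        result = protein_accuracy(pset, labels, "m", "p")
        assert result.fraction == 0.75
        assert (result.n_correct, result.n_sites) == (3, 4)

    def test_all_match(self):
        pset, labels = self._build("ACDE", "ACDE")
        assert protein_accuracy(pset, labels, "m", "p").fraction == 1.0

    def test_zero_sites_warns_nan(self):
        pset, labels = self._build("A", "A")
        with pytest.warns(UserWarning):
            result = protein_accuracy(pset, labels, "m", "nope")
        assert math.isnan(result.fraction)

    def test_brute_force_recount_oracle(self, small_panel):
        _, pset, labels = small_panel
        rng = np.random.default_rng(5)
        proteins = sorted({s.protein_id for s in labels})
        for pid in rng.choice(proteins, size=min(50, len(proteins)), replace=False):
            for mid in pset.model_ids:
                result = protein_accuracy(pset, labels, mid, pid)
                # independent site-by-site recount
                hits = total = 0
                for s in labels:
                    if s.protein_id != pid:
                        continue
                    v = pset.entries[(pid, s.position, mid)]
                    best = max(range(N_AA), key=lambda j: (v[j], -j))
                    hits += CANONICAL_AA[best] == s.wt_aa
                    total += 1
                assert (result.n_correct, result.n_sites) == (hits, total)


class TestClassAccuracy:
    def test_all_correct(self):
        pset = PredictionSet(model_ids=["m"])
        labels = []
        for i, aa in enumerate(CANONICAL_AA, start=1):
            pset.entries[("p", i, "m")] = one_hot(aa, 0.9)
            labels.append(SiteRecord("p", i, aa))
        acc = class_accuracy(pset, labels, "m")
        assert all(a.fraction == 1.0 for a in acc.values())

    def test_unique_only_predictor(self):
        pset = PredictionSet(model_ids=["m"])
        labels = []
        for i, aa in enumerate(CANONICAL_AA, start=1):
            top = aa if aa in "GP" else ("G" if aa != "G" else "P")
            pset.entries[("p", i, "m")] = one_hot(top, 0.9)
            labels.append(SiteRecord("p", i, aa))
        acc = class_accuracy(pset, labels, "m")
        assert acc["unique"].fraction == 1.0
        for cls in ("aliphatic", "aromatic", "polar", "positive", "negative"):
            assert acc[cls].fraction == 0.0

    def test_pooled_equals_weighted_mean_of_per_protein(self, small_panel):
        _, pset, labels = small_panel
        mid = pset.model_ids[0]
        pooled = class_accuracy(pset, labels, mid)
        for cls in ("aliphatic", "polar"):
            hits = total = 0
            for pid in sorted({s.protein_id for s in labels}):
                sub = [s for s in labels if s.protein_id == pid and
                       DEFAULT_CLASS_MAP[s.wt_aa] == cls]
                acc = class_accuracy(pset, sub, mid)
                hits += acc[cls].n_correct
                total += acc[cls].n_sites
            assert pooled[cls].n_correct == hits and pooled[cls].n_sites == total
            assert pooled[cls].fraction == pytest.approx(hits / total)

    def test_partial_class_map_rejected(self, tiny_pset):
        pset, labels = tiny_pset
        with pytest.raises(ConfigError):
            class_accuracy(pset, labels, "m1", class_map={"A": "aliphatic"})


class TestAccuracyCorrelation:
    def test_identity(self):
        a = [0.2, 0.5, 0.8, 0.3]
        r, p = accuracy_correlation(a, a)
        assert r == pytest.approx(1.0)

    def test_negation(self):
        a = np.array([0.2, 0.5, 0.8, 0.3])
        r, _ = accuracy_correlation(a, 1 - a)
        assert r == pytest.approx(-1.0)

    def test_closed_form_oracle(self):
        a = np.array([0.2, 0.4, 0.6])
        b = np.array([0.3, 0.3, 0.9])
        r, p = accuracy_correlation(a, b)
        # from-definition computation
        ca, cb = a - a.mean(), b - b.mean()
        r_expected = (ca * cb).sum() / np.sqrt((ca**2).sum() * (cb**2).sum())
        assert r == pytest.approx(r_expected, abs=1e-12)
        t = r_expected * np.sqrt(1 / (1 - r_expected**2))  # df = n - 2 = 1
        from scipy.stats import t as t_dist
        assert p == pytest.approx(2 * t_dist.sf(abs(t), 1), rel=1e-10)

    def test_random_vectors_match_definition(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = rng.random(15), rng.random(15)
            r, _ = accuracy_correlation(a, b)
            ca, cb = a - a.mean(), b - b.mean()
            expected = (ca * cb).sum() / np.sqrt((ca**2).sum() * (cb**2).sum())
            assert r == pytest.approx(expected, abs=1e-10)

    def test_constant_vector_nan_with_warning(self):
        with pytest.warns(UserWarning):
            r, p = accuracy_correlation([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert math.isnan(r) and math.isnan(p)

    def test_too_few_proteins(self):
        with pytest.raises(InputError):
            accuracy_correlation([0.1, 0.2], [0.3, 0.4])


class TestClassifyAgreement:
    def test_all(self):
        tops = {m: "A" for m in MODEL_TYPES}
        assert classify_agreement(tops, "A", MODEL_TYPES).label == "ALL"

    def test_structure_only(self):
        tops = {"s1": "A", "s2": "A", "q1": "C", "q2": "D"}
        cat = classify_agreement(tops, "A", MODEL_TYPES)
        assert cat.label == "STRUCTURE_ONLY"
        assert cat.agreeing_models == frozenset({"s1", "s2"})

    def test_mixed(self):
        tops = {"s1": "A", "s2": "C", "q1": "A", "q2": "D"}
        assert classify_agreement(tops, "A", MODEL_TYPES).label == "MIXED"

    def test_none(self):
        tops = {"s1": "C", "s2": "C", "q1": "D", "q2": "E"}
        assert classify_agreement(tops, "A", MODEL_TYPES).label == "NONE"

    def test_unknown_type_rejected(self):
        tops = {"s1": "A", "s2": "A", "q1": "A", "zz": "A"}
        with pytest.raises(ConfigError):
            classify_agreement(tops, "A", {**MODEL_TYPES, "zz": "banana"})

    def test_all_sixteen_subsets_total_and_exclusive(self):
        models = list(MODEL_TYPES)
        for agree_mask in itertools.product([True, False], repeat=4):
            tops = {m: ("A" if agree else "C")
                    for m, agree in zip(models, agree_mask)}
            cat = classify_agreement(tops, "A", MODEL_TYPES)
            assert cat.label in AGREEMENT_LABELS
            agreeing = {m for m, agree in zip(models, agree_mask) if agree}
            assert cat.agreeing_models == frozenset(agreeing)
            types = {MODEL_TYPES[m] for m in agreeing}
            if len(agreeing) == 4:
                assert cat.label == "ALL"
            elif not agreeing:
                assert cat.label == "NONE"
            elif types == {"structure"}:
                assert cat.label == "STRUCTURE_ONLY"
            elif types == {"sequence"}:
                assert cat.label == "SEQUENCE_ONLY"
            else:
                assert cat.label == "MIXED"


class TestAgreementSummary:
    def _panel(self, rows):
        """rows: list of (wt, s1, s2, q1, q2, combined) top amino acids."""
        pset = PredictionSet(model_ids=["s1", "s2", "q1", "q2", "combined"])
        labels = []
        for i, (wt, *tops) in enumerate(rows, start=1):
            labels.append(SiteRecord("p", i, wt))
            for mid, top in zip(["s1", "s2", "q1", "q2", "combined"], tops):
                pset.entries[("p", i, mid)] = one_hot(top, 0.9)
        return pset, labels

    def test_identical_oracles(self):
        rows = [(aa, aa, aa, aa, aa, aa) for aa in "ACDEF"]
        pset, labels = self._panel(rows)
        summary = agreement_summary(pset, labels, MODEL_TYPES)
        assert summary.proportion["ALL"] == 1.0
        assert summary.accuracy["ALL"] == 1.0
        assert summary.count["NONE"] == 0

    def test_hand_tallied_toy(self):
        rows = [
            ("A", "A", "A", "A", "A", "A"),  # ALL, correct
            ("A", "A", "A", "A", "A", "A"),  # ALL, correct
            ("C", "A", "A", "A", "A", "A"),  # ALL, wrong
            ("A", "A", "A", "C", "C", "A"),  # STRUCTURE_ONLY, correct
            ("A", "C", "C", "A", "A", "A"),  # SEQUENCE_ONLY, correct
            ("C", "C", "D", "E", "F", "C"),  # STRUCTURE_ONLY (s1 only), correct
            ("A", "A", "C", "A", "C", "A"),  # MIXED, correct
            ("A", "C", "C", "C", "C", "A"),  # NONE, correct
            ("D", "C", "C", "C", "C", "A"),  # NONE, wrong
            ("A", "A", "A", "A", "C", "A"),  # MIXED (3 agree), correct
        ]
        pset, labels = self._panel(rows)
        summary = agreement_summary(pset, labels, MODEL_TYPES)
        assert summary.count == {"ALL": 3, "STRUCTURE_ONLY": 2, "SEQUENCE_ONLY": 1,
                                 "MIXED": 2, "NONE": 2}
        assert summary.accuracy["ALL"] == pytest.approx(2 / 3)
        assert summary.accuracy["NONE"] == pytest.approx(1 / 2)
        assert sum(summary.proportion.values()) == pytest.approx(1.0, abs=1e-9)

    def test_proportions_sum_to_one_on_synthetic_panel(self, small_panel):
        from predstack.combiner import predict_average

        config, pset, labels = small_panel
        combined = predict_average(pset, model_id="combined")
        merged = PredictionSet(model_ids=pset.model_ids + ["combined"])
        merged.entries = {**pset.entries, **combined.entries}
        summary = agreement_summary(merged, labels, config.model_types())
        assert sum(summary.proportion.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(summary.count.values()) == len(labels)


class TestRsaConfidenceHistogram:
    def test_single_cell(self):
        sites = [SiteRecord("p", i + 1, "A", 0.05) for i in range(10)]
        hist = rsa_confidence_histogram(sites, [0.95] * 10)
        assert hist.counts.sum() == 10
        i, j = np.argwhere(hist.counts == 10)[0]
        assert hist.rsa_edges[i] == pytest.approx(0.05)
        assert hist.confidence_edges[j] == pytest.approx(0.95)
        assert hist.bands[i, j] == "1-25"

    def test_conservation_and_skips(self):
        rng = np.random.default_rng(2)
        sites = [SiteRecord("p", i + 1, "A", float(rng.random()) if i % 5 else None)
                 for i in range(200)]
        hist = rsa_confidence_histogram(sites, rng.random(200))
        evaluable = sum(s.rsa is not None for s in sites)
        assert hist.counts.sum() == evaluable
        assert hist.n_skipped == 200 - evaluable

    def test_band_boundaries(self):
        assert count_band(25) == "1-25"
        assert count_band(26) == "26-50"
        assert count_band(75) == "51-75"
        assert count_band(76) == ">75"
        sites = [SiteRecord("p", i + 1, "A", 0.01) for i in range(80)]
        hist = rsa_confidence_histogram(sites, [0.99] * 80)
        assert ">75" in hist.bands

    def test_rsa_above_one_kept(self):
        sites = [SiteRecord("p", 1, "A", 1.07)]
        hist = rsa_confidence_histogram(sites, [0.5])
        assert hist.counts.sum() == 1
        assert hist.rsa_edges[-1] >= 1.07

    def test_confidence_of_one_in_last_closed_bin(self):
        sites = [SiteRecord("p", 1, "A", 0.0)]
        hist = rsa_confidence_histogram(sites, [1.0])
        assert hist.counts[0, -1] == 1


class TestConfidenceTracksAccuracy:
    def test_decile_accuracy_nondecreasing(self, small_panel):
        _, pset, labels = small_panel
        mid = pset.model_ids[0]
        confs, hits = [], []
        for s in labels:
            aa, conf = top_prediction(pset.entries[(s.protein_id, s.position, mid)])
            confs.append(conf)
            hits.append(aa == s.wt_aa)
        confs, hits = np.array(confs), np.array(hits)
        order = np.argsort(confs, kind="stable")
        deciles = np.array_split(order, 10)
        acc = [hits[d].mean() for d in deciles]
        # allow small sampling wiggle at the plateau
        for lo, hi in zip(acc, acc[1:]):
            assert hi >= lo - 0.02


def test_default_class_map_total():
    validate_class_map(DEFAULT_CLASS_MAP)
    assert len(DEFAULT_CLASS_MAP) == 20
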