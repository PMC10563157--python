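"""Target-decoy q-values, the semi-supervised rescorer, and run comparison."""

import numpy as np
import pytest

from varipept.features import FeatureVector
from varipept.rescoring import (
    RescoreConfig,
    RescoreResult,
    compare_runs,
    peptide_qvalues,
    rescore,
    tdc_qvalues,
)


def _fv(sid, decoy, values, label="canonical", key=None):
    return FeatureVector(
        spectrum_id=sid,
        peptide_key=key or f"PEP{sid.replace('=', '')}K||2",
        is_decoy=decoy,
        schema="standard",
        values=dict(values),
        label=label,
    )


class TestTdcQvalues:
    def test_one_decoy_above_hundred_targets(self):
        scores = [101.0] + list(range(1, 101))
        decoy = [True] + [False] * 100
        q = tdc_qvalues(scores, decoy)
        # at the most permissive threshold: (1 decoy + 1) / 100 targets
        np.testing.assert_allclose(q[1:], 0.02)

    def test_no_decoys_above_top(self):
        scores = list(range(1, 51)) + [0.5, 0.4]
        decoy = [False] * 50 + [True, True]
        q = tdc_qvalues(scores, decoy)
        assert q[49] == pytest.approx(1.0 / 50)  # top target

    def test_all_decoys_outscore_targets(self):
        scores = [10.0, 9.0, 1.0, 0.5]
        decoy = [True, True, False, False]
        q = tdc_qvalues(scores, decoy)
        assert np.all(q[2:] == 1.0)

    def test_monotone_in_score(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(5, 200))
            scores = rng.normal(size=n)
            decoy = rng.random(n) < 0.5
            if not (~decoy).any():
                decoy[0] = False
            q = tdc_qvalues(scores, decoy)
            order = np.argsort(-scores)
            assert np.all(np.diff(q[order]) >= -1e-12)

    def test_tied_scores_share_q(self):
        q = tdc_qvalues([1.0, 1.0, 0.5], [False, True, False])
        assert q[0] == q[1]


def _simulated_features(n_correct=300, n_incorrect=100, n_decoy=200, seed=0, planted=True):
    rng = np.random.default_rng(seed)
    fvs = []
    i = 0
    for group, n in (("c", n_correct), ("i", n_incorrect), ("d", n_decoy)):
        for _ in range(n):
            i += 1
            values = {
                "engine_score": float(rng.normal(1.0 if group == "c" else 0.0, 1.0)),
                "noise": float(rng.normal()),
            }
            if planted:
                values["planted"] = float(
                    rng.uniform(2, 3) if group == "c" else rng.uniform(0, 1)
                )
            fvs.append(_fv(f"scan={i}", group == "d", values, label="canonical"))
    return fvs


class TestRescore:
    def test_single_feature_reduces_to_engine_ranking(self):
        rng = np.random.default_rng(5)
        fvs = [
            _fv(f"scan={i}", i % 3 == 0, {"engine_score": float(rng.normal())})
            for i in range(120)
        ]
        results = rescore(fvs, RescoreConfig(seed=1))
        engine = np.array([fv.values["engine_score"] for fv in fvs])
        final = np.array([r.score for r in results])
        order_a = np.argsort(engine)
        assert np.all(np.diff(final[order_a]) >= 0)

    def test_perfect_planted_feature_accepts_correct(self):
        fvs = _simulated_features(seed=7)
        results = rescore(fvs, RescoreConfig(seed=7))
        correct = [r for fv, r in zip(fvs, results) if fv.values.get("planted", 0) >= 2]
        accepted = sum(r.q_value <= 0.01 for r in correct)
        assert accepted >= 0.99 * len(correct)

    def test_feature_order_invariance(self):
        fvs = _simulated_features(seed=11)
        reordered = [
            FeatureVector(
                fv.spectrum_id,
                fv.peptide_key,
                fv.is_decoy,
                fv.schema,
                {k: fv.values[k] for k in reversed(list(fv.values))},
                fv.label,
            )
            for fv in fvs
        ]
        r1 = rescore(fvs, RescoreConfig(seed=3))
        r2 = rescore(reordered, RescoreConfig(seed=3))
        np.testing.assert_allclose(
            [r.q_value for r in r1], [r.q_value for r in r2], atol=1e-6
        )

    def test_affine_transform_of_single_feature_invariant(self):
        fvs = _simulated_features(seed=13)
        scaled = [
            FeatureVector(
                fv.spectrum_id,
                fv.peptide_key,
                fv.is_decoy,
                fv.schema,
                {**fv.values, "noise": 3.0 * fv.values["noise"] - 7.0},
                fv.label,
            )
            for fv in fvs
        ]
        r1 = rescore(fvs, RescoreConfig(seed=3))
        r2 = rescore(scaled, RescoreConfig(seed=3))
        acc1 = {r.spectrum_id for r in r1 if r.q_value <= 0.01}
        acc2 = {r.spectrum_id for r in r2 if r.q_value <= 0.01}
        assert acc1 == acc2
        np.testing.assert_allclose(
            [r.score for r in r1], [r.score for r in r2], atol=1e-5
        )

    def test_deterministic_given_seed(self):
        fvs = _simulated_features(seed=17)
        r1 = rescore(fvs, RescoreConfig(seed=9))
        r2 = rescore(fvs, RescoreConfig(seed=9))
        assert [(r.score, r.q_value) for r in r1] == [(r.score, r.q_value) for r in r2]

    def test_q_monotone_in_final_score(self):
        fvs = _simulated_features(seed=19)
        results = rescore(fvs, RescoreConfig(seed=2))
        scores = np.array([r.score for r in results])
        q = np.array([r.q_value for r in results])
        order = np.argsort(-scores)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_requires_both_labels(self):
        fvs = [_fv(f"scan={i}", False, {"engine_score": float(i)}) for i in range(5)]
        with pytest.raises(ValueError, match="target and decoy"):
            rescore(fvs, RescoreConfig())


def _result(sid, pep, q, decoy=False, label="canonical"):
    return RescoreResult(sid, f"{pep}||2", decoy, label, -q, q)


class TestCompareRuns:
    def _universe(self, accepted_a, accepted_b):
        peps = ["AAAAAAAK", "CCCCCCCK", "DDDDDDDK", "EEEEEEEK"]
        a = [
            _result(f"scan={i}", p, 0.001 if p in accepted_a else 0.5)
            for i, p in enumerate(peps)
        ]
        b = [
            _result(f"scan={i}", p, 0.001 if p in accepted_b else 0.5)
            for i, p in enumerate(peps)
        ]
        # q-value competition needs a decoy in each universe
        a.append(_result("scan=99", "GGGGGGGK", 0.9, decoy=True))
        b.append(_result("scan=99", "GGGGGGGK", 0.9, decoy=True))
        return a, b

    def test_identical_runs(self):
        a, b = self._universe({"AAAAAAAK"}, {"AAAAAAAK"})
        counts = compare_runs(a, b, 0.01)
        assert counts["psm"]["canonical"] == {"only_a": 0, "shared": 1, "only_b": 0}

    def test_disjoint_runs(self):
        a, b = self._universe({"AAAAAAAK"}, {"CCCCCCCK"})
        counts = compare_runs(a, b, 0.01)
        assert counts["psm"]["canonical"]["shared"] == 0

    def test_toy_venn(self):
        a, b = self._universe({"AAAAAAAK", "CCCCCCCK"}, {"CCCCCCCK", "DDDDDDDK"})
        c = compare_runs(a, b, 0.01)["psm"]["canonical"]
        assert (c["only_a"], c["shared"], c["only_b"]) == (1, 1, 1)

    def test_mismatched_universes_error(self):
        a, b = self._universe(set(), set())
        with pytest.raises(ValueError, match="universe"):
            compare_runs(a, b[:-1] + [_result("scan=77", "TTTTTTTK", 0.5)], 0.01)


class TestPeptideRollup:
    def test_best_psm_per_peptide(self):
        results = [
            _result("scan=1", "AAAAAAAK", 0.001),
            _result("scan=2", "AAAAAAAK", 0.5),
            _result("scan=3", "CCCCCCCK", 0.2),
            _result("scan=4", "GGGGGGGK", 0.9, decoy=True),
        ]
        peps = peptide_qvalues(results)
        seqs = [p.peptide_key.split("|")[0] for p in peps if not p.is_decoy]
        assert sorted(seqs) == ["AAAAAAAK", "CCCCCCCK"]
        best_a = next(p for p in peps if p.peptide_key.startswith("AAAAAAAK"))
        assert best_a.spectrum_id == "scan=1"
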