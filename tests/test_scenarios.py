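import math

import numpy as np
import pytest

from oracles import pgen_table, read_likelihoods
from repgen.generation import ReadConfig, realize_read, sample_scenario
from repgen.recomb_model import GermlineSegment, build_model
from repgen.scenarios import (
    AnnotationResult,
    PruneConfig,
    Scenario,
    annotate,
    pgen,
    pgen_mutated,
    rank_coverage,
)

DEEP = PruneConfig(prune_ratio=1e-12, max_scenarios=10**6)


def _rank_of(res, key):
    for k, s in enumerate(res.ranked_scenarios, 1):
        if s.event_tuple() == key:
            return k
    return math.inf


class TestEnumerateAgainstOracle:
    @pytest.mark.parametrize("fixture", ["toy_vj_model", "toy_vdj_model"])
    def test_full_scenario_set_and_p_read(
        self, fixture, request, exhaustive_align_params
    ):
        """p_read and the full scenario set match a generate-and-match oracle
        that loops over every scenario in the event space."""
        model = request.getfixturevalue(fixture)
        rng = np.random.default_rng(31)
        for trial in range(4):
            rec = realize_read(sample_scenario(model, rng), model, rng)
            total, per = read_likelihoods(rec.read, model, model.error_rate)
            res = annotate(
                rec.read, model, align_params=exhaustive_align_params, prune=DEEP
            )
            assert res.p_read == pytest.approx(total, rel=1e-10)
            engine = {s.event_tuple(): s.p_scenario for s in res.ranked_scenarios}
            assert len(engine) == len(res.ranked_scenarios)  # no duplicates
            for key, p in engine.items():
                assert p == pytest.approx(per[key], rel=1e-9)
            missing_mass = sum(p for k, p in per.items() if k not in engine)
            # bound computed as a difference of near-equal sums: allow roundoff
            assert missing_mass <= res.truncated_mass_bound + 1e-12 * res.p_read

    def test_single_scenario_closed_form(self):
        """Deterministic toy: one scenario, p_read = (1-p)^L."""
        v = [GermlineSegment(name="V0", seg_class="V", seq="ACGTACGTACGTACGTACGT")]
        j = [GermlineSegment(name="J0", seg_class="J", seq="TTGCAATTGCAATTGCAATG")]
        m = build_model(
            {"chain_type": "VJ", "max_palindrome": 0,
             "ranges": {"del_v": (0, 0), "del_j": (0, 0), "ins_vj": (0, 0)}},
            {"V": v, "J": j},
        )
        m.error_rate = 0.01
        read = v[0].seq + j[0].seq
        res = annotate(
            read, m,
            align_params=None,
            prune=PruneConfig(prune_ratio=1e-9),
        )
        assert res.n_enumerated == 1
        assert res.p_read == pytest.approx((1 - 0.01) ** 40, rel=1e-9)

    def test_junction_base_ambiguity_lists_both(self, exhaustive_align_params):
        """A junction base equal to the V's next germline base yields at least
        the templated and the inserted explanation, both with p_recomb > 0."""
        v = [GermlineSegment(name="V0", seg_class="V", seq="ACGTACGTACGA")]
        j = [GermlineSegment(name="J0", seg_class="J", seq="TTGCAATTGCAA")]
        m = build_model(
            {"chain_type": "VJ", "max_palindrome": 0,
             "ranges": {"del_v": (0, 2), "del_j": (0, 0), "ins_vj": (0, 2)}},
            {"V": v, "J": j},
        )
        m.error_rate = 1e-3
        # read: V kept fully; the final V base 'A' could also be an insertion
        read = v[0].seq + j[0].seq
        res = annotate(read, m, align_params=exhaustive_align_params, prune=DEEP)
        keys = {s.event_tuple() for s in res.ranked_scenarios}
        templated = ("V0", None, "J0", 0, None, None, 0, "", "", "")
        inserted = ("V0", None, "J0", 1, None, None, 0, "A", "", "")
        assert templated in keys and inserted in keys
        by_key = {s.event_tuple(): s for s in res.ranked_scenarios}
        assert by_key[templated].p_recomb > 0
        assert by_key[inserted].p_recomb > 0

    def test_failed_read_not_exception(self, toy_vj_model):
        res = annotate("G" * 30, toy_vj_model, prune=PruneConfig())
        assert res.failed and res.ranked_scenarios == []

    def test_ranking_deterministic_and_sorted(
        self, toy_vdj_model, exhaustive_align_params
    ):
        rng = np.random.default_rng(44)
        rec = realize_read(sample_scenario(toy_vdj_model, rng), toy_vdj_model, rng)
        r1 = annotate(rec.read, toy_vdj_model, align_params=exhaustive_align_params,
                      prune=DEEP)
        r2 = annotate(rec.read, toy_vdj_model, align_params=exhaustive_align_params,
                      prune=DEEP)
        assert [s.event_tuple() for s in r1.ranked_scenarios] == [
            s.event_tuple() for s in r2.ranked_scenarios
        ]
        ps = [s.p_scenario for s in r1.ranked_scenarios]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_posterior_weights_sum(self, toy_vdj_model, exhaustive_align_params):
        rng = np.random.default_rng(45)
        rec = realize_read(sample_scenario(toy_vdj_model, rng), toy_vdj_model, rng)
        res = annotate(rec.read, toy_vdj_model,
                       align_params=exhaustive_align_params, prune=DEEP)
        w = sum(s.p_scenario for s in res.ranked_scenarios) / res.p_read
        assert w <= 1 + 1e-9
        assert w >= 1 - res.truncated_mass_bound / res.p_read - 1e-9

    def test_reconstruct_matches_read_outside_mismatches(
        self, toy_vdj_model, exhaustive_align_params
    ):
        rng = np.random.default_rng(46)
        rec = realize_read(sample_scenario(toy_vdj_model, rng), toy_vdj_model, rng)
        res = annotate(rec.read, toy_vdj_model,
                       align_params=exhaustive_align_params, prune=DEEP)
        for s in res.ranked_scenarios[:20]:
            anc = s.reconstruct(toy_vdj_model, len(rec.read))
            assert len(anc) == len(rec.read)
            diffs = {i for i, (a, b) in enumerate(zip(anc, rec.read)) if a != b}
            assert diffs == set(s.mismatches)


class TestPgen:
    def test_deterministic_model_pgen_one(self):
        v = [GermlineSegment(name="V0", seg_class="V", seq="ACGTACGTACGTACGTACGT")]
        j = [GermlineSegment(name="J0", seg_class="J", seq="TTGCAATTGCAATTGCAATG")]
        m = build_model(
            {"chain_type": "VJ", "max_palindrome": 0,
             "ranges": {"del_v": (0, 0), "del_j": (0, 0), "ins_vj": (0, 0)}},
            {"V": v, "J": j},
        )
        assert pgen(v[0].seq + j[0].seq, m) == pytest.approx(1.0)
        other = "A" * 40
        assert pgen(other, m) == 0.0

    def test_pgen_sums_to_one(self, toy_vj_model, exhaustive_align_params):
        """Sum of pgen over every generatable sequence equals 1."""
        table = pgen_table(toy_vj_model)
        total = 0.0
        for seq, expected in table.items():
            got = pgen(seq, toy_vj_model, align_params=exhaustive_align_params)
            assert got == pytest.approx(expected, rel=1e-8)
            total += got
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_sequences_sum_scenarios(
        self, toy_vj_model, exhaustive_align_params
    ):
        """Sequences generatable by >= 2 scenarios have pgen strictly larger
        than any single scenario's probability."""
        from oracles import build_sequence, iter_scenarios
        from repgen.recomb_model import scenario_prob

        counts = {}
        best = {}
        for s in iter_scenarios(toy_vj_model):
            seq, _ = build_sequence(toy_vj_model, s)
            p = scenario_prob(toy_vj_model, s)
            if p <= 0:
                continue
            counts[seq] = counts.get(seq, 0) + 1
            best[seq] = max(best.get(seq, 0.0), p)
        multi = [seq for seq, c in counts.items() if c >= 2][:5]
        assert multi, "toy model should have degenerate sequences"
        for seq in multi:
            assert (
                pgen(seq, toy_vj_model, align_params=exhaustive_align_params)
                > best[seq]
            )


class TestPgenMutated:
    def test_unmutated_read_reduces_to_pgen(
        self, toy_vj_model, exhaustive_align_params
    ):
        from repgen.hypermutation import PwmModel

        # a vanishing mutation rate makes mutated interpretations negligible,
        # so the weighted geometric mean collapses onto pgen(read)
        hm = PwmModel.null(m=1, mu=1e-8)
        rng = np.random.default_rng(50)
        scen = sample_scenario(toy_vj_model, rng)
        rec = realize_read(scen, toy_vj_model, rng)  # error_rate applies
        # construct an error-free read directly from the scenario
        read = rec.ancestor
        est, n_anc = pgen_mutated(
            read, toy_vj_model, hm, align_params=exhaustive_align_params,
            prune=DEEP, anchor="both",
        )
        truth = pgen(read, toy_vj_model, align_params=exhaustive_align_params)
        assert est == pytest.approx(truth, rel=1e-5)

    def test_single_plausible_ancestor(self, exhaustive_align_params):
        """One mismatch deep inside V: the estimate approximates the single
        plausible ancestor's pgen."""
        from repgen.hypermutation import PwmModel

        v = [GermlineSegment(name="V0", seg_class="V", seq="ACGTACGTACGTACGTACGT")]
        j = [GermlineSegment(name="J0", seg_class="J", seq="TTGCAATTGCAATTGCAATG")]
        m = build_model(
            {"chain_type": "VJ", "max_palindrome": 0,
             "ranges": {"del_v": (0, 2), "del_j": (0, 2), "ins_vj": (0, 2)}},
            {"V": v, "J": j},
        )
        hm = PwmModel.null(m=1, mu=1e-2)
        ancestor = v[0].seq + j[0].seq
        read = list(ancestor)
        read[5] = "C" if read[5] != "C" else "G"
        read = "".join(read)
        est, _ = pgen_mutated(
            read, m, hm, align_params=exhaustive_align_params, prune=DEEP,
            anchor="both",
        )
        truth = pgen(ancestor, m, align_params=exhaustive_align_params)
        assert est == pytest.approx(truth, rel=1e-3)


class TestRankCoverage:
    def _result(self, ps, p_read=None):
        scens = [
            Scenario(v="V", j="J", d=None, del_v=0, del_j=0, del_d_left=None,
                     del_d_right=None, p_scenario=p)
            for p in ps
        ]
        return AnnotationResult(
            read_id="r", read="A" * 10, ranked_scenarios=scens,
            p_read=p_read if p_read is not None else sum(ps),
            truncated_mass_bound=0.0,
        )

    def test_single_scenario(self):
        assert rank_coverage(self._result([0.3]), 0.5) == 1
        assert rank_coverage(self._result([0.3]), 1.0) == 1

    def test_full_fraction_gives_count(self):
        res = self._result([0.4, 0.3, 0.2, 0.1])
        assert rank_coverage(res, 1.0) == 4

    def test_partial_sum_example(self):
        res = self._result([0.4, 0.3, 0.2, 0.1])
        assert rank_coverage(res, 0.75) == 3

    def test_unreachable_is_inf(self):
        res = self._result([0.1], p_read=1.0)
        assert rank_coverage(res, 0.5) == math.inf

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            rank_coverage(self._result([1.0]), 0.0)
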