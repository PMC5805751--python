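import numpy as np
import pytest
from scipy.stats import chisquare

from repgen.errors import RepgenError
from repgen.generation import (
    ReadConfig,
    TruthRecord,
    generate_batch,
    realize_read,
    sample_scenario,
)
from repgen.recomb_model import GermlineSegment, build_model


def _deterministic_model():
    v = [GermlineSegment(name="V0", seg_class="V", seq="ACGTACGTACGTACGTACGT", anchor=0)]
    j = [GermlineSegment(name="J0", seg_class="J", seq="TTGCAATTGCAATTGCAATG", anchor=2)]
    m = build_model(
        {"chain_type": "VJ", "max_palindrome": 0,
         "ranges": {"del_v": (0, 0), "del_j": (0, 0), "ins_vj": (0, 0)}},
        {"V": v, "J": j},
    )
    m.error_rate = 0.0
    return m


class TestSampleScenario:
    def test_deterministic_model_fixed_scenario(self):
        m = _deterministic_model()
        rng = np.random.default_rng(0)
        scens = {sample_scenario(m, rng).event_tuple() for _ in range(10)}
        assert len(scens) == 1

    def test_empirical_dj_matches_model(self, toy_vdj_model):
        """Empirical P(D,J) passes a goodness-of-fit test; masked pairs never
        appear."""
        m = toy_vdj_model
        rng = np.random.default_rng(1)
        n = 20_000
        counts = np.zeros_like(m.gene_dj)
        didx = m.event_space.gene_index("D")
        jidx = m.event_space.gene_index("J")
        for _ in range(n):
            s = sample_scenario(m, rng)
            counts[didx[s.d], jidx[s.j]] += 1
        assert counts[m.dj_mask].sum() == 0
        keep = m.gene_dj.ravel() > 0
        stat, p = chisquare(
            counts.ravel()[keep], m.gene_dj.ravel()[keep] * n
        )
        assert p > 0.01

    def test_insertion_length_tv_distance(self, toy_vdj_model):
        """TV distance between empirical and model insertion lengths within
        the analytic multinomial sampling bound."""
        m = toy_vdj_model
        rng = np.random.default_rng(2)
        n = 20_000
        emp = np.zeros_like(m.ins["vd"])
        for _ in range(n):
            s = sample_scenario(m, rng)
            emp[len(s.ins_vd)] += 1
        emp /= n
        tv = 0.5 * np.abs(emp - m.ins["vd"]).sum()
        # E[TV] <= (1/2) sum_k sqrt(p_k(1-p_k)/n); allow 3x
        bound = 0.5 * np.sum(np.sqrt(m.ins["vd"] * (1 - m.ins["vd"]) / n))
        assert tv < 3 * bound


class TestRealizeRead:
    def test_zero_error_exact_sequence(self):
        m = _deterministic_model()
        rng = np.random.default_rng(3)
        s = sample_scenario(m, rng)
        rec = realize_read(s, m, rng)
        assert rec.read == rec.full_seq == rec.ancestor
        assert rec.mutations == () and rec.all_errors == ()

    def test_error_rate_binomial(self, toy_vdj_model):
        m = toy_vdj_model.copy()
        m.error_rate = 1e-3
        rng = np.random.default_rng(4)
        bases = 0
        errors = 0
        for _ in range(300):
            s = sample_scenario(m, rng)
            rec = realize_read(s, m, rng)
            bases += len(rec.full_seq)
            errors += len(rec.all_errors)
        p = 1e-3
        se = np.sqrt(bases * p * (1 - p))
        assert abs(errors - bases * p) < 5 * se

    def test_truncation_anchors(self, toy_vdj_model):
        rng = np.random.default_rng(5)
        s = sample_scenario(toy_vdj_model, rng)
        rec3 = realize_read(s, toy_vdj_model, rng, read_cfg=ReadConfig(length=20))
        assert len(rec3.read) == 20
        rec5 = realize_read(
            s, toy_vdj_model, rng, read_cfg=ReadConfig(length=20, anchor="5p")
        )
        assert len(rec5.read) == 20

    def test_short_sequence_flagged(self, toy_vdj_model):
        rng = np.random.default_rng(6)
        s = sample_scenario(toy_vdj_model, rng)
        rec = realize_read(s, toy_vdj_model, rng, read_cfg=ReadConfig(length=500))
        assert rec.short and rec.read == rec.full_seq if not rec.all_errors else True

    def test_hypermutation_per_context_frequency(self):
        """Per-context empirical mutation frequency reproduces the model's
        mut_prob within binomial error."""
        from repgen.hypermutation import PwmModel, ShmModelSet, mut_prob

        rng = np.random.default_rng(7)
        pwm = PwmModel(m=1, e=rng.normal(0, 0.8, (3, 4)), mu=0.05).gauged()
        shm = ShmModelSet.shared(pwm)
        v = [GermlineSegment(name="V0", seg_class="V",
                             seq="ACGTTGCAGATCCGTAGGCTACGTTGCAGATCCGTAGGCT")]
        j = [GermlineSegment(name="J0", seg_class="J",
                             seq="TTGCAATTGCAATTGCAATG")]
        m = build_model(
            {"chain_type": "VJ", "max_palindrome": 0,
             "ranges": {"del_v": (0, 0), "del_j": (0, 0), "ins_vj": (0, 0)}},
            {"V": v, "J": j},
        )
        s = sample_scenario(m, rng)
        ctx_hits = {}
        ctx_tot = {}
        for _ in range(4000):
            rec = realize_read(s, m, rng, hm_model=shm)
            full = rec.full_seq
            muts = set(rec.mutations)
            for p in range(1, len(full) - 1):
                ctx = full[p - 1 : p + 2]
                ctx_tot[ctx] = ctx_tot.get(ctx, 0) + 1
                if p in muts:
                    ctx_hits[ctx] = ctx_hits.get(ctx, 0) + 1
        for ctx, n in ctx_tot.items():
            if n < 2000:
                continue
            expected = mut_prob(ctx, pwm)
            observed = ctx_hits.get(ctx, 0) / n
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < 5 * se + 1e-6


class TestGenerateBatch:
    def test_same_seed_byte_identical(self, toy_vdj_model):
        b1 = generate_batch(toy_vdj_model, 50, seed=7)
        b2 = generate_batch(toy_vdj_model, 50, seed=7)
        assert [(r.read_id, r.read, r.scenario.event_tuple()) for r in b1] == [
            (r.read_id, r.read, r.scenario.event_tuple()) for r in b2
        ]
        b3 = generate_batch(toy_vdj_model, 50, seed=8)
        assert [r.read for r in b1] != [r.read for r in b3]

    def test_out_of_frame_postcondition(self, toy_vdj_model):
        recs = generate_batch(toy_vdj_model, 80, seed=9, out_of_frame_only=True)
        assert all(not r.productive for r in recs)

    def test_impossible_filter_aborts(self, toy_vdj_model):
        with pytest.raises(RepgenError):
            generate_batch(
                toy_vdj_model, 10, seed=10,
                cdr3_length_match={1000: 1.0}, min_acceptance=0.2,
            )

    def test_cdr3_length_match_vs_resampling_oracle(self, toy_vdj_model):
        """Rejection-sampled CDR3-length histogram matches a direct stratified
        resampling oracle within multinomial noise."""
        pool = generate_batch(toy_vdj_model, 3000, seed=11)
        lengths = np.array([r.cdr3_length or -1 for r in pool])
        ok = lengths > 0
        vals, counts = np.unique(lengths[ok], return_counts=True)
        # target: reweight toward the upper half of the length distribution
        target = {}
        for v, c in zip(vals, counts):
            target[int(v)] = float(c) * (2.0 if v >= np.median(lengths[ok]) else 0.5)
        tot = sum(target.values())
        target = {k: v / tot for k, v in target.items()}

        got = generate_batch(
            toy_vdj_model, 1500, seed=12, cdr3_length_match=target,
            min_acceptance=1e-4,
        )
        emp = np.zeros(max(target) + 1)
        for r in got:
            emp[r.cdr3_length] += 1
        emp /= emp.sum()
        # oracle: direct multinomial draw from the target itself
        rng = np.random.default_rng(13)
        keys = sorted(target)
        probs = np.array([target[k] for k in keys])
        oracle = rng.multinomial(len(got), probs) / len(got)
        for i, k in enumerate(keys):
            se = np.sqrt(probs[i] * (1 - probs[i]) / len(got))
            assert abs(emp[k] - probs[i]) < 6 * se + 0.02
            assert abs(oracle[i] - probs[i]) < 6 * se + 0.02

    def test_truth_record_fields(self, toy_vdj_model):
        recs = generate_batch(
            toy_vdj_model, 5, seed=14, read_cfg=ReadConfig(length=25)
        )
        for r in recs:
            assert isinstance(r, TruthRecord)
            assert len(r.read) <= 25
            assert r.scenario.v and r.scenario.j
            assert r.ancestor[-1] == r.full_seq[-1]  # J-anchored window
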