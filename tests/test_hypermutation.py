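import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from repgen._nt import all_context_digits, encode
from repgen.errors import ConfigError
from repgen.hypermutation import (
    CoLocalizationResult,
    NmerTable,
    PwmModel,
    ShmModelSet,
    colocalization,
    fit_nmer,
    fit_pwm,
    mut_prob,
    posterior_mutation_profile,
)

NT = "ACGT"


class TestMutProb:
    def test_zero_pwm_logistic_identity(self):
        pwm = PwmModel.null(m=1, mu=1e-3)
        for ctx in ("ACG", "TTT", "GCA"):
            assert mut_prob(ctx, pwm) == pytest.approx(1e-3 / (1 + 1e-3))

    def test_mu_to_zero_limit(self):
        pwm = PwmModel.null(m=1, mu=1e-12)
        assert mut_prob("ACG", pwm) < 1e-11

    def test_n_fallback_policy(self):
        rng = np.random.default_rng(1)
        pwm = PwmModel(m=1, e=rng.normal(0, 1, (3, 4)), mu=0.01).gauged()
        assert mut_prob("ANG", pwm) == pytest.approx(pwm.fallback_rate())
        with pytest.raises(ConfigError):
            mut_prob("ANG", pwm, n_policy="error")

    @pytest.mark.parametrize("m", [1, 2])
    def test_geometric_mean_identity(self, m):
        """Under the zero-sum gauge, the geometric mean of the odds over all
        contexts equals mu (exhaustive product)."""
        rng = np.random.default_rng(2)
        pwm = PwmModel(m=m, e=rng.normal(0, 0.8, (2 * m + 1, 4)), mu=0.02).gauged()
        logs = []
        for ctx in itertools.product(NT, repeat=2 * m + 1):
            p = mut_prob("".join(ctx), pwm)
            logs.append(np.log(p / (1 - p)))
        assert np.exp(np.mean(logs)) == pytest.approx(pwm.mu, rel=1e-10)

    def test_gauge_invariance_of_predictions(self):
        rng = np.random.default_rng(3)
        e = rng.normal(0, 1, (3, 4))
        raw = PwmModel(m=1, e=e, mu=0.01)
        gauged = raw.gauged()
        assert np.allclose(raw.rate_table(), gauged.rate_table(), rtol=1e-12)
        assert np.allclose(gauged.e.sum(axis=1), 0.0, atol=1e-12)
        # normal form is unique: re-gauging is the identity
        again = gauged.gauged()
        assert np.allclose(again.e, gauged.e) and again.mu == pytest.approx(gauged.mu)


def _simulate_counts(rng, pwm, n_sites):
    """Weighted (context, mutated) counts from the model itself."""
    w = 2 * pwm.m + 1
    counts = np.zeros((4**w, 2))
    rates = pwm.rate_table()
    ctx = rng.integers(0, 4**w, size=n_sites)
    mut = rng.random(n_sites) < rates[ctx]
    np.add.at(counts, (ctx, mut.astype(int)), 1.0)
    return counts


class TestFitPwm:
    def test_null_model_identifiable(self):
        """Context-independent mutations at rate q: fitted e ~ 0 and
        mu/(1+mu) ~ q."""
        rng = np.random.default_rng(4)
        q = 0.03
        truth = PwmModel.null(m=1, mu=q / (1 - q))
        counts = _simulate_counts(rng, truth, 200_000)
        fit = fit_pwm(counts, PwmModel.null(m=1, mu=1e-3))
        assert np.abs(fit.e).max() < 0.08
        assert fit.mu / (1 + fit.mu) == pytest.approx(q, rel=0.05)

    def test_known_pwm_recovery(self):
        rng = np.random.default_rng(5)
        truth = PwmModel(m=2, e=rng.normal(0, 0.7, (5, 4)), mu=0.03).gauged()
        counts = _simulate_counts(rng, truth, 400_000)
        fit = fit_pwm(counts, PwmModel.null(m=2, mu=1e-3))
        r = np.corrcoef(truth.e.ravel(), fit.e.ravel())[0, 1]
        assert r > 0.97
        assert fit.mu == pytest.approx(truth.mu, rel=0.15)

    def test_matches_independent_maximizer(self):
        """Fitted parameters maximize the same weighted Bernoulli objective as
        an independent scipy optimizer (m=1)."""
        rng = np.random.default_rng(6)
        truth = PwmModel(m=1, e=rng.normal(0, 0.6, (3, 4)), mu=0.05).gauged()
        counts = _simulate_counts(rng, truth, 30_000)
        fit = fit_pwm(counts, PwmModel.null(m=1, mu=1e-2), grad_tol=1e-9)
        digits = all_context_digits(3)
        n_tot = counts.sum(axis=1)
        y = counts[:, 1]

        def neg_ll(theta):
            b = theta[0]
            e = theta[1:].reshape(3, 4)
            lo = b + e[np.arange(3)[None, :], digits].sum(1)
            p = expit(lo)
            eps = 1e-12
            return -float(
                np.sum(y * np.log(p + eps) + (n_tot - y) * np.log(1 - p + eps))
            )

        x0 = np.concatenate([[np.log(fit.mu)], fit.e.ravel()])
        res = minimize(neg_ll, x0, method="Nelder-Mead",
                       options={"maxiter": 20000, "fatol": 1e-10})
        # our fit should already sit at (or extremely near) the optimum
        assert neg_ll(x0) <= res.fun + 1e-3

    def test_no_mutations_floor_model(self):
        counts = np.zeros((4**3, 2))
        counts[:, 0] = 10.0
        with pytest.warns(UserWarning):
            fit = fit_pwm(counts, PwmModel.null(m=1))
        assert fit.mu <= 1e-6


class TestFitNmer:
    def test_1024_rows_for_5mers(self):
        counts = np.zeros((4**5, 2))
        table = fit_nmer(counts, n=5)
        assert len(table) == 1024
        assert len(table.rate) == 1024

    def test_rate_and_estimable(self):
        counts = np.zeros((4**3, 2))
        counts[10] = [93.0, 7.0]
        table = fit_nmer(counts, n=3, coverage_threshold=50)
        assert table.rate[10] == pytest.approx(0.07)
        assert table.estimable[10]

    def test_below_threshold_inestimable(self):
        counts = np.zeros((4**3, 2))
        counts[10] = [9.0, 1.0]
        table = fit_nmer(counts, n=3, coverage_threshold=50)
        assert not table.estimable[10]

    def test_even_n_rejected(self):
        with pytest.raises(ConfigError):
            fit_nmer(np.zeros((16, 2)), n=2)

    def test_pwm_simulated_rates_match_truth(self):
        """Estimable n-mer rates agree with the generating PWM's rates within
        binomial error."""
        rng = np.random.default_rng(7)
        truth = PwmModel(m=1, e=rng.normal(0, 0.5, (3, 4)), mu=0.05).gauged()
        counts = _simulate_counts(rng, truth, 300_000)
        table = fit_nmer(counts, n=3, coverage_threshold=200)
        rates = truth.rate_table()
        for ctx in np.nonzero(table.estimable)[0]:
            n = table.coverage[ctx]
            se = np.sqrt(rates[ctx] * (1 - rates[ctx]) / n)
            assert abs(table.rate[ctx] - rates[ctx]) < 5 * se + 1e-9


class TestShmModelSet:
    def test_shared_mode(self):
        pwm = PwmModel.null(m=1, mu=0.01)
        s = ShmModelSet.shared(pwm)
        assert s.model_for("V") is pwm and s.model_for("J") is pwm

    def test_mixed_m_rejected(self):
        with pytest.raises(ConfigError):
            ShmModelSet(v=PwmModel.null(m=1), j=PwmModel.null(m=2))


class TestPoissonBinomial:
    def test_mutation_counts_match_poisson_binomial(self, toy_vdj_model):
        """Per-read mutation counts from independent-site generation follow
        the Poisson-binomial of the per-site probabilities."""
        from repgen.generation import realize_read, sample_scenario

        pwm = ShmModelSet.shared(PwmModel.null(m=1, mu=0.05))
        rng = np.random.default_rng(8)
        scen = sample_scenario(toy_vdj_model, rng)
        counts = []
        for _ in range(3000):
            rec = realize_read(scen, toy_vdj_model, rng, hm_model=pwm)
            counts.append(len(rec.mutations))
        counts = np.asarray(counts)
        # same scenario every time: all templated sites share p ~ mu/(1+mu)
        # except edge sites at the fallback (equal here); Binomial check
        rec = realize_read(scen, toy_vdj_model, rng, hm_model=pwm)
        n_templ = len(rec.read) - sum(
            map(len, [rec.scenario.ins_vd, rec.scenario.ins_dj])
        )
        p = 0.05 / 1.05
        mean, var = n_templ * p, n_templ * p * (1 - p)
        assert abs(counts.mean() - mean) < 5 * np.sqrt(var / len(counts))


class TestProfilesAndColocalization:
    @pytest.fixture(scope="class")
    def annotated(self, toy_vdj_model):
        from repgen.generation import generate_batch
        from repgen.scenarios import PruneConfig, annotate

        shm = ShmModelSet.shared(PwmModel.null(m=1, mu=0.18))
        recs = generate_batch(toy_vdj_model, 400, seed=91, hm_model=shm)
        anns = [
            annotate(r.read, toy_vdj_model, hm_model=shm, read_id=r.read_id,
                     prune=PruneConfig(prune_ratio=1e-3))
            for r in recs
        ]
        return toy_vdj_model, shm, recs, anns

    def test_profile_self_consistency(self, annotated):
        model, shm, recs, anns = annotated
        gene = model.event_space.v_genes[0].name
        pos, obs, pred, r = posterior_mutation_profile(anns, gene, model, shm)
        assert len(pos) == len(obs) == len(pred)
        assert len(pos) > 0
        # null PWM: prediction constant; observed should fluctuate around it
        assert np.allclose(pred, shm.v.fallback_rate(), rtol=1e-9)
        assert abs(obs.mean() - shm.v.fallback_rate()) < 0.02

    def test_unused_gene_empty_profile(self, annotated):
        model, shm, recs, anns = annotated
        es = model.event_space
        from repgen.recomb_model import GermlineSegment

        with pytest.raises(Exception):
            posterior_mutation_profile(anns, "NOPE", model, shm)

    def test_independent_mutations_g_near_one(self, annotated):
        model, shm, recs, anns = annotated
        res = colocalization(anns, model, min_pair_count=20.0, max_r=8)
        assert isinstance(res, CoLocalizationResult)
        assert len(res.g) > 0
        assert np.all(res.g >= 0)
        assert abs(np.mean(res.g) - 1.0) < 0.2

    def test_toy_perfect_cooccurrence(self, toy_vdj_model):
        """Hand-built annotations with perfectly co-occurring mutations at
        distance 3: g(3) = 1/f, matching a direct evaluation of the formula."""
        from repgen.scenarios import AnnotationResult, Scenario

        model = toy_vdj_model
        es = model.event_space
        v = es.v_genes[0]
        j = es.j_genes[0]
        d = es.d_genes[0]
        f = 0.5  # half of the reads carry the mutation pair
        anns = []
        for k in range(40):
            mm = (2, 5) if k < 20 else ()
            s = Scenario(
                v=v.name, j=j.name, d=d.name, del_v=0, del_j=0,
                del_d_left=0, del_d_right=0, ins_vd="", ins_dj="",
                mismatches=mm, p_scenario=1.0, p_recomb=1.0, p_err=1.0,
            )
            read_len = (len(v.seq) + len(d.seq) + len(j.seq))
            anns.append(
                AnnotationResult(
                    read_id=f"r{k}", read="A" * read_len,
                    ranked_scenarios=[s], p_read=1.0, truncated_mass_bound=0.0,
                )
            )
        res = colocalization(anns, model, min_pair_count=1.0, max_r=6)
        g3 = res.g[list(res.r).index(3)]
        # direct hand evaluation: the only admitted distance-3 pair with
        # mutated ends is (2,5), with f(i,j)=f, f(i)=f(j)=f => g(3)=1/f > 1
        a = res.f1[v.name]
        assert a[2] == pytest.approx(f) and a[5] == pytest.approx(f)
        assert g3 == pytest.approx(1.0 / f)
        assert g3 > 1.0

    def test_single_mutation_reads_zero_g(self, toy_vdj_model):
        from repgen.scenarios import AnnotationResult, Scenario

        model = toy_vdj_model
        es = model.event_space
        v, d, j = es.v_genes[0], es.d_genes[0], es.j_genes[0]
        anns = []
        for k in range(20):
            s = Scenario(
                v=v.name, j=j.name, d=d.name, del_v=0, del_j=0,
                del_d_left=0, del_d_right=0,
                mismatches=(k % 8,), p_scenario=1.0, p_recomb=1.0, p_err=1.0,
            )
            read_len = len(v.seq) + len(d.seq) + len(j.seq)
            anns.append(
                AnnotationResult(
                    read_id=f"r{k}", read="A" * read_len,
                    ranked_scenarios=[s], p_read=1.0, truncated_mass_bound=0.0,
                )
            )
        res = colocalization(anns, model, min_pair_count=1.0, max_r=6)
        assert np.all(res.g == 0.0)


class TestNmerCsv:
    def test_roundtrip(self, tmp_path):
        import numpy as np

        from repgen.hypermutation import (
            fit_nmer,
            nmer_table_from_csv,
            nmer_table_to_csv,
        )

        rng = np.random.default_rng(31)
        counts = rng.integers(0, 200, size=(4**3, 2)).astype(float)
        table = fit_nmer(counts, n=3, coverage_threshold=100)
        p = tmp_path / "nmer.csv"
        nmer_table_to_csv(table, p)
        back = nmer_table_from_csv(p)
        assert back.n == 3
        assert np.allclose(back.rate, table.rate)
        assert np.allclose(back.coverage, table.coverage)
        assert np.array_equal(back.estimable, table.estimable)
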