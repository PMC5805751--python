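"""Independent brute-force oracles used by the test suite.

Everything here enumerates explicitly (nested loops, string building) and never
calls the package's engine internals, so it provides an independent check of
the chain-factorized implementation.
"""

from __future__ import annotations

import itertools

import numpy as np

from repgen.recomb_model import RecombModel, scenario_prob

NT = "ACGT"


class _S:
    pass


def iter_scenarios(model: RecombModel):
    """Yield every scenario object in the model's event space."""
    es = model.event_space
    rng_d = lambda k: range(es.ranges[k][0], es.ranges[k][1] + 1)
    if model.chain_type == "VJ":
        for vseg in es.v_genes:
            for jseg in es.j_genes:
                for dv in rng_d("del_v"):
                    for dj in rng_d("del_j"):
                        for g in range(es.ranges["ins_vj"][1] + 1):
                            for ins in itertools.product(NT, repeat=g):
                                s = _S()
                                s.v, s.j = vseg.name, jseg.name
                                s.del_v, s.del_j = dv, dj
                                s.ins_vj = "".join(ins)
                                s.vseg, s.jseg = vseg, jseg
                                yield s
        return
    for vseg in es.v_genes:
        for dseg in es.d_genes:
            for jseg in es.j_genes:
                for dv in rng_d("del_v"):
                    for dl in rng_d("del_d_l"):
                        for dr in rng_d("del_d_r"):
                            if dl + dr > len(dseg.seq):
                                continue
                            for dj in rng_d("del_j"):
                                for g1 in range(es.ranges["ins_vd"][1] + 1):
                                    for i1 in itertools.product(NT, repeat=g1):
                                        for g2 in range(
                                            es.ranges["ins_dj"][1] + 1
                                        ):
                                            for i2 in itertools.product(
                                                NT, repeat=g2
                                            ):
                                                s = _S()
                                                s.v, s.d, s.j = (
                                                    vseg.name,
                                                    dseg.name,
                                                    jseg.name,
                                                )
                                                s.del_v, s.del_j = dv, dj
                                                s.del_d_left = dl
                                                s.del_d_right = dr
                                                s.ins_vd = "".join(i1)
                                                s.ins_dj = "".join(i2)
                                                s.vseg, s.dseg, s.jseg = (
                                                    vseg,
                                                    dseg,
                                                    jseg,
                                                )
                                                yield s


def build_sequence(model: RecombModel, s) -> tuple[str, list[bool]]:
    """Assembled sequence and per-position templated flags for a scenario."""
    rv = s.vseg.retained(s.del_v)
    rj = s.jseg.retained(s.del_j)
    if model.chain_type == "VJ":
        seq = rv + s.ins_vj + rj
        tmpl = [True] * len(rv) + [False] * len(s.ins_vj) + [True] * len(rj)
    else:
        rd = s.dseg.retained(s.del_d_left, s.del_d_right)
        seq = rv + s.ins_vd + rd + s.ins_dj + rj
        tmpl = (
            [True] * len(rv)
            + [False] * len(s.ins_vd)
            + [True] * len(rd)
            + [False] * len(s.ins_dj)
            + [True] * len(rj)
        )
    return seq, tmpl


def scenario_key(model: RecombModel, s) -> tuple:
    if model.chain_type == "VJ":
        return (s.v, None, s.j, s.del_v, None, None, s.del_j, s.ins_vj, "", "")
    return (
        s.v, s.d, s.j, s.del_v, s.del_d_left, s.del_d_right, s.del_j,
        "", s.ins_vd, s.ins_dj,
    )


def read_likelihoods(read: str, model: RecombModel, error_rate: float):
    """(total P_read, {scenario key: P_scenario}) by full enumeration.

    Scenarios must reproduce the read length exactly; mismatches are allowed
    only at templated positions, each carrying a factor error_rate/3.
    """
    total = 0.0
    per: dict[tuple, float] = {}
    for s in iter_scenarios(model):
        seq, tmpl = build_sequence(model, s)
        if len(seq) != len(read):
            continue
        k = 0
        bad = False
        for t, (a, b) in zip(tmpl, zip(seq, read)):
            if a != b:
                if not t:
                    bad = True
                    break
                k += 1
        if bad:
            continue
        pr = scenario_prob(model, s)
        if pr == 0.0:
            continue
        n_templ = sum(tmpl)
        pe = (error_rate / 3.0) ** k * (1.0 - error_rate) ** (n_templ - k)
        p = pr * pe
        total += p
        key = scenario_key(model, s)
        per[key] = per.get(key, 0.0) + p
    return total, per


def pgen_table(model: RecombModel) -> dict[str, float]:
    """{sequence: generation probability} over the full scenario space."""
    out: dict[str, float] = {}
    for s in iter_scenarios(model):
        seq, _ = build_sequence(model, s)
        pr = scenario_prob(model, s)
        if pr > 0:
            out[seq] = out.get(seq, 0.0) + pr
    return out


def brute_kl_bits(ma: RecombModel, mb: RecombModel) -> float:
    """KL divergence over all scenarios, in bits."""
    tot = 0.0
    for s in iter_scenarios(ma):
        p1 = scenario_prob(ma, s)
        if p1 <= 0:
            continue
        p2 = scenario_prob(mb, s)
        tot += p1 * np.log(p1 / p2)
    return float(tot / np.log(2.0))


def sw_score_dp(a: str, b: str, match=5.0, mismatch=-14.0, gap=-50.0) -> float:
    """Textbook Smith-Waterman local alignment score (linear gap penalty)."""
    n, m = len(a), len(b)
    prev = [0.0] * (m + 1)
    best = 0.0
    for i in range(1, n + 1):
        cur = [0.0] * (m + 1)
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            cur[j] = max(0.0, prev[j - 1] + sub, prev[j] + gap, cur[j - 1] + gap)
            if cur[j] > best:
                best = cur[j]
        prev = cur
    return best
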