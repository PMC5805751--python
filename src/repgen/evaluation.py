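"""Model comparison and scenario-degeneracy statistics.

Kullback-Leibler divergence between two recombination models is computed
exactly over the scenario space by the chain rule: each conditional CPT
contributes its conditional KL weighted by the first model's marginal over the
conditioning events, and the insertion Markov chains contribute their per-state
row KLs weighted by the exact expected conditioning-state occupancy under the
first model.  All terms are in bits and sum to the total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._nt import encode
from .alignment import AlignParams, align_all
from .errors import ConfigError, InputError
from .recomb_model import RecombModel

LOG2 = math.log(2.0)


@dataclass
class KlReport:
    total_bits: float
    per_event_bits: dict[str, float]
    infinite_cells: list[tuple] = field(default_factory=list)

    def __post_init__(self):
        s = sum(self.per_event_bits.values())
        if math.isfinite(self.total_bits):
            assert abs(self.total_bits - s) < 1e-8


def _kl(p: np.ndarray, q: np.ndarray, label: str, cells: list) -> float:
    """Discrete KL in bits; records cells where q=0 < p."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    bad = (p > 0) & (q <= 0)
    if bad.any():
        cells.extend((label, int(i)) for i in np.nonzero(bad)[0])
        return math.inf
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask]))) / LOG2


def _cond_kl(w: np.ndarray, p: np.ndarray, q: np.ndarray, label: str, cells: list):
    """Sum_i w_i KL(p_i || q_i) over leading-axis conditioning values."""
    total = 0.0
    for i in range(p.shape[0]):
        if w[i] <= 0:
            continue
        total += w[i] * _kl(p[i], q[i], f"{label}[{i}]", cells)
    return total


def _anchor_base_dist(model: RecombModel, side: str) -> np.ndarray:
    """Distribution over the 5 conditioning states (A,C,G,T,init) of the
    insertion chain's first step: the last retained V base (side='v') or the
    first retained J base (side='j')."""
    es = model.event_space
    out = np.zeros(5)
    if side == "v":
        genes = es.v_genes
        gene_p = (
            model.gene_vj.sum(axis=1)
            if model.chain_type == "VJ"
            else model.gene_joint().sum(axis=(1, 2))
        )
        dels = model.del_v
        lo = es.ranges["del_v"][0]
    else:
        genes = es.j_genes
        gene_p = (
            model.gene_vj.sum(axis=0)
            if model.chain_type == "VJ"
            else model.gene_joint().sum(axis=(0, 1))
        )
        dels = model.del_j
        lo = es.ranges["del_j"][0]
    for gi, seg in enumerate(genes):
        ec = encode(seg.extended_seq)
        L = len(seg.seq)
        for k in range(dels.shape[1]):
            p = gene_p[gi] * dels[gi, k]
            if p <= 0:
                continue
            d = lo + k
            if L - d >= 1:
                base = ec[L - d - 1] if side == "v" else ec[seg.pal_left + d]
                out[int(base) if base < 4 else 4] += p
            else:
                out[4] += p
    return out


def _markov_kl(model_a: RecombModel, model_b: RecombModel, junc: str, cells: list):
    """Occupancy-weighted KL of one junction's insertion chain (bits)."""
    side = "j" if junc == "dj" else "v"
    rho = _anchor_base_dist(model_a, side)
    ins = model_a.ins[junc]
    t1 = model_a.markov[junc]["trans"]
    i1 = model_a.markov[junc]["init"]
    t2 = model_b.markov[junc]["trans"]
    i2 = model_b.markov[junc]["init"]
    # occupancy[state] = expected number of transitions issued from state:
    # transition k+1 happens iff ins >= k+1, from the state distribution d_k.
    occ = np.zeros(5)
    d = rho.copy()
    for k in range(len(ins) - 1):
        p_ge = float(np.sum(ins[k + 1 :]))
        if p_ge <= 0:
            break
        occ += d * p_ge
        nxt = np.zeros(5)
        nxt[:4] = t1.T @ d[:4] + i1 * d[4]
        d = nxt
    total = 0.0
    for s in range(5):
        if occ[s] <= 0:
            continue
        p = t1[s] if s < 4 else i1
        q = t2[s] if s < 4 else i2
        total += occ[s] * _kl(p, q, f"markov_{junc}[{s}]", cells)
    return total


def kl_divergence(model_a: RecombModel, model_b: RecombModel) -> KlReport:
    """Exact D(model_a || model_b) over scenarios, decomposed per feature."""
    es_a, es_b = model_a.event_space, model_b.event_space
    if es_a.chain_type != es_b.chain_type or dict(es_a.ranges) != dict(es_b.ranges):
        raise ConfigError("models have different event spaces")
    for ga, gb in zip(
        es_a.v_genes + es_a.d_genes + es_a.j_genes,
        es_b.v_genes + es_b.d_genes + es_b.j_genes,
    ):
        if ga.name != gb.name or ga.seq != gb.seq:
            raise ConfigError("models have different germline segments")
    cells: list[tuple] = []
    per: dict[str, float] = {}
    if model_a.chain_type == "VJ":
        per["gene_vj"] = _kl(model_a.gene_vj, model_b.gene_vj, "gene_vj", cells)
        pv = model_a.gene_vj.sum(axis=1)
        pj = model_a.gene_vj.sum(axis=0)
        per["ins_vj"] = _kl(model_a.ins["vj"], model_b.ins["vj"], "ins_vj", cells)
        per["markov_vj"] = _markov_kl(model_a, model_b, "vj", cells)
    else:
        if model_a.factorized and model_b.factorized:
            per["gene_v"] = _kl(model_a.gene_v, model_b.gene_v, "gene_v", cells)
            per["gene_dj"] = _kl(model_a.gene_dj, model_b.gene_dj, "gene_dj", cells)
        else:
            per["gene_vdj"] = _kl(
                model_a.gene_joint(), model_b.gene_joint(), "gene_vdj", cells
            )
        joint = model_a.gene_joint()
        pv = joint.sum(axis=(1, 2))
        pd = joint.sum(axis=(0, 2))
        pj = joint.sum(axis=(0, 1))
        per["del_d"] = _cond_kl(
            pd,
            model_a.del_d.reshape(model_a.del_d.shape[0], -1),
            model_b.del_d.reshape(model_b.del_d.shape[0], -1),
            "del_d",
            cells,
        )
        per["ins_vd"] = _kl(model_a.ins["vd"], model_b.ins["vd"], "ins_vd", cells)
        per["ins_dj"] = _kl(model_a.ins["dj"], model_b.ins["dj"], "ins_dj", cells)
        per["markov_vd"] = _markov_kl(model_a, model_b, "vd", cells)
        per["markov_dj"] = _markov_kl(model_a, model_b, "dj", cells)
    per["del_v"] = _cond_kl(pv, model_a.del_v, model_b.del_v, "del_v", cells)
    per["del_j"] = _cond_kl(pj, model_a.del_j, model_b.del_j, "del_j", cells)
    total = sum(per.values())
    return KlReport(total_bits=total, per_event_bits=per, infinite_cells=cells)


# ---------------------------------------------------------------------------
# Scenario-rank statistics


FEATURES = ("v_gene", "d_gene", "j_gene", "deletions", "insertions")


@dataclass
class RankStats:
    ranks: np.ndarray  # float; inf = true scenario not in the enumerated list
    n_excluded: int  # truth junction off the read window
    n_failed: int
    top1_accuracy: float
    feature_accuracy: dict[str, float]

    def quantile(self, q: float) -> float:
        """q-th population quantile of the true-scenario rank."""
        if not len(self.ranks):
            return math.nan
        srt = np.sort(self.ranks)
        k = int(math.ceil(q * len(srt))) - 1
        return float(srt[max(k, 0)])

    def histogram(self, bins: Sequence[float]) -> np.ndarray:
        return np.histogram(
            np.clip(self.ranks, 0, np.nextafter(np.inf, 0)), bins=bins
        )[0]


def _features_match(truth, top) -> dict[str, bool]:
    return {
        "v_gene": truth.v == top.v,
        "d_gene": truth.d == top.d,
        "j_gene": truth.j == top.j,
        "deletions": (
            truth.del_v == top.del_v
            and truth.del_j == top.del_j
            and truth.del_d_left == top.del_d_left
            and truth.del_d_right == top.del_d_right
        ),
        "insertions": (
            truth.ins_vj == top.ins_vj
            and truth.ins_vd == top.ins_vd
            and truth.ins_dj == top.ins_dj
        ),
    }


def rank_stats(truth_records: Sequence, annotations: Sequence) -> RankStats:
    """Rank of the exact true scenario in each read's ranked list, plus top-1
    overall and per-feature accuracies (failed reads count as incorrect)."""
    ann = {a.read_id: a for a in annotations}
    ranks = []
    n_excluded = 0
    n_failed = 0
    top1 = 0
    feat_hits = {f: 0 for f in FEATURES}
    n_scored = 0
    for rec in truth_records:
        if rec.read_id not in ann:
            raise InputError(f"no annotation for read {rec.read_id}")
        if not rec.in_window:
            n_excluded += 1
            continue
        res = ann[rec.read_id]
        n_scored += 1
        if res.failed or not res.ranked_scenarios:
            n_failed += 1
            ranks.append(math.inf)
            continue
        truth_key = rec.scenario.event_tuple()
        rank = math.inf
        for k, s in enumerate(res.ranked_scenarios, start=1):
            if s.event_tuple() == truth_key:
                rank = k
                break
        ranks.append(rank)
        if rank == 1:
            top1 += 1
        for f, hit in _features_match(rec.scenario, res.ranked_scenarios[0]).items():
            feat_hits[f] += int(hit)
    denom = max(n_scored, 1)
    return RankStats(
        ranks=np.asarray(ranks, dtype=float),
        n_excluded=n_excluded,
        n_failed=n_failed,
        top1_accuracy=top1 / denom,
        feature_accuracy={f: feat_hits[f] / denom for f in FEATURES},
    )


# ---------------------------------------------------------------------------
# Tandem-D detection


def _d_placements(window: str, dseq: str, min_len: int):
    """Ungapped placements of dseq on window with >= min_len matching bases."""
    wc = encode(window)
    dc = encode(dseq)
    out = []
    for off in range(-len(dseq) + min_len, len(window) - min_len + 1):
        a, b = max(0, off), min(len(window), off + len(dseq))
        if b - a < min_len:
            continue
        matches = int(np.count_nonzero(wc[a:b] == dc[a - off : b - off]))
        if matches >= min_len:
            out.append((matches, a, b))
    out.sort(key=lambda t: (-t[0], t[1]))
    return out


def tandem_d_frequency(
    reads: Sequence[str],
    germline: Mapping[str, Sequence],
    min_len: int = 10,
    params: AlignParams | None = None,
):
    """Fraction of reads admitting two non-overlapping D alignments of at
    least ``min_len`` matching nucleotides between the best V and J
    placements.  Returns (frequency, flags, n_no_vj)."""
    params = params or AlignParams()
    flags = []
    n_no_vj = 0
    for read in reads:
        al = align_all(read, germline, params)
        if not al["V"] or not al["J"]:
            n_no_vj += 1
            flags.append(None)
            continue
        best_v = al["V"][0]
        best_j = al["J"][0]
        lo = min(
            len(read), max(0, best_v.offset + len(best_v.segment.seq))
        )  # end of the V core alignment
        hi = max(lo, best_j.offset)  # start of the J core alignment
        window = read[lo:hi]
        placements = []
        for dseg in germline.get("D", ()):
            placements.extend(_d_placements(window, dseg.seq, min_len))
        placements.sort(key=lambda t: (-t[0], t[1]))
        found = False
        if placements:
            first = placements[0]
            for second in placements[1:]:
                if second[2] <= first[1] or second[1] >= first[2]:
                    found = True
                    break
        flags.append(found)
    scored = [f for f in flags if f is not None]
    freq = sum(scored) / len(scored) if scored else math.nan
    return freq, flags, n_no_vj
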