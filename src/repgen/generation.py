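"""Sampling synthetic receptor reads with ground truth.

Scenarios are drawn in the Bayesian-network order (genes, deletions,
insertion lengths, inserted nucleotides via the junction Markov chains),
realized into nucleotide sequences, optionally hit by uniform sequencing
errors or context-dependent hypermutations, and truncated to read length
(3'/J-anchored by default).  All randomness flows from one seed through
per-attempt ``SeedSequence`` substreams, making batches reproducible and
order-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ._nt import NT, STOP_CODONS, encode
from .errors import RepgenError
from .recomb_model import RecombModel
from .scenarios import Scenario


@dataclass(frozen=True)
class ReadConfig:
    length: int | None = None  # None = emit the full sequence
    anchor: str = "3p"  # '3p' (J-anchored truncation) or '5p'


@dataclass
class TruthRecord:
    """Ground truth for one synthetic read."""

    read_id: str
    read: str
    scenario: Scenario  # observable scenario (window coords, post-error ins)
    full_seq: str  # full ancestral (pre-error) sequence
    ancestor: str  # ancestral sequence over the emitted window
    raw_ins: tuple[str, ...]  # pre-error inserted strings
    mutations: tuple[int, ...]  # read coords of templated errors/hypermutations
    all_errors: tuple[int, ...]  # read coords of every flipped position
    productive: bool
    cdr3_length: int | None
    in_window: bool  # true V-J junction region visible on the read
    short: bool  # full sequence shorter than the requested read length


def _sample_ins(model: RecombModel, junc: str, length: int, cond: int | None, rng) -> str:
    """Sample an inserted string (genomic order).  The DJ chain runs 3'->5'
    conditioned on the first retained J base."""
    if length == 0:
        return ""
    trans = model.markov[junc]["trans"]
    init = model.markov[junc]["init"]
    out = []
    prev = cond
    for _ in range(length):
        p = init if prev is None else trans[prev]
        b = int(rng.choice(4, p=p))
        out.append(b)
        prev = b
    s = "".join(NT[b] for b in out)
    return s[::-1] if junc == "dj" else s


def sample_scenario(model: RecombModel, rng: np.random.Generator) -> Scenario:
    """Draw one scenario from the model (ancestral order; no error events)."""
    es = model.event_space

    def draw_del(cpt_row: np.ndarray, key: str) -> int:
        lo = es.ranges[key][0]
        return lo + int(rng.choice(len(cpt_row), p=cpt_row))

    if model.chain_type == "VJ":
        flat = rng.choice(model.gene_vj.size, p=model.gene_vj.ravel())
        vi, ji = np.unravel_index(flat, model.gene_vj.shape)
        di = None
    else:
        if model.factorized:
            vi = int(rng.choice(len(es.v_genes), p=model.gene_v))
            flat = rng.choice(model.gene_dj.size, p=model.gene_dj.ravel())
            di, ji = np.unravel_index(flat, model.gene_dj.shape)
        else:
            flat = rng.choice(model.gene_vdj.size, p=model.gene_vdj.ravel())
            vi, di, ji = np.unravel_index(flat, model.gene_vdj.shape)
        di = int(di)
    vi, ji = int(vi), int(ji)
    vseg = es.v_genes[vi]
    jseg = es.j_genes[ji]
    del_v = draw_del(model.del_v[vi], "del_v")
    del_j = draw_del(model.del_j[ji], "del_j")
    ret_v = vseg.retained(del_v)
    ret_j = jseg.retained(del_j)
    v_cond = int(encode(ret_v[-1])[0]) if ret_v else None
    j_cond = int(encode(ret_j[0])[0]) if ret_j else None
    v_cond = None if (v_cond is not None and v_cond >= 4) else v_cond
    j_cond = None if (j_cond is not None and j_cond >= 4) else j_cond
    if model.chain_type == "VJ":
        n_ins = int(rng.choice(len(model.ins["vj"]), p=model.ins["vj"]))
        ins_vj = _sample_ins(model, "vj", n_ins, v_cond, rng)
        return Scenario(
            v=vseg.name, j=jseg.name, d=None,
            del_v=del_v, del_j=del_j, del_d_left=None, del_d_right=None,
            ins_vj=ins_vj,
        )
    dseg = es.d_genes[di]
    cpt = model.del_d[di]
    flat = rng.choice(cpt.size, p=cpt.ravel())
    kl, kr = np.unravel_index(flat, cpt.shape)
    del_d_l = es.ranges["del_d_l"][0] + int(kl)
    del_d_r = es.ranges["del_d_r"][0] + int(kr)
    n_vd = int(rng.choice(len(model.ins["vd"]), p=model.ins["vd"]))
    n_dj = int(rng.choice(len(model.ins["dj"]), p=model.ins["dj"]))
    ins_vd = _sample_ins(model, "vd", n_vd, v_cond, rng)
    ins_dj = _sample_ins(model, "dj", n_dj, j_cond, rng)
    return Scenario(
        v=vseg.name, j=jseg.name, d=dseg.name,
        del_v=del_v, del_j=del_j, del_d_left=del_d_l, del_d_right=del_d_r,
        ins_vd=ins_vd, ins_dj=ins_dj,
    )


def _assemble(scenario: Scenario, model: RecombModel) -> tuple[str, list[str]]:
    """Full ancestral sequence and its parts [V, insVD, D, insDJ, J] (or
    [V, insVJ, J])."""
    es = model.event_space
    vseg = es.v_genes[es.gene_index("V")[scenario.v]]
    jseg = es.j_genes[es.gene_index("J")[scenario.j]]
    ret_v = vseg.retained(scenario.del_v)
    ret_j = jseg.retained(scenario.del_j)
    if model.chain_type == "VJ":
        parts = [ret_v, scenario.ins_vj, ret_j]
    else:
        dseg = es.d_genes[es.gene_index("D")[scenario.d]]
        ret_d = dseg.retained(scenario.del_d_left, scenario.del_d_right)
        parts = [ret_v, scenario.ins_vd, ret_d, scenario.ins_dj, ret_j]
    return "".join(parts), parts


def _productivity(scenario: Scenario, model: RecombModel, full_seq: str):
    """(productive, cdr3_length) from the conserved V/J anchors."""
    es = model.event_space
    vseg = es.v_genes[es.gene_index("V")[scenario.v]]
    jseg = es.j_genes[es.gene_index("J")[scenario.j]]
    if vseg.anchor is None or jseg.anchor is None:
        return False, None
    ret_v_len = len(vseg.seq) - scenario.del_v
    if ret_v_len < vseg.anchor + 3:  # V anchor codon deleted
        return False, None
    if scenario.del_j > jseg.anchor:  # J anchor trimmed
        return False, None
    v_pos = vseg.anchor
    j_pos = len(full_seq) - len(jseg.seq) + jseg.anchor
    cdr3 = j_pos + 3 - v_pos
    if cdr3 <= 0:
        return False, None
    if cdr3 % 3 != 0:
        return False, cdr3
    for k in range(v_pos, j_pos + 3, 3):
        if full_seq[k : k + 3] in STOP_CODONS:
            return False, cdr3
    return True, cdr3


def _mutation_probs(full_seq: str, classes: np.ndarray, model, hm_model):
    """Per-position flip probability along the full ancestral sequence.
    ``classes`` labels each position 0=V, 1=D, 2=J, -1=insertion (no
    context-dependent mutation)."""
    n = len(full_seq)
    if hm_model is None:
        return np.full(n, model.error_rate)
    m = int(hm_model.m)
    codes = encode(full_seq)
    probs = np.zeros(n)
    tables = {k: np.asarray(hm_model.rate_table_for(c), dtype=float)
              for k, c in ((0, "V"), (1, "D"), (2, "J"))}
    fb = float(hm_model.fallback_rate())
    for p in np.nonzero(classes >= 0)[0]:
        rates = tables[int(classes[p])]
        if p - m < 0 or p + m >= n:
            probs[p] = fb
            continue
        window = codes[p - m : p + m + 1]
        if np.any(window >= 4):
            probs[p] = fb
            continue
        idx = 0
        for c in window:
            idx = idx * 4 + int(c)
        probs[p] = rates[idx]
    return probs


def realize_read(
    scenario: Scenario,
    model: RecombModel,
    rng: np.random.Generator,
    hm_model=None,
    read_cfg: ReadConfig | None = None,
    read_id: str = "read",
) -> TruthRecord:
    """Build the read for a scenario: assemble, mutate, truncate; returns the
    read plus a ground-truth record in read (window) coordinates."""
    read_cfg = read_cfg or ReadConfig()
    full_seq, parts = _assemble(scenario, model)
    n = len(full_seq)
    codes = encode(full_seq).copy()

    # Templated mask and segment class per position of the ancestral sequence.
    templated = np.ones(n, dtype=bool)
    classes = np.full(n, -1, dtype=np.int8)
    part_cls = [0, -1, 2] if model.chain_type == "VJ" else [0, -1, 1, -1, 2]
    pos = 0
    ins_slices = []
    for k, part in enumerate(parts):
        if part_cls[k] < 0:  # insertion parts
            templated[pos : pos + len(part)] = False
            ins_slices.append((pos, pos + len(part)))
        else:
            classes[pos : pos + len(part)] = part_cls[k]
        pos += len(part)

    if hm_model is None:
        flip = rng.random(n) < model.error_rate
    else:
        probs = _mutation_probs(full_seq, classes, model, hm_model)
        flip = rng.random(n) < probs
    for p in np.nonzero(flip)[0]:
        codes[p] = (codes[p] + 1 + rng.integers(3)) % 4
    mutated_seq = "".join(NT[c] for c in codes)

    length = read_cfg.length
    short = length is not None and n < length
    if length is None or n <= length:
        woff, read = 0, mutated_seq
    elif read_cfg.anchor == "5p":
        woff, read = 0, mutated_seq[:length]
    else:
        woff = n - length
        read = mutated_seq[woff:]

    productive, cdr3 = _productivity(scenario, model, full_seq)

    # Observable scenario in window coordinates.
    ret_v_len = len(parts[0])
    in_window = (ret_v_len - woff) >= 0 if read_cfg.anchor != "5p" else True
    if read_cfg.anchor == "5p":
        in_window = n - len(parts[-1]) <= woff + len(read)

    def window_str(a: int, b: int) -> str:
        return mutated_seq[max(a, woff) : min(b, woff + len(read))]

    obs_kwargs = {}
    raw_ins: tuple[str, ...]
    if model.chain_type == "VJ":
        (s0, e0) = ins_slices[0]
        obs_kwargs["ins_vj"] = window_str(s0, e0)
        raw_ins = (scenario.ins_vj,)
    else:
        (s0, e0), (s1, e1) = ins_slices
        obs_kwargs["ins_vd"] = window_str(s0, e0)
        obs_kwargs["ins_dj"] = window_str(s1, e1)
        raw_ins = (scenario.ins_vd, scenario.ins_dj)

    flips = np.nonzero(flip)[0]
    all_err = tuple(int(p - woff) for p in flips if woff <= p < woff + len(read))
    mut = tuple(
        int(p - woff) for p in flips if templated[p] and woff <= p < woff + len(read)
    )
    from dataclasses import replace

    obs_scenario = replace(scenario, mismatches=mut, **obs_kwargs)
    return TruthRecord(
        read_id=read_id,
        read=read,
        scenario=obs_scenario,
        full_seq=full_seq,
        ancestor=full_seq[woff:] if read_cfg.anchor != "5p" else full_seq[: len(read)],
        raw_ins=raw_ins,
        mutations=mut,
        all_errors=all_err,
        productive=productive,
        cdr3_length=cdr3,
        in_window=bool(in_window),
        short=bool(short),
    )


def generate_batch(
    model: RecombModel,
    n: int,
    seed: int,
    hm_model=None,
    read_cfg: ReadConfig | None = None,
    out_of_frame_only: bool = False,
    cdr3_length_match: Mapping[int, float] | None = None,
    min_acceptance: float = 1e-3,
    id_prefix: str = "read",
) -> list[TruthRecord]:
    """Sample ``n`` reads (with truth records), reproducibly for a fixed seed.

    Optional rejection samplers: keep only non-productive (out-of-frame/stop)
    rearrangements, and/or match a target CDR3-length histogram.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    root = np.random.SeedSequence(seed)

    accept_cdr3 = None
    if cdr3_length_match is not None:
        accept_cdr3 = _cdr3_acceptance(
            model, hm_model, cdr3_length_match, root, out_of_frame_only
        )

    out: list[TruthRecord] = []
    attempts = 0
    max_attempts = max(int(n / min_acceptance), 10 * n)
    stream = _substreams(root.spawn(1)[0])
    while len(out) < n:
        if attempts >= max_attempts:
            raise RepgenError(
                f"filter acceptance rate below {min_acceptance}: "
                f"{len(out)} reads after {attempts} attempts"
            )
        rng = np.random.default_rng(next(stream))
        attempts += 1
        scen = sample_scenario(model, rng)
        rec = realize_read(
            scen, model, rng, hm_model=hm_model, read_cfg=read_cfg,
            read_id=f"{id_prefix}{len(out):06d}",
        )
        if out_of_frame_only and rec.productive:
            continue
        if accept_cdr3 is not None:
            if rec.cdr3_length is None:
                continue
            if rng.random() >= accept_cdr3(rec.cdr3_length):
                continue
        out.append(rec)
    return out


def _substreams(seed_seq: np.random.SeedSequence):
    i = 0
    while True:
        yield np.random.SeedSequence(
            entropy=seed_seq.entropy, spawn_key=seed_seq.spawn_key + (i,)
        )
        i += 1


def _cdr3_acceptance(model, hm_model, target, root, out_of_frame_only):
    """Rejection-acceptance function from a pilot estimate of the proposal
    CDR3-length distribution."""
    tot = float(sum(target.values()))
    t = {int(k): v / tot for k, v in target.items() if v > 0}
    pilot_stream = _substreams(
        np.random.SeedSequence(entropy=root.entropy, spawn_key=root.spawn_key + (999,))
    )
    counts: dict[int, int] = {}
    n_pilot = 4000
    kept = 0
    for _ in range(n_pilot * 20):
        if kept >= n_pilot:
            break
        rng = np.random.default_rng(next(pilot_stream))
        scen = sample_scenario(model, rng)
        rec = realize_read(scen, model, rng, hm_model=hm_model)
        if out_of_frame_only and rec.productive:
            continue
        if rec.cdr3_length is None:
            continue
        kept += 1
        counts[rec.cdr3_length] = counts.get(rec.cdr3_length, 0) + 1
    q = {k: v / kept for k, v in counts.items()}
    missing = [k for k in t if k not in q]
    if missing:
        warnings.warn(f"target CDR3 lengths never proposed: {sorted(missing)}")
    ratios = {k: t[k] / q[k] for k in t if k in q}
    if not ratios:
        raise RepgenError("no overlap between target and proposal CDR3 lengths")
    big = max(ratios.values())

    def accept(length: int) -> float:
        return ratios.get(length, 0.0) / big

    return accept
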