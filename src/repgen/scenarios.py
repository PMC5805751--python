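"""Scenario enumeration, ranking, read likelihood and generation probability.

For each read, every explanation consistent with the candidate germline
placements is a *scenario*: gene choices, deletion counts (negative =
P-nucleotides), inserted junction nucleotides, and the set of read positions
explained as errors/hypermutations.  This module ranks scenarios by their
likelihood p_scenario = p_recomb x p_err, computes the total read probability
P_read, and derives generation probabilities P_gen.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._engine import (
    ModelTables,
    RawScenario,
    ReadGeometry,
    chain_sum,
    enumerate_scenarios as _enumerate_raw,
)
from .alignment import AlignParams
from .recomb_model import RecombModel


@dataclass(frozen=True)
class PruneConfig:
    """Enumeration pruning thresholds."""

    prune_ratio: float = 1e-4
    likelihood_floor: float = 1e-40
    max_scenarios: int = 100_000
    top_k: int | None = None  # scenarios kept on the result (None = all)


@dataclass(frozen=True)
class Scenario:
    """One fully specified recombination(+mutation) explanation of a read."""

    v: str
    j: str
    d: str | None
    del_v: int
    del_j: int
    del_d_left: int | None
    del_d_right: int | None
    ins_vj: str = ""
    ins_vd: str = ""
    ins_dj: str = ""
    mismatches: tuple[int, ...] = ()
    p_recomb: float = 0.0
    p_err: float = 1.0
    p_scenario: float = 0.0

    def sort_key(self):
        return (
            -self.p_scenario,
            self.v,
            self.d or "",
            self.j,
            self.del_v,
            self.del_d_left if self.del_d_left is not None else 0,
            self.del_d_right if self.del_d_right is not None else 0,
            self.del_j,
            self.ins_vj,
            self.ins_vd,
            self.ins_dj,
        )

    def event_tuple(self):
        """Identity of the scenario's events (used for truth matching)."""
        return (
            self.v,
            self.d,
            self.j,
            self.del_v,
            self.del_d_left,
            self.del_d_right,
            self.del_j,
            self.ins_vj,
            self.ins_vd,
            self.ins_dj,
        )

    def reconstruct(self, model: RecombModel, read_len: int) -> str:
        """Ancestral (pre-error) sequence over the read window."""
        es = model.event_space
        vseg = es.v_genes[es.gene_index("V")[self.v]]
        jseg = es.j_genes[es.gene_index("J")[self.j]]
        ret_v = vseg.retained(self.del_v)
        ret_j = jseg.retained(self.del_j)
        if model.chain_type == "VJ":
            full = ret_v + self.ins_vj + ret_j
        else:
            dseg = es.d_genes[es.gene_index("D")[self.d]]
            ret_d = dseg.retained(self.del_d_left, self.del_d_right)
            full = ret_v + self.ins_vd + ret_d + self.ins_dj + ret_j
        return full[-read_len:] if len(full) > read_len else full


@dataclass
class AnnotationResult:
    """Ranked scenarios and derived probabilities for one read."""

    read_id: str
    read: str
    ranked_scenarios: list[Scenario]
    p_read: float
    truncated_mass_bound: float
    failed: bool = False
    p_gen: float | None = None
    n_enumerated: int = 0

    @property
    def enumerated_mass(self) -> float:
        return float(sum(s.p_scenario for s in self.ranked_scenarios))


def _decode(
    raw: RawScenario, geom: ReadGeometry, model: RecombModel
) -> Scenario:
    es = model.event_space
    vg = geom.v[raw.iv]
    jg = geom.j[raw.ij]
    v_end = int(vg.edge[raw.kv])
    j_start = int(jg.edge[raw.kj])
    p = math.exp(raw.logp)
    perr = math.exp(raw.log_perr)
    mism: list[int] = []
    a0 = max(0, vg.aln.offset - vg.aln.segment.pal_left)
    mism += [q for q in vg.aln.mismatch_positions if a0 <= q < v_end]
    jend = min(geom.n, jg.aln.offset + len(jg.aln.segment.seq))
    mism += [q for q in jg.aln.mismatch_positions if j_start <= q < jend]
    if raw.idd < 0:
        return Scenario(
            v=vg.aln.segment.name,
            j=jg.aln.segment.name,
            d=None,
            del_v=int(vg.dvals[raw.kv]),
            del_j=int(jg.dvals[raw.kj]),
            del_d_left=None,
            del_d_right=None,
            ins_vj=geom.read[v_end:j_start],
            mismatches=tuple(sorted(mism)),
            p_recomb=p / perr if perr > 0 else 0.0,
            p_err=perr,
            p_scenario=p,
        )
    dg = geom.d[raw.idd]
    d_start = int(dg.d_start[raw.kl])
    d_end = int(dg.d_end[raw.kr])
    mism += [q for q in dg.aln.mismatch_positions if d_start <= q < d_end]
    return Scenario(
        v=vg.aln.segment.name,
        j=jg.aln.segment.name,
        d=dg.aln.segment.name,
        del_v=int(vg.dvals[raw.kv]),
        del_j=int(jg.dvals[raw.kj]),
        del_d_left=int(dg.dl_vals[raw.kl]),
        del_d_right=int(dg.dr_vals[raw.kr]),
        ins_vd=geom.read[v_end:d_start],
        ins_dj=geom.read[d_end:j_start],
        mismatches=tuple(sorted(mism)),
        p_recomb=p / perr if perr > 0 else 0.0,
        p_err=perr,
        p_scenario=p,
    )


def annotate(
    read: str,
    model: RecombModel,
    alignments=None,
    hm_model=None,
    prune: PruneConfig | None = None,
    align_params: AlignParams | None = None,
    read_id: str = "read",
    geometry: ReadGeometry | None = None,
) -> AnnotationResult:
    """Enumerate, rank and weigh the scenarios consistent with a read.

    Reads with log P_read below the likelihood floor are reported as failed
    (empty scenario list), not raised.
    """
    prune = prune or PruneConfig()
    tables = ModelTables(model, hm_model=hm_model)
    if geometry is None:
        geometry = ReadGeometry(
            read,
            model,
            align_params=align_params,
            alignments=alignments,
            ctx_halfwidth=None if hm_model is None else int(hm_model.m),
        )
    raw, logz, _best, _fac = _enumerate_raw(
        geometry, tables, prune.prune_ratio, prune.max_scenarios
    )
    if not np.isfinite(logz) or logz < math.log(prune.likelihood_floor):
        return AnnotationResult(
            read_id=read_id,
            read=geometry.read,
            ranked_scenarios=[],
            p_read=0.0,
            truncated_mass_bound=0.0,
            failed=True,
        )
    scens = [_decode(r, geometry, model) for r in raw]
    scens.sort(key=Scenario.sort_key)
    p_read = float(math.exp(logz))
    if prune.top_k is not None:
        kept = scens[: prune.top_k]
    else:
        kept = scens
    mass = float(sum(s.p_scenario for s in scens))
    return AnnotationResult(
        read_id=read_id,
        read=geometry.read,
        ranked_scenarios=kept,
        p_read=p_read,
        truncated_mass_bound=max(p_read - mass, 0.0),
        n_enumerated=len(scens),
    )


def pgen(
    sequence: str,
    model: RecombModel,
    align_params: AlignParams | None = None,
    anchor: str = "both",
    placements_from: ReadGeometry | None = None,
) -> float:
    """Generation probability: total P_recomb over all scenarios reconstructing
    ``sequence`` exactly (error-free).

    ``placements_from`` reuses another same-length sequence's germline
    placements (mismatch maps are recomputed) — used for candidate ancestral
    sequences of an already-aligned read.
    """
    from .alignment import replay_placements

    params = align_params or AlignParams(
        anchor=anchor, thresholds={"V": 20.0, "D": 10.0, "J": 15.0}
    )
    tables = ModelTables(model, error_free=True)
    try:
        alignments = (
            replay_placements(sequence, placements_from.alignments)
            if placements_from is not None and placements_from.n == len(sequence)
            else None
        )
        geom = ReadGeometry(
            sequence, model, align_params=params, alignments=alignments
        )
    except Exception:
        warnings.warn(f"unalignable sequence of length {len(sequence)}")
        return 0.0
    logz, _acc, _fac = chain_sum(geom, tables)
    if not np.isfinite(logz):
        return 0.0
    return float(math.exp(logz))


def pgen_mutated(
    read: str,
    model: RecombModel,
    hm_model,
    prune: PruneConfig | None = None,
    align_params: AlignParams | None = None,
    max_ancestors: int = 12,
    most_likely_only: bool = False,
    anchor: str = "3p",
):
    """Approximate generation probability of a mutated read.

    Posterior-weighted geometric mean of P_gen over the candidate unmutated
    ancestral sequences implied by the enumerated scenarios; with
    ``most_likely_only`` the estimator collapses to the single most probable
    ancestor.  Returns (estimate, n_ancestors_used); (0.0, 0) if the read
    failed annotation.
    """
    prune = prune or PruneConfig()
    geometry = ReadGeometry(
        read, model, align_params=align_params,
        ctx_halfwidth=None if hm_model is None else int(hm_model.m),
    )
    res = annotate(
        read, model, hm_model=hm_model, prune=prune,
        align_params=align_params, geometry=geometry,
    )
    if res.failed or not res.ranked_scenarios:
        return 0.0, 0
    weights: dict[str, float] = {}
    for s in res.ranked_scenarios:
        anc = s.reconstruct(model, len(res.read))
        weights[anc] = weights.get(anc, 0.0) + s.p_scenario
    ranked = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    if most_likely_only:
        ranked = ranked[:1]
    else:
        ranked = ranked[:max_ancestors]
    pg_params = align_params or AlignParams(
        anchor=anchor, thresholds={"V": 20.0, "D": 10.0, "J": 15.0}
    )
    logs, ws = [], []
    for anc, w in ranked:
        pg = pgen(
            anc, model, align_params=pg_params, anchor=anchor,
            placements_from=geometry,
        )
        if pg > 0:
            logs.append(math.log(pg))
            ws.append(w)
    if not ws:
        return 0.0, 0
    ws_arr = np.asarray(ws) / sum(ws)
    return float(math.exp(float(ws_arr @ np.asarray(logs)))), len(ws)


def rank_coverage(result: AnnotationResult, f: float) -> float:
    """Smallest k such that the top-k scenarios carry >= f x P_read;
    inf if the enumerated list cannot reach that mass."""
    if not (0.0 < f <= 1.0):
        raise ValueError("f must be in (0, 1]")
    target = f * result.p_read * (1.0 - 1e-12)
    total = 0.0
    for k, s in enumerate(result.ranked_scenarios, start=1):
        total += s.p_scenario
        if total >= target:
            return k
    return math.inf


# Spec-facing alias (the operation is named "enumerate" in the interface).
enumerate_read = annotate
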