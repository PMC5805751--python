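"""Parameter learning by expectation-maximization.

The E step computes, for every read, exact posterior expectations of each
recombination event (and of the error/mutation counts) under the current
model, using the chain-factorized engine — equivalent to enumerating all
scenarios with weights P_scenario / P_read.  The M step renormalizes the
weighted counts into CPTs, keeping structural zeros masked.  Alignments and
read geometry are computed once and cached across iterations (the "sparse"
part of the procedure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._engine import ModelTables, ReadGeometry, SufficientStats, accumulate_read
from .alignment import AlignParams
from .errors import InputError, RepgenError
from .hypermutation import NmerTable, PwmModel, ShmModelSet, fit_nmer, fit_pwm
from .recomb_model import RecombModel

logger = logging.getLogger(__name__)

__all__ = [
    "SufficientStats",
    "EMConfig",
    "e_step",
    "m_step",
    "em_learn",
    "filter_out_of_frame",
    "prepare_geometries",
]


@dataclass(frozen=True)
class EMConfig:
    max_iter: int = 20
    tol: float = 1e-3  # absolute mean log P_read improvement per read
    seed: int = 0
    likelihood_floor: float = 1e-40
    align_params: AlignParams | None = None
    fit_error_rate: bool = True
    monotonicity_rel_tol: float = 1e-6


def filter_out_of_frame(records: Sequence) -> list:
    """Keep synthetic truth records that fail the productivity rule (CDR3
    length not a multiple of 3, a stop codon inside, or a lost anchor)."""
    return [r for r in records if not r.productive]


def prepare_geometries(
    reads: Sequence[str],
    model: RecombModel,
    align_params: AlignParams | None = None,
    ctx_halfwidth: int | None = None,
) -> list[ReadGeometry]:
    """Align every read once; the cached geometry is reused by all EM
    iterations."""
    return [
        ReadGeometry(r, model, align_params=align_params, ctx_halfwidth=ctx_halfwidth)
        for r in reads
    ]


def e_step(
    reads: Sequence[str] | None,
    model: RecombModel,
    hm_model=None,
    geometries: Sequence[ReadGeometry] | None = None,
    align_params: AlignParams | None = None,
    likelihood_floor: float = 1e-40,
    collect_shm: bool = False,
) -> SufficientStats:
    """Accumulate exact posterior event counts over all analyzable reads."""
    if geometries is None:
        if not reads:
            raise InputError("no reads to analyze")
        geometries = prepare_geometries(
            reads, model, align_params,
            ctx_halfwidth=None if hm_model is None else int(hm_model.m),
        )
    tables = ModelTables(model, hm_model=hm_model)
    stats = SufficientStats(
        model,
        collect_shm=collect_shm,
        shm_m=0 if hm_model is None else int(hm_model.m),
    )
    for geom in geometries:
        accumulate_read(geom, tables, stats, likelihood_floor=likelihood_floor)
    if stats.n_reads == 0 or stats.n_reads == stats.n_failed:
        raise RepgenError("zero successfully analyzed reads")
    return stats


def _normalize_rows(counts: np.ndarray, old: np.ndarray, label: str) -> np.ndarray:
    """Each leading-axis row becomes normalized counts; all-zero rows keep the
    previous value (logged)."""
    flat = counts.reshape(counts.shape[0], -1)
    sums = flat.sum(axis=1)
    out = old.reshape(flat.shape).copy()
    good = sums > 0
    out[good] = flat[good] / sums[good, None]
    if not good.all():
        logger.info(
            "%s: %d conditioning row(s) had zero posterior mass; kept previous",
            label, int((~good).sum()),
        )
    return out.reshape(counts.shape)


def m_step(stats: SufficientStats, model: RecombModel) -> RecombModel:
    """Maximize the pseudo-log-likelihood: CPT rows = normalized counts."""
    new = model.copy()
    if model.chain_type == "VJ":
        tot = stats.gene.sum()
        if tot > 0:
            new.gene_vj = stats.gene / tot
    else:
        if model.dj_mask is not None:
            masked_mass = float(stats.gene.sum(axis=0)[model.dj_mask].sum())
            if masked_mass > 0:
                raise RepgenError(
                    "posterior mass on structurally forbidden D-J pairs"
                )
        tot = stats.gene.sum()
        if tot > 0:
            if model.factorized:
                new.gene_v = stats.gene.sum(axis=(1, 2)) / tot
                new.gene_dj = stats.gene.sum(axis=0) / tot
            else:
                new.gene_vdj = stats.gene / tot
        new.del_d = _normalize_rows(stats.del_d, model.del_d, "del_d")
    new.del_v = _normalize_rows(stats.del_v, model.del_v, "del_v")
    new.del_j = _normalize_rows(stats.del_j, model.del_j, "del_j")
    for junc, counts in stats.ins.items():
        s = counts.sum()
        if s > 0:
            new.ins[junc] = counts / s
        t5 = stats.trans5[junc]
        old5 = np.vstack(
            [model.markov[junc]["trans"], model.markov[junc]["init"][None, :]]
        )
        new5 = _normalize_rows(t5, old5, f"markov_{junc}")
        new.markov[junc] = {"trans": new5[:4], "init": new5[4]}
    if stats.err_opportunities > 0:
        new.error_rate = float(stats.err_events / stats.err_opportunities)
    return new


@dataclass
class EMResult:
    model: RecombModel
    hm_model: object | None
    trajectory: list[dict]  # per-iteration {'iter', 'mean_log_p_read', 'pseudo_loglik', 'n_failed'}
    converged: bool


def em_learn(
    reads: Sequence[str],
    init_model: RecombModel,
    config: EMConfig | None = None,
    hm_model=None,
    fit_shm: bool = False,
    geometries: Sequence[ReadGeometry] | None = None,
) -> EMResult:
    """Fit the recombination model (and optionally the hypermutation model) to
    reads.  Stops at ``max_iter`` or when the mean log P_read improves by less
    than ``tol``; a decreasing trajectory beyond numerical tolerance is a hard
    error (EM contract violation)."""
    config = config or EMConfig()
    model = init_model.copy()
    model.validate()
    hm = hm_model
    if geometries is None:
        geometries = prepare_geometries(
            reads, model, config.align_params,
            ctx_halfwidth=None if hm is None else int(hm.m),
        )
    if not geometries:
        raise InputError("need at least one analyzable read")
    trajectory: list[dict] = []
    prev_ll = -np.inf
    converged = False
    # Reads below the likelihood floor at the first iteration are excluded
    # once; the analyzed set is then frozen so the mean log-likelihood is
    # comparable (and provably non-decreasing) across iterations.
    active = list(geometries)
    prev_n_ok = None
    for it in range(config.max_iter):
        tables = ModelTables(model, hm_model=hm)
        stats = SufficientStats(
            model, collect_shm=fit_shm, shm_m=0 if hm is None else int(hm.m)
        )
        floor = config.likelihood_floor if it == 0 else 0.0
        kept = []
        for geom in active:
            lz = accumulate_read(geom, tables, stats, likelihood_floor=floor)
            if np.isfinite(lz):
                kept.append(geom)
        n_ok = stats.n_reads - stats.n_failed
        if n_ok == 0:
            raise RepgenError("zero successfully analyzed reads")
        ll = stats.loglik / n_ok
        trajectory.append(
            {
                "iter": it,
                "mean_log_p_read": ll,
                "pseudo_loglik": stats.pseudo_loglik(tables),
                "n_failed": stats.n_failed,
            }
        )
        if it > 0:
            drop = prev_ll - ll
            if prev_n_ok == n_ok and drop > config.monotonicity_rel_tol * max(
                abs(prev_ll), 1.0
            ):
                raise RepgenError(
                    f"EM contract violation: mean log-likelihood decreased "
                    f"from {prev_ll:.6f} to {ll:.6f} at iteration {it}"
                )
            if abs(ll - prev_ll) < config.tol:
                converged = True
                break
        prev_ll = ll
        prev_n_ok = n_ok
        active = kept
        model = m_step(stats, model)
        if not config.fit_error_rate:
            model.error_rate = init_model.error_rate
        if fit_shm and hm is not None:
            hm = _refit_shm(hm, stats)
    return EMResult(model=model, hm_model=hm, trajectory=trajectory, converged=converged)


def _refit_shm(hm, stats: SufficientStats):
    """M-step for the hypermutation model from posterior context counts."""

    def fit_one(sub, counts):
        if isinstance(sub, PwmModel):
            return fit_pwm(counts, sub)
        if isinstance(sub, NmerTable):
            return fit_nmer(counts, sub.n)
        raise RepgenError(f"cannot refit hypermutation model {type(sub)!r}")

    if isinstance(hm, ShmModelSet):
        return ShmModelSet(
            v=fit_one(hm.v, stats.shm_counts["V"]),
            d=None if hm.d is None else fit_one(hm.d, stats.shm_counts["D"]),
            j=None if hm.j is None else fit_one(hm.j, stats.shm_counts["J"]),
        )
    total = sum(stats.shm_counts.values())
    return fit_one(hm, total)
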