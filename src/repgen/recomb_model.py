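"""Generative recombination model: germline segments, event space, Bayesian-network CPTs.

The model describes receptor formation as a chain of stochastic events — gene
choices, end deletions (negative values = retained P-nucleotides), junctional
insertions whose nucleotide identities follow dinucleotide Markov chains — and a
per-nucleotide error process.  Two architectures are supported:

* ``VJ``  : P(V,J) P(delV|V) P(delJ|J) P(insVJ) x Markov(VJ insertions)
* ``VDJ`` : P(V,D,J) P(delV|V) P(delDl,delDr|D) P(delJ|J)
            P(insVD) P(insDJ) x Markov(VD) x Markov(DJ)

with the VDJ gene-usage table optionally factorized as P(V)P(D,J).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._nt import NT_INDEX, revcomp
from .errors import ConfigError, EventRangeError, ModelValidationError, StructureError

NORM_TOL = 1e-10

# ---------------------------------------------------------------------------
# Germline segments


@dataclass(frozen=True)
class GermlineSegment:
    """A named V/D/J germline template with its palindromic extension.

    ``seq`` is the germline sequence proper; ``extended_seq`` carries ``max_p``
    P-nucleotides appended in mirrored orientation at each recombination-facing
    end (3' for V, 5' for J, both for D), so that a deletion count of ``-k``
    retains ``k`` palindromic bases.
    """

    name: str
    seg_class: str  # 'V', 'D' or 'J'
    seq: str
    family: str = ""
    max_p: int = 0
    extended_seq: str = ""
    is_reverse_complement: bool = False
    anchor: int | None = None  # 0-based start of the conserved CDR3 codon in seq

    def __post_init__(self) -> None:
        if self.seg_class not in ("V", "D", "J"):
            raise ConfigError(f"bad seg_class {self.seg_class!r} for {self.name!r}")
        if not self.seq:
            raise ConfigError(f"empty sequence for segment {self.name!r}")
        if not self.extended_seq:
            object.__setattr__(self, "extended_seq", self.seq)

    # Length of the palindromic extension on each side of extended_seq.
    @property
    def pal_left(self) -> int:
        return self.max_p if self.seg_class in ("D", "J") else 0

    @property
    def pal_right(self) -> int:
        return self.max_p if self.seg_class in ("D", "V") else 0

    def __len__(self) -> int:
        return len(self.seq)

    def retained(self, *dels: int) -> str:
        """Retained (ancestral) sequence after applying deletion counts.

        V: ``retained(del_v)``; J: ``retained(del_j)``;
        D: ``retained(del_d_left, del_d_right)``.
        """
        n = len(self.seq)
        if self.seg_class == "V":
            (d,) = dels
            _check_del(self, d, d)
            return self.extended_seq[: n - d]
        if self.seg_class == "J":
            (d,) = dels
            _check_del(self, d, d)
            return self.extended_seq[self.pal_left + d :]
        dl, dr = dels
        _check_del(self, dl, dr)
        if dl + dr > n:
            raise EventRangeError(
                f"deletions ({dl},{dr}) exceed D length {n} for {self.name}"
            )
        return self.extended_seq[self.pal_left + dl : self.pal_left + n - dr]


def _check_del(seg: GermlineSegment, *dels: int) -> None:
    for d in dels:
        if d < -seg.max_p or d > len(seg.seq):
            raise EventRangeError(
                f"deletion {d} outside [-{seg.max_p},{len(seg.seq)}] for {seg.name}"
            )


def extend_palindrome(segment: GermlineSegment, max_p: int) -> GermlineSegment:
    """Append the mirrored reverse complement of the terminal ``max_p`` bases
    at each recombination-facing end of ``segment``."""
    if max_p < 0:
        raise ConfigError("max_p must be >= 0")
    if max_p > len(segment.seq):
        raise ConfigError(
            f"max_p {max_p} exceeds segment length {len(segment.seq)} ({segment.name})"
        )
    seq = segment.seq
    ext = seq
    if segment.seg_class in ("V", "D"):
        ext = ext + revcomp(seq[len(seq) - max_p :]) if max_p else ext
    if segment.seg_class in ("D", "J"):
        ext = (revcomp(seq[:max_p]) + ext) if max_p else ext
    return replace(segment, max_p=max_p, extended_seq=ext)


# ---------------------------------------------------------------------------
# Event space


_DEL_KEYS = {"VJ": ("del_v", "del_j"), "VDJ": ("del_v", "del_j", "del_d_l", "del_d_r")}
_INS_KEYS = {"VJ": ("ins_vj",), "VDJ": ("ins_vd", "ins_dj")}

DEFAULT_RANGES = {
    "del_v": (-4, 16),
    "del_j": (-4, 16),
    "del_d_l": (-4, 16),
    "del_d_r": (-4, 16),
    "ins_vj": (0, 40),
    "ins_vd": (0, 40),
    "ins_dj": (0, 40),
}


@dataclass(frozen=True)
class EventSpace:
    """Discrete domain of every recombination event."""

    chain_type: str  # 'VJ' or 'VDJ'
    v_genes: tuple[GermlineSegment, ...]
    d_genes: tuple[GermlineSegment, ...]
    j_genes: tuple[GermlineSegment, ...]
    ranges: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.chain_type not in ("VJ", "VDJ"):
            raise ConfigError(f"unknown chain_type {self.chain_type!r}")
        if not self.v_genes or not self.j_genes:
            raise ConfigError("V and J gene lists must be non-empty")
        if self.chain_type == "VJ" and self.d_genes:
            raise ConfigError("D genes declared for a VJ chain")
        if self.chain_type == "VDJ" and not self.d_genes:
            raise ConfigError("VDJ chain requires D genes")
        for key in _DEL_KEYS[self.chain_type] + _INS_KEYS[self.chain_type]:
            lo, hi = self.ranges[key]
            if lo > hi:
                raise ConfigError(f"empty range for {key}: [{lo},{hi}]")
            if key.startswith("ins") and lo < 0:
                raise ConfigError(f"negative insertion bound for {key}")
        for genes, keys in (
            (self.v_genes, ("del_v",)),
            (self.j_genes, ("del_j",)),
            (self.d_genes, ("del_d_l", "del_d_r")),
        ):
            for g in genes:
                for key in keys:
                    lo, hi = self.ranges[key]
                    if -lo > g.max_p:
                        raise ConfigError(
                            f"{key} lower bound {lo} exceeds palindrome length "
                            f"{g.max_p} of {g.name}"
                        )
                    if hi > len(g.seq):
                        raise ConfigError(
                            f"{key} upper bound {hi} exceeds length of {g.name}"
                        )

    def del_values(self, key: str) -> np.ndarray:
        lo, hi = self.ranges[key]
        return np.arange(lo, hi + 1)

    def n_del(self, key: str) -> int:
        lo, hi = self.ranges[key]
        return hi - lo + 1

    def ins_max(self, key: str) -> int:
        return self.ranges[key][1]

    def gene_index(self, seg_class: str) -> dict[str, int]:
        genes = {"V": self.v_genes, "D": self.d_genes, "J": self.j_genes}[seg_class]
        return {g.name: i for i, g in enumerate(genes)}


# ---------------------------------------------------------------------------
# Model


def _markov_uniform() -> dict[str, np.ndarray]:
    return {"trans": np.full((4, 4), 0.25), "init": np.full(4, 0.25)}


@dataclass
class RecombModel:
    """Bayesian network of recombination events with CPTs and an error model.

    CPT shapes (nV/nD/nJ gene counts, nd* deletion-range sizes):

    * VJ: ``gene_vj`` (nV,nJ)
    * VDJ factorized: ``gene_v`` (nV,), ``gene_dj`` (nD,nJ);
      joint: ``gene_vdj`` (nV,nD,nJ)
    * ``del_v`` (nV,ndv), ``del_j`` (nJ,ndj), ``del_d`` (nD,ndl,ndr) (joint l/r)
    * ``ins`` maps junction -> length distribution (ins_max+1,)
    * ``markov`` maps junction -> {'trans': (4,4) rows=conditioning base,
      'init': (4,)} — the first inserted base conditions on the last retained
      germline base of the flanking segment (V side for VJ/VD; J side, running
      3'->5', for DJ), falling back to 'init' when that segment is fully deleted.
    """

    event_space: EventSpace
    factorized: bool = True
    gene_vj: np.ndarray | None = None
    gene_v: np.ndarray | None = None
    gene_dj: np.ndarray | None = None
    gene_vdj: np.ndarray | None = None
    del_v: np.ndarray | None = None
    del_j: np.ndarray | None = None
    del_d: np.ndarray | None = None
    ins: dict[str, np.ndarray] = field(default_factory=dict)
    markov: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    error_rate: float = 1e-3
    dj_mask: np.ndarray | None = None  # True = structurally forbidden (D,J) pair
    dj_markov_direction: str = "3to5"
    forbidden_dj: tuple[tuple[str, str], ...] = ()

    @property
    def chain_type(self) -> str:
        return self.event_space.chain_type

    # -- construction -------------------------------------------------------

    @classmethod
    def uniform(
        cls,
        event_space: EventSpace,
        factorized: bool = True,
        forbidden_dj: Sequence[tuple[str, str]] = (),
        error_rate: float = 1e-3,
        dj_markov_direction: str = "3to5",
    ) -> "RecombModel":
        es = event_space
        nv, nj = len(es.v_genes), len(es.j_genes)
        m = cls(
            event_space=es,
            factorized=factorized,
            error_rate=error_rate,
            dj_markov_direction=dj_markov_direction,
            forbidden_dj=tuple(forbidden_dj),
        )
        m.del_v = _uniform_rows(nv, es.n_del("del_v"))
        m.del_j = _uniform_rows(nj, es.n_del("del_j"))
        if es.chain_type == "VJ":
            m.gene_vj = np.full((nv, nj), 1.0 / (nv * nj))
            m.ins["vj"] = _uniform_vec(es.ins_max("ins_vj") + 1)
            m.markov["vj"] = _markov_uniform()
        else:
            nd = len(es.d_genes)
            m.dj_mask = _build_dj_mask(es, forbidden_dj)
            if factorized:
                m.gene_v = np.full(nv, 1.0 / nv)
                m.gene_dj = _masked_uniform(m.dj_mask)
            else:
                joint = np.broadcast_to(
                    _masked_uniform(m.dj_mask)[None, :, :], (nv, nd, nj)
                ).copy()
                m.gene_vdj = joint / nv
            m.del_d = _uniform_del_d(es)
            m.ins["vd"] = _uniform_vec(es.ins_max("ins_vd") + 1)
            m.ins["dj"] = _uniform_vec(es.ins_max("ins_dj") + 1)
            m.markov["vd"] = _markov_uniform()
            m.markov["dj"] = _markov_uniform()
        return m

    def copy(self) -> "RecombModel":
        m = RecombModel(
            event_space=self.event_space,
            factorized=self.factorized,
            error_rate=self.error_rate,
            dj_markov_direction=self.dj_markov_direction,
            forbidden_dj=self.forbidden_dj,
        )
        for attr in ("gene_vj", "gene_v", "gene_dj", "gene_vdj", "del_v", "del_j", "del_d", "dj_mask"):
            val = getattr(self, attr)
            setattr(m, attr, None if val is None else val.copy())
        m.ins = {k: v.copy() for k, v in self.ins.items()}
        m.markov = {
            k: {kk: vv.copy() for kk, vv in v.items()} for k, v in self.markov.items()
        }
        return m

    # -- accessors -----------------------------------------------------------

    def gene_joint(self) -> np.ndarray:
        """Joint gene-usage table: (nV,nJ) for VJ, (nV,nD,nJ) for VDJ."""
        if self.chain_type == "VJ":
            return self.gene_vj
        if self.factorized:
            return self.gene_v[:, None, None] * self.gene_dj[None, :, :]
        return self.gene_vdj

    def junctions(self) -> tuple[str, ...]:
        return ("vj",) if self.chain_type == "VJ" else ("vd", "dj")

    # -- contracts -----------------------------------------------------------

    def validate(self, tol: float = NORM_TOL) -> None:
        es = self.event_space

        def check(name: str, arr: np.ndarray, axis) -> None:
            if np.any(arr < -tol) or np.any(arr > 1 + tol):
                raise ModelValidationError(f"{name}: probabilities outside [0,1]")
            sums = arr.sum(axis=axis)
            bad = np.abs(sums - 1.0) > tol
            if np.any(bad):
                raise ModelValidationError(
                    f"{name}: {int(np.count_nonzero(bad))} row(s) do not sum to 1 "
                    f"(max dev {float(np.max(np.abs(sums - 1.0))):.3g})"
                )

        if self.chain_type == "VJ":
            check("gene_vj", self.gene_vj, (0, 1))
        elif self.factorized:
            check("gene_v", self.gene_v, 0)
            check("gene_dj", self.gene_dj, (0, 1))
        else:
            check("gene_vdj", self.gene_vdj, (0, 1, 2))
        if self.dj_mask is not None:
            table = self.gene_dj if self.factorized else self.gene_vdj.sum(axis=0)
            if np.any(table[self.dj_mask] != 0.0):
                raise ModelValidationError("mass on structurally forbidden D-J pairs")
        check("del_v", self.del_v, 1)
        check("del_j", self.del_j, 1)
        if self.chain_type == "VDJ":
            check("del_d", self.del_d, (1, 2))
        for junc in self.junctions():
            check(f"ins_{junc}", self.ins[junc], 0)
            check(f"markov_{junc}.trans", self.markov[junc]["trans"], 1)
            check(f"markov_{junc}.init", self.markov[junc]["init"], 0)
        if not (0.0 <= self.error_rate < 1.0):
            raise ModelValidationError(f"error_rate {self.error_rate} outside [0,1)")


def _uniform_rows(n: int, k: int) -> np.ndarray:
    return np.full((n, k), 1.0 / k)


def _uniform_vec(k: int) -> np.ndarray:
    return np.full(k, 1.0 / k)


def _masked_uniform(mask: np.ndarray) -> np.ndarray:
    out = np.where(mask, 0.0, 1.0)
    return out / out.sum()


def _build_dj_mask(es: EventSpace, forbidden: Sequence[tuple[str, str]]) -> np.ndarray:
    mask = np.zeros((len(es.d_genes), len(es.j_genes)), dtype=bool)
    for dfam, jfam in forbidden:
        hit = False
        for i, d in enumerate(es.d_genes):
            for j, jg in enumerate(es.j_genes):
                if d.family == dfam and jg.family == jfam:
                    mask[i, j] = True
                    hit = True
        if not hit:
            raise ConfigError(f"forbidden pair {dfam}:{jfam} matches no D/J families")
    if mask.all():
        raise ConfigError("all D-J pairs forbidden")
    return mask


def _uniform_del_d(es: EventSpace) -> np.ndarray:
    """Uniform P(delDl,delDr|D) over combinations that leave a non-negative
    retained length; impossible cells carry exactly 0."""
    dl = es.del_values("del_d_l")
    dr = es.del_values("del_d_r")
    out = np.zeros((len(es.d_genes), len(dl), len(dr)))
    for i, d in enumerate(es.d_genes):
        valid = (dl[:, None] + dr[None, :]) <= len(d.seq)
        out[i] = valid / valid.sum()
    return out


# ---------------------------------------------------------------------------
# build_model

_SUPPORTED_EVENTS = {
    "VJ": {"gene_v", "gene_j", "del_v", "del_j", "ins_vj"},
    "VDJ": {"gene_v", "gene_d", "gene_j", "del_v", "del_j", "del_d", "ins_vd", "ins_dj"},
}


def _check_dependencies(deps: Iterable[tuple[str, str]], chain_type: str) -> None:
    """Validate a user-declared event dependency graph: known events, acyclic."""
    events = _SUPPORTED_EVENTS[chain_type]
    adj: dict[str, list[str]] = {}
    for parent, child in deps:
        for node in (parent, child):
            if node not in events:
                raise StructureError(f"unknown event {node!r} for chain {chain_type}")
        adj.setdefault(parent, []).append(child)
    state: dict[str, int] = {}

    def visit(node: str) -> None:
        state[node] = 1
        for nxt in adj.get(node, ()):
            if state.get(nxt) == 1:
                raise StructureError(f"cyclic dependency through {nxt!r}")
            if state.get(nxt, 0) == 0:
                visit(nxt)
        state[node] = 2

    for node in list(adj):
        if state.get(node, 0) == 0:
            visit(node)


def build_model(
    structure_config: Mapping,
    germline: Mapping[str, Sequence[GermlineSegment]],
) -> RecombModel:
    """Build a (uniform-CPT) model from a structure description and germline.

    ``structure_config`` keys: ``chain_type`` ('VJ'|'VDJ'), ``factorized``,
    ``max_palindrome``, ``ranges`` (partial override of defaults),
    ``forbidden_dj`` (list of (D family, J family) pairs), ``reverse_d``,
    ``error_rate``, ``dependencies`` (optional explicit DAG edges),
    ``dj_markov_direction``.
    """
    cfg = dict(structure_config)
    chain_type = cfg.get("chain_type")
    if chain_type not in ("VJ", "VDJ"):
        raise ConfigError(f"chain_type must be 'VJ' or 'VDJ', got {chain_type!r}")
    if chain_type == "VJ" and germline.get("D"):
        raise ConfigError("D germline segments supplied for a VJ chain")
    _check_dependencies(cfg.get("dependencies", ()), chain_type)

    max_p = int(cfg.get("max_palindrome", 4))
    ranges = dict(DEFAULT_RANGES)
    ranges.update(cfg.get("ranges", {}))

    def prep(segs: Sequence[GermlineSegment], keys: tuple[str, ...]) -> tuple:
        out = []
        for s in segs:
            s = extend_palindrome(s, max_p)
            for key in keys:
                lo, hi = ranges[key]
                # Clip per-class deletion bounds to the shortest gene.
                if hi > len(s.seq):
                    ranges[key] = (lo, len(s.seq))
            out.append(s)
        return tuple(out)

    v = prep(tuple(germline.get("V", ())), ("del_v",))
    j = prep(tuple(germline.get("J", ())), ("del_j",))
    d = tuple(germline.get("D", ()))
    if cfg.get("reverse_d"):
        d = d + tuple(
            replace(s, name=s.name + "_rev", seq=revcomp(s.seq), is_reverse_complement=True)
            for s in d
        )
    d = prep(d, ("del_d_l", "del_d_r")) if chain_type == "VDJ" else ()

    es = EventSpace(chain_type=chain_type, v_genes=v, d_genes=d, j_genes=j, ranges=ranges)
    return RecombModel.uniform(
        es,
        factorized=bool(cfg.get("factorized", True)),
        forbidden_dj=tuple(tuple(p) for p in cfg.get("forbidden_dj", ())),
        error_rate=float(cfg.get("error_rate", 1e-3)),
        dj_markov_direction=str(cfg.get("dj_markov_direction", "3to5")),
    )


# ---------------------------------------------------------------------------
# Scenario probability (recombination factor only)


def _markov_logp(
    model: RecombModel, junction: str, ins: str, cond_base: str | None
) -> float:
    """Log probability of an inserted string under a junction's Markov chain.

    ``ins`` is given in genomic (5'->3') order; for the DJ junction the chain
    runs 3'->5' so the string is traversed in reverse, conditioned on
    ``cond_base`` (first retained J base).  ``cond_base=None`` uses the
    initial-nucleotide distribution.
    """
    if not ins:
        return 0.0
    trans = model.markov[junction]["trans"]
    init = model.markov[junction]["init"]
    order = ins[::-1] if junction == "dj" else ins
    codes = [NT_INDEX[c] for c in order]
    first = init[codes[0]] if cond_base is None else trans[NT_INDEX[cond_base], codes[0]]
    logp = np.log(first) if first > 0 else -np.inf
    for a, b in zip(codes, codes[1:]):
        p = trans[a, b]
        logp += np.log(p) if p > 0 else -np.inf
    return float(logp)


def scenario_prob(model: RecombModel, scenario) -> float:
    """P_recomb of a fully specified scenario (no error factor).

    Raises :class:`EventRangeError` for out-of-range event values; returns
    exactly 0.0 for structurally forbidden but in-range combinations.
    """
    es = model.event_space
    vi = es.gene_index("V")[scenario.v]
    ji = es.gene_index("J")[scenario.j]
    vseg, jseg = es.v_genes[vi], es.j_genes[ji]

    def didx(key: str, val: int) -> int:
        lo, hi = es.ranges[key]
        if not (lo <= val <= hi):
            raise EventRangeError(f"{key}={val} outside [{lo},{hi}]")
        return val - lo

    logp = 0.0
    ret_v = vseg.retained(scenario.del_v)
    if model.chain_type == "VJ":
        ins_vj = scenario.ins_vj
        nins = len(ins_vj)
        if nins > es.ins_max("ins_vj"):
            raise EventRangeError(f"insVJ={nins} exceeds cap")
        p_gene = model.gene_vj[vi, ji]
        if p_gene == 0.0:
            return 0.0
        logp += np.log(p_gene)
        logp += _safe_log(model.del_v[vi, didx("del_v", scenario.del_v)])
        logp += _safe_log(model.del_j[ji, didx("del_j", scenario.del_j)])
        logp += _safe_log(model.ins["vj"][nins])
        logp += _markov_logp(model, "vj", ins_vj, ret_v[-1] if ret_v else None)
        return float(np.exp(logp))

    di = es.gene_index("D")[scenario.d]
    dseg = es.d_genes[di]
    if model.dj_mask is not None and model.dj_mask[di, ji]:
        return 0.0
    p_gene = model.gene_joint()[vi, di, ji]
    if p_gene == 0.0:
        return 0.0
    logp += np.log(p_gene)
    logp += _safe_log(model.del_v[vi, didx("del_v", scenario.del_v)])
    logp += _safe_log(model.del_j[ji, didx("del_j", scenario.del_j)])
    logp += _safe_log(
        model.del_d[
            di, didx("del_d_l", scenario.del_d_left), didx("del_d_r", scenario.del_d_right)
        ]
    )
    for junc, ins in (("vd", scenario.ins_vd), ("dj", scenario.ins_dj)):
        nins = len(ins)
        if nins > es.ins_max(f"ins_{junc}"):
            raise EventRangeError(f"ins{junc.upper()}={nins} exceeds cap")
        logp += _safe_log(model.ins[junc][nins])
    ret_j = jseg.retained(scenario.del_j)
    logp += _markov_logp(model, "vd", scenario.ins_vd, ret_v[-1] if ret_v else None)
    logp += _markov_logp(model, "dj", scenario.ins_dj, ret_j[0] if ret_j else None)
    return float(np.exp(logp))


def _safe_log(p: float) -> float:
    return float(np.log(p)) if p > 0 else -np.inf
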