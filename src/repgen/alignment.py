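"""Pre-alignment of reads against germline templates.

Each read is scored against every germline gene with the Smith-Waterman
algorithm (Biopython's :class:`Bio.Align.PairwiseAligner`); genes whose local
alignment score clears a per-class threshold are admitted.  Candidate
*placements* — gap-free registers of the extended template on the read, the
only registers the scenario space can express — come from an exhaustive
ungapped offset scan.  V placements are anchored toward the read 5' end,
J placements toward the 3' end, and D templates are scanned across the region
between the best V and best J placements.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from ._nt import encode
from .errors import InputError
from .recomb_model import EventSpace, GermlineSegment


@dataclass(frozen=True)
class AlignParams:
    """Scoring configuration for germline pre-alignment."""

    match: float = 5.0
    mismatch: float = -14.0
    gap_open: float = -50.0
    gap_extend: float = -50.0
    thresholds: Mapping[str, float] = field(
        default_factory=lambda: {"V": 30.0, "D": 15.0, "J": 30.0}
    )
    # Deletion-range slack (nt) around the best V/J placements when scanning
    # candidate D registers.
    d_window_slack: int = 16
    # Read-window anchoring: 'both' = read is the full recombined sequence
    # (V starts at read 0, J ends at read end); '3p' = read is a 3'-anchored
    # window (V may extend left of the read start).
    anchor: str = "3p"
    min_read_length: int = 15
    # Keep at most this many placements per gene (best-scoring first).
    max_placements: int = 8
    # Additionally keep one D register every this many positions across the
    # V-J window (regardless of score), so scenarios with a fully deleted D
    # remain expressible everywhere in the junction.
    d_fallback_step: int = 8
    # Keep only the best-scoring V genes (by SW score) among those admitted.
    max_v_genes: int = 4


@dataclass(frozen=True)
class SegmentAlignment:
    """One gap-free placement of a germline template on a read.

    ``offset`` is the read coordinate of ``segment.seq[0]`` (may be negative
    for V templates on truncated reads).  ``read_range``/``seg_range`` describe
    the full overlap of ``extended_seq`` with the read at this register (read
    coordinates, half-open; ``seg_range`` in extended_seq coordinates).
    ``mismatch_positions`` are read coordinates where the read differs from the
    extended template over that overlap; ``n_positions`` are read coordinates
    with an N base (guaranteed mismatches for scoring, excluded from error
    counting).
    """

    segment: GermlineSegment
    score: float  # Smith-Waterman score of read vs segment.seq
    placement_score: float  # ungapped score of this register (core seq only)
    offset: int
    read_range: tuple[int, int]
    seg_range: tuple[int, int]
    mismatch_positions: tuple[int, ...]
    n_positions: tuple[int, ...] = ()


@functools.lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float):
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def sw_score(read: str, seq: str, params: AlignParams) -> float:
    """Smith-Waterman local alignment score (library-backed)."""
    al = _aligner(params.match, params.mismatch, params.gap_open, params.gap_extend)
    return float(al.score(read, seq))


def _ungapped_scores(
    rcodes: np.ndarray, scodes: np.ndarray, offsets: np.ndarray, params: AlignParams
) -> np.ndarray:
    """Best local (contiguous) match/mismatch score of the core sequence at
    each gap-free register — Smith-Waterman restricted to that register, so a
    heavily trimmed segment still scores by its retained part."""
    n, m = len(rcodes), len(scodes)
    if not len(offsets):
        return np.full(0, -np.inf)
    idx = offsets[:, None] + np.arange(m)[None, :]
    valid = (idx >= 0) & (idx < n)
    rp = np.where(valid, rcodes[np.clip(idx, 0, n - 1)], -1)
    eq = (rp == scodes[None, :]) & (rp >= 0) & (rp < 4)
    profile = np.where(
        valid, np.where(eq, params.match, params.mismatch), -1e9
    )
    prefix = np.concatenate(
        [np.zeros((len(offsets), 1)), np.cumsum(profile, axis=1)], axis=1
    )
    best = np.max(prefix[:, 1:] - np.minimum.accumulate(prefix[:, :-1], axis=1), axis=1)
    best[best < -1e8] = -np.inf
    return best


def _placement(
    read: str,
    rcodes: np.ndarray,
    seg: GermlineSegment,
    offset: int,
    score: float,
    placement_score: float,
) -> SegmentAlignment | None:
    """Build the SegmentAlignment for a register, with the full extended-seq
    overlap mismatch map."""
    ecodes = encode(seg.extended_seq)
    n, me = len(rcodes), len(ecodes)
    ext_off = offset - seg.pal_left  # read coordinate of extended_seq[0]
    a, b = max(0, ext_off), min(n, ext_off + me)
    if b <= a:
        return None
    rseg = rcodes[a:b]
    sseg = ecodes[a - ext_off : b - ext_off]
    nmask = rseg >= 4
    mm = np.nonzero((rseg != sseg) & ~nmask)[0] + a
    npos = np.nonzero(nmask)[0] + a
    return SegmentAlignment(
        segment=seg,
        score=score,
        placement_score=placement_score,
        offset=offset,
        read_range=(a, b),
        seg_range=(a - ext_off, b - ext_off),
        mismatch_positions=tuple(int(p) for p in mm),
        n_positions=tuple(int(p) for p in npos),
    )


def align_all(
    read: str,
    germline: Mapping[str, Sequence[GermlineSegment]],
    params: AlignParams | None = None,
) -> dict[str, list[SegmentAlignment]]:
    """Align a read to all germline templates; returns per-class candidate
    placements sorted by decreasing placement score."""
    params = params or AlignParams()
    if not read:
        raise InputError("empty read")
    read = read.upper().replace("U", "T")
    if len(read) < params.min_read_length:
        raise InputError(
            f"read shorter than minimum length {params.min_read_length}"
        )
    rcodes = encode(read)
    n = len(rcodes)
    out: dict[str, list[SegmentAlignment]] = {"V": [], "D": [], "J": []}

    v_gene_scores = []
    for seg in germline.get("V", ()):
        L = len(seg.seq)
        gene_score = sw_score(read, seg.seq, params)
        if gene_score < params.thresholds["V"]:
            continue
        v_gene_scores.append((gene_score, seg.name))
        if params.anchor == "both":
            offsets = np.array([0])
        else:  # 3'-anchored window: V starts at or left of the read start
            offsets = np.arange(-(L - 1), 1)
        scores = _ungapped_scores(rcodes, encode(seg.seq), offsets, params)
        out["V"].extend(
            _keep(read, rcodes, seg, offsets, scores, gene_score, params, "V")
        )
    if len(v_gene_scores) > params.max_v_genes:
        v_gene_scores.sort(key=lambda t: (-t[0], t[1]))
        admitted = {name for _s, name in v_gene_scores[: params.max_v_genes]}
        out["V"] = [a for a in out["V"] if a.segment.name in admitted]

    for seg in germline.get("J", ()):
        L = len(seg.seq)
        gene_score = sw_score(read, seg.seq, params)
        if gene_score < params.thresholds["J"]:
            continue
        # J's 3' end is never trimmed: it sits at (or beyond) the read end.
        offsets = np.array([n - L])
        scores = _ungapped_scores(rcodes, encode(seg.seq), offsets, params)
        out["J"].extend(
            _keep(read, rcodes, seg, offsets, scores, gene_score, params, "J")
        )

    # D search window: between the best V placement's end and the best J
    # placement's start (generous by the deletion-range slack).
    lo, hi = 0, n
    if out["V"]:
        best_v = max(out["V"], key=lambda a: a.placement_score)
        lo = max(0, best_v.offset + len(best_v.segment.seq) - params.d_window_slack)
    if out["J"]:
        best_j = max(out["J"], key=lambda a: a.placement_score)
        hi = min(n, best_j.offset + params.d_window_slack)
    for seg in germline.get("D", ()):
        L = len(seg.seq)
        gene_score = sw_score(read, seg.seq, params)
        if gene_score < params.thresholds["D"]:
            continue
        offsets = np.arange(lo - L + 1, hi + 1)
        scores = _ungapped_scores(rcodes, encode(seg.seq), offsets, params)
        kept = _keep(read, rcodes, seg, offsets, scores, gene_score, params, "D")
        have = {a.offset for a in kept}
        for k in range(0, len(offsets), max(1, params.d_fallback_step)):
            o = int(offsets[k])
            if o in have or not np.isfinite(scores[k]):
                continue
            pl = _placement(read, rcodes, seg, o, gene_score, float(scores[k]))
            if pl is not None:
                kept.append(pl)
        out["D"].extend(kept)

    for cls in out:
        out[cls].sort(key=lambda a: (-a.placement_score, a.segment.name, a.offset))
    return out


def _keep(
    read: str,
    rcodes: np.ndarray,
    seg: GermlineSegment,
    offsets: np.ndarray,
    scores: np.ndarray,
    gene_score: float,
    params: AlignParams,
    cls: str,
) -> list[SegmentAlignment]:
    thr = params.thresholds[cls]
    order = np.argsort(-scores, kind="stable")
    kept: list[SegmentAlignment] = []
    for k in order:
        if len(kept) >= params.max_placements or not np.isfinite(scores[k]):
            break
        if scores[k] < thr:
            # The gene already cleared the SW gate: keep at least its best
            # register so the scenario space can arbitrate.
            if kept:
                break
        pl = _placement(read, rcodes, seg, int(offsets[k]), gene_score, float(scores[k]))
        if pl is not None:
            kept.append(pl)
        if scores[k] < thr:
            break
    return kept


def alignment_rows(
    read_id: str, alignments: Mapping[str, Sequence[SegmentAlignment]]
) -> list[dict]:
    """Flatten per-class alignments into dump rows (read_id, seg_class,
    segment, score, read/segment intervals, semicolon-joined mismatches)."""
    rows = []
    for cls in ("V", "D", "J"):
        for a in alignments.get(cls, ()):
            rows.append(
                {
                    "read_id": read_id,
                    "seg_class": cls,
                    "segment": a.segment.name,
                    "score": a.score,
                    "read_start": a.read_range[0],
                    "read_end": a.read_range[1],
                    "seg_start": a.seg_range[0],
                    "seg_end": a.seg_range[1],
                    "mismatches": ";".join(str(p) for p in a.mismatch_positions),
                }
            )
    return rows


def replay_placements(
    sequence: str, alignments: Mapping[str, Sequence[SegmentAlignment]]
) -> dict[str, list[SegmentAlignment]]:
    """Re-evaluate existing placements against a different same-length
    sequence (e.g. a candidate ancestral sequence of the read): offsets and
    scores are kept, mismatch maps recomputed."""
    rcodes = encode(sequence.upper().replace("U", "T"))
    out: dict[str, list[SegmentAlignment]] = {}
    for cls, alns in alignments.items():
        kept = []
        for a in alns:
            pl = _placement(
                sequence, rcodes, a.segment, a.offset, a.score, a.placement_score
            )
            if pl is not None:
                kept.append(pl)
        out[cls] = kept
    return out


def feasible_deletions(
    alignment: SegmentAlignment, event_space: EventSpace
) -> tuple[int, int] | None:
    """Deletion values that keep the retained germline portion on the read and
    within the event-space range.  Returns an inclusive interval or None."""
    seg = alignment.segment
    L = len(seg.seq)
    n = alignment.read_range[1] if seg.seg_class == "J" else None
    if seg.seg_class == "V":
        lo_r, hi_r = event_space.ranges["del_v"]
        # retained end on read: v_end = offset + L - d, require 0 <= v_end
        # and retained length >= 0 and palindrome limit.
        lo = max(lo_r, -seg.max_p)
        hi = min(hi_r, L, alignment.offset + L)  # v_end >= 0
        return (lo, hi) if lo <= hi else None
    if seg.seg_class == "J":
        lo_r, hi_r = event_space.ranges["del_j"]
        lo = max(lo_r, -seg.max_p, -alignment.offset)  # j_start >= 0
        hi = min(hi_r, L)
        return (lo, hi) if lo <= hi else None
    raise ValueError("feasible_deletions is defined per end for D segments")
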