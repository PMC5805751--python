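"""Core likelihood engine over recombination scenarios.

A scenario for a read decomposes along the read as
``V-retained | VD insertions | D-retained | DJ insertions | J-retained``
(or ``V | insertions | J`` for VJ chains).  For fixed germline placements the
scenario probability factorizes as a chain over the junction coordinates

    f_V(v_end) * g_VD(v_end, d_start) * f_D(d_start, d_end)
    * g_DJ(d_end, j_start) * f_J(j_start)

which lets us compute the read likelihood and *exact* posterior marginals of
every event by forward-backward message passing (sum mode), and enumerate all
scenarios above a probability threshold (list mode) without visiting the full
cross product.

All probabilities are handled in log space; per-triple linear-space passes are
shifted by the triple's maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nt import encode
from .alignment import AlignParams, SegmentAlignment, align_all
from .recomb_model import RecombModel

NEG = -np.inf


def _log(a: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(a)


# ---------------------------------------------------------------------------
# Model-dependent lookup tables (rebuilt once per EM iteration)


class ModelTables:
    """Log-space CPTs plus the error/hypermutation factor tables."""

    def __init__(self, model: RecombModel, hm_model=None, error_free: bool = False):
        self.model = model
        es = model.event_space
        self.es = es
        self.chain = es.chain_type
        self.lg_del_v = _log(model.del_v)
        self.lg_del_j = _log(model.del_j)
        if self.chain == "VDJ":
            self.lg_del_d = _log(model.del_d)
            self.lg_gene_vdj = _log(model.gene_joint())
        else:
            self.lg_gene_vj = _log(model.gene_vj)
        self.lg_ins = {k: _log(v) for k, v in model.ins.items()}
        self.ins_cap = {k: len(v) - 1 for k, v in model.ins.items()}
        # Row 4 of lg_trans5 is the initial-nucleotide distribution, used when
        # the conditioning segment is fully deleted.
        self.lg_trans5 = {
            k: np.vstack([_log(v["trans"]), _log(v["init"])[None, :]])
            for k, v in model.markov.items()
        }
        self.error_free = error_free
        self.hm = hm_model
        if error_free:
            self.uniform_err = True
            self.lr_mm, self.lr_ok = NEG, 0.0
        elif hm_model is None:
            r = model.error_rate
            self.uniform_err = True
            self.lr_mm = float(np.log(r / 3.0)) if r > 0 else NEG
            self.lr_ok = float(np.log1p(-r))
        else:
            self.uniform_err = False
            self.m = int(hm_model.m)
            self.l_mm, self.l_ok = {}, {}
            for cls in "VDJ":
                rates = np.asarray(hm_model.rate_table_for(cls), dtype=float)
                self.l_mm[cls] = _log(rates / 3.0)
                self.l_ok[cls] = np.log1p(-rates)
            fb = float(hm_model.fallback_rate())
            self.l_fb_mm = float(np.log(fb / 3.0)) if fb > 0 else NEG
            self.l_fb_ok = float(np.log1p(-fb))


# ---------------------------------------------------------------------------
# Per-read geometry (model-value independent; cacheable across EM iterations)


def _searchcount(positions: np.ndarray, start, end) -> np.ndarray:
    """Number of sorted ``positions`` in [start, end) (vectorized)."""
    return np.searchsorted(positions, end) - np.searchsorted(positions, start)


@dataclass
class _SideGeom:
    """Admissible deletions and windows for one V or J placement."""

    aln: SegmentAlignment
    gi: int
    dvals: np.ndarray  # deletion values
    didx: np.ndarray  # CPT column indices
    edge: np.ndarray  # v_end (V) or j_start (J) per deletion value
    err: np.ndarray
    nn: np.ndarray
    cov: np.ndarray
    anc: np.ndarray  # conditioning base code (0..3) or 4 = fully deleted
    ctx: "_CtxGeom | None" = None


@dataclass
class _DGeom:
    aln: SegmentAlignment
    gi: int
    dl_vals: np.ndarray
    dl_idx: np.ndarray
    d_start: np.ndarray
    dr_vals: np.ndarray
    dr_idx: np.ndarray
    d_end: np.ndarray
    valid: np.ndarray  # (ndl, ndr) retained length >= 0
    err: np.ndarray  # (ndl, ndr)
    nn: np.ndarray
    cov: np.ndarray
    ctx: "_CtxGeom | None" = None


@dataclass
class _CtxGeom:
    """Hypermutation context indices over an alignment's overlap.

    ``ctx[p - a]`` is the plain-context index at read coordinate p (germline
    bases inside the extended-template overlap, read bases outside; -1 if the
    context is undefined).  ``cut_right[k, c-1]`` / ``cut_left[k, c-1]`` are
    the variants where coordinates at distance >= c beyond a junction cut are
    replaced by read (ancestral-insertion) bases.
    """

    a: int
    b: int
    mm: np.ndarray  # bool per position: read mismatches germline
    is_n: np.ndarray
    ctx: np.ndarray
    cut_right: np.ndarray | None  # (b-a, m) position p, cut at p+c
    cut_left: np.ndarray | None  # (b-a, m) position p, cut at p-c+1


def _build_ctx(
    rcodes: np.ndarray, aln: SegmentAlignment, m: int, right: bool, left: bool
) -> _CtxGeom:
    seg = aln.segment
    ec = encode(seg.extended_seq)
    ext_off = aln.offset - seg.pal_left
    a, b = aln.read_range
    n = len(rcodes)
    lo, hi = a - m, b + m
    coords = np.arange(lo, hi)

    # Read-only source (ancestral insertions) and germline-priority source.
    src_r = np.full(hi - lo, -1, dtype=np.int32)
    inside = (coords >= 0) & (coords < n)
    src_r[inside] = rcodes[coords[inside]]
    src_r[src_r >= 4] = -1
    src_g = src_r.copy()
    in_ext = (coords >= ext_off) & (coords < ext_off + len(ec))
    src_g[in_ext] = ec[coords[in_ext] - ext_off]
    src_g[src_g >= 4] = -1

    def windows(germ_slot) -> np.ndarray:
        """Context index per position; slot q takes the germline-priority
        source iff germ_slot(q), the read source otherwise."""
        out = np.zeros(b - a, dtype=np.int64)
        ok = np.ones(b - a, dtype=bool)
        for q in range(-m, m + 1):
            src = src_g if germ_slot(q) else src_r
            col = src[q + m : q + m + (b - a)]
            ok &= col >= 0
            out = out * 4 + np.maximum(col, 0)
        out[~ok] = -1
        return out

    plain = windows(lambda q: True)
    cut_r = cut_l = None
    if right:
        # Cut at coordinate p + c: slots q >= c lie beyond the retained end.
        cut_r = np.stack(
            [windows(lambda q, c=c: q < c) for c in range(1, m + 1)], axis=1
        )
    if left:
        # Cut at coordinate p - c + 1: slots q <= -c lie before the start.
        cut_l = np.stack(
            [windows(lambda q, c=c: q > -c) for c in range(1, m + 1)], axis=1
        )
    rseg = rcodes[a:b]
    eseg = ec[a - ext_off : b - ext_off]
    is_n = rseg >= 4
    mm = (rseg != eseg) & ~is_n
    return _CtxGeom(a=a, b=b, mm=mm, is_n=is_n, ctx=plain, cut_right=cut_r, cut_left=cut_l)


class ReadGeometry:
    """Alignment-derived geometry for one read (cached across EM iterations)."""

    def __init__(
        self,
        read: str,
        model: RecombModel,
        align_params: AlignParams | None = None,
        alignments: dict[str, list[SegmentAlignment]] | None = None,
        ctx_halfwidth: int | None = None,
    ):
        read = read.upper().replace("U", "T")
        self.read = read
        self.rcodes = encode(read)
        self.n = len(read)
        self.align_params = align_params or AlignParams()
        es = model.event_space
        germ = {"V": es.v_genes, "D": es.d_genes, "J": es.j_genes}
        self.alignments = (
            alignments
            if alignments is not None
            else align_all(read, germ, self.align_params)
        )
        vidx = es.gene_index("V")
        jidx = es.gene_index("J")
        self.v: list[_SideGeom] = [
            g
            for a in self.alignments["V"]
            if (g := self._v_geom(a, vidx[a.segment.name], es)) is not None
        ]
        self.j: list[_SideGeom] = [
            g
            for a in self.alignments["J"]
            if (g := self._j_geom(a, jidx[a.segment.name], es)) is not None
        ]
        self.d: list[_DGeom] = []
        if es.chain_type == "VDJ":
            didx = es.gene_index("D")
            self.d = self._d_geoms(
                [a for a in self.alignments["D"]], didx, es
            )
        if ctx_halfwidth is not None:
            self.build_ctx(ctx_halfwidth)

    def build_ctx(self, m: int) -> None:
        for g in self.v:
            g.ctx = _build_ctx(self.rcodes, g.aln, m, right=True, left=False)
        for g in self.j:
            g.ctx = _build_ctx(self.rcodes, g.aln, m, right=False, left=True)
        for g in self.d:
            g.ctx = _build_ctx(self.rcodes, g.aln, m, right=True, left=True)

    def _v_geom(self, aln, gi, es) -> _SideGeom | None:
        seg = aln.segment
        L = len(seg.seq)
        lo, hi = es.ranges["del_v"]
        d = np.arange(lo, hi + 1)
        v_end = aln.offset + L - d
        keep = (v_end >= 0) & (v_end <= self.n)
        if not keep.any():
            return None
        d, v_end = d[keep], v_end[keep]
        a0 = max(0, aln.offset - seg.pal_left)
        mm = np.asarray(aln.mismatch_positions)
        nn = np.asarray(aln.n_positions)
        start = np.maximum(a0, 0)
        err = _searchcount(mm, start, np.maximum(v_end, start))
        nnc = _searchcount(nn, start, np.maximum(v_end, start))
        cov = np.maximum(v_end - start, 0)
        ec = encode(seg.extended_seq)
        anc = np.where(L - d >= 1, ec[np.clip(L - d - 1, 0, len(ec) - 1)], 4)
        anc = np.where(anc >= 4, 4, anc).astype(np.int64)
        return _SideGeom(aln, gi, d, d - lo, v_end, err, nnc, cov, anc)

    def _j_geom(self, aln, gi, es) -> _SideGeom | None:
        seg = aln.segment
        L = len(seg.seq)
        lo, hi = es.ranges["del_j"]
        d = np.arange(lo, hi + 1)
        j_start = aln.offset + d
        keep = (j_start >= 0) & (j_start <= self.n)
        if not keep.any():
            return None
        d, j_start = d[keep], j_start[keep]
        end = min(self.n, aln.offset + L)
        mm = np.asarray(aln.mismatch_positions)
        nn = np.asarray(aln.n_positions)
        err = _searchcount(mm, np.minimum(j_start, end), end)
        nnc = _searchcount(nn, np.minimum(j_start, end), end)
        cov = np.maximum(end - j_start, 0)
        ec = encode(seg.extended_seq)
        pl = seg.pal_left
        anc = np.where(
            L - d >= 1, ec[np.clip(pl + d, 0, len(ec) - 1)], 4
        )
        anc = np.where(anc >= 4, 4, anc).astype(np.int64)
        return _SideGeom(aln, gi, d, d - lo, j_start, err, nnc, cov, anc)

    def _d_geoms(self, alns, didx, es) -> list[_DGeom]:
        """Batched D-register geometry: the full deletion ranges are kept for
        every register (uniform shapes, so they can be stacked), with invalid
        cells masked."""
        if not alns:
            return []
        n = self.n
        lo_l, hi_l = es.ranges["del_d_l"]
        lo_r, hi_r = es.ranges["del_d_r"]
        dl = np.arange(lo_l, hi_l + 1)
        dr = np.arange(lo_r, hi_r + 1)
        offs = np.array([a.offset for a in alns])
        Ls = np.array([len(a.segment.seq) for a in alns])
        d_start3 = offs[:, None] + dl[None, :]  # (R, ndl)
        d_end3 = offs[:, None] + Ls[:, None] - dr[None, :]  # (R, ndr)
        kl3 = (d_start3 >= 0) & (d_start3 <= n)
        kr3 = (d_end3 >= 0) & (d_end3 <= n)
        valid3 = (
            kl3[:, :, None]
            & kr3[:, None, :]
            & (d_end3[:, None, :] >= d_start3[:, :, None])
            & ((dl[:, None] + dr[None, :])[None, :, :] <= Ls[:, None, None])
        )
        # per-register prefix counts of mismatches / N bases
        mmpre = np.zeros((len(alns), n + 1))
        nnpre = np.zeros((len(alns), n + 1))
        for k, a in enumerate(alns):
            if a.mismatch_positions:
                np.add.at(mmpre[k], np.asarray(a.mismatch_positions) + 1, 1.0)
            if a.n_positions:
                np.add.at(nnpre[k], np.asarray(a.n_positions) + 1, 1.0)
        mmpre = np.cumsum(mmpre, axis=1)
        nnpre = np.cumsum(nnpre, axis=1)
        s3 = np.clip(d_start3, 0, n)[:, :, None]
        e3 = np.maximum(np.clip(d_end3, 0, n)[:, None, :], s3)
        ridx = np.arange(len(alns))[:, None, None]
        err3 = mmpre[ridx, e3] - mmpre[ridx, s3]
        nn3 = nnpre[ridx, e3] - nnpre[ridx, s3]
        cov3 = e3 - s3
        out = []
        for k, a in enumerate(alns):
            if not valid3[k].any():
                continue
            out.append(
                _DGeom(
                    a, didx[a.segment.name], dl, dl - lo_l, d_start3[k],
                    dr, dr - lo_r, d_end3[k], valid3[k], err3[k], nn3[k], cov3[k],
                )
            )
        return out


# ---------------------------------------------------------------------------
# Model-dependent per-read factors


class ReadFactors:
    """Log factor arrays for one read under one set of model tables."""

    def __init__(self, geom: ReadGeometry, tables: ModelTables):
        self.geom = geom
        self.t = tables
        r = geom.rcodes.astype(np.int64)
        n = geom.n
        self.rcodes = r
        # Markov prefix sums.  S[t] = sum_{u=1..t} log T[r[u-1], r[u]]
        # (transitions *into* positions 1..t, both bases inserted).
        self.S = {}
        rsafe = np.minimum(r, 3)
        has_n = (r >= 4)
        for junc, lt5 in tables.lg_trans5.items():
            if junc == "dj":
                c = lt5[rsafe[1:], rsafe[:-1]].astype(float)  # into u from u+1
                c[has_n[1:] | has_n[:-1]] = NEG
                # S2[t] = sum_{u=0..t-1} c[u], t in 0..n-1
                self.S[junc] = np.concatenate([[0.0], np.cumsum(c)])
            else:
                c = lt5[rsafe[:-1], rsafe[1:]].astype(float)
                c[has_n[1:] | has_n[:-1]] = NEG
                self.S[junc] = np.concatenate([[0.0], np.cumsum(c)])
        self.v = [self._side_factors(g, "V") for g in geom.v]
        self.j = [self._side_factors(g, "J") for g in geom.j]
        self.d = [self._d_factors(g) for g in geom.d]
        self._dstack = None

    def d_stack(self):
        """Stacked D-register arrays for the batched chain: (b3, d_start3,
        d_end3, gene_index) with leading axis = register (geom.d order)."""
        if self._dstack is None and self.geom.d:
            self._dstack = (
                np.stack([f["b"] for f in self.d]),
                np.stack([g.d_start for g in self.geom.d]),
                np.stack([g.d_end for g in self.geom.d]),
                np.array([g.gi for g in self.geom.d]),
            )
        return self._dstack

    # -- error factors -------------------------------------------------------

    def _uniform_errfac(self, err, nn, cov):
        t = self.t
        ok = np.asarray(cov - err - nn, dtype=float)
        err = np.asarray(err, dtype=float)
        if np.isfinite(t.lr_mm):
            return err * t.lr_mm + ok * t.lr_ok
        # error-free mode: any mismatch kills the placement
        return np.where(err > 0, NEG, ok * t.lr_ok)

    def _ctx_logfac(
        self, ctx_idx: np.ndarray, mm: np.ndarray, is_n: np.ndarray, cls: str
    ):
        """Per-position log factor given context indices and mismatch flags."""
        t = self.t
        l_mm, l_ok = t.l_mm[cls], t.l_ok[cls]
        lf = np.where(
            ctx_idx >= 0,
            np.where(mm, l_mm[np.maximum(ctx_idx, 0)], l_ok[np.maximum(ctx_idx, 0)]),
            np.where(mm, t.l_fb_mm, t.l_fb_ok),
        )
        lf = np.where(is_n, 0.0, lf)
        return lf

    def _shm_side(self, g: _SideGeom, cls: str):
        t = self.t
        cg = g.ctx
        lf = self._ctx_logfac(cg.ctx, cg.mm, cg.is_n, cls)
        pre = np.concatenate([[0.0], np.cumsum(lf)])  # over [a, b)
        a = cg.a
        if cls == "V":
            start = max(0, a)
            base = pre[np.maximum(g.edge, start) - a] - pre[start - a]
            out = base.copy()
            m = t.m
            for c in range(1, m + 1):
                p = g.edge - c  # position whose context is cut at distance c
                okp = (p >= start) & (p < cg.b)
                if not okp.any():
                    continue
                k = p[okp] - a
                cut_ctx = cg.cut_right[k, c - 1]
                corr = self._ctx_logfac(cut_ctx, cg.mm[k], cg.is_n[k], cls) - lf[k]
                out[okp] += corr
            return out
        # J: windows [j_start, b)
        start = np.minimum(g.edge, cg.b)
        base = pre[cg.b - a] - pre[np.maximum(start, a) - a]
        out = base.copy()
        m = t.m
        for c in range(1, m + 1):
            p = g.edge + c - 1
            okp = (p >= a) & (p < cg.b)
            if not okp.any():
                continue
            k = p[okp] - a
            cut_ctx = cg.cut_left[k, c - 1]
            corr = self._ctx_logfac(cut_ctx, cg.mm[k], cg.is_n[k], cls) - lf[k]
            out[okp] += corr
        return out

    def _shm_d(self, g: _DGeom):
        t = self.t
        cg = g.ctx
        lf = self._ctx_logfac(cg.ctx, cg.mm, cg.is_n, "D")
        # per-position log factors under each cut-distance variant
        m = t.m
        lfL = np.stack(
            [
                self._ctx_logfac(cg.cut_left[:, c], cg.mm, cg.is_n, "D")
                for c in range(m)
            ],
            axis=1,
        )
        lfR = np.stack(
            [
                self._ctx_logfac(cg.cut_right[:, c], cg.mm, cg.is_n, "D")
                for c in range(m)
            ],
            axis=1,
        )
        pre = np.concatenate([[0.0], np.cumsum(lf)])
        a = cg.a
        s = np.clip(g.d_start, a, cg.b)
        e = np.clip(g.d_end, a, cg.b)
        base = pre[np.maximum(e[None, :], s[:, None]) - a] - pre[s[:, None] - a]
        corr_l = np.zeros(len(g.d_start))
        for c in range(1, m + 1):
            p = g.d_start + c - 1
            okp = (p >= a) & (p < cg.b)
            if okp.any():
                k = p[okp] - a
                corr_l[okp] += lfL[k, c - 1] - lf[k]
        corr_r = np.zeros(len(g.d_end))
        for c in range(1, m + 1):
            p = g.d_end - c
            okp = (p >= a) & (p < cg.b)
            if okp.any():
                k = p[okp] - a
                corr_r[okp] += lfR[k, c - 1] - lf[k]
        out = base + corr_l[:, None] + corr_r[None, :]
        # For retained windows narrower than 2m the independent corrections
        # above may touch positions outside [d_start, d_end); recompute those
        # few cells from the precomputed per-position variants, preferring the
        # nearer cut when both fall inside one context window.
        width = np.maximum(g.d_end[None, :] - g.d_start[:, None], 0)
        narrow = g.valid & (width > 0) & (width < 2 * m)
        for il, ir in np.argwhere(narrow):
            sc, ec = int(g.d_start[il]), int(g.d_end[ir])
            corr = 0.0
            for p in range(max(sc, a), min(ec, cg.b)):
                k = p - a
                cl = p - sc + 1
                cr = ec - p
                if cl <= m and (cr > m or cl <= cr):
                    corr += lfL[k, cl - 1] - lf[k]
                elif cr <= m:
                    corr += lfR[k, cr - 1] - lf[k]
            out[il, ir] = base[il, ir] + corr
        return out

    # -- per-placement factor arrays ----------------------------------------

    def _side_factors(self, g: _SideGeom, cls: str):
        t = self.t
        if cls == "V":
            lg_del = t.lg_del_v[g.gi, g.didx]
        else:
            lg_del = t.lg_del_j[g.gi, g.didx]
        if t.uniform_err:
            errfac = self._uniform_errfac(g.err, g.nn, g.cov)
        else:
            errfac = self._shm_side(g, cls)
        return {"a": lg_del + errfac, "errfac": errfac}

    def _d_factors(self, g: _DGeom):
        t = self.t
        lg_del = t.lg_del_d[g.gi][np.ix_(g.dl_idx, g.dr_idx)]
        if t.uniform_err:
            errfac = self._uniform_errfac(g.err, g.nn, g.cov)
        else:
            errfac = self._shm_d(g)
        b = lg_del + errfac
        b[~g.valid] = NEG
        return {"b": b, "errfac": np.where(g.valid, errfac, NEG)}

    # -- pair (junction) terms ----------------------------------------------

    def pair_x(self, vg: _SideGeom, starts: np.ndarray, junc: str):
        """(n_dv, n_starts) log term for the junction following V: insertion
        length factor + Markov chain over read[v_end:start)."""
        t = self.t
        S = self.S[junc]
        cap = t.ins_cap[junc]
        lt5 = t.lg_trans5[junc]
        v_end = vg.edge
        gap = starts[None, :] - v_end[:, None]
        ok = (gap >= 0) & (gap <= cap)
        lp = np.where(ok, t.lg_ins[junc][np.clip(gap, 0, cap)], NEG)
        first_ok = ok & (gap >= 1)
        if first_ok.any():
            ve = np.clip(v_end, 0, self.geom.n - 1)
            rbase = np.minimum(self.rcodes[ve], 3)
            first = lt5[vg.anc, rbase]  # (n_dv,)
            first = np.where(self.rcodes[ve] >= 4, NEG, first)
            with np.errstate(invalid="ignore"):
                interior = S[np.maximum(starts - 1, 0)][None, :] - S[ve][:, None]
                lp = lp + np.where(first_ok, first[:, None] + interior, 0.0)
            lp[np.isnan(lp)] = NEG
        return lp

    def pair_y(self, jg: _SideGeom, ends: np.ndarray, junc: str = "dj"):
        """(n_ends, n_dj) log term for the junction preceding J (chain runs
        3'->5' from the first retained J base)."""
        t = self.t
        S2 = self.S[junc]
        cap = t.ins_cap[junc]
        lt5 = t.lg_trans5[junc]
        j_start = jg.edge
        gap = j_start[None, :] - ends[:, None]
        ok = (gap >= 0) & (gap <= cap)
        lp = np.where(ok, t.lg_ins[junc][np.clip(gap, 0, cap)], NEG)
        first_ok = ok & (gap >= 1)
        if first_ok.any():
            js = np.clip(j_start - 1, 0, self.geom.n - 1)
            rbase = np.minimum(self.rcodes[js], 3)
            first = lt5[jg.anc, rbase]  # (n_dj,)
            first = np.where(self.rcodes[js] >= 4, NEG, first)
            with np.errstate(invalid="ignore"):
                interior = (
                    S2[np.clip(j_start - 1, 0, len(S2) - 1)][None, :]
                    - S2[np.clip(ends, 0, len(S2) - 1)][:, None]
                )
                lp = lp + np.where(first_ok, first[None, :] + interior, 0.0)
            lp[np.isnan(lp)] = NEG
        return lp

    def pair_x3(self, vg: _SideGeom, starts3: np.ndarray, junc: str):
        """Batched pair_x over stacked registers: starts3 (R, ndl) ->
        (R, ndv, ndl)."""
        t = self.t
        S = self.S[junc]
        cap = t.ins_cap[junc]
        lt5 = t.lg_trans5[junc]
        v_end = vg.edge
        gap = starts3[:, None, :] - v_end[None, :, None]
        ok = (gap >= 0) & (gap <= cap)
        lp = np.where(ok, t.lg_ins[junc][np.clip(gap, 0, cap)], NEG)
        first_ok = ok & (gap >= 1)
        if first_ok.any():
            ve = np.clip(v_end, 0, self.geom.n - 1)
            rbase = np.minimum(self.rcodes[ve], 3)
            first = lt5[vg.anc, rbase]
            first = np.where(self.rcodes[ve] >= 4, NEG, first)
            sclip = np.clip(starts3 - 1, 0, len(S) - 1)
            with np.errstate(invalid="ignore"):
                interior = S[sclip][:, None, :] - S[ve][None, :, None]
                lp = lp + np.where(first_ok, first[None, :, None] + interior, 0.0)
            lp[np.isnan(lp)] = NEG
        return lp

    def pair_y3(self, jg: _SideGeom, ends3: np.ndarray, junc: str = "dj"):
        """Batched pair_y over stacked registers: ends3 (R, ndr) ->
        (R, ndr, ndj)."""
        t = self.t
        S2 = self.S[junc]
        cap = t.ins_cap[junc]
        lt5 = t.lg_trans5[junc]
        j_start = jg.edge
        gap = j_start[None, None, :] - ends3[:, :, None]
        ok = (gap >= 0) & (gap <= cap)
        lp = np.where(ok, t.lg_ins[junc][np.clip(gap, 0, cap)], NEG)
        first_ok = ok & (gap >= 1)
        if first_ok.any():
            js = np.clip(j_start - 1, 0, self.geom.n - 1)
            rbase = np.minimum(self.rcodes[js], 3)
            first = lt5[jg.anc, rbase]
            first = np.where(self.rcodes[js] >= 4, NEG, first)
            jclip = np.clip(j_start - 1, 0, len(S2) - 1)
            eclip = np.clip(ends3, 0, len(S2) - 1)
            with np.errstate(invalid="ignore"):
                interior = S2[jclip][None, None, :] - S2[eclip][:, :, None]
                lp = lp + np.where(first_ok, first[None, None, :] + interior, 0.0)
            lp[np.isnan(lp)] = NEG
        return lp


# ---------------------------------------------------------------------------
# Sufficient statistics


class SufficientStats:
    """Posterior-weighted event counts accumulated over reads (E step)."""

    def __init__(self, model: RecombModel, collect_shm: bool = False, shm_m: int = 3):
        es = model.event_space
        self.chain = es.chain_type
        if self.chain == "VJ":
            self.gene = np.zeros((len(es.v_genes), len(es.j_genes)))
        else:
            self.gene = np.zeros(
                (len(es.v_genes), len(es.d_genes), len(es.j_genes))
            )
        self.del_v = np.zeros_like(model.del_v)
        self.del_j = np.zeros_like(model.del_j)
        self.del_d = None if model.del_d is None else np.zeros_like(model.del_d)
        self.ins = {k: np.zeros_like(v) for k, v in model.ins.items()}
        self.trans5 = {k: np.zeros((5, 4)) for k in model.markov}
        self.err_events = 0.0
        self.err_opportunities = 0.0
        self.n_reads = 0
        self.n_failed = 0
        self.loglik = 0.0
        self.collect_shm = collect_shm
        self.shm_m = shm_m
        if collect_shm:
            w = 4 ** (2 * shm_m + 1)
            self.shm_counts = {cls: np.zeros((w, 2)) for cls in "VDJ"}

    def pseudo_loglik(self, tables: ModelTables) -> float:
        """Expected log scenario probability under the posterior (the EM
        auxiliary objective), reconstructed from the accumulated counts."""

        def dot(counts, logs):
            mask = counts > 0
            return float(np.sum(counts[mask] * logs[mask]))

        q = 0.0
        if self.chain == "VJ":
            q += dot(self.gene, tables.lg_gene_vj)
        else:
            q += dot(self.gene, tables.lg_gene_vdj)
            q += dot(self.del_d, tables.lg_del_d)
        q += dot(self.del_v, tables.lg_del_v)
        q += dot(self.del_j, tables.lg_del_j)
        for junc in self.ins:
            q += dot(self.ins[junc], tables.lg_ins[junc])
            q += dot(self.trans5[junc], tables.lg_trans5[junc])
        if tables.uniform_err and not tables.error_free:
            if self.err_events > 0:
                q += self.err_events * tables.lr_mm
            q += (self.err_opportunities - self.err_events) * tables.lr_ok
        return q


class _Acc:
    """Per-read unnormalized marginal accumulators with streaming rescale."""

    def __init__(self, geom: ReadGeometry, model: RecombModel):
        self.ref = NEG
        self.z = 0.0
        self.mv = [np.zeros(len(g.dvals)) for g in geom.v]
        self.mj = [np.zeros(len(g.dvals)) for g in geom.j]
        dshape = (len(geom.d),) + (geom.d[0].valid.shape if geom.d else (0, 0))
        self.md3 = np.zeros(dshape)
        if model.chain_type == "VJ":
            self.gene = np.zeros((len(geom.v), len(geom.j)))
        else:
            self.gene = np.zeros((len(geom.v), len(geom.d), len(geom.j)))
        self.ins = {k: np.zeros_like(v) for k, v in model.ins.items()}
        self.trans5 = {k: np.zeros((5, 4)) for k in model.markov}
        self.covw = {k: np.zeros(geom.n + 1) for k in model.markov}

    def rescale_to(self, new_ref: float) -> float:
        """Returns the scale factor for contributions at ``new_ref``."""
        if new_ref > self.ref:
            f = np.exp(self.ref - new_ref)
            self.z *= f
            for arr in self.mv + self.mj:
                arr *= f
            self.md3 *= f
            self.gene *= f
            for d in (self.ins, self.trans5, self.covw):
                for arr in d.values():
                    arr *= f
            self.ref = new_ref
            return 1.0
        return float(np.exp(new_ref - self.ref))


def _pair_marg_updates(acc, junc, vg_anc, edge, starts, marg, rcodes, cap):
    """Insertion-length, first-transition and interior-coverage updates from a
    joint (left-deletion x start) marginal ``marg`` for one junction."""
    gap = starts[None, :] - edge[:, None]
    use = (marg > 0) & (gap >= 0) & (gap <= cap)
    if not use.any():
        return
    g = gap[use]
    w = marg[use]
    np.add.at(acc.ins[junc], g, w)
    first = use & (gap >= 1)
    if first.any():
        wf = marg[first]
        kdv, kst = np.nonzero(first)
        ve = edge[kdv]
        rb = np.minimum(rcodes[ve], 3)
        np.add.at(acc.trans5[junc], (vg_anc[kdv], rb), wf)
        np.add.at(acc.covw[junc], ve + 1, wf)
        np.add.at(acc.covw[junc], starts[kst], -wf)


def _pair_marg_updates_dj(acc, junc, jg_anc, ends, j_start, marg, rcodes, cap):
    """DJ-side analogue: ``marg`` is the joint (end x j_start-deletion)
    marginal; the chain runs 3'->5' conditioned on the first retained J base."""
    gap = j_start[None, :] - ends[:, None]
    use = (marg > 0) & (gap >= 0) & (gap <= cap)
    if not use.any():
        return
    np.add.at(acc.ins[junc], gap[use], marg[use])
    first = use & (gap >= 1)
    if first.any():
        wf = marg[first]
        kend, kdj = np.nonzero(first)
        js = j_start[kdj]
        rb = np.minimum(rcodes[js - 1], 3)
        np.add.at(acc.trans5[junc], (jg_anc[kdj], rb), wf)
        # interior transitions (u+1 -> u) for u in [d_end, j_start-2]
        np.add.at(acc.covw[junc], ends[kend], wf)
        np.add.at(acc.covw[junc], js - 1, -wf)


def _pair_marg_updates3(acc, junc, anc, edge, starts3, marg3, rcodes, cap):
    """Batched-register analogue of _pair_marg_updates:
    marg3 (R, ndv, ndl), starts3 (R, ndl), edge (ndv,)."""
    gap = starts3[:, None, :] - edge[None, :, None]
    tiny = float(marg3.max()) * 1e-14
    use = (marg3 > tiny) & (gap >= 0) & (gap <= cap)
    if not use.any():
        return
    np.add.at(acc.ins[junc], gap[use], marg3[use])
    first = use & (gap >= 1)
    if first.any():
        rr, kdv, kdl = np.nonzero(first)
        wf = marg3[first]
        ve = edge[kdv]
        rb = np.minimum(rcodes[ve], 3)
        np.add.at(acc.trans5[junc], (anc[kdv], rb), wf)
        np.add.at(acc.covw[junc], ve + 1, wf)
        np.add.at(acc.covw[junc], starts3[rr, kdl], -wf)


def _pair_marg_updates3_dj(acc, junc, anc_j, ends3, j_start, marg3, rcodes, cap):
    """Batched-register DJ-side analogue: marg3 (R, ndr, ndj),
    ends3 (R, ndr), j_start (ndj,)."""
    gap = j_start[None, None, :] - ends3[:, :, None]
    tiny = float(marg3.max()) * 1e-14
    use = (marg3 > tiny) & (gap >= 0) & (gap <= cap)
    if not use.any():
        return
    np.add.at(acc.ins[junc], gap[use], marg3[use])
    first = use & (gap >= 1)
    if first.any():
        rr, kdr, kdj = np.nonzero(first)
        wf = marg3[first]
        js = j_start[kdj]
        rb = np.minimum(rcodes[js - 1], 3)
        np.add.at(acc.trans5[junc], (anc_j[kdj], rb), wf)
        np.add.at(acc.covw[junc], ends3[rr, kdr], wf)
        np.add.at(acc.covw[junc], js - 1, -wf)


def chain_sum(
    geom: ReadGeometry,
    tables: ModelTables,
    want_marginals: bool = False,
    factors: "ReadFactors | None" = None,
):
    """Exact log P(read) by summing every scenario; optionally also the exact
    unnormalized posterior marginals of all events (returned as _Acc)."""
    fac = factors or ReadFactors(geom, tables)
    acc = _Acc(geom, tables.model) if want_marginals else None
    logz = NEG
    if not geom.v or not geom.j or (tables.chain == "VDJ" and not geom.d):
        return (logz, acc, fac)

    if tables.chain == "VJ":
        for iv, vg in enumerate(geom.v):
            av = fac.v[iv]["a"]
            for ij, jg in enumerate(geom.j):
                const = tables.lg_gene_vj[vg.gi, jg.gi]
                if const == NEG:
                    continue
                X = av[:, None] + fac.j[ij]["a"][None, :] + fac.pair_x(
                    vg, jg.edge, "vj"
                )
                sx = np.max(X)
                if sx == NEG:
                    continue
                eX = np.exp(X - sx)
                z = float(eX.sum())
                lt = np.log(z) + sx + const
                logz = np.logaddexp(logz, lt)
                if acc is not None:
                    scale = acc.rescale_to(sx + const)
                    m2 = eX * scale
                    acc.z += z * scale
                    acc.gene[iv, ij] += z * scale
                    acc.mv[iv] += m2.sum(1)
                    acc.mj[ij] += m2.sum(0)
                    _pair_marg_updates(
                        acc, "vj", vg.anc, vg.edge, jg.edge, m2,
                        fac.rcodes, tables.ins_cap["vj"],
                    )
        return (logz, acc, fac)

    # VDJ: batch the chain across all D registers at once.
    ds = fac.d_stack()
    if ds is None:
        return (logz, acc, fac)
    b3, d_start3, d_end3, gd = ds
    sb = np.max(b3)
    if sb == NEG:
        return (logz, acc, fac)
    eb3 = np.exp(b3 - sb)  # (R, ndl, ndr)
    xs = []
    for iv, vg in enumerate(geom.v):
        X3 = fac.v[iv]["a"][None, :, None] + fac.pair_x3(vg, d_start3, "vd")
        sx = np.max(X3)
        if sx == NEG:
            xs.append(None)
            continue
        eX3 = np.exp(X3 - sx)
        F1 = eX3.sum(axis=1)  # (R, ndl)
        F2 = np.einsum("rl,rlm->rm", F1, eb3)  # (R, ndr)
        xs.append((eX3, sx, F1, F2))
    for ij, jg in enumerate(geom.j):
        Y3 = fac.pair_y3(jg, d_end3, "dj") + fac.j[ij]["a"][None, None, :]
        sy = np.max(Y3)
        if sy == NEG:
            continue
        eY3 = np.exp(Y3 - sy)  # (R, ndr, ndj)
        B2 = eY3.sum(axis=2)  # (R, ndr)
        B1 = np.einsum("rlm,rm->rl", eb3, B2)  # (R, ndl)
        for iv, vg in enumerate(geom.v):
            if xs[iv] is None:
                continue
            eX3, sx, F1, F2 = xs[iv]
            cvec = tables.lg_gene_vdj[vg.gi, gd, jg.gi]  # (R,)
            sc = np.max(cvec)
            if sc == NEG:
                continue
            w_r = np.exp(cvec - sc)
            z_r = np.einsum("rl,rl->r", F1, B1) * w_r
            z = float(z_r.sum())
            if z <= 0.0:
                continue
            shift = sx + sb + sy + sc
            logz = np.logaddexp(logz, np.log(z) + shift)
            if acc is not None:
                # marginal mass below e^-30 of the accumulated total cannot
                # move any count beyond 1e-12: skip the expensive block
                if acc.z > 0 and np.log(z) + shift < np.log(acc.z) + acc.ref - 30.0:
                    continue
                scale = acc.rescale_to(shift)
                acc.z += z * scale
                acc.gene[iv, :, ij] += z_r * scale
                ws = (w_r * scale)[:, None, None]
                m_v_dl3 = eX3 * B1[:, None, :] * ws
                m_dl_dr3 = np.einsum("rl,rlm,rm->rlm", F1, eb3, B2) * ws
                m_dr_dj3 = F2[:, :, None] * eY3 * ws
                acc.mv[iv] += m_v_dl3.sum(axis=(0, 2))
                acc.md3 += m_dl_dr3
                acc.mj[ij] += m_dr_dj3.sum(axis=(0, 1))
                _pair_marg_updates3(
                    acc, "vd", vg.anc, vg.edge, d_start3, m_v_dl3,
                    fac.rcodes, tables.ins_cap["vd"],
                )
                _pair_marg_updates3_dj(
                    acc, "dj", jg.anc, d_end3, jg.edge, m_dr_dj3,
                    fac.rcodes, tables.ins_cap["dj"],
                )
    return (logz, acc, fac)


def accumulate_read(
    geom: ReadGeometry,
    tables: ModelTables,
    stats: SufficientStats,
    likelihood_floor: float = 1e-40,
) -> float:
    """E-step contribution of one read: exact posterior marginals normalized
    by P(read), added into ``stats``.  Returns log P(read) (NEG if failed)."""
    logz, acc, fac = chain_sum(geom, tables, want_marginals=True)
    stats.n_reads += 1
    floor = np.log(likelihood_floor) if likelihood_floor > 0 else -np.inf
    if not np.isfinite(logz) or logz < floor:
        stats.n_failed += 1
        return NEG
    z = acc.z
    stats.loglik += logz
    if stats.chain == "VJ":
        for iv, vg in enumerate(geom.v):
            for ij, jg in enumerate(geom.j):
                stats.gene[vg.gi, jg.gi] += acc.gene[iv, ij] / z
    else:
        gv = np.array([g.gi for g in geom.v])
        gd = np.array([g.gi for g in geom.d])
        gj = np.array([g.gi for g in geom.j])
        np.add.at(
            stats.gene,
            (gv[:, None, None], gd[None, :, None], gj[None, None, :]),
            acc.gene / z,
        )
    for vg, mv in zip(geom.v, acc.mv):
        np.add.at(stats.del_v[vg.gi], vg.didx, mv / z)
        stats.err_events += float(mv @ vg.err) / z
        stats.err_opportunities += float(mv @ (vg.cov - vg.nn)) / z
    for jg, mj in zip(geom.j, acc.mj):
        np.add.at(stats.del_j[jg.gi], jg.didx, mj / z)
        stats.err_events += float(mj @ jg.err) / z
        stats.err_opportunities += float(mj @ (jg.cov - jg.nn)) / z
    for k, dg in enumerate(geom.d):
        md = acc.md3[k]
        np.add.at(stats.del_d[dg.gi], (dg.dl_idx[:, None], dg.dr_idx[None, :]), md / z)
        stats.err_events += float(np.sum(md * dg.err)) / z
        stats.err_opportunities += float(np.sum(md * (dg.cov - dg.nn))) / z
    r = fac.rcodes
    for junc, covw in acc.covw.items():
        cum = np.cumsum(covw) / z
        if junc == "dj":
            u = np.nonzero(cum[: geom.n - 1] > 0)[0]
            if len(u):
                np.add.at(
                    stats.trans5[junc],
                    (np.minimum(r[u + 1], 3), np.minimum(r[u], 3)),
                    cum[u],
                )
        else:
            u = np.nonzero(cum[1 : geom.n] > 0)[0] + 1
            if len(u):
                np.add.at(
                    stats.trans5[junc],
                    (np.minimum(r[u - 1], 3), np.minimum(r[u], 3)),
                    cum[u],
                )
        stats.trans5[junc] += acc.trans5[junc] / z
        stats.ins[junc] += acc.ins[junc] / z
    if stats.collect_shm:
        _accumulate_shm(geom, tables, stats, acc, z)
    return logz


def _accumulate_shm(geom, tables, stats, acc, z):
    """Posterior-weighted (context, mutated?) counts per segment class."""
    m = stats.shm_m
    for side, margs, cls in (
        (geom.v, acc.mv, "V"),
        (geom.j, acc.mj, "J"),
    ):
        for g, mv in zip(side, margs):
            cg = g.ctx
            w = mv / z
            a = cg.a
            npos = cg.b - a
            covw = np.zeros(npos + 1)
            if cls == "V":
                # covered: [a, v_end)
                hi = np.clip(g.edge - a, 0, npos)
                for k in range(len(g.dvals)):
                    covw[0] += w[k]
                    covw[hi[k]] -= w[k]
            else:
                lo = np.clip(g.edge - a, 0, npos)
                for k in range(len(g.dvals)):
                    covw[lo[k]] += w[k]
                    covw[npos] -= w[k]
            cw = np.cumsum(covw)[:npos]
            _add_ctx_counts(stats.shm_counts[cls], cg.ctx, cg.mm, cg.is_n, cw)
            # boundary corrections: swap plain context for cut context
            for k in range(len(g.dvals)):
                if w[k] <= 0:
                    continue
                for c in range(1, m + 1):
                    p = (g.edge[k] - c) if cls == "V" else (g.edge[k] + c - 1)
                    if p < a or p >= cg.b:
                        continue
                    kk = p - a
                    if cg.is_n[kk]:
                        continue
                    cut = cg.cut_right if cls == "V" else cg.cut_left
                    col = 1 if cg.mm[kk] else 0
                    if cg.ctx[kk] >= 0:
                        stats.shm_counts[cls][cg.ctx[kk], col] -= w[k]
                    if cut[kk, c - 1] >= 0:
                        stats.shm_counts[cls][cut[kk, c - 1], col] += w[k]
    for g, md in zip(geom.d, acc.md3):
        cg = g.ctx
        a = cg.a
        npos = cg.b - a
        wl = md.sum(1) / z
        covw = np.zeros(npos + 1)
        lo = np.clip(g.d_start - a, 0, npos)
        hi_arr = np.clip(g.d_end - a, 0, npos)
        wr = md.sum(0) / z
        for k in range(len(g.d_start)):
            covw[lo[k]] += wl[k]
        for k in range(len(g.d_end)):
            covw[hi_arr[k]] -= wr[k]
        cw = np.cumsum(covw)[:npos]
        cw = np.maximum(cw, 0.0)
        _add_ctx_counts(stats.shm_counts["D"], cg.ctx, cg.mm, cg.is_n, cw)
        for k in range(len(g.d_start)):
            if wl[k] <= 0:
                continue
            for c in range(1, m + 1):
                p = g.d_start[k] + c - 1
                if p < a or p >= cg.b or cg.is_n[p - a]:
                    continue
                kk = p - a
                col = 1 if cg.mm[kk] else 0
                if cg.ctx[kk] >= 0:
                    stats.shm_counts["D"][cg.ctx[kk], col] -= wl[k]
                if cg.cut_left[kk, c - 1] >= 0:
                    stats.shm_counts["D"][cg.cut_left[kk, c - 1], col] += wl[k]
        for k in range(len(g.d_end)):
            if wr[k] <= 0:
                continue
            for c in range(1, m + 1):
                p = g.d_end[k] - c
                if p < a or p >= cg.b or cg.is_n[p - a]:
                    continue
                kk = p - a
                col = 1 if cg.mm[kk] else 0
                if cg.ctx[kk] >= 0:
                    stats.shm_counts["D"][cg.ctx[kk], col] -= wr[k]
                if cg.cut_right[kk, c - 1] >= 0:
                    stats.shm_counts["D"][cg.cut_right[kk, c - 1], col] += wr[k]


def _add_ctx_counts(counts, ctx, mm, is_n, weights):
    use = (ctx >= 0) & ~is_n & (weights > 0)
    if use.any():
        np.add.at(counts, (ctx[use], mm[use].astype(int)), weights[use])


# ---------------------------------------------------------------------------
# List mode: thresholded enumeration


@dataclass(frozen=True)
class RawScenario:
    """Engine-internal scenario record (indices into a ReadGeometry)."""

    iv: int
    idd: int  # -1 for VJ
    ij: int
    kv: int  # index into geom.v[iv].dvals
    kl: int
    kr: int
    kj: int
    logp: float
    log_perr: float


def enumerate_scenarios(
    geom: ReadGeometry,
    tables: ModelTables,
    prune_ratio: float = 1e-4,
    max_scenarios: int = 100_000,
):
    """All scenarios with probability >= prune_ratio x best, plus exact
    log P(read).  Returns (raw_list, log_pread, log_best)."""
    fac = ReadFactors(geom, tables)
    logz = NEG
    best = NEG
    cache = []
    if not geom.v or not geom.j or (tables.chain == "VDJ" and not geom.d):
        return ([], logz, best, fac)

    if tables.chain == "VJ":
        for iv, vg in enumerate(geom.v):
            for ij, jg in enumerate(geom.j):
                const = tables.lg_gene_vj[vg.gi, jg.gi]
                if const == NEG:
                    continue
                X = (
                    fac.v[iv]["a"][:, None]
                    + fac.j[ij]["a"][None, :]
                    + fac.pair_x(vg, jg.edge, "vj")
                    + const
                )
                mx = np.max(X)
                if mx == NEG:
                    continue
                eX = np.exp(X - mx)
                logz = np.logaddexp(logz, np.log(eX.sum()) + mx)
                best = max(best, mx)
                cache.append((iv, ij, X))
        tau = best + np.log(prune_ratio)
        out = []
        for iv, ij, X in cache:
            hits = np.argwhere(X >= tau)
            errv = fac.v[iv]["errfac"]
            errj = fac.j[ij]["errfac"]
            for kv, kj in hits:
                out.append(
                    RawScenario(
                        iv, -1, ij, int(kv), -1, -1, int(kj),
                        float(X[kv, kj]), float(errv[kv] + errj[kj]),
                    )
                )
        out.sort(key=lambda s: -s.logp)
        return (out[:max_scenarios], logz, best, fac)

    # VDJ pass 1: batched over D registers -- exact Z and per-triple maxima
    # via max-product messages.
    ds = fac.d_stack()
    if ds is None:
        return ([], logz, best, fac)
    b3, d_start3, d_end3, gd = ds
    sb = np.max(b3)
    if sb == NEG:
        return ([], logz, best, fac)
    eb3 = np.exp(b3 - sb)
    xcache = []
    for iv, vg in enumerate(geom.v):
        X3 = fac.v[iv]["a"][None, :, None] + fac.pair_x3(vg, d_start3, "vd")
        sx = np.max(X3)
        if sx == NEG:
            xcache.append(None)
            continue
        mX3 = np.max(X3, axis=1)
        xcache.append((X3, np.exp(X3 - sx).sum(axis=1), sx, mX3))
    ycache = []
    for ij, jg in enumerate(geom.j):
        Y3 = fac.pair_y3(jg, d_end3, "dj") + fac.j[ij]["a"][None, None, :]
        sy = np.max(Y3)
        if sy == NEG:
            ycache.append(None)
            continue
        eY3 = np.exp(Y3 - sy)
        B2 = eY3.sum(axis=2)
        B1 = np.einsum("rlm,rm->rl", eb3, B2)
        mY3 = np.max(Y3, axis=2)
        mB1 = np.max(b3 + mY3[:, None, :], axis=2)
        ycache.append((Y3, B1, sy, mB1))
    for iv in range(len(geom.v)):
        if xcache[iv] is None:
            continue
        X3, F1, sx, mX3 = xcache[iv]
        for ij in range(len(geom.j)):
            if ycache[ij] is None:
                continue
            Y3, B1, sy, mB1 = ycache[ij]
            cvec = tables.lg_gene_vdj[geom.v[iv].gi, gd, geom.j[ij].gi]  # (R,)
            sc = np.max(cvec)
            if sc == NEG:
                continue
            z_r = np.einsum("rl,rl->r", F1, B1) * np.exp(cvec - sc)
            z = float(z_r.sum())
            if z > 0:
                logz = np.logaddexp(logz, np.log(z) + sx + sb + sy + sc)
            cmax_r = np.max(mX3 + mB1, axis=1) + cvec
            best = max(best, float(np.max(cmax_r)))
            cache.append((iv, ij, cmax_r))
    tau = best + np.log(prune_ratio)
    out = []
    for iv, ij, cmax_r in cache:
        if len(out) > 4 * max_scenarios:
            break
        X3 = xcache[iv][0]
        Y3 = ycache[ij][0]
        for r in np.nonzero(cmax_r >= tau)[0]:
            dg = geom.d[r]
            jg = geom.j[ij]
            vg = geom.v[iv]
            idd = int(r)
            const = tables.lg_gene_vdj[vg.gi, dg.gi, jg.gi]
            logp4 = (
                const
                + X3[r][:, :, None, None]
                + b3[r][None, :, :, None]
                + Y3[r][None, None, :, :]
            )
            hits = np.argwhere(logp4 >= tau)
            if not len(hits):
                continue
            errv = fac.v[iv]["errfac"]
            errd = fac.d[idd]["errfac"]
            errj = fac.j[ij]["errfac"]
            for kv, kl, kr, kj in hits:
                out.append(
                    RawScenario(
                        iv, idd, ij, int(kv), int(kl), int(kr), int(kj),
                        float(logp4[kv, kl, kr, kj]),
                        float(errv[kv] + errd[kl, kr] + errj[kj]),
                    )
                )
    out.sort(key=lambda s: -s.logp)
    return (out[:max_scenarios], logz, best, fac)
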