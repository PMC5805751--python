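"""Context-dependent somatic hypermutation models.

The additive model scores the (2m+1)-mer context around a candidate site with
a position weight matrix and maps it to a mutation probability through a
logistic link:  P_mut / (1 - P_mut) = mu * exp(sum_i e_i(pi_i)).  The PWM is
kept in the zero-sum gauge (sum_sigma e_i(sigma) = 0 at every position), which
makes mu the geometric mean of the mutation odds over all contexts.  A
non-additive variant assigns one rate per n-mer, estimable only where coverage
suffices.  Spatial co-localization of posterior-called mutations is summarized
by the radial enrichment g(r).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from ._nt import all_context_digits, encode
from .errors import ConfigError

MIN_RATE = 1e-9


# ---------------------------------------------------------------------------
# Additive PWM model


@dataclass(frozen=True)
class PwmModel:
    """Additive log-odds PWM with overall rate scale ``mu``."""

    m: int
    e: np.ndarray  # (2m+1, 4)
    mu: float

    def __post_init__(self):
        e = np.asarray(self.e, dtype=float)
        if e.shape != (2 * self.m + 1, 4):
            raise ConfigError(f"PWM shape {e.shape} != {(2 * self.m + 1, 4)}")
        object.__setattr__(self, "e", e)
        if not self.mu > 0:
            raise ConfigError("mu must be > 0")

    @classmethod
    def null(cls, m: int = 3, mu: float = 1e-3) -> "PwmModel":
        return cls(m=m, e=np.zeros((2 * m + 1, 4)), mu=mu)

    def gauged(self) -> "PwmModel":
        """Equivalent model in the zero-sum gauge (normal form)."""
        means = self.e.mean(axis=1, keepdims=True)
        return PwmModel(
            m=self.m,
            e=self.e - means,
            mu=float(self.mu * np.exp(means.sum())),
        )

    def log_odds(self, digits: np.ndarray) -> np.ndarray:
        """Log odds for contexts given as digit arrays (n_ctx, 2m+1)."""
        w = 2 * self.m + 1
        return float(np.log(self.mu)) + self.e[np.arange(w)[None, :], digits].sum(1)

    def rate_table(self) -> np.ndarray:
        """P_mut for every possible context (4^(2m+1),)."""
        digits = all_context_digits(2 * self.m + 1)
        return expit(self.log_odds(digits))

    def rate_table_for(self, seg_class: str) -> np.ndarray:
        return self.rate_table()

    def fallback_rate(self) -> float:
        return float(self.mu / (1.0 + self.mu))


def mut_prob(context: str, pwm: PwmModel, n_policy: str = "fallback") -> float:
    """P_mut for one (2m+1)-mer context (center = candidate site)."""
    w = 2 * pwm.m + 1
    if len(context) != w:
        raise ConfigError(f"context length {len(context)} != {w}")
    codes = encode(context)
    if np.any(codes >= 4):
        if n_policy == "fallback":
            return pwm.fallback_rate()
        raise ConfigError(f"context contains non-ACGT base: {context}")
    x = pwm.mu * float(np.exp(pwm.e[np.arange(w), codes].sum()))
    return x / (1.0 + x)


def fit_pwm(
    weighted_context_counts: np.ndarray,
    init: PwmModel,
    max_iter: int = 2000,
    grad_tol: float = 1e-6,
    damping: float = 0.7,
) -> PwmModel:
    """Weighted Bernoulli maximum likelihood for (mu, e) by damped diagonal
    Newton ascent; the zero-sum gauge is re-imposed after every step.

    ``weighted_context_counts`` has shape (4^(2m+1), 2): column 0 = weighted
    unmutated observations, column 1 = weighted mutations.
    """
    m = init.m
    w = 2 * m + 1
    counts = np.asarray(weighted_context_counts, dtype=float)
    if counts.shape != (4**w, 2):
        raise ConfigError(f"counts shape {counts.shape} != {(4 ** w, 2)}")
    n_tot = counts.sum(axis=1)
    y = counts[:, 1]
    total = float(n_tot.sum())
    if float(y.sum()) <= 0.0:
        warnings.warn("no mutated contexts observed; returning floor-rate model")
        return PwmModel.null(m=m, mu=1e-6)
    seen = n_tot > 0
    digits = all_context_digits(w)
    # one-hot masks per (position, base) for gradient gathers
    onehot = [
        [(digits[:, i] == s) for s in range(4)] for i in range(w)
    ]
    n_pos_base = np.array(
        [[float(n_tot[oh].sum()) for oh in row] for row in onehot]
    )  # (w, 4)
    step_e = damping / (0.25 * n_pos_base + 1e-12)
    step_b = damping / (0.25 * total + 1e-12)

    model = init.gauged()
    b = float(np.log(model.mu))
    e = model.e.copy()
    for _ in range(max_iter):
        lo = b + e[np.arange(w)[None, :], digits].sum(1)
        p = expit(lo)
        resid = y - n_tot * p  # zero where unseen
        gb = float(resid.sum())
        ge = np.empty_like(e)
        for i in range(w):
            for s in range(4):
                ge[i, s] = float(resid[onehot[i][s]].sum())
        gnorm = max(abs(gb), float(np.max(np.abs(ge))))
        if gnorm / max(total, 1.0) < grad_tol:
            break
        b += step_b * gb
        e += step_e * ge
        # re-impose the gauge
        means = e.mean(axis=1, keepdims=True)
        e -= means
        b += float(means.sum())
    return PwmModel(m=m, e=e, mu=float(np.exp(b)))


# ---------------------------------------------------------------------------
# Non-additive n-mer table


@dataclass(frozen=True)
class NmerTable:
    """Per-n-mer mutation rates with estimability flags."""

    n: int
    rate: np.ndarray  # (4^n,)
    coverage: np.ndarray  # weighted observations per n-mer
    estimable: np.ndarray  # bool
    fallback: float  # rate used for inestimable contexts

    @property
    def m(self) -> int:
        return (self.n - 1) // 2

    def __len__(self) -> int:
        return 4**self.n

    def rate_table(self) -> np.ndarray:
        out = np.where(self.estimable, self.rate, self.fallback)
        return np.clip(out, MIN_RATE, 1.0 - MIN_RATE)

    def rate_table_for(self, seg_class: str) -> np.ndarray:
        return self.rate_table()

    def fallback_rate(self) -> float:
        return float(self.fallback)


def nmer_table_to_csv(table: "NmerTable", path) -> None:
    """Serialize an n-mer table as CSV: n-mer, rate, coverage, estimable."""
    from ._nt import NT, all_context_digits

    digits = all_context_digits(table.n)
    with open(path, "w") as fh:
        fh.write("nmer,rate,coverage,estimable\n")
        for k in range(4**table.n):
            nmer = "".join(NT[d] for d in digits[k])
            fh.write(
                f"{nmer},{float(table.rate[k])!r},{float(table.coverage[k])!r},"
                f"{int(table.estimable[k])}\n"
            )


def nmer_table_from_csv(path) -> "NmerTable":
    import pandas as pd

    df = pd.read_csv(path)
    n = len(df["nmer"].iloc[0])
    rate = df["rate"].to_numpy(dtype=float)
    cov = df["coverage"].to_numpy(dtype=float)
    est = df["estimable"].to_numpy(dtype=bool)
    tot = float(cov.sum())
    fallback = (
        float((rate * cov).sum() / tot) if tot > 0 else MIN_RATE
    )
    return NmerTable(
        n=n, rate=rate, coverage=cov, estimable=est,
        fallback=max(fallback, MIN_RATE),
    )


def fit_nmer(
    weighted_context_counts: np.ndarray, n: int, coverage_threshold: float = 100.0
) -> NmerTable:
    """Per-n-mer rate = weighted mutated / weighted total; n-mers below the
    coverage threshold are flagged inestimable."""
    if n % 2 != 1:
        raise ConfigError("n must be odd")
    counts = np.asarray(weighted_context_counts, dtype=float)
    if counts.shape != (4**n, 2):
        raise ConfigError(f"counts shape {counts.shape} != {(4 ** n, 2)}")
    cov = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(cov > 0, counts[:, 1] / np.maximum(cov, 1e-300), 0.0)
    estimable = cov >= coverage_threshold
    tot = float(cov.sum())
    fallback = float(counts[:, 1].sum() / tot) if tot > 0 else MIN_RATE
    return NmerTable(
        n=n, rate=rate, coverage=cov, estimable=estimable,
        fallback=max(fallback, MIN_RATE),
    )


# ---------------------------------------------------------------------------
# Per-segment-class model set


@dataclass(frozen=True)
class ShmModelSet:
    """Separate hypermutation models per segment class ('shared' mode simply
    points every class at the same model)."""

    v: PwmModel | NmerTable
    d: PwmModel | NmerTable | None = None
    j: PwmModel | NmerTable | None = None

    def __post_init__(self):
        for other in (self.d, self.j):
            if other is not None and other.m != self.v.m:
                raise ConfigError("all class models must share the same half-width m")

    @classmethod
    def shared(cls, model) -> "ShmModelSet":
        return cls(v=model, d=model, j=model)

    @property
    def m(self) -> int:
        return self.v.m

    def model_for(self, seg_class: str):
        got = {"V": self.v, "D": self.d, "J": self.j}[seg_class]
        return got if got is not None else self.v

    def rate_table_for(self, seg_class: str) -> np.ndarray:
        return self.model_for(seg_class).rate_table()

    def rate_table(self) -> np.ndarray:
        return self.v.rate_table()

    def fallback_rate(self) -> float:
        return self.v.fallback_rate()


# ---------------------------------------------------------------------------
# Posterior mutation statistics


def _segment_read_windows(scenario, model, read_len: int):
    """Read-coordinate windows and offsets of each retained segment.

    Returns {class: (offset, start, end, seg)} where ``offset`` is the read
    coordinate of the segment's seq[0].
    """
    es = model.event_space
    vseg = es.v_genes[es.gene_index("V")[scenario.v]]
    jseg = es.j_genes[es.gene_index("J")[scenario.j]]
    lj_ret = len(jseg.seq) - scenario.del_j
    j_start = read_len - lj_ret
    out = {}
    if model.chain_type == "VJ":
        v_end = j_start - len(scenario.ins_vj)
    else:
        dseg = es.d_genes[es.gene_index("D")[scenario.d]]
        ld_ret = len(dseg.seq) - scenario.del_d_left - scenario.del_d_right
        d_end = j_start - len(scenario.ins_dj)
        d_start = d_end - ld_ret
        v_end = d_start - len(scenario.ins_vd)
        out["D"] = (d_start - scenario.del_d_left, d_start, d_end, dseg)
    o_v = v_end - (len(vseg.seq) - scenario.del_v)
    out["V"] = (o_v, max(0, o_v), v_end, vseg)
    out["J"] = (j_start - scenario.del_j, j_start, read_len, jseg)
    return out


def posterior_mutation_profile(
    annotations: Sequence, gene: str, model, hm_model, min_coverage: float = 1.0
):
    """Observed (posterior-weighted) vs PWM-predicted mutation rate along one
    germline gene.  Returns (positions, observed, predicted, pearson_r)."""
    seg = None
    for cls in ("V", "D", "J"):
        genes = {
            "V": model.event_space.v_genes,
            "D": model.event_space.d_genes,
            "J": model.event_space.j_genes,
        }[cls]
        for g in genes:
            if g.name == gene:
                seg, seg_class = g, cls
    if seg is None:
        raise ConfigError(f"unknown gene {gene}")
    L = len(seg.seq)
    cov = np.zeros(L)
    mut = np.zeros(L)
    for res in annotations:
        if res.failed or res.p_read <= 0:
            continue
        for s in res.ranked_scenarios:
            name = {"V": s.v, "D": s.d, "J": s.j}[seg_class]
            if name != gene:
                continue
            w = s.p_scenario / res.p_read
            wins = _segment_read_windows(s, model, len(res.read))
            off, start, end, _ = wins[seg_class]
            g0, g1 = max(0, start - off), min(L, end - off)
            if g1 <= g0:
                continue
            cov[g0:g1] += w
            for p in s.mismatches:
                if start <= p < end and 0 <= p - off < L:
                    mut[p - off] += w
    keep = cov >= min_coverage
    positions = np.nonzero(keep)[0]
    if not len(positions):
        return positions, np.array([]), np.array([]), float("nan")
    observed = mut[keep] / cov[keep]
    cls_model = hm_model.model_for(seg_class) if isinstance(
        hm_model, ShmModelSet
    ) else hm_model
    mm = cls_model.m
    rates = cls_model.rate_table()
    fb = cls_model.fallback_rate()
    codes = encode(seg.seq)
    predicted = []
    for p in positions:
        if p - mm < 0 or p + mm >= L or np.any(codes[p - mm : p + mm + 1] >= 4):
            predicted.append(fb)
            continue
        idx = 0
        for c in codes[p - mm : p + mm + 1]:
            idx = idx * 4 + int(c)
        predicted.append(float(rates[idx]))
    predicted = np.asarray(predicted)
    if len(positions) > 1 and observed.std() > 0 and predicted.std() > 0:
        r = float(np.corrcoef(observed, predicted)[0, 1])
    else:
        r = float("nan")
    return positions, observed, predicted, r


@dataclass
class CoLocalizationResult:
    """Radial mutation-pair enrichment g(r) and its ingredients."""

    r: np.ndarray
    g: np.ndarray
    pair_counts: dict  # gene -> |C_V(r)| per r
    n_r: np.ndarray
    f1: dict  # gene -> per-position mutation frequency
    f2: dict  # gene -> dict r -> per-position pair frequency


def colocalization(
    annotations: Sequence,
    model,
    min_pair_count: float = 5.0,
    max_r: int = 25,
    seg_class: str = "V",
):
    """g(r) = (1/N_r) sum_{V,(i,j) in C_V(r)} f(i,j,V) / f(i,V) f(j,V), with
    posterior-weighted frequencies; pairs observed fewer than
    ``min_pair_count`` (weighted) times are excluded."""
    genes = {
        "V": model.event_space.v_genes,
        "D": model.event_space.d_genes,
        "J": model.event_space.j_genes,
    }[seg_class]
    acc = {
        g.name: {
            "cov": np.zeros(len(g.seq)),
            "mut": np.zeros(len(g.seq)),
            "cov2": np.zeros((max_r + 1, len(g.seq))),
            "mut2": np.zeros((max_r + 1, len(g.seq))),
        }
        for g in genes
    }
    for res in annotations:
        if res.failed or res.p_read <= 0:
            continue
        for s in res.ranked_scenarios:
            name = {"V": s.v, "D": s.d, "J": s.j}[seg_class]
            if name not in acc:
                continue
            a = acc[name]
            L = len(a["cov"])
            w = s.p_scenario / res.p_read
            wins = _segment_read_windows(s, model, len(res.read))
            off, start, end, _ = wins[seg_class]
            g0, g1 = max(0, start - off), min(L, end - off)
            if g1 <= g0:
                continue
            a["cov"][g0:g1] += w
            muts = sorted(
                p - off for p in s.mismatches if start <= p < end and 0 <= p - off < L
            )
            for i in muts:
                a["mut"][i] += w
            for r in range(1, max_r + 1):
                if g1 - g0 > r:
                    a["cov2"][r, g0 : g1 - r] += w
            for ki, i in enumerate(muts):
                for jj in muts[ki + 1 :]:
                    if jj - i <= max_r:
                        a["mut2"][jj - i, i] += w
    rs, gs, nrs = [], [], []
    pair_counts = {}
    f1 = {name: a["mut"] / np.maximum(a["cov"], 1e-300) for name, a in acc.items()}
    f2: dict = {name: {} for name in acc}
    for r in range(1, max_r + 1):
        total = 0.0
        n_pairs = 0
        pc = {}
        for name, a in acc.items():
            good = a["cov2"][r] >= min_pair_count
            idx = np.nonzero(good)[0]
            pc[name] = len(idx)
            if not len(idx):
                continue
            fij = a["mut2"][r, idx] / a["cov2"][r, idx]
            fi = f1[name][idx]
            fj = f1[name][idx + r]
            ok = (fi > 0) & (fj > 0)
            total += float(np.sum(fij[ok] / (fi[ok] * fj[ok])))
            n_pairs += int(ok.sum())
            f2[name][r] = fij
        if n_pairs:
            rs.append(r)
            gs.append(total / n_pairs)
            nrs.append(n_pairs)
            pair_counts[r] = pc
    return CoLocalizationResult(
        r=np.asarray(rs),
        g=np.asarray(gs),
        pair_counts=pair_counts,
        n_r=np.asarray(nrs),
        f1=f1,
        f2=f2,
    )
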