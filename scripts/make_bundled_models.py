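"""Regenerate the bundled germline sets and model files under src/repgen/data/.

The bundled fixtures are deterministic (fixed seeds) and committed as text:

* ``toy_vj`` / ``toy_vdj`` — miniature event spaces small enough for
  exhaustive-oracle tests and fast CLI smoke runs.
* ``trb_synth`` — a TRB-like VDJ model (8 V x 2 D x 6 J, D2 excluded from the
  J1 family, realistic insertion/deletion spreads) for 60-bp J-anchored reads.
* ``igh_synth`` — an IGH-like VDJ model (6 V x 3 D x 4 J, more insertions) for
  130-bp reads, with a 7-mer hypermutation PWM set (V/D/J).

Run from the repository root:  python scripts/make_bundled_models.py
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.stats import nbinom

from repgen.cli_io.model_file import write_model
from repgen.hypermutation import PwmModel, ShmModelSet
from repgen.recomb_model import GermlineSegment, build_model

DATA = Path(__file__).resolve().parent.parent / "src" / "repgen" / "data"
NT = "ACGT"


def rand_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(NT), n))


def make_v(rng, name: str, length: int, family: str = "") -> GermlineSegment:
    seq = list(rand_seq(rng, length))
    anchor = length - 9  # conserved Cys codon near the 3' end
    anchor -= anchor % 3
    seq[anchor : anchor + 3] = "TGT"
    return GermlineSegment(
        name=name, seg_class="V", seq="".join(seq), family=family, anchor=anchor
    )


def make_j(rng, name: str, length: int, family: str) -> GermlineSegment:
    seq = list(rand_seq(rng, length))
    anchor = 9  # conserved Phe codon
    seq[anchor : anchor + 3] = "TTT"
    return GermlineSegment(
        name=name, seg_class="J", seq="".join(seq), family=family, anchor=anchor
    )


def mutate_allele(rng, seg: GermlineSegment, name: str, frac: float = 0.08):
    """Derive a homologous allele: point-substitute ~frac of positions,
    keeping the conserved anchor codon intact."""
    seq = list(seg.seq)
    k = max(1, int(round(frac * len(seq))))
    protected = set()
    if seg.anchor is not None:
        protected = set(range(seg.anchor, seg.anchor + 3))
    sites = [i for i in range(len(seq)) if i not in protected]
    for i in rng.choice(sites, size=k, replace=False):
        seq[i] = NT[(NT.index(seq[i]) + 1 + int(rng.integers(3))) % 4]
    from dataclasses import replace as _replace

    return _replace(seg, name=name, seq="".join(seq))


def peaked(values: np.ndarray, mode: float, sigma: float, floor=1e-4) -> np.ndarray:
    x = np.exp(-0.5 * ((values - mode) / sigma) ** 2) + floor
    return x / x.sum()


def ins_dist(cap: int, mean: float, r: float = 1.6) -> np.ndarray:
    p = r / (r + mean)
    x = nbinom.pmf(np.arange(cap + 1), r, p) + 1e-6
    return x / x.sum()


def markov(rng, gc_bias: float = 0.25) -> dict[str, np.ndarray]:
    trans = rng.dirichlet(np.full(4, 4.0), size=4)
    trans[:, 1] += gc_bias / 2  # favour C/G insertions, as junctions do
    trans[:, 2] += gc_bias / 2
    trans /= trans.sum(axis=1, keepdims=True)
    init = rng.dirichlet(np.full(4, 6.0))
    return {"trans": trans, "init": init}


def decreasing_usage(n: int, decay: float) -> np.ndarray:
    x = decay ** np.arange(n)
    return x / x.sum()


def fill_realistic(model, rng, ins_mean: float, del_mode=(-0.5, 3.5)) -> None:
    es = model.event_space
    nv, nd, nj = len(es.v_genes), len(es.d_genes), len(es.j_genes)
    model.gene_v = decreasing_usage(nv, 0.82)
    dj = np.outer(decreasing_usage(nd, 0.7), decreasing_usage(nj, 0.85))
    if model.dj_mask is not None:
        dj[model.dj_mask] = 0.0
    model.gene_dj = dj / dj.sum()
    dv = es.del_values("del_v")
    model.del_v = np.stack(
        [peaked(dv, rng.uniform(*del_mode), rng.uniform(2.8, 4.2)) for _ in range(nv)]
    )
    djv = es.del_values("del_j")
    model.del_j = np.stack(
        [peaked(djv, rng.uniform(*del_mode), rng.uniform(2.8, 4.2)) for _ in range(nj)]
    )
    dl = es.del_values("del_d_l")
    dr = es.del_values("del_d_r")
    deld = []
    for d in es.d_genes:
        joint = np.outer(
            peaked(dl, rng.uniform(del_mode[0], 2.5), rng.uniform(2.4, 3.4)),
            peaked(dr, rng.uniform(del_mode[0], 2.5), rng.uniform(2.4, 3.4)),
        )
        joint[(dl[:, None] + dr[None, :]) > len(d.seq)] = 0.0
        deld.append(joint / joint.sum())
    model.del_d = np.stack(deld)
    cap_vd = es.ins_max("ins_vd")
    cap_dj = es.ins_max("ins_dj")
    model.ins["vd"] = ins_dist(cap_vd, ins_mean)
    model.ins["dj"] = ins_dist(cap_dj, ins_mean)
    model.markov["vd"] = markov(rng)
    model.markov["dj"] = markov(rng)
    model.validate()


def hotspot_pwm(rng, m: int, mu: float, strength: float) -> PwmModel:
    """WRC/WA-flavoured additive motif plus seeded noise, zero-sum gauged."""
    e = rng.normal(0.0, 0.25, size=(2 * m + 1, 4))
    # center: C strongly mutable, T cold
    e[m] += strength * np.array([0.3, 1.1, 0.1, -1.5])
    # 5' neighbours: W (A/T) hot, S (C/G) cold
    e[m - 1] += strength * np.array([0.6, -0.5, -0.6, 0.5])
    if m >= 2:
        e[m - 2] += strength * np.array([0.5, -0.4, 0.3, -0.4])
    # 3' neighbour: Y (C/T) mildly hot
    e[m + 1] += strength * np.array([-0.3, 0.4, -0.4, 0.3])
    return PwmModel(m=m, e=e, mu=mu).gauged()


def toy_models() -> None:
    rng = np.random.default_rng(11)
    v = [
        GermlineSegment(name="TVA", seg_class="V", seq="CATGGCGTACGTTAGC", anchor=6),
        GermlineSegment(name="TVB", seg_class="V", seq="CATGGCGGTATGCAAT", anchor=6),
    ]
    j = [
        GermlineSegment(name="TJA", seg_class="J", seq="TGTTTTCGGAGCAT", anchor=3, family="J1"),
        GermlineSegment(name="TJB", seg_class="J", seq="ACTTTTGGCAGCAT", anchor=3, family="J2"),
    ]
    cfg = dict(
        chain_type="VJ",
        max_palindrome=2,
        ranges={"del_v": (-2, 4), "del_j": (-2, 4), "ins_vj": (0, 4)},
        error_rate=1e-3,
    )
    model = build_model(cfg, {"V": v, "J": j})
    model.gene_vj = np.array([[0.4, 0.2], [0.25, 0.15]])
    model.del_v = np.stack([peaked(np.arange(-2, 5), 1.0, 1.5)] * 2)
    model.del_j = np.stack([peaked(np.arange(-2, 5), 1.0, 1.5)] * 2)
    model.ins["vj"] = ins_dist(4, 1.5)
    model.markov["vj"] = markov(rng)
    model.error_rate = 1e-3
    model.validate()
    write_model(model, DATA / "model_toy_vj.txt")
    write_germline(DATA / "germline_toy_vj.fasta", {"V": v, "J": j})

    v3 = [make_v(rng, f"TVD{i+1}", 30) for i in range(3)]
    d2 = [
        GermlineSegment(name="TDD1", seg_class="D", seq="GGGACAGGGGGC", family="D1"),
        GermlineSegment(name="TDD2", seg_class="D", seq="GGGACTAGCGGG", family="D2"),
    ]
    j3 = [
        make_j(rng, "TJD1", 18, "J1"),
        make_j(rng, "TJD2", 18, "J1"),
        make_j(rng, "TJD3", 18, "J2"),
    ]
    cfg = dict(
        chain_type="VDJ",
        max_palindrome=2,
        ranges={
            "del_v": (-2, 4),
            "del_j": (-2, 4),
            "del_d_l": (-2, 4),
            "del_d_r": (-2, 4),
            "ins_vd": (0, 4),
            "ins_dj": (0, 4),
        },
        forbidden_dj=[("D2", "J1")],
        error_rate=1e-3,
    )
    model = build_model(cfg, {"V": v3, "D": d2, "J": j3})
    rng2 = np.random.default_rng(12)
    fill_realistic(model, rng2, ins_mean=1.5)
    model.error_rate = 1e-3
    write_model(model, DATA / "model_toy_vdj.txt")
    write_germline(DATA / "germline_toy_vdj.fasta", {"V": v3, "D": d2, "J": j3})


def write_germline(path: Path, genes: dict) -> None:
    with open(path, "w") as fh:
        for cls, segs in genes.items():
            for g in segs:
                meta = f"class={cls}"
                if g.family:
                    meta += f" family={g.family}"
                if g.anchor is not None:
                    meta += f" anchor={g.anchor}"
                fh.write(f">{g.name} {meta}\n{g.seq}\n")


def trb_model() -> None:
    rng = np.random.default_rng(21)
    # 4 homologous families x 2 alleles
    v = []
    for fam in range(4):
        base = make_v(rng, f"TRBV{fam+1}-1", 70, family=f"V{fam+1}")
        v.append(base)
        v.append(mutate_allele(rng, base, f"TRBV{fam+1}-2"))
    d = [
        GermlineSegment(name="TRBD1", seg_class="D", seq="GGGACAGGGGGC", family="D1"),
        GermlineSegment(name="TRBD2", seg_class="D", seq="CCTAGTAGTTACCTCG", family="D2"),
    ]
    # homologous alleles within each J family
    j = []
    for fam in ("J1", "J2"):
        base = make_j(rng, f"TRB{fam}-1", 25, fam)
        j.append(base)
        j.append(mutate_allele(rng, base, f"TRB{fam}-2"))
        j.append(mutate_allele(rng, base, f"TRB{fam}-3"))
    cfg = dict(
        chain_type="VDJ",
        max_palindrome=4,
        ranges={
            "del_v": (-4, 14),
            "del_j": (-4, 14),
            "del_d_l": (-4, 10),
            "del_d_r": (-4, 10),
            "ins_vd": (0, 14),
            "ins_dj": (0, 14),
        },
        forbidden_dj=[("D2", "J1")],
        error_rate=5e-3,
    )
    model = build_model(cfg, {"V": v, "D": d, "J": j})
    fill_realistic(model, rng, ins_mean=5.5, del_mode=(-2.0, 2.0))
    model.error_rate = 5e-3
    write_model(model, DATA / "model_trb_synth.txt")
    write_germline(DATA / "germline_trb_synth.fasta", {"V": v, "D": d, "J": j})


def igh_model() -> None:
    rng = np.random.default_rng(31)
    # 2 homologous families x 3 close alleles
    v = []
    for fam in range(2):
        base = make_v(rng, f"IGHV{fam+1}-1", 100, family=f"V{fam+1}")
        v.append(base)
        v.append(mutate_allele(rng, base, f"IGHV{fam+1}-2", frac=0.03))
        v.append(mutate_allele(rng, base, f"IGHV{fam+1}-3", frac=0.03))
    d2 = GermlineSegment(
        name="IGHD2", seg_class="D", seq="AGGATATTGTAGTAGTAC", family="D2"
    )
    d = [
        GermlineSegment(name="IGHD1", seg_class="D", seq="GGTATAACTGGAACG", family="D1"),
        d2,
        # D3 is a homologous variant of D2 (overlapping D families, as in
        # real heavy-chain loci)
        mutate_allele(rng, d2, "IGHD3", frac=0.18),
    ]
    jbase = make_j(rng, "IGHJ1", 30, "J")
    j = [jbase, mutate_allele(rng, jbase, "IGHJ2")]
    jbase2 = make_j(rng, "IGHJ3", 30, "J")
    j += [jbase2, mutate_allele(rng, jbase2, "IGHJ4")]
    cfg = dict(
        chain_type="VDJ",
        max_palindrome=4,
        ranges={
            "del_v": (-4, 14),
            "del_j": (-4, 14),
            "del_d_l": (-4, 12),
            "del_d_r": (-4, 12),
            "ins_vd": (0, 20),
            "ins_dj": (0, 20),
        },
        error_rate=5e-3,
    )
    model = build_model(cfg, {"V": v, "D": d, "J": j})
    fill_realistic(model, rng, ins_mean=8.5, del_mode=(-2.0, 2.0))
    model.error_rate = 5e-3
    write_model(model, DATA / "model_igh_synth.txt")
    write_germline(DATA / "germline_igh_synth.fasta", {"V": v, "D": d, "J": j})
    shm = ShmModelSet(
        v=hotspot_pwm(rng, m=3, mu=0.020, strength=1.0),
        d=hotspot_pwm(rng, m=3, mu=0.024, strength=0.9),
        j=hotspot_pwm(rng, m=3, mu=0.017, strength=1.1),
    )
    write_model(model, DATA / "model_igh_shm.txt", hm_model=shm)


if __name__ == "__main__":
    DATA.mkdir(parents=True, exist_ok=True)
    toy_models()
    trb_model()
    igh_model()
    print(f"wrote fixtures to {DATA}")
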