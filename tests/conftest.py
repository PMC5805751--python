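import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from repgen.alignment import AlignParams
from repgen.recomb_model import GermlineSegment, build_model

NT = "ACGT"


def _rand_dist(rng, shape, floor=1e-3):
    a = rng.gamma(1.0, size=shape) + floor
    return a / a.sum(axis=-1, keepdims=True)


def randomize_cpts(model, rng):
    """Fill a model with random (normalized) CPTs, respecting masks."""
    es = model.event_space
    nv, nj = len(es.v_genes), len(es.j_genes)
    if model.chain_type == "VJ":
        g = rng.gamma(1.0, size=(nv, nj)) + 1e-3
        model.gene_vj = g / g.sum()
        model.ins["vj"] = _rand_dist(rng, es.ins_max("ins_vj") + 1)
        model.markov["vj"] = {
            "trans": _rand_dist(rng, (4, 4)),
            "init": _rand_dist(rng, 4),
        }
    else:
        nd = len(es.d_genes)
        model.gene_v = _rand_dist(rng, nv)
        g = rng.gamma(1.0, size=(nd, nj)) + 1e-3
        if model.dj_mask is not None:
            g[model.dj_mask] = 0.0
        model.gene_dj = g / g.sum()
        dl = es.del_values("del_d_l")
        dr = es.del_values("del_d_r")
        dd = rng.gamma(1.0, size=(nd, len(dl), len(dr))) + 1e-3
        for i, seg in enumerate(es.d_genes):
            dd[i][(dl[:, None] + dr[None, :]) > len(seg.seq)] = 0.0
            dd[i] /= dd[i].sum()
        model.del_d = dd
        model.ins["vd"] = _rand_dist(rng, es.ins_max("ins_vd") + 1)
        model.ins["dj"] = _rand_dist(rng, es.ins_max("ins_dj") + 1)
        for junc in ("vd", "dj"):
            model.markov[junc] = {
                "trans": _rand_dist(rng, (4, 4)),
                "init": _rand_dist(rng, 4),
            }
    model.del_v = _rand_dist(rng, (nv, es.n_del("del_v")))
    model.del_j = _rand_dist(rng, (nj, es.n_del("del_j")))
    model.validate()
    return model


def rand_seq(rng, n):
    return "".join(rng.choice(list(NT), n))


@pytest.fixture(scope="session")
def toy_vj_model():
    """Tiny VJ model with random CPTs, small enough for full enumeration."""
    rng = np.random.default_rng(101)
    v = [
        GermlineSegment(name=f"V{i}", seg_class="V", seq=rand_seq(rng, 12), anchor=0)
        for i in range(2)
    ]
    j = [
        GermlineSegment(name=f"J{i}", seg_class="J", seq=rand_seq(rng, 10), anchor=2)
        for i in range(2)
    ]
    cfg = dict(
        chain_type="VJ",
        max_palindrome=1,
        ranges={"del_v": (-1, 2), "del_j": (-1, 2), "ins_vj": (0, 3)},
    )
    model = build_model(cfg, {"V": v, "J": j})
    randomize_cpts(model, rng)
    model.error_rate = 0.01
    return model


@pytest.fixture(scope="session")
def toy_vdj_model():
    """Tiny VDJ model (with a forbidden D-J family pair), fully enumerable."""
    rng = np.random.default_rng(202)
    v = [
        GermlineSegment(name=f"V{i}", seg_class="V", seq=rand_seq(rng, 14), anchor=0)
        for i in range(2)
    ]
    d = [
        GermlineSegment(
            name=f"D{i}", seg_class="D", seq=rand_seq(rng, 6), family=f"D{i + 1}"
        )
        for i in range(2)
    ]
    j = [
        GermlineSegment(
            name=f"J{i}",
            seg_class="J",
            seq=rand_seq(rng, 10),
            anchor=2,
            family=["J1", "J2"][i],
        )
        for i in range(2)
    ]
    cfg = dict(
        chain_type="VDJ",
        max_palindrome=1,
        ranges={
            "del_v": (-1, 1),
            "del_j": (-1, 1),
            "del_d_l": (-1, 1),
            "del_d_r": (-1, 1),
            "ins_vd": (0, 2),
            "ins_dj": (0, 2),
        },
        forbidden_dj=[("D2", "J1")],
    )
    model = build_model(cfg, {"V": v, "D": d, "J": j})
    randomize_cpts(model, rng)
    model.error_rate = 0.02
    return model


@pytest.fixture
def exhaustive_align_params():
    """Alignment settings that keep every gene and register (oracle mode)."""
    return AlignParams(
        anchor="both",
        thresholds={"V": -1e9, "D": -1e9, "J": -1e9},
        max_placements=1000,
        d_fallback_step=1,
        max_v_genes=100,
    )
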