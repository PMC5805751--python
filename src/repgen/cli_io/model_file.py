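"""Human-readable model file: @structure / @cpt / @error / @shm sections.

The file is self-contained (germline segments are embedded as ``gene`` lines)
and round-trips bit-exactly: floats are serialized with ``repr``, so
``write(load(f)) == write(load(write(load(f))))``.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np

from ..errors import ConfigError, InputError, ModelValidationError
from ..hypermutation import PwmModel, ShmModelSet
from ..recomb_model import (
    EventSpace,
    GermlineSegment,
    RecombModel,
    extend_palindrome,
)

FILE_TOL = 1e-6

_RANGE_KEYS = ("del_v", "del_j", "del_d_l", "del_d_r", "ins_vj", "ins_vd", "ins_dj")


def _fmt(x: float) -> str:
    return repr(float(x))


def write_model(model: RecombModel, path=None, hm_model=None) -> str:
    """Serialize a model (and optional PWM hypermutation model) to text."""
    es = model.event_space
    out = io.StringIO()
    w = out.write
    w("# repgen recombination model\n@structure\n")
    w(f"chain_type {es.chain_type}\n")
    w(f"factorized {'true' if model.factorized else 'false'}\n")
    max_p = max((g.max_p for g in es.v_genes + es.d_genes + es.j_genes), default=0)
    w(f"max_palindrome {max_p}\n")
    w(f"dj_markov_direction {model.dj_markov_direction}\n")
    for key in _RANGE_KEYS:
        if key in es.ranges:
            lo, hi = es.ranges[key]
            w(f"range {key} {lo} {hi}\n")
    for dfam, jfam in model.forbidden_dj:
        w(f"forbid_dj {dfam}:{jfam}\n")
    for cls, genes in (("V", es.v_genes), ("D", es.d_genes), ("J", es.j_genes)):
        for g in genes:
            anchor = "-" if g.anchor is None else str(g.anchor)
            family = g.family or "-"
            rev = "1" if g.is_reverse_complement else "0"
            w(f"gene {cls} {g.name} {family} {anchor} {rev} {g.seq}\n")

    def table(name: str, labels, arr: np.ndarray):
        w(f"@cpt {name}\n")
        arr = np.atleast_2d(arr)
        for lab, row in zip(labels, arr):
            w(lab + " " + " ".join(_fmt(x) for x in np.ravel(row)) + "\n")

    vnames = [g.name for g in es.v_genes]
    jnames = [g.name for g in es.j_genes]
    if es.chain_type == "VJ":
        table("gene_vj", vnames, model.gene_vj)
        table("ins_vj", ["len"], model.ins["vj"][None, :])
        _write_markov(w, "vj", model)
    else:
        dnames = [g.name for g in es.d_genes]
        if model.factorized:
            table("gene_v", ["p"], model.gene_v[None, :])
            table("gene_dj", dnames, model.gene_dj)
        else:
            table("gene_vdj", vnames, model.gene_vdj.reshape(len(vnames), -1))
        for di, name in enumerate(dnames):
            dl_labels = [str(v) for v in es.del_values("del_d_l")]
            table(f"del_d {name}", dl_labels, model.del_d[di])
        table("ins_vd", ["len"], model.ins["vd"][None, :])
        table("ins_dj", ["len"], model.ins["dj"][None, :])
        _write_markov(w, "vd", model)
        _write_markov(w, "dj", model)
    table("del_v", vnames, model.del_v)
    table("del_j", jnames, model.del_j)
    w("@error\n")
    w(f"rate {_fmt(model.error_rate)}\n")
    if hm_model is not None:
        _write_shm(w, hm_model)
    text = out.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def _write_markov(w, junc: str, model: RecombModel):
    w(f"@cpt markov_{junc}\n")
    mk = model.markov[junc]
    for lab, row in zip("ACGT", mk["trans"]):
        w(lab + " " + " ".join(_fmt(x) for x in row) + "\n")
    w("init " + " ".join(_fmt(x) for x in mk["init"]) + "\n")


def _write_shm(w, hm):
    w("@shm\n")
    if isinstance(hm, PwmModel):
        hm = ShmModelSet.shared(hm)
    if not isinstance(hm, ShmModelSet):
        raise ConfigError("only PWM hypermutation models serialize to model files")
    w(f"m {hm.m}\n")
    for cls in "VDJ":
        sub = {"V": hm.v, "D": hm.d, "J": hm.j}[cls.upper()]
        if sub is None:
            continue
        if not isinstance(sub, PwmModel):
            raise ConfigError("n-mer tables are serialized separately as CSV")
        w(f"class {cls}\n")
        w(f"mu {_fmt(sub.mu)}\n")
        for i, row in zip(range(-sub.m, sub.m + 1), sub.e):
            w(f"e {i} " + " ".join(_fmt(x) for x in row) + "\n")


def load_model(path_or_text) -> tuple[RecombModel, ShmModelSet | None]:
    """Parse a model file; validates normalization (tolerance 1e-6)."""
    text = (
        path_or_text
        if isinstance(path_or_text, str) and "\n" in path_or_text
        else Path(path_or_text).read_text()
    )
    sections: list[tuple[str, list[str]]] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("@"):
            sections.append((line[1:].strip(), []))
        else:
            if not sections:
                raise InputError(f"line {lineno}: content before any @section")
            sections[-1][1].append(line)

    structure = None
    cpts: dict[str, list[str]] = {}
    error_lines: list[str] = []
    shm_lines: list[str] = []
    for header, lines in sections:
        if header == "structure":
            structure = lines
        elif header.startswith("cpt"):
            cpts[header[3:].strip()] = lines
        elif header == "error":
            error_lines = lines
        elif header == "shm":
            shm_lines = lines
        else:
            raise InputError(f"unknown section @{header}")
    if structure is None:
        raise InputError("missing @structure section")

    cfg: dict = {"ranges": {}, "forbidden_dj": []}
    genes: dict[str, list[GermlineSegment]] = {"V": [], "D": [], "J": []}
    for line in structure:
        tok = line.split()
        key = tok[0]
        if key == "range":
            cfg["ranges"][tok[1]] = (int(tok[2]), int(tok[3]))
        elif key == "forbid_dj":
            dfam, jfam = tok[1].split(":")
            cfg["forbidden_dj"].append((dfam, jfam))
        elif key == "gene":
            cls, name, family, anchor, rev, seq = tok[1:7]
            genes[cls].append(
                GermlineSegment(
                    name=name,
                    seg_class=cls,
                    seq=seq,
                    family="" if family == "-" else family,
                    anchor=None if anchor == "-" else int(anchor),
                    is_reverse_complement=rev == "1",
                )
            )
        elif key in ("chain_type", "dj_markov_direction"):
            cfg[key] = tok[1]
        elif key == "factorized":
            cfg[key] = tok[1] == "true"
        elif key == "max_palindrome":
            cfg[key] = int(tok[1])
        else:
            raise InputError(f"unknown @structure key {key!r}")

    max_p = cfg.get("max_palindrome", 4)
    for cls in genes:
        genes[cls] = [extend_palindrome(g, max_p) for g in genes[cls]]
    es = EventSpace(
        chain_type=cfg["chain_type"],
        v_genes=tuple(genes["V"]),
        d_genes=tuple(genes["D"]),
        j_genes=tuple(genes["J"]),
        ranges=cfg["ranges"],
    )
    model = RecombModel.uniform(
        es,
        factorized=cfg.get("factorized", True),
        forbidden_dj=tuple(cfg["forbidden_dj"]),
        dj_markov_direction=cfg.get("dj_markov_direction", "3to5"),
    )

    def parse_rows(lines: list[str]) -> dict[str, np.ndarray]:
        return {
            t[0]: np.array([float(x) for x in t[1:]])
            for t in (line.split() for line in lines)
        }

    def fill(name: str, labels, target_shape) -> np.ndarray:
        if name not in cpts:
            raise InputError(f"missing @cpt {name}")
        rows = parse_rows(cpts[name])
        arr = np.empty(target_shape)
        flat = arr.reshape(len(labels), -1)
        for k, lab in enumerate(labels):
            if lab not in rows:
                raise InputError(f"@cpt {name}: missing row {lab!r}")
            if len(rows[lab]) != flat.shape[1]:
                raise InputError(f"@cpt {name}: row {lab!r} has wrong width")
            flat[k] = rows[lab]
        return arr

    vnames = [g.name for g in es.v_genes]
    jnames = [g.name for g in es.j_genes]
    if es.chain_type == "VJ":
        model.gene_vj = fill("gene_vj", vnames, (len(vnames), len(jnames)))
        model.ins["vj"] = fill("ins_vj", ["len"], (1, es.ins_max("ins_vj") + 1))[0]
        model.markov["vj"] = _read_markov(cpts, "vj")
    else:
        dnames = [g.name for g in es.d_genes]
        if model.factorized:
            model.gene_v = fill("gene_v", ["p"], (1, len(vnames)))[0]
            model.gene_dj = fill("gene_dj", dnames, (len(dnames), len(jnames)))
        else:
            model.gene_vdj = fill(
                "gene_vdj", vnames, (len(vnames), len(dnames), len(jnames))
            )
        ndl, ndr = es.n_del("del_d_l"), es.n_del("del_d_r")
        dl_labels = [str(v) for v in es.del_values("del_d_l")]
        model.del_d = np.stack(
            [fill(f"del_d {name}", dl_labels, (ndl, ndr)) for name in dnames]
        )
        model.ins["vd"] = fill("ins_vd", ["len"], (1, es.ins_max("ins_vd") + 1))[0]
        model.ins["dj"] = fill("ins_dj", ["len"], (1, es.ins_max("ins_dj") + 1))[0]
        model.markov["vd"] = _read_markov(cpts, "vd")
        model.markov["dj"] = _read_markov(cpts, "dj")
    model.del_v = fill("del_v", vnames, (len(vnames), es.n_del("del_v")))
    model.del_j = fill("del_j", jnames, (len(jnames), es.n_del("del_j")))
    for line in error_lines:
        tok = line.split()
        if tok[0] == "rate":
            model.error_rate = float(tok[1])
    try:
        model.validate(tol=FILE_TOL)
    except ModelValidationError as exc:
        raise ModelValidationError(f"model file failed validation: {exc}") from exc
    hm = _read_shm(shm_lines) if shm_lines else None
    return model, hm


def _read_markov(cpts, junc: str):
    rows = {
        t[0]: np.array([float(x) for x in t[1:]])
        for t in (line.split() for line in cpts[f"markov_{junc}"])
    }
    trans = np.stack([rows[c] for c in "ACGT"])
    return {"trans": trans, "init": rows["init"]}


def _read_shm(lines: list[str]) -> ShmModelSet:
    m = None
    per: dict[str, dict] = {}
    cur = None
    for line in lines:
        tok = line.split()
        if tok[0] == "m":
            m = int(tok[1])
        elif tok[0] == "class":
            cur = tok[1]
            per[cur] = {"e": {}}
        elif tok[0] == "mu":
            per[cur]["mu"] = float(tok[1])
        elif tok[0] == "e":
            per[cur]["e"][int(tok[1])] = [float(x) for x in tok[2:]]
        else:
            raise InputError(f"unknown @shm key {tok[0]!r}")
    if m is None or not per:
        raise InputError("incomplete @shm section")

    def build(d):
        e = np.array([d["e"][i] for i in range(-m, m + 1)])
        return PwmModel(m=m, e=e, mu=d["mu"])

    return ShmModelSet(
        v=build(per["V"]),
        d=build(per["D"]) if "D" in per else None,
        j=build(per["J"]) if "J" in per else None,
    )


def model_roundtrip(path) -> tuple[RecombModel, ShmModelSet | None]:
    """Load and validate a model file (read -> write -> read is the identity)."""
    return load_model(path)
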