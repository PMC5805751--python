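"""Sequence file I/O (FASTA/FASTQ, plain or gzipped) via Biopython."""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path

from Bio import SeqIO

from ..errors import InputError
from ..recomb_model import GermlineSegment


def _open(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path: Path) -> str:
    name = str(path).removesuffix(".gz")
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    if name.endswith((".fa", ".fasta", ".fna")):
        return "fasta"
    with _open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return "fastq"
    if first == ">":
        return "fasta"
    raise InputError(f"{path}: cannot determine sequence format")


def read_sequences(path) -> list[tuple[str, str]]:
    """(id, sequence) records; ids deduplicated with suffixes, sequences
    uppercased with U->T."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    fmt = _sniff_format(path)
    out: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    with _open(path) as fh:
        try:
            for k, rec in enumerate(SeqIO.parse(fh, fmt)):
                rid = rec.id or f"seq{k}"
                if rid in seen:
                    seen[rid] += 1
                    new = f"{rid}.{seen[rid]}"
                    warnings.warn(f"duplicate id {rid!r} renamed to {new!r}")
                    rid = new
                else:
                    seen[rid] = 0
                seq = str(rec.seq).upper().replace("U", "T")
                if not seq:
                    raise InputError(f"record {rid!r} (number {k + 1}) is empty")
                out.append((rid, seq))
        except ValueError as exc:
            raise InputError(
                f"{path}: malformed record after {len(out)} good record(s): {exc}"
            ) from exc
    return out


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def read_germline(path) -> dict[str, list[GermlineSegment]]:
    """Germline FASTA with metadata tokens in the description:
    ``>name class=V family=V1 anchor=30``."""
    path = Path(path)
    out: dict[str, list[GermlineSegment]] = {"V": [], "D": [], "J": []}
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            meta = {}
            for tok in rec.description.split()[1:]:
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            cls = meta.get("class")
            if cls not in out:
                raise InputError(
                    f"germline record {rec.id!r} lacks a class=V|D|J token"
                )
            out[cls].append(
                GermlineSegment(
                    name=rec.id,
                    seg_class=cls,
                    seq=str(rec.seq).upper().replace("U", "T"),
                    family=meta.get("family", ""),
                    anchor=int(meta["anchor"]) if "anchor" in meta else None,
                )
            )
    if not out["V"] and not out["J"]:
        raise InputError(f"{path}: no germline records found")
    return out
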