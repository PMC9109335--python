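"""File formats and rendering: FASTA inputs, NCBI substitution matrices,
text/JSON/TSV output of bi-alignments.

Sequences and structure annotation strings are both read as FASTA records
(two records per file, paired by order); the structure file carries one
annotation symbol per residue.  Substitution matrices use the NCBI
whitespace-delimited format; the standard BLOSUM62 matrix ships with the
package and is the default.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import NamedTuple

from Bio import SeqIO
from Bio.Align import substitution_matrices

from .core import (
    ALL_GAP,
    BiAlignment,
    DELETION,
    INSERTION,
    InputError,
    LengthMismatchError,
    MatrixFormatError,
    RecordCountError,
    ScoringConfig,
    SubstitutionTable,
    UnknownSymbolError,
    decompose,
)
from .engine import EngineResult

__all__ = [
    "InputBundle",
    "read_inputs",
    "read_matrix",
    "write_matrix",
    "render_text",
    "result_to_dict",
    "result_to_json",
    "result_to_tsv",
]

_DEFAULT_MATRIX = "BLOSUM62"


class InputBundle(NamedTuple):
    """Validated inputs: two (id, sequence, structure) triples."""

    ids: tuple[str, str]
    seq_a: str
    seq_b: str
    str_a: str
    str_b: str


def _two_records(path, what: str) -> list:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise RecordCountError(
            f"{what} file {path} must contain exactly two FASTA records, "
            f"found {len(records)}"
        )
    return records


def read_inputs(
    seq_path, struct_path, matrix: SubstitutionTable | None = None
) -> InputBundle:
    """Read and validate the two sequences and their structure strings.

    Both files must hold exactly two FASTA records; records pair by order
    and each structure string must match its sequence's length.  When a
    ``matrix`` is given, residues are checked against its alphabet.
    """
    seqs = _two_records(seq_path, "sequence")
    structs = _two_records(struct_path, "structure")
    out_seqs, out_structs = [], []
    for rec, srec in zip(seqs, structs):
        seq = str(rec.seq).upper()
        struct = str(srec.seq).upper()
        if len(seq) != len(struct):
            raise LengthMismatchError(
                f"structure string for record {rec.id!r} has length "
                f"{len(struct)}, sequence has length {len(seq)}"
            )
        out_seqs.append(seq)
        out_structs.append(struct)
    if matrix is not None:
        unknown = sorted(set("".join(out_seqs)) - set(matrix.alphabet))
        if unknown:
            raise UnknownSymbolError(
                f"residue symbol(s) {unknown!r} not covered by matrix "
                f"{matrix.name or '<anonymous>'}"
            )
    return InputBundle(
        (seqs[0].id, seqs[1].id), out_seqs[0], out_seqs[1], out_structs[0], out_structs[1]
    )


def read_matrix(path=None) -> SubstitutionTable:
    """Read an NCBI-format substitution matrix; packaged BLOSUM62 by default."""
    if path is None:
        ref = resources.files("bialignment").joinpath("data", _DEFAULT_MATRIX)
        with resources.as_file(ref) as p:
            return read_matrix(p)
    try:
        arr = substitution_matrices.read(str(path))
    except Exception as exc:
        raise MatrixFormatError(f"cannot parse substitution matrix {path}: {exc}") from exc
    alphabet = tuple(arr.alphabet)
    scores = {
        (a, b): float(arr[a, b]) for a in alphabet for b in alphabet
    }
    import os

    return SubstitutionTable(scores, alphabet, name=os.path.basename(str(path)))


def write_matrix(table: SubstitutionTable, path) -> None:
    """Write a substitution table in NCBI format (round-trips with
    :func:`read_matrix`)."""
    width = max(
        4, *(len(f"{table.scores[(a, b)]:g}") + 1 for a in table.alphabet for b in table.alphabet)
    )
    with open(path, "w") as fh:
        fh.write(" " + "".join(f"{s:>{width}}" for s in table.alphabet) + "\n")
        for a in table.alphabet:
            row = "".join(f"{table.scores[(a, b)]:>{width}g}" for b in table.alphabet)
            fh.write(f"{a}{row}\n")


_SHIFT_MARK = {DELETION: "<", INSERTION: ">"}


def _shift_line(ba: BiAlignment, pair: str) -> str:
    """Per-column shift annotation for one object: '<' marks columns where
    the structure trails its sequence, '>' where it runs ahead."""
    sel = {"aa": lambda col: col.p13, "bb": lambda col: col.p24}[pair]
    return "".join(_SHIFT_MARK.get(sel(col), " ") for col in ba.columns)


def render_text(ba: BiAlignment, wrap: int = 60, ids: tuple[str, str] = ("a", "b")) -> str:
    """Human-readable block rendering of a bi-alignment.

    Rows per block: shift marks of a, structure of a, sequence of a,
    sequence of b, structure of b, shift marks of b; blocks wrap at
    ``wrap`` columns (0 disables wrapping).
    """
    seq_a_row, seq_b_row, str_a_row, str_b_row = ba.rows()
    lines = [
        (f"shifts {ids[0]}", _shift_line(ba, "aa")),
        (f"struct {ids[0]}", str_a_row),
        (f"seq    {ids[0]}", seq_a_row),
        (f"seq    {ids[1]}", seq_b_row),
        (f"struct {ids[1]}", str_b_row),
        (f"shifts {ids[1]}", _shift_line(ba, "bb")),
    ]
    gutter = max(len(label) for label, _ in lines) + 2
    total = len(ba.columns)
    step = wrap if wrap and wrap > 0 else max(total, 1)
    blocks = []
    for start in range(0, max(total, 1), step):
        chunk = [
            f"{label:<{gutter}}{row[start:start + step]}" for label, row in lines
        ]
        blocks.append("\n".join(chunk))
    return "\n\n".join(blocks) + "\n"


def result_to_dict(result: EngineResult, cfg: ScoringConfig) -> dict:
    """Machine-readable summary: score, decomposition, rows, column codes."""
    ba = result.alignment
    seq_a_row, seq_b_row, str_a_row, str_b_row = ba.rows()
    parts = decompose(ba, cfg)
    return {
        "mode": result.mode,
        "lambda": result.lam,
        "score": result.score,
        "shift_count": ba.shift_count,
        "decomposition": {
            "u": parts["u"],
            "v": parts["v"],
            "shift": parts["shift"],
        },
        "rows": {
            "seq_a": seq_a_row,
            "seq_b": seq_b_row,
            "struct_a": str_a_row,
            "struct_b": str_b_row,
        },
        "columns": [col.code() for col in ba.columns],
        "stats": {
            "states": result.n_states,
            "column_types": result.n_column_types,
            "cells_filled": result.cells_filled,
        },
    }


def result_to_json(result: EngineResult, cfg: ScoringConfig) -> str:
    return json.dumps(result_to_dict(result, cfg), indent=2)


def result_to_tsv(result: EngineResult, cfg: ScoringConfig) -> str:
    """Flat key<TAB>value dialect of :func:`result_to_dict`."""
    d = result_to_dict(result, cfg)
    lines = []

    def emit(prefix: str, value) -> None:
        if isinstance(value, dict):
            for k, v in value.items():
                emit(f"{prefix}.{k}" if prefix else k, v)
        elif isinstance(value, list):
            lines.append(f"{prefix}\t{','.join(map(str, value))}")
        else:
            lines.append(f"{prefix}\t{value}")

    emit("", d)
    return "\n".join(lines) + "\n"
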