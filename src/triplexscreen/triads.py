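"""Hoogsteen/reverse-Hoogsteen triad stability table.

A triad is a third-strand RNA base hydrogen-bonded to a Watson-Crick duplex
pair.  The table maps ``(rna_base, duplex_base, orientation)`` to an integer
stability weight in {0, 1, 2}: 2 for canonical triads, 1 for documented weak
triads, 0 otherwise.  ``duplex_base`` is the base of the duplex strand the
RNA is scanned against (its Watson-Crick partner is implied), written first
in the conventional pair notation, e.g. the weight of the canonical parallel
T-A:T triad is looked up as ``("U", "A", "parallel")``.

Orientation is the direction of the third strand relative to the scanned
duplex strand: "parallel" (pyrimidine motif) or "antiparallel" (purine
motif).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

RNA_BASES = ("A", "C", "G", "U")
DNA_BASES = ("A", "C", "G", "T")
ORIENTATIONS = ("parallel", "antiparallel")

#: index used by the numeric scan kernels: A=0, C=1, G=2, T/U=3
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# Canonical (weight 2) and documented weak (weight 1) triads.
_DEFAULT_WEIGHTS: dict[tuple[str, str, str], int] = {
    # pyrimidine motif: third strand parallel to the purine strand
    ("U", "A", "parallel"): 2,  # T-A:T / U-A:T
    ("C", "G", "parallel"): 2,  # C+-G:C
    ("G", "G", "parallel"): 1,
    ("G", "T", "parallel"): 1,  # G-T:A
    # purine motif: third strand antiparallel to the purine strand
    ("A", "A", "antiparallel"): 2,  # A-A:T
    ("G", "G", "antiparallel"): 2,  # G-G:C
    ("U", "A", "antiparallel"): 2,  # U-A:T (mixed motif)
    ("C", "A", "antiparallel"): 1,
}


def _normalise_rna(base: str) -> str:
    base = base.upper()
    return "U" if base == "T" else base


def _normalise_dna(base: str) -> str:
    base = base.upper()
    return "T" if base == "U" else base


@dataclass(frozen=True)
class TriadTable:
    """Complete triad weight mapping; every (rna, duplex, orientation) key present."""

    weights: dict[tuple[str, str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full: dict[tuple[str, str, str], int] = {}
        for orientation in ORIENTATIONS:
            for r in RNA_BASES:
                for d in DNA_BASES:
                    full[(r, d, orientation)] = 0
        for (r, d, orientation), w in self.weights.items():
            key = (_normalise_rna(r), _normalise_dna(d), orientation)
            if key not in full:
                raise ValueError(f"invalid triad key {(r, d, orientation)!r}")
            if not 0 <= int(w) <= 2:
                raise ValueError(f"triad weight must be in [0, 2], got {w}")
            full[key] = int(w)
        object.__setattr__(self, "weights", full)

    @classmethod
    def default(cls) -> "TriadTable":
        return cls(dict(_DEFAULT_WEIGHTS))

    def weight_matrix(self, orientation: str) -> np.ndarray:
        """5x5 int8 matrix indexed by BASE_INDEX (row RNA, column duplex base).

        Index 4 on either axis is the ambiguous-base bin and always scores 0.
        """
        if orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        mat = np.zeros((5, 5), dtype=np.int8)
        for r in RNA_BASES:
            for d in DNA_BASES:
                mat[BASE_INDEX[r], BASE_INDEX[d]] = self.weights[(r, d, orientation)]
        return mat

    def save(self, path: str | Path) -> None:
        """Write the table as an editable key-value config file."""
        lines = ["# triad table: orientation rna_base duplex_base weight"]
        for (r, d, orientation), w in sorted(self.weights.items(), key=lambda kv: kv[0][2]):
            if w:
                lines.append(f"{orientation}\t{r}\t{d}\t{w}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TriadTable":
        weights: dict[tuple[str, str, str], int] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            orientation, r, d, w = parts
            weights[(r, d, orientation)] = int(w)
        return cls(weights)


def triad_weight(
    rna_base: str, duplex_base: str, orientation: str, table: TriadTable | None = None
) -> int:
    """Stability weight of one triad; raises on non-nucleotide symbols."""
    table = table or TriadTable.default()
    r = _normalise_rna(rna_base)
    d = _normalise_dna(duplex_base)
    if r not in RNA_BASES:
        raise ValueError(f"non-nucleotide RNA symbol {rna_base!r}")
    if d not in DNA_BASES:
        raise ValueError(f"non-nucleotide DNA symbol {duplex_base!r}")
    if orientation not in ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}")
    return table.weights[(r, d, orientation)]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 indices (ambiguous symbols -> 4)."""
    out = np.full(len(seq), 4, dtype=np.uint8)
    for i, ch in enumerate(seq.upper()):
        out[i] = BASE_INDEX.get(ch, 4)
    return out
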