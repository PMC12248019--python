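"""Effective sequence count (Neff) of a multiple sequence alignment.

Pairwise identity ignores columns gapped in both sequences; a gap against
a residue counts as a mismatch.  Each sequence's weight is the number of
sequences (itself included) with identity strictly above the 0.8
threshold, and Neff is the sum of inverse weights.  Including self keeps
every weight >= 1 (the exclude-self reading would divide by zero for a
unique sequence); this matches common practice in MSA-based structure
prediction.  Comparisons are case-insensitive, T is equated to U, and N
matches nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["MSA", "MsaDepthParams", "read_msa", "pairwise_identity", "neff"]

_GAP_CHARS = ".-~"
_GAP = 0
_N_CODE = 99
_ALPHABET = {"A": 1, "C": 2, "G": 3, "U": 4, "T": 4, "N": _N_CODE}


@dataclass
class MSA:
    names: list[str]
    rows: list[str]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("an MSA needs at least one row")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("aligned rows must all have the same length")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])


@dataclass
class MsaDepthParams:
    identity_threshold: float = 0.8
    weights: np.ndarray | None = field(default=None, repr=False)


def read_msa(path: str | Path) -> MSA:
    """Read an aligned FASTA / A2M file."""
    names, rows = [], []
    current: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if current:
                rows.append("".join(current))
                current = []
            names.append(line[1:].split()[0] if len(line) > 1 else f"seq{len(names) + 1}")
        else:
            current.append(line)
    if current:
        rows.append("".join(current))
    if not rows:
        raise ValueError(f"no sequences in {path}")
    return MSA(names=names or [f"seq{i + 1}" for i in range(len(rows))], rows=rows)


def _encode(row: str) -> np.ndarray:
    out = np.empty(len(row), dtype=np.int8)
    for i, ch in enumerate(row):
        if ch in _GAP_CHARS:
            out[i] = _GAP
        else:
            out[i] = _ALPHABET.get(ch.upper(), _N_CODE)
    return out


def pairwise_identity(a: str, b: str) -> float | None:
    """Fraction of matching positions, ignoring dual-gap columns.

    Returns None when every column is gapped in both sequences.
    """
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    ea, eb = _encode(a), _encode(b)
    valid = ~((ea == _GAP) & (eb == _GAP))
    n_valid = int(valid.sum())
    if n_valid == 0:
        return None
    matches = (ea == eb) & valid & (ea != _GAP) & (ea != _N_CODE)
    return float(matches.sum()) / n_valid


def neff(msa: MSA, params: MsaDepthParams | None = None) -> float:
    """Normalized effective sequence count of the alignment."""
    params = params or MsaDepthParams()
    n = len(msa)
    if n == 1:
        return 1.0
    enc = np.stack([_encode(r) for r in msa.rows])  # (n, L)
    gaps = enc == _GAP
    weights = np.ones(n)
    for i in range(n):
        valid = ~(gaps[i][None, :] & gaps)  # (n, L)
        matches = (enc == enc[i][None, :]) & valid & ~gaps[i][None, :] & (
            enc[i][None, :] != _N_CODE)
        n_valid = valid.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident = np.where(n_valid > 0, matches.sum(axis=1) / n_valid, 0.0)
        similar = ident > params.identity_threshold
        similar[i] = True  # include-self convention
        weights[i] = similar.sum()
    params.weights = weights
    return float(np.sum(1.0 / weights))
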