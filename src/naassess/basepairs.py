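"""Base-pair annotation, topology classification, and F1 scoring.

Canonical pairs are Watson-Crick-Franklin (A-U/A-T, G-C) and wobble
(G-U).  Annotation is geometric: complementary base identity, a short
N1-N3 hydrogen-bonding distance, roughly coplanar bases, and a C1'-C1'
separation near the canonical 10.4 A.  Every residue joins at most one
canonical pair (closest-distance wins).  Detected pairs that fail the
identity test are recorded as non-canonical.

Topology follows the standard definitions over intramolecular canonical
pairs in global residue order: a pair (i, j) is *crossed* (pseudoknotted)
when another canonical pair (k, l) interleaves with it (i<k<j<l or
k<i<l<j), and *singlet* when neither stacked neighbor (i+1, j-1) nor
(i-1, j+1) is present.  Intermolecular canonical pairs are inventoried
separately and excluded from the crossing/singlet analysis.

F1 conventions: a prediction matches a target pair when it joins the same
two nucleotides; overprediction against an empty target scores 0; when
both sides are empty the score is null (no score); predicted pairs that
touch a reference-unresolved nucleotide are removed before scoring so
they count neither for nor against precision.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .structures import Structure

__all__ = [
    "BasePair",
    "PairInventory",
    "PrecisionRecallF1",
    "PairGeometry",
    "annotate_pairs",
    "ingest_pairs",
    "parse_dotbracket",
    "classify_topology",
    "score_f1",
    "aggregate_f1",
]

CANONICAL_PAIRS = {
    frozenset(("A", "U")), frozenset(("A", "T")), frozenset(("G", "C")),
    frozenset(("G", "U")),
}
PURINES = {"A", "G"}

OPEN_BRACKETS = "([{<"
CLOSE_BRACKETS = ")]}>"


@dataclass(frozen=True)
class BasePair:
    """A base pair between global residue positions i < j (1-based).

    ``ref_i``/``ref_j`` optionally carry (chain_id, residue number,
    insertion code) identifiers; when present they define pair identity
    for matching, otherwise the global positions do.
    """

    i: int
    j: int
    klass: str = "canonical"  # canonical | noncanonical
    intermolecular: bool = False
    ref_i: tuple[str, int, str] | None = None
    ref_j: tuple[str, int, str] | None = None

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("a base pair needs two distinct residues")
        if self.i > self.j:
            object.__setattr__(self, "i", self.j)
            object.__setattr__(self, "j", self.i)
            ri, rj = self.ref_i, self.ref_j
            object.__setattr__(self, "ref_i", rj)
            object.__setattr__(self, "ref_j", ri)

    def key(self) -> frozenset:
        if self.ref_i is not None and self.ref_j is not None:
            return frozenset((self.ref_i, self.ref_j))
        return frozenset((self.i, self.j))


@dataclass
class PairInventory:
    all_canonical: set[BasePair] = field(default_factory=set)
    crossed: set[BasePair] = field(default_factory=set)
    singlet: set[BasePair] = field(default_factory=set)
    noncanonical: set[BasePair] = field(default_factory=set)
    intermolecular: set[BasePair] = field(default_factory=set)

    def by_class(self, name: str) -> set[BasePair]:
        return getattr(self, name)


@dataclass
class PrecisionRecallF1:
    precision: float | None
    recall: float | None
    f1: float | None
    null_score: bool = False

    @classmethod
    def null(cls) -> "PrecisionRecallF1":
        return cls(None, None, None, null_score=True)


@dataclass
class PairGeometry:
    """Geometric criteria for canonical-pair detection."""

    hbond_max: float = 3.5        # N1-N3 distance, A
    plane_angle_max: float = 30.0  # degrees between base planes
    c1_distance: float = 10.4     # canonical C1'-C1' separation, A
    c1_tolerance: float = 1.5


# ---------------------------------------------------------------------------
# geometric annotation

def _base_frame(res) -> tuple[np.ndarray, np.ndarray, np.ndarray | None] | None:
    """(C1', pairing N, base-plane normal) for a nucleotide, or None."""
    c1 = res.atoms.get("C1'")
    if c1 is None:
        return None
    letter = res.one_letter()
    n_atom = "N1" if letter in PURINES else "N3"
    n = res.atoms.get(n_atom)
    if n is None:
        # all-atom files carry both; fall back to whichever exists
        n = res.atoms.get("N3" if letter in PURINES else "N1")
    if n is None:
        return None
    third = next((res.atoms[a] for a in ("C2", "C4", "C6") if a in res.atoms),
                 None)
    normal = None
    if third is not None:
        v1, v2 = n - c1, third - c1
        cr = np.cross(v1, v2)
        nrm = np.linalg.norm(cr)
        if nrm > 1e-6:
            normal = cr / nrm
    return c1, n, normal


def _plane_angle(n1: np.ndarray | None, n2: np.ndarray | None) -> float:
    if n1 is None or n2 is None:
        return 0.0  # undeterminable plane: do not reject on angle
    c = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def annotate_pairs(structure: Structure,
                   geometry: PairGeometry | None = None) -> list[BasePair]:
    """Detect base pairs geometrically in RNA/DNA chains.

    Canonical pairs require complementary identity plus geometry; each
    residue participates in at most one canonical pair (closest N-N
    distance wins).  Geometrically paired but non-complementary residues
    are reported as non-canonical pairs.
    """
    from scipy.spatial import cKDTree

    geometry = geometry or PairGeometry()
    index = structure.residue_index()
    nucs = []  # (global position, chain id, residue, frame)
    for ch in structure.chains:
        if ch.polymer_type not in ("RNA", "DNA"):
            continue
        chain_had_bases = False
        for res in ch.residues:
            if not res.resolved:
                continue
            frame = _base_frame(res)
            if frame is None:
                continue
            chain_had_bases = True
            pos = index[(ch.chain_id, res.number, res.insertion_code)]
            nucs.append((pos, ch.chain_id, res, frame))
        if ch.residues and not chain_had_bases:
            warnings.warn(f"chain {ch.chain_id} lacks base atoms; skipped",
                          stacklevel=2)
    if len(nucs) < 2:
        return []

    c1s = np.array([f[3][0] for f in nucs])
    tree = cKDTree(c1s)
    lo = geometry.c1_distance - geometry.c1_tolerance
    hi = geometry.c1_distance + geometry.c1_tolerance
    candidates = []  # (nn_dist, idx_a, idx_b, canonical?)
    for ia, ib in tree.query_pairs(hi, output_type="ndarray"):
        d_c1 = float(np.linalg.norm(c1s[ia] - c1s[ib]))
        if d_c1 < lo:
            continue
        _, _, res_a, (c1a, na, nrm_a) = nucs[ia]
        _, _, res_b, (c1b, nb, nrm_b) = nucs[ib]
        d_nn = float(np.linalg.norm(na - nb))
        if d_nn > geometry.hbond_max:
            continue
        if _plane_angle(nrm_a, nrm_b) > geometry.plane_angle_max:
            continue
        identity = frozenset((res_a.one_letter(), res_b.one_letter()))
        candidates.append((d_nn, int(ia), int(ib), identity in CANONICAL_PAIRS))

    pairs: list[BasePair] = []
    used: set[int] = set()
    for d_nn, ia, ib, canonical in sorted(candidates):
        pos_a, ch_a, res_a, _ = nucs[ia]
        pos_b, ch_b, res_b, _ = nucs[ib]
        ref_a = (ch_a, res_a.number, res_a.insertion_code)
        ref_b = (ch_b, res_b.number, res_b.insertion_code)
        if canonical and ia not in used and ib not in used:
            used.add(ia)
            used.add(ib)
            klass = "canonical"
        else:
            klass = "noncanonical"
        pairs.append(BasePair(pos_a, pos_b, klass=klass,
                              intermolecular=(ch_a != ch_b),
                              ref_i=ref_a, ref_j=ref_b))
    pairs.sort(key=lambda p: (p.i, p.j))
    return pairs


# ---------------------------------------------------------------------------
# annotation ingestion

def parse_dotbracket(text: str) -> list[tuple[int, int]]:
    """Decode a (possibly pseudoknotted) dot-bracket string to 1-based pairs.

    Layers: ``( [ { <`` plus uppercase letters open, matching closers
    close.  ``&`` marks a chain break and does not consume a position.
    """
    stacks: dict[str, list[int]] = {}
    pairs: list[tuple[int, int]] = []
    pos = 0
    for col, ch in enumerate(text.strip()):
        if ch == "&":
            continue
        pos += 1
        if ch in ".-:,_":
            continue
        if ch in OPEN_BRACKETS:
            stacks.setdefault(ch, []).append(pos)
        elif ch in CLOSE_BRACKETS:
            opener = OPEN_BRACKETS[CLOSE_BRACKETS.index(ch)]
            stack = stacks.get(opener, [])
            if not stack:
                raise ValueError(f"unbalanced bracket {ch!r} at position {col + 1}")
            pairs.append((stack.pop(), pos))
        elif ch.isalpha():
            if ch.isupper():
                stacks.setdefault(ch, []).append(pos)
            else:
                stack = stacks.get(ch.upper(), [])
                if not stack:
                    raise ValueError(f"unbalanced bracket {ch!r} at position {col + 1}")
                pairs.append((stack.pop(), pos))
        else:
            raise ValueError(f"unrecognized character {ch!r} at position {col + 1}")
    for opener, stack in stacks.items():
        if stack:
            raise ValueError(
                f"unbalanced bracket {opener!r} opened at position {stack[-1]}")
    pairs.sort()
    return pairs


def chain_breaks(text: str) -> list[int]:
    """Positions after which a new chain starts, from '&' markers."""
    breaks = []
    pos = 0
    for ch in text.strip():
        if ch == "&":
            breaks.append(pos)
        else:
            pos += 1
    return breaks


def ingest_pairs(path: str | Path, format: str = "dotbracket") -> list[BasePair]:
    """Load base-pair annotations from a dot-bracket or pair-list CSV file.

    CSV columns: chain_i, res_i, chain_j, res_j, klass.  Duplicate rows
    are dropped with a warning.
    """
    path = Path(path)
    if format == "dotbracket":
        lines = [ln.strip() for ln in path.read_text().splitlines()
                 if ln.strip() and not ln.startswith((">", "#"))]
        # a sequence line may precede the structure line
        struct_line = lines[-1]
        raw = parse_dotbracket(struct_line)
        breaks = chain_breaks(struct_line)

        def chain_of(pos: int) -> int:
            return sum(1 for b in breaks if b < pos)

        return [BasePair(i, j, klass="canonical",
                         intermolecular=chain_of(i) != chain_of(j))
                for i, j in raw]
    if format == "csv":
        pairs: list[BasePair] = []
        seen: set[frozenset] = set()
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            dummy = 0
            for row in reader:
                if not row or row[0].lower() in ("chain_i", "#"):
                    continue
                ch_i, res_i, ch_j, res_j = row[0], int(row[1]), row[2], int(row[3])
                klass = row[4].strip() if len(row) > 4 and row[4].strip() else "canonical"
                if klass not in ("canonical", "noncanonical"):
                    raise ValueError(f"unknown pair class {klass!r} in {path}")
                key = frozenset(((ch_i, res_i, ""), (ch_j, res_j, "")))
                if key in seen:
                    warnings.warn(f"duplicate pair {row[:4]} dropped", stacklevel=2)
                    continue
                seen.add(key)
                dummy += 1
                pairs.append(BasePair(2 * dummy - 1, 2 * dummy, klass=klass,
                                      intermolecular=(ch_i != ch_j),
                                      ref_i=(ch_i, res_i, ""),
                                      ref_j=(ch_j, res_j, "")))
        return pairs
    raise ValueError(f"unknown annotation format {format!r}")


def pairs_with_positions(pairs: Iterable[BasePair],
                         structure: Structure) -> list[BasePair]:
    """Re-index pairs carrying residue identifiers onto a structure's
    global residue order (needed before topology classification of
    ingested CSV annotations)."""
    index = structure.residue_index()
    out = []
    for p in pairs:
        if p.ref_i is None or p.ref_j is None:
            out.append(p)
            continue
        if p.ref_i not in index or p.ref_j not in index:
            raise KeyError(f"pair residue {p.ref_i} / {p.ref_j} not in structure")
        out.append(BasePair(index[p.ref_i], index[p.ref_j], klass=p.klass,
                            intermolecular=p.intermolecular,
                            ref_i=p.ref_i, ref_j=p.ref_j))
    return out


# ---------------------------------------------------------------------------
# topology

def classify_topology(pairs: Sequence[BasePair]) -> PairInventory:
    """Partition pairs into the five inventory classes.

    Crossing and singlet predicates apply to intramolecular canonical
    pairs only, in global residue order.
    """
    inv = PairInventory()
    for p in pairs:
        if p.klass == "noncanonical":
            inv.noncanonical.add(p)
            continue
        inv.all_canonical.add(p)
        if p.intermolecular:
            inv.intermolecular.add(p)
    intra = sorted((p for p in inv.all_canonical if not p.intermolecular),
                   key=lambda p: (p.i, p.j))
    occupied = {(p.i, p.j) for p in intra}
    for p in intra:
        for q in intra:
            if q is p:
                continue
            if p.i < q.i < p.j < q.j or q.i < p.i < q.j < p.j:
                inv.crossed.add(p)
                break
        if ((p.i + 1, p.j - 1) not in occupied
                and (p.i - 1, p.j + 1) not in occupied):
            inv.singlet.add(p)
    return inv


# ---------------------------------------------------------------------------
# F1 scoring

def score_f1(pred: Iterable[BasePair], target: Iterable[BasePair],
             unresolved: Iterable | None = None) -> PrecisionRecallF1:
    """Precision/recall/F1 over pair sets matched by nucleotide identity."""
    unresolved_set = set(unresolved or ())
    target_keys = {p.key() for p in target}
    pred_keys = set()
    for p in pred:
        if unresolved_set and (
                (p.ref_i in unresolved_set or p.ref_j in unresolved_set)
                or (p.i in unresolved_set or p.j in unresolved_set)):
            continue
        pred_keys.add(p.key())
    if not target_keys and not pred_keys:
        return PrecisionRecallF1.null()
    if not target_keys:
        return PrecisionRecallF1(0.0, None, 0.0)
    if not pred_keys:
        return PrecisionRecallF1(None, 0.0, 0.0)
    tp = len(pred_keys & target_keys)
    precision = tp / len(pred_keys)
    recall = tp / len(target_keys)
    f1 = 0.0 if tp == 0 else 2 * precision * recall / (precision + recall)
    return PrecisionRecallF1(precision, recall, f1)


def best_f1(scores: Sequence[PrecisionRecallF1]) -> PrecisionRecallF1:
    """Best score over models/references; a null score beats any number
    (correctly predicting no interaction is the best outcome)."""
    if not scores:
        raise ValueError("no scores to reduce")
    for s in scores:
        if s.null_score:
            return s
    return max(scores, key=lambda s: s.f1)


def aggregate_f1(scores: Mapping[str, Mapping[str, Sequence[PrecisionRecallF1]]],
                 targets: Sequence[str]) -> dict[str, float | None]:
    """Per-group mean of per-target best F1 scores.

    ``scores[group][target]`` holds one score per (model, reference)
    combination.  A missing target for a group contributes 0; null best
    scores are excluded from the mean.  Groups whose every target is null
    get a null (None) mean.
    """
    out: dict[str, float | None] = {}
    for group, per_target in scores.items():
        values = []
        for target in targets:
            entry = per_target.get(target)
            if not entry:
                values.append(0.0)  # no submission
                continue
            best = best_f1(list(entry))
            if best.null_score:
                continue
            values.append(best.f1)
        out[group] = float(np.mean(values)) if values else None
    return out
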