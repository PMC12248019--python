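"""Hierarchical structure model and PDB/mmCIF input/output.

The in-memory model is deliberately small: a :class:`Structure` holds
ordered :class:`Chain` objects, each holding ordered :class:`Residue`
objects with a plain ``name -> xyz`` atom mapping.  Polymer typing (RNA,
DNA, protein, ligand) is inferred from residue-name vocabulary because
predicted model files frequently lack entity records.  All downstream
metrics operate on this model.

File parsing and writing are delegated to :mod:`gemmi`; this module only
converts between the gemmi hierarchy and the lightweight one used here.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Residue",
    "Chain",
    "Structure",
    "Correspondence",
    "StructureError",
    "StructureFormatError",
    "read_structure",
    "write_structure",
    "structure_from_text",
    "residue_correspondence",
    "chain_mapping_search",
]

RNA_RESIDUES = {"A", "C", "G", "U", "I"}
DNA_RESIDUES = {"DA", "DC", "DG", "DT", "DU", "DI"}
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
# one-letter codes for sequence/stoichiometry work
_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

REPRESENTATIVE_ATOMS = {"RNA": "C4'", "DNA": "C4'", "protein": "CA"}


class StructureError(ValueError):
    """Invalid structure content (empty file, no correspondence, ...)."""


class StructureFormatError(StructureError):
    """Unparsable PDB/mmCIF input."""


@dataclass
class Residue:
    """A residue (or ligand component) with author numbering.

    ``atoms`` maps atom name to a length-3 float array in Angstrom.  A
    residue with no atoms is kept but flagged ``resolved=False`` so that
    correspondences can exclude it.
    """

    name: str
    number: int
    insertion_code: str = ""
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def resolved(self) -> bool:
        return len(self.atoms) > 0

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.insertion_code)

    def representative_atom(self, polymer_type: str) -> np.ndarray | None:
        name = REPRESENTATIVE_ATOMS.get(polymer_type)
        if name is not None and name in self.atoms:
            return self.atoms[name]
        if polymer_type == "ligand" and self.atoms:
            # ligands have no canonical representative; use the centroid
            return np.mean(list(self.atoms.values()), axis=0)
        return None

    def one_letter(self) -> str:
        n = self.name.strip()
        if n in RNA_RESIDUES:
            return n
        if n in DNA_RESIDUES:
            return n[1]
        return _AA3TO1.get(n, "X")


@dataclass
class Chain:
    chain_id: str
    polymer_type: str  # RNA | DNA | protein | ligand
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def sequence(self) -> str:
        return "".join(r.one_letter() for r in self.residues)

    def get(self, number: int, insertion_code: str = "") -> Residue | None:
        for r in self.residues:
            if r.number == number and r.insertion_code == insertion_code:
                return r
        return None

    def sort_residues(self) -> None:
        self.residues.sort(key=lambda r: (r.number, r.insertion_code))


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    source_format: str = "pdb"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ch in self.chains:
            if ch.chain_id in seen:
                raise StructureError(
                    f"duplicate chain id {ch.chain_id!r} in structure {self.id!r}")
            seen.add(ch.chain_id)

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(chain_id)

    def has_chain(self, chain_id: str) -> bool:
        return any(ch.chain_id == chain_id for ch in self.chains)

    def polymer_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.polymer_type != "ligand"]

    def iter_residues(self) -> Iterator[tuple[Chain, Residue]]:
        for ch in self.chains:
            for res in ch.residues:
                yield ch, res

    def residue_index(self) -> dict[tuple[str, int, str], int]:
        """Global 1-based position of every residue in chain-then-number order."""
        idx: dict[tuple[str, int, str], int] = {}
        i = 1
        for ch, res in self.iter_residues():
            idx[(ch.chain_id, res.number, res.insertion_code)] = i
            i += 1
        return idx

    def coordinates(self) -> np.ndarray:
        coords = [a for _, res in self.iter_residues() for a in res.atoms.values()]
        if not coords:
            return np.empty((0, 3))
        return np.asarray(coords)

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def copy(self) -> "Structure":
        return Structure(
            id=self.id,
            chains=[
                Chain(
                    ch.chain_id,
                    ch.polymer_type,
                    [
                        Residue(r.name, r.number, r.insertion_code,
                                {k: v.copy() for k, v in r.atoms.items()})
                        for r in ch.residues
                    ],
                )
                for ch in self.chains
            ],
            source_format=self.source_format,
        )

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        out = self.copy()
        for _, res in out.iter_residues():
            for name in res.atoms:
                res.atoms[name] = rotation @ res.atoms[name] + translation
        return out


# ---------------------------------------------------------------------------
# polymer typing

def classify_residue(name: str) -> str:
    n = name.strip().upper()
    if n in RNA_RESIDUES:
        return "RNA"
    if n in DNA_RESIDUES:
        return "DNA"
    if n in AMINO_ACIDS:
        return "protein"
    return "ligand"


def infer_polymer_type(residues: Sequence[Residue]) -> str:
    counts = {"RNA": 0, "DNA": 0, "protein": 0, "ligand": 0}
    for r in residues:
        counts[classify_residue(r.name)] += 1
    best = max(counts, key=lambda k: (counts[k], k != "ligand"))
    if counts[best] == 0:
        return "ligand"
    return best


# ---------------------------------------------------------------------------
# reading / writing

def _convert_gemmi_model(model: gemmi.Model, struct_id: str, fmt: str) -> Structure:
    chains: list[Chain] = []
    for gch in model:
        residues: list[Residue] = []
        for gres in gch:
            atoms: dict[str, np.ndarray] = {}
            occ: dict[str, float] = {}
            for atom in gres:
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
                if not np.all(np.isfinite(pos)):
                    continue
                name = atom.name
                # altloc policy: keep the highest-occupancy conformer
                if name in atoms and occ.get(name, 0.0) >= atom.occ:
                    continue
                atoms[name] = pos
                occ[name] = atom.occ
            residues.append(
                Residue(
                    name=gres.name.strip(),
                    number=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    atoms=atoms,
                )
            )
        if not residues:
            continue
        chains.append(Chain(gch.name, infer_polymer_type(residues), residues))
    if not chains:
        raise StructureError(f"structure {struct_id!r} contains no residues")
    return Structure(id=struct_id, chains=chains, source_format=fmt)


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    return "pdb"


def read_structure(path: str | Path, format: str | None = None,
                   model_index: int = 0) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Multi-model files yield the model at ``model_index`` (default: first).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _detect_format(path)
    if fmt not in {"pdb", "mmcif"}:
        raise ValueError(f"unknown structure format {fmt!r}")
    try:
        if fmt == "pdb":
            gst = gemmi.read_pdb(str(path))
        else:
            gst = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(gst) == 0:
        raise StructureError(f"{path} contains no models")
    if model_index >= len(gst):
        raise StructureError(f"{path} has {len(gst)} models; index {model_index} out of range")
    return _convert_gemmi_model(gst[model_index], path.stem, fmt)


def structure_from_text(text: str, struct_id: str = "structure",
                        format: str = "pdb") -> Structure:
    """Parse structure records held in a string (PDB or mmCIF)."""
    try:
        if format == "pdb":
            gst = gemmi.read_pdb_string(text)
        else:
            doc = gemmi.cif.read_string(text)
            gst = gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {struct_id}: {exc}") from exc
    if len(gst) == 0:
        raise StructureError(f"{struct_id} contains no models")
    return _convert_gemmi_model(gst[0], struct_id, format)


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    gst = gemmi.Structure()
    gst.name = structure.id
    model = gemmi.Model("1")
    for ch in structure.chains:
        gch = gemmi.Chain(ch.chain_id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            if ch.polymer_type == "ligand":
                gres.het_flag = "H"
            else:
                gres.het_flag = "A"
            for name, pos in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(_element_of(name))
                atom.pos = gemmi.Position(*map(float, pos))
                atom.occ = 1.0
                gres.add_atom(atom)
            gch.add_residue(gres)
        model.add_chain(gch)
    gst.add_model(model)
    gst.setup_entities()
    return gst


def _element_of(atom_name: str) -> str:
    stripped = atom_name.strip("0123456789'*")
    if len(stripped) >= 2 and stripped[:2].capitalize() in {"Cl", "Br", "Fe", "Mg", "Mn", "Zn", "Na"}:
        return stripped[:2].capitalize()
    return stripped[:1].upper() if stripped else "C"


def write_structure(structure: Structure, path: str | Path,
                    format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _detect_format(path)
    gst = _to_gemmi(structure)
    if fmt == "pdb":
        gst.write_pdb(str(path))
    else:
        gst.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# residue correspondence

@dataclass
class Correspondence:
    """One-to-one residue pairing between a model and a reference.

    Each entry pairs a model residue with a reference residue; reference
    residues that are unresolved are never included.  ``chain_pairs``
    records which model chain serves each reference chain (identity unless
    a chain map was supplied).
    """

    pairs: list[tuple[tuple[Chain, Residue], tuple[Chain, Residue]]]
    mode: str = "sequence"
    chain_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def representative_points(self) -> tuple[np.ndarray, np.ndarray, list[int]]:
        """Matched representative-atom coordinates (model, reference).

        Returns the subset of pairs where both sides carry a representative
        atom, plus their indices into ``pairs``.
        """
        xs, ys, idx = [], [], []
        for i, ((mch, mres), (rch, rres)) in enumerate(self.pairs):
            xm = mres.representative_atom(mch.polymer_type)
            xr = rres.representative_atom(rch.polymer_type)
            if xm is not None and xr is not None:
                xs.append(xm)
                ys.append(xr)
                idx.append(i)
        if not xs:
            return np.empty((0, 3)), np.empty((0, 3)), []
        return np.asarray(xs), np.asarray(ys), idx


def residue_correspondence(model: Structure, reference: Structure,
                           mode: str = "sequence",
                           chain_map: dict[str, str] | None = None) -> Correspondence:
    """Match model residues to reference residues.

    In ``sequence`` mode residues are matched by chain id (optionally via
    ``chain_map``: reference chain -> model chain) and author residue
    number + insertion code.  Unresolved reference residues are excluded.
    ``structural`` mode derives the pairing from a sequence-independent
    structural alignment (single polymer chain on each side).
    """
    if mode == "structural":
        return _structural_correspondence(model, reference)
    if mode != "sequence":
        raise ValueError(f"unknown correspondence mode {mode!r}")
    pairs = []
    chain_pairs = []
    for rch in reference.chains:
        model_chain_id = (chain_map or {}).get(rch.chain_id, rch.chain_id)
        if not model.has_chain(model_chain_id):
            continue
        mch = model.chain(model_chain_id)
        chain_pairs.append((model_chain_id, rch.chain_id))
        model_residues = {r.key: r for r in mch.residues if r.resolved}
        for rres in rch.residues:
            if not rres.resolved:
                continue
            mres = model_residues.get(rres.key)
            if mres is not None:
                pairs.append(((mch, mres), (rch, rres)))
    if not pairs:
        raise StructureError(
            f"no correspondence between {model.id!r} and {reference.id!r}")
    return Correspondence(pairs=pairs, mode="sequence", chain_pairs=chain_pairs)


def _structural_correspondence(model: Structure, reference: Structure) -> Correspondence:
    from .metrics import tm_align  # local import to avoid a cycle

    mchs = model.polymer_chains()
    rchs = reference.polymer_chains()
    if len(mchs) != 1 or len(rchs) != 1:
        raise StructureError("structural correspondence requires single-chain structures")
    mch, rch = mchs[0], rchs[0]
    alignment, _score = tm_align(model, reference)
    mres = [r for r in mch.residues if r.resolved]
    rres = [r for r in rch.residues if r.resolved]
    pairs = [((mch, mres[i]), (rch, rres[j])) for i, j in alignment]
    if not pairs:
        raise StructureError("no structural correspondence found")
    return Correspondence(pairs=pairs, mode="structural",
                          chain_pairs=[(mch.chain_id, rch.chain_id)])


# ---------------------------------------------------------------------------
# chain mapping for homo-oligomers

def _sequence_classes(chains: Iterable[Chain]) -> dict[str, list[Chain]]:
    classes: dict[str, list[Chain]] = {}
    for ch in chains:
        classes.setdefault(ch.sequence(), []).append(ch)
    return classes


def default_mapping_objective(model: Structure, reference: Structure,
                              chain_map: dict[str, str]) -> float:
    """Global lDDT of the model under a candidate chain map."""
    from .metrics import lddt

    corr = residue_correspondence(model, reference, chain_map=chain_map)
    return lddt(model, reference, corr)


def chain_mapping_search(
    model: Structure,
    reference: Structure,
    objective: Callable[[Structure, Structure, dict[str, str]], float] | None = None,
    max_exhaustive: int = 8,
) -> dict[str, str]:
    """Find the model chain for each reference chain maximizing an objective.

    Chains are grouped into sequence-identity classes; only within-class
    assignments are legal.  Classes with up to ``max_exhaustive`` members
    are searched exhaustively, larger ones with a greedy seed-and-extend
    heuristic based on centroid proximity after a seed superposition.
    Returns a ``reference chain id -> model chain id`` map.  Ties are
    broken towards the lexicographically smallest assignment.
    """
    objective = objective or default_mapping_objective
    ref_classes = _sequence_classes(reference.polymer_chains())
    mod_classes = _sequence_classes(model.polymer_chains())
    if sorted(len(v) for v in ref_classes.values()) != sorted(
            len(v) for v in mod_classes.values()):
        raise StructureError("incompatible stoichiometry between model and reference")

    # pair up classes: identical sequence when possible, else by length multiset
    class_pairs: list[tuple[list[Chain], list[Chain]]] = []
    unused_mod = dict(mod_classes)
    for seq, rlist in sorted(ref_classes.items()):
        if seq in unused_mod and len(unused_mod[seq]) == len(rlist):
            class_pairs.append((rlist, unused_mod.pop(seq)))
        else:
            match = next((k for k, v in sorted(unused_mod.items())
                          if len(v) == len(rlist) and len(k) == len(seq)), None)
            if match is None:
                raise StructureError("incompatible stoichiometry between model and reference")
            class_pairs.append((rlist, unused_mod.pop(match)))

    per_class_options: list[list[list[tuple[str, str]]]] = []
    for rlist, mlist in class_pairs:
        if len(rlist) <= max_exhaustive:
            options = [
                [(r.chain_id, m.chain_id) for r, m in zip(rlist, perm)]
                for perm in itertools.permutations(mlist)
            ]
        else:
            options = [_greedy_class_assignment(model, reference, rlist, mlist)]
        per_class_options.append(options)

    best_map: dict[str, str] | None = None
    best_score = -np.inf
    for combo in itertools.product(*per_class_options):
        cmap = {r: m for part in combo for r, m in part}
        try:
            score = objective(model, reference, cmap)
        except StructureError:
            continue
        key = tuple(cmap[r] for r in sorted(cmap))
        if score > best_score + 1e-12 or (
                abs(score - best_score) <= 1e-12 and best_map is not None
                and key < tuple(best_map[r] for r in sorted(best_map))):
            best_score = score
            best_map = cmap
    if best_map is None:
        raise StructureError("no legal chain mapping found")
    return best_map


def _greedy_class_assignment(model: Structure, reference: Structure,
                             rlist: list[Chain], mlist: list[Chain]
                             ) -> list[tuple[str, str]]:
    """Greedy mapping for large classes: superpose a seed chain pair, then
    assign remaining chains by nearest centroid (Hungarian assignment)."""
    from scipy.optimize import linear_sum_assignment

    from .metrics import kabsch_superpose

    def chain_points(ch: Chain) -> np.ndarray:
        pts = [r.representative_atom(ch.polymer_type) for r in ch.residues]
        return np.asarray([p for p in pts if p is not None])

    seed_ref = rlist[0]
    pr = chain_points(seed_ref)
    best = None
    for mch in mlist:
        pm = chain_points(mch)
        n = min(len(pr), len(pm))
        if n < 3:
            continue
        sup = kabsch_superpose(pm[:n], pr[:n])
        if best is None or sup.rmsd < best[0]:
            best = (sup.rmsd, mch, sup)
    if best is None:
        raise StructureError("cannot seed greedy chain assignment")
    _, seed_mod, sup = best
    centros_ref = np.array([chain_points(c).mean(axis=0) for c in rlist])
    centros_mod = np.array([
        sup.rotation @ chain_points(c).mean(axis=0) + sup.translation for c in mlist
    ])
    cost = np.linalg.norm(centros_ref[:, None, :] - centros_mod[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    return [(rlist[i].chain_id, mlist[j].chain_id) for i, j in zip(rows, cols)]


def next_chain_ids(n: int) -> list[str]:
    """A, B, ..., Z, AA, AB, ... chain identifiers."""
    letters = string.ascii_uppercase
    ids = list(letters)
    for a in letters:
        for b in letters:
            ids.append(a + b)
    return ids[:n]
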