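"""Synthetic inputs for every pipeline stage.

The structure builder produces coarse-grained nucleotides (P, C4', C1',
the pairing nitrogen N1/N3, and a base-plane atom C2) from a sequence
plus a possibly pseudoknotted dot-bracket.  Paired regions become ideal
double-helical stems (A-form-like rise/twist constants); each stem is
placed as its own block in space and unpaired regions are laid out as
smooth elevated linker arcs between their anchors.  The construction
guarantees that paired bases sit at canonical pairing geometry while
unpaired bases are kept out of pairing geometry (tilted base planes,
separated linker levels), so geometric annotation recovers exactly the
specified canonical pairs.  The layout is schematic, not a folded RNA:
chains may take non-physical paths between stems, which no implemented
metric depends on.

Also provided: exact Cn/Dn assembly construction, graded perturbation
modes (per-atom Gaussian noise, rigid domain shuffles, chain-placement
errors), protein helices and ligand pockets for complex targets, MSAs of
controlled pairwise identity, and full submission rosters with known
quality ordering.  Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .basepairs import chain_breaks, parse_dotbracket
from .structures import Chain, Residue, Structure, next_chain_ids, write_structure

__all__ = [
    "SecStructSpec",
    "PerturbationSpec",
    "GroupProfile",
    "RosterSpec",
    "build_structure",
    "build_protein",
    "build_assembly",
    "build_na_protein_complex",
    "build_ligand_complex",
    "perturb_model",
    "simulate_msa",
    "simulate_submissions",
    "random_secstruct",
]

# helix geometry constants (A-form-like; config values, not measurements)
RISE = 2.8
TWIST_DEG = 32.7
R_C1 = 5.2       # C1' radius -> C1'-C1' across a pair = 10.4 A
R_N = 1.5        # pairing-nitrogen radius -> N-N across a pair = 3.0 A
R_C2 = 3.3
T_C2 = 1.2       # tangential offset keeping the base plane well defined
STEM_SPACING = 26.0

_PURINES = {"A", "G"}
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "T": "A"}


@dataclass
class SecStructSpec:
    """Sequence and dot-bracket; ``&`` marks chain breaks in both."""

    sequence: str
    structure: str
    molecule: str = "RNA"  # RNA | DNA

    def __post_init__(self):
        seq = self.sequence.replace("&", "")
        db = self.structure.replace("&", "")
        if len(seq) != len(db):
            raise ValueError("sequence and dot-bracket lengths differ")
        if self.sequence.count("&") != self.structure.count("&"):
            raise ValueError("chain breaks differ between sequence and structure")

    @property
    def length(self) -> int:
        return len(self.sequence.replace("&", ""))


@dataclass
class PerturbationSpec:
    sigma: float
    mode: str = "gaussian"  # gaussian | domain_shuffle | chain_placement
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.mode not in ("gaussian", "domain_shuffle", "chain_placement"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")


@dataclass
class GroupProfile:
    sigma: float | Mapping[str, float]
    participation: float = 1.0
    models_per_target: int = 5

    def sigma_for(self, target: str) -> float:
        if isinstance(self.sigma, Mapping):
            return float(self.sigma[target])
        return float(self.sigma)


@dataclass
class RosterSpec:
    groups: dict[str, GroupProfile]


# ---------------------------------------------------------------------------
# stems

def _stems(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Decompose a pair list into maximal stacked runs."""
    pair_set = set(pairs)
    seen: set[tuple[int, int]] = set()
    stems = []
    for p in sorted(pairs):
        if p in seen:
            continue
        stem = [p]
        seen.add(p)
        i, j = p
        while (i + 1, j - 1) in pair_set:
            i, j = i + 1, j - 1
            stem.append((i, j))
            seen.add((i, j))
        stems.append(stem)
    return stems


def _residue_name(letter: str, molecule: str) -> str:
    if molecule == "DNA":
        return "D" + ("T" if letter == "U" else letter)
    return "U" if letter == "T" else letter


def _pair_atoms(theta: float, z: float, origin: np.ndarray, flip: bool
                ) -> dict[str, np.ndarray]:
    """Coarse nucleotide atoms at helix angle theta (one strand of a pair)."""
    if flip:
        theta = theta + np.pi
    r_hat = np.array([np.cos(theta), np.sin(theta), 0.0])
    t_hat = np.array([-np.sin(theta), np.cos(theta), 0.0])
    zv = np.array([0.0, 0.0, z])
    return {
        "P": origin + 8.5 * r_hat + 2.5 * t_hat + zv + np.array([0, 0, 1.2]),
        "C4'": origin + 6.6 * r_hat + 1.5 * t_hat + zv + np.array([0, 0, 0.5]),
        "C1'": origin + R_C1 * r_hat + zv,
        # pairing nitrogen name depends on identity; filled by the caller
        "_N": origin + R_N * r_hat + zv,
        "C2": origin + R_C2 * r_hat + T_C2 * t_hat + zv,
    }


def _linker_atoms(point: np.ndarray, tangent: np.ndarray) -> dict[str, np.ndarray]:
    """Coarse nucleotide on a linker: base plane tilted 45 degrees away
    from the helix planes so linker bases never satisfy pairing geometry
    against stem bases."""
    y = np.array([0.0, 1.0, 0.0])
    up = np.array([0.0, 1.0, 1.0]) / np.sqrt(2.0)
    x = np.array([1.0, 0.0, 0.0])
    return {
        "P": point - 2.6 * y + 0.8 * x,
        "C4'": point - 1.3 * y,
        "C1'": point.copy(),
        "_N": point + 2.0 * up,
        "C2": point + 1.2 * x,
    }


def build_structure(spec: SecStructSpec, seed: int = 0,
                    structure_id: str = "synthetic") -> Structure:
    """Build a coarse-grained 3D structure realizing a secondary structure."""
    seq = spec.sequence.replace("&", "").upper()
    pairs = parse_dotbracket(spec.structure)
    breaks = chain_breaks(spec.structure)
    n = len(seq)
    in_pair: dict[int, int] = {}
    for i, j in pairs:
        if i in in_pair or j in in_pair:
            raise ValueError(
                f"residue in more than one pair near ({i},{j}); split the "
                "conflicting layer into separate pairs")
        in_pair[i] = j
        in_pair[j] = i

    rng = np.random.default_rng(seed)
    coords: dict[int, dict[str, np.ndarray]] = {}

    stems = _stems(pairs)
    twist = np.radians(TWIST_DEG)
    for s_idx, stem in enumerate(stems):
        origin = np.array([STEM_SPACING * s_idx, 0.0, 0.0])
        for t, (i, j) in enumerate(stem):
            theta = t * twist
            z = t * RISE
            coords[i] = _pair_atoms(theta, z, origin, flip=False)
            coords[j] = _pair_atoms(theta, z, origin, flip=True)

    # linkers: maximal unpaired runs, each on its own elevated arc
    run_idx = 0
    pos = 1
    while pos <= n:
        if pos in coords:
            pos += 1
            continue
        start = pos
        while pos <= n and pos not in coords:
            pos += 1
        end = pos - 1  # inclusive unpaired run [start, end]
        k = end - start + 1
        anchor_a = coords[start - 1]["C1'"] if start > 1 else None
        anchor_b = coords[end + 1]["C1'"] if end < n else None
        h = 14.0 + 5.0 * (run_idx % 4)
        if anchor_a is None and anchor_b is None:
            # fully unpaired chain: extended strand along x
            for m, g in enumerate(range(start, end + 1)):
                pt = np.array([6.0 * m, 0.0, 0.0])
                coords[g] = _linker_atoms(pt, np.array([1.0, 0.0, 0.0]))
        elif anchor_a is None or anchor_b is None:
            anchor = anchor_b if anchor_a is None else anchor_a
            ang = 2.399963 * run_idx  # golden-angle spread between runs
            step = np.array([3.0 * np.cos(ang), 4.0, 3.0 * np.sin(ang)])
            order = range(k, 0, -1) if anchor_a is None else range(1, k + 1)
            for m, g in zip(order, range(start, end + 1)):
                pt = anchor + step * m
                coords[g] = _linker_atoms(pt, step)
        else:
            y = np.array([0.0, 1.0, 0.0])
            for m, g in enumerate(range(start, end + 1), start=1):
                t = m / (k + 1)
                bump = h * np.sin(np.pi * (0.15 + 0.7 * t))
                pt = anchor_a + (anchor_b - anchor_a) * t + y * bump
                coords[g] = _linker_atoms(pt, anchor_b - anchor_a)
        run_idx += 1

    # tiny deterministic jitter breaks exact degeneracies without moving
    # anything out of its geometric tolerance
    jitter = rng.normal(0.0, 0.02, size=(n, 5, 3))

    chain_of = [sum(1 for b in breaks if b < g) for g in range(1, n + 1)]
    n_chains = (max(chain_of) + 1) if chain_of else 1
    ids = next_chain_ids(n_chains)
    chains = [Chain(ids[c], spec.molecule, []) for c in range(n_chains)]
    res_counter = [0] * n_chains
    for g in range(1, n + 1):
        c = chain_of[g - 1]
        res_counter[c] += 1
        letter = seq[g - 1]
        name = _residue_name(letter, spec.molecule)
        n_name = "N1" if letter in _PURINES else "N3"
        atoms = {}
        for a_idx, (key, xyz) in enumerate(coords[g].items()):
            atom_name = n_name if key == "_N" else key
            atoms[atom_name] = xyz + jitter[g - 1, a_idx]
        chains[c].residues.append(Residue(name, res_counter[c], "", atoms))
    return Structure(id=structure_id, chains=chains, source_format="pdb")


# ---------------------------------------------------------------------------
# proteins, complexes, ligands

_AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def build_protein(sequence: str, seed: int = 0, chain_id: str = "A",
                  origin: np.ndarray | None = None) -> Structure:
    """An idealized CA/CB helix for protein chains in hybrid complexes."""
    rng = np.random.default_rng(seed)
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    residues = []
    for i, aa in enumerate(sequence.upper()):
        theta = np.radians(100.0) * i
        ca = origin + np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
        cb = origin + np.array([3.3 * np.cos(theta), 3.3 * np.sin(theta), 1.5 * i])
        jit = rng.normal(0, 0.02, size=(2, 3))
        residues.append(Residue(_AA1TO3.get(aa, "ALA"), i + 1, "",
                                {"CA": ca + jit[0], "CB": cb + jit[1]}))
    return Structure(id="protein", chains=[Chain(chain_id, "protein", residues)])


def build_na_protein_complex(rna_spec: SecStructSpec, protein_sequence: str,
                             seed: int = 0) -> Structure:
    """RNA/DNA structure with a protein helix docked against its first stem."""
    na = build_structure(rna_spec, seed=seed, structure_id="hybrid")
    used = {ch.chain_id for ch in na.chains}
    prot_id = next(c for c in next_chain_ids(30) if c not in used)
    prot = build_protein(protein_sequence, seed=seed + 1, chain_id=prot_id,
                         origin=np.array([-11.0, 0.0, 0.0]))
    na.chains.append(prot.chains[0])
    return na


def build_ligand_complex(rna_spec: SecStructSpec, seed: int = 0,
                         ligand_name: str = "LIG") -> Structure:
    """RNA structure with a small ligand capping the first stem (pocket =
    nucleotides of the top pairs)."""
    na = build_structure(rna_spec, seed=seed, structure_id="ligand_target")
    pairs = parse_dotbracket(rna_spec.structure)
    stems = _stems(pairs)
    if not stems:
        raise ValueError("ligand placement needs at least one stem")
    top = len(stems[0]) - 1
    center = np.array([0.0, 0.0, top * RISE + 3.5])
    rng = np.random.default_rng(seed + 2)
    offsets = np.array([[0.8, 0, 0], [-0.8, 0, 0], [0, 0.8, 0.6], [0, -0.8, 0.6]])
    atoms = {f"C{i + 1}": center + off + rng.normal(0, 0.02, 3)
             for i, off in enumerate(offsets)}
    used = {ch.chain_id for ch in na.chains}
    lig_id = next(c for c in reversed(next_chain_ids(26)) if c not in used)
    na.chains.append(Chain(lig_id, "ligand", [Residue(ligand_name, 1, "", atoms)]))
    return na


# ---------------------------------------------------------------------------
# assemblies

def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_ROT_X_PI = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, -1.0]])


def build_assembly(monomer: Structure, group: str, order: int,
                   radius: float = 30.0, seed: int = 0) -> Structure:
    """Place copies of a monomer under exact Cn or Dn symmetry operators.

    ``group`` is "C" or "D"; a Dn assembly contains 2n chains (per chain
    of the monomer).  Chains are renamed A, B, C, ... in operator order.
    """
    if group not in ("C", "D"):
        raise ValueError("group must be 'C' or 'D'")
    if order < 1:
        raise ValueError("order must be >= 1")
    if group == "C" and order == 1:
        return monomer.copy()
    base = monomer.copy()
    coords = base.coordinates()
    centroid = coords.mean(axis=0)
    extent = float(coords[:, 2].max() - coords[:, 2].min()) if len(coords) else 0.0
    h = extent / 2.0 + 4.0
    ops: list[np.ndarray] = []
    shift = np.array([radius, 0.0, h if group == "D" else 0.0])
    for m in range(order):
        ops.append(_rot_z(2 * np.pi * m / order))
    if group == "D":
        for m in range(order):
            ops.append(_rot_z(2 * np.pi * m / order) @ _ROT_X_PI)

    n_monomer_chains = len(base.chains)
    ids = next_chain_ids(len(ops) * n_monomer_chains)
    chains: list[Chain] = []
    idx = 0
    for R in ops:
        for ch in base.chains:
            new_res = []
            for res in ch.residues:
                atoms = {name: R @ (pos - centroid + shift)
                         for name, pos in res.atoms.items()}
                new_res.append(Residue(res.name, res.number, res.insertion_code, atoms))
            chains.append(Chain(ids[idx], ch.polymer_type, new_res))
            idx += 1
    assembly = Structure(id=f"{monomer.id}_{group}{order}", chains=chains)
    _check_assembly_clashes(assembly)
    return assembly


def _check_assembly_clashes(assembly: Structure, min_dist: float = 1.5) -> None:
    from scipy.spatial import cKDTree

    xyz, chain_ids = [], []
    for ch in assembly.chains:
        for res in ch.residues:
            for pos in res.atoms.values():
                xyz.append(pos)
                chain_ids.append(ch.chain_id)
    tree = cKDTree(np.asarray(xyz))
    for a, b in tree.query_pairs(min_dist, output_type="ndarray"):
        if chain_ids[a] != chain_ids[b]:
            raise ValueError("assembly radius too small: inter-chain clash")


# ---------------------------------------------------------------------------
# perturbation

def _random_rotation(rng: np.random.Generator, max_angle: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0, max_angle)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def perturb_model(structure: Structure, spec: PerturbationSpec) -> Structure:
    """Deterministic degraded copy of a structure (sigma = 0 is identity)."""
    out = structure.copy()
    if spec.sigma == 0:
        return out
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "gaussian":
        for _, res in out.iter_residues():
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + rng.normal(0, spec.sigma, 3)
    elif spec.mode == "domain_shuffle":
        residues = [(ch, r) for ch, r in out.iter_residues()]
        n = len(residues)
        size = max(3, n // 3)
        start = int(rng.integers(0, max(1, n - size)))
        block = residues[start:start + size]
        pts = np.array([a for _, r in block for a in r.atoms.values()])
        center = pts.mean(axis=0)
        R = _random_rotation(rng, max_angle=0.15 * spec.sigma)
        t = rng.normal(0, spec.sigma, 3)
        for _, res in block:
            for name in res.atoms:
                res.atoms[name] = R @ (res.atoms[name] - center) + center + t
    elif spec.mode == "chain_placement":
        for ch in out.chains[1:]:
            pts = np.array([a for r in ch.residues for a in r.atoms.values()])
            center = pts.mean(axis=0)
            R = _random_rotation(rng, max_angle=0.15 * spec.sigma)
            t = rng.normal(0, 4.0 * spec.sigma, 3)
            for res in ch.residues:
                for name in res.atoms:
                    res.atoms[name] = R @ (res.atoms[name] - center) + center + t
    return out


# ---------------------------------------------------------------------------
# MSAs

def simulate_msa(seq: str, n_rows: int, target_identity: float, seed: int = 0
                 ) -> "MSA":
    """Rows mutated i.i.d. so the expected pairwise identity between two
    generated rows is approximately ``target_identity``.

    Two rows independently mutated with per-site probability q agree with
    probability (1-q)^2 + q^2/3 (uniform substitution among the three
    alternatives), which is solved for q.
    """
    from .msa import MSA

    if not 0.0 <= target_identity <= 1.0:
        raise ValueError("target_identity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    seq = seq.upper().replace("T", "U")
    if n_rows <= 1 or target_identity >= 1.0:
        return MSA(names=[f"seq{i + 1}" for i in range(max(1, n_rows))],
                   rows=[seq] * max(1, n_rows))
    disc = 1.0 - (4.0 / 3.0) * (1.0 - target_identity)
    q = 0.75 if disc < 0 else (1.0 - np.sqrt(disc)) * 0.75
    alphabet = np.array(list("ACGU"))
    base = np.array(list(seq))
    rows = [seq]
    for _ in range(n_rows - 1):
        mutate = rng.random(len(seq)) < q
        row = base.copy()
        for pos in np.nonzero(mutate)[0]:
            choices = [c for c in alphabet if c != base[pos]]
            row[pos] = choices[rng.integers(0, 3)]
        rows.append("".join(row))
    return MSA(names=[f"seq{i + 1}" for i in range(n_rows)], rows=rows)


# ---------------------------------------------------------------------------
# submissions

def simulate_submissions(targets: Mapping[str, Structure], roster: RosterSpec,
                         seed: int = 0, outdir: str | Path | None = None
                         ) -> dict:
    """Perturbed predictions per group/target with known quality ordering.

    Returns ``{"models": {group: {target: [Structure, ...]}},
    "roster": [(group, target, model_index, path-or-None)], "truth": ...}``.
    Model 1 carries the group's nominal sigma; later models degrade.
    When ``outdir`` is given, PDB files and a roster CSV are written.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    target_ids = sorted(targets)
    models: dict[str, dict[str, list[Structure]]] = {}
    roster_rows = []
    truth = {}
    for group in sorted(roster.groups):
        profile = roster.groups[group]
        n_part = int(round(profile.participation * len(target_ids)))
        chosen = sorted(rng.choice(target_ids, size=n_part, replace=False))
        models[group] = {}
        truth[group] = {}
        for target in chosen:
            sigma = profile.sigma_for(target)
            truth[group][target] = sigma
            model_list = []
            for m in range(profile.models_per_target):
                msigma = sigma * (1.0 + 0.5 * m)
                pspec = PerturbationSpec(
                    sigma=msigma, mode="gaussian",
                    seed=int(rng.integers(0, 2**31 - 1)))
                model = perturb_model(targets[target], pspec)
                model.id = f"{target}_{group}_{m + 1}"
                model_list.append(model)
                path = None
                if outdir is not None:
                    path = outdir / f"{target}_{group}_m{m + 1}.pdb"
                    write_structure(model, path)
                roster_rows.append((group, target, m + 1,
                                    str(path) if path else None))
            models[group][target] = model_list
    if outdir is not None:
        import csv as _csv

        with open(outdir / "roster.csv", "w", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow(["group", "target", "model", "path"])
            w.writerows(roster_rows)
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return {"models": models, "roster": roster_rows, "truth": truth}


# ---------------------------------------------------------------------------
# random secondary structures (for property tests and pipelines)

_LAYER_BRACKETS = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">"),
                   ("A", "a"), ("B", "b"), ("C", "c")]


def _pairs_to_dotbracket(pairs: list[tuple[int, int]], length: int) -> str:
    """Assign crossing-free layers greedily and emit a dot-bracket string
    (0-based pair positions) that decodes back to exactly ``pairs``."""
    layers: list[list[tuple[int, int]]] = []
    db = ["."] * length
    for i, j in sorted(pairs):
        for depth, members in enumerate(layers):
            if not any(i < k < j < l or k < i < l < j for k, l in members):
                members.append((i, j))
                break
        else:
            depth = len(layers)
            layers.append([(i, j)])
        if depth >= len(_LAYER_BRACKETS):
            raise ValueError("too many crossing layers for the bracket alphabet")
        op, cl = _LAYER_BRACKETS[depth]
        db[i], db[j] = op, cl
    return "".join(db)


def random_secstruct(length: int, seed: int = 0, pk_probability: float = 0.3
                     ) -> SecStructSpec:
    """A random secondary structure (nested stems, sometimes a crossing
    pseudoknot stem) with a compatible random sequence.

    Stems are contiguous blocks of stacked pairs with hairpin loops of at
    least 3 nucleotides; crossing stems are emitted on separate bracket
    layers so the dot-bracket decodes to exactly the intended pair set.
    """
    rng = np.random.default_rng(seed)
    seq = [str(c) for c in rng.choice(list("ACGU"), size=length)]
    taken = np.zeros(length, dtype=bool)
    pairs: list[tuple[int, int]] = []

    def try_stem(a: int, b: int, sl: int) -> bool:
        if a < 0 or b >= length or b - a < 2 * sl + 2:
            return False
        left = range(a, a + sl)
        right = range(b - sl + 1, b + 1)
        if taken[list(left)].any() or taken[list(right)].any():
            return False
        for t in range(sl):
            i, j = a + t, b - t
            pairs.append((i, j))
            taken[i] = taken[j] = True
            seq[j] = _COMPLEMENT[seq[i]]
        return True

    n_stems = max(1, length // 12)
    for _ in range(4 * n_stems):
        if len(pairs) >= 2 * n_stems + 4:
            break
        sl = int(rng.integers(2, 5))
        a = int(rng.integers(0, max(1, length - 2 * sl - 3)))
        span = int(rng.integers(2 * sl + 3, min(length - a, 4 * sl + 12) + 1)) \
            if length - a >= 2 * sl + 4 else 0
        if span:
            try_stem(a, a + span - 1, sl)

    if pairs and rng.random() < pk_probability:
        # a stem whose left block sits inside an existing pair's loop and
        # whose right block sits beyond it: a guaranteed crossing
        i, j = pairs[int(rng.integers(0, len(pairs)))]
        inner_free = [p for p in range(i + 1, j) if not taken[p]]
        outer_free = [p for p in range(j + 1, length) if not taken[p]]
        if len(inner_free) >= 2 and len(outer_free) >= 2:
            for t, (a, b) in enumerate(zip(inner_free[:2],
                                           sorted(outer_free[-2:],
                                                  reverse=True))):
                if not taken[a] and not taken[b] and a < b:
                    pairs.append((a, b))
                    taken[a] = taken[b] = True
                    seq[b] = _COMPLEMENT[seq[a]]
    db = _pairs_to_dotbracket(pairs, length)
    return SecStructSpec(sequence="".join(seq), structure=db)
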