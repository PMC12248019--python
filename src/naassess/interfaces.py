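"""Interface and ligand-pocket scoring for multimeric complexes.

Contacts are inter-chain residue pairs with any heavy-atom pair within a
5 A threshold (strict inequality).  ICS is the F1 over contact sets, IPS
the Jaccard coefficient over interface residues, and i-lDDT the lDDT
restricted to reference atom pairs spanning different chains.  For hybrid
complexes the NA-NA and NA-protein interface scores are combined by a
residue-count-weighted mean; protein-protein interfaces are excluded.

Ligand metrics: i-lDDT over nucleic-acid/ligand atom pairs, lDDT of the
pocket nucleotides, and the RMSD of the pocket nucleotides after
superposing the pocket.  When only a half pocket could be predicted the
score is normalized by the better target half-pocket score, capped at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .basepairs import PrecisionRecallF1
from .metrics import LDDTParams, _element_of_atom, _lddt_core, kabsch_superpose
from .structures import Correspondence, Residue, Structure, StructureError

__all__ = [
    "ContactSet",
    "InterfaceRecord",
    "LigandPocket",
    "extract_contacts",
    "ics",
    "ips",
    "interface_lddt",
    "interface_records",
    "aggregate_na_interfaces",
    "find_pocket",
    "ligand_metrics",
    "normalize_half_pocket",
    "detect_no_interaction",
]

CONTACT_THRESHOLD = 5.0
POCKET_RADIUS = 4.0

ResidueId = tuple[str, int, str]


@dataclass
class ContactSet:
    contacts: set[frozenset]  # frozensets of two ResidueId
    threshold: float = CONTACT_THRESHOLD

    def residues(self) -> set[ResidueId]:
        return {r for c in self.contacts for r in c}

    def __len__(self) -> int:
        return len(self.contacts)


@dataclass
class InterfaceRecord:
    chain_pair: tuple[str, str]
    type: str  # NA-NA | NA-protein | protein-protein
    residue_count: int
    scores: dict[str, float | None] = field(default_factory=dict)


@dataclass
class LigandPocket:
    ligand: ResidueId
    pocket_residues: set[ResidueId]
    radius: float = POCKET_RADIUS


def _heavy_atom_table(structure: Structure):
    xyz, chain_ids, rids = [], [], []
    for ch in structure.chains:
        for res in ch.residues:
            rid = (ch.chain_id, res.number, res.insertion_code)
            for name, pos in res.atoms.items():
                if _element_of_atom(name) == "H":
                    continue
                xyz.append(pos)
                chain_ids.append(ch.chain_id)
                rids.append(rid)
    return np.asarray(xyz), chain_ids, rids


def extract_contacts(structure: Structure,
                     threshold: float = CONTACT_THRESHOLD) -> ContactSet:
    """All inter-chain residue pairs with any heavy-atom distance < threshold."""
    if len(structure.chains) < 2:
        warnings.warn(f"structure {structure.id!r} has a single chain; "
                      "no inter-chain contacts", stacklevel=2)
        return ContactSet(set(), threshold)
    xyz, chain_ids, rids = _heavy_atom_table(structure)
    contacts: set[frozenset] = set()
    if len(xyz) == 0 or threshold <= 0:
        return ContactSet(contacts, threshold)
    tree = cKDTree(xyz)
    for a, b in tree.query_pairs(threshold, output_type="ndarray"):
        if chain_ids[a] == chain_ids[b]:
            continue
        if np.linalg.norm(xyz[a] - xyz[b]) >= threshold:
            continue
        contacts.add(frozenset((rids[a], rids[b])))
    return ContactSet(contacts, threshold)


def map_contacts(contacts: ContactSet, chain_map: Mapping[str, str]) -> ContactSet:
    """Relabel contact chains (model chain -> reference chain)."""
    mapped = {
        frozenset(((chain_map.get(a[0], a[0]), a[1], a[2]),
                   (chain_map.get(b[0], b[0]), b[1], b[2])))
        for a, b in (tuple(c) for c in contacts.contacts)
    }
    return ContactSet(mapped, contacts.threshold)


def ics(pred: ContactSet, ref: ContactSet) -> PrecisionRecallF1:
    """Interface contact similarity: F1 over contact sets."""
    if not ref.contacts and not pred.contacts:
        return PrecisionRecallF1.null()
    if not ref.contacts:
        return PrecisionRecallF1(0.0, None, 0.0)
    if not pred.contacts:
        return PrecisionRecallF1(None, 0.0, 0.0)
    tp = len(pred.contacts & ref.contacts)
    precision = tp / len(pred.contacts)
    recall = tp / len(ref.contacts)
    f1 = 0.0 if tp == 0 else 2 * precision * recall / (precision + recall)
    return PrecisionRecallF1(precision, recall, f1)


def ips(pred: ContactSet, ref: ContactSet) -> float | None:
    """Interface patch similarity: Jaccard over interface residues."""
    pr, rr = pred.residues(), ref.residues()
    union = pr | rr
    if not union:
        return None
    return len(pr & rr) / len(union)


def _interchain_filter(a, b, chain_ids, res_ids):
    return chain_ids[a] != chain_ids[b]


def interface_lddt(model: Structure, reference: Structure,
                   corr: Correspondence,
                   params: LDDTParams | None = None) -> float | None:
    """lDDT restricted to reference atom pairs spanning different chains."""
    params = params or LDDTParams()
    return _lddt_core(corr, params, pair_filter=_interchain_filter)


def interface_records(model: Structure, reference: Structure,
                      corr: Correspondence,
                      threshold: float = CONTACT_THRESHOLD,
                      chain_map: Mapping[str, str] | None = None
                      ) -> list[InterfaceRecord]:
    """Score every reference interface (chain pair with >=1 contact)."""
    ref_contacts = extract_contacts(reference, threshold)
    model_contacts = extract_contacts(model, threshold)
    if chain_map:
        model_contacts = map_contacts(model_contacts, dict(chain_map))
    by_pair: dict[tuple[str, str], set[frozenset]] = {}
    for c in ref_contacts.contacts:
        a, b = sorted(tuple(c), key=lambda r: r[0])
        by_pair.setdefault((a[0], b[0]), set()).add(c)
    mod_by_pair: dict[tuple[str, str], set[frozenset]] = {}
    for c in model_contacts.contacts:
        a, b = sorted(tuple(c), key=lambda r: r[0])
        mod_by_pair.setdefault((a[0], b[0]), set()).add(c)

    def iface_type(c1: str, c2: str) -> str:
        kinds = []
        for cid in (c1, c2):
            t = reference.chain(cid).polymer_type
            kinds.append("NA" if t in ("RNA", "DNA") else t)
        kinds.sort()
        if kinds == ["NA", "NA"]:
            return "NA-NA"
        if kinds == ["NA", "protein"]:
            return "NA-protein"
        return "protein-protein"

    records = []
    for (c1, c2), contacts in sorted(by_pair.items()):
        ref_set = ContactSet(contacts, threshold)
        pred_set = ContactSet(mod_by_pair.get((c1, c2), set()), threshold)
        pair_lddt = _pair_interface_lddt(corr, (c1, c2))
        records.append(InterfaceRecord(
            chain_pair=(c1, c2),
            type=iface_type(c1, c2),
            residue_count=len(ref_set.residues()),
            scores={
                "ics": ics(pred_set, ref_set).f1,
                "ips": ips(pred_set, ref_set),
                "i_lddt": pair_lddt,
            },
        ))
    return records


def _pair_interface_lddt(corr: Correspondence, pair: tuple[str, str]) -> float | None:
    wanted = set(pair)

    def filt(a, b, chain_ids, res_ids):
        return ((chain_ids[a] != chain_ids[b])
                & np.isin(chain_ids[a], list(wanted))
                & np.isin(chain_ids[b], list(wanted)))

    return _lddt_core(corr, LDDTParams(), pair_filter=filt)


def aggregate_na_interfaces(records: Sequence[InterfaceRecord],
                            metric: str) -> float | None:
    """Residue-count-weighted mean over NA-containing interfaces."""
    total_w = 0.0
    total = 0.0
    for rec in records:
        if rec.type == "protein-protein":
            continue
        value = rec.scores.get(metric)
        if value is None:
            continue
        total += rec.residue_count * value
        total_w += rec.residue_count
    if total_w == 0:
        return None
    return total / total_w


# ---------------------------------------------------------------------------
# ligand pockets

def find_pocket(reference: Structure, ligand: ResidueId,
                radius: float = POCKET_RADIUS) -> LigandPocket:
    """Nucleotides with any heavy atom within ``radius`` of the ligand."""
    lig_chain = reference.chain(ligand[0])
    lig_res = lig_chain.get(ligand[1], ligand[2])
    if lig_res is None or not lig_res.resolved:
        raise StructureError(f"ligand {ligand} not found in {reference.id!r}")
    lig_xyz = np.asarray(list(lig_res.atoms.values()))
    pocket: set[ResidueId] = set()
    for ch in reference.chains:
        if ch.polymer_type not in ("RNA", "DNA"):
            continue
        for res in ch.residues:
            if not res.resolved:
                continue
            xyz = np.asarray(list(res.atoms.values()))
            d = np.linalg.norm(xyz[:, None, :] - lig_xyz[None, :, :], axis=2)
            if d.min() < radius:
                pocket.add((ch.chain_id, res.number, res.insertion_code))
    return LigandPocket(ligand=ligand, pocket_residues=pocket, radius=radius)


def _residue_by_id(structure: Structure, rid: ResidueId) -> Residue | None:
    if not structure.has_chain(rid[0]):
        return None
    return structure.chain(rid[0]).get(rid[1], rid[2])


def ligand_metrics(model: Structure, reference: Structure,
                   corr: Correspondence, pocket: LigandPocket
                   ) -> dict[str, float | None]:
    """i-lDDT of the NA-ligand interface, pocket lDDT, and pocket RMSD."""
    lig_model = _residue_by_id(model, pocket.ligand)
    if lig_model is None or not lig_model.resolved:
        return {"i_lddt": None, "lddt_pocket": None, "pocket_rmsd": None,
                "ligand_missing": True}
    lig_chain = pocket.ligand[0]
    pocket_ids = set(pocket.pocket_residues)

    def ligand_na_filter(a, b, chain_ids, res_ids):
        a_lig = np.asarray(chain_ids[a]) == lig_chain
        b_lig = np.asarray(chain_ids[b]) == lig_chain
        return a_lig != b_lig  # exactly one side in the ligand chain

    i_lddt = _lddt_core(corr, LDDTParams(), pair_filter=ligand_na_filter)

    # pocket lDDT: restrict correspondence to pocket nucleotides
    pocket_pairs = [
        pair for pair in corr.pairs
        if (pair[1][0].chain_id, pair[1][1].number, pair[1][1].insertion_code)
        in pocket_ids
    ]
    lddt_pocket = None
    if pocket_pairs:
        sub = Correspondence(pairs=pocket_pairs, mode=corr.mode)
        lddt_pocket = _lddt_core(sub, LDDTParams())

    pocket_rmsd = None
    xs, ys = [], []
    for (mch, mres), (rch, rres) in pocket_pairs:
        for name, rpos in rres.atoms.items():
            mpos = mres.atoms.get(name)
            if mpos is not None:
                xs.append(mpos)
                ys.append(rpos)
    if len(xs) >= 3:
        pocket_rmsd = kabsch_superpose(np.asarray(xs), np.asarray(ys)).rmsd
    return {"i_lddt": i_lddt, "lddt_pocket": lddt_pocket,
            "pocket_rmsd": pocket_rmsd, "ligand_missing": False}


def normalize_half_pocket(score_model: float, score_half_A: float,
                          score_half_B: float) -> float | None:
    """Normalize a half-pocket prediction by the better target half-pocket."""
    denom = max(score_half_A, score_half_B)
    if denom <= 0:
        return None
    return min(1.0, score_model / denom)


# ---------------------------------------------------------------------------
# degenerate-model detection

def detect_no_interaction(model: Structure,
                          contact_threshold: float = CONTACT_THRESHOLD,
                          centroid_tol: float = 1.0,
                          clash_fraction: float = 0.5) -> bool:
    """True when a multimer model predicts no meaningful inter-chain
    interactions: either fully separated chains (zero contacts) or chains
    piled on top of each other (coincident centroids with mostly clashing
    atom pairs)."""
    if len(model.chains) < 2:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        contacts = extract_contacts(model, contact_threshold)
    if len(contacts) == 0:
        return True
    coords = {}
    for ch in model.chains:
        pts = [a for res in ch.residues for a in res.atoms.values()]
        if pts:
            coords[ch.chain_id] = np.asarray(pts)
    ids = sorted(coords)
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            A, B = coords[ids[x]], coords[ids[y]]
            if np.linalg.norm(A.mean(axis=0) - B.mean(axis=0)) > centroid_tol:
                continue
            d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
            # fraction of atoms whose nearest other-chain atom clashes
            frac = 0.5 * (np.mean(d.min(axis=1) < 2.0)
                          + np.mean(d.min(axis=0) < 2.0))
            if frac > clash_fraction:
                return True
    return False
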