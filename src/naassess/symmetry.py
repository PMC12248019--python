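"""Stoichiometry inference and Cn/Dn point-group detection.

Chains are clustered into entities at >=95% sequence identity (tolerating
minor crystallization mutations) and reported in the conventional
``A4B2`` notation, copies in descending count.  Symmetry detection works
on phosphate (P) positions for nucleic acids and C-alpha positions for
proteins: candidate groups are every cyclic Ck with k dividing the chain
count and every dihedral Dk with 2k dividing it.  For each candidate the
principal axes of the chain-centroid cloud provide trial symmetry axes;
the structure is rotated by each group element and matched to itself
under the best chain permutation, and the mean RMSD over all non-identity
elements is the fit error.  Among candidates fitting within the RMSD
cutoff (default 10 A) the assignment with the most chains involved, then
the most symmetry elements, wins, with dihedral groups preferred over
cyclic on ties (so D4 beats C8).  C1 is the universal fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from scipy.optimize import linear_sum_assignment

from .structures import Chain, Structure

__all__ = [
    "Stoichiometry",
    "SymmetryAssignment",
    "infer_stoichiometry",
    "stoichiometry_accuracy",
    "detect_symmetry",
    "symmetry_accuracy",
]

ENTITY_IDENTITY = 0.95
RMSD_CUTOFF = 10.0


@dataclass(frozen=True)
class Stoichiometry:
    counts: tuple[tuple[str, int], ...]  # ((entity letter, copies), ...)

    @property
    def label(self) -> str:
        return "".join(f"{e}{n}" for e, n in self.counts)

    def __str__(self) -> str:
        return self.label


@dataclass
class SymmetryAssignment:
    group: str  # "C" or "D"
    order: int
    chains_involved: int
    n_elements: int
    fit_rmsd: float

    @property
    def label(self) -> str:
        return f"{self.group}{self.order}"

    def same_symmetry(self, other: "SymmetryAssignment") -> bool:
        return (self.group, self.order) == (other.group, other.order)


# ---------------------------------------------------------------------------
# stoichiometry

def _sequence_identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    result = edlib.align(a, b, task="distance")
    return 1.0 - result["editDistance"] / max(len(a), len(b))


def infer_stoichiometry(structure: Structure,
                        identity_threshold: float = ENTITY_IDENTITY) -> Stoichiometry:
    """Cluster polymer chains into entities and build the A4B2-style label."""
    chains = structure.polymer_chains()
    if not chains:
        raise ValueError(f"structure {structure.id!r} has no polymer chains")
    entities: list[list[Chain]] = []
    for ch in chains:
        for members in entities:
            if _sequence_identity(ch.sequence(), members[0].sequence()) >= identity_threshold:
                members.append(ch)
                break
        else:
            entities.append([ch])
    sizes = sorted((len(m) for m in entities), reverse=True)
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    return Stoichiometry(tuple((letters[i], n) for i, n in enumerate(sizes)))


def stoichiometry_accuracy(predictions: list[Stoichiometry],
                           accepted: set[Stoichiometry] | set[str]) -> float:
    """Percentage of predictions matching any accepted stoichiometry."""
    if not predictions:
        raise ValueError("empty prediction list")
    if not accepted:
        raise ValueError("empty accepted set")
    accepted_labels = {a.label if isinstance(a, Stoichiometry) else str(a)
                       for a in accepted}
    hits = sum(1 for p in predictions if p.label in accepted_labels)
    return 100.0 * hits / len(predictions)


# ---------------------------------------------------------------------------
# symmetry detection

def _chain_points(ch: Chain) -> np.ndarray:
    """Phosphate positions for nucleic acids, C-alpha for proteins."""
    name = "P" if ch.polymer_type in ("RNA", "DNA") else "CA"
    pts = [res.atoms[name] for res in ch.residues if name in res.atoms]
    if not pts:  # fall back to every atom's centroid per residue
        pts = [np.mean(list(res.atoms.values()), axis=0)
               for res in ch.residues if res.resolved]
    return np.asarray(pts, dtype=float)


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _element_rmsd(points: list[np.ndarray], centroids: np.ndarray,
                  R: np.ndarray, center: np.ndarray) -> float:
    """RMSD between the structure and its image under one symmetry element,
    matching chains by rotated-centroid proximity (optimal assignment)."""
    rot_centroids = (centroids - center) @ R.T + center
    cost = np.linalg.norm(rot_centroids[:, None, :] - centroids[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    total, count = 0.0, 0
    for i, j in zip(rows, cols):
        pi, pj = points[i], points[j]
        n = min(len(pi), len(pj))
        if n == 0:
            return np.inf
        diff = (pi[:n] - center) @ R.T + center - pj[:n]
        total += float(np.sum(diff * diff))
        count += n
    return float(np.sqrt(total / count)) if count else np.inf


def _candidate_axes(centroids: np.ndarray) -> list[np.ndarray]:
    """Principal axes of the chain-centroid cloud (all three, most
    symmetric-variance first)."""
    centered = centroids - centroids.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    return [v[:, i] for i in np.argsort(w)]  # smallest-variance axis first


def _perp_axis_candidates(axis: np.ndarray, centroids: np.ndarray,
                          center: np.ndarray) -> list[np.ndarray]:
    """Candidate 2-fold axes perpendicular to the main axis, pointing at
    chain centroids and at midpoints of centroid pairs."""
    cands = []
    axis = axis / np.linalg.norm(axis)
    targets = list(centroids)
    for i in range(len(centroids)):
        for j in range(i + 1, len(centroids)):
            targets.append(0.5 * (centroids[i] + centroids[j]))
    for tgt in targets:
        v = tgt - center
        v = v - np.dot(v, axis) * axis
        n = np.linalg.norm(v)
        if n > 1e-6:
            cands.append(v / n)
    if not cands:
        ref = np.array([1.0, 0.0, 0.0])
        v = ref - np.dot(ref, axis) * axis
        cands.append(v / np.linalg.norm(v))
    return cands


def _divisors(n: int) -> list[int]:
    return [k for k in range(2, n + 1) if n % k == 0]


def detect_symmetry(structure: Structure,
                    rmsd_cutoff: float = RMSD_CUTOFF) -> SymmetryAssignment:
    """Detect the highest-order Cn/Dn point group of a homo-oligomer."""
    chains = structure.polymer_chains()
    n = len(chains)
    c1 = SymmetryAssignment("C", 1, chains_involved=n, n_elements=1, fit_rmsd=0.0)
    if n < 2:
        return c1
    points = [_chain_points(ch) for ch in chains]
    if any(len(p) == 0 for p in points):
        return c1
    centroids = np.asarray([p.mean(axis=0) for p in points])
    center = centroids.mean(axis=0)
    axes = _candidate_axes(centroids)

    candidates: list[SymmetryAssignment] = []
    for k in _divisors(n):
        best = np.inf
        for axis in axes:
            rmsds = []
            for m in range(1, k):
                R = _rotation_about(axis, 2 * np.pi * m / k)
                rmsds.append(_element_rmsd(points, centroids, R, center))
            best = min(best, float(np.mean(rmsds)))
        if best <= rmsd_cutoff:
            candidates.append(SymmetryAssignment(
                "C", k, chains_involved=n, n_elements=k, fit_rmsd=best))

    for k in _divisors(n):  # dihedral groups start at D2
        if (2 * k) > n or n % (2 * k) != 0:
            continue
        best = np.inf
        for axis in axes:
            main_rmsds = []
            for m in range(1, k):
                R = _rotation_about(axis, 2 * np.pi * m / k)
                main_rmsds.append(_element_rmsd(points, centroids, R, center))
            # best perpendicular 2-fold axis, then the remaining k-1 flips
            # follow by composition with the main rotations
            best_perp = np.inf
            for perp in _perp_axis_candidates(axis, centroids, center):
                R2 = _rotation_about(perp, np.pi)
                r = _element_rmsd(points, centroids, R2, center)
                if r < best_perp:
                    best_perp = r
                    best_perp_axis = perp
            if not np.isfinite(best_perp):
                continue
            flip_rmsds = [best_perp]
            for m in range(1, k):
                Rm = _rotation_about(axis, 2 * np.pi * m / k)
                R2 = _rotation_about(best_perp_axis, np.pi)
                flip_rmsds.append(_element_rmsd(points, centroids, Rm @ R2, center))
            total = float(np.mean(main_rmsds + flip_rmsds))
            best = min(best, total)
        if best <= rmsd_cutoff:
            candidates.append(SymmetryAssignment(
                "D", k, chains_involved=n, n_elements=2 * k, fit_rmsd=best))

    if not candidates:
        return c1
    # most chains involved, then most elements, dihedral preferred on ties
    candidates.sort(key=lambda a: (a.chains_involved, a.n_elements,
                                   a.group == "D", -a.fit_rmsd))
    return candidates[-1]


def symmetry_accuracy(predictions: list[SymmetryAssignment],
                      reference: SymmetryAssignment) -> float | None:
    """Percentage of predictions with the reference (group, order)."""
    if not predictions:
        return None
    hits = sum(1 for p in predictions if p.same_symmetry(reference))
    return 100.0 * hits / len(predictions)
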