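# naassess

Assessment of predicted nucleic-acid structures and complexes.

Blind-prediction challenges for RNA and DNA structure need a scoring
stack that treats every kind of target the same way: monomeric RNAs,
DNA aptamers, symmetric RNA homo-oligomers, protein–nucleic-acid hybrid
complexes, and NA–ligand pockets. `naassess` provides that stack for
assessors and method developers: biomolecule-agnostic accuracy metrics,
base-pair topology scoring, interface and ligand-pocket metrics,
stoichiometry/symmetry checks, MSA depth, an outlier-robust group
ranking, and a synthetic-structure generator that makes the whole
pipeline testable without any external data.

## What it computes

**Global metrics** (representative atoms: C4′ for nucleic acids, CA for
proteins; all scores on a 0–1 scale):

- **TM-score** — length-normalized superposition score,
  `max over superpositions of (1/L_ref) Σᵢ 1/(1 + (dᵢ/d₀)²)`, with the
  nucleic-acid `d₀(L) = 0.6 √(L − 0.5) − 2.5` (floored at 0.3 Å).
- **GDT_TS** — mean fraction of residues superposable within 1/2/4/8 Å
  (computed exactly for small structures, by a seeded multi-phase search
  otherwise; a CLI flag reports the traditional 0–100 scale).
- **lDDT** — superposition-free fraction of preserved local interatomic
  distances at thresholds 0.5/1/2/4 Å within a 15 Å inclusion radius,
  with a steric penalty: model atom pairs closer than the van-der-Waals
  contact distance minus 1.5 Å count as unpreserved.
- **TM-align score** — the same TM functional over a sequence-independent
  structural alignment, for comparing targets with templates of
  different sequence.

**Base pairs** (geometric annotation or ingestion of dot-bracket /
pair-list CSV): canonical Watson–Crick–Franklin + wobble pairs,
partitioned into crossed (pseudoknot), singlet, non-canonical, and
intermolecular classes, scored with precision/recall/F1 under explicit
conventions (overprediction → 0, dual absence → no score, missing
submission → 0).

**Interfaces and ligands**: ICS (F1 over inter-chain residue contacts at
5 Å), IPS (Jaccard over interface residues), i-lDDT (lDDT restricted to
inter-chain atom pairs), residue-count-weighted aggregation over
NA-containing interfaces, ligand-pocket lDDT/RMSD with half-pocket
normalization, and a detector for degenerate models (fully separated or
piled-up chains).

**Assemblies**: stoichiometry inference at 95% sequence identity
("A4B2" notation) and Cn/Dn point-group detection with a 10 Å fit
cutoff, selecting the assignment with the most chains, then the most
symmetry elements, dihedral preferred on ties (D4 beats C8).

**Ranking**: per-metric best over up to 5 models and all references,
one-pass outlier-trimmed Z-scores (scores ≥ 2 SD below the mean are
excluded from the trimmed statistics), weighted category combinations

```
Z_monomer  = 0.3 Z_TM + 0.3 Z_GDT + 0.4 Z_lDDT
Z_complex  = 0.3 Z_monomer-blend + 0.7 (Z_ICS + Z_IPS + Z_i-lDDT)/3
Z_ligand   = 0.5 Z_i-lDDT + 0.5 Z_lDDT-pocket
```

same-sequence target grouping, flooring of negative Z at zero, a 60%
participation filter, and 68.2% bootstrap confidence intervals from
1,000 target resamples.

**MSA depth**: Neff = Σ 1/wₛ where wₛ counts sequences (self included)
with pairwise identity above 0.8, dual-gap columns ignored.

## Worked example

```python
import naassess as na

spec = na.SecStructSpec("GGGGGGAAAACCCCCC", "((((((....))))))")
reference = na.build_structure(spec, seed=11, structure_id="toy")
model = na.perturb_model(reference, na.PerturbationSpec(sigma=0.5, seed=5))

corr = na.residue_correspondence(model, reference)
print(f"TM-score : {na.tm_score(model, reference, corr):.3f}")
print(f"GDT_TS   : {na.gdt_ts(model, reference, corr):.3f}")
print(f"lDDT     : {na.lddt(model, reference, corr):.3f}")

inv_ref = na.classify_topology(na.annotate_pairs(reference))
inv_mod = na.classify_topology(na.annotate_pairs(model))
f1 = na.score_f1(inv_mod.all_canonical, inv_ref.all_canonical)
print(f"base-pair F1: {f1.f1:.3f}")

asm = na.build_assembly(reference, "D", 2, radius=30.0)
sym = na.detect_symmetry(asm)
print(f"assembly: {na.infer_stoichiometry(asm).label}, "
      f"symmetry {sym.label}, fit RMSD {sym.fit_rmsd:.2f} A")
```

prints

```
TM-score : 0.234
GDT_TS   : 0.938
lDDT     : 0.858
base-pair F1: 0.500
assembly: A4, symmetry D2, fit RMSD 0.00 A
```

A per-atom noise of 0.5 Å leaves local geometry largely intact (high
GDT_TS and lDDT) while the TM-score is low because d₀ for a 16-mer is
only 0.3 Å — short chains are judged very strictly. Half the stem pairs
no longer meet the strict hydrogen-bond geometry (recall 0.333, F1 0.5),
and the exactly constructed dihedral tetramer is recognized as D2 with
zero fit error.

The same flow scales to a full assessment: describe targets, references,
models, category weights, grouping sets, and exclusions in one YAML file
and run `naassess run config.yaml` (or `naassess score / secstruct /
symmetry / neff / simulate` for individual stages). Reports are tidy
CSVs plus a summary JSON.

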