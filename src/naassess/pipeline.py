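"""End-to-end assessment orchestration.

``run_assessment`` ingests a configuration describing targets (each with
one or more reference structures, a category, and submitted models per
group), scores every model with the metrics of its category, reduces to
per-group bests, computes outlier-trimmed Z-scores, combines them with
the category weights, applies same-sequence grouping / flooring / the
participation filter, and attaches bootstrap confidence intervals.
Reports are tidy CSV tables plus a summary JSON.

Missing-data policy (centralized here): a model that cannot be scored for
a metric is recorded as missing and simply does not enter the best-of
reduction; a group with no scoreable model for a target has no Z for that
target (it contributes 0 after flooring).  Base-pair F1 is the exception:
no submission scores 0, while dual absence of an interaction type is a
null that drops out of means.  Exclusions (group, target) are applied
before reduction and logged, never silently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import basepairs, interfaces, ranking
from .metrics import gdt_ts, lddt, tm_score
from .structures import (Structure, StructureError, chain_mapping_search,
                         read_structure, residue_correspondence)
from .symmetry import detect_symmetry, infer_stoichiometry

logger = logging.getLogger("naassess")

__all__ = ["TargetSpec", "AssessmentConfig", "run_assessment",
           "validate_submission", "load_config"]


@dataclass
class TargetSpec:
    target_id: str
    category: str  # monomer | multimer | hybrid | ligand
    references: list[Structure]
    models: dict[str, list[Structure]]  # group -> up to 5 models
    ligand: tuple[str, int, str] | None = None  # ligand residue for pockets
    pair_annotations: dict | None = None  # optional pre-computed pair lists


@dataclass
class AssessmentConfig:
    targets: list[TargetSpec]
    grouping: Sequence[Sequence[str]] = ()
    exclusions: Sequence[tuple[str, str]] = ()  # (group, target)
    seed: int = 0
    output_dir: Path | None = None
    zconfig: ranking.ZScoreConfig = field(default_factory=ranking.ZScoreConfig)

    def __post_init__(self):
        if not self.targets:
            raise ValueError("assessment needs at least one target")
        known = {t.target_id for t in self.targets}
        for group_set in self.grouping:
            for t in group_set:
                if t not in known:
                    raise ValueError(f"grouping references unknown target {t!r}")


# ---------------------------------------------------------------------------
# per-model scoring

def _score_model(model: Structure, reference: Structure, category: str,
                 target: TargetSpec) -> dict[str, float | None]:
    scores: dict[str, float | None] = {}
    chain_map = None
    if len(reference.polymer_chains()) > 1:
        try:
            chain_map = chain_mapping_search(model, reference)
        except StructureError as exc:
            logger.warning("chain mapping failed for %s vs %s: %s",
                           model.id, reference.id, exc)
            return {}
    try:
        corr = residue_correspondence(model, reference, chain_map=chain_map)
    except StructureError as exc:
        logger.warning("no correspondence for %s vs %s: %s",
                       model.id, reference.id, exc)
        return {}
    for name, fn in (("tm_score", tm_score), ("gdt_ts", gdt_ts), ("lddt", lddt)):
        try:
            scores[name] = fn(model, reference, corr)
        except StructureError as exc:
            logger.warning("%s failed for %s: %s", name, model.id, exc)
            scores[name] = None
    if category in ("multimer", "hybrid"):
        model_map = {v: k for k, v in (chain_map or {}).items()}
        records = interfaces.interface_records(model, reference, corr,
                                               chain_map=model_map)
        for metric in ("ics", "ips", "i_lddt"):
            scores[metric] = interfaces.aggregate_na_interfaces(records, metric)
        scores["no_interaction_flag"] = float(
            interfaces.detect_no_interaction(model))
    if category == "ligand" and target.ligand is not None:
        pocket = interfaces.find_pocket(reference, target.ligand)
        lm = interfaces.ligand_metrics(model, reference, corr, pocket)
        scores["i_lddt"] = lm["i_lddt"]
        scores["lddt_pocket"] = lm["lddt_pocket"]
        scores["pocket_rmsd"] = lm["pocket_rmsd"]
    return scores


_RANKED_METRICS = {
    "monomer": ["tm_score", "gdt_ts", "lddt"],
    "multimer": ["tm_score", "gdt_ts", "lddt", "ics", "ips", "i_lddt"],
    "hybrid": ["tm_score", "gdt_ts", "lddt", "ics", "ips", "i_lddt"],
    "ligand": ["i_lddt", "lddt_pocket"],
}


def run_assessment(config: AssessmentConfig) -> dict:
    """Score, reduce, rank, and report.  Returns a dict of DataFrames and
    summary values; writes CSV/JSON reports when an output directory is
    configured."""
    excluded = set(map(tuple, config.exclusions))
    rows = []
    symmetry_rows = []
    f1_scores: dict[str, dict[str, dict[str, list]]] = {}
    for target in config.targets:
        ref_invs = None
        if target.category in ("monomer", "multimer"):
            ref_invs = [basepairs.classify_topology(basepairs.annotate_pairs(ref))
                        for ref in target.references]
        if target.category == "multimer":
            ref_sym = detect_symmetry(target.references[0])
            symmetry_rows.append({
                "target": target.target_id, "group": "<reference>",
                "stoichiometry": infer_stoichiometry(target.references[0]).label,
                "symmetry": ref_sym.label, "fit_rmsd": ref_sym.fit_rmsd,
            })
        for group, models in sorted(target.models.items()):
            if (group, target.target_id) in excluded:
                logger.info("excluding %s on %s (exclusion list)",
                            group, target.target_id)
                continue
            for model_idx, model in enumerate(models, start=1):
                for ref_idx, reference in enumerate(target.references):
                    scores = _score_model(model, reference, target.category, target)
                    for metric, value in scores.items():
                        rows.append({
                            "target": target.target_id, "group": group,
                            "model": model_idx, "reference": ref_idx,
                            "metric": metric, "value": value,
                        })
                if target.category == "multimer":
                    sym = detect_symmetry(model)
                    symmetry_rows.append({
                        "target": target.target_id, "group": group,
                        "stoichiometry": infer_stoichiometry(model).label,
                        "symmetry": sym.label, "fit_rmsd": sym.fit_rmsd,
                    })
            if ref_invs is not None:
                _collect_f1(f1_scores, target, group, models, ref_invs)

    score_table = pd.DataFrame(rows)
    if score_table.empty:
        raise ValueError("no models could be scored")

    # ranking per category
    results = {}
    catz_frames = []
    for category, sub in score_table.groupby(
            score_table["target"].map({t.target_id: t.category
                                       for t in config.targets})):
        metrics = _RANKED_METRICS[category]
        best = ranking.reduce_best(sub[sub["metric"].isin(metrics)])
        ztable = ranking.trimmed_z_table(best, config.zconfig.outlier_sd)
        catz = ranking.category_z(ztable, category, config.zconfig)
        cat_targets = [t.target_id for t in config.targets
                       if t.category == category]
        res = ranking.sum_ranking(catz, config.grouping, config.zconfig,
                                  all_targets=cat_targets)
        if res.per_unit_z.shape[1] >= 1 and len(res.per_unit_z) > 0:
            res.intervals = ranking.bootstrap_ci(
                res.per_unit_z, config.zconfig.bootstrap_replicates,
                config.zconfig.ci_level, config.seed)
        results[category] = res
        catz["category"] = category
        catz_frames.append(catz)

    # overall ranking: categories summed
    overall = None
    if results:
        overall = (pd.concat([r.summed_z.rename(c) for c, r in results.items()],
                             axis=1)
                   .fillna(0.0))
        overall["total"] = overall.sum(axis=1)
        overall = overall.sort_values("total", ascending=False)

    # base-pair F1 report
    f1_rows = []
    bp_targets = [t.target_id for t in config.targets
                  if t.category in ("monomer", "multimer")]
    for klass, per_group in f1_scores.items():
        means = basepairs.aggregate_f1(per_group, bp_targets)
        for group, mean in means.items():
            f1_rows.append({"class": klass, "group": group, "mean_f1": mean})
    f1_table = pd.DataFrame(f1_rows)

    out = {
        "scores": score_table,
        "rankings": results,
        "overall": overall,
        "basepair_f1": f1_table,
        "symmetry": pd.DataFrame(symmetry_rows),
    }
    if config.output_dir is not None:
        _write_reports(out, config)
    return out


_F1_CLASSES = ("all_canonical", "crossed", "singlet", "noncanonical",
               "intermolecular")


def _collect_f1(f1_scores, target: TargetSpec, group: str,
                models: Sequence[Structure], ref_invs) -> None:
    unresolved = set()
    for ref in target.references:
        for ch in ref.chains:
            for res in ch.residues:
                if not res.resolved:
                    unresolved.add((ch.chain_id, res.number, res.insertion_code))
    for model in models:
        inv_m = basepairs.classify_topology(basepairs.annotate_pairs(model))
        for klass in _F1_CLASSES:
            for inv_r in ref_invs:
                score = basepairs.score_f1(inv_m.by_class(klass),
                                           inv_r.by_class(klass),
                                           unresolved=unresolved)
                (f1_scores.setdefault(klass, {})
                 .setdefault(group, {})
                 .setdefault(target.target_id, [])
                 .append(score))


def _write_reports(out: dict, config: AssessmentConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    out["scores"].to_csv(outdir / "scores_models.csv", index=False)
    if not out["basepair_f1"].empty:
        out["basepair_f1"].to_csv(outdir / "basepair_f1.csv", index=False)
    if not out["symmetry"].empty:
        out["symmetry"].to_csv(outdir / "symmetry.csv", index=False)
    summary = {"categories": {}, "excluded": list(map(list, config.exclusions))}
    for category, res in out["rankings"].items():
        frame = res.summed_z.rename("summed_z").to_frame()
        if res.intervals is not None:
            frame = frame.join(res.intervals)
        frame.to_csv(outdir / f"ranking_{category}.csv")
        summary["categories"][category] = {
            "excluded_groups": res.excluded_groups,
            "top_group": res.summed_z.index[0] if len(res.summed_z) else None,
        }
    if out["overall"] is not None:
        out["overall"].to_csv(outdir / "ranking_overall.csv")
        summary["overall_top"] = (out["overall"].index[0]
                                  if len(out["overall"]) else None)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))


# ---------------------------------------------------------------------------
# submission validation

def validate_submission(model: Structure,
                        target_spec: Mapping[str, str]) -> list[str]:
    """Diagnostics only: sequence mismatches, missing chains, degenerate
    geometry.  ``target_spec`` maps chain id -> expected sequence."""
    diagnostics = []
    for chain_id, expected in target_spec.items():
        if not model.has_chain(chain_id):
            diagnostics.append(f"missing chain {chain_id}")
            continue
        got = model.chain(chain_id).sequence()
        if len(got) != len(expected):
            diagnostics.append(
                f"chain {chain_id}: length {len(got)} != expected {len(expected)}")
        else:
            mismatches = [i + 1 for i, (a, b) in enumerate(zip(got, expected))
                          if a != b]
            if mismatches:
                diagnostics.append(
                    f"chain {chain_id}: sequence mismatch at positions "
                    f"{mismatches[:10]}")
    if len(model.chains) > 1:
        # atoms piled at one point (e.g. every chain after the first at the
        # origin) or chains without any meaningful interaction
        for ch in model.chains[1:]:
            pts = np.array([a for r in ch.residues for a in r.atoms.values()])
            if len(pts) > 3 and float(pts.std()) < 1e-3:
                diagnostics.append(
                    f"chain {ch.chain_id}: degenerate geometry (atoms piled "
                    "at a point)")
        if interfaces.detect_no_interaction(model):
            diagnostics.append("no meaningful inter-chain interactions "
                               "(overlapping or fully separated chains)")
    return diagnostics


# ---------------------------------------------------------------------------
# config loading

def load_config(path: str | Path) -> AssessmentConfig:
    """Build an :class:`AssessmentConfig` from a YAML/JSON file.

    Schema::

        seed: 7
        output_dir: reports/
        grouping: [[T1, T2]]
        exclusions: [[group_b, T3]]
        targets:
          - id: T1
            category: monomer
            references: [ref/T1.pdb]
            ligand: [L, 1]            # ligand chain/residue (ligand category)
            models:
              group_a: [models/T1_a_1.pdb, models/T1_a_2.pdb]
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    targets = []
    for tdef in raw["targets"]:
        refs = [read_structure(_resolve(p)) for p in tdef["references"]]
        models = {g: [read_structure(_resolve(p)) for p in paths]
                  for g, paths in tdef.get("models", {}).items()}
        ligand = None
        if "ligand" in tdef:
            lig = tdef["ligand"]
            ligand = (str(lig[0]), int(lig[1]), str(lig[2]) if len(lig) > 2 else "")
        targets.append(TargetSpec(
            target_id=str(tdef["id"]), category=tdef["category"],
            references=refs, models=models, ligand=ligand))
    zconfig = ranking.ZScoreConfig(**raw.get("zscore", {}))
    zconfig.seed = int(raw.get("seed", 0))
    return AssessmentConfig(
        targets=targets,
        grouping=[list(g) for g in raw.get("grouping", [])],
        exclusions=[tuple(e) for e in raw.get("exclusions", [])],
        seed=int(raw.get("seed", 0)),
        output_dir=_resolve(raw["output_dir"]) if "output_dir" in raw else None,
        zconfig=zconfig,
    )
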