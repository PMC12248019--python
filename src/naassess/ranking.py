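"""Z-score ranking: best-of-model reduction, outlier-trimmed Z-scores,
weighted category combination, same-sequence target grouping, floor-at-
zero summation, a participation filter, and bootstrap confidence
intervals.

The trimming procedure makes one pass: scores two or more (sample)
standard deviations below the initial mean are set aside, the mean and
standard deviation are recomputed without them, and every score —
including the outliers — is standardized against the trimmed statistics.
A zero trimmed standard deviation yields Z = 0 for every group.

Category weights follow the assessment scheme:

* nucleic-acid monomer: ``0.3 Z_TM + 0.3 Z_GDT + 0.4 Z_lDDT``
* multimer / hybrid: ``0.3 (monomer blend) + 0.7 (Z_ICS + Z_IPS + Z_ilDDT)/3``
* ligand: ``0.5 Z_ilDDT + 0.5 Z_lDDTpocket``

For the summed ranking, targets sharing a sequence count once (their best
Z), negative Z-scores are floored at zero, and groups participating in
fewer than 60% of a category's scoring units are excluded.  Confidence
intervals come from 1,000 bootstrap replicates over targets at the 68.2%
central-percentile level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ZScoreConfig",
    "RankingResult",
    "reduce_best",
    "trimmed_z",
    "trimmed_z_table",
    "category_z",
    "sum_ranking",
    "bootstrap_ci",
]

MONOMER_WEIGHTS = {"tm_score": 0.3, "gdt_ts": 0.3, "lddt": 0.4}
INTERFACE_WEIGHTS = {"ics": 1 / 3, "ips": 1 / 3, "i_lddt": 1 / 3}
LIGAND_WEIGHTS = {"i_lddt": 0.5, "lddt_pocket": 0.5}


@dataclass
class ZScoreConfig:
    outlier_sd: float = 2.0
    participation_min: float = 0.6
    floor_at_zero: bool = True
    monomer_weight_in_complex: float = 0.3
    bootstrap_replicates: int = 1000
    ci_level: float = 68.2
    seed: int = 0


@dataclass
class RankingResult:
    summed_z: pd.Series  # per group
    per_unit_z: pd.DataFrame  # group x scoring unit (floored contributions)
    excluded_groups: list[str] = field(default_factory=list)
    intervals: pd.DataFrame | None = None  # columns lo, hi per group


# ---------------------------------------------------------------------------
# best-of reduction

def reduce_best(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-metric best over models and references.

    Input: tidy frame with columns (group, target, metric, value) plus any
    of (model, reference).  Output: one row per (group, target, metric)
    with the maximal value, metrics decoupled.
    """
    required = {"group", "target", "metric", "value"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"score table lacks columns {sorted(missing)}")
    df = scores.dropna(subset=["value"])
    best = (df.groupby(["group", "target", "metric"], as_index=False)["value"]
            .max())
    return best


# ---------------------------------------------------------------------------
# trimmed Z

def trimmed_z(values: Mapping[str, float] | pd.Series,
              outlier_sd: float = 2.0) -> pd.Series:
    """One-pass low-side outlier-trimmed Z-scores for one target-metric."""
    s = pd.Series(dict(values), dtype=float) if not isinstance(values, pd.Series) \
        else values.astype(float)
    if len(s) < 2:
        return pd.Series(0.0, index=s.index)
    mean0 = s.mean()
    sd0 = s.std(ddof=1)
    if sd0 > 0:
        # "2 or more standard deviations below the mean" -> trimmed
        kept = s[s > mean0 - outlier_sd * sd0]
    else:
        kept = s
    mean1 = kept.mean()
    sd1 = kept.std(ddof=1) if len(kept) > 1 else 0.0
    if not np.isfinite(sd1) or sd1 == 0:
        return pd.Series(0.0, index=s.index)
    return (s - mean1) / sd1


def trimmed_z_table(best: pd.DataFrame, outlier_sd: float = 2.0) -> pd.DataFrame:
    """Z-scores per (group, target, metric) from a reduced score table."""
    frames = []
    for (target, metric), sub in best.groupby(["target", "metric"]):
        z = trimmed_z(sub.set_index("group")["value"], outlier_sd)
        frames.append(pd.DataFrame({
            "group": z.index, "target": target, "metric": metric, "z": z.values,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# category combination

def category_z(ztable: pd.DataFrame, category: str,
               config: ZScoreConfig | None = None) -> pd.DataFrame:
    """Weighted Z combination for one category.

    Returns a frame with columns (group, target, z).  Missing interface or
    pocket components are omitted with their weights renormalized, and the
    affected rows flagged in a ``renormalized`` column.
    """
    config = config or ZScoreConfig()
    if category in ("monomer", "NA"):
        weight_sets = [(1.0, MONOMER_WEIGHTS)]
    elif category in ("multimer", "hybrid"):
        weight_sets = [(config.monomer_weight_in_complex, MONOMER_WEIGHTS),
                       (1.0 - config.monomer_weight_in_complex, INTERFACE_WEIGHTS)]
    elif category == "ligand":
        weight_sets = [(1.0, LIGAND_WEIGHTS)]
    else:
        raise ValueError(f"unknown category {category!r}")

    wide = ztable.pivot_table(index=["group", "target"], columns="metric",
                              values="z", aggfunc="first")
    rows = []
    for (group, target), zrow in wide.iterrows():
        total = 0.0
        renorm = False
        for block_weight, weights in weight_sets:
            avail = {m: w for m, w in weights.items()
                     if m in zrow.index and pd.notna(zrow[m])}
            if not avail:
                renorm = True
                continue
            wsum = sum(avail.values())
            if abs(wsum - sum(weights.values())) > 1e-12:
                renorm = True
            total += block_weight * sum(zrow[m] * w for m, w in avail.items()) / wsum
        rows.append({"group": group, "target": target, "z": total,
                     "renormalized": renorm})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# summed ranking

def _grouping_units(targets: Iterable[str],
                    grouping: Sequence[Sequence[str]] | None
                    ) -> dict[str, str]:
    """Map each target to its scoring-unit label (same-sequence sets
    collapse onto one unit)."""
    targets = list(dict.fromkeys(targets))
    unit_of = {t: t for t in targets}
    for group_set in grouping or ():
        members = [t for t in group_set if t in unit_of]
        if not members:
            continue
        label = "+".join(sorted(members))
        for t in members:
            unit_of[t] = label
    return unit_of


def sum_ranking(catz: pd.DataFrame,
                grouping: Sequence[Sequence[str]] | None = None,
                config: ZScoreConfig | None = None,
                all_targets: Sequence[str] | None = None) -> RankingResult:
    """Summed ranking with grouping, flooring, and participation filter."""
    config = config or ZScoreConfig()
    targets = list(all_targets) if all_targets is not None else \
        list(catz["target"].unique())
    unit_of = _grouping_units(targets, grouping)
    units = sorted(set(unit_of.values()))
    df = catz.copy()
    df["unit"] = df["target"].map(unit_of)
    # best Z within each same-sequence unit
    per_unit = (df.groupby(["group", "unit"], as_index=False)["z"].max())
    mat = per_unit.pivot_table(index="group", columns="unit", values="z",
                               aggfunc="first").reindex(columns=units)
    participation = mat.notna().mean(axis=1)
    excluded = sorted(participation[participation < config.participation_min].index)
    mat = mat.drop(index=excluded)
    floored = mat.clip(lower=0.0) if config.floor_at_zero else mat
    floored = floored.fillna(0.0)
    summed = floored.sum(axis=1).sort_values(ascending=False)
    return RankingResult(summed_z=summed, per_unit_z=floored,
                         excluded_groups=excluded)


def bootstrap_ci(per_unit_z: pd.DataFrame,
                 replicates: int = 1000,
                 level: float = 68.2,
                 seed: int = 0) -> pd.DataFrame:
    """Central percentile interval of the summed Z under target resampling.

    ``per_unit_z`` holds one column per scoring unit and one row per
    group (floored contributions).  Units are resampled with replacement;
    the interval is the central ``level``% of the resummed totals.
    """
    k = per_unit_z.shape[1]
    if k == 0:
        raise ValueError("no scoring units to resample")
    rng = np.random.default_rng(seed)
    values = per_unit_z.to_numpy()
    if k == 1:
        point = values.sum(axis=1)
        return pd.DataFrame({"lo": point, "hi": point}, index=per_unit_z.index)
    sums = np.empty((replicates, len(per_unit_z)))
    for b in range(replicates):
        cols = rng.integers(0, k, size=k)
        sums[b] = values[:, cols].sum(axis=1)
    alpha = (100.0 - level) / 2.0
    lo = np.percentile(sums, alpha, axis=0)
    hi = np.percentile(sums, 100.0 - alpha, axis=0)
    return pd.DataFrame({"lo": lo, "hi": hi}, index=per_unit_z.index)
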