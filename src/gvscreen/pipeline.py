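"""Screening decisions: replicate aggregation, ranking, layouts, titrations.

Replication is two-level: *technical* replicates are repeated measurements
of one culture and are averaged first; *biological* replicates are
independent cultures, and the reported statistic is the mean of per-culture
means with a standard error computed across cultures (sample SD, n-1
denominator, divided by sqrt(n_bio)).  A sample measured in a single
culture reports SEM 0 with n_bio = 1 as the flag.

Ranking uses the grand mean of the nonlinear difference SBR; "unique"
mutants are deduplicated by their amino-acid mutation signature (protein
identity, not DNA), keeping the best-scoring representative, with a
deterministic lexicographic tie-break on sample id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import well_name

ROLES = ("mutant", "parent", "empty")

PLATE_MAP_COLUMNS = ["well", "sample_id", "role", "bio_rep", "tech_rep", "plate"]


@dataclass(frozen=True)
class PlateMap:
    """Well -> sample assignments across one or more plates."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in PLATE_MAP_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"plate map lacks columns {missing}")
        bad_roles = sorted(set(df["role"]) - set(ROLES))
        if bad_roles:
            raise ValueError(f"invalid roles {bad_roles}")
        occupied = df[df["role"] != "empty"]
        key = occupied[["sample_id", "bio_rep", "tech_rep", "plate"]]
        if key.duplicated().any():
            dupes = key[key.duplicated()].to_dict("records")
            raise ValueError(f"duplicate (sample, bio, tech, plate) keys: {dupes}")
        wells = df[["plate", "well"]]
        if wells.duplicated().any():
            raise ValueError("the same well is assigned twice on one plate")

    @classmethod
    def from_csv(cls, path) -> "PlateMap":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class SampleResult:
    """Replicate-aggregated signal for one sample."""

    sample_id: str
    bio_means: tuple[float, ...]
    grand_mean: float
    sem: float
    n_bio: int
    n_tech: int


def aggregate(per_well: pd.DataFrame, plate_map: PlateMap) -> list[SampleResult]:
    """Two-level replicate aggregation of a per-well metric table.

    ``per_well`` needs columns ``well`` and ``value`` (and ``plate`` when
    the map spans several plates).  Technical replicates are averaged within
    each biological replicate; the grand mean and SEM are taken across
    biological replicates.  Empty wells are excluded; wells measured but
    absent from the map are an error.
    """
    if "value" not in per_well.columns or "well" not in per_well.columns:
        raise ValueError("per_well table needs 'well' and 'value' columns")
    map_df = plate_map.table
    keys = ["well", "plate"] if "plate" in per_well.columns else ["well"]
    if "plate" not in per_well.columns and map_df["plate"].nunique() > 1:
        raise ValueError("per_well table needs a 'plate' column for multi-plate maps")
    merged = per_well.merge(map_df, on=keys, how="left", validate="m:1")
    orphans = merged[merged["sample_id"].isna()]
    if len(orphans):
        raise ValueError(
            f"measured wells missing from plate map: "
            f"{sorted(orphans['well'].unique().tolist())}"
        )
    merged = merged[merged["role"] != "empty"]
    results: list[SampleResult] = []
    for sample_id, group in merged.groupby("sample_id", sort=True):
        bio = group.groupby("bio_rep", sort=True)["value"].mean()
        n_bio = len(bio)
        grand = float(bio.mean())
        sem = float(bio.std(ddof=1) / math.sqrt(n_bio)) if n_bio > 1 else 0.0
        n_tech = int(group.groupby("bio_rep")["value"].count().max())
        results.append(
            SampleResult(
                sample_id=str(sample_id),
                bio_means=tuple(float(v) for v in bio),
                grand_mean=grand,
                sem=sem,
                n_bio=n_bio,
                n_tech=n_tech,
            )
        )
    return results


def fold_change(mutant: SampleResult, parent: SampleResult) -> float:
    """Ratio of grand means (mutant over parent)."""
    if parent.grand_mean <= 0:
        raise ValueError(
            f"fold change undefined: parent {parent.sample_id!r} grand mean "
            f"{parent.grand_mean} is not positive"
        )
    return mutant.grand_mean / parent.grand_mean


@dataclass(frozen=True)
class RankedSelection:
    """Top-n unique samples, best first."""

    ranked: tuple[SampleResult, ...]
    dropped_duplicates: tuple[str, ...]  # sample_ids collapsed by signature


def rank_select_top(
    results: Sequence[SampleResult],
    mutation_keys: Mapping[str, str] | None = None,
    n: int = 10,
) -> RankedSelection:
    """Sort by grand mean (descending), collapse duplicates by mutation
    signature keeping the highest, return up to ``n``.

    Ties break lexicographically on sample_id, so the selection is
    deterministic and stable under input permutation.  Samples without a
    signature entry count as their own signature.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mutation_keys = mutation_keys or {}
    ordered = sorted(results, key=lambda r: (-r.grand_mean, r.sample_id))
    seen: set[str] = set()
    unique: list[SampleResult] = []
    dropped: list[str] = []
    for r in ordered:
        sig = mutation_keys.get(r.sample_id, r.sample_id)
        if sig in seen:
            dropped.append(r.sample_id)
            continue
        seen.add(sig)
        unique.append(r)
    return RankedSelection(tuple(unique[:n]), tuple(dropped))


@dataclass(frozen=True)
class TitrationGrid:
    """Mean/STD of the metric over a (glucose, arabinose) factorial grid."""

    glucose_levels: tuple[float, ...]
    arabinose_levels: tuple[float, ...]
    mean: np.ndarray  # shape (n_glucose, n_arabinose)
    std: np.ndarray
    argmax: tuple[float, float]
    missing_cells: tuple[tuple[float, float], ...]


def titration_summary(
    results: pd.DataFrame, population_std: bool = True
) -> TitrationGrid:
    """Summarize replicate measurements over an autoinduction titration.

    ``results`` needs columns ``glucose``, ``arabinose`` and ``value``; each
    (glucose, arabinose) cell may hold several replicates.  Per-cell mean
    and STD (population STD by default, matching how N=3 error bars are
    usually plotted) are reported together with the argmax cell and any
    missing cells of the factorial grid.
    """
    for col in ("glucose", "arabinose", "value"):
        if col not in results.columns:
            raise ValueError(f"results table needs a {col!r} column")
    if len(results) == 0:
        raise ValueError("empty titration table")
    glucose = tuple(sorted(results["glucose"].unique()))
    arabinose = tuple(sorted(results["arabinose"].unique()))
    mean = np.full((len(glucose), len(arabinose)), np.nan)
    std = np.full_like(mean, np.nan)
    missing = []
    ddof = 0 if population_std else 1
    grouped = results.groupby(["glucose", "arabinose"])["value"]
    stats = {key: (g.mean(), g.std(ddof=ddof) if len(g) > ddof else 0.0)
             for key, g in grouped}
    for i, g in enumerate(glucose):
        for j, a in enumerate(arabinose):
            if (g, a) in stats:
                mean[i, j], std[i, j] = stats[(g, a)]
            else:
                missing.append((g, a))
    flat = np.where(np.isnan(mean), -np.inf, mean)
    i, j = np.unravel_index(int(np.argmax(flat)), mean.shape)
    return TitrationGrid(
        glucose_levels=glucose,
        arabinose_levels=arabinose,
        mean=mean,
        std=std,
        argmax=(glucose[i], arabinose[j]),
        missing_cells=tuple(missing),
    )


@dataclass(frozen=True)
class TrayLayout:
    """Scan-tray capacity: phantoms per automated scan x wells per phantom."""

    phantoms_per_scan: int = 12
    wells_per_phantom: int = 96

    def __post_init__(self) -> None:
        if self.phantoms_per_scan < 0 or self.wells_per_phantom < 0:
            raise ValueError("layout counts must be >= 0")


def tray_capacity(layout: TrayLayout = TrayLayout()) -> int:
    """Samples per automated scan (default 12 x 96 = 1152)."""
    return layout.phantoms_per_scan * layout.wells_per_phantom


def build_screen_layout(
    n_mutant_picks: int,
    n_parent: int,
    wells_per_plate: int = 96,
    pick_prefix: str = "pick",
    parent_id: str = "parent",
) -> PlateMap:
    """Lay out picked colonies plus parent controls across 96-well plates.

    Picks fill consecutive wells from A1; one parent control is placed in
    the last well of each plate (so later per-plate normalization is
    possible), with any parents beyond the plate count appended after the
    picks.  380 picks + 4 parents therefore occupy 4 full plates.
    """
    if n_mutant_picks < 0 or n_parent < 0:
        raise ValueError("counts must be >= 0")
    if wells_per_plate < 1:
        raise ValueError("wells_per_plate must be >= 1")
    total = n_mutant_picks + n_parent
    n_plates = max(1, -(-total // wells_per_plate)) if total else 0
    # one parent reserved per plate while parents remain
    reserved = min(n_parent, n_plates)
    rows = []
    pick_iter = iter(range(1, n_mutant_picks + 1))
    extra_parents = n_parent - reserved
    n_cols = 12 if wells_per_plate % 12 == 0 else wells_per_plate
    parent_rep = 1
    remaining_picks = n_mutant_picks
    for plate in range(1, n_plates + 1):
        has_parent = plate <= reserved
        capacity = wells_per_plate - (1 if has_parent else 0)
        plate_rows = []
        for _ in range(min(capacity, remaining_picks)):
            k = next(pick_iter)
            plate_rows.append((f"{pick_prefix}-{k:04d}", "mutant", 1, 1))
        remaining_picks -= len(plate_rows)
        while extra_parents and len(plate_rows) < capacity:
            plate_rows.append((parent_id, "parent", parent_rep, 1))
            parent_rep += 1
            extra_parents -= 1
        if has_parent:
            plate_rows.append((parent_id, "parent", parent_rep, 1))
            parent_rep += 1
        for idx, (sid, role, bio, tech) in enumerate(plate_rows):
            r, c = divmod(idx, n_cols)
            rows.append(
                {
                    "well": well_name(r, c),
                    "sample_id": sid,
                    "role": role,
                    "bio_rep": bio,
                    "tech_rep": tech,
                    "plate": plate,
                }
            )
    return PlateMap(pd.DataFrame(rows, columns=PLATE_MAP_COLUMNS))
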