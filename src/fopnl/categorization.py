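"""Category crosswalk: launch-database categories -> THCL subgroups -> the 18
reporting groups, plus scope exclusions and per-subgroup eligibility windows.

The window logic reflects the staged roll-out of the labeling scheme: a
subgroup only contributes to uptake denominators from the year its nutrient
criteria were first published (inclusive), so e.g. a bread launched in 2018
is not counted against a criteria set that only appeared in 2019.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable, Mapping, Optional

import pandas as pd
from pydantic import BaseModel

from ._assets import load_asset
from .data_model import ProductRecord

#: the 18 reporting groups used for stratified uptake reports
REPORTING_GROUPS = (
    "bakery products",
    "bread",
    "breakfast cereal",
    "dairy products",
    "fats and oils",
    "ice cream",
    "instant foods",
    "instant tea and coffee",
    "malted and chocolate drinks",
    "plant-based milk substitutes",
    "prepared meals",
    "seasoning",
    "small meals",
    "snacks (starch- and meat-based)",
    "snacks (nut- and bean-based)",
    "soups",
    "soft drinks",
    "vegetable and fruit juices",
)

STATUS_IN_WINDOW = "assigned_in_window"
STATUS_OUT_OF_WINDOW = "assigned_out_of_window"
STATUS_EXCLUDED = "excluded"
STATUS_UNMAPPED = "unmapped"


class CategoryAssignment(BaseModel):
    thcl_subgroup: Optional[str] = None
    reporting_group: Optional[str] = None
    in_scheme_scope: bool = False
    in_eligibility_window: bool = False
    exclusion_reason: Optional[str] = None


@dataclass(frozen=True)
class SubgroupInfo:
    reporting_group: Optional[str]
    start_year: int
    hsr_hint: str
    basis: str
    anchored: bool
    fiber_homogeneous: bool


class CategoryMap:
    """The three edge sets (minor->subgroup, subgroup->group, start years)."""

    def __init__(self, data: Mapping[str, Any]):
        self.version: str = data.get("version", "unversioned")
        self.subgroups: dict[str, SubgroupInfo] = {}
        for section in ("subgroups", "extension_subgroups"):
            for name, info in (data.get(section) or {}).items():
                self.subgroups[name] = SubgroupInfo(
                    reporting_group=info.get("reporting_group"),
                    start_year=int(info["start_year"]),
                    hsr_hint=info.get("hsr_hint", "unscored"),
                    basis=info.get("basis", "per100g"),
                    anchored=bool(info.get("anchored", False)),
                    fiber_homogeneous=bool(info.get("fiber_homogeneous", False)),
                )
        self.minor_to_subgroup: dict[str, str] = {
            str(k).lower(): v for k, v in (data.get("minor_to_subgroup") or {}).items()
        }
        self.exclusions: dict[str, str] = {
            str(k).lower(): v for k, v in (data.get("exclusions") or {}).items()
        }
        self._validate()

    def _validate(self) -> None:
        groups = {
            info.reporting_group
            for info in self.subgroups.values()
            if info.reporting_group is not None
        }
        unknown = groups - set(REPORTING_GROUPS)
        if unknown:
            raise ValueError(f"unknown reporting groups in map: {sorted(unknown)}")
        missing = set(REPORTING_GROUPS) - groups
        if missing:
            raise ValueError(f"reporting groups with no subgroup: {sorted(missing)}")
        dangling = set(self.minor_to_subgroup.values()) - set(self.subgroups)
        if dangling:
            raise ValueError(f"minors mapped to unknown subgroups: {sorted(dangling)}")

    def subgroup_of(self, gnpd_minor: str) -> Optional[str]:
        return self.minor_to_subgroup.get(gnpd_minor.strip().lower())

    def info(self, subgroup: str) -> SubgroupInfo:
        return self.subgroups[subgroup]


def load_category_map(path: str | None = None) -> CategoryMap:
    return CategoryMap(load_asset(path, "category_map.yaml"))


def apply_exclusions(
    record: ProductRecord | Mapping[str, Any], cmap: CategoryMap | None = None
) -> Optional[str]:
    """Return an exclusion reason for out-of-scope categories, else ``None``."""
    cmap = cmap or load_category_map()
    if isinstance(record, ProductRecord):
        minor, major = record.gnpd_minor, record.gnpd_major
    else:
        minor, major = record.get("gnpd_minor", ""), record.get("gnpd_major", "")
    for key in (str(minor).lower().strip(), str(major).lower().strip()):
        if key in cmap.exclusions:
            return cmap.exclusions[key]
    return None


def eligibility_window(
    release_year: int, subgroup: str, cmap: CategoryMap | None = None
) -> bool:
    """True iff the release year falls at or after the subgroup's criteria
    start year (the adoption year's launches are counted)."""
    cmap = cmap or load_category_map()
    return release_year >= cmap.info(subgroup).start_year


def assign_category(
    record: ProductRecord | Mapping[str, Any], cmap: CategoryMap | None = None
) -> CategoryAssignment:
    """Assign a record to its THCL subgroup and reporting group.

    Categorization depends only on the record's category codes and release
    year — never on its nutrients. Out-of-scope categories get an exclusion
    reason; minors absent from the map get neither subgroup nor reason and
    surface in the ``unmapped`` partition.
    """
    cmap = cmap or load_category_map()
    if isinstance(record, ProductRecord):
        minor, year = record.gnpd_minor, record.release_year
    else:
        minor, year = record.get("gnpd_minor", ""), int(record.get("release_year", 0))

    reason = apply_exclusions(record, cmap)
    if reason is not None:
        return CategoryAssignment(in_scheme_scope=False, exclusion_reason=reason)

    subgroup = cmap.subgroup_of(str(minor))
    if subgroup is None:
        return CategoryAssignment(in_scheme_scope=False)

    info = cmap.info(subgroup)
    return CategoryAssignment(
        thcl_subgroup=subgroup,
        reporting_group=info.reporting_group,
        in_scheme_scope=True,
        in_eligibility_window=year >= info.start_year,
    )


def categorize_frame(frame: pd.DataFrame, cmap: CategoryMap | None = None) -> pd.DataFrame:
    """Vectorized categorization; adds subgroup/reporting-group/status columns."""
    cmap = cmap or load_category_map()
    minors = frame["gnpd_minor"].astype(str).str.strip().str.lower()
    majors = frame["gnpd_major"].astype(str).str.strip().str.lower()

    exclusion = minors.map(cmap.exclusions)
    exclusion = exclusion.where(exclusion.notna(), majors.map(cmap.exclusions))
    subgroup = minors.map(cmap.minor_to_subgroup).where(exclusion.isna())

    start_year = subgroup.map(
        {name: info.start_year for name, info in cmap.subgroups.items()}
    )
    in_window = frame["release_year"] >= start_year

    out = frame.copy()
    out["thcl_subgroup"] = subgroup
    out["reporting_group"] = subgroup.map(
        {name: info.reporting_group for name, info in cmap.subgroups.items()}
    )
    out["exclusion_reason"] = exclusion
    out["in_window"] = in_window
    out["status"] = STATUS_UNMAPPED
    out.loc[exclusion.notna(), "status"] = STATUS_EXCLUDED
    out.loc[subgroup.notna() & ~out["in_window"], "status"] = STATUS_OUT_OF_WINDOW
    out.loc[subgroup.notna() & out["in_window"], "status"] = STATUS_IN_WINDOW
    return out


def partition_summary(frame: pd.DataFrame) -> dict[str, int]:
    """Counts of the four disjoint outcomes; they always sum to ``len(frame)``."""
    counts = frame["status"].value_counts().to_dict()
    return {
        status: int(counts.get(status, 0))
        for status in (
            STATUS_IN_WINDOW,
            STATUS_OUT_OF_WINDOW,
            STATUS_EXCLUDED,
            STATUS_UNMAPPED,
        )
    }
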