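"""Synthetic product-launch database with ground-truth annotations.

Generates launch-database-like batches: one row per barcode with category
codes, an ordered ingredient list, a standardized nutrition panel and a
label-display flag. The default scenario reproduces the aggregate structure
of a five-year serial cross-section (per-group launch counts, eligible
shares and a linearly rising display propensity among eligible products);
every distributional choice is invented and documented in the scenario file.

Ground truth (panel-level eligibility, FVNL bands, true fiber, display
probability) is emitted alongside the products so that every pipeline stage
can be tested closed-loop: the rules engine must recompute the generator's
eligibility annotation exactly, because eligible rows are drawn with all
criteria conditions satisfied and ineligible rows with their subgroup's
leading condition violated.

Display is modeled conditional on eligibility: P(display | eligible, year,
group) = r_g * (intercept + slope * X), with r_g solved per group so the
group's pooled eligible uptake over its active years matches the scenario
target; P(display | ineligible) is an anomaly knob, zero by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from ._assets import load_asset
from .categorization import CategoryMap, load_category_map
from .thcl_eligibility import CriteriaRegistry, load_criteria


class ConfigError(ValueError):
    pass


class DisplayModel(BaseModel):
    intercept: float
    slope: float
    x_start: int


class ManufacturerModel(BaseModel):
    n_firms: int = Field(gt=0)
    zipf_exponent: float = 1.25
    #: optional per-firm multiplier on the display probability (index -> factor)
    propensity: dict[int, float] = Field(default_factory=dict)


class GroupConfig(BaseModel):
    n_total: int = Field(ge=0)
    eligible_frac: float = Field(ge=0, le=1)
    #: pooled eligible-uptake target over the group's active years; ``None``
    #: means "use the display model unscaled" (r_g = 1)
    uptake_eligible: Optional[float] = Field(default=None, ge=0, le=1)
    subgroups: dict[str, float]
    pre_window_extra: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _weights_sum(self) -> "GroupConfig":
        total = sum(self.subgroups.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(f"subgroup weights sum to {total}, expected 1")
        return self


class GeneratorConfig(BaseModel):
    seed: Optional[int] = None
    years: list[int]
    display_model: DisplayModel
    anomaly_rate: float = Field(default=0.0, ge=0, le=1)
    missing_fiber_rate: float = Field(default=0.0, ge=0, le=1)
    fvnl_undeclared_rate: float = Field(default=1.0, ge=0, le=1)
    manufacturers: ManufacturerModel
    groups: dict[str, GroupConfig]
    nutrient_models: dict[str, str]
    archetypes: dict[str, dict[str, Any]]

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        for gcfg in self.groups.values():
            for sub in gcfg.subgroups:
                if sub not in self.nutrient_models:
                    raise ConfigError(f"no nutrient model for subgroup {sub}")
                if self.nutrient_models[sub] not in self.archetypes:
                    raise ConfigError(f"unknown archetype for subgroup {sub}")
        return self


def default_study_scenario() -> GeneratorConfig:
    """The shipped scenario; aggregate calibration targets ~27% eligible,
    ~10.7% labeled overall and ~39.5% labeled among eligible at n = 7767."""
    return load_scenario(None)


def load_scenario(path: str | None) -> GeneratorConfig:
    return GeneratorConfig(**{
        k: v for k, v in load_asset(path, "default_study.yaml").items() if k != "version"
    })


# ---------------------------------------------------------------------------
# ingredient templates per archetype: (weight, ingredients, truth) where truth
# fixes the FVNL decision-tree outcome and fiber-source flag by construction

_T = lambda conc, nonconc, fiber, concd: {  # noqa: E731
    "conc_band": conc, "nonconc_band": nonconc, "fiber_source": fiber, "concentrated": concd,
}

INGREDIENT_TEMPLATES: dict[str, list[tuple[float, tuple[str, ...], dict]]] = {
    "ssb": [
        (0.60, ("water", "sugar", "flavouring"), _T("lt25", "le40", False, False)),
        (0.25, ("water", "sugar", "apple juice concentrate"), _T("ge25", "le40", False, True)),
        (0.15, ("water", "sugar", "inulin", "flavouring"), _T("lt25", "le40", True, False)),
    ],
    "juice": [
        (0.50, ("orange juice",), _T("eq100", "eq100", False, False)),
        (0.30, ("apple juice concentrate",), _T("eq100", "eq100", False, True)),
        (0.20, ("water", "grape juice concentrate", "sugar"), _T("ge25", "gt40", False, True)),
    ],
    "dairy_beverage": [
        (0.70, ("milk", "sugar", "flavouring"), _T("lt25", "le40", False, False)),
        (0.30, ("milk", "sugar", "strawberry puree"), _T("ge25", "le40", False, False)),
    ],
    "yogurt_food": [
        (0.60, ("milk", "sugar", "milk solids"), _T("lt25", "le40", False, False)),
        (0.40, ("milk", "mango", "sugar"), _T("ge25", "gt40", False, False)),
    ],
    "plant_beverage": [
        (0.70, ("water", "soybean", "sugar"), _T("ge25", "gt40", False, False)),
        (0.30, ("water", "almond", "sugar"), _T("ge25", "gt40", False, False)),
    ],
    "malted": [
        (0.60, ("water", "milk", "malt extract", "cocoa"), _T("lt25", "le40", False, False)),
        (0.40, ("milk", "cocoa", "sugar"), _T("lt25", "le40", False, False)),
    ],
    "ice_cream": [
        (0.70, ("milk", "cream", "sugar"), _T("lt25", "le40", False, False)),
        (0.30, ("milk", "sugar", "strawberry"), _T("ge25", "le40", False, False)),
    ],
    "sweet_bakery": [
        (0.70, ("wheat flour", "sugar", "palm oil", "egg"), _T("lt25", "le40", False, False)),
        (0.30, ("wheat flour", "sugar", "shortening", "banana"), _T("lt25", "le40", False, False)),
    ],
    "bread": [
        (0.60, ("wheat flour", "water", "yeast", "salt"), _T("lt25", "le40", False, False)),
        (0.40, ("whole wheat flour", "water", "yeast", "salt"), _T("lt25", "le40", True, False)),
    ],
    "cereal": [
        (0.50, ("whole grain oat", "sugar", "salt"), _T("lt25", "le40", True, False)),
        (0.30, ("corn", "sugar", "salt"), _T("ge25", "gt40", False, False)),
        (0.20, ("rice", "whole wheat", "sugar", "inulin"), _T("lt25", "le40", True, False)),
    ],
    "noodle": [
        (0.80, ("wheat flour", "palm oil", "salt", "flavour enhancer"), _T("lt25", "le40", False, False)),
        (0.20, ("rice noodle", "palm oil", "dried vegetable", "seasoning"), _T("ge25", "le40", False, True)),
    ],
    "ready_meal": [
        (0.60, ("rice", "chicken", "seasoning"), _T("lt25", "le40", False, False)),
        (0.40, ("rice", "chicken", "carrot", "salt"), _T("ge25", "le40", False, False)),
    ],
    "fish_sauce": [
        (1.00, ("anchovy extract", "salt", "sugar"), _T("lt25", "le40", False, False)),
    ],
    "soy_sauce": [
        (1.00, ("water", "soybean", "wheat flour", "salt"), _T("ge25", "gt40", False, False)),
    ],
    "seasoning_powder": [
        (1.00, ("salt", "sugar", "monosodium glutamate", "dried garlic"), _T("lt25", "le40", False, False)),
    ],
    "dressing": [
        (1.00, ("palm oil", "water", "vinegar", "sugar", "salt"), _T("lt25", "le40", False, False)),
    ],
    "small_meal": [
        (0.60, ("wheat flour", "pork", "salt"), _T("lt25", "le40", False, False)),
        (0.40, ("rice", "mushroom", "salt"), _T("ge25", "gt40", False, False)),
    ],
    "snack": [
        (0.60, ("potato", "palm oil", "salt"), _T("ge25", "gt40", False, False)),
        (0.40, ("rice flour", "palm oil", "salt", "flavouring"), _T("lt25", "le40", False, False)),
    ],
    "nut_snack": [
        (0.70, ("peanuts", "salt"), _T("ge67", "gt80", False, False)),
        (0.30, ("almond",), _T("eq100", "eq100", False, False)),
    ],
    "soup": [
        (0.60, ("water", "pumpkin", "cream", "salt"), _T("ge25", "gt40", False, False)),
        (0.40, ("water", "chicken", "salt"), _T("lt25", "le40", False, False)),
    ],
}


@dataclass
class SyntheticBatch:
    products: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig


@dataclass(frozen=True)
class _Block:
    group: str
    subgroup: str
    year: int
    n: int
    in_window: bool
    display_scale: float  # r_g


def _largest_remainder(total: int, weights: list[float]) -> list[int]:
    raw = [w * total for w in weights]
    counts = [int(np.floor(r)) for r in raw]
    short = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def _year_factor(model: DisplayModel, year: int) -> float:
    return model.intercept + model.slope * (year - model.x_start + 1)


def plan_blocks(
    config: GeneratorConfig, cmap: CategoryMap | None = None
) -> list[_Block]:
    """Deterministic (group, subgroup, year) launch-count plan shared by the
    generator and the analytic expectation."""
    cmap = cmap or load_category_map()
    blocks: list[_Block] = []
    for group, gcfg in config.groups.items():
        names = list(gcfg.subgroups)
        sub_counts = _largest_remainder(gcfg.n_total, [gcfg.subgroups[s] for s in names])
        extra_counts = _largest_remainder(gcfg.pre_window_extra, [gcfg.subgroups[s] for s in names])
        for sub, n_sub, n_extra in zip(names, sub_counts, extra_counts):
            start = cmap.info(sub).start_year
            active = [y for y in config.years if y >= start]
            before = [y for y in config.years if y < start]
            if not active:
                continue
            factors = [_year_factor(config.display_model, y) for y in active]
            mean_factor = float(np.mean(factors))
            if gcfg.uptake_eligible is None:
                scale = 1.0
            else:
                scale = gcfg.uptake_eligible / mean_factor if mean_factor > 0 else 0.0
            base, rem = divmod(n_sub, len(active))
            for i, year in enumerate(active):
                n = base + (1 if i >= len(active) - rem else 0)
                if n:
                    blocks.append(_Block(group, sub, year, n, True, scale))
            if before and n_extra:
                base, rem = divmod(n_extra, len(before))
                for i, year in enumerate(before):
                    n = base + (1 if i >= len(before) - rem else 0)
                    if n:
                        blocks.append(_Block(group, sub, year, n, False, scale))
    return blocks


def _representative_minors(cmap: CategoryMap) -> dict[str, str]:
    rep: dict[str, str] = {}
    for minor, sub in cmap.minor_to_subgroup.items():
        rep.setdefault(sub, minor)
    return rep


def _draw_lognormal(rng: np.random.Generator, median: float, sigma: float, n: int) -> np.ndarray:
    if median <= 0:
        return np.zeros(n)
    return median * np.exp(rng.normal(0.0, sigma, n))


def _draw_truncnormal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, n), 0.0, None)


def _condition_threshold_per100(cond) -> float:
    if cond.basis == "per_serving":
        return cond.threshold * 100.0 / cond.serving_size_g
    return cond.threshold


def generate_products(
    config: GeneratorConfig,
    seed: int | None = None,
    cmap: CategoryMap | None = None,
    registry: CriteriaRegistry | None = None,
) -> SyntheticBatch:
    """Generate a launch batch with ground-truth annotations.

    Identical ``(config, seed)`` pairs regenerate identical batches. Barcodes
    are unique; display flags are drawn from the eligibility-conditional
    model; panels are standardized per-100 basis units in kJ by construction.
    """
    cmap = cmap or load_category_map()
    registry = registry or load_criteria()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    firm_weights = 1.0 / np.arange(1, config.manufacturers.n_firms + 1) ** config.manufacturers.zipf_exponent
    firm_weights /= firm_weights.sum()

    blocks = plan_blocks(config, cmap)
    rep_minor = _representative_minors(cmap)

    frames: list[pd.DataFrame] = []
    truths: list[pd.DataFrame] = []
    next_id = 0
    for blk in blocks:
        n = blk.n
        info = cmap.info(blk.subgroup)
        archetype = config.nutrient_models[blk.subgroup]
        model = config.archetypes[archetype]
        templates = INGREDIENT_TEMPLATES[archetype]

        eligible = rng.random(n) < config.groups[blk.group].eligible_frac

        # nutrient draws, then overwrite nutrients named in the criteria
        energy = _draw_lognormal(rng, *model["energy"], n)
        sugar = _draw_lognormal(rng, *model["total_sugar"], n)
        sodium = _draw_lognormal(rng, *model["sodium"], n)
        satfat = _draw_lognormal(rng, *model["saturated_fat"], n)
        protein = _draw_truncnormal(rng, *model["protein"], n)
        fiber_true = _draw_truncnormal(rng, *model["fiber"], n)
        columns = {
            "energy": energy,
            "total_sugar": sugar,
            "sodium": sodium,
            "saturated_fat": satfat,
            "protein": protein,
            "fiber": fiber_true,
        }

        criteria = registry.get(blk.subgroup)
        fat_conditioned = False
        if criteria is not None:
            for j, cond in enumerate(criteria.conditions):
                thr = _condition_threshold_per100(cond)
                vals = columns.get(cond.nutrient)
                if vals is None:
                    # nutrient has no archetype model (e.g. total fat): seed a
                    # spread straddling the threshold
                    vals = thr * rng.uniform(0.3, 1.7, n)
                if cond.op == "le":
                    ok_vals = thr * rng.uniform(0.15, 0.98, n)
                    bad_vals = thr * (1.0 + rng.uniform(0.05, 0.9, n))
                else:
                    ok_vals = thr * (1.0 + np.minimum(rng.exponential(0.35, n), 2.0))
                    bad_vals = thr * rng.uniform(0.3, 0.97, n)
                if j == 0:
                    vals = np.where(eligible, ok_vals, bad_vals)
                else:
                    vals = np.where(eligible, ok_vals, vals)
                columns[cond.nutrient] = vals
                if cond.nutrient == "total_fat":
                    fat_conditioned = True

        if fat_conditioned:
            total_fat = columns["total_fat"]
            columns["saturated_fat"] = total_fat * rng.uniform(0.08, 0.45, n)
        else:
            total_fat = columns["saturated_fat"] * rng.uniform(1.3, 3.5, n) + 0.05
        columns["total_fat"] = total_fat
        columns["total_carbohydrate"] = columns["total_sugar"] * (
            1.0 + rng.uniform(0.0, 0.6, n)
        ) + rng.uniform(0.0, 10.0, n)

        # label display conditional on eligibility
        p_display = 0.0 if not blk.in_window else float(
            np.clip(blk.display_scale * _year_factor(config.display_model, blk.year), 0.0, 1.0)
        )
        displayed = np.where(
            eligible, rng.random(n) < p_display, rng.random(n) < (config.anomaly_rate if blk.in_window else 0.0)
        )

        # ingredient template per row
        probs = np.array([t[0] for t in templates])
        t_idx = rng.choice(len(templates), size=n, p=probs / probs.sum())
        ingredient_lists = [templates[i][1] for i in t_idx]
        truth_bands = [templates[i][2] for i in t_idx]

        # missingness
        fiber_missing = rng.random(n) < config.missing_fiber_rate
        panel_fiber = np.where(fiber_missing, np.nan, columns["fiber"])
        fvnl_declared = rng.random(n) >= config.fvnl_undeclared_rate

        firms = rng.choice(config.manufacturers.n_firms, size=n, p=firm_weights)

        barcodes = [f"885{next_id + i:010d}" for i in range(n)]
        next_id += n

        frames.append(
            pd.DataFrame(
                {
                    "barcode": barcodes,
                    "release_year": blk.year,
                    "manufacturer": [f"Company {i:04d}" for i in firms],
                    "product_name": [f"{blk.subgroup.replace('_', ' ')} {next_id - n + i}" for i in range(n)],
                    "package_descriptor": "",
                    "gnpd_major": blk.group,
                    "gnpd_minor": rep_minor.get(blk.subgroup, blk.subgroup),
                    "ingredients": ingredient_lists,
                    "basis": info.basis,
                    "serving_size": float(model["serving"]),
                    "energy": columns["energy"],
                    "total_fat": columns["total_fat"],
                    "saturated_fat": columns["saturated_fat"],
                    "protein": columns["protein"],
                    "total_carbohydrate": columns["total_carbohydrate"],
                    "fiber": panel_fiber,
                    "total_sugar": columns["total_sugar"],
                    "sodium": columns["sodium"],
                    "fvnl_nonconc_pct": np.where(fvnl_declared, 0.0, np.nan),
                    "fvnl_conc_pct": np.where(fvnl_declared, 0.0, np.nan),
                    "thcl_displayed": displayed,
                }
            )
        )
        truths.append(
            pd.DataFrame(
                {
                    "barcode": barcodes,
                    "thcl_subgroup": blk.subgroup,
                    "reporting_group": info.reporting_group,
                    "release_year": blk.year,
                    "in_window": blk.in_window,
                    "eligible_true": eligible,
                    "display_prob": p_display,
                    "fiber_true": columns["fiber"],
                    "conc_band_true": [t["conc_band"] for t in truth_bands],
                    "nonconc_band_true": [t["nonconc_band"] for t in truth_bands],
                    "fiber_source_true": [t["fiber_source"] for t in truth_bands],
                    "template_id": t_idx,
                }
            )
        )

    products = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    return SyntheticBatch(products=products, truth=truth, config=config)


def expected_uptake_curve(
    config: GeneratorConfig, cmap: CategoryMap | None = None
) -> pd.DataFrame:
    """Analytic expected yearly uptake under the scenario (in-window blocks
    only): per-year expected eligible count, labeled count, totals and the
    implied uptake proportions. This is the generator's ground-truth curve
    for parameter-recovery tests."""
    cmap = cmap or load_category_map()
    rows: dict[int, dict[str, float]] = {}
    for blk in plan_blocks(config, cmap):
        if not blk.in_window:
            continue
        gcfg = config.groups[blk.group]
        e = blk.n * gcfg.eligible_frac
        p = float(np.clip(blk.display_scale * _year_factor(config.display_model, blk.year), 0.0, 1.0))
        row = rows.setdefault(blk.year, {"n_total": 0.0, "n_eligible": 0.0, "n_labeled": 0.0})
        row["n_total"] += blk.n
        row["n_eligible"] += e
        row["n_labeled"] += e * p
    out = (
        pd.DataFrame([{"year": y, **vals} for y, vals in sorted(rows.items())])
        .assign(
            uptake_total=lambda d: d["n_labeled"] / d["n_total"],
            uptake_eligible=lambda d: d["n_labeled"] / d["n_eligible"],
        )
    )
    return out
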