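"""End-to-end annotation: categorize -> impute -> score -> classify.

The pipeline operates on a flat product frame (one row per barcode with
standardized panel columns) and adds, stage by stage, the category
assignment, imputed fiber/FVNL, the HSR result and the eligibility verdict
with its display-consistency tag. Stages are individually selectable so
callers that only need counts (e.g. replicate simulation studies) can skip
the ingredient-scanning stages.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .categorization import CategoryMap, categorize_frame, load_category_map
from .hsr_scoring import HsrTables, load_tables, score_frame
from .imputation import allocate_fvnl_frame, impute_fiber_frame
from .thcl_eligibility import CriteriaRegistry, check_frame, load_criteria

ALL_STAGES = ("categorize", "impute", "hsr", "eligibility")


def annotate_products(
    frame: pd.DataFrame,
    stages: Sequence[str] = ALL_STAGES,
    cmap: CategoryMap | None = None,
    registry: CriteriaRegistry | None = None,
    tables: HsrTables | None = None,
) -> pd.DataFrame:
    """Run the selected pipeline stages over a standardized product frame."""
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    cmap = cmap or load_category_map()
    out = frame
    if "categorize" in stages:
        out = categorize_frame(out, cmap)
    if "impute" in stages:
        out = impute_fiber_frame(out, cmap)
        out = allocate_fvnl_frame(out)
    if "hsr" in stages:
        out = score_frame(out, tables or load_tables(), cmap)
    if "eligibility" in stages:
        out = check_frame(out, registry or load_criteria())
    return out
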