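"""Rule-based modified AHA plaque typing from quantitative T2 measures.

The advanced-lesion types used here are IV-V (lipid-core plaque), VI
(complicated plaque with hemorrhage), VII (calcified plaque) and VIII
(fibrous plaque).  Classification is a fixed precedence cascade over
quantitative features derived from the T2 map plus a calcium mask supplied
as input (calcium is identified on bright-blood angiography, never inferred
from T2):

1. significant hemorrhage present          -> VI
2. calcium area above the calcium cutoff   -> VII
3. lipid core at or above the minimum core -> IV-V
4. otherwise                               -> VIII

Both cutoffs are configurable (defaults: calcium 10%, minimum core 10% of
wall area) and every feature combination maps to exactly one type.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["AHAType", "AHARules", "PlaqueFeatures", "classify_plaque",
           "agreement_table", "AHA_ORDER"]


class AHAType(str, Enum):
    IV_V = "IV_V"
    VI = "VI"
    VII = "VII"
    VIII = "VIII"


AHA_ORDER = [AHAType.IV_V, AHAType.VI, AHAType.VII, AHAType.VIII]


@dataclass(frozen=True)
class AHARules:
    calcium_threshold_pct: float = 10.0
    min_core_pct: float = 10.0


@dataclass(frozen=True)
class PlaqueFeatures:
    """Quantitative features of one plaque used for typing."""

    lipid_area_pct: float
    significant_iph: bool
    calcium_area_pct: float

    def __post_init__(self) -> None:
        for v in (self.lipid_area_pct, self.calcium_area_pct):
            if not 0 <= v <= 100:
                raise ValueError("percentages must lie in [0, 100]")

    def fibrous_dominant(self, rules: "AHARules" = AHARules()) -> bool:
        return self.lipid_area_pct < rules.min_core_pct


def classify_plaque(features: PlaqueFeatures, rules: AHARules = AHARules()) -> AHAType:
    """Assign one modified AHA type by the precedence cascade."""
    if features.significant_iph:
        return AHAType.VI
    if features.calcium_area_pct > rules.calcium_threshold_pct:
        return AHAType.VII
    if features.lipid_area_pct >= rules.min_core_pct:
        return AHAType.IV_V
    return AHAType.VIII


def agreement_table(predicted: Sequence[AHAType], reference: Sequence[AHAType]) -> pd.DataFrame:
    """Confusion counts, rows = reference (histology), columns = predicted.

    Category order is fixed to IV-V, VI, VII, VIII so the table feeds
    directly into Cohen's kappa.
    """
    predicted = list(predicted)
    reference = list(reference)
    if len(predicted) != len(reference):
        raise ValueError("predicted and reference lengths differ")
    if not predicted:
        raise ValueError("empty type lists")
    idx = {t: i for i, t in enumerate(AHA_ORDER)}
    counts = np.zeros((4, 4), dtype=int)
    for p, r in zip(predicted, reference):
        counts[idx[AHAType(r)], idx[AHAType(p)]] += 1
    names = [t.value for t in AHA_ORDER]
    return pd.DataFrame(counts, index=pd.Index(names, name="reference"),
                        columns=pd.Index(names, name="predicted"))
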