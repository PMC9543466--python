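"""Linking hunting regulations to population risk.

Licensed hunters who cannot reliably tell the protected Lesser
White-fronted Goose apart from legal quarry (Greater White-fronted and
Greylag Geese) remove protected birds accidentally.  The expected
accidental offtake is simply the regional legal quota times the
misidentification rate; classifying that number against the simulated
(offtake, phi) surfaces says whether it threatens the population.

Reported misidentification rates for northern Kazakhstan are one to three
protected birds per 100 legal geese, locally as high as one per 20-30;
the 2017 regional goose quota was 71,240 birds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OfftakeEstimate",
    "MISID_RATE_TYPICAL",
    "MISID_RATE_HIGH",
    "MISID_RATE_EXTREME",
    "QUOTA_2017",
    "expected_accidental_offtake",
    "offtake_risk_report",
]

QUOTA_2017 = 71_240
MISID_RATE_TYPICAL = 1 / 100
MISID_RATE_HIGH = 3 / 100
#: the "one per 20-30 legal geese" local extreme, encoded at its upper end
MISID_RATE_EXTREME = 1 / 20


@dataclass(frozen=True)
class OfftakeEstimate:
    quota: int
    misid_rate: float
    expected_offtake: float


def expected_accidental_offtake(quota: int, misid_rate: float) -> OfftakeEstimate:
    """Expected protected-species kills per season: quota x misidentification rate."""
    if quota < 0:
        raise ValueError(f"quota must be non-negative, got {quota}")
    if not 0.0 <= misid_rate <= 1.0:
        raise ValueError(f"misid_rate must be in [0, 1], got {misid_rate}")
    return OfftakeEstimate(quota, misid_rate, quota * misid_rate)


def offtake_risk_report(offtake: float, summary: pd.DataFrame,
                        extinction_risk_level: float = 0.5) -> dict:
    """Classify an offtake estimate against the simulated scenario grid.

    For each simulated return rate phi, looks up the nearest simulated
    offtake level and labels the scenario ``growing`` (positive mean
    growth), ``extinction-risk`` (extinction probability at or above
    ``extinction_risk_level``) or ``declining`` otherwise.  Also reports
    the smallest phi with positive growth at this offtake.

    ``summary`` is the per-cell table from ``summarize_scenarios``.
    """
    offt = np.sort(summary["offtake"].unique())
    if not offt[0] <= offtake <= offt[-1]:
        raise ValueError(
            f"offtake {offtake} lies outside the simulated grid [{offt[0]}, {offt[-1]}]")
    nearest = float(offt[np.argmin(np.abs(offt - offtake))])
    at = summary[summary["offtake"] == nearest].sort_values("phi")
    classes = []
    for _, row in at.iterrows():
        if row["mean_growth_total"] > 0:
            label = "growing"
        elif row["extinction_probability"] >= extinction_risk_level:
            label = "extinction-risk"
        else:
            label = "declining"
        classes.append({"phi": float(row["phi"]),
                        "mean_growth_total": float(row["mean_growth_total"]),
                        "extinction_probability": float(row["extinction_probability"]),
                        "classification": label})
    growing = [c["phi"] for c in classes if c["classification"] == "growing"]
    return {
        "offtake": float(offtake),
        "nearest_grid_offtake": nearest,
        "per_phi": classes,
        "min_phi_with_positive_growth": min(growing) if growing else None,
    }
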