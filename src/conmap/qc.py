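"""Marker-level quality filters and the Mendelian segregation test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .markers import MISSING, CrossType
from .io import PopulationDataset

__all__ = ["SegregationResult", "filter_markers", "segregation_test"]


@dataclass
class SegregationResult:
    """Chi-square goodness of fit to the expected Mendelian ratio.

    Expected ratios are 1:2:1 for B3.7 markers and 1:1 for the testcross
    types, computed over non-missing calls; ``distorted`` applies the
    Bonferroni-corrected threshold ``alpha / n_tested``.
    """

    marker_name: str
    cross_type: CrossType
    chi2: float
    df: int
    p_value: float
    distorted: bool


def filter_markers(
    dataset: PopulationDataset, max_missing: float = 0.25
) -> tuple[PopulationDataset, pd.DataFrame]:
    """Drop markers whose missing-call fraction is ``>= max_missing``.

    The boundary is exclusive for retention (a marker must have *less than*
    ``max_missing`` missing data to survive).  Returns the filtered dataset
    and a report of removed markers.
    """
    kept, removed = [], []
    for m in dataset.markers:
        frac = m.missing_fraction
        if frac < max_missing:
            kept.append(m.name)
        else:
            removed.append({
                "marker_name": m.name,
                "reason": "missing_data",
                "missing_fraction": round(frac, 4),
            })
    report = pd.DataFrame(removed,
                          columns=["marker_name", "reason", "missing_fraction"])
    return dataset.subset(kept), report


def segregation_test(
    dataset: PopulationDataset, alpha: float = 0.05
) -> list[SegregationResult]:
    """Chi-square segregation test per marker, Bonferroni-corrected.

    df = number of expected classes - 1 (2 for B3.7, 1 for D types).  The
    Bonferroni divisor is the number of markers tested.
    """
    n_tested = dataset.n_markers
    results: list[SegregationResult] = []
    for m in dataset.markers:
        obs_calls = m.calls[m.calls != MISSING]
        if obs_calls.size == 0:
            raise ValueError(f"marker {m.name}: all calls missing")
        classes = m.cross_type.observable_classes
        counts = np.array([np.sum(obs_calls == c) for c in classes], float)
        expected = np.array(m.cross_type.expected_ratio) * counts.sum()
        chi2 = float(np.sum((counts - expected) ** 2 / expected))
        df = len(classes) - 1
        p = float(stats.chi2.sf(chi2, df))
        results.append(SegregationResult(
            marker_name=m.name,
            cross_type=m.cross_type,
            chi2=chi2,
            df=df,
            p_value=p,
            distorted=bool(p < alpha / n_tested),
        ))
    return results


def segregation_report(results: list[SegregationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "marker_name": r.marker_name,
        "cross_type": r.cross_type.value,
        "chi2": round(r.chi2, 4),
        "df": r.df,
        "p_value": r.p_value,
        "distorted": r.distorted,
    } for r in results])
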