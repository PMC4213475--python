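"""Differential circuit activation between two conditions.

Per circuit, the two groups of per-sample transmission probabilities are
compared with the two-sample Wilcoxon rank-sum test (exact when both groups
have <= 25 samples and no ties, otherwise the tie-corrected normal
approximation with continuity correction — the convention of R's
``wilcox.test``).  The reported location estimate is the Hodges–Lehmann
shift, the median of all pairwise differences (condition2 − condition1);
its sign gives the activated condition.  p-values are Benjamini–Hochberg
adjusted within each pathway's circuit set (optionally globally).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .circuits import Circuit

logger = logging.getLogger("sigcircuits.difftest")

EXACT_MAX_N = 25

DIRECTION_UP = "up_in_condition2"
DIRECTION_DOWN = "down_in_condition2"
DIRECTION_NONE = "none"


@dataclass(frozen=True)
class CircuitResult:
    circuit_id: str
    pathway_id: str
    p_value: float
    fdr_adjusted_p: float
    direction: str
    location_estimate: float
    input_node: str = ""
    output_node: str = ""


def wilcoxon_circuit(
    probs_group1: Sequence[float] | np.ndarray,
    probs_group2: Sequence[float] | np.ndarray,
) -> tuple[float, float]:
    """Rank-sum p-value and Hodges–Lehmann shift (group2 − group1)."""
    g1 = np.asarray(probs_group1, dtype=float)
    g2 = np.asarray(probs_group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    diffs = np.subtract.outer(g2, g1).ravel()
    location = float(np.median(diffs))
    combined = np.concatenate([g1, g2])
    if np.all(combined == combined[0]):
        return 1.0, 0.0
    has_ties = len(np.unique(combined)) < len(combined)
    exact = len(g1) <= EXACT_MAX_N and len(g2) <= EXACT_MAX_N and not has_ties
    res = stats.mannwhitneyu(
        g2, g1, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(min(res.pvalue, 1.0)), location


def adjust_fdr(
    p_values: Sequence[float] | np.ndarray,
    groups: Sequence[str] | None = None,
) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, within groups when given."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    out = np.empty_like(p)
    if groups is None:
        out[:] = multipletests(p, method="fdr_bh")[1]
        return out
    groups_arr = np.asarray(groups)
    if groups_arr.shape != p.shape:
        raise ValueError("groups must align with p_values")
    for g in pd.unique(groups_arr):
        mask = groups_arr == g
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def compare_conditions(
    activity: pd.DataFrame,
    design: Mapping[str, str],
    alpha: float = 0.05,
    global_fdr: bool = False,
    circuits: Sequence[Circuit] | None = None,
) -> list[CircuitResult]:
    """Test every circuit row of ``activity`` for differential activation.

    ``design`` maps each sample (column) to one of exactly two group labels;
    condition order is the sorted label order, and directions are reported
    relative to the second.  Significance is ``fdr_adjusted_p < alpha``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    missing = [s for s in activity.columns if s not in design]
    if missing:
        raise ValueError(f"samples missing from design: {missing[:5]}")
    labels = sorted({design[s] for s in activity.columns})
    if len(labels) != 2:
        raise ValueError(f"the model compares exactly two conditions, got {labels}")
    cond1, cond2 = labels
    cols1 = [s for s in activity.columns if design[s] == cond1]
    cols2 = [s for s in activity.columns if design[s] == cond2]

    meta: dict[str, Circuit] = {c.circuit_id: c for c in circuits} if circuits else {}

    ids, pvals, locs, pathways = [], [], [], []
    for circuit_id, row in activity.iterrows():
        p, loc = wilcoxon_circuit(row[cols1].to_numpy(), row[cols2].to_numpy())
        ids.append(str(circuit_id))
        pvals.append(p)
        locs.append(loc)
        if circuit_id in meta:
            pathways.append(meta[str(circuit_id)].pathway_id)
        else:
            pathways.append(str(circuit_id).split(":", 1)[0])
    adjusted = adjust_fdr(pvals, groups=None if global_fdr else pathways)

    results: list[CircuitResult] = []
    for cid, pid, p, q, loc in zip(ids, pathways, pvals, adjusted, locs):
        if q < alpha and loc != 0.0:
            direction = DIRECTION_UP if loc > 0 else DIRECTION_DOWN
        else:
            direction = DIRECTION_NONE
        c = meta.get(cid)
        results.append(
            CircuitResult(
                circuit_id=cid,
                pathway_id=pid,
                p_value=p,
                fdr_adjusted_p=float(q),
                direction=direction,
                location_estimate=loc,
                input_node=c.input_node if c else "",
                output_node=c.output_node if c else "",
            )
        )
    return results


def results_table(results: Sequence[CircuitResult]) -> pd.DataFrame:
    """Results as the standard output table (one row per circuit)."""
    return pd.DataFrame(
        {
            "circuit_id": [r.circuit_id for r in results],
            "pathway_id": [r.pathway_id for r in results],
            "input": [r.input_node for r in results],
            "output": [r.output_node for r in results],
            "p_value": [r.p_value for r in results],
            "fdr_adjusted_p": [r.fdr_adjusted_p for r in results],
            "direction": [r.direction for r in results],
            "location": [r.location_estimate for r in results],
        }
    )
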