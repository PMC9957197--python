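"""Univariate screening, the per-pair filter cascade and the marker panel.

A compound becomes a pairwise candidate marker only if it clears all four
filters simultaneously: the S-plot magnitude/reliability cutoffs, VIP > 1,
Welch-t p < 0.05 and |log2 fold change| > 1.  The final panel intersects the
union of pairwise candidates with the OAV > 1 primary-aroma set, so a marker
must be both statistically discriminating and aroma-active.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data import FeatureTable, PipelineConfig
from .diagnostics import SPlotRow

logger = logging.getLogger(__name__)

__all__ = [
    "UnivariateRow",
    "MarkerDecision",
    "PanelResult",
    "univariate_screen",
    "select_pair_candidates",
    "assemble_panel",
]


@dataclass(frozen=True)
class UnivariateRow:
    """Welch t-test and fold change of one compound for one region pair.

    ``log2_fc = log2(mean_B / mean_A)`` (second-listed over first-listed
    region); absent when the compound is a structural zero in one region, in
    which case ``qualitative`` is True and the fold-change filter is judged
    on presence/absence instead (detected-region mean > 3 x its SD).
    """

    compound: str
    pair: tuple[str, str]
    mean_a: float
    mean_b: float
    p_value: float
    log2_fc: float | None
    direction: str  # up_in_A | up_in_B | tie
    qualitative: bool = False
    passes_fc: bool = False


@dataclass(frozen=True)
class MarkerDecision:
    """Pass/fail state of each filter for one compound in one contrast."""

    compound: str
    pair: tuple[str, str]
    passes_splot: bool
    passes_vip: bool
    passes_p: bool
    passes_fc: bool

    @property
    def candidate(self) -> bool:
        return (self.passes_splot and self.passes_vip
                and self.passes_p and self.passes_fc)


@dataclass
class PanelResult:
    """Panel assembly: pairwise candidates, their union, and the OAV gate."""

    per_pair_candidates: dict[tuple[str, str], set[str]]
    chemometric_union: set[str]
    oav_primary: set[str]
    final_panel: set[str]


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sample p; degenerate zero-variance cases handled explicitly."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def univariate_screen(
    table: FeatureTable,
    pair: tuple[str, str],
    log2fc_threshold: float = 1.0,
) -> list[UnivariateRow]:
    """Welch t-test and log2 fold change per compound for one region pair.

    Compounds not detected in both regions get p = 1 and never pass the fold
    change filter; compounds detected in exactly one region are evaluated
    qualitatively (see :class:`UnivariateRow`).
    """
    region_a, region_b = pair
    ia = table.region_indices(region_a)
    ib = table.region_indices(region_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("both regions need >= 2 samples")
    rows = []
    for j, name in enumerate(table.compound_names):
        a = table.values[ia, j]
        b = table.values[ib, j]
        nd_a = bool(table.nd_mask[ia, j].all())
        nd_b = bool(table.nd_mask[ib, j].all())
        mean_a, mean_b = float(a.mean()), float(b.mean())
        p = _welch_p(a, b)
        if mean_a > mean_b:
            direction = "up_in_A"
        elif mean_b > mean_a:
            direction = "up_in_B"
        else:
            direction = "tie"
        if nd_a and nd_b:
            rows.append(UnivariateRow(name, pair, mean_a, mean_b, 1.0, None,
                                      "tie", qualitative=True, passes_fc=False))
            continue
        if nd_a or nd_b:
            det = b if nd_a else a
            det_ok = det.mean() > 3 * det.std(ddof=1)
            rows.append(UnivariateRow(name, pair, mean_a, mean_b, p, None,
                                      direction, qualitative=True,
                                      passes_fc=bool(det_ok)))
            continue
        log2_fc = math.log2(mean_b / mean_a)
        rows.append(UnivariateRow(
            name, pair, mean_a, mean_b, p, log2_fc, direction,
            qualitative=False,
            passes_fc=abs(log2_fc) > log2fc_threshold,
        ))
    return rows


def select_pair_candidates(
    splot_rows: Sequence[SPlotRow],
    vip_rows: Sequence[tuple[str, float]],
    univariate_rows: Sequence[UnivariateRow],
    config: PipelineConfig | None = None,
) -> list[MarkerDecision]:
    """Conjunction of the four filters for one pairwise contrast.

    All three diagnostic inputs must cover the same compounds; a missing
    compound raises ``KeyError`` naming it.  Decisions are ordered by
    |p(corr)| descending for reporting.
    """
    config = config or PipelineConfig()
    splot_by = {r.compound: r for r in splot_rows}
    vip_by = dict(vip_rows)
    uni_by = {r.compound: r for r in univariate_rows}
    decisions = []
    for name in splot_by:
        if name not in vip_by:
            raise KeyError(f"compound {name!r} missing from VIP rows")
        if name not in uni_by:
            raise KeyError(f"compound {name!r} missing from univariate rows")
        sp = splot_by[name]
        uni = uni_by[name]
        decisions.append(MarkerDecision(
            compound=name,
            pair=uni.pair,
            passes_splot=sp.selected,
            passes_vip=vip_by[name] > config.vip_threshold,
            passes_p=uni.p_value < config.p_threshold,
            passes_fc=uni.passes_fc,
        ))
    for name in vip_by:
        if name not in splot_by:
            raise KeyError(f"compound {name!r} missing from S-plot rows")
    decisions.sort(
        key=lambda d: (-abs(splot_by[d.compound].p_corr)
                       if np.isfinite(splot_by[d.compound].p_corr) else 0.0,
                       d.compound)
    )
    return decisions


def assemble_panel(
    per_pair: Mapping[tuple[str, str], Sequence[MarkerDecision]],
    oav_primary: set[str],
) -> PanelResult:
    """Final marker panel: union of pairwise candidates ∩ OAV-primary set."""
    if not per_pair:
        raise ValueError("at least one pairwise contrast is required")
    per_pair_candidates = {
        pair: {d.compound for d in decisions if d.candidate}
        for pair, decisions in per_pair.items()
    }
    union: set[str] = set().union(*per_pair_candidates.values())
    panel = union & oav_primary
    if union and not panel:
        logger.warning(
            "chemometric candidates %s are disjoint from the OAV-primary "
            "set; panel is empty", sorted(union)
        )
    return PanelResult(per_pair_candidates, union, oav_primary, panel)
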