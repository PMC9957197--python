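"""Retention-index arithmetic, semi-quantification and odor activity values.

The odor activity value (OAV) of a compound is its concentration divided by
its odor detection threshold; compounds with OAV > 1 in at least one region
are flagged as primary aroma-active compounds.  Concentrations are in µg/kg
and thresholds in µg/L (literature values in water); the ratio is taken
without a density correction, which is the convention for water-rich fruit
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import CompoundMeta, RegionSummary

__all__ = [
    "AlkaneLadder",
    "PeakMeasurement",
    "OAVRecord",
    "retention_index",
    "semi_quantify",
    "compute_oav",
    "oav_records",
    "oav_table",
    "primary_aroma_screen",
]

#: Default internal-standard (2-butanol) concentration, mg/L.
DEFAULT_IS_CONC = 2.70


@dataclass(frozen=True)
class AlkaneLadder:
    """n-alkane external reference ladder for Kovats retention indices.

    ``entries`` is a sequence of ``(n_carbons, retention_time_minutes)``
    pairs with both coordinates strictly increasing; carbon numbers must lie
    within C7-C40.
    """

    entries: tuple[tuple[int, float], ...]

    def __init__(self, entries: Iterable[tuple[int, float]]):
        entries = tuple((int(n), float(t)) for n, t in entries)
        if len(entries) < 2:
            raise ValueError("ladder needs at least two alkanes")
        ns = [n for n, _ in entries]
        ts = [t for _, t in entries]
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise ValueError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("retention times must be strictly increasing")
        if ns[0] < 7 or ns[-1] > 40:
            raise ValueError("ladder must lie within C7-C40")
        object.__setattr__(self, "entries", entries)


@dataclass(frozen=True)
class PeakMeasurement:
    """One integrated GC-MS peak with its internal-standard reference."""

    compound: CompoundMeta
    area: float
    internal_standard_area: float
    internal_standard_conc: float = DEFAULT_IS_CONC

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("peak area must be >= 0")
        if self.internal_standard_area <= 0:
            raise ValueError("internal standard area must be > 0")


@dataclass(frozen=True)
class OAVRecord:
    """Odor activity value of one compound in one region.

    ``oav`` is ``None`` exactly when no literature threshold exists;
    ``primary_flag`` is True when OAV > 1.
    """

    compound: str
    region: str
    concentration: float
    threshold: float | None
    oav: float | None
    primary_flag: bool


def retention_index(t_a: float, ladder: AlkaneLadder) -> float:
    """Kovats retention index by linear interpolation between bracketing alkanes.

    ``RI = 100*n + 100*(t_a - t_n)/(t_{n+1} - t_n)`` where ``t_n <= t_a <=
    t_{n+1}`` are the retention times of the Cn and Cn+1 alkanes.  No
    extrapolation: times outside the ladder span raise ``ValueError``.
    """
    entries = ladder.entries
    if not entries[0][1] <= t_a <= entries[-1][1]:
        raise ValueError(
            f"retention time {t_a} min outside ladder span "
            f"[{entries[0][1]}, {entries[-1][1]}]"
        )
    for (n_lo, t_lo), (n_hi, t_hi) in zip(entries, entries[1:]):
        if t_lo <= t_a <= t_hi:
            # ladder gaps (skipped alkanes) interpolate across 100*(n_hi-n_lo)
            return 100.0 * n_lo + 100.0 * (n_hi - n_lo) * (t_a - t_lo) / (t_hi - t_lo)
    raise AssertionError("unreachable")  # pragma: no cover


def semi_quantify(peak: PeakMeasurement) -> float:
    """Concentration from the analyte/internal-standard peak-area ratio.

    ``C = (A_c / A_i) * C_i`` in the units of the internal-standard
    concentration ``C_i``.
    """
    return peak.area / peak.internal_standard_area * peak.internal_standard_conc


def compute_oav(concentration: float, meta: CompoundMeta,
                region: str = "") -> OAVRecord:
    """OAV of one compound: concentration / odor threshold.

    When the compound has no literature threshold the OAV is absent and the
    primary flag is False.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if meta.odor_threshold is None:
        return OAVRecord(meta.name, region, concentration, None, None, False)
    oav = concentration / meta.odor_threshold
    return OAVRecord(meta.name, region, concentration, meta.odor_threshold,
                     oav, oav > 1.0)


def oav_records(summaries: Sequence[RegionSummary],
                metas: Sequence[CompoundMeta]) -> list[OAVRecord]:
    """OAVs of every (compound, region) pair from region mean concentrations."""
    by_name = {m.name: m for m in metas}
    out = []
    for summ in summaries:
        for name, conc in zip(summ.compound_names, summ.means):
            meta = by_name.get(name)
            if meta is None:
                raise KeyError(f"no metadata for compound {name!r}")
            out.append(compute_oav(float(conc), meta, summ.region))
    return out


def primary_aroma_screen(records: Sequence[OAVRecord],
                         rule: str = "any_region") -> set[str]:
    """Compounds whose OAV exceeds 1, under the given screening rule.

    ``any_region`` (default): OAV > 1 in at least one region.
    ``all_regions``: OAV > 1 in every region where the compound has a
    threshold.
    """
    if rule not in ("any_region", "all_regions"):
        raise ValueError(f"unknown rule {rule!r}")
    oavs: dict[str, list[float]] = {}
    for rec in records:
        if rec.oav is not None:
            oavs.setdefault(rec.compound, []).append(rec.oav)
    agg = max if rule == "any_region" else min
    return {name for name, vals in oavs.items() if agg(vals) > 1.0}


def oav_table(summaries: Sequence[RegionSummary],
              metas: Sequence[CompoundMeta],
              rule: str = "any_region") -> pd.DataFrame:
    """Compound x region OAV matrix with the primary-aroma flag.

    Rows are restricted to compounds with a known threshold; the ``primary``
    column applies the screening rule across regions.
    """
    records = oav_records(summaries, metas)
    primary = primary_aroma_screen(records, rule)
    regions = sorted({r.region for r in summaries})
    rows: dict[str, dict[str, float]] = {}
    for rec in records:
        if rec.oav is not None:
            rows.setdefault(rec.compound, {})[rec.region] = rec.oav
    names = [m.name for m in metas if m.name in rows]
    df = pd.DataFrame(
        [[rows[n].get(r, np.nan) for r in regions] for n in names],
        index=names, columns=regions,
    )
    df["primary"] = [n in primary for n in names]
    return df
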