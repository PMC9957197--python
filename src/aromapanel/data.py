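"""Domain types and tabular I/O for volatile feature tables.

The central container is :class:`FeatureTable`: a samples x compounds
concentration matrix (µg/kg) with one region label per sample and a boolean
mask marking not-detected ("nd") cells.  nd cells are stored as 0 but kept
distinguishable from a measured zero so that downstream log-ratio and
presence/absence logic can treat them as structural zeros.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CATEGORIES",
    "ND_TOKENS",
    "CompoundMeta",
    "FeatureTable",
    "RegionSummary",
    "PipelineConfig",
    "read_feature_table",
    "write_feature_table",
    "read_compound_meta",
    "write_compound_meta",
    "summarize_by_region",
]

#: Closed set of chemical classes used for compound annotation.
CATEGORIES = frozenset(
    {"ester", "alcohol", "aldehyde", "ketone", "hydrocarbon", "benzene",
     "lactone", "ether", "acid"}
)

#: Tokens in an input cell that denote "not detected".
ND_TOKENS = frozenset({"nd", "n.d", "n.d.", ""})


@dataclass(frozen=True)
class CompoundMeta:
    """Identity, retention data and odor annotation of one volatile compound.

    Parameters
    ----------
    name
        Unique compound name within a study.
    retention_time
        GC retention time in minutes, if known.
    retention_index_calc, retention_index_lib
        Kovats retention index calculated from an n-alkane ladder and the
        library reference value, respectively.
    odor_threshold
        Odor detection threshold in µg/L (literature value in water), or
        ``None`` when no literature value exists.
    odor_description
        Free-text odor descriptor (e.g. "sweet, fruity").
    category
        Chemical class; one of :data:`CATEGORIES`.
    """

    name: str
    retention_time: float | None = None
    retention_index_calc: float | None = None
    retention_index_lib: float | None = None
    odor_threshold: float | None = None
    odor_description: str | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("compound name must be non-empty")
        if self.retention_time is not None and self.retention_time < 0:
            raise ValueError(f"{self.name}: retention time must be >= 0")
        if self.odor_threshold is not None and self.odor_threshold <= 0:
            raise ValueError(
                f"{self.name}: odor threshold must be strictly positive, "
                f"got {self.odor_threshold}"
            )
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(
                f"{self.name}: unknown category {self.category!r}; "
                f"expected one of {sorted(CATEGORIES)}"
            )


@dataclass
class FeatureTable:
    """Samples x compounds concentration matrix with region labels.

    ``values[i, j]`` is the concentration (µg/kg) of compound ``j`` in sample
    ``i``; ``nd_mask[i, j]`` is True where the compound was not detected (the
    stored value is then exactly 0).
    """

    sample_ids: list[str]
    region_labels: list[str]
    compounds: list[CompoundMeta]
    values: np.ndarray
    nd_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nd_mask = np.asarray(self.nd_mask, dtype=bool)
        n, p = len(self.sample_ids), len(self.compounds)
        if self.values.shape != (n, p):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} samples x {p} compounds"
            )
        if self.nd_mask.shape != (n, p):
            raise ValueError("nd_mask shape does not match values")
        if len(self.region_labels) != n:
            raise ValueError("one region label required per sample")
        if len(set(self.sample_ids)) != n:
            dup = [s for s in self.sample_ids if self.sample_ids.count(s) > 1]
            raise ValueError(f"duplicate sample id(s): {sorted(set(dup))}")
        names = [c.name for c in self.compounds]
        if len(set(names)) != p:
            raise ValueError("duplicate compound names")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative concentration at sample {self.sample_ids[i]!r}, "
                f"compound {names[j]!r}"
            )
        if np.any(self.values[self.nd_mask] != 0):
            raise ValueError("nd cells must carry value 0")

    # -- convenience accessors -------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def compound_names(self) -> list[str]:
        return [c.name for c in self.compounds]

    @property
    def regions(self) -> list[str]:
        return sorted(set(self.region_labels))

    def region_indices(self, region: str) -> np.ndarray:
        idx = np.array([i for i, r in enumerate(self.region_labels) if r == region])
        if idx.size == 0:
            raise KeyError(
                f"region {region!r} not present; valid regions: {self.regions}"
            )
        return idx

    def subset_regions(self, regions: Sequence[str]) -> "FeatureTable":
        """Rows restricted to the given regions (order of rows preserved)."""
        idx = np.concatenate([self.region_indices(r) for r in regions])
        idx = np.sort(idx)
        return FeatureTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            region_labels=[self.region_labels[i] for i in idx],
            compounds=list(self.compounds),
            values=self.values[idx],
            nd_mask=self.nd_mask[idx],
        )

    def restrict_compounds(self, names: Sequence[str]) -> "FeatureTable":
        """Columns restricted to the given compounds, in the given order."""
        lookup = {c.name: j for j, c in enumerate(self.compounds)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"compound(s) not in table: {missing}")
        cols = [lookup[n] for n in names]
        return FeatureTable(
            sample_ids=list(self.sample_ids),
            region_labels=list(self.region_labels),
            compounds=[self.compounds[j] for j in cols],
            values=self.values[:, cols],
            nd_mask=self.nd_mask[:, cols],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids,
                          columns=self.compound_names)
        df.insert(0, "region", self.region_labels)
        return df


@dataclass
class RegionSummary:
    """Per-region per-compound mean and sample SD (denominator n - 1)."""

    region: str
    compound_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    n: int
    degenerate_n: bool = False  # True when n == 1 and SD is reported as 0

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if np.any(self.sds < 0) or np.any(self.means < 0):
            raise ValueError("means and SDs must be non-negative")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    def mean_of(self, compound: str) -> float:
        return float(self.means[self.compound_names.index(compound)])


@dataclass
class PipelineConfig:
    """Tunable thresholds and run parameters for the marker pipeline.

    Defaults mirror common chemometric practice for volatile marker
    discovery: Pareto scaling, S-plot cutoffs |p(cov)| >= 0.1 and
    |p(corr)| >= 0.5, VIP > 1, Welch p < 0.05, |log2 FC| > 1, 7-fold
    cross-validation and a 200-iteration permutation test.
    """

    scaling_mode: str = "pareto"
    splot_cov_threshold: float = 0.1
    splot_corr_threshold: float = 0.5
    vip_threshold: float = 1.0
    p_threshold: float = 0.05
    log2fc_threshold: float = 1.0
    cv_folds: int = 7
    n_permutations: int = 200
    alpha_ci: float = 0.05
    oav_rule: str = "any_region"
    seed: int = 1

    def __post_init__(self) -> None:
        if self.scaling_mode not in ("pareto", "unit_variance", "center_only"):
            raise ValueError(f"unknown scaling mode {self.scaling_mode!r}")
        if self.oav_rule not in ("any_region", "all_regions"):
            raise ValueError(f"unknown OAV rule {self.oav_rule!r}")
        for fname in ("splot_cov_threshold", "splot_corr_threshold",
                      "vip_threshold", "p_threshold", "log2fc_threshold",
                      "alpha_ci"):
            if getattr(self, fname) <= 0:
                raise ValueError(f"{fname} must be > 0")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_optional_float(token: object) -> float | None:
    if token is None:
        return None
    s = str(token).strip()
    if s.lower() in ("", "n.f", "nf", "na", "nan", "none", "/"):
        return None
    return float(s)


def read_feature_table(
    path: str | Path,
    delimiter: str = ",",
    region_column: str = "region",
    valid_regions: Sequence[str] | None = None,
    compounds: Sequence[CompoundMeta] | None = None,
) -> FeatureTable:
    """Read a samples-in-rows feature table from CSV/TSV.

    The first column holds sample ids, ``region_column`` holds the region
    label, and every remaining column is one compound's concentration in
    µg/kg.  nd tokens ("nd", empty cell) map to value 0 with the nd mask set.

    Parameters
    ----------
    valid_regions
        When given, any region token outside this set raises an error that
        lists the valid labels.
    compounds
        Optional metadata to attach; matched by compound name.  Columns with
        no metadata get a bare :class:`CompoundMeta`.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                     keep_default_na=False)
    if region_column not in df.columns:
        raise ValueError(f"missing required column {region_column!r}")
    regions = [str(r).strip() for r in df[region_column]]
    if valid_regions is not None:
        bad = sorted(set(regions) - set(valid_regions))
        if bad:
            raise ValueError(
                f"unknown region token(s) {bad}; valid labels: "
                f"{sorted(valid_regions)}"
            )
    sample_ids = [str(s) for s in df.index]
    if len(set(sample_ids)) != len(sample_ids):
        dup = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicate sample id(s): {dup}")

    value_cols = [c for c in df.columns if c != region_column]
    n, p = len(sample_ids), len(value_cols)
    values = np.zeros((n, p))
    nd_mask = np.zeros((n, p), dtype=bool)
    for j, col in enumerate(value_cols):
        for i, raw in enumerate(df[col]):
            s = str(raw).strip()
            if s.lower() in ND_TOKENS:
                nd_mask[i, j] = True
                continue
            v = float(s.replace("−", "-"))  # tolerate unicode minus
            if v < 0:
                raise ValueError(
                    f"negative concentration {v} at sample "
                    f"{sample_ids[i]!r}, compound {col!r}"
                )
            values[i, j] = v

    meta_by_name = {c.name: c for c in compounds} if compounds else {}
    metas = [meta_by_name.get(c, CompoundMeta(name=c)) for c in value_cols]
    return FeatureTable(sample_ids, regions, metas, values, nd_mask)


def write_feature_table(table: FeatureTable, path: str | Path,
                        delimiter: str = ",") -> None:
    """Write a feature table to CSV/TSV; nd cells are written as ``nd``.

    ``read_feature_table(write_feature_table(t))`` round-trips values
    bit-exactly (floats are written with ``repr`` precision).
    """
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["sample_id", "region"] + table.compound_names)
        for i, sid in enumerate(table.sample_ids):
            cells: list[str] = [sid, table.region_labels[i]]
            for j in range(len(table.compounds)):
                cells.append("nd" if table.nd_mask[i, j]
                             else repr(float(table.values[i, j])))
            writer.writerow(cells)


def read_compound_meta(path: str | Path, delimiter: str = ",") -> list[CompoundMeta]:
    """Read compound metadata from CSV.

    Required columns: ``name``, ``threshold``, ``description``, ``category``;
    optional: ``retention_time``, ``ri_calc``, ``ri_lib``.  A threshold of
    ``n.f`` (not found in the literature) parses as absent.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    required = {"name", "threshold", "description", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required column(s): {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        thr = _parse_optional_float(row["threshold"])
        desc = row["description"].strip() or None
        if desc == "/":
            desc = None
        cat = row["category"].strip() or None
        out.append(CompoundMeta(
            name=row["name"].strip(),
            retention_time=_parse_optional_float(row.get("retention_time")),
            retention_index_calc=_parse_optional_float(row.get("ri_calc")),
            retention_index_lib=_parse_optional_float(row.get("ri_lib")),
            odor_threshold=thr,
            odor_description=desc,
            category=cat,
        ))
    names = [c.name for c in out]
    if len(set(names)) != len(names):
        raise ValueError("duplicate compound names in metadata")
    return out


def write_compound_meta(metas: Iterable[CompoundMeta], path: str | Path) -> None:
    rows = []
    for c in metas:
        rows.append({
            "name": c.name,
            "retention_time": c.retention_time,
            "ri_calc": c.retention_index_calc,
            "ri_lib": c.retention_index_lib,
            "threshold": c.odor_threshold if c.odor_threshold is not None else "n.f",
            "description": c.odor_description or "/",
            "category": c.category or "",
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def summarize_by_region(table: FeatureTable) -> list[RegionSummary]:
    """Per-region sample mean and sample SD (ddof=1) of every compound.

    A region with a single sample gets SD 0 and ``degenerate_n=True``.
    """
    out = []
    for region in table.regions:
        idx = table.region_indices(region)
        block = table.values[idx]
        n = len(idx)
        means = block.mean(axis=0)
        if n == 1:
            sds = np.zeros(block.shape[1])
        else:
            sds = block.std(axis=0, ddof=1)
        out.append(RegionSummary(
            region=region,
            compound_names=table.compound_names,
            means=means,
            sds=sds,
            n=n,
            degenerate_n=(n == 1),
        ))
    return out
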