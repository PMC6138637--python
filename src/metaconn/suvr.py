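"""Regional SUVR data matrices and per-region group comparison.

A group's data live in an M x 90 matrix (subjects x AAL regions) of
standardized uptake value ratios (SUVR): each region's mean SUV divided by
the subject's whole-cerebellum mean SUV. The ratio removes global,
per-subject scaling (injected dose, body weight), which makes values
comparable across subjects — the property the covariance analysis relies
on.

Group differences are assessed region-by-region with a two-sample t-test
(pooled-variance by default, Welch optional), at a configurable alpha with
optional Bonferroni or Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import RegionAtlas

__all__ = [
    "SuvrDataset",
    "RegionalSuvTable",
    "RegionComparison",
    "GroupComparisonResult",
    "compute_suvr",
    "load_suvr_table",
    "group_ttest",
]

REFERENCE_COLUMN = "Cerebellum_Reference"


@dataclass
class SuvrDataset:
    """One group's subjects x regions SUVR matrix, in atlas region order."""

    group_label: str
    subject_ids: list[str]
    region_names: list[str]
    values: np.ndarray  # (M, 90), positive

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.region_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.region_names)} regions"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUVR matrix contains missing or non-finite values")
        if np.any(self.values <= 0):
            raise ValueError("SUVR values must be strictly positive")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.region_names)
        df.insert(0, "subject_id", self.subject_ids)
        return df


@dataclass
class RegionalSuvTable:
    """Raw regional SUVs plus the per-subject whole-cerebellum reference."""

    group_label: str
    subject_ids: list[str]
    region_names: list[str]
    region_suv: np.ndarray  # (M, 90)
    reference_suv: np.ndarray  # (M,)

    def __post_init__(self):
        self.region_suv = np.asarray(self.region_suv, dtype=float)
        self.reference_suv = np.asarray(self.reference_suv, dtype=float)
        m = len(self.subject_ids)
        if self.region_suv.shape != (m, len(self.region_names)):
            raise ValueError("region_suv shape inconsistent with ids/regions")
        if self.reference_suv.shape != (m,):
            raise ValueError("reference_suv must have one entry per subject")


def compute_suvr(table: RegionalSuvTable) -> SuvrDataset:
    """Divide each subject's regional SUVs by their cerebellar reference SUV.

    Raises ``ValueError`` listing the offending subjects if any reference
    value is zero or negative.
    """
    bad = [
        sid
        for sid, ref in zip(table.subject_ids, table.reference_suv)
        if not ref > 0
    ]
    if bad:
        raise ValueError(f"non-positive cerebellar reference SUV for subjects: {bad}")
    values = table.region_suv / table.reference_suv[:, None]
    return SuvrDataset(
        group_label=table.group_label,
        subject_ids=list(table.subject_ids),
        region_names=list(table.region_names),
        values=values,
    )


def load_suvr_table(
    path: str | Path, atlas: RegionAtlas, group_label: str | None = None
) -> SuvrDataset:
    """Read a delimited subjects-x-regions table and align it to atlas order.

    The file is CSV or TSV (autodetected) with a header row: first column
    the subject id, then one column per AAL region label, in any order. If
    a ``Cerebellum_Reference`` column is present the remaining columns are
    treated as raw SUVs and divided by it.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected subject-id column plus region columns")
    id_col = df.columns[0]
    subject_ids = df[id_col].astype(str).tolist()
    if len(set(subject_ids)) != len(subject_ids):
        dupes = sorted({s for s in subject_ids if subject_ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate subject ids: {dupes}")

    data_cols = set(df.columns[1:])
    has_reference = REFERENCE_COLUMN in data_cols
    region_cols = data_cols - {REFERENCE_COLUMN}
    missing = [n for n in atlas.names if n not in region_cols]
    if missing:
        raise ValueError(f"{path}: missing region columns: {missing}")
    extra = sorted(region_cols - set(atlas.names))
    if extra:
        raise ValueError(f"{path}: unrecognized region columns: {extra}")

    block = df[atlas.names]
    numeric = block.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value at row {r + 1}, column {atlas.names[c]!r}"
        )
    label = group_label if group_label is not None else path.stem
    if has_reference:
        ref = pd.to_numeric(df[REFERENCE_COLUMN], errors="coerce").to_numpy()
        if np.isnan(ref).any():
            raise ValueError(f"{path}: non-numeric {REFERENCE_COLUMN} value")
        table = RegionalSuvTable(
            group_label=label,
            subject_ids=subject_ids,
            region_names=list(atlas.names),
            region_suv=numeric.to_numpy(),
            reference_suv=ref,
        )
        return compute_suvr(table)
    return SuvrDataset(
        group_label=label,
        subject_ids=subject_ids,
        region_names=list(atlas.names),
        values=numeric.to_numpy(),
    )


@dataclass
class RegionComparison:
    region_name: str
    t_statistic: float
    p_value: float
    p_corrected: float
    significant: bool
    direction: int  # sign of mean(a) - mean(b); 0 if equal
    degenerate: bool = False


@dataclass
class GroupComparisonResult:
    group_a: str
    group_b: str
    alpha: float
    test_variant: str  # "pooled" | "welch"
    correction: str  # "none" | "bonferroni" | "bh"
    regions: list[RegionComparison] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": [r.region_name for r in self.regions],
                "t": [r.t_statistic for r in self.regions],
                "p": [r.p_value for r in self.regions],
                "p_corrected": [r.p_corrected for r in self.regions],
                "significant": [r.significant for r in self.regions],
                "direction": [r.direction for r in self.regions],
                "degenerate": [r.degenerate for r in self.regions],
            }
        )

    @property
    def significant_regions(self) -> list[str]:
        return [r.region_name for r in self.regions if r.significant]


def group_ttest(
    a: SuvrDataset,
    b: SuvrDataset,
    alpha: float = 0.01,
    variant: str = "pooled",
    correction: str = "none",
) -> GroupComparisonResult:
    """Per-region two-sample t-test between two groups.

    ``variant`` selects pooled-variance ("pooled") or Welch ("welch") tests;
    ``correction`` applies no, Bonferroni, or Benjamini-Hochberg adjustment
    before comparing to ``alpha``. A region where both groups have zero
    variance is flagged degenerate and never reported significant.
    """
    if a.region_names != b.region_names:
        raise ValueError("datasets do not share a region ordering")
    if a.n_subjects < 2 or b.n_subjects < 2:
        raise ValueError("each group needs at least 2 subjects")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant: {variant!r}")
    if correction not in ("none", "bonferroni", "bh"):
        raise ValueError(f"unknown correction: {correction!r}")

    t, p = stats.ttest_ind(a.values, b.values, axis=0, equal_var=(variant == "pooled"))
    mean_diff = a.values.mean(axis=0) - b.values.mean(axis=0)
    degenerate = np.isnan(t)
    # identical samples give sd 0 and t=0/0; report t=0, p=1, never significant
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)

    if correction == "none":
        p_corr = p.copy()
    else:
        method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[correction]
        _, p_corr, _, _ = multipletests(p, alpha=alpha, method=method)

    result = GroupComparisonResult(
        group_a=a.group_label,
        group_b=b.group_label,
        alpha=alpha,
        test_variant=variant,
        correction=correction,
    )
    for k, name in enumerate(a.region_names):
        sig = bool(p_corr[k] < alpha) and not bool(degenerate[k])
        result.regions.append(
            RegionComparison(
                region_name=name,
                t_statistic=float(t[k]),
                p_value=float(p[k]),
                p_corrected=float(p_corr[k]),
                significant=sig,
                direction=int(np.sign(mean_diff[k])),
                degenerate=bool(degenerate[k]),
            )
        )
    return result
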