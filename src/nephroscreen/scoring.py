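"""Normalization and per-treatment scoring of the screen.

The chain: per-measurement outlier exclusion (mean ± k·SD, default k = 2,
within each treatment group per feature), division by the same-day negative
control mean (fold change), z-scoring of the per-treatment fold changes
across all treatments per feature, per-category annotation ratios,
gross-morphology ratios, and assembly into one record per treatment with
compound-library / ATC metadata.

The assembled table exposes 26 scored parameters: 10 quantitative mean fold
changes, 10 qualitative category ratios, 6 gross-morphology ratios (edema
mild, edema severe, curved back/tail, heartbeat alteration, somite
malformation, yolk necrosis).  Mortality and the derived z-scores travel
alongside but are not counted among the 26.

Sample standard deviations (ddof = 1) are used throughout: treatment groups
of 7–12 embryos make the n−1 correction material.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .morphometry import PARAM_NAMES
from .plate_io import (
    ABNORMALITY_CATEGORIES,
    CATEGORIES,
    GROSS_RATIO_FIELDS,
    AnnotationRecord,
    CompoundRecord,
    GrossMorphologyRecord,
)

__all__ = [
    "OutlierResult",
    "NormalizationError",
    "ScreenResultTable",
    "AbnormalityRule",
    "filter_outliers",
    "control_fold_change",
    "zscore_features",
    "category_ratios",
    "gross_ratios",
    "assemble_results",
    "flag_abnormal",
    "fc_col",
    "z_col",
    "ratio_col",
    "gross_col",
]


class NormalizationError(ValueError):
    """Controls are missing or unusable for a day/feature."""


def fc_col(param: str) -> str:
    return f"fc_{param}"


def z_col(param: str) -> str:
    return f"z_{param}"


def ratio_col(category: str) -> str:
    return f"ratio_{category}"


def gross_col(name: str) -> str:
    return f"gross_{name}"


FC_COLUMNS = tuple(fc_col(p) for p in PARAM_NAMES)
Z_COLUMNS = tuple(z_col(p) for p in PARAM_NAMES)
RATIO_COLUMNS = tuple(ratio_col(c) for c in CATEGORIES)
GROSS_COLUMNS = tuple(gross_col(g) for g in GROSS_RATIO_FIELDS)

#: The 26 scored parameters of the per-treatment record.
SCORED_PARAMETER_COLUMNS: Tuple[str, ...] = FC_COLUMNS + RATIO_COLUMNS + GROSS_COLUMNS


# ---------------------------------------------------------------------------
# Outlier exclusion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutlierResult:
    """Kept values, a keep-mask aligned with the input, and a warning flag."""

    kept: np.ndarray
    keep_mask: np.ndarray
    warned: bool = False


def filter_outliers(values: Sequence[float], k: float = 2.0) -> OutlierResult:
    """Exclude points more than ``k`` sample SDs from the mean (single pass).

    Removes the gross artefacts of damaged, misaligned or severely malformed
    embryos before normalization.  Series shorter than 3 are returned
    unfiltered with ``warned=True`` (no meaningful SD); a zero-variance
    series keeps everything.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("values must be a non-empty 1-D series")
    if x.size < 3:
        return OutlierResult(kept=x, keep_mask=np.ones(x.size, dtype=bool), warned=True)
    m = x.mean()
    s = x.std(ddof=1)
    if s == 0.0:
        keep = np.ones(x.size, dtype=bool)
    else:
        keep = np.abs(x - m) <= k * s
    return OutlierResult(kept=x[keep], keep_mask=keep, warned=False)


# ---------------------------------------------------------------------------
# Control-normalized fold changes
# ---------------------------------------------------------------------------


def _require_feature_frame(features: pd.DataFrame) -> None:
    needed = {"treatment", "day", "is_control", *PARAM_NAMES}
    missing = needed - set(features.columns)
    if missing:
        raise ValueError(f"feature table lacks columns {sorted(missing)}")


def control_fold_change(
    features: pd.DataFrame,
    k: float = 2.0,
    outlier_scope: str = "treatment",
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, int]]:
    """Normalize every measurement by its same-day control mean.

    Parameters
    ----------
    features
        Per-embryo table with columns ``treatment, day, is_control`` plus
        the ten parameters.
    k
        SD multiplier of the outlier exclusion applied per feature within
        each treatment group before any normalization (``outlier_scope`` may
        be set to ``"screen"`` to filter per feature across the whole
        screen instead).

    Returns
    -------
    per_embryo
        The input rows that survived filtering, parameters replaced by fold
        changes.
    per_treatment
        One row per treatment: mean fold change per feature, ``n_embryos``
        (the per-feature minimum of surviving embryo counts), ``day`` and
        ``is_control``.
    exclusions
        Count of excluded measurements per feature.

    Controls normalize to a per-day mean of exactly 1 by construction.
    """
    _require_feature_frame(features)
    if outlier_scope not in ("treatment", "screen"):
        raise ValueError("outlier_scope must be 'treatment' or 'screen'")
    df = features.reset_index(drop=True).copy()
    excluded = {p: 0 for p in PARAM_NAMES}

    keep = pd.DataFrame(True, index=df.index, columns=list(PARAM_NAMES))
    groups = [((None,), df)] if outlier_scope == "screen" else df.groupby(
        "treatment", sort=False
    )
    for _, grp in groups:
        for p in PARAM_NAMES:
            res = filter_outliers(grp[p].to_numpy(), k=k)
            keep.loc[grp.index, p] = res.keep_mask
            excluded[p] += int((~res.keep_mask).sum())

    values = df[list(PARAM_NAMES)].where(keep)  # NaN where excluded

    control_means = (
        values[df["is_control"]].groupby(df.loc[df["is_control"], "day"]).mean()
    )
    for day in df["day"].unique():
        if day not in control_means.index:
            raise NormalizationError(f"no surviving control embryos on day {day!r}")
        bad = [
            p
            for p in PARAM_NAMES
            if not np.isfinite(control_means.loc[day, p])
            or control_means.loc[day, p] <= 0
        ]
        if bad:
            raise NormalizationError(
                f"control mean missing or <= 0 on day {day!r} for features {bad}"
            )

    denom = control_means.loc[df["day"], list(PARAM_NAMES)].to_numpy()
    fc = values.to_numpy() / denom
    per_embryo = df[["plate", "well", "day", "treatment", "embryo", "is_control"]
                    if "plate" in df.columns and "well" in df.columns
                    and "embryo" in df.columns
                    else ["day", "treatment", "is_control"]].copy()
    for i, p in enumerate(PARAM_NAMES):
        per_embryo[fc_col(p)] = fc[:, i]

    agg = per_embryo.groupby("treatment", sort=True)
    rows = []
    for treatment, grp in agg:
        fc_means = {c: grp[c].mean() for c in FC_COLUMNS}
        n = int(grp[list(FC_COLUMNS)].notna().min(axis=1).sum())
        rows.append(
            {
                "treatment": treatment,
                "day": grp["day"].iloc[0],
                "is_control": bool(grp["is_control"].iloc[0]),
                "n_embryos": n,
                **fc_means,
            }
        )
    per_treatment = pd.DataFrame(rows)
    return per_embryo, per_treatment, excluded


# ---------------------------------------------------------------------------
# z-scores
# ---------------------------------------------------------------------------


def zscore_features(fold_changes: pd.DataFrame) -> pd.DataFrame:
    """z-score each feature column across all treatments (ddof = 1).

    Accepts a treatments × features frame (fold-change columns or raw
    parameter names).  Constant columns map to all-zero with a warning;
    a single-row table is an error.  NaNs are ignored in the column moments
    and propagate to the output.
    """
    if len(fold_changes) < 2:
        raise ValueError("z-scores need at least two treatments")
    out = fold_changes.copy()
    numeric = out.select_dtypes(include=[np.number]).columns
    cols = [c for c in numeric if c.startswith("fc_") or c in PARAM_NAMES]
    if not cols:
        raise ValueError("no fold-change columns to z-score")
    for c in cols:
        x = out[c].astype(float)
        m = x.mean(skipna=True)
        s = x.std(ddof=1, skipna=True)
        zname = z_col(c[3:] if c.startswith("fc_") else c)
        if not np.isfinite(s) or s == 0.0:
            warnings.warn(f"constant feature column {c!r}: z-scores set to 0")
            out[zname] = np.where(x.notna(), 0.0, np.nan)
        else:
            out[zname] = (x - m) / s
    return out


# ---------------------------------------------------------------------------
# Qualitative and gross ratios
# ---------------------------------------------------------------------------


def category_ratios(
    annotations: Iterable[AnnotationRecord],
    treatment_of_well: Mapping[Tuple[str, str], str],
) -> pd.DataFrame:
    """Per-treatment ratio of annotated embryos carrying each category.

    ``treatment_of_well`` maps (plate, well label) to the treatment ID.
    Every annotated embryo counts in the denominator — including "empty"
    ones — and an embryo with several tags counts toward each of them, so
    ratios may sum to more than 1.
    """
    counts: Dict[str, Dict[str, int]] = {}
    totals: Dict[str, int] = {}
    for rec in annotations:
        key = (rec.well.plate, rec.well.label)
        try:
            treatment = treatment_of_well[key]
        except KeyError:
            raise ValueError(f"no treatment mapped for well {key}") from None
        totals[treatment] = totals.get(treatment, 0) + 1
        bucket = counts.setdefault(treatment, {c: 0 for c in CATEGORIES})
        for cat in rec.categories:
            bucket[cat] += 1
    if not totals:
        raise ValueError("no annotated embryos")
    rows = []
    for treatment in sorted(totals):
        n = totals[treatment]
        rows.append(
            {
                "treatment": treatment,
                "n_annotated": n,
                **{ratio_col(c): counts[treatment][c] / n for c in CATEGORIES},
            }
        )
    return pd.DataFrame(rows)


def gross_ratios(record: GrossMorphologyRecord) -> Dict[str, float]:
    """Ratios of the six gross parameters plus the mortality fraction."""
    n = record.total_exposed
    return {
        gross_col("curved_back_tail"): record.curved_back_tail / n,
        gross_col("edema_mild"): record.edema_mild / n,
        gross_col("edema_severe"): record.edema_severe / n,
        gross_col("heartbeat_alteration"): record.heartbeat_alteration / n,
        gross_col("somite_malformation"): record.somite_malformation / n,
        gross_col("yolk_necrosis"): record.yolk_necrosis / n,
        "mortality": record.mortality / n,
    }


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

METADATA_COLUMNS = (
    "treatment",
    "compound_id",
    "compound_name",
    "atc_d_level",
    "day",
    "is_control",
    "n_embryos",
    "n_annotated",
    "quantitative_missing",
    "mortality",
)


@dataclass
class ScreenResultTable:
    """One record per treatment: the 26 scored parameters plus metadata.

    ``frame`` columns: metadata, 10 ``fc_*`` mean fold changes, 10 ``z_*``
    z-scores, 10 ``ratio_*`` category ratios, 6 ``gross_*`` ratios.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = (
            set(SCORED_PARAMETER_COLUMNS) | set(Z_COLUMNS) | set(METADATA_COLUMNS)
        ) - set(self.frame.columns)
        if missing:
            raise ValueError(f"result table lacks columns {sorted(missing)}")
        if self.frame["treatment"].duplicated().any():
            raise ValueError("result table must have exactly one row per treatment")

    @property
    def scored_parameters(self) -> Tuple[str, ...]:
        return SCORED_PARAMETER_COLUMNS

    def sorted_by_atc(self) -> pd.DataFrame:
        """Rows sorted by ATC D-level (N/A last), then treatment ID."""
        df = self.frame.copy()
        df["_na"] = df["atc_d_level"].eq("N/A")
        df = df.sort_values(["_na", "atc_d_level", "treatment"]).drop(columns="_na")
        return df.reset_index(drop=True)


def assemble_results(
    per_treatment_fc: pd.DataFrame,
    annotations: Iterable[AnnotationRecord],
    gross: Iterable[GrossMorphologyRecord],
    library: Iterable[CompoundRecord],
    treatment_of_well: Mapping[Tuple[str, str], str],
    all_treatments: Optional[Sequence[str]] = None,
    allow_unknown_compounds: bool = False,
) -> ScreenResultTable:
    """Combine fold changes, z-scores, ratios and metadata per treatment.

    Treatments with no surviving quantitative data (all embryos empty or
    dead) keep their qualitative and gross fields, with quantitative fields
    flagged missing.  A treatment absent from the compound library is an
    error unless ``allow_unknown_compounds`` (controls are always exempt and
    labelled ``DMSO``).
    """
    fc = zscore_features(per_treatment_fc)
    cats = category_ratios(annotations, treatment_of_well)
    gross_by_treatment = {g.treatment: g for g in gross}
    lib_by_id = {c.compound_id: c for c in library}

    treatments = set(fc["treatment"]) | set(cats["treatment"])
    if all_treatments is not None:
        treatments |= set(all_treatments)
    fc_idx = fc.set_index("treatment")
    cat_idx = cats.set_index("treatment")

    rows = []
    for treatment in sorted(treatments):
        is_control = treatment.startswith("DMSO_")
        has_quant = treatment in fc_idx.index
        row: Dict[str, object] = {"treatment": treatment}
        if is_control:
            row.update(compound_id="DMSO", compound_name="DMSO (vehicle control)",
                       atc_d_level="N/A")
        elif treatment in lib_by_id:
            rec = lib_by_id[treatment]
            row.update(
                compound_id=rec.compound_id,
                compound_name=rec.name,
                atc_d_level=rec.d_level,
            )
        elif allow_unknown_compounds:
            row.update(compound_id=treatment, compound_name="unknown compound",
                       atc_d_level="N/A")
        else:
            raise ValueError(f"treatment {treatment!r} absent from compound library")

        if has_quant:
            sub = fc_idx.loc[treatment]
            row["day"] = sub["day"]
            row["n_embryos"] = int(sub["n_embryos"])
            for c in FC_COLUMNS + Z_COLUMNS:
                row[c] = float(sub[c]) if pd.notna(sub[c]) else np.nan
            row["quantitative_missing"] = bool(
                any(pd.isna(sub[c]) for c in FC_COLUMNS)
            )
        else:
            row["day"] = ""
            row["n_embryos"] = 0
            for c in FC_COLUMNS + Z_COLUMNS:
                row[c] = np.nan
            row["quantitative_missing"] = True
        row["is_control"] = is_control

        if treatment in cat_idx.index:
            crow = cat_idx.loc[treatment]
            row["n_annotated"] = int(crow["n_annotated"])
            for c in RATIO_COLUMNS:
                row[c] = float(crow[c])
        else:
            row["n_annotated"] = 0
            for c in RATIO_COLUMNS:
                row[c] = np.nan

        if treatment in gross_by_treatment:
            row.update(gross_ratios(gross_by_treatment[treatment]))
        else:
            for c in GROSS_COLUMNS:
                row[c] = np.nan
            row["mortality"] = np.nan
        rows.append(row)

    columns = list(METADATA_COLUMNS) + list(FC_COLUMNS) + list(Z_COLUMNS) \
        + list(RATIO_COLUMNS) + list(GROSS_COLUMNS)
    frame = pd.DataFrame(rows).reindex(columns=columns)
    return ScreenResultTable(frame=frame)


# ---------------------------------------------------------------------------
# Abnormality flag
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AbnormalityRule:
    """Configurable formalization of the screen's manual hit heuristic.

    A treatment is flagged abnormal if the normal-kidney ratio falls below
    ``max_normal_ratio``, or any abnormality-category ratio reaches
    ``min_category_ratio``, or any quantitative |z-score| reaches
    ``min_abs_z``.  Each clause can be disabled by setting its threshold to
    None.  This is an explicit rule standing in for the expert's heuristic
    calls, not a reconstruction of them.
    """

    max_normal_ratio: Optional[float] = 0.5
    min_category_ratio: Optional[float] = 0.5
    min_abs_z: Optional[float] = 2.0


def flag_abnormal(
    table: ScreenResultTable, rule: AbnormalityRule = AbnormalityRule()
) -> pd.DataFrame:
    """Apply the abnormality rule; returns treatment, flag, fired clauses."""
    df = table.frame
    rows = []
    for row in df.itertuples(index=False):
        fired: List[str] = []
        if rule.max_normal_ratio is not None:
            nk = getattr(row, ratio_col("normal_kidney"))
            if pd.notna(nk) and nk < rule.max_normal_ratio:
                fired.append(f"normal_kidney<{rule.max_normal_ratio}")
        if rule.min_category_ratio is not None:
            for cat in ABNORMALITY_CATEGORIES:
                r = getattr(row, ratio_col(cat).replace("-", "_"), None)
                if r is None:  # pandas namedtuple mangles '-' in identifiers
                    r = df.loc[df["treatment"] == row.treatment, ratio_col(cat)].iloc[0]
                if pd.notna(r) and r >= rule.min_category_ratio:
                    fired.append(f"{cat}>={rule.min_category_ratio}")
        if rule.min_abs_z is not None:
            for p in PARAM_NAMES:
                z = getattr(row, z_col(p))
                if pd.notna(z) and abs(z) >= rule.min_abs_z:
                    fired.append(f"|z_{p}|>={rule.min_abs_z}")
        rows.append(
            {
                "treatment": row.treatment,
                "abnormal": bool(fired),
                "fired_rules": ";".join(fired),
            }
        )
    return pd.DataFrame(rows)
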