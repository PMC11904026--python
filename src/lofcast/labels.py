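"""Functional labels from residual thyroid-hormone transport assays.

Transport assays express variant-mediated T3/T4 uptake relative to
wild-type MCT8 (100%) after background (empty-vector) correction.  The
classifier training labels derive from two activity cut-offs: variants
below 50% relative activity are pathogenic, and among those, activity
below 10% marks moderate/severe loss of function versus mild.  The
clinical LoF classes bin the same axis with assay-system-specific
thresholds (COS-1, JEG-3, patient fibroblasts).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .io import VariantSpec

#: stage-1 training cut-off: relative activity below this is pathogenic.
PATHOGENICITY_CUTOFF = 50.0
#: stage-2 training cut-off: below this, moderate/severe rather than mild LoF.
SEVERITY_CUTOFF = 10.0
#: protein truncation before this residue is fully inactivating.
TRUNCATION_NULL_BEFORE = 575


class LoFClass(str, Enum):
    SEVERE = "severe"
    MODERATE = "moderate"
    MILD = "mild"
    NONE = "none"


#: per-scheme (severe_upper, moderate_upper, mild_upper) activity thresholds,
#: as percent of wild type.  Intervals are closed on the left of the milder
#: side: activity < threshold falls in the more severe class.  The fibroblast
#: scheme has no moderate class.
LOF_SCHEMES: dict[str, tuple[float, float | None, float]] = {
    "COS1_T3": (20.0, 40.0, 75.0),
    "COS1_T4": (20.0, 40.0, 65.0),
    "JEG3_T3": (5.0, 10.0, 50.0),
    "JEG3_T4": (5.0, 10.0, 40.0),
    "FIBRO": (50.0, None, 75.0),
}


class AssayQualityError(ValueError):
    """Wild-type signal does not exceed background: assay uninterpretable."""


@dataclass(frozen=True)
class FunctionalRecord:
    """Residual transport of one variant in one cell model / substrate."""

    variant: VariantSpec
    cell_model: str  # COS-1 | JEG-3 | fibroblast
    substrate: str  # T3 | T4
    relative_activity: float  # percent of wild type, >= 0

    def __post_init__(self) -> None:
        if self.relative_activity < 0:
            raise ValueError("relative activity cannot be negative")


def relative_activity(
    variant_counts: float, wt_counts: float, background_counts: float = 0.0
) -> float:
    """Background-corrected uptake as percent of wild type, clipped at 0."""
    if wt_counts <= background_counts:
        raise AssayQualityError(
            f"wild-type counts ({wt_counts}) do not exceed background "
            f"({background_counts})"
        )
    value = 100.0 * (variant_counts - background_counts) / (
        wt_counts - background_counts
    )
    return max(value, 0.0)


def pathogenicity_label(activity: float) -> str:
    """'pathogenic' iff relative activity < 50%, else 'benign'."""
    if activity < 0:
        raise ValueError(f"negative relative activity: {activity}")
    return "pathogenic" if activity < PATHOGENICITY_CUTOFF else "benign"


def severity_label(activity: float) -> str:
    """Split pathogenic variants: < 10% moderate/severe, 10-50% mild.

    Only defined for pathogenic activity (< 50%).
    """
    if activity < 0:
        raise ValueError(f"negative relative activity: {activity}")
    if activity >= PATHOGENICITY_CUTOFF:
        raise ValueError(
            f"activity {activity}% is not pathogenic (>= "
            f"{PATHOGENICITY_CUTOFF}%); severity is undefined"
        )
    return "moderate_severe" if activity < SEVERITY_CUTOFF else "mild"


def lof_class(activity: float, scheme: str) -> LoFClass:
    """Clinical LoF class of a relative activity under an assay scheme."""
    if scheme not in LOF_SCHEMES:
        raise ValueError(
            f"unknown LoF scheme {scheme!r}; one of {sorted(LOF_SCHEMES)}"
        )
    if activity < 0:
        raise ValueError(f"negative relative activity: {activity}")
    severe_upper, moderate_upper, mild_upper = LOF_SCHEMES[scheme]
    if activity < severe_upper:
        return LoFClass.SEVERE
    if moderate_upper is not None and activity < moderate_upper:
        return LoFClass.MODERATE
    if activity < mild_upper:
        return LoFClass.MILD
    return LoFClass.NONE


def truncation_activity(termination_position: int) -> float | None:
    """Imputed activity for a truncating variant, if imputable.

    Premature termination before residue 575 abolishes transport; such
    variants get 0% relative activity without assay data.  Later
    truncations need measurement and return None.
    """
    if termination_position < 1:
        raise ValueError("termination position must be >= 1")
    if termination_position < TRUNCATION_NULL_BEFORE:
        return 0.0
    return None


def label_table(
    records: list[FunctionalRecord] | pd.DataFrame,
    scheme: str = "JEG3_T4",
) -> pd.DataFrame:
    """Tabulate labels for functional records.

    Accepts a list of :class:`FunctionalRecord` or a DataFrame with
    (variant, relative_activity) columns.  Returns one row per variant
    with pathogenicity_label, severity_label (empty for benign) and the
    LoF class under ``scheme``.
    """
    if isinstance(records, pd.DataFrame):
        df = records[["variant", "relative_activity"]].copy()
    else:
        df = pd.DataFrame(
            {
                "variant": [str(r.variant) for r in records],
                "relative_activity": [r.relative_activity for r in records],
            }
        )
    dup = df["variant"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate variant keys: {sorted(df.loc[dup, 'variant'])}"
        )
    act = df["relative_activity"].to_numpy(dtype=float)
    df["pathogenicity_label"] = [pathogenicity_label(a) for a in act]
    df["severity_label"] = [
        severity_label(a) if a < PATHOGENICITY_CUTOFF else "" for a in act
    ]
    df[f"lof_class_{scheme}"] = [lof_class(a, scheme).value for a in act]
    return df
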