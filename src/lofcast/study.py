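"""Published summary counts of the MCT8 deficiency cohort, used as inputs.

These are the printed cohort-level tallies of the MCT8 (SLC16A2) variant
study this package models: unique patient variants by mutation class,
the transfected-cell assay tallies of complete loss of function, and the
dual classifier's predicted class sizes over the full missense
landscape.  They are inputs to consistency checks (summing subgroup
counts, recomputing percentages), not outputs of this package.
"""

from __future__ import annotations

#: unique SLC16A2 patient variants by mutation class.
VARIANT_CLASS_COUNTS: dict[str, int] = {
    "missense": 63,
    "nonsense": 22,
    "frameshift": 37,
    "small_indel": 9,
    "large_deletion": 14,
    "splice": 10,
}

#: tested variants with completely abolished transport, per assay
#: (cell model, substrate) -> (complete-LoF count, tested count).
COMPLETE_LOF_COUNTS: dict[tuple[str, str], tuple[int, int]] = {
    ("COS-1", "T3"): (70, 112),
    ("JEG-3", "T3"): (76, 112),
    ("COS-1", "T4"): (75, 112),
    ("JEG-3", "T4"): (77, 112),
}

#: dual-classifier predictions over the missense landscape, by class.
PREDICTED_CLASS_COUNTS: dict[str, int] = {
    "benign": 5183,
    "mild": 1071,
    "moderate_severe": 1916,
}


def total_unique_variants() -> int:
    """Sum of the per-class unique-variant counts."""
    return sum(VARIANT_CLASS_COUNTS.values())


def predicted_pathogenic_total() -> int:
    """Predicted pathogenic variants = mild + moderate/severe."""
    return (
        PREDICTED_CLASS_COUNTS["mild"]
        + PREDICTED_CLASS_COUNTS["moderate_severe"]
    )


def complete_lof_percent(cell_model: str = "COS-1", substrate: str = "T3") -> float:
    """Percentage of tested variants with complete loss of function."""
    k, n = COMPLETE_LOF_COUNTS[(cell_model, substrate)]
    return 100.0 * k / n
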