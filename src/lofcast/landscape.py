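"""Full mutational-landscape prediction over a protein region.

Enumerates all 19 non-synonymous substitutions at every position of a
region, runs the dual cascade on each, and exports the resulting matrix
as a long-format CSV or a heat map (color = class, glyph size =
predicted-class probability).  The per-position tolerability summary is
the fraction of substitutions predicted benign.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cascade import CascadeResults
from .io import AMINO_ACIDS, VariantSpec, parse_variant


def enumerate_missense(
    sequence: str, region_start: int, region_end: int
) -> list[VariantSpec]:
    """All 19 substitutions per position, ordered by position then
    alphabetical target residue.  Positions are 1-based on ``sequence``."""
    if not 1 <= region_start <= region_end <= len(sequence):
        raise IndexError(
            f"region {region_start}..{region_end} outside sequence of length "
            f"{len(sequence)}"
        )
    out: list[VariantSpec] = []
    for pos in range(region_start, region_end + 1):
        wt = sequence[pos - 1]
        for mut in AMINO_ACIDS:
            if mut != wt:
                out.append(VariantSpec(pos, wt, mut))
    return out


@dataclass
class MutationalLandscape:
    """Prediction records for (position x 19 substitutions)."""

    records: pd.DataFrame  # columns: position, wt, mut, label, severity, probability

    def __post_init__(self) -> None:
        counts = self.records.groupby("position").size()
        bad = counts[counts != 19]
        if len(bad):
            raise ValueError(
                f"positions without exactly 19 substitutions: {bad.index.tolist()}"
            )
        p = self.records["probability"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("probabilities outside [0, 1]")

    @property
    def positions(self) -> np.ndarray:
        return np.sort(self.records["position"].unique())

    def tolerability(self) -> pd.Series:
        """Per-position fraction of substitutions predicted benign."""
        out = (
            self.records.assign(benign=self.records["label"] == "benign")
            .groupby("position")["benign"]
            .mean()
        )
        return out.rename("tolerability")

    def class_counts(self) -> dict[str, int]:
        benign = int((self.records["label"] == "benign").sum())
        mild = int((self.records["severity"] == "mild").sum())
        mod_sev = int((self.records["severity"] == "moderate_severe").sum())
        return {"benign": benign, "mild": mild, "moderate_severe": mod_sev}


def predict_landscape(
    cascade: CascadeResults,
    feature_provider,
    variants: list[VariantSpec],
) -> MutationalLandscape:
    """Predict every enumerated variant with the cascade.

    ``feature_provider`` maps a list of variants to a feature DataFrame
    indexed by variant string; any provider failure aborts listing the
    failed variants (no partial silent output).
    """
    try:
        table = feature_provider(variants)
    except Exception as exc:  # noqa: BLE001 - annotate which variants failed
        raise RuntimeError(
            f"feature provider failed for the requested {len(variants)} "
            f"variants: {exc}"
        ) from exc
    index = [str(v) for v in variants]
    missing = sorted(set(index) - set(table.index))
    if missing:
        raise RuntimeError(f"feature provider missed variants: {missing}")

    pred = cascade.predict(table.loc[index])
    records = pd.DataFrame(
        {
            "position": [v.position for v in variants],
            "wt": [v.wt for v in variants],
            "mut": [v.mut for v in variants],
            "label": pred["label"].to_numpy(),
            "severity": pred["severity"].to_numpy(),
            "probability": pred["probability"].to_numpy(),
        }
    ).sort_values(["position", "mut"], kind="stable").reset_index(drop=True)
    return MutationalLandscape(records=records)


def export_heatmap(
    landscape: MutationalLandscape, path: str | Path, format: str = "csv"
) -> Path:
    """Write the landscape as long-format CSV or an SVG/PNG heat map."""
    path = Path(path)
    if len(landscape.records) == 0:
        raise ValueError("empty landscape")
    if format == "csv":
        landscape.records.to_csv(path, index=False)
        return path
    if format in ("svg", "png"):
        _render_heatmap(landscape, path, format)
        legend = path.with_suffix(".legend.txt")
        legend.write_text(
            "mutational landscape legend\n"
            "color: green = benign, gold = mild LoF, "
            "darkred = moderate/severe LoF\n"
            "glyph size: predicted-class probability of the deciding stage\n",
            encoding="utf-8",
        )
        return path
    raise ValueError(f"unknown export format {format!r}")


def _render_heatmap(
    landscape: MutationalLandscape, path: Path, format: str
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rec = landscape.records
    positions = landscape.positions
    pos_index = {p: i for i, p in enumerate(positions)}
    muts = [m for m in AMINO_ACIDS]
    mut_index = {m: i for i, m in enumerate(muts)}
    colors = {"benign": "#2ca02c", "mild": "#e6b800", "moderate_severe": "#8b0000"}

    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.28 * len(positions)), 6.0), constrained_layout=True
    )
    for _, row in rec.iterrows():
        key = row["severity"] if row["label"] == "pathogenic" else "benign"
        ax.scatter(
            pos_index[row["position"]],
            mut_index[row["mut"]],
            s=10 + 60 * row["probability"],
            c=colors[key],
            edgecolors="none",
        )
    ax.set_yticks(range(len(muts)), muts, fontsize=6)
    step = max(1, len(positions) // 25)
    ax.set_xticks(
        range(0, len(positions), step),
        [str(p) for p in positions[::step]],
        rotation=90,
        fontsize=6,
    )
    ax.set_xlabel("position")
    ax.set_ylabel("substituted residue")
    ax.set_title("predicted mutational landscape")
    fig.savefig(path, format=format, dpi=150)
    plt.close(fig)


def read_landscape_csv(path: str | Path) -> MutationalLandscape:
    df = pd.read_csv(path, keep_default_na=False)
    df["severity"] = df["severity"].astype(str)
    return MutationalLandscape(records=df)
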