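"""Variant x feature table construction.

Feature families, mirroring the classifier's inputs:

* substitution-matrix scores (AAindex2 accessions, one column each);
* per-position conservation scores from the weighted alignment;
* topology one-hots (transmembrane domain / intracellular loop /
  extracellular loop) from a residue topology map;
* structural features computed on wild-type structure models —
  solvent-accessible surface area (Shrake-Rupley), ligand/membrane
  interface areas, substrate distances, ad-hoc geometry measurements;
* ingested columns (ddG predictions, MD flexibility, external
  conservation grades) consumed as numbers, never recomputed;
* the evolutionary index from the alignment VAE ensemble.

Per-position structural features broadcast to all 19 substitutions at
that position: the structures are wild-type models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    AMINO_ACIDS,
    Alignment,
    StructureModel,
    SubstitutionMatrixSet,
    VariantSpec,
    structure_without_ligand,
)
from .evolution import GAP_CODE, SequenceWeights

#: stage-1 (benign vs pathogenic) canonical feature list, in order.
PATHOGENICITY9 = (
    "LINK010101",
    "GEOD900101",
    "DAYM780301",
    "is_ICL",
    "is_ECL",
    "is_TMD",
    "evolutionary_index",
    "ddG_outward",
    "mean_substrate_distance_outward",
)

#: stage-2 (mild vs moderate/severe) canonical feature list, in order.
SEVERITY22 = (
    "membrane_interface_area_outward",
    "substrate_channel_area_inward",
    "membrane_interface_area_inward",
    "conservation_score",
    "MEHP950101",
    "OVEJ920103",
    "FEND850101",
    "LUTR910107",
    "FITW660101",
    "JOHM930101",
    "MOHR870101",
    "KOSJ950107",
    "CSEM940101",
    "DOSZ010103",
    "KOSJ950101",
    "GIAG010101",
    "KOSJ950114",
    "in_substrate_interaction_surface",
    "evolutionary_index",
    "is_TMD",
    "has_substrate_interaction",
    "is_alpha_helix",
)

CANONICAL_SETS: dict[str, tuple[str, ...]] = {
    "pathogenicity9": PATHOGENICITY9,
    "severity22": SEVERITY22,
}

#: default ligand-proximity cut-off (Angstrom) for the substrate
#: interaction flag; overridable wherever used.
SUBSTRATE_CONTACT_CUTOFF = 4.5

#: default membrane slab half-thickness and dummy-sphere lattice.
MEMBRANE_HALF_THICKNESS = 15.0
MEMBRANE_LATTICE_SPACING = 2.0
MEMBRANE_SPHERE_RADIUS = 1.8


class AssemblyError(ValueError):
    """A canonical feature column has no registered provider."""


# ---------------------------------------------------------------------------
# Feature table container
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Variants x named features with per-column provenance.

    ``data`` is indexed by variant string; ``provenance`` maps column ->
    {"provenance": "computed"|"ingested", "model": tag}.  Computed
    columns must be complete; ingested columns may hold NaN.
    """

    data: pd.DataFrame
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate variant keys: {dups}")
        for col, meta in self.provenance.items():
            if meta.get("provenance") == "computed" and self.data[col].isna().any():
                raise ValueError(f"computed column {col!r} contains missing values")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# Substitution-matrix scores
# ---------------------------------------------------------------------------

def substitution_features(
    variants: list[VariantSpec],
    matrix_set: SubstitutionMatrixSet,
    selection: list[str] | str = "all",
) -> pd.DataFrame:
    """One column per AAindex2 accession; value = lookup(wt, mut)."""
    accessions = matrix_set.accessions if selection == "all" else list(selection)
    out = {}
    for acc in accessions:
        out[acc] = [matrix_set.lookup(acc, v.wt, v.mut) for v in variants]
    return pd.DataFrame(out, index=[str(v) for v in variants])


# ---------------------------------------------------------------------------
# Conservation scores
# ---------------------------------------------------------------------------

#: uniform background over the 20 amino acids (documented choice for the
#: Jensen-Shannon divergence score).
BACKGROUND = np.full(20, 1.0 / 20.0)

CONSERVATION_METHODS = (
    "norm_entropy",
    "jsd_background",
    "gap_adjusted_entropy",
    "ingested_grades",
)


def conservation_features(
    alignment: Alignment,
    weights: SequenceWeights,
    methods: list[str] = ("norm_entropy",),
    grades: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-position conservation, one column per method, all in [0, 1].

    norm_entropy = 1 - H(column) / ln 20 on weighted residue frequencies
    (gaps excluded); jsd_background = Jensen-Shannon divergence to the
    uniform background, normalised by ln 2; gap_adjusted_entropy scales
    norm_entropy by the weighted non-gap fraction; ingested_grades passes
    through an external per-position score (values must be in [0, 1]).
    """
    unknown = set(methods) - set(CONSERVATION_METHODS)
    if unknown:
        raise ValueError(f"unknown conservation methods: {sorted(unknown)}")
    idx = alignment.to_indices()
    w = weights.weights
    L = alignment.length
    out: dict[str, np.ndarray] = {m: np.zeros(L) for m in methods}

    for j in range(L):
        col = idx[:, j]
        nongap = col != GAP_CODE
        wj = w[nongap]
        if wj.sum() == 0:
            warnings.warn(f"column {j + 1} is all gaps; scores set to 0", stacklevel=2)
            continue
        freqs = np.zeros(20)
        np.add.at(freqs, col[nongap], wj)
        freqs /= freqs.sum()
        nz = freqs[freqs > 0]
        entropy = float(-(nz * np.log(nz)).sum())
        nongap_frac = float(wj.sum() / w.sum())
        if "norm_entropy" in out:
            out["norm_entropy"][j] = 1.0 - entropy / np.log(20.0)
        if "gap_adjusted_entropy" in out:
            out["gap_adjusted_entropy"][j] = (1.0 - entropy / np.log(20.0)) * nongap_frac
        if "jsd_background" in out:
            out["jsd_background"][j] = _jsd(freqs, BACKGROUND) / np.log(2.0)

    if "ingested_grades" in out:
        if grades is None:
            raise ValueError("ingested_grades requested but no grades provided")
        g = grades.reindex(range(1, L + 1)).to_numpy(dtype=float)
        if np.nanmin(g) < 0 or np.nanmax(g) > 1:
            raise ValueError("ingested grades must lie in [0, 1]")
        out["ingested_grades"] = g

    df = pd.DataFrame(out, index=pd.RangeIndex(1, L + 1, name="position"))
    return df


def _jsd(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float((a[mask] * np.log(a[mask] / b[mask])).sum())

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

TOPOLOGY_CLASSES = ("TMD", "ICL", "ECL", "N-term", "C-term")


@dataclass
class TopologyMap:
    """Ordered residue segments covering the modelled region."""

    segments: list[tuple[int, int, str]]

    def __post_init__(self) -> None:
        prev_end = None
        for start, end, cls in self.segments:
            if cls not in TOPOLOGY_CLASSES:
                raise ValueError(f"unknown topology class {cls!r}")
            if start > end:
                raise ValueError(f"segment ({start}, {end}) reversed")
            if prev_end is not None and start != prev_end + 1:
                raise ValueError(
                    f"segments must be ascending and contiguous; gap or overlap "
                    f"before position {start}"
                )
            prev_end = end

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    def segment_class(self, position: int) -> str:
        if not self.start <= position <= self.end:
            raise IndexError(
                f"position {position} outside topology map "
                f"({self.start}..{self.end})"
            )
        for start, end, cls in self.segments:
            if start <= position <= end:
                return cls
        raise AssertionError("unreachable: contiguous segments")


def topology_features(
    variant: VariantSpec | int, topology_map: TopologyMap
) -> tuple[int, int, int]:
    """(is_TMD, is_ICL, is_ECL); terminal segments give (0, 0, 0)."""
    position = variant.position if isinstance(variant, VariantSpec) else variant
    cls = topology_map.segment_class(position)
    return (int(cls == "TMD"), int(cls == "ICL"), int(cls == "ECL"))


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform points on the unit sphere; fully deterministic."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def _sasa_arrays(
    coords: np.ndarray, radii: np.ndarray, probe_radius: float, n_points: int
) -> np.ndarray:
    """Per-atom accessible area for arbitrary sphere sets."""
    n = len(coords)
    points = _fibonacci_sphere(n_points)
    expanded = radii + probe_radius
    areas = np.zeros(n)
    # neighbour prefilter by pairwise distances
    diffs = coords[:, None, :] - coords[None, :, :]
    dists = np.sqrt((diffs ** 2).sum(axis=-1))
    for i in range(n):
        cutoff = expanded[i] + expanded
        neighbours = np.where((dists[i] < cutoff) & (np.arange(n) != i))[0]
        surface = coords[i] + expanded[i] * points
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = ((surface - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 >= expanded[j] ** 2
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
    return areas


def sasa(
    structure: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    include_ligand: bool = True,
) -> tuple[np.ndarray, pd.Series]:
    """Shrake-Rupley accessible area: per atom, and summed per residue.

    Deterministic for a fixed point count (Fibonacci sphere sampling).
    Per-residue sums cover protein residues only.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be > 0")
    atoms = structure.atoms if include_ligand else structure.protein_atoms()
    if not atoms:
        raise ValueError("no atoms to compute SASA on")
    coords = np.array([a.xyz for a in atoms])
    radii = np.array([a.radius for a in atoms])
    per_atom = _sasa_arrays(coords, radii, probe_radius, n_points)
    lig_names = set(structure.ligand_residues)
    residues: dict[int, float] = {}
    for atom, area in zip(atoms, per_atom):
        if atom.residue_name in lig_names:
            continue
        residues[atom.residue_number] = residues.get(atom.residue_number, 0.0) + area
    per_residue = pd.Series(residues, name="sasa").sort_index()
    per_residue.index.name = "position"
    return per_atom, per_residue


def interface_area(
    structure: StructureModel,
    partner: str = "ligand",
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> pd.Series:
    """Per-residue area buried by the partner (ligand or membrane slab).

    buried(res) = SASA(protein alone) - SASA(protein + partner), clipped
    at 0.  The membrane partner is a dummy-sphere lattice filling the
    slab between the two z-planes.
    """
    protein = structure.protein_atoms()
    if not protein:
        raise ValueError("structure has no protein atoms")
    coords_p = np.array([a.xyz for a in protein])
    radii_p = np.array([a.radius for a in protein])

    if partner == "ligand":
        extra = structure.ligand_atoms()
        if not extra:
            raise ValueError("no ligand atoms: configure ligand_residues")
        coords_x = np.array([a.xyz for a in extra])
        radii_x = np.array([a.radius for a in extra])
    elif partner == "membrane_slab":
        if structure.membrane_slab is None:
            raise ValueError("structure has no membrane slab configured")
        coords_x, radii_x = _slab_spheres(coords_p, structure.membrane_slab)
    else:
        raise ValueError(f"unknown partner {partner!r}")

    free = _sasa_arrays(coords_p, radii_p, probe_radius, n_points)
    joint = _sasa_arrays(
        np.vstack([coords_p, coords_x]),
        np.concatenate([radii_p, radii_x]),
        probe_radius,
        n_points,
    )[: len(protein)]
    buried = np.clip(free - joint, 0.0, None)

    residues: dict[int, float] = {}
    for atom, area in zip(protein, buried):
        residues[atom.residue_number] = residues.get(atom.residue_number, 0.0) + area
    out = pd.Series(residues, name=f"interface_{partner}").sort_index()
    out.index.name = "position"
    return out


def _slab_spheres(
    protein_coords: np.ndarray,
    slab: tuple[float, float],
    spacing: float = MEMBRANE_LATTICE_SPACING,
    radius: float = MEMBRANE_SPHERE_RADIUS,
    margin: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    z_lo, z_hi = sorted(slab)
    x_lo, y_lo = protein_coords[:, :2].min(axis=0) - margin
    x_hi, y_hi = protein_coords[:, :2].max(axis=0) + margin
    xs = np.arange(x_lo, x_hi + spacing, spacing)
    ys = np.arange(y_lo, y_hi + spacing, spacing)
    zs = np.arange(z_lo, z_hi + spacing / 2, spacing)
    grid = np.array(np.meshgrid(xs, ys, zs, indexing="ij")).reshape(3, -1).T
    # drop lattice spheres overlapping the protein interior
    keep = np.ones(len(grid), dtype=bool)
    for i, c in enumerate(protein_coords):
        keep &= ((grid - c) ** 2).sum(axis=1) > (radius + 1.0) ** 2
        if not keep.any():
            break
    grid = grid[keep]
    return grid, np.full(len(grid), radius)


# ---------------------------------------------------------------------------
# Distances and geometry
# ---------------------------------------------------------------------------

def substrate_distance(
    structure: StructureModel, position: int, mode: str = "mean"
) -> float:
    """Distance (Angstrom) from a residue to the docked substrate.

    ``mean`` (default, the classifier's "mean distance to substrate")
    averages over all residue-atom x ligand-atom pairs; ``min`` takes the
    closest pair.
    """
    ligand = structure.ligand_atoms()
    if not ligand:
        raise ValueError("structure has no ligand atoms for substrate distance")
    res_atoms = structure.residue_atoms(position)
    rc = np.array([a.xyz for a in res_atoms])
    lc = np.array([a.xyz for a in ligand])
    d = np.sqrt(((rc[:, None, :] - lc[None, :, :]) ** 2).sum(axis=-1))
    if mode == "mean":
        return float(d.mean())
    if mode == "min":
        return float(d.min())
    raise ValueError(f"unknown mode {mode!r}")


def geometry_measure(
    structure: StructureModel,
    *selectors: dict,
) -> float:
    """Distance between two selected atoms, or angle (degrees) over three.

    A selector is a dict of atom attributes, e.g. ``{"residue_number":
    193, "name": "OD1"}``; each must match exactly one atom.
    """
    if len(selectors) not in (2, 3):
        raise ValueError("provide two selectors (distance) or three (angle)")
    picked = []
    for sel in selectors:
        matches = [
            a
            for a in structure.atoms
            if all(getattr(a, k) == v for k, v in sel.items())
        ]
        if len(matches) != 1:
            raise ValueError(
                f"selector {sel} matched {len(matches)} atoms; need exactly 1"
            )
        picked.append(np.array(matches[0].xyz))
    if len(picked) == 2:
        return float(np.linalg.norm(picked[0] - picked[1]))
    ba = picked[0] - picked[1]
    bc = picked[2] - picked[1]
    cosine = np.dot(ba, bc) / (np.linalg.norm(ba) * np.linalg.norm(bc))
    return float(np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0))))


def substrate_contact_flag(
    structure: StructureModel,
    position: int,
    cutoff: float = SUBSTRATE_CONTACT_CUTOFF,
) -> int:
    """1 if any residue atom lies within ``cutoff`` of any ligand atom."""
    return int(substrate_distance(structure, position, mode="min") <= cutoff)


def substrate_channel_area(
    structure: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> pd.Series:
    """Per-residue surface facing the substrate channel.

    The substrate molecule is deleted first; the channel-facing area is
    the solvent-accessible area revealed by that deletion, i.e. the
    ligand interface area measured on the solvated apo structure.
    """
    return interface_area(
        structure, partner="ligand", probe_radius=probe_radius, n_points=n_points
    ).rename("substrate_channel_area")


# ---------------------------------------------------------------------------
# Ingested features
# ---------------------------------------------------------------------------

def ingest_features(
    path,
    schema: dict,
    variants: list[VariantSpec],
) -> pd.DataFrame:
    """Join external per-variant or per-position columns onto variants.

    ``schema`` declares {"key": "variant"|"position", "columns": [...]}.
    Per-position values broadcast to all substitutions at that position.
    Missing rows become NaN (provenance: ingested).  Duplicate keys and
    unparseable numerics are errors.
    """
    key = schema.get("key", "variant")
    columns = schema["columns"]
    df = pd.read_csv(path, sep="\t" if str(path).endswith(".tsv") else ",")
    missing_cols = set(columns) - set(df.columns)
    if missing_cols:
        raise ValueError(f"ingested file lacks columns: {sorted(missing_cols)}")
    if df[key].duplicated().any():
        dups = df.loc[df[key].duplicated(), key].tolist()
        raise ValueError(f"duplicate {key} keys in ingested file: {dups}")
    for col in columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.where(bad)[0][0]) + 2  # 1-based incl. header
            raise ValueError(f"unparseable numeric in column {col!r}, row {row}")
        df[col] = pd.to_numeric(df[col], errors="coerce")

    index = [str(v) for v in variants]
    if key == "variant":
        joined = df.set_index("variant")[columns].reindex(index)
    elif key == "position":
        by_pos = df.set_index("position")[columns]
        joined = by_pos.reindex([v.position for v in variants])
        joined.index = pd.Index(index)
    else:
        raise ValueError(f"unknown ingest key {key!r}")
    joined.index.name = "variant"
    return joined


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_feature_table(
    variants: list[VariantSpec],
    provided: pd.DataFrame | FeatureTable,
    canonical_set: str = "all",
    provenance: dict[str, dict] | None = None,
) -> FeatureTable:
    """Order provided columns into a canonical feature set.

    ``canonical_set``: 'pathogenicity9' (the 9 stage-1 features),
    'severity22' (the 22 stage-2 features) or 'all' (every provided
    column).  A canonical column with no provider raises
    :class:`AssemblyError` naming it.
    """
    if isinstance(provided, FeatureTable):
        provenance = provenance or provided.provenance
        provided = provided.data
    index = [str(v) for v in variants]
    missing_rows = set(index) - set(provided.index)
    if missing_rows:
        raise AssemblyError(f"no feature rows for variants: {sorted(missing_rows)}")
    data = provided.loc[index]

    if canonical_set == "all":
        columns = list(data.columns)
    else:
        if canonical_set not in CANONICAL_SETS:
            raise ValueError(f"unknown canonical set {canonical_set!r}")
        columns = list(CANONICAL_SETS[canonical_set])
        absent = [c for c in columns if c not in data.columns]
        if absent:
            raise AssemblyError(
                f"no provider for canonical column(s): {absent}"
            )
    data = data[columns]
    meta = {
        c: (provenance or {}).get(c, {"provenance": "computed", "model": ""})
        for c in columns
    }
    return FeatureTable(data=data, provenance=meta)
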