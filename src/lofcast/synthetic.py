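"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the real inputs:

* alignments with planted per-column conservation (and optional
  cluster structure), for the reweighting/VAE/conservation stack;
* variant feature tables with a known activity-generating model, for
  the two-stage classifier — the default scenario mirrors the study's
  table shape (480 variants x 134 features, 9 stage-1- and 22
  stage-2-informative columns);
* toy structures with analytically known geometry, for the
  SASA/interface/distance operations.

Everything is bit-reproducible from (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, Alignment, Atom, StructureModel, VariantSpec
from . import features as _features

#: canonical stage-1 / stage-2 feature names, used as the informative
#: columns of the default table scenario so the canonical sets are
#: exercised end-to-end.
STAGE1_FEATURES = list(_features.PATHOGENICITY9)
STAGE2_FEATURES = list(_features.SEVERITY22)


# ---------------------------------------------------------------------------
# Alignments with planted conservation
# ---------------------------------------------------------------------------

@dataclass
class MSAScenario:
    """Column-wise generative recipe for a synthetic protein alignment.

    ``conservation`` gives each column's probability of emitting the
    consensus residue (1 = invariant).  Optional cluster structure makes
    non-consensus draws within a cluster agree, mimicking phylogeny.
    """

    n_sequences: int = 200
    length: int = 40
    conservation: np.ndarray | float = 0.5
    consensus: str | None = None
    n_clusters: int = 1
    cluster_cohesion: float = 0.0  # P(non-consensus draw copies cluster ancestor)
    seed: int = 0

    def conservation_vector(self) -> np.ndarray:
        c = np.asarray(self.conservation, dtype=float)
        if c.ndim == 0:
            c = np.full(self.length, float(c))
        if c.shape != (self.length,):
            raise ValueError("conservation must be scalar or length-long")
        if ((c < 0) | (c > 1)).any():
            raise ValueError("conservation strengths must lie in [0, 1]")
        return c


def generate_msa(scenario: MSAScenario) -> Alignment:
    """Emit an alignment; row 0 is the (ungapped) consensus reference."""
    rng = np.random.default_rng(scenario.seed)
    cons = scenario.conservation_vector()
    L, n = scenario.length, scenario.n_sequences

    if scenario.consensus is None:
        consensus = "".join(rng.choice(list(AMINO_ACIDS), size=L))
    else:
        consensus = scenario.consensus
        if len(consensus) != L:
            raise ValueError("consensus length mismatch")

    aa = np.array(list(AMINO_ACIDS))
    cons_idx = np.array([AMINO_ACIDS.index(c) for c in consensus])
    # per-column alternative residues for each cluster ancestor
    clusters = rng.integers(0, max(scenario.n_clusters, 1), size=n)
    anc_alt = rng.integers(0, 19, size=(max(scenario.n_clusters, 1), L))

    seqs = [consensus]
    for i in range(n - 1):
        u = rng.random(L)
        v = rng.random(L)
        fresh = rng.integers(0, 19, size=L)
        alt_choice = np.where(v < scenario.cluster_cohesion, anc_alt[clusters[i]], fresh)
        # map 0..18 onto the 19 non-consensus residues
        alt_idx = alt_choice + (alt_choice >= cons_idx)
        row_idx = np.where(u < cons, cons_idx, alt_idx)
        seqs.append("".join(aa[row_idx]))

    ids = ["reference"] + [f"seq{i:04d}" for i in range(1, n)]
    return Alignment(ids=ids, seqs=seqs, ref_index=0)


# ---------------------------------------------------------------------------
# Feature tables with a known activity model
# ---------------------------------------------------------------------------

@dataclass
class TableTruth:
    """Ground truth behind a generated feature table."""

    stage1_features: list[str]
    stage2_features: list[str]
    beta1: np.ndarray
    beta2: np.ndarray
    intercept1: float
    intercept2: float
    activity: np.ndarray
    pathogenic: np.ndarray
    moderate_severe: np.ndarray


@dataclass
class TableScenario:
    """Recipe for a variant table with separable two-stage structure.

    The latent relative activity is a deterministic function of the
    informative features plus Gaussian noise:

    * stage 1: a1 = 100 * sigmoid(-(X_s1 @ beta1 + b1 + eps1));
      pathogenic iff a1 < 50;
    * stage 2 (pathogenic rows only): activity = 50 * sigmoid(-(X_s2 @
      beta2 + b2 + eps2)); moderate/severe iff < 10.

    Coefficient magnitudes are drawn in [coef_min, coef_max] with random
    signs, keeping every informative feature genuinely informative.
    """

    n_variants: int = 480
    n_features: int = 134
    stage1_features: list[str] = field(default_factory=lambda: list(STAGE1_FEATURES))
    stage2_features: list[str] = field(default_factory=lambda: list(STAGE2_FEATURES))
    noise_sd: float = 1.0
    coef_min: float = 0.6
    coef_max: float = 1.4
    intercept1: float = 0.0
    #: centres the severe/mild split inside the pathogenic stratum
    intercept2: float = 1.386
    protein_length: int = 613  # MCT8 long-isoform length
    seed: int = 42

    def feature_names(self) -> list[str]:
        informative = list(dict.fromkeys(self.stage1_features + self.stage2_features))
        n_noise = self.n_features - len(informative)
        if n_noise < 0:
            raise ValueError("n_features smaller than the informative set")
        return informative + [f"noise_{i:03d}" for i in range(n_noise)]


def generate_feature_table(
    scenario: TableScenario,
) -> tuple[pd.DataFrame, pd.DataFrame, TableTruth]:
    """Returns (feature table, functional records, truth).

    The feature table is indexed by variant string with one named column
    per feature; functional records carry the generated relative
    activity (JEG-3 / T4 by convention).
    """
    if scenario.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(scenario.seed)
    names = scenario.feature_names()
    n, p = scenario.n_variants, len(names)

    variants = _random_variants(rng, n, scenario.protein_length)
    X = rng.standard_normal((n, p))
    table = pd.DataFrame(X, columns=names, index=[str(v) for v in variants])
    table.index.name = "variant"

    def draw_coefs(k: int) -> np.ndarray:
        mags = rng.uniform(scenario.coef_min, scenario.coef_max, size=k)
        signs = rng.choice([-1.0, 1.0], size=k)
        return mags * signs

    beta1 = draw_coefs(len(scenario.stage1_features))
    beta2 = draw_coefs(len(scenario.stage2_features))
    s1 = [names.index(f) for f in scenario.stage1_features]
    s2 = [names.index(f) for f in scenario.stage2_features]

    eps1 = rng.normal(0.0, scenario.noise_sd, size=n)
    eps2 = rng.normal(0.0, scenario.noise_sd, size=n)
    eta1 = X[:, s1] @ beta1 + scenario.intercept1 + eps1
    eta2 = X[:, s2] @ beta2 + scenario.intercept2 + eps2

    a1 = 100.0 / (1.0 + np.exp(eta1))
    pathogenic = a1 < 50.0
    a2 = 50.0 / (1.0 + np.exp(eta2))
    activity = np.where(pathogenic, a2, a1)
    moderate_severe = pathogenic & (activity < 10.0)

    functional = pd.DataFrame(
        {
            "variant": [str(v) for v in variants],
            "cell_model": "JEG-3",
            "substrate": "T4",
            "relative_activity": activity,
        }
    )
    truth = TableTruth(
        stage1_features=list(scenario.stage1_features),
        stage2_features=list(scenario.stage2_features),
        beta1=beta1,
        beta2=beta2,
        intercept1=scenario.intercept1,
        intercept2=scenario.intercept2,
        activity=activity,
        pathogenic=pathogenic,
        moderate_severe=moderate_severe,
    )
    return table, functional, truth


def _random_variants(
    rng: np.random.Generator, n: int, protein_length: int
) -> list[VariantSpec]:
    reference = rng.choice(list(AMINO_ACIDS), size=protein_length)
    seen: set[str] = set()
    out: list[VariantSpec] = []
    while len(out) < n:
        pos = int(rng.integers(1, protein_length + 1))
        wt = str(reference[pos - 1])
        mut = str(rng.choice([a for a in AMINO_ACIDS if a != wt]))
        v = VariantSpec(pos, wt, mut)
        if str(v) not in seen:
            seen.add(str(v))
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

def toy_structure(
    residue_atoms: list[tuple[int, str, str, str, tuple[float, float, float], float]],
    ligand_atoms: list[tuple[str, str, tuple[float, float, float], float]] = (),
    membrane_slab: tuple[float, float] | None = None,
    ligand_residue: str = "LIG",
    conformation: str = "other",
) -> StructureModel:
    """Assemble a minimal structure with analytically known geometry.

    ``residue_atoms``: (residue_number, residue_name, atom_name, element,
    xyz, radius) tuples; ``ligand_atoms``: (atom_name, element, xyz,
    radius).  Duplicate (residue, atom-name) pairs are rejected.
    """
    atoms: list[Atom] = []
    seen: set[tuple[int, str]] = set()
    for resnum, resname, name, element, xyz, radius in residue_atoms:
        key = (resnum, name)
        if key in seen:
            raise ValueError(f"duplicate atom id {key}")
        seen.add(key)
        atoms.append(Atom(name, resnum, resname, "A", tuple(xyz), element, radius))
    for i, (name, element, xyz, radius) in enumerate(ligand_atoms):
        key = (9000 + i, name)
        atoms.append(Atom(name, 9000, ligand_residue, "L", tuple(xyz), element, radius))
    return StructureModel(
        atoms=atoms,
        ligand_residues=(ligand_residue,),
        membrane_slab=membrane_slab,
        conformation=conformation,
    )


def write_pdb(structure: StructureModel, path) -> None:
    """Write a minimal PDB file (ATOM for protein, HETATM for ligand)."""
    lines = []
    lig = structure.is_ligand()
    for i, (atom, is_lig) in enumerate(zip(structure.atoms, lig), start=1):
        record = "HETATM" if is_lig else "ATOM  "
        x, y, z = atom.xyz
        lines.append(
            f"{record}{i:5d} {atom.name:<4.4s}{atom.residue_name:>4.3s} "
            f"{atom.chain:1.1s}{atom.residue_number % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{atom.element:>2.2s}"
        )
    lines.append("END")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
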