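"""Readers and writers for the external formats the pipeline touches.

Covers protein multiple sequence alignments (FASTA / A2M), AAindex2
substitution-matrix flat files, PDB structure models with a docked
substrate, variant tables, and HGVS-style protein variant notation.

All residue numbering is 1-based on the reference protein (codon 1 is the
initiator Met of the long MCT8 isoform, NP_006508.1); no 0-based positions
are ever user-visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: alignment alphabet: 20 amino acids + gap (gap is category 20)
ALPHABET = AMINO_ACIDS + GAP
AA_TO_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: van der Waals radii (Angstrom) used for surface-area calculations;
#: override via the ``radii`` argument of :func:`read_structure`.
DEFAULT_ATOM_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "I": 1.98, "H": 1.20, "P": 1.80,
}
DEFAULT_UNKNOWN_RADIUS = 1.70


class FormatError(ValueError):
    """Malformed input file or notation."""


class UnsupportedNotationError(FormatError):
    """Variant notation outside the supported protein-level forms."""


class SynonymousVariantError(ValueError):
    """wt == mut: not a missense variant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class VariantSpec:
    """A single-residue missense substitution in reference coordinates.

    ``position`` is 1-based on the reference protein; ``wt`` and ``mut``
    are one-letter amino-acid codes.  This triple is the universal key
    joining alignments, feature tables and functional-assay records.
    """

    position: int
    wt: str
    mut: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for attr in ("wt", "mut"):
            aa = getattr(self, attr)
            if aa not in AMINO_ACIDS:
                raise ValueError(f"unknown amino acid {aa!r} for {attr}")

    def __str__(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"

    @property
    def hgvs(self) -> str:
        return f"p.{ONE_TO_THREE[self.wt]}{self.position}{ONE_TO_THREE[self.mut]}"

    @property
    def is_synonymous(self) -> bool:
        return self.wt == self.mut


@dataclass
class Alignment:
    """A protein multiple sequence alignment in reference-column space.

    After A2M filtering, columns map 1:1 to reference positions; the
    reference (query) row contains no gaps.
    """

    ids: list[str]
    seqs: list[str]
    ref_index: int = 0

    def __post_init__(self) -> None:
        if not self.seqs:
            raise FormatError("alignment has no sequences")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1 or 0 in lengths:
            raise FormatError(
                f"ragged or empty alignment: row lengths {sorted(lengths)}"
            )
        if len(self.ids) != len(self.seqs):
            raise FormatError("ids and seqs differ in length")
        bad = set("".join(self.seqs)) - set(ALPHABET) - {"X"}
        if bad:
            raise FormatError(f"non-amino-acid symbols in alignment: {sorted(bad)}")

    @property
    def n_sequences(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def reference(self) -> str:
        return self.seqs[self.ref_index]

    def to_indices(self) -> np.ndarray:
        """Integer-encode as (n_sequences, length); 'X' counts as gap."""
        idx = np.empty((self.n_sequences, self.length), dtype=np.int8)
        gap_code = AA_TO_INDEX[GAP]
        for i, seq in enumerate(self.seqs):
            idx[i] = [AA_TO_INDEX.get(c, gap_code) for c in seq]
        return idx


@dataclass
class SubstitutionMatrixSet:
    """AAindex2 substitution matrices keyed by accession.

    Each matrix is a 20x20 array indexed by ``AMINO_ACIDS`` order with
    symmetric lookup; missing cells hold NaN and are rejected at feature
    time, never silently imputed.
    """

    matrices: dict[str, np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.matrices)

    def __contains__(self, accession: str) -> bool:
        return accession in self.matrices

    @property
    def accessions(self) -> list[str]:
        return list(self.matrices)

    def lookup(self, accession: str, a: str, b: str) -> float:
        m = self.matrices[accession]
        value = m[AMINO_ACIDS.index(a), AMINO_ACIDS.index(b)]
        if np.isnan(value):
            raise ValueError(
                f"matrix {accession} has no value for pair ({a}, {b})"
            )
        return float(value)


@dataclass(frozen=True)
class Atom:
    name: str
    residue_number: int
    residue_name: str
    chain: str
    xyz: tuple[float, float, float]
    element: str
    radius: float


@dataclass
class StructureModel:
    """A protein structure model, optionally with a docked substrate.

    ``ligand_residues`` names the HETATM residue(s) of the docked
    substrate (e.g. T4); ``membrane_slab`` is the (z_lower, z_upper) pair
    of bilayer planes in Angstrom when the model is membrane-embedded.
    """

    atoms: list[Atom]
    ligand_residues: tuple[str, ...] = ("T44", "T4", "LIG")
    membrane_slab: tuple[float, float] | None = None
    conformation: str = "other"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise FormatError("structure has no atoms")
        if not np.all(np.isfinite(self.coordinates)):
            raise FormatError("non-finite atom coordinates")

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def is_ligand(self) -> np.ndarray:
        names = set(self.ligand_residues)
        return np.array([a.residue_name in names for a in self.atoms])

    def ligand_atoms(self) -> list[Atom]:
        mask = self.is_ligand()
        return [a for a, m in zip(self.atoms, mask) if m]

    def protein_atoms(self) -> list[Atom]:
        mask = self.is_ligand()
        return [a for a, m in zip(self.atoms, mask) if not m]

    def residue_atoms(self, residue_number: int) -> list[Atom]:
        out = [
            a for a, lig in zip(self.atoms, self.is_ligand())
            if not lig and a.residue_number == residue_number
        ]
        if not out:
            modelled = sorted({a.residue_number for a in self.protein_atoms()})
            raise KeyError(
                f"residue {residue_number} not in structure; modelled range "
                f"{modelled[0]}..{modelled[-1]}"
            )
        return out


# ---------------------------------------------------------------------------
# Alignment reading
# ---------------------------------------------------------------------------

def read_alignment(
    path: str | Path,
    format: str = "fasta",
    ref_index: int = 0,
) -> Alignment:
    """Read a FASTA or A2M alignment into reference-column space.

    A2M lowercase columns (insertions relative to the query) are deleted
    and '.' is treated as a gap; residues are uppercased.  The first
    record is the reference unless ``ref_index`` overrides it.
    """
    if format not in ("fasta", "a2m"):
        raise ValueError(f"unknown alignment format {format!r}")
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise FormatError(f"no sequences in {path}")
    ids = [r.id for r in records]
    raw = [str(r.seq) for r in records]

    if format == "a2m":
        seqs = ["".join(c for c in s if not (c.islower() or c == ".")) for s in raw]
    else:
        seqs = [s.replace(".", GAP) for s in raw]
    seqs = [s.upper() for s in seqs]

    aln = Alignment(ids=ids, seqs=seqs, ref_index=ref_index)
    if GAP in aln.reference or "X" in aln.reference:
        raise FormatError(
            "reference row contains gaps or ambiguous residues after column "
            "filtering; choose another ref_index or fix the alignment"
        )
    return aln


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in zip(alignment.ids, alignment.seqs):
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# AAindex2
# ---------------------------------------------------------------------------

def parse_aaindex2(path: str | Path) -> SubstitutionMatrixSet:
    """Parse an AAindex2 flat file into a :class:`SubstitutionMatrixSet`.

    Entries are delimited by '//'; the 'H' line carries the accession and
    the 'M' line declares row/column amino-acid orders.  Triangular input
    is mirrored so that ``lookup(a, b) == lookup(b, a)``.  '-' cells are
    stored as NaN.
    """
    text = Path(path).read_text(encoding="utf-8")
    out = SubstitutionMatrixSet()
    for chunk in text.split("//"):
        lines = [ln for ln in chunk.splitlines() if ln.strip()]
        if not lines:
            continue
        accession = None
        m_line_idx = None
        for i, ln in enumerate(lines):
            if ln.startswith("H "):
                accession = ln[2:].strip()
            elif ln.startswith("M "):
                m_line_idx = i
        if accession is None:
            continue
        if m_line_idx is None:
            raise FormatError(f"AAindex2 entry {accession} lacks an M section")
        rows_order, cols_order = _parse_m_header(lines[m_line_idx], accession)

        matrix = np.full((20, 20), np.nan)
        value_lines = lines[m_line_idx + 1:]
        if len(value_lines) < len(rows_order):
            raise FormatError(
                f"AAindex2 entry {accession}: expected {len(rows_order)} value "
                f"rows, found {len(value_lines)}"
            )
        value_lines = value_lines[: len(rows_order)]
        triangular = len(value_lines[0].split()) == 1 and len(cols_order) > 1
        for r, ln in enumerate(value_lines):
            tokens = ln.split()
            n_expected = r + 1 if triangular else len(cols_order)
            if len(tokens) != n_expected:
                raise FormatError(
                    f"AAindex2 entry {accession} row {r + 1}: expected "
                    f"{n_expected} values, found {len(tokens)}"
                )
            for c, tok in enumerate(tokens):
                value = np.nan if tok == "-" else float(tok)
                ai = AMINO_ACIDS.index(rows_order[r])
                bi = AMINO_ACIDS.index(cols_order[c])
                matrix[ai, bi] = value
                matrix[bi, ai] = value
        out.matrices[accession] = matrix
    if not out.matrices:
        raise FormatError(f"no AAindex2 entries found in {path}")
    return out


def _parse_m_header(line: str, accession: str) -> tuple[str, str]:
    # e.g. "M rows = ARNDCQEGHILKMFPSTWYV, cols = ARNDCQEGHILKMFPSTWYV"
    try:
        body = line[2:]
        parts = {}
        for p in body.split(","):
            if "=" in p:
                k, v = p.split("=", 1)
                parts[k.strip()] = v.strip()
        rows, cols = parts["rows"], parts["cols"]
    except Exception as exc:  # noqa: BLE001 - re-raise as format error
        raise FormatError(f"AAindex2 entry {accession}: bad M line {line!r}") from exc
    for order in (rows, cols):
        if sorted(order) != sorted(AMINO_ACIDS):
            raise FormatError(
                f"AAindex2 entry {accession}: M line does not list the 20 "
                f"amino acids ({order!r})"
            )
    return rows, cols


# ---------------------------------------------------------------------------
# Variant notation
# ---------------------------------------------------------------------------

def parse_variant(text: str) -> VariantSpec:
    """Parse "D498N" or "p.Asp498Asn" into a :class:`VariantSpec`.

    cDNA notation ("c.1301G>A") is rejected: transcript-to-protein mapping
    is out of scope.  A synonymous substitution raises
    :class:`SynonymousVariantError` so callers can treat it distinctly.
    """
    s = text.strip()
    if s.startswith("c."):
        raise UnsupportedNotationError(
            f"cDNA notation not supported: {text!r}; use protein-level notation"
        )
    if s.startswith("p."):
        s = s[2:].strip("()")
        wt3, pos, mut3 = _split_hgvs(s, text)
        try:
            wt, mut = THREE_TO_ONE[wt3], THREE_TO_ONE[mut3]
        except KeyError as exc:
            raise FormatError(f"unknown residue code in {text!r}") from exc
    else:
        if len(s) < 3 or not s[1:-1].isdigit():
            raise FormatError(f"cannot parse variant notation {text!r}")
        wt, pos, mut = s[0].upper(), s[1:-1], s[-1].upper()
        if wt not in AMINO_ACIDS or mut not in AMINO_ACIDS:
            raise FormatError(f"unknown residue code in {text!r}")
    position = int(pos)
    if position < 1:
        raise FormatError(f"position must be positive in {text!r}")
    if wt == mut:
        raise SynonymousVariantError(f"synonymous substitution: {text!r}")
    return VariantSpec(position=position, wt=wt, mut=mut)


def _split_hgvs(s: str, original: str) -> tuple[str, str, str]:
    if len(s) < 7:
        raise FormatError(f"cannot parse HGVS protein notation {original!r}")
    wt3, rest = s[:3].capitalize(), s[3:]
    digits = ""
    while rest and rest[0].isdigit():
        digits, rest = digits + rest[0], rest[1:]
    if not digits or len(rest) != 3:
        raise FormatError(f"cannot parse HGVS protein notation {original!r}")
    return wt3, digits, rest.capitalize()


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV variant table; parses a 'variant' column if present.

    Returns a DataFrame with at least (variant, position, wt, mut) columns;
    extra columns pass through untouched.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if "variant" in df.columns:
        specs = [parse_variant(v) for v in df["variant"]]
        df["position"] = [v.position for v in specs]
        df["wt"] = [v.wt for v in specs]
        df["mut"] = [v.mut for v in specs]
    elif not {"position", "wt", "mut"} <= set(df.columns):
        raise FormatError(
            f"variant table {path} needs a 'variant' column or "
            "(position, wt, mut) columns"
        )
    else:
        df["variant"] = [
            str(VariantSpec(int(p), w, m))
            for p, w, m in zip(df["position"], df["wt"], df["mut"])
        ]
    return df


def write_variant_table(
    variants: Iterable[VariantSpec], path: str | Path,
    extra: pd.DataFrame | None = None,
) -> None:
    variants = list(variants)
    df = pd.DataFrame(
        {
            "variant": [str(v) for v in variants],
            "position": [v.position for v in variants],
            "wt": [v.wt for v in variants],
            "mut": [v.mut for v in variants],
        }
    )
    if extra is not None:
        df = pd.concat([df, extra.reset_index(drop=True)], axis=1)
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False)


def variants_from_table(df: pd.DataFrame) -> list[VariantSpec]:
    return [
        VariantSpec(int(p), w, m)
        for p, w, m in zip(df["position"], df["wt"], df["mut"])
    ]


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

def read_structure(
    path: str | Path,
    ligand_residues: Sequence[str] = ("T44", "T4", "LIG"),
    radii: dict[str, float] | None = None,
    unknown_radius: float = DEFAULT_UNKNOWN_RADIUS,
    membrane_slab: tuple[float, float] | None = None,
    conformation: str = "other",
) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Atom radii come from a documented element table; unknown elements get
    ``unknown_radius`` with a warning.  Ligand atoms are identified by
    residue name from ``ligand_residues``.
    """
    radii = dict(DEFAULT_ATOM_RADII if radii is None else radii)
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure("model", str(path))
    except ValueError as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    atoms: list[Atom] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    element = (atom.element or atom.get_name()[0]).upper()
                    if element not in radii:
                        warnings.warn(
                            f"unknown element {element!r}; using default "
                            f"radius {unknown_radius} A",
                            stacklevel=2,
                        )
                    atoms.append(
                        Atom(
                            name=atom.get_name(),
                            residue_number=residue.id[1],
                            residue_name=residue.get_resname().strip(),
                            chain=chain.id,
                            xyz=tuple(float(x) for x in atom.coord),
                            element=element,
                            radius=radii.get(element, unknown_radius),
                        )
                    )
        break  # first model only
    if not atoms:
        raise FormatError(f"no atoms in {path}")
    return StructureModel(
        atoms=atoms,
        ligand_residues=tuple(ligand_residues),
        membrane_slab=membrane_slab,
        conformation=conformation,
    )


def structure_without_ligand(structure: StructureModel) -> StructureModel:
    """Copy with the docked substrate removed (e.g. before channel SASA)."""
    return replace(structure, atoms=structure.protein_atoms())
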