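"""Feature engineering: substitution scores, conservation, topology,
surface areas, distances and canonical assembly."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lofcast.evolution import compute_sequence_weights
from lofcast.features import (
    AssemblyError,
    FeatureTable,
    PATHOGENICITY9,
    SEVERITY22,
    TopologyMap,
    assemble_feature_table,
    conservation_features,
    geometry_measure,
    ingest_features,
    interface_area,
    sasa,
    substitution_features,
    substrate_channel_area,
    substrate_contact_flag,
    substrate_distance,
    topology_features,
)
from lofcast.io import Alignment, VariantSpec, parse_aaindex2
from lofcast.synthetic import TableScenario, generate_feature_table, toy_structure


def grid_oracle_sasa(structure, probe_radius=1.4, n_theta=80, n_phi=160):
    """Dense latitude-longitude surface integration, independent of the
    Fibonacci sampling used by the implementation."""
    coords = structure.coordinates
    radii = structure.radii + probe_radius
    total = 0.0
    thetas = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    phis = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
    t, p = np.meshgrid(thetas, phis, indexing="ij")
    unit = np.stack(
        [np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)], axis=-1
    ).reshape(-1, 3)
    weight = (np.sin(t) * (np.pi / n_theta) * (2 * np.pi / n_phi)).reshape(-1)
    for i in range(len(coords)):
        pts = coords[i] + radii[i] * unit
        ok = np.ones(len(pts), dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            ok &= ((pts - coords[j]) ** 2).sum(axis=1) >= radii[j] ** 2
        total += radii[i] ** 2 * (weight * ok).sum()
    return total


class TestSubstitutionFeatures:
    def test_lookup_values(self, aaindex_file):
        ms = parse_aaindex2(aaindex_file)
        out = substitution_features(
            [VariantSpec(498, "D", "N")], ms, selection=["IDEN900102"]
        )
        assert out.loc["D498N", "IDEN900102"] == 0.0
        assert list(out.columns) == ["IDEN900102"]

    def test_one_column_per_matrix(self, aaindex_file):
        ms = parse_aaindex2(aaindex_file)
        out = substitution_features([VariantSpec(10, "A", "V")], ms)
        assert set(out.columns) == set(ms.accessions)


class TestConservation:
    @pytest.fixture()
    def toy_alignment(self):
        # col0 invariant A; col1 uniform over all 20; col2 half A half V
        rows = []
        for i in range(40):
            c1 = "ACDEFGHIKLMNPQRSTVWY"[i % 20]
            c2 = "A" if i % 2 == 0 else "V"
            rows.append("A" + c1 + c2)
        return Alignment(ids=[f"s{i}" for i in range(40)], seqs=rows)

    def test_entropy_extremes_and_half_half(self, toy_alignment):
        w = compute_sequence_weights(toy_alignment, theta=0.01)
        # force equal weights for the hand computation
        w.weights[:] = 1.0
        scores = conservation_features(toy_alignment, w, ["norm_entropy"])
        assert scores.loc[1, "norm_entropy"] == pytest.approx(1.0)
        assert scores.loc[2, "norm_entropy"] == pytest.approx(0.0, abs=1e-12)
        assert scores.loc[3, "norm_entropy"] == pytest.approx(
            1 - np.log(2) / np.log(20)
        )

    def test_scores_bounded_and_invariant_column_maximal(self, toy_alignment):
        w = compute_sequence_weights(toy_alignment, theta=0.01)
        w.weights[:] = 1.0
        scores = conservation_features(
            toy_alignment, w,
            ["norm_entropy", "jsd_background", "gap_adjusted_entropy"],
        )
        assert ((scores >= 0) & (scores <= 1)).all().all()
        for method in scores.columns:
            assert scores.loc[1, method] == scores[method].max()

    def test_all_gap_column_scores_zero_with_warning(self):
        aln = Alignment(ids=["r", "a", "b"], seqs=["AAA", "A-A", "A-A"])
        w = compute_sequence_weights(aln, theta=0.01)
        # zero out the reference's weight share at column 2 by masking rows:
        # simplest honest construction: all non-reference rows gapped and
        # reference weight set to 0 for the column statistic
        w.weights[0] = 0.0
        with pytest.warns(UserWarning, match="all gaps"):
            scores = conservation_features(aln, w, ["norm_entropy"])
        assert scores.loc[2, "norm_entropy"] == 0.0


class TestTopology:
    @pytest.fixture()
    def tmap(self):
        return TopologyMap(
            segments=[
                (1, 10, "N-term"),
                (11, 30, "TMD"),
                (31, 40, "ICL"),
                (41, 60, "TMD"),
                (61, 70, "ECL"),
                (71, 80, "C-term"),
            ]
        )

    def test_flags(self, tmap):
        assert topology_features(VariantSpec(15, "A", "V"), tmap) == (1, 0, 0)
        assert topology_features(35, tmap) == (0, 1, 0)
        assert topology_features(65, tmap) == (0, 0, 1)
        assert topology_features(5, tmap) == (0, 0, 0)

    def test_position_outside_map_rejected(self, tmap):
        with pytest.raises(IndexError):
            topology_features(81, tmap)

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            TopologyMap(segments=[(1, 10, "TMD"), (5, 20, "ICL")])


class TestSASA:
    def test_isolated_sphere_matches_closed_form(self, carbon_sphere):
        per_atom, per_res = sasa(carbon_sphere, probe_radius=1.4, n_points=960)
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert per_atom[0] == pytest.approx(exact, rel=0.005)
        assert per_res.loc[1] == pytest.approx(exact, rel=0.005)

    def test_two_overlapping_spheres_match_cap_formula(self):
        r, w, d = 1.7, 1.4, 2.0
        R = r + w
        cap = 2 * np.pi * R * (R - d / 2)
        expected = 2 * (4 * np.pi * R ** 2 - cap)
        s = toy_structure(
            [
                (1, "GLY", "CA", "C", (0.0, 0.0, 0.0), r),
                (2, "GLY", "CA", "C", (d, 0.0, 0.0), r),
            ]
        )
        per_atom, _ = sasa(s, probe_radius=w, n_points=4000)
        assert per_atom.sum() == pytest.approx(expected, rel=0.01)

    def test_five_atom_cluster_matches_grid_oracle(self):
        rng = np.random.default_rng(5)
        atoms = [
            (i + 1, "ALA", "CA", "C", tuple(rng.uniform(-2, 2, 3)), 1.7)
            for i in range(5)
        ]
        s = toy_structure(atoms)
        per_atom, _ = sasa(s, probe_radius=1.4, n_points=2000)
        oracle = grid_oracle_sasa(s)
        assert per_atom.sum() == pytest.approx(oracle, rel=0.02)

    def test_doubling_points_changes_area_below_one_percent(self, carbon_sphere):
        a1, _ = sasa(carbon_sphere, n_points=960)
        a2, _ = sasa(carbon_sphere, n_points=1920)
        assert abs(a2.sum() - a1.sum()) / a1.sum() < 0.01

    def test_invalid_probe_rejected(self, carbon_sphere):
        with pytest.raises(ValueError):
            sasa(carbon_sphere, probe_radius=0.0)


class TestInterfaceArea:
    def test_distant_ligand_buries_nothing(self):
        s = toy_structure(
            [(1, "GLY", "CA", "C", (0.0, 0.0, 0.0), 1.7)],
            [("I1", "I", (15.0, 0.0, 0.0), 1.98)],
        )
        buried = interface_area(s, "ligand")
        assert buried.loc[1] == 0.0

    def test_tangent_spheres_match_cap_overlap(self, ligand_contact_structure):
        r, w, d = 1.7, 1.4, 2.0
        R = r + w
        cap = 2 * np.pi * R * (R - d / 2)
        buried = interface_area(ligand_contact_structure, "ligand", n_points=4000)
        assert buried.loc[1] == pytest.approx(cap, rel=0.02)

    def test_membrane_interface_only_inside_slab(self, helix_in_slab):
        buried = interface_area(helix_in_slab, "membrane_slab", n_points=400)
        z = {a.residue_number: a.xyz[2] for a in helix_in_slab.protein_atoms()}
        for res, area in buried.items():
            if -8.0 <= z[res] <= 8.0:
                assert area > 0.0
            elif abs(z[res]) > 12.0:  # clear of the slab plus probe reach
                assert area == 0.0

    def test_bounded_by_free_sasa(self, ligand_contact_structure):
        buried = interface_area(ligand_contact_structure, "ligand")
        _, free = sasa(ligand_contact_structure, include_ligand=False)
        assert (buried <= free + 1e-9).all()
        assert (buried >= 0).all()

    def test_missing_partner_configuration_rejected(self, carbon_sphere):
        with pytest.raises(ValueError, match="ligand"):
            interface_area(carbon_sphere, "ligand")
        with pytest.raises(ValueError, match="slab"):
            interface_area(carbon_sphere, "membrane_slab")


class TestDistancesAndGeometry:
    def test_substrate_distance_single_pair(self):
        s = toy_structure(
            [(1, "ASN", "OD1", "O", (0.0, 0.0, 0.0), 1.52)],
            [("I5", "I", (3.0, 0.0, 0.0), 1.98)],
        )
        assert substrate_distance(s, 1, "mean") == pytest.approx(3.0)
        assert substrate_distance(s, 1, "min") == pytest.approx(3.0)

    def test_ligandless_structure_rejected(self, carbon_sphere):
        with pytest.raises(ValueError, match="ligand"):
            substrate_distance(carbon_sphere, 1)

    def test_unmodelled_residue_lists_range(self, ligand_contact_structure):
        with pytest.raises(KeyError, match="modelled range"):
            substrate_distance(ligand_contact_structure, 99)

    def test_geometry_distance_and_angle(self):
        s = toy_structure(
            [
                (1, "GLY", "A1", "C", (0.0, 0.0, 0.0), 1.7),
                (1, "GLY", "A2", "C", (0.0, 4.0, 0.0), 1.7),
                (1, "GLY", "A3", "C", (0.0, 8.0, 0.0), 1.7),
            ]
        )
        d = geometry_measure(
            s, {"name": "A1"}, {"name": "A2"}
        )
        assert d == pytest.approx(4.0)
        angle = geometry_measure(s, {"name": "A1"}, {"name": "A2"}, {"name": "A3"})
        assert angle == pytest.approx(180.0)

    def test_ambiguous_selector_rejected(self):
        s = toy_structure(
            [
                (1, "GLY", "CA", "C", (0.0, 0.0, 0.0), 1.7),
                (2, "GLY", "CA", "C", (4.0, 0.0, 0.0), 1.7),
            ]
        )
        with pytest.raises(ValueError, match="matched 2"):
            geometry_measure(s, {"name": "CA"}, {"residue_number": 2})

    def test_contact_flag_cutoff(self, ligand_contact_structure):
        assert substrate_contact_flag(ligand_contact_structure, 1) == 1
        assert (
            substrate_contact_flag(ligand_contact_structure, 1, cutoff=1.0) == 0
        )


class TestIngest:
    def test_variant_keyed_join(self, tmp_path):
        p = tmp_path / "ddg.csv"
        p.write_text(
            "variant,ddG_outward\nD498N,2.5\nF298A,1.1\n", encoding="utf-8"
        )
        variants = [VariantSpec(498, "D", "N"), VariantSpec(298, "F", "A"),
                    VariantSpec(10, "A", "V")]
        out = ingest_features(p, {"key": "variant", "columns": ["ddG_outward"]}, variants)
        assert out.loc["D498N", "ddG_outward"] == 2.5
        assert np.isnan(out.loc["A10V", "ddG_outward"])

    def test_position_broadcast_to_substitutions(self, tmp_path):
        p = tmp_path / "flex.csv"
        p.write_text("position,flexibility\n5,0.8\n", encoding="utf-8")
        variants = [VariantSpec(5, "A", m) for m in "VLI"]
        out = ingest_features(p, {"key": "position", "columns": ["flexibility"]}, variants)
        assert (out["flexibility"] == 0.8).all()

    def test_duplicate_key_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("variant,ddG\nD498N,1\nD498N,2\n", encoding="utf-8")
        with pytest.raises(ValueError, match="duplicate"):
            ingest_features(p, {"key": "variant", "columns": ["ddG"]},
                            [VariantSpec(498, "D", "N")])

    def test_unparseable_numeric_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("variant,ddG\nD498N,oops\n", encoding="utf-8")
        with pytest.raises(ValueError, match="row 2"):
            ingest_features(p, {"key": "variant", "columns": ["ddG"]},
                            [VariantSpec(498, "D", "N")])


class TestAssembly:
    def test_canonical_set_sizes(self, default_table):
        table, _, _ = default_table
        from lofcast.io import parse_variant

        variants = [parse_variant(v) for v in table.index]
        nine = assemble_feature_table(variants, table, "pathogenicity9")
        assert nine.columns == list(PATHOGENICITY9)
        twentytwo = assemble_feature_table(variants, table, "severity22")
        assert twentytwo.columns == list(SEVERITY22)
        everything = assemble_feature_table(variants, table, "all")
        assert len(everything.columns) == 134

    def test_missing_provider_named(self, default_table):
        table, _, _ = default_table
        from lofcast.io import parse_variant

        variants = [parse_variant(v) for v in table.index]
        crippled = table.drop(columns=["evolutionary_index"])
        with pytest.raises(AssemblyError, match="evolutionary_index"):
            assemble_feature_table(variants, crippled, "pathogenicity9")

    def test_assembly_idempotent_byte_for_byte(self, default_table):
        table, _, _ = default_table
        from lofcast.io import parse_variant

        variants = [parse_variant(v) for v in table.index]
        a = assemble_feature_table(variants, table, "severity22")
        b = assemble_feature_table(variants, table, "severity22")
        assert a.data.to_csv() == b.data.to_csv()

    def test_duplicate_variant_keys_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0]}, index=["A1V", "A1V"])
        with pytest.raises(ValueError, match="duplicate"):
            FeatureTable(data=df)
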