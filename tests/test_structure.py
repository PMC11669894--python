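import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kellvar.errors import ConfigError, FormatError
from kellvar.structure import (
    ResidueContext,
    assign_domain,
    atom_asa,
    burial_class,
    cluster_epitope_candidates,
    compute_rsa,
    load_max_asa,
    membrane_distance,
    membrane_proximity,
    read_structure,
)


def brute_force_asa(coords, radii, probe, n_points, seed=0):
    """Independent oracle: Monte Carlo surface points at high density."""
    rng = np.random.default_rng(seed)
    expanded = np.asarray(radii) + probe
    out = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = rng.normal(size=(n_points, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts = coords[i] + expanded[i] * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            accessible &= np.linalg.norm(pts - coords[j], axis=1) >= expanded[j]
        out[i] = 4 * math.pi * expanded[i] ** 2 * accessible.mean()
    return out


class TestAtomAsa:
    def test_lone_sphere_closed_form(self):
        r, p = 1.7, 1.4
        asa = atom_asa(np.zeros((1, 3)), np.array([r]), p, 960)
        assert asa[0] == pytest.approx(4 * math.pi * (r + p) ** 2, rel=1e-9)

    def test_symmetric_pair_equal_areas(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        asa = atom_asa(coords, np.array([1.7, 1.7]), 1.4, 960)
        # identical overlapping atoms placed symmetrically: equal per-atom area
        assert asa[0] == pytest.approx(asa[1], rel=0.02)
        assert asa[0] < 4 * math.pi * 3.1**2

    def test_matches_brute_force_oracle(self, rng):
        coords = rng.uniform(0, 8, size=(20, 3))
        radii = rng.uniform(1.5, 1.9, size=20)
        ours = atom_asa(coords, radii, 1.4, 960)
        oracle = brute_force_asa(coords, radii, 1.4, 9600)
        assert ours.sum() == pytest.approx(oracle.sum(), rel=0.02)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.uniform(0, 8, size=(12, 3))
        radii = np.full(12, 1.7)
        base = atom_asa(coords, radii, 1.4, 960)
        theta = 0.7
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = coords @ rot.T + np.array([5.0, -3.0, 11.0])
        assert atom_asa(moved, radii, 1.4, 960) == pytest.approx(base, abs=2.0)

    def test_occluders_never_increase_area(self, rng):
        coords = rng.uniform(0, 6, size=(8, 3))
        radii = np.full(8, 1.7)
        base = atom_asa(coords, radii, 1.4, 960)[0]
        occluded = np.vstack([coords, coords[0] + [2.5, 0, 0]])
        after = atom_asa(occluded, np.full(9, 1.7), 1.4, 960)[0]
        assert after <= base + 1e-9

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            atom_asa(np.zeros((1, 3)), np.array([1.7]), 0.0, 960)
        with pytest.raises(ValueError):
            atom_asa(np.zeros((1, 3)), np.array([1.7]), 1.4, 50)


class TestRsaAndBurial:
    @pytest.mark.parametrize(
        "rsa,expected",
        [
            (0.0, "buried"),
            (0.049, "buried"),
            (0.05, "half_buried"),  # boundary belongs to the upper class
            (0.249, "half_buried"),
            (0.25, "exposed"),
            (1.0, "exposed"),
        ],
    )
    def test_half_open_partition(self, rsa, expected):
        assert burial_class(rsa) == expected

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    @settings(derandomize=True, max_examples=50)
    def test_exactly_one_class(self, rsa):
        assert burial_class(rsa) in ("buried", "half_buried", "exposed")

    def test_rsa_clamped(self):
        table = load_max_asa()
        rsa, burial = compute_rsa(table["A"] * 2, "A", table)
        assert rsa == 1.0 and burial == "exposed"

    def test_unknown_residue(self):
        with pytest.raises(KeyError):
            compute_rsa(10.0, "X")


class TestDomains:
    domains = {"IC": [[1, 47]], "TM": [[48, 67]], "extracellular": [[68, 732]],
               "MPD": [], "MDD": []}

    @pytest.mark.parametrize(
        "position,expected",
        [(20, "IC"), (47, "IC"), (48, "TM"), (55, "TM"), (67, "TM"),
         (68, "extracellular_unassigned"), (700, "extracellular_unassigned")],
    )
    def test_assignment(self, position, expected):
        assert assign_domain(position, self.domains) == expected

    def test_mpd_interval_refines_extracellular(self):
        domains = dict(self.domains, MPD=[[68, 120]], MDD=[[121, 300]])
        assert assign_domain(100, domains) == "MPD"
        assert assign_domain(200, domains) == "MDD"
        assert assign_domain(400, domains) == "extracellular_unassigned"

    def test_overlap_rejected(self):
        domains = dict(self.domains, MPD=[[60, 80]])
        with pytest.raises(ConfigError):
            assign_domain(70, domains)


class TestMembrane:
    plane = {"point": [0, 0, 0], "normal": [0, 0, 2.0]}

    def test_point_on_plane(self):
        assert membrane_proximity([1, 5, 0], self.plane, threshold=1.0)

    def test_point_beyond_threshold(self):
        assert not membrane_proximity([0, 0, 20.0], self.plane, threshold=15.0)

    def test_signed_distance_arithmetic(self):
        # helix axis along z: residue i at z = 1.5 * i
        for i in range(10):
            coord = [3.0, -2.0, 1.5 * i]
            assert membrane_distance(coord, self.plane) == pytest.approx(1.5 * i)

    def test_zero_normal_rejected(self):
        with pytest.raises(ValueError):
            membrane_proximity([0, 0, 0], {"point": [0, 0, 0], "normal": [0, 0, 0]})


def _contexts_from_points(points):
    return {
        i + 1: ResidueContext(
            position=i + 1, aa="A", ca_coord=np.asarray(p, dtype=float),
            asa_abs=50.0, rsa=0.5, burial="exposed", domain="extracellular_unassigned",
        )
        for i, p in enumerate(points)
    }


class TestEpitopeClustering:
    def test_triangle_within_cutoff(self):
        ctx = _contexts_from_points([[0, 0, 0], [5, 0, 0], [0, 5, 0]])
        clusters, _ = cluster_epitope_candidates([1, 2, 3], ctx, 12.0)
        assert len(clusters) == 1
        assert clusters[0].member_positions == {1, 2, 3}

    def test_distant_points_stay_singletons(self):
        ctx = _contexts_from_points([[0, 0, 0], [100, 0, 0]])
        clusters, _ = cluster_epitope_candidates([1, 2], ctx, 12.0)
        assert len(clusters) == 2
        assert all(c.is_singleton for c in clusters)

    def test_matches_brute_force_components(self, rng):
        points = rng.uniform(0, 40, size=(20, 3))
        ctx = _contexts_from_points(points)
        clusters, _ = cluster_epitope_candidates(range(1, 21), ctx, 12.0)

        # oracle: exhaustive pairwise threshold graph + flood fill
        adj = {i: set() for i in range(20)}
        for i in range(20):
            for j in range(i + 1, 20):
                if np.linalg.norm(points[i] - points[j]) <= 12.0:
                    adj[i].add(j)
                    adj[j].add(i)
        seen, components = set(), []
        for i in range(20):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                k = stack.pop()
                if k in comp:
                    continue
                comp.add(k)
                stack.extend(adj[k] - comp)
            seen |= comp
            components.append({k + 1 for k in comp})
        assert sorted(map(sorted, (c.member_positions for c in clusters))) == sorted(
            map(sorted, components)
        )

    def test_cluster_count_monotone_in_cutoff(self, rng):
        points = rng.uniform(0, 30, size=(15, 3))
        ctx = _contexts_from_points(points)
        counts = [
            len(cluster_epitope_candidates(range(1, 16), ctx, d)[0])
            for d in (4.0, 8.0, 12.0, 20.0, 60.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_missing_coordinates_reported(self):
        ctx = _contexts_from_points([[0, 0, 0]])
        clusters, unclusterable = cluster_epitope_candidates([1, 99], ctx, 12.0)
        assert unclusterable == [99]
        assert len(clusters) == 1

    def test_buried_members_flagged_indirect(self):
        ctx = _contexts_from_points([[0, 0, 0], [5, 0, 0]])
        ctx[2].rsa = 0.01
        clusters, _ = cluster_epitope_candidates([1, 2], ctx, 12.0)
        assert clusters[0].indirect_members == {2}


class TestReadStructure:
    def test_synthetic_roundtrip(self, toy_spec, toy_structure_path):
        residues = read_structure(toy_structure_path)
        assert len(residues) == toy_spec.n_residues
        assert residues.aa[61] == "L" and residues.aa[64] == "R"
        assert 61 in residues.ca_coords

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(FormatError):
            read_structure(path)

    def test_duplicate_residue_numbers_rejected(self, tmp_path):
        lines = [
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C",
            "ATOM      2  CA  GLY A   1       4.000   0.000   0.000  1.00  0.00           C",
            "END",
        ]
        path = tmp_path / "dup.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError):
            read_structure(path)
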