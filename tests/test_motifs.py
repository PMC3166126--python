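import itertools
import math

import numpy as np
import pytest

from lenstomo.motifs import (detect_files, detect_polyhedra, estimate_mass,
                             motif_counts)
from lenstomo.network import CutoffPolicy, build_connections
from lenstomo.simulate import SceneParams, build_scene, scene_particle_table
from lenstomo.classify import classify_unlabeled
from tests.conftest import make_particles


class TestMassEstimate:
    @pytest.mark.parametrize("volume,mass_da,kda", [
        (22.0, 16923.0769, 17),      # mean blue particle volume
        (78.0, 60000.0, 60),         # mean yellow particle volume
        (0.0013, 1.0, 0),
        (26.0, 20000.0, 20),
    ])
    def test_protein_density_conversion(self, volume, mass_da, kda):
        est = estimate_mass(volume)
        assert est.mass_da == pytest.approx(mass_da, rel=1e-6)
        assert est.mass_kda_rounded == kda

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            estimate_mass(0.0)


def connected(df, policy=None):
    return build_connections(df, policy or CutoffPolicy.labeled())


class TestFiles:
    def test_five_collinear_points_one_file(self):
        df = make_particles([(7.0 * i, 0, 0) for i in range(5)],
                            classes=["blue"] * 5)
        files = detect_files(df, connected(df))
        assert len(files) == 1
        assert len(files[0].member_ids) == 5
        np.testing.assert_allclose(files[0].edge_lengths, 7.0)

    def test_right_angle_is_not_a_file(self):
        df = make_particles([(0, 0, 0), (7, 0, 0), (7, 7, 0)],
                            classes=["blue"] * 3)
        assert detect_files(df, connected(df), collinearity_tol=1.0) == []

    def test_uneven_spacing_breaks_the_file(self):
        df = make_particles([(0, 0, 0), (7, 0, 0), (16.5, 0, 0)],
                            classes=["blue"] * 3)
        # 7 vs 9.5 spacing: outside the 20% tolerance
        assert detect_files(df, connected(df), spacing_tol=0.2) == []

    def test_jittered_filament_sites_recovered(self):
        params = SceneParams(seed=5, n_filaments=1, box_size=160,
                             filament_length=70, spacing_jitter_sd=0.3,
                             curvature_sd_deg=2.0, gold_label_fraction=0.0,
                             bead_fraction=0.0)
        truth = build_scene(params)
        df = classify_unlabeled(scene_particle_table(truth, params))
        files = detect_files(df, connected(df))
        covered = set().union(*(f.member_ids for f in files)) if files else set()
        assert len(covered) >= 0.9 * truth.n_sites


class TestPolyhedra:
    def test_regular_tetrahedron_detected(self):
        v = 7.0 / math.sqrt(2.0) * np.array(
            [[1, 1, 0], [1, 0, 1], [0, 1, 1], [0, 0, 0]])
        df = make_particles(v + 20.0, classes=["blue"] * 4)
        motifs = detect_polyhedra(df, connected(df))
        kinds = motif_counts(motifs)
        assert kinds["tetrahedron"] == 1

    def test_isosceles_and_equilateral_triangles(self):
        iso = make_particles([(0, 0, 0), (7, 0, 0), (3.5, 8.0, 0)],
                             classes=["blue"] * 3)
        m = detect_polyhedra(iso, connected(iso), edge_tol=0.05)
        assert [x.kind for x in m] == ["isosceles_triangle"]
        assert not m[0].equilateral

        h = 7.0 * math.sqrt(3) / 2
        eq = make_particles([(0, 0, 0), (7, 0, 0), (3.5, h, 0)],
                            classes=["blue"] * 3)
        m = detect_polyhedra(eq, connected(eq), edge_tol=0.05)
        assert m[0].equilateral

    def test_square_detected(self):
        df = make_particles([(0, 0, 0), (7, 0, 0), (7, 7, 0), (0, 7, 0)],
                            classes=["blue"] * 4)
        counts = motif_counts(detect_polyhedra(df, connected(df)))
        assert counts["square"] == 1
        assert counts["tetrahedron"] == 0

    def test_pyramid_square_plus_apex(self):
        base = [(0, 0, 0), (7, 0, 0), (7, 7, 0), (0, 7, 0)]
        apex = (3.5, 3.5, 7.0 / math.sqrt(2.0))
        df = make_particles(base + [apex], classes=["blue"] * 5)
        counts = motif_counts(detect_polyhedra(df, connected(df)))
        assert counts["pyramid"] == 1
        assert counts["square"] == 1

    def test_motif_edges_are_connections(self, rng):
        df = make_particles(rng.uniform(0, 30, (40, 3)), classes=["blue"] * 40)
        conns = connected(df)
        edges = set(zip(conns["a"], conns["b"]))
        for m in detect_polyhedra(df, conns):
            ids = m.member_ids
            if m.kind == "tetrahedron":
                need = itertools.combinations(sorted(ids), 2)
            elif m.kind == "square":
                need = [tuple(sorted(p)) for p in zip(ids, ids[1:] + ids[:1])]
            elif m.kind == "pyramid":
                corners, apex = ids[:4], ids[4]
                need = ([tuple(sorted(p)) for p in zip(corners, corners[1:] + corners[:1])]
                        + [tuple(sorted((apex, c))) for c in corners])
            else:
                need = itertools.combinations(sorted(ids), 2)
            for a, b in need:
                assert (min(a, b), max(a, b)) in edges

    def test_rigid_motion_invariance(self, rng):
        xyz = rng.uniform(0, 30, (35, 3))
        theta = 1.1
        rot = np.array([[np.cos(theta), 0, np.sin(theta)], [0, 1, 0],
                        [-np.sin(theta), 0, np.cos(theta)]])
        df1 = make_particles(xyz, classes=["blue"] * 35)
        df2 = make_particles(xyz @ rot.T + 5.0, classes=["blue"] * 35)
        c1 = motif_counts(detect_polyhedra(df1, connected(df1)))
        c2 = motif_counts(detect_polyhedra(df2, connected(df2)))
        assert c1 == c2

    def test_tightening_tolerance_never_adds_motifs(self, rng):
        df = make_particles(rng.uniform(0, 30, (40, 3)), classes=["blue"] * 40)
        conns = connected(df)
        n = [sum(motif_counts(detect_polyhedra(df, conns, edge_tol=t)).values())
             for t in (0.05, 0.15, 0.3)]
        assert n[0] <= n[1] <= n[2]


def brute_force_counts(df, conns, edge_tol=0.2, planarity_tol=1.5):
    """Independent exhaustive enumeration using the documented predicates."""
    pos = {int(r.id): np.array([r.x_nm, r.y_nm, r.z_nm]) for r in df.itertuples()}
    edges = {(min(r.a, r.b), max(r.a, r.b)): r.distance_nm
             for r in conns.itertuples()}

    def elen(u, v):
        return edges.get((min(u, v), max(u, v)))

    def eq(l1, l2):
        return abs(l1 - l2) <= edge_tol * (l1 + l2) / 2

    def spread_ok(ls):
        m = np.mean(ls)
        return max(abs(l - m) for l in ls) <= edge_tol * m

    ids = sorted(pos)
    tri = tet = sq = pyr = 0
    for t in itertools.combinations(ids, 3):
        ls = [elen(*p) for p in itertools.combinations(t, 2)]
        if None in ls:
            continue
        if any(eq(ls[i], ls[j]) for i, j in ((0, 1), (1, 2), (0, 2))):
            tri += 1
    for q in itertools.combinations(ids, 4):
        ls = [elen(*p) for p in itertools.combinations(q, 2)]
        if None not in ls and spread_ok(ls):
            tet += 1

    def is_square(order):
        a, b, c, d = order
        sides = [elen(a, b), elen(b, c), elen(c, d), elen(d, a)]
        if None in sides or not spread_ok(sides):
            return False
        side = np.mean(sides)
        d1 = np.linalg.norm(pos[a] - pos[c])
        d2 = np.linalg.norm(pos[b] - pos[d])
        if not eq(d1, d2):
            return False
        if abs((d1 + d2) / 2 - math.sqrt(2) * side) > edge_tol * side:
            return False
        n = np.cross(pos[b] - pos[a], pos[c] - pos[a])
        nn = np.linalg.norm(n)
        return not (nn > 1e-12
                    and abs(np.dot(pos[d] - pos[a], n / nn)) > planarity_tol)

    square_sets = []
    for q in itertools.combinations(ids, 4):
        a, b, c, d = q
        orders = [(a, b, c, d), (a, b, d, c), (a, c, b, d)]
        if any(is_square(o) for o in orders):
            sq += 1
            square_sets.append(set(q))
    for corners in square_sets:
        for apex in ids:
            if apex in corners:
                continue
            ls = [elen(apex, c) for c in corners]
            if None not in ls and spread_ok(ls):
                pyr += 1
    return {"isosceles_triangle": tri, "tetrahedron": tet, "square": sq,
            "pyramid": pyr}


class TestBruteForceEquivalence:
    def test_counts_match_exhaustive_enumeration(self, rng):
        df = make_particles(rng.uniform(0, 32, (55, 3)), classes=["blue"] * 55)
        conns = build_connections(df, CutoffPolicy.labeled())
        counts = motif_counts(detect_polyhedra(df, conns))
        brute = brute_force_counts(df, conns)
        for kind in ("isosceles_triangle", "tetrahedron", "square", "pyramid"):
            assert counts[kind] == brute[kind], kind
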