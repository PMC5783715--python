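"""SWC parsing, Sholl profiling, morphometrics, and group comparison."""

import numpy as np
import pytest

from gliamotion.morphometry import (MorphTree, SWCFormatError, compare_groups,
                                    count_processes, read_swc,
                                    sholl_intersections, total_length,
                                    write_swc)


def straight_tree(length=30.0, step=1.0):
    """Soma at origin with one straight radial process along +x."""
    n = int(length / step)
    ids = [1] + [i + 2 for i in range(n)]
    types = [1] + [3] * n
    xyz = [[0.0, 0.0, 0.0]] + [[(i + 1) * step, 0.0, 0.0] for i in range(n)]
    parent = [-1] + [i + 1 for i in range(n)]
    return MorphTree(ids=np.array(ids), types=np.array(types),
                     xyz=np.array(xyz), radius=np.ones(n + 1),
                     parent=np.array(parent))


class TestSwcIO:
    def test_minimal_two_node_file(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("1 1 0 0 0 4 -1\n2 3 10 0 0 1 1\n")
        tree = read_swc(p)
        assert tree.n_nodes == 2
        assert len(tree.edges()) == 1

    def test_comments_and_blank_lines_ignored(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("# header\n\n1 1 0 0 0 4 -1\n  # indented comment\n"
                     "2 3 10 0 0 1 1  # trailing\n\n")
        tree = read_swc(p)
        assert tree.n_nodes == 2

    def test_round_trip_preserves_node_table(self, tmp_path):
        from gliamotion.synthetic import generate_swc_population

        trees, _ = generate_swc_population(1, seed=9)
        p1 = tmp_path / "a.swc"
        p2 = tmp_path / "b.swc"
        write_swc(trees[0], p1)
        back = read_swc(p1)
        write_swc(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_dangling_parent_rejected(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("1 1 0 0 0 4 -1\n2 3 1 0 0 1 99\n")
        with pytest.raises(SWCFormatError):
            read_swc(p)

    def test_two_roots_rejected(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("1 1 0 0 0 4 -1\n2 1 9 0 0 4 -1\n")
        with pytest.raises(SWCFormatError):
            read_swc(p)

    def test_cycle_rejected(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("1 1 0 0 0 4 2\n2 3 1 0 0 1 1\n")
        with pytest.raises(SWCFormatError):
            read_swc(p)

    def test_wrong_column_count_reports_line(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("1 1 0 0 0 4 -1\n2 3 1 0 0 1\n")
        with pytest.raises(SWCFormatError, match=":2"):
            read_swc(p)


class TestSholl:
    def test_straight_process_one_crossing_per_shell(self):
        prof = sholl_intersections(straight_tree(30.0), dr_um=1.0)
        inner = prof.radii_um < 30.0
        np.testing.assert_array_equal(prof.intersections[inner], 1)
        np.testing.assert_array_equal(prof.intersections[~inner], 0)

    def test_bifurcation_doubles_crossings(self):
        # one stem to 5 um, two daughters out to 20 um
        ids, types, xyz, parent = [1], [1], [[0., 0., 0.]], [-1]
        nid = 2
        prev = 1
        for i in range(5):
            ids.append(nid); types.append(3)
            xyz.append([i + 1.0, 0.0, 0.0]); parent.append(prev)
            prev = nid; nid += 1
        fork = prev
        for sign in (1.0, -1.0):
            prev = fork
            for i in range(15):
                ids.append(nid); types.append(3)
                xyz.append([5.0 + (i + 1), sign * (i + 1) * 0.1, 0.0])
                parent.append(prev)
                prev = nid; nid += 1
        tree = MorphTree(ids=np.array(ids), types=np.array(types),
                         xyz=np.array(xyz), radius=np.ones(len(ids)),
                         parent=np.array(parent))
        prof = sholl_intersections(tree, dr_um=1.0)
        for r, c in zip(prof.radii_um, prof.intersections):
            if r < 5.0:
                assert c == 1
            elif 6.0 <= r < 15.0:
                assert c == 2

    def test_matches_dense_resampling_oracle(self):
        """Random generated trees: shell crossings equal sign changes of
        the resampled distance profile along every edge (0.05 um steps)."""
        from gliamotion.synthetic import generate_swc_population

        trees, _ = generate_swc_population(8, seed=13, mean_length_um=18.0)
        for tree in trees:
            prof = sholl_intersections(tree, dr_um=1.0)
            center = tree.soma_centroid()
            counts = np.zeros_like(prof.intersections)
            for ci, pi in tree.edges():
                p0, p1 = tree.xyz[pi], tree.xyz[ci]
                L = np.linalg.norm(p1 - p0)
                if L == 0:
                    continue
                n = max(2, int(np.ceil(L / 0.05)))
                t = np.linspace(0.0, 1.0, n + 1)
                d = np.linalg.norm(p0 + t[:, None] * (p1 - p0) - center,
                                   axis=1)
                for j, r in enumerate(prof.radii_um):
                    s = np.sign(d - r)
                    counts[j] += int(np.sum(s[:-1] * s[1:] < 0))
            np.testing.assert_array_equal(prof.intersections, counts)

    def test_rotation_invariance_about_soma(self):
        from gliamotion.synthetic import generate_swc_population
        from scipy.spatial.transform import Rotation

        trees, _ = generate_swc_population(3, seed=4)
        rot = Rotation.from_euler("xyz", [31.0, -54.0, 112.0],
                                  degrees=True).as_matrix()
        for tree in trees:
            prof = sholl_intersections(tree, dr_um=1.0)
            center = tree.soma_centroid()
            xyz2 = (tree.xyz - center) @ rot.T + center
            tree2 = MorphTree(ids=tree.ids, types=tree.types, xyz=xyz2,
                              radius=tree.radius, parent=tree.parent)
            prof2 = sholl_intersections(tree2, dr_um=1.0)
            np.testing.assert_array_equal(prof.intersections,
                                          prof2.intersections)

    def test_crossings_bound_by_tip_count(self):
        from gliamotion.synthetic import generate_swc_population

        trees, _ = generate_swc_population(5, seed=2)
        for tree in trees:
            prof = sholl_intersections(tree, dr_um=1.0)
            counts = tree.children_counts()
            center = tree.soma_centroid()
            d = np.linalg.norm(tree.xyz - center, axis=1)
            tips_beyond = int(np.sum((counts == 0) & (d > 1.0)))
            assert prof.intersections.sum() >= tips_beyond


class TestMorphometrics:
    def test_soma_only_zero_counts(self):
        tree = MorphTree(ids=[1], types=[1], xyz=[[0., 0., 0.]],
                         radius=[4.0], parent=[-1])
        assert count_processes(tree) == (0, 0)
        assert total_length(tree) == 0.0

    def test_five_unbranched_stems(self):
        ids, types, xyz, parent = [1], [1], [[0., 0., 0.]], [-1]
        nid = 2
        for k in range(5):
            ang = 2 * np.pi * k / 5
            ids.append(nid); types.append(3)
            xyz.append([10 * np.cos(ang), 10 * np.sin(ang), 0.0])
            parent.append(1)
            nid += 1
        tree = MorphTree(ids=np.array(ids), types=np.array(types),
                         xyz=np.array(xyz), radius=np.ones(6),
                         parent=np.array(parent))
        assert count_processes(tree) == (5, 0)
        assert total_length(tree) == pytest.approx(50.0)

    def test_single_straight_process_length(self):
        assert total_length(straight_tree(30.0)) == pytest.approx(30.0)

    def test_length_scales_with_coordinates(self):
        tree = straight_tree(30.0)
        tree2 = MorphTree(ids=tree.ids, types=tree.types, xyz=tree.xyz * 2,
                          radius=tree.radius, parent=tree.parent)
        assert total_length(tree2) == pytest.approx(2 * total_length(tree))

    def test_generated_population_matches_ground_truth(self):
        from gliamotion.synthetic import generate_swc_population

        trees, gt = generate_swc_population(6, seed=31, n_stems=5)
        for i, tree in enumerate(trees):
            stems, bp = count_processes(tree)
            assert stems == gt.n_processes[i] == 5
            assert bp == gt.n_branch_points[i]
            assert total_length(tree) == pytest.approx(
                gt.total_length_um[i], abs=1e-6)


class TestCompareGroups:
    def test_identical_groups_null_group_effect(self):
        from gliamotion.synthetic import generate_swc_population

        trees, gt = generate_swc_population(2, seed=8)
        pair = gt.sholl
        summary, anova = compare_groups({"a": pair, "b": pair})
        assert anova.loc["group", "F"] == pytest.approx(0.0, abs=1e-10)
        assert anova.loc["group", "PR(>F)"] == pytest.approx(1.0, abs=1e-9)

    def test_distinct_generators_detected(self):
        """Populations grown with 8 vs 4 stems give a significant group
        main effect."""
        from gliamotion.synthetic import generate_swc_population

        _, g_hi = generate_swc_population(10, seed=101, n_stems=8)
        _, g_lo = generate_swc_population(10, seed=202, n_stems=4)
        _, anova = compare_groups({"hi": g_hi.sholl, "lo": g_lo.sholl})
        assert anova.loc["group", "PR(>F)"] < 0.05

    def test_anova_matches_textbook_decomposition(self):
        """Small balanced two-way layout against hand-computed sums of
        squares."""
        from gliamotion.morphometry import ShollProfile

        # 2 groups x 2 cells, 3 radii; intersections chosen by hand
        data = {
            "A": [[4, 6, 2], [6, 8, 4]],
            "B": [[8, 10, 6], [10, 12, 8]],
        }
        groups = {
            g: [ShollProfile(radii_um=np.array([1.0, 2.0, 3.0]),
                             intersections=np.array(v), n_processes=0,
                             n_branch_points=0, total_length_um=0.0,
                             label=f"{g}{i}")
                for i, v in enumerate(vals)]
            for g, vals in data.items()
        }
        _, anova = compare_groups(groups)
        y = np.array([v for vals in data.values() for v in vals], float)
        grand = y.mean()
        # balanced design: classical SS
        g_means = y.reshape(2, 2, 3).mean(axis=(1, 2))
        ss_group = 6 * ((g_means - grand) ** 2).sum()
        r_means = y.reshape(2, 2, 3).mean(axis=(0, 1))
        ss_radius = 4 * ((r_means - grand) ** 2).sum()
        cell_means = y.reshape(2, 2, 3).mean(axis=1)
        ss_inter = 2 * ((cell_means - g_means[:, None] - r_means[None, :]
                         + grand) ** 2).sum()
        ss_resid = ((y.reshape(2, 2, 3) - cell_means[:, None, :]) ** 2).sum()
        assert anova.loc["group", "sum_sq"] == pytest.approx(ss_group)
        assert anova.loc["radius", "sum_sq"] == pytest.approx(ss_radius)
        assert anova.loc["group:radius", "sum_sq"] == pytest.approx(ss_inter)
        assert anova.loc["residual", "sum_sq"] == pytest.approx(ss_resid)

    def test_single_group_rejected(self):
        from gliamotion.synthetic import generate_swc_population

        _, gt = generate_swc_population(2, seed=8)
        with pytest.raises(ValueError):
            compare_groups({"only": gt.sholl})
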