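"""Template matching, CAST, merging and hierarchical splitting."""

import numpy as np
import pandas as pd
import pytest

from cremap.clustering import (
    BehaviourTemplate,
    assign_clusters,
    cast_cluster,
    extend_by_template,
    hierarchical_split,
    merge_matching_clusters,
    profile_correlations,
)


def make_profiles(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["c1", "c2", "c3", "c4"])


def vector_at_correlation(template: np.ndarray, r: float) -> list[float]:
    """Construct a 4-vector with exact Pearson correlation r to template."""
    t = np.asarray(template, dtype=float)
    tc = t - t.mean()
    tc /= np.linalg.norm(tc)
    # orthogonal centered direction
    o = np.array([1.0, -1.0, 1.0, -1.0])
    o = o - o.mean()
    o = o - (o @ tc) * tc
    o /= np.linalg.norm(o)
    v = r * tc + np.sqrt(1 - r**2) * o
    return list(v)


class TestTemplateMatching:
    def test_gene_identical_to_template_always_retrieved(self):
        profiles = make_profiles(
            {"s1": [1, 2, 3, 4], "s2": [1.1, 2, 3, 4.2], "g": [1, 2, 3, 4]}
        )
        tpl = BehaviourTemplate.from_seeds("A", ["s1", "s2"], profiles)
        members, r_star = extend_by_template(profiles, tpl)
        assert "g" in members and r_star <= 1.0

    def test_anticorrelated_gene_retrieved_in_absolute_mode_only(self):
        profiles = make_profiles(
            {"s1": [1, 2, 3, 4], "s2": [1, 2, 3, 4], "neg": [4, 3, 2, 1]}
        )
        tpl = BehaviourTemplate.from_seeds("A", ["s1", "s2"], profiles)
        members_abs, _ = extend_by_template(profiles, tpl, mode="absolute")
        members_signed, _ = extend_by_template(profiles, tpl, mode="signed")
        assert "neg" in members_abs
        assert "neg" not in members_signed

    def test_threshold_fixed_at_minimum_seed_correlation(self):
        template = np.array([3.0, 0.0, -3.0, 0.0])
        profiles = make_profiles(
            {
                "s1": list(template),
                "s2": vector_at_correlation(template, 0.9),
                "in": vector_at_correlation(template, 0.95),
                "out": vector_at_correlation(template, 0.85),
            }
        )
        tpl = BehaviourTemplate.from_seeds("A", ["s1", "s2"], profiles)
        members, r_star = extend_by_template(profiles, tpl)
        assert r_star == pytest.approx(
            profile_correlations(profiles, tpl.template_profile).loc["s2"]
        )
        assert "in" in members
        assert "out" not in members

    def test_constant_profile_skipped_with_warning(self, caplog):
        profiles = make_profiles(
            {"s1": [1, 2, 3, 4], "s2": [1, 2, 3, 4], "flat": [2, 2, 2, 2]}
        )
        tpl = BehaviourTemplate.from_seeds("A", ["s1", "s2"], profiles)
        with caplog.at_level("WARNING"):
            members, _ = extend_by_template(profiles, tpl)
        assert "flat" not in members
        assert "undefined correlation" in caplog.text


class TestCAST:
    def test_two_anticorrelated_blocks_recovered(self):
        rng = np.random.default_rng(1)
        base = np.array([2.0, 1.0, -1.0, -2.0])
        rows = {}
        for i in range(5):
            rows[f"a{i}"] = list(base + rng.normal(0, 0.05, 4))
            rows[f"b{i}"] = list(-base + rng.normal(0, 0.05, 4))
        clusters = cast_cluster(make_profiles(rows))
        assert sorted(len(c) for c in clusters) == [5, 5]
        for c in clusters:
            assert len({g[0] for g in c}) == 1  # pure 'a' or pure 'b'

    def test_single_gene_is_singleton(self):
        clusters = cast_cluster(make_profiles({"g1": [1, 2, 3, 4]}))
        assert clusters == [["g1"]]

    def test_identical_genes_form_one_cluster(self):
        rows = {f"g{i}": [1.0, 2.0, 3.0, 4.0] for i in range(6)}
        clusters = cast_cluster(make_profiles(rows))
        assert len(clusters) == 1 and len(clusters[0]) == 6

    def test_input_order_invariance(self):
        rng = np.random.default_rng(2)
        rows = {f"g{i:02d}": list(rng.normal(size=4)) for i in range(20)}
        profiles = make_profiles(rows)
        shuffled = profiles.sample(frac=1.0, random_state=3)
        assert cast_cluster(profiles) == cast_cluster(shuffled)


class TestMerging:
    def _templates(self):
        profiles = make_profiles(
            {"s1": [3, 0, -3, 0], "s2": [2.9, 0.1, -3.1, 0]}
        )
        tpl = BehaviourTemplate.from_seeds("A", ["s1", "s2"], profiles)
        _, r_star = extend_by_template(profiles, tpl)
        return {"A": (tpl, r_star)}, profiles

    def test_cluster_mean_equal_to_template_merges(self):
        templates, seed_profiles = self._templates()
        tpl = templates["A"][0]
        profiles = pd.concat(
            [seed_profiles, make_profiles({"n1": list(tpl.template_profile),
                                           "n2": list(tpl.template_profile)})]
        )
        merged, novel = merge_matching_clusters([["n1", "n2"]], templates, profiles)
        assert merged["A"] == ["n1", "n2"] and novel == []

    def test_orthogonal_cluster_kept_novel(self):
        templates, seed_profiles = self._templates()
        profiles = pd.concat(
            [seed_profiles, make_profiles({"n1": [0, 3, 0, -3], "n2": [0, 3, 0, -3]})]
        )
        merged, novel = merge_matching_clusters([["n1", "n2"]], templates, profiles)
        assert merged["A"] == [] and novel == [["n1", "n2"]]

    def test_merge_is_decided_by_r_star(self):
        templates, seed_profiles = self._templates()
        tpl, r_star = templates["A"]
        above = vector_at_correlation(tpl.template_profile, min(1.0, r_star + 0.005))
        below = vector_at_correlation(tpl.template_profile, r_star - 0.01)
        profiles = pd.concat(
            [seed_profiles, make_profiles({"hi": above, "lo": below})]
        )
        merged_hi, _ = merge_matching_clusters([["hi"]], templates, profiles)
        _, novel_lo = merge_matching_clusters([["lo"]], templates, profiles)
        assert merged_hi["A"] == ["hi"]
        assert novel_lo == [["lo"]]


class TestHierarchicalSplit:
    def test_two_genes_split_apart(self):
        a, b = hierarchical_split(make_profiles({"g1": [0, 0, 0, 0], "g2": [5, 5, 5, 5]}))
        assert a == ["g1"] and b == ["g2"]

    def test_two_value_groups_split_exactly(self):
        rows = {f"lo{i}": [0, 0, 0, 0] for i in range(3)}
        rows.update({f"hi{i}": [5, 5, 5, 5] for i in range(3)})
        a, b = hierarchical_split(make_profiles(rows))
        groups = {frozenset(a), frozenset(b)}
        assert groups == {
            frozenset(["lo0", "lo1", "lo2"]),
            frozenset(["hi0", "hi1", "hi2"]),
        }

    def test_singleton_returned_unsplit_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            a, b = hierarchical_split(make_profiles({"g1": [1, 2, 3, 4]}))
        assert a == ["g1"] and b == []
        assert "unsplit" in caplog.text


class TestCascade:
    def _profiles_and_seeds(self):
        rng = np.random.default_rng(5)
        centroids = {
            "A": np.array([3, 3, 0, 0], float),
            "B": np.array([-3, -3, 0, 0], float),
            "E": np.array([0, 0, 3, 0], float),
        }
        rows, truth = {}, {}
        for label, mu in centroids.items():
            for i in range(8):
                g = f"{label.lower()}{i}"
                rows[g] = list(mu + rng.normal(0, 0.2, 4))
                truth[g] = label
        for i in range(4):  # heterogeneous leftovers
            g = f"x{i}"
            rows[g] = list(np.array([3, -3, 3, -3]) + rng.normal(0, 0.2, 4))
            truth[g] = "X"
        seeds = {lab: [f"{lab.lower()}{i}" for i in range(4)] for lab in centroids}
        return make_profiles(rows), seeds, truth

    def test_labels_partition_input(self):
        profiles, seeds, _ = self._profiles_and_seeds()
        out = assign_clusters(profiles, seeds)
        assert set(out.index) == set(profiles.index)
        assert out["label"].notna().all()

    def test_anticorrelated_pair_not_conflated(self):
        """A and B seeds are mutually anticorrelated; absolute-R
        retrieval pulls both in, but signed-argmax assignment keeps
        them apart."""
        profiles, seeds, truth = self._profiles_and_seeds()
        out = assign_clusters(profiles, seeds)
        for g, lab in truth.items():
            if lab in ("A", "B"):
                assert out.loc[g, "label"] == lab

    def test_gene_order_invariance(self):
        profiles, seeds, _ = self._profiles_and_seeds()
        out1 = assign_clusters(profiles, seeds)
        out2 = assign_clusters(profiles.sample(frac=1.0, random_state=7), seeds)
        assert out1["label"].sort_index().equals(out2["label"].sort_index())

    def test_leftovers_become_x(self):
        profiles, seeds, truth = self._profiles_and_seeds()
        out = assign_clusters(profiles, seeds)
        x_genes = [g for g, lab in truth.items() if lab == "X"]
        assert (out.loc[x_genes, "label"] == "X").all()

    def test_subclusters_cover_each_label(self):
        profiles, seeds, _ = self._profiles_and_seeds()
        out = assign_clusters(profiles, seeds, split=True)
        for lab, grp in out.groupby("label"):
            if len(grp) >= 2:
                assert set(grp["subcluster"]) <= {1, 2}
                assert 1 in set(grp["subcluster"])
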