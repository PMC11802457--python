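"""Age profiles, fuzzy c-means, monotone trends, NAS/CAS assembly."""
import numpy as np
import pandas as pd
import pytest

from nichetrack import signatures
from nichetrack.datatypes import ParameterError
from nichetrack.signatures import AgeProfileMatrix, TrendSets
from nichetrack.trajectory import ModuleAssignment
from conftest import block_genes, make_matrix


def profiles_from_array(z, genes=None):
    genes = genes or [f"g{i}" for i in range(len(z))]
    return AgeProfileMatrix(
        z=pd.DataFrame(z, index=pd.Index(genes, name="gene"), columns=["young", "middle", "old"]),
        excluded=[],
        population="toy",
    )


class TestAgeProfiles:
    def make_aged_matrix(self, rng, means_by_gene):
        """3 cells per age with per-age Poisson means planted per gene."""
        cols = []
        ages = []
        for ai, age in enumerate(("young", "middle", "old")):
            for _ in range(40):
                cols.append([rng.poisson(mu[ai]) for mu in means_by_gene])
                ages.append(age)
        counts = np.array(cols).T
        meta = pd.DataFrame(
            {"cell_type": "x", "age": ages},
            index=[f"c{i}" for i in range(counts.shape[1])],
        )
        return make_matrix(counts, cell_ids=list(meta.index), meta=meta)

    def test_linear_means_standardize_to_symmetric_profile(self):
        m = make_matrix(np.zeros((1, 3), dtype=int), lognorm=False)
        m.lognorm = np.array([[1.0, 2.0, 3.0]])
        m.cell_meta["age"] = ["young", "middle", "old"]
        prof = signatures.age_profiles(m, flat_alpha=None)
        np.testing.assert_allclose(
            prof.z.iloc[0].to_numpy(), [-1.22474487, 0.0, 1.22474487], rtol=1e-8
        )

    def test_constant_gene_excluded_and_flagged(self):
        m = make_matrix(np.zeros((2, 3), dtype=int), lognorm=False)
        m.lognorm = np.array([[1.0, 2.0, 3.0], [2.0, 2.0, 2.0]])
        m.cell_meta["age"] = ["young", "middle", "old"]
        prof = signatures.age_profiles(m, flat_alpha=None)
        assert prof.excluded == ["g1"]
        assert list(prof.z.index) == ["g0"]

    def test_rows_centered(self, rng):
        m = self.make_aged_matrix(rng, [(5, 9, 14), (14, 9, 5), (8, 8, 8)])
        prof = signatures.age_profiles(m)
        np.testing.assert_allclose(prof.z.mean(axis=1).to_numpy(), 0.0, atol=1e-10)

    def test_flatness_filter_drops_stable_genes(self, rng):
        # one rising gene among a stable background: the background genes are
        # indistinguishable from flat and should drop out of the profiles
        means = [(5, 9, 14)] + [(8, 8, 8)] * 20
        m = self.make_aged_matrix(rng, means)
        prof = signatures.age_profiles(m, flat_alpha=0.05)
        assert "g0" in prof.z.index
        flat = [f"g{i}" for i in range(1, 21)]
        assert np.mean([g in prof.excluded for g in flat]) >= 0.8

    def test_missing_age_group_named(self):
        m = make_matrix(np.ones((1, 2), dtype=int))
        m.cell_meta["age"] = ["young", "old"]
        with pytest.raises(ParameterError, match="middle"):
            signatures.age_profiles(m)


class TestFuzzyCmeans:
    def test_identical_profiles_share_membership_equally(self):
        prof = profiles_from_array(np.tile([-1.0, 0.0, 1.0], (10, 1)))
        out = signatures.fuzzy_cmeans(prof, c=4, seed=0)
        np.testing.assert_allclose(out.membership.to_numpy(), 0.25, atol=1e-9)

    def test_planted_groups_recovered_with_high_membership(self, rng):
        z = np.array([1.0, 0.0, -1.0]) * 1.2247
        profs = np.vstack(
            [z + rng.normal(scale=0.05, size=3) for _ in range(20)]
            + [-z + rng.normal(scale=0.05, size=3) for _ in range(20)]
        )
        # re-standardize rows as AgeProfileMatrix guarantees
        profs = (profs - profs.mean(1, keepdims=True)) / profs.std(1, keepdims=True)
        out = signatures.fuzzy_cmeans(profiles_from_array(profs), c=2, m_fuzzifier=1.25, seed=1)
        u = out.membership.to_numpy()
        assert (u.max(axis=1) > 0.9).all()
        lead = u.argmax(axis=1)
        assert len(set(lead[:20])) == 1 and len(set(lead[20:])) == 1
        assert lead[0] != lead[-1]

    def test_objective_trace_non_increasing(self, rng):
        profs = rng.normal(size=(50, 3))
        profs = (profs - profs.mean(1, keepdims=True)) / profs.std(1, keepdims=True)
        out = signatures.fuzzy_cmeans(profiles_from_array(profs), c=8, seed=2)
        assert all(np.diff(out.objective_trace) <= 1e-9)

    def test_memberships_sum_to_one(self, rng):
        profs = rng.normal(size=(30, 3))
        out = signatures.fuzzy_cmeans(profiles_from_array(profs), c=5, seed=3)
        np.testing.assert_allclose(out.membership.sum(axis=1).to_numpy(), 1.0, atol=1e-8)

    def test_near_hard_fuzzifier_matches_kmeans(self, rng):
        from sklearn.cluster import KMeans

        z = np.array([1.0, 0.0, -1.0])
        profs = np.vstack(
            [z + rng.normal(scale=0.05, size=3) for _ in range(15)]
            + [-z + rng.normal(scale=0.05, size=3) for _ in range(15)]
        )
        out = signatures.fuzzy_cmeans(profiles_from_array(profs), c=2, m_fuzzifier=1.01, seed=0)
        hard = out.membership.to_numpy().argmax(axis=1)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(profs)
        agreement = max((hard == km).mean(), (hard != km).mean())
        assert agreement == 1.0

    def test_too_few_clusters_rejected(self):
        prof = profiles_from_array(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(ParameterError):
            signatures.fuzzy_cmeans(prof, c=1)


class TestMonotoneTrends:
    def run_with_centers(self, centers):
        c = len(centers)
        clust = signatures.FuzzyClustering(
            centers=pd.DataFrame(centers, columns=["young", "middle", "old"]),
            membership=pd.DataFrame(
                np.eye(c), index=[f"g{i}" for i in range(c)],
                columns=[f"cluster_{j}" for j in range(c)],
            ),
            fuzzifier=1.25,
            objective_trace=[0.0],
        )
        return signatures.monotone_trend_sets(clust)

    def test_strictly_increasing_center_is_up(self):
        out = self.run_with_centers([[-1.1, 0.0, 1.1], [0.0, 1.0, -1.0]])
        assert out.cluster_direction["cluster_0"] == "up"
        assert out.up_genes == ["g0"]

    def test_non_monotone_center_is_neither(self):
        out = self.run_with_centers([[-1.0, 1.0, 0.0]])
        assert out.cluster_direction["cluster_0"] == "neither"
        assert out.up_genes == [] and out.down_genes == []

    def test_membership_threshold_gates_assignment(self):
        clust = signatures.FuzzyClustering(
            centers=pd.DataFrame([[-1.0, 0.0, 1.0], [1.0, 0.0, -1.0]],
                                 columns=["young", "middle", "old"]),
            membership=pd.DataFrame(
                [[0.9, 0.1], [0.45, 0.55]], index=["gA", "gB"],
                columns=["cluster_0", "cluster_1"],
            ),
            fuzzifier=1.25,
            objective_trace=[0.0],
        )
        out = signatures.monotone_trend_sets(clust, membership_threshold=0.6)
        assert out.up_genes == ["gA"] and out.down_genes == []

    def test_planted_recovery_on_lineage_atlas(self, lineage_atlas):
        m, truth = lineage_atlas
        prof = signatures.age_profiles(m)
        clust = signatures.fuzzy_cmeans(prof, c=8, m_fuzzifier=1.25, seed=0)
        out = signatures.monotone_trend_sets(clust, 0.5)
        up_true = set(block_genes(truth, "aging_up"))
        dn_true = set(block_genes(truth, "aging_down"))
        null = set(block_genes(truth, "null"))
        up, dn = set(out.up_genes), set(out.down_genes)
        assert len(up & up_true) / len(up_true) >= 0.9
        assert len(dn & dn_true) / len(dn_true) >= 0.9
        assert len((up | dn) & null) / len(null) <= 0.05


def trend(up=(), down=()):
    return TrendSets(
        up_genes=list(up), down_genes=list(down),
        max_membership=pd.Series(dtype=float), cluster_direction={},
    )


def modules_from(mapping):
    s = pd.Series(mapping)
    return ModuleAssignment(
        module=s, profiles=pd.DataFrame(index=s.index),
        peak_position=pd.Series(0.0, index=s.index), unassigned=[],
    )


class TestBuildNas:
    def test_intersection_rule(self):
        mods = modules_from({"A": 1, "B": 1, "C": 3, "D": 4})
        out = signatures.build_nas(trend(up=["A", "X"], down=["C", "D", "Y"]), mods)
        assert out.up == ["A"] and out.down == ["C", "D"]
        assert "realtime_up" in out.provenance["A"]

    def test_disjoint_inputs_give_empty_signature(self, caplog):
        mods = modules_from({"A": 2})
        out = signatures.build_nas(trend(up=["Z"], down=["Q"]), mods)
        assert out.up == [] and out.down == []

    def test_order_independent_exhaustive(self, rng):
        genes = [f"g{i}" for i in range(30)]
        mapping = {g: int(k) for g, k in zip(genes, rng.integers(1, 5, 30))}
        up = list(rng.choice(genes, 10, replace=False))
        down = [g for g in genes if g not in up][:10]
        mods = modules_from(mapping)
        out = signatures.build_nas(trend(up=up, down=down), mods)
        assert set(out.up) == {g for g in up if mapping[g] == 1}
        assert set(out.down) == {g for g in down if mapping[g] in (3, 4)}


class TestBuildCas:
    def test_shared_by_two_populations_included(self):
        pops = {
            "astro": trend(up=["A", "B"]),
            "qNSC": trend(up=["A"]),
            "gc": trend(up=["C"]),
            "endo": trend(up=["B"]),
        }
        out = signatures.build_cas(pops, trend(up=["A", "B", "C"]), min_shared=2)
        assert out.up == ["A", "B"]
        assert set(out.provenance["A"][1:]) == {"astro", "qNSC"}

    def test_single_population_excluded(self):
        pops = {"astro": trend(up=["A"]), "qNSC": trend(up=[])}
        out = signatures.build_cas(pops, trend(up=["A"]), min_shared=2)
        assert out.up == []

    def test_matches_exhaustive_oracle(self, rng):
        genes = [f"g{i}" for i in range(10)]
        pops = {}
        for p in range(4):
            ups = [g for g in genes if rng.random() < 0.4]
            downs = [g for g in genes if g not in ups and rng.random() < 0.4]
            pops[f"pop{p}"] = trend(up=ups, down=downs)
        st = trend(up=genes[:6], down=genes[6:])
        out = signatures.build_cas(pops, st, min_shared=2)
        for g in genes:
            n_up = sum(g in t.up_genes for t in pops.values())
            n_dn = sum(g in t.down_genes for t in pops.values())
            assert (g in out.up) == (g in st.up_genes and n_up >= 2)
            assert (g in out.down) == (g in st.down_genes and n_dn >= 2)

    def test_monotone_in_min_shared(self):
        pops = {
            "a": trend(up=["A", "B"]), "b": trend(up=["A"]),
            "c": trend(up=["A", "B"]), "d": trend(up=[]),
        }
        st = trend(up=["A", "B"])
        sizes = [
            len(signatures.build_cas(pops, st, min_shared=k).up) for k in (1, 2, 3, 4)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_min_shared_exceeding_populations_rejected(self):
        with pytest.raises(ParameterError, match="min_shared"):
            signatures.build_cas({"a": trend()}, trend(), min_shared=2)
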