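import numpy as np
import pandas as pd
import pytest

from domstat import (PeakTable, build_dendrogram, dendro_diversity,
                     dissimilarity, functional_structure, pcoa,
                     taxonomic_diversity)
from domstat.diversity import mpd_mntd, raoq_bruteforce
from domstat.transformations import TransformationDatabase, build_transformation_network


def _pt(data, samples=None):
    df = pd.DataFrame(data)
    if samples:
        df.columns = samples
    return PeakTable(df)


class TestTaxonomic:
    def test_uniform_closed_forms(self):
        pt = _pt({"s": [1.0, 1.0, 1.0, 1.0]})
        row = taxonomic_diversity(pt).iloc[0]
        assert row["richness"] == 4
        assert row["shannon"] == pytest.approx(np.log(4))
        assert row["gini_simpson"] == pytest.approx(0.75)
        assert row["pielou"] == pytest.approx(1.0)

    def test_single_molecule(self):
        row = taxonomic_diversity(_pt({"s": [3.0, 0.0]})).iloc[0]
        assert row["richness"] == 1
        assert row["shannon"] == 0.0
        assert row["gini_simpson"] == 0.0
        assert np.isnan(row["pielou"])

    def test_skewed_example(self):
        row = taxonomic_diversity(_pt({"s": [0.5, 0.25, 0.25]})).iloc[0]
        assert row["shannon"] == pytest.approx(1.0397, abs=1e-4)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            taxonomic_diversity(_pt({"s": [0.0, 0.0]}))

    def test_shannon_bounded_by_log_richness(self, study):
        table = taxonomic_diversity(study["peaks"])
        assert (table["shannon"] <= np.log(table["richness"]) + 1e-12).all()
        assert table["gini_simpson"].between(0, 1).all()


class TestFunctional:
    def test_cwm_and_raoq_two_molecules(self):
        pt = _pt({"s": [1.0, 1.0]})
        traits = pd.DataFrame({"t": [0.0, 1.0]}, index=pt.molecules)
        cwm = functional_structure(pt, traits, ["t"], metric="CWM")
        assert cwm.iloc[0, 0] == pytest.approx(0.5)
        raoq = functional_structure(pt, traits, ["t"], metric="RaoQ")
        # full double sum: 2 * (0.5 * 0.5 * 1) = 0.5
        assert raoq.iloc[0, 0] == pytest.approx(0.5)

    def test_identical_traits_zero_raoq(self):
        pt = _pt({"s": [1.0, 2.0, 3.0]})
        traits = pd.DataFrame({"t": [2.0, 2.0, 2.0]}, index=pt.molecules)
        assert functional_structure(pt, traits, ["t"], metric="RaoQ").iloc[0, 0] \
            == pytest.approx(0.0)

    def test_dominant_molecule_drives_cwm(self):
        pt = _pt({"s": [1e9, 1.0]})
        traits = pd.DataFrame({"t": [7.0, -3.0]}, index=pt.molecules)
        assert functional_structure(pt, traits, ["t"], metric="CWM").iloc[0, 0] \
            == pytest.approx(7.0, abs=1e-6)

    def test_raoq_matches_bruteforce(self, study, trait_table):
        pt = PeakTable(study["peaks"].intensities.iloc[:200])
        traits = trait_table.loc[pt.molecules, ["nosc"]]
        fast = functional_structure(pt, traits, ["nosc"], metric="RaoQ")
        sample = pt.samples[0]
        p = pt.relative_abundance()[sample].to_numpy()
        t = traits["nosc"].to_numpy()
        d = np.abs(t[:, None] - t[None, :])
        assert fast.loc[sample, "raoq"] == pytest.approx(raoq_bruteforce(p, d))

    def test_missing_traits_excluded_with_warning(self):
        pt = _pt({"s": [1.0, 1.0]})
        traits = pd.DataFrame({"t": [1.0, np.nan]}, index=pt.molecules)
        with pytest.warns(UserWarning, match="missing"):
            cwm = functional_structure(pt, traits, ["t"], metric="CWM")
        assert cwm.iloc[0, 0] == pytest.approx(1.0)


class TestDendrogram:
    def test_two_molecules(self):
        traits = pd.DataFrame({"t": [0.0, 1.0]}, index=["a", "b"])
        d = build_dendrogram(trait_table=traits, kind="MCD")
        D = d.cophenetic_matrix()
        assert D.loc["a", "b"] > 0
        assert D.loc["a", "a"] == 0

    def test_three_molecule_topology(self):
        # d(a,b) << d(a,c) = d(b,c) forces ((a,b),c)
        traits = pd.DataFrame({"t": [0.0, 0.1, 10.0]}, index=["a", "b", "c"])
        d = build_dendrogram(trait_table=traits, kind="MCD")
        D = d.cophenetic_matrix()
        assert D.loc["a", "b"] < D.loc["a", "c"]
        assert D.loc["a", "c"] == pytest.approx(D.loc["b", "c"])

    def test_td_from_path_network(self):
        db = TransformationDatabase.from_mapping({"CH2": 14.01565})
        masses = pd.Series({"a": 200.0, "b": 214.01565, "c": 228.0313})
        net = build_transformation_network(masses, db, 1e-3)  # path a-b-c
        d = build_dendrogram(transformation_network=net, kind="TD")
        D = d.cophenetic_matrix()
        assert D.loc["a", "b"] < D.loc["a", "c"]

    def test_twcd_needs_both_inputs(self, trait_table):
        with pytest.raises(ValueError, match="requires"):
            build_dendrogram(trait_table=trait_table, kind="TWCD")
        with pytest.raises(ValueError, match="requires"):
            build_dendrogram(kind="MCD")

    def test_degenerate_traits_rejected(self):
        traits = pd.DataFrame({"t": [1.0, 1.0, 1.0]}, index=list("abc"))
        with pytest.raises(ValueError, match="identical"):
            build_dendrogram(trait_table=traits, kind="MCD")

    def test_newick_roundtrip(self, mcd, tmp_path):
        path = tmp_path / "tree.nwk"
        mcd.write_newick(path)
        from skbio import TreeNode
        tree = TreeNode.read(str(path))
        assert {t.name for t in tree.tips()} == set(mcd.ids)


class TestDendroDiversity:
    def test_full_tip_set_gives_total_length(self, mcd):
        ones = pd.DataFrame(
            np.ones((mcd.n_tips, 1)), index=mcd.ids, columns=["s"])
        dd = dendro_diversity(mcd, PeakTable(ones)).loc["s", "dd"]
        assert dd == pytest.approx(mcd.total_length(), rel=1e-9)

    def test_two_molecule_sample(self, mcd):
        a, b = mcd.ids[0], mcd.ids[17]
        col = pd.DataFrame({"s": [1.0, 1.0]}, index=[a, b])
        row = dendro_diversity(mcd, PeakTable(col)).loc["s"]
        expected = mcd.cophenetic_matrix().loc[a, b]
        assert row["mpd"] == pytest.approx(expected)
        assert row["mntd"] == pytest.approx(expected)

    def test_three_tip_bruteforce(self, mcd):
        ids = [mcd.ids[i] for i in (0, 5, 40)]
        col = pd.DataFrame({"s": [1.0, 1.0, 1.0]}, index=ids)
        row = dendro_diversity(mcd, PeakTable(col)).loc["s"]
        D = mcd.cophenetic_matrix().loc[ids, ids].to_numpy()
        pairs = [D[0, 1], D[0, 2], D[1, 2]]
        assert row["mpd"] == pytest.approx(np.mean(pairs))
        nearest = [min(D[0, 1], D[0, 2]), min(D[0, 1], D[1, 2]), min(D[0, 2], D[1, 2])]
        assert row["mntd"] == pytest.approx(np.mean(nearest))

    def test_mntd_not_above_mpd(self, study, mcd):
        table = dendro_diversity(mcd, study["peaks"]).dropna()
        assert (table["mntd"] <= table["mpd"] + 1e-12).all()


class TestDissimilarity:
    def test_identical_samples_zero(self):
        pt = _pt({"s1": [1.0, 2.0], "s2": [1.0, 2.0]})
        for metric in ("jaccard", "bray_curtis"):
            assert dissimilarity(pt, metric).loc["s1", "s2"] == pytest.approx(0.0)

    def test_disjoint_samples_one(self):
        pt = PeakTable(pd.DataFrame({"s1": [1.0, 0.0], "s2": [0.0, 1.0]},
                                    index=["a", "b"]))
        assert dissimilarity(pt, "jaccard").loc["s1", "s2"] == pytest.approx(1.0)
        assert dissimilarity(pt, "bray_curtis").loc["s1", "s2"] == pytest.approx(1.0)
        two_tip = build_dendrogram(
            trait_table=pd.DataFrame({"t": [0.0, 1.0]}, index=["a", "b"]),
            kind="MCD")
        uw = dissimilarity(pt, "unifrac_unweighted", dendrogram=two_tip)
        assert uw.loc["s1", "s2"] == pytest.approx(1.0)

    def test_bray_curtis_hand_example(self):
        pt = _pt({"s1": [2.0, 1.0, 1.0], "s2": [1.0, 1.0, 2.0]})
        # relative abundances (.5,.25,.25) vs (.25,.25,.5): sum|x-y| / sum(x+y)
        expected = (0.25 + 0.0 + 0.25) / 2.0
        assert dissimilarity(pt, "bray_curtis").loc["s1", "s2"] == pytest.approx(expected)

    def test_metric_axioms(self, study, mcd):
        pt = study["peaks"]
        for metric in ("jaccard", "bray_curtis", "unifrac_unweighted",
                       "unifrac_weighted"):
            dm = dissimilarity(pt, metric, dendrogram=mcd)
            v = dm.to_numpy()
            assert np.allclose(np.diag(v), 0)
            assert np.allclose(v, v.T)
            assert (v >= -1e-12).all() and (v <= 1 + 1e-9).all()

    def test_tree_required_for_unifrac(self, study):
        with pytest.raises(ValueError, match="dendrogram"):
            dissimilarity(study["peaks"], "unifrac_unweighted")


class TestPcoa:
    def test_three_equidistant_samples(self):
        dm = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        coords, eigvals = pcoa(dm)
        pos = np.sort(eigvals[eigvals > 1e-12].to_numpy())
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_duplicate_samples_coincide(self):
        d = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        coords, _ = pcoa(pd.DataFrame(d, index=list("abc"), columns=list("abc")))
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-9)

    def test_euclidean_roundtrip(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 3))
        from scipy.spatial.distance import pdist, squareform
        dm = pd.DataFrame(squareform(pdist(X)),
                          index=[f"s{i}" for i in range(6)],
                          columns=[f"s{i}" for i in range(6)])
        coords, _ = pcoa(dm)
        back = squareform(pdist(coords.to_numpy()))
        assert np.allclose(back, dm.to_numpy(), atol=1e-9)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            pcoa(pd.DataFrame(np.zeros((2, 3))))
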