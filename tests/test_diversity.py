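"""Alpha-diversity metrics against independent brute-force oracles.

The exhaustive suite checks Faith PD, MPD, FRic, FDis, Shannon and CWM on
every one of the 2^6 species subsets of a fixed six-species fixture, each
against an implementation built along a different route (path enumeration
on the tree, pairwise loops, an independent geometry library for hulls).
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import MultiPoint

from spoilveg.diversity import (
    NullModelConfig,
    cwm,
    diversity_profile,
    faith_pd,
    fdis,
    fric,
    functional_space,
    gower_distance,
    mpd,
    richness_shannon,
    ses_null,
)
from spoilveg.traits import patristic_distances


# ------------------------------------------------------------------ oracles #

def pd_oracle(species, tree):
    """Union of root-ward paths from each tip to the subset's MRCA."""
    if not species:
        return 0.0
    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    if len(species) == 1:
        return 0.0
    mrca = tree.mrca(taxon_labels=list(species))
    edges = set()
    for s in species:
        node = tips[s]
        while node is not mrca:
            edges.add(node)
            node = node.parent_node
    return sum(n.edge.length or 0.0 for n in edges)


def mpd_oracle(species, tree):
    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}

    def depth(n):
        d = 0.0
        while n.parent_node is not None:
            d += n.edge.length or 0.0
            n = n.parent_node
        return d

    vals = []
    for a, b in itertools.combinations(sorted(species), 2):
        mrca = tree.mrca(taxon_labels=[a, b])
        vals.append(depth(tips[a]) + depth(tips[b]) - 2 * depth(mrca))
    return float(np.mean(vals)) if vals else float("nan")


def shannon_oracle(abunds):
    present = [a for a in abunds if a > 0]
    total = sum(present)
    return -sum((a / total) * np.log(a / total) for a in present) if present else 0.0


def fdis_oracle(abunds, pts):
    w = np.asarray(abunds, dtype=float)
    centroid = np.zeros(pts.shape[1])
    for j in range(pts.shape[1]):
        centroid[j] = sum(w[i] * pts[i, j] for i in range(len(w))) / w.sum()
    total = 0.0
    for i in range(len(w)):
        total += w[i] * np.sqrt(((pts[i] - centroid) ** 2).sum())
    return total / w.sum()


def cwm_oracle(abunds, traits):
    num = den = 0.0
    for a, t in zip(abunds, traits):
        if a > 0 and not np.isnan(t):
            num += a * t
            den += a
    return num / den if den > 0 else float("nan")


# -------------------------------------------------------------------- tests #

class TestExhaustiveSixSpeciesSuite:
    def test_all_subsets_match_oracles(self, six_tree, six_traits, six_abundances):
        species = list("ABCDEF")
        dist = patristic_distances(six_tree)
        coords2 = functional_space(six_traits, n_axes=2)
        for r in range(len(species) + 1):
            for subset in itertools.combinations(species, r):
                sub = list(subset)
                ab = six_abundances.copy()
                ab[~ab.index.isin(sub)] = 0.0
                # Shannon
                rich, sh = richness_shannon(ab)
                assert rich == len(sub)
                assert np.isclose(sh, shannon_oracle(ab.to_numpy()), atol=1e-8)
                # Faith PD
                got_pd = faith_pd(sub, six_tree) if sub else 0.0
                assert np.isclose(got_pd, pd_oracle(sub, six_tree), atol=1e-8)
                # MPD
                got_mpd = mpd(sub, dist)
                want_mpd = mpd_oracle(sub, six_tree)
                if len(sub) < 2:
                    assert np.isnan(got_mpd)
                else:
                    assert np.isclose(got_mpd, want_mpd, atol=1e-8)
                # FRic via independent hull (shapely / GEOS) in 2 axes
                got_fric = fric(sub, coords2)
                if len(sub) < 2:
                    assert np.isnan(got_fric)
                elif len(sub) == 2:
                    pts = coords2.loc[sub].to_numpy()
                    assert np.isclose(got_fric, abs(pts[1, 0] - pts[0, 0]),
                                      atol=1e-8)
                else:
                    hull = MultiPoint(
                        [tuple(p) for p in coords2.loc[sub].to_numpy()]
                    ).convex_hull
                    if hull.geom_type == "Polygon":
                        assert np.isclose(got_fric, hull.area, atol=1e-8)
                # FDis
                if sub:
                    got_fdis = fdis(ab, coords2)
                    want = fdis_oracle(ab[sub].to_numpy(),
                                       coords2.loc[sub].to_numpy())
                    assert np.isclose(got_fdis, want, atol=1e-8)
                # CWM
                got_cwm = cwm(ab, six_traits["sla"])
                want_cwm = cwm_oracle(ab[sub].to_numpy() if sub else [],
                                      six_traits.loc[sub, "sla"].to_numpy()
                                      if sub else [])
                if sub:
                    assert np.isclose(got_cwm, want_cwm, atol=1e-8)

    def test_pd_monotone_under_species_addition(self, six_tree):
        species = list("ABCDEF")
        for r in range(1, 6):
            for subset in itertools.combinations(species, r):
                base = faith_pd(list(subset), six_tree)
                for extra in set(species) - set(subset):
                    assert faith_pd(list(subset) + [extra], six_tree) >= base - 1e-12


class TestShannon:
    def test_two_equal_covers(self):
        rich, h = richness_shannon(np.array([0.3, 0.3]))
        assert rich == 2
        assert np.isclose(h, np.log(2))

    def test_single_species_zero(self):
        assert richness_shannon(np.array([0.7]))[1] == 0.0

    def test_hand_value(self):
        _, h = richness_shannon(np.array([0.5, 0.3, 0.2]))
        assert np.isclose(h, 1.0297, atol=5e-5)

    def test_maximal_at_equal_abundances(self):
        rng = np.random.default_rng(0)
        for s in (3, 5, 8):
            uneven = rng.dirichlet(np.ones(s)) + 1e-6
            assert richness_shannon(uneven)[1] <= np.log(s) + 1e-12

    def test_negative_abundance_raises(self):
        with pytest.raises(ValueError):
            richness_shannon(np.array([-0.1, 0.2]))


class TestFaithPd:
    def test_all_tips_is_total_branch_length(self, six_tree):
        total = sum(e.length or 0.0 for e in six_tree.preorder_edge_iter())
        assert np.isclose(faith_pd(list("ABCDEF"), six_tree), total)

    def test_two_tips_equals_patristic(self, six_tree):
        dist = patristic_distances(six_tree)
        assert np.isclose(faith_pd(["A", "E"], six_tree), dist.loc["A", "E"])

    def test_include_root_adds_root_path(self, six_tree):
        # A and B coalesce below the root; the root flag adds their stem
        excl = faith_pd(["A", "B"], six_tree)
        incl = faith_pd(["A", "B"], six_tree, include_root=True)
        assert np.isclose(excl, 2.0)
        assert np.isclose(incl, 4.0)

    def test_missing_species_raises(self, six_tree):
        with pytest.raises(KeyError):
            faith_pd(["A", "nope"], six_tree)


class TestFunctionalSpace:
    def test_identical_species_zero_distance(self):
        t = pd.DataFrame({"x": [1.0, 1.0], "cat": ["u", "u"]}, index=["a", "b"])
        assert gower_distance(t).loc["a", "b"] == 0.0

    def test_single_full_range_difference(self):
        # two species differing in 1 of 4 traits -> Gower distance 1/4
        t = pd.DataFrame(
            {"x": [0.0, 1.0, 0.5], "y": [2.0, 2.0, 2.5],
             "z": [1.0, 1.0, 3.0], "cat": ["u", "u", "v"]},
            index=["a", "b", "c"],
        )
        assert np.isclose(gower_distance(t).loc["a", "b"], 0.25)

    def test_single_trait_space_reproduces_scaled_distances(self):
        rng = np.random.default_rng(1)
        x = rng.random(6)
        t = pd.DataFrame({"x": x}, index=[f"s{i}" for i in range(6)])
        coords = functional_space(t, n_axes=1)
        from scipy.spatial.distance import pdist, squareform
        got = squareform(pdist(coords.to_numpy()))
        want = squareform(pdist(x[:, None] / np.ptp(x)))
        assert np.allclose(got, want, atol=1e-8)

    def test_zero_range_trait_dropped(self):
        t = pd.DataFrame({"x": [1.0, 1.0], "y": [0.0, 2.0]}, index=["a", "b"])
        D = gower_distance(t)
        assert np.isclose(D.loc["a", "b"], 1.0)  # only y contributes


class TestFricFdis:
    def test_right_triangle_area(self):
        coords = pd.DataFrame({"a1": [0.0, 1.0, 0.0], "a2": [0.0, 0.0, 1.0]},
                              index=["a", "b", "c"])
        assert np.isclose(fric(["a", "b", "c"], coords), 0.5)

    def test_collinear_points_fall_back_to_range(self):
        coords = pd.DataFrame({"a1": [0.0, 1.0, 3.0], "a2": [0.0, 0.0, 0.0]},
                              index=["a", "b", "c"])
        assert np.isclose(fric(["a", "b", "c"], coords), 3.0)

    def test_hull_monotone_in_fixed_axes(self):
        rng = np.random.default_rng(2)
        coords = pd.DataFrame(rng.random((8, 2)), columns=["a1", "a2"],
                              index=[f"s{i}" for i in range(8)])
        full = fric(list(coords.index), coords)
        sub = fric(list(coords.index[:5]), coords)
        assert sub <= full + 1e-12

    def test_fdis_two_points_half_distance(self):
        coords = pd.DataFrame({"a1": [0.0, 3.0]}, index=["a", "b"])
        ab = pd.Series([0.2, 0.2], index=["a", "b"])
        assert np.isclose(fdis(ab, coords), 1.5)

    def test_fdis_weighted_hand_case(self):
        coords = pd.DataFrame({"a1": [0.0, 4.0]}, index=["a", "b"])
        ab = pd.Series([3.0, 1.0], index=["a", "b"])
        # centroid at 1; FDis = (3*1 + 1*3)/4
        assert np.isclose(fdis(ab, coords), 1.5)

    def test_single_species_zero(self):
        coords = pd.DataFrame({"a1": [1.0, 2.0]}, index=["a", "b"])
        assert fdis(pd.Series([0.5, 0.0], index=["a", "b"]), coords) == 0.0


class TestCwm:
    def test_shared_value(self):
        ab = pd.Series([0.2, 0.5], index=["a", "b"])
        tr = pd.Series([7.0, 7.0], index=["a", "b"])
        assert np.isclose(cwm(ab, tr), 7.0)

    def test_weighted_mean(self):
        ab = pd.Series([0.75, 0.25], index=["a", "b"])
        tr = pd.Series([4.0, 8.0], index=["a", "b"])
        assert cwm(ab, tr) == 5.0

    def test_missing_trait_renormalized(self):
        ab = pd.Series([0.5, 0.5, 0.5], index=["a", "b", "c"])
        tr = pd.Series([2.0, 4.0, np.nan], index=["a", "b", "c"])
        assert cwm(ab, tr) == 3.0

    def test_no_coverage_nan(self):
        ab = pd.Series([0.5], index=["a"])
        tr = pd.Series([np.nan], index=["a"])
        assert np.isnan(cwm(ab, tr))


class TestNullModels:
    def test_null_drawn_set_has_centered_ses(self, six_tree):
        """Communities drawn from the null itself average SES near 0."""
        rng = np.random.default_rng(0)
        pool = list("ABCDEF")
        ses_vals = []
        for i in range(40):
            draw = list(rng.choice(pool, size=3, replace=False))
            s, p = ses_null("pd", draw, pool, tree=six_tree,
                            config=NullModelConfig(n_randomizations=199, seed=i))
            ses_vals.append(s)
        assert abs(np.nanmean(ses_vals)) < 0.2

    def test_closest_pair_is_clustered(self, six_tree):
        # C and D are the closest tips (distance 1.0)
        dist = patristic_distances(six_tree)
        s, p = ses_null("mpd", ["C", "D"], list("ABCDEF"), dist=dist,
                        config=NullModelConfig(n_randomizations=499, seed=1))
        assert s < 0

    def test_richness_equals_pool_degenerate(self, six_tree):
        s, p = ses_null("pd", list("ABCDEF"), list("ABCDEF"), tree=six_tree,
                        config=NullModelConfig(n_randomizations=99, seed=0))
        assert np.isnan(s)


class TestProfile:
    def test_column_order_invariance(self, six_tree, six_traits):
        rng = np.random.default_rng(3)
        comm = pd.DataFrame(rng.random((4, 6)) * (rng.random((4, 6)) > 0.4),
                            columns=list("ABCDEF"),
                            index=[f"p{i}" for i in range(4)])
        dist = patristic_distances(six_tree)
        coords = functional_space(six_traits)
        a = diversity_profile(comm, tree=six_tree, dist=dist, coords=coords,
                              traits=six_traits)
        shuffled = comm[list("FCEABD")]
        b = diversity_profile(shuffled, tree=six_tree, dist=dist, coords=coords,
                              traits=six_traits)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_plot_marked(self, six_tree):
        comm = pd.DataFrame([[0.0] * 6], columns=list("ABCDEF"), index=["p0"])
        prof = diversity_profile(comm, tree=six_tree)
        assert prof.loc["p0", "richness"] == 0
        assert prof.loc["p0", "shannon"] == 0.0
        assert np.isnan(prof.loc["p0", "faith_pd"])
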