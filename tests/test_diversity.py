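import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull

from macrofacets import (
    build_trait_space,
    functional_dispersion,
    functional_divergence,
    functional_evenness,
    functional_richness,
    gower_distance,
    taxonomic_distance_matrix,
    taxonomic_distinctness,
    taxonomic_richness,
)
from macrofacets.diversity import TraitSpace

from conftest import toy_taxonomy


def _tax(rows, species=None):
    species = species or [f"s{i + 1}" for i in range(len(rows))]
    return pd.DataFrame(
        rows,
        index=species,
        columns=["genus", "family", "order", "subclass", "class", "phylum"],
    )


def _space_from_points(pts, species=None):
    pts = np.asarray(pts, dtype=float)
    species = species or [f"s{i}" for i in range(len(pts))]
    coords = pd.DataFrame(
        pts - pts.mean(axis=0),
        index=species,
        columns=[f"axis{i + 1}" for i in range(pts.shape[1])],
    )
    return TraitSpace(
        coords=coords,
        eigenvalues=np.ones(pts.shape[1]),
        correction="none",
        gower=pd.DataFrame(),
    )


def _occ_all(species, sites=("site1",)):
    return pd.DataFrame(1, index=list(sites), columns=species)


class TestTaxonomicDistance:
    # values frozen from the reference rank-distance implementation
    # (equal branch lengths, max realized distance rescaled to 100)
    def test_single_phylum_table_matches_reference(self):
        tax = _tax(
            [
                ["G1", "F1", "O1", "SC1", "C1", "P1"],
                ["G1", "F1", "O1", "SC1", "C1", "P1"],
                ["G2", "F1", "O1", "SC1", "C1", "P1"],
                ["G3", "F2", "O2", "SC2", "C2", "P1"],
            ]
        )
        d = taxonomic_distance_matrix(tax)
        expected = np.array(
            [
                [0.0, 16.66667, 33.33333, 100.0],
                [16.66667, 0.0, 33.33333, 100.0],
                [33.33333, 33.33333, 0.0, 100.0],
                [100.0, 100.0, 100.0, 0.0],
            ]
        )
        np.testing.assert_allclose(d.to_numpy(), expected, atol=1e-4)

    def test_cross_phylum_table_matches_reference(self):
        tax = _tax(
            [
                ["G1", "F1", "O1", "SC1", "C1", "P1"],
                ["G1", "F1", "O1", "SC1", "C1", "P1"],
                ["G2", "F1", "O1", "SC1", "C1", "P1"],
                ["G3", "F2", "O2", "SC2", "C2", "P1"],
                ["G4", "F3", "O3", "SC3", "C3", "P2"],
            ]
        )
        d = taxonomic_distance_matrix(tax)
        # with a cross-phylum pair present, congeners sit at 100/7
        expected = np.array(
            [
                [0.0, 14.2857, 28.5714, 85.7143, 100.0],
                [14.2857, 0.0, 28.5714, 85.7143, 100.0],
                [28.5714, 28.5714, 0.0, 85.7143, 100.0],
                [85.7143, 85.7143, 85.7143, 0.0, 100.0],
                [100.0, 100.0, 100.0, 100.0, 0.0],
            ]
        )
        np.testing.assert_allclose(d.to_numpy(), expected, atol=1e-4)

    def test_diagonal_zero_symmetric_ultrametric(self):
        tax = toy_taxonomy(10)
        d = taxonomic_distance_matrix(tax).to_numpy()
        assert np.allclose(np.diag(d), 0)
        assert np.allclose(d, d.T)
        assert d.max() == pytest.approx(100.0)
        # ultrametric: d(i,k) <= max(d(i,j), d(j,k))
        for i, j, k in itertools.permutations(range(10), 3):
            assert d[i, k] <= max(d[i, j], d[j, k]) + 1e-9


class TestTaxonomicDistinctness:
    def test_richness_counts_presences(self):
        occ = pd.DataFrame([[1, 0, 1, 1], [0, 0, 0, 0], [1, 1, 1, 1]],
                           columns=list("abcd"))
        assert list(taxonomic_richness(occ)) == [3, 0, 4]

    def test_reference_community_values(self):
        # frozen from the reference distinctness implementation on the
        # single-phylum table above: all 4 present -> 63.888..; first
        # three -> 27.777..; a congeneric pair -> 16.666..
        tax = _tax(
            [
                ["G1", "F1", "O1", "SC1", "C1", "P1"],
                ["G1", "F1", "O1", "SC1", "C1", "P1"],
                ["G2", "F1", "O1", "SC1", "C1", "P1"],
                ["G3", "F2", "O2", "SC2", "C2", "P1"],
            ]
        )
        d = taxonomic_distance_matrix(tax)
        occ = pd.DataFrame(
            [[1, 1, 1, 1], [1, 1, 1, 0], [1, 1, 0, 0]],
            index=["siteA", "siteB", "siteC"],
            columns=tax.index,
        )
        td = taxonomic_distinctness(occ, d)
        np.testing.assert_allclose(
            td.to_numpy(), [63.88889, 27.77778, 16.66667], atol=1e-4
        )

    def test_matches_bruteforce_over_random_subsets(self, rng):
        tax = toy_taxonomy(10)
        d = taxonomic_distance_matrix(tax)
        rows = []
        for _ in range(50):
            rows.append((rng.random(10) < 0.5).astype(int))
        occ = pd.DataFrame(rows, columns=tax.index)
        td = taxonomic_distinctness(occ, d)
        dm = d.to_numpy()
        for i, row in enumerate(occ.to_numpy()):
            present = np.flatnonzero(row)
            if len(present) < 2:
                assert np.isnan(td.iloc[i])
                continue
            pairs = [dm[a, b] for a, b in itertools.combinations(present, 2)]
            assert td.iloc[i] == pytest.approx(np.mean(pairs), abs=1e-10)

    def test_single_species_undefined(self):
        tax = toy_taxonomy(4)
        d = taxonomic_distance_matrix(tax)
        occ = pd.DataFrame([[1, 0, 0, 0]], columns=tax.index)
        assert np.isnan(taxonomic_distinctness(occ, d).iloc[0])

    def test_congeneric_twin_of_central_species_never_increases_tdis(self, rng):
        # a congeneric duplicate shares every supra-species rank with its
        # twin, so its distances to the rest equal the twin's; twinning the
        # species with the smallest mean distance to the others provably
        # dilutes (or preserves) the mean pairwise distance
        base_tax = toy_taxonomy(10)
        dm_base = taxonomic_distance_matrix(base_tax).to_numpy()
        for trial in range(20):
            present = rng.choice(10, size=5, replace=False)
            sub = dm_base[np.ix_(present, present)]
            means = (sub.sum(axis=1)) / (len(present) - 1)
            i_central = int(np.argmin(means))
            # build the twinned taxonomy: copy the central species' ranks
            twin_tax = base_tax.iloc[present].copy()
            twin_row = twin_tax.iloc[[i_central]].rename(index={twin_tax.index[i_central]: "twin"})
            twin_tax = pd.concat([twin_tax, twin_row])
            d2 = taxonomic_distance_matrix(twin_tax)
            occ_before = pd.DataFrame(
                [[1] * 5 + [0]], columns=twin_tax.index
            )
            occ_after = pd.DataFrame([[1] * 6], columns=twin_tax.index)
            before = taxonomic_distinctness(occ_before, d2).iloc[0]
            after = taxonomic_distinctness(occ_after, d2).iloc[0]
            assert after <= before + 1e-9


class TestGower:
    def _traits(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "life_form", "life_cycle", "morphology",
                "sexual_propagation", "adult_weight",
            ],
            index=[f"s{i}" for i in range(len(rows))],
        )

    def test_identical_rows_zero(self):
        t = self._traits([["submerged", "annual", "stem", "dioecy", 2.0]] * 2
                         + [["emergent", "perennial", "leafy", "monoecism", 5.0]])
        d = gower_distance(t)
        assert d.iloc[0, 1] == 0.0

    def test_all_categorical_mismatch_equal_weight(self):
        t = self._traits(
            [
                ["submerged", "annual", "stem", "dioecy", 2.0],
                ["emergent", "perennial", "leafy", "monoecism", 2.0],
                ["free-floating", "annual", "turion", "dioecy", 4.0],
            ]
        )
        d = gower_distance(t)
        assert d.iloc[0, 1] == pytest.approx(0.8)

    def test_weight_extremes_only(self):
        t = self._traits(
            [
                ["submerged", "annual", "stem", "dioecy", 1.0],
                ["submerged", "annual", "stem", "dioecy", 9.0],
                ["submerged", "annual", "stem", "dioecy", 5.0],
            ]
        )
        d = gower_distance(t)
        assert d.iloc[0, 1] == pytest.approx(0.2)
        assert d.iloc[0, 2] == pytest.approx(0.1)

    def test_bounds_symmetry_zero_diagonal(self, rng):
        forms = ["submerged", "emergent", "floating-leaved", "free-floating"]
        rows = [
            [
                rng.choice(forms),
                rng.choice(["annual", "perennial"]),
                rng.choice(["turion", "stem", "rosette", "leafy"]),
                rng.choice(["monoecism", "dioecy"]),
                float(rng.uniform(0.1, 50)),
            ]
            for _ in range(15)
        ]
        d = gower_distance(self._traits(rows)).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()


class TestTraitSpace:
    def test_three_equidistant_species_form_equilateral_triangle(self):
        d = pd.DataFrame(
            0.6 * (1 - np.eye(3)), index=list("abc"), columns=list("abc")
        )
        space = build_trait_space(d, correction="none")
        ev = space.eigenvalues
        assert ev[0] == pytest.approx(ev[1], rel=1e-10)
        pts = space.coords.to_numpy()
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(pts), [0.6] * 3, atol=1e-10)

    def test_euclidean_distances_reproduced(self, rng):
        pts = rng.normal(size=(8, 3))
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(pts)))
        space = build_trait_space(d, correction="none")
        np.testing.assert_allclose(
            pdist(space.coords.to_numpy()), pdist(pts), atol=1e-8
        )
        assert np.allclose(space.coords.to_numpy().mean(axis=0), 0, atol=1e-10)

    def test_two_species_half_distance(self):
        d = pd.DataFrame([[0.0, 0.8], [0.8, 0.0]], index=list("ab"), columns=list("ab"))
        space = build_trait_space(d, correction="none")
        np.testing.assert_allclose(
            np.abs(space.coords.to_numpy().ravel()), [0.4, 0.4], atol=1e-10
        )

    def test_sqrt_correction_removes_negative_eigenvalues(self, rng):
        # Gower matrices on categorical data are typically non-Euclidean
        forms = ["submerged", "emergent", "floating-leaved", "free-floating"]
        rows = {
            "life_form": rng.choice(forms, 12),
            "life_cycle": rng.choice(["annual", "perennial"], 12),
            "morphology": rng.choice(["turion", "stem", "rosette", "leafy"], 12),
            "sexual_propagation": rng.choice(["monoecism", "dioecy"], 12),
            "adult_weight": rng.uniform(0.5, 20, 12),
        }
        g = gower_distance(pd.DataFrame(rows, index=[f"s{i}" for i in range(12)]))
        space = build_trait_space(g, correction="sqrt")
        assert space.eigenvalues.min() > -1e-6 * space.eigenvalues.max()

    def test_matches_skbio_pcoa(self, rng):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        pts = rng.normal(size=(7, 2))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        space = build_trait_space(
            pd.DataFrame(d, index=list("abcdefg"), columns=list("abcdefg")),
            correction="none",
        )
        ref = skbio_pcoa(d, number_of_dimensions=2)
        ours = space.coords.to_numpy()[:, :2]
        theirs = ref.samples.to_numpy()
        for k in range(2):  # axes defined up to sign
            assert min(
                np.abs(ours[:, k] - theirs[:, k]).max(),
                np.abs(ours[:, k] + theirs[:, k]).max(),
            ) < 1e-8


class TestFunctionalIndices:
    def test_fric_unit_square(self):
        space = _space_from_points([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]])
        occ = _occ_all(space.coords.index)
        assert functional_richness(space, occ, 2).iloc[0] == pytest.approx(1.0)

    def test_fric_degenerate_collinear_zero(self):
        space = _space_from_points([[0, 0], [1, 1], [2, 2], [3, 3]])
        occ = _occ_all(space.coords.index)
        with pytest.warns(UserWarning, match="degenerate"):
            val = functional_richness(space, occ, 2).iloc[0]
        assert val == 0.0

    def test_fric_undefined_when_too_few_species(self):
        # S <= n_axes leaves the hull volume undefined; S = n_axes + 1 is
        # the smallest defined case (a simplex)
        space = _space_from_points([[0, 0], [1, 0], [0, 1]])
        sp = list(space.coords.index)
        occ = pd.DataFrame([[1, 1, 0]], index=["s"], columns=sp)
        assert np.isnan(functional_richness(space, occ, 2).iloc[0])
        occ3 = _occ_all(sp)
        assert functional_richness(space, occ3, 2).iloc[0] == pytest.approx(0.5)

    def test_fric_monotone_under_hull_extension(self, rng):
        pts = rng.normal(size=(6, 2))
        space = _space_from_points(np.vstack([pts, pts.mean(axis=0)]))
        sp = list(space.coords.index)
        occ_base = pd.DataFrame(0, index=["s"], columns=sp)
        occ_base.loc["s", sp[:6]] = 1
        base = functional_richness(space, occ_base, 2).iloc[0]
        occ_inside = occ_base.copy()
        occ_inside.loc["s", sp[6]] = 1  # centroid is strictly inside
        inside = functional_richness(space, occ_inside, 2).iloc[0]
        assert inside == pytest.approx(base, abs=1e-10)
        far = np.vstack([pts, [pts[:, 0].max() + 5.0, 0.0]])
        space2 = _space_from_points(far)
        occ2 = _occ_all(space2.coords.index)
        assert functional_richness(space2, occ2, 2).iloc[0] > base

    def test_feve_equally_spaced_line_is_one(self):
        for s in (3, 5, 8):
            space = _space_from_points([[i, 0.0] for i in range(s)])
            occ = _occ_all(space.coords.index)
            assert functional_evenness(space, occ).iloc[0] == pytest.approx(1.0)

    def test_feve_two_branch_hand_formula(self):
        # 3 species on a line at 0, 1, 1+eps: branches 1 and eps
        eps = 1e-3
        space = _space_from_points([[0, 0], [1, 0], [1 + eps, 0]])
        occ = _occ_all(space.coords.index)
        pew = np.array([1.0, eps]) / (1.0 + eps)
        expected = (np.minimum(pew, 0.5).sum() - 0.5) / 0.5
        assert functional_evenness(space, occ).iloc[0] == pytest.approx(expected)

    def test_feve_undefined_below_three(self):
        space = _space_from_points([[0, 0], [1, 0]])
        occ = _occ_all(space.coords.index)
        assert np.isnan(functional_evenness(space, occ).iloc[0])

    def test_fdiv_regular_polygon_is_one(self):
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        space = _space_from_points(np.c_[np.cos(ang), np.sin(ang)])
        occ = _occ_all(space.coords.index)
        assert functional_divergence(space, occ).iloc[0] == pytest.approx(1.0)

    def test_fdiv_center_point_hand_evaluation(self):
        ang = np.linspace(0, 2 * np.pi, 3, endpoint=False)
        pts = np.vstack([np.c_[np.cos(ang), np.sin(ang)], [[0.0, 0.0]]])
        space = _space_from_points(pts)
        occ = _occ_all(space.coords.index)
        # hull vertices are the 3 circle points; G = their centroid = origin
        dg = np.array([1.0, 1.0, 1.0, 0.0])
        dbar = dg.mean()
        dev = dg - dbar
        expected = (dev.mean() + dbar) / (np.abs(dev).mean() + dbar)
        assert functional_divergence(space, occ).iloc[0] == pytest.approx(expected)

    def test_fdis_two_species_half_distance(self):
        space = _space_from_points([[0, 0], [3, 4]])
        occ = _occ_all(space.coords.index)
        assert functional_dispersion(space, occ).iloc[0] == pytest.approx(2.5)

    def test_fdis_singleton_zero(self):
        space = _space_from_points([[2, 5], [0, 0]])
        occ = pd.DataFrame([[1, 0]], index=["s"], columns=space.coords.index)
        assert functional_dispersion(space, occ).iloc[0] == 0.0

    def test_indices_invariant_to_rotation_and_relabeling(self, rng):
        pts = rng.normal(size=(7, 2))
        theta = 1.1
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        space_a = _space_from_points(pts)
        space_b = _space_from_points(pts @ rot.T)
        occ = _occ_all(space_a.coords.index)
        for fn in (
            functional_richness,
            functional_evenness,
            functional_divergence,
            functional_dispersion,
        ):
            va = fn(space_a, occ, 2).iloc[0]
            vb = fn(space_b, occ, 2).iloc[0]
            assert va == pytest.approx(vb, abs=1e-8)


class TestProfileAssembly:
    def test_profile_shape_and_boundaries(self, tiny_dataset):
        from macrofacets import diversity_profile

        prof = diversity_profile(tiny_dataset)
        assert list(prof.columns) == ["S", "TRic", "TDis", "FRic", "FEve", "FDiv", "FDis"]
        assert (prof["TRic"] == prof["S"]).all()
        defined = prof.dropna()
        assert ((defined["FEve"] >= 0) & (defined["FEve"] <= 1)).all()
        assert ((defined["FDiv"] >= 0) & (defined["FDiv"] <= 1)).all()
        assert (defined["FDis"] >= 0).all()

    def test_profile_invariant_to_species_column_order(self, tiny_dataset):
        from dataclasses import replace

        from macrofacets import diversity_profile

        prof = diversity_profile(tiny_dataset)
        perm = list(tiny_dataset.occurrence.columns[::-1])
        shuffled = replace(
            tiny_dataset,
            occurrence=tiny_dataset.occurrence[perm],
            traits=tiny_dataset.traits.loc[perm],
            taxonomy=tiny_dataset.taxonomy.loc[perm],
        )
        prof2 = diversity_profile(shuffled)
        pd.testing.assert_frame_equal(prof, prof2, atol=1e-8, rtol=0)
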