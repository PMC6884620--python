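import numpy as np
import pandas as pd
import pytest

from invafun.abundance import correct_abundance, hellinger
from invafun.data_model import (
    DEFAULT_GUILD_VOCABULARIES,
    ECOLOGICAL_FUNCTIONS,
    AbundanceMatrix,
    SpeciesTable,
    TraitTable,
)
from invafun.traits_fd import embed, fdis, gower, richness, site_fdis


def random_trait_table(rng, n_species, vocab_sizes=(5, 5, 4, 3, 5)):
    data = {"species_id": [f"sp{i}" for i in range(n_species)]}
    vocabularies = {}
    for fn, size in zip(ECOLOGICAL_FUNCTIONS, vocab_sizes):
        full = list(DEFAULT_GUILD_VOCABULARIES[fn])[: max(size, 1)]
        vocabularies[fn] = full
        data[fn] = rng.choice(full, size=n_species).tolist()
    return TraitTable(pd.DataFrame(data), vocabularies=vocabularies)


def fdis_from_dissimilarities(d_corrected, weights):
    """Independent FDis oracle using only pairwise distances.

    For points embedded so that Euclidean distances equal d_corrected, the
    distance of point j to the weighted centroid satisfies
    z_j^2 = sum_k w_k d_jk^2 - 0.5 * sum_kl w_k w_l d_kl^2 (w normalised).
    No eigendecomposition involved.
    """
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    d2 = np.asarray(d_corrected, dtype=float) ** 2
    mean_to_all = d2 @ w
    grand = 0.5 * w @ d2 @ w
    z = np.sqrt(np.maximum(mean_to_all - grand, 0.0))
    return float(w @ z)


# ---------------------------------------------------------------- gower


def test_gower_mismatch_fractions(tiny_traits):
    d = gower(tiny_traits)
    assert d.loc["barbel", "barbel"] == 0.0
    # chub vs carp differ in reproduction and habitat_use only -> 2/5
    assert d.loc["chub", "carp"] == pytest.approx(0.4)
    np.testing.assert_allclose(d.values, d.values.T)
    assert ((d.values >= 0) & (d.values <= 1)).all()


def test_gower_identical_and_fully_distinct():
    tt = TraitTable(
        pd.DataFrame(
            {
                "species_id": ["a", "b", "c"],
                "feeding": ["omnivorous", "omnivorous", "piscivorous"],
                "reproduction": ["phytophilic", "phytophilic", "lithophilic"],
                "migration": ["resident", "resident", "anadromous"],
                "tolerance": ["tolerant", "tolerant", "intolerant"],
                "habitat_use": ["benthic", "benthic", "rheophilic"],
            }
        )
    )
    d = gower(tt)
    assert d.loc["a", "b"] == 0.0
    assert d.loc["a", "c"] == 1.0


def test_gower_empty_subset_errors(tiny_traits):
    with pytest.raises(ValueError):
        gower(tiny_traits, subset=[])


# ---------------------------------------------------------------- embed


def test_two_point_embedding_closed_form():
    d = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["a", "b"], columns=["a", "b"])
    space = embed(d)  # sqrt correction: embedded separation sqrt(0.4)
    dist = space.distances().loc["a", "b"]
    assert dist == pytest.approx(np.sqrt(0.4), abs=1e-10)
    assert space.coordinates.shape[1] == 1


def test_three_equidistant_species_embed_symmetrically():
    ids = ["a", "b", "c"]
    d = pd.DataFrame(1.0 - np.eye(3), index=ids, columns=ids)
    space = embed(d)
    dist = space.distances()
    off = [dist.iloc[i, j] for i in range(3) for j in range(3) if i < j]
    np.testing.assert_allclose(off, off[0], atol=1e-10)


def test_embedding_reproduces_corrected_dissimilarities():
    rng = np.random.default_rng(3)
    tt = random_trait_table(rng, 12)
    d = gower(tt)
    space = embed(d)
    np.testing.assert_allclose(space.distances().values, np.sqrt(d.values), atol=1e-8)


def test_embed_matches_reference_pcoa():
    """Coordinates agree with scikit-bio's PCoA up to axis sign."""
    skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
    from skbio import DistanceMatrix

    rng = np.random.default_rng(11)
    tt = random_trait_table(rng, 10)
    d = gower(tt)
    space = embed(d)
    ref = skbio_pcoa(DistanceMatrix(np.sqrt(d.values), ids=d.index))
    k = space.coordinates.shape[1]
    ref_coords = ref.samples.values[:, :k]
    for axis in range(k):
        ours, theirs = space.coordinates.values[:, axis], ref_coords[:, axis]
        assert min(np.abs(ours - theirs).max(), np.abs(ours + theirs).max()) < 1e-8


def test_embed_rejects_asymmetry_and_flags_degenerate():
    bad = pd.DataFrame([[0.0, 0.3], [0.6, 0.0]], index=["a", "b"], columns=["a", "b"])
    with pytest.raises(ValueError, match="symmetric"):
        embed(bad)
    zero = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
    assert embed(zero).coordinates.shape[1] == 0  # zero-dimensional space


# ---------------------------------------------------------------- fdis


def test_fdis_degenerate_and_two_point_cases():
    ids = ["a", "b"]
    d = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=ids, columns=ids)
    space = embed(d)
    de = space.distances().loc["a", "b"]
    # equal weights: centroid at midpoint -> FDis = De/2
    assert fdis(space, np.array([1.0, 1.0])) == pytest.approx(de / 2, abs=1e-12)
    # weights 3:1 -> centroid at the 3:1 point -> FDis = 0.375 * De
    assert fdis(space, np.array([3.0, 1.0])) == pytest.approx(0.375 * de, abs=1e-12)
    # single species
    assert fdis(space, np.array([2.0, 0.0])) == 0.0
    with pytest.raises(ValueError):
        fdis(space, np.array([0.0, 0.0]))


def test_fdis_weight_scale_invariance():
    rng = np.random.default_rng(5)
    tt = random_trait_table(rng, 8)
    space = embed(gower(tt))
    w = rng.uniform(0.1, 3.0, size=8)
    a, b = fdis(space, w), fdis(space, w * 137.0)
    assert abs(a - b) / a < 1e-12


def test_fdis_equal_weights_is_unweighted_mean_distance():
    rng = np.random.default_rng(6)
    tt = random_trait_table(rng, 7)
    space = embed(gower(tt))
    x = space.coordinates.values
    c = x.mean(axis=0)
    expected = np.sqrt(((x - c) ** 2).sum(axis=1)).mean()
    assert fdis(space, np.ones(7)) == pytest.approx(expected, abs=1e-12)


def test_fdis_matches_distance_only_oracle_on_random_instances():
    """embed+fdis equals the Gram-identity oracle on 200 random small pools."""
    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(200):
        n = int(rng.integers(2, 11))
        tt = random_trait_table(rng, n, vocab_sizes=tuple(rng.integers(2, 6, size=5)))
        d = gower(tt)
        space = embed(d)
        w = rng.uniform(0.05, 2.0, size=n)
        worst = max(worst, abs(fdis(space, w) - fdis_from_dissimilarities(np.sqrt(d.values), w)))
    assert worst < 1e-8


def test_duplicating_a_species_and_splitting_weight_preserves_fdis():
    rng = np.random.default_rng(9)
    tt = random_trait_table(rng, 6)
    w = rng.uniform(0.2, 2.0, size=6)
    base = fdis(embed(gower(tt)), w)

    dup = tt.data.reset_index(drop=True)
    clone = dup.iloc[[0]].assign(species_id="sp0_clone")
    tt2 = TraitTable(pd.concat([dup, clone], ignore_index=True), vocabularies=tt.vocabularies)
    w2 = np.concatenate([w, [w[0] / 2]])
    w2[0] = w[0] / 2
    split = fdis(embed(gower(tt2)), w2)
    assert abs(base - split) < 1e-10


# ---------------------------------------------------------------- site_fdis / richness


def test_site_fdis_subsets(tiny_abundance, tiny_traits, tiny_species):
    hel = hellinger(correct_abundance(tiny_abundance, tiny_species))
    res_all = site_fdis(hel, tiny_traits, tiny_species, "all")
    res_nat = site_fdis(hel, tiny_traits, tiny_species, "native")
    res_exo = site_fdis(hel, tiny_traits, tiny_species, "exotic")
    # 'up' hosts only the two natives: all == native there, exotic undefined
    assert res_all.fdis["up"] == pytest.approx(res_nat.fdis["up"], abs=1e-12)
    assert np.isnan(res_exo.fdis["up"])
    # single-species subset gives 0: site 'low' has one native (chub)
    assert res_nat.fdis["low"] == 0.0
    assert res_nat.richness["low"] == 1


def test_trait_restricted_exotics_have_lower_fdis():
    """Natives spanning 4 feeding guilds vs exotics sharing 1 -> native FDis
    is higher at every mixed site."""
    n_nat, n_exo = 4, 3
    species = SpeciesTable(
        pd.DataFrame(
            {
                "species_id": [f"n{i}" for i in range(n_nat)] + [f"e{i}" for i in range(n_exo)],
                "origin": ["native"] * n_nat + ["exotic"] * n_exo,
                "body_mass_class": [2] * (n_nat + n_exo),
            }
        )
    )
    feeding = ["omnivorous", "invertivorous", "piscivorous", "herbivorous"] + ["omnivorous"] * 3
    base = {
        "reproduction": "phytophilic",
        "migration": "resident",
        "tolerance": "tolerant",
        "habitat_use": "benthic",
    }
    traits = TraitTable(
        pd.DataFrame(
            {
                "species_id": species.species_ids,
                "feeding": feeding,
                **{fn: [v] * (n_nat + n_exo) for fn, v in base.items()},
            }
        )
    )
    rng = np.random.default_rng(2)
    grid = rng.integers(1, 6, size=(10, n_nat + n_exo))
    ab = AbundanceMatrix(
        pd.DataFrame(grid, index=[f"s{i}" for i in range(10)], columns=species.species_ids)
    )
    hel = hellinger(correct_abundance(ab, species))
    nat = site_fdis(hel, traits, species, "native").fdis
    exo = site_fdis(hel, traits, species, "exotic").fdis
    assert (nat > exo).all()  # exotics are functionally identical -> FDis 0
    assert (exo == 0).all()


def test_richness_counts(tiny_abundance, tiny_species):
    assert richness(tiny_abundance, tiny_species, "all").tolist() == [2, 4, 3]
    assert richness(tiny_abundance, tiny_species, "exotic")["mid"] == 2
    empty = AbundanceMatrix(
        pd.DataFrame({"site_id": ["void"], "barbel": [0], "carp": [0]})
    )
    assert richness(empty, tiny_species, "all")["void"] == 0
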