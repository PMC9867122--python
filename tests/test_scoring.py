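"""Interaction scoring: Tanimoto, per-pair combiner, matrix assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugsig import CompoundRecord, build_matrix, score_interaction, tanimoto
from drugsig.datatypes import BindingSite, ProteinSiteModel, as_fingerprint
from drugsig.scoring import PROTOCOLS


def fp(bits, length=16):
    return as_fingerprint(set(bits), length)


def brute_force_score(compound, protein, protocol):
    """Independent oracle: exhaustive enumeration over (site, ligand) pairs.

    Selects the pair with maximum Tanimoto, breaking ties by higher site
    score then lexicographically smaller site id, and combines with the
    selected site's score.
    """
    pairs = []
    for site in protein.sites:
        for lig in site.ligand_fingerprints:
            a = set(np.flatnonzero(compound.fingerprint))
            b = set(np.flatnonzero(lig))
            t = len(a & b) / len(a | b) if (a | b) else 0.0
            pairs.append((t, site.site_score, site.site_id))
    t, s, _ = max(pairs, key=lambda p: (p[0], p[1], [-ord(ch) for ch in p[2]]))
    if protocol == "product":
        return t * s
    if protocol == "tanimoto_only":
        return t
    return 0.5 * t + 0.5 * s


def random_instance(rng, length=24, max_sites=5, max_ligands=10):
    compound = CompoundRecord(
        "C", "c", "approved",
        rng.random(length) < rng.uniform(0.1, 0.6),
    )
    if not compound.fingerprint.any():
        compound = CompoundRecord("C", "c", "approved", fp({0}, length))
    n_sites = int(rng.integers(1, max_sites + 1))
    sites = []
    for s in range(n_sites):
        n_lig = int(rng.integers(1, max_ligands + 1))
        ligs = tuple(rng.random(length) < rng.uniform(0.1, 0.6) for _ in range(n_lig))
        # quantise site scores so score ties actually occur across sites
        score = float(rng.integers(0, 5)) / 4.0
        sites.append(BindingSite(f"S{s}", score, ligs))
    return compound, ProteinSiteModel("P", tuple(sites))


class TestTanimoto:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (fp({1, 5, 9}), fp({1, 5, 9}), 1.0),
            (fp({0, 1}), fp({2, 3}), 0.0),
            (fp({1, 2, 3}), fp({2, 3, 4}), 0.5),
            (fp(set()), fp(set()), 0.0),  # empty union defined as 0
        ],
    )
    def test_worked_examples(self, a, b, expected):
        assert tanimoto(a, b) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            tanimoto(fp({1}, 16), fp({1}, 32))

    @given(st.lists(st.booleans(), min_size=8, max_size=8),
           st.lists(st.booleans(), min_size=8, max_size=8))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        t = tanimoto(np.array(a), np.array(b))
        assert t == tanimoto(np.array(b), np.array(a))
        assert 0.0 <= t <= 1.0
        if any(a):
            assert tanimoto(np.array(a), np.array(a)) == 1.0


class TestScoreInteraction:
    def test_identical_ligand_gives_site_score_under_product(self):
        c = CompoundRecord("C", "c", "approved", fp({1, 2, 3}))
        p = ProteinSiteModel("P", (BindingSite("S0", 0.8, (fp({1, 2, 3}),)),))
        assert score_interaction(c, p, "product") == pytest.approx(0.8)

    def test_disjoint_ligands_give_zero_under_product(self):
        c = CompoundRecord("C", "c", "approved", fp({1, 2}))
        p = ProteinSiteModel(
            "P",
            (BindingSite("S0", 0.9, (fp({5, 6}), fp({7}))),
             BindingSite("S1", 0.2, (fp({8, 9}),))),
        )
        assert score_interaction(c, p, "product") == 0.0

    @pytest.mark.parametrize("protocol", PROTOCOLS)
    def test_matches_exhaustive_enumeration(self, protocol, rng):
        for _ in range(200):
            compound, protein = random_instance(rng)
            assert score_interaction(compound, protein, protocol) == brute_force_score(
                compound, protein, protocol
            )

    def test_tie_broken_by_site_score_then_id(self):
        c = CompoundRecord("C", "c", "approved", fp({1, 2}))
        # both sites hold an identical copy of the compound: Tanimoto ties at 1
        p = ProteinSiteModel(
            "P",
            (BindingSite("S1", 0.3, (fp({1, 2}),)),
             BindingSite("S0", 0.7, (fp({1, 2}),))),
        )
        assert score_interaction(c, p, "product") == pytest.approx(0.7)
        # equal site scores: lexicographically smaller site id wins (same value)
        p2 = ProteinSiteModel(
            "P",
            (BindingSite("SB", 0.5, (fp({1, 2}),)),
             BindingSite("SA", 0.5, (fp({1, 2}),))),
        )
        assert score_interaction(c, p2, "product") == pytest.approx(0.5)

    def test_adding_a_ligand_to_top_site_never_decreases_product_score(self, rng):
        """Max over a superset: a new ligand in the highest-confidence site can
        only raise the selected Tanimoto there, so the product score cannot
        drop.  (A new ligand in a low-confidence site CAN lower the product
        score by stealing the best-match selection, so the guarantee is
        restricted to the top-score site; under tanimoto_only it holds for
        any site.)"""
        for _ in range(50):
            compound, protein = random_instance(rng, max_sites=3, max_ligands=4)
            extra = rng.random(24) < 0.4
            top_idx = max(range(len(protein.sites)),
                          key=lambda i: (protein.sites[i].site_score,
                                         protein.sites[i].site_id))
            site = protein.sites[top_idx]
            bigger_sites = list(protein.sites)
            bigger_sites[top_idx] = BindingSite(
                site.site_id, site.site_score, site.ligand_fingerprints + (extra,)
            )
            bigger = ProteinSiteModel("P", tuple(bigger_sites))
            base = score_interaction(compound, protein, "product")
            assert score_interaction(compound, bigger, "product") >= base - 1e-12

            any_site = ProteinSiteModel(
                "P",
                (BindingSite(protein.sites[0].site_id, protein.sites[0].site_score,
                             protein.sites[0].ligand_fingerprints + (extra,)),)
                + protein.sites[1:],
            )
            base_t = score_interaction(compound, protein, "tanimoto_only")
            assert score_interaction(compound, any_site, "tanimoto_only") >= base_t - 1e-12

    def test_unknown_protocol_rejected(self):
        c = CompoundRecord("C", "c", "approved", fp({1}))
        p = ProteinSiteModel("P", (BindingSite("S0", 0.5, (fp({1}),)),))
        with pytest.raises(ValueError, match="protocol"):
            score_interaction(c, p, "docking")


class TestBuildMatrix:
    def test_single_pair_matches_score_interaction(self):
        c = CompoundRecord("C", "c", "approved", fp({1, 2, 3}))
        p = ProteinSiteModel("P", (BindingSite("S0", 0.6, (fp({2, 3, 4}),)),))
        m = build_matrix([c], [p])
        assert m.shape == (1, 1)
        assert m.scores[0, 0] == score_interaction(c, p)

    @pytest.mark.parametrize("protocol", PROTOCOLS)
    def test_every_entry_matches_per_pair_recomputation(self, small_world, protocol):
        compounds = small_world.compounds[:10]
        proteins = small_world.site_models[:10]
        m = build_matrix(compounds, proteins, protocol)
        for i, c in enumerate(compounds):
            for j, p in enumerate(proteins):
                assert m.scores[i, j] == score_interaction(c, p, protocol)

    def test_permuting_proteins_permutes_columns(self, small_world):
        compounds = small_world.compounds[:6]
        proteins = small_world.site_models[:6]
        m1 = build_matrix(compounds, proteins)
        m2 = build_matrix(compounds, proteins[::-1])
        assert np.array_equal(m1.scores, m2.scores[:, ::-1])
        assert m2.protein_ids == [p.protein_id for p in proteins[::-1]]

    def test_scores_bounded_and_finite(self, small_matrix):
        assert np.all(np.isfinite(small_matrix.scores))
        assert small_matrix.scores.min() >= 0.0
        assert small_matrix.scores.max() <= 1.0

    def test_duplicate_compound_ids_rejected(self):
        c = CompoundRecord("C", "c", "approved", fp({1}))
        p = ProteinSiteModel("P", (BindingSite("S0", 0.5, (fp({1}),)),))
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix([c, c], [p])
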