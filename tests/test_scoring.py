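"""B/H/tanh impact scores: closed forms, oracles, and score properties."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from casomics.scoring import (
    HotspotTable,
    MutationProfile,
    Substitution,
    b_score,
    combined_score,
    h_score,
    load_blosum100,
    parse_aa_change,
    score_samples,
)
from casomics.simulate import random_mutation_profiles

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# independently sourced entries (R Biostrings BLOSUM100 data)
FROZEN_ENTRIES = {
    ("A", "A"): 8, ("R", "K"): 3, ("C", "C"): 14, ("W", "W"): 17,
    ("G", "D"): -4, ("R", "H"): -1, ("I", "V"): 4, ("F", "Y"): 4,
    ("E", "Q"): 2, ("M", "L"): 3,
}


def profile(*subs, sample="S1"):
    return MutationProfile(
        sample_id=sample,
        substitutions=tuple(
            Substitution(gene=g, ref_aa=r, position=p, alt_aa=a) for g, r, p, a in subs
        ),
    )


substitutions = st.builds(
    Substitution,
    gene=st.sampled_from(["G1", "G2", "G3"]),
    ref_aa=st.sampled_from(AA20),
    position=st.integers(1, 50),
    alt_aa=st.sampled_from(AA20),
).filter(lambda s: s.ref_aa != s.alt_aa or True)

profiles = st.lists(substitutions, max_size=30).map(
    lambda subs: MutationProfile(sample_id="H", substitutions=tuple(subs))
)


class TestMatrix:
    def test_matches_independent_reference_entries(self, blosum):
        for (a, b), value in FROZEN_ENTRIES.items():
            assert blosum.score(a, b) == value

    def test_symmetric_over_canonical_alphabet(self, blosum):
        for a in AA20:
            for b in AA20:
                assert blosum.score(a, b) == blosum.score(b, a)

    def test_ambiguous_codes_rejected(self, blosum):
        for bad in ("B", "Z", "X", "*"):
            with pytest.raises(ValueError):
                blosum.score("A", bad)

    def test_substitution_rejects_non_canonical(self):
        with pytest.raises(ValueError, match="non-canonical"):
            Substitution(gene="G", ref_aa="U", position=1, alt_aa="A")

    def test_parse_aa_change(self):
        assert parse_aa_change("R175H") == ("R", 175, "H")
        with pytest.raises(ValueError):
            parse_aa_change("175H")


class TestClosedForms:
    def test_empty_profile_scores_zero(self, blosum):
        assert b_score(profile(), blosum) == 0.0

    def test_negative_entry_contributes_minus_s(self, blosum):
        # G->D has score -4, so B = 4
        assert b_score(profile(("G1", "G", 12, "D")), blosum) == 4.0

    def test_nonnegative_entry_contributes_zero(self, blosum):
        # M->L has score +3
        assert b_score(profile(("G1", "M", 5, "L")), blosum) == 0.0

    def test_h_score_quarter_p_gives_two(self):
        hs = HotspotTable({("G1", "R", 175, "H"): 0.25})
        assert h_score(profile(("G1", "R", 175, "H")), hs) == pytest.approx(2.0)

    def test_h_score_additive(self):
        hs = HotspotTable({("G1", "R", 1, "H"): 0.5, ("G1", "K", 2, "E"): 0.5})
        p = profile(("G1", "R", 1, "H"), ("G1", "K", 2, "E"))
        assert h_score(p, hs) == pytest.approx(2.0)

    def test_no_hotspot_match_scores_zero(self):
        hs = HotspotTable({("G1", "R", 175, "H"): 0.25})
        assert h_score(profile(("G1", "R", 175, "C")), hs) == 0.0

    def test_combined_zero_and_tanh2(self):
        assert combined_score(0.0, 0.0) == 0.0
        assert combined_score(2.0, 0.0) == pytest.approx(math.tanh(2.0))
        assert combined_score(2.0, 0.0) == pytest.approx(0.96403, abs=1e-5)

    def test_combined_saturates_at_one(self):
        value = combined_score(50.0, 50.0)
        assert value <= 1.0
        assert value == pytest.approx(1.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            combined_score(-0.1, 0.0)

    def test_hotspot_validation(self):
        with pytest.raises(ValueError, match="p-value"):
            HotspotTable({("G1", "R", 1, "H"): 0.0})
        frame = pd.DataFrame(
            [{"gene": "G1", "aa_ref": "R", "aa_pos": 1, "aa_alt": "H", "p_value": 0.5}]
        )
        assert HotspotTable.from_frame(frame).entries

    def test_position_only_matching_mode(self):
        hs = HotspotTable({("G1", "R", 175, "H"): 0.25, ("G1", "R", 175, "C"): 0.0625})
        p = profile(("G1", "R", 175, "G"))
        assert h_score(p, hs, match_on="exact") == 0.0
        # position mode uses the smallest p at that residue: -log2(1/16) = 4
        assert h_score(p, hs, match_on="position") == pytest.approx(4.0)


class TestOracles:
    def test_b_score_matches_naive_loop(self, blosum, rng):
        for _ in range(5):
            subs = []
            for _ in range(25):
                ref = AA20[rng.integers(20)]
                alt = AA20[rng.integers(20)]
                subs.append(("G1", ref, int(rng.integers(1, 400)), alt))
            p = profile(*subs)
            expected = 0.0
            for _, ref, _, alt in subs:
                s = blosum.score(ref, alt)
                if s < 0:
                    expected += -s
            assert b_score(p, blosum) == pytest.approx(expected)

    def test_score_samples_matches_per_sample_recomputation(self, blosum):
        hs = HotspotTable({("G1", "R", 175, "H"): 0.25, ("G2", "G", 12, "D"): 0.1})
        samples = random_mutation_profiles(
            10, seed=77, n_substitutions=(1, 15), genes=["G1", "G2", "G3"]
        )
        gene_sets = {"setA": {"G1", "G2"}, "all": {"G1", "G2", "G3"}}
        table, ledger = score_samples(samples, blosum, hs, gene_sets)
        for row in table.itertuples(index=False):
            p = next(s for s in samples if s.sample_id == row.sample)
            b = b_score(p, blosum, gene_sets[row.gene_set])
            h = h_score(p, hs, gene_sets[row.gene_set])
            assert row.b_score == pytest.approx(b)
            assert row.h_score == pytest.approx(h)
            assert row.combined == pytest.approx(math.tanh(b + h))
        assert len(table) == len(samples) * len(gene_sets)
        assert not ledger.empty

    def test_planted_hotspot_sample_outranks_clean_sample(self, blosum):
        hs = HotspotTable({("G1", "R", 175, "H"): 1e-6})
        planted = profile(("G1", "R", 175, "H"), sample="hot")
        clean = profile(("G1", "M", 5, "L"), sample="clean")
        table, _ = score_samples([planted, clean], blosum, hs, {"set": {"G1"}})
        by = table.set_index("sample")["combined"]
        assert by["hot"] > by["clean"]

    def test_empty_gene_set_rejected(self, blosum):
        hs = HotspotTable({})
        with pytest.raises(ValueError, match="empty"):
            score_samples([profile()], blosum, hs, {"bad": set()})


class TestProperties:
    @given(profiles)
    @settings(max_examples=150, deadline=None)
    def test_bounds_and_permutation_invariance(self, p):
        blosum = load_blosum100()
        hs = HotspotTable({("G1", "R", 175, "H"): 0.25})
        b, h = b_score(p, blosum), h_score(p, hs)
        c = combined_score(b, h)
        assert b >= 0 and h >= 0
        assert 0 <= c <= 1
        reversed_p = MutationProfile(p.sample_id, tuple(reversed(p.substitutions)))
        assert b_score(reversed_p, blosum) == pytest.approx(b)
        assert h_score(reversed_p, hs) == pytest.approx(h)

    @given(profiles, substitutions)
    @settings(max_examples=100, deadline=None)
    def test_adding_a_substitution_never_decreases_scores(self, p, extra):
        blosum = load_blosum100()
        hs = HotspotTable({("G1", "R", 175, "H"): 0.25})
        grown = MutationProfile(p.sample_id, p.substitutions + (extra,))
        assert b_score(grown, blosum) >= b_score(p, blosum)
        assert h_score(grown, hs) >= h_score(p, hs)
        assert combined_score(
            b_score(grown, blosum), h_score(grown, hs)
        ) >= combined_score(b_score(p, blosum), h_score(p, hs))

    @given(profiles)
    @settings(max_examples=100, deadline=None)
    def test_gene_set_restriction_equals_intersection(self, p):
        blosum = load_blosum100()
        gene_set = {"G1", "G3"}
        restricted = MutationProfile(
            p.sample_id,
            tuple(s for s in p.substitutions if s.gene in gene_set),
        )
        assert b_score(p, blosum, gene_set) == pytest.approx(b_score(restricted, blosum))

    def test_repeated_substitutions_each_contribute(self, blosum):
        one = profile(("G1", "G", 12, "D"))
        two = profile(("G1", "G", 12, "D"), ("G1", "G", 12, "D"))
        assert b_score(two, blosum) == pytest.approx(2 * b_score(one, blosum))
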