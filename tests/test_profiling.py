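"""Gene-level codon counting, conditional profiles and preference tallies."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import codonbias as cb
from codonbias.errors import ProfileError
from codonbias.profiling import rounded_percentages

from .conftest import random_cds

LEU_CODONS = ["CTA", "CTC", "CTG", "CTT", "TTA", "TTG"]


def leucine_counts(source, **leu):
    """CodonCounts holding only leucine codons, from keyword counts."""
    counts = {c: n for c, n in leu.items() if n}
    return cb.CodonCounts(
        source=source, counts=counts, stop_counts={}, total=sum(counts.values())
    )


class TestCodonCounts:
    def test_stop_codons_tracked_separately(self, code):
        counts = cb.codon_counts(cb.CodingSequence("x", "ATGCTGCTGTAA"), code)
        assert counts.counts == {"ATG": 1, "CTG": 2}
        assert counts.stop_counts == {"TAA": 1}
        assert counts.total == 3

    def test_ambiguous_codons_reduce_total(self, code):
        counts = cb.codon_counts(cb.CodingSequence("x", "ATGNNNCTGTAA"), code)
        assert counts.total == 2

    def test_matches_brute_force_tally(self, rng, code):
        cds = random_cds(rng, 200, code)
        counts = cb.codon_counts(cds, code)
        oracle = Counter(
            cds.sequence[i : i + 3] for i in range(0, len(cds.sequence), 3)
        )
        for codon, n in oracle.items():
            if code.translate_codon(codon) == "*":
                assert counts.stop_counts[codon] == n
            else:
                assert counts.counts[codon] == n
        assert counts.total == sum(
            n for c, n in oracle.items() if code.translate_codon(c) != "*"
        )


class TestAAProfile:
    @pytest.mark.parametrize(
        "kwargs,codon,percent",
        [
            # leucine tallies as printed for the four receptor genes:
            # chicken-style 41 CTG / 13 TTA of 119; crocodile-style
            # 19 CTG / 28 TTA of 111
            (dict(CTG=41, TTA=13, TTG=22, CTT=15, CTC=18, CTA=10), "CTG", 34),
            (dict(CTG=19, TTA=28, TTG=21, CTT=17, CTC=14, CTA=12), "CTG", 17),
            (dict(CTG=41, TTA=13, TTG=22, CTT=15, CTC=18, CTA=10), "TTA", 11),
            (dict(CTG=19, TTA=28, TTG=21, CTT=17, CTC=14, CTA=12), "TTA", 25),
        ],
    )
    def test_printed_leucine_percentages(self, code, kwargs, codon, percent):
        assert sum(kwargs.values()) in (119, 111)
        profile = cb.aa_profile(leucine_counts("gene", **kwargs), code)
        assert rounded_percentages(profile, "L")[codon] == percent

    def test_single_codon_type_family_is_degenerate(self, code):
        profile = cb.aa_profile(leucine_counts("g", TTG=7), code)
        assert profile.fractions("L")["TTG"] == 1.0
        assert profile.fractions("L")["CTG"] == 0.0

    def test_fractions_sum_to_one_per_family(self, rng, code):
        cds = random_cds(rng, 300, code)
        profile = cb.aa_profile(cb.codon_counts(cds, code), code)
        for aa, dist in profile.per_aa.items():
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_concatenation_profile_is_count_weighted_mixture(self, rng, code):
        a = random_cds(rng, 80, code, id="a", with_stop=False)
        b = random_cds(rng, 120, code, id="b", with_stop=False)
        joined = cb.CodingSequence("ab", a.sequence + b.sequence)
        ca, cb_, cj = (
            cb.codon_counts(x, code) for x in (a, b, joined)
        )
        pj = cb.aa_profile(cj, code)
        pa, pb = cb.aa_profile(ca, code), cb.aa_profile(cb_, code)
        for aa in pj.per_aa:
            fam = code.family(aa)
            na = sum(ca.counts.get(c, 0) for c in fam)
            nb = sum(cb_.counts.get(c, 0) for c in fam)
            for c in fam:
                fa = pa.fractions(aa)[c] if aa in pa.per_aa else 0.0
                fb = pb.fractions(aa)[c] if aa in pb.per_aa else 0.0
                expected = (na * fa + nb * fb) / (na + nb)
                assert pj.fractions(aa)[c] == pytest.approx(expected)


class TestPreferenceTally:
    def test_all_most_preferred_cds(self, human_table, code):
        ranking = cb.rank_codons(human_table, code)
        codons = [ranking.most(aa) for aa in sorted(ranking.per_aa)] * 3
        cds = cb.CodingSequence("best", "".join(codons))
        tally = cb.preference_tally(cb.codon_counts(cds, code), ranking, code)
        assert tally.n_least == 0
        assert tally.n_other == 0
        assert tally.n_most == len(codons)

    def test_single_codon_families_count_as_excluded(self, human_table, code):
        ranking = cb.rank_codons(human_table, code)
        cds = cb.CodingSequence("mw", "ATGTGGATGTAA")  # M W M stop
        tally = cb.preference_tally(cb.codon_counts(cds, code), ranking, code)
        assert tally.n_excluded == 3
        assert tally.total == 3

    def test_partition_identity_on_random_cds(self, rng, human_table, code):
        ranking = cb.rank_codons(human_table, code)
        for i in range(25):
            cds = random_cds(rng, int(rng.integers(5, 150)), code, id=f"p{i}")
            counts = cb.codon_counts(cds, code)
            tally = cb.preference_tally(counts, ranking, code)
            assert tally.total == counts.total

    def test_matches_brute_force_classification(self, rng, human_table, code):
        ranking = cb.rank_codons(human_table, code)
        cds = random_cds(rng, 300, code)
        counts = cb.codon_counts(cds, code)
        tally = cb.preference_tally(counts, ranking, code)
        most = least = other = excluded = 0
        for codon in cb.codons_of(cds):
            aa = code.translate_codon(codon)
            if aa == "*":
                continue
            if len(code.family(aa)) == 1:
                excluded += 1
            elif codon == ranking.per_aa[aa][0]:
                most += 1
            elif codon == ranking.per_aa[aa][1]:
                least += 1
            else:
                other += 1
        assert (tally.n_most, tally.n_least, tally.n_other, tally.n_excluded) == (
            most,
            least,
            other,
            excluded,
        )

    def test_missing_family_in_ranking_is_consistency_error(self, code):
        ranking = cb.PreferenceRanking(
            reference_species="partial",
            per_aa={"F": ("TTC", "TTT")},
            excluded=frozenset({"M", "W"}),
        )
        counts = leucine_counts("g", CTG=3)
        with pytest.raises(ProfileError, match="L"):
            cb.preference_tally(counts, ranking, code)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(deadline=None, max_examples=30)
    def test_partition_identity_on_constructed_counts(self, n_ctg, n_cta, n_ttg):
        table = cb.human_like_table()
        code = cb.standard_code()
        ranking = cb.rank_codons(table, code)
        counts = leucine_counts("h", CTG=n_ctg, CTA=n_cta, TTG=n_ttg)
        tally = cb.preference_tally(counts, ranking, code)
        assert tally.total == counts.total
        assert tally.n_most == n_ctg  # CTG most-preferred
        assert tally.n_least == n_cta  # CTA least-preferred
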