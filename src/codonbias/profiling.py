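"""Per-gene codon counting, conditional profiles and preference tallies.

This is the gene-level half of the analysis: count every codon of a CDS,
condition the counts on the encoded amino acid to get the gene's synonymous
codon profile, and classify each codon occurrence as the reference species'
most-preferred, least-preferred or intermediate synonymous choice. The
tallies count codon occurrences, not distinct codon types. Reported
percentages are rounded to the nearest integer for display; full precision
is kept internally.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .errors import ProfileError
from .seqio import DNA_ALPHABET, CodingSequence, GeneticCode, codons_of, standard_code
from .usage_tables import AAConditionalProfile, PreferenceRanking

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CodonCounts:
    """Codon occurrence counts for one source gene.

    ``counts`` covers amino-acid-coding codons only; stop codons are kept in
    ``stop_counts``. ``total`` is the number of amino-acid codons.
    """

    source: str
    counts: dict[str, int] = field(repr=False)
    stop_counts: dict[str, int] = field(repr=False)
    total: int = 0

    def __post_init__(self) -> None:
        if self.total != sum(self.counts.values()):
            raise ValueError("total must equal the sum of amino-acid codon counts")


@dataclass(frozen=True)
class PreferenceTally:
    """Counts of most-/least-preferred codon occurrences in one gene."""

    source: str
    n_most: int
    n_least: int
    n_other: int
    n_excluded: int

    @property
    def total(self) -> int:
        return self.n_most + self.n_least + self.n_other + self.n_excluded


def codon_counts(cds: CodingSequence, code: GeneticCode | None = None) -> CodonCounts:
    """Tally the codons of a CDS.

    Codons containing non-ACGT characters (possible under the ``skip-codon``
    ambiguity policy) are dropped with a log message, reducing the total.
    """
    code = code or standard_code()
    aa_counts: Counter[str] = Counter()
    stop_counts: Counter[str] = Counter()
    skipped = 0
    for codon in codons_of(cds):
        if set(codon) - DNA_ALPHABET:
            skipped += 1
            continue
        if code.translate_codon(codon) == "*":
            stop_counts[codon] += 1
        else:
            aa_counts[codon] += 1
    if skipped:
        logger.warning("source %r: skipped %d ambiguous codons", cds.id, skipped)
    return CodonCounts(
        source=cds.id,
        counts=dict(aa_counts),
        stop_counts=dict(stop_counts),
        total=sum(aa_counts.values()),
    )


def aa_profile(
    counts: CodonCounts,
    code: GeneticCode | None = None,
    small_sample_threshold: int = 10,
) -> AAConditionalProfile:
    """Condition codon counts on the encoded amino acid.

    For each amino acid observed in the gene, ``fraction(codon) =
    count(codon) / family total``; unobserved families are absent. Families
    observed fewer than ``small_sample_threshold`` times are logged as a
    warning, since their fractions are noisy.
    """
    code = code or standard_code()
    per_aa: dict[str, dict[str, float]] = {}
    for aa, family in code.families().items():
        family_total = sum(counts.counts.get(c, 0) for c in family)
        if family_total == 0:
            continue
        if family_total < small_sample_threshold and len(family) > 1:
            logger.warning(
                "source %r: only %d observations for amino acid %s; "
                "fractions are noisy",
                counts.source,
                family_total,
                aa,
            )
        per_aa[aa] = {c: counts.counts.get(c, 0) / family_total for c in family}
    return AAConditionalProfile(source=counts.source, per_aa=per_aa)


def preference_tally(
    counts: CodonCounts,
    ranking: PreferenceRanking,
    code: GeneticCode | None = None,
) -> PreferenceTally:
    """Classify every amino-acid codon occurrence against a reference ranking.

    Occurrences of the reference's most-preferred synonymous codon go to
    ``n_most``, of the least-preferred to ``n_least``, other multi-codon
    family members to ``n_other``; single-codon amino acids (which have no
    most/least distinction) to ``n_excluded``. Stop codons do not
    participate. The four fields always partition the amino-acid codon
    total.
    """
    code = code or standard_code()
    n_most = n_least = n_other = n_excluded = 0
    for codon, n in counts.counts.items():
        aa = code.translate_codon(codon)
        if aa in ranking.excluded:
            n_excluded += n
        elif aa not in ranking.per_aa:
            raise ProfileError(
                f"ranking from {ranking.reference_species!r} lacks family {aa!r} "
                f"present in {counts.source!r}"
            )
        elif codon == ranking.most(aa):
            n_most += n
        elif codon == ranking.least(aa):
            n_least += n
        else:
            n_other += n
    return PreferenceTally(
        source=counts.source,
        n_most=n_most,
        n_least=n_least,
        n_other=n_other,
        n_excluded=n_excluded,
    )


def rounded_percentages(profile: AAConditionalProfile, aa: str) -> dict[str, int]:
    """Family fractions as integer percentages, for report display."""
    return {c: round(100 * f) for c, f in profile.fractions(aa).items()}
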