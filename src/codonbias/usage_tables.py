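"""Genome-wide codon usage tables and per-amino-acid codon preference.

A :class:`CodonUsageTable` holds one species' genome-wide per-codon
abundances (raw counts, per-1000 frequencies, or fractions — downstream
quantities are ratios within synonymous families, so the scale never
matters). Two on-disk dialects are supported: a simple two-column TSV
(``codon<TAB>value``) and the Kazusa/HIVE-CUT block format whose fields look
like ``TTT 17.6 ( 714298)``.

From a table we derive, per amino acid, the distribution over its synonymous
codons (:class:`AAConditionalProfile`) and the most-/least-preferred codon
(:class:`PreferenceRanking`). Stop codons never participate; single-codon
amino acids (Met, Trp under the standard code) are excluded from rankings
because most-vs-least is undefined for a one-member family.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .errors import TableFormatError
from .seqio import GeneticCode, standard_code

logger = logging.getLogger(__name__)

_KAZUSA_FIELD = re.compile(r"([ACGTU]{3})\s+(\d+(?:\.\d+)?)\s*\(\s*(\d+)\s*\)")


@dataclass(frozen=True)
class CodonUsageTable:
    """Genome-wide per-codon abundances for one species."""

    species: str
    values: dict[str, float] = field(repr=False)
    scale: str = "count"

    def __post_init__(self) -> None:
        if len(self.values) != 64:
            raise TableFormatError(
                f"table {self.species!r}: expected 64 codons, got {len(self.values)}"
            )
        if any(v < 0 for v in self.values.values()):
            raise TableFormatError(f"table {self.species!r}: negative abundance")
        if not any(v > 0 for v in self.values.values()):
            raise TableFormatError(f"table {self.species!r}: all abundances zero")


@dataclass(frozen=True)
class AAConditionalProfile:
    """Per amino acid, the fraction of occurrences on each synonymous codon.

    Families with zero observations are absent from ``per_aa`` rather than
    zero-filled, so consumers can distinguish "not observed" from "observed
    never using codon X".
    """

    source: str
    per_aa: dict[str, dict[str, float]] = field(repr=False)

    def amino_acids(self) -> frozenset[str]:
        return frozenset(self.per_aa)

    def fractions(self, aa: str) -> dict[str, float]:
        return self.per_aa[aa]


@dataclass(frozen=True)
class PreferenceRanking:
    """Most- and least-preferred synonymous codon per amino acid."""

    reference_species: str
    per_aa: dict[str, tuple[str, str]] = field(repr=False)
    excluded: frozenset[str] = frozenset()

    def most(self, aa: str) -> str:
        return self.per_aa[aa][0]

    def least(self, aa: str) -> str:
        return self.per_aa[aa][1]


def _normalize_codon(codon: str) -> str:
    return codon.upper().replace("U", "T")


def _infer_scale(values: dict[str, float]) -> str:
    total = sum(values.values())
    if abs(total - 1.0) < 0.05:
        return "fraction"
    if abs(total - 1000.0) < 50.0:
        return "per1000"
    return "count"


def load_usage_table(
    path, dialect: str = "two-column-tsv", species: str | None = None
) -> CodonUsageTable:
    """Load a codon usage table from disk.

    ``dialect="two-column-tsv"`` expects one ``codon<TAB>value`` pair per
    line (``#`` comments allowed); ``"kazusa-block"`` scans free text for
    ``CODON freq ( count )`` fields and keeps the per-1000 frequency. RNA
    codons are normalized to DNA. Duplicated or missing codons are errors.
    """
    with open(path) as handle:
        text = handle.read()
    values: dict[str, float] = {}
    if dialect == "two-column-tsv":
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                parts = line.split()
            if len(parts) != 2:
                raise TableFormatError(f"{path}:{lineno}: expected 'codon value'")
            codon = _normalize_codon(parts[0])
            try:
                value = float(parts[1])
            except ValueError as exc:
                raise TableFormatError(
                    f"{path}:{lineno}: non-numeric value {parts[1]!r}"
                ) from exc
            if codon in values:
                raise TableFormatError(f"{path}:{lineno}: duplicate codon {codon}")
            values[codon] = value
        scale = _infer_scale(values) if values else "count"
    elif dialect == "kazusa-block":
        for match in _KAZUSA_FIELD.finditer(text):
            codon = _normalize_codon(match.group(1))
            if codon in values:
                raise TableFormatError(f"{path}: duplicate codon {codon}")
            values[codon] = float(match.group(2))
        scale = "per1000"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if len(values) != 64:
        raise TableFormatError(
            f"{path}: incomplete table, {len(values)} of 64 codons present"
        )
    name = species if species is not None else str(path)
    return CodonUsageTable(species=name, values=values, scale=scale)


def write_usage_table(path, table: CodonUsageTable) -> None:
    """Write the two-column TSV dialect; float repr round-trips bit-exactly."""
    with open(path, "w") as handle:
        handle.write(f"# codon usage table: {table.species} (scale={table.scale})\n")
        for codon in sorted(table.values):
            handle.write(f"{codon}\t{table.values[codon]!r}\n")


def synonymous_fractions(
    table: CodonUsageTable, code: GeneticCode | None = None
) -> AAConditionalProfile:
    """Normalize a usage table to within-family synonymous fractions.

    For each amino acid, ``fraction(codon) = value(codon) / sum over the
    family``. Stop codons are excluded; a family whose abundances are all
    zero is marked absent. The result is invariant under rescaling of the
    table, so counts, per-1000 frequencies and fractions all give the same
    profile.
    """
    code = code or standard_code()
    per_aa: dict[str, dict[str, float]] = {}
    for aa, family in code.families().items():
        total = sum(table.values[c] for c in family)
        if total <= 0:
            continue
        per_aa[aa] = {c: table.values[c] / total for c in family}
    return AAConditionalProfile(source=table.species, per_aa=per_aa)


def rank_codons(
    table: CodonUsageTable, code: GeneticCode | None = None
) -> PreferenceRanking:
    """Rank each multi-codon family into most- and least-preferred codons.

    Ties are broken lexicographically by codon (and logged); if an entire
    family is tied, the least-preferred pick skips the codon already chosen
    as most-preferred so the two never coincide. Single-codon amino acids
    and stop codons are excluded.
    """
    code = code or standard_code()
    per_aa: dict[str, tuple[str, str]] = {}
    excluded: set[str] = set()
    for aa, family in code.families().items():
        if len(family) < 2:
            excluded.add(aa)
            continue
        vmax = max(table.values[c] for c in family)
        vmin = min(table.values[c] for c in family)
        argmax = [c for c in family if table.values[c] == vmax]
        most = argmax[0]
        argmin = [c for c in family if table.values[c] == vmin and c != most]
        if not argmin:  # whole family tied on a single value
            argmin = [c for c in family if c != most]
        least = argmin[0]
        if len(argmax) > 1 or (vmax == vmin) or len(argmin) > 1:
            logger.info(
                "table %r: tie in family %s resolved lexicographically "
                "(most=%s, least=%s)",
                table.species,
                aa,
                most,
                least,
            )
        per_aa[aa] = (most, least)
    return PreferenceRanking(
        reference_species=table.species,
        per_aa=per_aa,
        excluded=frozenset(excluded),
    )
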