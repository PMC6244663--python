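"""Coding-sequence I/O, codon splitting, translation and protein motif scanning.

Coding sequences are handled strictly in reading frame: a valid CDS has a
length that is a positive multiple of three and, after normalization
(uppercasing, RNA ``U`` mapped to DNA ``T``), an alphabet of ``{A,C,G,T}``.
Translation uses the standard nuclear genetic code (NCBI translation table 1)
by default; the code is a parameter for forward compatibility.

Reported positions are 1-based, following the convention of sequence
annotation; all internal indices are half-open and 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AmbiguityError, FastaError, FrameError, PrematureStopError

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")

#: Translation lookup marker for stop codons.
STOP = "*"


@dataclass(frozen=True)
class CodingSequence:
    """A named nucleotide sequence read in frame.

    Parameters
    ----------
    id : str
        Record label.
    sequence : str
        Nucleotide string, uppercase DNA after normalization.
    species : str, optional
        Species tag used when sequences from several organisms are pooled.
    """

    id: str
    sequence: str
    species: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) == 0 or len(self.sequence) % 3 != 0:
            raise FrameError(
                f"record {self.id!r}: length {len(self.sequence)} is not a "
                "positive multiple of 3"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence over the standard 20-letter alphabet.

    A single terminal ``*`` marking the stop is permitted.
    """

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-codon translation table.

    ``mapping`` sends every codon to a one-letter amino acid or ``*`` (stop).
    """

    mapping: dict[str, str] = field(repr=False)
    id: str = "standard"

    def __post_init__(self) -> None:
        if len(self.mapping) != 64:
            raise ValueError(f"genetic code needs 64 codons, got {len(self.mapping)}")

    def translate_codon(self, codon: str) -> str:
        return self.mapping[codon]

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.mapping.items() if aa == STOP)

    def family(self, aa: str) -> tuple[str, ...]:
        """Synonymous codon family of ``aa``, lexicographically sorted."""
        return tuple(sorted(c for c, a in self.mapping.items() if a == aa))

    def families(self) -> dict[str, tuple[str, ...]]:
        """All amino-acid families (stops excluded), keyed by residue."""
        out: dict[str, list[str]] = {}
        for codon, aa in self.mapping.items():
            if aa != STOP:
                out.setdefault(aa, []).append(codon)
        return {aa: tuple(sorted(cs)) for aa, cs in sorted(out.items())}


def standard_code(table_id: int = 1) -> GeneticCode:
    """Build a :class:`GeneticCode` from an NCBI translation table."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for codon in table.stop_codons:
        mapping[codon] = STOP
    return GeneticCode(mapping=mapping, id=f"ncbi-{table_id}")


def normalize_sequence(raw: str) -> str:
    """Uppercase and map RNA U to DNA T; whitespace is removed."""
    return "".join(raw.split()).upper().replace("U", "T")


def read_cds_fasta(
    path,
    ambiguity_policy: str = "error",
    species: str | None = None,
) -> list[CodingSequence]:
    """Read coding sequences from a FASTA file.

    Records are normalized (uppercase, U->T) and must be in frame. Records
    containing non-ACGT characters raise :class:`AmbiguityError` under
    ``ambiguity_policy="error"``; under ``"skip-codon"`` they are kept and the
    offending codons are dropped later, at counting time, with a log message.
    """
    if ambiguity_policy not in ("error", "skip-codon"):
        raise ValueError(f"unknown ambiguity policy {ambiguity_policy!r}")
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Biopython raises bare ValueError on bad input
        raise FastaError(f"cannot parse {path}: {exc}") from exc
    if not parsed:
        raise FastaError(f"no FASTA records in {path}")
    for rec in parsed:
        seq = normalize_sequence(str(rec.seq))
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise FrameError(
                f"record {rec.id!r}: length {len(seq)} is not a positive "
                "multiple of 3"
            )
        bad = set(seq) - DNA_ALPHABET
        if bad:
            if ambiguity_policy == "error":
                raise AmbiguityError(
                    f"record {rec.id!r}: ambiguous characters {sorted(bad)}"
                )
            logger.warning(
                "record %r: ambiguous characters %s; affected codons will be "
                "skipped in downstream counts",
                rec.id,
                sorted(bad),
            )
        records.append(CodingSequence(id=rec.id, sequence=seq, species=species))
    return records


def write_cds_fasta(path, sequences: list[CodingSequence]) -> None:
    """Write coding sequences as plain FASTA, wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(cds.sequence), id=cds.id, description="") for cds in sequences
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def codons_of(cds: CodingSequence) -> list[str]:
    """Split a CDS into its ordered, non-overlapping codons."""
    seq = cds.sequence
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def translate(
    cds: CodingSequence,
    code: GeneticCode | None = None,
    stop_policy: str = "error-internal",
) -> ProteinSequence:
    """Translate a CDS to protein.

    A terminal stop codon is always stripped. Under
    ``stop_policy="error-internal"`` (default) an internal stop raises
    :class:`PrematureStopError`; under ``"strip-terminal"`` internal stops are
    retained as ``*`` so the caller can inspect them.
    """
    if stop_policy not in ("error-internal", "strip-terminal"):
        raise ValueError(f"unknown stop policy {stop_policy!r}")
    code = code or standard_code()
    codons = codons_of(cds)
    residues = [code.translate_codon(c) for c in codons]
    if residues and residues[-1] == STOP:
        residues.pop()
    if STOP in residues and stop_policy == "error-internal":
        pos = residues.index(STOP) + 1
        raise PrematureStopError(
            f"record {cds.id!r}: internal stop codon at codon position {pos}"
        )
    return ProteinSequence(id=cds.id, residues="".join(residues))


def find_spacing_motif(
    protein: ProteinSequence, residue: str, gaps: list[int]
) -> list[int]:
    """Find all occurrences of a fixed-spacing residue motif.

    The motif places ``len(gaps) + 1`` copies of ``residue`` separated by the
    given numbers of arbitrary intervening residues. ``residue="C"`` with
    ``gaps=[1, 24, 20]`` is the CxCx24Cx20C cysteine arrangement that marks the
    C-terminal cap of a leucine-rich-repeat ectodomain. Returned start
    positions are 1-based; overlapping matches are all reported. A motif
    longer than the protein yields an empty list.
    """
    if any(g < 0 for g in gaps):
        raise ValueError("gaps must be non-negative")
    offsets = [0]
    for g in gaps:
        offsets.append(offsets[-1] + g + 1)
    seq = protein.residues
    span = offsets[-1] + 1
    hits = []
    for start in range(len(seq) - span + 1):
        if all(seq[start + off] == residue for off in offsets):
            hits.append(start + 1)
    return hits
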