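"""Synthetic coding sequences, genome tables and multi-species gene families.

Generates inputs with controlled codon-usage structure so every stage of the
pipeline can be exercised at desk scale without any downloads:

* a packaged "vertebrate-like" genome-wide usage table in which CTG is the
  most abundant leucine codon and CTA/TTA the least abundant — the pattern
  conserved across human, bird and reptile genomes;
* gene-level leucine codon distributions modeled on the two poles seen in
  real receptor genes: a "gaga-like" distribution dominated by the preferred
  CTG (34%, TTA 11%) and a "crpo-like" distribution biased toward the
  unpreferred TTA (25%, CTG 17%);
* a multinomial CDS sampler (codons drawn independently per residue from the
  residue's synonymous distribution) and a Dirichlet mechanism that spreads
  per-species gene distributions around a shared base with a single
  divergence knob.

The divergence parameter ``delta`` controls the Dirichlet concentration as
``alpha = base / delta``: ``delta = 0`` collapses all species onto the base
distribution, larger ``delta`` spreads them further apart. All randomness
flows through one explicitly seeded NumPy generator; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import ProfileError
from .seqio import CodingSequence, GeneticCode, ProteinSequence, standard_code
from .usage_tables import AAConditionalProfile, CodonUsageTable, load_usage_table

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Leucine fraction mirroring its dominance in leucine-rich-repeat receptors.
DEFAULT_LEU_FRACTION = 0.13

GAGA_LIKE_LEU = {
    "CTG": 0.34,
    "TTA": 0.11,
    "TTG": 0.1375,
    "CTT": 0.1375,
    "CTC": 0.1375,
    "CTA": 0.1375,
}

CRPO_LIKE_LEU = {
    "CTG": 0.17,
    "TTA": 0.25,
    "TTG": 0.145,
    "CTT": 0.145,
    "CTC": 0.145,
    "CTA": 0.145,
}


def default_aa_composition() -> dict[str, float]:
    """Leucine-enriched amino-acid composition (~13% L, rest uniform)."""
    rest = (1.0 - DEFAULT_LEU_FRACTION) / (len(AMINO_ACIDS) - 1)
    return {aa: (DEFAULT_LEU_FRACTION if aa == "L" else rest) for aa in AMINO_ACIDS}


def human_like_table() -> CodonUsageTable:
    """The packaged synthetic human-like genome-wide usage table."""
    path = resources.files("codonbias.data") / "human_like_synthetic.tsv"
    with resources.as_file(path) as p:
        return load_usage_table(p, dialect="two-column-tsv", species="human-like")


def vertebrate_like_profile(code: GeneticCode | None = None) -> AAConditionalProfile:
    """Genome-wide conditional profile of the packaged vertebrate-style table."""
    from .usage_tables import synonymous_fractions

    return synonymous_fractions(human_like_table(), code or standard_code())


def _with_leucine(
    base: AAConditionalProfile, leu: dict[str, float], source: str
) -> AAConditionalProfile:
    per_aa = {aa: dict(d) for aa, d in base.per_aa.items()}
    per_aa["L"] = dict(leu)
    return AAConditionalProfile(source=source, per_aa=per_aa)


def gaga_like_profile(code: GeneticCode | None = None) -> AAConditionalProfile:
    """Gene-style profile with preferred-codon-dominated leucine usage."""
    return _with_leucine(vertebrate_like_profile(code), GAGA_LIKE_LEU, "gaga-like")


def crpo_like_profile(code: GeneticCode | None = None) -> AAConditionalProfile:
    """Gene-style profile biased toward unpreferred codons.

    In every multi-codon family the fractions of the genome's most- and
    least-preferred codons are swapped, emulating a gene enriched for
    infrequently used codons; the leucine distribution is set to the
    crpo-style values (CTG 17%, TTA 25%).
    """
    base = vertebrate_like_profile(code)
    per_aa = {}
    for aa, dist in base.per_aa.items():
        d = dict(dist)
        if len(d) > 1:
            most = min(c for c in d if d[c] == max(d.values()))
            least = min(c for c in d if d[c] == min(d.values()))
            if most != least:
                d[most], d[least] = d[least], d[most]
        per_aa[aa] = d
    per_aa["L"] = dict(CRPO_LIKE_LEU)
    return AAConditionalProfile(source="crpo-like", per_aa=per_aa)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a simulated multi-species gene family.

    ``divergence`` is the Dirichlet spread of per-species leucine
    distributions around the base profile (0 = identical species);
    ``aa_composition`` fixes the protein composition of the simulated genes.
    """

    n_codons: int = 600
    species: tuple[str, ...] = ("sp1", "sp2", "sp3", "sp4")
    aa_composition: dict[str, float] = field(default_factory=default_aa_composition)
    per_species_leu_dist: dict[str, dict[str, float]] | None = None
    divergence: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.aa_composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"aa_composition sums to {total}, expected 1")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.n_codons < 1:
            raise ValueError("n_codons must be positive")


def random_protein(
    n_residues: int,
    aa_composition: dict[str, float] | None = None,
    seed: int | np.random.Generator | None = None,
    id: str = "synthetic-protein",
) -> ProteinSequence:
    """Draw an i.i.d. protein sequence from an amino-acid composition."""
    comp = aa_composition or default_aa_composition()
    rng = np.random.default_rng(seed)
    aas = sorted(comp)
    probs = np.array([comp[a] for a in aas])
    probs = probs / probs.sum()
    idx = rng.choice(len(aas), size=n_residues, p=probs)
    return ProteinSequence(id=id, residues="".join(aas[i] for i in idx))


def simulate_cds(
    protein: ProteinSequence,
    codon_dists: AAConditionalProfile,
    seed: int | np.random.Generator | None = None,
    append_stop: bool = True,
) -> CodingSequence:
    """Back-translate a protein by sampling codons per residue.

    Codons are drawn independently for each residue from that residue's
    synonymous distribution in ``codon_dists``. A TAA stop codon is appended
    by default. The translation of the output always equals ``protein``.
    """
    rng = np.random.default_rng(seed)
    residues = [aa for aa in protein.residues if aa != "*"]
    missing = set(residues) - set(codon_dists.per_aa)
    if missing:
        raise ProfileError(
            f"codon distributions {codon_dists.source!r} lack amino acids "
            f"{sorted(missing)}"
        )
    codons = [""] * len(residues)
    by_aa: dict[str, list[int]] = {}
    for i, aa in enumerate(residues):
        by_aa.setdefault(aa, []).append(i)
    for aa in sorted(by_aa):  # fixed order keeps draws reproducible
        positions = by_aa[aa]
        dist = codon_dists.fractions(aa)
        family = sorted(dist)
        probs = np.array([dist[c] for c in family])
        probs = probs / probs.sum()
        draws = rng.choice(len(family), size=len(positions), p=probs)
        for pos, k in zip(positions, draws):
            codons[pos] = family[int(k)]
    if append_stop:
        codons.append("TAA")
    return CodingSequence(id=f"{protein.id}|cds", sequence="".join(codons))


def simulate_genome_table(
    base_profile: AAConditionalProfile,
    total_per1000: float = 1000.0,
    seed: int | np.random.Generator | None = None,
    mode: str = "deterministic",
    aa_weights: dict[str, float] | None = None,
    species: str = "synthetic-genome",
    code: GeneticCode | None = None,
) -> CodonUsageTable:
    """Build a genome-wide usage table whose synonymous fractions match
    ``base_profile``.

    ``deterministic`` assigns each codon ``weight(aa) * fraction(codon|aa)``
    rescaled to ``total_per1000``, so normalizing the table recovers the base
    profile to machine precision. ``sampled`` draws a multinomial of
    ``round(total_per1000)`` codon observations from the same probabilities,
    recovering it within multinomial noise. Amino-acid weights default to the
    leucine-enriched composition; stop codons get zero abundance (they never
    enter profiles or rankings).
    """
    if mode not in ("deterministic", "sampled"):
        raise ValueError(f"unknown mode {mode!r}")
    code = code or standard_code()
    weights = aa_weights or default_aa_composition()
    values = {codon: 0.0 for codon in code.mapping}
    probs = {}
    for aa, dist in base_profile.per_aa.items():
        w = weights.get(aa, 0.0)
        for codon, frac in dist.items():
            probs[codon] = w * frac
    total_p = sum(probs.values())
    if total_p <= 0:
        raise ValueError("base profile and weights give zero total mass")
    if mode == "deterministic":
        for codon, p in probs.items():
            values[codon] = total_per1000 * p / total_p
    else:
        rng = np.random.default_rng(seed)
        codons = sorted(probs)
        pvec = np.array([probs[c] for c in codons])
        draws = rng.multinomial(int(round(total_per1000)), pvec / pvec.sum())
        for codon, n in zip(codons, draws):
            values[codon] = float(n)
    return CodonUsageTable(species=species, values=values, scale="per1000")


def simulate_family(
    spec: SyntheticSpec,
    base_profile: AAConditionalProfile | None = None,
    code: GeneticCode | None = None,
) -> tuple[dict[str, CodingSequence], dict[str, CodonUsageTable]]:
    """Simulate a gene family across species plus per-species genome tables.

    One protein of ``spec.n_codons`` residues is drawn from
    ``spec.aa_composition`` and shared by all species, so any codon-usage
    difference between the simulated genes reflects the per-species codon
    distributions alone. Each species' leucine distribution is either taken
    from ``spec.per_species_leu_dist`` or drawn from a Dirichlet centered on
    the base profile's leucine distribution with concentration
    ``1/divergence`` (``divergence = 0`` leaves every species on the base).
    Genome tables are built deterministically from the shared base profile,
    emulating the conservation of genome-wide codon usage across species.
    """
    if len(spec.species) < 2:
        raise ValueError("a family needs at least 2 species")
    code = code or standard_code()
    base = base_profile or vertebrate_like_profile(code)
    root = np.random.SeedSequence(spec.seed)
    protein_seed, *species_seeds = root.spawn(1 + len(spec.species))
    protein = random_protein(
        spec.n_codons,
        spec.aa_composition,
        seed=np.random.default_rng(protein_seed),
        id=f"family-{spec.seed}",
    )
    leu_family = sorted(base.per_aa["L"])
    base_leu = np.array([base.per_aa["L"][c] for c in leu_family])

    genes: dict[str, CodingSequence] = {}
    tables: dict[str, CodonUsageTable] = {}
    for sp, sseq in zip(spec.species, species_seeds):
        rng = np.random.default_rng(sseq)
        if spec.per_species_leu_dist is not None:
            leu = dict(spec.per_species_leu_dist[sp])
        elif spec.divergence == 0:
            leu = {c: float(p) for c, p in zip(leu_family, base_leu)}
        else:
            alpha = np.maximum(base_leu / spec.divergence, 1e-6)
            drawn = rng.dirichlet(alpha)
            leu = {c: float(p) for c, p in zip(leu_family, drawn)}
        profile = _with_leucine(base, leu, source=f"{sp}-gene-dist")
        cds = simulate_cds(protein, profile, seed=rng)
        genes[sp] = CodingSequence(id=f"{sp}|{protein.id}", sequence=cds.sequence,
                                   species=sp)
        tables[sp] = simulate_genome_table(
            base, mode="deterministic", species=sp, code=code
        )
    return genes, tables
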