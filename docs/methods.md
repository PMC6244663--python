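# Methods

## Model and procedure

The package treats a coding sequence as an ordered list of in-frame codons
and all codon-usage quantities as conditional distributions: for each amino
acid, the fraction of its occurrences carried by each synonymous codon.
Conditioning within families makes every statistic invariant to amino-acid
composition and to the scale of the input table (raw counts, per-1000
frequencies and fractions give identical profiles), which is what allows a
single gene to be compared against a genome-wide table.

Preference is defined per family from a reference table: the codon with the
largest abundance is most-preferred, the smallest least-preferred. The
preference tally classifies codon *occurrences* (not distinct codon types),
so a gene's tally partitions its amino-acid codon total into
most / least / other / excluded. Met and Trp are excluded because a
one-member family has no most-vs-least distinction; stop codons never enter
profiles, rankings or tallies. Ties in a ranking are broken
lexicographically by codon and logged; in a fully tied family the
least-preferred pick skips the codon already chosen as most-preferred so the
two are always distinct (relevant only for degenerate inputs such as uniform
tables).

Cross-species variability of a gene family is the mean Jensen–Shannon
divergence (base 2) over all unordered species pairs, computed per
amino-acid family and averaged with equal weight over the chosen subset
(default `{L}`). JSD was chosen over alternatives because it is symmetric,
bounded in [0, 1] in base 2, zero exactly at equality, and finite when a
codon has zero probability in one gene — all of which χ²-style or
Kullback–Leibler measures lack. Equal weighting across amino acids (rather
than count-weighting) keeps the statistic independent of protein
composition; count-weighting would let abundant residues dominate. The
"excess" subtracts the same statistic computed on the species' genome-wide
baselines, isolating gene-family variability from genome-level divergence.
This divergence statistic is this package's formalization of a comparison
that is usually made visually from bar charts; it is a design choice, and
other bounded divergences would order strongly contrasting families the
same way.

Codon optimization has two modes. `max` substitutes every codon by the
target's most-preferred synonymous codon: deterministic, idempotent, and the
strongest possible shift (100% of leucines on CTG for any vertebrate-style
table, above the ≥95% level commercial vendors reach; vendors keep a few
percent of secondary codons for synthesis-related reasons this package does
not model). `sampled` draws each codon from the target's synonymous
fractions, harmonizing the gene to genome-wide usage. Both preserve the
protein exactly and leave the stop codon untouched. Restriction-site
avoidance, GC windowing and mRNA-structure terms are out of scope.

## Synthetic data generator

The generator emulates the statistical structure of a gene family whose
members encode (nearly) the same protein with species-specific codon usage
over a conserved genome baseline:

- **Protein composition** — i.i.d. residues, by default leucine-enriched at
  13%, mirroring leucine's dominance in leucine-rich-repeat receptors; the
  remaining mass is uniform over the other 19 residues.
- **CDS sampling** — codons drawn independently per residue from the
  residue's synonymous distribution (a product-multinomial). One protein is
  shared by all species of a family so that codon usage is the only
  difference between the simulated genes.
- **Genome tables** — constructed from a base conditional profile and
  amino-acid weights, either deterministically (normalizing the table
  recovers the base profile to machine precision) or by a multinomial draw.
  Stop codons receive zero abundance; they play no role downstream.
- **Cross-species spread** — per-species leucine distributions are drawn
  from a Dirichlet centered on the base profile with concentration
  `base / delta`; `delta = 0` collapses all species onto the base, larger
  values spread them apart. This is the minimal generative mechanism that
  supports a variable-vs-conserved family contrast; it does not model
  mutation, selection or phylogenetic correlation, so passing tests show the
  pipeline's statistics behave correctly under controlled codon-usage
  structure, not that any real family evolved this way.

Packaged fixtures: a synthetic human-like per-1000 usage table
(`data/human_like_synthetic.tsv`) with the vertebrate genome-wide structure
(CTG the most abundant leucine codon, CTA/TTA the least); a "gaga-like"
gene-style leucine distribution (CTG 34%, TTA 11%, remainder uniform) and a
"crpo-like" one (CTG 17%, TTA 25%, remainder uniform). The crpo-like *gene
profile* additionally swaps the most- and least-preferred fractions of the
base profile in every other multi-codon family: a gene biased toward
unpreferred codons only in leucine would still tally more most- than
least-frequent codons overall, because the other 17 multi-codon families
would keep genome-preferred usage; the swap makes the fixture an
unpreferred-biased gene overall, which is the phenomenon the fixture exists
to emulate.

All randomness flows through one explicitly seeded NumPy generator
(`default_rng`); multi-species simulations spawn independent child streams
per species from a `SeedSequence`, so results are reproducible and
insensitive to species order.

## Numerical choices and problem sizes

- JSD is computed via `scipy.spatial.distance.jensenshannon` (squared, since
  SciPy returns the distance) and clipped to 1 against rounding overshoot.
- Profile fractions sum to 1 within 1e-9 per family; the deterministic
  genome-table inverse is verified at 1e-12.
- Report percentages are rounded to the nearest integer to match how such
  tallies are usually quoted; full precision is kept internally.
- Families observed fewer than 10 times in a gene trigger a log warning
  (small-sample fractions are noisy); the threshold is configurable.
- Test problem sizes: oracle-equivalence checks run 100–200 seeded random
  instances per operation; parameter-recovery and sampled-mode convergence
  use 10,000 leucine codons (binomial 3–4σ tolerances); the
  divergence-monotonicity check uses 20 replicates of 4-species families at
  600 codons per level. These sizes put multinomial noise well below the
  effects being tested while keeping the suite fast.

## Input handling

FASTA records are uppercased and RNA `U` is mapped to `T` (GenBank dumps
vary); out-of-frame records are rejected by name. Ambiguous bases error by
default; the `skip-codon` policy instead keeps the record and drops affected
codons from counts, logged. Translation uses NCBI table 1; a terminal stop
is always stripped and internal stops error by default. Usage tables parse
from a two-column TSV (bit-exact round trip) or from Kazusa/HIVE-CUT-style
blocks (`TTT 17.6 ( 714298)`, per-1000 value kept); both require all 64
codons and reject duplicates.

## Known limitations

- The variability statistic ignores phylogeny: closely related species
  count like distant ones in the pairwise mean.
- No statistical tests accompany tallies or divergences; the package
  reports descriptive quantities only.
- Codon-adaptation indices (CAI, Nc, GC3) and tRNA-adaptation measures are
  not implemented.
- The generator's i.i.d. codon draws cannot produce autocorrelated codon
  usage along a gene, and its genome tables contain no stop-codon counts.
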