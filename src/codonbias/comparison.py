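"""Divergence between codon profiles and cross-species family variability.

The question this module answers: does a gene family use
synonymous codons more variably across species than the species' genomes do?
The statistic is the mean pairwise Jensen-Shannon divergence (base 2) of the
per-amino-acid conditional codon distributions, averaged with equal weight
over a chosen amino-acid subset (default: leucine, the six-codon family that
dominates leucine-rich-repeat proteins). JSD base 2 is symmetric, zero iff
the distributions coincide, bounded by 1 per family, and well-defined when a
codon has zero probability — properties a bar-chart comparison lacks. The
family-level "excess" is the gene mean minus the genome-baseline mean over
the same species pairs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import jensenshannon

from .errors import ProfileError
from .usage_tables import AAConditionalProfile

logger = logging.getLogger(__name__)

DEFAULT_AA_SUBSET = frozenset({"L"})


@dataclass(frozen=True)
class DivergenceResult:
    """Jensen-Shannon divergence between two conditional codon profiles."""

    pair: tuple[str, str]
    amino_acids: frozenset[str]
    value: float  # bits, in [0, 1]


@dataclass(frozen=True)
class FamilyVariabilitySummary:
    """Cross-species variability of one gene family vs genome baselines."""

    family: str
    species: tuple[str, ...]
    per_pair: dict[tuple[str, str], float] = field(repr=False)
    mean_pairwise: float = 0.0
    baseline_mean_pairwise: float = 0.0

    @property
    def excess(self) -> float:
        """Gene-level variability above the genome-wide baseline, in bits."""
        return self.mean_pairwise - self.baseline_mean_pairwise


def _family_jsd(p: dict[str, float], q: dict[str, float]) -> float:
    codons = sorted(set(p) | set(q))
    pv = np.array([p.get(c, 0.0) for c in codons])
    qv = np.array([q.get(c, 0.0) for c in codons])
    # scipy returns the JS *distance* (square root of the divergence)
    d = jensenshannon(pv, qv, base=2)
    if math.isnan(d):  # identical zero vectors cannot occur for valid profiles
        return 0.0
    return min(float(d) ** 2, 1.0)


def profile_divergence(
    p: AAConditionalProfile,
    q: AAConditionalProfile,
    aa_subset: frozenset[str] = DEFAULT_AA_SUBSET,
    method: str = "jsd",
) -> DivergenceResult:
    """Jensen-Shannon divergence (base 2) between two profiles.

    Computed per amino-acid family and averaged with equal weight over
    ``aa_subset``. Symmetric in its arguments; 0 iff the distributions agree
    on the subset; at most 1.
    """
    if method != "jsd":
        raise ValueError(f"unknown divergence method {method!r}")
    if not aa_subset:
        raise ValueError("aa_subset must be non-empty")
    values = []
    for aa in sorted(aa_subset):
        for prof in (p, q):
            if aa not in prof.per_aa:
                raise ProfileError(
                    f"profile {prof.source!r} has no observations for "
                    f"amino acid {aa!r}"
                )
        values.append(_family_jsd(p.fractions(aa), q.fractions(aa)))
    return DivergenceResult(
        pair=(p.source, q.source),
        amino_acids=frozenset(aa_subset),
        value=float(np.mean(values)),
    )


def family_variability(
    profiles: dict[str, AAConditionalProfile],
    baselines: dict[str, AAConditionalProfile],
    aa_subset: frozenset[str] = DEFAULT_AA_SUBSET,
    family: str = "gene-family",
) -> FamilyVariabilitySummary:
    """Mean pairwise divergence of a gene family across species.

    ``profiles`` maps species to the gene-level profile, ``baselines`` to the
    species' genome-wide profile; both must cover the same species, at least
    two. The summary reports the mean over all unordered species pairs for
    genes and baselines; the difference (``excess``) is the family's
    variability beyond what the genomes themselves show. Invariant under
    permutation of species order.
    """
    species = tuple(sorted(profiles))
    if len(species) < 2:
        raise ValueError("family variability needs at least 2 species")
    missing = set(species) - set(baselines)
    if missing:
        raise ValueError(f"baselines missing for species: {sorted(missing)}")
    per_pair: dict[tuple[str, str], float] = {}
    baseline_values = []
    for a, b in itertools.combinations(species, 2):
        per_pair[(a, b)] = profile_divergence(
            profiles[a], profiles[b], aa_subset
        ).value
        baseline_values.append(
            profile_divergence(baselines[a], baselines[b], aa_subset).value
        )
    return FamilyVariabilitySummary(
        family=family,
        species=species,
        per_pair=per_pair,
        mean_pairwise=float(np.mean(list(per_pair.values()))),
        baseline_mean_pairwise=float(np.mean(baseline_values)),
    )
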