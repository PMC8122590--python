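"""Multi-species family-count matrices and comparative set algebra.

The census operates on a families × species matrix of per-gene TF counts
(one TF = one gene). "Presence" of a family in a species means count > 0;
all shared/exclusive/Venn operations work on presence at family level.
Superfamily membership is carried as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd


class LookupError_(KeyError):
    """Unknown family or species name."""


@dataclass
class FamilyCountMatrix:
    """Non-negative integer counts of TF genes per (family, species)."""

    counts: pd.DataFrame
    superfamily: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if self.counts.index.duplicated().any() or self.counts.columns.duplicated().any():
            raise ValueError("family and species names must be unique")

    @property
    def families(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    def _check_species(self, *names: str) -> None:
        unknown = [s for s in names if s not in self.counts.columns]
        if unknown:
            raise LookupError_(f"unknown species: {unknown}")

    def _check_family(self, family: str) -> None:
        if family not in self.counts.index:
            raise LookupError_(f"unknown family: {family}")


def build_count_matrix(
    assignments_per_species: Mapping[str, Iterable],
    all_families: Sequence[str] | None = None,
    superfamily: Mapping[str, str] | None = None,
) -> FamilyCountMatrix:
    """Cross-tabulate TF assignments into a families × species count matrix.

    ``all_families`` (typically the rule set's family list) forces zero rows
    for families with no member anywhere.
    """
    species = list(assignments_per_species)
    fams: list[str] = list(all_families) if all_families else []
    seen = set(fams)
    tallies: dict[str, dict[str, int]] = {s: {} for s in species}
    for s, assignments in assignments_per_species.items():
        for a in assignments:
            tallies[s][a.family] = tallies[s].get(a.family, 0) + 1
            if a.family not in seen:
                seen.add(a.family)
                fams.append(a.family)
    counts = pd.DataFrame(0, index=fams, columns=species, dtype=int)
    for s in species:
        for fam, n in tallies[s].items():
            counts.loc[fam, s] = n
    sf = pd.Series({f: (superfamily or {}).get(f, "") for f in fams}) if superfamily else None
    return FamilyCountMatrix(counts, superfamily=sf)


def total_tfs(matrix: FamilyCountMatrix, species: str) -> int:
    """Column sum: total TF genes of a species."""
    matrix._check_species(species)
    return int(matrix.counts[species].sum())


def total_families(matrix: FamilyCountMatrix, species: str) -> int:
    """Number of families with at least one member in the species."""
    matrix._check_species(species)
    return int((matrix.counts[species] > 0).sum())


def present_families(matrix: FamilyCountMatrix, species: str) -> set[str]:
    matrix._check_species(species)
    col = matrix.counts[species]
    return set(col.index[col > 0])


def shared_families(matrix: FamilyCountMatrix, species_subset: Iterable[str]) -> set[str]:
    """Families present (count > 0) in every species of the subset."""
    subset = list(species_subset)
    if not subset:
        raise ValueError("species subset must be non-empty")
    matrix._check_species(*subset)
    shared = present_families(matrix, subset[0])
    for s in subset[1:]:
        shared &= present_families(matrix, s)
    return shared


def exclusive_shared(
    matrix: FamilyCountMatrix, group_a: Iterable[str], group_b: Iterable[str]
) -> tuple[set[str], set[str], set[str]]:
    """Families shared within each species group, split into the common part
    and the parts exclusive to one group."""
    sa = shared_families(matrix, group_a)
    sb = shared_families(matrix, group_b)
    return sa & sb, sa - sb, sb - sa


def family_expansion(
    matrix: FamilyCountMatrix, family: str, species_a: str, species_b: str
) -> int:
    """Signed count difference count(family, a) − count(family, b)."""
    matrix._check_family(family)
    matrix._check_species(species_a, species_b)
    return int(matrix.counts.loc[family, species_a] - matrix.counts.loc[family, species_b])


def family_fraction(matrix: FamilyCountMatrix, family: str, species: str) -> float:
    """Family share of the species' TFs, in percent rounded half-up to 2 dp."""
    matrix._check_family(family)
    total = total_tfs(matrix, species)
    if total == 0:
        raise ZeroDivisionError(f"no TFs counted for {species}")
    frac = Fraction(100 * int(matrix.counts.loc[family, species]), total)
    exact = Decimal(frac.numerator) / Decimal(frac.denominator)
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def extremal_family_species(
    matrix: FamilyCountMatrix, family: str, species_subset: Iterable[str]
) -> tuple[set[str], set[str]]:
    """Species attaining the max / min count of a family within a subset
    (returned as sets so ties stay visible)."""
    subset = list(species_subset)
    if not subset:
        raise ValueError("species subset must be non-empty")
    matrix._check_family(family)
    matrix._check_species(*subset)
    row = matrix.counts.loc[family, subset]
    return set(row.index[row == row.max()]), set(row.index[row == row.min()])


def orphan_families(matrix: FamilyCountMatrix, species: str) -> set[str]:
    """Families with exactly one member gene in the species."""
    matrix._check_species(species)
    col = matrix.counts[species]
    return set(col.index[col == 1])


def venn_regions(
    matrix: FamilyCountMatrix, species_subset: Sequence[str]
) -> dict[frozenset[str], set[str]]:
    """Disjoint Venn regions over family presence for k species: region key =
    the exact set of subset species a family is present in (non-empty keys
    only). Regions partition the union of present-family sets."""
    subset = list(species_subset)
    matrix._check_species(*subset)
    pres = {s: present_families(matrix, s) for s in subset}
    regions: dict[frozenset[str], set[str]] = {}
    for k in range(1, len(subset) + 1):
        for combo in combinations(subset, k):
            key = frozenset(combo)
            members = set.intersection(*(pres[s] for s in combo))
            for s in subset:
                if s not in key:
                    members = members - pres[s]
            if members:
                regions[key] = members
    return regions
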