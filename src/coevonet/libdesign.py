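"""Degenerate-codon design for combinatorial mutant libraries.

Network positions selected for mutagenesis are randomised to a small set
of amino acids — typically the most frequent residues at that position
across the super-family.  Each target set is encoded by a minimal set of
degenerate codons (IUPAC nucleotide ambiguity codes) whose combined
translation equals the target exactly: no off-target amino acids and no
stop codons.  Library size is the full factorial over the jointly
randomised position group plus the sum over independently randomised
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Data.IUPACData import ambiguous_dna_values

from .errors import InfeasibleDesignError
from .msa import AMINO_ACIDS, ResidueDistribution

_TABLE = unambiguous_dna_by_id[1]  # the standard genetic code
_IUPAC = {k: v for k, v in ambiguous_dna_values.items() if k != "U"}
IUPAC_CODES = "".join(sorted(_IUPAC))  # ABCDGHKMNRSTVWY


@dataclass(frozen=True)
class CodonExpansion:
    """Joint translation of a set of degenerate codons."""

    amino_acids: frozenset[str]
    contains_stop: bool


@dataclass(frozen=True)
class PositionDesign:
    """Codon design at one core position."""

    position: int
    target: frozenset[str]
    codons: tuple[str, ...]
    encoded: frozenset[str]
    wild_type: str | None = None

    @property
    def size(self) -> int:
        return len(self.encoded)


@dataclass
class LibraryDesign:
    """A combinatorial (joint) block plus independently randomised positions."""

    joint: list[PositionDesign] = field(default_factory=list)
    independent: list[PositionDesign] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, designs in (("joint", self.joint), ("independent", self.independent)):
            for d in designs:
                rows.append(
                    (
                        d.position,
                        group,
                        "/".join(d.codons),
                        ",".join(sorted(d.encoded)),
                        d.wild_type or "",
                    )
                )
        return pd.DataFrame(
            rows, columns=["position", "group", "codons", "encoded_aas", "wild_type"]
        )


def _expand_one(codon: str) -> tuple[set[str], bool]:
    """Amino acids and stop flag for one degenerate codon."""
    if len(codon) != 3 or any(c not in _IUPAC for c in codon):
        raise ValueError(f"invalid IUPAC codon {codon!r}")
    aas: set[str] = set()
    stop = False
    for triplet in ("".join(t) for t in product(*(_IUPAC[c] for c in codon))):
        if triplet in _TABLE.stop_codons:
            stop = True
        else:
            aas.add(_TABLE.forward_table[triplet])
    return aas, stop


_ALL_CODONS: list[tuple[str, frozenset[str], bool]] | None = None


def _all_codons() -> list[tuple[str, frozenset[str], bool]]:
    """All 15^3 degenerate codons with their expansions, computed once."""
    global _ALL_CODONS
    if _ALL_CODONS is None:
        _ALL_CODONS = []
        for codon in ("".join(c) for c in product(IUPAC_CODES, repeat=3)):
            aas, stop = _expand_one(codon)
            _ALL_CODONS.append((codon, frozenset(aas), stop))
    return _ALL_CODONS


def expand_codons(codons: Iterable[str]) -> CodonExpansion:
    """Union of the translations of a list of degenerate codons."""
    aas: set[str] = set()
    stop = False
    for codon in codons:
        a, s = _expand_one(codon.upper())
        aas |= a
        stop = stop or s
    return CodonExpansion(frozenset(aas), stop)


def top_k_residues(distribution: ResidueDistribution, k: int) -> list[str]:
    """The k most frequent residues at a position, ties alphabetical.

    Returns fewer than k when fewer residue types were observed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not distribution.counts:
        raise ValueError(f"position {distribution.position}: empty distribution")
    ranked = sorted(distribution.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [aa for aa, _ in ranked[:k]]


def _candidate_sets(target: frozenset[str]) -> dict[frozenset[str], str]:
    """Stop-free codons encoding a non-empty subset of the target.

    Returns one codon per distinct encoded set — the lexicographically
    smallest — since any cover can swap in that representative.
    """
    best: dict[frozenset[str], str] = {}
    for codon, aas, stop in _all_codons():
        if stop or not aas or not aas <= target:
            continue
        if aas not in best or codon < best[aas]:
            best[aas] = codon
    return best


def design_codons(
    target: Iterable[str], max_codons: int = 3, allow_superset: bool = False
) -> tuple[str, ...]:
    """Minimum-cardinality degenerate codons encoding the target set exactly.

    Searches all stop-free IUPAC codons whose translation is a subset of
    the target and returns the smallest exact cover (ties: the
    lexicographically smallest codon list).  When no exact cover exists
    within ``max_codons`` an :class:`InfeasibleDesignError` is raised,
    unless ``allow_superset`` is set, in which case a minimal covering
    set possibly encoding extra amino acids is returned.
    """
    target = frozenset(target)
    if not target or not target <= set(AMINO_ACIDS):
        raise ValueError("target must be a non-empty set of standard amino acids")
    if max_codons < 1:
        raise ValueError("max_codons must be >= 1")
    candidates = _candidate_sets(target)
    sets = sorted(candidates, key=lambda s: candidates[s])
    for size in range(1, max_codons + 1):
        solutions = []
        for combo in combinations(sets, size):
            union = frozenset().union(*combo)
            if union == target:
                solutions.append(tuple(sorted(candidates[s] for s in combo)))
        if solutions:
            return min(solutions)
    if allow_superset:
        return _superset_design(target, max_codons)
    raise InfeasibleDesignError(
        f"no exact degenerate-codon cover of {{{','.join(sorted(target))}}} "
        f"within {max_codons} codons"
    )


def _superset_design(target: frozenset[str], max_codons: int) -> tuple[str, ...]:
    """Minimal stop-free cover allowed to encode extra amino acids."""
    best: dict[frozenset[str], str] = {}
    for codon, aas, stop in _all_codons():
        if stop or not aas & target:
            continue
        if aas not in best or codon < best[aas]:
            best[aas] = codon
    sets = sorted(best, key=lambda s: best[s])
    for size in range(1, max_codons + 1):
        solutions = []
        for combo in combinations(sets, size):
            if frozenset().union(*combo) >= target:
                solutions.append(tuple(sorted(best[s] for s in combo)))
        if solutions:
            # smallest extra amino-acid load first, then lexicographic
            def extra(sol):
                return len(expand_codons(sol).amino_acids - target)
            return min(solutions, key=lambda s: (extra(s), s))
    raise InfeasibleDesignError(
        f"no degenerate-codon cover of {{{','.join(sorted(target))}}} "
        f"within {max_codons} codons even allowing extra amino acids"
    )


def design_position(
    position: int,
    target: Iterable[str],
    wild_type: str | None = None,
    max_codons: int = 3,
    allow_superset: bool = False,
) -> PositionDesign:
    """Design codons for one position; warns when wild-type is not encoded."""
    import warnings

    codons = design_codons(target, max_codons, allow_superset)
    encoded = expand_codons(codons).amino_acids
    if wild_type is not None and wild_type not in encoded:
        warnings.warn(
            f"position {position}: wild-type {wild_type} is not encoded by the design",
            stacklevel=2,
        )
    return PositionDesign(position, frozenset(target), codons, encoded, wild_type)


def count_variants(design: LibraryDesign) -> int:
    """Library size: product over the joint block plus sum over singles."""
    if not design.joint and not design.independent:
        raise ValueError("empty library design")
    total = 0
    if design.joint:
        prod = 1
        for d in design.joint:
            prod *= d.size
        total += prod
    total += sum(d.size for d in design.independent)
    return total
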