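"""Degenerate-codon arithmetic for saturation-mutagenesis library design.

An IUPAC degenerate triplet (e.g. VDS = [ACG][AGT][GC]) encodes a set of
concrete codons; sweeping it across a list of positions yields a library
whose size is n_positions x (distinct amino acids encoded).  VDS covers all
amino-acid chemistries while omitting stops, proline and the large
hydrophobics F/W/Y, so fluorescence changes in a screen cannot be blamed on
truncation or gross destabilization.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_dna_values

_STOPS = set(standard_dna_table.stop_codons)


@dataclass(frozen=True)
class CodonExpansion:
    code: str
    n_positions: int
    codons: tuple
    amino_acids: tuple          # distinct, sorted, stops excluded
    stop_present: bool

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    @property
    def n_amino_acids(self) -> int:
        return len(self.amino_acids)

    @property
    def library_size(self) -> int:
        """Distinct amino-acid variants across all positions."""
        return self.n_positions * self.n_amino_acids

    @property
    def codon_variants(self) -> int:
        """Total concrete codon variants across all positions."""
        return self.n_positions * self.n_codons


def expand_degenerate_codon(code: str, n_positions: int = 1) -> CodonExpansion:
    """Enumerate a degenerate triplet and report library arithmetic."""
    code = code.strip().upper()
    if len(code) != 3:
        raise ValueError(f"degenerate codon must have 3 letters, got {code!r}")
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    bases = []
    for letter in code:
        if letter not in ambiguous_dna_values:
            raise ValueError(f"invalid IUPAC letter {letter!r} in {code!r}")
        bases.append(ambiguous_dna_values[letter])
    codons = tuple("".join(triplet) for triplet in product(*bases))
    stop_present = any(c in _STOPS for c in codons)
    amino_acids = tuple(sorted({
        standard_dna_table.forward_table[c] for c in codons if c not in _STOPS
    }))
    return CodonExpansion(code, n_positions, codons, amino_acids, stop_present)
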