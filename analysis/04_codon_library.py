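#!/usr/bin/env python
"""Degenerate-codon library arithmetic for near-saturation mutagenesis.

Expands the VDS triplet used to mutate the 85 solvent-exposed scaffold
positions, alongside common alternatives (NNN, NNK, NDT) for comparison.
Writes results/codon_library.json.
"""

import argparse
import json
from pathlib import Path

from metabolon.codons import expand_degenerate_codon


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--positions", type=int, default=85)
    ap.add_argument("--out", type=Path,
                    default=Path("results/codon_library.json"))
    args = ap.parse_args()

    table = {}
    for code in ("VDS", "NNN", "NNK", "NDT"):
        exp = expand_degenerate_codon(code, args.positions)
        table[code] = {
            "codons": exp.n_codons,
            "amino_acids": exp.n_amino_acids,
            "amino_acid_list": list(exp.amino_acids),
            "stop_codons": exp.stop_present,
            "codon_variants": exp.codon_variants,
            "library_size": exp.library_size,
        }
        print(f"{code}: {exp.n_codons} codons -> {exp.n_amino_acids} amino "
              f"acids{' (stops!)' if exp.stop_present else ''}; library "
              f"{exp.library_size} over {args.positions} positions")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(table, indent=2))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
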