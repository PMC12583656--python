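#!/usr/bin/env python
"""Cluster permutation statistics on the synthetic screen.

Loads the matrices written by 01_simulate_screen.py (regenerating them if
absent), classifies every pair, tests the planted 5-protein cluster against
the 10,000-draw permutation null, tests the TM-selected pair set on the
fluorescence matrix, scores each protein's interaction propensity, and
extracts the strong-interaction graph.  Writes
results/cluster_statistics.json.
"""

import argparse
import json
from pathlib import Path

from metabolon.matrix import PPIMatrix, classify, strong_pair_count, symmetrize
from metabolon.permutation import (PermutationSpec, cluster_permutation_test,
                                   conditional_cross_test, interaction_graph,
                                   protein_propensity_test)
from metabolon.synth import default_cluster_spec, synth_mfi, synth_tm


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--n-perm", type=int, default=10_000)
    ap.add_argument("--screen-dir", type=Path,
                    default=Path("results/synthetic_screen"))
    ap.add_argument("--out", type=Path,
                    default=Path("results/cluster_statistics.json"))
    args = ap.parse_args()

    spec = default_cluster_spec(seed=args.seed)
    mfi_path = args.screen_dir / "mfi_symmetric.tsv"
    if mfi_path.exists():
        matrix = PPIMatrix.read_tsv(mfi_path)
        tm = PPIMatrix.read_tsv(args.screen_dir / "tm_scores.tsv")
    else:
        matrix = symmetrize(synth_mfi(spec), min_cells=spec.min_cells)
        tm = synth_tm(spec, coupling=1.0)

    classes = {"none": 0, "weak": 0, "moderate": 0, "strong": 0}
    for a, b in matrix.offdiagonal_pairs():
        classes[classify(matrix.value(a, b))] += 1

    cluster = list(spec.clusters[0])
    pairs = [(a, b) for i, a in enumerate(cluster) for b in cluster[i + 1:]
             if not matrix.is_missing(a, b)]
    pspec = PermutationSpec(n_perm=args.n_perm, seed=args.seed)
    res_cluster = cluster_permutation_test(matrix, pairs, pspec)
    res_cross = conditional_cross_test(tm, lambda v: v > 0.5, matrix, pspec)
    propensity = {p: protein_propensity_test(matrix, p, pspec).p
                  for p in cluster + ["P20"]}
    graph = interaction_graph(matrix, threshold=1100.0)

    out = {
        "class_counts": classes,
        "strong_pairs_750": strong_pair_count(matrix, 750.0),
        "planted_cluster": {"pairs": len(pairs),
                            "median_mfi": res_cluster.s_obs,
                            "p": res_cluster.p},
        "tm_selected": {"pairs": len(res_cross.pair_set), "p": res_cross.p},
        "propensity_p": propensity,
        "graph": {"components": [c for c in graph.graph["components"]
                                 if len(c) > 1],
                  "core_nodes": graph.graph["core_nodes"]},
    }
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(out, indent=2))
    print(f"planted cluster: median MFI {res_cluster.s_obs:.0f} over "
          f"{len(pairs)} pairs, p = {res_cluster.p:.2g}")
    print(f"TM > 0.5 selection on the fluorescence matrix: p = {res_cross.p:.2g}")
    print(f"strong graph core: {graph.graph['core_nodes']}")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
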