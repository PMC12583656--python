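"""Permutation statistics over PPI / structure-similarity matrices.

The central test asks whether a named set of protein pairs (a putative
pathway cluster) has systematically higher values than the matrix at large.
The null distribution is built by repeatedly drawing an equal number of
distinct non-missing off-diagonal pairs uniformly from the matrix and
recomputing the summary statistic (median by default); the one-sided
empirical p value is

    p = (#(S_null >= S_obs) + 1) / (N + 1)

which is bounded below by 1/(N+1) and above by 1 and needs no
distributional assumption.  Ties are handled by the ">=" comparison itself;
no mid-p correction is applied.

The same machinery drives conditional cross-matrix tests (select pairs on
one matrix, e.g. TM score > 0.5, evaluate the statistic on the other),
per-protein interaction-propensity tests, and the concordance score between
simulation-predicted binders and fluorescence calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy import stats

from .matrix import PPIMatrix

_STATISTICS = {"median": np.median, "mean": np.mean}


@dataclass(frozen=True)
class PermutationSpec:
    statistic: str = "median"
    n_perm: int = 10_000
    seed: int | None = None
    side: str = "greater"
    include_diagonal: bool = False

    def __post_init__(self):
        if self.statistic not in _STATISTICS:
            raise ValueError(f"statistic must be one of {sorted(_STATISTICS)}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.side != "greater":
            raise ValueError("only the one-sided 'greater' alternative is defined")


@dataclass
class PermutationResult:
    s_obs: float
    null_sample: np.ndarray
    p: float
    pair_set: list = field(default_factory=list)
    statistic: str = "median"
    seed: int | None = None

    @property
    def n_perm(self) -> int:
        return len(self.null_sample)

    def to_dict(self) -> dict:
        return {
            "pair_set": [list(p) for p in self.pair_set],
            "statistic": self.statistic,
            "s_obs": float(self.s_obs),
            "n_perm": int(self.n_perm),
            "seed": self.seed,
            "p": float(self.p),
        }


def empirical_p(null_sample: np.ndarray, s_obs: float) -> float:
    """One-sided (greater) empirical p with the +1 correction."""
    null_sample = np.asarray(null_sample, dtype=float)
    n = len(null_sample)
    return (int(np.count_nonzero(null_sample >= s_obs)) + 1) / (n + 1)


def null_pool(matrix: PPIMatrix, include_diagonal: bool = False):
    """Index pairs eligible for null draws: non-missing, unique unordered.

    Diagonal (homo-oligomer) entries are excluded by default because the
    tested clusters are heterodimeric pairs.
    """
    pool = []
    for i in range(matrix.n):
        start = i if include_diagonal else i + 1
        for j in range(start, matrix.n):
            if not matrix.missing[i, j]:
                pool.append((i, j))
    return pool


def _resolve_pairs(matrix: PPIMatrix, pair_set):
    idx = []
    for a, b in pair_set:
        i, j = matrix.index(a), matrix.index(b)
        if matrix.missing[i, j]:
            raise ValueError(f"pair ({a}, {b}) is missing in the matrix")
        idx.append((i, j))
    return idx


def cluster_permutation_test(matrix: PPIMatrix, pair_set,
                             spec: PermutationSpec | None = None) -> PermutationResult:
    """Test whether pair_set values exceed random draws from the matrix."""
    if spec is None:
        spec = PermutationSpec()
    pair_set = list(pair_set)
    if len(pair_set) < 1:
        raise ValueError("pair_set must contain at least one pair")
    idx = _resolve_pairs(matrix, pair_set)
    stat = _STATISTICS[spec.statistic]
    obs_values = np.array([matrix.values[i, j] for i, j in idx])
    s_obs = float(stat(obs_values))

    pool = null_pool(matrix, spec.include_diagonal)
    k = len(idx)
    if k > len(pool):
        raise ValueError(
            f"pair_set size {k} exceeds the {len(pool)} available non-missing pairs"
        )
    pool_values = np.array([matrix.values[i, j] for i, j in pool])
    rng = np.random.default_rng(spec.seed)
    null_sample = np.empty(spec.n_perm)
    for t in range(spec.n_perm):
        draw = rng.choice(len(pool_values), size=k, replace=False)
        null_sample[t] = stat(pool_values[draw])
    return PermutationResult(
        s_obs=s_obs,
        null_sample=null_sample,
        p=empirical_p(null_sample, s_obs),
        pair_set=pair_set,
        statistic=spec.statistic,
        seed=spec.seed,
    )


def conditional_cross_test(select_matrix: PPIMatrix, predicate,
                           value_matrix: PPIMatrix,
                           spec: PermutationSpec | None = None,
                           subset=None) -> PermutationResult:
    """Select pairs by a rule on one matrix, test their values on another.

    ``predicate`` is a callable on a scalar (e.g. ``lambda tm: tm > 0.5``);
    ``subset`` optionally restricts the selection to a protein subset (the
    null pool always remains the whole value matrix).
    """
    if select_matrix.proteins != value_matrix.proteins:
        raise ValueError("matrices must share the protein list")
    allowed = set(subset) if subset is not None else None
    pair_set = []
    for a, b in select_matrix.offdiagonal_pairs():
        if allowed is not None and not (a in allowed and b in allowed):
            continue
        if predicate(select_matrix.value(a, b)) and not value_matrix.is_missing(a, b):
            pair_set.append((a, b))
    if not pair_set:
        raise ValueError("predicate selects no non-missing off-diagonal pair")
    return cluster_permutation_test(value_matrix, pair_set, spec)


def protein_propensity_test(matrix: PPIMatrix, protein: str,
                            spec: PermutationSpec | None = None) -> PermutationResult:
    """Test whether one protein's row dominates the matrix (hub propensity)."""
    i = matrix.index(protein)
    pair_set = []
    for j in range(matrix.n):
        if j != i and not matrix.missing[i, j]:
            a, b = sorted((protein, matrix.proteins[j]))
            pair_set.append((a, b))
    if not pair_set:
        raise ValueError(f"protein {protein!r} has no non-missing off-diagonal entry")
    return cluster_permutation_test(matrix, pair_set, spec)


def welch_two_sample(x, y):
    """Unpaired Welch t test; returns (t, Welch-Satterthwaite df, two-sided p).

    Two degenerate samples with zero variance and equal means return
    (0, nan, 1) by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least two observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, float("nan"), 1.0
        return float(np.sign(np.mean(x) - np.mean(y)) * np.inf), float("nan"), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def interaction_graph(matrix: PPIMatrix, threshold: float) -> nx.Graph:
    """Undirected graph of pairs with value >= threshold (no self-loops).

    Graph attributes: ``components`` (list of node lists) and ``core_nodes``
    (members of at least one clique of size >= 3).
    """
    if not matrix.symmetric:
        raise ValueError("interaction graph requires a symmetric matrix")
    g = nx.Graph()
    g.add_nodes_from(matrix.proteins)
    for a, b in matrix.offdiagonal_pairs():
        if matrix.value(a, b) >= threshold:
            g.add_edge(a, b, weight=matrix.value(a, b))
    components = [sorted(c) for c in nx.connected_components(g)]
    core = sorted({n for clique in nx.find_cliques(g) if len(clique) >= 3 for n in clique})
    g.graph["components"] = components
    g.graph["core_nodes"] = core
    return g


@dataclass(frozen=True)
class ConcordanceSpec:
    """Thresholds pairing simulation binding free energies with MFI calls."""

    dg_threshold: float = -3.0   # kcal/mol; dimers at or below are "stable binders"
    mfi_threshold: float = 670.0

    def __post_init__(self):
        if not (np.isfinite(self.dg_threshold) and np.isfinite(self.mfi_threshold)):
            raise ValueError("thresholds must be finite")


def prediction_concordance(dg_values: dict, matrix: PPIMatrix,
                           spec: ConcordanceSpec | None = None,
                           n_perm: int = 10_000, seed: int | None = None):
    """Fraction of predicted binders confirmed by fluorescence, with p value.

    Pairs with binding free energy <= ``dg_threshold`` are predicted
    binders; a true prediction additionally has MFI > ``mfi_threshold``.
    The null relabels predicted-binder status uniformly over the evaluated
    pairs, holding the number of predicted binders fixed, so both margins'
    counts are preserved.
    """
    if spec is None:
        spec = ConcordanceSpec()
    pairs = list(dg_values)
    mfi = np.array([matrix.value(a, b) for a, b in pairs])
    if any(matrix.is_missing(a, b) for a, b in pairs):
        raise ValueError("all evaluated pairs must be non-missing in the matrix")
    dg = np.array([dg_values[p] for p in pairs])
    binder = dg <= spec.dg_threshold
    n_binders = int(binder.sum())
    if n_binders == 0:
        raise ValueError("no predicted binders at this free-energy threshold")
    confirmed = mfi > spec.mfi_threshold
    fraction = float(confirmed[binder].mean())

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for t in range(n_perm):
        draw = rng.choice(len(pairs), size=n_binders, replace=False)
        null[t] = confirmed[draw].mean()
    return fraction, empirical_p(null, fraction)
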