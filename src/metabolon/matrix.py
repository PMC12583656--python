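"""Protein-protein interaction (PPI) matrices from split-fluorophore assays.

A bimolecular fluorescence complementation (BiFC) screen measures each
protein pair in two fusion orientations (N-half on A / C-half on B, and the
reverse).  Because a fusion can sterically block an interaction in one
orientation only, the working symmetric matrix takes, for every unordered
pair, the maximum mean fluorescence intensity (MFI) over the retained
orientations.  Wells with too few analyzed cells are discarded and the pair
is marked missing.

The :class:`PPIMatrix` container also serves for structure-similarity
(TM-score-like) matrices, which share the same square labelled layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ORIENTATIONS = ("N_A_C_B", "N_B_C_A")

#: Number of analyzed cells below which a well is discarded.
DEFAULT_MIN_CELLS = 10_000


@dataclass(frozen=True)
class OrientedMeasurement:
    """One well of the two-orientation fluorescence screen."""

    protein_a: str
    protein_b: str
    orientation: str
    mfi: float
    n_cells: int = DEFAULT_MIN_CELLS

    def __post_init__(self):
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}"
            )
        if self.mfi < 0:
            raise ValueError(f"mfi must be >= 0, got {self.mfi}")
        if self.n_cells < 0:
            raise ValueError(f"n_cells must be >= 0, got {self.n_cells}")


@dataclass(frozen=True)
class ClassificationScheme:
    """MFI thresholds separating none / weak / moderate / strong calls.

    Boundary values are assigned by half-open intervals [none_below,
    weak_upper), [weak_upper, moderate_upper), [moderate_upper, inf) so that
    every nonnegative MFI maps to exactly one class.
    """

    none_below: float = 750.0
    weak_upper: float = 900.0
    moderate_upper: float = 1100.0

    def __post_init__(self):
        if not (self.none_below < self.weak_upper < self.moderate_upper):
            raise ValueError("thresholds must satisfy none_below < weak_upper < moderate_upper")


def classify(mfi: float, scheme: ClassificationScheme | None = None) -> str:
    """Classify a fluorescence value as none / weak / moderate / strong."""
    if scheme is None:
        scheme = ClassificationScheme()
    if not np.isfinite(mfi) or mfi < 0:
        raise ValueError(f"mfi must be finite and >= 0, got {mfi}")
    if mfi < scheme.none_below:
        return "none"
    if mfi < scheme.weak_upper:
        return "weak"
    if mfi < scheme.moderate_upper:
        return "moderate"
    return "strong"


class PPIMatrix:
    """Square labelled matrix of pairwise values with a missing-entry mask.

    Parameters
    ----------
    proteins
        Ordered protein identifiers (length P).
    values
        P x P float array.  Entries at missing positions are ignored
        (conventionally NaN).
    missing
        P x P boolean mask, True where no measurement exists.  Defaults to
        ``isnan(values)``.
    symmetric
        Declares the matrix symmetric; verified on construction.
    """

    def __init__(self, proteins, values, missing=None, symmetric=True):
        self.proteins = list(proteins)
        values = np.asarray(values, dtype=float)
        p = len(self.proteins)
        if values.shape != (p, p):
            raise ValueError(f"values must be {p}x{p}, got {values.shape}")
        if missing is None:
            missing = np.isnan(values)
        missing = np.asarray(missing, dtype=bool)
        if missing.shape != (p, p):
            raise ValueError("missing mask shape mismatch")
        missing = missing | np.isnan(values)
        self.values = values
        self.missing = missing
        self.symmetric = bool(symmetric)
        self._index = {name: i for i, name in enumerate(self.proteins)}
        if len(self._index) != p:
            raise ValueError("duplicate protein identifiers")
        if self.symmetric:
            if not np.array_equal(missing, missing.T):
                raise ValueError("symmetric matrix has asymmetric missing mask")
            ok = missing | np.isclose(values, values.T, equal_nan=True)
            if not ok.all():
                bad = np.argwhere(~ok)
                raise ValueError(f"matrix flagged symmetric but differs at {bad[:5].tolist()}")
        with np.errstate(invalid="ignore"):
            if np.nanmin(np.where(missing, np.nan, values), initial=0.0) < 0:
                raise ValueError("non-missing values must be >= 0")

    # -- access -----------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.proteins)

    def index(self, protein: str) -> int:
        try:
            return self._index[protein]
        except KeyError:
            raise KeyError(f"unknown protein {protein!r}") from None

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def is_missing(self, a: str, b: str) -> bool:
        return bool(self.missing[self.index(a), self.index(b)])

    def offdiagonal_pairs(self, include_missing=False):
        """Unordered off-diagonal (a, b) label pairs, a before b in order."""
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if include_missing or not self.missing[i, j]:
                    out.append((self.proteins[i], self.proteins[j]))
        return out

    # -- I/O --------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        vals = np.where(self.missing, np.nan, self.values)
        return pd.DataFrame(vals, index=self.proteins, columns=self.proteins)

    def write_tsv(self, path) -> None:
        # %.17g guarantees a value-exact float64 round trip
        self.to_frame().to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, symmetric=True) -> "PPIMatrix":
        if list(frame.index) != list(frame.columns):
            raise ValueError("row and column labels differ")
        return cls(list(frame.index), frame.to_numpy(dtype=float), symmetric=symmetric)

    @classmethod
    def read_tsv(cls, path, symmetric=True) -> "PPIMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                            float_precision="round_trip")
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        return cls.from_frame(frame, symmetric=symmetric)


def symmetrize(measurements, min_cells: int = DEFAULT_MIN_CELLS,
               proteins=None) -> PPIMatrix:
    """Build the symmetric PPI matrix from two-orientation measurements.

    Each unordered pair takes the maximum MFI over orientations whose wells
    analyzed at least ``min_cells`` cells; a pair with no retained
    orientation is marked missing.  Duplicate (pair, orientation) records
    are rejected with a report of the offending rows.
    """
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    seen = {}
    duplicates = []
    for idx, m in enumerate(measurements):
        a, b = sorted((m.protein_a, m.protein_b))
        # orientation is defined relative to the (a, b) sorted pair
        if (m.protein_a, m.protein_b) == (a, b) or a == b:
            orient = m.orientation
        else:
            orient = ORIENTATIONS[1 - ORIENTATIONS.index(m.orientation)]
        key = (a, b, orient)
        if key in seen:
            duplicates.append((seen[key], idx, key))
        else:
            seen[key] = idx
    if duplicates:
        report = "; ".join(
            f"rows {i} and {j} duplicate pair ({k[0]}, {k[1]}) orientation {k[2]}"
            for i, j, k in duplicates[:10]
        )
        raise ValueError(f"duplicate (pair, orientation) records: {report}")

    measurements = list(measurements)
    if proteins is None:
        proteins = sorted({m.protein_a for m in measurements} | {m.protein_b for m in measurements})
    else:
        proteins = list(proteins)
    p = len(proteins)
    idx = {name: i for i, name in enumerate(proteins)}
    values = np.full((p, p), np.nan)
    for m in measurements:
        if m.n_cells < min_cells:
            continue
        i, j = idx[m.protein_a], idx[m.protein_b]
        cur = values[i, j]
        best = m.mfi if np.isnan(cur) else max(cur, m.mfi)
        values[i, j] = best
        values[j, i] = best
    return PPIMatrix(proteins, values, symmetric=True)


def strong_pair_count(matrix: PPIMatrix, threshold: float = 750.0) -> int:
    """Count unordered off-diagonal pairs with value >= threshold."""
    count = 0
    for a, b in matrix.offdiagonal_pairs():
        if matrix.value(a, b) >= threshold:
            count += 1
    return count


def validate_matrix(path, expect_symmetric=True) -> dict:
    """Validate a matrix TSV file; returns a report dict with ``ok`` flag.

    Checks squareness, row/column label consistency, NA coding, value
    nonnegativity, and (when expected) symmetry, listing offending cells.
    """
    report = {"path": str(path), "ok": True, "errors": []}

    def fail(msg):
        report["ok"] = False
        report["errors"].append(msg)

    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    except Exception as exc:  # malformed file
        fail(f"unreadable TSV: {exc}")
        return report
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if frame.shape[0] != frame.shape[1]:
        fail(f"not square: {frame.shape}")
    if list(frame.index) != list(frame.columns):
        fail("row labels differ from column labels")
        return report
    vals = frame.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        bad = np.argwhere(vals < 0)
        fail(f"negative values at {[tuple(map(int, b)) for b in bad[:10]]}")
    if expect_symmetric:
        miss = np.isnan(vals)
        asym = []
        if not np.array_equal(miss, miss.T):
            asym = [tuple(map(int, b)) for b in np.argwhere(miss != miss.T)[:10]]
        ok = miss | np.isclose(vals, vals.T, equal_nan=True)
        asym += [tuple(map(int, b)) for b in np.argwhere(~ok)[:10]]
        if asym:
            fail(f"asymmetric cells: {asym[:10]}")
    report["shape"] = list(frame.shape)
    return report
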