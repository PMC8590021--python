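"""Pentamer-table DNA shape featurization.

Every base pair of a double helix carries six intra-base-pair parameters
(shear, stretch, stagger, buckle, propeller twist, opening), six
inter-base-pair step parameters (shift, slide, rise, tilt, roll, helix
twist) and a minor groove width (MGW).  All thirteen are well approximated
by a lookup on the local pentamer, so a 1024-row query table turns any
sequence window into a positions x 13 shape matrix.  This module loads such
tables (full 1024-row or reverse-complement-collapsed 512-row dialects),
extracts strand-canonicalized windows around motif hits, and flattens the
per-position matrix into a named feature vector for model training.

Conventions: coordinates are 0-based half-open; the two outermost bases on
each side of a window only provide pentamer context, so a window of length
L yields L - 4 feature positions; positions are labelled -b..-1 (upstream
flank), 1..m (motif core) and +1..+b (downstream flank) -- there is no
position 0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Fixed feature order used everywhere in the package.
FEATURE_NAMES: tuple[str, ...] = (
    "MGW",
    "shear",
    "stretch",
    "stagger",
    "buckle",
    "propeller_twist",
    "opening",
    "shift",
    "slide",
    "rise",
    "tilt",
    "roll",
    "helix_twist",
)

#: Parameters whose sign flips under reverse complementation (standard
#: base-pair / base-pair-step sign conventions); the rest are copied.
ODD_FEATURES: frozenset[str] = frozenset({"shear", "buckle", "shift", "tilt"})

INTRA_FEATURES: frozenset[str] = frozenset(
    {"shear", "stretch", "stagger", "buckle", "propeller_twist", "opening"}
)
INTER_FEATURES: frozenset[str] = frozenset(
    {"shift", "slide", "rise", "tilt", "roll", "helix_twist"}
)

#: Pentamer half-width: bases consumed as context at each end of a window.
CONTEXT = 2

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_ALIASES = {
    "mgw": "MGW",
    "minor_groove_width": "MGW",
    "propeller": "propeller_twist",
    "proptw": "propeller_twist",
    "propellertwist": "propeller_twist",
    "helixtwist": "helix_twist",
    "helt": "helix_twist",
    "twist": "helix_twist",
}


class ShapeTableError(ValueError):
    """Raised for malformed shape query tables."""


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a sequence over {A,C,G,T,N}."""
    seq = seq.upper()
    if any(c not in "ACGTN" for c in seq):
        bad = next(c for c in seq if c not in "ACGTN")
        raise ValueError(f"non-DNA character {bad!r} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def _canon_feature(name: str) -> str:
    key = name.strip().strip('"')
    low = key.lower().replace(" ", "_").replace("-", "_")
    if low in _ALIASES:
        return _ALIASES[low]
    for f in FEATURE_NAMES:
        if low == f.lower():
            return f
    raise ShapeTableError(f"unrecognized shape feature column {name!r}")


@dataclass(frozen=True)
class ShapeTable:
    """Pentamer -> 13 shape values lookup.

    ``entries`` maps each of the 1024 ACGT pentamers to a length-13 float
    array ordered as :data:`FEATURE_NAMES`.
    """

    entries: Mapping[str, np.ndarray]
    feature_names: tuple[str, ...] = FEATURE_NAMES
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.entries) != 1024:
            raise ShapeTableError(
                f"shape table has {len(self.entries)} pentamers, expected 1024"
            )
        for p, v in self.entries.items():
            if len(p) != 5 or any(c not in "ACGT" for c in p):
                raise ShapeTableError(f"invalid pentamer key {p!r}")
            if len(v) != 13 or not np.all(np.isfinite(v)):
                raise ShapeTableError(f"pentamer {p!r} lacks 13 finite values")

    def lookup(self, pentamer: str) -> np.ndarray:
        return self.entries[pentamer.upper()]

    def write(self, path: str | Path) -> None:
        """Serialize as a tab-delimited full-dialect table."""
        with open(path, "w") as fh:
            fh.write("pentamer\t" + "\t".join(self.feature_names) + "\n")
            for p in sorted(self.entries):
                vals = "\t".join(repr(float(x)) for x in self.entries[p])
                fh.write(f"{p}\t{vals}\n")


def expand_collapsed(rows: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Expand a revcomp-collapsed (512-row) table to all 1024 pentamers.

    The reverse-complement pentamer keeps even-symmetry values and flips the
    sign of shear, buckle, shift and tilt.
    """
    sign = np.array([-1.0 if f in ODD_FEATURES else 1.0 for f in FEATURE_NAMES])
    out: dict[str, np.ndarray] = {}
    for p, v in rows.items():
        rc = reverse_complement(p)
        for key, val in ((p, v), (rc, v * sign)):
            if key in out and not np.allclose(out[key], val):
                raise ShapeTableError(
                    f"conflicting values for pentamer {key} during expansion"
                )
            out[key] = val
    return out


def read_shape_table(path: str | Path, dialect: str = "auto") -> ShapeTable:
    """Read a pentamer shape query table.

    Accepts tab- or comma-delimited text with a header row naming the 13
    features and a first column holding the pentamer.  ``dialect`` is one of
    ``"full"`` (1024 rows), ``"collapsed"`` (512 rows, one per
    pentamer/revcomp pair, expanded on load) or ``"auto"`` (decide from the
    keys present).
    """
    if dialect not in {"full", "collapsed", "auto"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if sample.count("\t") >= sample.count(",") else ","
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader)
        feats = [_canon_feature(h) for h in header[1:]]
        if sorted(feats) != sorted(FEATURE_NAMES):
            missing = set(FEATURE_NAMES) - set(feats)
            raise ShapeTableError(f"missing feature columns: {sorted(missing)}")
        order = [feats.index(f) for f in FEATURE_NAMES]
        rows: dict[str, np.ndarray] = {}
        for rec in reader:
            if not rec or not rec[0].strip():
                continue
            p = rec[0].strip().upper()
            if len(p) != 5 or any(c not in "ACGT" for c in p):
                raise ShapeTableError(f"non-ACGT pentamer key {p!r}")
            vals = np.array([float(rec[1 + j]) for j in order])
            if p in rows and not np.allclose(rows[p], vals):
                raise ShapeTableError(f"duplicate pentamer {p} with conflicting values")
            rows[p] = vals
    if dialect == "auto":
        dialect = "full" if len(rows) > 512 else "collapsed"
    if dialect == "collapsed":
        rows = expand_collapsed(rows)
    if len(rows) != 1024:
        missing = next(
            p for p in _all_pentamers() if p not in rows
        ) if len(rows) < 1024 else None
        raise ShapeTableError(
            f"table has {len(rows)} pentamers after expansion, expected 1024"
            + (f" (e.g. missing {missing})" if missing else "")
        )
    return ShapeTable(entries=rows, provenance=f"{path}:{dialect}")


def _all_pentamers() -> Iterable[str]:
    from itertools import product

    for tup in product("ACGT", repeat=5):
        yield "".join(tup)


class UnfeaturizableHit(ValueError):
    """A hit whose extended window leaves the contig or contains N."""


def canonical_window(
    hit,
    genome: Mapping[str, str],
    b: int,
    context: int = CONTEXT,
) -> str:
    """Extract the motif window plus ``b + context`` bases per side.

    Minus-strand hits are reverse complemented so the window always reads in
    the motif's 5'->3' orientation.  Raises :class:`UnfeaturizableHit` when
    the window crosses a contig end (the caller discards such hits; no
    padding rule exists for shape lookup).
    """
    if b < 0:
        raise ValueError("border b must be >= 0")
    try:
        contig = genome[hit.contig]
    except KeyError:
        raise UnfeaturizableHit(f"unknown contig {hit.contig!r}") from None
    pad = b + context
    lo, hi = hit.start - pad, hit.end + pad
    if lo < 0 or hi > len(contig):
        raise UnfeaturizableHit(
            f"window [{lo},{hi}) outside contig {hit.contig} (len {len(contig)})"
        )
    window = contig[lo:hi].upper()
    if hit.strand == "-":
        window = reverse_complement(window)
    return window


@dataclass
class ShapeProfile:
    """Per-position shape matrix for one sequence window."""

    positions: list[int]  # offsets into source_window (0-based, central base)
    values: np.ndarray  # (n_positions, 13)
    source_window: str

    def __post_init__(self) -> None:
        assert self.values.shape == (len(self.positions), 13)


def featurize(window: str, table: ShapeTable) -> ShapeProfile:
    """Assign each full-context position its pentamer's 13 shape values.

    Position ``i`` (0-based, ``2 <= i <= len-3``) gets the table row of
    ``window[i-2 : i+3]``; the profile therefore has ``len(window) - 4``
    positions in 5'->3' order.
    """
    window = window.upper()
    if len(window) < 5:
        raise ValueError(f"window of length {len(window)} is shorter than a pentamer")
    if any(c not in "ACGT" for c in window):
        raise UnfeaturizableHit("window contains non-ACGT characters")
    n = len(window) - 2 * CONTEXT
    vals = np.empty((n, 13))
    for k in range(n):
        vals[k] = table.entries[window[k : k + 5]]
    return ShapeProfile(
        positions=list(range(CONTEXT, CONTEXT + n)), values=vals, source_window=window
    )


def position_labels(motif_length: int, b: int) -> list[str]:
    """Labels -b..-1, 1..m, +1..+b (no position 0)."""
    return (
        [str(-i) for i in range(b, 0, -1)]
        + [str(i) for i in range(1, motif_length + 1)]
        + [f"+{i}" for i in range(1, b + 1)]
    )


def feature_vector_names(motif_length: int, b: int) -> list[str]:
    """Row-major ``feature@position`` names: position outer, feature inner."""
    return [
        f"{f}@{pos}" for pos in position_labels(motif_length, b) for f in FEATURE_NAMES
    ]


@dataclass
class FeatureVector:
    """Flattened, named shape features for one motif hit."""

    names: list[str]
    values: np.ndarray
    motif_length: int
    border: int


def flatten(profile: ShapeProfile, motif_length: int, b: int) -> FeatureVector:
    """Flatten a profile covering exactly ``motif_length + 2 b`` positions."""
    expected = motif_length + 2 * b
    if len(profile.positions) != expected:
        raise ValueError(
            f"profile has {len(profile.positions)} positions, "
            f"expected {expected} for m={motif_length}, b={b}"
        )
    return FeatureVector(
        names=feature_vector_names(motif_length, b),
        values=profile.values.reshape(-1).copy(),
        motif_length=motif_length,
        border=b,
    )


def parse_feature_name(name: str) -> tuple[str, str]:
    """Split ``feature@position`` into (feature, position label)."""
    try:
        feat, pos = name.rsplit("@", 1)
    except ValueError:
        raise ValueError(f"feature name {name!r} is not of the form feature@position")
    if feat not in FEATURE_NAMES:
        raise ValueError(f"unknown shape feature in {name!r}")
    return feat, pos
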