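"""Design of novel high- and low-affinity binding sequences.

Mirrors the EMSA candidate-design procedure: generate unique random
sequences of a fixed length (default 18 nt) carrying the TF's core motif
at a centered offset, discard any sequence occurring in the genome on
either strand, predict affinity for all of them with the trained shape
regressor, and keep the most extreme candidates above/below the high/low
affinity thresholds (defaults >150 and <15 peak-height units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .shape import CONTEXT, ShapeTable, featurize, flatten, reverse_complement


@dataclass
class DesignConfig:
    core: str = "ACGT"
    length: int = 18
    n_candidates: int = 100_000
    high_threshold: float = 150.0
    low_threshold: float = 15.0
    per_class: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.core = self.core.upper()
        if any(c not in "ACGT" for c in self.core):
            raise ValueError("core must be over {A,C,G,T}")
        if self.length < len(self.core):
            raise ValueError("length shorter than core")
        if not 0 <= self.low_threshold < self.high_threshold <= 1000:
            raise ValueError("need 0 <= low < high <= 1000")

    @property
    def core_offset(self) -> int:
        """Centered placement (length 18, 4-mer core -> offset 7)."""
        return (self.length - len(self.core)) // 2


def genome_kmer_index(genome: Mapping[str, str], k: int) -> frozenset[str]:
    """All k-mers occurring in the genome on either strand."""
    kmers: set[str] = set()
    for seq in genome.values():
        seq = seq.upper()
        rc = reverse_complement(seq.replace("N", "N"))
        for s in (seq, rc):
            for i in range(len(s) - k + 1):
                km = s[i : i + k]
                if "N" not in km:
                    kmers.add(km)
    return frozenset(kmers)


def generate_candidates(
    config: DesignConfig, genome: Mapping[str, str]
) -> list[str]:
    """Unique random core-containing sequences absent from the genome.

    Seeded and reproducible; aborts (reporting the count achieved) if the
    sequence space cannot supply enough admissible candidates.
    """
    rng = np.random.default_rng(config.seed)
    index = genome_kmer_index(genome, config.length)
    n_flank = config.length - len(config.core)
    out: list[str] = []
    seen: set[str] = set()
    max_tries = max(50 * config.n_candidates, 10_000)
    tries = 0
    off = config.core_offset
    while len(out) < config.n_candidates:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could only generate {len(out)} of {config.n_candidates} "
                "admissible candidates; sequence space too small"
            )
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n_flank))
        cand = flank[:off] + config.core + flank[off:]
        if cand in seen or cand in index:
            continue
        seen.add(cand)
        out.append(cand)
    return out


def predict_candidates(
    predictor,
    candidates: Sequence[str],
    table: ShapeTable,
    motif_length: int,
    border: int,
) -> np.ndarray:
    """Predict affinity for candidates using their own bases as shape context.

    The core sits at the centered offset; the featurized window is the
    ``m + 2*(border + 2)`` bases around it, which must fit in the candidate.
    """
    need = motif_length + 2 * (border + CONTEXT)
    rows = []
    for cand in candidates:
        if len(cand) < need:
            raise ValueError(
                f"candidate length {len(cand)} < {need} required for border {border}"
            )
        off = (len(cand) - motif_length) // 2
        lo = off - (border + CONTEXT)
        if lo < 0 or lo + need > len(cand):
            raise ValueError("core too close to candidate edge for this border")
        window = cand[lo : lo + need]
        rows.append(flatten(featurize(window, table), motif_length, border).values)
    X = np.vstack(rows)
    return predictor.predict(X)


def select_extremes(
    predictor,
    candidates: Sequence[str],
    config: DesignConfig,
    table: ShapeTable,
    border: int = 4,
) -> tuple[list[tuple[str, float]], list[tuple[str, float]], np.ndarray]:
    """Pick the most extreme qualifying candidates per class.

    Returns (high, low, predictions): ``high`` holds up to ``per_class``
    (sequence, prediction) pairs with prediction > high_threshold, largest
    first; ``low`` up to ``per_class`` with prediction < low_threshold,
    smallest first.  Warns when a class cannot be filled.
    """
    preds = predict_candidates(
        predictor, candidates, table, len(config.core), border
    )
    order = np.argsort(-preds, kind="stable")
    high = [
        (candidates[i], float(preds[i]))
        for i in order[: config.per_class]
        if preds[i] > config.high_threshold
    ]
    low = [
        (candidates[i], float(preds[i]))
        for i in order[::-1][: config.per_class]
        if preds[i] < config.low_threshold
    ]
    if len(high) < config.per_class or len(low) < config.per_class:
        warnings.warn(
            f"only {len(high)} high / {len(low)} low candidates met the "
            f">{config.high_threshold}/<{config.low_threshold} thresholds",
            stacklevel=2,
        )
    return high, low, preds


def write_candidates_fasta(path, candidates: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(candidates):
            fh.write(f">candidate_{i}\n{c}\n")


def write_predictions(path, candidates: Sequence[str], preds: np.ndarray) -> None:
    import pandas as pd

    pd.DataFrame({"sequence": list(candidates), "prediction": preds}).to_csv(
        path, sep="\t", index=False
    )
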