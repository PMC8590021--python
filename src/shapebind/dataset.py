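"""From peak files and motif hits to a labeled, balanced training dataset.

The labeling model: a motif occurrence within 80 bp of an ampDAP-seq peak
summit is an experimentally validated binding event and inherits the peak's
signal value (peak height, the affinity proxy); every other genomic
occurrence is an unbound negative.  Datasets are filtered by FRiP (>5%),
cross-dataset artifact peaks are removed, organelle contigs are excluded,
bound/unbound class imbalance is capped (1:5, then 1:3 if the total would
exceed 120,000 sites), signals are min-max normalized to [0, 1000], bound
sites get the unbound:bound ratio as sample weight, and an 80/20 stratified
split separates a validation set never touched during model selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .motifs import MotifHit
from .shape import (
    ShapeTable,
    UnfeaturizableHit,
    canonical_window,
    feature_vector_names,
    featurize,
    flatten,
)

PEAK_WIDTH = 200
SUMMIT_RADIUS = 80
DEFAULT_ORGANELLES = frozenset({"ChrC", "ChrM", "chloroplast", "mitochondria"})

#: Shape windows are always precomputed at this border so that any border
#: b <= 32 can be trained by column selection without re-extraction.
MAX_BORDER = 32


class PipelineAbort(RuntimeError):
    """Unrecoverable dataset condition (e.g. no bound sites)."""


@dataclass(frozen=True)
class Peak:
    """A 200-bp called peak with absolute summit and signal value."""

    contig: str
    start: int
    end: int
    summit: int
    signal: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"summit {self.summit} outside [{self.start},{self.end})")
        if self.signal < 0:
            raise ValueError("signal must be non-negative")


@dataclass
class DatasetManifest:
    """Datasets entering the artifact filter: (id, peak path, FRiP)."""

    entries: list[tuple[str, str, float]]
    target_id: str

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if self.target_id not in ids:
            raise ValueError(f"target {self.target_id!r} not among datasets {ids}")
        for _, _, frip in self.entries:
            if not 0.0 <= frip <= 1.0:
                raise ValueError(f"FRiP {frip} outside [0,1]")

    @classmethod
    def read(cls, path: str | Path, target_id: str) -> "DatasetManifest":
        """Read a tab-delimited manifest: dataset_id, peak_path, frip."""
        df = pd.read_csv(path, sep="\t")
        req = {"dataset_id", "peak_path", "frip"}
        if not req.issubset(df.columns):
            raise ValueError(f"manifest needs columns {sorted(req)}")
        base = Path(path).parent
        entries = [
            (str(r.dataset_id), str(base / r.peak_path), float(r.frip))
            for r in df.itertuples()
        ]
        return cls(entries=entries, target_id=target_id)


def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Read ENCODE narrowPeak (BED6+4).

    A summit offset of -1 (peak caller did not report one) falls back to the
    interval midpoint with a warning; intervals that are not 200 bp are
    accepted with a warning (foreign peak files).
    """
    peaks: list[Peak] = []
    warned_summit = warned_width = False
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(
                    f"{path}:{ln}: narrowPeak needs 10 columns, got {len(f)}"
                )
            contig, start, end = f[0], int(f[1]), int(f[2])
            signal = float(f[6])
            offset = int(f[9])
            if offset < 0:
                summit = (start + end) // 2
                if not warned_summit:
                    warnings.warn(
                        f"{path}: summit offset -1; using interval midpoint",
                        stacklevel=2,
                    )
                    warned_summit = True
            else:
                summit = start + offset
            if end - start != PEAK_WIDTH and not warned_width:
                warnings.warn(
                    f"{path}:{ln}: peak width {end - start} != {PEAK_WIDTH}",
                    stacklevel=2,
                )
                warned_width = True
            peaks.append(
                Peak(
                    contig=contig, start=start, end=end,
                    summit=summit, signal=signal, name=f[3],
                )
            )
    return peaks


def write_narrowpeak(path: str | Path, peaks: Sequence[Peak]) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.contig}\t{p.start}\t{p.end}\t{p.name or f'peak{i}'}\t0\t."
                f"\t{p.signal:.4f}\t-1\t-1\t{p.summit - p.start}\n"
            )


def filter_frip(manifest: DatasetManifest, min_frip: float = 0.05) -> DatasetManifest:
    """Keep only datasets with FRiP strictly above ``min_frip``."""
    kept = [e for e in manifest.entries if e[2] > min_frip]
    if manifest.target_id not in {e[0] for e in kept}:
        target_frip = next(e[2] for e in manifest.entries if e[0] == manifest.target_id)
        raise PipelineAbort(
            f"target dataset {manifest.target_id!r} has FRiP "
            f"{target_frip:.3f} <= {min_frip}; nothing to train on"
        )
    return DatasetManifest(entries=kept, target_id=manifest.target_id)


def filter_artifacts(
    target_peaks: Sequence[Peak],
    all_peak_sets: Mapping[str, Sequence[Peak]],
    max_fraction: float = 1 / 3,
    summit_tolerance: int = 100,
) -> list[Peak]:
    """Drop target peaks recurring in more than ``max_fraction`` of datasets.

    A peak "occurs" in a dataset when that dataset has a peak on the same
    contig whose summit lies within ``summit_tolerance`` bp.  The occurrence
    fraction counts the target dataset itself.  With fewer than 3 datasets
    the filter is skipped (every peak would trivially exceed 1/3).
    """
    n_datasets = len(all_peak_sets)
    if n_datasets < 3:
        warnings.warn(
            f"artifact filter skipped: only {n_datasets} datasets", stacklevel=2
        )
        return list(target_peaks)
    summits: dict[str, dict[str, np.ndarray]] = {}
    for ds, peaks in all_peak_sets.items():
        by_contig: dict[str, list[int]] = {}
        for p in peaks:
            by_contig.setdefault(p.contig, []).append(p.summit)
        summits[ds] = {c: np.sort(np.array(v)) for c, v in by_contig.items()}
    kept = []
    for p in target_peaks:
        n_occ = 0
        for ds in all_peak_sets:
            arr = summits[ds].get(p.contig)
            if arr is None or len(arr) == 0:
                continue
            i = np.searchsorted(arr, p.summit)
            near = min(
                abs(int(arr[j]) - p.summit)
                for j in (max(i - 1, 0), min(i, len(arr) - 1))
            )
            if near <= summit_tolerance:
                n_occ += 1
        if n_occ / n_datasets <= max_fraction:
            kept.append(p)
    return kept


def label_hits(
    hits: Sequence[MotifHit],
    peaks: Sequence[Peak],
    radius: int = SUMMIT_RADIUS,
) -> pd.DataFrame:
    """Label each hit bound/unbound by summit proximity.

    A hit is bound iff the minimum distance from some peak summit to any
    base of the motif interval is <= ``radius``; it inherits that peak's
    signal (the highest-signal peak if several qualify).  Returns a frame
    with one row per hit: contig, start, end, strand, score, pvalue, bound,
    signal, peak_id.
    """
    by_contig: dict[str, list[tuple[int, float, int]]] = {}
    for pid, p in enumerate(peaks):
        by_contig.setdefault(p.contig, []).append((p.summit, p.signal, pid))
    rows = []
    for h in hits:
        bound, signal, peak_id = False, 0.0, -1
        for summit, sig, pid in by_contig.get(h.contig, ()):
            # distance from summit to nearest base of [start, end)
            if summit < h.start:
                d = h.start - summit
            elif summit >= h.end:
                d = summit - (h.end - 1)
            else:
                d = 0
            if d <= radius and (not bound or sig > signal):
                bound, signal, peak_id = True, sig, pid
        rows.append(
            {
                "contig": h.contig, "start": h.start, "end": h.end,
                "strand": h.strand, "score": h.score, "pvalue": h.pvalue,
                "bound": bound, "signal": signal, "peak_id": peak_id,
            }
        )
    return pd.DataFrame(rows)


def detect_homodimer(labeled: pd.DataFrame) -> tuple[bool, pd.DataFrame]:
    """Classify the TF's binding mode and drop the minority peak class.

    Counts bound peaks with >= 2 in-radius motif occurrences against those
    with exactly 1.  If multi-occurrence peaks are the strict majority the
    TF is treated as a homodimer binder and bound hits from
    single-occurrence peaks are dropped; otherwise (including ties) bound
    hits from multi-occurrence peaks are dropped.  Unbound hits are never
    touched.
    """
    bound = labeled[labeled["bound"]]
    counts = bound.groupby("peak_id").size()
    n_multi = int((counts >= 2).sum())
    n_single = int((counts == 1).sum())
    homodimer = n_multi > n_single
    if homodimer:
        drop_peaks = set(counts.index[counts == 1])
    else:
        drop_peaks = set(counts.index[counts >= 2])
    keep = ~(labeled["bound"] & labeled["peak_id"].isin(drop_peaks))
    return homodimer, labeled[keep].reset_index(drop=True)


def exclude_organelles(
    labeled: pd.DataFrame,
    organelle_names: frozenset[str] | set[str] = DEFAULT_ORGANELLES,
) -> pd.DataFrame:
    """Drop hits on chloroplast/mitochondrial contigs (not assayed in vitro)."""
    return labeled[~labeled["contig"].isin(organelle_names)].reset_index(drop=True)


def balance_ratio(
    labeled: pd.DataFrame,
    max_ratio: int = 5,
    cap: int = 120_000,
    fallback_ratio: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Cap the unbound:bound ratio at 1:5, or 1:3 if the total exceeds the cap.

    Unbound sites are uniformly subsampled (seeded); bound sites are never
    removed.  Aborts when there are no bound sites at all.
    """
    n_bound = int(labeled["bound"].sum())
    n_unbound = len(labeled) - n_bound
    if n_bound == 0:
        raise PipelineAbort("no bound sites; cannot train a regressor")
    target_unbound = n_unbound
    if n_unbound > max_ratio * n_bound:
        target_unbound = max_ratio * n_bound
        if n_bound + target_unbound > cap:
            target_unbound = fallback_ratio * n_bound
    if target_unbound >= n_unbound:
        return labeled.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    unbound_idx = labeled.index[~labeled["bound"]].to_numpy()
    keep_unbound = rng.choice(unbound_idx, size=target_unbound, replace=False)
    mask = labeled["bound"].to_numpy().copy()
    mask[keep_unbound] = True
    return labeled[mask].reset_index(drop=True)


def normalize_signal(labeled: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale bound signals onto [0, 1000]; unbound labels are 0.

    If all bound signals are equal every bound label becomes 1000.
    """
    out = labeled.copy()
    out["label"] = 0.0
    bound = out["bound"]
    if bound.any():
        sig = out.loc[bound, "signal"]
        lo, hi = float(sig.min()), float(sig.max())
        if hi > lo:
            out.loc[bound, "label"] = (sig - lo) / (hi - lo) * 1000.0
        else:
            out.loc[bound, "label"] = 1000.0
    return out


def compute_sample_weights(labeled: pd.DataFrame) -> pd.DataFrame:
    """Bound sites weigh unbound/bound (the class ratio); unbound weigh 1.

    Up-weighting validated events counters the bias towards calling
    everything unbound on these imbalanced datasets.
    """
    out = labeled.copy()
    n_bound = int(out["bound"].sum())
    n_unbound = len(out) - n_bound
    if n_bound == 0:
        raise PipelineAbort("no bound sites; weights undefined")
    out["weight"] = 1.0
    out.loc[out["bound"], "weight"] = max(n_unbound / n_bound, 1e-12)
    return out


@dataclass
class TrainingDataset:
    """Featurized, labeled sites with a frozen train/validation split.

    ``features`` holds the 13 x (m + 2*MAX_BORDER) shape columns for every
    site; a smaller training border selects sub-columns.
    """

    sites: pd.DataFrame  # labels, weights, coordinates
    features: pd.DataFrame  # shape columns, same index as sites
    motif_length: int
    homodimer_mode: bool
    train_idx: np.ndarray
    val_idx: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def max_border(self) -> int:
        n_pos = self.features.shape[1] // 13
        return (n_pos - self.motif_length) // 2

    def columns_for_border(self, b: int) -> list[str]:
        if b > self.max_border:
            raise ValueError(f"border {b} exceeds precomputed {self.max_border}")
        return feature_vector_names(self.motif_length, b)

    def design(self, b: int, idx: np.ndarray | None = None):
        """(X, y, w) numpy arrays at border b, optionally on an index subset."""
        cols = self.columns_for_border(b)
        feats = self.features[cols]
        sites = self.sites
        if idx is not None:
            feats, sites = feats.iloc[idx], sites.iloc[idx]
        return (
            feats.to_numpy(),
            sites["label"].to_numpy(),
            sites["weight"].to_numpy(),
            cols,
        )

    def write(self, path: str | Path) -> None:
        """Serialize as a delimited table plus a provenance sidecar."""
        path = Path(path)
        table = pd.concat([self.sites, self.features], axis=1)
        table.to_csv(path, sep="\t", index=False)
        side = {
            "motif_length": self.motif_length,
            "homodimer_mode": self.homodimer_mode,
            "train_idx": self.train_idx.tolist(),
            "val_idx": self.val_idx.tolist(),
            "provenance": self.provenance,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(side))

    @classmethod
    def read(cls, path: str | Path) -> "TrainingDataset":
        path = Path(path)
        table = pd.read_csv(path, sep="\t")
        side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        feat_cols = [c for c in table.columns if "@" in c]
        return cls(
            sites=table.drop(columns=feat_cols),
            features=table[feat_cols],
            motif_length=side["motif_length"],
            homodimer_mode=side["homodimer_mode"],
            train_idx=np.array(side["train_idx"], dtype=int),
            val_idx=np.array(side["val_idx"], dtype=int),
            provenance=side["provenance"],
        )


def split_dataset(
    labeled: pd.DataFrame,
    validation_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified split on the bound flag; returns (train, val) indices."""
    idx = np.arange(len(labeled))
    if validation_fraction <= 0:
        warnings.warn("validation_fraction <= 0: empty validation set", stacklevel=2)
        return idx, np.array([], dtype=int)
    train, val = train_test_split(
        idx,
        test_size=validation_fraction,
        random_state=seed,
        stratify=labeled["bound"].to_numpy(),
    )
    return np.sort(train), np.sort(val)


def featurize_sites(
    labeled: pd.DataFrame,
    genome: Mapping[str, str],
    table: ShapeTable,
    motif_length: int,
    border: int = MAX_BORDER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach flattened shape features; silently drops unfeaturizable hits.

    Returns (sites, features) with aligned fresh indices.
    """
    names = feature_vector_names(motif_length, border)
    keep_rows, vectors = [], []
    for i, row in enumerate(labeled.itertuples()):
        hit = MotifHit(
            contig=row.contig, start=row.start, end=row.end,
            strand=row.strand, score=row.score, pvalue=row.pvalue,
            matched_seq="",
        )
        try:
            window = canonical_window(hit, genome, border)
            profile = featurize(window, table)
        except UnfeaturizableHit:
            continue
        vectors.append(flatten(profile, motif_length, border).values)
        keep_rows.append(i)
    if not vectors:
        raise PipelineAbort("no featurizable sites")
    sites = labeled.iloc[keep_rows].reset_index(drop=True)
    features = pd.DataFrame(np.vstack(vectors), columns=names)
    return sites, features


def build_dataset(
    hits: Sequence[MotifHit],
    manifest: DatasetManifest,
    genome: Mapping[str, str],
    table: ShapeTable,
    motif_length: int,
    seed: int = 0,
    organelle_names: frozenset[str] | set[str] = DEFAULT_ORGANELLES,
    artifact_max_fraction: float = 1 / 3,
    validation_fraction: float = 0.2,
    border: int = MAX_BORDER,
) -> TrainingDataset:
    """Run the full labeling pipeline for the manifest's target dataset."""
    manifest = filter_frip(manifest)
    peak_sets = {ds: read_narrowpeak(p) for ds, p, _ in manifest.entries}
    target_peaks = peak_sets[manifest.target_id]
    target_peaks = filter_artifacts(
        target_peaks, peak_sets, max_fraction=artifact_max_fraction
    )
    labeled = label_hits(hits, target_peaks)
    homodimer, labeled = detect_homodimer(labeled)
    labeled = exclude_organelles(labeled, organelle_names)
    labeled = balance_ratio(labeled, seed=seed)
    labeled = normalize_signal(labeled)
    labeled = compute_sample_weights(labeled)
    sites, features = featurize_sites(labeled, genome, table, motif_length, border)
    train_idx, val_idx = split_dataset(sites, validation_fraction, seed=seed)
    return TrainingDataset(
        sites=sites,
        features=features,
        motif_length=motif_length,
        homodimer_mode=homodimer,
        train_idx=train_idx,
        val_idx=val_idx,
        provenance={
            "seed": seed,
            "target": manifest.target_id,
            "n_datasets": len(manifest.entries),
            "artifact_max_fraction": artifact_max_fraction,
        },
    )
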