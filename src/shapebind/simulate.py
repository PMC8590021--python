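"""Synthetic study generator: genome, planted motifs, shape-driven affinity.

Emulates the study design the trainer expects from real data: a
multi-contig genome (with organelle-named contigs that the pipeline must
exclude), a TF whose binding affinity is a stated linear function of two
local DNA-shape features plus Gaussian noise, 200-bp peaks whose signal
value is that affinity, several pseudo-datasets sharing artifact peaks for
the cross-dataset filter, and a symmetry-respecting random pentamer shape
table.  Ground truth (locus, strand, true affinity, bound flag) is kept so
tests can assert exact recovery.

The generated table is synthetic: values are drawn per pentamer within
loosely realistic ranges (MGW a few angstroms, angles tens of degrees) and
then symmetrized, so reverse-complement lookups obey the same sign rules
as a real query table, but the values carry no biophysical meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dataset import DatasetManifest, Peak, write_narrowpeak
from .motifs import PositionWeightMatrix
from .shape import (
    CONTEXT,
    FEATURE_NAMES,
    ODD_FEATURES,
    ShapeTable,
    feature_vector_names,
    featurize,
    flatten,
    position_labels,
    reverse_complement,
)

#: Margin kept free at contig ends so the +/-32-base shape window and the
#: 200-bp peak around any planted locus are always extractable.
PLANT_MARGIN = 110
#: Jitter of a planted start within its grid slot; kept small enough that
#: adjacent loci stay > 180 bp apart.
PLANT_JITTER = 60
#: Minimum spacing between planted loci; larger than peak radius + motif so
#: each planted locus labels against its own peak only.
PLANT_SPACING = 250


@dataclass
class SimulationConfig:
    """Ground-truth generative model for one synthetic TF study."""

    contigs: dict[str, int] = field(
        default_factory=lambda: {"Chr1": 1_000_000, "ChrC": 30_000, "ChrM": 20_000}
    )
    gc: float = 0.36
    consensus: str = "TTGACC"
    n_instances: int = 1000
    #: (feature@position, weight in label units per SD of the feature)
    causal_features: tuple[tuple[str, float], ...] = (
        ("roll@-1", 300.0),
        ("MGW@+2", -250.0),
    )
    baseline_affinity: float = 400.0
    noise_sd: float = 50.0
    bound_threshold: float = 500.0
    n_datasets: int = 5
    n_artifact_peaks: int = 30
    n_decoy_peaks: int = 100
    frips: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.bound_threshold < 1000:
            raise ValueError("bound_threshold must lie in (0, 1000)")
        if self.frips is not None and len(self.frips) != self.n_datasets:
            raise ValueError("frips must have one value per dataset")

    @property
    def organelles(self) -> tuple[str, ...]:
        return tuple(c for c in self.contigs if c in {"ChrC", "ChrM"})


def make_shape_table_fixture(seed: int) -> ShapeTable:
    """Random 1024-pentamer table obeying the revcomp symmetry rules exactly."""
    rng = np.random.default_rng(seed)
    # per-feature (center, sd) in loosely realistic units
    scales = {
        "MGW": (5.0, 0.7),
        "shear": (0.0, 0.3), "stretch": (0.0, 0.25), "stagger": (0.0, 0.3),
        "buckle": (0.0, 6.0), "propeller_twist": (-7.0, 5.0), "opening": (0.0, 4.0),
        "shift": (0.0, 0.4), "slide": (0.0, 0.5), "rise": (3.3, 0.15),
        "tilt": (0.0, 3.0), "roll": (0.0, 5.0), "helix_twist": (34.0, 3.0),
    }
    sign = np.array([-1.0 if f in ODD_FEATURES else 1.0 for f in FEATURE_NAMES])
    # odd features have zero mean so the sign flip stays within realistic range
    mu = np.array(
        [0.0 if f in ODD_FEATURES else scales[f][0] for f in FEATURE_NAMES]
    )
    sd = np.array([scales[f][1] for f in FEATURE_NAMES])
    entries: dict[str, np.ndarray] = {}
    from itertools import product

    for tup in product("ACGT", repeat=5):
        p = "".join(tup)
        if p in entries:
            continue
        vals = mu + sd * rng.standard_normal(13)
        entries[p] = vals
        entries[reverse_complement(p)] = vals * sign
    return ShapeTable(entries=entries, provenance=f"synthetic:seed={seed}")


def simulate_genome(config: SimulationConfig, rng: np.random.Generator) -> dict[str, str]:
    """I.i.d. bases at the configured GC content, one string per contig."""
    p = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    genome = {}
    for name, length in config.contigs.items():
        idx = rng.choice(4, size=length, p=p)
        genome[name] = "".join(np.array(list("ACGT"))[idx])
    return genome


def plant_motifs(
    genome: Mapping[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Overwrite spaced positions with motif instances on random strands.

    Instances are allotted to contigs proportionally to length and placed on
    a shuffled grid with :data:`PLANT_SPACING` spacing, so no two loci
    overlap and each is far enough from contig ends to featurize.  Returns
    the modified genome and a truth frame (contig, start, end, strand).
    """
    m = len(config.consensus)
    total = sum(config.contigs.values())
    out_genome = {}
    rows = []
    for name, length in config.contigs.items():
        n_here = int(round(config.n_instances * length / total))
        slots = np.arange(
            PLANT_MARGIN, length - PLANT_MARGIN - m - PLANT_SPACING, PLANT_SPACING
        )
        if n_here > len(slots):
            raise ValueError(f"contig {name} too short for {n_here} instances")
        rng.shuffle(slots)
        seq = list(genome[name])
        for start in sorted(int(s) + int(rng.integers(0, PLANT_JITTER + 1)) for s in slots[:n_here]):
            strand = "+" if rng.random() < 0.5 else "-"
            inst = config.consensus if strand == "+" else reverse_complement(
                config.consensus
            )
            seq[start : start + m] = inst
            rows.append(
                {"contig": name, "start": start, "end": start + m, "strand": strand}
            )
        out_genome[name] = "".join(seq)
    return out_genome, pd.DataFrame(rows)


def _causal_column_indices(config: SimulationConfig, border: int) -> list[int]:
    m = len(config.consensus)
    names = feature_vector_names(m, border)
    idx = []
    for fname, _ in config.causal_features:
        if fname not in names:
            raise ValueError(
                f"causal feature {fname!r} outside the border-{border} window"
            )
        idx.append(names.index(fname))
    return idx


def assign_affinity(
    truth: pd.DataFrame,
    genome: Mapping[str, str],
    table: ShapeTable,
    config: SimulationConfig,
    rng: np.random.Generator,
    border: int = 8,
) -> pd.DataFrame:
    """True affinity = clip(a0 + sum_j w_j z_j + noise, 0, 1000), bound above
    the threshold.

    ``z_j`` is the j-th causal shape feature standardized over the planted
    loci, so effect weights are in label units per SD and are scale-free
    with respect to the table.
    """
    m = len(config.consensus)
    cols = _causal_column_indices(config, border)
    feats = np.empty((len(truth), len(cols)))
    for i, row in enumerate(truth.itertuples()):
        pad = border + CONTEXT
        window = genome[row.contig][row.start - pad : row.end + pad]
        if row.strand == "-":
            window = reverse_complement(window)
        vec = flatten(featurize(window, table), m, border).values
        feats[i] = vec[cols]
    z = (feats - feats.mean(axis=0)) / feats.std(axis=0)
    weights = np.array([w for _, w in config.causal_features])
    affinity = (
        config.baseline_affinity
        + z @ weights
        + rng.normal(0.0, config.noise_sd, size=len(truth))
    )
    affinity = np.clip(affinity, 0.0, 1000.0)
    out = truth.copy()
    out["affinity"] = affinity
    out["bound"] = affinity > config.bound_threshold
    return out


def emit_peaks(
    truth: pd.DataFrame,
    config: SimulationConfig,
    outdir: str | Path,
    rng: np.random.Generator,
) -> tuple[DatasetManifest, dict[str, list[Peak]]]:
    """Write narrowPeak pseudo-datasets and a manifest.

    The target dataset holds one 200-bp peak per bound nuclear locus
    (summit at the motif midpoint, signal = true affinity) plus the shared
    artifact peaks.  Every other dataset gets the same artifact peaks (so
    they recur in all datasets, fraction 1 > 1/3) plus its own decoy peaks
    drawn from a disjoint motif-free position pool.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    organelles = set(config.organelles)
    nuclear = truth[~truth["contig"].isin(organelles)]
    bound = nuclear[nuclear["bound"]]

    def peak_at(contig: str, mid: int, signal: float, tag: str) -> Peak:
        return Peak(
            contig=contig, start=mid - 100, end=mid + 100,
            summit=mid, signal=signal, name=tag,
        )

    target_peaks = [
        peak_at(r.contig, (r.start + r.end) // 2, r.affinity, f"true_{i}")
        for i, r in enumerate(bound.itertuples())
    ]

    # motif-free pool: grid positions offset from every planted locus
    pool: list[tuple[str, int]] = []
    planted = {
        c: np.sort(g["start"].to_numpy()) for c, g in truth.groupby("contig")
    }
    for contig, length in config.contigs.items():
        if contig in organelles:
            continue
        starts = planted.get(contig, np.array([], dtype=int))
        for pos in range(300, length - 300, 137):
            i = np.searchsorted(starts, pos)
            near = min(
                (abs(int(starts[j]) - pos) for j in (max(i - 1, 0), min(i, len(starts) - 1))
                 if len(starts)),
                default=10**9,
            )
            if near > 250:
                pool.append((contig, pos))
    pool_idx = rng.permutation(len(pool))
    need = config.n_artifact_peaks + config.n_decoy_peaks * config.n_datasets
    if need > len(pool):
        raise ValueError("motif-free pool too small for requested peak counts")
    cursor = 0

    def take(n: int) -> list[tuple[str, int]]:
        nonlocal cursor
        sel = [pool[pool_idx[cursor + j]] for j in range(n)]
        cursor += n
        return sel

    artifacts = [
        peak_at(c, p, float(rng.uniform(100, 900)), f"artifact_{j}")
        for j, (c, p) in enumerate(take(config.n_artifact_peaks))
    ]

    frips = config.frips or tuple(
        [0.30] + [0.20] * (config.n_datasets - 2) + [0.04]
    )
    peak_sets: dict[str, list[Peak]] = {}
    entries = []
    for d in range(config.n_datasets):
        ds = "target" if d == 0 else f"ds{d}"
        if d == 0:
            peaks = target_peaks + artifacts
        else:
            decoys = [
                peak_at(c, p, float(rng.uniform(50, 500)), f"decoy_{ds}_{j}")
                for j, (c, p) in enumerate(take(config.n_decoy_peaks))
            ]
            peaks = decoys + artifacts
        peaks.sort(key=lambda p: (p.contig, p.start))
        path = outdir / f"{ds}.narrowPeak"
        write_narrowpeak(path, peaks)
        peak_sets[ds] = peaks
        entries.append((ds, str(path), float(frips[d])))
    manifest = DatasetManifest(entries=entries, target_id="target")
    manifest_df = pd.DataFrame(
        [(ds, Path(p).name, f) for ds, p, f in entries],
        columns=["dataset_id", "peak_path", "frip"],
    )
    manifest_df.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest, peak_sets


def consensus_pwm(
    consensus: str, p_consensus: float = 0.85, name: str = "planted"
) -> PositionWeightMatrix:
    """Near-deterministic PWM around a consensus, uniform background."""
    m = len(consensus)
    probs = np.full((m, 4), (1 - p_consensus) / 3)
    for i, c in enumerate(consensus.upper()):
        probs[i, "ACGT".index(c)] = p_consensus
    return PositionWeightMatrix(
        probs=probs, background=np.full(4, 0.25), pseudocount=0.0, name=name
    )


@dataclass
class SimulatedStudy:
    """Everything one synthetic TF study produces."""

    config: SimulationConfig
    genome: dict[str, str]
    truth: pd.DataFrame
    table: ShapeTable
    pwm: PositionWeightMatrix
    manifest: DatasetManifest
    peak_sets: dict[str, list[Peak]]
    outdir: Path


def simulate_study(
    config: SimulationConfig, outdir: str | Path
) -> SimulatedStudy:
    """Run the whole generator: genome, motifs, affinities, peaks, files."""
    rng = np.random.default_rng(config.seed)
    table = make_shape_table_fixture(config.seed)
    genome = simulate_genome(config, rng)
    genome, truth = plant_motifs(genome, config, rng)
    truth = assign_affinity(truth, genome, table, config, rng)
    manifest, peak_sets = emit_peaks(truth, config, Path(outdir), rng)
    table.write(Path(outdir) / "shape_table.tsv")
    truth.to_csv(Path(outdir) / "truth.tsv", sep="\t", index=False)
    return SimulatedStudy(
        config=config,
        genome=genome,
        truth=truth,
        table=table,
        pwm=consensus_pwm(config.consensus),
        manifest=manifest,
        peak_sets=peak_sets,
        outdir=Path(outdir),
    )
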