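# shapebind

Predicting transcription-factor (TF) binding affinity from local **DNA
shape**.

Members of large plant TF families often share nearly identical sequence
motifs, yet bind different genomic sites with different strengths.  A large
part of that discrimination is carried not by the base sequence itself but
by the three-dimensional geometry it imposes on the double helix: the base
pairs of a binding site are sheared, stretched, staggered, buckled,
propeller-twisted and opened within each pair, and shifted, slid, risen,
tilted, rolled and helically twisted between pairs, with a position-specific
minor groove width (MGW).  `shapebind` trains, per TF, a random-forest
regressor that predicts in-vitro binding affinity (ampDAP-seq peak height)
from those 13 per-position shape features around every genomic motif
occurrence, and explains the trained model with exact Shapley attributions.

## What it does

1. **Shape featurization** — a pentamer query table (1024 rows, or the
   512-row reverse-complement-collapsed dialect) maps every position of a
   sequence window to 13 shape parameters.  Windows around motif hits are
   strand-canonicalized (minus-strand hits are reverse complemented) and
   flattened to named features `feature@position`, with core positions
   `1..m` and flanks `-b..-1`, `+1..+b`.
2. **Motif scanning** — a MEME-format motif is scored as a log-odds PWM
   (bits); exact p-values come from a dynamic program over a discretized
   score grid, and the genome is scanned on both strands at p ≤ 5·10⁻⁴ with
   palindromic matches counted once per locus.
3. **Dataset construction** — peaks are filtered by FRiP (> 5 %) and by
   cross-dataset recurrence (a peak in more than ⅓ of datasets is an
   artifact); a motif occurrence within 80 bp of a peak summit is a bound
   site labeled with the peak's signal; homodimeric binders are detected by
   multi-occurrence majority; organelle contigs are excluded; the
   unbound:bound ratio is capped at 5:1 (3:1 when the total would exceed
   120,000 sites); signals are scaled to [0, 1000]; bound sites are
   weighted by the class ratio; an 80/20 stratified split reserves a
   validation set.
4. **Training & evaluation** — randomized hyperparameter search (default
   75 draws over `n_estimators` 10–200, `max_features` ∈ {all, sqrt,
   log2}, `max_depth` 4–12) under 5-fold cross-validated weighted MSE on
   the training split; the model's ranking of validation sites is scored
   by AUPRC against the motif log-odds score as the motif-only baseline.
5. **Attribution** — exact interventional Shapley values for the forest
   (closed-form leaf-path algorithm, no sampling), global importance as
   mean |contribution|, top-5 extraction and intra/inter/MGW ×
   core/flank categorization.
6. **Sequence design** — 100,000 random core-bearing 18-mers absent from
   the genome are scored by the model; the most extreme candidates above
   150 and below 15 affinity units are the proposed high/low binders.

A synthetic-study generator (`shapebind.simulate`) produces genomes with
planted motifs whose ground-truth affinity is a stated function of two
shape features, so the whole pipeline is testable end to end without any
downloads.

## Worked example

```sh
shapebind demo --seed 1 --out demo.json
```

simulates a 1-Mb study (1,000 planted motif instances of the consensus
`TTGACC`, causal features `roll@-1` and `MGW@+2`, noise sd 50 affinity
units), scans, trains and explains.  Typical output:

```
"n_sites": 1282        # labeled motif occurrences after balancing
"n_bound": 379         # occurrences under a peak summit (within 80 bp)
"model_auprc": 0.776   # shape model, validation split
"baseline_auprc": 0.296  # motif log-odds ranking of the same sites
"auprc_gain_percent": 162.3
"causal_in_top5": 2    # both planted causal features recovered
"top5_features": ["roll@-1", "MGW@+2", ...]
```

The shape model roughly halves-to-quarters the precision-recall gap left
by the motif score alone, and the Shapley ranking identifies exactly the
two shape features that generated the affinities.

For real data, `shapebind fit` takes a genome FASTA, a MEME motif file, a
narrowPeak manifest (TSV: `dataset_id`, `peak_path`, `frip`) and a shape
query table, and writes the serialized dataset plus a training summary;
`shapebind scan` writes a FIMO-style hit table.

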