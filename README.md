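# twinephys

Quantitative phenotyping pipeline for neuron cohorts, exercised end-to-end
on synthetic data with known ground truth. The package covers:

* **`twinephys.synth`** — generators for every input the pipeline consumes:
  a single-compartment conductance-based neuron (leak + transient Na +
  delayed-rectifier K + A-type K, exponential-Euler at 0.05 ms), Poisson
  EPSC traces with bi-exponential kernels, bursty multi-electrode spike
  trains, random branched SWC morphologies, and differential-expression
  tables. Every generator is a pure function of its parameters and seed.
* **`twinephys.iclamp`** — current-clamp phenotypes: evoked AP counts over a
  20-step protocol (3 pA increments, 400 ms, starting 12 pA below holding),
  spike threshold (first maximum of d²V/dt²), amplitude, FWHM width, fAHP
  at +5 ms, two-point input conductance (ΔI over 20 mV between −70 and
  −50 mV), median-baseline resting potential, charge-integration
  capacitance. Neurons needing > 50 pA holding current are excluded.
* **`twinephys.vclamp`** — Na/K current amplitudes per voltage step
  (−90…80 mV) with optional linear leak subtraction; I–V curve assembly.
* **`twinephys.epsc`** — spontaneous inward-event detection (low-pass,
  rolling-median baseline, MAD-scaled threshold) with rate/amplitude
  summaries.
* **`twinephys.mea`** — raw-trace spike detection (band-pass, ±5.5 SD
  adaptive threshold), Poisson-surprise burst detection, network-burst
  intervals, and per-well longitudinal aggregation.
* **`twinephys.morpho`** — SWC I/O with structural validation, 3-D Sholl
  profiles at 10 µm increments, branch count / maximal branch length /
  total dendritic length, soma area.
* **`twinephys.stats`** — KS normality check on standardized samples,
  Welch/Student t-tests, one-way ANOVA with Tukey–Kramer pairwise
  comparisons, two-way (group × day) ANOVA, and the significance-star
  convention (\* < 0.05 … \*\*\*\* < 0.0001).
* **`twinephys.genesets`** — gene-symbol standardization, DEG × GWAS-catalog
  intersection (weights = study counts, down = blue / up = red), three-way
  Venn partitions.
* **`twinephys.pipeline`** — seeded end-to-end runs: synthesize three-group
  cohorts, extract all phenotypes, run the statistics layer, and emit
  TSV + Markdown reports stamped with the config hash and seed.

## Command line

```bash
# generate inputs
twinephys synth iclamp --seed 1 --out runs/cc/          # current-clamp sweeps
twinephys synth vclamp --seed 1 --out runs/vc/          # voltage-clamp sweeps
twinephys synth epsc   --seed 1 --out runs/epsc/        # EPSC trace + truth
twinephys synth mea    --seed 1 --out runs/mea/         # spike trains + truth
twinephys synth morph  --seed 1 --out runs/swc/ --n 10  # SWC morphologies
twinephys synth deg    --seed 1 --out runs/degs.tsv     # DEG table

# analyze
twinephys iclamp --sweeps runs/cc/manifest.json --out features.tsv
twinephys vclamp --sweeps runs/vc/manifest.json --out iv.tsv
twinephys epsc   --trace runs/epsc/trace.csv --out events.tsv
twinephys mea    --spikes runs/mea/spikes.csv --duration 600 --out well.tsv
twinephys morpho --swc runs/swc/ --out morpho.tsv
twinephys stats  --table measures.tsv --design oneway --out stats.tsv
twinephys genesets intersect --degs degs.tsv --gwas gwas.tsv --out shared.tsv
twinephys genesets venn --a a.txt --b b.txt --c c.txt

# full pipeline (synth -> features -> stats -> report)
twinephys run --config run.yaml --seed 1 --out report/
```

Trace files are two-column CSV (`time_s,value`) with a JSON manifest per
sweep set; spike trains are long CSV (`electrode_id,spike_time_s`);
morphologies are standard 7-column SWC.

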