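# scritscreen

Analysis toolkit for **multi-parametric high-content screening of
differential mitochondrial toxicity**: from per-cell fluorescence features
(measured on an imaging cytometer, or simulated) through per-well statistics
to compound-level response fingerprints and unsupervised mechanistic
classification.

The assay it models treats HepG2-like cells with compounds in two media —
glucose (**glu+**) and galactose-substituted (**glu−**) — and reads out three
dyes per cell: TMRM (mitochondrial membrane potential, MMP), TO-PRO-3
(plasma-membrane integrity / viability) and Hoechst33342 (nuclear
segmentation and morphology). Galactose forces cells onto oxidative
phosphorylation, so compounds that poison mitochondria directly become far
more toxic in glu− while glycolysis-independent toxicants do not: comparing
dose responses *across* media separates mechanisms that a single-condition
screen cannot.

It is intended for screening scientists and computational biologists who
want the complete analysis chain as a library and CLI, including a synthetic
plate generator so that every stage is testable without instrument data.

## The statistics at the core

**Signed KS distance.** Each treated well is compared with the pooled
in-plate negative-control (DMSO) cells. For a parameter's empirical CDFs
F_ref and F_sample,

    D = F_ref(x*) − F_sample(x*),   x* = argmax |F_ref − F_sample|,

so D ∈ [−1, 1]; D < 0 means signal loss (FCCP-like TMRM collapse), D > 0
a shift to brighter values (the nicardipine-like TMRM increase). The exact
statistic is computed over all CDF breakpoints — no asymptotics, no p-value.

**Viability.** TO-PRO-3 intensity is bimodal (live/dead); a well's viability
is the fraction of cells below an intensity gate found at the valley of the
smoothed log10 histogram (fallback 10^3.25 a.u.), rescaled to
2·f − 1 ∈ [−1, 1] so it shares the KS range.

**Plate QC.** The screening window is summarised by the Z′ factor on
per-well |KS| of the TMRM peripheral integral:

    Z′ = 1 − 3(σ_p + σ_n) / |μ_p − μ_n|.

**SCRIT vectors.** The Specialized-Cell-Response-to-Induced-Toxicity vector
concatenates well statistics over parameters × conditions × doses
(parameter-major, glu+ before glu−, doses ascending): 2×10×2 = 40
components for the classic TMRM+viability fingerprint, 3×10×2 = 60 with the
Hoechst mean, 7×1×2 = 14 for the single-dose primary screen.

**Classification.** Replicate fingerprints are items; compounds whose
replicates disagree (pairwise Pearson distance > 0.2) are removed as
outliers. Pearson distance (1 − r) feeds average-linkage hierarchical
clustering and classical MDS, and flat clusters are labelled by matching
their medoid against reference fingerprints of five mechanistic groups:
**I** direct mitochondrial toxins, **II** glucose-independent toxins,
**III** glucose-dependent toxins, **IV** inactive compounds, **V**
uncouplers (FCCP-like).

## Worked example

Simulate the 48 FCCP / 48 DMSO assay-development plate and check the
screening window, then run a five-compound secondary screen end to end:

```python
from scritscreen import pipeline

config = pipeline.RunConfig(stage="control_qc", seed=7, n_cells_per_well=500)
report = pipeline.run_control_qc(config)
print("Z' =", round(report["z_prime"], 3))
print("FCCP TMRM |KS|: %.3f +/- %.3f" % (
    report["parameters"]["tmrm_peripheral_integral"]["pos_ks_mean"],
    report["parameters"]["tmrm_peripheral_integral"]["pos_ks_sd"]))
print("FCCP viability:", round(report["positive_control_viability_mean"], 3))
print("gate: %.0f a.u. (%s)" % (report["gate"], report["gate_method"]))

config = pipeline.RunConfig(
    stage="secondary", seed=7, n_replicates=2, n_cells_per_well=300,
    compounds={"rotenoid": "I", "ionophore": "II", "galtoxin": "III",
               "inert": "IV", "protonophore": "V"})
bundle = pipeline.run_secondary_screen(config)
for compound, group in sorted(bundle["compound_groups"].items()):
    r = bundle["consistency"][compound]
    print(f"{compound:13s} -> group {group:3s} (replicate distance {r.max_distance:.3f})")
```

prints

```
Z' = 0.621
FCCP TMRM |KS|: 0.784 +/- 0.066
FCCP viability: 0.498
gate: 2113 a.u. (valley)
galtoxin      -> group III (replicate distance 0.011)
inert         -> group IV  (replicate distance 0.010)
ionophore     -> group II  (replicate distance 0.008)
protonophore  -> group V   (replicate distance 0.007)
rotenoid      -> group I   (replicate distance 0.006)
```

The Z′ of ~0.62 says positive and negative controls are cleanly separated on
the KS scale; FCCP wells lose most TMRM signal (|KS| ≈ 0.78) while about
half their cells stay TO-PRO-3-negative, the hallmark of an uncoupler; and
each simulated compound is recovered in its mechanistic group with highly
reproducible replicates (Pearson distances ≪ 0.2). The `bundle` also carries
the full distance matrix, dendrogram (Newick), MDS coordinates and a
structured exclusion log; `pipeline.write_secondary_bundle(bundle, "out/")`
writes everything as plain text.

The same stages are available from the shell:

```sh
scritscreen layout --template control --out layout.yaml
scritscreen simulate --layout layout.yaml --seed 1 --out plate.tsv
scritscreen stats --features plate.tsv --layout layout.yaml --out wells.tsv --qc qc.json
scritscreen scrit --wellstats wells.tsv --out scrit.tsv
scritscreen classify --scrit scrit.tsv --out results/
```

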