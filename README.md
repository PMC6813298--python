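# rsgica

Group spatial ICA for awake-animal resting-state fMRI — a tested,
reusable implementation of the analysis pipeline used to map
resting-state networks (RSNs) in unrestrained dogs: temporal denoising,
temporal-concatenation group ICA with GICA1 back-projection,
dual-FDR-thresholded component maps, rule-based artifact screening, and
split-half Dice-coefficient reproducibility.

It is written for researchers who want to run or scrutinise this class
of pipeline without scanner data: a synthetic multi-subject phantom with
known ground truth reproduces the study design (22 subjects × 2 runs,
139 volumes at TR 2.64 s with the first 5 discarded, 0.01–0.1 Hz source
dynamics, WM/CSF nuisance structure, motion traces, and edge-ring /
vessel / susceptibility artifact sources), so every stage is exercisable
in seconds to minutes on a laptop.

## The method

Given runs $Y_s \in \mathbb{R}^{t_s \times V}$ (preprocessed: dummy
discard, motion QC against 2 mm/2° limits, 4 mm FWHM smoothing, linear
detrend, 0.01–0.1 Hz band-pass, regression of WM/CSF means and the six
realignment parameters):

1. **Variance normalization** — every voxel time series to zero mean,
   unit variance, per run.
2. **Temporal concatenation** — $Y = [Y_1; \dots; Y_n] \in
   \mathbb{R}^{T \times V}$ with row provenance.
3. **Group PCA** to the model order $k$ (top-$k$ temporal subspace).
4. **fastICA** (logcosh contrast, symmetric decorrelation) for maximally
   spatially independent group maps $S \in \mathbb{R}^{k \times V}$.
5. **GICA1 back-projection** — the concatenated mixing $A = Y S^+$ is
   partitioned by run; subject maps are $S_s = A_s^{+} Y_s$, averaged
   across a subject's runs.
6. **Group inference** — per component, a one-sample t-test over subject
   maps; voxel-wise Benjamini–Hochberg FDR ($q < 0.001$), 26-connectivity
   clusters, and a cluster-extent FDR ($q < 0.005$) from a sign-flip
   maximum-extent null.
7. **Screening** — three codified artifact rules (susceptibility-region
   cluster centres, brain-edge ring fraction, vessel-mask Dice).
8. **Reproducibility** — split the study into first-run and second-run
   halves, re-decompose each, label components against the full
   decomposition by maximum Dice similarity coefficient
   $\mathrm{DSC}(A,B) = 2|A\cap B|/(|A|+|B|)$ with a 0.3 match
   threshold, and report the cross-half DSC per label (good if > 0.25).

## Worked example

`examples/05_published_worked_example.py` replays the bundled split-half
DSC matrices of a published 22-dog awake resting-state study (15
reference components A–O) through the match-and-label algorithm:

```
half 1: matched ABCDEFGHIJKLMN | unmatched O | fresh letters for 1 component(s)
half 2: matched ABCDFGHIJKLN | unmatched E,M,O | fresh letters for 3 component(s)

cross-half consistency of the matched labels:
label candidate_1 candidate_2  dsc  good
    A           A           A 0.58  True
    B           B           B 0.15 False
    ...
    F           F           F 0.16 False
    ...
    N           N           N 0.52  True
```

Fourteen components find a match in the first half with only O (the
motion-ring artifact) unmatched; E, M and O go unmatched in the second
half; and all matched labels are consistent across halves (DSC > 0.25)
except B (0.15) and F (0.16).

`examples/02_group_ica_recovery.py` runs the full pipeline on a phantom
and prints, per planted source, the best-matching estimated component
and its spatial correlation — networks recover at
$|r| \ge 0.8$ under the default study conditions:

```
 source                   label  component  abs_corr
      0                 network          2  0.916113
      1                 network          5  0.904496
      2                 network          4  0.856961
      3                 network          3  0.802173
      4           ring_artifact          0  0.797482
      5         vessel_artifact          1  0.872457
      6 susceptibility_artifact          6  0.807829
```

## Command line

The same stages are available as a thin CLI operating on a work
directory:

```
rsgica simulate   --workdir demo --subjects 22 --seed 11
rsgica preprocess --workdir demo
rsgica gica       --workdir demo -k 15
rsgica maps       --workdir demo -k 15
rsgica screen     --workdir demo -k 15
rsgica reproduce  --workdir demo -k 15
rsgica report     --workdir demo -k 15
```

Every stage writes the exact configuration it used next to its outputs;
re-running with the same seed reproduces them bit for bit.

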