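# glycocap

Information-theoretic analysis of glycan–lectin signaling channels from
dose-indexed single-cell fluorescence data.

Immune cells read glycan-encoded information through lectin receptors (e.g.
the C-type lectins dectin-1, dectin-2, MINCLE, MCL, DC-SIGN) that signal to
NF-κB. With an NF-κB–driven GFP reporter, a receptor's signaling pathway
becomes a noisy communication channel: the input X is the stimulant dose, the
output Y is per-cell fluorescence measured by flow cytometry. `glycocap`
quantifies how much information such a channel transmits and why, for anyone
analyzing dose-ladder single-cell reporter data (flow cytometry FCS files or
per-cell CSVs plus a sample sheet).

## What it computes

**Channel capacity.** The per-cell outputs at each dose are binned on a
rectangular grid (dose index *i*, output bin *j*; counts N_ij, total N_t).
From the empirical conditional P(j|i) = N_ij / N_i, mutual information

    I(X;Y) = H(X) + H(Y) − H(X,Y)        [bits]

is maximized over input distributions with the Blahut–Arimoto algorithm,
giving the capacity C = max_p(x) I(X;Y). The positive finite-sample bias of
the plug-in estimate is removed by re-estimating on subsamples and
extrapolating capacity linearly in 1/N to the infinite-data intercept;
bootstrap resampling of cells within each dose gives a 95% CI. A
capacity-versus-maximum-dose curve re-estimates C on truncated dose ladders
to localize where a channel earns its information.

**Signal/noise decomposition.** With mean_i and var_i the per-dose mean and
variance of the (log-scale) output,

    signal power = Var_i(mean_i),  noise power = E_i(var_i),  SNR = signal/noise.

**Dose–response.** Four-parameter logistic fits
y = bottom + (top − bottom) / (1 + (EC50/x)^hill) give EC50 sensitivity;
EC50s of two conditions are compared with the extra-sum-of-squares F test,
and per-replicate metrics across conditions with exact two-sided Wilcoxon
rank-sum tests.

**Synthetic reporter data.** A two-component lognormal mixture generator
reproduces the broad, overlapping stimulated/unstimulated populations of
NF-κB reporters with 4PL dose-dependent activation; a known-channel mode
samples from an explicit conditional Q(j|i) whose true capacity is computable
analytically, so estimator accuracy is measurable exactly.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
six-condition receptor panel (12 half-log doses, 1000 cells/dose, 3
replicates):

```
python analysis/01_simulate_reporter_panel.py
python analysis/02_estimate_capacity.py
python analysis/03_noise_decomposition.py
python analysis/04_dose_response.py
python analysis/05_compare_channels.py
```

`02_estimate_capacity.py` prints, for example:

```
channel capacity (bits) per condition, mean +- sd over replicates:
                           mean    std
receptor       ligand
TNFaR          TNFa       0.796  0.021
dectin-1       FurFurMan  0.664  0.004
MINCLE         TDB        0.631  0.026
dectin-2       FurFurMan  0.549  0.024
dectin-2+MCL   invertase  0.543  0.025
dectin-2-alone invertase  0.419  0.025
```

— the cytokine-receptor-like channel transmits the most dose information and
the weak lectin channel the least, even though all are read out through the
same reporter. `03` shows the weak channel is the one whose noise power
exceeds its signal power (SNR 0.63 vs 1.13 for the strong channel), and `04`
recovers the 10-fold EC50 sensitization built into the co-receptor condition
(measured fold change 9.8, extra-sum-of-squares F test p = 5e-41). `05`
shows the co-receptor channel wins its capacity advantage specifically at low
maximal doses (0.15 vs 0.01 bits with the ladder truncated at 0.1 dose
units), converging with the single-receptor channel once saturating doses are
included.

The same stages run on real data through the CLI:

```
glycocap capacity --sample-sheet sheet.csv --events-dir data/ \
    --bins auto --bootstrap 100 --seed 1 --outdir results/
glycocap noise --sample-sheet sheet.csv --outdir results/
glycocap run --config run.toml          # full configured pipeline
```

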