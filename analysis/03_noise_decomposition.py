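#!/usr/bin/env python
"""Decompose each channel into signal power and noise power.

Signal power: variance across doses of the per-dose mean log10 output.
Noise power: mean across doses of the per-dose variance.  A channel whose
noise power exceeds its signal power (SNR < 1) transmits little dose
information however bright its maximal response is.

Writes results/noise.csv and tests the weak channel's SNR against the
strong channels (two-sided Wilcoxon rank-sum on per-replicate SNRs).
"""

from pathlib import Path

import pandas as pd

from glycocap import noise_power, pipeline

import importlib.util as _ilu

_spec = _ilu.spec_from_file_location(
    "estimate_capacity_driver", Path(__file__).parent / "02_estimate_capacity.py")
_mod = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
load_panel = _mod.load_panel


def main() -> None:
    datasets = load_panel()
    rows = []
    for ds in datasets:
        dec = noise_power.decompose(ds)
        receptor, ligand, rep = ds.condition
        rows.append(dict(receptor=receptor, ligand=ligand, replicate=rep,
                         signal_power=dec.signal_power,
                         noise_power=dec.noise_power, snr=dec.snr))
    df = pd.DataFrame(rows)
    Path("results").mkdir(exist_ok=True)
    df.to_csv("results/noise.csv", index=False,
              float_format="%.6g", lineterminator="\n")
    print("signal/noise decomposition per condition (means over replicates):")
    print(df.groupby(["receptor", "ligand"], sort=False)
          [["signal_power", "noise_power", "snr"]].mean().round(3).to_string())

    weak = df[df.receptor == "dectin-2"]["snr"]
    strong = df[df.receptor == "TNFaR"]["snr"]
    stat, p = pipeline.wilcoxon_rank_sum(weak, strong)
    print(f"\ndectin-2 vs TNFaR SNR: rank-sum={stat:g}, two-sided p={p:.3g}")
    print("wrote results/noise.csv")


if __name__ == "__main__":
    main()
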