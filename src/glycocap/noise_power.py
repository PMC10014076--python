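"""Signal/noise power decomposition of a dose-response channel.

Signal power is the variation across doses of the per-dose mean output
(population variance, 1/D); noise power is the average across doses of the
per-dose output variance.  Their ratio (SNR) summarizes how far dose-driven
shifts in the mean stand out above within-dose cell-to-cell variability, on
the same transformed scale used for capacity estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import DomainError, SampleSizeError
from .flow_data import DoseResponseDataset

__all__ = ["NoiseDecomposition", "decompose", "snr_compare"]


@dataclass
class NoiseDecomposition:
    doses: np.ndarray
    mean_i: np.ndarray
    var_i: np.ndarray
    signal_power: float
    noise_power: float
    snr: float
    condition: tuple[str, str, int] | None = None


def decompose(
    dataset: DoseResponseDataset,
    across_dose_ddof: int = 0,
) -> NoiseDecomposition:
    """Decompose a dataset into signal power, noise power and SNR.

    Per-dose variances use the unbiased (ddof=1) estimator; the variance of
    the per-dose means across doses divides by the number of doses D
    (``across_dose_ddof=0``) by default — doses are the full input alphabet,
    not a sample from one.  Doses are unweighted throughout.
    """
    if dataset.n_doses < 2:
        raise SampleSizeError("noise decomposition needs >= 2 doses")
    small = dataset.cells_per_dose < 2
    if small.any():
        raise SampleSizeError(
            f"doses {dataset.doses[small].tolist()} have < 2 cells; variance undefined"
        )
    mean_i = np.array([y.mean() for y in dataset.outputs_per_dose])
    var_i = np.array([y.var(ddof=1) for y in dataset.outputs_per_dose])
    signal_power = float(mean_i.var(ddof=across_dose_ddof))
    noise_power = float(var_i.mean())
    snr = signal_power / noise_power if noise_power > 0 else float("inf")
    return NoiseDecomposition(
        doses=dataset.doses.copy(),
        mean_i=mean_i,
        var_i=var_i,
        signal_power=signal_power,
        noise_power=noise_power,
        snr=float(snr),
        condition=dataset.condition,
    )


def snr_compare(
    a: Sequence[NoiseDecomposition],
    b: Sequence[NoiseDecomposition],
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum on per-replicate SNR values."""
    from .pipeline import wilcoxon_rank_sum

    if len(a) == 0 or len(b) == 0:
        raise DomainError("snr_compare requires at least one decomposition per group")
    return wilcoxon_rank_sum([d.snr for d in a], [d.snr for d in b])
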