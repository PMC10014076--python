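"""End-to-end orchestration and group-comparison statistics.

``run`` executes the stages of the analysis (simulate or load → capacity →
noise decomposition → dose-response → comparisons) under one TOML-style
config, writing tidy CSVs (6 significant digits, fixed column order, LF line
endings — byte-identical across re-runs at a fixed seed), a JSON manifest and
a plain-text log.

The comparison unit is the biological replicate: one capacity / SNR / EC50
value per replicate, compared across conditions with a two-sided Wilcoxon
rank-sum test (exact by enumeration for small samples) or Student's t test.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from . import dose_response as dr
from . import flow_data, infocap, noise_power
from .exceptions import ConfigError, DomainError

__all__ = [
    "wilcoxon_rank_sum",
    "students_t_test",
    "TTestResult",
    "ComparisonResult",
    "run",
    "load_config",
]

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX_N = 12


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank sum of a, p value).

    Exact null distribution by enumeration of all C(n_a+n_b, n_a) rank
    assignments (midranks for ties) when the pooled size is at most 12;
    otherwise the normal approximation with tie and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("wilcoxon_rank_sum requires two non-empty groups")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[:n_a].sum())
    if n_a + n_b <= EXACT_WILCOXON_MAX_N:
        sums = np.array(
            [sum(c) for c in itertools.combinations(ranks, n_a)]
        )
        eps = 1e-9
        p_low = np.mean(sums <= w_obs + eps)
        p_high = np.mean(sums >= w_obs - eps)
        p = min(1.0, 2.0 * min(p_low, p_high))
        return w_obs, float(p)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return w_obs, float(res.pvalue)


class TTestResult(NamedTuple):
    statistic: float
    p_value: float
    degenerate: bool


def students_t_test(a, b) -> TTestResult:
    """Unpaired two-tailed Student's t test with pooled variance.

    Zero pooled variance is degenerate: equal means give p = 1, unequal means
    give the limit p -> 0, both flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("t test requires >= 2 values per group")
    n_a, n_b = a.size, b.size
    pooled_var = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / (
        n_a + n_b - 2
    )
    if pooled_var == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, True)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return TTestResult(sign * float("inf"), 0.0, True)
    t = (a.mean() - b.mean()) / np.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    p = 2.0 * stats.t.sf(abs(t), n_a + n_b - 2)
    return TTestResult(float(t), float(p), False)


@dataclass
class ComparisonResult:
    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    test: str


# ---------------------------------------------------------------------------
# Config handling
# ---------------------------------------------------------------------------

VALID_METRICS = ("capacity_bits", "snr", "ec50")


def load_config(path) -> dict:
    """Read a TOML run config."""
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()


def _selector_label(sel: dict) -> str:
    return "/".join(str(sel[k]) for k in sorted(sel))


def _matches(sel: dict, condition: tuple[str, str, int]) -> bool:
    receptor, ligand, replicate = condition
    fields = {"receptor": receptor, "ligand": ligand, "replicate": replicate}
    return all(str(fields.get(k)) == str(v) for k, v in sel.items())


def _validate_config(config: dict) -> None:
    inp = config.get("input", {})
    mode = inp.get("mode")
    if mode not in ("simulate", "load"):
        raise ConfigError("input.mode must be 'simulate' or 'load'")
    stochastic = mode == "simulate" or config.get("capacity", {}).get(
        "n_bootstrap", 0
    ) > 0 or config.get("capacity", {}).get("bias_correction", True)
    if stochastic and "seed" not in config:
        raise ConfigError("a top-level seed is required when stochastic steps run")
    for comp in config.get("comparisons", []):
        if comp.get("metric") not in VALID_METRICS:
            raise ConfigError(
                f"comparison metric must be one of {VALID_METRICS}, "
                f"got {comp.get('metric')!r}"
            )
        if "group_a" not in comp or "group_b" not in comp:
            raise ConfigError("each comparison needs group_a and group_b selectors")


def _conditions_from_config(config: dict) -> list[tuple[str, str, int]]:
    inp = config["input"]
    if inp["mode"] == "simulate":
        conditions = []
        for spec in inp.get("conditions", []):
            for rep in range(1, int(spec.get("n_replicates", 1)) + 1):
                conditions.append((spec["receptor"], spec["ligand"], rep))
        if not conditions:
            raise ConfigError("simulate mode requires [[input.conditions]] entries")
        return conditions
    sheet = flow_data.read_sample_sheet(inp["sample_sheet"])
    return sheet.conditions()


def _simulate_datasets(config: dict) -> list[flow_data.DoseResponseDataset]:
    from . import synthetic

    rng = np.random.default_rng(int(config["seed"]))
    datasets = []
    for spec in config["input"]["conditions"]:
        n_reps = int(spec.get("n_replicates", 1))
        mixture_keys = {
            "n_cells_per_dose", "basal_log_mean", "basal_log_sd",
            "active_log_mean", "active_log_sd", "p_min", "p_max",
            "ec50", "hill",
        }
        kwargs = {k: spec[k] for k in mixture_keys if k in spec}
        if "doses" in spec:
            kwargs["doses"] = np.asarray(spec["doses"], dtype=float)
        for rep in range(1, n_reps + 1):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            cfg = synthetic.MixtureReporterConfig(seed=sub_seed, **kwargs)
            datasets.append(
                synthetic.simulate_mixture_reporter(
                    cfg, condition=(spec["receptor"], spec["ligand"], rep)
                )
            )
    return datasets


def _load_datasets(config: dict) -> list[flow_data.DoseResponseDataset]:
    inp = config["input"]
    sheet = flow_data.read_sample_sheet(inp["sample_sheet"])
    events_dir = Path(inp.get("events_dir", Path(inp["sample_sheet"]).parent))
    fmt = inp.get("format", "csv")
    tables = {}
    for _, row in sheet.table.iterrows():
        sid = row["sample_id"]
        if sid in tables:
            continue
        if fmt == "csv":
            path = events_dir / f"{sid}.csv"
            tables[sid] = flow_data.read_events_csv(path, [row["output_channel"]])
        else:
            tables[sid] = flow_data.read_fcs(events_dir / sid)
        tables[sid].sample_id = sid
    transform = config.get("transform", {})
    return flow_data.assemble_dataset(
        sheet, tables,
        transform=transform.get("method", "log10_floor"),
        cofactor=transform.get("cofactor"),
    )


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def run(config: dict, outdir=None) -> dict:
    """Execute the configured stages; returns the manifest dictionary.

    Re-running with an identical config (and seed) writes byte-identical
    CSVs.  A stage failure aborts the run with the stage name; outputs
    written so far are kept and the manifest is marked FAILED.
    """
    _validate_config(config)
    outdir = Path(outdir or config.get("output", {}).get("dir", "results"))
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("glycocap")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.get("seed"),
        "outputs": [],
        "status": "RUNNING",
        "started_unix": int(time.time()),
    }
    try:
        from . import __version__

        manifest["version"] = __version__

        conditions = _conditions_from_config(config)
        for comp in config.get("comparisons", []):
            for key in ("group_a", "group_b"):
                if not any(_matches(comp[key], c) for c in conditions):
                    raise ConfigError(
                        f"comparison selector {comp[key]} matches no condition"
                    )

        stage = "input"
        logger.info("stage %s: assembling datasets", stage)
        if config["input"]["mode"] == "simulate":
            datasets = _simulate_datasets(config)
        else:
            datasets = _load_datasets(config)

        cap_rows, noise_rows, dr_rows = [], [], []
        cap_by_cond: dict[tuple, float] = {}
        snr_by_cond: dict[tuple, float] = {}
        ec50_by_cond: dict[tuple, float] = {}
        diagnostics: dict[str, dict] = {}

        cap_cfg = config.get("capacity", {"enabled": True})
        if cap_cfg.get("enabled", True):
            stage = "capacity"
            logger.info("stage %s", stage)
            seed_rng = np.random.default_rng(int(config.get("seed", 0)) + 1)
            for ds in datasets:
                est = infocap.estimate_capacity(
                    ds,
                    n_bins=cap_cfg.get("bins", "auto"),
                    bias_correction=cap_cfg.get("bias_correction", True),
                    n_bootstrap=int(cap_cfg.get("n_bootstrap", 0)),
                    seed=int(seed_rng.integers(0, 2**31 - 1)),
                )
                receptor, ligand, rep = ds.condition
                cap_rows.append(dict(
                    receptor=receptor, ligand=ligand, replicate=rep,
                    n_bins=est.n_bins, bits=est.bits,
                    ci_low=est.ci_low, ci_high=est.ci_high,
                ))
                cap_by_cond[ds.condition] = est.bits
                diagnostics[f"{receptor}/{ligand}/{rep}"] = {
                    "bias_curve": est.bias_curve,
                    "optimal_input": est.optimal_input.tolist(),
                    "uncorrected_bits": est.uncorrected_bits,
                }
            df = pd.DataFrame(cap_rows, columns=[
                "receptor", "ligand", "replicate", "n_bins",
                "bits", "ci_low", "ci_high"])
            _write_csv(df, outdir / "capacity.csv")
            manifest["outputs"].append("capacity.csv")
            with open(outdir / "capacity_diagnostics.json", "w") as fh:
                json.dump(diagnostics, fh, indent=1, sort_keys=True)
            manifest["outputs"].append("capacity_diagnostics.json")

        if config.get("noise", {}).get("enabled", True):
            stage = "noise"
            logger.info("stage %s", stage)
            for ds in datasets:
                dec = noise_power.decompose(ds)
                receptor, ligand, rep = ds.condition
                noise_rows.append(dict(
                    receptor=receptor, ligand=ligand, replicate=rep,
                    signal_power=dec.signal_power,
                    noise_power=dec.noise_power, snr=dec.snr,
                ))
                snr_by_cond[ds.condition] = dec.snr
            df = pd.DataFrame(noise_rows, columns=[
                "receptor", "ligand", "replicate",
                "signal_power", "noise_power", "snr"])
            _write_csv(df, outdir / "noise.csv")
            manifest["outputs"].append("noise.csv")

        if config.get("dose_response", {}).get("enabled", True):
            stage = "dose_response"
            logger.info("stage %s", stage)
            response = config.get("dose_response", {}).get(
                "response", "geometric_mean")
            for ds in datasets:
                x, y = dr.dose_response_points(ds, response=response)
                fit = dr.fit_4pl(x, y)
                receptor, ligand, rep = ds.condition
                dr_rows.append(dict(
                    receptor=receptor, ligand=ligand, replicate=rep,
                    bottom=fit.bottom, top=fit.top, ec50=fit.ec50,
                    hill=fit.hill, rss=fit.rss, converged=fit.converged,
                ))
                if fit.converged:
                    ec50_by_cond[ds.condition] = fit.ec50
            df = pd.DataFrame(dr_rows, columns=[
                "receptor", "ligand", "replicate", "bottom", "top",
                "ec50", "hill", "rss", "converged"])
            _write_csv(df, outdir / "dose_response.csv")
            manifest["outputs"].append("dose_response.csv")

        comp_rows = []
        if config.get("comparisons"):
            stage = "comparisons"
            logger.info("stage %s", stage)
            by_metric = {
                "capacity_bits": cap_by_cond, "snr": snr_by_cond,
                "ec50": ec50_by_cond,
            }
            for comp in config["comparisons"]:
                values = by_metric[comp["metric"]]
                va = [v for c, v in values.items() if _matches(comp["group_a"], c)]
                vb = [v for c, v in values.items() if _matches(comp["group_b"], c)]
                if not va or not vb:
                    raise ConfigError(
                        f"comparison on {comp['metric']} resolved to an empty group "
                        "(was the producing stage enabled?)"
                    )
                stat, p = wilcoxon_rank_sum(va, vb)
                comp_rows.append(dict(
                    metric=comp["metric"],
                    group_a=_selector_label(comp["group_a"]),
                    group_b=_selector_label(comp["group_b"]),
                    n_a=len(va), n_b=len(vb),
                    statistic=stat, p_value=p, test="wilcoxon_rank_sum",
                ))
            df = pd.DataFrame(comp_rows, columns=[
                "metric", "group_a", "group_b", "n_a", "n_b",
                "statistic", "p_value", "test"])
            _write_csv(df, outdir / "comparisons.csv")
            manifest["outputs"].append("comparisons.csv")

        manifest["status"] = "OK"
    except Exception as exc:
        failed_stage = locals().get("stage", "setup")
        per_dataset = locals().get("stage") in ("capacity", "noise", "dose_response")
        failed_cond = locals().get("ds") if per_dataset else None
        manifest["status"] = "FAILED"
        manifest["failed_stage"] = failed_stage
        manifest["error"] = str(exc)
        if failed_cond is not None:
            manifest["failed_condition"] = list(failed_cond.condition)
            exc.add_note(
                f"stage {failed_stage!r} failed on condition "
                f"{failed_cond.condition}"
            )
        else:
            exc.add_note(f"stage {failed_stage!r} failed")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        root.removeHandler(handler)
        handler.close()
        raise
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    manifest["outputs"].append("manifest.json")
    root.removeHandler(handler)
    handler.close()
    return manifest
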