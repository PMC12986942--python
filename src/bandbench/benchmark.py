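"""End-to-end benchmark: simulate a cohort, apply the four filters, score
band power and SNR per subject, and run the repeated-measures statistics."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .errors import ConfigurationError, DataError
from .expfilter import ExpBandpassParams, exp_bandpass_filter
from .iir import IIRDesignSpec, apply_causal, apply_zero_phase, design_iir
from .rmstats import (AnovaResult, MetricsTable, PairwiseResult,
                      bonferroni_posthoc, rm_anova)
from .simulate import (EEGSimSpec, IMUSimSpec, generate_eeg_like,
                       generate_imu_like, grand_average)
from .spectral import WelchSpec, band_power, band_snr, residual_snr, welch_psd
from .timeseries import BandSpec, TimeSeries

__all__ = [
    "FILTER_NAMES",
    "BenchmarkConfig",
    "BenchmarkReport",
    "build_filter_bank",
    "run_benchmark",
    "write_report",
    "subject_seed",
]

log = logging.getLogger("bandbench")

FILTER_NAMES = ("butterworth", "chebyshev1", "elliptic", "exponential")

_MODALITY_DEFAULTS = {
    "eeg": {"fs": 512.0, "band": (0.5, 50.0), "cheby_rp": 0.5,
            "ellip_rp": 1.0, "ellip_rs": 40.0},
    "imu": {"fs": 128.0, "band": (0.5, 5.0), "cheby_rp": 1.0,
            "ellip_rp": 1.0, "ellip_rs": 40.0},
}


@dataclass(frozen=True)
class BenchmarkConfig:
    """Everything the pipeline needs; the report is a pure function of it."""

    modality: str = "imu"
    n_subjects: int = 20
    seed: int = 0
    duration_s: float = 60.0
    band: BandSpec | None = None        # None -> modality default
    filters: tuple[str, ...] = FILTER_NAMES
    mode: str = "zero_phase"            # or "causal" (IIR filters only)
    snr_mode: str = "both"              # band_ratio | residual | both
    welch: WelchSpec = field(default_factory=WelchSpec)

    def __post_init__(self) -> None:
        if self.modality not in _MODALITY_DEFAULTS:
            raise ConfigurationError(f"unknown modality {self.modality!r}")
        if self.n_subjects < 2:
            raise ConfigurationError("need at least 2 subjects")
        if self.mode not in ("zero_phase", "causal"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.snr_mode not in ("band_ratio", "residual", "both"):
            raise ConfigurationError(f"unknown snr_mode {self.snr_mode!r}")
        for name in self.filters:
            if name not in FILTER_NAMES:
                raise ConfigurationError(f"unknown filter {name!r}")

    @property
    def fs(self) -> float:
        return _MODALITY_DEFAULTS[self.modality]["fs"]

    def resolved_band(self) -> BandSpec:
        if self.band is not None:
            band = self.band
        else:
            band = BandSpec(*_MODALITY_DEFAULTS[self.modality]["band"])
        band.validate_against(self.fs)
        return band


@dataclass
class BenchmarkReport:
    metrics: dict[str, MetricsTable]
    anova: dict[str, AnovaResult]
    posthoc: dict[str, list[PairwiseResult]]
    provenance: dict


def subject_seed(master_seed: int, index: int) -> int:
    """Fixed counter scheme: extending the cohort never reseeds old subjects."""
    return (master_seed * 1_000_003 + index) % (2 ** 63)


def build_filter_bank(config: BenchmarkConfig):
    """Map filter name -> callable(TimeSeries) -> TimeSeries for the config."""
    defaults = _MODALITY_DEFAULTS[config.modality]
    band = config.resolved_band()
    fs = config.fs
    apply_iir = apply_zero_phase if config.mode == "zero_phase" else apply_causal

    def iir_runner(spec: IIRDesignSpec):
        filt = design_iir(spec)
        return lambda ts: apply_iir(filt, ts)

    bank = {}
    for name in config.filters:
        if name == "butterworth":
            bank[name] = iir_runner(IIRDesignSpec("butterworth", 4, band, fs))
        elif name == "chebyshev1":
            bank[name] = iir_runner(
                IIRDesignSpec("chebyshev1", 4, band, fs, rp_db=defaults["cheby_rp"]))
        elif name == "elliptic":
            bank[name] = iir_runner(
                IIRDesignSpec("elliptic", 4, band, fs, rp_db=defaults["ellip_rp"],
                              rs_db=defaults["ellip_rs"]))
        elif name == "exponential":
            params = ExpBandpassParams()
            bank[name] = lambda ts, _b=band, _p=params: exp_bandpass_filter(ts, _b, _p)
    return bank


def _simulate_subject(config: BenchmarkConfig, index: int) -> TimeSeries:
    seed = subject_seed(config.seed, index)
    if config.modality == "eeg":
        spec = EEGSimSpec(duration_s=config.duration_s)
        return generate_eeg_like(spec, seed)
    spec = IMUSimSpec(duration_s=config.duration_s)
    return generate_imu_like(spec, seed)


def run_benchmark(config: BenchmarkConfig, filter_bank=None) -> BenchmarkReport:
    """Run the full pipeline and return the statistics report.

    Per subject: simulate -> grand-average -> filter (each bank entry) ->
    Welch PSD -> band power and SNR.  Any per-subject failure is logged and
    that subject is dropped; fewer than 2 survivors aborts.
    """
    band = config.resolved_band()
    if filter_bank is None:
        filter_bank = build_filter_bank(config)

    outcomes = ["band_power"]
    if config.snr_mode in ("band_ratio", "both"):
        outcomes.append("snr_band")
    if config.snr_mode in ("residual", "both"):
        outcomes.append("snr_residual")

    records: dict[str, list] = {name: [] for name in outcomes}
    n_ok = 0
    for i in range(config.n_subjects):
        sid = f"sub{i:03d}"
        try:
            raw = grand_average(_simulate_subject(config, i))
            for fname, apply_filter in filter_bank.items():
                filtered = apply_filter(raw)
                psd = welch_psd(filtered, config.welch)
                records["band_power"].append(
                    (sid, fname, band_power(psd, band)))
                if "snr_band" in records:
                    records["snr_band"].append((sid, fname, band_snr(psd, band)))
                if "snr_residual" in records:
                    records["snr_residual"].append(
                        (sid, fname, residual_snr(raw, filtered)))
            n_ok += 1
        except Exception:  # noqa: BLE001 - exclusion, not failure
            log.exception("subject %s failed; excluding", sid)
    if n_ok < 2:
        raise DataError(f"only {n_ok} subjects survived the pipeline")

    metrics = {k: MetricsTable.from_records(v) for k, v in records.items()}
    anova = {k: rm_anova(t) for k, t in metrics.items()}
    posthoc = {k: bonferroni_posthoc(t) for k, t in metrics.items()}

    provenance = {
        "version": __version__,
        "config": _config_dict(config),
        "subject_seeds": {f"sub{i:03d}": subject_seed(config.seed, i)
                          for i in range(config.n_subjects)},
    }
    return BenchmarkReport(metrics=metrics, anova=anova, posthoc=posthoc,
                           provenance=provenance)


def _config_dict(config: BenchmarkConfig) -> dict:
    out = dataclasses.asdict(config)
    band = config.resolved_band()
    out["band"] = [band.f_lo, band.f_hi]
    out["filters"] = list(config.filters)
    out["welch"] = dataclasses.asdict(config.welch)
    return out


def write_report(report: BenchmarkReport, out_dir) -> dict[str, str]:
    """Emit metrics.csv, anova.csv, posthoc.csv and provenance.json.

    Output is byte-stable for identical reports.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    frames = []
    for outcome, table in report.metrics.items():
        df = table.data.copy()
        df.insert(2, "outcome", outcome)
        frames.append(df)
    metrics = pd.concat(frames, ignore_index=True)[
        ["subject", "filter", "outcome", "value"]]
    paths["metrics"] = os.path.join(out_dir, "metrics.csv")
    metrics.to_csv(paths["metrics"], index=False)

    anova_rows = []
    for outcome, res in report.anova.items():
        anova_rows.append({
            "outcome": outcome, "F": res.F, "df1": res.df1, "df2": res.df2,
            "p": res.p, "eta_p2": res.eta_p2, "ss_effect": res.ss_effect,
            "ss_error": res.ss_error, "ss_subject": res.ss_subject,
            "n_subjects": res.n_subjects,
        })
    paths["anova"] = os.path.join(out_dir, "anova.csv")
    pd.DataFrame(anova_rows).to_csv(paths["anova"], index=False)

    posthoc_rows = []
    for outcome, results in report.posthoc.items():
        for r in results:
            posthoc_rows.append({
                "outcome": outcome, "filter_a": r.pair[0], "filter_b": r.pair[1],
                "mean_diff": r.mean_diff, "t": r.t, "df": r.df, "p": r.p,
                "alpha_adj": r.alpha_adj, "significant": r.significant,
            })
    paths["posthoc"] = os.path.join(out_dir, "posthoc.csv")
    columns = ["outcome", "filter_a", "filter_b", "mean_diff", "t", "df", "p",
               "alpha_adj", "significant"]
    pd.DataFrame(posthoc_rows, columns=columns).to_csv(paths["posthoc"],
                                                       index=False)

    paths["provenance"] = os.path.join(out_dir, "provenance.json")
    with open(paths["provenance"], "w") as fh:
        json.dump(report.provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
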