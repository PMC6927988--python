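"""End-to-end orchestration: simulate or load recordings, extract every
feature, and produce the two-group comparison report.

The report mirrors the standard intrinsic-excitability table: one row
per parameter with group means +/- SEM, per-parameter n (cells with a
computable value), the routed test and its p-value — plus the same
comparison restricted to the prominent-H-current subgroup, and a
provenance block (config hash, seed, package version)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import CellRecording, read_archive
from .params import NeuronParams, ProtocolSpec
from .passive import FeatureUndefined, passive_features
from .phase import DEFAULT_CONVENTION, first_ap_of_train, slope_sd_ratio
from .simulate import simulate_cohort
from .spikes import extract_cell_features
from .stats import GroupSample, route_and_compare

__all__ = [
    "PipelineConfig",
    "GroupReport",
    "extract_features",
    "feature_table",
    "compare_groups",
    "run",
    "report_render",
]

#: feature columns that enter the comparison table, with display units
FEATURE_COLUMNS = {
    "rmp": "mV",
    "input_resistance": "MOhm",
    "sag": "fraction",
    "rheobase": "pA",
    "spike_latency": "ms",
    "threshold": "mV",
    "peak_amplitude": "mV",
    "half_width": "ms",
    "mahp": "mV",
    "dvdt_max": "mV/ms",
    "dvdt_min": "mV/ms",
    "n7_current": "pA",
    "isi_1": "ms",
    "isi_6": "ms",
    "accommodation_ratio": "ratio",
    "slope_sd_ratio": "ratio",
    "sd_slope_a": "mV/ms",
    "peak_slope_b": "mV/ms",
    "ais_component": "mV/ms",
}


@dataclass
class PipelineConfig:
    """Declarative configuration; exactly one input source.

    ``archive_dir`` loads every ``*.h5`` sweep archive below the
    directory; alternatively ``control_params``/``shifted_params`` run
    the simulator.
    """

    archive_dir: str | None = None
    control_params: NeuronParams | None = None
    shifted_params: NeuronParams | None = None
    n_per_group: int = 25
    inter_cell_variability: float = 0.1
    protocol: ProtocolSpec | None = None
    seed: int = 0
    group_labels: tuple = ("control", "shifted")
    rin_method: str = "step"
    phase_convention: str = DEFAULT_CONVENTION
    baseline_window_ms: float = 50.0
    steady_fraction: float = 0.2
    output_dir: str | None = None

    def __post_init__(self):
        sim = self.control_params is not None and self.shifted_params is not None
        if bool(self.archive_dir) == sim:
            raise ValueError(
                "configure exactly one input source: archive_dir or the "
                "simulator templates"
            )

    def to_jsonable(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        for key in ("control_params", "shifted_params"):
            if d[key] is not None:
                d[key] = d[key].to_dict()
        if d["protocol"] is not None:
            d["protocol"] = asdict(d["protocol"])
        d["group_labels"] = list(d["group_labels"])
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class GroupReport:
    features: pd.DataFrame
    comparison: pd.DataFrame
    subgroup_comparison: pd.DataFrame
    prominent_h_fraction: dict
    provenance: dict
    warnings: list = field(default_factory=list)


def extract_features(recording: CellRecording, config: PipelineConfig | None = None
                     ) -> dict:
    """One row of the per-cell feature table (NaN = not computable)."""
    cfg = config or PipelineConfig(control_params=NeuronParams(),
                                   shifted_params=NeuronParams())
    row: dict = {"cell_id": recording.cell_id, "group": recording.group}
    pf = passive_features(
        recording, window_ms=cfg.baseline_window_ms,
        steady_fraction=cfg.steady_fraction, rin_method=cfg.rin_method,
    )
    row["rmp"] = pf.rmp
    row["input_resistance"] = pf.input_resistance
    row["sag"] = pf.sag
    row["prominent_h"] = pf.prominent_h

    fs = extract_cell_features(recording)
    row["rheobase"] = fs.train.rheobase
    row["spike_latency"] = fs.train.spike_latency
    row["n7_current"] = fs.train.n7_current
    row["isi_1"] = fs.train.isi_1
    row["isi_6"] = fs.train.isi_6
    row["accommodation_ratio"] = fs.train.accommodation_ratio
    ap = fs.rheobase_ap
    for name, attr in (
        ("threshold", "threshold_voltage"), ("peak_amplitude", "peak_amplitude"),
        ("half_width", "half_width"), ("mahp", "mahp"),
        ("dvdt_max", "dvdt_max"), ("dvdt_min", "dvdt_min"),
    ):
        row[name] = getattr(ap, attr) if ap is not None else np.nan

    try:
        sweep, first_ap, approx = first_ap_of_train(recording)
        dec = slope_sd_ratio(sweep, first_ap, convention=cfg.phase_convention)
        row["slope_sd_ratio"] = dec.slope_sd_ratio
        row["sd_slope_a"] = dec.a
        row["peak_slope_b"] = dec.b
        row["ais_component"] = dec.ais_component
        row["phase_convention"] = dec.convention
        row["train_approximate"] = approx
    except FeatureUndefined:
        for name in ("slope_sd_ratio", "sd_slope_a", "peak_slope_b",
                     "ais_component"):
            row[name] = np.nan
        row["phase_convention"] = cfg.phase_convention
        row["train_approximate"] = None
    return row


def feature_table(recordings: list, config: PipelineConfig | None = None
                  ) -> pd.DataFrame:
    return pd.DataFrame([extract_features(r, config) for r in recordings])


def compare_groups(features: pd.DataFrame, label_a: str, label_b: str
                   ) -> pd.DataFrame:
    """One comparison row per feature column, using per-parameter
    available cells (n varies across rows)."""
    rows = []
    for col, unit in FEATURE_COLUMNS.items():
        if col not in features.columns:
            continue
        va = features.loc[features["group"] == label_a, col].dropna().to_numpy()
        vb = features.loc[features["group"] == label_b, col].dropna().to_numpy()
        if va.size < 1 or vb.size < 1:
            rows.append({"parameter": col, "unit": unit, "test": "NA",
                         "p_value": np.nan,
                         f"mean_{label_a}": np.nan, f"sem_{label_a}": np.nan,
                         f"n_{label_a}": va.size,
                         f"mean_{label_b}": np.nan, f"sem_{label_b}": np.nan,
                         f"n_{label_b}": vb.size})
            continue
        res = route_and_compare(GroupSample(label_a, va), GroupSample(label_b, vb))
        rows.append({
            "parameter": col, "unit": unit, "test": res.test,
            "statistic": res.statistic, "p_value": res.p_value,
            f"mean_{label_a}": res.summary_a.mean,
            f"sem_{label_a}": res.summary_a.sem,
            f"n_{label_a}": res.summary_a.n,
            f"mean_{label_b}": res.summary_b.mean,
            f"sem_{label_b}": res.summary_b.sem,
            f"n_{label_b}": res.summary_b.n,
        })
    return pd.DataFrame(rows)


def _load_recordings(config: PipelineConfig) -> list:
    if config.archive_dir is not None:
        paths = sorted(Path(config.archive_dir).glob("**/*.h5"))
        if not paths:
            raise FileNotFoundError(
                f"no *.h5 sweep archives under {config.archive_dir}")
        return [read_archive(p) for p in paths]
    protocol = config.protocol or ProtocolSpec.default_ladder()
    ctrl, shifted, _gt = simulate_cohort(
        config.control_params, config.shifted_params, config.n_per_group,
        config.inter_cell_variability, seed=config.seed, protocol=protocol,
        labels=tuple(config.group_labels),
    )
    return ctrl + shifted


def run(config: PipelineConfig) -> GroupReport:
    """Simulate/load -> extract -> compare.  Deterministic for a given
    config + seed; not-computable features propagate as NaN, never as
    silent zeros."""
    recordings = _load_recordings(config)
    feats = feature_table(recordings, config)
    label_a, label_b = config.group_labels
    for lab in (label_a, label_b):
        usable = feats.loc[feats["group"] == lab].drop(
            columns=["cell_id", "group"]).notna().any(axis=1).sum()
        if usable == 0:
            raise RuntimeError(
                f"group {lab!r} has zero usable cells; aborting report")
    comparison = compare_groups(feats, label_a, label_b)

    sub = feats[feats["prominent_h"] == True]  # noqa: E712  (NaN-safe)
    warnings_list = []
    if (sub["group"] == label_a).any() and (sub["group"] == label_b).any():
        subgroup = compare_groups(sub, label_a, label_b)
    else:
        subgroup = pd.DataFrame()
        warnings_list.append(
            "prominent-H subgroup empty in at least one group; subgroup "
            "comparison skipped")
    fractions = {}
    for lab in (label_a, label_b):
        g = feats.loc[feats["group"] == lab, "prominent_h"].dropna()
        fractions[lab] = {
            "n_prominent": int(g.sum()), "n_classified": int(g.size),
            "percent": float(100.0 * g.sum() / g.size) if g.size else np.nan,
        }
    provenance = {
        "package_version": __version__,
        "config": config.to_jsonable(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "n_cells": len(recordings),
    }
    return GroupReport(
        features=feats, comparison=comparison, subgroup_comparison=subgroup,
        prominent_h_fraction=fractions, provenance=provenance,
        warnings=warnings_list,
    )


def report_render(report: GroupReport, output_dir: str | Path) -> dict:
    """Write features.csv, comparison.csv, subgroup_comparison.csv and
    provenance.json; missing values render as NA."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("features", report.features),
        ("comparison", report.comparison),
        ("subgroup_comparison", report.subgroup_comparison),
    ):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, na_rep="NA")
        paths[name] = p
    prov = dict(report.provenance)
    prov["prominent_h_fraction"] = report.prominent_h_fraction
    prov["warnings"] = report.warnings
    p = out / "provenance.json"
    p.write_text(json.dumps(prov, indent=1, sort_keys=True, default=str))
    paths["provenance"] = p
    return paths
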