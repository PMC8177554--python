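"""End-to-end orchestration: records → windows → events → features →
statistics → cross-validated classification reports.

A run is a pure function of (input data, configuration, master seed).
Every random stage — simulation, fold splitting, ensemble resampling —
derives its generator from the master seed through a fixed seed-sequence
scheme, so rerunning a configuration reproduces every report byte for
byte.  Outputs per signal type: a feature CSV, a group-comparison CSV,
and one cross-validation JSON per requested model, plus a manifest of
dropped windows with reasons and a run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import events as ev
from . import features as ft
from . import io as gio
from . import preprocess as pp
from . import stats as st
from . import synthetic as syn

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    out_dir: str = "gaitdnd-run"
    seed: int = 0
    # input: either a simulation request or a record directory + manifest
    simulate_n_per_class: int | None = None
    simulate_duration_s: float = 300.0
    input_dir: str | None = None
    manifest: str | None = None
    dialect: str = "plain_text"
    # preprocessing
    trim_s: float = 15.0
    window_s: float = 30.0
    median_kernel: int = 5
    max_spike_fraction: float = 0.05
    exclude_file: str | None = None
    # event detection
    min_phase_s: float = ev.DEFAULT_MIN_PHASE_S
    min_cycles: int = 3
    # analysis
    signal_types: tuple = gio.SIGNAL_TYPES
    methods: tuple = clf.METHODS
    params: str = "default"       # "default" | "paper"
    n_cycles: int | None = None   # optional override for scaled runs
    cv_folds: int = 10
    run_stats: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.simulate_n_per_class is None and self.input_dir is None:
            raise ValueError("config needs simulate_n_per_class or input_dir")
        if self.input_dir is not None:
            if not Path(self.input_dir).is_dir():
                raise ValueError(f"input_dir {self.input_dir} does not exist")
            if self.manifest is not None and not Path(self.manifest).exists():
                raise ValueError(f"manifest {self.manifest} does not exist")
        if self.exclude_file is not None and not Path(self.exclude_file).exists():
            raise ValueError(f"exclude file {self.exclude_file} does not exist")
        if self.params not in ("default", "paper"):
            raise ValueError("params must be 'default' or 'paper'")
        for s in self.signal_types:
            if s not in gio.SIGNAL_TYPES:
                raise ValueError(f"unknown signal type {s!r}")
        for m in self.methods:
            if m not in clf.METHODS:
                raise ValueError(f"unknown method {m!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _derived_seed(master: int, *key: int) -> int:
    return int(
        np.random.SeedSequence([int(master), *key]).generate_state(1)[0]
        % (2**31)
    )


def _load_records(config: RunConfig) -> list[gio.GaitRecord]:
    if config.simulate_n_per_class is not None:
        cohort = syn.simulate_cohort(
            config.simulate_n_per_class,
            seed=_derived_seed(config.seed, 1),
            duration_s=config.simulate_duration_s,
        )
        return [record for record, _ in cohort]
    manifest = gio.read_manifest(config.manifest) if config.manifest else None
    suffix = {"plain_text": (".txt", ".tsv", ".csv"), "wfdb": (".hea",)}
    skip = {Path(config.manifest).resolve()} if config.manifest else set()
    records = []
    for path in sorted(Path(config.input_dir).iterdir()):
        if path.suffix.lower() not in suffix[config.dialect]:
            continue
        # not records: manifests and ground-truth event sidecars
        if path.resolve() in skip or path.name.endswith(".events.csv") \
                or path.stem.lower() == "manifest":
            continue
        if config.dialect == "wfdb":
            path = path.with_suffix(".dat")
        records.append(
            gio.read_record(path, dialect=config.dialect, manifest=manifest)
        )
    if not records:
        raise ValueError(f"no {config.dialect} records found in {config.input_dir}")
    return records


def _model_spec(config: RunConfig, method: str, signal_type: str,
                seed: int) -> clf.ModelSpec:
    params: dict = {}
    if config.params == "paper":
        params = clf.paper_params(method, signal_type)
    if config.n_cycles is not None and method != "tree":
        params["n_cycles"] = config.n_cycles
    return clf.ModelSpec(method=method, seed=seed, **params)


def extract_features(
    windows: list[pp.SignalWindow], config: RunConfig
) -> tuple[dict, list[dict]]:
    """Run event detection + feature assembly on every window.

    Returns ``(tables, dropped)``: one feature DataFrame per signal type
    and the list of (window, signal type) drops with reasons.
    """
    vectors: dict[str, list] = {s: [] for s in config.signal_types}
    dropped: list[dict] = []
    for window in windows:
        signals = ev.extract_all_signals(
            window, min_phase_s=config.min_phase_s, min_cycles=config.min_cycles
        )
        produced = ft.window_features(signals, config.signal_types)
        for signal_type in config.signal_types:
            if signal_type in produced:
                vectors[signal_type].append(produced[signal_type])
            else:
                dropped.append(
                    {
                        "window_id": window.window_id,
                        "reason": f"{signal_type} series unusable "
                                  "(too few cycles or degenerate)",
                    }
                )
    tables = {
        s: gio.features_to_frame(v) for s, v in vectors.items()
    }
    return tables, dropped


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full framework and write all reports under
    ``config.out_dir``; returns that directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("gaitdnd")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper()))
    try:
        return _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> Path:
    logger.info("stage simulate/read: loading records")
    records = _load_records(config)

    logger.info("stage preprocess: trim %.0f s, median kernel %d, windows %.0f s",
                config.trim_s, config.median_kernel, config.window_s)
    exclude = (
        pp.load_exclude_list(config.exclude_file)
        if config.exclude_file else set()
    )
    windows: list[pp.SignalWindow] = []
    dropped: list[dict] = []
    for record in records:
        try:
            record = pp.trim_edges(record, config.trim_s)
        except ValueError as exc:
            logger.warning("stage preprocess: %s; record skipped", exc)
            dropped.append({"window_id": f"{record.subject_id}:*",
                            "reason": str(exc)})
            continue
        record = pp.despike_record(record, config.median_kernel)
        windows.extend(pp.segment_windows(record, config.window_s))
    kept, rejected = pp.reject_noisy_windows(
        windows, config.max_spike_fraction, exclude
    )
    dropped.extend(rejected)

    logger.info("stage events/features: %d windows", len(kept))
    tables, feature_drops = extract_features(kept, config)
    dropped.extend(feature_drops)
    pd.DataFrame(dropped, columns=["window_id", "reason"]).to_csv(
        out / "dropped_windows.csv", index=False
    )

    class_counts: dict[str, dict] = {}
    for signal_type in config.signal_types:
        table = tables[signal_type]
        gio.write_features(table, out / f"features_{signal_type}.csv")
        class_counts[signal_type] = (
            table["condition"].value_counts().to_dict() if not table.empty else {}
        )

        if config.run_stats and not table.empty:
            logger.info("stage stats: %s", signal_type)
            report = st.compare_features(
                table, seed=_derived_seed(config.seed, 2)
            )
            report.to_csv(
                out / f"stats_{signal_type}.csv", index=False,
                float_format="%.17g",
            )

        for mi, method in enumerate(config.methods):
            logger.info("stage classify: %s / %s", signal_type, method)
            si = gio.SIGNAL_TYPES.index(signal_type)
            seed = _derived_seed(config.seed, 3, si, mi)
            spec = _model_spec(config, method, signal_type, seed)
            result = clf.cross_validate(table, spec, k=config.cv_folds,
                                        seed=seed)
            payload = result.to_dict()
            payload["signal_type"] = signal_type
            with open(out / f"cv_{signal_type}_{method}.json", "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
                fh.write("\n")

    summary = {
        "seed": config.seed,
        "n_records": len(records),
        "n_windows_kept": len(kept),
        "n_dropped": len(dropped),
        "class_counts": class_counts,
        "signal_types": list(config.signal_types),
        "methods": list(config.methods),
        "params": config.params,
        "cv_folds": config.cv_folds,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete: %s", out)
    return out
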