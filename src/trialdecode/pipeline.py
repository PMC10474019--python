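"""Dataset container I/O, end-to-end orchestration and the run manifest.

Datasets live in a BIDS-flavoured directory: one binary array per subject
with a JSON sidecar (channel names, groups, time grid, sampling rate) and a
per-subject events TSV, plus a combined trial table at the root.  All
derived artifacts are JSON; every numeric output carries the seed and a
config hash through the manifest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .controls import behavioral_control
from .crossval import DecodingCurve, SplitPlan, make_split_plan
from .model import TrialDecodingModel
from .simulate import (
    EpochSet,
    PatternSpec,
    SimConfig,
    TRIAL_TABLE_COLUMNS,
    demo_pattern,
    simulate_dataset,
    validate_trial_table,
)

EVENTS_COLUMNS = TRIAL_TABLE_COLUMNS


# ---------------------------------------------------------------------------
# dataset container


def save_dataset(epochs: list[EpochSet], trials: pd.DataFrame, path,
                 config_echo: dict | None = None, seed: int | None = None) -> Path:
    """Write the dataset layout: per-subject array + sidecar + events TSV."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    desc = {"name": "trialdecode dataset", "package_version": __version__,
            "seed": seed, "config": config_echo}
    (path / "dataset_description.json").write_text(json.dumps(desc, indent=2))
    validate_trial_table(trials)
    trials.to_csv(path / "trials.tsv", sep="\t", index=False)
    for ep in epochs:
        sub_dir = path / ep.subject_id / "eeg"
        sub_dir.mkdir(parents=True, exist_ok=True)
        np.save(sub_dir / f"{ep.subject_id}_epo.npy", ep.data)
        sidecar = {
            "subject_id": ep.subject_id,
            "ch_names": ep.ch_names,
            "ch_groups": ep.ch_groups,
            "times": ep.times.tolist(),
            "sfreq": ep.sfreq,
        }
        (sub_dir / f"{ep.subject_id}_epo.json").write_text(json.dumps(sidecar))
        rows = trials[trials["subject_id"] == ep.subject_id]
        rows.to_csv(sub_dir / f"{ep.subject_id}_events.tsv", sep="\t", index=False)
    return path


def load_bids_epochs(path) -> tuple[list[EpochSet], pd.DataFrame]:
    """Read a dataset directory back into EpochSets and a trial table.

    Schema problems (missing sidecars, missing events columns) raise
    explicit errors rather than producing partial data.
    """
    path = Path(path)
    sub_dirs = sorted(p for p in path.glob("sub-*") if p.is_dir())
    if not sub_dirs:
        raise FileNotFoundError(f"no sub-* directories under {path}")
    epochs = []
    events = []
    for sub in sub_dirs:
        eeg = sub / "eeg"
        arr_files = sorted(eeg.glob("*_epo.npy"))
        if len(arr_files) != 1:
            raise FileNotFoundError(f"expected exactly one *_epo.npy in {eeg}")
        arr = np.load(arr_files[0])
        sidecar_file = arr_files[0].with_suffix(".json")
        if not sidecar_file.exists():
            raise FileNotFoundError(f"missing sidecar {sidecar_file}")
        sidecar = json.loads(sidecar_file.read_text())
        for key in ("subject_id", "ch_names", "ch_groups", "times", "sfreq"):
            if key not in sidecar:
                raise ValueError(f"sidecar {sidecar_file} missing field {key!r}")
        ev_files = sorted(eeg.glob("*_events.tsv"))
        if len(ev_files) != 1:
            raise FileNotFoundError(f"expected exactly one *_events.tsv in {eeg}")
        ev = pd.read_csv(ev_files[0], sep="\t")
        missing = [c for c in EVENTS_COLUMNS if c not in ev.columns]
        if missing:
            raise ValueError(f"events file {ev_files[0]} missing columns {missing}")
        epochs.append(EpochSet(
            subject_id=sidecar["subject_id"], data=arr,
            ch_names=list(sidecar["ch_names"]), ch_groups=dict(sidecar["ch_groups"]),
            times=np.asarray(sidecar["times"], dtype=float), sfreq=float(sidecar["sfreq"]),
        ))
        events.append(ev)
    trials = pd.concat(events, ignore_index=True)
    validate_trial_table(trials)
    return epochs, trials


def load_mne_epochs(path, trials_path, ch_groups: dict[str, str]) -> tuple[list[EpochSet], pd.DataFrame]:
    """Adapter for epochs saved by the host EEG library (FIF).

    ``path`` may be a single -epo.fif or a directory of them; the trial
    table TSV and the channel-to-10-20-group map come from sidecars.
    """
    import mne  # optional dependency

    path = Path(path)
    files = sorted(path.glob("*epo.fif")) if path.is_dir() else [path]
    epochs = []
    for f in files:
        ep = mne.read_epochs(f, preload=True, verbose="error")
        data = ep.get_data(copy=True) * 1e6  # volts -> microvolts
        epochs.append(EpochSet(
            subject_id=f.stem.split("_")[0], data=data, ch_names=ep.ch_names,
            ch_groups=ch_groups, times=ep.times, sfreq=float(ep.info["sfreq"]),
        ))
    trials = pd.read_csv(trials_path, sep="\t")
    validate_trial_table(trials)
    return epochs, trials


# ---------------------------------------------------------------------------
# curve / cluster serialization


def curve_to_json(curve: DecodingCurve, path) -> None:
    payload = {
        "auc": np.where(np.isnan(curve.auc), None, curve.auc).tolist(),
        "times": curve.times.tolist(),
        "target": curve.target,
        "plan": {"seed": curve.split_plan.seed,
                 "halves": [[sorted(a), sorted(b)] for a, b in curve.split_plan.halves]},
    }
    Path(path).write_text(json.dumps(payload))


def curve_from_json(path) -> DecodingCurve:
    payload = json.loads(Path(path).read_text())
    plan = SplitPlan(
        halves=tuple((frozenset(a), frozenset(b)) for a, b in payload["plan"]["halves"]),
        seed=payload["plan"]["seed"],
    )
    auc = np.array([[[np.nan if v is None else v for v in row]
                     for row in orient] for orient in payload["auc"]], dtype=float)
    return DecodingCurve(auc=auc, times=np.asarray(payload["times"]),
                         target=payload["target"], split_plan=plan)


# ---------------------------------------------------------------------------
# config + manifest


def config_from_dict(cfg: dict) -> SimConfig:
    """Build a SimConfig from a plain (YAML-friendly) mapping.

    Pattern entries give window/amplitude/target and either an explicit
    ``spatial`` vector or a smooth bump via ``center``/``width``.
    """
    cfg = dict(cfg)
    pattern_cfgs = cfg.pop("patterns", [])
    n_channels = cfg.get("n_channels", SimConfig.n_channels)
    patterns = []
    for p in pattern_cfgs:
        if "spatial" in p:
            spatial = np.asarray(p["spatial"], dtype=float)
        else:
            spatial = demo_pattern(n_channels, p.get("center", 0.5), p.get("width", 0.15))
        patterns.append(PatternSpec(spatial=spatial, window=tuple(p["window"]),
                                    amplitude=float(p["amplitude"]),
                                    target=p.get("target", "choice")))
    return SimConfig(patterns=tuple(patterns), **cfg)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance for one end-to-end run."""

    config: dict
    seed: int
    versions: dict = field(default_factory=dict)
    hashes: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def _versions() -> dict:
    import scipy
    import sklearn
    import statsmodels

    return {"trialdecode": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__}


def run_all(config: dict, out_dir, seed: int = 0) -> RunManifest:
    """simulate -> decode (choice, market) -> infer -> patterns -> controls.

    Writes every stage artifact under ``out_dir`` and returns the manifest
    (also written as manifest.json).  Stage failures propagate with their
    own diagnostics.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config, seed=seed, versions=_versions())

    sim_cfg = config_from_dict({**config.get("simulate", {}), "seed": seed})
    epochs, trials = simulate_dataset(sim_cfg)
    data_dir = save_dataset(epochs, trials, out / "dataset",
                            config_echo=config.get("simulate", {}), seed=seed)

    k = int(config.get("k", 10))
    alpha = float(config.get("alpha", 0.05))
    target_fdp = float(config.get("target_fdp", 0.05))
    stimulus_ids = sorted(trials["stimulus_id"].unique())
    plan = make_split_plan(stimulus_ids, k=k, seed=seed)

    report = {"seed": seed, "k": k, "alpha": alpha}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for target in ("choice", "market"):
            model = TrialDecodingModel(epochs, trials, target=target)
            res = model.fit(plan=plan)
            res.alpha, res.target_fdp = alpha, target_fdp
            curve_to_json(res.curve, out / f"decoding_{target}.json")
            cs = res.clusters()
            cluster_payload = {
                "clusters_s": cs.cluster_times(), "tdp_lower": cs.tdp_lower,
                "threshold": cs.threshold, "h": cs.h, "alpha": cs.alpha,
            }
            (out / f"clusters_{target}.json").write_text(
                json.dumps(cluster_payload, default=float))
            pm = res.patterns()
            (out / f"patterns_{target}.json").write_text(json.dumps({
                "A": np.where(np.isnan(pm.A), None, pm.A).tolist(),
                "times": pm.times.tolist(), "ch_names": pm.ch_names,
            }))
            peak_auc, peak_t = res.peak()
            report[f"{target}_peak_auc"] = peak_auc
            report[f"{target}_peak_time_s"] = peak_t
            report[f"{target}_n_clusters"] = cs.n_clusters
            (out / f"summary_{target}.txt").write_text(res.summary())

        ctrl = behavioral_control(trials, plan, reference_plan=plan)
        (out / "control_behavioral.json").write_text(json.dumps({
            "mean_auc": float(np.nanmean(ctrl.auc)), "coef": ctrl.insample_coef,
            "ci": list(ctrl.insample_ci), "z": ctrl.z, "p": ctrl.p,
            "t": ctrl.t_stat, "t_p": ctrl.t_p, "df": ctrl.df,
        }))
        report["behavioral_control_auc"] = float(np.nanmean(ctrl.auc))
    manifest.warnings = [str(w.message) for w in caught]

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest.hashes[str(f.relative_to(out))] = _sha256(f)
    manifest.save(out / "manifest.json")
    return manifest
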