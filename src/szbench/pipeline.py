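"""End-to-end orchestration from a single structured (YAML) config.

A run executes sample -> folds -> train -> evaluate -> report and leaves
a run directory containing a manifest (config hash, fan-out seeds,
library versions, per-stage counts), the window manifest, the fold
report, and logs.  Reruns with an identical config reproduce all
deterministic outputs.

Config schema (version 1)::

    schema_version: 1
    seed: 0
    source:
      kind: synth            # or "chbmit"
      gain: 3.0              # synth: preictal signature gain
      rate: 32.0
      n_channels: 3
      # chbmit: {root: /path/to/chbmit, subject: chb01}
    sampling: {sph: 300, sop: 1800, t_free: 14400, ...}   # optional overrides
    network: {conv_widths: [16,16,16,16,16], ...}          # optional overrides
    training: {epochs: 20, batch_size: 32, learning_rate: 0.001, balance: true}
    threshold: null          # vote threshold; null = n_channels / 2

For a CHB-MIT-layout source the subject directory must hold
``<subject>-summary.txt`` plus the EDF files it names (requires the
optional ``mne`` dependency).  Synthetic sources need nothing on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from typing import Dict, Optional, Tuple

import numpy as np
import yaml

from .annotations_io import EdfSignalStore, SubjectTimeline, parse_summary
from .evaluation import EligibilityError, TrainParams, run_loocv
from .network import NetworkConfig
from .sampling import SamplingParams, build_sample_set, find_leading_seizures
from .synthgen import make_separability_subject, separability_sampling_params

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class RunConfigError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    seed: int
    source: Dict
    sampling: SamplingParams
    network: NetworkConfig
    training: TrainParams
    threshold: Optional[float]
    raw: Dict

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Dict) -> "RunConfig":
        if raw.get("schema_version", 1) != SCHEMA_VERSION:
            raise RunConfigError(
                f"unsupported schema_version {raw.get('schema_version')}"
            )
        source = raw.get("source") or {}
        kind = source.get("kind")
        if kind not in ("synth", "chbmit"):
            raise RunConfigError("source.kind must be 'synth' or 'chbmit'")
        seed = int(raw.get("seed", 0))
        sampling_kw = dict(raw.get("sampling") or {})
        if kind == "synth" and "sampling" not in raw:
            sampling = separability_sampling_params()
        else:
            sampling = SamplingParams(**sampling_kw)
        net_kw = dict(raw.get("network") or {})
        if "conv_widths" in net_kw:
            net_kw["conv_widths"] = tuple(net_kw["conv_widths"])
        network = NetworkConfig(**net_kw) if net_kw else None
        train_kw = dict(raw.get("training") or {})
        train_kw.setdefault("seed", seed)
        training = TrainParams(**train_kw)
        return cls(
            seed=seed,
            source=source,
            sampling=sampling,
            network=network,
            training=training,
            threshold=raw.get("threshold"),
            raw=raw,
        )


def _config_hash(raw: Dict) -> str:
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _load_timeline(cfg: RunConfig) -> Tuple[SubjectTimeline, SamplingParams]:
    kind = cfg.source["kind"]
    if kind == "synth":
        timeline, sp = make_separability_subject(
            seed=cfg.seed,
            gain=float(cfg.source.get("gain", 3.0)),
            rate=float(cfg.source.get("rate", 32.0)),
            n_channels=int(cfg.source.get("n_channels", 3)),
        )
        sampling = cfg.sampling if "sampling" in cfg.raw else sp
        return timeline, sampling
    root = cfg.source["root"]
    subject = cfg.source["subject"]
    subj_dir = os.path.join(root, subject)
    summary_path = os.path.join(subj_dir, f"{subject}-summary.txt")
    with open(summary_path) as fh:
        text = fh.read()
    timeline = parse_summary(
        text, subject_id=subject, signal_store=EdfSignalStore(subj_dir)
    )
    return timeline, cfg.sampling


def eligibility_screen(timeline: SubjectTimeline, sampling: SamplingParams) -> Dict:
    leading = find_leading_seizures(timeline.seizures, sampling.t_free)
    return {
        "subject": timeline.subject_id,
        "n_seizures": len(timeline.seizures),
        "n_leading": len(leading),
        "eligible": len(leading) >= 3,
    }


def run(config: RunConfig, out_dir: str) -> Dict:
    """Execute the full pipeline; returns the run manifest dict."""
    os.makedirs(out_dir, exist_ok=True)
    log_path = os.path.join(out_dir, "run.log")
    handler = logging.FileHandler(log_path)
    logging.getLogger("szbench").addHandler(handler)
    try:
        timeline, sampling = _load_timeline(config)
        screen = eligibility_screen(timeline, sampling)
        if not screen["eligible"]:
            raise EligibilityError(
                f"{timeline.subject_id}: {screen['n_leading']} leading "
                f"seizure(s); at least three are required"
            )
        sample_set = build_sample_set(timeline, sampling)
        with open(os.path.join(out_dir, "windows.tsv"), "w") as fh:
            fh.write(sample_set.manifest())
        with open(os.path.join(out_dir, "segments.bed"), "w") as fh:
            fh.write(sample_set.segments_bed())
        report = run_loocv(
            timeline,
            sampling_params=sampling,
            net_config=config.network,
            train_params=config.training,
            threshold=config.threshold,
            sample_set=sample_set,
        )
        with open(os.path.join(out_dir, "report.tsv"), "w") as fh:
            fh.write(report.to_text())
        manifest = {
            "schema_version": SCHEMA_VERSION,
            "config_hash": _config_hash(config.raw),
            "seed": config.seed,
            "fold_seeds": [
                config.training.fold_seed(f.fold_id) for f in report.folds
            ],
            "versions": _versions(),
            "subject": screen,
            "n_windows": len(sample_set.windows),
            "n_preictal": sample_set.n_preictal,
            "n_interictal": sample_set.n_interictal,
            "n_folds": len(report.folds),
            "accuracy": report.accuracy,
            "sensitivity": report.sensitivity,
            "specificity": report.specificity,
            "audit_passed": report.audit_passed,
        }
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    finally:
        logging.getLogger("szbench").removeHandler(handler)
        handler.close()


def _versions() -> Dict[str, str]:
    import scipy
    import sklearn

    from . import __version__

    return {
        "szbench": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }
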