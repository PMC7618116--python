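"""End-to-end orchestration: config schema, per-image runs, tidy reports.

A :class:`RunConfig` names the channel roles and carries every module's
parameter block; :func:`run_pipeline` executes
preprocess → detect → ROI → classify → pair → summarize per image,
isolates per-image failures, and emits per-cell and per-call tables plus a
descriptive group summary (mean ± s.e.m.; inferential statistics are left
to downstream tools).  The full configuration is serialized next to every
output for provenance.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from synquant.image_io import CalibratedImage, read_image
from synquant.preprocess import PreprocessParams, preprocess_channel
from synquant.puncta import DetectionParams, detect_puncta
from synquant.rois import build_roi
from synquant.synapses import (
    SYNAPSE_MIN_OVERLAP,
    call_synapses,
    calls_table,
    classify_puncta,
    summarize_cell,
)

log = logging.getLogger("synquant")

SCHEMA_VERSION = 1


@dataclass
class ChannelRoles:
    presynaptic: str = "pre"
    postsynaptic: str = "post"
    marker: str = "marker"
    measurement: str | None = None


@dataclass
class RoiParams:
    method: str = "auto"
    threshold: float = 60.0
    kind: str = "soma"
    band_width: float = 0.5


@dataclass
class PairingParams:
    min_overlap: float = SYNAPSE_MIN_OVERLAP
    mode: str = "best_match"
    bouton_min_overlap: float = 0.1
    cluster_min_overlap: float = 0.2
    inside_cutoff: float = 0.5


@dataclass
class RunConfig:
    """Full configuration of one quantification run."""

    experiment: str = "experiment"
    channels: ChannelRoles = field(default_factory=ChannelRoles)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    roi: RoiParams = field(default_factory=RoiParams)
    pairing: PairingParams = field(default_factory=PairingParams)
    seed: int = 0
    output_dir: str | None = None

    def validate_against(self, img: CalibratedImage) -> None:
        """Check every referenced channel exists before any computation."""
        needed = [self.channels.presynaptic, self.channels.postsynaptic]
        if self.roi.method == "auto":
            needed.append(self.channels.marker)
        if self.channels.measurement:
            needed.append(self.channels.measurement)
        for name in needed:
            img.channel_index(name)
        if self.detection.intensity_threshold < 0 or self.roi.threshold < 0:
            raise ValueError("thresholds must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("schema_version", None)
        return cls(
            experiment=d.get("experiment", "experiment"),
            channels=ChannelRoles(**d.get("channels", {})),
            preprocess=PreprocessParams(**d.get("preprocess", {})),
            detection=DetectionParams(**d.get("detection", {})),
            roi=RoiParams(**d.get("roi", {})),
            pairing=PairingParams(**d.get("pairing", {})),
            seed=int(d.get("seed", 0)),
            output_dir=d.get("output_dir"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class RunResult:
    """Bundle returned by :func:`run_pipeline`."""

    per_cell: pd.DataFrame
    per_call: pd.DataFrame
    summary: pd.DataFrame
    failures: list[dict]

    @property
    def ok(self) -> bool:
        return not self.failures


def quantify_image(
    img: CalibratedImage, config: RunConfig, cell_id: str
) -> tuple[dict, pd.DataFrame]:
    """Quantify one single-cell image; returns (per-cell row, per-call table)."""
    config.validate_against(img)
    ch = config.channels
    proc = img
    for name in dict.fromkeys(
        [ch.marker, ch.presynaptic, ch.postsynaptic]
        if config.roi.method == "auto"
        else [ch.presynaptic, ch.postsynaptic]
    ):
        proc = preprocess_channel(proc, name, config.preprocess)

    pre = detect_puncta(proc, ch.presynaptic, config.detection, measurement=img.channel(ch.presynaptic))
    post = detect_puncta(proc, ch.postsynaptic, config.detection, measurement=img.channel(ch.postsynaptic))
    roi = build_roi(
        proc,
        ch.marker,
        method=config.roi.method,
        threshold=config.roi.threshold,
        cell_id=cell_id,
        kind=config.roi.kind,
        band_width=config.roi.band_width,
    )
    p = config.pairing
    pre_cls = classify_puncta(
        pre, roi, role="pre",
        bouton_min_overlap=p.bouton_min_overlap,
        cluster_min_overlap=p.cluster_min_overlap,
        inside_cutoff=p.inside_cutoff,
    )
    post_cls = classify_puncta(
        post, roi, role="post",
        bouton_min_overlap=p.bouton_min_overlap,
        cluster_min_overlap=p.cluster_min_overlap,
        inside_cutoff=p.inside_cutoff,
    )
    calls = call_synapses(pre, post, pre_cls, post_cls, p.min_overlap, p.mode)
    report = summarize_cell(calls, pre_cls, post_cls, roi)
    ct = calls_table(calls)
    ct.insert(0, "cell_id", cell_id)
    return report.as_row(), ct


def run_pipeline(
    config: RunConfig,
    inputs: list[tuple[str, CalibratedImage]] | list[str] | list[Path],
) -> RunResult:
    """Run the synapse-quantification pipeline over a set of images.

    ``inputs`` is either a list of image paths (cell ids from file stems)
    or ``(cell_id, CalibratedImage)`` pairs.  A failure in one image is
    logged and recorded but does not abort the run.  When
    ``config.output_dir`` is set, per-cell/per-call/summary CSVs and the
    serialized config are written there.
    """
    rows: list[dict] = []
    call_tables: list[pd.DataFrame] = []
    failures: list[dict] = []
    for item in inputs:
        if isinstance(item, (str, Path)):
            cell_id = Path(item).stem
            loader = lambda p=item: read_image(p)
        else:
            cell_id, img_obj = item
            loader = lambda o=img_obj: o
        try:
            row, ct = quantify_image(loader(), config, str(cell_id))
            rows.append(row)
            call_tables.append(ct)
        except Exception as exc:  # per-image isolation
            log.error("image %s failed: %s", cell_id, exc)
            failures.append({"cell_id": str(cell_id), "error": str(exc)})

    per_cell = pd.DataFrame(rows)
    per_call = (
        pd.concat(call_tables, ignore_index=True)
        if call_tables
        else pd.DataFrame(columns=["cell_id", "pre_id", "post_id", "overlap_area_um2"])
    )
    summary = summarize_group(per_cell, config.experiment)
    result = RunResult(per_cell=per_cell, per_call=per_call, summary=summary, failures=failures)

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_cell.to_csv(out / "per_cell.csv", index=False)
        per_call.to_csv(out / "per_call.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        config.to_yaml(out / "config.yaml")
        if failures:
            pd.DataFrame(failures).to_csv(out / "failures.csv", index=False)
    return result


def summarize_group(per_cell: pd.DataFrame, experiment: str) -> pd.DataFrame:
    """Descriptive mean ± s.e.m. per numeric column across cells."""
    rows = []
    numeric = per_cell.select_dtypes("number") if len(per_cell) else pd.DataFrame()
    for col in numeric.columns:
        vals = numeric[col].dropna().to_numpy(dtype=float)
        rows.append(
            {
                "experiment": experiment,
                "metric": col,
                "n": len(vals),
                "mean": float(np.mean(vals)) if len(vals) else float("nan"),
                "sem": float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1
                else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["experiment", "metric", "n", "mean", "sem"])
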