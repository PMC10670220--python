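"""End-to-end evaluation pipeline.

One run realizes the full protocol for every image in a manifest:

    source score mask -> binarize -> checkpoint prompts -> promptable
    backend -> weighted fusion with the source -> metrics vs ground truth

and reports three metric tables against the ground truth: the binarized
source (baseline), the backend alone, and the fusion.  Prompts are computed
once per image and shared, so backends are compared on identical prompts.

Backends are pluggable: the built-in mock (a controllable oracle over the
ground truth) or any external command following the subprocess contract
(image path + prompt JSON in, score-mask PNG out), which keeps pretrained
models entirely out of the core.
"""

from __future__ import annotations

import json
import subprocess
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .fusion import FusionConfig, fuse
from .masks import (
    BinaryMask,
    MaskValidationError,
    Polarity,
    ScoreMask,
    binarize,
    read_mask,
    write_mask,
)
from .metrics import METRIC_COLUMNS, MetricReport, evaluate_pairs
from .prompts import PromptConfig, PromptSet, extract_prompts
from .synthetic import MockPromptableBackend

__all__ = [
    "ManifestEntry",
    "BackendSpec",
    "RunConfig",
    "RunRecord",
    "run",
    "compare_runs",
    "ComparisonTable",
    "load_run_config",
]

#: Named binarization presets; "strict32" is the conservative margin that
#: keeps prompts inside the most confident part of the source mask.
THRESHOLD_PRESETS = {"default": 128, "strict32": 32}


@dataclass(frozen=True)
class ManifestEntry:
    image_id: str
    source_mask: Path
    ground_truth: Path
    image: Optional[Path] = None  # RGB payload, passed through to backends


@dataclass(frozen=True)
class BackendSpec:
    """Which promptable segmentator to invoke.

    ``mock`` builds a :class:`~promptfuse.synthetic.MockPromptableBackend`
    from each image's ground truth (fidelity 1 with ground-truth prompts is
    the oracle protocol).  ``external-command`` runs ``command`` with the
    arguments ``<image> <prompts.json> <out.png>`` appended.
    """

    kind: str = "mock"
    fidelity: float = 1.0
    command: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("mock", "external-command"):
            raise MaskValidationError(f"unknown backend kind {self.kind!r}")
        if self.kind == "external-command" and not self.command:
            raise MaskValidationError("external-command backend requires a command")


@dataclass(frozen=True)
class RunConfig:
    manifest: tuple[ManifestEntry, ...]
    prompt: PromptConfig = PromptConfig()
    fusion: FusionConfig = FusionConfig()
    source_polarity: Polarity = Polarity.FOREGROUND_HIGH
    backend_polarity: Polarity = Polarity.FOREGROUND_HIGH
    source_threshold: Union[int, str] = 128
    backend: BackendSpec = BackendSpec()
    output_dir: Path = Path("promptfuse_run")
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.manifest) == 0:
            raise MaskValidationError("manifest must not be empty")
        object.__setattr__(self, "output_dir", Path(self.output_dir))

    @property
    def resolved_threshold(self) -> int:
        t = self.source_threshold
        if isinstance(t, str):
            try:
                return THRESHOLD_PRESETS[t]
            except KeyError:
                raise MaskValidationError(f"unknown threshold preset {t!r}") from None
        return int(t)


def load_run_config(path: Union[str, Path]) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML or JSON file.

    Recognized keys mirror the dataclass fields; ``manifest`` is either a
    list of ``{image_id, source_mask, ground_truth[, image]}`` mappings or a
    path to a manifest CSV, both resolved relative to the config file.
    """
    import csv

    import yaml

    path = Path(path)
    payload = yaml.safe_load(path.read_text())  # YAML is a JSON superset
    base = path.parent

    raw_manifest = payload.get("manifest", [])
    entries: list[ManifestEntry] = []
    if isinstance(raw_manifest, (str, Path)):
        csv_path = base / raw_manifest
        csv_base = csv_path.parent  # rows are relative to the CSV itself
        with open(csv_path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries.append(
                    ManifestEntry(
                        row["image_id"],
                        csv_base / row["source_mask"],
                        csv_base / row["ground_truth"],
                    )
                )
    else:
        for row in raw_manifest:
            entries.append(
                ManifestEntry(
                    row["image_id"],
                    base / row["source_mask"],
                    base / row["ground_truth"],
                    base / row["image"] if row.get("image") else None,
                )
            )

    backend_raw = dict(payload.get("backend", {}))
    if "command" in backend_raw:
        backend_raw["command"] = tuple(backend_raw["command"])
    return RunConfig(
        manifest=tuple(entries),
        prompt=PromptConfig(**payload.get("prompt", {})),
        fusion=FusionConfig(**payload.get("fusion", {})),
        source_polarity=Polarity(payload.get("source_polarity", "foreground_high")),
        backend_polarity=Polarity(payload.get("backend_polarity", "foreground_high")),
        source_threshold=payload.get("source_threshold", 128),
        backend=BackendSpec(**backend_raw),
        output_dir=Path(payload.get("output_dir", base / "promptfuse_run")),
        rng_seed=int(payload.get("rng_seed", 0)),
    )


@dataclass
class RunRecord:
    """Artifacts and metric reports of one pipeline run."""

    reports: dict[str, MetricReport]  # keys: source, backend, fused
    per_image: pd.DataFrame  # artifact paths per image
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (image_id, reason)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def _invoke_backend(
    config: RunConfig, entry: ManifestEntry, gt: BinaryMask, prompts_path: Path, out_dir: Path
) -> ScoreMask:
    if config.backend.kind == "mock":
        backend = MockPromptableBackend(gt, fidelity=config.backend.fidelity, rng_seed=config.rng_seed)
        from .prompts import load_prompts

        return backend.predict(None, load_prompts(prompts_path))
    out_path = out_dir / f"{entry.image_id}_backend_raw.png"
    cmd = [*config.backend.command, str(entry.image or entry.source_mask), str(prompts_path), str(out_path)]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise MaskValidationError(f"backend command failed ({proc.returncode}): {proc.stderr.strip()}")
    return read_mask(out_path, config.backend_polarity)


def run(config: RunConfig) -> RunRecord:
    """Execute the pipeline over the manifest; write artifacts and reports.

    Per-image failures are logged, skipped, and counted; the run completes
    with the remaining images.  Reruns with identical config and seed
    produce byte-identical prompt files, masks, and CSVs.
    """
    out_dir = config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    threshold = config.resolved_threshold

    pairs: dict[str, list[tuple[BinaryMask, BinaryMask, str]]] = {"source": [], "backend": [], "fused": []}
    rows = []
    skipped: list[tuple[str, str]] = []
    for entry in config.manifest:
        try:
            source = read_mask(entry.source_mask, config.source_polarity)
            gt = _read_gt(entry.ground_truth)
            source_bin = binarize(source, threshold)
            prompts = extract_prompts(source_bin, config.prompt)
            prompts_path = out_dir / f"{entry.image_id}_prompts.json"
            prompts.save(prompts_path)
            backend_mask = _invoke_backend(config, entry, gt, prompts_path, out_dir)
            backend_bin = binarize(backend_mask, 128)
            # strict-margin variant: prompts come from the strict binarization,
            # but fusion always uses the original continuous source mask
            fused_score, fused_bin = fuse(source, backend_mask, config.fusion)
            backend_path = out_dir / f"{entry.image_id}_backend.png"
            fused_path = out_dir / f"{entry.image_id}_fused.png"
            fused_bin_path = out_dir / f"{entry.image_id}_fused_binary.png"
            write_mask(backend_mask.to_foreground_high(), backend_path)
            write_mask(fused_score, fused_path)
            write_mask(fused_bin, fused_bin_path)
            pairs["source"].append((source_bin, gt, entry.image_id))
            pairs["backend"].append((backend_bin, gt, entry.image_id))
            pairs["fused"].append((fused_bin, gt, entry.image_id))
            # paths stored relative to output_dir: artifacts stay valid if
            # the run directory is moved, and reruns are byte-identical
            rows.append(
                {
                    "image_id": entry.image_id,
                    "prompts": prompts_path.name,
                    "backend_mask": backend_path.name,
                    "fused_mask": fused_path.name,
                    "fused_binary": fused_bin_path.name,
                    "n_prompts": len(prompts),
                }
            )
        except (OSError, MaskValidationError) as exc:
            skipped.append((entry.image_id, str(exc)))

    if not rows:
        raise MaskValidationError("no image in the manifest could be processed")
    reports = {name: evaluate_pairs(plist) for name, plist in pairs.items()}
    record = RunRecord(reports=reports, per_image=pd.DataFrame(rows), skipped=skipped)

    for name, report in reports.items():
        report.to_csv(out_dir / f"metrics_{name}.csv")
    record.per_image.to_csv(out_dir / "artifacts.csv", index=False)
    _write_run_manifest(config, record, out_dir / "run_manifest.json")
    return record


def _read_gt(path: Path) -> BinaryMask:
    score = read_mask(path, Polarity.FOREGROUND_HIGH)
    return binarize(score, 128)


def _write_run_manifest(config: RunConfig, record: RunRecord, path: Path) -> None:
    payload = {
        "n_images": len(config.manifest),
        "n_processed": len(record.per_image),
        "skipped": [{"image_id": i, "reason": r} for i, r in record.skipped],
        "rng_seed": config.rng_seed,
        "source_threshold": config.resolved_threshold,
        "source_polarity": config.source_polarity.value,
        "backend_polarity": config.backend_polarity.value,
        "prompt": {
            "method": config.prompt.method,
            "b": config.prompt.b,
            "border_mode": config.prompt.border_mode,
            "rng_seed": config.prompt.rng_seed,
        },
        "fusion": {
            "seg_weight": config.fusion.seg_weight,
            "zs_weight": config.fusion.zs_weight,
            "threshold": config.fusion.threshold,
        },
        "backend": {"kind": config.backend.kind, "fidelity": config.backend.fidelity},
        "versions": {"python": sys.version.split()[0], "numpy": np.__version__, "pandas": pd.__version__},
        "aggregates": {name: rep.aggregate for name, rep in record.reports.items()},
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


@dataclass(frozen=True)
class ComparisonTable:
    """Side-by-side aggregates of several runs plus paired differences."""

    aggregates: pd.DataFrame  # rows: metrics; columns: run names (+ diffs)
    per_image_diffs: pd.DataFrame  # per-image metric differences vs first run


def compare_runs(
    records: Sequence[RunRecord], names: Optional[Sequence[str]] = None, which: str = "fused"
) -> ComparisonTable:
    """Lay the aggregates of several runs side by side.

    All records must share image ids (paired comparison).  Columns appear in
    the order given; for every run after the first a ``Δ`` column holds the
    aggregate difference to the first run, and ``per_image_diffs`` the
    per-image paired differences.
    """
    if names is None:
        names = [f"run_{i}" for i in range(len(records))]
    if len(names) != len(records):
        raise MaskValidationError("one name per record required")
    ids0 = list(records[0].reports[which].per_image["image_id"])
    for rec in records[1:]:
        if list(rec.reports[which].per_image["image_id"]) != ids0:
            raise MaskValidationError("records do not share image ids")

    agg = pd.DataFrame(
        {name: pd.Series(rec.reports[which].aggregate) for name, rec in zip(names, records)}
    ).loc[list(METRIC_COLUMNS)]
    for name in names[1:]:
        agg[f"Δ({name})"] = agg[name] - agg[names[0]]

    diffs = []
    base = records[0].reports[which].per_image.set_index("image_id")
    for name, rec in zip(names[1:], records[1:]):
        d = rec.reports[which].per_image.set_index("image_id")[list(METRIC_COLUMNS)] - base[list(METRIC_COLUMNS)]
        d["run"] = name
        diffs.append(d.reset_index())
    per_image_diffs = (
        pd.concat(diffs, ignore_index=True) if diffs else pd.DataFrame(columns=["image_id", *METRIC_COLUMNS, "run"])
    )
    return ComparisonTable(aggregates=agg, per_image_diffs=per_image_diffs)
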