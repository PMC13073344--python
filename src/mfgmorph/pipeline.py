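"""End-to-end analysis pipeline: images → particles → classes → summaries.

``run_analyze`` turns one or more micrographs into per-sample CSV bundles
(particles.csv, classified.csv, summary.csv) plus a machine-readable run
manifest (config, seed, package version, input names) so every report row
is traceable. ``run_compare`` aligns two per-sample summary tables by
sample id and emits the full agreement ledger per metric.

Configuration round-trips through a flat TOML file with one section per
stage; unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import BootstrapConfig, PairedMeasurements, compare_methods
from .classify import ClassificationConfig, classify_sample
from .distributions import summarize
from .morphometry import descriptors, records_to_dataframe
from .segmentation import SegmentationConfig, segment

__all__ = ["PipelineConfig", "load_config", "save_config", "run_analyze", "run_compare"]

log = logging.getLogger("mfgmorph")

_METRIC_COLUMNS = ["d10_mean", "pn10", "pn50", "pn90", "d43", "pv10", "pv50", "pv90"]


@dataclass
class PipelineConfig:
    pixel_size_um: float = 0.0625
    seed: int = 0
    log_level: str = "INFO"
    apply_qc: bool = True
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)

    def to_dict(self) -> dict:
        def clean(obj):
            d = {}
            for f in dataclasses.fields(obj):
                if f.name.startswith("_"):
                    continue
                v = getattr(obj, f.name)
                if isinstance(v, tuple):
                    v = list(v)
                elif isinstance(v, frozenset):
                    v = sorted(v)
                d[f.name] = v
            return d

        top = {
            "pixel_size_um": self.pixel_size_um,
            "seed": self.seed,
            "log_level": self.log_level,
            "apply_qc": self.apply_qc,
            "segmentation": clean(self.segmentation),
            "classification": clean(self.classification),
            "bootstrap": clean(self.bootstrap),
        }
        return top

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sections = {}
        for name, sub_cls in (
            ("segmentation", SegmentationConfig),
            ("classification", ClassificationConfig),
            ("bootstrap", BootstrapConfig),
        ):
            sub = dict(d.pop(name, {}))
            known = {f.name for f in dataclasses.fields(sub_cls) if not f.name.startswith("_")}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
            for k, v in list(sub.items()):
                if isinstance(v, list):
                    fld = next(f for f in dataclasses.fields(sub_cls) if f.name == k)
                    if "frozenset" in str(fld.type):
                        sub[k] = frozenset(v)
                    else:
                        sub[k] = tuple(v)
            sections[name] = sub_cls(**sub)
        known_top = {"pixel_size_um", "seed", "log_level", "apply_qc"}
        unknown = set(d) - known_top
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(**d, **sections)


def load_config(path) -> PipelineConfig:
    """Read a pipeline config from a TOML file (unknown keys rejected)."""
    with open(path, "rb") as fh:
        return PipelineConfig.from_dict(tomllib.load(fh))


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    if v is None:
        raise ValueError("TOML cannot encode None; set an explicit value")
    return repr(v)


def save_config(config: PipelineConfig, path) -> None:
    """Write the config as TOML; ``load_config`` round-trips it losslessly."""
    d = config.to_dict()
    lines = []
    for k, v in d.items():
        if not isinstance(v, dict):
            lines.append(f"{k} = {_toml_value(v)}")
    for section, sub in d.items():
        if isinstance(sub, dict):
            lines.append(f"\n[{section}]")
            for k, v in sub.items():
                if v is None:
                    continue  # unset seeds stay unset
                lines.append(f"{k} = {_toml_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_image(path) -> np.ndarray:
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        img = tifffile.imread(path)
    else:
        from PIL import Image

        img = np.asarray(Image.open(path).convert("L"))
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image, got shape {img.shape}")
    return img


def _analyze_image(image: np.ndarray, config: PipelineConfig, sample_id: str):
    labeled = segment(image, config.segmentation)
    log.info("%s: %d particles detected", sample_id, labeled.n_particles)
    records = []
    for lab in range(1, labeled.n_particles + 1):
        sl = labeled.particle_slices(lab)
        sub = labeled.labels[sl] == lab
        records.append(
            descriptors(
                sub,
                image[sl],
                config.pixel_size_um,
                particle_id=lab,
                origin_px=(sl[0].start, sl[1].start),
            )
        )
    classified = classify_sample(
        sample_id, records, config.classification, apply_qc=config.apply_qc
    )
    return records, classified


def _summary_rows(classified) -> list[dict]:
    rows = []
    for cls in ("total", "individual", "agglomerate"):
        d = classified.diameters(None if cls == "total" else cls)
        row = {"sample_id": classified.sample_id, "particle_class": cls, "n": d.size}
        if d.size:
            s = summarize(d)
            row.update({c: getattr(s, c) for c in _METRIC_COLUMNS})
        else:
            row.update({c: np.nan for c in _METRIC_COLUMNS})
        rows.append(row)
    return rows


def run_analyze(image_paths, config: PipelineConfig, out_dir) -> pd.DataFrame:
    """Analyze images into per-sample CSV bundles; returns the summary table.

    For each image ``<stem>``: writes ``<stem>_particles.csv`` (all
    descriptor records) and ``<stem>_classified.csv`` (class label or
    exclusion reasons per particle). One ``summary.csv`` collects the
    per-sample, per-class size-distribution metrics, and ``manifest.json``
    records config, seed and versions. Deterministic: rerunning with the
    same manifest reproduces byte-identical CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_summary: list[dict] = []
    inputs = []
    for path in map(Path, image_paths):
        if not path.exists():
            raise FileNotFoundError(f"input image not found: {path}")
        image = _read_image(path)
        sample_id = path.stem
        records, classified = _analyze_image(image, config, sample_id)
        df = records_to_dataframe(records)
        df.to_csv(out / f"{sample_id}_particles.csv", index=False, float_format="%.6g")

        label_of = {r.particle_id: lab for r, lab in classified.records}
        reason_of = {r.particle_id: ";".join(why) for r, why in classified.excluded}
        cdf = df.copy()
        cdf["particle_class"] = [
            label_of.get(pid, "excluded") for pid in cdf["particle_id"]
        ]
        cdf["exclusion_reasons"] = [reason_of.get(pid, "") for pid in cdf["particle_id"]]
        cdf.to_csv(out / f"{sample_id}_classified.csv", index=False, float_format="%.6g")

        all_summary.extend(_summary_rows(classified))
        inputs.append(path.name)

    summary = pd.DataFrame(all_summary)
    summary.to_csv(out / "summary.csv", index=False, float_format="%.6g")
    manifest = {
        "tool": "mfgmorph",
        "version": __version__,
        "inputs": inputs,
        "config": config.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return summary


def run_compare(
    summary_a, summary_b, config: PipelineConfig | None = None, out_path=None
) -> pd.DataFrame:
    """Agreement report between two per-sample summary CSVs (or DataFrames).

    Rows are matched on (sample_id, particle_class); every shared metric
    column yields one report row with r, p-values, CCC, mean bias, limits
    of agreement and the proportional-bias slope with its BCa CI.
    Differences are method A − method B.
    """
    config = config or PipelineConfig()
    a = pd.read_csv(summary_a) if not isinstance(summary_a, pd.DataFrame) else summary_a
    b = pd.read_csv(summary_b) if not isinstance(summary_b, pd.DataFrame) else summary_b
    for df, name in ((a, "A"), (b, "B")):
        if "sample_id" not in df.columns:
            raise ValueError(f"summary {name} lacks a sample_id column")
    keys = ["sample_id"]
    if "particle_class" in a.columns and "particle_class" in b.columns:
        keys.append("particle_class")
    only_a = set(map(tuple, a[keys].to_numpy())) - set(map(tuple, b[keys].to_numpy()))
    only_b = set(map(tuple, b[keys].to_numpy())) - set(map(tuple, a[keys].to_numpy()))
    if only_a or only_b:
        raise ValueError(
            f"unmatched sample ids: only in A {sorted(only_a)}, only in B {sorted(only_b)}"
        )
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    metrics = [c for c in _METRIC_COLUMNS if f"{c}_a" in merged.columns]

    rows = []
    classes = merged["particle_class"].unique() if "particle_class" in keys else [None]
    for cls in classes:
        part = merged if cls is None else merged[merged.particle_class == cls]
        for metric in metrics:
            x = part[f"{metric}_a"].to_numpy(float)
            y = part[f"{metric}_b"].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3:
                continue
            paired = PairedMeasurements(
                sample_ids=[str(s) for s in part["sample_id"][ok]], x=x[ok], y=y[ok]
            )
            res = compare_methods(paired, config.bootstrap)
            rows.append(
                {
                    "metric": metric,
                    "particle_class": cls if cls is not None else "all",
                    "n": int(ok.sum()),
                    "r": res.r,
                    "r_p": res.r_p,
                    "t_p": res.t_p,
                    "ccc": res.ccc,
                    "mean_diff": res.mean_diff,
                    "loa_low": res.loa[0],
                    "loa_high": res.loa[1],
                    "slope": res.slope,
                    "slope_ci_low": res.slope_ci[0],
                    "slope_ci_high": res.slope_ci[1],
                    "proportional_bias": res.proportional_bias,
                }
            )
    report = pd.DataFrame(rows)
    if out_path is not None:
        report.to_csv(out_path, index=False, float_format="%.6g")
    return report
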