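"""Quality-control filtering and individual/agglomerate classification.

QC exclusion (applied first, on descriptor records): a particle is
excluded when convexity < 0.750, solidity < 0.700, area < 100 pixels, or
intensity SD < 10 — strict inequalities, so values exactly at a threshold
are kept. The CE-diameter size gate (default 1.5–130 µm, inclusive) is
applied in the same pass so every exclusion is attributable.

Classification of QC-passing particles:

* individual  — HS circularity ≥ 0.920 and CE diameter < 25 µm;
* agglomerate — HS circularity < 0.920 and solidity < 0.970;
* unclassified — everything else (still counted in the total, mirroring
  instrument count tables whose class sums can fall short of the total).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import ParticleRecord

__all__ = [
    "ClassificationConfig",
    "ClassifiedSample",
    "qc_filter",
    "classify_record",
    "classify_sample",
    "tabulate",
]

_QC_FIELDS = ("convexity", "solidity", "area_px", "intensity_sd", "ce_diameter_um")


@dataclass
class ClassificationConfig:
    # QC exclusion thresholds (excluded when strictly below)
    min_convexity: float = 0.750
    min_solidity: float = 0.700
    min_area_px: int = 100
    min_intensity_sd: float = 10.0
    size_gate_um: tuple[float, float] = (1.5, 130.0)
    # class boundaries
    individual_min_hs_circularity: float = 0.920
    individual_max_ce_diameter_um: float = 25.0
    agglomerate_max_hs_circularity: float = 0.920
    agglomerate_max_solidity: float = 0.970
    # optional manual exclusion (stand-in for expert visual rejection)
    excluded_particle_ids: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name in (
            "min_convexity",
            "min_solidity",
            "min_area_px",
            "min_intensity_sd",
            "individual_min_hs_circularity",
            "individual_max_ce_diameter_um",
            "agglomerate_max_hs_circularity",
            "agglomerate_max_solidity",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.individual_min_hs_circularity != self.agglomerate_max_hs_circularity:
            raise ValueError(
                "the individual/agglomerate circularity boundary must be shared"
            )
        lo, hi = self.size_gate_um
        if not lo < hi:
            raise ValueError("size_gate_um must satisfy low < high")


@dataclass
class ClassifiedSample:
    """Per-sample classification outcome with class counts and percentages."""

    sample_id: str
    records: list[tuple[ParticleRecord, str]]  # (record, class label)
    excluded: list[tuple[ParticleRecord, list[str]]]  # (record, failed criteria)
    n_total: int
    n_individual: int
    n_agglomerate: int
    n_unclassified: int

    @property
    def pct_individual(self) -> float:
        return 100.0 * self.n_individual / self.n_total if self.n_total else float("nan")

    @property
    def pct_agglomerate(self) -> float:
        return 100.0 * self.n_agglomerate / self.n_total if self.n_total else float("nan")

    @property
    def pct_unclassified(self) -> float:
        return 100.0 * self.n_unclassified / self.n_total if self.n_total else float("nan")

    def diameters(self, particle_class: str | None = None) -> np.ndarray:
        """CE diameters (µm) of QC-passing particles of one class (or all)."""
        return np.array(
            [
                r.ce_diameter_um
                for r, lab in self.records
                if particle_class is None or lab == particle_class
            ]
        )


def _check_fields(record: ParticleRecord) -> None:
    for name in _QC_FIELDS:
        v = getattr(record, name, None)
        if v is None or (isinstance(v, float) and not np.isfinite(v)):
            raise ValueError(f"record {record.particle_id}: missing descriptor {name!r}")


def qc_reasons(record: ParticleRecord, config: ClassificationConfig) -> list[str]:
    """Every QC criterion the record fails (empty list = kept)."""
    _check_fields(record)
    reasons = []
    if record.convexity < config.min_convexity:
        reasons.append("convexity")
    if record.solidity < config.min_solidity:
        reasons.append("solidity")
    if record.area_px < config.min_area_px:
        reasons.append("area")
    if record.intensity_sd < config.min_intensity_sd:
        reasons.append("intensity_sd")
    lo, hi = config.size_gate_um
    if not lo <= record.ce_diameter_um <= hi:
        reasons.append("size_gate")
    if record.particle_id in config.excluded_particle_ids:
        reasons.append("manual")
    return reasons


def qc_filter(
    records: list[ParticleRecord], config: ClassificationConfig | None = None
) -> tuple[list[ParticleRecord], list[tuple[ParticleRecord, list[str]]]]:
    """Split records into (kept, excluded-with-reasons)."""
    config = config or ClassificationConfig()
    kept, excluded = [], []
    for r in records:
        reasons = qc_reasons(r, config)
        if reasons:
            excluded.append((r, reasons))
        else:
            kept.append(r)
    return kept, excluded


def classify_record(record: ParticleRecord, config: ClassificationConfig | None = None) -> str:
    """Class label of one QC-passing record."""
    config = config or ClassificationConfig()
    if (
        record.hs_circularity >= config.individual_min_hs_circularity
        and record.ce_diameter_um < config.individual_max_ce_diameter_um
    ):
        return "individual"
    if (
        record.hs_circularity < config.agglomerate_max_hs_circularity
        and record.solidity < config.agglomerate_max_solidity
    ):
        return "agglomerate"
    return "unclassified"


def classify_sample(
    sample_id: str,
    records: list[ParticleRecord],
    config: ClassificationConfig | None = None,
    apply_qc: bool = True,
) -> ClassifiedSample:
    """QC-filter (optionally) and classify all records of one sample."""
    config = config or ClassificationConfig()
    if apply_qc:
        kept, excluded = qc_filter(records, config)
    else:
        kept, excluded = list(records), []
    labeled = [(r, classify_record(r, config)) for r in kept]
    counts = {"individual": 0, "agglomerate": 0, "unclassified": 0}
    for _, lab in labeled:
        counts[lab] += 1
    return ClassifiedSample(
        sample_id=sample_id,
        records=labeled,
        excluded=excluded,
        n_total=len(labeled),
        n_individual=counts["individual"],
        n_agglomerate=counts["agglomerate"],
        n_unclassified=counts["unclassified"],
    )


def tabulate(samples: list[ClassifiedSample]) -> pd.DataFrame:
    """Per-sample count table with a Mean (SD) footer row.

    Columns mirror the instrument count-table layout: total n, then n and
    % for individual particles and agglomerates. Percentages of an empty
    sample are reported as missing, not zero.
    """
    if not samples:
        raise ValueError("at least one classified sample required")
    rows = [
        {
            "sample_id": s.sample_id,
            "n_total": s.n_total,
            "n_individual": s.n_individual,
            "pct_individual": s.pct_individual,
            "n_agglomerate": s.n_agglomerate,
            "pct_agglomerate": s.pct_agglomerate,
            "n_unclassified": s.n_unclassified,
        }
        for s in samples
    ]
    df = pd.DataFrame(rows)
    numeric = df.drop(columns="sample_id")
    mean = numeric.mean()
    sd = numeric.std(ddof=1)
    footer_mean = {"sample_id": "Mean", **mean.to_dict()}
    footer_sd = {"sample_id": "SD", **sd.to_dict()}
    return pd.concat(
        [df, pd.DataFrame([footer_mean, footer_sd])], ignore_index=True
    )
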