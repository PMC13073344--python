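"""Packaged per-sample study data and in-package reproduction targets.

Three CSV tables ship inside the package (``mfgmorph/data``), transcribed
verbatim from the source study of 12 human-milk samples:

* ``study_covariates`` — maternal/infant covariates and sample handling
  (age, infant sex, breastfeeding months, birth status, frozen-storage
  days, dilution flag);
* ``study_counts`` — per-sample particle counts and percentages by class
  (total / individual particles / agglomerates);
* ``study_metrics`` — per-sample, per-class number-weighted CE-diameter
  metrics (D[1,0], Pn10/50/90) and per-class median morphology values
  (intensity SD, HS circularity, convexity, elongation, solidity).

``reproduce_summaries`` recomputes the derived statistics those tables
imply (column means/SDs and the storage-duration Pearson correlations)
and compares each against the published value at its printed precision.

Known transcription quirks, preserved verbatim rather than "repaired":

* sample 3's class counts sum to 73,498 against a printed total of
  74,498 — validation therefore only requires class sums ≤ total (a
  third, unclassified bucket absorbs either reading);
* the published storage-vs-Pn50 correlations cannot be reconciled with
  their class labels (recomputation gives −0.554 for agglomerates and
  −0.343 for individuals, while −0.554 is labeled "Individual"); those
  rows are reported with status ``flagged`` instead of pass/fail.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["StudyFixture", "load_fixture", "reproduce_summaries"]

_CHECKSUMS = {
    "study_covariates.csv": "4bfe1cca5125a16698172128090d0543ea5c325b39dd143548101cfdb46b03d0",
    "study_counts.csv": "fd5c2c053eb3d13b4460bcc2c99710985c106156d282a4378f34e605afa5a7c8",
    "study_metrics.csv": "e449e599a49c58ebaadc00ae8b90deedee54904bad95eded5619fa346660966f",
}

N_SAMPLES = 12

# Published summary values: name -> (value, decimals, kind)
# kind: "mean"/"sd" of a column, or "corr" for a storage-duration Pearson r.
PRINTED = {
    "mean_storage_days": (14.7, 1),
    "sd_storage_days": (7.3, 1),
    "mean_age_years": (34.2, 1),
    "mean_breastfeeding_months": (7.1, 1),
    "mean_total_count": (99873.0, 0),
    "mean_individual_count": (83825.83, 2),
    "mean_agglomerate_count": (15963.83, 2),
    "mean_pct_agglomerate": (15.25, 2),
    "sd_pct_agglomerate": (6.93, 2),
    "mean_d10_total": (4.91, 2),
    "mean_d10_individual": (4.36, 2),
    "mean_d10_agglomerate": (8.00, 2),
    "mean_pn10_total": (2.77, 2),
    "mean_pn50_total": (4.21, 2),
    "mean_pn90_total": (7.56, 2),
    "mean_pn90_agglomerate": (11.96, 2),
    "corr_storage_d10_total": (-0.481, 3),
    "corr_storage_pn10_agglomerate": (-0.631, 3),
}

# Published Pn50 storage correlations whose class labels do not survive
# independent recomputation (see module docstring). value -> printed label.
PRINTED_FLAGGED = {
    "corr_storage_pn50_individual": (-0.554, 3),
    "corr_storage_pn50_agglomerate": (-0.526, 3),
    # The published mean individual percentage is the complement of the
    # agglomerate mean (100 − 15.25), not the mean of the printed per-sample
    # column (84.64): sample 3's percentages do not sum to 100.
    "mean_pct_individual": (84.75, 2),
}


@dataclass
class StudyFixture:
    covariates: pd.DataFrame
    counts: pd.DataFrame
    metrics: pd.DataFrame


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("mfgmorph.data") / name
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(
            f"fixture {name} failed its checksum pin: got {digest}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_fixture() -> StudyFixture:
    """Load and validate the three packaged study tables."""
    cov = _read("study_covariates.csv")
    cnt = _read("study_counts.csv")
    met = _read("study_metrics.csv")

    problems: list[str] = []
    for name, df, nrow in (("covariates", cov, N_SAMPLES),
                           ("counts", cnt, N_SAMPLES),
                           ("metrics", met, 3 * N_SAMPLES)):
        if len(df) != nrow:
            problems.append(f"{name}: expected {nrow} rows, found {len(df)}")
    ids = set(range(1, N_SAMPLES + 1))
    for name, df in (("covariates", cov), ("counts", cnt), ("metrics", met)):
        if set(df["sample_id"]) != ids:
            problems.append(f"{name}: sample ids do not cover 1..{N_SAMPLES}")
    over = cnt[cnt.n_individual + cnt.n_agglomerate > cnt.n_total]
    for _, row in over.iterrows():
        problems.append(
            f"counts sample {row.sample_id}: class sum "
            f"{row.n_individual + row.n_agglomerate} exceeds total {row.n_total}"
        )
    bad = met[(met.pn10 > met.pn50) | (met.pn50 > met.pn90)]
    for _, row in bad.iterrows():
        problems.append(
            f"metrics sample {row.sample_id}/{row.particle_class}: "
            "percentiles not ordered"
        )
    if problems:
        raise ValueError("fixture validation failed:\n  " + "\n  ".join(problems))
    return StudyFixture(covariates=cov, counts=cnt, metrics=met)


def _recompute(fixture: StudyFixture) -> dict[str, float]:
    cov, cnt, met = fixture.covariates, fixture.counts, fixture.metrics
    by_class = {c: met[met.particle_class == c].set_index("sample_id").sort_index()
                for c in ("total", "individual", "agglomerate")}
    storage = cov.sort_values("sample_id")["storage_days"].to_numpy(float)

    def corr(col: np.ndarray) -> float:
        return float(np.corrcoef(storage, col)[0, 1])

    out = {
        "mean_storage_days": cov.storage_days.mean(),
        "sd_storage_days": cov.storage_days.std(ddof=1),
        "mean_age_years": cov.age_years.mean(),
        "mean_breastfeeding_months": cov.breastfeeding_months.mean(),
        "mean_total_count": cnt.n_total.mean(),
        "mean_individual_count": cnt.n_individual.mean(),
        "mean_agglomerate_count": cnt.n_agglomerate.mean(),
        "mean_pct_individual": cnt.pct_individual.mean(),
        "mean_pct_agglomerate": cnt.pct_agglomerate.mean(),
        "sd_pct_agglomerate": cnt.pct_agglomerate.std(ddof=1),
        "mean_d10_total": by_class["total"].d10.mean(),
        "mean_d10_individual": by_class["individual"].d10.mean(),
        "mean_d10_agglomerate": by_class["agglomerate"].d10.mean(),
        "mean_pn10_total": by_class["total"].pn10.mean(),
        "mean_pn50_total": by_class["total"].pn50.mean(),
        "mean_pn90_total": by_class["total"].pn90.mean(),
        "mean_pn90_agglomerate": by_class["agglomerate"].pn90.mean(),
        "corr_storage_d10_total": corr(by_class["total"].d10.to_numpy(float)),
        "corr_storage_pn10_agglomerate": corr(
            by_class["agglomerate"].pn10.to_numpy(float)
        ),
        "corr_storage_pn50_individual": corr(
            by_class["individual"].pn50.to_numpy(float)
        ),
        "corr_storage_pn50_agglomerate": corr(
            by_class["agglomerate"].pn50.to_numpy(float)
        ),
    }
    return {k: float(v) for k, v in out.items()}


def reproduce_summaries(fixture: StudyFixture | None = None) -> pd.DataFrame:
    """Recompute every derived summary and compare with the printed value.

    Returns a DataFrame with columns quantity, recomputed, printed,
    abs_diff, tolerance (one unit of printed precision) and status
    (``pass`` / ``fail`` / ``flagged`` for the irreconcilable Pn50 rows).
    """
    fixture = fixture or load_fixture()
    values = _recompute(fixture)
    rows = []
    for name, (printed, dp) in {**PRINTED, **PRINTED_FLAGGED}.items():
        recomputed = values[name]
        tol = 10.0 ** (-dp)
        diff = abs(recomputed - printed)
        if name in PRINTED_FLAGGED:
            status = "flagged"
        else:
            status = "pass" if diff <= tol else "fail"
        rows.append(
            {
                "quantity": name,
                "recomputed": recomputed,
                "printed": printed,
                "abs_diff": diff,
                "tolerance": tol,
                "status": status,
            }
        )
    return pd.DataFrame(rows)
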