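"""Cross-reconstruction comparison: the study design matrix, differences
against the FBP 5 mm reference, Bland-Altman agreement and summary statistics.

The design matrix mirrors the study: each PET-CT dataset is reconstructed 6
times (FBP and OSEM, each with 5/10/15 mm post-filters) and each PET-MR
dataset 13 times (OSEM with the three filters plus BSREM/"Q.Clear" at
beta = 100..1000).  NEMA datasets use 8 OSEM subsets and Hoffman datasets 16.

Differences are reported as ``reference - method`` (the sign convention the
study's reported differences follow, e.g. SNR 23.0 vs 84.8 printed as
-61.8).  Bland-Altman agreement between two paired metric series reports the
mean difference (bias) and 1.96 SD limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recon import ConfigError, ReconConfig

__all__ = [
    "DATASET_PHANTOMS",
    "MODALITIES",
    "ReconMatrix",
    "MetricRecord",
    "BlandAltmanResult",
    "SummaryStats",
    "build_recon_matrix",
    "records_to_frame",
    "difference_vs_reference",
    "bland_altman",
    "coefficient_of_variation",
    "summary_stats",
]

DATASET_PHANTOMS = {
    "F18_NEMA": "nema",
    "F18_HOFFMAN": "hoffman",
    "C11_HOFFMAN": "hoffman",
}
MODALITIES = ("PET-CT", "PET-MR")
FILTERS_MM = (5.0, 10.0, 15.0)
BETA_GRID = tuple(float(b) for b in range(100, 1001, 100))


@dataclass
class MetricRecord:
    dataset: str
    modality: str
    recon: str
    metric: str
    value: float
    units: str = ""
    sphere_diameter_mm: float | None = None


@dataclass
class ReconMatrix:
    rows: list[tuple[str, str, ReconConfig]] = field(default_factory=list)

    def configs_for(self, dataset: str, modality: str) -> list[ReconConfig]:
        return [c for d, m, c in self.rows if d == dataset and m == modality]


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int


@dataclass
class SummaryStats:
    mean: float
    sd: float
    median: float
    cv_percent: float


def _configs(modality: str, phantom: str, betas=BETA_GRID, filters=FILTERS_MM):
    subsets = 8 if phantom == "nema" else 16
    osem = [
        ReconConfig("OSEM", iterations=4, subsets=subsets, post_filter_fwhm_mm=f)
        for f in filters
    ]
    if modality == "PET-CT":
        fbp = [ReconConfig("FBP", post_filter_fwhm_mm=f) for f in filters]
        return fbp + osem
    return osem + [
        ReconConfig("BSREM", iterations=25, subsets=subsets, beta=b) for b in betas
    ]


def build_recon_matrix(
    datasets: list[tuple[str, str]] | None = None,
    betas=BETA_GRID,
    filters=FILTERS_MM,
) -> ReconMatrix:
    """Build the reconstruction design matrix for the requested
    (dataset, modality) pairs (all six by default)."""
    if datasets is None:
        datasets = [(d, m) for d in DATASET_PHANTOMS for m in MODALITIES]
    rows = []
    for dataset, modality in datasets:
        if dataset not in DATASET_PHANTOMS:
            raise ConfigError(f"unknown dataset {dataset!r}")
        if modality not in MODALITIES:
            raise ConfigError(f"unknown modality {modality!r}")
        for cfg in _configs(modality, DATASET_PHANTOMS[dataset], betas, filters):
            rows.append((dataset, modality, cfg))
    return ReconMatrix(rows)


def records_to_frame(records: list[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dataset": r.dataset,
                "modality": r.modality,
                "recon": r.recon,
                "metric": r.metric,
                "sphere_diameter_mm": r.sphere_diameter_mm,
                "value": r.value,
                "units": r.units,
            }
            for r in records
        ]
    )


def difference_vs_reference(
    records: list[MetricRecord] | pd.DataFrame,
    reference_nomenclature: str = "FBP_5mm",
) -> tuple[pd.DataFrame, list[dict]]:
    """Differences ``reference - method`` per (dataset, metric, sphere).

    The reference value is the record with ``reference_nomenclature`` for the
    same dataset (phantom + isotope), regardless of modality — the study
    compares PET-MR reconstructions against the PET-CT FBP reference.
    Missing references are returned in an exclusions list, never silently
    dropped.
    """
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    df["sphere_diameter_mm"] = df["sphere_diameter_mm"].astype(float)
    rows, exclusions = [], []
    for (dataset, metric, sphere), grp in df.groupby(
        ["dataset", "metric", "sphere_diameter_mm"], dropna=False
    ):
        ref = grp[grp["recon"] == reference_nomenclature]
        if ref.empty:
            exclusions.append(
                {"dataset": dataset, "metric": metric, "sphere_diameter_mm": sphere}
            )
            continue
        ref_value = float(ref["value"].iloc[0])
        for _, r in grp.iterrows():
            rows.append(
                {
                    "dataset": dataset,
                    "modality": r["modality"],
                    "metric": metric,
                    "sphere_diameter_mm": sphere,
                    "recon": r["recon"],
                    "value": r["value"],
                    "reference": reference_nomenclature,
                    "reference_value": ref_value,
                    "difference": ref_value - r["value"],
                }
            )
    return pd.DataFrame(rows), exclusions


def bland_altman(series_a, series_b) -> BlandAltmanResult:
    """Bland-Altman agreement of paired series: bias = mean(a - b), limits of
    agreement at bias +/- 1.96 SD (N-1 denominator)."""
    a = np.asarray(series_a, dtype=np.float64)
    b = np.asarray(series_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"pairing error: lengths {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n_pairs=int(a.size),
    )


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV% = 100 * SD / mean."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * sd / mean


def summary_stats(values) -> SummaryStats:
    """Mean, sample SD (N-1), median and CV% of a metric series."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    return SummaryStats(
        mean=mean,
        sd=sd,
        median=float(np.median(v)),
        cv_percent=coefficient_of_variation(mean, sd),
    )
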