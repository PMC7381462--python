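"""Quality-control filtering, TIC normalization and mean centering.

Four filters are applied in a fixed order to each cohort's feature matrix:

1. mass accuracy — drop lipids whose mean |ppm deviation| exceeds 5 ppm;
2. blank ratio — drop signals whose mean sample intensity is less than
   5x their mean intensity in extraction blanks;
3. missingness — drop signals with zero values in more than 10% of samples;
4. dilution linearity — drop lipids whose intensity does not correlate
   (Pearson r >= 0.9) with serum fraction across the 100/50/25% QC series.

All four thresholds are strict inequalities. Retained signals are then
normalized to total signal intensity per sample (TIC) and mean-centred per
cohort so the two cohorts are directly comparable.

Each filter is a scikit-learn style transformer (``fit`` learns the columns
to drop, ``transform`` drops them); the module-level ``filter_*`` functions
are thin wrappers that also emit a :class:`FilterEntry` for the run report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .spectra import QC_SERUM_FRACTION, FeatureMatrix

__all__ = [
    "FilterEntry",
    "FilterReport",
    "MassDeviationFilter",
    "BlankRatioFilter",
    "MissingnessFilter",
    "DilutionLinearityFilter",
    "TICNormalizer",
    "CohortMeanCenterer",
    "filter_mass_deviation",
    "filter_blank_ratio",
    "filter_missingness",
    "filter_qc_linearity",
    "normalize_tic",
    "mean_center",
    "run_qc_pipeline",
]


@dataclass
class FilterEntry:
    """Audit record of one filter application."""

    name: str
    threshold: float
    lipids_in: list[str]
    lipids_removed: list[str]
    notes: dict = field(default_factory=dict)

    @property
    def lipids_out(self) -> list[str]:
        removed = set(self.lipids_removed)
        return [l for l in self.lipids_in if l not in removed]


@dataclass
class FilterReport:
    """Ordered filter audit for one cohort."""

    cohort_id: str
    entries: list[FilterEntry] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        return self.entries[-1].lipids_out if self.entries else []

    def add(self, entry: FilterEntry) -> None:
        if self.entries and entry.lipids_in != self.entries[-1].lipids_out:
            raise ValueError("filter chain broken: inputs do not match previous outputs")
        self.entries.append(entry)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filter": [e.name for e in self.entries],
                "threshold": [e.threshold for e in self.entries],
                "n_in": [len(e.lipids_in) for e in self.entries],
                "n_removed": [len(e.lipids_removed) for e in self.entries],
                "removed": [";".join(e.lipids_removed) for e in self.entries],
            }
        )


class _ColumnDropper(BaseEstimator):
    """Shared fit/transform plumbing for per-column filters."""

    def fit(self, m: FeatureMatrix, **kw) -> "_ColumnDropper":
        removed, notes = self._removed(m, **kw)
        self.removed_ = list(removed)
        self.retained_ = [l for l in m.lipids if l not in set(removed)]
        self.notes_ = notes
        return self

    def transform(self, m: FeatureMatrix) -> FeatureMatrix:
        return m.subset_lipids(
            [l for l in m.lipids if l not in set(self.removed_)],
            log_entry=f"{self._name}(removed={len(self.removed_)})",
        )

    def fit_transform(self, m: FeatureMatrix, **kw) -> FeatureMatrix:
        return self.fit(m, **kw).transform(m)

    def entry(self, m: FeatureMatrix) -> FilterEntry:
        return FilterEntry(
            name=self._name,
            threshold=self._threshold,
            lipids_in=list(m.lipids),
            lipids_removed=list(self.removed_),
            notes=self.notes_,
        )


class MassDeviationFilter(_ColumnDropper):
    """Drop lipids whose mean mass deviation exceeds ``max_ppm`` (strict).

    By default the mean of |signed ppm deviation| over matched samples is
    used, so large symmetric errors cannot cancel; ``signed=True`` switches to
    the signed mean. Lipids that never matched (no deviations at all) are
    removed and reported distinctly.
    """

    _name = "mass_deviation"

    def __init__(self, max_ppm: float = 5.0, signed: bool = False):
        self.max_ppm = max_ppm
        self.signed = signed

    @property
    def _threshold(self) -> float:
        return self.max_ppm

    def _removed(self, m: FeatureMatrix) -> tuple[list[str], dict]:
        mean_dev = m.mean_signed_deviation().abs() if self.signed else m.mean_abs_deviation()
        never = mean_dev.index[mean_dev.isna()].tolist()
        over = mean_dev.index[(mean_dev > self.max_ppm).fillna(False)].tolist()
        return never + over, {"never_matched": never, "over_threshold": over}


class BlankRatioFilter(_ColumnDropper):
    """Drop signals whose mean sample intensity is < ``min_ratio`` x blank mean.

    A lipid with zero blank signal has infinite ratio and is always retained.
    """

    _name = "blank_ratio"

    def __init__(self, min_ratio: float = 5.0):
        self.min_ratio = min_ratio

    @property
    def _threshold(self) -> float:
        return self.min_ratio

    def _removed(self, m: FeatureMatrix, blanks: FeatureMatrix = None) -> tuple[list[str], dict]:
        if blanks is None or len(blanks.samples) == 0:
            raise ValueError("blank matrix required and must be nonempty")
        blank_mean = blanks.intensities.reindex(columns=m.lipids).fillna(0.0).mean(axis=0)
        sample_mean = m.intensities.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = sample_mean / blank_mean
        removed = m.lipids[(blank_mean > 0) & (sample_mean < self.min_ratio * blank_mean)]
        no_blank = m.lipids[(blank_mean == 0) & (sample_mean > 0)].tolist()
        return list(removed), {"ratio": ratio.to_dict(), "no_blank_signal": no_blank}


class MissingnessFilter(_ColumnDropper):
    """Drop signals with zero values in more than ``max_zero_frac`` of samples."""

    _name = "missingness"

    def __init__(self, max_zero_frac: float = 0.10):
        self.max_zero_frac = max_zero_frac

    @property
    def _threshold(self) -> float:
        return self.max_zero_frac

    def _removed(self, m: FeatureMatrix) -> tuple[list[str], dict]:
        zero_frac = (m.intensities == 0).mean(axis=0)
        removed = m.lipids[zero_frac > self.max_zero_frac]
        return list(removed), {"zero_frac": zero_frac.to_dict()}


class DilutionLinearityFilter(_ColumnDropper):
    """Drop lipids with Pearson r < ``min_r`` against QC serum fraction.

    r is computed over every QC replicate (levels x replicates points), not
    over level means, so replicate scatter informs the fit. A lipid with zero
    variance across the QC series has undefined r and is removed: a flat
    signal cannot show the required linear increase.
    """

    _name = "qc_linearity"

    def __init__(self, min_r: float = 0.9):
        self.min_r = min_r

    @property
    def _threshold(self) -> float:
        return self.min_r

    def _removed(self, m: FeatureMatrix, qc: FeatureMatrix = None) -> tuple[list[str], dict]:
        if qc is None:
            raise ValueError("QC matrix required")
        fracs = qc.row_roles.map(QC_SERUM_FRACTION)
        if fracs.isna().any():
            raise ValueError("QC matrix contains non-QC rows")
        present = sorted(set(qc.row_roles))
        if len(present) < len(QC_SERUM_FRACTION):
            raise ValueError(f"need all QC levels, got {present}")
        x = fracs.to_numpy(dtype=float)
        X = qc.intensities.reindex(columns=m.lipids).fillna(0.0).to_numpy()
        xc = x - x.mean()
        Yc = X - X.mean(axis=0)
        denom = np.sqrt((xc**2).sum() * (Yc**2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (xc @ Yc) / denom
        r = pd.Series(r, index=m.lipids)
        undefined = r.index[r.isna()].tolist()
        failed = r.index[(r < self.min_r).fillna(False)].tolist()
        return undefined + failed, {"r": r.to_dict(), "undefined_r": undefined}


class TICNormalizer(BaseEstimator):
    """Normalize each sample to total signal intensity (rows sum to 1).

    Stateless and idempotent; controls for differing amounts of biological
    material (e.g. blood-spot punch volume) between samples.
    """

    def fit(self, m, y=None):
        self.n_features_in_ = m.intensities.shape[1] if isinstance(m, FeatureMatrix) else np.shape(m)[1]
        return self

    def transform(self, m: FeatureMatrix) -> FeatureMatrix:
        totals = m.intensities.sum(axis=1)
        zero = totals[totals == 0]
        if len(zero) > 0:
            raise ValueError(f"all-zero sample(s) cannot be TIC-normalized: {list(zero.index)[:5]}")
        return m.copy_with(m.intensities.div(totals, axis=0), "tic_normalize")

    def fit_transform(self, m: FeatureMatrix, y=None) -> FeatureMatrix:
        return self.fit(m).transform(m)


class CohortMeanCenterer(BaseEstimator):
    """Subtract per-lipid column means, learned from the cohort itself.

    Centering is per cohort: each cohort's matrix is centred on its own means
    so the two cohorts can be compared on a common scale.
    """

    def fit(self, m: FeatureMatrix, y=None):
        self.means_ = m.intensities.mean(axis=0)
        return self

    def transform(self, m: FeatureMatrix) -> FeatureMatrix:
        return m.copy_with(m.intensities - self.means_, "mean_center")

    def fit_transform(self, m: FeatureMatrix, y=None) -> FeatureMatrix:
        return self.fit(m).transform(m)


def _apply(flt: _ColumnDropper, m: FeatureMatrix, **kw) -> tuple[FeatureMatrix, FilterEntry]:
    flt.fit(m, **kw)
    return flt.transform(m), flt.entry(m)


def filter_mass_deviation(
    m: FeatureMatrix, max_ppm: float = 5.0, signed: bool = False
) -> tuple[FeatureMatrix, FilterEntry]:
    return _apply(MassDeviationFilter(max_ppm, signed), m)


def filter_blank_ratio(
    m: FeatureMatrix, blanks: FeatureMatrix, min_ratio: float = 5.0
) -> tuple[FeatureMatrix, FilterEntry]:
    return _apply(BlankRatioFilter(min_ratio), m, blanks=blanks)


def filter_missingness(
    m: FeatureMatrix, max_zero_frac: float = 0.10
) -> tuple[FeatureMatrix, FilterEntry]:
    return _apply(MissingnessFilter(max_zero_frac), m)


def filter_qc_linearity(
    m: FeatureMatrix, qc: FeatureMatrix, min_r: float = 0.9
) -> tuple[FeatureMatrix, FilterEntry]:
    return _apply(DilutionLinearityFilter(min_r), m, qc=qc)


def normalize_tic(m: FeatureMatrix) -> FeatureMatrix:
    return TICNormalizer().fit_transform(m)


def mean_center(m: FeatureMatrix) -> FeatureMatrix:
    return CohortMeanCenterer().fit_transform(m)


def run_qc_pipeline(
    samples: FeatureMatrix,
    blanks: FeatureMatrix,
    qc: FeatureMatrix,
    max_ppm: float = 5.0,
    min_blank_ratio: float = 5.0,
    max_zero_frac: float = 0.10,
    min_qc_r: float = 0.9,
    signed_deviation: bool = False,
    enabled: bool = True,
) -> tuple[FeatureMatrix, FilterReport]:
    """Filters 1→4, then TIC normalization, then per-cohort mean centering.

    With ``enabled=False`` the four filters become pass-throughs (zero
    removals are still reported) but normalization/centering still apply.
    """
    report = FilterReport(cohort_id=samples.cohort_id)
    m = samples
    steps = [
        (MassDeviationFilter(max_ppm, signed_deviation), {}),
        (BlankRatioFilter(min_blank_ratio), {"blanks": blanks}),
        (MissingnessFilter(max_zero_frac), {}),
        (DilutionLinearityFilter(min_qc_r), {"qc": qc}),
    ]
    for flt, kw in steps:
        if enabled:
            new_m, entry = _apply(flt, m, **kw)
        else:
            new_m, entry = m, FilterEntry(flt._name, flt._threshold, list(m.lipids), [])
        report.add(entry)
        m = new_m
    if len(m.lipids) == 0:
        raise ValueError("all lipids removed by QC filtering")
    m = normalize_tic(m)
    m = mean_center(m)
    return m, report
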