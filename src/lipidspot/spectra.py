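"""Spectral matching: assign centroids to lipid targets and build feature matrices.

Direct-infusion MS yields one composite centroided spectrum per sample. Each
lipid species in a target library is looked up by m/z within a ppm window; the
matched centroid's intensity and signed ppm mass deviation are recorded per
lipid per sample, and the per-sample records are assembled into a subjects x
lipids :class:`FeatureMatrix` with a parallel mass-deviation table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "Spectrum",
    "LipidTarget",
    "LipidSignal",
    "FeatureMatrix",
    "match_spectrum",
    "build_matrix",
]

#: serum fraction of each QC dilution level
QC_SERUM_FRACTION = {"qc100": 1.0, "qc50": 0.5, "qc25": 0.25}


class Role(str, Enum):
    """Sample role in an acquisition batch."""

    SAMPLE = "sample"
    BLANK = "blank"
    QC100 = "qc100"
    QC50 = "qc50"
    QC25 = "qc25"


@dataclass(frozen=True)
class LipidTarget:
    """A named lipid species with its expected m/z, used for peak assignment."""

    name: str
    lipid_class: str
    expected_mz: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.expected_mz) or self.expected_mz <= 0:
            raise ValueError(f"expected_mz must be positive, got {self.expected_mz}")


@dataclass
class Spectrum:
    """One sample's centroided peak list with its acquisition role.

    Peaks are an (n, 2) array of (m/z, intensity); m/z strictly increasing,
    intensities non-negative.
    """

    sample_id: str
    role: Role
    batch: str
    peaks: np.ndarray

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        peaks = np.asarray(self.peaks, dtype=float)
        if peaks.size == 0:
            peaks = peaks.reshape(0, 2)
        if peaks.ndim != 2 or peaks.shape[1] != 2:
            raise ValueError("peaks must be an (n, 2) array of (m/z, intensity)")
        if peaks.shape[0] > 1 and not np.all(np.diff(peaks[:, 0]) > 0):
            bad = int(np.flatnonzero(np.diff(peaks[:, 0]) <= 0)[0]) + 1
            raise ValueError(
                f"spectrum {self.sample_id!r}: m/z not strictly increasing at row {bad}"
            )
        if np.any(peaks[:, 1] < 0):
            raise ValueError(f"spectrum {self.sample_id!r}: negative intensity")
        self.peaks = peaks

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]


@dataclass(frozen=True)
class LipidSignal:
    """One lipid's record in one sample.

    ``mass_deviation_ppm`` is signed, (observed - expected)/expected * 1e6,
    and ``None`` when no peak fell inside the match window; in that case
    intensity is 0 by convention so unmatched lipids feed the missingness
    filter naturally.
    """

    lipid_name: str
    sample_id: str
    intensity: float
    mass_deviation_ppm: float | None
    shared_window: bool = False


@dataclass
class FeatureMatrix:
    """Samples x lipids intensity table with paired mass-deviation table.

    ``deviations`` holds the signed ppm deviation per cell (NaN where the
    lipid did not match). ``row_roles`` records each row's acquisition role so
    QC matrices know their serum fractions. ``transform_log`` is append-only
    provenance of the transforms applied.
    """

    intensities: pd.DataFrame
    deviations: pd.DataFrame | None = None
    transform_log: list[str] = field(default_factory=list)
    cohort_id: str = "cohort"
    row_roles: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.intensities.index.duplicated().any():
            raise ValueError("duplicate sample ids in feature matrix")
        if self.intensities.columns.duplicated().any():
            raise ValueError("duplicate lipid names in feature matrix")
        if self.deviations is not None:
            if not self.deviations.index.equals(self.intensities.index) or not (
                self.deviations.columns.equals(self.intensities.columns)
            ):
                raise ValueError("deviation table labels must mirror the intensity table")
        if self.row_roles is None:
            self.row_roles = pd.Series(
                Role.SAMPLE.value, index=self.intensities.index, name="role"
            )

    @property
    def samples(self) -> pd.Index:
        return self.intensities.index

    @property
    def lipids(self) -> pd.Index:
        return self.intensities.columns

    def mean_abs_deviation(self) -> pd.Series:
        """Mean |ppm deviation| per lipid over the samples where it matched."""
        if self.deviations is None:
            raise ValueError("feature matrix has no deviation table")
        return self.deviations.abs().mean(axis=0, skipna=True)

    def mean_signed_deviation(self) -> pd.Series:
        if self.deviations is None:
            raise ValueError("feature matrix has no deviation table")
        return self.deviations.mean(axis=0, skipna=True)

    def subset_lipids(self, keep: Sequence[str], log_entry: str | None = None) -> "FeatureMatrix":
        keep = list(keep)
        out = FeatureMatrix(
            intensities=self.intensities.loc[:, keep].copy(),
            deviations=None if self.deviations is None else self.deviations.loc[:, keep].copy(),
            transform_log=list(self.transform_log),
            cohort_id=self.cohort_id,
            row_roles=self.row_roles.copy(),
        )
        if log_entry:
            out.transform_log.append(log_entry)
        return out

    def copy_with(self, intensities: pd.DataFrame, log_entry: str) -> "FeatureMatrix":
        out = FeatureMatrix(
            intensities=intensities,
            deviations=None if self.deviations is None else self.deviations.copy(),
            transform_log=list(self.transform_log) + [log_entry],
            cohort_id=self.cohort_id,
            row_roles=self.row_roles.copy(),
        )
        return out


def ppm_deviation(observed_mz: float, expected_mz: float) -> float:
    """Signed mass deviation in parts per million."""
    return (observed_mz - expected_mz) / expected_mz * 1e6


def match_spectrum(
    spectrum: Spectrum,
    library: Sequence[LipidTarget],
    window_ppm: float = 10.0,
) -> list[LipidSignal]:
    """Assign each library target the nearest in-window centroid of a spectrum.

    For every target the peak with the smallest |ppm deviation| within
    ±``window_ppm`` is assigned and its intensity and signed deviation are
    recorded. Targets with no in-window peak get intensity 0 and an absent
    deviation. Ties (two peaks equidistant in ppm) go to the more intense
    peak, deterministically. A peak may serve several targets only when their
    windows overlap; such signals are flagged ``shared_window``.
    """
    if window_ppm <= 0:
        raise ValueError("window_ppm must be positive")
    if len(library) == 0:
        raise ValueError("empty lipid library")
    names = [t.name for t in library]
    if len(set(names)) != len(names):
        raise ValueError("lipid names must be unique within a library")

    mz = spectrum.mz
    if mz.size == 0:
        warnings.warn(
            f"spectrum {spectrum.sample_id!r} is empty; all signals zero", stacklevel=2
        )
        return [
            LipidSignal(t.name, spectrum.sample_id, 0.0, None) for t in library
        ]

    expected = np.array([t.expected_mz for t in library])
    # candidate peaks bracketing each expected m/z
    hi = np.searchsorted(mz, expected)
    lo = np.clip(hi - 1, 0, mz.size - 1)
    hi = np.clip(hi, 0, mz.size - 1)

    assigned_peak = np.full(len(library), -1, dtype=int)
    deviation = np.full(len(library), np.nan)
    dev_lo = (mz[lo] - expected) / expected * 1e6
    dev_hi = (mz[hi] - expected) / expected * 1e6
    candidates = np.flatnonzero(
        (np.abs(dev_lo) <= window_ppm) | (np.abs(dev_hi) <= window_ppm)
    )
    for j in candidates:
        best = -1
        best_abs = np.inf
        for idx in {int(lo[j]), int(hi[j])}:
            dev = ppm_deviation(mz[idx], expected[j])
            a = abs(dev)
            if a > window_ppm:
                continue
            if a < best_abs or (
                a == best_abs and spectrum.intensity[idx] > spectrum.intensity[best]
            ):
                best, best_abs = idx, a
        if best >= 0:
            assigned_peak[j] = best
            deviation[j] = ppm_deviation(mz[best], expected[j])

    # flag peaks claimed by more than one target (overlapping windows)
    used, counts = np.unique(assigned_peak[assigned_peak >= 0], return_counts=True)
    shared = set(used[counts > 1])

    signals = []
    for j, target in enumerate(library):
        p = assigned_peak[j]
        if p < 0:
            signals.append(LipidSignal(target.name, spectrum.sample_id, 0.0, None))
        else:
            signals.append(
                LipidSignal(
                    target.name,
                    spectrum.sample_id,
                    float(spectrum.intensity[p]),
                    float(deviation[j]),
                    shared_window=p in shared,
                )
            )
    return signals


def match_spectra(
    spectra: Iterable[Spectrum],
    library: Sequence[LipidTarget],
    window_ppm: float = 10.0,
) -> list[LipidSignal]:
    """Match a collection of spectra against one library (flat signal list)."""
    out: list[LipidSignal] = []
    for s in spectra:
        out.extend(match_spectrum(s, library, window_ppm))
    return out


def build_matrix(
    signals: Iterable[LipidSignal],
    roles: dict[str, str | Role],
    role_filter: str | Role | set | None = Role.SAMPLE,
    cohort_id: str = "cohort",
) -> FeatureMatrix:
    """Assemble signals into a FeatureMatrix for samples of the given role(s).

    ``roles`` maps sample_id -> role for every sample that produced signals.
    ``role_filter`` may be a single role, a set of roles, or None (keep all).
    """
    if role_filter is None:
        wanted = {Role(r).value for r in Role}
    elif isinstance(role_filter, (set, frozenset, list, tuple)):
        wanted = {Role(r).value for r in role_filter}
    else:
        wanted = {Role(role_filter).value}
    role_map = {sid: Role(r).value for sid, r in roles.items()}

    rows: dict[str, dict[str, float]] = {}
    devs: dict[str, dict[str, float]] = {}
    seen: set[tuple[str, str]] = set()
    lipid_order: list[str] = []
    lipid_seen: set[str] = set()
    for sig in signals:
        if sig.lipid_name not in lipid_seen:
            lipid_seen.add(sig.lipid_name)
            lipid_order.append(sig.lipid_name)
        role = role_map.get(sig.sample_id)
        if role is None:
            raise ValueError(f"sample {sig.sample_id!r} has no declared role")
        if role not in wanted:
            continue
        key = (sig.sample_id, sig.lipid_name)
        if key in seen:
            raise ValueError(f"duplicate signal for sample/lipid {key}")
        seen.add(key)
        rows.setdefault(sig.sample_id, {})[sig.lipid_name] = sig.intensity
        if sig.mass_deviation_ppm is not None:
            devs.setdefault(sig.sample_id, {})[sig.lipid_name] = sig.mass_deviation_ppm

    index = pd.Index(list(rows), name="sample_id")
    intens = pd.DataFrame(rows).T.reindex(index=index, columns=lipid_order).fillna(0.0)
    deviations = pd.DataFrame(devs).T.reindex(index=index, columns=lipid_order)
    row_roles = pd.Series({sid: role_map[sid] for sid in index}, name="role")
    return FeatureMatrix(
        intensities=intens,
        deviations=deviations,
        cohort_id=cohort_id,
        row_roles=row_roles,
    )
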