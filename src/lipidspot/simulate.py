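"""Synthetic paired-cohort generator for the lipidomics → clinical-lipid pipeline.

The study data (a plasma cohort of middle-aged adults and a dried-blood-spot
cohort of children) are available only on request, so this module generates
two linked synthetic cohorts with the statistical structure the analysis
assumes: clinical lipoprotein tables matched in mean/SD to the published
cohort characteristics, per-subject centroided spectra whose lipid intensities
carry planted lipid–lipoprotein associations, ppm-scale mass error, blank
contamination, missingness, and a three-level QC dilution series — so every
downstream stage (matching, the four QC filters, panel selection, translation,
stratification) has positive and negative cases and is testable end to end.

Intensity model
---------------
For subject *i* and detectable lipid *j*,

    I_ij = B_j * max(eps, 1 + a_j * z_i(target_j) + e_ij) * LN(noise_cv)

where B_j is a per-lipid baseline, z_i the subject's z-scored lipoprotein
value, e_ij ~ N(0, bio_cv²) intrinsic biological scatter, and LN a
mean-one lognormal measurement noise with coefficient of variation
``noise_cv``. The amplitude a_j = bio_cv * sqrt(f/(1-f)) is calibrated so a
planted effect size *f* (fraction of variance explained) yields a lipid–
lipoprotein correlation of √f in the noise-free limit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import LipidTarget, Role, Spectrum

__all__ = [
    "CohortSpec",
    "Cohort",
    "PLASMA_COHORT",
    "DBS_COHORT",
    "make_lipid_library",
    "simulate_clinical",
    "simulate_spectra",
    "simulate_cohort",
    "make_paired_cohorts",
    "default_association_map",
    "friedewald_ldl",
]

LIPOPROTEINS = ("TriG", "HDL", "LDL", "TC")

#: acquisition m/z range
MZ_RANGE = (150.0, 2000.0)

#: default search window used by the matcher (ppm); library spacing must
#: exceed 3x this so assignments are unambiguous
DEFAULT_WINDOW_PPM = 10.0


def friedewald_ldl(tc: np.ndarray, hdl: np.ndarray, trig: np.ndarray) -> np.ndarray:
    """Friedewald estimate LDL = TC − HDL − TriG/2.2 (all mmol/L)."""
    return np.asarray(tc) - np.asarray(hdl) - np.asarray(trig) / 2.2


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``clinical_means``/``clinical_sds`` give the target mmol/L mean and SD of
    TriG, HDL and the pre-mix total cholesterol used by the Friedewald step;
    ``association_map`` plants lipid → (lipoprotein, variance fraction f)
    effects. ``n_fail_*`` counts plant lipids that each QC filter must catch:
    systematic >5 ppm mass error, blank contamination above 1/5 of the sample
    mean, excess zero rate, and an inverted (non-linear) dilution response.
    """

    cohort_id: str = "cohort"
    n_subjects: int = 200
    clinical_means: dict = field(
        default_factory=lambda: {"TriG": 1.53, "HDL": 1.51, "TC": 5.83}
    )
    clinical_sds: dict = field(
        default_factory=lambda: {"TriG": 1.00, "HDL": 0.42, "TC": 1.08}
    )
    n_lipids_detectable: int = 163
    shared_lipid_fraction: float = 0.71
    association_map: dict = field(default_factory=dict)
    noise_cv: float = 0.10
    bio_cv: float = 0.30
    missing_rate: float = 0.02
    mass_error_ppm_sd: float = 1.5
    seed: int = 0
    tc_mode: str = "hdl_plus_ldl"  # or "premix"
    n_blanks: int = 3
    n_qc_replicates: int = 3
    n_fail_mass: int = 3
    n_fail_blank: int = 3
    n_fail_missing: int = 3
    n_fail_qc: int = 3
    fail_mass_offset_ppm: float = 8.0
    fail_blank_ratio: float = 3.0
    fail_missing_rate: float = 0.30
    attenuation: float = 1.0
    n_contaminants: int = 20

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_lipids_detectable <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.shared_lipid_fraction <= 1.0:
            raise ValueError("shared_lipid_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if any(s < 0 for s in self.clinical_sds.values()):
            raise ValueError("clinical SDs must be non-negative")
        if self.noise_cv < 0 or self.bio_cv < 0 or self.mass_error_ppm_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.tc_mode not in ("hdl_plus_ldl", "premix"):
            raise ValueError("tc_mode must be 'hdl_plus_ldl' or 'premix'")


@dataclass
class Cohort:
    """One simulated cohort: spectra, clinical table, library and provenance."""

    cohort_id: str
    spec: CohortSpec
    clinical: pd.DataFrame
    spectra: list[Spectrum]
    library: list[LipidTarget]
    detectable: list[str]
    association_map: dict
    fail_lipids: dict = field(default_factory=dict)

    @property
    def roles(self) -> dict[str, str]:
        return {s.sample_id: s.role.value for s in self.spectra}


# Published cohort characteristics used as generator defaults: the plasma
# ("discovery") cohort of 777 adults and the dried-blood-spot ("validation")
# cohort of 835 children.
PLASMA_COHORT = CohortSpec(
    cohort_id="plasma",
    n_subjects=777,
    clinical_means={"TriG": 1.53, "HDL": 1.51, "TC": 5.83},
    clinical_sds={"TriG": 1.00, "HDL": 0.42, "TC": 1.08},
    n_lipids_detectable=163,
)
DBS_COHORT = CohortSpec(
    cohort_id="dbs",
    n_subjects=835,
    clinical_means={"TriG": 0.97, "HDL": 1.48, "TC": 4.09},
    clinical_sds={"TriG": 0.54, "HDL": 0.32, "TC": 0.65},
    n_lipids_detectable=118,
    attenuation=0.8,
)


def make_lipid_library(
    n_lipids: int = 1649, n_classes: int = 11, seed: int = 0
) -> list[LipidTarget]:
    """Generate a lipid target library with unambiguous m/z spacing.

    Targets are laid on a jittered geometric grid across the acquisition
    range so adjacent expected m/z are separated by more than 3x the default
    10 ppm match window, making assignments unambiguous by construction.
    """
    if n_classes < 1 or n_lipids < n_classes:
        raise ValueError("need n_lipids >= n_classes >= 1")
    lo, hi = MZ_RANGE[0] * 1.02, MZ_RANGE[1] * 0.98
    log_gap = math.log(hi / lo) / max(n_lipids - 1, 1)
    min_gap = 3.0 * DEFAULT_WINDOW_PPM * 1e-6
    if n_lipids > 1 and log_gap <= min_gap / 0.4:
        raise ValueError(
            f"{n_lipids} lipids cannot satisfy the >3x-window spacing in "
            f"[{MZ_RANGE[0]}, {MZ_RANGE[1]}] m/z"
        )
    rng = np.random.default_rng(seed)
    base = np.log(lo) + np.arange(n_lipids) * log_gap
    jitter = rng.uniform(-0.3, 0.3, size=n_lipids) * log_gap if n_lipids > 1 else np.zeros(1)
    mz = np.exp(base + jitter)
    classes = [f"class{1 + rng.integers(0, n_classes)}" for _ in range(n_lipids)]
    # guarantee every class is represented
    for k in range(n_classes):
        classes[k] = f"class{k + 1}"
    return [
        LipidTarget(name=f"L{j:04d}_{classes[j]}", lipid_class=classes[j], expected_mz=float(m))
        for j, m in enumerate(mz)
    ]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Positive-truncated normal draws."""
    if sd == 0:
        return np.full(n, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_clinical(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate a clinical lipoprotein table (mmol/L) for one cohort.

    TriG is drawn right-skewed (lognormal); HDL and a latent pre-mix total
    cholesterol are truncated-normal. LDL follows by Friedewald
    (LDL = TC_premix − HDL − TriG/2.2) and the reported TC is either
    HDL + LDL (default, mirroring the discovery cohort's description) or the
    latent pre-mix value, per ``spec.tc_mode``. Draws yielding non-positive
    LDL are rejection-resampled.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.n_subjects
    trig_mean = spec.clinical_means["TriG"]
    if trig_mean > 0:
        mu, sigma = _lognormal_params(trig_mean, spec.clinical_sds["TriG"])
    else:
        mu, sigma = -math.inf, 0.0

    def draw(k: int) -> pd.DataFrame:
        if trig_mean == 0:
            trig = np.zeros(k)
        elif sigma > 0:
            trig = np.exp(rng.normal(mu, sigma, size=k))
        else:
            trig = np.full(k, trig_mean)
        hdl = _truncnorm(rng, spec.clinical_means["HDL"], spec.clinical_sds["HDL"], k)
        tc_pre = _truncnorm(rng, spec.clinical_means["TC"], spec.clinical_sds["TC"], k)
        ldl = friedewald_ldl(tc_pre, hdl, trig)
        return pd.DataFrame({"TriG": trig, "HDL": hdl, "LDL": ldl, "_TC_premix": tc_pre})

    out = draw(n)
    bad = out["LDL"] <= 0
    if bad.mean() > 0.05:
        warnings.warn(
            f"{bad.mean():.0%} of draws gave non-positive LDL; rejection-resampling",
            stacklevel=2,
        )
    for _ in range(20):
        if not bad.any():
            break
        out.loc[bad, :] = draw(int(bad.sum())).to_numpy()
        bad = out["LDL"] <= 0
    else:
        raise RuntimeError("could not generate positive LDL after bounded retries")

    out["TC"] = out["HDL"] + out["LDL"] if spec.tc_mode == "hdl_plus_ldl" else out["_TC_premix"]
    out = out.drop(columns="_TC_premix")
    out.index = pd.Index(
        [f"{spec.cohort_id}_S{i:04d}" for i in range(n)], name="subject_id"
    )
    return out[list(LIPOPROTEINS)]


def default_association_map(
    detectable: Sequence[str],
    effects: Mapping[str, tuple[int, float]] | None = None,
    seed: int = 0,
) -> dict[str, tuple[str, float]]:
    """Plant panels of associated lipids for each lipoprotein.

    ``effects`` maps lipoprotein -> (panel size, per-lipid variance fraction
    f). Defaults mirror the reported panel sizes (12/11/10/11) with effect
    strengths ordered TriG > HDL > LDL ≈ TC, which reproduces the qualitative
    ordering of the published test-set correlations. Per-lipid strengths vary
    mildly (0.9x-1.1x of f) so the marginal lipid contribution tapers and
    forward panel growth needs most of the planted panel before matching the
    all-lipid model.
    """
    if effects is None:
        effects = {
            "TriG": (12, 0.30),
            "HDL": (11, 0.14),
            "LDL": (10, 0.07),
            "TC": (11, 0.06),
        }
    need = sum(k for k, _ in effects.values())
    if need > len(detectable):
        # small demo libraries: shrink panels proportionally, >= 1 lipid each
        factor = len(detectable) / (2 * need)
        effects = {
            t: (max(1, int(k * factor)), f) for t, (k, f) in effects.items()
        }
        need = sum(k for k, _ in effects.values())
        if need > len(detectable):
            raise ValueError("not enough detectable lipids to plant all panels")
    rng = np.random.default_rng(seed)
    names = list(detectable)
    amap: dict[str, tuple[str, float]] = {}
    pos = 0
    for target, (k, f) in effects.items():
        scales = np.linspace(1.1, 0.9, k)
        for s in scales:
            amap[names[pos]] = (target, float(np.clip(f * s, 0.005, 0.9)))
            pos += 1
    return amap


def _lipid_baselines(rng: np.random.Generator, n: int) -> np.ndarray:
    """Per-lipid baseline abundances, log-uniform over 4 decades."""
    return 10.0 ** rng.uniform(3.0, 7.0, size=n)


def _as_peaks(mz: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    """Sort peaks by m/z and merge exact duplicates (summed intensity)."""
    order = np.argsort(mz)
    mz, intensity = mz[order], intensity[order]
    if mz.size > 1 and np.any(np.diff(mz) <= 0):
        uniq, inv = np.unique(mz, return_inverse=True)
        merged = np.zeros_like(uniq)
        np.add.at(merged, inv, intensity)
        mz, intensity = uniq, merged
    return np.column_stack([mz, intensity])


def simulate_spectra(
    clinical: pd.DataFrame,
    library: Sequence[LipidTarget],
    spec: CohortSpec,
    detectable: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[Spectrum], dict[str, list[str]]]:
    """Simulate subject, blank and QC dilution-series spectra for one cohort.

    Returns the spectra plus the planted fail-lipid sets per QC filter
    (keys ``mass``, ``blank``, ``missing``, ``qc``). Fail lipids are chosen
    among detectable lipids that carry no planted association, so QC
    filtering never destroys a planted panel at defaults.
    """
    if len(library) == 0 or len(clinical) == 0:
        raise ValueError("library and clinical table must be nonempty")
    by_name = {t.name: t for t in library}
    for lip in spec.association_map:
        if lip not in by_name:
            raise ValueError(f"association_map references unknown lipid {lip!r}")
    if detectable is None:
        detectable = [t.name for t in library][: spec.n_lipids_detectable]
    detectable = list(detectable)
    missing_assoc = [l for l in spec.association_map if l not in detectable]
    if missing_assoc:
        raise ValueError(f"association lipids not detectable: {missing_assoc[:3]}")

    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    n_sub = len(clinical)
    p = len(detectable)
    targets = [by_name[l] for l in detectable]
    expected_mz = np.array([t.expected_mz for t in targets])
    baselines = _lipid_baselines(rng, p)

    # planted fail subsets, drawn from non-associated detectable lipids
    free = [l for l in detectable if l not in spec.association_map]
    counts = [spec.n_fail_mass, spec.n_fail_blank, spec.n_fail_missing, spec.n_fail_qc]
    if sum(counts) > len(free):
        # small demo libraries: cap planted failures to the unassociated pool
        counts = [min(c, len(free) // 4) for c in counts]
        warnings.warn(
            "few unassociated lipids; planted QC failures reduced to "
            f"{counts} (mass/blank/missing/qc)",
            stacklevel=2,
        )
    n_fail = sum(counts)
    picked = list(rng.choice(len(free), size=n_fail, replace=False))
    cut = np.cumsum(counts)
    fail = {
        "mass": [free[i] for i in picked[: cut[0]]],
        "blank": [free[i] for i in picked[cut[0] : cut[1]]],
        "missing": [free[i] for i in picked[cut[1] : cut[2]]],
        "qc": [free[i] for i in picked[cut[2] : cut[3]]],
    }
    idx = {l: j for j, l in enumerate(detectable)}
    mass_off = np.zeros(p)
    for l in fail["mass"]:
        mass_off[idx[l]] = spec.fail_mass_offset_ppm * (1 if rng.random() < 0.5 else -1)
    miss_rate = np.full(p, spec.missing_rate)
    for l in fail["missing"]:
        miss_rate[idx[l]] = spec.fail_missing_rate

    # association amplitudes per lipid, attenuated for the validation cohort
    z = (clinical - clinical.mean()) / clinical.std(ddof=0).replace(0.0, 1.0)
    amp = np.zeros(p)
    zcol = np.zeros((n_sub, p))
    for lip, (target, f) in spec.association_map.items():
        f_eff = f * spec.attenuation
        if lip not in idx or f_eff <= 0:
            continue
        j = idx[lip]
        amp[j] = spec.bio_cv * math.sqrt(f_eff / (1.0 - f_eff))
        zcol[:, j] = z[target].to_numpy()

    ln_sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2)) if spec.noise_cv > 0 else 0.0

    def meas_noise(shape) -> np.ndarray:
        if ln_sigma == 0:
            return np.ones(shape)
        return np.exp(rng.normal(-ln_sigma**2 / 2.0, ln_sigma, size=shape))

    spectra: list[Spectrum] = []

    # subject spectra
    bio = rng.normal(0.0, spec.bio_cv, size=(n_sub, p)) if spec.bio_cv > 0 else np.zeros((n_sub, p))
    signal = baselines * np.maximum(0.05, 1.0 + amp * zcol + bio) * meas_noise((n_sub, p))
    zero_mask = rng.random((n_sub, p)) < miss_rate
    signal[zero_mask] = 0.0
    ppm_err = np.broadcast_to(mass_off, (n_sub, p)) + (
        rng.normal(0.0, spec.mass_error_ppm_sd, size=(n_sub, p))
        if spec.mass_error_ppm_sd > 0
        else 0.0
    )
    for i, sid in enumerate(clinical.index):
        keep = signal[i] > 0
        mzs = expected_mz[keep] * (1.0 + ppm_err[i, keep] * 1e-6)
        spectra.append(
            Spectrum(
                sample_id=str(sid),
                role=Role.SAMPLE,
                batch=f"{spec.cohort_id}_b1",
                peaks=_as_peaks(mzs, signal[i, keep]),
            )
        )

    # blanks: contaminant peaks plus low-level leakage of the blank-fail lipids
    contam_mz = np.sort(
        rng.uniform(MZ_RANGE[0], MZ_RANGE[1], size=spec.n_contaminants)
        * (1.0 + rng.normal(0, 1e-6, size=spec.n_contaminants))
    )
    blank_level = np.zeros(p)
    for l in fail["blank"]:
        blank_level[idx[l]] = baselines[idx[l]] / spec.fail_blank_ratio
    for b in range(spec.n_blanks):
        lev = blank_level * meas_noise(p)
        keep = lev > 0
        mzs = expected_mz[keep] * (
            1.0 + rng.normal(0.0, spec.mass_error_ppm_sd, size=int(keep.sum())) * 1e-6
        )
        allmz = np.concatenate([mzs, contam_mz])
        allint = np.concatenate(
            [lev[keep], 10.0 ** rng.uniform(3.0, 5.0, size=spec.n_contaminants)]
        )
        spectra.append(
            Spectrum(
                sample_id=f"{spec.cohort_id}_blank{b}",
                role=Role.BLANK,
                batch=f"{spec.cohort_id}_b1",
                peaks=_as_peaks(allmz, allint),
            )
        )

    # QC dilution series: linear in serum fraction except the planted
    # qc-fail lipids, whose response is inverted
    qc_fail_mask = np.zeros(p, dtype=bool)
    for l in fail["qc"]:
        qc_fail_mask[idx[l]] = True
    for role, frac in ((Role.QC100, 1.0), (Role.QC50, 0.5), (Role.QC25, 0.25)):
        for r in range(spec.n_qc_replicates):
            lev = baselines * frac * meas_noise(p)
            lev[qc_fail_mask] = (
                baselines[qc_fail_mask] * (1.25 - frac) * meas_noise(int(qc_fail_mask.sum()))
            )
            mzs = expected_mz * (
                1.0 + (mass_off + rng.normal(0.0, spec.mass_error_ppm_sd, size=p)) * 1e-6
            )
            spectra.append(
                Spectrum(
                    sample_id=f"{spec.cohort_id}_{role.value}_{r}",
                    role=role,
                    batch=f"{spec.cohort_id}_b1",
                    peaks=_as_peaks(mzs, lev),
                )
            )
    return spectra, fail


def simulate_cohort(
    spec: CohortSpec,
    library: Sequence[LipidTarget] | None = None,
    detectable: Sequence[str] | None = None,
) -> Cohort:
    """Simulate one full cohort (clinical table + spectra) from a spec."""
    rng = np.random.default_rng(spec.seed)
    if library is None:
        library = make_lipid_library(seed=spec.seed)
    if detectable is None:
        detectable = [t.name for t in library][: spec.n_lipids_detectable]
    spec = replace(spec)
    if not spec.association_map:
        spec.association_map = default_association_map(detectable, seed=spec.seed)
    clinical = simulate_clinical(spec, rng)
    spectra, fail = simulate_spectra(clinical, library, spec, detectable, rng)
    return Cohort(
        cohort_id=spec.cohort_id,
        spec=spec,
        clinical=clinical,
        spectra=spectra,
        library=list(library),
        detectable=list(detectable),
        association_map=dict(spec.association_map),
        fail_lipids=fail,
    )


def make_paired_cohorts(
    discovery_spec: CohortSpec = PLASMA_COHORT,
    validation_spec: CohortSpec = DBS_COHORT,
    panel_dropout: Sequence[str] = (),
    library: Sequence[LipidTarget] | None = None,
) -> tuple[Cohort, Cohort]:
    """Simulate linked discovery (plasma-like) and validation (DBS-like) cohorts.

    The validation cohort's detectable set shares ``shared_lipid_fraction`` of
    its lipids with the discovery set, excludes ``panel_dropout`` (lipids not
    measured in dried blood spots, e.g. the two diglycerides of the published
    triglyceride panel), and its planted associations are attenuated by
    ``validation_spec.attenuation`` to emulate the weaker DBS correlations.
    """
    if library is None:
        library = make_lipid_library(seed=discovery_spec.seed)
    names = [t.name for t in library]
    d_spec = replace(discovery_spec)
    v_spec = replace(validation_spec)

    d_detect = names[: d_spec.n_lipids_detectable]
    unknown = [l for l in panel_dropout if l not in d_detect]
    if unknown:
        raise ValueError(f"panel_dropout lipids not in discovery set: {unknown[:3]}")
    if not d_spec.association_map:
        d_spec.association_map = default_association_map(d_detect, seed=d_spec.seed)

    # validation detectable set: shared core from discovery (associated lipids
    # first so panels are transferable) plus cohort-specific extras
    n_shared = int(round(v_spec.shared_lipid_fraction * v_spec.n_lipids_detectable))
    assoc = [l for l in d_spec.association_map if l not in panel_dropout]
    rng = np.random.default_rng(v_spec.seed + 7)
    pool = [l for l in d_detect if l not in assoc and l not in panel_dropout]
    extra_shared = list(
        rng.choice(pool, size=max(0, n_shared - len(assoc)), replace=False)
    )
    shared = (assoc + extra_shared)[:n_shared]
    fresh_pool = [l for l in names if l not in d_detect]
    fresh = list(
        rng.choice(fresh_pool, size=v_spec.n_lipids_detectable - len(shared), replace=False)
    )
    v_detect = [l for l in names if l in set(shared) | set(fresh)]

    v_assoc = {l: tf for l, tf in d_spec.association_map.items() if l in set(v_detect)}
    dropped_panels = {
        t for t, _ in d_spec.association_map.values()
    } - {t for t, _ in v_assoc.values()}
    if dropped_panels:
        warnings.warn(
            f"panel_dropout removed every planted lipid for {sorted(dropped_panels)}; "
            "those panels are unlearnable in the validation cohort",
            stacklevel=2,
        )
    v_spec.association_map = v_assoc

    discovery = simulate_cohort(d_spec, library, d_detect)
    validation = simulate_cohort(v_spec, library, v_detect)
    return discovery, validation
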