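"""Per-lipid univariate associations with clinical lipids.

Each lipid's centred relative abundance is regressed on its own against a
clinical lipid with a Gaussian-family GLM (equivalently OLS with an
intercept) fit on the whole cohort, no split. Type-I error is controlled
with a Bonferroni threshold computed from the number of lipids tested.
Cross-cohort concordance is the Pearson correlation of the per-lipid
correlation coefficients over lipids measured in both cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AssociationResult",
    "glm_per_lipid",
    "bonferroni_threshold",
    "apply_bonferroni",
    "concordance",
]


@dataclass
class AssociationResult:
    """One lipid's GLM association with one clinical lipid."""

    lipid: str
    target: str
    coefficient: float
    correlation: float
    p_value: float
    passes_bonferroni: bool | None = None
    cohort_id: str = "cohort"


def glm_per_lipid(
    X: pd.DataFrame, y, target: str = "y", cohort_id: str = "cohort"
) -> list[AssociationResult]:
    """One single-predictor Gaussian GLM per lipid on the whole cohort.

    Records the slope (mmol/L per centred-abundance unit), the Pearson
    correlation, and the two-sided slope p-value. Constant lipid columns get
    no result (with a warning).
    """
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("X and y lengths differ")
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing cells")
    results: list[AssociationResult] = []
    constant: list[str] = []
    for lipid in X.columns:
        x = X[lipid].to_numpy(dtype=float)
        if np.std(x) == 0:
            constant.append(str(lipid))
            continue
        # Gaussian-family GLM == OLS; OLS gives the exact t-based slope test
        # (matching how R's glm reports Gaussian coefficients)
        model = sm.OLS(y, sm.add_constant(x)).fit()
        r = float(np.corrcoef(x, y)[0, 1]) if np.std(y) > 0 else float("nan")
        results.append(
            AssociationResult(
                lipid=str(lipid),
                target=target,
                coefficient=float(model.params[1]),
                correlation=r,
                p_value=float(model.pvalues[1]),
                cohort_id=cohort_id,
            )
        )
    if constant:
        warnings.warn(
            f"{len(constant)} constant lipid(s) skipped, no association fit "
            f"(first: {constant[0]!r})",
            stacklevel=2,
        )
    return results


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Bonferroni-adjusted significance threshold alpha/n_tests.

    With the study-wide 125-lipid count this gives the canonical 0.0004; by
    default callers pass the cohort's own retained lipid count.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def apply_bonferroni(
    results: list[AssociationResult], n_tests: int | None = None, alpha: float = 0.05
) -> float:
    """Set ``passes_bonferroni`` on each result; returns the threshold used."""
    if n_tests is None:
        n_tests = len(results)
    thr = bonferroni_threshold(n_tests, alpha)
    for res in results:
        res.passes_bonferroni = res.p_value < thr
    return thr


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lipid": [r.lipid for r in results],
            "target": [r.target for r in results],
            "coefficient": [r.coefficient for r in results],
            "correlation": [r.correlation for r in results],
            "p_value": [r.p_value for r in results],
            "passes_bonferroni": [r.passes_bonferroni for r in results],
            "cohort_id": [r.cohort_id for r in results],
        }
    )


def concordance(
    source_results: list[AssociationResult],
    target_results: list[AssociationResult],
) -> tuple[float | None, list[str], list[str]]:
    """Cross-cohort agreement of per-lipid association strengths.

    Returns (Pearson r between the two cohorts' per-lipid correlation
    coefficients over shared lipids, shared lipid list, lipids present in
    only one cohort). r is None with fewer than 3 shared lipids.
    """
    a = {r.lipid: r.correlation for r in source_results}
    b = {r.lipid: r.correlation for r in target_results}
    shared = sorted(set(a) & set(b))
    not_measured = sorted(set(a) ^ set(b))
    if len(shared) < 3:
        return None, shared, not_measured
    va = np.array([a[l] for l in shared])
    vb = np.array([b[l] for l in shared])
    if np.std(va) == 0 or np.std(vb) == 0:
        return None, shared, not_measured
    return float(np.corrcoef(va, vb)[0, 1]), shared, not_measured
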