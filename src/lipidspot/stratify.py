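"""Risk-category and quartile stratification of measured vs predicted lipids.

Subjects are binned either by clinical cut-offs (Desirable / Borderline /
Poor, appropriate for adult cohorts) or by cohort quartiles (appropriate
when nearly everyone is in the healthy range, as in a paediatric cohort).
Measured and predicted concentrations are binned independently and the
per-category overlap — subjects landing in the same category both ways — is
tabulated, along with the total accuracy and a permutation chance baseline
(25% for quartiles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CutoffScheme",
    "DEFAULT_CUTOFFS",
    "OverlapTable",
    "assign_clinical",
    "assign_quartiles",
    "overlap_table",
    "chance_baseline",
]

CATEGORIES = ("Desirable", "Borderline", "Poor")
QUARTILES = ("Q1", "Q2", "Q3", "Q4")


@dataclass(frozen=True)
class CutoffScheme:
    """Two boundaries per lipoprotein splitting (0, inf) into three bands.

    ``low``/``high`` are the printed band edges in mmol/L;
    ``higher_is_worse=False`` flips the direction (HDL: high = Desirable).
    Values equal to a boundary fall in the Borderline band by default (the
    printed Desirable/Poor bounds are strict); ``boundary_in_middle=False``
    assigns boundary values to the outer bands instead.
    """

    low: float
    high: float
    higher_is_worse: bool = True
    boundary_in_middle: bool = True

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("boundaries must be strictly ordered")

    def assign(self, value: float) -> str:
        if value <= 0:
            raise ValueError("concentration must be positive")
        below = value < self.low if self.boundary_in_middle else value <= self.low
        above = value > self.high if self.boundary_in_middle else value >= self.high
        band = 0 if below else (2 if above else 1)
        if not self.higher_is_worse:
            band = 2 - band
        return CATEGORIES[band]


#: Standard clinical cut-offs (mmol/L). HDL is reversed (high is good) and
#: its printed 'Poor' bound contains a typo; <1.1 is used, consistent with
#: the 1.5-1.1 Borderline band.
DEFAULT_CUTOFFS: dict[str, CutoffScheme] = {
    "TriG": CutoffScheme(low=1.7, high=2.2),
    "HDL": CutoffScheme(low=1.1, high=1.5, higher_is_worse=False),
    "LDL": CutoffScheme(low=2.6, high=5.0),
    "TC": CutoffScheme(low=5.2, high=6.2),
}


def assign_clinical(
    values, lipoprotein: str, schemes: dict[str, CutoffScheme] | None = None
) -> np.ndarray:
    """Assign clinical risk categories to one or many concentrations."""
    schemes = schemes or DEFAULT_CUTOFFS
    if lipoprotein not in schemes:
        raise KeyError(f"no cut-off scheme for {lipoprotein!r}")
    scheme = schemes[lipoprotein]
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    return np.array([scheme.assign(v) for v in arr], dtype=object)


def assign_quartiles(values) -> np.ndarray:
    """Quartile labels Q1..Q4 by rank, group sizes differing by at most 1.

    Ties are broken by stable input order after average ranking, which keeps
    the groups balanced; a warning is emitted when more than 10% of values
    tie.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 8:
        raise ValueError("need at least 8 values for quartiles")
    n_dup = n - np.unique(values).size
    if n_dup > 0.10 * n:
        warnings.warn(
            f"{n_dup} tied values; quartile assignment uses stable-order tie-breaks",
            stacklevel=2,
        )
    order = np.argsort(values, kind="stable")
    sizes = [n // 4 + (1 if q < n % 4 else 0) for q in range(4)]
    labels = np.empty(n, dtype=object)
    pos = 0
    for q, size in enumerate(sizes):
        labels[order[pos : pos + size]] = QUARTILES[q]
        pos += size
    return labels


@dataclass
class OverlapTable:
    """Per-category agreement between measured and predicted stratification.

    ``counts[c]`` is the number of subjects whose measured *and* predicted
    category is c; ``denominators[c]`` the number measured as c (measured-side
    conditioning). ``total_accuracy`` is the overall fraction agreeing, as a
    percentage.
    """

    categories: list[str]
    counts: dict[str, int]
    denominators: dict[str, int]
    scheme: str = "quartile"
    notes: dict = field(default_factory=dict)

    @property
    def percentages(self) -> dict[str, float]:
        return {
            c: (100.0 * self.counts[c] / self.denominators[c])
            if self.denominators[c]
            else float("nan")
            for c in self.categories
        }

    @property
    def total_accuracy(self) -> float:
        denom = sum(self.denominators.values())
        return 100.0 * sum(self.counts.values()) / denom if denom else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": self.categories,
                "overlap": [self.counts[c] for c in self.categories],
                "n_measured": [self.denominators[c] for c in self.categories],
                "pct_overlap": [self.percentages[c] for c in self.categories],
            }
        )


def overlap_table(
    measured_labels, predicted_labels, categories: list[str] | None = None, scheme: str = "quartile"
) -> OverlapTable:
    """Cross-tabulate measured vs predicted category agreement."""
    m = np.asarray(measured_labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    if m.size != p.size:
        raise ValueError("label vectors differ in length")
    if categories is None:
        categories = sorted(set(m) | set(p))
    cat_set = set(categories)
    if not (set(m) <= cat_set and set(p) <= cat_set):
        raise ValueError("labels outside the declared category set")
    counts = {c: int(np.sum((m == c) & (p == c))) for c in categories}
    denoms = {c: int(np.sum(m == c)) for c in categories}
    return OverlapTable(list(categories), counts, denoms, scheme=scheme)


def chance_baseline(
    n: int,
    n_categories: int = 4,
    n_reps: int = 1000,
    seed: int = 0,
    measured_labels=None,
) -> tuple[float, tuple[float, float]]:
    """Expected per-category overlap percentage under random assignment.

    Predicted labels are permuted uniformly at random against fixed measured
    labels; the mean per-category overlap percentage is returned with a 95%
    Monte-Carlo interval. For balanced categories this converges to
    100/n_categories % (25% for quartiles).
    """
    if n_reps < 100:
        raise ValueError("need at least 100 permutation replicates")
    rng = np.random.default_rng(seed)
    if measured_labels is None:
        base = np.array(
            [f"C{1 + (i * n_categories) // n}" for i in range(n)], dtype=object
        )
    else:
        base = np.asarray(measured_labels, dtype=object)
        n = base.size
        n_categories = len(set(base))
    cats = sorted(set(base))
    means = np.empty(n_reps)
    for rep in range(n_reps):
        perm = base[rng.permutation(n)]
        pcts = [
            100.0 * np.sum((base == c) & (perm == c)) / max(np.sum(base == c), 1)
            for c in cats
        ]
        means[rep] = float(np.mean(pcts))
    mean = float(means.mean())
    half = 1.96 * float(means.std(ddof=1)) / np.sqrt(n_reps)
    return mean, (mean - half, mean + half)
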