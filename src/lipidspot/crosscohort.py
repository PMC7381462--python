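"""Cross-cohort translation and validation of discovered lipid panels.

A panel found in the plasma discovery cohort is carried into the dried-blood-
spot validation cohort by lipid identity only: lipids not measured in the
target cohort are dropped, the remaining panel is retrained from scratch on
the target cohort's 70:30 training split, and performance is assessed on its
test split. Trees and coefficients are never transported — only names —
except in the explicitly non-default ``transport`` mode, which applies the
source-trained forest directly for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import PanelModel, RFConfig, SplitSpec, evaluate, split_cohort

__all__ = ["TranslationRecord", "translate_panel", "validate_in_cohort", "PanelValidator"]


@dataclass
class TranslationRecord:
    """A panel's journey from source to target cohort."""

    source_panel: list[str]
    lipids_missing_in_target: list[str]
    lipids_used: list[str]
    target_model: PanelModel | None = None
    mode: str = "retrain"
    extras: dict = field(default_factory=dict)


def translate_panel(panel: PanelModel, target_lipids: Sequence[str]) -> TranslationRecord:
    """Intersect a source panel with the target cohort's measured lipid set."""
    target = set(target_lipids)
    used = [l for l in panel.panel if l in target]
    missing = [l for l in panel.panel if l not in target]
    if not used:
        raise ValueError(
            "no panel lipid is measured in the target cohort; validation impossible"
        )
    return TranslationRecord(
        source_panel=list(panel.panel),
        lipids_missing_in_target=missing,
        lipids_used=used,
    )


def validate_in_cohort(
    rec: TranslationRecord,
    X_target: pd.DataFrame,
    y_target,
    split: SplitSpec | None = None,
    rf_config: RFConfig | None = None,
    target_name: str = "y",
) -> TranslationRecord:
    """Retrain the translated panel in the target cohort and score its test split."""
    split = split or SplitSpec()
    rf_config = rf_config or RFConfig()
    missing_cols = [l for l in rec.lipids_used if l not in X_target.columns]
    if missing_cols:
        raise ValueError(f"lipids_used not in target matrix: {missing_cols[:3]}")
    y = np.asarray(y_target, dtype=float)
    train, test = split_cohort(X_target.shape[0], split, y)
    cols = rec.lipids_used
    forest = rf_config.make_forest().fit(X_target.iloc[train][cols], y[train])
    train_msr = float(np.mean((forest.predict(X_target.iloc[train][cols]) - y[train]) ** 2))
    r, p, _ = evaluate(forest.predict(X_target.iloc[test][cols]), y[test])
    rec.target_model = PanelModel(
        target=target_name,
        panel=list(cols),
        training_msr=train_msr,
        test_r=r,
        test_p=p,
        all_lipid_test_r=None,
        rf_config=rf_config,
        split=split,
    )
    rec.extras["forest"] = forest
    rec.extras["train_idx"], rec.extras["test_idx"] = train, test
    return rec


class PanelValidator:
    """Convenience wrapper running translate → retrain → evaluate in one call.

    ``mode="transport"`` skips retraining and applies the source cohort's
    fitted forest to the target test split (not the reported procedure;
    provided for comparison only).
    """

    def __init__(
        self,
        split: SplitSpec | None = None,
        rf_config: RFConfig | None = None,
        mode: str = "retrain",
    ):
        if mode not in ("retrain", "transport"):
            raise ValueError("mode must be 'retrain' or 'transport'")
        self.split = split or SplitSpec()
        self.rf_config = rf_config or RFConfig()
        self.mode = mode

    def run(
        self,
        panel: PanelModel,
        X_target: pd.DataFrame,
        y_target,
        source_forest=None,
        target_name: str = "y",
    ) -> TranslationRecord:
        rec = translate_panel(panel, X_target.columns)
        rec.mode = self.mode
        if self.mode == "retrain":
            return validate_in_cohort(
                rec, X_target, y_target, self.split, self.rf_config, target_name
            )
        if source_forest is None:
            raise ValueError("transport mode needs the source-trained forest")
        if rec.lipids_missing_in_target:
            raise ValueError(
                "transport mode cannot drop lipids; the source forest needs its full panel"
            )
        y = np.asarray(y_target, dtype=float)
        _, test = split_cohort(X_target.shape[0], self.split, y)
        pred = source_forest.predict(X_target.iloc[test][rec.lipids_used])
        r, p, msr = evaluate(pred, y[test])
        rec.target_model = PanelModel(
            target=target_name,
            panel=list(rec.lipids_used),
            training_msr=float("nan"),
            test_r=r,
            test_p=p,
            all_lipid_test_r=None,
            rf_config=self.rf_config,
            split=self.split,
        )
        return rec
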