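"""Shared selection containers and the estimator base class."""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

METHOD_IDS = (
    "UNIV-BFN",
    "LASSO-MIN", "LASSO-1SE", "ELNET-MIN", "ELNET-1SE",
    "HCLST-CORR-SGL", "HCLST-BOOT-SGL",
    "RF", "BAGGING",
    "BART-LOCAL", "BART-GLOBALSE", "BART-GLOBALMAX",
)

__all__ = ["METHOD_IDS", "SelectionResult", "BaseSelector"]


@dataclass
class SelectionResult:
    """A method's selected variables in discovery, and the validated subset."""

    method_id: str
    selected_discovery: np.ndarray
    validated: np.ndarray | None = None
    tuning: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method_id not in METHOD_IDS:
            raise ValueError(f"unknown method id {self.method_id!r}")
        self.selected_discovery = np.asarray(sorted(set(map(int, self.selected_discovery))))
        if self.validated is not None:
            self.validated = np.asarray(sorted(set(map(int, self.validated))))
            if not set(self.validated) <= set(self.selected_discovery):
                raise ValueError("validated set must be a subset of the discovery selection")

    def to_csv(self, path, names: list[str] | None = None, meta_path=None) -> None:
        idx = self.selected_discovery
        val = set() if self.validated is None else set(self.validated)
        rows = {
            "method": [self.method_id] * len(idx),
            "variable": [names[i] if names else f"V{i + 1:04d}" for i in idx],
            "selected_discovery": [1] * len(idx),
            "validated": [int(i in val) for i in idx],
        }
        pd.DataFrame(rows).to_csv(path, index=False)
        if meta_path is not None:
            Path(meta_path).write_text(json.dumps(self.tuning, indent=1, default=str))


class BaseSelector(SelectorMixin, BaseEstimator):
    """fit(X, y) sets ``support_`` (bool mask) and ``selected_`` (indices)."""

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def _finalize(self, X, mask: np.ndarray):
        self.n_features_in_ = X.shape[1]
        self.support_ = np.asarray(mask, dtype=bool)
        self.selected_ = np.flatnonzero(self.support_)
        return self
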