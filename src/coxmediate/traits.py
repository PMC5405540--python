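"""Glycemic mediator derivation and transforms.

The three mediators are fasting glucose (mg/dl), fasting insulin (uIU/ml)
and HOMA-IR, the homeostatic model assessment of insulin resistance,
computed as glucose x insulin / 405.  Mediators enter the models on their
raw scale by default; a natural-log transform is available for sensitivity
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MediatorSpec", "MEDIATORS", "homa_ir", "apply_transform", "ensure_homa_ir"]

MEDIATORS = ("glucose", "insulin", "homa_ir")

HOMA_DENOMINATOR = 405.0


@dataclass(frozen=True)
class MediatorSpec:
    """A mediator column and the transform applied before modelling."""

    name: str
    transform: str = "identity"

    def __post_init__(self):
        if self.name not in MEDIATORS:
            raise ValueError(f"mediator must be one of {MEDIATORS}, got {self.name!r}")
        if self.transform not in ("identity", "natural-log"):
            raise ValueError(f"unknown transform {self.transform!r}")


def homa_ir(glucose, insulin):
    """HOMA-IR = glucose (mg/dl) x insulin (uIU/ml) / 405, elementwise.

    Raises on non-positive glucose (a physiologic impossibility that
    usually signals unit confusion, e.g. mmol/l input).
    """
    g = np.asarray(glucose, dtype=float)
    i = np.asarray(insulin, dtype=float)
    if np.any(g <= 0):
        raise ValueError("glucose must be strictly positive (mg/dl)")
    if np.any(i < 0):
        raise ValueError("insulin must be non-negative (uIU/ml)")
    out = g * i / HOMA_DENOMINATOR
    if out.ndim == 0:
        return float(out)
    return out


def apply_transform(values, spec: MediatorSpec):
    """Apply the spec's transform (identity or natural log) elementwise."""
    v = np.asarray(values, dtype=float)
    if spec.transform == "identity":
        return v.copy()
    bad = np.nonzero(v <= 0)[0]
    if bad.size:
        head = ", ".join(map(str, bad[:10]))
        raise ValueError(
            f"natural-log transform of {spec.name} undefined for "
            f"{bad.size} non-positive value(s) at index {head}"
        )
    return np.log(v)


def ensure_homa_ir(table: pd.DataFrame) -> pd.DataFrame:
    """Add a homa_ir column derived from glucose and insulin if absent."""
    if "homa_ir" not in table.columns:
        table = table.copy()
        table["homa_ir"] = homa_ir(table["glucose"], table["insulin"])
    return table
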