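"""Entropy and information-gain feature ranking.

Quantifies how much each ordinal clinical feature (pain, swelling,
stability, functional limitation) reduces uncertainty about the
disability grade D:

    H(D)       = -sum_k p_k log2 p_k
    H(D | A)   = sum_i P(A = a_i) H(D | A = a_i)
    IG(D, A)   = H(D) - H(D | A)

All quantities are in bits; 0 * log 0 is taken as 0 and empty strata
contribute nothing.  Features must already be categorical: raw continuous
measurements (e.g. swelling diameter in cm) are refused and must first go
through :func:`discretize` with explicit cut-points, mirroring the
three-level ordinal coding the clinical protocol uses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "EntropyReport",
    "empirical_entropy",
    "conditional_entropy",
    "information_gain",
    "rank_features",
    "discretize",
    "entropy_reference",
]


def _categorical(values, what: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValidationError(f"{what}: empty sequence")
    if arr.dtype.kind == "f":
        raise ValidationError(
            f"{what}: continuous values; discretize with explicit cut-points first"
        )
    return arr


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def empirical_entropy(labels: Sequence) -> float:
    """Shannon entropy (bits) of a categorical label sequence."""
    arr = _categorical(labels, "labels")
    _, counts = np.unique(arr, return_counts=True)
    return _entropy_from_counts(counts)


def conditional_entropy(labels: Sequence, feature: Sequence) -> float:
    """H(labels | feature): stratum-weighted entropy in bits."""
    y = _categorical(labels, "labels")
    x = _categorical(feature, "feature")
    if len(x) != len(y):
        raise ValidationError(
            f"length mismatch: {len(y)} labels vs {len(x)} feature values"
        )
    total = len(y)
    out = 0.0
    for value in np.unique(x):
        mask = x == value
        _, counts = np.unique(y[mask], return_counts=True)
        out += (mask.sum() / total) * _entropy_from_counts(counts)
    return out


def information_gain(labels: Sequence, feature: Sequence) -> float:
    """IG(labels, feature) = H(labels) - H(labels | feature), in bits."""
    return empirical_entropy(labels) - conditional_entropy(labels, feature)


@dataclass
class EntropyReport:
    """Per-feature conditional entropy and information gain, ranked.

    ``ranking`` sorts features by descending gain; exact ties break toward
    the feature listed first, so reports are deterministic.
    """

    h_d: float
    per_feature: list[tuple[str, float, float]]
    ranking: list[str]

    def to_dict(self) -> dict:
        return {
            "h_d_bits": self.h_d,
            "features": [
                {"id": fid, "conditional_entropy_bits": ce, "information_gain_bits": ig}
                for fid, ce, ig in self.per_feature
            ],
            "ranking": self.ranking,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_markdown(self) -> str:
        lines = [
            f"Dataset entropy H(D) = {self.h_d:.3f} bits",
            "",
            "| Feature | Conditional entropy (bits) | Information gain (bits) |",
            "| --- | --- | --- |",
        ]
        by_rank = {fid: (ce, ig) for fid, ce, ig in self.per_feature}
        for fid in self.ranking:
            ce, ig = by_rank[fid]
            lines.append(f"| {fid} | {ce:.3f} | {ig:.3f} |")
        return "\n".join(lines) + "\n"


def rank_features(cohort: pd.DataFrame, feature_ids: Sequence[str],
                  label: str = "D") -> EntropyReport:
    """Rank features of a cohort table by information gain about ``label``."""
    if label not in cohort.columns:
        raise LookupError(f"label column {label!r} not in cohort")
    missing = [f for f in feature_ids if f not in cohort.columns]
    if missing:
        raise LookupError(f"unknown feature id(s) {missing}")
    h_d = empirical_entropy(cohort[label])
    rows = []
    for fid in feature_ids:
        ce = conditional_entropy(cohort[label], cohort[fid])
        rows.append((fid, ce, h_d - ce))
    order = sorted(range(len(rows)), key=lambda k: (-rows[k][2], k))
    return EntropyReport(h_d, rows, [rows[k][0] for k in order])


def discretize(values: Sequence[float], cut_points: Sequence[float],
               labels: Sequence[str] | None = None) -> np.ndarray:
    """Bin continuous measurements at explicit cut-points.

    ``cut_points`` are the interior boundaries; ``labels`` (default
    ``bin0..binN``) name the resulting ``len(cut_points) + 1`` ordinal
    levels.
    """
    cuts = np.asarray(cut_points, dtype=float)
    if cuts.size == 0 or np.any(np.diff(cuts) <= 0):
        raise ValidationError("cut_points must be non-empty and strictly increasing")
    if labels is None:
        labels = [f"bin{k}" for k in range(cuts.size + 1)]
    if len(labels) != cuts.size + 1:
        raise ValidationError("need exactly one label per bin")
    idx = np.searchsorted(cuts, np.asarray(values, dtype=float), side="right")
    return np.asarray(labels, dtype=object)[idx]


def entropy_reference() -> dict:
    """Packaged published feature-ranking table (see the file's notes on
    its internal consistency)."""
    text = resources.files("bigrehab.data").joinpath("entropy_reference.json").read_text()
    return json.loads(text)
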