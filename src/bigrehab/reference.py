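"""Loaders for the packaged published probability tables.

The baseline table lists one state-probability per node rather than full
distributions; :func:`load_partial_priors` spreads the remaining mass
equally over the unlisted states and flags those entries as imputed.  Two
printed rows reference a state that does not exist on their binary node
and are skipped (their notes are preserved in the data file).

The post-intervention table is loaded by :func:`load_posterior_reference`;
its talocrural pair sums to 0.996 as printed, and renormalisation is a
switch, off by default.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .errors import ValidationError

__all__ = ["load_partial_priors", "load_posterior_reference"]

_CARD = {"P1": 3, "B1": 3, "B2": 3, "B3": 3, "B4": 3,
         "R1": 2, "R2": 2, "G1": 2, "G2": 2, "G3": 2, "G4": 2}


def _read(name: str) -> dict:
    return json.loads(resources.files("bigrehab.data").joinpath(name).read_text())


def load_partial_priors() -> dict[str, dict]:
    """Expand the packaged baseline proportions into full distributions.

    Returns ``{node: {"probs": array, "imputed": bool-array, "skipped":
    bool}}``; skipped nodes are those whose printed state is inconsistent
    with the node's coding.
    """
    out: dict[str, dict] = {}
    for entry in _read("prior_reference.json")["entries"]:
        node, state, p = entry["node"], entry["state"], entry["probability"]
        card = _CARD[node]
        if state >= card:
            out[node] = {"probs": None, "imputed": None, "skipped": True,
                         "note": entry.get("note", "")}
            continue
        probs = np.full(card, (1.0 - p) / (card - 1))
        probs[state] = p
        imputed = np.ones(card, dtype=bool)
        imputed[state] = False
        out[node] = {"probs": probs, "imputed": imputed, "skipped": False}
    return out


def load_posterior_reference(normalize: bool = False) -> dict[str, np.ndarray]:
    """Published post-intervention marginals per node.

    With ``normalize=True`` each vector is rescaled to sum to one (the
    printed talocrural pair sums to 0.996); the default keeps the printed
    values.
    """
    out = {}
    for node, vec in _read("posterior_reference.json")["marginals"].items():
        arr = np.asarray(vec, dtype=float)
        total = arr.sum()
        if total <= 0:
            raise ValidationError(f"non-positive reference mass for {node}")
        out[node] = arr / total if normalize else arr
    return out
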