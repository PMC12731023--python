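"""Seeded synthetic patient cohorts for the ankle-rehabilitation analysis.

The study's clinical data exists only as printed summary tables, so every
downstream stage is exercised on synthetic cohorts that carry the same
statistical structure: disability grades drawn with the published baseline
proportions, node states sampled ancestrally through the generative network
(grade -> joint repair -> functional states and goals), ordinal clinical
features tied to the grade, and a configurable "weak feature correlation"
discordance mechanism that plants records such as extensive swelling at a
low disability level.

Generation is vectorised over patients from a single counter-based Philox
stream derived from the master seed, so a fixed seed yields a bit-identical
cohort at any size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .network import BayesNet, build_network, default_network_config, exact_inference

__all__ = [
    "PatientRecord",
    "CohortSpec",
    "ImprovementModel",
    "cohort_defaults",
    "generate_cohort",
    "generate_sessions",
    "write_cohort",
    "read_cohort",
    "generative_marginals",
]

NODE_COLUMNS = ["P1", "B1", "B2", "B3", "B4", "R1", "R2", "G1", "G2", "G3", "G4"]
GRADES = ("I", "II", "III")
LEVELS = ("low", "mid", "high")


def cohort_defaults() -> dict:
    text = resources.files("bigrehab.data").joinpath("cohort_defaults.json").read_text()
    return json.loads(text)


@dataclass(frozen=True)
class PatientRecord:
    """One patient-session of categorical clinical and network-node states."""

    patient_id: str
    session: int
    D: str
    A1: str
    A2: str
    A3: str
    A4: str
    P1: int
    B1: int
    B2: int
    B3: int
    B4: int
    R1: int
    R2: int
    G1: int
    G2: int
    G3: int
    G4: int
    traj_error: float
    emg_features: tuple[float, ...]

    def __post_init__(self):
        if self.session < 0:
            raise ValidationError("session must be non-negative")
        if self.D not in GRADES:
            raise ValidationError(f"D={self.D!r} not in {GRADES}")
        for f in ("A1", "A2", "A3", "A4"):
            if getattr(self, f) not in LEVELS:
                raise ValidationError(f"{f}={getattr(self, f)!r} not in {LEVELS}")
        if self.P1 not in (0, 1, 2):
            raise ValidationError("P1 must be 0, 1 or 2")
        for f in ("B1", "B2", "B3", "B4"):
            if getattr(self, f) not in (0, 1, 2):
                raise ValidationError(f"{f} must be 0, 1 or 2")
        for f in ("R1", "R2", "G1", "G2", "G3", "G4"):
            if getattr(self, f) not in (0, 1):
                raise ValidationError(f"{f} must be 0 or 1")
        if self.traj_error < 0:
            raise ValidationError("traj_error must be >= 0")


@dataclass
class CohortSpec:
    """Generation settings; defaults are the study's stated conditions."""

    n_patients: int = 100
    grade_probs: tuple[float, float, float] | None = None
    cpt_set: Mapping | BayesNet | None = None
    discordance_rate: float | None = None
    n_sessions: int = 1
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients <= 0:
            raise ValidationError("n_patients: must be a positive integer")
        gp = self.resolved_grade_probs()
        if len(gp) != 3 or any(p < 0 for p in gp):
            raise ValidationError("grade_probs: must be 3 non-negative values")
        if abs(sum(gp) - 1.0) > 1e-9:
            raise ValidationError("grade_probs: must sum to 1 within 1e-9")
        dr = self.resolved_discordance_rate()
        if not 0.0 <= dr <= 1.0:
            raise ValidationError("discordance_rate: must lie in [0, 1]")
        if not isinstance(self.n_sessions, (int, np.integer)) or self.n_sessions <= 0:
            raise ValidationError("n_sessions: must be a positive integer")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed: must be an integer")

    def resolved_grade_probs(self) -> tuple[float, ...]:
        if self.grade_probs is None:
            return tuple(cohort_defaults()["grade_probs"])
        return tuple(self.grade_probs)

    def resolved_discordance_rate(self) -> float:
        if self.discordance_rate is None:
            return float(cohort_defaults()["discordance_rate"])
        return float(self.discordance_rate)

    def network(self) -> BayesNet:
        """The generative network with the grade prior overridden."""
        if isinstance(self.cpt_set, BayesNet):
            net = self.cpt_set.copy()
        elif self.cpt_set is not None:
            net = build_network(self.cpt_set)
        else:
            net = build_network(default_network_config())
        cpt = net.cpts["P1"]
        cpt.table = np.asarray(self.resolved_grade_probs(), dtype=float)
        net.set_cpt(cpt)
        return net


@dataclass(frozen=True)
class ImprovementModel:
    """Per-session probability of moving one state toward recovery.

    The session unit follows the training schedule: the default 0.133 per
    block lifts a 20% goal-achievement fraction to roughly 66% over six
    weekly blocks (1 - 0.8 * (1 - p)^6).
    """

    p_repair: float = 0.133
    p_function: float = 0.133
    p_goal: float = 0.133

    def __post_init__(self):
        for name, p in (("p_repair", self.p_repair),
                        ("p_function", self.p_function),
                        ("p_goal", self.p_goal)):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}: improvement probability must be in [0, 1]")


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=np.uint64(seed)))


def _sample_categorical(rng, rows: np.ndarray) -> np.ndarray:
    """Vectorised draw: one categorical sample per row of probabilities."""
    cum = np.cumsum(rows, axis=1)
    u = rng.random(rows.shape[0])
    return (u[:, None] < cum).argmax(axis=1)


def _ancestral_sample(net: BayesNet, n: int, rng) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for nid in net.topological_order():
        cpt = net.cpts[nid]
        if cpt.parents:
            idx = tuple(out[p] for p in cpt.parents)
            rows = cpt.table[idx]
        else:
            rows = np.broadcast_to(cpt.table, (n, cpt.table.shape[-1]))
        out[nid] = _sample_categorical(rng, rows)
    return out


def _severity(df_or_states: Mapping[str, np.ndarray]) -> np.ndarray:
    return np.maximum.reduce([np.asarray(df_or_states[b]) for b in
                              ("B1", "B2", "B3", "B4")])


def _draw_signals(rng, severity: np.ndarray, noise: Mapping) -> dict[str, np.ndarray]:
    n = len(severity)
    k = int(noise["n_emg_channels"])
    cols = {}
    for j in range(k):
        mean = (noise["emg_base_mean"] + noise["emg_severity_shift"] * severity
                + noise["emg_channel_offset"] * j)
        cols[f"emg_{j + 1}"] = rng.normal(mean, noise["emg_sd"])
    mean = noise["traj_base_mean_mm"] + noise["traj_severity_shift_mm"] * severity
    cols["traj_error"] = np.abs(rng.normal(mean, noise["traj_sd_mm"]))
    return cols


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate the baseline (session 0) cohort for a validated spec.

    Node states are sampled ancestrally through the generative network;
    the functional-limitation level A4 is the deterministic map of the
    worst functional state; A1-A3 come from grade-conditioned tables; with
    probability ``discordance_rate`` a record's swelling level is forced
    high or its pain level forced low, planting the grade-discordant cases
    the feature-selection stage must tolerate.  Discordance touches only
    the A fields, never node states.
    """
    spec.validate()
    defaults = cohort_defaults()
    rng = _rng(spec.seed)
    n = int(spec.n_patients)
    net = spec.network()

    states = _ancestral_sample(net, n, rng)
    severity = _severity(states)

    data: dict[str, object] = {
        "patient_id": [f"p{idx:05d}" for idx in range(n)],
        "session": np.zeros(n, dtype=np.int64),
        "D": np.asarray(GRADES, dtype=object)[states["P1"]],
    }
    levels = np.asarray(LEVELS, dtype=object)
    for fid in ("A1", "A2", "A3"):
        table = np.asarray(defaults["feature_tables"][fid], dtype=float)
        data[fid] = levels[_sample_categorical(rng, table[states["P1"]])]
    data["A4"] = levels[severity]

    dr = spec.resolved_discordance_rate()
    fire = rng.random(n) < dr
    swap_swelling = rng.random(n) < 0.5
    a1, a2 = np.asarray(data["A1"]), np.asarray(data["A2"])
    a2[fire & swap_swelling] = "high"     # extensive swelling, whatever the grade
    a1[fire & ~swap_swelling] = "low"     # mild pain, whatever the grade
    data["A1"], data["A2"] = a1, a2

    for nid in NODE_COLUMNS:
        data[nid] = states[nid].astype(np.int64)
    data.update(_draw_signals(rng, severity, defaults["noise"]))
    return pd.DataFrame(data)


def generate_sessions(cohort: pd.DataFrame, n_sessions: int,
                      improvement_model: ImprovementModel | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Longitudinal stream: the baseline plus ``n_sessions`` transitions.

    Each transition moves every repair, functional and goal state one step
    toward recovery with its class's probability (independently per node
    and patient); signal noise is redrawn conditioned on the new
    functional severity, and A4 is re-derived from it.  The output stacks
    sessions 0..n_sessions, sorted by patient then session.
    """
    if n_sessions < 1:
        raise ValidationError("n_sessions must be >= 1")
    model = improvement_model or ImprovementModel()
    defaults = cohort_defaults()
    rng = _rng(seed ^ 0x5E55)
    frames = [cohort]
    current = cohort.copy()
    for s in range(1, n_sessions + 1):
        nxt = current.copy()
        nxt["session"] = s
        n = len(nxt)
        for col in ("R1", "R2"):
            move = (nxt[col].to_numpy() > 0) & (rng.random(n) < model.p_repair)
            nxt.loc[move, col] = nxt.loc[move, col] - 1
        for col in ("B1", "B2", "B3", "B4"):
            move = (nxt[col].to_numpy() > 0) & (rng.random(n) < model.p_function)
            nxt.loc[move, col] = nxt.loc[move, col] - 1
        for col in ("G1", "G2", "G3", "G4"):
            move = (nxt[col].to_numpy() > 0) & (rng.random(n) < model.p_goal)
            nxt.loc[move, col] = nxt.loc[move, col] - 1
        severity = _severity({b: nxt[b].to_numpy() for b in ("B1", "B2", "B3", "B4")})
        nxt["A4"] = np.asarray(LEVELS, dtype=object)[severity]
        for col, vals in _draw_signals(rng, severity, defaults["noise"]).items():
            nxt[col] = vals
        frames.append(nxt)
        current = nxt
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["patient_id", "session"], kind="stable").reset_index(drop=True)


def generative_marginals(spec: CohortSpec) -> dict[str, np.ndarray]:
    """Exact node marginals of the generative model (ancestral summation)."""
    return exact_inference(spec.network(), {}).marginals


# -- I/O -------------------------------------------------------------------

_STR_COLS = ["patient_id", "D", "A1", "A2", "A3", "A4"]


def write_cohort(cohort: pd.DataFrame, path, format: str = "csv") -> None:
    if format == "csv":
        cohort.to_csv(path, index=False)
    elif format == "json":
        payload = {
            "columns": list(cohort.columns),
            "records": cohort.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
    else:
        raise ValidationError(f"unknown cohort format {format!r}")


def read_cohort(path, format: str = "csv") -> pd.DataFrame:
    try:
        if format == "csv":
            df = pd.read_csv(path)
        elif format == "json":
            with open(path) as fh:
                payload = json.load(fh)
            df = pd.DataFrame(payload["records"], columns=payload["columns"])
        else:
            raise ValidationError(f"unknown cohort format {format!r}")
    except ValidationError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with a locator
        raise ParseError(f"could not parse cohort file {path}: {exc}") from exc
    return _coerce(df, path)


def _coerce(df: pd.DataFrame, path) -> pd.DataFrame:
    for col in df.columns:
        if col in _STR_COLS:
            df[col] = df[col].astype(object)
        elif col in NODE_COLUMNS or col == "session":
            try:
                df[col] = df[col].astype(np.int64)
            except (TypeError, ValueError) as exc:
                bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
                loc = bad.index[0] if len(bad) else "?"
                raise ParseError(
                    f"{path}: column {col}, record {loc}: non-integer state"
                ) from exc
        else:
            df[col] = df[col].astype(float)
    return df
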