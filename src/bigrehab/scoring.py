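"""Factor scoring, intervention prioritisation, and the value-of-information
session loop.

The factor-score table assigns each node state an intervention weight
(1-5); goal nodes carry a score only for their achieved state, because the
priority of reaching an unachieved goal is implicitly represented by the
weight of the achieved state.  Priorities combine that weight with the
posterior probability that the goal is still unachieved:

    priority(G) = score(G = achieved) * P(G = not achieved)

i.e. the expected scoreable gain from flipping the goal.

Action selection is driven by expected information gain: observing a
candidate node is worth the expected reduction in posterior entropy of the
query nodes (injury grade and the four goals by default), which equals the
conditional mutual information between candidate and query given the
current evidence.  The session loop recalibrates CPTs from cumulative
session counts, updates posteriors in the hierarchical order observation ->
intermediate -> target -> grade, and picks the next observation target.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Hashable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateEvidenceError, ValidationError
from .network import (
    BayesNet,
    PosteriorState,
    exact_inference,
    learn_parameters,
    posterior_intermediate,
    posterior_target,
    update_observation_nodes,
)

__all__ = [
    "FactorScoreTable",
    "StrategyTrace",
    "load_score_table",
    "intervention_priority",
    "expected_information_gain",
    "select_next_action",
    "run_session_loop",
]

DEFAULT_QUERY_SET = ("P1", "G1", "G2", "G3", "G4")
DEFAULT_CANDIDATES = ("B1", "B2", "B3", "B4")


@dataclass
class FactorScoreTable:
    """Map (node id, state) -> integer score 1-5; goal nodes score only
    their achieved state (0)."""

    scores: dict[tuple[str, int], int]
    labels: dict[tuple[str, int], str] = field(default_factory=dict)
    goal_nodes: tuple[str, ...] = ("G1", "G2", "G3", "G4")

    def validate(self) -> None:
        for (node, state), score in self.scores.items():
            if not isinstance(score, (int, np.integer)) or not 1 <= score <= 5:
                raise ValidationError(
                    f"score for ({node}, {state}) is {score!r}; must be an "
                    "integer in 1..5"
                )
            if node in self.goal_nodes and state != 0:
                raise ValidationError(
                    f"goal node {node} may only score its achieved state (0), "
                    f"got a score for state {state}"
                )

    def score(self, node: str, state: int) -> int | None:
        return self.scores.get((node, state))

    def to_csv(self, path) -> None:
        rows = [
            {"node": node, "state": state,
             "label": self.labels.get((node, state), ""), "score": score}
            for (node, state), score in self.scores.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def load_score_table(config: Mapping | None = None) -> FactorScoreTable:
    """Build and validate a score table; the packaged default reproduces
    the published scoring criteria exactly."""
    if config is None:
        text = resources.files("bigrehab.data").joinpath("score_table.json").read_text()
        config = json.loads(text)
    try:
        rows = config["scores"]
    except (KeyError, TypeError) as exc:
        raise ValidationError("score-table config must carry a 'scores' list") from exc
    scores: dict[tuple[str, int], int] = {}
    labels: dict[tuple[str, int], str] = {}
    for row in rows:
        try:
            key = (row["node"], int(row["state"]))
            scores[key] = row["score"]
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"malformed score row {row!r}") from exc
        if "label" in row:
            labels[key] = row["label"]
    table = FactorScoreTable(scores, labels,
                             tuple(config.get("goal_nodes", ("G1", "G2", "G3", "G4"))))
    table.validate()
    return table


def intervention_priority(posterior: PosteriorState | Mapping[str, np.ndarray],
                          table: FactorScoreTable) -> list[tuple[str, float]]:
    """Rank goal nodes by expected scoreable gain, descending.

    priority = score(achieved) * P(not achieved); exact ties break toward
    the lower node index.
    """
    marginals = posterior.marginals if isinstance(posterior, PosteriorState) else posterior
    out = []
    for node in table.goal_nodes:
        if node not in marginals:
            raise LookupError(f"posterior is missing goal marginal {node}")
        score = table.score(node, 0)
        if score is None:
            raise LookupError(f"score table has no achieved-state score for {node}")
        out.append((node, float(score * marginals[node][1])))
    out.sort(key=lambda item: (-item[1], item[0]))
    return out


def _marginal_entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def expected_information_gain(net: BayesNet, evidence: Mapping[str, Hashable],
                              candidate: str, query: str) -> float:
    """Expected reduction (bits) in posterior entropy of ``query`` from
    observing ``candidate``, given the current evidence.

    Equals the conditional mutual information I(candidate; query | evidence)
    computed through exact inference.
    """
    evidence = dict(evidence or {})
    if candidate in evidence:
        raise ValidationError(f"candidate {candidate} is already evidenced")
    if candidate == query:
        raise ValidationError("candidate and query must differ")
    base = exact_inference(net, evidence)
    h_query = _marginal_entropy(base.marginals[query])
    p_candidate = base.marginals[candidate]
    expected = 0.0
    for state_idx, p_b in enumerate(p_candidate):
        if p_b <= 0:
            continue
        state = net.nodes[candidate].states[state_idx]
        post = exact_inference(net, {**evidence, candidate: state})
        expected += p_b * _marginal_entropy(post.marginals[query])
    return h_query - expected


def select_next_action(net: BayesNet, evidence: Mapping[str, Hashable],
                       candidates: Sequence[str] = DEFAULT_CANDIDATES,
                       query_set: Sequence[str] = DEFAULT_QUERY_SET,
                       ) -> tuple[str, dict[str, float]]:
    """Pick the candidate observation with the largest summed expected
    information gain over the query set; ties break toward the lowest
    index.  Returns (chosen candidate, per-candidate EIG sums)."""
    if not candidates:
        raise ValidationError("candidate list is empty")
    eig: dict[str, float] = {}
    for cand in candidates:
        eig[cand] = sum(
            expected_information_gain(net, evidence, cand, q)
            for q in query_set if q != cand and q not in (evidence or {})
        )
    best = max(eig, key=lambda c: (eig[c], -list(candidates).index(c)))
    return best, eig


@dataclass
class SessionEntry:
    session: int
    posteriors: dict[str, list[float]]
    cpt_drift: float | None
    selected_action: str | None
    expected_ig_bits: float | None
    priority_ranking: list[tuple[str, float]]
    flagged: bool = False

    def to_dict(self) -> dict:
        return {
            "session": self.session,
            "posteriors": self.posteriors,
            "cpt_drift": self.cpt_drift,
            "selected_action": self.selected_action,
            "expected_ig_bits": self.expected_ig_bits,
            "priority_ranking": [[n, p] for n, p in self.priority_ranking],
            "flagged": self.flagged,
        }


@dataclass
class StrategyTrace:
    """Per-session record of the closed-loop strategy."""

    entries: list[SessionEntry] = field(default_factory=list)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for entry in self.entries:
                fh.write(json.dumps(entry.to_dict()) + "\n")

    def summary_markdown(self) -> str:
        lines = [
            "| Session | CPT drift | Action | Expected IG (bits) | Top priority |",
            "| --- | --- | --- | --- | --- |",
        ]
        for e in self.entries:
            drift = "" if e.cpt_drift is None else f"{e.cpt_drift:.4f}"
            eig = "" if e.expected_ig_bits is None else f"{e.expected_ig_bits:.4f}"
            top = e.priority_ranking[0][0] if e.priority_ranking else ""
            lines.append(f"| {e.session} | {drift} | {e.selected_action or ''} "
                         f"| {eig} | {top} |")
        return "\n".join(lines) + "\n"


def _grade_soft_update(net: BayesNet, r_marginals: Mapping[str, np.ndarray]) -> np.ndarray:
    """Soft-evidence update of the injury grade from repair marginals:
    P(P1=p) is reweighted by the expected likelihood of the repair
    posteriors under each grade."""
    prior = net.cpts["P1"].table
    weight = prior.copy()
    for rid, post in r_marginals.items():
        if net.parents(rid) == ("P1",):
            weight = weight * (net.cpts[rid].table @ np.asarray(post))
    total = weight.sum()
    if total <= 0:
        raise DegenerateEvidenceError("zero mass in grade update")
    return weight / total


def run_session_loop(net: BayesNet, session_stream: Iterable[pd.DataFrame],
                     n_sessions: int,
                     pseudocount: float = 1.0,
                     candidates: Sequence[str] = DEFAULT_CANDIDATES,
                     query_set: Sequence[str] = DEFAULT_QUERY_SET,
                     score_table: FactorScoreTable | None = None,
                     ) -> StrategyTrace:
    """Run the closed training loop for ``n_sessions`` batches.

    Per session: (1) recalibrate all CPTs from the cumulative session
    counts (with the loop's pseudocount); (2) update posteriors in the
    hierarchical order observation -> intermediate -> target -> grade;
    (3) rank goal priorities and select the next observation action.  A
    batch whose functional states carry zero posterior mass flags the
    session and carries the previous posterior forward.  The loop is
    deterministic given the stream.
    """
    table = score_table or load_score_table()
    trace = StrategyTrace()
    if n_sessions == 0:
        return trace
    stream: Iterator[pd.DataFrame] = iter(session_stream)
    batches: list[pd.DataFrame] = []
    current = net.copy()
    prev_posteriors: dict[str, np.ndarray] = exact_inference(current, {}).marginals
    prev_tables = None
    for session in range(n_sessions):
        try:
            batch = next(stream)
        except StopIteration:
            warnings.warn(
                f"session stream exhausted after {session} of {n_sessions} "
                "sessions; trace truncated",
                stacklevel=2,
            )
            break
        batches.append(batch)
        cumulative = pd.concat(batches, ignore_index=True)
        recal = learn_parameters(net, cumulative, pseudocount)
        drift = None
        if prev_tables is not None:
            drift = max(
                float(np.abs(recal.cpts[nid].table - prev_tables[nid]).max())
                for nid in recal.nodes
            )
        prev_tables = {nid: recal.cpts[nid].table.copy() for nid in recal.nodes}
        current = recal

        flagged = False
        try:
            b_marginals = update_observation_nodes(current, batch)
            priors = exact_inference(current, {}).marginals
            configs = batch.groupby(["B1", "B2", "B3", "B4"]).size()
            weighted: dict[str, np.ndarray] = {}
            total = 0
            for states, count in configs.items():
                b_evidence = dict(zip(("B1", "B2", "B3", "B4"), map(int, states)))
                post = posterior_intermediate(current, b_evidence, r_priors=priors)
                for rid, vec in post.items():
                    weighted[rid] = weighted.get(rid, 0.0) + count * vec
                total += count
            r_marginals = {rid: vec / total for rid, vec in weighted.items()}
            g_marginals = posterior_target(current, r_marginals)
            p1 = _grade_soft_update(current, r_marginals)
            posteriors = {**b_marginals, **r_marginals, **g_marginals, "P1": p1}
        except DegenerateEvidenceError:
            flagged = True
            posteriors = prev_posteriors
        prev_posteriors = posteriors

        action, eig = select_next_action(current, {}, candidates, query_set)
        ranking = intervention_priority(
            {g: posteriors[g] for g in table.goal_nodes}, table
        )
        trace.entries.append(SessionEntry(
            session=session,
            posteriors={k: np.asarray(v).tolist() for k, v in posteriors.items()},
            cpt_drift=drift,
            selected_action=action,
            expected_ig_bits=eig[action],
            priority_ranking=ranking,
            flagged=flagged,
        ))
    return trace
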