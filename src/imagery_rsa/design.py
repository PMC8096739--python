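"""Experimental designs: stimulus sets and continuous carry-over trial timelines.

Three event-related fMRI experiments on mental imagery and perception of
topological (campus buildings) and non-topological (cities on the map of
Italy, hours on the clock face, famous faces) stimuli:

* Experiment 1 — imagery only; 8 buildings + 8 cities + 8 hours, each item
  located in one of four spatial quadrants (two items per quadrant per
  category); 5 scans of 120 experimental + 5 null + 9 question trials.
* Experiment 2 — imagery and perception of the 8 buildings; 3 scans of
  48 + 48 experimental + 12 null + 6 question trials.
* Experiment 3 — imagery and perception of 6 buildings and 6 famous faces
  (no quadrant task); 5 scans of 60 + 60 experimental + 5 null + 9 question
  trials.

Stimuli are presented in serially balanced sequences in which each stimulus
precedes and follows every other stimulus (continuous carry-over design).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("building", "city", "hour", "face")
QUADRANTS = ("NE", "SE", "SW", "NW")
DOMAINS = ("imagery", "perception")

#: scans per experiment
N_RUNS = {1: 5, 2: 3, 3: 5}
#: per-run presentations of each condition
REPS_PER_RUN = {1: 5, 2: 6, 3: 5}
#: per-run (experimental, null, question) trial counts
TRIAL_COUNTS = {1: (120, 5, 9), 2: (96, 12, 6), 3: (120, 5, 9)}

EVENT_DURATION_S = 2.0
FIXATION_GAP_S = 2.0
QUESTION_DURATION_S = 4.0

_BUILDINGS = (
    ("literature", "NE"), ("mathematics", "NE"),
    ("chemistry", "SE"), ("orthopedics", "SE"),
    ("hygiene", "SW"), ("chapel", "SW"),
    ("political_science", "NW"), ("law", "NW"),
)
_CITIES = (
    ("bolzano", "NE"), ("trieste", "NE"),
    ("lecce", "SE"), ("foggia", "SE"),
    ("salerno", "SW"), ("frosinone", "SW"),
    ("alessandria", "NW"), ("cuneo", "NW"),
)
_HOURS = (
    ("01:00", "NE"), ("02:00", "NE"),
    ("04:00", "SE"), ("05:00", "SE"),
    ("07:00", "SW"), ("08:00", "SW"),
    ("10:00", "NW"), ("11:00", "NW"),
)
# Experiment-3 landmark subset (quadrant task not administered there).
_EXP3_BUILDINGS = ("literature", "orthopedics", "hygiene",
                   "chapel", "mathematics", "law")
_EXP3_FACES = tuple(f"face_{i + 1}" for i in range(6))


@dataclass(frozen=True)
class StimulusItem:
    """One imaginable/perceivable target item."""

    item_id: str
    label: str
    category: str
    quadrant: Optional[str]
    experiment: int

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.quadrant is not None and self.quadrant not in QUADRANTS:
            raise ValueError(f"unknown quadrant {self.quadrant!r}")


@dataclass(frozen=True)
class Condition:
    """A stimulus item within a task domain (imagery or perception)."""

    item: StimulusItem
    domain: str

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")

    @property
    def name(self) -> str:
        return f"{self.domain}:{self.item.item_id}"


@dataclass
class TrialTimeline:
    """Ordered, timed trials of one scanning run.

    ``trials`` rows are (onset_s, duration_s, kind, condition) with kind in
    {"experimental", "null", "question"}; null and question trials carry no
    condition.
    """

    experiment: int
    run_id: int
    trials: list = field(default_factory=list)

    def counts(self) -> dict:
        out = {"experimental": 0, "null": 0, "question": 0}
        for _, _, kind, _ in self.trials:
            out[kind] += 1
        return out

    def condition_counts(self) -> dict:
        out: dict = {}
        for _, _, kind, cond in self.trials:
            if kind == "experimental":
                out[cond.name] = out.get(cond.name, 0) + 1
        return out

    def experimental_conditions(self) -> list:
        return [cond for _, _, kind, cond in self.trials if kind == "experimental"]

    def to_events_frame(self) -> pd.DataFrame:
        rows = []
        for onset, dur, kind, cond in self.trials:
            rows.append({
                "onset": onset,
                "duration": dur,
                "kind": kind,
                "item_id": cond.item.item_id if cond else "n/a",
                "category": cond.item.category if cond else "n/a",
                "domain": cond.domain if cond else "n/a",
                "quadrant": (cond.item.quadrant or "n/a") if cond else "n/a",
            })
        return pd.DataFrame(rows)

    def write_events(self, path) -> None:
        """BIDS-events-like TSV."""
        self.to_events_frame().to_csv(path, sep="\t", index=False)

    @property
    def duration(self) -> float:
        if not self.trials:
            return 0.0
        onset, dur, kind, _ = self.trials[-1]
        gap = 0.0 if kind == "question" else FIXATION_GAP_S
        return onset + dur + gap


def _items_for_experiment(experiment: int) -> list:
    if experiment == 1:
        specs = ([(n, "building", q) for n, q in _BUILDINGS]
                 + [(n, "city", q) for n, q in _CITIES]
                 + [(n, "hour", q) for n, q in _HOURS])
    elif experiment == 2:
        specs = [(n, "building", q) for n, q in _BUILDINGS]
    elif experiment == 3:
        specs = ([(n, "building", None) for n in _EXP3_BUILDINGS]
                 + [(n, "face", None) for n in _EXP3_FACES])
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    return [StimulusItem(item_id=f"{cat}:{name}", label=name, category=cat,
                         quadrant=quad, experiment=experiment)
            for name, cat, quad in specs]


def make_stimulus_set(experiment: int) -> list:
    """Full condition list (item × domain) of one experiment.

    Experiment 1 is imagery-only; Experiments 2 and 3 cross every item with
    both the imagery and the perception domain.
    """
    items = _items_for_experiment(experiment)
    domains = ("imagery",) if experiment == 1 else DOMAINS
    return [Condition(item=item, domain=d) for d in domains for item in items]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _hierholzer(arcs_by_node: list, start: int, rng: np.random.Generator) -> list:
    """Eulerian circuit over the given out-arc lists (consumed), seeded order."""
    for lst in arcs_by_node:
        rng.shuffle(lst)
    stack = [start]
    circuit = []
    ptr = [0] * len(arcs_by_node)
    while stack:
        v = stack[-1]
        if ptr[v] < len(arcs_by_node[v]):
            stack.append(arcs_by_node[v][ptr[v]])
            ptr[v] += 1
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    return circuit


def _weakly_connected(arcs: Iterable, n: int) -> bool:
    adj: list = [[] for _ in range(n)]
    for a, b in arcs:
        adj[a].append(b)
        adj[b].append(a)
    seen = [False] * n
    todo = [0]
    seen[0] = True
    while todo:
        v = todo.pop()
        for w in adj[v]:
            if not seen[w]:
                seen[w] = True
                todo.append(w)
    return all(seen)


def _disjoint_permutations(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """k pairwise arc-disjoint random permutations of range(n), as (k, n)."""
    for _ in range(1000):
        perms = np.empty((k, n), dtype=int)
        ok = True
        for j in range(k):
            for _ in range(200):
                p = rng.permutation(n)
                if not (perms[:j] == p).any():
                    perms[j] = p
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        arcs = [(i, perms[j, i]) for j in range(k) for i in range(n)]
        if _weakly_connected(arcs, n):
            return perms
    raise RuntimeError("could not sample arc-disjoint permutations")


def carryover_sequence(n_items: int, n_trials: int, seed) -> np.ndarray:
    """Serially balanced stimulus order of length ``n_trials``.

    Over the returned index sequence the counts of every ordered successor
    pair, self-successions included, differ by at most one: the sequence is
    a (possibly truncated or chained) Eulerian circuit on the complete
    directed graph with self-loops.  When ``n_trials`` is a multiple
    ``k * n_items`` with ``k <= n_items``, the circuit is taken over the
    union of ``k`` arc-disjoint random permutation digraphs, so every item
    additionally occurs exactly ``k`` times.
    """
    if n_items < 1 or n_trials < 1:
        raise ValueError("n_items and n_trials must be >= 1")
    rng = _as_rng(seed)
    if n_items == 1:
        return np.zeros(n_trials, dtype=int)

    k, rem = divmod(n_trials, n_items)
    if rem == 0 and 1 <= k <= n_items:
        perms = _disjoint_permutations(n_items, k, rng)
        arcs = [list(perms[:, i]) for i in range(n_items)]
        circuit = _hierholzer(arcs, start=int(rng.integers(n_items)), rng=rng)
        # circuit has n_trials + 1 nodes with last == first; drop the last
        return np.asarray(circuit[:-1], dtype=int)

    # chained full circuits on K_n with self-loops, truncated
    out: list = []
    start = int(rng.integers(n_items))
    while len(out) < n_trials:
        arcs = [list(range(n_items)) for _ in range(n_items)]
        circuit = _hierholzer(arcs, start=start, rng=rng)
        out.extend(circuit[:-1])  # last node == start of the next circuit
    return np.asarray(out[:n_trials], dtype=int)


def successor_counts(sequence: Sequence[int], n_items: int) -> np.ndarray:
    """Ordered successor-pair count matrix of a sequence (balance oracle)."""
    counts = np.zeros((n_items, n_items), dtype=int)
    seq = np.asarray(sequence)
    np.add.at(counts, (seq[:-1], seq[1:]), 1)
    return counts


def build_trial_timeline(experiment: int, run_id: int, seed) -> TrialTimeline:
    """One run's timed trial list for the given experiment.

    Experimental trials follow a carry-over sequence over all conditions
    (domain is part of the condition identity in Experiments 2–3); null and
    question trials are inserted at seeded random positions afterwards so
    the stimulus balance stays exact.  Experimental and null trials last 2 s
    and are followed by a 2 s fixation; question trials last 4 s.
    """
    if experiment not in N_RUNS:
        raise ValueError(f"unknown experiment {experiment!r}")
    if not 1 <= run_id <= N_RUNS[experiment]:
        raise ValueError(
            f"run_id {run_id} out of range for experiment {experiment} "
            f"(1..{N_RUNS[experiment]})")
    conditions = make_stimulus_set(experiment)
    n_exp, n_null, n_question = TRIAL_COUNTS[experiment]
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(experiment, run_id)))
    order = carryover_sequence(len(conditions), n_exp, rng)

    slots = [("experimental", conditions[i]) for i in order]
    n_total = n_exp + n_null + n_question
    insert_at = rng.choice(n_total, size=n_null + n_question, replace=False)
    extras = ["null"] * n_null + ["question"] * n_question
    rng.shuffle(extras)
    for pos, kind in sorted(zip(insert_at, extras), reverse=True):
        slots.insert(int(pos), (kind, None))

    timeline = TrialTimeline(experiment=experiment, run_id=run_id)
    t = 0.0
    for kind, cond in slots:
        if kind == "question":
            timeline.trials.append((t, QUESTION_DURATION_S, kind, cond))
            t += QUESTION_DURATION_S
        else:
            timeline.trials.append((t, EVENT_DURATION_S, kind, cond))
            t += EVENT_DURATION_S + FIXATION_GAP_S
    return timeline
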