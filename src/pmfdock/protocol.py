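"""Staged replicate ranking of docking decoys by binding free energy.

The protocol trades simulation cost against ranking accuracy in two stages:

1. every decoy gets a single replicate (one full window series) and the
   decoys are ranked on that one dG_off estimate;
2. the best (lowest) half survives and receives four more replicates; the
   final ranking sorts survivors on the mean dG_off over all five
   replicates.  Decoys cut at stage 1 keep their single-replicate score and
   are appended after the survivors in stage-1 order, so set-level
   statistics over the full decoy set remain computable.

Ties are broken lexicographically on the decoy id, which makes every
ranking total and reproducible.  A crystal-reference helper runs the native
structure at a higher replicate count (20 by default) to provide the
reference free energy the decoy distributions are compared against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .pmfcalc import (WindowSchedule, make_schedule, integrate_pmf,
                      extract_dgoff, average_dgoff, DGoff)

# engine(decoy_id, schedule, replicate) -> list[WindowSample]
Engine = Callable[[str, WindowSchedule, int], list]

__all__ = ["DecoySet", "Ranking", "stage1_rank", "select_best_half",
           "run_full_protocol", "top_k", "crystal_reference"]


@dataclass
class DecoyEntry:
    structure: object = None          # Structure or None (score-only sets)
    dock_com: float = float("nan")    # nm
    dgoff: dict = field(default_factory=dict)   # replicate -> DGoff


@dataclass
class DecoySet:
    """Decoy ids with structures, COM distances and per-replicate scores."""

    entries: dict = field(default_factory=dict)  # id -> DecoyEntry

    def __post_init__(self):
        for did, e in self.entries.items():
            for d in e.dgoff.values():
                if d.value > 1e-9:
                    raise ValueError(f"positive dG_off for {did}")

    @property
    def ids(self) -> list:
        return list(self.entries)

    def add(self, decoy_id: str, structure=None, dock_com=float("nan")):
        if decoy_id in self.entries:
            raise ValueError(f"duplicate decoy id {decoy_id!r}")
        self.entries[decoy_id] = DecoyEntry(structure=structure,
                                            dock_com=dock_com)

    def set_dgoff(self, decoy_id: str, replicate: int, value: DGoff):
        self.entries[decoy_id].dgoff[replicate] = value

    def score(self, decoy_id: str, replicates=None) -> float:
        """Mean dG_off over the given replicates (all present if None)."""
        reps = self.entries[decoy_id].dgoff
        if replicates is None:
            vals = [d.value for d in reps.values()]
        else:
            vals = [reps[r].value for r in replicates]
        if not vals:
            raise ValueError(f"no dG_off values for {decoy_id!r}")
        return float(np.mean(vals))


@dataclass(frozen=True)
class Ranking:
    """Ordered decoy ids with the scores that produced the order."""

    ids: tuple
    scores: tuple                  # same order; non-decreasing in scope
    stage: str                     # "stage1" | "final"
    cut_after: int | None = None   # index of first stage-1-only decoy

    def __post_init__(self):
        if len(self.ids) != len(self.scores):
            raise ValueError("ids and scores differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in ranking")

    def score_of(self, decoy_id) -> float:
        return self.scores[self.ids.index(decoy_id)]


def _sorted_ranking(scored: list, stage: str, cut_after=None) -> Ranking:
    order = sorted(scored, key=lambda t: (t[1], t[0]))
    return Ranking(ids=tuple(i for i, _ in order),
                   scores=tuple(s for _, s in order),
                   stage=stage, cut_after=cut_after)


def stage1_rank(decoys: DecoySet, replicate: int = 1) -> Ranking:
    """Rank all decoys ascending on their single-replicate dG_off.

    Requires the given replicate (default 1) for every decoy; ties are
    broken lexicographically on the decoy id.
    """
    scored = []
    for did, e in decoys.entries.items():
        if replicate not in e.dgoff:
            raise ValueError(f"decoy {did!r} is missing replicate {replicate}")
        scored.append((did, e.dgoff[replicate].value))
    if not scored:
        raise ValueError("empty decoy set")
    return _sorted_ranking(scored, "stage1")


def select_best_half(ranking: Ranking) -> set:
    """Ids of the best (lowest-scoring) ceil(N/2) decoys."""
    n = len(ranking.ids)
    if n == 0:
        raise ValueError("empty ranking")
    return set(ranking.ids[:math.ceil(n / 2)])


def top_k(ranking: Ranking, k: int) -> list:
    """First min(k, N) decoy ids of a ranking."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return list(ranking.ids[:k])


def run_full_protocol(decoys: DecoySet, engine: Engine,
                      n_extra_replicates: int = 4,
                      temperature: float = 300.0,
                      jacobian_correction: bool = True) -> Ranking:
    """Run the staged ranking end to end.

    ``engine(decoy_id, schedule, replicate)`` must return one
    :class:`~pmfdock.dynamics.WindowSample` per scheduled distance and be
    deterministic given its arguments.  Stage 1 runs replicate 1 for every
    decoy; the best half then receives replicates 2..(1+n_extra) and the
    final ranking sorts survivors on the mean over all their replicates
    (the stage-1 replicate included).  Cut decoys follow in stage-1 order.
    """
    schedules = {}
    for did, e in decoys.entries.items():
        if not np.isfinite(e.dock_com):
            raise ValueError(f"decoy {did!r} has no dock_com")
        schedules[did] = make_schedule(e.dock_com)

    def run_one(did, replicate):
        try:
            samples = engine(did, schedules[did], replicate)
        except Exception as exc:
            raise RuntimeError(
                f"engine failed for decoy {did!r}, replicate {replicate}: "
                f"{exc}") from exc
        profile = integrate_pmf(samples, temperature, jacobian_correction)
        decoys.set_dgoff(did, replicate,
                         extract_dgoff(profile, replicate=replicate))

    for did in decoys.ids:
        run_one(did, 1)
    s1 = stage1_rank(decoys)
    survivors = select_best_half(s1)

    for did in sorted(survivors):
        for rep in range(2, 2 + n_extra_replicates):
            run_one(did, rep)

    scored = [(did, decoys.score(did)) for did in survivors]
    final = sorted(scored, key=lambda t: (t[1], t[0]))
    tail = [(did, s1.score_of(did)) for did in s1.ids if did not in survivors]
    ids = tuple(i for i, _ in final) + tuple(i for i, _ in tail)
    scores = tuple(s for _, s in final) + tuple(s for _, s in tail)
    return Ranking(ids=ids, scores=scores, stage="final",
                   cut_after=len(final))


def crystal_reference(decoy_id: str, dock_com: float, engine: Engine,
                      n_replicates: int = 20, temperature: float = 300.0,
                      jacobian_correction: bool = True) -> DGoff:
    """Reference dG_off of the native complex from many replicates."""
    schedule = make_schedule(dock_com)
    per_rep = []
    for rep in range(1, n_replicates + 1):
        samples = engine(decoy_id, schedule, rep)
        profile = integrate_pmf(samples, temperature, jacobian_correction)
        per_rep.append(extract_dgoff(profile, replicate=rep))
    return average_dgoff(per_rep)
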