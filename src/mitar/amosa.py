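"""Archived multi-objective simulated annealing over fixed-length bitstrings.

Maximizes N objectives simultaneously while maintaining a bounded archive
of mutually non-dominated solutions.  The archive has a soft limit SL and
a hard limit HL <= SL: whenever its size exceeds SL it is reduced to HL by
single-linkage clustering in objective space, each cluster replaced by the
member with minimum average distance to the others.

Acceptance of a perturbed solution follows the three-case outline:
(a) the new point dominates the current point -> accept (and archive it if
no archived member dominates it); (b) the current point dominates the new
point -> accept with probability 1/(1 + exp(dom_avg / T)) where dom_avg
averages the amount of domination of the current point and any dominating
archive members over the new point; (c) mutually non-dominating -> accept
and archive if undominated by the archive, else accept with the same
probabilistic form.  The amount of domination of a over b is the product
over objectives with a_i != b_i of |a_i - b_i| / R_i, with R_i the running
range of objective i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

Bits = tuple[int, ...]
Objectives = tuple[float, ...]
Evaluator = Callable[[Bits], Objectives]

RANGE_FLOOR = 1e-6
_EXP_CLAMP = 60.0


@dataclass(frozen=True)
class Solution:
    bits: Bits
    objectives: Objectives

    @property
    def n_set(self) -> int:
        return sum(self.bits)


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """a dominates b: a >= b componentwise with at least one strict >."""
    if len(a) != len(b):
        raise ValueError("objective vectors differ in length")
    ge = all(x >= y for x, y in zip(a, b))
    return ge and any(x > y for x, y in zip(a, b))


def domination_amount(
    a: Sequence[float], b: Sequence[float], ranges: Sequence[float]
) -> float:
    """Product of normalized gaps over the objectives where a and b differ."""
    if len(a) != len(b) or len(a) != len(ranges):
        raise ValueError("objective/range vectors differ in length")
    if any(r <= 0 for r in ranges):
        raise ValueError("all objective ranges must be > 0")
    prod = 1.0
    differ = False
    for x, y, r in zip(a, b, ranges):
        if x != y:
            differ = True
            prod *= abs(x - y) / r
    return prod if differ else 0.0


class Archive:
    """Bounded store of mutually non-dominated solutions."""

    def __init__(self, HL: int = 30, SL: int = 60):
        if SL < HL:
            raise ValueError("SL must be >= HL")
        self.HL = HL
        self.SL = SL
        self.members: list[Solution] = []

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def dominating_members(self, obj: Objectives) -> list[Solution]:
        return [m for m in self.members if dominates(m.objectives, obj)]

    def insert(self, sol: Solution) -> bool:
        """Insert if not dominated; drop members the new solution dominates.

        Returns True if inserted.  The caller is responsible for size
        reduction (see :meth:`needs_reduction`).
        """
        if any(m.bits == sol.bits for m in self.members):
            return False
        if self.dominating_members(sol.objectives):
            return False
        self.members = [
            m for m in self.members if not dominates(sol.objectives, m.objectives)
        ]
        self.members.append(sol)
        return True

    def needs_reduction(self) -> bool:
        return len(self.members) > self.SL


@dataclass(frozen=True)
class Schedule:
    """Annealing schedule and archive/search sizes.

    Defaults are conservative generic settings; runs scale linearly in
    ``iters_per_temp`` times the number of temperature steps.
    """

    Tmax: float = 100.0
    Tmin: float = 1e-4
    alpha: float = 0.9
    iters_per_temp: int = 50
    n_init: int = 10
    hc_iters: int = 20
    HL: int = 30
    SL: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.Tmax > self.Tmin > 0):
            raise ValueError("need Tmax > Tmin > 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


class _RangeTracker:
    """Running per-objective min/max over every evaluated solution."""

    def __init__(self) -> None:
        self.lo: Optional[np.ndarray] = None
        self.hi: Optional[np.ndarray] = None

    def update(self, obj: Objectives) -> None:
        v = np.asarray(obj, dtype=float)
        if self.lo is None:
            self.lo = v.copy()
            self.hi = v.copy()
        else:
            np.minimum(self.lo, v, out=self.lo)
            np.maximum(self.hi, v, out=self.hi)

    @property
    def ranges(self) -> tuple[float, ...]:
        return tuple(float(max(h - l, RANGE_FLOOR)) for l, h in zip(self.lo, self.hi))


def _random_bits(rng: np.random.Generator, L: int) -> Bits:
    while True:
        bits = tuple(int(b) for b in rng.integers(0, 2, size=L))
        if any(bits):
            return bits


def _flip_one(rng: np.random.Generator, bits: Bits) -> Bits:
    while True:
        i = int(rng.integers(0, len(bits)))
        new = list(bits)
        new[i] = 1 - new[i]
        if any(new):
            return tuple(new)


def cluster_reduce(archive: Archive, target: int) -> Archive:
    """Reduce the archive to ``target`` members by single-linkage clustering.

    Clusters are formed in objective space (Euclidean); each is replaced by
    the member whose average distance to the other cluster members is
    minimal (ties: lexicographically smallest bitstring).  Archives already
    within the target are returned unchanged.
    """
    if len(archive) <= target:
        return archive
    objs = np.array([m.objectives for m in archive.members], dtype=float)
    Z = linkage(objs, method="single")
    assignments = fcluster(Z, t=target, criterion="maxclust")
    dist = squareform(pdist(objs))
    reduced = Archive(HL=archive.HL, SL=archive.SL)
    for cluster_id in np.unique(assignments):
        idx = np.flatnonzero(assignments == cluster_id)
        if len(idx) == 1:
            reduced.members.append(archive.members[idx[0]])
            continue
        sub = dist[np.ix_(idx, idx)]
        avg = sub.sum(axis=1) / (len(idx) - 1)
        best = min(range(len(idx)), key=lambda j: (avg[j], archive.members[idx[j]].bits))
        reduced.members.append(archive.members[idx[best]])
    return reduced


def _accept_prob(dom_avg: float, T: float) -> float:
    return 1.0 / (1.0 + math.exp(min(dom_avg / T, _EXP_CLAMP)))


def initialize(
    evaluator: Evaluator,
    L: int,
    schedule: Schedule,
    rng: Optional[np.random.Generator] = None,
    tracker: Optional[_RangeTracker] = None,
) -> Archive:
    """Random solutions refined by hill climbing, then non-dominated filter.

    Each of ``n_init`` random bitstrings is improved for ``hc_iters``
    single-bit-flip steps (a neighbor is accepted iff it dominates); the
    non-dominated survivors seed the archive, clustered down to HL if
    needed.
    """
    rng = rng if rng is not None else np.random.default_rng(schedule.seed)
    tracker = tracker or _RangeTracker()
    refined: list[Solution] = []
    for _ in range(schedule.n_init):
        bits = _random_bits(rng, L)
        obj = tuple(evaluator(bits))
        tracker.update(obj)
        cur = Solution(bits, obj)
        for _ in range(schedule.hc_iters):
            nb = _flip_one(rng, cur.bits)
            nobj = tuple(evaluator(nb))
            tracker.update(nobj)
            if dominates(nobj, cur.objectives):
                cur = Solution(nb, nobj)
        refined.append(cur)
    archive = Archive(HL=schedule.HL, SL=schedule.SL)
    for sol in refined:
        archive.insert(sol)
    if len(archive) > schedule.HL:
        archive = cluster_reduce(archive, schedule.HL)
    return archive


def run(
    evaluator: Evaluator,
    L: int,
    schedule: Schedule,
    on_archive_change: Optional[Callable[[Archive], None]] = None,
    log_path: Optional[str] = None,
) -> Archive:
    """Full annealing run; returns the final archive (<= HL members).

    ``on_archive_change`` is invoked after every archive update (used by
    invariant checks); ``log_path`` writes a TSV run log of temperature,
    iteration, acceptance and archive size.
    """
    rng = np.random.default_rng(schedule.seed)
    tracker = _RangeTracker()
    archive = initialize(evaluator, L, schedule, rng, tracker)
    if on_archive_change:
        on_archive_change(archive)

    current = archive.members[int(rng.integers(0, len(archive)))]
    log_rows: list[str] = []
    best_third = max(m.objectives[-1] for m in archive.members)

    T = schedule.Tmax
    while T >= schedule.Tmin:
        for it in range(schedule.iters_per_temp):
            new_bits = _flip_one(rng, current.bits)
            try:
                new_obj = tuple(evaluator(new_bits))
            except Exception:
                raise RuntimeError(
                    f"objective evaluation failed for bitstring {''.join(map(str, new_bits))}"
                )
            tracker.update(new_obj)
            new = Solution(new_bits, new_obj)
            R = tracker.ranges
            accepted = False
            if dominates(new.objectives, current.objectives):  # case (a)
                current = new
                accepted = True
                if not archive.dominating_members(new.objectives):
                    if archive.insert(new):
                        archive = _reduced(archive)
                        if on_archive_change:
                            on_archive_change(archive)
            elif dominates(current.objectives, new.objectives):  # case (b)
                doms = [current] + archive.dominating_members(new.objectives)
                dom_avg = float(
                    np.mean([
                        domination_amount(d.objectives, new.objectives, R) for d in doms
                    ])
                )
                if rng.random() < _accept_prob(dom_avg, T):
                    current = new
                    accepted = True
            else:  # case (c): current and new mutually non-dominating
                dominating = archive.dominating_members(new.objectives)
                if dominating:
                    dom_avg = float(
                        np.mean([
                            domination_amount(d.objectives, new.objectives, R)
                            for d in dominating
                        ])
                    )
                    if rng.random() < _accept_prob(dom_avg, T):
                        current = new
                        accepted = True
                else:
                    archive.insert(new)
                    archive = _reduced(archive)
                    current = new
                    accepted = True
                    if on_archive_change:
                        on_archive_change(archive)
            best_third = max(best_third, new.objectives[-1])
            if log_path:
                log_rows.append(
                    f"{T:.6g}\t{it}\t{int(accepted)}\t{len(archive)}\t{best_third:.6g}"
                )
        T *= schedule.alpha

    if len(archive) > schedule.HL:
        archive = cluster_reduce(archive, schedule.HL)
        if on_archive_change:
            on_archive_change(archive)
    if log_path:
        with open(log_path, "w") as fh:
            fh.write("temperature\titeration\taccepted\tarchive_size\tbest_last_objective\n")
            fh.write("\n".join(log_rows) + "\n")
    return archive


def _reduced(archive: Archive) -> Archive:
    if archive.needs_reduction():
        return cluster_reduce(archive, archive.HL)
    return archive


def dump_archive(archive: Archive, path: str) -> None:
    """Archive dump: one row per member, bits then objectives (TSV)."""
    with open(path, "w") as fh:
        fh.write("bits\tobjectives\n")
        for m in archive.members:
            bits = "".join(str(b) for b in m.bits)
            objs = ",".join(f"{o:.6g}" for o in m.objectives)
            fh.write(f"{bits}\t{objs}\n")
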