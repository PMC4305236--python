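"""Two-phase scaffold ordering and orientation for one chromosome.

Phase 1 computes a fast initial configuration: pairwise orientation scores
assembled into a symmetric matrix whose leading-eigenvector signs orient
the scaffolds, and a travelling-salesman path over pairwise marker
distances to order them (nearest-neighbour construction plus 2-opt /
Or-opt improvement; an exact external solver can be plugged in via
``tsp_solver``).

Phase 2 refines the configuration with an elitist genetic algorithm over
permutations (inversion and insertion mutations, partially-mapped
crossover) interleaved with greedy single-scaffold flip passes, repeated
in rounds until the weighted colinearity score L stops improving.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .colinearity import lms
from .map_model import MapCollection, Marker, ScaffoldConfiguration
from .preprocess import ChromosomeProblem

logger = logging.getLogger(__name__)

__all__ = [
    "OrientationMatrix",
    "DistanceMatrix",
    "GAParams",
    "ChromosomeScorer",
    "orientation_score",
    "build_orientation_matrix",
    "orient_by_eigenvector",
    "pairwise_distance",
    "build_distance_matrix",
    "initial_order",
    "flip_pass",
    "ga_refine",
    "order_and_orient",
]

EIGENVECTOR_TOL = 1e-9


@dataclass
class OrientationMatrix:
    scaffold_ids: list[str]
    M: np.ndarray

    def __post_init__(self) -> None:
        if self.M.shape != (len(self.scaffold_ids),) * 2:
            raise ValueError("orientation matrix shape mismatch")


@dataclass
class DistanceMatrix:
    scaffold_ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        if self.D.shape != (len(self.scaffold_ids),) * 2:
            raise ValueError("distance matrix shape mismatch")
        if (self.D < 0).any():
            raise ValueError("distances must be nonnegative")


@dataclass
class GAParams:
    """Genetic-algorithm knobs; all runtime-adjustable."""

    npop: int = 100
    window: int = 1000  # generations with no best-score change -> converged
    p_mut: float = 0.2
    p_cross: float = 0.7
    tournament: int = 3
    max_rounds: int = 10
    max_gen: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_mut, self.p_cross):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of range: {p}")
        if self.npop < 2 or self.window < 1 or self.tournament < 1:
            raise ValueError("invalid GA parameters")


class ChromosomeScorer:
    """Fast L evaluation for permutations of one chromosome's scaffolds.

    Precomputes, per (map, linkage group) track and per scaffold, the map
    positions sorted by ascending physical position (and the reverse).
    """

    def __init__(self, problem: ChromosomeProblem):
        self.problem = problem
        self.scaffold_ids = list(problem.scaffold_ids)
        self.index = {sid: i for i, sid in enumerate(self.scaffold_ids)}
        n = len(self.scaffold_ids)
        self.tracks: list[tuple[str, float, list[tuple], list[tuple]]] = []
        for (map_name, lg), per_scaffold in sorted(problem.tracks.items()):
            fwd: list[tuple] = [()] * n
            rev: list[tuple] = [()] * n
            for sid, markers in per_scaffold.items():
                i = self.index.get(sid)
                if i is None:
                    continue
                ys = tuple(m.map_pos for m in markers)  # already pos-sorted
                fwd[i] = ys
                rev[i] = ys[::-1]
            self.tracks.append((map_name, problem.weights[map_name], fwd, rev))
        # marker count per scaffold per track, for the orientation-0 rule
        self.max_track_markers = [0] * n
        for _, _, fwd, _ in self.tracks:
            for i, ys in enumerate(fwd):
                if len(ys) > self.max_track_markers[i]:
                    self.max_track_markers[i] = len(ys)

    def score(self, perm: Sequence[int], signs: Sequence[int]) -> float:
        total = 0.0
        for _, w, fwd, rev in self.tracks:
            seq: list[float] = []
            for i in perm:
                seq.extend(fwd[i] if signs[i] >= 0 else rev[i])
            total += w * lms(seq)
        return total

    def pivot_direction(self, perm: Sequence[int], signs: Sequence[int]) -> int:
        """+1 if the pivot map reads better increasing, -1 decreasing."""
        up = down = 0
        for map_name, _, fwd, rev in self.tracks:
            if map_name != self.problem.pivot:
                continue
            seq: list[float] = []
            for i in perm:
                seq.extend(fwd[i] if signs[i] >= 0 else rev[i])
            up += _lnds(seq)
            down += _lnds([-v for v in seq])
        return 1 if up >= down else -1

    def config(self, perm: Sequence[int], signs: Sequence[int]) -> ScaffoldConfiguration:
        entries = []
        for i in perm:
            s = signs[i]
            if self.max_track_markers[i] < 2:
                s = 0  # orientation undeterminable from any single map
            entries.append((self.scaffold_ids[i], int(s) if s else 0))
        return ScaffoldConfiguration(self.problem.chromosome_id, entries)


def _lnds(values: Sequence[float]) -> int:
    tails: list[float] = []
    for v in values:
        i = bisect_right(tails, v)
        if i == len(tails):
            tails.append(v)
        else:
            tails[i] = v
    return len(tails)


def _as_problem(maps: MapCollection, scaffold_ids: Sequence[str]) -> ChromosomeProblem:
    """Wrap a raw MapCollection as a single-chromosome problem (all tracks)."""
    tracks: dict[tuple[str, str], dict[str, list[Marker]]] = {}
    wanted = set(scaffold_ids)
    for gm in maps.maps:
        for lg, markers in gm.linkage_groups.items():
            per: dict[str, list[Marker]] = {}
            for m in markers:
                if m.scaffold_id in wanted:
                    per.setdefault(m.scaffold_id, []).append(m)
            if per:
                tracks[(gm.name, lg)] = {
                    sid: sorted(ms, key=lambda m: m.pos) for sid, ms in per.items()
                }
    from .preprocess import select_pivot

    return ChromosomeProblem(
        chromosome_id="chr",
        scaffold_ids=list(scaffold_ids),
        tracks=tracks,
        weights={gm.name: gm.weight for gm in maps.maps},
        pivot=select_pivot(maps),
        scaffold_sizes=maps.scaffold_sizes,
    )


def orientation_score(a: str, b: str, problem: ChromosomeProblem | MapCollection) -> float:
    """Pairwise orientation evidence: weighted sum over maps of
    LMS(a||b) - LMS(a||-b).  Positive means same orientation, negative
    opposite, zero undetermined.
    """
    if isinstance(problem, MapCollection):
        problem = _as_problem(problem, [a, b])
    scorer = ChromosomeScorer(problem)
    ia, ib = scorer.index[a], scorer.index[b]
    total = 0.0
    for _, w, fwd, rev in scorer.tracks:
        same = lms(list(fwd[ia]) + list(fwd[ib]))
        opposite = lms(list(fwd[ia]) + list(rev[ib]))
        total += w * (same - opposite)
    return total


def build_orientation_matrix(problem: ChromosomeProblem) -> OrientationMatrix:
    scorer = ChromosomeScorer(problem)
    n = len(scorer.scaffold_ids)
    M = np.zeros((n, n))
    for ia in range(n):
        for ib in range(ia + 1, n):
            total = 0.0
            for _, w, fwd, rev in scorer.tracks:
                if not fwd[ia] or not fwd[ib]:
                    continue
                same = lms(list(fwd[ia]) + list(fwd[ib]))
                opposite = lms(list(fwd[ia]) + list(rev[ib]))
                total += w * (same - opposite)
            M[ia, ib] = M[ib, ia] = total
    return OrientationMatrix(scorer.scaffold_ids, M)


def orient_by_eigenvector(matrix: OrientationMatrix, tol: float = EIGENVECTOR_TOL) -> np.ndarray:
    """Signs of the leading eigenvector of the orientation matrix.

    Components with magnitude below ``tol`` get sign 0 (undetermined).
    The global polarity is fixed so the first non-zero component is +1.
    """
    M = matrix.M
    if not np.any(M):
        return np.zeros(len(matrix.scaffold_ids), dtype=int)
    eigvals, eigvecs = np.linalg.eigh(M)
    y = eigvecs[:, -1]  # largest algebraic eigenvalue
    signs = np.where(np.abs(y) < tol, 0, np.sign(y)).astype(int)
    for s in signs:
        if s != 0:
            if s < 0:
                signs = -signs
            break
    return signs


def pairwise_distance(
    a: str,
    b: str,
    problem: ChromosomeProblem | MapCollection,
    penalty: dict[str, float] | None = None,
) -> float:
    """Weighted sum over maps of the minimum |map_pos difference| between
    markers of the two scaffolds.  A map on which either scaffold carries
    no markers contributes its span (or a caller-supplied penalty).
    """
    if isinstance(problem, MapCollection):
        # include every scaffold so linkage-group spans are computed fully
        problem = _as_problem(problem, problem.scaffolds_with_markers())
    if a == b:
        return 0.0
    by_map: dict[str, list[tuple[tuple, tuple]]] = {}
    spans: dict[str, float] = {}
    for (map_name, lg), per_scaffold in sorted(problem.tracks.items()):
        ys_all = [m.map_pos for ms in per_scaffold.values() for m in ms]
        span = (max(ys_all) - min(ys_all)) if ys_all else 0.0
        spans[map_name] = max(spans.get(map_name, 0.0), span)
        ma = per_scaffold.get(a)
        mb = per_scaffold.get(b)
        if ma and mb:
            by_map.setdefault(map_name, []).append(
                (tuple(m.map_pos for m in ma), tuple(m.map_pos for m in mb))
            )
    total = 0.0
    for map_name, w in problem.weights.items():
        pairs = by_map.get(map_name)
        if pairs:
            dmin = min(
                abs(x - y) for ya, yb in pairs for x in ya for y in yb
            )
            total += w * dmin
        else:
            pen = penalty.get(map_name) if penalty else spans.get(map_name, 0.0)
            total += w * (pen if pen is not None else 0.0)
    return total


def build_distance_matrix(
    problem: ChromosomeProblem, penalty: dict[str, float] | None = None
) -> DistanceMatrix:
    sids = list(problem.scaffold_ids)
    n = len(sids)
    # per track, per scaffold, numpy arrays of map positions
    track_arrays: list[tuple[str, list[np.ndarray | None]]] = []
    spans: dict[str, float] = {n2: 0.0 for n2 in problem.weights}
    index = {sid: i for i, sid in enumerate(sids)}
    for (map_name, lg), per_scaffold in sorted(problem.tracks.items()):
        arrays: list[np.ndarray | None] = [None] * n
        ys_all = []
        for sid, ms in per_scaffold.items():
            i = index.get(sid)
            if i is None:
                continue
            arr = np.array([m.map_pos for m in ms])
            arrays[i] = arr
            ys_all.append(arr)
        if ys_all:
            allv = np.concatenate(ys_all)
            spans[map_name] = max(spans[map_name], float(allv.max() - allv.min()))
        track_arrays.append((map_name, arrays))
    D = np.zeros((n, n))
    for ia in range(n):
        for ib in range(ia + 1, n):
            total = 0.0
            per_map_min: dict[str, float] = {}
            for map_name, arrays in track_arrays:
                xa, xb = arrays[ia], arrays[ib]
                if xa is None or xb is None:
                    continue
                dmin = float(np.min(np.abs(xa[:, None] - xb[None, :])))
                prev = per_map_min.get(map_name)
                if prev is None or dmin < prev:
                    per_map_min[map_name] = dmin
            for map_name, w in problem.weights.items():
                if map_name in per_map_min:
                    total += w * per_map_min[map_name]
                else:
                    pen = penalty.get(map_name) if penalty else spans.get(map_name, 0.0)
                    total += w * (pen if pen is not None else 0.0)
            D[ia, ib] = D[ib, ia] = total
    return DistanceMatrix(sids, D)


# ---------------------------------------------------------------------------
# Phase 1 ordering: heuristic path-TSP
# ---------------------------------------------------------------------------


def _tour_cost(D: np.ndarray, tour: list[int]) -> float:
    return float(sum(D[a, b] for a, b in zip(tour, tour[1:] + tour[:1])))


def _nearest_neighbor_tour(D: np.ndarray, start: int) -> list[int]:
    n = D.shape[0]
    unvisited = set(range(n))
    tour = [start]
    unvisited.discard(start)
    while unvisited:
        last = tour[-1]
        nxt = min(unvisited, key=lambda j: (D[last, j], j))
        tour.append(nxt)
        unvisited.discard(nxt)
    return tour


def _two_opt(D: np.ndarray, tour: list[int]) -> list[int]:
    n = len(tour)
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            a, b = tour[i], tour[i + 1]
            for j in range(i + 2, n):
                c, d = tour[j], tour[(j + 1) % n]
                if a == d:
                    continue
                delta = D[a, c] + D[b, d] - D[a, b] - D[c, d]
                if delta < -1e-12:
                    tour[i + 1 : j + 1] = reversed(tour[i + 1 : j + 1])
                    b = tour[i + 1]
                    improved = True
    return tour


def _or_opt(D: np.ndarray, tour: list[int]) -> list[int]:
    """Relocate segments of length 1-3 while gains exist."""
    n = len(tour)
    improved = True
    while improved:
        improved = False
        for seg_len in (1, 2, 3):
            i = 0
            while i < n:
                j = i + seg_len
                if j > n:
                    break
                prev = tour[i - 1]
                nxt = tour[j % n]
                if prev in tour[i:j] or nxt in tour[i:j]:
                    i += 1
                    continue
                seg = tour[i:j]
                removal = D[prev, seg[0]] + D[seg[-1], nxt] - D[prev, nxt]
                rest = tour[:i] + tour[j:]
                best_gain, best_k = 0.0, None
                for k in range(len(rest)):
                    p, q = rest[k - 1], rest[k]
                    add = D[p, seg[0]] + D[seg[-1], q] - D[p, q]
                    gain = removal - add
                    if gain > best_gain + 1e-12:
                        best_gain, best_k = gain, k
                if best_k is not None:
                    tour = rest[:best_k] + seg + rest[best_k:]
                    improved = True
                    i = 0
                    continue
                i += 1
    return tour


def initial_order(
    matrix: DistanceMatrix,
    tsp_solver: Callable[[np.ndarray], list[int]] | None = None,
) -> list[int]:
    """Hamiltonian-path ordering minimizing the sum of adjacent distances.

    Reduces path-TSP to cyclic TSP with a zero-cost dummy node, then
    applies nearest-neighbour construction with 2-opt and Or-opt
    improvement.  ``tsp_solver`` may supply an external exact tour solver
    (given the full (n+1)-node matrix, returns a tour as a node list).
    Deterministic given input order.
    """
    n = len(matrix.scaffold_ids)
    if n <= 2:
        return list(range(n))
    full = np.zeros((n + 1, n + 1))
    full[:n, :n] = matrix.D
    if tsp_solver is not None:
        tour = list(tsp_solver(full))
    else:
        starts = [n] + list(range(0, n, max(1, n // 8)))
        best_tour: list[int] | None = None
        best_cost = float("inf")
        for start in starts:
            tour = _nearest_neighbor_tour(full, start=start)
            prev_cost = float("inf")
            cost = _tour_cost(full, tour)
            while cost < prev_cost - 1e-12:
                prev_cost = cost
                tour = _two_opt(full, tour)
                tour = _or_opt(full, tour)
                cost = _tour_cost(full, tour)
            if cost < best_cost - 1e-12:
                best_cost, best_tour = cost, tour
        tour = best_tour if best_tour is not None else list(range(n + 1))
    k = tour.index(n)
    path = tour[k + 1 :] + tour[:k]
    # canonical direction: keep the endpoint with the smaller index first
    if path[0] > path[-1]:
        path.reverse()
    return path


# ---------------------------------------------------------------------------
# Phase 2: genetic algorithm + flip refinement
# ---------------------------------------------------------------------------


Individual = tuple[list[int], list[int]]  # permutation, signs (by scaffold index)


def _pmx_signed(
    p1: list[int],
    s1: list[int],
    p2: list[int],
    s2: list[int],
    rng: np.random.Generator,
) -> tuple[Individual, Individual]:
    """Partially-mapped crossover on signed permutations.

    Each child scaffold inherits its orientation from the parent that
    contributed it (segment donor inside the cut, the other parent
    elsewhere).
    """
    n = len(p1)
    if n < 2:
        return (p1[:], s1[:]), (p2[:], s2[:])
    i, j = sorted(rng.integers(0, n, size=2))
    if i == j:
        return (p1[:], s1[:]), (p2[:], s2[:])

    def cross(a: list[int], sa: list[int], b: list[int], sb: list[int]) -> Individual:
        child = [-1] * n
        child[i:j] = a[i:j]
        placed = set(child[i:j])
        for k in range(i, j):
            v = b[k]
            if v in placed:
                continue
            pos = k
            while i <= pos < j:
                pos = b.index(a[pos])
            child[pos] = v
            placed.add(v)
        for k in range(n):
            if child[k] == -1:
                child[k] = b[k]
        segment = set(a[i:j])
        signs = [sa[v] if v in segment else sb[v] for v in range(n)]
        return child, signs

    return cross(p1, s1, p2, s2), cross(p2, s2, p1, s1)


def _pmx(p1: list[int], p2: list[int], rng: np.random.Generator) -> tuple[list[int], list[int]]:
    """Partially-mapped crossover for bare permutations."""
    ones = [1] * len(p1)
    (c1, _), (c2, _) = _pmx_signed(p1, ones, p2, list(ones), rng)
    return c1, c2


def _mutate(perm: list[int], signs: list[int], rng: np.random.Generator) -> None:
    """Apply inversion or insertion (chosen 50/50) in place.

    Inversion reverses a run of scaffolds and negates their orientations
    (reversing a block of oriented scaffolds flips each member); insertion
    relocates one scaffold, orientation unchanged.
    """
    n = len(perm)
    if n < 2:
        return
    if rng.random() < 0.5:
        i, j = sorted(rng.integers(0, n, size=2))
        perm[i : j + 1] = reversed(perm[i : j + 1])
        for k in perm[i : j + 1]:
            signs[k] = -signs[k]
    else:
        i = int(rng.integers(0, n))
        v = perm.pop(i)
        j = int(rng.integers(0, n))
        perm.insert(j, v)


def _tournament(
    pop: list[list[int]],
    fits: list[float],
    rng: np.random.Generator,
    k: int,
) -> list[int]:
    picks = rng.integers(0, len(pop), size=k)
    best = max(picks, key=lambda i: fits[i])
    return pop[best]


def _ga_order(
    scorer: ChromosomeScorer,
    perm0: list[int],
    signs0: list[int],
    params: GAParams,
    rng: np.random.Generator,
) -> tuple[list[int], list[int], float]:
    """Elitist generational GA over signed scaffold permutations."""
    cache: dict[tuple, float] = {}

    def fitness(ind: Individual) -> float:
        key = (tuple(ind[0]), tuple(ind[1]))
        f = cache.get(key)
        if f is None:
            f = scorer.score(ind[0], ind[1])
            if len(cache) > 50_000:
                cache.clear()
            cache[key] = f
        return f

    pop: list[Individual] = [(perm0[:], signs0[:]) for _ in range(params.npop)]
    best: Individual = (perm0[:], signs0[:])
    best_f = fitness(best)
    stall, gen = 0, 0
    while stall < params.window and gen < params.max_gen:
        gen += 1
        fits = [fitness(ind) for ind in pop]
        newpop: list[Individual] = [(best[0][:], best[1][:])]  # elitism of 1
        while len(newpop) < params.npop:
            p1, s1 = _tournament(pop, fits, rng, params.tournament)
            p2, s2 = _tournament(pop, fits, rng, params.tournament)
            if rng.random() < params.p_cross:
                c1, c2 = _pmx_signed(p1, s1, p2, s2, rng)
            else:
                c1, c2 = (p1[:], s1[:]), (p2[:], s2[:])
            for child in (c1, c2):
                if len(newpop) >= params.npop:
                    break
                if rng.random() < params.p_mut:
                    _mutate(child[0], child[1], rng)
                newpop.append(child)
        pop = newpop
        improved = False
        for ind in pop:
            f = fitness(ind)
            if f > best_f:
                best, best_f, improved = (ind[0][:], ind[1][:]), f, True
        stall = 0 if improved else stall + 1
    return best[0], best[1], best_f


def flip_pass(
    config: ScaffoldConfiguration,
    problem: ChromosomeProblem | MapCollection,
) -> ScaffoldConfiguration:
    """Greedy orientation refinement: flip any scaffold whose flip strictly
    increases L; sweep until a full pass makes no change.
    """
    if isinstance(problem, MapCollection):
        problem = _as_problem(problem, config.scaffold_ids)
    scorer = ChromosomeScorer(problem)
    perm = [scorer.index[sid] for sid, _ in config.entries]
    signs = [0] * len(scorer.scaffold_ids)
    for sid, o in config.entries:
        signs[scorer.index[sid]] = o
    signs, _ = _flip_signs(scorer, perm, signs)
    return ScaffoldConfiguration(
        config.chromosome_id, [(scorer.scaffold_ids[i], signs[i]) for i in perm]
    )


def _flip_signs(
    scorer: ChromosomeScorer, perm: Sequence[int], signs: list[int]
) -> tuple[list[int], float]:
    score = scorer.score(perm, signs)
    changed = True
    while changed:
        changed = False
        for i in perm:
            old = signs[i]
            signs[i] = -1 if old >= 0 else 1
            trial = scorer.score(perm, signs)
            if trial > score:
                score = trial
                changed = True
            else:
                signs[i] = old
    return signs, score


def ga_refine(
    initial: ScaffoldConfiguration,
    problem: ChromosomeProblem | MapCollection,
    params: GAParams | None = None,
) -> ScaffoldConfiguration:
    """Phase 2: alternate GA order refinement and flip passes until L
    stops improving.  The returned configuration never scores below the
    initial one (elitism), and the run is deterministic under
    ``params.seed``.
    """
    params = params or GAParams()
    if isinstance(problem, MapCollection):
        problem = _as_problem(problem, initial.scaffold_ids)
    scorer = ChromosomeScorer(problem)
    rng = np.random.default_rng(params.seed)
    perm = [scorer.index[sid] for sid, _ in initial.entries]
    signs = [1] * len(scorer.scaffold_ids)
    for sid, o in initial.entries:
        signs[scorer.index[sid]] = o if o != 0 else 1
    # polish the incoming orientations first: the eigenvector signs are
    # only globally consistent, and the GA preserves (never loses) the
    # best configuration via elitism
    signs, best_score = _flip_signs(scorer, perm, signs)
    for round_no in range(params.max_rounds):
        perm, signs, score = _ga_order(scorer, perm, signs, params, rng)
        signs, score = _flip_signs(scorer, perm, signs)
        logger.info(
            "%s: refinement round %d, L = %g",
            problem.chromosome_id,
            round_no + 1,
            score,
        )
        if score <= best_score:
            break
        best_score = score
    # canonical polarity: pivot map reads increasing where possible
    if scorer.pivot_direction(perm, signs) < 0:
        perm = perm[::-1]
        signs = [-s if s else 0 for s in signs]
    return scorer.config(perm, signs)


def order_and_orient(
    problem: ChromosomeProblem,
    params: GAParams | None = None,
    tsp_solver: Callable[[np.ndarray], list[int]] | None = None,
) -> ScaffoldConfiguration:
    """Full two-phase optimization for one chromosome."""
    params = params or GAParams()
    sids = problem.scaffold_ids
    if not sids:
        return ScaffoldConfiguration(problem.chromosome_id, [])
    if len(sids) == 1:
        scorer = ChromosomeScorer(problem)
        return scorer.config([0], [1])
    M = build_orientation_matrix(problem)
    signs = orient_by_eigenvector(M)
    D = build_distance_matrix(problem)
    perm = initial_order(D, tsp_solver=tsp_solver)
    entries = [(sids[i], int(signs[i]) if signs[i] else 1) for i in perm]
    phase1 = ScaffoldConfiguration(problem.chromosome_id, entries)
    return ga_refine(phase1, problem, params)
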