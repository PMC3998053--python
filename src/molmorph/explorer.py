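"""The iterative exploration engine.

Starting from a single root (the start molecule M_S), each iteration takes the
current candidate generation, produces a batch of one-edit morphs per
candidate, filters them by weight and synthetic accessibility, scores each
survivor by its fingerprint distance to the target M_T (averaged with the
closest decoy when decoys are present), and accepts a subset into the tree:

* survivors are sorted by distance (ties broken by canonical SMILES);
* the best ``accept_best`` (K) morphs are accepted unconditionally;
* a morph at sorted rank r > K is accepted with probability
  ``exp(-lambda * (r - K) / K)``, so acceptance decays smoothly with rank and
  reduces to plain top-K as lambda grows;
* acceptance stops once ``accept_cap`` morphs have been taken.

Accepted morphs become the next generation.  A candidate that produced no
accepted child stays in the generation with an incremented idle counter;
once idle for ``idle_threshold`` iterations it is pruned (with its subtree)
unless it lies on the lineage of the current best molecule.  Pruned molecules
enter a tabu set and are never re-admitted.  The search ends when a morph's
canonical form equals the target's (complete path), when no candidates remain
(dead), or at the iteration cap (partial path to the best molecule found).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .chem import (
    DistanceModel,
    FingerprintKind,
    MoleculeRecord,
    SimilarityCoefficient,
    canonicalize,
    fingerprint,
    similarity,
)
from .filters import FilterConfig, SyntheticAccessibilityModel, apply_filters
from .operators import (
    DEFAULT_OPERATORS,
    ElementPalette,
    MorphResult,
    OperatorKind,
    apply_operator,
    generate_morphs,
)

__all__ = [
    "TreeNode",
    "ExplorationTree",
    "ExplorationConfig",
    "MorphingPath",
    "NeighbourhoodSpec",
    "ExplorationResult",
    "init_job",
    "select_candidates",
    "iterate",
    "prune",
    "run",
    "extract_path",
    "generate_neighbourhood",
]


@dataclass
class TreeNode:
    mol: MoleculeRecord
    parent: str | None            # canonical form of parent; None for root
    op_from_parent: OperatorKind | None
    site_from_parent: object | None
    dist: float                   # distance to the target at creation
    born_iter: int
    idle_iters: int = 0
    children: set[str] = field(default_factory=set)


@dataclass
class ExplorationTree:
    nodes: dict[str, TreeNode]
    candidates: list[str]         # current generation M_i (canonical forms)
    root: str
    target: str
    best: str                     # canonical form of the minimum-dist node
    iteration: int = 0
    tabu: set[str] = field(default_factory=set)
    log: list[dict] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return self.target in self.nodes

    def best_lineage(self) -> set[str]:
        lineage: set[str] = set()
        key: str | None = self.best
        while key is not None:
            lineage.add(key)
            key = self.nodes[key].parent
        return lineage


@dataclass(frozen=True)
class ExplorationConfig:
    """All knobs of one exploration job; defaults are the engine defaults."""

    fp_kind: FingerprintKind = FingerprintKind.MORGAN
    coeff: SimilarityCoefficient = SimilarityCoefficient.TANIMOTO
    enabled_ops: frozenset[OperatorKind] = DEFAULT_OPERATORS
    palette: ElementPalette | None = None  # None -> target elements + carbon
    filters: FilterConfig = FilterConfig()
    decoys: tuple[MoleculeRecord, ...] = ()
    n_gen_per_parent: int = 80
    accept_best: int = 50
    accept_cap: int = 150
    decay: float = 1.0
    idle_threshold: int = 5
    max_iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.accept_best > self.accept_cap:
            raise ValueError("accept_best must not exceed accept_cap")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.n_gen_per_parent < 1 or self.accept_best < 1:
            raise ValueError("n_gen_per_parent and accept_best must be >= 1")


@dataclass
class MorphingPath:
    """Ordered molecule/operator sequence from the start molecule."""

    molecules: list[MoleculeRecord]
    operators: list[OperatorKind]
    complete: bool

    def __post_init__(self) -> None:
        if len(self.operators) != len(self.molecules) - 1:
            raise ValueError("a path of n molecules needs exactly n-1 operators")

    def __len__(self) -> int:
        return len(self.molecules)


@dataclass(frozen=True)
class NeighbourhoodSpec:
    """The near neighbourhood of an origin molecule: bounded in size, in
    fingerprint distance from the origin (radius) and in edit depth."""

    origin: MoleculeRecord
    max_size: int = 100
    max_radius: float = 0.5
    max_depth: int = 2

    def __post_init__(self) -> None:
        if self.max_size < 1 or self.max_depth < 0 or self.max_radius <= 0:
            raise ValueError("neighbourhood bounds must be positive")


@dataclass
class ExplorationResult:
    path: MorphingPath
    iterations_used: int
    complete: bool
    status: str                   # found | dead | capped | trivial
    tree: ExplorationTree


def _resolve_palette(cfg: ExplorationConfig, target: MoleculeRecord) -> ElementPalette:
    return cfg.palette if cfg.palette is not None else ElementPalette.from_molecules(target)


def _distance_model(cfg: ExplorationConfig, target: MoleculeRecord) -> DistanceModel:
    return DistanceModel.from_molecules(target, cfg.decoys, cfg.fp_kind, cfg.coeff)


def init_job(
    start: MoleculeRecord,
    target: MoleculeRecord,
    cfg: ExplorationConfig,
    model: DistanceModel | None = None,
) -> ExplorationTree:
    """A fresh tree: the start molecule as root, candidates = {root}."""
    start = canonicalize(start)
    target = canonicalize(target)
    model = model or _distance_model(cfg, target)
    root = TreeNode(
        mol=start, parent=None, op_from_parent=None, site_from_parent=None,
        dist=model(start), born_iter=0,
    )
    return ExplorationTree(
        nodes={start.canonical_form: root},
        candidates=[start.canonical_form],
        root=start.canonical_form,
        target=target.canonical_form,
        best=start.canonical_form,
    )


def select_candidates(
    scored: Sequence[tuple[MorphResult, float]],
    cfg: ExplorationConfig,
    rng: np.random.Generator,
) -> list[tuple[MorphResult, float]]:
    """Rank-based probabilistic selection of the next generation.

    Input must already be deduplicated against the tree.  Output preserves
    the sorted (ascending-distance) order.
    """
    ordered = sorted(scored, key=lambda item: (item[1], item[0].product.canonical_form))
    accepted: list[tuple[MorphResult, float]] = []
    k = cfg.accept_best
    for rank, item in enumerate(ordered, start=1):
        if len(accepted) >= cfg.accept_cap:
            break
        if rank <= k:
            accepted.append(item)
            continue
        p = math.exp(-cfg.decay * (rank - k) / k)
        if rng.random() < p:
            accepted.append(item)
    return accepted


def prune(tree: ExplorationTree, cfg: ExplorationConfig) -> list[str]:
    """Discard idle molecules (and their subtrees) from the exploration.

    A non-root node is removed once its idle counter reaches
    ``idle_threshold``, unless it is an ancestor of (or is) the current best
    molecule.  Removed canonical forms go into the tabu set so they are never
    re-accepted.
    """
    protected = tree.best_lineage()
    doomed_roots = [
        key
        for key, node in tree.nodes.items()
        if node.parent is not None
        and node.idle_iters >= cfg.idle_threshold
        and key not in protected
    ]
    removed: list[str] = []
    for root_key in doomed_roots:
        if root_key not in tree.nodes:  # already removed inside another subtree
            continue
        stack = [root_key]
        while stack:
            key = stack.pop()
            node = tree.nodes.pop(key, None)
            if node is None:
                continue
            removed.append(key)
            tree.tabu.add(key)
            stack.extend(node.children)
            if node.parent is not None and node.parent in tree.nodes:
                tree.nodes[node.parent].children.discard(key)
    if removed:
        gone = set(removed)
        tree.candidates = [c for c in tree.candidates if c not in gone]
    return removed


def iterate(
    tree: ExplorationTree,
    cfg: ExplorationConfig,
    model: DistanceModel,
    rng: np.random.Generator,
    palette: ElementPalette,
    sa_model: SyntheticAccessibilityModel | None = None,
) -> str:
    """Advance the tree by one generation; returns found | running | dead."""
    if tree.complete:
        return "found"

    parents = sorted(tree.candidates)
    pool: dict[str, tuple[MorphResult, float]] = {}
    n_generated = 0
    n_filtered = 0
    for parent_key in parents:
        parent = tree.nodes[parent_key].mol
        morphs = generate_morphs(
            parent, cfg.n_gen_per_parent, cfg.enabled_ops, palette, rng
        )
        n_generated += len(morphs)
        survivors, _rejected = apply_filters(morphs, cfg.filters, sa_model)
        n_filtered += len(morphs) - len(survivors)
        for morph in survivors:
            key = morph.product.canonical_form
            if key in tree.nodes or key in tree.tabu or key in pool:
                continue
            pool[key] = (morph, model(morph.product))

    accepted = select_candidates(list(pool.values()), cfg, rng)

    # Attach accepted morphs; the generating parent of each morph is recorded
    # in its provenance.
    new_generation: list[str] = []
    improved_parents: set[str] = set()
    parents_with_child: set[str] = set()
    found = False
    for morph, dist in accepted:
        key = morph.product.canonical_form
        parent_key = morph.parent_id
        node = TreeNode(
            mol=morph.product,
            parent=parent_key,
            op_from_parent=morph.operator,
            site_from_parent=morph.site,
            dist=dist,
            born_iter=tree.iteration + 1,
        )
        tree.nodes[key] = node
        tree.nodes[parent_key].children.add(key)
        new_generation.append(key)
        parents_with_child.add(parent_key)
        if dist < tree.nodes[parent_key].dist:
            improved_parents.add(parent_key)
        if dist < tree.nodes[tree.best].dist or (
            dist == tree.nodes[tree.best].dist and key < tree.best
        ):
            tree.best = key
        if key == tree.target:
            found = True

    # Idle bookkeeping: childless parents stay in the generation, one strike
    # added; an improving child resets the idle counters of its whole lineage.
    carried: list[str] = []
    for parent_key in parents:
        if parent_key not in tree.nodes:
            continue
        if parent_key in parents_with_child:
            continue
        tree.nodes[parent_key].idle_iters += 1
        carried.append(parent_key)
    for parent_key in improved_parents:
        key: str | None = parent_key
        while key is not None and key in tree.nodes:
            tree.nodes[key].idle_iters = 0
            key = tree.nodes[key].parent

    tree.candidates = sorted(set(new_generation) | set(carried))
    removed = prune(tree, cfg)
    tree.iteration += 1
    tree.log.append(
        {
            "iteration": tree.iteration,
            "candidates": len(parents),
            "generated": n_generated,
            "filtered": n_filtered,
            "accepted": len(accepted),
            "pruned": len(removed),
            "best_dist": tree.nodes[tree.best].dist,
        }
    )
    if found:
        return "found"
    if not tree.candidates:
        return "dead"
    if n_generated == 0:
        return "dead"  # no candidate admits any edit: search exhausted
    return "running"


def extract_path(tree: ExplorationTree, end: str) -> MorphingPath:
    """Follow parent links from `end` back to the root."""
    if end not in tree.nodes:
        raise KeyError(f"molecule not in tree: {end!r}")
    mols: list[MoleculeRecord] = []
    ops: list[OperatorKind] = []
    key: str | None = end
    while key is not None:
        node = tree.nodes[key]
        mols.append(node.mol)
        if node.op_from_parent is not None:
            ops.append(node.op_from_parent)
        key = node.parent
    mols.reverse()
    ops.reverse()
    return MorphingPath(molecules=mols, operators=ops, complete=end == tree.target)


def run(
    start: "MoleculeRecord | str",
    target: "MoleculeRecord | str",
    cfg: ExplorationConfig,
    sa_model: SyntheticAccessibilityModel | None = None,
) -> ExplorationResult:
    """Full exploration: iterate until the target is found, the search dies,
    or the iteration cap is reached.  Fixed seed => bit-reproducible outcome.
    """
    start = canonicalize(start)
    target = canonicalize(target)
    if start.canonical_form == target.canonical_form:
        tree = ExplorationTree(
            nodes={
                start.canonical_form: TreeNode(
                    mol=start, parent=None, op_from_parent=None,
                    site_from_parent=None, dist=0.0, born_iter=0,
                )
            },
            candidates=[start.canonical_form],
            root=start.canonical_form,
            target=target.canonical_form,
            best=start.canonical_form,
        )
        path = MorphingPath(molecules=[start], operators=[], complete=True)
        return ExplorationResult(path, 0, True, "trivial", tree)

    rng = np.random.default_rng(cfg.seed)
    palette = _resolve_palette(cfg, target)
    model = _distance_model(cfg, target)
    tree = init_job(start, target, cfg, model)
    status = "running"
    while tree.iteration < cfg.max_iterations:
        status = iterate(tree, cfg, model, rng, palette, sa_model)
        if status in ("found", "dead"):
            break
    if status == "found":
        path = extract_path(tree, tree.target)
        return ExplorationResult(path, tree.iteration, True, "found", tree)
    end = tree.best
    path = extract_path(tree, end)
    final = "dead" if status == "dead" else "capped"
    return ExplorationResult(path, tree.iteration, False, final, tree)


def generate_neighbourhood(
    spec: NeighbourhoodSpec,
    cfg: ExplorationConfig,
    rng: np.random.Generator,
) -> list[tuple[MoleculeRecord, int, float]]:
    """Breadth-first one-edit expansion around an origin molecule.

    Returns (molecule, depth, distance-to-origin) triples; the origin itself
    is excluded.  Kept molecules satisfy depth <= max_depth and
    1 - similarity(origin) <= max_radius; expansion stops at max_size.
    """
    origin = canonicalize(spec.origin)
    palette = cfg.palette if cfg.palette is not None else ElementPalette.from_molecules(origin)
    origin_fp = fingerprint(origin, cfg.fp_kind)
    kept: list[tuple[MoleculeRecord, int, float]] = []
    seen: set[str] = {origin.canonical_form}
    frontier: list[MoleculeRecord] = [origin]
    depth = 0
    while frontier and depth < spec.max_depth and len(kept) < spec.max_size:
        depth += 1
        next_frontier: list[MoleculeRecord] = []
        for mol in frontier:
            if len(kept) >= spec.max_size:
                break
            for morph in generate_morphs(
                mol, cfg.n_gen_per_parent, cfg.enabled_ops, palette, rng
            ):
                key = morph.product.canonical_form
                if key in seen:
                    continue
                seen.add(key)
                d = 1.0 - similarity(
                    fingerprint(morph.product, cfg.fp_kind), origin_fp, cfg.coeff
                )
                if d <= spec.max_radius:
                    kept.append((morph.product, depth, d))
                    next_frontier.append(morph.product)
                    if len(kept) >= spec.max_size:
                        break
        frontier = next_frontier
    return kept
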