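"""Exploration tree: selection, iteration, pruning, paths, neighbourhoods."""

import math

import numpy as np
import pytest

from molmorph.chem import DistanceModel, canonicalize, fingerprint
from molmorph.explorer import (
    ExplorationConfig,
    ExplorationTree,
    MorphingPath,
    NeighbourhoodSpec,
    TreeNode,
    extract_path,
    generate_neighbourhood,
    init_job,
    iterate,
    prune,
    run,
    select_candidates,
)
from molmorph.filters import FilterConfig
from molmorph.operators import (
    ElementPalette,
    MorphResult,
    OperatorKind,
    Site,
    apply_operator,
    enumerate_sites,
)

OK = OperatorKind

SMALL_CFG = dict(
    n_gen_per_parent=30,
    accept_best=10,
    accept_cap=20,
    filters=FilterConfig(sa_enabled=False),
    max_iterations=50,
)


def scored_list(dists):
    """Synthetic (MorphResult, dist) pairs with distinct products."""
    smiles = ["C" * (n + 1) for n in range(len(dists))]
    out = []
    for s, d in zip(smiles, dists):
        mol = canonicalize(s)
        out.append(
            (
                MorphResult(
                    product=mol, operator=OK.ADD_ATOM,
                    site=Site(OK.ADD_ATOM, (0,), "C"), parent_id="C",
                ),
                d,
            )
        )
    return out


class TestInitJob:
    def test_fresh_tree(self):
        cfg = ExplorationConfig()
        tree = init_job(canonicalize("CCO"), canonicalize("CCCN"), cfg)
        assert len(tree.nodes) == 1
        assert tree.iteration == 0
        assert tree.candidates == [tree.root]
        assert 0.0 < tree.nodes[tree.root].dist <= 1.0

    def test_identical_pair_is_trivially_complete(self):
        result = run("CCO", "OCC", ExplorationConfig())
        assert result.complete
        assert result.iterations_used == 0
        assert len(result.path) == 1 and result.path.operators == []


class TestSelectCandidates:
    def test_top_k_unconditional(self, rng):
        cfg = ExplorationConfig(accept_best=2, accept_cap=2)
        accepted = select_candidates(scored_list([0.5, 0.1, 0.3]), cfg, rng)
        assert [d for _, d in accepted] == [0.1, 0.3]

    def test_large_decay_reduces_to_top_k(self, rng):
        cfg = ExplorationConfig(accept_best=3, accept_cap=100, decay=1e9)
        accepted = select_candidates(scored_list([i / 10 for i in range(10)]), cfg, rng)
        assert len(accepted) == 3

    def test_empty_input(self, rng):
        assert select_candidates([], ExplorationConfig(), rng) == []

    def test_cap_respected_and_order_sorted(self, rng):
        cfg = ExplorationConfig(accept_best=5, accept_cap=7, decay=0.0)
        accepted = select_candidates(scored_list([i / 20 for i in range(15)]), cfg, rng)
        assert len(accepted) == 7  # decay 0 accepts every rank until the cap
        dists = [d for _, d in accepted]
        assert dists == sorted(dists)

    def test_acceptance_frequency_matches_rank_decay(self):
        # Rank K+1 is accepted with probability exp(-lambda/K).
        k, lam, trials = 5, 1.0, 10_000
        cfg = ExplorationConfig(accept_best=k, accept_cap=100, decay=lam)
        scored = scored_list([i / 10 for i in range(k + 2)])
        rng = np.random.default_rng(123)
        hits = 0
        for _ in range(trials):
            accepted = select_candidates(scored, cfg, rng)
            if any(item[1] == scored[k][1] for item in accepted):
                hits += 1
        p = math.exp(-lam / k)
        sigma = math.sqrt(p * (1 - p) / trials)
        assert abs(hits / trials - p) < 3 * sigma


class TestIterate:
    def test_one_edit_target_found_first_iteration(self):
        # target one AA edit away; n_gen exceeds the AA site count -> exhaustive
        cfg = ExplorationConfig(
            enabled_ops=frozenset({OK.ADD_ATOM}),
            palette=ElementPalette(("C", "O")),
            seed=5,
            **SMALL_CFG,
        )
        result = run("CC", "CCO", cfg)
        assert result.complete and result.iterations_used == 1

    def test_exhausted_search_is_dead(self):
        cfg = ExplorationConfig(
            enabled_ops=frozenset({OK.REMOVE_ATOM}),
            palette=ElementPalette(("C",)),
            seed=0,
            **SMALL_CFG,
        )
        result = run("C", "CCCCC", cfg)
        assert result.status == "dead" and not result.complete

    def test_iteration_counter_increments_by_one(self):
        cfg = ExplorationConfig(seed=1, **SMALL_CFG)
        start, target = canonicalize("CCO"), canonicalize("CCCCN")
        tree = init_job(start, target, cfg)
        model = DistanceModel.from_molecules(target)
        palette = ElementPalette.from_molecules(target)
        rng = np.random.default_rng(1)
        iterate(tree, cfg, model, rng, palette)
        assert tree.iteration == 1
        iterate(tree, cfg, model, rng, palette)
        assert tree.iteration == 2
        assert len(tree.log) == 2

    def test_no_molecule_appears_twice(self):
        cfg = ExplorationConfig(seed=3, **SMALL_CFG)
        result = run("CCO", "NCCc1ccccc1", cfg)
        keys = list(result.tree.nodes)
        assert len(keys) == len(set(keys))
        for key, node in result.tree.nodes.items():
            if node.parent is not None:
                assert node.parent in result.tree.nodes


def toy_tree() -> ExplorationTree:
    """root -> a -> b, plus stale branch root -> c -> d."""
    def rec(s):
        return canonicalize(s)

    nodes = {
        "ROOT": TreeNode(rec("CCO"), None, None, None, 0.9, 0),
        "A": TreeNode(rec("CCN"), "ROOT", OK.MUTATE_ATOM, None, 0.5, 1),
        "B": TreeNode(rec("CCC"), "A", OK.MUTATE_ATOM, None, 0.2, 2),
        "C": TreeNode(rec("CC=O"), "ROOT", OK.ADD_BOND, None, 0.8, 1, idle_iters=5),
        "D": TreeNode(rec("C=CO"), "C", OK.BOND_REROUTE, None, 0.85, 2),
    }
    nodes["ROOT"].children = {"A", "C"}
    nodes["A"].children = {"B"}
    nodes["C"].children = {"D"}
    return ExplorationTree(
        nodes=nodes, candidates=["B", "C", "D"], root="ROOT", target="TARGET",
        best="B",
    )


class TestPrune:
    def test_idle_branch_removed_with_subtree(self):
        tree = toy_tree()
        removed = prune(tree, ExplorationConfig(idle_threshold=5))
        assert set(removed) == {"C", "D"}
        assert "C" not in tree.nodes and "D" not in tree.nodes
        assert tree.tabu == {"C", "D"}
        assert tree.candidates == ["B"]

    def test_best_lineage_protected(self):
        tree = toy_tree()
        tree.nodes["A"].idle_iters = 99  # ancestor of best node B
        removed = prune(tree, ExplorationConfig(idle_threshold=5))
        assert "A" in tree.nodes and "B" in tree.nodes
        assert set(removed) == {"C", "D"}

    def test_root_never_removed(self):
        tree = toy_tree()
        tree.nodes["ROOT"].idle_iters = 1000
        prune(tree, ExplorationConfig(idle_threshold=5))
        assert "ROOT" in tree.nodes

    def test_below_threshold_retained(self):
        tree = toy_tree()
        tree.nodes["C"].idle_iters = 4
        assert prune(tree, ExplorationConfig(idle_threshold=5)) == []


class TestRunAndPath:
    def test_mutation_pair_converges_across_seeds(self):
        start = canonicalize("CC(=O)Nc1ccc(O)cc1")
        pal = ElementPalette.from_molecules(start)
        # target one MA edit away: O -> N on the phenol
        target = canonicalize("CC(=O)Nc1ccc(N)cc1")
        successes = 0
        for seed in range(20):
            # n_gen above the total site count -> exhaustive one-edit coverage
            cfg = ExplorationConfig(
                palette=pal, seed=seed, n_gen_per_parent=2000,
                accept_best=10, accept_cap=20,
                filters=FilterConfig(sa_enabled=False), max_iterations=5,
            )
            result = run(start, target, cfg)
            if result.complete and result.iterations_used <= 3:
                successes += 1
        assert successes >= 18

    def test_seeded_run_reproducible(self):
        cfg = ExplorationConfig(seed=11, **SMALL_CFG)
        a = run("CCO", "OCCc1ccccc1", cfg)
        b = run("CCO", "OCCc1ccccc1", cfg)
        assert sorted(a.tree.nodes) == sorted(b.tree.nodes)
        assert a.iterations_used == b.iterations_used
        assert [m.canonical_form for m in a.path.molecules] == [
            m.canonical_form for m in b.path.molecules
        ]
        assert a.tree.log == b.tree.log

    def test_extract_path_shapes(self):
        tree = toy_tree()
        path = extract_path(tree, "B")
        assert len(path.molecules) == 3 and len(path.operators) == 2
        assert extract_path(tree, "ROOT").operators == []
        with pytest.raises(KeyError):
            extract_path(tree, "missing")

    def test_complete_path_validates_step_by_step(self):
        cfg = ExplorationConfig(seed=2, **SMALL_CFG)
        result = run("CCO", "CCCO", cfg)
        assert result.complete
        path = result.path
        assert path.molecules[-1].canonical_form == result.tree.target
        # every consecutive pair reproduces under the logged operator/site
        for i in range(1, len(path.molecules)):
            node = result.tree.nodes[path.molecules[i].canonical_form]
            replay = apply_operator(
                result.tree.nodes[node.parent].mol, node.op_from_parent,
                node.site_from_parent,
            )
            assert replay.product.canonical_form == path.molecules[i].canonical_form

    def test_iteration_cap_prefix_property(self):
        # success at a low cap implies success at any higher cap (same seed)
        base = dict(SMALL_CFG)
        outcomes = {}
        for cap in (1, 2, 5, 10):
            base["max_iterations"] = cap
            cfg = ExplorationConfig(seed=4, **base)
            outcomes[cap] = run("CCO", "CCCN", cfg)
        caps = sorted(outcomes)
        for low, high in zip(caps, caps[1:]):
            if outcomes[low].complete:
                assert outcomes[high].complete
                assert outcomes[high].iterations_used == outcomes[low].iterations_used


class TestNeighbourhood:
    def test_zero_depth_is_empty(self, rng):
        spec = NeighbourhoodSpec(origin=canonicalize("CCO"), max_depth=0)
        cfg = ExplorationConfig(**SMALL_CFG)
        assert generate_neighbourhood(spec, cfg, rng) == []

    def test_radius_contract(self, rng):
        spec = NeighbourhoodSpec(
            origin=canonicalize("CC(=O)O"), max_size=40, max_radius=0.4, max_depth=2
        )
        cfg = ExplorationConfig(**SMALL_CFG)
        hood = generate_neighbourhood(spec, cfg, rng)
        assert hood
        for mol, depth, dist in hood:
            assert depth <= 2 and dist <= 0.4
            assert mol.canonical_form != spec.origin.canonical_form
        assert len(hood) <= 40

    def test_methane_single_neighbour(self, rng):
        spec = NeighbourhoodSpec(
            origin=canonicalize("C"), max_size=10, max_radius=1.0, max_depth=1
        )
        cfg = ExplorationConfig(
            enabled_ops=frozenset({OK.ADD_ATOM}),
            palette=ElementPalette(("C",)),
            **SMALL_CFG,
        )
        hood = generate_neighbourhood(spec, cfg, rng)
        assert [m.canonical_form for m, _, _ in hood] == [canonicalize("CC").canonical_form]
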