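"""Synthetic start/target pair generation for testing and benchmarking.

Real benchmark sets bin start/target pairs by fingerprint similarity; the
generators here emulate that design.  ``make_synthetic_pair`` builds a target
a known number of operator applications away from a seed molecule, so the
shortest morphing path length is bounded and convergence can be asserted.
``make_band_pairs`` instead walks away from a seed until the Morgan/Tanimoto
similarity between start and current molecule falls inside a requested band,
emulating the three similarity tiers of the benchmark datasets:
70-80% (near pairs), 50-60% (mid pairs) and 30-40% (far pairs).

The seed pool is a fixed list of small drug-like molecules (8-21 heavy atoms,
C/N/O/S chemistry) — the size regime in which single-edit morphing operators
move fingerprint similarity by a few percent per step, as in lead-like
chemical space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import (
    FingerprintKind,
    MoleculeRecord,
    SimilarityCoefficient,
    canonicalize,
    fingerprint,
    similarity,
)
from .operators import (
    DEFAULT_OPERATORS,
    ElementPalette,
    MorphResult,
    OperatorKind,
    random_morph,
)

__all__ = [
    "SEED_SMILES",
    "SIMILARITY_BANDS",
    "SyntheticPair",
    "make_synthetic_pair",
    "make_band_pairs",
    "pair_similarity",
]

#: Small drug-like seed molecules for pair generation.
SEED_SMILES: tuple[str, ...] = (
    "CC(=O)Oc1ccccc1C(=O)O",          # aspirin
    "CC(=O)Nc1ccc(O)cc1",             # paracetamol
    "Cc1ccc(cc1)S(=O)(=O)N",          # tosylamide
    "OC(=O)c1ccncc1",                 # isonicotinic acid
    "CCOC(=O)c1ccc(N)cc1",            # benzocaine
    "Nc1nc(O)c2ncn(C)c2n1",           # methylated purinol
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",     # ibuprofen
    "OCC1OC(O)C(O)C(O)C1O",           # glucose
    "c1ccc2[nH]ccc2c1",               # indole
    "CSCCC(N)C(=O)O",                 # methionine
    "Nc1ccc(cc1)S(=O)(=O)Nc1ncccn1",  # sulfadiazine core
    "OC(=O)CCc1ccccc1",               # hydrocinnamic acid
)

#: Similarity bands (fraction of Morgan/Tanimoto similarity) emulating the
#: near/mid/far benchmark tiers.
SIMILARITY_BANDS: dict[str, tuple[float, float]] = {
    "70-80": (0.70, 0.80),
    "50-60": (0.50, 0.60),
    "30-40": (0.30, 0.40),
}


@dataclass(frozen=True)
class SyntheticPair:
    start: MoleculeRecord
    target: MoleculeRecord
    trace: tuple[MorphResult, ...]
    similarity: float  # Morgan/Tanimoto start-target similarity


def pair_similarity(
    a: MoleculeRecord,
    b: MoleculeRecord,
    kind: FingerprintKind = FingerprintKind.MORGAN,
    coeff: SimilarityCoefficient = SimilarityCoefficient.TANIMOTO,
) -> float:
    return similarity(fingerprint(a, kind), fingerprint(b, kind), coeff)


def _random_walk(
    start: MoleculeRecord,
    k: int,
    enabled: frozenset[OperatorKind],
    palette: ElementPalette,
    rng: np.random.Generator,
) -> tuple[MorphResult, ...] | None:
    """k successive random edits avoiding previously visited molecules."""
    trace: list[MorphResult] = []
    visited = {start.canonical_form}
    current = start
    for _ in range(k):
        morph = None
        for _attempt in range(20):
            candidate = random_morph(current, enabled, palette, rng)
            if candidate is not None and candidate.product.canonical_form not in visited:
                morph = candidate
                break
        if morph is None:
            return None
        trace.append(morph)
        visited.add(morph.product.canonical_form)
        current = morph.product
    return tuple(trace)


def make_synthetic_pair(
    seed_mol: "MoleculeRecord | str",
    k: int,
    enabled: frozenset[OperatorKind] = DEFAULT_OPERATORS,
    palette: ElementPalette | None = None,
    rng: "np.random.Generator | int | None" = None,
    max_retries: int = 50,
) -> SyntheticPair:
    """A start/target pair separated by exactly `k` operator applications.

    The returned trace replays on the start molecule to the target's
    canonical form.  Raises when the seed molecule dead-ends before k edits in
    every retry.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    start = canonicalize(seed_mol)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    palette = palette or ElementPalette.from_molecules(start)
    for _ in range(max_retries):
        trace = _random_walk(start, k, enabled, palette, rng)
        if trace is None:
            continue
        target = trace[-1].product
        if target.canonical_form == start.canonical_form:
            continue
        return SyntheticPair(
            start=start,
            target=target,
            trace=trace,
            similarity=pair_similarity(start, target),
        )
    raise RuntimeError(f"could not build a {k}-edit pair from {start.canonical_form}")


def make_band_pairs(
    band: tuple[float, float],
    n_pairs: int,
    seed_smiles: tuple[str, ...] = SEED_SMILES,
    enabled: frozenset[OperatorKind] = DEFAULT_OPERATORS,
    rng: "np.random.Generator | int | None" = None,
    max_walk: int = 60,
    max_attempts_per_pair: int = 120,
    max_step_drop: float = 0.3,
) -> list[SyntheticPair]:
    """Start/target pairs whose Morgan/Tanimoto similarity lies in `band`.

    Each pair comes from a random walk away from a seed molecule that stops
    as soon as the running similarity to the start enters the band; walks
    that overshoot below the band are retried.  Steps that drop the running
    similarity by more than `max_step_drop` are rejected, so band membership
    reflects cumulative structural divergence over several edits (as in real
    similarity-tiered pair sets) rather than one drastic edit such as a ring
    opening: lower bands genuinely lie more operator applications away.
    """
    lo, hi = band
    if not 0 <= lo < hi <= 1:
        raise ValueError(f"invalid similarity band {band}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seeds = [canonicalize(s) for s in seed_smiles]
    pairs: list[SyntheticPair] = []
    attempts = 0
    while len(pairs) < n_pairs:
        attempts += 1
        if attempts > max_attempts_per_pair * n_pairs:
            raise RuntimeError(
                f"could not build {n_pairs} pairs in band {band} "
                f"(built {len(pairs)})"
            )
        start = seeds[int(rng.integers(len(seeds)))]
        palette = ElementPalette.from_molecules(start)
        start_fp = fingerprint(start)
        current = start
        current_sim = 1.0
        visited = {start.canonical_form}
        trace: list[MorphResult] = []
        hit = None
        for _step in range(max_walk):
            morph = random_morph(current, enabled, palette, rng)
            if morph is None or morph.product.canonical_form in visited:
                break
            sim = similarity(fingerprint(morph.product), start_fp)
            if current_sim - sim > max_step_drop or sim < lo:
                continue  # too drastic an edit, or overshot the band
            trace.append(morph)
            visited.add(morph.product.canonical_form)
            current = morph.product
            current_sim = sim
            if lo <= sim <= hi:
                hit = SyntheticPair(
                    start=start, target=current, trace=tuple(trace), similarity=sim
                )
                break
        if hit is not None:
            pairs.append(hit)
    return pairs
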