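"""Morph filtering: molecular weight cap and synthetic-accessibility score.

Morphs are screened before selection so the search does not wander into
overly heavy or practically unsynthesizable structures.  The synthetic
accessibility score (SAScore) is the fragment-contribution + complexity-penalty
estimate of Ertl & Schuffenhauer on a 1 (easy) … 10 (hard) scale; the score is
computed with RDKit's published implementation and its accompanying
fragment-frequency table, loaded once on first use.
"""

from __future__ import annotations

import importlib.util
import os
import sys
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from rdkit import Chem, RDConfig

from .chem import MoleculeRecord
from .operators import MorphResult

__all__ = [
    "FilterConfig",
    "SyntheticAccessibilityModel",
    "sa_score",
    "apply_filters",
]


@dataclass(frozen=True)
class FilterConfig:
    """Filter settings.

    mw_limit: maximum morph molecular weight in daltons (default 500 Da).
    sa_enabled: whether the synthetic-accessibility filter is applied.
    sa_threshold: maximum tolerated SAScore, on the 1-10 scale; 6 marks the
        conventional boundary beyond which a structure is considered hard to
        make.
    """

    mw_limit: float = 500.0
    sa_enabled: bool = True
    sa_threshold: float = 6.0

    def __post_init__(self) -> None:
        if self.mw_limit <= 0:
            raise ValueError("mw_limit must be positive")
        if not 1.0 <= self.sa_threshold <= 10.0:
            raise ValueError("sa_threshold must lie in [1, 10]")


def _load_sascorer():
    path = os.path.join(RDConfig.RDContribDir, "SA_Score", "sascorer.py")
    spec = importlib.util.spec_from_file_location("_rdkit_sascorer", path)
    module = importlib.util.module_from_spec(spec)
    sys.modules.setdefault("_rdkit_sascorer", module)
    spec.loader.exec_module(module)
    return module


class SyntheticAccessibilityModel:
    """Fragment-contribution synthetic accessibility scorer (1 easy - 10 hard).

    Combines a log-frequency contribution of circular fragments (how common
    each atom environment is among known synthesizable molecules) with
    penalties for size, ring complexity (fused/bridged/spiro), stereo centres
    and macrocycles.  The fragment table and formula are RDKit's published
    implementation of the score.
    """

    def __init__(self) -> None:
        self._scorer = None

    def _ensure(self):
        if self._scorer is None:
            self._scorer = _load_sascorer()
            self._scorer.readFragmentScores()
        return self._scorer

    @property
    def fragment_scores(self) -> dict:
        """Circular-fragment key -> log-frequency contribution."""
        return self._ensure()._fscores

    def score(self, mol: MoleculeRecord) -> float:
        value = float(self._ensure().calculateScore(mol.graph_handle))
        return min(10.0, max(1.0, value))


_DEFAULT_MODEL = SyntheticAccessibilityModel()


def sa_score(mol: MoleculeRecord, model: SyntheticAccessibilityModel | None = None) -> float:
    """Deterministic synthetic-accessibility score of a molecule in [1, 10]."""
    return (model or _DEFAULT_MODEL).score(mol)


def apply_filters(
    morphs: Sequence[MorphResult],
    cfg: FilterConfig,
    model: SyntheticAccessibilityModel | None = None,
) -> tuple[list[MorphResult], Counter]:
    """Screen morphs; returns (survivors in input order, rejection counts).

    A morph survives iff its weight is within `mw_limit` and, when the SA
    filter is on, its SAScore is at most `sa_threshold`.  The weight check
    runs first (it is the cheaper of the two); ordering does not change the
    survivor set.
    """
    model = model or _DEFAULT_MODEL
    survivors: list[MorphResult] = []
    rejected: Counter = Counter()
    for morph in morphs:
        if morph.product.mol_weight > cfg.mw_limit:
            rejected["mol_weight"] += 1
            continue
        if cfg.sa_enabled and model.score(morph.product) > cfg.sa_threshold:
            rejected["sa_score"] += 1
            continue
        survivors.append(morph)
    return survivors, rejected
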