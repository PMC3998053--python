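"""Structural mutation ("morphing") operators on molecular graphs.

Each operator performs one elementary edit on the heavy-atom graph of a
reactant molecule and yields a product molecule:

======  ====================  ===========================================
code    name                  edit
======  ====================  ===========================================
AA      add atom              attach a new single-bonded atom
RA      remove atom           delete a degree-1 atom
AB      add bond              new single bond, or increment an existing
                              bond's order (up to triple)
RB      remove bond           decrement a multiple bond, or delete a
                              single ring bond (connectivity preserved)
MA      mutate atom           change an atom's element
BR      bond reroute          detach one end of a bond and reattach it to
                              another atom, keeping the graph connected
BC      bond contraction      delete a degree-2 atom and bond its two
                              neighbours directly (single bond)
IA      interlay atom         insert a new atom into a single bond
                              (inverse of BC; off by default)
======  ====================  ===========================================

Operators act on the kekulized heavy-atom graph (hydrogens are implicit);
every product must satisfy standard valence rules and remain a single
connected component.  AA↔RA, AB↔RB and BC↔IA are inverse pairs; MA and BR
are self-inverse-capable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .chem import MoleculeRecord, canonicalize, record_from_mol

__all__ = [
    "OperatorKind",
    "ElementPalette",
    "Site",
    "MorphResult",
    "InapplicableSiteError",
    "enumerate_sites",
    "apply_operator",
    "random_morph",
    "generate_morphs",
    "DEFAULT_OPERATORS",
]


class OperatorKind(enum.Enum):
    ADD_ATOM = "AA"
    REMOVE_ATOM = "RA"
    ADD_BOND = "AB"
    REMOVE_BOND = "RB"
    MUTATE_ATOM = "MA"
    BOND_REROUTE = "BR"
    BOND_CONTRACTION = "BC"
    INTERLAY_ATOM = "IA"

    @property
    def code(self) -> str:
        return self.value

    @classmethod
    def from_code(cls, code: str) -> "OperatorKind":
        code = code.strip().upper()
        for kind in cls:
            if kind.value == code:
                return kind
        raise ValueError(f"unknown operator code: {code!r}")

    def __lt__(self, other: "OperatorKind") -> bool:
        return self.value < other.value


#: Operators enabled by default.  IA is implemented but off by default; it can
#: be enabled through configuration.
DEFAULT_OPERATORS: frozenset[OperatorKind] = frozenset(
    k for k in OperatorKind if k is not OperatorKind.INTERLAY_ATOM
)

_PT = Chem.GetPeriodicTable()


@dataclass(frozen=True)
class ElementPalette:
    """The pool of element symbols available to atom-introducing operators.

    Each element carries its standard maximum valence (periodic-table default
    valence).  The recommended pool is the set of elements present in the
    target molecule plus carbon, which biases mutation chemistry toward the
    target without a hand-tuned list.
    """

    elements: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("element palette must not be empty")
        seen = []
        for sym in self.elements:
            if _PT.GetAtomicNumber(sym) == 0:
                raise ValueError(f"unknown element symbol: {sym!r}")
            if sym not in seen:
                seen.append(sym)
        object.__setattr__(self, "elements", tuple(seen))

    @staticmethod
    def max_valence(symbol: str) -> int:
        v = _PT.GetDefaultValence(_PT.GetAtomicNumber(symbol))
        return v if v >= 0 else 4

    @classmethod
    def from_molecules(cls, *mols: MoleculeRecord) -> "ElementPalette":
        symbols: list[str] = ["C"]
        for mol in mols:
            for sym, _ in mol.element_multiset:
                if sym not in symbols:
                    symbols.append(sym)
        return cls(tuple(sorted(symbols)))

    def __iter__(self):
        return iter(self.elements)

    def __contains__(self, sym: str) -> bool:
        return sym in self.elements


DEFAULT_PALETTE = ElementPalette(("C", "N", "O", "S"))


@dataclass(frozen=True, order=True)
class Site:
    """Where an operator acts: atom/bond indices in the parent, plus an
    element symbol for atom-introducing or mutating edits.

    ``atoms`` are indices into the parent's canonical atom order.  The textual
    form (``str(site)``, e.g. ``"AA@3:N"`` or ``"BR@0-2->5"``) is what appears
    in logs and provenance records.
    """

    op: OperatorKind
    atoms: tuple[int, ...]
    element: str | None = None

    def __str__(self) -> str:
        if self.op is OperatorKind.BOND_REROUTE:
            u, v, w = self.atoms
            body = f"{u}-{v}->{w}"
        else:
            body = "-".join(str(i) for i in self.atoms)
        if self.element is not None:
            body += f":{self.element}"
        return f"{self.op.code}@{body}"


@dataclass(frozen=True)
class MorphResult:
    """Product of one operator application, with provenance."""

    product: MoleculeRecord
    operator: OperatorKind
    site: Site
    parent_id: str  # canonical form of the parent


class InapplicableSiteError(ValueError):
    """The requested site is not applicable to the molecule."""


# ---------------------------------------------------------------------------
# site enumeration
# ---------------------------------------------------------------------------

def _kekulized(mol: Chem.Mol) -> Chem.RWMol:
    rw = Chem.RWMol(mol)
    Chem.Kekulize(rw, clearAromaticFlags=True)
    return rw


def _free_valence(atom: Chem.Atom) -> int:
    # Implicit+explicit hydrogens = spare valence on the heavy-atom graph.
    if atom.GetFormalCharge() != 0:
        return 0  # edits never touch charged centres
    return atom.GetTotalNumHs()


def _bond_order(bond: Chem.Bond) -> int:
    return int(round(bond.GetBondTypeAsDouble()))


def _bond_order_sum(atom: Chem.Atom) -> int:
    return sum(_bond_order(b) for b in atom.GetBonds())


def _component_after_cut(mol: Chem.Mol, u: int, v: int, start: int) -> set[int]:
    """Atoms reachable from `start` when bond u-v is removed."""
    seen = {start}
    stack = [start]
    while stack:
        a = stack.pop()
        for nb in mol.GetAtomWithIdx(a).GetNeighbors():
            i = nb.GetIdx()
            if {a, i} == {u, v}:
                continue
            if i not in seen:
                seen.add(i)
                stack.append(i)
    return seen


def _reroute_is_noop(mol: MoleculeRecord, site: Site) -> bool:
    rw = _kekulized(mol.graph_handle)
    try:
        _apply_edit(rw, OperatorKind.BOND_REROUTE, site)
        for atom in rw.GetAtoms():
            atom.SetNumExplicitHs(0)
            atom.SetNoImplicit(False)
        product = rw.GetMol()
        Chem.SanitizeMol(product)
    except Exception:
        return True  # unusable site: treat as inapplicable
    return Chem.MolToSmiles(product) == mol.canonical_form


def enumerate_sites(
    mol: MoleculeRecord,
    op: OperatorKind,
    palette: ElementPalette = DEFAULT_PALETTE,
) -> list[Site]:
    """All sites where `op` applies without violating valence or connectivity.

    An empty list signals that the operator is inapplicable to this molecule.
    Sites are returned in a deterministic order (canonical atom indices).
    """
    m = _kekulized(mol.graph_handle)
    n = m.GetNumAtoms()
    sites: list[Site] = []

    if op is OperatorKind.ADD_ATOM:
        for atom in m.GetAtoms():
            if _free_valence(atom) >= 1:
                for el in palette:
                    sites.append(Site(op, (atom.GetIdx(),), el))

    elif op is OperatorKind.REMOVE_ATOM:
        if n >= 2:
            for atom in m.GetAtoms():
                if atom.GetDegree() == 1:
                    sites.append(Site(op, (atom.GetIdx(),)))

    elif op is OperatorKind.ADD_BOND:
        for i in range(n):
            ai = m.GetAtomWithIdx(i)
            if _free_valence(ai) < 1:
                continue
            for j in range(i + 1, n):
                aj = m.GetAtomWithIdx(j)
                if _free_valence(aj) < 1:
                    continue
                bond = m.GetBondBetweenAtoms(i, j)
                if bond is None or _bond_order(bond) < 3:
                    sites.append(Site(op, (i, j)))

    elif op is OperatorKind.REMOVE_BOND:
        for bond in m.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            i, j = min(i, j), max(i, j)
            if _bond_order(bond) >= 2:
                sites.append(Site(op, (i, j)))
            elif bond.IsInRing():
                sites.append(Site(op, (i, j)))

    elif op is OperatorKind.MUTATE_ATOM:
        for atom in m.GetAtoms():
            if atom.GetFormalCharge() != 0:
                continue
            order_sum = _bond_order_sum(atom)
            for el in palette:
                if el == atom.GetSymbol():
                    continue
                if ElementPalette.max_valence(el) >= max(order_sum, 1):
                    sites.append(Site(op, (atom.GetIdx(),), el))

    elif op is OperatorKind.BOND_REROUTE:
        for bond in m.GetBonds():
            order = _bond_order(bond)
            for u, v in (
                (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()),
                (bond.GetEndAtomIdx(), bond.GetBeginAtomIdx()),
            ):
                # v is the moving end: cut u-v, rebond v to w.
                reachable_from_u = _component_after_cut(m, u, v, u)
                v_side = v not in reachable_from_u
                v_neighbors = {nb.GetIdx() for nb in m.GetAtomWithIdx(v).GetNeighbors()}
                for w in range(n):
                    if w in (u, v) or w in v_neighbors:
                        continue
                    aw = m.GetAtomWithIdx(w)
                    if _free_valence(aw) < order:
                        continue
                    # Connectivity: if the cut bond is a bridge, w must lie on
                    # u's side so that reattaching v spans the cut.
                    if v_side and w not in reachable_from_u:
                        continue
                    site = Site(op, (u, v, w))
                    # Rerouting is the one edit that preserves both formula and
                    # bond multiset, so a symmetric molecule can map the
                    # product back onto the parent; verify by application.
                    if _reroute_is_noop(mol, site):
                        continue
                    sites.append(site)

    elif op is OperatorKind.BOND_CONTRACTION:
        for atom in m.GetAtoms():
            if atom.GetDegree() != 2 or n < 3:
                continue
            nb1, nb2 = [nb.GetIdx() for nb in atom.GetNeighbors()]
            if m.GetBondBetweenAtoms(nb1, nb2) is None:
                sites.append(Site(op, (atom.GetIdx(),)))

    elif op is OperatorKind.INTERLAY_ATOM:
        for bond in m.GetBonds():
            if _bond_order(bond) != 1:
                continue
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            i, j = min(i, j), max(i, j)
            for el in palette:
                if ElementPalette.max_valence(el) >= 2:
                    sites.append(Site(op, (i, j), el))

    else:  # pragma: no cover
        raise ValueError(f"unhandled operator {op}")

    return sites


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def _apply_edit(rw: Chem.RWMol, op: OperatorKind, site: Site) -> None:
    atoms = site.atoms
    if op is OperatorKind.ADD_ATOM:
        (i,) = atoms
        new = rw.AddAtom(Chem.Atom(site.element))
        rw.AddBond(i, new, Chem.BondType.SINGLE)
    elif op is OperatorKind.REMOVE_ATOM:
        (i,) = atoms
        rw.RemoveAtom(i)
    elif op is OperatorKind.ADD_BOND:
        i, j = atoms
        bond = rw.GetBondBetweenAtoms(i, j)
        if bond is None:
            rw.AddBond(i, j, Chem.BondType.SINGLE)
        else:
            bond.SetBondType(_BOND_TYPES[_bond_order(bond) + 1])
    elif op is OperatorKind.REMOVE_BOND:
        i, j = atoms
        bond = rw.GetBondBetweenAtoms(i, j)
        if bond is None:
            raise InapplicableSiteError(f"no bond {i}-{j}")
        order = _bond_order(bond)
        if order >= 2:
            bond.SetBondType(_BOND_TYPES[order - 1])
        else:
            rw.RemoveBond(i, j)
    elif op is OperatorKind.MUTATE_ATOM:
        (i,) = atoms
        atom = rw.GetAtomWithIdx(i)
        atom.SetAtomicNum(_PT.GetAtomicNumber(site.element))
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(False)
    elif op is OperatorKind.BOND_REROUTE:
        u, v, w = atoms
        bond = rw.GetBondBetweenAtoms(u, v)
        if bond is None:
            raise InapplicableSiteError(f"no bond {u}-{v}")
        order = _bond_order(bond)
        rw.RemoveBond(u, v)
        rw.AddBond(v, w, _BOND_TYPES[order])
    elif op is OperatorKind.BOND_CONTRACTION:
        (i,) = atoms
        nbrs = [nb.GetIdx() for nb in rw.GetAtomWithIdx(i).GetNeighbors()]
        if len(nbrs) != 2:
            raise InapplicableSiteError(f"atom {i} is not degree-2")
        rw.AddBond(nbrs[0], nbrs[1], Chem.BondType.SINGLE)
        rw.RemoveAtom(i)
    elif op is OperatorKind.INTERLAY_ATOM:
        i, j = atoms
        if rw.GetBondBetweenAtoms(i, j) is None:
            raise InapplicableSiteError(f"no bond {i}-{j}")
        rw.RemoveBond(i, j)
        new = rw.AddAtom(Chem.Atom(site.element))
        rw.AddBond(i, new, Chem.BondType.SINGLE)
        rw.AddBond(new, j, Chem.BondType.SINGLE)
    else:  # pragma: no cover
        raise ValueError(f"unhandled operator {op}")


def apply_operator(mol: MoleculeRecord, op: OperatorKind, site: Site) -> MorphResult:
    """Apply one operator at the given site, returning a valid product.

    The parent record is left untouched.  Raises
    :class:`InapplicableSiteError` when the site cannot be applied or the
    product fails valence/connectivity validation.
    """
    if site.op is not op:
        raise InapplicableSiteError(f"site {site} is for {site.op.code}, not {op.code}")
    rw = _kekulized(mol.graph_handle)
    try:
        _apply_edit(rw, op, site)
        for atom in rw.GetAtoms():
            atom.SetNumExplicitHs(0)
            atom.SetNoImplicit(False)
        product = rw.GetMol()
        Chem.SanitizeMol(product)
    except InapplicableSiteError:
        raise
    except Exception as exc:
        raise InapplicableSiteError(f"site {site} invalid on {mol.canonical_form}: {exc}") from exc
    if product.GetNumAtoms() == 0:
        raise InapplicableSiteError(f"site {site} would delete the whole molecule")
    record = record_from_mol(product)  # raises on disconnection
    if record.canonical_form == mol.canonical_form:
        raise InapplicableSiteError(f"site {site} is a no-op on {mol.canonical_form}")
    return MorphResult(product=record, operator=op, site=site, parent_id=mol.canonical_form)


# ---------------------------------------------------------------------------
# randomized generation
# ---------------------------------------------------------------------------

def random_morph(
    mol: MoleculeRecord,
    enabled: Iterable[OperatorKind],
    palette: ElementPalette,
    rng: np.random.Generator,
    max_retries: int = 10,
) -> MorphResult | None:
    """One random edit: operator uniform over `enabled`, site uniform over its
    sites.  Returns ``None`` (never raises) when no enabled operator applies.
    """
    ops = sorted(set(enabled))
    if not ops:
        raise ValueError("enabled operator set must not be empty")
    site_cache: dict[OperatorKind, list[Site]] = {}

    def sites_of(op: OperatorKind) -> list[Site]:
        if op not in site_cache:
            site_cache[op] = enumerate_sites(mol, op, palette)
        return site_cache[op]

    for _ in range(max_retries):
        op = ops[int(rng.integers(len(ops)))]
        sites = sites_of(op)
        if not sites:
            continue
        site = sites[int(rng.integers(len(sites)))]
        try:
            return apply_operator(mol, op, site)
        except InapplicableSiteError:  # pragma: no cover - defensive
            continue
    # Retries exhausted: fail only if genuinely no operator applies.
    for op in ops:
        sites = sites_of(op)
        while sites:
            k = int(rng.integers(len(sites)))
            site = sites.pop(k)
            try:
                return apply_operator(mol, op, site)
            except InapplicableSiteError:  # pragma: no cover - defensive
                continue
    return None


def generate_morphs(
    parent: MoleculeRecord,
    n_gen: int,
    enabled: Iterable[OperatorKind],
    palette: ElementPalette,
    rng: np.random.Generator,
) -> list[MorphResult]:
    """Generate up to `n_gen` distinct morphs of `parent`.

    Products are deduplicated by canonical form and the parent itself is
    excluded.  When `n_gen` is at least the number of applicable
    (operator, site) pairs the batch is exhaustive — every distinct one-edit
    product is returned; otherwise edits are sampled (operator uniform over
    the enabled kinds that have sites, then site uniform within the operator).
    """
    if n_gen < 1:
        raise ValueError("n_gen must be >= 1")
    ops = sorted(set(enabled))
    if not ops:
        raise ValueError("enabled operator set must not be empty")
    per_op: dict[OperatorKind, list[Site]] = {
        op: enumerate_sites(parent, op, palette) for op in ops
    }
    per_op = {op: s for op, s in per_op.items() if s}
    if not per_op:
        return []
    total = sum(len(s) for s in per_op.values())

    chosen: list[tuple[OperatorKind, Site]]
    if total <= n_gen:
        chosen = [(op, s) for op in sorted(per_op) for s in per_op[op]]
    else:
        live_ops = sorted(per_op)
        picked: set[tuple[OperatorKind, Site]] = set()
        chosen = []
        for _ in range(n_gen):
            op = live_ops[int(rng.integers(len(live_ops)))]
            sites = per_op[op]
            site = sites[int(rng.integers(len(sites)))]
            key = (op, site)
            if key not in picked:
                picked.add(key)
                chosen.append(key)

    results: list[MorphResult] = []
    seen: set[str] = {parent.canonical_form}
    for op, site in chosen:
        try:
            morph = apply_operator(parent, op, site)
        except InapplicableSiteError:  # pragma: no cover - enumeration is exact
            continue
        if morph.product.canonical_form in seen:
            continue
        seen.add(morph.product.canonical_form)
        results.append(morph)
    return results
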