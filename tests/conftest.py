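import numpy as np
import pytest

from molmorph import (
    DEFAULT_OPERATORS,
    ElementPalette,
    MoleculeRecord,
    canonicalize,
    random_morph,
)


@pytest.fixture
def palette() -> ElementPalette:
    return ElementPalette(("C", "N", "O"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def grow_random_molecule(
    rng: np.random.Generator,
    max_heavy: int = 20,
    n_edits: int = 8,
    palette: ElementPalette | None = None,
) -> MoleculeRecord:
    """A random small organic molecule built by successive random edits on ethane."""
    palette = palette or ElementPalette(("C", "N", "O", "S"))
    mol = canonicalize("CC")
    for _ in range(n_edits):
        morph = random_morph(mol, DEFAULT_OPERATORS, palette, rng)
        if morph is None:
            break
        if morph.product.num_heavy_atoms > max_heavy:
            continue
        mol = morph.product
    return mol


@pytest.fixture
def random_molecules(rng) -> list[MoleculeRecord]:
    """A reproducible pool of 30 random small molecules."""
    return [grow_random_molecule(rng) for _ in range(30)]
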