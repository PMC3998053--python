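"""File formats: SDF molecules, SMILES+ID pair files, JSON job files.

Pair files follow the two-line dialect used for benchmark sets: each line is
``<SMILES> <ID>``; odd lines hold start structures and each start's target is
on the following line, so the file must have an even number of lines.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import (
    FingerprintKind,
    MoleculeRecord,
    MoleculeError,
    SimilarityCoefficient,
    canonicalize,
    record_from_mol,
)
from .explorer import ExplorationConfig
from .filters import FilterConfig
from .operators import ElementPalette, OperatorKind

__all__ = [
    "read_sdf",
    "write_sdf",
    "BenchmarkPairSet",
    "read_pairs",
    "write_pairs",
    "JobFile",
    "read_job",
]


def read_sdf(path: "str | Path", lenient: bool = False) -> list[MoleculeRecord]:
    """Read V2000/V3000 SDF records.

    In fail-fast mode (default) a malformed record raises an error naming its
    1-based index; with ``lenient=True`` bad records are skipped with a
    warning.  Record titles (or the ``_Name`` property) become labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        return []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    records: list[MoleculeRecord] = []
    for index, mol in enumerate(supplier, start=1):
        if mol is None:
            if lenient:
                warnings.warn(f"skipping malformed SDF record {index} in {path}")
                continue
            raise MoleculeError(f"malformed SDF record {index} in {path}")
        label = mol.GetProp("_Name") if mol.HasProp("_Name") else None
        records.append(record_from_mol(mol, label=label or None))
    return records


def write_sdf(mols: Sequence[MoleculeRecord], path: "str | Path") -> None:
    """Write molecules as a V2000 SDF; labels become record titles."""
    writer = Chem.SDWriter(str(path))
    try:
        for mol in mols:
            m = Chem.Mol(mol.graph_handle)
            m.SetProp("_Name", mol.label or mol.canonical_form)
            AllChem.Compute2DCoords(m)
            writer.write(m)
    finally:
        writer.close()


@dataclass
class BenchmarkPairSet:
    """Start/target molecule pairs plus the dialect tag of their source."""

    pairs: list[tuple[MoleculeRecord, MoleculeRecord]]
    dialect: str = "smiles-id-pairs"

    def __len__(self) -> int:
        return len(self.pairs)


def read_pairs(path: "str | Path") -> BenchmarkPairSet:
    """Parse a SMILES+ID pair file (odd line = start, next line = its target)."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) % 2 != 0:
        raise ValueError(
            f"pair file {path} has an odd number of structure lines ({len(lines)})"
        )
    mols: list[MoleculeRecord] = []
    for lineno, line in enumerate(lines, start=1):
        parts = line.split()
        smiles = parts[0]
        label = parts[1] if len(parts) > 1 else None
        try:
            mols.append(canonicalize(smiles, label=label))
        except MoleculeError as exc:
            raise MoleculeError(f"{path}, line {lineno}: {exc}") from exc
    pairs = [(mols[2 * k], mols[2 * k + 1]) for k in range(len(mols) // 2)]
    return BenchmarkPairSet(pairs=pairs)


def write_pairs(pairs: Iterable[tuple[MoleculeRecord, MoleculeRecord]], path: "str | Path") -> None:
    lines = []
    for k, (start, target) in enumerate(pairs, start=1):
        lines.append(f"{start.canonical_form} {start.label or f'start-{k}'}")
        lines.append(f"{target.canonical_form} {target.label or f'target-{k}'}")
    Path(path).write_text("\n".join(lines) + "\n")


_KNOWN_JOB_KEYS = {
    "start", "target", "decoys", "fingerprint", "coefficient", "operators",
    "mw_limit", "sa_enabled", "sa_threshold", "n_gen_per_parent",
    "accept_best", "accept_cap", "decay", "idle_threshold", "max_iterations",
    "seed", "palette", "output_dir",
}


@dataclass
class JobFile:
    """A parsed flat key/value job configuration."""

    start: MoleculeRecord
    target: MoleculeRecord
    config: ExplorationConfig
    output_dir: Path


def _structure_from_ref(ref, base: Path) -> MoleculeRecord:
    """A structure reference: a SMILES string, or {"sdf": path, "name": label}."""
    if isinstance(ref, str):
        return canonicalize(ref)
    sdf_path = base / ref["sdf"]
    records = read_sdf(sdf_path)
    name = ref.get("name")
    if name is None:
        return records[0]
    for record in records:
        if record.label == name:
            return record
    raise KeyError(f"no record named {name!r} in {sdf_path}")


def read_job(path: "str | Path") -> JobFile:
    """Read a JSON job file; unknown keys are rejected with a warning."""
    path = Path(path)
    data = json.loads(path.read_text())
    unknown = set(data) - _KNOWN_JOB_KEYS
    if unknown:
        warnings.warn(f"ignoring unknown job keys in {path}: {sorted(unknown)}")
    base = path.parent
    start = _structure_from_ref(data["start"], base)
    target = _structure_from_ref(data["target"], base)
    decoys = tuple(_structure_from_ref(d, base) for d in data.get("decoys", []))
    filters = FilterConfig(
        mw_limit=float(data.get("mw_limit", 500.0)),
        sa_enabled=bool(data.get("sa_enabled", True)),
        sa_threshold=float(data.get("sa_threshold", 6.0)),
    )
    palette = None
    if "palette" in data:
        palette = ElementPalette(tuple(data["palette"]))
    kwargs = dict(
        fp_kind=FingerprintKind.from_name(data.get("fingerprint", "morgan")),
        coeff=SimilarityCoefficient.from_name(data.get("coefficient", "tanimoto")),
        filters=filters,
        decoys=decoys,
        palette=palette,
    )
    if "operators" in data:
        kwargs["enabled_ops"] = frozenset(
            OperatorKind.from_code(c) for c in data["operators"]
        )
    for key in ("n_gen_per_parent", "accept_best", "accept_cap", "idle_threshold",
                "max_iterations", "seed"):
        if key in data:
            kwargs[key] = int(data[key])
    if "decay" in data:
        kwargs["decay"] = float(data["decay"])
    cfg = ExplorationConfig(**kwargs)
    out = Path(data.get("output_dir", "."))
    if not out.is_absolute():
        out = base / out
    return JobFile(start=start, target=target, config=cfg, output_dir=out)
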