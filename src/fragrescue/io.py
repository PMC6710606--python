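"""Readers and writers for fragment libraries and screen reports.

Canonical on-disk library schema (CSV or TSV, header required)::

    fragment_id, pocket_id, smiles, n_heavy, affinity_value, affinity_kind

``smiles`` and ``n_heavy`` are individually optional but at least one must be
present (and they must agree when both are).  ``affinity_kind`` is one of
``kd_M``, ``kd_nM``, ``kd_uM`` (dissociation constants, converted to ΔG at
parse time) or ``dg_kcal_mol`` (signed free energy taken as-is).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Iterable

import pandas as pd
from rdkit import Chem

from .errors import (
    ConsistencyError,
    InvalidInputError,
    SchemaError,
    SmilesParseError,
)
from .metrics import Fragment, ThermoParams, delta_g_from_kd, heavy_atom_count
from .screen import Combination, PocketLibrary, ScreenConfig, ScreenResult

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("fragment_id", "pocket_id", "affinity_value", "affinity_kind")
OPTIONAL_COLUMNS = ("smiles", "n_heavy")

#: Multiplier to molar for each Kd affinity kind.
KD_SCALE = {"kd_M": 1.0, "kd_nM": 1e-9, "kd_uM": 1e-6}
AFFINITY_KINDS = tuple(KD_SCALE) + ("dg_kcal_mol",)


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or (
        isinstance(value, str) and value.strip() == ""
    )


def _row_to_fragment(row: pd.Series, line: int, params: ThermoParams) -> Fragment:
    kind = str(row["affinity_kind"]).strip()
    if kind not in AFFINITY_KINDS:
        raise SchemaError(
            f"line {line}: unknown affinity_kind {kind!r} (expected one of {AFFINITY_KINDS})"
        )
    try:
        value = float(row["affinity_value"])
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"line {line}: affinity_value {row['affinity_value']!r} is not a number") from exc
    if kind in KD_SCALE:
        if value <= 0:
            raise InvalidInputError(f"line {line}: Kd must be > 0, got {value}")
        delta_g = delta_g_from_kd(value * KD_SCALE[kind], params)
    else:
        delta_g = value

    smiles = None if "smiles" not in row or _is_missing(row.get("smiles")) else str(row["smiles"]).strip()
    n_heavy_raw = None if "n_heavy" not in row or _is_missing(row.get("n_heavy")) else row["n_heavy"]
    if smiles is None and n_heavy_raw is None:
        raise SchemaError(f"line {line}: need smiles and/or n_heavy")

    if smiles is not None:
        try:
            n_from_smiles = heavy_atom_count(smiles)
        except SmilesParseError as exc:
            raise SmilesParseError(f"line {line}: {exc}") from exc
    if n_heavy_raw is not None:
        n_heavy = int(float(n_heavy_raw))
        if smiles is not None and n_heavy != n_from_smiles:
            raise ConsistencyError(
                f"line {line}: fragment {row['fragment_id']!r} declares n_heavy={n_heavy} "
                f"but SMILES {smiles!r} has {n_from_smiles} heavy atoms"
            )
    else:
        n_heavy = n_from_smiles

    return Fragment(
        fragment_id=str(row["fragment_id"]).strip(),
        pocket_id=str(row["pocket_id"]).strip(),
        delta_g=delta_g,
        n_heavy=n_heavy,
        smiles=smiles,
    )


def read_library(path: str | Path, params: ThermoParams | None = None) -> PocketLibrary:
    """Read a fragment library table (comma or tab delimited, sniffed).

    Kd affinities are converted to signed ΔG (kcal/mol) at the given
    temperature; rows become validated :class:`~fragrescue.metrics.Fragment`
    objects in file order.  Duplicate ``(pocket_id, fragment_id)`` pairs are
    rejected.
    """
    if params is None:
        params = ThermoParams()
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    fragments = [
        _row_to_fragment(row, line=idx + 2, params=params)  # +2: header + 1-based
        for idx, row in df.iterrows()
    ]
    return PocketLibrary.from_fragments(fragments, target_id=path.stem)


def write_library(library: PocketLibrary, path: str | Path) -> None:
    """Write a library in the canonical schema (ΔG stored as ``dg_kcal_mol``, full precision)."""
    rows = [
        {
            "fragment_id": f.fragment_id,
            "pocket_id": f.pocket_id,
            "smiles": f.smiles if f.smiles is not None else "",
            "n_heavy": f.n_heavy,
            "affinity_value": repr(f.delta_g),
            "affinity_kind": "dg_kcal_mol",
        }
        for f in library.fragments()
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS[:2]) + list(OPTIONAL_COLUMNS) + list(REQUIRED_COLUMNS[2:])).to_csv(
        path, index=False
    )


def read_sdf_fragments(
    path: str | Path,
    pocket_field: str = "pocket_id",
    params: ThermoParams | None = None,
) -> list[Fragment]:
    """Load fragments from an SDF (MDL V2000) file.

    Each record must carry the pocket property and an affinity: either the
    ``affinity_value`` + ``affinity_kind`` pair, or a single property named
    after the kind (``dg_kcal_mol``, ``kd_M``, ``kd_nM``, ``kd_uM``) holding
    the value.  Heavy atoms are counted from the connection table.  Records
    with problems are skipped with a logged summary; the rest are loaded.
    """
    if params is None:
        params = ThermoParams()
    path = Path(path)
    if path.read_text().strip() == "":
        logger.warning("%s: empty SDF, no fragments loaded", path.name)
        return []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    fragments: list[Fragment] = []
    failures: list[str] = []
    n_records = 0
    for i, mol in enumerate(supplier):
        n_records += 1
        if mol is None:
            failures.append(f"record {i + 1}: unparseable molecule")
            continue
        props = mol.GetPropsAsDict()
        if pocket_field not in props:
            failures.append(f"record {i + 1}: missing pocket property {pocket_field!r}")
            continue
        try:
            delta_g = _sdf_affinity(props, params)
        except (SchemaError, InvalidInputError) as exc:
            failures.append(f"record {i + 1}: {exc}")
            continue
        fragment_id = str(props.get("fragment_id", "")) or (
            mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"record{i + 1}"
        )
        fragments.append(
            Fragment(
                fragment_id=fragment_id,
                pocket_id=str(props[pocket_field]),
                delta_g=delta_g,
                n_heavy=mol.GetNumHeavyAtoms(),
                smiles=Chem.MolToSmiles(mol),
            )
        )
    if failures:
        logger.warning(
            "%s: skipped %d of %d records: %s", path.name, len(failures), n_records, "; ".join(failures)
        )
    return fragments


def _sdf_affinity(props: dict, params: ThermoParams) -> float:
    if "affinity_value" in props and "affinity_kind" in props:
        kind = str(props["affinity_kind"])
        value = float(props["affinity_value"])
    else:
        for kind in AFFINITY_KINDS:
            if kind in props:
                value = float(props[kind])
                break
        else:
            raise SchemaError("no affinity property found")
    if kind not in AFFINITY_KINDS:
        raise SchemaError(f"unknown affinity_kind {kind!r}")
    if kind in KD_SCALE:
        if value <= 0:
            raise InvalidInputError(f"Kd must be > 0, got {value}")
        return delta_g_from_kd(value * KD_SCALE[kind], params)
    return value


# ---------------------------------------------------------------------------
# Screen reports


def result_to_dict(result: ScreenResult) -> dict:
    """JSON-serializable view of a screen result (the report format)."""
    config = dataclasses.asdict(result.config)
    config["mode"] = result.config.mode.value
    return {
        "config": config,
        "accepted": [
            {
                "fragments": {f.pocket_id: f.fragment_id for f in combo.fragments},
                "le_t_app": combo.le_t_app.value,
                "mode": combo.le_t_app.mode.value,
                "rescued_fragment_ids": list(combo.rescued_fragment_ids),
            }
            for combo in result.accepted
        ],
        "classification": dict(result.classification),
        "counts": dict(result.counts),
        "search": {
            "combinations_evaluated": result.n_evaluated,
            "branches_pruned": result.n_pruned_branches,
            "total_combinations": result.n_total_combinations,
        },
    }


def write_report(result: ScreenResult, path: str | Path, format: str = "csv") -> None:
    """Write a screen result as CSV (accepted combinations) or JSON (full report).

    CSV columns: one per pocket (the chosen fragment id), ``le_t_app`` at six
    decimal places, and the semicolon-joined rescued fragment keys.  The JSON
    report round-trips through :func:`read_report` to an equal dictionary.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(result_to_dict(result), indent=2) + "\n")
        return
    if format != "csv":
        raise InvalidInputError(f"unknown report format {format!r}")
    pocket_ids = [f.pocket_id for f in result.accepted[0].fragments] if result.accepted else []
    rows = []
    for combo in result.accepted:
        row = {f.pocket_id: f.fragment_id for f in combo.fragments}
        row["le_t_app"] = f"{combo.le_t_app.value:.6f}"
        row["rescued_fragment_ids"] = ";".join(combo.rescued_fragment_ids)
        rows.append(row)
    columns = pocket_ids + ["le_t_app", "rescued_fragment_ids"]
    if not rows:
        # Header-only CSV: pocket columns are unknown without accepted combos.
        columns = ["le_t_app", "rescued_fragment_ids"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_report(path: str | Path) -> dict:
    """Read back a JSON screen report as the dictionary :func:`result_to_dict` produced."""
    return json.loads(Path(path).read_text())
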