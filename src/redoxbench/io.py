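"""Delimited readers/writers and flat-file configuration.

The interchange format is plain comma-separated UTF-8. Energy tables use
the columns::

    complex_id, oxidation_state, multiplicity, method, basis_label,
    e_hf, e_corr, unit

with ``unit`` one of ``hartree`` / ``kcal_per_mol`` and ``basis_label``
either a correlation-consistent label (``aug-cc-pVTZ``) or a bare cardinal
number. Reference tables carry ``complex_id, delta_e_kcal, scheme,
correction_basis``; prediction tables carry ``functional, complex_id,
delta_e_kcal``. Energies are written at full precision, no locale
formatting.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .composite import ReferenceValue
from .extrapolation import DEFAULT_ALPHA, DEFAULT_BETA, ExtrapolationParams, HfCbsMode
from .model import (
    DEFAULT_S2_TOLERANCE,
    BasisLevel,
    ComponentEnergy,
    EnergyRecord,
    EnergyTable,
    LIGAND_CHARGES,
    OxState,
    SpeciesState,
)
from .units import Quantity, Unit

ENERGY_COLUMNS = ("complex_id", "oxidation_state", "multiplicity", "method",
                  "basis_label", "e_hf", "e_corr", "unit")
_ENERGY_UNITS = {Unit.HARTREE.value, Unit.KCAL_PER_MOL.value}


class TableFormatError(ValueError):
    """Malformed delimited input; message lists every bad row with its line."""


def read_energy_table(path: str | os.PathLike) -> EnergyTable:
    """Read and validate an energy-table CSV.

    All malformed rows are reported at once, each with its file line
    number (header is line 1). Duplicate (species, method, basis) keys are
    rejected.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ENERGY_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s) {missing}; "
            f"expected {list(ENERGY_COLUMNS)}"
        )
    table = EnergyTable()
    problems: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            unit = row["unit"].strip()
            if unit not in _ENERGY_UNITS:
                raise ValueError(f"unknown unit {unit!r} "
                                 f"(expected one of {sorted(_ENERGY_UNITS)})")
            basis = BasisLevel.from_label(row["basis_label"])
            complex_id = row["complex_id"].strip()
            species = SpeciesState(
                complex_id=complex_id,
                oxidation_state=OxState(row["oxidation_state"].strip()),
                spin_multiplicity=int(row["multiplicity"]),
                ligand_charge_sum=LIGAND_CHARGES.get(complex_id, 0),
            )
            energy = ComponentEnergy(
                hf=Quantity(float(row["e_hf"]), Unit(unit)),
                corr=Quantity(float(row["e_corr"]), Unit(unit)),
            )
            table.add(EnergyRecord(species, row["method"].strip(), basis, energy))
        except (ValueError, KeyError) as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise TableFormatError(
            f"{path}: {len(problems)} malformed row(s):\n  " + "\n  ".join(problems)
        )
    return table


def write_energy_table(table: EnergyTable, path: str | os.PathLike) -> None:
    rows = [
        {
            "complex_id": rec.species.complex_id,
            "oxidation_state": rec.species.oxidation_state.value,
            "multiplicity": rec.species.spin_multiplicity,
            "method": rec.method,
            "basis_label": rec.basis.label,
            "e_hf": repr(rec.energy.hf.value),
            "e_corr": repr(rec.energy.corr.value),
            "unit": rec.energy.unit.value,
        }
        for rec in table
    ]
    pd.DataFrame(rows, columns=list(ENERGY_COLUMNS)).to_csv(path, index=False)


def write_reference_table(references: Iterable[ReferenceValue],
                          path: str | os.PathLike) -> None:
    rows = [
        {
            "complex_id": ref.complex_id,
            "delta_e_kcal": repr(ref.delta_e.value),
            "scheme": ref.scheme.value,
            "correction_basis": ref.correction_basis.cardinal,
        }
        for ref in references
    ]
    pd.DataFrame(
        rows, columns=["complex_id", "delta_e_kcal", "scheme", "correction_basis"]
    ).to_csv(path, index=False)


def read_reference_table(path: str | os.PathLike) -> dict[str, float]:
    """References as {complex_id: delta_e_kcal}."""
    df = pd.read_csv(path)
    for col in ("complex_id", "delta_e_kcal"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    dupes = df["complex_id"][df["complex_id"].duplicated()].tolist()
    if dupes:
        raise TableFormatError(f"{path}: duplicate complex id(s) {dupes}")
    return dict(zip(df["complex_id"], df["delta_e_kcal"].astype(float)))


def write_predictions(predictions: Mapping[str, Mapping[str, float]],
                      path: str | os.PathLike) -> None:
    rows = [
        {"functional": f, "complex_id": cid, "delta_e_kcal": repr(float(v))}
        for f, per in predictions.items() for cid, v in per.items()
    ]
    pd.DataFrame(
        rows, columns=["functional", "complex_id", "delta_e_kcal"]
    ).to_csv(path, index=False)


def read_predictions(path: str | os.PathLike) -> dict[str, dict[str, float]]:
    """Predictions as {functional: {complex_id: delta_e_kcal}}."""
    df = pd.read_csv(path)
    for col in ("functional", "complex_id", "delta_e_kcal"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    dupes = df.duplicated(subset=["functional", "complex_id"])
    if dupes.any():
        bad = df.loc[dupes, ["functional", "complex_id"]].values.tolist()
        raise TableFormatError(f"{path}: duplicate (functional, complex) rows {bad}")
    out: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["functional"], {})[row["complex_id"]] = float(
            row["delta_e_kcal"])
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "alpha": DEFAULT_ALPHA,
    "beta": DEFAULT_BETA,
    "hf_cbs_mode": HfCbsMode.EXPONENTIAL.value,
    "group1_volts": 0.1,
    "group2_volts": 0.2,
    "rounded_thresholds": False,
    "s2_tolerance": DEFAULT_S2_TOLERANCE,
}


def load_config(path: str | os.PathLike | None = None,
                overrides: Mapping[str, object] | None = None) -> dict:
    """Defaults, overlaid by a flat YAML file, overlaid by explicit overrides.

    Unknown keys are rejected (a typo in a scheme parameter must not pass
    silently).
    """
    config = dict(DEFAULT_CONFIG)
    for source_name, source in (("config file", _read_yaml(path)),
                                ("overrides", overrides or {})):
        for key, value in source.items():
            if key not in DEFAULT_CONFIG:
                raise KeyError(
                    f"unknown configuration key {key!r} in {source_name}; "
                    f"known keys: {sorted(DEFAULT_CONFIG)}"
                )
            if value is not None:
                config[key] = value
    return config


def _read_yaml(path) -> dict:
    if path is None:
        return {}
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise TableFormatError(f"{path}: config must be a flat key-value mapping")
    return data


def extrapolation_params(config: Mapping[str, object]) -> ExtrapolationParams:
    return ExtrapolationParams(
        alpha=float(config["alpha"]),
        beta=float(config["beta"]),
        hf_cbs_mode=HfCbsMode(config["hf_cbs_mode"]),
    )
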