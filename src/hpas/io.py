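"""Dataset bundle plus SDF/CSV readers and writers.

A dataset is a file pair: an SDF holding one connection table per molecule
(name in the title line) and a CSV holding one row per molecule and charge
state with the structural and electronic property columns.  Two column
names contain spaces (``lumo + 1``, ``homo - 1``); they are reproduced
verbatim.  Output ordering is canonical (rows by name then charge, known
columns in schema order), so re-serializing an unmodified bundle is
byte-identical.  ``.gz`` paths are compressed transparently and gzipped
inputs are auto-detected from their magic bytes.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .annotator import BLOCK_COLUMN_ORDER, ELEMENTS, DescriptorRow
from .energetics import EnergyRecord, adiabatic_ea, adiabatic_ip, homo_lumo_gap
from .enumerator import MoleculeRecord
from .errors import ContractError, SchemaError

logger = logging.getLogger(__name__)

#: Structural descriptor columns, in schema order.
STRUCTURAL_COLUMNS = (
    "name",
    "charge",
    "formula",
    "inchi",
    "smiles",
    "rings",
    "aromatic_rings",
    "atoms",
    "heteroatoms",
    "heterocycles",
    "branch",
    *BLOCK_COLUMN_ORDER,
    *ELEMENTS,
)

#: Electronic property columns, in schema order (note the spaces in the
#: secondary-orbital column names).
PROPERTY_COLUMNS = (
    "homo",
    "lumo",
    "lumo + 1",
    "homo - 1",
    "gap",
    "zero_point_energy",
    "dispersion",
    "energy",
    "aip",
    "aea",
    "dipole",
    "homo_corr",
    "lumo_corr",
    "gap_corr",
    "energy_corr",
    "aip_corr",
    "aea_corr",
    "rmsd",
)

CSV_COLUMN_ORDER = (*STRUCTURAL_COLUMNS, *PROPERTY_COLUMNS)

REQUIRED_COLUMNS = ("name", "charge", "inchi", "smiles")

#: Extra provenance column: semicolon-joined building-block sequence.
BLOCKS_COLUMN = "blocks"


def format_dipole(vector) -> str:
    """Three-component dipole as one semicolon-joined CSV cell."""
    x, y, z = (float(v) for v in vector)
    return f"{x!r};{y!r};{z!r}"


def parse_dipole(cell: str) -> tuple[float, float, float]:
    parts = str(cell).split(";")
    if len(parts) != 3:
        raise ContractError(f"malformed dipole cell {cell!r}")
    return tuple(float(p) for p in parts)  # type: ignore[return-value]


@dataclass
class DatasetBundle:
    """Aligned record/descriptor/property tables plus provenance metadata.

    ``descriptors`` has one row per molecule; ``properties`` (optional) has
    one row per molecule and charge state, with exactly one neutral row per
    molecule.  All tables are keyed by the 9-character ``name``.
    """

    records: list[MoleculeRecord]
    descriptors: pd.DataFrame
    properties: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise ContractError("duplicate record names")
        if "name" not in self.descriptors.columns:
            raise ContractError("descriptor table lacks a 'name' column")
        if sorted(self.descriptors["name"]) != sorted(names):
            raise ContractError("descriptor names do not align with records")
        if self.properties is not None:
            if not {"name", "charge"}.issubset(self.properties.columns):
                raise ContractError("property table needs 'name' and 'charge'")
            unknown = set(self.properties["name"]) - set(names)
            if unknown:
                raise ContractError(f"property rows for unknown names: {sorted(unknown)[:5]}")
            neutral = self.properties[self.properties["charge"] == 0]
            counts = neutral.groupby("name").size()
            if sorted(counts.index) != sorted(names) or (counts != 1).any():
                raise ContractError("need exactly one neutral property row per record")


def property_rows(
    name: str, by_charge: dict[int, EnergyRecord]
) -> list[dict]:
    """CSV-ready rows for one molecule's charge states.

    Gap/AIP/AEA are attached to the neutral row only; the charged rows carry
    their own orbital energies and total energy.
    """
    if 0 not in by_charge:
        raise ContractError(f"molecule {name!r} lacks a neutral record")
    rows = []
    neutral = by_charge[0]
    for charge in sorted(by_charge):
        rec = by_charge[charge]
        row = {
            "name": name,
            "charge": charge,
            "homo": rec.homo,
            "lumo": rec.lumo,
            "lumo + 1": rec.lumo_plus1,
            "homo - 1": rec.homo_minus1,
            "zero_point_energy": rec.zpe,
            "dispersion": rec.dispersion,
            "energy": rec.e_tot,
        }
        if charge == 0:
            row["gap"] = homo_lumo_gap(rec)
            if 1 in by_charge:
                row["aip"] = adiabatic_ip(neutral, by_charge[1])
            if -1 in by_charge:
                row["aea"] = adiabatic_ea(neutral, by_charge[-1])
        rows.append(row)
    return rows


def _ordered_columns(frame: pd.DataFrame) -> list[str]:
    known = [c for c in CSV_COLUMN_ORDER if c in frame.columns]
    extras = [c for c in frame.columns if c not in CSV_COLUMN_ORDER]
    return known + extras


def _merged_frame(bundle: DatasetBundle) -> pd.DataFrame:
    descriptors = bundle.descriptors.copy()
    provenance = {
        r.name: ";".join(r.block_sequence)
        for r in bundle.records
        if r.block_sequence
    }
    if provenance and BLOCKS_COLUMN not in descriptors.columns:
        descriptors[BLOCKS_COLUMN] = descriptors["name"].map(provenance)
    if bundle.properties is None:
        frame = descriptors
        if "charge" not in frame.columns:
            frame["charge"] = 0
    else:
        structural = descriptors.drop(
            columns=[c for c in ("charge",) if c in descriptors.columns]
        )
        frame = bundle.properties.merge(structural, on="name", how="left")
    frame = frame[_ordered_columns(frame)]
    sort_cols = ["name"] + (["charge"] if "charge" in frame.columns else [])
    return frame.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)


def write_dataset(bundle: DatasetBundle, sdf_path, csv_path) -> None:
    """Write the SDF/CSV file pair; ``.gz`` suffixes enable compression.

    The SDF carries a 2D connection table per record (title line = name)
    whose property fields mirror that molecule's neutral CSV row, so the SDF
    is self-contained.  Raises before touching any file when the bundle
    tables are misaligned.
    """
    bundle.validate()
    frame = _merged_frame(bundle)
    csv_path, sdf_path = Path(csv_path), Path(sdf_path)
    frame.to_csv(csv_path, index=False)

    neutral = frame[frame["charge"] == 0].set_index("name")
    opener = gzip.open if sdf_path.suffix == ".gz" else open
    with opener(sdf_path, "wt", encoding="utf-8") as fh:
        writer = Chem.SDWriter(fh)
        try:
            for record in sorted(bundle.records, key=lambda r: r.name):
                mol = record.mol()
                AllChem.Compute2DCoords(mol)
                mol.SetProp("_Name", record.name)
                for column, value in neutral.loc[record.name].items():
                    if value is None or (isinstance(value, float) and np.isnan(value)):
                        continue
                    mol.SetProp(column, str(value))
                writer.write(mol)
        finally:
            writer.close()


def _is_gzip(path: Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def read_dataset(sdf_path, csv_path) -> DatasetBundle:
    """Read a file pair back into a bundle (inverse of :func:`write_dataset`).

    Unknown extra CSV columns are preserved as opaque descriptor columns.
    Gzipped inputs are detected from their magic bytes regardless of suffix.
    """
    sdf_path, csv_path = Path(sdf_path), Path(csv_path)
    compression = "gzip" if _is_gzip(csv_path) else None
    frame = pd.read_csv(csv_path, compression=compression, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(missing)

    neutral = frame[frame["charge"] == 0]
    records = []
    for _, row in neutral.iterrows():
        blocks = None
        if BLOCKS_COLUMN in row and isinstance(row[BLOCKS_COLUMN], str):
            blocks = tuple(row[BLOCKS_COLUMN].split(";"))
        n_rings = int(row["rings"]) if "rings" in row else (len(blocks) if blocks else 0)
        records.append(
            MoleculeRecord(
                name=row["name"],
                smiles=row["smiles"],
                inchi=row["inchi"],
                block_sequence=blocks,
                n_rings=n_rings,
            )
        )

    property_cols = [c for c in PROPERTY_COLUMNS if c in frame.columns]
    structural_cols = [c for c in frame.columns if c not in property_cols]
    descriptors = neutral[structural_cols].drop(columns=["charge"]).reset_index(drop=True)
    properties = None
    if property_cols:
        properties = frame[["name", "charge", *property_cols]].reset_index(drop=True)

    # count SDF entries so a truncated geometry file is caught early
    opener = gzip.open if _is_gzip(sdf_path) else open
    with opener(sdf_path, "rt", encoding="utf-8") as fh:
        n_sdf = sum(1 for line in fh if line.strip() == "$$$$")
    if n_sdf != len(records):
        logger.warning(
            "SDF holds %d molecules but CSV has %d records", n_sdf, len(records)
        )

    bundle = DatasetBundle(
        records=records, descriptors=descriptors, properties=properties
    )
    bundle.validate()
    return bundle


def descriptor_frame(rows: list[DescriptorRow]) -> pd.DataFrame:
    """Stack descriptor rows into the structural half of the CSV schema."""
    return pd.DataFrame([r.as_dict() for r in rows])
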