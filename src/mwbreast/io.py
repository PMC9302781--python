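"""File formats and the clinical roster.

* S21 containers: HDF5 with datasets ``/s21``, ``/frequencies``,
  ``/receiver_azimuths`` and the geometry stored as root attributes, plus a
  plain CSV export (columns n, m, p, f_hz, re, im).
* Intensity maps: 32-bit float TIFF or plain-text CSV matrix, each with a
  JSON sidecar carrying the grid axes and labels.
* Segmentation masks: 8-bit multi-page TIFF (one page per iteration);
  regions as CSV.
* Roster: CSV mirroring the study table (61 breasts from 35 patients);
  a packaged transcription ships with the library.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, fields as dataclass_fields
from importlib import resources
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

from .geometry import AcquisitionGeometry
from .recon import IntensityMap
from .simulate import S21Dataset

__all__ = [
    "RosterRecord",
    "RosterFormatError",
    "read_roster",
    "load_packaged_roster",
    "roster_stats",
    "write_s21",
    "read_s21",
    "s21_to_csv",
    "write_map",
    "read_map",
    "write_mask_stack",
    "regions_to_csv",
]

#: Cell values treated as explicit missing markers in the roster.
_MISSING = {"", "-", "–", "—", "not available", "n/a", "na"}


class RosterFormatError(ValueError):
    pass


@dataclass(frozen=True)
class RosterRecord:
    """One examined breast of the clinical roster."""

    breast_index: int
    patient_index: int
    age: int
    side: str  # "L" or "R"
    breast_type: str  # "NF" or "WF"
    inclusion_position: str | None  # "Upper Zone", "Lower Zone", "More Areas"
    inclusion_dimension: str | None
    final_assessment: str | None  # "Benign" or "Malignant"


_ROSTER_COLUMNS = [f.name for f in dataclass_fields(RosterRecord)]


def _norm_cell(value: object) -> str | None:
    s = str(value).strip()
    return None if s.lower() in _MISSING else s


def read_roster(path) -> list[RosterRecord]:
    """Parse a roster CSV into validated records.

    Em-dash and "Not Available" cells are normalized to ``None``.  Raises
    :class:`RosterFormatError` naming the offending row for a missing
    column, a duplicate breast index, or an unparseable age.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = set(_ROSTER_COLUMNS) - set(df.columns)
    if missing:
        raise RosterFormatError(f"missing roster columns: {sorted(missing)}")
    records: list[RosterRecord] = []
    seen: set[int] = set()
    for i, row in df.iterrows():
        rownum = i + 2  # header is line 1
        try:
            breast_index = int(row["breast_index"])
            patient_index = int(row["patient_index"])
        except ValueError as exc:
            raise RosterFormatError(f"row {rownum}: bad index ({exc})") from None
        if breast_index in seen:
            raise RosterFormatError(f"row {rownum}: duplicate breast index {breast_index}")
        seen.add(breast_index)
        try:
            age = int(row["age"])
        except ValueError:
            raise RosterFormatError(
                f"row {rownum}: unparseable age {row['age']!r}"
            ) from None
        if not 18 <= age <= 100:
            raise RosterFormatError(f"row {rownum}: age {age} outside [18, 100]")
        btype = row["breast_type"].strip()
        if btype not in {"NF", "WF"}:
            raise RosterFormatError(f"row {rownum}: unknown breast type {btype!r}")
        records.append(
            RosterRecord(
                breast_index=breast_index,
                patient_index=patient_index,
                age=age,
                side=row["side"].strip(),
                breast_type=btype,
                inclusion_position=_norm_cell(row["inclusion_position"]),
                inclusion_dimension=_norm_cell(row["inclusion_dimension"]),
                final_assessment=_norm_cell(row["final_assessment"]),
            )
        )
    return records


def load_packaged_roster() -> list[RosterRecord]:
    """The packaged roster transcription (61 breasts, 35 patients)."""
    ref = resources.files("mwbreast").joinpath("data/roster.csv")
    with resources.as_file(ref) as path:
        return read_roster(path)


def roster_stats(records: Sequence[RosterRecord]) -> dict:
    """Cohort summary: totals, age bands, mean age, malignant count.

    The age bands follow the study summary labels (20-49 and 50-80 years)
    but count roster *rows* (breasts): the published band counts sum to the
    number of breasts, not patients.
    """
    if not records:
        raise RosterFormatError("empty roster")
    ages = np.array([r.age for r in records])
    return {
        "n_breasts": len(records),
        "n_patients": len({r.patient_index for r in records}),
        "mean_age": int(round(float(ages.mean()))),
        "age_20_49": int(np.sum((ages >= 20) & (ages <= 49))),
        "age_50_80": int(np.sum((ages >= 50) & (ages <= 80))),
        "n_malignant": sum(r.final_assessment == "Malignant" for r in records),
        "n_benign": sum(r.final_assessment == "Benign" for r in records),
        "n_wf": sum(r.breast_type == "WF" for r in records),
        "n_nf": sum(r.breast_type == "NF" for r in records),
    }


# ---------------------------------------------------------------------------
# S21 containers
# ---------------------------------------------------------------------------

_GEOM_SCALARS = (
    "receiver_radius", "tx_radius", "n_receivers", "receiver_step",
    "doublet_offset", "freq_start", "freq_stop", "freq_step",
)


def write_s21(dataset: S21Dataset, path) -> None:
    g = dataset.geometry
    with h5py.File(path, "w") as h5:
        h5.create_dataset("s21", data=dataset.values)
        h5.create_dataset("frequencies", data=g.frequencies)
        h5.create_dataset("receiver_azimuths", data=g.receiver_azimuths)
        for name in _GEOM_SCALARS:
            h5.attrs[name] = getattr(g, name)
        h5.attrs["section_centers"] = np.asarray(g.section_centers)


def read_s21(path) -> S21Dataset:
    with h5py.File(path, "r") as h5:
        values = h5["s21"][()]
        kwargs = {name: h5.attrs[name] for name in _GEOM_SCALARS}
        kwargs["n_receivers"] = int(kwargs["n_receivers"])
        kwargs["section_centers"] = tuple(float(a) for a in h5.attrs["section_centers"])
        geometry = AcquisitionGeometry(**kwargs)
    return S21Dataset(values=values, geometry=geometry)


def s21_to_csv(dataset: S21Dataset, path) -> None:
    """Plain tabular export: one row per (receiver, section, doublet, freq)."""
    freqs = dataset.geometry.frequencies
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["n", "m", "p", "f_hz", "re", "im"])
        v = dataset.values
        for n in range(v.shape[0]):
            for m in range(v.shape[1]):
                for p in range(v.shape[2]):
                    for i, f in enumerate(freqs):
                        z = v[n, m, p, i]
                        writer.writerow(
                            [n, m, p, f"{f:.0f}", repr(float(z.real)),
                             repr(float(z.imag))]
                        )


# ---------------------------------------------------------------------------
# Intensity maps and masks
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_map(imap: IntensityMap, path) -> None:
    """Write a map as float32 TIFF (.tif) or CSV matrix, plus JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, imap.values.astype(np.float32))
    else:
        np.savetxt(path, imap.values, delimiter=",")
    meta = {
        "kind": imap.kind,
        "grid_radius": imap.grid_radius,
        "conductivity_label": imap.conductivity_label,
        "breast_id": imap.breast_id,
        "rho": None if imap.rho is None else list(map(float, imap.rho)),
        "phi": None if imap.phi is None else list(map(float, imap.phi)),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_map(path) -> IntensityMap:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        values = tifffile.imread(path).astype(np.float64)
    else:
        values = np.loadtxt(path, delimiter=",")
    meta = json.loads(_sidecar_path(path).read_text())
    return IntensityMap(
        values=values,
        kind=meta["kind"],
        grid_radius=meta["grid_radius"],
        rho=None if meta["rho"] is None else np.asarray(meta["rho"]),
        phi=None if meta["phi"] is None else np.asarray(meta["phi"]),
        conductivity_label=meta["conductivity_label"],
        breast_id=meta["breast_id"],
    )


def write_mask_stack(masks: Sequence[np.ndarray], path) -> None:
    """8-bit TIFF stack, one page per PCNN iteration (0/255)."""
    stack = np.stack([np.asarray(m, dtype=np.uint8) * 255 for m in masks])
    tifffile.imwrite(path, stack, photometric="minisblack")


def regions_to_csv(regions, path) -> None:
    rows = [
        {
            "region_id": i + 1,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
            "area_px": r.area,
            "zone": r.zone,
        }
        for i, r in enumerate(regions)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
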