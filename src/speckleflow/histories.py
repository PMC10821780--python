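"""Photon-history tables: the contract between photon transport and the
correlation forward models.

A table holds one row per *detected* photon with, for each tissue
category, the partial pathlength ``L`` (cm) and the dimensionless
momentum transfer ``Y`` accumulated in that tissue, plus the detector the
photon exited into.  Two on-disk encodings are supported: a
tab-separated text format with a ``#``-prefixed metadata header (human
readable, used for small fixtures) and an HDF5 layout with the same
field names (for large runs).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["DetectorSpec", "PhotonHistoryTable", "write_history_table", "read_history_table"]


@dataclass(frozen=True)
class DetectorSpec:
    """One detector of a transport run: annular ring at ``sds_mm`` of
    half-width ``radius_mm``, accepting exit angles within ``na`` (measured
    in the exit medium)."""

    detector_id: int
    sds_mm: float
    radius_mm: float = 0.5
    na: float = 1.0


class SchemaError(ValueError):
    """A history table or file violates the table schema."""


@dataclass
class PhotonHistoryTable:
    """Per-detected-photon partial pathlengths and momentum transfer.

    Attributes
    ----------
    n_launched : int
        Photons launched by the generating simulation.
    tissue_labels : tuple of str
        Ordered tissue categories; columns of ``L`` and ``Y``.
    wavelength_nm : float
    detectors : tuple of DetectorSpec
    detector_id : ndarray of int, shape (Np,)
    L : ndarray, shape (Np, Nt)
        Partial pathlength per tissue (cm).
    Y : ndarray, shape (Np, Nt)
        Dimensionless momentum transfer per tissue.
    source : str
        Free-form provenance tag (e.g. "layered_mc seed=7").
    """

    n_launched: int
    tissue_labels: tuple
    wavelength_nm: float
    detectors: tuple
    detector_id: np.ndarray
    L: np.ndarray
    Y: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.tissue_labels = tuple(self.tissue_labels)
        self.detectors = tuple(self.detectors)
        self.detector_id = np.asarray(self.detector_id, dtype=np.int64)
        self.L = np.asarray(self.L, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.validate()

    def validate(self) -> None:
        nt = len(self.tissue_labels)
        np_rows = self.detector_id.shape[0]
        if self.L.shape != (np_rows, nt) or self.Y.shape != (np_rows, nt):
            raise SchemaError(
                f"L/Y shape mismatch: expected ({np_rows}, {nt}), "
                f"got L {self.L.shape}, Y {self.Y.shape}"
            )
        bad = np.flatnonzero(np.any(self.L < 0, axis=1) | np.any(self.Y < 0, axis=1))
        if bad.size:
            raise SchemaError(f"negative pathlength or momentum transfer at row {bad[0]}")
        ids = {d.detector_id for d in self.detectors}
        unknown = np.setdiff1d(np.unique(self.detector_id), sorted(ids))
        if unknown.size:
            raise SchemaError(f"detector_id {unknown[0]} not declared in detector table")
        if self.n_launched < np_rows:
            raise SchemaError("n_launched smaller than number of detected photons")

    @property
    def n_detected(self) -> int:
        return int(self.detector_id.shape[0])

    def detector(self, detector_id: int) -> DetectorSpec:
        for d in self.detectors:
            if d.detector_id == detector_id:
                return d
        raise KeyError(f"no detector with id {detector_id}")

    def select(self, detector_id: int | None = None):
        """Return (L, Y) rows for one detector (or all rows if the table
        has a single detector and ``detector_id`` is None)."""
        if detector_id is None:
            if len(self.detectors) > 1:
                raise ValueError("table has several detectors; pass detector_id")
            return self.L, self.Y
        mask = self.detector_id == detector_id
        return self.L[mask], self.Y[mask]


def write_history_table(table: PhotonHistoryTable, path, fmt: str | None = None) -> None:
    """Write a table to ``path`` as TSV (``.tsv``/``.txt``) or HDF5
    (``.h5``/``.hdf5``); ``fmt`` overrides extension sniffing."""
    path = Path(path)
    fmt = fmt or ("hdf5" if path.suffix in (".h5", ".hdf5") else "tsv")
    if fmt == "tsv":
        _write_tsv(table, path)
    elif fmt == "hdf5":
        _write_hdf5(table, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_history_table(path, fmt: str | None = None) -> PhotonHistoryTable:
    """Read a table written by :func:`write_history_table`; validates the
    schema and raises :class:`SchemaError` on malformed content."""
    path = Path(path)
    fmt = fmt or ("hdf5" if path.suffix in (".h5", ".hdf5") else "tsv")
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "hdf5":
        return _read_hdf5(path)
    raise ValueError(f"unknown format {fmt!r}")


# -- TSV encoding -----------------------------------------------------------

def _write_tsv(table: PhotonHistoryTable, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_launched\t{table.n_launched}\n")
        fh.write(f"# wavelength_nm\t{table.wavelength_nm!r}\n")
        fh.write("# tissue_labels\t" + "\t".join(table.tissue_labels) + "\n")
        if table.source:
            fh.write(f"# source\t{table.source}\n")
        for d in table.detectors:
            fh.write(f"# detector\t{d.detector_id}\t{d.sds_mm!r}\t{d.radius_mm!r}\t{d.na!r}\n")
        cols = ["detector_id"]
        cols += [f"L_{t}_cm" for t in table.tissue_labels]
        cols += [f"Y_{t}" for t in table.tissue_labels]
        fh.write("\t".join(cols) + "\n")
        data = np.column_stack([table.detector_id.astype(float), table.L, table.Y])
        np.savetxt(fh, data, delimiter="\t", fmt="%.17g")


def _read_tsv(path: Path) -> PhotonHistoryTable:
    meta = {"detectors": []}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            header_lines += 1
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                key = parts[0]
                if key == "detector":
                    meta["detectors"].append(
                        DetectorSpec(int(parts[1]), float(parts[2]), float(parts[3]), float(parts[4]))
                    )
                else:
                    meta[key] = parts[1:]
            else:
                columns = line.strip().split("\t")
                break
        else:
            raise SchemaError(f"{path}: no column header line found")
        body = fh.read()

    for required in ("n_launched", "wavelength_nm", "tissue_labels"):
        if required not in meta:
            raise SchemaError(f"{path}: missing metadata line '# {required}'")
    labels = tuple(meta["tissue_labels"])
    expected = (["detector_id"] + [f"L_{t}_cm" for t in labels] + [f"Y_{t}" for t in labels])
    if columns != expected:
        raise SchemaError(f"{path}: column header {columns} != expected {expected}")

    data = np.loadtxt(io.StringIO(body), delimiter="\t", ndmin=2)
    if data.size == 0:
        data = data.reshape(0, len(expected))
    nt = len(labels)
    try:
        return PhotonHistoryTable(
            n_launched=int(meta["n_launched"][0]),
            tissue_labels=labels,
            wavelength_nm=float(meta["wavelength_nm"][0]),
            detectors=tuple(meta["detectors"]),
            detector_id=data[:, 0].astype(np.int64),
            L=data[:, 1:1 + nt],
            Y=data[:, 1 + nt:1 + 2 * nt],
            source=(meta.get("source") or [""])[0],
        )
    except SchemaError as err:
        raise SchemaError(f"{path}: {err}") from err


# -- HDF5 encoding ----------------------------------------------------------

def _write_hdf5(table: PhotonHistoryTable, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["n_launched"] = table.n_launched
        f.attrs["wavelength_nm"] = table.wavelength_nm
        f.attrs["tissue_labels"] = list(table.tissue_labels)
        f.attrs["source"] = table.source
        det = np.array(
            [(d.detector_id, d.sds_mm, d.radius_mm, d.na) for d in table.detectors],
            dtype=[("detector_id", "i8"), ("sds_mm", "f8"), ("radius_mm", "f8"), ("na", "f8")],
        )
        f.create_dataset("detectors", data=det)
        f.create_dataset("detector_id", data=table.detector_id)
        f.create_dataset("L", data=table.L)
        f.create_dataset("Y", data=table.Y)


def _read_hdf5(path: Path) -> PhotonHistoryTable:
    import h5py

    with h5py.File(path, "r") as f:
        det = f["detectors"][()]
        detectors = tuple(
            DetectorSpec(int(r["detector_id"]), float(r["sds_mm"]), float(r["radius_mm"]), float(r["na"]))
            for r in det
        )
        try:
            return PhotonHistoryTable(
                n_launched=int(f.attrs["n_launched"]),
                tissue_labels=tuple(str(t) for t in f.attrs["tissue_labels"]),
                wavelength_nm=float(f.attrs["wavelength_nm"]),
                detectors=detectors,
                detector_id=f["detector_id"][()],
                L=f["L"][()],
                Y=f["Y"][()],
                source=str(f.attrs.get("source", "")),
            )
        except SchemaError as err:
            raise SchemaError(f"{path}: {err}") from err
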