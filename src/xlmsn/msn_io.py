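"""MS^n spectrum container and MGF round-trip I/O.

The MGF dialect carries the MS2->MS3 scan lineage in the TITLE line as
``scan=<id> parent=<id> level=<n>`` (``parent`` omitted for MS2 scans
without a recorded survey parent).  Everything else is standard MGF, so
the files open in any viewer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from pyteomics import mgf as _mgf

__all__ = ["MSnSpectrum", "write_mgf", "read_mgf"]


@dataclass
class MSnSpectrum:
    scan_id: int
    ms_level: int
    precursor_mz: float
    precursor_z: int
    peaks: list[tuple[float, float]]  # (m/z, intensity), sorted by m/z
    parent_scan: int | None = None

    def __post_init__(self) -> None:
        if self.ms_level not in (1, 2, 3):
            raise ValueError(f"ms_level must be 1-3, got {self.ms_level}")
        if self.ms_level == 3 and self.parent_scan is None:
            raise ValueError("MS3 spectrum requires a parent MS2 scan id")
        self.peaks = sorted(self.peaks)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])


_TITLE_RE = re.compile(
    r"scan=(?P<scan>\d+)(?:\s+parent=(?P<parent>\d+))?\s+level=(?P<level>\d)")


def write_mgf(spectra: Sequence[MSnSpectrum], path: str | Path) -> None:
    """Write spectra to MGF, lineage encoded in TITLE."""
    entries = []
    for s in spectra:
        title = f"scan={s.scan_id}"
        if s.parent_scan is not None:
            title += f" parent={s.parent_scan}"
        title += f" level={s.ms_level}"
        entries.append({
            "m/z array": s.mz_array,
            "intensity array": s.intensity_array,
            "params": {
                "title": title,
                "pepmass": round(s.precursor_mz, 6),
                "charge": s.precursor_z,
            },
        })
    _mgf.write(entries, str(path), file_mode="w")


def read_mgf(path: str | Path) -> list[MSnSpectrum]:
    """Read an MGF written by :func:`write_mgf` (lossless to ~1e-4 m/z)."""
    out: list[MSnSpectrum] = []
    with _mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            m = _TITLE_RE.search(params.get("title", ""))
            if m is None:
                raise ValueError(
                    f"MGF title lacks scan/level lineage: {params.get('title')!r}")
            parent = m.group("parent")
            charge = params.get("charge")
            z = int(charge[0]) if charge else 1
            peaks = list(zip(entry["m/z array"].tolist(),
                             entry["intensity array"].tolist()))
            out.append(MSnSpectrum(
                scan_id=int(m.group("scan")),
                ms_level=int(m.group("level")),
                precursor_mz=float(params["pepmass"][0]),
                precursor_z=z,
                peaks=peaks,
                parent_scan=int(parent) if parent else None,
            ))
    return out
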