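"""Plain-text input/output: delimited maps, scan metadata XML, cohort and
visual-field CSVs, and JSON provenance records.

Scan metadata uses a minimal XML dialect::

    <scan>
      <fovea_x>255.5</fovea_x>
      <fovea_y>63.5</fovea_y>
      <laterality>OD</laterality>
      <tilt_deg>6.9</tilt_deg>
      <layer>GCIPL</layer>
    </scan>
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from .types import ParticipantRecord, ThicknessMap, VFResult


def write_map(tmap: ThicknessMap, path: Path) -> None:
    """Write values as a delimited matrix (invalid pixels as nan) + metadata."""
    path = Path(path)
    out = np.where(tmap.valid, tmap.values, np.nan)
    np.savetxt(path, out, fmt="%.6g", delimiter="\t")
    write_metadata(tmap, path.with_suffix(".xml"))


def read_map(path: Path) -> ThicknessMap:
    path = Path(path)
    values = np.loadtxt(path, delimiter="\t")
    valid = np.isfinite(values)
    meta = read_metadata(path.with_suffix(".xml"))
    return ThicknessMap(values=np.where(valid, values, 0.0), valid=valid, **meta)


def write_metadata(tmap: ThicknessMap, path: Path) -> None:
    root = ET.Element("scan")
    for tag, value in (
        ("fovea_x", tmap.fovea_xy[0]),
        ("fovea_y", tmap.fovea_xy[1]),
        ("laterality", tmap.laterality),
        ("tilt_deg", tmap.tilt_deg),
        ("layer", tmap.layer),
    ):
        ET.SubElement(root, tag).text = str(value)
    ET.ElementTree(root).write(path, encoding="unicode")


def read_metadata(path: Path) -> dict:
    root = ET.parse(path).getroot()

    def grab(tag: str) -> str:
        el = root.find(tag)
        if el is None or el.text is None:
            raise ValueError(f"metadata file {path} lacks <{tag}>")
        return el.text

    return {
        "fovea_xy": (float(grab("fovea_x")), float(grab("fovea_y"))),
        "laterality": grab("laterality"),
        "tilt_deg": float(grab("tilt_deg")),
        "layer": grab("layer"),
    }


def write_vf(vf: VFResult, csv_path: Path) -> None:
    """Point table as CSV plus an MD/PSD sidecar JSON."""
    csv_path = Path(csv_path)
    vf.points.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps({"MD": vf.md, "PSD": vf.psd}))


def read_vf(csv_path: Path) -> VFResult:
    csv_path = Path(csv_path)
    points = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return VFResult(points=points, md=float(meta["MD"]), psd=float(meta["PSD"]))


def write_cohort(records: list[ParticipantRecord], path: Path) -> None:
    rows = [
        {"pid": r.pid, "age": r.age, "sex": r.sex, "se": r.se,
         "eye": r.eye, "tilt_deg": r.tilt_deg}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort(path: Path) -> list[ParticipantRecord]:
    frame = pd.read_csv(path)
    return [
        ParticipantRecord(pid=str(row.pid), age=float(row.age), sex=str(row.sex),
                          se=float(row.se), eye=str(row.eye),
                          tilt_deg=float(row.tilt_deg))
        for row in frame.itertuples()
    ]


def file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_provenance(path: Path, stage: str, config: dict,
                     inputs: dict[str, str] | None = None) -> None:
    """JSON provenance record: stage, config, input hashes, versions."""
    record = {
        "stage": stage,
        "config": config,
        "inputs": inputs or {},
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str))
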