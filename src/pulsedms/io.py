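"""Readers and writers: mzML scan data, study metadata, cell counts and
feature matrices.

The mzML support is deliberately minimal: centroided MS1 spectra with
base64-encoded 32/64-bit float arrays (zlib or no compression), which is
what an MSConvert centroid export contains. Profile-mode spectra are
rejected with a pointer to the remedy.
"""

from __future__ import annotations

import base64
import json
import struct
import xml.etree.ElementTree as ET
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CellCountTable,
    EmptyInputError,
    FeatureMatrix,
    ROLES,
    SampleMetadata,
    SampleScanSet,
    Scan,
    UnsupportedDialectError,
    ValidationError,
)

__all__ = [
    "read_mzml",
    "write_mzml",
    "read_metadata",
    "write_metadata",
    "read_cell_counts",
    "write_cell_counts",
    "read_feature_matrix",
    "write_feature_matrix",
]

_NS = "http://psi.hupo.org/ms/mzml"

# PSI-MS controlled-vocabulary accessions used below
_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_NEG_SCAN = "MS:1000129"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NO_COMPRESSION = "MS:1000576"


def _cv_params(element: ET.Element) -> dict[str, str]:
    out = {}
    for cv in element.findall(f"{{{_NS}}}cvParam"):
        out[cv.get("accession", "")] = cv.get("value", "")
    return out


def _decode_binary_array(bda: ET.Element) -> tuple[str, np.ndarray]:
    params = _cv_params(bda)
    if _ACC_MZ_ARRAY in params:
        kind = "mz"
    elif _ACC_INT_ARRAY in params:
        kind = "intensity"
    else:
        return "other", np.empty(0)
    dtype = "<d" if _ACC_F64 in params else "<f" if _ACC_F32 in params else None
    if dtype is None:
        raise UnsupportedDialectError(
            "binary array is not 32- or 64-bit float; re-export with MSConvert"
        )
    binary = bda.find(f"{{{_NS}}}binary")
    text = (binary.text or "") if binary is not None else ""
    raw = base64.b64decode(text)
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    n = len(raw) // struct.calcsize(dtype)
    return kind, np.asarray(struct.unpack(f"<{n}{dtype[-1]}", raw), dtype=float)


def read_mzml(path: str | Path, sample_id: str | None = None,
              plate_id: str = "", well: str = "") -> SampleScanSet:
    """Read a centroided MS1 mzML file into one :class:`SampleScanSet`.

    Scans keep file order and get 0-based indices; labels start ``unknown``;
    unsorted m/z arrays are sorted. Raises :class:`OSError` on missing or
    corrupt files, :class:`EmptyInputError` when the file holds no spectra,
    and :class:`UnsupportedDialectError` on profile-mode data.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except FileNotFoundError:
        raise
    except ET.ParseError as exc:
        raise OSError(f"corrupt mzML file {path}: {exc}") from exc
    root = tree.getroot()

    scans: list[Scan] = []
    for idx, spectrum in enumerate(root.iter(f"{{{_NS}}}spectrum")):
        params = _cv_params(spectrum)
        if _ACC_PROFILE in params:
            raise UnsupportedDialectError(
                f"{path}: profile-mode spectrum found; centroid upstream "
                "(e.g. MSConvert peakPicking filter) before processing"
            )
        level = params.get(_ACC_MS_LEVEL, "1")
        if level != "1":
            continue
        time_s = 0.0
        for scan_el in spectrum.iter(f"{{{_NS}}}scan"):
            sp = scan_el.findall(f"{{{_NS}}}cvParam")
            for cv in sp:
                if cv.get("accession") == _ACC_SCAN_START:
                    value = float(cv.get("value", "0"))
                    unit = cv.get("unitName", "second")
                    time_s = value * 60.0 if unit == "minute" else value
        mz = np.empty(0)
        inten = np.empty(0)
        for bda in spectrum.iter(f"{{{_NS}}}binaryDataArray"):
            kind, arr = _decode_binary_array(bda)
            if kind == "mz":
                mz = arr
            elif kind == "intensity":
                inten = arr
        scans.append(Scan(index=len(scans), mz=mz, intensity=inten, time=time_s))

    if not scans:
        raise EmptyInputError(f"{path}: no MS1 spectra found")
    return SampleScanSet(
        sample_id=sample_id or path.stem, scans=scans, plate_id=plate_id, well=well
    )


def write_mzml(scans: list[Scan], path: str | Path, sample_id: str = "sample") -> Path:
    """Write centroided MS1 spectra as standards-compliant mzML.

    Arrays are encoded as uncompressed base64 64-bit floats, so the file is
    plain ASCII text and round-trips exactly through :func:`read_mzml`.
    """
    if not scans:
        raise ValidationError("cannot write mzML with zero scans")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def b64(arr: np.ndarray) -> str:
        return base64.b64encode(
            struct.pack(f"<{arr.size}d", *np.asarray(arr, dtype=float))
        ).decode("ascii")

    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        f'<mzML xmlns="{_NS}" version="1.1.0" id="{sample_id}">',
        '  <cvList count="1">',
        '    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        "  </cvList>",
        f'  <run id="{sample_id}" defaultInstrumentConfigurationRef="IC1">',
        f'    <spectrumList count="{len(scans)}" defaultDataProcessingRef="DP1">',
    ]
    for scan in scans:
        lines += [
            f'      <spectrum index="{scan.index}" id="scan={scan.index + 1}" defaultArrayLength="{scan.n_peaks}">',
            f'        <cvParam cvRef="MS" accession="{_ACC_MS_LEVEL}" name="ms level" value="1"/>',
            f'        <cvParam cvRef="MS" accession="{_ACC_CENTROID}" name="centroid spectrum" value=""/>',
            f'        <cvParam cvRef="MS" accession="{_ACC_NEG_SCAN}" name="negative scan" value=""/>',
            '        <scanList count="1">',
            "          <scan>",
            f'            <cvParam cvRef="MS" accession="{_ACC_SCAN_START}" name="scan start time" value="{scan.time:.6f}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>',
            "          </scan>",
            "        </scanList>",
            '        <binaryDataArrayList count="2">',
        ]
        for acc, name, arr in (
            (_ACC_MZ_ARRAY, "m/z array", scan.mz),
            (_ACC_INT_ARRAY, "intensity array", scan.intensity),
        ):
            encoded = b64(arr)
            lines += [
                f'          <binaryDataArray encodedLength="{len(encoded)}">',
                f'            <cvParam cvRef="MS" accession="{_ACC_F64}" name="64-bit float" value=""/>',
                f'            <cvParam cvRef="MS" accession="{_ACC_NO_COMPRESSION}" name="no compression" value=""/>',
                f'            <cvParam cvRef="MS" accession="{acc}" name="{name}" value=""/>',
                f"            <binary>{encoded}</binary>",
                "          </binaryDataArray>",
            ]
        lines += [
            "        </binaryDataArrayList>",
            "      </spectrum>",
        ]
    lines += ["    </spectrumList>", "  </run>", "</mzML>", ""]
    path.write_text("\n".join(lines), encoding="utf-8")
    return path


_META_COLUMNS = ["sample_id", "plate_id", "well", "role", "drug",
                 "concentration_M", "replicate"]


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the sample/plate metadata CSV.

    Required columns: sample_id, plate_id, well, role, drug,
    concentration_M, replicate. Unknown roles and duplicate sample ids
    raise :class:`ValidationError` naming the offending row.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "plate_id": str, "well": str,
                                  "role": str, "drug": str},
                     float_precision="round_trip")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata file {path} lacks columns: {missing}")
    records: list[SampleMetadata] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        role = str(row["role"])
        if role not in ROLES:
            raise ValidationError(
                f"metadata row {i} (sample {row['sample_id']!r}): unknown role {role!r}"
            )
        sid = str(row["sample_id"])
        if sid in seen:
            raise ValidationError(f"metadata row {i}: duplicate sample_id {sid!r}")
        seen.add(sid)
        conc = row["concentration_M"]
        conc = None if pd.isna(conc) else float(conc)
        drug = "" if pd.isna(row["drug"]) else str(row["drug"])
        records.append(
            SampleMetadata(
                sample_id=sid,
                plate_id=str(row["plate_id"]),
                well=str(row["well"]),
                role=role,
                drug=drug,
                concentration=conc,
                replicate=int(row["replicate"]),
            )
        )
    return records


def write_metadata(records: list[SampleMetadata], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "sample_id": r.sample_id,
            "plate_id": r.plate_id,
            "well": r.well,
            "role": r.role,
            "drug": r.drug,
            "concentration_M": "" if r.concentration is None else repr(r.concentration),
            "replicate": r.replicate,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, index=False)
    return path


def read_cell_counts(path: str | Path) -> CellCountTable:
    """Read per-well cell counts (columns: [plate_id,] well, cell_count)."""
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str})
    if "well" not in df.columns or "cell_count" not in df.columns:
        raise ValidationError(f"cell-count file {path} needs well and cell_count columns")
    counts: dict[tuple[str, str], int] = {}
    for _, row in df.iterrows():
        plate = str(row["plate_id"]) if "plate_id" in df.columns else ""
        key = (plate, str(row["well"]))
        if key in counts:
            raise ValidationError(f"duplicate cell count for {key}")
        counts[key] = int(row["cell_count"])
    return CellCountTable(counts)


def write_cell_counts(table: CellCountTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {"plate_id": plate, "well": well, "cell_count": count}
        for (plate, well), count in table.items()
    ]
    pd.DataFrame(rows, columns=["plate_id", "well", "cell_count"]).to_csv(
        path, index=False
    )
    return path


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> Path:
    """Write a feature matrix as TSV with a JSON metadata sidecar.

    Missing cells are written as empty fields, never "0", so the
    missingness pattern survives the round trip exactly.
    """
    if matrix.n_samples < 1 or matrix.n_features < 1:
        raise ValidationError("feature matrix must have >= 1 sample and >= 1 feature")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # default float repr is shortest-round-trip, so values survive exactly
    matrix.intensities.to_csv(path, sep="\t", index_label="sample_id", na_rep="")
    sidecar = {
        "feature_mz": {fid: float(mz) for fid, mz in matrix.feature_mz.items()},
        "sample_meta": {
            sid: {
                k: (None if pd.isna(v) else v)
                for k, v in row.items()
            }
            for sid, row in matrix.sample_meta.to_dict(orient="index").items()
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1), encoding="utf-8"
    )
    return path


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    """Read a matrix written by :func:`write_feature_matrix`."""
    path = Path(path)
    intensities = pd.read_csv(path, sep="\t", index_col="sample_id",
                              float_precision="round_trip")
    intensities.index = intensities.index.astype(str)
    intensities.index.name = None
    intensities.columns.name = None
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    feature_mz = pd.Series(
        {fid: float(mz) for fid, mz in sidecar["feature_mz"].items()}, name="mz"
    ).loc[list(intensities.columns)]
    feature_mz.index.name = None
    sample_meta = pd.DataFrame.from_dict(sidecar["sample_meta"], orient="index")
    sample_meta.index = sample_meta.index.astype(str)
    sample_meta.index.name = None
    sample_meta = sample_meta.loc[intensities.index]
    return FeatureMatrix(
        intensities=intensities, feature_mz=feature_mz, sample_meta=sample_meta
    )
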