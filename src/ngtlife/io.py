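"""Reading and writing the package's on-disk formats.

All formats are plain text: the manifest CSV, split CSV, JSON-lines exclusion
log, and a headered columnar embeddings file; images go out as 16-bit
grayscale PNG named by record_id, with optional minimal DICOM via pydicom
when it is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .containers import EmbeddingSet

MANIFEST_COLUMNS = [
    "record_id", "patient_id", "study_date", "birth_date", "sex", "view",
    "body_part", "width", "height", "manufacturer", "department",
    "report_text", "label", "rater1", "rater2", "rater3",
]


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"record_id": str, "patient_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    return df


def write_split(assignment: dict, path, header_note: str | None = None) -> None:
    df = pd.DataFrame(
        {"record_id": list(assignment), "split": list(assignment.values())}
    )
    _to_csv(df, path, header_note)


def read_split(path) -> dict:
    df = pd.read_csv(path, dtype=str, comment="#")
    return dict(zip(df["record_id"], df["split"]))


def _to_csv(df: pd.DataFrame, path, header_note: str | None) -> None:
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        df.to_csv(fh, index=False)


def write_exclusion_log(entries, path) -> None:
    """JSON-lines, one object per excluded record: {record_id, rule}."""
    with open(path, "w") as fh:
        for e in entries:
            fh.write(json.dumps(e) + "\n")


def write_embeddings(es: EmbeddingSet, path, header_note: str | None = None) -> None:
    cols = {"record_id": es.record_id}
    for j in range(es.d):
        cols[f"dim{j + 1}"] = es.X[:, j]
    df = pd.DataFrame(cols)
    if es.labels is not None:
        df["label"] = es.labels
    for c in es.tags.columns:
        df[f"tag_{c}"] = es.tags[c].to_numpy()
    _to_csv(df, path, header_note)


def read_embeddings(path) -> EmbeddingSet:
    df = pd.read_csv(path, dtype={"record_id": str}, comment="#")
    dims = sorted(
        (c for c in df.columns if c.startswith("dim")), key=lambda c: int(c[3:])
    )
    tags = df[[c for c in df.columns if c.startswith("tag_")]].rename(
        columns=lambda c: c[4:]
    )
    return EmbeddingSet(
        X=df[dims].to_numpy(dtype=float),
        record_id=df["record_id"].to_numpy(),
        labels=df["label"].to_numpy() if "label" in df.columns else None,
        tags=tags.reset_index(drop=True),
        provenance=[f"read_embeddings({path})"],
    )


def write_png(pixels: np.ndarray, path) -> None:
    iio.imwrite(Path(path), np.asarray(pixels, dtype=np.uint16))


def write_dicom(record, pixels: np.ndarray, path) -> None:
    """Minimal DICOM secondary-capture writer (requires pydicom)."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.BodyPartExamined = str(record["body_part"])
    ds.ViewPosition = str(record["view"])
    ds.StudyDate = str(record["study_date"]).replace("-", "")
    ds.PatientBirthDate = str(record["birth_date"]).replace("-", "")
    ds.Manufacturer = str(record["manufacturer"])
    ds.InstitutionalDepartmentName = str(record["department"])
    px = np.asarray(pixels, dtype=np.uint16)
    ds.Rows, ds.Columns = px.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = px.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
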