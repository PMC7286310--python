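"""File formats, cohort manifests and the end-to-end pipeline runner.

All on-disk formats are plain text: time series as TSV (rows = time points,
columns = ROIs, header = ROI names) with a JSON sidecar holding metadata
(tr, subject, condition, seed); matrices as dense CSV with ROI-name header
row and column.  EC files carry a comment line stating the orientation
convention (row = source, column = target), which readers check.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import MouParameters, SignalSession, StructuralMask

logger = logging.getLogger("mouec")

FORMAT_VERSION = "1"
ORIENTATION_COMMENT = "# orientation: row = source, column = target"
VERSION_COMMENT = f"# mouec format_version={FORMAT_VERSION}"


class FileFormatError(ValueError):
    """Malformed on-disk artifact."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_timeseries(session: SignalSession, path: str | Path) -> None:
    """Write a session as TSV (time x ROI) plus a JSON metadata sidecar."""
    path = Path(path)
    frame = pd.DataFrame(session.data.T, columns=session.roi_names)
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
    meta = {
        "format_version": FORMAT_VERSION,
        "package_version": __version__,
        "tr": session.tr,
        "subject_id": session.subject_id,
        "condition": session.condition,
        "n_rois": session.n_rois,
        "n_timepoints": session.n_timepoints,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_timeseries(path: str | Path) -> SignalSession:
    """Read a TSV session; validates header, numeric cells and the sidecar."""
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, sep="\t", header=0, float_precision="round_trip"
        )
    except Exception as exc:  # malformed header / unreadable file
        raise FileFormatError(f"{path}: malformed TSV header or body: {exc}") from exc
    if frame.columns.str.match(r"^Unnamed").any() or frame.columns.duplicated().any():
        raise FileFormatError(f"{path}: malformed header (unnamed/duplicate columns)")
    non_numeric = [
        c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)
    ]
    if non_numeric:
        raise FileFormatError(
            f"{path}: non-numeric cells in column(s) {non_numeric}"
        )
    if frame.isna().any().any():
        rows, cols = np.nonzero(frame.isna().to_numpy())
        raise FileFormatError(
            f"{path}: NaN cell at row {rows[0]}, column {frame.columns[cols[0]]!r}"
        )
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileFormatError(f"{path}: missing metadata sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    if int(meta.get("n_rois", -1)) != frame.shape[1]:
        raise FileFormatError(
            f"{path}: orientation error: sidecar n_rois={meta.get('n_rois')} but "
            f"file has {frame.shape[1]} columns (rows must be time points)"
        )
    return SignalSession(
        data=frame.to_numpy().T,
        tr=float(meta["tr"]),
        subject_id=str(meta.get("subject_id", "sub-00")),
        condition=str(meta.get("condition", "rest")),
        roi_names=list(frame.columns),
    )


def write_matrix(
    matrix: np.ndarray,
    path: str | Path,
    roi_names: list[str] | None = None,
    oriented: bool = True,
) -> None:
    """Write a labelled dense CSV matrix; EC files carry the orientation
    comment so a transposed file is detectable."""
    path = Path(path)
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    if matrix.shape != (n, n):
        raise ValueError("matrix must be square")
    names = roi_names or [f"roi_{i:03d}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write(VERSION_COMMENT + "\n")
        if oriented:
            fh.write(ORIENTATION_COMMENT + "\n")
        pd.DataFrame(matrix, index=names, columns=names).to_csv(
            fh, float_format="%.17g"
        )


def read_matrix(
    path: str | Path, expect_oriented: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Read a labelled CSV matrix; returns (matrix, roi_names)."""
    path = Path(path)
    with open(path) as fh:
        comments = []
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            comments.append(line.strip())
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh, index_col=0, float_precision="round_trip")
    if expect_oriented and ORIENTATION_COMMENT not in comments:
        logger.warning(
            "%s: no orientation comment found; the matrix may be transposed "
            "(expected %r)",
            path,
            ORIENTATION_COMMENT,
        )
    if frame.shape[0] != frame.shape[1]:
        raise FileFormatError(
            f"{path}: matrix is not square ({frame.shape[0]}x{frame.shape[1]})"
        )
    if list(frame.index) != list(frame.columns):
        raise FileFormatError(f"{path}: row and column labels differ")
    return frame.to_numpy(dtype=float), list(frame.columns)


def write_mask(mask: StructuralMask, path: str | Path, roi_names=None) -> None:
    write_matrix(mask.mask.astype(int), path, roi_names, oriented=True)


def read_mask(path: str | Path) -> StructuralMask:
    mat, _ = read_matrix(path, expect_oriented=True)
    return StructuralMask(mask=mat.astype(int))


# ---------------------------------------------------------------------------
# cohort manifest


def write_manifest(entries: list[dict], path: str | Path) -> None:
    payload = {"format_version": FORMAT_VERSION, "entries": entries}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_manifest(path: str | Path, check_files: bool = True) -> list[dict]:
    path = Path(path)
    payload = json.loads(path.read_text())
    entries = payload["entries"]
    seen = set()
    for e in entries:
        key = (e["subject_id"], e["condition"], e["session_id"])
        if key in seen:
            raise FileFormatError(f"{path}: duplicate manifest entry {key}")
        seen.add(key)
        if check_files and "file" in e:
            f = path.parent / e["file"]
            if not f.exists():
                raise FileFormatError(f"{path}: listed file missing: {e['file']}")
    return entries


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
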