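"""Readers, writers and study-manifest handling.

The canonical exchange format is delimited text (tab or comma,
autodetected): one file per subject with rows = ROIs and columns = time
points, optionally carrying a header row of time stamps and a first column
of ROI names.  A manifest (CSV with columns ``file, subject, group`` and
optional ``sex``, or an equivalent YAML mapping) assembles the per-group
samples.  Matrices are written as TSV with ROI names as header row and
column, at full double precision, next to a JSON sidecar recording the
estimator tag and parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fdcore import (
    MultivariateFunctionalSample,
    TimeGrid,
    ValidationError,
    make_trapezoid_grid,
)
from .correlation import ConnectivityMatrix
from .inference import GroupDifferenceResult

__all__ = [
    "StudyManifest",
    "ManifestEntry",
    "read_subject_matrix",
    "write_subject_matrix",
    "read_manifest",
    "load_study",
    "write_connectivity_matrix",
    "read_connectivity_matrix",
    "write_group_difference",
]

logger = logging.getLogger(__name__)


@dataclass
class ManifestEntry:
    file: Path
    subject: str
    group: str
    sex: str | None = None


@dataclass
class StudyManifest:
    """Maps per-subject files to subjects, groups and optional covariates."""

    entries: list[ManifestEntry]
    grid_points: np.ndarray | None = None
    time_step: float | None = None
    roi_names: list[str] = field(default_factory=list)
    root: Path = Path(".")

    def __post_init__(self) -> None:
        subjects = [e.subject for e in self.entries]
        if len(set(subjects)) != len(subjects):
            raise ValidationError("subject ids must be unique")
        if not self.entries:
            raise ValidationError("manifest has no entries")

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.group not in seen:
                seen.append(e.group)
        return seen


def _detect_delimiter(line: str) -> str | None:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # whitespace


def read_subject_matrix(
    path: str | Path,
    expected_rois: int | None = None,
    expected_times: int | None = None,
) -> tuple[np.ndarray, list[str] | None, np.ndarray | None]:
    """Parse one subject's K x J matrix from delimited text.

    Returns ``(values, roi_names, time_stamps)``; the latter two are None
    when the file carries no labels.  A time-stamp header row is recognized
    by its corner cell ``time`` (the writer's convention); a first column
    of non-numeric cells is read as ROI names.  Ragged or non-numeric rows
    raise a parse error naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    raw_lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not raw_lines:
        raise ValidationError(f"{path}: empty file")
    delim = _detect_delimiter(raw_lines[0])
    rows = [ln.split(delim) if delim else ln.split() for ln in raw_lines]

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    time_stamps = None
    header_offset = 0
    first = rows[0]
    if first and first[0].strip().lower() == "time":
        tail = first[1:]
        if not tail or not all(_is_number(tok) for tok in tail):
            raise ValidationError(f"{path}: malformed time-stamp header")
        time_stamps = np.array([float(tok) for tok in tail])
        header_offset = 1

    body = rows[header_offset:]
    if not body:
        raise ValidationError(f"{path}: no data rows")
    roi_names = None
    if not _is_number(body[0][0]):
        roi_names = []
        data_rows = []
        for ln_no, r in enumerate(body, start=header_offset + 1):
            roi_names.append(r[0])
            data_rows.append(r[1:])
    else:
        data_rows = body

    widths = {len(r) for r in data_rows}
    if len(widths) != 1:
        bad = next(
            i for i, r in enumerate(data_rows, start=header_offset + 1)
            if len(r) != len(data_rows[0])
        )
        raise ValidationError(f"{path}: ragged row at line {bad + (1 if roi_names else 0)}")
    try:
        values = np.array([[float(tok) for tok in r] for r in data_rows])
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric cell ({exc})") from exc
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{path}: non-finite values")
    if roi_names is not None and len(set(roi_names)) != len(roi_names):
        raise ValidationError(f"{path}: duplicate ROI names")
    if expected_rois is not None and values.shape[0] != expected_rois:
        raise ValidationError(
            f"{path}: expected {expected_rois} ROIs, found {values.shape[0]}"
        )
    if expected_times is not None and values.shape[1] != expected_times:
        raise ValidationError(
            f"{path}: expected {expected_times} time points, found {values.shape[1]}"
        )
    return values, roi_names, time_stamps


def write_subject_matrix(
    path: str | Path,
    values: np.ndarray,
    roi_names: list[str] | None = None,
    time_points: np.ndarray | None = None,
) -> None:
    """Write one subject's K x J matrix as TSV at full precision."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    with path.open("w") as fh:
        if time_points is not None:
            fh.write("\t".join(["time"] + [repr(float(t)) for t in time_points]) + "\n")
        for k, row in enumerate(values):
            lead = [roi_names[k]] if roi_names is not None else []
            fh.write("\t".join(lead + [repr(float(x)) for x in row]) + "\n")


def read_manifest(path: str | Path) -> StudyManifest:
    """Read a study manifest from CSV or YAML."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: manifest not found")
    root = path.parent
    if path.suffix.lower() in {".yml", ".yaml"}:
        doc = yaml.safe_load(path.read_text())
        entries = [
            ManifestEntry(
                file=root / e["file"],
                subject=str(e["subject"]),
                group=str(e["group"]),
                sex=e.get("sex"),
            )
            for e in doc["entries"]
        ]
        grid_points = np.asarray(doc["grid"], dtype=float) if "grid" in doc else None
        time_step = doc.get("time_step")
        roi_names = list(doc.get("roi_names", []))
    else:
        df = pd.read_csv(path)
        required = {"file", "subject", "group"}
        if not required.issubset(df.columns):
            raise ValidationError(f"{path}: manifest needs columns {sorted(required)}")
        entries = [
            ManifestEntry(
                file=root / str(r.file),
                subject=str(r.subject),
                group=str(r.group),
                sex=getattr(r, "sex", None),
            )
            for r in df.itertuples(index=False)
        ]
        grid_points = None
        time_step = None
        roi_names = []
    return StudyManifest(
        entries=entries,
        grid_points=grid_points,
        time_step=time_step,
        roi_names=roi_names,
        root=root,
    )


def load_study(
    manifest: str | Path | StudyManifest,
) -> dict[str, MultivariateFunctionalSample]:
    """Assemble one :class:`MultivariateFunctionalSample` per group.

    All files must agree on K and J; inconsistencies are reported for every
    offending file at once.  The grid comes from the manifest (explicit
    points or a time step), from time stamps in the files, or defaults to
    unit spacing.
    """
    if not isinstance(manifest, StudyManifest):
        manifest = read_manifest(manifest)
    missing = [str(e.file) for e in manifest.entries if not Path(e.file).exists()]
    if missing:
        raise ValidationError("missing files: " + ", ".join(missing))

    parsed = []
    for e in manifest.entries:
        values, roi_names, stamps = read_subject_matrix(e.file)
        parsed.append((e, values, roi_names, stamps))
    shapes = {p[1].shape for p in parsed}
    if len(shapes) != 1:
        offenders = ", ".join(
            f"{p[0].file} ({p[1].shape[0]}x{p[1].shape[1]})" for p in parsed
        )
        raise ValidationError(f"inconsistent K x J across files: {offenders}")
    K, J = parsed[0][1].shape

    if manifest.grid_points is not None:
        grid = make_trapezoid_grid(manifest.grid_points)
    elif manifest.time_step is not None:
        grid = make_trapezoid_grid(np.arange(J) * float(manifest.time_step))
    elif parsed[0][3] is not None:
        grid = make_trapezoid_grid(parsed[0][3])
    else:
        grid = make_trapezoid_grid(np.arange(J, dtype=float))
    if grid.n_points != J:
        raise ValidationError("grid length does not match the data")

    roi_names = list(manifest.roi_names) or (parsed[0][2] or [f"roi{k}" for k in range(K)])

    out: dict[str, MultivariateFunctionalSample] = {}
    for group in manifest.groups:
        rows = [p for p in parsed if p[0].group == group]
        out[group] = MultivariateFunctionalSample(
            grid=grid,
            values=np.stack([p[1] for p in rows]),
            group_label=group,
            subject_ids=[p[0].subject for p in rows],
            roi_names=list(roi_names),
        )
        logger.info(
            "group %s: n=%d subjects, K=%d ROIs, J=%d time points",
            group, len(rows), K, J,
        )
    return out


def write_connectivity_matrix(
    path: str | Path,
    matrix: ConnectivityMatrix,
    delta: float | None = None,
    L: int | None = None,
    provenance: dict | None = None,
) -> None:
    """Write a connectivity matrix as TSV plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, index=matrix.roi_names, columns=matrix.roi_names)
    df.to_csv(path, sep="\t", float_format="%.17g")
    side = {
        "estimator": matrix.estimator_tag,
        "group": matrix.group_label,
        "n_rois": matrix.n_rois,
        "delta": delta,
        "L": L,
    }
    if provenance:
        side["provenance"] = provenance
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=2))


def read_connectivity_matrix(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    side_path = path.with_suffix(path.suffix + ".json")
    tag, group = "TCC", ""
    if side_path.exists():
        side = json.loads(side_path.read_text())
        tag = side.get("estimator", tag)
        group = side.get("group", "")
    return ConnectivityMatrix(
        values=df.to_numpy(dtype=float),
        estimator_tag=tag,
        roi_names=[str(c) for c in df.columns],
        group_label=group,
    )


def write_group_difference(
    outdir: str | Path, result: GroupDifferenceResult, provenance: dict | None = None
) -> None:
    """Write difference matrix, p-values, rejection mask and a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = result.roi_names
    for fname, mat in [
        ("difference.tsv", result.U),
        ("pvalues.tsv", result.pvalues),
        ("pvalues_adjusted.tsv", result.adjusted),
    ]:
        if mat is None:
            continue
        pd.DataFrame(mat, index=names, columns=names).to_csv(
            outdir / fname, sep="\t", float_format="%.17g"
        )
    K = len(names)
    mask = np.zeros((K, K), dtype=int)
    for k, l in result.rejected:
        mask[k, l] = mask[l, k] = 1
    pd.DataFrame(mask, index=names, columns=names).to_csv(
        outdir / "rejected.tsv", sep="\t"
    )
    summary = {
        "alpha": result.alpha,
        "B": result.B,
        "m0_hat": result.m0_hat,
        "Q": result.Q,
        "seed": result.seed,
        "rejected_pairs": sorted(
            [names[k], names[l]] for k, l in result.rejected
        ),
    }
    if provenance:
        summary["provenance"] = provenance
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
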