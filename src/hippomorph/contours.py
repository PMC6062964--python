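"""Contour-stack I/O and planimetric volumetry.

A subject's hippocampus is stored as an ordered stack of closed planar
contours, one per coronal slice, traced rostral to caudal.  Coordinates are
millimetres in a right-handed, rigidly pre-aligned space; slice planes are
parallel with ``z = slice_index * slice_thickness``.  Contours are stored
*open* (no duplicated terminal vertex) and closure is implicit.  Orientation
is normalized to counter-clockwise on read; the tracing direction of the
rater is arbitrary and carries no information.

Volume follows the classical planimetric rule: the sum over slices of the
enclosed cross-sectional area times the slice thickness.

Two on-disk formats are supported and mirror each other field for field:

* a line-oriented text format (``.ctr``)::

      subject s001
      side left
      thickness 1.0
      slice 0 0.0
      12.1 4.3
      ...
      slice 1 1.0
      ...

* a JSON equivalent (``.json``) with keys ``subject_id``, ``side``,
  ``slice_thickness`` and ``slices`` (each with ``slice_index``, ``z`` and
  ``points``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .errors import ContourFormatError, ValidationError

__all__ = [
    "Contour",
    "ContourStack",
    "CohortTable",
    "polygon_area",
    "signed_polygon_area",
    "stack_volume",
    "read_contour_stack",
    "write_contour_stack",
    "read_cohort_table",
    "write_results",
]

#: Smallest cross-sectional area (mm^2) treated as non-degenerate.
_MIN_AREA = 1e-12


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Contour:
    """One closed planar tracing on a single slice.

    Parameters
    ----------
    points
        ``(n, 2)`` array of in-plane vertices (x, y) in mm, ``n >= 3``,
        ordered counter-clockwise after validation, first vertex *not*
        repeated at the end.
    slice_index
        Integer slice number, rostral to caudal.
    z
        Slice position along the stack axis in mm.
    """

    points: np.ndarray
    slice_index: int
    z: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError(
                f"slice {self.slice_index}: contour points must be (n, 2), "
                f"got {self.points.shape}"
            )

    @property
    def n_vertices(self) -> int:
        return len(self.points)

    def validate(self) -> "Contour":
        """Check closure convention, simplicity and orientation in place.

        A duplicated terminal vertex is removed; orientation is flipped to
        counter-clockwise when the signed area is negative.
        """
        pts = self.points
        if len(pts) >= 2 and np.allclose(pts[0], pts[-1], atol=1e-12):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ValidationError(
                f"slice {self.slice_index}: contour needs >= 3 distinct vertices"
            )
        if not np.all(np.isfinite(pts)):
            raise ValidationError(f"slice {self.slice_index}: non-finite coordinates")
        area2 = _signed_area(pts)
        if abs(area2) < _MIN_AREA:
            raise ValidationError(
                f"slice {self.slice_index}: degenerate (collinear) contour"
            )
        if area2 < 0.0:
            pts = pts[::-1].copy()
        ring = LineString(np.vstack([pts, pts[:1]]))
        if not ring.is_simple:
            raise ValidationError(
                f"slice {self.slice_index}: self-intersecting contour"
            )
        self.points = pts
        return self


@dataclass
class ContourStack:
    """All tracings of one hippocampus, ordered rostral to caudal."""

    subject_id: str
    contours: list[Contour]
    slice_thickness: float
    side: str = "left"

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")

    def validate(self) -> "ContourStack":
        if self.slice_thickness <= 0:
            raise ValidationError("slice_thickness must be positive")
        if len(self.contours) < 3:
            raise ValidationError(
                f"{self.subject_id}: stack needs >= 3 slices, got {len(self.contours)}"
            )
        idx = np.array([c.slice_index for c in self.contours])
        if np.any(np.diff(idx) <= 0):
            raise ValidationError(f"{self.subject_id}: slice indices not strictly increasing")
        z = np.array([c.z for c in self.contours])
        expect = np.diff(idx) * self.slice_thickness
        if not np.allclose(np.diff(z), expect, atol=1e-6):
            raise ValidationError(
                f"{self.subject_id}: z spacing inconsistent with slice_thickness"
            )
        for c in self.contours:
            c.validate()
        return self

    @property
    def n_slices(self) -> int:
        return len(self.contours)


# ---------------------------------------------------------------------------
# planimetry
# ---------------------------------------------------------------------------

def _signed_area(points: np.ndarray) -> float:
    """Signed shoelace area of an open vertex ring (CCW positive)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def signed_polygon_area(contour: Contour | np.ndarray) -> float:
    """Signed shoelace area in mm^2 (positive for counter-clockwise order)."""
    pts = contour.points if isinstance(contour, Contour) else np.asarray(contour, float)
    return _signed_area(pts)


def polygon_area(contour: Contour | np.ndarray) -> float:
    """Enclosed area of a closed contour in mm^2 (shoelace formula).

    Raises
    ------
    ValidationError
        If the vertices are collinear (zero-area polygon).
    """
    a = abs(signed_polygon_area(contour))
    if a < _MIN_AREA:
        idx = contour.slice_index if isinstance(contour, Contour) else "?"
        raise ValidationError(f"slice {idx}: degenerate (collinear) contour")
    return a


def stack_volume(stack: ContourStack) -> float:
    """Planimetric volume: sum of per-slice areas times slice thickness (mm^3)."""
    areas = [polygon_area(c) for c in stack.contours]
    return float(np.sum(areas) * stack.slice_thickness)


# ---------------------------------------------------------------------------
# contour file I/O
# ---------------------------------------------------------------------------

def read_contour_stack(path: str | Path) -> ContourStack:
    """Read and validate a contour stack from ``.ctr`` text or ``.json``.

    The returned stack has counter-clockwise contours with any duplicated
    terminal vertex removed.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        stack = _read_json(path)
    else:
        stack = _read_ctr(path)
    return stack.validate()


def _read_ctr(path: Path) -> ContourStack:
    subject_id = side = None
    thickness = None
    slices: list[tuple[int, float, list[list[float]]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            try:
                if tok[0] == "subject":
                    subject_id = tok[1]
                elif tok[0] == "side":
                    side = tok[1]
                elif tok[0] == "thickness":
                    thickness = float(tok[1])
                elif tok[0] == "slice":
                    slices.append((int(tok[1]), float(tok[2]), []))
                else:
                    if not slices:
                        raise ContourFormatError(
                            f"{path}:{lineno}: vertex line before any 'slice' header"
                        )
                    if len(tok) != 2:
                        raise ContourFormatError(
                            f"{path}:{lineno}: expected 'x y', got {line!r}"
                        )
                    slices[-1][2].append([float(tok[0]), float(tok[1])])
            except ContourFormatError:
                raise
            except (IndexError, ValueError) as exc:
                raise ContourFormatError(f"{path}:{lineno}: cannot parse {line!r}") from exc
    if subject_id is None or thickness is None:
        raise ContourFormatError(f"{path}: missing 'subject' or 'thickness' header")
    contours = [
        Contour(points=np.asarray(pts, float), slice_index=k, z=z)
        for k, z, pts in slices
    ]
    return ContourStack(subject_id, contours, thickness, side or "left")


def _read_json(path: Path) -> ContourStack:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ContourFormatError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    try:
        contours = [
            Contour(np.asarray(s["points"], float), int(s["slice_index"]), float(s["z"]))
            for s in payload["slices"]
        ]
        return ContourStack(
            payload["subject_id"],
            contours,
            float(payload["slice_thickness"]),
            payload.get("side", "left"),
        )
    except (KeyError, TypeError) as exc:
        raise ContourFormatError(f"{path}: missing field {exc}") from exc


def write_contour_stack(stack: ContourStack, path: str | Path) -> Path:
    """Write a stack; the format follows the extension (``.ctr`` or ``.json``)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "subject_id": stack.subject_id,
            "side": stack.side,
            "slice_thickness": stack.slice_thickness,
            "slices": [
                {
                    "slice_index": c.slice_index,
                    "z": c.z,
                    "points": np.asarray(c.points, float).tolist(),
                }
                for c in stack.contours
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        lines = [
            f"subject {stack.subject_id}",
            f"side {stack.side}",
            f"thickness {stack.slice_thickness:.17g}",
        ]
        for c in stack.contours:
            lines.append(f"slice {c.slice_index} {c.z:.17g}")
            lines.extend(f"{x:.17g} {y:.17g}" for x, y in c.points)
        path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# covariate tables
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("id", "group", "age", "tiv")
OPTIONAL_COLUMNS = ("alsfrs_r", "duration_months")


@dataclass
class CohortTable:
    """Per-subject covariates: group, age, TIV and optional clinical scores.

    ``data`` is a pandas DataFrame indexed by subject id with columns
    ``group`` (two levels), ``age`` (years), ``tiv`` (mm^3) and the optional
    clinical columns.  Volume columns (``hv``, ``hv_adjusted``) are joined in
    by downstream stages.
    """

    data: pd.DataFrame
    control_label: str = "HC"
    patient_label: str = field(default="")

    def __post_init__(self) -> None:
        levels = sorted(self.data["group"].unique())
        if len(levels) != 2:
            raise ValidationError(f"group must have exactly two levels, got {levels}")
        if self.control_label not in levels:
            raise ValidationError(
                f"control label {self.control_label!r} not among group levels {levels}"
            )
        if not self.patient_label:
            self.patient_label = next(g for g in levels if g != self.control_label)

    @property
    def group_indicator(self) -> np.ndarray:
        """1 for patients, 0 for controls."""
        return (self.data["group"] == self.patient_label).to_numpy(int)

    def controls(self) -> pd.DataFrame:
        return self.data[self.data["group"] == self.control_label]

    def patients(self) -> pd.DataFrame:
        return self.data[self.data["group"] == self.patient_label]


def read_cohort_table(path: str | Path, control_label: str = "HC") -> CohortTable:
    """Read and validate the covariate CSV.

    Required columns: ``id,group,age,tiv``; optional: ``alsfrs_r``,
    ``duration_months``.  Errors name every missing column, duplicate id or
    non-positive TIV.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s): {', '.join(missing)}")
    dup = df["id"][df["id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate subject id(s): {dup}")
    bad_tiv = df.loc[df["tiv"] <= 0, "id"].tolist()
    if bad_tiv:
        raise ValidationError(f"{path}: non-positive TIV for subject(s): {bad_tiv}")
    df = df.set_index("id")
    return CohortTable(df, control_label=control_label)


def write_results(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a results table as CSV (index kept when named)."""
    path = Path(path)
    df.to_csv(path, index=df.index.name is not None)
    return path
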