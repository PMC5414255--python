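"""Reader/writer for the tpsDig landmark+curve text format.

Each record block holds ``LM=`` followed by the fixed-landmark coordinates,
optionally ``CURVES=`` / ``POINTS=`` sub-blocks with digitized polylines, and
trailing ``IMAGE=``, ``ID=``, ``SCALE=`` records.  Coordinates are multiplied
by SCALE on read when present, so stored values are in physical units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .scheme import N_CURVES, N_LANDMARKS

log = logging.getLogger(__name__)

#: Taxon abbreviation codes of the 15 extant equid groups studied.
TAXON_CODES = (
    "CBL", "PRZ", "AFR", "ASN", "KNG", "MNG", "ONG", "KHR",
    "KLN", "HMP", "GRV", "ZBR", "QGA", "BRC", "HBR",
)

TOOTH_POSITIONS = ("P3", "P4", "M1", "M2")
SIDES = ("left", "right")


class TpsParseError(ValueError):
    """Raised when a TPS record block is malformed."""


@dataclass
class RawSpecimen:
    """One digitized tooth: fixed landmarks, raw curves and metadata."""

    specimen_id: str
    fixed_landmarks: np.ndarray          # (8, 2)
    curves: list[np.ndarray]             # 8 polylines, each (k_i >= 2, 2)
    taxon_code: str | None = None
    tooth_position: str | None = None    # P3 / P4 / M1 / M2
    side: str | None = None              # left / right
    image: str | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        self.fixed_landmarks = np.asarray(self.fixed_landmarks, dtype=float)
        if self.fixed_landmarks.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"{self.specimen_id}: expected {N_LANDMARKS} fixed landmarks, "
                f"got shape {self.fixed_landmarks.shape}"
            )
        self.curves = [np.asarray(c, dtype=float) for c in self.curves]
        if len(self.curves) != N_CURVES:
            raise ValueError(
                f"{self.specimen_id}: expected {N_CURVES} curves, got {len(self.curves)}"
            )
        for i, c in enumerate(self.curves):
            if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] != 2:
                raise ValueError(
                    f"{self.specimen_id}: curve {i} must be a polyline of >=2 2D points"
                )
        pts = np.vstack([self.fixed_landmarks, *self.curves])
        if not np.all(np.isfinite(pts)):
            raise ValueError(f"{self.specimen_id}: non-finite coordinates")


def _parse_block(lines: list[str], lineno: int) -> RawSpecimen:
    it = iter(lines)
    first = next(it)
    if not first.upper().startswith("LM="):
        raise TpsParseError(f"line {lineno}: block must start with LM=, got {first!r}")
    n_lm = int(first.split("=", 1)[1])
    landmarks = []
    for _ in range(n_lm):
        try:
            x, y = next(it).split()
        except (StopIteration, ValueError) as exc:
            raise TpsParseError(f"block at line {lineno}: LM count mismatch") from exc
        landmarks.append((float(x), float(y)))

    curves: list[np.ndarray] = []
    spec_id = None
    image = None
    scale = None
    tok = next(it, None)
    if tok is not None and tok.upper().startswith("CURVES="):
        n_curves = int(tok.split("=", 1)[1])
        for _ in range(n_curves):
            ptok = next(it, None)
            if ptok is None or not ptok.upper().startswith("POINTS="):
                raise TpsParseError(
                    f"block at line {lineno}: missing POINTS= for a curve"
                )
            n_pts = int(ptok.split("=", 1)[1])
            pts = []
            for _ in range(n_pts):
                try:
                    x, y = next(it).split()
                except (StopIteration, ValueError) as exc:
                    raise TpsParseError(
                        f"block at line {lineno}: POINTS count mismatch"
                    ) from exc
                pts.append((float(x), float(y)))
            curves.append(np.asarray(pts))
        tok = next(it, None)
    while tok is not None:
        up = tok.upper()
        if up.startswith("IMAGE="):
            image = tok.split("=", 1)[1]
        elif up.startswith("ID="):
            spec_id = tok.split("=", 1)[1]
        elif up.startswith("SCALE="):
            scale = float(tok.split("=", 1)[1])
        else:
            raise TpsParseError(f"block at line {lineno}: unrecognized record {tok!r}")
        tok = next(it, None)

    if spec_id is None:
        raise TpsParseError(f"block at line {lineno}: missing ID= record")

    lm = np.asarray(landmarks)
    if scale is not None:
        lm = lm * scale
        curves = [c * scale for c in curves]
    try:
        return RawSpecimen(
            specimen_id=spec_id, fixed_landmarks=lm, curves=curves,
            image=image, scale=scale,
        )
    except ValueError as exc:
        raise TpsParseError(f"specimen {spec_id!r}: {exc}") from exc


def read_tps(path: str | Path, metadata: pd.DataFrame | None = None) -> list[RawSpecimen]:
    """Read a TPS file; optionally join taxon/tooth/side metadata by specimen ID.

    Parameters
    ----------
    path:
        TPS file in the tpsDig dialect.
    metadata:
        Optional table with columns specimen_id, taxon, tooth, side.

    Raises
    ------
    TpsParseError
        On a malformed block, naming the offending ID or line.
    KeyError
        If a specimen ID is missing from ``metadata``.
    """
    lines = [
        ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    blocks: list[tuple[int, list[str]]] = []
    current: list[str] = []
    start = 1
    for i, ln in enumerate(lines, start=1):
        if ln.upper().startswith("LM=") and current:
            blocks.append((start, current))
            current, start = [], i
        current.append(ln)
    if current:
        blocks.append((start, current))
    specimens = [_parse_block(b, n) for n, b in blocks]
    if metadata is not None:
        specimens = attach_metadata(specimens, metadata)
    return specimens


def write_tps(path: str | Path, specimens: list[RawSpecimen]) -> None:
    """Write specimens in the same dialect ``read_tps`` consumes.

    Coordinates are written as stored (already in physical units), so no
    SCALE= record is emitted and read∘write is the identity.
    """
    out = []
    for s in specimens:
        out.append(f"LM={len(s.fixed_landmarks)}")
        out.extend(f"{x:.12g} {y:.12g}" for x, y in s.fixed_landmarks)
        out.append(f"CURVES={len(s.curves)}")
        for c in s.curves:
            out.append(f"POINTS={len(c)}")
            out.extend(f"{x:.12g} {y:.12g}" for x, y in c)
        if s.image:
            out.append(f"IMAGE={s.image}")
        out.append(f"ID={s.specimen_id}")
    Path(path).write_text("\n".join(out) + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the companion metadata table (specimen_id, taxon, tooth, side)."""
    df = pd.read_csv(path, dtype=str)
    required = {"specimen_id", "taxon", "tooth", "side"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    return df


def attach_metadata(
    specimens: list[RawSpecimen], metadata: pd.DataFrame
) -> list[RawSpecimen]:
    """Join taxon/tooth/side onto specimens, keyed by specimen ID."""
    table = metadata.set_index("specimen_id")
    out = []
    for s in specimens:
        if s.specimen_id not in table.index:
            raise KeyError(f"unmatched specimen: {s.specimen_id!r} not in metadata")
        row = table.loc[s.specimen_id]
        out.append(
            replace(
                s,
                taxon_code=str(row["taxon"]),
                tooth_position=str(row["tooth"]),
                side=str(row["side"]),
            )
        )
    return out


def mirror_to_left(spec: RawSpecimen) -> RawSpecimen:
    """Reflect a right-side digitization to the left-side convention.

    X coordinates are negated about the configuration's centroid (so the
    points stay in the positive quadrant); ordering is unchanged and the
    reflection is an isometry, preserving centroid size exactly.
    """
    if spec.side != "right":
        warnings.warn(
            f"mirror_to_left: specimen {spec.specimen_id} is not right-sided; no-op"
        )
        return spec
    all_pts = np.vstack([spec.fixed_landmarks, *spec.curves])
    cx = all_pts[:, 0].mean()

    def refl(p: np.ndarray) -> np.ndarray:
        q = p.copy()
        q[:, 0] = 2.0 * cx - q[:, 0]
        return q

    return replace(
        spec,
        fixed_landmarks=refl(spec.fixed_landmarks),
        curves=[refl(c) for c in spec.curves],
        side="left",
    )
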