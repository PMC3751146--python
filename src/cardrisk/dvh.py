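"""Dose-volume histogram containers, conversions and plain-text I/O.

A differential DVH stores the fraction of an organ's volume receiving a
dose inside each dose bin; a cumulative DVH stores the fraction receiving
at least a threshold dose.  All volumes here are *fractional* (they sum to
one): every downstream dose-response computation only ever uses relative
subvolumes, so absolute organ volumes in cm^3 are never needed and are
normalised away on read.

Doses carry a unit tag, either ``Gy`` (absorbed dose / RBE-weighted
prescription dose) or ``Sv`` (equivalent dose after radiation weighting).
Operations that would silently mix the two raise instead; an explicit
weighting step (see :mod:`cardrisk.radiobiology`) performs the conversion.

The on-disk format is a two-column delimited text file with a one-line
header::

    # structure=whole_heart unit=Gy kind=differential binwidth=0.05
    0.025\t0.0013
    0.075\t0.0021
    ...

Binary formats (DICOM RT-DOSE etc.) are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DVHError",
    "DVHParseError",
    "DifferentialDVH",
    "CumulativeDVH",
    "mean_dose",
    "differential_to_cumulative",
    "cumulative_to_differential",
    "rebin",
    "read_dvh",
    "write_dvh",
]

#: absolute tolerance on the fractional-volume sum
VOLUME_TOL = 1e-9

_UNITS = ("Gy", "Sv")


class DVHError(ValueError):
    """A DVH violates its structural invariants."""


class DVHParseError(DVHError):
    """A DVH text file is malformed; the message names the offending line."""


def _as_readonly(a) -> np.ndarray:
    out = np.asarray(a, dtype=float).copy()
    out.flags.writeable = False
    return out


@dataclass(frozen=True)
class DifferentialDVH:
    """Differential dose-volume histogram on bin-center doses.

    Parameters
    ----------
    structure
        Anatomical structure label (no whitespace; use underscores).
    dose_unit
        ``"Gy"`` or ``"Sv"``.
    doses
        Bin-center doses, strictly increasing, all >= 0.
    volumes
        Fractional volumes per bin, >= 0, summing to 1 within 1e-9.
    bin_width
        Common bin width for a uniform grid, or ``None`` for a non-uniform
        dose axis (e.g. after a non-linear fractionation correction).
    """

    structure: str
    dose_unit: str
    doses: np.ndarray
    volumes: np.ndarray
    bin_width: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", _as_readonly(self.doses))
        object.__setattr__(self, "volumes", _as_readonly(self.volumes))
        self.validate()

    def validate(self) -> None:
        if self.dose_unit not in _UNITS:
            raise DVHError(f"unknown dose unit {self.dose_unit!r}; expected one of {_UNITS}")
        d, v = self.doses, self.volumes
        if d.ndim != 1 or v.ndim != 1 or d.size != v.size or d.size == 0:
            raise DVHError("doses and volumes must be equal-length, non-empty 1-D arrays")
        if np.any(v < 0):
            raise DVHError("negative fractional volume")
        total = float(v.sum())
        if abs(total - 1.0) > VOLUME_TOL:
            raise DVHError(f"fractional volumes sum to {total!r}, not 1 within {VOLUME_TOL}")
        if np.any(d < 0):
            raise DVHError("negative dose bin center")
        if d.size > 1 and np.any(np.diff(d) <= 0):
            raise DVHError("bin-center doses must be strictly increasing")
        if self.bin_width is not None:
            if not self.bin_width > 0:
                raise DVHError("bin_width must be positive")
            if d.size > 1:
                spacing = np.diff(d)
                if np.any(np.abs(spacing - self.bin_width) > 1e-6 * self.bin_width):
                    raise DVHError("bin spacing does not match declared bin_width")

    # -- summaries -----------------------------------------------------
    def mean_dose(self) -> float:
        """Volume-weighted mean dose, sum(v_i * D_i)."""
        return float(np.dot(self.volumes, self.doses))

    def max_dose(self) -> float:
        """Largest bin-center dose carrying non-zero volume (0 if empty)."""
        nz = np.nonzero(self.volumes)[0]
        return float(self.doses[nz[-1]]) if nz.size else 0.0

    def with_doses(self, doses, bin_width: float | None = None) -> "DifferentialDVH":
        """Return a copy on a new dose axis, volumes unchanged."""
        return DifferentialDVH(self.structure, self.dose_unit, doses, self.volumes, bin_width)

    def edges(self) -> np.ndarray:
        """Bin edges implied by the centers (uniform or midpoint-based)."""
        d = self.doses
        if self.bin_width is not None:
            w = self.bin_width
            e = np.concatenate([d - w / 2.0, [d[-1] + w / 2.0]])
        elif d.size >= 2:
            mid = (d[:-1] + d[1:]) / 2.0
            e = np.concatenate([[d[0] - (mid[0] - d[0])], mid, [d[-1] + (d[-1] - mid[-1])]])
        else:
            raise DVHError("bin edges of a single-bin DVH require an explicit bin_width")
        return np.maximum(e, 0.0)


@dataclass(frozen=True)
class CumulativeDVH:
    """Cumulative DVH: fraction of volume receiving at least each threshold."""

    structure: str
    dose_unit: str
    thresholds: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "thresholds", _as_readonly(self.thresholds))
        object.__setattr__(self, "volumes", _as_readonly(self.volumes))
        self.validate()

    def validate(self) -> None:
        if self.dose_unit not in _UNITS:
            raise DVHError(f"unknown dose unit {self.dose_unit!r}; expected one of {_UNITS}")
        t, v = self.thresholds, self.volumes
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size or t.size < 2:
            raise DVHError("thresholds and volumes must be equal-length arrays with >= 2 points")
        if np.any(np.diff(t) <= 0):
            raise DVHError("thresholds must be strictly increasing")
        if np.any(t < 0):
            raise DVHError("negative dose threshold")
        if np.any(np.diff(v) > VOLUME_TOL):
            raise DVHError("cumulative volume must be non-increasing in dose")
        if abs(float(v[0]) - 1.0) > VOLUME_TOL:
            raise DVHError("cumulative DVH must start at volume fraction 1")
        if float(v[-1]) < -VOLUME_TOL:
            raise DVHError("cumulative volume fraction below 0")

    def volume_at(self, dose: float) -> float:
        """Volume fraction receiving at least `dose` (step interpolation)."""
        if dose <= self.thresholds[0]:
            return float(self.volumes[0])
        idx = int(np.searchsorted(self.thresholds, dose, side="right")) - 1
        return float(self.volumes[idx])


def mean_dose(dvh: DifferentialDVH) -> float:
    """Volume-weighted mean dose of a differential DVH."""
    return dvh.mean_dose()


def differential_to_cumulative(dvh: DifferentialDVH) -> CumulativeDVH:
    """Convert to cumulative form on the bin edges.

    The cumulative volume at threshold d is the total fractional volume in
    bins whose center dose is >= d; evaluated at every bin edge this gives
    an exactly volume-conserving staircase whose round trip through
    :func:`cumulative_to_differential` recovers the input.
    """
    e = dvh.edges()
    tail = np.concatenate([np.cumsum(dvh.volumes[::-1])[::-1], [0.0]])
    return CumulativeDVH(dvh.structure, dvh.dose_unit, e, tail)


def cumulative_to_differential(cdvh: CumulativeDVH) -> DifferentialDVH:
    """Invert :func:`differential_to_cumulative` (bin centers at edge midpoints)."""
    t, v = cdvh.thresholds, cdvh.volumes
    centers = (t[:-1] + t[1:]) / 2.0
    vols = -np.diff(v)
    vols = np.clip(vols, 0.0, None)
    total = float(v[0] - v[-1])
    if abs(total - 1.0) > VOLUME_TOL:
        raise DVHError("cumulative DVH does not bracket the full volume; cannot normalise")
    spacing = np.diff(t)
    width = float(spacing[0]) if np.allclose(spacing, spacing[0], rtol=1e-6, atol=0.0) else None
    return DifferentialDVH(cdvh.structure, cdvh.dose_unit, centers, vols, width)


def rebin(dvh: DifferentialDVH, new_bin_width: float) -> DifferentialDVH:
    """Rebin onto a uniform grid by conservative overlap redistribution.

    Volume in each source bin is treated as uniformly distributed across
    the bin and split among destination bins in proportion to overlap, so
    total volume is conserved exactly and the mean dose moves by less than
    one source bin width.
    """
    if not new_bin_width > 0:
        raise DVHError("new bin width must be positive")
    old_edges = dvh.edges()
    n_new = max(1, int(math.ceil(old_edges[-1] / new_bin_width - 1e-12)))
    new_edges = np.arange(n_new + 1) * new_bin_width
    widths = np.diff(old_edges)
    if np.any(widths <= 0):
        raise DVHError("degenerate source bins")
    new_v = np.zeros(n_new)
    lo = np.maximum.outer(new_edges[:-1], old_edges[:-1])
    hi = np.minimum.outer(new_edges[1:], old_edges[1:])
    overlap = np.clip(hi - lo, 0.0, None)
    new_v = overlap @ (dvh.volumes / widths)
    new_v /= new_v.sum()
    centers = (new_edges[:-1] + new_edges[1:]) / 2.0
    return DifferentialDVH(dvh.structure, dvh.dose_unit, centers, new_v, new_bin_width)


# ---------------------------------------------------------------------------
# plain-text I/O

def write_dvh(dvh: DifferentialDVH | CumulativeDVH, path) -> None:
    """Write a DVH as header + two tab-separated float columns (full precision)."""
    path = Path(path)
    if isinstance(dvh, DifferentialDVH):
        kind = "differential"
        bw = "none" if dvh.bin_width is None else repr(float(dvh.bin_width))
        header = f"# structure={dvh.structure} unit={dvh.dose_unit} kind={kind} binwidth={bw}\n"
        x, y = dvh.doses, dvh.volumes
    elif isinstance(dvh, CumulativeDVH):
        header = f"# structure={dvh.structure} unit={dvh.dose_unit} kind=cumulative\n"
        x, y = dvh.thresholds, dvh.volumes
    else:
        raise TypeError(f"not a DVH: {type(dvh).__name__}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        for xi, yi in zip(x, y):
            fh.write(f"{float(xi)!r}\t{float(yi)!r}\n")


def _parse_header(line: str) -> dict:
    if not line.startswith("#"):
        raise DVHParseError("line 1: missing '#' header line")
    fields = {}
    for token in line[1:].split():
        if "=" not in token:
            raise DVHParseError(f"line 1: malformed header token {token!r}")
        key, _, value = token.partition("=")
        fields[key] = value
    for required in ("structure", "unit", "kind"):
        if required not in fields:
            raise DVHParseError(f"line 1: header missing {required}=")
    if fields["unit"] not in _UNITS:
        raise DVHParseError(f"line 1: unknown unit {fields['unit']!r}")
    if fields["kind"] not in ("differential", "cumulative"):
        raise DVHParseError(f"line 1: unknown kind {fields['kind']!r}")
    return fields


def read_dvh(path) -> DifferentialDVH | CumulativeDVH:
    """Read a DVH text file; errors name the offending line number."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise DVHParseError("line 1: empty file")
    header = _parse_header(lines[0])
    xs, ys = [], []
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise DVHParseError(f"line {lineno}: expected 2 columns, found {len(parts)}")
        try:
            x, y = float(parts[0]), float(parts[1])
        except ValueError:
            raise DVHParseError(f"line {lineno}: non-numeric value in {line!r}") from None
        if xs and x <= xs[-1]:
            raise DVHParseError(f"line {lineno}: dose axis not strictly increasing")
        xs.append(x)
        ys.append(y)
    if not xs:
        raise DVHParseError("line 2: no data rows")
    try:
        if header["kind"] == "differential":
            bw_raw = header.get("binwidth", "none")
            bw = None if bw_raw == "none" else float(bw_raw)
            vols = np.asarray(ys, dtype=float)
            total = vols.sum()
            if total <= 0:
                raise DVHError("total volume is not positive")
            if abs(total - 1.0) > VOLUME_TOL:
                # absolute volumes (e.g. cm^3 TPS export): normalise on read
                vols = vols / total
            return DifferentialDVH(header["structure"], header["unit"], xs, vols, bw)
        return CumulativeDVH(header["structure"], header["unit"], xs, ys)
    except DVHError as exc:
        raise DVHParseError(f"{path.name}: {exc}") from exc
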