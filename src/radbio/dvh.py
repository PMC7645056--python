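"""Dose-volume histogram (DVH) data model, ASCII I/O and dose-volume metrics.

A DVH summarises a 3-D dose distribution within one contoured structure as a
curve of volume against dose.  Two equivalent representations are supported:

* **cumulative** -- ``V(D)``, the volume receiving at least dose ``D``,
  tabulated at a strictly increasing list of dose points starting at 0;
* **differential** -- the volume falling inside each dose bin
  ``[edge_i, edge_{i+1})``, with one value per bin (``len(edges) == bins+1``).

Doses are in Gray-equivalent (GyE), treated as numerically identical to Gy;
volumes are either percent of the structure or absolute cc, with the absolute
total volume always attached so the two units interconvert.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "DoseVolumeHistogram",
    "FractionationScheme",
    "PlanRecord",
    "DVHError",
    "DVHParseError",
    "read_dvh",
    "write_dvh",
    "to_differential",
    "to_cumulative",
    "volume_at_dose",
    "dose_at_volume",
    "d_max",
    "d_mean",
    "combine_structures",
    "resample_cumulative",
]

#: default internal resampling grid spacing, GyE
DEFAULT_BIN_WIDTH = 0.1

_REL_TOL = 1e-6


class DVHError(ValueError):
    """Invalid DVH content (failed invariant, wrong mode, bad units)."""


class DVHParseError(DVHError):
    """Malformed DVH file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class FractionationScheme:
    """Prescription dose (GyE), number of fractions and tissue alpha/beta (Gy)."""

    prescription_dose: float
    n_fractions: int
    alpha_beta: float

    def __post_init__(self):
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be > 0")
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ValueError("n_fractions must be a positive integer")
        if self.alpha_beta <= 0:
            raise ValueError("alpha_beta must be > 0")

    @property
    def dose_per_fraction(self) -> float:
        return self.prescription_dose / self.n_fractions


@dataclass(frozen=True)
class DoseVolumeHistogram:
    """One structure's dose-volume curve.

    Parameters
    ----------
    structure_label : str
        Name of the contoured structure.
    total_volume : float
        Absolute structure volume in cc (> 0).
    dose : ndarray
        Strictly increasing dose values in GyE starting at 0.  For
        ``mode='cumulative'`` these are the tabulation points (one volume
        value each); for ``mode='differential'`` they are the bin edges
        (one volume value per bin, so ``len(values) == len(dose) - 1``).
    values : ndarray
        Volumes, in ``volume_unit``.
    mode : {'cumulative', 'differential'}
    volume_unit : {'percent', 'cc'}
    dose_space : {'physical', 'eqd2'}
        Whether doses are physical or already converted to the equivalent
        dose in 2-Gy fractions.
    """

    structure_label: str
    total_volume: float
    dose: np.ndarray
    values: np.ndarray
    mode: str = "cumulative"
    volume_unit: str = "percent"
    dose_space: str = "physical"

    def __post_init__(self):
        object.__setattr__(self, "dose", np.asarray(self.dose, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        self._validate()

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        if self.mode not in ("cumulative", "differential"):
            raise DVHError(f"unknown mode {self.mode!r}")
        if self.volume_unit not in ("percent", "cc"):
            raise DVHError(f"unknown volume_unit {self.volume_unit!r}")
        if self.dose_space not in ("physical", "eqd2"):
            raise DVHError(f"unknown dose_space {self.dose_space!r}")
        if not self.total_volume > 0:
            raise DVHError("total_volume must be > 0")
        d, v = self.dose, self.values
        if d.ndim != 1 or v.ndim != 1:
            raise DVHError("dose and values must be 1-D")
        if d.size < 2:
            raise DVHError("need at least two dose points")
        if d[0] != 0:
            raise DVHError("dose axis must start at 0")
        if np.any(np.diff(d) <= 0):
            raise DVHError("dose values must be strictly increasing")
        if self.mode == "cumulative":
            if v.size != d.size:
                raise DVHError("cumulative DVH needs one volume per dose point")
            if np.any(np.diff(v) > self.full_volume * _REL_TOL):
                raise DVHError("cumulative volumes must be non-increasing")
            if abs(v[0] - self.full_volume) > self.full_volume * 1e-3:
                raise DVHError(
                    "cumulative volume at zero dose must equal the full volume"
                )
            if np.any(v < -self.full_volume * _REL_TOL):
                raise DVHError("negative volume")
        else:
            if v.size != d.size - 1:
                raise DVHError("differential DVH needs len(dose) == len(values)+1")
            if np.any(v < -self.full_volume * _REL_TOL):
                raise DVHError("negative bin volume")
            total = v.sum()
            if abs(total - self.full_volume) > self.full_volume * _REL_TOL:
                raise DVHError(
                    f"differential volumes sum to {total:g}, expected "
                    f"{self.full_volume:g}"
                )

    # -- helpers ---------------------------------------------------------

    @property
    def full_volume(self) -> float:
        """100 (percent) or total_volume (cc) -- the value at zero dose."""
        return 100.0 if self.volume_unit == "percent" else self.total_volume

    def as_unit(self, unit: str) -> "DoseVolumeHistogram":
        """Return this DVH with volumes expressed in ``unit`` (percent or cc)."""
        if unit == self.volume_unit:
            return self
        if unit == "cc":
            factor = self.total_volume / 100.0
        elif unit == "percent":
            factor = 100.0 / self.total_volume
        else:
            raise DVHError(f"unknown volume_unit {unit!r}")
        return replace(self, values=self.values * factor, volume_unit=unit)

    @property
    def bin_midpoints(self) -> np.ndarray:
        if self.mode != "differential":
            raise DVHError("bin_midpoints defined for differential DVHs only")
        return 0.5 * (self.dose[:-1] + self.dose[1:])


@dataclass
class PlanRecord:
    """One patient x one treatment modality: a labelled set of DVHs."""

    patient_id: str
    modality: str
    dvhs: dict[str, DoseVolumeHistogram] = field(default_factory=dict)
    fractionation: FractionationScheme | None = None

    def __post_init__(self):
        for label, dvh in self.dvhs.items():
            if label != dvh.structure_label:
                raise ValueError(
                    f"key {label!r} does not match structure {dvh.structure_label!r}"
                )

    def __getitem__(self, label: str) -> DoseVolumeHistogram:
        try:
            return self.dvhs[label]
        except KeyError:
            raise KeyError(
                f"structure {label!r} not in plan {self.patient_id}/{self.modality}"
            ) from None

    def add(self, dvh: DoseVolumeHistogram) -> None:
        if dvh.structure_label in self.dvhs:
            raise ValueError(f"duplicate structure {dvh.structure_label!r}")
        self.dvhs[dvh.structure_label] = dvh


# ---------------------------------------------------------------------------
# ASCII I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = {
    "structure",
    "total_volume_cc",
    "mode",
    "volume_unit",
    "dose_unit",
    "dose_space",
}


def read_dvh(path) -> DoseVolumeHistogram:
    """Read one DVH from the package's ASCII dialect.

    The dialect is UTF-8 text with ``# key: value`` header lines
    (structure, total_volume_cc, mode, volume_unit, dose_unit) followed by
    two comma-separated columns ``dose,volume``.
    """
    header: dict[str, str] = {}
    doses: list[float] = []
    vols: list[float] = []
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" not in body:
                raise DVHParseError(f"malformed header {line!r}", lineno)
            key, _, value = body.partition(":")
            key = key.strip()
            if key not in _HEADER_KEYS:
                raise DVHParseError(f"unknown header key {key!r}", lineno)
            header[key] = value.strip()
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise DVHParseError("expected 'dose,volume'", lineno)
        try:
            doses.append(float(parts[0]))
            vols.append(float(parts[1]))
        except ValueError:
            raise DVHParseError(f"non-numeric row {line!r}", lineno) from None
        if vols[-1] < 0:
            raise DVHParseError(f"negative volume {vols[-1]:g}", lineno)

    for req in ("structure", "total_volume_cc", "mode", "volume_unit"):
        if req not in header:
            raise DVHParseError(f"missing required header '# {req}:'")
    if header.get("dose_unit", "GyE") not in ("GyE", "Gy"):
        raise DVHParseError(f"unsupported dose_unit {header['dose_unit']!r}")
    try:
        total = float(header["total_volume_cc"])
    except ValueError:
        raise DVHParseError("total_volume_cc is not numeric") from None

    mode = header["mode"]
    dose = np.array(doses)
    values = np.array(vols)
    if mode == "differential" and values.size >= 2:
        # the final row is the closing bin edge; its volume slot is unused
        values = values[:-1]
    if mode == "cumulative" and values.size and np.any(np.diff(values) > 0):
        bad = int(np.argmax(np.diff(values) > 0))
        raise DVHParseError(
            "cumulative volume increases with dose", line=_data_lineno(text, bad + 1)
        )
    try:
        return DoseVolumeHistogram(
            structure_label=header["structure"],
            total_volume=total,
            dose=dose,
            values=values,
            mode=mode,
            volume_unit=header["volume_unit"],
            dose_space=header.get("dose_space", "physical"),
        )
    except DVHError as exc:
        raise DVHParseError(str(exc)) from exc


def _data_lineno(text: str, data_index: int) -> int | None:
    """Line number of the ``data_index``-th (0-based) data row."""
    count = -1
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        count += 1
        if count == data_index:
            return lineno
    return None


def write_dvh(dvh: DoseVolumeHistogram, path) -> None:
    """Write ``dvh`` in the ASCII dialect; ``read_dvh`` round-trips it."""
    buf = io.StringIO()
    buf.write(f"# structure: {dvh.structure_label}\n")
    buf.write(f"# total_volume_cc: {dvh.total_volume!r}\n")
    buf.write(f"# mode: {dvh.mode}\n")
    buf.write(f"# volume_unit: {dvh.volume_unit}\n")
    buf.write("# dose_unit: GyE\n")
    if dvh.dose_space != "physical":
        buf.write(f"# dose_space: {dvh.dose_space}\n")
    if dvh.mode == "cumulative":
        rows = zip(dvh.dose, dvh.values)
    else:
        # differential: emit edges; the final edge carries an empty volume slot
        rows = zip(dvh.dose, list(dvh.values) + [0.0])
    for d, v in rows:
        buf.write(f"{float(d)!r},{float(v)!r}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# representation conversions
# ---------------------------------------------------------------------------


def to_differential(dvh: DoseVolumeHistogram) -> DoseVolumeHistogram:
    """Convert a cumulative DVH to differential form.

    Bin ``[d_i, d_{i+1})`` receives ``V(d_i) - V(d_{i+1})``.  Any residual
    volume at the last tabulated dose is placed in one appended trailing bin
    of the median bin width (generated curves always end at zero volume, so
    this path is an edge-case approximation for truncated exports).
    """
    if dvh.mode != "cumulative":
        raise DVHError("to_differential expects a cumulative DVH")
    edges = dvh.dose
    vols = -np.diff(dvh.values)
    vols = np.clip(vols, 0.0, None)  # tolerate tiny negative noise
    residual = dvh.values[-1]
    if residual > dvh.full_volume * _REL_TOL:
        width = float(np.median(np.diff(edges)))
        edges = np.append(edges, edges[-1] + width)
        vols = np.append(vols, residual)
    # conserve total exactly against clipping round-off
    total = vols.sum()
    if total > 0:
        vols = vols * (dvh.values[0] / total)
    return replace(dvh, dose=edges, values=vols, mode="differential")


def to_cumulative(dvh: DoseVolumeHistogram) -> DoseVolumeHistogram:
    """Convert a differential DVH to cumulative form on the same edge grid."""
    if dvh.mode != "differential":
        raise DVHError("to_cumulative expects a differential DVH")
    # cumulative value at edge j = sum of bins at or above that edge
    cum = np.concatenate([np.cumsum(dvh.values[::-1])[::-1], [0.0]])
    return replace(dvh, values=cum, mode="cumulative")


def _as_cumulative(dvh: DoseVolumeHistogram) -> DoseVolumeHistogram:
    return dvh if dvh.mode == "cumulative" else to_cumulative(dvh)


def resample_cumulative(
    dvh: DoseVolumeHistogram, new_dose: np.ndarray
) -> DoseVolumeHistogram:
    """Linearly resample the cumulative curve onto ``new_dose`` (must start at 0)."""
    cum = _as_cumulative(dvh)
    new_dose = np.asarray(new_dose, dtype=float)
    vals = np.interp(new_dose, cum.dose, cum.values, right=0.0)
    vals = np.minimum.accumulate(vals)  # guard monotonicity against fp noise
    return replace(cum, dose=new_dose, values=vals, mode="cumulative")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def volume_at_dose(
    dvh: DoseVolumeHistogram, dose: float, unit: str = "percent"
) -> float:
    """V_dose: volume receiving at least ``dose`` GyE, by linear interpolation."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    cum = _as_cumulative(dvh).as_unit(unit)
    return float(np.interp(dose, cum.dose, cum.values, right=0.0))


def dose_at_volume(dvh: DoseVolumeHistogram, volume_percent: float) -> float:
    """D_x%: minimum dose received by the hottest ``volume_percent`` of the structure.

    Inverse linear interpolation of the cumulative curve; on flat segments the
    tie is broken toward the higher dose.
    """
    if not 0 <= volume_percent <= 100:
        raise ValueError("volume_percent must be in [0, 100]")
    cum = _as_cumulative(dvh).as_unit("percent")
    d, v = cum.dose, cum.values
    target = volume_percent
    if target <= v[-1]:
        return float(d[-1])
    if target >= v[0]:
        return float(d[0])
    # scan from the high-dose end: first index (largest dose) with v >= target
    idx = np.nonzero(v >= target)[0][-1]
    if v[idx] == target:
        return float(d[idx])  # highest dose attaining the value exactly
    d0, d1 = d[idx], d[idx + 1]
    v0, v1 = v[idx], v[idx + 1]
    return float(d0 + (target - v0) * (d1 - d0) / (v1 - v0))


def d_max(dvh: DoseVolumeHistogram) -> float:
    """Near-maximum dose: midpoint of the highest differential bin with volume.

    A DVH no longer carries the single hottest voxel, so the point Dmax of the
    3-D dose grid is approximated by the midpoint of the last occupied bin.
    """
    diff = dvh if dvh.mode == "differential" else to_differential(dvh)
    nz = np.nonzero(diff.values > diff.full_volume * _REL_TOL)[0]
    if nz.size == 0:
        return 0.0
    return float(diff.bin_midpoints[nz[-1]])


def d_mean(dvh: DoseVolumeHistogram) -> float:
    """Mean dose: sum of fractional bin volume times bin-midpoint dose."""
    diff = dvh if dvh.mode == "differential" else to_differential(dvh)
    w = diff.values / diff.values.sum()
    return float(np.sum(w * diff.bin_midpoints))


def combine_structures(
    a: DoseVolumeHistogram,
    b: DoseVolumeHistogram,
    label: str | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> DoseVolumeHistogram:
    """Union of two non-overlapping structures (e.g. stomach + duodenum).

    Both DVHs are converted to absolute (cc) cumulative curves, resampled to a
    shared grid and added; the composite total volume is the sum.
    """
    if a.dose_space != b.dose_space:
        raise DVHError("cannot combine DVHs from different dose spaces")
    ca = _as_cumulative(a).as_unit("cc")
    cb = _as_cumulative(b).as_unit("cc")
    top = max(ca.dose[-1], cb.dose[-1])
    n = int(np.ceil(top / bin_width)) + 1
    grid = np.linspace(0.0, n * bin_width, n + 1)
    va = np.interp(grid, ca.dose, ca.values, right=0.0)
    vb = np.interp(grid, cb.dose, cb.values, right=0.0)
    return DoseVolumeHistogram(
        structure_label=label or f"{a.structure_label}+{b.structure_label}",
        total_volume=a.total_volume + b.total_volume,
        dose=grid,
        values=va + vb,
        mode="cumulative",
        volume_unit="cc",
        dose_space=a.dose_space,
    )


def dvh_from_samples(
    samples: Iterable[float],
    structure_label: str = "structure",
    total_volume: float = 100.0,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> DoseVolumeHistogram:
    """Build a differential DVH from equal-volume raw dose samples.

    Convenience for testing and for emulating voxel dose lists: each sample
    stands for an equal share of the structure volume.
    """
    samples = np.asarray(list(samples), dtype=float)
    if samples.size == 0:
        raise ValueError("need at least one dose sample")
    if np.any(samples < 0):
        raise ValueError("negative dose sample")
    n_bins = max(1, int(np.ceil((samples.max() + 1e-12) / bin_width)))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts, _ = np.histogram(samples, bins=edges)
    values = counts / samples.size * 100.0
    return DoseVolumeHistogram(
        structure_label=structure_label,
        total_volume=total_volume,
        dose=edges,
        values=values,
        mode="differential",
        volume_unit="percent",
    )
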