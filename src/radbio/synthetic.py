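"""Synthetic pancreatic-cancer planning cohort.

Generates a reproducible virtual cohort (default 24 patients, three plans
each: IMRT, VMAT and passive-scattering proton archetypes) of per-structure
DVHs carrying the statistical structure a paired plan-comparison analysis
assumes:

* patient geometry (CTV/PTV volumes, PTV-OAR overlap fractions) drawn to
  match the published cohort's summary statistics;
* GI-OAR DVHs built as a mixture of a high-dose plateau (fractional volume
  tracking the PTV overlap, falling off logistically around the
  prescription dose and tapering to zero at a per-plan truncation dose), a
  modality-common intermediate shoulder (the 30-45 GyE region differs
  little between techniques), and a modality-specific low-dose "bath"
  decaying exponentially -- the proton archetype carries a markedly smaller
  bath and a lower truncation (near-maximum) dose than either photon
  archetype;
* parallel organs (kidneys, liver) and the cord as bath-only curves;
* near-uniform target DVHs normalised so that exactly 50% of the PTV
  receives the full prescription (D50% = prescription), plus ground-truth
  conformity inputs (TV95, V95) that a per-structure DVH cannot supply.

Randomness is counter-based: every (patient, structure, modality-slot)
triple owns an independent stream derived from the single global seed, so
any subset of the cohort regenerates bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .dvh import (
    DEFAULT_BIN_WIDTH,
    DoseVolumeHistogram,
    FractionationScheme,
    PlanRecord,
    combine_structures,
)

__all__ = [
    "PatientGeometry",
    "ModalityArchetype",
    "SyntheticCohort",
    "DEFAULT_ARCHETYPES",
    "DEFAULT_SCHEME",
    "DEFAULT_SEED",
    "sample_geometry",
    "generate_oar_dvh",
    "generate_target_dvh",
    "build_cohort",
]

DEFAULT_SEED = 2020
GI_STRUCTURES = ("stomach", "duodenum", "small_bowel")

#: standard fractionation: 50.4 GyE in 28 fractions, alpha/beta = 4 Gy (GI)
DEFAULT_SCHEME = FractionationScheme(
    prescription_dose=50.4, n_fractions=28, alpha_beta=4.0
)

# cohort geometry calibration (mean, SD)
_CTV_STATS = (79.90, 46.85)  # cc
_PTV_STATS = (198.06, 74.04)  # cc
_OVERLAP_STATS = {  # % of PTV overlapping each GI OAR
    "stomach": (7.15, 5.77),
    "duodenum": (5.52, 5.24),
    "small_bowel": (2.76, 2.01),
}
_OVERLAP_MAX = 25.0  # observed overlaps never exceeded ~24% of the PTV

# typical contoured absolute volumes (cc); CV 0.25 log-normal spread
_OAR_VOLUME_MEANS = {
    "stomach": 200.0,
    "duodenum": 70.0,
    "small_bowel": 180.0,
    "kidneys": 340.0,
    "liver": 1500.0,
    "spinal_cord": 35.0,
}

# per-structure adjustments to the archetype plateau (GyE): the duodenum
# sits hardest against the target and tolerates 55 GyE, the small bowel is
# intermediate, the stomach falls off earliest
_STRUCT_EDGE_OFFSET = {"stomach": 0.0, "duodenum": 2.3, "small_bowel": 1.7}
_STRUCT_CAP_OFFSET = {"stomach": 0.0, "duodenum": -1.3, "small_bowel": -0.7}
_STRUCT_CAP_LIMIT = {"stomach": 53.9, "duodenum": 54.9, "small_bowel": 53.9}
# relative bath intensity by anatomical proximity to the target
_STRUCT_BATH_FACTOR = {"stomach": 1.0, "duodenum": 1.45, "small_bowel": 0.85}
# intermediate-dose shoulder (common to all modalities: the 30-45 GyE region
# differs little between techniques, the proton benefit lives below ~30 GyE)
_STRUCT_MID_FRAC = {"stomach": 0.13, "duodenum": 0.19, "small_bowel": 0.05}
_MID_EDGE = 33.0
_MID_WIDTH = 5.5

# dose beyond which the bath (and, higher up, the shoulder) has died off and
# the conformal falloff owns the curve
_BATH_CUTOFF_DOSE = 32.0
_SHOULDER_CUTOFF_DOSE = 42.0
_CUTOFF_WIDTH = 2.5
# the volume density tapers quadratically to zero over the last stretch
# before the truncation dose, as real falloffs do near Dmax
_CAP_TAPER = 1.5

# noise scales: anatomy-driven spread shared by all three plans of a patient,
# plus a smaller plan-to-plan component
_SHARED_BATH_SIGMA = 0.25
_MODALITY_BATH_SIGMA = 0.10
_SHARED_EDGE_SIGMA = 0.60
_MODALITY_EDGE_SIGMA = 0.15
_CAP_SHARED_W, _CAP_MODALITY_W = 0.75, 0.66

_GRID_TOP = 55.0


def _grid() -> np.ndarray:
    n = int(round(_GRID_TOP / DEFAULT_BIN_WIDTH))
    return np.round(np.linspace(0.0, _GRID_TOP, n + 1), 10)


@dataclass(frozen=True)
class PatientGeometry:
    """Anatomy of one virtual patient."""

    patient_id: str
    ctv_volume: float
    ptv_volume: float
    overlap_fraction: dict[str, float]  # % of PTV overlapping each GI OAR
    oar_volumes: dict[str, float]  # cc

    def __post_init__(self):
        if not self.ptv_volume > self.ctv_volume > 0:
            raise ValueError("require ptv_volume > ctv_volume > 0")
        for s, f in self.overlap_fraction.items():
            if not 0 <= f <= _OVERLAP_MAX:
                raise ValueError(f"overlap fraction for {s} outside [0, {_OVERLAP_MAX}]")

    def plateau_fraction(self, structure: str) -> float:
        """Fraction of the OAR volume inside the high-dose plateau."""
        overlap_cc = self.overlap_fraction[structure] / 100.0 * self.ptv_volume
        return min(0.45, overlap_cc / self.oar_volumes[structure])


@dataclass(frozen=True)
class ModalityArchetype:
    """Parametric DVH shape of one delivery technique.

    ``bath_fraction`` is the fractional organ volume caught in the low-dose
    bath, ``bath_scale`` its exponential decay constant (GyE),
    ``tail_width`` the logistic falloff width near the prescription,
    ``plateau_edge`` the dose at which the conformal falloff is half-way
    down, ``cap_mean``/``cap_sd`` the near-maximum truncation dose of the
    curve, and ``hotspot_cap`` a hard upper bound on any dose.
    ``stream_slot`` indexes the plan's independent noise stream.
    """

    modality: str
    bath_fraction: float
    bath_scale: float
    tail_width: float
    plateau_edge: float
    cap_mean: float
    cap_sd: float
    hotspot_cap: float = 53.9
    stream_slot: int = 0
    ptv_hi_mean: float = 0.10
    ptv_cn_mean: float = 0.82
    # bath-only organs: structure -> (bath level, decay scale, cap mean, cap sd)
    organ_baths: dict = field(
        default_factory=lambda: {
            "kidneys": (0.45, 12.0, 26.0, 4.0),
            "liver": (0.28, 8.0, 30.0, 5.0),
            "spinal_cord": (0.60, 9.0, 20.6, 3.0),
        }
    )

    def __post_init__(self):
        for name in ("bath_fraction", "bath_scale", "tail_width", "hotspot_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


DEFAULT_ARCHETYPES = (
    ModalityArchetype(
        modality="IMRT",
        bath_fraction=0.52,
        bath_scale=13.0,
        tail_width=1.3,
        plateau_edge=47.6,
        cap_mean=52.4,
        cap_sd=0.8,
        stream_slot=0,
        ptv_hi_mean=0.10,
        ptv_cn_mean=0.82,
        organ_baths={
            "kidneys": (0.45, 12.0, 26.0, 4.0),
            "liver": (0.28, 8.0, 30.0, 5.0),
            "spinal_cord": (0.60, 9.0, 20.6, 3.0),
        },
    ),
    ModalityArchetype(
        modality="VMAT",
        bath_fraction=0.57,
        bath_scale=16.0,
        tail_width=1.3,
        plateau_edge=47.6,
        cap_mean=52.1,
        cap_sd=0.75,
        stream_slot=1,
        ptv_hi_mean=0.10,
        ptv_cn_mean=0.81,
        organ_baths={
            "kidneys": (0.55, 13.5, 28.0, 4.0),
            "liver": (0.42, 9.0, 32.0, 5.0),
            "spinal_cord": (0.60, 9.0, 19.3, 2.5),
        },
    ),
    ModalityArchetype(
        modality="PSPBT",
        bath_fraction=0.40,
        bath_scale=10.5,
        tail_width=1.25,
        plateau_edge=47.6,
        cap_mean=50.3,
        cap_sd=1.2,
        stream_slot=2,
        ptv_hi_mean=0.12,
        ptv_cn_mean=0.81,
        organ_baths={
            "kidneys": (0.30, 15.0, 25.0, 5.0),
            "liver": (0.25, 13.0, 34.0, 6.0),
            "spinal_cord": (0.45, 8.0, 14.9, 4.0),
        },
    ),
)

_STRUCT_STREAM = {
    "stomach": 0,
    "duodenum": 1,
    "small_bowel": 2,
    "kidneys": 3,
    "liver": 4,
    "spinal_cord": 5,
    "target": 6,
}
_GEOMETRY_STREAM = 99


def _rng(seed: int, patient_idx: int, structure: str, slot: int) -> np.random.Generator:
    """Independent stream for one (patient, structure, plan-slot) triple."""
    key = (int(seed), int(patient_idx), _STRUCT_STREAM[structure], int(slot))
    return np.random.default_rng(np.random.SeedSequence(key))


def _lognormal(rng, mean: float, sd: float) -> float:
    var_log = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - var_log / 2.0
    return float(rng.lognormal(mu, math.sqrt(var_log)))


def _gamma(rng, mean: float, sd: float) -> float:
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return float(rng.gamma(shape, scale))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def sample_geometry(
    n_patients: int, seed: int = DEFAULT_SEED
) -> list[PatientGeometry]:
    """Draw ``n_patients`` anatomies matched to the cohort summary statistics.

    CTV volumes are log-normal (mean 79.9, SD 46.85 cc); the PTV adds an
    independent log-normal margin increment so the PTV marginally matches
    mean 198.06, SD 74.04 cc.  Overlap fractions are gamma-distributed with
    the published means/SDs and clipped to the observed [0, 25]% range.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    inc_mean = _PTV_STATS[0] - _CTV_STATS[0]
    inc_sd = math.sqrt(max(_PTV_STATS[1] ** 2 - _CTV_STATS[1] ** 2, 1.0))
    out = []
    for i in range(n_patients):
        rng = np.random.default_rng(
            np.random.SeedSequence((int(seed), i, _GEOMETRY_STREAM))
        )
        ctv = _lognormal(rng, *_CTV_STATS)
        ptv = ctv + _lognormal(rng, inc_mean, inc_sd)
        overlaps = {
            s: min(_gamma(rng, *stats), _OVERLAP_MAX)
            for s, stats in _OVERLAP_STATS.items()
        }
        oars = {
            s: _lognormal(rng, m, 0.25 * m) for s, m in _OAR_VOLUME_MEANS.items()
        }
        out.append(
            PatientGeometry(
                patient_id=f"P{i + 1:03d}",
                ctv_volume=ctv,
                ptv_volume=ptv,
                overlap_fraction=overlaps,
                oar_volumes=oars,
            )
        )
    return out


# ---------------------------------------------------------------------------
# OAR DVHs
# ---------------------------------------------------------------------------


def _gi_curve(
    grid: np.ndarray,
    f_high: float,
    bath: float,
    bath_scale: float,
    mid: float,
    edge: float,
    width: float,
    cap: float,
) -> np.ndarray:
    """Cumulative fractional volume: plateau + mid shoulder + low-dose bath."""
    plateau = f_high / (1.0 + np.exp((grid - edge) / width))
    g_bath = 1.0 / (1.0 + np.exp((grid - _BATH_CUTOFF_DOSE) / _CUTOFF_WIDTH))
    g_mid = 1.0 / (1.0 + np.exp((grid - _SHOULDER_CUTOFF_DOSE) / _CUTOFF_WIDTH))
    shoulder = mid / (1.0 + np.exp((grid - _MID_EDGE) / _MID_WIDTH))
    v = plateau + shoulder * g_mid + bath * np.exp(-grid / bath_scale) * g_bath
    taper = np.clip((cap - grid) / _CAP_TAPER, 0.0, 1.0) ** 2
    v = v * np.where(grid > cap - _CAP_TAPER, taper, 1.0)
    v[grid >= cap] = 0.0
    v[0] = 1.0
    return np.minimum.accumulate(v)


def _exact_v(grid: np.ndarray, values: np.ndarray, dose: float) -> float:
    return float(np.interp(dose, grid, values))


def generate_oar_dvh(
    geometry: PatientGeometry,
    structure: str,
    archetype: ModalityArchetype,
    scheme: FractionationScheme = DEFAULT_SCHEME,
    seed: int = DEFAULT_SEED,
    patient_idx: int = 0,
) -> DoseVolumeHistogram:
    """Cumulative percent DVH for one OAR under one modality archetype.

    GI organs get the plateau+bath mixture; kidneys, liver and cord are
    bath-only.  After construction the curve is iteratively relaxed (the
    plateau edge pulled down) until the packaged planning constraints for
    that structure hold, emulating the planner's constraint-driven
    trade-off against coverage.
    """
    if structure not in geometry.oar_volumes:
        raise KeyError(f"unknown structure {structure!r}")
    grid = _grid()
    sh = _rng(seed, patient_idx, structure, 3)  # shared anatomical stream
    md = _rng(seed, patient_idx, structure, 10 + archetype.stream_slot)
    bath_mult = math.exp(
        sh.normal(0.0, _SHARED_BATH_SIGMA) + md.normal(0.0, _MODALITY_BATH_SIGMA)
    )
    edge_shift = sh.normal(0.0, _SHARED_EDGE_SIGMA) + md.normal(
        0.0, _MODALITY_EDGE_SIGMA
    )
    cap_z = _CAP_SHARED_W * sh.normal() + _CAP_MODALITY_W * md.normal()

    if structure in GI_STRUCTURES:
        f_high = geometry.plateau_fraction(structure)
        # the intermediate shoulder is anatomy-driven: identical draw for all
        # three plans of a patient, so it cancels in paired differences
        mid = _STRUCT_MID_FRAC[structure] * math.exp(sh.normal(0.0, 0.35))
        bath = min(
            archetype.bath_fraction * _STRUCT_BATH_FACTOR[structure] * bath_mult,
            0.97 - f_high - mid,
        )
        edge = archetype.plateau_edge + _STRUCT_EDGE_OFFSET[structure] + edge_shift
        cap_limit = _STRUCT_CAP_LIMIT[structure]
        cap = float(
            np.clip(
                archetype.cap_mean
                + _STRUCT_CAP_OFFSET[structure]
                + archetype.cap_sd * cap_z,
                46.0,
                cap_limit,
            )
        )
        edge = min(edge, cap - 0.5)

        def curve(e):
            return _gi_curve(
                grid, f_high, bath, archetype.bath_scale, mid, e,
                archetype.tail_width, cap,
            )

        values = curve(edge)
        # constraint-enforcement pass (planner emulation): V50 <= 2% where it
        # applies, V45 below the organ limit, with a small safety margin
        v45_limit = {"stomach": 24.0, "duodenum": 32.0, "small_bowel": 24.0}[structure]
        v50_limit = 1.9 if structure in ("stomach", "small_bowel") else None
        for _ in range(60):
            v45 = 100.0 * _exact_v(grid, values, 45.0)
            v50 = 100.0 * _exact_v(grid, values, 50.0)
            if v45 <= v45_limit and (v50_limit is None or v50 <= v50_limit):
                break
            edge -= 0.25
            values = curve(edge)
    else:
        level, scale, cap_mean, cap_sd = archetype.organ_baths[structure]
        bath = min(level * bath_mult, 0.97)
        cap = float(np.clip(cap_mean + cap_sd * cap_z, 4.0, 44.0))
        v = bath * np.exp(-grid / scale)
        v[grid >= cap] = 0.0
        v[0] = 1.0
        values = np.minimum.accumulate(v)

    return DoseVolumeHistogram(
        structure_label=structure,
        total_volume=geometry.oar_volumes[structure],
        dose=grid,
        values=100.0 * values,
        mode="cumulative",
        volume_unit="percent",
    )


# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------


def generate_target_dvh(
    geometry: PatientGeometry,
    archetype: ModalityArchetype,
    scheme: FractionationScheme = DEFAULT_SCHEME,
    seed: int = DEFAULT_SEED,
    patient_idx: int = 0,
) -> tuple[DoseVolumeHistogram, DoseVolumeHistogram, dict]:
    """CTV and PTV DVHs plus ground-truth conformity inputs for one plan.

    Target curves are Gaussian-tailed around the prescription with the
    median pinned exactly at it (the plan-normalisation rule: 100% of the
    prescription covers 50% of the PTV) and truncated just below 107% of
    the prescription (the hotspot rule).  Returns
    ``(ctv_dvh, ptv_dvh, truth)`` where ``truth`` carries TV95 volumes and
    the 95% isodose volume for conformation-number evaluation.
    """
    grid = _grid()
    rx = scheme.prescription_dose
    sh = _rng(seed, patient_idx, "target", 3)
    md = _rng(seed, patient_idx, "target", 10 + archetype.stream_slot)
    hi_noise = math.exp(sh.normal(0.0, 0.30) + md.normal(0.0, 0.20))
    cap = 1.069 * rx  # strictly below the 107% hotspot ceiling

    def curve(sigma: float) -> np.ndarray:
        v = 1.0 - ndtr((grid - rx) / sigma)
        v[grid >= cap] = 0.0
        v[0] = 1.0
        return np.minimum.accumulate(v)

    # HI = (D2 - D98)/D50 = 2 * 2.054 * sigma / rx for the untruncated curve
    sigma_ptv = archetype.ptv_hi_mean * rx / (2 * 2.0537) * hi_noise
    sigma_ctv = 0.04 * rx / (2 * 2.0537) * hi_noise
    ptv = DoseVolumeHistogram(
        structure_label="PTV",
        total_volume=geometry.ptv_volume,
        dose=grid,
        values=100.0 * curve(sigma_ptv),
        mode="cumulative",
        volume_unit="percent",
    )
    ctv = DoseVolumeHistogram(
        structure_label="CTV",
        total_volume=geometry.ctv_volume,
        dose=grid,
        values=100.0 * curve(sigma_ctv),
        mode="cumulative",
        volume_unit="percent",
    )
    cn = float(
        np.clip(
            archetype.ptv_cn_mean + 0.04 * (0.7 * sh.normal() + 0.7 * md.normal()),
            0.55,
            0.95,
        )
    )
    d95 = 0.95 * rx
    tv95_ptv = geometry.ptv_volume * float(np.interp(d95, grid, ptv.values)) / 100.0
    tv95_ctv = geometry.ctv_volume * float(np.interp(d95, grid, ctv.values)) / 100.0
    # the isodose volume always contains the covered part of the target;
    # when coverage falls below the drawn CN the realised CN follows coverage
    v95_iso = max(tv95_ptv, tv95_ptv**2 / (geometry.ptv_volume * cn))
    truth = {
        "tv95_ctv": tv95_ctv,
        "tv95_ptv": tv95_ptv,
        "v95_iso": v95_iso,
    }
    return ctv, ptv, truth


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """A generated cohort: one PlanRecord per patient x modality, plus the
    ground-truth manifest (geometry and conformity inputs per plan)."""

    plans: list[PlanRecord]
    manifest: pd.DataFrame
    seed: int
    scheme: FractionationScheme


def build_cohort(
    n_patients: int = 24,
    seed: int = DEFAULT_SEED,
    archetypes: tuple[ModalityArchetype, ...] = DEFAULT_ARCHETYPES,
    scheme: FractionationScheme = DEFAULT_SCHEME,
    structures: tuple[str, ...] | None = None,
) -> SyntheticCohort:
    """Generate the full cohort (default 24 patients x 3 modalities).

    Each plan carries stomach, duodenum, small-bowel, composite stoduo,
    kidneys, liver, spinal-cord, CTV and PTV DVHs.  ``structures`` restricts
    the generated OARs (targets are then skipped unless requested), which
    the statistical-calibration tests use to keep replicates cheap.
    """
    geometries = sample_geometry(n_patients, seed)
    plans: list[PlanRecord] = []
    rows = []
    oar_list = list(structures) if structures is not None else (
        list(GI_STRUCTURES) + ["kidneys", "liver", "spinal_cord"]
    )
    with_targets = structures is None or "target" in structures
    oar_list = [s for s in oar_list if s != "target"]
    for i, geo in enumerate(geometries):
        for arch in archetypes:
            plan = PlanRecord(
                patient_id=geo.patient_id,
                modality=arch.modality,
                fractionation=scheme,
            )
            for s in oar_list:
                plan.add(
                    generate_oar_dvh(geo, s, arch, scheme, seed=seed, patient_idx=i)
                )
            if "stomach" in oar_list and "duodenum" in oar_list:
                plan.add(
                    combine_structures(
                        plan["stomach"], plan["duodenum"], label="stoduo"
                    )
                )
            row = {
                "patient_id": geo.patient_id,
                "modality": arch.modality,
                "ctv_volume": geo.ctv_volume,
                "ptv_volume": geo.ptv_volume,
                **{f"overlap_{s}": geo.overlap_fraction[s] for s in GI_STRUCTURES},
                **{f"volume_{s}": v for s, v in geo.oar_volumes.items()},
            }
            if with_targets:
                ctv, ptv, truth = generate_target_dvh(
                    geo, arch, scheme, seed=seed, patient_idx=i
                )
                plan.add(ctv)
                plan.add(ptv)
                row.update(truth)
            plans.append(plan)
            rows.append(row)
    return SyntheticCohort(
        plans=plans,
        manifest=pd.DataFrame(rows),
        seed=seed,
        scheme=scheme,
    )
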