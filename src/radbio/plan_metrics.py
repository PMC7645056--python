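"""Target conformity/homogeneity indices and planning-constraint checks.

The two target-quality indices follow the standard definitions:

* homogeneity index ``HI = (D2% - D98%) / D50%`` -- 0 for a perfectly
  uniform target dose;
* conformation number ``CN = TV95^2 / (TV * V95)`` -- 1 when the 95%
  isodose exactly wraps the target, penalising both under-coverage
  (``TV95 < TV``) and spill of the isodose outside the target
  (``V95 > TV95``).

``TV95`` (target volume covered by the 95% isodose) and ``V95`` (total 95%
isodose volume) cannot be recovered from per-structure DVHs alone; they are
supplied either from the synthetic generator's ground truth or from an
explicit body-structure DVH.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .dvh import (
    DoseVolumeHistogram,
    PlanRecord,
    d_max,
    d_mean,
    dose_at_volume,
    volume_at_dose,
)

__all__ = [
    "ConstraintRule",
    "ConstraintReport",
    "TargetIndexReport",
    "homogeneity_index",
    "conformation_number",
    "check_constraints",
    "percent_reduction",
    "load_oar_constraints",
]


def homogeneity_index(target_dvh: DoseVolumeHistogram, prescription: float) -> float:
    """RTOG homogeneity index ``(D2% - D98%) / D50%`` (dimensionless >= 0)."""
    d2 = dose_at_volume(target_dvh, 2.0)
    d98 = dose_at_volume(target_dvh, 98.0)
    d50 = dose_at_volume(target_dvh, 50.0)
    if d50 == 0:
        raise ValueError("D50% is zero; homogeneity index undefined")
    return (d2 - d98) / d50


def conformation_number(
    target_volume: float, target_covered_by_95: float, isodose95_volume: float
) -> float:
    """Conformation number ``TV95^2 / (TV * V95)`` in [0, 1]."""
    if target_volume <= 0 or isodose95_volume <= 0:
        raise ValueError("target and isodose volumes must be > 0")
    if not 0 <= target_covered_by_95 <= min(target_volume, isodose95_volume) * (
        1 + 1e-9
    ):
        raise ValueError("covered volume exceeds target or isodose volume")
    return target_covered_by_95**2 / (target_volume * isodose95_volume)


def percent_reduction(reference: float, comparator: float) -> float:
    """Relative reduction ``100 (ref - comp) / ref`` in percent."""
    if reference <= 0:
        raise ValueError("reference must be > 0")
    return 100.0 * (reference - comparator) / reference


@dataclass(frozen=True)
class TargetIndexReport:
    """Conformity/homogeneity summary for one target of one plan."""

    hi: float
    cn: float
    covered_volume_95: float
    isodose_volume_95: float

    def __post_init__(self):
        if not 0 <= self.cn <= 1 + 1e-9:
            raise ValueError("CN must lie in [0, 1]")
        if self.hi < 0:
            raise ValueError("HI must be >= 0")


@dataclass(frozen=True)
class ConstraintRule:
    """One planning rule against one structure.

    kinds: ``max_dose`` (Dmax <= limit GyE), ``volume_at_dose_le``
    (V_dose <= limit, percent), ``mean_dose_le`` (Dmean <= limit GyE),
    ``coverage_ge`` (V_dose >= limit percent), ``hotspot_eq_zero``
    (V_dose == 0).  ``dose`` may be given directly in GyE or as
    ``dose_fraction`` of the prescription.
    """

    structure: str
    kind: str
    limit: float | None = None
    dose: float | None = None
    dose_fraction: float | None = None

    _KINDS = (
        "max_dose",
        "volume_at_dose_le",
        "mean_dose_le",
        "coverage_ge",
        "hotspot_eq_zero",
    )

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        if self.kind in ("volume_at_dose_le", "coverage_ge", "hotspot_eq_zero"):
            if self.dose is None and self.dose_fraction is None:
                raise ValueError(f"{self.kind} needs dose or dose_fraction")
        if self.kind != "hotspot_eq_zero" and self.limit is None:
            raise ValueError(f"{self.kind} needs a limit")
        if self.dose is not None and self.dose < 0:
            raise ValueError("dose must be >= 0")

    def dose_gye(self, prescription: float | None) -> float | None:
        if self.dose is not None:
            return self.dose
        if self.dose_fraction is not None:
            if prescription is None:
                raise ValueError("dose_fraction rule needs a prescription dose")
            return self.dose_fraction * prescription
        return None


@dataclass(frozen=True)
class ConstraintReport:
    """Verdict for one rule on one plan."""

    rule: ConstraintRule
    observed: float | None
    limit: float | None
    passed: bool | None  # None = not evaluable (structure missing)
    note: str = ""


def check_constraints(
    plan: PlanRecord, rules: list[ConstraintRule]
) -> list[ConstraintReport]:
    """Evaluate every rule against the plan's DVHs.

    A rule whose structure is absent from the plan is reported as
    not-evaluable (``passed=None``) rather than silently passed.
    """
    rx = plan.fractionation.prescription_dose if plan.fractionation else None
    out = []
    for rule in rules:
        if rule.structure not in plan.dvhs:
            out.append(
                ConstraintReport(rule, None, rule.limit, None, "structure missing")
            )
            continue
        dvh = plan.dvhs[rule.structure]
        dose = rule.dose_gye(rx)
        if rule.kind == "max_dose":
            obs = d_max(dvh)
            ok = obs <= rule.limit
        elif rule.kind == "mean_dose_le":
            obs = d_mean(dvh)
            ok = obs <= rule.limit
        elif rule.kind == "volume_at_dose_le":
            obs = volume_at_dose(dvh, dose, "percent")
            ok = obs <= rule.limit
        elif rule.kind == "coverage_ge":
            obs = volume_at_dose(dvh, dose, "percent")
            ok = obs >= rule.limit
        else:  # hotspot_eq_zero
            obs = volume_at_dose(dvh, dose, "percent")
            ok = obs <= 1e-9
        out.append(ConstraintReport(rule, float(obs), rule.limit, bool(ok)))
    return out


def load_oar_constraints() -> list[ConstraintRule]:
    """Packaged planning constraint set (GI organs, kidneys, liver, cord, targets)."""
    text = (
        resources.files("radbio.data").joinpath("oar_constraints.yaml").read_text()
    )
    return [ConstraintRule(**row) for row in yaml.safe_load(text)]
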