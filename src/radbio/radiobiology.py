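"""EQD2 conversion, generalized EUD and the Lyman-Kutcher-Burman NTCP model.

The complication-probability chain implemented here is

1. convert each DVH dose bin to its equivalent dose in 2-Gy fractions
   (EQD2) with the linear-quadratic model,
2. reduce the inhomogeneous EQD2 distribution to a single effective dose
   ``Deff`` with the generalized equivalent uniform dose
   ``gEUD = (sum_i v_i D_i^(1/n))^n``, and
3. map ``Deff`` through the probit dose-response
   ``NTCP = Phi((Deff - TD50) / (m TD50))``.

``n`` encodes the organ's volume effect (small n: serial, max-dose driven;
n = 1: parallel, mean-dose driven), ``TD50`` the uniform dose giving a 50%
complication rate, and ``m`` the slope of the response curve.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml
from scipy.special import ndtr

from .dvh import (
    DoseVolumeHistogram,
    FractionationScheme,
    PlanRecord,
    to_differential,
)

__all__ = [
    "LKBParameterSet",
    "NTCPResult",
    "eqd2",
    "eqd2_transform",
    "geud",
    "lkb_ntcp",
    "ntcp_from_plan",
    "delta_ntcp",
    "load_lkb_parameters",
]


@dataclass(frozen=True)
class LKBParameterSet:
    """One published LKB parameter triple with its endpoint and source."""

    organ: str
    endpoint: str
    source: str
    td50: float
    m: float
    n: float
    td50_range: tuple[float, float] | None = None
    m_range: tuple[float, float] | None = None
    n_range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.td50 <= 0:
            raise ValueError("td50 must be > 0")
        if self.m <= 0:
            raise ValueError("m must be > 0")
        if not 0 < self.n <= 1:
            raise ValueError("n must be in (0, 1]")
        for name in ("td50", "m", "n"):
            rng = getattr(self, f"{name}_range")
            if rng is not None and not rng[0] <= getattr(self, name) <= rng[1]:
                raise ValueError(f"{name}_range does not bracket the point value")


@dataclass(frozen=True)
class NTCPResult:
    """Outcome of the LKB chain for one structure/endpoint on one plan."""

    structure_label: str
    endpoint: str
    deff: float
    t: float
    ntcp: float


def load_lkb_parameters() -> list[LKBParameterSet]:
    """Packaged published LKB parameter sets for the upper-GI endpoints."""
    text = (
        resources.files("radbio.data").joinpath("lkb_parameters.yaml").read_text()
    )
    out = []
    for row in yaml.safe_load(text):
        out.append(
            LKBParameterSet(
                organ=row["organ"],
                endpoint=row["endpoint"],
                source=row["source"],
                td50=float(row["td50"]),
                m=float(row["m"]),
                n=float(row["n"]),
                td50_range=tuple(row["td50_range"]) if "td50_range" in row else None,
                m_range=tuple(row["m_range"]) if "m_range" in row else None,
                n_range=tuple(row["n_range"]) if "n_range" in row else None,
            )
        )
    return out


def eqd2(total_dose: float, n_fractions: int, alpha_beta: float) -> float:
    """Equivalent dose in 2-Gy fractions: ``D (d + a/b) / (2 + a/b)``.

    ``d = D / n_fractions`` is the dose per fraction.  ``total_dose = 0``
    maps to 0; negative inputs are rejected.
    """
    if total_dose < 0:
        raise ValueError("total_dose must be >= 0")
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if alpha_beta <= 0:
        raise ValueError("alpha_beta must be > 0")
    d = total_dose / n_fractions
    return total_dose * (d + alpha_beta) / (2.0 + alpha_beta)


def eqd2_transform(
    dvh: DoseVolumeHistogram, scheme: FractionationScheme
) -> DoseVolumeHistogram:
    """Map every dose bin of a physical-dose DVH into EQD2 space.

    Each bin dose ``D_i`` is assumed delivered evenly over all fractions
    (per-bin fraction size ``d_i = D_i / n_fractions``), the standard reading
    for a uniformly fractionated course.  Volumes are untouched; the result
    is flagged ``dose_space='eqd2'`` and a second application raises.
    """
    if dvh.dose_space == "eqd2":
        raise ValueError("DVH is already in EQD2 space")
    ab = scheme.alpha_beta
    nf = scheme.n_fractions
    new_dose = dvh.dose * (dvh.dose / nf + ab) / (2.0 + ab)
    return replace(dvh, dose=new_dose, dose_space="eqd2")


def geud(dvh: DoseVolumeHistogram, n: float) -> float:
    """Generalized equivalent uniform dose ``(sum_i v_i D_i^(1/n))^n``.

    Accepts cumulative or differential DVHs; fractional volumes are
    normalized internally.  The evaluation factors out the largest bin dose
    so that exponents as large as 1/0.07 ~ 14.3 cannot overflow, and
    zero-dose bins contribute exactly 0.
    """
    if n <= 0:
        raise ValueError("volume parameter n must be > 0")
    if n > 1:
        raise ValueError("volume parameter n must be <= 1")
    diff = dvh if dvh.mode == "differential" else to_differential(dvh)
    d = diff.bin_midpoints
    v = diff.values / diff.values.sum()
    dmax = d[v > 0].max(initial=0.0)
    if dmax == 0.0:
        return 0.0
    ratio = np.where(d > 0, d / dmax, 0.0)
    s = np.sum(v * ratio ** (1.0 / n))
    return float(dmax * s**n)


def lkb_ntcp(deff: float, params: LKBParameterSet) -> NTCPResult:
    """Probit dose response: ``NTCP = Phi((Deff - TD50)/(m TD50))``.

    The standard-normal CDF is evaluated in closed form via the error
    function; no numeric quadrature is involved.
    """
    if deff < 0:
        raise ValueError("deff must be >= 0")
    t = (deff - params.td50) / (params.m * params.td50)
    return NTCPResult(
        structure_label=params.organ,
        endpoint=params.endpoint,
        deff=float(deff),
        t=float(t),
        ntcp=float(ndtr(t)),
    )


def ntcp_from_plan(
    plan: PlanRecord,
    structure_label: str,
    params: LKBParameterSet,
    scheme: FractionationScheme | None = None,
) -> NTCPResult:
    """Full LKB chain for one structure of one plan.

    EQD2-transforms the structure's DVH (unless it already is in EQD2
    space), reduces it to gEUD with the parameter set's volume exponent and
    evaluates the probit response.
    """
    scheme = scheme or plan.fractionation
    if scheme is None:
        raise ValueError("no fractionation scheme available")
    dvh = plan[structure_label]
    if dvh.dose_space != "eqd2":
        dvh = eqd2_transform(dvh, scheme)
    deff = geud(dvh, params.n)
    res = lkb_ntcp(deff, params)
    return replace(res, structure_label=structure_label)


def delta_ntcp(a: NTCPResult, b: NTCPResult) -> float:
    """Signed complication-probability difference ``NTCP(a) - NTCP(b)``."""
    if a.endpoint != b.endpoint:
        raise ValueError(
            f"endpoint mismatch: {a.endpoint!r} vs {b.endpoint!r}"
        )
    if a.structure_label != b.structure_label:
        raise ValueError(
            f"structure mismatch: {a.structure_label!r} vs {b.structure_label!r}"
        )
    return a.ntcp - b.ntcp
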