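"""Cohort assembly and paired three-modality comparison.

The cohort is a complete-block design: every patient is planned with every
modality, so per-metric comparisons use a one-way within-subject
(repeated-measures) ANOVA followed by Bonferroni-adjusted paired t-tests
for the three modality pairs.

The analysis is organised statsmodels-style: :class:`PlanComparison` is a
model object built from a long-format cohort table (``patient_id``,
``modality``, ``structure``, ``metric``, ``value``); ``.fit()`` returns a
:class:`PlanComparisonResults` carrying per-metric means, F statistics,
adjusted pairwise p-values and per-patient photon-minus-proton NTCP
differences, with a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dvh import PlanRecord, d_max, d_mean, volume_at_dose
from .plan_metrics import conformation_number, homogeneity_index
from .radiobiology import load_lkb_parameters, ntcp_from_plan

__all__ = [
    "PlanComparison",
    "PlanComparisonResults",
    "cohort_metrics_table",
    "summarize",
    "rm_anova",
    "bonferroni_pairwise",
    "build_dose_table",
    "build_ntcp_table",
]

_PREFERRED_ORDER = ("IMRT", "VMAT", "PSPBT")
_VX_DOSES = (5, 10, 15, 20, 25, 30, 35, 40, 45, 50)


# ---------------------------------------------------------------------------
# metric extraction
# ---------------------------------------------------------------------------


def cohort_metrics_table(
    plans: list[PlanRecord],
    manifest: pd.DataFrame | None = None,
    include_ntcp: bool = True,
) -> pd.DataFrame:
    """Long-format per-plan metric table.

    For the GI organs: Dmax and V5..V50 in 5-GyE steps (percent); for the
    stoduo composite: V50 in cc; kidneys/liver: mean dose; cord: Dmax;
    CTV/PTV: homogeneity index and (when the manifest supplies the
    ground-truth TV95/V95 volumes) the conformation number.  With
    ``include_ntcp`` every packaged LKB parameter set is evaluated through
    the full EQD2 -> gEUD -> probit chain, reported in percent.
    """
    lkb = load_lkb_parameters() if include_ntcp else []
    truth = None
    if manifest is not None and "v95_iso" in manifest.columns:
        truth = manifest.set_index(["patient_id", "modality"])
    rows = []

    def put(plan, structure, metric, value):
        rows.append(
            {
                "patient_id": plan.patient_id,
                "modality": plan.modality,
                "structure": structure,
                "metric": metric,
                "value": float(value),
            }
        )

    for plan in plans:
        rx = plan.fractionation.prescription_dose if plan.fractionation else None
        for s in ("stomach", "duodenum", "small_bowel"):
            if s not in plan.dvhs:
                continue
            dvh = plan[s]
            put(plan, s, "Dmax", d_max(dvh))
            for dx in _VX_DOSES:
                put(plan, s, f"V{dx}", volume_at_dose(dvh, float(dx), "percent"))
        if "stoduo" in plan.dvhs:
            put(plan, "stoduo", "V50cc", volume_at_dose(plan["stoduo"], 50.0, "cc"))
        for s in ("kidneys", "liver"):
            if s in plan.dvhs:
                put(plan, s, "Dmean", d_mean(plan[s]))
        if "spinal_cord" in plan.dvhs:
            put(plan, "spinal_cord", "Dmax", d_max(plan["spinal_cord"]))
        for s in ("CTV", "PTV"):
            if s not in plan.dvhs or rx is None:
                continue
            put(plan, s, "HI", homogeneity_index(plan[s], rx))
            if truth is not None:
                t = truth.loc[(plan.patient_id, plan.modality)]
                tv = t["ctv_volume"] if s == "CTV" else t["ptv_volume"]
                tv95 = t["tv95_ctv"] if s == "CTV" else t["tv95_ptv"]
                put(plan, s, "CN", conformation_number(tv, tv95, t["v95_iso"]))
        for params in lkb:
            if params.organ in plan.dvhs:
                res = ntcp_from_plan(plan, params.organ, params)
                put(plan, params.organ, f"NTCP {params.endpoint}", 100.0 * res.ntcp)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics primitives
# ---------------------------------------------------------------------------


def _block(table: pd.DataFrame, metric: str, structure: str) -> pd.DataFrame:
    """Patients x modalities block for one metric; errors on missing cells."""
    sub = table[(table["metric"] == metric) & (table["structure"] == structure)]
    if sub.empty:
        raise KeyError(f"no data for {structure}/{metric}")
    wide = sub.pivot(index="patient_id", columns="modality", values="value")
    if wide.isna().any().any():
        raise ValueError(f"unbalanced design for {structure}/{metric}")
    order = [m for m in _PREFERRED_ORDER if m in wide.columns] + [
        m for m in wide.columns if m not in _PREFERRED_ORDER
    ]
    return wide[order]


def summarize(table: pd.DataFrame, metric: str, structure: str) -> pd.DataFrame:
    """Mean and sample SD (n-1 denominator) per modality for one metric."""
    wide = _block(table, metric, structure)
    if len(wide) < 2:
        raise ValueError("SD undefined for a single subject")
    return pd.DataFrame({"mean": wide.mean(axis=0), "sd": wide.std(axis=0, ddof=1)})


def _rm_anova_blockmatrix(x: np.ndarray) -> tuple[float, float, int, int]:
    """Within-subject one-way ANOVA from the sums-of-squares definitions.

    ``x`` is subjects x treatments.  Total variation is partitioned into
    treatment, subject and residual components; F = MS_treat / MS_resid on
    (k-1, (k-1)(n-1)) degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 treatments")
    grand = x.mean()
    ss_treat = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_resid = max(ss_total - ss_treat - ss_subj, 0.0)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_treat = ss_treat / df1
    ms_resid = ss_resid / df2
    if ms_resid == 0.0:
        f = 0.0 if ms_treat == 0.0 else np.inf
    else:
        f = ms_treat / ms_resid
    p = 1.0 if f == 0.0 else float(stats.f.sf(f, df1, df2))
    return float(f), p, df1, df2


def rm_anova(
    table: pd.DataFrame, metric: str, structure: str
) -> tuple[float, float]:
    """Repeated-measures ANOVA F and p for one metric across modalities."""
    wide = _block(table, metric, structure)
    f, p, _, _ = _rm_anova_blockmatrix(wide.to_numpy())
    return f, p


def _paired_t_p(a: np.ndarray, b: np.ndarray) -> float:
    d = np.asarray(a) - np.asarray(b)
    if np.allclose(d.std(ddof=1), 0.0):
        if not np.allclose(d.mean(), 0.0):
            warnings.warn("constant nonzero paired difference; p set to 1")
        return 1.0
    return float(stats.ttest_rel(a, b).pvalue)


def bonferroni_pairwise(
    table: pd.DataFrame, metric: str, structure: str
) -> dict[tuple[str, str], float]:
    """Bonferroni-adjusted paired t-tests for every modality pair.

    Adjusted p = min(1, n_pairs * p_raw); identical paired samples give an
    adjusted p of exactly 1.
    """
    wide = _block(table, metric, structure)
    mods = list(wide.columns)
    pairs = [(a, b) for i, a in enumerate(mods) for b in mods[i + 1 :]]
    out = {}
    for a, b in pairs:
        p = _paired_t_p(wide[a].to_numpy(), wide[b].to_numpy())
        out[(a, b)] = min(1.0, len(pairs) * p)
    return out


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class PlanComparison:
    """Paired plan-comparison model over a long-format cohort table.

    Parameters
    ----------
    table : DataFrame
        Columns ``patient_id, modality, structure, metric, value``; every
        patient must appear under every modality for every metric
        (complete blocks).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"patient_id", "modality", "structure", "metric", "value"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"table lacks columns {sorted(missing)}")
        self.table = table.copy()
        mods = list(pd.unique(table["modality"]))
        self.modalities = [m for m in _PREFERRED_ORDER if m in mods] + [
            m for m in mods if m not in _PREFERRED_ORDER
        ]
        self.metrics = list(
            table[["structure", "metric"]].drop_duplicates().itertuples(index=False)
        )

    @classmethod
    def from_cohort(
        cls,
        plans: list[PlanRecord],
        manifest: pd.DataFrame | None = None,
        include_ntcp: bool = True,
    ) -> "PlanComparison":
        return cls(cohort_metrics_table(plans, manifest, include_ntcp))

    def fit(self, alpha: float = 0.05) -> "PlanComparisonResults":
        """Run the RM-ANOVA and Bonferroni pairwise tests for every metric."""
        rows = []
        for structure, metric in self.metrics:
            wide = _block(self.table, metric, structure)
            summ = summarize(self.table, metric, structure)
            f, p, _, _ = _rm_anova_blockmatrix(wide.to_numpy())
            pw = bonferroni_pairwise(self.table, metric, structure)
            row = {"structure": structure, "metric": metric}
            for m in self.modalities:
                row[f"mean_{m}"] = summ.loc[m, "mean"]
                row[f"sd_{m}"] = summ.loc[m, "sd"]
            row["F"] = f
            row["p_anova"] = p
            for (a, b), padj in pw.items():
                row[f"p_{a}_vs_{b}"] = padj
            rows.append(row)
        summary_frame = pd.DataFrame(rows)
        delta_frame = self._delta_ntcp_frame()
        return PlanComparisonResults(self, summary_frame, delta_frame, alpha)

    def _delta_ntcp_frame(self) -> pd.DataFrame:
        """Per-patient photon-minus-proton NTCP differences, summarised."""
        if "PSPBT" not in self.modalities:
            return pd.DataFrame()
        rows = []
        for structure, metric in self.metrics:
            if not metric.startswith("NTCP"):
                continue
            wide = _block(self.table, metric, structure)
            for m in self.modalities:
                if m == "PSPBT":
                    continue
                delta = wide[m] - wide["PSPBT"]
                rows.append(
                    {
                        "structure": structure,
                        "metric": metric,
                        "comparison": f"{m}-PSPBT",
                        "delta_mean": delta.mean(),
                        "delta_sd": delta.std(ddof=1),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class PlanComparisonResults:
    """Fitted plan comparison: per-metric summaries and test statistics.

    ``summary_frame`` has one row per (structure, metric) with per-modality
    mean/SD, the RM-ANOVA F and p, and the three Bonferroni-adjusted
    pairwise p-values; ``delta_ntcp_frame`` summarises the per-patient
    photon-minus-proton NTCP differences (percentage points).
    """

    model: PlanComparison
    summary_frame: pd.DataFrame
    delta_ntcp_frame: pd.DataFrame
    alpha: float = 0.05

    def pairwise_p(self, structure: str, metric: str, a: str, b: str) -> float:
        row = self._row(structure, metric)
        for key in (f"p_{a}_vs_{b}", f"p_{b}_vs_{a}"):
            if key in row.index and not pd.isna(row[key]):
                return float(row[key])
        raise KeyError(f"no pairwise test {a} vs {b}")

    def mean(self, structure: str, metric: str, modality: str) -> float:
        return float(self._row(structure, metric)[f"mean_{modality}"])

    def _row(self, structure: str, metric: str) -> pd.Series:
        sel = self.summary_frame[
            (self.summary_frame["structure"] == structure)
            & (self.summary_frame["metric"] == metric)
        ]
        if sel.empty:
            raise KeyError(f"no results for {structure}/{metric}")
        return sel.iloc[0]

    def summary(self) -> str:
        """Human-readable comparison table (mean +/- SD, F, adjusted p)."""
        mods = self.model.modalities
        lines = ["Paired plan comparison (RM-ANOVA + Bonferroni paired t)", ""]
        header = f"{'structure':<12} {'metric':<28}"
        for m in mods:
            header += f" {m:>16}"
        header += f" {'F':>8} {'p':>8}"
        lines.append(header)
        lines.append("-" * len(header))
        for _, r in self.summary_frame.iterrows():
            line = f"{r['structure']:<12} {r['metric']:<28}"
            for m in mods:
                line += f" {r[f'mean_{m}']:>7.2f}±{r[f'sd_{m}']:<8.2f}"
            line += f" {r['F']:>8.2f} {r['p_anova']:>8.3g}"
            lines.append(line)
        if not self.delta_ntcp_frame.empty:
            lines += ["", "Delta NTCP (photon - proton, percentage points)"]
            for _, r in self.delta_ntcp_frame.iterrows():
                lines.append(
                    f"{r['structure']:<12} {r['metric']:<34} {r['comparison']:<12}"
                    f" {r['delta_mean']:+.2f} ± {r['delta_sd']:.2f}"
                )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.summary_frame.to_csv(path, index=False, float_format="%.10g")


def build_dose_table(
    plans: list[PlanRecord], manifest: pd.DataFrame | None = None
) -> PlanComparisonResults:
    """Dose-metric comparison report (Dmax, V5..V50, HI/CN per metric)."""
    return PlanComparison.from_cohort(plans, manifest, include_ntcp=False).fit()


def build_ntcp_table(plans: list[PlanRecord]) -> PlanComparisonResults:
    """NTCP comparison report: per-endpoint NTCP summaries and delta NTCP."""
    table = cohort_metrics_table(plans, manifest=None, include_ntcp=True)
    table = table[table["metric"].str.startswith("NTCP")]
    return PlanComparison(table).fit()
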