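"""Agreement metrics between membrane predictions and the in silico truth.

Two per-curve measures are used across the pressure sweep.  The signed
maximum difference

    Delta_max = Delta_k* with k* = argmax_k |y_pre,k - y_k|

retains the sign of the largest discrepancy (ties resolved toward the higher
pressure).  The offset-corrected coefficient of determination

    R^2_hat = 1 - sum_k (Delta_k - mean(Delta))^2 / sum_k (y_k - mean(y))^2

removes any constant offset between the curves (that offset lives in
Delta_max instead) and quantifies shape agreement only; negative values are
clipped to zero, and it is undefined when the reference curve is constant.

Group differences (hg vs lc vs cs) are assessed with a Kruskal-Wallis test
followed, when significant, by pairwise Mann-Whitney-Wilcoxon tests at a
Bonferroni-corrected level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import (ComparisonMetrics, MembraneParams, MetricPair,
                       RunConfig, SilicoArtery, StressSeries)
from .membrane import membrane_stress_series
from .thickwall import (midwall_stress_series, pressure_sweep,
                        transmural_gradient, transmural_profile)

__all__ = ["delta_max", "r_hat_squared", "compare_set", "gradient_table",
           "correlation_delta_vs_gradient", "group_tests", "GroupTestReport",
           "build_report", "COMPONENTS"]

#: (direction, component) keys of a full comparison row
COMPONENTS: tuple[tuple[str, str], ...] = tuple(
    [(d, c) for d in ("theta", "z") for c in ("iso", "aniso", "total", "fraction")]
    + [("", "reaction")])


def delta_max(y_pre, y) -> float:
    """Signed difference of maximum magnitude, ties toward higher pressure."""
    y_pre = np.asarray(y_pre, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_pre.size == 0 or y_pre.shape != y.shape:
        raise ValueError("series must be non-empty and of equal length")
    delta = y_pre - y
    mag = np.abs(delta)
    idx = len(mag) - 1 - int(np.argmax(mag[::-1]))
    return float(delta[idx])


def r_hat_squared(y_pre, y, *, rel_tol: float = 1e-12) -> float | None:
    """Offset-corrected coefficient of determination, clipped to [0, 1].

    Returns ``None`` when the reference series is constant (zero variance),
    mirroring the '-' entries where shape agreement is undefined.
    """
    y_pre = np.asarray(y_pre, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_pre.shape != y.shape or y_pre.size < 2:
        raise ValueError("series must be of equal length >= 2")
    ss_ref = float(np.sum(np.square(y - y.mean())))
    scale = float(np.sum(np.square(y)))
    if ss_ref <= rel_tol * max(scale, 1.0):
        return None
    delta = y_pre - y
    ss_res = float(np.sum(np.square(delta - delta.mean())))
    return max(1.0 - ss_res / ss_ref, 0.0)


def compare_series(pred: StressSeries, ref: StressSeries) -> ComparisonMetrics:
    """MetricPair for every stress component and load fraction."""
    out = {}
    for direction, component in COMPONENTS:
        d = direction or "theta"  # reaction stress is direction-free
        y_pre = pred.component(d, component)
        y = ref.component(d, component)
        out[(direction, component)] = MetricPair(
            delta_max=delta_max(y_pre, y), r_hat_sq=r_hat_squared(y_pre, y))
    return ComparisonMetrics(set_id="", group="", metrics=out)


@dataclass
class SetComparison:
    """Full per-set evaluation: series, metrics and systolic gradients."""

    set_id: str
    group: str
    silico: StressSeries
    membrane: StressSeries
    metrics: ComparisonMetrics
    gradient_theta: float  # at SBP, kPa
    gradient_z: float


def compare_set(artery: SilicoArtery, params: MembraneParams,
                config: RunConfig | None = None) -> SetComparison:
    """Run the full testing pipeline for one set.

    Sweeps the thick-walled artery over the pressure grid, evaluates its
    mid-wall stresses and wall-averaged load fractions, evaluates the
    membrane predictions with ``params`` on the 'measured' (P, ri, h), and
    compares component by component.
    """
    if artery.set_id != params.set_id:
        raise ValueError(f"set mismatch: {artery.set_id} vs {params.set_id}")
    config = config or RunConfig()
    series, states = pressure_sweep(artery, config)
    silico = midwall_stress_series(artery, states, config)
    pred = membrane_stress_series(series, params, config)
    metrics = compare_series(pred, silico)
    metrics.set_id, metrics.group = artery.set_id, artery.group
    prof = transmural_profile(states[-1], artery, config)  # SBP level
    return SetComparison(
        set_id=artery.set_id, group=artery.group, silico=silico,
        membrane=pred, metrics=metrics,
        gradient_theta=transmural_gradient(prof, "theta"),
        gradient_z=transmural_gradient(prof, "z"))


def _quartiles(values, method: str = "linear") -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75],
                                method=("linear" if method == "linear"
                                        else "nearest"))
    return float(med), float(q1), float(q3)


def gradient_table(comparisons: list[SetComparison],
                   quantile_method: str = "linear") -> pd.DataFrame:
    """Per-set systolic transmural gradients plus group median/IQR rows."""
    rows = [{"set_id": c.set_id, "group": c.group, "kind": "set",
             "gradient_theta_kPa": c.gradient_theta,
             "gradient_z_kPa": c.gradient_z} for c in comparisons]
    df = pd.DataFrame(rows)
    for group, sub in df.groupby("group", sort=False):
        summary = {"set_id": "", "group": group, "kind": "summary"}
        for col in ("gradient_theta_kPa", "gradient_z_kPa"):
            med, q1, q3 = _quartiles(sub[col].to_numpy(), quantile_method)
            summary[col] = med
            summary[col.replace("_kPa", "_q1_kPa")] = q1
            summary[col.replace("_kPa", "_q3_kPa")] = q3
        rows.append(summary)
    return pd.DataFrame(rows)


def correlation_delta_vs_gradient(comparisons: list[SetComparison]) -> float:
    """Pearson r between circumferential total-stress Delta_max and |gradient|."""
    if len(comparisons) < 3:
        raise ValueError("need at least 3 sets for a correlation")
    dmax = [c.metrics.metrics[("theta", "total")].delta_max for c in comparisons]
    grad = [abs(c.gradient_theta) for c in comparisons]
    return float(stats.pearsonr(dmax, grad).statistic)


@dataclass
class GroupTestReport:
    """Kruskal-Wallis + pairwise Mann-Whitney-Wilcoxon summary."""

    kruskal_p: float
    significant: bool
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)
    bonferroni_level: float | None = None
    flagged_group: str | None = None  # differs from *both* other groups
    flagged_p: float | None = None  # highest pairwise p of the flagged group


def group_tests(values: dict[str, np.ndarray], alpha: float = 0.05
                ) -> GroupTestReport:
    """Nonparametric group comparison with Bonferroni-corrected follow-up.

    A group is flagged only when its pairwise tests against *both* other
    groups are significant at the corrected level; the highest of those
    p-values is reported.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 members each")
    kw = stats.kruskal(*groups.values())
    report = GroupTestReport(kruskal_p=float(kw.pvalue),
                             significant=bool(kw.pvalue < alpha))
    if not report.significant:
        return report
    pairs = list(combinations(groups, 2))
    level = alpha / len(pairs)
    report.bonferroni_level = level
    for a, b in pairs:
        mw = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided",
                                method="exact")
        report.pairwise_p[(a, b)] = float(mw.pvalue)
    for g in groups:
        ps = [p for pair, p in report.pairwise_p.items() if g in pair]
        if len(ps) == len(groups) - 1 and all(p < level for p in ps):
            report.flagged_group = g
            report.flagged_p = max(ps)
            break
    return report


def metrics_frame(comparisons: list[SetComparison]) -> pd.DataFrame:
    """Long-format per-set metric table (one row per direction/component)."""
    records = []
    for c in comparisons:
        records.extend(c.metrics.to_records())
    return pd.DataFrame(records)


def build_report(comparisons: list[SetComparison], out_dir,
                 config: RunConfig | None = None) -> dict[str, Path]:
    """Write the evaluation tables and figure data as CSV/JSON files.

    Produces the per-set metric tables (circumferential, axial, reaction),
    group summary rows, the systolic gradient table, the Delta_max-gradient
    correlation, load-fraction-by-group bar data at DBP/SBP, and the per-set
    pressure-stress curves.  Missing sets are tolerated; whatever is present
    is reported.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    long = metrics_frame(comparisons)
    for name, mask in [("metrics_circumferential", long.direction == "theta"),
                       ("metrics_axial", long.direction == "z"),
                       ("metrics_reaction", long.component == "reaction")]:
        df = long[mask].copy()
        med = (df.groupby(["group", "component"], sort=False)
               [["delta_max", "r_hat_sq"]].median().reset_index())
        med.insert(0, "set_id", "median")
        paths[name] = out_dir / f"{name}.csv"
        pd.concat([df, med], ignore_index=True).to_csv(paths[name], index=False)

    grad = gradient_table(comparisons)
    paths["gradients"] = out_dir / "gradients_sbp.csv"
    grad.to_csv(paths["gradients"], index=False)

    corr = (correlation_delta_vs_gradient(comparisons)
            if len(comparisons) >= 3 else np.nan)
    paths["correlation"] = out_dir / "correlation.csv"
    pd.DataFrame([{"pearson_r_delta_vs_gradient": corr,
                   "n_sets": len(comparisons)}]).to_csv(paths["correlation"],
                                                        index=False)

    bars = []
    for c in comparisons:
        for model, s in (("membrane", c.membrane), ("silico", c.silico)):
            bars.append({"set_id": c.set_id, "group": c.group, "model": model,
                         "psi_theta_dbp": float(s.psi_aniso_theta[0]),
                         "psi_theta_sbp": float(s.psi_aniso_theta[-1]),
                         "psi_z_dbp": float(s.psi_aniso_z[0]),
                         "psi_z_sbp": float(s.psi_aniso_z[-1])})
    paths["load_fractions"] = out_dir / "load_fractions.csv"
    pd.DataFrame(bars).to_csv(paths["load_fractions"], index=False)

    curves = []
    for c in comparisons:
        for s in (c.silico, c.membrane):
            df = s.to_frame()
            df.insert(0, "set_id", c.set_id)
            curves.append(df)
    paths["stress_curves"] = out_dir / "stress_curves.csv"
    pd.concat(curves, ignore_index=True).to_csv(paths["stress_curves"], index=False)
    return paths
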