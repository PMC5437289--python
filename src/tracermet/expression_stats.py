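"""qPCR fold change and the variance-gated statistical decision procedure.

The testing procedure mirrors common wet-lab practice: a two-sided F-test
on the variance ratio decides the routing — if variances differ at the gate
level, a two-tailed Welch t-test is used, otherwise a two-tailed
pooled-variance Student t-test.  Single outliers may be removed by Grubbs'
test (at most one per call, removal always logged).  Differential read-outs
are filtered by a relative-change magnitude gate combined with the p-value
gate (defaults: >25% change for carbon-contribution data, >27% for
metabolite levels, p ≤ 0.05).  No multiple-testing correction is part of
the procedure; a Benjamini–Hochberg column is emitted as clearly labeled
supplementary output only.

qPCR relative quantification uses the ΔΔCt method against a reference gene
(default RPL19) with amplification efficiency fixed at 2 (perfect doubling
per cycle), configurable.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)

__all__ = [
    "CtTable",
    "FilterThresholds",
    "TestResult",
    "ddct_fold_change",
    "differential_filter",
    "grubbs_outlier",
    "variance_gated_ttest",
    "variance_gated_ttest_batch",
]


@dataclasses.dataclass(frozen=True)
class FilterThresholds:
    """Depiction-filter settings: magnitude gates and significance level."""

    contribution_change: float = 0.25
    level_change: float = 0.27
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("contribution_change", "level_change", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    def magnitude(self, kind: str) -> float:
        if kind == "contribution":
            return self.contribution_change
        if kind == "level":
            return self.level_change
        raise ValueError(f"unknown filter kind {kind!r}")


@dataclasses.dataclass(frozen=True)
class TestResult:
    """Outcome of the F-test-gated two-sample comparison."""

    statistic: float
    p_value: float
    test_used: str  # "student" or "welch"
    f_test_p: float
    degenerate: bool = False


@dataclasses.dataclass(frozen=True)
class CtTable:
    """qPCR cycle-threshold table: rows of (sample, condition, gene, ct).

    Every sample must include a Ct for the reference gene; Ct values must
    lie in (0, 45) — the usual 40-cycle run plus margin.
    """

    data: pd.DataFrame
    reference_gene: str = "RPL19"

    def __post_init__(self) -> None:
        required = {"sample", "condition", "gene", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns {sorted(missing)}")
        ct = self.data["ct"]
        if not ((ct > 0) & (ct < 45)).all():
            raise ValueError("Ct values must lie in (0, 45)")
        with_ref = set(self.data.loc[self.data["gene"] == self.reference_gene, "sample"])
        without = sorted(set(self.data["sample"]) - with_ref)
        if without:
            raise ValueError(
                f"samples missing reference gene {self.reference_gene!r}: {without}"
            )


def ddct_fold_change(
    ct: CtTable,
    target_gene: str,
    treated_condition: str,
    control_condition: str,
    efficiency: float = 2.0,
) -> float:
    """ΔΔCt fold change of ``target_gene`` in treated vs control condition.

    Per replicate ΔCt = Ct_target − Ct_reference; the fold change is
    ``efficiency ** −(mean ΔCt_treated − mean ΔCt_control)``.
    """
    dcts: dict[str, list[float]] = {treated_condition: [], control_condition: []}
    for condition in dcts:
        sub = ct.data[ct.data["condition"] == condition]
        for sample, grp in sub.groupby("sample"):
            target = grp.loc[grp["gene"] == target_gene, "ct"]
            ref = grp.loc[grp["gene"] == ct.reference_gene, "ct"]
            if len(target) == 0:
                continue
            if len(ref) == 0:
                raise ValueError(f"sample {sample!r} lacks reference Ct")
            dcts[condition].append(float(target.mean() - ref.mean()))
        if not dcts[condition]:
            raise ValueError(
                f"no {target_gene!r} replicates in condition {condition!r}"
            )
    ddct = float(np.mean(dcts[treated_condition]) - np.mean(dcts[control_condition]))
    return float(efficiency ** -ddct)


def variance_gated_ttest(group_a, group_b, gate_alpha: float = 0.05) -> TestResult:
    """Two-tailed t-test with F-test gating of the equal-variance assumption.

    A two-sided F-test on the variance ratio is run first; if its p-value is
    below ``gate_alpha`` the comparison uses Welch's correction, otherwise a
    pooled-variance Student t-test.  Zero variance in both groups yields
    p = 1 for equal means and p = 0 (flagged degenerate) otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        equal = a.mean() == b.mean()
        return TestResult(
            statistic=0.0 if equal else np.inf,
            p_value=1.0 if equal else 0.0,
            test_used="student",
            f_test_p=1.0,
            degenerate=not equal,
        )
    f_stat = va / vb if vb > 0 else np.inf
    f_dist = scipy.stats.f(len(a) - 1, len(b) - 1)
    f_p = float(min(1.0, 2 * min(f_dist.sf(f_stat), f_dist.cdf(f_stat))))
    use_welch = f_p < gate_alpha
    stat, p = scipy.stats.ttest_ind(a, b, equal_var=not use_welch)
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        test_used="welch" if use_welch else "student",
        f_test_p=f_p,
    )


def variance_gated_ttest_batch(
    a: np.ndarray, b: np.ndarray, gate_alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized gated test over rows of ``a`` (m×na) and ``b`` (m×nb).

    Returns ``(p_values, used_welch)``; used by large calibration
    simulations.  Row semantics identical to :func:`variance_gated_ttest`
    for non-degenerate data (cross-checked in the test suite).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = va / vb
    f_dist = scipy.stats.f(na - 1, nb - 1)
    f_p = np.minimum(1.0, 2 * np.minimum(f_dist.sf(f_stat), f_dist.cdf(f_stat)))
    used_welch = f_p < gate_alpha

    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_student = (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))
        se2 = va / na + vb / nb
        t_welch = (ma - mb) / np.sqrt(se2)
        df_welch = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p_student = 2 * scipy.stats.t.sf(np.abs(t_student), na + nb - 2)
    p_welch = 2 * scipy.stats.t.sf(np.abs(t_welch), df_welch)
    return np.where(used_welch, p_welch, p_student), used_welch


def grubbs_outlier(values, alpha: float = 0.05) -> int | None:
    """Grubbs' single-outlier test: index of the outlier, or ``None``.

    The statistic G = max|xᵢ − mean| / sd is compared with the two-sided
    critical value derived from the Student t quantile at level ``alpha``.
    At most one outlier is flagged per call; zero spread flags nothing.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs' test needs >= 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        return None
    deviations = np.abs(x - x.mean())
    idx = int(np.argmax(deviations))
    g = deviations[idx] / sd
    t_crit = scipy.stats.t.ppf(1 - alpha / (2 * n), n - 2)
    g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t_crit**2 / (n - 2 + t_crit**2))
    if g > g_crit:
        logger.info("Grubbs outlier at index %d (G=%.3f > %.3f)", idx, g, g_crit)
        return idx
    return None


def differential_filter(
    table: pd.DataFrame,
    kind: str,
    control: str,
    treated: str,
    thresholds: FilterThresholds | None = None,
    change_definition: str = "relative",
    bh_supplementary: bool = True,
) -> pd.DataFrame:
    """Depiction-style differential filter over per-metabolite replicate values.

    ``table`` holds columns ``metabolite, condition, value`` with >= 2
    replicates per condition per metabolite.  A metabolite is retained iff
    its change exceeds the magnitude gate for ``kind`` (``"contribution"``
    or ``"level"``) AND the variance-gated t-test p-value is <= alpha.
    The change is the relative change of the group mean,
    |mean_t − mean_c| / mean_c, by default; ``change_definition="absolute"``
    uses the absolute difference instead (percentage-point dialect).
    Direction is the sign of mean_t − mean_c.  Metabolites with zero
    baseline mean are skipped with a warning.  A Benjamini–Hochberg column
    (``bh_q_supplementary``) is appended as supplementary output only; it
    plays no role in the retained flag.
    """
    if thresholds is None:
        thresholds = FilterThresholds()
    magnitude_gate = thresholds.magnitude(kind)
    rows = []
    for metabolite, grp in table.groupby("metabolite", sort=True):
        vals_c = grp.loc[grp["condition"] == control, "value"].to_numpy(float)
        vals_t = grp.loc[grp["condition"] == treated, "value"].to_numpy(float)
        if len(vals_c) < 2 or len(vals_t) < 2:
            raise ValueError(f"{metabolite}: >= 2 replicates required per condition")
        mean_c, mean_t = vals_c.mean(), vals_t.mean()
        if change_definition == "relative":
            if mean_c == 0:
                logger.warning("%s: zero baseline mean, skipped", metabolite)
                continue
            change = abs(mean_t - mean_c) / abs(mean_c)
        elif change_definition == "absolute":
            change = abs(mean_t - mean_c)
        else:
            raise ValueError(f"unknown change_definition {change_definition!r}")
        result = variance_gated_ttest(vals_c, vals_t, gate_alpha=thresholds.alpha)
        rows.append(
            {
                "metabolite": metabolite,
                "mean_control": mean_c,
                "mean_treated": mean_t,
                "change": change,
                "f_test_p": result.f_test_p,
                "test_used": result.test_used,
                "p_value": result.p_value,
                "retained": change > magnitude_gate and result.p_value <= thresholds.alpha,
                "direction": int(np.sign(mean_t - mean_c)),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "metabolite", "mean_control", "mean_treated", "change",
            "f_test_p", "test_used", "p_value", "retained", "direction",
        ],
    )
    if bh_supplementary and len(out):
        # supplementary only — not part of the replication's decision rule
        out["bh_q_supplementary"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q
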