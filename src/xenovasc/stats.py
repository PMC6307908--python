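"""Normality-gated statistical routing for two-group and multi-group data.

The decision tree mirrors the study's analysis protocol:

two groups
    Shapiro–Wilk on each sample. Both normal → two-sided F-test on the
    variances; unequal (p < gate) → Welch's t-test, else pooled t-test.
    Either sample non-normal → two-sided Mann–Whitney U.

three or more groups
    Shapiro–Wilk per group. All normal → one-way ANOVA followed by
    Dunnett's many-to-one comparisons against the control group (critical
    values from the equicorrelated multivariate-t distribution). Any group
    non-normal → Kruskal–Wallis.

All gates use the same significance level (default 0.05), recorded step by
step in ``decision_path`` so the route taken is fully auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import SampleSizeError

GateRecord = tuple[str, float, str]  # (gate name, p or statistic, outcome)


@dataclass
class TestResult:
    """Outcome of the routed comparison, with the full decision path."""

    test_name: str  # t | welch_t | mann_whitney | anova_dunnett | kruskal_wallis
    statistic: float
    p_value: float
    decision_path: list[GateRecord]
    alpha_gate: float
    comparisons: list[dict] = field(default_factory=list)  # Dunnett branch only

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value!r}")

    def summary(self) -> str:
        lines = [f"test: {self.test_name}  statistic={self.statistic:.6g}  p={self.p_value:.6g}"]
        for gate, p, outcome in self.decision_path:
            lines.append(f"  gate {gate}: p={p:.6g} -> {outcome}")
        for comp in self.comparisons:
            lines.append(
                f"  dunnett group {comp['group']} vs control: "
                f"stat={comp['statistic']:.6g} p_adj={comp['p_adjusted']:.6g}"
            )
        return "\n".join(lines)


def _as_sample(x, name: str, min_n: int = 3) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_n:
        raise SampleSizeError(f"sample {name!r} needs n >= {min_n}, got n = {arr.size}")
    return arr


def _shapiro_gate(sample: np.ndarray, name: str, alpha: float, path: list[GateRecord]) -> bool:
    if np.ptp(sample) == 0:
        # constant sample: Shapiro-Wilk undefined; treat as non-normal
        path.append((f"shapiro_{name}", float("nan"), "constant sample -> non-normal"))
        return False
    p = float(sps.shapiro(sample).pvalue)
    ok = p >= alpha
    path.append((f"shapiro_{name}", p, "normal" if ok else "non-normal"))
    return ok


def _f_test_two_sided(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    cdf = sps.f.cdf(f, dfa, dfb)
    return f, float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))


def compare_two(a, b, alpha_gate: float = 0.05) -> TestResult:
    """Route a two-group comparison through the normality/variance gates."""
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    path: list[GateRecord] = []
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # both samples constant: every gate is degenerate; pooled t by convention
        path.append(("degenerate", float("nan"), "both samples constant -> pooled t"))
        equal_means = float(a.mean()) == float(b.mean())
        return TestResult(
            test_name="t",
            statistic=0.0 if equal_means else float("inf") * np.sign(a.mean() - b.mean()),
            p_value=1.0 if equal_means else 0.0,
            decision_path=path,
            alpha_gate=alpha_gate,
        )
    normal_a = _shapiro_gate(a, "a", alpha_gate, path)
    normal_b = _shapiro_gate(b, "b", alpha_gate, path)

    if normal_a and normal_b:
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        if va == 0 and vb == 0:
            # both samples constant: F gate degenerate, pooled t by convention
            path.append(("f_variance", float("nan"), "degenerate -> pooled t"))
            equal_var = True
        else:
            f, p_f = _f_test_two_sided(a, b)
            equal_var = p_f >= alpha_gate
            path.append(("f_variance", p_f, "equal -> pooled t" if equal_var else "unequal -> welch"))
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        return TestResult(
            test_name="t" if equal_var else "welch_t",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            decision_path=path,
            alpha_gate=alpha_gate,
        )

    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    small = max(a.size, b.size) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    path.append(("mann_whitney_method", float("nan"), method))
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        test_name="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        decision_path=path,
        alpha_gate=alpha_gate,
    )


def compare_many(
    groups: Sequence, control_index: int = 0, alpha_gate: float = 0.05
) -> TestResult:
    """Route a >= 3 group comparison: ANOVA + Dunnett, or Kruskal–Wallis."""
    if len(groups) < 3:
        raise SampleSizeError(f"compare_many needs >= 3 groups, got {len(groups)}")
    samples = [_as_sample(g, f"group{i}") for i, g in enumerate(groups)]
    if not 0 <= control_index < len(samples):
        raise ValueError(f"control_index {control_index} out of range for {len(samples)} groups")
    path: list[GateRecord] = []
    all_normal = all(
        _shapiro_gate(s, f"group{i}", alpha_gate, path) for i, s in enumerate(samples)
    )

    if all_normal:
        anova = sps.f_oneway(*samples)
        path.append(("route", float("nan"), "all normal -> anova + dunnett"))
        control = samples[control_index]
        treatments = [s for i, s in enumerate(samples) if i != control_index]
        treatment_ids = [i for i in range(len(samples)) if i != control_index]
        dn = sps.dunnett(*treatments, control=control)
        comparisons = [
            {
                "group": gid,
                "statistic": float(stat),
                "p_adjusted": float(p),
            }
            for gid, stat, p in zip(treatment_ids, np.atleast_1d(dn.statistic), np.atleast_1d(dn.pvalue))
        ]
        return TestResult(
            test_name="anova_dunnett",
            statistic=float(anova.statistic),
            p_value=float(anova.pvalue),
            decision_path=path,
            alpha_gate=alpha_gate,
            comparisons=comparisons,
        )

    path.append(("route", float("nan"), "non-normal group -> kruskal-wallis"))
    kw = sps.kruskal(*samples)
    return TestResult(
        test_name="kruskal_wallis",
        statistic=float(kw.statistic),
        p_value=float(kw.pvalue),
        decision_path=path,
        alpha_gate=alpha_gate,
    )
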