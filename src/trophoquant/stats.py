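"""Inference layer: large-sample Mann-Whitney U, variance-gated t-test, ΔΔCT.

Per-cell normalized intensities are not normally distributed, so group
comparisons of image-derived intensities use the Mann-Whitney U test in its
large-sample normal approximation, with midranks for ties and the standard
tie-corrected variance; ties are frequent because fallback cells share the
normalized value 1.0 exactly. No continuity correction is applied by default
(a config flag enables it); an exact enumeration oracle bounds the
approximation error in the test suite.

All other comparisons use a two-tailed Student's t-test whose equal/unequal
variance choice is gated by a two-sample F-test for equality of variances at
alpha 0.05.

qPCR fold changes follow the ΔΔCT method: each Ct is normalized against the
geometric mean of the housekeeping Cts (GAPDH and ACTB by default, the
geometric mean taken over the Ct values themselves), ΔΔCt is referenced to
the day-0 condition, and log2 fold change = −ΔΔCt with SE across replicates.

Raw p-values are reported at the 0.05 level without multiple-testing
correction; an optional Benjamini-Hochberg adjustment is available but off
by default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney_large_sample",
    "exact_mann_whitney_oracle",
    "variance_gated_t_test",
    "delta_delta_ct",
    "significance_marker",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    tails: str = "two"
    notes: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def significance_marker(p: float) -> str:
    """Marker convention: * p<0.05, ** p<0.005, *** p<0.0005, else ns."""
    if p != p:  # nan
        return ""
    if p < 0.0005:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Midrank U statistic for the first sample, plus pooled ranks."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return float(u1), ranks


def mann_whitney_large_sample(
    x: Sequence[float], y: Sequence[float], *, continuity: bool = False
) -> TestResult:
    """Two-sided Mann-Whitney U test via the normal approximation.

    U is computed from midranks; z = (U − n1·n2/2)/σ_U with the
    tie-corrected σ_U, and the two-sided p comes from the standard normal.
    When every pooled value is identical the test is degenerate and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be nonempty")
    u, ranks = _mann_whitney_u(x, y)
    n = n1 + n2
    mu = n1 * n2 / 2.0

    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    if n > 1:
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    else:
        var = 0.0

    notes: dict = {"tie_correction": bool((tie_counts > 1).any()), "continuity": continuity}
    if var <= 0:
        return TestResult(u, 1.0, "mann-whitney-normal", n1, n2, notes={**notes, "degenerate": True})
    dev = u - mu
    if continuity and dev != 0:
        dev -= math.copysign(0.5, dev)
    z = dev / math.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    notes["z"] = z
    return TestResult(u, p, "mann-whitney-normal", n1, n2, notes=notes)


_COMBO_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _label_combinations(n: int, n1: int) -> np.ndarray:
    """All C(n, n1) index subsets, cached (repeated enumeration is the cost)."""
    key = (n, n1)
    if key not in _COMBO_CACHE:
        _COMBO_CACHE[key] = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n), n1)),
            dtype=np.intp,
        ).reshape(-1, n1)
    return _COMBO_CACHE[key]


def exact_mann_whitney_oracle(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided Mann-Whitney p by complete enumeration (n1 + n2 ≤ 20).

    Enumerates every assignment of the pooled values to a group of size n1,
    and returns the probability of a U at least as far from its mean as the
    observed one. Intended as a test oracle for the normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    if n > 20:
        raise ValueError("enumeration oracle limited to n1 + n2 <= 20")
    u_obs, ranks = _mann_whitney_u(x, y)
    mu = n1 * n2 / 2.0
    combos = _label_combinations(n, n1)
    u_all = ranks[combos].sum(axis=1) - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    return float(np.mean(np.abs(u_all - mu) >= dev_obs - 1e-9))


def variance_gated_t_test(
    x: Sequence[float], y: Sequence[float], alpha_f: float = 0.05
) -> TestResult:
    """Two-tailed t-test with the variance assumption gated by an F-test.

    A two-sided F-test on the sample-variance ratio decides the branch: if
    its p < ``alpha_f`` the Welch (unequal-variance) test is used, otherwise
    the pooled Student test. The F decision is recorded in the notes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need n >= 2")
    v1 = float(x.var(ddof=1))
    v2 = float(y.var(ddof=1))

    # variances that are zero up to float fuzz (replicates identical to
    # rounding) make the t statistic meaningless; compare means directly
    scale = max(float(np.abs(x).max()), float(np.abs(y).max()), 1.0)
    tol = (1e-12 * scale) ** 2
    if v1 <= tol and v2 <= tol:
        equal_means = abs(float(x.mean()) - float(y.mean())) <= 1e-9 * scale
        return TestResult(
            0.0 if equal_means else math.inf,
            1.0 if equal_means else 0.0,
            "t-student",
            n1,
            n2,
            notes={"degenerate": True, "f_p": 1.0, "welch": False},
        )

    if v1 >= v2:
        f, d1, d2 = (v1 / v2 if v2 > 0 else math.inf), n1 - 1, n2 - 1
    else:
        f, d1, d2 = v2 / v1, n2 - 1, n1 - 1
    f_p = 1.0 if math.isinf(f) else float(min(1.0, 2.0 * sps.f.sf(f, d1, d2)))
    if math.isinf(f):
        f_p = 0.0
    welch = f_p < alpha_f

    res = sps.ttest_ind(x, y, equal_var=not welch)
    return TestResult(
        float(res.statistic),
        float(res.pvalue),
        "t-welch" if welch else "t-student",
        n1,
        n2,
        notes={"f_statistic": f, "f_p": f_p, "welch": welch},
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; raw p is the default
    reporting convention here)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def _hk_geomean(sample: pd.DataFrame, housekeeping: Sequence[str], sample_name: str) -> float:
    cts = []
    for hk in housekeeping:
        vals = sample.loc[sample["gene"] == hk, "ct"]
        if vals.empty:
            raise ValueError(f"sample {sample_name}: missing housekeeping Ct for {hk}")
        cts.append(float(vals.mean()))
    return float(sps.gmean(cts))


def delta_delta_ct(
    table: pd.DataFrame,
    housekeeping: Sequence[str] = ("GAPDH", "ACTB"),
    reference: str | None = None,
) -> pd.DataFrame:
    """ΔΔCT relative quantification of a tidy Ct table.

    Per sample (condition × replicate), ΔCt(gene) = Ct(gene) − geometric
    mean of the housekeeping Cts. Per gene and condition, ΔΔCt = mean
    replicate ΔCt minus the reference condition's mean ΔCt, and
    log2 fold change = −ΔΔCt. The SE is across replicate ΔCt values, and
    the p-value compares per-replicate ΔCt against the reference condition
    with the variance-gated two-tailed t-test.

    The table needs columns gene, condition, replicate, ct (a ``role``
    column, if present, restricts the output to target genes).
    """
    required = {"gene", "condition", "replicate", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if reference is None:
        if "reference_condition" in table.columns:
            reference = str(table["reference_condition"].iloc[0])
        else:
            reference = "day0"
    if reference not in set(table["condition"]):
        raise ValueError(f"reference condition {reference!r} not present")

    delta_rows = []
    for (cond, rep), sample in table.groupby(["condition", "replicate"], sort=False):
        hk_gm = _hk_geomean(sample, housekeeping, f"{cond}/rep{rep}")
        targets = sample[~sample["gene"].isin(housekeeping)]
        for _, row in targets.iterrows():
            delta_rows.append(
                {
                    "gene": row["gene"],
                    "condition": cond,
                    "replicate": rep,
                    "delta_ct": float(row["ct"]) - hk_gm,
                }
            )
    delta = pd.DataFrame(delta_rows)

    out_rows = []
    for gene, gdf in delta.groupby("gene", sort=False):
        ref_dcts = gdf.loc[gdf["condition"] == reference, "delta_ct"].to_numpy()
        if len(ref_dcts) == 0:
            raise ValueError(f"gene {gene}: no Ct in reference condition {reference!r}")
        ref_mean = float(ref_dcts.mean())
        for cond, cdf in gdf.groupby("condition", sort=False):
            dcts = cdf["delta_ct"].to_numpy()
            ddct = float(dcts.mean()) - ref_mean
            if cond == reference:
                ddct = 0.0  # identically zero by definition
            se = float(dcts.std(ddof=1) / math.sqrt(len(dcts))) if len(dcts) > 1 else math.nan
            if cond == reference or len(dcts) < 2 or len(ref_dcts) < 2:
                p = math.nan
            else:
                p = variance_gated_t_test(dcts, ref_dcts).p_value
            out_rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "n_replicates": len(dcts),
                    "mean_delta_ct": float(dcts.mean()),
                    "delta_delta_ct": ddct,
                    "log2fc": -ddct + 0.0,
                    "se": se,
                    "p_value": p,
                    "significance": significance_marker(p),
                }
            )
    return pd.DataFrame(out_rows)
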