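"""Foci-count and pollen-viability comparisons, and comparative-CT qPCR.

Cytology side: per-group summaries (mean, n) and Welch's unequal-variance
t-test with Welch–Satterthwaite degrees of freedom.

qPCR side: the comparative-CT (ΔΔCT) method.  Technical replicates are
averaged to one CT per sample × gene; ΔCT = CT(target) − CT(control) per
sample; ΔΔCT = mean ΔCT(treatment) − mean ΔCT(reference); fold change =
2^−ΔΔCT.  Treatments are compared by one-way ANOVA on ΔCT followed by
Tukey's honest significant difference test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import FociRecord, QpcrRecord

__all__ = [
    "WelchResult",
    "DdctResult",
    "summarize_foci",
    "welch_t",
    "delta_ct",
    "ddct_fold_change",
    "anova_tukey",
    "significance_label",
]


# ---------------------------------------------------------------------------
# Cytology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def _foci_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = [
        {
            "cell_id": r.cell_id,
            "genotype": r.genotype,
            "temperature": r.temperature,
            "antibody": r.antibody,
            "count": r.count,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["cell_id", "genotype", "temperature", "antibody", "count"]
    )


def summarize_foci(records, group_keys: Sequence[str]) -> pd.DataFrame:
    """Mean focus count and n per group.

    ``records`` is an iterable of :class:`FociRecord` or a DataFrame with a
    ``count`` column; ``group_keys`` are column names to group by (e.g.
    ``["genotype", "temperature"]``).  Empty groups simply do not appear.
    """
    frame = _foci_frame(records)
    if (frame["count"] < 0).any():
        raise ValueError("focus counts must be non-negative")
    if frame.empty:
        return pd.DataFrame(columns=[*group_keys, "mean", "n"])
    out = (
        frame.groupby(list(group_keys), sort=True)["count"]
        .agg(mean="mean", n="size")
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


def welch_t(group_a, group_b) -> WelchResult:
    """Welch's two-sample t-test (unequal variances), two-sided.

    Both groups need n ≥ 2.  If both variances are zero the statistic is
    defined only for equal means (t = 0, p = 1); unequal constant groups are
    infinitely separated (t = ±inf, p = 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        diff = a.mean() - b.mean()
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0.0 else 0.0
        df = float(a.size + b.size - 2)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return WelchResult(
        t=t,
        df=df,
        p=p,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def significance_label(p: float) -> str:
    """Figure-legend significance label for a p-value.

    Follows the plotting convention used throughout: ``****`` p ≤ 0.0001,
    ``***`` p ≤ 0.001, ``**`` p ≤ 0.01, ``*`` p ≤ 0.05, and ``ns`` for
    p > 0.5 — the legend defines "ns" with that threshold verbatim, which
    leaves p in (0.05, 0.5] unlabeled (empty string).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    if p > 0.5:
        return "ns"
    return ""


# ---------------------------------------------------------------------------
# Comparative-CT qPCR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DdctResult:
    """Comparative-CT analysis of one target gene against a control gene."""

    target_gene: str
    control_gene: str
    reference_treatment: str
    sample_delta_ct: pd.DataFrame  # sample_id, treatment, delta_ct
    mean_delta_ct: dict[str, float]  # per treatment
    delta_delta_ct: dict[str, float]  # per treatment, vs reference
    fold_change: dict[str, float]  # 2^-ΔΔCT per treatment
    anova_f: float
    anova_p: float
    tukey_p: dict[tuple[str, str], float]  # adjusted p per treatment pair


def _qpcr_frame(plate) -> pd.DataFrame:
    if isinstance(plate, pd.DataFrame):
        return plate
    rows = [
        {
            "sample_id": r.sample_id,
            "treatment": r.treatment,
            "gene": r.gene,
            "ct": r.ct,
            "tech_rep": r.tech_rep,
        }
        for r in plate
    ]
    return pd.DataFrame(rows, columns=["sample_id", "treatment", "gene", "ct", "tech_rep"])


def delta_ct(plate, target_gene: str, control_gene: str) -> pd.DataFrame:
    """Per-sample ΔCT = mean CT(target) − mean CT(control), in cycles.

    Technical replicates are averaged within sample × gene before the
    subtraction.  Samples missing control-gene wells raise a ``ValueError``
    naming them; samples missing the target gene are likewise rejected.
    """
    frame = _qpcr_frame(plate)
    if target_gene == control_gene:
        raise ValueError("target and control gene must differ")
    means = (
        frame[frame["gene"].isin([target_gene, control_gene])]
        .groupby(["sample_id", "treatment", "gene"])["ct"]
        .mean()
        .unstack("gene")
        .reset_index()
    )
    for gene in (target_gene, control_gene):
        if gene not in means.columns:
            missing = sorted(means["sample_id"])
            raise ValueError(f"no {gene!r} wells for samples: {missing}")
        bad = means.loc[means[gene].isna(), "sample_id"].tolist()
        if bad:
            raise ValueError(f"missing {gene!r} wells for samples: {bad}")
    means["delta_ct"] = means[target_gene] - means[control_gene]
    return means[["sample_id", "treatment", "delta_ct"]]


def anova_tukey(
    delta_cts: pd.DataFrame,
) -> tuple[float, float, dict[tuple[str, str], float]]:
    """One-way ANOVA on ΔCT across treatments + Tukey HSD adjusted p per pair.

    ``delta_cts`` is the frame returned by :func:`delta_ct`.  Requires at
    least two treatments with n ≥ 2 each.
    """
    groups = {t: g["delta_ct"].to_numpy() for t, g in delta_cts.groupby("treatment")}
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two treatments")
    for t, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"treatment {t!r} has fewer than 2 samples")
    labels = sorted(groups)
    arrays = [groups[t] for t in labels]
    f_res = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    tukey_p: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            tukey_p[(a, labels[j])] = float(hsd.pvalue[i, j])
    return float(f_res.statistic), float(f_res.pvalue), tukey_p


def ddct_fold_change(
    delta_cts: pd.DataFrame,
    reference_treatment: str,
    target_gene: str = "",
    control_gene: str = "",
) -> DdctResult:
    """ΔΔCT and 2^−ΔΔCT fold changes per treatment, with ANOVA + Tukey.

    ΔΔCT(treatment) = mean ΔCT(treatment) − mean ΔCT(reference); the
    reference treatment's fold change is exactly 1.
    """
    treatments = list(dict.fromkeys(delta_cts["treatment"]))
    if reference_treatment not in treatments:
        raise ValueError(
            f"reference treatment {reference_treatment!r} absent "
            f"(have: {treatments})"
        )
    mean_dct = delta_cts.groupby("treatment")["delta_ct"].mean().to_dict()
    ref = mean_dct[reference_treatment]
    ddct = {t: mean_dct[t] - ref for t in mean_dct}
    fold = {t: 2.0 ** (-d) for t, d in ddct.items()}
    fold[reference_treatment] = 1.0  # exact by definition
    f, p, tukey_p = anova_tukey(delta_cts)
    return DdctResult(
        target_gene=target_gene,
        control_gene=control_gene,
        reference_treatment=reference_treatment,
        sample_delta_ct=delta_cts,
        mean_delta_ct={t: float(v) for t, v in mean_dct.items()},
        delta_delta_ct={t: float(v) for t, v in ddct.items()},
        fold_change={t: float(v) for t, v in fold.items()},
        anova_f=f,
        anova_p=p,
        tukey_p=tukey_p,
    )
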