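"""Group statistics across clearing protocols and report generation.

Size-type metrics (diameters, depth metrics) are compared with the
non-parametric Kruskal–Wallis test followed by Dunn's multiple-comparison
test; count-type metrics (segmentation counts) with one-way ANOVA followed
by Tukey's HSD. Normality is screened per group with the Lilliefors variant
of the Kolmogorov–Smirnov test (estimated mean/SD). α = 0.05; all pairwise
p-values are adjusted for multiple comparisons.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass
class GroupComparison:
    """Outcome of one metric's comparison across protocol groups."""

    metric_name: str
    groups: list[str]
    normality_p: dict[str, float]
    normality_test: str
    test_used: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group1, group2, p_adj
    alpha: float = ALPHA
    degenerate: bool = False


def _dunn_test(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post-hoc test after Kruskal–Wallis.

    Pairwise z statistics on tie-corrected mean ranks of the pooled sample;
    two-sided normal p-values with Bonferroni adjustment across all pairs.
    """
    names = list(samples)
    pooled = np.concatenate([samples[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks = {}
    start = 0
    for g in names:
        n = len(samples[g])
        mean_ranks[g] = ranks[start : start + n].mean()
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12 - tie_term
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for g1, g2 in pairs:
        se = np.sqrt(var_base * (1 / len(samples[g1]) + 1 / len(samples[g2])))
        if se == 0:
            p = np.nan
        else:
            z = (mean_ranks[g1] - mean_ranks[g2]) / se
            p = min(1.0, 2 * stats.norm.sf(abs(z)) * len(pairs))
        rows.append({"group1": g1, "group2": g2, "p_adj": p})
    return pd.DataFrame(rows)


def compare_groups(
    values: dict[str, "np.ndarray | list[float]"],
    metric_kind: str,
    metric_name: str = "",
) -> GroupComparison:
    """Compare one metric across protocol groups.

    ``metric_kind``: ``"size"`` → Kruskal–Wallis + Dunn (Bonferroni);
    ``"count"`` → one-way ANOVA + Tukey HSD. Groups of identical constants
    are flagged degenerate (p-values NaN) rather than crashing.
    """
    if metric_kind not in ("size", "count"):
        raise ValueError("metric_kind must be 'size' or 'count'")
    if len(values) < 2:
        raise ValueError("need at least 2 groups")
    samples = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    for g, v in samples.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has {len(v)} samples; need >= 3")
    names = list(samples)
    pairs = list(itertools.combinations(names, 2))

    from statsmodels.stats.diagnostic import kstest_normal

    normality = {}
    for g, v in samples.items():
        if np.ptp(v) == 0:
            normality[g] = np.nan
        else:
            normality[g] = float(kstest_normal(v, dist="norm")[1])

    pooled = np.concatenate(list(samples.values()))
    if np.ptp(pooled) == 0:
        pairwise = pd.DataFrame(
            [{"group1": a, "group2": b, "p_adj": np.nan} for a, b in pairs]
        )
        return GroupComparison(
            metric_name, names, normality, "lilliefors",
            "kruskal-wallis+dunn" if metric_kind == "size" else "anova+tukey",
            np.nan, np.nan, pairwise, degenerate=True,
        )

    if metric_kind == "size":
        stat, p = stats.kruskal(*samples.values())
        pairwise = _dunn_test(samples)
        test_used = "kruskal-wallis+dunn"
    else:
        stat, p = stats.f_oneway(*samples.values())
        res = stats.tukey_hsd(*samples.values())
        pairwise = pd.DataFrame(
            [
                {"group1": names[i], "group2": names[j],
                 "p_adj": float(res.pvalue[i, j])}
                for i, j in [(names.index(a), names.index(b)) for a, b in pairs]
            ]
        )
        test_used = "anova+tukey"
    return GroupComparison(
        metric_name, names, normality, "lilliefors", test_used,
        float(stat), float(p), pairwise,
    )


def build_report(
    results: pd.DataFrame,
    comparisons: list[GroupComparison],
    out_dir: str | os.PathLike,
    z_profiles: dict[str, object] | None = None,
    snr_profiles: dict[str, object] | None = None,
) -> None:
    """Write summary/per-metric CSVs, pairwise statistics, and profile plots.

    ``z_profiles`` / ``snr_profiles`` map protocol name to a profile object;
    each produces one plot with one curve per protocol versus normalized
    depth. CSV output is deterministic (sorted rows, fixed float format).
    """
    os.makedirs(out_dir, exist_ok=True)
    results = results.sort_values(
        ["protocol", "sample_id", "channel", "metric_name"]
    ).reset_index(drop=True)
    results.to_csv(os.path.join(out_dir, "results.csv"), index=False, float_format="%.6g")

    summary = (
        results.groupby(["protocol", "channel", "metric_name"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .sort_values(["metric_name", "channel", "protocol"])
    )
    summary.to_csv(os.path.join(out_dir, "summary.csv"), index=False, float_format="%.6g")

    for metric, sub in results.groupby("metric_name"):
        sub.to_csv(
            os.path.join(out_dir, f"metric_{metric}.csv"), index=False, float_format="%.6g"
        )

    if comparisons:
        rows = []
        for c in comparisons:
            for _, r in c.pairwise.iterrows():
                rows.append(
                    {
                        "metric_name": c.metric_name,
                        "test": c.test_used,
                        "group1": r["group1"],
                        "group2": r["group2"],
                        "p_adj": r["p_adj"],
                        "significant": bool(r["p_adj"] < c.alpha)
                        if np.isfinite(r["p_adj"])
                        else False,
                    }
                )
        pd.DataFrame(rows).sort_values(["metric_name", "group1", "group2"]).to_csv(
            os.path.join(out_dir, "pairwise_stats.csv"), index=False, float_format="%.6g"
        )

    _plot_profiles(z_profiles, "mean_intensity", "Mean intensity (a.u.)",
                   os.path.join(out_dir, "intensity_vs_depth.png"))
    _plot_profiles(snr_profiles, "snr", "SNR", os.path.join(out_dir, "snr_vs_depth.png"),
                   hline=5.0)


def _plot_profiles(profiles, attr, ylabel, path, hline=None) -> None:
    if not profiles:
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, prof in profiles.items():
        ax.plot(prof.normalized_depths_um, getattr(prof, attr), label=name)
    if hline is not None:
        ax.axhline(hline, color="gray", ls="--", lw=0.8)
    ax.set_xlabel("Normalized depth (μm)")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
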