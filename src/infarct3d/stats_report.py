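"""Two-branch group comparisons and figure-style summary tables.

Each pairwise day-group comparison first checks normality of both samples
with the Shapiro–Wilk test; if both pass at the chosen alpha the groups are
compared with an independent-samples t test (Welch variant — the safer
default when variances may differ), otherwise with the Mann–Whitney U test.
Descriptives follow the same branch: mean ± SD for the normal branch,
median (IQR) otherwise.  No multiple-testing correction is applied by
default, matching the underlying reporting style; a Benjamini–Hochberg
option is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientSampleError

__all__ = ["GroupComparison", "compare_groups", "benjamini_hochberg",
           "build_report"]


@dataclass
class GroupComparison:
    variable: str
    group_labels: tuple[str, str]
    n: tuple[int, int]
    mean: tuple[float, float]
    sd: tuple[float, float]
    median: tuple[float, float]
    iqr: tuple[float, float]
    normality_p: tuple[float, float]
    test_used: str              # "t" | "mann-whitney"
    p_value: float
    significant: bool

    def describe(self, i: int) -> str:
        """Group descriptive in the reporting style of its branch."""
        if self.test_used == "t":
            return f"{self.mean[i]:.4g} ± {self.sd[i]:.4g}"
        return f"{self.median[i]:.4g} ({self.iqr[i]:.4g})"


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) < 1e-12:        # constant sample: trivially non-normal
        return 0.0
    return float(stats.shapiro(x).pvalue)


def compare_groups(sample_a, sample_b, alpha: float = 0.05,
                   variable: str = "", labels: tuple[str, str] = ("a", "b")
                   ) -> GroupComparison:
    """Compare two independent samples with the normality-gated two-branch
    procedure (Shapiro–Wilk, then Welch t or Mann–Whitney U)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientSampleError(
            f"need n >= 3 per group, got {len(a)} and {len(b)}")
    pa, pb = _shapiro_p(a), _shapiro_p(b)
    if pa > alpha and pb > alpha:
        test_used = "t"
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    else:
        test_used = "mann-whitney"
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    q75a, q25a = np.percentile(a, [75, 25])
    q75b, q25b = np.percentile(b, [75, 25])
    return GroupComparison(
        variable=variable, group_labels=tuple(labels),
        n=(len(a), len(b)),
        mean=(float(a.mean()), float(b.mean())),
        sd=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        median=(float(np.median(a)), float(np.median(b))),
        iqr=(float(q75a - q25a), float(q75b - q25b)),
        normality_p=(pa, pb), test_used=test_used, p_value=p,
        significant=bool(p < alpha))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p values (off by default in reports)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def build_report(summaries: dict, comparisons: list[GroupComparison] | None = None,
                 out_dir: str | Path = "report", plots: bool = False) -> dict:
    """Render day-keyed lobe summaries (and optional comparisons) to CSV.

    ``summaries`` maps a day label to a
    :class:`~infarct3d.morphometry.LobeSummary`.  Returns the written paths.
    """
    if not summaries:
        raise ValueError("need at least one lobe summary")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for day, s in summaries.items():
        row = {
            "day": day,
            "n_infarcts": s.n_infarcts,
            "total_volume_um3": s.total_volume_um3,
            "volume_ratio": s.volume_ratio,
            "confluent_fraction": s.confluent_fraction,
            "mean_channels_per_infarct": s.mean_channels_per_infarct,
        }
        for z in (1, 2, 3):
            pz = s.per_zone.get(z, {})
            row[f"zone{z}_count_fraction"] = pz.get("count_fraction", 0.0)
            row[f"zone{z}_total_volume_um3"] = pz.get("total_volume_um3", 0.0)
            sph = pz.get("sphericities", [])
            row[f"zone{z}_sphericity_median"] = float(np.median(sph)) if sph else np.nan
        rows.append(row)
    summary_df = pd.DataFrame(rows)
    paths = {"summary": out / "lobe_summaries.csv"}
    summary_df.to_csv(paths["summary"], index=False)

    if comparisons:
        comp_df = pd.DataFrame([{
            "variable": c.variable,
            "group_a": c.group_labels[0], "group_b": c.group_labels[1],
            "n_a": c.n[0], "n_b": c.n[1],
            "desc_a": c.describe(0), "desc_b": c.describe(1),
            "normality_p_a": c.normality_p[0], "normality_p_b": c.normality_p[1],
            "test_used": c.test_used, "p_value": c.p_value,
            "significant": c.significant,
        } for c in comparisons])
        paths["comparisons"] = out / "comparisons.csv"
        comp_df.to_csv(paths["comparisons"], index=False)

    if plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
        days = summary_df["day"].astype(str)
        axes[0].bar(days, summary_df["n_infarcts"], color="firebrick")
        axes[0].set_ylabel("number of infarcts")
        axes[1].bar(days, summary_df["total_volume_um3"], color="firebrick")
        axes[1].set_ylabel("total infarct volume (µm³)")
        axes[2].bar(days, summary_df["volume_ratio"], color="firebrick")
        axes[2].set_ylabel("volume ratio in lobe")
        for ax in axes:
            ax.set_xlabel("day post-ligation")
        fig.tight_layout()
        paths["plot"] = out / "summary_bars.png"
        fig.savefig(paths["plot"], dpi=120)
        plt.close(fig)
    return paths
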