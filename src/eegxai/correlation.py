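"""Spearman correlation between channel features and channel importances.

For each (feature, band, explanation method) the per-channel feature values
of correctly classified ictal windows are paired with the per-channel
importance values and Spearman's rank correlation is computed, then banded
into the conventional interpretation scale (negligible < 0.30 <= low <
0.50 <= moderate < 0.70 <= high < 0.90 <= very high, signed).

Spearman's rho is the Pearson correlation of average ranks (ties share the
mean rank).  The two-sided p-value uses the exact permutation distribution
for n < 10 and the t approximation t = rho * sqrt((n-2)/(1-rho^2)) with
n - 2 degrees of freedom otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "SpearmanResult",
    "spearman",
    "classify_correlation",
    "correlate_all",
    "report",
    "BAND_THRESHOLDS",
]

BAND_THRESHOLDS = (0.30, 0.50, 0.70, 0.90)
_BAND_NAMES = ("negligible", "low", "moderate", "high", "very high")


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    pvalue: float
    n: int


def _rank(x: np.ndarray) -> np.ndarray:
    return sp_stats.rankdata(x, method="average")


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def spearman(x, y, exact_below: int = 10) -> SpearmanResult:
    """Spearman rho with tie-aware average ranks and a two-sided p-value.

    Constant input yields rho = NaN with a warning.  |rho| = 1 is reported
    with p = 0 (the permutation convention for a perfect monotone relation).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx, ry = _rank(x), _rank(y)
    rho = _rho_of_ranks(rx, ry)
    if np.isnan(rho):
        warnings.warn("constant input: rho undefined", stacklevel=2)
        return SpearmanResult(float("nan"), float("nan"), n)
    if abs(rho) >= 1 - 1e-12:
        return SpearmanResult(float(np.sign(rho)), 0.0, n)
    if n < exact_below:
        perms = np.array(list(permutations(range(n))))
        ry_perm = ry[perms]  # (n!, n)
        rxc = rx - rx.mean()
        ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc ** 2).sum()) * np.sqrt((ryc ** 2).sum(axis=1))
        rhos = (ryc @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2 * sp_stats.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho, p, n)


def classify_correlation(rho: float) -> str:
    """Interpretation band of a correlation coefficient.

    Boundary values belong to the higher band; e.g. 0.50 is moderate,
    -0.20 negligible, 0.71 high positive.
    """
    if np.isnan(rho):
        return "undefined"
    a = abs(rho)
    if a > 1:
        raise ValueError("|rho| must be <= 1")
    idx = sum(a >= t for t in BAND_THRESHOLDS)
    name = _BAND_NAMES[idx]
    if name == "negligible":
        return "negligible"
    return f"{name} {'positive' if rho >= 0 else 'negative'}"


def correlate_all(features: pd.DataFrame, importances: pd.DataFrame,
                  subject: str = "S0", mode: str = "pooled",
                  min_pairs: int = 3) -> pd.DataFrame:
    """One Spearman result per (feature, band, method) for one subject.

    ``features`` is the tidy feature table, ``importances`` the tidy
    importance matrix (only correctly classified ictal windows appear
    there, so the inner join restricts the analysis to those windows).
    ``mode='pooled'`` treats every (window, channel) pair as one
    observation; ``mode='per_channel_mean'`` averages both quantities over
    windows first, leaving one observation per channel.
    """
    if mode not in ("pooled", "per_channel_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    merged = features.merge(
        importances.rename(columns={"value": "importance"}),
        on=["window", "channel"], how="inner",
    )
    rows = []
    for (feat, band, method), grp in merged.groupby(
            ["feature", "band", "method"], sort=True):
        if mode == "per_channel_mean":
            grp = grp.groupby("channel", as_index=False)[
                ["value", "importance"]].mean()
        xv = grp["value"].to_numpy()
        yv = grp["importance"].to_numpy()
        if len(xv) < min_pairs:
            rows.append((subject, method, feat, band, len(xv),
                         float("nan"), float("nan"), "undefined",
                         "insufficient_pairs"))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = spearman(xv, yv)
        flag = "" if not np.isnan(res.rho) else "constant_input"
        rows.append((subject, method, feat, band, res.n, res.rho,
                     res.pvalue, classify_correlation(res.rho), flag))
    return pd.DataFrame(rows, columns=["subject", "method", "feature", "band",
                                       "n", "rho", "p", "label", "flag"])


def report(results: pd.DataFrame, outdir: str | Path | None = None,
           top_k: int = 3) -> dict:
    """Summaries: per-subject top correlations and per-method rho histograms.

    The top table lists, per subject and method, the ``top_k`` band/feature
    combinations with the largest correlation coefficients.  Histogram
    counts use the interpretation-band boundaries at +-0.30 and +-0.50.
    If ``outdir`` is given, a CSV and a histogram panel per method are
    written there.
    """
    if results.empty:
        raise ValueError("no correlation results to report")
    res = results.dropna(subset=["rho"]).copy()
    res["band_feature"] = res["band"].str.capitalize() + "/" + res["feature"]
    top = (res.sort_values("rho", ascending=False)
              .groupby(["subject", "method"], sort=True)
              .head(top_k)
              .loc[:, ["subject", "method", "band_feature", "rho", "p", "label"]]
              .reset_index(drop=True))
    edges = np.array([-1.0, -0.5, -0.3, 0.3, 0.5, 1.0])
    hist = {
        method: np.histogram(grp["rho"].to_numpy(), bins=edges)[0].tolist()
        for method, grp in res.groupby("method")
    }
    out = {"top": top, "histogram_edges": edges.tolist(), "histogram": hist}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        top.to_csv(outdir / "top_correlations.csv", index=False)
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        methods = sorted(res["method"].unique())
        fig, axes = plt.subplots(1, len(methods), figsize=(5 * len(methods), 4),
                                 squeeze=False)
        for ax, method in zip(axes[0], methods):
            ax.hist(res.loc[res["method"] == method, "rho"],
                    bins=np.arange(-1.0, 1.01, 0.1), color="0.6")
            for b in (-0.3, 0.3):
                ax.axvline(b, color="tab:blue", ls="--")
            for b in (-0.5, 0.5):
                ax.axvline(b, color="tab:red", ls="--")
            ax.set_title(method)
            ax.set_xlabel("Spearman rho")
        fig.tight_layout()
        fig.savefig(outdir / "rho_histograms.png", dpi=120)
        plt.close(fig)
    return out
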