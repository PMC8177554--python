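"""Feature-wise group comparison across the four diagnostic classes.

For each feature the four class distributions are compared with a
non-parametric Kruskal–Wallis ANOVA (tie-corrected H, chi-square reference
with k−1 df) after balanced subsampling, followed by pairwise Dunn z-tests
under a Šidák family-wise adjustment ``p_adj = 1 − (1 − p)^m`` over the
m = C(4,2) = 6 pairs.  Significance tiers follow the usual convention
(* p ≤ 0.05, ** p ≤ 0.01, *** p ≤ 0.001 on the adjusted p).

Dunn's pairwise statistic for groups i, j uses the pooled ranks::

    z = (R̄_i − R̄_j) / sqrt( (N(N+1)/12 − T) (1/n_i + 1/n_j) )

with tie correction ``T = Σ(t³ − t) / (12 (N − 1))`` over tie groups of
size t.  A one-sample Kolmogorov–Smirnov screen against a fitted normal is
provided for reporting only; it never gates the pipeline.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

TIER_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_tier(p_adj: float) -> str:
    for threshold, tier in TIER_THRESHOLDS:
        if p_adj <= threshold:
            return tier
    return "ns"


def balanced_subsample(
    samples: dict[str, np.ndarray], n: int = 130, seed: int = 0
) -> dict[str, np.ndarray]:
    """Draw exactly ``n`` values per class without replacement, seeded."""
    for label, values in samples.items():
        if len(values) < n:
            raise ValueError(
                f"class {label} has {len(values)} samples, fewer than n={n}"
            )
    rng = np.random.default_rng(seed)
    return {
        label: np.asarray(values)[
            rng.choice(len(values), size=n, replace=False)
        ]
        for label, values in samples.items()
    }


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    if sum(g.size for g in groups) < 5:
        raise ValueError("need >= 5 observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise ValueError("all observations identical: zero rank variance")
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def sidak_adjust(p: float, m: int) -> float:
    """Šidák family-wise adjustment: 1 − (1 − p)^m (identity for m = 1)."""
    return float(1.0 - (1.0 - p) ** m)


def dunn_sidak_posthoc(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise Dunn z-tests on pooled ranks with Šidák adjustment.

    Returns one row per pair with z, raw p, adjusted p, the significance
    tier, and whether the pair is significant at ``alpha``.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[lb], dtype=float) for lb in labels]
    kruskal_wallis(arrays)  # enforces shared preconditions
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    pos = 0
    for label, arr in zip(labels, arrays):
        mean_ranks[label] = float(np.mean(ranks[pos : pos + arr.size]))
        sizes[label] = arr.size
        pos += arr.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (
        12.0 * (n_total - 1)
    )
    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        se = np.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term)
            * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        p_adj = sidak_adjust(p, m)
        rows.append(
            {
                "pair": f"{a}-{b}",
                "z": float(z),
                "p": float(p),
                "p_adj": p_adj,
                "tier": significance_tier(p_adj),
                "significant": p_adj <= alpha,
            }
        )
    return pd.DataFrame(rows)


def normality_screen(x: np.ndarray) -> tuple[float, float]:
    """One-sample KS statistic and p against a normal fitted to ``x``
    (reporting only)."""
    x = np.asarray(x, dtype=float)
    d, p = sps.kstest(x, "norm", args=(np.mean(x), np.std(x, ddof=1)))
    return float(d), float(p)


def plot_feature_distributions(
    features: pd.DataFrame, path, features_to_plot=None
) -> None:
    """Optional violin/box rendering of per-class feature distributions
    (one panel per descriptor).  Imports matplotlib lazily; everything
    else in this module is figure-free."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(features_to_plot or FEATURE_COLUMNS[4:])
    classes = sorted(features["condition"].unique())
    fig, axes = plt.subplots(
        2, (len(names) + 1) // 2, figsize=(3 * len(names) / 2 + 2, 6)
    )
    for ax, name in zip(np.ravel(axes), names):
        data = [features.loc[features["condition"] == c, name] for c in classes]
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(range(1, len(classes) + 1), classes)
        ax.set_title(name)
    for ax in np.ravel(axes)[len(names):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class GroupComparison:
    feature_name: str
    signal_type: str
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame


def compare_features(
    features: pd.DataFrame,
    n: int | None = None,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature Kruskal–Wallis + Dunn–Šidák report for one feature table.

    ``n`` is the balanced per-class subsample size; by default the
    smallest class size.  Returns a long table with one row per
    (feature, pair), carrying the omnibus H and p alongside the pairwise
    results.
    """
    signal_type = features["signal_type"].iloc[0]
    by_class = {
        label: frame for label, frame in features.groupby("condition")
    }
    if n is None:
        n = min(len(frame) for frame in by_class.values())
    rows = []
    for feature_name in FEATURE_COLUMNS[4:]:
        samples = {
            label: frame[feature_name].to_numpy()
            for label, frame in by_class.items()
        }
        balanced = balanced_subsample(samples, n=n, seed=seed)
        try:
            h, p = kruskal_wallis(list(balanced.values()))
            pairwise = dunn_sidak_posthoc(balanced, alpha=alpha)
        except ValueError as exc:
            logger.warning("feature %s: %s; skipped", feature_name, exc)
            continue
        for _, pair_row in pairwise.iterrows():
            rows.append(
                {
                    "signal_type": signal_type,
                    "feature": feature_name,
                    "H": h,
                    "p": p,
                    **pair_row.to_dict(),
                }
            )
    return pd.DataFrame(rows)
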