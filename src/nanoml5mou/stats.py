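"""Mann-Whitney comparison of modified vs unmodified signal features.

The separation between the two samples of a k-mer dataset is quantified
feature by feature with the two-sided Mann-Whitney U test.  The statistic
follows the pairwise-count convention: U is the number of (x_i, y_j) pairs
with x_i > y_j, plus half the tied pairs — this is also the effect-size W
reported alongside the p-value (W/(n0*n1) is the common-language effect size).

Small tie-free samples (combined n <= 10) get an exact p-value from the null
U distribution; larger or tied samples use the normal approximation with tie
correction and continuity correction.  A fully degenerate comparison (zero
rank variance, e.g. all values identical) returns p = 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import LabellingError
from .features import KmerDataset

EXACT_MAX_N = 10  # combined-sample cutoff for the exact null distribution


@dataclass(frozen=True)
class FeatureTestResult:
    """Mann-Whitney outcome for one feature column of one k-mer dataset."""

    kmer: str
    feature_name: str
    u_stat: float
    p_value: float
    n0: int
    n1: int
    median0: float
    median1: float
    top_of_position: bool = False  # smallest p among the four statistics of its position


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two numeric samples.

    Returns ``(u_stat, p_value)`` where ``u_stat`` counts pairs with
    ``x_i > y_j`` (ties counted half).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u requires non-empty samples")
    n0, n1 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u = float(np.sum(ranks[:n0]) - n0 * (n0 + 1) / 2.0)

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    n = n0 + n1

    if not has_ties and n <= EXACT_MAX_N:
        # exact null distribution of U (scipy's recursion); valid only tie-free
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
        return u, p

    mean_u = n0 * n1 / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    if n > 1:
        var_u = n0 * n1 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    else:  # pragma: no cover - both samples non-empty implies n >= 2
        var_u = 0.0
    if var_u <= 0:
        return u, 1.0  # zero rank variance: no evidence either way
    diff = u - mean_u
    # continuity correction pulls |U - mean| in by 1/2
    cc = min(0.5, abs(diff))
    z = (diff - np.sign(diff) * cc) / np.sqrt(var_u)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return u, p


def compare_features(dataset: KmerDataset) -> list[FeatureTestResult]:
    """Test every feature column of a labelled k-mer dataset, modified vs unmodified.

    Results come back sorted by ascending p-value; within each of the five
    window positions the most significant of the four statistics carries
    ``top_of_position=True`` (the feature one would display for that position).
    """
    y = dataset.y
    if dataset.n_pos == 0 or dataset.n_neg == 0:
        raise LabellingError(
            f"k-mer {dataset.kmer}: need both modified and unmodified rows "
            f"(n_pos={dataset.n_pos}, n_neg={dataset.n_neg})"
        )
    results = []
    for col in dataset.X.columns:
        x0 = dataset.X.loc[y == 0, col].to_numpy()
        x1 = dataset.X.loc[y == 1, col].to_numpy()
        # convention: U counts modified-above-unmodified pairs
        u, p = mann_whitney_u(x1, x0)
        results.append(
            FeatureTestResult(
                kmer=dataset.kmer,
                feature_name=col,
                u_stat=u,
                p_value=p,
                n0=x0.size,
                n1=x1.size,
                median0=float(np.median(x0)),
                median1=float(np.median(x1)),
            )
        )

    by_position: dict[str, FeatureTestResult] = {}
    for r in results:
        pos = r.feature_name.rsplit("_", 1)[1]
        if pos not in by_position or r.p_value < by_position[pos].p_value:
            by_position[pos] = r
    flagged = {id(r) for r in by_position.values()}
    results = [
        FeatureTestResult(**{**r.__dict__, "top_of_position": id(r) in flagged}) for r in results
    ]
    return sorted(results, key=lambda r: (r.p_value, r.feature_name))


def results_to_frame(results: list[FeatureTestResult]) -> pd.DataFrame:
    """Tabulate test results; adds a supplementary Benjamini-Hochberg ``q_value`` column.

    The q-values are informational only — significance calls in this framework
    use the raw p < 0.05 threshold.
    """
    frame = pd.DataFrame([r.__dict__ for r in results])
    if not frame.empty:
        order = frame["p_value"].to_numpy()
        frame["q_value"] = sps.false_discovery_control(order, method="bh")
    return frame


def plot_feature_comparison(dataset: KmerDataset, feature_name: str, ax=None):
    """Box plot of one feature, unmodified (0) vs modified (1).  Needs matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3.5, 3.5))
    y = dataset.y
    data = [dataset.X.loc[y == 0, feature_name], dataset.X.loc[y == 1, feature_name]]
    ax.boxplot(data, tick_labels=["0", "1"])
    ax.set_xlabel("sample label")
    ax.set_ylabel(feature_name)
    ax.set_title(dataset.kmer)
    return ax
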