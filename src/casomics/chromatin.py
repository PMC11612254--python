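"""Single-cell chromatin-accessibility post-processing.

Operates on a peaks x cells count matrix (:class:`casomics.io.CellMatrix`):

* differentially accessible region (DAR) selection at strict thresholds
  (BH-adjusted FDR < 0.01 and log2 fold-change > 0.3 by default), with an
  optional built-in Wilcoxon rank-sum test so the stage is self-contained;
* k-means grouping of DAR fold-change profiles (k = 10 by default,
  k-means++ with multiple restarts and a fixed seed);
* background-corrected per-cell module scores over a peak set;
* a simplified co-accessibility estimator: Pearson correlation of binarized
  accessibility between nearby peak pairs, thresholded at 0.05, with
  candidate target genes reported when a linked peak overlaps a gene's
  1 kb upstream region (this deliberately replaces graphical-lasso
  co-accessibility networks with a transparent correlation link);
* motif-deviation TF activity scores (observed minus expected motif-peak
  count fraction, z-scored against seeded background peak sets matched on
  mean accessibility) and their per-peak Pearson correlation ranking.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io import CellMatrix, GeneModel

DEFAULT_FDR_MAX = 0.01
DEFAULT_LFC_MIN = 0.3
DEFAULT_K = 10
DEFAULT_LINK_SCORE_MIN = 0.05


# ---------------------------------------------------------------------------
# DAR statistics and selection
# ---------------------------------------------------------------------------


def dar_stats(
    matrix: CellMatrix,
    cell_groups: Sequence[str],
    group: str,
    pseudocount: float = 1.0,
    scale: float = 1e4,
) -> pd.DataFrame:
    """Per-peak differential accessibility of `group` cells vs the rest.

    Counts are depth-normalized to `scale` per cell; the two-sided Wilcoxon
    rank-sum test compares in-group vs out-group cells per peak, and log2fc
    compares the group means of the normalized signal (pseudocount on the
    normalized scale, as marker-detection tools report fold changes).
    """
    groups = np.asarray(cell_groups)
    if groups.shape[0] != matrix.shape[1]:
        raise ValueError("cell_groups length must equal the number of cells")
    mask = groups == group
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError(f"group {group!r} must split cells into two non-empty sets")
    X = matrix.dense()
    depth = X.sum(axis=0)
    depth[depth == 0] = 1.0
    norm = X / depth * scale
    a, b = norm[:, mask], norm[:, ~mask]
    res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
    log2fc = np.log2((a.mean(axis=1) + pseudocount) / (b.mean(axis=1) + pseudocount))
    return pd.DataFrame(
        {"peak": matrix.feature_ids, "log2fc": log2fc, "p_value": res.pvalue}
    )


def select_dars(
    stats_table: pd.DataFrame,
    fdr_max: float = DEFAULT_FDR_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> pd.DataFrame:
    """Select peaks with FDR strictly below `fdr_max` and log2fc strictly
    above `lfc_min`.

    The table needs `peak` and `log2fc` columns and either an `fdr` column
    or a raw `p_value` column (BH-adjusted internally). Output order follows
    the input restricted to the selected rows, so reordering input peaks
    permutes but never changes the selected set.
    """
    for col in ("peak", "log2fc"):
        if col not in stats_table.columns:
            raise ValueError(f"per-peak stats missing column {col!r}")
    table = stats_table.copy()
    if "fdr" not in table.columns:
        if "p_value" not in table.columns:
            raise ValueError("per-peak stats need an 'fdr' or 'p_value' column")
        table["fdr"] = multipletests(table["p_value"], method="fdr_bh")[1]
    selected = table[(table["fdr"] < fdr_max) & (table["log2fc"] > lfc_min)]
    return selected.reset_index(drop=True)


def group_dars(
    profiles: pd.DataFrame,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = 25,
) -> tuple[pd.Series, pd.DataFrame]:
    """Group DAR fold-change profiles (rows = DARs) by seeded k-means.

    Returns (labels indexed like `profiles`, per-group mean profiles).
    """
    if len(profiles) < k:
        raise ValueError(
            f"{len(profiles)} DARs but k={k}; choose k <= number of DARs"
        )
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    labels = pd.Series(km.fit_predict(profiles.values), index=profiles.index, name="group")
    centers = pd.DataFrame(km.cluster_centers_, columns=profiles.columns)
    centers.index.name = "group"
    return labels, centers


# ---------------------------------------------------------------------------
# Module scores
# ---------------------------------------------------------------------------


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf  # degenerate peaks score 0 after centering
    return (X - mu) / sd


def module_score(
    matrix: CellMatrix,
    peak_set: Sequence[str],
    n_bins: int = 25,
    seed: int = 0,
) -> np.ndarray:
    """Background-corrected per-cell accessibility score of a peak set.

    Each peak is z-scored across cells; the score is the mean z over the set
    minus the mean z over a size-matched control set, sampled one control
    per set peak from the same mean-accessibility bin (quantile bins,
    seeded). A random peak set therefore scores ~0 on average.
    """
    if len(peak_set) == 0:
        raise ValueError("peak set is empty")
    idx = np.array([matrix.feature_index(p) for p in peak_set])
    X = matrix.dense()
    Z = _zscore_rows(X)
    means = X.mean(axis=1)
    # quantile bins on mean accessibility
    n_bins = min(n_bins, len(means))
    ranks = stats.rankdata(means, method="average")
    bins = np.ceil(ranks / len(means) * n_bins).astype(int)
    rng = np.random.default_rng(seed)
    in_set = np.zeros(len(means), dtype=bool)
    in_set[idx] = True
    controls = []
    for i in idx:
        candidates = np.flatnonzero((bins == bins[i]) & ~in_set)
        if candidates.size == 0:
            candidates = np.flatnonzero(~in_set)
        if candidates.size == 0:  # single-peak matrix: control = the peak itself
            candidates = np.array([i])
        controls.append(int(rng.choice(candidates)))
    return Z[idx].mean(axis=0) - Z[np.array(controls)].mean(axis=0)


# ---------------------------------------------------------------------------
# Co-accessibility links
# ---------------------------------------------------------------------------


def coaccessibility_links(
    matrix: CellMatrix,
    distance_max: int = 500_000,
    score_min: float = DEFAULT_LINK_SCORE_MIN,
) -> pd.DataFrame:
    """Link nearby peak pairs whose binarized accessibility correlates.

    A link joins two peaks on the same chromosome whose centers lie within
    `distance_max` and whose across-cell Pearson correlation of binarized
    (open/closed) accessibility exceeds `score_min`. Constant peaks (always
    open or always closed) never form links.
    """
    if matrix.feature_coords is None:
        raise ValueError("co-accessibility needs peak coordinates")
    B = (matrix.dense() > 0).astype(float)
    sd = B.std(axis=1)
    centers = [
        (iv.chrom, (iv.start + iv.end) / 2) if iv is not None else (None, None)
        for iv in matrix.feature_coords
    ]
    order = sorted(
        (i for i, c in enumerate(centers) if c[0] is not None),
        key=lambda i: (centers[i][0], centers[i][1]),
    )
    rows = []
    for a_pos, i in enumerate(order):
        for j in order[a_pos + 1:]:
            if centers[j][0] != centers[i][0]:
                break
            if centers[j][1] - centers[i][1] > distance_max:
                break
            if sd[i] == 0 or sd[j] == 0:
                continue
            score = float(np.corrcoef(B[i], B[j])[0, 1])
            if score > score_min:
                rows.append(
                    {"peak_a": matrix.feature_ids[i], "peak_b": matrix.feature_ids[j],
                     "score": score}
                )
    return pd.DataFrame(rows, columns=["peak_a", "peak_b", "score"])


def link_target_genes(
    links: pd.DataFrame,
    matrix: CellMatrix,
    genes: Sequence[GeneModel],
    upstream: int = 1_000,
) -> pd.DataFrame:
    """Genes whose 1 kb upstream region overlaps any linked peak."""
    linked = set(links["peak_a"]) | set(links["peak_b"])
    coords = {
        pid: iv
        for pid, iv in zip(matrix.feature_ids, matrix.feature_coords or [])
        if pid in linked and iv is not None
    }
    rows = []
    for g in genes:
        if g.strand == "-":
            lo, hi = g.end, g.end + upstream
        else:
            lo, hi = max(0, g.start - upstream), g.start
        if lo >= hi:
            continue
        for pid, iv in coords.items():
            if iv.chrom == g.chrom and iv.start < hi and lo < iv.end:
                rows.append({"gene": g.gene_id, "peak": pid})
    return pd.DataFrame(rows, columns=["gene", "peak"])


# ---------------------------------------------------------------------------
# TF activity (motif deviations) and peak-level correlation
# ---------------------------------------------------------------------------


def tf_activity(
    matrix: CellMatrix,
    motif_peaks: Mapping[str, Sequence[str]],
    n_background: int = 50,
    n_bins: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell motif activity z-scores (motifs x cells).

    For each motif, the raw deviation per cell is the observed fraction of
    that cell's counts falling in the motif's peaks minus the expectation
    from overall peak abundances. The deviation is z-scored against
    `n_background` seeded background peak sets matched on mean accessibility
    (quantile bins). Motifs mapping to zero known peaks are skipped with a
    warning.
    """
    X = matrix.dense()
    depth = X.sum(axis=0)
    depth[depth == 0] = 1.0
    frac = X / depth  # per-cell count fractions
    expect = X.sum(axis=1) / X.sum()  # expected fraction per peak
    n_peaks = X.shape[0]
    n_bins = min(n_bins, n_peaks)
    ranks = stats.rankdata(expect, method="average")
    bins = np.ceil(ranks / n_peaks * n_bins).astype(int)
    by_bin = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}
    rng = np.random.default_rng(seed)

    id_to_row = {pid: i for i, pid in enumerate(matrix.feature_ids)}
    rows = {}
    for motif in sorted(motif_peaks):
        peak_rows = np.array(
            [id_to_row[p] for p in motif_peaks[motif] if p in id_to_row], dtype=int
        )
        if peak_rows.size == 0:
            warnings.warn(f"motif {motif!r} maps to no peaks in the matrix; skipped")
            continue
        raw = frac[peak_rows].sum(axis=0) - expect[peak_rows].sum()
        bg = np.empty((n_background, X.shape[1]))
        for b in range(n_background):
            sampled = np.array(
                [int(rng.choice(by_bin[bins[i]])) for i in peak_rows]
            )
            bg[b] = frac[sampled].sum(axis=0) - expect[sampled].sum()
        mu = bg.mean(axis=0)
        sd = bg.std(axis=0)
        sd[sd == 0] = np.inf
        rows[motif] = (raw - mu) / sd
    return pd.DataFrame(rows, index=matrix.barcodes).T


def peak_activity_pcc(
    matrix: CellMatrix,
    activity: pd.DataFrame,
    focal_peaks: Sequence[str],
) -> pd.DataFrame:
    """Pearson correlation between focal-peak accessibility and each motif's
    activity across cells; motifs ranked by PCC per focal peak."""
    X = matrix.dense()
    rows = []
    for pid in focal_peaks:
        x = X[matrix.feature_index(pid)]
        for motif, z in activity.iterrows():
            zv = z.values.astype(float)
            if x.std() == 0 or zv.std() == 0:
                pcc = float("nan")
            else:
                pcc = float(np.corrcoef(x, zv)[0, 1])
            rows.append({"focal_peak": pid, "motif": motif, "pcc": pcc})
    out = pd.DataFrame(rows, columns=["focal_peak", "motif", "pcc"])
    return (
        out.sort_values(["focal_peak", "pcc"], ascending=[True, False], kind="mergesort")
        .reset_index(drop=True)
    )


def tf_activity_and_pcc(
    matrix: CellMatrix,
    motif_peaks: Mapping[str, Sequence[str]],
    focal_peaks: Sequence[str],
    n_background: int = 50,
    n_bins: int = 25,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: activity scores plus their focal-peak PCC ranking."""
    activity = tf_activity(
        matrix, motif_peaks, n_background=n_background, n_bins=n_bins, seed=seed
    )
    return activity, peak_activity_pcc(matrix, activity, focal_peaks)
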