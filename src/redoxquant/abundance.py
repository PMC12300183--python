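"""TMT differential protein abundance between two strains.

Processing order mirrors standard isobaric-tag practice: merge designated
protein groups (e.g. the LHCII chlorophyll a/b-binding entries) into single
rows, drop degenerate channels (orders of magnitude lower total signal or
mostly missing), rescale every channel to the common grand-mean total,
log2-transform and mean-center per channel, then test each protein with a
moderated t-statistic d = diff / (s + s0) where diff is the difference of
mean log2 intensities (HT − LT), s the pooled standard error, and s0 a
fudge factor damping low-variance artifacts.  Significance is decided by a
permutation-based FDR: balanced group-label permutations rebuild the null
distribution of |d|, and the smallest |d| cutoff with estimated FDR at or
below the target flags the differentially abundant proteins (DAPs).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .enrichment import benjamini_hochberg
from .tables import (
    ChannelDesign,
    PipelineError,
    ProteinQuantMatrix,
    ROLE_ABUNDANCE,
    STRAIN_HT,
    STRAIN_LT,
    UsageError,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Group merging and channel QC
# ---------------------------------------------------------------------------

def merge_protein_groups(matrix: ProteinQuantMatrix,
                         group_map: dict[str, str]) -> ProteinQuantMatrix:
    """Collapse designated proteins into single summed rows.

    ``group_map`` maps member protein ids to a group id.  Member cells are
    summed element-wise; a merged cell is missing only when every member is
    missing there.  Members absent from the matrix are skipped with a
    warning.  Provenance is recorded in ``merged_groups``.
    """
    if not group_map:
        return ProteinQuantMatrix(matrix.values.copy(), matrix.psm_counts.copy(),
                                  dict(matrix.merged_groups))
    values = matrix.values
    counts = matrix.psm_counts
    groups: dict[str, list[str]] = {}
    for pid, gid in group_map.items():
        if pid not in values.index:
            log.warning("merge group %s: member %s absent from matrix, skipped", gid, pid)
            continue
        groups.setdefault(gid, []).append(pid)
    new_vals, new_counts, provenance = [], [], dict(matrix.merged_groups)
    drop: list[str] = []
    for gid, members in groups.items():
        new_vals.append(values.loc[members].sum(min_count=1).rename(gid))
        new_counts.append(counts.loc[members].sum().rename(gid))
        provenance[gid] = sorted(members)
        drop += members
    out_vals = pd.concat([values.drop(index=drop)] +
                         [v.to_frame().T for v in new_vals])
    out_counts = pd.concat([counts.drop(index=drop)] +
                           [c.to_frame().T for c in new_counts])
    out_vals.index.name = values.index.name
    out_counts.index.name = counts.index.name
    return ProteinQuantMatrix(out_vals, out_counts, provenance)


def qc_channels(
    matrix: ProteinQuantMatrix,
    ratio_threshold: float = 100.0,
    missing_frac: float = 0.5,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Identify degenerate channels.

    A channel is dropped iff the median of the other channels' summed
    intensities is at least ``ratio_threshold`` times its own total, or its
    per-protein missing fraction exceeds ``missing_frac``.  Returns
    (kept ids, dropped ids, per-channel report).
    """
    if len(matrix.channels) < 2:
        raise UsageError("channel QC needs at least 2 channels")
    totals = matrix.channel_totals()
    missing = matrix.values.isna().mean(axis=0)
    kept, dropped, rows = [], [], []
    for ch in matrix.channels:
        other_median = float(totals.drop(ch).median())
        total = float(totals[ch])
        ratio = np.inf if total <= 0 else other_median / total
        drop = ratio >= ratio_threshold or missing[ch] > missing_frac
        rows.append(
            {"channel_id": ch, "total_intensity": total,
             "median_other_totals": other_median, "ratio_to_others": ratio,
             "missing_fraction": float(missing[ch]), "dropped": drop}
        )
        (dropped if drop else kept).append(ch)
    if not kept:
        raise PipelineError("channel QC dropped every channel")
    for ch in dropped:
        log.info("channel QC: dropping %s (ratio %.3g, missing %.2f)",
                 ch, rows[matrix.channels.index(ch)]["ratio_to_others"],
                 missing[ch])
    return kept, dropped, pd.DataFrame(rows)


def scale_channels(matrix: ProteinQuantMatrix) -> ProteinQuantMatrix:
    """Multiply each channel by a global factor equalizing channel totals.

    The common target is the grand mean of the channel totals; after scaling
    every total equals it to within 1e-9 relative.  A zero-total channel is
    a pipeline error (it should have been QC-dropped).
    """
    totals = matrix.channel_totals()
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise PipelineError(f"cannot scale channel(s) with zero total: {bad}")
    factors = totals.mean() / totals
    return ProteinQuantMatrix(matrix.values * factors, matrix.psm_counts.copy(),
                              dict(matrix.merged_groups))


def log2_and_center(matrix: ProteinQuantMatrix, center: str = "mean") -> pd.DataFrame:
    """log2-transform and center each channel (mean or median subtraction).

    Zeros become missing before the log.  Returns a protein × channel
    DataFrame of normalized log2 intensities.
    """
    if center not in ("mean", "median"):
        raise UsageError(f"center must be 'mean' or 'median', got {center!r}")
    vals = matrix.values.where(matrix.values > 0)
    logged = np.log2(vals)
    offset = logged.mean(axis=0) if center == "mean" else logged.median(axis=0)
    return logged - offset


# ---------------------------------------------------------------------------
# Moderated t and permutation FDR
# ---------------------------------------------------------------------------

def _group_stats(x1: np.ndarray, x2: np.ndarray, s0: float):
    """Row-wise diff, pooled SE, plain t, p, and moderated d (NaN-aware)."""
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n1 = np.sum(~np.isnan(x1), axis=1).astype(float)
        n2 = np.sum(~np.isnan(x2), axis=1).astype(float)
        m1 = np.nanmean(x1, axis=1)
        m2 = np.nanmean(x2, axis=1)
        v1 = np.where(n1 > 1, np.nanvar(x1, axis=1, ddof=1), np.nan)
        v2 = np.where(n2 > 1, np.nanvar(x2, axis=1, ddof=1), np.nan)
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        diff = m1 - m2
        t = np.where(se > 0, diff / se, np.nan)
        p = np.where(~np.isnan(t), 2.0 * stats.t.sf(np.abs(t), df), np.nan)
        d = diff / (se + s0)
    return diff, se, t, p, df, d


def balanced_permutations(
    labels: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Balanced group-label permutations.

    ``labels`` is a boolean vector (True = group 1) over the sample columns.
    A balanced permutation reassigns group-1 membership so that the permuted
    group 1 contains as close to half true-group-1 members as possible
    (k = n1/2 for even n1, k in {floor, ceil} for odd), which keeps strong
    true signal from contaminating the permutation null.  All distinct
    assignments are enumerated when there are at most ``n_perm`` of them (or
    few enough to enumerate cheaply); otherwise ``n_perm`` distinct
    assignments are sampled without replacement.  Returns boolean masks.
    """
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    pos1 = np.flatnonzero(labels)
    pos2 = np.flatnonzero(~labels)
    ks = [n1 // 2] if n1 % 2 == 0 else [n1 // 2, n1 // 2 + 1]
    ks = [k for k in ks if k <= len(pos1) and (n1 - k) <= len(pos2)]

    from math import comb
    total = sum(comb(len(pos1), k) * comb(len(pos2), n1 - k) for k in ks)
    masks: list[np.ndarray] = []
    if total <= max(n_perm, 10000):
        for k in ks:
            for a in itertools.combinations(pos1, k):
                for b in itertools.combinations(pos2, n1 - k):
                    m = np.zeros(len(labels), dtype=bool)
                    m[list(a) + list(b)] = True
                    masks.append(m)
        if total < n_perm:
            log.info("only %d distinct balanced permutations available "
                     "(requested %d); using all", total, n_perm)
        elif total > n_perm:
            idx = rng.choice(total, size=n_perm, replace=False)
            masks = [masks[i] for i in sorted(idx)]
    else:
        seen: set[tuple[int, ...]] = set()
        while len(masks) < n_perm:
            k = ks[0] if len(ks) == 1 else int(rng.integers(0, 2)) + ks[0]
            a = rng.choice(pos1, size=k, replace=False)
            b = rng.choice(pos2, size=n1 - k, replace=False)
            key = tuple(sorted(a.tolist() + b.tolist()))
            if key in seen:
                continue
            seen.add(key)
            m = np.zeros(len(labels), dtype=bool)
            m[list(key)] = True
            masks.append(m)
    return masks


def permutation_fdr_threshold(
    d_obs: np.ndarray,
    d_perm_abs: np.ndarray,
    target_fdr: float,
    n_permutations: int | None = None,
) -> tuple[float, pd.DataFrame]:
    """Symmetric |d| cutoff controlling the permutation-estimated FDR.

    For each candidate cutoff c (the observed |d| values), FDR(c) is the
    mean over permutations of #{|d_perm| >= c} divided by #{|d_obs| >= c},
    clipped to 1.  The curve is monotone-smoothed (the q-value of flagging
    at least i proteins is the best FDR achievable by any cutoff flagging
    at least i) and the smallest cutoff with smoothed FDR <= target is
    returned, along with the candidate table.  Returns (cutoff, curve);
    cutoff is +inf when no candidate qualifies.
    """
    obs_abs = np.sort(np.abs(d_obs[~np.isnan(d_obs)]))
    if len(obs_abs) == 0:
        return np.inf, pd.DataFrame(columns=["cutoff", "n_flagged", "mean_null", "fdr", "fdr_smoothed"])
    perm_sorted = np.sort(d_perm_abs[~np.isnan(d_perm_abs)])
    n_perm_vals = len(perm_sorted)
    n_obs = len(obs_abs)
    # average null count per permutation; fall back to pooled-size estimate
    b = float(n_permutations) if n_permutations else (n_perm_vals / n_obs if n_obs else 1.0)

    cands = obs_abs[::-1]  # descending: most stringent first
    r = n_obs - np.searchsorted(obs_abs, cands, side="left")
    v = (n_perm_vals - np.searchsorted(perm_sorted, cands, side="left")) / b
    fdr = np.clip(v / np.maximum(r, 1), 0.0, 1.0)
    smoothed = np.minimum.accumulate(fdr[::-1])[::-1]
    curve = pd.DataFrame(
        {"cutoff": cands, "n_flagged": r, "mean_null": v,
         "fdr": fdr, "fdr_smoothed": smoothed}
    )
    ok = smoothed <= target_fdr
    if not ok.any():
        return np.inf, curve
    cutoff = float(cands[np.flatnonzero(ok)[-1]])  # smallest qualifying cutoff
    return cutoff, curve


@dataclass
class DifferentialAbundanceResult:
    """Per-protein statistics plus the permutation-FDR decision."""

    table: pd.DataFrame
    d_cutoff: float
    n_permutations: int
    target_fdr: float
    s0: float
    fdr_curve: pd.DataFrame
    n_untestable: int = 0

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def volcano_frame(self) -> pd.DataFrame:
        """x = diff (log2), y = −log10 p, with the significance flag."""
        out = self.table[["diff", "p_value", "significant"]].copy()
        out["neg_log10_p"] = -np.log10(out["p_value"].clip(lower=1e-300))
        return out.reset_index(names="protein_id")


def differential_abundance(
    norm: pd.DataFrame,
    design: ChannelDesign,
    s0: float = 1.0,
    target_fdr: float = 0.02,
    n_perm: int = 250,
    seed: int = 0,
) -> DifferentialAbundanceResult:
    """Moderated-t differential abundance with permutation FDR.

    ``norm`` is the normalized log2 protein × channel matrix.  The reference
    channel (if any) is excluded from testing.  Proteins need at least two
    defined values per strain; the rest are reported untestable.  For each
    protein: diff = mean(HT) − mean(LT), pooled homoscedastic SE s, plain
    two-sided t-test p (with BH q for cross-checking), and d = diff/(s+s0).
    Flags come from :func:`permutation_fdr_threshold` over balanced label
    permutations.
    """
    ht = [c for c in design.channels_for(STRAIN_HT, ROLE_ABUNDANCE) if c in norm.columns]
    lt = [c for c in design.channels_for(STRAIN_LT, ROLE_ABUNDANCE) if c in norm.columns]
    if len(ht) < 2 or len(lt) < 2:
        raise UsageError("need >= 2 sample channels per strain")
    X = norm[ht + lt].to_numpy(float)
    labels = np.array([True] * len(ht) + [False] * len(lt))

    n1_def = np.sum(~np.isnan(X[:, labels]), axis=1)
    n2_def = np.sum(~np.isnan(X[:, ~labels]), axis=1)
    testable = (n1_def >= 2) & (n2_def >= 2)
    n_untestable = int((~testable).sum())
    if n_untestable:
        log.info("differential abundance: %d protein(s) untestable "
                 "(<2 values in a group)", n_untestable)
    Xt = X[testable]

    diff, se, t, p, dfree, d = _group_stats(Xt[:, labels], Xt[:, ~labels], s0)

    rng = np.random.default_rng(seed)
    masks = balanced_permutations(labels, n_perm, rng)
    perm_abs = np.concatenate([
        np.abs(_group_stats(Xt[:, m], Xt[:, ~m], s0)[5]) for m in masks
    ])
    cutoff, curve = permutation_fdr_threshold(d, perm_abs, target_fdr,
                                              n_permutations=len(masks))
    significant = np.abs(d) >= cutoff

    table = pd.DataFrame(index=norm.index)
    for ch in ht + lt:
        table[f"log2_{ch}"] = norm[ch]
    full = lambda arr: _expand(arr, testable, len(norm))  # noqa: E731
    table["mean_ht"] = full(np.nanmean(Xt[:, labels], axis=1))
    table["mean_lt"] = full(np.nanmean(Xt[:, ~labels], axis=1))
    table["diff"] = full(diff)
    table["fold_change"] = np.exp2(table["diff"])
    table["se"] = full(se)
    table["t_statistic"] = full(t)
    table["p_value"] = full(p)
    q = np.full(len(p), np.nan)
    okp = ~np.isnan(p)
    if okp.any():
        q[okp] = benjamini_hochberg(p[okp])
    table["q_value"] = full(q)
    table["d_statistic"] = full(d)
    sig = np.zeros(len(norm), dtype=bool)
    sig[np.flatnonzero(testable)] = significant
    table["significant"] = sig
    table["testable"] = testable

    return DifferentialAbundanceResult(
        table=table, d_cutoff=cutoff, n_permutations=len(masks),
        target_fdr=target_fdr, s0=s0, fdr_curve=curve,
        n_untestable=n_untestable,
    )


def _expand(arr: np.ndarray, mask: np.ndarray, n: int) -> np.ndarray:
    out = np.full(n, np.nan)
    out[np.flatnonzero(mask)] = arr
    return out


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Z-scored matrix with row/column dendrograms and the 2-cut partition."""

    z_matrix: pd.DataFrame
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]
    col_partition: pd.Series  # channel -> cluster label from a 2-cluster cut
    n_dropped_rows: int = 0


def hierarchical_cluster(norm: pd.DataFrame, z_score: bool = True) -> ClusterResult:
    """Average-linkage Euclidean clustering of proteins and samples.

    Rows are Z-scored first (mean 0, sd 1) unless ``z_score`` is False;
    rows with missing values or zero variance are dropped with a warning.
    The column dendrogram is cut into (at most) two clusters, the partition
    the two strains are expected to form.
    """
    complete = norm.dropna(axis=0, how="any")
    if z_score:
        sd = complete.std(axis=1, ddof=0)
        keep = sd > 0
        dropped = int((~keep).sum()) + (len(norm) - len(complete))
        complete = complete[keep]
        z = complete.sub(complete.mean(axis=1), axis=0).div(
            complete.std(axis=1, ddof=0), axis=0)
    else:
        dropped = len(norm) - len(complete)
        z = complete
    if dropped:
        log.warning("clustering: dropped %d row(s) (missing values or zero variance)",
                    dropped)
    if z.empty:
        raise PipelineError("no rows left to cluster")
    row_link = hierarchy.linkage(z.to_numpy(), method="average", metric="euclidean")
    col_link = hierarchy.linkage(z.to_numpy().T, method="average", metric="euclidean")
    row_order = [z.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [z.columns[i] for i in hierarchy.leaves_list(col_link)]
    partition = pd.Series(
        hierarchy.fcluster(col_link, t=2, criterion="maxclust"),
        index=z.columns, name="cluster",
    )
    return ClusterResult(
        z_matrix=z, row_linkage=row_link, col_linkage=col_link,
        row_order=row_order, col_order=col_order,
        col_partition=partition, n_dropped_rows=dropped,
    )
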