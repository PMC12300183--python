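"""Per-protein cysteine redox stoichiometry from differential-labeling data.

The stoichiometry of a protein in one sample is the summed light-label
(reduced-cysteine) reporter intensity divided by the summed intensity of
both labels — the fraction of its cysteines that were reduced in vivo,
a number in [0, 1] where lower means more oxidized.  Stoichiometries are
computed per replicate from PSM roll-ups, averaged per strain, compared
between strains with a global paired t-test and per-protein homoscedastic
t-tests, and summarized as fold changes HT/LT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import benjamini_hochberg
from .tables import (
    ChannelDesign,
    ProteinQuantMatrix,
    STRAIN_HT,
    STRAIN_LT,
    UsageError,
    validate_psm_table,
)

log = logging.getLogger(__name__)

#: smallest p-value ever reported; smaller values display as "< 2.2e-16"
P_FLOOR = 2.2e-16


def format_p(p: float) -> str:
    """Human-readable p-value with an underflow floor (never literally 0)."""
    if np.isnan(p):
        return "NA"
    if p < P_FLOOR:
        return f"< {P_FLOOR:.2g}"
    return f"{p:.6g}"


# ---------------------------------------------------------------------------
# PSM roll-up
# ---------------------------------------------------------------------------

def aggregate_psms(psms: pd.DataFrame, design: ChannelDesign) -> ProteinQuantMatrix:
    """Sum PSM reporter intensities per protein and channel.

    A cell is missing only if every contributing PSM was missing there;
    proteins with no intensity in any channel are dropped.
    """
    validate_psm_table(psms, design)
    channels = design.channels
    if psms.empty:
        empty = pd.DataFrame(columns=channels, index=pd.Index([], name="protein_id"),
                             dtype=float)
        return ProteinQuantMatrix(empty, empty.copy())
    grouped = psms.groupby("protein_id", sort=True)
    sums = grouped[channels].sum(min_count=1)
    counts = grouped[channels].count()
    keep = sums.notna().any(axis=1)
    return ProteinQuantMatrix(sums[keep], counts[keep])


# ---------------------------------------------------------------------------
# Stoichiometry
# ---------------------------------------------------------------------------

def compute_stoichiometry(matrix: ProteinQuantMatrix, design: ChannelDesign) -> pd.DataFrame:
    """light/(light+heavy) per (protein, strain, replicate), plus strain
    means and replicate-presence counts.

    Missing when both channels are missing or the total is zero; a missing
    single channel is treated as zero intensity (no signal for that label).
    Columns: ``stoich_<strain>_r<k>``, ``mean_HT``, ``mean_LT``,
    ``n_reps_HT``, ``n_reps_LT``; index ``protein_id``.
    """
    pairs = design.redox_pairs()  # raises UsageError on non-redox designs
    vals = matrix.values
    out = pd.DataFrame(index=vals.index)
    for strain, rep, light, heavy in pairs:
        l = vals[light]
        h = vals[heavy]
        both_missing = l.isna() & h.isna()
        total = l.fillna(0.0) + h.fillna(0.0)
        s = l.fillna(0.0) / total.where(total > 0)
        s[both_missing] = np.nan
        out[f"stoich_{strain}_r{rep}"] = s
    for strain in (STRAIN_HT, STRAIN_LT):
        cols = [c for c in out.columns if c.startswith(f"stoich_{strain}_")]
        out[f"mean_{strain}"] = out[cols].mean(axis=1)
        out[f"n_reps_{strain}"] = out[cols].notna().sum(axis=1)
    return out


def stoich_columns(table: pd.DataFrame, strain: str) -> list[str]:
    return [c for c in table.columns if c.startswith(f"stoich_{strain}_")]


def filter_by_replicate_presence(table: pd.DataFrame, min_reps: int = 3) -> pd.DataFrame:
    """Keep proteins with >= ``min_reps`` defined stoichiometries per strain.

    ``min_reps=0`` is the identity.  Both the filtered and the unfiltered
    tables are meant to be reported (downstream summaries accept either).
    """
    n_ht = len(stoich_columns(table, STRAIN_HT))
    n_lt = len(stoich_columns(table, STRAIN_LT))
    if min_reps > max(n_ht, n_lt):
        raise UsageError(
            f"min_reps={min_reps} exceeds the number of replicates ({max(n_ht, n_lt)})"
        )
    if min_reps == 0:
        return table.copy()
    keep = (table[f"n_reps_{STRAIN_HT}"] >= min_reps) & (
        table[f"n_reps_{STRAIN_LT}"] >= min_reps
    )
    return table[keep].copy()


# ---------------------------------------------------------------------------
# Strain comparison
# ---------------------------------------------------------------------------

def _ttest_ind_rows(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sided homoscedastic t-test, NaN-aware.

    Returns (t, p, df); NaN where a group has < 2 values or the pooled
    variance is zero.
    """
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n1 = np.sum(~np.isnan(x1), axis=1).astype(float)
        n2 = np.sum(~np.isnan(x2), axis=1).astype(float)
        m1 = np.nanmean(np.where(np.isnan(x1), np.nan, x1), axis=1)
        m2 = np.nanmean(np.where(np.isnan(x2), np.nan, x2), axis=1)
        v1 = np.nanvar(x1, axis=1, ddof=1)
        v2 = np.nanvar(x2, axis=1, ddof=1)
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        t = (m1 - m2) / se
        ok = (n1 >= 2) & (n2 >= 2) & (se > 0)
        t = np.where(ok, t, np.nan)
        p = np.where(ok, 2.0 * stats.t.sf(np.abs(t), df), np.nan)
    return t, p, df


@dataclass
class RedoxSummary:
    """Distribution and test summary for one protein set."""

    n_proteins: int
    mean_stoich_ht: float
    sd_stoich_ht: float
    mean_stoich_lt: float
    sd_stoich_lt: float
    fc_mean: float
    fc_sd: float
    fc_median: float
    frac_fc_below_1: float
    global_t: float
    global_df: int
    global_p: float          # floored at P_FLOOR when it underflows
    global_p_display: str
    n_tested: int            # proteins with a defined per-protein p
    histogram_bin_edges: list[float] = field(default_factory=list)
    histogram_counts: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        d = {k: v for k, v in self.__dict__.items()
             if not k.startswith("histogram")}
        return pd.DataFrame([d])

    def histogram_frame(self) -> pd.DataFrame:
        e = self.histogram_bin_edges
        return pd.DataFrame(
            {"bin_left": e[:-1], "bin_right": e[1:], "count": self.histogram_counts}
        )


def redox_comparison(
    table: pd.DataFrame,
    fc_bins: np.ndarray | None = None,
) -> tuple[pd.DataFrame, RedoxSummary]:
    """Strain comparison on a stoichiometry table.

    Adds per-protein columns: ``fold_change`` (mean over replicates of the
    per-replicate HT/LT stoichiometry ratio — replicates are paired within a
    labeling run), ``fc_ratio_of_means`` (ratio of strain means), ``p_value``
    and BH ``q_value`` from the two-sided homoscedastic t-test on replicate
    stoichiometries.  Returns the augmented table and a :class:`RedoxSummary`
    with the global paired t-test across proteins on (HT mean, LT mean).
    """
    table = table.copy()
    ht_cols = stoich_columns(table, STRAIN_HT)
    lt_cols = stoich_columns(table, STRAIN_LT)
    reps_ht = {c.rsplit("_r", 1)[1]: c for c in ht_cols}
    reps_lt = {c.rsplit("_r", 1)[1]: c for c in lt_cols}
    shared = sorted(set(reps_ht) & set(reps_lt), key=int)

    # per-replicate paired ratios -> mean-of-ratios fold change
    ratios = pd.DataFrame(index=table.index)
    for r in shared:
        denom = table[reps_lt[r]].where(table[reps_lt[r]] > 0)
        ratios[r] = table[reps_ht[r]] / denom
    table["fold_change"] = ratios.mean(axis=1)
    denom = table[f"mean_{STRAIN_LT}"].where(table[f"mean_{STRAIN_LT}"] > 0)
    table["fc_ratio_of_means"] = table[f"mean_{STRAIN_HT}"] / denom

    # per-protein homoscedastic t-test on replicate stoichiometries
    t, p, _ = _ttest_ind_rows(table[ht_cols].to_numpy(float),
                              table[lt_cols].to_numpy(float))
    n_zero_var = int(np.sum(np.isnan(p) & (np.sum(~np.isnan(table[ht_cols]), axis=1) >= 2)
                            & (np.sum(~np.isnan(table[lt_cols]), axis=1) >= 2)))
    if n_zero_var:
        log.info("redox per-protein t-test: %d protein(s) with zero pooled variance "
                 "reported as missing p", n_zero_var)
    table["t_statistic"] = t
    table["p_value"] = p
    q = np.full(len(table), np.nan)
    defined = ~np.isnan(p)
    if defined.any():
        q[defined] = benjamini_hochberg(p[defined])
    table["q_value"] = q

    # global paired t-test across proteins on the strain means
    mh = table[f"mean_{STRAIN_HT}"]
    ml = table[f"mean_{STRAIN_LT}"]
    both = mh.notna() & ml.notna()
    diffs = (mh[both] - ml[both]).to_numpy()
    if len(diffs) >= 2 and np.nanstd(diffs, ddof=1) > 0:
        res = stats.ttest_rel(mh[both], ml[both])
        gt, gp = float(res.statistic), float(res.pvalue)
        gdf = int(both.sum() - 1)
        gp_display = format_p(gp)  # underflow shows as "< 2.2e-16"
        gp_floored = max(gp, P_FLOOR)
    elif len(diffs) >= 2:
        # identical strain profiles: zero differences, no shift to test
        log.info("global paired t-test undefined (all paired differences zero); "
                 "reported as no shift")
        gt, gp, gdf, gp_floored = np.nan, np.nan, int(both.sum() - 1), np.nan
        gp_display = "NA (no shift: all paired differences zero)"
    else:
        raise UsageError("global comparison needs strain means for >= 2 proteins")

    fc = table["fold_change"].dropna()
    if fc_bins is None:
        top = max(2.0, float(np.ceil(fc.max() * 10) / 10)) if len(fc) else 2.0
        fc_bins = np.arange(0.0, top + 0.1, 0.1)
    counts, edges = np.histogram(fc, bins=fc_bins)

    summary = RedoxSummary(
        n_proteins=int(len(table)),
        mean_stoich_ht=float(mh.mean()),
        sd_stoich_ht=float(mh.std(ddof=1)),
        mean_stoich_lt=float(ml.mean()),
        sd_stoich_lt=float(ml.std(ddof=1)),
        fc_mean=float(fc.mean()) if len(fc) else np.nan,
        fc_sd=float(fc.std(ddof=1)) if len(fc) > 1 else np.nan,
        fc_median=float(fc.median()) if len(fc) else np.nan,
        frac_fc_below_1=float((fc < 1.0).mean()) if len(fc) else np.nan,
        global_t=gt,
        global_df=gdf,
        global_p=gp_floored,
        global_p_display=gp_display,
        n_tested=int(defined.sum()),
        histogram_bin_edges=[float(e) for e in edges],
        histogram_counts=[int(c) for c in counts],
    )
    return table, summary


# ---------------------------------------------------------------------------
# Replicate reproducibility
# ---------------------------------------------------------------------------

def replicate_correlation(data: pd.DataFrame | ProteinQuantMatrix,
                          columns: list[str] | None = None) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix across columns.

    The diagonal is 1 by convention; a zero-variance column yields missing
    correlations with every other column.
    """
    df = data.values if isinstance(data, ProteinQuantMatrix) else data
    if columns is not None:
        df = df[columns]
    df = df.select_dtypes(include=[np.number])
    if df.shape[1] < 2:
        raise UsageError("correlation needs at least 2 columns")
    corr = df.corr(method="pearson", min_periods=2)
    np.fill_diagonal(corr.values, 1.0)
    return corr
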