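"""Categorical enrichment statistics over protein annotations.

Two complementary tests used to interpret differential-abundance calls:

* :func:`fisher_enrichment` — per annotation term, a 2×2 Fisher exact test
  of membership against a significance flag, with an observed/expected
  enrichment factor;
* :func:`one_d_annotation_enrichment` — a Mann–Whitney rank test per term
  on a numeric protein score (normalized intensity or fold change), with a
  position score s in [−1, 1]: +1 when all members rank at the top, −1 at
  the bottom, 0 when member and non-member mean ranks coincide.

Both report Benjamini–Hochberg adjusted q-values; the step-up adjustment
itself is :func:`benjamini_hochberg`.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .tables import UsageError

log = logging.getLogger(__name__)


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, clipped to 1
    and mapped back to the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise UsageError("benjamini_hochberg expects a 1-D array")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise UsageError("p-values must lie in [0, 1] with no missing entries")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Fisher exact enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(
    flags: pd.Series,
    catalog: Mapping[str, frozenset[str] | set[str]],
    universe_policy: str = "annotated-only",
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Per-term two-sided Fisher exact test of term membership vs a flag.

    ``flags`` is a boolean Series indexed by protein id (True = significant,
    e.g. a DAP call).  The universe is either the flagged-or-not proteins
    that carry at least one annotation (``annotated-only``, the default) or
    all proteins in ``flags`` (``all``).  Terms with fewer than
    ``min_term_size`` members in the universe are skipped and logged.

    The enrichment factor is observed/expected: a / [(a+b)(a+c)/N] for the
    2×2 table (a = flagged members, b = unflagged members, c = flagged
    non-members, d = the rest).  Two-sided p sums hypergeometric point
    probabilities <= the observed table's.
    """
    if universe_policy not in ("annotated-only", "all"):
        raise UsageError(f"unknown universe_policy {universe_policy!r}")
    flags = flags.astype(bool)
    if universe_policy == "annotated-only":
        universe = [pid for pid in flags.index if catalog.get(pid)]
    else:
        universe = list(flags.index)
    n_univ = len(universe)
    if n_univ == 0:
        raise UsageError("empty universe: no proteins to test")
    flagged = {pid for pid in universe if flags[pid]}
    terms = sorted({t for pid in universe for t in catalog.get(pid, ())})

    rows = []
    skipped = 0
    for term in terms:
        members = {pid for pid in universe if term in catalog.get(pid, ())}
        a = len(members & flagged)
        b = len(members) - a
        if a + b < min_term_size:
            skipped += 1
            continue
        c = len(flagged) - a
        d = n_univ - a - b - c
        expected = (a + b) * (a + c) / n_univ
        factor = a / expected if expected > 0 else np.nan
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "term": term,
                "a_flagged_member": a,
                "b_unflagged_member": b,
                "c_flagged_nonmember": c,
                "d_rest": d,
                "enrichment_factor": factor,
                "direction": "enriched" if factor > 1 else "depleted",
                "p_value": float(p),
            }
        )
    if skipped:
        log.info("fisher_enrichment: %d term(s) below min size %d skipped",
                 skipped, min_term_size)
    result = pd.DataFrame(
        rows,
        columns=["term", "a_flagged_member", "b_unflagged_member",
                 "c_flagged_nonmember", "d_rest", "enrichment_factor",
                 "direction", "p_value"],
    )
    if len(result):
        result["q_value"] = benjamini_hochberg(result["p_value"].to_numpy())
    else:
        result["q_value"] = pd.Series(dtype=float)
    return result


# ---------------------------------------------------------------------------
# 1D annotation enrichment (rank-based)
# ---------------------------------------------------------------------------

def _one_d_single(values: np.ndarray, member_mask: np.ndarray) -> tuple[float, float, int, int]:
    """Position score s and two-sided rank-sum p for one term on one value
    vector (NaNs already removed).  Returns (s, p, n1, n2)."""
    n1 = int(member_mask.sum())
    n2 = int(len(values) - n1)
    ranks = stats.rankdata(values)  # average ranks handle ties
    u = float(ranks[member_mask].sum()) - n1 * (n1 + 1) / 2.0
    s = 2.0 * u / (n1 * n2) - 1.0
    # normal approximation with tie correction
    n = n1 + n2
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0, 1.0, n1, n2  # all values tied
    z = (u - n1 * n2 / 2.0) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return s, min(p, 1.0), n1, n2


def one_d_annotation_enrichment(
    values: pd.Series | pd.DataFrame,
    catalog: Mapping[str, frozenset[str] | set[str]],
    min_members: int = 2,
) -> pd.DataFrame:
    """Rank-based enrichment of each annotation term in a numeric score.

    ``values`` is a Series (one score per protein, e.g. log2 fold change)
    or a DataFrame (one column per sample, e.g. normalized intensities);
    with a DataFrame one result row is emitted per (term, sample).  Ranks
    are ascending, so s > 0 means members tend to hold high values.  Terms
    need at least ``min_members`` members and 2 non-members with defined
    values.  q-values are BH-adjusted within each sample.
    """
    frame = values.to_frame(name="value") if isinstance(values, pd.Series) else values
    terms = sorted({t for pid in frame.index for t in catalog.get(pid, ())})
    rows = []
    for col in frame.columns:
        v = frame[col].dropna()
        ids = v.index
        arr = v.to_numpy(float)
        col_rows = []
        for term in terms:
            mask = np.array([term in catalog.get(pid, ()) for pid in ids])
            if mask.sum() < min_members or (~mask).sum() < 2:
                continue
            s, p, n1, n2 = _one_d_single(arr, mask)
            col_rows.append(
                {"term": term, "sample": col, "n_members": n1,
                 "n_nonmembers": n2, "score": s, "p_value": p}
            )
        if col_rows:
            sub = pd.DataFrame(col_rows)
            sub["q_value"] = benjamini_hochberg(sub["p_value"].to_numpy())
            rows.append(sub)
    if not rows:
        return pd.DataFrame(
            columns=["term", "sample", "n_members", "n_nonmembers",
                     "score", "p_value", "q_value"]
        )
    return pd.concat(rows, ignore_index=True)


def one_d_score_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """Pivot 1D-enrichment results into a term × sample matrix of scores."""
    return results.pivot(index="term", columns="sample", values="score")
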