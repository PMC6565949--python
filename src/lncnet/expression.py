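"""RPKM normalisation, differential expression and the lncRNA candidate filter.

The differential-expression contract is deliberately small: downstream stages
only consume a group-mean fold change (ratio of the larger group mean to the
smaller) and a Benjamini–Hochberg adjusted p-value, with the filter
``ratio >= 2 and p_adj < 0.05``.  The test statistic behind the p-value is a
Welch two-sample t-test on log2(RPKM + 1); it is pluggable behind the record
table's columns.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

#: ratio reported when one group mean is exactly zero (flagged in ratio_capped)
RATIO_CAP = 1e6

DE_COLUMNS = [
    "transcript_id",
    "mean_control",
    "mean_case",
    "ratio",
    "ratio_capped",
    "signed_fc",
    "log2fc",
    "p_raw",
    "p_adj",
    "direction",
    "passes_filter",
]


def compute_rpkm(counts: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Reads per kilobase of exonic length per million mapped reads.

    ``RPKM[t, s] = counts[t, s] * 1e9 / (exonic_length[t] * library_size[s])``
    with library size the per-sample column sum of the count matrix.
    """
    lengths = annotation.set_index("transcript_id")["exonic_length"]
    missing = counts.index.difference(lengths.index)
    if len(missing) > 0:
        raise KeyError(f"no annotation for transcript(s): {list(missing[:5])}")
    lengths = lengths.reindex(counts.index).astype(float)
    if (lengths < 1).any():
        raise ValueError("exonic_length must be >= 1 for every transcript")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for sample(s): {bad}")
    return counts.div(lengths, axis=0).div(lib, axis=1) * 1e9


def differential_expression(
    expr: pd.DataFrame, groups: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-transcript Welch t-test on log2(RPKM+1) with BH adjustment.

    ``groups`` maps sample id to ``control``/``case``; each group needs at
    least two samples.  Transcripts constant across all samples get
    ``p_raw = 1``; a transcript with zero within-group variance but unequal
    means is infinitely well separated on this statistic and gets
    ``p_raw = 0``.  BH runs jointly over all tested transcripts.
    """
    groups = pd.Series(groups)
    ctrl = [s for s in expr.columns if groups.get(s) == "control"]
    case = [s for s in expr.columns if groups.get(s) == "case"]
    unknown = [s for s in expr.columns if s not in groups.index]
    if unknown:
        raise ValueError(f"samples without group label: {unknown}")
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError("each group needs >= 2 samples for a variance-based test")

    xc = expr[ctrl].to_numpy(dtype=float)
    xa = expr[case].to_numpy(dtype=float)
    mean_control = xc.mean(axis=1)
    mean_case = xa.mean(axis=1)

    lc = np.log2(xc + 1.0)
    la = np.log2(xa + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(la, lc, axis=1, equal_var=False)

    var0 = (lc.var(axis=1) == 0) & (la.var(axis=1) == 0)
    equal_means = np.isclose(lc.mean(axis=1), la.mean(axis=1))
    p = np.where(var0 & equal_means, 1.0, p)
    p = np.where(var0 & ~equal_means, 0.0, p)
    p = np.where(np.isnan(p), 1.0, p)  # residual degenerate cases: no evidence

    p_adj = multipletests(p, method="fdr_bh")[1]

    hi = np.maximum(mean_control, mean_case)
    lo = np.minimum(mean_control, mean_case)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lo > 0, hi / lo, np.where(hi > 0, np.inf, 1.0))
    capped = ~np.isfinite(ratio)
    if capped.any():
        log.info("capping %d infinite fold ratios at %g", int(capped.sum()), RATIO_CAP)
    ratio = np.where(capped, RATIO_CAP, ratio)
    signed_fc = np.where(mean_case >= mean_control, ratio, -ratio)
    log2fc = np.log2((mean_case + 1.0) / (mean_control + 1.0))
    direction = np.where(
        mean_case > mean_control, "up", np.where(mean_case < mean_control, "down", "unchanged")
    )

    records = pd.DataFrame(
        {
            "transcript_id": expr.index,
            "mean_control": mean_control,
            "mean_case": mean_case,
            "ratio": ratio,
            "ratio_capped": capped,
            "signed_fc": signed_fc,
            "log2fc": log2fc,
            "p_raw": p,
            "p_adj": p_adj,
            "direction": direction,
        }
    ).reset_index(drop=True)
    records["passes_filter"] = (records["ratio"] >= 2.0) & (records["p_adj"] < 0.05)
    return records[DE_COLUMNS]


def filter_de(
    records: pd.DataFrame, min_ratio: float = 2.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Keep records with ratio >= min_ratio and p_adj < alpha, order preserved.

    The ratio bound is inclusive, the significance bound strict.
    """
    keep = (records["ratio"] >= min_ratio) & (records["p_adj"] < alpha)
    return records.loc[keep].copy()


def classify_lncrna_candidates(annotation: pd.DataFrame) -> pd.DataFrame:
    """Apply the lncRNA candidate filter; label rejects with the failed rule.

    A transcript is a candidate iff exonic length > 200 nt (strict), more
    than two exons (strict), and all three coding-potential verdicts are
    non-coding.  Returns a copy with ``is_candidate`` and ``fail_reason``
    columns; ``fail_reason`` is the first failed rule in that order.
    """
    out = annotation.copy()
    reasons = []
    for row in out.itertuples(index=False):
        if row.exonic_length <= 200:
            reasons.append("length<=200nt")
        elif row.exon_count <= 2:
            reasons.append("exons<=2")
        elif row.flag_cpc or row.flag_cnci or row.flag_pfam:
            reasons.append("coding_flag")
        else:
            reasons.append("")
    out["fail_reason"] = reasons
    out["is_candidate"] = out["fail_reason"] == ""
    return out


def top_table(records: pd.DataFrame, n_up: int = 10, n_down: int = 10) -> pd.DataFrame:
    """Largest-fold-change records per direction, down block then up block.

    Rank key is ratio descending; ties break by smaller adjusted p, then by
    transcript id.  Requests beyond the available rows return what exists.
    """
    def top(direction: str, n: int) -> pd.DataFrame:
        block = records.loc[records["direction"] == direction].copy()
        block = block.sort_values(
            ["ratio", "p_adj", "transcript_id"], ascending=[False, True, True]
        )
        return block.head(n)

    return pd.concat([top("down", n_down), top("up", n_up)], ignore_index=True)
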