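"""Figure-ready tables: volcano, heatmap matrix and hub ranking.

No plots are rendered here; each function emits a plain table any plotting
tool can consume.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .network import NetworkSummary


def volcano_table(records: pd.DataFrame) -> pd.DataFrame:
    """Signed fold change vs −log10 adjusted p, with the highlight flag.

    ``highlight`` is exactly the DE filter membership (ratio >= 2 and
    adjusted p < 0.05), i.e. the red-dot set of a volcano plot.
    """
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(records["p_adj"].to_numpy(dtype=float))
    return pd.DataFrame(
        {
            "transcript_id": records["transcript_id"],
            "signed_fc": records["signed_fc"],
            "log2fc": records["log2fc"],
            "neg_log10_p_adj": neg_log10,
            "highlight": records["passes_filter"],
        }
    ).reset_index(drop=True)


def heatmap_matrix(
    expr: pd.DataFrame, ids, groups: dict[str, str] | pd.Series | None = None
) -> pd.DataFrame:
    """Row-standardised log2(RPKM+1) for the selected transcripts.

    Each non-constant row is z-scored (population SD) to mean 0, variance 1;
    constant rows become all zeros with a warning.  When ``groups`` is given
    the columns are reordered control samples first, then case, preserving
    the original order within each block.
    """
    ids = list(ids)
    missing = [t for t in ids if t not in expr.index]
    if missing:
        raise KeyError(f"unknown transcript id(s): {missing[:5]}")
    sub = expr.loc[ids]
    if groups is not None:
        groups = pd.Series(groups)
        ordered = [s for s in sub.columns if groups.get(s) == "control"] + [
            s for s in sub.columns if groups.get(s) != "control"
        ]
        sub = sub[ordered]
    logx = np.log2(sub.to_numpy(dtype=float) + 1.0)
    mu = logx.mean(axis=1, keepdims=True)
    sd = logx.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant row(s) emitted as all zeros", stacklevel=2
        )
    sd[sd == 0] = 1.0
    z = (logx - mu) / sd
    z[flat, :] = 0.0
    return pd.DataFrame(z, index=sub.index, columns=sub.columns)


def hub_report(
    summary: NetworkSummary | pd.DataFrame, n: int = 10, role: str | None = None
) -> pd.DataFrame:
    """Top-n nodes per role by degree (ties broken by id).

    Accepts either a :class:`NetworkSummary` or a bare node table with
    columns id/role/direction/degree.  ``role`` restricts the report to one
    side of the bipartite graph; n beyond the node count returns all nodes.
    """
    nodes = summary.nodes if isinstance(summary, NetworkSummary) else summary
    blocks = []
    for r, block in nodes.groupby("role", sort=True):
        if role is not None and r != role:
            continue
        block = block.sort_values(["degree", "id"], ascending=[False, True])
        blocks.append(block.head(n))
    if not blocks:
        return nodes.head(0).copy()
    return pd.concat(blocks, ignore_index=True)
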