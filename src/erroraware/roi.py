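"""Cluster-wise activity extraction and brain-behavior correlations.

Per-subject mean percent-area activation is averaged (unweighted) over
the voxels of each surviving cluster, then related to behavioral indices
with Spearman correlations, Holm-adjusted within user-declared families.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import holm_adjust, spearman_rho

__all__ = ["cluster_means", "behavior_correlations"]


def cluster_means(
    activation_maps: dict[str, np.ndarray],
    label_map: np.ndarray,
    subject_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Mean activation per subject, cluster, and condition.

    ``activation_maps`` maps condition name to a stacked (n_subjects,
    x, y, z) array on the cluster grid. Returns a long table with
    columns subject_id, cluster_id, condition, mean. Raises if the label
    map contains no clusters or a grid does not match.
    """
    ids = np.unique(label_map)
    ids = ids[ids > 0]
    if len(ids) == 0:
        raise ValueError("label map contains no clusters")
    rows = []
    for cond, stack in activation_maps.items():
        stack = np.asarray(stack, dtype=float)
        if stack.shape[1:] != label_map.shape:
            raise ValueError(
                f"{cond} maps {stack.shape[1:]} do not match cluster grid "
                f"{label_map.shape}"
            )
        n = stack.shape[0]
        subjects = subject_ids or [f"sub-{i:02d}" for i in range(n)]
        for cid in ids:
            mask = label_map == cid
            means = stack[:, mask].mean(axis=1)
            for sid, m in zip(subjects, means):
                rows.append(
                    {
                        "subject_id": sid,
                        "cluster_id": int(cid),
                        "condition": cond,
                        "mean": float(m),
                    }
                )
    return pd.DataFrame(rows)


def behavior_correlations(
    roi: pd.DataFrame,
    behavior: pd.DataFrame,
    pairs: list[tuple[str, str, str]],
    min_n: int = 3,
) -> pd.DataFrame:
    """Spearman correlations between ROI activity and behavioral indices.

    ``roi`` and ``behavior`` are subject-indexed wide tables; ``pairs``
    lists (roi_column, behavior_column, family) triples. Subjects with a
    missing value in either member of a pair are dropped pairwise and the
    retained n reported. Holm adjustment is applied within each family.
    Pairs with fewer than ``min_n`` complete observations get NaN output.
    """
    joined = roi.join(behavior, how="inner", lsuffix="", rsuffix="_beh")
    rows = []
    for roi_col, beh_col, family in pairs:
        if roi_col not in joined.columns or beh_col not in joined.columns:
            raise KeyError(f"unknown column in pair ({roi_col}, {beh_col})")
        sub = joined[[roi_col, beh_col]].dropna()
        if len(sub) < min_n:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = spearman_rho(sub[roi_col].to_numpy(), sub[beh_col].to_numpy())
        rows.append(
            {
                "roi": roi_col,
                "behavior": beh_col,
                "family": family,
                "rho": rho,
                "p": p,
                "n": len(sub),
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = np.nan
    for fam, grp in out.groupby("family"):
        ok = grp["p"].notna()
        if ok.any():
            out.loc[grp.index[ok], "p_holm"] = holm_adjust(grp.loc[ok, "p"].to_numpy())
    return out
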