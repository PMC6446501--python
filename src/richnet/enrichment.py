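"""Pre-ranked competitive gene set testing and direction classification.

The test is the pre-ranked variant of camera: for each gene set, the mean of
the in-set ranking statistics is compared with the mean of all other
statistics by a two-sample t-test whose variance is inflated by a factor
``1 + (m - 1) * rho`` to account for an assumed inter-gene correlation
``rho`` within the set. With ``rho = 0`` the statistic reduces exactly to the
classical pooled two-sample t-test.

Each set is tested twice: on the signed statistics (directional test, label
Up or Down from the sign of the mean difference) and on their absolute
values (the "mixed" test, which detects coherent dysregulation without a
preferred direction). Classification then works on BH-adjusted values: a set
keeps its directional label if its directional FDR passes the cut, is
re-labelled Mixed if only the mixed-test FDR passes (and that FDR is then
the one reported), and is dropped otherwise.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .geneset_io import ENRICHMENT_COLUMNS, GeneSetLibrary

__all__ = [
    "camera_pr",
    "bh_adjust",
    "run_enrichment",
    "classify_direction",
]

#: documented default of the inter-gene correlation assumed by the test
DEFAULT_INTER_GENE_COR = 0.01


def _as_stat_series(stats: pd.DataFrame | pd.Series) -> pd.Series:
    if isinstance(stats, pd.Series):
        return stats
    return pd.Series(stats["stat"].to_numpy(), index=stats["gene_id"].to_numpy())


def camera_pr(
    stats: pd.DataFrame | pd.Series,
    set_members: Iterable[str],
    inter_gene_cor: float = DEFAULT_INTER_GENE_COR,
) -> tuple[str, float]:
    """Competitive pre-ranked test of one gene set against the rest.

    Parameters
    ----------
    stats
        Per-gene ranking statistics: either a DataFrame with columns
        ``gene_id``/``stat`` or a Series indexed by gene ID.
    set_members
        Gene IDs of the tested set; all must be present in ``stats``.
    inter_gene_cor
        Assumed correlation between in-set gene statistics (``rho``); the
        variance inflation factor is ``1 + (m - 1) * rho``.

    Returns
    -------
    (direction, p)
        ``direction`` is ``"Up"`` if the in-set mean is >= the out-of-set
        mean, else ``"Down"``; ``p`` is the two-sided p-value from a t
        distribution with ``G - 2`` degrees of freedom.
    """
    s = _as_stat_series(stats)
    members = frozenset(set_members)
    G = len(s)
    if G < 2:
        raise ValueError("need at least 2 ranked genes")
    in_mask = s.index.isin(members)
    m = int(in_mask.sum())
    if m != len(members):
        missing = sorted(members - set(s.index))
        raise ValueError(f"set members absent from statistics: {missing[:10]}")
    if m == 0 or m == G:
        raise ValueError("degenerate partition: set is empty or spans all genes")

    x = s.to_numpy(dtype=float)
    in_stats = x[in_mask]
    out_stats = x[~in_mask]
    m2 = G - m
    df = G - 2

    delta = in_stats.mean() - out_stats.mean()
    # pooled two-group variance on G - 2 df
    ss_in = ((in_stats - in_stats.mean()) ** 2).sum()
    ss_out = ((out_stats - out_stats.mean()) ** 2).sum()
    sigma2 = (ss_in + ss_out) / df

    vif = 1.0 + (m - 1) * inter_gene_cor
    if sigma2 > 0:
        t = delta / np.sqrt(sigma2 * (vif / m + 1.0 / m2))
        p = 2.0 * sps.t.sf(abs(t), df)
    elif delta == 0:
        p = 1.0
    else:  # zero within-group variance but distinct group means
        p = 0.0
    direction = "Up" if delta >= 0 else "Down"
    return direction, float(min(p, 1.0))


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-aligned with input."""
    p = np.asarray(list(pvals) if not isinstance(pvals, np.ndarray) else pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_enrichment(
    stats: pd.DataFrame | pd.Series,
    lib: GeneSetLibrary,
    inter_gene_cor: float = DEFAULT_INTER_GENE_COR,
) -> pd.DataFrame:
    """Directional and mixed competitive tests for every set in the library.

    The library must already be restricted to the measured universe (every
    member of every set present in ``stats``). Returns a DataFrame in
    library order with columns name, NGenes, Direction, PValue,
    PValue.Mixed — unadjusted; see :func:`classify_direction`.
    """
    s = _as_stat_series(stats)
    s_abs = s.abs()
    rows = []
    for name in lib.names:
        members = lib.members(name, "restricted")
        direction, p = camera_pr(s, members, inter_gene_cor)
        _, p_mixed = camera_pr(s_abs, members, inter_gene_cor)
        rows.append((name, len(members), direction, p, p_mixed))
    return pd.DataFrame(
        rows, columns=["name", "NGenes", "Direction", "PValue", "PValue.Mixed"]
    )


def classify_direction(raw: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Classify sets as Up/Down/Mixed and drop non-significant ones.

    Both p-value families are BH-adjusted over *all* tested sets (adjust
    first, filter second). A set keeps its directional label iff its
    directional FDR <= ``alpha``; otherwise it becomes Mixed iff its
    mixed-test FDR <= ``alpha``, in which case the reported FDR is the mixed
    one (PValue stays directional); otherwise it is dropped.
    """
    if raw.empty:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    out = raw.copy().reset_index(drop=True)
    fdr = bh_adjust(out["PValue"].to_numpy())
    fdr_mixed = bh_adjust(out["PValue.Mixed"].to_numpy())
    out["FDR"] = fdr

    demote = fdr > alpha
    out.loc[demote, "Direction"] = "Mixed"
    out.loc[demote, "FDR"] = fdr_mixed[demote]
    drop = demote & (fdr_mixed > alpha)
    out = out.loc[~drop, ENRICHMENT_COLUMNS].reset_index(drop=True)
    return out
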