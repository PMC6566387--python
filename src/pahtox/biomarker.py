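"""cyp1a biomarker status, cluster concordance, DEG set algebra and the
concentration-uptake-ratio (CUR) correlation analysis.

*cyp1a* induction is the classical transcript biomarker of aryl hydrocarbon
receptor (AhR) activation: an exposure is called marker-elevated when its
cyp1a log2 fold change exceeds 1 with BH-adjusted p below 0.05 (strict
inequalities).  Concordance with the transcriptomic clusters asks how often
"cluster B" coincides with "marker elevated" and attaches a Fisher exact
test.  CUR = nominal medium concentration / measured embryo concentration;
its log10 mean per chemical is correlated (Pearson) with the chemical's DEG
count, restricted to chemicals below a log Kow cutoff (default 5.5) since
very hydrophobic compounds sorb to plates and break the nominal-dose
assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarkerStatus",
    "CorrelationResult",
    "marker_status",
    "cluster_marker_concordance",
    "deg_overlap",
    "cur_correlation",
]


@dataclass(frozen=True)
class MarkerStatus:
    condition: str
    marker_log2fc: float
    marker_padj: float
    elevated: bool


@dataclass(frozen=True)
class CorrelationResult:
    r2: float
    p: float
    n: int


def marker_status(
    de: pd.DataFrame,
    condition: str,
    marker: str = "cyp1a",
    fc_log2_min: float = 1.0,
    alpha: float = 0.05,
) -> MarkerStatus:
    """Marker-elevation call for one condition from its DE table.

    Elevated iff log2FC > fc_log2_min AND padj < alpha (both strict).
    """
    if marker not in de.index:
        raise KeyError(f"marker gene {marker!r} missing from DE table")
    row = de.loc[marker]
    log2fc = float(row["log2fc"])
    padj = float(row["padj"])
    return MarkerStatus(
        condition=condition,
        marker_log2fc=log2fc,
        marker_padj=padj,
        elevated=(log2fc > fc_log2_min) and (padj < alpha),
    )


def cluster_marker_concordance(labels: pd.Series, statuses) -> dict:
    """Agreement between cluster-B membership and marker elevation.

    ``labels``: condition -> "A"/"B" (controls already excluded);
    ``statuses``: iterable of :class:`MarkerStatus` over the same conditions.
    Returns concordance fraction, the 2x2 table (rows: cluster B yes/no;
    columns: elevated yes/no) and a two-sided Fisher exact p-value.
    """
    status_map = {s.condition: s.elevated for s in statuses}
    if set(status_map) != set(labels.index):
        raise ValueError(
            "condition sets differ between cluster labels and marker statuses"
        )
    is_b = labels == "B"
    elev = pd.Series({c: status_map[c] for c in labels.index})
    table = np.array(
        [
            [int((is_b & elev).sum()), int((is_b & ~elev).sum())],
            [int((~is_b & elev).sum()), int((~is_b & ~elev).sum())],
        ]
    )
    concordance = float((is_b == elev).mean())
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    return {"concordance": concordance, "table": table, "fisher_p": float(fisher_p)}


def deg_overlap(sets: dict):
    """Exact set algebra over per-treatment DEG sets.

    Returns (shared-by-all set, per-treatment unique sets, symmetric
    pairwise intersection-count DataFrame).
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 DEG sets")
    names = sorted(sets)
    shared = set.intersection(*(set(sets[n]) for n in names))
    unique = {
        n: {g for g in sets[n] if not any(g in sets[m] for m in names if m != n)}
        for n in names
    }
    pairwise = pd.DataFrame(
        [[len(set(sets[a]) & set(sets[b])) for b in names] for a in names],
        index=names,
        columns=names,
    )
    return shared, unique, pairwise


def cur_correlation(
    records: pd.DataFrame,
    deg_counts,
    log_kow_max: float = 5.5,
) -> tuple[CorrelationResult, pd.DataFrame]:
    """Pearson correlation of log10 mean CUR against per-chemical DEG counts.

    ``records`` columns: chemical, cur, log_kow (one row per replicate
    measurement).  ``deg_counts``: chemical -> DEG total.  Chemicals with
    log Kow >= ``log_kow_max`` are excluded.  The per-chemical CUR standard
    deviation is computed and reported alongside, but the correlation uses
    the log10 mean.  Returns (CorrelationResult with r^2, two-sided Pearson
    t-test p and n, per-chemical summary table).
    """
    required = {"chemical", "cur", "log_kow"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"CUR table missing columns: {sorted(missing)}")
    if (records["cur"] <= 0).any():
        raise ValueError("CUR values must be positive")
    deg_counts = pd.Series(dict(deg_counts))
    summary = (
        records.groupby("chemical")
        .agg(
            mean_cur=("cur", "mean"),
            sd_cur=("cur", lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0),
            log_kow=("log_kow", "first"),
            n_records=("cur", "size"),
        )
        .sort_index()
    )
    summary["log10_mean_cur"] = summary["mean_cur"].map(math.log10)
    summary["deg_count"] = summary.index.map(deg_counts)
    if summary["deg_count"].isna().any():
        missing_chems = summary.index[summary["deg_count"].isna()].tolist()
        raise ValueError(f"no DEG count for chemicals: {missing_chems}")
    used = summary.loc[summary["log_kow"] < log_kow_max]
    if len(used) < 3:
        raise ValueError(
            f"fewer than 3 chemicals below log Kow {log_kow_max}; cannot correlate"
        )
    r, p = stats.pearsonr(used["log10_mean_cur"], used["deg_count"].astype(float))
    result = CorrelationResult(r2=float(r**2), p=float(p), n=int(len(used)))
    return result, summary
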