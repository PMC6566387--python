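"""Count normalization, differential expression, DEG filtering and
condition-mean profiles for the whole-animal RNA-seq arm.

Counts are normalized with median-of-ratios size factors.  Each treatment
is tested against its day-matched vehicle control with a per-gene Welch
test on log2(normalized + 1); this is a deliberate lightweight surrogate
for a negative-binomial Wald test — the downstream pipeline only consumes
the (log2FC, p, padj) table, and on log-scale planted effects the surrogate
is unbiased.  DEGs are |FC| >= 1.5 with Benjamini-Hochberg adjusted
p < 0.05.  Outlier replicates are flagged from a 2-D classical MDS of the
log-expression distance matrix, and condition-mean profiles feed the
coefficient-of-variation gene ranking used by the network stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEGSet",
    "size_factors",
    "normalized_counts",
    "bh_adjust",
    "de_table",
    "filter_degs",
    "flag_outlier_replicates",
    "condition_means",
    "top_cv_genes",
]


def _check_meta(counts: pd.DataFrame, meta: pd.DataFrame) -> None:
    required = {"sample_id", "treatment", "day", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if set(counts.columns) != set(meta["sample_id"]):
        raise ValueError("count matrix columns and metadata sample_ids differ")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are rows with no zero entry.  For sample s,
    factor_s = median over reference genes g of counts_gs / geomean_g(counts).
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    positive = counts.loc[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no gene row with all-positive counts; cannot normalize")
    log_counts = np.log(positive.to_numpy(dtype=float))
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_counts - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _matched_control(meta: pd.DataFrame, treatment: str) -> str:
    rows = meta.loc[meta["treatment"] == treatment]
    if rows.empty:
        raise ValueError(f"treatment {treatment!r} absent from metadata")
    day = rows["day"].iloc[0]
    if "is_control" not in meta.columns:
        raise ValueError("metadata needs an is_control column to find matched controls")
    ctrl = meta.loc[meta["is_control"].astype(bool) & (meta["day"] == day), "treatment"]
    ctrl_names = ctrl.unique()
    if len(ctrl_names) != 1:
        raise ValueError(f"expected exactly one day-{day} control, found {list(ctrl_names)}")
    return str(ctrl_names[0])


def de_table(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    treatment: str,
    factors: pd.Series | None = None,
    control: str | None = None,
    keep: pd.Series | None = None,
    eps: float = 1.0,
) -> pd.DataFrame:
    """Per-gene differential expression of ``treatment`` vs its day-matched control.

    Returns a DataFrame indexed by gene with columns log2fc, p, padj where
    log2fc = log2((mean_norm_treatment + eps) / (mean_norm_control + eps))
    and p comes from a per-gene Welch two-sample test on log2(norm + eps).
    ``keep`` (sample_id -> bool) drops outlier-flagged replicates first.
    """
    _check_meta(counts, meta)
    if control is None:
        control = _matched_control(meta, treatment)
    norm = normalized_counts(counts, factors)
    if keep is not None:
        retained = [s for s in counts.columns if bool(keep.get(s, True))]
        meta = meta.loc[meta["sample_id"].isin(retained)]
        norm = norm[ [s for s in norm.columns if s in retained] ]
    t_samples = meta.loc[meta["treatment"] == treatment, "sample_id"].tolist()
    c_samples = meta.loc[meta["treatment"] == control, "sample_id"].tolist()
    if len(t_samples) < 2 or len(c_samples) < 2:
        raise ValueError(
            f"need >= 2 retained replicates per group, got {len(t_samples)} "
            f"({treatment}) and {len(c_samples)} ({control})"
        )
    t_norm = norm[t_samples].to_numpy(dtype=float)
    c_norm = norm[c_samples].to_numpy(dtype=float)
    log2fc = np.log2(t_norm.mean(axis=1) + eps) - np.log2(c_norm.mean(axis=1) + eps)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(
            np.log2(t_norm + eps), np.log2(c_norm + eps), axis=1, equal_var=False
        )
    p = np.where(np.isnan(p), 1.0, p)  # zero variance in both groups
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "padj": bh_adjust(p)}, index=counts.index
    )


@dataclass
class DEGSet:
    """Filtered differentially expressed genes for one treatment."""

    treatment: str
    elevated: set = field(default_factory=set)
    reduced: set = field(default_factory=set)

    @property
    def genes(self) -> set:
        return self.elevated | self.reduced


def filter_degs(
    de: pd.DataFrame, treatment: str = "", fc_min: float = 1.5, alpha: float = 0.05
) -> DEGSet:
    """Apply the DEG criterion |log2FC| >= log2(fc_min) and padj < alpha."""
    if fc_min < 1:
        raise ValueError(f"fc_min must be >= 1, got {fc_min}")
    thr = np.log2(fc_min)
    sig = de["padj"] < alpha
    elevated = set(de.index[sig & (de["log2fc"] >= thr)])
    reduced = set(de.index[sig & (de["log2fc"] <= -thr)])
    return DEGSet(treatment=treatment, elevated=elevated, reduced=reduced)


def _classical_mds(dist2: np.ndarray, ndim: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS coordinates from squared distances."""
    n = dist2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ dist2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:ndim]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def flag_outlier_replicates(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    factors: pd.Series | None = None,
    detach_factor: float = 3.0,
) -> pd.Series:
    """Flag replicates that drift into another condition's cloud.

    Samples are embedded by classical 2-D MDS of Euclidean distances between
    log2(normalized + 1) profiles; a replicate is a candidate when its
    nearest neighbour in that plane belongs to a different condition.  Many
    conditions in a screen are transcriptionally equivalent (quiet
    treatments sit on top of the controls), so crossing a condition
    boundary alone is not evidence of a bad replicate: a candidate is only
    flagged when it is also detached from its own replicates — its nearest
    same-condition distance exceeds ``detach_factor`` times the study-wide
    median nearest-same-condition distance.  Flags are only allowed for
    conditions with >= 3 replicates and are capped at one per condition
    (the sample farthest from its own-condition centroid wins).  Returns
    sample_id -> keep (True = retain).
    """
    _check_meta(counts, meta)
    samples = list(counts.columns)
    log_norm = np.log2(normalized_counts(counts, factors).to_numpy(dtype=float).T + 1.0)
    dist2 = (
        np.sum(log_norm**2, axis=1)[:, None]
        + np.sum(log_norm**2, axis=1)[None, :]
        - 2.0 * log_norm @ log_norm.T
    )
    np.fill_diagonal(dist2, 0.0)
    coords = _classical_mds(np.clip(dist2, 0.0, None))
    cond = meta.set_index("sample_id").loc[samples, "treatment"].to_numpy()
    n = len(samples)
    d2 = (
        np.sum(coords**2, axis=1)[:, None]
        + np.sum(coords**2, axis=1)[None, :]
        - 2.0 * coords @ coords.T
    )
    np.fill_diagonal(d2, np.inf)
    nn = np.argmin(d2, axis=1)
    same = cond[:, None] == cond[None, :]
    nn_same = np.sqrt(np.min(np.where(same, d2, np.inf), axis=1))
    cutoff = detach_factor * float(np.median(nn_same))
    counts_per_cond = pd.Series(cond).value_counts()
    flagged = {
        i
        for i in range(n)
        if cond[nn[i]] != cond[i]
        and nn_same[i] > cutoff
        and counts_per_cond[cond[i]] >= 3
    }
    # cap at one drop per condition: keep the flag on the sample farthest
    # from its own-condition centroid
    keep = pd.Series(True, index=pd.Index(samples, name="sample_id"), name="keep")
    for c in np.unique(cond):
        members = [i for i in flagged if cond[i] == c]
        if not members:
            continue
        centroid = coords[cond == c].mean(axis=0)
        worst = max(members, key=lambda i: float(np.sum((coords[i] - centroid) ** 2)))
        keep.iloc[worst] = False
    return keep


def condition_means(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    factors: pd.Series | None = None,
    keep: pd.Series | None = None,
) -> pd.DataFrame:
    """Conditions x genes matrix of mean normalized expression over retained replicates."""
    _check_meta(counts, meta)
    norm = normalized_counts(counts, factors)
    if keep is not None:
        retained = [s for s in counts.columns if bool(keep.get(s, True))]
    else:
        retained = list(counts.columns)
    rows = {}
    for condition, grp in meta.groupby("treatment", sort=True):
        samples = [s for s in grp["sample_id"] if s in retained]
        if not samples:
            raise ValueError(f"condition {condition!r} has zero retained replicates")
        rows[condition] = norm[samples].mean(axis=1)
    return pd.DataFrame(rows).T


def top_cv_genes(cm: pd.DataFrame, n: int = 500) -> list[str]:
    """Genes ranked by coefficient of variation across condition means.

    CV = sample sd (n-1 denominator) / mean over the condition rows; genes
    with non-positive mean are excluded; ties broken by gene identifier.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    mean = cm.mean(axis=0)
    sd = cm.std(axis=0, ddof=1)
    eligible = mean > 0
    cv = sd[eligible] / mean[eligible]
    order = sorted(cv.index, key=lambda g: (-cv[g], str(g)))
    return order[:n]
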