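"""Lowest-effect-level calling and hierarchical phenotype binning.

A high-throughput developmental screen records, per chemical, endpoint and
concentration, the number of embryos showing an abnormal phenotype out of
those tested.  For each chemical-endpoint series the lowest effect level
(LEL) is the smallest tested concentration whose incidence significantly
exceeds the background rate under a one-sided exact binomial test.  LEL
profiles are encoded into a numeric severity matrix (more potent = larger
score) together with Cyp1a protein tissue-localization flags, and chemicals
are grouped into hazard bins by agglomerative clustering of that matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.stats import binom

__all__ = [
    "CYP1A_TISSUES",
    "IncidenceRecord",
    "LELProfile",
    "binomial_exceedance_test",
    "pooled_control_rate",
    "compute_lel",
    "lel_profiles",
    "encode_lel_matrix",
    "assign_bins",
]

#: Cyp1a protein localization sites scored in the screen.
CYP1A_TISSUES = ("vasculature", "liver", "skin", "neuromasts", "yolk")


@dataclass(frozen=True)
class IncidenceRecord:
    chemical: str
    endpoint: str
    conc: float  # µM; 0 = vehicle control
    n_affected: int
    n_total: int

    def __post_init__(self) -> None:
        if self.conc < 0:
            raise ValueError(f"conc must be >= 0, got {self.conc}")
        if not (0 <= self.n_affected <= self.n_total):
            raise ValueError(
                f"need 0 <= n_affected <= n_total, got {self.n_affected}/{self.n_total}"
            )


@dataclass
class LELProfile:
    """Per-chemical lowest effect levels plus Cyp1a tissue flags."""

    chemical: str
    lel: dict  # endpoint -> dose (µM) or None
    cmax: float  # highest tested dose
    cyp1a_flags: dict = field(default_factory=dict)  # tissue -> bool

    def __post_init__(self) -> None:
        for ep, dose in self.lel.items():
            if dose is not None and dose > self.cmax:
                raise ValueError(
                    f"{self.chemical}/{ep}: LEL {dose} exceeds cmax {self.cmax}"
                )


def binomial_exceedance_test(x: int, n: int, p0: float) -> float:
    """One-sided upper-tail exact binomial p-value P(X >= x | X ~ Bin(n, p0)).

    x = 0 returns 1 by convention (the event "at least zero affected" is
    certain); x = n returns p0**n.
    """
    if not (0 <= x <= n):
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if not (0 < p0 < 1):
        raise ValueError(f"background rate p0 must lie in (0, 1), got {p0}")
    # sf(x-1) = P(X >= x)
    return float(binom.sf(x - 1, n, p0))


def pooled_control_rate(n_affected_control: int, n_control: int) -> float:
    """Background rate from pooled vehicle controls.

    Zero affected controls would make the exact test flag any single event,
    so the rate is floored at 0.5 / (n_control + 1), a half-count continuity
    adjustment.
    """
    if n_control < 1:
        raise ValueError("no control animals: cannot estimate background rate")
    if n_affected_control == 0:
        return 0.5 / (n_control + 1)
    return n_affected_control / n_control


def compute_lel(records, control_rate: float | None = None, alpha: float = 0.05):
    """Smallest tested dose whose exceedance p-value is below ``alpha``.

    ``records`` is an iterable of :class:`IncidenceRecord` (or a DataFrame
    with columns conc, n_affected, n_total) for a single chemical-endpoint
    series.  Dose-0 rows are pooled into the background rate unless
    ``control_rate`` is supplied explicitly.  Returns the LEL dose, or
    ``None`` when no dose reaches significance.
    """
    if isinstance(records, pd.DataFrame):
        rows = list(records[["conc", "n_affected", "n_total"]].itertuples(index=False))
    else:
        rows = [(r.conc, r.n_affected, r.n_total) for r in records]
    doses = [(c, x, n) for c, x, n in rows if c > 0]
    controls = [(x, n) for c, x, n in rows if c == 0]
    if not doses:
        raise ValueError("need at least one non-control dose")
    if control_rate is None:
        if not controls:
            raise ValueError(
                "no control (dose-0) records and no control_rate supplied"
            )
        control_rate = pooled_control_rate(
            sum(x for x, _ in controls), sum(n for _, n in controls)
        )
    for conc, x, n in sorted(doses):
        if binomial_exceedance_test(x, n, control_rate) < alpha:
            return conc
    return None


def lel_profiles(
    incidence: pd.DataFrame,
    cyp1a_flags: pd.DataFrame | None = None,
    control_rate: float | None = None,
    alpha: float = 0.05,
) -> list[LELProfile]:
    """Compute one :class:`LELProfile` per chemical from a long incidence table.

    ``incidence`` columns: chemical, endpoint, conc_uM, n_affected, n_total.
    ``cyp1a_flags`` (optional): one row per chemical, 0/1 columns per tissue.
    """
    required = {"chemical", "endpoint", "conc_uM", "n_affected", "n_total"}
    missing = required - set(incidence.columns)
    if missing:
        raise ValueError(f"incidence table missing columns: {sorted(missing)}")
    profiles = []
    for chemical, chem_df in incidence.groupby("chemical", sort=True):
        cmax = float(chem_df["conc_uM"].max())
        lels: dict = {}
        for endpoint, ep_df in chem_df.groupby("endpoint", sort=True):
            sub = ep_df.rename(columns={"conc_uM": "conc"})
            lels[endpoint] = compute_lel(sub, control_rate=control_rate, alpha=alpha)
        flags: dict = {}
        if cyp1a_flags is not None:
            row = cyp1a_flags.loc[cyp1a_flags["chemical"] == chemical]
            if len(row):
                flags = {
                    t: bool(row.iloc[0][t]) for t in CYP1A_TISSUES if t in row.columns
                }
        profiles.append(
            LELProfile(chemical=str(chemical), lel=lels, cmax=cmax, cyp1a_flags=flags)
        )
    return profiles


def encode_lel_matrix(profiles: list[LELProfile], cyp1a_weight: float = 1.0) -> pd.DataFrame:
    """Numeric chemicals x features matrix for clustering.

    Severity per endpoint is ``1 + log10(cmax / lel)`` for affected
    endpoints (LEL at the top tested dose scores 1; each decade of extra
    potency adds 1) and 0 for inactive ones.  Cyp1a tissue flags are
    appended as 0/``cyp1a_weight`` columns.
    """
    if not profiles:
        raise ValueError("no profiles to encode")
    endpoints = sorted(profiles[0].lel)
    for p in profiles[1:]:
        if sorted(p.lel) != endpoints:
            raise ValueError(f"profile {p.chemical} has a different endpoint set")
    rows = {}
    for p in profiles:
        scores = []
        for ep in endpoints:
            dose = p.lel[ep]
            scores.append(0.0 if dose is None else 1.0 + math.log10(p.cmax / dose))
        scores.extend(
            cyp1a_weight * float(bool(p.cyp1a_flags.get(t, False)))
            for t in CYP1A_TISSUES
        )
        rows[p.chemical] = scores
    cols = endpoints + [f"cyp1a_{t}" for t in CYP1A_TISSUES]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols).sort_index()


def assign_bins(
    matrix: pd.DataFrame,
    k: int = 8,
    linkage: str = "ward",
    metric: str = "euclidean",
):
    """Agglomerative clustering of the encoded matrix cut at ``k`` bins.

    Bins are renumbered canonically: bin 1 has the highest mean row severity
    (mean over all encoded columns averaged over members), bin ``k`` the
    lowest; ties broken by the lexicographically smallest member chemical.
    Returns a (chemical -> bin) Series and the scipy linkage matrix.
    """
    if matrix.shape[0] == 0:
        raise ValueError("empty matrix")
    if not 1 <= k <= matrix.shape[0]:
        raise ValueError(f"k must be in [1, {matrix.shape[0]}], got {k}")
    values = matrix.to_numpy(dtype=float)
    if matrix.shape[0] == 1:
        return pd.Series([1], index=matrix.index, name="bin"), None
    Z = scipy_linkage(values, method=linkage, metric=metric)
    raw = fcluster(Z, t=k, criterion="maxclust")
    severity = values.mean(axis=1)
    order = sorted(
        np.unique(raw),
        key=lambda lab: (
            -severity[raw == lab].mean(),
            min(matrix.index[raw == lab]),
        ),
    )
    relabel = {lab: i + 1 for i, lab in enumerate(order)}
    bins = pd.Series([relabel[lab] for lab in raw], index=matrix.index, name="bin")
    return bins, Z
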