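"""Seeded synthetic data with the statistical structure the pipeline assumes.

No raw data accompany the study design this package targets (no GEO/SRA
accession exists for it), so every downstream stage is exercised on
generated inputs:

* a phenotype screen — chemicals drawn from a set of per-bin endpoint
  potency templates; affected counts are binomial with per-dose probability
  given by an LL.4 curve clipped to [background_rate, 1], dose-0 vehicle
  rows at the background rate;
* an expression study — negative-binomial gene x sample counts for 16
  treatments plus two day-matched vehicle controls, four replicates each
  (72 samples), with a planted shared "AhR battery" module (containing the
  cyp1a marker) elevated in B-like treatments, treatment-private DEGs, a
  library-size factor per sample, and a multiplicative day/batch shift on a
  random 5% of genes in day-2 samples;
* a body-burden table — replicated concentration-uptake-ratio (CUR) draws
  around a per-chemical true ratio under lognormal noise.

Randomness is organized as one stream per chemical/gene/sample derived
from (seed, stream-kind, index), so enlarging a simulation never reshuffles
existing draws; fixing the seed fixes every byte of output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doseresponse import LL4Params, ll4
from .phenotypes import CYP1A_TISSUES

__all__ = [
    "ScreenSimConfig",
    "Condition",
    "ExpressionSimConfig",
    "BurdenSimConfig",
    "generate_phenotype_screen",
    "generate_expression_study",
    "generate_body_burden",
    "default_screen_config",
    "default_expression_config",
    "default_burden_config",
]

# stream-kind tags keeping the per-entity substreams disjoint
_SCREEN, _GENE, _SAMPLE, _CHEM = 11, 12, 13, 14

#: day/batch effect hits this fraction of genes in day-2 samples
DAY_EFFECT_FRACTION = 0.05


def _rng(seed: int, kind: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), kind, int(index)]))


# ---------------------------------------------------------------------------
# phenotype screen


@dataclass
class ScreenSimConfig:
    """Configuration of a synthetic developmental-toxicity screen.

    ``bin_templates`` is a list (one entry per planted bin) of dicts mapping
    endpoint name to an :class:`~pahtox.doseresponse.LL4Params` potency
    curve or ``None`` for an inactive endpoint.  ``cyp1a_flags`` gives the
    per-bin tissue-localization booleans.
    """

    n_chemicals: int
    bin_templates: list
    concentrations: tuple
    cyp1a_flags: list
    n_per_conc: int = 32
    background_rate: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_chemicals < 1:
            raise ValueError("n_chemicals must be >= 1")
        if not self.bin_templates:
            raise ValueError("bin_templates must be non-empty")
        conc = np.asarray(self.concentrations, dtype=float)
        if len(conc) == 0 or np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
            raise ValueError(
                "concentrations must be strictly positive and strictly increasing"
            )
        if not 0 <= self.background_rate < 1:
            raise ValueError("background_rate must satisfy 0 <= rate < 1")
        if self.n_per_conc < 1:
            raise ValueError("n_per_conc must be >= 1")
        if len(self.cyp1a_flags) != len(self.bin_templates):
            raise ValueError("cyp1a_flags must have one entry per bin template")


def generate_phenotype_screen(config: ScreenSimConfig):
    """Simulate the incidence table of a screen with planted bin structure.

    Chemicals are assigned to bin templates round-robin.  Returns
    (incidence DataFrame with columns chemical/endpoint/conc_uM/n_affected/
    n_total, truth DataFrame with the planted bin per chemical, Cyp1a flag
    DataFrame with one 0/1 column per tissue).
    """
    config.validate()
    n_bins = len(config.bin_templates)
    endpoints = sorted(config.bin_templates[0])
    for t in config.bin_templates[1:]:
        if sorted(t) != endpoints:
            raise ValueError("all bin_templates must share one endpoint set")
    records = []
    truth = []
    flag_rows = []
    for i in range(config.n_chemicals):
        chem = f"chem_{i:03d}"
        b = i % n_bins
        template = config.bin_templates[b]
        rng = _rng(config.seed, _SCREEN, i)
        truth.append({"chemical": chem, "bin": b + 1})
        flags = config.cyp1a_flags[b]
        flag_rows.append(
            {"chemical": chem, **{t: int(bool(flags.get(t, False))) for t in CYP1A_TISSUES}}
        )
        for ep in endpoints:
            curve = template[ep]
            # vehicle control row at dose 0
            records.append(
                {
                    "chemical": chem,
                    "endpoint": ep,
                    "conc_uM": 0.0,
                    "n_affected": int(
                        rng.binomial(config.n_per_conc, config.background_rate)
                    ),
                    "n_total": config.n_per_conc,
                }
            )
            for dose in config.concentrations:
                if curve is None:
                    prob = config.background_rate
                else:
                    prob = float(
                        np.clip(ll4(dose, curve), config.background_rate, 1.0)
                    )
                records.append(
                    {
                        "chemical": chem,
                        "endpoint": ep,
                        "conc_uM": float(dose),
                        "n_affected": int(rng.binomial(config.n_per_conc, prob)),
                        "n_total": config.n_per_conc,
                    }
                )
    incidence = pd.DataFrame.from_records(records)
    return incidence, pd.DataFrame(truth), pd.DataFrame(flag_rows)


def default_screen_config(n_chemicals: int = 64, seed: int = 0) -> ScreenSimConfig:
    """Eight well-separated bin templates over the screen's 0.1-50 µM range.

    Templates follow the hazard ladder of the screen design: bin 1 is
    broadly and potently active (morphology + behavior + Cyp1a), bins 2-3
    morphologically active with decreasing breadth, bins 4-7 behavioral
    only, bin 8 inactive.  Steep slopes (b = -6) keep the per-endpoint LELs
    sharply defined at desk-scale replication, and the default background
    rate is 0 (clean-plate idealization): with any nonzero spontaneous
    rate, exact-test false LEL calls at the lowest doses inject severity
    outliers that swamp the between-template separation this config is
    meant to plant.  Nonzero background rates are fully supported and are
    exercised by the LEL test suite.
    """

    def curve(e: float) -> LL4Params:
        return LL4Params(b=-6.0, c=0.0, d=1.0, e=e)

    endpoints = [
        "mortality",
        "body_axis",
        "pericardial_edema",
        "caudal_fin",
        "epr",
        "lpr_dark",
        "lpr_light",
    ]

    def template(active: dict) -> dict:
        return {ep: active.get(ep) for ep in endpoints}

    templates = [
        template(
            {
                "mortality": curve(1.0),
                "body_axis": curve(1.0),
                "pericardial_edema": curve(1.0),
                "epr": curve(1.0),
                "lpr_dark": curve(1.0),
                "lpr_light": curve(1.0),
            }
        ),
        template(
            {
                "body_axis": curve(5.0),
                "pericardial_edema": curve(5.0),
                "caudal_fin": curve(5.0),
                "lpr_dark": curve(1.0),
                "lpr_light": curve(1.0),
            }
        ),
        template({"body_axis": curve(5.0), "pericardial_edema": curve(11.2)}),
        template({"lpr_dark": curve(5.0), "lpr_light": curve(5.0)}),
        template({"epr": curve(5.0), "lpr_dark": curve(11.2), "lpr_light": curve(11.2)}),
        template({"lpr_dark": curve(11.2), "lpr_light": curve(11.2)}),
        template({"lpr_light": curve(11.2)}),
        template({}),
    ]
    flags = [
        {"vasculature": True, "liver": True, "skin": True, "neuromasts": True},
        {"vasculature": True, "skin": True},
        {"vasculature": True},
        {"vasculature": True, "liver": True},
        {"liver": True},
        {},
        {},
        {},
    ]
    return ScreenSimConfig(
        n_chemicals=n_chemicals,
        bin_templates=templates,
        concentrations=(0.1, 1.0, 5.0, 11.2, 50.0),
        cyp1a_flags=flags,
        n_per_conc=32,
        background_rate=0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# expression study


@dataclass(frozen=True)
class Condition:
    """One experimental condition: a treatment or a vehicle control."""

    name: str
    day: int
    cluster: str | None = None  # "A"/"B" for treatments, None for controls
    is_control: bool = False


@dataclass
class ExpressionSimConfig:
    n_genes: int
    conditions: list
    n_replicates: int = 4
    battery_size: int = 100
    battery_log2fc: float = 2.0
    private_degs_per_treatment: int = 20
    dispersion_shape: float = 2.0
    libsize_sigma: float = 0.15
    day_effect_log2fc: float = 0.5
    marker_gene: str = "cyp1a"
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.battery_size < 1:
            raise ValueError("battery_size must be >= 1")
        controls = [c for c in self.conditions if c.is_control]
        if len(controls) != 2 or {c.day for c in controls} != {1, 2}:
            raise ValueError("need exactly 2 control conditions, one per day")
        treatments = [c for c in self.conditions if not c.is_control]
        planted = self.battery_size + len(treatments) * self.private_degs_per_treatment
        if planted > self.n_genes:
            raise ValueError(
                f"battery ({self.battery_size}) plus private DEGs "
                f"({len(treatments)} x {self.private_degs_per_treatment}) "
                f"exceed n_genes ({self.n_genes})"
            )


#: The study's 16 treatments with their transcriptomic cluster membership.
_DEFAULT_TREATMENTS = [
    ("retene", "B"),
    ("BkF", "B"),
    ("BjF", "B"),
    ("DB(a,i)P", "B"),
    ("DB(a,h)P", "B"),
    ("BbF", "B"),
    ("4h-CPdefP", "A"),
    ("3-NF", "A"),
    ("carbazole", "A"),
    ("9-MA", "A"),
    ("fluoranthene", "A"),
    ("1,5-DMN", "A"),
    ("acenaphthene", "A"),
    ("2-MN", "A"),
    ("phenanthrene", "A"),
    ("anthracene", "A"),
]


def default_expression_config(n_genes: int = 2000, seed: int = 0) -> ExpressionSimConfig:
    """16 treatments (6 B-like) + 2 day-matched controls, 4 replicates each.

    Collection days are assigned round-robin over the treatment list (the
    actual day split is not public); the assignment is recorded in the
    returned metadata.
    """
    conditions = [
        Condition(name=name, day=(i % 2) + 1, cluster=cluster)
        for i, (name, cluster) in enumerate(_DEFAULT_TREATMENTS)
    ]
    conditions.append(Condition(name="control_d1", day=1, is_control=True))
    conditions.append(Condition(name="control_d2", day=2, is_control=True))
    return ExpressionSimConfig(n_genes=n_genes, conditions=conditions, seed=seed)


def generate_expression_study(config: ExpressionSimConfig):
    """Simulate NB counts with planted battery/private/day structure.

    Gene g in sample s is NegativeBinomial with
    mean = baseline_g * libsize_s * 2^(battery fc if g in battery and the
    sample's treatment is B-like) * 2^(signed private fc if g is private to
    the treatment) * 2^(day effect if g is a day gene and the sample was
    collected on day 2), and variance mean + dispersion_g * mean^2.

    Returns (counts genes x samples DataFrame, metadata DataFrame, truth
    dict with battery genes, marker gene, per-treatment private DEGs and
    directions, true cluster labels, day-shifted genes and day assignment).
    """
    config.validate()
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    battery = genes[: config.battery_size]
    if config.marker_gene:
        genes[0] = config.marker_gene
        battery[0] = config.marker_gene
    treatments = [c for c in config.conditions if not c.is_control]
    private: dict = {}
    private_dir: dict = {}
    cursor = config.battery_size
    for t in treatments:
        private[t.name] = genes[cursor : cursor + config.private_degs_per_treatment]
        cursor += config.private_degs_per_treatment

    # per-sample library sizes
    meta_rows = []
    libsizes = []
    s_idx = 0
    for cond in config.conditions:
        for rep in range(1, config.n_replicates + 1):
            sid = f"{cond.name}_r{rep}"
            meta_rows.append(
                {
                    "sample_id": sid,
                    "treatment": cond.name,
                    "day": cond.day,
                    "replicate": rep,
                    "is_control": cond.is_control,
                }
            )
            libsizes.append(
                float(_rng(config.seed, _SAMPLE, s_idx).lognormal(0.0, config.libsize_sigma))
            )
            s_idx += 1
    meta = pd.DataFrame(meta_rows)
    libsizes = np.asarray(libsizes)
    days = meta["day"].to_numpy()
    cond_of_sample = meta["treatment"].to_numpy()
    cluster_of = {t.name: t.cluster for t in treatments}
    battery_set = set(battery)
    private_of_gene = {g: t for t, gs in private.items() for g in gs}

    counts = np.zeros((config.n_genes, len(meta)), dtype=np.int64)
    day_genes = []
    for gi, g in enumerate(genes):
        rng = _rng(config.seed, _GENE, gi)
        planted = g in battery_set or g in private_of_gene
        if planted:
            # xenobiotic-response inductions are measured on robustly
            # expressed genes; model them as such
            baseline = rng.lognormal(math.log(500.0), 0.5)
        else:
            baseline = rng.lognormal(math.log(100.0), 1.2)
        # dispersion follows the usual mean-dependent trend (asymptotic
        # component plus a 1/mean term) with gene-wise gamma scatter
        disp_trend = 0.005 + 2.0 / baseline
        dispersion = disp_trend * rng.gamma(
            2.0 * config.dispersion_shape, 0.5 / config.dispersion_shape
        )
        is_day_gene = bool(rng.random() < DAY_EFFECT_FRACTION)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if g in private_of_gene:
            private_dir[g] = "elevated" if sign > 0 else "reduced"
        if is_day_gene:
            day_genes.append(g)
        log2_effect = np.zeros(len(meta))
        if g in battery_set:
            in_b = np.array(
                [cluster_of.get(c) == "B" for c in cond_of_sample], dtype=bool
            )
            log2_effect += np.where(in_b, config.battery_log2fc, 0.0)
        if g in private_of_gene and config.private_degs_per_treatment > 0:
            own = cond_of_sample == private_of_gene[g]
            log2_effect += np.where(own, sign * config.battery_log2fc, 0.0)
        if is_day_gene:
            log2_effect += np.where(days == 2, config.day_effect_log2fc, 0.0)
        mu = baseline * libsizes * np.exp2(log2_effect)
        n_param = 1.0 / max(dispersion, 1e-8)
        counts[gi] = rng.negative_binomial(n_param, n_param / (n_param + mu))

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=meta["sample_id"])
    truth = {
        "battery_genes": list(battery),
        "marker_gene": config.marker_gene,
        "private_degs": {t.name: list(private[t.name]) for t in treatments},
        "private_directions": dict(private_dir),
        "clusters": {t.name: t.cluster for t in treatments},
        "controls": [c.name for c in config.conditions if c.is_control],
        "day_assignment": {c.name: c.day for c in config.conditions},
        "day_genes": day_genes,
    }
    if config.battery_log2fc == 0:
        truth["battery_genes"] = []
    if config.private_degs_per_treatment == 0:
        truth["private_degs"] = {t.name: [] for t in treatments}
    return counts_df, meta, truth


# ---------------------------------------------------------------------------
# body burden


@dataclass
class BurdenSimConfig:
    """Replicated CUR measurements around per-chemical true ratios."""

    true_cur: dict  # chemical -> positive ratio
    log_kow: dict  # chemical -> log Kow
    concentrations: tuple = (5.39, 11.6, 25.0)
    n_reps: int = 3
    noise_sigma: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if not self.true_cur:
            raise ValueError("true_cur must be non-empty")
        for chem, cur in self.true_cur.items():
            if cur <= 0:
                raise ValueError(f"true_cur must be positive, got {cur} for {chem}")
        if set(self.log_kow) != set(self.true_cur):
            raise ValueError("log_kow must cover exactly the chemicals in true_cur")
        if len(self.concentrations) < 1 or self.n_reps < 1:
            raise ValueError("need at least one concentration and one replicate")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def generate_body_burden(config: BurdenSimConfig) -> pd.DataFrame:
    """One CUR draw per chemical x nominal concentration x replicate.

    cur = true_cur * lognormal(0, noise_sigma); measured embryo
    concentration is back-computed as nominal / cur.
    """
    config.validate()
    rows = []
    for ci, chem in enumerate(sorted(config.true_cur)):
        rng = _rng(config.seed, _CHEM, ci)
        for conc in config.concentrations:
            for rep in range(1, config.n_reps + 1):
                cur = config.true_cur[chem] * float(
                    rng.lognormal(0.0, config.noise_sigma)
                )
                rows.append(
                    {
                        "chemical": chem,
                        "nominal_conc": float(conc),
                        "replicate": rep,
                        "measured": float(conc) / cur,
                        "cur": cur,
                        "log_kow": float(config.log_kow[chem]),
                    }
                )
    return pd.DataFrame(rows)


def default_burden_config(seed: int = 0) -> BurdenSimConfig:
    """Six chemicals spanning the log Kow range around the 5.5 cutoff.

    Four low-Kow chemicals form the correlating set; the two high-Kow ones
    (retene, BbF) are present to exercise the hydrophobicity filter.  True
    CURs sit in a realistic 1-5 range; log Kow values are the compounds'
    literature octanol-water coefficients.
    """
    return BurdenSimConfig(
        true_cur={
            "fluoranthene": 1.2,
            "acenaphthene": 2.0,
            "2-MN": 3.0,
            "phenanthrene": 5.0,
            "retene": 2.5,
            "BbF": 1.8,
        },
        log_kow={
            "fluoranthene": 5.16,
            "acenaphthene": 3.92,
            "2-MN": 3.86,
            "phenanthrene": 4.46,
            "retene": 6.35,
            "BbF": 6.11,
        },
        seed=seed,
    )
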