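"""Synthetic prostate-cancer cohort generator.

Emulates the statistical structure of a large real-world tumor-registry
cohort so the whole classification/survival/enrichment pipeline can be
exercised at desk scale: per-class alteration prevalences back-filled
from the published aggregate rates, race- and site-conditional mixes,
class-conditional molecular feature probabilities, proportional-hazards
Weibull survival with per-class log-hazards encoding the published
forest-plot effects, and an insurance-claims event stream in which true
deaths manifest as claim gaps exceeding the 100-day inference rule.

The generator also retains a ground-truth table (true class, true death
day, generating log-hazard) so recovery tests can compare pipeline output
against the generating values.  Everything is deterministic given
(config, seed).  Dates are integer day offsets from study start.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .classifier import DomainModel, FoxA1Class

_AAS = "ACDEFGHIKLMNPQRSTVWY"

#: approximate per-class prevalences consistent with a 16% overall
#: alteration rate; the within-class split is approximate (config, not a
#: fidelity claim).
DEFAULT_CLASS_PREVALENCE = {
    "1A": 0.020,
    "1B": 0.070,
    "1C": 0.018,
    "2": 0.005,
    "3A": 0.017,
    "3B": 0.011,
    "4": 0.018,
}

DEFAULT_RACE_MIX = {"EA": 0.747, "AF": 0.173, "AP": 0.0301, "other": 0.0499}

#: per-race overrides of class prevalences (AP enriched for 1B and 3A,
#: AF for 1C).
DEFAULT_RACE_CLASS_TILTS = {
    "AP": {"1B": 0.175, "3A": 0.032},
    "AF": {"1C": 0.032},
}

#: generating hazard ratios vs WT (all-tumors forest values where
#: published; modest non-null placeholders elsewhere).
DEFAULT_HAZARD_RATIOS = {
    "1A": 0.85,
    "1B": 0.90,
    "1C": 1.10,
    "2": 2.05,
    "3A": 0.70,
    "3B": 1.50,
    "4": 1.15,
}

DEFAULT_ERG_FUSION_P = {
    "WT": 0.345, "1A": 0.30, "1B": 0.005, "1C": 0.30,
    "2": 0.005, "3A": 0.20, "3B": 0.20, "4": 0.30,
}
DEFAULT_TP53_P = {
    "WT": 0.358, "1A": 0.358, "1B": 0.204, "1C": 0.358,
    "2": 0.358, "3A": 0.358, "3B": 0.358, "4": 0.358,
}
DEFAULT_MSI_HIGH_P = {
    "WT": 0.033, "1A": 0.033, "1B": 0.033, "1C": 0.131,
    "2": 0.033, "3A": 0.033, "3B": 0.155, "4": 0.033,
}
DEFAULT_TMB_HIGH_P = {
    "WT": 0.034, "1A": 0.034, "1B": 0.034, "1C": 0.121,
    "2": 0.034, "3A": 0.034, "3B": 0.190, "4": 0.034,
}
DEFAULT_NEPC_P = {"2": 0.333}

#: additive shifts of FOXA1 log2(TPM+1) per class (activating classes up).
DEFAULT_FOXA1_LOG2_SHIFT = {
    "1A": 0.6, "1B": 0.6, "1C": 0.0, "2": 0.2, "3A": 0.5, "3B": 0.5, "4": 0.9,
}

#: small expression panel: the target gene, AR, and four editable
#: signature sets plus inert filler genes.
DEFAULT_SIGNATURES = {
    "AR": ["KLK3", "KLK2", "NKX3-1", "TMPRSS2"],
    "NEPC": ["SYP", "CHGA", "ENO2", "NCAM1"],
    "IFNG": ["STAT1", "CXCL9", "CXCL10", "IDO1"],
    "T_cell_inflammation": ["CD8A", "GZMB", "PRF1", "CCL5"],
}

_ADT_DRUGS = ["leuprolide", "goserelin", "triptorelin", "degarelix", "relugolix"]
_ARSI_DRUGS = ["enzalutamide", "abiraterone", "apalutamide", "darolutamide"]
_TAXANE_DRUGS = ["docetaxel", "cabazitaxel"]


@dataclass
class GeneratorConfig:
    """All the knobs of the synthetic cohort, with study defaults."""

    n_patients: int = 5014
    class_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PREVALENCE))
    race_mix: dict = field(default_factory=lambda: dict(DEFAULT_RACE_MIX))
    race_class_tilts: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_RACE_CLASS_TILTS.items()}
    )
    metastatic_site_p: float = 0.397
    # survival process
    weibull_shape: float = 1.2
    wt_median_days: float = 1096.0  # ~36 months
    hazard_ratios: dict = field(default_factory=lambda: dict(DEFAULT_HAZARD_RATIOS))
    enrollment_window_days: int = 730
    data_cutoff_day: int = 4380  # 12 years of claims history
    # claims process
    claim_gap_mean_days: float = 30.0
    ltfu_prob: float = 0.02
    # treatment process
    p_first_line_adt: float = 0.85
    p_arsi: float = 0.50
    arsi_delay_mean_days: float = 300.0
    p_taxane: float = 0.30
    taxane_delay_mean_days: float = 600.0
    # molecular features
    erg_fusion_p: dict = field(default_factory=lambda: dict(DEFAULT_ERG_FUSION_P))
    tp53_p: dict = field(default_factory=lambda: dict(DEFAULT_TP53_P))
    msi_high_p: dict = field(default_factory=lambda: dict(DEFAULT_MSI_HIGH_P))
    tmb_high_p: dict = field(default_factory=lambda: dict(DEFAULT_TMB_HIGH_P))
    nepc_p: dict = field(default_factory=lambda: dict(DEFAULT_NEPC_P))
    vus_decoy_p: float = 0.05
    # expression
    include_expression: bool = True
    foxa1_log2_shift: dict = field(default_factory=lambda: dict(DEFAULT_FOXA1_LOG2_SHIFT))
    n_filler_genes: int = 12
    domain: DomainModel = field(default_factory=DomainModel)

    def validate(self) -> None:
        prev = sum(self.class_prevalence.values())
        if prev >= 1 or any(p < 0 for p in self.class_prevalence.values()):
            raise ValueError("class prevalences must be non-negative and sum to < 1")
        for race, tilts in self.race_class_tilts.items():
            base = dict(self.class_prevalence)
            base.update(tilts)
            if sum(base.values()) >= 1:
                raise ValueError(f"tilted prevalences for race {race!r} sum to >= 1")
        if any(hr <= 0 for hr in self.hazard_ratios.values()):
            raise ValueError("hazard ratios must be positive")
        for name in ("erg_fusion_p", "tp53_p", "msi_high_p", "tmb_high_p"):
            if any(not 0 <= p <= 1 for p in getattr(self, name).values()):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.metastatic_site_p < 1:
            raise ValueError("metastatic_site_p must lie in (0, 1)")

    def null(self) -> "GeneratorConfig":
        """A copy with no class effects: shared hazard, WT feature rates."""
        cfg = dataclasses.replace(
            self,
            hazard_ratios={k: 1.0 for k in self.hazard_ratios},
            race_class_tilts={},
            erg_fusion_p={k: self.erg_fusion_p["WT"] for k in self.erg_fusion_p},
            tp53_p={k: self.tp53_p["WT"] for k in self.tp53_p},
            msi_high_p={k: self.msi_high_p["WT"] for k in self.msi_high_p},
            tmb_high_p={k: self.tmb_high_p["WT"] for k in self.tmb_high_p},
            nepc_p={},
            foxa1_log2_shift={k: 0.0 for k in self.foxa1_log2_shift},
        )
        return cfg


@dataclass
class SyntheticCohort:
    """Generated tables in the same dialects the analysis modules read."""

    variants: pd.DataFrame
    copy_number: pd.DataFrame
    claims: pd.DataFrame
    features: pd.DataFrame
    expression: Optional[pd.DataFrame]
    ground_truth: pd.DataFrame
    config: GeneratorConfig
    seed: int

    def to_dir(self, path) -> None:
        """Write every table as TSV (expression wide, samples x genes)."""
        import pathlib

        p = pathlib.Path(path)
        p.mkdir(parents=True, exist_ok=True)
        self.variants.to_csv(p / "variants.tsv", sep="\t", index=False)
        self.copy_number.to_csv(p / "copy_number.tsv", sep="\t", index=False)
        self.claims.to_csv(p / "claims.tsv", sep="\t", index=False)
        self.features.to_csv(p / "features.tsv", sep="\t", index=False)
        if self.expression is not None:
            self.expression.to_csv(p / "expression.tsv", sep="\t", index_label="sample_id")
        self.ground_truth.to_csv(p / "ground_truth.tsv", sep="\t", index=False)
        (p / "metadata.txt").write_text(f"seed\t{self.seed}\n")


def _class_regions(d: DomainModel) -> dict[str, list[tuple[int, int]]]:
    return {
        "1A": [(d.fkh_start, d.wing2_start - 1)],
        "1B": [(d.wing2_start, d.fkh_end)],
        "1C": [(1, d.fkh_start - 1), (d.fkh_end + 1, d.protein_length)],
        "3A": [(2, d.fkh_end)],
        "3B": [(d.fkh_end + 1, d.protein_length - 1)],
    }


def _draw_residue(regions, rng) -> int:
    lens = np.array([hi - lo + 1 for lo, hi in regions], dtype=float)
    lo, hi = regions[rng.choice(len(regions), p=lens / lens.sum())]
    return int(rng.integers(lo, hi + 1))


def _synth_variant(label: str, d: DomainModel, rng) -> tuple[str, str]:
    """One (hgvs_p, effect) pair guaranteed to classify to ``label``."""
    regions = _class_regions(d)
    if label == "2":
        alt = rng.choice(sorted(d.class2_alt_residues))
        return f"p.R{d.class2_residue}{alt}", "missense"
    if label in ("1A", "1B", "1C"):
        pos = _draw_residue(regions[label], rng)
        u = rng.random()
        ref = _AAS[rng.integers(0, 20)]
        if u < 0.78:  # missense
            alt = _AAS[rng.integers(0, 20)]
            while alt == ref or (
                pos == d.class2_residue and alt in d.class2_alt_residues
            ):
                alt = _AAS[rng.integers(0, 20)]
            return f"p.{ref}{pos}{alt}", "missense"
        if u < 0.93:  # in-frame deletion of 1-3 residues
            span = int(rng.integers(1, 4))
            end = min(pos + span - 1, d.protein_length)
            if end == pos:
                return f"p.{ref}{pos}del", "inframe_deletion"
            ref2 = _AAS[rng.integers(0, 20)]
            return f"p.{ref}{pos}_{ref2}{end}del", "inframe_deletion"
        ins = "".join(_AAS[i] for i in rng.integers(0, 20, size=int(rng.integers(1, 3))))
        end = min(pos + 1, d.protein_length)
        ref2 = _AAS[rng.integers(0, 20)]
        return f"p.{ref}{pos}_{ref2}{end}ins{ins}", "inframe_insertion"
    if label in ("3A", "3B"):
        pos = _draw_residue(regions[label], rng)
        ref = _AAS[rng.integers(0, 20)]
        if rng.random() < 0.5:
            return f"p.{ref}{pos}*", "nonsense"
        alt = _AAS[rng.integers(0, 20)]
        return f"p.{ref}{pos}{alt}fs*{int(rng.integers(2, 40))}", "frameshift"
    raise ValueError(f"no sequence variant for class {label!r}")


def generate_cohort(config: GeneratorConfig, seed: int) -> SyntheticCohort:
    """Generate one cohort; deterministic given (config, seed)."""
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_patients
    d = config.domain
    pids = np.array([f"P{i:05d}" for i in range(1, n + 1)])

    # race, then class conditional on race
    races = list(config.race_mix)
    race_p = np.array([config.race_mix[r] for r in races], dtype=float)
    race = rng.choice(races, size=n, p=race_p / race_p.sum())
    class_labels = np.empty(n, dtype=object)
    all_classes = list(config.class_prevalence)
    for r in races:
        mask = race == r
        prev = dict(config.class_prevalence)
        prev.update(config.race_class_tilts.get(r, {}))
        probs = np.array([prev[c] for c in all_classes] + [1 - sum(prev.values())])
        class_labels[mask] = rng.choice(
            all_classes + ["WT"], size=int(mask.sum()), p=probs
        )

    site = np.where(rng.random(n) < config.metastatic_site_p, "metastatic", "prostate")

    # sequence variants + copy number
    var_rows, cn_rows = [], []
    for i in range(n):
        lab = class_labels[i]
        if lab == "4":
            cn_rows.append((pids[i], "FOXA1", float(6 + rng.integers(0, 15))))
        elif lab != "WT":
            hgvs, eff = _synth_variant(lab, d, rng)
            a, b = (3.5, 6.0) if site[i] == "metastatic" else (2.2, 6.5)
            patho = "pathogenic" if rng.random() < 0.6 else "likely_pathogenic"
            var_rows.append(
                (pids[i], "FOXA1", hgvs, eff, patho, round(float(rng.beta(a, b)), 4))
            )
        if rng.random() < config.vus_decoy_p:
            pos = int(rng.integers(1, d.protein_length + 1))
            ref = _AAS[rng.integers(0, 20)]
            alt = _AAS[rng.integers(0, 20)]
            if alt == ref:
                alt = "A" if ref != "A" else "G"
            var_rows.append(
                (pids[i], "FOXA1", f"p.{ref}{pos}{alt}", "missense", "VUS",
                 round(float(rng.beta(2, 8)), 4))
            )
    variants = pd.DataFrame(
        var_rows,
        columns=["sample_id", "gene", "hgvs_p", "effect", "pathogenicity", "vaf"],
    )
    copy_number = pd.DataFrame(cn_rows, columns=["sample_id", "gene", "copies"])

    # survival + claims
    shape = config.weibull_shape
    scale = config.wt_median_days / (np.log(2.0)) ** (1.0 / shape)
    log_hr = np.array(
        [0.0 if c == "WT" else np.log(config.hazard_ratios[c]) for c in class_labels]
    )
    enroll = rng.integers(0, config.enrollment_window_days, size=n)
    u = rng.random(n)
    death_from_index = scale * (-np.log(u) / np.exp(log_hr)) ** (1.0 / shape)
    death_day = enroll + death_from_index
    cutoff = config.data_cutoff_day
    is_ltfu = rng.random(n) < config.ltfu_prob

    claim_rows = []
    gt_rows = []
    p_gap = 1.0 / config.claim_gap_mean_days
    for i in range(n):
        e = int(enroll[i])
        # treatment plan
        treatments = []
        if rng.random() < config.p_first_line_adt:
            treatments.append((e, str(rng.choice(_ADT_DRUGS)), "first_line_ADT"))
            if rng.random() < config.p_arsi:
                day = e + int(rng.exponential(config.arsi_delay_mean_days)) + 1
                treatments.append((day, str(rng.choice(_ARSI_DRUGS)), "second_gen_ARSI"))
            if rng.random() < config.p_taxane:
                day = e + int(rng.exponential(config.taxane_delay_mean_days)) + 1
                treatments.append((day, str(rng.choice(_TAXANE_DRUGS)), "taxane"))
        else:
            drug, cat = (
                (str(rng.choice(_ARSI_DRUGS)), "second_gen_ARSI")
                if rng.random() < 0.6
                else (str(rng.choice(_TAXANE_DRUGS)), "taxane")
            )
            treatments.append((e, drug, cat))
        ltfu_day = (
            e + 1 + rng.integers(0, max(int(min(death_day[i], cutoff) - e), 1))
            if is_ltfu[i]
            else np.inf
        )
        end = min(death_day[i], ltfu_day, cutoff)
        # claim stream: enrollment claim then geometric gaps until `end`
        gaps = rng.geometric(p_gap, size=max(int((end - e) * p_gap * 2) + 20, 20))
        days = e + np.concatenate([[0], np.cumsum(gaps)])
        days = days[days <= end]
        for day in days:
            claim_rows.append((pids[i], int(day), "claim", "", ""))
        for day, drug, cat in treatments:
            if day <= end:
                claim_rows.append((pids[i], int(day), "treatment_start", drug, cat))
        # true vital status at cutoff (loss to contact hides, not changes, it)
        died = death_day[i] <= cutoff
        gt_rows.append(
            (
                pids[i], class_labels[i], float(log_hr[i]), e,
                int(died), round(float(death_day[i]), 1) if died else np.nan,
            )
        )
    claims = pd.DataFrame(
        claim_rows, columns=["patient_id", "date", "kind", "drug", "drug_category"]
    ).sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)
    ground_truth = pd.DataFrame(
        gt_rows,
        columns=["sample_id", "true_class", "true_log_hr", "enroll_day",
                 "true_event", "true_death_day"],
    )

    # molecular / demographic features
    def per_class(p_map):
        return np.array([p_map.get(c, p_map.get("WT", 0.0)) for c in class_labels])

    erg = rng.random(n) < per_class(config.erg_fusion_p)
    tp53 = rng.random(n) < per_class(config.tp53_p)
    msi = rng.random(n) < per_class(config.msi_high_p)
    tmb_high = rng.random(n) < per_class(config.tmb_high_p)
    tmb_val = np.where(
        tmb_high,
        10.0 + rng.gamma(1.5, 6.0, size=n),
        np.minimum(rng.lognormal(np.log(2.5), 0.55, size=n), 9.9),
    )
    nepc = rng.random(n) < per_class({**{"WT": 0.02}, **config.nepc_p})
    features = pd.DataFrame(
        {
            "sample_id": pids,
            "biopsy_site": site,
            "histology": np.where(nepc, "NEPC", "adenocarcinoma"),
            "race": race,
            "tmb": np.round(tmb_val, 2),
            "msi_status": np.where(msi, "MSI-high", "MSS"),
            "erg_fusion": erg.astype(int),
            "tp53_mut": tp53.astype(int),
        }
    )

    expression = None
    if config.include_expression:
        genes = (
            ["FOXA1", "AR"]
            + [g for gs in DEFAULT_SIGNATURES.values() for g in gs]
            + [f"FILLER{i:03d}" for i in range(1, config.n_filler_genes + 1)]
        )
        base = rng.normal(5.0, 0.4, size=len(genes))
        logx = rng.normal(0.0, 0.8, size=(n, len(genes))) + base
        gi = {g: j for j, g in enumerate(genes)}
        logx[:, gi["FOXA1"]] += 1.0 + np.array(
            [config.foxa1_log2_shift.get(c, 0.0) for c in class_labels]
        )
        is_c2 = class_labels == "2"
        shift = config.foxa1_log2_shift
        if any(v != 0 for v in shift.values()):  # class effects enabled
            for g in DEFAULT_SIGNATURES["NEPC"]:
                logx[is_c2, gi[g]] += 1.5
            for g in DEFAULT_SIGNATURES["AR"] + ["AR"]:
                logx[is_c2, gi[g]] -= 1.0
            cold = np.isin(class_labels, ["1A", "1B"])
            for g in DEFAULT_SIGNATURES["IFNG"] + DEFAULT_SIGNATURES["T_cell_inflammation"]:
                logx[cold, gi[g]] -= 0.5
        expression = pd.DataFrame(
            np.round(np.maximum(2.0**logx - 1.0, 0.0), 3), index=pids, columns=genes
        )
        expression.index.name = "sample_id"

    return SyntheticCohort(
        variants=variants,
        copy_number=copy_number,
        claims=claims,
        features=features,
        expression=expression,
        ground_truth=ground_truth,
        config=config,
        seed=seed,
    )


def generate_null_cohort(config: GeneratorConfig, seed: int) -> SyntheticCohort:
    """Cohort with no class effects (shared hazard, WT feature rates)."""
    return generate_cohort(config.null(), seed)
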