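"""Orchestration: simulate -> classify -> analyze as one reproducible run.

``run_pipeline`` takes the cohort tables (from files or the generator),
applies the classifier, derives claims-based survival records, fits every
class-vs-WT contrast overall / by biopsy site / by treatment category,
runs the molecular and race enrichment tests, summarises expression by
class, and emits tidy TSV tables plus a run manifest (config hash, seed,
input checksums) so identical inputs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Mapping, Optional

import pandas as pd

from . import __version__
from .associations import flag_tmb_high, race_distribution, test_feature_enrichment
from .classifier import ALTERED_CLASSES, classify_cohort
from .config import AnalysisConfig, dump_config
from .expression import compare_numeric_by_class, score_signatures
from .survival import build_survival_records, forest_table, km_coordinates

REQUIRED_COLUMNS = {
    "variants": ["sample_id", "gene", "hgvs_p", "pathogenicity"],
    "copy_number": ["sample_id", "gene", "copies"],
    "claims": ["patient_id", "date", "kind"],
    "features": ["sample_id"],
}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def validate_table(df: pd.DataFrame, kind: str, source: str = "<memory>") -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{source}: {kind} table is missing required column(s) {missing}"
        )
    return df


def read_table(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_table(df, kind, source=str(path))


@dataclass
class RunManifest:
    config_hash: str
    seed: Optional[int]
    input_checksums: dict
    version: str
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def _df_checksum(df: pd.DataFrame) -> str:
    return _sha256(df.to_csv(index=False))


def run_pipeline(
    tables: Mapping[str, pd.DataFrame],
    cfg: AnalysisConfig = AnalysisConfig(),
    *,
    seed: Optional[int] = None,
    out_dir=None,
) -> dict:
    """Run the full analysis over in-memory tables; optionally write TSVs.

    ``tables`` holds ``variants``, ``copy_number``, ``claims``,
    ``features`` and optionally ``expression`` (samples x genes TPM,
    sample ids as index).  Returns a dict of result DataFrames plus the
    manifest.
    """
    for kind in ("variants", "copy_number", "claims", "features"):
        validate_table(tables[kind], kind)
    features = tables["features"].copy()
    sample_ids = features["sample_id"].astype(str).tolist()

    samples, alterations = classify_cohort(
        tables["variants"],
        tables["copy_number"],
        sample_ids=sample_ids,
        d=cfg.domain,
        include_vus=cfg.include_vus,
    )
    features = features.merge(samples, on="sample_id")
    class_order = [c.value for c in ALTERED_CLASSES]
    present = [c for c in class_order if (features["class"] == c).any()]

    labels = samples.rename(columns={"sample_id": "patient_id"})
    records = build_survival_records(
        labels, tables["claims"], "any",
        gap_days=cfg.gap_days, castration_window_days=cfg.castration_window_days,
    )
    site = features[["sample_id", "biopsy_site"]].rename(
        columns={"sample_id": "patient_id"}
    ) if "biopsy_site" in features else None
    if site is not None:
        records = records.merge(site, on="patient_id", how="left")
    forests = {"all_tumors": forest_table(records, present)}
    if site is not None:
        for s, grp in records.groupby("biopsy_site"):
            forests[f"site_{s}"] = forest_table(grp, present)
    for cat in ("first_line_ADT", "second_gen_ARSI", "taxane"):
        cat_records = build_survival_records(
            labels, tables["claims"], cat,
            gap_days=cfg.gap_days,
            castration_window_days=cfg.castration_window_days,
        )
        forests[f"treatment_{cat}"] = forest_table(cat_records, present)
    # class-vs-class contrasts against the hotspot class
    if "2" in present:
        forests["class2_reference"] = forest_table(
            records, [c for c in present if c != "2"], reference="2"
        )
    forest = pd.concat(
        [t.assign(analysis=name) for name, t in forests.items()], ignore_index=True
    )

    flags = features.copy()
    if "tmb" in flags:
        flags["tmb_high"] = flags["tmb"].map(
            lambda t: flag_tmb_high(t, cfg.tmb_high_threshold)
        )
    if "msi_status" in flags:
        flags["msi_high"] = flags["msi_status"] == "MSI-high"
    feature_cols = [
        c for c in ("erg_fusion", "tp53_mut", "msi_high", "tmb_high")
        if c in flags.columns
    ]
    associations = test_feature_enrichment(
        flags, feature_columns=feature_cols, classes=present,
        continuity=cfg.chi2_continuity,
    ) if feature_cols else pd.DataFrame()
    race_freq = race_tests = pd.DataFrame()
    if "race" in features:
        race_freq, race_tests = race_distribution(features)

    expr_summary = scores = pd.DataFrame()
    if tables.get("expression") is not None:
        expr = tables["expression"]
        cls = features.set_index("sample_id")["class"].reindex(expr.index.astype(str))
        if "FOXA1" in expr.columns:
            expr_summary = compare_numeric_by_class(expr["FOXA1"], cls)
        scores = score_signatures(expr, cfg.signatures)
        scores.insert(0, "class", cls.to_numpy())

    km = km_coordinates(records) if len(records) else pd.DataFrame()

    manifest = RunManifest(
        config_hash=_sha256(dump_config(cfg)),
        seed=seed,
        input_checksums={k: _df_checksum(v) for k, v in tables.items() if v is not None},
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    results = {
        "samples": samples,
        "alterations": alterations,
        "survival_records": records,
        "forest": forest,
        "associations": associations,
        "race_frequencies": race_freq,
        "race_tests": race_tests,
        "expression_summary": expr_summary,
        "signature_scores": scores,
        "km_coordinates": km,
        "manifest": manifest,
    }
    if out_dir is not None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, obj in results.items():
            if isinstance(obj, pd.DataFrame) and len(obj):
                obj.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        (out / "manifest.json").write_text(manifest.to_json())
    return results
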