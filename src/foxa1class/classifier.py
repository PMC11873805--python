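"""The structurally oriented FOXA1 alteration classification schema.

FOXA1's DNA-binding forkhead (FKH) domain spans residues 168-269, with the
flexible Wing2 region occupying its C-terminal part (247-269 in this
schema).  Alterations are partitioned into four classes and seven
subclasses relative to those boundaries:

* class 1 — missense / in-frame indels, split by position: 1A inside FKH
  but before Wing2 (168-246), 1B inside Wing2 (247-269), 1C outside FKH
  (1-167 and 270 onward);
* class 2 — the R219C and R219S hotspot missense mutations (a class of
  their own: enriched in neuroendocrine disease, worst prognosis);
* class 3 — predicted truncating events (nonsense/frameshift), split at
  the end of FKH: 3A truncates at or before residue 269, 3B at 270+;
* class 4 — gene amplification (>= 6 copies);
* WT — no qualifying alteration.

Only pathogenic and likely-pathogenic variants count as alterations;
benign, likely-benign and VUS calls are excluded (a flag retains VUS for
sensitivity analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .variants import (
    Effect,
    INFRAME_EFFECTS,
    TRUNCATING_EFFECTS,
    Pathogenicity,
    ProteinVariant,
)

#: Default FOXA1 protein length (UniProt P55317-1).
FOXA1_PROTEIN_LENGTH = 472


class FoxA1Class(str, Enum):
    """The eight sample/alteration labels of the classification."""

    WT = "WT"
    C1A = "1A"
    C1B = "1B"
    C1C = "1C"
    C2 = "2"
    C3A = "3A"
    C3B = "3B"
    C4 = "4"


#: All non-WT subclass labels.
ALTERED_CLASSES = (
    FoxA1Class.C1A,
    FoxA1Class.C1B,
    FoxA1Class.C1C,
    FoxA1Class.C2,
    FoxA1Class.C3A,
    FoxA1Class.C3B,
    FoxA1Class.C4,
)

#: Sample-level precedence: rarest / most prognostically extreme first.
DEFAULT_PRECEDENCE = (
    FoxA1Class.C2,
    FoxA1Class.C1B,
    FoxA1Class.C1A,
    FoxA1Class.C3A,
    FoxA1Class.C3B,
    FoxA1Class.C1C,
    FoxA1Class.C4,
    FoxA1Class.WT,
)


class ClassificationError(ValueError):
    """Raised for alterations the rule set cannot place."""


@dataclass(frozen=True)
class DomainModel:
    """Residue boundaries and thresholds driving the classification.

    Coordinates are 1-based inclusive.  Defaults encode the published
    schema for FOXA1; they are configurable so the same rule engine can be
    pointed at other boundary choices.
    """

    fkh_start: int = 168
    fkh_end: int = 269
    wing2_start: int = 247
    class2_residue: int = 219
    class2_alt_residues: frozenset[str] = frozenset({"C", "S"})
    protein_length: int = FOXA1_PROTEIN_LENGTH
    amplification_min_copies: float = 6
    #: classify in-frame indels by lowest affected residue ("anchor") or
    #: by any overlap with Wing2 ("overlap").
    indel_boundary_policy: str = "anchor"
    #: treat splice variants as truncating (class 3) or exclude them.
    splice_policy: str = "truncating"

    def __post_init__(self) -> None:
        if not (1 <= self.fkh_start < self.wing2_start <= self.fkh_end <= self.protein_length):
            raise ValueError(
                "domain boundaries must satisfy "
                "1 <= fkh_start < wing2_start <= fkh_end <= protein_length"
            )
        if not (self.fkh_start <= self.class2_residue <= self.fkh_end):
            raise ValueError("class2_residue must lie inside the FKH domain")
        if self.amplification_min_copies < 1:
            raise ValueError("amplification_min_copies must be >= 1")
        if self.indel_boundary_policy not in ("anchor", "overlap"):
            raise ValueError(f"unknown indel policy {self.indel_boundary_policy!r}")
        if self.splice_policy not in ("truncating", "exclude"):
            raise ValueError(f"unknown splice policy {self.splice_policy!r}")


@dataclass(frozen=True)
class CopyNumberCall:
    gene: str
    copies: float

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError(f"negative copy number {self.copies}")


#: Pathogenicity labels counted as mutations.
INCLUDED_PATHOGENICITY = frozenset(
    {Pathogenicity.PATHOGENIC, Pathogenicity.LIKELY_PATHOGENIC}
)


def filter_pathogenic(
    variants: Iterable[ProteinVariant],
    *,
    include_vus: bool = False,
    permissive_missing: bool = False,
) -> list[ProteinVariant]:
    """Keep pathogenic / likely-pathogenic variants (optionally VUS).

    A missing pathogenicity label raises unless ``permissive_missing`` is
    set, in which case the variant passes through.
    """
    included = set(INCLUDED_PATHOGENICITY)
    if include_vus:
        included.add(Pathogenicity.VUS)
    kept = []
    for v in variants:
        if v.pathogenicity is None:
            if permissive_missing:
                kept.append(v)
                continue
            raise ValueError(f"variant {v.hgvs_p!r} has no pathogenicity label")
        if v.pathogenicity in included:
            kept.append(v)
    return kept


def classify_variant(v: ProteinVariant, d: DomainModel = DomainModel()) -> FoxA1Class:
    """Assign one sequence alteration to its class.

    Rules, in order: (1) missense at the hotspot residue with a hotspot
    alternate amino acid -> class 2; (2) missense/in-frame events by
    anchor position -> 1A / 1B / 1C; (3) truncating events (nonsense,
    frameshift, and splice under the default policy) -> 3A at or before
    the FKH end, 3B after; (4) synonymous -> WT (not an alteration).
    """
    if v.end_aa > d.protein_length:
        raise ValueError(
            f"residue {v.end_aa} exceeds protein length {d.protein_length}"
        )
    e = v.effect
    if (
        e is Effect.MISSENSE
        and v.start_aa == d.class2_residue
        and v.alt_aa in d.class2_alt_residues
    ):
        return FoxA1Class.C2
    if e in INFRAME_EFFECTS:
        anchor = v.start_aa
        if d.indel_boundary_policy == "overlap" and e is not Effect.MISSENSE:
            # any overlap with Wing2 pulls the indel into 1B
            if v.start_aa <= d.fkh_end and v.end_aa >= d.wing2_start:
                return FoxA1Class.C1B
        if d.fkh_start <= anchor < d.wing2_start:
            return FoxA1Class.C1A
        if d.wing2_start <= anchor <= d.fkh_end:
            return FoxA1Class.C1B
        return FoxA1Class.C1C
    if e in TRUNCATING_EFFECTS or (
        e is Effect.SPLICE and d.splice_policy == "truncating"
    ):
        return FoxA1Class.C3A if v.start_aa <= d.fkh_end else FoxA1Class.C3B
    if e is Effect.SYNONYMOUS or (
        e is Effect.SPLICE and d.splice_policy == "exclude"
    ):
        return FoxA1Class.WT
    raise ClassificationError(
        f"no classification rule for effect {e.value!r} ({v.hgvs_p})"
    )


def classify_copy_number(
    c: CopyNumberCall, d: DomainModel = DomainModel()
) -> Optional[FoxA1Class]:
    """Class 4 iff the call reaches the amplification threshold, else None."""
    if c.copies < 0:
        raise ValueError(f"negative copy number {c.copies}")
    return FoxA1Class.C4 if c.copies >= d.amplification_min_copies else None


def classify_sample(
    variants: Sequence[ProteinVariant],
    cn_calls: Sequence[CopyNumberCall] = (),
    d: DomainModel = DomainModel(),
    *,
    precedence: Sequence[FoxA1Class] = DEFAULT_PRECEDENCE,
    include_vus: bool = False,
) -> tuple[FoxA1Class, list[FoxA1Class]]:
    """Label one sample: per-alteration labels plus a sample-level label.

    Variants are first passed through the pathogenicity filter.  The
    sample label is the highest-precedence label among the alteration
    labels; an empty input yields WT.
    """
    kept = filter_pathogenic(variants, include_vus=include_vus)
    labels = [classify_variant(v, d) for v in kept]
    for c in cn_calls:
        lab = classify_copy_number(c, d)
        if lab is not None:
            labels.append(lab)
    non_wt = [l for l in labels if l is not FoxA1Class.WT]
    if not non_wt:
        return FoxA1Class.WT, labels
    rank = {lab: i for i, lab in enumerate(precedence)}
    return min(non_wt, key=lambda l: rank.get(l, len(rank))), labels


def classify_truth_table(d: DomainModel = DomainModel()) -> pd.DataFrame:
    """Exhaustive (effect, residue, alt) -> class sweep.

    Enumerates every missense (all 19 alternates at the hotspot residue,
    one representative elsewhere), in-frame and truncating event at every
    residue and tabulates the assigned class.  Used as an oracle surface
    and to drive partition/boundary checks.
    """
    rows = []
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for pos in range(1, d.protein_length + 1):
        alts = aas if pos == d.class2_residue else "A"
        for alt in alts:
            ref = "G" if alt != "G" else "A"
            v = ProteinVariant("FOXA1", f"p.{ref}{pos}{alt}", Effect.MISSENSE, pos, pos, ref, alt)
            rows.append((Effect.MISSENSE.value, pos, alt, classify_variant(v, d).value))
        for eff in (Effect.INFRAME_DELETION, Effect.NONSENSE, Effect.FRAMESHIFT):
            v = ProteinVariant("FOXA1", f"p.X{pos}", eff, pos, pos, "A", "")
            rows.append((eff.value, pos, "", classify_variant(v, d).value))
    return pd.DataFrame(rows, columns=["effect", "residue", "alt_aa", "class"])


def classify_cohort(
    variants: pd.DataFrame,
    copy_number: Optional[pd.DataFrame] = None,
    *,
    sample_ids: Optional[Sequence[str]] = None,
    d: DomainModel = DomainModel(),
    include_vus: bool = False,
    precedence: Sequence[FoxA1Class] = DEFAULT_PRECEDENCE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify a whole cohort from MAF-like tables.

    ``variants`` needs columns ``sample_id``, ``hgvs_p``, ``pathogenicity``
    and optionally ``effect`` and ``vaf``; ``copy_number`` needs
    ``sample_id`` and ``copies``.  ``sample_ids`` lists every sample in
    the cohort (samples with no rows are WT); it defaults to the union of
    ids seen in the two tables.  Returns (per-sample labels, per-alteration
    labels) as DataFrames.
    """
    from .variants import parse_hgvs_p, parse_pathogenicity

    by_sample: dict[str, list[ProteinVariant]] = {}
    alt_rows = []
    for row in variants.itertuples(index=False):
        patho = parse_pathogenicity(str(row.pathogenicity))
        vaf = getattr(row, "vaf", None)
        vaf = None if vaf is None or pd.isna(vaf) else float(vaf)
        effect = getattr(row, "effect", None)
        if effect is not None and not pd.isna(effect) and str(effect) == "splice":
            v = ProteinVariant(
                gene=str(getattr(row, "gene", "FOXA1")),
                hgvs_p=str(row.hgvs_p),
                effect=Effect.SPLICE,
                start_aa=int(getattr(row, "start_aa", 1)),
                end_aa=int(getattr(row, "start_aa", 1)),
                pathogenicity=patho,
                vaf=vaf,
            )
        else:
            v = parse_hgvs_p(
                str(row.hgvs_p),
                gene=str(getattr(row, "gene", "FOXA1")),
                pathogenicity=patho,
                vaf=vaf,
                protein_length=d.protein_length,
            )
        by_sample.setdefault(str(row.sample_id), []).append(v)
    cn_by_sample: dict[str, list[CopyNumberCall]] = {}
    if copy_number is not None:
        for row in copy_number.itertuples(index=False):
            cn_by_sample.setdefault(str(row.sample_id), []).append(
                CopyNumberCall(str(getattr(row, "gene", "FOXA1")), float(row.copies))
            )
    if sample_ids is None:
        sample_ids = sorted(set(by_sample) | set(cn_by_sample))
    sample_rows = []
    for sid in sample_ids:
        sid = str(sid)
        vs = by_sample.get(sid, [])
        cns = cn_by_sample.get(sid, [])
        label, per_alt = classify_sample(
            vs, cns, d, precedence=precedence, include_vus=include_vus
        )
        sample_rows.append({"sample_id": sid, "class": label.value})
        kept = filter_pathogenic(vs, include_vus=include_vus)
        for v, l in zip(kept, per_alt[: len(kept)]):
            alt_rows.append(
                {"sample_id": sid, "hgvs_p": v.hgvs_p, "effect": v.effect.value,
                 "class": l.value}
            )
        for c in cns:
            l4 = classify_copy_number(c, d)
            if l4 is not None:
                alt_rows.append(
                    {"sample_id": sid, "hgvs_p": "", "effect": "amplification",
                     "class": l4.value}
                )
    samples_df = pd.DataFrame(sample_rows, columns=["sample_id", "class"])
    alts_df = pd.DataFrame(alt_rows, columns=["sample_id", "hgvs_p", "effect", "class"])
    return samples_df, alts_df


def residue_counts(
    variants: Iterable[ProteinVariant], d: DomainModel = DomainModel()
) -> pd.DataFrame:
    """Lollipop-ready per-residue counts: (residue, effect, class, count)."""
    rows = [
        (v.start_aa, v.effect.value, classify_variant(v, d).value)
        for v in variants
    ]
    df = pd.DataFrame(rows, columns=["residue", "effect", "class"])
    if df.empty:
        return pd.DataFrame(columns=["residue", "effect", "class", "count"])
    out = (
        df.value_counts(["residue", "effect", "class"])
        .rename("count")
        .reset_index()
        .sort_values(["residue", "effect"], kind="stable")
        .reset_index(drop=True)
    )
    return out
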