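import dataclasses

import pytest

from foxa1class import (
    CopyNumberCall,
    DomainModel,
    Effect,
    FoxA1Class,
    Pathogenicity,
    ProteinVariant,
    classify_copy_number,
    classify_sample,
    classify_variant,
    filter_pathogenic,
    parse_hgvs_p,
    residue_counts,
)
from foxa1class.classifier import ClassificationError, classify_truth_table


def mk(effect, start, end=None, alt="", ref="A", patho=Pathogenicity.PATHOGENIC):
    return ProteinVariant(
        "FOXA1", f"p.test{start}", effect, start, end or start, ref, alt,
        pathogenicity=patho,
    )


class TestClassifyVariant:
    @pytest.mark.parametrize("alt", ["C", "S"])
    def test_r219_hotspot_is_class_2(self, domain, alt):
        assert classify_variant(mk(Effect.MISSENSE, 219, alt=alt, ref="R"), domain) is FoxA1Class.C2

    def test_r219_other_substitution_is_class_1a(self, domain):
        assert classify_variant(mk(Effect.MISSENSE, 219, alt="H", ref="R"), domain) is FoxA1Class.C1A

    def test_r219_inframe_indel_is_not_class_2(self, domain):
        v = mk(Effect.INFRAME_DELETION, 219)
        assert classify_variant(v, domain) is FoxA1Class.C1A

    @pytest.mark.parametrize(
        "effect, pos, expected",
        [
            (Effect.MISSENSE, 50, FoxA1Class.C1C),
            (Effect.MISSENSE, 200, FoxA1Class.C1A),
            (Effect.INFRAME_DELETION, 250, FoxA1Class.C1B),
            (Effect.INFRAME_INSERTION, 300, FoxA1Class.C1C),
            (Effect.NONSENSE, 100, FoxA1Class.C3A),
            (Effect.FRAMESHIFT, 300, FoxA1Class.C3B),
            (Effect.NONSENSE, 269, FoxA1Class.C3A),
            (Effect.FRAMESHIFT, 270, FoxA1Class.C3B),
        ],
    )
    def test_positional_rules(self, domain, effect, pos, expected):
        assert classify_variant(mk(effect, pos, alt="V"), domain) is expected

    @pytest.mark.parametrize(
        "pos, expected",
        [
            (167, FoxA1Class.C1C), (168, FoxA1Class.C1A),
            (246, FoxA1Class.C1A), (247, FoxA1Class.C1B),
            (269, FoxA1Class.C1B), (270, FoxA1Class.C1C),
        ],
    )
    def test_missense_boundaries_are_exact(self, domain, pos, expected):
        assert classify_variant(mk(Effect.MISSENSE, pos, alt="V"), domain) is expected

    def test_synonymous_is_wt(self, domain):
        assert classify_variant(mk(Effect.SYNONYMOUS, 219, alt="A"), domain) is FoxA1Class.WT

    def test_splice_policies(self, domain):
        v = mk(Effect.SPLICE, 100)
        assert classify_variant(v, domain) is FoxA1Class.C3A
        excl = dataclasses.replace(domain, splice_policy="exclude")
        assert classify_variant(v, excl) is FoxA1Class.WT

    def test_effect_other_raises(self, domain):
        with pytest.raises(ClassificationError):
            classify_variant(mk(Effect.OTHER, 100), domain)

    def test_boundary_spanning_indel_policies(self, domain):
        # deletion 245-250 anchors at 245 -> 1A; overlap policy pulls to 1B
        v = mk(Effect.INFRAME_DELETION, 245, end=250)
        assert classify_variant(v, domain) is FoxA1Class.C1A
        overlap = dataclasses.replace(domain, indel_boundary_policy="overlap")
        assert classify_variant(v, overlap) is FoxA1Class.C1B


class TestCopyNumber:
    @pytest.mark.parametrize("copies, expected", [(6, FoxA1Class.C4), (20, FoxA1Class.C4),
                                                  (5.99, None), (5, None), (0, None)])
    def test_amplification_threshold(self, domain, copies, expected):
        assert classify_copy_number(CopyNumberCall("FOXA1", copies), domain) is expected

    def test_negative_copies_rejected(self):
        with pytest.raises(ValueError):
            CopyNumberCall("FOXA1", -1)


class TestPathogenicityFilter:
    def test_keeps_only_pathogenic_and_likely(self):
        vs = [
            mk(Effect.MISSENSE, 10, alt="V", patho=p)
            for p in (Pathogenicity.PATHOGENIC, Pathogenicity.VUS, Pathogenicity.BENIGN,
                      Pathogenicity.LIKELY_PATHOGENIC, Pathogenicity.LIKELY_BENIGN)
        ]
        kept = filter_pathogenic(vs)
        assert [v.pathogenicity for v in kept] == [
            Pathogenicity.PATHOGENIC, Pathogenicity.LIKELY_PATHOGENIC,
        ]

    def test_vus_opt_in(self):
        vs = [mk(Effect.MISSENSE, 10, alt="V", patho=Pathogenicity.VUS)]
        assert filter_pathogenic(vs) == []
        assert filter_pathogenic(vs, include_vus=True) == vs

    def test_empty_input(self):
        assert filter_pathogenic([]) == []

    def test_missing_label_raises_unless_permissive(self):
        vs = [mk(Effect.MISSENSE, 10, alt="V", patho=None)]
        with pytest.raises(ValueError):
            filter_pathogenic(vs)
        assert filter_pathogenic(vs, permissive_missing=True) == vs


class TestClassifySample:
    def test_hotspot_outranks_amplification(self, domain):
        label, per_alt = classify_sample(
            [mk(Effect.MISSENSE, 219, alt="S", ref="R")],
            [CopyNumberCall("FOXA1", 8)],
            domain,
        )
        assert label is FoxA1Class.C2
        assert set(per_alt) == {FoxA1Class.C2, FoxA1Class.C4}

    def test_empty_sample_is_wt(self, domain):
        label, per_alt = classify_sample([], [], domain)
        assert label is FoxA1Class.WT and per_alt == []

    def test_single_alteration(self, domain):
        label, _ = classify_sample([parse_hgvs_p("p.F254del", pathogenicity=Pathogenicity.PATHOGENIC)], [], domain)
        assert label is FoxA1Class.C1B

    def test_custom_precedence(self, domain):
        variants = [mk(Effect.MISSENSE, 219, alt="S", ref="R")]
        cn = [CopyNumberCall("FOXA1", 9)]
        label, _ = classify_sample(
            variants, cn, domain,
            precedence=(FoxA1Class.C4, FoxA1Class.C2, FoxA1Class.WT),
        )
        assert label is FoxA1Class.C4


def brute_force_class(effect: str, residue: int, alt: str) -> str:
    """Flat truth table over (effect, residue, alt) — independent oracle."""
    if effect == "missense" and residue == 219 and alt in ("C", "S"):
        return "2"
    if effect in ("missense", "inframe_deletion", "inframe_insertion", "inframe_delins"):
        if 168 <= residue <= 246:
            return "1A"
        if 247 <= residue <= 269:
            return "1B"
        return "1C"
    if effect in ("nonsense", "frameshift"):
        return "3A" if residue <= 269 else "3B"
    raise AssertionError(effect)


class TestPartitionProperties:
    def test_truth_table_oracle_equivalence(self, domain):
        """Rule-ordered classifier == flat truth table on the full sweep."""
        sweep = classify_truth_table(domain)
        expected = [
            brute_force_class(e, r, a)
            for e, r, a in zip(sweep["effect"], sweep["residue"], sweep["alt_aa"])
        ]
        assert sweep["class"].tolist() == expected

    def test_sweep_yields_exactly_seven_subclasses(self, domain):
        sweep = classify_truth_table(domain)
        labels = set(sweep["class"]) | {
            classify_copy_number(CopyNumberCall("FOXA1", 6), domain).value
        }
        assert labels == {"1A", "1B", "1C", "2", "3A", "3B", "4"}
        # every (effect, residue, alt) combination got exactly one label
        assert sweep["class"].notna().all()


def test_residue_counts_lollipop_table(domain):
    vs = [
        parse_hgvs_p("p.R219C"), parse_hgvs_p("p.R219C"), parse_hgvs_p("p.F254del"),
    ]
    out = residue_counts(vs, domain)
    assert out.loc[(out.residue == 219), "count"].item() == 2
    assert out.loc[(out.residue == 219), "class"].item() == "2"
    assert out.loc[(out.residue == 254), "class"].item() == "1B"


def test_domain_model_invariants_enforced():
    with pytest.raises(ValueError):
        DomainModel(fkh_start=300, fkh_end=269)
    with pytest.raises(ValueError):
        DomainModel(class2_residue=10)
    with pytest.raises(ValueError):
        DomainModel(amplification_min_copies=0)
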