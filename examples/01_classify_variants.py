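"""Classify individual FOXA1 protein alterations.

Parses HGVS protein-change strings as emitted by clinical NGS reports and
assigns each to its structural class relative to the forkhead (FKH)
domain (168-269) and its Wing2 region (247-269).
"""

from foxa1class import (
    CopyNumberCall,
    DomainModel,
    Pathogenicity,
    classify_copy_number,
    classify_sample,
    classify_variant,
    parse_hgvs_p,
)

domain = DomainModel()

for raw in ["p.R219C", "p.R219H", "p.M253K", "p.F254_E255del", "p.A200V",
            "p.E255*", "p.P358Lfs*13", "p.S42L"]:
    v = parse_hgvs_p(raw, pathogenicity=Pathogenicity.PATHOGENIC)
    label = classify_variant(v, domain)
    print(f"{raw:18s} {v.effect.value:18s} residue {v.start_aa:3d} -> class {label.value}")

print()
amp = classify_copy_number(CopyNumberCall("FOXA1", 8), domain)
print(f"copy number 8     amplification         -> class {amp.value}")

# a sample carrying both a hotspot mutation and an amplification takes the
# label of the rarer, more prognostically extreme event (class 2)
label, per_alt = classify_sample(
    [parse_hgvs_p("p.R219S", pathogenicity=Pathogenicity.PATHOGENIC)],
    [CopyNumberCall("FOXA1", 9)],
    domain,
)
print(f"\nsample with R219S + amplification -> sample label {label.value} "
      f"(alteration labels: {[l.value for l in per_alt]})")
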