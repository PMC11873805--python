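# foxa1class

Structurally oriented classification of somatic **FOXA1** alterations in
prostate cancer, with the full downstream cohort analysis: real-world
overall survival inferred from insurance-claims streams, class-vs-WT Cox
hazard ratios, molecular and demographic enrichment testing, expression
and gene-set signature comparisons, and per-residue missense tolerance
ratio (MTR) scanning. A synthetic cohort generator with class-conditional
survival hazards and feature rates makes every stage testable at desk
scale without access to proprietary clinical-genomic registries.

Intended for computational oncologists and biostatisticians working with
MAF-like variant tables, copy-number calls, and claims-derived outcomes.

## The classification schema

FOXA1 is a pioneer transcription factor whose DNA-binding forkhead (FKH)
domain spans residues 168–269; its flexible Wing2 region occupies the
C-terminal part of FKH (247–269 here). Alterations are assigned to four
classes and seven subclasses:

| class | rule |
|-------|------|
| 1A | missense / in-frame indel, anchor residue 168–246 (FKH before Wing2) |
| 1B | missense / in-frame indel, anchor residue 247–269 (Wing2) |
| 1C | missense / in-frame indel outside FKH (1–167, 270+) |
| 2  | the R219C / R219S hotspot substitutions |
| 3A | truncating (nonsense/frameshift) at residue ≤ 269 |
| 3B | truncating at residue ≥ 270 |
| 4  | gene amplification (≥ 6 copies) |

Only pathogenic / likely-pathogenic variants count as alterations;
benign, likely-benign, and VUS calls are excluded (a flag retains VUS for
sensitivity analyses). Samples carrying several alterations take one
label by a configurable precedence (rarest / most prognostically extreme
first, class 2 on top).

Downstream, overall survival runs from treatment initiation to death or
last contact, with death assumed for any patient whose claims stop more
than 100 days before the data cutoff; therapies starting within 90 days
of first-line ADT count as hormone-sensitive, later starts as
castration-resistant. Class-vs-WT contrasts use a two-arm Cox
proportional-hazards model (Efron ties) with log-rank p values; 2×2
feature enrichment uses Fisher's exact test (χ² when all expected counts
≥ 5) with Benjamini–Hochberg q values; TMB-high is ≥ 10 mutations/Mb.
The MTR of a residue is the observed missense fraction over the expected
missense fraction in a centred 31-codon window, with exact binomial tests
per residue.

## Worked example

```python
from foxa1class import DomainModel, classify_variant, parse_hgvs_p

d = DomainModel()
for raw in ["p.R219C", "p.R219H", "p.F254_E255del", "p.E255*", "p.P358Lfs*13"]:
    print(raw, "->", classify_variant(parse_hgvs_p(raw), d).value)
```

```
p.R219C -> 2
p.R219H -> 1A
p.F254_E255del -> 1B
p.E255* -> 3A
p.P358Lfs*13 -> 3B
```

R219C is the hotspot (class 2) while R219H is an ordinary FKH missense
(1A); the Wing2 deletion is 1B; truncations split at residue 270.

End to end on a synthetic cohort (`examples/03_synthetic_cohort_analysis.py`,
n = 2,000, seed 1):

```
all-tumors overall survival, class vs WT:
comparison  n_class  events_class    hr  ci_low  ci_high  p_logrank
  1B vs WT      155           143 0.829   0.699    0.984      0.032
   2 vs WT       16            16 1.607   0.981    2.632      0.057
  3A vs WT       40            36 0.787   0.565    1.095      0.154
  3B vs WT       22            22 1.936   1.269    2.953      0.002
```

HR > 1 means worse survival than FOXA1-WT. The generator's default
outcome parameters place class 2 at HR 2.05 and split the truncating
classes (3A protective at 0.70, 3B deleterious at 1.50); the fitted
values recover these within sampling noise, which is substantial for the
rarest classes at this cohort size.

The `examples/` directory holds one short script per capability
(classification, claims survival, cohort analysis, MTR scanning,
expression/signatures); each prints the numbers it computes with a note
on their meaning. A thin CLI wraps the same functions:
`foxa1class simulate | classify | analyze | mtr | run-all`.

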