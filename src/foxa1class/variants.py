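"""Protein-level variant model and HGVS p. notation parsing.

Parses the protein-change strings emitted by clinical NGS reports
(one-letter or three-letter amino-acid codes, with or without surrounding
parentheses) into a :class:`ProteinVariant` carrying the consequence type
and the affected residue span.  Only protein-level (``p.``) notation is
handled; DNA-level (``c.``) parsing and transcript mapping are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from Bio.SeqUtils import IUPACData


class Effect(str, Enum):
    """Functional consequence of a protein-level alteration."""

    MISSENSE = "missense"
    INFRAME_INSERTION = "inframe_insertion"
    INFRAME_DELETION = "inframe_deletion"
    INFRAME_DELINS = "inframe_delins"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Consequences treated as missense/in-frame ("class 1 type") events.
INFRAME_EFFECTS = frozenset(
    {Effect.MISSENSE, Effect.INFRAME_INSERTION, Effect.INFRAME_DELETION, Effect.INFRAME_DELINS}
)
#: Consequences treated as predicted truncating ("class 3 type") events.
TRUNCATING_EFFECTS = frozenset({Effect.NONSENSE, Effect.FRAMESHIFT})


class Pathogenicity(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "VUS"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


_PATHOGENICITY_ALIASES = {
    "pathogenic": Pathogenicity.PATHOGENIC,
    "likely pathogenic": Pathogenicity.LIKELY_PATHOGENIC,
    "likely_pathogenic": Pathogenicity.LIKELY_PATHOGENIC,
    "vus": Pathogenicity.VUS,
    "variant of unknown significance": Pathogenicity.VUS,
    "uncertain significance": Pathogenicity.VUS,
    "likely benign": Pathogenicity.LIKELY_BENIGN,
    "likely_benign": Pathogenicity.LIKELY_BENIGN,
    "benign": Pathogenicity.BENIGN,
}


def parse_pathogenicity(label: str) -> Pathogenicity:
    try:
        return _PATHOGENICITY_ALIASES[label.strip().lower()]
    except KeyError:
        raise ValueError(f"unrecognised pathogenicity label: {label!r}") from None


class HgvsParseError(ValueError):
    """Raised when a protein-change string cannot be interpreted."""


@dataclass(frozen=True)
class ProteinVariant:
    """One parsed protein-level alteration.

    Residue coordinates are 1-based and inclusive (HGVS convention).
    ``ref_aa``/``alt_aa`` are one-letter strings and may be empty for
    indels; ``*`` denotes a stop.
    """

    gene: str
    hgvs_p: str
    effect: Effect
    start_aa: int
    end_aa: int
    ref_aa: str = ""
    alt_aa: str = ""
    pathogenicity: Optional[Pathogenicity] = None
    vaf: Optional[float] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start_aa <= self.end_aa):
            raise ValueError(
                f"invalid residue span {self.start_aa}-{self.end_aa} for {self.hgvs_p!r}"
            )
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")


_AA3_TO_1 = {k.upper(): v for k, v in IUPACData.protein_letters_3to1_extended.items()}
_AA3_TO_1["TER"] = "*"
_AA1_TO_3 = {v: k for k, v in IUPACData.protein_letters_3to1.items()}
_AA1_TO_3["*"] = "Ter"

_AA_TOKEN = r"(?:\*|X|[A-Za-z][a-z]{2}|[A-Z])"


def _aa1(token: str) -> str:
    """Normalise an amino-acid token to a one-letter code."""
    if token in ("*", "X"):
        return "*"
    if len(token) == 1:
        if token.upper() not in IUPACData.protein_letters:
            raise HgvsParseError(f"unknown amino-acid code {token!r}")
        return token.upper()
    try:
        return _AA3_TO_1[token.upper()]
    except KeyError:
        raise HgvsParseError(f"unknown amino-acid code {token!r}") from None


def _aa_seq1(tokens: str) -> str:
    """Normalise a run of amino-acid tokens (1- or 3-letter) to 1-letter."""
    if not tokens:
        return ""
    if re.fullmatch(r"(?:[A-Z][a-z]{2})+", tokens):
        return "".join(_aa1(tokens[i : i + 3]) for i in range(0, len(tokens), 3))
    return "".join(_aa1(c) for c in tokens)


_RE_SITE = re.compile(rf"({_AA_TOKEN})(\d+)")
_RE_FS = re.compile(
    rf"^({_AA_TOKEN})(\d+)({_AA_TOKEN})?fs(?:(?:\*|Ter)(\d+|\?))?$", re.IGNORECASE
)
_RE_SUB = re.compile(rf"^({_AA_TOKEN})(\d+)(=|\*|X|(?:[A-Z][a-z]{{2}})|[A-Z])$")
_RE_RANGE_OP = re.compile(
    rf"^({_AA_TOKEN})(\d+)(?:_({_AA_TOKEN})(\d+))?(delins|del|dup|ins)([A-Za-z*]*)$"
)


def parse_hgvs_p(
    raw: str,
    *,
    gene: str = "FOXA1",
    pathogenicity: Optional[Pathogenicity] = None,
    vaf: Optional[float] = None,
    protein_length: Optional[int] = None,
) -> ProteinVariant:
    """Parse an HGVS protein-change string.

    Supported forms include ``p.R219C``, ``p.Arg219Cys``, ``p.F254del``,
    ``p.F254_E255del``, ``p.A100_T101insG``, ``p.D226delinsEV``,
    ``p.A100dup``, ``p.E100*`` / ``p.E100X``, ``p.P358Lfs*13`` /
    ``p.P358fs`` and ``p.R219R`` / ``p.R219=`` (synonymous), optionally
    wrapped in parentheses.

    Raises
    ------
    HgvsParseError
        If the string cannot be interpreted, naming the offending token.
    ValueError
        If a residue index exceeds ``protein_length``.
    """
    if not raw or not raw.strip():
        raise HgvsParseError("empty protein-change string")
    body = raw.strip()
    if body.startswith("(") and body.endswith(")"):
        body = body[1:-1]
    if body.startswith("p."):
        body = body[2:]
    body = body.strip()
    if body.startswith("(") and body.endswith(")"):
        body = body[1:-1]

    effect: Effect
    ref = alt = ""

    m = _RE_FS.match(body)
    if m:
        ref = _aa1(m.group(1))
        start = end = int(m.group(2))
        effect = Effect.FRAMESHIFT
        alt = _aa1(m.group(3)) if m.group(3) else ""
    else:
        m = _RE_RANGE_OP.match(body)
        if m:
            ref = _aa1(m.group(1))
            start = int(m.group(2))
            end = int(m.group(4)) if m.group(4) else start
            if m.group(3):
                ref += _aa1(m.group(3))
            op = m.group(5).lower()
            payload = _aa_seq1(m.group(6)) if m.group(6) else ""
            if op == "del":
                effect = Effect.INFRAME_DELETION
            elif op == "dup":
                effect = Effect.INFRAME_INSERTION
            elif op == "ins":
                effect, alt = Effect.INFRAME_INSERTION, payload
            else:
                effect, alt = Effect.INFRAME_DELINS, payload
        else:
            m = _RE_SUB.match(body)
            if m is None:
                raise HgvsParseError(f"unparseable protein change: {raw!r}")
            ref = _aa1(m.group(1))
            start = end = int(m.group(2))
            alt_tok = m.group(3)
            if alt_tok == "=":
                effect, alt = Effect.SYNONYMOUS, ref
            else:
                alt = _aa1(alt_tok)
                if alt == "*":
                    effect = Effect.NONSENSE
                elif alt == ref:
                    effect = Effect.SYNONYMOUS
                else:
                    effect = Effect.MISSENSE

    if start > end:
        raise HgvsParseError(f"inverted residue range in {raw!r}")
    if protein_length is not None and end > protein_length:
        raise ValueError(
            f"residue {end} in {raw!r} exceeds protein length {protein_length}"
        )
    return ProteinVariant(
        gene=gene,
        hgvs_p=raw.strip(),
        effect=effect,
        start_aa=start,
        end_aa=end,
        ref_aa=ref,
        alt_aa=alt,
        pathogenicity=pathogenicity,
        vaf=vaf,
    )


def format_hgvs_p(v: ProteinVariant, *, three_letter: bool = False) -> str:
    """Render a ProteinVariant back to canonical HGVS p. notation."""

    def aa(code: str) -> str:
        return "".join(_AA1_TO_3[c] for c in code) if three_letter else code

    e = v.effect
    if e in (Effect.MISSENSE, Effect.SYNONYMOUS, Effect.NONSENSE):
        return f"p.{aa(v.ref_aa)}{v.start_aa}{aa(v.alt_aa)}"
    if e is Effect.FRAMESHIFT:
        mid = aa(v.alt_aa) if v.alt_aa else ""
        return f"p.{aa(v.ref_aa)}{v.start_aa}{mid}fs"
    first, last = v.ref_aa[:1], v.ref_aa[1:2]
    left = f"{aa(first)}{v.start_aa}" if first else f"{v.start_aa}"
    if v.end_aa != v.start_aa:
        left += f"_{aa(last)}{v.end_aa}" if last else f"_{v.end_aa}"
    if e is Effect.INFRAME_DELETION:
        return f"p.{left}del"
    if e is Effect.INFRAME_INSERTION:
        return f"p.{left}ins{aa(v.alt_aa)}" if v.alt_aa else f"p.{left}dup"
    if e is Effect.INFRAME_DELINS:
        return f"p.{left}delins{aa(v.alt_aa)}"
    raise ValueError(f"cannot format effect {e}")
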