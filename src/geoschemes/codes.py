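"""Code grammar and label syntax for marine geounits.

The marine scheme parallels the terrestrial WGSRPD code system while staying
disjoint from it.  Terrestrial codes are purely numeric at levels 1-2 (one
digit, two digits) and three *letters* at level 3; marine codes always carry
at least one letter at level 1-2 and at least one *digit* at level 3, which
makes the two grammars mutually exclusive by shape alone:

===========  ======================  =========================
level        marine                  terrestrial
===========  ======================  =========================
1            ocean letter (RAIPS)    digit 1-9
2            letter + digit (A1)     two digits (10)
3 coastal    letter letter digit     three letters (FRA)
3 high seas  letter digit letter
4            ``XXX-YY``              ``XXX-YY``
===========  ======================  =========================

A level-4 suffix of ``OO`` marks a unit coincident with its level-3 parent.
High-seas units carry the reserved ISO 3166 alpha-2 code ``QP``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

#: Single-letter codes of the five ocean-scale level-1 units:
#: R Arctic, A Atlantic, I Indian, P Pacific, S Southern.
OCEAN_LETTERS = frozenset("RAIPS")

#: Reserved ISO 3166 alpha-2 code for the high seas.
HIGH_SEAS_ISO = "QP"

#: Level-4 suffix marking coincidence with the level-3 parent.
COINCIDENT_SUFFIX = "OO"

#: Canonical label separator (en-dash with single spaces).
LABEL_SEP = " – "


class CodeError(ValueError):
    """A string matches no production of the geounit code grammar."""


@dataclass(frozen=True)
class ParsedCode:
    """Decomposition of a geounit code string.

    Attributes mirror the grammar: ``ocean_letter``/``l2_digit`` are set for
    marine codes where derivable, ``l3_body`` is the three-character level-3
    stem, and ``l4_suffix`` the two letters after the dash at level 4.
    """

    raw: str
    scheme: str               # "marine" | "terrestrial"
    level: int                # 1..4
    ocean_letter: Optional[str] = None
    l2_digit: Optional[str] = None
    l3_body: Optional[str] = None
    l4_suffix: Optional[str] = None
    high_seas: bool = False

    @property
    def coincident(self) -> bool:
        return self.l4_suffix == COINCIDENT_SUFFIX

    @property
    def derivable_parent(self) -> Optional[str]:
        """Parent code when it is implied by the code itself.

        Level-4 codes embed their level-3 parent; marine high-seas level-3
        codes embed their level-2 parent; level-2 codes embed level 1.
        Coastal marine level-3 codes (two letters + digit) do not encode an
        ocean, so their parent must come from the registry table.
        """
        if self.level == 4:
            return self.l3_body
        if self.level == 3 and self.high_seas:
            return self.raw[:2]
        if self.level == 2:
            return self.raw[0] if self.scheme == "marine" else None
        return None


def _classify3(s: str) -> ParsedCode:
    a, b, c = s
    if a.isalpha() and b.isalpha() and c.isdigit():
        return ParsedCode(raw=s, scheme="marine", level=3, l3_body=s)
    if a.isalpha() and b.isdigit() and c.isalpha():
        if a not in OCEAN_LETTERS:
            raise CodeError(
                f"{s!r}: high-seas level-3 codes start with an ocean letter "
                f"(one of {''.join(sorted(OCEAN_LETTERS))})"
            )
        return ParsedCode(raw=s, scheme="marine", level=3, l3_body=s,
                          ocean_letter=a, l2_digit=b, high_seas=True)
    if s.isalpha():
        return ParsedCode(raw=s, scheme="terrestrial", level=3, l3_body=s)
    raise CodeError(
        f"{s!r}: three-character codes must be letter-letter-digit (marine "
        "coastal), letter-digit-letter (marine high seas) or three letters "
        "(terrestrial)"
    )


def parse_code(code: str) -> ParsedCode:
    """Parse a geounit code into its grammatical components.

    Parsing is case-insensitive; the canonical form is upper-case.  Raises
    :class:`CodeError` for strings matching no production.
    """
    if not isinstance(code, str) or not code.strip():
        raise CodeError("empty code string")
    s = code.strip().upper()
    n = len(s)
    if n == 1:
        if s in OCEAN_LETTERS:
            return ParsedCode(raw=s, scheme="marine", level=1, ocean_letter=s)
        if s.isdigit() and s != "0":
            return ParsedCode(raw=s, scheme="terrestrial", level=1)
        raise CodeError(
            f"{s!r}: level-1 codes are an ocean letter "
            f"({''.join(sorted(OCEAN_LETTERS))}) or a digit 1-9"
        )
    if n == 2:
        if s[0].isalpha() and s[1].isdigit():
            if s[0] not in OCEAN_LETTERS:
                raise CodeError(
                    f"{s!r}: marine level-2 codes start with an ocean letter"
                )
            return ParsedCode(raw=s, scheme="marine", level=2,
                              ocean_letter=s[0], l2_digit=s[1])
        if s.isdigit():
            return ParsedCode(raw=s, scheme="terrestrial", level=2)
        raise CodeError(
            f"{s!r}: two-character codes are ocean-letter+digit (marine) or "
            "two digits (terrestrial)"
        )
    if n == 3:
        return _classify3(s)
    if n == 6 and s[3] == "-":
        body, suffix = s[:3], s[4:]
        if not (len(suffix) == 2 and suffix.isalpha()):
            raise CodeError(f"{s!r}: level-4 suffix must be two letters")
        parent = _classify3(body)
        return ParsedCode(raw=s, scheme=parent.scheme, level=4,
                          ocean_letter=parent.ocean_letter,
                          l2_digit=parent.l2_digit, l3_body=body,
                          l4_suffix=suffix, high_seas=parent.high_seas)
    raise CodeError(
        f"{code!r}: matches no production (expected 1-3 characters or "
        "XXX-YY)"
    )


def code_level(code: str) -> int:
    return parse_code(code).level


def make_code(
    level: int,
    *,
    ocean: Optional[str] = None,
    digit: Optional[int | str] = None,
    letters: Optional[str] = None,
    l2: Optional[str] = None,
    discriminator: Optional[str] = None,
    l3: Optional[str] = None,
    suffix: Optional[str] = None,
    coincident: bool = False,
    high_seas: bool = False,
) -> str:
    """Assemble a canonical marine code from components.

    ``make_code(1, ocean="A")`` -> ``"A"``;
    ``make_code(2, ocean="A", digit=1)`` -> ``"A1"``;
    ``make_code(3, letters="FR", digit=1)`` -> ``"FR1"``;
    ``make_code(3, high_seas=True, l2="A5", discriminator="B")`` -> ``"A5B"``;
    ``make_code(4, l3="EG1", suffix="RS")`` -> ``"EG1-RS"``;
    ``make_code(4, l3="FR1", coincident=True)`` -> ``"FR1-OO"``.

    The result always round-trips through :func:`parse_code`.
    """
    if level == 1:
        if not ocean or ocean.upper() not in OCEAN_LETTERS:
            raise CodeError(f"invalid ocean letter {ocean!r}")
        out = ocean.upper()
    elif level == 2:
        if not ocean or ocean.upper() not in OCEAN_LETTERS:
            raise CodeError(f"invalid ocean letter {ocean!r}")
        d = str(digit)
        if not (len(d) == 1 and d.isdigit()):
            raise CodeError(f"invalid level-2 digit {digit!r}")
        out = ocean.upper() + d
    elif level == 3:
        if high_seas:
            if l2 is None or discriminator is None:
                raise CodeError("high-seas level 3 needs l2 and discriminator")
            base = parse_code(l2)
            if base.level != 2 or base.scheme != "marine":
                raise CodeError(f"{l2!r} is not a marine level-2 code")
            if not (len(discriminator) == 1 and discriminator.isalpha()):
                raise CodeError(f"invalid discriminator {discriminator!r}")
            out = base.raw + discriminator.upper()
        else:
            if letters is None or digit is None:
                raise CodeError("coastal level 3 needs letters and digit")
            if not (len(letters) == 2 and letters.isalpha()):
                raise CodeError(f"invalid level-3 letters {letters!r}")
            d = str(digit)
            if not (len(d) == 1 and d.isdigit()):
                raise CodeError(f"invalid level-3 digit {digit!r}")
            out = letters.upper() + d
    elif level == 4:
        if l3 is None:
            raise CodeError("level 4 needs its level-3 stem")
        stem = _classify3(l3.strip().upper())
        sfx = COINCIDENT_SUFFIX if coincident else (suffix or "").strip().upper()
        if not (len(sfx) == 2 and sfx.isalpha()):
            raise CodeError(f"invalid level-4 suffix {suffix!r}")
        if coincident and suffix not in (None, COINCIDENT_SUFFIX):
            raise CodeError("coincident level-4 units always use the -OO suffix")
        out = f"{stem.raw}-{sfx}"
    else:
        raise CodeError(f"invalid level {level!r}")
    parsed = parse_code(out)
    assert parsed.level == level
    return out


def check_collisions(marine_codes: Iterable[str],
                     terrestrial_codes: Iterable[str]) -> list[str]:
    """Codes violating disjointness of the marine and terrestrial grammars.

    Returns the sorted union of (a) exact string intersections of the two
    sets and (b) marine codes that parse as terrestrial (or do not parse at
    all) -- grammar violations, impossible for codes emitted by
    :func:`make_code`.
    """
    marine = {str(c).strip().upper() for c in marine_codes}
    terrestrial = {str(c).strip().upper() for c in terrestrial_codes}
    bad = set(marine & terrestrial)
    for c in marine:
        try:
            if parse_code(c).scheme != "marine":
                bad.add(c)
        except CodeError:
            bad.add(c)
    return sorted(bad)


# ---------------------------------------------------------------------------
# Labels

LABEL_STYLES = frozenset({"EEZ", "SEA_AREA", "MSFD", "IMCRA", "HIGH_SEAS"})


@dataclass(frozen=True)
class LabelSpec:
    """Components of a human-readable geounit label.

    ``style`` selects the template; ``own_iso`` marks a territory with its
    own ISO 3166 code, which is then named on its own (e.g. "Martinique EEZ"
    rather than "France – Martinique EEZ").
    """

    style: str
    country_name: Optional[str] = None
    own_iso: bool = False
    qualifier: Optional[str] = None
    sector_tag: Optional[str] = None
    feature_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.style not in LABEL_STYLES:
            raise ValueError(f"unknown label style {self.style!r}")


def format_label(spec: LabelSpec) -> str:
    """Render a label from its components.

    Coastal labels always start with the adjacent country or dependency
    name.  "EEZ" is appended for plain jurisdictional units (to keep them
    distinct from same-named terrestrial units) but omitted when the part is
    explicitly named a sea area, or for MSFD/IMCRA subunits.  High-seas
    labels are "<sector tag> – <undersea feature name>".
    """
    s = spec.style
    if s == "HIGH_SEAS":
        if not (spec.sector_tag and spec.feature_name):
            raise ValueError("HIGH_SEAS labels need sector_tag and feature_name")
        return f"{spec.sector_tag}{LABEL_SEP}{spec.feature_name}"
    if not spec.country_name:
        raise ValueError(f"{s} labels need a country name")
    if s == "EEZ":
        if spec.qualifier:
            return f"{spec.country_name}{LABEL_SEP}{spec.qualifier} EEZ"
        if spec.own_iso:
            return f"{spec.country_name} EEZ"
        return f"{spec.country_name}{LABEL_SEP}EEZ"
    if s in ("SEA_AREA", "MSFD", "IMCRA"):
        if not spec.qualifier:
            raise ValueError(f"{s} labels need a qualifier")
        return f"{spec.country_name}{LABEL_SEP}{spec.qualifier}"
    raise AssertionError("unreachable")


def normalize_label(label: str) -> str:
    """Canonicalize dash and whitespace variants for label comparison."""
    s = " ".join(label.replace("—", "-").replace("–", "-").split())
    return s.replace(" - ", LABEL_SEP)
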