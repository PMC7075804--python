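"""Back-of-pack ingredient-list parsing and rule-based classification.

Food labels list ingredients in order of predominance (heaviest first).
This module parses a raw label into an ordered token tree — top-level
commas separate tokens, parenthesized or square-bracketed groups become
sub-ingredients, and trailing percentage declarations (QUID, the EU
quantitative ingredient declaration) are stored per token — then applies
three classification rules:

* **dairy-first** — milk, yogurt, or cheese is the first listed ingredient.
  Derived dairy solids ("milk powder", "milk solids") and "milk chocolate"
  never qualify; neither does cream, because the rule enumerates only milk,
  yogurt, and cheese.
* **fruit-first** — a fruit (whole or puree) is the first listed ingredient,
  or second after water (the "water, oranges" pattern of juice from
  concentrate).  Fruit after sugar does not count, and neither do fruit
  concentrates, jams, pectins, or flavors, which act as sweeteners or
  aromas rather than fruit.
* **FVN presence** — a fruit, vegetable, nut, peanut, or seed term occurs
  anywhere on the list, sub-ingredients included, after the same fruit
  exclusions.  Starchy vegetables (potato, corn) in chip products get no
  credit; the shipped vegetable lexicon excludes them everywhere,
  conservatively.

Matching is lexicon-driven: term lists ship as editable plain-text data
files (one term per line, ``#`` comments).  Exclusion terms are checked
before inclusion terms, and all matching is on whole words within a
token's normalized name, so "milk chocolate" never matches "milk".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import EmptyLabelError, LabelParseError

#: WWEIA codes for chip categories; potato/corn tokens in these products
#: never earn FVN credit (starchy vegetables as chips are excluded).
CHIP_WWEIA_CODES = frozenset({5002, 5004, 5008})

_STARCHY_CHIP_TERMS = ("potato", "potatoes", "corn")


@dataclass
class IngredientToken:
    """One entry of an ingredient list, possibly with nested sub-ingredients."""

    position: int  # 1-based rank among its siblings
    name: str  # normalized lowercase text
    quid_percent: float | None = None
    sub_ingredients: list["IngredientToken"] = field(default_factory=list)


@dataclass
class IngredientClassification:
    """Classification flags for one label, with the matches that explain them."""

    dairy_first: bool
    fruit_first: bool
    fvn_present: bool
    matched_terms: list[tuple[str, str]] = field(default_factory=list)

    @property
    def fruit_or_dairy_first(self) -> bool:
        return self.dairy_first or self.fruit_first


# ---------------------------------------------------------------------------
# Lexicons
# ---------------------------------------------------------------------------


def _load_lexicon(filename: str) -> tuple[str, ...]:
    path = resources.files("snacknrf.data.lexicons").joinpath(filename)
    terms = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip().lower()
        if line:
            terms.append(line)
    # longest-match-first so multi-word exclusions dominate their substrings
    return tuple(sorted(set(terms), key=len, reverse=True))


class Lexicon:
    """An inclusion term list with an optional exclusion term list.

    A token name matches when an inclusion term occurs as a whole-word
    phrase and no exclusion term does; exclusions are checked first.
    """

    def __init__(self, include: tuple[str, ...], exclude: tuple[str, ...] = ()):
        self.include = include
        self.exclude = exclude

    @staticmethod
    def _contains(name: str, term: str) -> bool:
        pattern = rf"(?<![a-z0-9]){re.escape(term)}(?![a-z0-9])"
        return re.search(pattern, name) is not None

    def match(self, name: str) -> str | None:
        """Return the matching inclusion term, or None."""
        for term in self.exclude:
            if self._contains(name, term):
                return None
        for term in self.include:
            if self._contains(name, term):
                return term
        return None


def _default_lexicons() -> dict[str, Lexicon]:
    fruit_exclude = _load_lexicon("fruit_exclude.txt")
    return {
        "dairy": Lexicon(
            _load_lexicon("dairy.txt"), _load_lexicon("dairy_exclude.txt")
        ),
        "fruit": Lexicon(_load_lexicon("fruit.txt"), fruit_exclude),
        "vegetable": Lexicon(_load_lexicon("vegetables.txt"), fruit_exclude),
        "nut_seed": Lexicon(_load_lexicon("nuts_seeds.txt"), fruit_exclude),
        "water": Lexicon(_load_lexicon("water.txt")),
    }


_LEXICONS: dict[str, Lexicon] | None = None


def get_lexicons() -> dict[str, Lexicon]:
    global _LEXICONS
    if _LEXICONS is None:
        _LEXICONS = _default_lexicons()
    return _LEXICONS


def load_lexicons_from_dir(directory: str | Path) -> dict[str, Lexicon]:
    """Load user-edited lexicon files from ``directory`` (same filenames
    as the shipped defaults)."""

    def read(fn: str) -> tuple[str, ...]:
        terms = []
        for line in (Path(directory) / fn).read_text().splitlines():
            line = line.split("#", 1)[0].strip().lower()
            if line:
                terms.append(line)
        return tuple(sorted(set(terms), key=len, reverse=True))

    fruit_exclude = read("fruit_exclude.txt")
    return {
        "dairy": Lexicon(read("dairy.txt"), read("dairy_exclude.txt")),
        "fruit": Lexicon(read("fruit.txt"), fruit_exclude),
        "vegetable": Lexicon(read("vegetables.txt"), fruit_exclude),
        "nut_seed": Lexicon(read("nuts_seeds.txt"), fruit_exclude),
        "water": Lexicon(read("water.txt")),
    }


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_QUID_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*%\s*$")
_TRAILING_PCT_RE = re.compile(r"[\s]*(\d+(?:\.\d+)?)\s*%\s*$")

_OPEN = {"(": ")", "[": "]"}
_CLOSE = {")", "]"}


def _split_top_level(text: str, base_offset: int) -> list[tuple[str, int]]:
    """Split on commas outside any (nested) parentheses/brackets.

    Returns (piece, absolute offset) pairs; raises on unbalanced groups.
    """
    pieces: list[tuple[str, int]] = []
    depth = 0
    stack: list[tuple[str, int]] = []
    start = 0
    for i, ch in enumerate(text):
        if ch in _OPEN:
            depth += 1
            stack.append((ch, i))
        elif ch in _CLOSE:
            if not stack or _OPEN[stack[-1][0]] != ch:
                raise LabelParseError(
                    f"unbalanced {ch!r} in ingredient list", base_offset + i
                )
            depth -= 1
            stack.pop()
        elif ch == "," and depth == 0:
            pieces.append((text[start:i], base_offset + start))
            start = i + 1
    if stack:
        ch, pos = stack[-1]
        raise LabelParseError(
            f"unclosed {ch!r} in ingredient list", base_offset + pos
        )
    pieces.append((text[start:], base_offset + start))
    return pieces


def _normalize(name: str) -> str:
    name = name.strip().strip(".").strip()
    return re.sub(r"\s+", " ", name.lower())


def _parse_piece(piece: str, offset: int) -> IngredientToken | None:
    """Parse one comma-delimited piece into a token (or None if blank)."""
    # Extract top-level groups: "name (a, b) [c]" -> name plus group bodies.
    name_parts: list[str] = []
    groups: list[tuple[str, int]] = []
    depth = 0
    gstart = 0
    for i, ch in enumerate(piece):
        if ch in _OPEN:
            if depth == 0:
                gstart = i + 1
            depth += 1
        elif ch in _CLOSE:
            depth -= 1
            if depth == 0:
                groups.append((piece[gstart:i], offset + gstart))
        elif depth == 0:
            name_parts.append(ch)
    name = _normalize("".join(name_parts))

    quid: float | None = None
    subs: list[IngredientToken] = []
    for body, goff in groups:
        m = _QUID_RE.match(body)
        if m:
            quid = float(m.group(1))
            continue
        for sub_piece, soff in _split_top_level(body, goff):
            sub = _parse_piece(sub_piece, soff)
            if sub is not None:
                sub.position = len(subs) + 1
                subs.append(sub)

    # trailing "5%" directly in the name ("raspberry 5%")
    m = _TRAILING_PCT_RE.search(name)
    if m:
        quid = float(m.group(1))
        name = name[: m.start()].strip()

    if not name and not subs:
        return None
    return IngredientToken(position=0, name=name, quid_percent=quid,
                           sub_ingredients=subs)


def parse_ingredients(label_text: str) -> list[IngredientToken]:
    """Parse a raw ingredient label into an ordered list of tokens.

    Top-level commas separate tokens; parenthesized and square-bracketed
    groups become ``sub_ingredients``; pure-percentage groups such as
    ``(59.5%)`` and trailing ``5%`` annotations are stored as
    ``quid_percent``.  Names are lowercased and whitespace-normalized.
    """
    if label_text is None or not label_text.strip():
        raise EmptyLabelError("ingredient label is empty")
    tokens: list[IngredientToken] = []
    for piece, offset in _split_top_level(label_text, 0):
        token = _parse_piece(piece, offset)
        if token is not None:
            token.position = len(tokens) + 1
            tokens.append(token)
    if not tokens:
        raise EmptyLabelError("ingredient label contains no ingredients")
    return tokens


def _format_token(token: IngredientToken) -> str:
    s = token.name
    if token.quid_percent is not None:
        s += f" ({token.quid_percent:g}%)"
    if token.sub_ingredients:
        s += " (" + ", ".join(_format_token(t) for t in token.sub_ingredients) + ")"
    return s


def serialize_ingredients(tokens: list[IngredientToken]) -> str:
    """Render a token tree back to a canonical label string.

    Re-parsing the result yields an identical tree (round-trip contract).
    """
    return ", ".join(_format_token(t) for t in tokens)


# ---------------------------------------------------------------------------
# Classification rules
# ---------------------------------------------------------------------------


def classify_dairy_first(
    tokens: list[IngredientToken],
    lexicons: dict[str, Lexicon] | None = None,
) -> tuple[bool, list[tuple[str, str]]]:
    """Dairy-first rule: milk, yogurt, or cheese as the first ingredient.

    Only the top-level name of the first token is examined.  Returns the
    flag plus ``(token, rule)`` evidence pairs.
    """
    if not tokens:
        return False, []
    lex = (lexicons or get_lexicons())["dairy"]
    term = lex.match(tokens[0].name)
    if term is not None:
        return True, [(tokens[0].name, f"dairy-first:{term}")]
    return False, []


def classify_fruit_first(
    tokens: list[IngredientToken],
    lexicons: dict[str, Lexicon] | None = None,
) -> tuple[bool, list[tuple[str, str]]]:
    """Fruit-first rule: fruit first, or second after water (never after
    sugar or any other ingredient).  Concentrates, jams, pectins and
    flavors are excluded by the fruit lexicon."""
    if not tokens:
        return False, []
    lexmap = lexicons or get_lexicons()
    fruit = lexmap["fruit"]
    term = fruit.match(tokens[0].name)
    if term is not None:
        return True, [(tokens[0].name, f"fruit-first:{term}")]
    if len(tokens) >= 2 and lexmap["water"].match(tokens[0].name):
        term = fruit.match(tokens[1].name)
        if term is not None:
            return True, [(tokens[1].name, f"fruit-after-water:{term}")]
    return False, []


def _walk(tokens: list[IngredientToken]):
    for token in tokens:
        yield token
        yield from _walk(token.sub_ingredients)


def detect_fvn(
    tokens: list[IngredientToken],
    wweia_code: int | None = None,
    lexicons: dict[str, Lexicon] | None = None,
) -> tuple[bool, list[tuple[str, str]]]:
    """Fruit-vegetable-nut presence anywhere on the list (sub-ingredients
    included).  Peanuts and seeds count as nuts.  In chip categories
    (``wweia_code`` in :data:`CHIP_WWEIA_CODES`) potato/corn tokens never
    qualify."""
    lexmap = lexicons or get_lexicons()
    in_chip_category = wweia_code in CHIP_WWEIA_CODES
    matches: list[tuple[str, str]] = []
    for token in _walk(tokens):
        if in_chip_category and any(
            Lexicon._contains(token.name, t) for t in _STARCHY_CHIP_TERMS
        ):
            continue
        for kind in ("fruit", "vegetable", "nut_seed"):
            term = lexmap[kind].match(token.name)
            if term is not None:
                matches.append((token.name, f"fvn-{kind}:{term}"))
    return bool(matches), matches


def classify_ingredients(
    label_text: str,
    wweia_code: int | None = None,
    lexicons: dict[str, Lexicon] | None = None,
) -> IngredientClassification:
    """Parse a label and apply all three rules in one call."""
    tokens = parse_ingredients(label_text)
    dairy, ev_d = classify_dairy_first(tokens, lexicons)
    fruit, ev_f = classify_fruit_first(tokens, lexicons)
    fvn, ev_n = detect_fvn(tokens, wweia_code, lexicons)
    return IngredientClassification(
        dairy_first=dairy,
        fruit_first=fruit,
        fvn_present=fvn,
        matched_terms=ev_d + ev_f + ev_n,
    )
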