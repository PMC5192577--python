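"""Parser for the domain-grammar describing simulated chromatin fibers.

A fiber configuration is an ordered sequence of elements written as::

    lin(x)                       linear stretch of x kb
    dom(y)[loop(a) - loop(b) …]  domain of y kb made of loops (a rosette)
    dom(y)[glob(z)]              domain of y kb made of one globular stretch

Loop lengths may carry variants, ``loop(100/125/150)``, meaning the length
is varied across ensemble realizations; parsing keeps the variants and the
mean length is used where a single value is required.  All lengths are in
kb and are rounded to whole lattice bonds (2.5 kb by default) downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["Lin", "Loop", "Glob", "Dom", "DomainConfig", "parse_domain_config",
           "FIG1D_CONFIG", "FIG1E_CONFIG", "ROSETTE_1300_CONFIG"]


@dataclass(frozen=True)
class Lin:
    """Linear (unlooped) stretch of ``kb`` kilobases."""

    kb: float

    def serialize(self) -> str:
        return f"lin({_fmt(self.kb)})"


@dataclass(frozen=True)
class Loop:
    """A loop; ``variants`` holds alternative lengths varied across runs."""

    kb: float
    variants: tuple[float, ...] = ()

    def serialize(self) -> str:
        if self.variants:
            return "loop(" + "/".join(_fmt(v) for v in self.variants) + ")"
        return f"loop({_fmt(self.kb)})"

    def length(self, variant_index: int | None = None) -> float:
        if self.variants and variant_index is not None:
            return self.variants[variant_index % len(self.variants)]
        return self.kb


@dataclass(frozen=True)
class Glob:
    """Globular (compact, unlooped) stretch of ``kb`` kilobases."""

    kb: float

    def serialize(self) -> str:
        return f"glob({_fmt(self.kb)})"


@dataclass(frozen=True)
class Dom:
    """Domain of declared size ``kb`` containing loops or one glob."""

    kb: float
    content: tuple[Loop, ...] | tuple[Glob, ...]

    @property
    def is_rosette(self) -> bool:
        return bool(self.content) and isinstance(self.content[0], Loop)

    @property
    def content_kb(self) -> float:
        return sum(c.kb for c in self.content)

    def serialize(self) -> str:
        inner = " - ".join(c.serialize() for c in self.content)
        return f"dom({_fmt(self.kb)})[{inner}]"


@dataclass(frozen=True)
class DomainConfig:
    """Parsed fiber configuration: an ordered tuple of Lin/Dom elements."""

    elements: tuple[Lin | Dom, ...]

    @property
    def total_kb(self) -> float:
        """Genomic length actually realized (domain content, not labels)."""
        return sum(
            e.kb if isinstance(e, Lin) else e.content_kb for e in self.elements
        )

    def serialize(self) -> str:
        return " - ".join(e.serialize() for e in self.elements)

    def domains(self) -> list[Dom]:
        return [e for e in self.elements if isinstance(e, Dom)]


def _fmt(x: float) -> str:
    return f"{x:g}"


_TOKEN = re.compile(
    r"\s*(?:(?P<lin>lin)\s*\(\s*(?P<linval>[\d./]+)\s*\)"
    r"|(?P<dom>dom)\s*\(\s*(?P<domval>[\d.]+)\s*\)\s*\[(?P<body>[^\]]*)\]"
    r"|(?P<sep>[-–])"
    r")\s*"
)
_INNER = re.compile(
    r"\s*(?:(?P<kind>loop|glob)\s*\(\s*(?P<val>[\d./]+)\s*\)|(?P<sep>[-–]))\s*"
)


class DomainGrammarError(ValueError):
    """Malformed configuration text; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def _parse_lengths(text: str) -> tuple[float, tuple[float, ...]]:
    parts = [p for p in text.split("/") if p]
    values = tuple(float(p) for p in parts)
    if len(values) == 1:
        return values[0], ()
    return sum(values) / len(values), values


def parse_domain_config(
    text: str, content_tolerance: float | None = 0.0
) -> DomainConfig:
    """Parse a configuration string into a :class:`DomainConfig`.

    ``content_tolerance`` is the allowed relative mismatch between a
    domain's declared size and the sum of its contents; 0 requires exact
    agreement and ``None`` disables the check (some published configuration
    listings are internally inconsistent at the 10 % level).
    """
    elements: list[Lin | Dom] = []
    pos = 0
    n = len(text)
    while pos < n:
        m = _TOKEN.match(text, pos)
        if not m:
            raise DomainGrammarError(f"unrecognized token {text[pos:pos + 12]!r}", pos)
        if m.group("sep"):
            pos = m.end()
            continue
        if m.group("lin"):
            kb, variants = _parse_lengths(m.group("linval"))
            if variants:
                raise DomainGrammarError("lin() does not take variants", pos)
            if kb <= 0:
                raise DomainGrammarError("lin length must be positive", pos)
            elements.append(Lin(kb))
        else:
            dom_kb = float(m.group("domval"))
            body = m.group("body")
            content: list[Loop | Glob] = []
            bpos = 0
            while bpos < len(body):
                im = _INNER.match(body, bpos)
                if not im:
                    raise DomainGrammarError(
                        f"unrecognized domain content {body[bpos:bpos + 12]!r}",
                        pos + bpos,
                    )
                if im.group("sep"):
                    bpos = im.end()
                    continue
                kb, variants = _parse_lengths(im.group("val"))
                if kb <= 0:
                    raise DomainGrammarError("element length must be positive", pos + bpos)
                if im.group("kind") == "loop":
                    content.append(Loop(kb, variants))
                else:
                    content.append(Glob(kb))
                bpos = im.end()
            if not content:
                raise DomainGrammarError("empty domain body", pos)
            kinds = {type(c) for c in content}
            if kinds == {Glob} and len(content) > 1:
                raise DomainGrammarError("a domain holds at most one glob", pos)
            if len(kinds) > 1:
                raise DomainGrammarError("domain mixes loops and globs", pos)
            dom = Dom(dom_kb, tuple(content))
            if content_tolerance is not None:
                mismatch = abs(dom.content_kb - dom_kb) / dom_kb
                if mismatch > content_tolerance + 1e-12:
                    raise DomainGrammarError(
                        f"dom({_fmt(dom_kb)}) content sums to {_fmt(dom.content_kb)} kb",
                        pos,
                    )
            elements.append(dom)
        pos = m.end()
    if not elements:
        raise DomainGrammarError("empty configuration", 0)
    return DomainConfig(tuple(elements))


#: Five-Mb model fiber of four rosette domains separated by linkers
#: (the published listing; domain labels and loop sums disagree slightly,
#: so it parses with the content check disabled).
FIG1D_CONFIG = (
    "lin(100) - dom(1000)[loop(166) - loop(167) - loop(166) - loop(167) - loop(166)]"
    " - lin(150) - dom(1300)[loop(100/125/150/175/200) - loop(95) - loop(90) - loop(85)"
    " - loop(120/145/170/195/220) - loop(150) - loop(125) - loop(115) - loop(160) - loop(150)]"
    " - lin(150) - dom(1000)[loop(185) - loop(120) - loop(95) - loop(120) - loop(235) - loop(245)]"
    " - lin(50) - dom(1100)[loop(138) - loop(160) - loop(95) - loop(170) - loop(160)"
    " - loop(183) - loop(128) - loop(68)] - lin(150)"
)

#: Globular counterpart of the same fiber.
FIG1E_CONFIG = (
    "lin(100) - dom(1000)[glob(1000)] - lin(150) - dom(1300)[glob(1300)]"
    " - lin(150) - dom(1000)[glob(1000)] - lin(50) - dom(1100)[glob(1100)] - lin(150)"
)

#: The 1300-kb ten-loop rosette domain alone (varied loops at their mean
#: lengths), flanked by short linkers.
ROSETTE_1300_CONFIG = (
    "lin(50) - dom(1290)[loop(150) - loop(95) - loop(90) - loop(85) - loop(170)"
    " - loop(150) - loop(125) - loop(115) - loop(160) - loop(150)] - lin(50)"
)
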