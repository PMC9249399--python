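"""Minimal CSS-selector support over lxml trees.

The registry extraction tables only ever use three selector forms — ``#id``,
``tag.class`` / ``.class`` and descendant chains of those (e.g.
``ul.addresses li.address``) — so selectors are compiled to XPath by a small
translator rather than pulling in a full CSS engine.

Text extraction deliberately preserves internal whitespace: downstream change
detection must notice even a single inserted space, so only leading/trailing
whitespace is stripped.
"""

from __future__ import annotations

import re

from lxml import html as lxml_html

_TOKEN_RE = re.compile(
    r"^(?P<tag>[a-zA-Z][a-zA-Z0-9]*)?"
    r"(?:(?P<kind>[#.])(?P<name>[a-zA-Z_][\w-]*))?$"
)


class SelectorError(ValueError):
    """Raised at load time for a selector outside the supported grammar."""


def css_to_xpath(selector: str) -> str:
    """Translate a simple CSS selector to a relative XPath expression."""
    parts = []
    tokens = selector.split()
    if not tokens:
        raise SelectorError(f"empty selector: {selector!r}")
    for token in tokens:
        m = _TOKEN_RE.match(token)
        if not m or (not m.group("tag") and not m.group("name")):
            raise SelectorError(f"unsupported selector token: {token!r}")
        tag = m.group("tag") or "*"
        if m.group("kind") == "#":
            parts.append(f"{tag}[@id={_xpath_literal(m.group('name'))}]")
        elif m.group("kind") == ".":
            cls = m.group("name")
            parts.append(
                f"{tag}[contains(concat(' ', normalize-space(@class), ' '), "
                f"' {cls} ')]"
            )
        else:
            parts.append(tag)
    # descendant-or-self so a selector can match the tree root itself
    # (lxml parses bare fragments with the payload element as root)
    return "descendant-or-self::" + "//".join(parts)


def _xpath_literal(value: str) -> str:
    if "'" not in value:
        return f"'{value}'"
    return '"%s"' % value


def select(tree, selector: str) -> list:
    """All elements matching *selector*, in document order."""
    return tree.xpath(css_to_xpath(selector))


def select_one(tree, selector: str):
    """First element matching *selector*, or None."""
    found = select(tree, selector)
    return found[0] if found else None


def parse_html(text: str):
    """Parse an HTML document into an lxml element tree root."""
    return lxml_html.fromstring(text)


def element_text(el) -> str:
    """Text content of *el* with outer whitespace stripped, inner preserved.

    ``<br>`` elements are rendered as newlines so that line-structured cells
    can be split by the caller.
    """
    chunks: list[str] = []
    _collect_text(el, chunks, skip_tags=frozenset())
    return "".join(chunks).strip()


def element_text_excluding(el, skip_tags: frozenset[str]) -> str:
    """Like :func:`element_text` but skipping subtrees with the given tags."""
    chunks: list[str] = []
    _collect_text(el, chunks, skip_tags=skip_tags)
    return "".join(chunks).strip()


def _collect_text(el, chunks: list[str], skip_tags: frozenset[str]) -> None:
    if not isinstance(el.tag, str):  # comments, PIs
        if el.tail:
            chunks.append(el.tail)
        return
    if el.tag.lower() in skip_tags:
        if el.tail:
            chunks.append(el.tail)
        return
    if el.tag.lower() == "br":
        chunks.append("\n")
    if el.text:
        chunks.append(el.text)
    for child in el:
        _collect_text(child, chunks, skip_tags)
    if el.tail:
        chunks.append(el.tail)


def text_lines(el) -> list[str]:
    """Non-blank lines of an element's text, each stripped at the edges.

    Line breaks come from ``<br>`` tags or literal newlines in the source.
    Internal (non-edge) whitespace within a line is preserved byte-for-byte.
    """
    chunks: list[str] = []
    _collect_text(el, chunks, skip_tags=frozenset())
    raw = "".join(chunks)
    return [line.strip() for line in raw.split("\n") if line.strip()]
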