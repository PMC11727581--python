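"""Reader/writer for UCSC net-format pairwise alignment files.

A net file describes the hierarchy of syntenic blocks from a pairwise
whole-genome alignment.  Each reference chromosome opens with a
``net <chrom> <size>`` header followed by indented ``fill`` and ``gap``
records.  ``fill`` marks a region aligned in both genomes, ``gap`` marks a
region present in the reference but absent from the query, and nesting
depth (one leading space per level) encodes synteny levels: a fill found
inside another fill's gap is a deeper synteny level — the signature this
package exploits to find retrotransposed copies.

Coordinates follow the UCSC convention: 0-based half-open, reference
always on the plus strand, query on the strand named in the record.
Attribute key/value pairs after the six coordinate fields (``id``,
``score``, ``ali``, ``type``, ...) are preserved verbatim and never
interpreted, so both raw chainNet output and netSyntenic-annotated files
round-trip unchanged.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO, Union


class NetParseError(ValueError):
    """Raised for malformed net syntax; the message names the line number."""


class NetStructureError(ValueError):
    """Raised when the fill/gap hierarchy violates containment or alternation."""


@dataclass
class NetNode:
    """One ``fill`` or ``gap`` record plus its nested children.

    ``level`` is the synteny level of a fill (1 for top-level fills, 2 for
    fills nested inside a level-1 fill's gap, ...); it is ``None`` for gaps.
    """

    kind: str  # "fill" | "gap"
    ref_chrom: str
    ref_start: int
    ref_size: int
    query_chrom: str
    query_strand: str  # "+" | "-"
    query_start: int  # on the strand given by query_strand (UCSC convention)
    query_size: int
    level: int | None = None
    attributes: list[tuple[str, str]] = field(default_factory=list)
    children: list["NetNode"] = field(default_factory=list)

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_size

    def walk(self) -> Iterator["NetNode"]:
        """Depth-first traversal in document (reference-coordinate) order."""
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class NetChrom:
    """All top-level fills for one reference chromosome."""

    name: str
    size: int
    fills: list[NetNode] = field(default_factory=list)

    def walk(self) -> Iterator[NetNode]:
        for f in self.fills:
            yield from f.walk()


@dataclass
class NetFile:
    chroms: list[NetChrom] = field(default_factory=list)

    def walk(self) -> Iterator[NetNode]:
        for chrom in self.chroms:
            yield from chrom.walk()


def _indent_of(line: str) -> int:
    # One space per level; tabs tolerated on input (one level each), never emitted.
    n = 0
    for ch in line:
        if ch in (" ", "\t"):
            n += 1
        else:
            break
    return n


def parse_net(source: Union[str, TextIO, Iterable[str]]) -> NetFile:
    """Parse a net file into a :class:`NetFile` tree.

    ``source`` may be a string, an open text handle, or an iterable of lines.
    Raises :class:`NetParseError` for bad syntax and
    :class:`NetStructureError` when a child escapes its parent's reference
    interval or the fill/gap alternation is broken.
    """
    if isinstance(source, str):
        lines: Iterable[str] = io.StringIO(source)
    else:
        lines = source

    net = NetFile()
    chrom: NetChrom | None = None
    # stack[d] = node at indentation depth d (1-based); depth 0 = chromosome header
    stack: list[NetNode | None] = [None]

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        depth = _indent_of(line)
        tokens = line.split()
        kind = tokens[0]

        if kind == "net":
            if depth != 0:
                raise NetParseError(f"line {lineno}: 'net' header must not be indented")
            if len(tokens) < 3:
                raise NetParseError(f"line {lineno}: 'net' header needs a name and a size")
            try:
                size = int(tokens[2])
            except ValueError:
                raise NetParseError(f"line {lineno}: chromosome size is not an integer") from None
            chrom = NetChrom(name=tokens[1], size=size)
            net.chroms.append(chrom)
            stack = [None]
            continue

        if kind not in ("fill", "gap"):
            raise NetParseError(f"line {lineno}: unknown record type {kind!r}")
        if chrom is None:
            raise NetParseError(f"line {lineno}: {kind!r} record before any 'net' header")
        if depth < 1:
            raise NetParseError(f"line {lineno}: {kind!r} record must be indented")
        if depth > len(stack):
            raise NetParseError(
                f"line {lineno}: indentation depth {depth} skips level {len(stack)}"
            )
        if len(tokens) < 7:
            raise NetParseError(f"line {lineno}: expected 6 coordinate fields after {kind!r}")
        try:
            ref_start, ref_size = int(tokens[1]), int(tokens[2])
            query_start, query_size = int(tokens[5]), int(tokens[6])
        except ValueError:
            raise NetParseError(f"line {lineno}: malformed coordinate field") from None
        query_chrom, query_strand = tokens[3], tokens[4]
        if query_strand not in ("+", "-"):
            raise NetParseError(f"line {lineno}: query strand must be '+' or '-'")
        if ref_size < 0 or query_size < 0:
            raise NetParseError(f"line {lineno}: negative span")

        attr_tokens = tokens[7:]
        if len(attr_tokens) % 2:
            raise NetParseError(f"line {lineno}: dangling attribute token {attr_tokens[-1]!r}")
        attributes = [
            (attr_tokens[i], attr_tokens[i + 1]) for i in range(0, len(attr_tokens), 2)
        ]

        node = NetNode(
            kind=kind,
            ref_chrom=chrom.name,
            ref_start=ref_start,
            ref_size=ref_size,
            query_chrom=query_chrom,
            query_strand=query_strand,
            query_start=query_start,
            query_size=query_size,
            level=(depth + 1) // 2 if kind == "fill" else None,
            attributes=attributes,
        )

        parent = stack[depth - 1]
        if parent is None:
            # top of the hierarchy: must be a fill directly under the header
            if kind != "fill":
                raise NetStructureError(f"line {lineno}: top-level record must be a fill")
            if node.ref_end > chrom.size:
                raise NetStructureError(
                    f"line {lineno}: fill end {node.ref_end} exceeds chromosome size {chrom.size}"
                )
            chrom.fills.append(node)
        else:
            if parent.kind == kind:
                raise NetStructureError(
                    f"line {lineno}: a {parent.kind}'s children must alternate kind"
                )
            if node.ref_start < parent.ref_start or node.ref_end > parent.ref_end:
                raise NetStructureError(
                    f"line {lineno}: child interval [{node.ref_start},{node.ref_end}) "
                    f"escapes parent [{parent.ref_start},{parent.ref_end})"
                )
            parent.children.append(node)

        del stack[depth:]
        stack.append(node)

    return net


def _write_node(node: NetNode, depth: int, out: list[str]) -> None:
    fields = [
        node.kind,
        str(node.ref_start),
        str(node.ref_size),
        node.query_chrom,
        node.query_strand,
        str(node.query_start),
        str(node.query_size),
    ]
    for key, value in node.attributes:
        fields.append(key)
        fields.append(value)
    out.append(" " * depth + " ".join(fields))
    for child in node.children:
        _write_node(child, depth + 1, out)


def write_net(net: NetFile) -> str:
    """Serialize a :class:`NetFile` back to net text (round-trips with parse_net)."""
    out: list[str] = []
    for chrom in net.chroms:
        out.append(f"net {chrom.name} {chrom.size}")
        for fill in chrom.fills:
            _write_node(fill, 1, out)
    if not out:
        return ""
    return "\n".join(out) + "\n"


def iter_gap_fill_pairs(net: NetFile) -> Iterator[tuple[NetNode, NetNode]]:
    """Yield every (gap, child fill) pair in reference-coordinate order.

    These pairs are the retrotransposition signature: the gap is sequence
    absent from the query at this locus, and the nested fill re-aligns part
    of it to a (parental) locus elsewhere in the query genome.
    """
    for node in net.walk():
        if node.kind == "gap":
            for child in node.children:
                if child.kind == "fill":
                    yield node, child
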