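"""Gene-order file dialect, PHYLIP matrices and example fixtures.

Gene-order files look like FASTA: a ``>name`` header starts a genome, and
each following line is one chromosome — whitespace-separated signed marker
tokens closed by ``$`` (linear) or ``)`` (circular).  A leading ``-``
reverses a marker.  Example::

    >A
    a b -d $
    >X
    b c z )
    w $
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

from .errors import DuplicateMarkerError, ParseError
from .genome import Chromosome, Genome, genome_from_chromosomes, make_universe

__all__ = [
    "parse_gene_orders",
    "read_gene_orders",
    "write_gene_orders",
    "format_gene_orders",
    "genomes_from_records",
    "fixtures",
]

Record = tuple[str, list[Chromosome]]


def _parse_chromosome(tokens: Sequence[str], lineno: int) -> Chromosome:
    terminator = tokens[-1]
    if terminator not in ("$", ")"):
        raise ParseError(
            f"chromosome must end with '$' or ')', got {terminator!r}", lineno
        )
    body = tokens[:-1]
    if not body:
        raise ParseError("empty chromosome", lineno)
    content = []
    for tok in body:
        if tok in ("$", ")"):
            raise ParseError(f"unexpected terminator {tok!r} inside line", lineno)
        sign = 1
        if tok.startswith("-"):
            sign = -1
            tok = tok[1:]
        if not tok:
            raise ParseError("empty marker token", lineno)
        content.append((tok, sign))
    kind = "linear" if terminator == "$" else "circular"
    return Chromosome(kind, tuple(content))


def parse_gene_orders(text: str) -> list[Record]:
    """Parse the gene-order dialect into (name, chromosomes) records."""
    records: list[Record] = []
    name: str | None = None
    chroms: list[Chromosome] = []
    seen_names: set[str] = set()

    def flush(lineno):
        if name is None:
            return
        if not chroms:
            raise ParseError(f"genome {name!r} has no chromosomes", lineno)
        records.append((name, list(chroms)))

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            flush(lineno)
            name = line[1:].strip()
            if not name:
                raise ParseError("empty genome name", lineno)
            if name in seen_names:
                raise ParseError(f"duplicate genome name {name!r}", lineno)
            seen_names.add(name)
            chroms = []
            continue
        if name is None:
            raise ParseError("content before the first '>' header", lineno)
        chroms.append(_parse_chromosome(line.split(), lineno))
    flush(len(text.splitlines()))
    # duplicate markers within one genome are detected here with a line-less
    # error; genome assembly will re-check, but fail early for clarity
    for gname, gchroms in records:
        seen: set[str] = set()
        for chrom in gchroms:
            for marker, _ in chrom.content:
                if marker in seen:
                    raise ParseError(
                        f"marker {marker!r} repeated in genome {gname!r}"
                    )
                seen.add(marker)
    if not records:
        raise ParseError("no genome records found")
    return records


def read_gene_orders(path) -> list[Record]:
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    try:
        return parse_gene_orders(text)
    except ParseError as exc:
        raise ParseError(f"{os.fspath(path)}: {exc}") from None


def format_gene_orders(records: Iterable[Record]) -> str:
    lines = []
    for name, chroms in records:
        lines.append(f">{name}")
        for chrom in chroms:
            toks = [
                marker if sign > 0 else f"-{marker}"
                for marker, sign in chrom.content
            ]
            toks.append("$" if chrom.kind == "linear" else ")")
            lines.append(" ".join(toks))
    return "\n".join(lines) + "\n"


def write_gene_orders(records: Iterable[Record], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(format_gene_orders(records))


def genomes_from_records(
    records: Sequence[Record],
) -> list[tuple[str, Genome]]:
    """Build genomes over the union universe (marker names sorted)."""
    markers: set[str] = set()
    for _, chroms in records:
        for chrom in chroms:
            markers.update(m for m, _ in chrom.content)
    universe = make_universe(sorted(markers))
    return [
        (name, genome_from_chromosomes(universe, chroms))
        for name, chroms in records
    ]


_FIXTURE_TEXT = {
    # four-marker pair: one marker private to each genome, distance 8
    "abcd": ">A\na b -d $\n>B\nb c d $\n",
    # one-marker replacement: distance 4, indel-only distance 6
    "axy": ">A\na x $\n>B\na y $\n",
    # double replacement with a relocation: distance 8
    "xbcy": ">A\nx b c y $\n>B\nb c z )\nw $\n",
}


def fixtures() -> dict[str, tuple[Genome, Genome]]:
    """Built-in worked-example genome pairs (A, B), each over the union
    universe of its own pair."""
    out = {}
    for key, text in _FIXTURE_TEXT.items():
        genomes = genomes_from_records(parse_gene_orders(text))
        out[key] = (genomes[0][1], genomes[1][1])
    return out
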