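"""Pfam domain annotation reports with boolean keyword querying.

Joins PFAMScan hit tables with the textual domain descriptions from a
``pfamA.txt``-style dump, supports AND/OR/NOT keyword queries over those
descriptions, and renders fasta-like static HTML pages (one index page,
plus one page per contig cluster when a clustering is supplied) together
with a machine-readable TSV twin.

Query semantics: a bare term matches a protein when it is a
case-insensitive substring of any of the protein's domain descriptions or
Pfam ids. Precedence NOT > AND > OR, parentheses allowed, and adjacency
implies AND (``lipase NOT phage`` reads as ``lipase AND NOT phage``). NOT
complements within the universe of annotated proteins; proteins with no
domain hit are outside that universe.
"""

from __future__ import annotations

import html as _html
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "DomainAnnotation",
    "load_pfam_descriptions",
    "parse_pfamscan",
    "parse_query",
    "evaluate_query",
    "render_report",
    "strip_pfam_version",
]

_PFAM_ACC = re.compile(r"^PF\d{5}(\.\d+)?$")
PFAM_URL = "https://pfam.xfam.org/family/{acc}"


@dataclass(frozen=True)
class DomainAnnotation:
    """One PFAMScan domain hit, optionally joined to its description."""

    protein_id: str
    pfam_acc: str
    pfam_id: str
    env_start: int
    env_end: int
    evalue: float
    description: str = ""

    def __post_init__(self) -> None:
        if not _PFAM_ACC.match(self.pfam_acc):
            raise ValueError(f"malformed Pfam accession {self.pfam_acc!r}")
        if self.env_start > self.env_end:
            raise ValueError(
                f"{self.protein_id}/{self.pfam_acc}: env_start > env_end"
            )
        if self.evalue < 0:
            raise ValueError("negative e-value")

    @property
    def display_description(self) -> str:
        return self.description or self.pfam_id


def strip_pfam_version(acc: str) -> str:
    return acc.split(".", 1)[0]


def load_pfam_descriptions(
    path: str | Path,
    col_acc: int = 1,
    col_id: int = 2,
    col_desc: int = 4,
) -> dict[str, tuple[str, str]]:
    """Parse a pfamA.txt-style TSV into acc -> (pfam_id, description).

    Column indices are 1-based and configurable because the dump layout
    varies across Pfam releases. Version suffixes are stripped from
    accessions so hit tables can join regardless of release; a duplicated
    accession keeps the last row seen.
    """
    path = Path(path)
    need = max(col_acc, col_id, col_desc)
    table: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < need:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {need} columns, got {len(parts)}"
                )
            acc = strip_pfam_version(parts[col_acc - 1])
            if not _PFAM_ACC.match(acc):
                raise ValueError(
                    f"{path}:{lineno}: malformed Pfam accession {parts[col_acc - 1]!r}"
                )
            table[acc] = (parts[col_id - 1], parts[col_desc - 1])
    return table


def parse_pfamscan(
    path: str | Path,
    descriptions: Optional[Mapping[str, tuple[str, str]]] = None,
) -> list[DomainAnnotation]:
    """Parse pfam_scan.pl output (whitespace-delimited, ``#`` comments).

    Expected columns: seq id, aln start/end, env start/end, hmm acc, hmm
    name, type, hmm start/end/length, bit score, e-value, ... Passing the
    description table joins descriptions in immediately.
    """
    path = Path(path)
    annotations: list[DomainAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 13:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 13 columns, got {len(parts)}"
                )
            try:
                env_start, env_end = int(parts[3]), int(parts[4])
                evalue = float(parts[12])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            acc = strip_pfam_version(parts[5])
            desc = ""
            if descriptions and acc in descriptions:
                desc = descriptions[acc][1]
            annotations.append(
                DomainAnnotation(
                    protein_id=parts[0],
                    pfam_acc=acc,
                    pfam_id=parts[6],
                    env_start=env_start,
                    env_end=env_end,
                    evalue=evalue,
                    description=desc,
                )
            )
    return annotations


# ---------------------------------------------------------------- queries

class QueryError(ValueError):
    pass


_TOKEN = re.compile(r'\(|\)|"[^"]*"|[^\s()]+')


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens = []
    for m in _TOKEN.finditer(expression):
        tokens.append((m.group(0), m.start()))
    return tokens


class _Node:
    def evaluate(self, matches, universe):  # pragma: no cover - interface
        raise NotImplementedError


@dataclass
class _Term(_Node):
    term: str

    def evaluate(self, matches, universe):
        return matches(self.term)


@dataclass
class _Not(_Node):
    child: _Node

    def evaluate(self, matches, universe):
        return universe - self.child.evaluate(matches, universe)


@dataclass
class _And(_Node):
    left: _Node
    right: _Node

    def evaluate(self, matches, universe):
        return self.left.evaluate(matches, universe) & self.right.evaluate(
            matches, universe
        )


@dataclass
class _Or(_Node):
    left: _Node
    right: _Node

    def evaluate(self, matches, universe):
        return self.left.evaluate(matches, universe) | self.right.evaluate(
            matches, universe
        )


class _Parser:
    """Recursive descent over OR > AND (explicit or by adjacency) > NOT."""

    def __init__(self, expression: str):
        self.tokens = _tokenize(expression)
        self.pos = 0
        self.expression = expression

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def fail(self, message: str) -> None:
        at = (
            self.tokens[self.pos][1]
            if self.pos < len(self.tokens)
            else len(self.expression)
        )
        raise QueryError(f"query syntax error at position {at}: {message}")

    def parse(self) -> _Node:
        if not self.tokens:
            raise QueryError("empty query")
        node = self.parse_or()
        if self.pos != len(self.tokens):
            self.fail(f"unexpected token {self.peek()!r}")
        return node

    def parse_or(self) -> _Node:
        node = self.parse_and()
        while self.peek() is not None and self.peek().upper() == "OR":
            self.next()
            node = _Or(node, self.parse_and())
        return node

    def parse_and(self) -> _Node:
        node = self.parse_not()
        while True:
            tok = self.peek()
            if tok is None or tok == ")" or tok.upper() == "OR":
                return node
            if tok.upper() == "AND":
                self.next()
            node = _And(node, self.parse_not())

    def parse_not(self) -> _Node:
        tok = self.peek()
        if tok is not None and tok.upper() == "NOT":
            self.next()
            return _Not(self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> _Node:
        tok = self.peek()
        if tok is None:
            self.fail("expected a term")
        if tok == "(":
            self.next()
            node = self.parse_or()
            if self.peek() != ")":
                self.fail("expected ')'")
            self.next()
            return node
        if tok == ")" or tok.upper() in ("AND", "OR", "NOT"):
            self.fail(f"expected a term, found {tok!r}")
        term, _ = self.next()
        if term.startswith('"') and term.endswith('"'):
            term = term[1:-1]
        if not term:
            self.fail("empty term")
        return _Term(term)


def parse_query(expression: str) -> _Node:
    """Parse a keyword expression into an evaluable tree."""
    return _Parser(expression).parse()


def evaluate_query(
    expression: str | _Node,
    annotations: Iterable[DomainAnnotation],
) -> set[str]:
    """Protein ids whose domain annotations satisfy the expression.

    A term matches a protein when it is a case-insensitive substring of
    any domain's description or Pfam id; NOT complements within the set
    of annotated proteins.
    """
    node = parse_query(expression) if isinstance(expression, str) else expression
    texts: dict[str, list[str]] = {}
    for a in annotations:
        texts.setdefault(a.protein_id, []).append(
            f"{a.display_description}\t{a.pfam_id}".lower()
        )
    universe = set(texts)

    def matches(term: str) -> set[str]:
        needle = term.lower()
        return {p for p, ts in texts.items() if any(needle in t for t in ts)}

    return node.evaluate(matches, universe)


# ---------------------------------------------------------------- rendering

_PAGE = """<!DOCTYPE html>
<html>
<head><meta charset="utf-8"><title>{title}</title></head>
<body>
<h1>{title}</h1>
{nav}
<pre>
{body}
</pre>
</body>
</html>
"""


def _domain_summary(annots: Sequence[DomainAnnotation]) -> str:
    if not annots:
        return "no domain detected"
    parts = []
    for a in sorted(annots, key=lambda x: (x.env_start, x.pfam_acc)):
        url = PFAM_URL.format(acc=a.pfam_acc)
        parts.append(
            f'<a href="{url}">{a.pfam_acc}</a> {_html.escape(a.pfam_id)} '
            f"[{a.env_start}-{a.env_end}] {_html.escape(a.display_description)}"
        )
    return " | ".join(parts)


def _fasta_like(
    protein_ids: Sequence[str],
    sequences: Mapping[str, str],
    by_protein: Mapping[str, list[DomainAnnotation]],
    width: int = 60,
) -> str:
    chunks = []
    for pid in protein_ids:
        seq = sequences[pid]
        header = f"&gt;{_html.escape(pid)}  {_domain_summary(by_protein.get(pid, []))}"
        body = "\n".join(seq[i : i + width] for i in range(0, len(seq), width))
        chunks.append(f"{header}\n{body}\n")
    return "\n".join(chunks)


def render_report(
    sequences: Mapping[str, str],
    annotations: Sequence[DomainAnnotation],
    out_dir: str | Path,
    clusters: Optional[Mapping[str, str]] = None,
    query: Optional[str] = None,
    title: str = "Pfam domain report",
) -> dict[str, Path]:
    """Write the fasta-like HTML report and its TSV twin.

    ``sequences`` maps protein id -> amino-acid sequence; ``clusters``
    (protein id -> cluster name), when given, adds one page per cluster
    with a hyperlink index at the top of the main page. A ``query``
    restricts the report to matching proteins. Returns the paths written,
    keyed by page name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for a in annotations:
        if a.protein_id not in sequences:
            raise ValueError(
                f"annotation references protein {a.protein_id!r} with no sequence"
            )
        by_protein.setdefault(a.protein_id, []).append(a)

    selected = sorted(sequences)
    if query is not None:
        keep = evaluate_query(query, annotations)
        selected = [p for p in selected if p in keep]

    written: dict[str, Path] = {}
    nav = ""
    if clusters is not None:
        names = sorted({clusters.get(p, "unclustered") for p in selected})
        links = " | ".join(
            f'<a href="cluster_{_safe(n)}.html">{_html.escape(n)}</a>' for n in names
        )
        nav = f"<p>Clusters: {links}</p>"
        for name in names:
            members = [p for p in selected if clusters.get(p, "unclustered") == name]
            page = out_dir / f"cluster_{_safe(name)}.html"
            page.write_text(
                _PAGE.format(
                    title=f"{title} — cluster {_html.escape(name)}",
                    nav='<p><a href="index.html">back to index</a></p>',
                    body=_fasta_like(members, sequences, by_protein),
                )
            )
            written[f"cluster_{name}"] = page

    index = out_dir / "index.html"
    index.write_text(
        _PAGE.format(
            title=title, nav=nav, body=_fasta_like(selected, sequences, by_protein)
        )
    )
    written["index"] = index

    tsv = out_dir / "report.tsv"
    with open(tsv, "w") as fh:
        fh.write(
            "protein_id\tcluster\tpfam_acc\tpfam_id\tenv_start\tenv_end\t"
            "evalue\tdescription\n"
        )
        for pid in selected:
            cluster = clusters.get(pid, "unclustered") if clusters else ""
            annots = by_protein.get(pid, [])
            if not annots:
                fh.write(f"{pid}\t{cluster}\t\t\t\t\t\tno domain detected\n")
            for a in sorted(annots, key=lambda x: (x.env_start, x.pfam_acc)):
                fh.write(
                    f"{pid}\t{cluster}\t{a.pfam_acc}\t{a.pfam_id}\t"
                    f"{a.env_start}\t{a.env_end}\t{a.evalue:g}\t"
                    f"{a.display_description}\n"
                )
    written["tsv"] = tsv
    return written


def _safe(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]", "_", name)
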