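"""Fingerprint motif grammar, scanning and discovery.

The curation filter requires a candidate NifB protein to carry six short
conserved motifs of the SAM-radical domain — HPC, the AdoMet cysteine triad
Cx3Cx2C, ExRP, AGPG, TxTxN and Cx2CRxDAxG — in N-to-C order.  Patterns use a
minimal grammar: an uppercase letter matches exactly that residue, ``x``
matches any single residue (including the unknown code ``X``), and an integer
immediately after ``x`` repeats the wildcard, so ``Cx3Cx2C`` spans eight
residues.  A literal never matches ``X``: an unknown residue cannot confirm a
strictly conserved position.

Coordinates in all hits and reports are 1-based and inclusive on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .core_io import ProteinRecord

# ---------------------------------------------------------------------------
# Pattern grammar
# ---------------------------------------------------------------------------

#: Token kinds.
LITERAL = "LITERAL"
WILDCARD = "WILDCARD"


@dataclass(frozen=True)
class Token:
    kind: str
    value: str = ""   # residue letter for literals
    count: int = 1    # repeat count for wildcards


@dataclass(frozen=True)
class MotifPattern:
    """A parsed motif pattern with its total residue span."""

    name: str
    tokens: tuple[Token, ...]
    text: str = ""

    @property
    def span(self) -> int:
        return sum(1 if t.kind == LITERAL else t.count for t in self.tokens)

    @property
    def n_literals(self) -> int:
        return sum(1 for t in self.tokens if t.kind == LITERAL)


@dataclass(frozen=True)
class MotifHit:
    """One placement of a pattern on a sequence (1-based, inclusive)."""

    pattern_name: str
    start: int
    end: int
    matched: str


def parse_pattern(text: str, name: str | None = None) -> MotifPattern:
    """Parse pattern ``text`` (e.g. ``"Cx3Cx2C"``) into a :class:`MotifPattern`.

    Raises ``ValueError`` ("pattern syntax error") with the offending position
    on an empty string, a lowercase letter other than ``x``, a digit that does
    not follow ``x``, or a wildcard count below 1.
    """
    if not text:
        raise ValueError("pattern syntax error: empty pattern")
    tokens: list[Token] = []
    i = 0
    has_literal = False
    while i < len(text):
        ch = text[i]
        if ch.isupper() and ch.isalpha():
            tokens.append(Token(LITERAL, value=ch))
            has_literal = True
            i += 1
        elif ch == "x":
            j = i + 1
            while j < len(text) and text[j].isdigit():
                j += 1
            count = int(text[i + 1 : j]) if j > i + 1 else 1
            if count < 1:
                raise ValueError(
                    f"pattern syntax error at position {i + 1}: "
                    "wildcard count must be >= 1"
                )
            tokens.append(Token(WILDCARD, count=count))
            i = j
        else:
            raise ValueError(
                f"pattern syntax error at position {i + 1}: unexpected {ch!r}"
            )
    if not has_literal:
        raise ValueError("pattern syntax error: pattern needs at least one literal")
    return MotifPattern(name=name or text, tokens=tuple(tokens), text=text)


def pattern_to_text(pattern: MotifPattern) -> str:
    """Render a pattern back to grammar text."""
    parts: list[str] = []
    for tok in pattern.tokens:
        if tok.kind == LITERAL:
            parts.append(tok.value)
        else:
            parts.append("x" if tok.count == 1 else f"x{tok.count}")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Fingerprint
# ---------------------------------------------------------------------------

#: The six conserved SAM-radical motifs, in N-to-C order.
DEFAULT_MOTIF_TEXTS = ("HPC", "Cx3Cx2C", "ExRP", "AGPG", "TxTxN", "Cx2CRxDAxG")


@dataclass(frozen=True)
class Fingerprint:
    """An ordered collection of motif patterns."""

    patterns: tuple[MotifPattern, ...]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("empty fingerprint")
        names = [p.name for p in self.patterns]
        if len(set(names)) != len(names):
            raise ValueError("fingerprint pattern names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)


def default_fingerprint() -> Fingerprint:
    """The six-motif NifB fingerprint."""
    return Fingerprint(tuple(parse_pattern(t) for t in DEFAULT_MOTIF_TEXTS))


def read_fingerprint(path: str | Path) -> Fingerprint:
    """Read a fingerprint definition file (one ``name<TAB>pattern`` per line)."""
    patterns: list[MotifPattern] = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln.strip() or ln.startswith("#"):
                continue
            name, _, text = ln.partition("\t")
            if not text:
                raise ValueError(f"malformed fingerprint line {ln!r}")
            patterns.append(parse_pattern(text.strip(), name.strip()))
    return Fingerprint(tuple(patterns))


def write_fingerprint(fingerprint: Fingerprint, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in fingerprint.patterns:
            fh.write(f"{p.name}\t{pattern_to_text(p)}\n")


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _matches_at(sequence: str, pattern: MotifPattern, offset: int) -> bool:
    """Does the pattern match at 0-based ``offset``?"""
    pos = offset
    for tok in pattern.tokens:
        if tok.kind == LITERAL:
            if sequence[pos] != tok.value:
                return False
            pos += 1
        else:
            pos += tok.count
    return True


def scan(sequence: str, pattern: MotifPattern) -> list[MotifHit]:
    """All occurrences of ``pattern`` in ``sequence``, left to right.

    Overlapping occurrences are all reported.  A sequence shorter than the
    pattern span yields an empty list.
    """
    span = pattern.span
    hits: list[MotifHit] = []
    for off in range(len(sequence) - span + 1):
        if _matches_at(sequence, pattern, off):
            hits.append(
                MotifHit(pattern.name, off + 1, off + span,
                         sequence[off : off + span])
            )
    return hits


# ---------------------------------------------------------------------------
# Ordered fingerprint matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FingerprintResult:
    """Per-record verdict of the fingerprint filter."""

    record_id: str
    passed: bool
    hits: tuple[MotifHit, ...]
    missing: tuple[str, ...]


def _greedy_place(sequence: str, fingerprint: Fingerprint
                  ) -> tuple[list[MotifHit], list[str]]:
    hits: list[MotifHit] = []
    missing: list[str] = []
    cursor = 0  # 0-based index after which the next motif may start
    for pat in fingerprint.patterns:
        placed = None
        for off in range(cursor, len(sequence) - pat.span + 1):
            if _matches_at(sequence, pat, off):
                placed = MotifHit(pat.name, off + 1, off + pat.span,
                                  sequence[off : off + pat.span])
                break
        if placed is None:
            missing.append(pat.name)
        else:
            hits.append(placed)
            cursor = placed.end  # next motif starts strictly after this end
    return hits, missing


def _backtrack_place(sequence: str, patterns: Sequence[MotifPattern],
                     cursor: int) -> list[MotifHit] | None:
    """Leftmost-first complete ordered placement, or None."""
    if not patterns:
        return []
    pat = patterns[0]
    for off in range(cursor, len(sequence) - pat.span + 1):
        if _matches_at(sequence, pat, off):
            rest = _backtrack_place(sequence, patterns[1:], off + pat.span)
            if rest is not None:
                hit = MotifHit(pat.name, off + 1, off + pat.span,
                               sequence[off : off + pat.span])
                return [hit] + rest
    return None


def _compact_rightward(sequence: str, fingerprint: Fingerprint,
                       hits: list[MotifHit]) -> list[MotifHit]:
    """Move hits to their rightmost feasible occurrences, keeping the last.

    The leftmost pass decides *whether* an ordered placement exists; this
    pass localizes it tightly by maximizing every start position subject to
    the ordering constraint, so a spurious early occurrence of the first
    motif (e.g. inside an N-terminal homology domain) cannot inflate the
    inferred domain span.
    """
    out = list(hits)
    for i in range(len(out) - 2, -1, -1):
        pat = fingerprint.patterns[i]
        limit = out[i + 1].start  # this hit must end strictly before it
        floor = out[i].start      # never move left of the leftmost placement
        best = out[i]
        for cand in scan(sequence, pat):
            if cand.end < limit and cand.start >= floor:
                best = cand
        out[i] = best
    return out


def match_fingerprint(
    record: ProteinRecord,
    fingerprint: Fingerprint,
    *,
    ordered: bool = True,
    backtrack: bool = True,
    compact: bool = False,
) -> FingerprintResult:
    """Test a record against a fingerprint.

    In ordered mode (default) each pattern must be placed strictly after the
    end of the previous pattern's chosen hit; placement is greedy leftmost,
    with a backtracking fallback that rescues the rare adversarial overlap
    where greedy fails but a valid ordered placement exists.  In unordered
    mode each pattern only needs at least one hit anywhere.  With
    ``compact=True`` a passing ordered placement is re-packed rightward for
    tight domain localization (the verdict itself never changes).
    """
    if not ordered:
        hits: list[MotifHit] = []
        missing: list[str] = []
        for pat in fingerprint.patterns:
            found = scan(record.sequence, pat)
            if found:
                hits.append(found[0])
            else:
                missing.append(pat.name)
        return FingerprintResult(record.id, not missing, tuple(hits),
                                 tuple(missing))

    hits, missing = _greedy_place(record.sequence, fingerprint)
    if missing and backtrack:
        full = _backtrack_place(record.sequence, fingerprint.patterns, 0)
        if full is not None:
            hits, missing = full, []
    if compact and not missing:
        hits = _compact_rightward(record.sequence, fingerprint, hits)
    return FingerprintResult(record.id, not missing, tuple(hits),
                             tuple(missing))


# ---------------------------------------------------------------------------
# Motif discovery from an alignment of validated proteins
# ---------------------------------------------------------------------------

def discover_fingerprint(
    rows: Sequence[tuple[str, str]] | Sequence[str],
    min_conservation: float = 1.0,
    min_motif_len: int = 2,
    max_wildcard_run: int = 3,
) -> list[MotifPattern]:
    """Derive conserved motif patterns from an alignment of trusted proteins.

    A column is *conserved* when a single residue's frequency (computed over
    all rows; columns containing any gap are never conserved) reaches
    ``min_conservation`` and the column is gap-free.  Maximal runs mixing
    conserved columns (emitted as literals) with at most ``max_wildcard_run``
    consecutive non-conserved gap-free columns (emitted as wildcards) become
    candidate patterns; each pattern must start and end on a literal and
    contain at least ``min_motif_len`` literals.  The default wildcard-run
    cap of 3 is the smallest value able to represent the AdoMet Cx3Cx2C triad.

    ``rows`` may be ``(id, sequence)`` pairs or bare aligned strings.
    """
    seqs = [r[1] if isinstance(r, tuple) else r for r in rows]
    if len(seqs) < 2:
        raise ValueError("insufficient sequences: need at least 2 rows")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("not an alignment: rows differ in length")
    if not (0.0 < min_conservation <= 1.0):
        raise ValueError("min_conservation must be in (0, 1]")

    n = len(seqs)
    # Column classification: literal residue, wildcard-able, or break.
    col_kind: list[str] = []       # "LIT", "WILD", "BREAK"
    col_residue: list[str] = []
    for j in range(length):
        column = [s[j] for s in seqs]
        if "-" in column:
            col_kind.append("BREAK")
            col_residue.append("")
            continue
        # ties broken toward the alphabetically smallest residue (ties can
        # only occur when min_conservation <= 0.5)
        best = min(set(column), key=lambda r: (-column.count(r), r))
        if column.count(best) / n >= min_conservation:
            col_kind.append("LIT")
            col_residue.append(best)
        else:
            col_kind.append("WILD")
            col_residue.append("")

    patterns: list[MotifPattern] = []

    def emit(start: int, end: int) -> None:
        # trim flanks to literals
        while start <= end and col_kind[start] != "LIT":
            start += 1
        while end >= start and col_kind[end] != "LIT":
            end -= 1
        if start > end:
            return
        n_lit = sum(1 for j in range(start, end + 1) if col_kind[j] == "LIT")
        if n_lit < min_motif_len:
            return
        text_parts: list[str] = []
        j = start
        while j <= end:
            if col_kind[j] == "LIT":
                text_parts.append(col_residue[j])
                j += 1
            else:
                k = j
                while k <= end and col_kind[k] == "WILD":
                    k += 1
                run = k - j
                text_parts.append("x" if run == 1 else f"x{run}")
                j = k
        text = "".join(text_parts)
        patterns.append(parse_pattern(text))

    # Split at BREAK columns and at wildcard runs longer than max_wildcard_run.
    seg_start = None
    wild_run = 0
    for j in range(length + 1):
        kind = col_kind[j] if j < length else "BREAK"
        if kind == "BREAK" or (kind == "WILD" and wild_run + 1 > max_wildcard_run):
            if seg_start is not None:
                emit(seg_start, j - 1)
                seg_start = None
            wild_run = 0
            # a too-long wildcard run keeps breaking until the next literal
            if kind == "WILD":
                wild_run = max_wildcard_run + 1
        else:
            if kind == "WILD":
                wild_run += 1
            else:
                wild_run = 0
            if seg_start is None and kind == "LIT":
                seg_start = j
    return patterns
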