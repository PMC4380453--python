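"""Scanning of ADAM cytosolic tails for SH3 target motifs.

SH3 domains recognize short proline-rich motifs.  The canonical consensus
sequences are class I (``+ΦPxxP``) and class II (``PxΦPx+``), where ``+``
is K or R, ``Φ`` a hydrophobic residue and ``x`` any residue; atypical
motifs such as ``PxxDY`` (Eps8 family) and high-affinity specials such as
``RxAPxxP`` (SNX9) or ``RxLPxxP`` (nephrocystin) follow the same grammar
with literal positions.  This module compiles such pattern strings into
position-set automata, scans tail sequences exhaustively (overlapping
matches included), merges hits into proline clusters numbered with Roman
numerals from the transmembrane end, and tiles clusters into 14-17-mer
peptides suitable for array synthesis.

Coordinates are 1-based with inclusive ends, relative to the first residue
of the tail (not the full-length protein).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

from Bio import SeqIO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Default hydrophobic residue set for the Φ wildcard.  A deliberate
#: superset of common definitions (includes P and Y) to err toward
#: sensitivity; configurable in :func:`compile_pattern`.
HYDROPHOBIC = frozenset("AVLIMFWYP")

BASIC = frozenset("KR")

_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
    (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
    (5, "V"), (4, "IV"), (1, "I"),
]


def roman(n: int) -> str:
    """Roman numeral for a positive integer (cluster indexing)."""
    if n <= 0:
        raise ValueError("Roman numerals are defined for positive integers")
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


@dataclass(frozen=True)
class ProteinTail:
    """A cytosolic tail sequence with identifier and provenance note."""

    id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = [(i + 1, c) for i, c in enumerate(self.sequence) if c not in AMINO_ACIDS]
        if bad:
            pos, char = bad[0]
            raise ValueError(
                f"{self.id}: non-amino-acid character {char!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifPattern:
    """A compiled motif: an ordered list of allowed-residue sets."""

    name: str
    positions: tuple[frozenset[str], ...]
    class_tag: str = "custom"

    def __post_init__(self) -> None:
        if len(self.positions) < 4:
            raise ValueError(f"{self.name}: motif length must be >= 4")
        if any(not p for p in self.positions):
            raise ValueError(f"{self.name}: empty position set")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class MotifHit:
    """One motif match on one tail; 1-based inclusive coordinates."""

    tail_id: str
    pattern_name: str
    start: int
    end: int
    matched: str


@dataclass(frozen=True)
class ProlineCluster:
    """A run of merged motif hits, numbered I, II, ... from the N-terminus."""

    tail_id: str
    index: str
    start: int
    end: int
    hit_count: int


@dataclass(frozen=True)
class Peptide:
    """A cluster-derived array peptide (verbatim tail substring)."""

    name: str
    tail_id: str
    start: int
    end: int
    sequence: str
    short: bool = False  # tail shorter than the minimum peptide length


def parse_tails(handle: IO[str] | str) -> list[ProteinTail]:
    """Read tail sequences from FASTA.

    A single trailing ``*`` stop marker per record is stripped; any other
    non-standard residue raises ``ValueError`` naming the record and the
    1-based offending position.
    """
    records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise ValueError("empty FASTA input: no records found")
    tails = []
    for rec in records:
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        tails.append(ProteinTail(id=rec.id, sequence=seq, source=rec.description))
    return tails


_CLASS_TAGS = {"classI": "classI", "classII": "classII", "PxxDY": "atypical"}


def compile_pattern(
    spec: str,
    name: str | None = None,
    hydrophobic: Iterable[str] = HYDROPHOBIC,
) -> MotifPattern:
    """Compile a motif string into a :class:`MotifPattern`.

    Symbols: an uppercase residue letter is a literal; ``+`` matches K or R;
    ``Φ`` (ASCII alias ``h``) matches the hydrophobic set; ``x`` matches any
    residue.  Unknown symbols raise ``ValueError``.
    """
    name = name if name is not None else spec
    hydro = frozenset(hydrophobic)
    positions: list[frozenset[str]] = []
    for i, sym in enumerate(spec):
        if sym == "x":
            positions.append(AMINO_ACIDS)
        elif sym == "+":
            positions.append(BASIC)
        elif sym in ("Φ", "φ", "h"):
            positions.append(hydro)
        elif sym in AMINO_ACIDS:
            positions.append(frozenset(sym))
        else:
            raise ValueError(f"unknown motif symbol {sym!r} at position {i + 1} of {spec!r}")
    return MotifPattern(name=name, positions=tuple(positions),
                        class_tag=_CLASS_TAGS.get(name, "custom"))


def load_patterns(source: IO[str] | str | dict,
                  hydrophobic: Iterable[str] = HYDROPHOBIC) -> list[MotifPattern]:
    """Load a name -> spec-string mapping (YAML stream/path or dict)."""
    import yaml

    if isinstance(source, dict):
        mapping = source
    elif isinstance(source, str):
        with open(source) as fh:
            mapping = yaml.safe_load(fh)
    else:
        mapping = yaml.safe_load(source)
    return [compile_pattern(spec, name=name, hydrophobic=hydrophobic)
            for name, spec in mapping.items()]


def default_patterns() -> list[MotifPattern]:
    """The shipped default grammar: class I/II, PxxDY and the named specials."""
    from importlib.resources import files

    return load_patterns(str(files("sh3screen.data") / "patterns.yaml"))


def _pattern_regex(pattern: MotifPattern) -> re.Pattern[str]:
    parts = []
    for pos in pattern.positions:
        if pos == AMINO_ACIDS:
            parts.append(".")
        elif len(pos) == 1:
            parts.append(next(iter(pos)))
        else:
            parts.append("[" + "".join(sorted(pos)) + "]")
    # lookahead so that overlapping matches are all reported
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_motifs(tail: ProteinTail, patterns: Sequence[MotifPattern]) -> list[MotifHit]:
    """Exhaustive window scan of one tail against every pattern.

    All matches are reported, overlapping ones included; duplicates on the
    same (start, pattern) pair are impossible by construction.  Hits are
    sorted by (start, pattern_name).
    """
    hits: list[MotifHit] = []
    for pattern in patterns:
        rx = _pattern_regex(pattern)
        for m in rx.finditer(tail.sequence):
            start = m.start() + 1
            end = start + len(pattern) - 1
            hits.append(MotifHit(tail.id, pattern.name, start, end, m.group(1)))
    hits.sort(key=lambda h: (h.start, h.pattern_name))
    return hits


def find_clusters(hits: Sequence[MotifHit], tail: ProteinTail,
                  gap_merge: int = 8) -> list[ProlineCluster]:
    """Merge motif hits into proline clusters.

    Hits whose spans are separated by at most ``gap_merge`` residues are
    merged into one cluster; clusters are numbered I, II, ... from the
    N-terminus.  A hit referencing a different tail raises ``ValueError``.
    """
    for h in hits:
        if h.tail_id != tail.id:
            raise ValueError(f"hit on {h.tail_id!r} does not belong to tail {tail.id!r}")
    spans = sorted((h.start, h.end) for h in hits)
    merged: list[list[int]] = []  # [start, end, count]
    for start, end in spans:
        if merged and start - merged[-1][1] - 1 <= gap_merge:
            merged[-1][1] = max(merged[-1][1], end)
            merged[-1][2] += 1
        else:
            merged.append([start, end, 1])
    return [
        ProlineCluster(tail.id, roman(i + 1), start, end, count)
        for i, (start, end, count) in enumerate(merged)
    ]


def _peptide_prefix(tail_id: str) -> str:
    return "A" + tail_id[4:] if tail_id.upper().startswith("ADAM") else tail_id


def tile_peptides(cluster: ProlineCluster, tail: ProteinTail,
                  min_len: int = 14, max_len: int = 17, flank: int = 4,
                  min_overlap: int = 7) -> list[Peptide]:
    """Tile one proline cluster into 14-17-mer array peptides.

    The cluster is padded with ``flank`` residues on each side (clipped at
    the tail termini).  If the padded region fits in ``max_len`` a single
    centered peptide is emitted, extended to ``min_len`` where the tail
    allows; longer regions are tiled left to right with at least
    ``min_overlap`` residues of overlap so no motif is split without
    appearing whole in some tile.  Multi-tile clusters get suffixes a, b, c
    after the Roman numeral (e.g. ``A12-IIIb``).
    """
    if not (cluster.tail_id == tail.id and 1 <= cluster.start <= cluster.end <= len(tail)):
        raise ValueError(f"cluster {cluster.index} is not valid on tail {tail.id}")
    n = len(tail)
    prefix = f"{_peptide_prefix(tail.id)}-{cluster.index}"

    def cut(start: int, end: int, suffix: str = "", short: bool = False) -> Peptide:
        return Peptide(prefix + suffix, tail.id, start, end,
                       tail.sequence[start - 1:end], short=short)

    if n < min_len:
        return [cut(1, n, short=True)]

    start = max(1, cluster.start - flank)
    end = min(n, cluster.end + flank)
    region = end - start + 1

    if region <= max_len:
        # single peptide; grow symmetrically to min_len where possible
        while end - start + 1 < min_len:
            if start > 1:
                start -= 1
            if end - start + 1 < min_len and end < n:
                end += 1
        return [cut(start, end)]

    length = max_len
    step = length - min_overlap
    ntiles = -(-(region - length) // step) + 1  # ceil division
    # distribute tiles evenly so the last one ends exactly at the region end
    peptides = []
    for i in range(ntiles):
        if ntiles == 1:
            s = start
        else:
            s = start + round(i * (region - length) / (ntiles - 1))
        suffix = chr(ord("a") + i)
        peptides.append(cut(s, s + length - 1, suffix))
    return peptides


def tile_all(tails: Sequence[ProteinTail], patterns: Sequence[MotifPattern],
             gap_merge: int = 8, **tile_kwargs) -> dict[str, list[Peptide]]:
    """Scan, cluster and tile every tail; returns peptides keyed by tail id."""
    out: dict[str, list[Peptide]] = {}
    for tail in tails:
        hits = scan_motifs(tail, patterns)
        peptides: list[Peptide] = []
        for cluster in find_clusters(hits, tail, gap_merge=gap_merge):
            peptides.extend(tile_peptides(cluster, tail, **tile_kwargs))
        out[tail.id] = peptides
    return out


def hits_to_tsv(hits: Sequence[MotifHit]) -> str:
    """TSV hit table (tail_id, pattern, start, end, matched)."""
    lines = ["tail_id\tpattern\tstart\tend\tmatched"]
    lines += [f"{h.tail_id}\t{h.pattern_name}\t{h.start}\t{h.end}\t{h.matched}"
              for h in hits]
    return "\n".join(lines) + "\n"


def clusters_to_tsv(clusters: Sequence[ProlineCluster]) -> str:
    lines = ["tail_id\tindex\tstart\tend\thit_count"]
    lines += [f"{c.tail_id}\t{c.index}\t{c.start}\t{c.end}\t{c.hit_count}"
              for c in clusters]
    return "\n".join(lines) + "\n"


def peptides_to_fasta(peptides: Sequence[Peptide]) -> str:
    out = []
    for p in peptides:
        flag = " short" if p.short else ""
        out.append(f">{p.name} {p.tail_id}:{p.start}-{p.end}{flag}\n{p.sequence}")
    return "\n".join(out) + "\n"
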