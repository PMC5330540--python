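"""Stockholm reading/writing for structurally annotated seed alignments.

Only the subset needed by the bundled tRNA-Sec seeds is supported: a
single alignment per file, one ``#=GC SS_cons`` consensus-structure line
(WUSS bracket subset), an optional ``#=GF DOMAIN`` tag and an optional
``#=GF POS`` line carrying one whitespace-separated tRNA position label
per column (labels such as ``5a`` are multi-character, which is why they
cannot live on a per-column ``#=GC`` line).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from secscan.alphabet import GAP_CHARS, NT_INDEX

WUSS_OPEN = "<([{"
WUSS_CLOSE = ">)]}"
WUSS_UNPAIRED = ".,_-:~"

DOMAINS = ("bacteria", "archaea", "eukaryota")


class StockholmFormatError(ValueError):
    """Raised for malformed Stockholm input."""


@dataclass
class SeedAlignment:
    """A structurally annotated multiple alignment used for model training.

    sequences : list of (id, aligned string) rows, all the same length
    consensus_structure : WUSS-subset string, same length as the rows
    position_labels : per-column tRNA position label or None
    domain_tag : 'bacteria' | 'archaea' | 'eukaryota' | None
    """

    sequences: list[tuple[str, str]]
    consensus_structure: str
    position_labels: list[str | None] | None = None
    domain_tag: str | None = None
    name: str | None = None
    _pairs: list[tuple[int, int]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise StockholmFormatError("alignment has no sequences")
        ncol = len(self.consensus_structure)
        for sid, row in self.sequences:
            if len(row) != ncol:
                raise StockholmFormatError(
                    f"row {sid!r} length {len(row)} != structure length {ncol}"
                )
            for ch in row.upper():
                if ch not in NT_INDEX and ch not in GAP_CHARS:
                    raise StockholmFormatError(f"row {sid!r}: bad character {ch!r}")
        if self.position_labels is not None and len(self.position_labels) != ncol:
            raise StockholmFormatError("position-label line length mismatch")
        if self.domain_tag is not None and self.domain_tag not in DOMAINS:
            raise StockholmFormatError(f"unknown domain tag {self.domain_tag!r}")
        self._pairs = parse_wuss(self.consensus_structure)

    @property
    def ncol(self) -> int:
        return len(self.consensus_structure)

    @property
    def nseq(self) -> int:
        return len(self.sequences)

    def pair_partner(self) -> dict[int, int]:
        """Column->column involution from the consensus structure."""
        out: dict[int, int] = {}
        for i, j in self._pairs:
            out[i] = j
            out[j] = i
        return out

    def match_columns(self, gap_fraction: float = 0.5) -> list[int]:
        """Columns where fewer than ``gap_fraction`` of rows are gaps."""
        cols = []
        for c in range(self.ncol):
            gaps = sum(1 for _, row in self.sequences if row[c] in GAP_CHARS)
            if gaps / self.nseq < gap_fraction:
                cols.append(c)
        return cols


def parse_wuss(structure: str) -> list[tuple[int, int]]:
    """Return base-pair columns (i<j) of a nested WUSS-subset string."""
    stacks: dict[str, list[int]] = {c: [] for c in WUSS_OPEN}
    pairs = []
    for idx, ch in enumerate(structure):
        if ch in WUSS_OPEN:
            stacks[ch].append(idx)
        elif ch in WUSS_CLOSE:
            opener = WUSS_OPEN[WUSS_CLOSE.index(ch)]
            if not stacks[opener]:
                raise StockholmFormatError(
                    f"unbalanced structure: unmatched {ch!r} at column {idx}"
                )
            pairs.append((stacks[opener].pop(), idx))
        elif ch not in WUSS_UNPAIRED:
            raise StockholmFormatError(f"bad WUSS character {ch!r} at column {idx}")
    for opener, stack in stacks.items():
        if stack:
            raise StockholmFormatError(
                f"unbalanced structure: unmatched {opener!r} at column {stack[-1]}"
            )
    pairs.sort()
    # reject pseudoknots (crossing pairs); the subset is strictly nested
    open_close = sorted(pairs)
    for a, b in open_close:
        for c, d in open_close:
            if a < c < b < d:
                raise StockholmFormatError("crossing base pairs are not supported")
    return pairs


def parse_stockholm(text: str) -> SeedAlignment:
    """Parse a single-alignment Stockholm document into a SeedAlignment."""
    seqs: dict[str, list[str]] = {}
    order: list[str] = []
    ss_parts: list[str] = []
    domain = None
    poslabels = None
    name = None
    for raw in text.splitlines():
        line = raw.rstrip()
        if not line or line.startswith("# STOCKHOLM"):
            continue
        if line == "//":
            break
        if line.startswith("#=GC SS_cons"):
            ss_parts.append(line.split(None, 2)[2])
        elif line.startswith("#=GF DOMAIN"):
            domain = line.split(None, 2)[2].strip()
        elif line.startswith("#=GF ID"):
            name = line.split(None, 2)[2].strip()
        elif line.startswith("#=GF POS"):
            poslabels = [t if t != "." else None for t in line.split()[2:]]
        elif line.startswith("#"):
            continue
        else:
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise StockholmFormatError(f"malformed sequence line: {line!r}")
            sid, chunk = parts
            if sid not in seqs:
                seqs[sid] = []
                order.append(sid)
            seqs[sid].append(chunk.replace(" ", ""))
    if not ss_parts:
        raise StockholmFormatError("missing #=GC SS_cons consensus structure line")
    return SeedAlignment(
        sequences=[(sid, "".join(seqs[sid])) for sid in order],
        consensus_structure="".join(ss_parts),
        position_labels=poslabels,
        domain_tag=domain,
        name=name,
    )


def write_stockholm(aln: SeedAlignment) -> str:
    width = max(len(sid) for sid, _ in aln.sequences)
    width = max(width, len("#=GC SS_cons"))
    lines = ["# STOCKHOLM 1.0"]
    if aln.name:
        lines.append(f"#=GF ID {aln.name}")
    if aln.domain_tag:
        lines.append(f"#=GF DOMAIN {aln.domain_tag}")
    if aln.position_labels is not None:
        toks = [lbl if lbl is not None else "." for lbl in aln.position_labels]
        lines.append("#=GF POS " + " ".join(toks))
    for sid, row in aln.sequences:
        lines.append(f"{sid:<{width}} {row}")
    lines.append(f"{'#=GC SS_cons':<{width}} {aln.consensus_structure}")
    lines.append("//")
    return "\n".join(lines) + "\n"
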