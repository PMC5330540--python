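"""Genome scanning with covariance models and overlap resolution.

Every start position on both strands is evaluated with a glocal CYK over
a span band of W = consensus length + 30 (exhaustive at desk scale; a
`stride` option subsamples starts for very large inputs).  Hits at or
above the bit-score threshold are reported in forward-strand
coordinates; overlapping same-strand hits are then collapsed, keeping
for each locus only the highest-scoring hit, which also assigns the
domain label when several models find the same locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from secscan.alphabet import encode, revcomp
from secscan.cmcore.cyk import Parse, score_sequence, window_scores
from secscan.cmcore.model import CovarianceModel

logger = logging.getLogger(__name__)

DOMAIN_PRIORITY = {"eukaryota": 0, "bacteria": 1, "archaea": 2, None: 3}

MIN_CONTIG = 30          # shorter contigs cannot hold any plausible parse
CHUNK = 4000             # scanning chunk length (plus one window of overlap)


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a contig's forward strand."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.contig == other.contig and self.strand == other.strand
                and self.start < other.end and other.start < self.end)


@dataclass
class Hit:
    """A scored model match at a genomic locus."""

    interval: GenomicInterval
    domain_tag: str | None
    bit_score: float
    matched_sequence: str               # in hit (strand) orientation
    model: CovarianceModel = field(repr=False, default=None)
    _parse: Parse | None = field(default=None, repr=False)

    @property
    def parse(self) -> Parse:
        """Model alignment of the matched sequence (computed on demand)."""
        if self._parse is None:
            _, self._parse = score_sequence(self.model, self.matched_sequence)
        return self._parse


@dataclass
class ScanConfig:
    threshold: float = 40.0
    stringent_threshold: float = 55.0   # applied later, to non-UCA anticodons
    window_extra: int = 30              # W = consensus length + window_extra
    stride: int = 1
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= self.stringent_threshold:
            raise ScanError("need 0 < threshold <= stringent_threshold")
        if self.stride < 1:
            raise ScanError("stride must be >= 1")


def scan_genome(genome: dict[str, str], models: list[CovarianceModel],
                config: ScanConfig | None = None) -> list[Hit]:
    """Scan all contigs (both strands) with each model; return raw hits.

    For each start position only the best-span parse is kept; every hit
    with bit score >= threshold is reported.  Output order and content
    are deterministic.
    """
    config = config or ScanConfig()
    if not genome:
        raise ScanError("empty genome")
    if not models:
        raise ScanError("no models given")
    hits: list[Hit] = []
    for contig_id, seq in genome.items():
        seq = seq.upper()
        if len(seq) < MIN_CONTIG:
            logger.warning("contig %s shorter than %d nt: skipped",
                           contig_id, MIN_CONTIG)
            continue
        strands = ("+", "-") if config.both_strands else ("+",)
        for strand in strands:
            oriented = seq if strand == "+" else revcomp(seq)
            codes = encode(oriented)
            for model in models:
                W = model.default_window(config.window_extra)
                for s0, scores, spans in _chunked_scores(codes, model, W):
                    idx = np.nonzero(scores >= config.threshold)[0]
                    for i in idx:
                        if (s0 + int(i)) % config.stride:
                            continue
                        d = int(spans[i])
                        if d == 0:
                            continue
                        a = s0 + int(i)
                        b = a + d
                        if strand == "+":
                            iv = GenomicInterval(contig_id, a, b, "+")
                        else:
                            L = len(seq)
                            iv = GenomicInterval(contig_id, L - b, L - a, "-")
                        hits.append(Hit(
                            interval=iv, domain_tag=model.domain_tag,
                            bit_score=float(scores[i]),
                            matched_sequence=oriented[a:b], model=model))
    hits.sort(key=_hit_order)
    return hits


def _chunked_scores(codes: np.ndarray, model: CovarianceModel, W: int):
    """Yield (chunk offset, scores, spans) covering every start position."""
    L = len(codes)
    for s0 in range(0, L, CHUNK):
        sub = codes[s0: s0 + CHUNK + W]
        scores, spans = window_scores(model, sub, W)
        n = min(CHUNK, L - s0)
        yield s0, scores[:n], spans[:n]


def _hit_order(h: Hit):
    return (h.interval.contig, h.interval.strand, h.interval.start,
            h.interval.end, DOMAIN_PRIORITY.get(h.domain_tag, 3))


def _better(a: Hit, b: Hit) -> bool:
    """True if a wins over b (score, then longer, then domain, then leftmost)."""
    ka = (-a.bit_score, -a.interval.length,
          DOMAIN_PRIORITY.get(a.domain_tag, 3), a.interval.start)
    kb = (-b.bit_score, -b.interval.length,
          DOMAIN_PRIORITY.get(b.domain_tag, 3), b.interval.start)
    return ka < kb


def resolve_overlaps(hits: list[Hit]) -> list[Hit]:
    """Collapse same-strand overlapping hits, keeping each cluster's best."""
    out: list[Hit] = []
    by_key: dict[tuple[str, str], list[Hit]] = {}
    for h in sorted(hits, key=_hit_order):
        by_key.setdefault((h.interval.contig, h.interval.strand), []).append(h)
    for _, group in sorted(by_key.items()):
        cluster: list[Hit] = []
        cluster_end = -1
        for h in group:
            if cluster and h.interval.start >= cluster_end:
                out.append(_cluster_best(cluster))
                cluster = []
                cluster_end = -1
            cluster.append(h)
            cluster_end = max(cluster_end, h.interval.end)
        if cluster:
            out.append(_cluster_best(cluster))
    out.sort(key=_hit_order)
    return out


def _cluster_best(cluster: list[Hit]) -> Hit:
    best = cluster[0]
    for h in cluster[1:]:
        if _better(h, best):
            best = h
    return best


def assign_domain(cluster: list[Hit]) -> str | None:
    """Domain label of an overlap cluster = tag of its maximum-score hit."""
    if not cluster:
        raise ScanError("empty cluster")
    return _cluster_best(cluster).domain_tag
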