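"""Genome-level benchmark harness and alignment conservation statistics.

tRNA-Sec is the only tRNA for which a genome-level benchmark is
possible: selenocysteine is not universal, so a prediction in a
Sec-devoid genome is necessarily a false positive and a Sec-positive
genome without predictions is a false negative.  Sensitivity is the
fraction of positive genomes with at least one prediction; specificity
the fraction of negative genomes with none; the mean number of
predictions per genome is an indirect specificity measure.  The harness
consumes a neutral per-genome prediction table so any predictor's
output can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from secscan.alphabet import GAP_CHARS
from secscan.cmcore.stockholm import SeedAlignment


class BenchError(ValueError):
    pass


@dataclass(frozen=True)
class GenomeLabel:
    genome_id: str
    lineage: str
    sec_positive: bool


@dataclass
class LineageResult:
    n_pos: int
    n_neg: int
    sn: float | None          # percent, 1 decimal, None = NA
    sp: float | None
    n_plus: float | None      # mean predictions per positive genome
    n_minus: float | None


@dataclass
class BenchmarkResult:
    overall: LineageResult
    per_lineage: dict[str, LineageResult] = field(default_factory=dict)

    @property
    def sn(self) -> float | None:
        return self.overall.sn

    @property
    def sp(self) -> float | None:
        return self.overall.sp


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def counts_from_rows(rows: list[tuple[str, str]]) -> dict[str, int]:
    """Per-genome prediction counts from (genome_id, locus_id) rows.

    Duplicate rows for the same locus count once.
    """
    seen: set[tuple[str, str]] = set()
    counts: dict[str, int] = {}
    for genome_id, locus_id in rows:
        key = (genome_id, locus_id)
        if key in seen:
            continue
        seen.add(key)
        counts[genome_id] = counts.get(genome_id, 0) + 1
    return counts


def _stats(counts: dict[str, int], labels: list[GenomeLabel]) -> LineageResult:
    pos = [l for l in labels if l.sec_positive]
    neg = [l for l in labels if not l.sec_positive]
    sn = sp = n_plus = n_minus = None
    if pos:
        hit = sum(1 for l in pos if counts.get(l.genome_id, 0) >= 1)
        sn = _round1(100.0 * hit / len(pos))
        n_plus = sum(counts.get(l.genome_id, 0) for l in pos) / len(pos)
    if neg:
        clean = sum(1 for l in neg if counts.get(l.genome_id, 0) == 0)
        sp = _round1(100.0 * clean / len(neg))
        n_minus = sum(counts.get(l.genome_id, 0) for l in neg) / len(neg)
    return LineageResult(n_pos=len(pos), n_neg=len(neg), sn=sn, sp=sp,
                         n_plus=n_plus, n_minus=n_minus)


def evaluate(predictions: dict[str, int],
             labels: list[GenomeLabel]) -> BenchmarkResult:
    """Genome-level sensitivity/specificity from per-genome counts.

    sn = 100 * |positive genomes with >=1 prediction| / |positives|;
    sp = 100 * |negative genomes with 0 predictions| / |negatives|;
    N+/N- are arithmetic means.  Values rounded half-up to 1 decimal;
    an empty positive or negative set yields None ("NA").
    """
    ids = {l.genome_id for l in labels}
    if len(ids) != len(labels):
        raise BenchError("duplicate genome ids in labels")
    unknown = set(predictions) - ids
    if unknown:
        raise BenchError(f"predictions for unknown genomes: {sorted(unknown)[:5]}")
    overall = _stats(predictions, labels)
    per_lineage = {}
    for lineage in sorted({l.lineage for l in labels}):
        per_lineage[lineage] = _stats(
            predictions, [l for l in labels if l.lineage == lineage])
    return BenchmarkResult(overall=overall, per_lineage=per_lineage)


# ---------------------------------------------------------------------------
# alignment conservation
# ---------------------------------------------------------------------------


@dataclass
class ColumnStats:
    conservation: list[float | None]      # per column; None = all-gap
    paired_mean: float | None             # mean over paired columns (percent)
    unpaired_mean: float | None
    fully_conserved: list[int]            # columns at 100%


def column_stats(aln: SeedAlignment) -> ColumnStats:
    """Per-column conservation = modal non-gap residue frequency.

    Means are partitioned into consensus-paired vs unpaired columns;
    all-gap columns are excluded.
    """
    if aln.nseq < 2:
        raise BenchError("need at least 2 sequences")
    partner = aln.pair_partner()
    cons: list[float | None] = []
    for c in range(aln.ncol):
        residues = [row[c].upper().replace("U", "T")
                    for _, row in aln.sequences if row[c] not in GAP_CHARS]
        if not residues:
            cons.append(None)
            continue
        modal = max(set(residues), key=lambda r: (residues.count(r), r))
        cons.append(residues.count(modal) / len(residues))
    paired = [v for c, v in enumerate(cons) if v is not None and c in partner]
    unpaired = [v for c, v in enumerate(cons) if v is not None and c not in partner]
    return ColumnStats(
        conservation=cons,
        paired_mean=_round1(100 * sum(paired) / len(paired)) if paired else None,
        unpaired_mean=_round1(100 * sum(unpaired) / len(unpaired)) if unpaired else None,
        fully_conserved=[c for c, v in enumerate(cons) if v == 1.0],
    )
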