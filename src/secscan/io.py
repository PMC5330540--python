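"""File I/O: FASTA, GFF3, BED6, TSV writers and benchmark tables.

Internal coordinates are 0-based half-open; conversion to 1-based
inclusive GFF3 (and back) happens only here.  All writers are
deterministic.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

from Bio import SeqIO

from secscan.annotate import TRNACandidate
from secscan.bench import BenchmarkResult, GenomeLabel, LineageResult


class IOError_(ValueError):
    pass


def read_fasta(source) -> dict[str, str]:
    """Read a (possibly line-wrapped, mixed-case) FASTA into an ordered dict."""
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        handle = open(source)
    else:
        handle = _io.StringIO(source if isinstance(source, str) else source.read())
    out: dict[str, str] = {}
    with handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in out:
                raise IOError_(f"duplicate contig id {rec.id!r}")
            out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: dict[str, str], width: int = 60) -> str:
    lines = []
    for sid, seq in seqs.items():
        lines.append(f">{sid}")
        for k in range(0, len(seq), width):
            lines.append(seq[k:k + width])
    return "\n".join(lines) + "\n"


def _attrs(cand: TRNACandidate, idx: int) -> str:
    parts = [f"ID=trnasec{idx}", f"domain_model={cand.hit.domain_tag}"]
    parts.append(f"anticodon={cand.anticodon or 'undefined'}")
    if cand.discriminator is not None:
        parts.append(f"discriminator={cand.discriminator[0]}")
    parts.append(f"g73={'true' if cand.g73 else 'false'}")
    parts.append(f"cca={'true' if cand.cca_tail else 'false'}")
    parts.append(f"fold={cand.fold_label}")
    if cand.intron is not None:
        parts.append(f"intron={cand.intron.start + 1}-{cand.intron.end}")
    if cand.copy_class:
        parts.append(f"copy_class={cand.copy_class}")
    return ";".join(parts)


def candidates_to_gff3(cands: list[TRNACandidate]) -> str:
    lines = ["##gff-version 3"]
    for k, c in enumerate(cands, 1):
        iv = c.hit.interval
        lines.append("\t".join([
            iv.contig, "secscan", "tRNA", str(iv.start + 1), str(iv.end),
            f"{c.bit_score:.2f}", iv.strand, ".", _attrs(c, k)]))
    return "\n".join(lines) + "\n"


def candidates_to_bed(cands: list[TRNACandidate]) -> str:
    lines = []
    for k, c in enumerate(cands, 1):
        iv = c.hit.interval
        lines.append("\t".join([
            iv.contig, str(iv.start), str(iv.end), f"trnasec{k}",
            f"{c.bit_score:.2f}", iv.strand]))
    return "\n".join(lines) + ("\n" if lines else "")


TSV_HEADER = ("candidate", "contig", "start", "end", "strand", "score", "domain",
              "anticodon", "discriminator", "g73", "cca", "fold", "at_stem",
              "intron", "copy_class")


def candidates_to_tsv(cands: list[TRNACandidate]) -> str:
    lines = ["\t".join(TSV_HEADER)]
    for k, c in enumerate(cands, 1):
        iv = c.hit.interval
        lines.append("\t".join(map(str, [
            f"trnasec{k}", iv.contig, iv.start + 1, iv.end, iv.strand,
            f"{c.bit_score:.2f}", c.hit.domain_tag,
            c.anticodon or "undefined",
            c.discriminator[0] if c.discriminator else "undefined",
            str(c.g73).lower(), str(c.cca_tail).lower(), c.fold_label,
            c.arm_annotation.at_stem_total if c.arm_annotation else "NA",
            f"{c.intron.start + 1}-{c.intron.end}" if c.intron else "none",
            c.copy_class or "NA"])))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# benchmark tables
# ---------------------------------------------------------------------------


def read_labels_tsv(text: str) -> list[GenomeLabel]:
    """`genome_id  lineage  sec_positive` rows (header optional)."""
    labels = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("genome_id"):
            continue
        gid, lineage, flag = line.split("\t")[:3]
        labels.append(GenomeLabel(gid, lineage,
                                  flag.strip().lower() in ("1", "true", "yes")))
    return labels


def read_predictions_tsv(text: str) -> list[tuple[str, str]]:
    """`genome_id  locus_id  score` rows -> (genome_id, locus_id) pairs."""
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("genome_id"):
            continue
        parts = line.split("\t")
        rows.append((parts[0], parts[1]))
    return rows


def _fmt(v: float | None) -> str:
    return "NA" if v is None else f"{v:.1f}"


def benchmark_to_tsv(result: BenchmarkResult) -> str:
    header = "\t".join(("lineage", "n_pos", "n_neg", "sn", "sp", "N+", "N-"))
    def row(name: str, r: LineageResult) -> str:
        return "\t".join((name, str(r.n_pos), str(r.n_neg), _fmt(r.sn),
                          _fmt(r.sp), _fmt(r.n_plus), _fmt(r.n_minus)))
    lines = [header, row("full_set", result.overall)]
    for lineage, r in result.per_lineage.items():
        lines.append(row(lineage, r))
    return "\n".join(lines) + "\n"


def truth_to_bed(truth) -> str:
    lines = []
    for k, t in enumerate(truth, 1):
        lines.append("\t".join([t.contig, str(t.start), str(t.end),
                                f"{t.kind}{k}", "0", t.strand]))
    return "\n".join(lines) + ("\n" if lines else "")


def truth_to_tsv(truth) -> str:
    header = "\t".join(("contig", "start", "end", "strand", "kind", "mutation",
                        "intron_start", "intron_end", "seed"))
    lines = [header]
    for t in truth:
        lines.append("\t".join(map(str, [
            t.contig, t.start, t.end, t.strand, t.kind, t.mutation,
            t.intron_start, t.intron_end, t.seed])))
    return "\n".join(lines) + "\n"
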