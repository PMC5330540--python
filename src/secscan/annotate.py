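"""Candidate annotation: arms, anticodon, discriminator, fold, introns.

Raw scan hits become tRNA-Sec candidates here.  The anticodon is read
from the residues aligned to positions 34-36; hits whose anticodon is
not UCA must clear a more stringent bit-score threshold (55 vs 40).  The
discriminator base (position 73) is not part of the models: it is found
by locating the residue aligned to position 61 and reading the 14th
genomic residue 3' of it — exact for the 13-bp AT-stem, and knowingly
one residue 3' of the structural discriminator for the rare 12-bp
(7/5-fold) variants, which are flagged.  A genomically encoded CCA
triplet immediately 3' of the discriminator is recorded, introns are
recognised as insertions one base 3' of the anticodon, and extra gene
copies are classified as identical / equivalent / compensatory /
disrupted relative to the top-scoring candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from secscan.alphabet import pairs_canonically, to_rna
from secscan.cmcore.model import CovarianceModel
from secscan.scan import GenomicInterval, Hit

logger = logging.getLogger(__name__)

RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N"}

KNOWN_BULGE_LABELS = frozenset({"3a", "4a", "5a", "7a", "13a", "43a"})

STEMS = ("A-stem", "D-stem", "C-stem", "V-stem", "T-stem")
LOOPS = ("D-loop", "C-loop", "V-loop", "T-loop")

DISCRIMINATOR_OFFSET = 14   # residues 3' of position 61 (13-bp AT-stem + 1)


class AnnotateError(ValueError):
    pass


@dataclass
class ArmAnnotation:
    """Realized pair counts, loop lengths and stem bulges of one hit."""

    pair_counts: dict[str, int]
    loop_lengths: dict[str, int]
    bulges: list[tuple[str, str]]      # (position label or 'other', base)

    @property
    def at_stem_total(self) -> int:
        return self.pair_counts.get("A-stem", 0) + self.pair_counts.get("T-stem", 0)


@dataclass
class TRNACandidate:
    """A fully annotated tRNA-Sec candidate."""

    hit: Hit
    arm_annotation: ArmAnnotation | None = None
    anticodon: str | None = None                 # RNA 3-mer or None
    discriminator: tuple[str, int] | None = None  # (RNA base, forward genomic pos)
    discriminator_flagged: bool = False           # 7/5 fold: +14 rule overshoots
    cca_tail: bool = False
    fold_label: str = "other"
    intron: GenomicInterval | None = None
    mature_sequence: str = ""                     # RNA, intron spliced out
    genome_id: str | None = None
    copy_class: str | None = None

    @property
    def g73(self) -> bool:
        return self.discriminator is not None and self.discriminator[0] == "G"

    @property
    def bit_score(self) -> float:
        return self.hit.bit_score


# ---------------------------------------------------------------------------
# per-hit annotation primitives
# ---------------------------------------------------------------------------


def parse_arms(hit: Hit, model: CovarianceModel) -> ArmAnnotation:
    """Count realized stem pairs and loop residues from the hit's parse."""
    if model.structure is None:
        raise AnnotateError("model has no arm-annotated structure")
    arm = model.structure.arm
    parse = hit.parse
    counts = {s: 0 for s in STEMS}
    for lcol, rcol, _, _ in parse.realized_pairs:
        label = arm.get(lcol)
        if label in counts:
            counts[label] += 1
    loops = {l: 0 for l in LOOPS}
    for col, _pos in parse.col_to_pos.items():
        label = arm.get(col)
        if label in loops:
            loops[label] += 1
    bulges: list[tuple[str, str]] = []
    pmap = model.position_map
    for node_idx, side, pos in sorted(parse.inserts, key=lambda x: x[2]):
        node = model.nodes[node_idx]
        anchor = node.lcol if side == "L" else node.rcol
        if anchor is None or not arm.get(anchor, "").endswith("stem"):
            continue
        base = hit.matched_sequence[pos].upper()
        label = "other"
        if pmap is not None:
            anchor_label = pmap.col_to_label.get(anchor, "")
            cand = f"{anchor_label}a"
            label = cand if cand in KNOWN_BULGE_LABELS else "other"
        bulges.append((label, to_rna(base)))
    return ArmAnnotation(pair_counts=counts, loop_lengths=loops, bulges=bulges)


def extract_anticodon(hit: Hit, model: CovarianceModel) -> str | None:
    """Bases aligned to positions 34-36 (RNA), or None if any is deleted."""
    if model.position_map is None:
        raise AnnotateError("model has no position map")
    cols = model.position_map.anticodon_columns()
    parse = hit.parse
    bases = []
    for c in cols:
        pos = parse.col_to_pos.get(c)
        if pos is None:
            return None
        bases.append(hit.matched_sequence[pos].upper())
    return to_rna("".join(bases))


def apply_thresholds(candidates: list[TRNACandidate], T: float = 40.0,
                     T_nonUCA: float = 55.0) -> list[TRNACandidate]:
    """UCA candidates kept at T; all others (incl. undefined) need T_nonUCA."""
    if T > T_nonUCA:
        raise AnnotateError("threshold T must not exceed the stringent threshold")
    kept = []
    for c in candidates:
        cut = T if c.anticodon == "UCA" else T_nonUCA
        if c.bit_score >= cut:
            kept.append(c)
    return kept


def default_arm_minima(model: CovarianceModel) -> dict[str, int]:
    """Per-stem minimum realized pairs: consensus - 2, but V-stem >= 2."""
    cons = model.structure.pair_counts()
    minima = {s: max(1, cons.get(s, 0) - 2) for s in STEMS}
    minima["V-stem"] = 2
    return minima


def filter_arms(candidates: list[TRNACandidate],
                minima: dict[str, int] | None = None) -> list[TRNACandidate]:
    """Drop candidates with any stem below its minimum realized pair count."""
    kept = []
    for c in candidates:
        mins = minima or default_arm_minima(c.hit.model)
        pc = c.arm_annotation.pair_counts
        if all(pc.get(s, 0) >= m for s, m in mins.items()):
            kept.append(c)
    return kept


def _hit_pos_to_forward(interval: GenomicInterval, pos: int) -> int:
    """Map a hit-orientation offset to a forward-strand genomic coordinate."""
    if interval.strand == "+":
        return interval.start + pos
    return interval.end - 1 - pos


def _genome_base(genome: dict[str, str], interval: GenomicInterval,
                 pos: int) -> str | None:
    """Genomic residue at hit-orientation offset ``pos`` (hit orientation)."""
    contig = genome[interval.contig]
    g = _hit_pos_to_forward(interval, pos)
    if not 0 <= g < len(contig):
        return None
    base = contig[g].upper()
    if interval.strand == "-":
        base = RNA_COMPLEMENT.get(base, "N").replace("U", "T")
    return base


def find_discriminator(hit: Hit, genome: dict[str, str],
                       model: CovarianceModel | None = None
                       ) -> tuple[str, int] | None:
    """Position-73 base: the 14th genomic residue 3' of position 61.

    Read from the genome, not the alignment, so the offset is fixed
    regardless of insertions or acceptor-stem deletions in the parse.
    Returns (RNA base, forward-strand genomic position) or None when
    position 61 is deleted or the contig ends first.
    """
    model = model or hit.model
    if model.position_map is None:
        raise AnnotateError("model has no position map")
    col61 = model.position_map.col("61")
    if col61 is None:
        raise AnnotateError("model position map lacks label 61")
    pos61 = hit.parse.col_to_pos.get(col61)
    if pos61 is None:
        return None
    pos = pos61 + DISCRIMINATOR_OFFSET
    base = _genome_base(genome, hit.interval, pos)
    if base is None:
        return None
    return to_rna(base), _hit_pos_to_forward(hit.interval, pos)


def detect_cca(candidate: TRNACandidate, genome: dict[str, str]) -> bool:
    """True iff the 3 residues immediately 3' of the discriminator are CCA."""
    if candidate.discriminator is None:
        logger.warning("CCA check skipped: discriminator undefined")
        return False
    hit = candidate.hit
    col61 = hit.model.position_map.col("61")
    pos61 = hit.parse.col_to_pos[col61]
    start = pos61 + DISCRIMINATOR_OFFSET + 1
    bases = [_genome_base(genome, hit.interval, start + k) for k in range(3)]
    return bases == ["C", "C", "A"]


def classify_fold(arm: ArmAnnotation) -> str:
    """(9,4)->'9/4', (8,5)->'8/5', (7,5)->'7/5', anything else 'other'."""
    key = (arm.pair_counts.get("A-stem", 0), arm.pair_counts.get("T-stem", 0))
    return {(9, 4): "9/4", (8, 5): "8/5", (7, 5): "7/5"}.get(key, "other")


def detect_intron(hit: Hit, min_len: int = 8,
                  model: CovarianceModel | None = None
                  ) -> tuple[GenomicInterval, str] | None:
    """An insertion of >= min_len starting one base 3' of the anticodon.

    Eukaryotic tRNA introns invariably interrupt the anticodon loop
    between positions 37 and 38.  Returns (intron interval in forward
    coordinates, mature RNA sequence with the intron spliced out).
    """
    model = model or hit.model
    if model.position_map is None:
        raise AnnotateError("model has no position map")
    col37 = model.position_map.col("37")
    if col37 is None:
        return None
    parse = hit.parse
    pos37 = parse.col_to_pos.get(col37)
    if pos37 is None:
        return None
    for _node, _side, run in parse.insert_runs():
        if run[0] == pos37 + 1 and len(run) >= min_len:
            a, b = run[0], run[-1] + 1
            iv = hit.interval
            if iv.strand == "+":
                intron = GenomicInterval(iv.contig, iv.start + a, iv.start + b, "+")
            else:
                intron = GenomicInterval(iv.contig, iv.end - b, iv.end - a, "-")
            mature = hit.matched_sequence[:a] + hit.matched_sequence[b:]
            return intron, to_rna(mature)
    return None


# ---------------------------------------------------------------------------
# copy classification
# ---------------------------------------------------------------------------


@dataclass
class PairDetail:
    lcol: int
    rcol: int
    top_bases: tuple[str | None, str | None]
    copy_bases: tuple[str | None, str | None]
    klass: str                          # 'equivalent' | 'compensatory' | 'disruptive'


def _flanked_sequence(cand: TRNACandidate, genome: dict[str, str],
                      flank: int) -> str | None:
    iv = cand.hit.interval
    contig = genome.get(iv.contig)
    if contig is None:
        return None
    lo, hi = max(0, iv.start - flank), min(len(contig), iv.end + flank)
    seq = contig[lo:hi].upper()
    if iv.strand == "-":
        from secscan.alphabet import revcomp
        seq = revcomp(seq)
    return seq


def classify_copy(copy: TRNACandidate, top: TRNACandidate,
                  model: CovarianceModel, flank: int = 100,
                  genome: dict[str, str] | None = None
                  ) -> tuple[str, list[PairDetail]]:
    """Classify an extra gene copy against the top-scoring candidate.

    identical: sequences (including ``flank`` nt of genomic context when a
    genome is supplied) match exactly.  Per consensus pair: disruptive if
    the copy's bases no longer form a WC/GU pair, compensatory if both
    partners differ from the top yet still pair.  Overall: disrupted >=1
    disruptive; else compensatory if >=1 compensatory; else equivalent.
    """
    if copy.genome_id is not None and top.genome_id is not None \
            and copy.genome_id != top.genome_id:
        raise AnnotateError("copy and top candidate come from different genomes")
    if genome is not None:
        fa = _flanked_sequence(copy, genome, flank)
        fb = _flanked_sequence(top, genome, flank)
        identical = fa is not None and fa == fb
    else:
        identical = copy.hit.matched_sequence.upper() == top.hit.matched_sequence.upper()

    ptop = top.hit.parse
    pcopy = copy.hit.parse
    details: list[PairDetail] = []
    n_disr = n_comp = 0
    for i, j in sorted((i, j) for i, j in model.pair_of.items() if i < j):
        tb = _bases_at(top, ptop, i), _bases_at(top, ptop, j)
        cb = _bases_at(copy, pcopy, i), _bases_at(copy, pcopy, j)
        t_ok = tb[0] is not None and tb[1] is not None and pairs_canonically(*tb)
        c_ok = cb[0] is not None and cb[1] is not None and pairs_canonically(*cb)
        if not t_ok and not c_ok:
            continue   # pair realized in neither candidate: uninformative
        if t_ok != c_ok:
            klass = "disruptive"     # broken in exactly one (role-symmetric)
        elif cb[0] != tb[0] and cb[1] != tb[1]:
            klass = "compensatory"
        else:
            klass = "equivalent"
        if klass == "disruptive":
            n_disr += 1
        elif klass == "compensatory":
            n_comp += 1
        details.append(PairDetail(i, j, tb, cb, klass))

    if identical:
        overall = "identical"
    elif n_disr:
        overall = "disrupted"
    elif n_comp:
        overall = "compensatory"
    else:
        overall = "equivalent"
    return overall, details


def _bases_at(cand: TRNACandidate, parse, col: int) -> str | None:
    pos = parse.col_to_pos.get(col)
    if pos is None:
        return None
    return cand.hit.matched_sequence[pos].upper().replace("U", "T")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def annotate_hit(hit: Hit, genome: dict[str, str],
                 intron_min_len: int = 8,
                 genome_id: str | None = None) -> TRNACandidate:
    """Full annotation of a single resolved hit."""
    model = hit.model
    cand = TRNACandidate(hit=hit, genome_id=genome_id)
    cand.arm_annotation = parse_arms(hit, model)
    cand.anticodon = extract_anticodon(hit, model)
    cand.fold_label = classify_fold(cand.arm_annotation)
    cand.discriminator = find_discriminator(hit, genome, model)
    cand.discriminator_flagged = cand.fold_label == "7/5" and cand.discriminator is not None
    cand.cca_tail = detect_cca(cand, genome) if cand.discriminator else False
    res = detect_intron(hit, min_len=intron_min_len, model=model)
    if res is not None:
        cand.intron, cand.mature_sequence = res
    else:
        cand.mature_sequence = to_rna(hit.matched_sequence)
    return cand


def annotate_hits(hits: list[Hit], genome: dict[str, str],
                  T: float = 40.0, T_nonUCA: float = 55.0,
                  arm_minima: dict[str, int] | None = None,
                  intron_min_len: int = 8,
                  genome_id: str | None = None) -> list[TRNACandidate]:
    """Annotate resolved hits, then apply anticodon and arm filters."""
    cands = [annotate_hit(h, genome, intron_min_len, genome_id) for h in hits]
    logger.info("annotated %d hits", len(cands))
    cands = apply_thresholds(cands, T=T, T_nonUCA=T_nonUCA)
    logger.info("%d candidates after anticodon thresholds", len(cands))
    cands = filter_arms(cands, minima=arm_minima)
    logger.info("%d candidates after arm filter", len(cands))
    return cands
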