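"""TGA-readthrough ORF screen for novel selenoprotein candidates.

Annotated genes are extended in their frame through consecutive
in-frame TGA codons, 3' to the first TAA/TAG and 5' to the first
upstream non-TGA stop (restarting at the furthest upstream start codon).
Because every selenoprotein family has Cys-containing homologues, an
extended ORF whose TGA aligns to a cysteine in three or more homologues
is a selenoprotein candidate.  Protein comparison is Smith-Waterman
local alignment (BLOSUM62, affine gaps) with selenocysteine (U) scored
as cysteine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id

from secscan.alphabet import revcomp

STOPS_HARD = {"TAA", "TAG"}
STARTS = {"ATG", "GTG", "TTG"}           # bacterial table 11 initiators
_TABLE11 = unambiguous_dna_by_id[11]


class OrfError(ValueError):
    pass


@dataclass
class ExtendedORF:
    orf_id: str
    contig: str
    start: int                 # forward strand, 0-based half-open, excl. stop
    end: int
    strand: str
    sequence: str              # oriented nucleotide sequence, len % 3 == 0
    tga_codons: list[int]      # codon indices with TGA
    translation: str           # with U at TGA positions
    terminal_stop: str         # 'TAA' | 'TAG' | '' (contig boundary)


@dataclass
class HomologHit:
    subject_id: str
    score: float
    query_range: tuple[int, int]       # aa coordinates, half-open
    subject_range: tuple[int, int]
    tga_pairs: list[tuple[int, str]] = field(default_factory=list)


def _translate(codon: str, first: bool = False) -> str:
    if codon == "TGA":
        return "U"
    if codon in STOPS_HARD:
        return "*"
    if first and codon in STARTS:
        return "M"
    try:
        return _TABLE11.forward_table[codon]
    except KeyError:
        return "X"


def parse_gff3_cds(text: str) -> list[dict]:
    """Minimal GFF3 CDS reader: contig, 0-based start/end, strand, ID."""
    feats = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 9 or parts[2] != "CDS":
            continue
        attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
        feats.append({
            "contig": parts[0],
            "start": int(parts[3]) - 1,
            "end": int(parts[4]),
            "strand": parts[6],
            "id": attrs.get("ID", f"cds{len(feats) + 1}"),
        })
    return feats


def extend_orfs(genome: dict[str, str], annotations: str | list[dict]
                ) -> list[ExtendedORF]:
    """Extend every annotated CDS through in-frame TGA; keep TGA-containing ORFs."""
    feats = parse_gff3_cds(annotations) if isinstance(annotations, str) else annotations
    out: list[ExtendedORF] = []
    for feat in feats:
        contig = feat["contig"]
        seq = genome[contig].upper()
        L = len(seq)
        if (feat["end"] - feat["start"]) % 3:
            raise OrfError(f"CDS {feat['id']}: length not a multiple of 3")
        if feat["strand"] == "+":
            oriented, ostart = seq, feat["start"]
        else:
            oriented, ostart = revcomp(seq), L - feat["end"]

        # 3' extension: through TGA to the first TAA/TAG (or contig end)
        p = ostart
        terminal = ""
        while p + 3 <= L:
            codon = oriented[p:p + 3]
            if codon in STOPS_HARD:
                terminal = codon
                break
            p += 3
        end3 = p

        # 5' extension: back to the first upstream non-TGA stop ...
        q = ostart - 3
        bound = ostart % 3
        while q >= 0:
            if oriented[q:q + 3] in STOPS_HARD:
                bound = q + 3
                break
            q -= 3
        # ... then forward to the furthest upstream start codon
        new_start = ostart
        r = bound
        while r < ostart:
            if oriented[r:r + 3] in STARTS:
                new_start = r
                break
            r += 3

        orf_seq = oriented[new_start:end3]
        tga = [k for k in range(len(orf_seq) // 3)
               if orf_seq[3 * k:3 * k + 3] == "TGA"]
        if not tga:
            continue
        translation = "".join(_translate(orf_seq[3 * k:3 * k + 3], first=(k == 0))
                              for k in range(len(orf_seq) // 3))
        if feat["strand"] == "+":
            fstart, fend = new_start, end3
        else:
            fstart, fend = L - end3, L - new_start
        out.append(ExtendedORF(
            orf_id=feat["id"], contig=contig, start=fstart, end=fend,
            strand=feat["strand"], sequence=orf_seq, tga_codons=tga,
            translation=translation, terminal_stop=terminal))
    return out


def _aligner(open_gap: float = -11.0, extend_gap: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def align_homologs(orf: ExtendedORF, proteins: list[tuple[str, str]],
                   min_score: float = 40.0,
                   open_gap: float = -11.0,
                   extend_gap: float = -1.0) -> list[HomologHit]:
    """Best local alignment per subject; U in the query scores as C.

    Returns hits with score >= min_score, with the subject residue
    aligned to each query TGA recorded.
    """
    if not proteins:
        raise OrfError("empty protein set")
    aligner = _aligner(open_gap, extend_gap)
    query = orf.translation.replace("U", "C").replace("*", "X")
    hits: list[HomologHit] = []
    for sid, prot in proteins:
        prot = prot.upper().replace("U", "C").replace("*", "").replace("-", "")
        alns = aligner.align(query, prot)
        if len(alns) == 0:
            continue
        best = alns[0]
        if best.score < min_score:
            continue
        qblocks, sblocks = best.aligned
        pairs: list[tuple[int, str]] = []
        for (qa, qb), (sa, _sb) in zip(qblocks, sblocks):
            for t in orf.tga_codons:
                if qa <= t < qb:
                    pairs.append((t, prot[sa + (t - qa)]))
        hits.append(HomologHit(
            subject_id=sid, score=float(best.score),
            query_range=(int(qblocks[0][0]), int(qblocks[-1][1])),
            subject_range=(int(sblocks[0][0]), int(sblocks[-1][1])),
            tga_pairs=sorted(set(pairs))))
    hits.sort(key=lambda h: (-h.score, h.subject_id))
    return hits


def select_candidates(orfs: list[ExtendedORF],
                      hits: dict[str, list[HomologHit]],
                      min_cys_hits: int = 3) -> list[ExtendedORF]:
    """ORFs whose TGA aligns to Cys in >= min_cys_hits distinct subjects."""
    selected = []
    for orf in orfs:
        subjects = {h.subject_id for h in hits.get(orf.orf_id, [])
                    if any(res == "C" for _t, res in h.tga_pairs)}
        if len(subjects) >= min_cys_hits:
            selected.append(orf)
    return selected


def n_cys_subjects(orf: ExtendedORF, hits: list[HomologHit]) -> int:
    return len({h.subject_id for h in hits
                if any(res == "C" for _t, res in h.tga_pairs)})
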