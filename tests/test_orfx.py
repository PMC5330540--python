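import numpy as np
import pytest

from secscan.alphabet import revcomp
from secscan.orfx import (
    OrfError,
    align_homologs,
    extend_orfs,
    n_cys_subjects,
    select_candidates,
)

from .oracles import sw_affine_score

CODON = {"A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGC", "Q": "CAA",
         "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTG", "K": "AAA",
         "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
         "Y": "TAT", "V": "GTT"}

PROT = ("MKTAYIAKQRQISFVKSHFSRQLEERLGLIECQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ"
        "FEVVHSLAKWKRQTLGQHDFSAGEGLYTHMKALRPDEDRLSPLHSVYVDQWDWE")
CYS_AT = PROT.index("C")


def _gene(prot, sec_at=None):
    """Back-translate; encode the given position as TGA (selenocysteine)."""
    return "".join("TGA" if i == sec_at else CODON[a] for i, a in enumerate(prot))


def _genome_with_gene(seed=5, sec_at=CYS_AT, stop="TAA"):
    rng = np.random.default_rng(seed)
    gene = _gene(PROT, sec_at)
    left = "".join("ACGT"[i] for i in rng.integers(4, size=120))
    right = "".join("ACGT"[i] for i in rng.integers(4, size=120))
    contig = left + gene + stop + right
    # annotation truncated at the TGA, as a mispredicted selenoprotein would be
    cds_start, cds_end = len(left), len(left) + (sec_at * 3 if sec_at else 30)
    gff = f"chr1\tsrc\tCDS\t{cds_start + 1}\t{cds_end}\t.\t+\t0\tID=gene1\n"
    return {"chr1": contig}, gff, len(left), len(left) + len(gene)


def test_extension_through_tga_to_next_stop():
    genome, gff, gstart, gend = _genome_with_gene()
    orfs = extend_orfs(genome, gff)
    assert len(orfs) == 1
    o = orfs[0]
    assert o.tga_codons == [CYS_AT]
    assert o.terminal_stop == "TAA"
    assert o.end == gend
    assert len(o.sequence) % 3 == 0
    assert o.translation[CYS_AT] == "U"


def test_gene_without_tga_is_dropped():
    prot = PROT.replace("C", "S")
    gene = _gene(prot)            # no TGA anywhere
    contig = "A" * 99 + gene + "TAA" + "C" * 99
    gff = f"chr1\tsrc\tCDS\t100\t{99 + len(gene)}\t.\t+\t0\tID=g\n"
    assert extend_orfs({"chr1": contig}, gff) == []


def test_two_consecutive_tga_both_recorded():
    prot = PROT[:40]
    gene = _gene(prot)
    # append two TGA codons then a TAG
    contig = "A" * 90 + gene + "TGA" + "TGA" + "TAG" + "G" * 90
    gff = f"chr1\tsrc\tCDS\t91\t{90 + len(gene)}\t.\t+\t0\tID=g\n"
    orfs = extend_orfs({"chr1": contig}, gff)
    assert len(orfs) == 1
    assert orfs[0].tga_codons == [len(prot), len(prot) + 1]
    assert orfs[0].terminal_stop == "TAG"


def test_reverse_strand_orf_matches_forward():
    genome, gff, *_ = _genome_with_gene()
    fwd = extend_orfs(genome, gff)[0]
    L = len(genome["chr1"])
    rgenome = {"chr1": revcomp(genome["chr1"])}
    parts = gff.split("\t")
    start, end = int(parts[3]), int(parts[4])
    rgff = f"chr1\tsrc\tCDS\t{L - end + 1}\t{L - start + 1}\t.\t-\t0\tID=gene1\n"
    rev = extend_orfs(rgenome, rgff)[0]
    assert rev.sequence == fwd.sequence
    assert rev.tga_codons == fwd.tga_codons


def test_inconsistent_frame_rejected():
    gff = "chr1\tsrc\tCDS\t1\t10\t.\t+\t0\tID=g\n"   # length 10, not %3
    with pytest.raises(OrfError):
        extend_orfs({"chr1": "ATG" * 30}, gff)


def test_translation_u_positions_roundtrip():
    genome, gff, *_ = _genome_with_gene()
    o = extend_orfs(genome, gff)[0]
    u_positions = [i for i, a in enumerate(o.translation) if a == "U"]
    assert u_positions == o.tga_codons
    assert all(o.sequence[3 * k:3 * k + 3] == "TGA" for k in u_positions)


# -- homologue alignment ------------------------------------------------------


def test_tga_cys_pair_in_near_identical_homolog():
    genome, gff, *_ = _genome_with_gene()
    o = extend_orfs(genome, gff)[0]
    hits = align_homologs(o, [("hom", PROT)])
    assert len(hits) == 1
    assert (CYS_AT, "C") in hits[0].tga_pairs


def test_unrelated_protein_scores_below_minimum():
    genome, gff, *_ = _genome_with_gene()
    o = extend_orfs(genome, gff)[0]
    rng = np.random.default_rng(0)
    aas = "ARNDCQEGHILKMFPSTWYV"
    junk = [(f"r{i}", "".join(aas[j] for j in rng.integers(20, size=110)))
            for i in range(5)]
    hits = align_homologs(o, junk)
    assert hits == []


def test_alignment_score_matches_bruteforce_dp():
    rng = np.random.default_rng(3)
    aas = "ARNDCQEGHILKMFPSTWYV"
    from secscan.orfx import _aligner
    aligner = _aligner()
    for _ in range(6):
        q = "".join(aas[j] for j in rng.integers(20, size=int(rng.integers(8, 21))))
        s = "".join(aas[j] for j in rng.integers(20, size=int(rng.integers(8, 21))))
        got = aligner.align(q, s)
        score = got.score if len(got) else 0.0
        assert score == pytest.approx(max(0.0, sw_affine_score(q, s)))


# -- candidate selection ------------------------------------------------------


def _hits_fixture(n_cys, n_trp=0):
    genome, gff, *_ = _genome_with_gene()
    o = extend_orfs(genome, gff)[0]
    prots = [(f"cys{i}", PROT) for i in range(n_cys)]
    trp = PROT[:CYS_AT] + "W" + PROT[CYS_AT + 1:]
    prots += [(f"trp{i}", trp) for i in range(n_trp)]
    return o, align_homologs(o, prots)


@pytest.mark.parametrize("n_cys,selected", [(3, True), (2, False)])
def test_three_cys_subjects_required(n_cys, selected):
    o, hits = _hits_fixture(n_cys)
    out = select_candidates([o], {o.orf_id: hits})
    assert (out == [o]) is selected


def test_tga_trp_pairs_do_not_count():
    o, hits = _hits_fixture(0, n_trp=5)
    assert n_cys_subjects(o, hits) == 0
    assert select_candidates([o], {o.orf_id: hits}) == []


def test_selection_monotone_in_min_cys_hits():
    o, hits = _hits_fixture(4)
    sizes = [len(select_candidates([o], {o.orf_id: hits}, min_cys_hits=k))
             for k in (1, 3, 5)]
    assert sizes == sorted(sizes, reverse=True)


def test_brachyspira_like_cluster_yields_the_planted_candidate():
    """One Cys homologue + one Sec gene sharing a domain: only the TGA gene
    is selected."""
    rng = np.random.default_rng(9)
    sec_gene = _gene(PROT, CYS_AT)
    cys_gene = _gene(PROT)
    spacer = "".join("ACGT"[i] for i in rng.integers(4, size=60))
    contig = spacer + cys_gene + "TAA" + spacer + sec_gene + "TAA" + spacer
    a0 = len(spacer)
    b0 = a0 + len(cys_gene)
    a1 = b0 + 3 + len(spacer)
    gff = (f"c\tsrc\tCDS\t{a0 + 1}\t{b0}\t.\t+\t0\tID=cysgene\n"
           f"c\tsrc\tCDS\t{a1 + 1}\t{a1 + CYS_AT * 3}\t.\t+\t0\tID=secgene\n")
    orfs = extend_orfs({"c": contig}, gff)
    assert [o.orf_id for o in orfs] == ["secgene"]
    homs = [(f"h{i}", PROT) for i in range(3)]
    hits = {o.orf_id: align_homologs(o, homs) for o in orfs}
    assert [o.orf_id for o in select_candidates(orfs, hits)] == ["secgene"]
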