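"""Consensus-structure annotation: arms, loops and tRNA position labels.

The tRNA-Sec cloverleaf is an acceptor stem (A-stem) whose multiloop
holds exactly four arms in 5'->3' order: the D arm, the anticodon arm
(C), the long variable arm (V) and the T arm.  The acceptor and T stems
stack coaxially into the AT-stem (13 bp in tRNA-Sec, 12 bp in canonical
tRNAs).  Position labels follow standard tRNA numbering with
letter-suffixed inserts; the discriminator (position 73) is deliberately
not a model column, and label 61 is the last T-loop column so that the
discriminator sits exactly 14 residues 3' of it when the AT-stem has
13 bp.
"""

from __future__ import annotations

from dataclasses import dataclass

from secscan.cmcore.stockholm import SeedAlignment

ARMS = (
    "A-stem",
    "D-stem",
    "D-loop",
    "C-stem",
    "C-loop",
    "V-stem",
    "V-loop",
    "T-stem",
    "T-loop",
    "linker",
)

STEM_ORDER = ("D", "C", "V", "T")

REQUIRED_LABELS = ("18", "19", "33", "34", "35", "36", "55", "61", "66")


class StructureError(ValueError):
    """Raised when a consensus structure is not a cloverleaf-plus-V-arm."""


@dataclass
class PositionMap:
    """Bidirectional map between match columns and tRNA position labels."""

    col_to_label: dict[int, str]
    label_to_col: dict[str, int]

    @classmethod
    def from_labels(cls, labels: dict[int, str]) -> "PositionMap":
        inv: dict[str, int] = {}
        for col, lbl in labels.items():
            if lbl in inv:
                raise StructureError(f"duplicate position label {lbl!r}")
            inv[lbl] = col
        return cls(col_to_label=dict(labels), label_to_col=inv)

    def col(self, label: str) -> int | None:
        return self.label_to_col.get(label)

    def anticodon_columns(self) -> tuple[int, int, int]:
        cols = tuple(self.label_to_col[l] for l in ("34", "35", "36"))
        return cols  # type: ignore[return-value]

    def validate(self) -> None:
        missing = [l for l in REQUIRED_LABELS if l not in self.label_to_col]
        if missing:
            raise StructureError(f"position map lacks required labels {missing}")
        if "73" in self.label_to_col:
            raise StructureError("discriminator (73) must not be a model column")


@dataclass
class ConsensusStructure:
    """Arm-annotated consensus structure over the match columns."""

    match_cols: list[int]              # alignment column indices, ascending
    pair_partner: dict[int, int]       # involution over match columns
    arm: dict[int, str]                # per match column, one of ARMS
    ncol: int                          # total alignment columns

    def is_match(self, col: int) -> bool:
        return col in self.arm

    def stem_pairs(self, stem: str) -> list[tuple[int, int]]:
        """Consensus pairs (i<j) whose columns carry the given stem label."""
        out = []
        for i, j in sorted((i, j) for i, j in self.pair_partner.items() if i < j):
            if self.arm[i] == stem:
                out.append((i, j))
        return out

    def pair_counts(self) -> dict[str, int]:
        return {s: len(self.stem_pairs(s)) for s in
                ("A-stem", "D-stem", "C-stem", "V-stem", "T-stem")}

    def loop_columns(self, loop: str) -> list[int]:
        return [c for c in self.match_cols if self.arm[c] == loop]


def _helixes(pairs: list[tuple[int, int]], paired_cols: set[int]) -> list[list[tuple[int, int]]]:
    """Group nested pairs into helixes (maximal stacked runs, bulges allowed
    only as unpaired columns between consecutive pairs)."""
    helixes: list[list[tuple[int, int]]] = []
    cur: list[tuple[int, int]] = []
    for p in sorted(pairs):
        if cur:
            pi, pj = cur[-1]
            i, j = p
            between_left = any(c in paired_cols for c in range(pi + 1, i))
            between_right = any(c in paired_cols for c in range(j + 1, pj))
            if pi < i and j < pj and not between_left and not between_right:
                cur.append(p)
                continue
            helixes.append(cur)
        cur = [p]
    if cur:
        helixes.append(cur)
    return helixes


def annotate_structure(aln: SeedAlignment,
                       gap_fraction: float = 0.5) -> tuple[ConsensusStructure, PositionMap]:
    """Assign every match column to an arm and build the position map.

    Raises StructureError unless the consensus is an acceptor stem whose
    multiloop contains exactly four stems (D, C, V, T in 5'->3' order).
    """
    match_cols = aln.match_columns(gap_fraction)
    match_set = set(match_cols)
    partner_all = aln.pair_partner()
    # keep only pairs with both partners in match columns
    pair_partner = {i: j for i, j in partner_all.items()
                    if i in match_set and j in match_set}
    pairs = sorted((i, j) for i, j in pair_partner.items() if i < j)
    if not pairs:
        raise StructureError("consensus has no base pairs")
    paired_cols = set(pair_partner)

    helixes = _helixes(pairs, paired_cols)

    def span(h: list[tuple[int, int]]) -> tuple[int, int]:
        return h[0][0], h[0][1]

    def inner(h: list[tuple[int, int]]) -> tuple[int, int]:
        return h[-1][0], h[-1][1]

    def children_of(h: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
        lo, hi = inner(h)
        kids = []
        for other in helixes:
            o_lo, o_hi = span(other)
            if lo < o_lo and o_hi < hi:
                if not any(span(t)[0] < o_lo and o_hi < span(t)[1] and t is not other
                           and lo < span(t)[0] for t in helixes):
                    kids.append(other)
        kids.sort(key=lambda k: span(k)[0])
        return kids

    # outermost helix chain = acceptor stem (absorb stacked sub-helixes)
    top = [h for h in helixes
           if not any(span(t)[0] < span(h)[0] and span(h)[1] < span(t)[1]
                      for t in helixes)]
    if len(top) != 1:
        raise StructureError(f"expected a single enclosing acceptor stem, found {len(top)}")

    arm: dict[int, str] = {}

    def absorb_chain(h: list[tuple[int, int]], label: str) -> list[list[tuple[int, int]]]:
        """Label helix h (and stacked continuations) as `label`; return the
        multiloop children where the chain stops."""
        current = h
        while True:
            for i, j in current:
                arm[i] = label
                arm[j] = label
            kids = children_of(current)
            if len(kids) == 1:
                current = kids[0]
                continue
            return kids

    kids = absorb_chain(top[0], "A-stem")
    if len(kids) != 4:
        raise StructureError(
            f"acceptor multiloop must hold 4 stems (D, C, V, T); found {len(kids)}"
        )
    for stem_name, kid in zip(STEM_ORDER, kids):
        tail = absorb_chain(kid, f"{stem_name}-stem")
        if tail:
            raise StructureError(f"{stem_name} arm contains an internal multiloop")

    # unpaired match columns: loops inside an arm's innermost pair, else linker
    arm_regions = {}
    for name in ("A", "D", "C", "V", "T"):
        cols = [c for c, a in arm.items() if a == f"{name}-stem"]
        if cols:
            inner_lo = max(c for c in cols if pair_partner[c] > c)
            inner_hi = min(c for c in cols if pair_partner[c] < c)
            arm_regions[name] = (inner_lo, inner_hi)
    for c in match_cols:
        if c in arm:
            continue
        placed = False
        for name in ("D", "C", "V", "T"):
            lo, hi = arm_regions[name]
            if lo < c < hi:
                arm[c] = f"{name}-loop"
                placed = True
                break
        if not placed:
            # bulge column inside a stem region, or a true linker
            for name in ("A", "D", "C", "V", "T"):
                scols = [x for x, a in arm.items() if a == f"{name}-stem"]
                lo5 = min(x for x in scols if pair_partner[x] > x)
                hi5 = max(x for x in scols if pair_partner[x] > x)
                lo3 = min(x for x in scols if pair_partner[x] < x)
                hi3 = max(x for x in scols if pair_partner[x] < x)
                if lo5 < c < hi5 or lo3 < c < hi3:
                    arm[c] = f"{name}-stem"
                    placed = True
                    break
        if not placed:
            arm[c] = "linker"

    cs = ConsensusStructure(match_cols=match_cols, pair_partner=pair_partner,
                            arm=arm, ncol=aln.ncol)

    if aln.position_labels is not None:
        labels = {c: aln.position_labels[c] for c in match_cols
                  if aln.position_labels[c] is not None}
        pmap = PositionMap.from_labels(labels)
    else:
        pmap = default_position_map(cs)
    return cs, pmap


def _range_labels(base: int, extra_after: int, n: int, head: int) -> list[str]:
    """n labels: base..base+head-1, then letter-suffixed inserts on the last
    integer before the tail, then the remaining integers."""
    ints = [str(base + i) for i in range(head)]
    if n <= head:
        return ints[:n]
    n_extra = n - head
    suffixes = [f"{base + extra_after}{chr(ord('a') + k)}" for k in range(n_extra)]
    cut = extra_after + 1
    return ints[:cut] + suffixes + ints[cut:]


def default_position_map(cs: ConsensusStructure) -> PositionMap:
    """Label match columns with standard-style tRNA numbering.

    Anticodon loop centre = 34-36 (33 just 5' of it), D-loop second and
    third columns = 18/19, T-loop ends at 61, acceptor 3' strand runs
    66..72 with letter inserts, so 73 (the discriminator) is never a
    model column.
    """
    labels: dict[int, str] = {}

    def stem_strands(name: str) -> tuple[list[int], list[int]]:
        cols = [c for c in cs.match_cols if cs.arm[c] == name and c in cs.pair_partner]
        five = [c for c in cols if cs.pair_partner[c] > c]
        three = [c for c in cols if cs.pair_partner[c] < c]
        return five, three

    a5, a3 = stem_strands("A-stem")
    for col, lbl in zip(a5, _range_labels(1, 4, len(a5), 7)):
        labels[col] = lbl
    # 3' strand in column order pairs innermost first: 66,67,[67a..],68..72
    for col, lbl in zip(a3, _range_labels(66, 1, len(a3), 7)):
        labels[col] = lbl

    d5, d3 = stem_strands("D-stem")
    for col, lbl in zip(d5, _range_labels(10, 2, len(d5), 4)):
        labels[col] = lbl
    for col, lbl in zip(d3, _range_labels(21, 2, len(d3), 5)):
        labels[col] = lbl
    dloop = cs.loop_columns("D-loop")
    for col, lbl in zip(dloop, _range_labels(17, 3, len(dloop), 4)):
        labels[col] = lbl

    c5, c3 = stem_strands("C-stem")
    for col, lbl in zip(c5, _range_labels(27, 3, len(c5), 5)):
        labels[col] = lbl
    for col, lbl in zip(c3, _range_labels(39, 3, len(c3), 6)):
        labels[col] = lbl
    cloop = cs.loop_columns("C-loop")
    mid = len(cloop) // 2  # anticodon centre: labels 34,35,36 on middle three
    for i, col in enumerate(cloop):
        labels[col] = str(35 + (i - mid))

    v5, v3 = stem_strands("V-stem")
    for col, lbl in zip(v5, _range_labels(45, 2, len(v5), 3)):
        labels[col] = lbl
    for i, col in enumerate(v3):
        labels[col] = f"48{chr(ord('a') + i)}"
    for i, col in enumerate(cs.loop_columns("V-loop")):
        labels[col] = f"v{i + 1}"

    t5, t3 = stem_strands("T-stem")
    for col, lbl in zip(t5, _range_labels(49, 4, len(t5), 5)):
        labels[col] = lbl
    tloop = cs.loop_columns("T-loop")
    for i, col in enumerate(tloop):
        labels[col] = str(61 - (len(tloop) - 1) + i)
    for col, lbl in zip(t3, _range_labels(62, 3, len(t3), 4)):
        labels[col] = lbl

    # canonical linkers: A5'->D gets 8/9, D->C gets 26, C->V gets 44a.., V->T gets 48
    linkers = [c for c in cs.match_cols if c not in labels and cs.arm[c] == "linker"]
    a5_end = a5[-1] if a5 else -1
    d_start = d5[0] if d5 else 10**9
    d3_end = d3[-1] if d3 else -1
    c_start = c5[0] if c5 else 10**9
    c3_end = c3[-1] if c3 else -1
    v_start = min(v5) if v5 else 10**9
    v3_end = max(v3) if v3 else -1
    t_start = t5[0] if t5 else 10**9
    counters = {"ad": 0, "dc": 0, "cv": 0, "vt": 0, "other": 0}
    for col in linkers:
        if a5_end < col < d_start:
            k = counters["ad"]
            labels[col] = str(8 + k) if k < 2 else f"9{chr(ord('a') + k - 2)}"
            counters["ad"] += 1
        elif d3_end < col < c_start:
            k = counters["dc"]
            labels[col] = "26" if k == 0 else f"26{chr(ord('a') + k - 1)}"
            counters["dc"] += 1
        elif c3_end < col < v_start:
            k = counters["cv"]
            labels[col] = f"44{chr(ord('a') + k)}"
            counters["cv"] += 1
        elif v3_end < col < t_start:
            k = counters["vt"]
            labels[col] = "48" if k == 0 else f"48.{k}"
            counters["vt"] += 1
        else:
            counters["other"] += 1
            labels[col] = f"x{counters['other']}"

    # remaining unlabeled match columns (bulges in stems): suffix off the
    # previous labeled column
    prev = None
    for col in cs.match_cols:
        if col in labels:
            prev = labels[col]
        else:
            labels[col] = f"{prev}+" if prev else "x0"
            prev = labels[col]

    return PositionMap.from_labels(labels)
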