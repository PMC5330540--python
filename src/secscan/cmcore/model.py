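"""Covariance-model construction from structurally annotated alignments.

A model is a profile stochastic context-free grammar whose guide tree is
derived deterministically from the consensus structure: pair-match nodes
(MATP) for consensus base pairs, left/right single-strand nodes
(MATL/MATR), bifurcations (BIF with BEGL/BEGR children) where the
structure branches, plus ROOT and END.  Each node carries match, delete
and insert states; transitions and match emissions are estimated from
the alignment with pseudocounts and converted to bit scores against an
iid null model.  Alignment is glocal: global in the model (no local
begins or ends), local in the genomic window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from secscan.alphabet import GAP_CHARS, NT_INDEX
from secscan.cmcore.stockholm import SeedAlignment, StockholmFormatError
from secscan.cmcore.structure import (
    ConsensusStructure,
    PositionMap,
    StructureError,
    annotate_structure,
)

SPLIT_STATES = {
    "ROOT": ("S",),
    "MATP": ("MP", "ML", "MR", "D"),
    "MATL": ("ML", "D"),
    "MATR": ("MR", "D"),
    "BIF": ("B",),
    "BEGL": ("S",),
    "BEGR": ("S",),
    "END": ("E",),
}

INSERTS = {
    "ROOT": ("IL", "IR"),
    "MATP": ("IL", "IR"),
    "MATL": ("IL",),
    "MATR": ("IR",),
    "BEGR": ("IL",),
    "BIF": (),
    "BEGL": (),
    "END": (),
}

# (left-emitted, right-emitted) residues per state kind
EMIT_DELTA = {
    "S": (0, 0), "D": (0, 0), "B": (0, 0), "E": (0, 0),
    "MP": (1, 1), "ML": (1, 0), "MR": (0, 1), "IL": (1, 0), "IR": (0, 1),
}

NEG_INF = float("-inf")


class ModelError(ValueError):
    pass


@dataclass
class Node:
    idx: int
    kind: str
    lcol: int | None = None
    rcol: int | None = None
    child: int | None = None       # next node (non-BIF)
    bif_left: int | None = None    # BEGL node (BIF only)
    bif_right: int | None = None   # BEGR node (BIF only)
    parent: int | None = None


@dataclass
class State:
    idx: int
    kind: str
    node: int
    children: list[int] = field(default_factory=list)
    t: np.ndarray | None = None        # transition bit scores (may be floored)
    t_prob: np.ndarray | None = None   # underlying probabilities (sum to 1)
    emit: np.ndarray | None = None     # (6,) or (6,6) emission bit scores
    emit_prob: np.ndarray | None = None  # (4,) or (4,4) probabilities

    @property
    def dl(self) -> int:
        return EMIT_DELTA[self.kind][0]

    @property
    def dr(self) -> int:
        return EMIT_DELTA[self.kind][1]


def _build_guide_tree(match_cols: list[int], pair_of: dict[int, int]) -> list[Node]:
    """Deterministic guide tree over the match columns."""
    nodes: list[Node] = []

    def new(kind: str, lcol=None, rcol=None, parent=None) -> Node:
        n = Node(idx=len(nodes), kind=kind, lcol=lcol, rcol=rcol, parent=parent)
        nodes.append(n)
        return n

    pos_in_match = {c: i for i, c in enumerate(match_cols)}
    root = new("ROOT")

    def rec(lo: int, hi: int, parent: Node) -> Node:
        if lo > hi:
            return new("END", parent=parent.idx)
        cl, ch = match_cols[lo], match_cols[hi]
        partner = pair_of.get(cl)
        if partner == ch:
            n = new("MATP", lcol=cl, rcol=ch, parent=parent.idx)
            n.child = rec(lo + 1, hi - 1, n).idx
            return n
        if partner is None:
            n = new("MATL", lcol=cl, parent=parent.idx)
            n.child = rec(lo + 1, hi, n).idx
            return n
        if pair_of.get(ch) is None:
            n = new("MATR", rcol=ch, parent=parent.idx)
            n.child = rec(lo, hi - 1, n).idx
            return n
        # both ends paired, but not to each other: bifurcate at lo's partner
        mid = pos_in_match[partner]
        bif = new("BIF", parent=parent.idx)
        begl = new("BEGL", parent=bif.idx)
        begl.child = rec(lo, mid, begl).idx
        bif.bif_left = begl.idx
        begr = new("BEGR", parent=bif.idx)
        begr.child = rec(mid + 1, hi, begr).idx
        bif.bif_right = begr.idx
        return bif

    root.child = rec(0, len(match_cols) - 1, root).idx if match_cols else new("END", parent=0).idx
    return nodes


def _make_states(nodes: list[Node]) -> tuple[list[State], dict[tuple[int, str], int]]:
    states: list[State] = []
    sid: dict[tuple[int, str], int] = {}
    for n in nodes:
        for kind in SPLIT_STATES[n.kind] + INSERTS.get(n.kind, ()):
            s = State(idx=len(states), kind=kind, node=n.idx)
            sid[(n.idx, kind)] = s.idx
            states.append(s)

    def splits(node_idx: int) -> list[int]:
        n = nodes[node_idx]
        return [sid[(n.idx, k)] for k in SPLIT_STATES[n.kind]]

    for n in nodes:
        ins = [sid[(n.idx, k)] for k in INSERTS.get(n.kind, ())]
        if n.kind in ("ROOT", "MATP", "MATL", "MATR", "BEGL", "BEGR"):
            child_splits = splits(n.child)
            for k in SPLIT_STATES[n.kind]:
                states[sid[(n.idx, k)]].children = ins + child_splits
            if (n.idx, "IL") in sid:
                il = states[sid[(n.idx, "IL")]]
                il.children = [il.idx] + ([sid[(n.idx, "IR")]] if (n.idx, "IR") in sid else []) + child_splits
            if (n.idx, "IR") in sid:
                ir = states[sid[(n.idx, "IR")]]
                ir.children = [ir.idx] + child_splits
        elif n.kind == "BIF":
            b = states[sid[(n.idx, "B")]]
            b.children = [sid[(nodes[n.bif_left].idx, "S")],
                          sid[(nodes[n.bif_right].idx, "S")]]
    return states, sid


@dataclass
class CovarianceModel:
    """Profile SCFG over a tRNA(-like) consensus, scores in bits."""

    name: str
    domain_tag: str | None
    match_cols: list[int]
    pair_of: dict[int, int]             # partner per paired match column
    nodes: list[Node]
    states: list[State]
    state_id: dict[tuple[int, str], int]
    position_map: PositionMap | None = None
    structure: ConsensusStructure | None = None
    null: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    emission_pseudocount: float = 1.0
    transition_pseudocount: float = 1.0
    insert_owner: dict[int, tuple[int, str]] = field(default_factory=dict)

    @property
    def consensus_length(self) -> int:
        return len(self.match_cols)

    @property
    def root_state(self) -> int:
        return self.state_id[(0, "S")]

    def default_window(self, extra: int = 30) -> int:
        return self.consensus_length + extra

    def consensus_sequence(self) -> str:
        """Highest-emission-probability residue at each match column (DNA)."""
        letters = "ACGT"
        best: dict[int, str] = {}
        for s in self.states:
            n = self.nodes[s.node]
            if s.kind == "MP":
                i, j = np.unravel_index(int(np.argmax(s.emit_prob)), (4, 4))
                best[n.lcol] = letters[i]
                best[n.rcol] = letters[j]
            elif s.kind == "ML" and n.kind == "MATL":
                best[n.lcol] = letters[int(np.argmax(s.emit_prob))]
            elif s.kind == "MR" and n.kind == "MATR":
                best[n.rcol] = letters[int(np.argmax(s.emit_prob))]
        return "".join(best[c] for c in self.match_cols)

    # -- serialization ---------------------------------------------------

    FORMAT_VERSION = 1

    def to_json(self) -> str:
        d = {
            "format": "secscan-cm",
            "version": self.FORMAT_VERSION,
            "name": self.name,
            "domain_tag": self.domain_tag,
            "match_cols": self.match_cols,
            "pair_of": {str(k): v for k, v in self.pair_of.items()},
            "null": list(self.null),
            "emission_pseudocount": self.emission_pseudocount,
            "transition_pseudocount": self.transition_pseudocount,
            "nodes": [
                {"idx": n.idx, "kind": n.kind, "lcol": n.lcol, "rcol": n.rcol,
                 "child": n.child, "bif_left": n.bif_left,
                 "bif_right": n.bif_right, "parent": n.parent}
                for n in self.nodes
            ],
            "states": [
                {"idx": s.idx, "kind": s.kind, "node": s.node,
                 "children": s.children,
                 "t": None if s.t is None else [float(x) for x in s.t],
                 "t_prob": None if s.t_prob is None else [float(x) for x in s.t_prob],
                 "emit": None if s.emit is None else np.asarray(s.emit, dtype=float).ravel().tolist(),
                 "emit_prob": None if s.emit_prob is None else np.asarray(s.emit_prob, dtype=float).ravel().tolist()}
                for s in self.states
            ],
            "position_labels": None if self.position_map is None else
                {str(c): l for c, l in self.position_map.col_to_label.items()},
            "arm": None if self.structure is None else
                {str(c): a for c, a in self.structure.arm.items()},
            "ncol": None if self.structure is None else self.structure.ncol,
            "insert_owner": {str(c): [n, side] for c, (n, side) in self.insert_owner.items()},
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CovarianceModel":
        d = json.loads(text)
        if d.get("format") != "secscan-cm":
            raise ModelError("not a secscan covariance-model file")
        nodes = [Node(**nd) for nd in d["nodes"]]
        states = []
        for sd in d["states"]:
            emit = sd["emit"]
            eprob = sd["emit_prob"]
            if emit is not None:
                k = sd["kind"]
                shape = (6, 6) if k == "MP" else (6,)
                pshape = (4, 4) if k == "MP" else (4,)
                emit = np.asarray(emit, dtype=np.float64).reshape(shape)
                eprob = np.asarray(eprob, dtype=np.float64).reshape(pshape)
            states.append(State(
                idx=sd["idx"], kind=sd["kind"], node=sd["node"],
                children=list(sd["children"]),
                t=None if sd["t"] is None else np.asarray(sd["t"], dtype=np.float64),
                t_prob=None if sd["t_prob"] is None else np.asarray(sd["t_prob"], dtype=np.float64),
                emit=emit, emit_prob=eprob))
        sid = {}
        for s in states:
            sid[(s.node, s.kind)] = s.idx
        pmap = None
        if d["position_labels"] is not None:
            pmap = PositionMap.from_labels({int(c): l for c, l in d["position_labels"].items()})
        structure = None
        if d["arm"] is not None:
            pair_of = {int(k): v for k, v in d["pair_of"].items()}
            structure = ConsensusStructure(
                match_cols=list(d["match_cols"]),
                pair_partner=pair_of, arm={int(c): a for c, a in d["arm"].items()},
                ncol=d["ncol"])
        return cls(
            name=d["name"], domain_tag=d["domain_tag"],
            match_cols=list(d["match_cols"]),
            pair_of={int(k): v for k, v in d["pair_of"].items()},
            nodes=nodes, states=states, state_id=sid,
            position_map=pmap, structure=structure,
            null=tuple(d["null"]),
            emission_pseudocount=d["emission_pseudocount"],
            transition_pseudocount=d["transition_pseudocount"],
            insert_owner={int(c): (n, side) for c, (n, side) in d["insert_owner"].items()},
        )


def _assign_insert_owners(nodes: list[Node], match_cols: list[int],
                          ncol: int) -> dict[int, tuple[int, str]]:
    """Map every non-match alignment column to the insert state owning it."""
    match_set = set(match_cols)
    node_of_left = {n.lcol: n for n in nodes if n.lcol is not None}
    node_of_right = {n.rcol: n for n in nodes if n.rcol is not None and n.kind in ("MATP", "MATR")}
    left_consumed = set(node_of_left)
    right_consumed = set(node_of_right)
    owners: dict[int, tuple[int, str]] = {}
    for c in range(ncol):
        if c in match_set:
            continue
        p = max((m for m in match_cols if m < c), default=None)
        q = min((m for m in match_cols if m > c), default=None)
        if p is not None and p in left_consumed:
            owners[c] = (node_of_left[p].idx, "IL")
        elif q is not None and q in right_consumed:
            owners[c] = (node_of_right[q].idx, "IR")
        elif p is None and q is not None:
            owners[c] = (0, "IL")
        elif q is None and p is not None:
            owners[c] = (0, "IR")
        else:
            # between two arms: the BEGR insert of the separating bifurcation
            owner = (0, "IL")
            if q is not None:
                n = node_of_left.get(q) or node_of_right.get(q)
                while n is not None and n.parent is not None:
                    par = nodes[n.parent]
                    if par.kind == "BIF" and par.bif_right == n.idx:
                        owner = (n.idx, "IL")
                        break
                    if n.kind == "BEGR":
                        owner = (n.idx, "IL")
                        break
                    n = par
            owners[c] = owner
    return owners


def _implied_path(model_nodes: list[Node], sid: dict[tuple[int, str], int],
                  owners: dict[int, tuple[int, str]], row: str,
                  states: list[State]) -> list[int]:
    """State path implied by one aligned row (for transition counting)."""
    il_counts: dict[int, int] = {}
    ir_counts: dict[int, int] = {}
    for col, (nidx, side) in owners.items():
        if row[col] not in GAP_CHARS:
            tgt = il_counts if side == "IL" else ir_counts
            tgt[nidx] = tgt.get(nidx, 0) + 1

    path: list[int] = []

    def emitted(col: int | None) -> bool:
        return col is not None and row[col] not in GAP_CHARS

    def walk(nidx: int) -> None:
        n = model_nodes[nidx]
        if n.kind == "END":
            path.append(sid[(nidx, "E")])
            return
        if n.kind == "BIF":
            path.append(sid[(nidx, "B")])
            walk(n.bif_left)
            walk(n.bif_right)
            return
        if n.kind in ("ROOT", "BEGL", "BEGR"):
            path.append(sid[(nidx, "S")])
        elif n.kind == "MATP":
            le, re_ = emitted(n.lcol), emitted(n.rcol)
            kind = "MP" if le and re_ else "ML" if le else "MR" if re_ else "D"
            path.append(sid[(nidx, kind)])
        elif n.kind == "MATL":
            path.append(sid[(nidx, "ML" if emitted(n.lcol) else "D")])
        elif n.kind == "MATR":
            path.append(sid[(nidx, "MR" if emitted(n.rcol) else "D")])
        if (nidx, "IL") in sid:
            path.extend([sid[(nidx, "IL")]] * il_counts.get(nidx, 0))
        if (nidx, "IR") in sid:
            path.extend([sid[(nidx, "IR")]] * ir_counts.get(nidx, 0))
        walk(n.child)

    walk(0)
    return path


def build_model(aln: SeedAlignment, pseudocount: float = 1.0,
                transition_pseudocount: float = 1.0,
                gap_fraction: float = 0.5,
                name: str | None = None,
                intron_entry_floor: float | None = None,
                intron_extend_floor: float | None = None) -> CovarianceModel:
    """Build a covariance model from a structurally annotated alignment.

    ``pseudocount`` smooths match emissions (Laplace-style);
    ``transition_pseudocount`` scales a structured transition prior
    (continuation weight 1.0 per target, insert 0.02, delete 0.03) so
    indel paths stay improbable when trained on small gap-free seeds.  For cloverleaf
    seeds with a position map, the insert state at the canonical C-loop
    intron point (between positions 37 and 38) can have its entry/
    extension costs floored so intron-containing genes remain parseable.
    """
    if pseudocount <= 0:
        raise ModelError("pseudocount must be positive")
    if not aln.sequences:
        raise ModelError("empty alignment")

    match_cols = aln.match_columns(gap_fraction)
    if not match_cols:
        raise ModelError("alignment has no match columns")
    match_set = set(match_cols)
    partner_all = aln.pair_partner()
    pair_of = {i: j for i, j in partner_all.items()
               if i in match_set and j in match_set}

    nodes = _build_guide_tree(match_cols, pair_of)
    states, sid = _make_states(nodes)
    owners = _assign_insert_owners(nodes, match_cols, aln.ncol)

    # --- counts ---------------------------------------------------------
    tcounts = {s.idx: np.zeros(len(s.children)) for s in states
               if s.children and s.kind not in ("B", "E")}
    ecounts: dict[int, np.ndarray] = {}
    for s in states:
        if s.kind == "MP":
            ecounts[s.idx] = np.zeros((4, 4))
        elif s.kind in ("ML", "MR"):
            ecounts[s.idx] = np.zeros(4)

    child_index = {s.idx: {c: k for k, c in enumerate(s.children)} for s in states}

    for _, row in aln.sequences:
        path = _implied_path(nodes, sid, owners, row, states)
        for u, v in zip(path, path[1:]):
            ci = child_index[u].get(v)
            if ci is not None and u in tcounts:
                tcounts[u][ci] += 1
        for s_idx in path:
            s = states[s_idx]
            n = nodes[s.node]
            if s.kind == "MP":
                a = NT_INDEX.get(row[n.lcol].upper(), 4)
                b = NT_INDEX.get(row[n.rcol].upper(), 4)
                if a < 4 and b < 4:
                    ecounts[s_idx][a, b] += 1
            elif s.kind == "ML" and n.lcol is not None:
                a = NT_INDEX.get(row[n.lcol].upper(), 4)
                if a < 4:
                    ecounts[s_idx][a] += 1
            elif s.kind == "MR" and n.rcol is not None:
                b = NT_INDEX.get(row[n.rcol].upper(), 4)
                if b < 4:
                    ecounts[s_idx][b] += 1

    # --- probabilities and bit scores -----------------------------------
    # transition prior: continuation into match/begin/end states is likely,
    # indel states are not — keeps indels expensive even where the seed
    # provides no transition counts.  ML/MR of a pair node are half-deletions
    # and share the delete weight.
    def _prior_w(target: State) -> float:
        if target.kind in ("IL", "IR"):
            return 0.02
        if target.kind == "D":
            return 0.03
        if target.kind in ("ML", "MR") and nodes[target.node].kind == "MATP":
            return 0.03
        return 1.0

    null = np.asarray((0.25, 0.25, 0.25, 0.25))
    for s in states:
        if s.idx in tcounts:
            w = np.asarray([_prior_w(states[c]) for c in s.children])
            c = tcounts[s.idx] + transition_pseudocount * w
            p = c / c.sum()
            s.t_prob = p
            s.t = np.log2(p)
        if s.kind == "MP":
            c = ecounts[s.idx] + pseudocount
            p = c / c.sum()
            s.emit_prob = p
            e = np.full((6, 6), NEG_INF)
            e[:4, :4] = np.log2(p / np.outer(null, null))
            e[4, :5] = 0.0   # N emits at null odds
            e[:5, 4] = 0.0
            s.emit = e
        elif s.kind in ("ML", "MR"):
            c = ecounts[s.idx] + pseudocount
            p = c / c.sum()
            s.emit_prob = p
            e = np.full(6, NEG_INF)
            e[:4] = np.log2(p / null)
            e[4] = 0.0
            s.emit = e
        elif s.kind in ("IL", "IR"):
            s.emit_prob = null.copy()
            e = np.full(6, NEG_INF)
            e[:5] = 0.0       # inserts emit at the null distribution
            s.emit = e

    structure = None
    pmap = None
    try:
        structure, pmap = annotate_structure(aln, gap_fraction)
    except (StructureError, StockholmFormatError):
        pass

    model = CovarianceModel(
        name=name or aln.name or (aln.domain_tag or "model"),
        domain_tag=aln.domain_tag,
        match_cols=match_cols, pair_of=pair_of,
        nodes=nodes, states=states, state_id=sid,
        position_map=pmap, structure=structure,
        emission_pseudocount=pseudocount,
        transition_pseudocount=transition_pseudocount,
        insert_owner=owners,
    )

    # cap the insertion penalty at the canonical C-loop intron point
    if pmap is not None and pmap.col("37") is not None:
        entry = -2.0 if intron_entry_floor is None else intron_entry_floor
        extend = -0.25 if intron_extend_floor is None else intron_extend_floor
        _relax_intron_insert(model, entry, extend)
    return model


def intron_insert_state(model: CovarianceModel) -> int | None:
    """The IL state that emits between tRNA positions 37 and 38."""
    if model.position_map is None:
        return None
    col37 = model.position_map.col("37")
    if col37 is None:
        return None
    for n in model.nodes:
        if n.lcol == col37 and (n.idx, "IL") in model.state_id:
            return model.state_id[(n.idx, "IL")]
    return None


def _relax_intron_insert(model: CovarianceModel, entry_floor: float,
                         extend_floor: float) -> None:
    il = intron_insert_state(model)
    if il is None:
        return
    s = model.states[il]
    self_k = s.children.index(il)
    s.t = s.t.copy()
    s.t[self_k] = max(s.t[self_k], extend_floor)
    for other in model.states:
        if other.t is None or il not in other.children or other.idx == il:
            continue
        k = other.children.index(il)
        other.t = other.t.copy()
        other.t[k] = max(other.t[k], entry_floor)
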