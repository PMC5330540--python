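"""Covariance-model core: seed alignments, structure annotation, CYK scoring."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from secscan.cmcore.cyk import Parse, score_sequence, window_scores
from secscan.cmcore.model import (
    CovarianceModel,
    ModelError,
    build_model,
    intron_insert_state,
)
from secscan.cmcore.stockholm import (
    SeedAlignment,
    StockholmFormatError,
    parse_stockholm,
    write_stockholm,
)
from secscan.cmcore.structure import (
    ConsensusStructure,
    PositionMap,
    StructureError,
    annotate_structure,
)

BUNDLED = ("eukaryota", "bacteria", "archaea", "canonical")


def bundled_seed(name: str) -> SeedAlignment:
    """Load one of the bundled seed alignments (domain name or 'canonical')."""
    if name not in BUNDLED:
        raise ValueError(f"unknown bundled seed {name!r}; choose from {BUNDLED}")
    text = resources.files("secscan.data").joinpath(f"{name}.stk").read_text()
    return parse_stockholm(text)


@lru_cache(maxsize=None)
def load_bundled_model(name: str) -> CovarianceModel:
    """Build (and cache) the covariance model for a bundled seed."""
    return build_model(bundled_seed(name), name=name)


__all__ = [
    "BUNDLED",
    "ConsensusStructure",
    "CovarianceModel",
    "ModelError",
    "Parse",
    "PositionMap",
    "SeedAlignment",
    "StockholmFormatError",
    "StructureError",
    "annotate_structure",
    "build_model",
    "bundled_seed",
    "intron_insert_state",
    "load_bundled_model",
    "parse_stockholm",
    "score_sequence",
    "window_scores",
    "write_stockholm",
]
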