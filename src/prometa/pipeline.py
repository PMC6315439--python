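"""End-to-end convenience: harmonize simulated or loaded studies to consensus."""

from __future__ import annotations

from typing import Optional, Sequence

from .consensus import (
    ConsensusEntry,
    build_presence_matrix,
    call_consensus,
    cross_disease_overlap,
    jaccard,
)
from .ingest import IdMap, StudyTable, harmonize
from .simulate import SimulationConfig, simulate_study_set


def recover_consensus(
    studies: Sequence[StudyTable],
    idmap: IdMap,
    disease: str,
    stratum: str,
    min_studies: int = 2,
    tau: float = 1.2,
    convention: str = "ratio",
) -> list[ConsensusEntry]:
    """Map -> gate -> deduplicate -> presence matrix -> consensus for one stratum."""
    selected = [
        t for t in studies
        if t.meta.disease == disease and t.meta.stratum == stratum
    ]
    if not selected:
        raise ValueError(f"no studies for disease={disease!r}, stratum={stratum!r}")
    harmonized = [harmonize(t, idmap, tau=tau, convention=convention)[0] for t in selected]
    matrix = build_presence_matrix(harmonized, disease=disease, stratum=stratum)
    return call_consensus(matrix, min_studies=min_studies)


def recovery_jaccard(
    config: SimulationConfig,
    min_studies: int = 2,
    tau: float = 1.2,
) -> float:
    """Simulate, run the full pipeline, and score planted-overlap recovery.

    Returns the Jaccard similarity between the recovered cross-disease
    overlap symbol set and the planted shared set.
    """
    studies, idmap, truth = simulate_study_set(config)
    diseases = sorted(config.planted)
    if len(diseases) != 2:
        raise ValueError("recovery_jaccard needs exactly two planted diseases")
    consensus = [
        recover_consensus(studies, idmap, d, config.stratum, min_studies=min_studies, tau=tau)
        for d in diseases
    ]
    overlap = cross_disease_overlap(*consensus)
    return jaccard([e.symbol for e in overlap], truth["shared_symbols"])
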