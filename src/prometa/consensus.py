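"""Vote-counting consensus across harmonized study tables.

No effect sizes are pooled: a protein is a consensus hit within a stratum
when at least ``min_studies`` independent studies report it, and its
direction class records whether those studies agree (consistent_up /
consistent_down) or disagree (mixed). Biofluid and tissue/cell strata are
never pooled, because secretion into CSF or serum can invert a
tissue-level change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .ingest import StudyTable, UNMAPPED

ABSENT = "absent"

CONSISTENT_UP = "consistent_up"
CONSISTENT_DOWN = "consistent_down"
MIXED = "mixed"


@dataclass
class PresenceMatrix:
    """Symbol-by-study direction matrix for one disease and stratum.

    ``frame`` holds one row per gene symbol and one column per study id;
    cells are ``"up"``, ``"down"`` or ``"absent"``.
    """

    disease: str
    stratum: str
    frame: pd.DataFrame

    @property
    def symbols(self) -> list[str]:
        return list(self.frame.index)

    @property
    def study_ids(self) -> list[str]:
        return list(self.frame.columns)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="symbol")


@dataclass
class ConsensusEntry:
    symbol: str
    support: int
    n_up: int
    n_down: int
    direction_class: str
    supporting_study_ids: list[str] = field(default_factory=list)


@dataclass
class OverlapEntry:
    """A symbol reaching consensus in both diseases being compared."""

    symbol: str
    a: ConsensusEntry
    b: ConsensusEntry
    cross_disease_consistent: bool


def build_presence_matrix(
    studies: Sequence[StudyTable],
    disease: Optional[str] = None,
    stratum: Optional[str] = None,
) -> PresenceMatrix:
    """Cross-tabulate mapped, filtered study tables into a presence matrix.

    All studies must share one disease and one stratum (pass them explicitly
    to assert, or leave ``None`` to infer). Excluded and unmapped records are
    ignored; a symbol reported twice by one study with different directions
    is a contract violation (run :func:`prometa.ingest.deduplicate` first).
    """
    if not studies:
        raise ValueError("at least one study table is required")
    diseases = {t.meta.disease for t in studies}
    strata = {t.meta.stratum for t in studies}
    if len(diseases) > 1:
        raise ValueError(f"mixed diseases in input: {sorted(diseases)}")
    if len(strata) > 1:
        raise ValueError(f"mixed strata in input: {sorted(strata)}")
    if disease is not None and diseases != {disease}:
        raise ValueError(f"studies are {diseases}, expected {disease}")
    if stratum is not None and strata != {stratum}:
        raise ValueError(f"studies are {strata}, expected {stratum}")
    study_ids = [t.meta.study_id for t in studies]
    if len(set(study_ids)) != len(study_ids):
        raise ValueError("duplicate study_id in input")

    cells: dict[str, dict[str, str]] = {}
    for table in studies:
        sid = table.meta.study_id
        for rec in table.active_records():
            if rec.symbol in (None, UNMAPPED):
                continue
            row = cells.setdefault(rec.symbol, {})
            if sid in row and row[sid] != rec.direction:
                raise ValueError(
                    f"study {sid} reports {rec.symbol} in both directions; deduplicate first"
                )
            row[sid] = rec.direction

    frame = pd.DataFrame(ABSENT, index=sorted(cells), columns=study_ids, dtype=object)
    for symbol, row in cells.items():
        for sid, direction in row.items():
            frame.at[symbol, sid] = direction
    return PresenceMatrix(disease=diseases.pop(), stratum=strata.pop(), frame=frame)


def call_consensus(matrix: PresenceMatrix, min_studies: int = 2) -> list[ConsensusEntry]:
    """Return symbols supported by at least ``min_studies`` studies.

    Entries are sorted by support (descending) then symbol (ascending);
    ``direction_class`` is ``mixed`` iff both directions occur.
    """
    if min_studies < 1:
        raise ValueError(f"min_studies must be >= 1, got {min_studies}")
    entries: list[ConsensusEntry] = []
    for symbol in matrix.symbols:
        row = matrix.frame.loc[symbol]
        supporting = sorted(sid for sid in matrix.study_ids if row[sid] != ABSENT)
        n_up = int((row == "up").sum())
        n_down = int((row == "down").sum())
        support = n_up + n_down
        if support < min_studies:
            continue
        if n_up and n_down:
            direction_class = MIXED
        elif n_up:
            direction_class = CONSISTENT_UP
        else:
            direction_class = CONSISTENT_DOWN
        entries.append(
            ConsensusEntry(
                symbol=symbol,
                support=support,
                n_up=n_up,
                n_down=n_down,
                direction_class=direction_class,
                supporting_study_ids=supporting,
            )
        )
    entries.sort(key=lambda e: (-e.support, e.symbol))
    return entries


def cross_disease_overlap(
    consensus_a: Iterable[ConsensusEntry],
    consensus_b: Iterable[ConsensusEntry],
) -> list[OverlapEntry]:
    """Intersect two consensus lists on symbol.

    All consensus entries participate, including mixed-direction ones;
    ``cross_disease_consistent`` is True only when both entries are
    non-mixed and agree in direction. Output is sorted by symbol.
    """
    by_symbol_a = {e.symbol: e for e in consensus_a}
    by_symbol_b = {e.symbol: e for e in consensus_b}
    shared = sorted(set(by_symbol_a) & set(by_symbol_b))
    out = []
    for symbol in shared:
        ea, eb = by_symbol_a[symbol], by_symbol_b[symbol]
        consistent = (
            ea.direction_class != MIXED
            and ea.direction_class == eb.direction_class
        )
        out.append(OverlapEntry(symbol=symbol, a=ea, b=eb, cross_disease_consistent=consistent))
    return out


def consensus_to_frame(entries: Iterable[ConsensusEntry]) -> pd.DataFrame:
    rows = [
        {
            "symbol": e.symbol,
            "support": e.support,
            "n_up": e.n_up,
            "n_down": e.n_down,
            "direction_class": e.direction_class,
            "supporting_study_ids": ";".join(e.supporting_study_ids),
        }
        for e in entries
    ]
    return pd.DataFrame(rows, columns=[
        "symbol", "support", "n_up", "n_down", "direction_class", "supporting_study_ids",
    ])


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard similarity of two symbol sets; 1.0 when both are empty."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)
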