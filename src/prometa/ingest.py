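"""Reading, harmonizing and gating per-study differential-expression tables.

Published proteomic studies report their differentially expressed proteins
under heterogeneous identifiers (RefSeq/GI/IPI accessions, protein names,
gene symbols) and with heterogeneous effect summaries (fold changes,
qualitative up/down calls). Before any cross-study comparison the tables are
brought onto a common currency: official gene symbols, a symmetric
fold-change gate, and one record per symbol per study.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DISEASES = ("ALS", "SMA")
STRATA = ("biofluid", "tissue_cell")
DIRECTIONS = ("up", "down")

#: Sentinel symbol for records whose raw identifier has no mapping.
UNMAPPED = "UNMAPPED"

# excluded_reason values
BELOW_FC_THRESHOLD = "below_fc_threshold"
UNMAPPED_REASON = "unmapped"
DIRECTION_CONFLICT = "direction_conflict"
DUPLICATE_COLLAPSED = "duplicate_collapsed"
NOT_VS_HEALTHY_CONTROL = "not_vs_healthy_control"


@dataclass(frozen=True)
class StudyMeta:
    """Metadata of one source study.

    ``fc_prefiltered`` marks studies whose authors already applied a
    fold-change cutoff before publishing their table; the downstream 20%
    gate is skipped for those.
    """

    study_id: str
    disease: str
    stratum: str
    species: str = "human"
    sample_type: str = ""
    fc_prefiltered: bool = False
    citation: str = ""

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValueError("study_id must be non-empty")
        if self.disease not in DISEASES:
            raise ValueError(f"disease must be one of {DISEASES}, got {self.disease!r}")
        if self.stratum not in STRATA:
            raise ValueError(f"stratum must be one of {STRATA}, got {self.stratum!r}")


@dataclass
class StudyRecord:
    """One differentially expressed protein as reported by one study.

    ``fold_change`` is the positive disease/control ratio when the study
    reported one; some studies only report a direction. ``symbol`` is filled
    by :func:`map_identifiers`; excluded records stay in the table with an
    ``excluded_reason`` so that bookkeeping is auditable.
    """

    raw_id: str
    direction: str
    fold_change: Optional[float] = None
    symbol: Optional[str] = None
    excluded_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if self.fold_change is not None:
            fc = float(self.fold_change)
            if not math.isfinite(fc) or fc <= 0:
                raise ValueError(f"fold_change must be finite and > 0, got {fc!r}")
            if fc != 1.0:
                implied = "up" if fc > 1.0 else "down"
                if implied != self.direction:
                    raise ValueError(
                        f"direction {self.direction!r} inconsistent with fold change {fc}"
                    )
            self.fold_change = fc

    @property
    def direction_only(self) -> bool:
        """True when the study reported a qualitative change without a ratio."""
        return self.fold_change is None

    @property
    def active(self) -> bool:
        return self.excluded_reason is None


@dataclass
class StudyTable:
    meta: StudyMeta
    records: list[StudyRecord] = field(default_factory=list)

    def active_records(self) -> list[StudyRecord]:
        """Records that survived all filters so far (mapped ones if mapping ran)."""
        return [r for r in self.records if r.active]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class IdMap:
    """Raw identifier -> official gene symbol mapping, case-insensitive.

    ``overrides`` shadow ``entries`` — they replay the manual assignment
    step used when an accession is not recognized by the base resource.
    """

    entries: dict[str, str]
    overrides: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = self._normalize(self.entries)
        self.overrides = self._normalize(self.overrides)

    @staticmethod
    def _normalize(mapping: Mapping[str, str]) -> dict[str, str]:
        out: dict[str, str] = {}
        for raw, symbol in mapping.items():
            symbol = str(symbol).strip().upper()
            if not symbol:
                raise ValueError(f"empty symbol for raw id {raw!r}")
            out[str(raw).strip().lower()] = symbol
        return out

    def lookup(self, raw_id: str) -> Optional[str]:
        key = raw_id.strip().lower()
        if key in self.overrides:
            return self.overrides[key]
        return self.entries.get(key)

    def __len__(self) -> int:
        return len(set(self.entries) | set(self.overrides))

    @classmethod
    def from_tsv(cls, path: str | Path, overrides_path: str | Path | None = None) -> "IdMap":
        """Load a two-column ``raw_id<TAB>symbol`` table (no header)."""
        entries = _read_two_col(path)
        overrides = _read_two_col(overrides_path) if overrides_path else {}
        return cls(entries=entries, overrides=overrides)


def _read_two_col(path: str | Path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def _coerce_direction(value: str) -> str:
    token = str(value).strip().lower()
    aliases = {
        "up": "up", "increased": "up", "increase": "up", "+": "up",
        "down": "down", "decreased": "down", "decrease": "down", "-": "down",
    }
    if token not in aliases:
        raise ValueError(f"unrecognized direction value {value!r}")
    return aliases[token]


def read_study_table(
    path: str | Path,
    meta: StudyMeta,
    column_spec: Mapping[str, str],
) -> StudyTable:
    """Read one study's table into a :class:`StudyTable`.

    ``column_spec`` maps roles to column names and must contain ``"id"``
    plus at least one of ``"fc"`` / ``"direction"``. A row must provide a
    usable fold change or a direction; fold changes must be positive
    (ratios), and a fold change of exactly 1 needs an explicit direction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if "id" not in column_spec:
        raise ValueError("column_spec must name the identifier column under 'id'")
    if "fc" not in column_spec and "direction" not in column_spec:
        raise ValueError("column_spec must name a fold-change or direction column")

    frame = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
    for role, col in column_spec.items():
        if col not in frame.columns:
            raise ValueError(f"{path}: column {col!r} (role {role!r}) not found")

    records: list[StudyRecord] = []
    for idx, row in frame.iterrows():
        raw_id = str(row[column_spec["id"]]).strip()
        fc: Optional[float] = None
        if "fc" in column_spec:
            cell = row[column_spec["fc"]]
            if cell is not None and not pd.isna(cell) and str(cell).strip():
                try:
                    fc = float(cell)
                except ValueError as exc:
                    raise ValueError(f"{path} row {idx}: non-numeric fold change {cell!r}") from exc
                if not math.isfinite(fc) or fc <= 0:
                    raise ValueError(f"{path} row {idx}: non-positive fold change {fc}")
        direction: Optional[str] = None
        if "direction" in column_spec:
            cell = row[column_spec["direction"]]
            if cell is not None and not pd.isna(cell) and str(cell).strip():
                direction = _coerce_direction(cell)
        if fc is None and direction is None:
            raise ValueError(f"{path} row {idx}: neither fold change nor direction available")
        if direction is None:
            if fc == 1.0:
                raise ValueError(f"{path} row {idx}: fold change 1.0 carries no direction")
            direction = "up" if fc > 1.0 else "down"
        records.append(StudyRecord(raw_id=raw_id, direction=direction, fold_change=fc))
    return StudyTable(meta=meta, records=records)


def map_identifiers(table: StudyTable, idmap: IdMap) -> tuple[StudyTable, list[str]]:
    """Assign official gene symbols; unmapped ids are reported, not fatal.

    Matching is case-insensitive on the raw identifier; override entries win.
    Re-applying the same map is a fixed point.
    """
    if len(idmap) == 0:
        raise ValueError("identifier map is empty")
    unmapped: list[str] = []
    new_records = []
    for rec in table.records:
        symbol = idmap.lookup(rec.raw_id)
        if symbol is None:
            unmapped.append(rec.raw_id)
            new_records.append(replace(rec, symbol=UNMAPPED, excluded_reason=UNMAPPED_REASON))
        else:
            reason = rec.excluded_reason
            if reason == UNMAPPED_REASON:
                reason = None  # a better map may rescue a previously unmapped record
            new_records.append(replace(rec, symbol=symbol, excluded_reason=reason))
    return StudyTable(meta=table.meta, records=new_records), sorted(set(unmapped))


def apply_fc_filter(
    table: StudyTable,
    tau: float = 1.2,
    convention: str = "ratio",
) -> StudyTable:
    """Apply the "at least 20% change" gate (tau = 1.2 by default).

    Under the default ``ratio`` convention a record passes iff
    FC >= tau or FC <= 1/tau (boundaries inclusive) — symmetric in log
    space. The ``arithmetic`` convention gates on \\|FC - 1\\| >= tau - 1
    (down cutoff 0.8 at tau = 1.2). Direction-only records pass, studies
    whose authors already applied a cutoff (``fc_prefiltered``) pass
    unchanged, and removed records stay in the table flagged
    ``below_fc_threshold``.
    """
    if tau <= 1:
        raise ValueError(f"tau must be > 1, got {tau}")
    if convention not in ("ratio", "arithmetic"):
        raise ValueError(f"convention must be 'ratio' or 'arithmetic', got {convention!r}")
    if table.meta.fc_prefiltered:
        return table

    def passes(fc: float) -> bool:
        if convention == "ratio":
            return fc >= tau or fc <= 1.0 / tau
        return abs(fc - 1.0) >= tau - 1.0

    new_records = []
    for rec in table.records:
        if not rec.active or rec.fold_change is None:
            new_records.append(rec)
        elif passes(rec.fold_change):
            new_records.append(rec)
        else:
            new_records.append(replace(rec, excluded_reason=BELOW_FC_THRESHOLD))
    return StudyTable(meta=table.meta, records=new_records)


def deduplicate(table: StudyTable) -> StudyTable:
    """Collapse duplicate symbols (isoforms/peptides) to one record per study.

    Same-direction duplicates keep the record with the largest |log FC|
    (direction-only records rank lowest). Duplicates with conflicting
    directions contribute to neither direction: all of them are excluded
    with reason ``direction_conflict`` and the conflict is logged.
    """
    groups: dict[str, list[StudyRecord]] = {}
    passthrough: list[StudyRecord] = []
    order: list[str] = []
    for rec in table.records:
        if rec.active and rec.symbol not in (None, UNMAPPED):
            if rec.symbol not in groups:
                groups[rec.symbol] = []
                order.append(rec.symbol)
            groups[rec.symbol].append(rec)
        else:
            passthrough.append(rec)

    kept: list[StudyRecord] = []
    for symbol in order:
        recs = groups[symbol]
        directions = {r.direction for r in recs}
        if len(directions) > 1:
            logger.warning(
                "study %s: symbol %s reported in conflicting directions; dropped",
                table.meta.study_id, symbol,
            )
            kept.extend(replace(r, excluded_reason=DIRECTION_CONFLICT) for r in recs)
            continue
        best = max(
            recs,
            key=lambda r: abs(math.log(r.fold_change)) if r.fold_change is not None else -1.0,
        )
        kept.append(best)
        kept.extend(
            replace(r, excluded_reason=DUPLICATE_COLLAPSED) for r in recs if r is not best
        )
    return StudyTable(meta=table.meta, records=kept + passthrough)


def harmonize(
    table: StudyTable,
    idmap: IdMap,
    tau: float = 1.2,
    convention: str = "ratio",
) -> tuple[StudyTable, list[str]]:
    """Full per-study pipeline: map identifiers, gate fold changes, deduplicate."""
    mapped, unmapped = map_identifiers(table, idmap)
    gated = apply_fc_filter(mapped, tau=tau, convention=convention)
    return deduplicate(gated), unmapped
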