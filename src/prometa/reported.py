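"""Published per-protein study-membership tables, as printed.

Three small tables transcribed from the published comparison are shipped
with the package so the presence-matrix/consensus machinery can be checked
against printed counts:

* the ALS biofluid proteins whose per-study citations are given explicitly
  (cystatin C, down in four studies; chitinase-3-like 1, up in three);
* the eleven ALS tissue/cell proteins upregulated across three or more
  studies, with their supporting-study citations;
* the fifteen proteins differentially expressed in both ALS and SMA, with
  their supporting studies split by disease.

The cross-disease table records *membership* only: the per-study directions
behind it were published as a figure, not as text, so the loader assigns a
placeholder direction and downstream results from it are meaningful for
support counts and overlap size — never for direction classes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .ingest import StudyMeta, StudyRecord, StudyTable

_PLACEHOLDER_DIRECTION = "up"


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("prometa.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def _studies_from_membership(
    frame: pd.DataFrame,
    disease: str,
    stratum: str,
    studies_col: str,
    direction_col: str | None,
) -> list[StudyTable]:
    """Invert a symbol -> supporting-studies table into per-study tables."""
    per_study: dict[str, list[StudyRecord]] = {}
    for _, row in frame.iterrows():
        symbol = row["symbol"].strip().upper()
        direction = row[direction_col].strip() if direction_col else _PLACEHOLDER_DIRECTION
        for sid in str(row[studies_col]).split(";"):
            sid = sid.strip()
            if not sid:
                continue
            per_study.setdefault(sid, []).append(
                StudyRecord(raw_id=symbol, direction=direction, symbol=symbol)
            )
    tables = []
    for sid in sorted(per_study):
        meta = StudyMeta(
            study_id=sid, disease=disease, stratum=stratum,
            species="as published", fc_prefiltered=True, citation=sid,
        )
        tables.append(StudyTable(meta=meta, records=per_study[sid]))
    return tables


def biofluid_consensus_studies() -> list[StudyTable]:
    """ALS biofluid studies behind the two explicitly cited consensus proteins."""
    frame = _read_packaged("als_biofluid_consensus.tsv")
    return _studies_from_membership(frame, "ALS", "biofluid", "studies", "direction")


def tissue_top_studies() -> list[StudyTable]:
    """ALS tissue/cell studies behind the eleven 3+-study upregulated proteins."""
    frame = _read_packaged("als_tissue_top_upregulated.tsv")
    return _studies_from_membership(frame, "ALS", "tissue_cell", "studies", "direction")


def cross_disease_studies() -> tuple[list[StudyTable], list[StudyTable]]:
    """(ALS studies, SMA studies) behind the 15 shared proteins — membership only.

    Directions are placeholders (see module docstring); use the result for
    support counts and overlap membership, not for direction classes.
    """
    frame = _read_packaged("cross_disease_members.tsv")
    als = _studies_from_membership(frame, "ALS", "tissue_cell", "als_studies", None)
    sma = _studies_from_membership(frame, "SMA", "tissue_cell", "sma_studies", None)
    return als, sma


def overlap_symbols() -> list[str]:
    """The published 15 shared symbols, sorted."""
    frame = _read_packaged("cross_disease_members.tsv")
    return sorted(frame["symbol"].str.strip().str.upper())
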