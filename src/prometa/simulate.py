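"""Synthetic multi-study datasets with known ground truth.

The generator emulates the statistical structure a cross-study differential
proteomics comparison operates on: a shared gene universe, a planted
dysregulated set per disease (with a shared core across diseases), per-study
detection of planted genes, log-normal fold changes around a planted
direction with occasional direction flips, sporadic background (false
positive) genes near fold change 1, and heterogeneous accession styles that
force identifier mapping. Generation starts at the differential-protein-table
level — no spectra, peptides or instrument noise are modelled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .ingest import IdMap, StudyMeta, StudyRecord, StudyTable
from .quantify import QuantSample

_ACCESSION_STYLES = ("NP_{:06d}", "gi|{:d}", "IPI{:08d}", "{sym}")


@dataclass
class SimulationConfig:
    """Study-condition knobs for the multi-study generator.

    Defaults reflect a benign multi-study setting: five studies per disease,
    high per-study detection of truly dysregulated proteins (most published
    tables are post-cutoff), rare direction flips, a small false-positive
    rate, and planted |log2 FC| = log2 1.5 with spread 0.3 so that a
    realistic fraction of noisy draws falls below the 1.2 gate.
    """

    n_genes: int = 500
    planted: dict[str, dict[str, str]] = field(default_factory=dict)  # disease -> symbol -> direction
    n_studies: int = 5                # per disease (one stratum)
    detect_prob: float = 0.95
    flip_prob: float = 0.02
    fc_lognormal_sigma: float = 0.3   # spread of log2 FC
    mean_log_fc: float = math.log2(1.5)  # planted |log2 FC|
    background_rate: float = 0.01     # expected fraction of unplanted genes per study
    background_log_fc_sigma: float = 0.5  # log2 spread of false-positive FCs (some inside the gate)
    id_obfuscation: bool = True
    stratum: str = "tissue_cell"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("detect_prob", "flip_prob", "background_rate"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


def gene_universe(n_genes: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n_genes)]


def default_two_disease_config(
    seed: int = 0,
    n_genes: int = 500,
    n_planted_per_disease: int = 40,
    n_shared: int = 15,
    **overrides,
) -> SimulationConfig:
    """Config with planted ALS and SMA sets sharing ``n_shared`` genes.

    The shared-core size defaults to 15 — the scale of overlap a two-disease
    comparison is expected to resolve. Directions are drawn independently
    per disease, so a shared gene may disagree in direction across diseases.
    """
    if 2 * n_planted_per_disease - n_shared > n_genes:
        raise ValueError("planted sets do not fit in the universe")
    rng = np.random.default_rng(seed)
    universe = gene_universe(n_genes)
    chosen = rng.choice(n_genes, size=2 * n_planted_per_disease - n_shared, replace=False)
    shared = chosen[:n_shared]
    only_a = chosen[n_shared:n_planted_per_disease]
    only_b = chosen[n_planted_per_disease:]
    planted = {}
    for disease, idx in (("ALS", np.concatenate([shared, only_a])),
                         ("SMA", np.concatenate([shared, only_b]))):
        directions = rng.choice(["up", "down"], size=idx.size)
        planted[disease] = {universe[i]: d for i, d in zip(sorted(idx), directions)}
    return SimulationConfig(
        n_genes=n_genes, planted=planted, seed=seed, **overrides
    )


def _make_idmap(
    universe: list[str], obfuscate: bool, rng: np.random.Generator
) -> tuple[IdMap, dict[str, str]]:
    """Accession -> symbol map plus the symbol -> styled-accession inverse."""
    entries: dict[str, str] = {}
    symbol_to_raw: dict[str, str] = {}
    seen: set[str] = set()
    for symbol in universe:
        if obfuscate:
            while True:
                style = _ACCESSION_STYLES[int(rng.integers(len(_ACCESSION_STYLES)))]
                number = int(rng.integers(1, 10_000_000))
                raw = style.format(number, sym=symbol.lower())
                if raw.lower() not in seen:
                    break
        else:
            raw = symbol
        seen.add(raw.lower())
        entries[raw] = symbol
        symbol_to_raw[symbol] = raw
    return IdMap(entries=entries), symbol_to_raw


def simulate_study_set(
    config: SimulationConfig,
) -> tuple[list[StudyTable], IdMap, dict]:
    """Generate per-study differential tables, an identifier map and the truth.

    Each study reports each planted gene of its disease with
    ``detect_prob``; the reported direction is the planted one flipped with
    ``flip_prob``, and the fold change is 2**x with
    x ~ Normal(±mean_log_fc, fc_lognormal_sigma) on the reported side.
    Unplanted genes appear with probability ``background_rate`` per study,
    with log2 FC ~ Normal(0, background_log_fc_sigma) — many of those fall
    inside the 20% band and exercise the fold-change gate. The same config
    (including seed) reproduces identical output.
    """
    rng = np.random.default_rng(config.seed)
    universe = gene_universe(config.n_genes)
    for disease, genes in config.planted.items():
        unknown = set(genes) - set(universe)
        if unknown:
            raise ValueError(f"planted symbols outside the universe: {sorted(unknown)[:5]}")
    idmap, symbol_to_raw = _make_idmap(universe, config.id_obfuscation, rng)

    studies: list[StudyTable] = []
    for disease in sorted(config.planted):
        planted = config.planted[disease]
        unplanted = [g for g in universe if g not in planted]
        for s in range(config.n_studies):
            meta = StudyMeta(
                study_id=f"{disease}_{config.stratum}_s{s:02d}",
                disease=disease,
                stratum=config.stratum,
                species="synthetic",
                sample_type="synthetic",
                fc_prefiltered=False,
                citation="simulated",
            )
            records: list[StudyRecord] = []
            for symbol in sorted(planted):
                if rng.random() > config.detect_prob:
                    continue
                direction = planted[symbol]
                if rng.random() < config.flip_prob:
                    direction = "down" if direction == "up" else "up"
                sign = 1.0 if direction == "up" else -1.0
                log2_fc = rng.normal(sign * config.mean_log_fc, config.fc_lognormal_sigma)
                # keep the drawn FC on the reported side so record invariants hold
                if sign * log2_fc <= 0:
                    log2_fc = sign * abs(log2_fc) if log2_fc != 0 else sign * 1e-6
                records.append(StudyRecord(
                    raw_id=symbol_to_raw[symbol],
                    direction=direction,
                    fold_change=2.0 ** log2_fc,
                ))
            for symbol in unplanted:
                if rng.random() >= config.background_rate:
                    continue
                log2_fc = rng.normal(0.0, config.background_log_fc_sigma)
                if log2_fc == 0.0:
                    continue
                records.append(StudyRecord(
                    raw_id=symbol_to_raw[symbol],
                    direction="up" if log2_fc > 0 else "down",
                    fold_change=2.0 ** log2_fc,
                ))
            studies.append(StudyTable(meta=meta, records=records))

    truth = {
        "planted": {d: dict(sorted(g.items())) for d, g in config.planted.items()},
        "shared_symbols": sorted(
            set.intersection(*(set(g) for g in config.planted.values()))
        ) if len(config.planted) > 1 else [],
        "universe_size": config.n_genes,
    }
    return studies, idmap, truth


def write_study_set(
    studies: list[StudyTable],
    idmap: IdMap,
    truth: dict,
    out_dir: str | Path,
) -> None:
    """Emit study TSVs + meta YAMLs, the IdMap TSV and the truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for table in studies:
        sid = table.meta.study_id
        with open(out_dir / f"{sid}.tsv", "w") as fh:
            fh.write("identifier\tfold_change\tdirection\n")
            for rec in table.records:
                fc = "" if rec.fold_change is None else f"{rec.fold_change:.6g}"
                fh.write(f"{rec.raw_id}\t{fc}\t{rec.direction}\n")
        with open(out_dir / f"{sid}.meta.yaml", "w") as fh:
            yaml.safe_dump(asdict(table.meta), fh, sort_keys=True)
    with open(out_dir / "idmap.tsv", "w") as fh:
        for raw in sorted(idmap.entries):
            fh.write(f"{raw}\t{idmap.entries[raw]}\n")
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)


def simulate_quant_fixture(
    effect: float,
    n_per_group: int = 5,
    noise_cv: float = 0.0,
    seed: int = 0,
    baseline: float = 1.0,
) -> tuple[QuantSample, QuantSample]:
    """Disease/control measurement pair with a planted mean ratio ``effect``.

    Control values follow a log-normal law with arithmetic mean ``baseline``
    and coefficient of variation ``noise_cv`` (exactly constant at cv = 0);
    disease values are an independent draw scaled by ``effect``. With
    noise_cv = 0 the percent change is exactly 100 x (effect - 1).
    """
    if effect <= 0:
        raise ValueError("effect must be > 0")
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    if noise_cv == 0:
        control = np.full(n_per_group, baseline)
        disease = np.full(n_per_group, baseline * effect)
    else:
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        mu = math.log(baseline) - sigma**2 / 2.0  # arithmetic mean = baseline
        control = rng.lognormal(mu, sigma, size=n_per_group)
        disease = effect * rng.lognormal(mu, sigma, size=n_per_group)
    return QuantSample("disease", disease), QuantSample("control", control)
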