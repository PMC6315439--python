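"""Over-representation and association-network summaries of the overlap set.

The 15 shared proteins are tested against a synthetic annotation collection
(written by this script as a GMT so the file-driven path is exercised) and a
synthetic confidence-scored edge table thresholded at the conventional 0.700
high-confidence score. Both inputs are stand-ins with a planted structure —
an "extracellular vesicle" term containing the whole overlap set and a core
association module around the glycolytic/chaperone proteins — so the point
of this script is the machinery, not biological novelty.
"""

import argparse
import itertools
import json
from pathlib import Path

import numpy as np

from prometa import (
    enrich,
    filter_edges,
    merge_redundant_terms,
    read_edge_table,
    read_gmt,
    reported,
    summarize,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def write_synthetic_gmt(path: Path, symbols: list[str], rng: np.random.Generator) -> None:
    filler = [f"BG{i:03d}" for i in range(400)]
    lines = [
        "CC:EV\textracellular vesicle\t" + "\t".join(symbols + filler[:85]),
        "CC:EV_DUP\textracellular organelle\t" + "\t".join(symbols + filler[85:170]),
        "BP:GLYCO\tglucose catabolism\t" + "\t".join(
            ["ALDOA", "GAPDH", "PGK1"] + filler[200:260]),
        "CC:OTHER\tunrelated compartment\t" + "\t".join(filler[100:250]),
    ]
    path.write_text("\n".join(lines) + "\n")


def write_synthetic_edges(path: Path, symbols: list[str], rng: np.random.Generator) -> None:
    """One isolate (CNP) plus a connected module over the remaining proteins."""
    connected = [s for s in symbols if s != "CNP"]
    rows = ["node_a\tnode_b\tcombined_score"]
    hub = "GAPDH"
    for other in connected:
        if other != hub:
            rows.append(f"{hub}\t{other}\t{int(rng.integers(750, 999))}")
    for a, b in itertools.combinations(connected, 2):
        if hub in (a, b):
            continue
        score = int(rng.integers(200, 999))
        rows.append(f"{a}\t{b}\t{score}")
    path.write_text("\n".join(rows) + "\n")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--min-score", type=float, default=0.700)
    args = parser.parse_args()

    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(args.seed)
    symbols = reported.overlap_symbols()

    gmt_path = RESULTS / "synthetic_annotation.gmt"
    write_synthetic_gmt(gmt_path, symbols, rng)
    collection = read_gmt(gmt_path)
    records = merge_redundant_terms(
        enrich(symbols, collection, method="hypergeometric", min_term_overlap=3)
    )
    print(f"enriched terms (raw p <= 0.05, >= 3 proteins): {len(records)}")
    for rec in records:
        print(f"  {rec.term_name}: k={rec.k}/{rec.n}, K={rec.K}, "
              f"p={rec.p_raw:.3g}, BH p={rec.p_adjusted:.3g}")

    edges_path = RESULTS / "synthetic_edges.tsv"
    write_synthetic_edges(edges_path, symbols, rng)
    edge_list = read_edge_table(edges_path, score_scale="milli", nodes=symbols)
    summary = summarize(filter_edges(edge_list, args.min_score))
    print(f"network at score >= {args.min_score}: "
          f"largest component {len(summary.components[0])} of {len(symbols)} proteins, "
          f"isolates: {sorted(summary.isolates)}, top degree: {summary.top_degree()}")

    (RESULTS / "enrichment_network.json").write_text(json.dumps({
        "enriched_terms": [
            {"term": r.term_name, "k": r.k, "p_raw": r.p_raw, "p_bh": r.p_adjusted}
            for r in records
        ],
        "largest_component_size": len(summary.components[0]),
        "isolates": sorted(summary.isolates),
        "top_degree_node": summary.top_degree(),
    }, indent=2) + "\n")


if __name__ == "__main__":
    main()
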