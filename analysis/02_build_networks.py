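#!/usr/bin/env python
"""Build single-sample networks and summarize their edge structure.

For every sample of the simulated cohort, constructs the SSN against the
control-group reference and records the number of significant
differential-correlation edges plus how many fall inside the planted
module. Stage-A samples should show clear enrichment of module-internal
edges; one stage-A sample's full edge list is exported for inspection.
"""

import json
from pathlib import Path

import pandas as pd

from ldnb.io import read_abundance, read_metadata, write_edges, write_sif
from ldnb.ssn import build_ssn, compute_reference_stats

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    abundance = read_abundance(BASE / "cohort" / "abundance.tsv")
    metadata = read_metadata(BASE / "cohort" / "metadata.tsv")
    truth = json.loads((BASE / "cohort" / "truth.json").read_text())
    module = set(truth["truth_module"])

    refs = list(metadata.index[metadata["group"] == "control"])
    ref_stats = compute_reference_stats(abundance, refs)

    rows = []
    example_net = None
    for sid in metadata.index:
        net = build_ssn(abundance, refs, sid, ref_stats=ref_stats)
        idx = {m: i for i, m in enumerate(net.molecule_ids)}
        mod_idx = [idx[m] for m in module]
        in_module = net.adjacency[mod_idx][:, mod_idx].sum() // 2
        rows.append(
            (sid, metadata.loc[sid, "group"], net.n_edges, int(in_module))
        )
        if example_net is None and metadata.loc[sid, "group"] == "stageA":
            example_net = net
    table = pd.DataFrame(
        rows, columns=["sample_id", "group", "n_edges", "module_edges"]
    )
    table.to_csv(BASE / "ssn_edge_summary.tsv", sep="\t", index=False)
    write_edges(example_net, BASE / f"ssn_{example_net.sample_id}_edges.tsv")
    write_sif(example_net, BASE / f"ssn_{example_net.sample_id}.sif")

    by_group = table.groupby("group")[["n_edges", "module_edges"]].mean().round(1)
    print("mean SSN edges per group (45 possible module-internal pairs):")
    print(by_group.to_string())
    a = by_group.loc["stageA", "module_edges"]
    c = by_group.loc["control", "module_edges"]
    print(
        f"\nstage-A samples carry {a:.1f} module-internal edges on average "
        f"vs {c:.1f} in controls -- the planted module lights up at the "
        "predisease stage."
    )
    print(f"tables written to {BASE}")


if __name__ == "__main__":
    main()
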