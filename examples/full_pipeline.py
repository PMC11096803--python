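"""Run the three analyses end to end from a YAML config.

Writes a complete synthetic input set (tree ensemble + seeds, virus/host
trees + tip-host map, GenBank segments) into a working directory, then
drives classification, congruence, and RBS scanning through the pipeline
exactly as the `picobirnatax run --config run.yaml` command would.
"""

import json
import tempfile
from pathlib import Path

import yaml

from picobirnatax.pipeline import RunConfig, run_all
from picobirnatax.rbs import write_genbank
from picobirnatax.simulate import (
    simulate_cophylogeny,
    simulate_ensemble,
    simulate_segments,
    yule_tree,
)
from picobirnatax.trees import write_newick

workdir = Path(tempfile.mkdtemp(prefix="picobirnatax_demo_"))

ens = simulate_ensemble(n_clusters=4, cluster_sizes=[10] * 4, n_trees=5,
                        n_migrants=2, seed=1)
manifest = ["tree_id\tpath\trooting"]
for tid, tree in zip(ens.tree_ids, ens.trees):
    (workdir / f"{tid}.nwk").write_text(write_newick(tree) + "\n")
    manifest.append(f"{tid}\t{tid}.nwk\tnone")
(workdir / "manifest.tsv").write_text("\n".join(manifest) + "\n")
seed_rows = ["genus_label\ttip_id"]
for s in ens.seeds:
    seed_rows += [f"{s.genus_label}\t{t}" for t in sorted(s.member_tips)]
(workdir / "seeds.tsv").write_text("\n".join(seed_rows) + "\n")

host = yule_tree(12, seed=2, tip_prefix="H")
hist = simulate_cophylogeny(host, p_transfer=0.25, seed=3, n_extant_target=8)
(workdir / "host.nwk").write_text(write_newick(host) + "\n")
(workdir / "virus.nwk").write_text(write_newick(hist.virus_tree) + "\n")
hist.tip_map.to_tsv(workdir / "map.tsv")

pss = simulate_segments(n_segments=20, orfs_per_segment=2, seed=4,
                        dataset_label="synthetic segment 1")
write_genbank(pss.segments, workdir / "segments.gbk")

config = {
    "seed": 11,
    "output_dir": "out",
    "classify": {"trees_manifest": "manifest.tsv", "seeds": "seeds.tsv",
                 "min_support": 80, "purity": 0.9},
    "congruence": {"virus_tree": "virus.nwk", "host_tree": "host.nwk",
                   "map": "map.tsv", "costs": [0, 1, 1, 1], "samples": 100},
    "rbs": {"inputs": [{"path": "segments.gbk",
                        "label": "synthetic segment 1"}], "window": 24},
}
(workdir / "run.yaml").write_text(yaml.safe_dump(config))

report = run_all(RunConfig.from_yaml(workdir / "run.yaml"))
print(f"outputs in {workdir / 'out'}")
print(json.dumps(
    {
        "classify": {k: report["classify"][k]
                     for k in ("n_assigned", "n_unclassified")},
        "congruence": {
            "nPH85": report["congruence"]["nph85"]["nPH85"],
            "CST": report["congruence"]["reconciliation"]
            ["event_proportions"]["cross_species_transmission"],
        },
        "rbs": {"pct_with_motif": report["rbs"]["table"][0]
                ["pct_with_motif"]},
    },
    indent=2, sort_keys=True,
))
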