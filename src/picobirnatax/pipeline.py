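"""End-to-end orchestration: classification, congruence, and RBS scanning.

A run is driven by a YAML config naming the inputs and thresholds for each
stage; stages present in the config are executed in order (classify,
congruence, rbs) and each writes its own TSV/JSON outputs plus a shared
``report.json`` and run manifest. Reports are byte-identical across runs
with the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from picobirnatax import __version__
from picobirnatax.classify import (
    classify_ensemble,
    detect_seeds,
    read_seeds_tsv,
)
from picobirnatax.cophylogeny import (
    EventCosts,
    TipHostMap,
    event_likelihoods,
    nph85,
    reconcile_mpr,
)
from picobirnatax.rbs import (
    filter_segments,
    frequency_table,
    read_fasta_gff3,
    read_genbank,
    scan_segments,
)
from picobirnatax.trees import (
    Tree,
    midpoint_root,
    parse_newick,
    root_with_outgroup,
)

log = logging.getLogger("picobirnatax")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    output_dir: Path = Path("picobirnatax_out")
    classify: Optional[dict] = None
    congruence: Optional[dict] = None
    rbs: Optional[dict] = None
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def resolve(p) -> str:
            q = Path(p)
            return str(q if q.is_absolute() else base / q)

        cfg = cls(
            seed=int(raw.get("seed", 0)),
            output_dir=Path(resolve(raw.get("output_dir", "picobirnatax_out"))),
            classify=raw.get("classify"),
            congruence=raw.get("congruence"),
            rbs=raw.get("rbs"),
            raw=raw,
        )
        # resolve and validate referenced paths up front
        missing = []
        if cfg.classify:
            cfg.classify["trees_manifest"] = resolve(
                cfg.classify["trees_manifest"]
            )
            if not Path(cfg.classify["trees_manifest"]).exists():
                missing.append(cfg.classify["trees_manifest"])
            if cfg.classify.get("seeds"):
                cfg.classify["seeds"] = resolve(cfg.classify["seeds"])
                if not Path(cfg.classify["seeds"]).exists():
                    missing.append(cfg.classify["seeds"])
        if cfg.congruence:
            for key in ("virus_tree", "host_tree", "map"):
                cfg.congruence[key] = resolve(cfg.congruence[key])
                if not Path(cfg.congruence[key]).exists():
                    missing.append(cfg.congruence[key])
        if cfg.rbs:
            for inp in cfg.rbs.get("inputs", []):
                for key in ("path", "fasta", "gff3"):
                    if key in inp:
                        inp[key] = resolve(inp[key])
                        if not Path(inp[key]).exists():
                            missing.append(inp[key])
        if missing:
            raise ConfigError(f"missing input files: {missing}")
        for key, lo, hi in (
            ("min_support", 0, 100),
            ("purity", 0, 1),
        ):
            if cfg.classify and key in cfg.classify:
                v = cfg.classify[key]
                if not (lo <= v <= hi):
                    raise ConfigError(f"classify.{key}={v} outside [{lo},{hi}]")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_tree(path, rooting: str = "none") -> Tree:
    """Read one Newick tree and apply its rooting scheme.

    ``rooting`` is ``midpoint``, ``outgroup:<file with one tip per line>``,
    or ``none``.
    """
    with open(path) as fh:
        tree = parse_newick(fh.read())
    if rooting == "midpoint":
        return midpoint_root(tree)
    if rooting.startswith("outgroup:"):
        ogfile = rooting.split(":", 1)[1]
        with open(ogfile) as fh:
            tips = [line.strip() for line in fh if line.strip()]
        return root_with_outgroup(tree, tips)
    if rooting in ("none", "", None):
        return tree
    raise ConfigError(f"unknown rooting scheme {rooting!r}")


def load_ensemble(manifest_path) -> tuple[list[Tree], list[str]]:
    """Read an ensemble manifest (TSV: tree_id, path, rooting)."""
    df = pd.read_csv(manifest_path, sep="\t", dtype=str)
    need = {"tree_id", "path"}
    if not need <= set(df.columns):
        raise ConfigError("manifest needs columns tree_id, path[, rooting]")
    base = Path(manifest_path).parent
    trees, ids = [], []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        rooting = row.get("rooting", "none")
        if not isinstance(rooting, str):
            rooting = "none"
        if rooting.startswith("outgroup:"):
            og = Path(rooting.split(":", 1)[1])
            if not og.is_absolute():
                og = base / og
            rooting = f"outgroup:{og}"
        trees.append(load_tree(p, rooting))
        ids.append(row["tree_id"])
    return trees, ids


def run_classify(cfg: RunConfig, outdir: Path) -> dict:
    c = cfg.classify
    t0 = time.monotonic()
    trees, ids = load_ensemble(c["trees_manifest"])
    if c.get("seeds"):
        seeds = read_seeds_tsv(c["seeds"])
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            seeds = detect_seeds(
                trees[0],
                min_support=c.get("min_support", 80.0),
                min_stem_factor=c.get("min_stem_factor", 2.0),
                min_seed_size=c.get("min_seed_size", 5),
            )
        if not seeds:
            raise ValueError(
                "no seeds detected on the reference tree; supply a seeds file"
            )
    ga = classify_ensemble(
        trees,
        seeds,
        min_support=c.get("min_support", 80.0),
        purity=c.get("purity", 0.90),
        tree_ids=ids,
        allow_missing_tips=bool(c.get("allow_missing_tips", False)),
    )
    ga.assignments_frame().to_csv(
        outdir / "assignments.tsv", sep="\t", index=False
    )
    ga.evidence_frame().to_csv(outdir / "evidence.tsv", sep="\t", index=False)
    core = ga.core_counts()
    n_uncl = sum(1 for g in ga.assignments.values() if g == "unclassified")
    log.info(
        "classify: %d trees, %d seeds, %d assigned, %d unclassified "
        "(%.1fs)",
        len(trees), len(seeds), sum(core.values()), n_uncl,
        time.monotonic() - t0,
    )
    return {
        "n_trees": len(trees),
        "n_seeds": len(seeds),
        "core_counts": dict(sorted(core.items())),
        "n_assigned": sum(core.values()),
        "n_unclassified": n_uncl,
    }


def run_congruence(cfg: RunConfig, outdir: Path) -> dict:
    c = cfg.congruence
    t0 = time.monotonic()
    virus = load_tree(c["virus_tree"], c.get("virus_rooting", "none"))
    host = load_tree(c["host_tree"], c.get("host_rooting", "none"))
    tip_map = TipHostMap.from_tsv(c["map"])

    subset_cats = c.get("animal_categories")
    if subset_cats:
        keep_hosts = {
            h for h, cat in tip_map.host_category.items() if cat in subset_cats
        }
        keep = {
            v
            for v, h in tip_map.virus_to_host.items()
            if h in keep_hosts and v in set(virus.tip_labels())
        }
        from picobirnatax.trees import restrict_to

        virus = restrict_to(virus, keep)
        tip_map = tip_map.subset(keep)
        log.info("congruence: restricted to %d animal-associated tips",
                 len(keep))

    costs_list = c.get("costs", [0, 1, 1, 1])
    costs = EventCosts(*[float(x) for x in costs_list])
    res = nph85(
        virus, host, tip_map,
        mode=c.get("nph85_mode", "expanded-host-tree"),
        resamples=int(c.get("nph85_resamples", 100)),
        seed=cfg.seed,
    )
    dp = reconcile_mpr(
        virus, host, tip_map, costs=costs, host_resolution_seed=cfg.seed
    )
    summ = event_likelihoods(
        dp, n_samples=int(c.get("samples", 100)), seed=cfg.seed
    )
    pd.DataFrame(summ.per_sample_counts).to_csv(
        outdir / "event_samples.tsv", sep="\t", index=False
    )
    out = {
        "nph85": res.to_dict(),
        "reconciliation": summ.to_dict(),
        "n_host_polytomies_resolved": dp.n_host_polytomies_resolved,
    }
    with open(outdir / "congruence.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
    log.info(
        "congruence: nPH85=%.3f min_cost=%g mprs=%d (%.1fs)",
        res.distance, dp.min_cost, dp.mpr_count, time.monotonic() - t0,
    )
    return out


def run_rbs(cfg: RunConfig, outdir: Path) -> dict:
    c = cfg.rbs
    t0 = time.monotonic()
    window = int(c.get("window", 24))
    segments = []
    for inp in c.get("inputs", []):
        label = inp.get("label", "")
        if "path" in inp:
            segs = read_genbank(inp["path"], dataset_label=label)
        else:
            segs = read_fasta_gff3(
                inp["fasta"], inp["gff3"], dataset_label=label
            )
        segments.extend(segs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kept = filter_segments(segments, min_utr=window)
        table = frequency_table(kept, window=window)
        hits = scan_segments(kept, window=window)
    n_dropped = len(segments) - len(kept)
    if n_dropped:
        log.warning("rbs: dropped %d segments without a full 5' window",
                    n_dropped)
    table.to_csv(outdir / "rbs_frequency.tsv", sep="\t", index=False)
    hits.to_csv(outdir / "rbs_hits.tsv", sep="\t", index=False)
    log.info("rbs: %d segments, %d ORFs scanned (%.1fs)",
             len(kept), len(hits), time.monotonic() - t0)
    return {
        "n_segments_input": len(segments),
        "n_segments_kept": len(kept),
        "table": table.to_dict(orient="records"),
    }


def run_all(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the report."""
    outdir = cfg.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "manifest": {
            "tool": "picobirnatax",
            "version": __version__,
            "seed": cfg.seed,
            "config_sha256": cfg.config_hash(),
        }
    }
    stages = (
        ("classify", cfg.classify, run_classify),
        ("congruence", cfg.congruence, run_congruence),
        ("rbs", cfg.rbs, run_rbs),
    )
    for name, section, fn in stages:
        if not section:
            continue
        try:
            report[name] = fn(cfg, outdir)
        except Exception:
            log.error("stage %s failed", name)
            with open(outdir / "report.json", "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
            raise
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
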