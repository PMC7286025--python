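"""End-to-end pipeline: generate/load -> classify -> align -> distances ->
tree -> network -> report, as one reproducible, seeded run.

Every stage writes its artefact into the output directory before the next
stage starts, so a failing stage leaves partial outputs behind; the failure
is re-raised naming the stage.  A manifest records the configuration, seed
and library versions.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cyanogst import __version__, motifs, phylo, seqio, ssn
from cyanogst.synthetic import SyntheticConfig, generate

logger = logging.getLogger("cyanogst")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """One pipeline run.  Defaults: 500 bootstrap replicates, SSN threshold
    1e-11, JTT-free gamma-Poisson distances with shape 1.0, majority-gap
    column filter."""

    fasta: str | None = None
    metadata: str | None = None
    synthetic: SyntheticConfig | None = None
    class_file: str | None = None
    distance_method: str = "gamma-poisson"
    alpha: float = 1.0
    bootstrap_replicates: int = 500
    ssn_threshold: float = 1e-11
    trim_gap_fraction: float = 0.5
    seed: int = 0
    policy: str = "rank"

    def __post_init__(self) -> None:
        if self.fasta is None and self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)


def _write_assignments(assignments, path: Path) -> None:
    with path.open("w") as fh:
        fh.write(
            "id\tclass\tmotif\tposition\tambiguous\tcandidates\t"
            "catalytic_type\tcatalytic_concordant\n"
        )
        for a in assignments:
            fh.write(
                f"{a.sequence_id}\t{a.class_name}\t{a.matched_motif}\t"
                f"{a.match_position}\t{int(a.ambiguous)}\t"
                f"{','.join(a.candidates)}\t{a.catalytic_type_called}\t"
                f"{int(a.catalytic_concordant)}\n"
            )


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the whole pipeline; returns the summary dict it also writes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    classes = motifs.load_class_definitions(config.class_file)
    summary: dict = {}
    stage = "setup"
    t0 = time.perf_counter()
    try:
        stage = "input"
        if config.fasta is not None:
            seqs = seqio.read_fasta(config.fasta, config.metadata)
        else:
            seqs, truth = generate(config.synthetic, classes)
            truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        seqio.write_fasta(seqs, outdir / "sequences.fasta")
        seqio.write_order_table(seqs, outdir / "orders.tsv")
        logger.info("input: %d sequences", len(seqs))

        stage = "classify"
        assignments = motifs.classify_all(seqs, classes, config.policy)
        _write_assignments(assignments, outdir / "assignments.tsv")
        called = sorted(
            {a.class_name for a in assignments if a.classified and not a.ambiguous}
        )
        summary["n_sequences"] = len(seqs)
        summary["classes_called"] = called
        summary["n_classes_called"] = len(called)
        type_counts: dict[str, int] = {}
        for a in assignments:
            type_counts[a.catalytic_type_called] = (
                type_counts.get(a.catalytic_type_called, 0) + 1
            )
        summary["catalytic_type_counts"] = type_counts

        stage = "incidence"
        inc = motifs.build_incidence(
            assignments, seqs.orders(), [c.name for c in classes]
        )
        inc.to_tsv(outdir / "incidence.tsv")
        summary["classes_per_order"] = {
            order: int(cnt) for order, cnt in inc.counts.items()
        }

        stage = "align"
        msa = phylo.center_star_msa(seqs)
        msa = phylo.trim_columns(msa, config.trim_gap_fraction)
        write_msa_fasta(msa, outdir / "alignment.fasta")
        logger.info("align: %d columns after trimming", msa.n_columns)

        stage = "distances"
        dm = phylo.pairwise_distance(
            msa, method=config.distance_method, alpha=config.alpha
        )
        dm.to_tsv(outdir / "distances.tsv")
        order_dm = phylo.between_group_mean(dm, seqs.orders())
        order_dm.to_tsv(outdir / "order_divergence.tsv")
        off = order_dm.values[~np.eye(len(order_dm.labels), dtype=bool)]
        summary["order_divergence_min"] = round(float(off.min()), 4)
        summary["order_divergence_max"] = round(float(off.max()), 4)

        stage = "tree"
        tree = phylo.bootstrap_support(
            msa,
            replicates=config.bootstrap_replicates,
            method=config.distance_method,
            alpha=config.alpha,
            seed=np.random.default_rng(config.seed),
        )
        seqio.write_newick(tree, outdir / "tree.nwk")
        truth_classes = {
            a.sequence_id: a.class_name for a in assignments if a.classified
        }
        mono = phylo.monophyly_check(tree, truth_classes)
        summary["monophyletic_classes"] = {k: bool(v) for k, v in mono.items()}

        stage = "ssn"
        net = ssn.build_network(seqs, threshold=config.ssn_threshold)
        seqio.write_edgelist(net, outdir / "ssn_edges.tsv")
        comps = ssn.components(net)
        with (outdir / "components.tsv").open("w") as fh:
            fh.write("component\tid\n")
            for k, comp in enumerate(comps):
                for node in sorted(comp):
                    fh.write(f"{k}\t{node}\n")
        report = ssn.cluster_label_concordance(
            comps, {a.sequence_id: a.class_name for a in assignments}
        )
        summary["n_components"] = len(comps)
        summary["component_mean_purity"] = round(report.mean_purity, 4)

        stage = "report"
        summary_path = outdir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        manifest = {
            "cyanogst_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": config.seed,
            "config": _config_dict(config),
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        logger.info("run complete in %.1fs", time.perf_counter() - t0)
        return summary
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    if d.get("synthetic") and d["synthetic"].get("background_freqs") is not None:
        d["synthetic"]["background_freqs"] = list(
            map(float, d["synthetic"]["background_freqs"])
        )
    return d


def write_msa_fasta(msa: phylo.MultipleAlignment, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rid, row in msa.rows.items():
            fh.write(f">{rid}\n")
            for k in range(0, len(row), 60):
                fh.write(row[k : k + 60] + "\n")


def read_msa_fasta(path: str | Path) -> phylo.MultipleAlignment:
    rows: dict[str, list[str]] = {}
    current: str | None = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            current = line[1:].split()[0]
            rows[current] = []
        elif current is not None:
            rows[current].append(line.strip())
    return phylo.MultipleAlignment({k: "".join(v).upper() for k, v in rows.items()})
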