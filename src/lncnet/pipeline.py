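"""Config-driven end-to-end run: counts → RPKM → DE → network → annotation.

One :class:`PipelineConfig` collects every stage threshold (all defaulting to
the study-standard values: candidate length > 200 nt, > 2 exons, fold change
>= 2, adjusted p < 0.05, edge |r| >= 0.95 with permutation p < 0.05, 10-kb
cis window), so a default run is fully specified by the input paths and a
seed.  All artifacts are staged in a scratch directory and moved into place
only when every stage succeeded — a failed run leaves no partial output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import annotation as ann
from . import expression as expr
from . import io as lio
from . import network as net
from . import reporting, simulate

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    counts: str | None = None
    annotation: str | None = None
    #: sample -> control/case; inferred from a fixture manifest when absent
    groups: dict[str, str] | None = None
    gmt: str | None = None
    gene_lists: dict[str, str] = field(default_factory=dict)
    min_ratio: float = 2.0
    alpha_de: float = 0.05
    r_cutoff: float = 0.95
    alpha_edge: float = 0.05
    cis_window: int = 10_000
    lncrna_min_length: int = 200  # strict: length must exceed this
    lncrna_min_exons: int = 2  # strict: exon count must exceed this
    permutation_mode: str = "auto"
    permutation_draws: int = 10_000
    outdir: str = "lncnet_out"
    seed: int = 0
    log_level: str = "INFO"
    #: when counts/annotation are absent, simulate a fixture with these
    simulate: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("min_ratio", "alpha_de", "r_cutoff", "alpha_edge", "cis_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Digest of the analysis-relevant settings (where output lands and
        how loudly we log are not part of the scientific configuration)."""
        payload = {
            k: v
            for k, v in self.to_dict().items()
            if k not in {"outdir", "log_level"}
        }
        canonical = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunSummary:
    """Stage-by-stage counts of one pipeline run."""

    transcripts_in: int = 0
    lncrna_candidates: int = 0
    de_lncrna_up: int = 0
    de_lncrna_down: int = 0
    de_mrna_up: int = 0
    de_mrna_down: int = 0
    pairs_evaluated: int = 0
    edges_retained: int = 0
    cis_calls: int = 0
    enriched_sets: int = 0
    version: str = __version__
    config_hash: str = ""
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig) -> RunSummary:
    """Execute every stage and write all artifacts under ``config.outdir``."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    staging = Path(tempfile.mkdtemp(prefix="lncnet_staging_"))
    try:
        summary = _run_stages(config, staging)
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    outdir.mkdir(parents=True, exist_ok=True)
    for item in staging.iterdir():
        shutil.move(str(item), outdir / item.name)
    staging.rmdir()
    return summary


def _load_inputs(config: PipelineConfig, staging: Path):
    if config.counts is None or config.annotation is None:
        sim_cfg = simulate.SimulationConfig(
            **{**config.simulate, "seed": config.simulate.get("seed", config.seed)}
        )
        counts, annotation, truth = simulate.simulate_fixture(sim_cfg, staging / "fixture")
        groups = {
            s: ("control" if s.startswith("ctrl") else "case") for s in counts.columns
        }
        return counts, annotation, groups
    for path in [config.counts, config.annotation, config.gmt, *config.gene_lists.values()]:
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(path)
    counts = lio.read_counts(config.counts)
    annotation = (
        lio.read_gtf(config.annotation)
        if str(config.annotation).endswith(".gtf")
        else lio.read_annotation_tsv(config.annotation)
    )
    if config.groups is None:
        raise ValueError("groups mapping required with user-supplied counts")
    return counts, annotation, dict(config.groups)


def _run_stages(config: PipelineConfig, staging: Path) -> RunSummary:
    counts, annotation, groups = _load_inputs(config, staging)
    summary = RunSummary(config_hash=config.hash(), seed=config.seed)
    summary.transcripts_in = len(counts)

    rpkm = expr.compute_rpkm(counts, annotation)
    classified = expr.classify_lncrna_candidates(annotation)
    candidates = set(classified.loc[classified["is_candidate"], "transcript_id"])
    summary.lncrna_candidates = len(candidates)

    de = expr.differential_expression(rpkm, groups)
    de.to_csv(staging / "de_all.tsv", sep="\t", index=False)
    de_pass = expr.filter_de(de, config.min_ratio, config.alpha_de)

    coding_ids = set(
        classified.loc[classified["biotype"] == "coding", "transcript_id"]
    )
    de_lnc = de_pass.loc[de_pass["transcript_id"].isin(candidates)]
    de_mrna = de_pass.loc[de_pass["transcript_id"].isin(coding_ids)]
    summary.de_lncrna_up = int((de_lnc["direction"] == "up").sum())
    summary.de_lncrna_down = int((de_lnc["direction"] == "down").sum())
    summary.de_mrna_up = int((de_mrna["direction"] == "up").sum())
    summary.de_mrna_down = int((de_mrna["direction"] == "down").sum())
    de_lnc.to_csv(staging / "de_lncrna.tsv", sep="\t", index=False)
    de_mrna.to_csv(staging / "de_mrna.tsv", sep="\t", index=False)

    reporting.volcano_table(de).to_csv(staging / "volcano.tsv", sep="\t", index=False)
    selected = de_pass["transcript_id"].tolist()
    if selected:
        reporting.heatmap_matrix(rpkm, selected, groups).to_csv(
            staging / "heatmap.tsv", sep="\t"
        )

    scheme = net.PermutationScheme(
        mode=config.permutation_mode, n_draws=config.permutation_draws, seed=config.seed
    )
    directions = de.set_index("transcript_id")["direction"]
    edges, network_summary = net.build_network(
        rpkm.loc[de_lnc["transcript_id"]],
        rpkm.loc[de_mrna["transcript_id"]],
        r_cutoff=config.r_cutoff,
        alpha=config.alpha_edge,
        scheme=scheme,
        directions=directions,
    )
    summary.pairs_evaluated = len(edges)
    summary.edges_retained = int(edges["retained"].sum())
    edges.to_csv(staging / "edges_all.tsv", sep="\t", index=False)
    net.export_network(network_summary, staging)
    reporting.hub_report(network_summary).to_csv(staging / "hubs.tsv", sep="\t", index=False)

    cis_frames = []
    ann_idx = annotation.set_index("transcript_id")
    gene_table = annotation.loc[annotation["biotype"] == "coding"]
    for lnc_id in de_lnc["transcript_id"]:
        row = ann_idx.loc[lnc_id]
        locus = ann.GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
        hits = ann.cis_targets(locus, gene_table, config.cis_window)
        hits.insert(0, "lncrna_id", lnc_id)
        cis_frames.append(hits)
    cis = (
        pd.concat(cis_frames, ignore_index=True)
        if cis_frames
        else pd.DataFrame(columns=["lncrna_id", "transcript_id", "chrom", "start", "end", "distance"])
    )
    summary.cis_calls = len(cis)
    cis.to_csv(staging / "cis_targets.tsv", sep="\t", index=False)

    if config.gmt is not None:
        universe = set(counts.index)
        collection = ann.GeneSetCollection(lio.read_gmt(config.gmt), universe)
        enrichment = ann.gene_set_enrichment(set(de_pass["transcript_id"]), collection)
        summary.enriched_sets = int(enrichment["enriched"].sum()) if len(enrichment) else 0
        enrichment.to_csv(staging / "enrichment.tsv", sep="\t", index=False)

    if config.gene_lists:
        named = {name: lio.read_gene_list(p) for name, p in config.gene_lists.items()}
        if not 2 <= len(named) + 1 <= 3:
            named = dict(list(named.items())[:2])
        venn_sets = {"de_mrna": set(de_mrna["transcript_id"]), **named}
        ann.set_overlap(venn_sets).to_csv(staging / "venn.tsv", sep="\t", index=False)

    with open(staging / "run_summary.yaml", "w") as fh:
        yaml.safe_dump(summary.to_dict(), fh, sort_keys=True)
    return summary
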