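"""End-to-end orchestration: align/import -> filter -> pan -> network ->
optional synteny / phylogeny / motif stages, with a checksummed run manifest.

Every threshold actually used is echoed into the manifest; re-running the
same configuration on the same inputs reproduces identical checksums (the
native and blast backends are deterministic, and all randomness flows from
the single top-level seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as sio
from .align import ScoringScheme, align_all_pairs
from .motif import MotifModel, scan_gene_set
from .pan import (
    MatchCriteria,
    PrevalenceScheme,
    build_network,
    classify_prevalence,
    cluster_rows,
    filter_matches,
    presence_matrix,
)
from .phylo import MSA, bootstrap, concatenate_homologs, progressive_align
from .records import GenomeBundle, protein_genome_map
from .synteny import ClusterSpec, compare_cluster, prevalence_of_cluster

__all__ = ["RunConfig", "run_pipeline", "load_genomes"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    ``genomes`` maps genome id -> {"proteins": faa, "gff": gff3 (optional),
    "dna": fna (optional)}. ``backend`` is "native" (exact Smith-Waterman),
    "blast" (external search engine) or "import" (pre-computed tabular hits
    at ``hits_path``).
    """

    genomes: dict[str, dict[str, str]]
    outdir: str
    focal: str | None = None
    backend: str = "native"
    hits_path: str | None = None
    max_evalue: float = 1e-20
    min_coverage_both: float = 0.65
    softcore_min: int | None = None
    rare_min: int = 2
    stages: tuple[str, ...] = ("pan", "network")
    cluster_tsv: str | None = None
    max_locus_gap: int = 10_000
    motif_consensus: str | None = None
    motif_pwm: str | None = None
    motif_window: int = 300
    motif_proximal: int = 150
    n_marker_families: int = 10
    bootstrap_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("native", "blast", "import"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.backend == "import" and not self.hits_path:
            raise ValueError("import backend needs hits_path")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def criteria(self) -> MatchCriteria:
        return MatchCriteria(self.max_evalue, self.min_coverage_both)

    def scheme(self, n: int) -> PrevalenceScheme:
        return PrevalenceScheme(
            N=n, softcore_min=self.softcore_min, rare_min=self.rare_min
        )


def load_genomes(config: RunConfig) -> list[GenomeBundle]:
    bundles = []
    for gid, paths in config.genomes.items():
        if not Path(paths["proteins"]).exists():
            raise FileNotFoundError(paths["proteins"])
        b = sio.read_proteome(paths["proteins"], gid)
        if paths.get("gff"):
            sio.attach_gene_table(b, sio.read_gene_table(paths["gff"]))
        if paths.get("dna"):
            b.contigs = sio.read_dna(paths["dna"])
        bundles.append(b)
    return bundles


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _compute_hits(config: RunConfig, bundles: list[GenomeBundle]):
    if config.backend == "import":
        lengths = {p.protein_id: p.length for b in bundles for p in b}
        return sio.read_tabular_hits(
            config.hits_path, lengths, protein_genome_map(bundles)
        )
    if config.backend == "blast":
        from .blast import all_vs_all_blast

        return all_vs_all_blast(bundles)
    scheme = ScoringScheme()
    hits = []
    for A in bundles:
        for B in bundles:
            hits.extend(align_all_pairs(A, B, scheme))
    return hits


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundles = load_genomes(config)
    genome_ids = [b.genome_id for b in bundles]
    focal = config.focal or genome_ids[0]
    if focal not in genome_ids:
        raise ValueError(f"focal genome {focal!r} not among inputs")
    sizes = {b.genome_id: len(b) for b in bundles}
    manifest: dict = {
        "parameters": {
            "backend": config.backend,
            "max_evalue": config.max_evalue,
            "min_coverage_both": config.min_coverage_both,
            "softcore_min": config.scheme(len(bundles)).softcore_min,
            "rare_min": config.rare_min,
            "max_locus_gap": config.max_locus_gap,
            "motif_window": config.motif_window,
            "motif_proximal": config.motif_proximal,
            "bootstrap_reps": config.bootstrap_reps,
            "seed": config.seed,
            "focal": focal,
            "stages": list(config.stages),
        },
        "genomes": {g: sizes[g] for g in genome_ids},
        "outputs": {},
        "failures": [],
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    hits = _compute_hits(config, bundles)
    filtered = filter_matches(hits, config.criteria())
    hits_path = outdir / "filtered_hits.tsv"
    sio.write_hits(filtered, hits_path)
    record("filtered_hits", hits_path)

    focal_bundle = next(b for b in bundles if b.genome_id == focal)
    try:
        if "pan" in config.stages:
            M = presence_matrix(
                filtered, focal, genome_ids, focal_bundle.protein_ids
            )
            mpath = outdir / "presence_absence.csv"
            sio.write_matrix(M.table, mpath)
            record("presence_absence", mpath)
            assign, counts, pct = classify_prevalence(
                M, config.scheme(len(bundles))
            )
            cpath = outdir / "categories.tsv"
            assign.rename_axis("protein_id").to_csv(cpath, sep="\t")
            record("categories", cpath)
            manifest["category_counts"] = {k: int(v) for k, v in counts.items()}
            manifest["category_pct"] = {k: float(v) for k, v in pct.items()}
            manifest["genome_order"] = cluster_rows(M)
        if "network" in config.stages:
            net = build_network(filtered, sizes)
            for ext in ("graphml", "tsv"):
                npath = outdir / f"sharing_network.{ext}"
                sio.write_network(net, npath)
                record(f"network_{ext}", npath)
        if "synteny" in config.stages and config.cluster_tsv:
            cluster = ClusterSpec.from_tsv(
                config.cluster_tsv, max_locus_gap=config.max_locus_gap
            )
            ref = next(b for b in bundles if b.genome_id == cluster.genome_id)
            comp = compare_cluster(cluster, ref, bundles, filtered)
            spath = outdir / "cluster_comparison.tsv"
            comp.to_csv(spath, sep="\t", index=False)
            record("cluster_comparison", spath)
            prev = prevalence_of_cluster(cluster, filtered)
            ppath = outdir / "cluster_prevalence.tsv"
            prev.rename_axis("ref_gene").to_csv(ppath, sep="\t")
            record("cluster_prevalence", ppath)
        if "phylo" in config.stages:
            tree = _marker_tree(config, bundles, filtered, focal)
            tpath = outdir / "genome_tree.nwk"
            sio.write_newick(tree, tpath)
            record("genome_tree", tpath)
        if "motif" in config.stages and (
            config.motif_consensus or config.motif_pwm
        ):
            model = (
                MotifModel.from_consensus(config.motif_consensus)
                if config.motif_consensus
                else MotifModel.from_pwm_tsv(config.motif_pwm)
            )
            table, summary = scan_gene_set(
                focal_bundle,
                focal_bundle.proteins,
                model,
                config.motif_window,
                config.motif_proximal,
            )
            mpath = outdir / "motif_hits.tsv"
            table.to_csv(mpath, sep="\t", index=False)
            record("motif_hits", mpath)
            manifest["motif_summary"] = summary
    except Exception as exc:  # partial manifest with the failure on record
        manifest["failures"].append(str(exc))
        raise
    finally:
        mpath = outdir / "manifest.json"
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _marker_tree(config, bundles, filtered, focal):
    """Genome tree from concatenated single-copy shared families.

    Picks up to ``n_marker_families`` focal proteins whose reciprocal best
    hits exist in every genome, aligns each homolog set, concatenates the
    aligned blocks and runs bootstrapped NJ on Poisson distances.
    """
    from .synteny import reciprocal_best_hits

    genome_ids = [b.genome_id for b in bundles]
    others = [g for g in genome_ids if g != focal]
    rbh = {
        g: dict(reciprocal_best_hits(focal, g, filtered)) for g in others
    }
    by_id = {b.genome_id: b.as_dict() for b in bundles}
    focal_bundle = next(b for b in bundles if b.genome_id == focal)
    slots: dict[str, list[str | None]] = {g: [] for g in genome_ids}
    n_used = 0
    for p in focal_bundle.proteins:
        partners = {g: rbh[g].get(p.protein_id) for g in others}
        if any(v is None for v in partners.values()):
            continue
        seqs = {focal: p.sequence}
        for g, pid in partners.items():
            seqs[g] = by_id[g][pid].sequence
        msa = progressive_align(seqs)
        block = msa.to_dict()
        for g in genome_ids:
            slots[g].append(block[g])
        n_used += 1
        if n_used >= config.n_marker_families:
            break
    if n_used < 1:
        raise ValueError("no single-copy shared families found for the tree")
    concat = concatenate_homologs(slots)
    msa = MSA(ids=genome_ids, rows=[concat[g] for g in genome_ids])
    return bootstrap(
        msa, n_reps=config.bootstrap_reps,
        seed=np.random.default_rng(config.seed), model="poisson",
    )
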