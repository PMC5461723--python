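"""Synthetic pan-proteome datasets with known ground truth.

The generator emulates the statistical structure of a small-order pan-genome
comparison: N genomes share protein families at controlled prevalence (core
in all, accessory in k of N, unique in one), family members diverge from a
random ancestral protein by substitutions only, conserved multi-gene clusters
keep order and orientation (with optional planted inversions and
relocations), and promoters carry a fixed-length motif at known offsets.
Proteins are back-translated with uniform synonymous codons and placed on one
contig per genome with random intergenic spacers, so the same dataset
exercises alignment, partitioning, synteny and motif scanning against an
exact truth ledger.

Soft-core and rare families always include the first (focal) genome, so the
focal proteome contains exactly the planted number of proteins of each
category. Everything is reproducible from the single mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .motif import IUPAC, MotifModel
from .pan import PrevalenceScheme
from .records import GenomeBundle, Locus, ProteinRecord

__all__ = [
    "ClusterPlan",
    "MotifPlan",
    "SynthSpec",
    "SynthTruth",
    "generate_dataset",
    "evaluate_recovery",
    "write_dataset",
]

_AAS = "ACDEFGHIKLMNPQRSTVWY"
_PAD = 25  # bp between a gene's 3' end and the next block


def _codon_map() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[1]
    out: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        out.setdefault(aa, []).append(codon)
    for aa in out:
        out[aa].sort()
    return out


_CODONS = _codon_map()
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ClusterPlan:
    """A conserved multi-gene cluster planted in a subset of genomes.

    ``inverted``/``relocated`` map genome index -> gene ordinals (0-based
    within the cluster) whose strand is flipped or which are moved
    ``relocation_gap`` bp away from the cluster locus. The first genome in
    ``present_in`` is the cluster's reference.
    """

    name: str
    n_genes: int
    present_in: tuple[int, ...]
    inverted: dict[int, tuple[int, ...]] = field(default_factory=dict)
    relocated: dict[int, tuple[int, ...]] = field(default_factory=dict)
    identity: float = 0.9
    relocation_gap: int = 50_000

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("a cluster needs at least two genes")
        if len(self.present_in) < 1:
            raise ValueError("cluster must be present somewhere")


@dataclass(frozen=True)
class MotifPlan:
    """Motif consensus plus planted placements.

    Placements are (genome index, gene ordinal in that genome's final gene
    order, offset) with offset the *positive* distance o meaning the motif's
    3' end sits at position -o relative to the start codon.
    """

    consensus: str
    placements: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        for c in self.consensus.upper():
            if c not in IUPAC:
                raise ValueError(f"not an IUPAC base code: {c!r}")
        for _g, _o, off in self.placements:
            if off < 1:
                raise ValueError("offsets are positive upstream distances")

    def instance(self) -> str:
        """A concrete maximal-scoring realisation of the consensus."""
        return "".join(IUPAC[c][0] for c in self.consensus.upper())


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for one synthetic dataset."""

    seed: int
    n_genomes: int = 14
    n_core: int = 100
    n_softcore: int = 40
    n_rare: int = 60
    n_unique_per_genome: int = 30
    length_range: tuple[int, int] = (200, 600)
    within_family_identity: float = 0.85
    clusters: tuple[ClusterPlan, ...] = ()
    motif: MotifPlan | None = None
    intergenic_range: tuple[int, int] = (150, 400)
    shuffle_gene_order: bool = True

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("need at least two genomes")
        if not (0 < self.within_family_identity <= 1):
            raise ValueError("within_family_identity must be in (0, 1]")
        if min(self.n_core, self.n_softcore, self.n_rare,
               self.n_unique_per_genome) < 0:
            raise ValueError("family counts must be non-negative")
        scheme = self.scheme
        if self.n_rare > 0 and scheme.rare_min > scheme.softcore_min - 1:
            raise ValueError(
                f"infeasible spec: no rare prevalence band exists for "
                f"N={self.n_genomes} (rare needs [{scheme.rare_min}, "
                f"{scheme.softcore_min - 1}])"
            )
        if self.n_softcore > 0 and scheme.softcore_min > scheme.core_min - 1:
            raise ValueError(
                f"infeasible spec: no soft-core prevalence band exists for "
                f"N={self.n_genomes}"
            )
        for cp in self.clusters:
            if max(cp.present_in) >= self.n_genomes:
                raise ValueError(
                    f"cluster {cp.name}: genome index out of range"
                )
        if self.motif is not None:
            for g, _o, _off in self.motif.placements:
                if g >= self.n_genomes:
                    raise ValueError("motif placement genome index out of range")

    @property
    def scheme(self) -> PrevalenceScheme:
        return PrevalenceScheme(N=self.n_genomes)


@dataclass
class SynthTruth:
    """Ground-truth ledger for one generated dataset."""

    focal_genome: str
    genome_ids: list[str]
    scheme: PrevalenceScheme
    families: dict[str, dict]  # family -> {members, prevalence, category}
    focal_categories: dict[str, str]  # focal protein -> planted category
    clusters: dict[str, dict]
    motifs: list[tuple[str, str, int]]  # (genome, protein, signed offset)

    def category_counts(self) -> dict[str, int]:
        out = {"unique": 0, "rare": 0, "softcore": 0, "core": 0}
        for c in self.focal_categories.values():
            out[c] += 1
        return out

    def expected_sharing(self) -> dict[str, float]:
        """Planted percentage of focal proteins with a family member in each
        other genome."""
        n_focal = len(self.focal_categories)
        shared = {g: 0 for g in self.genome_ids if g != self.focal_genome}
        for fam in self.families.values():
            genomes_of = {g for g, _p in fam["members"]}
            if self.focal_genome not in genomes_of:
                continue
            n_focal_members = sum(
                1 for g, _p in fam["members"] if g == self.focal_genome
            )
            for g in genomes_of:
                if g != self.focal_genome:
                    shared[g] += n_focal_members
        return {g: 100.0 * c / n_focal for g, c in shared.items()}


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(_AAS))[rng.integers(0, 20, size=length)])


def _mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Binomially sampled substitution sites, uniform replacement residues."""
    if identity >= 1.0:
        return seq
    L = len(seq)
    n_sub = rng.binomial(L, 1.0 - identity)
    if n_sub == 0:
        return seq
    pos = rng.choice(L, size=n_sub, replace=False)
    out = list(seq)
    for p in pos:
        choices = [a for a in _AAS if a != out[p]]
        out[p] = choices[rng.integers(0, 19)]
    return "".join(out)


def _backtranslate(rng: np.random.Generator, protein: str) -> str:
    codons = [
        _CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein
    ]
    return "".join(codons) + "TAA"


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@dataclass
class _Gene:
    protein_id: str
    family: str | None
    sequence: str
    strand: str
    relocated: bool = False


def generate_dataset(spec: SynthSpec):
    """Generate (bundles, truth): one GenomeBundle per genome with proteins,
    DNA contig and loci, plus the SynthTruth ledger."""
    rng = np.random.default_rng(spec.seed)
    N = spec.n_genomes
    genome_ids = [f"G{i + 1:02d}" for i in range(N)]
    focal = genome_ids[0]
    scheme = spec.scheme
    lo, hi = spec.length_range

    families: dict[str, dict] = {}
    per_genome_genes: dict[str, list[_Gene]] = {g: [] for g in genome_ids}

    def add_family(fam_id, member_idx, identity, length=None, strand_by=None):
        length = length or int(rng.integers(lo, hi + 1))
        ancestor = _random_protein(rng, length)
        members = []
        for gi in member_idx:
            gid = genome_ids[gi]
            pid = f"{fam_id}_{gid}"
            seq = _mutate(rng, ancestor, identity)
            strand = strand_by(gi) if strand_by else ("+" if rng.random() < 0.7 else "-")
            per_genome_genes[gid].append(_Gene(pid, fam_id, seq, strand))
            members.append((gid, pid))
        families[fam_id] = {
            "members": members,
            "prevalence": len(member_idx),
            "category": scheme.category(len(member_idx)),
        }

    fam_counter = 0

    def next_fam() -> str:
        nonlocal fam_counter
        fam_counter += 1
        return f"F{fam_counter:04d}"

    for _ in range(spec.n_core):
        add_family(next_fam(), list(range(N)), spec.within_family_identity)
    for _ in range(spec.n_softcore):
        prev = int(rng.integers(scheme.softcore_min, scheme.core_min))
        others = rng.choice(np.arange(1, N), size=prev - 1, replace=False)
        add_family(next_fam(), [0] + sorted(int(x) for x in others),
                   spec.within_family_identity)
    for _ in range(spec.n_rare):
        prev = int(rng.integers(scheme.rare_min, scheme.softcore_min))
        others = rng.choice(np.arange(1, N), size=prev - 1, replace=False)
        add_family(next_fam(), [0] + sorted(int(x) for x in others),
                   spec.within_family_identity)
    for gi, gid in enumerate(genome_ids):
        for u in range(spec.n_unique_per_genome):
            pid = f"U{u + 1:03d}_{gid}"
            fam_id = f"UF_{pid}"
            seq = _random_protein(rng, int(rng.integers(lo, hi + 1)))
            per_genome_genes[gid].append(
                _Gene(pid, fam_id, seq, "+" if rng.random() < 0.7 else "-")
            )
            families[fam_id] = {
                "members": [(gid, pid)],
                "prevalence": 1,
                "category": "unique",
            }

    # optional deterministic shuffle of the non-cluster gene order
    if spec.shuffle_gene_order:
        for gid in genome_ids:
            genes = per_genome_genes[gid]
            order = rng.permutation(len(genes))
            per_genome_genes[gid] = [genes[i] for i in order]

    # clusters: contiguous blocks appended after the shuffled genes
    cluster_truth: dict[str, dict] = {}
    for cp in spec.clusters:
        ref_gi = cp.present_in[0]
        lengths = [int(rng.integers(lo, hi + 1)) for _ in range(cp.n_genes)]
        ancestors = [_random_protein(rng, L) for L in lengths]
        ref_strands = [
            "+" if rng.random() < 0.7 else "-" for _ in range(cp.n_genes)
        ]
        info: dict = {
            "reference": genome_ids[ref_gi],
            "gene_families": [f"{cp.name}g{k + 1}" for k in range(cp.n_genes)],
            "ref_strands": ref_strands,
            "members": {},
            "inverted": {},
            "relocated": {},
        }
        for gi in cp.present_in:
            gid = genome_ids[gi]
            inverted = set(cp.inverted.get(gi, ()))
            relocated = set(cp.relocated.get(gi, ()))
            pids = []
            for k in range(cp.n_genes):
                fam_id = f"{cp.name}g{k + 1}"
                pid = f"{fam_id}_{gid}"
                seq = (
                    ancestors[k]
                    if gi == ref_gi
                    else _mutate(rng, ancestors[k], cp.identity)
                )
                strand = ref_strands[k]
                if k in inverted:
                    strand = "-" if strand == "+" else "+"
                per_genome_genes[gid].append(
                    _Gene(pid, fam_id, seq, strand, relocated=k in relocated)
                )
                pids.append(pid)
                families.setdefault(
                    fam_id,
                    {"members": [], "prevalence": 0, "category": None},
                )
                families[fam_id]["members"].append((gid, pid))
            info["members"][gid] = pids
            info["inverted"][gid] = sorted(inverted)
            info["relocated"][gid] = sorted(relocated)
        cluster_truth[cp.name] = info
    for cp in spec.clusters:
        for k in range(cp.n_genes):
            fam = families[f"{cp.name}g{k + 1}"]
            fam["prevalence"] = len(fam["members"])
            fam["category"] = scheme.category(len(fam["members"]))

    # motif placements, resolved to concrete genes after ordering
    motif_truth: list[tuple[str, str, int]] = []
    planted: dict[tuple[str, str], int] = {}
    if spec.motif is not None:
        for gi, ordinal, off in spec.motif.placements:
            gid = genome_ids[gi]
            genes = per_genome_genes[gid]
            if ordinal >= len(genes):
                raise ValueError(
                    f"motif placement ordinal {ordinal} out of range for {gid}"
                )
            g = genes[ordinal]
            planted[(gid, g.protein_id)] = off
            motif_truth.append((gid, g.protein_id, -off))
    motif_instance = spec.motif.instance() if spec.motif else ""
    motif_len = len(motif_instance)

    # assemble DNA: per gene a block of [promoter spacer][CDS][pad] on '+',
    # [pad][CDS][promoter spacer] on '-'; relocated genes go last after a
    # long neutral gap.
    bundles: list[GenomeBundle] = []
    ig_lo, ig_hi = spec.intergenic_range
    for gid in genome_ids:
        genes = per_genome_genes[gid]
        ordered = [g for g in genes if not g.relocated] + [
            g for g in genes if g.relocated
        ]
        contig_id = f"{gid}_c1"
        parts: list[str] = []
        pos = 0  # 0-based length so far
        proteins: list[ProteinRecord] = []
        seen_relocated = False
        for g in ordered:
            if g.relocated and not seen_relocated:
                gap = max(
                    (cp.relocation_gap for cp in spec.clusters), default=50_000
                )
                parts.append(_random_dna(rng, gap))
                pos += gap
                seen_relocated = True
            off = planted.get((gid, g.protein_id))
            spacer_len = int(rng.integers(ig_lo, ig_hi + 1))
            if off is not None:
                spacer_len = max(spacer_len, off + motif_len + 5)
            spacer = _random_dna(rng, spacer_len)
            cds = _backtranslate(rng, g.sequence)
            if g.strand == "+":
                if off is not None:
                    # promoter spacer precedes the CDS; its last base is -1,
                    # so the motif's 3' end (-off) is spacer index
                    # spacer_len - off and the motif starts motif_len-1
                    # bases further upstream
                    start_idx = spacer_len - off - motif_len + 1
                    spacer = _fill_motif(
                        spacer_len, start_idx, motif_instance, rng,
                        prebuilt=spacer,
                    )
                block = spacer + cds + _random_dna(rng, _PAD)
                start = pos + len(spacer) + 1
                end = start + len(cds) - 1
            else:
                rc = _revcomp(cds)
                if off is not None:
                    # promoter spacer follows the reverse-complemented CDS;
                    # spacer index k-1 is coding position -k, so the motif
                    # occupies indices off-1 .. off+motif_len-2, written as
                    # the reverse complement of the coding-strand instance
                    spacer = _fill_motif(
                        spacer_len, off - 1, _revcomp(motif_instance), rng,
                        prebuilt=spacer,
                    )
                block = _random_dna(rng, _PAD) + rc + spacer
                start = pos + _PAD + 1
                end = start + len(rc) - 1
            parts.append(block)
            pos += len(block)
            proteins.append(
                ProteinRecord(
                    protein_id=g.protein_id,
                    genome_id=gid,
                    sequence=g.sequence,
                    locus=Locus(contig_id, start, end, g.strand),
                    annotation=g.family or "",
                )
            )
        contig = "".join(parts) + _random_dna(rng, 50)
        bundles.append(
            GenomeBundle(genome_id=gid, proteins=proteins,
                         contigs={contig_id: contig})
        )

    focal_categories = {}
    for fam in families.values():
        for g, pid in fam["members"]:
            if g == focal:
                focal_categories[pid] = fam["category"]

    truth = SynthTruth(
        focal_genome=focal,
        genome_ids=genome_ids,
        scheme=scheme,
        families=families,
        focal_categories=focal_categories,
        clusters=cluster_truth,
        motifs=motif_truth,
    )
    return bundles, truth


def _fill_motif(
    spacer_len: int,
    start_idx: int,
    instance: str,
    rng: np.random.Generator,
    prebuilt: str | None = None,
) -> str:
    """A spacer of ``spacer_len`` random bases with ``instance`` written at
    ``start_idx`` (0-based)."""
    if start_idx < 0 or start_idx + len(instance) > spacer_len:
        raise ValueError("motif does not fit in the spacer")
    base = prebuilt if prebuilt is not None else _random_dna(rng, spacer_len)
    return base[:start_idx] + instance + base[start_idx + len(instance):]


def evaluate_recovery(truth: SynthTruth, observed, *, proximal_cutoff: int = 150):
    """Exact-match confusion counts between planted and inferred labels.

    Dispatches on the observed table: a ``category`` column compares
    prevalence categories for the focal proteome; a ``class`` column compares
    motif presence calls; a ``co_located`` column compares cluster relocation
    calls. Identifier mismatches are errors.
    """
    if not isinstance(observed, pd.DataFrame):
        raise TypeError("observed must be a DataFrame")
    if "category" in observed.columns:
        obs = observed["category"]
        planted = pd.Series(truth.focal_categories)
        if set(obs.index) != set(planted.index):
            raise ValueError("observed protein ids do not match the truth ledger")
        return pd.crosstab(
            planted.reindex(obs.index), obs, rownames=["planted"],
            colnames=["observed"], dropna=False,
        )
    if "class" in observed.columns:
        planted_off = {p: o for _g, p, o in truth.motifs}
        rows = []
        for _, r in observed.iterrows():
            off = planted_off.get(r["gene_id"])
            if off is None:
                p_class = "-"
            else:
                p_class = "+" if -off <= proximal_cutoff else "?"
            rows.append((p_class, r["class"]))
        df = pd.DataFrame(rows, columns=["planted", "observed"])
        return pd.crosstab(df["planted"], df["observed"], dropna=False)
    if "co_located" in observed.columns:
        rows = []
        for name, info in truth.clusters.items():
            fams = info["gene_families"]
            ref = info["reference"]
            for gid, pids in info["members"].items():
                if gid == ref:
                    continue
                relocated = set(info["relocated"].get(gid, ()))
                for k, fam in enumerate(fams):
                    ref_gene = f"{fam}_{ref}"
                    sel = observed[
                        (observed["ref_gene"] == ref_gene)
                        & (observed["target_genome"] == gid)
                    ]
                    if sel.empty:
                        continue
                    obs_co = sel.iloc[0]["co_located"]
                    rows.append(
                        ("relocated" if k in relocated else "in_place",
                         "relocated" if obs_co is False else "in_place")
                    )
        df = pd.DataFrame(rows, columns=["planted", "observed"])
        return pd.crosstab(df["planted"], df["observed"], dropna=False)
    raise ValueError("unrecognised observation table")


def write_dataset(bundles, truth: SynthTruth, outdir) -> dict[str, str]:
    """Emit per-genome protein FASTA, DNA FASTA and GFF3 plus truth TSVs.

    Returns {description: path} for the manifest.
    """
    from pathlib import Path

    from .io import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    for b in bundles:
        faa = outdir / f"{b.genome_id}.faa"
        write_fasta({p.protein_id: p.sequence for p in b.proteins}, faa)
        fna = outdir / f"{b.genome_id}.fna"
        write_fasta(b.contigs, fna)
        gff = outdir / f"{b.genome_id}.gff3"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for p in b.proteins:
                l = p.locus
                fh.write(
                    f"{l.contig_id}\tsulfopan_sim\tCDS\t{l.start}\t{l.end}\t."
                    f"\t{l.strand}\t0\tID={p.protein_id}\n"
                )
        written[f"proteins:{b.genome_id}"] = str(faa)
        written[f"dna:{b.genome_id}"] = str(fna)
        written[f"gff:{b.genome_id}"] = str(gff)
    fam = outdir / "truth_families.tsv"
    pd.DataFrame(
        [
            (fid, f["prevalence"], f["category"],
             ";".join(p for _g, p in f["members"]))
            for fid, f in truth.families.items()
        ],
        columns=["family", "prevalence", "category", "members"],
    ).to_csv(fam, sep="\t", index=False)
    written["truth:families"] = str(fam)
    if truth.motifs:
        mo = outdir / "truth_motifs.tsv"
        pd.DataFrame(
            truth.motifs, columns=["genome", "protein", "offset"]
        ).to_csv(mo, sep="\t", index=False)
        written["truth:motifs"] = str(mo)
    return written
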