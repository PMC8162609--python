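"""Pipeline orchestration: configuration, resumable step state, reports.

A run executes a fixed sequence of steps (stage 1 per genome with reads, then
the comparative stage over all genomes).  The status of every step is saved
in a JSON state file in the run directory; with ``resume=True`` a step is
skipped when it is already done *and* its parameter hash still matches.
Hashes chain: each step's hash folds in its upstream step's hash plus content
digests of the input files, so editing an input or a parameter invalidates
everything downstream but nothing upstream.  Steps communicate exclusively
through files in the run directory, which is what makes resumption exact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import assembly, mapping, novel_products, pangenome, seqio
from .annotation import AnnotParams, annotate_genome
from .similarity import ScoringScheme, Thresholds

__all__ = ["GenomeInput", "RunConfig", "StepRecord", "STEP_ORDER", "save_state", "load_state", "run", "render_reports"]

log = logging.getLogger("pankit")

STEP_ORDER = [
    "partition",
    "repair",
    "assemble",
    "annotate_ref",
    "annotate_asm",
    "identify",
    "update",
    "reannotate",
    "genfiles",
    "cluster",
    "curves",
    "fit",
    "reports",
]


@dataclass
class GenomeInput:
    genome_id: str
    fasta: str
    reads1: str | None = None
    reads2: str | None = None

    @property
    def has_reads(self) -> bool:
        return self.reads1 is not None


@dataclass
class RunConfig:
    genomes: list[GenomeInput]
    outdir: str
    seed: int = 0
    n_perms: int = 1000
    evalue: float = 1e-10
    identity: float = 0.7
    coverage: float = 0.7
    kmer_map: int = 21
    kmer_asm: int = 31
    min_orf: int = 150
    min_contig: int = 200
    known_proteins: str | None = None

    def __post_init__(self) -> None:
        for g in self.genomes:
            if g.reads2 is not None and g.reads1 is None:
                raise ValueError(f"genome {g.genome_id}: reads2 without reads1")

    @property
    def thresholds(self) -> Thresholds:
        return Thresholds(self.evalue, self.identity, self.coverage)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        genomes = [GenomeInput(**g) for g in raw.pop("genomes")]
        return cls(genomes=genomes, **raw)


@dataclass
class StepRecord:
    step_name: str
    status: str = "pending"  # pending | running | done | failed
    params_hash: str = ""
    outputs: list[str] = field(default_factory=list)
    started_at: float | None = None
    ended_at: float | None = None


# ---------------------------------------------------------------------------
# state store
# ---------------------------------------------------------------------------

def save_state(state: dict[str, StepRecord], path: str) -> None:
    """Atomic (temp + rename) human-readable JSON dump of the step states."""
    payload = {name: dataclasses.asdict(rec) for name, rec in state.items()}
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    os.replace(tmp, path)


def load_state(path: str) -> dict[str, StepRecord]:
    """Load step states; a missing file yields a fresh all-pending state,
    a corrupt file raises naming the file (never a silent reset)."""
    if not os.path.exists(path):
        return {name: StepRecord(name) for name in STEP_ORDER}
    try:
        with open(path) as fh:
            payload = json.load(fh)
        state = {name: StepRecord(**rec) for name, rec in payload.items()}
    except (json.JSONDecodeError, TypeError, ValueError) as exc:
        raise ValueError(f"corrupt state file {path!r}: {exc}") from exc
    for name in STEP_ORDER:
        state.setdefault(name, StepRecord(name))
    return state


def _digest(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _file_digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# step implementations (file-level; each reads its inputs from the run dir)
# ---------------------------------------------------------------------------

class _Runner:
    def __init__(self, config: RunConfig):
        self.c = config
        self.out = config.outdir
        os.makedirs(self.out, exist_ok=True)

    def gdir(self, gid: str) -> str:
        d = os.path.join(self.out, "stage1", gid)
        os.makedirs(d, exist_ok=True)
        return d

    @property
    def s2dir(self) -> str:
        d = os.path.join(self.out, "stage2")
        os.makedirs(d, exist_ok=True)
        return d

    def annot_params(self) -> AnnotParams:
        return AnnotParams(min_orf_nt=self.c.min_orf)

    def map_params(self) -> mapping.MapParams:
        return mapping.MapParams(k=self.c.kmer_map)

    # -- stage 1 ------------------------------------------------------------

    def partition(self) -> list[str]:
        outputs = []
        for g in self.c.genomes:
            if not g.has_reads:
                continue
            d = self.gdir(g.genome_id)
            ref = seqio.read_fasta(g.fasta)
            reads1 = seqio.read_fastq(g.reads1)
            reads2 = seqio.read_fastq(g.reads2) if g.reads2 else []
            index = mapping.build_index(ref, self.c.kmer_map)
            up1, up2, singles, counts = mapping.partition_reads(
                reads1, reads2, index, self.map_params()
            )
            for name, reads in (
                ("unmapped_1.fastq", up1),
                ("unmapped_2.fastq", up2),
                ("unmapped_singletons.fastq", singles),
            ):
                seqio.write_fastq(reads, os.path.join(d, name))
                outputs.append(os.path.join(d, name))
            mapping.write_mapping_summary(counts, os.path.join(d, "mapping_summary.tsv"))
            outputs.append(os.path.join(d, "mapping_summary.tsv"))
        return outputs

    def repair(self) -> list[str]:
        outputs = []
        for g in self.c.genomes:
            if not g.has_reads:
                continue
            d = self.gdir(g.genome_id)
            r1 = seqio.read_fastq(os.path.join(d, "unmapped_1.fastq"))
            r2 = seqio.read_fastq(os.path.join(d, "unmapped_2.fastq"))
            singles = seqio.read_fastq(os.path.join(d, "unmapped_singletons.fastq"))
            p1, p2, orphans = mapping.repair_pairs(r1, r2)
            for name, reads in (
                ("repaired_1.fastq", p1),
                ("repaired_2.fastq", p2),
                ("assembly_singletons.fastq", orphans + singles),
            ):
                seqio.write_fastq(reads, os.path.join(d, name))
                outputs.append(os.path.join(d, name))
        return outputs

    def assemble(self) -> list[str]:
        outputs = []
        for g in self.c.genomes:
            if not g.has_reads:
                continue
            d = self.gdir(g.genome_id)
            reads = []
            for name in ("repaired_1.fastq", "repaired_2.fastq", "assembly_singletons.fastq"):
                reads.extend(seqio.read_fastq(os.path.join(d, name)))
            graph = assembly.prune(assembly.build_graph(reads, self.c.kmer_asm))
            contigs = assembly.extract_contigs(graph, self.c.min_contig)
            path = os.path.join(d, "contigs.fasta")
            recs = assembly.contigs_to_records(contigs)
            if recs:
                seqio.write_fasta(recs, path)
            else:
                open(path, "w").close()
            outputs.append(path)
        return outputs

    def _annotate_to(self, gid: str, records: list[seqio.SeqRecord], out_gff: str) -> None:
        ann = annotate_genome(gid, records, self.annot_params())
        seqio.write_gff3(ann, out_gff)

    def annotate_ref(self) -> list[str]:
        outputs = []
        for g in self.c.genomes:
            d = self.gdir(g.genome_id)
            out = os.path.join(d, "ref.gff3")
            self._annotate_to(g.genome_id, seqio.read_fasta(g.fasta), out)
            outputs.append(out)
        return outputs

    def annotate_asm(self) -> list[str]:
        outputs = []
        for g in self.c.genomes:
            if not g.has_reads:
                continue
            d = self.gdir(g.genome_id)
            path = os.path.join(d, "contigs.fasta")
            recs = seqio.read_fasta(path) if os.path.getsize(path) else []
            out = os.path.join(d, "asm.gff3")
            self._annotate_to(f"{g.genome_id}_asm", recs, out)
            outputs.append(out)
        return outputs

    def identify(self) -> list[str]:
        outputs = []
        known = (
            seqio.read_fasta(self.c.known_proteins, alphabet="protein")
            if self.c.known_proteins
            else None
        )
        for g in self.c.genomes:
            if not g.has_reads:
                continue
            d = self.gdir(g.genome_id)
            ref_ann = seqio.read_gff3(os.path.join(d, "ref.gff3"), g.fasta)
            contig_path = os.path.join(d, "contigs.fasta")
            if os.path.getsize(contig_path):
                asm_ann = seqio.read_gff3(os.path.join(d, "asm.gff3"), contig_path)
            else:
                asm_ann = seqio.AnnotationSet(f"{g.genome_id}_asm")
            novel = novel_products.identify_new_products(
                ref_ann, asm_ann, thresholds=self.c.thresholds
            )
            named = seqio.AnnotationSet("new", asm_ann.contigs, list(novel))
            if known:
                from .annotation import assign_products

                named = assign_products(named, known, self.c.thresholds)
            listing = os.path.join(d, "new_products.tsv")
            with open(listing, "w") as fh:
                fh.write("feature_id\tcontig\tstart\tend\tstrand\tlength_nt\tproduct\n")
                for f in named.features:
                    fh.write(
                        f"{f.feature_id}\t{f.contig_id}\t{f.start}\t{f.end}\t{f.strand}\t{len(f)}\t{f.product}\n"
                    )
            outputs.append(listing)
            nuc = [
                seqio.SeqRecord(f.feature_id, asm_ann.feature_nuc(f), f.product)
                for f in named.features
            ]
            nuc_path = os.path.join(d, "new_products.nuc.fasta")
            if nuc:
                seqio.write_fasta(nuc, nuc_path)
            else:
                open(nuc_path, "w").close()
            outputs.append(nuc_path)
        return outputs

    def update(self) -> list[str]:
        outputs = []
        for g in self.c.genomes:
            if not g.has_reads:
                continue
            d = self.gdir(g.genome_id)
            ref = seqio.read_fasta(g.fasta)
            nuc_path = os.path.join(d, "new_products.nuc.fasta")
            updated = [seqio.SeqRecord(r.id, r.sequence, r.description) for r in ref]
            if os.path.getsize(nuc_path):
                for rec in seqio.read_fasta(nuc_path):
                    updated.append(seqio.SeqRecord(f"new_{rec.id}", rec.sequence, rec.description))
            out = os.path.join(d, "updated.fasta")
            seqio.write_fasta(updated, out)
            outputs.append(out)
        return outputs

    def reannotate(self) -> list[str]:
        outputs = []
        for g in self.c.genomes:
            if not g.has_reads:
                continue
            d = self.gdir(g.genome_id)
            out = os.path.join(d, "updated.gff3")
            self._annotate_to(g.genome_id, seqio.read_fasta(os.path.join(d, "updated.fasta")), out)
            outputs.append(out)
            # Table-2 style per-genome discovery report
            import csv

            with open(os.path.join(d, "new_products.tsv")) as fh:
                rows = list(csv.DictReader(fh, delimiter="\t"))
            named = sum(1 for r in rows if r["product"] != "hypothetical protein")
            lengths = [int(r["length_nt"]) for r in rows]
            rep = novel_products.DiscoveryReport(
                new_products=named,
                hypothetical=len(rows) - named,
                total=len(rows),
                mean_len_nt=round(sum(lengths) / len(lengths)) if lengths else 0,
            )
            rep_path = os.path.join(d, "report.tsv")
            rep.write_tsv(rep_path)
            outputs.append(rep_path)
        return outputs

    # -- stage 2 ------------------------------------------------------------

    def _final_fasta(self, g: GenomeInput) -> str:
        if g.has_reads:
            return os.path.join(self.gdir(g.genome_id), "updated.fasta")
        return g.fasta

    def genfiles(self) -> list[str]:
        outputs = []
        for g in self.c.genomes:
            records = seqio.read_fasta(self._final_fasta(g))
            ann = annotate_genome(g.genome_id, records, self.annot_params())
            prefix = os.path.join(self.s2dir, g.genome_id)
            outputs.extend(seqio.write_pgap_inputs(ann, prefix))
        return outputs

    def cluster(self) -> list[str]:
        prot_sets = {
            g.genome_id: seqio.read_fasta(
                os.path.join(self.s2dir, g.genome_id + ".pep"), alphabet="protein"
            )
            for g in self.c.genomes
        }
        clusters = pangenome.cluster_gene_families(
            prot_sets, ScoringScheme.protein(), self.c.thresholds
        )
        path = os.path.join(self.s2dir, "clusters.tsv")
        with open(path, "w") as fh:
            fh.write("cluster_id\tgenome\tgene\n")
            for i, cluster in enumerate(clusters.clusters):
                for gid, fid in sorted(cluster):
                    fh.write(f"cluster_{i + 1:05d}\t{gid}\t{fid}\n")
        return [path]

    def _load_matrix(self) -> pangenome.PanMatrix:
        import pandas as pd

        df = pd.read_csv(os.path.join(self.s2dir, "clusters.tsv"), sep="\t")
        clusters: dict[str, set[tuple[str, str]]] = {}
        for row in df.itertuples():
            clusters.setdefault(row.cluster_id, set()).add((row.genome, row.gene))
        gfc = pangenome.GeneFamilyClusters([clusters[k] for k in sorted(clusters)])
        return pangenome.pan_matrix(gfc, [g.genome_id for g in self.c.genomes])

    def curves(self) -> list[str]:
        samples = pangenome.sample_curves(self._load_matrix(), self.c.n_perms, self.c.seed)
        path = os.path.join(self.s2dir, "curves.tsv")
        with open(path, "w") as fh:
            fh.write("perm\tN\tpan\tcore\tnew\n")
            for s in samples:
                fh.write(f"{s.perm_id}\t{s.N}\t{s.pan}\t{s.core}\t{s.new}\n")
        return [path]

    def _load_samples(self) -> list[pangenome.CurveSample]:
        import pandas as pd

        df = pd.read_csv(os.path.join(self.s2dir, "curves.tsv"), sep="\t")
        return [
            pangenome.CurveSample(int(r.perm), int(r.N), int(r.pan), int(r.core), int(r.new))
            for r in df.itertuples()
        ]

    def fit(self) -> list[str]:
        samples = self._load_samples()
        fits = {
            stat: pangenome.fit_heaps_law(samples, stat).as_dict()
            for stat in ("mean", "median")
        }
        path = os.path.join(self.s2dir, "heapfit.json")
        with open(path, "w") as fh:
            json.dump(fits, fh, indent=2, sort_keys=True, default=str)
        return [path]

    def reports(self) -> list[str]:
        matrix = self._load_matrix()
        samples = self._load_samples()
        with open(os.path.join(self.s2dir, "heapfit.json")) as fh:
            fits = json.load(fh)
        return render_reports(
            {
                "matrix": matrix,
                "samples": samples,
                "fits": fits,
                "unique": pangenome.unique_genes(matrix),
                "shared": pangenome.shared_distribution(matrix),
            },
            self.s2dir,
        )

    # -- hashing ------------------------------------------------------------

    def step_params(self, name: str) -> dict:
        c = self.c
        common = {"genomes": [g.genome_id for g in c.genomes]}
        if name == "partition":
            files = {}
            for g in c.genomes:
                files[g.genome_id] = [
                    _file_digest(p) for p in (g.fasta, g.reads1, g.reads2) if p
                ]
            return common | {"kmer_map": c.kmer_map, "inputs": files}
        if name in ("repair", "assemble"):
            return common | {"kmer_asm": c.kmer_asm, "min_contig": c.min_contig}
        if name in ("annotate_ref", "annotate_asm", "reannotate", "genfiles"):
            return common | {"min_orf": c.min_orf}
        if name in ("identify", "cluster"):
            return common | {
                "evalue": c.evalue, "identity": c.identity, "coverage": c.coverage,
                "known": c.known_proteins,
            }
        if name in ("curves", "fit"):
            return common | {"n_perms": c.n_perms, "seed": c.seed}
        return common


def run(config: RunConfig, resume: bool = False) -> int:
    """Execute all steps in order; returns 0 on success, 1 on failure.

    With *resume*, steps recorded done whose parameter hash still matches are
    skipped; any upstream hash change invalidates all downstream steps.
    """
    runner = _Runner(config)
    os.makedirs(config.outdir, exist_ok=True)
    if not log.handlers:
        log.addHandler(logging.StreamHandler())
    fh = logging.FileHandler(os.path.join(config.outdir, "run.log"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    state_path = os.path.join(config.outdir, "state.json")
    state = load_state(state_path) if resume else {n: StepRecord(n) for n in STEP_ORDER}
    try:
        parent_hash = ""
        for name in STEP_ORDER:
            h = _digest({"step": name, "params": runner.step_params(name), "parent": parent_hash})
            rec = state[name]
            if resume and rec.status == "done" and rec.params_hash == h:
                log.info("step %-12s skipped (done, hash match)", name)
                parent_hash = h
                continue
            rec.status, rec.params_hash, rec.started_at = "running", h, time.time()
            save_state(state, state_path)
            try:
                rec.outputs = getattr(runner, name)()
            except Exception as exc:
                rec.status, rec.ended_at = "failed", time.time()
                save_state(state, state_path)
                log.error("step %-12s FAILED: %s", name, exc)
                return 1
            rec.status, rec.ended_at = "done", time.time()
            save_state(state, state_path)
            log.info("step %-12s done in %.2fs", name, rec.ended_at - rec.started_at)
            parent_hash = h
        return 0
    finally:
        log.removeHandler(fh)
        fh.close()


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def render_reports(results: dict, outdir: str) -> list[str]:
    """Write the stage-2 plots and their machine-readable sibling tables.

    Plots are rendered for human inspection; every number shown is also in a
    TSV/JSON sibling, which is the testable surface.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    matrix: pangenome.PanMatrix = results["matrix"]
    samples: list[pangenome.CurveSample] = results["samples"]
    fits = results["fits"]
    unique = results["unique"]
    shared = results["shared"]
    os.makedirs(outdir, exist_ok=True)
    paths: list[str] = []

    def save_tsv(df: pd.DataFrame, name: str) -> None:
        p = os.path.join(outdir, name)
        df.to_csv(p, sep="\t", index=True)
        paths.append(p)

    G = len(matrix.genome_ids)
    df = pd.DataFrame([dataclasses.asdict(s) for s in samples])

    # pan/core boxplot with fitted curves and alpha annotation
    fig, ax = plt.subplots(figsize=(7, 5))
    pan_by_n = [df[df.N == n]["pan"].to_numpy() for n in range(1, G + 1)]
    core_by_n = [df[df.N == n]["core"].to_numpy() for n in range(1, G + 1)]
    bp1 = ax.boxplot(pan_by_n, positions=np.arange(1, G + 1) - 0.15, widths=0.25,
                     patch_artist=True)
    bp2 = ax.boxplot(core_by_n, positions=np.arange(1, G + 1) + 0.15, widths=0.25,
                     patch_artist=True)
    for box in bp1["boxes"]:
        box.set_facecolor("steelblue")
    for box in bp2["boxes"]:
        box.set_facecolor("darkorange")
    ax.set_xticks(range(1, G + 1))
    ax.set_xticklabels(range(1, G + 1))
    ax.set_xlabel("genomes considered (N)")
    ax.set_ylabel("gene families")
    ax.set_title(
        "pangenome (blue) and core (orange); "
        f"alpha mean={fits['mean']['alpha']:.4f} median={fits['median']['alpha']:.4f} "
        f"({fits['median']['verdict']})"
    )
    fig.savefig(os.path.join(outdir, "boxplot.png"), dpi=110)
    plt.close(fig)
    paths.append(os.path.join(outdir, "boxplot.png"))

    # unique genes per genome
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(list(unique.keys()), list(unique.values()), color="seagreen")
    ax.set_ylabel("unique genes")
    plt.xticks(rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(os.path.join(outdir, "barplot_uniques.png"), dpi=110)
    plt.close(fig)
    paths.append(os.path.join(outdir, "barplot_uniques.png"))
    save_tsv(pd.Series(unique, name="unique_genes").to_frame(), "unique_genes.tsv")

    # ortholog sharing: bar + pie
    fig, ax = plt.subplots(figsize=(7, 4))
    ks = sorted(shared)
    ax.bar([str(k) for k in ks], [shared[k] for k in ks], color="slateblue")
    ax.set_xlabel("genomes sharing the family")
    ax.set_ylabel("gene families")
    fig.tight_layout()
    fig.savefig(os.path.join(outdir, "barplot.png"), dpi=110)
    plt.close(fig)
    paths.append(os.path.join(outdir, "barplot.png"))
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.pie([shared[k] for k in ks], labels=[f"{k} genomes" for k in ks],
           autopct="%1.0f%%")
    fig.savefig(os.path.join(outdir, "pie_shared.png"), dpi=110)
    plt.close(fig)
    paths.append(os.path.join(outdir, "pie_shared.png"))
    save_tsv(
        pd.Series(shared, name="clusters").rename_axis("n_genomes").to_frame(),
        "shared_distribution.tsv",
    )

    # distances and trees
    dist = pangenome.pan_distance_matrix(matrix)
    save_tsv(dist, "distances.tsv")
    for method, stem in (("nj", "PanBased.Neighbor-joining"), ("upgma", "PanBased.UPGMA")):
        nwk = pangenome.build_tree(dist, method)
        p = os.path.join(outdir, stem + ".nwk")
        with open(p, "w") as fh:
            fh.write(nwk + "\n")
        paths.append(p)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.text(0.02, 0.5, nwk, fontsize=7, wrap=True, va="center")
        ax.set_axis_off()
        ax.set_title(stem)
        fig.savefig(os.path.join(outdir, stem + ".png"), dpi=110)
        plt.close(fig)
        paths.append(os.path.join(outdir, stem + ".png"))
    return paths
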