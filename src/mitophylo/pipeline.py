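"""End-to-end pipeline orchestration with a reproducibility manifest.

Stages: parse mitogenomes (GenBank or synthetic) -> extract & translate the
13 PCGs -> per-gene protein alignment (or ingest pre-aligned FASTA) ->
back-translate -> concatenate into the codon supermatrix -> ML inference
(GTR+G+I) -> bootstrap -> outgroup rooting -> clade monophyly tests.  Every
intermediate is written to the run directory and a JSON manifest records
inputs, config, seeds, stage timings and output checksums — also on
failure, up to the failed stage.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .genes import CANONICAL_PCGS, extract_pcgs, validate_gene_order
from .ml.gtr import GTRGIParams
from .ml.model import PhyloGTRModel
from .ml.search import SearchSettings
from .msa import AlignParams, ProteinAlignment, progressive_align
from .seq_formats import read_fasta, read_genbank, write_fasta, write_supermatrix
from .simulate import SimulationConfig, build_synthetic_genbank
from .supermatrix import backtranslate, concatenate, supermatrix_report
from .trees import write_newick


class PipelineError(RuntimeError):
    pass


@dataclass
class RunManifest:
    config: dict
    tool_version: str = __version__
    inputs: dict = field(default_factory=dict)    # path -> sha256
    outputs: dict = field(default_factory=dict)   # path -> sha256
    timings: dict = field(default_factory=dict)   # stage -> seconds
    seeds: dict = field(default_factory=dict)
    status: str = "running"
    failed_stage: str | None = None
    error: str | None = None

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def parse_clade_file(path) -> list[tuple[str, list[str]]]:
    """One clade per line: ``label<TAB>taxon1,taxon2,...``."""
    clades = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, taxa = line.split("\t", 1)
        clades.append((label, [t.strip() for t in taxa.split(",") if t.strip()]))
    return clades


def run_pipeline(config, run_dir=None) -> tuple[int, RunManifest]:
    """Run all stages; returns (exit status, manifest).  Any stage error
    halts with status 1 and a manifest recording the failure point."""
    cfg = _load_config(config)
    run_dir = Path(run_dir or cfg.get("run_dir", "mitophylo_run"))
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg)
    manifest_path = run_dir / "manifest.json"
    stage = "setup"
    try:
        seed = int(cfg.get("seed", 0))
        manifest.seeds["pipeline"] = seed
        outgroup = cfg.get("outgroup") or []

        # ------------------------------------------------------------ parse
        stage = "parse"
        t0 = time.perf_counter()
        records = []
        if "synthetic" in cfg.get("input", {}):
            syn = dict(cfg["input"]["synthetic"])
            syn.setdefault("rng_seed", seed)
            if "model" in syn:
                syn["model"] = GTRGIParams(**syn["model"])
            bundle = build_synthetic_genbank(SimulationConfig(**syn))
            records = bundle.records
            write_newick(bundle.tree, run_dir / "true_tree.nwk")
        else:
            for path in cfg.get("input", {}).get("genbank", []):
                manifest.inputs[str(path)] = _sha256(Path(path))
                records.extend(read_genbank(path))
        if not records:
            raise PipelineError("no input records (configure input.genbank "
                                "or input.synthetic)")
        taxa = [r.organism or r.accession for r in records]
        missing_og = set(outgroup) - set(taxa)
        if missing_og:
            raise PipelineError(f"outgroup taxa not among inputs: {sorted(missing_og)}")
        manifest.timings[stage] = time.perf_counter() - t0

        # ---------------------------------------------------------- extract
        stage = "extract"
        t0 = time.perf_counter()
        gene_sets = []
        order_lines = []
        for rec in records:
            gene_sets.append(extract_pcgs(rec))
            report = validate_gene_order(rec)
            order_lines.append(
                f"{rec.accession}\t{report.counts}\t"
                + ("canonical" if report.is_canonical else
                   "; ".join(report.deviations)))
        (run_dir / "gene_order.tsv").write_text("\n".join(order_lines) + "\n")
        manifest.timings[stage] = time.perf_counter() - t0

        # ------------------------------------------------------------ align
        stage = "align"
        t0 = time.perf_counter()
        align_cfg = cfg.get("alignment", {})
        params = AlignParams(
            matrix_name=align_cfg.get("matrix", "BLOSUM62"),
            gap_open=float(align_cfg.get("gap_open", -10)),
            gap_extend=float(align_cfg.get("gap_extend", -1)))
        aligned_dir = cfg.get("aligned_dir")
        alignments: dict[str, ProteinAlignment] = {}
        for gene in CANONICAL_PCGS:
            if aligned_dir:
                path = Path(aligned_dir) / f"{gene}.fasta"
                if not path.exists():
                    raise PipelineError(f"pre-aligned file missing: {path}")
                manifest.inputs[str(path)] = _sha256(path)
                alignments[gene] = ProteinAlignment(gene, read_fasta(path))
            else:
                seqs = {gs.taxon: gs.genes[gene][1]
                        for gs in gene_sets if gene in gs.genes}
                if not seqs:
                    continue
                alignments[gene] = progressive_align(seqs, params, gene_name=gene)
            write_fasta(alignments[gene].rows, run_dir / f"{gene}.aln.fasta")
        manifest.timings[stage] = time.perf_counter() - t0

        # ---------------------------------------------- backtranslate+concat
        stage = "supermatrix"
        t0 = time.perf_counter()
        codon_alns = []
        for gene, aln in alignments.items():
            cds = {gs.taxon: gs.genes[gene][0]
                   for gs in gene_sets if gene in gs.genes}
            codon_alns.append(backtranslate(aln, cds))
        matrix = concatenate(codon_alns)
        for fmt, name in (("fasta", "supermatrix.fasta"),
                          ("phylip", "supermatrix.phy"),
                          ("nexus", "supermatrix.nex")):
            write_supermatrix(matrix, fmt, run_dir / name)
        supermatrix_report(matrix).to_csv(run_dir / "supermatrix_report.tsv",
                                          sep="\t", index=False)
        manifest.timings[stage] = time.perf_counter() - t0

        # -------------------------------------------------------------- ML
        stage = "ml_inference"
        t0 = time.perf_counter()
        model_cfg = cfg.get("model", {})
        model = PhyloGTRModel(
            matrix, n_rate_categories=int(model_cfg.get("gamma_categories", 4)))
        results = model.fit()
        (run_dir / "model_params.txt").write_text(results.params_report() + "\n")
        write_newick(results.tree, run_dir / "ml_tree.nwk")
        manifest.timings[stage] = time.perf_counter() - t0

        # -------------------------------------------------------- bootstrap
        stage = "bootstrap"
        t0 = time.perf_counter()
        boot_cfg = cfg.get("bootstrap", {})
        n_reps = int(boot_cfg.get("n_replicates", 0))
        if n_reps:
            results = results.bootstrap(
                n_replicates=n_reps,
                seed=int(boot_cfg.get("rng_seed", seed)),
                resample_unit=boot_cfg.get("resample_unit", "column"))
            manifest.seeds["bootstrap"] = int(boot_cfg.get("rng_seed", seed))
        manifest.timings[stage] = time.perf_counter() - t0

        # ------------------------------------------------------------- root
        stage = "rooting"
        t0 = time.perf_counter()
        if outgroup:
            results = results.root_with_outgroup(outgroup)
        write_newick(results.tree, run_dir / "best_tree.nwk")
        manifest.timings[stage] = time.perf_counter() - t0

        # ------------------------------------------------------ clade tests
        stage = "clade_tests"
        t0 = time.perf_counter()
        if cfg.get("clade_tests"):
            lines = ["label\tmonophyletic\tsupport\ttaxa"]
            for label, taxa_list in parse_clade_file(cfg["clade_tests"]):
                res = results.test_clade(taxa_list)
                sup = "" if res["support"] is None else f"{res['support']:.1f}"
                lines.append(f"{label}\t{res['monophyletic']}\t{sup}\t"
                             + ",".join(res["taxa"]))
            (run_dir / "clade_tests.tsv").write_text("\n".join(lines) + "\n")
        manifest.timings[stage] = time.perf_counter() - t0

        (run_dir / "summary.txt").write_text(results.summary() + "\n")
        for path in sorted(run_dir.iterdir()):
            if path.is_file() and path.name != "manifest.json":
                manifest.outputs[str(path)] = _sha256(path)
        manifest.status = "ok"
        manifest.write(manifest_path)
        return 0, manifest
    except Exception as exc:  # noqa: BLE001 - manifest must record any failure
        manifest.status = "failed"
        manifest.failed_stage = stage
        manifest.error = f"{exc}\n{traceback.format_exc()}"
        for path in sorted(run_dir.iterdir()):
            if path.is_file() and path.name != "manifest.json":
                manifest.outputs[str(path)] = _sha256(path)
        manifest.write(manifest_path)
        return 1, manifest
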