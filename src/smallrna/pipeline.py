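"""End-to-end orchestration and the packaged reference tables.

``run_all`` sequences every stage on a config: obtain inputs (generated
synthetically unless user paths are supplied), clean and collapse reads,
map and categorize tags, test known miRNAs for differential expression,
call novel hairpin candidates per library and intersect them, predict
targets of the novel matures, and run GO enrichment — writing one TSV per
report plus a JSON run log with per-stage read-conservation numbers and
output checksums.  A fixed seed gives a byte-identical bundle on re-run.

The package ships two published reference tables from a Klinefelter-syndrome
vs healthy-control PBMC small-RNA study (25 novel-miRNA candidate rows and
89 differentially expressed known-miRNA rows); ``verify_reference_tables``
re-derives the arithmetic those tables encode (coordinate spans, fold
changes, the sign partition) as a self-check of the package's conventions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import diffexpr as de
from . import enrichment as enr
from . import novel_discovery as novel
from . import preprocess as prep
from . import synthetic_data as sim
from . import target_prediction as tp
from ._seq import read_fasta, revcomp, write_fasta


# --- configuration ----------------------------------------------------------


@dataclass
class SyntheticConfig:
    """Shape of the generated study when no user inputs are supplied."""

    n_chrom: int = 2
    chrom_length: int = 12_000
    n_known: int = 12
    n_de: int = 4  # known miRNAs given a true 4-fold change
    de_fold: float = 4.0
    n_novel: int = 4
    novel_rpm: float = 800.0
    total_reads: int = 20_000
    error_rate: float = 0.001


@dataclass
class InputPaths:
    genome_fasta: str = ""
    annotation_bed: str = ""
    mature_fasta: str = ""
    transcripts_fasta: str = ""
    tx2gene_tsv: str = ""
    gene2go_tsv: str = ""
    fastq_a: str = ""
    fastq_b: str = ""

    def complete(self) -> bool:
        return all(dataclasses.astuple(self))


@dataclass
class RunConfig:
    outdir: str = "smallrna_run"
    seed: int = 7
    condition_labels: Tuple[str, str] = ("case", "control")
    adapter3: str = sim.DEFAULT_ADAPTER3
    adapter5: str = sim.DEFAULT_ADAPTER5
    min_len: int = 18
    max_len: int = 30
    fc_cut: float = 1.0
    p_cut: float = 0.001
    fdr_cut: float = 0.01
    use_fdr: bool = False
    mfe_ratio_cut: float = 0.75
    hairpin: novel.HairpinCallConfig = field(default_factory=novel.HairpinCallConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    inputs: InputPaths = field(default_factory=InputPaths)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["condition_labels"] = list(self.condition_labels)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["condition_labels"] = tuple(data.get("condition_labels", ("case", "control")))
        data["hairpin"] = novel.HairpinCallConfig(**data.get("hairpin", {}))
        data["synthetic"] = SyntheticConfig(**data.get("synthetic", {}))
        data["inputs"] = InputPaths(**data.get("inputs", {}))
        return cls(**data)


# --- synthetic input bundle -------------------------------------------------


@dataclass
class StudyInputs:
    paths: InputPaths
    design: Optional[sim.SpikeInDesign] = None
    truth_a: Optional[pd.DataFrame] = None
    truth_b: Optional[pd.DataFrame] = None


def build_synthetic_inputs(config: RunConfig, outdir: Path) -> StudyInputs:
    """Generate and write the full input bundle with known ground truth."""
    sc = config.synthetic
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 101])
    genome = sim.generate_genome(sc.n_chrom, sc.chrom_length, seed=config.seed)
    intervals = sim.generate_annotation(genome, seed=config.seed + 1)

    # known miRNAs: random matures embedded directly in the genome
    spikeins: List[sim.SpikeIn] = []
    known: Dict[str, str] = {}
    base_rpms = np.geomspace(300, 20_000, sc.n_known)
    for i in range(sc.n_known):
        length = int(rng.integers(20, 24))
        mature = "".join(rng.choice(sim.BASES, size=length))
        chrom, pos = sim._random_free_position(genome, length, rng)
        sim.embed_sequence(genome, mature, chrom, pos, f"known_mirna:known-mir-{i + 1}")
        name = f"known-mir-{i + 1:02d}"
        known[name] = mature
        rpm_a = rpm_b = float(base_rpms[i])
        # true effects go on well-expressed miRNAs, alternating direction
        if i >= sc.n_known - sc.n_de:
            if i % 2 == 0:
                rpm_b = rpm_a * sc.de_fold
            else:
                rpm_a = rpm_b * sc.de_fold
        spikeins.append(sim.SpikeIn(name, mature, rpm_a, rpm_b, "known_mirna"))

    # novel miRNAs: hairpins planted at random free loci
    hairpin_loci: Dict[str, novel.Locus] = {}
    for i in range(sc.n_novel):
        length = int(rng.integers(20, 24))
        mature = "".join(rng.choice(sim.BASES, size=length))
        chrom, pos = sim._random_free_position(genome, 80, rng)
        name = f"novel-{i + 1:02d}"
        locus = sim.plant_hairpin(
            genome, mature, arm="5p" if i % 2 == 0 else "3p", position=pos,
            chrom=chrom, seed=config.seed + 20 + i, label=f"hairpin:{name}",
        )
        hairpin_loci[name] = locus
        spikeins.append(sim.SpikeIn(name, mature, sc.novel_rpm, sc.novel_rpm, "novel_mirna"))

    # a couple of annotated-class fragments so the category summary is non-trivial
    for iv in intervals[:3]:
        frag = sim.interval_fragment(genome, iv, length=22)
        spikeins.append(sim.SpikeIn(f"frag-{iv.category}", frag, 2_000.0, 2_000.0, "fragment"))

    design = sim.SpikeInDesign(spikeins, hairpin_loci)
    cfg = sim.ReadSimConfig(
        total_reads=sc.total_reads,
        adapter3=config.adapter3,
        adapter5=config.adapter5,
        error_rate=sc.error_rate,
        seed=config.seed,
    )
    reads_a, truth_a = sim.simulate_library(genome, design, cfg, "A")
    reads_b, truth_b = sim.simulate_library(genome, design, cfg, "B")

    novel_matures = {s.name: s.sequence for s in spikeins if s.kind == "novel_mirna"}
    transcripts, tx2gene, _sites = sim.make_transcriptome(novel_matures, seed=config.seed + 2)
    target_gene_names = sorted(set(tx2gene[tx] for tx in transcripts if not tx.startswith("tx_decoy")))
    go_map = sim.generate_go_map(
        n_genes=60, n_terms=8, enriched_term="GO:0000001",
        target_genes=target_gene_names, seed=config.seed + 3,
    )

    paths = InputPaths(
        genome_fasta=str(outdir / "genome.fa"),
        annotation_bed=str(outdir / "annotation.bed"),
        mature_fasta=str(outdir / "mature.fa"),
        transcripts_fasta=str(outdir / "transcripts.fa"),
        tx2gene_tsv=str(outdir / "tx2gene.tsv"),
        gene2go_tsv=str(outdir / "gene2go.tsv"),
        fastq_a=str(outdir / "library_A.fastq"),
        fastq_b=str(outdir / "library_B.fastq"),
    )
    write_fasta(sorted(genome.chromosomes.items()), paths.genome_fasta)
    sim.write_bed(intervals, paths.annotation_bed)
    write_fasta(sorted(known.items()), paths.mature_fasta)
    write_fasta(sorted(transcripts.items()), paths.transcripts_fasta)
    with open(paths.tx2gene_tsv, "w") as fh:
        for tx in sorted(tx2gene):
            fh.write(f"{tx}\t{tx2gene[tx]}\n")
    sim.write_go_map(go_map, paths.gene2go_tsv)
    sim.write_fastq(reads_a, paths.fastq_a)
    sim.write_fastq(reads_b, paths.fastq_b)
    truth_a.to_csv(outdir / "truth_A.tsv", sep="\t", index=False)
    truth_b.to_csv(outdir / "truth_B.tsv", sep="\t", index=False)
    return StudyInputs(paths, design, truth_a, truth_b)


# --- the run ----------------------------------------------------------------


@dataclass
class RunResult:
    outdir: Path
    reports: Dict[str, Path]
    log: Dict
    inputs: Optional[StudyInputs] = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> RunResult:
    """Run every stage; deterministic given the config seed.

    Any stage failure aborts with the stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: Dict = {"stages": {}}
    stage = "inputs"
    try:
        if config.inputs.complete():
            inputs = StudyInputs(config.inputs)
        else:
            inputs = build_synthetic_inputs(config, outdir / "inputs")
        p = inputs.paths

        stage = "preprocess"
        label_a, label_b = config.condition_labels
        clean: Dict[str, prep.CleanResult] = {}
        for label, fq in ((label_a, p.fastq_a), (label_b, p.fastq_b)):
            res = prep.clean_fastq(
                fq, adapter3=config.adapter3, adapter5=config.adapter5,
                min_len=config.min_len, max_len=config.max_len,
            )
            clean[label] = res
            prep.write_tag_fasta(res.tags, outdir / f"tags_{label}.fa")
            log["stages"].setdefault("preprocess", {})[label] = {
                "total_reads": res.total_reads,
                "kept_reads": res.kept_reads,
                "rejections": dict(sorted(res.rejections.items())),
            }

        stage = "annotation"
        genome = read_fasta(p.genome_fasta)
        index = ann.GenomeIndex(genome)
        intervals = ann.read_bed(p.annotation_bed)
        matures = read_fasta(p.mature_fasta)
        known_by_seq = {seq: name for name, seq in matures.items()}
        assignments: Dict[str, List[ann.CategoryAssignment]] = {}
        summaries = []
        for label in (label_a, label_b):
            asn = ann.annotate(clean[label].tags, index, intervals, known_by_seq)
            assignments[label] = asn
            summary = ann.summarize(asn)
            assert int(summary["total_reads"].sum()) == clean[label].kept_reads
            summary.insert(0, "library", label)
            summaries.append(summary)
            matched = sum(a.tag.count for a in asn if a.hits)
            log["stages"].setdefault("annotation", {})[label] = {
                "genome_matched_reads": matched,
                "genome_match_percentage": ann.genome_match_percentage(
                    matched, clean[label].kept_reads
                ),
            }
        categories_path = outdir / "categories.tsv"
        pd.concat(summaries).to_csv(categories_path, sep="\t", index=False)

        stage = "diffexpr"
        counts_a = ann.known_mirna_counts(assignments[label_a], known_by_seq)
        counts_b = ann.known_mirna_counts(assignments[label_b], known_by_seq)
        totals = de.LibraryTotals(clean[label_a].kept_reads, clean[label_b].kept_reads)
        de_table = de.differential_expression(
            counts_a, counts_b, totals,
            fc_cut=config.fc_cut, p_cut=config.p_cut,
            use_fdr=config.use_fdr, fdr_cut=config.fdr_cut,
        )
        report = de_table.rename(
            columns={
                "name": "Name",
                "case_std": f"{label_a}-std",
                "control_std": f"{label_b}-std",
                "log2fc": "Fold change (log2 ratio)",
                "pvalue": "P-value",
                "fdr": "FDR",
                "class": "Class",
            }
        ).drop(columns=["case_count", "control_count"])
        diffexpr_path = outdir / "diffexpr.tsv"
        report.to_csv(diffexpr_path, sep="\t", index=False, float_format="%.8g")
        log["stages"]["diffexpr"] = {
            "n_mirnas": len(de_table),
            "n_up": int((de_table["class"] == "up").sum()),
            "n_down": int((de_table["class"] == "down").sum()),
        }

        stage = "novel_discovery"
        per_library: Dict[str, List[novel.HairpinCandidate]] = {}
        tables = []
        for label in (label_a, label_b):
            unannotated = [
                (a.tag, a.hits) for a in assignments[label] if a.category == ann.UNANNOTATED
            ]
            cands = novel.call_candidates(unannotated, genome, config.hairpin)
            per_library[label] = cands
            table = novel.candidates_table(cands)
            table.insert(0, "Library", label)
            tables.append(table)
        shared = novel.intersect_candidates(per_library[label_a], per_library[label_b])
        novel_path = outdir / "novel_candidates.tsv"
        pd.concat(tables, ignore_index=True).to_csv(novel_path, sep="\t", index=False)
        log["stages"]["novel_discovery"] = {
            label: len(per_library[label]) for label in (label_a, label_b)
        } | {"shared": len(shared)}

        stage = "target_prediction"
        by_sequence: Dict[str, str] = {}
        for label in (label_a, label_b):
            for c in per_library[label]:
                by_sequence.setdefault(c.sequence, f"{c.name}_{label}")
        novel_matures = {name: seq for seq, name in by_sequence.items()}
        transcripts = read_fasta(p.transcripts_fasta)
        tx2gene = {}
        with open(p.tx2gene_tsv) as fh:
            for line in fh:
                if line.strip():
                    tx, gene = line.rstrip("\n").split("\t")
                    tx2gene[tx] = gene
        targets_path = outdir / "targets.tsv"
        if novel_matures:
            targets = tp.predict_targets(
                novel_matures, transcripts, tx2gene, ratio_cut=config.mfe_ratio_cut
            )
        else:
            targets = tp.predict_targets({"_none_": "A" * 21}, transcripts, tx2gene).iloc[0:0]
        targets.to_csv(targets_path, sep="\t", index=False)
        log["stages"]["target_prediction"] = {"n_sites": len(targets)}

        stage = "enrichment"
        gene2go = enr.read_gene2go(p.gene2go_tsv)
        go_path = outdir / "go_enrichment.tsv"
        target_genes = sorted(set(targets["gene"])) if len(targets) else []
        annotated_targets = [g for g in target_genes if gene2go.get(g)]
        if annotated_targets:
            go = enr.enrich(annotated_targets, gene2go, p_cut=config.p_cut)
        else:
            go = pd.DataFrame(columns=["term", "k", "K", "n", "N", "pvalue", "fdr", "significant"])
        go.to_csv(go_path, sep="\t", index=False, float_format="%.8g")
        log["stages"]["enrichment"] = {"n_terms": len(go)}

        stage = "finalize"
        reports = {
            "categories": categories_path,
            "diffexpr": diffexpr_path,
            "novel_candidates": novel_path,
            "targets": targets_path,
            "go_enrichment": go_path,
        }
        log["checksums"] = {name: _sha256(path) for name, path in sorted(reports.items())}
        # outdir excluded so the same seed gives byte-identical logs anywhere
        config_echo = dataclasses.asdict(config) | {"condition_labels": list(config.condition_labels)}
        config_echo.pop("outdir")
        log["config"] = config_echo
        log_path = outdir / "run_log.json"
        log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
        reports["run_log"] = log_path
        return RunResult(outdir, reports, log, inputs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


# --- packaged reference tables ----------------------------------------------

_DATA = resources.files("smallrna") / "data"


def _normalize_minus(text: str) -> str:
    for uni in ("−", "–", "—"):
        text = text.replace(uni, "-")
    return text


def load_reference_de_table() -> pd.DataFrame:
    """The published 89-row differential-expression table (case-std,
    control-std, fold change as log2(control/case), p-value)."""
    with (_DATA / "de_known_mirnas.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    for col in df.columns[1:]:
        df[col] = df[col].map(lambda v: float(_normalize_minus(str(v)).strip()))
    return df


def load_reference_novel_table() -> pd.DataFrame:
    """The published 25-row novel-miRNA candidate table."""
    with (_DATA / "novel_candidates.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def verify_de_table(df: pd.DataFrame, tol: float = 1e-4) -> List[str]:
    """Re-derive each fold change from the std columns; list failing rows."""
    failures = []
    name_col, case_col, ctrl_col, fc_col = df.columns[:4]
    for _, row in df.iterrows():
        case_std = de.floor_zero(row[case_col])
        ctrl_std = de.floor_zero(row[ctrl_col])
        recomputed = float(de.log2_ratio(ctrl_std, case_std))
        if not math.isfinite(recomputed) or abs(recomputed - row[fc_col]) > tol:
            failures.append(f"{row[name_col]}: fold change {row[fc_col]} != recomputed {recomputed:.8f}")
    n_pos = int((df[fc_col] > 0).sum())
    n_neg = int((df[fc_col] < 0).sum())
    if (n_pos, n_neg) != (71, 18):
        failures.append(f"sign partition {n_pos} positive / {n_neg} negative != 71/18")
    if len(df) != 89:
        failures.append(f"expected 89 rows, found {len(df)}")
    return failures


def verify_novel_table(df: pd.DataFrame) -> List[str]:
    """Check coordinate arithmetic and sequence lengths; list failing rows."""
    failures = []
    for _, row in df.iterrows():
        name = row.iloc[0]
        try:
            locus = novel.parse_location(str(row["Location"]))
        except ValueError as exc:
            failures.append(f"{name}: {exc}")
            continue
        plen = int(row["Precursor length (nt)"])
        if novel.precursor_length(locus) != plen:
            failures.append(
                f"{name}: precursor length {plen} != span {novel.precursor_length(locus)}"
            )
        if len(str(row["Sequence"])) != int(row["Length"]):
            failures.append(f"{name}: sequence length != printed length")
    if len(df) != 25:
        failures.append(f"expected 25 rows, found {len(df)}")
    return failures


def verify_reference_tables() -> Dict:
    """Run all packaged-table self-checks; report pass/fail with details."""
    de_df = load_reference_de_table()
    novel_df = load_reference_novel_table()
    failures = verify_de_table(de_df) + verify_novel_table(novel_df)
    fc_col = de_df.columns[3]
    deltas = [
        abs(float(de.log2_ratio(de.floor_zero(r.iloc[2]), de.floor_zero(r.iloc[1]))) - r.iloc[3])
        for _, r in de_df.iterrows()
    ]
    return {
        "ok": not failures,
        "failures": failures,
        "de_rows": len(de_df),
        "novel_rows": len(novel_df),
        "max_fold_change_delta": max(deltas),
        "sign_partition": (int((de_df[fc_col] > 0).sum()), int((de_df[fc_col] < 0).sum())),
    }
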