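"""End-to-end orchestration: demo generation and staged runs.

A run executes preprocess -> annotate -> hairpin -> quantify -> diffexp
-> biomarker from a single YAML config, writing each stage's table plus
a line-delimited JSON log that reconciles record counts at every stage
boundary. Identical config + seed produces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as ann
from . import biomarker as bio
from . import diffexp as de
from . import hairpin as hp
from . import preprocess as pre
from . import quantify as q
from . import simulate as sim
from .seqio import write_fasta, write_fastq, write_table

STAGE_SEED_OFFSETS = {
    "reference": 11, "reads": 97, "cohort": 211,
}


@dataclass
class PipelineConfig:
    fastqs: dict[str, str]                  # sample id -> path
    reference: str
    contaminants: str | None
    cohort: str | None
    outdir: str
    groups: dict[str, str] = field(default_factory=dict)
    adapter: str = sim.DEFAULT_ADAPTER
    min_len: int = 18
    max_len: int = 26
    max_ambiguous: int = 0
    entropy_min: float = 1.0
    qual_min: float = 20.0
    max_adapter_mismatch: int = 1
    max_mismatch: int = 1
    max_end_shift: int = 2
    flank: int = 80
    criteria: dict = field(default_factory=dict)
    pseudocount: float = 0.0
    de_alpha: float = 0.05
    de_lfc_min: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True))

    def validate(self) -> None:
        missing = []
        for sample, p in self.fastqs.items():
            if not Path(p).exists():
                missing.append(f"fastq[{sample}]={p}")
        for name in ("reference", "contaminants", "cohort"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                missing.append(f"{name}={p}")
        if missing:
            raise FileNotFoundError(
                "missing input paths: " + ", ".join(missing))

    def clean_params(self) -> pre.CleanParams:
        return pre.CleanParams(
            adapter=self.adapter, min_len=self.min_len, max_len=self.max_len,
            max_ambiguous=self.max_ambiguous, entropy_min=self.entropy_min,
            qual_min=self.qual_min,
            max_adapter_mismatch=self.max_adapter_mismatch)

    def thresholds(self) -> hp.CriteriaThresholds:
        return hp.CriteriaThresholds(**self.criteria)


class _RunLog:
    def __init__(self, path: Path, seed: int):
        self.path = path
        self.entries: list[dict] = []
        self.seed = seed

    def add(self, stage: str, **info) -> None:
        self.entries.append({"stage": stage, "seed": self.seed, **info})

    def write(self) -> None:
        with open(self.path, "w") as fh:
            for e in self.entries:
                fh.write(json.dumps(e, sort_keys=True) + "\n")


def run(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(outdir / "run_log.jsonl", config.seed)

    # preprocess
    table = pre.preprocess_samples(config.fastqs, config.clean_params())
    table.write(outdir / "unique_sequences.tsv")
    table.write_log(outdir / "preprocess_log.tsv")
    for s, st in table.stats.items():
        if not st.conserved():
            raise RuntimeError(f"preprocess: count ledger broken for {s}")
    log.add("preprocess",
            input={s: st.input for s, st in table.stats.items()},
            accepted={s: st.accepted for s, st in table.stats.items()},
            unique_rows=int(len(table.counts)))

    # annotate
    reference = ann.PrecursorReference.from_fasta(config.reference)
    contaminants = []
    if config.contaminants:
        from .seqio import read_fasta
        contaminants = read_fasta(config.contaminants)
    result = ann.annotate_table(
        table, reference, contaminants,
        max_mismatch=config.max_mismatch,
        max_end_shift=config.max_end_shift, flank=config.flank)
    result.write(outdir / "annotations.tsv")
    class_counts = result.rows["class"].value_counts().to_dict()
    if sum(class_counts.values()) != len(table.counts):
        raise RuntimeError("annotate: class partition does not cover table")
    log.add("annotate", classes={k: int(v) for k, v in class_counts.items()})

    # hairpin screening of novel candidates
    thresholds = config.thresholds()
    novel = result.rows[result.rows["class"] == "novel_arm_candidate"]
    accepted_novel: set[str] = set()
    hp_rows = []
    for cand_id, sub in novel.groupby("assigned_id"):
        row = sub.iloc[0]
        rec = reference[row["precursor"]]
        fs, fe = int(row["flank_start"]), int(row["flank_end"])
        window = rec.sequence[fs:fe]
        mature = (int(row["offset"]) - fs,
                  int(row["offset"]) - fs + len(sub.index[0]))
        st, feats, report = hp.classify_candidate(window, mature, thresholds)
        if report.overall:
            accepted_novel.add(str(cand_id))
        hp_rows.append({"candidate": cand_id, "precursor": row["precursor"],
                        "energy": st.energy, "overall": report.overall,
                        **report.flags()})
    if hp_rows:
        write_table(pd.DataFrame(hp_rows).set_index("candidate"),
                    outdir / "hairpin_criteria.tsv", index_label="candidate")
    log.add("hairpin", candidates=len(hp_rows),
            accepted=len(accepted_novel))

    # quantify
    matrix = q.build_count_matrix(result, accepted_novel)
    matrix.write(outdir / "counts.tsv")
    factors = q.library_size_factors(matrix, pseudocount=config.pseudocount)
    factors.write(outdir / "library_size_factors.tsv")
    normalized = q.normalize(matrix, factors)
    write_table(normalized, outdir / "normalized.tsv", index_label="id")
    log.add("quantify", rows=int(matrix.counts.shape[0]),
            total=int(matrix.counts.values.sum()))

    # diffexp
    de_path = None
    if config.groups:
        design = de.GroupDesign(config.groups)
        if len(design.labels) == 2:
            res = de.compare_two_groups(normalized, design, test="t")
            res = de.call_de(res, config.de_alpha, config.de_lfc_min)
        else:
            res = de.compare_k_groups(normalized, design)
            lfc_cols = [c for c in res.columns if c.startswith("log2fc")]
            res = de.call_de(res, config.de_alpha, config.de_lfc_min,
                             lfc_col=lfc_cols[0])
        de_path = outdir / "diffexp.tsv"
        de.write_de_table(res, de_path)
        volcano_col = "log2fc" if "log2fc" in res.columns else \
            [c for c in res.columns if c.startswith("log2fc")][0]
        volcano = res[[volcano_col, "neg_log10_p", "direction"]]
        write_table(volcano, outdir / "volcano.tsv", index_label="id")
        log.add("diffexp", rows=int(len(res)), de=int(res["de"].sum()))

    # biomarker
    if config.cohort:
        cohort = pd.read_csv(config.cohort, sep="\t", index_col="sample")
        markers = list(normalized.mean(axis=1)
                       .sort_values(ascending=False).index[:2])
        overlap = [c for c in cohort.columns if c in normalized.index]
        joined = cohort.drop(columns=overlap).join(normalized.T, how="inner")
        bio_out: dict = {}
        if joined["neuropathic_pain"].nunique() == 2 and markers:
            rocs = {}
            for mk in markers:
                curve = bio.roc_auc(joined[mk], joined["neuropathic_pain"])
                rocs[mk] = curve.auc
            if len(markers) >= 2:
                combo = bio.combined_roc(joined[markers[0]],
                                         joined[markers[1]],
                                         joined["neuropathic_pain"])
                rocs["+".join(markers[:2])] = combo.auc
            bio_out["auc"] = rocs
        predictors = joined[["male", "age", "opioid", "spasmolytic",
                             "pack_years", "alcohol_grams"] + markers]
        uni = bio.univariate_fits(joined["interference_mood"], predictors)
        multi = bio.multivariable_fit(joined["interference_mood"],
                                      predictors, univariate=uni)
        bio_out["univariate"] = {k: v.to_dict() for k, v in uni.items()}
        bio_out["multivariable"] = multi.to_dict()
        (outdir / "biomarker.json").write_text(
            json.dumps(bio_out, indent=2, sort_keys=True, default=float))
        log.add("biomarker", n=int(len(joined)),
                markers=markers)

    log.write()
    return outdir


def make_demo(outdir: str | Path, seed: int = 0,
              n_reads: int = 2000) -> PipelineConfig:
    """Write a complete synthetic input set plus a ready config.

    Eight precursors (half annotated on a single arm so the opposite arm
    yields novel candidates), two groups of five samples with two planted
    4-fold up-regulated matures, and a cohort table with a planted
    interference slope.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = sim.generate_reference(8, 4, seed + STAGE_SEED_OFFSETS["reference"])
    mapping_ref = ref.to_reference(arms="alternate")
    write_fasta(mapping_ref.to_fasta_records(), outdir / "reference.fa")
    write_fasta(ref.contaminants, outdir / "contaminants.fa")

    annotated = {m.name for r in mapping_ref for m in r.matures}
    planted = sorted(annotated)[:2]
    groups: dict[str, str] = {}
    fastqs: dict[str, str] = {}
    marker_levels: dict[str, dict[str, float]] = {}
    sample_idx = 0
    for group in ("groupA", "groupB"):
        for rep in range(5):
            sample_idx += 1
            name = f"s{sample_idx:02d}"
            groups[name] = group
            expr = sim.plant_expression(
                ref, baseline=150.0,
                log2fc={p: 2.0 for p in planted},
                group=group, affected_group="groupB")
            cfg = sim.ReadSimConfig(
                n_reads=n_reads, fraction_junk=0.05,
                fraction_contaminant=0.05, end_variation_max=1,
                mismatch_rate=0.02, dispersion=0.05,
                seed=seed + STAGE_SEED_OFFSETS["reads"] + sample_idx)
            reads = sim.simulate_sample_reads(ref, expr, cfg)
            path = outdir / f"{name}.fastq"
            write_fastq(reads, path)
            fastqs[name] = str(path)
            marker_levels[name] = {p: expr[p] for p in planted}

    cohort_cfg = sim.CohortSimConfig(
        n_per_group={"groupA": 5, "groupB": 5},
        pain_prevalence={"groupA": 0.2, "groupB": 0.8},
        interference_slope=0.002, noise_sd=0.5,
        seed=seed + STAGE_SEED_OFFSETS["cohort"])
    cohort = sim.simulate_cohort(cohort_cfg, marker_levels, groups=groups)
    write_table(cohort, outdir / "cohort.tsv", index_label="sample")

    config = PipelineConfig(
        fastqs=fastqs,
        reference=str(outdir / "reference.fa"),
        contaminants=str(outdir / "contaminants.fa"),
        cohort=str(outdir / "cohort.tsv"),
        outdir=str(outdir / "run"),
        groups=groups,
        seed=seed,
    )
    config.to_yaml(outdir / "config.yaml")
    return config
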