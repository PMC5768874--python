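"""End-to-end workflows and canned demo fixtures.

Ties the modules together in the order a real assay analysis runs: panel
design -> library simulation -> read QC -> variant calling -> callset
benchmarking -> copy-number calling, writing every intermediate file plus a
machine-readable summary. All randomness flows from the explicit seeds in
:class:`RunConfig`, so a repeated run with the same configuration produces
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import panel as _panel
from . import simlib as _simlib
from . import readqc as _readqc
from . import varbench as _varbench
from . import cnacall as _cnacall

log = logging.getLogger("osseq")

# the demo mirrors the assay's validation design: somatic spike-ins across
# a VAF dilution series and three engineered amplifications
DEMO_VAFS = (0.05, 0.10, 0.15, 0.25, 0.40)
DEMO_CNA_RATIOS = {"GENE001": 4.90, "GENE002": 2.25, "GENE003": 1.32}


@dataclass
class RunConfig:
    """Configuration for the end-to-end demo workflow."""

    seed: int = 1
    out_dir: str = "osseq_demo"
    n_genes: int = 130
    roi_per_gene: int = 2
    roi_len: int = 250
    depth_target: float = 300.0
    deamination_rate: float = 0.02  # illustrative mild FFPE damage
    variants_per_vaf: int = 8
    design: dict = field(default_factory=lambda: {
        "probe_len": (25, 25), "anchor_step": 5, "score_threshold": 5.0})
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        return cfg

    def to_yaml(self, path) -> None:
        data = dict(self.__dict__)
        data["design"] = dict(self.design)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _design_config(cfg: RunConfig) -> _panel.DesignConfig:
    kwargs = dict(cfg.design)
    if "probe_len" in kwargs:
        kwargs["probe_len"] = tuple(kwargs["probe_len"])
    return _panel.DesignConfig(**kwargs)


def make_demo_fixtures(out_dir, seed: int = 1, cfg: RunConfig | None = None):
    """Emit the demo fixture bundle: reference FASTA, ROI BED, designed
    panel, truth VCF spanning the VAF dilution series, an amplified-gene
    spec (4.90/2.25/1.32), and FFPE repair-on/off read sets.

    Deterministic for a fixed seed. Returns a dict of the generated paths
    and in-memory objects.
    """
    import numpy as np

    cfg = cfg or RunConfig(seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    log.info("stage=reference building synthetic reference (seed=%d)", seed)
    genome, rois = _simlib.make_reference(
        cfg.n_genes, cfg.roi_per_gene, cfg.roi_len, seed=seed)
    _simlib.write_fasta(genome, out / "reference.fa")
    _panel.write_rois_bed(rois, out / "rois.bed")

    log.info("stage=panel designing probes")
    probes, gaps = _panel.design_panel(rois, genome, _design_config(cfg))
    _panel.write_panel_tsv(probes, out / "panel.tsv")
    _panel.write_panel_fasta(probes, out / "panel.fa")

    # somatic spike-ins across the VAF dilution series, avoiding the first
    # three genes (reserved for copy-number events)
    log.info("stage=variants spiking somatic variants")
    eligible = [r for r in rois if r.gene not in DEMO_CNA_RATIOS]
    variants = []
    used = set()
    for vaf in DEMO_VAFS:
        for _ in range(cfg.variants_per_vaf):
            while True:
                roi = eligible[rng.integers(len(eligible))]
                pos = int(rng.integers(roi.start + 10, roi.end - 10))
                if pos in used:
                    continue
                ref = genome[roi.chrom][pos].upper()
                alt = "ACGT"[(("ACGT".find(ref)) + 1 + int(rng.integers(3))) % 4]
                used.add(pos)
                break
            variants.append(_simlib.VariantSpec(
                roi.chrom, pos, ref, alt, vaf=vaf, origin="somatic"))
    _simlib.write_truth_vcf(variants, genome, out / "truth.vcf")

    cnas = [_simlib.CnaSpec(g, r) for g, r in DEMO_CNA_RATIOS.items()]
    with open(out / "cna_spec.tsv", "w") as fh:
        fh.write("gene\tcopy_ratio\n")
        for c in cnas:
            fh.write(f"{c.gene}\t{c.copy_ratio}\n")

    log.info("stage=simulate emitting repair-on/off libraries")
    bundles = {}
    for tag, repair in (("repair_on", "excision_on"), ("repair_off", "off")):
        lib = _simlib.simulate_library(
            genome, probes, rois, variants=variants, cnas=cnas,
            ffpe_model=_simlib.FfpeModel(
                deamination_rate=cfg.deamination_rate, repair=repair),
            depth_target=cfg.depth_target, seed=seed,
        )
        lib.write_fastq(out / f"{tag}.R1.fastq.gz", out / f"{tag}.R2.fastq.gz")
        lib.write_truth_sam(out / f"{tag}.truth.sam")
        bundles[tag] = lib

    # undamaged control library from the same panel (diploid, no variants)
    control = _simlib.simulate_library(
        genome, probes, rois, depth_target=cfg.depth_target, seed=seed + 1)
    control.write_truth_sam(out / "control.truth.sam")
    bundles["control"] = control

    cfg.to_yaml(out / "config.yaml")
    return {
        "genome": genome, "rois": rois, "probes": probes, "gaps": gaps,
        "variants": variants, "cnas": cnas, "libraries": bundles,
        "out_dir": out,
    }


def run_end_to_end(cfg: RunConfig) -> dict:
    """Run the full workflow and write a machine-readable summary JSON.

    Stages execute in order (panel, simulate, qc, call, bench, cna); a
    failure aborts with the stage name in the exception message.
    """
    logging.basicConfig(level=cfg.verbosity)
    out = Path(cfg.out_dir)
    stage = "fixtures"
    try:
        fx = make_demo_fixtures(out, seed=cfg.seed, cfg=cfg)
        genome, rois, probes = fx["genome"], fx["rois"], fx["probes"]
        test_lib = fx["libraries"]["repair_on"]
        control_lib = fx["libraries"]["control"]

        stage = "qc"
        log.info("stage=qc computing read metrics")
        pairs = _readqc.pairs_from_sam(out / "repair_on.truth.sam")
        report = _readqc.qc_report(pairs, rois, probes)
        report.to_json(out / "qc.json")

        stage = "call"
        log.info("stage=call pileups and somatic calling")
        piles = _varbench.RoiPileups(rois, genome)
        piles.add_sam(out / "repair_on.truth.sam")
        calls = [
            _varbench.call_somatic(site)
            for site in piles.candidate_sites(min_alt_reads=2)
        ]
        somatic = [c for c in calls if c.status == "somatic"]
        kept, removed = _varbench.filter_somatic_report(somatic)
        _varbench.write_calls_vcf(kept, genome, out / "calls.vcf")

        stage = "bench"
        log.info("stage=bench comparing against truth")
        counts = _varbench.compare_callsets(
            out / "calls.vcf", out / "truth.vcf", rois, reference=genome)
        bench = _varbench.accuracy_metrics(
            counts, tn_universe_bases=piles.callable_bases(min_depth=40))

        stage = "cna"
        log.info("stage=cna read-depth copy-number calling")
        import pandas as pd

        # depth for copy-number uses all distinct on-target molecules in
        # both samples symmetrically: the simulator emits no PCR
        # duplicates, and end-collision dedup would saturate amplified
        # genes at high depth
        test_cov = _readqc.coverage_over_rois(
            _readqc.tag_and_classify(pairs, rois, probes), rois,
            exclude_duplicates=False)
        ctl_pairs = _readqc.pairs_from_sam(out / "control.truth.sam")
        ctl_cov = _readqc.coverage_over_rois(
            _readqc.tag_and_classify(ctl_pairs, rois, probes), rois,
            exclude_duplicates=False)
        roi_gene = {r.roi_id: r.gene for r in rois}
        cov = pd.DataFrame({
            "gene": {rid: roi_gene[rid] for rid in test_cov},
            "test": {rid: float(a.mean()) for rid, a in test_cov.items()},
            "control": {rid: float(a.mean()) for rid, a in ctl_cov.items()},
        })
        cov.index.name = "roi_id"
        cov = cov.sort_index()
        _simlib.write_coverage_tsv(cov, out / "coverage.tsv")
        cna_calls, table, trace = _cnacall.call_cnas(cov)
        _cnacall.calls_to_frame(cna_calls).to_csv(out / "cna.tsv", sep="\t")

        stage = "summary"
        summary = {
            "seed": cfg.seed,
            "n_probes": len(probes),
            "n_gaps": len(fx["gaps"]),
            "n_pairs": test_lib.n_pairs,
            "qc": {
                "on_target_fraction": round(report.on_target_fraction, 4),
                "mean_on_target_coverage": round(
                    report.mean_on_target_coverage, 2),
                "fold80": (round(report.fold80, 3)
                           if report.fold80 is not None else None),
                "insert_mean": (round(report.insert_mean, 2)
                                if report.insert_mean is not None else None),
            },
            "bench": {
                "tp": bench.tp, "fn": bench.fn, "fp": bench.fp,
                "sensitivity": bench.sensitivity,
                "specificity": bench.specificity,
                "ppv": bench.ppv,
            },
            "cna": {
                "flagged": sorted(c.gene for c in cna_calls if c.flagged),
                "ratios": {
                    c.gene: round(c.ratio, 3)
                    for c in cna_calls if c.flagged
                },
            },
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return summary
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
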