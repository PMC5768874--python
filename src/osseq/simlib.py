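"""OS-Seq library simulation.

Emulates the physical library build on a synthetic reference: genomic DNA is
fragmented (~550 bp), optionally deaminated (FFPE damage) with or without an
excision-repair step, denatured, adapter-ligated as single strands, and
captured by primer-probes that prime Read 1 at a fixed genomic anchor while
Read 2 starts from the adapter at the fragment's ligated end.

The capture geometry follows the assay's observed insert behaviour: the
distance from the adapter-ligated end to the first eligible probe site is
uniform over one probe spacing, and the site actually used is a geometric
number of sites further in (capture probability ``p`` per site, default 2/3),
truncated to the fragment. With 100 bp per-strand spacing this yields a mean
truth insert of ~100 nt with inserts ranging up to ~600 nt.

FFPE cytosine deamination converts template C to U. With repair off the
polymerase inserts A opposite U, observed as a C>T (G>A on the opposite
strand) artifact; with excision repair on, the damaged base is removed
without corrective repair, so synthesis terminates at the lesion instead of
emitting the transition base.

The module also simulates per-ROI coverage matrices directly (negative
binomial with a shared lognormal per-ROI capture bias) as the fixture for
read-depth copy-number calling.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .panel import ROI, Probe, revcomp, extract_probe_sequence


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class VariantSpec:
    """A truth variant to spike into the library."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    vaf: float  # fraction of molecules carrying the variant
    kind: str = "SNV"  # SNV | insertion | deletion
    origin: str = "somatic"  # germline | somatic

    def __post_init__(self):
        if not (0.0 < self.vaf <= 1.0):
            raise ValueError(f"vaf must be in (0, 1], got {self.vaf}")
        if self.kind not in ("SNV", "insertion", "deletion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.origin not in ("germline", "somatic"):
            raise ValueError(f"unknown origin {self.origin!r}")


@dataclass(frozen=True)
class CnaSpec:
    """A copy-number alteration: fold change relative to the diploid control."""

    gene: str
    copy_ratio: float

    def __post_init__(self):
        if self.copy_ratio <= 0:
            raise ValueError("copy_ratio must be > 0")


@dataclass
class FragmentModel:
    """Sheared-fragment length distribution (Normal, truncated below)."""

    mean_length: float = 550.0
    sd: float = 50.0
    min_length: int = 100

    def __post_init__(self):
        if not (self.mean_length >= self.min_length > 0):
            raise ValueError("require mean_length >= min_length > 0")


@dataclass
class FfpeModel:
    """FFPE damage model: per-strand cytosine deamination and its repair."""

    deamination_rate: float = 0.0  # per-C probability per strand
    repair: str = "excision_on"  # excision_on | off
    single_strand_fraction: float = 0.0  # molecules denatured pre-ligation

    def __post_init__(self):
        for r in (self.deamination_rate, self.single_strand_fraction):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        if self.repair not in ("excision_on", "off"):
            raise ValueError("repair must be 'excision_on' or 'off'")


@dataclass
class CaptureModel:
    """Probe capture-site selection relative to the adapter-ligated end."""

    site_spacing_per_strand: int = 100
    capture_prob: float = 2.0 / 3.0  # geometric success prob per site
    max_insert: int = 700

    def __post_init__(self):
        if not (0.0 < self.capture_prob <= 1.0):
            raise ValueError("capture_prob must be in (0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    """Provenance of one emitted read pair."""

    pair_id: str
    probe_id: str
    fragment_end: int  # adapter-ligated end position (0-based)
    insert: int  # |probe anchor - fragment adapter end| after any truncation
    alleles: tuple  # variant keys carried by this molecule
    damage_positions: tuple  # reference positions deaminated on the template
    duplicate_of: str | None = None


@dataclass
class _Read:
    """One read in reference-forward representation."""

    chrom: str
    start: int  # aligned start (0-based)
    end: int  # aligned end (half-open)
    reverse: bool
    bases: str  # reference-forward orientation


@dataclass
class SimulatedLibrary:
    """In-memory result of a library simulation."""

    reads1: list = field(default_factory=list)  # _Read, probe-trimmed
    reads2: list = field(default_factory=list)
    fastq1: list = field(default_factory=list)  # (id, seq, qual)
    fastq2: list = field(default_factory=list)
    truth: list = field(default_factory=list)  # TruthRecord
    probes: dict = field(default_factory=dict)  # probe id -> Probe
    reference: dict = field(default_factory=dict)
    variants: list = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.truth)

    def truth_inserts(self) -> np.ndarray:
        return np.array([t.insert for t in self.truth], dtype=int)

    def truth_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair_id": [t.pair_id for t in self.truth],
                "probe_id": [t.probe_id for t in self.truth],
                "fragment_end": [t.fragment_end for t in self.truth],
                "insert": [t.insert for t in self.truth],
                "n_damage": [len(t.damage_positions) for t in self.truth],
                "duplicate_of": [t.duplicate_of or "" for t in self.truth],
            }
        )

    # -- serialization ----------------------------------------------------

    def write_fastq(self, path1, path2) -> None:
        for path, recs in ((path1, self.fastq1), (path2, self.fastq2)):
            if str(path).endswith(".gz"):
                # fixed mtime keeps re-runs byte-identical
                raw = open(path, "wb")
                fh = io.TextIOWrapper(
                    gzip.GzipFile(fileobj=raw, mode="wb", mtime=0))
            else:
                raw = None
                fh = open(path, "wt")
            with fh:
                for rid, seq, qual in recs:
                    fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            if raw is not None:
                raw.close()

    def write_truth_sam(self, path) -> None:
        """Truth alignments (R1 probe-trimmed, starting at the probe anchor).

        Lets downstream QC and calling run without an external aligner, the
        way the assay's own pipeline analyzes probe-trimmed reads.
        """
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": len(seq)}
                   for name, seq in self.reference.items()],
        }
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            tid = {name: i for i, name in enumerate(self.reference)}
            for rec, r1, r2 in zip(self.truth, self.reads1, self.reads2):
                for read, mate, first in ((r1, r2, True), (r2, r1, False)):
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = rec.pair_id
                    a.query_sequence = read.bases
                    a.reference_id = tid[read.chrom]
                    a.reference_start = read.start
                    a.mapping_quality = 60
                    a.cigarstring = f"{len(read.bases)}M"
                    a.flag = (
                        0x1 | 0x2
                        | (0x10 if read.reverse else 0)
                        | (0x20 if mate.reverse else 0)
                        | (0x40 if first else 0x80)
                        | (0x400 if rec.duplicate_of else 0)
                    )
                    a.next_reference_id = tid[mate.chrom]
                    a.next_reference_start = mate.start
                    span = (max(read.end, mate.end)
                            - min(read.start, mate.start))
                    a.template_length = span if read.start <= mate.start else -span
                    a.query_qualities = pysam.qualitystring_to_array(
                        "?" * len(read.bases))
                    a.set_tag("XP", rec.probe_id)
                    a.set_tag("XI", rec.insert)
                    if rec.duplicate_of:
                        a.set_tag("XD", rec.duplicate_of)
                    out.write(a)

    def write_truth_vcf(self, path) -> None:
        write_truth_vcf(self.variants, self.reference, path)


def write_truth_vcf(variants, reference, path) -> None:
    """Write truth variants as a minimal VCF 4.2 with VAF/ORIGIN INFO tags."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in reference.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,'
                 'Description="Truth variant allelic fraction">\n')
        fh.write('##INFO=<ID=ORIGIN,Number=1,Type=String,'
                 'Description="germline or somatic">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"VAF={v.vaf:g};ORIGIN={v.origin}\n"
            )


# ---------------------------------------------------------------------------
# synthetic reference


def make_reference(
    n_genes: int,
    roi_per_gene: int,
    roi_len: int,
    seed: int,
    gc: float = 0.5,
    intergenic: int = 700,
    margin: int = 1500,
    chrom: str = "chr1",
) -> tuple[dict[str, str], list[ROI]]:
    """Generate a random reference with evenly laid-out genes and ROIs.

    Deterministic for a fixed seed. ROIs are placed with generous margins so
    fragments around any probe stay within the chromosome.
    """
    if n_genes <= 0 or roi_per_gene <= 0 or roi_len <= 0:
        raise ValueError("n_genes, roi_per_gene and roi_len must be > 0")
    rng = np.random.default_rng(seed)
    total = margin * 2 + n_genes * roi_per_gene * (roi_len + intergenic)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=total, p=p))
    rois = []
    pos = margin
    for g in range(n_genes):
        gene = f"GENE{g + 1:03d}"
        for _ in range(roi_per_gene):
            rois.append(ROI(chrom, pos, pos + roi_len, gene))
            pos += roi_len + intergenic
    return {chrom: seq}, rois


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    return {name: str(rec[:]) for name, rec in Fasta(str(path)).items()}


# ---------------------------------------------------------------------------
# read simulation


def _apply_errors(bases: list, rng, rate: float) -> None:
    if rate <= 0 or not bases:
        return
    n = rng.binomial(len(bases), rate)
    for i in rng.choice(len(bases), size=n, replace=False) if n else ():
        cur = bases[i]
        options = [b for b in "ACGT" if b != cur]
        bases[i] = options[rng.integers(3)]


def simulate_library(
    reference: dict[str, str],
    probes: list[Probe],
    rois: list[ROI],
    variants: list[VariantSpec] = (),
    cnas: list[CnaSpec] = (),
    fragment_model: FragmentModel | None = None,
    ffpe_model: FfpeModel | None = None,
    capture_model: CaptureModel | None = None,
    depth_target: float = 500.0,
    seed: int = 0,
    n_pairs: int | None = None,
    read_len: int = 150,
    seq_error_rate: float = 1e-3,
    duplicate_rate: float = 0.0,
) -> SimulatedLibrary:
    """Simulate an OS-Seq paired-end library with full truth provenance.

    Every Read 1 begins with its generating probe's sequence at the probe's
    fixed genomic anchor; Read 2 starts at the fragment's adapter-ligated
    end. Per-variant observed alt fractions converge to their truth VAF
    (binomial sampling per molecule); genes under a CnaSpec receive pair
    counts scaled by their copy ratio. Only SNV specs are supported at the
    read level; indel specs belong in the truth VCF and pileup-level
    simulations.
    """
    fragment_model = fragment_model or FragmentModel()
    ffpe_model = ffpe_model or FfpeModel()
    capture_model = capture_model or CaptureModel()
    rng = np.random.default_rng(seed)

    for v in variants:
        if v.kind != "SNV":
            raise ValueError(
                f"read-level simulation supports SNVs only, got {v.kind} "
                f"at {v.chrom}:{v.pos}")
        ref_base = reference[v.chrom][v.pos].upper()
        if ref_base != v.ref.upper():
            raise ValueError(
                f"variant ref {v.ref} at {v.chrom}:{v.pos} does not match "
                f"reference base {ref_base}")

    roi_by_id = {r.roi_id: r for r in rois}
    for p in probes:
        if p.chrom not in reference:
            raise ValueError(f"probe {p.id}: chrom {p.chrom} not in reference")
        if extract_probe_sequence(p, reference) != p.sequence.upper():
            raise ValueError(
                f"probe {p.id} sequence does not match reference at its anchor")

    ratio = {c.gene: c.copy_ratio for c in cnas}
    weights = np.array([
        ratio.get(roi_by_id[p.roi_id].gene, 1.0) if p.roi_id in roi_by_id
        else 1.0
        for p in probes
    ], dtype=float)
    weights /= weights.sum()

    if n_pairs is None:
        # expected aligned bases per pair: both reads cover the extension
        # (probe bases are trimmed), whose analytic mean length is
        # spacing/2 + spacing*(1-p)/p under the capture model
        spacing_ = capture_model.site_spacing_per_strand
        p_ = capture_model.capture_prob
        mean_ins = spacing_ / 2 + spacing_ * (1 - p_) / p_
        mean_probe = float(np.mean([len(p.sequence) for p in probes]))
        per_pair = (min(read_len - mean_probe, mean_ins)
                    + min(read_len, mean_ins))
        total_roi = sum(len(r) for r in rois)
        n_pairs = max(1, int(round(depth_target * total_roi / per_pair)))

    counts = rng.multinomial(n_pairs, weights)

    # per-probe lookup tables: overlapping variants and damage-eligible sites
    spacing = capture_model.site_spacing_per_strand
    horizon = capture_model.max_insert + spacing
    var_by_chrom: dict[str, list[VariantSpec]] = {}
    for v in variants:
        var_by_chrom.setdefault(v.chrom, []).append(v)

    lib = SimulatedLibrary(reference=reference, variants=list(variants),
                           probes={p.id: p for p in probes})
    qual = "?" * read_len  # constant Q30
    pair_n = 0
    deam = ffpe_model.deamination_rate
    repair_on = ffpe_model.repair == "excision_on"

    for p_idx, probe in enumerate(probes):
        n_probe = counts[p_idx]
        if n_probe == 0:
            continue
        chrom_seq = reference[probe.chrom]
        L_p = len(probe.sequence)
        a = probe.anchor_pos
        fwd = probe.strand == "+"
        # extension window attainable from this probe
        if fwd:
            lo, hi = a, min(a + horizon, len(chrom_seq))
        else:
            lo, hi = max(0, a - horizon + 1), a + 1
        region = chrom_seq[lo:hi].upper()
        local_vars = [v for v in var_by_chrom.get(probe.chrom, ())
                      if lo <= v.pos < hi]
        if deam > 0:
            tmpl_base = "G" if fwd else "C"  # template C appears as this
            dmg_sites = np.array(
                [lo + i for i, b in enumerate(region) if b == tmpl_base],
                dtype=int)
        else:
            dmg_sites = np.empty(0, dtype=int)

        frag_lens = np.maximum(
            fragment_model.min_length,
            np.rint(rng.normal(fragment_model.mean_length, fragment_model.sd,
                               size=n_probe)).astype(int))
        offsets = rng.integers(1, spacing + 1, size=n_probe)
        extra = rng.geometric(capture_model.capture_prob, size=n_probe) - 1

        for j in range(n_probe):
            cap = min(frag_lens[j] - L_p, capture_model.max_insert)
            k = extra[j]
            insert = offsets[j] + k * spacing
            while insert > cap and k > 0:
                k -= 1
                insert = offsets[j] + k * spacing
            insert = max(1, min(insert, cap))
            # clip to the chromosome
            insert = min(insert, (hi - a) if fwd else (a - lo + 1))

            # molecule alleles (shared by both reads of the pair)
            alleles = tuple(
                (v.chrom, v.pos, v.alt) for v in local_vars
                if rng.random() < v.vaf)
            # template deamination
            if deam > 0 and dmg_sites.size:
                if fwd:
                    elig = dmg_sites[(dmg_sites >= a) & (dmg_sites < a + insert)]
                else:
                    elig = dmg_sites[(dmg_sites > a - insert) & (dmg_sites <= a)]
                hit = elig[rng.random(elig.size) < deam]
            else:
                hit = np.empty(0, dtype=int)

            damage = ()
            if hit.size:
                if repair_on:
                    # excision breaks the template: synthesis terminates at
                    # the lesion nearest the probe, shortening the insert
                    first = hit.min() if fwd else hit.max()
                    insert = max(1, (first - a) if fwd else (a - first))
                    damage = (int(first),)
                else:
                    damage = tuple(int(x) for x in np.sort(hit))

            if fwd:
                f_end = a + insert  # adapter-ligated end (exclusive)
                ext = list(chrom_seq[a:f_end].upper())
                base0 = a
            else:
                f_end = a - insert + 1  # adapter-ligated end (inclusive)
                ext = list(chrom_seq[f_end:a + 1].upper())
                base0 = f_end
            for (vc, vp, valt) in alleles:
                if base0 <= vp < base0 + len(ext):
                    ext[vp - base0] = valt.upper()
            if not repair_on:
                for d in damage:
                    if base0 <= d < base0 + len(ext):
                        ext[d - base0] = "A" if fwd else "T"

            # aligned reads carry the genomic extension only: synthetic
            # probe bases are removed before analysis, exactly as the
            # assay's pipeline trims them, so pileups never see the
            # reference alleles the probe itself contributes
            r1_len = min(read_len - L_p, insert)

            if fwd:
                r1 = _Read(probe.chrom, a, a + r1_len, False,
                           "".join(ext[:r1_len]))
                r2_start = max(a, f_end - read_len)
                r2 = _Read(probe.chrom, r2_start, f_end, True,
                           "".join(ext[r2_start - a:]))
            else:
                r1 = _Read(probe.chrom, a + 1 - r1_len, a + 1, True,
                           "".join(ext[-r1_len:]) if r1_len else "")
                r2_end = min(a + 1, f_end + read_len)
                r2 = _Read(probe.chrom, f_end, r2_end, False,
                           "".join(ext[:r2_end - f_end]))

            def _emit(duplicate_of=None):
                nonlocal pair_n
                pair_n += 1
                pid = f"pair{pair_n:08d}"
                b1 = list(r1.bases)
                b2 = list(r2.bases)
                _apply_errors(b1, rng, seq_error_rate)
                _apply_errors(b2, rng, seq_error_rate)
                rd1 = _Read(r1.chrom, r1.start, r1.end, r1.reverse, "".join(b1))
                rd2 = _Read(r2.chrom, r2.start, r2.end, r2.reverse, "".join(b2))
                lib.reads1.append(rd1)
                lib.reads2.append(rd2)
                # FASTQ keeps the physical 5'->3' reads: R1 starts with the
                # probe sequence; R2 may read through the extension into the
                # probe footprint (reference bases) when the molecule is
                # shorter than the read length
                fq1 = probe.sequence + ("".join(b1) if fwd
                                        else revcomp("".join(b1)))
                tail_len = min(read_len, insert + L_p) - len(b2)
                if fwd:
                    tail = revcomp(chrom_seq[a - tail_len:a].upper()) \
                        if tail_len > 0 else ""
                    fq2 = revcomp("".join(b2)) + tail
                else:
                    tail = chrom_seq[a + 1:a + 1 + tail_len].upper() \
                        if tail_len > 0 else ""
                    fq2 = "".join(b2) + tail
                lib.fastq1.append((pid, fq1, qual[:len(fq1)]))
                lib.fastq2.append((pid, fq2, qual[:len(fq2)]))
                lib.truth.append(TruthRecord(
                    pair_id=pid, probe_id=probe.id,
                    fragment_end=(f_end if fwd else f_end),
                    insert=int(insert), alleles=alleles,
                    damage_positions=damage, duplicate_of=duplicate_of))
                return pid

            pid = _emit()
            if duplicate_rate > 0 and rng.random() < duplicate_rate:
                _emit(duplicate_of=pid)

    return lib


# ---------------------------------------------------------------------------
# direct coverage-matrix simulation


def simulate_roi_coverage(
    n_genes: int,
    rois_per_gene: int = 16,
    mean_depth: float = 2000.0,
    dispersion: float = 400.0,
    cnas: list[CnaSpec] = (),
    seed: int = 0,
    roi_bias_sd: float = 0.3,
    samples: tuple[str, ...] = ("test", "control"),
    cna_samples: tuple[str, ...] = ("test",),
) -> pd.DataFrame:
    """Simulate a per-ROI read-depth matrix for copy-number calling.

    Depths are negative binomial with mean ``mean_depth`` scaled by each
    gene's copy ratio (in ``cna_samples`` only) and by a lognormal per-ROI
    capture bias shared across samples — the region-specific bias the
    test/control ratio is designed to cancel. ``dispersion`` is the negative
    binomial size parameter (variance = m + m^2/dispersion; ``np.inf`` gives
    the Poisson limit). Deterministic per seed.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = np.random.default_rng(seed)
    ratio = {c.gene: c.copy_ratio for c in cnas}
    genes = [f"GENE{g + 1:03d}" for g in range(n_genes)]
    rows = []
    for gene in genes:
        for r in range(rois_per_gene):
            rows.append((f"{gene}_roi{r + 1}", gene))
    bias = np.exp(rng.normal(0.0, roi_bias_sd, size=len(rows)))
    data = {"roi_id": [r[0] for r in rows], "gene": [r[1] for r in rows]}
    for sample in samples:
        means = np.array([
            mean_depth * (ratio.get(gene, 1.0) if sample in cna_samples else 1.0)
            for _, gene in rows
        ]) * bias
        if np.isinf(dispersion):
            depths = rng.poisson(means)
        else:
            p = dispersion / (dispersion + means)
            depths = rng.negative_binomial(dispersion, p)
        data[sample] = depths
    df = pd.DataFrame(data).set_index("roi_id")
    return df


def write_coverage_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_coverage_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="roi_id")
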