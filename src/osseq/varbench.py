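"""Minimal Bayesian variant calling, somatic filtering, and benchmarking.

The caller is an intentionally small binomial-likelihood model that makes
the toolkit testable end to end; it is not numerically equivalent to the
production callers (GATK, MuTect, RTG) a real pipeline would use.

Germline genotyping compares hom-ref / het / hom-alt binomial read
likelihoods under Hardy-Weinberg priors derived from a per-site germline
allele frequency. Somatic calling uses a two-node tumor/normal network: the
tumor inherits the normal genotype (observed, or imputed from the germline
prior when no normal sample exists) and may additionally incur a de novo
somatic mutation with a small prior; each site is labelled germline,
somatic, or artifact by maximum posterior.

Benchmarking matches normalized (left-aligned, minimally represented)
variants by position and alleles within the ROI intervals (plus flank), and
reports sensitivity, specificity and PPV with the assay's definitions: the
true-negative universe is the count of callable ROI bases minus truth
positions, and specificity defaults to TN/(TN+FN) as the assay defines it
(the conventional TN/(TN+FP) is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam
from scipy.stats import binom

from .panel import ROI

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# domain types


@dataclass
class SitePileup:
    chrom: str
    pos: int  # 0-based
    ref: str
    counts: dict  # allele -> read count

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def alt_allele(self) -> tuple[str, int]:
        """Most supported non-reference allele and its count."""
        best, n = "", 0
        for allele, c in sorted(self.counts.items()):
            if allele != self.ref and c > n:
                best, n = allele, c
        return best, n


@dataclass
class PriorTable:
    """Per-site (or default) germline and somatic priors.

    ``site_priors`` maps (chrom, pos, alt) -> (germline allele frequency,
    somatic prior probability); unknown sites fall back to the defaults.
    """

    default_germline_af: float = 1e-3
    default_somatic_prior: float = 1e-6
    site_priors: dict = field(default_factory=dict)

    def __post_init__(self):
        for p in (self.default_germline_af, self.default_somatic_prior):
            if not (0.0 < p < 1.0):
                raise ValueError("priors must be in (0, 1)")

    def for_site(self, chrom, pos, alt) -> tuple[float, float]:
        return self.site_priors.get(
            (chrom, pos, alt),
            (self.default_germline_af, self.default_somatic_prior))

    @classmethod
    def from_tsv(cls, path, **defaults) -> "PriorTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        site = {
            (str(r.chrom), int(r.pos), str(r.alt)):
                (float(r.germline_af), float(r.somatic_prior))
            for r in df.itertuples()
        }
        return cls(site_priors=site, **defaults)


@dataclass
class VariantCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    status: str  # hom_ref | het | hom_alt | germline | somatic | artifact | no_call
    vaf: float | None
    posterior: float | None
    depth: int
    alt_count: int
    filters: tuple = ()


@dataclass
class BenchmarkResult:
    tp: int
    fn: int
    fp: int
    tn: int | None = None
    sensitivity: float | None = None  # percent
    specificity: float | None = None  # percent
    ppv: float | None = None  # percent


# ---------------------------------------------------------------------------
# genotype likelihoods


def _genotype_loglik(k: int, n: int, error_rate: float) -> dict[str, float]:
    """log P(k alt of n | genotype) with per-read alt probabilities
    e, 1/2 and 1-e for hom-ref, het and hom-alt."""
    return {
        "hom_ref": binom.logpmf(k, n, error_rate),
        "het": binom.logpmf(k, n, 0.5),
        "hom_alt": binom.logpmf(k, n, 1.0 - error_rate),
    }


def call_germline(
    pileup: SitePileup,
    error_rate: float = 1e-3,
    priors: PriorTable | None = None,
) -> VariantCall:
    """Genotype one site by maximum posterior over hom-ref/het/hom-alt."""
    priors = priors or PriorTable()
    n = pileup.depth
    alt, k = pileup.alt_allele()
    if n == 0:
        return VariantCall(pileup.chrom, pileup.pos, pileup.ref, alt,
                           "no_call", None, None, 0, 0)
    f, _ = priors.for_site(pileup.chrom, pileup.pos, alt)
    logprior = {
        "hom_ref": np.log((1 - f) ** 2),
        "het": np.log(2 * f * (1 - f)),
        "hom_alt": np.log(f ** 2),
    }
    loglik = _genotype_loglik(k, n, error_rate)
    logpost = {g: loglik[g] + logprior[g] for g in loglik}
    norm = np.logaddexp.reduce(list(logpost.values()))
    status = max(logpost, key=logpost.get)
    return VariantCall(
        pileup.chrom, pileup.pos, pileup.ref, alt, status,
        vaf=k / n, posterior=float(np.exp(logpost[status] - norm)),
        depth=n, alt_count=k)


def call_somatic(
    tumor: SitePileup,
    normal: SitePileup | None = None,
    priors: PriorTable | None = None,
    error_rate: float = 1e-3,
) -> VariantCall:
    """Label one site germline / somatic / artifact via the tumor/normal
    network. Without a normal pileup the normal genotype is imputed from
    the germline prior alone."""
    priors = priors or PriorTable()
    n_t = tumor.depth
    alt, k_t = tumor.alt_allele()
    if n_t == 0:
        return VariantCall(tumor.chrom, tumor.pos, tumor.ref, alt,
                           "no_call", None, None, 0, 0)
    f, somatic_prior = priors.for_site(tumor.chrom, tumor.pos, alt)
    log_g_prior = {
        "hom_ref": np.log((1 - f) ** 2),
        "het": np.log(2 * f * (1 - f)),
        "hom_alt": np.log(f ** 2),
    }
    if normal is not None and normal.depth > 0:
        k_n = normal.counts.get(alt, 0)
        ll_n = _genotype_loglik(k_n, normal.depth, error_rate)
        log_g = {g: log_g_prior[g] + ll_n[g] for g in log_g_prior}
    else:
        log_g = dict(log_g_prior)
    norm_g = np.logaddexp.reduce(list(log_g.values()))
    log_g = {g: v - norm_g for g, v in log_g.items()}

    ll_t = _genotype_loglik(k_t, n_t, error_rate)
    # germline: tumor carries the inherited het/hom-alt genotype
    log_germline = np.logaddexp(log_g["het"] + ll_t["het"],
                                log_g["hom_alt"] + ll_t["hom_alt"])
    # somatic: normal hom-ref, de novo event with uniform tumor VAF
    # (marginal binomial likelihood integrates to 1/(n+1))
    log_somatic = (log_g["hom_ref"] + np.log(somatic_prior)
                   - np.log(n_t + 1))
    # artifact: normal hom-ref, alt reads explained by sequencing error
    log_artifact = (log_g["hom_ref"] + np.log1p(-somatic_prior)
                    + ll_t["hom_ref"])
    logpost = {"germline": log_germline, "somatic": log_somatic,
               "artifact": log_artifact}
    norm = np.logaddexp.reduce(list(logpost.values()))
    status = max(logpost, key=logpost.get)
    return VariantCall(
        tumor.chrom, tumor.pos, tumor.ref, alt, status,
        vaf=k_t / n_t, posterior=float(np.exp(logpost[status] - norm)),
        depth=n_t, alt_count=k_t)


def filter_somatic_report(
    calls: list[VariantCall], min_depth: int = 40, min_alt_reads: int = 2,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Apply the reporting filter: multiple read support above an overall
    depth floor (default 40X). Returns (kept, removed); removed calls carry
    their failure reasons in ``filters``."""
    kept, removed = [], []
    for c in calls:
        reasons = []
        if c.depth < min_depth:
            reasons.append(f"depth<{min_depth}")
        if c.alt_count < min_alt_reads:
            reasons.append(f"alt_reads<{min_alt_reads}")
        if reasons:
            removed.append(VariantCall(
                c.chrom, c.pos, c.ref, c.alt, c.status, c.vaf, c.posterior,
                c.depth, c.alt_count, tuple(reasons)))
        else:
            kept.append(c)
    return kept, removed


# ---------------------------------------------------------------------------
# pileups over ROIs


class RoiPileups:
    """Per-base allele counts over ROI intervals, built from alignments."""

    def __init__(self, rois: list[ROI], reference: dict[str, str]):
        self.rois = list(rois)
        self.reference = reference
        self._counts = {
            r.roi_id: np.zeros((4, len(r)), dtype=np.int64) for r in rois}
        self._by_chrom: dict[str, list[ROI]] = {}
        for r in rois:
            self._by_chrom.setdefault(r.chrom, []).append(r)

    _BASE_LUT = np.full(256, -1, dtype=np.int8)
    for _i, _b in enumerate(_BASES):
        _BASE_LUT[ord(_b)] = _i
        _BASE_LUT[ord(_b.lower())] = _i
    del _i, _b

    def add_read(self, chrom: str, start: int, bases: str) -> None:
        end = start + len(bases)
        codes = None
        for roi in self._by_chrom.get(chrom, ()):
            lo, hi = max(start, roi.start), min(end, roi.end)
            if lo >= hi:
                continue
            if codes is None:
                codes = self._BASE_LUT[
                    np.frombuffer(bases.encode(), dtype=np.uint8)]
            arr = self._counts[roi.roi_id]
            seg = codes[lo - start:hi - start]
            cols = np.arange(lo - roi.start, hi - roi.start)
            ok = seg >= 0
            np.add.at(arr, (seg[ok], cols[ok]), 1)

    def add_sam(self, path, exclude_duplicates: bool = True) -> None:
        mode = "rb" if str(path).endswith(".bam") else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                if exclude_duplicates and rec.is_duplicate:
                    continue
                self.add_read(rec.reference_name, rec.reference_start,
                              rec.query_sequence.upper())

    def site(self, chrom: str, pos: int) -> SitePileup:
        ref_base = self.reference[chrom][pos].upper()
        counts = {b: 0 for b in _BASES}
        for roi in self._by_chrom.get(chrom, ()):
            if roi.start <= pos < roi.end:
                col = self._counts[roi.roi_id][:, pos - roi.start]
                for i, b in enumerate(_BASES):
                    counts[b] += int(col[i])
                break
        return SitePileup(chrom, pos, ref_base, counts)

    def candidate_sites(self, min_alt_reads: int = 2) -> list[SitePileup]:
        """Sites with at least ``min_alt_reads`` non-reference reads."""
        out = []
        for roi in self.rois:
            arr = self._counts[roi.roi_id]
            refseq = self.reference[roi.chrom][roi.start:roi.end].upper()
            total = arr.sum(axis=0)
            for j in np.nonzero(total)[0]:
                ref_idx = _BASES.find(refseq[j])
                alt_total = total[j] - (arr[ref_idx, j] if ref_idx >= 0 else 0)
                if alt_total >= min_alt_reads:
                    out.append(self.site(roi.chrom, roi.start + int(j)))
        return out

    def callable_bases(self, min_depth: int = 1) -> int:
        return int(sum(
            (self._counts[r.roi_id].sum(axis=0) >= min_depth).sum()
            for r in self.rois))


# ---------------------------------------------------------------------------
# callset comparison


def normalize_variant(chrom, pos, ref, alt, reference=None):
    """Left-align and minimally represent one variant (0-based pos).

    Follows the standard normalization algorithm: trim shared trailing
    bases (extending left from the reference when an allele would empty),
    then trim shared leading bases.
    """
    ref, alt = ref.upper(), alt.upper()
    refseq = reference.get(chrom) if reference else None
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif (ref and alt and ref[-1] == alt[-1]
              and refseq is not None and pos > 0):
            b = refseq[pos - 1].upper()
            ref, alt = b + ref[:-1], b + alt[:-1]
            pos -= 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def _read_vcf_records(path):
    """Yield (chrom, pos0, ref, alt) per alt allele from a VCF."""
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if alt is None or alt == ".":
                    continue
                yield rec.chrom, rec.start, rec.ref, alt


def compare_callsets(
    test_vcf, truth_vcf, rois: list[ROI],
    reference: dict[str, str] | None = None,
    allele_match_mode: bool = True,
) -> BenchmarkResult:
    """Match normalized test calls against truth by position + alleles.

    Restricted to ROI intervals enlarged by each ROI's flank. In allele
    match mode genotypes are ignored (the squash-ploidy convention).
    Returns raw TP/FN/FP counts; combine with :func:`accuracy_metrics` for
    percentages.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    for r in rois:
        intervals.setdefault(r.chrom, []).append(
            (r.start - r.flank, r.end + r.flank))

    def in_roi(chrom, pos):
        return any(lo <= pos < hi for lo, hi in intervals.get(chrom, ()))

    def load(path):
        out = set()
        try:
            for chrom, pos, ref, alt in _read_vcf_records(path):
                key = normalize_variant(chrom, pos, ref, alt, reference)
                if in_roi(key[0], key[1]):
                    out.add(key)
        except (ValueError, OSError) as exc:
            raise ValueError(f"malformed VCF {path}: {exc}") from exc
        return out

    test = load(test_vcf)
    truth = load(truth_vcf)
    tp = len(test & truth)
    return BenchmarkResult(tp=tp, fn=len(truth) - tp, fp=len(test) - tp)


def accuracy_metrics(
    counts: BenchmarkResult,
    tn_universe_bases: int | None = None,
    specificity_formula: str = "as_printed",
) -> BenchmarkResult:
    """Sensitivity/specificity/PPV percentages (one decimal).

    The TN count is the callable ROI bases minus truth positions
    (``tn_universe_bases`` is that universe; TN = universe - TP - FN).
    ``specificity_formula`` is ``"as_printed"`` for TN/(TN+FN) — the
    assay's stated definition — or ``"conventional"`` for TN/(TN+FP).
    """
    tp, fn, fp = counts.tp, counts.fn, counts.fp
    if min(tp, fn, fp) < 0:
        raise ValueError("counts must be >= 0")
    sens = round(100.0 * tp / (tp + fn), 1) if (tp + fn) > 0 else None
    ppv = round(100.0 * tp / (tp + fp), 1) if (tp + fp) > 0 else None
    tn = spec = None
    if tn_universe_bases is not None:
        tn = max(0, tn_universe_bases - (tp + fn))
        denom = tn + (fn if specificity_formula == "as_printed" else fp)
        spec = round(100.0 * tn / denom, 1) if denom > 0 else None
    return BenchmarkResult(tp=tp, fn=fn, fp=fp, tn=tn,
                           sensitivity=sens, specificity=spec, ppv=ppv)


def detected_fraction(tp: int, truth_total: int) -> float:
    """Fraction of truth variants detected, rounded to two decimals."""
    if truth_total <= 0:
        raise ValueError("truth_total must be > 0")
    return round(tp / truth_total, 2)


# ---------------------------------------------------------------------------
# FFPE damage-ratio analysis


def ct_ag_ratio(snvs) -> float | None:
    """Percentage of SNVs that are C>T or G>A (the deamination signature).

    ``snvs`` is an iterable of (ref, alt) pairs or objects with ref/alt
    attributes. Returns None when the set is empty.
    """
    total = ct = 0
    for item in snvs:
        ref, alt = (item if isinstance(item, tuple)
                    else (item.ref, item.alt))
        ref, alt = ref.upper(), alt.upper()
        if len(ref) != 1 or len(alt) != 1 or ref == alt:
            continue
        total += 1
        if (ref, alt) in (("C", "T"), ("G", "A")):
            ct += 1
    if total == 0:
        return None
    return 100.0 * ct / total


def write_calls_vcf(calls: list[VariantCall], reference, path) -> None:
    """Write calls as a minimal VCF 4.2 (status and VAF in INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in reference.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##INFO=<ID=STATUS,Number=1,Type=String,Description="Call status">\n')
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="Alt fraction">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            vaf = f"{c.vaf:.4f}" if c.vaf is not None else "."
            fh.write(f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t"
                     f"STATUS={c.status};VAF={vaf};DP={c.depth}\n")
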