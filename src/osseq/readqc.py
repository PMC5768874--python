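"""Probe-aware read QC and the assay's coverage/uniformity metrics.

Because every Read 1 of an OS-Seq pair starts with the sequence of the probe
that generated it, reads can be attributed to probes by prefix matching, and
a pair is on-target only when its probe is identified, the mate orientation
is consistent with the probe strand, the alignment falls within the probe's
ROI (plus flank), and the insert does not exceed the off-target limit
(default 1.5 kb).

Metrics follow the assay's definitions: coverage is computed over ROI bases
from on-target, non-duplicate pairs; the fold 80 base penalty is the mean
non-zero ROI coverage divided by its 20th percentile (1 = perfectly
uniform); threshold fractions report ROI bases at or above 2X..100X.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .panel import ROI, Probe


@dataclass
class QCConfig:
    quality_floor: int = 28  # Phred; bases strictly below are masked
    off_target_insert: int = 1500  # bp
    coverage_thresholds: tuple = tuple(range(2, 101))  # X
    min_recommended_coverage: int = 200  # X

    def __post_init__(self):
        if self.quality_floor < 0:
            raise ValueError("quality_floor must be >= 0")
        if self.off_target_insert <= 0:
            raise ValueError("off_target_insert must be > 0")


@dataclass
class TaggedPair:
    """A read pair tagged with its generating probe and alignment facts."""

    pair_id: str
    probe_id: str | None
    chrom: str
    r1_start: int
    r1_end: int
    r1_reverse: bool
    r2_start: int
    r2_end: int
    r2_reverse: bool
    insert: int  # R1 anchor to R2 outer end, bp
    on_target: bool = False
    reason: str = ""
    duplicate: bool = False
    proper: bool = True
    sum_qual: int = 0


@dataclass
class QCReport:
    """Per-sample sequencing metrics."""

    n_pairs: int
    on_target_fraction: float
    duplicate_rate: float
    mean_on_target_coverage: float
    fold80: float | None
    coverage_fractions: dict  # threshold X -> fraction of ROI bases
    insert_mean: float | None
    insert_max: int | None

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["coverage_fractions"] = {
            str(k): v for k, v in self.coverage_fractions.items()}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


# ---------------------------------------------------------------------------
# FASTQ pre-processing


def _open(path, mode="rt"):
    return gzip.open(path, mode) if str(path).endswith(".gz") else open(path, mode)


def quality_mask(fastq_in, fastq_out, floor: int = 28) -> int:
    """Mask bases with Phred quality strictly below ``floor`` as N.

    Masking rather than trimming preserves read lengths and pair
    coordinates. Returns the number of reads processed.
    """
    n = 0
    with _open(fastq_in) as fin, _open(fastq_out, "wt") as fout:
        for rid, seq, qual in FastqGeneralIterator(fin):
            if len(seq) != len(qual):
                raise ValueError(f"read {rid}: sequence/quality length mismatch")
            masked = "".join(
                b if (ord(q) - 33) >= floor else "N"
                for b, q in zip(seq, qual))
            fout.write(f"@{rid}\n{masked}\n+\n{qual}\n")
            n += 1
    return n


def subsample_pairs(fq1_in, fq2_in, fq1_out, fq2_out,
                    probability: float, seed: int) -> int:
    """Keep each read pair with the given probability, both mates together.

    Deterministic per seed. Returns the number of pairs kept.
    """
    if not (0.0 <= probability <= 1.0):
        raise ValueError("probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    kept = 0
    with _open(fq1_in) as f1, _open(fq2_in) as f2, \
            _open(fq1_out, "wt") as o1, _open(fq2_out, "wt") as o2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for rec1 in it1:
            try:
                rec2 = next(it2)
            except StopIteration:
                raise ValueError("mate files desynchronized: R2 ended early")
            if rec1[0].split()[0] != rec2[0].split()[0]:
                raise ValueError(
                    f"mate files desynchronized at {rec1[0]} / {rec2[0]}")
            if rng.random() < probability:
                o1.write(f"@{rec1[0]}\n{rec1[1]}\n+\n{rec1[2]}\n")
                o2.write(f"@{rec2[0]}\n{rec2[1]}\n+\n{rec2[2]}\n")
                kept += 1
        if next(it2, None) is not None:
            raise ValueError("mate files desynchronized: R1 ended early")
    return kept


# ---------------------------------------------------------------------------
# probe tagging


class PanelIndex:
    """Prefix index over probe sequences for Read 1 attribution."""

    def __init__(self, probes: list[Probe], mismatch_budget: int = 0):
        if not probes:
            raise ValueError("empty panel")
        self.probes = list(probes)
        self.mismatch_budget = mismatch_budget
        self._by_seq: dict[str, list[str]] = {}
        for p in probes:
            self._by_seq.setdefault(p.sequence.upper(), []).append(p.id)
        self._lengths = sorted({len(p.sequence) for p in probes})

    def tag(self, read1_seq: str) -> str | None:
        """Return the generating probe id, 'ambiguous', or None."""
        seq = read1_seq.upper()
        hits: list[str] = []
        for L in self._lengths:
            hits.extend(self._by_seq.get(seq[:L], ()))
        if not hits and self.mismatch_budget > 0:
            best, best_mm = [], self.mismatch_budget + 1
            for p in self.probes:
                ps = p.sequence.upper()
                prefix = seq[:len(ps)]
                if len(prefix) < len(ps):
                    continue
                mm = sum(1 for x, y in zip(prefix, ps) if x != y)
                if mm < best_mm:
                    best, best_mm = [p.id], mm
                elif mm == best_mm:
                    best.append(p.id)
            if best_mm <= self.mismatch_budget:
                hits = best
        if not hits:
            return None
        if len(set(hits)) > 1:
            return "ambiguous"
        return hits[0]


def probe_tag(read1_seq: str, panel: PanelIndex | list[Probe]) -> str | None:
    index = panel if isinstance(panel, PanelIndex) else PanelIndex(panel)
    return index.tag(read1_seq)


# ---------------------------------------------------------------------------
# on-target classification


def classify_on_target(
    pair: TaggedPair,
    rois_by_id: dict[str, ROI],
    probes_by_id: dict[str, Probe],
    config: QCConfig | None = None,
) -> tuple[bool, str]:
    """Decide on/off-target; the reason records the first failed criterion."""
    config = config or QCConfig()
    if pair.probe_id is None or pair.probe_id == "ambiguous":
        return False, "no_probe" if pair.probe_id is None else "ambiguous_probe"
    probe = probes_by_id.get(pair.probe_id)
    if probe is None:
        return False, "unknown_probe"
    # orientation: a '+' probe primes a forward R1 with a reverse mate
    expected_r1_reverse = probe.strand == "-"
    if pair.r1_reverse != expected_r1_reverse or pair.r2_reverse == pair.r1_reverse:
        return False, "orientation"
    roi = rois_by_id.get(probe.roi_id)
    if roi is None:
        return False, "unknown_roi"
    lo, hi = roi.start - roi.flank, roi.end + roi.flank
    if pair.chrom != roi.chrom or pair.r1_start >= hi or pair.r1_end <= lo:
        return False, "outside_roi"
    if pair.insert > config.off_target_insert:
        return False, "insert>1.5kb"
    return True, "on_target"


def tag_and_classify(pairs, rois, probes, config=None):
    """Classify every pair in place; returns the pairs."""
    rois_by_id = {r.roi_id: r for r in rois}
    probes_by_id = {p.id: p for p in probes}
    for pair in pairs:
        pair.on_target, pair.reason = classify_on_target(
            pair, rois_by_id, probes_by_id, config)
    return pairs


# ---------------------------------------------------------------------------
# duplicates


def mark_duplicates(pairs: list[TaggedPair]) -> list[TaggedPair]:
    """Collapse pairs sharing (probe, fragment end, orientation).

    Read 1's start is fixed by the probe, so duplicates are recognized by
    the randomly generated fragment end alone; the pair with the highest
    summed base quality is retained.
    """
    groups: dict[tuple, list[TaggedPair]] = {}
    for pair in pairs:
        frag_end = pair.r2_end if not pair.r1_reverse else pair.r2_start
        key = (pair.probe_id, frag_end, pair.r1_reverse)
        groups.setdefault(key, []).append(pair)
    for members in groups.values():
        best = max(members, key=lambda p: p.sum_qual)
        for p in members:
            p.duplicate = p is not best
    return pairs


# ---------------------------------------------------------------------------
# coverage metrics


def fold80(per_base_coverage) -> float:
    """Fold 80 base penalty: mean non-zero ROI coverage over its 20th
    percentile. 1 means perfectly uniform coverage; undefined when all
    bases have zero coverage."""
    cov = np.asarray(per_base_coverage, dtype=float)
    nz = np.sort(cov[cov > 0])
    if nz.size == 0:
        raise ValueError("fold80 undefined: all bases have zero coverage")
    rank = max(1, math.ceil(0.2 * nz.size))
    return float(nz.mean() / nz[rank - 1])


def coverage_fractions(per_base_coverage, thresholds) -> dict[int, float]:
    """Fraction of ROI bases at or above each coverage threshold."""
    cov = np.asarray(per_base_coverage, dtype=float)
    if cov.size == 0:
        return {int(t): 0.0 for t in thresholds}
    return {int(t): float((cov >= t).mean()) for t in thresholds}


def coverage_over_rois(
    pairs: list[TaggedPair], rois: list[ROI],
    on_target_only: bool = True, exclude_duplicates: bool = True,
) -> dict[str, np.ndarray]:
    """Per-base coverage arrays over ROI bases from the selected pairs."""
    arrays = {r.roi_id: np.zeros(len(r), dtype=np.int64) for r in rois}
    by_chrom: dict[str, list[ROI]] = {}
    for r in rois:
        by_chrom.setdefault(r.chrom, []).append(r)
    for pair in pairs:
        if on_target_only and not pair.on_target:
            continue
        if exclude_duplicates and pair.duplicate:
            continue
        for roi in by_chrom.get(pair.chrom, ()):
            for s, e in ((pair.r1_start, pair.r1_end),
                         (pair.r2_start, pair.r2_end)):
                lo, hi = max(s, roi.start), min(e, roi.end)
                if lo < hi:
                    arrays[roi.roi_id][lo - roi.start:hi - roi.start] += 1
    return arrays


# ---------------------------------------------------------------------------
# insert statistics


def insert_stats(pairs: list[TaggedPair], bin_width: int = 10) -> dict:
    """Insert-size summary over proper pairs (R1 start to R2 end distance).

    Returns mean, max and a histogram {bin_start: count}; empty input gives
    an empty report rather than an error.
    """
    inserts = [p.insert for p in pairs if p.proper]
    if not inserts:
        return {"n": 0, "mean": None, "max": None, "histogram": {}}
    arr = np.array(inserts)
    hist: dict[int, int] = {}
    for v in arr:
        b = int(v // bin_width) * bin_width
        hist[b] = hist.get(b, 0) + 1
    return {"n": int(arr.size), "mean": float(arr.mean()),
            "max": int(arr.max()), "histogram": dict(sorted(hist.items()))}


# ---------------------------------------------------------------------------
# SAM ingestion and report


def pairs_from_sam(path) -> list[TaggedPair]:
    """Read paired alignments (SAM/BAM) into TaggedPair records.

    The probe id is taken from the XP tag when present (the tag the
    simulator and the tagging step write); pairs lacking both mates are
    skipped.
    """
    first: dict[str, pysam.AlignedSegment] = {}
    second: dict[str, pysam.AlignedSegment] = {}
    mode = "rb" if str(path).endswith(".bam") else "r"
    pairs = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_name is None:
                continue
            (first if rec.is_read1 else second)[rec.query_name] = rec
    for name, r1 in first.items():
        r2 = second.get(name)
        if r2 is None:
            continue
        if not r1.is_reverse:
            insert = r2.reference_end - r1.reference_start
        else:
            insert = r1.reference_end - r2.reference_start
        qsum = int(sum(r1.query_qualities or ()) + sum(r2.query_qualities or ()))
        pairs.append(TaggedPair(
            pair_id=name,
            probe_id=r1.get_tag("XP") if r1.has_tag("XP") else None,
            chrom=r1.reference_name,
            r1_start=r1.reference_start, r1_end=r1.reference_end,
            r1_reverse=r1.is_reverse,
            r2_start=r2.reference_start, r2_end=r2.reference_end,
            r2_reverse=r2.is_reverse,
            insert=int(insert),
            proper=r1.is_proper_pair,
            sum_qual=qsum,
        ))
    pairs.sort(key=lambda p: p.pair_id)
    return pairs


def qc_report(
    pairs: list[TaggedPair], rois: list[ROI], probes: list[Probe],
    config: QCConfig | None = None,
) -> QCReport:
    """Full QC: classify, deduplicate, and compute the assay's metrics.

    The on-target denominator is all aligned pairs, including those whose
    probe attribution is ambiguous.
    """
    config = config or QCConfig()
    tag_and_classify(pairs, rois, probes, config)
    mark_duplicates(pairs)
    n = len(pairs)
    on = [p for p in pairs if p.on_target]
    dups = sum(1 for p in pairs if p.duplicate)
    cov = coverage_over_rois(pairs, rois)
    allcov = (np.concatenate(list(cov.values()))
              if cov else np.zeros(0, dtype=np.int64))
    try:
        f80 = fold80(allcov)
    except ValueError:
        f80 = None
    ins = insert_stats(on)
    return QCReport(
        n_pairs=n,
        on_target_fraction=(len(on) / n) if n else 0.0,
        duplicate_rate=(dups / n) if n else 0.0,
        mean_on_target_coverage=float(allcov.mean()) if allcov.size else 0.0,
        fold80=f80,
        coverage_fractions=coverage_fractions(
            allcov, config.coverage_thresholds),
        insert_mean=ins["mean"],
        insert_max=ins["max"],
    )
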