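"""Primer-probe panel design.

An OS-Seq primer-probe anneals to adapter-ligated single-stranded DNA and is
extended by polymerase, so Read 1 of every pair begins at the probe's fixed
genomic position. Panels tile probes across both strands of each region of
interest (ROI) at a target density (default one probe every 100 bp per
strand). Candidate probes are scored with a weighted sum of bounded
components covering intrinsic sequence features (GC content, melting
temperature, homopolymers, hairpin/self-dimer propensity) and genomic
features (masked SNP overlap, genome-wide k-mer specificity, position
relative to the ROI, coverage gained); candidates below a score threshold
are discarded and the highest-scoring candidate per tiling window is
selected.

Coordinates are 0-based half-open (BED convention) throughout. A probe's
``anchor_pos`` is the position of the first template base copied by
extension: a ``+`` probe occupies ``[anchor - L, anchor)`` and extends
rightward; a ``-`` probe occupies ``[anchor + 1, anchor + 1 + L)`` and
extends leftward.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict

import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = re.compile(r"^[ACGT]+$")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_acgt(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    m = re.search(r"[^ACGT]", seq)
    if m:
        raise ValueError(
            f"non-ACGT character {seq[m.start()]!r} at position {m.start()}"
        )


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ROI:
    """A targeted region of interest, 0-based half-open."""

    chrom: str
    start: int
    end: int
    gene: str
    flank: int = 50  # bp added per side for variant-calling intervals

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"ROI {self.gene}: end must exceed start")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    @property
    def roi_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Probe:
    """A designed primer-probe with fixed genomic anchor."""

    id: str
    chrom: str
    anchor_pos: int  # first extended template position (0-based)
    strand: str  # '+' or '-'
    sequence: str  # 5'->3'
    roi_id: str
    score: float
    tm: float

    def footprint(self) -> tuple[int, int]:
        """Genomic interval occupied by the annealed probe (half-open)."""
        L = len(self.sequence)
        if self.strand == "+":
            return self.anchor_pos - L, self.anchor_pos
        return self.anchor_pos + 1, self.anchor_pos + 1 + L


@dataclass
class DesignConfig:
    """Tunable panel-design parameters.

    ``weights`` maps component names to non-negative weights; components are
    each normalized to [0, 1] before weighting.
    """

    target_spacing_per_strand: int = 100  # bp between probes on one strand
    probe_len: tuple[int, int] = (23, 27)  # [min, max] nt
    tm_window: tuple[float, float] = (58.0, 68.0)  # degC
    gc_window: tuple[float, float] = (0.35, 0.65)  # fraction
    max_homopolymer: int = 5  # bp
    max_hairpin_stem: int = 5  # bp of self-complementary stem
    max_self_dimer: int = 8  # bp of self-complementary run
    snp_mask: set = field(default_factory=set)  # {(chrom, pos)}
    specificity_k: int = 16
    score_threshold: float = 5.0
    anchor_step: int = 1  # candidate anchor stride within a window
    length_step: int = 2
    read_len: int = 150  # extension horizon used by positional components
    weights: dict = field(default_factory=lambda: {
        "gc": 1.0, "tm": 1.0, "homopolymer": 1.0, "hairpin": 1.0,
        "self_dimer": 1.0, "snp": 1.0, "specificity": 1.0,
        "position": 1.0, "coverage_gain": 1.0,
    })

    def __post_init__(self):
        if self.target_spacing_per_strand <= 0:
            raise ValueError("spacing must be > 0")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be >= 0")


@dataclass(frozen=True)
class CoverageGap:
    """A tiling window for which no candidate passed the score threshold."""

    roi_id: str
    strand: str
    window_start: int
    window_end: int
    reason: str


# ---------------------------------------------------------------------------
# melting temperature


def compute_tm(sequence: str, salt_params: dict | None = None) -> float:
    """Nearest-neighbor melting temperature in degC.

    Uses the SantaLucia unified dinucleotide table with a configurable
    monovalent/divalent salt correction. Deterministic; monotone in GC
    content at fixed length.
    """
    _validate_acgt(sequence)
    kwargs = dict(Na=50, Mg=2.0, dNTPs=0.8, saltcorr=7, dnac1=250, dnac2=0)
    if salt_params:
        kwargs.update(salt_params)
    return float(_mt.Tm_NN(sequence, nn_table=_mt.DNA_NN3, **kwargs))


# ---------------------------------------------------------------------------
# k-mer specificity index


class GenomeIndex:
    """Exact k-mer multiplicity over both strands of a genome.

    ``genome`` maps sequence name -> sequence string. Counting is exact and
    case-insensitive; a probe's 3'-terminal k-mer occurring more than once
    genome-wide marks it non-specific.
    """

    def __init__(self, genome: dict[str, str], k: int = 16):
        self.k = k
        counts: dict[str, int] = {}
        for seq in genome.values():
            s = seq.upper()
            for i in range(len(s) - k + 1):
                kmer = s[i:i + k]
                counts[kmer] = counts.get(kmer, 0) + 1
        self._counts = counts

    def occurrences(self, kmer: str) -> int:
        kmer = kmer.upper()
        return self._counts.get(kmer, 0) + self._counts.get(revcomp(kmer), 0)


# ---------------------------------------------------------------------------
# scoring


def _max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _longest_complementary_run(a: str, b: str) -> int:
    """Longest contiguous stretch of ``a`` that can anneal to ``b``.

    Equivalent to the longest common substring of ``a`` and revcomp(b).
    """
    rb = revcomp(b)
    n, m = len(a), len(rb)
    best = 0
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == rb[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def _window_component(value: float, lo: float, hi: float, margin: float) -> float:
    """1 inside [lo, hi], linear falloff to 0 over ``margin`` outside."""
    if lo <= value <= hi:
        return 1.0
    dist = (lo - value) if value < lo else (value - hi)
    return max(0.0, 1.0 - dist / margin)


def _excess_penalty(run: int, allowed: int) -> float:
    """1 when run <= allowed, then linear to 0 once run reaches 2x allowed."""
    if run <= allowed:
        return 1.0
    return max(0.0, 1.0 - (run - allowed) / max(allowed, 1))


def score_candidate(
    candidate: Probe,
    config: DesignConfig,
    genome_index: GenomeIndex | None = None,
    roi: ROI | None = None,
    covered: set | None = None,
) -> tuple[float, dict[str, float]]:
    """Score a candidate probe; returns (total, per-component breakdown).

    Components are each in [0, 1]; the total is their weighted sum.
    Degenerate candidates (non-ACGT) score 0. ``covered`` is the set of
    ROI positions already covered by previously selected probes and feeds
    the coverage-gain component during greedy selection.
    """
    seq = candidate.sequence.upper()
    if not seq or not _VALID.match(seq):
        return 0.0, {k: 0.0 for k in config.weights}

    comp: dict[str, float] = {}
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    comp["gc"] = _window_component(gc, *config.gc_window, margin=0.15)
    comp["tm"] = _window_component(candidate.tm, *config.tm_window, margin=5.0)
    comp["homopolymer"] = _excess_penalty(
        _max_homopolymer_run(seq), config.max_homopolymer)
    # hairpin: a stem forms between two parts of the same molecule
    comp["hairpin"] = _excess_penalty(
        _longest_complementary_run(seq, seq), config.max_hairpin_stem)
    comp["self_dimer"] = _excess_penalty(
        _longest_complementary_run(seq, seq), config.max_self_dimer)

    fp_start, fp_end = candidate.footprint()
    overlaps_snp = any(
        (candidate.chrom, p) in config.snp_mask for p in range(fp_start, fp_end)
    ) if config.snp_mask else False
    comp["snp"] = 0.0 if overlaps_snp else 1.0

    if genome_index is not None:
        tail = seq[-genome_index.k:]
        occ = genome_index.occurrences(tail)
        comp["specificity"] = 1.0 if occ <= 1 else 1.0 / occ
    else:
        comp["specificity"] = 1.0

    # extension window: bases the probe's Read 1 is expected to cover
    ext = config.read_len - len(seq)
    if candidate.strand == "+":
        win = range(candidate.anchor_pos, candidate.anchor_pos + ext)
    else:
        win = range(candidate.anchor_pos - ext + 1, candidate.anchor_pos + 1)
    if roi is not None and ext > 0:
        inside = [p for p in win if roi.start <= p < roi.end]
        comp["position"] = len(inside) / ext
        if covered is not None and inside:
            gained = sum(1 for p in inside if p not in covered)
            comp["coverage_gain"] = gained / len(inside)
        else:
            comp["coverage_gain"] = 1.0
    else:
        comp["position"] = 1.0
        comp["coverage_gain"] = 1.0

    total = sum(config.weights.get(k, 0.0) * v for k, v in comp.items())
    return total, comp


# ---------------------------------------------------------------------------
# pool interactions


def _three_prime_tail_anneal(a: str, b: str) -> int:
    """Longest 3'-terminal tail of ``a`` that anneals to a stretch of ``b``."""
    best = 0
    for t in range(1, min(len(a), len(b)) + 1):
        if revcomp(a[-t:]) in b:
            best = t
        # longer tails may still match elsewhere; keep scanning
    return best


def check_pool_interactions(
    probes: list[Probe], min_run: int = 6
) -> list[tuple[str, str]]:
    """Flag probe pairs whose 3'-end complementarity reaches ``min_run`` bp.

    A 3' tail of one probe annealing to the other can prime extension in the
    pool (primer-dimer). Symmetric: flag(a, b) iff flag(b, a).
    """
    if len(probes) < 2:
        raise ValueError("need at least 2 probes to evaluate a pool")
    flagged = []
    for i in range(len(probes)):
        for j in range(i + 1, len(probes)):
            a, b = probes[i], probes[j]
            run = max(
                _three_prime_tail_anneal(a.sequence.upper(), b.sequence.upper()),
                _three_prime_tail_anneal(b.sequence.upper(), a.sequence.upper()),
            )
            if run >= min_run:
                flagged.append((a.id, b.id))
    return flagged


# ---------------------------------------------------------------------------
# panel design


def _candidate_probes(roi, strand, site, genome_seq, chrom, config):
    """Enumerate candidate probes for one tiling window, deterministically."""
    half = config.target_spacing_per_strand // 2
    out = []
    lmin, lmax = config.probe_len
    for anchor in range(site - half, site + half, config.anchor_step):
        for L in range(lmin, lmax + 1, config.length_step):
            if strand == "+":
                s, e = anchor - L, anchor
            else:
                s, e = anchor + 1, anchor + 1 + L
            if s < 0 or e > len(genome_seq):
                continue
            raw = genome_seq[s:e].upper()
            if not _VALID.match(raw):
                continue
            # extension must run through callable sequence: a probe whose
            # read window contains N cannot contribute ROI coverage
            ext = config.read_len - L
            if strand == "+":
                win = genome_seq[anchor:min(anchor + ext, len(genome_seq))]
            else:
                win = genome_seq[max(0, anchor - ext + 1):anchor + 1]
            if not win or not _VALID.match(win.upper()):
                continue
            seq = raw if strand == "+" else revcomp(raw)
            try:
                tm = compute_tm(seq)
            except ValueError:
                continue
            out.append(Probe(
                id=f"cand_{chrom}_{anchor}_{strand}_{L}", chrom=chrom,
                anchor_pos=anchor, strand=strand, sequence=seq,
                roi_id=roi.roi_id, score=0.0, tm=tm,
            ))
    return out


def design_panel(
    rois: list[ROI],
    genome: dict[str, str],
    config: DesignConfig | None = None,
    genome_index: GenomeIndex | None = None,
) -> tuple[list[Probe], list[CoverageGap]]:
    """Greedily select the highest-scoring probe per tiling window per strand.

    Windows of ``target_spacing_per_strand`` bp tile each ROI on both
    strands; within a window every anchor/length combination is scored and
    the best candidate at or above ``score_threshold`` is selected
    (tie-break: leftmost anchor, then '+' strand — fully deterministic).
    Windows with no passing candidate are recorded as coverage gaps.
    """
    config = config or DesignConfig()
    if genome_index is None:
        genome_index = GenomeIndex(genome, k=config.specificity_k)
    selected: list[Probe] = []
    gaps: list[CoverageGap] = []
    n = 0
    for roi in rois:
        if roi.chrom not in genome:
            raise ValueError(f"ROI chrom {roi.chrom} absent from genome")
        if roi.end > len(genome[roi.chrom]):
            raise ValueError(f"ROI {roi.roi_id} exceeds {roi.chrom} bounds")
        seq = genome[roi.chrom]
        covered: set[int] = set()
        spacing = config.target_spacing_per_strand
        lmin = config.probe_len[0]
        if len(roi) < lmin:
            gaps.append(CoverageGap(roi.roi_id, "*", roi.start, roi.end,
                                    "ROI shorter than minimum probe length"))
            continue
        for strand in ("+", "-"):
            if strand == "+":
                sites = list(range(roi.start, roi.end, spacing))
            else:
                sites = list(range(roi.end - 1, roi.start - 1, -spacing))
            for site in sites:
                cands = _candidate_probes(roi, strand, site, seq, roi.chrom,
                                          config)
                best = None
                for c in cands:
                    total, _ = score_candidate(c, config, genome_index, roi,
                                               covered)
                    if total < config.score_threshold:
                        continue
                    key = (-total, c.anchor_pos, 0 if c.strand == "+" else 1)
                    if best is None or key < best[0]:
                        best = (key, c, total)
                if best is None:
                    half = spacing // 2
                    gaps.append(CoverageGap(
                        roi.roi_id, strand, site - half, site + half,
                        "no candidate at or above score threshold"))
                    continue
                _, c, total = best
                n += 1
                probe = Probe(
                    id=f"P{n:05d}", chrom=c.chrom, anchor_pos=c.anchor_pos,
                    strand=c.strand, sequence=c.sequence, roi_id=c.roi_id,
                    score=round(total, 4), tm=round(c.tm, 2),
                )
                selected.append(probe)
                ext = config.read_len - len(c.sequence)
                if strand == "+":
                    covered.update(range(c.anchor_pos, c.anchor_pos + ext))
                else:
                    covered.update(range(c.anchor_pos - ext + 1,
                                         c.anchor_pos + 1))
    return selected, gaps


# ---------------------------------------------------------------------------
# I/O


def read_rois_bed(path, flank: int = 50) -> list[ROI]:
    """Read a 4+ column BED (chrom, start, end, gene) into ROI records."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "gene"])
    return [ROI(r.chrom, int(r.start), int(r.end), str(r.gene), flank)
            for r in df.itertuples()]


def write_rois_bed(rois: list[ROI], path) -> None:
    with open(path, "w") as fh:
        for r in rois:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\n")


PANEL_COLUMNS = ["id", "chrom", "anchor_pos", "strand", "sequence",
                 "roi_id", "score", "tm"]


def write_panel_tsv(probes: list[Probe], path) -> None:
    """The probe metadata file consumed by read QC."""
    df = pd.DataFrame([asdict(p) for p in probes], columns=PANEL_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path) -> list[Probe]:
    df = pd.read_csv(path, sep="\t")
    return [Probe(str(r.id), str(r.chrom), int(r.anchor_pos), str(r.strand),
                  str(r.sequence), str(r.roi_id), float(r.score), float(r.tm))
            for r in df.itertuples()]


def write_panel_fasta(probes: list[Probe], path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f">{p.id}\n{p.sequence}\n")


def extract_probe_sequence(probe: Probe, genome: dict[str, str]) -> str:
    """Re-extract a probe's sequence from the reference at its anchor."""
    s, e = probe.footprint()
    raw = genome[probe.chrom][s:e].upper()
    return raw if probe.strand == "+" else revcomp(raw)
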