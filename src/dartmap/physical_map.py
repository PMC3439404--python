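"""Probe-to-genome alignment post-processing and a naive aligner.

Alignment hits (from an external aligner via SAM, or from the built-in
seed-and-extend aligner at synthetic scale) are thresholded, reduced to
at most two retained hits per probe, and classified into placement
categories: a unique locus (single hit, or a second hit overlapping the
same locus), a proximal tandem duplication (two hits on one scaffold
separated by < 1 kb), a distal (1-10 kb) or far (> 10 kb) same-scaffold
pair, or a multi-chromosome placement.  Probes retaining more than two
hits within the score band are "unsuccessfully mapped" (ambiguous); their
frequency among all evaluated probes is the mapping error rate.

Scores use the affine-gap scheme score = a*matches - b*mismatches -
sum(q + r*gaplen) with defaults a=1, b=3, q=5, r=2.  The retention band
threshold T is twice the median of 5.5*ln(L) over the probe lengths L
(natural log), rounded up - T=70 at the reference median probe length of
534 bp.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .synthetic_data import SyntheticGenome, revcomp

UNMAPPED = "unmapped"
UNIQUE_LOCUS = "unique_locus"
TANDEM_PROXIMAL = "tandem_proximal"
SAME_SCAFFOLD_DISTAL = "same_scaffold_distal"
SAME_SCAFFOLD_FAR = "same_scaffold_far"
MULTI_CHROMOSOME = "multi_chromosome"
MULTI_WITH_UNANCHORED = "multi_with_unanchored"
AMBIGUOUS = "ambiguous"

#: distance class boundaries (strict inequalities on the hit gap)
TANDEM_MAX_BP = 1_000
FAR_MIN_BP = 10_000


@dataclass(frozen=True)
class AlignmentHit:
    probe_id: str
    scaffold_id: str
    start: int  # 0-based half-open
    end: int
    strand: str
    score: float
    is_main_scaffold: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("hit interval must satisfy start < end")
        if self.score < 0:
            raise ValueError("hit score must be >= 0")


@dataclass
class ScoringParams:
    match_award: float = 1.0
    mismatch_penalty: float = 3.0
    gap_open: float = 5.0
    gap_extend: float = 2.0
    threshold_t: float | None = None  # computed from probe lengths if None

    def __post_init__(self) -> None:
        for name in ("match_award", "mismatch_penalty", "gap_open", "gap_extend"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ProbePlacement:
    probe_id: str
    status: str
    primary_hit: AlignmentHit | None = None
    secondary_hit: AlignmentHit | None = None
    inter_hit_distance: int | None = None
    n_retained: int = 0


def compute_threshold(probe_lengths: list[int] | np.ndarray) -> int:
    """Retention band T = ceil(2 * median(5.5 ln L)) over probe lengths."""
    lengths = np.asarray(probe_lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("no probe lengths")
    if np.any(lengths <= 1):
        raise ValueError("probe lengths must exceed 1")
    return math.ceil(2.0 * float(np.median(5.5 * np.log(lengths))))


def retain_hits(hits: list[AlignmentHit], threshold_t: float) -> list[AlignmentHit]:
    """Best hit plus any hit scoring within T of it, sorted by score.

    Idempotent; may return more than two hits, in which case the probe's
    placement is ambiguous (an unsuccessful mapping).
    """
    if not hits:
        return []
    ranked = sorted(hits, key=lambda h: (-h.score, h.scaffold_id, h.start))
    best = ranked[0].score
    return [h for h in ranked if h.score >= best - threshold_t]


def _hit_gap(a: AlignmentHit, b: AlignmentHit) -> int:
    """Gap between nearest interval ends; negative means overlap."""
    if a.start > b.start:
        a, b = b, a
    return b.start - a.end


def classify_placement(retained: list[AlignmentHit], probe_id: str | None = None) -> ProbePlacement:
    """Classify at most two retained hits into a placement category."""
    if len(retained) > 2:
        raise ValueError(
            "more than two retained hits; reduce through retain_hits first"
        )
    if not retained:
        return ProbePlacement(probe_id=probe_id or "", status=UNMAPPED)
    pid = probe_id or retained[0].probe_id
    primary = retained[0]
    if len(retained) == 1:
        return ProbePlacement(pid, UNIQUE_LOCUS, primary, n_retained=1)
    secondary = retained[1]
    if primary.scaffold_id == secondary.scaffold_id:
        gap = _hit_gap(primary, secondary)
        if gap <= 0:  # overlapping: same locus
            return ProbePlacement(pid, UNIQUE_LOCUS, primary, secondary, None, 2)
        if gap < TANDEM_MAX_BP:
            status = TANDEM_PROXIMAL
        elif gap > FAR_MIN_BP:
            status = SAME_SCAFFOLD_FAR
        else:
            status = SAME_SCAFFOLD_DISTAL
        return ProbePlacement(pid, status, primary, secondary, gap, 2)
    status = (
        MULTI_CHROMOSOME
        if primary.is_main_scaffold and secondary.is_main_scaffold
        else MULTI_WITH_UNANCHORED
    )
    return ProbePlacement(pid, status, primary, secondary, None, 2)


def place_probe(
    hits: list[AlignmentHit], threshold_t: float, probe_id: str | None = None
) -> ProbePlacement:
    """Threshold, retain and classify one probe's hit list."""
    retained = retain_hits(hits, threshold_t)
    if len(retained) > 2:
        pid = probe_id or retained[0].probe_id
        return ProbePlacement(
            pid, AMBIGUOUS, retained[0], retained[1], n_retained=len(retained)
        )
    return classify_placement(retained, probe_id=probe_id)


def mapping_reliability(placements: list[ProbePlacement]) -> tuple[float, float]:
    """(error rate, reliability) over evaluated (non-unmapped) probes.

    The error rate is the fraction of unsuccessfully mapped probes (more
    than two retained hits), reported to 3 decimal places.
    """
    evaluated = [p for p in placements if p.status != UNMAPPED]
    if not evaluated:
        raise ValueError("no evaluated placements")
    n_ambiguous = sum(1 for p in evaluated if p.status == AMBIGUOUS)
    rate = round(n_ambiguous / len(evaluated), 3)
    return rate, 1.0 - rate


# ---------------------------------------------------------------------------
# naive seed-and-extend aligner


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int64)
    for base, code in zip(b"ACGT", range(4)):
        out[arr == base] = code
    return out


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-mer; -1 where any base is ambiguous."""
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    n = codes.size - k + 1
    vals = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        vals = vals * 4 + np.where(window >= 0, window, 0)
        bad |= window < 0
    vals[bad] = -1
    return vals


class GenomeIndex:
    """Sorted exact k-mer index over a set of scaffolds."""

    def __init__(self, sequences: dict[str, str], k: int = 15):
        self.k = k
        self.names = list(sequences)
        self.seqs = {n: sequences[n].upper() for n in self.names}
        offsets = {}
        pos = 0
        chunks = []
        for name in self.names:
            offsets[name] = pos
            codes = _encode(self.seqs[name])
            chunks.append(_kmer_codes(codes, k))
            pos += len(self.seqs[name])
        self.offsets = offsets
        self.starts = np.array([offsets[n] for n in self.names])
        self.lengths = np.array([len(self.seqs[n]) for n in self.names])
        kmers = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
        positions = np.concatenate(
            [
                np.arange(c.size, dtype=np.int64) + offsets[n]
                for n, c in zip(self.names, chunks)
            ]
        ) if chunks else np.empty(0, dtype=np.int64)
        keep = kmers >= 0
        order = np.argsort(kmers[keep], kind="stable")
        self.sorted_kmers = kmers[keep][order]
        self.sorted_positions = positions[keep][order]

    def scaffold_of(self, global_pos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.starts, global_pos, side="right")) - 1
        return self.names[i], global_pos - int(self.starts[i])

    def lookup(self, kmer_codes: np.ndarray, cap_per_kmer: int = 64):
        """Yield (probe_offset, global_position) seed matches."""
        lo = np.searchsorted(self.sorted_kmers, kmer_codes, side="left")
        hi = np.searchsorted(self.sorted_kmers, kmer_codes, side="right")
        for qpos in range(kmer_codes.size):
            if kmer_codes[qpos] < 0:
                continue
            span = hi[qpos] - lo[qpos]
            if span == 0 or span > cap_per_kmer:
                continue
            for gpos in self.sorted_positions[lo[qpos] : hi[qpos]]:
                yield qpos, int(gpos)


def _make_aligner(params: ScoringParams):
    from Bio.Align import PairwiseAligner

    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match_award
    aligner.mismatch_score = -params.mismatch_penalty
    # first gap base costs q + r, each further base r
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def naive_align(
    probe_id: str,
    probe_seq: str,
    index: GenomeIndex,
    params: ScoringParams | None = None,
    min_score: float = 0.0,
    main_scaffolds: set[str] | None = None,
    max_windows: int = 20,
) -> list[AlignmentHit]:
    """Seed-and-extend local alignment of one probe against an indexed genome.

    Seed k-mer matches are clustered by scaffold and diagonal; each
    candidate window is extended with affine-gap local alignment.  Hits
    scoring below ``min_score`` are discarded; overlapping hits keep the
    best scorer.  Probes shorter than the index k are unmappable.
    """
    params = params or ScoringParams()
    if len(probe_seq) < index.k:
        return []
    hits: list[AlignmentHit] = []
    aligner = _make_aligner(params)
    for strand, seq in (("+", probe_seq.upper()), ("-", revcomp(probe_seq.upper()))):
        seeds = defaultdict(list)  # (scaffold idx, diag bin) -> diag positions
        codes = _kmer_codes(_encode(seq), index.k)
        for qpos, gpos in index.lookup(codes):
            sc = int(np.searchsorted(index.starts, gpos, side="right")) - 1
            diag = gpos - int(index.starts[sc]) - qpos
            seeds[(sc, diag // 100)].append(diag)
        merged: dict[tuple[int, int], list[int]] = {}
        for (sc, dbin), diags in seeds.items():
            anchor = (sc, dbin - 1)
            if anchor in merged:
                merged[anchor].extend(diags)
            else:
                merged[(sc, dbin)] = list(diags)
        windows = sorted(
            merged.items(), key=lambda kv: -len(kv[1])
        )[:max_windows]
        for (sc, _), diags in windows:
            name = index.names[sc]
            target = index.seqs[name]
            lo = max(0, min(diags) - 30)
            hi = min(len(target), max(diags) + len(seq) + 30)
            window = target[lo:hi]
            alignments = aligner.align(seq, window)
            if not len(alignments):
                continue
            best = alignments[0]
            score = float(best.score)
            if score < min_score:
                continue
            tstart = int(best.aligned[1][0][0]) + lo
            tend = int(best.aligned[1][-1][1]) + lo
            hits.append(
                AlignmentHit(
                    probe_id=probe_id,
                    scaffold_id=name,
                    start=tstart,
                    end=tend,
                    strand=strand,
                    score=score,
                    is_main_scaffold=(
                        name in main_scaffolds if main_scaffolds is not None else True
                    ),
                )
            )
    # deduplicate overlapping hits on the same scaffold, keep the best
    hits.sort(key=lambda h: -h.score)
    kept: list[AlignmentHit] = []
    for h in hits:
        if any(
            k.scaffold_id == h.scaffold_id and _hit_gap(k, h) <= 0 for k in kept
        ):
            continue
        kept.append(h)
    return kept


def align_probes(
    probes: dict[str, str],
    genome: SyntheticGenome | dict[str, str],
    params: ScoringParams | None = None,
    k: int = 15,
    threshold_t: float | None = None,
) -> dict[str, list[AlignmentHit]]:
    """Align a probe set to a genome; hits below T are discarded."""
    params = params or ScoringParams()
    if isinstance(genome, SyntheticGenome):
        sequences = genome.sequences
        main = set(genome.chromosomes)
    else:
        sequences = genome
        main = set(genome)
    if threshold_t is None:
        threshold_t = params.threshold_t
    if threshold_t is None:
        threshold_t = compute_threshold([len(s) for s in probes.values()])
    index = GenomeIndex(sequences, k=k)
    return {
        pid: naive_align(
            pid, seq, index, params, min_score=threshold_t, main_scaffolds=main
        )
        for pid, seq in probes.items()
    }


def place_probes(
    hits_by_probe: dict[str, list[AlignmentHit]], threshold_t: float
) -> list[ProbePlacement]:
    return [
        place_probe(hits, threshold_t, probe_id=pid)
        for pid, hits in hits_by_probe.items()
    ]


def read_sam_hits(
    path: str, main_scaffolds: set[str] | None = None
) -> dict[str, list[AlignmentHit]]:
    """Load hits from SAM: primary and secondary alignments with AS scores."""
    import pysam

    hits: dict[str, list[AlignmentHit]] = defaultdict(list)
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_supplementary:
                continue
            score = float(read.get_tag("AS")) if read.has_tag("AS") else 0.0
            name = sam.get_reference_name(read.reference_id)
            hits[read.query_name].append(
                AlignmentHit(
                    probe_id=read.query_name,
                    scaffold_id=name,
                    start=int(read.reference_start),
                    end=int(read.reference_end),
                    strand="-" if read.is_reverse else "+",
                    score=score,
                    is_main_scaffold=(
                        name in main_scaffolds if main_scaffolds is not None else True
                    ),
                )
            )
    return dict(hits)
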