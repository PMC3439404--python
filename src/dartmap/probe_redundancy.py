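"""Probe-sequence redundancy clustering and unique-locus accounting.

Array probes are cloned genomic inserts, and distinct clones frequently
sample the same locus.  The locus count behind an array is estimated by
clustering the probe sequences under a set of assembly-style stringency
presets (A1 most stringent to A4 most liberal) and counting singletons
plus multi-sequence clusters.

Candidate probe pairs are found through shared exact words (k-mer index),
verified by pairwise alignment (edit-distance alignment via edlib), and
merged when the overlap is at least 50 bp with overlap identity >= 98%
and the preset's mismatch/gap allowances hold.  Both orientations are
considered: probes are cloned inserts of unknown strand.  Clusters are
the transitive closure of accepted merges; no consensus sequences are
built because only cluster membership feeds the accounting.
"""

from __future__ import annotations

import math
import re
from collections import defaultdict
from dataclasses import dataclass

import edlib

from .synthetic_data import revcomp

_VALID_SEQ = re.compile(r"^[ACGTRYSWKMBDHVNacgtryswkmbdhvn]+$")
_AMBIG = set("RYSWKMBDHVNryswkmbdhvn")

_CIGAR_OP = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class AssemblyParams:
    """Stringency preset for pairwise probe assembly.

    ``word_length`` is the minimum exact-match seed; ``index_word_length``
    the k-mer size used for candidate lookup; mismatch and gap allowances
    are percentages of the overlap length; ``min_overlap`` (50 bp) and
    ``min_overlap_identity`` (98%) are fixed across presets.
    """

    word_length: int
    index_word_length: int
    max_mismatch_pct: float
    max_ambiguities: int
    max_gap_pct: float
    max_gap_size: int
    preset_name: str = "custom"
    min_overlap: int = 50
    min_overlap_identity: float = 0.98

    def __post_init__(self) -> None:
        if self.word_length < self.index_word_length:
            raise ValueError("word_length must be >= index_word_length")


PRESETS: dict[str, AssemblyParams] = {
    "A1": AssemblyParams(18, 13, 10.0, 4, 10.0, 1, "A1"),
    "A2": AssemblyParams(14, 12, 15.0, 4, 15.0, 2, "A2"),
    "A3": AssemblyParams(12, 11, 20.0, 16, 20.0, 5, "A3"),
    "A4": AssemblyParams(10, 10, 20.0, 16, 20.0, 5, "A4"),
}


@dataclass
class ProbeClustering:
    """Cluster label per probe (labels are arbitrary integers)."""

    labels: dict[str, int]

    @property
    def n_total(self) -> int:
        return len(self.labels)

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = defaultdict(list)
        for pid, lab in self.labels.items():
            out[lab].append(pid)
        return dict(out)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _alignment_stats(query: str, target: str) -> tuple[int, int, int, int, int] | None:
    """(overlap, matches, mismatches, n_gaps, max_gap) of the best alignment.

    The shorter sequence is aligned as an infix of the longer (mode HW),
    which covers full-length duplicates and contained fragments; staggered
    dovetail overlaps are not modelled.
    """
    if len(query) > len(target):
        query, target = target, query
    res = edlib.align(query, target, mode="HW", task="path")
    cigar = res.get("cigar")
    if not cigar:
        return None
    overlap = matches = mismatches = n_gaps = max_gap = 0
    for length_s, op in _CIGAR_OP.findall(cigar):
        length = int(length_s)
        overlap += length
        if op == "=":
            matches += length
        elif op in ("X", "M"):
            mismatches += length
        else:  # I or D: one gap of this size
            n_gaps += 1
            max_gap = max(max_gap, length)
    return overlap, matches, mismatches, n_gaps, max_gap


def _pair_merges(seq_a: str, seq_b: str, params: AssemblyParams) -> bool:
    stats = _alignment_stats(seq_a, seq_b)
    if stats is None:
        return False
    overlap, matches, mismatches, n_gaps, max_gap = stats
    if overlap < params.min_overlap:
        return False
    # ambiguity codes count as matches up to the allowance, then as mismatches
    n_ambig = sum(1 for c in seq_a if c in _AMBIG) + sum(
        1 for c in seq_b if c in _AMBIG
    )
    excess_ambig = max(0, n_ambig - params.max_ambiguities)
    mismatches += excess_ambig
    matches -= excess_ambig
    if matches / overlap < params.min_overlap_identity:
        return False
    if mismatches > params.max_mismatch_pct / 100.0 * overlap:
        return False
    if n_gaps > params.max_gap_pct / 100.0 * overlap:
        return False
    if max_gap > params.max_gap_size:
        return False
    return True


def cluster_probes(
    probes: dict[str, str], params: AssemblyParams | str = "A1"
) -> ProbeClustering:
    """Cluster probe sequences by transitive closure of pairwise merges.

    ``params`` is an :class:`AssemblyParams` or a preset name (A1..A4).
    Candidate pairs share at least one exact word of ``word_length`` in
    either orientation (looked up through an ``index_word_length``-mer
    index); accepted merges satisfy the preset's overlap criteria.
    """
    if isinstance(params, str):
        params = PRESETS[params]
    if not probes:
        raise ValueError("no probes to cluster")
    for pid, seq in probes.items():
        if not seq:
            raise ValueError(f"empty sequence for probe {pid}")
        if not _VALID_SEQ.match(seq):
            raise ValueError(f"non-DNA characters in probe {pid}")

    ids = list(probes)
    fwd = {pid: probes[pid].upper() for pid in ids}
    rev = {pid: revcomp(s) for pid, s in fwd.items()}

    index: dict[str, set[str]] = defaultdict(set)
    ik = params.index_word_length
    for pid in ids:
        for word in _kmers(fwd[pid], ik):
            index[word].add(pid)

    uf = _UnionFind(ids)
    checked: set[tuple[str, str]] = set()
    for pid in ids:
        candidates: set[str] = set()
        for seq in (fwd[pid], rev[pid]):
            for word in _kmers(seq, ik):
                candidates |= index[word]
        candidates.discard(pid)
        for other in candidates:
            key = (pid, other) if pid < other else (other, pid)
            if key in checked:
                continue
            checked.add(key)
            if uf.find(pid) == uf.find(other):
                continue
            # seed requirement: a shared exact word of word_length in
            # either orientation; verify every seeded orientation (a
            # chance forward word must not mask a reverse-complement hit)
            words_other = _kmers(fwd[other], params.word_length)
            for oriented in (fwd[pid], rev[pid]):
                if not (_kmers(oriented, params.word_length) & words_other):
                    continue
                if _pair_merges(oriented, fwd[other], params):
                    uf.union(pid, other)
                    break

    roots: dict[str, int] = {}
    labels: dict[str, int] = {}
    for pid in ids:
        root = uf.find(pid)
        labels[pid] = roots.setdefault(root, len(roots))
    return ProbeClustering(labels=labels)


@dataclass
class RedundancyReport:
    """Singleton/cluster accounting of a probe clustering.

    ``n_unique_loci = n_singletons + n_clusters``; the redundancy rate is
    the percentage of probes collapsed away, truncated to 2 decimal
    places (the convention of the reference tabulation this reproduces).
    """

    n_total: int
    n_singletons: int
    n_redundant_members: int
    n_clusters: int

    @property
    def n_unique_loci(self) -> int:
        return self.n_singletons + self.n_clusters

    @property
    def redundancy_rate(self) -> float:
        exact = 100.0 * (self.n_total - self.n_unique_loci) / self.n_total
        return math.floor(exact * 100.0 + 1e-9) / 100.0


def redundancy_report(clustering: ProbeClustering) -> RedundancyReport:
    """Summarize a clustering into the unique-locus accounting."""
    sizes = [len(members) for members in clustering.clusters().values()]
    n_singletons = sum(1 for s in sizes if s == 1)
    multi = [s for s in sizes if s >= 2]
    return RedundancyReport(
        n_total=clustering.n_total,
        n_singletons=n_singletons,
        n_redundant_members=sum(multi),
        n_clusters=len(multi),
    )


def extrapolate_unique_loci(array_size: int, report: RedundancyReport) -> int:
    """Scale the unique-locus count to the full array size (floor)."""
    if report.n_total == 0:
        raise ValueError("empty report")
    if array_size < report.n_total:
        raise ValueError("array_size must be >= sequenced probe count")
    return math.floor(array_size * report.n_unique_loci / report.n_total)
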