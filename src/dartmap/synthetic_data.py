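"""Synthetic genomes, probe sets and outbred mapping populations.

The generator emulates the study system the rest of the package is built
for: a plant genome assembled into eleven pseudochromosomes plus a tail of
small unanchored scaffolds, a hybridization array of ~300-500 bp cloned
probes with substantial sequence redundancy, and an outbred F1 ("CP")
mapping population of two heterozygous parents in which dominant markers
segregate 1:1 (heterozygous in a single parent) or 3:1 (heterozygous in
both), alongside fully informative codominant anchor markers.

Ground truth (gene intervals, probe source coordinates, probe duplication
clusters, marker positions and phases) is returned in machine-readable
form so downstream estimates can be scored against it.

Meioses are simulated without crossover interference: the parental homolog
transmitted along a chromosome follows a two-state Markov chain whose
switch probability between adjacent loci is the Haldane recombination
fraction for their distance, which is exactly the locus-level law of a
Poisson crossover process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = "NA"

#: segregation type codes used throughout the package
TESTCROSS_P1 = "testcross_1to1_P1"
TESTCROSS_P2 = "testcross_1to1_P2"
INTERCROSS = "intercross_3to1"
FULLY_INFORMATIVE = "fully_informative"
F2_INTERCROSS = "f2_1to2to1"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ParameterError(ValueError):
    """Invalid simulation parameter."""


@dataclass
class SyntheticGenomeSpec:
    """Layout of a synthetic genome.

    gene_density is in gene models per Mbp; lengths are in bp.
    """

    n_chromosomes: int = 11
    chromosome_lengths: list[int] | None = None
    n_unanchored_scaffolds: int = 0
    unanchored_length_range: tuple[int, int] = (5_000, 50_000)
    gene_density: float = 10.0
    gene_length_range: tuple[int, int] = (1_000, 4_000)
    gc_fraction: float = 0.4
    seed: int = 0

    def resolved_lengths(self) -> list[int]:
        if self.chromosome_lengths is not None:
            if len(self.chromosome_lengths) != self.n_chromosomes:
                raise ParameterError(
                    "chromosome_lengths must have n_chromosomes entries"
                )
            return list(self.chromosome_lengths)
        return [1_000_000] * self.n_chromosomes

    def validate(self) -> None:
        if self.n_chromosomes <= 0:
            raise ParameterError("need at least one chromosome")
        if any(length <= 0 for length in self.resolved_lengths()):
            raise ParameterError("chromosome lengths must be positive")
        if self.n_unanchored_scaffolds < 0:
            raise ParameterError("negative scaffold count")
        lo, hi = self.unanchored_length_range
        if lo <= 0 or hi < lo:
            raise ParameterError("bad unanchored_length_range")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ParameterError("bad gene_length_range")
        if self.gene_density < 0:
            raise ParameterError("gene_density must be >= 0")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ParameterError("gc_fraction must be in (0,1)")


@dataclass
class SyntheticGenome:
    """Sequences plus gene-model truth for a simulated genome."""

    spec: SyntheticGenomeSpec
    sequences: dict[str, str]
    chromosomes: list[str]
    unanchored: list[str]
    genes: pd.DataFrame  # gene_id, scaffold, start, end, strand (0-based half-open)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def is_main(self, scaffold: str) -> bool:
        return scaffold in set(self.chromosomes)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draw = rng.choice(4, size=length, p=p)
    return _BASES[draw].tobytes().decode("ascii")


def _place_nonoverlapping(
    rng: np.random.Generator, scaffold_len: int, lengths: np.ndarray
) -> np.ndarray:
    """Starts for intervals of the given lengths, packed without overlap."""
    total = int(lengths.sum())
    free = scaffold_len - total
    if free < 0:
        raise ParameterError("gene intervals exceed scaffold length")
    cuts = np.sort(rng.integers(0, free + 1, size=lengths.size))
    return cuts + np.concatenate(([0], np.cumsum(lengths[:-1])))


def simulate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Generate chromosome and scaffold sequences plus gene-model truth.

    Deterministic for a given spec (single seeded generator); gene
    intervals never overlap within a scaffold.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lengths = spec.resolved_lengths()
    chromosomes = [f"Chr{i + 1:02d}" for i in range(spec.n_chromosomes)]
    sequences: dict[str, str] = {}
    for name, length in zip(chromosomes, lengths):
        sequences[name] = _random_sequence(rng, length, spec.gc_fraction)
    unanchored = [
        f"scaffold_{i + 1}" for i in range(spec.n_unanchored_scaffolds)
    ]
    lo, hi = spec.unanchored_length_range
    for name in unanchored:
        sequences[name] = _random_sequence(
            rng, int(rng.integers(lo, hi + 1)), spec.gc_fraction
        )

    rows = []
    glo, ghi = spec.gene_length_range
    for name, length in zip(chromosomes, lengths):
        n_genes = rng.poisson(spec.gene_density * length / 1e6)
        while n_genes * ghi > 0.9 * length:  # keep packing feasible
            n_genes -= 1
        if n_genes <= 0:
            continue
        glens = rng.integers(glo, ghi + 1, size=n_genes)
        starts = _place_nonoverlapping(rng, length, glens)
        strands = rng.choice(np.array(["+", "-"]), size=n_genes)
        for j in range(n_genes):
            rows.append(
                (
                    f"{name}.g{j + 1}",
                    name,
                    int(starts[j]),
                    int(starts[j] + glens[j]),
                    strands[j],
                )
            )
    genes = pd.DataFrame(
        rows, columns=["gene_id", "scaffold", "start", "end", "strand"]
    )
    return SyntheticGenome(
        spec=spec,
        sequences=sequences,
        chromosomes=chromosomes,
        unanchored=unanchored,
        genes=genes,
    )


# ---------------------------------------------------------------------------
# probe planting


_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ProbeSet:
    """Planted probe sequences with source-coordinate and cluster truth."""

    sequences: dict[str, str]
    truth: pd.DataFrame  # probe_id, scaffold, start, end, strand, cluster, is_copy

    @property
    def probe_ids(self) -> list[str]:
        return list(self.truth["probe_id"])

    def truth_labels(self) -> dict[str, int]:
        return dict(zip(self.truth["probe_id"], self.truth["cluster"]))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([choices[rng.integers(0, 3)]])
    return arr.tobytes().decode("ascii")


def plant_probes(
    genome: SyntheticGenome,
    n_probes: int,
    redundancy_rate: float = 0.0,
    mutation_rate: float = 0.0,
    length_range: tuple[int, int] = (300, 500),
    seed: int = 0,
    p_genic: float | None = None,
    require_psti_motif: bool = False,
) -> ProbeSet:
    """Extract probes from a genome, planting a known fraction of duplicates.

    ``round(n_probes * redundancy_rate)`` probes are mutated copies of
    earlier (unique) probes; truth clustering and source coordinates are
    recorded.  With ``p_genic`` set, each unique probe lies fully inside a
    gene model with that probability and strictly outside all gene models
    otherwise.  ``require_psti_motif`` stamps a CTGCAG (PstI) site at both
    fragment boundaries in the genome before extraction, mirroring a PstI
    complexity-reduced representation.
    """
    if not 0.0 <= redundancy_rate < 1.0:
        raise ParameterError("redundancy_rate must be in [0,1)")
    lo, hi = length_range
    min_scaffold = min(len(s) for s in genome.sequences.values())
    if hi > min_scaffold:
        raise ParameterError("length_range exceeds shortest scaffold")
    rng = np.random.default_rng(seed)
    n_copies = int(round(n_probes * redundancy_rate))
    n_unique = n_probes - n_copies
    if n_unique < 1:
        raise ParameterError("redundancy_rate leaves no unique probes")

    names = list(genome.sequences)
    seq_arrays = {
        name: bytearray(genome.sequences[name], "ascii") for name in names
    }
    weights = np.array([len(genome.sequences[n]) for n in names], dtype=float)
    weights /= weights.sum()

    genes_by_chrom: dict[str, pd.DataFrame] = {}
    if p_genic is not None and len(genome.genes):
        genes_by_chrom = {
            c: g.sort_values("start") for c, g in genome.genes.groupby("scaffold")
        }

    records = []
    source_seqs: list[str] = []
    used: dict[str, list[tuple[int, int]]] = {name: [] for name in names}

    def collides(scaffold: str, start: int, end: int) -> bool:
        # distinct source loci must not overlap, or the truth clustering
        # would disagree with genuine sequence redundancy
        return any(s < end and e > start for s, e in used[scaffold])

    for u in range(n_unique):
        length = int(rng.integers(lo, hi + 1))
        placed = False
        if p_genic is not None and genes_by_chrom and rng.random() < p_genic:
            # inside a random gene model long enough to contain the probe
            genes = genome.genes[genome.genes.end - genome.genes.start >= length]
            for _ in range(200):
                if not len(genes):
                    break
                g = genes.iloc[int(rng.integers(0, len(genes)))]
                start = int(rng.integers(g.start, g.end - length + 1))
                scaffold = g.scaffold
                if not collides(scaffold, start, start + length):
                    placed = True
                    break
        if not placed:
            for _ in range(500):
                scaffold = names[
                    int(rng.choice(len(names), p=weights))
                ]
                start = int(
                    rng.integers(0, len(genome.sequences[scaffold]) - length + 1)
                )
                if collides(scaffold, start, start + length):
                    continue
                if p_genic is None:
                    break
                g = genes_by_chrom.get(scaffold)
                if g is None or not _overlaps_any(
                    g["start"].to_numpy(), g["end"].to_numpy(), start, start + length
                ):
                    break
            else:
                raise ParameterError("could not place a non-overlapping probe")
        end = start + length
        used[scaffold].append((start, end))
        if require_psti_motif:
            arr = seq_arrays[scaffold]
            arr[start : start + 6] = b"CTGCAG"
            arr[end - 6 : end] = b"CTGCAG"
        records.append((scaffold, start, end, u))
        source_seqs.append("")  # filled after motif stamping

    # materialize sequences only after all motif edits
    sequences: dict[str, str] = {}
    rows = []
    stamped = {name: bytes(seq_arrays[name]).decode("ascii") for name in names}
    for u, (scaffold, start, end, cluster) in enumerate(records):
        source_seqs[u] = stamped[scaffold][start:end]
        pid = f"probe{u + 1:05d}"
        sequences[pid] = source_seqs[u]
        rows.append((pid, scaffold, start, end, "+", cluster, False))

    for c in range(n_copies):
        src = int(rng.integers(0, n_unique))
        scaffold, start, end, cluster = records[src]
        seq = _mutate(rng, source_seqs[src], mutation_rate)
        strand = "+"
        if rng.random() < 0.5:
            seq = revcomp(seq)
            strand = "-"
        pid = f"probe{n_unique + c + 1:05d}"
        sequences[pid] = seq
        rows.append((pid, scaffold, start, end, strand, cluster, True))

    truth = pd.DataFrame(
        rows,
        columns=["probe_id", "scaffold", "start", "end", "strand", "cluster", "is_copy"],
    )
    return ProbeSet(sequences=sequences, truth=truth)


def _overlaps_any(starts: np.ndarray, ends: np.ndarray, s: int, e: int) -> bool:
    return bool(np.any((starts < e) & (ends > s)))


def extract_marker_probes(
    genome: SyntheticGenome,
    truth: pd.DataFrame,
    length: int = 400,
    seed: int = 0,
) -> ProbeSet:
    """Probe sequences for simulated markers, cut at their truth positions.

    Array markers are assayed by cloned probes; this links the two
    synthetic worlds by extracting one fragment per marker, centered on
    the marker's genomic position, with the marker id as the probe id.
    """
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    rows = []
    for mid, row in truth.iterrows():
        chrom = row["chromosome"]
        seq = genome.sequences[chrom]
        half = length // 2
        start = int(np.clip(int(row["bp"]) - half, 0, max(0, len(seq) - length)))
        end = min(start + length, len(seq))
        frag = seq[start:end]
        strand = "+"
        if rng.random() < 0.5:
            frag = revcomp(frag)
            strand = "-"
        sequences[str(mid)] = frag
        rows.append((str(mid), chrom, start, end, strand, len(rows), False))
    probe_truth = pd.DataFrame(
        rows,
        columns=["probe_id", "scaffold", "start", "end", "strand", "cluster", "is_copy"],
    )
    return ProbeSet(sequences=sequences, truth=probe_truth)


# ---------------------------------------------------------------------------
# cross simulation


@dataclass
class CrossSimSpec:
    """Parameters of the simulated outbred F1 mapping population."""

    n_progeny: int = 177
    markers_per_chromosome: int = 100
    fraction_3to1: float = 0.4
    fraction_codominant: float = 0.1
    missing_rate: float = 0.0
    error_rate: float = 0.0
    kbp_per_cm_truth: float = 500.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_progeny < 2:
            raise ParameterError("n_progeny must be >= 2")
        for name in ("fraction_3to1", "fraction_codominant", "missing_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0,1]")
        if self.fraction_3to1 + self.fraction_codominant > 1.0:
            raise ParameterError("type fractions exceed 1")
        if self.markers_per_chromosome < 1:
            raise ParameterError("need at least one marker per chromosome")
        if self.kbp_per_cm_truth <= 0:
            raise ParameterError("kbp_per_cm_truth must be positive")


@dataclass
class CrossResult:
    """Genotype matrix, per-marker quality metrics and truth map."""

    spec: CrossSimSpec
    genotypes: pd.DataFrame  # index marker_id; columns P1, P2, then progeny
    quality: pd.DataFrame  # marker_id, reproducibility, q_score, call_rate
    truth: pd.DataFrame  # marker_id, chromosome, bp, cm, seg_type, phase_p1, phase_p2
    #: noise-free marked-allele transmissions per parent, keyed "P1"/"P2";
    #: arrays are (n_progeny x n_markers) in truth-table marker order
    transmissions: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def progeny_columns(self) -> list[str]:
        return [c for c in self.genotypes.columns if c not in ("P1", "P2")]


def simulate_meioses(
    positions_cm: np.ndarray, n_gametes: int, rng: np.random.Generator
) -> np.ndarray:
    """Transmitted-homolog matrix (n_gametes x n_loci) for one parent.

    Exact locus-level sampler of a no-interference (Poisson) crossover
    process: adjacent loci recombine with the Haldane fraction of their
    cM distance.
    """
    order = np.argsort(positions_cm)
    pos = np.asarray(positions_cm, dtype=float)[order]
    m = pos.size
    theta = (1.0 - np.exp(-2.0 * np.diff(pos) / 100.0)) / 2.0
    start = rng.integers(0, 2, size=(n_gametes, 1))
    if m > 1:
        switches = rng.random((n_gametes, m - 1)) < theta[None, :]
        states = (start + np.concatenate(
            [np.zeros((n_gametes, 1), dtype=int), np.cumsum(switches, axis=1)], axis=1
        )) % 2
    else:
        states = start % 2
    out = np.empty_like(states)
    out[:, order] = states
    return out


def simulate_cross(
    chromosome_lengths: dict[str, int] | SyntheticGenome,
    spec: CrossSimSpec,
) -> CrossResult:
    """Simulate the mapping population over a genome truth map.

    ``chromosome_lengths`` is either a mapping of chromosome name to bp
    length or a :class:`SyntheticGenome` (its main chromosomes are used).
    Marker bp positions are drawn uniformly per chromosome and converted
    to cM truth with the planted kbp/cM ratio.  Dominant scores are
    presence/absence of the marked allele; fully informative codominant
    genotypes are coded ``ac/ad/bc/bd`` with parents ``ab`` and ``cd``.
    Missing entries and random score flips are injected at the stated
    rates.
    """
    spec.validate()
    if isinstance(chromosome_lengths, SyntheticGenome):
        lengths = {
            c: len(chromosome_lengths.sequences[c])
            for c in chromosome_lengths.chromosomes
        }
    else:
        lengths = dict(chromosome_lengths)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_progeny
    progeny = [f"I{i + 1:03d}" for i in range(n)]

    truth_rows = []
    geno_rows = []
    qual_rows = []
    x1_all: list[np.ndarray] = []
    x2_all: list[np.ndarray] = []
    for chrom, length in lengths.items():
        m = spec.markers_per_chromosome
        bp = np.sort(rng.integers(0, length, size=m))
        cm = bp / 1000.0 / spec.kbp_per_cm_truth
        u = rng.random(m)
        seg = np.where(
            u < spec.fraction_codominant,
            FULLY_INFORMATIVE,
            np.where(
                u < spec.fraction_codominant + spec.fraction_3to1,
                INTERCROSS,
                np.where(rng.random(m) < 0.5, TESTCROSS_P1, TESTCROSS_P2),
            ),
        )
        phase1 = rng.integers(0, 2, size=m)
        phase2 = rng.integers(0, 2, size=m)
        hom1 = simulate_meioses(cm, n, rng)  # homolog transmitted by P1
        hom2 = simulate_meioses(cm, n, rng)
        x1 = (hom1 == phase1[None, :]).astype(np.int8)  # marked allele from P1
        x2 = (hom2 == phase2[None, :]).astype(np.int8)

        err = spec.error_rate
        # all noise draws happen unconditionally so that identical seeds
        # give identical meioses across error/missing settings
        miss = rng.random((n, m)) < spec.missing_rate
        flip_a = rng.random((n, m)) < err
        flip_b = rng.random((n, m)) < err
        reproducibility = np.clip(rng.beta(300, 3, size=m), 0, 1)
        q_scores = np.clip(rng.normal(80, 8, size=m), 0, 100)

        x1_all.append(x1)
        x2_all.append(x2)
        for j in range(m):
            mid = f"{chrom}_M{j + 1:04d}"
            stype = seg[j]
            # score flips are injected at the observation level: a dominant
            # presence/absence call flips as a whole; a codominant genotype
            # flips each transmitted-allele call independently
            if stype == FULLY_INFORMATIVE:
                g1 = np.where(flip_a[:, j], 1 - x1[:, j], x1[:, j])
                g2 = np.where(flip_b[:, j], 1 - x2[:, j], x2[:, j])
                a = np.where(g1 == 1, "a", "b")
                c = np.where(g2 == 1, "c", "d")
                scores = np.char.add(a, c)
                parents = ("ab", "cd")
            else:
                if stype == TESTCROSS_P1:
                    present = x1[:, j]
                    parents = ("1", "0")
                elif stype == TESTCROSS_P2:
                    present = x2[:, j]
                    parents = ("0", "1")
                else:  # intercross 3:1
                    present = x1[:, j] | x2[:, j]
                    parents = ("1", "1")
                present = np.where(flip_a[:, j], 1 - present, present)
                scores = np.where(present == 1, "1", "0")
            scores = scores.astype(object)
            scores[miss[:, j]] = MISSING
            call_rate = 1.0 - miss[:, j].mean()
            geno_rows.append([mid, parents[0], parents[1], *scores])
            qual_rows.append(
                (mid, float(reproducibility[j]), float(q_scores[j]), float(call_rate))
            )
            truth_rows.append(
                (mid, chrom, int(bp[j]), float(cm[j]), stype, int(phase1[j]), int(phase2[j]))
            )

    genotypes = pd.DataFrame(
        geno_rows, columns=["marker_id", "P1", "P2", *progeny]
    ).set_index("marker_id")
    quality = pd.DataFrame(
        qual_rows, columns=["marker_id", "reproducibility", "q_score", "call_rate"]
    ).set_index("marker_id")
    truth = pd.DataFrame(
        truth_rows,
        columns=["marker_id", "chromosome", "bp", "cm", "seg_type", "phase_p1", "phase_p2"],
    ).set_index("marker_id")
    transmissions = {
        "P1": np.concatenate(x1_all, axis=1),
        "P2": np.concatenate(x2_all, axis=1),
    }
    return CrossResult(
        spec=spec,
        genotypes=genotypes,
        quality=quality,
        truth=truth,
        transmissions=transmissions,
    )
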