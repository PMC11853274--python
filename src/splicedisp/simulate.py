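"""Synthetic acceptor windows and a planted toy annotation.

The window generator emulates the statistical structure the analysis
assumes around human acceptor sites: a pyrimidine-rich upstream tract
(bases -50..-8), a low-entropy core (bases -7..+6) with the invariant AG
fixed at -2/-1, and a separate downstream base composition (bases
+7..+50).  Optional injections enrich one dinucleotide in a site interval
of one mode, creating a detectable dispersion difference for power and
discrimination checks.

``generate_toy_annotation`` builds a small two-contig genome and GTF whose
transcripts plant ground-truth common / constitutive / alternative
(normal, exonic, intronic) and ambiguous acceptors with canonical GT..AG
introns, plus exactly one sub-100-bp intron and one pair of alternative
acceptors closer than 100 bp, to exercise the exclusion filters
end-to-end.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .kmers import BASES
from .windows import (
    FLANK,
    WINDOW_LENGTH,
    AcceptorWindow,
    label_to_offset,
    offset_to_label,
)

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _stream(seed: int, tag: str) -> np.random.Generator:
    """Deterministic named sub-stream of a master seed."""
    return np.random.default_rng([seed, zlib.crc32(tag.encode()) & 0x7FFFFFFF])


@dataclass(frozen=True)
class Injection:
    """Enrich dinucleotide ``pattern`` in [start_label, end_label] of one mode."""

    pattern: str
    start_label: int
    end_label: int
    multiplier: float
    mode: str

    def __post_init__(self):
        if len(self.pattern) != 2 or any(c not in _BASE_INDEX for c in self.pattern):
            raise ValueError(f"pattern must be a dinucleotide, got {self.pattern!r}")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")


def default_core_weights() -> Dict[int, Tuple[float, float, float, float]]:
    """Per-label base probabilities (A, C, G, T) for core bases -7..+6.

    The polypyrimidine run-in continues through -3, A and G are fixed at
    -2/-1, and the first exon bases carry a mild G bias, enough to
    reproduce the qualitative dispersion dip in the core region.
    """
    weights: Dict[int, Tuple[float, float, float, float]] = {}
    for label in range(-7, -2):
        weights[label] = (0.08, 0.40, 0.07, 0.45)
    weights[-2] = (1.0, 0.0, 0.0, 0.0)
    weights[-1] = (0.0, 0.0, 1.0, 0.0)
    weights[1] = (0.25, 0.15, 0.45, 0.15)
    for label in range(2, 7):
        weights[label] = (0.27, 0.23, 0.27, 0.23)
    return weights


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic window generator."""

    n_per_mode: int = 2000
    seed: int = 0
    upstream_pyrimidine_fraction: float = 0.7
    core_weights: Mapping[int, Tuple[float, float, float, float]] = field(
        default_factory=default_core_weights
    )
    downstream_composition: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    injections: Tuple[Injection, ...] = ()

    def __post_init__(self):
        if self.n_per_mode < 1:
            raise ValueError("n_per_mode must be positive")
        if not 0 <= self.upstream_pyrimidine_fraction <= 1:
            raise ValueError("pyrimidine fraction must lie in [0, 1]")
        for label, w in self.core_weights.items():
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(f"core weights at label {label} do not sum to 1")
        if abs(sum(self.downstream_composition) - 1.0) > 1e-9:
            raise ValueError("downstream composition must sum to 1")


def position_probabilities(config: GeneratorConfig) -> np.ndarray:
    """(100, 4) matrix of per-offset base probabilities (A, C, G, T)."""
    f = config.upstream_pyrimidine_fraction
    upstream = ((1 - f) / 2, f / 2, (1 - f) / 2, f / 2)
    probs = np.empty((WINDOW_LENGTH, 4))
    for offset in range(WINDOW_LENGTH):
        label = offset_to_label(offset)
        if label in config.core_weights:
            probs[offset] = config.core_weights[label]
        elif label < 0:
            probs[offset] = upstream
        else:
            probs[offset] = config.downstream_composition
    return probs


def _injection_slots(inj: Injection) -> np.ndarray:
    start = label_to_offset(inj.start_label)
    end = label_to_offset(inj.end_label)
    if end <= start:
        raise ValueError("injection interval must span at least two bases")
    return np.arange(start, end)  # dinucleotide start offsets within the interval


def _apply_injection(
    codes: np.ndarray, inj: Injection, probs: np.ndarray, rng: np.random.Generator
) -> None:
    """Plant extra pattern occurrences in-place to reach the enriched expectation.

    The per-window number of planted occurrences is Poisson with mean
    (multiplier - 1) x the baseline expected occurrence count in the
    interval; placements are non-overlapping uniform starts.
    """
    slots = _injection_slots(inj)
    x, y = _BASE_INDEX[inj.pattern[0]], _BASE_INDEX[inj.pattern[1]]
    baseline = float(np.sum(probs[slots, x] * probs[slots + 1, y]))
    capacity = (slots.size + 1) // 2
    if inj.multiplier * baseline > capacity:
        raise ValueError(
            f"injection infeasible: expected {inj.multiplier * baseline:.1f} "
            f"occurrences exceed interval capacity {capacity}"
        )
    extra = rng.poisson((inj.multiplier - 1.0) * baseline, size=codes.shape[0])
    for w, k in enumerate(extra):
        if k == 0:
            continue
        placed: List[int] = []
        for c in rng.permutation(slots):
            if all(abs(int(c) - p) >= 2 for p in placed):
                placed.append(int(c))
                if len(placed) == min(int(k), capacity):
                    break
        for c in placed:
            codes[w, c] = x
            codes[w, c + 1] = y


def _sample_codes(
    config: GeneratorConfig, mode: str, rng: np.random.Generator
) -> np.ndarray:
    probs = position_probabilities(config)
    cdf = np.cumsum(probs, axis=1)
    u = rng.random((config.n_per_mode, WINDOW_LENGTH))
    codes = (u[:, :, None] > cdf[None, :, :]).sum(axis=2).astype(np.uint8)
    for inj in config.injections:
        if inj.mode == mode:
            _apply_injection(codes, inj, probs, rng)
    # the canonical AG is invariant, never disturbed by injections
    codes[:, label_to_offset(-2)] = _BASE_INDEX["A"]
    codes[:, label_to_offset(-1)] = _BASE_INDEX["G"]
    return codes


def generate_windows(config: GeneratorConfig, mode: str = "common") -> List[AcceptorWindow]:
    """Draw ``n_per_mode`` synthetic acceptor windows for one mode.

    Deterministic given (config.seed, mode); distinct modes use distinct
    sub-streams of the master seed, so equal configs give independent
    null draws across modes.
    """
    rng = _stream(config.seed, f"windows:{mode}")
    codes = _sample_codes(config, mode, rng)
    seqs = _BASE_BYTES[codes]
    return [
        AcceptorWindow(
            sequence=seqs[i].tobytes().decode("ascii"),
            mode=mode,
            event_id=f"sim-{mode}-{i}",
            chrom="synthetic",
        )
        for i in range(codes.shape[0])
    ]


def generate_null_pair(
    config: GeneratorConfig,
) -> Tuple[List[AcceptorWindow], List[AcceptorWindow]]:
    """Two independent draws from the identical generator (distinct sub-seeds)."""
    return (
        generate_windows(config, mode="null_a"),
        generate_windows(config, mode="null_b"),
    )


# --------------------------------------------------------------------------
# planted toy annotation


@dataclass
class ToyAnnotation:
    """A small synthetic genome + GTF with planted acceptor mode labels."""

    genome: Dict[str, str]
    gtf: str
    truth: pd.DataFrame

    def write(self, out_dir) -> Dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "toy_genome.fa",
            "gtf": out / "toy_annotation.gtf",
            "truth": out / "toy_truth.tsv",
        }
        with open(paths["genome"], "w") as fh:
            for name, seq in self.genome.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        with open(paths["gtf"], "w") as fh:
            fh.write(self.gtf)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


#: (gene, transcript, chrom, strand, exon intervals) for the planted toy.
_TOY_TRANSCRIPTS: Tuple[Tuple[str, str, str, str, Tuple[Tuple[int, int], ...]], ...] = (
    # common one-to-one acceptor
    ("G1", "t1", "chrA", "+", ((101, 300), (501, 700))),
    # constitutive: one acceptor, two donors of degree 1
    ("G2", "t2a", "chrA", "+", ((1101, 1250), (1601, 1800))),
    ("G2", "t2b", "chrA", "+", ((1101, 1400), (1601, 1800))),
    # alternative with an exonic partner; reference pairing has 2 supporters
    ("G3", "t3a", "chrA", "+", ((2101, 2300), (2701, 3000))),
    ("G3", "t3b", "chrA", "+", ((2101, 2300), (2701, 2950))),
    ("G3", "t3c", "chrA", "+", ((2101, 2300), (2821, 3000))),
    # alternative with an intronic partner
    ("G4", "t4a", "chrA", "+", ((3601, 3800), (4301, 4500))),
    ("G4", "t4b", "chrA", "+", ((3601, 3800), (4301, 4450))),
    ("G4", "t4c", "chrA", "+", ((3601, 3800), (4151, 4500))),
    # alternative trio: normal plus two exonic acceptors only 50 bp apart
    ("G5", "t5a", "chrA", "+", ((5101, 5300), (5701, 6000))),
    ("G5", "t5b", "chrA", "+", ((5101, 5300), (5701, 5950))),
    ("G5", "t5c", "chrA", "+", ((5101, 5300), (5851, 6000))),
    ("G5", "t5d", "chrA", "+", ((5101, 5300), (5901, 6000))),
    # common acceptor behind an 80-bp intron (filter violation)
    ("G6", "t6", "chrA", "+", ((6601, 6800), (6881, 7000))),
    # minus-strand common acceptor
    ("G7", "t7", "chrB", "-", ((101, 200), (401, 600))),
    # ambiguous: acceptor with two donors, one donor with two acceptors
    ("G8", "t8a", "chrB", "+", ((1101, 1300), (1701, 1900))),
    ("G8", "t8b", "chrB", "+", ((1101, 1300), (1701, 1850))),
    ("G8", "t8c", "chrB", "+", ((1101, 1300), (1801, 1900))),
    ("G8", "t8d", "chrB", "+", ((1101, 1250), (1701, 1900))),
)

_TOY_CONTIG_LENGTHS = {"chrA": 7500, "chrB": 2500}

#: planted ground truth per acceptor: mode, submode, filter reason ('' = retained)
_TOY_TRUTH: Tuple[Tuple[str, str, int, str, str, str], ...] = (
    ("chrA", "+", 500, "common", "not_applicable", ""),
    ("chrA", "+", 1600, "constitutive", "not_applicable", ""),
    ("chrA", "+", 2700, "alternative", "normal", ""),
    ("chrA", "+", 2820, "alternative", "exonic", ""),
    ("chrA", "+", 4150, "alternative", "intronic", ""),
    ("chrA", "+", 4300, "alternative", "normal", ""),
    ("chrA", "+", 5700, "alternative", "normal", ""),
    ("chrA", "+", 5850, "alternative", "exonic", "alt_proximity"),
    ("chrA", "+", 5900, "alternative", "exonic", "alt_proximity"),
    ("chrA", "+", 6880, "common", "not_applicable", "short_intron"),
    ("chrB", "-", 201, "common", "not_applicable", ""),
    ("chrB", "+", 1700, "ambiguous", "not_applicable", ""),
    ("chrB", "+", 1800, "alternative", "exonic", ""),
)


def generate_toy_annotation(seed: int = 0) -> ToyAnnotation:
    """Build the planted toy genome, GTF and ground-truth table.

    The background sequence is random; every planted intron carries the
    canonical GT..AG on its transcribed strand.  Deterministic given the
    seed.
    """
    rng = _stream(seed, "toy-genome")
    genome = {
        name: _BASE_BYTES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")
        for name, n in _TOY_CONTIG_LENGTHS.items()
    }

    def set_bases(chrom: str, pos: int, bases: str) -> None:
        s = genome[chrom]
        genome[chrom] = s[: pos - 1] + bases + s[pos - 1 + len(bases) :]

    gtf_lines = []
    for gene, tx, chrom, strand, exons in _TOY_TRANSCRIPTS:
        attrs = f'gene_id "{gene}"; transcript_id "{tx}";'
        gtf_lines.append(
            f"{chrom}\ttoy\ttranscript\t{exons[0][0]}\t{exons[-1][1]}\t.\t{strand}\t.\t{attrs}"
        )
        for s, e in exons:
            gtf_lines.append(f"{chrom}\ttoy\texon\t{s}\t{e}\t.\t{strand}\t.\t{attrs}")
        for i in range(len(exons) - 1):
            intron = (exons[i][1] + 1, exons[i + 1][0] - 1)
            if strand == "+":
                set_bases(chrom, intron[0], "GT")
                set_bases(chrom, intron[1] - 1, "AG")
            else:
                # transcribed GT..AG reads CT..AC on the plus strand
                set_bases(chrom, intron[0], "CT")
                set_bases(chrom, intron[1] - 1, "AC")

    truth = pd.DataFrame(
        list(_TOY_TRUTH),
        columns=["chrom", "strand", "acceptor_pos", "mode", "submode", "filter_reason"],
    )
    return ToyAnnotation(genome=genome, gtf="\n".join(gtf_lines) + "\n", truth=truth)
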