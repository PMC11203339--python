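"""Synthetic paired-end amplicon datasets with per-read ground truth.

Emulates the input of the editing-outcome pipeline: an amplicon-sequencing
library drawn from a mixture of three alleles — HDR-corrected, NHEJ
(mutant plus one indel sampled from a spectrum centred at the cut site)
and unmodified mutant — read as an overlapping R1/R2 pair from the two
fragment ends. Fragments are whole amplicons (fixed PCR primers, no
shearing). Qualities follow a position-dependent Gaussian on the Phred
scale, clipped to [2, 41], with a mild 3'-end decline; substitution errors
are applied at a configurable mean rate, weighted toward low-quality
positions (proportional to the Phred error probability). Sequencing
indel errors are not simulated, which keeps the per-read class truth
unambiguous.

Every draw flows from one seeded generator in a fixed order, so a given
configuration reproduces its FASTQ output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gzip
import numpy as np

from .amplicon import AlleleSet, encode
from .merge import Read, ReadPair

__all__ = [
    "IndelSpectrum",
    "SimulationConfig",
    "TruthRecord",
    "DEFAULT_INDEL_SPECTRUM",
    "sample_nhej_indel",
    "apply_indel",
    "simulate_dataset",
    "write_paired_fastq",
    "write_truth",
    "truth_class_counts",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class IndelSpectrum:
    """NHEJ outcome spectrum: signed size (negative = deletion) -> probability."""

    size_distribution: dict[int, float]
    position_jitter: int = 3

    def __post_init__(self) -> None:
        if 0 in self.size_distribution:
            raise ValueError("0 is not a valid indel size")
        total = sum(self.size_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"indel size probabilities sum to {total}, not 1")
        if self.position_jitter < 0:
            raise ValueError("position_jitter must be >= 0")

    def sizes_and_probs(self) -> tuple[np.ndarray, np.ndarray]:
        sizes = np.array(sorted(self.size_distribution), dtype=np.int64)
        probs = np.array([self.size_distribution[int(s)] for s in sizes])
        return sizes, probs


#: Plausible NHEJ profile: mostly small deletions plus +1 insertions,
#: centred at the cut site.
DEFAULT_INDEL_SPECTRUM = IndelSpectrum(
    size_distribution={
        -1: 0.25, -2: 0.15, -3: 0.12, -4: 0.10, -5: 0.08,
        -6: 0.06, -7: 0.05, -8: 0.04, -9: 0.03, -10: 0.02,
        1: 0.10,
    },
    position_jitter=3,
)

_CLASSES = ("hdr", "nhej", "unmodified")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated library.

    Defaults mirror a treated-sample composition (19% HDR, 75% NHEJ, 6%
    unmodified) sequenced as overlapping 150-nt pairs at a 0.3% mean
    substitution-error rate.
    """

    proportions: dict[str, float] = field(
        default_factory=lambda: {"hdr": 0.19, "nhej": 0.75, "unmodified": 0.06}
    )
    n_pairs: int = 10000
    read_length: int = 150
    substitution_error_rate: float = 0.003
    quality_mean: float = 37.0
    quality_sd: float = 3.0
    quality_decline: float = 4.0  # mean Phred drop from first to last cycle
    indel_spectrum: IndelSpectrum = DEFAULT_INDEL_SPECTRUM
    seed: int = 0

    def __post_init__(self) -> None:
        extra = set(self.proportions) - set(_CLASSES)
        if extra:
            raise ValueError(f"unknown classes in proportions: {sorted(extra)}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("class proportions must be non-negative")
        if self.read_length < 30:
            raise ValueError("read_length must be >= 30")
        if not (0.0 <= self.substitution_error_rate < 0.5):
            raise ValueError("substitution_error_rate must be in [0, 0.5)")

    def class_probs(self) -> np.ndarray:
        return np.array([self.proportions.get(c, 0.0) for c in _CLASSES])


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    true_class: str
    indel_description: str | None = None


def truth_class_counts(truth: list[TruthRecord]) -> dict[str, int]:
    counts = {c: 0 for c in _CLASSES}
    for rec in truth:
        counts[rec.true_class] += 1
    return counts


def sample_nhej_indel(
    spectrum: IndelSpectrum,
    cut_site: int,
    rng: np.random.Generator,
    seq_len: int | None = None,
) -> tuple[int, int]:
    """Draw one NHEJ event as ``(start, signed size)``.

    ``start`` is 1-based, within ``position_jitter`` of the cut site; a
    deletion of d bases removes positions ``start .. start+d-1``, an
    insertion sits after position ``start``. Events are clamped so that
    deletions never extend past the sequence ends.
    """
    sizes, probs = spectrum.sizes_and_probs()
    size = int(sizes[rng.choice(len(sizes), p=probs)])
    jitter = int(rng.integers(-spectrum.position_jitter, spectrum.position_jitter + 1))
    start = max(1, cut_site + jitter)
    if seq_len is not None:
        start = min(start, seq_len)
        if size < 0 and start - size - 1 > seq_len:
            size = -(seq_len - start + 1)
    return start, size


def apply_indel(seq: str, event: tuple[int, int], rng: np.random.Generator) -> str:
    """Apply an NHEJ event to a template; insertions draw random bases."""
    start, size = event
    if size < 0:
        return seq[: start - 1] + seq[start - 1 - size :]
    ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=size))
    return seq[:start] + ins + seq[start:]


def _qualities(
    rng: np.random.Generator, n: int, config: SimulationConfig
) -> np.ndarray:
    rl = config.read_length
    profile = config.quality_mean - config.quality_decline * np.linspace(0.0, 1.0, rl)
    q = rng.normal(loc=profile, scale=config.quality_sd, size=(n, rl))
    return np.clip(np.rint(q), 2, 41).astype(np.int16)


def _apply_errors(
    rng: np.random.Generator,
    codes: np.ndarray,
    quals: np.ndarray,
    rate: float,
    weight_norm: float,
) -> None:
    """Substitute bases in place at probability rate * w(q) / E[w(q)]."""
    p = np.minimum(rate * np.power(10.0, -quals / 10.0) / weight_norm, 0.75)
    mask = rng.random(codes.shape) < p
    n_err = int(mask.sum())
    if n_err:
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=n_err)) % 4


def _decode_rows(codes: np.ndarray) -> list[str]:
    chars = _BASES[codes]
    return [row.tobytes().decode("ascii") for row in chars]


def simulate_dataset(
    config: SimulationConfig,
    alleles: AlleleSet,
    read_id_prefix: str = "sim",
) -> tuple[list[ReadPair], list[TruthRecord]]:
    """Generate a paired-read dataset with per-read truth.

    For each pair a class is drawn from the configured proportions, the
    corresponding template materialised (HDR allele; mutant with one
    sampled indel; mutant unchanged), R1 taken from the template's 5' end
    and R2 as the reverse complement from its 3' end, qualities assigned
    and substitution errors applied.
    """
    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    mutant = alleles.mutant.bases
    hdr = alleles.hdr.bases
    max_del = max(
        (-s for s in config.indel_spectrum.size_distribution if s < 0), default=0
    )
    if rl > len(mutant) - max_del - config.indel_spectrum.position_jitter:
        raise ValueError("read_length exceeds the shortest possible template")
    if 2 * rl <= len(hdr):
        raise ValueError("reads must overlap: 2*read_length must exceed amplicon length")

    n = config.n_pairs
    classes = rng.choice(3, size=n, p=config.class_probs())
    cut = alleles.cut_site_mutant

    templates: list[str] = []
    truth: list[TruthRecord] = []
    for i in range(n):
        cls = _CLASSES[classes[i]]
        rid = f"{read_id_prefix}_{i:06d}"
        if cls == "hdr":
            templates.append(hdr)
            truth.append(TruthRecord(rid, "hdr"))
        elif cls == "nhej":
            event = sample_nhej_indel(config.indel_spectrum, cut, rng, len(mutant))
            templates.append(apply_indel(mutant, event, rng))
            kind = "del" if event[1] < 0 else "ins"
            truth.append(
                TruthRecord(rid, "nhej", f"{kind}@{event[0]}:{abs(event[1])}")
            )
        else:
            templates.append(mutant)
            truth.append(TruthRecord(rid, "unmodified"))

    r1_codes = np.empty((n, rl), dtype=np.int16)
    r2_codes = np.empty((n, rl), dtype=np.int16)
    for i, t in enumerate(templates):
        enc = encode(t)
        r1_codes[i] = enc[:rl]
        # complement is 3 - code under the A,C,G,T = 0..3 encoding
        r2_codes[i] = (3 - enc[::-1])[:rl]

    q1 = _qualities(rng, n, config)
    q2 = _qualities(rng, n, config)
    rate = config.substitution_error_rate
    if rate > 0:
        weight_norm = float(
            np.power(10.0, -np.concatenate([q1, q2]) / 10.0).mean()
        )
        _apply_errors(rng, r1_codes, q1, rate, weight_norm)
        _apply_errors(rng, r2_codes, q2, rate, weight_norm)

    b1 = _decode_rows(r1_codes)
    b2 = _decode_rows(r2_codes)
    pairs = [
        ReadPair(
            Read(f"{truth[i].read_id}/1", b1[i], q1[i]),
            Read(f"{truth[i].read_id}/2", b2[i], q2[i]),
        )
        for i in range(n)
    ]
    return pairs, truth


def _open_write(path, compress: bool):
    if compress:
        # fixed mtime/filename keep gzip output byte-identical across runs
        return gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0)
    return open(path, "wb")


def write_paired_fastq(
    pairs: list[ReadPair], path_r1, path_r2, compress: bool | None = None
) -> None:
    """Write the pairs as two Phred+33 FASTQ files (gzip if *.gz)."""
    for path, mate in ((path_r1, "r1"), (path_r2, "r2")):
        use_gz = str(path).endswith(".gz") if compress is None else compress
        with _open_write(path, use_gz) as fh:
            for pair in pairs:
                read = getattr(pair, mate)
                qual = "".join(chr(q + 33) for q in read.qualities)
                fh.write(f"@{read.id}\n{read.bases}\n+\n{qual}\n".encode("ascii"))


def write_truth(truth: list[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttrue_class\tindel\n")
        for rec in truth:
            fh.write(f"{rec.read_id}\t{rec.true_class}\t{rec.indel_description or ''}\n")
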