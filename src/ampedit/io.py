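"""File formats and configuration: FASTQ pairs, FASTA references, configs."""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO

from .amplicon import AlleleSet, GuideSpec, NucleotideSequence, build_allele_set
from .merge import Read, ReadPair

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq_pairs",
    "load_allele_config",
    "load_config",
]


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> list[NucleotideSequence]:
    with _open_text(path) as fh:
        return [NucleotideSequence(str(rec.seq), rec.id) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(sequences, path) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.name}\n{seq.bases}\n")


def _stem(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id.split()[0]


def read_fastq_pairs(path_r1, path_r2):
    """Stream matched read pairs from two (optionally gzipped) FASTQ files.

    Pairs are matched by record order; IDs must share a stem (identical, or
    differing only in a /1 /2 suffix). A length mismatch between the files,
    a malformed record or a Phred score outside [0, 60] raises a hard error
    naming the offending record.
    """
    with _open_text(path_r1) as fh1, _open_text(path_r2) as fh2:
        it1 = SeqIO.parse(fh1, "fastq")
        it2 = SeqIO.parse(fh2, "fastq")
        n = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            n += 1
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                short = path_r2 if rec2 is None else path_r1
                raise ValueError(
                    f"paired FASTQ length mismatch: {short} ends before record {n}"
                )
            if _stem(rec1.id) != _stem(rec2.id):
                raise ValueError(
                    f"record {n}: read IDs do not pair ({rec1.id!r} vs {rec2.id!r})"
                )
            reads = []
            for rec in (rec1, rec2):
                quals = np.asarray(
                    rec.letter_annotations["phred_quality"], dtype=np.int16
                )
                if len(quals) and quals.max() > 60:
                    raise ValueError(
                        f"record {n} ({rec.id}): Phred score above 60 — "
                        "is this really Phred+33?"
                    )
                reads.append(Read(rec.id, str(rec.seq).upper(), quals))
            yield ReadPair(*reads)


def load_config(path) -> dict:
    """Load a JSON or YAML mapping (YAML is a superset, so one loader)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping")
    return data


def load_allele_config(data_or_path) -> tuple[AlleleSet, GuideSpec | None]:
    """Build an AlleleSet (and optional guide) from a config block.

    Keys: ``wildtype`` (sequence string), ``target_position``, ``markers``
    (list of [position, base]), optional ``cut_site``, ``guide``
    (protospacer) and ``pam``.
    """
    data = (
        load_config(data_or_path)
        if not isinstance(data_or_path, dict)
        else data_or_path
    )
    wt = NucleotideSequence(data["wildtype"], data.get("name", "amplicon"))
    markers = [(int(p), str(b)) for p, b in data.get("markers", [])]
    alleles = build_allele_set(
        wt,
        target_position=int(data["target_position"]),
        marker_edits=markers,
        cut_site=int(data["cut_site"]) if "cut_site" in data else None,
        guide_strand=data.get("guide_strand", "+"),
    )
    guide = None
    if "guide" in data:
        guide = GuideSpec(
            protospacer=data["guide"],
            pam=data.get("pam", "NGG"),
            strand=data.get("guide_strand", "+"),
        )
    return alleles, guide


def dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
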