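"""Readers and writers for the pipeline's interchange formats.

FASTA carries allele catalogs (headers ``locus|allele``), FASTQ carries
reads, and a genotype CSV (columns ``sample_id, age_cal_bp, locus_id,
allele1, allele2``) is the canonical hand-off between the calling stage and
the population-genetic stages.  Configuration is a flat YAML file.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import Allele, AlleleCatalog, GenotypeMatrix, SampleRecord


def read_fasta(path: str | Path, loci: dict[str, int] | None = None) -> AlleleCatalog:
    """Read an allele catalog from FASTA.

    Headers must be ``locus|allele``.  Sequences are uppercased; non-ACGT
    characters and duplicate ids are rejected.  If ``loci`` is omitted,
    expected lengths are taken from the first allele seen at each locus.
    """
    catalog = AlleleCatalog(loci)
    infer = loci is None
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(
                f"FASTA record {rec.id!r}: header must be 'locus|allele'"
            )
        locus_id, allele_id = rec.id.split("|", 1)
        seq = str(rec.seq).upper()
        if infer and locus_id not in catalog.loci:
            catalog.add_locus(locus_id, len(seq))
        catalog.add(Allele(allele_id=allele_id, locus_id=locus_id, sequence=seq))
    return catalog


def write_fasta(catalog: AlleleCatalog, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(a.sequence), id=f"{a.locus_id}|{a.allele_id}", description="")
        for a in catalog.alleles()
    ]
    SeqIO.write(records, str(path), "fasta")


GENOTYPE_COLUMNS = ["sample_id", "age_cal_bp", "locus_id", "allele1", "allele2"]


def read_genotype_table(
    path: str | Path, catalog: AlleleCatalog | None = None
) -> GenotypeMatrix:
    """Read the canonical genotype CSV into a GenotypeMatrix.

    Homozygotes may be written with allele2 equal to allele1 or left blank.
    A blank allele1 marks a failed locus and produces no entry.  Duplicate
    (sample, locus) rows and alleles missing from the catalog are errors.
    """
    matrix = GenotypeMatrix()
    seen_samples: dict[str, SampleRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(GENOTYPE_COLUMNS[:4]) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"genotype CSV missing columns: {sorted(missing)}")
        for row in reader:
            sid = row["sample_id"].strip()
            if sid not in seen_samples:
                age_raw = (row.get("age_cal_bp") or "").strip()
                is_bound = age_raw.startswith((">", "≥"))
                age = float(age_raw.lstrip(">=≥ ").replace(" ", "") or 0.0)
                seen_samples[sid] = SampleRecord(
                    sample_id=sid,
                    age_cal_bp=age,
                    age_is_bound=is_bound,
                    region=row.get("region", "") or "",
                )
            loc = row["locus_id"].strip()
            a1 = (row.get("allele1") or "").strip()
            a2 = (row.get("allele2") or "").strip()
            if not a1 and not a2:
                continue  # failed locus: entry absent, not an error
            if not a1:
                a1, a2 = a2, ""
            if (sid, loc) in matrix.entries:
                raise ValueError(
                    f"duplicate genotype rows for sample {sid}, locus {loc}"
                )
            matrix.set_genotype(sid, loc, a1, a2 or None)
    matrix.samples = list(seen_samples.values())
    if catalog is not None:
        matrix.validate_against(catalog)
    return matrix


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path) -> None:
    ages = {s.sample_id: s.age_cal_bp for s in matrix.samples}
    regions = {s.sample_id: s.region for s in matrix.samples}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(GENOTYPE_COLUMNS + ["region"])
        for (sid, loc), pair in sorted(matrix.entries.items()):
            alleles = sorted(pair)
            if len(alleles) == 1:
                alleles = alleles * 2
            writer.writerow(
                [sid, ages.get(sid, ""), loc, alleles[0], alleles[1],
                 regions.get(sid, "")]
            )


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    """Read specimen metadata (sample_id, age_cal_bp, region, material)."""
    samples = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            age_raw = row["age_cal_bp"].strip()
            is_bound = age_raw.startswith((">", "≥")) or (
                row.get("age_is_bound", "").strip().lower() in {"1", "true", "yes"}
            )
            age = float(age_raw.lstrip(">=≥ ").replace(" ", ""))
            samples.append(
                SampleRecord(
                    sample_id=row["sample_id"].strip(),
                    age_cal_bp=age,
                    age_is_bound=is_bound,
                    region=(row.get("region") or "").strip(),
                    material=(row.get("material") or "").strip(),
                )
            )
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in sample table")
    return samples


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTQ file to (read_id, sequence) pairs; qualities ignored."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality: int = 30) -> None:
    """Write reads as 4-line FASTQ with a constant quality score."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{chr(quality + 33) * len(seq)}\n")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg
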