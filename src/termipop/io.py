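"""Readers and writers: Genepop genotype files, FASTA alignments, site CSVs.

The Genepop dialect accepted here is the classic one: a free-text title
line, locus names (one per line or comma-separated on one line), ``pop``
separators in any capitalisation, and individual lines of the form
``id , g1 g2 ...`` where each genotype field concatenates two alleles coded
with a fixed width of 2 or 3 digits.  An all-zero allele field means
missing; a half-missing field (e.g. ``001000``) is demoted to fully missing
so that no phantom allele enters downstream counts.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
from Bio import SeqIO

from termipop.datatypes import GenotypeTable, HaplotypeAlignment, SiteTable

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_POP = {"pop"}


class GenepopParseError(ValueError):
    pass


class GenepopEncodeError(ValueError):
    pass


def _parse_genotype_field(field: str, line_no: int) -> tuple[int, Optional[tuple[int, int]]]:
    """Return (allele width, genotype or None) for one genotype field."""
    if not field.isdigit() or len(field) not in (4, 6):
        raise GenepopParseError(
            f"line {line_no}: genotype field {field!r} is not a 4- or 6-digit code"
        )
    w = len(field) // 2
    a, b = int(field[:w]), int(field[w:])
    if a == 0 or b == 0:
        # half-missing treated as fully missing (Genepop convention)
        return w, None
    return w, (a, b)


def read_genepop(path: PathLike) -> GenotypeTable:
    """Parse a Genepop file into a :class:`GenotypeTable`.

    Groups are taken in file order and labelled by the id of the *last*
    individual in each ``pop`` block (Genepop's own convention), falling
    back to ``pop_<k>`` on clashes.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise GenepopParseError("file too short to be a Genepop file")
    # title line is free text and ignored
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() not in _POP:
        for tok in lines[i].split(","):
            tok = tok.strip()
            if tok:
                loci.append(tok)
        i += 1
    if not loci:
        raise GenepopParseError("no locus names found before first 'pop'")
    if i == len(lines):
        raise GenepopParseError("no 'pop' separator found")

    pops: list[list[tuple[str, list[Optional[tuple[int, int]]]]]] = []
    width: Optional[int] = None
    for line_no0, raw in enumerate(lines[i:], start=i + 1):
        s = raw.strip()
        if not s:
            continue
        if s.lower() in _POP:
            pops.append([])
            continue
        if "," in s:
            ind_id, rest = s.split(",", 1)
            ind_id = ind_id.strip()
        else:
            parts = s.split(None, 1)
            if len(parts) != 2:
                raise GenepopParseError(f"line {line_no0}: cannot split id from genotypes")
            ind_id, rest = parts
        fields = rest.split()
        if len(fields) != len(loci):
            raise GenepopParseError(
                f"line {line_no0}: {len(fields)} genotype fields for {len(loci)} loci"
            )
        row: list[Optional[tuple[int, int]]] = []
        for f in fields:
            w, g = _parse_genotype_field(f, line_no0)
            if width is None:
                width = w
            elif w != width:
                raise GenepopParseError(
                    f"line {line_no0}: mixed allele-code widths ({w} vs {width} digits)"
                )
            row.append(g)
        if not pops:
            raise GenepopParseError(f"line {line_no0}: individual before first 'pop'")
        pops[-1].append((ind_id, row))

    groups: list[str] = []
    individuals: list[str] = []
    genotypes: list[list[Optional[tuple[int, int]]]] = []
    group_of: dict[str, str] = {}
    for k, block in enumerate(pops):
        if not block:
            raise GenepopParseError(f"'pop' block {k + 1} is empty")
        label = block[-1][0]
        if label in groups:
            label = f"pop_{k + 1}"
        groups.append(label)
        for ind_id, row in block:
            uid = ind_id
            j = 1
            while uid in group_of:
                j += 1
                uid = f"{ind_id}.{j}"
            individuals.append(uid)
            genotypes.append(row)
            group_of[uid] = label
    table = GenotypeTable(loci, individuals, groups, genotypes, group_of)
    logger.info(
        "read %d individuals, %d loci, %d pops from %s",
        table.n_individuals, table.n_loci, len(table.groups), path,
    )
    return table


def write_genepop(table: GenotypeTable, path: PathLike, title: str = "termipop export") -> None:
    """Write a :class:`GenotypeTable` in the 3-digit-per-allele dialect.

    Following common Genepop practice the id column carries the sampling
    location (group) label on every line, so a re-read recovers the same
    group labels; individual ids themselves do not survive a round trip
    (the format has no separate field for them).
    """
    if not table.groups:
        raise GenepopEncodeError("cannot write a Genepop file with no groups")
    for row in table.genotypes:
        for g in row:
            if g is not None and max(g) > 999:
                raise GenepopEncodeError(
                    f"allele code {max(g)} exceeds the 3-digit Genepop limit"
                )
    out = [title]
    out.extend(table.loci)
    for group in table.groups:
        out.append("pop")
        for i in table.members(group):
            fields = []
            for g in table.genotypes[i]:
                if g is None:
                    fields.append("000000")
                else:
                    fields.append(f"{g[0]:03d}{g[1]:03d}")
            out.append(f"{group} , " + " ".join(fields))
    Path(path).write_text("\n".join(out) + "\n")
    logger.info("wrote %d individuals to %s", table.n_individuals, path)


def read_fasta_alignment(
    path: PathLike, counts_path: Optional[PathLike] = None
) -> HaplotypeAlignment:
    """Read an aligned FASTA; optional CSV ``label,count`` supplies counts."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    labels = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(
            f"records are not aligned: lengths {sorted(lengths)} in {path}"
        )
    counts: dict[str, int] = {}
    if counts_path is not None:
        with open(counts_path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower() in ("label", "haplotype"):
                    continue
                counts[row[0].strip()] = int(row[1])
    aln = HaplotypeAlignment(labels, seqs, counts)
    logger.info("read %d aligned haplotypes (L=%d) from %s", len(labels), aln.length, path)
    return aln


def read_site_table(path: PathLike) -> SiteTable:
    """Read site metadata CSV with columns site_id,label,x,y[,lonlat]."""
    site_ids, labels, xs, ys = [], [], [], []
    lonlat = False
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            site_ids.append(row["site_id"])
            labels.append(row["label"])
            xs.append(float(row["x"]))
            ys.append(float(row["y"]))
            if row.get("lonlat", "").strip().lower() in ("1", "true", "yes"):
                lonlat = True
    return SiteTable(site_ids, labels, np.asarray(xs), np.asarray(ys), lonlat=lonlat)


def write_site_table(sites: SiteTable, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["site_id", "label", "x", "y", "lonlat"])
        for sid, lab, x, y in zip(sites.site_ids, sites.labels, sites.x, sites.y):
            w.writerow([sid, lab, repr(float(x)), repr(float(y)), int(sites.lonlat)])
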