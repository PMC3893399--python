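"""Genotype and phenotype containers plus readers/writers for the formats the
pipeline touches: VCF 4.2 genotypes (with explicit haploid male-X handling),
tab-separated phenotype tables, and BED6 ancestry paintings.

Internal marker coordinates are 1-based (VCF convention).  BED output is
0-based half-open; that conversion happens in :func:`write_ancestry_bed` and
nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

MISSING = -1  # sentinel in GenotypeMatrix.counts


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class GenotypeMatrix:
    """Animals x markers alt-allele copy-count matrix.

    ``counts[i, m]`` is the number of copies of the alt allele carried by
    animal ``i`` at marker ``m`` (0..ploidy), or :data:`MISSING`.  ``ploidy``
    is per animal: 1 for hemizygous male X, 2 for autosomes/diploid data.
    """

    animal_ids: list[str]
    marker_ids: list[str]
    chrom: str
    positions: np.ndarray          # 1-based bp, strictly increasing
    alleles: list[tuple[str, str]]  # (ref, alt) per marker
    counts: np.ndarray             # int8, animals x markers
    ploidy: np.ndarray             # int8, per animal

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int8)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int8)
        n, m = self.counts.shape
        if len(self.animal_ids) != n or len(self.ploidy) != n:
            raise ValueError("animal dimension mismatch")
        if len(self.marker_ids) != m or len(self.positions) != m or len(self.alleles) != m:
            raise ValueError("marker dimension mismatch")
        if m > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        valid = (self.counts == MISSING) | (
            (self.counts >= 0) & (self.counts <= self.ploidy[:, None])
        )
        if not valid.all():
            raise ValueError("counts outside 0..ploidy and not MISSING")

    @property
    def n_animals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_markers(self) -> int:
        return self.counts.shape[1]

    def is_haploid(self) -> bool:
        return bool(np.all(self.ploidy == 1))

    def missing_mask(self) -> np.ndarray:
        return self.counts == MISSING

    def subset_markers(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            animal_ids=list(self.animal_ids),
            marker_ids=[self.marker_ids[i] for i in idx],
            chrom=self.chrom,
            positions=self.positions[idx],
            alleles=[self.alleles[i] for i in idx],
            counts=self.counts[:, idx],
            ploidy=self.ploidy.copy(),
        )

    def subset_animals(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            animal_ids=[self.animal_ids[i] for i in idx],
            marker_ids=list(self.marker_ids),
            chrom=self.chrom,
            positions=self.positions.copy(),
            alleles=list(self.alleles),
            counts=self.counts[idx],
            ploidy=self.ploidy[idx],
        )

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"marker {marker_id!r} not in matrix") from None


@dataclass
class PhenotypeTable:
    """Trait values plus the two fixed-effect factors of the association model
    (contemporary group, and year-by-month-of-birth interaction)."""

    data: pd.DataFrame            # indexed by animal_id
    trait_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise FormatError(f"duplicated animal id(s): {dups}")
        for col in ("contemporary_group", "year_month"):
            if col not in self.data.columns:
                raise FormatError(f"missing required column: {col}")
            if self.data[col].astype(str).str.len().eq(0).any():
                raise FormatError(f"empty factor level in column {col}")
        for t in self.trait_names:
            if t not in self.data.columns:
                raise FormatError(f"missing required column: {t}")

    @property
    def animal_ids(self) -> list[str]:
        return list(self.data.index)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a single-chromosome biallelic VCF into a :class:`GenotypeMatrix`.

    Haploid GT fields ("0"/"1") yield counts 0/1 at ploidy 1; diploid fields
    ("0/0", "0|1", ...) yield 0/1/2 at ploidy 2.  "." entries become missing.
    Multi-allelic records and mixed ploidy within one animal are rejected.
    """
    path = Path(path)
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    marker_ids: list[str] = []
    positions: list[int] = []
    alleles: list[tuple[str, str]] = []
    rows: list[np.ndarray] = []
    ploidy_rows: list[np.ndarray] = []
    chrom = None
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise FormatError(
                f"multi-allelic record at {rec.chrom}:{rec.pos} ({rec.id or '.'})"
            )
        if chrom is None:
            chrom = rec.chrom
        elif rec.chrom != chrom:
            raise FormatError("multiple chromosomes in one VCF are not supported")
        marker_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
        positions.append(rec.pos)
        alleles.append((rec.ref, rec.alts[0]))
        cnt = np.empty(len(samples), dtype=np.int8)
        pld = np.empty(len(samples), dtype=np.int8)
        for i, s in enumerate(samples):
            gt = rec.samples[s]["GT"]
            if gt is None:
                gt = (None,)
            pld[i] = len(gt)
            if any(a is None for a in gt):
                cnt[i] = MISSING
            else:
                cnt[i] = sum(gt)
        rows.append(cnt)
        ploidy_rows.append(pld)
    vf.close()
    if not rows:
        return GenotypeMatrix(samples, [], chrom or "X", np.empty(0, dtype=np.int64),
                              [], np.empty((len(samples), 0), dtype=np.int8),
                              np.ones(len(samples), dtype=np.int8))
    ploidy_mat = np.stack(ploidy_rows, axis=1)  # animals x markers
    ploidy = ploidy_mat[:, 0]
    if not np.all(ploidy_mat == ploidy[:, None]):
        bad = [samples[i] for i in np.nonzero((ploidy_mat != ploidy[:, None]).any(axis=1))[0]]
        raise FormatError(f"mixed ploidy within animal(s): {bad}")
    counts = np.stack(rows, axis=1)
    return GenotypeMatrix(samples, marker_ids, chrom, np.array(positions),
                          alleles, counts, ploidy)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as uncompressed VCF 4.2.

    Haploid animals are emitted with single-allele GT fields;
    ``read_vcf(write_vcf(gm))`` reproduces ``gm`` exactly.
    """
    header = pysam.VariantHeader()
    length = int(gm.positions.max()) + 1000 if gm.n_markers else 1000
    header.add_line(f"##contig=<ID={gm.chrom},length={length}>")
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"), ("Description", "Genotype")])
    for s in gm.animal_ids:
        header.add_sample(s)
    vf = pysam.VariantFile(str(path), "w", header=header)
    for m in range(gm.n_markers):
        rec = vf.new_record(
            contig=gm.chrom,
            start=int(gm.positions[m]) - 1,
            stop=int(gm.positions[m]),
            alleles=gm.alleles[m],
            id=gm.marker_ids[m],
        )
        for i, s in enumerate(gm.animal_ids):
            c = int(gm.counts[i, m])
            k = int(gm.ploidy[i])
            if c == MISSING:
                rec.samples[s]["GT"] = (None,) * k
            elif k == 1:
                rec.samples[s]["GT"] = (c,)
            else:
                rec.samples[s]["GT"] = (0,) * (k - c) + (1,) * c
        vf.write(rec)
    vf.close()


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

REQUIRED_PHENO_COLUMNS = ("animal_id", "contemporary_group", "year_month")


def read_phenotypes(path: str | Path, trait_names: Sequence[str]) -> PhenotypeTable:
    """Read a tab-separated phenotype table.

    Requires columns ``animal_id``, ``contemporary_group``, ``year_month`` and
    one column per trait; blanks in trait columns become missing values.
    """
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str,
                                            "contemporary_group": str,
                                            "year_month": str})
    missing_cols = [c for c in (*REQUIRED_PHENO_COLUMNS, *trait_names)
                    if c not in df.columns]
    if missing_cols:
        raise FormatError(f"missing required column(s): {missing_cols}")
    for t in trait_names:
        df[t] = pd.to_numeric(df[t], errors="raise")
    df = df.set_index("animal_id")
    return PhenotypeTable(df, list(trait_names))


def write_phenotypes(tbl: PhenotypeTable, path: str | Path) -> None:
    out = tbl.data.reset_index()
    if out.columns[0] != "animal_id":
        out = out.rename(columns={out.columns[0]: "animal_id"})
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# BED painting
# ---------------------------------------------------------------------------

def write_ancestry_bed(calls, path: str | Path) -> None:
    """Serialize ancestry calls as BED6, one line per animal x window.

    Span is 0-based half-open from (first marker position - 1) to the last
    marker position; name is ``animal:class``; score is ``round(1000 * b)``
    (0 for windows with no call).  Adjacent same-class windows are not merged.
    """
    calls = list(calls)
    with open(path, "w") as fh:
        fh.write('track name=ancestry description="taurine/indicine window painting"\n')
        for c in calls:
            w = c.window
            score = 0 if c.b is None else int(round(1000 * c.b))
            strand = "."
            fh.write(f"{w.chrom}\t{w.bp_start - 1}\t{w.bp_end}\t"
                     f"{c.animal_id}:{c.cls}\t{score}\t{strand}\n")
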